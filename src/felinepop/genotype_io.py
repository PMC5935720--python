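"""Genotype data model and PLINK-format I/O.

The central container is :class:`GenotypeDataset`: a samples x markers matrix of
biallelic genotype calls (0 = homozygous ``allele_a``, 1 = heterozygous,
2 = homozygous ``allele_b``, -1 = missing) together with a marker map and a
sample-metadata table.  Readers and writers are provided for the PLINK text
(PED/MAP) and binary (BED/BIM/FAM, SNP-major) dialects, plus a tab-separated
metadata sidecar carrying population labels, pedigree links, phenotypes and
replicate-group identifiers that the PLINK formats cannot represent.

Cat chromosomes are named A1-A3, B1-B4, C1-C2, D1-D4, E1-E3, F1-F2, X and
"unknown"; numeric PLINK codes (1-18, 19 = X, 0/20 = unknown) are accepted on
input and translated to the cat names, which are stored canonically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: Cat autosomes in karyotype order.
CAT_AUTOSOMES: tuple[str, ...] = (
    "A1", "A2", "A3",
    "B1", "B2", "B3", "B4",
    "C1", "C2",
    "D1", "D2", "D3", "D4",
    "E1", "E2", "E3",
    "F1", "F2",
)
CAT_CHROMS: tuple[str, ...] = CAT_AUTOSOMES + ("X", "unknown")

_CHROM_ORDER = {c: i for i, c in enumerate(CAT_CHROMS)}

# numeric PLINK dialect: 1-18 autosomes in karyotype order, 19/X = X,
# 0 and 20 = unknown placement (the array's convention for unplaced SNPs)
_NUM_TO_CAT = {str(i + 1): c for i, c in enumerate(CAT_AUTOSOMES)}
_NUM_TO_CAT.update({"19": "X", "X": "X", "x": "X", "0": "unknown", "20": "unknown"})
_CAT_TO_NUM = {c: str(i + 1) for i, c in enumerate(CAT_AUTOSOMES)}
_CAT_TO_NUM.update({"X": "19", "unknown": "20"})

SEX_CODES = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}

MARKER_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = [
    "sample_id", "sex", "population", "sire_id", "dam_id",
    "phenotype", "replicate_group",
]


class FormatError(ValueError):
    """Raised when a genotype file violates its dialect's contract."""


def canonical_chrom(name: str) -> str:
    """Translate a chromosome label (cat name or numeric PLINK code) to the
    canonical cat name."""
    name = str(name)
    if name in _CHROM_ORDER:
        return name
    if name in _NUM_TO_CAT:
        return _NUM_TO_CAT[name]
    raise FormatError(f"unrecognized chromosome name: {name!r}")


def chrom_sort_key(chroms: Iterable[str]) -> np.ndarray:
    return np.array([_CHROM_ORDER[c] for c in chroms])


@dataclass(frozen=True)
class MarkerRecord:
    """One array marker: id, map position and the two observed alleles."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual and its metadata."""

    sample_id: str
    sex: str = "unknown"
    population: str | None = None
    sire_id: str | None = None
    dam_id: str | None = None
    phenotype: str | None = None
    replicate_group: str | None = None


@dataclass
class GenotypeDataset:
    """Samples x markers biallelic genotype matrix with marker map and
    sample metadata.

    Attributes
    ----------
    markers : pandas.DataFrame
        Columns ``snp_id, chrom, pos_bp, allele_a, allele_b``; sorted by
        (chromosome, position) after loading.
    samples : pandas.DataFrame
        Columns ``sample_id, sex, population, sire_id, dam_id, phenotype,
        replicate_group``.
    calls : numpy.ndarray of int8, shape (n_samples, n_markers)
        0/1/2 copies of ``allele_b``; -1 for a missing call.
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise FormatError(f"duplicate sample ids: {sorted(set(dup))}")
        if self.markers["snp_id"].duplicated().any():
            dup = self.markers["snp_id"][self.markers["snp_id"].duplicated()]
            raise FormatError(f"duplicate marker ids: {sorted(set(dup))}")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise FormatError("genotype codes outside {-1, 0, 1, 2}")

    def autosomal_mask(self) -> np.ndarray:
        return self.markers["chrom"].isin(CAT_AUTOSOMES).to_numpy()

    def x_mask(self) -> np.ndarray:
        return (self.markers["chrom"] == "X").to_numpy()

    def male_mask(self) -> np.ndarray:
        return (self.samples["sex"] == "male").to_numpy()

    def marker_index(self, snp_id: str) -> int:
        idx = self.markers.index[self.markers["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown marker id: {snp_id}")
        return int(idx[0])

    def sample_index(self, sample_id: str) -> int:
        idx = self.samples.index[self.samples["sample_id"] == sample_id]
        if len(idx) == 0:
            raise KeyError(f"unknown sample id: {sample_id}")
        return int(idx[0])

    # -- projection ----------------------------------------------------------

    def sort_markers(self) -> "GenotypeDataset":
        """Stable sort of markers by (chromosome order, position)."""
        order = np.lexsort(
            (self.markers["pos_bp"].to_numpy(),
             chrom_sort_key(self.markers["chrom"]))
        )
        return GenotypeDataset(
            markers=self.markers.iloc[order],
            samples=self.samples,
            calls=self.calls[:, order],
        )

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        populations: Sequence[str] | None = None,
        marker_ids: Sequence[str] | None = None,
        region: tuple[str, int, int] | None = None,
    ) -> "GenotypeDataset":
        """Order-preserving projection onto samples and/or markers.

        Parameters
        ----------
        sample_ids, populations
            Keep samples with these ids / population labels (intersection if
            both given).
        marker_ids
            Keep markers with these ids.
        region
            ``(chrom, start_bp, end_bp)``; bounds inclusive on both ends.
        """
        smask = np.ones(self.n_samples, dtype=bool)
        if sample_ids is not None:
            wanted = set(sample_ids)
            unknown = wanted - set(self.samples["sample_id"])
            if unknown:
                raise KeyError(f"unknown sample ids: {sorted(unknown)}")
            smask &= self.samples["sample_id"].isin(wanted).to_numpy()
        if populations is not None:
            wanted = set(populations)
            unknown = wanted - set(self.samples["population"].dropna())
            if unknown:
                raise KeyError(f"unknown populations: {sorted(unknown)}")
            smask &= self.samples["population"].isin(wanted).to_numpy()

        mmask = np.ones(self.n_markers, dtype=bool)
        if marker_ids is not None:
            wanted = set(marker_ids)
            unknown = wanted - set(self.markers["snp_id"])
            if unknown:
                raise KeyError(f"unknown marker ids: {sorted(unknown)}")
            mmask &= self.markers["snp_id"].isin(wanted).to_numpy()
        if region is not None:
            chrom, start, end = region
            chrom = canonical_chrom(chrom)
            mmask &= (
                (self.markers["chrom"] == chrom)
                & (self.markers["pos_bp"] >= start)
                & (self.markers["pos_bp"] <= end)
            ).to_numpy()

        return GenotypeDataset(
            markers=self.markers.loc[mmask],
            samples=self.samples.loc[smask],
            calls=self.calls[np.ix_(smask, mmask)],
        )


def _empty_samples(n: int = 0) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series([None] * n, dtype=object) for c in SAMPLE_COLUMNS})


# ---------------------------------------------------------------------------
# metadata sidecar
# ---------------------------------------------------------------------------

def read_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(SAMPLE_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise FormatError(f"metadata sidecar lacks columns: {sorted(missing_cols)}")
    meta = meta[SAMPLE_COLUMNS].replace("", None)
    meta["sex"] = meta["sex"].map(lambda s: s if s in ("male", "female") else "unknown")
    return meta


def write_metadata(samples: pd.DataFrame, path: str) -> None:
    out = samples[SAMPLE_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# PED/MAP text dialect
# ---------------------------------------------------------------------------

def _read_map(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"malformed MAP line: {line!r}")
            rows.append((parts[1], canonical_chrom(parts[0]), int(parts[3])))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp"])


def _load_ped(prefix: str) -> GenotypeDataset:
    marker_map = _read_map(prefix + ".map")
    m = len(marker_map)
    allele_a = np.array(["0"] * m, dtype=object)
    allele_b = np.array(["0"] * m, dtype=object)
    # allele-order sidecar (written by write_dataset): the PED dialect cannot
    # itself record which allele is allele_a, so honor the sidecar when
    # present; otherwise allele_a is the first allele observed in file order
    allele_path = prefix + ".alleles.tsv"
    if os.path.exists(allele_path):
        al = pd.read_csv(allele_path, sep="\t", dtype=str)
        al = al.set_index("snp_id").reindex(marker_map["snp_id"])
        if not al["allele_a"].isna().any():
            allele_a = al["allele_a"].to_numpy(dtype=object)
            allele_b = al["allele_b"].to_numpy(dtype=object)
    rows: list[list] = []
    calls_rows: list[np.ndarray] = []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"PED line has {len(parts) - 6} genotype fields, "
                    f"expected {2 * m} for {m} markers"
                )
            fid, iid, pat, mat, sex, pheno = parts[:6]
            rows.append([fid, iid, pat, mat, sex, pheno])
            g = np.empty(m, dtype=np.int8)
            al = parts[6:]
            for j in range(m):
                a1, a2 = al[2 * j], al[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    g[j] = MISSING
                    continue
                code = 0
                for a in (a1, a2):
                    if a == allele_a[j]:
                        continue
                    if allele_a[j] == "0":
                        allele_a[j] = a
                    elif a == allele_b[j]:
                        code += 1
                    elif allele_b[j] == "0":
                        allele_b[j] = a
                        code += 1
                    else:
                        raise FormatError(
                            f">2 alleles at marker {marker_map['snp_id'][j]}: "
                            f"{allele_a[j]}, {allele_b[j]}, {a}"
                        )
                g[j] = code
            calls_rows.append(g)
    markers = marker_map.assign(allele_a=allele_a, allele_b=allele_b)
    samples = _samples_from_fam(rows)
    calls = (
        np.vstack(calls_rows) if calls_rows else np.empty((0, m), dtype=np.int8)
    )
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


def _samples_from_fam(rows: list[list]) -> pd.DataFrame:
    samples = _empty_samples(len(rows))
    for i, (fid, iid, pat, mat, sex, pheno) in enumerate(rows):
        samples.loc[i, "sample_id"] = iid
        samples.loc[i, "sex"] = SEX_CODES.get(sex, "unknown")
        samples.loc[i, "population"] = None if fid == "0" else fid
        samples.loc[i, "sire_id"] = None if pat == "0" else pat
        samples.loc[i, "dam_id"] = None if mat == "0" else mat
        samples.loc[i, "phenotype"] = {"2": "case", "1": "control"}.get(pheno)
    return samples


def _fam_rows(samples: pd.DataFrame) -> list[str]:
    lines = []
    for _, s in samples.iterrows():
        pheno = {"case": "2", "control": "1"}.get(s["phenotype"], "-9")
        lines.append(" ".join([
            s["population"] or "0",
            s["sample_id"],
            s["sire_id"] or "0",
            s["dam_id"] or "0",
            _SEX_TO_PED.get(s["sex"], "0"),
            pheno,
        ]))
    return lines


def _write_map(markers: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for _, mk in markers.iterrows():
            fh.write(f"{mk['chrom']}\t{mk['snp_id']}\t0\t{mk['pos_bp']}\n")


def _write_ped(ds: GenotypeDataset, prefix: str) -> None:
    _write_map(ds.markers, prefix + ".map")
    ds.markers[["snp_id", "allele_a", "allele_b"]].to_csv(
        prefix + ".alleles.tsv", sep="\t", index=False
    )
    aa = ds.markers["allele_a"].to_numpy()
    bb = ds.markers["allele_b"].to_numpy()
    fam = _fam_rows(ds.samples)
    with open(prefix + ".ped", "w") as fh:
        for i, famline in enumerate(fam):
            geno = []
            for j, g in enumerate(ds.calls[i]):
                if g == MISSING:
                    geno.append("0 0")
                elif g == 0:
                    geno.append(f"{aa[j]} {aa[j]}")
                elif g == 1:
                    geno.append(f"{aa[j]} {bb[j]}")
                else:
                    geno.append(f"{bb[j]} {bb[j]}")
            fh.write(famline + (" " + " ".join(geno) if geno else "") + "\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM binary dialect (SNP-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes, LSB-first within a byte:
# 00 hom allele_a, 01 missing, 10 het, 11 hom allele_b
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def _load_bed(prefix: str) -> GenotypeDataset:
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "allele_a", "allele_b"],
        dtype=str,
    )
    markers = pd.DataFrame({
        "snp_id": bim["snp_id"],
        "chrom": bim["chrom"].map(canonical_chrom),
        "pos_bp": bim["pos_bp"].astype(int),
        "allele_a": bim["allele_a"],
        "allele_b": bim["allele_b"],
    })
    fam_rows = []
    with open(prefix + ".fam") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                fam_rows.append(parts[:6])
    samples = _samples_from_fam(fam_rows)
    n, m = len(samples), len(markers)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise FormatError(
                f"bad BED magic bytes {magic!r} (expected SNP-major PLINK BED)"
            )
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if raw.size != bytes_per_snp * m:
        raise FormatError(
            f"BED payload of {raw.size} bytes does not match "
            f"{m} markers x {bytes_per_snp} bytes"
        )
    raw = raw.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, LSB first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    calls = _BED_DECODE[two_bit.reshape(m, -1)[:, :n]].T
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


def _write_bed(ds: GenotypeDataset, prefix: str) -> None:
    with open(prefix + ".bim", "w") as fh:
        for _, mk in ds.markers.iterrows():
            fh.write(
                f"{mk['chrom']}\t{mk['snp_id']}\t0\t{mk['pos_bp']}"
                f"\t{mk['allele_a']}\t{mk['allele_b']}\n"
            )
    with open(prefix + ".fam", "w") as fh:
        for line in _fam_rows(ds.samples):
            fh.write(line + "\n")
    n, m = ds.n_samples, ds.n_markers
    codes = np.empty((m, n), dtype=np.uint8)
    gt = ds.calls.T
    for g, bits in _BED_ENCODE.items():
        codes[gt == g] = bits
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded.reshape(m, bytes_per_snp, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)[None, None, :]
    ).sum(axis=2).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def load_dataset(path_prefix: str, format: str = "ped") -> GenotypeDataset:
    """Load a PLINK fileset (``.ped/.map`` or ``.bed/.bim/.fam``) plus the
    optional ``.meta.tsv`` sidecar, returning markers sorted by
    (chromosome, position).
    """
    if format == "ped":
        ds = _load_ped(path_prefix)
    elif format == "bed":
        ds = _load_bed(path_prefix)
    else:
        raise ValueError(f"unknown format {format!r}; use 'ped' or 'bed'")
    sidecar = path_prefix + ".meta.tsv"
    if os.path.exists(sidecar):
        meta = read_metadata(sidecar)
        order = {sid: i for i, sid in enumerate(ds.samples["sample_id"])}
        unknown = set(meta["sample_id"]) - set(order)
        if unknown:
            raise FormatError(f"sidecar references unknown samples: {sorted(unknown)}")
        meta = meta.set_index("sample_id").reindex(ds.samples["sample_id"])
        ds = GenotypeDataset(
            markers=ds.markers,
            samples=meta.reset_index()[SAMPLE_COLUMNS],
            calls=ds.calls,
        )
    return ds.sort_markers()


def write_dataset(ds: GenotypeDataset, path_prefix: str, format: str = "ped") -> None:
    """Write a dataset in the requested PLINK dialect plus the ``.meta.tsv``
    metadata sidecar.  ``load_dataset`` after ``write_dataset`` reproduces
    calls, ids and map exactly."""
    if format == "ped":
        _write_ped(ds, path_prefix)
    elif format == "bed":
        _write_bed(ds, path_prefix)
    else:
        raise ValueError(f"unknown format {format!r}; use 'ped' or 'bed'")
    write_metadata(ds.samples, path_prefix + ".meta.tsv")


def subset(
    ds: GenotypeDataset,
    sample_ids: Sequence[str] | None = None,
    populations: Sequence[str] | None = None,
    marker_ids: Sequence[str] | None = None,
    region: tuple[str, int, int] | None = None,
) -> GenotypeDataset:
    """Functional alias for :meth:`GenotypeDataset.subset`."""
    return ds.subset(
        sample_ids=sample_ids, populations=populations,
        marker_ids=marker_ids, region=region,
    )
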