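"""Per-population diversity summaries: allele frequencies, minor-allele
frequency (MAF), observed heterozygosity and the per-individual inbreeding
coefficient F.

Allele frequencies count two alleles per female and one per hemizygous male
on the X chromosome.  Heterozygosity and F are computed over autosomal
markers only, with the small-sample expected-homozygosity correction
``2n/(2n-1)``:

    E_hom(i) = sum_j [ 1 - 2 p_j (1 - p_j) * 2n_j / (2n_j - 1) ]
    F(i)     = (O_hom(i) - E_hom(i)) / (L_i - E_hom(i))

where the sum runs over individual *i*'s non-missing autosomal markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass(frozen=True)
class PopulationSummary:
    """Table-1-style summary line for one population."""

    population: str
    n: int
    pct_monomorphic: float
    mean_maf: float
    mean_ho: float
    mean_f: float
    n_polymorphic: int


def allele_stats(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-marker allele_b frequency, MAF, monomorphic flag and the number of
    counted alleles.

    Missing calls are ignored.  On X markers, males contribute a single
    allele (their hemizygous call); heterozygous male X calls are a QC
    signal, not a valid hemizygous genotype, and are excluded from counting.
    Markers with zero counted alleles get NaN frequencies.
    """
    calls = ds.calls
    nonmiss = calls != MISSING
    x = ds.x_mask()
    male = ds.male_mask()

    copies = np.where(nonmiss, 2, 0)                   # alleles contributed
    b_alleles = np.where(nonmiss, calls, 0).astype(float)
    if x.any() and male.any():
        mx = np.ix_(male, np.flatnonzero(x))
        male_calls = calls[mx]
        valid = (male_calls == 0) | (male_calls == 2)  # het males dropped
        copies[mx] = np.where(valid, 1, 0)
        b_alleles[mx] = np.where(valid, male_calls // 2, 0)

    n_alleles = copies.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_alleles > 0, b_alleles.sum(axis=0) / n_alleles, np.nan)
    maf = np.minimum(freq_b, 1.0 - freq_b)
    return pd.DataFrame(
        {
            "freq_b": freq_b,
            "maf": maf,
            "monomorphic": maf == 0.0,
            "n_alleles": n_alleles,
        },
        index=pd.Index(ds.markers["snp_id"], name="snp_id"),
    )


def heterozygosity_and_f(
    ds: GenotypeDataset, frequencies: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-individual observed homozygosity, expected homozygosity, observed
    heterozygosity and inbreeding coefficient F over autosomal markers.

    ``frequencies`` must come from :func:`allele_stats` on the same sample
    set (it is recomputed if omitted).  F is NaN when ``L - E_hom`` is zero.
    """
    auto = ds.autosomal_mask()
    sub = ds.calls[:, auto]
    if frequencies is None:
        frequencies = allele_stats(ds)
    p = frequencies["freq_b"].to_numpy()[auto]
    n_dip = frequencies["n_alleles"].to_numpy()[auto] / 2.0  # diploid count at marker

    nonmiss = sub != MISSING
    het = sub == 1
    # per-marker expected homozygosity with 2n/(2n-1) correction
    two_n = 2.0 * n_dip
    with np.errstate(invalid="ignore", divide="ignore"):
        e_hom_marker = 1.0 - 2.0 * p * (1.0 - p) * np.where(
            two_n > 1, two_n / (two_n - 1.0), np.nan
        )
    usable = nonmiss & np.isfinite(e_hom_marker)[None, :]

    L = usable.sum(axis=1).astype(float)
    het_count = (het & usable).sum(axis=1).astype(float)
    o_hom = L - het_count
    e_hom = np.where(usable, e_hom_marker[None, :], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_o = np.where(L > 0, het_count / L, np.nan)
        denom = L - e_hom
        f = np.where(denom != 0, (o_hom - e_hom) / denom, np.nan)
    return pd.DataFrame(
        {"L": L, "O_hom": o_hom, "E_hom": e_hom, "H_O": h_o, "F": f},
        index=pd.Index(ds.samples["sample_id"], name="sample_id"),
    )


def population_summaries(
    ds: GenotypeDataset, mean_maf_mode: str = "pooled"
) -> pd.DataFrame:
    """Per-population summary table (one row per population label).

    Statistics are recomputed on each population's samples alone.  The
    package also exposes two dataset-level MAF aggregations via
    :func:`mean_maf`: pooling all samples before averaging per-marker MAF
    versus averaging the per-population means.
    """
    rows = []
    for pop, grp in ds.samples.groupby("population", sort=True, dropna=True):
        if len(grp) == 0:
            warnings.warn(f"population {pop} has no samples; omitted")
            continue
        sub = ds.subset(sample_ids=grp["sample_id"].tolist())
        stats = allele_stats(sub)
        informative = stats["maf"].notna()
        hetf = heterozygosity_and_f(sub, stats)
        n_poly = int((stats["maf"] > 0).sum())
        n_info = int(informative.sum())
        rows.append(PopulationSummary(
            population=pop,
            n=len(grp),
            pct_monomorphic=(
                100.0 * (n_info - n_poly) / n_info if n_info else np.nan
            ),
            mean_maf=float(stats.loc[informative, "maf"].mean()),
            mean_ho=float(hetf["H_O"].mean()),
            mean_f=float(hetf["F"].mean()),
            n_polymorphic=n_poly,
        ))
    frame = pd.DataFrame([r.__dict__ for r in rows])
    return frame.set_index("population") if len(frame) else frame


def mean_maf(ds: GenotypeDataset, mode: str = "pooled") -> float:
    """Dataset-level mean MAF.

    ``pooled``: pool all samples, then average per-marker MAF (the headline
    aggregation).  ``population_mean``: mean of the per-population mean MAFs
    (the alternative summary reported for cross-population comparisons).
    """
    if mode == "pooled":
        stats = allele_stats(ds)
        return float(stats["maf"].mean())
    if mode == "population_mean":
        table = population_summaries(ds)
        return float(table["mean_maf"].mean())
    raise ValueError(f"unknown mode {mode!r}")
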