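"""Synthetic breed-panel generator.

Emulates the statistical structure of a multi-breed SNP-array dataset: a
shared ancestral haplotype pool from which each population draws ``2H``
founder haplotypes (so populations share alleles but differ in drift), then
``G`` non-overlapping generations of random mating with Poisson-recombination
gametes.  Small founder pools produce long-range linkage disequilibrium and
low diversity; large pools approach the ancestral allele-frequency spectrum —
the diversity gradient observed across real cat breeds versus random-bred
cats.

The X chromosome is simulated as one linkage group with a terminal
pseudoautosomal (PAR) segment in which males are diploid; outside the PAR,
males are hemizygous and their genotypes are emitted homozygous-coded.
Phenotypes for autosomal-recessive and X-linked traits, genotyping artifacts
(missingness, miscalls), replicate samples and parent-parent-offspring trios
are layered on top, with the simulation truth returned for QC validation.

All randomness flows from a single integer seed; a fixed seed yields a
byte-identical dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, chrom_sort_key

#: Approximate cat chromosome sizes (Mb) used to apportion markers when a
#: per-chromosome count map is not supplied.
CHROM_MB = {
    "A1": 239, "A2": 169, "A3": 142,
    "B1": 205, "B2": 154, "B3": 148, "B4": 144,
    "C1": 222, "C2": 161,
    "D1": 116, "D2": 89, "D3": 96, "D4": 96,
    "E1": 63, "E2": 64, "E3": 43,
    "F1": 68, "F2": 82,
    "X": 126,
}

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


def default_marker_counts(total: int = 62897) -> dict[str, int]:
    """Apportion ``total`` markers across the 18 autosomes plus X in
    proportion to chromosome size (the real array's ~63K design)."""
    sizes = np.array([CHROM_MB[c] for c in CHROM_MB])
    counts = np.maximum(1, np.round(total * sizes / sizes.sum()).astype(int))
    return dict(zip(CHROM_MB, counts))


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: census, founder pool and demographic history.

    The demographic model is a breed founding event: ``founder_pool_size`` (H)
    diploid founders drawn from the shared ancestral pool, a bottleneck of
    ``bottleneck_generations`` at census 2H (drift builds breed-specific LD in
    proportion to 1/H), then expansion to ``expansion_census`` for the
    remaining generations (recombination erodes LD without regenerating it,
    and sampled individuals are only distantly related).  The default of 60
    total generations matches breeds founded on the order of a century ago at
    a feline generation time of a few years.
    """

    label: str
    n_samples: int
    founder_pool_size: int       # H diploid founders from the ancestral pool
    generations: int = 60        # G non-overlapping random-mating generations
    bottleneck_generations: int = 5
    expansion_census: int = 300


@dataclass(frozen=True)
class TraitSpec:
    """A monogenic trait tied to one simulated marker.

    ``autosomal_recessive``: affected iff homozygous for ``allele_b`` at the
    causal SNP.  ``x_linked``: hemizygous carrier males and homozygous females
    are affected.  ``on_array=False`` drops the causal SNP from the emitted
    marker set after phenotypes are assigned (the indirect-mapping scenario).
    """

    mode: str               # "autosomal_recessive" | "x_linked"
    causal_snp: str
    on_array: bool = True
    penetrance: float = 1.0


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic panel.

    Defaults reproduce the array's genotyping regime: mean inter-marker
    spacing 37,741 bp, ~1% missing calls, 0.07% per-genotype miscalls (so a
    replicate pair differs at ~0.14% of compared genotypes), 86 trios and 20
    replicated samples.  Marker counts default to the full ~63K array scaled
    by chromosome size; desk-scale runs pass smaller maps.
    """

    populations: list[PopulationSpec] = field(default_factory=list)
    n_snps_per_chrom: dict[str, int] | None = None
    spacing_bp: float = 37_741.0
    recombination_rate: float = 1e-8   # per bp per meiosis (~1 cM/Mb)
    missing_rate: float = 0.01
    error_rate: float = 0.0007
    # small subpopulations of systematically poor assays, as on real arrays:
    # ~1% of markers fail the 10%-missingness screen, and a few per mille
    # miscall often enough to fail the trio transmission screen
    bad_marker_rate: float = 0.01
    bad_marker_missing_rate: float = 0.20
    error_marker_rate: float = 0.004
    error_marker_miscall_rate: float = 0.20
    n_trios: int = 86
    n_replicate_pairs: int = 20
    par_fraction: float = 0.02         # terminal X fraction where males are diploid
    trait_specs: list[TraitSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for p in self.populations:
            if p.founder_pool_size < 1:
                raise ConfigError(f"population {p.label}: founder pool H must be >= 1")
            if p.n_samples < 1 or p.generations < 1:
                raise ConfigError(f"population {p.label}: invalid census/generations")
        for r in ("recombination_rate", "missing_rate", "error_rate", "par_fraction"):
            v = getattr(self, r)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{r} must be in [0, 1], got {v}")

    def chrom_counts(self) -> dict[str, int]:
        return dict(self.n_snps_per_chrom or default_marker_counts())


# ---------------------------------------------------------------------------
# marker map and ancestral pool
# ---------------------------------------------------------------------------

def _build_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, n in cfg.chrom_counts().items():
        gaps = rng.exponential(cfg.spacing_bp, size=n)
        pos = np.cumsum(gaps).astype(np.int64) + 1
        pos = np.unique(pos)
        while len(pos) < n:  # collisions after rounding: re-draw the deficit
            extra = pos[-1] + np.cumsum(
                rng.exponential(cfg.spacing_bp, size=n - len(pos))
            ).astype(np.int64) + 1
            pos = np.unique(np.concatenate([pos, extra]))
        alleles = _BASES[
            np.array([rng.choice(4, size=2, replace=False) for _ in range(n)])
        ]
        for k in range(n):
            rows.append(
                (f"s{chrom}_{k:05d}", chrom, int(pos[k]),
                 alleles[k, 0], alleles[k, 1])
            )
    markers = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"]
    )
    order = np.lexsort((markers["pos_bp"], chrom_sort_key(markers["chrom"])))
    return markers.iloc[order].reset_index(drop=True)


def _ancestral_freqs(m: int, rng: np.random.Generator) -> np.ndarray:
    # U-shaped Beta(0.8, 0.8) spectrum truncated to pool MAF >= 0.01
    p = rng.beta(0.8, 0.8, size=m)
    while True:
        bad = (p < 0.01) | (p > 0.99)
        if not bad.any():
            return p
        p[bad] = rng.beta(0.8, 0.8, size=int(bad.sum()))


def _par_mask(markers: pd.DataFrame, par_fraction: float) -> np.ndarray:
    """Terminal (p-arm) segment of X where males are diploid."""
    mask = np.zeros(len(markers), dtype=bool)
    on_x = (markers["chrom"] == "X").to_numpy()
    if on_x.any() and par_fraction > 0:
        pos = markers.loc[on_x, "pos_bp"].to_numpy()
        cutoff = pos.min() + par_fraction * (pos.max() - pos.min())
        mask[on_x] = pos <= cutoff
    return mask


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _gamete(
    haps: np.ndarray,          # (2, m_chrom) parental haplotypes
    pos: np.ndarray,           # marker positions on this chromosome
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete: Poisson number of crossovers placed uniformly;
    a crossover exactly on a marker leaves that marker on the left segment."""
    span = int(pos[-1] - pos[0]) if len(pos) > 1 else 0
    start = rng.integers(2)
    n_xo = rng.poisson(rate * span) if span > 0 else 0
    if n_xo == 0:
        return haps[start].copy()
    xo = rng.integers(pos[0], pos[-1], size=n_xo) if span > 0 else np.empty(0)
    k = np.searchsorted(np.sort(xo), pos, side="left")  # crossovers strictly left
    return haps[(start + k) % 2, np.arange(len(pos))].copy()


class _Phase:
    """Hidden per-individual haplotypes kept alongside a simulated panel so
    trios can be bred by true Mendelian transmission."""

    def __init__(
        self,
        haplotypes: np.ndarray,   # (n, 2, m) uint8; [:,0]=paternal, [:,1]=maternal
        sexes: np.ndarray,        # "male"/"female"
        markers: pd.DataFrame,
        par: np.ndarray,
    ) -> None:
        self.haplotypes = haplotypes
        self.sexes = sexes
        self.markers = markers
        self.par = par
        self.x_nonpar = (markers["chrom"] == "X").to_numpy() & ~par
        self.pos = markers["pos_bp"].to_numpy()
        self.chrom_slices = {
            c: np.flatnonzero((markers["chrom"] == c).to_numpy())
            for c in markers["chrom"].unique()
        }

    def make_gamete(self, i: int, rate: float, rng: np.random.Generator) -> np.ndarray:
        g = np.empty(self.haplotypes.shape[2], dtype=np.uint8)
        for c, idx in self.chrom_slices.items():
            g[idx] = _gamete(self.haplotypes[i][:, idx], self.pos[idx], rate, rng)
        return g

    def child(
        self, sire: int, dam: int, sex: str,
        rate: float, rng: np.random.Generator,
    ) -> np.ndarray:
        hp = self.make_gamete(sire, rate, rng)
        hm = self.make_gamete(dam, rate, rng)
        haps = np.stack([hp, hm])
        if sex == "male":
            # hemizygous X: the son's only X is maternal; his "paternal" copy
            # outside the PAR mirrors it (the PAR segment arrives via Y-PAR)
            haps[0, self.x_nonpar] = haps[1, self.x_nonpar]
        return haps


def _emit_genotypes(haps: np.ndarray) -> np.ndarray:
    """Diploid genotype codes (copies of allele_b) from a (n, 2, m) phase."""
    return (haps[:, 0, :] + haps[:, 1, :]).astype(np.int8)


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def _assign_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    sexes = np.where(rng.random(n) < 0.5, "male", "female").astype(object)
    if n >= 2:  # guarantee both sexes so mating is always possible
        if (sexes == "male").all():
            sexes[rng.integers(n)] = "female"
        elif (sexes == "female").all():
            sexes[rng.integers(n)] = "male"
    return sexes


def _next_generation(
    phase: _Phase, n_next: int, rate: float, rng: np.random.Generator
) -> _Phase:
    """One generation of random mating, vectorized over children (the
    common crossover-free gametes are gathered in bulk)."""
    child_sexes = _assign_sexes(n_next, rng)
    males = np.flatnonzero(phase.sexes == "male")
    females = np.flatnonzero(phase.sexes == "female")
    if len(males) == 0 or len(females) == 0:  # single-founder selfing
        males = females = np.arange(len(phase.sexes))
    sires = rng.choice(males, size=n_next)
    dams = rng.choice(females, size=n_next)
    m = phase.haplotypes.shape[2]
    haps = np.empty((n_next, 2, m), dtype=np.uint8)
    for idx in phase.chrom_slices.values():
        pos = phase.pos[idx]
        span = int(pos[-1] - pos[0]) if len(pos) > 1 else 0
        for side, parents in ((0, sires), (1, dams)):
            par_haps = phase.haplotypes[parents][:, :, idx]  # (n, 2, mc)
            starts = rng.integers(2, size=n_next)
            n_xo = rng.poisson(rate * span, size=n_next) if span > 0 else \
                np.zeros(n_next, dtype=np.int64)
            gam = par_haps[np.arange(n_next), starts]
            for i in np.flatnonzero(n_xo > 0):
                xo = np.sort(rng.integers(pos[0], pos[-1], size=n_xo[i]))
                k = np.searchsorted(xo, pos, side="left")
                gam[i] = par_haps[i, (starts[i] + k) % 2, np.arange(len(pos))]
            haps[:, side, idx] = gam
    sons = child_sexes == "male"
    if sons.any() and phase.x_nonpar.any():
        hemi = np.ix_(sons, [0], phase.x_nonpar)
        haps[hemi] = haps[np.ix_(sons, [1], phase.x_nonpar)]
    return _Phase(haps, child_sexes, phase.markers, phase.par)


def _breed_population(
    spec: PopulationSpec,
    freqs: np.ndarray,
    markers: pd.DataFrame,
    par: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> _Phase:
    m = len(markers)
    H = spec.founder_pool_size
    founders = (rng.random((H, 2, m)) < freqs).astype(np.uint8)
    sexes = _assign_sexes(H, rng)
    phase = _Phase(founders, sexes, markers, par)
    for i in np.flatnonzero(sexes == "male"):
        phase.haplotypes[i, 0, phase.x_nonpar] = phase.haplotypes[i, 1, phase.x_nonpar]

    G = spec.generations
    bottleneck = max(2, 2 * H)
    expanded = max(spec.expansion_census, spec.n_samples)
    for g in range(G):
        if g == G - 1:
            n_next = spec.n_samples
        elif g < spec.bottleneck_generations:
            n_next = bottleneck
        else:
            n_next = expanded
        phase = _next_generation(phase, n_next, rate, rng)
    return phase


def simulate_panel(cfg: SimConfig) -> GenotypeDataset:
    """Simulate the multi-population breed panel (clean genotypes, no
    artifacts).  The returned dataset carries hidden phase information used
    by :func:`simulate_trios`."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    markers = _build_map(cfg, rng)
    freqs = _ancestral_freqs(len(markers), rng)
    par = _par_mask(markers, cfg.par_fraction)

    sample_rows = []
    calls = []
    phases: dict[str, _Phase] = {}
    for spec in cfg.populations:
        phase = _breed_population(spec, freqs, markers, par, cfg.recombination_rate, rng)
        phases[spec.label] = phase
        calls.append(_emit_genotypes(phase.haplotypes))
        for i in range(spec.n_samples):
            sample_rows.append({
                "sample_id": f"{spec.label}_{i:04d}",
                "sex": phase.sexes[i],
                "population": spec.label,
                "sire_id": None, "dam_id": None,
                "phenotype": None, "replicate_group": None,
            })

    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "sex", "population", "sire_id", "dam_id",
                 "phenotype", "replicate_group"],
    )
    ds = GenotypeDataset(
        markers=markers,
        samples=samples,
        calls=np.vstack(calls) if calls else np.empty((0, len(markers)), np.int8),
    )
    ds._phase = phases          # type: ignore[attr-defined]
    ds._par_mask = par          # type: ignore[attr-defined]
    ds._ancestral_freqs = freqs  # type: ignore[attr-defined]
    return ds


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

def simulate_trios(
    cfg: SimConfig, panel: GenotypeDataset
) -> tuple[GenotypeDataset, list[tuple[str, str, str]]]:
    """Breed ``cfg.n_trios`` offspring from panel parents by Mendelian
    transmission with recombination; returns the extended dataset and the
    (sire, dam, child) id triples.

    Sires are sampled from panel males and dams from panel females (parents
    may repeat, as in a multi-generational colony); sons receive their dam's
    X haplotype only.
    """
    phases = getattr(panel, "_phase", None)
    if phases is None:
        raise ValueError("panel lacks phase information; use simulate_panel output")
    rng = np.random.default_rng(cfg.seed + 1_000_003)

    pop_of, idx_in_pop, sex_of = {}, {}, {}
    offset = 0
    for label, phase in phases.items():
        n = phase.haplotypes.shape[0]
        for i in range(n):
            sid = panel.samples["sample_id"].iloc[offset + i]
            pop_of[sid], idx_in_pop[sid], sex_of[sid] = label, i, phase.sexes[i]
        offset += n

    sires = [s for s in pop_of if sex_of[s] == "male"]
    dams = [s for s in pop_of if sex_of[s] == "female"]
    if not sires or not dams:
        raise ConfigError("panel lacks a male/female pair for trio breeding")

    trio_list: list[tuple[str, str, str]] = []
    child_rows, child_calls = [], []
    for t in range(cfg.n_trios):
        sire = sires[rng.integers(len(sires))]
        dam = dams[rng.integers(len(dams))]
        sex = "male" if rng.random() < 0.5 else "female"
        # cross-population matings allowed: the colony is cross-bred
        ph_s, ph_d = phases[pop_of[sire]], phases[pop_of[dam]]
        hp = ph_s.make_gamete(idx_in_pop[sire], cfg.recombination_rate, rng)
        hm = ph_d.make_gamete(idx_in_pop[dam], cfg.recombination_rate, rng)
        haps = np.stack([hp, hm])
        if sex == "male":
            haps[0, ph_s.x_nonpar] = haps[1, ph_s.x_nonpar]
        child_id = f"trio{t:03d}_child"
        trio_list.append((sire, dam, child_id))
        child_rows.append({
            "sample_id": child_id, "sex": sex, "population": "Colony",
            "sire_id": sire, "dam_id": dam,
            "phenotype": None, "replicate_group": None,
        })
        child_calls.append((haps[0] + haps[1]).astype(np.int8))

    samples = pd.concat(
        [panel.samples, pd.DataFrame(child_rows)], ignore_index=True
    )
    calls = np.vstack([panel.calls] + [np.array(child_calls, dtype=np.int8)]) \
        if child_calls else panel.calls
    out = GenotypeDataset(markers=panel.markers, samples=samples, calls=calls)
    for attr in ("_phase", "_par_mask", "_ancestral_freqs"):
        setattr(out, attr, getattr(panel, attr, None))
    return out, trio_list


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def assign_trait(
    panel: GenotypeDataset, spec: TraitSpec, seed: int = 0
) -> pd.Series:
    """Phenotype labels ("case"/"control", None where the causal call is
    missing) under the trait model; penetrance thins cases at random."""
    j = panel.marker_index(spec.causal_snp)
    if spec.mode == "x_linked" and panel.markers["chrom"].iloc[j] != "X":
        raise ConfigError(f"x_linked causal SNP {spec.causal_snp} is not on X")
    g = panel.calls[:, j]
    if not np.isin(g, (1, 2)).any():
        warnings.warn(
            f"causal SNP {spec.causal_snp} is monomorphic; all samples unaffected"
        )
    rng = np.random.default_rng(seed)
    if spec.mode in ("autosomal_recessive", "x_linked"):
        # x_linked: hemizygous carrier males are homozygous-coded (2), and
        # affected females need two copies, so both reduce to code 2
        carrier = g == 2
    else:
        raise ConfigError(f"unknown trait mode {spec.mode!r}")
    affected = carrier & (rng.random(len(g)) < spec.penetrance)
    labels = np.where(affected, "case", "control").astype(object)
    labels[g == MISSING] = None
    return pd.Series(labels, index=panel.samples["sample_id"], name="phenotype")


# ---------------------------------------------------------------------------
# artifacts and replicates
# ---------------------------------------------------------------------------

def inject_artifacts(panel: GenotypeDataset, cfg: SimConfig) -> GenotypeDataset:
    """Apply i.i.d. per-genotype miscalls then missingness, and append
    ``cfg.n_replicate_pairs`` duplicated samples with independent artifact
    draws and a shared ``replicate_group`` label."""
    rng = np.random.default_rng(cfg.seed + 2_000_003)
    samples = panel.samples.copy()
    calls = panel.calls.copy()

    n_rep = min(cfg.n_replicate_pairs, panel.n_samples)
    if n_rep:
        chosen = rng.choice(panel.n_samples, size=n_rep, replace=False)
        rep_rows, rep_calls = [], []
        for k, i in enumerate(chosen):
            row = samples.iloc[i].copy()
            samples.loc[i, "replicate_group"] = f"rep{k:02d}"
            row["sample_id"] = row["sample_id"] + "_rep"
            row["replicate_group"] = f"rep{k:02d}"
            rep_rows.append(row)
            rep_calls.append(panel.calls[i].copy())
        samples = pd.concat([samples, pd.DataFrame(rep_rows)], ignore_index=True)
        calls = np.vstack([calls, np.array(rep_calls, dtype=np.int8)])

    nonmiss = calls != MISSING
    if cfg.error_rate > 0:
        err = (rng.random(calls.shape) < cfg.error_rate) & nonmiss
        # miscall: uniform over the two other genotype codes
        shift = rng.integers(1, 3, size=calls.shape)
        calls[err] = (calls[err] + shift[err]) % 3
    errm = np.zeros(calls.shape[1], dtype=bool)
    if cfg.error_rate > 0 and cfg.error_marker_rate > 0:
        errm = rng.random(calls.shape[1]) < cfg.error_marker_rate
        hit = (rng.random(calls.shape) < cfg.error_marker_miscall_rate) & nonmiss
        shift = rng.integers(1, 3, size=calls.shape)
        sel = hit & errm[None, :]
        calls[sel] = (calls[sel] + shift[sel]) % 3
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING
    bad = np.zeros(calls.shape[1], dtype=bool)
    if cfg.missing_rate > 0 and cfg.bad_marker_rate > 0:
        bad = rng.random(calls.shape[1]) < cfg.bad_marker_rate
        drop = rng.random(calls.shape) < cfg.bad_marker_missing_rate
        calls[:, bad] = np.where(drop[:, bad], MISSING, calls[:, bad])

    out = GenotypeDataset(markers=panel.markers, samples=samples, calls=calls)
    out._bad_markers = panel.markers["snp_id"].to_numpy()[bad].tolist()  # type: ignore[attr-defined]
    out._error_markers = panel.markers["snp_id"].to_numpy()[errm].tolist()  # type: ignore[attr-defined]
    for attr in ("_phase", "_par_mask", "_ancestral_freqs"):
        setattr(out, attr, getattr(panel, attr, None))
    return out


def inject_marker_errors(
    ds: GenotypeDataset, snp_id: str, rate: float, seed: int = 0
) -> GenotypeDataset:
    """Corrupt one marker with miscalls at the given per-genotype rate
    (targeted-error scenario for Mendelian-flagging validation)."""
    rng = np.random.default_rng(seed)
    j = ds.marker_index(snp_id)
    calls = ds.calls.copy()
    col = calls[:, j]
    hit = (rng.random(len(col)) < rate) & (col != MISSING)
    col[hit] = (col[hit] + rng.integers(1, 3, size=int(hit.sum()))) % 3
    calls[:, j] = col
    out = GenotypeDataset(markers=ds.markers, samples=ds.samples, calls=calls)
    for attr in ("_phase", "_par_mask", "_ancestral_freqs"):
        setattr(out, attr, getattr(ds, attr, None))
    return out


# ---------------------------------------------------------------------------
# one-call study assembly
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimConfig) -> tuple[GenotypeDataset, dict]:
    """Full study build: panel + trios + trait phenotypes + artifacts and
    replicates.  Returns the dataset and a truth record (causal SNPs, trio
    list, PAR marker ids, replicate pairs)."""
    panel = simulate_panel(cfg)
    ds, trios = simulate_trios(cfg, panel) if cfg.n_trios else (panel, [])

    # the dataset's phenotype column carries the first trait; additional
    # traits are re-assigned on demand via assign_trait
    if cfg.trait_specs:
        labels = assign_trait(ds, cfg.trait_specs[0], seed=cfg.seed + 3_000_003)
        ds.samples["phenotype"] = labels.reindex(ds.samples["sample_id"]).to_numpy()

    off_array = [t.causal_snp for t in cfg.trait_specs if not t.on_array]
    if off_array:
        keep = ~ds.markers["snp_id"].isin(off_array).to_numpy()
        ds = GenotypeDataset(
            markers=ds.markers.loc[keep], samples=ds.samples,
            calls=ds.calls[:, keep],
        )

    ds = inject_artifacts(ds, cfg)
    par = _par_mask(ds.markers, cfg.par_fraction)
    rep = ds.samples.dropna(subset=["replicate_group"])
    pairs = [
        tuple(grp["sample_id"]) for _, grp in rep.groupby("replicate_group")
        if len(grp) == 2
    ]
    truth = {
        "causal_snps": {t.causal_snp: t.mode for t in cfg.trait_specs},
        "trios": trios,
        "par_markers": ds.markers["snp_id"].to_numpy()[par].tolist(),
        "replicate_pairs": pairs,
        "bad_markers": getattr(ds, "_bad_markers", []),
        "error_markers": getattr(ds, "_error_markers", []),
        "seed": cfg.seed,
    }
    return ds, truth
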