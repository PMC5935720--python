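"""Case-control association, max-T permutation, genomic inflation,
case-shared haplotype blocks and the LD-based sample-size calculation.

The allelic test is the 1-df Pearson chi-square on the 2x2 allele-count
table (no continuity correction); on X markers males contribute one allele
and females two.  The stratified test is the Cochran-Mantel-Haenszel (CMH)
statistic over 2x2xK allele-count tables, which for K = 1 equals
((N-1)/N) times the allelic chi-square.  Genome-wide multiple-testing
correction is max-T: case/control labels are permuted (within strata for the
CMH test, optionally within sex for X-linked traits), the maximum statistic
over markers is recorded per permutation, and the corrected p-value is the
empirical tail probability (1 + #{max_r >= observed}) / (R + 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import MISSING, GenotypeDataset
from .popstats import allele_stats

#: median of the 1-df chi-square distribution (lambda denominator)
CHI2_MEDIAN_1DF = float(sps.chi2.ppf(0.5, 1))


@dataclass
class AssocResult:
    """Per-marker association statistics plus run-level summaries."""

    table: pd.DataFrame        # snp_id, chrom, pos_bp, chi2, p_raw[, p_genome]
    lambda_gc: float
    n_cases: int
    n_controls: int
    test: str                  # "allelic" | "cmh"
    n_permutations: int = 0
    skipped: list[str] = field(default_factory=list)  # zero-margin markers


@dataclass(frozen=True)
class HaplotypeBlock:
    """Contiguous run of identical case-shared homozygosity around a causal
    variant (or population-fixed run of homozygosity)."""

    chrom: str
    start_bp: int
    end_bp: int
    anchor_snp: str
    kind: str                  # "case_shared" | "fixed_roh"
    n_markers: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class PowerEstimate:
    """Indirect-association sample-size inflation n / r2."""

    n_current: int
    r2_link: float
    n_required: int


# ---------------------------------------------------------------------------
# allele-count machinery
# ---------------------------------------------------------------------------

def _allele_contributions(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample, per-marker allele_b copies and total allele copies.

    Autosomal calls contribute (g, 2); male X calls contribute (g/2, 1) and
    heterozygous male X calls contribute nothing (invalid hemizygous call).
    """
    calls = ds.calls
    nonmiss = calls != MISSING
    b = np.where(nonmiss, calls, 0).astype(np.float64)
    tot = np.where(nonmiss, 2.0, 0.0)
    x = ds.x_mask()
    male = ds.male_mask()
    if x.any() and male.any():
        mx = np.ix_(male, np.flatnonzero(x))
        g = calls[mx]
        valid = (g == 0) | (g == 2)
        b[mx] = np.where(valid, g / 2.0, 0.0)
        tot[mx] = np.where(valid, 1.0, 0.0)
    return b, tot


def _phenotype_vector(
    ds: GenotypeDataset, case_labels: pd.Series | None
) -> np.ndarray:
    """+1 case, 0 control, -1 unphenotyped, aligned to dataset sample order."""
    if case_labels is None:
        case_labels = pd.Series(
            ds.samples["phenotype"].to_numpy(),
            index=ds.samples["sample_id"].to_numpy(),
        )
    aligned = case_labels.reindex(ds.samples["sample_id"].to_numpy())
    y = np.full(ds.n_samples, -1, dtype=np.int8)
    y[(aligned == "case").to_numpy()] = 1
    y[(aligned == "control").to_numpy()] = 0
    return y


def _chi2_2x2(
    b_case: np.ndarray, t_case: np.ndarray,
    b_all: np.ndarray, t_all: np.ndarray,
) -> np.ndarray:
    """Pearson 1-df chi-square from allele counts; NaN on zero margins."""
    a = b_case                      # case allele_b
    b = t_case - b_case             # case allele_a
    c = b_all - b_case              # control allele_b
    d = (t_all - t_case) - c        # control allele_a
    n = t_all
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, np.nan)
    return chi2


def _qc_filter(
    ds: GenotypeDataset, y: np.ndarray,
    maf_min: float, call_rate_min: float,
) -> tuple[GenotypeDataset, np.ndarray]:
    """Marker/sample filters applied before association: samples and markers
    with call rate >= 90% and markers with MAF >= 0.05 (computed on the
    phenotyped samples)."""
    phen = y >= 0
    sub = ds.subset(sample_ids=ds.samples["sample_id"].to_numpy()[phen].tolist())
    y = y[phen]
    nonmiss = sub.calls != MISSING
    keep_s = nonmiss.mean(axis=1) >= call_rate_min
    if not keep_s.all():
        sub = sub.subset(
            sample_ids=sub.samples["sample_id"].to_numpy()[keep_s].tolist()
        )
        y = y[keep_s]
    stats_ = allele_stats(sub)
    keep_m = (
        ((sub.calls != MISSING).mean(axis=0) >= call_rate_min)
        & (np.nan_to_num(stats_["maf"].to_numpy()) >= maf_min)
    )
    sub = GenotypeDataset(
        markers=sub.markers.loc[keep_m], samples=sub.samples,
        calls=sub.calls[:, keep_m],
    )
    return sub, y


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def allelic_association(
    ds: GenotypeDataset,
    case_labels: pd.Series | None = None,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
) -> AssocResult:
    """Per-marker allelic chi-square association (cases vs controls)."""
    y = _phenotype_vector(ds, case_labels)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("association requires at least one case and one control")
    sub, y = _qc_filter(ds, y, maf_min, call_rate_min)
    b, tot = _allele_contributions(sub)
    case = (y == 1).astype(np.float64)
    chi2 = _chi2_2x2(case @ b, case @ tot, b.sum(axis=0), tot.sum(axis=0))
    p_raw = sps.chi2.sf(chi2, 1)
    table = pd.DataFrame({
        "snp_id": sub.markers["snp_id"].to_numpy(),
        "chrom": sub.markers["chrom"].to_numpy(),
        "pos_bp": sub.markers["pos_bp"].to_numpy(),
        "chi2": chi2, "p_raw": p_raw,
    })
    skipped = table.loc[table["chi2"].isna(), "snp_id"].tolist()
    return AssocResult(
        table=table,
        lambda_gc=genomic_inflation(chi2),
        n_cases=int((y == 1).sum()), n_controls=int((y == 0).sum()),
        test="allelic", skipped=skipped,
    )


def _cmh_terms(
    b: np.ndarray, tot: np.ndarray, case: np.ndarray,
    strata_codes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum over strata of (a_k - E[a_k]) and Var(a_k) per marker; strata
    with no cases or no controls contribute nothing."""
    num = 0.0
    den = 0.0
    for s in np.unique(strata_codes):
        rows = strata_codes == s
        cs = case[rows]
        if cs.sum() == 0 or (1 - cs).sum() == 0:
            continue
        bk, tk = b[rows], tot[rows]
        a = cs @ bk
        r1 = cs @ tk
        n = tk.sum(axis=0)
        c1 = bk.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            e = np.where(n > 0, r1 * c1 / n, 0.0)
            v = np.where(
                n > 1,
                r1 * (n - r1) * c1 * (n - c1) / (n * n * (n - 1)),
                0.0,
            )
        num = num + (a - e)
        den = den + v
    return np.asarray(num), np.asarray(den)


def cmh_association(
    ds: GenotypeDataset,
    case_labels: pd.Series | None = None,
    strata: pd.Series | None = None,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
) -> AssocResult:
    """Cochran-Mantel-Haenszel 2x2xK association stratified on population
    labels (default) or a supplied sample->stratum map."""
    y = _phenotype_vector(ds, case_labels)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("association requires at least one case and one control")
    sub, y = _qc_filter(ds, y, maf_min, call_rate_min)
    codes = _strata_codes(sub, strata)
    b, tot = _allele_contributions(sub)
    case = (y == 1).astype(np.float64)
    num, den = _cmh_terms(b, tot, case, codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(den > 0, num ** 2 / den, np.nan)
    table = pd.DataFrame({
        "snp_id": sub.markers["snp_id"].to_numpy(),
        "chrom": sub.markers["chrom"].to_numpy(),
        "pos_bp": sub.markers["pos_bp"].to_numpy(),
        "chi2": chi2, "p_raw": sps.chi2.sf(chi2, 1),
    })
    return AssocResult(
        table=table,
        lambda_gc=genomic_inflation(chi2),
        n_cases=int((y == 1).sum()), n_controls=int((y == 0).sum()),
        test="cmh",
        skipped=table.loc[table["chi2"].isna(), "snp_id"].tolist(),
    )


def _strata_codes(ds: GenotypeDataset, strata: pd.Series | None) -> np.ndarray:
    if strata is None:
        labels = ds.samples["population"].fillna("__none__").to_numpy()
    else:
        labels = strata.reindex(ds.samples["sample_id"].to_numpy()).to_numpy()
    _, codes = np.unique(labels.astype(str), return_inverse=True)
    return codes


# ---------------------------------------------------------------------------
# max-T permutation
# ---------------------------------------------------------------------------

def maxT_permutation(
    ds: GenotypeDataset,
    case_labels: pd.Series | None = None,
    R: int = 100_000,
    seed: int = 0,
    test: str = "allelic",
    strata: pd.Series | None = None,
    permute_within_sex: bool = False,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    batch: int = 256,
) -> AssocResult:
    """Max-T genome-wide corrected p-values.

    Case/control labels are permuted R times (Fisher-Yates via the seeded
    generator); for the CMH test labels permute within strata, and
    ``permute_within_sex`` additionally confines swaps to sexes (the X-linked
    design, preserving the male/female allele-count imbalance).  P_genome for
    a marker is (1 + #{permutation max >= observed}) / (R + 1), bounded below
    by 1/(R+1) and monotone non-increasing in the observed statistic.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    y = _phenotype_vector(ds, case_labels)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("association requires at least one case and one control")
    sub, y = _qc_filter(ds, y, maf_min, call_rate_min)
    b, tot = _allele_contributions(sub)
    case = (y == 1).astype(np.float64)
    codes = _strata_codes(sub, strata) if test == "cmh" else None

    def stat_for(case_rows: np.ndarray) -> np.ndarray:
        if test == "allelic":
            return _chi2_2x2(
                case_rows @ b, case_rows @ tot, b.sum(axis=0), tot.sum(axis=0)
            )
        num, den = _cmh_terms(b, tot, case_rows, codes)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num ** 2 / den, np.nan)

    observed = stat_for(case)

    groups: list[np.ndarray] = []
    key = np.zeros(len(y), dtype=np.int64)
    if test == "cmh":
        key = key * 1000 + codes
    if permute_within_sex:
        sex = sub.samples["sex"].to_numpy()
        key = key * 7 + pd.factorize(sex)[0]
    for g in np.unique(key):
        groups.append(np.flatnonzero(key == g))

    rng = np.random.default_rng(seed)
    max_stats = np.empty(R)
    for r0 in range(0, R, batch):
        nb = min(batch, R - r0)
        perm = np.tile(case, (nb, 1))
        for r in range(nb):
            for rows in groups:
                perm[r, rows] = perm[r, rows[rng.permutation(len(rows))]]
        if test == "allelic":
            chi2 = _chi2_2x2(
                perm @ b, perm @ tot,
                b.sum(axis=0)[None, :], tot.sum(axis=0)[None, :],
            )
        else:
            chi2 = np.stack([stat_for(perm[r]) for r in range(nb)])
        max_stats[r0:r0 + nb] = np.nanmax(chi2, axis=1)

    obs = np.nan_to_num(observed, nan=-np.inf)
    exceed = (max_stats[None, :] >= obs[:, None]).sum(axis=1)
    p_genome = (1.0 + exceed) / (R + 1.0)
    p_genome[~np.isfinite(observed)] = np.nan

    table = pd.DataFrame({
        "snp_id": sub.markers["snp_id"].to_numpy(),
        "chrom": sub.markers["chrom"].to_numpy(),
        "pos_bp": sub.markers["pos_bp"].to_numpy(),
        "chi2": observed, "p_raw": sps.chi2.sf(observed, 1),
        "p_genome": p_genome,
    })
    return AssocResult(
        table=table,
        lambda_gc=genomic_inflation(observed),
        n_cases=int((y == 1).sum()), n_controls=int((y == 0).sum()),
        test=test, n_permutations=R,
        skipped=table.loc[table["chi2"].isna(), "snp_id"].tolist(),
    )


# ---------------------------------------------------------------------------
# genomic inflation
# ---------------------------------------------------------------------------

def genomic_inflation(chi2_values: np.ndarray) -> float:
    """lambda_GC = median(observed chi-square) / median(chi-square, 1 df)."""
    vals = np.asarray(chi2_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        return float("nan")
    return float(np.median(vals) / CHI2_MEDIAN_1DF)


# ---------------------------------------------------------------------------
# case-shared haplotype blocks
# ---------------------------------------------------------------------------

def case_shared_block(
    ds: GenotypeDataset,
    cases: list[str],
    anchor_snp: str,
    window_bp: int = 5_000_000,
    kind: str = "case_shared",
) -> HaplotypeBlock:
    """Maximal contiguous marker run around ``anchor_snp`` at which every
    case is homozygous for one and the same genotype.

    The anchor must be a recessive causal variant: all cases non-missing and
    homozygous there.  For ``kind="fixed_roh"`` pass the full membership of a
    population fixed for the variant as ``cases``.  A marker where any case
    is heterozygous, or where cases carry different homozygotes, breaks the
    run; missing calls are tolerated (as when exported genotypes are
    inspected by eye) provided at least one case is genotyped.
    """
    j = ds.marker_index(anchor_snp)
    chrom = ds.markers["chrom"].iloc[j]
    pos0 = int(ds.markers["pos_bp"].iloc[j])
    rows = [ds.sample_index(s) for s in cases]
    g_anchor = ds.calls[rows, j]
    if (g_anchor == MISSING).any():
        raise ValueError("all cases must be genotyped at the anchor marker")
    if not ((g_anchor == g_anchor[0]).all() and g_anchor[0] in (0, 2)):
        raise ValueError(
            "cases are not identically homozygous at the anchor; "
            "the anchor must be the recessive causal variant"
        )
    win = ds.subset(region=(chrom, pos0 - window_bp, pos0 + window_bp))
    jj = win.marker_index(anchor_snp)
    g = win.calls[[win.sample_index(s) for s in cases], :]
    called = g != MISSING
    some = called.any(axis=0)
    all_aa = ((g == 0) | ~called).all(axis=0)
    all_bb = ((g == 2) | ~called).all(axis=0)
    shared = some & (all_aa | all_bb)
    lo = jj
    while lo > 0 and shared[lo - 1]:
        lo -= 1
    hi = jj
    while hi < len(shared) - 1 and shared[hi + 1]:
        hi += 1
    return HaplotypeBlock(
        chrom=chrom,
        start_bp=int(win.markers["pos_bp"].iloc[lo]),
        end_bp=int(win.markers["pos_bp"].iloc[hi]),
        anchor_snp=anchor_snp,
        kind=kind,
        n_markers=hi - lo + 1,
    )


# ---------------------------------------------------------------------------
# LD-based required sample size
# ---------------------------------------------------------------------------

def required_sample_size(n_current: int, r2_link: float) -> PowerEstimate:
    """Samples needed for the nearest array marker to match the causal
    variant's association: n / r2 (indirect-association inflation)."""
    if not 0.0 < r2_link <= 1.0:
        raise ValueError(f"r2_link must be in (0, 1], got {r2_link}")
    return PowerEstimate(
        n_current=n_current,
        r2_link=r2_link,
        n_required=math.ceil(n_current / r2_link),
    )


def closest_marker(
    ds: GenotypeDataset, snp_id: str, frequencies: pd.DataFrame | None = None
) -> str:
    """Nearest same-chromosome marker to ``snp_id``; ties broken toward the
    larger MAF, then the lexicographically smaller id."""
    j = ds.marker_index(snp_id)
    chrom = ds.markers["chrom"].iloc[j]
    pos0 = int(ds.markers["pos_bp"].iloc[j])
    cand = ds.markers[
        (ds.markers["chrom"] == chrom) & (ds.markers["snp_id"] != snp_id)
    ]
    if cand.empty:
        raise ValueError(f"no other markers on chromosome {chrom}")
    if frequencies is None:
        frequencies = allele_stats(ds)
    dist = (cand["pos_bp"] - pos0).abs()
    maf = frequencies["maf"].reindex(cand["snp_id"]).to_numpy()
    order = sorted(
        range(len(cand)),
        key=lambda i: (dist.iloc[i], -np.nan_to_num(maf[i]), cand["snp_id"].iloc[i]),
    )
    return str(cand["snp_id"].iloc[order[0]])
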