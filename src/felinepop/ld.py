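"""Linkage disequilibrium from unphased genotypes.

Pairwise r-squared is computed from two-locus haplotype frequencies estimated
by expectation-maximization (EM): every genotype class except the double
heterozygote contributes known haplotypes; the double heterozygote's two
phasings are weighted by their current relative likelihood.  The EM is run
simultaneously for all marker pairs of a chromosome (arrays over pairs), is
initialized at linkage equilibrium, and stops when the largest haplotype
frequency change falls below 1e-10 (or after 1,000 iterations); the two-locus
likelihood has a single interior optimum almost everywhere, so restarts are
unnecessary.

Decay curves average r2 within 50-Kb distance bins spanning 50 Kb - 4 Mb
(half-open [lo, hi); a [0, 50 Kb) bin is retained for plotting but never
enters the extent determination).  The cross-population "extent of LD" is the
distance at which a population's binned curve decays to the maximum bin mean
of a reference (random-bred) population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset
from .popstats import allele_stats

BIN_BP = 50_000
MAX_DIST_BP = 4_000_000

# ordered-haplotype-pair compatibility: C[h, h', g1, g2] = 1 iff haplotypes
# h=(x,y), h'=(x',y') (allele_b indicators) produce genotypes g1=x+x', g2=y+y'
_HAPS = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (locus1 allele, locus2 allele)
_COMPAT = np.zeros((4, 4, 3, 3))
for _i, (_x, _y) in enumerate(_HAPS):
    for _j, (_u, _v) in enumerate(_HAPS):
        _COMPAT[_i, _j, _x + _u, _y + _v] = 1.0


def em_haplotype_freqs(
    counts: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
    return_loglik: bool = False,
):
    """EM estimate of the four two-locus haplotype frequencies.

    Parameters
    ----------
    counts : array of shape (..., 3, 3)
        Genotype-class counts (rows locus 1, columns locus 2) for one or many
        marker pairs.
    return_loglik : bool
        Also return the per-iteration observed-data log-likelihood trajectory
        (list of arrays), used to assert EM monotonicity.

    Returns
    -------
    freqs : array of shape (..., 4)
        Frequencies of haplotypes (00, 01, 10, 11) in ``_HAPS`` order, i.e.
        index 3 is the allele_b/allele_b haplotype.
    """
    counts = np.asarray(counts, dtype=np.float64)
    single = counts.ndim == 2
    n = counts[None] if single else counts
    total = n.sum(axis=(1, 2))
    # linkage-equilibrium initialization from marginal allele frequencies
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (n * np.arange(3)[None, :, None]).sum(axis=(1, 2)) / (2 * total)
        p2 = (n * np.arange(3)[None, None, :]).sum(axis=(1, 2)) / (2 * total)
    f = np.stack([
        (1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2,
    ], axis=1)
    logliks = []
    active = np.ones(len(f), dtype=bool)  # pairs still moving
    for _ in range(max_iter):
        fa, na, ta = f[active], n[active], total[active]
        # P(g1, g2) over ordered haplotype pairs (the ordering supplies the
        # factor 2 for heterozygous combinations)
        pg = np.einsum("ph,pk,hkgf->pgf", fa, fa, _COMPAT)
        if return_loglik:
            full_pg = np.einsum("ph,pk,hkgf->pgf", f, f, _COMPAT)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.where(
                    n > 0, n * np.log(np.where(full_pg > 0, full_pg, 1.0)), 0.0
                )
            logliks.append(ll.sum(axis=(1, 2)))
        # E-step: expected ordered-haplotype counts
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(pg > 0, na / pg, 0.0)
        new = 2.0 * fa * np.einsum("pk,hkgf,pgf->ph", fa, _COMPAT, w)
        with np.errstate(invalid="ignore", divide="ignore"):
            new = new / (2.0 * ta)[:, None]
        moved = np.nanmax(np.abs(new - fa), axis=1) if new.size else np.empty(0)
        f[active] = new
        still = np.isnan(moved) | (moved >= tol)
        if not still.any():
            break
        active[active] = still
    result = f[0] if single else f
    if return_loglik:
        return result, logliks
    return result


def _r2_from_freqs(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(r2, D) from haplotype frequencies in ``_HAPS`` order."""
    p1 = f[..., 2] + f[..., 3]
    p2 = f[..., 1] + f[..., 3]
    d = f[..., 3] - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, d * d / denom, np.nan)
    return r2, d


def pairwise_r2(
    ds: GenotypeDataset,
    maf_min: float = 0.05,
    max_dist_bp: int = MAX_DIST_BP,
) -> pd.DataFrame:
    """All same-chromosome autosomal marker pairs within ``max_dist_bp``.

    Markers are filtered to MAF >= ``maf_min`` on the supplied samples (one
    population at a time); pairs where either marker is monomorphic after
    subsetting are skipped.  Returns one row per pair with columns
    ``snp_a, snp_b, chrom, distance_bp, r2, D, f00, f01, f10, f11``.
    """
    stats = allele_stats(ds)
    keep = (
        ds.autosomal_mask()
        & (np.nan_to_num(stats["maf"].to_numpy()) >= maf_min)
    )
    rows = []
    markers = ds.markers
    for chrom in markers.loc[keep, "chrom"].unique():
        idx = np.flatnonzero(keep & (markers["chrom"] == chrom).to_numpy())
        if len(idx) < 2:
            continue
        pos = markers["pos_bp"].to_numpy()[idx]
        ids = markers["snp_id"].to_numpy()[idx]
        calls = ds.calls[:, idx]
        onehot = [(calls == g).astype(np.float64) for g in (0, 1, 2)]
        ii, jj = np.triu_indices(len(idx), k=1)
        dist = pos[jj] - pos[ii]
        sel = dist <= max_dist_bp
        ii, jj, dist = ii[sel], jj[sel], dist[sel]
        if len(ii) == 0:
            continue
        if len(idx) <= 700:
            # counts[g1, g2] for every marker pair of the chromosome at once
            cnt = np.empty((len(idx), len(idx), 3, 3))
            for g1 in range(3):
                for g2 in range(3):
                    cnt[:, :, g1, g2] = onehot[g1].T @ onehot[g2]
            pair_counts = cnt[ii, jj]
        else:  # dense-map path: gather only the needed pairs
            pair_counts = np.empty((len(ii), 3, 3))
            for g1 in range(3):
                a = onehot[g1][:, ii]
                for g2 in range(3):
                    pair_counts[:, g1, g2] = np.einsum(
                        "sp,sp->p", a, onehot[g2][:, jj]
                    )
        freqs = em_haplotype_freqs(pair_counts)
        r2, d = _r2_from_freqs(freqs)
        rows.append(pd.DataFrame({
            "snp_a": ids[ii], "snp_b": ids[jj], "chrom": chrom,
            "distance_bp": dist, "r2": r2, "D": d,
            "f00": freqs[:, 0], "f01": freqs[:, 1],
            "f10": freqs[:, 2], "f11": freqs[:, 3],
        }))
    if not rows:
        return pd.DataFrame(
            columns=["snp_a", "snp_b", "chrom", "distance_bp", "r2", "D",
                     "f00", "f01", "f10", "f11"]
        )
    out = pd.concat(rows, ignore_index=True)
    return out[out["r2"].notna()].reset_index(drop=True)


# ---------------------------------------------------------------------------
# decay curves and extent of LD
# ---------------------------------------------------------------------------

@dataclass
class LdDecayCurve:
    """Binned mean r2 versus inter-marker distance for one population."""

    population: str
    table: pd.DataFrame  # columns bin_lo_bp, bin_hi_bp, mean_r2, n_pairs

    def bins_in_range(self) -> pd.DataFrame:
        """The 50 Kb - 4 Mb bins that enter the extent determination
        (excludes the plotting-only [0, 50 Kb) bin)."""
        return self.table[self.table["bin_lo_bp"] >= BIN_BP].reset_index(drop=True)


@dataclass
class LdExtent:
    """Extent of LD against a reference population's maximum bin mean."""

    population: str
    extent_kb: int | None   # None = below the first bin ("<50")
    threshold_r2: float

    @property
    def label(self) -> str:
        return "<50" if self.extent_kb is None else str(self.extent_kb)


def decay_curve(
    pairs: pd.DataFrame,
    population: str = "",
    bin_bp: int = BIN_BP,
    max_dist_bp: int = MAX_DIST_BP,
) -> LdDecayCurve:
    """Mean r2 per half-open 50-Kb distance bin [lo, hi), from the [0, 50 Kb)
    plotting bin up to 4 Mb; empty bins carry NaN means and zero counts."""
    edges = np.arange(0, max_dist_bp + bin_bp, bin_bp)
    lo, hi = edges[:-1], edges[1:]
    which = np.searchsorted(edges, pairs["distance_bp"].to_numpy(), side="right") - 1
    ok = (which >= 0) & (which < len(lo))
    mean_r2 = np.full(len(lo), np.nan)
    n_pairs = np.zeros(len(lo), dtype=int)
    if ok.any():
        grp = pd.Series(pairs["r2"].to_numpy()[ok]).groupby(which[ok])
        mean_r2[grp.mean().index] = grp.mean().to_numpy()
        n_pairs[grp.count().index] = grp.count().to_numpy()
    return LdDecayCurve(
        population=population,
        table=pd.DataFrame({
            "bin_lo_bp": lo, "bin_hi_bp": hi,
            "mean_r2": mean_r2, "n_pairs": n_pairs,
        }),
    )


def ld_extent(curve: LdDecayCurve, reference: LdDecayCurve) -> LdExtent:
    """Extent of LD: the distance (Kb, lower edge of the last bin) up to
    which the curve's mean r2 stays at or above the reference population's
    maximum bin mean, scanning the 50 Kb - 4 Mb bins from the first upward.

    LD confined to the first bin [50, 100 Kb) reports 50; a curve already
    below the threshold in the first bin reports None, printed "<50" (the
    random-bred population compared with itself).  An empty bin (no marker
    pairs) terminates the run.
    """
    ct, rt = curve.bins_in_range(), reference.bins_in_range()
    if not np.array_equal(ct["bin_lo_bp"], rt["bin_lo_bp"]):
        raise ValueError("curve and reference are binned differently")
    threshold = float(np.nanmax(rt["mean_r2"].to_numpy()))
    extent_kb = None
    for _, row in ct.iterrows():
        if np.isnan(row["mean_r2"]) or row["mean_r2"] < threshold:
            break
        extent_kb = int(row["bin_lo_bp"] // 1000)
    return LdExtent(
        population=curve.population, extent_kb=extent_kb, threshold_r2=threshold
    )


def subsample_sensitivity(
    ds: GenotypeDataset,
    sizes: list[int],
    n_reps: int = 1,
    seed: int = 0,
    maf_min: float = 0.05,
    max_dist_bp: int = MAX_DIST_BP,
) -> pd.DataFrame:
    """Effect of sample size on the LD decay curve.

    For each size, draws ``n_reps`` random subsets without replacement,
    computes the decay curve, and reports the mean absolute difference of bin
    means between consecutive sizes (averaged over shared non-empty bins and
    replicates).
    """
    sizes = sorted(sizes)
    usable = [s for s in sizes if s <= ds.n_samples]
    for s in sizes:
        if s > ds.n_samples:
            warnings.warn(f"subsample size {s} exceeds population; skipped")
    rng = np.random.default_rng(seed)
    ids = ds.samples["sample_id"].to_numpy()
    deltas: dict[tuple[int, int], list[float]] = {}
    for _ in range(n_reps):
        curves = {}
        for s in usable:
            chosen = rng.choice(ids, size=s, replace=False)
            sub = ds.subset(sample_ids=list(chosen))
            curves[s] = decay_curve(
                pairwise_r2(sub, maf_min=maf_min, max_dist_bp=max_dist_bp),
                population=f"n={s}", max_dist_bp=max_dist_bp,
            ).bins_in_range()
        for a, b in zip(usable[:-1], usable[1:]):
            ca, cb = curves[a]["mean_r2"], curves[b]["mean_r2"]
            both = ca.notna() & cb.notna()
            if both.any():
                deltas.setdefault((a, b), []).append(
                    float((ca[both] - cb[both]).abs().mean())
                )
    rows = [
        {"size_a": a, "size_b": b, "mean_abs_delta": float(np.mean(v))}
        for (a, b), v in sorted(deltas.items())
    ]
    return pd.DataFrame(rows)
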