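"""Pairwise relatedness and population structure.

IBS similarity (PLINK's DST), method-of-moments IBD (PI_HAT), classical
Torgerson multidimensional scaling of 1 - DST, greedy unrelated-subset
selection, and the per-population circle summaries used to depict breed
clusters on MDS plots.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genotype_io import MISSING, GenotypeDataset
from .popstats import allele_stats


def _code_indicators(calls: np.ndarray) -> tuple[np.ndarray, ...]:
    """Float indicator matrices for genotype codes 0/1/2 (missing excluded)."""
    return tuple((calls == g).astype(np.float64) for g in (0, 1, 2))


def ibs_distance(ds: GenotypeDataset) -> pd.DataFrame:
    """Pairwise IBS similarity DST = (IBS2 + 0.5*IBS1) / N over jointly
    non-missing autosomal markers (NaN for pairs with no shared markers)."""
    if ds.n_samples < 2:
        raise ValueError("ibs_distance requires at least two samples")
    calls = ds.calls[:, ds.autosomal_mask()]
    a0, a1, a2 = _code_indicators(calls)
    nonmiss = a0 + a1 + a2
    n_joint = nonmiss @ nonmiss.T
    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    ibs1 = a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dst = np.where(n_joint > 0, (ibs2 + 0.5 * ibs1) / n_joint, np.nan)
    ids = ds.samples["sample_id"]
    return pd.DataFrame(dst, index=ids.to_numpy(), columns=ids.to_numpy())


def ibd_estimates(
    ds: GenotypeDataset, frequencies: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Method-of-moments PI_HAT from IBS counts and allele frequencies.

    Uses bias-corrected (without-replacement) expectations of P(IBS | IBD)
    computed from pooled allele counts on the analyzed sample set, solves the
    moment equations marker-set-wide for P(IBD = 0, 1, 2), clamps to [0, 1]
    and renormalizes.  Only polymorphic autosomal markers with at least four
    counted alleles enter the estimate.
    """
    if frequencies is None:
        frequencies = allele_stats(ds)
    auto = ds.autosomal_mask()
    maf = frequencies["maf"].to_numpy()
    n_al = frequencies["n_alleles"].to_numpy().astype(float)
    use = auto & (np.nan_to_num(maf) > 0) & (n_al >= 4)
    if use.sum() < 50:
        warnings.warn(
            f"only {int(use.sum())} informative markers; IBD estimates unstable"
        )

    calls = ds.calls[:, use]
    N = n_al[use]
    X = frequencies["freq_b"].to_numpy()[use] * N  # allele_b count
    Y = N - X

    def ff(z: np.ndarray, k: int) -> np.ndarray:  # falling factorial z(z-1)...(z-k+1)
        out = np.ones_like(z)
        for i in range(k):
            out = out * (z - i)
        return out

    d4 = ff(N, 4)
    d3 = ff(N, 3)
    d2 = ff(N, 2)
    e00 = 2.0 * ff(X, 2) * ff(Y, 2) / d4                      # P(IBS0 | IBD0)
    e10 = 4.0 * (ff(X, 3) * Y + X * ff(Y, 3)) / d4            # P(IBS1 | IBD0)
    e20 = (ff(X, 4) + ff(Y, 4) + 4.0 * ff(X, 2) * ff(Y, 2)) / d4
    e11 = 2.0 * (ff(X, 2) * Y + X * ff(Y, 2)) / d3            # P(IBS1 | IBD1)
    e21 = (ff(X, 2) + ff(Y, 2)) / d2                          # P(IBS2 | IBD1)

    a0, a1, a2 = _code_indicators(calls)
    nonmiss = a0 + a1 + a2
    O0 = a0 @ a2.T + a2 @ a0.T
    O1 = a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T
    O2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    Nj = nonmiss @ nonmiss.T

    def pairsum(e: np.ndarray) -> np.ndarray:
        return (nonmiss * e) @ nonmiss.T

    E00, E10, E20, E11, E21 = map(pairsum, (e00, e10, e20, e11, e21))
    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = O0 / E00
        z1 = (O1 - z0 * E10) / E11
        z2 = (O2 - z0 * E20 - z1 * E21) / Nj
    z = np.stack([z0, z1, z2])
    z = np.clip(z, 0.0, 1.0)
    total = z.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(total > 0, z / total, np.nan)
    pi_hat = z[2] + 0.5 * z[1]
    np.fill_diagonal(pi_hat, 1.0)
    ids = ds.samples["sample_id"]
    return pd.DataFrame(pi_hat, index=ids.to_numpy(), columns=ids.to_numpy())


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

def classical_mds(dst: pd.DataFrame, k: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Torgerson MDS of the genetic distance 1 - DST.

    Missing pairwise values are imputed with the mean off-diagonal distance
    (logged via a warning).  Returns coordinates (components ordered by
    decreasing eigenvalue, scaled by sqrt(eigenvalue), deterministic sign:
    the largest-magnitude loading of each component is positive) and the full
    eigenvalue spectrum — negative eigenvalues are reported, not truncated.
    """
    d = 1.0 - dst.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        mean_d = np.nanmean(d[~np.eye(len(d), dtype=bool)])
        warnings.warn("missing pairwise distances imputed with the mean distance")
        d = np.where(np.isnan(d), mean_d, d)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int((eigval > 1e-12).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {k_eff} positive eigenvalues; returning {k_eff} components"
        )
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    for c in range(k_eff):  # deterministic sign convention
        col = coords[:, c]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    frame = pd.DataFrame(
        coords, index=dst.index,
        columns=[f"C{i + 1}" for i in range(k_eff)],
    )
    return frame, eigval


# ---------------------------------------------------------------------------
# unrelated-subset selection
# ---------------------------------------------------------------------------

def select_unrelated(pi: pd.DataFrame, target_n: int) -> list[str]:
    """Greedy selection of the ``target_n`` most unrelated samples.

    Repeatedly drops the sample with the largest mean PI_HAT to the remaining
    samples; ties broken by larger max PI_HAT, then by dropping the
    lexicographically larger id.  Returns kept ids in their original order.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    ids = list(pi.index)
    if target_n >= len(ids):
        if target_n > len(ids):
            warnings.warn("target_n exceeds available samples; returning all")
        return ids
    mat = pi.to_numpy(dtype=float).copy()
    np.fill_diagonal(mat, np.nan)
    alive = np.ones(len(ids), dtype=bool)
    while alive.sum() > target_n:
        sub = mat[np.ix_(alive, alive)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_pi = np.nanmean(sub, axis=1)
            max_pi = np.nanmax(sub, axis=1)
        mean_pi = np.nan_to_num(mean_pi)
        max_pi = np.nan_to_num(max_pi)
        alive_idx = np.flatnonzero(alive)
        cand = np.flatnonzero(mean_pi == mean_pi.max())
        if len(cand) > 1:
            cand = cand[max_pi[cand] == max_pi[cand].max()]
        if len(cand) > 1:
            labels = [ids[alive_idx[c]] for c in cand]
            cand = cand[[labels.index(max(labels))]]
        alive[alive_idx[cand[0]]] = False
    return [ids[i] for i in np.flatnonzero(alive)]


def cluster_strata(dst: pd.DataFrame, height: float = 0.1) -> pd.Series:
    """Complete-linkage clustering of samples on the IBS distance 1 - DST,
    cut at a fixed height — the simplified fallback for deriving association
    strata when population labels are unavailable."""
    d = 1.0 - dst.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform((d + d.T) / 2.0, checks=False), method="complete")
    labels = fcluster(z, t=height, criterion="distance")
    return pd.Series(labels, index=dst.index, name="stratum")


# ---------------------------------------------------------------------------
# population circles
# ---------------------------------------------------------------------------

def population_circles(
    coords: pd.DataFrame,
    populations: pd.Series,
    dims: tuple[str, str] = ("C1", "C2"),
) -> pd.DataFrame:
    """Circle summary per population on one MDS dimension pair: center =
    (mean dim_i, mean dim_j), radius = the larger of the two sample standard
    deviations (0 for singleton populations)."""
    di, dj = dims
    rows = []
    pops = populations.reindex(coords.index)
    for pop, grp in coords.groupby(pops, sort=True):
        sd_i = grp[di].std(ddof=1) if len(grp) > 1 else 0.0
        sd_j = grp[dj].std(ddof=1) if len(grp) > 1 else 0.0
        rows.append({
            "population": pop,
            "dim_pair": f"{di}-{dj}",
            "cx": grp[di].mean(),
            "cy": grp[dj].mean(),
            "r": max(sd_i, sd_j),
        })
    return pd.DataFrame(rows)
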