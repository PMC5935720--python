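"""Genotype quality control.

Call-rate filtering, trio Mendelian-error detection, pseudoautosomal-region
(PAR) detection from male X heterozygosity, replicate concordance and
exclusion-list assembly.  Threshold semantics follow the array study's
reporting: a marker *fails* when >=10% of its genotypes are missing or >=10%
of informative trios show a Mendelian error; a sample *passes* at a call rate
>=90% (all boundaries inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

MARKER_MISSING_FAIL = 0.10   # missing fraction >= this fails the marker
SAMPLE_RATE_PASS = 0.90      # call rate >= this passes the sample
MENDEL_FLAG = 0.10           # trio-error fraction >= this flags the marker
PAR_FLAG = 0.10              # male-het fraction >= this flags an X marker


@dataclass
class QcReport:
    """Aggregated QC results; built incrementally by the stage functions."""

    snp_call_rate: pd.Series | None = None
    sample_call_rate: pd.Series | None = None
    failing_markers: list[str] = field(default_factory=list)
    failing_samples: list[str] = field(default_factory=list)
    snp_mendel_rate: pd.Series | None = None
    trio_mendel_rate: pd.Series | None = None
    mendel_flagged: list[str] = field(default_factory=list)
    par_flags: pd.DataFrame | None = None
    replicate_mismatch: pd.DataFrame | None = None
    exclusions: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# call rates
# ---------------------------------------------------------------------------

def call_rates(ds: GenotypeDataset) -> QcReport:
    """Per-marker and per-sample call rates, plus the failing sets.

    A marker fails when its missing fraction is >= 10%; a sample fails when
    its call rate is < 90%.
    """
    if ds.n_samples == 0 or ds.n_markers == 0:
        raise ValueError("call_rates requires a non-empty dataset")
    nonmiss = ds.calls != MISSING
    snp_rate = pd.Series(
        nonmiss.mean(axis=0), index=ds.markers["snp_id"], name="snp_call_rate"
    )
    sample_rate = pd.Series(
        nonmiss.mean(axis=1), index=ds.samples["sample_id"], name="sample_call_rate"
    )
    report = QcReport(snp_call_rate=snp_rate, sample_call_rate=sample_rate)
    # missing fraction computed directly (1 - rate is not exact in floats)
    missing_frac = (ds.calls == MISSING).mean(axis=0)
    report.failing_markers = snp_rate.index[
        missing_frac >= MARKER_MISSING_FAIL
    ].tolist()
    report.failing_samples = sample_rate.index[
        sample_rate.to_numpy() < SAMPLE_RATE_PASS
    ].tolist()
    return report


# ---------------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------------

def _autosomal_error_table() -> np.ndarray:
    """error[sire, dam, child] for genotype codes 0/1/2 under biallelic
    Mendelian transmission (True = impossible child)."""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    tab = np.ones((3, 3, 3), dtype=bool)
    for gs, (s1, s2) in alleles.items():
        for gd, (d1, d2) in alleles.items():
            for a in (s1, s2):
                for b in (d1, d2):
                    tab[gs, gd, a + b] = False
    return tab


_ERR_TABLE = _autosomal_error_table()


def mendelian_error_rates(
    ds: GenotypeDataset,
    trios: list[tuple[str, str, str]],
) -> QcReport:
    """Per-marker and per-trio Mendelian-error rates over (sire, dam, child)
    triples.

    Autosomes use the full transmission rule table.  X markers test sons
    against the dam only (a hemizygous son's allele must be carried by the
    dam); heterozygous sons are not counted here — they are the signal for
    :func:`detect_pseudoautosomal`.  Daughters on X are tested with the sire
    contributing his single hemizygous allele.  A trio enters a marker's
    denominator only when all required genotypes are non-missing; markers with
    an error rate >= 10% are flagged.
    """
    sid = {s: i for i, s in enumerate(ds.samples["sample_id"])}
    for trio in trios:
        for member in trio:
            if member not in sid:
                raise KeyError(f"trio references unknown sample: {member}")

    m = ds.n_markers
    x = ds.x_mask()
    auto = ~x
    err_count = np.zeros(m, dtype=np.int64)
    informative = np.zeros(m, dtype=np.int64)
    trio_rates = {}
    sex = ds.samples["sex"].to_numpy()

    for sire, dam, child in trios:
        gs = ds.calls[sid[sire]]
        gd = ds.calls[sid[dam]]
        gc = ds.calls[sid[child]]
        ok = (gs != MISSING) & (gd != MISSING) & (gc != MISSING)
        err = np.zeros(m, dtype=bool)

        a_ok = ok & auto
        err[a_ok] = _ERR_TABLE[gs[a_ok], gd[a_ok], gc[a_ok]]
        tested = a_ok.copy()

        x_ok = ok & x
        if x_ok.any():
            if sex[sid[child]] == "male":
                # son vs dam only; heterozygous sons belong to the PAR check
                son_test = x_ok & (gc != 1)
                # hemizygous son carries allele 0 (code 0) or 1 (code 2)
                carried = gc[son_test] // 2
                dam_has = np.where(
                    gd[son_test] == 1, True,
                    (gd[son_test] // 2) == carried,
                )
                err[son_test] = ~dam_has
                tested |= son_test
            else:
                # daughter: sire contributes his hemizygous allele
                dtest = x_ok & (gs != 1)  # het sires on X are PAR signals, skipped
                sire_allele = gs[dtest] // 2
                # possible daughters: sire_allele + {dam alleles}
                gd_t, gc_t = gd[dtest], gc[dtest]
                possible = np.zeros(len(gc_t), dtype=bool)
                for db in (0, 1):
                    dam_carries = np.where(gd_t == 1, True, (gd_t // 2) == db)
                    possible |= dam_carries & (gc_t == sire_allele + db)
                err[dtest] = ~possible
                tested |= dtest

        informative[tested] += 1
        err_count[tested] += err[tested]
        trio_rates[child] = (
            err[tested].sum() / tested.sum() if tested.any() else np.nan
        )

    with np.errstate(invalid="ignore"):
        rate = np.where(informative > 0, err_count / np.maximum(informative, 1), np.nan)
    snp_rate = pd.Series(rate, index=ds.markers["snp_id"], name="snp_mendel_rate")
    report = QcReport(
        snp_mendel_rate=snp_rate,
        trio_mendel_rate=pd.Series(trio_rates, name="trio_mendel_rate"),
    )
    report.mendel_flagged = snp_rate.index[
        (informative > 0) & (rate >= MENDEL_FLAG)
    ].tolist()
    return report


# ---------------------------------------------------------------------------
# pseudoautosomal detection
# ---------------------------------------------------------------------------

def detect_pseudoautosomal(ds: GenotypeDataset) -> pd.DataFrame:
    """Fraction of heterozygous males per X marker; flagged at >= 10%.

    Returns a frame indexed by X-marker id with columns ``male_het_fraction``,
    ``n_males`` (non-missing male calls) and ``flagged``.
    """
    x = ds.x_mask()
    if not x.any():
        warnings.warn("no X-chromosome markers; PAR detection skipped")
        return pd.DataFrame(
            columns=["male_het_fraction", "n_males", "flagged"]
        )
    males = ds.male_mask()
    if not males.any():
        raise ValueError("PAR detection requires at least one male")
    gx = ds.calls[np.ix_(males, x)]
    nonmiss = (gx != MISSING).sum(axis=0)
    het = (gx == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)
    return pd.DataFrame(
        {
            "male_het_fraction": frac,
            "n_males": nonmiss,
            "flagged": (nonmiss > 0) & (frac >= PAR_FLAG),
        },
        index=pd.Index(ds.markers["snp_id"].to_numpy()[x], name="snp_id"),
    )


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------

def replicate_concordance(
    ds: GenotypeDataset,
    pairs: list[tuple[str, str]],
    drop_markers: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-pair genotype discordance over jointly non-missing markers.

    ``drop_markers`` maps scenario names to marker-id lists to remove before
    comparison; the mismatch is reported once per scenario plus once on all
    markers (column ``all``), mirroring the three-way reporting of the array
    study (all SNPs / after call-rate exclusion / after Mendelian exclusion).
    """
    scenarios = {"all": []}
    if drop_markers:
        scenarios.update(drop_markers)
    snp_ids = ds.markers["snp_id"].to_numpy()
    out = {}
    for name, dropped in scenarios.items():
        keep = ~np.isin(snp_ids, list(dropped))
        col = {}
        for s1, s2 in pairs:
            g1 = ds.calls[ds.sample_index(s1)][keep]
            g2 = ds.calls[ds.sample_index(s2)][keep]
            both = (g1 != MISSING) & (g2 != MISSING)
            n = int(both.sum())
            col[(s1, s2)] = (g1[both] != g2[both]).sum() / n if n else np.nan
        out[name] = col
    frame = pd.DataFrame(out)
    frame.index.names = ["sample_1", "sample_2"]
    return frame


# ---------------------------------------------------------------------------
# exclusion assembly
# ---------------------------------------------------------------------------

def build_exclusions(
    ds: GenotypeDataset, report: QcReport
) -> tuple[GenotypeDataset, dict[str, str]]:
    """Union of low-call-rate and Mendelian-flagged markers with reason codes
    {LOW_CALL, MENDEL, BOTH}; overlapping markers are counted once.

    Excluded markers are removed from the returned analysis dataset, except
    that Mendelian-flagged markers are retained but reassigned to chromosome
    "unknown" (the array study parks them on the unknown chromosome for
    potential future use).
    """
    low = set(report.failing_markers)
    mend = set(report.mendel_flagged)
    exclusions = {}
    for snp in sorted(low | mend):
        if snp in low and snp in mend:
            exclusions[snp] = "BOTH"
        elif snp in low:
            exclusions[snp] = "LOW_CALL"
        else:
            exclusions[snp] = "MENDEL"
    report.exclusions = exclusions

    markers = ds.markers.copy()
    mendel_mask = markers["snp_id"].isin(mend).to_numpy()
    markers.loc[mendel_mask, "chrom"] = "unknown"
    drop = markers["snp_id"].isin(low - mend).to_numpy()
    kept = GenotypeDataset(
        markers=markers.loc[~drop],
        samples=ds.samples,
        calls=ds.calls[:, ~drop],
    ).sort_markers()
    return kept, exclusions
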