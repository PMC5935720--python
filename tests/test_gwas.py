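"""Association machinery: allelic chi-square hand checks, CMH reduction and
Simpson's-paradox behavior, max-T permutation properties, genomic inflation,
haplotype blocks and the sample-size calculation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from felinepop import (
    allelic_association,
    case_shared_block,
    closest_marker,
    cmh_association,
    genomic_inflation,
    maxT_permutation,
    required_sample_size,
)

from conftest import make_dataset


def _assoc_fixture(case_geno, control_geno, populations=None):
    calls = np.array(case_geno + control_geno, dtype=np.int8).reshape(-1, 1)
    n_case, n_ctrl = len(case_geno), len(control_geno)
    return make_dataset(
        calls,
        phenotypes=["case"] * n_case + ["control"] * n_ctrl,
        populations=populations or ["P"] * (n_case + n_ctrl),
    )


def test_equal_frequencies_give_zero_chi2():
    ds = _assoc_fixture([0, 1, 2, 1], [0, 1, 2, 1])
    res = allelic_association(ds, maf_min=0.0, call_rate_min=0.0)
    assert res.table["chi2"].iloc[0] == pytest.approx(0.0)
    assert res.table["p_raw"].iloc[0] == pytest.approx(1.0)


def test_chi2_hand_evaluation():
    """Cases (B=30, A=10) vs controls (B=10, A=30): chi2 = 20,
    p ~ 7.74e-6 by N(ad-bc)^2 / (row and column products)."""
    cases = [2] * 15 + [0] * 5      # 30 B, 10 A alleles
    controls = [2] * 5 + [0] * 15   # 10 B, 30 A alleles
    ds = _assoc_fixture(cases, controls)
    res = allelic_association(ds, maf_min=0.0, call_rate_min=0.0)
    assert res.table["chi2"].iloc[0] == pytest.approx(20.0, abs=1e-12)
    assert res.table["p_raw"].iloc[0] == pytest.approx(7.744216e-6, rel=1e-4)
    assert res.n_cases == 20 and res.n_controls == 20


def test_zero_margin_marker_skipped():
    ds = _assoc_fixture([0, 0], [0, 0])  # monomorphic: zero column margin
    res = allelic_association(ds, maf_min=0.0, call_rate_min=0.0)
    assert np.isnan(res.table["chi2"].iloc[0])
    assert res.skipped == [ds.markers["snp_id"].iloc[0]]


def test_requires_both_phenotype_classes():
    ds = _assoc_fixture([0, 1], [])
    ds.samples.loc[:, "phenotype"] = "case"
    with pytest.raises(ValueError, match="case and one control"):
        allelic_association(ds)


def test_x_marker_males_contribute_one_allele():
    ds = make_dataset(
        [[2], [2], [0], [0]],
        chroms=["X"],
        sexes=["male", "female", "male", "female"],
        phenotypes=["case", "case", "control", "control"],
    )
    res = allelic_association(ds, maf_min=0.0, call_rate_min=0.0)
    # cases: 3 B alleles of 3; controls: 0 of 3 -> chi2 = 6 (2x2 exact)
    a, b, c, d = 3, 0, 0, 3
    n = a + b + c + d
    expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert res.table["chi2"].iloc[0] == pytest.approx(expect)


# -- CMH ---------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(8))
def test_cmh_single_stratum_equals_scaled_allelic_chi2(seed):
    """K=1: CMH = ((N-1)/N) * allelic chi2 to 1e-10 on random tables."""
    rng = np.random.default_rng(seed)
    genos = rng.integers(0, 3, size=30).astype(int)
    phen = ["case"] * 12 + ["control"] * 18
    ds = make_dataset(np.array(genos).reshape(-1, 1), phenotypes=phen)
    allelic = allelic_association(ds, maf_min=0.0, call_rate_min=0.0)
    cmh = cmh_association(ds, maf_min=0.0, call_rate_min=0.0)
    chi2 = allelic.table["chi2"].iloc[0]
    n_alleles = 2 * 30
    assert cmh.table["chi2"].iloc[0] == pytest.approx(
        (n_alleles - 1) / n_alleles * chi2, abs=1e-10
    )


def test_cmh_resolves_simpsons_paradox():
    """Two strata with opposite confounding: pooled allelic chi2 is large
    while the stratified CMH statistic is near zero."""
    # within each stratum cases and controls share the allele frequency
    # (no true association), but stratum S1 is B-rich and case-heavy while
    # S2 is A-rich and control-heavy, so pooling fabricates association
    s1_cases = [2] * 9 + [0] * 3
    s1_ctrls = [2] * 3 + [0] * 1
    s2_cases = [2] * 1 + [0] * 3
    s2_ctrls = [2] * 3 + [0] * 9
    calls = np.array(s1_cases + s1_ctrls + s2_cases + s2_ctrls,
                     dtype=np.int8).reshape(-1, 1)
    ds = make_dataset(
        calls,
        phenotypes=(["case"] * 12 + ["control"] * 4
                    + ["case"] * 4 + ["control"] * 12),
        populations=["S1"] * 16 + ["S2"] * 16,
    )
    pooled = allelic_association(ds, maf_min=0.0, call_rate_min=0.0)
    stratified = cmh_association(ds, maf_min=0.0, call_rate_min=0.0)
    assert pooled.table["chi2"].iloc[0] > 3.84  # nominally significant
    assert stratified.table["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-10)


def test_cmh_all_case_stratum_dropped_without_effect():
    base = make_dataset(
        np.array([2, 2, 0, 0, 1, 1], dtype=np.int8).reshape(-1, 1),
        phenotypes=["case", "case", "control", "control", "case", "control"],
        populations=["P"] * 6,
    )
    ref = cmh_association(base, maf_min=0.0, call_rate_min=0.0)
    extra = make_dataset(
        np.array([2, 2, 0, 0, 1, 1, 2, 1], dtype=np.int8).reshape(-1, 1),
        phenotypes=["case", "case", "control", "control", "case", "control",
                    "case", "case"],
        populations=["P"] * 6 + ["ONLYCASES"] * 2,
    )
    res = cmh_association(extra, maf_min=0.0, call_rate_min=0.0)
    assert res.table["chi2"].iloc[0] == pytest.approx(
        ref.table["chi2"].iloc[0], abs=1e-12
    )


# -- max-T -------------------------------------------------------------------

def _random_assoc_ds(rng, n=12, m=6, n_case=6):
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    return make_dataset(
        calls, phenotypes=["case"] * n_case + ["control"] * (n - n_case)
    )


def test_maxt_p_bounds_and_monotonicity():
    rng = np.random.default_rng(2)
    ds = _random_assoc_ds(rng, n=40, m=30, n_case=20)
    res = maxT_permutation(ds, R=499, seed=3, maf_min=0.0, call_rate_min=0.0)
    p = res.table["p_genome"].to_numpy()
    chi2 = res.table["chi2"].to_numpy()
    fin = np.isfinite(chi2)
    assert (p[fin] >= 1 / 500).all() and (p[fin] <= 1).all()
    order = np.argsort(-chi2[fin])
    assert (np.diff(p[fin][order]) >= 0).all()


def test_maxt_zero_statistic_p_one():
    ds = _assoc_fixture([0, 1, 2, 1], [0, 1, 2, 1])
    res = maxT_permutation(ds, R=99, seed=1, maf_min=0.0, call_rate_min=0.0)
    assert res.table["p_genome"].iloc[0] == 1.0


def test_maxt_agrees_with_exhaustive_enumeration_six_samples():
    """Monte-Carlo P_genome matches the exhaustive distribution over all
    C(6,3) case assignments within binomial error."""
    import itertools

    from felinepop.gwas import _allele_contributions, _chi2_2x2

    rng = np.random.default_rng(5)
    ds = _random_assoc_ds(rng, n=6, m=4, n_case=3)
    res = maxT_permutation(ds, R=40_000, seed=7, maf_min=0.0, call_rate_min=0.0)

    b, tot = _allele_contributions(ds)
    maxes = []
    for comb in itertools.combinations(range(6), 3):
        y = np.zeros(6)
        y[list(comb)] = 1
        chi2 = _chi2_2x2(y @ b, y @ tot, b.sum(0), tot.sum(0))
        maxes.append(np.nanmax(chi2))
    maxes = np.array(maxes)
    obs = res.table["chi2"].to_numpy()
    exact = np.array([(maxes >= o).mean() for o in obs])
    mc = res.table["p_genome"].to_numpy()
    se = np.sqrt(exact * (1 - exact) / 40_000)
    assert (np.abs(mc - exact) <= 4 * se + 1e-4).all()


def test_maxt_within_sex_permutation_preserves_sex_totals():
    rng = np.random.default_rng(11)
    calls = rng.integers(0, 3, size=(20, 5)).astype(np.int8)
    sexes = ["male"] * 10 + ["female"] * 10
    phen = (["case"] * 7 + ["control"] * 3) + (["case"] * 2 + ["control"] * 8)
    ds = make_dataset(calls, sexes=sexes, phenotypes=phen)
    res = maxT_permutation(
        ds, R=199, seed=5, permute_within_sex=True,
        maf_min=0.0, call_rate_min=0.0,
    )
    assert res.n_cases == 9 and res.n_controls == 11
    assert np.isfinite(res.table["p_genome"].to_numpy()[
        np.isfinite(res.table["chi2"].to_numpy())
    ]).all()


# -- genomic inflation -------------------------------------------------------

def test_lambda_one_at_null_median():
    null_median = sps.chi2.ppf(0.5, 1)
    assert genomic_inflation([null_median]) == pytest.approx(1.0)


def test_lambda_scale_equivariance():
    rng = np.random.default_rng(0)
    vals = rng.chisquare(1, 1001)
    assert genomic_inflation(2 * vals) == pytest.approx(
        2 * genomic_inflation(vals)
    )


def test_lambda_empty_is_nan():
    assert np.isnan(genomic_inflation([]))


# -- haplotype blocks --------------------------------------------------------

def _block_fixture():
    """9 markers; 4 cases share identical homozygosity at markers 3-7 only
    (1-based), i.e. columns 2..6."""
    calls = np.ones((6, 9), dtype=np.int8)          # controls: het everywhere
    shared = [0, 0, 2, 2, 0, 2, 2, 1, 0]
    for i in range(4):
        calls[i] = shared
    calls[0, 0] = 2        # case 1 differs at marker 1
    calls[1, 1] = 1        # case 2 heterozygous at marker 2
    calls[2, 7] = 0        # marker 8 already breaks via shared het
    calls[3, 8] = 2        # cases disagree at marker 9
    positions = (np.arange(9) + 1) * 100_000
    return make_dataset(
        calls, positions=positions,
        phenotypes=["case"] * 4 + ["control"] * 2,
    )


def test_case_shared_block_spans_constructed_run():
    ds = _block_fixture()
    cases = list(ds.samples["sample_id"][:4])
    blk = case_shared_block(ds, cases, anchor_snp="s004", window_bp=10_000_000)
    assert (blk.start_bp, blk.end_bp) == (300_000, 700_000)
    assert blk.length_bp == 400_000
    assert blk.n_markers == 5


def test_single_case_block_is_own_homozygous_run():
    ds = _block_fixture()
    one = [ds.samples["sample_id"].iloc[0]]
    blk = case_shared_block(ds, one, anchor_snp="s004", window_bp=10_000_000)
    # case 1: homozygous run around marker 5 spans markers 1-7 (col 0 is 2,
    # col 1 is 0 ... all homozygous until the het at col 7)
    assert blk.start_bp == 100_000
    assert blk.end_bp == 700_000


def test_block_anchor_contract_violation_raises():
    ds = _block_fixture()
    cases = list(ds.samples["sample_id"][:4])
    with pytest.raises(ValueError, match="homozygous"):
        case_shared_block(ds, cases, anchor_snp="s007")  # het in cases
    ds.calls[0, 4] = -1
    with pytest.raises(ValueError, match="genotyped"):
        case_shared_block(ds, cases, anchor_snp="s004")


# -- power -------------------------------------------------------------------

def test_required_sample_size_closed_form():
    assert required_sample_size(100, 1.0).n_required == 100
    assert required_sample_size(100, 0.25).n_required == 400
    est = required_sample_size(54, 0.82)
    assert est.n_required == 66
    with pytest.raises(ValueError):
        required_sample_size(100, 0.0)
    with pytest.raises(ValueError):
        required_sample_size(100, 1.5)


def test_closest_marker_distance_then_maf_tiebreak():
    ds = make_dataset(
        [[0, 1, 1, 0], [0, 1, 0, 0], [0, 1, 2, 0], [2, 1, 1, 0]],
        positions=[100, 200, 300, 301],
    )
    # from s001 (pos 200): s000 and s002 both at distance 100;
    # s002 has the larger MAF (s003 is monomorphic and farther)
    from felinepop import allele_stats

    stats = allele_stats(ds)
    assert stats.loc["s002", "maf"] > stats.loc["s000", "maf"]
    assert closest_marker(ds, "s001") == "s002"
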