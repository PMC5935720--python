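"""Quality control: call-rate boundaries, Mendelian transmission rules
(against an exhaustive enumeration oracle), pseudoautosomal detection,
replicate concordance and exclusion assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from felinepop import (
    GenotypeDataset,
    QcReport,
    build_exclusions,
    call_rates,
    detect_pseudoautosomal,
    inject_marker_errors,
    mendelian_error_rates,
    replicate_concordance,
)

from conftest import make_dataset


# -- call rates --------------------------------------------------------------

def test_no_missing_data_all_rates_one(two_pop_panel):
    report = call_rates(two_pop_panel)
    assert (report.snp_call_rate == 1.0).all()
    assert (report.sample_call_rate == 1.0).all()
    assert report.failing_markers == [] and report.failing_samples == []


def test_marker_missingness_boundary_is_inclusive():
    """1 missing call among 10 samples = 10% missing: the marker fails."""
    calls = np.zeros((10, 2), dtype=np.int8)
    calls[0, 0] = -1
    ds = make_dataset(calls)
    report = call_rates(ds)
    assert report.failing_markers == ["s000"]
    # 1 of 20 markers missing would be 5%: passes
    calls = np.zeros((20, 1), dtype=np.int8)
    calls[0, 0] = -1
    assert call_rates(make_dataset(calls)).failing_markers == []


def test_sample_call_rate_boundary_is_inclusive():
    """A sample at exactly 90% call rate passes; below fails."""
    calls = np.zeros((2, 10), dtype=np.int8)
    calls[0, 0] = -1                      # exactly 0.9
    calls[1, :2] = -1                     # 0.8
    report = call_rates(make_dataset(calls))
    assert report.failing_samples == ["i001"]


# -- Mendelian errors --------------------------------------------------------

def brute_force_error(gs: int, gd: int, gc: int) -> bool:
    """Independent enumeration oracle over parental allele transmissions."""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    possible = {
        a + b for a in alleles[gs] for b in alleles[gd]
    }
    return gc not in possible


def test_autosomal_rule_matches_exhaustive_enumeration():
    """All 27 ordered (sire, dam, child) genotype combinations, laid out as
    27 markers of a single trio; exactly 12 are Mendelian errors."""
    combos = list(itertools.product((0, 1, 2), repeat=3))
    calls = np.array([
        [gs for gs, gd, gc in combos],
        [gd for gs, gd, gc in combos],
        [gc for gs, gd, gc in combos],
    ], dtype=np.int8)
    ds = make_dataset(
        calls,
        sexes=["male", "female", "female"],
        sample_ids=["sire", "dam", "kid"],
        sires=[None, None, "sire"],
        dams=[None, None, "dam"],
    )
    report = mendelian_error_rates(ds, [("sire", "dam", "kid")])
    expected = np.array([brute_force_error(*c) for c in combos], dtype=float)
    assert np.array_equal(report.snp_mendel_rate.to_numpy(), expected)
    assert expected.sum() == 12
    assert report.trio_mendel_rate["kid"] == pytest.approx(12 / 27)


def test_sire_aa_dam_aa_child_het_is_error():
    ds = make_dataset(
        [[0, 0], [0, 0], [1, 0]],
        sexes=["male", "female", "female"],
        sample_ids=["f", "m", "c"],
    )
    report = mendelian_error_rates(ds, [("f", "m", "c")])
    assert report.snp_mendel_rate.tolist() == [1.0, 0.0]


def test_missing_genotype_excluded_from_denominator():
    ds = make_dataset(
        [[0, 0], [0, -1], [2, 2]],
        sexes=["male", "female", "female"],
        sample_ids=["f", "m", "c"],
    )
    report = mendelian_error_rates(ds, [("f", "m", "c")])
    assert report.snp_mendel_rate.iloc[0] == 1.0
    assert np.isnan(report.snp_mendel_rate.iloc[1])  # no informative trio


def test_x_son_tested_against_dam_only():
    # son hemizygous allele_b (code 2); dam lacks allele_b -> error;
    # sire's genotype is irrelevant for sons
    ds = make_dataset(
        [[0], [0], [2]],
        chroms=["X"],
        sexes=["male", "female", "male"],
        sample_ids=["f", "m", "c"],
    )
    report = mendelian_error_rates(ds, [("f", "m", "c")])
    assert report.snp_mendel_rate.iloc[0] == 1.0
    # dam heterozygous: son may carry either allele
    ds2 = make_dataset(
        [[0], [1], [2]],
        chroms=["X"],
        sexes=["male", "female", "male"],
        sample_ids=["f", "m", "c"],
    )
    assert mendelian_error_rates(ds2, [("f", "m", "c")]).snp_mendel_rate.iloc[0] == 0.0


def test_x_heterozygous_son_not_counted_as_trio_error():
    ds = make_dataset(
        [[0], [0], [1]],
        chroms=["X"],
        sexes=["male", "female", "male"],
        sample_ids=["f", "m", "c"],
    )
    report = mendelian_error_rates(ds, [("f", "m", "c")])
    assert np.isnan(report.snp_mendel_rate.iloc[0])  # left to the PAR check


def test_x_daughter_requires_sires_hemizygous_allele():
    # sire carries allele_b (code 2); daughter aa (code 0) is impossible
    ds = make_dataset(
        [[2], [0], [0]],
        chroms=["X"],
        sexes=["male", "female", "female"],
        sample_ids=["f", "m", "c"],
    )
    report = mendelian_error_rates(ds, [("f", "m", "c")])
    assert report.snp_mendel_rate.iloc[0] == 1.0


def test_unknown_trio_member_raises(trio_panel):
    ds, _ = trio_panel
    with pytest.raises(KeyError):
        mendelian_error_rates(ds, [("ghost", "ghost2", "ghost3")])


def test_random_trios_match_enumeration_oracle(trio_panel):
    """Per-marker rates agree with the brute-force rule applied trio by trio
    on a simulated pedigree with injected noise."""
    ds, trios = trio_panel
    noisy = inject_marker_errors(ds, ds.markers["snp_id"].iloc[3], 0.5, seed=2)
    report = mendelian_error_rates(noisy, trios)
    sid = {s: i for i, s in enumerate(noisy.samples["sample_id"])}
    auto = ~noisy.x_mask()
    for j in np.flatnonzero(auto)[:40]:
        errs = n_inf = 0
        for sire, dam, child in trios:
            gs, gd, gc = (noisy.calls[sid[x], j] for x in (sire, dam, child))
            if -1 in (gs, gd, gc):
                continue
            n_inf += 1
            errs += brute_force_error(gs, gd, gc)
        expect = errs / n_inf if n_inf else np.nan
        got = report.snp_mendel_rate.iloc[j]
        assert (np.isnan(expect) and np.isnan(got)) or got == pytest.approx(expect)


# -- pseudoautosomal detection ----------------------------------------------

def _x_dataset(n_het_males: int, n_males: int = 52):
    calls = np.zeros((n_males, 1), dtype=np.int8)
    calls[:n_het_males, 0] = 1
    return make_dataset(calls, chroms=["X"], sexes=["male"] * n_males)


@pytest.mark.parametrize("n_het,flagged", [(0, False), (5, False), (6, True)])
def test_par_flag_threshold(n_het, flagged):
    """6/52 het males (11.5%) flags the marker; 5/52 (9.6%) does not."""
    par = detect_pseudoautosomal(_x_dataset(n_het))
    assert bool(par["flagged"].iloc[0]) is flagged
    assert par["male_het_fraction"].iloc[0] == pytest.approx(n_het / 52)


def test_par_detection_recovers_simulated_par_segment():
    from felinepop import PopulationSpec, SimConfig, simulate_panel

    cfg = SimConfig(
        populations=[PopulationSpec("P", 120, 200, 4, 2, 200)],
        n_snps_per_chrom={"X": 120}, par_fraction=0.1,
        n_trios=0, n_replicate_pairs=0,
        missing_rate=0.0, error_rate=0.0, seed=31,
    )
    ds = simulate_panel(cfg)
    par_truth = set(ds.markers["snp_id"].to_numpy()[ds._par_mask])  # noqa: SLF001
    result = detect_pseudoautosomal(ds)
    flagged = set(result.index[result["flagged"]])
    # without errors nothing outside the PAR can be flagged
    assert flagged <= par_truth
    # flagged set covers the polymorphic part of the PAR
    informative = {
        s for s in par_truth
        if result.loc[s, "male_het_fraction"] >= 0.10
    }
    assert flagged == informative


def test_no_x_markers_warns_empty():
    ds = make_dataset([[0], [1]], chroms=["A1"], sexes=["male", "female"])
    with pytest.warns(UserWarning, match="no X"):
        out = detect_pseudoautosomal(ds)
    assert out.empty


# -- replicate concordance ---------------------------------------------------

def test_identical_replicates_have_zero_mismatch():
    ds = make_dataset([[0, 1, 2], [0, 1, 2]])
    out = replicate_concordance(ds, [("i000", "i001")])
    assert out["all"].iloc[0] == 0.0


def test_mismatch_arithmetic_and_symmetry():
    calls = np.zeros((2, 200), dtype=np.int8)
    calls[1, 0] = 1  # one discordance in 200
    ds = make_dataset(calls)
    fwd = replicate_concordance(ds, [("i000", "i001")])["all"].iloc[0]
    rev = replicate_concordance(ds, [("i001", "i000")])["all"].iloc[0]
    assert fwd == pytest.approx(0.005)
    assert fwd == rev


def test_mismatch_invariant_to_marker_order():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(2, 50)).astype(np.int8)
    ds = make_dataset(calls)
    perm = rng.permutation(50)
    shuffled = GenotypeDataset(
        markers=ds.markers.iloc[perm], samples=ds.samples, calls=ds.calls[:, perm]
    )
    a = replicate_concordance(ds, [("i000", "i001")])["all"].iloc[0]
    b = replicate_concordance(shuffled, [("i000", "i001")])["all"].iloc[0]
    assert a == b


def test_zero_joint_markers_reported_missing():
    ds = make_dataset([[-1, 0], [0, -1]])
    out = replicate_concordance(ds, [("i000", "i001")])
    assert np.isnan(out["all"].iloc[0])


def test_three_way_reporting_drops_markers():
    calls = np.zeros((2, 4), dtype=np.int8)
    calls[1, 0] = 2
    ds = make_dataset(calls)
    out = replicate_concordance(
        ds, [("i000", "i001")], drop_markers={"cleaned": ["s000"]}
    )
    assert out["all"].iloc[0] == pytest.approx(0.25)
    assert out["cleaned"].iloc[0] == 0.0


# -- exclusions --------------------------------------------------------------

def _report(low, mendel):
    r = QcReport()
    r.failing_markers = low
    r.mendel_flagged = mendel
    return r


def test_exclusion_union_disjoint_and_overlap(two_pop_panel):
    ids = list(two_pop_panel.markers["snp_id"])
    _, excl = build_exclusions(two_pop_panel, _report(ids[0:3], ids[3:7]))
    assert len(excl) == 7
    _, excl = build_exclusions(
        two_pop_panel, _report([ids[0], ids[1]], [ids[1], ids[2]])
    )
    assert len(excl) == 3
    assert excl[ids[1]] == "BOTH"
    assert excl[ids[0]] == "LOW_CALL" and excl[ids[2]] == "MENDEL"


def test_mendelian_markers_reassigned_to_unknown_not_deleted(two_pop_panel):
    ids = list(two_pop_panel.markers["snp_id"])
    kept, _ = build_exclusions(two_pop_panel, _report([ids[0]], [ids[5]]))
    assert ids[0] not in set(kept.markers["snp_id"])          # low call: dropped
    row = kept.markers[kept.markers["snp_id"] == ids[5]]
    assert list(row["chrom"]) == ["unknown"]                  # mendel: parked
    assert kept.n_markers == two_pop_panel.n_markers - 1
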