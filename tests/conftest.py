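"""Shared fixtures: hand-built tiny datasets and session-scoped simulated
panels reused across test modules (everything is generated in memory)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from felinepop import (
    GenotypeDataset,
    PopulationSpec,
    SimConfig,
    simulate_panel,
    simulate_trios,
)


def make_dataset(
    calls,
    chroms=None,
    positions=None,
    sexes=None,
    populations=None,
    phenotypes=None,
    snp_ids=None,
    sample_ids=None,
    sires=None,
    dams=None,
) -> GenotypeDataset:
    """Build a GenotypeDataset from a genotype matrix and optional metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = pd.DataFrame({
        "snp_id": snp_ids or [f"s{j:03d}" for j in range(m)],
        "chrom": chroms or ["A1"] * m,
        "pos_bp": positions if positions is not None else (np.arange(m) + 1) * 10_000,
        "allele_a": ["A"] * m,
        "allele_b": ["C"] * m,
    })
    samples = pd.DataFrame({
        "sample_id": sample_ids or [f"i{i:03d}" for i in range(n)],
        "sex": sexes or ["female"] * n,
        "population": populations or ["P"] * n,
        "sire_id": sires or [None] * n,
        "dam_id": dams or [None] * n,
        "phenotype": phenotypes or [None] * n,
        "replicate_group": [None] * n,
    })
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


def random_dataset(rng: np.random.Generator, n=8, m=12, miss=0.1) -> GenotypeDataset:
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    calls[rng.random((n, m)) < miss] = -1
    chroms = list(rng.choice(["A1", "B2", "C1", "X"], size=m))
    positions = np.sort(rng.choice(np.arange(1, 10_000_000), size=m, replace=False))
    sexes = list(rng.choice(["male", "female"], size=n))
    ds = make_dataset(calls, chroms=chroms, positions=positions, sexes=sexes)
    # hemizygous convention: male X calls are not heterozygous
    x = ds.x_mask()
    males = ds.male_mask()
    sub = ds.calls[np.ix_(males, np.flatnonzero(x))]
    sub[sub == 1] = 2
    ds.calls[np.ix_(males, np.flatnonzero(x))] = sub
    return ds.sort_markers()


@pytest.fixture(scope="session")
def two_pop_panel():
    """Clean two-population panel with a founder-diversity contrast."""
    cfg = SimConfig(
        populations=[
            PopulationSpec("BIR", 30, 5, 10, 5, 120),
            PopulationSpec("DOM", 40, 300, 10, 5, 300),
        ],
        n_snps_per_chrom={"A1": 150, "C1": 150, "X": 80},
        n_trios=0, n_replicate_pairs=0,
        missing_rate=0.0, error_rate=0.0, seed=11,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def trio_panel():
    """Clean panel plus 40 bred trios (error-free)."""
    cfg = SimConfig(
        populations=[PopulationSpec("COL", 50, 60, 8, 5, 150)],
        n_snps_per_chrom={"A1": 120, "D2": 120, "X": 60},
        n_trios=40, n_replicate_pairs=0,
        missing_rate=0.0, error_rate=0.0, seed=23,
    )
    panel = simulate_panel(cfg)
    ds, trios = simulate_trios(cfg, panel)
    return ds, trios
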