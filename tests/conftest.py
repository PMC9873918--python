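"""Shared fixtures: small synthetic studies generated once per session."""

import numpy as np
import pandas as pd
import pytest

from colitraj import simulate as sim


@pytest.fixture(scope="session")
def small_study():
    """A compact study with every kind of planted structure."""
    cfg = sim.SimulationConfig(
        n_genes=400,
        n_per_group_per_day=6,
        n_fixed_per_day=12,
        trajectory_members={k: 12 for k in "ABCDE"},
        n_splice=12,
        n_splice_dynamic=8,
        seed=42,
    )
    gene, exon, ann, meta, truth = sim.simulate_counts(cfg)
    return {
        "config": cfg, "gene": gene, "exon": exon, "annotation": ann,
        "meta": meta, "truth": truth,
    }


@pytest.fixture(scope="session")
def null_study():
    """A study with no planted effects at all (complete null)."""
    cfg = sim.SimulationConfig(
        n_genes=400, n_per_group_per_day=6, n_fixed_per_day=0,
        trajectory_members={}, n_splice=0, n_splice_dynamic=0, seed=7,
    )
    gene, exon, ann, meta, truth = sim.simulate_counts(cfg)
    return {
        "config": cfg, "gene": gene, "exon": exon, "annotation": ann,
        "meta": meta, "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_meta():
    rows = []
    for d in (5, 12, 17, 36):
        for grp in ("disease", "control"):
            for i in range(3):
                rows.append((f"{grp[:3]}{d}_{i}", grp, d, "TOY", "colon"))
    return pd.DataFrame(rows, columns=["sample_id", "group", "day", "cohort", "tissue"])
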