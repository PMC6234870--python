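"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the package's compiled traversal plan,
cached matrices and index tier: the similarity oracle is a scalar recursion
directly over the ``skbio`` tree, and the attention oracle is a plain
triple loop over pairwise similarity calls.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import mse
from mse.simulate import SimulationConfig, simulate_database


# ----------------------------------------------------------------------
# Independent oracles
# ----------------------------------------------------------------------

def oracle_similarity(a: dict, b: dict, phylo, decay_rate: float = 1.0) -> float:
    """Scalar recursion over the tree: matched mass plus decayed residuals."""

    def walk(node):
        if node.is_tip():
            av, bv = a.get(node.name, 0.0), b.get(node.name, 0.0)
            m = min(av, bv)
            return m, av - m, bv - m
        matched, res_a, res_b = 0.0, 0.0, 0.0
        for child in node.children:
            cm, ca, cb = walk(child)
            w = math.exp(-decay_rate * (child.length or 0.0))
            matched += cm
            res_a += ca * w
            res_b += cb * w
        m = min(res_a, res_b)
        return matched + m, res_a - m, res_b - m

    matched, _, _ = walk(phylo.tree)
    return min(1.0, matched)


def oracle_overlap(a: dict, b: dict) -> float:
    keys = set(a) | set(b)
    return sum(min(a.get(t, 0.0), b.get(t, 0.0)) for t in keys)


def oracle_mas(db, config, max_year=None) -> dict[str, float]:
    """Triple-loop attention scores from pair-by-pair kernel calls."""
    meta = db.metadata
    ids = [
        s
        for s in db.sample_ids
        if max_year is None
        or (not np.isnan(meta.at[s, "year"]) and meta.at[s, "year"] <= max_year)
    ]
    sims = {
        (x, y): mse.similarity(db.vector(x), db.vector(y), db.phylogeny, config.kernel)
        for i, x in enumerate(ids)
        for y in ids[i + 1 :]
    }

    def sim(x, y):
        return 1.0 if x == y else sims[(x, y) if (x, y) in sims else (y, x)]

    out = {s: 0.0 for s in ids}
    for i in ids:
        ranked = sorted((s for s in ids if s != i), key=lambda s: (-sim(i, s), s))
        for m in ranked[: config.n_top]:
            value = sim(i, m)
            if value >= config.theta_connect and meta.at[i, "study_id"] != meta.at[m, "study_id"]:
                out[m] += value
    return out


# ----------------------------------------------------------------------
# Fixtures
# ----------------------------------------------------------------------

@pytest.fixture(scope="session")
def toy():
    """The hand-checkable worked example: profiles, phylogeny, exact sims."""
    profiles, phylo, expected = mse.worked_example_fixture()
    return profiles, phylo, expected


@pytest.fixture(scope="session")
def toy_db(toy):
    profiles, phylo, _ = toy
    return mse.ReferenceDatabase.build(profiles, phylo)


@pytest.fixture(scope="session")
def sim200():
    """Two-year corpus (~210 samples) for attention-oracle equivalence."""
    return simulate_database(
        SimulationConfig(
            seed=42,
            years=(2010, 2011),
            emergent_habitat_year=2011,
            n_planted_duplicates=0,
            qc_fail_fraction=0.0,
        )
    )


@pytest.fixture(scope="session")
def db200(sim200):
    return mse.ReferenceDatabase.build(sim200.profiles, sim200.phylogeny)


@pytest.fixture(scope="session")
def sim300():
    """Three-year corpus (~310 samples) for search-oracle equivalence."""
    return simulate_database(
        SimulationConfig(
            seed=42,
            years=(2010, 2012),
            emergent_habitat_year=2012,
            n_planted_duplicates=0,
            qc_fail_fraction=0.0,
        )
    )


@pytest.fixture(scope="session")
def db300(sim300):
    return mse.ReferenceDatabase.build(sim300.profiles, sim300.phylogeny)


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions (~840 samples over 2010-2017)."""
    return simulate_database(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_db(default_sim):
    """Curated default corpus: quality-filtered then deduplicated."""
    profiles, _ = mse.quality_filter(default_sim.profiles)
    db = mse.ReferenceDatabase.build(profiles, default_sim.phylogeny)
    kept, _ = mse.deduplicate(db)
    return db.subset(kept)


@pytest.fixture(scope="session")
def default_panels(default_db):
    return mse.score_panel(default_db)
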