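"""Shared fixtures.

Heavy objects (SIFT extractions, multi-structure databases) are built
once per session and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import adams
from adams import fixtures as fx
from adams.features import FeatureMatrix, SiftParams, extract_features
from adams.search import FeatureDatabase
from adams.structure_io import CalphaTrace, distance_image

# Two-domain study conditions shared by the robustness tests: 80-residue
# domains (typical natural domain size) joined by a 10-residue linker.
DOMAIN_N = 80
LINKER_N = 10
ORIG_DOMAIN_SEEDS = (101, 202)
UNRELATED_DOMAIN_SEEDS = [(300 + 17 * i, 310 + 23 * i) for i in range(4)]
QUERY_LINKER_SEEDS = list(range(10, 20))
CONTROL_DOMAIN_SEEDS = [(900 + i, 950 + i) for i in range(3)]


def features_of(trace: CalphaTrace, params: SiftParams | None = None):
    return extract_features(
        distance_image(trace).img, params=params, structure_id=trace.id
    )


@pytest.fixture(scope="session")
def bundle_trace() -> CalphaTrace:
    """A compact two-helix bundle whose image reliably carries keypoints."""
    return fx.make_helix_bundle(50, seed=3)


@pytest.fixture(scope="session")
def bundle_features(bundle_trace) -> FeatureMatrix:
    return features_of(bundle_trace)


@pytest.fixture(scope="session")
def extended_trace() -> CalphaTrace:
    """Perfectly extended chain: a linear-ramp image with no keypoints."""
    n = 40
    coords = np.column_stack(
        [np.zeros(n), np.zeros(n), 3.8 * np.arange(n)]
    )
    return CalphaTrace(id="extended40", coords=coords)


@pytest.fixture(scope="session")
def two_domain_original() -> CalphaTrace:
    return fx.make_two_domain(
        DOMAIN_N, DOMAIN_N, LINKER_N, seed=1,
        domain_seeds=ORIG_DOMAIN_SEEDS, structure_id="original",
    )


@pytest.fixture(scope="session")
def linker_db(two_domain_original) -> FeatureDatabase:
    """Original two-domain fixture plus four unrelated two-domain folds."""
    db = FeatureDatabase()
    db.add(features_of(two_domain_original), source="synthetic")
    for i, ds in enumerate(UNRELATED_DOMAIN_SEEDS):
        trace = fx.make_two_domain(
            DOMAIN_N, DOMAIN_N, LINKER_N, seed=1,
            domain_seeds=ds, structure_id=f"unrelated_{i}",
        )
        db.add(features_of(trace), source="synthetic")
    return db


@pytest.fixture(scope="session")
def linker_queries() -> list[FeatureMatrix]:
    """The original fold with ten re-randomized linker conformations."""
    out = []
    for seed in QUERY_LINKER_SEEDS:
        trace = fx.make_two_domain(
            DOMAIN_N, DOMAIN_N, LINKER_N, seed=seed,
            domain_seeds=ORIG_DOMAIN_SEEDS,
            structure_id=f"requery_{seed}",
        )
        out.append(features_of(trace))
    return out


@pytest.fixture(scope="session")
def ten_fixture_db() -> FeatureDatabase:
    """Ten distinct non-trivial fixtures for self-retrieval checks."""
    db = FeatureDatabase()
    traces = [
        fx.make_helix_bundle(60 + 10 * i, seed=40 + i,
                             structure_id=f"bundle_{i}")
        for i in range(6)
    ] + [
        fx.make_two_domain(
            DOMAIN_N, DOMAIN_N, LINKER_N, seed=5 + i,
            domain_seeds=(700 + 31 * i, 800 + 37 * i),
            structure_id=f"twodom_{i}",
        )
        for i in range(4)
    ]
    for trace in traces:
        db.add(features_of(trace), source="synthetic")
    return db


def random_unit_rows(n: int, rng: np.random.Generator, dim: int = 128):
    """Non-negative unit-norm rows, like real SIFT descriptors."""
    mat = rng.random((n, dim))
    return mat / np.linalg.norm(mat, axis=1, keepdims=True)
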