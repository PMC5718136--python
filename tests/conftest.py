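"""Shared fixtures and independent oracles for the sarakit test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sarakit.ontology import load_sara_ontology
from sarakit.rulebase import build_sara_rulebase
from sarakit.scale import default_scale
from sarakit.simdata import table1_patients, toy_ontology

settings.register_profile(
    "sarakit", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("sarakit")


@pytest.fixture(scope="session")
def sara_ont():
    return load_sara_ontology()


@pytest.fixture(scope="session")
def scale():
    return default_scale()


@pytest.fixture(scope="session")
def rb(scale):
    return build_sara_rulebase(scale)


@pytest.fixture(scope="session")
def table1():
    return table1_patients()


@pytest.fixture()
def toy_ont():
    return toy_ontology()


# ----------------------------------------------------------------------
# independent oracles (deliberately naive; never reuse library code paths)
# ----------------------------------------------------------------------

def bfs_ancestors(parent_map: dict[str, set], node: str) -> set:
    """Brute-force reachability over parent links (BFS)."""
    seen: set = set()
    frontier = list(parent_map[node])
    while frontier:
        current = frontier.pop()
        if current in seen:
            continue
        seen.add(current)
        frontier.extend(parent_map[current])
    return seen


def parent_map_of(ont) -> dict[str, set]:
    return {cid: set(cls.parents) for cid, cls in ont.classes.items()}


def brute_weighted_kappa(counts, scheme: str) -> float:
    """Independent weighted-kappa implementation (explicit loops)."""
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    n = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    num = 0.0
    den = 0.0
    for i in range(k):
        for j in range(k):
            d = abs(i - j) / (k - 1)
            w = d if scheme == "linear" else d * d
            num += w * counts[i, j]
            den += w * row[i] * col[j] / n
    return 1.0 - num / den


def random_contingency(k: int, seed: int, concentration: float = 2.0):
    """Random k x k count table with diagonal bias, non-degenerate."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 20, size=(k, k))
    counts[np.diag_indices(k)] += rng.integers(5, 30, size=k)
    return counts
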