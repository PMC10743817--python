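"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from math import comb

import pytest
from hypothesis import HealthCheck, settings

from plgenes import datasets
from plgenes.synthdata import WorldConfig, build_world, generate_world

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def hypergeom_tail_bruteforce(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability by direct enumeration.

    Independent of the implementation under test: plain combinatorial
    sum P(X >= k) = sum_j C(K, j) C(N-K, n-j) / C(N, n).
    """
    total = comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return acc / total


@pytest.fixture(scope="session")
def fixture_records():
    """The packaged multi-study pregnancy-loss catalogue."""
    return datasets.load_multistudy_catalogue()


@pytest.fixture(scope="session")
def small_world():
    """In-memory synthetic world small enough for per-test reuse."""
    return build_world(
        WorldConfig(
            n_genes=600,
            n_decoys_per_stage=20,
            n_gene_sets=25,
            rng_seed=13,
        )
    )


@pytest.fixture(scope="session")
def emitted_world(tmp_path_factory):
    """A default-size world written to disk once per session."""
    outdir = tmp_path_factory.mktemp("world")
    return generate_world(WorldConfig(rng_seed=5), outdir)
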