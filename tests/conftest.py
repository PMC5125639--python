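"""Shared fixtures: one small synthetic dataset reused across test modules."""

from __future__ import annotations

import math

import pytest

from feadh.alignio import AlignConfig
from feadh.annotate import annotate
from feadh.classify import SeedScorer
from feadh.registry import load_registry
from feadh.simulate import GeneratorConfig, make_seed_sets, simulate_family


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(seed=0, n_per_subfamily=4)


@pytest.fixture(scope="session")
def dataset(small_config, registry):
    return simulate_family(small_config, registry)


@pytest.fixture(scope="session")
def reference(dataset):
    return dataset.reference


@pytest.fixture(scope="session")
def seed_sets(dataset, small_config):
    return make_seed_sets(dataset.ancestors, small_config)


@pytest.fixture(scope="session")
def scorer(seed_sets):
    return SeedScorer(seed_sets)


@pytest.fixture(scope="session")
def annotations(dataset):
    return {rec.id: annotate(rec, dataset.reference) for rec in dataset.records}


def brute_force_affine_score(
    a: str, b: str, config: AlignConfig
) -> float:
    """Exhaustive enumeration over all global gapped alignments.

    Walks every alignment path (match/insert/delete with affine costs:
    ``gap_open`` for the first column of a gap run, ``gap_extend`` for each
    further column) and returns the maximum total score.  Exponential —
    usable only for very short sequences, which is the point: it is an
    oracle independent of any dynamic-programming shortcut.
    """
    matrix = config.make_aligner().substitution_matrix
    best = -math.inf

    def rec(i: int, j: int, last: str | None, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "m", score + matrix[a[i], b[j]])
        if i < len(a):
            cost = config.gap_extend if last == "a" else config.gap_open
            rec(i + 1, j, "a", score - cost)
        if j < len(b):
            cost = config.gap_extend if last == "b" else config.gap_open
            rec(i, j + 1, "b", score - cost)

    rec(0, 0, None, 0.0)
    return best
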