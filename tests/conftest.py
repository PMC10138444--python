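"""Shared fixtures: small simulated scenarios and matrix builders."""

from __future__ import annotations

import numpy as np
import pytest

from cernapipe.expression import ExpressionMatrix
from cernapipe.simulate import ScenarioConfig, simulate_scenario


def make_matrix(values, stages=("A", "B"), reps=2, gene_ids=None, unit="count"):
    """Build an ExpressionMatrix from a 2-D array laid out stage-major."""
    values = np.asarray(values, dtype=float)
    samples = [(st, r + 1) for st in stages for r in range(reps)]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(list(gene_ids), samples, list(stages), values, unit)


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A small default scenario shared by read-only tests."""
    cfg = ScenarioConfig(seed=11)
    out = tmp_path_factory.mktemp("scenario")
    bundle, truth = simulate_scenario(cfg, out)
    return cfg, out, bundle, truth


@pytest.fixture(scope="session")
def noise_free_scenario(tmp_path_factory):
    cfg = ScenarioConfig(seed=5, n_triads=5, noise_free=True)
    out = tmp_path_factory.mktemp("noise_free")
    bundle, truth = simulate_scenario(cfg, out)
    return cfg, out, bundle, truth
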