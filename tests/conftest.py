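"""Shared fixtures: the expensive simulation + factorization products reused
across the acceptance tests."""

import numpy as np
import pytest

from ziptf.consensus import refit_consensus, run_ensemble
from ziptf.inference import ModelSpec
from ziptf.pseudobulk import build_tensor, cpm_normalize
from ziptf.simulate import simulate_scrnaseq, to_cell_matrix

SC_SPEC = ModelSpec("zip", rank=8, prior_shape=1.0, prior_rate=0.3)


def pseudobulk_of(sim):
    cells = to_cell_matrix(sim)
    singlets = np.flatnonzero(~cells.cell_meta["is_doublet"].to_numpy())
    return cpm_normalize(build_tensor(cells.subset(cells=singlets)))


def sc_trial(seed: int, intensity: float, n_restarts: int, max_iter: int = 1000):
    """Simulate, pseudobulk, run an ensemble and its consensus refit."""
    sim = simulate_scrnaseq(mean_de_log2fc=intensity, seed=seed)
    tensor = pseudobulk_of(sim)
    ens = run_ensemble(tensor, SC_SPEC, n_restarts, seed=seed + 1,
                       max_iter=max_iter)
    model = refit_consensus(tensor, ens, SC_SPEC, seed=seed + 2)
    return sim, tensor, ens, model


@pytest.fixture(scope="session")
def sc_trial_075_main():
    """The primary 0.75-intensity trial: 5 restarts + consensus refit."""
    return sc_trial(seed=1101, intensity=0.75, n_restarts=5)
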