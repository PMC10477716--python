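"""Shared fixtures: synthetic datasets reused across the test modules.

Expensive artifacts (PARAFAC fits, the co-occurrence network) are
session-scoped so the suite pays for each once.
"""

from __future__ import annotations

import numpy as np
import pytest

from soilcnet import eem as ee
from soilcnet import network as nw
from soilcnet import parafac as pf
from soilcnet import synth


@pytest.fixture(scope="session")
def design():
    """Default study design: 3 treatments x 8 replicates, 0.5% EEM noise."""
    return synth.SynthDesign(seed=7)


@pytest.fixture(scope="session")
def eem_data(design):
    """(raw cube, blank, truth) for the default noisy design."""
    return synth.gen_eem_dataset(design)


@pytest.fixture(scope="session")
def corrected_cube(eem_data):
    cube, blank, _ = eem_data
    return ee.correct_eems(cube, blank)


@pytest.fixture(scope="session")
def fitted_model(corrected_cube):
    """PARAFAC fit of the default noisy cube (multi-start, converged)."""
    return pf.fit_parafac(corrected_cube, n_components=3, n_starts=4, seed=7)


@pytest.fixture(scope="session")
def noiseless_setup():
    """Noiseless cube, its correction, truth, and an exact 3-component fit."""
    dsg = synth.SynthDesign(seed=3, noise_sd=0.0)
    cube, blank, truth = synth.gen_eem_dataset(dsg)
    corrected = ee.correct_eems(cube, blank)
    model = pf.fit_parafac(corrected, n_components=3, n_starts=2, seed=3, tol=1e-12)
    return {"design": dsg, "cube": cube, "blank": blank, "truth": truth,
            "corrected": corrected, "model": model}


@pytest.fixture(scope="session")
def community(design):
    """(OTUTable, truth) for the default planted-module community."""
    return synth.gen_community(design)


@pytest.fixture(scope="session")
def bact_network(community):
    """Prevalence-filtered significant-Spearman network with Louvain modules."""
    table, _ = community
    filt = nw.prevalence_filter(table, min_fraction=0.5)
    net = nw.correlation_network(filt, alpha=0.01)
    nw.detect_modules(net, seed=7)
    return net


@pytest.fixture(scope="session")
def mineralization_data(design):
    """(TitrationTable, truth) for the default noisy incubation."""
    return synth.gen_mineralization(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
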