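import numpy as np
import pytest

from forest_vuln import model_training as mt
from forest_vuln import synth
from forest_vuln.model_training import VulnerabilityModel


class FunctionModel(VulnerabilityModel):
    """A model whose prediction is an exact function of its inputs —
    lets interpretation operations be checked against closed forms."""

    def __init__(self, features, fn, ranges=None):
        self.disturbance = "fire"
        self.pft = "all"
        self.features = list(features)
        self.fn = fn
        self.hyperparams = {}
        self.importances = {}
        self.seed = 0
        self.feature_ranges = ranges or {f: (0.0, 1.0) for f in self.features}
        self.ensemble = None

    def predict(self, X):
        M = self._matrix(X)
        return np.asarray(self.fn(M), dtype=float)

    def predict_se(self, X):
        return np.zeros(len(self._matrix(X)))


@pytest.fixture(scope="session")
def fire_truth():
    return synth.default_truth("fire")


@pytest.fixture(scope="session")
def small_landscape():
    return synth.generate_landscape(7, 24, 24)


@pytest.fixture(scope="session")
def small_climate(small_landscape, fire_truth):
    return synth.generate_climate(8, range(1979, 2019), fire_truth,
                                  landscape=small_landscape)


@pytest.fixture(scope="session")
def dense_records(fire_truth):
    """5000-record tabular draw under the default study conditions."""
    recs = synth.generate_records(1, fire_truth, 5000)
    return recs[recs["retained"]].reset_index(drop=True)


@pytest.fixture(scope="session")
def binned_split(dense_records, fire_truth):
    return mt.pc_bin_split(dense_records, fire_truth.features, seed=1)


@pytest.fixture(scope="session")
def fitted_model(binned_split):
    train, test = binned_split
    return mt.fit(train, ["tmax", "pcum", "tree_age"], seed=1,
                  n_search=0, test=test)


def make_records(seed, n, weights, noise_sd=0.0, base=0.45, interactions=()):
    """Record table from an explicit truth (clip-free by default)."""
    truth = synth.GeneratorTruth(
        disturbance="fire", base=base, response_weights=dict(weights),
        interaction_terms=list(interactions), noise_sd=noise_sd)
    return truth, synth.generate_records(seed, truth, n)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
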