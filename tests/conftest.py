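"""Shared fixtures: planted factorization instances and stub pipelines."""

from __future__ import annotations

import numpy as np
import pytest

from nmftl.io import FeatureMatrix
from nmftl.synthetic import DomainPairSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def planted_instance(seed: int, n_s=60, n_t=40, d=12, r=3):
    """Noiseless two-domain instance with a known non-negative factorization."""
    gen = np.random.default_rng(seed)
    H = gen.uniform(0.1, 1.0, (r, d))
    Ws = gen.uniform(0.1, 1.0, (n_s, r))
    Wt = gen.uniform(0.1, 1.0, (n_t, r))
    return Ws @ H, Wt @ H, (Ws, Wt, H)


@pytest.fixture
def planted():
    return planted_instance


#: Study conditions for the domain-shift transfer experiment: many noisy
#: spectral features over a low-rank shared class structure.
SHIFT_SPEC = dict(
    d=20,
    r_true=4,
    n_s=150,
    n_t=50,
    n_classes=2,
    class_separation=2.0,
    domain_shift=1.0,
    noise_sd=0.8,
)


@pytest.fixture
def shift_spec_factory():
    def make(seed: int) -> DomainPairSpec:
        return DomainPairSpec(seed=seed, **SHIFT_SPEC)

    return make


class OracleStub:
    """Pipeline stub that reads the true label out of feature column 0.

    Used with data whose first feature encodes the class, so protocol
    harnesses can be checked against a classifier that cannot err.
    """

    def fit(self, X, y, X_target=None):
        return self

    def predict(self, X):
        return np.asarray(np.round(X[:, 0]), dtype=int)


class MajorityStub:
    """Predicts the majority class of its training fold."""

    def fit(self, X, y, X_target=None):
        labels, counts = np.unique(y, return_counts=True)
        self.majority_ = labels[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(X.shape[0], self.majority_)


class CountingStub(OracleStub):
    """Oracle stub that counts fits and records test indices via feature 1."""

    def __init__(self, log: dict):
        self.log = log

    def fit(self, X, y, X_target=None):
        self.log["fits"] = self.log.get("fits", 0) + 1
        if X_target is not None:
            self.log.setdefault("test_ids", []).append(
                np.asarray(np.round(X_target[:, 1]), dtype=int)
            )
        return self


def label_encoded_data(n: int, seed: int = 0, n_classes: int = 2) -> FeatureMatrix:
    """Data whose feature 0 is the label and feature 1 the sample index."""
    gen = np.random.default_rng(seed)
    labels = np.tile(np.arange(n_classes), n // n_classes + 1)[:n]
    X = np.column_stack(
        [labels.astype(float), np.arange(n, dtype=float), gen.random(n)]
    )
    return FeatureMatrix(values=X, labels=labels)
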