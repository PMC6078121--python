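import numpy as np
import pandas as pd
import pytest

from dranet import CohortSpec, RunConfig, generate_all_partners


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def logistic_spec():
    """The standard 3-partner logistic study conditions."""
    return CohortSpec(family="logistic", seed=11)


@pytest.fixture
def logistic_partners(logistic_spec):
    return generate_all_partners(logistic_spec)


@pytest.fixture
def cox_spec():
    return CohortSpec(
        family="cox", true_beta=(0.5, 0.3, -0.4), site_effect_sd=0.3, seed=12
    )


@pytest.fixture
def cox_partners(cox_spec):
    return generate_all_partners(cox_spec)


@pytest.fixture
def fast_config(tmp_path):
    """A small, quick-polling run configuration rooted in a temp dir."""

    def make(**overrides):
        defaults = dict(
            root=tmp_path / "tree",
            n_per_partner=(300, 300, 300),
            poll_interval=0.01,
            timeout=30.0,
            seed=7,
        )
        defaults.update(overrides)
        return RunConfig(**defaults)

    return make


def brute_force_cox(X, time, event, beta):
    """Independent risk-set enumeration oracle (Breslow ties, one stratum)."""
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    eta = X @ beta
    w = np.exp(eta)
    loglik, score = 0.0, np.zeros(X.shape[1])
    info = np.zeros((X.shape[1],) * 2)
    for t in np.unique(time[event == 1]):
        risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        s0 = w[risk].sum()
        s1 = w[risk] @ X[risk]
        s2 = (X[risk] * w[risk, None]).T @ X[risk]
        loglik += eta[dead].sum() - d * np.log(s0)
        score += X[dead].sum(axis=0) - d * s1 / s0
        info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
    return loglik, score, info


def pooled_frame(partners: list[pd.DataFrame], site_col: str | None = None):
    if site_col is None:
        return pd.concat(partners, ignore_index=True)
    frames = []
    for k, d in enumerate(partners, 1):
        d = d.copy()
        d[site_col] = k
        frames.append(d)
    return pd.concat(frames, ignore_index=True)
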