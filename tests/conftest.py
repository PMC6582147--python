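import numpy as np
import pytest

from finemapkit.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One-locus dataset with a strong planted causal, shared across tests."""
    cfg = SimulationConfig(
        seed=42,
        n_individuals=800,
        n_variants=200,
        causal_effect_sd=0.3,
        h2_polygenic=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def quadrature_log_marginal(y, X, Z, phi, gamma):
    """Independent oracle: effects integrated analytically, sigma_e^2 by
    adaptive quadrature of the Jeffreys-weighted Gaussian marginal."""
    from scipy import integrate

    y = np.asarray(y, float)
    n = len(y)
    W = np.hstack([X, Z]) if Z is not None and Z.size else np.asarray(X, float)
    ratios = [phi] * X.shape[1] + ([gamma] * Z.shape[1] if Z is not None else [])
    Sig = np.eye(n) + W @ np.diag(ratios) @ W.T
    _, logdet = np.linalg.slogdet(Sig)
    Q = y @ np.linalg.solve(Sig, y)
    peak = np.log(Q / n)
    shift = -0.5 * n * np.log(2 * np.pi * np.exp(peak)) - 0.5 * logdet - Q / (
        2 * np.exp(peak)
    )

    def integrand(ls2):
        s2 = np.exp(ls2)
        return np.exp(
            -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * logdet - Q / (2 * s2) - shift
        )

    val, _ = integrate.quad(integrand, peak - 40, peak + 40, limit=500, points=[peak])
    return np.log(val) + shift
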