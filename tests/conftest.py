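import numpy as np
import pytest

from migrainecast.repair import synchronize
from migrainecast.synthetic import SyntheticConfig, generate_patient


@pytest.fixture(scope="session")
def clean_patient():
    """Small noise- and drift-free patient: 3 events over 6 days."""
    cfg = SyntheticConfig(
        duration_days=6.0,
        n_migraines=3,
        lead_time=60.0,
        snr_db=None,
        circadian_scale=0.0,
        random_walk_scale=0.0,
        gap_rate=0.0,
        seed=3,
    )
    rec, truth = generate_patient(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def clean_frame(clean_patient):
    _, rec, _ = clean_patient
    return synchronize(list(rec.channels.values()))


def make_lti(nx, m, rng, rho=0.85):
    """Random stable LTI system for recovery oracles."""
    A = rng.standard_normal((nx, nx))
    A *= rho / np.max(np.abs(np.linalg.eigvals(A)))
    B = rng.standard_normal((nx, m))
    C = rng.standard_normal((1, nx))
    D = np.zeros((1, m))
    return A, B, C, D


def toy_bump_dataset(n_migraines=3, seed=0, n=900, lead=30):
    """Per-migraine (u, y) pairs where inputs lead a bump-shaped output.

    y is a pain-curve-like excursion (0..1, >=100 min wide); inputs are the
    output advanced by ``lead`` minutes and smoothed, so a low-order linear
    model can predict ahead.  Used by ensemble/evaluation tests.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_migraines):
        lo = int(rng.integers(300, n - 350))
        width = int(rng.integers(120, 220))
        t = np.arange(n)
        mid = lo + 0.4 * width
        sigma = width / 4.0
        y = np.exp(-((t - mid) ** 2) / (2 * sigma**2))
        adv = np.exp(-((t + lead - mid) ** 2) / (2 * sigma**2))
        u = np.column_stack([
            adv + 0.01 * rng.standard_normal(n),
            np.convolve(adv, np.ones(5) / 5, mode="same") + 0.01 * rng.standard_normal(n),
        ])
        out[i] = (u, y)
    return out


def simulate_lti(A, B, C, D, u, noise_sd=0.0, rng=None):
    """Reference simulator, independent of the package's model code."""
    x = np.zeros(A.shape[0])
    y = np.zeros(u.shape[0])
    for t in range(u.shape[0]):
        y[t] = (C @ x)[0] + (D @ u[t])[0]
        x = A @ x + B @ u[t]
    if noise_sd > 0:
        y = y + rng.standard_normal(y.size) * noise_sd
    return y
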