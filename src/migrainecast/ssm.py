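"""Subspace identification of linear predictors for the symptomatic curve.

Implements the combined deterministic-stochastic subspace scheme (N4SID):
block-Hankel matrices with ``ph`` past/future block rows, oblique projection
of the future outputs onto the past data along the future inputs, SVD rank
truncation to the requested order, state-sequence regression for
``A, B, C, D`` and an innovations-based Kalman predictor gain ``K`` from the
residual covariances via the discrete algebraic Riccati equation.

The identified model

    x[k+1] = A x[k] + B u[k] + w[k]
    y[k]   = C x[k] + D u[k] + v[k]

is used in predictor form for k-step-ahead prediction: the state is filtered
over observed data with innovation feedback, then rolled forward ``k`` steps
with the innovation set to zero and inputs held at their last observed value
(zero-order hold), since no future inputs exist at deployment time.

Accuracy is scored everywhere with the normalized-error fit

    fit = 100 * (1 - ||y - yhat|| / ||y - mean(y)||)
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.linalg import lstsq, pinv
from scipy.linalg import solve_discrete_are

__all__ = [
    "StateSpaceModel",
    "TrainingGridResult",
    "WindowTooShortError",
    "ConstantOutputError",
    "compute_fit",
    "fit_n4sid",
    "predict_k_ahead",
    "train_grid",
    "grid_combinations",
    "DEFAULT_PH_GRID",
    "DEFAULT_NX_GRID",
]

#: past-horizon grid in minutes: 5, 10, ..., 100 (20 values).
DEFAULT_PH_GRID: tuple[int, ...] = tuple(range(5, 101, 5))
#: model-order grid: 1..10.
DEFAULT_NX_GRID: tuple[int, ...] = tuple(range(1, 11))
#: future horizon (minutes) at which training fit is reported.
TRAIN_HORIZON = 30
#: predicted output is clamped to this range before probability mapping.
OUTPUT_CLAMP = (-0.2, 1.2)


class WindowTooShortError(ValueError):
    """Data window cannot support the requested past horizon."""


class ConstantOutputError(ValueError):
    """Fit metric undefined for a constant reference series."""


@dataclass
class StateSpaceModel:
    """Identified innovations-form state-space model (single output)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    K: np.ndarray
    nx: int
    ph: int
    input_names: tuple[str, ...]
    u_mean: np.ndarray
    u_std: np.ndarray
    y_mean: float
    y_std: float
    fh_train: int = TRAIN_HORIZON
    order_reduced: bool = False
    predictor_stabilized: bool = False

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    def predictor_matrix(self) -> np.ndarray:
        """Closed-loop predictor transition ``A - K C``."""
        return self.A - self.K @ self.C

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "D": self.D.tolist(),
            "K": self.K.tolist(),
            "nx": self.nx,
            "ph": self.ph,
            "input_names": list(self.input_names),
            "u_mean": self.u_mean.tolist(),
            "u_std": self.u_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "fh_train": self.fh_train,
            "order_reduced": self.order_reduced,
            "predictor_stabilized": self.predictor_stabilized,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateSpaceModel":
        return cls(
            A=np.array(d["A"], dtype=float),
            B=np.array(d["B"], dtype=float),
            C=np.array(d["C"], dtype=float),
            D=np.array(d["D"], dtype=float),
            K=np.array(d["K"], dtype=float),
            nx=int(d["nx"]),
            ph=int(d["ph"]),
            input_names=tuple(d["input_names"]),
            u_mean=np.array(d["u_mean"], dtype=float),
            u_std=np.array(d["u_std"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_std=float(d["y_std"]),
            fh_train=int(d.get("fh_train", TRAIN_HORIZON)),
            order_reduced=bool(d.get("order_reduced", False)),
            predictor_stabilized=bool(d.get("predictor_stabilized", False)),
        )


def compute_fit(y, yhat) -> float:
    """Normalized-error fit in percent; 100 is perfect, can be negative.

    NaNs in either series are ignored pairwise (prediction warm-up).
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    valid = np.isfinite(y) & np.isfinite(yhat)
    y, yhat = y[valid], yhat[valid]
    if y.size < 2:
        raise ValueError("need at least 2 valid samples")
    denom = np.linalg.norm(y - y.mean())
    if denom == 0.0:
        raise ConstantOutputError("fit undefined for constant y")
    return float(100.0 * (1.0 - np.linalg.norm(y - yhat) / denom))


def _block_hankel(data: np.ndarray, first: int, last: int, ncols: int) -> np.ndarray:
    """Stack block rows ``first..last`` (inclusive) of ``data`` (N, ch)."""
    ch = data.shape[1]
    rows = []
    for r in range(first, last + 1):
        rows.append(data[r : r + ncols].T)  # (ch, ncols)
    return np.concatenate(rows, axis=0) if rows else np.empty((0, ncols))


def _oblique_projection(Yf: np.ndarray, Uf: np.ndarray, Wp: np.ndarray) -> np.ndarray:
    """Project row space of Yf onto Wp along Uf."""
    Z = np.vstack([Wp, Uf])
    coef, *_ = lstsq(Z.T, Yf.T, rcond=None)
    return coef[: Wp.shape[0]].T @ Wp


def _stabilize_predictor(A: np.ndarray, C: np.ndarray, K: np.ndarray):
    """Shrink K (and as last resort A) until spectral radius(A - K C) < 1."""
    stabilized = False
    for _ in range(60):
        if np.max(np.abs(np.linalg.eigvals(A - K @ C))) < 1.0 - 1e-9:
            return A, K, stabilized
        K = 0.8 * K
        stabilized = True
    K = np.zeros_like(K)
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho >= 1.0:
        A = A * (0.98 / rho)
    return A, K, True


def fit_n4sid(
    u: np.ndarray,
    y: np.ndarray,
    nx: int,
    ph: int,
    input_names: tuple[str, ...] | None = None,
    min_cols_factor: float = 1.2,
) -> StateSpaceModel:
    """Identify a state-space model from inputs ``u`` (N, m) to output ``y`` (N,).

    ``ph`` sets the number of past and future block rows of the Hankel
    matrices (minutes at the 1/min grid).  Features and output are z-scored
    with window statistics stored on the model, so predictions are invariant
    to input scaling.

    Raises
    ------
    WindowTooShortError
        If the window cannot populate the Hankel matrices with at least
        ``min_cols_factor`` columns per row.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[0] < u.shape[1]:
        u = u.T
    y = np.asarray(y, dtype=float).ravel()
    N, m = u.shape
    if y.size != N:
        raise ValueError("u and y must cover the same window")
    if not 1 <= nx:
        raise ValueError("nx must be >= 1")
    i = int(ph)
    if i < nx + 1:
        i = nx + 1  # observability needs at least nx+1 block rows
    ncols = N - 2 * i + 1
    needed_rows = i * (2 * m + 1)
    if ncols < min_cols_factor * needed_rows:
        raise WindowTooShortError(
            f"window of {N} samples too short for ph={ph} with {m} inputs"
        )

    u_mean, u_std = u.mean(axis=0), u.std(axis=0)
    u_std = np.where(u_std < 1e-12, 1.0, u_std)
    y_mean, y_std = float(y.mean()), float(y.std())
    if y_std < 1e-12:
        y_std = 1.0
    un = (u - u_mean) / u_std
    yn = ((y - y_mean) / y_std)[:, None]

    Up = _block_hankel(un, 0, i - 1, ncols)
    Uf = _block_hankel(un, i, 2 * i - 1, ncols)
    Yp = _block_hankel(yn, 0, i - 1, ncols)
    Yf = _block_hankel(yn, i, 2 * i - 1, ncols)
    Wp = np.vstack([Up, Yp])

    # shifted quantities for the state at time i+1
    Up_plus = _block_hankel(un, 0, i, ncols)
    Yp_plus = _block_hankel(yn, 0, i, ncols)
    Wp_plus = np.vstack([Up_plus, Yp_plus])
    Uf_minus = _block_hankel(un, i + 1, 2 * i - 1, ncols)
    Yf_minus = _block_hankel(yn, i + 1, 2 * i - 1, ncols)

    Oi = _oblique_projection(Yf, Uf, Wp)
    Oim1 = _oblique_projection(Yf_minus, Uf_minus, Wp_plus)

    U_svd, S, _ = np.linalg.svd(Oi, full_matrices=False)
    tol = max(Oi.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int(np.sum(S > max(tol, 1e-10)))
    eff_nx = min(nx, max(rank, 1))
    order_reduced = eff_nx < nx

    Gam = U_svd[:, :eff_nx] * np.sqrt(S[:eff_nx])
    Gam_up = Gam[:-1]  # observability matrix with i-1 block rows (l = 1)

    Xi = pinv(Gam) @ Oi
    Xip = pinv(Gam_up) @ Oim1

    Uii = un[i : i + ncols].T  # inputs at time i
    Yii = yn[i : i + ncols].T

    lhs = np.vstack([Xip, Yii])  # (nx+1, ncols)
    rhs = np.vstack([Xi, Uii])  # (nx+m, ncols)
    Theta, *_ = lstsq(rhs.T, lhs.T, rcond=None)
    Theta = Theta.T
    A = Theta[:eff_nx, :eff_nx]
    B = Theta[:eff_nx, eff_nx:]
    C = Theta[eff_nx:, :eff_nx]
    D = Theta[eff_nx:, eff_nx:]

    resid = lhs - Theta @ rhs
    Sigma = (resid @ resid.T) / max(ncols - rhs.shape[0], 1)
    QQ = Sigma[:eff_nx, :eff_nx] + 1e-9 * np.eye(eff_nx)
    RR = Sigma[eff_nx:, eff_nx:] + 1e-9
    SS = Sigma[:eff_nx, eff_nx:]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            P = solve_discrete_are(A.T, C.T, QQ, RR, s=SS)
        K = (A @ P @ C.T + SS) @ np.linalg.inv(C @ P @ C.T + RR)
    except Exception:
        K = np.zeros((eff_nx, 1))

    A, K, stabilized = _stabilize_predictor(A, C, K)

    return StateSpaceModel(
        A=A,
        B=B,
        C=C,
        D=D,
        K=K,
        nx=eff_nx,
        ph=int(ph),
        input_names=tuple(input_names or (f"u{j}" for j in range(m))),
        u_mean=u_mean,
        u_std=u_std,
        y_mean=y_mean,
        y_std=y_std,
        order_reduced=order_reduced,
        predictor_stabilized=stabilized,
    )


def _filter_states(model: StateSpaceModel, un: np.ndarray, yn: np.ndarray) -> np.ndarray:
    """Innovation-form filter; returns states X with X[t] = xhat at time t.

    X has N+1 rows; X[t+1] incorporates data up to and including time t.
    """
    A, B, C, D, K = model.A, model.B, model.C, model.D, model.K
    N = un.shape[0]
    nx = A.shape[0]
    X = np.zeros((N + 1, nx))
    x = np.zeros(nx)
    for t in range(N):
        e = yn[t] - (C @ x)[0] - (D @ un[t])[0]
        x = A @ x + B @ un[t] + (K[:, 0] * e)
        X[t + 1] = x
    return X


def predict_k_ahead(
    model: StateSpaceModel, u: np.ndarray, y: np.ndarray, k: int, clamp: bool = False
) -> np.ndarray:
    """k-step-ahead prediction over a window; entry ``t`` predicts ``y[t]``
    using data up to ``t - k`` only.

    The first ``k`` entries are NaN (no history).  Future inputs are held at
    their last observed value.  With ``clamp=True`` the output is clamped to
    ``OUTPUT_CLAMP`` (the normalized pain-curve scale), as done right before
    the probability mapping of the decider stage.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 100:
        warnings.warn(f"horizon k={k} outside the validated 1..100 range")
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[0] < u.shape[1]:
        u = u.T
    y = np.asarray(y, dtype=float).ravel()
    N = u.shape[0]
    un = (u - model.u_mean) / model.u_std
    yn = (y - model.y_mean) / model.y_std

    X = _filter_states(model, un, yn)
    A, B, C, D = model.A, model.B, model.C, model.D
    # roll states forward k steps with zero innovation and ZOH inputs,
    # batched over every anchor time t: z starts at xhat_{t+1}
    Z = X[1:].copy()  # row t: state after observing time t
    Ucur = un
    for _ in range(k - 1):
        Z = Z @ A.T + Ucur @ B.T
    ypredn = (Z @ C.T + Ucur @ D.T).ravel()  # row t: prediction for time t+k

    yhat = np.full(N, np.nan)
    yhat[k:] = ypredn[: N - k] * model.y_std + model.y_mean
    if clamp:
        yhat = np.clip(yhat, OUTPUT_CLAMP[0], OUTPUT_CLAMP[1])
    return yhat


def simulate(model: StateSpaceModel, u: np.ndarray) -> np.ndarray:
    """Pure simulation with known inputs (no innovation feedback).

    Complements :func:`predict_k_ahead`: used for parameter-recovery checks
    and as an alternative training-fit definition.
    """
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[0] < u.shape[1]:
        u = u.T
    un = (u - model.u_mean) / model.u_std
    A, B, C, D = model.A, model.B, model.C, model.D
    x = np.zeros(model.A.shape[0])
    y = np.zeros(u.shape[0])
    for t in range(u.shape[0]):
        y[t] = (C @ x)[0] + (D @ un[t])[0]
        x = A @ x + B @ un[t]
    return y * model.y_std + model.y_mean


def grid_combinations(
    ph_values: tuple[int, ...] = DEFAULT_PH_GRID,
    nx_values: tuple[int, ...] = DEFAULT_NX_GRID,
) -> list[tuple[int, int]]:
    """Enumerate the training grid of (past horizon, order) pairs."""
    return list(itertools.product(ph_values, nx_values))


@dataclass
class TrainingGridResult:
    """All (ph, nx) fits for one migraine window plus the winning entry."""

    entries: dict = field(default_factory=dict)  # (ph, nx) -> fit % or None
    models: dict = field(default_factory=dict)  # (ph, nx) -> StateSpaceModel
    skipped: list = field(default_factory=list)
    best: tuple[int, int] | None = None

    @property
    def best_model(self) -> StateSpaceModel | None:
        return self.models.get(self.best) if self.best else None

    @property
    def best_fit(self) -> float | None:
        return self.entries.get(self.best) if self.best else None


def train_grid(
    u: np.ndarray,
    y: np.ndarray,
    input_names: tuple[str, ...] | None = None,
    ph_values: tuple[int, ...] = DEFAULT_PH_GRID,
    nx_values: tuple[int, ...] = DEFAULT_NX_GRID,
    fh_train: int = TRAIN_HORIZON,
) -> TrainingGridResult:
    """Fit every (ph, nx) combination on one migraine window.

    Each candidate is scored by the fit of its ``fh_train``-minute-ahead
    prediction on the training window itself; grid rows whose past horizon
    does not fit in the window are skipped and recorded.
    """
    result = TrainingGridResult()
    for ph, nx in grid_combinations(ph_values, nx_values):
        try:
            model = fit_n4sid(u, y, nx=nx, ph=ph, input_names=input_names)
            yhat = predict_k_ahead(model, u, y, fh_train)
            fit = compute_fit(y, yhat)
        except WindowTooShortError:
            result.entries[(ph, nx)] = None
            result.skipped.append((ph, nx))
            continue
        except (np.linalg.LinAlgError, ConstantOutputError, ValueError):
            result.entries[(ph, nx)] = None
            result.skipped.append((ph, nx))
            continue
        result.entries[(ph, nx)] = fit
        result.models[(ph, nx)] = model
        if result.best is None or fit > result.entries[result.best]:
            result.best = (ph, nx)
    return result
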