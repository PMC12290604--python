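"""Voxelwise GLM with per-duration regressors and layer profiles.

Each stimulus duration gets its own boxcar regressor convolved with a
canonical gamma haemodynamic response function (mean lag 6 s, sd 3 s by
default).  Low-frequency drift is absorbed by discrete-cosine regressors
below the high-pass cutoff (0.01 Hz).  Statistics are ordinary least squares;
contrast t values are mapped to z scores by matching CDF quantiles at the
residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import Trial


@dataclass(frozen=True)
class HRFKernel:
    """Sampled unit-area gamma HRF."""

    values: np.ndarray
    dt_s: float
    mean_lag_s: float
    sd_s: float

    @property
    def t(self) -> np.ndarray:
        return self.dt_s * np.arange(self.values.size)

    def moments(self) -> tuple[float, float]:
        """Discrete mean lag and sd of the sampled kernel."""
        w = self.values / self.values.sum()
        m = float((self.t * w).sum())
        sd = float(np.sqrt(((self.t - m) ** 2 * w).sum()))
        return m, sd


def gamma_hrf(mean_lag_s: float = 6.0, sd_s: float = 3.0, dt_s: float = 0.1,
              duration_s: float = 32.0) -> HRFKernel:
    """Gamma HRF by moment matching: shape=(mean/sd)^2, scale=sd^2/mean.

    Sampled at ``dt_s`` over ``duration_s`` and normalized to unit area
    (sum * dt = 1).
    """
    if mean_lag_s <= 0 or sd_s <= 0 or dt_s <= 0:
        raise ValueError("mean lag, sd and dt must be positive")
    shape = (mean_lag_s / sd_s) ** 2
    scale = sd_s**2 / mean_lag_s
    t = np.arange(0.0, duration_s, dt_s)
    vals = stats.gamma.pdf(t, shape, scale=scale)
    vals = vals / (vals.sum() * dt_s)
    return HRFKernel(vals, dt_s, mean_lag_s, sd_s)


def highpass_basis(n_vols: int, dt_s: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Discrete-cosine drift regressors with frequencies below the cutoff.

    Returns an (n_vols, K) matrix with K = floor(2 * T * cutoff) columns,
    cos(pi k (2n+1) / (2 N)) for k = 1..K; empty for cutoff 0.
    """
    if n_vols < 2:
        raise ValueError("need at least two volumes")
    total_s = n_vols * dt_s
    k_max = int(np.floor(2.0 * total_s * cutoff_hz))
    n = np.arange(n_vols)
    cols = [
        np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_vols)) for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_vols, 0))


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_vols, p)
    names: list[str]
    task_columns: list[int]

    def contrast_for(self, duration_s: float) -> np.ndarray:
        c = np.zeros(self.matrix.shape[1])
        c[self.names.index(f"stim_{duration_s:g}s")] = 1.0
        return c


def build_design(
    trials: list[Trial],
    hrf: HRFKernel,
    n_vols: int,
    dt_s: float,
    t0_s: float = 0.0,
    cutoff_hz: float = 0.01,
) -> DesignMatrix:
    """Design matrix with one HRF-convolved boxcar per stimulus duration.

    Boxcars are built and convolved on the HRF's fine grid and sampled at the
    volume acquisition times ``t0 + k*dt``.  Drift (DCT) columns and an
    intercept are appended.  Raises if any task column is identically zero or
    the matrix is rank deficient.
    """
    durations = sorted({tr.duration_s for tr in trials})
    t_vol = t0_s + dt_s * np.arange(n_vols)
    fine_dt = hrf.dt_s
    t_fine = np.arange(0.0, t_vol[-1] + hrf.t[-1] + fine_dt, fine_dt)
    cols = []
    names = []
    for dur in durations:
        box = np.zeros(t_fine.size)
        for tr in trials:
            if tr.duration_s == dur:
                box[(t_fine >= tr.onset_s) & (t_fine < tr.onset_s + dur)] = 1.0
        reg_fine = np.convolve(box, hrf.values)[: t_fine.size] * fine_dt
        reg = np.interp(t_vol, t_fine, reg_fine)
        if not np.any(reg != 0):
            raise ValueError(f"regressor for duration {dur:g}s is identically zero")
        cols.append(reg)
        names.append(f"stim_{dur:g}s")
    task_columns = list(range(len(cols)))
    drift = highpass_basis(n_vols, dt_s, cutoff_hz)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"dct_{k + 1}")
    cols.append(np.ones(n_vols))
    names.append("intercept")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns: "
            f"{names})"
        )
    return DesignMatrix(X, names, task_columns)


@dataclass
class GLMResults:
    """OLS fit of one series against a design matrix."""

    beta: np.ndarray  # (..., p)
    sigma2: np.ndarray  # (...,) residual variance
    df: int
    design: DesignMatrix

    def contrast(self, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Effect size and z map for contrast vector ``c``.

        t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c), converted to z through the
        normal quantile of the t CDF.  Zero-residual-variance voxels are
        flagged NaN.
        """
        X = self.design.matrix
        xtx_inv = np.linalg.inv(X.T @ X)
        var_c = float(c @ xtx_inv @ c)
        effect = self.beta @ c
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(self.sigma2 * var_c)
            t_val = np.where(se > 0, effect / se, np.nan)
        return effect, t_to_z(t_val, self.df)

    def summary(self) -> pd.DataFrame:
        """Mean beta per regressor over valid voxels."""
        flat = self.beta.reshape(-1, self.beta.shape[-1])
        return pd.DataFrame(
            {"regressor": self.design.names, "mean_beta": np.nanmean(flat, axis=0)}
        )


def t_to_z(t_val: np.ndarray, df: int) -> np.ndarray:
    """Convert t statistics to z scores by CDF matching (tail-stable)."""
    t_val = np.asarray(t_val, dtype=float)
    z = np.full(t_val.shape, np.nan)
    ok = np.isfinite(t_val)
    pos = ok & (t_val >= 0)
    neg = ok & (t_val < 0)
    # work on the survival side for numerical stability in the tails
    z[pos] = stats.norm.isf(stats.t.sf(t_val[pos], df))
    z[neg] = -stats.norm.isf(stats.t.sf(-t_val[neg], df))
    return z


def fit_glm(series_data: np.ndarray, design: DesignMatrix) -> GLMResults:
    """Ordinary least squares of a (..., T) array against the design."""
    X = design.matrix
    n, p = X.shape
    data = np.asarray(series_data, dtype=float)
    if data.shape[-1] != n:
        raise ValueError("series length does not match design rows")
    flat = data.reshape(-1, n).T  # (T, voxels)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    # voxels fitted to numerical precision have no meaningful error estimate
    scale = np.mean(flat**2, axis=0)
    sigma2 = np.where(sigma2 <= 1e-24 * scale, 0.0, sigma2)
    return GLMResults(
        beta=beta.T.reshape(data.shape[:-1] + (p,)),
        sigma2=sigma2.reshape(data.shape[:-1]),
        df=df,
        design=design,
    )


def combine_sessions(zmaps: list[np.ndarray]) -> np.ndarray:
    """Fixed-effects (Stouffer) combination: sum(z_i) / sqrt(k)."""
    if not zmaps:
        raise ValueError("need at least one session map")
    shape = zmaps[0].shape
    for z in zmaps[1:]:
        if z.shape != shape:
            raise ValueError("session maps are on different grids")
    return np.sum(zmaps, axis=0) / np.sqrt(len(zmaps))


def layer_profile(
    stat_map: np.ndarray,
    layer_map: np.ndarray,
    roi: np.ndarray | None = None,
    n_layers: int = 11,
) -> np.ndarray:
    """Mean statistic per layer bin (1..n_layers) within an optional ROI.

    Empty bins are flagged NaN.
    """
    sel = layer_map > 0
    if roi is not None:
        sel &= roi.astype(bool)
    profile = np.full(n_layers, np.nan)
    for layer in range(1, n_layers + 1):
        m = sel & (layer_map == layer)
        if m.any():
            profile[layer - 1] = np.nanmean(stat_map[m])
    return profile


def minmax_normalise(profile: np.ndarray) -> np.ndarray:
    """Scale a profile to [0, 1]; raises for constant profiles."""
    profile = np.asarray(profile, dtype=float)
    lo, hi = np.nanmin(profile), np.nanmax(profile)
    if not np.isfinite(hi - lo) or hi == lo:
        raise ValueError("cannot min-max normalise a constant profile")
    return (profile - lo) / (hi - lo)
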