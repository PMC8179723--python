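"""Autocorrelation estimation for photon-count traces.

The estimator is the normalized fluctuation autocorrelation

    G(tau) = < dF(t) dF(t + tau) > / <F>^2,   dF = F - <F>,

with the mean taken over the full trace (the simulation is stationary; no
bleaching correction) and the time average over all valid start times.
tau = 0 is excluded throughout: its shot-noise term is not described by the
diffusion models.  Lags are evaluated by direct summation on a quasi-
logarithmic grid of bin multiples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationCurve",
    "autocorrelate",
    "make_lag_grid",
    "average_curves",
    "residuals",
]


@dataclass(frozen=True)
class CorrelationCurve:
    """Estimated G(tau) on a strictly increasing positive lag grid.

    ``sd`` is the per-lag sample standard deviation across runs (empty array
    for a single run); ``n_runs`` the number of averaged runs.
    """

    lags: np.ndarray  # s
    G: np.ndarray
    sd: np.ndarray
    n_runs: int = 1

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        G = np.asarray(self.G, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if lags.ndim != 1 or len(lags) != len(G):
            raise ValueError("lags and G must be 1D arrays of equal length")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing and positive")
        if not np.all(np.isfinite(G)):
            raise ValueError("G must be finite")
        if sd.size and (len(sd) != len(G) or np.any(sd < 0)):
            raise ValueError("sd must be empty or non-negative, one per lag")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "sd", sd)

    def to_frame(self) -> pd.DataFrame:
        sd = self.sd if self.sd.size else np.full_like(self.G, np.nan)
        return pd.DataFrame({"lag_s": self.lags, "G": self.G, "sd": sd,
                             "n_runs": self.n_runs})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CorrelationCurve":
        df = pd.read_csv(path)
        sd = df["sd"].to_numpy()
        if np.all(np.isnan(sd)):
            sd = np.array([])
        return cls(lags=df["lag_s"].to_numpy(), G=df["G"].to_numpy(), sd=sd,
                   n_runs=int(df["n_runs"].iloc[0]))


def make_lag_grid(dt: float, n_steps: int, points_per_decade: int = 8) -> np.ndarray:
    """Quasi-logarithmic lag grid: integer multiples of ``dt`` approximately
    log-spaced from ``dt`` to ``n_steps * dt / 10``, deduplicated."""
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    max_k = max(1, n_steps // 10)
    n_decades = np.log10(max_k) if max_k > 1 else 1.0
    n_pts = max(2, int(np.ceil(n_decades * points_per_decade)) + 1)
    ks = np.unique(np.round(np.geomspace(1, max_k, n_pts)).astype(np.int64))
    return ks * dt


def autocorrelate(trace, lag_grid: np.ndarray, mean: float | None = None) -> CorrelationCurve:
    """Estimate G on ``lag_grid`` (multiples of the bin width) from one trace.

    ``mean`` overrides the reference intensity ⟨F⟩ used for both the
    fluctuations and the normalization; pass the mean pooled over several
    independent runs to shrink the finite-trace normalization bias (the
    self-estimated mean subtracts a fraction ~(2/T)∫G dτ of the amplitude,
    which is material when G(0) is large and the trace covers few correlation
    times).
    """
    counts = np.asarray(trace.counts, dtype=np.float64)
    dt = trace.dt
    n = len(counts)
    mean = counts.mean() if mean is None else float(mean)
    if mean <= 0.0:
        raise ValueError("trace has zero mean intensity; G is undefined")
    lag_grid = np.asarray(lag_grid, dtype=float)
    ks = np.round(lag_grid / dt).astype(np.int64)
    if np.any(np.abs(ks * dt - lag_grid) > 1e-9 * dt + 1e-30):
        raise ValueError("lags must be integer multiples of the bin width")
    if np.any(ks < 1):
        raise ValueError("tau = 0 and negative lags are excluded")
    if np.any(ks > n // 10):
        raise ValueError("maximum lag must not exceed one tenth of the trace")

    delta = counts - mean
    G = np.empty(len(ks))
    for i, k in enumerate(ks):
        G[i] = np.dot(delta[:-k], delta[k:]) / (n - k)
    G /= mean**2
    return CorrelationCurve(lags=ks * dt, G=G, sd=np.array([]), n_runs=1)


def average_curves(curves) -> CorrelationCurve:
    """Per-lag mean and sample standard deviation (n-1) across runs."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if len(c.lags) != len(lags) or not np.allclose(c.lags, lags):
            raise ValueError("curves must share an identical lag grid")
    stack = np.vstack([c.G for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    return CorrelationCurve(lags=lags, G=mean, sd=sd, n_runs=len(curves))


def residuals(curve: CorrelationCurve, model_values) -> np.ndarray:
    """Normalized residuals (G - model)/sd per lag; lags with sd = 0 yield NaN
    (flagged as excluded)."""
    model_values = np.asarray(model_values, dtype=float)
    if not curve.sd.size:
        raise ValueError("curve has no per-lag standard deviations")
    if model_values.shape != curve.G.shape:
        raise ValueError("model values must match the curve's lag grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = (curve.G - model_values) / curve.sd
    return np.where(curve.sd > 0, res, np.nan)
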