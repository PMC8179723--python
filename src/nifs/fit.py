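"""Weighted nonlinear least-squares fitting of correlation curves.

Fits one of the three ACF models to a :class:`~nifs.correlate.CorrelationCurve`
by trust-region least squares on log-transformed parameters (positivity
without explicit constraints), with a heuristic initial guess and a small
number of jittered restarts.  For the piecewise 2D model the branch-switch
time is not free: it is iterated to the intersection of the two fitted
branches (an outer fixed point, matching how the crossover is defined).

An optional additive offset absorbs the small negative bias of the
finite-trace fluctuation-ACF estimator (the trace mean is estimated from the
same trace); it matters for the slowest-decaying conventional-FCS curves at
desk-scale trace lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .correlate import CorrelationCurve, residuals as curve_residuals
from .models import (
    DerivedQuantities,
    ModelParams,
    branch_intersection,
    evaluate_model,
)

__all__ = ["FitResult", "initial_guess", "fit_curve", "derive_quantities"]

_FREE = {
    "FCS3D": ("G0", "tau_d", "kappa"),
    "NIFS3D": ("G0", "tau_d", "tau_z"),
    "NIFS2D": ("G0", "tau_d", "tau_c"),
}


@dataclass(frozen=True)
class FitResult:
    """Converged fit of one model to one averaged correlation curve."""

    model: str
    params: ModelParams
    stderr: dict
    lags: np.ndarray
    residuals: np.ndarray  # (G - model)/sd at the fitted lags (or unweighted)
    redchi: float
    n_restarts: int
    success: bool
    derived: DerivedQuantities | None = None

    def model_values(self, tau=None) -> np.ndarray:
        return evaluate_model(self.lags if tau is None else tau, self.params)

    def summary(self) -> dict:
        out = {"model": self.model, "redchi": self.redchi, "success": self.success}
        for name in _FREE[self.model] + ("tau_crit", "offset"):
            v = getattr(self.params, name, None)
            if v is not None:
                out[name] = v
                if name in self.stderr:
                    out[name + "_stderr"] = self.stderr[name]
        return out


def initial_guess(curve: CorrelationCurve, model: str) -> ModelParams:
    """Heuristic starting parameters: amplitude from the smallest lags, the
    lateral time from the half-decay lag, companion times from fixed ratios.

    Raises for flat or non-decaying curves (no half-decay crossing).
    """
    if len(curve.lags) < 10 or curve.lags[-1] / curve.lags[0] < 100:
        raise ValueError("need >= 10 lags spanning >= 2 decades for a guess")
    G0 = float(np.median(curve.G[:3]))
    tail = float(np.median(curve.G[-3:]))
    if not np.isfinite(G0) or G0 <= 0:
        raise ValueError("curve amplitude is not positive; cannot form a guess")
    if tail > 0.5 * G0:
        raise ValueError("curve does not decay; cannot form an initial guess")
    half = 0.5 * G0
    below = np.where(curve.G < half)[0]
    if len(below) == 0:
        raise ValueError("curve never falls below half its amplitude")
    i = below[0]
    if i == 0:
        tau_half = curve.lags[0]
    else:
        # log-linear interpolation of the half crossing
        l0, l1 = np.log(curve.lags[i - 1]), np.log(curve.lags[i])
        g0_, g1_ = curve.G[i - 1], curve.G[i]
        f = (g0_ - half) / max(g0_ - g1_, 1e-300)
        tau_half = float(np.exp(l0 + f * (l1 - l0)))
    if model == "FCS3D":
        return ModelParams(model=model, G0=G0, tau_d=tau_half, kappa=3.0)
    if model == "NIFS3D":
        # the axial term dominates the decay when tau_z << tau_D
        return ModelParams(model=model, G0=G0, tau_d=10.0 * tau_half,
                           tau_z=tau_half)
    if model == "NIFS2D":
        # small branch falls to G0/2 at tau = 3 tau_d
        tau_d = tau_half / 3.0
        p = ModelParams(model=model, G0=G0, tau_d=tau_d, tau_c=3.0 * tau_d)
        return p.with_tau_crit()
    raise ValueError(f"unknown model {model!r}")


def _smooth_sd(sd: np.ndarray, half_window: int = 2) -> np.ndarray:
    """Geometric moving average of the per-lag standard deviations.

    A sample sd from a handful of runs is itself noisy and correlated with
    the same-lag fluctuation of the mean; weighting by the raw 1/sd then
    systematically over-trusts downward-fluctuated points.  The true
    correlation error varies smoothly with lag, so averaging log(sd) over
    neighboring lags keeps the heteroscedastic structure while decorrelating
    the weight from the point it weights.
    """
    logs = np.log(sd)
    out = np.empty_like(logs)
    n = len(logs)
    for i in range(n):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        out[i] = logs[lo:hi].mean()
    return np.exp(out)


def _pack(params: ModelParams, fit_offset: bool, fixed: dict) -> tuple:
    names = [n for n in _FREE[params.model] if n not in fixed]
    x0 = [np.log(getattr(params, n)) for n in names]
    if fit_offset:
        names.append("offset")
        x0.append(params.offset)
    return names, np.array(x0, dtype=float)


def _unpack(x, names, template: ModelParams) -> ModelParams:
    kw = {}
    for name, v in zip(names, x):
        kw[name] = float(v) if name == "offset" else float(np.exp(v))
    return replace(template, **kw)


def fit_curve(curve: CorrelationCurve, model: str, weights: str = "sd",
              p0: ModelParams | None = None, fit_offset: bool = False,
              fixed: dict | None = None, max_restarts: int = 5,
              restart_seed: int = 0) -> FitResult:
    """Fit ``model`` to ``curve`` with weights ``"sd"`` (1/sd, lags with
    sd = 0 excluded) or ``"uniform"``.

    ``fixed`` pins named parameters (e.g. ``{"kappa": 3.0}``).  Restarts from
    jittered initial guesses (deterministic jitter) guard against poor local
    minima; the best result is returned, with ``success=False`` only if no
    attempt converged.
    """
    if weights not in ("sd", "uniform"):
        raise ValueError("weights must be 'sd' or 'uniform'")
    fixed = dict(fixed or {})
    if weights == "sd":
        if not curve.sd.size:
            raise ValueError("1/sd weighting needs a multi-run curve with sd")
        mask = curve.sd > 0
    else:
        mask = np.ones(len(curve.lags), dtype=bool)
    lags = curve.lags[mask]
    G = curve.G[mask]
    if weights == "sd":
        w = 1.0 / _smooth_sd(curve.sd[mask])
    else:
        w = np.ones_like(G)

    template = p0 if p0 is not None else initial_guess(curve, model)
    template = replace(template, **fixed)
    names, x0 = _pack(template, fit_offset, fixed)

    # generous box constraints around the guess keep the trust region out of
    # degenerate corners (e.g. kappa -> inf with a large negative offset)
    lb, ub = [], []
    for name, x in zip(names, x0):
        if name == "offset":
            lim = 0.5 * template.G0
            lb.append(-lim)
            ub.append(lim)
        elif name == "kappa":
            lb.append(0.0)  # kappa >= 1
            ub.append(np.log(50.0))
        else:
            lb.append(x - np.log(1e3))
            ub.append(x + np.log(1e3))
    lb, ub = np.array(lb), np.array(ub)
    x0 = np.clip(x0, lb, ub)

    def solve(tmpl, x_start):
        crit_tmpl = tmpl

        def resid(x):
            p = _unpack(x, names, crit_tmpl)
            return (evaluate_model(lags, p) - G) * w

        best = None
        for _ in range(11 if model == "NIFS2D" else 1):
            res = least_squares(resid, np.clip(x_start, lb, ub), method="trf",
                                bounds=(lb, ub), x_scale="jac", max_nfev=2000)
            p = _unpack(res.x, names, crit_tmpl)
            if model != "NIFS2D":
                return res, p
            # outer fixed point: branch switch at the fitted intersection
            try:
                crit = branch_intersection(p.tau_d / p.tau_c) * p.tau_c
            except ValueError:
                return res, p
            prev = crit_tmpl.tau_crit or np.inf
            crit_tmpl = replace(crit_tmpl, tau_crit=crit)
            p = replace(p, tau_crit=crit)
            best = (res, p)
            x_start = res.x
            if abs(crit - prev) <= 0.01 * crit:
                break
        return best

    rng = np.random.default_rng(restart_seed)
    best_res, best_p, attempts = None, None, 0
    x_try = x0.copy()
    for attempt in range(max_restarts + 1):
        attempts = attempt
        try:
            res, p = solve(template, x_try)
        except Exception:
            res = None
        if res is not None and (best_res is None or res.cost < best_res.cost):
            best_res, best_p = res, p
        if best_res is not None and best_res.status > 0:
            break
        jitter = rng.normal(0.0, np.log(2.0), size=len(x0))
        x_try = np.clip(x0 + np.where([n == "offset" for n in names], 0.0, jitter), lb, ub)
    if best_res is None:
        raise RuntimeError(f"fit of model {model} failed to converge")

    m, npar = len(G), len(names)
    dof = max(m - npar, 1)
    wres = (evaluate_model(lags, best_p) - G) * w
    redchi = float(np.sum(wres**2) / dof)

    # parameter covariance from the weighted Jacobian at the optimum
    # (approximate; log-parameters transformed back via sigma_p = p * sigma_logp)
    stderr = {}
    try:
        J = best_res.jac
        cov = np.linalg.pinv(J.T @ J) * max(redchi, np.finfo(float).tiny)
        sig = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        for name, s in zip(names, sig):
            val = getattr(best_p, name)
            stderr[name] = float(s if name == "offset" else abs(val) * s)
    except Exception:
        pass

    if weights == "sd":
        full_model = evaluate_model(curve.lags, best_p)
        norm_res = curve_residuals(curve, full_model)
    else:
        norm_res = evaluate_model(curve.lags, best_p) - curve.G

    return FitResult(model=model, params=best_p, stderr=stderr, lags=curve.lags,
                     residuals=norm_res, redchi=redchi, n_restarts=attempts,
                     success=bool(best_res.status > 0))


def derive_quantities(fit: FitResult, concentration: float) -> DerivedQuantities:
    """Effective volume/area and mean occupancy from the fitted amplitude and
    the known simulation concentration.

    FCS3D: Veff = 1/(G0 C); NIFS3D: Veff = 1/(2 G0 C); NIFS2D: Aeff = 1/(G0 C).
    """
    G0 = fit.params.G0
    if G0 <= 0:
        raise ValueError("fitted amplitude must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if fit.model == "FCS3D":
        veff = 1.0 / (G0 * concentration)
        return DerivedQuantities(veff=veff, n_molecules=veff * concentration,
                                 concentration=concentration)
    if fit.model == "NIFS3D":
        veff = 1.0 / (2.0 * G0 * concentration)
        return DerivedQuantities(veff=veff, n_molecules=veff * concentration,
                                 concentration=concentration)
    aeff = 1.0 / (G0 * concentration)
    return DerivedQuantities(aeff=aeff, n_molecules=aeff * concentration,
                             concentration=concentration)
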