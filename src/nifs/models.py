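"""Closed-form autocorrelation models for conventional and nanowaveguide FCS.

Three models are implemented, matched to the three illumination/diffusion
scenarios:

``FCS3D``
    Free 3D diffusion through a Gaussian-ellipsoid focus::

        G(tau) = G0 (1 + tau/tauD)^-1 (1 + tau/(kappa^2 tauD))^-1/2,
        G0 = 1/(Veff <C>),  Veff = pi^(3/2) r0^2 z0,  tauD = r0^2/(4D).

``NIFS3D``
    Half-space diffusion above the waveguide exit plane (reflecting wall),
    lateral Gaussian times exponential axial decay; the axial part is the
    evanescent-illumination result familiar from TIR-FCS::

        G(tau) = G0 (1 + tau/tauD)^-1
                 [ sqrt(tau/(pi tauz)) + (1 - tau/(2 tauz)) erfcx(sqrt(tau/(4 tauz))) ],
        G0 = 1/(2 Veff <C>),  Veff = pi r0^2 z0,  tauz = z0^2/(4D).

``NIFS2D``
    In-plane diffusion through the annular edge field, approximated by a
    piecewise two-timescale function with a shared amplitude G0::

        tau <= tau_crit:  G0 (1 + tau/tauD)^-1/2            (radial, 1D Gaussian)
        tau  > tau_crit:  G0 sqrt(4 pi (tauC/tau)(tauD/tau))
                          [1 + (tauC/tau)^2 + (tauC/tau)^4/4] exp(-2 tauC/tau)

    with tauD = b0^2/(2D), tauC = a0^2/(4D).  The bracket is the truncated
    series of I0(2 tauC/tau), the angular ring-to-ring correlation.  The two
    branches intersect at tau ~ 8 tauC for the nominal geometry
    (tauD/tauC = 2 b0^2/a0^2 = 0.32); ``tau_crit`` defaults to that
    intersection, found by root-finding (:func:`branch_intersection`).

A brute-force numeric oracle (:func:`numeric_acf_oracle`) evaluates the
underlying double integral of the ACF over the illumination profile and the
diffusion propagator by quadrature, independently of the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import integrate, special
from scipy.optimize import brentq

from .illumination import AnnularProfile, GaussianEllipsoidProfile, Nifs3DProfile

__all__ = [
    "ModelParams",
    "DerivedQuantities",
    "acf_fcs3d",
    "acf_nifs3d",
    "acf_nifs2d",
    "nifs2d_branches",
    "branch_intersection",
    "erfcx",
    "evaluate_model",
    "effective_volume",
    "effective_area_consistent",
    "characteristic_times",
    "numeric_acf_oracle",
]

MODELS = ("FCS3D", "NIFS3D", "NIFS2D")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one of the three ACF models.

    Times in seconds; ``G0`` dimensionless.  ``kappa`` applies to FCS3D,
    ``tau_z`` to NIFS3D, ``tau_c``/``tau_crit`` to NIFS2D.
    """

    model: str
    G0: float
    tau_d: float
    kappa: float | None = None
    tau_z: float | None = None
    tau_c: float | None = None
    tau_crit: float | None = None
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not (self.G0 > 0 and self.tau_d > 0):
            raise ValueError("G0 and tau_d must be positive")
        if self.model == "FCS3D":
            if self.kappa is None or self.kappa < 1:
                raise ValueError("FCS3D requires kappa >= 1")
        elif self.model == "NIFS3D":
            if self.tau_z is None or self.tau_z <= 0:
                raise ValueError("NIFS3D requires tau_z > 0")
        else:
            if self.tau_c is None or self.tau_c <= 0:
                raise ValueError("NIFS2D requires tau_c > 0")

    def with_tau_crit(self) -> "ModelParams":
        """Return a copy with tau_crit set to the branch intersection."""
        if self.model != "NIFS2D":
            return self
        xc = branch_intersection(self.tau_d / self.tau_c)
        return replace(self, tau_crit=xc * self.tau_c)


@dataclass(frozen=True)
class DerivedQuantities:
    """Quantities derived from a fitted amplitude and a known concentration."""

    veff: float | None = None  # m^3
    aeff: float | None = None  # m^2
    n_molecules: float | None = None
    concentration: float | None = None  # 1/m^3 or 1/m^2


def _check_tau(tau) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("negative delay time")
    return tau


def erfcx(x):
    """Scaled complementary error function exp(x^2) erfc(x), overflow-safe."""
    return special.erfcx(np.asarray(x, dtype=float))


def acf_fcs3d(tau, params: ModelParams) -> np.ndarray:
    """Conventional-FCS ACF (free 3D diffusion, Gaussian-ellipsoid focus)."""
    tau = _check_tau(tau)
    g = (1.0 + tau / params.tau_d) ** -1.0
    g = g * (1.0 + tau / (params.kappa**2 * params.tau_d)) ** -0.5
    return params.G0 * g + params.offset


def acf_nifs3d(tau, params: ModelParams) -> np.ndarray:
    """3D NIFS ACF (half-space diffusion, exponential axial illumination)."""
    tau = _check_tau(tau)
    s = tau / params.tau_z
    bracket = np.sqrt(s / np.pi) + (1.0 - s / 2.0) * special.erfcx(np.sqrt(s / 4.0))
    return params.G0 * (1.0 + tau / params.tau_d) ** -1.0 * bracket + params.offset


def nifs2d_branches(tau, params: ModelParams):
    """Return (small-timescale, large-timescale) branch values of the 2D model,
    both with the shared amplitude ``G0`` and without the offset."""
    tau = _check_tau(tau)
    small = params.G0 * (1.0 + tau / params.tau_d) ** -0.5
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        zc = np.where(tau > 0, params.tau_c / tau, np.inf)
        poly = 1.0 + zc**2 + 0.25 * zc**4
        pref = np.sqrt(4.0 * np.pi * zc * (params.tau_d / np.where(tau > 0, tau, 1.0)))
        large = params.G0 * pref * poly * np.exp(-2.0 * zc)
    large = np.where(tau > 0, large, 0.0)
    return small, large


def branch_intersection(tau_d_over_tau_c: float) -> float:
    """Delay time, in units of tauC, where the two branches of the 2D model
    are equal above tauC (the crossover the figure caption identifies at
    ~8 tauC for tauD/tauC = 0.32).  The shared amplitude cancels.

    Raises ``ValueError`` when no crossing exists above tauC.
    """
    rho = float(tau_d_over_tau_c)
    if rho <= 0:
        raise ValueError("tau_d/tau_c must be positive")
    p = ModelParams(model="NIFS2D", G0=1.0, tau_d=rho, tau_c=1.0, tau_crit=1.0)

    def diff(x):
        s, l = nifs2d_branches(np.asarray([x]), p)
        return float(l[0] - s[0])

    xs = np.geomspace(1.0, 1e4, 600)
    vals = np.array([diff(x) for x in xs])
    sign = np.sign(vals)
    idx = np.where(sign[:-1] * sign[1:] < 0)[0]
    if len(idx) == 0:
        raise ValueError("branches do not intersect for tau > tauC")
    i = idx[-1]  # crossing where the large branch drops below the small one
    return brentq(diff, xs[i], xs[i + 1], xtol=1e-12, rtol=1e-12)


def acf_nifs2d(tau, params: ModelParams) -> np.ndarray:
    """2D NIFS ACF: piecewise small/large-timescale branches switched at
    ``tau_crit`` (default: the branch intersection)."""
    tau = _check_tau(tau)
    if params.tau_crit is None:
        params = params.with_tau_crit()
    small, large = nifs2d_branches(tau, params)
    return np.where(tau <= params.tau_crit, small, large) + params.offset


_ACF = {"FCS3D": acf_fcs3d, "NIFS3D": acf_nifs3d, "NIFS2D": acf_nifs2d}


def evaluate_model(tau, params: ModelParams) -> np.ndarray:
    """Dispatch to the ACF of ``params.model``."""
    return _ACF[params.model](tau, params)


def effective_volume(model: str, *, r0=None, z0=None, a0=None, b0=None) -> float:
    """Effective illumination volume (m^3) or area (m^2) of a model.

    FCS3D: pi^(3/2) r0^2 z0; NIFS3D: pi r0^2 z0; NIFS2D: 2 pi^(3/2) a0 b0
    (the printed closed form; see :func:`effective_area_consistent` for the
    amplitude-consistent variant).
    """
    if model == "FCS3D":
        return float(np.pi**1.5 * r0**2 * z0)
    if model == "NIFS3D":
        return float(np.pi * r0**2 * z0)
    if model == "NIFS2D":
        return float(2.0 * np.pi**1.5 * a0 * b0)
    raise ValueError(f"unknown model {model!r}")


def effective_area_consistent(a0: float, b0: float) -> float:
    """Effective area 2*sqrt(2)*pi^(3/2)*a0*b0 (m^2): the value implied by the
    annular profile's own normalization integral ratio (intW)^2 / intW^2 and
    by the shared-amplitude piecewise ACF; larger by sqrt(2) than the printed
    closed form."""
    return float(2.0 * np.sqrt(2.0) * np.pi**1.5 * a0 * b0)


def characteristic_times(D: float, *, r0=None, z0=None, a0=None, b0=None) -> dict:
    """Characteristic diffusion times (s) from a diffusion constant (m^2/s).

    Returns whichever of tau_d (lateral Gaussian r0^2/4D), tau_z (axial decay
    z0^2/4D), tau_d_2d (radial width b0^2/2D) and tau_c (annulus radius
    a0^2/4D) the supplied lengths allow.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    out = {}
    if r0 is not None:
        out["tau_d"] = r0**2 / (4.0 * D)
    if z0 is not None:
        out["tau_z"] = z0**2 / (4.0 * D)
    if b0 is not None:
        out["tau_d_2d"] = b0**2 / (2.0 * D)
    if a0 is not None:
        out["tau_c"] = a0**2 / (4.0 * D)
    return out


# ---------------------------------------------------------------------------
# numeric oracle
# ---------------------------------------------------------------------------

def _gauss_panel(lo, hi, n):
    u, w = leggauss(n)
    return 0.5 * (hi - lo) * u + 0.5 * (hi + lo), 0.5 * (hi - lo) * w


def _axis_factor_free(tau, D, w0, n):
    """int W(u) W(v) g(u-v) du dv / (int W)^2 along one axis for the profile
    exp(-2 u^2 / w0^2) and free diffusion (units 1/length); the node count
    adapts so the propagator ridge of width sqrt(4 D tau) stays resolved."""
    width = np.sqrt(4.0 * D * tau)
    span = 3.0 * w0
    n_eff = min(max(n, int(8.0 * 2.0 * span / max(width, w0 / 60.0))), 3600)
    x, wx = _gauss_panel(-span, span, n_eff)
    W = np.exp(-2.0 * x**2 / w0**2)
    s = 4.0 * D * tau
    X, Xp = np.meshgrid(x, x, indexing="ij")
    g = np.exp(-((X - Xp) ** 2) / s) / np.sqrt(np.pi * s)
    num = np.einsum("i,j,ij->", W * wx, W * wx, g)
    return num / np.sum(W * wx) ** 2


def _axial_factor_halfspace(tau, D, z0, n):
    """As above for profile exp(-z/z0) on z >= 0 with a reflecting wall at 0
    (method-of-images propagator).

    In sum/difference coordinates u = (z+z')/2, v = z-z' the v-integral of
    each image term is an exact Gaussian integral, leaving a smooth 1D
    integral over u that adaptive quadrature handles at any tau:

        N = int_0^inf e^(-2u/z0) [ erf(2u/sqrt(s)) + (4u/sqrt(pi s)) e^(-4u^2/s) ] du,

    s = 4 D tau; the normalized factor is N / z0^2.
    """
    s = 4.0 * D * tau
    q = np.sqrt(s) / z0  # propagator width in units of z0

    def integrand(t):  # u = z0 * t
        return np.exp(-2.0 * t) * (
            special.erf(2.0 * t / q) + (4.0 * t / (np.sqrt(np.pi) * q)) * np.exp(-4.0 * t**2 / q**2)
        )

    split = min(25.0, max(1e-4, 3.0 * q))
    val = err = 0.0
    for lo, hi in ((0.0, split), (split, max(30.0, 10.0 * q + 30.0))):
        v, e = integrate.quad(integrand, lo, hi, epsabs=0.0, epsrel=1e-11, limit=400)
        val += v
        err += e
    if err > 1e-6 * abs(val):
        raise RuntimeError("half-space axial quadrature did not converge")
    return val / z0


def _plane_factor_annular(tau, D, profile: AnnularProfile, n):
    """In-plane <W W' P> for the annular profile and free 2D diffusion,
    using the polar form with the exponentially scaled Bessel function."""
    width = np.sqrt(4.0 * D * tau)
    rmax = profile.a0 + 6.0 * profile.b0
    n_eff = max(n, int(8.0 * rmax / max(width, profile.b0 / 60.0)))
    n_eff = min(n_eff, 3600)
    r, wr = _gauss_panel(0.0, rmax, n_eff)
    W = profile.evaluate_radial(r)
    s = 4.0 * D * tau
    R, Rp = np.meshgrid(r, r, indexing="ij")
    ker = special.i0e(2.0 * R * Rp / s) * np.exp(-((R - Rp) ** 2) / s) / (np.pi * s)
    num = np.einsum("i,j,ij->", W * r * wr, W * r * wr, ker) * (2.0 * np.pi) ** 2
    return num / (2.0 * np.pi * np.sum(W * r * wr)) ** 2


def numeric_acf_oracle(profile, D: float, geometry: str, tau, n_nodes: int = 400,
                       rtol: float = 1e-4):
    """Concentration-scaled ACF ``G(tau) * <C>`` by direct quadrature of the
    profile-weighted diffusion propagator.

    geometry: ``free3D`` (Gaussian ellipsoid, separable axes), ``halfspace3D``
    (lateral Gaussian x reflecting-wall exponential axial), or ``plane2D``
    (annular profile, free in-plane diffusion).  Convergence is checked by
    doubling the node count; non-convergence raises with the achieved
    tolerance.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau <= 0):
        raise ValueError("oracle requires tau > 0")

    def one(t, n):
        if geometry == "free3D":
            if not isinstance(profile, GaussianEllipsoidProfile):
                raise TypeError("free3D oracle expects a GaussianEllipsoidProfile")
            lat = _axis_factor_free(t, D, profile.r0, n)
            ax = _axis_factor_free(t, D, profile.z0, n)
            return lat * lat * ax
        if geometry == "halfspace3D":
            if not isinstance(profile, Nifs3DProfile):
                raise TypeError("halfspace3D oracle expects a Nifs3DProfile")
            lat = _axis_factor_free(t, D, profile.r0, n)
            ax = _axial_factor_halfspace(t, D, profile.z0, n)
            return lat * lat * ax
        if geometry == "plane2D":
            if not isinstance(profile, AnnularProfile):
                raise TypeError("plane2D oracle expects an AnnularProfile")
            return _plane_factor_annular(t, D, profile, n)
        raise ValueError(f"unknown geometry {geometry!r}")

    out = np.empty_like(tau)
    for i, t in enumerate(tau):
        coarse, fine = one(t, n_nodes), one(t, int(1.5 * n_nodes))
        if abs(fine - coarse) > rtol * abs(fine):
            raise RuntimeError(
                f"oracle quadrature not converged at tau={t:g}: "
                f"rel. change {abs(fine - coarse) / abs(fine):.2e} > rtol={rtol:g}"
            )
        out[i] = fine
    return out if out.size > 1 else float(out[0])
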