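"""Illumination profiles for conventional and nanowaveguide-illuminated FCS.

All profiles are dimensionless shapes normalized to a peak value of 1; the
absolute excitation amplitude lives in the simulator's ``brightness``
parameter.  The coordinate convention is that ``z = 0`` is the waveguide exit
plane and ``z > 0`` is the sample half-space.

Three analytic shapes are provided:

* :class:`GaussianEllipsoidProfile` -- the diffraction-limited confocal focus,
  ``W = exp(-2(x^2+y^2)/r0^2) * exp(-2 z^2/z0^2)``.
* :class:`Nifs3DProfile` -- the near field emerging from a nanowire waveguide,
  laterally Gaussian with an exponential axial decay,
  ``W = exp(-2(x^2+y^2)/r0^2) * exp(-z/z0)`` for ``z > 0`` and exactly 0 for
  ``z < 0`` (fluorophores cannot enter the waveguide).
* :class:`AnnularProfile` -- the ring-shaped field enhancement at the waveguide
  edge radius close to the exit surface (lightning-rod effect),
  ``W = exp(-(r - a0)^2 / b0^2)`` with ``r = sqrt(x^2+y^2)``.

A :class:`GridProfile` holds a grid-sampled intensity map (e.g. exported from
an electromagnetic field solver) and evaluates it by interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GaussianEllipsoidProfile",
    "Nifs3DProfile",
    "AnnularProfile",
    "GridProfile",
    "eval_profile",
    "profile_volume_integral",
]


def _check_positions(position: np.ndarray) -> np.ndarray:
    pos = np.asarray(position, dtype=float)
    if pos.shape[-1] != 3:
        raise ValueError(f"positions must have a trailing axis of length 3, got shape {pos.shape}")
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite position passed to illumination profile")
    return pos


@dataclass(frozen=True)
class GaussianEllipsoidProfile:
    """Gaussian-ellipsoid confocal focus.

    Parameters
    ----------
    r0 : float
        Lateral 1/e^2 radius (m).
    z0 : float
        Axial 1/e^2 half-length (m).  ``kappa = z0 / r0`` is the oblateness.
    """

    r0: float
    z0: float

    def __post_init__(self) -> None:
        if not (self.r0 > 0 and self.z0 > 0):
            raise ValueError("r0 and z0 must be positive")

    @property
    def kappa(self) -> float:
        return self.z0 / self.r0

    def evaluate(self, position) -> np.ndarray:
        pos = _check_positions(position)
        x, y, z = pos[..., 0], pos[..., 1], pos[..., 2]
        return np.exp(-2.0 * (x * x + y * y) / self.r0**2 - 2.0 * z * z / self.z0**2)

    def analytic_integral(self) -> float:
        """Closed form of the volume integral, (pi/2)^(3/2) r0^2 z0."""
        return (np.pi / 2.0) ** 1.5 * self.r0**2 * self.z0


@dataclass(frozen=True)
class Nifs3DProfile:
    """Near field above a nanowire waveguide exit: lateral Gaussian times an
    exponential axial decay, zero inside the waveguide (z < 0).

    Parameters
    ----------
    r0 : float
        Lateral extent (m); ~60 nm for a 40-nm-diameter wire.
    z0 : float
        Axial decay length (m); ~12 nm.
    """

    r0: float
    z0: float

    def __post_init__(self) -> None:
        if not (self.r0 > 0 and self.z0 > 0):
            raise ValueError("r0 and z0 must be positive")

    def evaluate(self, position) -> np.ndarray:
        pos = _check_positions(position)
        x, y, z = pos[..., 0], pos[..., 1], pos[..., 2]
        w = np.exp(-2.0 * (x * x + y * y) / self.r0**2 - np.clip(z, 0.0, None) / self.z0)
        return np.where(z < 0.0, 0.0, w)

    def analytic_integral(self) -> float:
        """Closed form of the volume integral over z > 0, (pi/2) r0^2 z0."""
        return (np.pi / 2.0) * self.r0**2 * self.z0


@dataclass(frozen=True)
class AnnularProfile:
    """Annular Gaussian centered at the waveguide edge radius, used when the
    motion is confined to a plane just above the exit surface.

    Parameters
    ----------
    a0 : float
        Annulus radius (m); the nanowire radius, ~20 nm.
    b0 : float
        Annular Gaussian width (m); ~8 nm.
    """

    a0: float
    b0: float

    def __post_init__(self) -> None:
        if not (self.a0 > 0 and self.b0 > 0):
            raise ValueError("a0 and b0 must be positive")

    def evaluate(self, position) -> np.ndarray:
        pos = _check_positions(position)
        x, y = pos[..., 0], pos[..., 1]
        r = np.sqrt(x * x + y * y)
        return np.exp(-((r - self.a0) ** 2) / self.b0**2)

    def evaluate_radial(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return np.exp(-((r - self.a0) ** 2) / self.b0**2)

    def asymptotic_integral(self) -> float:
        """Thin-ring (a0 >> b0) limit of the in-plane area integral,
        2 pi^(3/2) a0 b0."""
        return 2.0 * np.pi**1.5 * self.a0 * self.b0


@dataclass(frozen=True)
class GridProfile:
    """Grid-sampled intensity profile with multilinear (default) interpolation.

    ``axes`` are the monotone grid coordinates (2 axes for an in-plane map,
    3 for a volume map) and ``values`` the non-negative, peak-normalized
    intensities; positions outside the grid extent evaluate to 0.
    """

    axes: tuple
    values: np.ndarray
    order: int = 1  # 1 = multilinear, 0 = nearest
    _interp: RegularGridInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        values = np.asarray(self.values, dtype=float)
        if len(axes) not in (2, 3):
            raise ValueError("GridProfile needs 2 or 3 axes")
        if values.shape != tuple(len(a) for a in axes):
            raise ValueError("values shape does not match axes")
        for a in axes:
            if len(a) < 2 or np.any(np.diff(a) <= 0):
                raise ValueError("axes must be strictly increasing with >= 2 points")
        if np.any(values < 0):
            raise ValueError("grid intensities must be non-negative")
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "values", values)
        method = "nearest" if self.order == 0 else "linear"
        interp = RegularGridInterpolator(
            axes, values, method=method, bounds_error=False, fill_value=0.0
        )
        object.__setattr__(self, "_interp", interp)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def evaluate(self, position) -> np.ndarray:
        pos = _check_positions(position)
        pts = pos[..., : self.ndim]
        return np.clip(self._interp(pts), 0.0, None)

    @classmethod
    def from_profile(cls, profile, axes, order: int = 1) -> "GridProfile":
        """Sample an analytic profile on a rectilinear grid."""
        axes = tuple(np.asarray(a, dtype=float) for a in axes)
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.zeros(mesh[0].shape + (3,))
        for i, m in enumerate(mesh):
            pts[..., i] = m
        return cls(axes=axes, values=np.asarray(eval_profile(profile, pts)), order=order)

    @classmethod
    def from_csv(cls, path, order: int = 1) -> "GridProfile":
        """Read the documented plain-text grid format.

        Header lines ``axis,<name>,v1,v2,...`` (one per axis, in x,y[,z]
        order), followed by the intensity values row-major: one comma-separated
        line per index of the leading axes, each holding ``len(last axis)``
        values.
        """
        axes, rows = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(",")
                if parts[0] == "axis":
                    axes.append(np.array([float(v) for v in parts[2:]]))
                else:
                    rows.append([float(v) for v in parts])
        if not axes:
            raise ValueError("no axis header lines found")
        shape = tuple(len(a) for a in axes)
        values = np.array(rows, dtype=float).reshape(shape)
        return cls(axes=tuple(axes), values=values, order=order)

    def to_csv(self, path, names=("x", "y", "z")) -> None:
        with open(path, "w") as fh:
            for name, a in zip(names, self.axes):
                fh.write("axis," + name + "," + ",".join(f"{v:.9g}" for v in a) + "\n")
            flat = self.values.reshape(-1, self.values.shape[-1])
            for row in flat:
                fh.write(",".join(f"{v:.9g}" for v in row) + "\n")


def eval_profile(profile, position):
    """Evaluate the normalized excitation intensity W at ``position``.

    ``position`` is a 3-vector (or array of 3-vectors) in meters; the return
    value is dimensionless in [0, 1].
    """
    return profile.evaluate(position)


def profile_volume_integral(profile, n_nodes: int = 200, extent: float | None = None):
    """Numerically integrate W over its support.

    Returns the volume integral (m^3) for 3D profiles and the in-plane area
    integral (m^2) for the annular and 2D-grid profiles, by tensor-product
    Gauss-Legendre quadrature.  Raises if the profile has not decayed at the
    integration boundary (non-integrable input).
    """
    u, w = leggauss(n_nodes)

    def panel(lo, hi):
        return 0.5 * (hi - lo) * u + 0.5 * (hi + lo), 0.5 * (hi - lo) * w

    if isinstance(profile, GaussianEllipsoidProfile):
        L = extent or 4.0 * max(profile.r0, profile.z0)
        x, wx = panel(-L, L)
        lat = np.sum(np.exp(-2.0 * x**2 / profile.r0**2) * wx)
        ax_, wz = panel(-L, L)
        axial = np.sum(np.exp(-2.0 * ax_**2 / profile.z0**2) * wz)
        edge = np.exp(-2.0 * L**2 / min(profile.r0, profile.z0) ** 2)
    elif isinstance(profile, Nifs3DProfile):
        L = extent or 4.0 * profile.r0
        Lz = extent or 40.0 * profile.z0
        x, wx = panel(-L, L)
        lat = np.sum(np.exp(-2.0 * x**2 / profile.r0**2) * wx)
        z, wz = panel(0.0, Lz)
        axial = np.sum(np.exp(-z / profile.z0) * wz)
        return lat * lat * axial
    elif isinstance(profile, AnnularProfile):
        R = extent or profile.a0 + 6.0 * profile.b0
        r, wr = panel(0.0, R)
        vals = profile.evaluate_radial(r)
        if vals[-1] > 1e-6:
            raise ValueError("profile has not decayed at the integration boundary")
        return 2.0 * np.pi * np.sum(vals * r * wr)
    elif isinstance(profile, GridProfile):
        vals = profile.values
        b = np.concatenate([vals[0].ravel(), vals[-1].ravel()])
        if np.max(b) > 1e-3 * np.max(vals):
            raise ValueError("grid profile does not decay to ~0 at the grid boundary")
        out = vals
        for a in reversed(profile.axes):
            out = np.trapezoid(out, x=a, axis=-1)
        return float(out)
    else:
        raise TypeError(f"unsupported profile type {type(profile)!r}")

    if edge > 1e-6:
        raise ValueError("profile has not decayed at the integration boundary")
    return lat * lat * axial
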