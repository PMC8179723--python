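"""Brownian-dynamics Monte Carlo of photon emission under an illumination profile.

A simulated experiment proceeds in three stages: particles are placed
uniformly in a rectangular box, advanced by overdamped Brownian steps
(independent zero-mean Gaussian displacements of variance ``2 D dt`` per
axis) with periodic lateral boundaries — and, above a waveguide exit surface,
a specularly reflecting wall at ``z = 0`` — and finally each particle emits a
photon per step with Bernoulli probability ``brightness * W(position)``.
Counts are recorded in bins of width ``dt``.

The fused inner loop is JIT-compiled (:mod:`nifs._kernels`); a pure-numpy
engine replays the identical random stream for cross-validation and for
profiles the kernels do not special-case (grid-sampled maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .illumination import (
    AnnularProfile,
    GaussianEllipsoidProfile,
    GridProfile,
    Nifs3DProfile,
    eval_profile,
)

__all__ = [
    "SimulationConfig",
    "IntensityTrace",
    "init_positions",
    "step_particles",
    "apply_boundaries",
    "emit_photons",
    "calibrate_brightness",
    "run_simulation",
    "run_single",
]

MODES = ("FCS3D", "NIFS3D", "2D")
BERNOULLI_CAP = 0.1  # max emission probability per step at the profile peak


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, dynamics and emission parameters of one simulated experiment.

    ``box`` is (Lx, Ly, Lz) in meters (Lz ignored in 2D mode, where particles
    stay at height ``z_plane``).  ``brightness`` is the expected photon count
    per step for a particle sitting at the profile peak.  In ``NIFS3D`` mode
    the box spans z in [0, Lz] with the waveguide exit surface at z = 0.
    """

    box: tuple
    n_particles: int
    D: float  # m^2/s
    profile: object
    dt: float = 1e-7  # s, 100 ns
    n_steps: int = 10_000_000
    brightness: float = 0.01
    mode: str = "FCS3D"
    seed: int = 0
    n_runs: int = 1
    z_plane: float = 2.3e-9  # membrane height in 2D mode
    # NIFS3D top face.  "reflecting" is the only self-consistent choice with a
    # hard wall at z = 0: wrapping the top onto the bottom while reflecting at
    # the bottom sets up a one-way circulation that piles density onto the
    # exit surface (particles teleport down but can never wrap up).
    top_boundary: str = "reflecting"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if len(self.box) != 3 or any(L <= 0 for L in self.box):
            raise ValueError("box must be three positive lengths")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.D <= 0 or self.dt <= 0:
            raise ValueError("D and dt must be positive")
        if self.n_steps < 1 or self.n_runs < 1:
            raise ValueError("n_steps and n_runs must be >= 1")
        if not (0.0 <= self.brightness <= BERNOULLI_CAP):
            raise ValueError(
                f"brightness must lie in [0, {BERNOULLI_CAP}] for the per-step "
                "Bernoulli emission to approximate a Poisson count"
            )
        if self.top_boundary not in ("periodic", "reflecting"):
            raise ValueError("top_boundary must be 'periodic' or 'reflecting'")

    @property
    def concentration(self) -> float:
        """Mean particle density: 1/m^3 (3D modes) or 1/m^2 (2D mode)."""
        Lx, Ly, Lz = self.box
        if self.mode == "2D":
            return self.n_particles / (Lx * Ly)
        return self.n_particles / (Lx * Ly * Lz)

    @property
    def center(self) -> tuple:
        """Lateral profile center; the focus height for conventional FCS."""
        Lx, Ly, Lz = self.box
        cz = Lz / 2.0 if self.mode == "FCS3D" else 0.0
        return (Lx / 2.0, Ly / 2.0, cz)

    def scaled(self, scale: float, min_steps: int = 100_000, min_runs: int = 4) -> "SimulationConfig":
        """Proportionally reduced copy for desk-scale work (floors applied)."""
        if not (0 < scale <= 1):
            raise ValueError("scale must be in (0, 1]")
        return replace(
            self,
            n_steps=max(min(min_steps, self.n_steps), int(round(self.n_steps * scale))),
            n_runs=max(min(min_runs, self.n_runs), int(round(self.n_runs * scale))),
        )


@dataclass(frozen=True)
class IntensityTrace:
    """Photon counts per time bin from one run; bin width equals the time step."""

    counts: np.ndarray
    dt: float
    seed: int
    mean_wsum: float = float("nan")  # trajectory average of sum_i W(r_i)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or np.any(counts < 0):
            raise ValueError("counts must be a 1D non-negative array")
        object.__setattr__(self, "counts", counts)

    @property
    def mean_rate(self) -> float:
        """Mean photon count rate in Hz."""
        return float(self.counts.mean() / self.dt)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([np.arange(len(self.counts)), self.counts]),
                   fmt="%d", delimiter=",", header="bin,counts", comments="")


# ---------------------------------------------------------------------------
# modular stage operations
# ---------------------------------------------------------------------------

def init_positions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Stage 1: i.i.d. uniform positions over the box (or plane in 2D mode)."""
    Lx, Ly, Lz = config.box
    n = config.n_particles
    pos = np.empty((n, 3))
    pos[:, 0] = rng.random(n) * Lx
    pos[:, 1] = rng.random(n) * Ly
    if config.mode == "2D":
        pos[:, 2] = config.z_plane
    else:
        pos[:, 2] = rng.random(n) * Lz
    return pos


def step_particles(positions: np.ndarray, D: float, dt: float,
                   rng: np.random.Generator, in_plane: bool = False) -> np.ndarray:
    """Stage 2a: add independent Gaussian displacements of std sqrt(2 D dt)
    per axis (overdamped diffusion)."""
    if D < 0 or dt <= 0:
        raise ValueError("require D >= 0 and dt > 0")
    sigma = np.sqrt(2.0 * D * dt)
    disp = rng.standard_normal(positions.shape) * sigma
    if in_plane:
        disp[:, 2] = 0.0
    return positions + disp


def apply_boundaries(positions: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Stage 2b: periodic lateral wrap; reflecting wall at z = 0 in NIFS3D mode.

    Raises if any particle moved further than one box length in a single step
    (signals an inconsistent D/dt/box combination).
    """
    Lx, Ly, Lz = config.box
    pos = np.array(positions, dtype=float)
    L = np.array([Lx, Ly, Lz])
    if np.any(pos < -L) or np.any(pos >= 2.0 * L):
        raise ValueError("particle displaced by more than one box length in one step")

    for ax, Lax in ((0, Lx), (1, Ly)):
        pos[:, ax] = np.where(pos[:, ax] < 0.0, pos[:, ax] + Lax, pos[:, ax])
        pos[:, ax] = np.where(pos[:, ax] >= Lax, pos[:, ax] - Lax, pos[:, ax])
    if config.mode == "FCS3D":
        pos[:, 2] = np.where(pos[:, 2] < 0.0, pos[:, 2] + Lz, pos[:, 2])
        pos[:, 2] = np.where(pos[:, 2] >= Lz, pos[:, 2] - Lz, pos[:, 2])
    elif config.mode == "NIFS3D":
        pos[:, 2] = np.where(pos[:, 2] < 0.0, -pos[:, 2], pos[:, 2])
        if config.top_boundary == "reflecting":
            pos[:, 2] = np.where(pos[:, 2] > Lz, 2.0 * Lz - pos[:, 2], pos[:, 2])
        else:
            pos[:, 2] = np.where(pos[:, 2] >= Lz, pos[:, 2] - Lz, pos[:, 2])
    return pos


def emit_photons(positions: np.ndarray, profile, brightness: float,
                 rng: np.random.Generator, center=(0.0, 0.0, 0.0)) -> int:
    """Stage 3: each particle emits with probability brightness * W(r);
    returns the total photon count of this step."""
    if brightness < 0 or brightness > 1.0:
        raise ValueError("emission probability must lie in [0, 1]")
    rel = np.asarray(positions, dtype=float) - np.asarray(center, dtype=float)
    w = eval_profile(profile, rel)
    p = brightness * w
    if np.any(p > 1.0):
        raise ValueError("emission probability above 1")
    return int(np.count_nonzero(rng.random(len(p)) < p))


# ---------------------------------------------------------------------------
# fused runs
# ---------------------------------------------------------------------------

def _profile_kernel_params(config: SimulationConfig):
    p = config.profile
    cx, cy, cz = config.center
    if isinstance(p, GaussianEllipsoidProfile):
        return 0, p.r0, p.z0
    if isinstance(p, Nifs3DProfile):
        return 1, p.r0, p.z0
    if isinstance(p, AnnularProfile):
        return 2, p.a0, p.b0
    return None, 0.0, 0.0  # grid or custom profile: numpy engine only


def _intensity_numpy(pos, config: SimulationConfig):
    """Profile intensity with the same exp cutoff as the kernels."""
    cx, cy, cz = config.center
    p = config.profile
    dx = pos[:, 0] - cx
    dy = pos[:, 1] - cy
    if isinstance(p, GaussianEllipsoidProfile):
        dz = pos[:, 2] - cz
        e = -2.0 * (dx * dx + dy * dy) / p.r0**2 - 2.0 * dz * dz / p.z0**2
    elif isinstance(p, Nifs3DProfile):
        e = -2.0 * (dx * dx + dy * dy) / p.r0**2 - pos[:, 2] / p.z0
    elif isinstance(p, AnnularProfile):
        r = np.sqrt(dx * dx + dy * dy)
        e = -((r - p.a0) ** 2) / p.b0**2
    else:
        rel = pos - np.array([cx, cy, 0.0 if config.mode != "FCS3D" else cz])
        return np.asarray(eval_profile(p, rel), dtype=float)
    return np.where(e > _kernels.W_EXP_CUTOFF, np.exp(np.clip(e, _kernels.W_EXP_CUTOFF, 0.0)), 0.0)


def run_single(config: SimulationConfig, seed: int, engine: str = "numba") -> IntensityTrace:
    """One run: full three-stage simulation with the given seed."""
    Lx, Ly, Lz = config.box
    cx, cy, cz = config.center
    sigma = np.sqrt(2.0 * config.D * config.dt)
    if 6.0 * sigma > min(config.box[:2] if config.mode == "2D" else config.box):
        raise ValueError("per-step displacement is not small compared to the box")

    rng = np.random.Generator(np.random.SFC64(seed))
    pos = init_positions(config, rng)
    counts = np.zeros(config.n_steps, dtype=np.int32)
    wsum = np.zeros(config.n_steps, dtype=np.float64)

    profile_id, pa, pb = _profile_kernel_params(config)
    use_kernel = engine == "numba" and profile_id is not None
    if engine not in ("numba", "numpy"):
        raise ValueError("engine must be 'numba' or 'numpy'")
    two_d = config.mode == "2D"
    ndim = 2 if two_d else 3
    mode_flag = 0 if config.mode == "FCS3D" else 1
    top_reflect = 1 if config.top_boundary == "reflecting" else 0

    chunk = int(max(64, min(config.n_steps, 2_000_000 // config.n_particles)))
    pos_k = np.ascontiguousarray(pos[:, :2]) if (two_d and use_kernel) else pos
    done = 0
    while done < config.n_steps:
        m = min(chunk, config.n_steps - done)
        # float32 streams: displacement quantization (~1e-7 relative) is far
        # below any physical scale and halves generator + memory cost
        disp = rng.standard_normal((m, config.n_particles, ndim), dtype=np.float32)
        disp *= np.float32(sigma)
        unif = rng.random((m, config.n_particles), dtype=np.float32)
        sl = slice(done, done + m)
        if use_kernel:
            if two_d:
                _kernels.chunk_2d(pos_k, disp, unif, Lx, Ly, cx, cy,
                                  pa, pb, config.brightness, counts[sl], wsum[sl])
            else:
                _kernels.chunk_3d(pos, disp, unif, Lx, Ly, Lz, cx, cy, cz,
                                  mode_flag, top_reflect, profile_id, pa, pb,
                                  config.brightness, counts[sl], wsum[sl])
        else:
            for s in range(m):
                pos[:, :ndim] = pos[:, :ndim] + disp[s]
                pos = apply_boundaries(pos, config)
                w = _intensity_numpy(pos, config)
                wsum[done + s] = w.sum()
                counts[done + s] = np.count_nonzero(unif[s] < config.brightness * w)
        done += m

    return IntensityTrace(counts=counts, dt=config.dt, seed=seed,
                          mean_wsum=float(wsum.mean()))


def run_simulation(config: SimulationConfig, engine: str = "numba") -> list:
    """Run ``config.n_runs`` independent runs with seeds seed + run index.

    Deterministic: the same config and seed always produce identical traces.
    """
    return [run_single(config, config.seed + k, engine=engine)
            for k in range(config.n_runs)]


def calibrate_brightness(config: SimulationConfig, target_rate: float,
                         n_pilot_samples: int = 4_000_000, cap: str = "error") -> float:
    """Brightness that makes the mean count rate match ``target_rate`` (Hz).

    Uses a pilot Monte Carlo sample of the stationary state: uniform
    positions are the exact equilibrium of the periodic/reflected diffusion,
    so the expected counts per step equal ``brightness * n * E_uniform[W]``
    and a static ensemble average of W fixes the brightness with far less
    sampling noise than a short trajectory (whose occupation of the
    illuminated region decorrelates only over the diffusion time).

    ``cap`` controls behavior when the Bernoulli validity limit would be
    exceeded: ``"error"`` raises, ``"clip"`` returns the capped brightness.
    """
    if target_rate < 0:
        raise ValueError("target_rate must be >= 0")
    if target_rate == 0.0:
        return 0.0
    target_per_step = target_rate * config.dt
    if target_per_step >= config.n_particles:
        raise ValueError("target rate exceeds one photon per particle per step")
    rng = np.random.default_rng(config.seed)
    total, n_done = 0.0, 0
    pilot = replace(config, n_particles=min(n_pilot_samples, 500_000))
    while n_done < n_pilot_samples:
        pos = init_positions(pilot, rng)
        total += float(_intensity_numpy(pos, pilot).sum())
        n_done += pilot.n_particles
    mean_w = total / n_done
    if mean_w <= 0:
        raise RuntimeError("illumination profile vanishes over the whole box")
    b = target_per_step / (config.n_particles * mean_w)
    if b > BERNOULLI_CAP:
        if cap == "clip":
            return BERNOULLI_CAP
        raise ValueError(
            f"target rate {target_rate:g} Hz needs brightness {b:.3g} > "
            f"{BERNOULLI_CAP} (per-step Bernoulli cap); lower the rate or "
            "raise the concentration"
        )
    return float(b)
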