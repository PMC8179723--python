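"""JIT-compiled inner loops of the Monte Carlo engine.

The kernels consume pre-generated random displacement and uniform arrays (one
chunk of steps at a time) so that the random stream is owned by a single
numpy Generator in :mod:`nifs.simulate`; the pure-numpy engine there replays
the exact same stream and must produce identical photon counts.

Intensities below exp(-45) are treated as zero in both engines (an emission
probability < 3e-20 per draw).
"""

import numpy as np
from numba import njit

W_EXP_CUTOFF = -45.0


@njit(cache=False)
def chunk_3d(pos, disp, unif, Lx, Ly, Lz, cx, cy, cz, mode, top_reflect,
             profile_id, pa, pb, brightness, counts, wsum):
    """Advance one chunk of steps for 3D modes.

    mode 0: fully periodic box (conventional FCS); mode 1: reflecting wall at
    z = 0 (waveguide exit surface), top face periodic or reflecting.
    profile_id 0: Gaussian ellipsoid (pa=r0, pb=z0, centered at cx,cy,cz);
    profile_id 1: lateral Gaussian x exponential axial decay (pa=r0, pb=z0,
    measured from the z = 0 plane).
    """
    n_sub = disp.shape[0]
    n = pos.shape[0]
    for s in range(n_sub):
        c = 0
        wacc = 0.0
        for i in range(n):
            x = pos[i, 0] + disp[s, i, 0]
            y = pos[i, 1] + disp[s, i, 1]
            z = pos[i, 2] + disp[s, i, 2]
            if x < 0.0:
                x += Lx
            elif x >= Lx:
                x -= Lx
            if y < 0.0:
                y += Ly
            elif y >= Ly:
                y -= Ly
            if mode == 0:
                if z < 0.0:
                    z += Lz
                elif z >= Lz:
                    z -= Lz
            else:
                if z < 0.0:
                    z = -z
                if top_reflect == 1:
                    if z > Lz:
                        z = 2.0 * Lz - z
                else:
                    if z >= Lz:
                        z -= Lz
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            dx = x - cx
            dy = y - cy
            if profile_id == 0:
                dz = z - cz
                e = -2.0 * (dx * dx + dy * dy) / (pa * pa) - 2.0 * dz * dz / (pb * pb)
            else:
                e = -2.0 * (dx * dx + dy * dy) / (pa * pa) - z / pb
            if e > W_EXP_CUTOFF:
                w = np.exp(e)
                wacc += w
                if unif[s, i] < brightness * w:
                    c += 1
        counts[s] = c
        wsum[s] = wacc


@njit(cache=False)
def chunk_2d(pos, disp, unif, Lx, Ly, cx, cy, a0, b0, brightness, counts, wsum):
    """Advance one chunk of steps for the in-plane (membrane) mode with the
    annular edge-field profile (periodic lateral wrap)."""
    n_sub = disp.shape[0]
    n = pos.shape[0]
    for s in range(n_sub):
        c = 0
        wacc = 0.0
        for i in range(n):
            x = pos[i, 0] + disp[s, i, 0]
            y = pos[i, 1] + disp[s, i, 1]
            if x < 0.0:
                x += Lx
            elif x >= Lx:
                x -= Lx
            if y < 0.0:
                y += Ly
            elif y >= Ly:
                y -= Ly
            pos[i, 0] = x
            pos[i, 1] = y
            dx = x - cx
            dy = y - cy
            r = np.sqrt(dx * dx + dy * dy)
            e = -((r - a0) * (r - a0)) / (b0 * b0)
            if e > W_EXP_CUTOFF:
                w = np.exp(e)
                wacc += w
                if unif[s, i] < brightness * w:
                    c += 1
        counts[s] = c
        wsum[s] = wacc
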