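"""Numba inner loops for signal synthesis and backprojection.

All kernels are serial and deterministic; they operate on plain float
arrays with positions in um, times in us and frequencies in MHz.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=True)
def synth_spectra(
    el_pos,        # (P, E, 3) element positions, um
    elev,          # (P, 3) elevation unit vectors
    centres,       # (A, 3) absorber centres, um
    base,          # (A, F) real spectral weight per absorber (sphere spectrum x IR)
    amps,          # (A,) absorber amplitudes
    c,             # sound speed, um/us
    df,            # frequency bin spacing, MHz
    t_start,       # record start time, us
    sigma_psi,     # elevation acceptance sigma, rad (<=0 disables weighting)
    p_lo, p_hi,    # pulse chunk [p_lo, p_hi)
    out,           # (p_hi - p_lo, E, F) complex64, zeroed by caller
):
    """One-sided spectra of all traces in a pulse chunk.

    Each absorber contributes amp/d * w_elev * i*base(f) * exp(-i w (tau - t_start))
    where tau = d / c.  The imaginary unit comes from the odd N-wave shape
    being encoded as a real `base` (see forward.sphere_spectrum).
    """
    P = p_hi - p_lo
    E = el_pos.shape[1]
    A = centres.shape[0]
    F = base.shape[1]
    dw = TWO_PI * df
    for pp in range(P):
        p = p_lo + pp
        ex = elev[p, 0]
        ey = elev[p, 1]
        ez = elev[p, 2]
        for e in range(E):
            px = el_pos[p, e, 0]
            py = el_pos[p, e, 1]
            pz = el_pos[p, e, 2]
            for a in range(A):
                dx = centres[a, 0] - px
                dy = centres[a, 1] - py
                dz = centres[a, 2] - pz
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if d <= 0.0:
                    continue
                w = amps[a] / d
                if sigma_psi > 0.0:
                    s = (dx * ex + dy * ey + dz * ez) / d
                    w *= np.exp(-(s * s) / (2.0 * sigma_psi * sigma_psi))
                if w == 0.0:
                    continue
                tau = d / c - t_start
                # rotate e^{-i w_k tau} by recurrence over bins
                step_re = np.cos(dw * tau)
                step_im = -np.sin(dw * tau)
                rot_re = 1.0
                rot_im = 0.0
                for f in range(F):
                    b = base[a, f] * w
                    # contribution = i * b * rot
                    out[pp, e, f] += np.complex64(complex(-b * rot_im, b * rot_re))
                    nr = rot_re * step_re - rot_im * step_im
                    rot_im = rot_re * step_im + rot_im * step_re
                    rot_re = nr


@njit(cache=True, fastmath=True)
def synth_time_exact(
    el_pos, elev, centres, radii, amps,
    c, dt, t_start, n_samples, sigma_psi,
    out,           # (P, E, S) float32, zeroed
):
    """Exact sampling of the analytic N-wave (no detector response)."""
    P = el_pos.shape[0]
    E = el_pos.shape[1]
    A = centres.shape[0]
    for p in range(P):
        ex = elev[p, 0]
        ey = elev[p, 1]
        ez = elev[p, 2]
        for e in range(E):
            px = el_pos[p, e, 0]
            py = el_pos[p, e, 1]
            pz = el_pos[p, e, 2]
            for a in range(A):
                dx = centres[a, 0] - px
                dy = centres[a, 1] - py
                dz = centres[a, 2] - pz
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if d <= radii[a]:
                    continue
                w = amps[a] / d
                if sigma_psi > 0.0:
                    s = (dx * ex + dy * ey + dz * ez) / d
                    w *= np.exp(-(s * s) / (2.0 * sigma_psi * sigma_psi))
                tau = d / c
                half = radii[a] / c
                i0 = int(np.ceil((tau - half - t_start) / dt))
                i1 = int(np.floor((tau + half - t_start) / dt))
                if i0 < 0:
                    i0 = 0
                if i1 > n_samples - 1:
                    i1 = n_samples - 1
                for i in range(i0, i1 + 1):
                    t = t_start + i * dt
                    out[p, e, i] += np.float32(-w * (t - tau) / half)


@njit(cache=True, fastmath=True)
def backproject_sum(
    data,          # (P, E, S) float32 backprojection-ready signal
    el_pos,        # (P, E, 3)
    elev,          # (P, 3)
    origin,        # (3,) position of voxel (0, 0, 0) centre, um (x, y, z)
    voxel,         # voxel edge, um
    nx, ny, nz,
    c, dt, t_start,
    sigma_psi,     # <= 0 disables elevation weighting
    vol,           # (nz, ny, nx) float64 accumulator, zeroed
):
    """Delay-and-sum backprojection; returns the clipped-contribution count."""
    P = data.shape[0]
    E = data.shape[1]
    S = data.shape[2]
    clipped = 0
    for p in range(P):
        ex = elev[p, 0]
        ey = elev[p, 1]
        ez = elev[p, 2]
        for e in range(E):
            px = el_pos[p, e, 0]
            py = el_pos[p, e, 1]
            pz = el_pos[p, e, 2]
            trace = data[p, e]
            for iz in range(nz):
                z = origin[2] + iz * voxel
                dz = z - pz
                for iy in range(ny):
                    y = origin[1] + iy * voxel
                    dy = y - py
                    for ix in range(nx):
                        x = origin[0] + ix * voxel
                        dx = x - px
                        d = np.sqrt(dx * dx + dy * dy + dz * dz)
                        s = (d / c - t_start) / dt
                        i0 = int(s)
                        if s < 0.0 or i0 >= S - 1:
                            clipped += 1
                            continue
                        frac = s - i0
                        val = trace[i0] * (1.0 - frac) + trace[i0 + 1] * frac
                        w = 1.0 / d
                        if sigma_psi > 0.0:
                            q = (dx * ex + dy * ey + dz * ez) / d
                            w *= np.exp(-(q * q) / (2.0 * sigma_psi * sigma_psi))
                        vol[iz, iy, ix] += val * w
    return clipped
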