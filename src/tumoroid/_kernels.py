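"""Numba kernels for the population-scale hot loops.

These mirror the reference single-cell/pairwise implementations in
`grn_dynamics` and `mechanics_motion` exactly in their mathematics (closed
form relaxation, exponential burst clocks, linear overlap springs); the
tests check equivalence on small populations.  The PDMP kernel uses numba's
internal NumPy-compatible RNG; seed it with `seed_kernel_rng` once per run
for reproducibility.
"""

from __future__ import annotations

import numba as nb
import numpy as np

BIG = 1e30


@nb.njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@nb.njit(cache=True, inline="always")
def _relax_cell(M, P, i, dt, d0, d1, s1):
    for g in range(3):
        e0 = np.exp(-d0[g] * dt)
        e1 = np.exp(-d1[g] * dt)
        diff = d0[g] - d1[g]
        if diff != 0.0:
            conv = s1[g] * M[i, g] * (e1 - e0) / diff
        else:
            conv = s1[g] * M[i, g] * dt * e0
        P[i, g] = P[i, g] * e1 + conv
        M[i, g] = M[i, g] * e0


@nb.njit(cache=True)
def pdmp_population(M, P, signal, d0, d1, s1, k0, k1, beta, theta, burst_mean, dt):
    """Advance every cell's GRN over one interval of length dt, in place.

    signal[i] is the cell's signaling term (gamma*S or S_diff); it enters
    only the CD133 (gene 0) sigmoid.  Burst clocks are exponential at the
    current rate, recomputed after every burst.  Returns total burst count.
    """
    n = M.shape[0]
    n_bursts = 0
    for i in range(n):
        remaining = dt
        while True:
            tmin = BIG
            gmin = -1
            for g in range(3):
                sigma = beta[g]
                if g == 0:
                    sigma += signal[i]
                for s in range(3):
                    sigma += theta[s, g] * P[i, s]
                if sigma >= 0.0:
                    f = 1.0 / (1.0 + np.exp(-sigma))
                else:
                    e = np.exp(sigma)
                    f = e / (1.0 + e)
                k = k0[g] + (k1[g] - k0[g]) * f
                if k > 0.0:
                    w = np.random.exponential(1.0 / k)
                else:
                    w = BIG
                if w < tmin:
                    tmin = w
                    gmin = g
            if tmin >= remaining:
                _relax_cell(M, P, i, remaining, d0, d1, s1)
                break
            _relax_cell(M, P, i, tmin, d0, d1, s1)
            M[i, gmin] += np.random.exponential(burst_mean)
            n_bursts += 1
            remaining -= tmin
    return n_bursts


@nb.njit(cache=True)
def find_pairs_grid(pos, cutoff, max_pairs):
    """All unordered pairs with center distance < cutoff, via a cell grid.

    Returns (pairs_i, pairs_j, count); count == -1 signals that max_pairs
    was too small and the caller should retry with a larger buffer.
    Near-linear in the number of points for bounded local density.
    """
    n = pos.shape[0]
    pairs_i = np.empty(max_pairs, dtype=np.int64)
    pairs_j = np.empty(max_pairs, dtype=np.int64)
    if n < 2:
        return pairs_i, pairs_j, 0
    xmin = np.empty(3)
    xmax = np.empty(3)
    for d in range(3):
        lo = pos[0, d]
        hi = pos[0, d]
        for i in range(1, n):
            v = pos[i, d]
            if v < lo:
                lo = v
            if v > hi:
                hi = v
        xmin[d] = lo
        xmax[d] = hi
    ncell = np.empty(3, dtype=np.int64)
    for d in range(3):
        ncell[d] = max(1, int((xmax[d] - xmin[d]) / cutoff) + 1)
    nx, ny, nz = ncell[0], ncell[1], ncell[2]
    ntot = nx * ny * nz
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ntot + 1, dtype=np.int64)
    for i in range(n):
        cx = min(nx - 1, int((pos[i, 0] - xmin[0]) / cutoff))
        cy = min(ny - 1, int((pos[i, 1] - xmin[1]) / cutoff))
        cz = min(nz - 1, int((pos[i, 2] - xmin[2]) / cutoff))
        c = (cx * ny + cy) * nz + cz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ntot):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:ntot].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    cut2 = cutoff * cutoff
    m = 0
    for i in range(n):
        c = cell_of[i]
        cz = c % nz
        cy = (c // nz) % ny
        cx = c // (nz * ny)
        for ox in range(-1, 2):
            ax = cx + ox
            if ax < 0 or ax >= nx:
                continue
            for oy in range(-1, 2):
                ay = cy + oy
                if ay < 0 or ay >= ny:
                    continue
                for oz in range(-1, 2):
                    az = cz + oz
                    if az < 0 or az >= nz:
                        continue
                    cc = (ax * ny + ay) * nz + az
                    for p in range(counts[cc], counts[cc + 1]):
                        j = order[p]
                        if j <= i:
                            continue
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        if dx * dx + dy * dy + dz * dz < cut2:
                            if m >= max_pairs:
                                return pairs_i, pairs_j, -1
                            pairs_i[m] = i
                            pairs_j[m] = j
                            m += 1
    return pairs_i, pairs_j, m


@nb.njit(cache=True)
def find_pairs_radii(pos, r_ext, skin, cutoff, max_pairs):
    """Pairs with ||x_i - x_j|| < r_i + r_j + skin, plus their distances.

    Same cell-grid scheme as find_pairs_grid but with the radius criterion
    applied in place, so no NumPy post-filter pass is needed.
    Returns (pairs_i, pairs_j, dist, count); count == -1 on buffer overflow.
    """
    n = pos.shape[0]
    pairs_i = np.empty(max_pairs, dtype=np.int64)
    pairs_j = np.empty(max_pairs, dtype=np.int64)
    dist = np.empty(max_pairs)
    if n < 2:
        return pairs_i, pairs_j, dist, 0
    xmin = np.empty(3)
    xmax = np.empty(3)
    for d in range(3):
        lo = pos[0, d]
        hi = pos[0, d]
        for i in range(1, n):
            v = pos[i, d]
            if v < lo:
                lo = v
            if v > hi:
                hi = v
        xmin[d] = lo
        xmax[d] = hi
    nx = max(1, int((xmax[0] - xmin[0]) / cutoff) + 1)
    ny = max(1, int((xmax[1] - xmin[1]) / cutoff) + 1)
    nz = max(1, int((xmax[2] - xmin[2]) / cutoff) + 1)
    ntot = nx * ny * nz
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ntot + 1, dtype=np.int64)
    for i in range(n):
        cx = min(nx - 1, int((pos[i, 0] - xmin[0]) / cutoff))
        cy = min(ny - 1, int((pos[i, 1] - xmin[1]) / cutoff))
        cz = min(nz - 1, int((pos[i, 2] - xmin[2]) / cutoff))
        c = (cx * ny + cy) * nz + cz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ntot):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:ntot].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    cut2 = cutoff * cutoff
    m = 0
    for i in range(n):
        c = cell_of[i]
        cz = c % nz
        cy = (c // nz) % ny
        cx = c // (nz * ny)
        for ox in range(-1, 2):
            ax = cx + ox
            if ax < 0 or ax >= nx:
                continue
            for oy in range(-1, 2):
                ay = cy + oy
                if ay < 0 or ay >= ny:
                    continue
                for oz in range(-1, 2):
                    az = cz + oz
                    if az < 0 or az >= nz:
                        continue
                    cc = (ax * ny + ay) * nz + az
                    for p in range(counts[cc], counts[cc + 1]):
                        j = order[p]
                        if j <= i:
                            continue
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        d2 = dx * dx + dy * dy + dz * dz
                        if d2 < cut2:
                            dd = np.sqrt(d2)
                            if dd < r_ext[i] + r_ext[j] + skin:
                                if m >= max_pairs:
                                    return pairs_i, pairs_j, dist, -1
                                pairs_i[m] = i
                                pairs_j[m] = j
                                dist[m] = dd
                                m += 1
    return pairs_i, pairs_j, dist, m


@nb.njit(cache=True)
def relax_overlaps_kernel(
    pos, r_int, r_ext, pairs_i, pairs_j, n_pairs, k_shell, k_core, tol, max_sweeps
):
    """Iterative overdamped relaxation of pairwise sphere overlaps, in place.

    Soft linear spring on external-radius overlap, a k_core/k_shell-times
    stiffer spring on rigid-core overlap; symmetric central displacements.
    Sweeps stop when the worst core overlap drops below tol.  Returns
    (sweeps_used, residual_core_overlap).
    """
    n = pos.shape[0]
    disp = np.zeros((n, 3))
    max_core = 0.0
    for sweep in range(max_sweeps):
        max_core = 0.0
        for i in range(n):
            disp[i, 0] = 0.0
            disp[i, 1] = 0.0
            disp[i, 2] = 0.0
        any_overlap = False
        for p in range(n_pairs):
            i = pairs_i[p]
            j = pairs_j[p]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            sum_ext = r_ext[i] + r_ext[j]
            if d >= sum_ext:
                continue
            any_overlap = True
            ov_ext = sum_ext - d
            ov_core = (r_int[i] + r_int[j]) - d
            mag = k_shell * ov_ext
            if ov_core > 0.0:
                mag += k_core * ov_core
                if ov_core > max_core:
                    max_core = ov_core
            if d > 1e-12:
                ux = dx / d
                uy = dy / d
                uz = dz / d
            else:
                # coincident centers: deterministic tie-break along +x
                ux, uy, uz = 1.0, 0.0, 0.0
            half = 0.5 * mag
            disp[i, 0] += half * ux
            disp[i, 1] += half * uy
            disp[i, 2] += half * uz
            disp[j, 0] -= half * ux
            disp[j, 1] -= half * uy
            disp[j, 2] -= half * uz
        if max_core < tol and sweep > 0:
            return sweep, max_core
        if not any_overlap:
            return sweep, 0.0
        for i in range(n):
            pos[i, 0] += disp[i, 0]
            pos[i, 1] += disp[i, 1]
            pos[i, 2] += disp[i, 2]
    return max_sweeps, max_core


@nb.njit(cache=True)
def gauss_sum_pairs(values_out, q, pairs_i, pairs_j, dist2, delta):
    """Accumulate symmetric Gaussian-kernel contributions over source pairs."""
    for p in range(pairs_i.shape[0]):
        w = np.exp(-dist2[p] / delta)
        values_out[pairs_i[p]] += q * w
        values_out[pairs_j[p]] += q * w
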