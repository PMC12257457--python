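"""Numba kernels for voxel photon/electron transport.

Geometry: all positions in cm in the phantom frame (grid corner at
``(x0, y0, z0)``, beam travelling roughly +z). Grids are indexed
``[ix, iy, iz]``. Energy deposits are scored in MeV-weighted units; the
caller converts energy to dose by dividing by voxel mass.

Photon transport supports two estimators:

* ``scatter_mc`` — expected-value estimator used by the dose engine: the
  first-collision (primary) energy transfer is handled deterministically by
  ``primary_raytrace``; each Monte Carlo history then samples the chain of
  scattered generations, depositing the expected first-collision transfer
  of each generation continuously along its flight path (implicit capture),
  which keeps the variance low at desk-scale history counts.
* ``photon_analog`` — conventional analog transport scoring transferred
  energy at collision sites, optionally handing secondaries to the CSDA
  electron stepper. Used for physics sanity checks.
"""

import numpy as np
from numba import njit

_REST = 0.511
_PAIR_THRESH = 1.022
# direction kick per cm per tesla per (MeV/c): dv = s * KB * (v x B) / pc
_KB = 2.9979
_X0_WATER = 36.08  # radiation length, g/cm^2


@njit(cache=True, fastmath=True)
def _lut(table, loge0, dlog, e):
    x = (np.log(e) - loge0) / dlog
    n = table.shape[0]
    if x <= 0.0:
        return table[0]
    if x >= n - 1:
        return table[n - 1]
    i = int(x)
    f = x - i
    return table[i] * (1.0 - f) + table[i + 1] * f


@njit(cache=True, fastmath=True)
def _aabb(px, py, pz, vx, vy, vz, x0, y0, z0, x1, y1, z1):
    """Slab intersection; returns (t_in, t_out), t_in > t_out when missed."""
    tmin = -1.0e30
    tmax = 1.0e30
    for axis in range(3):
        if axis == 0:
            p, v, lo, hi = px, vx, x0, x1
        elif axis == 1:
            p, v, lo, hi = py, vy, y0, y1
        else:
            p, v, lo, hi = pz, vz, z0, z1
        if abs(v) < 1e-12:
            if p < lo or p > hi:
                return 1.0, 0.0
        else:
            t1 = (lo - p) / v
            t2 = (hi - p) / v
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    return tmin, tmax


@njit(cache=True)
def _rng_init(seed, history):
    """Counter-based per-history RNG state (splitmix64 of seed and index).

    Giving every history its own stream keeps trajectories reproducible
    independently of each other: a change in one history (e.g. a shifted
    pixel assignment when the fluence weights move slightly) cannot
    de-correlate the rest of the run, which closed-loop comparisons with
    common random numbers rely on.
    """
    s = np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15) + np.uint64(history + 1) * np.uint64(
        0xBF58476D1CE4E5B9
    )
    st = np.empty(1, dtype=np.uint64)
    st[0] = s
    return st


@njit(cache=True)
def _u01(state):
    """splitmix64 step mapped to (0, 1)."""
    state[0] = state[0] + np.uint64(0x9E3779B97F4A7C15)
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return (float(z >> np.uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _norm01(state):
    """Standard normal via Box-Muller."""
    u1 = _u01(state)
    u2 = _u01(state)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


@njit(cache=True, fastmath=True)
def _kahn_compton(e, state):
    """Sample a Compton event via Kahn's rejection; returns (e_out, cos_theta)."""
    alpha = e / _REST
    while True:
        r1 = _u01(state)
        r2 = _u01(state)
        r3 = _u01(state)
        if r1 <= (1.0 + 2.0 * alpha) / (9.0 + 2.0 * alpha):
            x = 1.0 + 2.0 * alpha * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                cost = 1.0 - (x - 1.0) / alpha
                return e / x, cost
        else:
            x = (1.0 + 2.0 * alpha) / (1.0 + 2.0 * alpha * r2)
            cost = 1.0 - (x - 1.0) / alpha
            if r3 <= 0.5 * (cost * cost + 1.0 / x):
                return e / x, cost


@njit(cache=True, fastmath=True)
def _rotate(vx, vy, vz, cost, phi):
    """Rotate unit vector v by polar angle acos(cost), azimuth phi."""
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    # orthonormal basis perpendicular to v
    if abs(vz) < 0.99:
        ux, uy, uz = -vy, vx, 0.0
    else:
        ux, uy, uz = 1.0, 0.0, 0.0
    n = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / n, uy / n, uz / n
    wx = vy * uz - vz * uy
    wy = vz * ux - vx * uz
    wz = vx * uy - vy * ux
    cp = np.cos(phi)
    sp = np.sin(phi)
    nx = cost * vx + sint * (cp * ux + sp * wx)
    ny = cost * vy + sint * (cp * uy + sp * wy)
    nz = cost * vz + sint * (cp * uz + sp * wz)
    n = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / n, ny / n, nz / n


@njit(cache=True, fastmath=True)
def primary_raytrace(
    pix_x, pix_y, pix_z, pix_w,
    sx, sy, sz,
    rho, x0, y0, z0, dx, dy, dz,
    mu, tbar, step, release,
):
    """Deterministic first-collision energy release for every fluence pixel.

    Each pixel carries ``pix_w`` photons; along the diverging ray from the
    source the expected energy transferred to charged particles per step is
    w * exp(-tau) * mu*rho*ds * tbar.
    """
    nx, ny, nz = rho.shape
    x1 = x0 + nx * dx
    y1 = y0 + ny * dy
    z1 = z0 + nz * dz
    for ip in range(pix_x.shape[0]):
        w = pix_w[ip]
        if w <= 0.0:
            continue
        vx = pix_x[ip] - sx
        vy = pix_y[ip] - sy
        vz = pix_z[ip] - sz
        n = np.sqrt(vx * vx + vy * vy + vz * vz)
        vx, vy, vz = vx / n, vy / n, vz / n
        tin, tout = _aabb(sx, sy, sz, vx, vy, vz, x0, y0, z0, x1, y1, z1)
        if tin >= tout:
            continue
        if tin < 0.0:
            tin = 0.0
        tau = 0.0
        t = tin
        while t < tout:
            ds = step if t + step <= tout else tout - t
            tm = t + 0.5 * ds
            px = sx + vx * tm
            py = sy + vy * tm
            pz = sz + vz * tm
            ix = int((px - x0) / dx)
            iy = int((py - y0) / dy)
            iz = int((pz - z0) / dz)
            if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                r = rho[ix, iy, iz]
                if r > 0.0:
                    dtau = mu * r * ds
                    dep = w * np.exp(-(tau + 0.5 * dtau)) * dtau * tbar
                    # bilinear (cloud-in-cell) lateral splatting: the 1 mm
                    # pixel-ray lattice is commensurate with the voxel grid,
                    # and nearest-voxel assignment of boundary rays aliases
                    # into persistent column artifacts on the beam axis
                    gx = (px - x0) / dx - 0.5
                    gy = (py - y0) / dy - 0.5
                    i0 = int(np.floor(gx))
                    j0 = int(np.floor(gy))
                    fx = gx - i0
                    fy = gy - j0
                    for di in range(2):
                        ii = i0 + di
                        if ii < 0 or ii >= nx:
                            continue
                        wxf = fx if di == 1 else 1.0 - fx
                        for dj in range(2):
                            jj = j0 + dj
                            if jj < 0 or jj >= ny:
                                continue
                            wyf = fy if dj == 1 else 1.0 - fy
                            release[ii, jj, iz] += dep * wxf * wyf
                    tau += dtau
            t += ds
            if tau > 30.0:
                break
    return


@njit(cache=True, fastmath=True)
def _fly_deposit(
    px, py, pz, vx, vy, vz, e, w, deposit,
    rho, x0, y0, z0, dx, dy, dz,
    loge0, dlog, mu_lut, tbar_lut,
    step, tau_birth, release,
):
    """March a photon through the grid.

    If ``deposit`` is true, scores the expected first-collision transfer of
    this generation continuously (weight decaying as exp(-tau)). Records the
    position where the optical depth crosses ``tau_birth`` (next-generation
    birth site). Returns (tau_exit, bx, by, bz, born).
    """
    nx, ny, nz = rho.shape
    x1 = x0 + nx * dx
    y1 = y0 + ny * dy
    z1 = z0 + nz * dz
    mu = _lut(mu_lut, loge0, dlog, e)
    tbar = _lut(tbar_lut, loge0, dlog, e)
    tin, tout = _aabb(px, py, pz, vx, vy, vz, x0, y0, z0, x1, y1, z1)
    if tin >= tout:
        return 0.0, 0.0, 0.0, 0.0, False
    if tin < 0.0:
        tin = 0.0
    tau = 0.0
    born = False
    bx = by = bz = 0.0
    t = tin
    while t < tout:
        ds = step if t + step <= tout else tout - t
        tm = t + 0.5 * ds
        qx = px + vx * tm
        qy = py + vy * tm
        qz = pz + vz * tm
        ix = int((qx - x0) / dx)
        iy = int((qy - y0) / dy)
        iz = int((qz - z0) / dz)
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            r = rho[ix, iy, iz]
            if r > 0.0:
                dtau = mu * r * ds
                if deposit:
                    release[ix, iy, iz] += w * np.exp(-(tau + 0.5 * dtau)) * dtau * tbar
                if (not born) and tau + dtau >= tau_birth:
                    frac = (tau_birth - tau) / dtau if dtau > 0 else 0.0
                    tb = t + frac * ds
                    bx = px + vx * tb
                    by = py + vy * tb
                    bz = pz + vz * tb
                    born = True
                    if not deposit:
                        # generation-0 flight: only the birth point matters
                        # (return an exit depth beyond the birth depth)
                        return tau_birth + 1.0, bx, by, bz, True
                tau += dtau
        t += ds
        if tau > 12.0:
            # exp(-12) of the weight remains; negligible deposit beyond
            break
    return tau, bx, by, bz, born


@njit(cache=True, fastmath=True)
def scatter_mc(
    pix_x, pix_y, pix_z, cdf, wtot,
    sx, sy, sz,
    n_hist, e0, seed,
    rho, x0, y0, z0, dx, dy, dz,
    loge0, dlog, mu_lut, pinc_lut, ppe_lut, tbar_lut,
    step, release, max_gen, e_cutoff,
):
    """Scattered-generation transport for one energy bin (see module docstring)."""
    w0 = wtot / n_hist
    # photon stack
    cap = 64
    st_px = np.empty(cap)
    st_py = np.empty(cap)
    st_pz = np.empty(cap)
    st_vx = np.empty(cap)
    st_vy = np.empty(cap)
    st_vz = np.empty(cap)
    st_e = np.empty(cap)
    st_w = np.empty(cap)
    st_g = np.empty(cap, dtype=np.int64)
    for _h in range(n_hist):
        state = _rng_init(seed, _h)
        u = _u01(state)
        ip = np.searchsorted(cdf, u)
        if ip >= pix_x.shape[0]:
            ip = pix_x.shape[0] - 1
        vx = pix_x[ip] - sx
        vy = pix_y[ip] - sy
        vz = pix_z[ip] - sz
        nrm = np.sqrt(vx * vx + vy * vy + vz * vz)
        vx, vy, vz = vx / nrm, vy / nrm, vz / nrm
        nstk = 0
        st_px[0], st_py[0], st_pz[0] = sx, sy, sz
        st_vx[0], st_vy[0], st_vz[0] = vx, vy, vz
        st_e[0] = e0
        st_w[0] = w0
        st_g[0] = 0
        nstk = 1
        while nstk > 0:
            nstk -= 1
            px, py, pz = st_px[nstk], st_py[nstk], st_pz[nstk]
            vx, vy, vz = st_vx[nstk], st_vy[nstk], st_vz[nstk]
            e = st_e[nstk]
            w = st_w[nstk]
            gen = st_g[nstk]
            # choose the prospective birth optical depth before flying
            xi = _u01(state)
            # fly; generation 0 deposition is covered by primary_raytrace
            dep = gen > 0
            tau_b = -np.log(1.0 - xi) if xi < 1.0 else 30.0
            tau_exit, bx, by, bz, born = _fly_deposit(
                px, py, pz, vx, vy, vz, e, w, dep,
                rho, x0, y0, z0, dx, dy, dz,
                loge0, dlog, mu_lut, tbar_lut, step, tau_b, release,
            )
            if gen + 1 > max_gen or tau_exit <= 0.0:
                continue
            # analog next-generation birth: the collision happens only if the
            # sampled optical depth was reached inside the grid
            if not born or tau_b >= tau_exit:
                continue
            w_next = w
            # Russian roulette on low weights
            if w_next < 1e-3 * w0:
                if _u01(state) < 0.5:
                    continue
                w_next *= 2.0
            # branch
            mu_i = _lut(pinc_lut, loge0, dlog, e)
            mu_p = _lut(ppe_lut, loge0, dlog, e)
            r = _u01(state)
            if r < mu_i:
                e_out, cost = _kahn_compton(e, state)
                if e_out <= e_cutoff:
                    continue
                phi = 2.0 * np.pi * _u01(state)
                nvx, nvy, nvz = _rotate(vx, vy, vz, cost, phi)
                if nstk < cap:
                    st_px[nstk], st_py[nstk], st_pz[nstk] = bx, by, bz
                    st_vx[nstk], st_vy[nstk], st_vz[nstk] = nvx, nvy, nvz
                    st_e[nstk] = e_out
                    st_w[nstk] = w_next
                    st_g[nstk] = gen + 1
                    nstk += 1
            elif r < mu_i + mu_p:
                pass  # photoelectric: transfer already scored in expectation
            else:
                # pair production: two annihilation quanta
                for _q in range(2):
                    cost = 2.0 * _u01(state) - 1.0
                    phi = 2.0 * np.pi * _u01(state)
                    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
                    if nstk < cap:
                        st_px[nstk], st_py[nstk], st_pz[nstk] = bx, by, bz
                        st_vx[nstk] = sint * np.cos(phi)
                        st_vy[nstk] = sint * np.sin(phi)
                        st_vz[nstk] = cost
                        st_e[nstk] = _REST
                        st_w[nstk] = w_next
                        st_g[nstk] = gen + 1
                        nstk += 1
    return


@njit(cache=True, fastmath=True)
def _electron_history(
    px, py, pz, vx, vy, vz, e, w,
    rho, x0, y0, z0, dx, dy, dz,
    loge0, dlog, s_lut, r_lut, e_grid,
    bx_f, by_f, bz_f, has_b, use_msc,
    step_cm, cutoff, dose, state,
):
    """CSDA condensed-history electron with optional magnetic deflection."""
    nx, ny, nz = rho.shape
    x1 = x0 + nx * dx
    y1 = y0 + ny * dy
    z1 = z0 + nz * dz
    # advance through vacuum to the grid if starting outside
    if not (x0 <= px < x1 and y0 <= py < y1 and z0 <= pz < z1):
        tin, tout = _aabb(px, py, pz, vx, vy, vz, x0, y0, z0, x1, y1, z1)
        if tin >= tout or tout < 0.0:
            return
        t = tin + 1e-6 if tin > 0.0 else 0.0
        px += vx * t
        py += vy * t
        pz += vz * t
    nstep_max = 100000
    for _i in range(nstep_max):
        if e <= cutoff:
            ix = int((px - x0) / dx)
            iy = int((py - y0) / dy)
            iz = int((pz - z0) / dz)
            if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                dose[ix, iy, iz] += w * e
            return
        ix = int((px - x0) / dx)
        iy = int((py - y0) / dy)
        iz = int((pz - z0) / dz)
        if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
            return
        r_loc = rho[ix, iy, iz]
        s = step_cm
        if r_loc > 1e-3:
            r_res = _lut(r_lut, loge0, dlog, e)  # g/cm^2
            path_left = r_res / r_loc
            if path_left < s:
                s = path_left
            r_new = r_res - s * r_loc
            # invert range -> energy
            if r_new <= r_lut[0]:
                e_new = 0.0
            else:
                # binary search on the monotone range table
                lo = 0
                hi = r_lut.shape[0] - 1
                while hi - lo > 1:
                    mid = (lo + hi) // 2
                    if r_lut[mid] <= r_new:
                        lo = mid
                    else:
                        hi = mid
                f = (r_new - r_lut[lo]) / (r_lut[hi] - r_lut[lo])
                e_new = e_grid[lo] * (1.0 - f) + e_grid[hi] * f
            de = e - e_new
            mx = px + 0.5 * s * vx
            my = py + 0.5 * s * vy
            mz = pz + 0.5 * s * vz
            jx = int((mx - x0) / dx)
            jy = int((my - y0) / dy)
            jz = int((mz - z0) / dz)
            if 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz:
                dose[jx, jy, jz] += w * de
            e = e_new
        # move
        px += s * vx
        py += s * vy
        pz += s * vz
        pc = np.sqrt(e * e + 2.0 * e * _REST)
        if pc <= 0.0:
            continue
        # magnetic deflection, first order: dv = s*KB/pc * (v x B)
        if has_b:
            # trilinear interpolation of the field at the new position
            fx = (px - x0) / dx - 0.5
            fy = (py - y0) / dy - 0.5
            fz = (pz - z0) / dz - 0.5
            i0 = int(np.floor(fx))
            j0 = int(np.floor(fy))
            k0 = int(np.floor(fz))
            tx = fx - i0
            ty = fy - j0
            tz = fz - k0
            bxv = byv = bzv = 0.0
            for di in range(2):
                ii = min(max(i0 + di, 0), nx - 1)
                wxf = tx if di == 1 else 1.0 - tx
                for dj in range(2):
                    jj = min(max(j0 + dj, 0), ny - 1)
                    wyf = ty if dj == 1 else 1.0 - ty
                    for dk in range(2):
                        kk = min(max(k0 + dk, 0), nz - 1)
                        wzf = tz if dk == 1 else 1.0 - tz
                        wgt = wxf * wyf * wzf
                        bxv += wgt * bx_f[ii, jj, kk]
                        byv += wgt * by_f[ii, jj, kk]
                        bzv += wgt * bz_f[ii, jj, kk]
            cxx = vy * bzv - vz * byv
            cyy = vz * bxv - vx * bzv
            czz = vx * byv - vy * bxv
            fac = s * _KB / pc
            vx += fac * cxx
            vy += fac * cyy
            vz += fac * czz
            nrm = np.sqrt(vx * vx + vy * vy + vz * vz)
            vx, vy, vz = vx / nrm, vy / nrm, vz / nrm
        # Highland multiple scattering
        if use_msc:
            r_loc2 = rho[min(max(int((px - x0) / dx), 0), nx - 1),
                         min(max(int((py - y0) / dy), 0), ny - 1),
                         min(max(int((pz - z0) / dz), 0), nz - 1)]
            if r_loc2 > 1e-3:
                t_rad = s * r_loc2 / _X0_WATER
                etot = e + _REST
                beta = pc / etot
                lg = np.log(t_rad)
                corr = 1.0 + 0.038 * lg
                if corr < 0.25:
                    corr = 0.25
                th0 = 13.6 / (beta * pc) * np.sqrt(t_rad) * corr
                txa = th0 * _norm01(state)
                tya = th0 * _norm01(state)
                if abs(vz) < 0.99:
                    ux, uy, uz = -vy, vx, 0.0
                else:
                    ux, uy, uz = 1.0, 0.0, 0.0
                nn = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux, uy, uz = ux / nn, uy / nn, uz / nn
                wxx = vy * uz - vz * uy
                wyy = vz * ux - vx * uz
                wzz = vx * uy - vy * ux
                vx += txa * ux + tya * wxx
                vy += txa * uy + tya * wyy
                vz += txa * uz + tya * wzz
                nrm = np.sqrt(vx * vx + vy * vy + vz * vz)
                vx, vy, vz = vx / nrm, vy / nrm, vz / nrm
    return


@njit(cache=True, fastmath=True)
def electron_mc(
    pos, direc, energy, weight,
    rho, x0, y0, z0, dx, dy, dz,
    loge0, dlog, s_lut, r_lut, e_grid,
    bx_f, by_f, bz_f, has_b, use_msc,
    step_cm, cutoff, seed, dose,
):
    for i in range(pos.shape[0]):
        state = _rng_init(seed, i)
        _electron_history(
            pos[i, 0], pos[i, 1], pos[i, 2],
            direc[i, 0], direc[i, 1], direc[i, 2],
            energy[i], weight[i],
            rho, x0, y0, z0, dx, dy, dz,
            loge0, dlog, s_lut, r_lut, e_grid,
            bx_f, by_f, bz_f, has_b, use_msc,
            step_cm, cutoff, dose, state,
        )
    return


@njit(cache=True, fastmath=True)
def photon_analog(
    pos, direc, energy, weight,
    rho, x0, y0, z0, dx, dy, dz,
    loge0, dlog, mu_lut, pinc_lut, ppe_lut,
    s_lut, r_lut, e_grid,
    bx_f, by_f, bz_f, has_b,
    step, seed, score_scatter, spawn_electrons, e_cutoff, el_cutoff, el_step,
    dose,
):
    """Analog photon transport scoring transferred energy at collision sites.

    With ``spawn_electrons`` the transferred energy starts a CSDA electron
    along the photon direction instead of being deposited locally. With
    ``score_scatter`` false, histories end at their first collision
    (narrow-beam conditions).
    """
    nx, ny, nz = rho.shape
    x1 = x0 + nx * dx
    y1 = y0 + ny * dy
    z1 = z0 + nz * dz
    for i in range(pos.shape[0]):
        state = _rng_init(seed, i)
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        vx, vy, vz = direc[i, 0], direc[i, 1], direc[i, 2]
        e = energy[i]
        w = weight[i]
        alive = True
        n_events = 0
        while alive and e > e_cutoff and n_events < 64:
            mu = _lut(mu_lut, loge0, dlog, e)
            tin, tout = _aabb(px, py, pz, vx, vy, vz, x0, y0, z0, x1, y1, z1)
            if tin >= tout or tout <= 0.0:
                break
            if tin < 0.0:
                tin = 0.0
            tau_s = -np.log(_u01(state))
            tau = 0.0
            t = tin
            collided = False
            while t < tout:
                ds = step if t + step <= tout else tout - t
                tm = t + 0.5 * ds
                qx = px + vx * tm
                qy = py + vy * tm
                qz = pz + vz * tm
                ix = int((qx - x0) / dx)
                iy = int((qy - y0) / dy)
                iz = int((qz - z0) / dz)
                if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                    r = rho[ix, iy, iz]
                    if r > 0.0:
                        dtau = mu * r * ds
                        if tau + dtau >= tau_s:
                            frac = (tau_s - tau) / dtau
                            tc = t + frac * ds
                            px += vx * tc
                            py += vy * tc
                            pz += vz * tc
                            collided = True
                            break
                        tau += dtau
                t += ds
            if not collided:
                break
            n_events += 1
            ix = min(max(int((px - x0) / dx), 0), nx - 1)
            iy = min(max(int((py - y0) / dy), 0), ny - 1)
            iz = min(max(int((pz - z0) / dz), 0), nz - 1)
            p_inc = _lut(pinc_lut, loge0, dlog, e)
            p_pe = _lut(ppe_lut, loge0, dlog, e)
            r1 = _u01(state)
            if r1 < p_inc:
                e_out, cost = _kahn_compton(e, state)
                transfer = e - e_out
                if spawn_electrons and transfer > el_cutoff:
                    _electron_history(
                        px, py, pz, vx, vy, vz, transfer, w,
                        rho, x0, y0, z0, dx, dy, dz,
                        loge0, dlog, s_lut, r_lut, e_grid,
                        bx_f, by_f, bz_f, has_b, True,
                        el_step, el_cutoff, dose, state,
                    )
                else:
                    dose[ix, iy, iz] += w * transfer
                phi = 2.0 * np.pi * _u01(state)
                vx, vy, vz = _rotate(vx, vy, vz, cost, phi)
                e = e_out
            elif r1 < p_inc + p_pe:
                if spawn_electrons and e > el_cutoff:
                    _electron_history(
                        px, py, pz, vx, vy, vz, e, w,
                        rho, x0, y0, z0, dx, dy, dz,
                        loge0, dlog, s_lut, r_lut, e_grid,
                        bx_f, by_f, bz_f, has_b, True,
                        el_step, el_cutoff, dose, state,
                    )
                else:
                    dose[ix, iy, iz] += w * e
                alive = False
            else:
                transfer = e - _PAIR_THRESH
                if transfer > 0.0:
                    if spawn_electrons and transfer > el_cutoff:
                        _electron_history(
                            px, py, pz, vx, vy, vz, transfer, w,
                            rho, x0, y0, z0, dx, dy, dz,
                            loge0, dlog, s_lut, r_lut, e_grid,
                            bx_f, by_f, bz_f, has_b, True,
                            el_step, el_cutoff, dose, state,
                        )
                    else:
                        dose[ix, iy, iz] += w * transfer
                alive = False  # annihilation quanta are not followed here
            if not score_scatter:
                alive = False
    return


@njit(cache=True, fastmath=True)
def mh_sample_2d(pmf, n, burn_in, sigma_px, seed):
    """Metropolis-Hastings random walk on a 2-D pmf; returns flat indices."""
    np.random.seed(seed)
    ny, nx = pmf.shape
    out = np.empty(n, dtype=np.int64)
    # start at the distribution mode to avoid a cold start in a zero region
    best = 0
    bv = -1.0
    for j in range(ny * nx):
        v = pmf.flat[j]
        if v > bv:
            bv = v
            best = j
    cy = best // nx
    cx = best % nx
    cur = pmf[cy, cx]
    k = 0
    it = 0
    total = n + burn_in
    while it < total:
        py = cy + int(round(sigma_px * np.random.normal(0.0, 1.0)))
        px = cx + int(round(sigma_px * np.random.normal(0.0, 1.0)))
        if 0 <= py < ny and 0 <= px < nx:
            prop = pmf[py, px]
            if prop > 0.0 and (prop >= cur or np.random.random() < prop / cur):
                cy, cx = py, px
                cur = prop
        if it >= burn_in:
            out[k] = cy * nx + cx
            k += 1
        it += 1
    return out
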