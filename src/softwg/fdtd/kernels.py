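"""Numba time-stepping kernels for the Yee lattice.

All six field components live in same-shaped arrays with the usual staggered
interpretation: Ex at (i+1/2, j, k), Ey at (i, j+1/2, k), Ez at (i, j, k+1/2),
Hx at (i, j+1/2, k+1/2), Hy at (i+1/2, j, k+1/2), Hz at (i+1/2, j+1/2, k).

The electric update uses per-cell coefficients

    ca = (1 - sigma dt / 2 eps) / (1 + sigma dt / 2 eps)
    cb = (dt / eps) / (1 + sigma dt / 2 eps)

(the semi-implicit treatment of the conduction current, averaging sigma E
across the half step), and the magnetic update the constant dt / mu0.  PML
accumulators follow the recursion in :mod:`softwg.fdtd.pml`; the ``c``
coefficient arrays double as membership masks (zero outside the slabs).

Boundary planes where a tangential E component would need a neighbour
outside the grid are skipped, which realizes perfectly conducting outer
walls; a ``periodic`` flag per axis wraps those neighbours instead.
"""
from __future__ import annotations

import numba


@numba.njit(cache=True, fastmath=True)
def update_e(
    ex, ey, ez, hx, hy, hz,
    ca, cb, inv_dx,
    pexy, pexz, peyz, peyx, pezx, pezy,
    be_x, ce_x, be_y, ce_y, be_z, ce_z,
    per_x, per_y, per_z,
):
    nx, ny, nz = ex.shape
    # Ex: needs Hz at j-1 and Hy at k-1
    for i in range(nx):
        for j in range(ny):
            jm = j - 1
            if j == 0:
                if per_y:
                    jm = ny - 1
                else:
                    continue
            for k in range(nz):
                km = k - 1
                if k == 0:
                    if per_z:
                        km = nz - 1
                    else:
                        continue
                dhzdy = (hz[i, j, k] - hz[i, jm, k]) * inv_dx
                dhydz = (hy[i, j, k] - hy[i, j, km]) * inv_dx
                if ce_y[j] != 0.0:
                    pexy[i, j, k] = be_y[j] * pexy[i, j, k] + ce_y[j] * dhzdy
                    dhzdy += pexy[i, j, k]
                if ce_z[k] != 0.0:
                    pexz[i, j, k] = be_z[k] * pexz[i, j, k] + ce_z[k] * dhydz
                    dhydz += pexz[i, j, k]
                ex[i, j, k] = ca[i, j, k] * ex[i, j, k] + cb[i, j, k] * (dhzdy - dhydz)
    # Ey: needs Hx at k-1 and Hz at i-1
    for i in range(nx):
        im = i - 1
        if i == 0:
            if per_x:
                im = nx - 1
            else:
                continue
        for j in range(ny):
            for k in range(nz):
                km = k - 1
                if k == 0:
                    if per_z:
                        km = nz - 1
                    else:
                        continue
                dhxdz = (hx[i, j, k] - hx[i, j, km]) * inv_dx
                dhzdx = (hz[i, j, k] - hz[im, j, k]) * inv_dx
                if ce_z[k] != 0.0:
                    peyz[i, j, k] = be_z[k] * peyz[i, j, k] + ce_z[k] * dhxdz
                    dhxdz += peyz[i, j, k]
                if ce_x[i] != 0.0:
                    peyx[i, j, k] = be_x[i] * peyx[i, j, k] + ce_x[i] * dhzdx
                    dhzdx += peyx[i, j, k]
                ey[i, j, k] = ca[i, j, k] * ey[i, j, k] + cb[i, j, k] * (dhxdz - dhzdx)
    # Ez: needs Hy at i-1 and Hx at j-1
    for i in range(nx):
        im = i - 1
        if i == 0:
            if per_x:
                im = nx - 1
            else:
                continue
        for j in range(ny):
            jm = j - 1
            if j == 0:
                if per_y:
                    jm = ny - 1
                else:
                    continue
            for k in range(nz):
                dhydx = (hy[i, j, k] - hy[im, j, k]) * inv_dx
                dhxdy = (hx[i, j, k] - hx[i, jm, k]) * inv_dx
                if ce_x[i] != 0.0:
                    pezx[i, j, k] = be_x[i] * pezx[i, j, k] + ce_x[i] * dhydx
                    dhydx += pezx[i, j, k]
                if ce_y[j] != 0.0:
                    pezy[i, j, k] = be_y[j] * pezy[i, j, k] + ce_y[j] * dhxdy
                    dhxdy += pezy[i, j, k]
                ez[i, j, k] = ca[i, j, k] * ez[i, j, k] + cb[i, j, k] * (dhydx - dhxdy)


@numba.njit(cache=True, fastmath=True)
def update_h(
    ex, ey, ez, hx, hy, hz,
    db, inv_dx,
    phxy, phxz, phyz, phyx, phzx, phzy,
    bh_x, ch_x, bh_y, ch_y, bh_z, ch_z,
    per_x, per_y, per_z,
):
    nx, ny, nz = hx.shape
    # Hx: needs Ez at j+1 and Ey at k+1
    for i in range(nx):
        for j in range(ny):
            jp = j + 1
            if j == ny - 1:
                if per_y:
                    jp = 0
                else:
                    continue
            for k in range(nz):
                kp = k + 1
                if k == nz - 1:
                    if per_z:
                        kp = 0
                    else:
                        continue
                dezdy = (ez[i, jp, k] - ez[i, j, k]) * inv_dx
                deydz = (ey[i, j, kp] - ey[i, j, k]) * inv_dx
                if ch_y[j] != 0.0:
                    phxy[i, j, k] = bh_y[j] * phxy[i, j, k] + ch_y[j] * dezdy
                    dezdy += phxy[i, j, k]
                if ch_z[k] != 0.0:
                    phxz[i, j, k] = bh_z[k] * phxz[i, j, k] + ch_z[k] * deydz
                    deydz += phxz[i, j, k]
                hx[i, j, k] -= db * (dezdy - deydz)
    # Hy: needs Ex at k+1 and Ez at i+1
    for i in range(nx):
        ip = i + 1
        if i == nx - 1:
            if per_x:
                ip = 0
            else:
                continue
        for j in range(ny):
            for k in range(nz):
                kp = k + 1
                if k == nz - 1:
                    if per_z:
                        kp = 0
                    else:
                        continue
                dexdz = (ex[i, j, kp] - ex[i, j, k]) * inv_dx
                dezdx = (ez[ip, j, k] - ez[i, j, k]) * inv_dx
                if ch_z[k] != 0.0:
                    phyz[i, j, k] = bh_z[k] * phyz[i, j, k] + ch_z[k] * dexdz
                    dexdz += phyz[i, j, k]
                if ch_x[i] != 0.0:
                    phyx[i, j, k] = bh_x[i] * phyx[i, j, k] + ch_x[i] * dezdx
                    dezdx += phyx[i, j, k]
                hy[i, j, k] -= db * (dexdz - dezdx)
    # Hz: needs Ey at i+1 and Ex at j+1
    for i in range(nx):
        ip = i + 1
        if i == nx - 1:
            if per_x:
                ip = 0
            else:
                continue
        for j in range(ny):
            jp = j + 1
            if j == ny - 1:
                if per_y:
                    jp = 0
                else:
                    continue
            for k in range(nz):
                deydx = (ey[ip, j, k] - ey[i, j, k]) * inv_dx
                dexdy = (ex[i, jp, k] - ex[i, j, k]) * inv_dx
                if ch_x[i] != 0.0:
                    phzx[i, j, k] = bh_x[i] * phzx[i, j, k] + ch_x[i] * deydx
                    deydx += phzx[i, j, k]
                if ch_y[j] != 0.0:
                    phzy[i, j, k] = bh_y[j] * phzy[i, j, k] + ch_y[j] * dexdy
                    dexdy += phzy[i, j, k]
                hz[i, j, k] -= db * (deydx - dexdy)
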