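"""Numba inner loops for vertex-model relaxation and reaction-diffusion.

Kept separate so the public modules stay readable; the kernels operate on
flat index arrays produced by ``CellNetwork._compiled`` and the RD state
vectors.  Conventions (force directions, clamp order) must stay in lockstep
with ``CellNetwork.vertex_force`` and the documented Euler update.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _areas_means(pos, flat, off, area, mx, my):
    nc = off.shape[0] - 1
    for c in range(nc):
        a = 0.0
        sx = 0.0
        sy = 0.0
        lo, hi = off[c], off[c + 1]
        for k in range(lo, hi):
            i = flat[k]
            j = flat[lo] if k == hi - 1 else flat[k + 1]
            a += pos[i, 0] * pos[j, 1] - pos[j, 0] * pos[i, 1]
            sx += pos[i, 0]
            sy += pos[i, 1]
        area[c] = 0.5 * a
        m = hi - lo
        mx[c] = sx / m
        my[c] = sy / m


@njit(cache=True)
def relax_kernel(pos, wv1, wv2, sw, sc, ss, flat, off,
                 k_t, k_s, l_0, k_p, dt, tol, max_iter, max_step):
    """Forward-Euler overdamped vertex dynamics; mutates ``pos`` in place.

    Returns (iterations used, last max per-step displacement).  Per-step
    displacements are rescaled so none exceeds ``max_step`` (stability cap
    for the explicit scheme); capped steps never count as converged because
    the uncapped displacement is what is compared with ``tol``.

    The rigid-body components of the force field (net force and net torque
    about the vertex centroid) are projected out before stepping: because
    each wall side receives a fixed pressure magnitude irrespective of wall
    length, the boundary pressure generically sums to a small net force and
    torque on the whole tissue, which would translate/rotate it rigidly
    forever without changing any length or area.  Removing those zero modes
    leaves the deformation dynamics untouched and makes the equilibrium well
    defined.
    """
    nv = pos.shape[0]
    nw = wv1.shape[0]
    ns = sw.shape[0]
    nc = off.shape[0] - 1
    F = np.zeros((nv, 2))
    trial = np.zeros((nv, 2))
    area = np.zeros(nc)
    mx = np.zeros(nc)
    my = np.zeros(nc)
    maxdisp = np.inf
    it = 0
    while it < max_iter:
        it += 1
        _areas_means(pos, flat, off, area, mx, my)
        for i in range(nv):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
        # elastic: k_s (l - l_0) along the wall, restoring toward l_0
        for w in range(nw):
            i, j = wv1[w], wv2[w]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            l = (dx * dx + dy * dy) ** 0.5
            if l < 1e-12:
                continue
            f = k_s * (l - l_0) / l
            F[i, 0] += f * dx
            F[i, 1] += f * dy
            F[j, 0] -= f * dx
            F[j, 1] -= f * dy
        # pressure: k_p / V per wall side, both endpoints; the outward
        # normal is the directed edge rotated by -90 degrees, with the sign
        # ss pre-computed from the cell's counter-clockwise cycle (exact
        # for any cell shape, unlike a centroid heuristic)
        for s in range(ns):
            w = sw[s]
            c = sc[s]
            i, j = wv1[w], wv2[w]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            l = (dx * dx + dy * dy) ** 0.5
            if l < 1e-12 or area[c] < 1e-12:
                continue
            nx = ss[s] * dy / l
            ny = -ss[s] * dx / l
            mag = k_p / area[c]
            F[i, 0] += mag * nx
            F[i, 1] += mag * ny
            F[j, 0] += mag * nx
            F[j, 1] += mag * ny
        fx = 0.0
        fy = 0.0
        cx = 0.0
        cy = 0.0
        for i in range(nv):
            fx += F[i, 0]
            fy += F[i, 1]
            cx += pos[i, 0]
            cy += pos[i, 1]
        fx /= nv
        fy /= nv
        cx /= nv
        cy /= nv
        for i in range(nv):
            F[i, 0] -= fx
            F[i, 1] -= fy
        torque = 0.0
        inertia = 0.0
        for i in range(nv):
            rx = pos[i, 0] - cx
            ry = pos[i, 1] - cy
            torque += rx * F[i, 1] - ry * F[i, 0]
            inertia += rx * rx + ry * ry
        if inertia > 0.0:
            omega = torque / inertia
            for i in range(nv):
                rx = pos[i, 0] - cx
                ry = pos[i, 1] - cy
                F[i, 0] += omega * ry
                F[i, 1] -= omega * rx
        step = dt * k_t
        maxdisp = 0.0
        for i in range(nv):
            d = step * (F[i, 0] * F[i, 0] + F[i, 1] * F[i, 1]) ** 0.5
            if d > maxdisp:
                maxdisp = d
        scale = 1.0
        if maxdisp > max_step:
            scale = max_step / maxdisp
        # area backtracking: turgor pressure diverges as a cell's area
        # shrinks, so the true overdamped dynamics can never invert a
        # polygon — only the explicit Euler step can.  Halve the step until
        # every cell keeps a positive area.
        for _ in range(60):
            for i in range(nv):
                trial[i, 0] = pos[i, 0] + step * scale * F[i, 0]
                trial[i, 1] = pos[i, 1] + step * scale * F[i, 1]
            _areas_means(trial, flat, off, area, mx, my)
            ok = True
            for c in range(nc):
                if area[c] <= 0.0:
                    ok = False
                    break
            if ok:
                break
            scale *= 0.5
        for i in range(nv):
            pos[i, 0] = trial[i, 0]
            pos[i, 1] = trial[i, 1]
        if maxdisp < tol:
            break
    return it, maxdisp


@njit(cache=True)
def rd_kernel(u, v, e1, e2, psi,
              alpha_s, alpha_d, beta, gamma, delta, eps,
              d_u, d_v, u_max, dt, n_steps):
    """Euler integration of the activator-inhibitor dynamics on the cell
    adjacency graph; mutates ``u`` and ``v`` in place.

    ``e1``/``e2`` are the wall-sharing cell pairs (each unordered pair once);
    ``psi`` is the per-cell extra activator decay (alpha_m in marginal cells,
    0 elsewhere).  After each step u is clipped to [0, u_max] and v to
    [0, inf).
    """
    n = u.shape[0]
    ne = e1.shape[0]
    lap_u = np.zeros(n)
    lap_v = np.zeros(n)
    phimax = alpha_d * u_max
    for _ in range(n_steps):
        for i in range(n):
            lap_u[i] = 0.0
            lap_v[i] = 0.0
        for k in range(ne):
            a, b = e1[k], e2[k]
            du = u[b] - u[a]
            dv = v[b] - v[a]
            lap_u[a] += du
            lap_u[b] -= du
            lap_v[a] += dv
            lap_v[b] -= dv
        for i in range(n):
            x = eps + alpha_s * u[i] - beta * v[i]
            if x < 0.0:
                x = 0.0
            elif x > phimax:
                x = phimax
            du_dt = x - (alpha_d + psi[i]) * u[i] + d_u * lap_u[i]
            dv_dt = gamma * u[i] - delta * v[i] + d_v * lap_v[i]
            u[i] += dt * du_dt
            v[i] += dt * dv_dt
            if u[i] < 0.0:
                u[i] = 0.0
            elif u[i] > u_max:
                u[i] = u_max
            if v[i] < 0.0:
                v[i] = 0.0
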