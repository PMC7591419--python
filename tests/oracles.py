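"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most transparent route
available (triple loops, exhaustive enumeration, all-pairs distances)
and share no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_step(T, T_min, D, Q, props, dt, spacing_mm):
    """One explicit bioheat step as pure-Python triple loops.

    Replicates the solver arithmetic (face-flux divergence, perfusion
    norming, enthalpy update and inversion) operation by operation so
    the comparison can be made bitwise.
    """
    nx, ny, nz = T.shape
    inv = [1.0 / (s * 1e-3) ** 2 for s in spacing_mm]
    rho, cf, cu = props.rho_tissue, props.c_frozen, props.c_unfrozen
    kf, ku, L = props.k_frozen, props.k_unfrozen, props.latent_heat
    Ts, W = props.T_solidus, props.T_liquidus - props.T_solidus
    om, rb, cb, Tb = (props.omega_perfusion, props.rho_blood,
                      props.c_blood, props.T_body)

    def k_of(t):
        frac = min(max((t - Ts) / W, 0.0), 1.0)
        return kf + (ku - kf) * frac

    def h_of(t):
        theta = min(max(t - Ts, 0.0), W)
        h = rho * (cf * theta + 0.5 * (cu - cf) * theta**2 / W + L * theta / W)
        h = h + (rho * cf * (t - Ts) if t < Ts else 0.0)
        h = h + (rho * cu * (t - Ts - W) if t > Ts + W else 0.0)
        return h

    a = 0.5 * rho * (cu - cf) / W
    b = rho * (cf + L / W)
    h_liq = rho * (0.5 * (cf + cu) * W + L)

    def t_of(h):
        hc = min(max(h, 0.0), h_liq)
        disc = np.sqrt(b * b + 4.0 * a * hc)
        t = Ts + 2.0 * hc / (b + disc)
        if h < 0.0:
            t = Ts + h / (rho * cf)
        if h > h_liq:
            t = Ts + W + (h - h_liq) / (rho * cu)
        return t

    k = np.empty_like(T)
    for i in range(nx):
        for j in range(ny):
            for l in range(nz):
                k[i, j, l] = k_of(T[i, j, l])

    # face fluxes per axis, then the same two-pass accumulation order as
    # the vectorised solver: (+right, -left) for x, then y, then z
    div = np.zeros_like(T)
    for axis, n_ax in ((0, nx), (1, ny), (2, nz)):
        g = {}
        for i in range(nx):
            for j in range(ny):
                for l in range(nz):
                    idx = (i, j, l)
                    if idx[axis] >= n_ax - 1:
                        continue
                    nb = list(idx)
                    nb[axis] += 1
                    nb = tuple(nb)
                    k_face = 0.5 * (k[idx] + k[nb])
                    g[idx] = k_face * (T[nb] - T[idx]) * inv[axis]
        for idx, gv in g.items():
            div[idx] += gv
        for idx, gv in g.items():
            nb = list(idx)
            nb[axis] += 1
            div[tuple(nb)] -= gv

    T_new = np.empty_like(T)
    for i in range(nx):
        for j in range(ny):
            for l in range(nz):
                t = T[i, j, l]
                w = (1.0 - D[i, j, l]) * om * rb * cb
                q = w * (Tb - t)
                if t <= Ts:
                    q = 0.0
                rhs = div[i, j, l] + q
                rhs = rhs + Q[i, j, l]
                h = h_of(t) + dt * rhs
                T_new[i, j, l] = t_of(h)
    T_min_new = np.minimum(T_min, T_new)
    return T_new, T_min_new


def _sphere_through(points: np.ndarray):
    """Sphere with all given points (1-4 of them) on its boundary."""
    pts = np.asarray(points, dtype=float)
    m = len(pts)
    if m == 1:
        return pts[0], 0.0
    if m == 2:
        c = 0.5 * (pts[0] + pts[1])
        return c, float(np.linalg.norm(pts[0] - c))
    p0 = pts[0]
    if m == 3:
        u, v = pts[1] - p0, pts[2] - p0
        G = np.array([[u @ u, u @ v], [u @ v, v @ v]])
        rhs = 0.5 * np.array([u @ u, v @ v])
        ab = np.linalg.solve(G, rhs)
        c = p0 + ab[0] * u + ab[1] * v
        return c, float(np.linalg.norm(p0 - c))
    A = 2.0 * (pts[1:] - p0)
    rhs = np.einsum("ij,ij->i", pts[1:], pts[1:]) - p0 @ p0
    c = np.linalg.solve(A, rhs)
    return c, float(np.linalg.norm(p0 - c))


def brute_force_min_sphere(points: np.ndarray):
    """Exhaustive minimal enclosing sphere over all <=4-point support sets."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    best_c, best_r = None, np.inf
    for size in (1, 2, 3, 4):
        for combo in itertools.combinations(range(n), size):
            try:
                c, r = _sphere_through(pts[list(combo)])
            except np.linalg.LinAlgError:
                continue
            if r < best_r - 1e-12:
                d = np.linalg.norm(pts - c, axis=1)
                if np.all(d <= r * (1 + 1e-10) + 1e-9):
                    best_c, best_r = c, r
    return best_c, best_r


def brute_force_aae(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    """Mean symmetric surface distance via the full distance matrix."""
    pts_a = np.asarray(pts_a, dtype=float)
    pts_b = np.asarray(pts_b, dtype=float)
    dmat = np.sqrt(
        ((pts_a[:, None, :] - pts_b[None, :, :]) ** 2).sum(axis=2)
    )
    d_ab = dmat.min(axis=1)
    d_ba = dmat.min(axis=0)
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))
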