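"""Numba kernels: site–site energy, analytic gradient, L-BFGS minimizer.

Atom layout is fixed package-wide: atom 0 is the ion, then O,H,H per
water.  Parameters travel as a flat float64 vector (see PARAM_* indices)
so the kernels stay signature-stable and cacheable.

Units: Å, kJ/mol, elementary charge, radians.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the parameter vector
PARAM_Q_O = 0
PARAM_Q_H = 1
PARAM_Q_ION = 2
PARAM_EPS_OO = 3
PARAM_SIG_OO = 4
PARAM_EPS_ION_O = 5
PARAM_SIG_ION_O = 6
PARAM_K_BOND = 7
PARAM_R0 = 8
PARAM_K_ANGLE = 9
PARAM_THETA0 = 10
PARAM_KE = 11
N_PARAMS = 12

STATUS_OK = 0
STATUS_SINGULAR = 1

_SINGULAR_R = 1e-6


@njit(cache=True)
def _site_charge(atom: int, params: np.ndarray) -> float:
    if atom == 0:
        return params[PARAM_Q_ION]
    if (atom - 1) % 3 == 0:
        return params[PARAM_Q_O]
    return params[PARAM_Q_H]


@njit(cache=True)
def energy_gradient(coords: np.ndarray, params: np.ndarray, n_waters: int):
    """Energy (kJ/mol) and analytic gradient (kJ/mol/Å) of a cluster.

    ``coords`` is the flat (n_atoms*3,) coordinate vector.  Returns
    (energy, gradient, status); status != STATUS_OK flags overlapping
    sites (r < 1e-6 Å) and the caller must not trust the numbers.
    """
    n_atoms = 1 + 3 * n_waters
    grad = np.zeros(n_atoms * 3)
    energy = 0.0
    ke = params[PARAM_KE]

    # ---- intermolecular: Coulomb on all unlike-molecule site pairs,
    # Lennard-Jones on O-O and ion-O pairs
    for a in range(n_atoms):
        mol_a = 0 if a == 0 else 1 + (a - 1) // 3
        qa = _site_charge(a, params)
        is_o_a = a > 0 and (a - 1) % 3 == 0
        for b in range(a + 1, n_atoms):
            mol_b = 0 if b == 0 else 1 + (b - 1) // 3
            if mol_a == mol_b:
                continue
            dx = coords[3 * a] - coords[3 * b]
            dy = coords[3 * a + 1] - coords[3 * b + 1]
            dz = coords[3 * a + 2] - coords[3 * b + 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            if r < _SINGULAR_R:
                return np.inf, grad, STATUS_SINGULAR
            qb = _site_charge(b, params)
            # Coulomb
            e_c = ke * qa * qb / r
            energy += e_c
            dedr = -e_c / r
            # Lennard-Jones
            is_o_b = b > 0 and (b - 1) % 3 == 0
            eps = 0.0
            sig = 0.0
            if is_o_a and is_o_b:
                eps = params[PARAM_EPS_OO]
                sig = params[PARAM_SIG_OO]
            elif (a == 0 and is_o_b) or (b == 0 and is_o_a):
                eps = params[PARAM_EPS_ION_O]
                sig = params[PARAM_SIG_ION_O]
            if eps > 0.0:
                sr6 = (sig / r) ** 6
                sr12 = sr6 * sr6
                energy += 4.0 * eps * (sr12 - sr6)
                dedr += 4.0 * eps * (-12.0 * sr12 + 6.0 * sr6) / r
            fx = dedr * dx / r
            fy = dedr * dy / r
            fz = dedr * dz / r
            grad[3 * a] += fx
            grad[3 * a + 1] += fy
            grad[3 * a + 2] += fz
            grad[3 * b] -= fx
            grad[3 * b + 1] -= fy
            grad[3 * b + 2] -= fz

    # ---- intramolecular restraints: k_bond (r-r0)^2 per O-H,
    # k_angle (theta-theta0)^2 per water
    kb = params[PARAM_K_BOND]
    r0 = params[PARAM_R0]
    ka = params[PARAM_K_ANGLE]
    th0 = params[PARAM_THETA0]
    for w in range(n_waters):
        io = 1 + 3 * w
        for hh in range(2):
            ih = io + 1 + hh
            dx = coords[3 * ih] - coords[3 * io]
            dy = coords[3 * ih + 1] - coords[3 * io + 1]
            dz = coords[3 * ih + 2] - coords[3 * io + 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < _SINGULAR_R:
                return np.inf, grad, STATUS_SINGULAR
            energy += kb * (r - r0) ** 2
            dedr = 2.0 * kb * (r - r0)
            grad[3 * ih] += dedr * dx / r
            grad[3 * ih + 1] += dedr * dy / r
            grad[3 * ih + 2] += dedr * dz / r
            grad[3 * io] -= dedr * dx / r
            grad[3 * io + 1] -= dedr * dy / r
            grad[3 * io + 2] -= dedr * dz / r
        # angle H1-O-H2
        i1 = io + 1
        i2 = io + 2
        ux = coords[3 * i1] - coords[3 * io]
        uy = coords[3 * i1 + 1] - coords[3 * io + 1]
        uz = coords[3 * i1 + 2] - coords[3 * io + 2]
        vx = coords[3 * i2] - coords[3 * io]
        vy = coords[3 * i2 + 1] - coords[3 * io + 1]
        vz = coords[3 * i2 + 2] - coords[3 * io + 2]
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        energy += ka * (theta - th0) ** 2
        s2 = 1.0 - c * c
        if s2 > 1e-12:
            dedc = -2.0 * ka * (theta - th0) / np.sqrt(s2)
            # d cos / d H1 and H2
            g1x = dedc * (vx / (ru * rv) - c * ux / (ru * ru))
            g1y = dedc * (vy / (ru * rv) - c * uy / (ru * ru))
            g1z = dedc * (vz / (ru * rv) - c * uz / (ru * ru))
            g2x = dedc * (ux / (ru * rv) - c * vx / (rv * rv))
            g2y = dedc * (uy / (ru * rv) - c * vy / (rv * rv))
            g2z = dedc * (uz / (ru * rv) - c * vz / (rv * rv))
            grad[3 * i1] += g1x
            grad[3 * i1 + 1] += g1y
            grad[3 * i1 + 2] += g1z
            grad[3 * i2] += g2x
            grad[3 * i2 + 1] += g2y
            grad[3 * i2 + 2] += g2z
            grad[3 * io] -= g1x + g2x
            grad[3 * io + 1] -= g1y + g2y
            grad[3 * io + 2] -= g1z + g2z

    return energy, grad, STATUS_OK


@njit(cache=True)
def fd_hessian(x: np.ndarray, params: np.ndarray, n_waters: int, step: float):
    """Central finite-difference Hessian of the energy (symmetrized)."""
    n = x.size
    hess = np.empty((n, n))
    xw = x.copy()
    for i in range(n):
        xi = xw[i]
        xw[i] = xi + step
        _, gp, _ = energy_gradient(xw, params, n_waters)
        xw[i] = xi - step
        _, gm, _ = energy_gradient(xw, params, n_waters)
        xw[i] = xi
        hess[i, :] = (gp - gm) / (2.0 * step)
    return 0.5 * (hess + hess.T)


@njit(cache=True)
def newton_polish(x0: np.ndarray, params: np.ndarray, n_waters: int,
                  gtol: float, max_iter: int):
    """Modified-Newton refinement near a minimum.

    Eigenvalue-clamped Newton steps (|lambda| floored) with a descent
    guard; used after L-BFGS because the cluster surface has nearly
    flat water-torsion modes that stall first-order methods.
    """
    x = x0.copy()
    f, g, status = energy_gradient(x, params, n_waters)
    if status != STATUS_OK or not np.isfinite(f):
        return x, np.inf, 0, False
    n = x.size
    v = np.zeros((n, n))
    lam = np.zeros(n)
    age = 99  # steps since the factorization was computed
    for it in range(max_iter):
        gmax = np.abs(g).max()
        if gmax <= gtol:
            return x, f, it, True
        if age >= 4:
            hess = fd_hessian(x, params, n_waters, 1e-4)
            w, v = np.linalg.eigh(hess)
            v = np.ascontiguousarray(v)
            lam = np.abs(w)
            for i in range(lam.size):
                if lam[i] < 0.05:
                    lam[i] = 0.05
            age = 0
        gh = g @ v  # == v.T g, contiguous-friendly
        d = -(v @ (gh / lam))
        step = 1.0
        ok = False
        fn = f
        gn = g
        xn = x
        for _ls in range(30):
            xn = x + step * d
            fn, gn, status = energy_gradient(xn, params, n_waters)
            if (
                status == STATUS_OK
                and np.isfinite(fn)
                and (fn <= f or np.abs(gn).max() < 0.5 * gmax)
            ):
                ok = True
                break
            step *= 0.5
        if not ok:
            if age == 0:
                return x, f, it, False
            age = 99  # retry once with a fresh Hessian at this point
            continue
        age = 99 if step < 1.0 else age + 1
        x = xn
        f = fn
        g = gn
    _, g, _ = energy_gradient(x, params, n_waters)
    return x, f, max_iter, np.abs(g).max() <= gtol


@njit(cache=True)
def lbfgs_minimize(x0: np.ndarray, params: np.ndarray, n_waters: int,
                   gtol: float, max_iter: int):
    """Limited-memory BFGS with Armijo backtracking.

    Returns (x, f, n_iter, converged).  ``converged`` is False when the
    iteration cap is hit or a line search fails; the best iterate seen
    is always returned.
    """
    m = 8
    n = x0.size
    x = x0.copy()
    s_hist = np.zeros((m, n))
    y_hist = np.zeros((m, n))
    rho = np.zeros(m)
    alpha = np.zeros(m)
    f, g, status = energy_gradient(x, params, n_waters)
    if status != STATUS_OK or not np.isfinite(f):
        return x, np.inf, 0, False
    n_hist = 0
    head = 0
    for it in range(max_iter):
        gmax = 0.0
        for i in range(n):
            a = abs(g[i])
            if a > gmax:
                gmax = a
        if gmax <= gtol:
            return x, f, it, True
        # two-loop recursion
        q = g.copy()
        for j in range(n_hist):
            i = (head - 1 - j) % m
            alpha[i] = rho[i] * np.dot(s_hist[i], q)
            q -= alpha[i] * y_hist[i]
        if n_hist > 0:
            last = (head - 1) % m
            gamma = np.dot(s_hist[last], y_hist[last]) / np.dot(
                y_hist[last], y_hist[last]
            )
            q *= gamma
        else:
            # cap the very first step to 0.05 Å per coordinate
            q *= 0.05 / max(1.0, gmax)
        for j in range(n_hist - 1, -1, -1):
            i = (head - 1 - j) % m
            beta = rho[i] * np.dot(y_hist[i], q)
            q += (alpha[i] - beta) * s_hist[i]
        d = -q
        gtd = np.dot(g, d)
        if gtd >= 0.0:  # not a descent direction; reset
            d = -g * (0.05 / max(1.0, gmax))
            gtd = np.dot(g, d)
        step = 1.0
        ok = False
        fn = f
        gn = g
        xn = x
        for _ls in range(50):
            xn = x + step * d
            fn, gn, status = energy_gradient(xn, params, n_waters)
            if status == STATUS_OK and np.isfinite(fn) and fn <= f + 1e-4 * step * gtd:
                ok = True
                break
            step *= 0.5
        if not ok:
            return x, f, it, False
        s = xn - x
        y = gn - g
        sy = np.dot(s, y)
        if sy > 1e-10:
            s_hist[head] = s
            y_hist[head] = y
            rho[head] = 1.0 / sy
            head = (head + 1) % m
            if n_hist < m:
                n_hist += 1
        x = xn
        f = fn
        g = gn
    return x, f, max_iter, False


@njit(cache=True)
def minimize_cluster(x0: np.ndarray, params: np.ndarray, n_waters: int,
                     gtol: float, max_iter: int):
    """Hybrid minimizer: coarse L-BFGS descent, then Newton polish.

    Returns (x, f, n_iter, converged) with n_iter the combined count.
    """
    coarse = gtol if gtol > 0.5 else 0.5
    x, f, it1, _ = lbfgs_minimize(x0, params, n_waters, coarse, max_iter)
    if not np.isfinite(f):
        return x, f, it1, False
    x, f, it2, conv = newton_polish(x, params, n_waters, gtol, 60)
    if not conv:
        # fall back to plain L-BFGS at the requested tolerance
        x, f, it3, conv = lbfgs_minimize(x, params, n_waters, gtol, max_iter)
        x, f, it4, conv2 = newton_polish(x, params, n_waters, gtol, 30)
        return x, f, it1 + it2 + it3 + it4, conv or conv2
    return x, f, it1 + it2, conv
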