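"""Numba-compiled per-cell implicit integrator for the population stepper.

The cell ODEs are stiff: evolved enzymes can reach rate constants of order
``v_max * [protein] / K`` in the thousands per time step, so explicit
solvers need thousands of evaluations per unit step.  Cells on different
sites are mutually decoupled within the cell-update phase, which makes a
per-cell implicit scheme with small dense Jacobians far cheaper than any
global solve.  Each cell is advanced by adaptive backward Euler with a
modified-Newton iteration (finite-difference Jacobian, reused across
substeps) and a free local-error estimate from the change of the
right-hand side across the accepted substep.  Accuracy is controlled by a
weighted-RMS test with the population-level tolerances; the high-accuracy
reference path for single cells remains the scipy LSODA route in
``microverse.cell.integrate_cell``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .genome import ENZYME

# state layout per cell: [Vol, B, cint(m), prot(g_i), cext(m)]


@njit(cache=True)
def _rhs(
    x, out, m, gi, e_idx, b1, b2,
    prom, ks, ke, vmax, is_enz, conv, sub, tdir,
    rs, ps, deg_m, mem_diff, par, b_pop, stoich_pow,
):
    g_rate, s_shrink, vol_max, expr_cost, deg_b, deg_p, energy_cost = (
        par[0], par[1], par[2], par[3], par[4], par[5], par[6]
    )
    vol = x[0]
    if vol < 1e-12:
        vol = 1e-12
    b = x[1] if x[1] > 0.0 else 0.0
    o_ci = 2
    o_pr = 2 + m
    o_ce = 2 + m + gi
    d = o_ce + m

    for k in range(d):
        out[k] = 0.0

    denom = b + b_pop
    scal = b / denom if denom > 0.0 else 0.0

    # gene fluxes
    pr_sum = 0.0
    v_tr_tot = 0.0
    ce_e = x[o_ci + e_idx]
    if ce_e < 0.0:
        ce_e = 0.0
    for j in range(gi):
        pj = x[o_pr + j]
        if pj < 0.0:
            pj = 0.0
        pr_sum += prom[j]
        if is_enz[j]:
            r = conv[j]
            rate = vmax[j] * pj
            for mm in range(m):
                st = rs[r, mm]
                if st > 0:
                    c = x[o_ci + mm]
                    if c < 0.0:
                        c = 0.0
                    if stoich_pow:
                        rate *= c ** st / (c + ks[j])
                        # stoichiometric power on the numerator only;
                        # denominator keeps one (c+K) factor per reactant
                    else:
                        rate *= c / (c + ks[j])
            for mm in range(m):
                st = ps[r, mm] - rs[r, mm]
                if st != 0:
                    out[o_ci + mm] += st * rate
        else:
            smet = sub[j]
            if tdir[j] > 0.0:
                s = x[o_ce + smet]
            else:
                s = x[o_ci + smet]
            if s < 0.0:
                s = 0.0
            rate = vmax[j] * pj * (s / (s + ks[j])) * (ce_e / (ce_e + ke[j]))
            out[o_ci + smet] += tdir[j] * rate
            out[o_ce + smet] -= tdir[j] * rate * vol
            v_tr_tot += rate
        # protein expression (degradation/dilution added below)
        out[o_pr + j] += prom[j] * scal

    out[o_ci + e_idx] -= energy_cost * v_tr_tot

    # passive membrane diffusion
    for mm in range(m):
        ci = x[o_ci + mm]
        if ci < 0.0:
            ci = 0.0
        ce = x[o_ce + mm]
        if ce < 0.0:
            ce = 0.0
        mem = mem_diff[mm] * (ce - ci)
        out[o_ci + mm] += mem
        out[o_ce + mm] -= mem * vol

    # production from building blocks
    cb1 = x[o_ci + b1]
    if cb1 < 0.0:
        cb1 = 0.0
    cb2 = x[o_ci + b2]
    if cb2 < 0.0:
        cb2 = 0.0
    production = cb1 * cb2 / (1.0 + abs(cb1 - cb2))
    out[o_ci + b1] -= production
    out[o_ci + b2] -= production

    # volume growth, budget and dilution
    vol_growth = g_rate * vol * (1.0 - vol) / vol_max * scal
    d_vol = vol_growth - s_shrink * vol
    rho = d_vol / vol
    out[0] = d_vol
    out[1] = (
        production
        - vol_growth * scal * b
        - expr_cost * pr_sum * scal * b
        - deg_b * b
        - rho * b
    )

    # degradation and dilution of internal molecules
    for mm in range(m):
        ci = x[o_ci + mm]
        if ci < 0.0:
            ci = 0.0
        out[o_ci + mm] -= deg_m[mm] * ci + rho * ci
    for j in range(gi):
        pj = x[o_pr + j]
        if pj < 0.0:
            pj = 0.0
        out[o_pr + j] -= deg_p * pj + rho * pj
    return production


@njit(cache=True)
def _lu_factor(a, piv):
    """In-place dense LU with partial pivoting; returns False if singular."""
    d = a.shape[0]
    for k in range(d):
        p = k
        amax = abs(a[k, k])
        for i in range(k + 1, d):
            v = abs(a[i, k])
            if v > amax:
                amax = v
                p = i
        if amax < 1e-300:
            return False
        piv[k] = p
        if p != k:
            for j in range(d):
                tmp = a[k, j]
                a[k, j] = a[p, j]
                a[p, j] = tmp
        inv = 1.0 / a[k, k]
        for i in range(k + 1, d):
            l = a[i, k] * inv
            a[i, k] = l
            if l != 0.0:
                for j in range(k + 1, d):
                    a[i, j] -= l * a[k, j]
    return True


@njit(cache=True)
def _lu_solve(a, piv, b):
    """Solve with factors from :func:`_lu_factor`; overwrites ``b``."""
    d = a.shape[0]
    for k in range(d):
        p = piv[k]
        if p != k:
            tmp = b[k]
            b[k] = b[p]
            b[p] = tmp
    for k in range(d):
        for i in range(k + 1, d):
            b[i] -= a[i, k] * b[k]
    for k in range(d - 1, -1, -1):
        s = b[k]
        for j in range(k + 1, d):
            s -= a[k, j] * b[j]
        b[k] = s / a[k, k]


@njit(cache=True)
def _build_newton_matrix(jac, h, mmat, piv):
    """Factor I - h*jac into ``mmat``/``piv``; returns False if singular."""
    d = jac.shape[0]
    for a in range(d):
        for bb in range(d):
            mmat[a, bb] = -h * jac[a, bb]
        mmat[a, a] += 1.0
    return _lu_factor(mmat, piv)


@njit(cache=True)
def _newton_be(
    x0, h, mmat, piv, res, f_work, y, rtol, atol, m, gi, e_idx, b1, b2,
    prom, ks, ke, vmax, is_enz, conv, sub, tdir,
    rs, ps, deg_m, mem_diff, par, b_pop, stoich_pow,
):
    """Solve y = x0 + h f(y) by modified Newton with a pre-factored
    iteration matrix (possibly built for a slightly different h).

    Returns True on convergence; y holds the solution.
    """
    d = x0.shape[0]
    for k in range(d):
        y[k] = x0[k]
    for _ in range(8):
        _rhs(y, f_work, m, gi, e_idx, b1, b2, prom, ks, ke, vmax, is_enz,
             conv, sub, tdir, rs, ps, deg_m, mem_diff, par, b_pop, stoich_pow)
        for k in range(d):
            res[k] = x0[k] + h * f_work[k] - y[k]
        _lu_solve(mmat, piv, res)
        nrm = 0.0
        for k in range(d):
            y[k] += res[k]
            w = atol + rtol * abs(y[k])
            nrm += (res[k] / w) ** 2
        if (nrm / d) ** 0.5 < 0.33:
            return True
    return False


@njit(cache=True)
def _fd_jacobian(
    x, f0, jac, f_work, m, gi, e_idx, b1, b2,
    prom, ks, ke, vmax, is_enz, conv, sub, tdir,
    rs, ps, deg_m, mem_diff, par, b_pop, stoich_pow,
):
    d = x.shape[0]
    xp = x.copy()
    for j in range(d):
        delta = 1e-7 * (abs(x[j]) + 1e-7)
        xp[j] = x[j] + delta
        _rhs(xp, f_work, m, gi, e_idx, b1, b2, prom, ks, ke, vmax, is_enz,
             conv, sub, tdir, rs, ps, deg_m, mem_diff, par, b_pop, stoich_pow)
        for a in range(d):
            jac[a, j] = (f_work[a] - f0[a]) / delta
        xp[j] = x[j]


@njit(cache=True)
def integrate_population(
    vol, budget, cint, prot, cext, h0, n_genes,
    prom, ks, ke, vmax, is_enz, conv, sub, tdir,
    rs, ps, deg_m, mem_diff, par, b_pop, stoich_pow,
    e_idx, b1, b2, dt, rtol, atol,
):
    """Advance every cell (and its local pools) by ``dt`` in place.

    Adaptive backward Euler per cell: the local error of an accepted
    substep is estimated from the right-hand-side change over the substep,
    controlled by a weighted-RMS test at (rtol, atol).  Returns 0 on
    success, or 1 + index of the first cell whose integration failed.
    """
    n = vol.shape[0]
    m = cint.shape[1]
    gmax = prot.shape[1]
    dmax = 2 + m + gmax + m
    x = np.empty(dmax)
    y = np.empty(dmax)
    f0 = np.empty(dmax)
    f1 = np.empty(dmax)
    fw = np.empty(dmax)
    mmat_buf = np.empty((dmax, dmax))
    piv_buf = np.empty(dmax, dtype=np.int64)
    res_buf = np.empty(dmax)

    for i in range(n):
        gi = n_genes[i]
        d = 2 + m + gi + m
        xi = x[:d]
        yi = y[:d]
        f0i = f0[:d]
        f1i = f1[:d]
        fwi = fw[:d]
        xi[0] = vol[i]
        xi[1] = budget[i]
        for mm in range(m):
            xi[2 + mm] = cint[i, mm]
            xi[2 + m + gi + mm] = cext[i, mm]
        for j in range(gi):
            xi[2 + m + j] = prot[i, j]

        pr = prom[i, :gi]
        ksj = ks[i, :gi]
        kej = ke[i, :gi]
        vmj = vmax[i, :gi]
        iej = is_enz[i, :gi]
        cvj = conv[i, :gi]
        sbj = sub[i, :gi]
        tdj = tdir[i, :gi]

        jac = np.empty((d, d))
        mmat = mmat_buf[:d, :d]
        piv = piv_buf[:d]
        resb = res_buf[:d]
        t = 0.0
        h = h0[i] * dt
        if h <= 0.0 or h > dt:
            h = 0.25 * dt
        h_mat = -1.0  # step size the Newton matrix was factored for
        failures = 0
        _rhs(xi, f0i, m, gi, e_idx, b1, b2, pr, ksj, kej, vmj, iej, cvj, sbj,
             tdj, rs, ps, deg_m, mem_diff, par, b_pop, stoich_pow)
        _fd_jacobian(xi, f0i, jac, fwi, m, gi, e_idx, b1, b2, pr, ksj, kej,
                     vmj, iej, cvj, sbj, tdj, rs, ps, deg_m, mem_diff, par,
                     b_pop, stoich_pow)
        fresh_jac = True
        while t < dt - 1e-12:
            if h < 1e-10 or h != h:
                return 1 + i
            if h > dt - t:
                h = dt - t
            # refactor only when h drifted away from the factored step
            if h_mat <= 0.0 or abs(h / h_mat - 1.0) > 0.3:
                if not _build_newton_matrix(jac, h, mmat, piv):
                    h *= 0.5
                    h_mat = -1.0
                    failures += 1
                    if failures > 60:
                        return 1 + i
                    continue
                h_mat = h
            ok = _newton_be(xi, h, mmat, piv, resb, fwi, yi, rtol, atol,
                            m, gi, e_idx, b1, b2, pr, ksj, kej, vmj, iej,
                            cvj, sbj, tdj, rs, ps, deg_m, mem_diff, par,
                            b_pop, stoich_pow)
            if not ok:
                if h != h_mat:
                    h_mat = -1.0  # retry with an exactly matching matrix
                elif not fresh_jac:
                    _rhs(xi, f0i, m, gi, e_idx, b1, b2, pr, ksj, kej, vmj,
                         iej, cvj, sbj, tdj, rs, ps, deg_m, mem_diff, par,
                         b_pop, stoich_pow)
                    _fd_jacobian(xi, f0i, jac, fwi, m, gi, e_idx, b1, b2, pr,
                                 ksj, kej, vmj, iej, cvj, sbj, tdj, rs, ps,
                                 deg_m, mem_diff, par, b_pop, stoich_pow)
                    fresh_jac = True
                    h_mat = -1.0
                else:
                    h *= 0.25
                    h_mat = -1.0
                    failures += 1
                    if failures > 60:
                        return 1 + i
                continue
            prod_i = _rhs(yi, f1i, m, gi, e_idx, b1, b2, pr, ksj, kej, vmj,
                          iej, cvj, sbj, tdj, rs, ps, deg_m, mem_diff, par,
                          b_pop, stoich_pow)
            # local error of backward Euler ~ (h^2/2) y'' ~ (h/2)(f1 - f0)
            err = 0.0
            for k in range(d):
                w = atol + rtol * abs(yi[k])
                err += (0.5 * h * (f1i[k] - f0i[k]) / w) ** 2
            err = (err / d) ** 0.5
            if err != err:  # NaN: force a strong rejection
                err = 1e6
            if err <= 1.0:
                t += h
                for k in range(d):
                    xi[k] = yi[k] if yi[k] > 0.0 else 0.0
                    f0i[k] = f1i[k]
                fac = 0.9 * err ** -0.5 if err > 1e-10 else 4.0
                if fac > 4.0:
                    fac = 4.0
                h *= fac
                fresh_jac = False
                failures = 0
            else:
                fac = 0.9 * err ** -0.5
                if fac < 0.1:
                    fac = 0.1
                h *= fac
                failures += 1
                if failures > 60:
                    return 1 + i
                if not fresh_jac:
                    _fd_jacobian(xi, f0i, jac, fwi, m, gi, e_idx, b1, b2, pr,
                                 ksj, kej, vmj, iej, cvj, sbj, tdj, rs, ps,
                                 deg_m, mem_diff, par, b_pop, stoich_pow)
                    fresh_jac = True
                    h_mat = -1.0

        h0[i] = h if h < dt else dt
        vol[i] = xi[0]
        budget[i] = xi[1]
        for mm in range(m):
            cint[i, mm] = xi[2 + mm]
            cext[i, mm] = xi[2 + m + gi + mm]
        for j in range(gi):
            prot[i, j] = xi[2 + m + j]
    return 0


class FastIntegrator:
    """Prepares packed arrays for :func:`integrate_population` from cell objects."""

    def __init__(self, universe, params):
        self.universe = universe
        self.params = params
        self.par = np.array([
            params.g, params.s_shrink, params.vol_max,
            params.expression_cost_scale, params.budget_degradation,
            params.protein_degradation, params.transport_energy_cost,
        ])
        self.rs = universe.reactant_stoich.astype(np.float64)
        self.ps = universe.product_stoich.astype(np.float64)
        self.deg_m = universe.degradation_rates
        self.mem_diff = params.membrane_diffusion_scale * universe.diffusion_rates
        u = universe
        self.e_idx = u.met_index[u.energy]
        bb1, bb2 = u.building_blocks
        self.b1 = u.met_index[bb1]
        self.b2 = u.met_index[bb2]

    def step(self, cells, cext, b_pop, dt=1.0, rtol=1e-4, atol=1e-6, h0=None):
        """Integrate a list of cells against their local pools, in place arrays.

        Returns (vol, budget, cint, prot, cext, production); raises on
        integrator failure.
        """
        n = len(cells)
        m = len(self.universe.metabolites)
        n_genes = np.array([len(c.genome) for c in cells], dtype=np.int64)
        gmax = max(1, int(n_genes.max()) if n else 1)
        vol = np.array([c.state.volume for c in cells])
        budget = np.array([c.state.budget for c in cells])
        cint = np.array([c.state.internal for c in cells])
        prot = np.zeros((n, gmax))
        prom = np.zeros((n, gmax))
        ks = np.ones((n, gmax))
        ke = np.ones((n, gmax))
        vmax = np.zeros((n, gmax))
        is_enz = np.zeros((n, gmax), dtype=np.uint8)
        conv = np.zeros((n, gmax), dtype=np.int64)
        sub = np.zeros((n, gmax), dtype=np.int64)
        tdir = np.zeros((n, gmax))
        for i, c in enumerate(cells):
            prot[i, : n_genes[i]] = c.state.proteins
            for j, gene in enumerate(c.genome):
                prom[i, j] = gene.promoter
                ks[i, j] = gene.k_s
                vmax[i, j] = gene.v_max
                if gene.gtype == ENZYME:
                    is_enz[i, j] = 1
                    conv[i, j] = gene.conversion_index
                else:
                    ke[i, j] = gene.k_e
                    sub[i, j] = self.universe.met_index[gene.substrate]
                    tdir[i, j] = -1.0 if gene.exporting else 1.0
        cext = np.ascontiguousarray(cext, dtype=np.float64)
        if h0 is None:
            h0 = np.full(n, 0.25)
        status = integrate_population(
            vol, budget, cint, prot, cext, h0, n_genes,
            prom, ks, ke, vmax, is_enz, conv, sub, tdir,
            self.rs, self.ps, self.deg_m, self.mem_diff, self.par, b_pop,
            self.params.stoichiometric_rate_law,
            self.e_idx, self.b1, self.b2, float(dt), rtol, atol,
        )
        if status != 0:
            from ._kinetics import CellIntegrationError

            raise CellIntegrationError(
                f"implicit integration failed for cell slot {status - 1}"
            )
        cb1 = cint[:, self.b1]
        cb2 = cint[:, self.b2]
        production = cb1 * cb2 / (1.0 + np.abs(cb1 - cb2))
        return vol, budget, cint, prot, cext, production
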