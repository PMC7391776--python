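"""Packed ODE kernel for cell + local-pool dynamics.

Cells on different sites are mutually decoupled within the cell-update
phase of a time step (each cell exchanges metabolites only with its own
site's external pools), so any number of cells can be integrated in a
single adaptive solver call over a packed, padded state vector.  The
layout per call with N cells, M metabolites and G padded gene slots is::

    y = [ Vol (N) | budget (N) | internal conc (N*M) | protein conc (N*G)
          | external pools (N*M) ]

All rate laws clamp concentrations at zero inside the right-hand side, so
small negative excursions of the integrator decay instead of amplifying.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .chemistry import MetabolicUniverse
from .genome import ENZYME, Genome


class CellIntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-finite state."""


class PackedCells:
    """Padded-array view of a batch of cells plus their local external pools."""

    def __init__(self, universe: MetabolicUniverse, params, genomes: list[Genome]):
        self.universe = universe
        self.params = params
        self.n = n = len(genomes)
        self.m = m = len(universe.metabolites)
        self.g = g = max(1, max((len(gn) for gn in genomes), default=1))
        self.genomes = genomes

        self.promoter = np.zeros((n, g))
        self.ks = np.ones((n, g))
        self.ke = np.ones((n, g))
        self.vmax = np.zeros((n, g))
        self.active = np.zeros((n, g), dtype=bool)
        is_enz = np.zeros((n, g), dtype=bool)
        conv = np.zeros((n, g), dtype=np.int64)
        sub = np.zeros((n, g), dtype=np.int64)
        tdir = np.zeros((n, g))

        for i, gn in enumerate(genomes):
            for j, gene in enumerate(gn):
                self.active[i, j] = True
                self.promoter[i, j] = gene.promoter
                self.ks[i, j] = gene.k_s
                self.vmax[i, j] = gene.v_max
                if gene.gtype == ENZYME:
                    is_enz[i, j] = True
                    conv[i, j] = gene.conversion_index
                else:
                    self.ke[i, j] = gene.k_e
                    sub[i, j] = universe.met_index[gene.substrate]
                    tdir[i, j] = -1.0 if gene.exporting else 1.0

        self.is_enz = is_enz
        self.sub = sub
        self.tdir = tdir
        # per-gene stoichiometry views, shape (n, g, m)
        rs = universe.reactant_stoich[conv].astype(float)
        ps = universe.product_stoich[conv].astype(float)
        rs[~is_enz] = 0.0
        ps[~is_enz] = 0.0
        self.r_stoich = rs
        self.r_mask = rs > 0
        self.net_stoich = ps - rs
        # transporter scatter: signed one-hot over the substrate metabolite
        subhot = np.zeros((n, g, m))
        tr = tdir != 0.0
        subhot[np.nonzero(tr) + (sub[tr],)] = tdir[tr]
        self.tdir_hot = subhot
        self.is_tr = tr

        u, p = universe, params
        self.e_idx = u.met_index[u.energy]
        b1, b2 = u.building_blocks
        self.b1 = u.met_index[b1]
        self.b2 = u.met_index[b2]
        self.deg_m = u.degradation_rates
        self.mem_diff = p.membrane_diffusion_scale * u.diffusion_rates
        self.pr_sum = (self.promoter * self.active).sum(axis=1)

    # -- state packing -------------------------------------------------------

    def pack_state(self, vol, budget, cint, prot, cext) -> np.ndarray:
        n, m, g = self.n, self.m, self.g
        prot_pad = np.zeros((n, g))
        for i, row in enumerate(prot):
            prot_pad[i, : len(row)] = row
        return np.concatenate(
            [np.asarray(vol, float), np.asarray(budget, float),
             np.asarray(cint, float).reshape(-1), prot_pad.reshape(-1),
             np.asarray(cext, float).reshape(-1)]
        )

    def unpack_state(self, y: np.ndarray):
        n, m, g = self.n, self.m, self.g
        vol = y[:n]
        budget = y[n : 2 * n]
        cint = y[2 * n : 2 * n + n * m].reshape(n, m)
        prot = y[2 * n + n * m : 2 * n + n * m + n * g].reshape(n, g)
        cext = y[2 * n + n * m + n * g :].reshape(n, m)
        return vol, budget, cint, prot, cext

    # -- dynamics ------------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, b_pop: float) -> np.ndarray:
        p = self.params
        vol, budget, cint, prot, cext = self.unpack_state(y)
        c = np.maximum(cint, 0.0)
        ce = np.maximum(cext, 0.0)
        pc = np.maximum(prot, 0.0) * self.active
        b = np.maximum(budget, 0.0)
        v = np.maximum(vol, 1e-12)

        denom = b + b_pop
        scal = np.divide(b, denom, out=np.zeros_like(b), where=denom > 0)

        # enzyme kinetics: v = vmax * [enzyme] * prod [R] / prod ([R] + K)
        cn = c[:, None, :]
        if p.stoichiometric_rate_law:
            numer = np.prod(np.where(self.r_mask, cn, 1.0) ** self.r_stoich, axis=-1)
        else:
            numer = np.prod(np.where(self.r_mask, cn, 1.0), axis=-1)
        den = np.prod(np.where(self.r_mask, cn + self.ks[:, :, None], 1.0), axis=-1)
        v_enz = np.where(self.is_enz, self.vmax * pc * numer / den, 0.0)

        # transporter kinetics: substrate is external for import, internal for export
        s_int = np.take_along_axis(c, self.sub, axis=1)
        s_ext = np.take_along_axis(ce, self.sub, axis=1)
        s = np.where(self.tdir > 0, s_ext, s_int)
        c_e = c[:, self.e_idx][:, None]
        v_tr = np.where(
            self.is_tr,
            self.vmax * pc * (s / (s + self.ks)) * (c_e / (c_e + self.ke)),
            0.0,
        )

        # metabolite fluxes: conversions (net stoichiometry) + transport (signed one-hot)
        d_cint = np.einsum("ng,ngm->nm", v_enz, self.net_stoich)
        tr_in = np.einsum("ng,ngm->nm", v_tr, self.tdir_hot)
        d_cint += tr_in
        d_cint[:, self.e_idx] -= p.transport_energy_cost * v_tr.sum(axis=1)
        d_cext = -tr_in * v[:, None]

        # passive membrane diffusion
        mem = self.mem_diff[None, :] * (ce - c)
        d_cint += mem
        d_cext -= mem * v[:, None]

        # biomass production from balanced building blocks
        cb1, cb2 = c[:, self.b1], c[:, self.b2]
        production = cb1 * cb2 / (1.0 + np.abs(cb1 - cb2))
        d_cint[:, self.b1] -= production
        d_cint[:, self.b2] -= production

        # volume growth and (signed) dilution
        vol_growth = p.g * v * (1.0 - v) / p.vol_max * scal
        d_vol = vol_growth - p.s_shrink * v
        rho = d_vol / v

        cost_growth = vol_growth * scal * b
        cost_expr = p.expression_cost_scale * self.pr_sum * scal * b
        d_b = production - cost_growth - cost_expr - p.budget_degradation * b - rho * b

        d_prot = self.promoter * scal[:, None] * self.active - p.protein_degradation * pc
        d_prot -= rho[:, None] * pc

        d_cint -= self.deg_m[None, :] * c + rho[:, None] * c

        out = np.concatenate(
            [d_vol, d_b, d_cint.reshape(-1), d_prot.reshape(-1), d_cext.reshape(-1)]
        )
        return out

    def production(self, cint: np.ndarray) -> np.ndarray:
        """Biomass production rate per cell from internal building-block levels."""
        c = np.maximum(cint, 0.0)
        cb1, cb2 = c[:, self.b1], c[:, self.b2]
        return cb1 * cb2 / (1.0 + np.abs(cb1 - cb2))

    def integrate(
        self,
        y0: np.ndarray,
        b_pop: float,
        dt: float = 1.0,
        method: str = "RK45",
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ) -> np.ndarray:
        sol = solve_ivp(
            self.rhs,
            (0.0, dt),
            y0,
            args=(b_pop,),
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            bad = ""
            if sol.success:
                vol, budget, cint, prot, cext = self.unpack_state(sol.y[:, -1])
                idx = np.nonzero(~np.isfinite(vol) | ~np.isfinite(budget)
                                 | ~np.isfinite(cint).all(1) | ~np.isfinite(prot).all(1))[0]
                bad = f"; non-finite state for cell slots {idx.tolist()}"
            raise CellIntegrationError(f"ODE integration failed: {sol.message}{bad}")
        y1 = sol.y[:, -1].copy()
        return np.maximum(y1, 0.0)  # concentrations, volume and budget clamp at 0
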