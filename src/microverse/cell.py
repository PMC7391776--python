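"""Single-cell state and physiology.

A cell carries a volume, a biomass production budget, internal metabolite
and protein concentrations, an accumulated toxic effect and lineage labels.
Its physiology is a system of ODEs: Michaelis–Menten transport and
catalysis, biomass production from the two building blocks, budget-limited
volume growth and protein expression, passive membrane diffusion, and
first-order degradation plus growth dilution for every molecule.  Death is
a stochastic per-step event whose probability starts at the intrinsic rate
and rises with the accumulated toxic effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._kinetics import CellIntegrationError, PackedCells
from .chemistry import MetabolicUniverse
from .genome import Gene, Genome

__all__ = [
    "CellState",
    "Cell",
    "DynamicsParams",
    "transport_rate",
    "enzyme_rate",
    "production_rate",
    "budget_scaling",
    "toxic_increment",
    "death_probability",
    "cell_odes",
    "integrate_cell",
    "CellIntegrationError",
]


@dataclass
class DynamicsParams:
    """Physiological constants shared by all cells.

    ``g`` volume growth rate; ``s_shrink`` volume decay; ``vol_max`` the
    asymptotic cell size; ``vol_divide`` the minimal size for division;
    ``vol_starve`` the starvation threshold below which a cell is marked
    for death; ``r_death`` the intrinsic per-step death probability;
    ``s_tox`` scales how the accumulated toxic effect saturates the death
    hazard.  ``b_pop_window`` is the horizon (steps) of the exponential
    moving average of population production used for budget scaling.
    """

    g: float = 1.0
    s_shrink: float = 0.01
    vol_max: float = 1.0
    vol_divide: float = 0.5
    vol_starve: float = 0.05
    r_death: float = 0.03
    s_tox: float = 1.0
    expression_cost_scale: float = 1.0
    budget_degradation: float = 0.01
    protein_degradation: float = 0.1
    membrane_diffusion_scale: float = 1.0
    transport_energy_cost: float = 1.0
    b_pop_window: float = 100.0
    stoichiometric_rate_law: bool = False

    def __post_init__(self):
        if not 0 < self.vol_starve < self.vol_divide <= self.vol_max:
            raise ValueError("need 0 < vol_starve < vol_divide <= vol_max")
        for name in ("g", "s_shrink", "r_death", "s_tox", "b_pop_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CellState:
    """Mutable physiological state of one cell."""

    volume: float
    budget: float
    internal: np.ndarray          # per-metabolite internal concentrations
    proteins: np.ndarray          # per-gene protein concentrations
    e_tox: float = 0.0
    lifetime: int = 0
    production: float = 0.0       # last-computed biomass production rate
    marker: int = 0               # renewing neutral lineage marker
    clade: int = 0                # metabolic-genotype clade id

    def copy(self) -> "CellState":
        return replace(self, internal=self.internal.copy(), proteins=self.proteins.copy())


@dataclass
class Cell:
    """A genome plus its physiological state."""

    genome: Genome
    state: CellState

    def copy(self) -> "Cell":
        return Cell(self.genome.copy(), self.state.copy())


# -- closed-form rate laws ----------------------------------------------------


def transport_rate(gene: Gene, s_conc: float, e_conc: float, t_conc: float) -> float:
    """Active transport rate v = v_max [T] ([S]/([S]+K_S)) ([E]/([E]+K_E)).

    ``s_conc`` is the external substrate concentration for importers and
    the internal one for exporters; one unit of the energy carrier is
    consumed per unit of substrate moved.
    """
    s = max(s_conc, 0.0)
    e = max(e_conc, 0.0)
    return gene.v_max * t_conc * (s / (s + gene.k_s)) * (e / (e + gene.k_e))


def enzyme_rate(gene: Gene, reactant_concs, enzyme_conc: float) -> float:
    """Catalysis rate v = v_max [enzyme] · prod[R] / prod([R] + K).

    One shared Michaelis constant per gene is applied to every distinct
    reactant; each reactant concentration enters the product once.
    """
    v = gene.v_max * enzyme_conc
    for c in np.atleast_1d(reactant_concs):
        c = max(float(c), 0.0)
        v *= c / (c + gene.k_s)
    return v


def production_rate(b1_conc: float, b2_conc: float) -> float:
    """Biomass production, maximal when the building blocks are balanced.

    production = [B1][B2] / (1 + |B1 - m| + |B2 - m|) with m the mean of
    the two concentrations; algebraically [B1][B2] / (1 + |B1 - B2|).
    """
    b1 = max(b1_conc, 0.0)
    b2 = max(b2_conc, 0.0)
    return b1 * b2 / (1.0 + abs(b1 - b2))


def budget_scaling(b: float, b_pop: float) -> float:
    """Fraction of the budget a cell may spend: B / (B + B_pop).

    ``b_pop`` is the running (exponential moving) average of population
    production, so selection pressure is maintained as populations get
    more productive.
    """
    if b <= 0 and b_pop <= 0:
        return 0.0
    return b / (b + b_pop)


def toxic_increment(
    internal: np.ndarray, thresholds: np.ndarray, dt: float = 1.0
) -> float:
    """Per-step addition to the cumulative toxic effect.

    Each internal metabolite above its toxicity threshold contributes its
    relative excess ([m] - tox_m)/tox_m, integrated over ``dt``.
    """
    excess = (np.maximum(internal, 0.0) - thresholds) / thresholds
    return float(np.maximum(excess, 0.0).sum() * dt)


def death_probability(e_tox: float, params: DynamicsParams) -> float:
    """Stochastic death probability d = e/(s+e) (1-r) + r, rising from r to 1."""
    r = params.r_death
    return e_tox / (params.s_tox + e_tox) * (1.0 - r) + r


# -- ODE assembly and integration ---------------------------------------------


def _pack_one(cell: Cell, env_concs, universe: MetabolicUniverse, params: DynamicsParams):
    packed = PackedCells(universe, params, [cell.genome])
    y0 = packed.pack_state(
        [cell.state.volume],
        [cell.state.budget],
        cell.state.internal[None, :],
        [cell.state.proteins],
        np.asarray(env_concs, float)[None, :],
    )
    return packed, y0


def cell_odes(
    cell: Cell,
    env_concs,
    params: DynamicsParams,
    universe: MetabolicUniverse,
    b_pop: float,
) -> dict:
    """Time derivatives of all state variables of one cell (plus its local pools).

    Returns a dict with ``volume``, ``budget``, ``internal`` (per
    metabolite), ``proteins`` (per gene) and ``external`` (per metabolite,
    the local pool seen by this cell).  Raises ``CellIntegrationError`` on
    non-finite derivatives.
    """
    packed, y0 = _pack_one(cell, env_concs, universe, params)
    dy = packed.rhs(0.0, y0, b_pop)
    if not np.all(np.isfinite(dy)):
        raise CellIntegrationError(
            f"non-finite derivative for cell (volume={cell.state.volume}, "
            f"budget={cell.state.budget})"
        )
    d_vol, d_b, d_cint, d_prot, d_cext = packed.unpack_state(dy)
    ng = len(cell.genome)
    return {
        "volume": float(d_vol[0]),
        "budget": float(d_b[0]),
        "internal": d_cint[0],
        "proteins": d_prot[0, :ng],
        "external": d_cext[0],
    }


def integrate_cell(
    cell: Cell,
    env_concs,
    params: DynamicsParams,
    universe: MetabolicUniverse,
    b_pop: float,
    dt: float = 1.0,
    method: str = "LSODA",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> tuple[Cell, np.ndarray, np.ndarray]:
    """Advance one cell and its local pools by ``dt`` with an adaptive solver.

    Returns ``(updated cell, updated external pools, net membrane fluxes)``
    where the flux vector is the per-metabolite amount the environment
    lost to the cell over the step (negative entries: net export).
    Concentrations are clamped at zero after the step.
    """
    packed, y0 = _pack_one(cell, env_concs, universe, params)
    y1 = packed.integrate(y0, b_pop, dt=dt, method=method, rtol=rtol, atol=atol)
    vol, budget, cint, prot, cext = packed.unpack_state(y1)
    ng = len(cell.genome)
    new = cell.copy()
    new.state.volume = float(vol[0])
    new.state.budget = float(budget[0])
    new.state.internal = cint[0].copy()
    new.state.proteins = prot[0, :ng].copy()
    new.state.production = float(packed.production(cint)[0])
    fluxes = np.asarray(env_concs, float) - cext[0]
    return new, cext[0].copy(), fluxes
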