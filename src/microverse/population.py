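"""Population scheduler: the per-time-step loop over a whole community.

Each step runs, in order: (1) ODE update of every cell coupled to its local
pools, (2) environmental influx/degradation/diffusion (or global mixing),
(3) toxicity accumulation and stochastic death with lysis, (4) lottery
reproduction into empty sites with genome mutation, (5) horizontal gene
transfer and gene discovery, (6) renewal of neutral lineage markers when a
single marker has fixed, and (7) time-series recording.

Randomness is split into named per-phase streams derived from one master
seed, so disabling one stochastic phase (e.g. mutations in a dependency
assay) does not perturb the draws of the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kinetics import PackedCells
from .analysis import CladeRecord, MetabolicGenotype, metabolic_genotype
from .cell import Cell, CellState, DynamicsParams, death_probability, toxic_increment
from .chemistry import MetabolicUniverse, is_viable_network, load_reference_universe
from .environment import EMPTY, Environment
from .genome import (
    Gene,
    Genome,
    MutationParams,
    discover_gene,
    hgt_copy,
    random_parameters,
    replicate_genome,
    PARAM_MIN,
    PARAM_MAX,
)

_STREAMS = ("init", "death", "lottery", "mutation", "hgt", "misc")


def lottery_pick(productions, b_pop: float, rng: np.random.Generator) -> int | None:
    """Weighted reproduction lottery over competitors plus a no-reproduction entrant.

    Each competitor enters with its production value as weight; a pseudo
    entrant with weight ``b_pop`` (the running population-production
    average) dynamically scales the chance that nobody reproduces.
    Returns the winning competitor's index, or None for no reproduction.
    """
    weights = np.array([max(p, 0.0) for p in productions] + [max(b_pop, 0.0)])
    total = weights.sum()
    if total <= 0:
        return None
    pick = int(rng.choice(len(weights), p=weights / total))
    return None if pick == len(weights) - 1 else pick


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run: universe, parameters, grid, seed.

    ``universe`` is ``"reference"`` or a path to a universe YAML file.
    ``n_initial=None`` fills the whole grid with founder cells.  Initial
    cells carry a bootstrap stock of internal metabolites (by default some
    energy carrier and a little of each building block) so that transport
    and expression can start; the external resource pool starts at its
    influx/degradation steady state unless overridden.
    """

    universe: str = "reference"
    width: int = 45
    height: int = 45
    well_mixed: bool = False
    n_steps: int = 1000
    seed: int = 0
    n_initial: int | None = None
    record_every: int = 1
    snapshot_every: int = 0
    mutation: MutationParams = field(default_factory=MutationParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    # founder-cell initial conditions: a small bootstrap stock, well below
    # the toxicity thresholds (~0.05-0.16) the reference universe imposes
    init_volume: float = 0.3
    init_budget: float = 0.01
    init_internal: dict = field(default_factory=lambda: {"E": 0.05, "B1": 0.02, "B2": 0.02})
    init_protein: float = 0.05
    init_resource_pool: float | None = 0.1  # None: influx/degradation steady state
    b_pop_init: float = 0.0
    # integrator for the per-step cell update: "fast" is the compiled
    # per-cell implicit solver; "RK45"/"BDF"/"LSODA" use scipy on the
    # packed system (slower, for cross-checks)
    integrator: str = "fast"
    rtol: float = 3e-4
    atol: float = 1e-6  # well below any concentration the dynamics care about

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mutation" in d and isinstance(d["mutation"], dict):
            d["mutation"] = MutationParams(**d["mutation"])
        if "dynamics" in d and isinstance(d["dynamics"], dict):
            d["dynamics"] = DynamicsParams(**d["dynamics"])
        return cls(**d)


@dataclass
class RunResult:
    """Artifacts of one run: per-step time series, clade registry, status."""

    time_series: pd.DataFrame
    clades: dict[int, CladeRecord]
    status: str
    n_steps: int
    sim: "Simulation"


class Simulation:
    """A population of digital microbes on a lattice, advanced step by step.

    Owns the cells, the environment, the clade registry, the marker
    bookkeeping and the running population-production average.
    """

    def __init__(
        self,
        config: SimulationConfig,
        universe: MetabolicUniverse | None = None,
        populate: bool = True,
    ):
        self.config = config
        if universe is not None:
            self.universe = universe
        elif config.universe == "reference":
            self.universe = load_reference_universe()
        else:
            self.universe = MetabolicUniverse.load(config.universe)
        self.dynamics = config.dynamics
        self.mutation = dataclasses.replace(config.mutation)

        u = self.universe
        if config.init_resource_pool is None:
            r = u.met_index[u.resource]
            influx, deg = u.influx_rates[r], u.degradation_rates[r]
            r_pool = influx / deg if deg > 0 else 0.0
        else:
            r_pool = config.init_resource_pool
        pools0 = np.zeros(len(u.metabolites))
        pools0[u.met_index[u.resource]] = r_pool
        self.env = Environment(
            u, config.width, config.height, well_mixed=config.well_mixed,
            initial_pools=pools0,
        )

        seqs = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
        self.rng = {name: np.random.default_rng(s) for name, s in zip(_STREAMS, seqs)}

        self.cells: dict[int, Cell] = {}
        self.sites: dict[int, tuple[int, int]] = {}
        self.step_count = 0
        self.b_pop = config.b_pop_init
        self.marker_epoch = 0
        self.renew_markers = True
        self._next_cell = 0
        self._next_marker = 0
        self._next_clade = 0
        self.clades: dict[int, CladeRecord] = {}
        self._genotypes: dict[int, np.ndarray] = {}
        self._rows: list[dict] = []
        self._fast = None
        self._h_memory: dict[int, float] = {}
        self.event_counts = {"death": 0, "birth": 0, "hgt": 0, "discovery": 0,
                             "marker_renewal": 0, "starvation": 0}
        self.status = "running"

        if populate:
            self._build_initial_population(config.n_initial)
            self._record()

    # -- construction ---------------------------------------------------------

    def _random_viable_genome(self, rng: np.random.Generator, max_tries: int = 10_000) -> Genome:
        u = self.universe
        importer_idx = u.transport_index(u.resource, exporting=False)
        n_conv = len(u.conversions)
        for _ in range(max_tries):
            conv_idx = rng.integers(n_conv, size=5)
            if not is_viable_network(set(conv_idx.tolist()) | {importer_idx}, u):
                continue
            genes = [
                Gene(
                    "transporter",
                    substrate=u.resource,
                    exporting=False,
                    k_e=float(rng.uniform(PARAM_MIN, PARAM_MAX)),
                    **random_parameters(rng),
                )
            ] + [
                Gene("enzyme", conversion_index=int(i), **random_parameters(rng))
                for i in conv_idx
            ]
            order = rng.permutation(len(genes))
            return Genome([genes[i] for i in order])
        raise RuntimeError(f"no viable founder genome found in {max_tries} tries")

    def _founder_state(self, genome: Genome, marker: int, clade: int) -> CellState:
        cfg, u = self.config, self.universe
        internal = np.zeros(len(u.metabolites))
        for met, conc in cfg.init_internal.items():
            internal[u.met_index[met]] = conc
        return CellState(
            volume=cfg.init_volume,
            budget=cfg.init_budget,
            internal=internal,
            proteins=np.full(len(genome), cfg.init_protein, dtype=float),
            marker=marker,
            clade=clade,
        )

    def _build_initial_population(self, n: int | None) -> None:
        """Fill the grid with minimally viable founders: one resource importer
        plus 5 random enzymes per genome, resampled until the network can make
        both building blocks and energy from the resource."""
        rng = self.rng["init"]
        n_sites = self.env.n_sites
        n = n_sites if n is None else n
        if n > n_sites:
            raise ValueError(f"{n} founders do not fit on {n_sites} sites")
        order = rng.permutation(n_sites)[:n]
        for flat in order:
            site = (int(flat) // self.env.width, int(flat) % self.env.width)
            genome = self._random_viable_genome(rng)
            self._add_founder(genome, site)

    def _add_founder(self, genome: Genome, site: tuple[int, int],
                     state: CellState | None = None) -> int:
        """Place a new independent cell (unique marker, root clade) on a site."""
        bits = metabolic_genotype(genome, self.universe)
        clade = self._new_clade(parent=None, genotype=bits)
        marker = self._next_marker
        self._next_marker += 1
        if state is None:
            state = self._founder_state(genome, marker, clade)
        else:
            state.marker = marker
            state.clade = clade
        cid = self._place_cell(Cell(genome, state), site)
        return cid

    def _place_cell(self, cell: Cell, site: tuple[int, int]) -> int:
        if self.env.occupant[site] != EMPTY:
            raise ValueError(f"site {site} already occupied")
        cid = self._next_cell
        self._next_cell += 1
        self.cells[cid] = cell
        self.sites[cid] = site
        self.env.occupant[site] = cid
        self._genotypes[cid] = self.clades[cell.state.clade].genotype.as_array()
        return cid

    def _new_clade(self, parent: int | None, genotype: MetabolicGenotype) -> int:
        cid = self._next_clade
        self._next_clade += 1
        self.clades[cid] = CladeRecord(cid, parent, genotype, self.step_count)
        return cid

    # -- bookkeeping ----------------------------------------------------------

    def genotype_key(self, cid: int) -> bytes:
        return self._genotypes[cid].tobytes()

    def remove_cell(self, cid: int, lyse: bool = True) -> None:
        cell = self.cells.pop(cid)
        site = self.sites.pop(cid)
        del self._genotypes[cid]
        self.env.occupant[site] = EMPTY
        if lyse:
            self.env.lyse(cell.state.internal, cell.state.volume, site)

    def gene_frequencies(self) -> np.ndarray:
        """Fraction of living cells whose metabolic genotype carries each reaction."""
        if not self.cells:
            return np.zeros(self.universe.n_reactions)
        return np.mean([self._genotypes[c] for c in self.cells], axis=0)

    def mean_production(self) -> float:
        if not self.cells:
            return 0.0
        return float(np.mean([c.state.production for c in self.cells.values()]))

    def _update_genotype(self, cid: int, parent_clade: int) -> None:
        """After a genome change, open a new clade if the genotype changed."""
        cell = self.cells[cid]
        bits = metabolic_genotype(cell.genome, self.universe)
        old = self.clades[parent_clade].genotype
        if bits.bits != old.bits:
            cell.state.clade = self._new_clade(parent=parent_clade, genotype=bits)
        else:
            cell.state.clade = parent_clade
        self._genotypes[cid] = bits.as_array()

    # -- the seven sub-steps ----------------------------------------------------

    def _integrate_phase(self) -> None:
        if not self.cells:
            return
        ids = list(self.cells)
        cells = [self.cells[i] for i in ids]
        cext = np.array([self.env.site_pools(self.sites[i]) for i in ids])
        cfg = self.config
        if cfg.integrator == "fast":
            if self._fast is None:
                from ._fastsolve import FastIntegrator

                self._fast = FastIntegrator(self.universe, self.dynamics)
            h0 = np.array([self._h_memory.get(i, 0.25) for i in ids])
            vol, budget, cint, prot, cext1, production = self._fast.step(
                cells, cext, self.b_pop, dt=1.0, rtol=cfg.rtol, atol=cfg.atol, h0=h0
            )
            self._h_memory = {i: float(h) for i, h in zip(ids, h0)}
        else:
            packed = PackedCells(self.universe, self.dynamics, [c.genome for c in cells])
            y0 = packed.pack_state(
                [c.state.volume for c in cells],
                [c.state.budget for c in cells],
                np.array([c.state.internal for c in cells]),
                [c.state.proteins for c in cells],
                cext,
            )
            y1 = packed.integrate(
                y0, self.b_pop, dt=1.0, method=cfg.integrator, rtol=cfg.rtol, atol=cfg.atol
            )
            vol, budget, cint, prot, cext1 = packed.unpack_state(y1)
            production = packed.production(cint)
        for k, (i, c) in enumerate(zip(ids, cells)):
            c.state.volume = float(vol[k])
            c.state.budget = float(budget[k])
            c.state.internal = cint[k].copy()
            c.state.proteins = prot[k, : len(c.genome)].copy()
            c.state.production = float(production[k])
            r, col = self.sites[i]
            self.env.pools[:, r, col] = cext1[k]
        # exponential moving average of population production
        w = self.dynamics.b_pop_window
        self.b_pop += (float(production.mean()) - self.b_pop) / w

    def _environment_phase(self) -> None:
        self.env.influx_and_degrade()
        self.env.diffuse()

    def _death_phase(self) -> None:
        if not self.cells:
            return
        ids = list(self.cells)
        draws = self.rng["death"].random(len(ids))
        thresholds = self.universe.toxicity_thresholds
        for cid, draw in zip(ids, draws):
            cell = self.cells[cid]
            st = cell.state
            st.e_tox += toxic_increment(st.internal, thresholds)
            st.lifetime += 1
            starved = st.volume < self.dynamics.vol_starve
            if starved or draw < death_probability(st.e_tox, self.dynamics):
                self.remove_cell(cid, lyse=True)
                self.event_counts["death"] += 1
                if starved:
                    self.event_counts["starvation"] += 1

    def _reproduction_phase(self) -> None:
        rng = self.rng["lottery"]
        empties = self.env.empty_sites()
        if not empties:
            return
        order = rng.permutation(len(empties))
        for k in order:
            site = empties[k]
            if self.env.occupant[site] != EMPTY:  # filled earlier this phase
                continue
            competitors = []
            for nb in self.env.moore_neighbours(site):
                occ = self.env.occupant[nb]
                if occ != EMPTY and self.cells[occ].state.volume >= self.dynamics.vol_divide:
                    competitors.append(occ)
            if not competitors:
                continue
            pick = lottery_pick(
                [self.cells[c].state.production for c in competitors], self.b_pop, rng
            )
            if pick is None:
                continue
            self._divide(competitors[pick], site)

    def _divide(self, parent_id: int, site: tuple[int, int]) -> None:
        parent = self.cells[parent_id]
        parent.state.volume /= 2.0
        child_genome, events, child_prot = replicate_genome(
            parent.genome,
            self.mutation,
            self.universe,
            self.rng["mutation"],
            payload=list(parent.state.proteins),
        )
        st = parent.state
        child_state = CellState(
            volume=st.volume,
            budget=st.budget,
            internal=st.internal.copy(),
            proteins=np.asarray(child_prot, dtype=float),
            e_tox=0.0,
            lifetime=0,
            production=st.production,
            marker=st.marker,
            clade=st.clade,
        )
        cid = self._place_cell(Cell(child_genome, child_state), site)
        self._update_genotype(cid, parent_clade=st.clade)
        self.event_counts["birth"] += 1

    def _hgt_discovery_phase(self) -> None:
        rng = self.rng["hgt"]
        p_hgt, p_disc = self.mutation.p_hgt, self.mutation.p_discovery
        if p_hgt == 0.0 and p_disc == 0.0:
            return
        for cid in list(self.cells):
            cell = self.cells[cid]
            if rng.random() < p_hgt:
                donors = [
                    self.env.occupant[nb]
                    for nb in self.env.moore_neighbours(self.sites[cid])
                    if self.env.occupant[nb] != EMPTY
                ]
                if donors:
                    donor = self.cells[donors[int(rng.integers(len(donors)))]]
                    new_genome, event = hgt_copy(cell.genome, donor.genome, rng)
                    if event.kind == "hgt":
                        _, pos = event.detail
                        cell.genome = new_genome
                        cell.state.proteins = np.insert(cell.state.proteins, pos, 0.0)
                        self._update_genotype(cid, parent_clade=cell.state.clade)
                        self.event_counts["hgt"] += 1
            if rng.random() < p_disc:
                gene = discover_gene(self.universe, rng)
                cell.genome.genes.append(gene)
                cell.state.proteins = np.append(cell.state.proteins, 0.0)
                self._update_genotype(cid, parent_clade=cell.state.clade)
                self.event_counts["discovery"] += 1

    def _marker_phase(self) -> None:
        if not self.renew_markers or not self.cells:
            return
        markers = {c.state.marker for c in self.cells.values()}
        if len(markers) == 1:
            for cell in self.cells.values():
                cell.state.marker = self._next_marker
                self._next_marker += 1
            self.marker_epoch += 1
            self.event_counts["marker_renewal"] += 1

    def _record(self) -> None:
        n = len(self.cells)
        freqs = self.gene_frequencies()
        row = {
            "step": self.step_count,
            "pop_size": n,
            "mean_production": self.mean_production(),
            "mean_genome_len": (
                float(np.mean([len(c.genome) for c in self.cells.values()])) if n else 0.0
            ),
            "marker_count": len({c.state.marker for c in self.cells.values()}),
            "epoch": self.marker_epoch,
            "b_pop": self.b_pop,
        }
        for i, f in enumerate(freqs):
            row[f"freq_{i}"] = float(f)
        self._rows.append(row)
        for cell in self.cells.values():
            rec = self.clades[cell.state.clade]
            rec.abundance[self.step_count] = rec.abundance.get(self.step_count, 0) + 1

    # -- driving -----------------------------------------------------------------

    def step(self) -> None:
        """Advance one time step (all seven sub-phases in order)."""
        self.step_count += 1
        self._integrate_phase()
        self._environment_phase()
        self._death_phase()
        self._reproduction_phase()
        self._hgt_discovery_phase()
        self._marker_phase()
        if self.step_count % self.config.record_every == 0:
            self._record()
        if not self.cells:
            self.status = "extinct"

    def run(self, n_steps: int | None = None, progress: bool = False) -> RunResult:
        """Run for ``n_steps`` (default: config) or until extinction."""
        n_steps = self.config.n_steps if n_steps is None else n_steps
        target = self.step_count + n_steps
        while self.step_count < target and self.cells:
            self.step()
            if progress and self.step_count % 500 == 0:
                print(
                    f"step {self.step_count}: {len(self.cells)} cells, "
                    f"mean production {self.mean_production():.4f}",
                    flush=True,
                )
        self.status = "extinct" if not self.cells else "completed"
        return RunResult(
            time_series=self.time_series(),
            clades=self.clades,
            status=self.status,
            n_steps=self.step_count,
            sim=self,
        )

    def time_series(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows)

    # -- snapshot / copy -----------------------------------------------------------

    def to_snapshot(self) -> dict:
        u = self.universe
        return {
            "schema": 1,
            "config": self.config.to_dict(),
            "universe": u.to_dict(),
            "step": self.step_count,
            "b_pop": self.b_pop,
            "marker_epoch": self.marker_epoch,
            "status": self.status,
            "counters": {
                "cell": self._next_cell,
                "marker": self._next_marker,
                "clade": self._next_clade,
            },
            "mutation": dataclasses.asdict(self.mutation),
            "event_counts": dict(self.event_counts),
            "rng": {name: g.bit_generator.state for name, g in self.rng.items()},
            "h_memory": {str(k): v for k, v in self._h_memory.items()},
            "pools": self.env.pools.tolist(),
            "cells": [
                {
                    "id": cid,
                    "site": list(self.sites[cid]),
                    "genome": cell.genome.to_list(u),
                    "state": {
                        "volume": cell.state.volume,
                        "budget": cell.state.budget,
                        "internal": cell.state.internal.tolist(),
                        "proteins": cell.state.proteins.tolist(),
                        "e_tox": cell.state.e_tox,
                        "lifetime": cell.state.lifetime,
                        "production": cell.state.production,
                        "marker": cell.state.marker,
                        "clade": cell.state.clade,
                    },
                }
                for cid, cell in self.cells.items()
            ],
            "clades": [
                {
                    "id": c.clade_id,
                    "parent": c.parent,
                    "bits": [int(b) for b in c.genotype.bits],
                    "origin": c.origin_step,
                    "abundance": {str(k): v for k, v in c.abundance.items()},
                }
                for c in self.clades.values()
            ],
        }

    @classmethod
    def from_snapshot(cls, snap: dict) -> "Simulation":
        config = SimulationConfig.from_dict(snap["config"])
        universe = MetabolicUniverse.from_dict(snap["universe"])
        sim = cls(config, universe=universe, populate=False)
        sim.step_count = snap["step"]
        sim.b_pop = snap["b_pop"]
        sim.marker_epoch = snap["marker_epoch"]
        sim.status = snap.get("status", "running")
        sim._next_cell = snap["counters"]["cell"]
        sim._next_marker = snap["counters"]["marker"]
        sim._next_clade = snap["counters"]["clade"]
        sim.mutation = MutationParams(**snap["mutation"])
        sim.event_counts.update(snap.get("event_counts", {}))
        for name, state in snap["rng"].items():
            sim.rng[name].bit_generator.state = state
        sim._h_memory = {int(k): v for k, v in snap.get("h_memory", {}).items()}
        sim.env.pools = np.asarray(snap["pools"], dtype=float)
        for c in snap["clades"]:
            rec = CladeRecord(
                c["id"],
                c["parent"],
                MetabolicGenotype(tuple(bool(b) for b in c["bits"])),
                c["origin"],
                {int(k): v for k, v in c["abundance"].items()},
            )
            sim.clades[rec.clade_id] = rec
        for entry in snap["cells"]:
            st = entry["state"]
            cell = Cell(
                Genome.from_list(entry["genome"], universe),
                CellState(
                    volume=st["volume"],
                    budget=st["budget"],
                    internal=np.asarray(st["internal"], dtype=float),
                    proteins=np.asarray(st["proteins"], dtype=float),
                    e_tox=st["e_tox"],
                    lifetime=st["lifetime"],
                    production=st["production"],
                    marker=st["marker"],
                    clade=st["clade"],
                ),
            )
            cid = entry["id"]
            site = tuple(entry["site"])
            sim.cells[cid] = cell
            sim.sites[cid] = site
            sim.env.occupant[site] = cid
            sim._genotypes[cid] = sim.clades[cell.state.clade].genotype.as_array()
        return sim

    def copy(self) -> "Simulation":
        return Simulation.from_snapshot(self.to_snapshot())

    def reseed(self, seed: int) -> "Simulation":
        """Re-derive all per-phase random streams from a new master seed.

        Lets one constructed community be propagated as independent
        stochastic replicates.
        """
        seqs = np.random.SeedSequence(seed).spawn(len(_STREAMS))
        self.rng = {name: np.random.default_rng(s) for name, s in zip(_STREAMS, seqs)}
        return self


def build_initial_population(
    universe: MetabolicUniverse | None = None,
    seed: int = 0,
    n: int | None = None,
    config: SimulationConfig | None = None,
) -> Simulation:
    """Construct the founder population: minimally viable genomes, one per site.

    Every founder genome holds one importer for the resource plus 5 random
    enzymes (random parameters, random gene order) and is resampled until
    it passes the viability closure check.  With the default 45x45 grid and
    ``n=None`` this yields 2025 founder cells, each with a unique lineage
    marker.
    """
    config = config or SimulationConfig(seed=seed)
    config.seed = seed
    config.n_initial = n
    return Simulation(config, universe=universe)
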