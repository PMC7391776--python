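"""Configuration files, run manifests, snapshots and engineered fixtures.

The config file is YAML with the same nesting as ``SimulationConfig``;
unknown keys are rejected so typos fail loudly.  Run outputs are plain-text
artifacts (TSV time series, GGMuller-style tables, Newick clade phylogeny,
JSON snapshot) plus a manifest written last as the atomicity marker.

The engineered fixtures build small, hand-parameterised communities whose
qualitative behaviour is known by construction (an obligately cross-feeding
pair; a self-sufficient major lineage with an obligately dependent minor
partner), used to validate the dependency assay.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .analysis import build_muller_table, metabolic_genotype
from .cell import Cell
from .chemistry import MetabolicUniverse
from .genome import Gene, Genome
from .population import RunResult, Simulation, SimulationConfig

SCHEMA_VERSION = 1


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML config; unknown keys and bad values are fatal.

    All schema violations are collected and reported together.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = []
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key in sorted(set(raw) - known):
        errors.append(f"unknown config key: {key!r}")
    try:
        config = SimulationConfig.from_dict({k: v for k, v in raw.items() if k in known})
    except (ValueError, TypeError) as exc:
        errors.append(str(exc))
        config = None
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return config


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def save_snapshot(sim: Simulation, path) -> None:
    with open(path, "w") as fh:
        json.dump(sim.to_snapshot(), fh)


def load_snapshot(path) -> Simulation:
    with open(path) as fh:
        return Simulation.from_snapshot(json.load(fh))


# -- run artifacts ---------------------------------------------------------------


@dataclass
class RunManifest:
    """Inventory of a finished run; written last so its presence marks completeness."""

    config_hash: str
    schema_version: int
    seed: int
    start_step: int
    end_step: int
    status: str
    files: dict[str, int] = field(default_factory=dict)  # name -> size in bytes

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def clades_to_newick(clades: dict) -> str:
    """Newick export of the clade phylogeny; labels are clade ids, branch
    lengths the origin-step difference to the parent."""
    children: dict = {}
    roots = []
    for c in clades.values():
        if c.parent is None:
            roots.append(c.clade_id)
        else:
            children.setdefault(c.parent, []).append(c.clade_id)

    def render(cid: int, parent_origin: int) -> str:
        c = clades[cid]
        kids = children.get(cid, [])
        label = f"c{cid}:{c.origin_step - parent_origin}"
        if not kids:
            return label
        inner = ",".join(render(k, c.origin_step) for k in sorted(kids))
        return f"({inner}){label}"

    if len(roots) == 1:
        return render(roots[0], 0) + ";"
    return "(" + ",".join(render(r, 0) for r in sorted(roots)) + ")root:0;"


def write_outputs(result: RunResult, out_dir, muller_subsample: int = 500) -> RunManifest:
    """Write the TSV/Newick/snapshot artifacts of a run; manifest written last."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = result.sim
    files = {}

    def record(name: str):
        files[name] = (out / name).stat().st_size

    result.time_series.to_csv(out / "timeseries.tsv", sep="\t", index=False)
    record("timeseries.tsv")

    edges, pops = build_muller_table(list(result.clades.values()), subsample=muller_subsample)
    edges.to_csv(out / "muller_edges.tsv", sep="\t", index=False)
    pops.to_csv(out / "muller_populations.tsv", sep="\t", index=False)
    record("muller_edges.tsv")
    record("muller_populations.tsv")

    (out / "clades.nwk").write_text(clades_to_newick(result.clades))
    record("clades.nwk")

    sim.env.grid_table().to_csv(out / "grid.tsv", sep="\t", index=False)
    record("grid.tsv")

    save_snapshot(sim, out / "snapshot.json")
    record("snapshot.json")

    manifest = RunManifest(
        config_hash=config_hash(sim.config),
        schema_version=SCHEMA_VERSION,
        seed=sim.config.seed,
        start_step=0,
        end_step=result.n_steps,
        status=result.status,
        files=files,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
    return manifest


# -- engineered fixtures -----------------------------------------------------------


@dataclass
class Fixture:
    """A named, deterministic test community."""

    name: str
    description: str
    sim: Simulation
    markers: dict[str, int]  # strain name -> lineage marker


def _gene(kind: str, universe: MetabolicUniverse, *, promoter, k_s, v_max,
          conversion=None, substrate=None, k_e=None, exporting=False) -> Gene:
    if kind == "enzyme":
        idx = next(
            r.index for r in universe.conversions if str(r) == conversion
        )
        return Gene("enzyme", promoter, k_s, v_max, conversion_index=idx)
    return Gene("transporter", promoter, k_s, v_max, substrate=substrate,
                k_e=k_e, exporting=exporting)


def _seed_community(
    universe: MetabolicUniverse,
    strains: dict[str, Genome],
    layout,
    width: int,
    height: int,
    init_internal: dict,
    dynamics_overrides: dict | None = None,
) -> Fixture:
    cfg = SimulationConfig(
        width=width, height=height, n_steps=0, seed=0,
        init_internal=init_internal,
    )
    if dynamics_overrides:
        cfg.dynamics = dataclasses.replace(cfg.dynamics, **dynamics_overrides)
    from .genome import MutationParams

    cfg.mutation = MutationParams.zero()
    sim = Simulation(cfg, universe=universe, populate=False)
    sim.renew_markers = False  # strain markers are the fixture's identity
    markers: dict[str, int] = {}
    clade_of: dict[str, int] = {}
    for name, genome in strains.items():
        markers[name] = sim._next_marker
        sim._next_marker += 1
        clade_of[name] = sim._new_clade(None, metabolic_genotype(genome, universe))
    for (r, c), name in layout.items():
        genome = strains[name].copy()
        state = sim._founder_state(genome, markers[name], clade_of[name])
        sim._place_cell(Cell(genome, state), (r, c))
    sim._record()
    return sim, markers


def make_fixture_crossfeeders(
    universe: MetabolicUniverse, width: int = 12, height: int = 12
) -> Fixture:
    """Deterministic obligate cross-feeding pair on a checkerboard.

    Strain A imports the resource, converts it to building block B1 (plus
    energy), exports B1 and imports B2; strain B is the mirror image.
    Neither strain can synthesise the partner's building block, so each is
    obligately dependent on the other.
    """
    def strain(own: str, other: str) -> Genome:
        conv = f"R -> {own} + E"
        return Genome([
            _gene("transporter", universe, promoter=3.0, k_s=1.0, v_max=4.0,
                  substrate="R", k_e=0.2, exporting=False),
            _gene("enzyme", universe, promoter=3.0, k_s=0.5, v_max=4.0, conversion=conv),
            _gene("transporter", universe, promoter=2.0, k_s=0.2, v_max=2.0,
                  substrate=other, k_e=0.2, exporting=False),
            _gene("transporter", universe, promoter=1.0, k_s=1.5, v_max=2.0,
                  substrate=own, k_e=0.2, exporting=True),
        ])

    strains = {"A": strain("B1", "B2"), "B": strain("B2", "B1")}
    layout = {
        (r, c): ("A" if (r + c) % 2 == 0 else "B")
        for r in range(height)
        for c in range(width)
    }
    sim, markers = _seed_community(
        universe, strains, layout, width, height,
        init_internal={"E": 0.04, "B1": 0.02, "B2": 0.02},
    )
    return Fixture(
        name="crossfeeders",
        description="obligate pair: A makes/exports B1 and imports B2; B mirrored",
        sim=sim,
        markers=markers,
    )


def make_fixture_major_minor(
    universe: MetabolicUniverse, width: int = 12, height: int = 12
) -> Fixture:
    """A cross-feeding community with a self-sufficient major lineage.

    The major lineage synthesises both building blocks (weakly for B2) and
    imports B2; the minor lineage specialises in B2, exports it and imports
    B1 scavenged from major-lineage lysis.  Removing the major lineage
    kills the minor; removing the minor leaves a surviving major that grows
    more slowly in isolation — the engineered analogue of the evolved
    major/minor cross-feeders.
    """
    major = Genome([
        _gene("transporter", universe, promoter=3.0, k_s=1.0, v_max=4.0,
              substrate="R", k_e=0.2, exporting=False),
        _gene("enzyme", universe, promoter=3.0, k_s=0.5, v_max=4.0, conversion="R -> B1 + E"),
        _gene("enzyme", universe, promoter=1.0, k_s=0.5, v_max=0.6, conversion="R -> B2 + E"),
        _gene("transporter", universe, promoter=2.0, k_s=0.2, v_max=2.5,
              substrate="B2", k_e=0.2, exporting=False),
    ])
    minor = Genome([
        _gene("transporter", universe, promoter=3.0, k_s=1.0, v_max=4.0,
              substrate="R", k_e=0.2, exporting=False),
        _gene("enzyme", universe, promoter=3.0, k_s=0.5, v_max=4.0, conversion="R -> B2 + E"),
        _gene("transporter", universe, promoter=2.0, k_s=0.2, v_max=2.0,
              substrate="B1", k_e=0.2, exporting=False),
        _gene("transporter", universe, promoter=1.0, k_s=1.5, v_max=2.0,
              substrate="B2", k_e=0.2, exporting=True),
    ])
    layout = {}
    for r in range(height):
        for c in range(width):
            layout[(r, c)] = "minor" if (r + c) % 3 == 0 else "major"
    sim, markers = _seed_community(
        universe,
        {"major": major, "minor": minor},
        layout,
        width,
        height,
        init_internal={"E": 0.04, "B1": 0.02, "B2": 0.02},
    )
    return Fixture(
        name="major_minor",
        description="major lineage survives alone but grows slower; minor is obligate",
        sim=sim,
        markers=markers,
    )


FIXTURES = {
    "crossfeeders": make_fixture_crossfeeders,
    "major_minor": make_fixture_major_minor,
}
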