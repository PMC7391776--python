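"""Artificial chemistry: metabolites, reactions and the metabolic universe.

A *metabolic universe* is the closed set of metabolites and reactions that
evolution can draw genes from.  The reference universe has 9 metabolites
(one resource R, two essential building blocks B1/B2, one energy carrier E
and five intermediates M1..M5) connected by 59 reactions: 43 conversion
reactions plus an importer and an exporter for every non-energy metabolite.
The canonical reaction ordering (conversions in listing order, then
importers, then exporters) defines the positions of the 59-bit metabolic
genotype used throughout the analysis code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

RESOURCE = "resource"
BUILDING_BLOCK = "building_block"
ENERGY = "energy"
INTERMEDIATE = "intermediate"

#: energy-substrate classes used for network-topology analysis
RESOURCE_ENERGY = "resource_energy"
BB_ENERGY = "bb_energy"
NO_ENERGY = "none"


@dataclass(frozen=True)
class Metabolite:
    """A chemical species with its environmental rate parameters.

    Rates are per-time-step fractions.  ``toxicity_threshold`` is the
    internal concentration above which the metabolite contributes to the
    cumulative toxic effect; ``influx_rate`` is the external supply per
    grid site per step (non-zero only for the resource in the reference
    universe).  ``mass`` is carried for completeness but not consumed by
    the dynamics.
    """

    id: str
    mclass: str
    diffusion_rate: float
    degradation_rate: float
    toxicity_threshold: float
    influx_rate: float = 0.0
    mass: float = 1.0


@dataclass(frozen=True)
class ConversionReaction:
    """An enzymatic conversion ``reactants -> products`` with integer stoichiometry."""

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    index: int = -1

    @property
    def reactant_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.reactants)

    @property
    def product_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.products)

    def __str__(self) -> str:
        return f"{format_side(self.reactants)} -> {format_side(self.products)}"


@dataclass(frozen=True)
class TransportReaction:
    """Active transport of one substrate across the membrane (never the energy carrier)."""

    substrate: str
    direction_role: str  # "importer" | "exporter"
    index: int = -1

    def __str__(self) -> str:
        arrow = "in" if self.direction_role == "importer" else "out"
        return f"{self.substrate} [{arrow}]"


def format_side(side: tuple[tuple[str, int], ...]) -> str:
    return " + ".join(f"{n} {m}" if n > 1 else m for m, n in side)


def parse_reaction(text: str) -> tuple[tuple[tuple[str, int], ...], tuple[tuple[str, int], ...]]:
    """Parse ``"A + 2 B -> C + 3 E"`` into (reactants, products) tuples."""
    text = text.replace("→", "->")
    try:
        lhs, rhs = text.split("->")
    except ValueError as exc:
        raise ValueError(f"reaction string needs one '->': {text!r}") from exc

    def side(s: str) -> tuple[tuple[str, int], ...]:
        out = []
        for term in s.split("+"):
            term = term.strip()
            m = re.fullmatch(r"(?:(\d+)\s+)?([A-Za-z]\w*)", term)
            if m is None:
                raise ValueError(f"cannot parse reaction term {term!r} in {text!r}")
            out.append((m.group(2), int(m.group(1) or 1)))
        return tuple(out)

    return side(lhs), side(rhs)


class MetabolicUniverse:
    """The closed reaction set evolution can sample genes from.

    Exposes a stable canonical ordering over all reactions (conversions
    first, then importers, then exporters) plus precomputed stoichiometry
    arrays used by the ODE kernels.
    """

    def __init__(
        self,
        metabolites: list[Metabolite],
        conversions: list[ConversionReaction],
        transports: list[TransportReaction],
        name: str = "custom",
    ):
        self.name = name
        self.metabolites = list(metabolites)
        self.met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        if len(self.met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")

        # re-index reactions into the canonical ordering
        self.conversions = [
            ConversionReaction(r.reactants, r.products, index=i)
            for i, r in enumerate(conversions)
        ]
        self.transports = [
            TransportReaction(t.substrate, t.direction_role, index=len(self.conversions) + j)
            for j, t in enumerate(transports)
        ]
        self._validate()

        n_met = len(self.metabolites)
        n_conv = len(self.conversions)
        #: stoichiometry arrays, shape (n_conversions, n_metabolites)
        self.reactant_stoich = np.zeros((n_conv, n_met), dtype=np.int64)
        self.product_stoich = np.zeros((n_conv, n_met), dtype=np.int64)
        for r in self.conversions:
            for m, n in r.reactants:
                self.reactant_stoich[r.index, self.met_index[m]] = n
            for m, n in r.products:
                self.product_stoich[r.index, self.met_index[m]] = n
        self.diffusion_rates = np.array([m.diffusion_rate for m in self.metabolites])
        self.degradation_rates = np.array([m.degradation_rate for m in self.metabolites])
        self.toxicity_thresholds = np.array([m.toxicity_threshold for m in self.metabolites])
        self.influx_rates = np.array([m.influx_rate for m in self.metabolites])

    # -- structural queries -------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.conversions) + len(self.transports)

    @property
    def resource(self) -> str:
        return next(m.id for m in self.metabolites if m.mclass == RESOURCE)

    @property
    def energy(self) -> str:
        return next(m.id for m in self.metabolites if m.mclass == ENERGY)

    @property
    def building_blocks(self) -> tuple[str, str]:
        bbs = tuple(m.id for m in self.metabolites if m.mclass == BUILDING_BLOCK)
        return bbs  # exactly two by invariant

    def reaction(self, index: int):
        """Reaction at canonical position ``index`` (0..n_reactions-1)."""
        n_conv = len(self.conversions)
        if 0 <= index < n_conv:
            return self.conversions[index]
        if n_conv <= index < self.n_reactions:
            return self.transports[index - n_conv]
        raise IndexError(f"reaction index {index} out of range 0..{self.n_reactions - 1}")

    def transport_index(self, substrate: str, exporting: bool) -> int:
        role = "exporter" if exporting else "importer"
        for t in self.transports:
            if t.substrate == substrate and t.direction_role == role:
                return t.index
        raise KeyError(f"no {role} for {substrate!r}")

    def _validate(self) -> None:
        classes = [m.mclass for m in self.metabolites]
        if classes.count(RESOURCE) != 1 or classes.count(ENERGY) != 1:
            raise ValueError("universe needs exactly one resource and one energy metabolite")
        if classes.count(BUILDING_BLOCK) != 2:
            raise ValueError("universe needs exactly two building blocks")
        energy = next(m.id for m in self.metabolites if m.mclass == ENERGY)
        for r in self.conversions:
            if set(r.reactant_ids) & set(r.product_ids):
                raise ValueError(f"reactants and products overlap in {r}")
            if len(r.reactants) > 2:
                raise ValueError(f"more than 2 distinct reactants in {r}")
            for m in r.reactant_ids + r.product_ids:
                if m not in self.met_index:
                    raise ValueError(f"unknown metabolite {m!r} in {r}")
        for t in self.transports:
            if t.substrate == energy:
                raise ValueError("the energy carrier cannot be transported")
            if t.substrate not in self.met_index:
                raise ValueError(f"unknown transport substrate {t.substrate!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metabolites": [
                {
                    "id": m.id,
                    "mclass": m.mclass,
                    "diffusion": m.diffusion_rate,
                    "degradation": m.degradation_rate,
                    "toxicity": m.toxicity_threshold,
                    "mass": m.mass,
                    "influx": m.influx_rate,
                }
                for m in self.metabolites
            ],
            "conversions": [str(r) for r in self.conversions],
            "transports": {
                "importers": [t.substrate for t in self.transports if t.direction_role == "importer"],
                "exporters": [t.substrate for t in self.transports if t.direction_role == "exporter"],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicUniverse":
        required = {"metabolites", "conversions", "transports"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"universe definition missing entries: {sorted(missing)}")
        mets = []
        for m in d["metabolites"]:
            try:
                mets.append(
                    Metabolite(
                        id=m["id"],
                        mclass=m["mclass"],
                        diffusion_rate=float(m["diffusion"]),
                        degradation_rate=float(m["degradation"]),
                        toxicity_threshold=float(m["toxicity"]),
                        influx_rate=float(m.get("influx", 0.0)),
                        mass=float(m.get("mass", 1.0)),
                    )
                )
            except KeyError as exc:
                raise ValueError(f"metabolite entry {m!r} missing field {exc}") from exc
        convs = []
        for s in d["conversions"]:
            reactants, products = parse_reaction(s)
            convs.append(ConversionReaction(reactants, products))
        transports = [
            TransportReaction(sub, "importer") for sub in d["transports"]["importers"]
        ] + [TransportReaction(sub, "exporter") for sub in d["transports"]["exporters"]]
        return cls(mets, convs, transports, name=d.get("name", "custom"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "MetabolicUniverse":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def __repr__(self) -> str:
        return (
            f"<MetabolicUniverse {self.name!r}: {len(self.metabolites)} metabolites, "
            f"{len(self.conversions)} conversions, {len(self.transports)} transports>"
        )


def load_reference_universe() -> MetabolicUniverse:
    """Load the packaged reference universe (9 metabolites, 59 reactions).

    Raises ``ValueError`` naming the missing entries if the packaged fixture
    is corrupt or incomplete.
    """
    text = resources.files("microverse.data").joinpath("reference_universe.yaml").read_text()
    uni = MetabolicUniverse.from_dict(yaml.safe_load(text))
    if len(uni.conversions) != 43 or len(uni.transports) != 16 or len(uni.metabolites) != 9:
        raise ValueError(
            "reference universe fixture incomplete: expected 9 metabolites, 43 conversions, "
            f"16 transports; got {len(uni.metabolites)}/{len(uni.conversions)}/{len(uni.transports)}"
        )
    return uni


def energy_substrate_class(rxn: ConversionReaction, universe: MetabolicUniverse) -> str:
    """Classify a conversion by which substrate it degrades for energy.

    ``resource_energy`` if it produces the energy carrier from the resource,
    ``bb_energy`` if it produces energy from a building block, ``none``
    otherwise.  Energy-topology of a network (which class its energy
    reactions fall in) predicts community strategy: resource-degrading
    networks cross-feed, building-block-degrading networks stay autonomous.
    """
    if universe.energy not in rxn.product_ids:
        return NO_ENERGY
    if universe.resource in rxn.reactant_ids:
        return RESOURCE_ENERGY
    if any(bb in rxn.reactant_ids for bb in universe.building_blocks):
        return BB_ENERGY
    return NO_ENERGY


def reachable_metabolites(
    start: set[str], conversions: list[ConversionReaction]
) -> set[str]:
    """Fixed-point closure: a reaction fires once all its reactants are present."""
    have = set(start)
    changed = True
    while changed:
        changed = False
        for r in conversions:
            if set(r.reactant_ids) <= have and not set(r.product_ids) <= have:
                have |= set(r.product_ids)
                changed = True
    return have


def is_viable_network(reaction_indices, universe: MetabolicUniverse) -> bool:
    """Whether a reaction set can make both building blocks and energy from the resource.

    True iff the set contains an importer for the resource and the closure
    of its conversion reactions over {resource} produces both building
    blocks and the energy carrier.
    """
    indices = set(int(i) for i in reaction_indices)
    n_conv = len(universe.conversions)
    has_r_importer = any(
        universe.transports[i - n_conv].substrate == universe.resource
        and universe.transports[i - n_conv].direction_role == "importer"
        for i in indices
        if i >= n_conv
    )
    if not has_r_importer:
        return False
    convs = [universe.conversions[i] for i in indices if i < n_conv]
    have = reachable_metabolites({universe.resource}, convs)
    b1, b2 = universe.building_blocks
    return b1 in have and b2 in have and universe.energy in have


def generate_universe(
    seed: int,
    n_intermediates: int = 5,
    n_conversions: int = 43,
    max_tries: int = 200,
) -> MetabolicUniverse:
    """Procedurally generate a random universe with the reference structure.

    The universe always contains one resource R, two building blocks B1/B2
    and one energy carrier E plus ``n_intermediates`` intermediates, with an
    importer and exporter per non-energy metabolite.  Conversions are drawn
    as either catabolic (one reactant -> one product + k energy) or
    synthetic (one or two reactants -> one product), the energy carrier is
    never a reactant, and generation retries until both building blocks and
    energy are reachable from the resource.

    Deterministic in ``seed``; raises ``RuntimeError`` (reporting the seed)
    if no reachable universe is found within ``max_tries``.
    """
    if n_intermediates < 1:
        raise ValueError("need at least one intermediate metabolite")
    if n_conversions < 4:
        raise ValueError("need at least 4 conversions for a reachable universe")
    rng = np.random.default_rng(seed)
    inter_ids = [f"M{i + 1}" for i in range(n_intermediates)]

    def draw_metabolite(mid: str, mclass: str, influx: float) -> Metabolite:
        return Metabolite(
            id=mid,
            mclass=mclass,
            diffusion_rate=float(rng.uniform(0.01, 0.05)),
            degradation_rate=float(10 ** rng.uniform(-3.5, -1.5)),
            toxicity_threshold=float(rng.uniform(0.04, 0.16)),
            influx_rate=influx,
        )

    for attempt in range(max_tries):
        mets = (
            [draw_metabolite("R", RESOURCE, influx=0.002)]
            + [draw_metabolite(b, BUILDING_BLOCK, 0.0) for b in ("B1", "B2")]
            + [draw_metabolite("E", ENERGY, 0.0)]
            + [draw_metabolite(m, INTERMEDIATE, 0.0) for m in inter_ids]
        )
        substrates = ["R", "B1", "B2"] + inter_ids  # everything but E
        seen: set[tuple] = set()
        convs: list[ConversionReaction] = []
        while len(convs) < n_conversions:
            if rng.random() < 0.5:  # catabolic: X -> Y + k E
                x, y = rng.choice(substrates, size=2, replace=False)
                rxn = ConversionReaction(
                    ((str(x), 1),), ((str(y), 1), ("E", int(rng.integers(1, 6))))
                )
            else:  # synthetic: up to 2 reactants -> product
                if rng.random() < 0.25:
                    x = str(rng.choice(substrates))
                    reactants = ((x, 2),)
                    pool = [s for s in substrates if s != x]
                else:
                    x, y = rng.choice(substrates, size=2, replace=False)
                    reactants = ((str(x), 1), (str(y), 1))
                    pool = [s for s in substrates if s not in (x, y)]
                rxn = ConversionReaction(reactants, ((str(rng.choice(pool)), 1),))
            key = (rxn.reactants, rxn.products)
            if key in seen:
                continue
            seen.add(key)
            convs.append(rxn)
        have = reachable_metabolites({"R"}, convs)
        if {"B1", "B2", "E"} <= have:
            transports = [TransportReaction(s, "importer") for s in substrates] + [
                TransportReaction(s, "exporter") for s in substrates
            ]
            return MetabolicUniverse(mets, convs, transports, name=f"generated-{seed}")
    raise RuntimeError(
        f"could not generate a reachable universe in {max_tries} tries (seed={seed}, "
        f"n_intermediates={n_intermediates}, n_conversions={n_conversions})"
    )
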