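"""Evolvable genomes: gene records, kinetic parameters and mutation operators.

A genome is a linear list of genes, each coding for a metabolic enzyme (one
conversion reaction) or a transporter (one substrate, importing or
exporting).  On replication, stretches of genes can be duplicated, deleted,
inverted or translocated, and each gene can suffer a point mutation that
modifies a single evolvable parameter.  Genes can also arrive by discovery
(a randomly parameterised reaction drawn from the universe) or by
horizontal transfer from a neighbouring cell; both are per-cell per-step
events handled by the population scheduler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chemistry import MetabolicUniverse, parse_reaction

#: all evolvable kinetic parameters live in this closed range
PARAM_MIN = 0.01
PARAM_MAX = 8.0

ENZYME = "enzyme"
TRANSPORTER = "transporter"


@dataclass
class Gene:
    """One gene: an enzyme referencing a conversion, or a transporter referencing a substrate.

    ``promoter`` (Pr) sets the expression rate, ``k_s`` the Michaelis
    constant for the substrate(s), ``k_e`` (transporters only) the Michaelis
    constant for the energy carrier that powers transport, ``v_max`` the
    maximal turnover.  All four are evolvable within [0.01, 8]; transporter
    direction (``exporting``) is an evolvable boolean.
    """

    gtype: str
    promoter: float
    k_s: float
    v_max: float
    conversion_index: int | None = None  # enzymes
    substrate: str | None = None         # transporters
    k_e: float | None = None             # transporters
    exporting: bool | None = None        # transporters

    def __post_init__(self):
        if self.gtype == ENZYME:
            if self.conversion_index is None:
                raise ValueError("enzyme gene needs a conversion_index")
        elif self.gtype == TRANSPORTER:
            if self.substrate is None or self.k_e is None or self.exporting is None:
                raise ValueError("transporter gene needs substrate, k_e and exporting")
        else:
            raise ValueError(f"unknown gene type {self.gtype!r}")

    def copy(self) -> "Gene":
        return replace(self)

    def reaction_index(self, universe: MetabolicUniverse) -> int:
        """Canonical index of the reaction this gene encodes."""
        if self.gtype == ENZYME:
            return self.conversion_index
        return universe.transport_index(self.substrate, self.exporting)

    def evolvable_parameters(self) -> list[str]:
        if self.gtype == ENZYME:
            return ["promoter", "k_s", "v_max"]
        return ["promoter", "k_s", "k_e", "v_max", "exporting"]

    def to_dict(self, universe: MetabolicUniverse) -> dict:
        d = {"type": self.gtype, "promoter": self.promoter, "k_s": self.k_s, "v_max": self.v_max}
        if self.gtype == ENZYME:
            d["reaction"] = str(universe.conversions[self.conversion_index])
        else:
            d.update(substrate=self.substrate, k_e=self.k_e, exporting=self.exporting)
        return d

    @classmethod
    def from_dict(cls, d: dict, universe: MetabolicUniverse) -> "Gene":
        if d["type"] == ENZYME:
            reactants, products = parse_reaction(d["reaction"])
            idx = next(
                r.index
                for r in universe.conversions
                if r.reactants == reactants and r.products == products
            )
            return cls(ENZYME, d["promoter"], d["k_s"], d["v_max"], conversion_index=idx)
        return cls(
            TRANSPORTER,
            d["promoter"],
            d["k_s"],
            d["v_max"],
            substrate=d["substrate"],
            k_e=d["k_e"],
            exporting=bool(d["exporting"]),
        )


@dataclass
class Genome:
    """Ordered list of genes; may be empty (such a cell starves rather than crashes)."""

    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def copy(self) -> "Genome":
        return Genome([g.copy() for g in self.genes])

    def to_list(self, universe: MetabolicUniverse) -> list[dict]:
        return [g.to_dict(universe) for g in self.genes]

    @classmethod
    def from_list(cls, records: list[dict], universe: MetabolicUniverse) -> "Genome":
        return cls([Gene.from_dict(d, universe) for d in records])


@dataclass
class MutationParams:
    """Mutation probabilities: stretch operators per replication, point per gene
    per replication, discovery and HGT per cell per time step."""

    p_dup: float = 0.001
    p_del: float = 0.001
    p_inv: float = 0.001
    p_transloc: float = 0.001
    p_point: float = 0.02
    stretch_p: float = 0.3
    p_discovery: float = 0.0001
    p_hgt: float = 0.0005

    def __post_init__(self):
        for name in ("p_dup", "p_del", "p_inv", "p_transloc", "p_point",
                     "stretch_p", "p_discovery", "p_hgt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def zero(cls) -> "MutationParams":
        """All rates zero — used for ecology-only runs and dependency assays."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.3, 0.0, 0.0)


@dataclass(frozen=True)
class MutationEvent:
    """Record of one mutation, sufficient for clade (genotype-change) tracking."""

    kind: str  # duplication|deletion|inversion|translocation|point|discovery|hgt|hgt_noop
    detail: tuple = ()


def sample_stretch_length(rng: np.random.Generator, stretch_p: float = 0.3) -> int:
    """Geometric stretch length on support {1, 2, ...} with mean 1/stretch_p."""
    if not 0.0 < stretch_p <= 1.0:
        raise ValueError("stretch_p must be in (0, 1]")
    return int(rng.geometric(stretch_p))


def _reflect(x: float, lo: float = PARAM_MIN, hi: float = PARAM_MAX) -> float:
    while x < lo or x > hi:
        if x > hi:
            x = 2 * hi - x
        else:
            x = 2 * lo - x
    return x


def _point_mutate(gene: Gene, rng: np.random.Generator) -> tuple[Gene, str]:
    g = gene.copy()
    param = str(rng.choice(g.evolvable_parameters()))
    if param == "exporting":
        g.exporting = not g.exporting
    else:
        factor = 2.0 ** rng.uniform(-1.0, 1.0)
        setattr(g, param, _reflect(getattr(g, param) * factor))
    return g, param


def point_mutate_parameter(gene: Gene, rng: np.random.Generator) -> Gene:
    """Mutate one uniformly chosen evolvable parameter of a gene copy.

    Numeric parameters are multiplied by a log-uniform factor in [1/2, 2]
    and reflected back into [0.01, 8]; the transporter direction flips.
    """
    return _point_mutate(gene, rng)[0]


def random_parameters(rng: np.random.Generator) -> dict:
    return {
        "promoter": float(rng.uniform(PARAM_MIN, PARAM_MAX)),
        "k_s": float(rng.uniform(PARAM_MIN, PARAM_MAX)),
        "v_max": float(rng.uniform(PARAM_MIN, PARAM_MAX)),
    }


def discover_gene(universe: MetabolicUniverse, rng: np.random.Generator) -> Gene:
    """Draw a uniformly random reaction from the universe with random parameters.

    Models innovation as horizontal transfer from an off-grid source.
    """
    idx = int(rng.integers(universe.n_reactions))
    params = random_parameters(rng)
    rxn = universe.reaction(idx)
    if idx < len(universe.conversions):
        return Gene(ENZYME, conversion_index=idx, **params)
    return Gene(
        TRANSPORTER,
        substrate=rxn.substrate,
        k_e=float(rng.uniform(PARAM_MIN, PARAM_MAX)),
        exporting=rxn.direction_role == "exporter",
        **params,
    )


def hgt_copy(
    recipient: Genome, donor: Genome, rng: np.random.Generator
) -> tuple[Genome, MutationEvent]:
    """Copy one uniformly chosen donor gene into a uniformly chosen position.

    An empty donor is a no-op, signalled by an ``hgt_noop`` event.
    """
    child = recipient.copy()
    if len(donor) == 0:
        return child, MutationEvent("hgt_noop")
    src = int(rng.integers(len(donor)))
    pos = int(rng.integers(len(child) + 1))
    child.genes.insert(pos, donor.genes[src].copy())
    return child, MutationEvent("hgt", (src, pos))


def _stretch(rng: np.random.Generator, n: int, stretch_p: float) -> tuple[int, int]:
    """Uniform start, geometric length truncated at the genome end."""
    start = int(rng.integers(n))
    length = min(sample_stretch_length(rng, stretch_p), n - start)
    return start, length


def replicate_genome(
    parent: Genome,
    params: MutationParams,
    universe: MetabolicUniverse,
    rng: np.random.Generator,
    payload: list | None = None,
) -> tuple[Genome, list[MutationEvent]] | tuple[Genome, list[MutationEvent], list]:
    """Copy a genome through one replication, applying mutation operators.

    Stretch operators (duplication, deletion, inversion, translocation) are
    tried in that fixed order, each with its own Bernoulli draw; point
    mutations are then applied independently per gene.  Returns the child
    genome and the list of mutation events.

    ``payload`` is an optional per-gene list (e.g. protein concentrations)
    that is carried through the structural operators in lockstep with the
    genes; when given, the rearranged payload is returned as a third value.
    """
    genes = [g.copy() for g in parent.genes]
    track = payload is not None
    pay = list(payload) if track else [None] * len(genes)
    if track and len(pay) != len(genes):
        raise ValueError("payload length must match genome length")
    events: list[MutationEvent] = []

    if genes and rng.random() < params.p_dup:
        start, length = _stretch(rng, len(genes), params.stretch_p)
        genes[start:start] = [g.copy() for g in genes[start:start + length]]
        pay[start:start] = pay[start:start + length]
        events.append(MutationEvent("duplication", (start, length)))
    if genes and rng.random() < params.p_del:
        start, length = _stretch(rng, len(genes), params.stretch_p)
        del genes[start:start + length]
        del pay[start:start + length]
        events.append(MutationEvent("deletion", (start, length)))
    if genes and rng.random() < params.p_inv:
        start, length = _stretch(rng, len(genes), params.stretch_p)
        genes[start:start + length] = genes[start:start + length][::-1]
        pay[start:start + length] = pay[start:start + length][::-1]
        events.append(MutationEvent("inversion", (start, length)))
    if genes and rng.random() < params.p_transloc:
        start, length = _stretch(rng, len(genes), params.stretch_p)
        chunk, pchunk = genes[start:start + length], pay[start:start + length]
        del genes[start:start + length]
        del pay[start:start + length]
        dest = int(rng.integers(len(genes) + 1))
        genes[dest:dest] = chunk
        pay[dest:dest] = pchunk
        events.append(MutationEvent("translocation", (start, length, dest)))

    for i in range(len(genes)):
        if rng.random() < params.p_point:
            genes[i], changed = _point_mutate(genes[i], rng)
            events.append(MutationEvent("point", (i, changed)))

    if track:
        return Genome(genes), events, pay
    return Genome(genes), events
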