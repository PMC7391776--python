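"""Analysis of simulated communities.

Covers the bookkeeping and assays used to interpret runs: 59-bit metabolic
genotypes and their clade phylogeny (for Muller plots), classification of
network energy topology (which substrate the energy-yielding reactions
degrade), lineage-removal dependency tests, community production rates,
and gene-frequency / proteome matrices with PCA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import (
    BB_ENERGY,
    NO_ENERGY,
    RESOURCE_ENERGY,
    MetabolicUniverse,
    energy_substrate_class,
)
from .genome import Genome

HYBRID = "hybrid"


@dataclass(frozen=True)
class MetabolicGenotype:
    """Presence/absence of each reaction of the universe in a genome.

    Invariant under gene copy number, promoter strength and kinetic
    parameters; the unit of clade tracking.
    """

    bits: tuple[bool, ...]

    @property
    def key(self) -> tuple[bool, ...]:
        return self.bits

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=bool)

    def __len__(self) -> int:
        return len(self.bits)


def metabolic_genotype(genome: Genome, universe: MetabolicUniverse) -> MetabolicGenotype:
    """Map a genome to its presence/absence reaction bit vector.

    Importer and exporter of the same substrate set distinct bits (the
    transporter gene's direction selects which transport reaction it
    realises).
    """
    bits = np.zeros(universe.n_reactions, dtype=bool)
    for gene in genome:
        bits[gene.reaction_index(universe)] = True
    return MetabolicGenotype(tuple(bits.tolist()))


@dataclass
class CladeRecord:
    """A clade of related microbes sharing one metabolic genotype.

    Created whenever a mutation changes a cell's metabolic genotype; the
    parent clade is the one the mutant arose from.  ``abundance`` maps
    recorded step -> number of living cells.
    """

    clade_id: int
    parent: int | None
    genotype: MetabolicGenotype
    origin_step: int
    abundance: dict[int, int] = field(default_factory=dict)


def build_muller_table(
    clades: list[CladeRecord],
    subsample: int = 500,
    cutoff_frac: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condense clade abundances into GGMuller-style edge and population tables.

    Abundances are sampled every ``subsample`` steps; clades whose maximum
    sampled abundance stays below ``cutoff_frac`` times the maximum
    population size are folded into their nearest surviving ancestor, so
    the total per sampled step is conserved.  Returns ``(edges,
    populations)`` with columns (Parent, Identity) and (Generation,
    Identity, Population).
    """
    by_id = {c.clade_id: c for c in clades}
    steps = sorted({s for c in clades for s in c.abundance})
    sampled = [s for s in steps if s % subsample == 0]
    if not sampled:
        sampled = steps[:1]
    pop_size = {s: sum(c.abundance.get(s, 0) for c in clades) for s in sampled}
    max_pop = max(pop_size.values()) if pop_size else 0
    cutoff = cutoff_frac * max_pop

    def max_abund(c: CladeRecord) -> int:
        return max((c.abundance.get(s, 0) for s in sampled), default=0)

    kept = {cid for cid, c in by_id.items() if max_abund(c) >= cutoff}
    if not kept and by_id:  # degenerate: keep the most abundant clade
        kept = {max(by_id, key=lambda cid: max_abund(by_id[cid]))}

    def surviving_ancestor(cid: int) -> int | None:
        p = by_id[cid].parent
        while p is not None and p not in kept:
            p = by_id[p].parent
        return p

    # fold pruned clades into their nearest surviving ancestor; pruned
    # root lines fall back to the earliest surviving clade
    fallback = min(kept, key=lambda cid: by_id[cid].origin_step) if kept else None
    target: dict[int, int] = {}
    for cid in by_id:
        if cid in kept:
            target[cid] = cid
        else:
            anc = surviving_ancestor(cid)
            target[cid] = anc if anc is not None else fallback

    abund: dict[tuple[int, int], int] = {}
    for cid, c in by_id.items():
        t = target[cid]
        if t is None:
            continue
        for s in sampled:
            n = c.abundance.get(s, 0)
            if n:
                abund[(s, t)] = abund.get((s, t), 0) + n

    edges = pd.DataFrame(
        [
            {"Parent": surviving_ancestor(cid), "Identity": cid}
            for cid in sorted(kept)
            if surviving_ancestor(cid) is not None
        ],
        columns=["Parent", "Identity"],
    )
    populations = pd.DataFrame(
        [
            {"Generation": s, "Identity": cid, "Population": abund.get((s, cid), 0)}
            for s in sampled
            for cid in sorted(kept)
        ],
        columns=["Generation", "Identity", "Population"],
    )
    return edges, populations


def classify_topology(
    genotype_or_freqs,
    universe: MetabolicUniverse,
    freq_threshold: float = 0.05,
) -> str:
    """Classify a network (or community) by the substrate of its energy reactions.

    ``resource_energy`` networks degrade the resource for energy (the
    cross-feeding-associated topology), ``bb_energy`` networks degrade a
    building block (autonomy-associated), ``hybrid`` networks do both,
    ``none`` networks have no energy-yielding conversion.  A community
    gene-frequency vector counts a reaction as present at frequency >=
    ``freq_threshold``.
    """
    if isinstance(genotype_or_freqs, MetabolicGenotype):
        present = genotype_or_freqs.as_array()
    else:
        present = np.asarray(genotype_or_freqs, dtype=float) >= freq_threshold
    classes = {
        energy_substrate_class(rxn, universe)
        for rxn in universe.conversions
        if present[rxn.index]
    }
    has_r = RESOURCE_ENERGY in classes
    has_bb = BB_ENERGY in classes
    if has_r and has_bb:
        return HYBRID
    if has_r:
        return RESOURCE_ENERGY
    if has_bb:
        return BB_ENERGY
    return NO_ENERGY


def community_production_rate(state) -> float:
    """Sum of the biomass production rates of all living cells.

    Accepts a population-state-like object (anything with a ``cells``
    mapping) or an iterable of cells.
    """
    cells = state.cells.values() if hasattr(state, "cells") else state
    return float(sum(c.state.production for c in cells))


@dataclass
class DependencyOutcome:
    """Result of one lineage-removal dependency assay."""

    removed_marker: int
    survived: bool
    survivor_genotypes: Counter
    production_before: float            # whole community, step before removal
    production_before_remaining: float  # remaining lineage(s) only, before removal
    production_after: float             # community at measure_at steps after removal
    steps_run: int


def dependency_test(
    sim,
    lineage_marker: int,
    max_steps: int = 2000,
    measure_at: int = 1500,
) -> DependencyOutcome:
    """Remove one marker lineage and assay whether the rest survives alone.

    All cells of the lineage are removed without lysis (their internal
    metabolites vanish with them), all mutation/HGT/discovery rates are set
    to zero, and the simulation continues for up to ``max_steps`` or until
    extinction.  Community production is recorded just before removal and
    ``measure_at`` steps after.  The input simulation is not modified.
    """
    from .genome import MutationParams

    test = sim.copy()
    markers = {c.state.marker for c in test.cells.values()}
    if lineage_marker not in markers:
        raise ValueError(f"marker {lineage_marker} not present (alive: {sorted(markers)})")

    production_before = community_production_rate(test)
    production_before_remaining = float(
        sum(c.state.production for c in test.cells.values() if c.state.marker != lineage_marker)
    )
    removed = [cid for cid, c in test.cells.items() if c.state.marker == lineage_marker]
    for cid in removed:
        test.remove_cell(cid, lyse=False)
    test.mutation = MutationParams.zero()
    test.renew_markers = False  # keep the assayed lineage identity stable

    production_after = 0.0
    steps = 0
    for step in range(1, max_steps + 1):
        if not test.cells:
            break
        test.step()
        steps = step
        if step == measure_at:
            production_after = community_production_rate(test)
    survived = len(test.cells) > 0
    if survived and steps < measure_at:
        production_after = community_production_rate(test)
    genotypes = Counter(test.genotype_key(cid) for cid in test.cells)
    return DependencyOutcome(
        removed_marker=lineage_marker,
        survived=survived,
        survivor_genotypes=genotypes,
        production_before=production_before,
        production_before_remaining=production_before_remaining,
        production_after=production_after,
        steps_run=steps,
    )


def gene_frequency_matrix(results) -> pd.DataFrame:
    """Stack per-step gene frequencies of one or more runs into a (run, step) x 59 matrix.

    Accepts run results (objects with a ``time_series`` DataFrame carrying
    ``freq_*`` columns) or such DataFrames directly.
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    rows = []
    for run_idx, res in enumerate(results):
        ts = res.time_series if hasattr(res, "time_series") else res
        freq_cols = [c for c in ts.columns if c.startswith("freq_")]
        block = ts[["step"] + freq_cols].copy()
        block.insert(0, "run", run_idx)
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    return out.set_index(["run", "step"])


def proteome_matrix(state, universe: MetabolicUniverse) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell relative protein investment across the universe's reactions.

    Protein concentrations of gene copies encoding the same reaction are
    pooled into one column; each row is normalised to the cell's total
    protein, so rows sum to 1.  Cells with zero total protein keep a zero
    row and are flagged in the returned boolean mask.
    """
    cells = state.cells if hasattr(state, "cells") else state
    ids = list(cells)
    mat = np.zeros((len(ids), universe.n_reactions))
    for i, cid in enumerate(ids):
        cell = cells[cid]
        for j, gene in enumerate(cell.genome):
            mat[i, gene.reaction_index(universe)] += max(cell.state.proteins[j], 0.0)
    totals = mat.sum(axis=1)
    zero = totals == 0
    mat[~zero] /= totals[~zero, None]
    cols = [f"rxn_{i}" for i in range(universe.n_reactions)]
    return pd.DataFrame(mat, index=ids, columns=cols), zero


def pca_scores(matrix, n_components: int = 2):
    """Centered PCA via SVD with a deterministic sign convention.

    Returns ``(scores, loadings, explained_variance)``; the loading with
    the largest magnitude in each component is made positive.  A constant
    matrix yields zero variance without error.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, len(s))
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u[:, :k] * s[:k]
    loadings = vt[:k]
    explained = s**2 / max(x.shape[0] - 1, 1)
    return scores, loadings, explained[:k]
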