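"""The spatial environment: a toroidal lattice of external metabolite pools.

Each site holds one external concentration per metabolite and at most one
cell.  Per step the environment receives resource influx, loses metabolites
to first-order degradation, and spreads them by a 4-neighbour discrete
Laplacian (toroidal wrap).  In well-mixed mode the diffusion step instead
replaces every site's pools by the global per-metabolite mean, which keeps
grand totals unchanged while destroying all spatial structure.
"""

from __future__ import annotations

import warnings

import numpy as np

from .chemistry import MetabolicUniverse

EMPTY = -1


class Environment:
    """External metabolite pools plus occupancy on a (height x width) torus."""

    def __init__(
        self,
        universe: MetabolicUniverse,
        width: int = 45,
        height: int = 45,
        well_mixed: bool = False,
        initial_pools: np.ndarray | None = None,
    ):
        self.universe = universe
        self.width = int(width)
        self.height = int(height)
        self.well_mixed = bool(well_mixed)
        m = len(universe.metabolites)
        self.pools = np.zeros((m, self.height, self.width))
        if initial_pools is not None:
            self.pools[:] = np.asarray(initial_pools, float).reshape(m, 1, 1)
        #: occupant cell id per site, EMPTY (-1) where vacant
        self.occupant = np.full((self.height, self.width), EMPTY, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    def totals(self) -> np.ndarray:
        """Grand total amount of each metabolite over the grid (site volume 1)."""
        return self.pools.sum(axis=(1, 2))

    # -- per-step physics ------------------------------------------------------

    def influx_and_degrade(self, dt: float = 1.0) -> None:
        """Constant influx at every site, then first-order degradation, clamped at 0."""
        u = self.universe
        self.pools += u.influx_rates[:, None, None] * dt
        self.pools -= u.degradation_rates[:, None, None] * self.pools * dt
        np.maximum(self.pools, 0.0, out=self.pools)

    def diffuse(self, dt: float = 1.0) -> None:
        """Spread pools between neighbouring sites (or mix globally).

        Structured mode applies a von Neumann 4-neighbour discrete
        Laplacian per metabolite at its diffusion rate, with toroidal
        wrap; the stencil conserves per-metabolite totals exactly.
        """
        if self.well_mixed:
            self.pools[:] = self.pools.mean(axis=(1, 2))[:, None, None]
            return
        rates = self.universe.diffusion_rates
        if np.any(rates * dt > 0.25):
            warnings.warn(
                "diffusion_rate*dt > 0.25: 4-neighbour explicit stencil may be unstable",
                stacklevel=2,
            )
        p = self.pools
        lap = (
            np.roll(p, 1, axis=1)
            + np.roll(p, -1, axis=1)
            + np.roll(p, 1, axis=2)
            + np.roll(p, -1, axis=2)
            - 4.0 * p
        )
        self.pools = p + rates[:, None, None] * dt * lap

    def lyse(self, internal: np.ndarray, volume: float, site: tuple[int, int],
             volume_to_site: float = 1.0) -> None:
        """Release a dead cell's internal metabolites into its site's pools.

        Internal concentrations are converted to pool units via the cell
        volume and a fixed volume-to-site factor (site volume 1).
        """
        r, c = site
        self.pools[:, r, c] += np.maximum(internal, 0.0) * volume * volume_to_site

    # -- topology ---------------------------------------------------------------

    def moore_neighbours(self, site: tuple[int, int]) -> list[tuple[int, int]]:
        """The 8 toroidally wrapped neighbours of a site."""
        r, c = site
        return [
            ((r + dr) % self.height, (c + dc) % self.width)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        ]

    def empty_sites(self) -> list[tuple[int, int]]:
        rs, cs = np.nonzero(self.occupant == EMPTY)
        return list(zip(rs.tolist(), cs.tolist()))

    def site_pools(self, site: tuple[int, int]) -> np.ndarray:
        r, c = site
        return self.pools[:, r, c]

    def grid_table(self):
        """Long-format table of the grid: one row per site with 0-based
        coordinates, the occupant cell id (-1 if empty) and one
        concentration column per metabolite."""
        import pandas as pd

        rows, cols = np.meshgrid(
            np.arange(self.height), np.arange(self.width), indexing="ij"
        )
        data = {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "occupant": self.occupant.ravel(),
        }
        for i, m in enumerate(self.universe.metabolites):
            data[m.id] = self.pools[i].ravel()
        return pd.DataFrame(data)
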