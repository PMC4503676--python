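"""Domain containers for colony maps, bait occupancy matrices and site records.

The three observational units of the study design are represented here:

* :class:`ColonyMap` — a mapped point pattern of ant colonies inside a
  rectangular plot, with species identity, functional group (generalist
  forager vs. *Messor* seed specialist), coordinates in meters and worker
  counts at up to four sampling periods;
* :class:`OccupancyMatrix` — a binary species × bait presence–absence
  matrix for one site-year, with an optional bait → plot mapping;
* :class:`SiteRecord` — one site's environmental covariates (mean annual
  precipitation, yearly rainfall, temperature, herbaceous plant biomass).

Result records returned by the statistical stages live here too, so that
every module shares one vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

GENERALIST = "generalist"
SEED_SPECIALIST = "seed_specialist"
FUNCTIONAL_GROUPS = (GENERALIST, SEED_SPECIALIST)


@dataclass(frozen=True)
class Colony:
    """A single colony record: one nest entrance (after merging) in a plot."""

    species: str
    functional_group: str
    x: float
    y: float
    forager_counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(
                f"functional_group must be one of {FUNCTIONAL_GROUPS}, "
                f"got {self.functional_group!r}"
            )
        if len(self.forager_counts) > 4:
            raise ValueError("at most four sampling periods are recorded per colony")
        if any(c < 0 for c in self.forager_counts):
            raise ValueError("forager counts must be non-negative")


def forager_number(colony: Colony) -> int:
    """Forager number of a colony: the maximum worker count over the
    (up to four) sampling periods.

    Raises ``ValueError`` if no period was recorded.
    """
    if not colony.forager_counts:
        raise ValueError(
            f"colony of {colony.species!r} at ({colony.x}, {colony.y}) "
            "has no recorded forager counts"
        )
    return max(colony.forager_counts)


@dataclass
class ColonyMap:
    """Point pattern of colonies in a rectangular plot of ``plot_width`` ×
    ``plot_height`` meters, for one plot and year."""

    plot_id: str
    plot_width: float
    plot_height: float
    year: int
    colonies: list[Colony] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.plot_width <= 0 or self.plot_height <= 0:
            raise ValueError("plot dimensions must be positive")
        for c in self.colonies:
            if not (0.0 <= c.x <= self.plot_width) or not (0.0 <= c.y <= self.plot_height):
                raise ValueError(
                    f"colony of {c.species!r} at ({c.x}, {c.y}) lies outside "
                    f"the {self.plot_width} x {self.plot_height} m plot"
                )

    def __len__(self) -> int:
        return len(self.colonies)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of colony coordinates in meters."""
        return np.array([[c.x, c.y] for c in self.colonies], dtype=float).reshape(-1, 2)

    @property
    def area(self) -> float:
        return self.plot_width * self.plot_height


class OccupancyMatrix:
    """Binary species × bait presence–absence matrix.

    Rows are species, columns are baits.  ``bait_plot`` maps every bait
    label to the plot it was placed in (all baits of a site-year pooled
    into one matrix, the plots kept recoverable through the mapping).

    Parameters
    ----------
    species : sequence of str
        Row labels, unique.
    baits : sequence of str
        Column labels, unique.
    values : array-like of {0, 1}
        Presence–absence matrix, shape ``(len(species), len(baits))``.
    bait_plot : mapping, optional
        Bait label -> plot id.  Defaults to a single plot ``"plot1"``.
    """

    def __init__(
        self,
        species: Sequence[str],
        baits: Sequence[str],
        values,
        bait_plot: Mapping[str, str] | None = None,
    ) -> None:
        self.species = list(species)
        self.baits = list(baits)
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        if len(set(self.baits)) != len(self.baits):
            raise ValueError("duplicate bait labels")
        arr = np.asarray(values)
        if arr.shape != (len(self.species), len(self.baits)):
            raise ValueError(
                f"values shape {arr.shape} does not match "
                f"{len(self.species)} species x {len(self.baits)} baits"
            )
        if not np.isin(arr, (0, 1)).all():
            bad = arr[~np.isin(arr, (0, 1))]
            raise ValueError(f"matrix cells must be 0 or 1; found {bad.ravel()[:5]}")
        self.values = arr.astype(np.int8)
        if bait_plot is None:
            bait_plot = {b: "plot1" for b in self.baits}
        missing = [b for b in self.baits if b not in bait_plot]
        if missing:
            raise ValueError(f"bait_plot mapping is missing baits {missing}")
        self.bait_plot = {b: bait_plot[b] for b in self.baits}

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_baits(self) -> int:
        return len(self.baits)

    def row_totals(self) -> np.ndarray:
        """Per-species bait occupancy counts r_i."""
        return self.values.sum(axis=1)

    def pair_shared(self) -> np.ndarray:
        """S, the (n_species, n_species) matrix of jointly occupied bait
        counts S_ij."""
        v = self.values.astype(np.int64)
        return v @ v.T

    def subset_species(self, keep: Sequence[str]) -> "OccupancyMatrix":
        idx = [self.species.index(s) for s in keep]
        return OccupancyMatrix(
            [self.species[i] for i in idx], self.baits, self.values[idx], self.bait_plot
        )

    def species_plots(self, sp: str) -> set[str]:
        """Plots in which species ``sp`` occupies at least one bait."""
        row = self.values[self.species.index(sp)]
        return {self.bait_plot[b] for b, v in zip(self.baits, row) if v}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OccupancyMatrix):
            return NotImplemented
        return (
            self.species == other.species
            and self.baits == other.baits
            and np.array_equal(self.values, other.values)
            and self.bait_plot == other.bait_plot
        )

    def __repr__(self) -> str:
        return f"OccupancyMatrix({self.n_species} species x {self.n_baits} baits)"


@dataclass(frozen=True)
class SiteRecord:
    """Environmental covariates of one study site.

    ``precip_mean`` is the 30-year mean annual precipitation in mm — the
    productivity surrogate used as covariate in every regression.
    ``biomass_mean`` is peak-season dry herbaceous biomass in g m^-2 yr^-1.
    """

    site_name: str
    precip_mean: float
    precip_by_year: Mapping[int, float]
    temp_mean: float
    biomass_mean: float

    def __post_init__(self) -> None:
        if self.precip_mean <= 0:
            raise ValueError("precip_mean must be positive")
        if self.biomass_mean < 0:
            raise ValueError("biomass_mean must be non-negative")
        if any(v < 0 for v in self.precip_by_year.values()):
            raise ValueError("yearly rainfall must be non-negative")


# ---------------------------------------------------------------------------
# result records


@dataclass(frozen=True)
class NullModelResult:
    """Outcome of a randomization test of the C-score.

    ``ses`` is the Standardized Effect Size (observed − null mean) / null
    sd; values outside ±1.96 flag non-random co-occurrence (positive:
    segregation, negative: aggregation).  ``degenerate`` is set when the
    null distribution has zero spread and the SES is undefined.
    """

    stat_obs: float
    null_mean: float
    null_sd: float
    ses: float
    p_upper: float
    p_lower: float
    n_rand: int
    n_species: int = 0
    n_baits: int = 0
    degenerate: bool = False


@dataclass(frozen=True)
class DispersionResult:
    """Clark–Evans style Monte-Carlo test of colony dispersion in a plot."""

    nnd_obs: float
    nnd_sim_mean: float
    nnd_sim_sd: float
    z: float
    n_points: int
    n_rand: int
    plot_id: str = ""

    @property
    def classification(self) -> str:
        """segregated (Z > 1.96), aggregated (Z < −1.96), else random."""
        if self.z > 1.96:
            return "segregated"
        if self.z < -1.96:
            return "aggregated"
        return "random"


@dataclass(frozen=True)
class RegressionResult:
    """Simple least-squares regression of a (possibly log10) response on
    the precipitation covariate."""

    slope: float
    intercept: float
    r2: float
    f_stat: float
    df: tuple[int, int]
    p: float
    n: int
    log10_response: bool = False

    def equation(self) -> str:
        resp = "log y" if self.log10_response else "y"
        sign = "+" if self.slope >= 0 else "−"
        return f"{resp} = {self.intercept:.2f} {sign} {abs(self.slope):.3f}x"


@dataclass(frozen=True)
class AncovaResult:
    """Slope-heterogeneity (homogeneity-of-slopes) ANCOVA between exactly
    two functional groups."""

    slope_by_group: Mapping[str, tuple[float, float]]  # group -> (slope, se)
    interaction_f: float
    interaction_df: tuple[int, int]
    interaction_p: float
    n: int
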