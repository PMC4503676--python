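"""Synthetic-data generators with the statistical structure the analysis
stages assume.

Three generators mirror the three kinds of field data:

* :func:`simulate_point_pattern` — colony point patterns in a rectangular
  plot under complete spatial randomness (CSR), a hard-core inhibition
  process (over-dispersed, as mature seed-harvester colonies are) or a
  parent–offspring cluster process (aggregated);
* :func:`simulate_occupancy` — species × bait presence–absence matrices
  with tunable pairwise segregation via a latent Gaussian copula;
* :func:`simulate_gradient` — site-level linear responses to the
  precipitation covariate with Gaussian noise, optionally with distinct
  slopes per functional group for ANCOVA power/recovery experiments.

Every generator takes its RNG seed from the spec object and touches no
global state, so identical specs give identical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm

from .data import Colony, ColonyMap, GENERALIST, OccupancyMatrix


@dataclass(frozen=True)
class PointProcessSpec:
    """Specification of a planar point process in a W × H m rectangle.

    kind:
        ``csr`` — independent uniform points; ``hardcore`` — simple
        sequential inhibition rejecting candidates within ``min_dist`` of
        accepted points; ``cluster`` — ``n_parents`` uniform parents with
        isotropic Gaussian offspring (sd ``cluster_sd``) truncated to the
        rectangle.
    """

    kind: str
    n_points: int
    plot_width: float
    plot_height: float
    min_dist: float = 0.0
    n_parents: int = 3
    cluster_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("csr", "hardcore", "cluster"):
            raise ValueError(f"unknown point process kind {self.kind!r}")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")
        if self.plot_width <= 0 or self.plot_height <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.min_dist < 0:
            raise ValueError("min_dist must be non-negative")
        if self.kind == "hardcore":
            packing = self.n_points * np.pi * (self.min_dist / 2) ** 2
            if packing > 0.5 * self.plot_width * self.plot_height:
                raise ValueError(
                    "hardcore spec infeasible: disc packing fraction "
                    f"{packing / (self.plot_width * self.plot_height):.2f} too high"
                )
        if self.kind == "cluster" and (self.n_parents < 1 or self.cluster_sd <= 0):
            raise ValueError("cluster process needs n_parents >= 1 and cluster_sd > 0")


def simulate_point_pattern(
    spec: PointProcessSpec,
    species: str = "SIM",
    functional_group: str = GENERALIST,
    plot_id: str = "sim",
    year: int = 0,
) -> ColonyMap:
    """Draw one realization of ``spec`` as a :class:`ColonyMap`."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "csr":
        pts = _csr(rng, spec.n_points, spec.plot_width, spec.plot_height)
    elif spec.kind == "hardcore":
        pts = _hardcore(rng, spec)
    else:
        pts = _cluster(rng, spec)
    colonies = [
        Colony(species, functional_group, float(x), float(y), (1,)) for x, y in pts
    ]
    return ColonyMap(plot_id, spec.plot_width, spec.plot_height, year, colonies)


def _csr(rng: np.random.Generator, n: int, w: float, h: float) -> np.ndarray:
    return rng.random((n, 2)) * [w, h]


def _hardcore(rng: np.random.Generator, spec: PointProcessSpec) -> np.ndarray:
    # simple sequential inhibition (dart throwing) with a bounded retry
    # budget; intensity of accepted points conditions on n_points
    budget = 1000 * spec.n_points
    accepted: list[np.ndarray] = []
    for _ in range(budget):
        cand = rng.random(2) * [spec.plot_width, spec.plot_height]
        if not accepted or (
            cdist(cand[None, :], np.array(accepted)).min() >= spec.min_dist
        ):
            accepted.append(cand)
            if len(accepted) == spec.n_points:
                return np.array(accepted)
    raise RuntimeError(
        f"hardcore packing failed: placed {len(accepted)} of {spec.n_points} "
        f"points at min_dist={spec.min_dist} within the retry budget"
    )


def _cluster(rng: np.random.Generator, spec: PointProcessSpec) -> np.ndarray:
    parents = rng.random((spec.n_parents, 2)) * [spec.plot_width, spec.plot_height]
    assign = rng.integers(0, spec.n_parents, size=spec.n_points)
    pts = np.empty((spec.n_points, 2))
    for i, p in enumerate(assign):
        while True:  # truncate to the rectangle by resampling
            cand = parents[p] + rng.normal(0.0, spec.cluster_sd, size=2)
            if 0.0 <= cand[0] <= spec.plot_width and 0.0 <= cand[1] <= spec.plot_height:
                pts[i] = cand
                break
    return pts


# ---------------------------------------------------------------------------
# occupancy matrices


@dataclass(frozen=True)
class MatrixSpec:
    """Specification of a synthetic species × bait occupancy matrix.

    ``segregation`` steers pairwise co-occurrence below (negative) or
    above (positive) independence through an equicorrelated latent
    Gaussian copula; 0 gives independent Bernoulli occupancy with
    per-species probabilities ``occupancy_probs``.
    """

    n_species: int
    n_baits: int
    occupancy_probs: tuple[float, ...]
    segregation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_baits < 2:
            raise ValueError("n_baits must be at least 2")
        if len(self.occupancy_probs) != self.n_species:
            raise ValueError("occupancy_probs must have one entry per species")
        if not all(0.0 < p < 1.0 for p in self.occupancy_probs):
            raise ValueError("occupancy probabilities must lie strictly in (0, 1)")
        if not -1.0 <= self.segregation <= 1.0:
            raise ValueError("segregation must lie in [-1, 1]")
        if self.n_species > 2 and self.segregation < -1.0 / (self.n_species - 1):
            raise ValueError(
                f"equicorrelation {self.segregation} is not positive semi-definite "
                f"for {self.n_species} species (needs >= {-1.0 / (self.n_species - 1):.3f})"
            )

    @staticmethod
    def uniform(n_species: int, n_baits: int, p: float, segregation: float = 0.0,
                seed: int = 0) -> "MatrixSpec":
        return MatrixSpec(n_species, n_baits, (p,) * n_species, segregation, seed)


def simulate_occupancy(spec: MatrixSpec) -> OccupancyMatrix:
    """Draw one occupancy matrix from ``spec``.

    Columns (baits) are independent; within a bait, species presences are
    thresholded equicorrelated Gaussians, so each species occupies a bait
    with its marginal probability while pairwise joint occupancy is
    depleted (segregation < 0) or enriched (> 0) relative to the product
    of marginals.
    """
    rng = np.random.default_rng(spec.seed)
    s, b = spec.n_species, spec.n_baits
    rho = spec.segregation
    if rho == 0.0 or s == 1:
        z = rng.standard_normal((s, b))
    else:
        corr = np.full((s, s), rho)
        np.fill_diagonal(corr, 1.0)
        # tiny jitter guards the PSD boundary (e.g. rho = -1/(s-1) exactly)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(s))
        z = chol @ rng.standard_normal((s, b))
    thresh = norm.ppf(np.asarray(spec.occupancy_probs))[:, None]
    values = (z < thresh).astype(np.int8)
    species = [f"sp{i + 1}" for i in range(s)]
    baits = [f"bait{j + 1}" for j in range(b)]
    return OccupancyMatrix(species, baits, values)


# ---------------------------------------------------------------------------
# gradient responses


@dataclass(frozen=True)
class GradientSpec:
    """Specification of a site-level linear response to precipitation.

    ``response = intercept + slope * covariate + N(0, noise_sd)`` per
    site; when ``group_slopes`` maps functional groups to slopes, one
    response row is generated per site per group (shared intercept),
    which is the design of the slope-heterogeneity ANCOVA.
    """

    site_covariates: tuple[float, ...]
    slope: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 0.0
    group_slopes: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.site_covariates) < 3:
            raise ValueError("need at least 3 sites")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_gradient(spec: GradientSpec) -> pd.DataFrame:
    """Generate a tidy site-level response table with columns
    ``covariate, response`` (plus ``group`` when group_slopes is set)."""
    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.site_covariates, dtype=float)
    if spec.group_slopes is None:
        y = spec.intercept + spec.slope * x + rng.normal(0.0, spec.noise_sd, x.size)
        return pd.DataFrame({"covariate": x, "response": y})
    frames = []
    for group in sorted(spec.group_slopes):
        slope = spec.group_slopes[group]
        y = spec.intercept + slope * x + rng.normal(0.0, spec.noise_sd, x.size)
        frames.append(pd.DataFrame({"covariate": x, "response": y, "group": group}))
    return pd.concat(frames, ignore_index=True)
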