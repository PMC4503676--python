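"""C-score null-model analysis of species co-occurrence at baits.

The C-score of a presence–absence matrix is the mean number of
checkerboard units over all unordered species pairs,

    C = mean_{i<j} (r_i − S_ij)(r_j − S_ij),

where ``r_i`` is the number of baits occupied by species *i* and
``S_ij`` the number occupied by both.  A checkerboard unit is a pair of
baits each held exclusively by one of the two species; an excess over
the null expectation indicates spatial segregation, the classic
signature of interference competition at food baits.

The null model randomizes each species row independently to ``r_i``
baits drawn uniformly without replacement — fixed row sums, equiprobable
columns — which is the recommended algorithm for bait/sample data where
sampling units are interchangeable.  Significance is summarized both by
add-one randomization p-values and by the Standardized Effect Size

    SES = (C_obs − mean C_null) / sd C_null,

with |SES| > 1.96 flagging non-random structure at the 5% level.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_random_state

from .data import NullModelResult, OccupancyMatrix

logger = logging.getLogger("antgrad")

__all__ = [
    "checkerboard_units",
    "c_score",
    "randomize_fixed_equiprobable",
    "null_model_test",
    "apply_inclusion_filters",
    "enumerate_null_distribution",
    "CScoreNullModel",
]


def checkerboard_units(mat: OccupancyMatrix, i: str, j: str) -> int:
    """Number of checkerboard units C_ij = (r_i − S_ij)(r_j − S_ij) for
    the species pair (i, j): bait pairs occupied exclusively by each."""
    if i == j:
        raise ValueError("checkerboard units need two distinct species")
    for label in (i, j):
        if label not in mat.species:
            raise KeyError(f"unknown species label {label!r}")
    ri = int(mat.values[mat.species.index(i)].sum())
    rj = int(mat.values[mat.species.index(j)].sum())
    s = int(
        (mat.values[mat.species.index(i)] & mat.values[mat.species.index(j)]).sum()
    )
    return (ri - s) * (rj - s)


def c_score(mat: OccupancyMatrix) -> float:
    """Mean checkerboard units over all unordered species pairs."""
    if mat.n_species < 2:
        raise ValueError("C-score needs at least two species rows")
    return float(_c_score_values(mat.values[None, ...])[0])


def _c_score_values(stack: np.ndarray) -> np.ndarray:
    """C-score of each matrix in a (n_rep, s, b) binary stack."""
    v = stack.astype(np.int64)
    r = v.sum(axis=2)  # (n_rep, s)
    shared = np.einsum("kib,kjb->kij", v, v)  # (n_rep, s, s)
    iu, ju = np.triu_indices(stack.shape[1], k=1)
    units = (r[:, iu] - shared[:, iu, ju]) * (r[:, ju] - shared[:, iu, ju])
    return units.mean(axis=1)


def randomize_fixed_equiprobable(
    mat: OccupancyMatrix, rng: np.random.Generator
) -> OccupancyMatrix:
    """One draw from the fixed-rows / equiprobable-columns null: each
    species is re-placed on r_i baits chosen uniformly without
    replacement; row sums are preserved exactly, column sums vary."""
    values = _randomize_stack(mat.row_totals(), mat.n_baits, 1, rng)[0]
    return OccupancyMatrix(mat.species, mat.baits, values, mat.bait_plot)


def _randomize_stack(
    row_totals: np.ndarray, n_baits: int, n_rep: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_rep, s, b) stack of independent null matrices with the given
    row sums.  Uniform placement via ranking iid uniforms per row."""
    s = len(row_totals)
    u = rng.random((n_rep, s, n_baits))
    ranks = u.argsort(axis=2).argsort(axis=2)
    return (ranks < np.asarray(row_totals)[None, :, None]).astype(np.int8)


class CScoreNullModel(BaseEstimator):
    """Randomization test of the C-score under the fixed-rows /
    equiprobable-columns null model.

    Parameters
    ----------
    n_rand : int, default=5000
        Number of randomized matrices.
    random_state : int, Generator or None
        Seed for the randomization stream.

    Attributes
    ----------
    c_score_ : float
        Observed C-score.
    null_mean_, null_sd_ : float
        Mean and sample (n−1) standard deviation of the null C-scores.
    ses_ : float
        Standardized effect size; ``nan`` when the null is degenerate.
    p_upper_, p_lower_ : float
        Add-one randomization p-values (ties count toward both tails).
    result_ : NullModelResult
        All of the above as one record.
    """

    def __init__(self, n_rand: int = 5000, random_state=None):
        self.n_rand = n_rand
        self.random_state = random_state

    def fit(self, X, y=None):
        """Run the randomization test on an :class:`OccupancyMatrix` or a
        binary 2-D array (rows = species, columns = baits)."""
        mat = _as_matrix(X)
        if self.n_rand < 2:
            raise ValueError("n_rand must be at least 2")
        rng = _as_generator(self.random_state)
        obs = c_score(mat)
        sims = self._null_c_scores(mat, rng)
        mean = float(sims.mean())
        sd = float(sims.std(ddof=1))
        degenerate = sd == 0.0
        if degenerate:
            logger.warning(
                "null distribution of the C-score is degenerate (sd = 0); "
                "SES undefined, p-values still reported"
            )
        ses = float("nan") if degenerate else (obs - mean) / sd
        p_upper = (1 + int((sims >= obs).sum())) / (1 + self.n_rand)
        p_lower = (1 + int((sims <= obs).sum())) / (1 + self.n_rand)
        self.c_score_ = obs
        self.null_mean_ = mean
        self.null_sd_ = sd
        self.ses_ = ses
        self.p_upper_ = p_upper
        self.p_lower_ = p_lower
        self.null_scores_ = sims
        self.result_ = NullModelResult(
            stat_obs=obs,
            null_mean=mean,
            null_sd=sd,
            ses=ses,
            p_upper=p_upper,
            p_lower=p_lower,
            n_rand=self.n_rand,
            n_species=mat.n_species,
            n_baits=mat.n_baits,
            degenerate=degenerate,
        )
        return self

    def _null_c_scores(self, mat: OccupancyMatrix, rng: np.random.Generator) -> np.ndarray:
        r = mat.row_totals()
        out = np.empty(self.n_rand)
        # chunked so memory stays bounded for large n_rand
        chunk = max(1, min(self.n_rand, 20_000_000 // (mat.n_species * mat.n_baits + 1)))
        done = 0
        while done < self.n_rand:
            k = min(chunk, self.n_rand - done)
            stack = _randomize_stack(r, mat.n_baits, k, rng)
            out[done : done + k] = _c_score_values(stack)
            done += k
        return out


def null_model_test(
    mat: OccupancyMatrix, n_rand: int = 5000, rng=None
) -> NullModelResult:
    """Functional wrapper over :class:`CScoreNullModel`."""
    return CScoreNullModel(n_rand=n_rand, random_state=rng).fit(mat).result_


def apply_inclusion_filters(
    mat: OccupancyMatrix, min_freq: float = 0.05
) -> OccupancyMatrix:
    """Apply the species-inclusion rules used before the null-model test:
    keep species occurring in at least ``min_freq`` of the baits
    (inclusive threshold), then keep only species sharing at least one
    plot with another retained species.

    Raises ``ValueError`` when fewer than two species survive, in which
    case the site-year analysis is skipped by the caller.
    """
    freq = mat.row_totals() / mat.n_baits
    frequent = [s for s, f in zip(mat.species, freq) if f >= min_freq]
    dropped = sorted(set(mat.species) - set(frequent))
    if dropped:
        logger.info("inclusion filter dropped rare species: %s", dropped)
    if len(frequent) < 2:
        raise ValueError(
            f"fewer than two species occur in >= {min_freq:.0%} of baits; "
            "co-occurrence analysis skipped"
        )
    sub = mat.subset_species(frequent)
    plots = {s: sub.species_plots(s) for s in sub.species}
    overlapping = [
        s for s in sub.species
        if any(plots[s] & plots[t] for t in sub.species if t != s)
    ]
    if len(overlapping) < 2:
        raise ValueError(
            "no two retained species occupy the same plots simultaneously; "
            "co-occurrence analysis skipped"
        )
    if len(overlapping) < len(sub.species):
        logger.info(
            "plot-overlap filter dropped species: %s",
            sorted(set(sub.species) - set(overlapping)),
        )
        sub = sub.subset_species(overlapping)
    return sub


def enumerate_null_distribution(
    row_totals: Iterable[int], n_baits: int
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Exhaustively enumerate the fixed-rows/equiprobable-columns null.

    Returns ``(mean, population sd, values, weights)`` of the C-score
    over every combination of row placements (each row: all C(b, r_i)
    bait subsets, equally likely).  Tractable for the small matrices used
    as oracles; the number of outcomes is prod_i C(b, r_i).
    """
    row_totals = list(row_totals)
    if len(row_totals) < 2:
        raise ValueError("need at least two rows")
    n_outcomes = math.prod(math.comb(n_baits, r) for r in row_totals)
    if n_outcomes > 2_000_000:
        raise ValueError(f"enumeration of {n_outcomes} outcomes is intractable")
    placements = [
        [np.array([1 if c in comb else 0 for c in range(n_baits)], dtype=np.int8)
         for comb in itertools.combinations(range(n_baits), r)]
        for r in row_totals
    ]
    stack = np.array(
        [rows for rows in itertools.product(*placements)], dtype=np.int8
    )
    values = _c_score_values(stack)
    uniq, counts = np.unique(values, return_counts=True)
    weights = counts / counts.sum()
    mean = float((uniq * weights).sum())
    var = float(((uniq - mean) ** 2 * weights).sum())
    return mean, math.sqrt(var), uniq, weights


def null_enumeration_deviation(
    row_totals, n_baits: int, n_rand: int, rng
) -> tuple[float, float]:
    """Deviation of the randomization null from exhaustive enumeration,
    in Monte-Carlo standard-error units.

    Draws ``n_rand`` null matrices for the given row-sum configuration
    and returns ``(|mean dev| / SE_mean, |sd dev| / SE_sd)`` against the
    exhaustively enumerated null mean and population sd.  Either value
    is ~|N(0,1)| when the randomizer is correct, so a single config
    should rarely exceed 3; across a sweep of many configs an isolated
    chance exceedance is expected and is resolved by one independent
    re-draw.
    """
    mean, sd, _, _ = enumerate_null_distribution(row_totals, n_baits)
    gen = _as_generator(rng)
    vals = _c_score_values(
        _randomize_stack(np.asarray(row_totals), n_baits, n_rand, gen)
    )
    if sd == 0:
        return abs(float(vals.mean()) - mean) * np.inf if vals.mean() != mean else 0.0, 0.0
    se_mean = sd / math.sqrt(n_rand)
    se_sd = sd / math.sqrt(2 * n_rand)
    return (
        abs(float(vals.mean()) - mean) / se_mean,
        abs(float(vals.std(ddof=1)) - sd) / se_sd,
    )


def _as_matrix(X) -> OccupancyMatrix:
    if isinstance(X, OccupancyMatrix):
        return X
    arr = np.asarray(X)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D presence-absence array")
    return OccupancyMatrix(
        [f"sp{i + 1}" for i in range(arr.shape[0])],
        [f"bait{j + 1}" for j in range(arr.shape[1])],
        arr,
    )


def _as_generator(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    if random_state is None or isinstance(random_state, (int, np.integer)):
        return np.random.default_rng(random_state)
    # accept legacy RandomState via sklearn's validation for pipeline use
    rs = check_random_state(random_state)
    return np.random.default_rng(rs.randint(0, 2**31 - 1))
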