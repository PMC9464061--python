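"""Dissimilarity index over census tracts and its multinomial allocation model.

The Duncan–Duncan dissimilarity index ``D`` measures how unevenly a minority
group (here: low-income households, defined by a minimum-wage cut-off) is
spread over the spatial units of a city relative to a reference group:

    D = 1/2 * sum_j | n_j^1 / n^1  -  n_j^0 / n^0 |

where ``n_j^c`` is the count of group-``c`` households in tract ``j`` and
``n^c`` the city total.  ``D`` is the fraction of the minority that would have
to relocate for both groups to share the same tract-level distribution.

The statistical model underneath treats the observed counts as draws from a
product of two independent multinomials — one per group — with tract
allocation probabilities ``p_j^1`` and ``p_j^0``.  The maximum-likelihood
estimates are the observed tract shares, so the plug-in ``D`` estimates the
population quantity ``D_pop = 1/2 * sum_j |p_j^1 - p_j^0|``.  That framing is
what makes the finite-sample bias of ``D`` quantifiable (see ``idiseg.bias``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: Tolerance for probability-vector checks.
PROB_TOL = 1e-12

#: IBGE-style household income brackets, in multiples of the minimum wage.
#: The last bracket is open-ended.
DEFAULT_BRACKETS: tuple[tuple[float, float], ...] = (
    (0.0, 0.5),
    (0.5, 1.0),
    (1.0, 2.0),
    (2.0, 3.0),
    (3.0, math.inf),
)

ComparisonMode = Literal["complement", "total"]


class SegregationError(ValueError):
    """Invalid input for a segregation computation."""


class CutoffError(SegregationError):
    """Cut-off does not match any bracket boundary of the table."""

    def __init__(self, cutoff: float, boundaries: Sequence[float]):
        self.cutoff = cutoff
        self.boundaries = tuple(boundaries)
        super().__init__(
            f"cut-off {cutoff} is not a bracket boundary; valid boundaries: "
            f"{sorted(self.boundaries)}"
        )


def bracket_label(lo: float, hi: float) -> str:
    """Column name for a bracket, e.g. ``mw_0_0.5`` or ``mw_3_plus``."""

    def fmt(x: float) -> str:
        return f"{x:g}"

    if math.isinf(hi):
        return f"mw_{fmt(lo)}_plus"
    return f"mw_{fmt(lo)}_{fmt(hi)}"


@dataclass
class TractTable:
    """Per-tract household counts by income bracket for one city.

    ``counts`` is a ``(J, K)`` integer array: ``J`` tracts by ``K`` ordered,
    mutually exclusive income brackets (in minimum-wage units, last one
    open-ended).  Households that did not report income are assumed to have
    been excluded upstream.
    """

    city_id: str
    region: str
    tract_ids: tuple[str, ...]
    brackets: tuple[tuple[float, float], ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise SegregationError("counts must be a 2-D (tracts x brackets) array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise SegregationError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise SegregationError(f"negative counts in city {self.city_id!r}")
        if len(self.tract_ids) != self.counts.shape[0]:
            raise SegregationError("tract_ids length does not match counts rows")
        if len(set(self.tract_ids)) != len(self.tract_ids):
            raise SegregationError(f"duplicate tract ids in city {self.city_id!r}")
        if len(self.brackets) != self.counts.shape[1]:
            raise SegregationError("brackets length does not match counts columns")
        los = [b[0] for b in self.brackets]
        his = [b[1] for b in self.brackets]
        if any(hi <= lo for lo, hi in self.brackets):
            raise SegregationError("each bracket must have upper > lower bound")
        if any(his[i] != los[i + 1] for i in range(len(self.brackets) - 1)):
            raise SegregationError(
                "brackets must be contiguous and in ascending-boundary order"
            )

    @property
    def n_tracts(self) -> int:
        return self.counts.shape[0]

    @property
    def totals(self) -> np.ndarray:
        """Households with reported income per tract."""
        return self.counts.sum(axis=1)

    @property
    def boundaries(self) -> tuple[float, ...]:
        """Finite bracket boundaries usable as minimum-wage cut-offs."""
        return tuple(hi for _, hi in self.brackets if math.isfinite(hi))

    def drop_empty_tracts(self) -> "TractTable":
        """Remove tracts with zero reported households (logged, never silent)."""
        keep = self.totals > 0
        if keep.all():
            return self
        dropped = [t for t, k in zip(self.tract_ids, keep) if not k]
        logger.warning(
            "city %s: dropping %d empty tract(s): %s",
            self.city_id, len(dropped), dropped,
        )
        return TractTable(
            city_id=self.city_id,
            region=self.region,
            tract_ids=tuple(t for t, k in zip(self.tract_ids, keep) if k),
            brackets=self.brackets,
            counts=self.counts[keep],
        )


@dataclass
class AllocationModel:
    """Estimated tract-allocation probabilities for the two income groups."""

    p1: np.ndarray  # minority allocation probabilities, sums to 1
    p0: np.ndarray  # reference allocation probabilities, sums to 1
    n1: int  # minority total
    n0: int  # reference total

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.p1.shape != self.p0.shape or self.p1.ndim != 1:
            raise SegregationError("p1 and p0 must be 1-D vectors of equal length")
        for name, p in (("p1", self.p1), ("p0", self.p0)):
            if (p < -PROB_TOL).any():
                raise SegregationError(f"{name} has negative entries")
            if abs(p.sum() - 1.0) > 1e-9:
                raise SegregationError(f"{name} does not sum to 1 (sum={p.sum()!r})")
        if self.n1 < 0 or self.n0 < 0:
            raise SegregationError("group totals must be non-negative")

    @property
    def n(self) -> int:
        return self.n1 + self.n0

    @property
    def n_tracts(self) -> int:
        return self.p1.shape[0]

    @property
    def minority_share(self) -> float:
        return self.n1 / self.n


@dataclass
class SegregationResult:
    """A city's dissimilarity index at one cut-off."""

    city_id: str
    cutoff: float
    D: float
    minority_share: float
    n_tracts: int
    comparison_mode: ComparisonMode
    D_corrected: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.D <= 1.0 + PROB_TOL):
            raise SegregationError(f"D={self.D} outside [0, 1]")
        if not (0.0 <= self.minority_share <= 1.0):
            raise SegregationError("minority share outside [0, 1]")


def cumulate_brackets(
    table: TractTable,
    cutoff: float,
    mode: ComparisonMode = "complement",
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse bracket counts into (minority, reference) per-tract counts.

    The minority group pools all brackets whose upper bound is at or below
    ``cutoff``.  ``mode="complement"`` sets the reference to the remaining
    households (the formula's ``n_j^0``); ``mode="total"`` sets it to all
    households with reported income, the alternative pairing in which the
    minority is compared against the whole city.
    """
    if table.n_tracts == 0:
        raise SegregationError("empty tract table")
    boundaries = table.boundaries
    if not any(math.isclose(cutoff, b, rel_tol=0, abs_tol=1e-9) for b in boundaries):
        raise CutoffError(cutoff, boundaries)
    sel = np.array([hi <= cutoff + 1e-9 for _, hi in table.brackets])
    minority = table.counts[:, sel].sum(axis=1)
    if mode == "complement":
        reference = table.totals - minority
    elif mode == "total":
        reference = table.totals.copy()
    else:
        raise SegregationError(f"unknown comparison mode {mode!r}")
    return minority, reference


def _validate_counts(minority: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    minority = np.asarray(minority, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if minority.shape != reference.shape or minority.ndim != 1:
        raise SegregationError("count vectors must be 1-D and of equal length")
    if minority.shape[0] < 2:
        raise SegregationError("need at least 2 tracts to compute the index")
    if (minority < 0).any() or (reference < 0).any():
        raise SegregationError("negative counts")
    if minority.sum() <= 0:
        raise SegregationError("minority group has zero total; index undefined")
    if reference.sum() <= 0:
        raise SegregationError("reference group has zero total; index undefined")
    return minority, reference


def dissimilarity_index(minority: np.ndarray, reference: np.ndarray) -> float:
    """Duncan dissimilarity index ``D`` of two per-tract count vectors."""
    minority, reference = _validate_counts(minority, reference)
    d = 0.5 * np.abs(minority / minority.sum() - reference / reference.sum()).sum()
    return float(min(d, 1.0))


def estimate_allocation(minority: np.ndarray, reference: np.ndarray) -> AllocationModel:
    """Maximum-likelihood allocation probabilities: observed tract shares."""
    minority, reference = _validate_counts(minority, reference)
    return AllocationModel(
        p1=minority / minority.sum(),
        p0=reference / reference.sum(),
        n1=int(round(minority.sum())),
        n0=int(round(reference.sum())),
    )


def population_dissimilarity(model: AllocationModel) -> float:
    """``D_pop = 1/2 sum_j |p_j^1 - p_j^0|``; zero iff the vectors coincide."""
    return float(0.5 * np.abs(model.p1 - model.p0).sum())


def conditional_population_dissimilarity(
    tract_sizes: np.ndarray,
    cond_prob_minority_given_tract: np.ndarray,
    overall_minority_prob: float,
) -> float:
    """``D_pop`` in its conditional form, for fixed tract sizes.

    With tract weights ``w_j = n_j / n``, conditional minority probabilities
    ``q_j = P(c=1 | tract j)`` and overall minority probability ``p``:

        D_pop = 1/2 * sum_j w_j | q_j / p  -  (1 - q_j) / (1 - p) |

    Algebraically identical to the unconditional form after the Bayes
    conversion ``p_j^1 = w_j q_j / p``, ``p_j^0 = w_j (1 - q_j) / (1 - p)``.
    """
    sizes = np.asarray(tract_sizes, dtype=float)
    q = np.asarray(cond_prob_minority_given_tract, dtype=float)
    p = float(overall_minority_prob)
    if sizes.shape != q.shape or sizes.ndim != 1:
        raise SegregationError("tract_sizes and conditional probabilities must match")
    if (sizes <= 0).any():
        raise SegregationError("tract sizes must be positive")
    if (q < 0).any() or (q > 1).any():
        raise SegregationError("conditional probabilities must lie in [0, 1]")
    if not (0.0 < p < 1.0):
        raise SegregationError(
            "overall minority probability must lie strictly in (0, 1)"
        )
    w = sizes / sizes.sum()
    d = 0.5 * np.sum(w * np.abs(q / p - (1.0 - q) / (1.0 - p)))
    return float(d)


def log_likelihood(
    model: AllocationModel, minority: np.ndarray, reference: np.ndarray
) -> float:
    """Product-multinomial log-likelihood of the counts under ``model``.

    Includes both log multinomial coefficients.  Uses the convention
    ``0 * log 0 = 0``; a positive count on a zero-probability tract yields
    ``-inf``.
    """
    minority = np.asarray(minority, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if minority.shape != model.p1.shape or reference.shape != model.p0.shape:
        raise SegregationError("counts do not match model dimensions")

    def group_ll(counts: np.ndarray, probs: np.ndarray) -> float:
        n = counts.sum()
        coef = gammaln(n + 1.0) - gammaln(counts + 1.0).sum()
        with np.errstate(divide="ignore"):
            logp = np.log(probs)
        bad = (counts > 0) & (probs <= 0)
        if bad.any():
            return -math.inf
        terms = np.where(counts > 0, counts * logp, 0.0)
        return float(coef + terms.sum())

    return group_ll(minority, model.p1) + group_ll(reference, model.p0)


def city_dissimilarity(
    table: TractTable,
    cutoff: float,
    mode: ComparisonMode = "complement",
) -> SegregationResult:
    """Compute a city's ``SegregationResult`` at one minimum-wage cut-off."""
    table = table.drop_empty_tracts()
    minority, reference = cumulate_brackets(table, cutoff, mode)
    n = table.totals.sum()
    share = float(minority.sum() / n) if n > 0 else 0.0
    d = dissimilarity_index(minority, reference)
    return SegregationResult(
        city_id=table.city_id,
        cutoff=cutoff,
        D=d,
        minority_share=share,
        n_tracts=table.n_tracts,
        comparison_mode=mode,
    )
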