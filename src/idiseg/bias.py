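"""Finite-sample bias of the dissimilarity index, and its bootstrap correction.

The plug-in index ``D`` is an upward-biased estimator of ``D_pop`` when tract
populations are small or the minority share is low: even under a perfectly
even allocation (``p_j^1 = p_j^0`` for every tract), sampling noise produces
strictly positive observed unevenness.  Two resampling schemes quantify this:

* ``parametric`` — Efron's bootstrap bias estimator applied to the fitted
  product-multinomial model: replicate count tables are simulated from the
  MLE allocation probabilities, ``bias_hat = mean(D*) - D_obs`` and
  ``D_corrected = D_obs - bias_hat = 2 D_obs - mean(D*)``.
* ``random_allocation`` — a no-segregation null in which both groups share
  the tract-size allocation ``p_j = n_j / n``.  The mean replicate ``D`` is
  the unevenness expected from chance alone, the classical reference point
  for "systematic vs. random" segregation.

``exact_expected_D`` enumerates the full product-multinomial outcome space on
tiny instances and serves as the independent oracle for the bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
from scipy.special import comb, gammaln

from .core import (
    AllocationModel,
    ComparisonMode,
    SegregationError,
    TractTable,
    cumulate_brackets,
    dissimilarity_index,
    estimate_allocation,
)

BiasMode = Literal["parametric", "random_allocation"]


@dataclass
class BiasEstimate:
    """Bootstrap bias diagnosis for one city's dissimilarity index."""

    city_id: str
    cutoff: float
    D_observed: float
    B: int
    replicate_D: np.ndarray
    bias_hat: float
    D_corrected: float
    se_boot: float
    mode: BiasMode
    seed: int
    degenerate: bool = False
    clipped: bool = False

    @property
    def bias_pct(self) -> float:
        """Bias as a percentage of the observed index (NaN if D = 0)."""
        if self.D_observed == 0.0:
            return math.nan
        return 100.0 * self.bias_hat / self.D_observed


def simulate_allocation(
    model: AllocationModel, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one (minority, reference) count table from the allocation model.

    Counts are independent multinomials: ``minority ~ Mult(n1, p1)`` and
    ``reference ~ Mult(n0, p0)``; group totals are conserved exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    minority = rng.multinomial(model.n1, model.p1)
    reference = rng.multinomial(model.n0, model.p0)
    return minority, reference


def _replicate_D(
    n1: int, p1: np.ndarray, n0: int, p0: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized dissimilarity of B product-multinomial replicates."""
    m = rng.multinomial(n1, p1, size=B).astype(float)
    r = rng.multinomial(n0, p0, size=B).astype(float)
    d = 0.5 * np.abs(m / n1 - r / n0).sum(axis=1)
    return np.minimum(d, 1.0)


def bootstrap_bias(
    table: TractTable,
    cutoff: float,
    B: int = 1000,
    seed: int = 0,
    mode: BiasMode = "parametric",
    comparison: ComparisonMode = "complement",
) -> BiasEstimate:
    """Bootstrap bias estimate of a city's dissimilarity index.

    In ``parametric`` mode replicates come from the fitted model (bias of the
    plug-in estimator); in ``random_allocation`` mode both groups are
    allocated by tract size (``p_j = n_j/n``), so the mean replicate ``D`` is
    the chance-unevenness baseline rather than a bias estimate per se — the
    same contract is reported for both.

    The bootstrap standard error is the standard deviation of the replicate
    values.  The corrected index is clipped to [0, 1] with a flag if needed.
    """
    if B < 2:
        raise SegregationError("need at least B=2 bootstrap replications")
    table = table.drop_empty_tracts()
    rng = np.random.default_rng(seed)

    if table.n_tracts < 2:
        # One tract: D is identically 0, with no sampling variability.
        return BiasEstimate(
            city_id=table.city_id, cutoff=cutoff, D_observed=0.0, B=B,
            replicate_D=np.zeros(B), bias_hat=0.0, D_corrected=0.0,
            se_boot=0.0, mode=mode, seed=int(seed), degenerate=True,
        )

    minority, reference = cumulate_brackets(table, cutoff, comparison)
    d_obs = dissimilarity_index(minority, reference)
    model = estimate_allocation(minority, reference)

    if mode == "parametric":
        p1, p0 = model.p1, model.p0
    elif mode == "random_allocation":
        sizes = minority + reference if comparison == "complement" else reference
        p_null = sizes / sizes.sum()
        p1 = p0 = p_null
    else:
        raise SegregationError(f"unknown bias mode {mode!r}")

    reps = _replicate_D(model.n1, p1, model.n0, p0, B, rng)
    bias_hat = float(reps.mean() - d_obs)
    corrected = d_obs - bias_hat
    clipped = not (0.0 <= corrected <= 1.0)
    corrected = float(min(max(corrected, 0.0), 1.0))
    return BiasEstimate(
        city_id=table.city_id, cutoff=cutoff, D_observed=d_obs, B=B,
        replicate_D=reps, bias_hat=bias_hat, D_corrected=corrected,
        se_boot=float(reps.std(ddof=1)), mode=mode, seed=int(seed),
        clipped=clipped,
    )


def random_allocation_baseline(
    table: TractTable, cutoff: float, B: int = 1000, seed: int = 0,
    comparison: ComparisonMode = "complement",
) -> BiasEstimate:
    """Chance-unevenness baseline: replicates under the no-segregation null."""
    return bootstrap_bias(
        table, cutoff, B=B, seed=seed, mode="random_allocation",
        comparison=comparison,
    )


def _compositions(n: int, k: int) -> Iterator[tuple[int, ...]]:
    """All ways to place n identical items into k ordered cells."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def _multinomial_logpmf(counts: np.ndarray, n: int, p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(p)
        terms = np.where(counts > 0, counts * logp, 0.0)
    terms = np.nan_to_num(terms, nan=0.0, neginf=-np.inf)
    bad = ((counts > 0) & (p <= 0)).any(axis=-1)
    out = gammaln(n + 1.0) - gammaln(counts + 1.0).sum(axis=-1) + terms.sum(axis=-1)
    return np.where(bad, -np.inf, out)


def exact_expected_D(model: AllocationModel, max_outcomes: int = 10**6) -> float:
    """Exact ``E[D]`` by full enumeration of the product-multinomial space.

    Intended as a test oracle on tiny instances; the outcome space has
    ``C(n1+J-1, J-1) * C(n0+J-1, J-1)`` points and is rejected when larger
    than ``max_outcomes``.
    """
    J = model.n_tracts
    size = comb(model.n1 + J - 1, J - 1, exact=True) * comb(
        model.n0 + J - 1, J - 1, exact=True
    )
    if size > max_outcomes:
        raise SegregationError(
            f"outcome space has {size} points, above the enumeration limit "
            f"{max_outcomes}"
        )
    m_outcomes = np.array(list(_compositions(model.n1, J)), dtype=float)
    r_outcomes = np.array(list(_compositions(model.n0, J)), dtype=float)
    log_pm = _multinomial_logpmf(m_outcomes, model.n1, model.p1)
    log_pr = _multinomial_logpmf(r_outcomes, model.n0, model.p0)
    pm = np.exp(log_pm)
    pr = np.exp(log_pr)
    # D for every (minority outcome, reference outcome) pair.
    diff = (
        m_outcomes[:, None, :] / model.n1 - r_outcomes[None, :, :] / model.n0
    )
    d = 0.5 * np.abs(diff).sum(axis=2)
    return float(pm @ d @ pr)
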