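"""Choosing the low-income cut-off that defines the minority group.

A candidate cut-off (in minimum wages) is evaluated on two axes across the
whole collection of cities: the pooled (household-weighted) national share of
households at or below it, and the distribution of per-city dissimilarity
indices it induces.  A cut-off whose pooled share is tiny produces an
unstable, upward-biased index; one whose share exceeds half the sample no
longer describes a minority.  The selection rule picks the smallest cut-off
whose pooled share falls inside configurable bounds (default [0.20, 0.50)).
The lower bound is this package's operationalization of "large enough to be
stable"; the 50% ceiling is the hard definition of a minority.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bias import BiasEstimate, bootstrap_bias
from .core import (
    ComparisonMode,
    SegregationError,
    SegregationResult,
    TractTable,
    city_dissimilarity,
    cumulate_brackets,
)

logger = logging.getLogger(__name__)

DEFAULT_LOWER = 0.20
DEFAULT_UPPER = 0.50


@dataclass
class CutoffScan:
    """Per-cutoff national summary of minority share, index level and bias."""

    summary: pd.DataFrame  # one row per cutoff
    per_city: pd.DataFrame  # one row per (cutoff, city)
    excluded: pd.DataFrame  # flagged exclusions: cutoff, city_id, reason
    selected_cutoff: float | None = None


def select_cutoff(
    pooled_shares: Mapping[float, float],
    lower_bound: float = DEFAULT_LOWER,
    upper_bound: float = DEFAULT_UPPER,
) -> float | None:
    """Smallest cut-off whose pooled minority share lies in [lower, upper).

    Returns ``None`` when no cut-off qualifies (share map exhausted without a
    share that is both large enough to be stable and still a minority).
    """
    if not pooled_shares:
        raise SegregationError("empty share map")
    if not (0.0 < lower_bound < upper_bound <= 1.0):
        raise SegregationError("require 0 < lower_bound < upper_bound <= 1")
    for cutoff in sorted(pooled_shares):
        share = pooled_shares[cutoff]
        if not (0.0 <= share <= 1.0):
            raise SegregationError(f"share {share} for cutoff {cutoff} outside [0,1]")
        if lower_bound <= share < upper_bound:
            return cutoff
    return None


def scan_cutoffs(
    tables: Sequence[TractTable],
    cutoffs: Sequence[float],
    B: int = 1000,
    seed: int = 0,
    comparison: ComparisonMode = "complement",
    lower_bound: float = DEFAULT_LOWER,
    upper_bound: float = DEFAULT_UPPER,
) -> CutoffScan:
    """Evaluate each cut-off over all cities and apply the selection rule.

    For each cut-off: the pooled share is household-weighted across cities
    (sum of minority counts over sum of all reported households); per-city
    ``D`` and parametric bootstrap bias are summarised over cities.  Cities
    that fail at a given cut-off are reported as flagged exclusions, never
    silently dropped.  Bootstrap seeds derive deterministically from ``seed``
    via one spawned stream per (cutoff, city) pair.
    """
    if not tables:
        raise SegregationError("need at least one city")
    rows = []
    per_city_rows = []
    excluded = []
    for ci, cutoff in enumerate(cutoffs):
        tot_minority = 0
        tot_households = 0
        for city_idx, table in enumerate(tables):
            city_seed = int(
                np.random.SeedSequence([int(seed), ci, city_idx]).generate_state(1)[0]
                % (2**31)
            )
            try:
                clean = table.drop_empty_tracts()
                minority, _ = cumulate_brackets(clean, cutoff, comparison)
                tot_minority += int(minority.sum())
                tot_households += int(clean.totals.sum())
                res = city_dissimilarity(clean, cutoff, comparison)
                est = bootstrap_bias(
                    clean, cutoff, B=B, seed=city_seed, comparison=comparison
                )
            except SegregationError as err:
                excluded.append(
                    {"cutoff": cutoff, "city_id": table.city_id, "reason": str(err)}
                )
                continue
            per_city_rows.append(
                {
                    "cutoff": cutoff,
                    "city_id": table.city_id,
                    "D": res.D,
                    "minority_share": res.minority_share,
                    "n_tracts": res.n_tracts,
                    "bias_hat": est.bias_hat,
                    "bias_pct": est.bias_pct,
                    "D_corrected": est.D_corrected,
                    "se_boot": est.se_boot,
                }
            )
        sub = [r for r in per_city_rows if r["cutoff"] == cutoff]
        d_vals = np.array([r["D"] for r in sub])
        bias_vals = np.array([r["bias_hat"] for r in sub])
        bias_pcts = np.array([r["bias_pct"] for r in sub])
        rows.append(
            {
                "cutoff": cutoff,
                "pooled_share": tot_minority / tot_households if tot_households else np.nan,
                "n_cities": len(sub),
                "D_mean": d_vals.mean() if len(sub) else np.nan,
                "D_min": d_vals.min() if len(sub) else np.nan,
                "D_max": d_vals.max() if len(sub) else np.nan,
                "D_sd": d_vals.std(ddof=1) if len(sub) > 1 else np.nan,
                "bias_mean_abs": bias_vals.mean() if len(sub) else np.nan,
                "bias_mean_pct": (
                    np.nanmean(bias_pcts)
                    if len(sub) and np.isfinite(bias_pcts).any()
                    else np.nan
                ),
            }
        )
    summary = pd.DataFrame(rows).sort_values("cutoff").reset_index(drop=True)
    shares = {
        row["cutoff"]: row["pooled_share"]
        for _, row in summary.iterrows()
        if np.isfinite(row["pooled_share"])
    }
    selected = select_cutoff(shares, lower_bound, upper_bound) if shares else None
    if selected is None:
        logger.warning("no cut-off selected: no pooled share in [%s, %s)",
                       lower_bound, upper_bound)
    else:
        logger.info("selected cut-off: %s minimum wages", selected)
    return CutoffScan(
        summary=summary,
        per_city=pd.DataFrame(
            per_city_rows,
            columns=["cutoff", "city_id", "D", "minority_share", "n_tracts",
                     "bias_hat", "bias_pct", "D_corrected", "se_boot"],
        ),
        excluded=pd.DataFrame(excluded, columns=["cutoff", "city_id", "reason"]),
        selected_cutoff=selected,
    )
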