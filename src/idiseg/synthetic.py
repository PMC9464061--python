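"""Synthetic IBGE-like census data with known segregation ground truth.

Real tract-level income tables are access-restricted, so every pipeline
stage is exercised on simulated cities built to mirror the Brazilian census
design: tracts of approximately equal household count (±10% jitter around a
target), household income drawn log-normal (the standard right-skewed choice
in the inequality literature) and binned into the minimum-wage brackets
{0–½, ½–1, 1–2, 2–3, 3+}, and a *known* population dissimilarity ``D_pop``
imposed through an exactly calibrated allocation model.

The default income model is log-normal with sigma = 0.9 and
mu = ln(2) + 0.418·sigma, which places 33.8% of households at or below two
minimum wages and reproduces the qualitative national bracket-share pattern
(a few percent below ½ MW, ~12% below 1 MW, just over half below 3 MW).

Calibration uses a two-block tilt that keeps *expected tract sizes equal*
(the IBGE design constraint): minority allocation probability is raised by
``delta`` on the first half of the tracts and lowered on the second half,
with the reference allocation compensating so every tract keeps the same
expected household count.  ``D_pop = h·delta/(1-p)`` (h tilted tracts,
minority share p) is solved for ``delta`` in closed form, so the requested
``D_pop`` is hit exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .associations import compute_gini, compute_sei, zscore
from .core import (
    DEFAULT_BRACKETS,
    AllocationModel,
    SegregationError,
    TractTable,
    population_dissimilarity,
)

#: Default log-income scale; region shifts perturb it.
INCOME_SIGMA = 0.9
#: Location chosen so that P(income <= 2 MW) = 0.338 at the default sigma.
INCOME_MU = math.log(2.0) + 0.41769 * INCOME_SIGMA

REGIONS = ("cw", "n", "ne", "s", "se")
#: Higher-inequality regions get a wider income distribution and a higher
#: target segregation level, echoing the north/north-east pattern.
REGION_SIGMA_SHIFT = {"cw": 0.05, "n": 0.08, "ne": 0.12, "s": -0.05, "se": 0.0}
REGION_DPOP_SHIFT = {"cw": 0.02, "n": 0.03, "ne": 0.06, "s": -0.03, "se": -0.01}


@dataclass
class CityBlueprint:
    """Recipe for one synthetic city."""

    city_id: str
    region: str = "se"
    n_tracts: int = 100
    households_per_tract: int = 300
    income_mu: float = INCOME_MU
    income_sigma: float = INCOME_SIGMA
    target_Dpop: float = 0.27
    poverty_line: float = 1.5  # minimum wages
    calibration_cutoff: float = 2.0  # minority definition used for the tilt
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracts < 2:
            raise SegregationError("need at least 2 tracts")
        if not (0.0 <= self.target_Dpop < 1.0):
            raise SegregationError("target_Dpop must lie in [0, 1)")
        if self.households_per_tract < 10:
            raise SegregationError("households_per_tract must be >= 10")


@dataclass
class PanelBlueprint:
    """Recipe for a city panel with a known regression structure.

    ``beta`` holds the true coefficients of the full-model design (on
    z-scored covariates); the outcome is generated as ``idi = Z(X)β + ε``
    with Gaussian noise, so fits on the same scale recover ``beta``
    unbiasedly.
    """

    n_cities: int = 152
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "gini": 0.5, "poverty_rate": 0.2, "sei": 0.0,
            "gdp_pc": 0.0, "unemployment": 0.1, "log_population": 0.1,
        }
    )
    noise_sd: float = 0.5
    households_per_city: int = 300  # incomes drawn per city for Gini/poverty
    poverty_line: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise SegregationError("noise SD must be positive")
        if not all(math.isfinite(v) for v in self.beta.values()):
            raise SegregationError("coefficients must be finite")
        if self.n_cities < len(self.beta) + 2:
            raise SegregationError("too few cities for the coefficient vector")


def calibrate_allocation(
    J: int,
    target_Dpop: float,
    minority_share: float,
    base_weights: np.ndarray | None = None,
) -> AllocationModel:
    """Allocation probabilities with ``D_pop`` exactly equal to the target.

    ``base_weights`` are the relative expected tract sizes (default: equal).
    The minority probability is tilted up by ``delta`` on the first
    ``h = J // 2`` tracts and down on the rest; the reference probability
    compensates so that ``p·p1_j + (1-p)·p0_j`` stays proportional to the
    base weight of every tract.  Raises with the feasible maximum when the
    target cannot be reached for the given share and tract count.
    """
    if J < 2:
        raise SegregationError("need at least 2 tracts")
    if not (0.0 <= target_Dpop < 1.0):
        raise SegregationError("target_Dpop must lie in [0, 1)")
    p = float(minority_share)
    if not (0.0 < p < 1.0):
        raise SegregationError("minority share must lie strictly in (0, 1)")
    if base_weights is None:
        w = np.full(J, 1.0 / J)
    else:
        w = np.asarray(base_weights, dtype=float)
        if w.shape != (J,) or (w <= 0).any():
            raise SegregationError("base weights must be J positive numbers")
        w = w / w.sum()
    h = J // 2
    lo = w[h:]
    hi = w[:h]
    # Feasibility: p1 >= 0 on the down-tilted block, p0 >= 0 on the up-tilted.
    delta_max = min(float(lo.min()) * (J - h) / h, float(hi.min()) * (1.0 - p) / p)
    feasible_max = h * delta_max / (1.0 - p)
    delta = target_Dpop * (1.0 - p) / h
    if delta > delta_max * (1 + 1e-12):
        raise SegregationError(
            f"target D_pop={target_Dpop} infeasible for J={J}, share={p}; "
            f"feasible maximum is {feasible_max:.6f}"
        )
    if delta == 0.0:
        # even allocation: both groups follow the tract weights exactly
        return AllocationModel(p1=w.copy(), p0=w.copy(), n1=1, n0=1)
    tilt = np.concatenate([np.full(h, delta), np.full(J - h, -delta * h / (J - h))])
    p1 = w + tilt
    p0 = (w - p * p1) / (1.0 - p)
    p1 = np.clip(p1, 0.0, None)
    p0 = np.clip(p0, 0.0, None)
    # n1/n0 here carry the share; actual counts are set by the caller.
    return AllocationModel(p1=p1 / p1.sum(), p0=p0 / p0.sum(), n1=1, n0=1)


def generate_city(
    blueprint: CityBlueprint,
) -> tuple[TractTable, np.ndarray, float]:
    """Simulate one city: tract table, raw household incomes, true ``D_pop``.

    Incomes are drawn log-normal and binned into the minimum-wage brackets;
    households at or below the calibration cut-off form the minority and are
    allocated to tracts by the calibrated probabilities, the rest by the
    compensating reference probabilities.  The returned ``true_Dpop`` is the
    population dissimilarity of the calibrated model (equal to the target).
    """
    bp = blueprint
    rng = np.random.default_rng(bp.seed)
    sizes = np.rint(
        bp.households_per_tract * rng.uniform(0.9, 1.1, size=bp.n_tracts)
    ).astype(int)
    n = int(sizes.sum())
    incomes = rng.lognormal(mean=bp.income_mu, sigma=bp.income_sigma, size=n)

    brackets = DEFAULT_BRACKETS
    edges = [hi for _, hi in brackets if math.isfinite(hi)]
    bracket_idx = np.searchsorted(edges, incomes, side="left")
    bracket_counts = np.bincount(bracket_idx, minlength=len(brackets))

    minority_brackets = np.array(
        [math.isfinite(hi) and hi <= bp.calibration_cutoff + 1e-9 for _, hi in brackets]
    )
    n1 = int(bracket_counts[minority_brackets].sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise SegregationError(
            f"degenerate income draw for city {bp.city_id!r}: one group is empty"
        )
    share = n1 / n
    model = calibrate_allocation(
        bp.n_tracts, bp.target_Dpop, share, base_weights=sizes / n
    )
    true_dpop = population_dissimilarity(model)

    counts = np.zeros((bp.n_tracts, len(brackets)), dtype=np.int64)
    for b, cnt in enumerate(bracket_counts):
        if cnt == 0:
            continue
        probs = model.p1 if minority_brackets[b] else model.p0
        counts[:, b] = rng.multinomial(int(cnt), probs)

    table = TractTable(
        city_id=bp.city_id,
        region=bp.region,
        tract_ids=tuple(f"{bp.city_id}-t{j:04d}" for j in range(bp.n_tracts)),
        brackets=brackets,
        counts=counts,
    )
    return table, incomes, true_dpop


def generate_panel(
    blueprint: PanelBlueprint,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """City panel with internally consistent covariates and known ``beta``.

    Gini and poverty rate are computed from each city's simulated incomes
    (poverty rate is exactly the fraction of incomes below the poverty
    line), so the two covariates carry their natural mutual correlation.
    The outcome is ``idi = Z(X) @ beta + noise`` on the z-scored design.
    """
    bp = blueprint
    rng = np.random.default_rng(bp.seed)
    n = bp.n_cities
    regions = [REGIONS[i % len(REGIONS)] for i in range(n)]
    sigma = np.array(
        [INCOME_SIGMA + REGION_SIGMA_SHIFT[r] for r in regions]
    ) + rng.normal(0.0, 0.05, size=n)
    mu = INCOME_MU + rng.normal(0.0, 0.15, size=n)

    gini = np.empty(n)
    poverty = np.empty(n)
    for i in range(n):
        incomes = rng.lognormal(mu[i], max(sigma[i], 0.3), size=bp.households_per_city)
        gini[i] = compute_gini(incomes)
        poverty[i] = float(np.mean(incomes < bp.poverty_line))

    population = np.exp(rng.normal(13.0, 1.0, size=n))  # ~1e5 .. 1e7 people
    gdp_pc = np.exp(rng.normal(math.log(16.0), 0.4, size=n))  # thousands US$
    unemployment = np.clip(rng.normal(0.085, 0.025, size=n), 0.01, 0.30)
    quality = zscore(np.log(gdp_pc)) * 0.5 + rng.normal(0.0, 1.0, size=n)
    education = np.clip(0.5 + 0.08 * quality + rng.normal(0, 0.05, n), 0.05, 0.99)
    water = np.clip(0.85 + 0.05 * quality + rng.normal(0, 0.04, n), 0.2, 1.0)
    sanitation = np.clip(0.6 + 0.1 * quality + rng.normal(0, 0.06, n), 0.05, 1.0)
    overcrowding = np.clip(0.25 - 0.06 * quality + rng.normal(0, 0.04, n), 0.01, 0.9)
    sei = compute_sei(education, water, sanitation, overcrowding)

    design = {
        "gini": zscore(gini),
        "poverty_rate": zscore(poverty),
        "sei": zscore(sei),
        "gdp_pc": zscore(gdp_pc),
        "unemployment": zscore(unemployment),
        "log_population": zscore(np.log(population)),
    }
    idi = sum(bp.beta.get(k, 0.0) * design[k] for k in design)
    idi = idi + rng.normal(0.0, bp.noise_sd, size=n)

    panel = pd.DataFrame(
        {
            "city_id": [f"city{i:03d}" for i in range(n)],
            "region": regions,
            "population": population,
            "gini": gini,
            "gdp_pc": gdp_pc,
            "unemployment": unemployment,
            "poverty_rate": poverty,
            "sei": sei,
            "idi": idi,
        }
    )
    truth = dict(bp.beta)
    truth["noise_sd"] = bp.noise_sd
    return panel, truth


def simulate_study(
    n_cities: int = 20,
    seed: int = 0,
    n_tracts: int = 60,
    households_per_tract: int = 150,
    mean_Dpop: float = 0.27,
) -> tuple[list[TractTable], pd.DataFrame, pd.DataFrame]:
    """Full synthetic study: tract tables, covariate table, ground truth.

    Per-city seeds derive deterministically from the global seed as
    ``seed + city index``, so any city can be regenerated in isolation.
    Gini and poverty rate are computed from the very incomes that fill the
    tract tables, keeping covariates and segregation internally consistent.
    """
    rng = np.random.default_rng(seed)
    tables: list[TractTable] = []
    cov_rows = []
    truth_rows = []
    for i in range(n_cities):
        region = REGIONS[i % len(REGIONS)]
        target = float(
            np.clip(
                mean_Dpop + REGION_DPOP_SHIFT[region] + rng.normal(0.0, 0.04),
                0.05, 0.6,
            )
        )
        bp = CityBlueprint(
            city_id=f"city{i:03d}",
            region=region,
            n_tracts=n_tracts,
            households_per_tract=households_per_tract,
            income_sigma=INCOME_SIGMA + REGION_SIGMA_SHIFT[region]
            + float(rng.normal(0.0, 0.05)),
            income_mu=INCOME_MU + float(rng.normal(0.0, 0.15)),
            target_Dpop=target,
            seed=seed + i,
        )
        table, incomes, true_dpop = generate_city(bp)
        tables.append(table)
        population = len(incomes) * 3.0  # ~3 persons per household
        quality = float(rng.normal(0.0, 1.0))
        education = float(np.clip(0.5 + 0.08 * quality + rng.normal(0, 0.05), 0.05, 0.99))
        water = float(np.clip(0.85 + 0.05 * quality + rng.normal(0, 0.04), 0.2, 1.0))
        sanitation = float(np.clip(0.6 + 0.1 * quality + rng.normal(0, 0.06), 0.05, 1.0))
        overcrowding = float(np.clip(0.25 - 0.06 * quality + rng.normal(0, 0.04), 0.01, 0.9))
        cov_rows.append(
            {
                "city_id": bp.city_id,
                "region": region,
                "population": population,
                "gini": compute_gini(incomes),
                "gdp_pc": float(np.exp(rng.normal(math.log(16.0), 0.4))),
                "unemployment": float(np.clip(rng.normal(0.085, 0.025), 0.01, 0.30)),
                "poverty_rate": float(np.mean(incomes < bp.poverty_line)),
                "education": education,
                "water": water,
                "sanitation": sanitation,
                "overcrowding": overcrowding,
            }
        )
        truth_rows.append(
            {"city_id": bp.city_id, "true_Dpop": true_dpop,
             "minority_share": float(np.mean(incomes <= bp.calibration_cutoff))}
        )
    covariates = pd.DataFrame(cov_rows)
    covariates["sei"] = compute_sei(
        covariates["education"], covariates["water"],
        covariates["sanitation"], covariates["overcrowding"],
    )
    return tables, covariates, pd.DataFrame(truth_rows)
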