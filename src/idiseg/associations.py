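"""City-level association models between segregation and socioeconomic context.

A city panel carries, per city, the income dissimilarity index (IDI) and the
2010-style covariates: Gini index, GDP per capita, unemployment, poverty
rate, and a Social Environment Index (SEI, an equal-weight z-score composite
of education, water access, sanitation and reverse-coded overcrowding).

Three OLS specifications relate the z-scored IDI to z-scored covariates:

* model 1 — IDI ~ Gini
* model 2 — IDI ~ poverty rate  (``model2_text`` swaps in SEI, the variable
  the running text names for the second model)
* model 3 — IDI ~ Gini + poverty + SEI + GDP pc + unemployment + log(pop)

Heteroscedasticity (Breusch–Pagan/Cook–Weisberg, White) and serial
correlation (Durbin–Watson over the stored row order; panels have no time
axis, so DW is reported as an order-sensitive descriptive) diagnostics come
with every fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan, het_white
from statsmodels.stats.stattools import durbin_watson

from .core import SegregationError

#: Covariate set of the full model, in reporting order.
MODEL3_TERMS = ("gini", "poverty_rate", "sei", "gdp_pc", "unemployment", "log_population")

MODEL_SPECS: dict[str, tuple[str, ...]] = {
    "1": ("gini",),
    "2": ("poverty_rate",),
    "model2_text": ("sei",),
    "3": MODEL3_TERMS,
}

PANEL_COLUMNS = (
    "city_id", "region", "population", "gini", "gdp_pc", "unemployment",
    "poverty_rate", "sei", "idi",
)


class Diagnostics(NamedTuple):
    bp_stat: float
    bp_p: float
    white_stat: float
    white_p: float
    dw: float


@dataclass
class RegressionResult:
    """One fitted model: coefficients, t-based 95% CIs, fit and diagnostics."""

    model_id: str
    outcome: str
    terms: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n: int
    r2: float
    diag: Diagnostics

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": self.model_id,
                "term": t,
                "coef": self.coef[t],
                "se": self.se[t],
                "ci_low": self.ci_low[t],
                "ci_high": self.ci_high[t],
            }
            for t in ("const", *self.terms)
        ]
        return pd.DataFrame(rows)

    def format_table(self) -> str:
        lines = [f"Model {self.model_id}: {self.outcome} (n={self.n}, R2={self.r2:.3f})"]
        for t in self.terms:
            lines.append(
                f"  {t:<16} {self.coef[t]:6.2f} ({self.se[t]:.2f}) "
                f"[{self.ci_low[t]:.2f}, {self.ci_high[t]:.2f}]"
            )
        lines.append(
            f"  BP={self.diag.bp_stat:.2f} (p={self.diag.bp_p:.3f})  "
            f"White={self.diag.white_stat:.2f} (p={self.diag.white_p:.3f})  "
            f"DW={self.diag.dw:.2f}"
        )
        return "\n".join(lines)


def compute_gini(household_incomes: np.ndarray) -> float:
    """Gini index as the normalized mean absolute income difference.

    ``G = sum_ij |x_i - x_j| / (2 n^2 mu)``, evaluated through the sorted
    cumulative form (exactly equivalent, O(n log n)).
    """
    x = np.sort(np.asarray(household_incomes, dtype=float))
    n = x.size
    if n < 2:
        raise SegregationError("need at least 2 incomes")
    if (x < 0).any():
        raise SegregationError("negative incomes")
    total = x.sum()
    if total <= 0:
        raise SegregationError("all incomes zero; Gini undefined")
    i = np.arange(1, n + 1)
    return float((2.0 * (i * x).sum()) / (n * total) - (n + 1.0) / n)


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise SegregationError("need at least 2 values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise SegregationError("zero standard deviation; cannot z-score")
    return (x - x.mean()) / sd


def compute_sei(
    education: np.ndarray,
    water: np.ndarray,
    sanitation: np.ndarray,
    overcrowding: np.ndarray,
) -> np.ndarray:
    """Social Environment Index over a city panel.

    Overcrowding is reverse coded so that higher is better on every
    component; each component is z-scored over the panel and the four are
    averaged with equal weight.
    """
    components = {
        "education": np.asarray(education, dtype=float),
        "water": np.asarray(water, dtype=float),
        "sanitation": np.asarray(sanitation, dtype=float),
        "overcrowding": -np.asarray(overcrowding, dtype=float),
    }
    zs = []
    for name, vec in components.items():
        if vec.std(ddof=1) == 0:
            raise SegregationError(f"component {name!r} has zero variance")
        zs.append(zscore(vec))
    return np.mean(zs, axis=0)


def _design_matrix(panel: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for term in terms:
        if term == "log_population":
            cols[term] = zscore(np.log(panel["population"].to_numpy(dtype=float)))
        else:
            if term not in panel.columns:
                raise SegregationError(f"term {term!r} not in panel")
            cols[term] = zscore(panel[term].to_numpy(dtype=float))
    return pd.DataFrame(cols, index=panel.index)


def fit_model(
    panel: pd.DataFrame,
    spec: int | str | Sequence[str] = 3,
    outcome: str = "idi",
    standardize_outcome: bool = True,
) -> RegressionResult:
    """OLS of the (z-scored) IDI on z-scored covariates, with diagnostics.

    ``spec`` is one of the named models (1, 2, "model2_text", 3) or an
    explicit term list.  Population always enters as the natural log before
    z-scoring.  Cities with any missing value among the used columns are
    dropped listwise.  ``standardize_outcome=False`` leaves the outcome on
    its stored scale, which keeps the coefficients on the scale a synthetic
    generator used and is what parameter-recovery checks need.
    """
    if isinstance(spec, (int,)) or isinstance(spec, str) and spec in MODEL_SPECS:
        model_id = str(spec)
        terms = MODEL_SPECS[model_id]
    else:
        terms = tuple(spec)
        model_id = "custom"

    used_cols = [outcome] + [
        "population" if t == "log_population" else t for t in terms
    ]
    sub = panel.dropna(subset=[c for c in used_cols if c in panel.columns])
    n_dropped = len(panel) - len(sub)
    if n_dropped:
        import logging
        logging.getLogger(__name__).warning(
            "listwise deletion dropped %d cities with missing covariates", n_dropped
        )
    if len(sub) <= len(terms) + 1:
        raise SegregationError("too few cities for the requested model")

    X = _design_matrix(sub, terms)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = _find_collinear(X)
        raise SegregationError(f"rank-deficient design; collinear terms: {collinear}")
    y = sub[outcome].to_numpy(dtype=float)
    if standardize_outcome:
        y = zscore(y)
    Xc = sm.add_constant(X.to_numpy())
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    names = ["const", *terms]
    diag = diagnostics(fit.resid, Xc)
    return RegressionResult(
        model_id=model_id,
        outcome=outcome,
        terms=terms,
        coef=dict(zip(names, fit.params)),
        se=dict(zip(names, fit.bse)),
        ci_low=dict(zip(names, ci[:, 0])),
        ci_high=dict(zip(names, ci[:, 1])),
        n=int(fit.nobs),
        r2=float(fit.rsquared),
        diag=diag,
    )


def _find_collinear(X: pd.DataFrame) -> list[str]:
    bad = []
    arr = X.to_numpy()
    for i, name in enumerate(X.columns):
        others = np.delete(arr, i, axis=1)
        if others.shape[1] == 0:
            continue
        resid = arr[:, i] - others @ np.linalg.lstsq(others, arr[:, i], rcond=None)[0]
        if np.allclose(resid, 0, atol=1e-8):
            bad.append(name)
    return bad or list(X.columns)


def diagnostics(residuals: np.ndarray, design: np.ndarray) -> Diagnostics:
    """Breusch–Pagan, White and Durbin–Watson statistics for a fitted model.

    ``design`` must include the constant column.  BP is the LM form
    (n·R² of squared residuals on the design); White adds squares and
    cross-products; DW runs over the given residual order.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise SegregationError("need at least 3 residuals for diagnostics")
    X = np.asarray(design, dtype=float)
    if np.ptp(e**2) == 0:
        # squared residuals constant: no heteroscedasticity signal exists
        bp_stat = white_stat = 0.0
        bp_p = white_p = 1.0
    else:
        bp_stat, bp_p, _, _ = het_breuschpagan(e, X)
        white_stat, white_p, _, _ = het_white(e, X)
    return Diagnostics(
        bp_stat=float(bp_stat), bp_p=float(bp_p),
        white_stat=float(white_stat), white_p=float(white_p),
        dw=float(durbin_watson(e)),
    )


def quartile_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of each indicator by city-population quartile.

    Cities are sorted by population with ties broken by ``city_id`` (stable),
    then split into four groups as equal as possible (152 -> 38/38/38/38).
    Groups of one city get SD reported as NaN with ``degenerate`` flagged.
    """
    if len(panel) < 4:
        raise SegregationError("need at least 4 cities for quartiles")
    ordered = panel.sort_values(
        ["population", "city_id"], kind="stable"
    ).reset_index(drop=True)
    groups = np.array_split(np.arange(len(ordered)), 4)
    variables = ["idi", "gini", "gdp_pc", "unemployment", "poverty_rate", "sei"]
    rows = []
    for qi, idx in enumerate(groups, start=1):
        sub = ordered.iloc[idx]
        row: dict[str, object] = {"quartile": f"Q{qi}", "n": len(sub),
                                  "degenerate": len(sub) < 2}
        for var in variables:
            vals = sub[var].to_numpy(dtype=float)
            row[f"{var}_mean"] = vals.mean()
            row[f"{var}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("quartile")


def rank_cities(panel: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k most segregated cities, ties broken by Gini then city id."""
    if k > len(panel):
        raise SegregationError("k exceeds panel size")
    ordered = panel.sort_values(
        ["idi", "gini", "city_id"],
        ascending=[False, False, True],
        kind="stable",
    )
    cols = [c for c in ("city_id", "region", "state", "idi", "population", "gini")
            if c in panel.columns]
    return ordered.head(k)[cols].reset_index(drop=True)


def correlation_matrix(panel: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among IDI and the socioeconomic indicators."""
    if len(panel) < 3:
        raise SegregationError("need at least 3 cities")
    data = pd.DataFrame(
        {
            "idi": panel["idi"].to_numpy(dtype=float),
            "gini": panel["gini"].to_numpy(dtype=float),
            "poverty_rate": panel["poverty_rate"].to_numpy(dtype=float),
            "unemployment": panel["unemployment"].to_numpy(dtype=float),
            "gdp_pc": panel["gdp_pc"].to_numpy(dtype=float),
            "sei": panel["sei"].to_numpy(dtype=float),
            "log_population": np.log(panel["population"].to_numpy(dtype=float)),
        }
    )
    for col in data.columns:
        if data[col].std(ddof=1) == 0:
            raise SegregationError(f"column {col!r} has zero variance")
    return data.corr(method="pearson")
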