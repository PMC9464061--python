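"""End-to-end study pipeline with a reproducible file contract.

Stage order follows the study design: cut-off scan over the candidate
minimum-wage thresholds, selection of the working cut-off by the
minority-share rule, per-city index plus bootstrap bias at that cut-off,
panel assembly with the socioeconomic covariates, the three association
models (fitted on both the raw and the bias-corrected index, reported side
by side), and the descriptive outputs (population-quartile summary, top-k
ranking, correlation matrix).

Every numeric output is a text table stamped with the run's config hash;
rerunning the same config and seed reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import associations, bias, cutoff, io, synthetic
from .core import SegregationError, TractTable, city_dissimilarity

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending cities."""

    def __init__(self, stage: str, detail: str, city_ids: Sequence[str] = ()):
        self.stage = stage
        self.city_ids = tuple(city_ids)
        suffix = f" (cities: {', '.join(city_ids)})" if city_ids else ""
        super().__init__(f"stage {stage!r} failed: {detail}{suffix}")


@dataclass
class RunConfig:
    """Validated, serializable configuration of one pipeline run."""

    out_dir: str
    tracts_path: str | None = None
    covariates_path: str | None = None
    simulate: dict[str, Any] | None = None  # passed to synthetic.simulate_study
    cutoffs: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0)
    comparison_mode: str = "complement"
    B: int = 1000
    seed: int = 0
    select_lower: float = cutoff.DEFAULT_LOWER
    select_upper: float = cutoff.DEFAULT_UPPER
    models: tuple[str, ...] = ("1", "2", "3")
    rank_k: int = 10

    def __post_init__(self) -> None:
        self.cutoffs = tuple(float(c) for c in self.cutoffs)
        self.models = tuple(str(m) for m in self.models)
        if self.tracts_path is None and self.simulate is None:
            raise SegregationError("config needs tracts_path or a simulate block")
        if self.comparison_mode not in ("complement", "total"):
            raise SegregationError("comparison_mode must be complement or total")
        if self.B < 2:
            raise SegregationError("B must be >= 2")
        if not (0.0 < self.select_lower < self.select_upper <= 1.0):
            raise SegregationError("invalid selection bounds")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    @property
    def config_hash(self) -> str:
        # The hash covers the scientific configuration, not where the run is
        # written: identical analyses in different directories share a hash.
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_panel(
    tables: Sequence[TractTable],
    covariates: pd.DataFrame,
    cutoff_mw: float,
    comparison: str = "complement",
    B: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-city IDI + bias at one cut-off, merged with the covariate table.

    Returns ``(panel, segregation)``: the regression-ready panel and the
    per-city segregation/bias report.
    """
    seg_rows = []
    for idx, table in enumerate(tables):
        city_seed = int(
            np.random.SeedSequence([int(seed), 997, idx]).generate_state(1)[0]
            % (2**31)
        )
        res = city_dissimilarity(table, cutoff_mw, comparison)
        est = bias.bootstrap_bias(
            table, cutoff_mw, B=B, seed=city_seed, comparison=comparison
        )
        seg_rows.append(
            {
                "city_id": res.city_id,
                "cutoff": res.cutoff,
                "comparison_mode": res.comparison_mode,
                "n_tracts": res.n_tracts,
                "minority_share": res.minority_share,
                "D": res.D,
                "bias_hat": est.bias_hat,
                "bias_pct": est.bias_pct,
                "D_corrected": est.D_corrected,
                "se_boot": est.se_boot,
                "B": est.B,
                "seed": est.seed,
            }
        )
    segregation = pd.DataFrame(seg_rows)
    panel = covariates.merge(
        segregation[["city_id", "D", "D_corrected", "minority_share"]],
        on="city_id", how="inner", validate="one_to_one",
    )
    panel = panel.rename(columns={"D": "idi", "D_corrected": "idi_corrected"})
    return panel, segregation


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full study and write all artifacts under ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``).  Any stage
    failure raises ``PipelineError`` naming the stage; partial outputs are
    marked incomplete in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    stamp = f"config_hash={h}"
    manifest: dict[str, Any] = {
        "config_hash": h, "stages": [], "complete": False, "dropped": [],
    }
    with open(out / "config_echo.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    def stage_done(name: str, **info: Any) -> None:
        manifest["stages"].append({"stage": name, **info})
        logger.info("stage %s done %s", name, info or "")

    def write_manifest() -> None:
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    # --- inputs ---------------------------------------------------------
    try:
        if config.simulate is not None:
            sim_args = dict(config.simulate)
            sim_args.setdefault("seed", config.seed)
            tables, covariates, truth = synthetic.simulate_study(**sim_args)
            inputs = out / "inputs"
            io.write_tract_tables(tables, inputs / "tracts.csv", stamp)
            io.write_table(covariates, inputs / "covariates.csv", stamp)
            io.write_table(truth, inputs / "ground_truth.csv", stamp)
        else:
            tables = io.read_tract_tables(config.tracts_path)
            covariates = (
                io.read_panel(config.covariates_path)
                if config.covariates_path else None
            )
        dropped = [
            {"city_id": t.city_id, "n_dropped": int((t.totals == 0).sum()),
             "reason": "zero-household tracts"}
            for t in tables if (t.totals == 0).any()
        ]
        manifest["dropped"].extend(dropped)
        tables = [t.drop_empty_tracts() for t in tables]
    except SegregationError as err:
        write_manifest()
        raise PipelineError("inputs", str(err)) from err
    stage_done("inputs", n_cities=len(tables))

    # --- cut-off scan and selection ------------------------------------
    try:
        scan = cutoff.scan_cutoffs(
            tables, config.cutoffs, B=config.B, seed=config.seed,
            comparison=config.comparison_mode,
            lower_bound=config.select_lower, upper_bound=config.select_upper,
        )
    except SegregationError as err:
        write_manifest()
        raise PipelineError("cutoff_scan", str(err)) from err
    io.write_table(scan.summary, out / "cutoff_scan.csv", stamp)
    io.write_table(scan.per_city, out / "cutoff_scan_per_city.csv", stamp)
    if len(scan.excluded):
        io.write_table(scan.excluded, out / "cutoff_exclusions.csv", stamp)
    manifest["selected_cutoff"] = scan.selected_cutoff
    stage_done("cutoff_scan", selected=scan.selected_cutoff)
    if scan.selected_cutoff is None:
        manifest["complete"] = False
        manifest["stopped"] = "no cutoff selected"
        write_manifest()
        logger.warning("pipeline stopped: no cut-off selected")
        return manifest

    # --- segregation + panel -------------------------------------------
    if covariates is None:
        manifest["complete"] = False
        manifest["stopped"] = "no covariate table; association stage skipped"
        write_manifest()
        return manifest
    try:
        panel, segregation = build_panel(
            tables, covariates, scan.selected_cutoff,
            comparison=config.comparison_mode, B=config.B, seed=config.seed,
        )
    except SegregationError as err:
        write_manifest()
        raise PipelineError("panel", str(err)) from err
    io.write_table(segregation, out / "segregation.csv", stamp)
    io.write_table(panel, out / "panel.csv", stamp)
    stage_done("panel", n_cities=len(panel))

    # --- association models, raw and bias-corrected IDI -----------------
    reg_frames = []
    text_blocks = []
    for outcome, label in (("idi", "raw"), ("idi_corrected", "corrected")):
        for model_id in config.models:
            try:
                res = associations.fit_model(panel, model_id, outcome=outcome)
            except SegregationError as err:
                write_manifest()
                raise PipelineError("regression", str(err)) from err
            frame = res.to_frame()
            frame.insert(0, "idi_version", label)
            frame["n"] = res.n
            frame["r2"] = res.r2
            frame["bp_stat"] = res.diag.bp_stat
            frame["bp_p"] = res.diag.bp_p
            frame["white_stat"] = res.diag.white_stat
            frame["white_p"] = res.diag.white_p
            frame["dw"] = res.diag.dw
            reg_frames.append(frame)
            if label == "raw":
                text_blocks.append(res.format_table())
    regressions = pd.concat(reg_frames, ignore_index=True)
    io.write_table(regressions, out / "regressions.csv", stamp)
    # Side-by-side raw vs corrected coefficients.
    side = regressions.pivot_table(
        index=["model", "term"], columns="idi_version", values="coef"
    ).reset_index()
    io.write_table(side, out / "regressions_raw_vs_corrected.csv", stamp)
    (out / "regressions.txt").write_text(
        f"# {stamp}\n" + "\n\n".join(text_blocks) + "\n", encoding="utf-8"
    )
    stage_done("regression", n_models=len(config.models))

    # --- descriptives ----------------------------------------------------
    try:
        io.write_table(
            associations.quartile_summary(panel), out / "quartile_summary.csv",
            stamp, index=True,
        )
        io.write_table(
            associations.rank_cities(panel, min(config.rank_k, len(panel))),
            out / "ranking.csv", stamp,
        )
        io.write_table(
            associations.correlation_matrix(panel), out / "correlations.csv",
            stamp, index=True,
        )
    except SegregationError as err:
        write_manifest()
        raise PipelineError("descriptives", str(err)) from err
    stage_done("descriptives")

    manifest["complete"] = True
    write_manifest()
    return manifest
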