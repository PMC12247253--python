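"""End-to-end analysis pipeline: clean -> kinship -> stats -> scans -> intervals.

:func:`run_full_analysis` wires the modules into the full workflow and
writes every result as CSV/JSON into an output directory, together with a
run log that echoes the configuration, its hash, and the cleaning report.
Two runs with the same config hash and inputs produce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .errors import ColonykinError, UndefinedStatisticError
from .ibd_stats import bin_and_anova, fit_binomial_glm, pearson
from .intervals import compute_intervals, interval_relatedness_association, intervals_to_frame
from .pedigree import attach_relatedness, build_pedigree, read_studbook
from .records_io import (
    clean_records,
    pairs_to_frame,
    read_records,
    records_to_frame,
    summarize_pairs,
)
from .trend_scan import DEFAULT_PHASE_BOUNDARIES, cumulative_scan


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    records_path: str
    out_dir: str
    registry_path: Optional[str] = None  # studbook with individual parentage
    schema: Optional[dict] = None
    date_format: str = "iso"
    pair_level_cleaning: bool = False
    max_generations: int = 5
    min_litters_glm: int = 1
    min_litters_bins: int = 3
    min_pairs: int = 10
    start_year: int = 1963
    end_year: int = 2024
    phase_boundaries: tuple[int, ...] = DEFAULT_PHASE_BOUNDARIES
    scan_outcomes: tuple[str, ...] = (
        "loss_by_mice",
        "loss_by_litter",
        "born",
        "weaned",
        "male_loss",
        "female_loss",
        "delivery_interval",
    )
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _glm_row(name, fit):
    return {
        "model": name,
        "beta0": fit.beta0,
        "beta1": fit.beta1,
        "mcfadden_r2": fit.mcfadden_r2,
        "lrt_stat": fit.lrt_stat,
        "lrt_p": fit.lrt_p,
        "n_obs": fit.n_obs,
        "total_weight": fit.total_weight,
        "converged": fit.converged,
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Returns a dict of the in-memory results.  Any stage failure raises a
    :class:`ColonykinError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config.config_hash()}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ColonykinError as exc:
                raise ColonykinError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # QC ---------------------------------------------------------------
    records = stage("read")(
        read_records, config.records_path, schema=config.schema,
        date_format=config.date_format,
    )
    cleaned, report = stage("clean")(
        clean_records, records, pair_level=config.pair_level_cleaning
    )
    results["cleaning_report"] = report
    records_to_frame(cleaned).to_csv(out / "litters_clean.csv", index=False)
    report.to_json(out / "cleaning_report.json")

    # Pedigree / kinship -----------------------------------------------
    registry = None
    if config.registry_path:
        registry = read_studbook(config.registry_path)[0].parents
    ped = stage("pedigree")(build_pedigree, cleaned, registry)
    pairs = stage("pairs")(summarize_pairs, cleaned, config.min_litters_glm)
    stage("kinship")(attach_relatedness, pairs, ped, config.max_generations)
    relatedness = {
        p.mating_id: p.relatedness_pct for p in pairs if p.relatedness_pct is not None
    }
    pairs_to_frame(pairs).to_csv(out / "pairs.csv", index=False)
    results["pairs"] = pairs

    # Pooled statistics -------------------------------------------------
    usable = [p for p in pairs if p.relatedness_pct is not None and p.total_born > 0]
    glm_rows, corr_rows = [], []
    if usable:
        x = [p.relatedness_pct for p in usable]
        for name, s_fn, t_fn in (
            ("loss_by_mice", lambda p: p.total_dead, lambda p: p.total_born),
            ("loss_by_litter", lambda p: p.n_litters_with_loss, lambda p: p.n_litters),
        ):
            try:
                fit = fit_binomial_glm(
                    x, [s_fn(p) for p in usable], [t_fn(p) for p in usable]
                )
                glm_rows.append(_glm_row(name, fit))
                results[f"glm_{name}"] = fit
            except ColonykinError:
                pass
            try:
                ratios = [s_fn(p) / t_fn(p) for p in usable]
                c = pearson(x, ratios)
                corr_rows.append({"model": name, "r": c.r, "p": c.p, "n": c.n})
                results[f"pearson_{name}"] = c
            except UndefinedStatisticError:
                pass
    pd.DataFrame(glm_rows).to_csv(out / "glm_fits.csv", index=False)
    pd.DataFrame(corr_rows).to_csv(out / "pearson.csv", index=False)

    # Binned ANOVA (pairs with enough litters for stable averages) ------
    bin_pairs = [p for p in pairs if p.n_litters >= config.min_litters_bins]
    for metric in ("by_mice", "by_litter"):
        try:
            comp = bin_and_anova(bin_pairs, metric=metric)
        except UndefinedStatisticError:
            continue
        results[f"anova_{metric}"] = comp
        pd.DataFrame(
            {
                "bin": comp.labels,
                "n": comp.n,
                "mean": comp.mean,
                "se": comp.se,
                "anova_f": comp.anova_f,
                "anova_p": comp.anova_p,
            }
        ).to_csv(out / f"bins_{metric}.csv", index=False)

    # Cumulative scans ---------------------------------------------------
    scan_frames = []
    for outcome in config.scan_outcomes:
        series = stage("scan")(
            cumulative_scan,
            cleaned,
            relatedness,
            outcome=outcome,
            start_year=config.start_year,
            end_year=config.end_year,
            min_pairs=config.min_pairs,
            boundaries=config.phase_boundaries,
        )
        results[f"scan_{outcome}"] = series
        scan_frames.append(series.to_frame())
    if scan_frames:
        pd.concat(scan_frames, ignore_index=True).to_csv(
            out / "trend_scan.csv", index=False
        )

    # Intervals ----------------------------------------------------------
    interval_records, interval_report = stage("intervals")(
        compute_intervals, cleaned, relatedness
    )
    intervals_to_frame(interval_records).to_csv(out / "intervals.csv", index=False)
    results["intervals"] = interval_records
    for mode in ("first", "delivery"):
        try:
            results[f"interval_corr_{mode}"] = interval_relatedness_association(
                interval_records, mode=mode, scope="pooled"
            )
        except UndefinedStatisticError:
            pass

    # Run log ------------------------------------------------------------
    log = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": results["config_hash"],
        "cleaning_report": dataclasses.asdict(report),
        "interval_report": interval_report,
        "n_pairs_analyzed": len(usable),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return results
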