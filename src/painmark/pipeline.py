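"""End-to-end study orchestration: measures -> time courses -> interpolation
-> correlations -> significance -> embeddings -> engram analysis.

``run_pipeline`` reads a series manifest and a JSON config, executes both
analysis parts (the per-measure correlation analysis and the unsupervised
comparative analysis) plus the engram analysis, writes CSV/JSON outputs and
returns a :class:`StudyReport`.  Every source of randomness cascades from
the configured seed, so a rerun with the same seed reproduces the report
payload byte for byte (timestamps excluded by construction: none are stored).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .embedding import (
    SignalMatrix,
    mce_embed,
    pca_embed,
    quantile_normalize_rows,
    sign_align,
    signal_matrix_from_signals,
    zscore_rows,
)
from .engram import RegionLinkCounts, RetainedLinks, engram_timecourse
from .graph_core import ConnectomeSeries, read_series
from .timeseries_stats import (
    MeasureTimeCourse,
    StudyConfig,
    compute_time_course,
    hourly_grid,
    interpolate_time_course,
    pchip_interpolate,
    summary_table,
)
from .topo_measures import MeasureConfig, NullEnsembleConfig, STOCHASTIC_MEASURES

logger = logging.getLogger("painmark")

BEHAVIORAL_LABEL = "VonFrey"

_CONFIG_KEYS = {
    "measures", "M", "alpha", "pl_accept_threshold", "null_models",
    "corr_types", "stochastic_subsample", "seed",
    "n_realizations", "swap_multiplier", "n_bootstrap",
    "perturb_fraction", "sc_repeats", "mce_skip_first",
}


@dataclass(frozen=True)
class StudyReport:
    """Aggregated outputs of one pipeline run."""

    summary: pd.DataFrame
    time_courses: dict[str, MeasureTimeCourse]
    pca_coords: pd.DataFrame
    mce_coords: pd.DataFrame
    region_counts: RegionLinkCounts
    retained: list[RetainedLinks]
    provenance: dict

    def payload(self) -> dict:
        """JSON-serializable report body (used for the determinism contract)."""
        return {
            "summary": self.summary.to_dict(orient="records"),
            "pca": {k: list(map(float, v)) for k, v in self.pca_coords.T.items()},
            "mce": {k: list(map(float, v)) for k, v in self.mce_coords.T.items()},
            "region_counts": {
                "step_hours": list(self.region_counts.step_hours),
                "intra_" + self.region_counts.region_names[0]: list(self.region_counts.intra_first),
                "intra_" + self.region_counts.region_names[1]: list(self.region_counts.intra_second),
                "inter": list(self.region_counts.inter),
            },
            "retained": [
                {
                    "interval": r.interval,
                    "full": r.count_full,
                    "intra_" + r.region_names[0]: r.count_intra_first,
                    "intra_" + r.region_names[1]: r.count_intra_second,
                    "inter": r.count_inter,
                }
                for r in self.retained
            ],
            "provenance": self.provenance,
        }


def validate_config(config: str | Path | dict | None) -> tuple[StudyConfig, dict]:
    """Normalize a JSON config into a :class:`StudyConfig` (defaults filled).

    Unknown keys are rejected; ranges validated.  Returns the normalized
    config plus a dict of extra pipeline options (currently only
    ``mce_skip_first``).
    """
    if config is None:
        raw: dict = {}
    elif isinstance(config, dict):
        raw = dict(config)
    else:
        raw = json.loads(Path(config).read_text())
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    extras = {"mce_skip_first": bool(raw.pop("mce_skip_first", False))}
    null = NullEnsembleConfig(
        n_realizations=int(raw.pop("n_realizations", 10)),
        swap_multiplier=int(raw.pop("swap_multiplier", 10)),
        seed=int(raw.get("seed", 0)),
    )
    measure = MeasureConfig(
        null=null,
        n_bootstrap=int(raw.pop("n_bootstrap", 1000)),
        perturb_fraction=float(raw.pop("perturb_fraction", 0.1)),
        sc_repeats=int(raw.pop("sc_repeats", 10)),
        seed=int(raw.get("seed", 0)),
    )
    kwargs = {}
    for key in ("measures", "null_models", "corr_types"):
        if key in raw:
            kwargs[key] = tuple(raw.pop(key))
    for key in ("M", "seed"):
        if key in raw:
            kwargs[key] = int(raw.pop(key))
    for key in ("alpha", "pl_accept_threshold"):
        if key in raw:
            kwargs[key] = float(raw.pop(key))
    if "stochastic_subsample" in raw:
        v = raw.pop("stochastic_subsample")
        kwargs["stochastic_subsample"] = None if v is None else int(v)
    cfg = StudyConfig(measure=measure, **kwargs)
    return cfg, extras


def build_signal_matrix(
    series: ConnectomeSeries,
    time_courses: dict[str, MeasureTimeCourse],
) -> SignalMatrix:
    """Interpolate every time course and the behavioural signal onto one grid."""
    grid = hourly_grid(series.step_hours)
    signals = {
        name: interpolate_time_course(tc, grid).array
        for name, tc in time_courses.items()
    }
    signals[BEHAVIORAL_LABEL] = pchip_interpolate(
        series.step_hours, series.behavioral, grid
    ).array
    return signal_matrix_from_signals(signals)


def run_pipeline(
    manifest: str | Path | ConnectomeSeries,
    config: str | Path | dict | None = None,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Execute the full analysis on a series and optionally write its outputs."""
    cfg, extras = validate_config(config)
    series = manifest if isinstance(manifest, ConnectomeSeries) else read_series(manifest)

    # stage 1: measure time courses
    time_courses: dict[str, MeasureTimeCourse] = {}
    for name in cfg.measures:
        sub = cfg.stochastic_subsample if name in STOCHASTIC_MEASURES else None
        try:
            time_courses[name] = compute_time_course(
                series, name, cfg.measure, subsample=sub
            )
        except ValueError as exc:
            raise RuntimeError(f"[measure stage] {name}: {exc}") from exc

    # stage 2: correlation + significance
    try:
        summary = summary_table(series, cfg, time_courses=time_courses)
    except Exception as exc:
        raise RuntimeError(f"[correlation stage] {exc}") from exc

    # stage 3: unsupervised comparative analysis
    try:
        sm = build_signal_matrix(series, time_courses)
        aligned = sign_align(zscore_rows(sm), BEHAVIORAL_LABEL)
        pca_coords = pca_embed(aligned, dims=2)
        mce_coords = mce_embed(
            quantile_normalize_rows(aligned), dims=2,
            skip_first=extras["mce_skip_first"],
        )
    except Exception as exc:
        raise RuntimeError(f"[embedding stage] {exc}") from exc

    # stage 4: engram analysis
    try:
        region_counts, retained = engram_timecourse(series)
    except Exception as exc:
        raise RuntimeError(f"[engram stage] {exc}") from exc

    provenance = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "M": cfg.M,
        "alpha": cfg.alpha,
        "versions": {
            "painmark": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    report = StudyReport(
        summary=summary,
        time_courses=time_courses,
        pca_coords=pca_coords,
        mce_coords=mce_coords,
        region_counts=region_counts,
        retained=retained,
        provenance=provenance,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write summary/embedding/engram CSVs plus the JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary.to_csv(out / "summary.csv", index=False)
    report.pca_coords.to_csv(out / "pca.csv", index_label="signal")
    report.mce_coords.to_csv(out / "mce.csv", index_label="signal")
    rc = report.region_counts
    pd.DataFrame(
        {
            "hours": rc.step_hours,
            f"intra_{rc.region_names[0]}": rc.intra_first,
            f"intra_{rc.region_names[1]}": rc.intra_second,
            "inter": rc.inter,
        }
    ).to_csv(out / "engram_counts.csv", index=False)
    retained_rows = []
    for r in report.retained:
        retained_rows.append(
            {
                "interval": r.interval,
                "full": r.count_full,
                f"intra_{r.region_names[0]}": r.count_intra_first,
                f"intra_{r.region_names[1]}": r.count_intra_second,
                "inter": r.count_inter,
            }
        )
        fname = "retained_" + r.interval.replace(" ", "").replace("/", "_") + ".tsv"
        with open(out / fname, "w") as fh:
            for i, j in sorted(r.edges):
                fh.write(f"{i}\t{j}\n")
    pd.DataFrame(retained_rows).to_csv(out / "retained_counts.csv", index=False)
    (out / "report.json").write_text(json.dumps(report.payload(), indent=1))
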