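"""End-to-end orchestration: ingestion -> preprocessing -> inclusion ->
variance curves -> window measures -> channel averaging -> asymmetry ->
extreme-value screen -> group statistics and logistic tiers -> outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry import asymmetry_table
from .datatypes import (
    CHANNELS,
    CONDITIONS,
    DEFAULT_WINDOWS,
    ConfigError,
    EpochSet,
    InsufficientDataError,
)
from .io import profiles_to_frame, read_epochs, read_metadata
from .preprocess import preprocess_epochs, segment
from .rvc import (
    MEASURE_NAMES,
    average_channel_measures,
    check_discernible_peak,
    compute_rvc,
    extract_window_measures,
    flag_extreme_values,
)
from .stats import ConvergenceError, fit_mci_logistic, pearson_chi2, two_sample_t
from .synthetic import GeneratorConfig, default_config, generate_cohort

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = (
    "no_clean_trials",
    "below_half_clean",
    "no_discernible_peak",
    "extreme_variability",
    "incomplete_metadata",
)

META_CONTINUOUS = ["age", "education", "mmse",
                   "attention", "language", "visuospatial", "memory", "frontal"]


@dataclass
class RunConfig:
    mode: str = "synthetic"  # synthetic | fixture | edf
    generator: GeneratorConfig | None = None
    epoch_paths: list = field(default_factory=list)
    metadata_path: str | None = None
    artifact_threshold: float = 100.0
    smoothing_order: int = 9
    smooth: bool = True
    min_clean_fraction: float = 0.5
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    fence_k: float = 3.0
    peak_rule: bool = True
    t_variant: str = "welch"
    scaling: str = "z_scored"
    outdir: str = "out"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "fixture", "edf"):
            raise ConfigError(f"mode must be synthetic|fixture|edf, got {self.mode!r}")
        if self.artifact_threshold <= 0:
            raise ConfigError("artifact_threshold must be > 0")
        if self.smoothing_order % 2 == 0 or self.smoothing_order < 1:
            raise ConfigError("smoothing_order must be odd and >= 1")
        if not 0 < self.min_clean_fraction <= 1:
            raise ConfigError("min_clean_fraction must be in (0, 1]")
        if self.fence_k <= 0:
            raise ConfigError("fence_k must be > 0")
        if self.mode in ("fixture", "edf"):
            if not self.epoch_paths:
                raise ConfigError(f"mode {self.mode!r} requires epoch_paths")
            for p in list(self.epoch_paths) + (
                [self.metadata_path] if self.metadata_path else []
            ):
                if not Path(p).exists():
                    raise ConfigError(f"input path does not exist: {p}")

    def echo(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "generator"}
        d["epoch_paths"] = [str(p) for p in d["epoch_paths"]]
        d["windows"] = {k: list(v) for k, v in self.windows.items()}
        d["generator_seed"] = self.generator.seed if self.generator else None
        return d


@dataclass
class RunReport:
    n_total: int
    n_included: int
    exclusions: list  # [{"subject_id": ..., "reason": ...}]
    output_paths: dict
    config: dict
    version: str
    seed: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def measure_key(window: str, condition: str, measure: str) -> str:
    return f"{window}_{condition}_{measure}"


def compute_subject_measures(
    clean: EpochSet, windows: dict, peak_rule: bool = True
) -> tuple[list[dict], bool]:
    """Measure rows (per window x condition x channel, plus channel average)
    and whether every analyzed curve has a discernible peak."""
    rows: list[dict] = []
    peaks_ok = True
    for cond in CONDITIONS:
        curves = {chan: compute_rvc(clean, cond, chan) for chan in CHANNELS}
        for wname, wspan in windows.items():
            per_channel = {}
            for chan in CHANNELS:
                m = extract_window_measures(curves[chan], wspan)
                ok = check_discernible_peak(curves[chan], wspan)
                if peak_rule and not ok:
                    peaks_ok = False
                per_channel[chan] = m
                rows.append({
                    "subject_id": clean.subject_id, "window": wname,
                    "condition": cond, "channel": chan,
                    **m.as_dict(), "discernible_peak": ok,
                })
            avg = {
                name: average_channel_measures(
                    getattr(per_channel["Fp1"], name),
                    getattr(per_channel["Fp2"], name),
                )
                for name in MEASURE_NAMES
            }
            rows.append({
                "subject_id": clean.subject_id, "window": wname,
                "condition": cond, "channel": "avg", **avg,
                "discernible_peak": all(
                    r["discernible_peak"] for r in rows[-2:]
                ),
            })
    return rows, peaks_ok


def _load_cohort(config: RunConfig) -> tuple[pd.DataFrame, list[EpochSet]]:
    if config.mode == "synthetic":
        gen = config.generator or default_config()
        if gen.seed != config.seed:
            from dataclasses import replace
            gen = replace(gen, seed=config.seed)
        cohort = generate_cohort(gen)
        meta = profiles_to_frame([p for p, _ in cohort])
        return meta, [e for _, e in cohort]

    if config.metadata_path is None:
        raise ConfigError("fixture/edf modes require metadata_path")
    meta = read_metadata(config.metadata_path)

    epoch_sets: list[EpochSet] = []
    for path in config.epoch_paths:
        path = Path(path)
        if config.mode == "fixture":
            epoch_sets.append(read_epochs(path))
        else:
            from .edf import read_edf

            rec = read_edf(path)
            events, correct = [], []
            for onset_s, text in rec.annotations:
                label, _, flag = text.partition("/")
                events.append((onset_s * 1000.0, label))
                correct.append(flag != "incorrect")
            epochs = segment(
                rec.signals, events,
                sampling_rate=rec.sampling_rate,
                subject_id=path.stem, correct=correct,
            )
            epoch_sets.append(epochs)
    order = {sid: i for i, sid in enumerate(meta["subject_id"])}
    epoch_sets.sort(key=lambda e: order.get(e.subject_id, len(order)))
    return meta, epoch_sets


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    meta, epoch_sets = _load_cohort(config)
    log_lines: list[str] = []
    exclusions: list[dict] = []
    preprocess_reports: list[dict] = []
    all_rows: list[dict] = []
    status: dict[str, str] = {}  # subject_id -> "included" | reason

    known_ids = set(meta["subject_id"])
    for epochs in epoch_sets:
        sid = epochs.subject_id
        if sid not in known_ids or meta.set_index("subject_id").loc[sid].isna().any():
            status[sid] = "incomplete_metadata"
            log_lines.append(f"{sid}: excluded (incomplete_metadata)")
            continue
        clean, report = preprocess_epochs(
            epochs,
            threshold=config.artifact_threshold,
            smoothing_order=config.smoothing_order,
            smooth=config.smooth,
            min_clean_fraction=config.min_clean_fraction,
        )
        preprocess_reports.append(report.to_dict())
        if not report.included:
            status[sid] = report.exclusion_reason
            log_lines.append(f"{sid}: excluded ({report.exclusion_reason})")
            continue
        try:
            rows, peaks_ok = compute_subject_measures(
                clean, config.windows, peak_rule=config.peak_rule
            )
        except InsufficientDataError as e:
            status[sid] = "no_clean_trials"
            log_lines.append(f"{sid}: excluded (no_clean_trials: {e})")
            continue
        if config.peak_rule and not peaks_ok:
            status[sid] = "no_discernible_peak"
            log_lines.append(f"{sid}: excluded (no_discernible_peak)")
            continue
        all_rows.extend(rows)
        status[sid] = "included"
        log_lines.append(f"{sid}: included")

    measures = pd.DataFrame(
        all_rows,
        columns=["subject_id", "window", "condition", "channel",
                 *MEASURE_NAMES, "discernible_peak"],
    )

    # cohort-level extreme-variability screen on channel-averaged measures
    if len(measures):
        avg = measures[measures["channel"] == "avg"]
        wide = avg.pivot_table(
            index="subject_id", columns=["window", "condition"],
            values=list(MEASURE_NAMES), sort=True,
        )
        flagged: set[str] = set()
        for col in wide.columns:
            vals = wide[col]
            if np.isfinite(vals).sum() >= 4:
                mask = flag_extreme_values(vals.to_numpy(), k=config.fence_k)
                flagged.update(wide.index[mask])
            else:
                logger.warning("extreme screen skipped for %s: < 4 values", col)
        for sid in sorted(flagged):
            status[sid] = "extreme_variability"
            log_lines.append(f"{sid}: excluded (extreme_variability)")
        measures = measures[~measures["subject_id"].isin(flagged)]

    included_ids = sorted(s for s, r in status.items() if r == "included")
    exclusions = [
        {"subject_id": s, "reason": r}
        for s, r in sorted(status.items()) if r != "included"
    ]

    asym = asymmetry_table(measures) if len(measures) else pd.DataFrame(
        columns=["subject_id", "window", "condition"]
        + [f"{m}_asym" for m in MEASURE_NAMES]
    )
    stats = _cohort_statistics(meta, measures, asym, included_ids, config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        n_total=len(epoch_sets),
        n_included=len(included_ids),
        exclusions=exclusions,
        output_paths={},
        config=config.echo(),
        version=__version__,
        seed=config.seed,
    )
    report.output_paths = write_outputs(
        measures, asym, stats, report, preprocess_reports, log_lines, outdir
    )
    return report


def _measure_wide(
    measures: pd.DataFrame, asym: pd.DataFrame, meta: pd.DataFrame,
    included_ids: list[str],
) -> pd.DataFrame:
    """One row per included subject: metadata + flat measure columns."""
    avg = measures[measures["channel"] == "avg"]
    frames = {}
    for _, row in avg.iterrows():
        for m in MEASURE_NAMES:
            frames.setdefault(
                measure_key(row["window"], row["condition"], m), {}
            )[row["subject_id"]] = row[m]
    for _, row in asym.iterrows():
        for m in MEASURE_NAMES:
            frames.setdefault(
                measure_key(row["window"], row["condition"], f"{m}_asym"), {}
            )[row["subject_id"]] = row[f"{m}_asym"]
    wide = pd.DataFrame(frames)
    wide.index.name = "subject_id"
    merged = meta.set_index("subject_id").join(wide, how="inner")
    return merged.loc[[i for i in included_ids if i in merged.index]].reset_index()


def _cohort_statistics(
    meta: pd.DataFrame, measures: pd.DataFrame, asym: pd.DataFrame,
    included_ids: list[str], config: RunConfig,
) -> dict:
    wide = _measure_wide(measures, asym, meta, included_ids)
    out: dict = {"group_comparisons": [], "logistic_models": [], "notes": []}
    cn = wide[wide["group"] == "CN"]
    mci = wide[wide["group"] == "MCI"]
    if len(cn) < 2 or len(mci) < 2:
        out["notes"].append(
            f"group statistics skipped: CN n={len(cn)}, MCI n={len(mci)}"
        )
        return out

    # Table-1-style characterization
    for var in META_CONTINUOUS:
        res = two_sample_t(
            cn[var].dropna().to_numpy(), mci[var].dropna().to_numpy(),
            variant="auto", variable=var,
        )
        out["group_comparisons"].append(res.to_dict())
    counts = [
        [int((cn["sex"] == "F").sum()), int((mci["sex"] == "F").sum())],
        [int((cn["sex"] == "M").sum()), int((mci["sex"] == "M").sum())],
    ]
    try:
        out["group_comparisons"].append(pearson_chi2(counts, variable="sex").to_dict())
    except ValueError as e:
        out["notes"].append(f"sex chi-squared skipped: {e}")

    measure_cols = [c for c in wide.columns if c.split("_")[0] in config.windows]
    for col in measure_cols:
        a, b = cn[col].dropna().to_numpy(), mci[col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            out["notes"].append(f"group test skipped for {col}: too few values")
            continue
        res = two_sample_t(a, b, variant=config.t_variant, variable=col)
        out["group_comparisons"].append(res.to_dict())
        for tier in (1, 2, 3):
            try:
                fit = fit_mci_logistic(
                    wide, col, tier=tier, scaling=config.scaling
                )
                out["logistic_models"].append(fit.to_dict())
            except (ConvergenceError, ValueError) as e:
                out["notes"].append(f"logistic tier {tier} for {col} failed: {e}")
    return out


def write_outputs(
    measures: pd.DataFrame, asym: pd.DataFrame, stats: dict,
    report: RunReport, preprocess_reports: list[dict],
    log_lines: list[str], outdir: Path,
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measures": str(outdir / "measures.csv"),
        "asymmetry": str(outdir / "asymmetry.csv"),
        "stats": str(outdir / "stats.json"),
        "run_report": str(outdir / "run_report.json"),
        "log": str(outdir / "run.log"),
    }
    measures.to_csv(paths["measures"], index=False)
    asym.to_csv(paths["asymmetry"], index=False)
    with open(paths["stats"], "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    report.output_paths = paths
    doc = report.to_dict()
    doc["preprocess_reports"] = preprocess_reports
    with open(paths["run_report"], "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
    with open(paths["log"], "w") as fh:
        fh.write("\n".join(log_lines) + ("\n" if log_lines else ""))
    return paths
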