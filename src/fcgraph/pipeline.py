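"""End-to-end pipeline orchestration with config, logging, and manifests.

Stages run in a fixed order — simulate -> qc -> connect -> metrics ->
analyze -> segregate -> report — with each stage writing delimited-text
outputs into the run directory. A manifest (config hash + seed + package
version) accompanies every run; with ``resume=True`` a stage whose outputs
already exist under the same manifest hash is skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    fit_interaction_model,
    fit_segregation_model,
    participants_frame,
    screen_significant,
    standardize_across_participants,
    stratify_by_age,
    system_segregation,
    average_over_thresholds,
    DMN_LABELS,
)
from .cohort import Cohort, CohortSpec, generate_cohort, write_cohort
from .connectivity import (
    ConnectivityMatrix,
    correlation_matrix,
    make_sweep,
    threshold_absolute,
    threshold_proportional,
    validate_sweep_bounds,
    write_matrix,
    DEFAULT_ABSOLUTE_SWEEP,
    DEFAULT_PROPORTIONAL_SWEEP,
)
from .metrics import MetricConfig, compute_all, GLOBAL_METRICS, REGIONAL_METRICS
from .timeseries import (
    bandpass,
    censor,
    check_minimum_duration,
    dvars,
    framewise_displacement,
    nuisance_regress,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_report", "INVERTED_INSTRUMENTS"]

#: Instruments scored so that HIGHER values mean POORER functioning
#: (the BRIEF-2 parent-report scales); the report flips the displayed
#: direction of effect for these.
INVERTED_INSTRUMENTS = frozenset(
    {
        "BRIEF-2 Parent Inhibit",
        "BRIEF-2 Parent Shift",
        "BRIEF-2 Parent Working Memory",
    }
)

STAGES = ("simulate", "qc", "connect", "metrics", "analyze", "segregate", "report")


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    outdir: str = "fcgraph_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    schemes: tuple[str, ...] = ("weighted", "absolute", "proportional")
    absolute_sweep: tuple[float, float, float] = DEFAULT_ABSOLUTE_SWEEP
    proportional_sweep: tuple[float, float, float] = DEFAULT_PROPORTIONAL_SWEEP
    # QC
    low_hz: float = 0.009
    high_hz: float = 0.08
    filter_order: int = 4
    fd_thresh: float = 0.5
    dvars_thresh: float = 5.0
    dvars_normalization: str = "median_1000"
    minimum_seconds: float = 270.0
    # metrics
    n_null: int = 10
    rewire_factor: float = 10.0
    n_restarts: int = 10
    gamma: float = 1.0
    metrics: tuple[str, ...] | None = None
    # analysis
    tests: tuple[str, ...] | None = None
    alpha: float = 0.001
    min_coverage: float = 0.5
    age_strata: tuple[tuple[float, float], ...] | None = None
    fdr: bool = False
    # report
    inverted_tests: tuple[str, ...] = tuple(sorted(INVERTED_INSTRUMENTS))
    robust_rule: int = 3  # schemes required for a cross-method-robust call
    segregation_enabled: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.cohort)
        kwargs.setdefault("seed", self.seed)
        if "effect_regions" in kwargs:
            kwargs["effect_regions"] = tuple(kwargs["effect_regions"])
        return CohortSpec(**kwargs)

    def metric_config(self) -> MetricConfig:
        return MetricConfig(
            n_null=self.n_null,
            rewire_factor=self.rewire_factor,
            n_restarts=self.n_restarts,
            gamma=self.gamma,
            seed=self.seed,
            metrics=tuple(self.metrics) if self.metrics is not None else None,
        )


def _write_manifest(outdir: Path, config: RunConfig) -> None:
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "config": config.to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _stage_fresh(outdir: Path, config: RunConfig, outputs: list[str], resume: bool) -> bool:
    """True if the stage must run (outputs missing, stale, or resume off)."""
    if not resume:
        return True
    manifest = outdir / "manifest.json"
    if not manifest.exists():
        return True
    try:
        recorded = json.loads(manifest.read_text())["config_hash"]
    except (KeyError, json.JSONDecodeError):
        return True
    if recorded != config.config_hash():
        return True
    return not all((outdir / o).exists() for o in outputs)


def run_pipeline(
    config: RunConfig, resume: bool = False, until: str | None = None
) -> Path:
    """Run the stages in order; returns the output directory.

    ``until`` stops after the named stage (None runs everything). Any
    stage failure aborts with the stage name (and participant id where
    applicable) in the exception message.
    """
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    final_outputs = [
        "qc_table.tsv",
        "metrics.tsv",
        "regression_results.tsv",
        "significant_interactions.tsv",
        "report.md",
    ]
    if resume and until is None and not _stage_fresh(
        outdir, config, final_outputs, resume
    ):
        logger.info("resume: all outputs present under matching config hash")
        return outdir
    if not resume and (outdir / "manifest.json").exists():
        recorded = json.loads((outdir / "manifest.json").read_text()).get("config_hash")
        if recorded != config.config_hash():
            logger.info("config changed (hash mismatch): caches invalidated")
    _write_manifest(outdir, config)
    last = STAGES.index(until) if until else len(STAGES) - 1

    stage = "simulate"
    try:
        cohort = _stage_simulate(config, outdir, resume)
        if last >= STAGES.index("qc"):
            stage = "qc"
            cohort, _qc = _stage_qc(config, cohort, outdir, resume)
        if last >= STAGES.index("connect"):
            stage = "connect"
            matrices = _stage_connect(config, cohort, outdir, resume)
        if last >= STAGES.index("metrics"):
            stage = "metrics"
            metric_table = _stage_metrics(config, cohort, matrices, outdir, resume)
        if last >= STAGES.index("analyze"):
            stage = "analyze"
            _stage_analyze(config, cohort, metric_table, outdir)
        if last >= STAGES.index("segregate"):
            stage = "segregate"
            _stage_segregate(config, cohort, matrices, outdir)
        if last >= STAGES.index("report"):
            stage = "report"
            render_report(config, outdir)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return outdir


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(config: RunConfig, outdir: Path, resume: bool) -> Cohort:
    spec = config.cohort_spec()
    cohort = generate_cohort(spec)
    cohort_dir = outdir / "cohort"
    if _stage_fresh(cohort_dir, config, ["participants.tsv"], resume):
        write_cohort(cohort, cohort_dir)
        _write_manifest(cohort_dir, config)
    logger.info(
        "simulated cohort: %d CHD, %d control, %d regions, %d timepoints",
        spec.n_chd,
        spec.n_control,
        spec.n_regions,
        spec.n_timepoints,
    )
    return cohort


def _stage_qc(
    config: RunConfig, cohort: Cohort, outdir: Path, resume: bool
) -> tuple[Cohort, pd.DataFrame]:
    if not cohort.participants:
        raise ValueError("empty cohort at QC stage")
    rows = []
    kept = []
    for p in cohort.participants:
        try:
            # DVARS on the raw-intensity series: the median-1000 rescaling
            # (and the conventional threshold of 5) refer to raw BOLD units,
            # which bandpass filtering deliberately removes
            dv = dvars(p.timeseries, normalization=config.dvars_normalization)
            fd = framewise_displacement(p.motion)
            ts = bandpass(
                p.timeseries, config.low_hz, config.high_hz, order=config.filter_order
            )
            ts = nuisance_regress(ts, p.motion)
            ts, report = censor(
                ts,
                fd,
                dv,
                fd_thresh=config.fd_thresh,
                dvars_thresh=config.dvars_thresh,
                minimum_seconds=config.minimum_seconds,
            )
        except Exception as exc:
            raise RuntimeError(f"participant {p.participant_id}: {exc}") from exc
        passes = check_minimum_duration(report, config.minimum_seconds)
        rows.append(
            {
                "participant_id": p.participant_id,
                "n_censored": report.n_censored,
                "usable_seconds": report.usable_seconds,
                "max_fd_mm": float(report.fd_mm.max()),
                "passes_minimum": passes,
            }
        )
        if passes:
            kept.append(
                dataclasses.replace(p, timeseries=ts)
            )
        else:
            logger.info(
                "excluding %s: %.0f s usable < %.0f s",
                p.participant_id,
                report.usable_seconds,
                config.minimum_seconds,
            )
    qc_table = pd.DataFrame(rows)
    qc_table.to_csv(outdir / "qc_table.tsv", sep="\t", index=False)
    logger.info(
        "QC: %d/%d participants retained, %d frames censored in total",
        len(kept),
        len(cohort.participants),
        int(qc_table["n_censored"].sum()),
    )
    return dataclasses.replace(cohort, participants=kept), qc_table


def _stage_connect(
    config: RunConfig, cohort: Cohort, outdir: Path, resume: bool
) -> dict[str, ConnectivityMatrix]:
    mat_dir = outdir / "matrices"
    mat_dir.mkdir(exist_ok=True)
    matrices: dict[str, ConnectivityMatrix] = {}
    for p in cohort.participants:
        try:
            cm = correlation_matrix(p.timeseries)
        except Exception as exc:
            raise RuntimeError(f"participant {p.participant_id}: {exc}") from exc
        matrices[p.participant_id] = cm
        write_matrix(cm, mat_dir / f"{p.participant_id}.tsv")
    # sweep diagnostics across the cohort
    diags = []
    mats = list(matrices.values())
    if "absolute" in config.schemes:
        diags.append(
            validate_sweep_bounds(mats, make_sweep("absolute", *config.absolute_sweep))
        )
    if "proportional" in config.schemes:
        diags.append(
            validate_sweep_bounds(
                mats, make_sweep("proportional", *config.proportional_sweep)
            )
        )
    if diags:
        pd.concat(diags).to_csv(outdir / "sweep_diagnostics.tsv", sep="\t", index=False)
    return matrices


def _networks_for(config: RunConfig, cm: ConnectivityMatrix):
    """Yield (scheme, threshold, network) per configured construction."""
    if "weighted" in config.schemes:
        from .connectivity import Network

        yield "weighted", None, Network(
            adjacency=cm.values,
            scheme="weighted",
            threshold=None,
            region_labels=list(cm.region_labels),
        )
    if "absolute" in config.schemes:
        for t in make_sweep("absolute", *config.absolute_sweep).thresholds:
            yield "absolute", t, threshold_absolute(cm, t)
    if "proportional" in config.schemes:
        for t in make_sweep("proportional", *config.proportional_sweep).thresholds:
            yield "proportional", t, threshold_proportional(cm, t)


def _stage_metrics(
    config: RunConfig,
    cohort: Cohort,
    matrices: dict[str, ConnectivityMatrix],
    outdir: Path,
    resume: bool,
) -> pd.DataFrame:
    mcfg = config.metric_config()
    want = set(mcfg.metrics) if mcfg.metrics is not None else set(
        REGIONAL_METRICS + GLOBAL_METRICS
    )
    rows: list[tuple] = []
    n_undefined = 0
    for pid, cm in matrices.items():
        labels = cm.region_labels
        for scheme, thr, net in _networks_for(config, cm):
            try:
                glob, reg = compute_all(net, mcfg)
            except Exception as exc:
                raise RuntimeError(f"participant {pid}: {exc}") from exc
            for name in GLOBAL_METRICS:
                if name not in want:
                    continue
                val = getattr(glob, name)
                if not np.isfinite(val):
                    n_undefined += 1
                rows.append((pid, scheme, thr, "GLOBAL", name, val))
            rows.append((pid, scheme, thr, "GLOBAL", "n_components", glob.n_components))
            for name, vec in reg.as_dict().items():
                if name not in want:
                    continue
                n_undefined += int(np.sum(~np.isfinite(vec)))
                rows.extend(
                    (pid, scheme, thr, labels[i], name, vec[i])
                    for i in range(len(labels))
                )
    table = pd.DataFrame(
        rows,
        columns=["participant_id", "scheme", "threshold", "region", "metric", "value"],
    )
    if n_undefined:
        logger.info("metrics: %d undefined values carried as missing", n_undefined)
    table.to_csv(
        outdir / "metrics.tsv", sep="\t", index=False, float_format="%.10g"
    )
    return table


def _stage_analyze(
    config: RunConfig, cohort: Cohort, metric_table: pd.DataFrame, outdir: Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    records = cohort.records()
    pf = participants_frame(records)
    tests = (
        list(config.tests)
        if config.tests is not None
        else [c for c in pf.columns if c not in ("participant_id", "chd", "age", "sex")]
    )
    standardized = standardize_across_participants(metric_table)
    summary = average_over_thresholds(standardized, min_coverage=config.min_coverage)
    summary.to_csv(
        outdir / "metric_summary.tsv", sep="\t", index=False, float_format="%.10g"
    )

    all_results = []
    for test in tests:
        res = fit_interaction_model(summary, pf, test)
        all_results.append(res)
    results = pd.concat(all_results, ignore_index=True)
    results.to_csv(
        outdir / "regression_results.tsv", sep="\t", index=False, float_format="%.6g"
    )
    significant = screen_significant(results, alpha=config.alpha, fdr=config.fdr)
    significant.to_csv(
        outdir / "significant_interactions.tsv",
        sep="\t",
        index=False,
        float_format="%.6g",
    )

    if config.age_strata:
        strata = stratify_by_age(records, bins=list(config.age_strata))
        for name, members in strata.items():
            ids = {p.participant_id for p in members}
            sub_summary = summary[summary["participant_id"].isin(ids)]
            sub_pf = pf[pf["participant_id"].isin(ids)]
            sub_res = pd.concat(
                [fit_interaction_model(sub_summary, sub_pf, t) for t in tests],
                ignore_index=True,
            )
            sub_res.to_csv(
                outdir / f"regression_results_age_{name}.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
    return results, significant


def _stage_segregate(
    config: RunConfig,
    cohort: Cohort,
    matrices: dict[str, ConnectivityMatrix],
    outdir: Path,
) -> pd.DataFrame | None:
    if not config.segregation_enabled:
        return None
    any_cm = next(iter(matrices.values()))
    if not set(DMN_LABELS) <= set(any_cm.region_labels):
        logger.info("segregation skipped: DMN labels absent from parcellation")
        return None
    seg = [
        system_segregation(cm, DMN_LABELS, participant_id=pid)
        for pid, cm in matrices.items()
    ]
    seg_df = pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in seg],
            "z_within": [s.z_within for s in seg],
            "z_between": [s.z_between for s in seg],
            "segregation": [s.segregation for s in seg],
        }
    )
    seg_df.to_csv(
        outdir / "segregation.tsv", sep="\t", index=False, float_format="%.10g"
    )
    model = fit_segregation_model(seg_df, cohort.records())
    model.to_csv(
        outdir / "segregation_model.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return model


# ---------------------------------------------------------------------------
# Report


def render_report(config: RunConfig, outdir: str | Path) -> str:
    """Human-readable markdown summary of a completed run.

    Significant interactions are listed per scheme with a direction-of-
    effect column: the sign of the interaction coefficient, flipped for
    inverted instruments (where higher raw scores mean poorer
    functioning). Rows significant under ``robust_rule`` or more schemes
    are marked cross-method robust.
    """
    outdir = Path(outdir)
    lines = ["# Functional-connectivity analysis report", ""]
    sig_path = outdir / "significant_interactions.tsv"
    inverted = set(config.inverted_tests)
    if sig_path.exists():
        sig = pd.read_csv(sig_path, sep="\t")
    else:
        sig = pd.DataFrame()
    if sig.empty:
        lines.append("No significant interaction effects were found "
                     f"(alpha = {config.alpha}).")
    else:
        robust_keys = (
            sig.groupby(["test", "region", "metric"])["scheme"]
            .nunique()
            .pipe(lambda s: set(s[s >= config.robust_rule].index))
        )
        lines.append(
            f"{len(sig)} significant interaction(s) at p < {config.alpha}:"
        )
        lines.append("")
        lines.append(
            "| Scheme | Test | Region | Measure | Interaction coef | p | "
            "Direction | Robust |"
        )
        lines.append("|---|---|---|---|---|---|---|---|")
        for _, row in sig.iterrows():
            coef = row["coef_chd_x_metric"]
            sign = np.sign(coef)
            if row["test"] in inverted:
                sign = -sign
            direction = "better" if sign > 0 else "worse"
            robust = (
                "yes"
                if (row["test"], row["region"], row["metric"]) in robust_keys
                else ""
            )
            lines.append(
                f"| {row['scheme']} | {row['test']} | {row['region']} | "
                f"{row['metric']} | {coef:.3f} | {row['p_chd_x_metric']:.2e} | "
                f"{direction} | {robust} |"
            )
    lines.append("")
    diag_path = outdir / "sweep_diagnostics.tsv"
    if diag_path.exists():
        diag = pd.read_csv(diag_path, sep="\t")
        flagged = diag[diag["flagged"]]
        lines.append("## Threshold sweep diagnostics")
        lines.append("")
        if flagged.empty:
            lines.append(
                "No thresholds flagged: mean and median component counts "
                "stayed below 2 across the cohort."
            )
        else:
            lines.append(
                f"{len(flagged)} threshold(s) flagged (mean or median "
                "component count >= 2):"
            )
            for _, row in flagged.iterrows():
                lines.append(
                    f"- {row['scheme']} t={row['threshold']}: "
                    f"mean={row['mean_components']:.2f}, "
                    f"median={row['median_components']:.1f}"
                )
    seg_path = outdir / "segregation_model.tsv"
    if seg_path.exists():
        model = pd.read_csv(seg_path, sep="\t")
        if "coef_chd" in model.columns:
            lines.append("")
            lines.append("## DMN system segregation")
            lines.append("")
            lines.append(
                f"CHD coefficient = {model['coef_chd'].iloc[0]:.4f} "
                f"(p = {model['p_chd'].iloc[0]:.4f}, n = {model['n_used'].iloc[0]})."
            )
    text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(text)
    return text
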