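"""End-to-end study orchestration.

Reproduces the analysis workflow: read or generate a multi-school study,
clean each school (isolate removal, carry-forward imputation, Jaccard
stability screen), fit the co-evolution model per school by Method of
Moments, pool the per-school estimates across schools, and render the
meta/descriptive tables.  Schools are processed independently and
sequentially; all randomness flows from a single master seed via a
documented per-school derivation, so reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import meta as meta_mod
from .effects import (
    EffectSpec,
    ModelSpec,
    default_behavior_effects,
    default_network_effects,
)
from .estimation import (
    DegenerateDataError,
    FitOptions,
    SchoolFit,
    fit_school,
)
from .panel import (
    AttritionSummary,
    SchoolPanel,
    attrition_summary,
    filter_isolates,
    impute_locf,
    jaccard_counts,
    jaccard_index,
    read_panel,
)
from .synthetic import SyntheticConfig, generate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full study run needs."""

    mode: str = "synthetic"  # "synthetic" | "real_data"
    synthetic: SyntheticConfig | None = None
    school_files: list | None = None  # [(wave1, wave2, covariates, school_id), ...]
    schema: dict | None = None
    network_effects: list[EffectSpec] = field(default_factory=default_network_effects)
    behavior_effects: list[EffectSpec] = field(default_factory=default_behavior_effects)
    fit_options: FitOptions = field(default_factory=FitOptions)
    jaccard_threshold: float = 0.20
    alpha_fisher: float = 0.025
    alpha_sb: float = 0.05
    master_seed: int = 1
    output_dir: str | None = None


@dataclass
class StudyReport:
    fits: list
    network_meta: list
    behavior_meta: list
    descriptives: pd.DataFrame
    attrition: AttritionSummary
    excluded: list  # (school_id, reason)
    manifest: dict


def school_seed(master_seed: int, index: int) -> int:
    """Per-school fit seed derived from the master seed."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0]) & 0x7FFFFFFF


def _descriptive_row(panel: SchoolPanel) -> dict:
    def recip_pct(x):
        ties = x.sum()
        return 100.0 * float((x * x.T).sum()) / ties if ties else np.nan

    try:
        j = jaccard_index(jaccard_counts(panel))
    except Exception:
        j = np.nan
    return {
        "school_id": panel.school_id,
        "n_actors": panel.n_actors,
        "n_responders_w2": int(panel.responded_wave2.sum()),
        "mean_nominations_w1": float(panel.wave1.sum(axis=1).mean()),
        "mean_nominations_w2": float(panel.wave2.sum(axis=1).mean()),
        "reciprocal_pct_w1": recip_pct(panel.wave1.astype(float)),
        "reciprocal_pct_w2": recip_pct(panel.wave2.astype(float)),
        "jaccard": j,
        **{
            f"alcohol_w1_level{k}_pct": 100.0 * float(np.mean(panel.behavior1 == k))
            for k in range(1, 7)
        },
    }


def load_study(config: RunConfig) -> list[SchoolPanel]:
    if config.mode == "synthetic":
        return generate_study(config.synthetic or SyntheticConfig()).panels
    panels = []
    for w1, w2, cov, sid in config.school_files or []:
        panels.append(read_panel((w1, w2), cov, schema=config.schema, school_id=sid))
    if not panels:
        raise ValueError("no input schools configured")
    return panels


def prepare_school(panel: SchoolPanel) -> SchoolPanel:
    """Cleaning order: isolate removal, then carry-forward imputation."""
    return impute_locf(filter_isolates(panel))


def run_study(config: RunConfig) -> StudyReport:
    """The full pipeline: load -> clean -> screen -> fit -> meta-analyze."""
    t0 = time.time()
    raw = load_study(config)
    model = ModelSpec(
        network_effects=[EffectSpec(e.name, e.side, e.covariate) for e in config.network_effects],
        behavior_effects=[EffectSpec(e.name, e.side, e.covariate) for e in config.behavior_effects],
        network_rate=1.0,
        behavior_rate=1.0,
    )
    panels: list[SchoolPanel] = []
    excluded: list[tuple[str, str]] = []
    for p in raw:
        try:
            clean = prepare_school(p)
            j = jaccard_index(jaccard_counts(clean))
            if j < config.jaccard_threshold:
                reason = f"Jaccard {j:.3f} < threshold {config.jaccard_threshold:.2f}"
                logger.warning("school %s excluded: %s", p.school_id, reason)
                excluded.append((p.school_id, reason))
                continue
            panels.append(clean)
        except Exception as exc:  # degenerate or unreadable school
            logger.warning("school %s excluded: %s", p.school_id, exc)
            excluded.append((p.school_id, str(exc)))
    if not panels:
        raise RuntimeError(
            f"zero retained schools ({len(excluded)} excluded): {excluded}"
        )

    fits: list[SchoolFit] = []
    for idx, panel in enumerate(panels):
        t1 = time.time()
        try:
            fit = fit_school(panel, model, config.fit_options, seed=school_seed(config.master_seed, idx))
        except DegenerateDataError as exc:
            logger.warning("school %s not fitted: %s", panel.school_id, exc)
            excluded.append((panel.school_id, str(exc)))
            continue
        logger.info(
            "stage=fit school=%s n=%d duration=%.1fs converged=%s",
            panel.school_id, panel.n_actors, time.time() - t1, fit.converged,
        )
        fits.append(fit)

    usable = [f for f in fits if f.converged]
    for f in fits:
        if not f.converged:
            logger.warning("school %s did not converge; excluded from meta-analysis", f.school_id)
    meta_results = (
        meta_mod.meta_analyze(usable, config.alpha_fisher, config.alpha_sb)
        if len(usable) >= 2
        else []
    )
    network_meta = [m for m in meta_results if m.effect.startswith("net:")]
    behavior_meta = [m for m in meta_results if m.effect.startswith("beh:")]
    descriptives = pd.DataFrame([_descriptive_row(p) for p in panels])
    report = StudyReport(
        fits=fits,
        network_meta=network_meta,
        behavior_meta=behavior_meta,
        descriptives=descriptives,
        attrition=attrition_summary(panels),
        excluded=excluded,
        manifest={
            "master_seed": config.master_seed,
            "jaccard_threshold": config.jaccard_threshold,
            "n_schools_input": len(raw),
            "n_schools_fitted": len(fits),
            "n_schools_converged": len(usable),
            "duration_s": round(time.time() - t0, 1),
        },
    )
    if config.output_dir:
        render_reports(report, config.output_dir)
    return report


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.4f}"
    return str(x)


def _meta_frame(results) -> pd.DataFrame:
    return meta_mod.meta_table(results)


def render_reports(report: StudyReport, directory, fmt: str = "both") -> dict:
    """Write the study tables as delimited text and/or markdown.

    Both renderings are produced from the same formatted values, so the
    numbers are identical.  Includes the per-school fit table, the two meta
    tables, the descriptive table, and the attrition summary.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    tables: dict[str, pd.DataFrame] = {}
    if report.fits:
        tables["school_fits"] = pd.concat([f.to_frame() for f in report.fits], ignore_index=True)
    if report.network_meta:
        tables["network_meta"] = _meta_frame(report.network_meta)
    if report.behavior_meta:
        tables["behavior_meta"] = _meta_frame(report.behavior_meta)
    tables["descriptives"] = report.descriptives
    att = report.attrition
    tables["attrition"] = pd.DataFrame(
        {
            "n_wave1": [att.n_wave1],
            "n_wave2": [att.n_wave2],
            "retention_pct": [att.retention_pct],
        }
    )

    for name, df in tables.items():
        formatted = df.copy()
        for col in formatted.columns:
            formatted[col] = formatted[col].map(_fmt)
        if fmt in ("both", "delimited"):
            path = directory / f"{name}.tsv"
            formatted.to_csv(path, sep="\t", index=False)
            paths[f"{name}.tsv"] = path
        if fmt in ("both", "markdown"):
            path = directory / f"{name}.md"
            with open(path, "w") as fh:
                fh.write(
                    formatted.to_markdown(index=False, disable_numparse=True) + "\n"
                )
            paths[f"{name}.md"] = path
    if not report.behavior_meta and report.network_meta:
        note = directory / "NOTE.txt"
        note.write_text("behavior meta table omitted: no behavior effects configured\n")
        paths["NOTE.txt"] = note

    with open(directory / "manifest.txt", "w") as fh:
        for k, v in report.manifest.items():
            if k == "duration_s":  # wall time would break byte-identical reruns
                continue
            fh.write(f"{k}: {v}\n")
        for sid, reason in report.excluded:
            fh.write(f"excluded: {sid}: {reason}\n")
    paths["manifest.txt"] = directory / "manifest.txt"
    return paths


def coefficient_figure(report: StudyReport, path) -> None:
    """Per-effect box summary of the school-level estimates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fits = [f for f in report.fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to plot")
    names = fits[0].parameter_names
    n_rates = fits[0].model.n_rates
    labels = names[n_rates:]
    data = [
        [f.theta_hat[k] for f in fits] for k in range(n_rates, len(names))
    ]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(labels) + 2))
    ax.boxplot(data, orientation="horizontal", tick_labels=labels)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("per-school parameter estimate")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
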