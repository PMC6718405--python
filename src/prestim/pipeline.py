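"""End-to-end orchestration: simulate -> preprocess -> decode -> infer -> behave.

A :class:`RunConfig` gathers every stage's parameters in one serializable
object (YAML round-trip safe); :func:`run_pipeline` executes the full
analysis for a simulated cohort and writes a manifest, machine-readable
results and a human-readable summary with the five analysis tables
(decoding AUROCs, permutation test, dissociation, trial history, pupil
linkage).  All randomness derives from the single global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .behavior import (
    compute_sdt,
    categorization_accuracy,
    dissociation_table,
    entropy,
    pupil_linkage,
    subject_decision_variables,
    subject_dissociation,
    trial_history,
)
from .decode import loo_cv_decode, cross_condition_decode, within_vs_across_category_decode
from .design import DesignSpec, GeneratorParams, simulate_experiment
from .inference import permutation_test_group
from .preprocess import (
    average_prestim,
    average_pupil_prestim,
    detect_blinks,
    detrend_blocks,
    reject_blink_trials,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("prestim")


@dataclass
class RunConfig:
    """Hierarchical configuration of one pipeline run."""

    design: DesignSpec = field(default_factory=DesignSpec)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    n_subjects: int = 6
    between_subject_b0_sd: float = 0.25
    penalty_C: float = 1.0
    permutation_B: int = 50
    run_permutation_test: bool = True
    min_recognized_scrambled: int = 5
    history_max_lag: int = 5
    seed: int = 0
    output_dir: str = "prestim_run"

    def to_dict(self) -> dict:
        return {
            "design": dataclasses.asdict(self.design),
            "generator": dataclasses.asdict(self.generator),
            **{
                f.name: getattr(self, f.name)
                for f in dataclasses.fields(self)
                if f.name not in ("design", "generator")
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        design = data.pop("design", {})
        if isinstance(design, dict):
            design = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in design.items()}
            design = DesignSpec(**design)
        generator = data.pop("generator", {})
        if isinstance(generator, dict):
            generator = GeneratorParams(**generator)
        return cls(design=design, generator=generator, **data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(data: dict) -> list[str]:
    """Diagnose a configuration mapping without raising.

    Reports unknown keys, out-of-range values and incompatible dimensions
    as a list of human-readable diagnostics (empty = valid).
    """
    diagnostics: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in known:
            diagnostics.append(f"unknown configuration key: {key!r}")
    for section, cls in (("design", DesignSpec), ("generator", GeneratorParams)):
        sub = data.get(section, {})
        if not isinstance(sub, dict):
            diagnostics.append(f"{section} must be a mapping")
            continue
        names = {f.name for f in dataclasses.fields(cls)}
        for key in sub:
            if key not in names:
                diagnostics.append(f"unknown {section} key: {key!r}")
        try:
            cls(**{k: tuple(v) if isinstance(v, list) else v
                   for k, v in sub.items() if k in names})
        except (ValueError, TypeError) as exc:
            diagnostics.append(f"invalid {section} values: {exc}")
    design = data.get("design", {})
    if isinstance(design, dict):
        n_sensors = design.get("n_sensors", DesignSpec.n_sensors)
        n_categories = design.get("n_categories", DesignSpec.n_categories)
        if isinstance(n_sensors, int) and isinstance(n_categories, int) \
                and n_sensors <= n_categories + 1:
            diagnostics.append(
                f"n_sensors={n_sensors} too small for {n_categories} category patterns"
            )
    if "n_subjects" in data and (not isinstance(data["n_subjects"], int)
                                 or data["n_subjects"] < 1):
        diagnostics.append("n_subjects must be a positive integer")
    if "permutation_B" in data and (not isinstance(data["permutation_B"], int)
                                    or data["permutation_B"] < 1):
        diagnostics.append("permutation_B must be a positive integer")
    return diagnostics


def _preprocess_subject(session, config: RunConfig):
    """Detrend, average, blink-reject and pupil-average one session."""
    epochs = detrend_blocks(session.epochs)
    X_all = average_prestim(epochs)
    blinks = detect_blinks(session.pupil)
    trials, n_rejected = reject_blink_trials(
        session.trials, blinks, session.spec.stimulus_duration
    )
    pupil_means_all = average_pupil_prestim(session.pupil, blinks,
                                            window=session.spec.prestim_duration)
    keep = trials["trial_index"].to_numpy()
    return trials.reset_index(drop=True), X_all[keep], pupil_means_all[keep], n_rejected


def _subject_aurocs(X, trials, config: RunConfig) -> dict:
    """The decoding AUROC battery for one subject (NaN where not estimable)."""
    real = trials["is_real"].to_numpy(dtype=bool)
    yes = trials["recognition_report"].to_numpy().astype(str) == "yes"
    objective = trials["objective_category"].astype(str).to_numpy()
    C = config.penalty_C
    out: dict[str, float] = {}

    res_real = loo_cv_decode(X[real], yes[real].astype(int), C=C, pos_label=1)
    out["recognition_real"] = res_real.auroc

    n_rec_scr = int((yes & ~real).sum())
    include_scr = (n_rec_scr >= config.min_recognized_scrambled
                   and np.unique(yes[~real]).size == 2
                   and min(np.bincount(yes[~real].astype(int))) >= 2)
    if include_scr:
        out["recognition_scrambled"] = loo_cv_decode(
            X[~real], yes[~real].astype(int), C=C, pos_label=1).auroc
        out["recognition_real_to_scrambled"] = cross_condition_decode(
            X[real], yes[real].astype(int), X[~real], yes[~real].astype(int),
            C=C, pos_label=1, train_condition="real", test_condition="scrambled",
        ).auroc
        out["recognition_scrambled_to_real"] = cross_condition_decode(
            X[~real], yes[~real].astype(int), X[real], yes[real].astype(int),
            C=C, pos_label=1, train_condition="scrambled", test_condition="real",
        ).auroc
    else:
        out["recognition_scrambled"] = np.nan
        out["recognition_real_to_scrambled"] = np.nan
        out["recognition_scrambled_to_real"] = np.nan

    wa = within_vs_across_category_decode(X[real], yes[real].astype(int),
                                          objective[real], C=C, pos_label=1)
    out["recognition_within_category"] = wa.within_mean if wa.within else np.nan
    out["recognition_across_category"] = wa.across_mean if wa.across else np.nan

    rec_real = real & yes
    unrec_real = real & ~yes
    for name, sel in (("category_recognized", rec_real),
                      ("category_unrecognized", unrec_real)):
        try:
            out[name] = loo_cv_decode(X[sel], objective[sel], C=C).auroc
        except ValueError:  # a category too thin in this condition
            out[name] = np.nan
    return out


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute the full pipeline for a simulated cohort.

    Returns the report dictionary and writes ``manifest.json``,
    ``results.json`` and ``summary.txt`` under the configured output
    directory.  The same configuration and seed reproduce the outputs
    exactly.
    """
    diagnostics = validate_config(config.to_dict())
    if diagnostics:
        raise ValueError("invalid configuration:\n" + "\n".join(diagnostics))
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("simulating %d subjects", config.n_subjects)
    sessions = simulate_experiment(
        config.n_subjects, config.design, config.generator, seed=config.seed,
        between_subject_b0_sd=config.between_subject_b0_sd,
    )

    auroc_rows, dvs, dissociations, pupil_subjects, histories = [], [], [], [], []
    perm_tasks = {}
    counts = {"generated": 0, "rejected": 0, "retained": 0}
    for i, session in enumerate(sessions):
        stage = f"subject {i}"
        try:
            trials, X, pupil_means, n_rejected = _preprocess_subject(session, config)
            counts["generated"] += len(session.trials)
            counts["rejected"] += n_rejected
            counts["retained"] += len(trials)
            log.info("%s: %d trials retained (%d rejected)", stage, len(trials), n_rejected)
            auroc_rows.append(_subject_aurocs(X, trials, config))
            dv = subject_decision_variables(X, trials, C=config.penalty_C)
            dvs.append(dv)
            dissociations.append(subject_dissociation(dv))
            ent = entropy(dv.category_proba, n=config.design.n_categories)
            pupil_subjects.append(
                (pupil_means, dv.trials["general_hi"].to_numpy(), ent.high)
            )
            histories.append(trial_history(
                dv.trials, p_recognition=dv.trials["p_recognition"].to_numpy(),
                predicted_category=dv.classes[np.argmax(dv.category_proba, axis=1)],
                max_lag=config.history_max_lag,
            ))
            real = trials["is_real"].to_numpy(dtype=bool)
            yes = trials["recognition_report"].to_numpy().astype(str) == "yes"
            perm_tasks[i] = (X[real], yes[real].astype(int))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    aurocs = {k: float(np.nanmean([row[k] for row in auroc_rows]))
              for k in auroc_rows[0]}

    permutation = None
    if config.run_permutation_test:
        log.info("label-permutation test (B=%d)", config.permutation_B)
        null = permutation_test_group(perm_tasks, B=config.permutation_B,
                                      seed=config.seed + 1)
        permutation = {
            "actual_mean_auroc": null.actual_score,
            "p_value": null.p_value,
            "p_value_smoothed": null.p_value_smoothed,
            "B": null.B,
        }

    dissociation = dissociation_table(dissociations)
    pupil = pupil_linkage(pupil_subjects)

    sdt_rows = []
    for dv in dvs:
        yes = dv.trials["recognition_report"].to_numpy().astype(str) == "yes"
        real = dv.trials["is_real"].to_numpy(dtype=bool)
        m = compute_sdt(yes, real)
        sdt_rows.append({
            "hit_rate": m.hit_rate, "false_alarm_rate": m.false_alarm_rate,
            "d_prime": m.d_prime, "criterion": m.criterion,
            "accuracy_recognized_real": categorization_accuracy(
                dv.trials["category_report"], dv.trials["objective_category"],
                real & yes),
            "accuracy_unrecognized_real": categorization_accuracy(
                dv.trials["category_report"], dv.trials["objective_category"],
                real & ~yes),
        })
    behavior_summary = {k: float(np.mean([r[k] for r in sdt_rows]))
                        for k in sdt_rows[0]}

    history_summary = {
        "lag1_recognition_rate_diff": float(np.mean(
            [h["recognition_rate_after_yes_minus_no"][1] for h in histories])),
        "predicted_matches_previous_objective_rate": float(np.mean(
            [h["predicted_matches_previous_objective_rate"] for h in histories])),
        "dv_lag1_autocorrelation": float(np.mean(
            [h["dv_lag1_autocorrelation"] for h in histories])),
    }

    report = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "trial_accounting": counts,
        "aurocs": aurocs,
        "permutation": permutation,
        "behavior": behavior_summary,
        "dissociation": {
            "table": dissociation.table.to_dict(orient="records"),
            "tests": {
                f"{model}:{metric}": {
                    "statistic": t.statistic, "p_value": t.p_value,
                    "test": t.test_name, "degenerate": t.degenerate,
                }
                for (model, metric), t in dissociation.tests.items()
            },
        },
        "trial_history": history_summary,
        "pupil": {
            "general_hi_mean": float(np.mean(pupil.general_hi_means)),
            "general_lo_mean": float(np.mean(pupil.general_lo_means)),
            "general_p": pupil.general_test.p_value,
            "entropy_high_mean": float(np.mean(pupil.entropy_high_means)),
            "entropy_low_mean": float(np.mean(pupil.entropy_low_means)),
            "entropy_p": pupil.entropy_test.p_value,
        },
    }

    canonical = json.dumps(report["config"], sort_keys=True)
    manifest = {
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "n_subjects": config.n_subjects,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "results.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "summary.txt").write_text(_render_summary(report))
    return report


def _render_summary(report: dict) -> str:
    """Human-readable summary with the five analysis tables."""
    lines = [
        f"prestim pipeline summary (seed {report['seed']}, "
        f"{report['config']['n_subjects']} subjects)",
        "",
        "Trial accounting: {generated} generated, {rejected} rejected, "
        "{retained} retained".format(**report["trial_accounting"]),
        "",
        "[1] Decoding AUROC (group mean)",
    ]
    for key, value in report["aurocs"].items():
        lines.append(f"    {key:36s} {value:.3f}")
    lines.append("")
    lines.append("[2] Group label-permutation test (recognition, real trials)")
    if report["permutation"] is None:
        lines.append("    skipped")
    else:
        p = report["permutation"]
        lines.append(
            f"    mean AUROC {p['actual_mean_auroc']:.3f}, "
            f"p = {p['p_value']:.4g} (B = {p['B']}, smoothed {p['p_value_smoothed']:.4g})"
        )
    lines.append("")
    lines.append("[3] Dissociation table (hi/lo split per model)")
    header = f"    {'model':9s}{'group':6s}{'HR':>7s}{'FAR':>7s}{'d-prime':>9s}{'c':>7s}{'acc(R)':>8s}{'acc(S)':>8s}"
    lines.append(header)
    for row in report["dissociation"]["table"]:
        lines.append(
            f"    {row['model']:9s}{row['group']:6s}"
            f"{row['hit_rate']:7.3f}{row['false_alarm_rate']:7.3f}"
            f"{row['d_prime']:9.3f}{row['criterion']:7.3f}"
            f"{row['accuracy_real']:8.2f}{row['accuracy_scrambled']:8.2f}"
        )
    for key, t in report["dissociation"]["tests"].items():
        if key.split(":")[1] in ("d_prime", "criterion"):
            lines.append(f"    {key:24s} p = {t['p_value']:.4g} ({t['test']})")
    lines.append("")
    lines.append("[4] Trial history")
    for key, value in report["trial_history"].items():
        lines.append(f"    {key:44s} {value: .4f}")
    lines.append("")
    lines.append("[5] Pupil linkage")
    p = report["pupil"]
    lines.append(
        f"    general split: hi {p['general_hi_mean']: .3f} vs lo "
        f"{p['general_lo_mean']: .3f} (p = {p['general_p']:.4g})"
    )
    lines.append(
        f"    entropy split: high {p['entropy_high_mean']: .3f} vs low "
        f"{p['entropy_low_mean']: .3f} (p = {p['entropy_p']:.4g})"
    )
    lines.append("")
    return "\n".join(lines)
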