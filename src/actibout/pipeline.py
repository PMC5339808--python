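"""Cohort workflow orchestration: preprocess -> events -> fits -> group stats.

Drives the full study design over a cohort of subjects: per-state
(pooled / wake / sleep) event extraction and seven-family fits per subject,
random-effects group model selection with exceedance probabilities,
evidence-weighted group-averaged parameters, a threshold-sensitivity sweep,
and an optional subgroup contrast by log Bayes factor.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distmodels import FAMILIES
from .events import (DEFAULT_SWEEP_FACTORS, activity_threshold, extract_events,
                     sweep_thresholds)
from .fitting import InsufficientDataError, fit_all, fit_mle
from .groupsel import (bms_dirichlet, compare_groups_logbf, evidence_matrix,
                       group_average_params, logbf_verbal_scale)
from .preprocess import CountsSeries, DiaryRecord, detect_nonwear, read_counts, read_diary, split_states
from .synthetic import SyntheticCohortConfig, generate_cohort

log = logging.getLogger("actibout")

__all__ = ["RunConfig", "run_subject", "run_cohort", "report"]

# family refitted per event type in the threshold sweep (the group-level
# winners of the main analysis)
SWEEP_FAMILIES = {"active": "exp_plus_tpl", "inactive": "trunc_power_law"}


@dataclass
class RunConfig:
    """Everything a reproducible cohort run needs."""

    counts_paths: list = field(default_factory=list)
    diary_paths: list = field(default_factory=list)
    synthetic: dict | None = None
    states: tuple = ("pooled",)
    epoch: int = 1
    threshold_factors: tuple = DEFAULT_SWEEP_FACTORS
    min_tail: int = 50
    x_min: float | None = None
    discretization: float | None = 1.0
    n_starts: int = 5
    bms_prior: float = 1.0
    mc_samples: int = 1_000_000
    subgroup_labels: dict | None = None
    output_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("states", "threshold_factors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["states"] = list(self.states)
        d["threshold_factors"] = list(self.threshold_factors)
        return d


def _load_cohort(config: RunConfig):
    """(series, diary, label) triples from files or the synthetic generator."""
    subjects = []
    if config.synthetic is not None:
        syn = SyntheticCohortConfig(**{**config.synthetic,
                                       "master_seed": config.synthetic.get(
                                           "master_seed", config.seed)})
        for series, truth in generate_cohort(syn):
            subjects.append((series, None, truth))
    else:
        for i, cpath in enumerate(config.counts_paths):
            series = read_counts(cpath, subject_id=Path(cpath).stem)
            diary = None
            if i < len(config.diary_paths) and config.diary_paths[i]:
                diary = read_diary(config.diary_paths[i])
            subjects.append((series, diary, None))
    if not subjects:
        raise ValueError("empty cohort: no counts inputs and no synthetic config")
    return subjects


def run_subject(series: CountsSeries, diary: DiaryRecord | None,
                config: RunConfig) -> tuple[dict, dict]:
    """Per-state, per-event-type fits for one subject.

    Returns ``(fitsets, info)`` where ``fitsets`` maps ``(state,
    event_type)`` to a SubjectFitSet.  Subjects failing the sleep
    sufficiency rule (worn wake:sleep ratio > 3) get wake-only analyses.
    """
    series = series.copy()
    series.wear &= detect_nonwear(series, diary)
    info = {"subject_id": series.subject_id, "exclusions": []}
    if diary is not None and diary.days:
        series, state_report = split_states(series, diary)
    else:
        # state annotations may already be present (e.g. synthetic series)
        wake_s = int((series.wear & (series.state == 0)).sum()) * series.epoch
        sleep_s = int((series.wear & (series.state == 1)).sum()) * series.epoch
        ratio = wake_s / sleep_s if sleep_s > 0 else math.inf
        state_report = {"worn_wake_s": wake_s, "worn_sleep_s": sleep_s,
                        "wake_sleep_ratio": ratio,
                        "insufficient_sleep": bool(ratio > 3)}
    info["state_report"] = state_report
    states = list(config.states)
    # subjects failing the sleep sufficiency rule keep wake-only analyses;
    # all-wake subjects (no sleep epochs at all) keep pooled, which then
    # coincides with wake by construction
    if state_report.get("insufficient_sleep") and (series.state == 1).any():
        dropped = [s for s in states if s != "wake"]
        states = [s for s in states if s == "wake"]
        if dropped:
            info["exclusions"].append(
                {"reason": "insufficient_sleep", "states": dropped})
    fitsets = {}
    for state in states:
        try:
            thr = activity_threshold(series, state=state)
        except ValueError as exc:
            info["exclusions"].append({"reason": str(exc), "states": [state]})
            continue
        es = extract_events(series, thr, state=state)
        for event_type in ("active", "inactive"):
            durations = es.durations(event_type)
            try:
                fitsets[(state, event_type)] = fit_all(
                    durations,
                    min_tail=config.min_tail,
                    n_starts=config.n_starts,
                    seed=config.seed,
                    subject_id=series.subject_id,
                    state=state,
                    event_type=event_type,
                    x_min=config.x_min,
                    discretization=config.discretization,
                )
            except InsufficientDataError as exc:
                info["exclusions"].append(
                    {"reason": str(exc), "states": [state],
                     "event_type": event_type})
    return fitsets, info


def _sweep_subject(series: CountsSeries, config: RunConfig) -> dict:
    """Winning-family parameter refits across threshold factors (pooled)."""
    sweeps = sweep_thresholds(series, config.threshold_factors, state="pooled")
    out = {}
    for es in sweeps:
        for event_type, family in SWEEP_FAMILIES.items():
            try:
                fit = fit_mle(family, es.durations(event_type),
                              config.x_min or 1.0, n_starts=config.n_starts,
                              seed=config.seed, compute_ks=False,
                              discretization=config.discretization)
            except InsufficientDataError:
                continue
            if fit.converged:
                out[(event_type, es.threshold_factor)] = dict(fit.spec.params)
    return out


def run_cohort(config: RunConfig, do_sweep: bool = True) -> dict:
    """Full cohort analysis; returns a results dictionary (see ``report``)."""
    subjects = _load_cohort(config)
    all_fits, infos, sweep_rows = [], [], []
    for series, diary, truth in subjects:
        log.info("subject %s: fitting", series.subject_id)
        fitsets, info = run_subject(series, diary, config)
        all_fits.append(fitsets)
        infos.append(info)
        if do_sweep and any(f != 1.0 for f in config.threshold_factors):
            swept = _sweep_subject(series, config)
            for (event_type, factor), params in swept.items():
                for pname, pval in params.items():
                    sweep_rows.append({
                        "subject_id": series.subject_id, "event_type": event_type,
                        "factor": factor, "param": pname, "value": pval,
                    })
    if len(subjects) < 2:
        raise ValueError("cohort analysis needs at least 2 subjects")

    group, per_subject_rows = {}, []
    for state in config.states:
        for event_type in ("active", "inactive"):
            fitsets = [fs[(state, event_type)] for fs in all_fits
                       if (state, event_type) in fs]
            for fs in fitsets:
                for fam, fr in fs.fits.items():
                    row = {"subject_id": fs.subject_id, "state": state,
                           "event_type": event_type, "family": fam,
                           "x_min": fs.x_min, "n_tail": fr.n_tail,
                           "loglik": fr.loglik, "bic": fr.bic, "ks": fr.ks,
                           "converged": fr.converged,
                           "best": fam == fs.best_family_by_bic}
                    if fr.spec is not None:
                        row.update({f"param_{k}": v
                                    for k, v in fr.spec.params.items()})
                    per_subject_rows.append(row)
            ev = evidence_matrix(fitsets)
            if ev.shape[0] < 2:
                continue
            bms = bms_dirichlet(ev, prior_alpha=config.bms_prior,
                                mc_samples=config.mc_samples, seed=config.seed)
            averages = {fam: group_average_params(fitsets, fam, ev)
                        for fam in FAMILIES}
            group[(state, event_type)] = {
                "bms": bms, "averages": averages, "n_subjects": ev.shape[0]}

    sweep_df = pd.DataFrame(sweep_rows)
    sensitivity = _sensitivity_table(sweep_df) if not sweep_df.empty else pd.DataFrame()

    subgroup = None
    if config.subgroup_labels:
        subgroup = _subgroup_contrast(subjects, config)

    return {
        "config": config,
        "per_subject": pd.DataFrame(per_subject_rows),
        "group": group,
        "sweep": sweep_df,
        "sensitivity": sensitivity,
        "subgroup": subgroup,
        "infos": infos,
    }


def _sensitivity_table(sweep_df: pd.DataFrame) -> pd.DataFrame:
    """Proportional change of each parameter from its factor-1.0 value."""
    rows = []
    for (sid, event_type, pname), g in sweep_df.groupby(
            ["subject_id", "event_type", "param"]):
        base = g.loc[g["factor"] == 1.0, "value"]
        if base.empty or base.iloc[0] == 0:
            continue
        b = base.iloc[0]
        for _, r in g.iterrows():
            rows.append({"subject_id": sid, "event_type": event_type,
                         "param": pname, "factor": r["factor"],
                         "prop_change": (r["value"] - b) / b})
    return pd.DataFrame(rows)


def _subgroup_contrast(subjects, config: RunConfig) -> dict:
    labels = config.subgroup_labels
    pools = {}
    for series, diary, _ in subjects:
        lab = labels.get(series.subject_id)
        if lab is None:
            continue
        thr = activity_threshold(series, state="pooled")
        es = extract_events(series, thr, state="pooled")
        pools.setdefault(lab, []).append(es.active)
    if len(pools) != 2:
        raise ValueError("subgroup contrast needs exactly 2 labelled groups")
    (la, xs_a), (lb, xs_b) = sorted(pools.items())
    a = np.concatenate(xs_a)
    b = np.concatenate(xs_b)
    lbf = compare_groups_logbf(a, b, SWEEP_FAMILIES["active"],
                               x_min=config.x_min or 1.0, seed=config.seed)
    return {"groups": (la, lb), "event_type": "active",
            "log_bayes_factor": lbf, "evidence": logbf_verbal_scale(lbf)}


def report(results: dict, output_dir=None) -> dict:
    """Write per-subject fits, group summary, sensitivity table and manifest."""
    config: RunConfig = results["config"]
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    per_subject = results["per_subject"]
    p = outdir / "subject_fits.csv"
    per_subject.to_csv(p, index=False)
    written["subject_fits"] = str(p)

    rows = []
    for (state, event_type), g in results["group"].items():
        bms = g["bms"]
        for i, fam in enumerate(bms.families):
            row = {"state": state, "event_type": event_type, "family": fam,
                   "exceedance": float(bms.exceedance[i]),
                   "expected_frequency": float(bms.expected_frequencies[i]),
                   "n_subjects": g["n_subjects"]}
            avg = g["averages"].get(fam)
            if avg is None:
                row["params"] = "NA"
            else:
                row["params"] = ";".join(
                    f"{k}={v:.6g}" for k, v in sorted(avg["params"].items()))
            rows.append(row)
    gp = outdir / "group_summary.csv"
    pd.DataFrame(rows).to_csv(gp, index=False)
    written["group_summary"] = str(gp)

    if not results["sensitivity"].empty:
        sp = outdir / "threshold_sensitivity.csv"
        results["sensitivity"].to_csv(sp, index=False)
        written["threshold_sensitivity"] = str(sp)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_subjects": len(results["infos"]),
        "exclusions": [i for i in results["infos"] if i["exclusions"]],
    }
    if results["subgroup"] is not None:
        manifest["subgroup"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in results["subgroup"].items()
        }
    mp = outdir / "run_manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    written["manifest"] = str(mp)
    return written
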