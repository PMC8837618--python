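"""Session-log serialisation, configuration files and the pipeline runner.

The on-disk session format is one CSV per cohort, one row per trial, with the
fixed column schema in :data:`CSV_COLUMNS`; missing values (aborted trials,
trials without a rating probe) are empty fields.  Externally collected data
in a different layout can be ingested by supplying a column-mapping config
(``column_map`` in the YAML config) that renames source columns onto this
schema — no network access happens in this package.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .task import SessionLog, TaskConfig, TrialRecord

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "subject_id",
    "group",
    "t",
    "shape_left",
    "shape_right",
    "colour_left",
    "colour_right",
    "chosen_side",
    "chosen_shape",
    "chosen_colour",
    "transition",
    "s2_state",
    "s2_shape_left",
    "s2_shape_right",
    "s2_chosen_shape",
    "reward",
    "attention_probe",
    "attention_correct",
    "rated_shape",
    "rating_raw",
    "aborted",
]

__all__ = [
    "CSV_COLUMNS",
    "RunConfig",
    "sessions_to_frame",
    "write_sessions",
    "read_sessions",
    "load_config",
    "run_pipeline",
]


def _opt(value):
    return "" if value is None else value


def sessions_to_frame(cohort: Sequence[SessionLog]) -> pd.DataFrame:
    """Flatten a cohort to the canonical one-row-per-trial frame."""
    rows = []
    for sess in cohort:
        for tr in sess.trials:
            s2l, s2r = (tr.s2_offered_shapes or (None, None))
            rows.append(
                dict(
                    subject_id=sess.subject_id,
                    group=sess.group,
                    t=tr.t,
                    shape_left=tr.offered_shapes[0],
                    shape_right=tr.offered_shapes[1],
                    colour_left=tr.offered_colours[0],
                    colour_right=tr.offered_colours[1],
                    chosen_side=_opt(tr.chosen_side),
                    chosen_shape=_opt(tr.chosen_shape),
                    chosen_colour=_opt(tr.chosen_colour),
                    transition=_opt(tr.transition),
                    s2_state=_opt(tr.s2_state),
                    s2_shape_left=_opt(s2l),
                    s2_shape_right=_opt(s2r),
                    s2_chosen_shape=_opt(tr.s2_chosen_shape),
                    reward=_opt(tr.reward),
                    attention_probe=int(tr.attention_probe),
                    attention_correct=_opt(
                        int(tr.attention_correct) if tr.attention_correct is not None else None
                    ),
                    rated_shape=_opt(tr.rated_shape),
                    rating_raw=_opt(tr.rating_raw),
                    aborted=int(tr.aborted),
                )
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_sessions(cohort: Sequence[SessionLog], path) -> None:
    sessions_to_frame(cohort).to_csv(path, index=False)


def _maybe_int(v) -> Optional[int]:
    if v == "" or v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return int(float(v))


def read_sessions(
    path,
    config: Optional[TaskConfig] = None,
    column_map: Optional[Dict[str, str]] = None,
) -> List[SessionLog]:
    """Read a cohort CSV back into typed session logs.

    A missing mandatory column is a hard error naming the column; rows that
    fail to parse are skipped with a logged warning and counted.  ``config``
    defaults to the standard task constants; ``column_map`` renames source
    columns onto the canonical schema before validation.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    config = config or TaskConfig()
    sessions: List[SessionLog] = []
    n_bad = 0
    for sid, grp in df.groupby("subject_id", sort=False):
        trials: List[TrialRecord] = []
        group = grp["group"].iloc[0]
        for i, row in grp.iterrows():
            try:
                aborted = bool(int(float(row.aborted)))
                s2l, s2r = _maybe_int(row.s2_shape_left), _maybe_int(row.s2_shape_right)
                rec = TrialRecord(
                    t=int(float(row.t)),
                    offered_shapes=(int(float(row.shape_left)), int(float(row.shape_right))),
                    offered_colours=(int(float(row.colour_left)), int(float(row.colour_right))),
                    chosen_side=row.chosen_side or None,
                    chosen_shape=_maybe_int(row.chosen_shape),
                    chosen_colour=_maybe_int(row.chosen_colour),
                    transition=row.transition or None,
                    s2_state=_maybe_int(row.s2_state),
                    s2_offered_shapes=(s2l, s2r) if s2l is not None else None,
                    s2_chosen_shape=_maybe_int(row.s2_chosen_shape),
                    reward=_maybe_int(row.reward),
                    attention_probe=bool(int(float(row.attention_probe))),
                    attention_correct=(
                        bool(_maybe_int(row.attention_correct))
                        if row.attention_correct != ""
                        else None
                    ),
                    rated_shape=_maybe_int(row.rated_shape),
                    rating_raw=float(row.rating_raw) if row.rating_raw != "" else None,
                    aborted=aborted,
                )
                trials.append(rec)
            except (ValueError, TypeError) as exc:
                n_bad += 1
                logger.warning("skipping unparseable row %d (%s)", i, exc)
        sessions.append(
            SessionLog(subject_id=str(sid), group=str(group), config=config, trials=trials)
        )
    if n_bad:
        logger.warning("%d unparseable rows skipped", n_bad)
    return sessions


@dataclass
class RunConfig:
    """Configuration for an end-to-end pipeline run."""

    out_dir: str = "retroval_out"
    sessions_path: Optional[str] = None  # None -> simulate
    seed: int = 0
    n_subjects: int = 30
    group: str = "explicit"
    rating_rule: str = "MBdQ"
    stages: tuple = ("simulate", "fit", "rpes", "analyze")
    fit_restarts: int = 4
    fit_hierarchical: bool = False
    task: Dict = field(default_factory=dict)
    column_map: Dict[str, str] = field(default_factory=dict)

    def task_config(self) -> TaskConfig:
        return TaskConfig(**self.task)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML (or key: value) mapping into a :class:`RunConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(**data)
    if "stages" in data:
        cfg.stages = tuple(data["stages"])
    return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.reset_index().to_dict(orient="records")
    return str(o)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the configured stages and write all artifacts to ``out_dir``.

    Stage order is simulate (or load) → fit → rpes → analyze.  Every artifact
    is stamped with the config hash and root seed; a stage failure aborts
    downstream stages but preserves what was already written.
    """
    from . import agents, fitting, rpe as rpe_mod, stats

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = dict(config_hash=config.hash(), seed=config.seed)
    report: Dict = dict(stamp=stamp, stages_run=[])
    task_cfg = config.task_config()

    # --- sessions ---------------------------------------------------------
    if config.sessions_path is not None:
        cohort = read_sessions(config.sessions_path, config=task_cfg,
                               column_map=config.column_map or None)
        truths = None
    else:
        rating_model = agents.RatingModel(rule=config.rating_rule)
        cohort, truths = agents.generate_cohort(
            config.n_subjects,
            agents.ParamDistribution(),
            rating_model,
            task_cfg,
            seed=config.seed,
            group=config.group,
        )
        if "simulate" in config.stages:
            write_sessions(cohort, out / "sessions.csv")
            with open(out / "true_params.json", "w") as fh:
                json.dump(
                    dict(
                        stamp,
                        subjects={
                            s.subject_id: vars(p) for s, p in zip(cohort, truths)
                        },
                    ),
                    fh,
                    indent=1,
                )
            report["stages_run"].append("simulate")

    # --- fit --------------------------------------------------------------
    fits = {}
    if "fit" in config.stages:
        ss = np.random.SeedSequence([config.seed, 1])
        if config.fit_hierarchical:
            prior, fit_list = fitting.fit_hierarchical(
                cohort, seed=config.seed + 1, restarts=config.fit_restarts
            )
            with open(out / "group_prior.json", "w") as fh:
                json.dump(dict(stamp, mean=prior.mean.tolist(), sd=prior.sd.tolist()), fh)
        else:
            fit_list = [
                fitting.fit_subject(
                    s,
                    prior=fitting.GroupPrior(),
                    restarts=config.fit_restarts,
                    seed=int(np.random.default_rng(child).integers(2**31)),
                )
                for s, child in zip(cohort, ss.spawn(len(cohort)))
            ]
        fits = {s.subject_id: f for s, f in zip(cohort, fit_list)}
        with open(out / "fits.json", "w") as fh:
            json.dump(
                dict(
                    stamp,
                    subjects={
                        sid: dict(
                            params=vars(f.params),
                            nll=f.nll,
                            converged=f.converged,
                            n_trials_used=f.n_trials_used,
                            se_transformed=f.se.tolist(),
                        )
                        for sid, f in fits.items()
                    },
                ),
                fh,
                indent=1,
            )
        report["stages_run"].append("fit")

    # --- rpes -------------------------------------------------------------
    rpes: Dict[str, pd.DataFrame] = {}
    trajs = {}
    if "rpes" in config.stages:
        if not fits:
            raise RuntimeError("rpes stage requires the fit stage (or fits.json)")
        frames = []
        for sess in cohort:
            traj = fitting.latent_trajectory(fits[sess.subject_id].params, sess)
            trajs[sess.subject_id] = traj
            r = rpe_mod.compute_rpes(sess, traj)
            rpes[sess.subject_id] = r
            frames.append(r.assign(subject_id=sess.subject_id))
        pd.concat(frames).to_csv(out / "rpes.csv", index=False)
        report["stages_run"].append("rpes")

    # --- analyze ----------------------------------------------------------
    if "analyze" in config.stages:
        included, excl_report = stats.apply_exclusions(cohort, group=config.group)
        indices = stats.subject_indices(included)
        indices.to_csv(out / "indices.csv", index=False)
        stay_rows = []
        for sess in included:
            tab = stats.stay_table(sess)
            stay_rows.append(dict(subject=sess.subject_id, **tab.probs))
        pd.DataFrame(stay_rows).to_csv(out / "stay_tables.csv", index=False)
        regression = stats.stay_regression(included)
        anova = stats.ratings_anova(included)
        analysis = dict(
            stamp,
            exclusions=excl_report,
            stay_regression=regression.reset_index().to_dict(orient="records"),
            stay_regression_method=regression.attrs.get("method"),
            ratings_anova=anova.reset_index().to_dict(orient="records"),
        )
        if rpes:
            changes = pd.concat(
                [
                    stats.extract_rating_changes(s, rpes[s.subject_id])
                    for s in included
                ],
                ignore_index=True,
            )
            changes.to_csv(out / "rating_changes.csv", index=False)
            if len(changes) >= 10:
                analysis["stepwise"] = rpe_stepwise_jsonable(stats.rpe_stepwise(changes))
                curve = stats.quantile_bin_curve(changes)
                curve.to_csv(out / "quantile_curve.csv", index=False)
        with open(out / "analysis.json", "w") as fh:
            json.dump(analysis, fh, indent=1, default=_json_default)
        report["stages_run"].append("analyze")
        report["exclusions"] = excl_report

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    return report


def rpe_stepwise_jsonable(rep: Dict) -> Dict:
    """Strip non-serialisable values from a stepwise report."""
    return json.loads(json.dumps(rep, default=_json_default))
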