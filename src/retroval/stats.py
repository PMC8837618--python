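"""Behavioural analysis stages for the two-stage task with rating probes.

Covers the one-trial-back stay-switch analysis and its mixed logistic
regression, the four summary indices

    Choice_MB  = stay[(CR + RU) − (CU + RR)]
    Choice_MF  = stay[(CR + RR) − (CU + RU)]
    Ratings_MB = ratings[(CR + RU) − (CU + RR)]
    Ratings_MF = ratings[(CR + RR) − (CU + RU)]

(C/R = common/rare transition, R/U = rewarded/unrewarded, on the previous
trial for stay probabilities and on the last trial the rated shape was chosen
for ratings), the within-subject percentile ranking of raw ratings, the mixed
ANOVA on condition-mean percentiles, rating-change extraction, the stepwise
comparison of the four candidate RPEs as predictors of rating change, the
quantile-binned visualisation curve, cohort exclusions, and the auxiliary
(location/shape stay, attention, forward-planning and intervening-trial
control, cross-cohort correlation) analyses.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logit

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM

from .task import SessionLog

logger = logging.getLogger(__name__)

CONDITIONS = ("CR", "CU", "RR", "RU")
RPE_COLUMNS = ("tde_s1", "tde_s2", "mf_dq", "mb_dq")

__all__ = [
    "StayTable",
    "IndexSet",
    "stay_table",
    "choice_indices",
    "stay_regression",
    "rank_ratings",
    "attribute_rating_conditions",
    "ratings_indices",
    "ratings_anova",
    "extract_rating_changes",
    "rpe_stepwise",
    "quantile_bin_curve",
    "apply_exclusions",
    "subject_indices",
    "auxiliary_analyses",
    "cross_experiment_correlation",
    "probe_distances",
]


def _condition(transition: str, reward: int) -> str:
    return ("C" if transition == "common" else "R") + ("R" if reward else "U")


@dataclass
class StayTable:
    """Per-subject stay probabilities in the four previous-trial conditions."""

    probs: Dict[str, float]  # condition -> stay probability (NaN if empty)
    counts: Dict[str, int]  # condition -> number of usable pairs

    def cell(self, cond: str) -> float:
        return self.probs.get(cond, float("nan"))


@dataclass
class IndexSet:
    """The four per-subject summary indices."""

    choice_mb: float
    choice_mf: float
    ratings_mb: float
    ratings_mf: float


def _consecutive_pairs(session: SessionLog):
    """Pairs of adjacent non-aborted trials (prev, cur)."""
    trials = session.trials
    for prev, cur in zip(trials, trials[1:]):
        if prev.aborted or cur.aborted:
            continue
        yield prev, cur


def stay_table(session: SessionLog) -> StayTable:
    """One-trial-back stay probabilities split by the previous trial's
    transition and reward.  Stay is defined on the chosen *colour*."""
    stays: Dict[str, List[int]] = {c: [] for c in CONDITIONS}
    n_pairs = 0
    for prev, cur in _consecutive_pairs(session):
        n_pairs += 1
        cond = _condition(prev.transition, prev.reward)
        stays[cond].append(int(cur.chosen_colour == prev.chosen_colour))
    if n_pairs == 0:
        raise ValueError("need at least 2 consecutive non-aborted trials")
    probs = {c: (float(np.mean(v)) if v else float("nan")) for c, v in stays.items()}
    counts = {c: len(v) for c, v in stays.items()}
    return StayTable(probs=probs, counts=counts)


def choice_indices(table: StayTable) -> Tuple[float, float]:
    """Model-based and model-free choice indices from a stay table."""
    cr, cu, rr, ru = (table.cell(c) for c in CONDITIONS)
    choice_mb = (cr + ru) - (cu + rr)
    choice_mf = (cr + rr) - (cu + ru)
    return float(choice_mb), float(choice_mf)


# ---------------------------------------------------------------------------
# mixed logistic stay regression


def _stay_frame(cohort: Sequence[SessionLog], stay_unit: str = "colour") -> pd.DataFrame:
    """Trial-level frame of stay outcomes with ±1-coded previous-trial factors."""
    rows = []
    for sess in cohort:
        for prev, cur in _consecutive_pairs(sess):
            if stay_unit == "colour":
                stay = int(cur.chosen_colour == prev.chosen_colour)
            elif stay_unit == "side":
                stay = int(cur.chosen_side == prev.chosen_side)
            else:
                raise ValueError(f"unknown stay unit {stay_unit!r}")
            rows.append(
                dict(
                    subject=sess.subject_id,
                    stay=stay,
                    reward=1.0 if prev.reward else -1.0,
                    transition=1.0 if prev.transition == "common" else -1.0,
                    attention=1.0 if prev.attention_probe else -1.0,
                )
            )
    df = pd.DataFrame(rows)
    df["rew_x_trans"] = df.reward * df.transition
    df["att_x_rew"] = df.attention * df.reward
    df["att_x_rew_x_trans"] = df.attention * df.rew_x_trans
    return df


def _cluster_logit(df: pd.DataFrame, terms: List[str]) -> pd.DataFrame:
    X = sm.add_constant(df[terms])
    model = sm.GLM(df.stay, X, family=sm.families.Binomial())
    res = model.fit(cov_type="cluster", cov_kwds={"groups": df.subject})
    out = pd.DataFrame(
        dict(coef=res.params, se=res.bse, z=res.tvalues, p=res.pvalues)
    )
    out.index.name = "term"
    return out


def stay_regression(
    cohort: Sequence[SessionLog],
    include_attention: bool = False,
    stay_unit: str = "colour",
    method: str = "mixed",
) -> pd.DataFrame:
    """Mixed-effects logistic regression of stay on previous-trial factors.

    Fixed effects: reward, transition and their interaction (±1 coding), plus
    attention interactions when requested.  Random effects: per-subject
    intercepts and slopes, fitted by variational Bayes; a singular or failed
    fit falls back to random intercepts only, then to a cluster-robust
    population-level logit (logged).  Returns a coefficient table with z
    statistics; the fallback used is recorded in ``df.attrs["method"]``.
    """
    df = _stay_frame(cohort, stay_unit=stay_unit)
    terms = ["reward", "transition", "rew_x_trans"]
    if include_attention:
        terms += ["attention", "att_x_rew", "att_x_rew_x_trans"]
    if method == "cluster":
        out = _cluster_logit(df, terms)
        out.attrs["method"] = "cluster"
        return out

    formula = "stay ~ " + " + ".join(terms)
    vc_full = {"icpt": "0 + C(subject)"}
    for term in terms:
        vc_full[f"s_{term}"] = f"0 + C(subject):{term}"
    vc_icpt = {"icpt": "0 + C(subject)"}
    for label, vcf in (("mixed-slopes", vc_full), ("mixed-intercept", vc_icpt)):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = BinomialBayesMixedGLM.from_formula(formula, vcf, df)
                res = model.fit_vb()
            k = len(terms) + 1
            coefs = res.fe_mean[:k]
            ses = res.fe_sd[:k]
            if not np.all(np.isfinite(coefs)) or not np.all(ses > 1e-8):
                raise RuntimeError("degenerate posterior")
            names = ["const"] + terms
            out = pd.DataFrame(
                dict(
                    coef=coefs,
                    se=ses,
                    z=coefs / ses,
                    p=2 * sps.norm.sf(np.abs(coefs / ses)),
                ),
                index=pd.Index(names, name="term"),
            )
            out.attrs["method"] = label
            return out
        except Exception as exc:  # noqa: BLE001 - fall through to simpler model
            logger.warning("%s stay regression failed (%s); falling back", label, exc)
    out = _cluster_logit(df, terms)
    out.attrs["method"] = "cluster-fallback"
    logger.warning("mixed stay regression singular; reporting cluster-robust logit")
    return out


# ---------------------------------------------------------------------------
# ratings


def rank_ratings(session: SessionLog) -> pd.DataFrame:
    """Within-subject percentile transform of the raw ratings.

    Average ranks for ties, mapped to (rank − 0.5)/n × 100 so a constant
    rater sits at the 50th percentile everywhere (such raters are flagged by
    the SD exclusion, not here).
    """
    rows = [
        (tr.t, tr.rated_shape, tr.rating_raw)
        for tr in session.usable_trials()
        if tr.rated_shape is not None
    ]
    if len(rows) < 2:
        raise ValueError("need at least 2 ratings to rank")
    df = pd.DataFrame(rows, columns=["t", "shape", "raw"])
    ranks = sps.rankdata(df.raw.to_numpy(), method="average")
    df["percentile"] = (ranks - 0.5) / len(ranks) * 100.0
    return df


def attribute_rating_conditions(session: SessionLog) -> pd.DataFrame:
    """Attach each rating to the last trial its shape was chosen at stage 1.

    Ratings of shapes never previously chosen are excluded.  Adds the
    condition (CR/CU/RR/RU) of that choice trial, its index ``t_choice``, its
    attention flag, and the probe distance ``t − t_choice``.
    """
    ranked = rank_ratings(session)
    usable = session.usable_trials()
    chosen_at: Dict[int, List] = {}
    by_t = {tr.t: tr for tr in usable}
    for tr in usable:
        chosen_at.setdefault(tr.chosen_shape, []).append(tr.t)
    out = []
    for row in ranked.itertuples():
        past = [t for t in chosen_at.get(int(row.shape), []) if t < row.t]
        if not past:
            continue
        tc = max(past)
        ch = by_t[tc]
        out.append(
            dict(
                t=row.t,
                shape=int(row.shape),
                percentile=row.percentile,
                raw=row.raw,
                cond=_condition(ch.transition, ch.reward),
                t_choice=tc,
                distance=row.t - tc,
                attention=bool(ch.attention_probe),
            )
        )
    return pd.DataFrame(
        out,
        columns=[
            "t",
            "shape",
            "percentile",
            "raw",
            "cond",
            "t_choice",
            "distance",
            "attention",
        ],
    )


def ratings_indices(session: SessionLog) -> Tuple[float, float]:
    """Model-based and model-free transfer indices (percentile units)."""
    attr = attribute_rating_conditions(session)
    means = attr.groupby("cond")["percentile"].mean()
    cr, cu, rr, ru = (means.get(c, float("nan")) for c in CONDITIONS)
    ratings_mb = (cr + ru) - (cu + rr)
    ratings_mf = (cr + rr) - (cu + ru)
    return float(ratings_mb), float(ratings_mf)


def _condition_means(cohort: Sequence[SessionLog]) -> pd.DataFrame:
    rows = []
    for sess in cohort:
        attr = attribute_rating_conditions(sess)
        means = attr.groupby("cond")["percentile"].mean()
        for cond in CONDITIONS:
            if cond in means.index:
                rows.append(
                    dict(
                        subject=sess.subject_id,
                        cond=cond,
                        value=float(means[cond]),
                        reward=1.0 if cond[1] == "R" else -1.0,
                        transition=1.0 if cond[0] == "C" else -1.0,
                    )
                )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["rew_x_trans"] = df.reward * df.transition
    return df


def ratings_anova(
    cohort: Sequence[SessionLog], values: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Mixed-effects ANOVA of condition-mean rating percentiles.

    Fixed factors reward, transition and their interaction on the per-subject
    condition means, with a per-subject random intercept (with one mean per
    cell the subject-level slopes are saturated, so the random part reduces
    to the intercept).  F is the squared Wald statistic on (1, N − 4) df.
    """
    df = _condition_means(cohort) if values is None else values
    if df.subject.nunique() < 2:
        raise ValueError("need at least 2 subjects")
    terms = ["reward", "transition", "rew_x_trans"]
    X = sm.add_constant(df[terms])
    df2 = max(len(df) - 4, 1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(df.value, X, groups=df.subject)
            res = model.fit(reml=True)
        coefs, ses = res.fe_params, res.bse_fe
        method = "mixedlm-intercept"
    except Exception as exc:  # noqa: BLE001
        logger.warning("MixedLM failed (%s); falling back to OLS", exc)
        res = sm.OLS(df.value, X).fit()
        coefs, ses = res.params, res.bse
        method = "ols-fallback"
    out_rows = []
    for term in terms:
        z = coefs[term] / ses[term]
        F = float(z**2)
        out_rows.append(
            dict(term=term, coef=float(coefs[term]), F=F, df1=1, df2=df2,
                 p=float(sps.f.sf(F, 1, df2)))
        )
    out = pd.DataFrame(out_rows).set_index("term")
    out.attrs["method"] = method
    return out


# ---------------------------------------------------------------------------
# rating changes and the stepwise RPE comparison


def extract_rating_changes(session: SessionLog, rpes: pd.DataFrame) -> pd.DataFrame:
    """Rating changes bracketing single stage-1 choices of a shape.

    For each pair of consecutive ratings of the same shape with *exactly one*
    stage-1 choice of that shape in between, emit the change in percentile
    rating together with the four RPEs at that choice trial.  Pairs whose
    interval contains no choice, or more than one, are dropped.
    """
    full_ranked = rank_ratings(session)
    rpes_by_t = rpes.set_index("t")
    usable = session.usable_trials()
    by_t = {tr.t: tr for tr in usable}
    choices: Dict[int, List[int]] = {}
    for tr in usable:
        choices.setdefault(tr.chosen_shape, []).append(tr.t)

    out = []
    for shape, grp in full_ranked.groupby("shape"):
        times = grp.sort_values("t")
        tlist = times.t.to_list()
        plist = times.percentile.to_list()
        for (tp, pp), (tn, pn) in zip(zip(tlist, plist), zip(tlist[1:], plist[1:])):
            between = [c for c in choices.get(int(shape), []) if tp < c < tn]
            if len(between) != 1:
                continue
            tc = between[0]
            if tc not in rpes_by_t.index:
                continue
            r = rpes_by_t.loc[tc]
            ch = by_t[tc]
            out.append(
                dict(
                    subject=session.subject_id,
                    shape=int(shape),
                    t_choice=tc,
                    t_prev_rating=tp,
                    t_next_rating=tn,
                    cond=_condition(ch.transition, ch.reward),
                    tde_s1=float(r.tde_s1),
                    tde_s2=float(r.tde_s2),
                    mf_dq=float(r.mf_dq),
                    mb_dq=float(r.mb_dq),
                    delta_rank=float(pn - pp),
                )
            )
    return pd.DataFrame(
        out,
        columns=[
            "subject",
            "shape",
            "t_choice",
            "t_prev_rating",
            "t_next_rating",
            "cond",
            *RPE_COLUMNS,
            "delta_rank",
        ],
    )


def _loglik_ols(y: np.ndarray, X: np.ndarray) -> Tuple[float, float, int]:
    """(loglik, F vs intercept-only, k params) of an OLS fit."""
    res = sm.OLS(y, X).fit()
    return float(res.llf), float(res.fvalue) if X.shape[1] > 1 else float("nan"), X.shape[1]


def rpe_stepwise(changes: pd.DataFrame, alpha: float = 0.05, variants: bool = True) -> Dict:
    """Forward stepwise comparison of the four RPEs as predictors of rating
    change.

    Each RPE is fitted as the single predictor of ``delta_rank``; the best
    (highest likelihood) candidate is entered if its F test against the
    intercept-only null passes ``alpha``.  AIC and natural-log likelihood
    ratios are reported for all candidates, and (with ``variants=True``) the
    selection is repeated with a per-subject random intercept and with random
    slope + intercept.  A second forward step is attempted and halted on
    collinearity.
    """
    if len(changes) < 10:
        raise ValueError("need at least 10 rating changes")
    y = changes.delta_rank.to_numpy()
    n = len(y)
    null = sm.OLS(y, np.ones((n, 1))).fit()
    report: Dict = {"n_changes": n, "candidates": {}}

    logliks = {}
    for col in RPE_COLUMNS:
        X = sm.add_constant(changes[col].to_numpy())
        res = sm.OLS(y, X).fit()
        logliks[col] = res.llf
        report["candidates"][col] = dict(
            coef=float(res.params[1]),
            t=float(res.tvalues[1]),
            loglik=float(res.llf),
            aic=float(res.aic),
            f_vs_null=float(res.fvalue),
            p_vs_null=float(res.f_pvalue),
        )
    best = max(logliks, key=logliks.get)
    entered = report["candidates"][best]["p_vs_null"] < alpha
    report["selected"] = best if entered else None
    report["f_selected"] = report["candidates"][best]["f_vs_null"]
    report["p_selected"] = report["candidates"][best]["p_vs_null"]
    report["df"] = (1, n - 2)
    # pairwise natural-log likelihood ratios (row minus column)
    report["loglik_ratios"] = {
        a: {b: float(logliks[a] - logliks[b]) for b in RPE_COLUMNS} for a in RPE_COLUMNS
    }

    # second forward step from the selected predictor
    report["second_step"] = None
    if entered:
        base_cols = [best]
        best2, best2_res = None, None
        for col in RPE_COLUMNS:
            if col == best:
                continue
            X2 = sm.add_constant(changes[base_cols + [col]].to_numpy())
            cond = np.linalg.cond(X2)
            if cond > 1e6:
                report["second_step"] = dict(halted="collinearity", candidate=col)
                break
            res2 = sm.OLS(y, X2).fit()
            if best2 is None or res2.llf > best2_res.llf:
                best2, best2_res = col, res2
        else:
            if best2 is not None:
                base = sm.OLS(y, sm.add_constant(changes[base_cols].to_numpy())).fit()
                lr = 2 * (best2_res.llf - base.llf)
                p2 = float(sps.chi2.sf(lr, 1))
                report["second_step"] = dict(
                    candidate=best2, lr=float(lr), p=p2, entered=bool(p2 < alpha)
                )

    # random-effect variants
    variant_specs = (
        (("random_intercept", None), ("random_slope_intercept", "~x")) if variants else ()
    )
    for label, re_formula in variant_specs:
        sel, best_ll, aics = None, -np.inf, {}
        try:
            for col in RPE_COLUMNS:
                d = changes[["subject", col, "delta_rank"]].rename(columns={col: "x"})
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    md = smf.mixedlm(
                        "delta_rank ~ x", d, groups=d.subject, re_formula=re_formula
                    )
                    res = md.fit(reml=False)
                aics[col] = float(2 * (res.df_modelwc) - 2 * res.llf)
                if res.llf > best_ll:
                    best_ll, sel = res.llf, col
            report[label] = dict(selected=sel, aic=aics)
        except Exception as exc:  # noqa: BLE001
            logger.warning("%s stepwise variant failed: %s", label, exc)
            report[label] = dict(selected=None, error=str(exc))
    report["aic_fixed"] = {c: report["candidates"][c]["aic"] for c in RPE_COLUMNS}
    return report


def quantile_bin_curve(
    changes: pd.DataFrame,
    predictor: str = "mb_dq",
    window: float = 20.0,
    step: float = 5.0,
) -> pd.DataFrame:
    """Sliding-window quantile curve of rating change against an RPE.

    Within each subject the predictor is percentile-ranked and rating changes
    are averaged in sliding windows ``window`` percentiles wide; window
    centres run from ``window/2`` to ``100 − window/2`` in steps of ``step``.
    Returns the across-subject mean and SEM per window centre.
    """
    if changes.empty:
        raise ValueError("no rating changes")
    centres = np.arange(window / 2, 100 - window / 2 + 1e-9, step)
    per_subject = []
    for _, grp in changes.groupby("subject"):
        if len(grp) < 5:
            continue
        x = grp[predictor].to_numpy()
        pct = (sps.rankdata(x, method="average") - 0.5) / len(x) * 100.0
        means = [
            grp.delta_rank.to_numpy()[np.abs(pct - c) <= window / 2].mean()
            if np.any(np.abs(pct - c) <= window / 2)
            else np.nan
            for c in centres
        ]
        per_subject.append(means)
    if not per_subject:
        raise ValueError("need at least 1 subject with >= 5 changes")
    arr = np.array(per_subject, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = np.nanmean(arr, axis=0)
        n_eff = np.sum(np.isfinite(arr), axis=0)
        sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    return pd.DataFrame(dict(centre=centres, mean=mean, sem=sem, n_subjects=n_eff))


# ---------------------------------------------------------------------------
# exclusions and per-subject summaries


def _rating_sd(session: SessionLog) -> float:
    raw = [tr.rating_raw for tr in session.usable_trials() if tr.rating_raw is not None]
    return float(np.std(raw, ddof=1)) if len(raw) >= 2 else float("nan")


def subject_indices(cohort: Sequence[SessionLog]) -> pd.DataFrame:
    """Per-subject summary: the four indices plus the raw-rating SD."""
    rows = []
    for sess in cohort:
        mb, mf = choice_indices(stay_table(sess))
        try:
            rmb, rmf = ratings_indices(sess)
        except ValueError:
            rmb = rmf = float("nan")
        rows.append(
            dict(
                subject=sess.subject_id,
                group=sess.group,
                choice_mb=mb,
                choice_mf=mf,
                ratings_mb=rmb,
                ratings_mf=rmf,
                rating_sd_raw=_rating_sd(sess),
            )
        )
    return pd.DataFrame(rows)


def apply_exclusions(
    cohort: Sequence[SessionLog],
    group: str,
    sd_threshold: float = 20.0,
    extra_excluded: Optional[Dict[str, str]] = None,
) -> Tuple[List[SessionLog], Dict]:
    """Apply the cohort exclusion rules.

    The explicit group drops subjects whose Choice_MB index is not positive
    (not model-based) and subjects whose raw-rating standard deviation falls
    below ``sd_threshold`` raw units; the implicit group applies no
    model-based filter (all participants analysed) but still screens
    near-constant raters.  ``extra_excluded`` maps subject ids to reasons
    decided upstream (e.g. a corrupt file).  The population-relative
    threshold (2.4 SD below the cohort mean rating-SD) is reported for
    comparison, not enforced.
    """
    extra_excluded = dict(extra_excluded or {})
    summary = subject_indices(cohort)
    exclusions = [dict(subject=s, reason=r) for s, r in extra_excluded.items()]
    included: List[SessionLog] = []
    n_model_based = 0
    for sess, row in zip(cohort, summary.itertuples()):
        if sess.subject_id in extra_excluded:
            continue
        model_based = row.choice_mb > 0
        n_model_based += int(model_based)
        if group == "explicit" and not model_based:
            exclusions.append(dict(subject=sess.subject_id, reason="not_model_based"))
            continue
        if np.isfinite(row.rating_sd_raw) and row.rating_sd_raw < sd_threshold:
            exclusions.append(dict(subject=sess.subject_id, reason="low_rating_sd"))
            continue
        included.append(sess)
    sds = summary.rating_sd_raw.to_numpy()
    rel_thresh = float(np.nanmean(sds) - 2.4 * np.nanstd(sds, ddof=1)) if len(sds) > 1 else float("nan")
    report = dict(
        group=group,
        n_input=len(cohort),
        n_included=len(included),
        n_model_based=n_model_based,
        exclusions=exclusions,
        sd_threshold=sd_threshold,
        relative_sd_threshold_2p4=rel_thresh,
    )
    return included, report


def probe_distances(cohort: Sequence[SessionLog]) -> np.ndarray:
    """Distances (in trials) between a shape's last stage-1 choice and its
    rating probe, pooled over the cohort."""
    out = []
    for sess in cohort:
        attr = attribute_rating_conditions(sess)
        out.extend(attr.distance.to_list())
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# auxiliary analyses


def _shape_stay_frame(cohort: Sequence[SessionLog]) -> pd.DataFrame:
    """Stay on the chosen irrelevant shape, evaluated at the next trial where
    that shape is offered again (shapes never repeat on the very next trial)."""
    rows = []
    for sess in cohort:
        usable = sess.usable_trials()
        for i, tr in enumerate(usable):
            nxt = next(
                (u for u in usable[i + 1 :] if tr.chosen_shape in u.offered_shapes),
                None,
            )
            if nxt is None:
                continue
            rows.append(
                dict(
                    subject=sess.subject_id,
                    stay=int(nxt.chosen_shape == tr.chosen_shape),
                    reward=1.0 if tr.reward else -1.0,
                    transition=1.0 if tr.transition == "common" else -1.0,
                )
            )
    df = pd.DataFrame(rows)
    df["rew_x_trans"] = df.reward * df.transition
    return df


def auxiliary_analyses(
    cohort: Sequence[SessionLog],
    trajectories: Optional[Dict[str, object]] = None,
) -> Dict:
    """The control analyses around the core pipeline.

    - location (side) stay regression and irrelevant-shape stay regression;
    - attention 2×2 on ratings (attention minus no-attention condition means);
    - forward-planning check: do the *rating trial's* own reward/transition
      predict the rating (they should not if ratings reflect value at choice);
    - intervening-trial check: does the change in the modelled (planning)
      value of the chosen colour between choice and rating predict the
      rating change (requires per-subject latent ``trajectories``);
    """
    report: Dict = {}
    report["location_stay"] = stay_regression(cohort, stay_unit="side", method="cluster")

    shp = _shape_stay_frame(cohort)
    if len(shp) >= 10 and shp.stay.nunique() > 1:
        report["shape_stay"] = _cluster_logit(shp, ["reward", "transition", "rew_x_trans"])
    else:
        logger.warning("shape-stay analysis skipped: insufficient data")
        report["shape_stay"] = None

    # attention effect: difference of condition means, attention minus not
    rows = []
    for sess in cohort:
        attr = attribute_rating_conditions(sess)
        for cond in CONDITIONS:
            sub = attr[attr.cond == cond]
            a = sub[sub.attention].percentile.mean()
            na = sub[~sub.attention].percentile.mean()
            if np.isfinite(a) and np.isfinite(na):
                rows.append(
                    dict(
                        subject=sess.subject_id,
                        cond=cond,
                        value=float(a - na),
                        reward=1.0 if cond[1] == "R" else -1.0,
                        transition=1.0 if cond[0] == "C" else -1.0,
                    )
                )
    att = pd.DataFrame(rows)
    if len(att) >= 8 and att.subject.nunique() >= 2:
        att["rew_x_trans"] = att.reward * att.transition
        report["attention_anova"] = ratings_anova(cohort, values=att)
    else:
        logger.warning("attention analysis skipped: insufficient data")
        report["attention_anova"] = None

    # forward-planning check: current rating-trial outcome -> rating
    rows = []
    for sess in cohort:
        attr = attribute_rating_conditions(sess)
        by_t = {tr.t: tr for tr in sess.usable_trials()}
        for r in attr.itertuples():
            cur = by_t[r.t]
            rows.append(
                dict(
                    subject=sess.subject_id,
                    value=r.percentile,
                    reward=1.0 if cur.reward else -1.0,
                    transition=1.0 if cur.transition == "common" else -1.0,
                )
            )
    cur_df = pd.DataFrame(rows)
    cur_df["rew_x_trans"] = cur_df.reward * cur_df.transition
    X = sm.add_constant(cur_df[["reward", "transition", "rew_x_trans"]])
    res = sm.GLM(cur_df.value, X).fit(
        cov_type="cluster", cov_kwds={"groups": cur_df.subject}
    )
    report["current_trial_outcome"] = pd.DataFrame(
        dict(coef=res.params, se=res.bse, z=res.tvalues, p=res.pvalues)
    )

    # intervening-trial value-change check
    report["intervening_value_change"] = None
    if trajectories:
        rows = []
        for sess in cohort:
            traj = trajectories.get(sess.subject_id)
            if traj is None:
                continue
            usable = sess.usable_trials()
            t_to_idx = {tr.t: i for i, tr in enumerate(usable)}
            by_t = {tr.t: tr for tr in usable}
            attr = attribute_rating_conditions(sess)
            ranked = rank_ratings(session=sess)
            pct_by_t = dict(zip(ranked.t, ranked.percentile))
            for r in attr.itertuples():
                if r.t_choice not in t_to_idx or r.t not in t_to_idx:
                    continue
                colour = by_t[r.t_choice].chosen_colour
                dv = float(
                    traj.q_mb_s1[t_to_idx[r.t], colour]
                    - traj.q_mb_s1[t_to_idx[r.t_choice], colour]
                )
                rows.append(
                    dict(subject=sess.subject_id, value=pct_by_t[r.t], dv=dv)
                )
        iv = pd.DataFrame(rows)
        if len(iv) >= 10 and iv.dv.std() > 0:
            X = sm.add_constant(iv[["dv"]])
            res = sm.GLM(iv.value, X).fit(
                cov_type="cluster", cov_kwds={"groups": iv.subject}
            )
            report["intervening_value_change"] = pd.DataFrame(
                dict(coef=res.params, se=res.bse, z=res.tvalues, p=res.pvalues)
            )
        else:
            logger.warning("intervening-trial analysis skipped: insufficient data")
    return report


def cross_experiment_correlation(indices: pd.DataFrame) -> pd.DataFrame:
    """Correlations between (log-odds transformed) choice indices and the
    ratings-transfer indices across pooled subjects.

    The choice indices live on [−2, 2]; they are mapped to (0, 1) via
    ``(x + 2)/4`` and logit-transformed before the Pearson correlations.
    """
    df = indices.dropna(subset=["choice_mb", "choice_mf", "ratings_mb", "ratings_mf"])
    eps = 1e-6
    tf = lambda x: logit(np.clip((x + 2.0) / 4.0, eps, 1 - eps))
    rows = []
    for cname in ("choice_mb", "choice_mf"):
        for rname in ("ratings_mb", "ratings_mf"):
            r, p = sps.pearsonr(tf(df[cname].to_numpy()), df[rname].to_numpy())
            rows.append(dict(choice=cname, ratings=rname, r=float(r), p=float(p), n=len(df)))
    return pd.DataFrame(rows)
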