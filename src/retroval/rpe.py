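"""The four candidate trial-wise reward prediction errors.

For each completed trial we compute, from the value snapshots taken *before*
any of the trial's updates are applied:

- ``tde_s1``: temporal-difference error at the stage-2 reveal,
  ``Q_s2[chosen s2 shape] − Q_mf_s1[chosen colour]``.
- ``tde_s2``: temporal-difference error at outcome, ``r − Q_s2[chosen s2 shape]``.
- ``mf_dq``:  retrospective model-free error, ``r − Q_mf_s1[retro colour]``.
- ``mb_dq``:  retrospective model-based error, ``r − Q_mb_s1[retro colour]``,
  where ``Q_mb_s1`` is the forward-planning value recomputed from the same
  stage-2 value snapshot.

The *retrospective colour* is the colour whose common transition leads to the
second-stage state actually experienced: on a common trial it is the chosen
colour, on a rare trial the unchosen one.  The two retrospective errors credit
the action that most likely *would have* produced the observed state — the
model-based teaching signal the ratings analysis is designed to detect.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .task import SessionLog, common_destination

RULES = ("TDE_S1", "TDE_S2", "MFdQ", "MBdQ")

__all__ = ["RULES", "plan_values", "trial_rpes", "compute_rpes", "rpe_correlation_report"]


def plan_values(q_s2: np.ndarray, p_common: float) -> np.ndarray:
    """Forward-planning (model-based) stage-1 colour values.

    ``q_mb(c) = p_common * max(q_s2 of c's common state pair)
              + (1 − p_common) * max(q_s2 of the other pair)``
    """
    best = np.array([max(q_s2[0], q_s2[1]), max(q_s2[2], q_s2[3])])
    out = np.empty(2)
    for c in (0, 1):
        d = common_destination(c)
        out[c] = p_common * best[d] + (1.0 - p_common) * best[1 - d]
    return out


def trial_rpes(
    q_mf_s1: np.ndarray,
    q_s2: np.ndarray,
    p_common: float,
    chosen_colour: int,
    s2_state: int,
    s2_chosen_shape: int,
    reward: float,
) -> Tuple[float, float, float, float, int]:
    """All four RPEs for one trial from pre-update value snapshots.

    Returns ``(tde_s1, tde_s2, mf_dq, mb_dq, retro_colour)``.
    """
    retro_colour = int(s2_state)  # colour whose common destination == s2_state
    tde_s1 = float(q_s2[s2_chosen_shape] - q_mf_s1[chosen_colour])
    tde_s2 = float(reward - q_s2[s2_chosen_shape])
    mf_dq = float(reward - q_mf_s1[retro_colour])
    q_mb = plan_values(q_s2, p_common)
    mb_dq = float(reward - q_mb[retro_colour])
    return tde_s1, tde_s2, mf_dq, mb_dq, retro_colour


def compute_rpes(session: SessionLog, traj) -> pd.DataFrame:
    """Per-trial RPE table for a session given its latent value trajectory.

    ``traj`` is a :class:`~retroval.fitting.QTrajectory` aligned to the
    session's non-aborted trials.  Returns a DataFrame with columns
    ``t, tde_s1, tde_s2, mf_dq, mb_dq, retro_colour``.
    """
    usable = session.usable_trials()
    if len(usable) != traj.n_trials:
        raise ValueError(
            f"trajectory length {traj.n_trials} does not match "
            f"{len(usable)} non-aborted trials"
        )
    p_common = session.config.p_common
    rows = []
    for i, tr in enumerate(usable):
        tde1, tde2, mfdq, mbdq, retro = trial_rpes(
            traj.q_mf_s1[i],
            traj.q_s2[i],
            p_common,
            tr.chosen_colour,
            tr.s2_state,
            tr.s2_chosen_shape,
            tr.reward,
        )
        rows.append(
            dict(t=tr.t, tde_s1=tde1, tde_s2=tde2, mf_dq=mfdq, mb_dq=mbdq, retro_colour=retro)
        )
    return pd.DataFrame(rows)


def rpe_correlation_report(records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between the four RPE series.

    Constant columns yield missing (NaN) entries off the diagonal.
    """
    cols = ["tde_s1", "tde_s2", "mf_dq", "mb_dq"]
    if len(records) < 3:
        raise ValueError("need at least 3 records for a correlation report")
    mat = records[cols].corr()
    np.fill_diagonal(mat.values, 1.0)
    return mat
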