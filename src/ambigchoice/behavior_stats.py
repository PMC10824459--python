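"""Descriptive behavioural statistics.

The task misaligns probabilities and rewards, so the rate at which a
subject chooses the objectively more probable (lower-reward) option
measures probability-guided choice; its drop from the no-ambiguity to
the ambiguity condition is the per-subject decision shift.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)


def _prepare(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["choice"].isna().any():
        raise ValueError("dataset contains trials without a choice")
    # "highest probability" by objective probability; visible ranking is
    # used when objective columns are absent (external data)
    if "p_obj_left" in df:
        left_p, right_p = df["p_obj_left"], df["p_obj_right"]
    else:
        left_p, right_p = df["p_obs_left"], df["p_obs_right"]
    ties = left_p == right_p
    if ties.any():
        logger.info("excluding %d trials with tied probabilities", int(ties.sum()))
        df = df[~ties]
        left_p, right_p = left_p[~ties], right_p[~ties]
    df["higher_side"] = np.where(left_p > right_p, "left", "right")
    df["chose_higher"] = (df["choice"] == df["higher_side"]).astype(float)
    return df


def highest_prob_rate(
    df: pd.DataFrame,
    condition: str | None = None,
    by_level: bool = False,
) -> pd.Series | pd.DataFrame:
    """Per-subject rate of choosing the objectively more probable option.

    ``condition`` filters to "ambiguity" or "no-ambiguity"; ``by_level``
    groups by ambiguity degree ``p_a`` instead (one row per subject and
    level).
    """
    df = _prepare(df)
    if condition is not None:
        df = df[df["condition"] == condition]
    if len(df) == 0:
        raise ValueError("no trials left after filtering")
    if by_level:
        out = df.groupby(["subject", "p_a"])["chose_higher"].mean()
        return out.rename("rate").reset_index()
    return df.groupby("subject")["chose_higher"].mean().rename("rate")


def decision_shift(df: pd.DataFrame) -> pd.Series:
    """Per-subject shift: ambiguity rate minus no-ambiguity rate.

    Negative values mean the subject abandons the more probable option
    under ambiguity.  Subjects missing either condition are excluded.
    """
    amb = highest_prob_rate(df, "ambiguity")
    noamb = highest_prob_rate(df, "no-ambiguity")
    common = amb.index.intersection(noamb.index)
    dropped = set(amb.index).symmetric_difference(noamb.index)
    if dropped:
        logger.info("excluding subjects missing a condition: %s", sorted(dropped))
    return (amb[common] - noamb[common]).rename("shift")


def shift_by_degree(df: pd.DataFrame):
    """Choice rate per ambiguity level and its rank correlation.

    Returns ``(table, rho_cells, rho_levels)``: per-(subject, level)
    rates, the Spearman correlation over subject-level cells, and the
    Spearman correlation over level means.
    """
    amb = df[df["condition"] == "ambiguity"]
    if amb["p_a"].nunique() < 2:
        raise ValueError("need >= 2 ambiguity levels")
    table = highest_prob_rate(amb, by_level=True)
    rho_cells = float(spearmanr(table["p_a"], table["rate"]).statistic)
    level_means = table.groupby("p_a")["rate"].mean()
    rho_levels = float(spearmanr(level_means.index, level_means.values).statistic)
    if np.isnan(rho_cells) and np.allclose(table["rate"], table["rate"].iloc[0]):
        rho_cells = 0.0  # constant rates: no association
    if np.isnan(rho_levels) and np.allclose(level_means, level_means.iloc[0]):
        rho_levels = 0.0
    return table, rho_cells, rho_levels
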