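"""Reaction-time rank analysis of category exemplars.

Participants whose overall accuracy falls below a threshold are
dropped.  For each retained participant, the mean reaction time to
each instance (over its presentations, errors included) is ranked
within that participant's instances of the same class, ties receiving
midranks.  An instance is scored by a two-sided Welch t-test of its
ranks (one per participant who saw it) against the pooled ranks of
all same-class peer instances; instances with significantly low ranks
were answered fast ("easy"), high ranks slow ("hard").  Finally the
per-instance mean correct-response count is correlated (Spearman)
with the per-instance mean rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("glyphcurate")


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class InstanceScore:
    """RT-rank summary of one exemplar, pooled over participants."""

    instance_id: str
    class_label: int
    mean_rank: float
    t_stat: float
    p_value: float
    direction: str            # "easy" | "hard" | "neither"
    mean_correct: float       # mean over participants of per-participant correct counts
    n_zero_correct: int       # participants who never answered it correctly
    n_participants: int
    degenerate: bool = False


@dataclass(frozen=True)
class AccuracyRTResult:
    rho: float
    p_value: float
    defined: bool = True


def filter_participants(records, min_accuracy: float) -> list:
    """Participant ids whose fraction of correct trials is >= `min_accuracy`."""
    if not (0.0 <= min_accuracy <= 1.0):
        raise AnalysisError("min_accuracy must be in [0, 1]")
    tally = {}
    for r in records:
        c, n = tally.get(r.participant_id, (0, 0))
        tally[r.participant_id] = (c + int(r.correct), n + 1)
    retained = []
    for pid, (c, n) in sorted(tally.items()):
        if n == 0:
            logger.warning("participant %s has zero trials; excluded", pid)
            continue
        if c / n >= min_accuracy:
            retained.append(pid)
    return retained


def rank_within_class(records, participants, instances=None) -> pd.DataFrame:
    """Midrank each participant's per-instance mean RTs within class.

    Returns a table with columns participant_id, instance_id,
    class_label, mean_rt, rank.  `instances` (optional id -> class
    mapping or iterable of ids) declares the universe every retained
    participant must have seen; if omitted, each participant is ranked
    over the instances they actually saw.
    """
    keep = set(participants)
    rows = [(r.participant_id, r.instance_id, r.true_class, r.rt)
            for r in records if r.participant_id in keep]
    if not rows:
        raise AnalysisError("no trials from retained participants")
    df = pd.DataFrame(rows, columns=["participant_id", "instance_id",
                                     "class_label", "rt"])
    means = (df.groupby(["participant_id", "instance_id", "class_label"],
                        as_index=False)["rt"].mean()
               .rename(columns={"rt": "mean_rt"}))
    if instances is not None:
        required = set(instances)
        for pid, grp in means.groupby("participant_id"):
            missing = required - set(grp["instance_id"])
            if missing:
                raise AnalysisError(
                    f"participant {pid} never saw instance {sorted(missing)[0]}")
    means["rank"] = (means.groupby(["participant_id", "class_label"])["mean_rt"]
                          .transform(lambda v: stats.rankdata(v, method="average")))
    return means.sort_values(["participant_id", "class_label",
                              "instance_id"]).reset_index(drop=True)


def _correct_counts(records, participants):
    """Per (participant, instance) count of correct responses."""
    keep = set(participants)
    rows = [(r.participant_id, r.instance_id, int(r.correct))
            for r in records if r.participant_id in keep]
    df = pd.DataFrame(rows, columns=["participant_id", "instance_id", "correct"])
    return df.groupby(["participant_id", "instance_id"], as_index=False)["correct"].sum()


def score_instances(ranks: pd.DataFrame, records=None) -> list:
    """Welch t-test of each instance's ranks against pooled same-class peer ranks.

    When the trial `records` are supplied, per-instance correctness
    tallies (mean correct count and the number of participants who
    never answered the instance correctly) are attached; these feed
    the curation exclusion rule.
    """
    n_participants = ranks["participant_id"].nunique()
    corr = None
    if records is not None:
        participants = ranks["participant_id"].unique()
        cc = _correct_counts(records, participants)
        corr = cc.groupby("instance_id")["correct"].agg(
            mean_correct="mean", n_zero_correct=lambda v: int((v == 0).sum()))
    scores = []
    for cls, grp in ranks.groupby("class_label"):
        inst_ids = sorted(grp["instance_id"].unique())
        if len(inst_ids) < 2:
            raise AnalysisError(f"class {cls}: need >= 2 instances to score")
        by_inst = {i: g["rank"].to_numpy() for i, g in grp.groupby("instance_id")}
        for iid in inst_ids:
            own = by_inst[iid]
            others = np.concatenate([by_inst[j] for j in inst_ids if j != iid])
            degenerate = False
            if len(own) < 2 or (own.std(ddof=1) == 0 and others.std(ddof=1) == 0):
                t, p, degenerate = float("nan"), float("nan"), True
            else:
                t, p = stats.ttest_ind(own, others, equal_var=False)
                t, p = float(t), float(p)
            mean_rank = float(own.mean())
            if degenerate or np.isnan(p):
                direction = "neither"
                degenerate = True
            else:
                direction = ("easy" if mean_rank < others.mean()
                             else "hard" if mean_rank > others.mean() else "neither")
            mc, nz = float("nan"), 0
            if corr is not None and iid in corr.index:
                mc = float(corr.loc[iid, "mean_correct"])
                nz = int(corr.loc[iid, "n_zero_correct"])
            scores.append(InstanceScore(
                instance_id=iid, class_label=int(cls), mean_rank=mean_rank,
                t_stat=t, p_value=p, direction=direction,
                mean_correct=mc, n_zero_correct=nz,
                n_participants=int(len(own)), degenerate=degenerate))
    return scores


def accuracy_rt_correlation(records, ranks: pd.DataFrame) -> AccuracyRTResult:
    """Spearman correlation of per-instance mean correct count vs mean RT rank."""
    participants = ranks["participant_id"].unique()
    cc = _correct_counts(records, participants)
    mean_correct = cc.groupby("instance_id")["correct"].mean()
    mean_rank = ranks.groupby("instance_id")["rank"].mean()
    common = mean_correct.index.intersection(mean_rank.index)
    if len(common) < 3:
        raise AnalysisError("need >= 3 instances for a correlation")
    x = mean_correct.loc[common].to_numpy()
    y = mean_rank.loc[common].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        return AccuracyRTResult(rho=float("nan"), p_value=float("nan"), defined=False)
    rho, p = stats.spearmanr(x, y)
    return AccuracyRTResult(rho=float(rho), p_value=float(p))


def scores_to_frame(scores) -> pd.DataFrame:
    """Instance-score table in the on-disk column order."""
    return pd.DataFrame([{
        "instance_id": s.instance_id, "class": s.class_label,
        "mean_rank": s.mean_rank, "t": s.t_stat, "p": s.p_value,
        "direction": s.direction, "mean_correct": s.mean_correct,
        "n_zero_correct": s.n_zero_correct, "n_participants": s.n_participants,
    } for s in scores])
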