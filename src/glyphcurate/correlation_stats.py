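"""Correlation analyses relating network confidence to reaction times.

Reaction times are first normalized per participant so that each
participant's mean RTs over the exemplars they saw sum to 1 (making
participants comparable without modeling their absolute speed);
network entropies are normalized the same way per network over the
evaluated item set.  The headline statistic is the Spearman
correlation between the per-item mean normalized confidence and the
per-item mean normalized RT, accompanied by the distribution of
per-network correlations.  Sets of correlations from different
training conditions are compared by Fisher z-transforming and
applying a two-sided Welch t-test; accuracy sets are compared the
same way without the transform.  Significance tiers follow the usual
figure-caption convention (***/**/* at 0.001 / 0.01 / 0.05).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("glyphcurate")

_RHO_CLAMP = 1.0 - 1e-7


class NormalizationError(ValueError):
    pass


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    defined: bool = True


@dataclass(frozen=True)
class CorrelationReport:
    rho_of_means: float
    p_of_means: float
    per_net_rhos: list
    per_net_ps: list
    mean_rho: float
    se_rho: float
    n_items: int
    defined: bool = True


@dataclass(frozen=True)
class PairwiseComparison:
    condition_a: str
    condition_b: str
    t_stat: float
    p_value: float
    tier: str      # "***" | "**" | "*" | "n.s."
    clamped: bool = False


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def normalize_per_unit(values: pd.DataFrame, unit_col: str = "unit_id",
                       value_col: str = "value") -> pd.DataFrame:
    """Scale each unit's values to sum to 1 (order within units preserved)."""
    if (values[value_col] <= 0).any():
        raise NormalizationError("all values must be positive")
    out = values.copy()
    sums = out.groupby(unit_col)[value_col].transform("sum")
    if (sums <= 0).any():
        raise NormalizationError("zero-sum unit encountered")
    out[value_col] = out[value_col] / sums
    return out


def spearman(x, y) -> SpearmanResult:
    """Midrank Spearman correlation with two-sided p; flags constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsError("input lengths differ")
    if len(x) < 3:
        raise StatsError("need at least 3 items")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(rho=float("nan"), p_value=float("nan"), defined=False)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p))


def normalized_rt_means(records, participants) -> pd.Series:
    """Per-item mean of per-participant normalized mean RTs.

    Each participant's per-exemplar mean RTs are scaled to sum to 1
    before averaging across participants, so the result is an
    RT profile over items rather than an absolute-time measure.
    """
    keep = set(participants)
    rows = [(r.participant_id, r.instance_id, r.rt)
            for r in records if r.participant_id in keep]
    df = pd.DataFrame(rows, columns=["unit_id", "instance_id", "value"])
    means = df.groupby(["unit_id", "instance_id"], as_index=False)["value"].mean()
    norm = normalize_per_unit(means)
    return norm.groupby("instance_id")["value"].mean()


def correlation_report(confidences: pd.DataFrame, rts: pd.Series,
                       normalize_confidence: bool = True) -> CorrelationReport:
    """Confidence-RT correspondence for one ensemble.

    `confidences` has one row per instance and one column of entropies
    per network; `rts` is a per-instance series of mean normalized
    RTs.  Item sets are intersected; each network's entropies are
    normalized to sum to 1 over those items (disable with
    `normalize_confidence=False` to correlate raw entropies).
    """
    common = confidences.index.intersection(rts.index)
    if len(common) < 3:
        raise StatsError("fewer than 3 overlapping items between confidences and RTs")
    conf = confidences.loc[common]
    rt = rts.loc[common].to_numpy()
    if normalize_confidence:
        sums = conf.sum(axis=0)
        if (sums <= 0).any():
            raise NormalizationError("a network's entropies sum to zero; "
                                     "cannot normalize")
        conf = conf / sums
    res_means = spearman(conf.mean(axis=1).to_numpy(), rt)
    per_rhos, per_ps = [], []
    for col in conf.columns:
        r = spearman(conf[col].to_numpy(), rt)
        per_rhos.append(r.rho)
        per_ps.append(r.p_value)
    arr = np.asarray(per_rhos)
    ok = ~np.isnan(arr)
    mean_rho = float(arr[ok].mean()) if ok.any() else float("nan")
    se_rho = (float(arr[ok].std(ddof=1) / math.sqrt(ok.sum()))
              if ok.sum() > 1 else float("nan"))
    return CorrelationReport(
        rho_of_means=res_means.rho, p_of_means=res_means.p_value,
        per_net_rhos=per_rhos, per_net_ps=per_ps,
        mean_rho=mean_rho, se_rho=se_rho,
        n_items=int(len(common)), defined=res_means.defined)


def _fisher_z(rhos: np.ndarray):
    clamped = bool((np.abs(rhos) >= 1.0).any())
    if clamped:
        logger.warning("correlation(s) at |rho| = 1 clamped before z-transform")
    return np.arctanh(np.clip(rhos, -_RHO_CLAMP, _RHO_CLAMP)), clamped


def compare_correlation_sets(rhos_a, rhos_b, label_a: str = "A",
                             label_b: str = "B") -> PairwiseComparison:
    """Fisher z-transform then two-sided Welch t-test between two rho samples."""
    a = np.asarray(rhos_a, dtype=float)
    b = np.asarray(rhos_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need at least 2 correlations per set")
    za, ca = _fisher_z(a)
    zb, cb = _fisher_z(b)
    t, p = stats.ttest_ind(za, zb, equal_var=False)
    return PairwiseComparison(condition_a=label_a, condition_b=label_b,
                              t_stat=float(t), p_value=float(p),
                              tier=significance_tier(float(p)),
                              clamped=ca or cb)


def compare_accuracy_sets(acc_a, acc_b, label_a: str = "A",
                          label_b: str = "B") -> PairwiseComparison:
    """Two-sided Welch t-test between two accuracy samples."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need at least 2 accuracies per set")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return PairwiseComparison(condition_a=label_a, condition_b=label_b,
                              t_stat=float(t), p_value=float(p),
                              tier=significance_tier(float(p)))


def crossed_grid(confidence_tables: dict, rts_by_condition: dict,
                 normalize_confidence: bool = True) -> dict:
    """One CorrelationReport per (net condition, participant condition) cell.

    Cells whose inputs are empty or non-overlapping are flagged with
    None; the rest of the grid is still returned.
    """
    if not confidence_tables or not rts_by_condition:
        raise StatsError("both grid factors need at least one condition")
    grid = {}
    for net_cond, conf in confidence_tables.items():
        for part_cond, rts in rts_by_condition.items():
            key = (net_cond, part_cond)
            try:
                grid[key] = correlation_report(
                    conf, rts, normalize_confidence=normalize_confidence)
            except (StatsError, NormalizationError) as exc:
                logger.warning("grid cell %s flagged: %s", key, exc)
                grid[key] = None
    return grid


def grid_table(grid: dict) -> str:
    """Labeled text table of a crossed grid's mean correlations."""
    lines = ["net_cond/participant_cond  rho_of_means  mean_rho  tier(mean)"]
    for (nc, pc), rep in sorted(grid.items()):
        if rep is None:
            lines.append(f"{nc}/{pc}  (flagged: no data)")
        else:
            lines.append(f"{nc}/{pc}  {rep.rho_of_means:+.3f}  "
                         f"{rep.mean_rho:+.3f}  {significance_tier(rep.p_of_means)}")
    return "\n".join(lines)
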