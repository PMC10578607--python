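"""Per-exemplar drift-rate estimation via the EZ-diffusion closed form.

Under a two-boundary diffusion with symmetric start, within-trial
noise s, drift v, boundary separation a and non-decision time Ter,
the accuracy and the mean and variance of correct-trial reaction
times have closed forms; the EZ estimator inverts them:

    L  = logit(Pc)
    v  = sign(Pc - 1/2) * s * [ L (L Pc^2 - L Pc + Pc - 1/2) / VRT ]^(1/4)
    a  = s^2 L / v
    Ter = MRT - (a / 2v) * (1 - e^{-va/s^2}) / (1 + e^{-va/s^2})

Because only the drift is assumed to vary across stimuli, the shared
boundary and non-decision time are taken as the medians of per-item
EZ fits, and each item's drift is then re-estimated from its accuracy
alone at the fixed boundary: v_i = s^2 logit(Pc_i) / a*.

Moments are pooled across participants per exemplar; MRT/VRT use
correct trials only (the EZ convention), and perfect accuracy is
edge-corrected to 1 - 1/(2n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .correlation_stats import SpearmanResult, spearman
from .synthetic_data import DIFFUSION_S

logger = logging.getLogger("glyphcurate")


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class DDMParams:
    drift: float                 # v, evidence/s
    boundary: float              # a, evidence units
    nondecision: float           # Ter, s
    s: float = DIFFUSION_S
    defined: bool = True         # False when a/Ter are undefined (v = 0)


@dataclass(frozen=True)
class EZMoments:
    """Accuracy and correct-trial RT moments for one exemplar."""

    item_id: str
    pc: float          # fraction correct, edge-corrected into (0, 1)
    mrt: float         # mean correct-trial RT, s
    vrt: float         # variance of correct-trial RTs, s^2
    n_trials: int
    flagged: bool = False
    flag_reason: str = ""


@dataclass(frozen=True)
class DriftTable:
    item_ids: list
    drifts: list
    boundary: float              # shared a*
    nondecision: float           # shared Ter*
    method: str = "ez-shared-boundary"
    flagged_items: tuple = ()

    def as_dict(self) -> dict:
        return dict(zip(self.item_ids, self.drifts))


def pool_moments(records, chance: float = 0.5) -> list:
    """Per-item accuracy and correct-trial RT moments, pooled across participants.

    Items with accuracy at or below `chance` (the two-boundary chance
    level), no correct trials, or a single correct trial (variance
    undefined) are flagged and excluded from fitting downstream.
    """
    by_item = {}
    for r in records:
        by_item.setdefault(r.instance_id, []).append(r)
    moments = []
    for iid in sorted(by_item):
        trials = by_item[iid]
        n = len(trials)
        n_correct = sum(t.correct for t in trials)
        crts = np.array([t.rt for t in trials if t.correct])
        pc = n_correct / n
        flagged, reason = False, ""
        if n_correct == 0:
            flagged, reason = True, "zero correct trials"
            mrt = vrt = float("nan")
        else:
            mrt = float(crts.mean())
            if n_correct < 2:
                flagged, reason = True, "variance undefined (single correct trial)"
                vrt = float("nan")
            else:
                vrt = float(crts.var(ddof=1))
        if not flagged and pc <= chance:
            flagged, reason = True, f"accuracy at or below chance ({pc:.3f})"
        if pc == 1.0:
            pc = 1.0 - 1.0 / (2 * n)
        moments.append(EZMoments(item_id=iid, pc=pc, mrt=mrt, vrt=vrt,
                                 n_trials=n, flagged=flagged, flag_reason=reason))
    return moments


def ez_fit(m: EZMoments, s: float = DIFFUSION_S) -> DDMParams:
    """Closed-form EZ inversion of one item's moments."""
    pc = m.pc
    if not (0.0 < pc < 1.0):
        raise FitError(f"{m.item_id}: Pc must lie strictly in (0, 1), got {pc}")
    if pc == 0.5:
        return DDMParams(drift=0.0, boundary=float("nan"),
                         nondecision=float("nan"), s=s, defined=False)
    if not (m.vrt > 0):
        raise FitError(f"{m.item_id}: VRT must be positive, got {m.vrt}")
    L = math.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / m.vrt
    v = math.copysign(s * x**0.25, pc - 0.5)
    a = s**2 * L / v
    y = -v * a / s**2
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    ter = m.mrt - mdt
    return DDMParams(drift=v, boundary=a, nondecision=ter, s=s)


def ez_forward(params: DDMParams) -> tuple:
    """Analytic (Pc, MRT, VRT) implied by diffusion parameters (the EZ forward model)."""
    v, a, ter, s = params.drift, params.boundary, params.nondecision, params.s
    if v == 0:
        raise FitError("forward moments undefined at zero drift")
    y = -v * a / s**2
    pc = 1.0 / (1.0 + math.exp(y))
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    L = -y  # logit(pc)
    vrt = s**4 * L * (L * pc**2 - L * pc + pc - 0.5) / v**4
    return pc, ter + mdt, vrt


def fit_drifts_shared(moments, s: float = DIFFUSION_S) -> DriftTable:
    """Two-stage fit: per-item EZ, then shared (a*, Ter*) with drifts from accuracy.

    Stage 1 fits every unflagged item independently; stage 2 fixes the
    boundary and non-decision time at the medians of those fits; stage
    3 re-estimates each drift from the item's accuracy alone at the
    shared boundary (the EZ accuracy relation inverted at fixed a).
    """
    if len(moments) < 2:
        raise FitError("need at least 2 items for a shared fit")
    usable = [m for m in moments if not m.flagged]
    if not usable:
        raise FitError("all items flagged; nothing to fit")
    stage1 = [(m, ez_fit(m, s=s)) for m in usable]
    defined = [(m, p) for m, p in stage1 if p.defined]
    if not defined:
        raise FitError("all per-item fits degenerate (zero drift)")
    a_star = float(np.median([p.boundary for _, p in defined]))
    ter_star = float(np.median([p.nondecision for _, p in defined]))
    item_ids, drifts = [], []
    for m in usable:
        L = math.log(m.pc / (1.0 - m.pc))
        item_ids.append(m.item_id)
        drifts.append(s**2 * L / a_star)
    return DriftTable(item_ids=item_ids, drifts=drifts, boundary=a_star,
                      nondecision=ter_star,
                      flagged_items=tuple(m.item_id for m in moments if m.flagged))


def drift_confidence_correlation(drifts: DriftTable,
                                 mean_entropy) -> SpearmanResult:
    """Spearman correlation of fitted drifts with mean network entropy.

    `mean_entropy` is a mapping (or pandas Series) from item id to the
    ensemble-mean output entropy.  High drift should pair with low
    entropy, so the expected sign is negative.
    """
    common = [iid for iid in drifts.item_ids if iid in mean_entropy]
    if len(common) < 3:
        raise FitError("fewer than 3 items overlap between drifts and confidences")
    v = drifts.as_dict()
    x = [v[iid] for iid in common]
    y = [float(mean_entropy[iid]) for iid in common]
    return spearman(x, y)
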