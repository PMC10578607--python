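"""Synthetic glyph stimuli and diffusion-model observers.

This module generates the inputs that every downstream analysis stage
consumes: small binary glyph images with a graded, known *typicality*
(how close an instance is to its class prototype), balanced trial
schedules in which every instance appears a fixed number of times, and
simulated participants whose choices and reaction times arise from a
two-boundary drift-diffusion process in which only the drift rate
depends on the stimulus.

Typicality is defined as ``tau = exp(-d / sigma_tau)`` where ``d`` is
the number of pixels flipped relative to the prototype, so ``tau = 1``
iff the instance is undeformed and ``tau`` decreases strictly with the
deformation count.

The diffusion simulator uses the classic scaling convention
(within-trial noise ``s = 0.1``) and an Euler-Maruyama step of 1 ms.
A four-alternative response is mapped onto the two-boundary process:
the upper boundary is the correct response, the lower boundary an
error whose class is drawn uniformly from the wrong labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("glyphcurate")

# Diffusion scaling convention and integration step.
DIFFUSION_S = 0.1
DT = 0.001
#: decision-time cap (s); trials still unabsorbed are resolved by the
#: sign of the accumulated evidence (vanishingly rare at default params)
MAX_DECISION_TIME = 10.0


class ConfigurationError(ValueError):
    """Raised when generator or schedule inputs are structurally invalid."""


class ParameterError(ValueError):
    """Raised when diffusion parameters are outside their domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlyphPrototype:
    """Canonical shape of one glyph class: a set of stroke pixels on an H x W grid."""

    class_label: int
    strokes: frozenset  # of (row, col) tuples
    shape: tuple = (28, 28)

    def __post_init__(self):
        h, w = self.shape
        for (r, c) in self.strokes:
            if not (0 <= r < h and 0 <= c < w):
                raise ConfigurationError(
                    f"stroke pixel ({r},{c}) outside {h}x{w} grid")

    def render(self) -> np.ndarray:
        img = np.zeros(self.shape, dtype=float)
        rows, cols = zip(*self.strokes)
        img[list(rows), list(cols)] = 1.0
        return img


@dataclass(frozen=True)
class GlyphInstance:
    """One labeled stimulus image with known ground-truth typicality."""

    instance_id: str
    class_label: int
    pixels: np.ndarray  # H x W, values in [0, 1]
    typicality: float   # tau in (0, 1]

    def __post_init__(self):
        if not (0.0 < self.typicality <= 1.0):
            raise ValueError(f"typicality {self.typicality} outside (0, 1]")


@dataclass(frozen=True)
class SimParticipant:
    """Diffusion-model observer: boundary, non-decision time, drift gain, lapse rate.

    The drift on a trial is ``beta * score`` where ``score`` is the
    stimulus' typicality (or, for trained cohorts, its similarity to
    the participant's training set).
    """

    participant_id: str
    boundary: float        # a, evidence units
    nondecision: float     # Ter, seconds
    drift_gain: float      # beta, 1/s per unit typicality
    lapse: float = 0.0     # probability of a random response

    def __post_init__(self):
        if self.boundary <= 0:
            raise ParameterError("boundary separation must be positive")
        if self.nondecision < 0:
            raise ParameterError("non-decision time must be non-negative")
        if not (0.0 <= self.lapse < 1.0):
            raise ParameterError("lapse rate must be in [0, 1)")


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    trial_index: int       # 1-based position in the schedule
    instance_id: str
    true_class: int
    response_class: int
    rt: float              # seconds
    correct: bool

    def __post_init__(self):
        if self.rt <= 0:
            raise ValueError("reaction time must be positive")
        if self.correct != (self.response_class == self.true_class):
            raise ValueError("correct flag inconsistent with response")


@dataclass(frozen=True)
class TrialSchedule:
    """Seeded random permutation in which every instance appears exactly `repeats` times."""

    instance_ids: tuple
    repeats: int


@dataclass(frozen=True)
class CohortParams:
    """Uniform ranges from which per-participant diffusion parameters are drawn.

    Defaults follow the conventional s = 0.1 scaling of empirical
    diffusion fits: boundaries near 0.1, drifts of a few tenths,
    non-decision times around 300 ms.  With the default glyph
    deformation level this yields cohort accuracy around 0.85 and mean
    reaction times around 0.4-0.5 s.
    """

    boundary: tuple = (0.08, 0.14)
    nondecision: tuple = (0.25, 0.40)
    drift_gain: tuple = (0.6, 0.9)
    lapse: tuple = (0.0, 0.04)

    def sample(self, participant_id: str, rng: np.random.Generator) -> SimParticipant:
        u = lambda lo_hi: float(rng.uniform(*lo_hi))
        return SimParticipant(
            participant_id=participant_id,
            boundary=u(self.boundary),
            nondecision=u(self.nondecision),
            drift_gain=u(self.drift_gain),
            lapse=u(self.lapse),
        )


# ---------------------------------------------------------------------------
# Prototypes
# ---------------------------------------------------------------------------

def _thicken(points, shape, width=2):
    """Dilate a 1-pixel path to `width` pixels, clipped to the grid."""
    h, w = shape
    out = set()
    for (r, c) in points:
        for dr in range(width):
            for dc in range(width):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    out.add((rr, cc))
    return out


def _hline(r, c0, c1):
    return [(r, c) for c in range(c0, c1)]


def _vline(c, r0, r1):
    return [(r, c) for r in range(r0, r1)]


def default_prototypes(n_classes: int = 4, shape=(28, 28)) -> list:
    """Confusable letter-like glyph prototypes sharing a vertical stem.

    The classes resemble P, R, B and D (plus F and E for larger K):
    they all share the left stem and differ only in bowls and legs, so
    class identity rests on a modest number of pixels -- mirroring the
    deliberately confusable character sets of perceptual
    categorization studies.  Deformation near those distinguishing
    strokes genuinely degrades the class evidence.
    """
    if not (2 <= n_classes <= 6):
        raise ConfigurationError("between 2 and 6 default prototype classes supported")
    h, w = shape
    top, mid, bot = h // 5, h // 2, 4 * h // 5       # 5, 14, 22 at 28
    stem_c = w // 4                                  # 7
    right = 3 * w // 4                               # 21
    stem = _vline(stem_c, top, bot)
    paths = [
        # P: stem + top bowl
        stem + _hline(top, stem_c, right) + _hline(mid, stem_c, right)
        + _vline(right - 1, top, mid),
        # R: P + diagonal leg
        stem + _hline(top, stem_c, right) + _hline(mid, stem_c, right)
        + _vline(right - 1, top, mid)
        + [(mid + i, stem_c + 3 + i) for i in range(bot - mid)],
        # B: stem + two stacked bowls
        stem + _hline(top, stem_c, right) + _hline(mid, stem_c, right)
        + _hline(bot - 1, stem_c, right)
        + _vline(right - 1, top, bot),
        # D: stem + one tall bowl
        stem + _hline(top, stem_c, right) + _hline(bot - 1, stem_c, right)
        + _vline(right - 1, top, bot),
        # F: stem + two left-anchored bars, no right side
        stem + _hline(top, stem_c, right) + _hline(mid, stem_c, right - 3),
        # E: stem + three bars
        stem + _hline(top, stem_c, right) + _hline(mid, stem_c, right - 3)
        + _hline(bot - 1, stem_c, right),
    ]
    protos = []
    for k in range(n_classes):
        strokes = frozenset(_thicken(paths[k], shape))
        protos.append(GlyphPrototype(class_label=k, strokes=strokes, shape=shape))
    return protos


# ---------------------------------------------------------------------------
# Instance generation
# ---------------------------------------------------------------------------

def _near_stroke(img: np.ndarray) -> list:
    """Candidate deformation sites: foreground pixels plus their 8-neighbourhood."""
    from scipy.ndimage import binary_dilation
    cand = binary_dilation(img >= 0.5, structure=np.ones((3, 3), dtype=bool))
    return list(zip(*np.nonzero(cand)))


def _sample_jitter(shape, rng: np.random.Generator, max_rotation: float = 12.0,
                   scale_range=(0.96, 1.04), max_shift: float = 1.5):
    """Random rotation/scale/translation transform emulating handwriting variation.

    Nuisance variability only: it carries no typicality penalty
    (typicality tracks the pixel-flip deformation count alone).
    """
    from skimage.transform import AffineTransform
    h, w = shape
    angle = np.deg2rad(rng.uniform(-max_rotation, max_rotation))
    scale = rng.uniform(*scale_range)
    shift = rng.uniform(-max_shift, max_shift, size=2)
    center = np.array([w / 2.0, h / 2.0])
    return (AffineTransform(translation=-center)
            + AffineTransform(rotation=angle, scale=(scale, scale))
            + AffineTransform(translation=center + shift))


def _apply_jitter(img: np.ndarray, tf) -> np.ndarray:
    from skimage.transform import warp
    out = warp(img, tf.inverse, order=0, preserve_range=True)
    return (out >= 0.5).astype(float)


def _confusable_sites(pixels: np.ndarray, target: np.ndarray) -> list:
    """Deformation sites that move the glyph toward a confusor class.

    Pixels (near either glyph's stroke) where the instance and the
    aligned confusor prototype disagree: flipping one deletes a
    distinguishing stroke pixel or adds one of the confusor's.
    """
    from scipy.ndimage import binary_dilation
    near = binary_dilation((pixels >= 0.5) | (target >= 0.5),
                           structure=np.ones((3, 3), dtype=bool))
    diff = (pixels >= 0.5) != (target >= 0.5)
    return list(zip(*np.nonzero(near & diff)))


def _flip_patches(pixels: np.ndarray, candidates: list, d: int,
                  rng: np.random.Generator, patch_size: int = 8) -> None:
    """Flip exactly `d` candidate pixels in contiguous patches (in place).

    Deformities are spatially coherent -- a missing or spurious chunk
    of stroke -- rather than salt-and-pepper noise, so a heavily
    deformed glyph loses (or fakes) whole stroke segments the way a
    malformed handwritten character does.
    """
    cand_arr = np.array(candidates)
    remaining = min(d, len(cand_arr))
    flipped = np.zeros(len(cand_arr), dtype=bool)
    while remaining > 0:
        avail = np.nonzero(~flipped)[0]
        seed_idx = avail[rng.integers(len(avail))]
        sr, sc = cand_arr[seed_idx]
        size = min(remaining, int(rng.integers(patch_size // 2, patch_size + 1)))
        dist = np.abs(cand_arr[:, 0] - sr) + np.abs(cand_arr[:, 1] - sc)
        dist = np.where(flipped, np.iinfo(np.int64).max, dist)
        patch = np.argsort(dist, kind="stable")[:size]
        for i in patch:
            r, c = cand_arr[i]
            pixels[r, c] = 1.0 - pixels[r, c]
        flipped[patch] = True
        remaining -= size


def generate_instances(prototypes: Sequence[GlyphPrototype], n_per_class: int,
                       deform_scale: float, seed: int,
                       sigma_tau: float = 5.0, id_prefix: str = "",
                       jitter: bool = True,
                       deform_dispersion: float | None = 2.5) -> list:
    """Generate ``len(prototypes) * n_per_class`` deformed glyph instances.

    Each instance first receives handwriting-like nuisance jitter (a
    random small rotation, scale and translation of the prototype;
    disable with ``jitter=False``), then flips ``d`` pixels near the
    stroke in contiguous patches.  The count ``d`` is gamma-Poisson
    (negative binomial) with mean ``deform_scale`` and dispersion
    ``deform_dispersion``, giving the heavy-tailed mix of mild and
    grossly malformed exemplars that handwriting exhibits; with
    ``deform_dispersion=None`` it reduces to plain Poisson.  Flips preferentially land where the instance's class
    differs from a randomly chosen confusor class (aligned under the
    same jitter), so a heavily deformed glyph loses its own
    distinguishing strokes and gains the confusor's -- a deformity
    that genuinely degrades class evidence, the way a malformed
    handwritten character comes to resemble a neighbouring one.

    Typicality is ``tau = exp(-d / sigma_tau)`` for the realized flip
    count ``d`` only -- the nuisance jitter carries no penalty.
    Deterministic under `seed`.
    """
    if not prototypes:
        raise ConfigurationError("prototype list is empty")
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    if deform_scale < 0:
        raise ConfigurationError("deform_scale must be >= 0")
    rng = np.random.default_rng(seed)

    def draw_count():
        if deform_scale == 0:
            return 0
        if deform_dispersion is None or not np.isfinite(deform_dispersion):
            return int(rng.poisson(deform_scale))
        r = deform_dispersion
        return int(rng.negative_binomial(r, r / (r + deform_scale)))

    bases = {p.class_label: p.render() for p in prototypes}
    labels = sorted(bases)
    instances = []
    for proto in prototypes:
        base = bases[proto.class_label]
        confusors = [l for l in labels if l != proto.class_label]
        for j in range(n_per_class):
            if jitter:
                tf = _sample_jitter(base.shape, rng)
                pixels = _apply_jitter(base, tf)
            else:
                tf = None
                pixels = base.copy()
            d = draw_count()
            if d > 0 and confusors:
                conf_base = bases[int(rng.choice(confusors))]
                target = _apply_jitter(conf_base, tf) if tf is not None else conf_base
                cand = _confusable_sites(pixels, target)
                d = min(d, len(cand))
                _flip_patches(pixels, cand, d, rng)
            elif d > 0:
                cand = _near_stroke(pixels)
                d = min(d, len(cand))
                _flip_patches(pixels, cand, d, rng)
            tau = float(np.exp(-d / sigma_tau))
            instances.append(GlyphInstance(
                instance_id=f"{id_prefix}c{proto.class_label}_i{j:03d}",
                class_label=proto.class_label,
                pixels=pixels,
                typicality=tau,
            ))
    return instances


def make_schedule(instances: Sequence[GlyphInstance], repeats: int, seed: int) -> TrialSchedule:
    """Random trial order in which every instance appears exactly `repeats` times."""
    if not instances:
        raise ConfigurationError("instance list is empty")
    if repeats < 1:
        raise ConfigurationError("repeats must be >= 1")
    ids = [inst.instance_id for inst in instances] * repeats
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return TrialSchedule(instance_ids=tuple(ids[i] for i in order), repeats=repeats)


# ---------------------------------------------------------------------------
# Diffusion simulation
# ---------------------------------------------------------------------------

def _first_passage(drifts: np.ndarray, boundary: float, rng: np.random.Generator):
    """Vectorized Euler-Maruyama first passage between 0 and `boundary`.

    Start at boundary/2.  Returns (decision_time_seconds, hit_upper).
    """
    n = len(drifts)
    x = np.full(n, boundary / 2.0)
    active = np.ones(n, dtype=bool)
    dtimes = np.zeros(n)
    upper = np.zeros(n, dtype=bool)
    sqdt = np.sqrt(DT)
    max_steps = int(MAX_DECISION_TIME / DT)
    step = 0
    while active.any() and step < max_steps:
        step += 1
        na = int(active.sum())
        x[active] = (x[active] + drifts[active] * DT
                     + DIFFUSION_S * sqdt * rng.standard_normal(na))
        hit_up = active & (x >= boundary)
        hit_lo = active & (x <= 0.0)
        newly = hit_up | hit_lo
        dtimes[newly] = step * DT
        upper[hit_up] = True
        active &= ~newly
    if active.any():  # cap reached: resolve by evidence sign
        dtimes[active] = MAX_DECISION_TIME
        upper[active] = x[active] >= boundary / 2.0
    return dtimes, upper


def simulate_trials(schedule: TrialSchedule, participant: SimParticipant,
                    instances: Mapping[str, GlyphInstance], seed: int,
                    drift_scores: Mapping[str, float] | None = None) -> list:
    """Simulate one participant running the whole schedule.

    Drift for instance *i* is ``drift_gain * score_i`` where the score
    defaults to the instance's typicality; `drift_scores` overrides it
    (used for cohorts "trained" on a particular exemplar set).  The
    reaction time is the first-passage time plus the non-decision
    time; lapses replace the response class with a uniform random
    label but keep the diffusion reaction time.
    """
    missing = [i for i in schedule.instance_ids if i not in instances]
    if missing:
        raise ConfigurationError(f"schedule references unknown instances: {missing[:3]}")
    classes = sorted({inst.class_label for inst in instances.values()})
    k = len(classes)
    rng = np.random.default_rng(seed)
    score = (drift_scores if drift_scores is not None
             else {i: inst.typicality for i, inst in instances.items()})
    drifts = np.array([participant.drift_gain * score[i] for i in schedule.instance_ids])
    dtimes, upper = _first_passage(drifts, participant.boundary, rng)
    records = []
    for t, iid in enumerate(schedule.instance_ids):
        inst = instances[iid]
        true = inst.class_label
        if upper[t]:
            resp = true
        else:
            wrong = [c for c in classes if c != true]
            resp = true if k == 1 else int(rng.choice(wrong))
        if participant.lapse > 0 and rng.random() < participant.lapse:
            resp = int(rng.choice(classes))
        rt = float(dtimes[t] + participant.nondecision)
        records.append(TrialRecord(
            participant_id=participant.participant_id,
            trial_index=t + 1,
            instance_id=iid,
            true_class=true,
            response_class=resp,
            rt=rt,
            correct=(resp == true),
        ))
    return records


def simulate_cohort(n_participants: int, params: CohortParams,
                    instances: Sequence[GlyphInstance], repeats: int, seed: int,
                    drift_scores: Mapping[str, float] | None = None) -> list:
    """Simulate a cohort; each participant gets an independently shuffled schedule."""
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    rng = np.random.default_rng(seed)
    inst_map = {inst.instance_id: inst for inst in instances}
    records = []
    for p in range(n_participants):
        participant = params.sample(f"p{p:03d}", rng)
        sched_seed = int(rng.integers(2**31 - 1))
        trial_seed = int(rng.integers(2**31 - 1))
        schedule = make_schedule(instances, repeats, sched_seed)
        records.extend(simulate_trials(schedule, participant, inst_map,
                                       trial_seed, drift_scores=drift_scores))
    return records


def two_boundary_hit_probability(drift: float, boundary: float,
                                 s: float = DIFFUSION_S) -> float:
    """Closed-form probability of absorbing at the upper boundary from a/2."""
    return float(1.0 / (1.0 + np.exp(-boundary * drift / s**2)))
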