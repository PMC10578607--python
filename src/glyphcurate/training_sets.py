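"""Curated training sets and the shift/rotation augmentation scheme.

The "good" set takes, per class, the k exemplars with the most
significantly below-average reaction-time ranks; the "bad" set the
most significantly above-average; "random" sets draw k per class
uniformly without replacement.  A good-set candidate that *no*
participant ever answered correctly is disqualified (its fast ranks
cannot reflect genuine ease) and replaced by the next most
significant candidate.

Confidence-based selection uses the entropy (in nats) of per-item
class-response count distributions: low entropy means respondents
agreed on a label (high confidence).

Augmentation produces, for each image, every combination of a
one-pixel shift (dx, dy in {-1, 0, +1}) and a rotation
(theta in {-10, 0, +10} degrees) -- 27 variants including the
identity.  Rotation (about the image center, nearest-neighbour
resampling, rebinarized at 0.5) is applied before the shift; shifted
content leaving the frame is dropped and vacated pixels become
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import rotate as _sk_rotate

logger = logging.getLogger("glyphcurate")

SHIFTS = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]
ROTATIONS = [-10.0, 0.0, 10.0]
VARIANTS_PER_IMAGE = len(SHIFTS) * len(ROTATIONS)  # 27


class CurationError(ValueError):
    pass


class ValidationError(ValueError):
    pass


class ImageFormatError(ValueError):
    pass


@dataclass(frozen=True)
class CuratedSet:
    """Named training subset with per-class member lists and provenance values."""

    label: str                      # good|bad|random|full|high_conf|low_conf
    members: dict                   # class_label -> list of instance_id
    provenance: dict                # instance_id -> p-value or entropy
    k_per_class: int

    def all_ids(self) -> list:
        return [iid for cls in sorted(self.members) for iid in self.members[cls]]

    def __len__(self):
        return sum(len(v) for v in self.members.values())


@dataclass(frozen=True)
class ResponseDistribution:
    """Per-item class-response tallies and their entropy in nats."""

    item_id: str
    counts: tuple

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ValidationError(f"{self.item_id}: negative response count")
        if sum(self.counts) < 1:
            raise ValidationError(f"{self.item_id}: empty response distribution")

    @property
    def entropy(self) -> float:
        return response_entropy(self.counts)


@dataclass(frozen=True)
class AugmentedItem:
    parent_id: str
    class_label: int
    shift: tuple       # (dx, dy)
    rotation: float    # degrees
    pixels: np.ndarray


@dataclass(frozen=True)
class AugmentedSet:
    source_label: str
    items: list = field(default_factory=list)

    def __len__(self):
        return len(self.items)

    def arrays(self):
        """(X, y) stacked for network training."""
        X = np.stack([it.pixels for it in self.items])
        y = np.array([it.class_label for it in self.items], dtype=int)
        return X, y


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def curate_extreme(scores, k_per_class: int, which: str) -> CuratedSet:
    """Top-k most significant easy ("good") or hard ("bad") exemplars per class.

    For the good set, a candidate that was never answered correctly by
    any participant is disqualified and the next most significant
    candidate takes its place.
    """
    if which not in ("good", "bad"):
        raise CurationError(f"which must be 'good' or 'bad', got {which!r}")
    direction = "easy" if which == "good" else "hard"
    members, provenance = {}, {}
    classes = sorted({s.class_label for s in scores})
    for cls in classes:
        cands = [s for s in scores
                 if s.class_label == cls and s.direction == direction
                 and not s.degenerate]
        if which == "good":
            dropped = [s for s in cands
                       if s.n_participants > 0 and s.n_zero_correct == s.n_participants]
            for s in dropped:
                logger.info("good-set candidate %s disqualified: never answered "
                            "correctly by any participant", s.instance_id)
            cands = [s for s in cands if s not in dropped]
        cands.sort(key=lambda s: (s.p_value, s.instance_id))
        if len(cands) < k_per_class:
            raise CurationError(
                f"class {cls}: only {len(cands)} {direction} candidates, "
                f"need {k_per_class}")
        chosen = cands[:k_per_class]
        members[cls] = [s.instance_id for s in chosen]
        provenance.update({s.instance_id: s.p_value for s in chosen})
    return CuratedSet(label=which, members=members, provenance=provenance,
                      k_per_class=k_per_class)


def curate_random(instances, k_per_class: int, seed: int) -> CuratedSet:
    """Uniform without-replacement draw of k instances per class."""
    rng = np.random.default_rng(seed)
    by_class = {}
    for inst in instances:
        by_class.setdefault(inst.class_label, []).append(inst.instance_id)
    members = {}
    for cls in sorted(by_class):
        pool = sorted(by_class[cls])
        if len(pool) < k_per_class:
            raise CurationError(f"class {cls}: only {len(pool)} instances, "
                                f"need {k_per_class}")
        picked = rng.choice(len(pool), size=k_per_class, replace=False)
        members[cls] = [pool[i] for i in sorted(picked)]
    return CuratedSet(label="random", members=members,
                      provenance={i: float("nan") for m in members.values() for i in m},
                      k_per_class=k_per_class)


def full_set(instances) -> CuratedSet:
    members = {}
    for inst in instances:
        members.setdefault(inst.class_label, []).append(inst.instance_id)
    k = max(len(v) for v in members.values())
    return CuratedSet(label="full", members={c: sorted(v) for c, v in members.items()},
                      provenance={}, k_per_class=k)


# ---------------------------------------------------------------------------
# Entropy-based selection
# ---------------------------------------------------------------------------

def response_entropy(counts) -> float:
    """Shannon entropy (nats) of a class-response tally, with 0*ln(0) = 0."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("negative response count")
    total = counts.sum()
    if total < 1:
        raise ValidationError("total response count must be >= 1")
    p = counts / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def select_by_confidence(dists, labels, k_per_class: int, which: str) -> CuratedSet:
    """Per class, the k items with lowest (high-confidence) or highest entropy.

    Ties are broken by item id order.
    """
    if which not in ("high", "low"):
        raise CurationError(f"which must be 'high' or 'low', got {which!r}")
    by_class = {}
    for d in dists:
        by_class.setdefault(labels[d.item_id], []).append(d)
    members, provenance = {}, {}
    sign = 1.0 if which == "high" else -1.0
    for cls in sorted(by_class):
        items = sorted(by_class[cls], key=lambda d: (sign * d.entropy, d.item_id))
        if len(items) < k_per_class:
            raise CurationError(f"class {cls}: only {len(items)} items, "
                                f"need {k_per_class}")
        chosen = items[:k_per_class]
        members[cls] = [d.item_id for d in chosen]
        provenance.update({d.item_id: d.entropy for d in chosen})
    return CuratedSet(label=f"{which}_conf", members=members,
                      provenance=provenance, k_per_class=k_per_class)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _shift(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate the foreground by (dx right, dy down), cropping at borders."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys, yd = (0, dy) if dy >= 0 else (-dy, 0)
    xs, xd = (0, dx) if dx >= 0 else (-dx, 0)
    out[yd:h - ys, xd:w - xs] = img[ys:h - yd, xs:w - xd]
    return out


def _rotate_binary(img: np.ndarray, angle: float) -> np.ndarray:
    if angle == 0.0:
        return img.copy()
    rot = _sk_rotate(img, angle, order=0, preserve_range=True)
    return (rot >= 0.5).astype(img.dtype)


def augment(images, binarize: bool = True) -> AugmentedSet:
    """All 27 shift x rotation variants of each (id, label, pixels) image.

    `images` may be an iterable of (instance_id, class_label, pixels)
    triples or an object with ``ids``/``labels``/``pixels`` attributes
    (an ImageStore).  Inputs are binarized at 0.5 unless `binarize` is
    False, in which case non-binary input is rejected.
    """
    if hasattr(images, "pixels"):
        images = list(zip(images.ids, images.labels, images.pixels))
    items = []
    source_label = "images"
    for iid, label, pixels in images:
        pixels = np.asarray(pixels, dtype=float)
        if binarize:
            pixels = (pixels >= 0.5).astype(float)
        elif not np.isin(pixels, (0.0, 1.0)).all():
            raise ImageFormatError(f"{iid}: non-binary pixels with binarize disabled")
        for theta in ROTATIONS:
            rotated = _rotate_binary(pixels, theta)
            for dx, dy in SHIFTS:
                items.append(AugmentedItem(
                    parent_id=iid, class_label=int(label),
                    shift=(dx, dy), rotation=theta,
                    pixels=_shift(rotated, dx, dy)))
    return AugmentedSet(source_label=source_label, items=items)
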