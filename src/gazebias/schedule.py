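"""Stimulus pairing, mirroring and the pseudo-random presentation schedule.

The stimulus set consists of 36 images, 12 per category (spiders, scorpions
and short-horned grasshoppers), matched into 18 two-animal pairs of three
types — spider-grasshopper, scorpion-grasshopper and spider-scorpion, six of
each — and then doubled by horizontal mirroring to 36 slides.  Colour
matching is modelled abstractly through a ``color_group`` label; no image
processing happens here.

A presentation schedule orders the 36 slides pseudo-randomly under the
interlacing constraint that a pair and its mirror image are separated by at
least two completely different slides (positional separation >= 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

CATEGORIES = ("spider", "scorpion", "grasshopper")
PAIR_TYPES = ("spider-grasshopper", "scorpion-grasshopper", "spider-scorpion")

# Which categories make up each pair type, in (left-of-original, right-of-original) order.
_TYPE_MEMBERS = {
    "spider-grasshopper": ("spider", "grasshopper"),
    "scorpion-grasshopper": ("scorpion", "grasshopper"),
    "spider-scorpion": ("spider", "scorpion"),
}

MIN_MIRROR_SEPARATION = 3  # >= 2 intervening different slides


@dataclass(frozen=True)
class StimulusImage:
    image_id: str
    category: str
    color_group: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class StimulusPair:
    pair_id: str
    base_pair_id: str
    pair_type: str
    left_image: StimulusImage
    right_image: StimulusImage
    orientation: str = "original"

    def __post_init__(self) -> None:
        if self.orientation not in ("original", "mirrored"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.left_image.category == self.right_image.category:
            raise ValueError("a pair must combine two different categories")
        if set(_TYPE_MEMBERS[self.pair_type]) != {self.left_image.category, self.right_image.category}:
            raise ValueError("pair_type inconsistent with image categories")

    @property
    def left_category(self) -> str:
        return self.left_image.category

    @property
    def right_category(self) -> str:
        return self.right_image.category


@dataclass
class PresentationSchedule:
    slides: list[StimulusPair]
    slide_ms: float = 5000.0
    cross_ms: float = 2000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(len(self.slides)),
                "slide_id": [s.pair_id for s in self.slides],
                "base_pair_id": [s.base_pair_id for s in self.slides],
                "pair_type": [s.pair_type for s in self.slides],
                "orientation": [s.orientation for s in self.slides],
                "left_image": [s.left_image.image_id for s in self.slides],
                "right_image": [s.right_image.image_id for s in self.slides],
                "left_category": [s.left_category for s in self.slides],
                "right_category": [s.right_category for s in self.slides],
            }
        )


def default_image_set() -> list[StimulusImage]:
    """36 abstract stimulus images: 12 per category, 6 colour groups twice."""
    groups = ["black", "brown", "disruptive", "yellow", "sandy", "grey"]
    images = []
    for cat in CATEGORIES:
        for i in range(12):
            images.append(StimulusImage(f"{cat}_{i + 1:02d}", cat, groups[i % 6]))
    return images


def build_pairs(images: list[StimulusImage]) -> list[StimulusPair]:
    """Match 36 images into 18 pairs, 6 of each type, respecting colour groups.

    Within each pair type the two categories are matched by ``color_group``
    where possible; leftovers fall back to arbitrary within-type pairing
    (with a warning).  Each image is used exactly once.
    """
    by_cat: dict[str, list[StimulusImage]] = {c: [] for c in CATEGORIES}
    for img in images:
        by_cat[img.category].append(img)
    for cat, imgs in by_cat.items():
        if len(imgs) != 12:
            raise ValueError(f"need 12 {cat} images, got {len(imgs)}")
        if len({i.image_id for i in imgs}) != len(imgs):
            raise ValueError(f"duplicate image ids in category {cat}")

    # Deterministic split: each category serves two pair types (spiders: SG
    # and SS; scorpions: CG and SS; grasshoppers: SG and CG).  Alternating
    # through the colour-sorted list sends one image of every colour group
    # to each role, so all three types can be colour-matched.
    for c in CATEGORIES:
        by_cat[c] = sorted(by_cat[c], key=lambda im: (im.color_group, im.image_id))
    split = {c: (by_cat[c][0::2], by_cat[c][1::2]) for c in CATEGORIES}
    allocation = {
        "spider-grasshopper": (split["spider"][0], split["grasshopper"][0]),
        "scorpion-grasshopper": (split["scorpion"][0], split["grasshopper"][1]),
        "spider-scorpion": (split["spider"][1], split["scorpion"][1]),
    }

    pairs: list[StimulusPair] = []
    prefixes = {"spider-grasshopper": "SG", "scorpion-grasshopper": "CG", "spider-scorpion": "SS"}
    for ptype, (lefts, rights) in allocation.items():
        lefts, rights = list(lefts), list(rights)
        matched: list[tuple[StimulusImage, StimulusImage]] = []
        for left in list(lefts):
            mate = next((r for r in rights if r.color_group == left.color_group), None)
            if mate is not None:
                matched.append((left, mate))
                lefts.remove(left)
                rights.remove(mate)
        if lefts:
            warnings.warn(
                f"{len(lefts)} {ptype} pair(s) could not be colour-matched; "
                "falling back to arbitrary within-type pairing"
            )
            matched.extend(zip(lefts, rights))
        for k, (left, right) in enumerate(matched):
            base = f"{prefixes[ptype]}{k + 1}"
            pairs.append(StimulusPair(f"{base}_o", base, ptype, left, right, "original"))
    return pairs


def mirror_pair(pair: StimulusPair) -> StimulusPair:
    """Horizontal mirror: swap left and right images, flip orientation."""
    flip = {"original": "mirrored", "mirrored": "original"}
    suffix = {"original": "_o", "mirrored": "_m"}
    new_orientation = flip[pair.orientation]
    return replace(
        pair,
        pair_id=pair.base_pair_id + suffix[new_orientation],
        left_image=pair.right_image,
        right_image=pair.left_image,
        orientation=new_orientation,
    )


def mirror_pairs(pairs: list[StimulusPair]) -> list[StimulusPair]:
    """Return the original pairs plus their horizontal mirrors (2n slides)."""
    if any(p.orientation != "original" for p in pairs):
        raise ValueError("input pairs must all have orientation 'original'")
    bases = [p.base_pair_id for p in pairs]
    if len(set(bases)) != len(bases):
        raise ValueError("duplicate base pair ids")
    return list(pairs) + [mirror_pair(p) for p in pairs]


def check_interlacing(slides: list[StimulusPair], min_separation: int = MIN_MIRROR_SEPARATION) -> list[tuple[int, int]]:
    """All position pairs (i, j) of mirror mates closer than ``min_separation``."""
    pos: dict[str, list[int]] = {}
    for i, s in enumerate(slides):
        pos.setdefault(s.base_pair_id, []).append(i)
    violations = []
    for positions in pos.values():
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                if positions[b] - positions[a] < min_separation:
                    violations.append((positions[a], positions[b]))
    return violations


def make_schedule(pairs: list[StimulusPair], seed: int,
                  max_retries: int = 10_000, slide_ms: float = 5000.0,
                  cross_ms: float = 2000.0) -> PresentationSchedule:
    """Seeded random permutation of the slides under the interlacing constraint.

    Rejection sampling with a bounded number of retries; the order is a
    deterministic function of ``seed``.
    """
    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.base_pair_id] = counts.get(p.base_pair_id, 0) + 1
    n = len(pairs)
    for base, c in counts.items():
        # c slides of one base pair need (c-1) gaps of >= min_sep positions
        if (c - 1) * MIN_MIRROR_SEPARATION + 1 > n:
            raise ValueError(f"interlacing constraint unsatisfiable for base pair {base!r}")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        order = rng.permutation(n)
        slides = [pairs[i] for i in order]
        if not check_interlacing(slides):
            return PresentationSchedule(slides, slide_ms=slide_ms, cross_ms=cross_ms)
    raise RuntimeError(f"no valid schedule found in {max_retries} retries")


def reverse_schedule(schedule: PresentationSchedule) -> PresentationSchedule:
    """Exactly reversed slide order (separation is symmetric, so still valid)."""
    return PresentationSchedule(
        list(reversed(schedule.slides)), slide_ms=schedule.slide_ms, cross_ms=schedule.cross_ms
    )


def schedule_from_frame(df: pd.DataFrame) -> PresentationSchedule:
    """Rebuild a PresentationSchedule from its CSV representation."""
    slides = []
    for _, row in df.sort_values("position").iterrows():
        left = StimulusImage(row["left_image"], row["left_category"])
        right = StimulusImage(row["right_image"], row["right_category"])
        slides.append(
            StimulusPair(row["slide_id"], row["base_pair_id"], row["pair_type"],
                         left, right, row["orientation"])
        )
    return PresentationSchedule(slides)
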