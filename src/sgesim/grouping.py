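"""Allocation of a cohort's offspring to pens.

Two designs:

* ``random`` — offspring are partitioned into pens of 12 uniformly at
  random, regardless of family, so pen mates can be sibs only by chance;
* ``four_families`` — litters are grouped into random quartets and each
  litter of 6 (3 males, 3 females) is split 3 + 3 across the quartet's male
  and female pen, so every pen holds members of exactly 4 litters with 3 per
  litter and every litter feeds exactly 2 pens.

Family pens are single-sex, which realizes the 3+3 split naturally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PenAssignment", "assign_random", "assign_four_families"]

RANDOM = "random"
FOUR_FAMILIES = "four_families"


@dataclass(frozen=True)
class PenAssignment:
    """Mapping of offspring to pens.

    ``ids`` and ``pen_of`` are parallel arrays: animal ``ids[i]`` lives in
    pen ``pen_of[i]``.  Pens partition the cohort and all have the same
    size.
    """

    design: str
    ids: np.ndarray
    pen_of: np.ndarray
    pen_size: int

    def __post_init__(self) -> None:
        if self.ids.shape != self.pen_of.shape:
            raise ValueError("ids and pen_of must align")
        _, counts = np.unique(self.pen_of, return_counts=True)
        if np.any(counts != self.pen_size):
            raise ValueError("all pens must have exactly pen_size members")
        if np.unique(self.ids).size != self.ids.size:
            raise ValueError("an animal may appear in exactly one pen")

    @property
    def n_pens(self) -> int:
        return int(np.unique(self.pen_of).size)

    def members(self) -> dict[int, np.ndarray]:
        order = np.argsort(self.pen_of, kind="stable")
        out: dict[int, np.ndarray] = {}
        for pen in np.unique(self.pen_of):
            out[int(pen)] = self.ids[self.pen_of == pen]
        return out


def assign_random(
    ids: np.ndarray, n_per_pen: int, rng: np.random.Generator
) -> PenAssignment:
    """Uniform random partition of a cohort into pens of ``n_per_pen``."""
    ids = np.asarray(ids)
    if ids.size % n_per_pen != 0:
        raise ValueError(
            f"{ids.size} offspring cannot be split into pens of {n_per_pen}"
        )
    perm = rng.permutation(ids.size)
    pen_of = np.empty(ids.size, dtype=np.int64)
    pen_of[perm] = np.arange(ids.size) // n_per_pen
    return PenAssignment(design=RANDOM, ids=ids, pen_of=pen_of, pen_size=n_per_pen)


def assign_four_families(
    ids: np.ndarray,
    litter: np.ndarray,
    sex: np.ndarray,
    rng: np.random.Generator,
    litter_size: int = 6,
    pen_size: int = 12,
) -> PenAssignment:
    """Four-families-per-pen design.

    Litters (each ``litter_size`` offspring, half of each sex) are grouped
    into random quartets; each quartet forms one male and one female pen of
    ``pen_size``.  Each litter therefore contributes equally (3 members) to
    exactly two pens.
    """
    ids = np.asarray(ids)
    litter = np.asarray(litter)
    sex = np.asarray(sex)
    per_pen_per_litter = pen_size // 4
    if 4 * per_pen_per_litter != pen_size:
        raise ValueError("pen size must be divisible by 4 litters")
    codes, counts = np.unique(litter, return_counts=True)
    if np.any(counts != litter_size):
        raise ValueError(f"every litter must have exactly {litter_size} offspring")
    if codes.size % 4 != 0:
        raise ValueError("number of litters must be divisible by 4")
    for s in (0, 1):
        c, k = np.unique(litter[sex == s], return_counts=True)
        if c.size != codes.size or np.any(k != litter_size // 2):
            raise ValueError("each litter must split its sexes evenly")

    quartets = rng.permutation(codes).reshape(-1, 4)
    pen_of = np.empty(ids.size, dtype=np.int64)
    litter_pos = {int(c): np.flatnonzero(litter == c) for c in codes}
    pen = 0
    for quartet in quartets:
        for s in (0, 1):
            for lit in quartet:
                pos = litter_pos[int(lit)]
                pos = pos[sex[pos] == s]
                pen_of[pos] = pen
            pen += 1
    return PenAssignment(
        design=FOUR_FAMILIES, ids=ids, pen_of=pen_of, pen_size=pen_size
    )
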