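"""Item-pool, ability and item-assignment generators for the simulation studies.

Two pool families are shipped as presets:

* ``study1``: a 2-dimensional pool of 900 operational + 30 replenished
  items covering the three nonzero patterns (1,0), (0,1), (1,1) with
  300/300/300 operational and 10/10/10 replenished items.
* ``study2``: a 3-dimensional pool of 910 operational + 35 replenished
  items covering all seven nonzero 3-bit patterns with 130 operational and
  5 replenished items per pattern.

Nonzero discriminations are uniform draws — U(0.7, 1.3) for moderately
discriminating pools, U(1.1, 1.7) for highly discriminating pools — and
intercepts are standard normal for every item.  Abilities are multivariate
normal with zero mean; correlated presets use off-diagonal 0.3 (2-D) and
(0.2, 0.3, 0.5) (3-D).

Replenished items are pretested in blocks: the items are split into
``n_groups`` groups of ``Z1`` items balanced over patterns, the examinees
into ``n_groups`` equal groups, and group g of examinees answers group g of
items, so each replenished item is answered by N / n_groups examinees
(400 under the default designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from catlasso.m2plm import ItemPool

__all__ = [
    "StudyDesign",
    "GroupAssignment",
    "study_design",
    "PRESETS",
    "generate_item_pool",
    "generate_abilities",
    "make_group_assignment",
]


@dataclass(frozen=True)
class StudyDesign:
    """Full specification of one simulated pretest condition.

    pattern_layout lists ``(pattern, n_operational, n_replenished)`` per
    nonzero pattern; ``disc_range`` bounds the uniform nonzero
    discriminations; ``Z0`` is the fixed operational test length (``None``
    for variable-length designs); ``Z1`` the number of replenished items
    each examinee answers.
    """

    K: int
    pattern_layout: tuple[tuple[tuple[int, ...], int, int], ...]
    disc_range: tuple[float, float]
    N: int
    ability_cov: np.ndarray
    Z0: int | None
    Z1: int
    n_groups: int

    def __post_init__(self) -> None:
        cov = np.asarray(self.ability_cov, dtype=float)
        object.__setattr__(self, "ability_cov", cov)
        if cov.shape != (self.K, self.K):
            raise ValueError(f"ability_cov must be {self.K}x{self.K}")
        if not np.allclose(cov, cov.T):
            raise ValueError("ability_cov must be symmetric")
        if not np.allclose(np.diag(cov), 1.0):
            raise ValueError("ability_cov must have unit diagonal")
        np.linalg.cholesky(cov)  # raises if not positive definite
        for pat, n_op, n_rep in self.pattern_layout:
            if len(pat) != self.K or not any(pat):
                raise ValueError(f"invalid pattern {pat} for K={self.K}")
            if n_op < 0 or n_rep < 0:
                raise ValueError("negative item counts")
        if self.J1 != self.n_groups * self.Z1:
            raise ValueError(
                f"J1={self.J1} must equal n_groups*Z1={self.n_groups * self.Z1}"
            )
        if self.N % self.n_groups:
            raise ValueError(f"N={self.N} not divisible by n_groups={self.n_groups}")

    @property
    def J0(self) -> int:
        return sum(n_op for _, n_op, _ in self.pattern_layout)

    @property
    def J1(self) -> int:
        return sum(n_rep for _, _, n_rep in self.pattern_layout)


_DISC_RANGES = {"moderate": (0.7, 1.3), "high": (1.1, 1.7)}

_STUDY1_COV_CORR = np.array([[1.0, 0.3], [0.3, 1.0]])
_STUDY2_COV_CORR = np.array(
    [[1.0, 0.2, 0.3], [0.2, 1.0, 0.5], [0.3, 0.5, 1.0]]
)


def study_design(
    study: str,
    discrimination: str = "high",
    correlated: bool = False,
    Z0: int | None = 50,
    N: int = 2000,
) -> StudyDesign:
    """Build one of the preset pretest designs.

    Parameters
    ----------
    study : {"study1", "study2"}
        2-D (900+30 items) or 3-D (910+35 items) pool family.
    discrimination : {"moderate", "high"}
        Nonzero discriminations U(0.7, 1.3) or U(1.1, 1.7).
    correlated : bool
        Independent traits (identity covariance) or the correlated preset.
    Z0 : int or None
        Fixed operational test length; ``None`` marks a variable-length
        (posterior-SE stopping) design.
    """
    if discrimination not in _DISC_RANGES:
        raise ValueError(f"unknown discrimination level {discrimination!r}")
    disc = _DISC_RANGES[discrimination]
    if study == "study1":
        layout = tuple(
            (pat, 300, 10) for pat in ((1, 0), (0, 1), (1, 1))
        )
        cov = _STUDY1_COV_CORR if correlated else np.eye(2)
        return StudyDesign(K=2, pattern_layout=layout, disc_range=disc,
                           N=N, ability_cov=cov, Z0=Z0, Z1=6, n_groups=5)
    if study == "study2":
        pats = [p for p in product((0, 1), repeat=3) if any(p)]
        # order: single-trait, two-trait, all-trait patterns
        pats.sort(key=lambda p: (sum(p), tuple(-q for q in p)))
        layout = tuple((tuple(p), 130, 5) for p in pats)
        cov = _STUDY2_COV_CORR if correlated else np.eye(3)
        return StudyDesign(K=3, pattern_layout=layout, disc_range=disc,
                           N=N, ability_cov=cov, Z0=Z0, Z1=7, n_groups=5)
    raise ValueError(f"unknown study {study!r}")


PRESETS = {
    "study1_moderate": dict(study="study1", discrimination="moderate"),
    "study1_high": dict(study="study1", discrimination="high"),
    "study2_moderate": dict(study="study2", discrimination="moderate"),
    "study2_high": dict(study="study2", discrimination="high"),
}


def generate_item_pool(design: StudyDesign, rng: np.random.Generator) -> ItemPool:
    """Draw an item pool per the design's pattern layout.

    For every item, ``a_k ~ U(disc_range)`` where ``q_k = 1`` and
    ``a_k = 0`` elsewhere; ``b ~ N(0, 1)`` for operational and replenished
    items alike.  Operational items come first (ids 0..J0-1), then
    replenished items, both blocked by pattern in layout order.
    """
    lo, hi = design.disc_range
    K = design.K

    def _draw(n: int, pat: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        q = np.tile(np.asarray(pat, dtype=int), (n, 1))
        a = np.where(q == 1, rng.uniform(lo, hi, size=(n, K)), 0.0)
        return a, q

    a_blocks, q_blocks, roles = [], [], []
    for pat, n_op, _ in design.pattern_layout:
        a, q = _draw(n_op, pat)
        a_blocks.append(a)
        q_blocks.append(q)
        roles.append(np.ones(n_op, dtype=bool))
    for pat, _, n_rep in design.pattern_layout:
        a, q = _draw(n_rep, pat)
        a_blocks.append(a)
        q_blocks.append(q)
        roles.append(np.zeros(n_rep, dtype=bool))
    a = np.vstack(a_blocks)
    b = rng.standard_normal(a.shape[0])
    return ItemPool(a=a, b=b, Q=np.vstack(q_blocks), operational=np.concatenate(roles))


def generate_abilities(
    N: int, cov: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw N i.i.d. ability vectors from MVN(0, cov)."""
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance must be positive definite") from err
    return rng.standard_normal((N, cov.shape[0])) @ L.T


@dataclass(frozen=True)
class GroupAssignment:
    """Which replenished items each examinee group answers.

    ``item_groups[g]`` are pool item ids (a block of Z1 replenished items),
    ``examinee_groups[g]`` the examinee indices answering them.  Both are
    disjoint, exhaustive partitions.
    """

    item_groups: tuple[np.ndarray, ...]
    examinee_groups: tuple[np.ndarray, ...]

    @property
    def n_groups(self) -> int:
        return len(self.item_groups)

    def group_of_item(self, item_id: int) -> int:
        for g, ids in enumerate(self.item_groups):
            if item_id in ids:
                return g
        raise KeyError(f"item {item_id} is not a replenished item")


def make_group_assignment(
    design: StudyDesign, rng: np.random.Generator
) -> GroupAssignment:
    """Partition replenished items and examinees into matched pretest groups.

    Items of each pattern are dealt round-robin over the groups so every
    group carries the same pattern mix (two items per pattern per group in
    the 2-D design, one per pattern in the 3-D design); the within-group
    item order is then shuffled.  Examinees are split into n_groups equal
    contiguous blocks.
    """
    G = design.n_groups
    groups: list[list[int]] = [[] for _ in range(G)]
    item_id = design.J0
    for _, _, n_rep in design.pattern_layout:
        if n_rep % G:
            raise ValueError(
                f"replenished count {n_rep} per pattern not divisible by {G} groups"
            )
        for r in range(n_rep):
            groups[r % G].append(item_id)
            item_id += 1
    item_groups = []
    for g in range(G):
        ids = np.array(groups[g], dtype=int)
        item_groups.append(ids[rng.permutation(len(ids))])
    examinee_groups = tuple(
        np.arange(design.N, dtype=int).reshape(G, design.N // G)
    )
    return GroupAssignment(item_groups=tuple(item_groups),
                           examinee_groups=examinee_groups)
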