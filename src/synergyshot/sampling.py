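"""Tissue-stratified train/test splitting and nested k-shot subset selection.

Each rare tissue is split once into an 80% training pool and a 20% test set,
stratified so binary labels are represented in both at their tissue-level
proportions. Shot sets are nested: the k-shot set is contained in the 2k-shot
set, each has exactly k indices drawn from the training pool, every set of
size >= 2 contains at least one positive and one negative, and the test set
is identical across all k.

Rounding of stratified counts uses largest-remainder allocation with a
one-per-present-class floor.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .schema_io import LabeledExample

log = logging.getLogger("synergyshot")

DEFAULT_K_GRID = (0, 2, 4, 8, 16, 32, 64, 128)
DEFAULT_TEST_FRACTION = 0.2


def _tissue_rng(tissue_name: str, seed: int) -> np.random.Generator:
    # stable per-(tissue, seed) stream, independent of dict/list ordering
    mix = zlib.crc32(tissue_name.encode("utf-8")) ^ (seed & 0x7FFFFFFF)
    return np.random.default_rng(mix & 0x7FFFFFFF)


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` across classes proportional to ``targets``."""
    floors = np.floor(targets).astype(int)
    short = total - int(floors.sum())
    if short > 0:
        order = np.argsort(-(targets - floors), kind="stable")
        floors[order[:short]] += 1
    elif short < 0:
        order = np.argsort(targets - floors, kind="stable")
        for i in order:
            if short == 0:
                break
            if floors[i] > 0:
                floors[i] -= 1
                short += 1
    return floors


def _stratified_counts(n_by_class: np.ndarray, total: int, enforce_floor: bool) -> np.ndarray:
    """Per-class counts summing to ``total`` that mirror class proportions.

    With ``enforce_floor``, every class that is present overall gets at least
    one slot when total allows it.
    """
    n = int(n_by_class.sum())
    counts = _largest_remainder(n_by_class * (total / n), total)
    counts = np.minimum(counts, n_by_class)
    if enforce_floor and total >= int((n_by_class > 0).sum()):
        for c in range(len(counts)):
            while counts[c] == 0 and n_by_class[c] > 0:
                donor = int(np.argmax(counts - (n_by_class == 0) * 10**9))
                if counts[donor] <= 1:
                    break
                counts[donor] -= 1
                counts[c] += 1
    # re-top-up if the min() clip left slots unused
    deficit = total - int(counts.sum())
    if deficit > 0:
        room = n_by_class - counts
        order = np.argsort(-room, kind="stable")
        for i in order:
            take = min(deficit, int(room[i]))
            counts[i] += take
            deficit -= take
            if deficit == 0:
                break
    return counts


@dataclass
class TissueSplit:
    tissue_name: str
    train_pool: list[int]
    test_set: list[int]
    seed: int
    test_fraction: float = DEFAULT_TEST_FRACTION
    labels: list[int] = field(default_factory=list)  # per-example labels, full tissue


def make_tissue_split(
    examples: list[LabeledExample],
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 0,
    tissue_name: str | None = None,
) -> TissueSplit:
    """Stratified 80/20-style split of one tissue's examples.

    Deterministic for a fixed (tissue, seed); indices refer to positions in
    ``examples``. A single-class tissue is allowed but logged: its test set
    cannot support ranking metrics downstream.
    """
    if not examples:
        raise ValueError("examples must be non-empty")
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    tissue = tissue_name or examples[0].record.tissue_name
    labels = np.array([e.label for e in examples], dtype=int)
    n = len(examples)
    n_by_class = np.array([(labels == 0).sum(), (labels == 1).sum()])
    if (n_by_class == 0).any():
        log.warning("tissue %s has a class with zero examples; test metrics will be undefined", tissue)
    n_test = int(round(test_fraction * n))
    n_test = max(1, min(n_test, n - 1))
    test_counts = _stratified_counts(n_by_class, n_test, enforce_floor=True)
    rng = _tissue_rng(tissue, seed)
    test_idx: list[int] = []
    for c in (0, 1):
        members = np.flatnonzero(labels == c)
        if len(members) == 0:
            continue
        chosen = rng.choice(members, size=int(test_counts[c]), replace=False)
        test_idx.extend(int(i) for i in chosen)
    test_idx = sorted(test_idx)
    train_pool = sorted(set(range(n)) - set(test_idx))
    return TissueSplit(
        tissue_name=tissue,
        train_pool=train_pool,
        test_set=test_idx,
        seed=seed,
        test_fraction=test_fraction,
        labels=[int(x) for x in labels],
    )


@dataclass
class ShotPlan:
    split: TissueSplit
    k_grid: list[int]
    shots: dict[int, list[int]]  # k -> indices into the tissue's examples
    seed: int

    def to_manifest(self) -> dict:
        return {
            "tissue": self.split.tissue_name,
            "seed": self.seed,
            "test_fraction": self.split.test_fraction,
            "k_grid": list(self.k_grid),
            "train_pool": list(self.split.train_pool),
            "test_set": list(self.split.test_set),
            "shots": {str(k): list(v) for k, v in self.shots.items()},
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_manifest(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ShotPlan":
        with open(path, encoding="utf-8") as fh:
            m = json.load(fh)
        split = TissueSplit(
            tissue_name=m["tissue"],
            train_pool=m["train_pool"],
            test_set=m["test_set"],
            seed=m["seed"],
            test_fraction=m["test_fraction"],
        )
        return cls(
            split=split,
            k_grid=m["k_grid"],
            shots={int(k): v for k, v in m["shots"].items()},
            seed=m["seed"],
        )


def truncate_k_grid(k_grid, pool_size: int) -> list[int]:
    """Drop grid entries exceeding the training pool, as small tissues require."""
    return [k for k in k_grid if k <= pool_size]


def make_shot_plan(
    split: TissueSplit,
    k_grid=DEFAULT_K_GRID,
    seed: int = 0,
) -> ShotPlan:
    """Nested, label-balanced k-shot training subsets of one tissue split.

    Per-class example orders are shuffled once; the k-shot set takes prefixes
    of those orders, so sets are nested by construction. Class counts at each
    k follow the tissue's overall proportions (largest remainder), with the
    floor that every k >= 2 holds at least one of each present class.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid or k_grid[0] != 0:
        raise ValueError("k_grid must start at 0")
    pool = np.asarray(split.train_pool, dtype=int)
    if k_grid[-1] > len(pool):
        raise ValueError(
            f"max shot count {k_grid[-1]} exceeds training pool size {len(pool)} "
            f"for tissue {split.tissue_name!r}; truncate the grid "
            f"(e.g. truncate_k_grid) as small tissues require"
        )
    labels = np.asarray(split.labels, dtype=int)[pool]
    n_by_class = np.array([(labels == 0).sum(), (labels == 1).sum()])
    present = [c for c in (0, 1) if n_by_class[c] > 0]
    rng = _tissue_rng(split.tissue_name, seed ^ 0x5A5A5A)
    class_order: dict[int, np.ndarray] = {}
    for c in present:
        members = pool[labels == c]
        class_order[c] = rng.permutation(members)
    prev_counts = np.zeros(2, dtype=int)
    shots: dict[int, list[int]] = {}
    for k in k_grid:
        if k == 0:
            shots[0] = []
            continue
        floor = k >= 2 and len(present) == 2
        counts = _stratified_counts(n_by_class, k, enforce_floor=floor)
        # nesting requires per-class counts to be non-decreasing in k
        counts = np.maximum(counts, prev_counts)
        overshoot = int(counts.sum()) - k
        if overshoot > 0:
            for c in np.argsort(-(counts - prev_counts), kind="stable"):
                give = min(overshoot, int(counts[c] - prev_counts[c]))
                if floor:
                    give = min(give, int(counts[c] - 1))
                counts[c] -= give
                overshoot -= give
                if overshoot == 0:
                    break
        chosen: list[int] = []
        for c in present:
            chosen.extend(int(i) for i in class_order[c][: int(counts[c])])
        shots[k] = sorted(chosen)
        prev_counts = counts
    return ShotPlan(split=split, k_grid=k_grid, shots=shots, seed=seed)
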