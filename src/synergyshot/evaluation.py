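"""Ranking metrics with explicit tie handling, and the few-shot experiment
runner producing per-(tissue, method, k) result tables.

AUROC is the Mann–Whitney probability (ties credited 0.5); AUPRC is average
precision with tied scores entering as one group (no trapezoidal
interpolation). Both refuse single-class label sets. The runner builds one
split and shot plan per (tissue, seed), fine-tunes each method from its base
state at every k, and scores the fixed test set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .sampling import make_tissue_split, make_shot_plan, truncate_k_grid, DEFAULT_K_GRID
from .schema_io import LabeledExample, TissuePartition

log = logging.getLogger("synergyshot")


def _check_inputs(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if not ((labels == 0) | (labels == 1)).all():
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        raise ValueError("metrics require both classes in labels")
    return scores, labels


def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC: P(score_pos > score_neg) + 0.5 P(equal).

    Computed from midranks, which is algebraically identical to the average
    over all (positive, negative) pairs with half credit for ties.
    """
    scores, labels = _check_inputs(scores, labels)
    from scipy.stats import rankdata

    ranks = rankdata(scores, method="average")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auprc(scores, labels) -> float:
    """Average precision with grouped ties.

    Scores are swept in descending order; all examples sharing a score enter
    together, and precision is evaluated at the group boundary. Equals
    sum over positives of precision(rank) * recall increment.
    """
    scores, labels = _check_inputs(scores, labels)
    n_pos = int(labels.sum())
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    ap = 0.0
    tp = 0
    seen = 0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        group_pos = int(y[i:j].sum())
        tp += group_pos
        seen = j
        if group_pos:
            ap += (group_pos / n_pos) * (tp / seen)
        i = j
    return ap


@dataclass
class EvalResult:
    tissue_name: str
    method_name: str
    k: int
    auprc: float | None
    auroc: float | None
    n_pos: int
    n_neg: int
    seed: int
    note: str = ""


class OracleMethod:
    """Plumbing-check method that scores each example with its true label."""

    name = "oracle"

    def prepare(self, common_examples, seed: int) -> None:
        pass

    def evaluate_shots(self, shot_examples, test_examples) -> np.ndarray:
        return np.array([float(e.label) for e in test_examples])


def run_experiment(
    examples_by_tissue: dict[str, list[LabeledExample]],
    partition: TissuePartition,
    methods: list,
    k_grids: dict[str, list[int]] | None = None,
    seeds: list[int] = (0,),
    test_fraction: float = 0.2,
    manifest_path: str | Path | None = None,
) -> list[EvalResult]:
    """Run the tissue-stratified few-shot protocol.

    For each (rare tissue, seed): one stratified split and one nested shot
    plan; for each method and each k in the tissue's grid (truncated to the
    training-pool size), the method is adapted from its base state on the
    k-shot set and scored on the fixed test set. Methods are prepared once
    per seed on the pooled common-tissue examples. Completed cells found in
    the JSON-lines manifest are skipped, making long runs resumable.
    """
    if not partition.rare:
        raise ValueError("partition has no rare tissues to evaluate")
    common_examples = [
        e for t in sorted(partition.common) for e in examples_by_tissue.get(t, [])
    ]
    done: set[tuple] = set()
    manifest_fh = None
    if manifest_path is not None:
        manifest_path = Path(manifest_path)
        if manifest_path.exists():
            for line in manifest_path.read_text().splitlines():
                if line.strip():
                    r = json.loads(line)
                    done.add((r["tissue_name"], r["method_name"], r["k"], r["seed"]))
        manifest_fh = open(manifest_path, "a", encoding="utf-8")
    results: list[EvalResult] = []
    try:
        for seed in seeds:
            prepared = {}
            for method in methods:
                method.prepare(common_examples, seed)
                prepared[method.name] = method
            for tissue in sorted(partition.rare):
                examples = examples_by_tissue.get(tissue, [])
                if not examples:
                    log.warning("rare tissue %s has no examples; skipped", tissue)
                    continue
                split = make_tissue_split(examples, test_fraction, seed, tissue_name=tissue)
                grid = (k_grids or {}).get(tissue, list(DEFAULT_K_GRID))
                grid = truncate_k_grid(grid, len(split.train_pool))
                plan = make_shot_plan(split, grid, seed)
                test = [examples[i] for i in split.test_set]
                test_labels = np.array([e.label for e in test])
                n_pos = int(test_labels.sum())
                n_neg = len(test_labels) - n_pos
                for method in methods:
                    for k in grid:
                        key = (tissue, method.name, k, seed)
                        if key in done:
                            continue
                        shots = [examples[i] for i in plan.shots[k]]
                        if n_pos == 0 or n_neg == 0:
                            res = EvalResult(
                                tissue, method.name, k, None, None, n_pos, n_neg, seed,
                                note="undefined: single-class test set",
                            )
                        else:
                            scores = method.evaluate_shots(shots, test)
                            res = EvalResult(
                                tissue, method.name, k,
                                auprc(scores, test_labels), auroc(scores, test_labels),
                                n_pos, n_neg, seed,
                            )
                        results.append(res)
                        if manifest_fh is not None:
                            manifest_fh.write(json.dumps(asdict(res)) + "\n")
                            manifest_fh.flush()
    finally:
        if manifest_fh is not None:
            manifest_fh.close()
    return results


def results_table(results: list[EvalResult]) -> pd.DataFrame:
    """Long-form results as a DataFrame, one row per (tissue, method, k, seed)."""
    return pd.DataFrame([asdict(r) for r in results])


def pivot_table(results: list[EvalResult], metric: str = "auprc") -> pd.DataFrame:
    """Tissues × (method, k) layout for visual comparison, averaged over seeds."""
    df = results_table(results)
    return df.pivot_table(
        index="tissue_name", columns=["method_name", "k"], values=metric, aggfunc="mean"
    )


def permutation_null_band(
    labels, n_permutations: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Central (1-alpha) AUROC band under label permutation (chance ranking)."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    scores = rng.random(len(labels))  # fixed random scorer; labels permuted
    vals = [
        auroc(scores, rng.permutation(labels)) for _ in range(n_permutations)
    ]
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
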