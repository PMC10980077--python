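"""Replicated splits, extrapolation benchmarks, metrics and epistasis.

Split constructions (all index sets are pairwise disjoint, replicates differ
only by seed):

* small-N: one global 10% test set shared by every size and replicate; each
  sampled training set of size n is split 80% train / 20% validation.  The
  default size schedule is 10..20480 (doubling) with replicate counts
  (101, 23, 11, 11, 11, 11, 7, 7, 5, 5, 3, 3).
* position / mutation extrapolation: 80% of sequence positions (or of the
  mutations present) are designated train, the rest test; variants mixing
  train- and test-designated elements are discarded; train pool split 90/10
  train/validation, the full test pool is the test set.  Datasets above the
  row cap (50,000 by default) are first resampled down to the cap.
* regime extrapolation: singles form the train pool (80/20 train/val) and
  doubles the test pool, of which a random 10% is the test set; a flag
  switches to singles+doubles -> triples-and-higher for deeper datasets.
* score extrapolation: below-wild-type scores (< 0) are the train pool
  (90/10), above-wild-type (> 0) the test set; exact-0 scores are dropped.

Epistasis for a multi-mutant S with per-variant effect w(S) = score(S) −
score(WT) is E(S) = w(S) − Σ_{m∈S} w(m); the positional statistic is the mean
|E| over variants mutating exactly a given position pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .simulate import ExperimentalDataset
from .variants import Variant, apply_variant

DEFAULT_SIZES = (10, 20, 40, 80, 160, 320, 640, 1280, 2560, 5120, 10240, 20480)
DEFAULT_REPLICATES = (101, 23, 11, 11, 11, 11, 7, 7, 5, 5, 3, 3)
RESAMPLE_CAP = 50_000


class SplitError(ValueError):
    pass


@dataclass
class SplitSpec:
    split_type: str
    replicate_id: int
    seed: int
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.val = np.asarray(self.val, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        for a, b in (("train", "val"), ("train", "test"), ("val", "test")):
            if len(np.intersect1d(getattr(self, a), getattr(self, b))):
                raise SplitError(f"{a} and {b} sets intersect")

    def to_json(self) -> str:
        return json.dumps(
            {
                "split_type": self.split_type,
                "replicate_id": self.replicate_id,
                "seed": self.seed,
                "train": self.train.tolist(),
                "val": self.val.tolist(),
                "test": self.test.tolist(),
                "metadata": self.metadata,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        return cls(**json.loads(text))


def make_small_splits(
    d: ExperimentalDataset,
    sizes=None,
    replicates=None,
    seed: int = 0,
    test_frac: float = 0.1,
) -> list[SplitSpec]:
    """Replicated small-N splits sharing one global random test set."""
    sizes = tuple(sizes) if sizes is not None else DEFAULT_SIZES
    replicates = tuple(replicates) if replicates is not None else DEFAULT_REPLICATES[: len(sizes)]
    if len(sizes) != len(replicates):
        raise SplitError("sizes and replicates must have equal length")
    n = len(d)
    rng = np.random.default_rng(seed)
    test = np.sort(rng.choice(n, size=int(round(test_frac * n)), replace=False))
    pool = np.setdiff1d(np.arange(n), test)
    out = []
    for size, n_rep in zip(sizes, replicates):
        if size > len(pool):
            raise SplitError(f"requested size {size} exceeds non-test pool {len(pool)}")
        for rep in range(n_rep):
            rep_seed = int(rng.integers(2**31))
            rep_rng = np.random.default_rng(rep_seed)
            sampled = rep_rng.choice(pool, size=size, replace=False)
            n_train = int(round(0.8 * size))
            train, val = sampled[:n_train], sampled[n_train:]
            out.append(
                SplitSpec(
                    split_type="small_n", replicate_id=rep, seed=rep_seed,
                    train=train, val=val, test=test,
                    metadata={"size": size},
                )
            )
    return out


def _resample_cap(n_rows: int, cap: int, rng) -> np.ndarray:
    if n_rows <= cap:
        return np.arange(n_rows)
    return np.sort(rng.choice(n_rows, size=cap, replace=False))


def _variant_mutations(d: ExperimentalDataset) -> list[list[tuple]]:
    """(position, mutant amino acid) pairs per row."""
    return [[(s.position, s.mut_aa) for s in v.subs] for v in d.variants()]


def make_extrapolation_split(
    d: ExperimentalDataset,
    kind: str,
    n_replicates: int = 9,
    seed: int = 0,
    cap: int = RESAMPLE_CAP,
    higher_regime: bool = False,
) -> list[SplitSpec]:
    """Position / mutation / regime / score extrapolation splits (see module doc)."""
    if kind not in ("position", "mutation", "regime", "score"):
        raise SplitError(f"unknown extrapolation kind {kind!r}")
    master = np.random.default_rng(seed)
    muts = _variant_mutations(d)
    scores = d.scores()
    out = []
    for rep in range(n_replicates):
        rep_seed = int(master.integers(2**31))
        rng = np.random.default_rng(rep_seed)
        rows = (
            _resample_cap(len(d), cap, rng)
            if kind in ("position", "mutation", "score")
            else np.arange(len(d))
        )
        meta: dict = {"cap": cap}

        if kind in ("position", "mutation"):
            if kind == "position":
                universe = sorted(set(range(len(d.base_seq))))
                designator = lambda m: m[0]
            else:
                universe = sorted({m for r in rows for m in muts[r]})
                designator = lambda m: m
            universe = list(universe)
            n_train_elem = int(round(0.8 * len(universe)))
            perm = rng.permutation(len(universe))
            train_elems = {universe[i] for i in perm[:n_train_elem]}
            test_elems = {universe[i] for i in perm[n_train_elem:]}
            train_pool, test_pool = [], []
            for r in rows:
                if not muts[r]:
                    train_pool.append(r)  # wild type has no test-designated element
                    continue
                elems = {designator(m) for m in muts[r]}
                if elems <= train_elems:
                    train_pool.append(r)
                elif elems <= test_elems:
                    test_pool.append(r)
                # variants mixing train and test designations are discarded
            train_pool, test_pool = np.array(train_pool), np.array(test_pool)
            if len(test_pool) == 0:
                raise SplitError(f"{kind} extrapolation has an empty test pool")
            perm = rng.permutation(len(train_pool))
            n_train = int(round(0.9 * len(train_pool)))
            train = train_pool[perm[:n_train]]
            val = train_pool[perm[n_train:]]
            test = test_pool
            meta["train_elements"] = sorted(train_elems)
            meta["test_elements"] = sorted(test_elems)

        elif kind == "regime":
            n_subs = np.array([len(m) for m in muts])
            if higher_regime:
                train_pool = np.where((n_subs >= 1) & (n_subs <= 2))[0]
                test_pool = np.where(n_subs >= 3)[0]
            else:
                train_pool = np.where(n_subs == 1)[0]
                test_pool = np.where(n_subs == 2)[0]
            if len(test_pool) == 0:
                raise SplitError("regime extrapolation has an empty test pool")
            perm = rng.permutation(len(train_pool))
            n_train = int(round(0.8 * len(train_pool)))
            train = train_pool[perm[:n_train]]
            val = train_pool[perm[n_train:]]
            n_test = max(1, int(round(0.1 * len(test_pool))))
            test = rng.choice(test_pool, size=n_test, replace=False)
            meta["higher_regime"] = higher_regime

        else:  # score
            train_pool = rows[scores[rows] < 0]
            test_pool = rows[scores[rows] > 0]  # exact wild-type scores dropped
            if len(test_pool) == 0:
                raise SplitError("score extrapolation has an empty test pool")
            perm = rng.permutation(len(train_pool))
            n_train = int(round(0.9 * len(train_pool)))
            train = train_pool[perm[:n_train]]
            val = train_pool[perm[n_train:]]
            test = test_pool

        out.append(
            SplitSpec(
                split_type=kind, replicate_id=rep, seed=rep_seed,
                train=np.sort(train), val=np.sort(val), test=np.sort(test),
                metadata=meta,
            )
        )
    return out


def top_k_indices(y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values; ties broken by stable index order."""
    return np.argsort(-np.asarray(y), kind="stable")[:k]


def evaluate_predictions(y_true, y_pred, k: int = 100) -> dict:
    """Spearman rank correlation and recall of the top-k true variants."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise SplitError("need two equal-length arrays of at least 2 values")
    if np.ptp(y_true) == 0:
        warnings.warn("constant y_true: Spearman undefined", stacklevel=2)
        rho = np.nan
    else:
        rho = float(spearmanr(y_true, y_pred).statistic)
    k = min(k, len(y_true))
    top_true = set(top_k_indices(y_true, k).tolist())
    top_pred = set(top_k_indices(y_pred, k).tolist())
    return {"spearman": rho, "recall_top_k": len(top_true & top_pred) / k, "k": k}


@dataclass
class EpistasisResult:
    effects: pd.DataFrame  # variant, n_subs, w, epistasis
    positional: np.ndarray  # (L, L) mean |E| per position pair (symmetric)
    wt_score: float

    def top_pair(self) -> tuple[int, int]:
        masked = np.where(np.isnan(self.positional), -np.inf, self.positional)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        return (int(i), int(j)) if i < j else (int(j), int(i))


def epistasis_scores(
    score_fn,
    base_seq: str,
    variants: list[Variant],
) -> EpistasisResult:
    """Epistasis of multi-mutants relative to their constituent singles.

    ``score_fn`` maps a sequence string to a scalar.  Effects w(S) are scored
    relative to the wild type; E(S) subtracts the summed effects of each
    constituent single (singles have E = 0 by convention).  The positional
    matrix averages |E| over double mutants at each position pair (NaN where
    no doubles were seen).
    """
    wt_score = float(score_fn(base_seq))
    single_cache: dict = {}

    def single_effect(sub) -> float:
        if sub not in single_cache:
            seq = apply_variant(base_seq, Variant(subs=(sub,)))
            single_cache[sub] = float(score_fn(seq)) - wt_score
        return single_cache[sub]

    rows = []
    length = len(base_seq)
    sums = np.zeros((length, length))
    counts = np.zeros((length, length), dtype=int)
    for v in variants:
        w = float(score_fn(apply_variant(base_seq, v))) - wt_score
        if v.n_subs <= 1:
            e = 0.0
        else:
            e = w - sum(single_effect(s) for s in v.subs)
        rows.append(
            {"variant": v.to_string(), "n_subs": v.n_subs, "w": w, "epistasis": e}
        )
        if v.n_subs == 2:
            i, j = v.positions
            sums[i, j] += abs(e)
            sums[j, i] += abs(e)
            counts[i, j] += 1
            counts[j, i] += 1
    with np.errstate(invalid="ignore"):
        positional = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return EpistasisResult(
        effects=pd.DataFrame(rows), positional=positional, wt_score=wt_score
    )
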