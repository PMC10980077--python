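"""Attribute-table cleaning and experimental-dataset normalization.

Pretraining tables are cleaned in a fixed order: (1) drop rows with any NaN
attribute, (2) deduplicate per (base_pdb, variant) keeping one seeded-random
row, (3) per base-protein group, remove rows whose *total_score* is a robust
outlier under the modified z-score

    s_i = |x_i - median(x)| / MAD,      MAD = median(|x_j - median(x)|),

dropping rows with s_i > 6.5.  The absolute deviation is used in the
numerator (a signed numerator would never flag low-side outliers and is
inconsistent with MAD's definition); no 0.6745 consistency constant is
applied.  Groups with MAD = 0 skip outlier removal.

Standardization is per (base_pdb, term), using means/sds computed on the
training rows only, so held-out rows are transformed with training statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import EXCLUDED_TERMS, ExperimentalDataset

META_COLUMNS = ("base_pdb", "variant", "injected_outlier")

DEFAULT_Z_THRESHOLD = 6.5


class PreprocessError(ValueError):
    pass


def _term_columns(t: pd.DataFrame) -> list[str]:
    return [c for c in t.columns if c not in META_COLUMNS]


@dataclass
class GroupOutlierStats:
    median: float
    mad: float
    scores: pd.Series  # modified z-score per row id
    removed: list = field(default_factory=list)


@dataclass
class OutlierReport:
    """Per-removal bookkeeping for one cleaning pass."""

    n_in: int
    n_out: int
    removed_nan: list
    removed_duplicate: list
    removed_outlier: list
    groups: dict  # base_pdb -> GroupOutlierStats

    @property
    def counts(self) -> dict:
        return {
            "nan": len(self.removed_nan),
            "duplicate": len(self.removed_duplicate),
            "outlier": len(self.removed_outlier),
        }

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "counts": self.counts,
            "groups": {
                k: {
                    "median": g.median,
                    "mad": g.mad,
                    "removed": list(g.removed),
                }
                for k, g in self.groups.items()
            },
        }


def modified_z_scores(x: pd.Series) -> tuple[pd.Series, float, float]:
    """Robust outlier statistic: |x - median| / MAD (MAD from absolute devs)."""
    med = float(x.median())
    abs_dev = (x - med).abs()
    mad = float(abs_dev.median())
    if mad == 0.0:
        return pd.Series(np.zeros(len(x)), index=x.index), med, mad
    return abs_dev / mad, med, mad


def clean_attribute_table(
    t: pd.DataFrame,
    seed: int = 0,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> tuple[pd.DataFrame, OutlierReport]:
    """NaN drop, seeded dedup, grouped modified-z-score outlier filter."""
    if len(t) == 0:
        raise PreprocessError("empty attribute table")
    if "total_score" not in t.columns:
        raise PreprocessError("attribute table lacks a total_score column")
    t = t.reset_index(drop=True)
    terms = _term_columns(t)

    nan_mask = t[terms].isna().any(axis=1)
    removed_nan = t.index[nan_mask].tolist()
    t1 = t.loc[~nan_mask]

    rng = np.random.default_rng(seed)
    keep_rows = []
    for _, group in t1.groupby(["base_pdb", "variant"], sort=False):
        keep_rows.append(group.index[rng.integers(len(group))])
    keep_rows = sorted(keep_rows)
    removed_dup = sorted(set(t1.index) - set(keep_rows))
    t2 = t1.loc[keep_rows]

    removed_out = []
    groups: dict = {}
    for pdb, group in t2.groupby("base_pdb", sort=False):
        scores, med, mad = modified_z_scores(group["total_score"])
        stats = GroupOutlierStats(median=med, mad=mad, scores=scores)
        if mad == 0.0:
            warnings.warn(
                f"group {pdb!r} has MAD 0; outlier removal skipped", stacklevel=2
            )
        else:
            stats.removed = scores.index[scores > z_threshold].tolist()
            removed_out.extend(stats.removed)
        groups[pdb] = stats
    t3 = t2.drop(index=removed_out).reset_index(drop=True)

    report = OutlierReport(
        n_in=len(t),
        n_out=len(t3),
        removed_nan=removed_nan,
        removed_duplicate=removed_dup,
        removed_outlier=sorted(removed_out),
        groups=groups,
    )
    return t3, report


def drop_excluded_terms(t: pd.DataFrame) -> pd.DataFrame:
    """Remove the five catalog terms excluded from training (55 remain)."""
    present = [c for c in EXCLUDED_TERMS if c in t.columns]
    missing = sorted(set(EXCLUDED_TERMS) - set(present))
    if missing:
        warnings.warn(f"excluded terms already absent: {missing}", stacklevel=2)
    return t.drop(columns=present)


def standardize_attributes(
    t: pd.DataFrame, train_ids
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(base_pdb, term) standardization with train-only statistics.

    Returns the transformed table and a tidy stats frame (base_pdb, term,
    mean, sd) for reuse on held-out data.  Constant terms (sd = 0) are
    centered only.
    """
    t = t.copy()
    terms = _term_columns(t)
    train_ids = pd.Index(train_ids)
    stats_rows = []
    for pdb, group in t.groupby("base_pdb", sort=False):
        train_rows = group.index.intersection(train_ids)
        if len(train_rows) == 0:
            raise PreprocessError(f"group {pdb!r} has no training rows")
        mean = t.loc[train_rows, terms].mean()
        sd = t.loc[train_rows, terms].std(ddof=0)
        scale = sd.replace(0.0, 1.0)
        t.loc[group.index, terms] = (group[terms] - mean) / scale
        for term in terms:
            stats_rows.append(
                {"base_pdb": pdb, "term": term, "mean": mean[term], "sd": sd[term]}
            )
    return t, pd.DataFrame(stats_rows)


def apply_standardization(t: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Transform a table with previously computed group/term statistics."""
    t = t.copy()
    lookup = stats.set_index(["base_pdb", "term"])
    for pdb, group in t.groupby("base_pdb", sort=False):
        for term in _term_columns(t):
            mean = lookup.loc[(pdb, term), "mean"]
            sd = lookup.loc[(pdb, term), "sd"] or 1.0
            t.loc[group.index, term] = (group[term] - mean) / sd
    return t


def normalize_experimental_dataset(
    raw: pd.DataFrame,
    base_seq: str,
    wt_score: float | None = None,
    log_already: bool = True,
    offset: int = 0,
    base_id: str = "",
) -> ExperimentalDataset:
    """Standardize a raw variant/score table into an ExperimentalDataset.

    Removes stop-codon variants (any token mutating to ``*``), converts
    indexing to 0-based via ``offset``, log-transforms unless ``log_already``,
    subtracts the wild-type score (inferred from a wild-type row when
    ``wt_score`` is None) and rounds to 7 decimals.
    """
    from .variants import parse_variant

    if not {"variant", "score"} <= set(raw.columns):
        raise PreprocessError("raw table needs 'variant' and 'score' columns")
    df = raw.copy().reset_index(drop=True)
    df["variant"] = df["variant"].fillna("").astype(str).str.strip()
    has_stop = df["variant"].str.contains(r"\*", regex=True)
    df = df.loc[~has_stop].reset_index(drop=True)
    canonical = [
        parse_variant(tok, base_seq, offset=offset).to_string()
        for tok in df["variant"]
    ]
    df["variant"] = canonical
    scores = pd.to_numeric(df["score"]).to_numpy(dtype=float)
    if not log_already:
        if np.any(scores <= 0):
            raise PreprocessError("cannot log-transform non-positive scores")
        scores = np.log(scores)
    if wt_score is None:
        wt_rows = np.where(df["variant"] == "")[0]
        if len(wt_rows) == 0:
            raise PreprocessError(
                "wt_score not given and no wild-type row to infer it from"
            )
        wt_score = float(scores[wt_rows[0]])
    elif not log_already:
        wt_score = float(np.log(wt_score))
    df["score"] = np.round(scores - wt_score, 7)
    return ExperimentalDataset(df=df, base_seq=base_seq, base_id=base_id)
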