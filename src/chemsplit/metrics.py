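"""Fold-quality evaluation: pair similarity leakage, data and label imbalance.

Three criteria quantify how a whole-compound-domain split behaves:

* **Intra-fold pair fraction by similarity bin** — random compound pairs
  are binned by fingerprint Tanimoto similarity into 10 equidistant bins;
  per bin, the fraction of pairs whose two members share a fold.  A purely
  random split gives 1/n_folds in every bin; a series-aware split should
  climb toward 1.0 as similarity approaches identity.
* **Data imbalance** — a task is flagged when any fold (including empty
  ones) holds fewer than 5 of its compounds.
* **Label imbalance** — a task is flagged when the population standard
  deviation of the fraction of actives across populated folds exceeds 0.05.

Task-level flags are aggregated into task-size bins with lower limits
10, 100, 1000, 10000, 100000 (tasks under 10 compounds reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import MoleculeRecord, pack_fingerprints
from .hashing import FoldAssignment

__all__ = [
    "ActivityTable",
    "PairSimilarityReport",
    "sample_pairs",
    "pair_similarities",
    "intra_fold_fraction",
    "task_data_imbalance",
    "task_label_imbalance",
    "imbalance_report",
    "aggregate_by_task_size",
    "TASK_SIZE_BIN_LOWER_LIMITS",
]

N_SIMILARITY_BINS = 10
TASK_SIZE_BIN_LOWER_LIMITS = (10, 100, 1000, 10000, 100000)
BELOW5_THRESHOLD = 5
LABEL_IMBALANCE_STD = 0.05


@dataclass
class ActivityTable:
    """Sparse binary activity triplets (compound_id, task_id, label)."""

    records: pd.DataFrame

    def __post_init__(self):
        required = {"compound_id", "task_id", "label"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"activity table missing columns: {sorted(missing)}")
        if not self.records["label"].isin((0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if self.records.duplicated(["compound_id", "task_id"]).any():
            raise ValueError("at most one label per (compound_id, task_id)")

    def __len__(self):
        return len(self.records)

    @property
    def task_ids(self):
        return self.records["task_id"].unique()


@dataclass
class PairSimilarityReport:
    """Per-similarity-bin pair counts and intra-fold fractions.

    ``intra_fold_fraction`` is NaN for empty bins (undefined, never 0).
    """

    bin_edges: np.ndarray
    pair_counts: np.ndarray
    intra_fold_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "n_pairs": self.pair_counts,
                "intra_fold_fraction": self.intra_fold_fraction,
            }
        )


def sample_pairs(
    molecules: Sequence[MoleculeRecord], n_pairs: int, seed: int
) -> list[tuple[str, str]]:
    """Sample unordered distinct-id pairs uniformly with replacement."""
    n = len(molecules)
    if n < 2:
        raise ValueError("need at least 2 molecules to sample pairs")
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    ids = [m.compound_id for m in molecules]
    out_a = np.empty(n_pairs, dtype=np.int64)
    out_b = np.empty(n_pairs, dtype=np.int64)
    filled = 0
    while filled < n_pairs:
        need = n_pairs - filled
        a = rng.integers(0, n, size=need + need // 8 + 8)
        b = rng.integers(0, n, size=a.size)
        keep = a != b  # self-pairs excluded; unordered pairs remain uniform
        take = min(int(keep.sum()), need)
        out_a[filled : filled + take] = a[keep][:take]
        out_b[filled : filled + take] = b[keep][:take]
        filled += take
    return [(ids[i], ids[j]) for i, j in zip(out_a, out_b)]


def pair_similarities(
    molecules: Sequence[MoleculeRecord],
    pairs: Sequence[tuple[str, str]],
    chunk: int = 65536,
) -> np.ndarray:
    """Tanimoto similarity for each (id, id) pair, popcount-vectorized."""
    index = {m.compound_id: i for i, m in enumerate(molecules)}
    packed = pack_fingerprints([m.fingerprint for m in molecules])
    pc = np.bitwise_count(packed).sum(axis=1)
    ia = np.fromiter((index[a] for a, _ in pairs), dtype=np.int64, count=len(pairs))
    ib = np.fromiter((index[b] for _, b in pairs), dtype=np.int64, count=len(pairs))
    sims = np.empty(len(pairs), dtype=float)
    for start in range(0, len(pairs), chunk):
        sl = slice(start, min(start + chunk, len(pairs)))
        inter = np.bitwise_count(packed[ia[sl]] & packed[ib[sl]]).sum(axis=1)
        union = pc[ia[sl]] + pc[ib[sl]] - inter
        with np.errstate(invalid="ignore"):
            s = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
        sims[sl] = s
    return sims


def intra_fold_fraction(
    pairs: Sequence[tuple[str, str]],
    similarities: np.ndarray,
    folds: FoldAssignment,
) -> PairSimilarityReport:
    """Fraction of same-fold pairs per similarity bin.

    Bins are [0,0.1), ..., [0.8,0.9), [0.9,1.0]; the top bin is closed so
    identical pairs (similarity 1.0) are counted there.
    """
    similarities = np.asarray(similarities, dtype=float)
    if len(pairs) != len(similarities):
        raise ValueError("pairs and similarities must align")
    missing = {c for p in pairs for c in p if c not in folds.mapping}
    if missing:
        raise ValueError(f"compounds without fold assignment: {sorted(missing)[:5]}")

    fold_a = np.fromiter((folds.mapping[a] for a, _ in pairs), dtype=np.int64)
    fold_b = np.fromiter((folds.mapping[b] for _, b in pairs), dtype=np.int64)
    same = fold_a == fold_b

    bins = np.clip(
        (similarities * N_SIMILARITY_BINS).astype(np.int64), 0, N_SIMILARITY_BINS - 1
    )
    counts = np.bincount(bins, minlength=N_SIMILARITY_BINS)
    same_counts = np.bincount(bins, weights=same, minlength=N_SIMILARITY_BINS)
    with np.errstate(invalid="ignore"):
        fractions = np.where(counts > 0, same_counts / np.maximum(counts, 1), np.nan)
    return PairSimilarityReport(
        bin_edges=np.linspace(0.0, 1.0, N_SIMILARITY_BINS + 1),
        pair_counts=counts,
        intra_fold_fraction=fractions,
    )


def _require_folds(activity: ActivityTable, folds: FoldAssignment) -> pd.DataFrame:
    df = activity.records.copy()
    missing = set(df["compound_id"]) - set(folds.mapping)
    if missing:
        raise ValueError(
            f"activity compounds without fold assignment: {sorted(missing)[:5]}"
        )
    df["fold"] = df["compound_id"].map(folds.mapping)
    return df


def task_data_imbalance(
    activity: ActivityTable, folds: FoldAssignment, n_folds: int | None = None
) -> pd.DataFrame:
    """Per task: total compounds, per-fold counts and the below-5 flag.

    Folds with none of a task's compounds count as 0, so any task smaller
    than 5*n_folds is necessarily flagged (pigeonhole).
    """
    n_folds = n_folds if n_folds is not None else folds.n_folds
    df = _require_folds(activity, folds)
    rows = []
    for task_id, grp in df.groupby("task_id", sort=True):
        counts = np.bincount(grp["fold"], minlength=n_folds)
        rows.append(
            {
                "task_id": task_id,
                "n_compounds": len(grp),
                "fold_counts": counts.tolist(),
                "min_fold_count": int(counts.min()),
                "below5_flag": bool(counts.min() < BELOW5_THRESHOLD),
            }
        )
    return pd.DataFrame(rows)


def task_label_imbalance(
    activity: ActivityTable, folds: FoldAssignment
) -> pd.DataFrame:
    """Per task: active fraction per populated fold and the imbalance flag.

    The standard deviation is the population std across folds holding at
    least one of the task's compounds (an active fraction is undefined for
    an empty fold); the flag is strict: std > 0.05.
    """
    df = _require_folds(activity, folds)
    rows = []
    for task_id, grp in df.groupby("task_id", sort=True):
        fractions = grp.groupby("fold")["label"].mean().to_numpy()
        std = float(np.std(fractions))  # population std (ddof=0)
        rows.append(
            {
                "task_id": task_id,
                "n_compounds": len(grp),
                "n_populated_folds": len(fractions),
                "active_fraction_std": std,
                "label_imbalance_flag": bool(std > LABEL_IMBALANCE_STD),
            }
        )
    return pd.DataFrame(rows)


def imbalance_report(
    activity: ActivityTable, folds: FoldAssignment, n_folds: int | None = None
) -> pd.DataFrame:
    """Joined per-task data- and label-imbalance table."""
    data = task_data_imbalance(activity, folds, n_folds)
    label = task_label_imbalance(activity, folds)
    return data.merge(
        label[["task_id", "active_fraction_std", "label_imbalance_flag"]], on="task_id"
    )


def _size_bin(n: int) -> str:
    label = "<10"
    for lo in TASK_SIZE_BIN_LOWER_LIMITS:
        if n >= lo:
            label = str(lo)
    return label


def aggregate_by_task_size(per_task: pd.DataFrame) -> pd.DataFrame:
    """Fraction of flagged tasks per task-size bin (lower limits 10..100000)."""
    df = per_task.copy()
    df["task_size_bin"] = df["n_compounds"].map(_size_bin)
    flag_cols = [c for c in ("below5_flag", "label_imbalance_flag") if c in df.columns]
    agg = df.groupby("task_size_bin")[flag_cols].mean()
    agg["n_tasks"] = df.groupby("task_size_bin").size()
    order = ["<10"] + [str(lo) for lo in TASK_SIZE_BIN_LOWER_LIMITS]
    agg = agg.reindex([b for b in order if b in agg.index])
    return agg.rename(
        columns={
            "below5_flag": "fraction_below5",
            "label_imbalance_flag": "fraction_label_imbalance",
        }
    ).reset_index()
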