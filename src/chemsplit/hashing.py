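"""Deterministic hash-based fold assignment.

Federated fold splitting forbids online coordination: every party must be
able to compute, locally and independently, the same fold for the same
standardized structure.  A cryptographic hash of the canonical SMILES gives
a pseudo-random but fully deterministic mapping.  Parties that want the
assignment to be private can agree on a shared secret which is mixed into
the hash input.

The reduction from hash output to fold index is fixed precisely so that
independent implementations agree bit-for-bit:

    fold = int.from_bytes(SHA256(secret || 0x00 || key)[:8], "big") % n_folds

A single 0x00 separator prevents ("ab","c") / ("a","bc") ambiguity.  Folds
are 0-based.  Modulo bias is negligible for n_folds << 2^64.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .chem import MoleculeRecord

__all__ = [
    "SplitConfig",
    "FoldAssignment",
    "hash_to_fold",
    "assign_random_folds",
    "partition_folds",
]

METHODS = ("random", "lsh", "sphere", "scaffold")


@dataclass
class SplitConfig:
    """Shared configuration of any split method."""

    n_folds: int = 5
    secret: str | None = None
    method: str = "random"

    def __post_init__(self):
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; one of {METHODS}")


@dataclass
class FoldAssignment:
    """The central output of every split method: compound_id -> fold index."""

    mapping: dict
    n_folds: int
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = {c: f for c, f in self.mapping.items() if not 0 <= f < self.n_folds}
        if bad:
            raise ValueError(f"fold indices outside [0, n_folds): {bad}")

    def __len__(self):
        return len(self.mapping)

    def __getitem__(self, compound_id):
        return self.mapping[compound_id]

    def fold_counts(self) -> list[int]:
        counts = [0] * self.n_folds
        for f in self.mapping.values():
            counts[f] += 1
        return counts

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"compound_id": list(self.mapping), "fold": list(self.mapping.values())}
        )


def hash_to_fold(key: str, n_folds: int, secret: str | None = None) -> int:
    """Map a text key to a fold index, deterministically across machines."""
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if not key:
        raise ValueError("key must be non-empty")
    secret_bytes = (secret or "").encode("utf-8")
    digest = hashlib.sha256(secret_bytes + b"\x00" + key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % n_folds


def assign_random_folds(
    molecules: Iterable[MoleculeRecord], config: SplitConfig
) -> FoldAssignment:
    """Pseudo-random split: hash each compound's canonical SMILES to a fold.

    Identical parent structures (identical canonical SMILES) always land in
    the same fold, at every party, without communication.
    """
    mapping = {
        mol.compound_id: hash_to_fold(mol.canonical_smiles, config.n_folds, config.secret)
        for mol in molecules
    }
    return FoldAssignment(
        mapping=mapping,
        n_folds=config.n_folds,
        method="random",
        params={"secret_used": config.secret is not None},
    )


def partition_folds(
    assignment: FoldAssignment, ratio: Sequence[int] = (3, 1, 1)
) -> Mapping[str, str]:
    """Map fold indices to train/valid/test sets by index order.

    With 5 folds and the default 3:1:1 ratio, folds {0,1,2} are training,
    {3} validation and {4} test (a 60-20-20 split in expectation).
    """
    if sum(ratio) != assignment.n_folds:
        raise ValueError(
            f"ratio {tuple(ratio)} does not sum to n_folds={assignment.n_folds}"
        )
    names = ("train", "valid", "test")[: len(ratio)]
    fold_to_set = {}
    fold = 0
    for name, count in zip(names, ratio):
        for _ in range(count):
            fold_to_set[fold] = name
            fold += 1
    return {cid: fold_to_set[f] for cid, f in assignment.mapping.items()}
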