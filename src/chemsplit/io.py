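"""CSV / SMILES-file readers and writers shared by the CLI and scripts.

Dialect: comma-separated, UTF-8, header row, no index column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .hashing import FoldAssignment

__all__ = [
    "read_compound_table",
    "write_fold_csv",
    "read_fold_csv",
    "write_error_report",
    "read_activity_csv",
]


def read_compound_table(path: str | Path) -> list[tuple[str, str]]:
    """(compound_id, smiles) entries from a CSV or a plain .smi file.

    CSV needs columns ``compound_id,smiles``.  A ``.smi`` file has one
    SMILES per line with an optional whitespace-separated identifier;
    missing identifiers become mol_<lineno>.
    """
    path = Path(path)
    if path.suffix.lower() in (".smi", ".smiles"):
        entries = []
        for lineno, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"mol_{lineno}"
            entries.append((cid, smiles))
        return entries
    df = pd.read_csv(path, dtype=str)
    missing = {"compound_id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return list(zip(df["compound_id"], df["smiles"]))


def write_fold_csv(assignment: FoldAssignment, path: str | Path) -> None:
    assignment.to_frame().to_csv(path, index=False)


def read_fold_csv(path: str | Path, n_folds: int | None = None) -> FoldAssignment:
    df = pd.read_csv(path, dtype={"compound_id": str, "fold": int})
    missing = {"compound_id", "fold"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    mapping = dict(zip(df["compound_id"], df["fold"]))
    if n_folds is None:
        n_folds = int(df["fold"].max()) + 1 if len(df) else 1
    return FoldAssignment(mapping=mapping, n_folds=n_folds, method="file")


def write_error_report(errors: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(errors, columns=["compound_id", "reason"]).to_csv(path, index=False)


def read_activity_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound_id": str, "task_id": str, "label": int})
    missing = {"compound_id", "task_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
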