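"""Locality-sensitive hashing split on fingerprint bits.

Compounds are binned by the values of the N fingerprint bits whose
frequency in a reference set is closest to 0.5 (for a binary feature that
is the maximum-entropy condition, so this *is* the highest-entropy bit
selection).  Similar compounds tend to agree on those bits and fall into
the same bin; each bin is then hashed to a fold with the same keyed SHA-256
scheme as the random split.

For federated use the reference set is public (e.g. a public bioactivity
collection), so every party derives the identical bit selection and the
identical bin -> fold mapping without exchanging structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chem import FoldedFingerprint, MoleculeRecord
from .hashing import FoldAssignment, SplitConfig, hash_to_fold

__all__ = ["LSHModel", "select_high_entropy_bits", "compute_bin", "assign_lsh_folds"]

DEFAULT_N_SELECT = 16
_KEY_PREFIX = "LSH:"  # namespaces bin keys against SMILES keys under a shared secret


@dataclass
class LSHModel:
    """Ordered high-entropy bit selection plus reference frequencies."""

    selected_bits: list
    reference_frequencies: list
    n_bits: int

    def __post_init__(self):
        bits = list(self.selected_bits)
        if bits != sorted(set(bits)):
            raise ValueError("selected_bits must be strictly ascending")
        if bits and not (0 <= bits[0] and bits[-1] < self.n_bits):
            raise ValueError("selected_bits outside [0, n_bits)")
        if len(self.reference_frequencies) != len(bits):
            raise ValueError("one reference frequency per selected bit")

    @property
    def n_select(self) -> int:
        return len(self.selected_bits)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_bits": [int(b) for b in self.selected_bits],
            "reference_frequencies": [float(f) for f in self.reference_frequencies],
            "n_bits": int(self.n_bits),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LSHModel":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def select_high_entropy_bits(
    reference: Sequence[FoldedFingerprint], n_select: int = DEFAULT_N_SELECT
) -> LSHModel:
    """Select the n_select bits whose reference frequency is closest to 0.5.

    Ties on |frequency - 0.5| are broken toward the lower bit index; the
    returned selection is sorted ascending.  Bit-for-bit reproducible for a
    given reference collection.
    """
    reference = list(reference)
    if not reference:
        raise ValueError("reference collection must be non-empty")
    n_bits = reference[0].n_bits
    if any(fp.n_bits != n_bits for fp in reference):
        raise ValueError("all reference fingerprints must share n_bits")
    if not 1 <= n_select <= n_bits:
        raise ValueError("n_select must be in [1, n_bits]")

    counts = np.zeros(n_bits, dtype=np.int64)
    for fp in reference:
        if fp.on_bits:
            counts[np.fromiter(fp.on_bits, dtype=np.int64)] += 1
    freqs = counts / len(reference)
    # stable sort on |f - 0.5| keeps the lower bit index first on ties
    order = np.argsort(np.abs(freqs - 0.5), kind="stable")
    chosen = np.sort(order[:n_select])
    return LSHModel(
        selected_bits=[int(b) for b in chosen],
        reference_frequencies=[float(freqs[b]) for b in chosen],
        n_bits=n_bits,
    )


def compute_bin(fp: FoldedFingerprint, model: LSHModel) -> str:
    """Bin key: '1'/'0' per selected bit in ascending index order."""
    if fp.n_bits != model.n_bits:
        raise ValueError(
            f"fingerprint space {fp.n_bits} does not match model {model.n_bits}"
        )
    return "".join("1" if b in fp.on_bits else "0" for b in model.selected_bits)


def assign_lsh_folds(
    molecules: Iterable[MoleculeRecord], model: LSHModel, config: SplitConfig
) -> FoldAssignment:
    """Bin each compound by its selected bits and hash the bin to a fold.

    All compounds in a bin share a fold; at most 2^N distinct bins occur.
    """
    mapping = {}
    for mol in molecules:
        key = _KEY_PREFIX + compute_bin(mol.fingerprint, model)
        mapping[mol.compound_id] = hash_to_fold(key, config.n_folds, config.secret)
    return FoldAssignment(
        mapping=mapping,
        n_folds=config.n_folds,
        method="lsh",
        params={
            "n_select": model.n_select,
            "secret_used": config.secret is not None,
        },
    )
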