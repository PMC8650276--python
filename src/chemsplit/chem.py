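"""Structure standardization and folded circular fingerprints.

Every fold-splitting method in this package keys off a *canonical*
representation of the parent compound: two inputs that differ only in salt
form, charge state of simple ionizable groups, isotope labels or atom
ordering must map to the same canonical SMILES, and therefore to the same
fingerprint and the same fold.  The standardization contract implemented
here is deliberately minimal:

1. keep the largest organic fragment (strips counter-ions / co-crystals),
2. neutralize simple charges where a neutral form exists,
3. strip isotope labels,
4. emit RDKit canonical SMILES.

Tautomer canonicalization and stereochemistry flattening are out of scope;
stereo descriptors present in the input are preserved as-is.

Fingerprints are Morgan (extended-connectivity) fingerprints of radius 3
(ECFP6) folded into a 32,768-bit space, represented sparsely as the set of
on-bit indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

DEFAULT_N_BITS = 32768
DEFAULT_RADIUS = 3

__all__ = [
    "FoldedFingerprint",
    "MoleculeRecord",
    "StructureError",
    "standardize_smiles",
    "compute_fingerprint",
    "tanimoto_similarity",
    "prepare_molecules",
    "pack_fingerprints",
    "packed_tanimoto",
]


class StructureError(ValueError):
    """Raised when a SMILES cannot be parsed or standardized.

    Carries the offending input so batch callers can skip-and-log.
    """

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        self.reason = reason
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class FoldedFingerprint:
    """Sparse folded circular fingerprint: the set of on-bit indices."""

    on_bits: frozenset
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS

    def __post_init__(self):
        if self.on_bits and not all(0 <= b < self.n_bits for b in self.on_bits):
            raise ValueError("on_bits outside [0, n_bits)")


@dataclass
class MoleculeRecord:
    """A compound: identifier, supplied SMILES, standardized parent, fingerprint."""

    compound_id: str
    raw_smiles: str
    canonical_smiles: str
    fingerprint: FoldedFingerprint | None = None


_largest_fragment = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()


def _parse(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureError(str(smiles), "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    return mol


def standardize_smiles(raw: str) -> str:
    """Canonical SMILES of the standardized parent structure.

    Largest organic fragment, neutralized where a neutral form exists,
    isotope labels stripped.  Deterministic.  Raises :class:`StructureError`
    on unparseable input.
    """
    mol = _parse(raw)
    mol = _largest_fragment.choose(mol)
    mol = _uncharger.uncharge(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    out = Chem.MolToSmiles(mol)
    if not out:
        raise StructureError(raw, "standardization produced empty structure")
    return out


def compute_fingerprint(
    canonical: str,
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_RADIUS,
) -> FoldedFingerprint:
    """Folded Morgan fingerprint of a (canonical) SMILES."""
    if n_bits < 2:
        raise ValueError("n_bits must be >= 2")
    mol = _parse(canonical)
    gen = _get_generator(radius, n_bits)
    bits = frozenset(gen.GetFingerprint(mol).GetOnBits())
    return FoldedFingerprint(on_bits=bits, n_bits=n_bits, radius=radius)


_GENERATORS: dict = {}


def _get_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _GENERATORS[key]


def tanimoto_similarity(a: FoldedFingerprint, b: FoldedFingerprint) -> float:
    """|A∩B| / |A∪B|; 1.0 when both bit sets are empty (degenerate convention)."""
    if a.n_bits != b.n_bits:
        raise ValueError(
            f"fingerprint spaces differ: {a.n_bits} vs {b.n_bits}"
        )
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 1.0
    return len(a.on_bits & b.on_bits) / union


def prepare_molecules(
    entries: Iterable[tuple[str, str]],
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_RADIUS,
) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Standardize and fingerprint a batch of (compound_id, smiles) entries.

    Returns (records, errors); errors are (compound_id, reason) pairs for
    inputs that failed to parse.  A failing structure never aborts the batch.
    """
    records: list[MoleculeRecord] = []
    errors: list[tuple[str, str]] = []
    for compound_id, smiles in entries:
        try:
            canonical = standardize_smiles(smiles)
            fp = compute_fingerprint(canonical, n_bits=n_bits, radius=radius)
        except StructureError as exc:
            errors.append((compound_id, exc.reason))
            continue
        records.append(
            MoleculeRecord(
                compound_id=str(compound_id),
                raw_smiles=smiles,
                canonical_smiles=canonical,
                fingerprint=fp,
            )
        )
    return records, errors


# ---------------------------------------------------------------------------
# Packed bit-matrix helpers.  Sphere exclusion and the pair-similarity
# metrics compute millions of Tanimoto coefficients; packing each
# fingerprint into uint64 words lets numpy popcount do the work.
# ---------------------------------------------------------------------------


def pack_fingerprints(fps: Sequence[FoldedFingerprint]) -> np.ndarray:
    """Pack fingerprints into a (n, n_bits/64) uint64 bit matrix."""
    if not fps:
        return np.zeros((0, 0), dtype=np.uint64)
    n_bits = fps[0].n_bits
    if any(fp.n_bits != n_bits for fp in fps):
        raise ValueError("all fingerprints must share n_bits")
    words = (n_bits + 63) // 64
    packed = np.zeros((len(fps), words), dtype=np.uint64)
    one = np.uint64(1)
    for i, fp in enumerate(fps):
        if not fp.on_bits:
            continue
        bits = np.fromiter(fp.on_bits, dtype=np.int64)
        w, b = np.divmod(bits, 64)
        np.bitwise_or.at(packed[i], w, one << b.astype(np.uint64))
    return packed


def packed_tanimoto(row: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Tanimoto similarity of one packed fingerprint against a packed matrix."""
    inter = np.bitwise_count(matrix & row).sum(axis=1)
    pc_row = int(np.bitwise_count(row).sum())
    pc_mat = np.bitwise_count(matrix).sum(axis=1)
    union = pc_row + pc_mat - inter
    out = np.ones(len(matrix), dtype=float)  # empty∪empty -> similarity 1
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out
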