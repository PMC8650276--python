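"""Scaffold-network binning split.

Each molecule is decomposed into its scaffold network: the side-chain
pruned (Murcko) core plus every scaffold reachable by iterative removal of
single peripheral rings, where fused, bridged and spiro ring systems are
never dissected.  Generic-atom abstraction and attachment-point retention
are both disabled.  One representative scaffold is then selected:

1. scaffolds with exactly 3 rings (a granularity that works well for
   medicinal-chemistry series);
2. if none, scaffolds with ring count closest to 3, preferring the smaller
   count when 2- and 4-ring scaffolds are equidistant (more generic
   scaffolds merge more of a series into one fold);
3. remaining ties resolved by a deterministic prioritization cascade:
   fewer acyclic (non-ring) bonds, then more ring heteroatoms, then the
   lexicographically smallest canonical SMILES.

The representative scaffold's canonical SMILES is hashed to a fold with the
same keyed SHA-256 scheme as the random split, so the method is fully
deterministic and locally computable at every party.  Acyclic molecules
have the empty scaffold and therefore all share one fold.

Note this binning is a heuristic that is independent of the fingerprint:
pairs with near-identical fingerprints can receive different scaffolds
(e.g. through ring-size or linker-length changes) and thus different folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold, rdScaffoldNetwork

from .chem import MoleculeRecord, StructureError
from .hashing import FoldAssignment, SplitConfig, hash_to_fold

__all__ = [
    "ScaffoldRecord",
    "compute_scaffold_set",
    "select_representative_scaffold",
    "assign_scaffold_folds",
]

_KEY_PREFIX = "SCF:"  # namespaces scaffold keys under a shared secret
_TARGET_RINGS = 3


@dataclass(frozen=True)
class ScaffoldRecord:
    """A scaffold: canonical SMILES (empty for acyclic) and its SSSR ring count."""

    scaffold_smiles: str
    ring_count: int

    def __post_init__(self):
        if (self.ring_count == 0) != (self.scaffold_smiles == ""):
            raise ValueError("ring_count == 0 iff scaffold_smiles is empty")


def _network_params() -> rdScaffoldNetwork.ScaffoldNetworkParams:
    params = rdScaffoldNetwork.ScaffoldNetworkParams()
    params.includeGenericScaffolds = False
    params.includeGenericBondScaffolds = False
    params.includeScaffoldsWithAttachments = False
    params.includeScaffoldsWithoutAttachments = True
    params.pruneBeforeFragmenting = True
    return params


def compute_scaffold_set(canonical: str) -> frozenset:
    """Scaffold network of a molecule as a set of :class:`ScaffoldRecord`.

    The network is built from the Murcko scaffold (so decorations never
    appear as scaffolds).  An acyclic molecule yields the single empty
    scaffold.
    """
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:
        raise StructureError(canonical)
    if rdMolDescriptors.CalcNumRings(mol) == 0:
        return frozenset({ScaffoldRecord("", 0)})

    core = MurckoScaffold.GetScaffoldForMol(mol)
    # stereo is flattened so that a scaffold has one canonical SMILES key
    # regardless of the stereochemistry of the molecules carrying it; the
    # explicit-H bookkeeping left behind by chiral atoms is cleared too,
    # otherwise [C@@H] and plain C cores canonicalize differently
    Chem.RemoveStereochemistry(core)
    for atom in core.GetAtoms():
        if atom.GetAtomicNum() == 6 and not atom.GetIsAromatic():
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
    Chem.SanitizeMol(core)
    network = rdScaffoldNetwork.CreateScaffoldNetwork([core], _network_params())
    records = set()
    for node in network.nodes:
        node_mol = Chem.MolFromSmiles(node)
        if node_mol is None:
            continue
        n_rings = rdMolDescriptors.CalcNumRings(node_mol)
        if n_rings == 0:
            continue  # cyclic molecules never carry the empty scaffold
        records.add(ScaffoldRecord(Chem.MolToSmiles(node_mol), n_rings))
    return frozenset(records)


def _acyclic_bond_count(mol: Chem.Mol) -> int:
    return sum(1 for b in mol.GetBonds() if not b.IsInRing())


def _ring_heteroatom_count(mol: Chem.Mol) -> int:
    return sum(
        1 for a in mol.GetAtoms() if a.IsInRing() and a.GetAtomicNum() not in (1, 6)
    )


def select_representative_scaffold(scaffolds: Iterable[ScaffoldRecord]) -> ScaffoldRecord:
    """Pick the single scaffold used for fold hashing.

    3-ring scaffolds first; otherwise ring count closest to 3 with ties
    toward the smaller count; remaining candidates ranked by the cascade
    (fewer acyclic bonds, more ring heteroatoms, smallest canonical SMILES).
    """
    scaffolds = list(scaffolds)
    if not scaffolds:
        raise ValueError("scaffold set must be non-empty")

    best_key = min((abs(s.ring_count - _TARGET_RINGS), s.ring_count) for s in scaffolds)
    candidates = [
        s
        for s in scaffolds
        if (abs(s.ring_count - _TARGET_RINGS), s.ring_count) == best_key
    ]
    if len(candidates) == 1:
        return candidates[0]

    def cascade(s: ScaffoldRecord):
        mol = Chem.MolFromSmiles(s.scaffold_smiles)
        return (
            _acyclic_bond_count(mol),
            -_ring_heteroatom_count(mol),
            s.scaffold_smiles,
        )

    return min(candidates, key=cascade)


def representative_scaffold(canonical: str) -> ScaffoldRecord:
    """Convenience: scaffold network + selection in one call."""
    return select_representative_scaffold(compute_scaffold_set(canonical))


def assign_scaffold_folds(
    molecules: Iterable[MoleculeRecord], config: SplitConfig
) -> FoldAssignment:
    """Hash each compound's representative scaffold SMILES to a fold.

    Molecules sharing a representative scaffold share a fold; all acyclic
    molecules (empty scaffold) share one fold.  Deterministic and locally
    computable, so overlapping libraries agree without communication.
    """
    mapping = {}
    scaffold_cache: dict = {}
    for mol in molecules:
        smiles = mol.canonical_smiles
        if smiles not in scaffold_cache:
            scaffold_cache[smiles] = representative_scaffold(smiles)
        scaffold = scaffold_cache[smiles]
        key = _KEY_PREFIX + scaffold.scaffold_smiles
        mapping[mol.compound_id] = hash_to_fold(key, config.n_folds, config.secret)
    return FoldAssignment(
        mapping=mapping,
        n_folds=config.n_folds,
        method="scaffold",
        params={"secret_used": config.secret is not None},
    )
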