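"""Sphere exclusion (Taylor-Butina / leader-follower) clustering split.

Compounds are visited in a seeded random order.  Each compound joins the
closest existing cluster center if its Tanimoto *distance* to that center
is at most ``t_tc`` (default 0.6), otherwise it founds a new cluster with
itself as center.  A single nearest-center re-assignment pass (analogous to
one k-means step) follows.  Each cluster then receives a fold drawn from a
seeded RNG, and every member inherits its cluster's fold.

Cluster centers are actual compounds, never averaged, so the construction
guarantees: pairwise center distance > t_tc, and every compound within
t_tc of its assigned center.  Complexity is O(N_clusters * N_compounds);
distances are computed against a packed uint64 bit matrix via popcount.

This method needs the compound set in one place (or a secure multi-party
protocol, which is out of scope here); unlike the hash-based methods it is
documented as requiring federated execution to be privacy preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem import FoldedFingerprint, MoleculeRecord, pack_fingerprints, packed_tanimoto
from .hashing import FoldAssignment, SplitConfig

__all__ = ["ClusterModel", "run_sphere_exclusion", "reassign_to_nearest", "assign_cluster_folds"]

DEFAULT_T_TC = 0.6


@dataclass
class ClusterModel:
    """Sphere-exclusion clustering result at Tanimoto distance cutoff t_tc."""

    centers: list            # FoldedFingerprint, in creation order
    center_compound_ids: list
    assignment: dict         # compound_id -> cluster index
    t_tc: float
    order_seed: int

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, cluster: int) -> list:
        return [c for c, k in self.assignment.items() if k == cluster]


def run_sphere_exclusion(
    molecules: Sequence[MoleculeRecord],
    t_tc: float = DEFAULT_T_TC,
    order_seed: int = 0,
) -> ClusterModel:
    """Leader-follower clustering over a seeded processing shuffle.

    A compound joins the closest existing center when its minimum Tanimoto
    distance is <= t_tc (ties to the lowest-index, i.e. earliest-created,
    center); otherwise it becomes a new center.
    """
    if not 0.0 <= t_tc <= 1.0:
        raise ValueError("t_tc must be in [0, 1]")
    molecules = list(molecules)
    if not molecules:
        return ClusterModel([], [], {}, t_tc, order_seed)

    packed = pack_fingerprints([m.fingerprint for m in molecules])
    order = np.random.default_rng(order_seed).permutation(len(molecules))

    center_rows: list[int] = []
    assignment: dict = {}
    center_matrix = np.zeros((0, packed.shape[1]), dtype=np.uint64)
    for idx in order:
        mol = molecules[idx]
        if len(center_rows):
            dists = 1.0 - packed_tanimoto(packed[idx], center_matrix)
            nearest = int(np.argmin(dists))  # argmin ties -> lowest index
            if dists[nearest] <= t_tc:
                assignment[mol.compound_id] = nearest
                continue
        assignment[mol.compound_id] = len(center_rows)
        center_rows.append(int(idx))
        center_matrix = np.vstack([center_matrix, packed[idx][None, :]])

    return ClusterModel(
        centers=[molecules[i].fingerprint for i in center_rows],
        center_compound_ids=[molecules[i].compound_id for i in center_rows],
        assignment=assignment,
        t_tc=t_tc,
        order_seed=order_seed,
    )


def reassign_to_nearest(
    model: ClusterModel, molecules: Sequence[MoleculeRecord]
) -> ClusterModel:
    """Single pass mapping every compound to its minimum-distance center.

    Centers are unchanged; ties go to the lowest-index center.  Idempotent.
    """
    molecules = list(molecules)
    unknown = [m.compound_id for m in molecules if m.compound_id not in model.assignment]
    if unknown:
        raise ValueError(f"compounds not in model: {unknown[:5]}")
    if not model.centers:
        return model

    packed = pack_fingerprints([m.fingerprint for m in molecules])
    center_matrix = pack_fingerprints(model.centers)
    assignment = dict(model.assignment)
    for i, mol in enumerate(molecules):
        dists = 1.0 - packed_tanimoto(packed[i], center_matrix)
        assignment[mol.compound_id] = int(np.argmin(dists))
    return ClusterModel(
        centers=model.centers,
        center_compound_ids=model.center_compound_ids,
        assignment=assignment,
        t_tc=model.t_tc,
        order_seed=model.order_seed,
    )


def assign_cluster_folds(
    model: ClusterModel, config: SplitConfig, fold_seed: int = 0
) -> FoldAssignment:
    """Draw one fold per cluster (seeded RNG, cluster-creation order).

    Clusters have no canonical cross-party key (centers are private
    compounds), so a seeded RNG stands in for the SHA-256 scheme used by
    the locally-computable methods.
    """
    rng = np.random.default_rng(fold_seed)
    cluster_folds = rng.integers(0, config.n_folds, size=model.n_clusters)
    mapping = {cid: int(cluster_folds[k]) for cid, k in model.assignment.items()}
    return FoldAssignment(
        mapping=mapping,
        n_folds=config.n_folds,
        method="sphere",
        params={
            "t_tc": model.t_tc,
            "order_seed": model.order_seed,
            "fold_seed": fold_seed,
            "n_clusters": model.n_clusters,
        },
    )
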