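"""Federated-consistency audit.

The minimum requirement of any federated split is that identical
standardized structures receive the same fold at every party, without any
data exchange.  Given per-party fold assignments this audit joins them on
compound id (or canonical SMILES when provided) and counts disagreements
on the shared compounds.  For the locally-computable methods (random, LSH
with a shared model, scaffold) the disagreement count must be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .hashing import FoldAssignment

__all__ = ["ConsistencyReport", "audit_consistency"]


@dataclass
class ConsistencyReport:
    n_parties: int
    shared_compounds: int          # keys present in >= 2 assignments
    disagreements: int             # shared keys with more than one fold value
    pairwise: list                 # (i, j, shared, disagreements) per party pair

    @property
    def consistent(self) -> bool:
        return self.disagreements == 0


def audit_consistency(
    assignments: Sequence[FoldAssignment | Mapping[str, int]],
    keys: Sequence[Mapping[str, str]] | None = None,
) -> ConsistencyReport:
    """Count fold disagreements on compounds shared between parties.

    ``keys`` optionally maps each party's compound ids to a join key such
    as the canonical SMILES; without it, compound ids are joined directly.
    An empty intersection yields a report with zero shared compounds.
    """
    if len(assignments) < 2:
        raise ValueError("need at least two fold assignments to audit")
    maps = []
    for i, a in enumerate(assignments):
        mapping = a.mapping if isinstance(a, FoldAssignment) else dict(a)
        if keys is not None:
            mapping = {keys[i][cid]: fold for cid, fold in mapping.items()}
        maps.append(mapping)

    seen: dict = {}
    conflicting: set = set()
    shared: set = set()
    for mapping in maps:
        for key, fold in mapping.items():
            if key in seen:
                shared.add(key)
                if seen[key] != fold:
                    conflicting.add(key)
            else:
                seen[key] = fold

    pairwise = []
    for i, j in combinations(range(len(maps)), 2):
        inter = maps[i].keys() & maps[j].keys()
        bad = sum(1 for k in inter if maps[i][k] != maps[j][k])
        pairwise.append((i, j, len(inter), bad))

    return ConsistencyReport(
        n_parties=len(maps),
        shared_compounds=len(shared),
        disagreements=len(conflicting),
        pairwise=pairwise,
    )
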