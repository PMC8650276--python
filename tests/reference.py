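"""Independent brute-force references used as oracles in tests.

Deliberately written with plain Python sets and loops, sharing no code
with the package implementations they check.
"""

from __future__ import annotations


def set_tanimoto_distance(a: frozenset, b: frozenset) -> float:
    union = a | b
    if not union:
        return 0.0  # both empty -> similarity 1 -> distance 0
    return 1.0 - len(a & b) / len(union)


def brute_force_sphere_exclusion(
    fingerprints: list[frozenset], order: list[int], t_tc: float
) -> tuple[list[int], dict[int, int]]:
    """Leader-follower clustering followed by one nearest-center pass.

    Returns (center indices in creation order, molecule index -> cluster).
    """
    centers: list[int] = []
    assignment: dict[int, int] = {}
    for idx in order:
        fp = fingerprints[idx]
        best_k, best_d = None, None
        for k, c in enumerate(centers):
            d = set_tanimoto_distance(fp, fingerprints[c])
            if best_d is None or d < best_d:  # strict: ties keep lowest k
                best_k, best_d = k, d
        if best_d is not None and best_d <= t_tc:
            assignment[idx] = best_k
        else:
            assignment[idx] = len(centers)
            centers.append(idx)
    # re-assignment pass
    for idx in order:
        fp = fingerprints[idx]
        best_k, best_d = None, None
        for k, c in enumerate(centers):
            d = set_tanimoto_distance(fp, fingerprints[c])
            if best_d is None or d < best_d:
                best_k, best_d = k, d
        assignment[idx] = best_k
    return centers, assignment
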