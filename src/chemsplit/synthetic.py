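"""Synthetic structure libraries and activity tables for offline testing.

Real QSAR libraries are dominated by chemical series: sets of analogues
sharing a scaffold core and differing in small substituents, so that
within-series fingerprint similarity is high while between-series
similarity is low.  The generators here emulate exactly that structure,
with known ground truth:

* :func:`generate_series_library` — decorated core templates (drug-like
  1-4-ring scaffolds, mostly 3-ring) plus diverse singletons plus optional
  salt-form duplicate entries (same parent, new counter-ion and compound
  id), which populate the identical-similarity bin the way duplicate salt
  forms do in corporate registries.
* :func:`generate_similarity_ladder` — a benchmark library whose random
  pair similarities cover *every* similarity bin densely (prefixes of one
  long non-repeating heteropolymer with log-spread lengths), used to
  estimate per-bin baselines with tight Monte-Carlo error.  Chemically
  contrived by design; it emulates a continuum of structural relatedness,
  not a realistic screening collection.
* :func:`generate_activity_table` — sparse binary multi-task labels where
  the actives of each task concentrate in a small number of series.

All generators are deterministic given their seed, and every emitted SMILES
survives standardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import MoleculeRecord, prepare_molecules

__all__ = [
    "SyntheticConfig",
    "LadderConfig",
    "SyntheticActivityConfig",
    "generate_series_library",
    "generate_similarity_ladder",
    "generate_activity_table",
    "CORE_TEMPLATES",
    "SUBSTITUENTS",
]

# Series core templates.  {0}/{1} are substitution sites placed directly
# after an atom so that a parenthesized fragment (or nothing at all)
# appends as valid SMILES.  Cores are 20-35 heavy atoms: large enough that
# swapping single-atom substituents at both sites keeps within-series
# Tanimoto similarity above 0.4 (distance under the 0.6 clustering
# cutoff), while distinct cores stay below ~0.2 between-series similarity.
# Ring counts span 1-5 so the 3-ring scaffold preference and its
# closest-to-3 fallback are both exercised.
CORE_TEMPLATES: tuple[str, ...] = (
    "Cc1ccc(-c2ccc(CN3C(=O)c4ccc{1}cc4C3=O)cc2)nc1CN1CCOCC1{0}",
    "O=C(Nc1cc(CC(F)(F)F)c2ncccc2c1{1})c1ccc(CN2CCOCC2)c(OCC2CCCO2)c1{0}",
    "c1ccc(N2CCN(c3ccnc(-c4ccc{1}nc4)c3{0})CC2)cc1CC(=O)N1CCCC1",
    "O=C(c1cccc(-n2cncn2)c1CN1CCC{0}C1)N1CCC(c2ccc{1}cc2OCC(F)(F)F)CC1",
    "c1cnc2[nH]c(-c3ccc(CN4CCCC4{1})cc3{0})cc2c1-c1ccco1",
    "O=S(=O)(c1ccc(-c2ccc{1}cn2)cc1{0})N1CCOc2ccccc21",
    "c1ccc(Oc2ccnc(N3CCN(c4ncc{1}cn4)CC3)c2{0})cc1S(=O)(=O)N1CCCC1",
    "O=C1N(Cc2ccc(-c3ccc{1}cc3)cc2{0})CCN1c1ccccc1OC",
    "COc1ccc(C(=O)Nc2ccc(S(=O)(=O)N3CCC{1}CC3)cc2{0})cc1CC(C)NC(C)=O",
    "O=C(NCc1ccc{1}cc1CN(C)C)c1cnn(-c2ccc(F)cc2{0})c1",
    "CC(=O)NCCc1ccc(-c2ccc(N3CCOCC3{1})cc2CNC(=O)C(C)C)c(OCC2CC2)c1{0}",
    "O=C(Nc1nc2ccc{1}cc2s1)C1CCN(Cc2ccccc2CC(N)=O)CC1C{0}",
    "c1ccc(CCN2CCC(Nc3ncnc4[nH]cc{1}c34)CC2{0})cc1OCCN1CCCC1",
    "Cc1nnc(SCC(=O)Nc2ccc(-c3ccc{1}cc3C(N)=O)cc2{0})o1",
    "O=C(Nc1cccc(-c2nc3ccc{1}cc3[nH]2)c1CCN2CCOCC2{0})C1CCN(S(C)(=O)=O)CC1",
    "CCOC(=O)c1ccc2c(c1{1})oc1ccc(CN3CCN(CC4CCC(F)(F)C4)CC3{0})cc12",
    "O=C(NC1CCC(CC#N){1}CC1)c1ccc2c(c1{0})OCC(CNC(=O)C1CCOC1)O2",
    "Clc1ccc(-n2cnnc2SCc2ccc(-c3ccc{1}cc3)cc2{0})cc1CCC(=O)N1CCCC1",
    "O=C(Cn1c(=O)oc2ccc{1}cc21)Nc1ccccc1-c1ccccc1OCCN(C)C{0}",
    "CC(C)(O)CCN(CCCNC(=O)C=CC(=O)NCC(C)(C)CO)CC1CCC(SC){1}CC1{0}",
)

# Single-heavy-atom substituents ("" leaves the core H): small enough that
# any pair of decorated analogues of one core stays within the series
# distance envelope.
SUBSTITUENTS: tuple[str, ...] = ("", "C", "F", "Cl", "Br", "O", "N")

# Counter-ions appended as extra fragments to make salt-form duplicates.
_COUNTER_IONS: tuple[str, ...] = (".Cl", ".Br", ".[Na+]", ".OS(=O)(=O)O")

# Singleton building blocks.  Singletons are small ring-linker-ring (or
# ring-linker-fragment) assemblies: the combinatorics yield hundreds of
# *distinct* Murcko scaffolds, so scaffold-based binning keeps the diverse
# background spread over many folds instead of lumping it.  The ring pool
# is disjoint from the series cores (singleton-to-series similarity stays
# well below the clustering cutoff) and contains no ring-size homolog
# pairs, so no two singletons with different scaffolds reach the top
# similarity bins.
_SINGLETON_CORES: tuple[str, ...] = (
    "c1ccoc1{0}",
    "c1ccsc1{0}",
    "c1ccncc1{0}",
    "c1ccnnc1{0}",
    "c1cnccn1{0}",
    "C1CCOCC1{0}",
    "C1CCNCC1{0}",
    "C1CCSCC1{0}",
    "c1cc[nH]c1{0}",
    "c1ocnc1{0}",
    "c1scnc1{0}",
    "C1CCCCC1{0}",
    "c1cnoc1{0}",
    "c1cnsc1{0}",
    "C1COCCN1{0}",
    "c1cncnc1{0}",
    "CCOCC{0}",
    "NCCNCC{0}",
)

_SINGLETON_LINKERS: tuple[str, ...] = ("C", "CC", "CCC", "CO", "CN", "CC(=O)N")

# terminal rings use ring-closure digit 9 to avoid clashing with the core
_SINGLETON_TERMINAL_RINGS: tuple[str, ...] = (
    "c9ccoc9",
    "c9ccsc9",
    "c9ccncc9",
    "c9ccnnc9",
    "c9cnccn9",
    "C9CCOCC9",
    "C9CCNCC9",
    "C9CCSCC9",
    "c9cc[nH]c9",
    "c9ocnc9",
    "c9scnc9",
    "C9CCCCC9",
    "c9cnoc9",
    "c9cnsc9",
    "C9COCCN9",
    "c9cncnc9",
)

_SINGLETON_TERMINAL_FRAGS: tuple[str, ...] = (
    "C",
    "CC",
    "CCO",
    "CCN",
    "C(C)C",
    "CBr",
    "CI",
    "C=C",
    "CC#N",
    "COC",
    "CSC",
    "CCCl",
    "CN(C)C",
    "CC(C)O",
    "CC(N)=O",
    "CCS",
)


@dataclass
class SyntheticConfig:
    """Series-library layout: 20 series of ~25 members plus 100 singletons."""

    n_series: int = 20
    series_size_range: tuple[int, int] = (25, 25)
    n_singletons: int = 100
    salt_duplicates_per_series: int = 3
    core_templates: Sequence[str] = CORE_TEMPLATES
    substituent_alphabet: Sequence[str] = SUBSTITUENTS
    seed: int = 0


@dataclass
class LadderConfig:
    """Similarity-ladder layout; defaults cover all ten bins densely."""

    n_molecules: int = 10000
    seed: int = 0
    k_min: int = 3
    k_max: int = 250
    band_fraction: float = 0.45
    band_ratio: tuple[float, float] = (0.80, 0.93)


@dataclass
class SyntheticActivityConfig:
    """Sparse multi-task binary labels with series-concentrated actives."""

    n_tasks: int = 50
    task_size_range: tuple[int, int] = (20, 400)
    task_size_choices: Sequence[int] | None = None
    task_size_probs: Sequence[float] | None = None
    n_active_series: int = 2
    active_fraction: float = 0.3
    seed: int = 0


def _wrap(sub: str) -> str:
    """Parenthesize a non-empty substituent so it appends as a branch."""
    return f"({sub})" if sub else ""


def generate_series_library(
    config: SyntheticConfig | None = None,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Build the series library; returns (records, ground-truth table).

    The ground-truth table has columns compound_id, series_id (singletons
    get a unique ``singleton_*`` series), is_duplicate.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    templates = list(config.core_templates)
    subs = list(config.substituent_alphabet)
    if config.n_series > 0 and not templates:
        raise ValueError("need at least one core template")
    for t in templates:
        if "{0}" not in t and max(config.series_size_range) > 1:
            raise ValueError(f"template without substitution point: {t}")

    entries: list[tuple[str, str]] = []
    truth_rows = []
    seen: set[str] = set()

    from .chem import standardize_smiles

    for s in range(config.n_series):
        template = templates[s % len(templates)]
        lo, hi = config.series_size_range
        size = int(rng.integers(lo, hi + 1))
        members: list[str] = []
        attempts = 0
        while len(members) < size and attempts < 60 * size:
            attempts += 1
            a = subs[rng.integers(0, len(subs))]
            b = subs[rng.integers(0, len(subs))]
            if "{1}" in template:
                smi = template.format(_wrap(a), _wrap(b))
            else:
                smi = template.format(_wrap(a))
            try:
                canonical = standardize_smiles(smi)
            except Exception:
                continue
            if canonical in seen:
                continue
            seen.add(canonical)
            members.append(smi)
        if len(members) < size:
            raise ValueError(
                f"could not build {size} distinct members for series {s}"
            )
        series_id = f"series_{s:03d}"
        for m, smi in enumerate(members):
            cid = f"{series_id}_m{m:03d}"
            entries.append((cid, smi))
            truth_rows.append(
                {"compound_id": cid, "series_id": series_id, "is_duplicate": False}
            )
        # salt-form duplicates: same parent under a new id and counter-ion
        for d in range(config.salt_duplicates_per_series):
            parent = members[int(rng.integers(0, len(members)))]
            ion = _COUNTER_IONS[int(rng.integers(0, len(_COUNTER_IONS)))]
            cid = f"{series_id}_dup{d:02d}"
            entries.append((cid, parent + ion))
            truth_rows.append(
                {"compound_id": cid, "series_id": series_id, "is_duplicate": True}
            )

    n_built = 0
    attempts = 0
    while n_built < config.n_singletons and attempts < 200 * max(config.n_singletons, 1):
        attempts += 1
        core = _SINGLETON_CORES[rng.integers(0, len(_SINGLETON_CORES))]
        linker = _SINGLETON_LINKERS[rng.integers(0, len(_SINGLETON_LINKERS))]
        if rng.random() < 0.7:
            terminal = _SINGLETON_TERMINAL_RINGS[
                rng.integers(0, len(_SINGLETON_TERMINAL_RINGS))
            ]
        else:
            terminal = _SINGLETON_TERMINAL_FRAGS[
                rng.integers(0, len(_SINGLETON_TERMINAL_FRAGS))
            ]
        smi = core.format(linker + terminal)  # bare append chain-extends the site atom
        try:
            canonical = standardize_smiles(smi)
        except Exception:
            continue
        if canonical in seen:
            continue
        seen.add(canonical)
        cid = f"singleton_{n_built:04d}"
        entries.append((cid, smi))
        truth_rows.append(
            {"compound_id": cid, "series_id": f"singleton_{n_built:04d}", "is_duplicate": False}
        )
        n_built += 1
    if n_built < config.n_singletons:
        raise ValueError("could not build the requested number of distinct singletons")

    records, errors = prepare_molecules(entries)
    if errors:  # generator invariant: everything it emits must standardize
        raise AssertionError(f"synthetic molecules failed standardization: {errors[:5]}")
    return records, pd.DataFrame(truth_rows)


# --- similarity ladder ------------------------------------------------------

_LADDER_UNITS = (
    "C", "CC", "CO", "CN", "C(C)", "C(O)", "C(N)",
    "C(F)", "C(Cl)", "C(Br)", "C(S)", "C(=O)",
)
_TAIL_FRAGS = (
    "F", "Cl", "Br", "I", "O", "N", "S", "C", "CC", "OC",
    "C#N", "C(F)(F)F", "C(C)C", "N(C)C", "OCC", "SC", "C=C", "CO", "CN", "C(N)=O",
)


def _tail_for_index(i: int) -> str:
    """Unlimited family of distinct terminal decorations, one per index."""
    n = len(_TAIL_FRAGS)
    a, b = divmod(i, n)
    tail = f"C({_TAIL_FRAGS[b]})"
    while a > 0:
        a, b = divmod(a - 1, n)
        tail += f"C({_TAIL_FRAGS[b]})"
    return tail


def generate_similarity_ladder(
    config: LadderConfig | None = None,
) -> list[MoleculeRecord]:
    """Library whose pair-similarity histogram covers every bin densely.

    Molecules are prefixes of one fixed random heteropolymer sequence with
    log-uniformly spread lengths (a fraction drawn as near-equal-length
    pairs) and per-molecule unique terminal decorations.  The Tanimoto
    similarity of a pair tracks the ratio of the shared prefix to the
    longer molecule, so log-spread lengths translate into broad similarity
    coverage.
    """
    config = config or LadderConfig()
    rng = np.random.default_rng(config.seed)
    seq_len = config.k_max + 10
    seq = [_LADDER_UNITS[rng.integers(0, len(_LADDER_UNITS))] for _ in range(seq_len)]

    log_lo, log_hi = math.log(config.k_min), math.log(config.k_max)

    def log_uniform(lo: float, hi: float) -> int:
        return int(round(math.exp(rng.uniform(lo, hi))))

    lengths: list[int] = []
    while len(lengths) < config.n_molecules:
        if rng.random() < config.band_fraction:
            base = log_uniform(math.log(max(40, config.k_min)), log_hi)
            ratio = rng.uniform(*config.band_ratio)
            lengths.append(base)
            lengths.append(max(config.k_min, int(round(base * ratio))))
        else:
            lengths.append(log_uniform(log_lo, log_hi))
    lengths = lengths[: config.n_molecules]

    from rdkit import Chem

    # tail indices count up per length; on the rare canonicalization
    # collision (a tail fragment can coincide with a chain unit) we advance
    # to the next tail index, keeping the library duplicate-free
    per_length_counter: dict[int, int] = {}
    seen: set[str] = set()
    entries = []
    for i, k in enumerate(lengths):
        prefix = "".join(seq[:k])
        j = per_length_counter.get(k, 0)
        while True:
            smi = prefix + _tail_for_index(j)
            j += 1
            canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
            if canonical not in seen:
                break
        seen.add(canonical)
        per_length_counter[k] = j
        entries.append((f"ladder_{i:05d}", smi))

    records, errors = prepare_molecules(entries)
    if errors:
        raise AssertionError(f"ladder molecules failed standardization: {errors[:5]}")
    canon = {r.canonical_smiles for r in records}
    if len(canon) != len(records):
        raise AssertionError("ladder library contains duplicate structures")
    return records


def generate_activity_table(
    series: pd.DataFrame,
    config: SyntheticActivityConfig | None = None,
) -> pd.DataFrame:
    """Sparse binary labels; actives concentrate in a few series per task.

    Returns a long-format frame (compound_id, task_id, label) with at most
    one label per pair.  Per task, a target fraction of the measured
    compounds comes from ``n_active_series`` randomly chosen real series
    (label 1); the remainder is drawn from the rest of the library
    (label 0).
    """
    config = config or SyntheticActivityConfig()
    rng = np.random.default_rng(config.seed)
    all_ids = series["compound_id"].to_numpy()
    real_series = sorted(
        series.loc[~series["series_id"].str.startswith("singleton"), "series_id"].unique()
    )
    if not real_series and config.n_active_series > 0:
        raise ValueError("library has no series to concentrate actives in")
    by_series = {
        s: series.loc[series["series_id"] == s, "compound_id"].to_numpy()
        for s in real_series
    }

    rows = []
    for t in range(config.n_tasks):
        task_id = f"task_{t:03d}"
        if config.task_size_choices is not None:
            size = int(
                rng.choice(np.asarray(config.task_size_choices), p=config.task_size_probs)
            )
        else:
            lo, hi = config.task_size_range
            size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        if size > len(all_ids):
            raise ValueError(
                f"task size {size} exceeds library size {len(all_ids)}"
            )

        chosen = rng.choice(
            len(real_series), size=min(config.n_active_series, len(real_series)), replace=False
        )
        active_pool = np.concatenate([by_series[real_series[i]] for i in chosen])
        n_active = min(int(round(config.active_fraction * size)), len(active_pool))
        actives = rng.choice(active_pool, size=n_active, replace=False)

        inactive_pool = np.setdiff1d(all_ids, active_pool, assume_unique=False)
        n_inactive = min(size - n_active, len(inactive_pool))
        inactives = rng.choice(inactive_pool, size=n_inactive, replace=False)

        for cid in actives:
            rows.append({"compound_id": cid, "task_id": task_id, "label": 1})
        for cid in inactives:
            rows.append({"compound_id": cid, "task_id": task_id, "label": 0})
    return pd.DataFrame(rows)
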