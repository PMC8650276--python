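"""Scaffold-network binning split.

Decomposes a molecule into its scaffold network (iterative single-ring
removal, fused systems kept intact), picks the representative scaffold
closest to 3 rings, and hashes its SMILES to a fold — fully deterministic
and locally computable at every party.
"""

import chemsplit as cs

flucloxacillin = (
    "Cc1onc(-c2c(F)cccc2Cl)c1C(=O)N[C@@H]1C(=O)N2[C@@H]1SC(C)(C)[C@@H]2C(=O)O"
)
canonical = cs.standardize_smiles(flucloxacillin)
network = cs.compute_scaffold_set(canonical)
print("scaffold network of flucloxacillin:")
for rec in sorted(network, key=lambda r: (r.ring_count, r.scaffold_smiles)):
    print(f"  {rec.ring_count} rings  {rec.scaffold_smiles}")
rep = cs.select_representative_scaffold(network)
print(f"representative (3-ring preference): {rep.scaffold_smiles}")

entries = [
    ("flucloxacillin", flucloxacillin),
    ("analog_methyl", "Cc1onc(-c2c(C)cccc2Cl)c1C(=O)NC1C(=O)N2C1SC(C)(C)C2C(=O)O"),
    ("hexane", "CCCCCC"),
    ("octanol", "CCCCCCCCO"),
]
records, _ = cs.prepare_molecules(entries)
assignment = cs.assign_scaffold_folds(records, cs.SplitConfig(n_folds=5))
for record in records:
    print(f"{record.compound_id:16s} fold {assignment[record.compound_id]}")
print("analogues sharing the representative scaffold share a fold; all "
      "acyclic molecules (empty scaffold) share one fold")
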