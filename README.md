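# chemsplit

Train/test fold splitting for chemical structure data sets, in the *whole
compound domain*: every compound, with all of its measurements across all
assays, is assigned to exactly one cross-validation fold.

## Why

QSAR libraries are dominated by chemical series — sets of close analogues
sharing a scaffold.  A plain random split scatters each series over all
folds, so the test set is full of near-copies of training compounds and the
measured performance is far more optimistic than what the model achieves on
genuinely new chemistry (the series effect, a.k.a. the Kubinyi paradox).
In sparse multi-task settings the only clean fix is to split in compound
space, keeping close analogues together.

A second constraint comes from federated, privacy-preserving model
training: several parties must assign folds *consistently* — an identical
standardized structure has to receive the same fold everywhere — without
ever exchanging structures.

`chemsplit` implements four splitting methods under these constraints,
the evaluation metrics to judge them, and synthetic libraries with known
series structure to test everything offline:

| method     | groups kept together        | federated use                     |
|------------|-----------------------------|-----------------------------------|
| `random`   | exact duplicates only       | local, deterministic              |
| `lsh`      | compounds agreeing on N high-entropy fingerprint bits | local, needs a shared public reference set |
| `sphere`   | Tanimoto clusters (cutoff 0.6) | needs centralized (or secure multi-party) execution |
| `scaffold` | compounds sharing a 3-ring representative scaffold | local, deterministic |

## The core machinery

* Structures are standardized (largest organic fragment, neutralized,
  isotopes stripped, canonical SMILES) and fingerprinted with a **32,768-bit
  folded ECFP6** (Morgan radius 3); a fingerprint is its set of on-bits *A*,
  compared by Tanimoto similarity `T(A,B) = |A∩B| / |A∪B|`.
* A text key (canonical SMILES, LSH bin, scaffold SMILES) maps to one of
  `N_folds` folds via

  ```
  fold = int.from_bytes(SHA256(secret ‖ 0x00 ‖ key)[:8], "big") mod N_folds
  ```

  which is pseudo-random, bit-exactly reproducible on every machine, and —
  with a shared secret — computable only by the consortium.
* **LSH**: the 16 fingerprint bits whose frequency in a reference set is
  closest to 0.5 (the maximum-entropy bits) define at most 2¹⁶ bins; a bin's
  key is hashed to a fold.
* **Sphere exclusion** (Taylor–Butina): compounds are visited in a seeded
  random order; each joins the nearest existing cluster center within
  Tanimoto distance `t_Tc = 0.6` or founds a new cluster, followed by one
  nearest-center re-assignment pass; each cluster draws a fold from a
  seeded RNG.
* **Scaffold network**: iterative single-ring removal from the Murcko
  scaffold (fused/bridged/spiro systems never dissected); the representative
  scaffold is the one with ring count closest to 3 (deterministic
  tie-breaking); its SMILES is hashed to a fold.  All acyclic molecules
  share one fold.

Split quality is evaluated the way practitioners in this area report it:
sampled compound pairs are binned by Tanimoto similarity into ten bins and
the fraction of *intra-fold* pairs is computed per bin (baseline `1/N_folds`
for a random split, approaching 1.0 near identity for series-aware splits),
alongside per-task data imbalance (any fold with < 5 of a task's compounds)
and label imbalance (fold std of the active fraction > 0.05).

## Worked example

`examples/evaluate_split.py` builds a synthetic library of 10 series on a
diverse background, splits it with the random hash and with sphere
exclusion, and prints the intra-fold pair fraction per similarity bin:

```
similarity bin   n_pairs   random   sphere
  [0.0,0.1)       73443   0.199    0.180
  [0.1,0.2)       21706   0.198    0.221
  [0.2,0.3)         960   0.212    0.204
  [0.3,0.4)         343   0.222    0.227
  [0.4,0.5)         402   0.224    0.878
  [0.5,0.6)        1320   0.166    0.994
  [0.6,0.7)        1116   0.203    1.000
  [0.7,0.8)         494   0.190    1.000
  [0.8,0.9)         196   0.337    1.000
  [0.9,1.0)          20   1.000    1.000
```

The random split stays at the 0.2 baseline in every bin (the top bin holds
identical structures, which hash together by construction), while sphere
exclusion keeps pairs of analogues above ~0.4 similarity in one fold —
those pairs can no longer leak between training and test.  The other
scripts in `examples/` demonstrate one capability each: `random_split.py`
(salt forms hashing together), `lsh_split.py` (bit selection and binning),
`sphere_split.py` (series capture), `scaffold_split.py` (scaffold network of
flucloxacillin), `federated_parties.py` (three parties, zero fold
disagreements), `evaluate_split.py` (the table above plus imbalance flags).

## Command line

```bash
chemsplit synth --out-dir data/                      # synthetic library + activity
chemsplit split --method scaffold --input data/mols.csv --output folds.csv
chemsplit split --method sphere --t-tc 0.6 --order-seed 42 --fold-seed 7 \
                --input data/mols.csv --output folds.csv
chemsplit eval  --folds folds.csv --mols data/mols.csv --activity data/y.csv \
                --pairs 100000 --seed 1 --out report/
chemsplit audit party1_folds.csv party2_folds.csv    # 0 disagreements expected
```

Every split writes a manifest JSON (method, parameters, seeds) next to its
output; re-running from the same inputs reproduces the output byte for byte.

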