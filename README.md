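# foodvs

Ligand-based virtual screening for food-compound libraries, built around the
question: *which constituents of food can bind and activate the dopamine D2
receptor?*  Classical virtual-screening stacks are tuned to drug-like
vendor libraries; food-compound collections are broader in molecular weight,
far more glycosylated and structurally more diverse, so a screening pipeline
for them has to combine pharmacophore searching (which can scaffold-hop)
with clustering and docking-pose filters rather than rely on 2D similarity
alone.  `foodvs` implements that pipeline end to end as a tested Python
library plus a `vs` command-line tool, exercisable entirely on synthetic
and in-repo inputs.

## What it does

- **`foodvs.compound_db`** — library preparation: read SMILES/SDF, drop
  entries > 750 Da or with more than two sugar moieties (poor gut
  absorption), enumerate tautomers and pH-7.4 protonation states as separate
  database entries sharing one parent identity.
- **`foodvs.confgen`** — bounded conformer ensembles (distance-geometry
  embedding, optional force-field minimisation, RMSD pruning, energy
  window, up to 255 conformers).
- **`foodvs.rigid_align`** — rigid-body alignment by Gaussian feature/volume
  overlap; selects each ligand's maximum-similarity conformer against a
  bioactive template; Kabsch superposition as the geometric primitive.
- **`foodvs.pharmacophore`** — feature perception (HBD, HBA, AR, PI, HY),
  common-feature model induction from aligned training ligands (no excluded
  volumes), fit-value scoring

      fit = Σ_f max(0, 1 − (d_f / t_f)²)  ∈ [0, n_features],

  3D database search with fit cut-offs, hit-list merging, and
  actives/decoys ROC validation.
- **`foodvs.hit_prioritization`** — circular (ECFP4-like) and 166-key
  structural fingerprints, Tanimoto similarity, complete-linkage clustering
  of hit lists into K groups with tautomer pooling, representative picking
  under fit cut-offs and a heavy-atom cap, and the 2D max-Tc baseline
  screen.
- **`foodvs.pose_interactions`** — docking-pose consumption (Vina PDBQT /
  SDF) and geometric acceptance rules: the mandatory salt bridge between a
  positively charged ligand moiety and the Asp114(3.32) carboxylate, plus
  hydrogen bonds to the pocket serines (193/5.42, 197/5.46).
- **`foodvs.binding_analysis`** — four-parameter logistic dose-response
  fits, the Cheng–Prusoff transform K_i = IC₅₀/(1 + [L]/K_D), BRET/cps
  normalisations, K_i ≤ 50 µM hit classification and pathway-bias efficacy
  labels.
- **`foodvs.fixtures`** — deterministic generators for every synthetic
  input: triad-bearing actives, property-matched decoys at validation scale,
  the 17-compound tested panel (plus dopamine and quinpirole) as curated
  SMILES, the printed K_i panel, a toy binding pocket and dose-response
  curves.

## Worked example

Classify the packaged binding panel at the 50 µM activity criterion:

```bash
vs fixtures --what ki-table --out tmp/
vs hit-rate --in tmp/ki_table.csv
```

prints

```
agonist_screen: 5/9 hits (56%)
antagonist_screen: 2/8 hits (25%)
overall: 7/17 (41%)
```

i.e. five of the nine agonist-screen compounds and two of the eight
antagonist-screen compounds bind with K_i ≤ 50 µM; censored entries
(">100,000 nM") never count as hits.

The same panel drives the 2D baseline comparison. In Python:

```python
>>> from foodvs.fixtures import make_named_compound_set
>>> from foodvs.hit_prioritization import similarity_screen
>>> panel = make_named_compound_set()
>>> refs = [m for m in panel if m.name == "dopamine"]
>>> ranking, _ = similarity_screen([m for m in panel if m.name != "dopamine"], refs)
>>> ranking.head(3)[["name", "max_tc"]]
          name    max_tc
0  kukoamine A  0.410256
1    hordenine  0.272727
2     muscimol  0.235294
```

Most of the experimentally confirmed binders (e.g. fumigaclavine A,
Tc ≈ 0.06) sit far down this 2D ranking — the motivation for running a 3D
pharmacophore screen instead.

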