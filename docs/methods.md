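# Methods

This note documents the models and procedures implemented in `foodvs`, the
parameters that matter, what the synthetic generators do and do not emulate,
and the design decisions taken where the underlying workflow left choices
open.

## Library preparation

A food-compound screening library is read from SMILES or SDF and filtered
by two absorption-motivated rules: molecular weight ≤ 750 Da (computed on
the neutral parent, not on charged state variants) and at most two sugar
moieties.  "Sugar moiety" has no universal definition; here it is a
saturated pyranose or furanose ring (SMARTS-configurable skeletons) whose
ring carbons carry at least two exocyclic oxygens, counted over
non-overlapping ring matches.  Glucose counts 1, sucrose 2, and plain
tetrahydropyran/furan rings 0.  This is deterministic and matches the
glycoside intent of the rule.

Because a 3D search scores individual structures, tautomers and
protonation states are enumerated as separate database entries tied to one
parent.  Tautomers come from RDKit's canonical tautomer enumerator (capped
at 8 per molecule).  Protonation uses a fixed rule table at pH 7.4 rather
than a pKa predictor: aliphatic amines, amidines and guanidines (pKa ≫ 7.4)
are protonated, carboxylic acids (pKa ≪ 7.4) deprotonated; anilines and
amides are untouched.  Sites are switched one at a time and, for
polyamines, jointly.  Variants are deduplicated by canonical SMILES.  The
rule table is a reproducible stand-in for the (unspecified) commercial
preparation step and is deliberately conservative; genuinely borderline
sites (e.g. imidazoles at pKa ≈ 7) are not enumerated.

## Conformer ensembles

Ensembles are generated by ETKDG distance-geometry embedding with a fixed
seed, optionally MMFF-minimised (UFF fallback), pruned at 0.5 Å heavy-atom
best-fit RMSD, restricted to a 20 kcal/mol window above the ensemble
minimum and sorted by ascending strain energy, up to 255 conformers.  The
minimisation toggle mirrors the two preparation runs (with and without
force-field refinement) used for training ligands.  The window value is our
choice; it encodes the standard assumption that bioactive conformers lie
near the global minimum.  The RMSD prune uses atom-order (non-symmetry-
aware) superposition, so topologically symmetric duplicates can in
principle survive; at these ensemble sizes this is harmless and fast.

## Rigid alignment

The alignment similarity between probe and template is

    S(R, t) = Σ_(matched feature pairs) exp(−d² / 2σ_f²)
            + w_vol · Σ_(heavy-atom pairs) exp(−d² / 2σ_v²)

with σ_f = σ_v = 1.0 Å and w_vol = 0.2, maximised over rigid transforms.
Feature pairs match only within a pharmacophoric type.  The volume term
keeps the objective informative for feature-poor molecules; its weight is
small enough that feature overlap dominates whenever features exist.

The optimiser is deterministic and has three stages: (1) candidate
rotations from Kabsch superposition of every kind-compatible triple of
feature points (exact for congruent feature sets); (2) a quasi-uniform
super-Fibonacci rotation grid (60 orientations plus the identity) about the
heavy-atom centroids; (3) Nelder-Mead refinement of the best five
candidates over rotation vector and translation, followed by a polish step
that matches mutually nearest heavy atoms and re-solves Kabsch — this
recovers applied rigid transforms to machine precision on congruent point
sets.  No randomness is involved anywhere.

`select_bioactive_conformer` aligns every ensemble member to the template
and returns the one with maximum similarity (ties: lower strain energy,
then lower index), transformed into the template frame.  This is the
open-algorithm replacement for the proprietary rigid-alignment step used to
pick the "bioactive approximation" conformer per training ligand.

## Pharmacophore features, models, fit

Feature perception is SMARTS-driven: HBD (neutral N/O with hydrogen), HBA
(N/O lone-pair acceptors; aryl-conjugated oxygens — phenols, aryl ethers —
are excluded as poor acceptors), PI (any positively charged nitrogen:
ammonium, amidinium, guanidinium; plus aromatic oxocarbenium for flavylium
cations such as anthocyanidins), AR (aromatic-ring centroid with ring
normal as direction) and HY (centroid of each connected cluster of ≥ 2
aliphatic carbons touching no heteroatom; isolated methyls and methane do
not count).  Directions are perceived for AR but not scored by default —
models use plain tolerance spheres of radius 1.6 Å.

Common-feature model induction takes pre-aligned training ligands, uses the
most feature-rich ligand as reference, and enumerates every k-feature
subset of its features (k = 3 by default).  A configuration survives when
every other ligand (up to a misses-allowed budget, default 0) can map each
feature within tolerance by an injective kind-compatible assignment in the
common frame.  Surviving configurations rank by (ligands mapped, mean fit)
and return at most 25 models whose centres average the mapped ligand
features.  Excluded volumes are never added: permissive models are the
point when the screening library is chemically far from the training set.

The fit value of a compound against a model is

    fit = Σ_f max(0, 1 − (d_f / t_f)²)

maximised over all conformers and all injective kind-compatible mappings;
each mapping is Kabsch-superposed onto the model centres and is admissible
only if every displacement d_f stays within its tolerance sphere.  The fit
lies in [0, n_features] and attains n_features exactly when all
displacements vanish.  Because the superposition is least-squares, a ligand
built with one feature off by t/2 scores slightly *above* the pinned-frame
value 3 − 0.25 = 2.75 (the optimiser spreads the error); the closed-form
scorer `fit_from_displacements` is exposed separately for pinned-frame
displacement vectors.  Mapping enumeration is exhaustive (bounded by a
20 000-mapping cap), which is exact at the 3-feature scale used here.

Database search keeps state variants with fit ≥ cut-off, ordered by
descending fit.  Hit lists merge by canonical structure with per-model fits
kept side by side, mirroring a two-model antagonist screen.  Validation
scores actives and decoys (unmapped compounds score 0), builds a ROC with
ties grouped, reports the trapezoidal AUC and the minimum fit among mapped
actives — the quantity from which prioritisation cut-offs (2.2 for the
agonist model; 1.9/2.3 for two antagonist models) are derived.

## Hit prioritisation

Clustering uses 166-key MACCS-style structural keys (a public stand-in for
MDL public keys — an approximation, documented as such) with complete-
linkage agglomerative clustering on 1 − Tanimoto, cut to exactly K
clusters.  Variants pool onto their parent before clustering, so tautomers
and protomers always co-cluster.  Representative picking keeps, per
cluster, entries whose fit passes the cut-off for at least one model and
whose heavy-atom count is ≤ 40 (the explicit, logged replacement for the
manual rejection of large, bulky compounds that score deceptively well),
then selects the best-fit entry; everything is emitted in a flagged table
for human review.  The 2D baseline ranks a library by max Tanimoto over a
reference set using radius-2/2048-bit hashed circular fingerprints.
Circular-fingerprint Tanimoto values are implementation-dependent;
cross-implementation equality with other ECFP4 variants is not promised,
and regression tests pin this package's own values.

## Pose filters

Poses are consumed from multi-MODEL Vina PDBQT (small dedicated parser;
scores from `REMARK VINA RESULT`) or SDF.  The mandatory acceptance rule is
a salt bridge: a cationic ligand heavy atom within 4.0 Å of the target
carboxylate oxygens (Asp114; Ballesteros–Weinstein 3.32, aliases carried in
config).  Cations come from formal charges when available; for PDBQT input
without formal charges a heuristic (nitrogen with ≥ 2 explicit polar
hydrogens, or partial charge ≥ +0.3) stands in.  Hydrogen bonds to chosen
residues use a 3.5 Å heavy-atom distance and, when the ligand has explicit
hydrogens, a 120° D–H···A angle floor; all cut-offs are literature-
conventional defaults, configurable.  The toy pocket fixture places one
aspartate carboxylate and two serine hydroxyls so that a mono-hydroxyl
ligand can reach only one serine — the geometric signature that separates a
single-H-bond binder from a catechol forming two.

## Pharmacology reduction

Dose-response curves are fitted with a four-parameter logistic on log₁₀
concentration (basal, plateau, midpoint, Hill slope; slope free by default,
fixable to ±1) by least squares with a deterministic 7-point multi-start on
the midpoint across the tested range.  Flat curves (span < 5 %) are fitted
but flagged rather than rejected.  Competition IC₅₀ values convert to K_i
by Cheng–Prusoff with the radioligand concentration and K_D supplied
explicitly (defaults 0.15 nM and 0.052 nM in the CLI).  Hit classification
applies K_i ≤ 50 µM; censored entries (">100,000") are lower bounds and
never hits.  Efficacy labels compare pathway maxima: ≥ 50 % in one pathway
with < 7 % in the other is a biased (functionally selective) agonist;
above-floor but sub-50 % activity is partial agonism; below-floor in both
activation assays is scored inactive-in-activation (an antagonist when
binding is established).

## Synthetic generators and their limits

The generators emulate the *conditions* of the original screen, not its
proprietary content.  Actives are rigid random placements of one canonical
conformer of a protonated phenolic phenethylamine (N-protonated hordenine),
whose perceived features realise the HBD–AR–PI triad; Gaussian atomic noise
(SD configurable) degrades the fit smoothly.  Decoys either lack the PI
feature (4-ethylphenol copies) or carry the scaffold with the cationic
nitrogen displaced 6 Å (> 2× tolerance).  Default sizes mirror the
validation scale: 136 actives and 39 decoys per active.  Dose-response
fixtures sample 8 concentrations over ±3.5 decades around a true EC₅₀ of
1 µM, E_max 80 %, Hill 1, in triplicate with 5 % additive noise.

What passing these tests shows: the induction, mapping, scoring, ROC,
alignment and curve-fitting machinery is correct on inputs whose ground
truth is known by construction.  What it does not show: performance on real
conformational diversity (actives here share one geometry by design, so at
zero noise separation is perfect), on real decoy property matching, or on
wet-lab variability beyond additive Gaussian noise.  The tested-compound
panel and its K_i values are transcribed printed numbers used for
classification logic, not re-measured quantities; compound structures are
constitution-level (stereochemistry not asserted).

## Numerical choices

Kabsch uses SVD with a determinant correction to enforce proper rotations;
strict mode rejects < 3 points and collinear sets, while fit scoring uses
the tolerant mode (rank-deficient mappings take one optimal rotation among
the many).  Ties everywhere break deterministically: by energy then index
in conformer selection, by input order in hit ordering, clustering and
representative picking.  ROC ties are grouped (diagonal segments), making
the all-equal-scores AUC exactly 0.5.  The 4PL multi-start bounds the
midpoint within ±4 decades of the tested range and the Hill slope within
[0.05, 10] in magnitude.  All stochastic generators take explicit seeds and
use NumPy's Generator API; nothing reads global random state.

## Problem sizes

Default test and acceptance runs use the full validation scale (136
actives, 5 304 decoys — single-conformer sets), 100 noisy dose-response
curves, and small ensembles elsewhere; the whole suite completes in well
under a minute on one CPU.  These sizes are the package's chosen study
conditions, large enough that rank statistics (AUC ≈ 0.5 ± 0.025 after
label shuffling) are tight.

## Known limitations

Protonation rules are fixed-pH and rule-based; no pKa regression.  Feature
SMARTS are compact and deliberately conservative rather than exhaustive
(e.g. thiols/halogens are not donors/acceptors).  The mapping search caps
at 20 000 enumerations per conformer — irrelevant for ≤ 3-feature models
but a truncation risk for large models on feature-dense ligands.  The
clustering tie-break depends on input order when distances tie exactly.
Docking itself, homology modelling and molecular-dynamics refinement are
out of scope: poses and receptors are inputs.
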