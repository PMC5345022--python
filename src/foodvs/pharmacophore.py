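"""Pharmacophore feature perception, common-feature model induction,
fit-value scoring, 3D database search and actives/decoys ROC validation.

A pharmacophore model is a small set of typed feature points (hydrogen-bond
donor/acceptor, aromatic ring, positive ionisable, hydrophobic) with
tolerance spheres.  Models are induced from a set of pre-aligned training
ligands by enumerating feature configurations of a reference ligand and
keeping those that every training ligand can map within tolerance — the
common-feature (shared-feature) approach.  No excluded volumes are used, so
hit lists stay permissive for structurally unusual libraries.

The fit value of a compound against a model with features f and tolerances
t_f is

    fit = sum_f max(0, 1 - (d_f / t_f)^2),

where d_f is the displacement of the mapped ligand feature from the model
feature centre after least-squares superposition of the mapped features;
it ranges from 0 to n_features and reaches the maximum only when every
displacement is zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._geometry import kabsch
from .confgen import Conformer, ConformerSet

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_SMARTS", "PharmacophoreFeature", "PharmacophoreModel",
    "FeatureMapping", "FitResult", "HitEntry", "HitList", "ROCResult",
    "perceive_features", "generate_common_feature_models", "fit_value",
    "fit_from_displacements", "search_database", "merge_hitlists",
    "validate_model", "model_to_json", "model_from_json",
]

DEFAULT_TOLERANCE = 1.6  # Å, feature tolerance sphere radius

# Feature perception patterns.  PI covers protonated amines/iminium,
# amidinium/guanidinium nitrogens and the aromatic oxocarbenium of
# flavylium cations (anthocyanidins).  Aromatic rings and hydrophobic
# clusters are perceived from ring/connectivity analysis, not SMARTS.
FEATURE_SMARTS: dict[str, tuple[str, ...]] = {
    "HBD": ("[#7,#8;+0;!H0]",),
    "HBA": (
        # aryl-conjugated O (phenols, aryl ethers) is a poor acceptor and excluded
        "[OX2;+0;!$(O=*);!$(O-a)]", "[OX1;+0]",
        "[nX2;+0]", "[NX2;+0;!$(N=O)]", "[NX1;+0]",
        "[NX3;+0;H0;!$(N-a);!$(N-C=[O,N,S])]",
    ),
    "PI": ("[N+;!$([N+]-[O-])]", "[o+]", "[O+;X2;R]"),
}
MIN_HYDROPHOBIC_CLUSTER = 2  # isolated aliphatic carbons (e.g. methane) are not HY


@dataclass
class PharmacophoreFeature:
    """A typed feature point with a tolerance sphere (and optional direction)."""

    kind: str  # HBD | HBA | AR | PI | HY
    center: np.ndarray
    tolerance: float = DEFAULT_TOLERANCE
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            self.direction = d / n if n > 0 else None


@dataclass
class PharmacophoreModel:
    """An ordered feature set; excluded volumes are absent by construction."""

    name: str
    features: list[PharmacophoreFeature]

    def __post_init__(self) -> None:
        if len(self.features) < 3:
            raise ValueError("a model needs at least 3 features")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(f.kind for f in self.features)

    @property
    def centers(self) -> np.ndarray:
        return np.vstack([f.center for f in self.features])

    @property
    def inter_feature_distances(self) -> np.ndarray:
        c = self.centers
        d = c[:, None, :] - c[None, :, :]
        return np.sqrt((d ** 2).sum(axis=2))

    @property
    def excluded_volumes(self) -> tuple:
        return ()


@dataclass
class FeatureMapping:
    """Injective assignment of model features to ligand features."""

    assignments: list[tuple[int, int]]  # (model feature idx, ligand feature idx)
    displacements: list[float]          # d_f in Å, parallel to assignments


@dataclass
class FitResult:
    compound_ref: str
    model_ref: str
    fit: float
    best_conformer: int | None  # index into the conformer set
    mapping: FeatureMapping | None


@dataclass
class HitEntry:
    """One scored database entry (a state variant) in a hit list."""

    id: str
    parent_id: str
    smiles: str
    fits: dict[str, float] = field(default_factory=dict)

    @property
    def best_fit(self) -> float:
        return max(self.fits.values()) if self.fits else 0.0


@dataclass
class HitList:
    entries: list[HitEntry]
    models: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    active_fits: np.ndarray
    decoy_fits: np.ndarray
    min_mapped_active_fit: float | None


def perceive_features(c: Conformer | Chem.Mol,
                      tolerance: float = DEFAULT_TOLERANCE) -> list[PharmacophoreFeature]:
    """Perceive pharmacophoric feature points on a 3D conformer.

    HBD/HBA/PI come from SMARTS matches placed on the matched atom; AR is
    the centroid of each aromatic ring with the ring normal as direction;
    HY is the centroid of each connected cluster of at least two aliphatic
    carbons that touch no heteroatom.
    """
    mol = c.mol if isinstance(c, Conformer) else c
    if mol.GetNumConformers() == 0:
        raise ValueError("conformer has no 3D coordinates")
    coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
    feats: list[PharmacophoreFeature] = []

    for kind, patterns in FEATURE_SMARTS.items():
        seen: set[int] = set()
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            for match in mol.GetSubstructMatches(patt):
                idx = match[0]
                if idx in seen:
                    continue
                seen.add(idx)
                feats.append(PharmacophoreFeature(kind, coords[idx], tolerance))

    # aromatic rings: centroid + normal
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        pts = coords[list(ring)]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        feats.append(PharmacophoreFeature("AR", centroid, tolerance,
                                          direction=vt[2]))

    # hydrophobic: connected clusters of pure-carbon aliphatic atoms
    hydro = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if all(n.GetAtomicNum() in (1, 6) for n in atom.GetNeighbors()):
            hydro.add(atom.GetIdx())
    visited: set[int] = set()
    for start in sorted(hydro):
        if start in visited:
            continue
        stack, cluster = [start], []
        while stack:
            i = stack.pop()
            if i in visited:
                continue
            visited.add(i)
            cluster.append(i)
            for n in mol.GetAtomWithIdx(i).GetNeighbors():
                if n.GetIdx() in hydro and n.GetIdx() not in visited:
                    stack.append(n.GetIdx())
        if len(cluster) >= MIN_HYDROPHOBIC_CLUSTER:
            feats.append(PharmacophoreFeature("HY", coords[cluster].mean(axis=0),
                                              tolerance))
    return feats


def fit_from_displacements(displacements, tolerances) -> float:
    """Closed-form fit value for given per-feature displacements d_f (Å)."""
    d = np.asarray(displacements, dtype=float)
    t = np.asarray(tolerances, dtype=float)
    return float(np.sum(np.maximum(0.0, 1.0 - (d / t) ** 2)))


def _kind_compatible_mappings(model_kinds, ligand_kinds, cap: int = 20000):
    """Yield injective assignments ligand-feature-index per model feature."""
    candidates = [[j for j, lk in enumerate(ligand_kinds) if lk == mk]
                  for mk in model_kinds]
    if any(not c for c in candidates):
        return
    count = 0
    for combo in itertools.product(*candidates):
        if len(set(combo)) != len(combo):
            continue
        count += 1
        if count > cap:
            logger.warning("mapping enumeration capped at %d", cap)
            return
        yield combo


def _score_mapping(model: PharmacophoreModel, ligand_pts: np.ndarray):
    """Superpose mapped ligand features onto the model and score.

    Returns (fit, displacements) or None when any displacement exceeds its
    tolerance (inadmissible mapping).
    """
    centers = model.centers
    rot, t, _ = kabsch(ligand_pts, centers, strict=False)
    placed = ligand_pts @ rot.T + t
    d = np.linalg.norm(placed - centers, axis=1)
    tol = np.array([f.tolerance for f in model.features])
    if np.any(d > tol):
        return None
    return fit_from_displacements(d, tol), d


def fit_value(model: PharmacophoreModel, cs, compound_ref: str | None = None) -> FitResult:
    """Best fit of a compound (conformer ensemble) against a model.

    All conformers and all kind-compatible injective feature mappings are
    enumerated; each mapping is superposed onto the model feature centres
    and is admissible only if every displacement stays within its tolerance
    sphere.  The maximum admissible fit is returned; 0 with an empty mapping
    when nothing maps.
    """
    if isinstance(cs, Conformer):
        cs = ConformerSet(cs.variant_ref, [cs])
    ref = compound_ref or cs.variant_ref
    best = FitResult(ref, model.name, 0.0, None, None)
    for ci, conf in enumerate(cs):
        feats = perceive_features(conf)
        if not feats:
            continue
        kinds = [f.kind for f in feats]
        pts = np.vstack([f.center for f in feats])
        for combo in _kind_compatible_mappings(model.kinds, kinds):
            scored = _score_mapping(model, pts[list(combo)])
            if scored is None:
                continue
            fit, d = scored
            if fit > best.fit:
                best = FitResult(ref, model.name, fit, ci,
                                 FeatureMapping(list(enumerate(combo)),
                                                d.tolist()))
    return best


def generate_common_feature_models(aligned: list[Conformer], k_features: int = 3,
                                   max_models: int = 25,
                                   tolerance: float = DEFAULT_TOLERANCE,
                                   misses_allowed: int = 0,
                                   name_prefix: str = "model",
                                   ) -> list[PharmacophoreModel]:
    """Induce common-feature models from pre-aligned training ligands.

    The most feature-rich ligand serves as reference; every k-subset of its
    features is a candidate configuration.  A configuration survives when
    all but at most ``misses_allowed`` ligands map each of its features
    within ``tolerance`` (direct distances in the common frame).  Surviving
    configurations are ranked by (number of ligands mapped, mean fit) and
    returned, at most ``max_models``, with feature centres averaged over the
    mapped ligand features.
    """
    if len(aligned) < 3:
        raise ValueError("need at least 3 aligned training ligands")
    all_feats = [perceive_features(c, tolerance) for c in aligned]
    ref_idx = max(range(len(aligned)), key=lambda i: len(all_feats[i]))
    ref_feats = all_feats[ref_idx]
    if len(ref_feats) < k_features:
        logger.warning("reference ligand has fewer than %d features", k_features)
        return []

    scored_models = []
    for config in itertools.combinations(range(len(ref_feats)), k_features):
        kinds = [ref_feats[i].kind for i in config]
        centers = np.vstack([ref_feats[i].center for i in config])
        mapped_centers = [centers]
        n_missed = 0
        fits = []
        for li, feats in enumerate(all_feats):
            if li == ref_idx:
                fits.append(float(k_features))
                continue
            lk = [f.kind for f in feats]
            lp = np.vstack([f.center for f in feats]) if feats else np.zeros((0, 3))
            best_assign, best_cost = None, np.inf
            for combo in _kind_compatible_mappings(kinds, lk):
                d = np.linalg.norm(lp[list(combo)] - centers, axis=1)
                if np.any(d > tolerance):
                    continue
                cost = float((d ** 2).sum())
                if cost < best_cost:
                    best_cost, best_assign = cost, combo
            if best_assign is None:
                n_missed += 1
                if n_missed > misses_allowed:
                    break
                continue
            pts = lp[list(best_assign)]
            mapped_centers.append(pts)
            d = np.linalg.norm(pts - centers, axis=1)
            fits.append(fit_from_displacements(d, [tolerance] * k_features))
        if n_missed > misses_allowed:
            continue
        avg = np.mean(np.stack(mapped_centers), axis=0)
        n_mapped = len(aligned) - n_missed
        scored_models.append((n_mapped, float(np.mean(fits)), kinds, avg))

    scored_models.sort(key=lambda x: (-x[0], -x[1]))
    models = []
    for rank, (n_mapped, mean_fit, kinds, centers) in enumerate(scored_models[:max_models]):
        feats = [PharmacophoreFeature(k, c, tolerance)
                 for k, c in zip(kinds, centers)]
        models.append(PharmacophoreModel(f"{name_prefix}_{rank + 1:03d}", feats))
    if not models:
        logger.warning("no common feature configuration found")
    return models


def search_database(model: PharmacophoreModel, db: list[ConformerSet],
                    fit_cutoff: float) -> HitList:
    """Score a database against a model and keep entries with fit >= cutoff.

    Hits are ordered by descending fit, ties by input order.
    """
    if not (0.0 <= fit_cutoff <= model.n_features):
        raise ValueError(f"fit cutoff must lie in [0, {model.n_features}]")
    scored = []
    for i, cs in enumerate(db):
        res = fit_value(model, cs)
        if res.fit >= fit_cutoff and res.mapping is not None:
            scored.append((res.fit, i, cs))
    scored.sort(key=lambda x: (-x[0], x[1]))
    entries = [HitEntry(id=cs.variant_ref,
                        parent_id=cs.parent_id or cs.variant_ref,
                        smiles=cs.smiles, fits={model.name: fit})
               for fit, _, cs in scored]
    return HitList(entries, models=(model.name,))


def merge_hitlists(a: HitList, b: HitList) -> HitList:
    """Union of two hit lists keyed by canonical structure.

    Duplicates collapse to one entry carrying the per-model fits from both
    lists side by side.
    """
    def canon(smi: str) -> str:
        mol = Chem.MolFromSmiles(smi)
        return Chem.MolToSmiles(mol) if mol is not None else smi

    merged: dict[str, HitEntry] = {}
    for entry in itertools.chain(a, b):
        key = canon(entry.smiles)
        if key in merged:
            merged[key].fits.update(entry.fits)
        else:
            merged[key] = HitEntry(entry.id, entry.parent_id,
                                   entry.smiles, dict(entry.fits))
    models = tuple(dict.fromkeys(a.models + b.models))
    return HitList(list(merged.values()), models=models)


def validate_model(model: PharmacophoreModel, actives: list[ConformerSet],
                   decoys: list[ConformerSet]) -> ROCResult:
    """Actives/decoys screen: score both sets by fit value and build a ROC.

    The score of an unmapped compound is 0.  Ties are grouped (a tied block
    contributes a diagonal ROC segment); AUC is the trapezoidal area.  The
    minimum fit among the mapped actives is reported, which is the basis
    for choosing a prioritisation fit cut-off.
    """
    if not actives or not decoys:
        raise ValueError("both actives and decoys must be non-empty")
    a_fits = np.array([fit_value(model, cs).fit for cs in actives])
    d_fits = np.array([fit_value(model, cs).fit for cs in decoys])
    scores = np.concatenate([a_fits, d_fits])
    labels = np.concatenate([np.ones(len(a_fits)), np.zeros(len(d_fits))])
    if np.all(scores == scores[0]):
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        thresholds = np.array([scores[0], scores[0]])
        roc_auc = 0.5
    else:
        fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
        roc_auc = float(_sk_auc(fpr, tpr))
    mapped = a_fits[a_fits > 0]
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=roc_auc,
                     active_fits=a_fits, decoy_fits=d_fits,
                     min_mapped_active_fit=float(mapped.min()) if len(mapped) else None)


def model_to_json(model: PharmacophoreModel) -> dict:
    return {
        "name": model.name,
        "features": [
            {"kind": f.kind, "center": f.center.tolist(),
             "tolerance": f.tolerance,
             "direction": None if f.direction is None else f.direction.tolist()}
            for f in model.features
        ],
        "inter_feature_distances": model.inter_feature_distances.tolist(),
    }


def model_from_json(data: dict) -> PharmacophoreModel:
    feats = [PharmacophoreFeature(f["kind"], np.array(f["center"]),
                                  f["tolerance"],
                                  None if f.get("direction") is None
                                  else np.array(f["direction"]))
             for f in data["features"]]
    return PharmacophoreModel(data["name"], feats)
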