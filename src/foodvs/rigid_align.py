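"""Rigid-body alignment of conformers to a template by Gaussian overlap.

The similarity between a probe and a template conformer is the sum of
Gaussian overlaps between feature points of matching pharmacophoric type,

    S = sum_{matched feature pairs} exp(-d^2 / 2 sigma^2)
      + w_vol * sum_{heavy atom pairs} exp(-d^2 / 2 sigma_vol^2),

maximised over rigid transformations of the probe.  The second term is a
soft volume-overlap that keeps the optimisation well-behaved for feature-
poor molecules.  The optimiser is deterministic: a quasi-uniform rotation
grid seeds a local simplex refinement, followed by a correspondence polish
(nearest-neighbour atom matching + Kabsch) that recovers exact transforms
for congruent point sets.

This alignment selects, for each training ligand, the ensemble conformer
with maximum similarity to a bioactive template — the conformer then used
for pharmacophore model induction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ._geometry import kabsch, rotation_grid
from .confgen import Conformer, ConformerSet

__all__ = ["AlignmentResult", "align_rigid", "select_bioactive_conformer",
           "kabsch_superpose", "self_similarity"]

SIGMA_FEATURE = 1.0   # Å, Gaussian width for feature overlap
SIGMA_VOLUME = 1.0    # Å, Gaussian width for heavy-atom volume overlap
W_VOLUME = 0.2        # weight of the volume term relative to features


@dataclass
class AlignmentResult:
    rotation: np.ndarray     # 3x3 proper rotation
    translation: np.ndarray  # Å; transformed probe = R x + t
    similarity: float
    probe_ref: str = ""
    template_ref: str = ""


def kabsch_superpose(coords_a, coords_b):
    """Optimal proper rotation/translation mapping point set A onto B.

    Returns ``(rotation, translation, rmsd)``.  Requires >= 3 matched,
    non-collinear points.
    """
    return kabsch(coords_a, coords_b, strict=True)


def _overlap(pa: np.ndarray, pb: np.ndarray, sigma: float) -> float:
    if len(pa) == 0 or len(pb) == 0:
        return 0.0
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    return float(np.exp(-d2 / (2.0 * sigma * sigma)).sum())


def _feature_points(conf: Conformer):
    from .pharmacophore import perceive_features  # local: avoids module cycle

    feats = perceive_features(conf)
    by_kind: dict[str, list[np.ndarray]] = {}
    for f in feats:
        by_kind.setdefault(f.kind, []).append(f.center)
    return {k: np.vstack(v) for k, v in by_kind.items()}


def _score(probe_feats, probe_heavy, tmpl_feats, tmpl_heavy,
           rot: np.ndarray, trans: np.ndarray) -> float:
    s = 0.0
    for kind, pts in probe_feats.items():
        if kind in tmpl_feats:
            s += _overlap(pts @ rot.T + trans, tmpl_feats[kind], SIGMA_FEATURE)
    s += W_VOLUME * _overlap(probe_heavy @ rot.T + trans, tmpl_heavy, SIGMA_VOLUME)
    return s


def self_similarity(template: Conformer) -> float:
    """Similarity of a conformer with itself under the identity transform
    (the attainable maximum for any probe of equal composition)."""
    feats = _feature_points(template)
    heavy = template.heavy_coords
    return _score(feats, heavy, feats, heavy, np.eye(3), np.zeros(3))


def align_rigid(probe: Conformer, template: Conformer,
                n_grid: int = 60, n_refine: int = 5) -> AlignmentResult:
    """Rigid alignment of ``probe`` onto ``template`` maximising S.

    Deterministic: ``n_grid`` quasi-uniform orientations (plus identity) are
    scored after centroid superposition; the best ``n_refine`` are each
    refined by Nelder-Mead over rotation vector and translation, and the
    winner is polished by nearest-neighbour correspondence + Kabsch.
    """
    p_heavy = probe.heavy_coords
    t_heavy = template.heavy_coords
    p_feats = _feature_points(probe)
    t_feats = _feature_points(template)
    if len(p_heavy) < 3 and not p_feats:
        raise ValueError("probe has no features and fewer than 3 heavy atoms")
    if len(t_heavy) < 3 and not t_feats:
        raise ValueError("template has no features and fewer than 3 heavy atoms")

    pc = p_heavy.mean(axis=0)
    tc = t_heavy.mean(axis=0)

    def full_transform(rot, trans_local):
        # rotate about probe centroid, then place at template centroid + shift
        r = rot
        t = tc + trans_local - r @ pc
        return r, t

    def neg_score(params, base_rot):
        r = Rotation.from_rotvec(params[:3]).as_matrix() @ base_rot
        rot, t = full_transform(r, params[3:])
        return -_score(p_feats, p_heavy, t_feats, t_heavy, rot, t)

    # stage 0: feature-correspondence candidates — Kabsch on every
    # kind-compatible triple of feature points gives exact seeds for
    # feature-rich molecules
    seeds: list[np.ndarray] = []
    pairs_by_kind = [(kp, i, j)
                     for kp in p_feats if kp in t_feats
                     for i in range(len(p_feats[kp]))
                     for j in range(len(t_feats[kp]))]
    if len(pairs_by_kind) >= 3:
        from itertools import combinations

        for triple in combinations(pairs_by_kind, 3):
            if len({(k, i) for k, i, _ in triple}) < 3:
                continue
            if len({(k, j) for k, _, j in triple}) < 3:
                continue
            a = np.vstack([p_feats[k][i] for k, i, _ in triple])
            b = np.vstack([t_feats[k][j] for k, _, j in triple])
            try:
                rot_c, t_c, _ = kabsch(a, b)
            except ValueError:
                continue
            seeds.append(rot_c)
            if len(seeds) >= 40:
                break

    # stage 1: orientation grid (centroid-pinned) plus correspondence seeds
    grid_scores = []
    for rot in rotation_grid(n_grid):
        r, t = full_transform(rot, np.zeros(3))
        grid_scores.append((_score(p_feats, p_heavy, t_feats, t_heavy, r, t), rot))
    for rot_c in seeds:
        # express the seeded full transform in centroid-pinned form
        grid_scores.append((_score(p_feats, p_heavy, t_feats, t_heavy,
                                   rot_c, tc - rot_c @ pc), rot_c))
    grid_scores.sort(key=lambda x: -x[0])

    # stage 2: local refinement from the best grid orientations
    best_val, best_rot, best_trans = -np.inf, np.eye(3), np.zeros(3)
    for s0, rot0 in grid_scores[:n_refine]:
        res = minimize(neg_score, np.zeros(6), args=(rot0,),
                       method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 800})
        r = Rotation.from_rotvec(res.x[:3]).as_matrix() @ rot0
        rot, t = full_transform(r, res.x[3:])
        val = -res.fun
        if val > best_val:
            best_val, best_rot, best_trans = val, rot, t

    # stage 3: correspondence polish (exact for congruent heavy-atom sets)
    placed = p_heavy @ best_rot.T + best_trans
    d2 = ((placed[:, None, :] - t_heavy[None, :, :]) ** 2).sum(axis=2)
    nn_p = d2.argmin(axis=1)
    nn_t = d2.argmin(axis=0)
    pairs = [(i, j) for i, j in enumerate(nn_p)
             if nn_t[j] == i and d2[i, j] < 1.0]
    if len(pairs) >= 3:
        pi, ti = zip(*pairs)
        try:
            rot_p, t_p, _ = kabsch(p_heavy[list(pi)], t_heavy[list(ti)])
            val = _score(p_feats, p_heavy, t_feats, t_heavy, rot_p, t_p)
            if val > best_val:
                best_val, best_rot, best_trans = val, rot_p, t_p
        except ValueError:
            pass  # degenerate correspondence; keep refined solution

    return AlignmentResult(rotation=best_rot, translation=best_trans,
                           similarity=best_val,
                           probe_ref=probe.variant_ref,
                           template_ref=template.variant_ref)


def select_bioactive_conformer(cs: ConformerSet, template: Conformer,
                               **align_kwargs):
    """Pick the ensemble member with maximum alignment similarity to the
    template (the working approximation to the bioactive conformer).

    Ties break by lower strain energy, then lower index.  Returns the
    selected conformer transformed into the template frame together with
    its :class:`AlignmentResult`.
    """
    if len(cs) == 0:
        raise ValueError("empty conformer set")
    best = None
    for i, conf in enumerate(cs):
        res = align_rigid(conf, template, **align_kwargs)
        key = (-res.similarity, conf.energy if conf.energy is not None else 0.0, i)
        if best is None or key < best[0]:
            best = (key, conf, res)
    _, conf, res = best
    return conf.transformed(res.rotation, res.translation), res
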