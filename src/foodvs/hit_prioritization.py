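"""Fingerprints, Tanimoto similarity, hit-list clustering and
representative picking, plus the 2D similarity baseline screen.

Hit lists from 3D pharmacophore searching are partitioned into K structural
clusters (complete-linkage agglomerative clustering on 1 - Tanimoto over
structural-key fingerprints) so that one representative per cluster can be
carried forward.  Tautomer/protonation variants of one parent are pooled
onto the parent before clustering, so corresponding states always land in
the same cluster.  The 2D baseline ranks a whole library by maximum
Tanimoto similarity to a reference (training) set with circular
fingerprints, the comparison that 3D pharmacophore screening is meant to
beat for scaffold-hopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .pharmacophore import HitEntry, HitList

__all__ = ["Fingerprint", "ClusterAssignment", "compute_fingerprint",
           "tanimoto", "cluster_hits", "pick_representatives",
           "similarity_screen"]

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class Fingerprint:
    """A fixed-length bit fingerprint.

    ``circular_r2`` is a radius-2 (diameter-4) hashed circular fingerprint;
    ``structural_keys`` is the 166-key MACCS-style structural key set, a
    public stand-in for MDL public keys.
    """

    bits: DataStructs.ExplicitBitVect
    kind: str
    length: int

    @property
    def popcount(self) -> int:
        return self.bits.GetNumOnBits()


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # cluster index (1..K) per hit entry
    K: int
    linkage_record: np.ndarray    # scipy merge history over parents
    parent_order: list[str] = field(default_factory=list)


def _as_mol(m) -> Chem.Mol:
    if isinstance(m, Chem.Mol):
        return m
    if isinstance(m, str):
        mol = Chem.MolFromSmiles(m)
        if mol is None:
            raise ValueError(f"invalid structure: {m!r}")
        return mol
    if hasattr(m, "mol"):
        return m.mol
    raise TypeError(f"cannot interpret {type(m)} as a molecule")


def compute_fingerprint(m, kind: str = "circular_r2") -> Fingerprint:
    """Deterministic, canonicalisation-invariant fingerprint of a structure."""
    mol = _as_mol(m)
    if kind == "circular_r2":
        bv = _MORGAN.GetFingerprint(mol)
        return Fingerprint(bv, kind, 2048)
    if kind == "structural_keys":
        bv = MACCSkeys.GenMACCSKeys(mol)
        return Fingerprint(bv, kind, bv.GetNumBits())
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| in [0, 1].

    Two empty fingerprints compare as identical (1.0).
    """
    if a.kind != b.kind or a.length != b.length:
        raise ValueError("fingerprints of different kind/length are not comparable")
    if a.popcount == 0 and b.popcount == 0:
        return 1.0
    return float(DataStructs.TanimotoSimilarity(a.bits, b.bits))


def cluster_hits(entries, K: int, kind: str = "structural_keys") -> ClusterAssignment:
    """Partition a hit list into K structural clusters.

    Complete-linkage agglomerative clustering on (1 - Tanimoto) distances,
    cut to exactly K clusters; deterministic with ties resolved by input
    order.  Variants sharing a parent are pooled before clustering so they
    always co-cluster.  Labels are renumbered by first appearance.
    """
    if isinstance(entries, HitList):
        entries = entries.entries
    if not entries:
        raise ValueError("empty hit list")
    parents: list[str] = []
    parent_smiles: dict[str, str] = {}
    for e in entries:
        if e.parent_id not in parent_smiles:
            parents.append(e.parent_id)
            parent_smiles[e.parent_id] = e.smiles
    n = len(parents)
    if not (1 <= K <= n):
        raise ValueError(f"K must be in [1, {n}] (distinct parents), got {K}")

    fps = [compute_fingerprint(parent_smiles[p], kind) for p in parents]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - tanimoto(fps[i], fps[j])
    if n == 1:
        z = np.zeros((0, 4))
        raw = np.array([1])
    else:
        z = linkage(squareform(dist, checks=False), method="complete")
        raw = fcluster(z, t=K, criterion="maxclust")

    relabel: dict[int, int] = {}
    parent_label: dict[str, int] = {}
    for p, r in zip(parents, raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        parent_label[p] = relabel[r]
    labels = np.array([parent_label[e.parent_id] for e in entries])
    return ClusterAssignment(labels=labels, K=K, linkage_record=z,
                             parent_order=parents)


def _heavy_atoms(smiles: str) -> int:
    return _as_mol(smiles).GetNumHeavyAtoms()


def pick_representatives(ca: ClusterAssignment, entries,
                         cutoff_rule: dict[str, float],
                         max_heavy_atoms: int = 40) -> pd.DataFrame:
    """Select one representative per cluster under the fit cut-off rule.

    An entry is eligible when its fit exceeds the cut-off for at least one
    model and its heavy-atom count does not exceed ``max_heavy_atoms`` (the
    stand-in for the manual rejection of large, bulky compounds that score
    deceptively high).  Per cluster the eligible entry with the highest fit
    is selected; the returned frame flags every entry for review.
    """
    if isinstance(entries, HitList):
        entries = entries.entries
    rows = []
    for i, e in enumerate(entries):
        passed = any(e.fits.get(m, 0.0) >= c for m, c in cutoff_rule.items())
        heavy = _heavy_atoms(e.smiles)
        rows.append({"index": i, "id": e.id, "parent": e.parent_id,
                     "cluster": int(ca.labels[i]), "best_fit": e.best_fit,
                     "passed_cutoff": passed,
                     "heavy_atoms": heavy,
                     "heavy_ok": heavy <= max_heavy_atoms,
                     "selected": False})
    df = pd.DataFrame(rows)
    for _, grp in df.groupby("cluster", sort=True):
        ok = grp[grp.passed_cutoff & grp.heavy_ok]
        if len(ok):
            df.loc[ok.best_fit.idxmax(), "selected"] = True
    return df


def similarity_screen(db, references, kind: str = "circular_r2",
                      top_n: int = 100) -> tuple[pd.DataFrame, float]:
    """Rank a library by maximum Tanimoto similarity to a reference set.

    Returns the descending ranking and the score of the rank-``top_n``
    entry (clamped to the library size) — the similarity a compound must
    beat to appear among the top N of a plain 2D screen.
    """
    if not db or not references:
        raise ValueError("db and references must be non-empty")
    ref_fps = [compute_fingerprint(r, kind) for r in references]
    rows = []
    for i, m in enumerate(db):
        fp = compute_fingerprint(m, kind)
        score = max(tanimoto(fp, r) for r in ref_fps)
        name = getattr(m, "name", None) or getattr(m, "id", None) or str(i)
        rows.append({"index": i, "name": name, "max_tc": score})
    df = pd.DataFrame(rows).sort_values(["max_tc", "index"],
                                        ascending=[False, True],
                                        kind="stable").reset_index(drop=True)
    threshold = float(df.max_tc.iloc[min(top_n, len(df)) - 1])
    return df, threshold
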