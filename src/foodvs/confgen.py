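"""Bounded conformer-ensemble generation.

Stochastic distance-geometry embedding (ETKDG) with an optional force-field
minimisation step, RMSD pruning and an energy window produces the diverse
low-energy ensembles that feed pharmacophore model induction and 3D
searching.  The bioactive conformer of a ligand is usually found near the
global minimum, which motivates keeping only conformers within a fixed
strain-energy window of the ensemble minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ._geometry import pairwise_rmsd

__all__ = ["Conformer", "ConformerSet", "generate_conformers",
           "ensemble_rmsd_matrix", "write_conformers_sdf"]


@dataclass
class Conformer:
    """A single 3D conformation (heavy atoms, Å) of a state variant."""

    variant_ref: str
    mol: Chem.Mol = field(repr=False)
    energy: float | None = None  # strain energy relative to ensemble minimum, kcal/mol

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    @property
    def heavy_coords(self) -> np.ndarray:
        idx = [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]
        return self.coords[idx]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        """Return a rigidly transformed copy (x -> R x + t)."""
        mol = Chem.Mol(self.mol)
        conf = mol.GetConformer()
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        for i, p in enumerate(new):
            conf.SetAtomPosition(i, p.tolist())
        return Conformer(self.variant_ref, mol, self.energy)


@dataclass
class ConformerSet:
    """Energy-sorted, RMSD-pruned ensemble for one state variant."""

    variant_ref: str
    conformers: list[Conformer]
    parent_id: str | None = None
    generation_params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.conformers[0].mol))


def generate_conformers(variant, max_n: int = 255, minimize: bool = True,
                        rmsd_prune: float = 0.5, seed: int = 0,
                        energy_window: float = 20.0) -> ConformerSet:
    """Generate up to ``max_n`` conformers for a state variant.

    Parameters mirror the two preparation runs used for training-set
    ligands: once with and once without force-field minimisation.  The
    ensemble is pruned at ``rmsd_prune`` Å heavy-atom RMSD, restricted to
    ``energy_window`` kcal/mol above the minimum and sorted by ascending
    strain energy.  Reproducible for a fixed ``seed``.

    ``variant`` may be a :class:`~foodvs.compound_db.StateVariant`, an RDKit
    Mol or a SMILES string.
    """
    if isinstance(variant, str):
        mol = Chem.MolFromSmiles(variant)
        ref, parent = variant, None
    elif isinstance(variant, Chem.Mol):
        mol, ref, parent = variant, Chem.MolToSmiles(variant), None
    else:  # StateVariant
        mol = variant.mol
        ref = f"{variant.parent_id}/{variant.variant_label}"
        parent = variant.parent_id
    if mol is None:
        raise ValueError(f"cannot embed variant {ref!r}: invalid structure")

    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = float(rmsd_prune)
    params.useRandomCoords = False
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=int(max_n), params=params)
    if len(conf_ids) == 0:
        raise RuntimeError(f"3D embedding failed for variant {ref!r}")

    energies: list[float] = []
    if minimize:
        if AllChem.MMFFHasAllMoleculeParams(molh):
            results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
        else:
            results = AllChem.UFFOptimizeMoleculeConfs(molh, maxIters=500)
        energies = [e for _, e in results]
    else:
        props = AllChem.MMFFGetMoleculeProperties(molh)
        if props is not None:
            ff_ok = True
            for cid in conf_ids:
                ff = AllChem.MMFFGetMoleculeForceField(molh, props, confId=cid)
                if ff is None:
                    ff_ok = False
                    break
                energies.append(ff.CalcEnergy())
            if not ff_ok:
                energies = []
        if not energies:
            energies = [0.0] * len(conf_ids)

    e0 = min(energies)
    order = sorted(range(len(conf_ids)), key=lambda i: (energies[i], i))

    kept: list[Conformer] = []
    kept_coords: list[np.ndarray] = []
    heavy_idx = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() > 1]
    for i in order:
        rel_e = energies[i] - e0
        if rel_e > energy_window:
            continue
        conf = molh.GetConformer(conf_ids[i])
        coords = np.asarray(conf.GetPositions(), dtype=float)[heavy_idx]
        if any(pairwise_rmsd(coords, prev) < rmsd_prune for prev in kept_coords):
            continue
        single = Chem.Mol(molh, confId=conf_ids[i])
        single = Chem.RemoveHs(single)
        kept.append(Conformer(variant_ref=ref, mol=single, energy=rel_e))
        kept_coords.append(coords)
        if len(kept) >= max_n:
            break

    return ConformerSet(
        variant_ref=ref, conformers=kept, parent_id=parent,
        generation_params={"max_n": max_n, "minimized": minimize,
                           "rmsd_prune": rmsd_prune, "seed": seed,
                           "energy_window": energy_window},
    )


def ensemble_rmsd_matrix(cs: ConformerSet) -> np.ndarray:
    """Symmetric matrix of pairwise heavy-atom best-fit RMSD (Å)."""
    if len(cs) < 1:
        raise ValueError("empty conformer set")
    coords = [c.heavy_coords for c in cs]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_rmsd(coords[i], coords[j])
    return mat


def write_conformers_sdf(sets, path) -> None:
    """Write one or more conformer sets to a multi-record SDF file."""
    if isinstance(sets, ConformerSet):
        sets = [sets]
    writer = Chem.SDWriter(str(path))
    for cs in sets:
        for i, c in enumerate(cs):
            mol = Chem.Mol(c.mol)
            mol.SetProp("_Name", f"{cs.variant_ref}#{i}")
            if c.energy is not None:
                mol.SetProp("rel_energy_kcal_mol", f"{c.energy:.4f}")
            writer.write(mol)
    writer.close()
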