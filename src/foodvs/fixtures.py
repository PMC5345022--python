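"""Deterministic generators for every synthetic input the pipeline needs.

Nothing is downloaded: validation-scale actives/decoys sets, the named
compound panel, a toy binding pocket and pharmacology curves are all built
in code from a seed.  Actives are real feature-bearing small molecules (a
protonated phenolic phenethylamine whose perceived features realise the
hydrogen-bond donor / aromatic ring / positive-ionisable triad of the
agonist pharmacophore), so the whole perception -> mapping -> fit path is
exercised, not just abstract point sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from .compound_db import Molecule
from .confgen import Conformer, ConformerSet

__all__ = ["FixtureSpec", "make_feature_triad_ligands", "make_decoys",
           "make_training_ligands", "triad_template", "make_named_compound_set",
           "make_toy_pocket", "make_dose_response", "make_ki_table_fixture",
           "make_screening_library", "NAMED_SMILES", "TABLE1_KI"]

# Cationic (N-protonated) hordenine: HBD on the phenol, AR on the ring,
# PI on the ammonium nitrogen — the agonist-model triad.
ACTIVE_SMILES = "C[NH+](C)CCc1ccc(O)cc1"
# 4-ethylphenol: same HBD/AR but no positive-ionisable feature.
DECOY_SMILES = "CCc1ccc(O)cc1"


@dataclass
class FixtureSpec:
    """All knobs of the synthetic study conditions, seed included.

    Defaults mirror the validation-set scale of the screen this package
    re-implements: 136 actives with 39 property-matched decoys each, and
    dose-response curves sampled at 8 concentrations in triplicate with
    5 % Gaussian noise.
    """

    seed: int = 7
    n_actives: int = 136
    n_decoys_per_active: int = 39
    library_size: int = 50
    noise: float = 0.0            # Å displacement SD on atom coordinates
    ec50: float = 1e-6            # mol/L
    emax: float = 80.0            # percent
    hill: float = 1.0
    basal: float = 0.0            # percent
    noise_sd: float = 5.0         # percent, additive Gaussian on responses
    n_points: int = 8
    n_replicates: int = 3


def _embed(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(mol)
    return Chem.RemoveHs(mol)


def triad_template(seed: int = 7) -> Conformer:
    """The canonical template conformer whose features define the triad."""
    return Conformer(variant_ref="triad_template", mol=_embed(ACTIVE_SMILES, seed))


def _noisy_copies(base: Conformer, n: int, noise: float, rng,
                  prefix: str, transform: bool = True,
                  displace_atom: str | None = None,
                  displacement: float = 0.0) -> list[ConformerSet]:
    coords0 = base.coords
    out = []
    for i in range(n):
        coords = coords0.copy()
        if displace_atom is not None:
            mol0 = base.mol
            idx = next(a.GetIdx() for a in mol0.GetAtoms()
                       if a.GetSymbol() == displace_atom)
            direction = rng.normal(size=3)
            coords[idx] += displacement * direction / np.linalg.norm(direction)
        if noise > 0:
            coords = coords + rng.normal(scale=noise, size=coords.shape)
        if transform:
            rot = Rotation.from_quat(_unit_quat(rng)).as_matrix()
            trans = rng.uniform(-10, 10, size=3)
            coords = coords @ rot.T + trans
        mol = Chem.Mol(base.mol)
        conf = mol.GetConformer()
        for k, p in enumerate(coords):
            conf.SetAtomPosition(k, p.tolist())
        ref = f"{prefix}_{i:05d}"
        out.append(ConformerSet(variant_ref=ref, parent_id=ref,
                                conformers=[Conformer(ref, mol)]))
    return out


def _unit_quat(rng) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def make_feature_triad_ligands(spec: FixtureSpec) -> list[ConformerSet]:
    """Actives: randomly placed copies of the triad scaffold conformer with
    Gaussian atomic noise of SD ``spec.noise`` Å.  At zero noise every
    active maps a template-built model perfectly (fit = n_features)."""
    rng = np.random.default_rng(spec.seed)
    base = triad_template(spec.seed)
    return _noisy_copies(base, spec.n_actives, spec.noise, rng, "active")


def make_training_ligands(spec: FixtureSpec, n: int = 5) -> list[Conformer]:
    """A small aligned training set (template frame, noise applied but no
    rigid scatter) for common-feature model induction."""
    rng = np.random.default_rng(spec.seed + 1)
    base = triad_template(spec.seed)
    sets = _noisy_copies(base, n, spec.noise, rng, "train", transform=False)
    return [cs.conformers[0] for cs in sets]


def make_decoys(spec: FixtureSpec, mode: str = "missing_pi") -> list[ConformerSet]:
    """Decoys at validation scale (``n_actives * n_decoys_per_active``).

    ``missing_pi`` decoys share the donor/aromatic chemistry but lack any
    positive-ionisable group; ``scrambled`` decoys keep the scaffold but
    displace the cationic nitrogen far outside (> 2x) the tolerance sphere.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n = spec.n_actives * spec.n_decoys_per_active
    if mode == "missing_pi":
        base = Conformer("decoy_base", _embed(DECOY_SMILES, spec.seed))
        return _noisy_copies(base, n, spec.noise, rng, "decoy")
    if mode == "scrambled":
        base = triad_template(spec.seed)
        return _noisy_copies(base, n, spec.noise, rng, "decoy",
                             displace_atom="N", displacement=6.0)
    raise ValueError(f"unknown decoy mode {mode!r}")


# The experimentally tested panel: nine agonist-screen hits, eight
# antagonist-screen hits, plus the reference ligands dopamine and
# quinpirole.  Structures transcribed from public records as constitutional
# SMILES (stereocentres not asserted); delphinidin is the flavylium cation.
NAMED_SMILES: dict[str, tuple[str, str]] = {
    # agonist-screen hits
    "clenbuterol": ("CC(C)(C)NCC(O)c1cc(Cl)c(N)c(Cl)c1", "agonist_screen"),
    "delphinidin": ("Oc1cc(O)c2cc(O)c(-c3cc(O)c(O)c(O)c3)[o+]c2c1", "agonist_screen"),
    "fumigaclavine A": ("CC1CN(C)C2Cc3c[nH]c4cccc(c34)C2C1OC(C)=O", "agonist_screen"),
    "hordenine": ("CN(C)CCc1ccc(O)cc1", "agonist_screen"),
    "kukoamine A": ("Oc1ccc(CCC(=O)NCCCNCCCCNCCCNC(=O)CCc2ccc(O)c(O)c2)cc1O",
                    "agonist_screen"),
    "leonurine": ("COc1cc(C(=O)OCCCCNC(=N)N)cc(OC)c1O", "agonist_screen"),
    "muscimol": ("NCc1cc(O)no1", "agonist_screen"),
    "pyrraline": ("OCc1ccc(C=O)n1CCCCC(N)C(=O)O", "agonist_screen"),
    "salsolinol": ("CC1NCCc2cc(O)c(O)cc12", "agonist_screen"),
    # antagonist-screen hits
    "ajmalicine": ("CC1OC=C(C(=O)OC)C2CN3CCc4c([nH]c5ccccc45)C3CC12",
                   "antagonist_screen"),
    "dihydroberberine": ("COc1ccc2c(c1OC)CN1CCc3cc4OCOc4cc3C1=C2",
                         "antagonist_screen"),
    "emetine": ("CCC1CN2CCc3cc(OC)c(OC)cc3C2CC1CC1NCCc2cc(OC)c(OC)cc12",
                "antagonist_screen"),
    "fenpropimorph": ("CC(Cc1ccc(C(C)(C)C)cc1)CN1CC(C)OC(C)C1", "antagonist_screen"),
    "halofuginone": ("O=C(CC1NCCCC1O)CN1C=Nc2cc(Cl)c(Br)cc2C1=O", "antagonist_screen"),
    "robenidine": ("Clc1ccc(/C=N/NC(=N)N/N=C/c2ccc(Cl)cc2)cc1", "antagonist_screen"),
    "roquefortine C": ("C=CC(C)(C)C12CC3C(=O)NC(=Cc4cnc[nH]4)C(=O)N3C1Nc1ccccc12",
                       "antagonist_screen"),
    "sarafloxacin": ("OC(=O)c1cn(-c2ccc(F)cc2)c2cc(N3CCNCC3)c(F)cc2c1=O",
                     "antagonist_screen"),
    # reference ligands
    "dopamine": ("NCCc1ccc(O)c(O)c1", "reference"),
    "quinpirole": ("CCCN1CCC2Cc3cn[nH]c3CC2C1", "reference"),
}


def make_named_compound_set() -> list[Molecule]:
    """The 17 tested compounds plus dopamine and quinpirole, as Molecules."""
    return [Molecule(id=name, name=name, smiles=smi, source="fixture")
            for name, (smi, _) in NAMED_SMILES.items()]


# Binding panel: Ki (nM) against the D2 receptor as printed, with censored
# entries kept as "> bound" strings and never imputed.  sem is the printed
# uncertainty where available.
TABLE1_KI: tuple[tuple[str, str, str, str], ...] = (
    ("clenbuterol", "agonist_screen", "50,000", "13,000"),
    ("delphinidin", "agonist_screen", "26,000", "6,800"),
    ("fumigaclavine A", "agonist_screen", "1,100", "160"),
    ("hordenine", "agonist_screen", "13,000", "2,700"),
    ("kukoamine A", "agonist_screen", ">100,000", ""),
    ("leonurine", "agonist_screen", ">100,000", ""),
    ("muscimol", "agonist_screen", ">100,000", ""),
    ("pyrraline", "agonist_screen", ">100,000", ""),
    ("salsolinol", "agonist_screen", "7,300", "1,900"),
    ("ajmalicine", "antagonist_screen", ">100,000", ""),
    ("dihydroberberine", "antagonist_screen", "75,000", "27,000"),
    ("emetine", "antagonist_screen", "37,000", "5,700"),
    ("fenpropimorph", "antagonist_screen", ">100,000", ""),
    ("halofuginone", "antagonist_screen", ">50,000", ""),
    ("robenidine", "antagonist_screen", "5,400", "1,600"),
    ("roquefortine C", "antagonist_screen", ">100,000", ""),
    ("sarafloxacin", "antagonist_screen", ">100,000", ""),
)


def make_ki_table_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """The tested-compound Ki panel as a data frame (optionally CSV)."""
    df = pd.DataFrame(TABLE1_KI,
                      columns=["compound", "screen_class", "ki_nM", "sem_nM"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


_PDB_ATOM = ("{rec:<6s}{serial:>5d} {name:<4s} {res:<3s} {chain}{resseq:>4d}"
             "    {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
             "          {elem:>2s}\n")

# Minimal binding-site mimic: an aspartate carboxylate and two serine
# hydroxyls arranged so that a phenolic ligand hydroxyl placed near one
# serine cannot simultaneously reach the other (mono- vs bis-hydroxyl
# discrimination), while an ammonium nitrogen can salt-bridge the
# carboxylate.  Coordinates are synthetic, fixed and printed in the file.
_POCKET_RESIDUES = [
    ("ASP", 114, [("N", "N", (3.5, 2.0, 1.3)), ("CA", "C", (2.9, 0.8, 1.4)),
                  ("CB", "C", (1.5, 0.5, 1.2)), ("CG", "C", (0.7, 0.9, 0.0)),
                  ("OD1", "O", (0.0, 0.0, 0.0)), ("OD2", "O", (1.1, 1.8, -0.9))]),
    ("SER", 193, [("N", "N", (8.2, -8.4, 2.8)), ("CA", "C", (7.6, -7.9, 2.6)),
                  ("CB", "C", (7.1, -8.1, 1.9)), ("OG", "O", (6.5, -7.5, 2.0))]),
    ("SER", 197, [("N", "N", (4.0, -7.2, 0.9)), ("CA", "C", (3.6, -6.8, 0.8)),
                  ("CB", "C", (3.2, -6.6, 0.6)), ("OG", "O", (2.9, -6.0, 0.5))]),
]


def make_toy_pocket(path: str | Path | None = None) -> str:
    """A synthetic PDB mini-site (Asp carboxylate + two Ser hydroxyls)."""
    lines = []
    serial = 1
    for resname, resseq, atoms in _POCKET_RESIDUES:
        for name, elem, (x, y, z) in atoms:
            lines.append(_PDB_ATOM.format(rec="ATOM", serial=serial, name=name,
                                          res=resname, chain="A", resseq=resseq,
                                          x=x, y=y, z=z, occ=1.0, b=0.0,
                                          elem=elem))
            serial += 1
    lines.append("END\n")
    text = "".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def make_dose_response(spec: FixtureSpec, compound: str = "synthetic",
                       path: str | Path | None = None) -> pd.DataFrame:
    """Replicate dose-response curves from a 4PL truth with Gaussian noise.

    Concentrations are log-spaced over +-3.5 decades around the true EC50;
    responses carry additive noise of SD ``spec.noise_sd`` percent.
    """
    rng = np.random.default_rng(spec.seed + 3)
    logc = np.linspace(np.log10(spec.ec50) - 3.5, np.log10(spec.ec50) + 3.5,
                       spec.n_points)
    conc = 10.0 ** logc
    rows = []
    for rep in range(spec.n_replicates):
        truth = spec.basal + (spec.emax - spec.basal) / (
            1.0 + 10.0 ** (spec.hill * (np.log10(spec.ec50) - logc)))
        resp = truth + rng.normal(scale=spec.noise_sd, size=truth.shape)
        for c, r in zip(conc, resp):
            rows.append({"compound": compound, "conc_M": c, "response": r,
                         "replicate": rep + 1})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def make_screening_library(spec: FixtureSpec) -> list[Molecule]:
    """A small deterministic SMILES library of phenethylamine/phenol
    variations for end-to-end demos (library preparation, 2D screen)."""
    scaffolds = [
        "NCCc1ccc(O)cc1", "CNCCc1ccc(O)cc1", "CN(C)CCc1ccc(O)cc1",
        "NCCc1ccc(O)c(O)c1", "CCc1ccc(O)cc1", "OCCc1ccccc1",
        "NCCc1ccccc1", "CC(N)Cc1ccc(O)cc1", "Oc1ccc(CCO)cc1",
        "CN(C)CCc1ccc(OC)cc1",
    ]
    mols = []
    for i in range(spec.library_size):
        smi = scaffolds[i % len(scaffolds)]
        mols.append(Molecule(id=f"lib_{i:04d}", name=f"lib_{i:04d}",
                             smiles=smi, source="fixture"))
    return mols
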