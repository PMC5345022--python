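"""Compound-library preparation: reading, food-likeness filtering and
tautomer/protonation-state enumeration.

A food-compound screening library differs from a drug-like one mainly in
what must be thrown away before 3D searching: very heavy compounds and
polyglycosides are unlikely to be absorbed in the gastrointestinal tract, so
entries heavier than 750 Da or carrying more than two sugar moieties are
removed.  Because a 3D pharmacophore search scores individual structures,
tautomers and physiologically relevant protonation states are enumerated and
treated as separate database entries that share one parent identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

__all__ = [
    "Molecule",
    "StateVariant",
    "read_library",
    "count_sugar_moieties",
    "filter_food_database",
    "enumerate_states",
    "compute_properties",
    "dedup_libraries",
    "write_sdf",
]

# Sugar moiety = saturated pyranose/furanose ring whose ring carbons carry at
# least MIN_RING_OXYGEN_SUBSTITUENTS exocyclic hydroxyl/ether oxygens.  The
# ring skeletons are SMARTS-configurable; the oxygen-substitution requirement
# separates true glycoside rings from plain tetrahydropyrans.
SUGAR_RING_SMARTS: tuple[str, ...] = (
    "[C;R]1[C;R][C;R][C;R][C;R][O;R]1",  # pyranose skeleton
    "[C;R]1[C;R][C;R][C;R][O;R]1",       # furanose skeleton
)
MIN_RING_OXYGEN_SUBSTITUENTS = 2

# pH 7.4 protonation rule table.  Each rule is (name, SMARTS for the atom to
# (de)protonate, charge delta).  Aliphatic amines, amidines and guanidines
# are basic enough (pKa > 9) to be protonated at physiological pH;
# carboxylic acids (pKa ~ 4) are deprotonated.  Anilines and amides are
# deliberately excluded (pKa far below 7.4).
PROTONATION_RULES: tuple[tuple[str, str, int], ...] = (
    ("aliphatic-amine",
     "[NX3;+0;!$(N-a);!$(N-C=[O,S,N]);!$(N-[S,P]=O);!$(N=*);!$(N-O)]", +1),
    ("amidine/guanidine",
     "[NX2;+0]=[CX3;+0;$(C-[#7])]", +1),
    ("carboxylic-acid",
     "[OX2H1;$(O-C=O)]", -1),
)


@dataclass
class Molecule:
    """A library entry: one parent structure with identity and source tag."""

    id: str
    name: str
    smiles: str
    source: str = "user"  # FCDB | PhyDB | fixture | user
    mol: Chem.Mol | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mol is None:
            self.mol = Chem.MolFromSmiles(self.smiles)
        if self.mol is None:
            raise ValueError(f"unparseable structure for {self.id!r}: {self.smiles!r}")
        self.smiles = Chem.MolToSmiles(self.mol)

    @property
    def mw(self) -> float:
        """Molecular weight in Da, computed on the parent structure."""
        return Descriptors.MolWt(self.mol)

    @property
    def n_sugar(self) -> int:
        return count_sugar_moieties(self)


@dataclass
class StateVariant:
    """One tautomer/protonation state of a parent :class:`Molecule`."""

    parent_id: str
    variant_label: str
    smiles: str
    net_charge: int
    mol: Chem.Mol = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.mol is None:
            self.mol = Chem.MolFromSmiles(self.smiles)
        if self.mol is None:
            raise ValueError(f"unparseable variant structure: {self.smiles!r}")


def read_library(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read a compound library from a SMILES (.smi) or SDF (.sdf) file.

    SMILES files hold one record per line, ``SMILES[<tab or space>name]``.
    Unparseable records are logged and skipped; the function fails only if
    the file is missing or contains no valid record at all.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "SDF" if path.suffix.lower() in {".sdf", ".sd", ".mol"} else "SMILES"
    format = format.upper()

    mols: list[Molecule] = []
    n_skipped = 0
    if format == "SMILES":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"record_{i + 1}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                n_skipped += 1
                logger.warning("skipping unparseable SMILES at line %d: %s", i + 1, smi)
                continue
            mols.append(Molecule(id=f"{path.stem}:{i + 1}", name=name,
                                 smiles=smi, mol=mol))
    elif format == "SDF":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                logger.warning("skipping unparseable SDF record %d", i + 1)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record_{i + 1}"
            mols.append(Molecule(id=f"{path.stem}:{i + 1}", name=name,
                                 smiles=Chem.MolToSmiles(mol), mol=mol))
    else:
        raise ValueError(f"unknown library format {format!r}")

    if n_skipped:
        logger.info("read %d molecules from %s (%d records skipped)",
                    len(mols), path, n_skipped)
    if not mols:
        raise ValueError(f"no valid records in {path}")
    return mols


def count_sugar_moieties(m: Molecule | Chem.Mol) -> int:
    """Count non-overlapping sugar rings (substituted pyranose/furanose).

    A match counts only if at least :data:`MIN_RING_OXYGEN_SUBSTITUENTS` of
    its ring carbons bear an exocyclic single-bonded oxygen, so glucose
    counts 1, sucrose 2 and an unsubstituted tetrahydropyran 0.
    """
    mol = m.mol if isinstance(m, Molecule) else m
    if mol is None:
        raise ValueError("invalid structure")
    used: set[int] = set()
    n = 0
    for smarts in SUGAR_RING_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            if used.intersection(match):
                continue
            n_oxy = 0
            for idx in match:
                atom = mol.GetAtomWithIdx(idx)
                if atom.GetAtomicNum() != 6:
                    continue
                for nbr in atom.GetNeighbors():
                    if nbr.GetIdx() in match:
                        continue
                    if nbr.GetAtomicNum() == 8:
                        n_oxy += 1
            if n_oxy >= MIN_RING_OXYGEN_SUBSTITUENTS:
                used.update(match)
                n += 1
    return n


def filter_food_database(mols: Sequence[Molecule], mw_max: float = 750.0,
                         sugar_max: int = 2) -> list[Molecule]:
    """Drop entries heavier than ``mw_max`` Da or with more than
    ``sugar_max`` sugar moieties (unlikely to be absorbed in the gut).

    Order-preserving; removal counts per criterion are logged.
    """
    kept: list[Molecule] = []
    n_heavy = n_sugar = 0
    for m in mols:
        if m.mw > mw_max:
            n_heavy += 1
            continue
        if m.n_sugar > sugar_max:
            n_sugar += 1
            continue
        kept.append(m)
    logger.info("filter_food_database: kept %d/%d (removed %d > %.0f Da, "
                "%d with > %d sugars)", len(kept), len(mols), n_heavy, mw_max,
                n_sugar, sugar_max)
    return kept


def _protonate(mol: Chem.Mol, atom_idx: int, delta: int) -> Chem.Mol | None:
    rw = Chem.RWMol(mol)
    atom = rw.GetAtomWithIdx(atom_idx)
    h = atom.GetTotalNumHs()
    if delta > 0:
        atom.SetFormalCharge(atom.GetFormalCharge() + 1)
        atom.SetNumExplicitHs(h + 1)
    else:
        if h < 1:
            return None
        atom.SetFormalCharge(atom.GetFormalCharge() - 1)
        atom.SetNumExplicitHs(h - 1)
    atom.SetNoImplicit(True)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:  # pragma: no cover - defensive
        return None


def enumerate_states(m: Molecule, pH: float = 7.4,
                     max_tautomers: int = 8) -> list[StateVariant]:
    """Enumerate tautomers and pH-7.4 protonation states of a molecule.

    Returns the input form plus rule-based protomers (aliphatic amines,
    amidines/guanidines protonated; carboxylic acids deprotonated) and
    RDKit-enumerated tautomers, deduplicated by canonical SMILES.  The rule
    table is a fixed-pH stand-in for a pKa predictor: each basic/acidic site
    is switched individually and, when several basic sites exist, jointly.
    """
    variants: dict[str, StateVariant] = {}

    def add(mol: Chem.Mol, label: str) -> None:
        smi = Chem.MolToSmiles(mol)
        if smi not in variants:
            variants[smi] = StateVariant(parent_id=m.id, variant_label=label,
                                         smiles=smi,
                                         net_charge=Chem.GetFormalCharge(mol),
                                         mol=mol)

    add(m.mol, "input")

    # single-site protonation/deprotonation
    basic_sites: list[int] = []
    for name, smarts, delta in PROTONATION_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in m.mol.GetSubstructMatches(patt):
            out = _protonate(m.mol, match[0], delta)
            if out is not None:
                add(out, name)
            if delta > 0:
                basic_sites.append(match[0])

    # jointly protonate all basic sites (polyamines at physiological pH)
    if len(basic_sites) > 1:
        mol = m.mol
        for idx in basic_sites:
            nxt = _protonate(mol, idx, +1)
            if nxt is None:
                break
            mol = nxt
        else:
            add(mol, "polycation")

    # tautomers of the input form
    enumerator = rdMolStandardize.TautomerEnumerator()
    enumerator.SetMaxTautomers(max_tautomers)
    try:
        for taut in enumerator.Enumerate(m.mol):
            add(taut, "tautomer")
    except Exception:  # pragma: no cover - RDKit edge cases
        logger.warning("tautomer enumeration failed for %s", m.id)

    return list(variants.values())


def compute_properties(m: Molecule) -> dict:
    """Descriptor record used for library characterization reports.

    HBD is counted as donor hydrogens (N-H + O-H), HBA as N + O counts;
    rotatable bonds follow the strict definition excluding terminal bonds.
    """
    mol = m.mol
    return {
        "id": m.id,
        "name": m.name,
        "mw": Descriptors.MolWt(mol),
        "alogp": Crippen.MolLogP(mol),
        "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "hbd": Lipinski.NHOHCount(mol),
        "hba": Lipinski.NOCount(mol),
    }


def dedup_libraries(*libraries: Iterable[Molecule]) -> list[Molecule]:
    """Merge libraries, removing canonical-SMILES duplicates.

    The first occurrence wins, keeping its source tag — compounds present in
    several source databases become a single entry.
    """
    seen: set[str] = set()
    merged: list[Molecule] = []
    for lib in libraries:
        for m in lib:
            if m.smiles in seen:
                continue
            seen.add(m.smiles)
            merged.append(m)
    return merged


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules (2D/3D as stored) to an SDF V2000 file."""
    writer = Chem.SDWriter(str(path))
    for m in mols:
        mol = Chem.Mol(m.mol)
        mol.SetProp("_Name", m.name)
        mol.SetProp("id", m.id)
        mol.SetProp("source", m.source)
        writer.write(mol)
    writer.close()
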