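"""Geometric filtering of docking poses.

Docking engines produce many poses per ligand; for an aminergic GPCR the
chemically meaningful ones form a salt bridge between a positively charged
ligand moiety and the carboxylate of the conserved aspartate (Asp114, in
Ballesteros-Weinstein numbering 3.32, for the dopamine D2 receptor).  This
module consumes poses (Vina PDBQT or SDF), detects that salt bridge and
hydrogen bonds to chosen residues (the serines 193/5.42 and 197/5.46 of the
orthosteric pocket), and keeps only poses passing the configured rules.
Docking itself is out of scope; poses are inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

__all__ = ["PoseAtom", "PosePacket", "InteractionReport", "HBond", "Receptor",
           "PoseFilterRules", "read_poses", "detect_salt_bridge",
           "detect_hbonds", "filter_poses", "BW_ALIASES"]

# Ballesteros-Weinstein aliases -> author residue numbering (D2R)
BW_ALIASES: dict[str, tuple[str, int]] = {
    "3.32": ("ASP", 114),
    "5.42": ("SER", 193),
    "5.46": ("SER", 197),
}

CARBOXYLATE_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_POLAR = {"N", "O"}
_PDBQT_CATION_CHARGE = 0.30  # partial-charge heuristic when no formal charges


@dataclass
class PoseAtom:
    element: str
    name: str
    coords: np.ndarray
    partial_charge: float | None = None
    formal_charge: int = 0


@dataclass
class PosePacket:
    """One docking pose: atoms with types/charges and an optional score."""

    atoms: list[PoseAtom]
    score: float | None = None
    index: int = 0
    ligand_name: str = ""

    @property
    def coords(self) -> np.ndarray:
        return np.vstack([a.coords for a in self.atoms])

    def cation_indices(self) -> list[int]:
        """Heavy atoms carrying positive charge (protonated N, guanidinium,
        aromatic oxocarbenium).  Falls back to a partial-charge heuristic
        and explicit-H counting for PDBQT input without formal charges."""
        out = []
        have_formal = any(a.formal_charge != 0 for a in self.atoms)
        for i, a in enumerate(self.atoms):
            if a.element == "H":
                continue
            if a.formal_charge > 0:
                out.append(i)
            elif not have_formal and a.element in _POLAR:
                n_h = sum(1 for b in self.atoms if b.element == "H"
                          and np.linalg.norm(b.coords - a.coords) < 1.2)
                q = a.partial_charge or 0.0
                if (a.element == "N" and n_h >= 2) or q >= _PDBQT_CATION_CHARGE:
                    out.append(i)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PosePacket":
        atoms = [PoseAtom(a.element, a.name,
                          np.asarray(rotation) @ a.coords + np.asarray(translation),
                          a.partial_charge, a.formal_charge)
                 for a in self.atoms]
        return PosePacket(atoms, self.score, self.index, self.ligand_name)


@dataclass
class HBond:
    donor: str
    acceptor: str
    distance: float
    angle: float | None = None


@dataclass
class InteractionReport:
    salt_bridge: bool
    salt_bridge_distance: float
    hbonds: list[HBond] = field(default_factory=list)
    accepted: bool = False


def _parse_pdbqt_atom(line: str) -> PoseAtom:
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    try:
        q = float(line[70:76])
    except (ValueError, IndexError):
        q = None
    atype = line[77:79].strip() if len(line) > 77 else ""
    element = atype[:1].upper() if atype else line[12:16].strip()[:1]
    if atype.upper() in {"CL", "BR"}:
        element = atype.capitalize()
    return PoseAtom(element=element, name=line[12:16].strip(),
                    coords=np.array([x, y, z]), partial_charge=q)


def read_poses(path: str | Path, format: str | None = None) -> list[PosePacket]:
    """Read docking poses from a multi-MODEL PDBQT or an SDF file.

    One packet per MODEL/record, preserving file order; Vina scores are
    parsed from ``REMARK VINA RESULT`` lines or SDF properties when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "SDF" if path.suffix.lower() in {".sdf", ".sd"} else "PDBQT"
    format = format.upper()

    packets: list[PosePacket] = []
    if format == "PDBQT":
        atoms: list[PoseAtom] = []
        score: float | None = None
        in_model = False
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                atoms, score = [], None
            elif rec == "ENDMDL":
                if not atoms:
                    raise ValueError(f"{path}:{lineno}: MODEL block without atoms")
                packets.append(PosePacket(atoms, score, len(packets), path.stem))
                in_model = False
            elif line.startswith("REMARK VINA RESULT:"):
                score = float(line.split(":", 1)[1].split()[0])
            elif rec in {"ATOM", "HETATM"}:
                try:
                    atoms.append(_parse_pdbqt_atom(line))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed atom line") from exc
        if atoms and not in_model and not packets:
            packets.append(PosePacket(atoms, score, 0, path.stem))
        elif atoms and in_model:
            raise ValueError(f"{path}: unterminated MODEL block")
    elif format == "SDF":
        from rdkit import Chem

        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"{path}: unparseable SDF record {i + 1}")
            conf = mol.GetConformer()
            atoms = [PoseAtom(element=a.GetSymbol(), name=f"{a.GetSymbol()}{a.GetIdx()}",
                              coords=np.array(conf.GetAtomPosition(a.GetIdx())),
                              formal_charge=a.GetFormalCharge())
                     for a in mol.GetAtoms()]
            score = None
            for prop in ("vina_score", "score", "minimizedAffinity", "docking_score"):
                if mol.HasProp(prop):
                    score = float(mol.GetProp(prop))
                    break
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem
            packets.append(PosePacket(atoms, score, i, name))
    else:
        raise ValueError(f"unknown pose format {format!r}")
    return packets


class Receptor:
    """Thin wrapper over a Bio.PDB structure with residue lookup."""

    def __init__(self, structure):
        self.structure = structure

    @classmethod
    def from_pdb(cls, path: str | Path) -> "Receptor":
        parser = PDBParser(QUIET=True)
        return cls(parser.get_structure("receptor", str(path)))

    def residue(self, spec: str):
        """Find a residue by ``"ASP 114"`` or a Ballesteros-Weinstein alias
        like ``"3.32"``."""
        if spec in BW_ALIASES:
            resname, resseq = BW_ALIASES[spec]
        else:
            parts = spec.split()
            resname, resseq = parts[0].upper(), int(parts[1])
        for model in self.structure:
            for chain in model:
                for res in chain:
                    if res.get_resname() == resname and res.get_id()[1] == resseq:
                        return res
        raise KeyError(f"residue {resname} {resseq} not found in receptor")


def _as_receptor(receptor) -> Receptor:
    if isinstance(receptor, Receptor):
        return receptor
    if isinstance(receptor, (str, Path)):
        return Receptor.from_pdb(receptor)
    return Receptor(receptor)


def detect_salt_bridge(pose: PosePacket, receptor, residue_spec: str = "ASP 114",
                       d_max: float = 4.0) -> tuple[bool, float]:
    """Is a cationic ligand heavy atom within ``d_max`` Å of the residue's
    carboxylate oxygens?  Returns (flag, minimum distance); a ligand with no
    cationic atom reports (False, inf)."""
    rec = _as_receptor(receptor)
    res = rec.residue(residue_spec)
    oxy_names = CARBOXYLATE_ATOMS.get(res.get_resname(), ("OD1", "OD2"))
    oxy = [np.array(res[nm].get_coord(), dtype=float)
           for nm in oxy_names if nm in res]
    if not oxy:
        raise KeyError(f"residue {residue_spec} has no carboxylate oxygens")
    cations = pose.cation_indices()
    if not cations:
        return False, math.inf
    coords = pose.coords
    dmin = min(float(np.linalg.norm(coords[i] - o))
               for i in cations for o in oxy)
    return dmin <= d_max, dmin


def detect_hbonds(pose: PosePacket, receptor, residues: list[str],
                  d_max: float = 3.5, angle_min: float = 120.0) -> list[HBond]:
    """Hydrogen bonds between ligand N/O atoms and side-chain N/O atoms of
    the named residues.

    Heavy-atom donor-acceptor distance must not exceed ``d_max``; when the
    ligand has explicit hydrogens on the donor, the D-H...A angle must reach
    ``angle_min`` degrees (distance-only fallback otherwise).
    """
    rec = _as_receptor(receptor)
    backbone = {"N", "C", "O", "CA", "OXT"}
    bonds: list[HBond] = []
    lig_heavy = [(i, a) for i, a in enumerate(pose.atoms) if a.element in _POLAR]
    lig_h = [a for a in pose.atoms if a.element == "H"]
    for spec in residues:
        res = rec.residue(spec)
        for atom in res:
            if atom.element not in _POLAR or atom.get_name() in backbone:
                continue
            acc = np.array(atom.get_coord(), dtype=float)
            for i, la in lig_heavy:
                d = float(np.linalg.norm(la.coords - acc))
                if d > d_max:
                    continue
                attached_h = [h for h in lig_h
                              if np.linalg.norm(h.coords - la.coords) < 1.2]
                angle = None
                if attached_h:
                    best = None
                    for h in attached_h:
                        v1 = la.coords - h.coords
                        v2 = acc - h.coords
                        cosang = float(np.dot(v1, v2)
                                       / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                        a_deg = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                        if best is None or a_deg > best:
                            best = a_deg
                    angle = best
                    if angle < angle_min:
                        continue
                bonds.append(HBond(donor=f"ligand:{la.name or i}",
                                   acceptor=f"{res.get_resname()}{res.get_id()[1]}:{atom.get_name()}",
                                   distance=d, angle=angle))
    return bonds


@dataclass
class PoseFilterRules:
    salt_bridge_residue: str = "ASP 114"
    salt_bridge_dmax: float = 4.0
    hbond_residues: list[str] = field(default_factory=list)
    require_hbond: bool = False  # optional rule: >=1 H-bond to the listed residues
    hbond_dmax: float = 3.5
    hbond_angle_min: float = 120.0


def filter_poses(poses: list[PosePacket], receptor,
                 rules: PoseFilterRules | None = None,
                 ) -> tuple[list[PosePacket], list[InteractionReport]]:
    """Apply the interaction rules; the salt bridge is mandatory.

    Accepted poses are returned ranked by docking score (ascending — more
    negative is better; unscored poses keep input order at the end), with
    the per-pose interaction reports in input order.
    """
    rules = rules or PoseFilterRules()
    rec = _as_receptor(receptor)
    reports: list[InteractionReport] = []
    accepted: list[tuple[int, PosePacket]] = []
    for k, pose in enumerate(poses):
        sb, dist = detect_salt_bridge(pose, rec, rules.salt_bridge_residue,
                                      rules.salt_bridge_dmax)
        hbonds = detect_hbonds(pose, rec, rules.hbond_residues,
                               rules.hbond_dmax, rules.hbond_angle_min) \
            if rules.hbond_residues else []
        ok = sb and (not rules.require_hbond or len(hbonds) > 0)
        reports.append(InteractionReport(salt_bridge=sb, salt_bridge_distance=dist,
                                         hbonds=hbonds, accepted=ok))
        if ok:
            accepted.append((k, pose))
    accepted.sort(key=lambda kp: (kp[1].score if kp[1].score is not None
                                  else math.inf, kp[0]))
    return [p for _, p in accepted], reports
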