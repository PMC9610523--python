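"""Reading and writing chemical structure files.

Supported dialects: SDF (V2000, multi-record), MOL, MOL2 (@<TRIPOS>
sections), PDB/ENT (ATOM/HETATM/CONECT/MODEL) and PDBQT (AutoDock Vina
MODEL blocks with ``REMARK VINA RESULT`` scores).  Gzip-wrapped files are
accepted via a ``.gz`` suffix.  SDF/MOL records are parsed with RDKit;
MOL2 and the PDB family use a column parser because no installed library
reads PDBQT and the two share a grammar.

All coordinates are taken as ångströms in a single shared frame; no unit
conversion is ever applied.  PDB-family records lacking CONECT get their
bonds perceived from interatomic distances (sum of covalent radii plus a
0.45 Å tolerance).
"""

from __future__ import annotations

import enum
import gzip
import io as _stdio
import os
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from ._elements import (
    BOND_TOLERANCE,
    COVALENT_RADII,
    element_from_autodock,
    normalise_element,
)
from .errors import CapacityError, ParseError, UnsupportedFormatError
from .graph import AtomNode, Bond, BondOrder, MoleculeGraph, normalise_aromatic_rings


class Format(enum.Enum):
    SDF = "sdf"
    MOL = "mol"
    MOL2 = "mol2"
    PDB = "pdb"
    PDBQT = "pdbqt"


class Program(enum.Enum):
    """Docking programs with recognised score dialects."""

    VINA = "vina"
    FRED = "fred"
    HYBRID = "hybrid"


#: SDF data-tag names tried in order when extracting FRED/HYBRID scores.
DEFAULT_SCORE_TAGS: tuple[str, ...] = (
    "FRED Chemgauss4 score",
    "HYBRID Chemgauss4 score",
    "Chemgauss4 score",
    "Chemgauss4",
    "CHEMGAUSS4",
    "docking_score",
    "Docking score",
    "Score",
    "SCORE",
    "score",
)

_EXTENSION_MAP = {
    ".sdf": Format.SDF,
    ".sd": Format.SDF,
    ".mol": Format.MOL,
    ".mol2": Format.MOL2,
    ".pdb": Format.PDB,
    ".ent": Format.PDB,
    ".pdbqt": Format.PDBQT,
}


def detect_format(filename: Union[str, os.PathLike]) -> Format:
    """Map a filename extension (case-insensitive) to a :class:`Format`.

    A trailing ``.gz`` is ignored; ``.ent`` maps to PDB, ``.sd`` to SDF.
    """
    name = str(filename)
    if name.lower().endswith(".gz"):
        name = name[:-3]
    ext = Path(name).suffix.lower()
    if not ext:
        raise UnsupportedFormatError(f"no file extension on {filename!r}")
    try:
        return _EXTENSION_MAP[ext]
    except KeyError:
        raise UnsupportedFormatError(
            f"unsupported extension {ext!r} (supported: "
            + ", ".join(sorted(e.lstrip('.') for e in _EXTENSION_MAP))
            + ")"
        ) from None


@dataclass
class ScoreRecord:
    """Docking score for one pose; ``score`` is None when absent."""

    pose_index: int
    score: Optional[float]
    source_tag: str = ""


@dataclass
class StructureFile:
    """A structure file split into raw per-molecule record blocks."""

    format: Format
    records: list[str]
    path: Optional[str] = None

    @classmethod
    def from_path(cls, path: Union[str, os.PathLike], format: Optional[Format] = None) -> "StructureFile":
        fmt = format or detect_format(path)
        p = str(path)
        if p.lower().endswith(".gz"):
            with gzip.open(p, "rt") as fh:
                text = fh.read()
        else:
            with open(p, "r") as fh:
                text = fh.read()
        return cls.from_text(text, fmt, path=p)

    @classmethod
    def from_text(cls, text: str, format: Format, path: Optional[str] = None) -> "StructureFile":
        records = _split_records(text, format)
        if not records:
            raise ParseError(f"no molecule records found in {path or '<text>'}")
        return cls(format=format, records=records, path=path)


# -- record splitting ----------------------------------------------------


def _split_records(text: str, fmt: Format) -> list[str]:
    if fmt in (Format.SDF,):
        # line-based split: an empty first line is a valid (blank) title
        records, current = [], []
        for line in text.split("\n"):
            if line.strip() == "$$$$":
                records.append("\n".join(current) + "\n")
                current = []
            else:
                current.append(line)
        if any(l.strip() for l in current):
            records.append("\n".join(current) + "\n")
        return [r for r in records if r.strip()]
    if fmt is Format.MOL:
        return [text] if text.strip() else []
    if fmt is Format.MOL2:
        chunks = re.split(r"(?=^@<TRIPOS>MOLECULE\s*$)", text, flags=re.M)
        return [c for c in chunks if c.strip().startswith("@<TRIPOS>MOLECULE")]
    if fmt in (Format.PDB, Format.PDBQT):
        if re.search(r"^MODEL", text, flags=re.M):
            blocks = re.findall(r"^MODEL[^\n]*\n(.*?)^ENDMDL", text, flags=re.M | re.S)
            if not blocks:
                raise ParseError("MODEL without matching ENDMDL")
            return blocks
        return [text] if text.strip() else []
    raise UnsupportedFormatError(str(fmt))


# -- per-record parsers --------------------------------------------------

_RDKIT_BOND_MAP = {
    "SINGLE": BondOrder.SINGLE,
    "DOUBLE": BondOrder.DOUBLE,
    "TRIPLE": BondOrder.TRIPLE,
    "AROMATIC": BondOrder.AROMATIC,
}


def _parse_molblock(block: str, index: int) -> MoleculeGraph:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    lines = block.split("\n")
    if len(lines) >= 4 and "V3000" in lines[3]:
        raise ParseError("V3000 molblocks are not supported (use V2000)", index)
    mol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
    if mol is None:
        raise ParseError("malformed molblock (RDKit rejected it)", index)
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    atoms = []
    for i, atom in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i) if conf is not None else None
        xyz = (pos.x, pos.y, pos.z) if pos is not None else (0.0, 0.0, 0.0)
        atoms.append(AtomNode(normalise_element(atom.GetSymbol()), xyz, i))
    bonds = [
        Bond(
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _RDKIT_BOND_MAP.get(str(b.GetBondType()), BondOrder.SINGLE),
        )
        for b in mol.GetBonds()
    ]
    name = lines[0].strip() if lines else ""
    props = _parse_sdf_tags(block)
    return MoleculeGraph(atoms, bonds, name=name, properties=props)


_TAG_RE = re.compile(r"^>\s*<([^>]+)>")


def _parse_sdf_tags(block: str) -> dict[str, str]:
    props: dict[str, str] = {}
    lines = block.split("\n")
    i = 0
    while i < len(lines):
        m = _TAG_RE.match(lines[i])
        if m:
            tag = m.group(1).strip()
            value_lines = []
            i += 1
            while i < len(lines) and lines[i].strip() != "":
                value_lines.append(lines[i])
                i += 1
            props[tag] = "\n".join(value_lines).strip()
        else:
            i += 1
    return props


_MOL2_BOND_MAP = {
    "1": BondOrder.SINGLE,
    "2": BondOrder.DOUBLE,
    "3": BondOrder.TRIPLE,
    "am": BondOrder.SINGLE,
    "ar": BondOrder.AROMATIC,
    "du": BondOrder.SINGLE,
    "un": BondOrder.SINGLE,
}


def _parse_mol2(block: str, index: int) -> MoleculeGraph:
    sections: dict[str, list[str]] = {}
    current = None
    for line in block.splitlines():
        if line.startswith("@<TRIPOS>"):
            current = line[9:].strip().upper()
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    if "ATOM" not in sections:
        raise ParseError("MOL2 record lacks an @<TRIPOS>ATOM section", index)
    name = ""
    mol_lines = [l for l in sections.get("MOLECULE", []) if l.strip()]
    if mol_lines:
        name = mol_lines[0].strip()
    atoms: list[AtomNode] = []
    id_map: dict[int, int] = {}
    for line in sections["ATOM"]:
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 6:
            raise ParseError(f"short MOL2 atom line: {line!r}", index)
        try:
            aid = int(f[0])
            xyz = (float(f[2]), float(f[3]), float(f[4]))
        except ValueError as exc:
            raise ParseError(f"bad MOL2 atom line: {line!r}", index) from exc
        elem = normalise_element(f[5].split(".")[0])
        id_map[aid] = len(atoms)
        atoms.append(AtomNode(elem, xyz, len(atoms), name=f[1]))
    bonds: list[Bond] = []
    for line in sections.get("BOND", []):
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 4:
            raise ParseError(f"short MOL2 bond line: {line!r}", index)
        try:
            i, j = id_map[int(f[1])], id_map[int(f[2])]
        except (ValueError, KeyError) as exc:
            raise ParseError(f"bad MOL2 bond line: {line!r}", index) from exc
        order = _MOL2_BOND_MAP.get(f[3].lower(), BondOrder.SINGLE)
        if order == BondOrder.SINGLE and f[3].lower() == "nc":
            continue  # "not connected"
        bonds.append(Bond(i, j, order))
    return MoleculeGraph(atoms, bonds, name=name)


def _pdb_element(line: str, fmt: Format) -> str:
    if fmt is Format.PDBQT:
        ad_type = line[77:79].strip() if len(line) > 77 else ""
        if ad_type:
            return element_from_autodock(ad_type)
    if len(line) >= 78:
        sym = line[76:78].strip()
        if sym and sym.isalpha():
            return normalise_element(sym)
    # fall back to the atom name, dropping leading digits/greek markers
    atname = line[12:16].strip()
    alpha = "".join(ch for ch in atname if ch.isalpha())
    if not alpha:
        raise ParseError(f"cannot infer element from line: {line!r}")
    # Names like CA/CD/NE/HG are ambiguous between a protein atom and an
    # element symbol; resolve those to the single-letter element.
    ambiguous = ("Ca", "Cd", "Co", "Cs", "Ne", "Ho", "Os", "Hg", "Pb", "Sg", "Cg", "Nd")
    if len(alpha) >= 2 and alpha[:2].capitalize() in COVALENT_RADII and alpha[:2].capitalize() not in ambiguous:
        return alpha[:2].capitalize()
    return alpha[0].upper()


def _parse_pdb(block: str, index: int, fmt: Format) -> MoleculeGraph:
    atoms: list[AtomNode] = []
    serial_map: dict[int, int] = {}
    conect: list[tuple[int, int]] = []
    for line in block.splitlines():
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            try:
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError as exc:
                raise ParseError(f"bad coordinates in line: {line!r}", index) from exc
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = len(atoms) + 1
            try:
                res_num = int(line[22:26])
            except ValueError:
                res_num = 0
            atoms.append(
                AtomNode(
                    _pdb_element(line, fmt),
                    xyz,
                    len(atoms),
                    name=line[12:16].strip(),
                    res_name=line[17:20].strip(),
                    res_num=res_num,
                    chain=line[21:22].strip(),
                )
            )
            serial_map[serial] = len(atoms) - 1
        elif rec == "CONECT":
            fields = line[6:].split()
            if fields:
                try:
                    src = int(fields[0])
                    for dst in fields[1:]:
                        conect.append((src, int(dst)))
                except ValueError:
                    continue
    if not atoms:
        raise ParseError("no ATOM/HETATM records", index)
    bonds: list[Bond] = []
    seen: set[tuple[int, int]] = set()
    for s, d in conect:
        if s in serial_map and d in serial_map:
            i, j = serial_map[s], serial_map[d]
            if i != j:
                key = (min(i, j), max(i, j))
                if key not in seen:
                    seen.add(key)
                    bonds.append(Bond(*key))
    mol = MoleculeGraph(atoms, bonds)
    if not bonds:
        mol = perceive_bonds(mol)
    return mol


def perceive_bonds(mol: MoleculeGraph) -> MoleculeGraph:
    """Perceive covalent bonds from interatomic distances.

    Two atoms are bonded when their distance does not exceed the sum of
    their covalent radii plus 0.45 Å.  Bonds are emitted as SINGLE; order
    information is not recoverable from coordinates alone.
    """
    coords = mol.coords
    n = len(mol)
    if n < 2:
        return MoleculeGraph(mol.atoms, [], mol.name, mol.properties)
    radii = np.array([COVALENT_RADII.get(a.element, 0.77) for a in mol.atoms])
    max_cut = 2 * radii.max() + BOND_TOLERANCE
    tree = cKDTree(coords)
    bonds = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        cutoff = radii[i] + radii[j] + BOND_TOLERANCE
        if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
            bonds.append(Bond(i, j))
    return MoleculeGraph(mol.atoms, bonds, mol.name, mol.properties)


# -- public reading API --------------------------------------------------

Source = Union[str, os.PathLike, StructureFile]


def _as_structure_file(source: Source, format: Optional[Format] = None) -> StructureFile:
    if isinstance(source, StructureFile):
        return source
    return StructureFile.from_path(source, format=format)


def read_structures(source: Source, format: Optional[Format] = None) -> list[MoleculeGraph]:
    """Parse every record of a structure file into a :class:`MoleculeGraph`.

    Records come back in file order with hydrogens retained; Kekulé rings
    are normalised to aromatic bond classes so mixed-format comparisons
    agree on signatures.
    """
    sf = _as_structure_file(source, format)
    mols: list[MoleculeGraph] = []
    for idx, record in enumerate(sf.records):
        if sf.format in (Format.SDF, Format.MOL):
            mol = _parse_molblock(record, idx)
        elif sf.format is Format.MOL2:
            mol = _parse_mol2(record, idx)
        else:
            mol = _parse_pdb(record, idx, sf.format)
        mols.append(normalise_aromatic_rings(mol))
    return mols


_VINA_RESULT_RE = re.compile(r"REMARK VINA RESULT:\s*(-?\d+(?:\.\d+)?)")


def extract_scores(
    source: Source,
    program: Program,
    format: Optional[Format] = None,
    score_tags: Sequence[str] = DEFAULT_SCORE_TAGS,
) -> list[ScoreRecord]:
    """Extract per-pose docking scores.

    Vina poses carry a ``REMARK VINA RESULT: affinity rmsd_lb rmsd_ub``
    line per MODEL (the first numeric field is the affinity); FRED and
    HYBRID store a Chemgauss score in an SDF data tag, whose exact name
    varies by release, so a configurable tag list is tried in order.
    Missing scores are recorded as ``None`` with a warning; clustering
    then falls back to pose order for representative selection.
    """
    sf = _as_structure_file(source, format)
    if program is Program.VINA and sf.format is not Format.PDBQT:
        raise UnsupportedFormatError("Vina scores are read from PDBQT files")
    if program in (Program.FRED, Program.HYBRID) and sf.format not in (Format.SDF, Format.MOL):
        raise UnsupportedFormatError(f"{program.value} scores are read from SDF files")
    records: list[ScoreRecord] = []
    for idx, block in enumerate(sf.records):
        score: Optional[float] = None
        tag = ""
        if program is Program.VINA:
            m = _VINA_RESULT_RE.search(block)
            if m:
                score = float(m.group(1))
                tag = "REMARK VINA RESULT"
        else:
            props = _parse_sdf_tags(block)
            for candidate in score_tags:
                if candidate in props:
                    try:
                        score = float(props[candidate].split()[0])
                        tag = candidate
                        break
                    except (ValueError, IndexError):
                        continue
        if score is not None and not np.isfinite(score):
            score = None
        if score is None:
            warnings.warn(
                f"no {program.value} score found for pose {idx}", stacklevel=2
            )
        records.append(ScoreRecord(idx, score, tag))
    return records


# -- writing -------------------------------------------------------------

_BOND_TO_SDF = {
    BondOrder.SINGLE: 1,
    BondOrder.DOUBLE: 2,
    BondOrder.TRIPLE: 3,
    BondOrder.AROMATIC: 4,
}


def _molblock(mol: MoleculeGraph) -> str:
    if len(mol) > 999:
        raise CapacityError(f"V2000 holds at most 999 atoms (got {len(mol)})")
    out = _stdio.StringIO()
    out.write(f"{mol.name}\n  posekit\n\n")
    out.write(f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000\n")
    for a in mol.atoms:
        x, y, z = a.position
        out.write(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0\n")
    for b in mol.bonds:
        out.write(f"{b.i + 1:3d}{b.j + 1:3d}{_BOND_TO_SDF[b.order]:3d}  0\n")
    out.write("M  END\n")
    return out.getvalue()


def write_structures(mols: Sequence[MoleculeGraph], format: Format = Format.SDF) -> str:
    """Serialise molecules to SDF (V2000) or PDB text.

    SDF round-trips elements, bonds and coordinates to the format's four
    decimal places; data tags in ``properties`` are written after each
    molblock.
    """
    if format is Format.SDF:
        parts = []
        for mol in mols:
            block = _molblock(mol)
            for tag, value in mol.properties.items():
                block += f"> <{tag}>\n{value}\n\n"
            parts.append(block + "$$$$\n")
        return "".join(parts)
    if format is Format.PDB:
        out = _stdio.StringIO()
        multi = len(mols) > 1
        for m_idx, mol in enumerate(mols):
            if multi:
                out.write(f"MODEL {m_idx + 1:>8d}\n")
            for i, a in enumerate(mol.atoms):
                x, y, z = a.position
                name = a.name or a.element
                out.write(
                    f"HETATM{i + 1:5d} {name:<4.4s} {a.res_name or 'LIG':<3.3s} "
                    f"{a.chain or 'A':1.1s}{a.res_num or 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2.2s}\n"
                )
            for b in mol.bonds:
                out.write(f"CONECT{b.i + 1:5d}{b.j + 1:5d}\n")
            out.write("ENDMDL\n" if multi else "END\n")
        return out.getvalue()
    raise UnsupportedFormatError(f"writing {format.value} is not supported")


def write_vina_pdbqt(
    mols: Sequence[MoleculeGraph], scores: Optional[Sequence[float]] = None
) -> str:
    """Serialise poses as a Vina-style multi-MODEL PDBQT with scores."""
    out = _stdio.StringIO()
    for m_idx, mol in enumerate(mols):
        out.write(f"MODEL {m_idx + 1}\n")
        if scores is not None:
            out.write(f"REMARK VINA RESULT:    {scores[m_idx]:8.3f}      0.000      0.000\n")
        for i, a in enumerate(mol.atoms):
            x, y, z = a.position
            ad_type = {"Cl": "Cl", "Br": "Br"}.get(a.element, a.element.upper())
            name = a.name or f"{a.element}{i + 1}"
            out.write(
                f"ATOM  {i + 1:5d} {name:<4.4s} LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00    +0.000 {ad_type:<2.2s}\n"
            )
        out.write("ENDMDL\n")
    return out.getvalue()
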