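"""Read and write PDB-format structures into a uniform coordinate model.

The supported dialect is the fixed-column PDB v3 subset needed for
glycoprotein analysis: ATOM, HETATM, TER, CONECT and MODEL/ENDMDL records.
Coordinates are stored in angstroms.  Residue identity follows the author
numbering convention (chain id, residue number, insertion code), which is
how glycosylation sites are referred to in the literature (e.g. Asn-60).

Alternate locations are resolved to a single conformer by keeping the
highest-occupancy altloc (ties broken by file order).  CONECT records are
retained as a serial-number bond-hint table; covalent protein-glycan
linkages can be recovered from either these hints or interatomic distances
(see :mod:`glycodelta.glycan_annotation`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueKind",
    "ChainModel",
    "StructureModel",
    "PDBParseError",
    "parse_structure",
    "parse_models",
    "chain_sequence",
    "write_structure",
    "structure_to_pdb_text",
]


class PDBParseError(ValueError):
    """Raised for malformed PDB input; carries the offending line number."""


class ResidueKind(str, Enum):
    AMINO_ACID = "amino_acid"
    SACCHARIDE = "saccharide"
    OTHER = "other"


#: Standard 20 amino acids, three- to one-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Common nonstandard amino-acid codes treated as polymer residues.  All of
#: them map to 'X' in one-letter sequences (including MSE): the pair matcher
#: requires strict identity and 'X' only matches 'X'.
NONSTANDARD_AMINO_ACIDS = frozenset({
    "MSE", "SEC", "PYL", "HYP", "SEP", "TPO", "PTR", "CSO", "MLY", "KCX",
})


@dataclass
class Atom:
    """A single atom: PDB atom name, element symbol, position in angstrom."""

    name: str
    element: str
    xyz: np.ndarray
    serial: int = 0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    """A residue with author numbering and a classified kind."""

    name: str
    number: int
    icode: str = ""
    kind: ResidueKind = ResidueKind.AMINO_ACID
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class ChainModel:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return chain_sequence(self)

    def amino_acid_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind is ResidueKind.AMINO_ACID]

    def residue(self, number: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None


@dataclass
class StructureModel:
    """A parsed structure: chains of residues plus CONECT bond hints.

    ``conect`` holds unordered atom-serial pairs exactly as read from (or
    destined for) CONECT records.
    """

    id: str = ""
    chains: list[ChainModel] = field(default_factory=list)
    conect: set[frozenset[int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("chain ids must be unique")

    def chain(self, chain_id: str) -> Optional[ChainModel]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def atoms(self) -> Iterator[tuple[ChainModel, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def atom_by_serial(self, serial: int) -> Optional[tuple[ChainModel, Residue, Atom]]:
        for c, r, a in self.atoms():
            if a.serial == serial:
                return c, r, a
        return None


def chain_sequence(chain: ChainModel) -> str:
    """One-letter sequence over the amino-acid residues of a chain.

    Saccharide and other het residues are excluded; nonstandard amino
    acids (MSE and friends) appear as ``'X'``.
    """
    return "".join(r.one_letter for r in chain.residues
                   if r.kind is ResidueKind.AMINO_ACID)


def _default_kind(record: str, resname: str) -> ResidueKind:
    if resname in THREE_TO_ONE or resname in NONSTANDARD_AMINO_ACIDS:
        return ResidueKind.AMINO_ACID
    if record == "ATOM":
        return ResidueKind.AMINO_ACID
    return ResidueKind.OTHER


def _parse_coord_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        resname = line[17:20].strip()
        chain_id = line[21:22].strip()
        resseq = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed coordinate record at line {lineno}: {line!r}") from exc
    occ_field = line[54:60].strip()
    occupancy = float(occ_field) if occ_field else 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1]  # crude fallback for minimal fixtures
    if not name:
        raise PDBParseError(f"empty atom name at line {lineno}")
    return serial, name, altloc, resname, chain_id, resseq, icode, (x, y, z), occupancy, element


def _read_text(source: Union[str, Path]) -> tuple[str, str]:
    """Return (text, label).  Accepts a path or raw PDB text."""
    if isinstance(source, Path):
        return source.read_text(), source.stem
    if isinstance(source, str) and source and "\n" not in source \
            and Path(source).is_file():
        p = Path(source)
        return p.read_text(), p.stem
    return source, ""


def _parse_model_records(lines, start_lineno, model_id):
    """Build a StructureModel from one model's worth of coordinate lines."""
    chains: dict[str, ChainModel] = {}
    # (chain, resseq, icode) -> residue; per-atom best altloc occupancy
    best_occ: dict[tuple, float] = {}
    conect: set[frozenset[int]] = set()
    n_coord = 0
    for lineno, line in lines:
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            (serial, name, altloc, resname, chain_id, resseq, icode,
             xyz, occ, element) = _parse_coord_line(line, lineno)
            n_coord += 1
            chain = chains.setdefault(chain_id, ChainModel(chain_id=chain_id))
            res = None
            if chain.residues:
                last = chain.residues[-1]
                if last.number == resseq and last.icode == icode and last.name == resname:
                    res = last
            if res is None:
                res = chain.residue(resseq, icode)
            if res is None:
                res = Residue(name=resname, number=resseq, icode=icode,
                              kind=_default_kind(rec, resname))
                chain.residues.append(res)
            atom_key = (chain_id, resseq, icode, name)
            existing = res.atom(name)
            if existing is not None:
                # altloc duplicate: keep the higher occupancy, first wins ties
                if altloc and occ > best_occ.get(atom_key, -1.0):
                    existing.xyz = np.asarray(xyz, dtype=float)
                    existing.element = element
                    existing.serial = serial
                    best_occ[atom_key] = occ
                continue
            best_occ[atom_key] = occ
            res.atoms.append(Atom(name=name, element=element, xyz=np.asarray(xyz), serial=serial))
        elif rec == "CONECT":
            fields = line[6:].split()
            try:
                serials = [int(f) for f in fields]
            except ValueError as exc:
                raise PDBParseError(f"malformed CONECT at line {lineno}: {line!r}") from exc
            if serials:
                root = serials[0]
                for other in serials[1:]:
                    conect.add(frozenset((root, other)))
    if n_coord == 0:
        raise PDBParseError("no ATOM/HETATM records found")
    return StructureModel(id=model_id, chains=list(chains.values()), conect=conect)


def parse_models(source: Union[str, Path], id: str = "") -> list[StructureModel]:
    """Parse every MODEL of a (possibly multi-model) PDB file.

    Files without MODEL records yield a single model.  CONECT records,
    which conventionally trail the last ENDMDL, are shared by all models.
    """
    text, label = _read_text(source)
    if not text.strip():
        raise PDBParseError("empty PDB input")
    entry_id = id or label or "structure"

    groups: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    trailing_conect: list[tuple[int, str]] = []
    in_model = False
    saw_model = False
    for lineno, line in enumerate(io.StringIO(text), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = []
        elif rec == "ENDMDL":
            in_model = False
            groups.append(current)
        elif rec in ("ATOM", "HETATM"):
            if saw_model and not in_model:
                continue  # stray coordinates between models
            current.append((lineno, line))
        elif rec == "CONECT":
            trailing_conect.append((lineno, line))
    if not saw_model:
        groups = [current]
    elif in_model:  # MODEL without ENDMDL
        groups.append(current)
    groups = [g for g in groups if g]
    if not groups:
        raise PDBParseError("no coordinate records found")

    models = []
    for i, g in enumerate(groups):
        mid = entry_id if len(groups) == 1 else f"{entry_id}:{i + 1}"
        models.append(_parse_model_records(g + trailing_conect, 0, mid))
    return models


def parse_structure(source: Union[str, Path], format: str = "pdb") -> StructureModel:
    """Parse a PDB file (path or text) into a :class:`StructureModel`.

    Multi-model files yield the first model; use :func:`parse_models` or
    the trajectory loader for frame-by-frame access.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format: {format!r}")
    return parse_models(source)[0]


# --------------------------------------------------------------------------
# writing

def _format_atom_line(record: str, serial: int, atom: Atom, res: Residue,
                      chain_id: str) -> str:
    name = atom.name
    # PDB name column convention: 1-char element names start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field} {res.name:>3s} {chain_id:1s}"
        f"{res.number:>4d}{res.icode or ' '}   "
        f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
    )


def structure_to_pdb_text(model: StructureModel) -> str:
    """Serialize a model to PDB text; assigns fresh serial numbers.

    Amino-acid residues are written as ATOM records, saccharides and other
    het groups as HETATM.  CONECT hints are re-emitted with the new
    serials.  The input model's atom serials are updated in place so that
    bond hints stay resolvable on the written file.
    """
    if not model.chains or all(not c.residues for c in model.chains):
        raise ValueError("refusing to write a structure with no residues")
    old_to_new: dict[int, int] = {}
    lines = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            record = "ATOM" if res.kind is ResidueKind.AMINO_ACID else "HETATM"
            for atom in res.atoms:
                serial += 1
                if atom.serial:
                    old_to_new[atom.serial] = serial
                atom.serial = serial
                lines.append(_format_atom_line(record, serial, atom, res, chain.chain_id))
        if chain.residues:
            last = chain.residues[-1]
            serial += 1
            lines.append(f"TER   {serial:>5d}      {last.name:>3s} "
                         f"{chain.chain_id:1s}{last.number:>4d}{last.icode or ' '}")
    new_conect = set()
    for pair in model.conect:
        mapped = frozenset(old_to_new.get(s, s) for s in pair)
        if len(mapped) == 2:
            new_conect.add(mapped)
    model.conect = new_conect
    for pair in sorted(tuple(sorted(p)) for p in new_conect):
        lines.append(f"CONECT{pair[0]:>5d}{pair[1]:>5d}")
        lines.append(f"CONECT{pair[1]:>5d}{pair[0]:>5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(model: StructureModel, path: Union[str, Path]) -> Path:
    """Write a model as PDB; the emitted text reparses to an equal model."""
    path = Path(path)
    path.write_text(structure_to_pdb_text(model))
    return path


def models_to_multimodel_pdb(models: list[StructureModel]) -> str:
    """Serialize frames as a MODEL/ENDMDL multi-model PDB (trajectories)."""
    if not models:
        raise ValueError("no models to write")
    out = []
    for i, m in enumerate(models, start=1):
        out.append(f"MODEL     {i:>4d}")
        body = structure_to_pdb_text(m).splitlines()
        out.extend(ln for ln in body if not (ln.startswith("END") or ln.startswith("CONECT")))
        out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"
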