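"""PDB structure I/O and pharmacophore atom typing.

Structures are read from fixed-width PDB files (wwPDB v3.3 ATOM/HETATM
records).  Loading normalises the model: hydrogens and waters are dropped,
alternate locations are resolved to a single atom per name, and hetero
residues are optionally routed to a ligand list.  Heavy atoms are typed
into the 8-class pharmacophore vocabulary via a shipped, swappable table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "PHARMACOPHORE_CLASSES",
    "Atom",
    "Residue",
    "Structure",
    "PharmacophoreTable",
    "PDBFormatError",
    "EmptyStructureError",
    "TypingError",
    "read_pdb",
    "write_pdb",
    "assign_pharmacophores",
    "load_default_table",
]

#: Fixed class order; everything downstream (pair indexing, signature
#: layout) depends on this exact sequence.
PHARMACOPHORE_CLASSES = (
    "hydrophobic",
    "positive",
    "negative",
    "acceptor",
    "donor",
    "aromatic",
    "sulfur",
    "neutral",
)

_CLASS_SET = frozenset(PHARMACOPHORE_CLASSES)

_WATER_NAMES = {"HOH", "WAT", "DOD"}

# Two-character element symbols that appear in protein/ligand PDB files.
_TWO_CHAR_ELEMENTS = {
    "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "CU", "NI", "CO", "SE",
}


class PDBFormatError(ValueError):
    """Raised when a PDB record cannot be parsed; carries the line number."""


class EmptyStructureError(ValueError):
    """Raised when an operation receives or produces a structure with no atoms."""


class TypingError(KeyError):
    """Raised when an atom cannot be assigned any pharmacophore class."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    alt_loc: str
    coords: tuple[float, float, float]
    occupancy: float
    is_hetero: bool

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insertion_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.res_name} {self.key}")


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def iter_atoms(self) -> Iterable[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    def find_residue(self, key: tuple[str, int, str]) -> Residue:
        for res in self.residues:
            if res.key == key:
                return res
        raise KeyError(f"residue {key} not found in structure {self.id!r}")


class PharmacophoreTable:
    """Maps (res_name, atom_name) — with element fallbacks — to class sets.

    The table is plain data (see ``data/pharmacophores.tsv``): explicit rows
    for every heavy atom of the 20 canonical residues, plus per-element
    fallback rows keyed by res_name ``*``.
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], frozenset[str]],
        element_fallback: Mapping[str, frozenset[str]],
    ) -> None:
        for key, classes in entries.items():
            if not classes or not classes <= _CLASS_SET:
                raise ValueError(f"bad class set {set(classes)} for {key}")
        self._entries = dict(entries)
        self._fallback = dict(element_fallback)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PharmacophoreTable":
        entries: dict[tuple[str, str], frozenset[str]] = {}
        fallback: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise PDBFormatError(
                        f"{path}:{lineno}: expected 3 tab-separated fields"
                    )
                res_name, atom_name, class_field = parts
                classes = frozenset(c.strip() for c in class_field.split(","))
                if res_name == "*":
                    fallback[atom_name] = classes
                else:
                    entries[(res_name, atom_name)] = classes
        return cls(entries, fallback)

    def lookup(self, res_name: str, atom_name: str, element: str) -> frozenset[str]:
        classes = self._entries.get((res_name, atom_name))
        if classes is None:
            classes = self._fallback.get(element)
        if not classes:
            raise TypingError(
                f"no pharmacophore class for atom {atom_name!r} "
                f"(residue {res_name!r}, element {element!r})"
            )
        return classes

    def covers(self, res_name: str) -> bool:
        return any(key[0] == res_name for key in self._entries)


_default_table: PharmacophoreTable | None = None


def load_default_table() -> PharmacophoreTable:
    """The shipped atom-typing table, loaded once from package data."""
    global _default_table
    if _default_table is None:
        with resources.as_file(
            resources.files("ssv.data").joinpath("pharmacophores.tsv")
        ) as p:
            _default_table = PharmacophoreTable.from_tsv(p)
    return _default_table


def _guess_element(atom_name: str, raw_element: str) -> str:
    el = raw_element.strip().upper()
    if el:
        return el
    # Columns 13-14 of the atom name field carry the element when the
    # element column is blank (old files, in-house writers).
    stripped = atom_name.strip()
    two = stripped[:2].upper()
    if two in _TWO_CHAR_ELEMENTS and not stripped[:1].isdigit():
        return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_record(line: str, lineno: int) -> tuple[Atom, str, str, int, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        seq_num = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = _guess_element(name, line[76:78] if len(line) >= 78 else "")
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: unparsable record: {exc}") from exc
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        alt_loc=alt_loc,
        coords=(x, y, z),
        occupancy=occupancy,
        is_hetero=line.startswith("HETATM"),
    )
    return atom, res_name, chain_id, seq_num, icode


def _resolve_alt_locs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties → alt-loc 'A', then first."""
    by_name: dict[str, Atom] = {}
    for atom in atoms:
        cur = by_name.get(atom.name)
        if cur is None:
            by_name[atom.name] = atom
            continue
        if atom.occupancy > cur.occupancy:
            by_name[atom.name] = atom
        elif atom.occupancy == cur.occupancy:
            if atom.alt_loc == "A" and cur.alt_loc != "A":
                by_name[atom.name] = atom
    return [replace(a, alt_loc="") for a in by_name.values()]


def read_pdb(path: str | Path, keep_ligands: bool = True) -> Structure:
    """Parse a PDB file into a normalised :class:`Structure`.

    Hydrogens and waters are dropped, alternate locations resolved
    (highest occupancy wins; ties prefer alt-loc ``A``), and only the
    first MODEL of a multi-model file is read.  Hetero residues go to
    ``Structure.ligands`` when *keep_ligands* is true and are discarded
    otherwise.
    """
    path = Path(path)
    order: list[tuple] = []
    buckets: dict[tuple, tuple[str, bool, list[Atom]]] = {}
    in_first_model = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "ENDMDL":
                in_first_model = False
                continue
            if not in_first_model:
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            atom, res_name, chain_id, seq_num, icode = _parse_atom_record(line, lineno)
            if atom.element == "H" or atom.element == "D":
                continue
            if res_name in _WATER_NAMES:
                continue
            key = (chain_id, seq_num, icode, res_name)
            if key not in buckets:
                buckets[key] = (res_name, atom.is_hetero, [])
                order.append(key)
            buckets[key][2].append(atom)

    structure = Structure(id=path.stem)
    for key in order:
        res_name, is_het, atoms = buckets[key]
        chain_id, seq_num, icode, _ = key
        residue = Residue(
            chain_id=chain_id,
            seq_num=seq_num,
            insertion_code=icode,
            res_name=res_name,
            atoms=_resolve_alt_locs(atoms),
        )
        if is_het:
            if keep_ligands:
                structure.ligands.append(residue)
        else:
            structure.residues.append(residue)
    if not structure.residues and not structure.ligands:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM content after filtering")
    return structure


def _format_atom_line(
    record: str, serial: int, atom: Atom, res: Residue
) -> str:
    name = atom.name
    # Standard alignment: 1-char elements start in column 14 unless the
    # name is 4 characters long.
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coords
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{res.res_name:>3s} "
        f"{res.chain_id:1s}{res.seq_num:>4d}{res.insertion_code:1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"{'':10s}{atom.element:>2s}\n"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write *structure* (protein residues, then ligands) as a PDB file.

    Round-trips through :func:`read_pdb` to an equal structure at PDB
    coordinate precision (3 decimals).
    """
    if not structure.residues and not structure.ligands:
        raise EmptyStructureError("refusing to write an empty structure")
    serial = 0
    lines: list[str] = []
    for res in structure.residues:
        for atom in res.atoms:
            serial += 1
            lines.append(_format_atom_line("ATOM", serial, atom, res))
    if structure.residues:
        lines.append(f"{'TER':<6s}{serial + 1:>5d}\n")
        serial += 1
    for res in structure.ligands:
        for atom in res.atoms:
            serial += 1
            lines.append(_format_atom_line("HETATM", serial, atom, res))
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def assign_pharmacophores(
    structure: Structure, table: PharmacophoreTable | None = None
) -> dict[tuple[tuple[str, int, str], str], frozenset[str]]:
    """Type every heavy protein atom, keyed by ``(residue key, atom name)``.

    Deterministic: depends only on residue/atom names and elements, never
    on ordering.  Raises :class:`TypingError` for atoms the table and the
    element fallbacks both miss.
    """
    if table is None:
        table = load_default_table()
    assignments: dict[tuple[tuple[str, int, str], str], frozenset[str]] = {}
    for res, atom in structure.iter_atoms():
        assignments[(res.key, atom.name)] = table.lookup(
            res.res_name, atom.name, atom.element
        )
    return assignments
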