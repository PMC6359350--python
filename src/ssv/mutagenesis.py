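"""Point-mutation parsing, saturation enumeration, and geometric mutants.

Mutant structures are built without homology modeling: *truncate* mode
renames the residue and keeps only atoms shared with the target type;
*graft* mode additionally places missing side-chain atoms at idealized
internal-coordinate geometry (most common rotamer, no clash resolution).
Externally modeled mutant PDBs remain first-class input to the scoring
layer.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass

import numpy as np

from .pocket import ONE_TO_THREE, THREE_TO_ONE
from .structure_io import Atom, Residue, Structure

__all__ = [
    "AMINO_ACIDS",
    "CANONICAL_ATOMS",
    "MutationSpec",
    "MutationParseError",
    "parse_mutation",
    "enumerate_saturation",
    "apply_mutation",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Heavy atoms of the 20 canonical residue types (PDB v3 names).
CANONICAL_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("N", "CA", "C", "O", "CB"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "GLY": ("N", "CA", "C", "O"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
}

# Internal-coordinate templates: (atom, ref_a, ref_b, ref_c, bond,
# angle, dihedral) places `atom` bonded to ref_c with dihedral
# ref_a-ref_b-ref_c-atom.  CB is defined for every non-GLY type; side
# chains use idealized bond geometry and a common rotamer.
_CB = ("CB", "C", "N", "CA", 1.53, 110.5, 122.5)
_ZMAT: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "ALA": [_CB],
    "ARG": [_CB,
            ("CG", "N", "CA", "CB", 1.52, 114.0, -65.0),
            ("CD", "CA", "CB", "CG", 1.52, 111.0, 180.0),
            ("NE", "CB", "CG", "CD", 1.46, 112.0, 180.0),
            ("CZ", "CG", "CD", "NE", 1.33, 124.0, 180.0),
            ("NH1", "CD", "NE", "CZ", 1.33, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.33, 120.0, 180.0)],
    "ASN": [_CB,
            ("CG", "N", "CA", "CB", 1.52, 113.0, -65.0),
            ("OD1", "CA", "CB", "CG", 1.23, 121.0, -60.0),
            ("ND2", "CA", "CB", "CG", 1.33, 117.0, 120.0)],
    "ASP": [_CB,
            ("CG", "N", "CA", "CB", 1.52, 113.0, -65.0),
            ("OD1", "CA", "CB", "CG", 1.25, 119.0, -60.0),
            ("OD2", "CA", "CB", "CG", 1.25, 118.5, 120.0)],
    "CYS": [_CB,
            ("SG", "N", "CA", "CB", 1.81, 114.0, -65.0)],
    "GLN": [_CB,
            ("CG", "N", "CA", "CB", 1.52, 114.0, -65.0),
            ("CD", "CA", "CB", "CG", 1.52, 112.0, 180.0),
            ("OE1", "CB", "CG", "CD", 1.23, 121.0, -60.0),
            ("NE2", "CB", "CG", "CD", 1.33, 117.0, 120.0)],
    "GLU": [_CB,
            ("CG", "N", "CA", "CB", 1.52, 114.0, -65.0),
            ("CD", "CA", "CB", "CG", 1.52, 112.0, 180.0),
            ("OE1", "CB", "CG", "CD", 1.25, 119.0, -60.0),
            ("OE2", "CB", "CG", "CD", 1.25, 118.5, 120.0)],
    "GLY": [],
    "HIS": [_CB,
            ("CG", "N", "CA", "CB", 1.49, 113.0, -65.0),
            ("ND1", "CA", "CB", "CG", 1.38, 122.7, -75.0),
            ("CD2", "CA", "CB", "CG", 1.36, 131.0, 105.0),
            ("CE1", "CB", "CG", "ND1", 1.32, 109.0, 180.0),
            ("NE2", "CB", "CG", "CD2", 1.37, 107.0, 180.0)],
    "ILE": [_CB,
            ("CG1", "N", "CA", "CB", 1.53, 110.5, -60.0),
            ("CG2", "N", "CA", "CB", 1.53, 110.5, 66.0),
            ("CD1", "CA", "CB", "CG1", 1.53, 114.0, 170.0)],
    "LEU": [_CB,
            ("CG", "N", "CA", "CB", 1.53, 116.0, -65.0),
            ("CD1", "CA", "CB", "CG", 1.53, 110.5, 180.0),
            ("CD2", "CA", "CB", "CG", 1.53, 110.5, 60.0)],
    "LYS": [_CB,
            ("CG", "N", "CA", "CB", 1.52, 114.0, -65.0),
            ("CD", "CA", "CB", "CG", 1.52, 111.0, 180.0),
            ("CE", "CB", "CG", "CD", 1.52, 111.0, 180.0),
            ("NZ", "CG", "CD", "CE", 1.49, 112.0, 180.0)],
    "MET": [_CB,
            ("CG", "N", "CA", "CB", 1.52, 114.0, -65.0),
            ("SD", "CA", "CB", "CG", 1.803, 112.7, 180.0),
            ("CE", "CB", "CG", "SD", 1.79, 100.8, 180.0)],
    "PHE": [_CB,
            ("CG", "N", "CA", "CB", 1.502, 113.8, -65.0),
            ("CD1", "CA", "CB", "CG", 1.39, 120.8, 90.0),
            ("CD2", "CA", "CB", "CG", 1.39, 120.8, -90.0),
            ("CE1", "CB", "CG", "CD1", 1.39, 120.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 120.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0)],
    "PRO": [_CB,
            ("CG", "N", "CA", "CB", 1.49, 104.0, 28.0),
            ("CD", "CA", "CB", "CG", 1.503, 105.0, -35.0)],
    "SER": [_CB,
            ("OG", "N", "CA", "CB", 1.41, 110.8, -65.0)],
    "THR": [_CB,
            ("OG1", "N", "CA", "CB", 1.43, 109.0, -60.0),
            ("CG2", "N", "CA", "CB", 1.53, 110.5, 60.0)],
    "TRP": [_CB,
            ("CG", "N", "CA", "CB", 1.498, 113.6, -65.0),
            ("CD1", "CA", "CB", "CG", 1.37, 127.0, 90.0),
            ("CD2", "CA", "CB", "CG", 1.43, 126.6, -90.0),
            ("NE1", "CB", "CG", "CD1", 1.38, 110.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.41, 107.0, 180.0),
            ("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
            ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
            ("CZ3", "CG", "CD2", "CE3", 1.392, 118.8, 180.0),
            ("CH2", "CD2", "CE2", "CZ2", 1.37, 117.5, 0.0)],
    "TYR": [_CB,
            ("CG", "N", "CA", "CB", 1.51, 113.9, -65.0),
            ("CD1", "CA", "CB", "CG", 1.39, 120.8, 90.0),
            ("CD2", "CA", "CB", "CG", 1.39, 120.8, -90.0),
            ("CE1", "CB", "CG", "CD1", 1.39, 121.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 121.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.38, 120.0, 180.0)],
    "VAL": [_CB,
            ("CG1", "N", "CA", "CB", 1.53, 110.5, -60.0),
            ("CG2", "N", "CA", "CB", 1.53, 110.5, 60.0)],
}

_SITE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class MutationParseError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSpec:
    """One or more point substitutions, e.g. ``H228T`` or ``V174C/A404V``."""

    sites: tuple[tuple[str, int, str], ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise MutationParseError("mutation spec needs at least one site")
        positions = [p for _, p, _ in self.sites]
        if len(set(positions)) != len(positions):
            raise MutationParseError(f"duplicate positions in {self.sites}")
        for wild, pos, mut in self.sites:
            if wild not in AMINO_ACIDS or mut not in AMINO_ACIDS:
                raise MutationParseError(
                    f"non-canonical amino acid in {wild}{pos}{mut}"
                )
            if wild == mut:
                raise MutationParseError(f"identity substitution {wild}{pos}{mut}")

    def __str__(self) -> str:
        return "/".join(f"{w}{p}{m}" for w, p, m in self.sites)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for _, p, _ in self.sites)


def parse_mutation(text: str) -> MutationSpec:
    """Parse ``X<pos>Y`` notation, multi-site joined with ``/``."""
    sites = []
    for token in text.strip().split("/"):
        m = _SITE_RE.match(token.strip())
        if m is None:
            raise MutationParseError(f"malformed mutation token {token!r}")
        sites.append((m.group(1), int(m.group(2)), m.group(3)))
    return MutationSpec(sites=tuple(sites))


def enumerate_saturation(
    pocket_residues: list[tuple[int, str]],
) -> list[MutationSpec]:
    """All 19 non-identity substitutions per pocket residue.

    *pocket_residues* is a list of ``(seq_num, res_name)``; the output is
    ordered by position, then target letter.
    """
    specs: list[MutationSpec] = []
    for seq_num, res_name in sorted(pocket_residues):
        wild = THREE_TO_ONE.get(res_name)
        if wild is None:
            raise KeyError(f"non-canonical residue {res_name!r} at {seq_num}")
        for target in sorted(AMINO_ACIDS):
            if target != wild:
                specs.append(MutationSpec(sites=((wild, seq_num, target),)))
    return specs


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """NeRF placement of an atom bonded to c with dihedral a-b-c-atom."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _mutate_residue(residue: Residue, new_name: str, mode: str) -> Residue:
    keep = set(CANONICAL_ATOMS[new_name]) | {"N", "CA", "C", "O", "OXT"}
    atoms = [a for a in residue.atoms if a.name in keep]
    if mode == "graft":
        coords = {a.name: np.asarray(a.coords, dtype=np.float64) for a in atoms}
        next_serial = max((a.serial for a in atoms), default=0) + 1
        for name, ra, rb, rc, bond, angle, dihedral in _ZMAT[new_name]:
            if name in coords:
                continue
            if not all(r in coords for r in (ra, rb, rc)):
                missing = [r for r in (ra, rb, rc) if r not in coords]
                raise KeyError(
                    f"cannot graft {name} onto residue {residue.key}: "
                    f"missing reference atoms {missing}"
                )
            pos = _place_atom(coords[ra], coords[rb], coords[rc], bond, angle, dihedral)
            coords[name] = pos
            atoms.append(
                Atom(
                    serial=next_serial,
                    name=name,
                    element=name[0],
                    alt_loc="",
                    coords=(float(pos[0]), float(pos[1]), float(pos[2])),
                    occupancy=1.0,
                    is_hetero=False,
                )
            )
            next_serial += 1
    return Residue(
        chain_id=residue.chain_id,
        seq_num=residue.seq_num,
        insertion_code=residue.insertion_code,
        res_name=new_name,
        atoms=atoms,
    )


def apply_mutation(
    structure: Structure, spec: MutationSpec, mode: str = "truncate"
) -> Structure:
    """Build a mutant structure; only mutated residues are touched.

    Sites are located by sequence number (first matching chain, blank
    insertion code).  The residue found must match the spec's wild-type
    letter.
    """
    if mode not in ("truncate", "graft"):
        raise ValueError(f"unknown mutation mode {mode!r}")
    mutant = copy.deepcopy(structure)
    mutant.id = f"{structure.id}_{spec}"
    for wild, pos, target in spec.sites:
        residue = None
        for res in mutant.residues:
            if res.seq_num == pos and res.insertion_code == "":
                residue = res
                break
        if residue is None:
            raise KeyError(f"no residue at position {pos} in {structure.id!r}")
        found = THREE_TO_ONE.get(residue.res_name, "X")
        if found != wild:
            raise ValueError(
                f"wild-type mismatch at {pos}: spec says {wild}, "
                f"structure has {residue.res_name} ({found})"
            )
        idx = mutant.residues.index(residue)
        mutant.residues[idx] = _mutate_residue(residue, ONE_TO_THREE[target], mode)
    return mutant
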