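"""Deterministic synthetic structures and planted scoring scenarios.

Everything here exists so the full pipeline is exercisable offline: toy
structures realising requested pharmacophore class sets, jittered template
databases standing in for a curated enzyme collection, planted
beneficial-mutation cases with a known score sign, and the deliberately
naive brute-force signature oracle used to pin the vectorised
implementation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mutagenesis import CANONICAL_ATOMS, _mutate_residue
from .scoring import TemplateDatabase, structure_signature
from .signature import (
    DEFAULT_GRID,
    CutoffGrid,
    SignatureVector,
    class_pair_index,
)
from .structure_io import (
    Atom,
    Residue,
    Structure,
    load_default_table,
)

__all__ = [
    "ToySpec",
    "ToySpecError",
    "make_toy_structure",
    "make_toy_chain",
    "make_template_db",
    "plant_beneficial_case",
    "brute_force_signature",
    "make_filter_fixture",
]


class ToySpecError(ValueError):
    pass


@dataclass
class ToySpec:
    """Atoms given as (pharmacophore class set, xyz); one residue per atom
    unless a grouping plan (list of group sizes summing to n) is given."""

    atoms: list[tuple[frozenset[str], tuple[float, float, float]]]
    grouping: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ToySpecError("toy spec needs at least one atom")
        if self.grouping is not None and sum(self.grouping) != len(self.atoms):
            raise ToySpecError("grouping plan does not cover all atoms")


def _realization_index() -> dict[frozenset[str], tuple[str, str]]:
    """Class set → a canonical (res_name, atom_name) realising it exactly."""
    table = load_default_table()
    index: dict[frozenset[str], tuple[str, str]] = {}
    for res_name, atom_names in CANONICAL_ATOMS.items():
        for atom_name in atom_names:
            classes = table.lookup(res_name, atom_name, atom_name[0])
            index.setdefault(classes, (res_name, atom_name))
    return index


_REALIZATIONS: dict[frozenset[str], tuple[str, str]] | None = None


def make_toy_structure(spec: ToySpec, structure_id: str = "toy") -> Structure:
    """Structure whose atoms carry residue/atom names that the shipped
    typing table maps back to exactly the requested class sets."""
    global _REALIZATIONS
    if _REALIZATIONS is None:
        _REALIZATIONS = _realization_index()
    grouping = spec.grouping or [1] * len(spec.atoms)
    structure = Structure(id=structure_id)
    atom_iter = iter(enumerate(spec.atoms))
    serial = 0
    for seq_num, group_size in enumerate(grouping, start=1):
        residue: Residue | None = None
        for _ in range(group_size):
            i, (classes, coords) = next(atom_iter)
            realization = _REALIZATIONS.get(frozenset(classes))
            if realization is None:
                raise ToySpecError(
                    f"no canonical atom realises class set {set(classes)}"
                )
            res_name, atom_name = realization
            if residue is None:
                residue = Residue(
                    chain_id="A", seq_num=seq_num, insertion_code="",
                    res_name=res_name, atoms=[],
                )
            if any(a.name == atom_name for a in residue.atoms) or (
                residue.res_name != res_name
            ):
                raise ToySpecError(
                    f"atom {i}: class set {set(classes)} cannot share residue "
                    f"{residue.res_name} (name clash or type mismatch)"
                )
            serial += 1
            residue.atoms.append(
                Atom(
                    serial=serial, name=atom_name, element=atom_name[0],
                    alt_loc="", coords=tuple(float(c) for c in coords),
                    occupancy=1.0, is_hetero=False,
                )
            )
        assert residue is not None
        structure.residues.append(residue)
    return structure


def make_toy_chain(
    sequence: str, seed: int = 0, structure_id: str = "toychain"
) -> Structure:
    """A chain of complete canonical residues with idealized side chains.

    Backbone atoms are laid out along x at 3.8 Å per residue with a small
    seeded jitter (so signatures are non-degenerate); side chains are
    grafted at internal-coordinate geometry.  Deterministic per seed.
    """
    from .pocket import ONE_TO_THREE

    rng = np.random.default_rng(seed)
    structure = Structure(id=structure_id)
    serial = 0
    for i, letter in enumerate(sequence):
        res_name = ONE_TO_THREE.get(letter)
        if res_name is None:
            raise ToySpecError(f"non-canonical residue letter {letter!r}")
        ox = 3.8 * i
        jitter = rng.uniform(-0.25, 0.25, size=(4, 3))
        backbone = {
            "N": (ox + 0.0, 0.0, 0.0),
            "CA": (ox + 1.46, 0.6, 0.0),
            "C": (ox + 2.3, 0.0, 1.1),
            "O": (ox + 2.1, -1.2, 1.3),
        }
        atoms = []
        for j, (name, xyz) in enumerate(backbone.items()):
            serial += 1
            atoms.append(
                Atom(
                    serial=serial, name=name, element=name[0], alt_loc="",
                    coords=tuple(float(v + jitter[j, k]) for k, v in enumerate(xyz)),
                    occupancy=1.0, is_hetero=False,
                )
            )
        residue = Residue(
            chain_id="A", seq_num=i + 1, insertion_code="",
            res_name="GLY", atoms=atoms,
        )
        if res_name != "GLY":
            residue = _mutate_residue(residue, res_name, mode="graft")
        structure.residues.append(residue)
    return structure


def _jittered(structure: Structure, amplitude: float, rng: np.random.Generator,
              new_id: str) -> Structure:
    out = copy.deepcopy(structure)
    out.id = new_id
    for res in out.residues:
        for i, atom in enumerate(res.atoms):
            shift = rng.uniform(-amplitude, amplitude, size=3)
            res.atoms[i] = Atom(
                serial=atom.serial, name=atom.name, element=atom.element,
                alt_loc=atom.alt_loc,
                coords=tuple(float(c + s) for c, s in zip(atom.coords, shift)),
                occupancy=atom.occupancy, is_hetero=atom.is_hetero,
            )
    return out


def make_template_db(
    base: Structure,
    n: int,
    jitter: float = 0.0,
    seed: int = 0,
    grid: CutoffGrid = DEFAULT_GRID,
) -> TemplateDatabase:
    """*n* templates derived from *base* by uniform coordinate noise of
    amplitude *jitter* Å; jitter 0 replicates the base signature."""
    if n < 1:
        raise ValueError("template database needs n >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n):
        tid = f"T{i + 1:02d}"
        template = _jittered(base, jitter, rng, tid) if jitter > 0 else copy.deepcopy(base)
        template.id = tid
        entries.append((tid, structure_signature(template, grid=grid)))
    return TemplateDatabase(entries=entries, grid=grid)


def _radial_displace(structure: Structure, displacement: float, new_id: str) -> Structure:
    """Scale coordinates about the centroid so the RMS atom displacement
    equals *displacement* Å; all pairwise distances grow monotonically."""
    out = copy.deepcopy(structure)
    out.id = new_id
    xyz = np.array([a.coords for _, a in structure.iter_atoms()])
    centroid = xyz.mean(axis=0)
    rms_radius = float(np.sqrt(np.mean(np.sum((xyz - centroid) ** 2, axis=1))))
    if rms_radius == 0:
        raise ToySpecError("degenerate structure: all atoms at the centroid")
    factor = 1.0 + displacement / rms_radius
    for res in out.residues:
        for i, atom in enumerate(res.atoms):
            new = centroid + factor * (np.asarray(atom.coords) - centroid)
            res.atoms[i] = Atom(
                serial=atom.serial, name=atom.name, element=atom.element,
                alt_loc=atom.alt_loc, coords=tuple(float(v) for v in new),
                occupancy=atom.occupancy, is_hetero=atom.is_hetero,
            )
    return out


def plant_beneficial_case(
    template: Structure,
    wild_displacement: float,
    mutant_displacement: float,
    seed: int = 0,
    grid: CutoffGrid = DEFAULT_GRID,
) -> tuple[Structure, Structure, TemplateDatabase]:
    """Wild and mutant derived from *template* by controlled expansion so
    the mutant signature is at least as close to the template as the
    wild's (strictly closer whenever some atom pair crosses a cutoff).

    Requires ``mutant_displacement <= wild_displacement``; equality yields
    identical structures and a zero score.
    """
    if mutant_displacement > wild_displacement:
        raise ToySpecError(
            "mutant displacement must not exceed wild displacement"
        )
    if min(mutant_displacement, wild_displacement) < 0:
        raise ToySpecError("displacements must be >= 0")
    wild = _radial_displace(template, wild_displacement, "wild")
    mutant = _radial_displace(template, mutant_displacement, "mutant")
    db = TemplateDatabase(
        entries=[(template.id, structure_signature(template, grid=grid))],
        grid=grid,
    )
    return wild, mutant, db


def brute_force_signature(
    atoms: Sequence[tuple[frozenset[str] | set[str], Sequence[float]]],
    grid: CutoffGrid = DEFAULT_GRID,
) -> SignatureVector:
    """Independent oracle: literal loops over every unordered atom pair,
    every derived class pair, and every cutoff point.  No vectorisation,
    no binning — intentionally slow and simple."""
    n_points = grid.n_points
    points = [grid.d_min + grid.step * k for k in range(n_points)]
    counts = [[0] * n_points for _ in range(36)]
    for i in range(len(atoms)):
        classes_i, ci = atoms[i]
        for j in range(i + 1, len(atoms)):
            classes_j, cj = atoms[j]
            d = (
                (ci[0] - cj[0]) ** 2
                + (ci[1] - cj[1]) ** 2
                + (ci[2] - cj[2]) ** 2
            ) ** 0.5
            pair_indices = set()
            for a in classes_i:
                for b in classes_j:
                    pair_indices.add(class_pair_index(a, b))
            for row in pair_indices:
                for k in range(n_points):
                    if points[k] >= d:
                        counts[row][k] += 1
    flat = np.array([v for row in counts for v in row], dtype=np.int64)
    return SignatureVector(values=flat, grid=grid, structure_id="oracle")


def make_filter_fixture(
    n_other_rows: int = 23,
) -> tuple[list, dict[str, str], dict[int, set[str]], dict[str, float]]:
    """A triage scenario with the published stage counts.

    Returns ``(candidates, alignment, sift_allowed, mcsm_ddg)`` engineered
    so that, applied in order, a 1.0-threshold conservation filter removes
    9 of 86 candidates, a SIFT tolerated-substitution filter removes 58,
    and a -2.0 kcal/mol mCSM cutoff removes 4, leaving 15 survivors.
    """
    from .mutagenesis import AMINO_ACIDS, MutationSpec

    # 22-position target; positions 1-6 are fully conserved columns.
    wild = [AMINO_ACIDS[i % len(AMINO_ACIDS)] for i in range(22)]
    conserved_positions = {1, 2, 3, 4, 5, 6}
    alignment = {"target": "".join(wild)}
    for row in range(n_other_rows):
        seq = []
        for pos0, aa in enumerate(wild):
            if pos0 + 1 in conserved_positions:
                seq.append(aa)
            else:
                # rotate so no unconserved column matches the target everywhere
                shift = (AMINO_ACIDS.index(aa) + 1 + row % 3) % len(AMINO_ACIDS)
                seq.append(AMINO_ACIDS[shift])
        alignment[f"row{row + 1:02d}"] = "".join(seq)

    def substitutions(position: int, count: int) -> list[MutationSpec]:
        out = []
        for target in AMINO_ACIDS:
            if target == wild[position - 1]:
                continue
            out.append(MutationSpec(sites=((wild[position - 1], position, target),)))
            if len(out) == count:
                break
        return out

    candidates: list[MutationSpec] = []
    # 9 candidates at conserved positions (removed by conservation).
    for pos, count in zip(sorted(conserved_positions), (2, 2, 2, 1, 1, 1)):
        candidates.extend(substitutions(pos, count))
    # 77 candidates at unconserved positions 7..22: 16 positions, 5 each
    # except three positions with 4.
    rest: list[MutationSpec] = []
    for i, pos in enumerate(range(7, 23)):
        rest.extend(substitutions(pos, 4 if i < 3 else 5))
    assert len(rest) == 77
    candidates.extend(rest)
    assert len(candidates) == 86

    # SIFT: first 19 of the unconserved candidates tolerated, 58 not.
    # Conserved-position candidates are also listed tolerated so the
    # stages stay independent predicates.
    sift_allowed: dict[int, set[str]] = {pos: set() for pos in range(1, 23)}
    for cand in candidates[:9]:
        _, pos, target = cand.sites[0]
        sift_allowed[pos].add(target)
    for cand in rest[:19]:
        _, pos, target = cand.sites[0]
        sift_allowed[pos].add(target)

    # mCSM: 4 of the 19 SIFT-tolerated candidates highly destabilizing.
    mcsm_ddg: dict[str, float] = {}
    for i, cand in enumerate(rest[:19]):
        mcsm_ddg[str(cand)] = -3.0 if i < 4 else -0.5

    return candidates, alignment, sift_allowed, mcsm_ddg
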