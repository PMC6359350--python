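"""Catalytic-pocket definition and transfer between homologous structures.

The pocket is defined on a reference structure as every protein residue
with a heavy atom within a cutoff of a bound ligand, and carried over to
other structures by global sequence alignment (residue correspondence)
plus optional Kabsch superposition for geometric QC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import Residue, Structure

__all__ = [
    "PocketDefinition",
    "EmptyPocketError",
    "MappingQualityError",
    "residues_near_ligand",
    "kabsch_superpose",
    "map_pocket",
    "extract_pocket",
    "whole_structure_pocket",
    "read_pocket_tsv",
    "write_pocket_tsv",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class EmptyPocketError(ValueError):
    pass


class MappingQualityError(ValueError):
    pass


@dataclass
class PocketDefinition:
    """Ordered residue list defining a pocket on a named structure."""

    reference_id: str
    residues: list[tuple[str, int, str, str]]  # (chain, seq_num, icode, res_name)
    cutoff: float

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("pocket cutoff must be > 0")
        keys = [(c, s, i) for c, s, i, _ in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys in pocket definition")

    def keys(self) -> list[tuple[str, int, str]]:
        return [(c, s, i) for c, s, i, _ in self.residues]

    def __len__(self) -> int:
        return len(self.residues)


def residues_near_ligand(
    structure: Structure,
    ligand_key: tuple[str, int, str],
    cutoff: float = 6.5,
) -> PocketDefinition:
    """Protein residues with any heavy atom within *cutoff* (inclusive) of
    any ligand heavy atom, in chain/sequence order."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    ligand = None
    for res in structure.ligands:
        if res.key == ligand_key:
            ligand = res
            break
    if ligand is None:
        raise KeyError(
            f"ligand {ligand_key} not found among hetero residues of {structure.id!r}"
        )
    lig_xyz = np.array([a.coords for a in ligand.atoms])
    members: list[tuple[str, int, str, str]] = []
    for res in structure.residues:
        xyz = np.array([a.coords for a in res.atoms])
        diff = xyz[:, None, :] - lig_xyz[None, :, :]
        if np.any(np.sum(diff * diff, axis=-1) <= cutoff * cutoff):
            members.append((res.chain_id, res.seq_num, res.insertion_code, res.res_name))
    if not members:
        raise EmptyPocketError(
            f"no residue of {structure.id!r} within {cutoff} A of ligand {ligand_key}"
        )
    members.sort(key=lambda r: (r[0], r[1], r[2]))
    return PocketDefinition(reference_id=structure.id, residues=members, cutoff=cutoff)


def kabsch_superpose(
    mobile_coords: Sequence[Sequence[float]],
    target_coords: Sequence[Sequence[float]],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of *mobile* onto *target*.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits *target*.
    """
    P = np.asarray(mobile_coords, dtype=np.float64)
    Q = np.asarray(target_coords, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def _chain_sequences(structure: Structure) -> dict[str, list[Residue]]:
    chains: dict[str, list[Residue]] = {}
    for res in structure.residues:
        chains.setdefault(res.chain_id, []).append(res)
    return chains


def _align(seq1: str, seq2: str) -> tuple[list[tuple[int | None, int | None]], float]:
    """Global alignment; returns column pairs of sequence indices and identity."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq1, seq2)[0]
    pairs: list[tuple[int | None, int | None]] = []
    i = j = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        while i < s1:
            pairs.append((i, None))
            i += 1
        while j < s2:
            pairs.append((None, j))
            j += 1
        for k in range(e1 - s1):
            pairs.append((s1 + k, s2 + k))
        i, j = e1, e2
    while i < len(seq1):
        pairs.append((i, None))
        i += 1
    while j < len(seq2):
        pairs.append((None, j))
        j += 1
    matched = sum(
        1 for a, b in pairs if a is not None and b is not None and seq1[a] == seq2[b]
    )
    aligned_cols = sum(1 for a, b in pairs if a is not None and b is not None)
    identity = matched / aligned_cols if aligned_cols else 0.0
    return pairs, identity


def map_pocket(
    reference: Structure,
    pocket: PocketDefinition,
    target: Structure,
    identity_floor: float = 0.20,
) -> tuple[PocketDefinition, list[tuple[str, int, str, str]]]:
    """Transfer *pocket* onto *target* via per-chain global alignment.

    Returns the mapped pocket plus the list of pocket residues that fell
    on gap columns and could not be mapped.  Raises
    :class:`MappingQualityError` when alignment identity is below
    *identity_floor* and :class:`EmptyPocketError` when nothing maps.
    """
    ref_chains = _chain_sequences(reference)
    tgt_chains = _chain_sequences(target)
    pocket_keys = set(pocket.keys())

    mapped: list[tuple[str, int, str, str]] = []
    unmapped: list[tuple[str, int, str, str]] = []
    seen_chains = {c for c, _, _, _ in pocket.residues}
    for chain_id in sorted(seen_chains):
        ref_residues = ref_chains.get(chain_id, [])
        # Map onto the same chain id when present, else the first target chain.
        tgt_residues = tgt_chains.get(chain_id)
        if tgt_residues is None:
            if len(tgt_chains) != 1:
                raise MappingQualityError(
                    f"chain {chain_id!r} absent from target {target.id!r}"
                )
            tgt_residues = next(iter(tgt_chains.values()))
        ref_seq = "".join(THREE_TO_ONE.get(r.res_name, "X") for r in ref_residues)
        tgt_seq = "".join(THREE_TO_ONE.get(r.res_name, "X") for r in tgt_residues)
        pairs, identity = _align(ref_seq, tgt_seq)
        if identity < identity_floor:
            raise MappingQualityError(
                f"alignment identity {identity:.2f} below floor {identity_floor:.2f} "
                f"for chain {chain_id!r}"
            )
        correspondence = {
            a: b for a, b in pairs if a is not None and b is not None
        }
        for ref_idx, res in enumerate(ref_residues):
            if res.key not in pocket_keys:
                continue
            tgt_idx = correspondence.get(ref_idx)
            entry = (res.chain_id, res.seq_num, res.insertion_code, res.res_name)
            if tgt_idx is None:
                unmapped.append(entry)
            else:
                tgt_res = tgt_residues[tgt_idx]
                mapped.append(
                    (tgt_res.chain_id, tgt_res.seq_num, tgt_res.insertion_code,
                     tgt_res.res_name)
                )
    if not mapped:
        raise EmptyPocketError(
            f"no pocket residue of {pocket.reference_id!r} maps onto {target.id!r}"
        )
    return (
        PocketDefinition(
            reference_id=target.id, residues=mapped, cutoff=pocket.cutoff
        ),
        unmapped,
    )


def extract_pocket(structure: Structure, pocket: PocketDefinition) -> Structure:
    """Sub-structure containing exactly the pocket residues, order preserved."""
    by_key = {res.key: res for res in structure.residues}
    missing = [k for k in pocket.keys() if k not in by_key]
    if missing:
        raise KeyError(
            f"pocket residues missing from {structure.id!r}: {missing}"
        )
    residues = [by_key[k] for k in pocket.keys()]
    return Structure(id=structure.id, residues=residues, ligands=[])


def whole_structure_pocket(structure: Structure, cutoff: float = 6.5) -> PocketDefinition:
    """A pocket enumerating every protein residue (whole-protein mode)."""
    residues = [
        (r.chain_id, r.seq_num, r.insertion_code, r.res_name)
        for r in structure.residues
    ]
    if not residues:
        raise EmptyPocketError(f"structure {structure.id!r} has no residues")
    return PocketDefinition(reference_id=structure.id, residues=residues, cutoff=cutoff)


def write_pocket_tsv(pocket: PocketDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reference={pocket.reference_id}\tcutoff={pocket.cutoff}\n")
        fh.write("chain\tseq_num\ticode\tres_name\n")
        for chain, seq, icode, name in pocket.residues:
            fh.write(f"{chain}\t{seq}\t{icode}\t{name}\n")


def read_pocket_tsv(path: str | Path) -> PocketDefinition:
    path = Path(path)
    reference_id = path.stem
    cutoff = 6.5
    residues: list[tuple[str, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split("\t"):
                    tok = tok.strip()
                    if tok.startswith("reference="):
                        reference_id = tok.split("=", 1)[1]
                    elif tok.startswith("cutoff="):
                        cutoff = float(tok.split("=", 1)[1])
                continue
            if line.startswith("chain\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            residues.append((parts[0], int(parts[1]), parts[2], parts[3]))
    if not residues:
        raise EmptyPocketError(f"{path}: pocket file lists no residues")
    return PocketDefinition(reference_id=reference_id, residues=residues, cutoff=cutoff)
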