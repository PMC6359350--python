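"""Template database handling and the ΔΔSSV mutation score.

A template database is a named matrix of signatures for curated "good"
enzymes.  For a wild/mutant structure pair, each side independently picks
its nearest template by Euclidean distance; the score is the difference
of those two minimal distances.  Negative scores predict beneficial
mutations, positive scores non-beneficial ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pocket import PocketDefinition, extract_pocket, map_pocket
from .signature import (
    DEFAULT_GRID,
    CutoffGrid,
    SignatureVector,
    compute_signature,
    read_signature_tsv,
    signature_distance,
)
from .structure_io import Structure, assign_pharmacophores, read_pdb

__all__ = [
    "TemplateDatabase",
    "SSVResult",
    "ConfigurationError",
    "load_template_db",
    "nearest_template",
    "score_mutation",
    "classify",
    "structure_signature",
]

LABEL_BENEFICIAL = "beneficial"
LABEL_NOT_BENEFICIAL = "not_beneficial"
LABEL_NEUTRAL = "neutral"


class ConfigurationError(ValueError):
    pass


@dataclass
class TemplateDatabase:
    entries: list[tuple[str, SignatureVector]]
    grid: CutoffGrid

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("template database must not be empty")
        ids = [tid for tid, _ in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({t for t in ids if ids.count(t) > 1})
            raise ConfigurationError(f"duplicate template ids: {dupes}")
        for tid, sig in self.entries:
            if sig.grid != self.grid:
                raise ValueError(f"template {tid!r} is on a different grid")

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return [tid for tid, _ in self.entries]


@dataclass
class SSVResult:
    wild_id: str
    mutant_id: str
    wild_template_id: str
    mutant_template_id: str
    dssv_wt: float
    dssv_mt: float
    ddssv: float
    label: str


def structure_signature(
    structure: Structure,
    pocket: PocketDefinition | None = None,
    grid: CutoffGrid = DEFAULT_GRID,
    reference: Structure | None = None,
) -> SignatureVector:
    """Signature of a structure, pocket-extracted when a pocket is given.

    When the pocket was defined on a different structure, *reference* must
    be supplied so the pocket can be transferred by sequence alignment
    first.
    """
    if pocket is not None:
        if pocket.reference_id != structure.id and reference is not None:
            pocket, _ = map_pocket(reference, pocket, structure)
        structure = extract_pocket(structure, pocket)
    assignments = assign_pharmacophores(structure)
    return compute_signature(structure, assignments, grid)


def load_template_db(
    paths: Iterable[str | Path],
    pocket: PocketDefinition | None = None,
    grid: CutoffGrid = DEFAULT_GRID,
    reference: Structure | None = None,
) -> TemplateDatabase:
    """Build a database from template PDB files or one precomputed
    signature TSV (as written by :func:`ssv.signature.write_signature_tsv`)."""
    paths = [Path(p) for p in paths]
    if not paths:
        raise ConfigurationError("no template inputs given")
    entries: list[tuple[str, SignatureVector]] = []
    for path in paths:
        if path.suffix.lower() in (".tsv", ".txt", ".csv"):
            for sig in read_signature_tsv(path, grid):
                entries.append((sig.structure_id, sig))
        else:
            structure = read_pdb(path)
            sig = structure_signature(structure, pocket, grid, reference)
            entries.append((structure.id, sig))
    return TemplateDatabase(entries=entries, grid=grid)


def nearest_template(
    sig: SignatureVector, db: TemplateDatabase
) -> tuple[str, float]:
    """Template minimising Euclidean distance; ties broken by smallest id."""
    best: tuple[float, str] | None = None
    for tid, tsig in db.entries:
        d = signature_distance(sig, tsig)
        if best is None or d < best[0] or (d == best[0] and tid < best[1]):
            best = (d, tid)
    assert best is not None
    return best[1], best[0]


def classify(ddssv: float, neutral_tol: float = 0.0) -> str:
    """Sign rule: negative → beneficial, positive → not beneficial,
    within ±neutral_tol of zero → neutral."""
    if neutral_tol < 0:
        raise ValueError("neutral_tol must be >= 0")
    if ddssv < -neutral_tol:
        return LABEL_BENEFICIAL
    if ddssv > neutral_tol:
        return LABEL_NOT_BENEFICIAL
    return LABEL_NEUTRAL


def score_mutation(
    wild_sig: SignatureVector,
    mutant_sig: SignatureVector,
    db: TemplateDatabase,
    neutral_tol: float = 0.0,
) -> SSVResult:
    """ΔΔSSV for one wild/mutant pair against a template database.

    Wild and mutant templates are selected independently, so they may
    differ.  ``ddssv = dssv_mt - dssv_wt`` exactly.
    """
    wt_id, dssv_wt = nearest_template(wild_sig, db)
    mt_id, dssv_mt = nearest_template(mutant_sig, db)
    ddssv = dssv_mt - dssv_wt
    return SSVResult(
        wild_id=wild_sig.structure_id,
        mutant_id=mutant_sig.structure_id,
        wild_template_id=wt_id,
        mutant_template_id=mt_id,
        dssv_wt=dssv_wt,
        dssv_mt=dssv_mt,
        ddssv=ddssv,
        label=classify(ddssv, neutral_tol),
    )
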