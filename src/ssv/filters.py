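"""Post-score candidate triage with an auditable filter chain.

Conservation is computed in-repo from a pocket alignment; SIFT and mCSM
are consumed strictly as externally produced result tables.  Every stage
records how many candidates it removed so the bookkeeping identity
``initial - sum(removed) = final`` always holds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .mutagenesis import MutationSpec, parse_mutation

__all__ = [
    "FilterAudit",
    "ConservationProfile",
    "conservation_profile",
    "filter_conserved",
    "read_sift_table",
    "read_mcsm_table",
    "sift_stage",
    "mcsm_stage",
    "conservation_stage",
    "apply_filter_chain",
    "read_alignment_fasta",
]

logger = logging.getLogger(__name__)

DEFAULT_MCSM_CUTOFF = -2.0  # kcal/mol; below this a mutation counts as highly destabilizing
SIFT_SCORE_CUTOFF = 0.05


@dataclass
class FilterAudit:
    initial_count: int
    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (name, removed, remaining)

    def record(self, name: str, removed: int, remaining: int) -> None:
        if self.stages and remaining > self.stages[-1][2]:
            raise ValueError("remaining count may not increase")
        self.stages.append((name, removed, remaining))
        assert self.initial_count - sum(r for _, r, _ in self.stages) == remaining

    @property
    def final_count(self) -> int:
        return self.stages[-1][2] if self.stages else self.initial_count


@dataclass
class ConservationProfile:
    """Per-target-position fraction of alignment rows with the target residue."""

    fractions: dict[int, float]

    def __post_init__(self) -> None:
        for pos, frac in self.fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"conservation fraction {frac} at {pos} out of [0,1]")

    def __getitem__(self, position: int) -> float:
        return self.fractions[position]

    def __contains__(self, position: int) -> bool:
        return position in self.fractions


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Aligned FASTA → ordered {id: gapped sequence} map."""
    rows: dict[str, str] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                current = line[1:].split()[0]
                rows[current] = ""
            elif current is not None:
                rows[current] += line.strip()
    if not rows:
        raise ValueError(f"{path}: no FASTA records")
    return rows


def conservation_profile(
    alignment: dict[str, str], target_row: str
) -> ConservationProfile:
    """Fraction of rows carrying the target's residue, per target position.

    Positions are 1-based indices into the ungapped target sequence; gap
    characters in other rows are excluded from both numerator and
    denominator.
    """
    if target_row not in alignment:
        raise KeyError(f"target row {target_row!r} not in alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    target_seq = alignment[target_row]
    others = [seq for rid, seq in alignment.items() if rid != target_row]
    fractions: dict[int, float] = {}
    position = 0
    for col, target_char in enumerate(target_seq):
        if target_char in "-.":
            continue
        position += 1
        column = [seq[col] for seq in others]
        residues = [c for c in column if c not in "-."]
        if residues:
            fractions[position] = sum(
                1 for c in residues if c.upper() == target_char.upper()
            ) / len(residues)
        else:
            fractions[position] = 0.0
    return ConservationProfile(fractions=fractions)


def filter_conserved(
    candidates: Sequence[MutationSpec],
    profile: ConservationProfile,
    threshold: float = 1.0,
) -> tuple[list[MutationSpec], list[MutationSpec]]:
    """Partition candidates: removed if any site sits at conservation >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    survivors, removed = [], []
    for cand in candidates:
        for pos in cand.positions:
            if pos not in profile:
                raise KeyError(f"position {pos} of {cand} absent from profile")
        if any(profile[pos] >= threshold for pos in cand.positions):
            removed.append(cand)
        else:
            survivors.append(cand)
    return survivors, removed


def read_sift_table(path: str | Path) -> dict[int, set[str]]:
    """Tolerated-substitution map from a SIFT result TSV.

    Rows are ``position<TAB>amino_acid<TAB>flag_or_score``; a third column
    of ``tolerated``/``not_tolerated`` is used directly, a numeric column
    is thresholded at the conventional 0.05.  Positions not listed are
    treated as unconstrained by :func:`sift_stage`.
    """
    allowed: dict[int, set[str]] = {}
    path = Path(path)
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("position"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            try:
                pos = int(parts[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position {parts[0]!r}") from exc
            aa = parts[1].strip().upper()
            flag_field = parts[2].strip().lower()
            if flag_field in ("tolerated", "not_tolerated", "deleterious"):
                tolerated = flag_field == "tolerated"
            else:
                try:
                    tolerated = float(flag_field) >= SIFT_SCORE_CUTOFF
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unrecognised flag {parts[2]!r}"
                    ) from exc
            allowed.setdefault(pos, set())
            if tolerated:
                allowed[pos].add(aa)
            n_rows += 1
    if n_rows == 0:
        warnings.warn(f"{path}: empty SIFT table; no position constrained")
    return allowed


def read_mcsm_table(path: str | Path) -> dict[str, float]:
    """Per-mutation predicted ddG (kcal/mol), keyed by canonical spec string."""
    table: dict[str, float] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("mutation"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: missing ddG column")
            key = str(parse_mutation(parts[0]))
            if key in table:
                raise ValueError(f"{path}:{lineno}: duplicate mutation {key}")
            # tolerate unicode minus from copy-pasted tables
            table[key] = float(parts[1].replace("−", "-"))
    return table


def conservation_stage(
    profile: ConservationProfile, threshold: float = 1.0
) -> tuple[str, Callable[[MutationSpec], bool]]:
    def keep(cand: MutationSpec) -> bool:
        return all(profile[pos] < threshold for pos in cand.positions)

    return "conservation", keep


def sift_stage(
    allowed: dict[int, set[str]]
) -> tuple[str, Callable[[MutationSpec], bool]]:
    """Keep a candidate only if every site's target residue is tolerated;
    positions absent from the table are unconstrained."""

    def keep(cand: MutationSpec) -> bool:
        for _, pos, target in cand.sites:
            if pos not in allowed:
                logger.debug("SIFT: position %d unlisted, treated as unconstrained", pos)
                continue
            if target not in allowed[pos]:
                return False
        return True

    return "sift", keep


def mcsm_stage(
    ddg: dict[str, float], cutoff: float = DEFAULT_MCSM_CUTOFF
) -> tuple[str, Callable[[MutationSpec], bool]]:
    """Drop candidates predicted highly destabilizing (ddG below *cutoff*);
    mutations missing from the table pass."""

    def keep(cand: MutationSpec) -> bool:
        value = ddg.get(str(cand))
        return value is None or value >= cutoff

    return "mcsm", keep


def apply_filter_chain(
    candidates: Sequence[MutationSpec],
    stages: Sequence[tuple[str, Callable[[MutationSpec], bool]]],
) -> tuple[list[MutationSpec], FilterAudit]:
    """Apply predicate stages in order, recording removals per stage."""
    audit = FilterAudit(initial_count=len(candidates))
    current = list(candidates)
    for name, keep in stages:
        survivors = [c for c in current if keep(c)]
        audit.record(name, len(current) - len(survivors), len(survivors))
        current = survivors
    return current, audit
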