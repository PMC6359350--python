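"""Cumulative pairwise-distance pocket signatures (aCSM-ALL style).

A signature counts, for every unordered pair of pharmacophore classes and
every cutoff on a distance grid, how many heavy-atom pairs lie within that
cutoff.  At the default grid (0–10 Å, step 0.1 Å) this gives
36 class pairs × 101 cutoffs = 3636 components.  Signatures are compared
by plain Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .structure_io import PHARMACOPHORE_CLASSES, Structure, TypingError

__all__ = [
    "CutoffGrid",
    "SignatureVector",
    "N_CLASS_PAIRS",
    "class_pair_index",
    "class_pair_labels",
    "compute_signature",
    "signature_distance",
    "write_signature_tsv",
    "read_signature_tsv",
]

_CLASS_INDEX = {c: i for i, c in enumerate(PHARMACOPHORE_CLASSES)}
N_CLASSES = len(PHARMACOPHORE_CLASSES)
#: 8 classes taken two at a time with repetition.
N_CLASS_PAIRS = N_CLASSES * (N_CLASSES + 1) // 2


def class_pair_index(c1: str, c2: str) -> int:
    """Canonical index of the unordered class pair, in ``[0, 36)``.

    Pairs are enumerated lexicographically over the fixed class order, so
    (hydrophobic, hydrophobic) is 0 and (neutral, neutral) is 35.  The
    lookup is symmetric.
    """
    try:
        a, b = _CLASS_INDEX[c1], _CLASS_INDEX[c2]
    except KeyError as exc:
        raise KeyError(f"unknown pharmacophore class {exc.args[0]!r}") from exc
    if a > b:
        a, b = b, a
    return a * N_CLASSES - a * (a - 1) // 2 + (b - a)


def class_pair_labels() -> list[tuple[str, str]]:
    """The 36 unordered class pairs in index order."""
    labels = []
    for i, c1 in enumerate(PHARMACOPHORE_CLASSES):
        for c2 in PHARMACOPHORE_CLASSES[i:]:
            labels.append((c1, c2))
    return labels


@dataclass(frozen=True)
class CutoffGrid:
    d_min: float = 0.0
    d_max: float = 10.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.step <= 0 or self.d_max <= self.d_min:
            raise ValueError("grid requires step > 0 and d_max > d_min")

    @property
    def n_points(self) -> int:
        return round((self.d_max - self.d_min) / self.step) + 1

    @property
    def points(self) -> np.ndarray:
        return self.d_min + self.step * np.arange(self.n_points)

    @property
    def dimension(self) -> int:
        return N_CLASS_PAIRS * self.n_points


DEFAULT_GRID = CutoffGrid()


@dataclass
class SignatureVector:
    """Flat count vector indexed by (class pair, cutoff point).

    ``values`` has shape ``(36 * n_points,)`` with the cutoff index varying
    fastest, i.e. row-major over the (pair, cutoff) matrix.
    """

    values: np.ndarray
    grid: CutoffGrid = field(default_factory=CutoffGrid)
    structure_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.grid.dimension,):
            raise ValueError(
                f"signature has {self.values.shape} values, grid expects "
                f"({self.grid.dimension},)"
            )

    @property
    def matrix(self) -> np.ndarray:
        """(36, n_points) view of the counts."""
        return self.values.reshape(N_CLASS_PAIRS, self.grid.n_points)

    def __len__(self) -> int:
        return self.values.shape[0]


def _check_compatible(a: SignatureVector, b: SignatureVector) -> None:
    if a.grid != b.grid or len(a) != len(b):
        raise ValueError(
            f"incompatible signatures: {len(a)} on {a.grid} vs {len(b)} on {b.grid}"
        )


def compute_signature(
    pocket_structure: Structure,
    assignments: Mapping[tuple[tuple[str, int, str], str], frozenset[str]],
    grid: CutoffGrid = DEFAULT_GRID,
) -> SignatureVector:
    """Cumulative class-pair counts over all unordered heavy-atom pairs.

    For each atom pair at distance ``d`` and every distinct class-pair
    index derivable from the two atoms' class sets, the count at every
    cutoff point ``>= d`` goes up by one.  Pairs beyond the grid maximum
    contribute nothing.  An empty structure yields the zero vector.

    Distances are compared at full floating precision; ties with a cutoff
    point count as inside (``<=``).
    """
    coords = []
    masks = []
    for res, atom in pocket_structure.iter_atoms():
        key = (res.key, atom.name)
        if key not in assignments:
            raise TypingError(f"no pharmacophore assignment for atom {key}")
        coords.append(atom.coords)
        mask = 0
        for cls in assignments[key]:
            mask |= 1 << _CLASS_INDEX[cls]
        masks.append(mask)

    n_points = grid.n_points
    counts = np.zeros((N_CLASS_PAIRS, n_points), dtype=np.int64)
    n = len(coords)
    if n >= 2:
        xyz = np.asarray(coords, dtype=np.float64)
        mask_arr = np.asarray(masks, dtype=np.int64)

        # Group atoms by class-set bitmask: the derived pair indices depend
        # only on the two masks, so pair counting reduces to histogramming
        # distances between (and within) mask groups.
        pair_rows_cache: dict[tuple[int, int], list[int]] = {}

        def pair_rows(m1: int, m2: int) -> list[int]:
            key = (m1, m2) if m1 <= m2 else (m2, m1)
            rows = pair_rows_cache.get(key)
            if rows is None:
                cls1 = [c for c in PHARMACOPHORE_CLASSES if m1 >> _CLASS_INDEX[c] & 1]
                cls2 = [c for c in PHARMACOPHORE_CLASSES if m2 >> _CLASS_INDEX[c] & 1]
                rows = sorted({class_pair_index(a, b) for a in cls1 for b in cls2})
                pair_rows_cache[key] = rows
            return rows

        unique_masks = sorted(set(masks))
        groups = {m: np.flatnonzero(mask_arr == m) for m in unique_masks}
        points = grid.points
        # Bin edges such that searchsorted(d) gives the first cutoff >= d.
        for gi, m1 in enumerate(unique_masks):
            idx1 = groups[m1]
            for m2 in unique_masks[gi:]:
                idx2 = groups[m2]
                if m1 == m2:
                    if len(idx1) < 2:
                        continue
                    sub = xyz[idx1]
                    diff = sub[:, None, :] - sub[None, :, :]
                    d2 = np.sum(diff * diff, axis=-1)
                    iu = np.triu_indices(len(idx1), k=1)
                    dists = np.sqrt(d2[iu])
                else:
                    diff = xyz[idx1][:, None, :] - xyz[idx2][None, :, :]
                    dists = np.sqrt(np.sum(diff * diff, axis=-1)).ravel()
                # First cutoff point >= d; pairs beyond the last point
                # (hence beyond d_max) contribute nothing.
                first_idx = np.searchsorted(points, dists, side="left")
                first_idx = first_idx[first_idx < n_points]
                if first_idx.size == 0:
                    continue
                hist = np.bincount(first_idx, minlength=n_points)
                cum = np.cumsum(hist)
                for row in pair_rows(m1, m2):
                    counts[row] += cum

    return SignatureVector(
        values=counts.reshape(-1),
        grid=grid,
        structure_id=pocket_structure.id,
    )


def signature_distance(a: SignatureVector, b: SignatureVector) -> float:
    """Euclidean distance between two signatures on the same grid."""
    _check_compatible(a, b)
    diff = a.values.astype(np.float64) - b.values.astype(np.float64)
    return float(np.sqrt(np.dot(diff, diff)))


def _header(grid: CutoffGrid) -> list[str]:
    cols = ["id"]
    for c1, c2 in class_pair_labels():
        for p in grid.points:
            cols.append(f"{c1}:{c2}:{p:.1f}")
    return cols


def write_signature_tsv(
    signatures: Sequence[SignatureVector], path: str | Path
) -> None:
    """One row per structure: id column then the 3636 count columns."""
    if not signatures:
        raise ValueError("no signatures to write")
    grid = signatures[0].grid
    for sig in signatures[1:]:
        _check_compatible(signatures[0], sig)
    with open(path, "w") as fh:
        fh.write("\t".join(_header(grid)) + "\n")
        for sig in signatures:
            fh.write(
                sig.structure_id
                + "\t"
                + "\t".join(str(int(v)) for v in sig.values)
                + "\n"
            )


def read_signature_tsv(
    path: str | Path, grid: CutoffGrid = DEFAULT_GRID
) -> list[SignatureVector]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = _header(grid)
        if header != expected:
            raise ValueError(
                f"{path}: signature header does not match grid "
                f"({len(header) - 1} columns vs {grid.dimension} expected)"
            )
        out = []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != grid.dimension + 1:
                raise ValueError(f"{path}:{lineno}: wrong column count")
            out.append(
                SignatureVector(
                    values=np.array([int(v) for v in parts[1:]], dtype=np.int64),
                    grid=grid,
                    structure_id=parts[0],
                )
            )
    return out
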