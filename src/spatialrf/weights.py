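"""Neighbourhood structures ("j ~ i") for areal data.

A :class:`NeighborhoodStructure` is the contiguity relation every other module
consumes: per-region neighbour lists over an ordered set of region identifiers,
viewed either with binary weights (w_ij = 1 for neighbours) or row-standardized
weights (w_ij = 1/deg(i)).  The relation is symmetric and irreflexive; islands
(regions with no neighbours) are allowed and each consumer defines its own
island behaviour.

Adjacency is taken as given — from a GAL file, an edge list, or the built-in
rook lattice used for simulation — rather than derived from polygon geometry,
which keeps the package geometry-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .exceptions import DataError, FormatError

logger = logging.getLogger(__name__)

BINARY = "binary"
ROW_STANDARDIZED = "row_standardized"


@dataclass(frozen=True, eq=False)
class NeighborhoodStructure:
    """Symmetric neighbour lists over an ordered set of regions.

    Parameters
    ----------
    region_ids
        Ordered unique region identifiers.
    neighbors
        For each region (in ``region_ids`` order) the sorted array of neighbour
        positions.  Must be symmetric as a relation and contain no self-links.
    weight_mode
        ``"binary"`` (w_ij = 1) or ``"row_standardized"`` (w_ij = 1/deg(i);
        island rows are all-zero).
    """

    region_ids: tuple[str, ...]
    neighbors: tuple[np.ndarray, ...]
    weight_mode: str = BINARY
    _pos: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        ids = tuple(str(r) for r in self.region_ids)
        if len(set(ids)) != len(ids):
            raise DataError("region identifiers must be unique")
        if len(self.neighbors) != len(ids):
            raise DataError("one neighbour list required per region")
        if self.weight_mode not in (BINARY, ROW_STANDARDIZED):
            raise DataError(f"unknown weight mode {self.weight_mode!r}")
        nbrs = []
        for i, nb in enumerate(self.neighbors):
            nb = np.asarray(sorted(set(int(j) for j in nb)), dtype=np.intp)
            if nb.size and (nb.min() < 0 or nb.max() >= len(ids)):
                raise DataError("neighbour index out of range")
            if i in nb:
                raise DataError(f"region {ids[i]!r} listed as its own neighbour")
            nbrs.append(nb)
        for i, nb in enumerate(nbrs):
            for j in nb:
                if i not in nbrs[j]:
                    raise DataError("neighbour relation is not symmetric")
        object.__setattr__(self, "region_ids", ids)
        object.__setattr__(self, "neighbors", tuple(nbrs))
        object.__setattr__(self, "_pos", {r: i for i, r in enumerate(ids)})

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NeighborhoodStructure)
            and self.region_ids == other.region_ids
            and self.weight_mode == other.weight_mode
            and all(np.array_equal(a, b) for a, b in zip(self.neighbors, other.neighbors))
        )

    # -- basic views -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.region_ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([nb.size for nb in self.neighbors], dtype=np.intp)

    @property
    def islands(self) -> list[str]:
        return [r for r, nb in zip(self.region_ids, self.neighbors) if nb.size == 0]

    @property
    def n_links(self) -> int:
        """Number of undirected links."""
        return int(self.degrees.sum()) // 2

    @property
    def s0(self) -> float:
        """Sum of all weights (2x links in binary mode; #non-islands row-standardized)."""
        if self.weight_mode == BINARY:
            return float(self.degrees.sum())
        return float(np.count_nonzero(self.degrees))

    def position(self, region_id: str) -> int:
        try:
            return self._pos[region_id]
        except KeyError:
            raise DataError(f"unknown region {region_id!r}") from None

    def weight_rows(self) -> list[np.ndarray]:
        """Per-region weight arrays aligned with :attr:`neighbors`."""
        if self.weight_mode == BINARY:
            return [np.ones(nb.size) for nb in self.neighbors]
        return [np.full(nb.size, 1.0 / nb.size) if nb.size else np.empty(0)
                for nb in self.neighbors]

    def to_sparse(self) -> sparse.csr_matrix:
        """The n x n weight matrix W in the current mode."""
        rows, cols, vals = [], [], []
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weight_rows())):
            rows.extend([i] * nb.size)
            cols.extend(nb.tolist())
            vals.extend(w.tolist())
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, self.n), dtype=float
        )

    def subgraph(self, keep_ids: Sequence[str]) -> "NeighborhoodStructure":
        """Restriction to ``keep_ids`` (in the given order); links leaving the
        subset are dropped, possibly creating islands."""
        keep = [str(r) for r in keep_ids]
        old_pos = [self.position(r) for r in keep]
        remap = {p: i for i, p in enumerate(old_pos)}
        nbrs = [
            np.array([remap[j] for j in self.neighbors[p] if j in remap], dtype=np.intp)
            for p in old_pos
        ]
        return NeighborhoodStructure(tuple(keep), tuple(nbrs), self.weight_mode)


def row_standardize(nbrs: NeighborhoodStructure) -> NeighborhoodStructure:
    """Row-standardized view: w_ij = 1/deg(i); island rows stay all-zero.

    Idempotent — applying it twice equals applying it once.
    """
    return replace(nbrs, weight_mode=ROW_STANDARDIZED)


def binary(nbrs: NeighborhoodStructure) -> NeighborhoodStructure:
    """Binary-weight view of the same relation."""
    return replace(nbrs, weight_mode=BINARY)


def from_edge_list(
    pairs: Iterable[tuple[str, str]], all_ids: Sequence[str]
) -> NeighborhoodStructure:
    """Build a binary symmetric structure from undirected id pairs.

    Regions in ``all_ids`` absent from ``pairs`` become islands.  Duplicate or
    reversed pairs collapse to a single link; self-edges are rejected.
    """
    ids = [str(r) for r in all_ids]
    pos = {r: i for i, r in enumerate(ids)}
    if len(pos) != len(ids):
        raise DataError("region identifiers must be unique")
    adj: list[set[int]] = [set() for _ in ids]
    for a, b in pairs:
        a, b = str(a), str(b)
        if a == b:
            raise DataError(f"self-edge ({a!r}, {b!r}) is not allowed")
        for r in (a, b):
            if r not in pos:
                raise DataError(f"edge references unknown region {r!r}")
        adj[pos[a]].add(pos[b])
        adj[pos[b]].add(pos[a])
    return NeighborhoodStructure(
        tuple(ids), tuple(np.array(sorted(s), dtype=np.intp) for s in adj)
    )


def lattice_rook(nrows: int, ncols: int) -> NeighborhoodStructure:
    """Rook contiguity on an ``nrows x ncols`` grid, cells in row-major order.

    Region ids are ``"r{row}c{col}"``; neighbours share a grid edge.
    """
    if nrows < 1 or ncols < 1:
        raise DataError("lattice dimensions must be >= 1")
    ids = [f"r{i}c{j}" for i in range(nrows) for j in range(ncols)]
    nbrs = []
    for i in range(nrows):
        for j in range(ncols):
            nb = []
            if i > 0:
                nb.append((i - 1) * ncols + j)
            if i < nrows - 1:
                nb.append((i + 1) * ncols + j)
            if j > 0:
                nb.append(i * ncols + j - 1)
            if j < ncols - 1:
                nb.append(i * ncols + j + 1)
            nbrs.append(np.array(sorted(nb), dtype=np.intp))
    return NeighborhoodStructure(tuple(ids), tuple(nbrs))


def lattice_centroids(nrows: int, ncols: int) -> np.ndarray:
    """Unit-spaced (x, y) centroids for :func:`lattice_rook`'s cell order."""
    return np.array(
        [(float(j), float(i)) for i in range(nrows) for j in range(ncols)]
    )


# -- GAL I/O ---------------------------------------------------------------

def read_gal(path) -> NeighborhoodStructure:
    """Read a GAL-dialect adjacency file.

    Layout: a header line whose last-but-one or only integer is the region
    count (both the bare ``n`` and the PySAL-style ``0 n ...`` headers are
    accepted), then for each region a line ``id k`` followed by a line with k
    neighbour ids (omitted or blank when k = 0).  Asymmetric input is
    symmetrized by union with a warning; an id that is referenced but never
    declared is a format error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty GAL file")
    header = lines[0].split()
    try:
        n = int(header[1]) if len(header) >= 2 and header[0] == "0" else int(header[0])
    except ValueError:
        raise FormatError(f"{path}: unreadable GAL header {lines[0]!r}") from None

    ids: list[str] = []
    listed: dict[str, list[str]] = {}
    k = 1
    while k < len(lines):
        head = lines[k].split()
        if len(head) != 2:
            raise FormatError(f"{path}: expected 'id count' line, got {lines[k]!r}")
        rid, cnt = head[0], head[1]
        try:
            cnt = int(cnt)
        except ValueError:
            raise FormatError(f"{path}: bad neighbour count on line {lines[k]!r}") from None
        k += 1
        if cnt == 0:
            nb = []
        else:
            if k >= len(lines):
                raise FormatError(f"{path}: truncated neighbour list for {rid!r}")
            nb = lines[k].split()
            if len(nb) != cnt:
                raise FormatError(
                    f"{path}: region {rid!r} declares {cnt} neighbours, lists {len(nb)}"
                )
            k += 1
        if rid in listed:
            raise FormatError(f"{path}: region {rid!r} declared twice")
        ids.append(rid)
        listed[rid] = nb
    if len(ids) != n:
        raise FormatError(f"{path}: header says {n} regions, found {len(ids)}")
    pos = {r: i for i, r in enumerate(ids)}
    for rid, nb in listed.items():
        for other in nb:
            if other not in pos:
                raise FormatError(f"{path}: neighbour {other!r} never declared")

    adj: list[set[int]] = [set() for _ in ids]
    asymmetric = False
    for rid, nb in listed.items():
        i = pos[rid]
        for other in nb:
            j = pos[other]
            if rid not in listed[other]:
                asymmetric = True
            adj[i].add(j)
            adj[j].add(i)
    if asymmetric:
        warnings.warn(
            f"{path}: asymmetric GAL links symmetrized by union", stacklevel=2
        )
        logger.warning("%s: asymmetric GAL links symmetrized by union", path)
    return NeighborhoodStructure(
        tuple(ids), tuple(np.array(sorted(s), dtype=np.intp) for s in adj)
    )


def write_gal(nbrs: NeighborhoodStructure, path) -> None:
    """Write the binary relation to a GAL file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{nbrs.n}\n")
        for rid, nb in zip(nbrs.region_ids, nbrs.neighbors):
            fh.write(f"{rid} {nb.size}\n")
            if nb.size:
                fh.write(" ".join(nbrs.region_ids[j] for j in nb) + "\n")


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read an undirected edge list from a two-column CSV (header optional)."""
    import csv

    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row_no, row in enumerate(csv.reader(fh)):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {row_no + 1} has fewer than 2 columns")
            a, b = row[0].strip(), row[1].strip()
            if row_no == 0 and {a.lower(), b.lower()} & {"from", "to", "id1", "id2", "source", "target"}:
                continue  # header row
            pairs.append((a, b))
    return pairs
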