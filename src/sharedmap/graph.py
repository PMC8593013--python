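"""Spatial neighbourhood graphs and intrinsic-CAR (Besag) structure matrices.

An :class:`AreaGraph` records which small areas share a border.  The induced
structure matrix ``R`` (degree on the diagonal, ``-1`` for each neighbour
pair) is the precision kernel of the intrinsic conditional autoregressive
prior used to smooth areal log-rates; its null space is spanned by the
indicator vectors of the connected components, which is why sum-to-zero
constraints are needed downstream.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp


@dataclasses.dataclass(frozen=True)
class AreaGraph:
    """An undirected contiguity graph over labelled areas.

    Parameters
    ----------
    area_ids
        Ordered area labels; their order is the canonical index order.
    edges
        Unordered neighbour pairs as ``(i, j)`` index tuples with ``i < j``.
    """

    area_ids: tuple[str, ...]
    edges: frozenset[tuple[int, int]]
    n_components: int = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        ids = tuple(self.area_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate area labels")
        norm = set()
        for e in self.edges:
            i, j = e
            if i == j:
                raise ValueError(f"self-edge on area index {i}")
            if not (0 <= i < len(ids) and 0 <= j < len(ids)):
                raise ValueError(f"edge {e} references an area index >= {len(ids)}")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "area_ids", ids)
        object.__setattr__(self, "edges", frozenset(norm))
        object.__setattr__(self, "n_components", nx.number_connected_components(self.to_networkx()))

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_areas, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.area_ids)))
        g.add_edges_from(self.edges)
        return g

    def component_labels(self) -> np.ndarray:
        """Component id per area, in area order."""
        lab = np.full(self.n_areas, -1, dtype=int)
        for c, comp in enumerate(nx.connected_components(self.to_networkx())):
            for i in comp:
                lab[i] = c
        return lab

    def reindex(self, area_ids: Sequence[str]) -> "AreaGraph":
        """Return the same graph with areas re-ordered to ``area_ids``.

        The canonical area order is the count table's; adjacency read from a
        file is re-indexed to it before any model is built.
        """
        if set(area_ids) != set(self.area_ids):
            missing = set(area_ids) ^ set(self.area_ids)
            raise ValueError(f"area sets differ; mismatched labels: {sorted(missing)}")
        pos = {a: k for k, a in enumerate(area_ids)}
        remap = [pos[a] for a in self.area_ids]
        edges = frozenset((min(remap[i], remap[j]), max(remap[i], remap[j])) for i, j in self.edges)
        return AreaGraph(tuple(area_ids), edges)


def read_adjacency(path: str | Path, area_ids: Sequence[str] | None = None) -> AreaGraph:
    """Read a whitespace-separated edge-list file into an :class:`AreaGraph`.

    One edge per line (``areaA areaB``); ``#`` starts a comment.  Orientation
    and duplicates are ignored.  If ``area_ids`` is given it fixes both the
    area set and order; otherwise areas are ordered by first appearance.
    """
    path = Path(path)
    tokens: list[tuple[str, str, int]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two area labels, got {len(parts)}")
            a, b = parts
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-edge on area {a!r}")
            tokens.append((a, b, lineno))
    if not tokens:
        raise ValueError(f"{path}: no edges found")

    if area_ids is not None:
        ids = tuple(area_ids)
        pos = {a: k for k, a in enumerate(ids)}
        for a, b, lineno in tokens:
            for lab in (a, b):
                if lab not in pos:
                    raise ValueError(f"{path}:{lineno}: unknown area {lab!r}")
    else:
        seen: dict[str, int] = {}
        for a, b, _ in tokens:
            for lab in (a, b):
                if lab not in seen:
                    seen[lab] = len(seen)
        ids = tuple(seen)
        pos = seen
    edges = frozenset(
        (min(pos[a], pos[b]), max(pos[a], pos[b])) for a, b, _ in tokens
    )
    return AreaGraph(ids, edges)


def load_spain_fixture() -> AreaGraph:
    """The packaged 47-province continental-Spain contiguity fixture."""
    ref = resources.files("sharedmap.data").joinpath("spain47_adjacency.txt")
    with resources.as_file(ref) as p:
        return read_adjacency(p)


@dataclasses.dataclass
class StructureMatrix:
    """ICAR structure matrix ``R`` plus the component structure behind it."""

    R: sp.csr_matrix
    n_components: int
    component_labels: np.ndarray

    _basis: tuple[np.ndarray, np.ndarray] | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    @property
    def n_areas(self) -> int:
        return self.R.shape[0]

    @property
    def rank(self) -> int:
        return self.n_areas - self.n_components

    def dense(self) -> np.ndarray:
        return self.R.toarray().astype(float)

    def eigenbasis(self, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal eigenvectors of ``R`` off its null space.

        Returns ``(A, lam)`` with ``A`` of shape ``(I, I - n_components)``
        and ``lam`` the matching positive eigenvalues.  ``kappa = A @ z``
        then satisfies the per-component sum-to-zero constraints exactly,
        and the ICAR quadratic form becomes ``sum(lam * z**2)``.
        """
        if self._basis is None:
            lam, V = np.linalg.eigh(self.dense())
            keep = lam > tol * max(1.0, lam.max())
            self._basis = (np.ascontiguousarray(V[:, keep]), lam[keep])
        return self._basis


def icar_structure(g: AreaGraph) -> StructureMatrix:
    """Build the ICAR structure matrix ``R`` from a contiguity graph.

    ``R[i, i]`` is the number of neighbours of area ``i`` and
    ``R[i, j] = -1`` iff ``{i, j}`` is an edge.  Rows sum to zero and the
    rank deficiency equals the number of connected components.  Isolated
    areas yield an all-zero row; whether that is acceptable is decided by
    the model layer, not here.
    """
    I = g.n_areas
    rows, cols, vals = [], [], []
    for i, j in g.edges:
        rows += [i, j]
        cols += [j, i]
        vals += [-1, -1]
    deg = g.degrees()
    rows += list(range(I))
    cols += list(range(I))
    vals += list(deg)
    R = sp.csr_matrix((vals, (rows, cols)), shape=(I, I), dtype=np.int64)
    return StructureMatrix(R=R, n_components=g.n_components, component_labels=g.component_labels())


def kron_two_block(struct: StructureMatrix) -> sp.csr_matrix:
    """The two-block precision ``I_2 (x) R`` (one ``R`` block per gender)."""
    return sp.kron(sp.identity(2, format="csr"), struct.R, format="csr")
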