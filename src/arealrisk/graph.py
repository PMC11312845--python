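"""Areal neighborhood graphs and the intrinsic CAR (ICAR) precision structure.

The structured spatial effect of a BYM model carries an intrinsic conditional
autoregressive prior whose precision pattern is ``Q = D - A`` (degree minus
adjacency).  ``Q`` is symmetric positive semi-definite with one null vector
per connected component; identifiability is restored by a per-component
sum-to-zero constraint on the effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely.strtree import STRtree

from .errors import GeometryError


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric areal neighbor structure.

    ids are ordered; ``neighbors[i]`` holds the ids adjacent to ``ids[i]``.
    Isolated areas are allowed and form singleton components.
    """

    ids: tuple[str, ...]
    neighbors: dict[str, frozenset[str]]
    component_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for a, nbrs in self.neighbors.items():
            if a in nbrs:
                raise GeometryError(f"self-loop at area {a}")
            for b in nbrs:
                if a not in self.neighbors[b]:
                    raise GeometryError(f"asymmetric adjacency: {a} -> {b}")
        if not self.component_of:
            g = nx.Graph()
            g.add_nodes_from(self.ids)
            g.add_edges_from(self.edges())
            comp_of = {}
            for label, comp in enumerate(nx.connected_components(g)):
                for a in comp:
                    comp_of[a] = label
            object.__setattr__(self, "component_of", comp_of)

    @property
    def n_areas(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.neighbors.values()) // 2

    @property
    def n_components(self) -> int:
        return len(set(self.component_of.values())) if self.ids else 0

    def degree(self, area_id: str) -> int:
        return len(self.neighbors[area_id])

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for a in self.ids:
            for b in self.neighbors[a]:
                if a < b:
                    out.append((a, b))
        return out

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "area_id": list(self.ids),
            "degree": [self.degree(a) for a in self.ids],
            "component": [self.component_of[a] for a in self.ids],
        })

    def write_edge_list(self, path: str | Path) -> None:
        lines = [f"{a} {b}" for a, b in sorted(self.edges())]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""),
                              encoding="utf-8")


def build_adjacency(source, rule: str = "queen",
                    ids: list[str] | None = None) -> AdjacencyGraph:
    """Build the neighbor graph from polygons or an edge list.

    Parameters
    ----------
    source : ``dict[area_id, shapely geometry]`` or an iterable of
        ``(a, b)`` edge tuples.
    rule : contiguity rule for polygon input — "queen" (a shared boundary
        point suffices) or "rook" (a shared boundary segment is required).
        Ignored for edge-list input.
    ids : for edge-list input, the full set of area ids (so isolated areas
        with no edges are represented); defaults to the ids seen in edges.
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule: {rule!r}")
    if isinstance(source, dict):
        return _from_polygons(source, rule)
    return _from_edges(list(source), ids)


def _from_polygons(geoms: dict, rule: str) -> AdjacencyGraph:
    if not geoms:
        raise GeometryError("empty geometry input")
    order = sorted(geoms)
    for aid in order:
        if not geoms[aid].is_valid:
            raise GeometryError(f"invalid geometry for area {aid}")
    glist = [geoms[a] for a in order]
    tree = STRtree(glist)
    nbrs: dict[str, set[str]] = {a: set() for a in order}
    pairs = tree.query(glist, predicate="intersects")
    for i, j in zip(*pairs):
        if i >= j:
            continue
        a, b = order[i], order[j]
        inter = glist[i].intersection(glist[j])
        if inter.is_empty:
            continue
        if rule == "rook" and inter.length == 0:
            continue  # point contact only
        nbrs[a].add(b)
        nbrs[b].add(a)
    return AdjacencyGraph(tuple(order), {a: frozenset(s) for a, s in nbrs.items()})


def _from_edges(edges: list[tuple[str, str]],
                ids: list[str] | None) -> AdjacencyGraph:
    seen: list[str] = []
    for a, b in edges:
        if a == b:
            raise GeometryError(f"self-loop at area {a}")
        seen.extend((a, b))
    if ids is None:
        order = sorted(set(seen))
    else:
        order = list(dict.fromkeys(str(i) for i in ids))
        unknown = set(seen) - set(order)
        if unknown:
            raise GeometryError(f"edge references unknown area ids: "
                                f"{', '.join(sorted(unknown))}")
    if not order:
        raise GeometryError("empty adjacency input")
    nbrs: dict[str, set[str]] = {a: set() for a in order}
    for a, b in edges:
        nbrs[a].add(b)
        nbrs[b].add(a)
    return AdjacencyGraph(tuple(order), {a: frozenset(s) for a, s in nbrs.items()})


def grid_polygons(nrows: int, ncols: int) -> dict:
    """Unit-square polygons on an nrows x ncols lattice, ids 'r{i}c{j}'."""
    from shapely.geometry import box

    return {f"r{i:02d}c{j:02d}": box(j, i, j + 1, i + 1)
            for i in range(nrows) for j in range(ncols)}


@dataclass(frozen=True)
class ICARStructure:
    """Sparse ICAR precision pattern with constraint metadata.

    ``Q = D - A`` over the graph's id ordering.  ``rank(Q) = n - c`` where c
    is the number of connected components; the constrained (per-component
    sum-to-zero) ICAR is proper on the complement of the null space.
    ``scaling_factor`` is the geometric mean of the constrained marginal
    variances — multiplying Q by it gives the "scaled" ICAR whose typical
    marginal variance is one.
    """

    ids: tuple[str, ...]
    Q: sp.csr_matrix
    components: np.ndarray          # component label per area, graph order
    scaling_factor: float

    @property
    def n_areas(self) -> int:
        return len(self.ids)

    @property
    def rank(self) -> int:
        return self.n_areas - len(np.unique(self.components))

    def component_indices(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.components == c)
                for c in np.unique(self.components)]


def icar_structure(graph: AdjacencyGraph,
                   max_dense: int = 2000) -> ICARStructure:
    """Assemble Q = D - A and the constrained-ICAR scaling factor."""
    n = graph.n_areas
    if n == 0:
        raise GeometryError("empty graph")
    index = {a: i for i, a in enumerate(graph.ids)}
    rows, cols = [], []
    for a, b in graph.edges():
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    Q = (sp.diags(deg) - A).tocsr()
    components = np.array([graph.component_of[a] for a in graph.ids])
    scaling = _scaling_factor(Q, components, max_dense)
    return ICARStructure(graph.ids, Q, components, scaling)


def _scaling_factor(Q: sp.csr_matrix, components: np.ndarray,
                    max_dense: int) -> float:
    """Geometric mean of constrained-ICAR marginal variances.

    Computed per non-singleton component from the eigendecomposition of the
    dense component block (generalized-inverse diagonal under the
    sum-to-zero constraint).  Singleton components carry no structured
    effect and are excluded; a graph of only singletons gets factor 1.
    """
    n = Q.shape[0]
    if n > max_dense:
        raise ValueError(f"scaling factor requires a dense eigensolve; "
                         f"graph has {n} > {max_dense} areas")
    log_vars: list[np.ndarray] = []
    for c in np.unique(components):
        idx = np.flatnonzero(components == c)
        if idx.size < 2:
            continue
        Qc = Q[np.ix_(idx, idx)].toarray()
        w, V = np.linalg.eigh(Qc)
        pos = w > w.max() * 1e-10
        ginv_diag = np.einsum("ij,j,ij->i", V[:, pos], 1.0 / w[pos], V[:, pos])
        log_vars.append(np.log(ginv_diag))
    if not log_vars:
        return 1.0
    return float(np.exp(np.mean(np.concatenate(log_vars))))


def sample_icar(structure: ICARStructure, tau: float,
                rng: np.random.Generator) -> np.ndarray:
    """Exact draw from the constrained ICAR prior with precision tau.

    Sampling is performed in the eigenbasis of each component block
    restricted to eigenvectors with positive eigenvalue (the pseudo-inverse
    square root), which enforces the per-component sum-to-zero constraint
    exactly.  Singleton components are fixed at zero.
    """
    n = structure.n_areas
    x = np.zeros(n)
    for idx in structure.component_indices():
        if idx.size < 2:
            continue
        Qc = structure.Q[np.ix_(idx, idx)].toarray()
        w, V = np.linalg.eigh(Qc)
        pos = w > w.max() * 1e-10
        z = rng.standard_normal(int(pos.sum()))
        x[idx] = V[:, pos] @ (z / np.sqrt(w[pos] * tau))
    return x
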