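"""Region adjacency graphs and the intrinsic CAR (ICAR) precision.

Spatial units (states/districts) enter the model through an undirected
contiguity graph. The intrinsic Gaussian Markov random field prior on the
spatial field f_s says that, conditional on its neighbours, the effect of
region s is normal with mean the neighbour average and variance tau^2 / N_s,
where N_s is the number of neighbours. Jointly this corresponds to an
(improper) Gaussian with precision proportional to the graph Laplacian
Q = diag(N_s) - A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp


@dataclass(frozen=True)
class RegionGraph:
    """Undirected adjacency over spatial units.

    Attributes
    ----------
    region_ids : tuple of str
        Stable ordering of the regions; all matrices follow this order.
    neighbors : dict
        Mapping region id -> tuple of neighbouring region ids.
    """

    region_ids: tuple
    neighbors: dict = field(hash=False)

    def __post_init__(self):
        ids = set(self.region_ids)
        if len(ids) != len(self.region_ids):
            raise ValueError("duplicate region ids")
        for s, nbrs in self.neighbors.items():
            if s not in ids:
                raise ValueError(f"neighbor list for unknown region {s!r}")
            if s in nbrs:
                raise ValueError(f"self-loop at region {s!r}")
            for t in nbrs:
                if t not in ids:
                    raise ValueError(f"unknown neighbor {t!r} of region {s!r}")
                if s not in self.neighbors.get(t, ()):
                    raise ValueError(f"asymmetric adjacency: {s!r} -> {t!r}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def neighbor_counts(self) -> np.ndarray:
        """N_s per region, in region_ids order."""
        return np.array([len(self.neighbors[s]) for s in self.region_ids])

    def index_of(self) -> dict:
        return {s: i for i, s in enumerate(self.region_ids)}

    def adjacency_matrix(self) -> sp.csr_matrix:
        idx = self.index_of()
        rows, cols = [], []
        for s, nbrs in self.neighbors.items():
            for t in nbrs:
                rows.append(idx[s])
                cols.append(idx[t])
        data = np.ones(len(rows))
        n = self.n_regions
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        for s, nbrs in self.neighbors.items():
            g.add_edges_from((s, t) for t in nbrs)
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def connected_components(self) -> list:
        return [sorted(c) for c in nx.connected_components(self.to_networkx())]


def make_lattice_graph(rows: int, cols: int) -> RegionGraph:
    """Rook-adjacency rectangular lattice with rows*cols regions.

    Serves as a stand-in contiguity graph when a real neighbour list is not
    supplied; region ids are "r<i>c<j>".
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice needs at least two regions")
    ids = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
    nbrs = {}
    for i in range(rows):
        for j in range(cols):
            cur = []
            if i > 0:
                cur.append(f"r{i-1}c{j}")
            if i < rows - 1:
                cur.append(f"r{i+1}c{j}")
            if j > 0:
                cur.append(f"r{i}c{j-1}")
            if j < cols - 1:
                cur.append(f"r{i}c{j+1}")
            nbrs[f"r{i}c{j}"] = tuple(cur)
    return RegionGraph(tuple(ids), nbrs)


def icar_precision(graph: RegionGraph) -> sp.csr_matrix:
    """Structure matrix Q = diag(N_s) - A of the intrinsic CAR prior.

    The full conditional implied by Q/tau^2 for node s given the rest is
    N(mean of the neighbours, tau^2 / N_s) — the standard ICAR conditional.
    Q is singular: row sums are zero, rank = n_regions - n_components.
    """
    adj = graph.adjacency_matrix()
    if (adj != adj.T).nnz:
        raise ValueError("asymmetric adjacency")
    deg = sp.diags(np.asarray(adj.sum(axis=1)).ravel())
    return (deg - adj).tocsr()


def write_neighbor_list(graph: RegionGraph, path) -> None:
    """Plain-text neighbour list: ``region_id: n_neighbors id id ...``"""
    with open(path, "w") as fh:
        for s in graph.region_ids:
            nbrs = graph.neighbors[s]
            fh.write(f"{s}: {len(nbrs)} " + " ".join(nbrs) + "\n")


def read_neighbor_list(path) -> RegionGraph:
    """Read the plain-text neighbour-list format written by write_neighbor_list."""
    ids = []
    nbrs = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            head, _, rest = line.partition(":")
            s = head.strip()
            toks = rest.split()
            if not toks:
                raise ValueError(f"malformed neighbour line for {s!r}")
            n = int(toks[0])
            lst = tuple(toks[1:])
            if len(lst) != n:
                raise ValueError(
                    f"region {s!r}: declared {n} neighbours, found {len(lst)}"
                )
            ids.append(s)
            nbrs[s] = lst
    return RegionGraph(tuple(ids), nbrs)
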