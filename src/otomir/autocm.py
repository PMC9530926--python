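"""Auto contractive map (AutoCM), MST projection and Spin Net queries.

The AutoCM is an unsupervised three-layer network trained on records scaled
to [0, 1].  Each variable has one input-to-hidden ("mono") connection and
the hidden layer is fully connected to the output layer; after training,
the hidden-to-output weight matrix encodes pairwise association strengths
among variables, conditioned on all the others.  Every variable enters
twice: as its scaled value (prefix ``Max_``) and as the complement to one
(prefix ``Min_``), so the map can represent negative associations as
proximity between a variable and another's complement.

Training is contractive: weights start near zero, grow monotonically under
non-negative inputs, and remain strictly below the contraction constant C.
The trained weight matrix is turned into distances d = 1 - w/C and
projected to a minimum spanning tree (Kruskal, deterministic lexicographic
tie-break).  Spin Net answers "what moves with this variable?" queries:
clamping a subset of variables at activation 1 and running damped label
propagation over the row-normalized weight matrix to its fixed point yields
an equilibrium activation for every variable, ranked descending.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ScaledDataset",
    "AutoCMModel",
    "AssociationGraph",
    "scale_with_complements",
    "train_autocm",
    "weights_to_distances",
    "minimum_spanning_tree",
    "spinnet_query",
    "export_graph",
    "import_graphml",
]

_GENOTYPE_LEVELS = ("wt", "het", "mut")


@dataclass
class ScaledDataset:
    """Records x variables in [0,1] with Max_/Min_ complement pairs."""

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if arr.size and (arr.min() < -1e-12 or arr.max() > 1 + 1e-12):
            raise ValueError("scaled data must lie in [0, 1]")


@dataclass
class AutoCMModel:
    C: float
    v: pd.Series  # mono (input->hidden) connection weights
    W: pd.DataFrame  # hidden->output full connection weights
    epochs_run: int
    convergence: list[float]  # mean |dW| per epoch

    @property
    def variables(self) -> list[str]:
        return list(self.W.index)


@dataclass
class AssociationGraph:
    graph: nx.Graph  # complete weighted graph (distance attribute)
    mst: nx.Graph
    mst_edges: list[tuple[str, str, float]]


def scale_with_complements(
    raw: pd.DataFrame, provenance: dict[str, str] | None = None
) -> ScaledDataset:
    """Min-max scale each variable to [0,1] and append complements.

    Categorical genotype columns (values among wt/het/mut) are expanded to
    per-variant indicator columns first.  Constant columns carry no
    information for the map and are dropped with a warning.  For every
    resulting variable x the output contains ``Max_x`` (scaled) and
    ``Min_x = 1 - Max_x``.
    """
    provenance = dict(provenance or {})
    cols: dict[str, np.ndarray] = {}
    for name in raw.columns:
        col = raw[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            values = set(col.astype(str))
            if not values <= set(_GENOTYPE_LEVELS):
                raise ValueError(
                    f"non-numeric column {name!r} with non-genotype values {values}"
                )
            for level in _GENOTYPE_LEVELS:
                if level in values:
                    cols[f"{name}_{level}"] = (col.astype(str) == level).to_numpy(float)
                    provenance.setdefault(f"{name}_{level}", provenance.get(name, "polymorphism"))
        else:
            cols[name] = col.to_numpy(dtype=float)

    out: dict[str, np.ndarray] = {}
    prov_out: dict[str, str] = {}
    for name, x in cols.items():
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            warnings.warn(f"dropping constant variable {name!r}", stacklevel=2)
            continue
        scaled = (x - lo) / (hi - lo)
        out[f"Max_{name}"] = scaled
        out[f"Min_{name}"] = 1.0 - scaled
        tag = provenance.get(name, "")
        prov_out[f"Max_{name}"] = tag
        prov_out[f"Min_{name}"] = tag
    if not out:
        raise ValueError("no non-constant variables to scale")
    return ScaledDataset(pd.DataFrame(out, index=raw.index), prov_out)


def train_autocm(
    data: ScaledDataset,
    C: float | None = None,
    max_epochs: int = 200,
    tol: float = 1e-6,
) -> AutoCMModel:
    """Train the auto contractive map on a [0,1]-scaled dataset.

    Per record m (presented in row order, once per epoch):

    - hidden      h_i   = m_i (1 - v_i / C)
    - mono update dv_i  = (m_i - h_i)(1 - v_i / C)
    - net input   Net_j = sum_i h_i (1 - W_ij / C)
    - output      out_j = h_j (1 - Net_j / C)
    - full update dW_ij = (h_i - out_i)(1 - W_ij / C) h_j

    C defaults to the number of records.  Training stops when the mean
    |dW| over an epoch drops below ``tol`` or after ``max_epochs``.
    Training is deterministic given the record order.
    """
    M = data.data.to_numpy(dtype=float)
    n_rec, n_var = M.shape
    if n_rec == 0:
        raise ValueError("empty dataset")
    C = float(C) if C is not None else float(n_rec)
    if C <= 0:
        raise ValueError("contraction constant C must be positive")

    v = np.full(n_var, C / 1e6)
    W = np.full((n_var, n_var), C / 1e6)
    history: list[float] = []
    epochs = 0
    for epoch in range(max_epochs):
        total = 0.0
        for m in M:
            h = m * (1.0 - v / C)
            dv = (m - h) * (1.0 - v / C)
            net = h @ (1.0 - W / C)  # Net_j = sum_i h_i (1 - W_ij/C)
            out = h * (1.0 - net / C)
            dW = np.outer((h - out), h) * (1.0 - W / C)
            if not (np.all(np.isfinite(dv)) and np.all(np.isfinite(dW))):
                raise FloatingPointError(f"non-finite update at epoch {epoch}")
            v = v + dv
            W = W + dW
            total += float(np.abs(dW).mean())
        history.append(total / n_rec)
        epochs = epoch + 1
        if history[-1] < tol:
            break
    if np.any(v >= C) or np.any(W >= C) or np.any(v < 0) or np.any(W < 0):
        raise FloatingPointError(
            "weights left [0, C); increase C (records should outnumber variables)"
        )
    names = list(data.data.columns)
    return AutoCMModel(
        C=C,
        v=pd.Series(v, index=names),
        W=pd.DataFrame(W, index=names, columns=names),
        epochs_run=epochs,
        convergence=history,
    )


def weights_to_distances(model: AutoCMModel) -> pd.DataFrame:
    """Symmetrized connection strengths mapped to distances in (0, 1].

    d_ij = 1 - Wbar_ij / C with Wbar = (W + W^T)/2; stronger connections
    are closer.  The diagonal is set to 0 and ignored downstream.
    """
    W = model.W.to_numpy(dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("non-finite weights")
    wbar = (W + W.T) / 2.0
    d = 1.0 - wbar / model.C
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=model.W.index, columns=model.W.columns)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(distances: pd.DataFrame) -> AssociationGraph:
    """Kruskal MST over a symmetric distance matrix.

    Edges are processed in (distance, u, v) order, so ties break
    lexicographically and the result is deterministic.
    """
    names = list(distances.index)
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate vertex name(s): {dupes}")
    if list(distances.columns) != names:
        raise ValueError("distance matrix must be square with matching labels")
    d = distances.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    full = nx.Graph()
    full.add_nodes_from(names)
    edges = []
    for i, u in enumerate(names):
        for j in range(i + 1, len(names)):
            vtx = names[j]
            edges.append((float(d[i, j]), u, vtx))
            full.add_edge(u, vtx, distance=float(d[i, j]))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))

    uf = _UnionFind(names)
    mst = nx.Graph()
    mst.add_nodes_from(names)
    mst_edges: list[tuple[str, str, float]] = []
    for dist, u, vtx in edges:
        if uf.union(u, vtx):
            mst.add_edge(u, vtx, distance=dist)
            mst_edges.append((u, vtx, dist))
            if len(mst_edges) == len(names) - 1:
                break
    if len(names) > 1 and len(mst_edges) != len(names) - 1:
        raise ValueError("distance matrix does not describe a connected graph")
    return AssociationGraph(graph=full, mst=mst, mst_edges=mst_edges)


def spinnet_query(
    model: AutoCMModel,
    clamped: list[str] | set[str],
    damping: float = 0.95,
    tol: float = 1e-6,
    max_cycles: int = 100000,
) -> tuple[pd.DataFrame, int]:
    """Equilibrium activations when a subset of variables is clamped at 1.

    The symmetrized weight matrix (diagonal removed) is row-normalized to
    transition weights; each variable then repeatedly takes the damped
    weighted average of its neighbours' activations,
    a_j <- damping * sum_i w_ji a_i, with clamped entries pinned at 1,
    starting from 1 on clamped and 0 elsewhere, until max |da| < tol.
    Because each row of w sums to 1 and damping < 1, the map is a
    sup-norm contraction: the equilibrium exists, is unique, lies in
    [0, 1] regardless of initialization, and the cycle count plays the
    role of the query network's depth.  Returns (table ranked by
    activation, cycles).
    """
    clamped = list(clamped)
    if not clamped:
        raise ValueError("at least one variable must be clamped")
    missing = [c for c in clamped if c not in model.variables]
    if missing:
        raise KeyError(f"clamped variable(s) not in model: {missing}")
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie strictly between 0 and 1")

    names = model.variables
    W = model.W.to_numpy(dtype=float)
    wbar = (W + W.T) / 2.0
    np.fill_diagonal(wbar, 0.0)
    rowsum = wbar.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    w = wbar / rowsum

    idx = [names.index(c) for c in clamped]
    a = np.zeros(len(names))
    a[idx] = 1.0
    cycles = 0
    for _ in range(max_cycles):
        new = damping * (w @ a)  # new_j = damping * sum_i w_ji a_i
        new[idx] = 1.0
        cycles += 1
        if np.max(np.abs(new - a)) < tol:
            a = new
            break
        a = new
    table = pd.DataFrame({"variable": names, "activation": a})
    table["clamped"] = table["variable"].isin(clamped)
    table = table.sort_values(
        ["activation", "clamped", "variable"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return table, cycles


def export_graph(
    graph: nx.Graph,
    directory: str | os.PathLike,
    name: str = "mst",
    annotations: dict[str, dict] | None = None,
) -> tuple[str, str]:
    """Write a graph as GraphML and DOT with vertex annotations.

    Annotations map vertex -> attribute dict (e.g. provenance tag); the
    Max_/Min_ prefix is recorded as a ``polarity`` attribute.  Returns the
    two file paths.  GraphML re-imports losslessly via
    :func:`import_graphml`.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty graph")
    names = list(graph.nodes)
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate vertex name(s): {dupes}")
    g = graph.copy()
    for node in g.nodes:
        attrs = dict((annotations or {}).get(node, {}))
        if str(node).startswith("Max_"):
            attrs.setdefault("polarity", "Max")
        elif str(node).startswith("Min_"):
            attrs.setdefault("polarity", "Min")
        g.nodes[node].update({k: v for k, v in attrs.items() if v is not None})

    os.makedirs(directory, exist_ok=True)
    graphml_path = os.path.join(directory, f"{name}.graphml")
    dot_path = os.path.join(directory, f"{name}.dot")
    nx.write_graphml(g, graphml_path)
    with open(dot_path, "w") as fh:
        fh.write("graph {\n")
        for node in sorted(g.nodes):
            attrs = g.nodes[node]
            label = ",".join(f'{k}="{v}"' for k, v in sorted(attrs.items()))
            fh.write(f'  "{node}" [{label}];\n' if label else f'  "{node}";\n')
        for u, vtx, data in sorted(g.edges(data=True)):
            dist = data.get("distance", "")
            fh.write(f'  "{u}" -- "{vtx}" [distance="{dist}"];\n')
        fh.write("}\n")
    return graphml_path, dot_path


def import_graphml(path: str | os.PathLike) -> nx.Graph:
    return nx.read_graphml(path)
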