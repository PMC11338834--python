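"""Thresholded gene graphs and multigraph Leiden module calling.

The averaged z-score matrix is thresholded (default z > 4.5) into a gene-gene
graph per eigenvalue power; connected components with fewer than four genes
are removed.  Graphs across powers p = 0, 0.25, 0.5, 0.75, 1 are combined by
multiplex Leiden clustering (RBConfiguration quality, equal layer weights)
into one partition; modules with at least ``min_report_size`` genes (default
10) are reported, smaller ones are kept with a sub-threshold flag.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd

from .zscore import ZScoreMatrix

logger = logging.getLogger("scdemon")

__all__ = [
    "GeneGraph",
    "ModuleSet",
    "build_graph",
    "layout_graph",
    "multigraph_leiden",
    "define_core_genes",
]

Z_CUT = 4.5
MIN_COMPONENT = 4
MIN_REPORT_SIZE = 10
RESOLUTION = 3.0
POWERS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class GeneGraph:
    """Gene-gene graph thresholded at a z cutoff, for one eigenvalue power."""

    graph: ig.Graph  # vertices carry 'name'; edges carry 'weight' (avg z)
    p: float = 0.0
    z_cut: float = Z_CUT
    layout: np.ndarray = None  # optional |V| x 2 coordinates

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.vs["name"]) if self.graph.vcount() else []

    @property
    def n_edges(self) -> int:
        return self.graph.ecount()

    def edge_set(self) -> set[tuple[str, str]]:
        names = self.graph.vs["name"] if self.graph.vcount() else []
        out = set()
        for e in self.graph.es:
            a, b = names[e.source], names[e.target]
            out.add((a, b) if a <= b else (b, a))
        return out

    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b) for a, b in sorted(self.edge_set())]
        w = {tuple(sorted((self.graph.vs["name"][e.source], self.graph.vs["name"][e.target]))): e["weight"] for e in self.graph.es}
        return pd.DataFrame(
            {"gene_i": [a for a, _ in rows], "gene_j": [b for _, b in rows],
             "weight": [w[(a, b)] for a, b in rows], "p": self.p}
        )

    def layout_table(self) -> pd.DataFrame:
        if self.layout is None:
            raise ValueError("graph has no layout; call layout_graph first")
        return pd.DataFrame({"gene": self.nodes, "x": self.layout[:, 0], "y": self.layout[:, 1]})


@dataclass
class ModuleSet:
    """Disjoint gene modules from one combined multigraph partition."""

    modules: dict[str, list[str]]  # reported modules only (>= min_report_size)
    resolution: float
    powers_used: list[float]
    min_report_size: int
    assignment: dict[str, str]  # every union-set gene -> module id
    sub_threshold: set[str] = field(default_factory=set)  # module ids < report size
    core_genes: dict[str, list[str]] = field(default_factory=dict)
    graphs: list[GeneGraph] = field(default_factory=list)

    @property
    def all_modules(self) -> dict[str, list[str]]:
        """Reported and sub-threshold modules together."""
        out = dict(self.modules)
        for g, m in self.assignment.items():
            if m in self.sub_threshold:
                out.setdefault(m, []).append(g)
        for m in self.sub_threshold:
            out[m] = sorted(out.get(m, []))
        return out

    def to_table(self) -> pd.DataFrame:
        rows = []
        for mid in sorted(self.modules, key=_module_sort_key):
            core = set(self.core_genes.get(mid, []))
            for gene in self.modules[mid]:
                rows.append((gene, mid, gene in core))
        return pd.DataFrame(rows, columns=["gene", "module", "is_core"])

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for mid in sorted(self.modules, key=_module_sort_key):
                genes = "\t".join(self.modules[mid])
                fh.write(f"{mid}\t{len(self.modules[mid])}_genes\t{genes}\n")


def _module_sort_key(mid: str):
    try:
        return (0, int(mid.lstrip("M")))
    except ValueError:
        return (1, mid)


def build_graph(
    z: ZScoreMatrix, z_cut: float = Z_CUT, min_component: int = MIN_COMPONENT, p: float = 0.0
) -> GeneGraph:
    """Threshold the z matrix into a graph and prune small components.

    An edge joins genes i, j iff ``z[i, j] > z_cut``; connected components
    with fewer than ``min_component`` genes (including isolated genes) are
    removed.  An empty result is valid and returned with a warning.
    """
    zm = z.z
    iu = np.triu_indices_from(zm, k=1)
    hits = zm[iu] > z_cut
    src, dst = iu[0][hits], iu[1][hits]
    used = np.unique(np.concatenate([src, dst])) if src.size else np.array([], dtype=int)
    g = ig.Graph()
    if used.size:
        remap = {int(v): i for i, v in enumerate(used)}
        g.add_vertices(len(used))
        g.vs["name"] = [str(z.gene_ids[v]) for v in used]
        g.add_edges([(remap[int(a)], remap[int(b)]) for a, b in zip(src, dst)])
        g.es["weight"] = zm[src, dst].tolist()
        comp = g.connected_components()
        small = [v.index for c in comp if len(c) < min_component for v in g.vs[c]]
        if small:
            g.delete_vertices(small)
    if g.vcount() == 0:
        logger.warning("graph empty after thresholding at z > %.2f", z_cut)
    return GeneGraph(graph=g, p=float(p), z_cut=z_cut)


def layout_graph(graph: GeneGraph, seed: int = 0) -> GeneGraph:
    """Fruchterman-Reingold layout, deterministic for a fixed seed."""
    g = graph.graph
    if g.vcount() == 0:
        raise ValueError("cannot lay out an empty graph")
    rng = np.random.default_rng(seed)
    init = rng.uniform(-1, 1, size=(g.vcount(), 2)).tolist()
    random.seed(seed)  # igraph draws from Python's RNG
    lay = g.layout_fruchterman_reingold(niter=500, seed=init)
    graph.layout = np.asarray(lay.coords)
    return graph


def multigraph_leiden(
    graphs: list[GeneGraph],
    resolution: float = RESOLUTION,
    min_report_size: int = MIN_REPORT_SIZE,
    seed: int = 0,
) -> ModuleSet:
    """One partition over the union gene set, optimized across all layers.

    Uses the Leiden algorithm with an RBConfiguration vertex partition per
    layer and equal layer weights.  Genes absent from a layer are isolated
    vertices there and contribute no edges.  Modules are numbered M1, M2,
    ... by decreasing size (ties broken by lexicographically smallest member
    gene); those below ``min_report_size`` stay in ``assignment`` flagged as
    sub-threshold.
    """
    nonempty = [gr for gr in graphs if gr.graph.vcount() > 0]
    if not nonempty:
        logger.warning("all layer graphs are empty; returning empty module set")
        return ModuleSet(
            modules={}, resolution=resolution, powers_used=[gr.p for gr in graphs],
            min_report_size=min_report_size, assignment={}, graphs=list(graphs),
        )
    union = sorted({name for gr in nonempty for name in gr.nodes})
    vidx = {name: i for i, name in enumerate(union)}
    layers = []
    for gr in nonempty:
        lg = ig.Graph()
        lg.add_vertices(len(union))
        lg.vs["name"] = union
        names = gr.graph.vs["name"]
        lg.add_edges([(vidx[names[e.source]], vidx[names[e.target]]) for e in gr.graph.es])
        layers.append(lg)
    membership, _ = la.find_partition_multiplex(
        layers,
        la.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        n_iterations=10,
        seed=int(seed),
    )
    groups: dict[int, list[str]] = {}
    for name, m in zip(union, membership):
        groups.setdefault(m, []).append(name)
    ordered = sorted(groups.values(), key=lambda gs: (-len(gs), min(gs)))
    modules, assignment, sub = {}, {}, set()
    for i, genes in enumerate(ordered, start=1):
        mid = f"M{i}"
        genes = sorted(genes)
        if len(genes) >= min_report_size:
            modules[mid] = genes
        else:
            sub.add(mid)
        for gname in genes:
            assignment[gname] = mid
    logger.info(
        "multigraph Leiden: %d reported modules (+%d sub-threshold) over %d genes",
        len(modules), len(sub), len(union),
    )
    return ModuleSet(
        modules=modules, resolution=resolution, powers_used=[gr.p for gr in graphs],
        min_report_size=min_report_size, assignment=assignment, sub_threshold=sub,
        graphs=list(graphs),
    )


def define_core_genes(
    modules: ModuleSet, graphs: list[GeneGraph] | None = None, top_fraction: float = 0.5
) -> ModuleSet:
    """Rank members by summed within-module edge weight across layers.

    Core genes are the top ``ceil(top_fraction * |m|)`` members (at least 5,
    capped at the module size); ties break lexicographically.
    """
    graphs = graphs if graphs is not None else modules.graphs
    wdeg: dict[str, dict[str, float]] = {}
    for gr in graphs:
        if gr.graph.vcount() == 0:
            continue
        names = gr.graph.vs["name"]
        for e in gr.graph.es:
            a, b = names[e.source], names[e.target]
            ma, mb = modules.assignment.get(a), modules.assignment.get(b)
            if ma is not None and ma == mb:
                wdeg.setdefault(ma, {}).setdefault(a, 0.0)
                wdeg.setdefault(ma, {}).setdefault(b, 0.0)
                wdeg[ma][a] += e["weight"]
                wdeg[ma][b] += e["weight"]
    core = {}
    for mid, genes in modules.modules.items():
        deg = wdeg.get(mid, {})
        ranked = sorted(genes, key=lambda gname: (-deg.get(gname, 0.0), gname))
        n_core = min(len(genes), max(5, math.ceil(top_fraction * len(genes))))
        core[mid] = ranked[:n_core]
    modules.core_genes = core
    return modules


def weighted_degree_table(modules: ModuleSet, graphs: list[GeneGraph] | None = None) -> pd.DataFrame:
    """Long table (gene, module, is_core, weighted_degree) for export."""
    graphs = graphs if graphs is not None else modules.graphs
    deg: dict[str, float] = {}
    for gr in graphs:
        if gr.graph.vcount() == 0:
            continue
        names = gr.graph.vs["name"]
        for e in gr.graph.es:
            a, b = names[e.source], names[e.target]
            if modules.assignment.get(a) == modules.assignment.get(b):
                deg[a] = deg.get(a, 0.0) + e["weight"]
                deg[b] = deg.get(b, 0.0) + e["weight"]
    rows = []
    for mid in sorted(modules.modules, key=_module_sort_key):
        core = set(modules.core_genes.get(mid, []))
        for gname in modules.modules[mid]:
            rows.append((gname, mid, gname in core, deg.get(gname, 0.0)))
    return pd.DataFrame(rows, columns=["gene", "module", "is_core", "weighted_degree"])
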