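"""Run configuration, presets, and the end-to-end pipeline driver."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .decorrelation import DEFAULT_K
from .graphs import (
    MIN_COMPONENT,
    MIN_REPORT_SIZE,
    POWERS,
    RESOLUTION,
    Z_CUT,
    build_graph,
    define_core_genes,
    layout_graph,
    multigraph_leiden,
    weighted_degree_table,
)
from .io import ExpressionMatrix, compute_sparsity, filter_genes, normalize, read_matrix
from .zscore import bootstrap_zscores

logger = logging.getLogger("scdemon")

__all__ = ["RunConfig", "run_pipeline", "discover_modules", "load_config"]

PRESETS = {
    "default": {},
    # parameters used unchanged across external published datasets
    "published-data": {"k": 100, "z_cut": 4.5, "resolution": 2.5},
}


@dataclass
class RunConfig:
    """All pipeline parameters; serialized verbatim into the run manifest."""

    matrix_path: str | None = None
    matrix_format: str = "mtx"
    meta_path: str | None = None
    out_dir: str = "scdemon_out"
    preset: str = "default"
    k: int = DEFAULT_K
    powers: tuple = POWERS
    z_cut: float = Z_CUT
    resolution: float = RESOLUTION
    n_boot: int = 10
    batch_fraction: float = 0.9
    min_fraction: float = 0.05
    min_component: int = MIN_COMPONENT
    min_report_size: int = MIN_REPORT_SIZE
    normalize_input: bool = True
    target_sum: float = 10_000.0
    seed: int = 0

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        for key, val in PRESETS[self.preset].items():
            setattr(self, key, val)
        self.powers = tuple(float(p) for p in self.powers)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["powers"] = list(self.powers)
        return d

    def manifest(self) -> dict:
        params = self.to_dict()
        digest = hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"version": __version__, "parameters": params, "parameter_hash": digest}


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML config; keyword arguments (CLI flags) take precedence."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)


def discover_modules(X: ExpressionMatrix, config: RunConfig):
    """normalize -> filter -> bootstrap z -> per-power graphs -> modules.

    Returns the :class:`~scdemon.graphs.ModuleSet` (with its layer graphs
    attached).  ``run_pipeline`` wraps this with file I/O.
    """
    if config.normalize_input and not X.normalized:
        logger.info("[io] normalizing to %g counts per cell + log1p", config.target_sum)
        X = normalize(X, target_sum=config.target_sum)
    sp_ = compute_sparsity(X)
    X = filter_genes(X, sp_, min_fraction=config.min_fraction)
    logger.info("[io] %d cells x %d genes after gene filter", X.n_cells, X.n_genes)

    logger.info(
        "[zscore] %d bootstraps of %.0f%% of batches, k=%d, powers=%s",
        config.n_boot, 100 * config.batch_fraction, config.k, list(config.powers),
    )
    z_by_p = bootstrap_zscores(
        X,
        p=list(config.powers),
        k=min(config.k, min(X.values.shape) - 1),
        n_boot=config.n_boot,
        batch_fraction=config.batch_fraction,
        seed=config.seed,
    )

    graphs = []
    for p, zs in z_by_p.items():
        gr = build_graph(zs, z_cut=config.z_cut, min_component=config.min_component, p=p)
        logger.info("[graph] p=%.2f: %d genes, %d edges", p, gr.graph.vcount(), gr.n_edges)
        if gr.graph.vcount():
            layout_graph(gr, seed=config.seed)
        graphs.append(gr)

    modules = multigraph_leiden(
        graphs,
        resolution=config.resolution,
        min_report_size=config.min_report_size,
        seed=config.seed,
    )
    return define_core_genes(modules, graphs)


def run_pipeline(config: RunConfig, X: ExpressionMatrix | None = None) -> Path:
    """End-to-end run with file outputs.

    Writes module tables, per-power edge lists, layouts, and a manifest to
    ``config.out_dir``; reruns with the same manifest produce byte-identical
    tables.  Returns the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if X is None:
        logger.info("[io] reading %s", config.matrix_path)
        X = read_matrix(config.matrix_path, format=config.matrix_format, meta_path=config.meta_path)
    modules = discover_modules(X, config)
    _write_outputs(out, config, modules.graphs, modules)
    logger.info("[done] %d modules written to %s", len(modules.modules), out)
    return out


def _write_outputs(out: Path, config: RunConfig, graphs, modules) -> None:
    weighted_degree_table(modules, graphs).to_csv(out / "modules.tsv", sep="\t", index=False)
    modules.write_gmt(out / "modules.gmt")
    for gr in graphs:
        tag = f"p{gr.p:g}".replace(".", "_")
        gr.edge_table().to_csv(out / f"edges_{tag}.tsv", sep="\t", index=False)
        if gr.layout is not None:
            gr.layout_table().to_csv(out / f"layout_{tag}.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(config.manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")
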