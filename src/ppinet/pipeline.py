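"""End-to-end orchestration: source -> build -> topology -> communities
-> enrichment, with a declarative config, deterministic writers and a
replayable run log.

Every output table is sorted and printed with full-precision ``repr``
floats, so identical config + identical inputs give byte-identical
artifacts.  The run log records every parameter, the SHA-256 of every
input file and the Louvain seed; it contains no timestamps, keeping
repeated runs byte-stable too.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, fields
from typing import Any, TextIO

import yaml

from . import communities as comm_mod
from . import enrichment as enr_mod
from . import interaction_source as src_mod
from . import network_build as net_mod
from . import topology as top_mod
from .errors import ConfigurationError, PPINetError


@dataclass
class RunConfig:
    """Flat declarative configuration; precedence CLI > file > defaults."""

    seed_list: str = ""
    interactions: str = ""
    score_scale: str = "unit"
    score_threshold: float = src_mod.DEFAULT_SCORE_THRESHOLD
    prune_isolates: bool = True
    max_partners_per_seed: int | None = None
    gamma: float = 1.0
    louvain_seed: int = comm_mod.DEFAULT_LOUVAIN_SEED
    weighted_louvain: bool = True
    gmt: list[str] = field(default_factory=list)
    universe: str = "union"
    alpha: float = enr_mod.DEFAULT_ALPHA
    top_k: int = 5
    make_plots: bool = False
    output_dir: str = "ppinet_out"

    def validate(self, require_interactions: bool = True) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ConfigurationError(
                f"score_threshold {self.score_threshold!r} outside [0, 1]"
            )
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigurationError(f"alpha {self.alpha!r} outside (0, 1]")
        if self.score_scale not in ("unit", "per_mille"):
            raise ConfigurationError(f"unknown score_scale {self.score_scale!r}")
        if self.top_k < 1:
            raise ConfigurationError(f"top_k must be >= 1, got {self.top_k}")
        if require_interactions and not self.interactions:
            raise ConfigurationError("no interaction source configured")
        if not self.seed_list:
            raise ConfigurationError("no seed list configured")

    @classmethod
    def from_file(cls, path: str, **overrides: Any) -> "RunConfig":
        """Load a flat YAML mapping, then apply keyword overrides."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path!r} is not a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class RunResult:
    network: net_mod.Network
    metrics: dict[str, top_mod.NodeMetrics]
    globals: top_mod.GlobalMetrics
    partition: comm_mod.Partition
    enrichments: dict[str, list[enr_mod.EnrichmentResult]]
    paths: dict[str, str]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, exc: Exception) -> PPINetError:
    return PPINetError(f"stage '{name}': {exc}")


def summarize_top_hubs(
    metrics: dict[str, top_mod.NodeMetrics], k: int = 5
) -> str:
    """Four ranked top-k hub lists (degree, betweenness, closeness,
    eigenvector), values rendered to 4 decimals."""
    sections = [
        ("Degree Centrality", {u: m.degree_centrality for u, m in metrics.items()}),
        ("Betweenness Centrality", {u: m.betweenness for u, m in metrics.items()}),
        ("Closeness Centrality", {u: m.closeness for u, m in metrics.items()}),
        ("Eigenvector Centrality", {u: m.eigenvector for u, m in metrics.items()}),
    ]
    lines: list[str] = []
    for title, values in sections:
        lines.append(f"Top {k} by {title}")
        for node, value in top_mod.top_k(values, k):
            lines.append(f"  {node}: {value:.4f}")
    return "\n".join(lines) + "\n"


def _write_global_summary(
    gm: top_mod.GlobalMetrics,
    partition: comm_mod.Partition,
    stream: TextIO,
) -> None:
    sizes = comm_mod.community_sizes(partition)
    stream.write(f"n_nodes={gm.n_nodes}\n")
    stream.write(f"n_edges={gm.n_edges}\n")
    stream.write(f"density={gm.density!r}\n")
    stream.write(f"avg_clustering={gm.avg_clustering!r}\n")
    diameter = "undefined" if gm.diameter_lcc is None else gm.diameter_lcc
    avg_path = (
        "undefined"
        if gm.avg_shortest_path_lcc is None
        else repr(gm.avg_shortest_path_lcc)
    )
    stream.write(f"diameter_lcc={diameter}\n")
    stream.write(f"avg_shortest_path_lcc={avg_path}\n")
    stream.write(f"n_communities={partition.n_communities}\n")
    stream.write(f"modularity={partition.modularity!r}\n")
    stream.write(f"louvain_seed={partition.rng_seed}\n")
    stream.write(f"gamma={partition.resolution!r}\n")
    stream.write(
        "community_sizes="
        + ",".join(f"{c}:{s}" for c, s in sorted(sizes.items()))
        + "\n"
    )


def _reconstruct_command(config: RunConfig) -> str:
    parts = [
        "ppinet run",
        f"--seed-list {config.seed_list}",
        f"--interactions {config.interactions}",
        f"--score-scale {config.score_scale}",
        f"--score-threshold {config.score_threshold!r}",
        f"--gamma {config.gamma!r}",
        f"--louvain-seed {config.louvain_seed}",
        f"--universe {config.universe}",
        f"--alpha {config.alpha!r}",
        f"--top-k {config.top_k}",
        f"--out {config.output_dir}",
    ]
    for path in config.gmt:
        parts.append(f"--gmt {path}")
    if not config.prune_isolates:
        parts.append("--keep-isolates")
    if not config.weighted_louvain:
        parts.append("--unweighted-louvain")
    if config.max_partners_per_seed is not None:
        parts.append(f"--max-partners-per-seed {config.max_partners_per_seed}")
    return " ".join(parts)


def run_pipeline(
    config: RunConfig,
    provider: src_mod.InteractionProvider | None = None,
) -> RunResult:
    """Run the full analysis and write the report bundle.

    A provider object may replace the file-backed interaction source
    (``config.interactions``); errors in any stage propagate with the
    stage name attached.
    """
    config.validate(require_interactions=provider is None)
    log_lines: list[str] = ["# ppinet run log"]
    for f in fields(config):
        log_lines.append(f"param.{f.name}={getattr(config, f.name)!r}")

    try:
        with open(config.seed_list, encoding="utf-8") as fh:
            seeds = src_mod.read_seed_list(fh)
        log_lines.append(f"checksum.seed_list={_sha256(config.seed_list)}")
    except OSError as exc:
        raise _stage("read_seeds", exc) from exc

    try:
        if provider is None:
            provider = src_mod.FileProvider(config.interactions, config.score_scale)
        if config.interactions:
            log_lines.append(
                f"checksum.interactions={_sha256(config.interactions)}"
            )
        params = getattr(provider, "last_request_params", None)
        records = src_mod.fetch_first_shell(
            seeds,
            provider,
            threshold=config.score_threshold,
            max_partners_per_seed=config.max_partners_per_seed,
        )
        params = getattr(provider, "last_request_params", params)
        if params:
            for key, value in sorted(params.items()):
                log_lines.append(f"provider.{key}={value}")
    except PPINetError as exc:
        raise _stage("interaction_source", exc) from exc

    if not records:
        raise PPINetError(
            "network is empty after filtering at combined-score threshold "
            f"{config.score_threshold}; lower the threshold or check the "
            "score scale"
        )

    net = net_mod.build_network(records, seeds, prune_isolates=config.prune_isolates)
    if net.pruned_isolates:
        log_lines.append("pruned_isolates=" + ",".join(net.pruned_isolates))
    missing = [s for s in seeds if s not in net and s not in net.pruned_isolates]
    if missing:
        log_lines.append("seeds_without_interactions=" + ",".join(sorted(missing)))
    log_lines.append(f"network.n_nodes={net.n_nodes}")
    log_lines.append(f"network.n_edges={net.n_edges}")

    try:
        metrics = top_mod.compute_node_metrics(net)
        gm = top_mod.global_metrics(net)
    except PPINetError as exc:
        raise _stage("topology", exc) from exc

    try:
        partition = comm_mod.louvain(
            net,
            gamma=config.gamma,
            rng_seed=config.louvain_seed,
            weighted=config.weighted_louvain,
        )
    except PPINetError as exc:
        raise _stage("communities", exc) from exc

    enrichments: dict[str, list[enr_mod.EnrichmentResult]] = {}
    query = net.nodes
    for gmt_path in config.gmt:
        try:
            with open(gmt_path, encoding="utf-8") as fh:
                library = enr_mod.read_gmt(fh)
            log_lines.append(f"checksum.gmt.{os.path.basename(gmt_path)}={_sha256(gmt_path)}")
            if config.universe == "union":
                universe = library.universe()
                log_lines.append(
                    f"universe.{os.path.basename(gmt_path)}=union of library genes"
                )
            else:
                with open(config.universe, encoding="utf-8") as fh:
                    universe = frozenset(src_mod.read_seed_list(fh))
                log_lines.append(f"checksum.universe={_sha256(config.universe)}")
            lib_name = os.path.splitext(os.path.basename(gmt_path))[0]
            enrichments[lib_name] = enr_mod.enrich(
                query, library, universe, alpha=config.alpha
            )
        except (PPINetError, OSError) as exc:
            raise _stage(f"enrichment[{gmt_path}]", exc) from exc

    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def _out(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    with open(_out("node_metrics.tsv"), "w", encoding="utf-8") as fh:
        top_mod.write_node_metrics(net, metrics, partition.assignment, fh)
    with open(_out("global_metrics.txt"), "w", encoding="utf-8") as fh:
        _write_global_summary(gm, partition, fh)
    with open(_out("partition.tsv"), "w", encoding="utf-8") as fh:
        comm_mod.write_partition(partition, fh)
    with open(_out("edge_list.tsv"), "w", encoding="utf-8") as fh:
        net_mod.write_edge_list(net, fh)
    with open(_out("network.graphml"), "w", encoding="utf-8") as fh:
        net_mod.write_graphml(net, fh)
    with open(_out("hub_summary.txt"), "w", encoding="utf-8") as fh:
        fh.write(summarize_top_hubs(metrics, config.top_k))
    for lib_name, results in enrichments.items():
        with open(_out(f"enrichment_{lib_name}.tsv"), "w", encoding="utf-8") as fh:
            enr_mod.write_enrichment_report(results, fh)
        if config.make_plots:
            enr_mod.plot_enrichment_bars(
                results, os.path.join(outdir, f"enrichment_{lib_name}.png")
            )

    log_lines.append("command=" + _reconstruct_command(config))
    with open(_out("run_log.txt"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return RunResult(
        network=net,
        metrics=metrics,
        globals=gm,
        partition=partition,
        enrichments=enrichments,
        paths=paths,
    )
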