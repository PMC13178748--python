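"""Ground-truthed synthetic inputs for the whole pipeline.

The generator plants exactly the structures the analysis claims to
detect: a stochastic block model gives non-overlapping modules with
dense intra-module wiring (edge probability ``p_in``) and sparse
inter-module wiring (``p_out``); designated hub nodes get extra
uniformly-chosen partners; combined scores are uniform on
``[score_low, score_high]`` (above the high-confidence threshold by
default); and the GMT library spikes one gene set per module with that
module's members, hidden among random decoy sets.  Everything is driven
by a single seeded NumPy stream with a documented draw order (intra
edges, inter edges, hubs, scores, library, seed panel), so a spec plus
seed reproduces byte-identical fixture bundles.

The default specification mirrors a small seed-protein interactome
study: ~90 proteins in 8 modules, ~220 expected high-confidence edges,
and an 18-protein seed panel (10 hubs plus one member per module).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np

from .enrichment import GeneSetCollection
from .errors import ConfigurationError
from .interaction_source import InteractionRecord, write_interactions_tsv


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the generator; invariants checked on construction."""

    n_modules: int = 8
    module_sizes: tuple[int, ...] = (14, 13, 12, 12, 11, 10, 9, 9)
    p_in: float = 0.36
    p_out: float = 0.005
    hub_count: int = 10
    hub_extra_degree: int = 3
    score_low: float = 0.700
    score_high: float = 0.999
    universe_size: int = 1000
    planted_set_overlap: int = 8
    decoy_set_count: int = 49
    decoy_set_size: int = 40
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ConfigurationError(
                f"module_sizes has {len(self.module_sizes)} entries "
                f"for n_modules={self.n_modules}"
            )
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ConfigurationError(
                f"need 0 <= p_out < p_in <= 1; got p_in={self.p_in}, p_out={self.p_out}"
            )
        if not 0.0 <= self.score_low <= self.score_high <= 1.0:
            raise ConfigurationError(
                f"score range [{self.score_low}, {self.score_high}] invalid"
            )
        if any(s < 1 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be >= 1")
        if self.universe_size < self.n_nodes:
            raise ConfigurationError(
                f"universe_size {self.universe_size} < node count {self.n_nodes}"
            )
        if self.hub_count > self.n_nodes or self.hub_count < 0:
            raise ConfigurationError(f"hub_count {self.hub_count} out of range")
        if self.planted_set_overlap > self.decoy_set_size:
            raise ConfigurationError(
                "planted_set_overlap cannot exceed decoy_set_size"
            )

    @property
    def n_nodes(self) -> int:
        return sum(self.module_sizes)

    @classmethod
    def planted_partition_benchmark(cls, rng_seed: int = 1) -> "SyntheticSpec":
        """The 4-block planted-partition benchmark (4 x 15 nodes,
        p_in = 0.30, p_out = 0.01, no hubs) used for community-recovery
        calibration."""
        return cls(
            n_modules=4,
            module_sizes=(15, 15, 15, 15),
            p_in=0.30,
            p_out=0.01,
            hub_count=0,
            hub_extra_degree=0,
            rng_seed=rng_seed,
        )


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream."""

    planted_assignment: dict[str, int]
    planted_hubs: frozenset[str]
    planted_edges: list[InteractionRecord]
    planted_enriched_terms: frozenset[str] = frozenset()
    planted_term_modules: dict[str, int] = field(default_factory=dict)
    seed_panel: tuple[str, ...] = ()


def _node_names(spec: SyntheticSpec) -> list[str]:
    return [f"G{i:03d}" for i in range(spec.n_nodes)]


def _background_names(spec: SyntheticSpec) -> list[str]:
    return [f"B{i:04d}" for i in range(spec.universe_size - spec.n_nodes)]


def generate_planted_network(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[list[InteractionRecord], GroundTruth]:
    """Sample the SBM-plus-hubs graph; fully determined by the seed."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    nodes = _node_names(spec)
    assignment: dict[str, int] = {}
    offset = 0
    modules: list[list[str]] = []
    for m, size in enumerate(spec.module_sizes):
        members = nodes[offset : offset + size]
        modules.append(members)
        for u in members:
            assignment[u] = m
        offset += size
    edges: set[tuple[str, str]] = set()
    # draw order 1: intra-module pairs, module by module, sorted pairs
    for members in modules:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < spec.p_in:
                    edges.add((members[i], members[j]))
    # draw order 2: inter-module pairs, global sorted order
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            u, v = nodes[i], nodes[j]
            if assignment[u] != assignment[v] and rng.random() < spec.p_out:
                edges.add((u, v))
    # draw order 3: hub selection, then extra wiring per hub
    hubs: list[str] = []
    if spec.hub_count:
        hubs = sorted(rng.choice(nodes, size=spec.hub_count, replace=False).tolist())
        for h in hubs:
            neighbors = {v for u, v in edges if u == h} | {
                u for u, v in edges if v == h
            }
            candidates = [v for v in nodes if v != h and v not in neighbors]
            extra = min(spec.hub_extra_degree, len(candidates))
            if extra:
                for v in rng.choice(candidates, size=extra, replace=False).tolist():
                    edges.add((h, v) if h <= v else (v, h))
    # draw order 4: scores, canonical edge order
    records = [
        InteractionRecord(u, v, float(rng.uniform(spec.score_low, spec.score_high)))
        for u, v in sorted(edges)
    ]
    truth = GroundTruth(
        planted_assignment=assignment,
        planted_hubs=frozenset(hubs),
        planted_edges=records,
    )
    return records, truth


def generate_gene_set_library(
    truth: GroundTruth,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """One spiked set per module plus uniform decoy sets.

    Set names are a uniform ``GS###`` sequence: nothing in the GMT text
    marks which sets are planted — only the GroundTruth does.  Fillers
    for a planted set are drawn outside its module, so the module/set
    overlap equals ``planted_set_overlap`` exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    modules: dict[int, list[str]] = {}
    for node, m in truth.planted_assignment.items():
        modules.setdefault(m, []).append(node)
    universe = sorted(truth.planted_assignment) + _background_names(spec)
    coll = GeneSetCollection()
    planted_names: list[str] = []
    idx = 0
    # draw order 5a: planted sets, module order
    for m in sorted(modules):
        members = sorted(modules[m])
        if spec.planted_set_overlap > len(members):
            raise ConfigurationError(
                f"planted_set_overlap {spec.planted_set_overlap} exceeds "
                f"module {m} size {len(members)}"
            )
        core = rng.choice(members, size=spec.planted_set_overlap, replace=False)
        pool = [g for g in universe if truth.planted_assignment.get(g) != m]
        n_fill = spec.decoy_set_size - spec.planted_set_overlap
        fill = rng.choice(pool, size=n_fill, replace=False) if n_fill else []
        name = f"GS{idx:03d}"
        idx += 1
        coll.add(name, f"synthetic set {name}", list(core) + list(fill))
        planted_names.append(name)
        truth.planted_term_modules[name] = m
    # draw order 5b: decoy sets
    for _ in range(spec.decoy_set_count):
        name = f"GS{idx:03d}"
        idx += 1
        genes = rng.choice(universe, size=spec.decoy_set_size, replace=False)
        coll.add(name, f"synthetic set {name}", list(genes))
    truth.planted_enriched_terms = frozenset(planted_names)
    return coll


def _pick_seed_panel(
    truth: GroundTruth, spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[str, ...]:
    """Hub nodes plus one random non-hub member per module (draw order 6)."""
    modules: dict[int, list[str]] = {}
    for node, m in truth.planted_assignment.items():
        modules.setdefault(m, []).append(node)
    panel = list(sorted(truth.planted_hubs))
    for m in sorted(modules):
        pool = [g for g in sorted(modules[m]) if g not in truth.planted_hubs]
        if pool:
            panel.append(str(rng.choice(pool)))
    return tuple(panel)


def write_manifest(
    truth: GroundTruth, spec: SyntheticSpec, stream: TextIO
) -> None:
    """Flat key=value ground-truth manifest (lossless round-trip)."""
    stream.write(f"rng_seed={spec.rng_seed}\n")
    stream.write(f"n_modules={spec.n_modules}\n")
    stream.write(f"module_sizes={','.join(map(str, spec.module_sizes))}\n")
    stream.write(f"p_in={spec.p_in!r}\n")
    stream.write(f"p_out={spec.p_out!r}\n")
    stream.write(f"n_nodes={len(truth.planted_assignment)}\n")
    stream.write(f"n_edges={len(truth.planted_edges)}\n")
    stream.write(
        "assignment="
        + ",".join(f"{u}:{c}" for u, c in sorted(truth.planted_assignment.items()))
        + "\n"
    )
    stream.write("hubs=" + ",".join(sorted(truth.planted_hubs)) + "\n")
    stream.write("seed_panel=" + ",".join(truth.seed_panel) + "\n")
    stream.write(
        "planted_terms=" + ",".join(sorted(truth.planted_enriched_terms)) + "\n"
    )
    stream.write(
        "planted_term_modules="
        + ",".join(f"{t}:{m}" for t, m in sorted(truth.planted_term_modules.items()))
        + "\n"
    )


def read_manifest(stream: TextIO) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key] = value
    return out


def truth_from_manifest(
    manifest: dict[str, str], records: list[InteractionRecord]
) -> GroundTruth:
    """Rebuild a GroundTruth from a manifest plus the parsed edge table."""
    assignment = {}
    if manifest.get("assignment"):
        for item in manifest["assignment"].split(","):
            node, _, comm = item.partition(":")
            assignment[node] = int(comm)
    term_modules = {}
    if manifest.get("planted_term_modules"):
        for item in manifest["planted_term_modules"].split(","):
            term, _, m = item.partition(":")
            term_modules[term] = int(m)
    return GroundTruth(
        planted_assignment=assignment,
        planted_hubs=frozenset(
            h for h in manifest.get("hubs", "").split(",") if h
        ),
        planted_edges=list(records),
        planted_enriched_terms=frozenset(
            t for t in manifest.get("planted_terms", "").split(",") if t
        ),
        planted_term_modules=term_modules,
        seed_panel=tuple(
            s for s in manifest.get("seed_panel", "").split(",") if s
        ),
    )


def generate_fixture_bundle(
    spec: SyntheticSpec, outdir: str
) -> dict[str, str]:
    """Write a complete offline input bundle; byte-identical per (spec, seed).

    Emits ``seeds.txt``, ``interactions.tsv`` (unit-scale scores, exact
    round-trip), ``library.gmt`` and ``manifest.txt``; returns the
    manifest mapping with file paths added.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)
    records, truth = generate_planted_network(spec, rng)
    library = generate_gene_set_library(truth, spec, rng)
    truth.seed_panel = _pick_seed_panel(truth, spec, rng)

    from .enrichment import write_gmt  # local to avoid cycle at import time

    paths = {
        "seeds": os.path.join(outdir, "seeds.txt"),
        "interactions": os.path.join(outdir, "interactions.tsv"),
        "gmt": os.path.join(outdir, "library.gmt"),
        "manifest": os.path.join(outdir, "manifest.txt"),
    }
    with open(paths["seeds"], "w", encoding="utf-8") as fh:
        fh.write("# synthetic seed panel\n")
        for s in truth.seed_panel:
            fh.write(s + "\n")
    with open(paths["interactions"], "w", encoding="utf-8") as fh:
        write_interactions_tsv(records, fh, score_scale="unit")
    with open(paths["gmt"], "w", encoding="utf-8") as fh:
        write_gmt(library, fh)
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        write_manifest(truth, spec, fh)
    with open(paths["manifest"], encoding="utf-8") as fh:
        manifest = read_manifest(fh)
    manifest.update({f"path_{k}": v for k, v in paths.items()})
    return manifest
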