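"""ppinet: seed-protein interaction-network analysis.

Builds a weighted undirected protein-protein interaction graph from a
seed-gene panel and STRING-dialect interaction tables, characterizes it
with from-scratch centrality and clustering metrics, partitions it with
a from-scratch Louvain modularity optimizer, and runs local gene-set
over-representation analysis — all offline, with a ground-truthed
synthetic-data generator for benchmarking every stage.
"""

from importlib import resources

from .communities import (
    DEFAULT_LOUVAIN_SEED,
    Partition,
    community_sizes,
    louvain,
    modularity,
    write_partition,
)
from .enrichment import (
    DEFAULT_ALPHA,
    EnrichmentResult,
    GeneSetCollection,
    bh_adjust,
    enrich,
    fisher_overrep,
    plot_enrichment_bars,
    read_gmt,
    write_enrichment_report,
    write_gmt,
)
from .errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateInputError,
    DuplicateTermError,
    MalformedInputError,
    PPINetError,
    SourceUnavailableError,
    UndefinedMetricError,
)
from .interaction_source import (
    DEFAULT_SCORE_THRESHOLD,
    FileProvider,
    InMemoryProvider,
    InteractionRecord,
    StringApiProvider,
    fetch_first_shell,
    filter_by_score,
    normalize_symbol,
    parse_interactions_tsv,
    read_seed_list,
    records_from_text,
    write_interactions_tsv,
)
from .network_build import (
    Network,
    build_network,
    connected_components,
    largest_connected_component,
    write_edge_list,
    write_graphml,
)
from .pipeline import RunConfig, RunResult, run_pipeline, summarize_top_hubs
from .synthetic_data import (
    GroundTruth,
    SyntheticSpec,
    generate_fixture_bundle,
    generate_gene_set_library,
    generate_planted_network,
    read_manifest,
    truth_from_manifest,
    write_manifest,
)
from .topology import (
    GlobalMetrics,
    NodeMetrics,
    betweenness_centrality,
    closeness_centrality,
    compute_node_metrics,
    degree_centrality,
    eigenvector_centrality,
    global_metrics,
    local_clustering,
    top_k,
    write_node_metrics,
)

__version__ = "0.1.0"


def cme_seed_panel() -> list[str]:
    """The 18-protein cystoid-macular-edema seed panel shipped as data."""
    text = (
        resources.files("ppinet").joinpath("data/cme_seed_panel.txt").read_text()
    )
    return read_seed_list(text.splitlines())
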