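import pytest

from ppinet import RunConfig, SyntheticSpec, generate_fixture_bundle, run_pipeline

from oracles import net_from_edges


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic fixture bundle (paper-scale, seed 1)."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = generate_fixture_bundle(SyntheticSpec(), str(outdir))
    return manifest


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    """One full pipeline run on the default bundle."""
    outdir = tmp_path_factory.mktemp("run")
    config = RunConfig(
        seed_list=default_bundle["path_seeds"],
        interactions=default_bundle["path_interactions"],
        gmt=[default_bundle["path_gmt"]],
        output_dir=str(outdir),
    )
    return run_pipeline(config)


@pytest.fixture
def triangle():
    return net_from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path4():
    return net_from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def star4():
    """4-node star centered on HUB."""
    return net_from_edges([("HUB", "L1"), ("HUB", "L2"), ("HUB", "L3")])


@pytest.fixture
def two_triangles():
    return net_from_edges(
        [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")]
    )


@pytest.fixture
def two_cliques_bridge():
    """Two 4-cliques joined by a single bridge edge."""
    left = ["A", "B", "C", "D"]
    right = ["E", "F", "G", "H"]
    pairs = [(u, v) for i, u in enumerate(left) for v in left[i + 1 :]]
    pairs += [(u, v) for i, u in enumerate(right) for v in right[i + 1 :]]
    pairs.append(("D", "E"))
    return net_from_edges(pairs)
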