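import networkx as nx
import pytest

import netpharm as nph


@pytest.fixture()
def two_clique_graph():
    """Two 4-cliques joined by a single bridge edge."""
    g = nx.Graph()
    for p in ("a", "b"):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(f"{p}{i}", f"{p}{j}", weight=1.0)
    g.add_edge("a0", "b0", weight=1.0)
    return g


@pytest.fixture()
def toy_scores():
    return nph.GeneScoreTable({"G1": 1.0, "G2": 2.0, "G3": 6.0})


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic benchmark, generated once per session."""
    return nph.make_benchmark(seed=7)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    bundle.write(outdir)
    return outdir


@pytest.fixture(scope="session")
def pipeline_config(bundle_dir):
    return nph.PipelineConfig(
        ppi=str(bundle_dir / "ppi.tsv"),
        scores=str(bundle_dir / "scores.tsv"),
        component_targets=str(bundle_dir / "component_targets.tsv"),
        properties=str(bundle_dir / "properties.tsv"),
        gene_sets=str(bundle_dir / "gene_sets.gmt"),
        seed=7,
    )


@pytest.fixture(scope="session")
def pipeline_run(pipeline_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    manifest = nph.run_pipeline(pipeline_config, outdir)
    return manifest, outdir
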