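import numpy as np
import pandas as pd
import pytest

from dgnet.io_formats import ExpressionRecord, GeneSetCollection, PPIEdge


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ppi_file(tmp_path):
    """Writer for small tab-delimited PPI tables."""

    def write(rows, columns=("gene_a", "gene_b", "mi_code", "source_db", "confidence")):
        path = tmp_path / "ppi.tsv"
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)
        return path

    return write


@pytest.fixture
def gmt_file(tmp_path):
    def write(lines, name="sets.gmt"):
        path = tmp_path / name
        path.write_text("".join(line + "\n" for line in lines))
        return path

    return write


@pytest.fixture
def path_graph_edges():
    return [PPIEdge("A", "B"), PPIEdge("B", "C")]


@pytest.fixture
def small_expression_records():
    """Two genes, one region, two stages, two replicates each."""
    rows = [
        ("g1", "R1", "s1", 1.0), ("g1", "R1", "s1", 1.0),
        ("g1", "R1", "s2", 0.0), ("g1", "R1", "s2", 10.0),
        ("g2", "R1", "s1", 100.0), ("g2", "R1", "s1", 100.0),
        ("g2", "R1", "s2", 0.0), ("g2", "R1", "s2", 0.0),
    ]
    return [ExpressionRecord(*r) for r in rows]


@pytest.fixture
def simple_collection():
    return GeneSetCollection(
        name="toy",
        sets={"S1": ["A", "B", "C", "D"], "S2": ["E", "F"], "S3": ["A", "E", "G"]},
    )


def two_bridged_cliques():
    """Two 5-cliques joined by a single bridge edge A4-B0."""
    import networkx as nx

    G = nx.Graph()
    a = [f"A{i}" for i in range(5)]
    b = [f"B{i}" for i in range(5)]
    for grp in (a, b):
        for i in range(5):
            for j in range(i + 1, 5):
                G.add_edge(grp[i], grp[j])
    G.add_edge("A4", "B0")
    return G, set(a), set(b)
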