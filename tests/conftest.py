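import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from methylquad.io_formats import Manifest, OmicsMatrix


@pytest.fixture
def small_beta_matrix():
    """3 CpGs x 4 samples, betas in [0,1], 2 cases vs 2 controls."""
    values = pd.DataFrame(
        {
            "s1": [0.2, 0.5, 0.9],
            "s2": [0.3, 0.4, 0.8],
            "s3": [0.6, 0.5, 0.1],
            "s4": [0.7, 0.6, 0.2],
        },
        index=pd.Index(["cg001", "cg002", "cg003"], name="feature_id"),
    )
    labels = pd.Series(["case", "case", "control", "control"], index=values.columns)
    return OmicsMatrix(values, labels, "methylation_beta")


@pytest.fixture
def toy_manifest():
    rows = [
        ("cg001", "1", 100, "GA", "TSS200"),
        ("cg002", "1", 200, "GA", "TSS200"),
        ("cg003", "1", 5000, "GA", "Body"),
        ("cg004", "2", 100, "GB", "5UTR"),
        ("cg005", "2", 150, "GB", "5UTR"),
        ("cg006", "3", 900, "", "intergenic"),
    ]
    return Manifest(
        pd.DataFrame(rows, columns=["probe_id", "chromosome", "position", "gene", "region"])
    )


def two_group_matrix(rng, n_features, n_case, n_control, layer="expression"):
    """Null matrix helper: i.i.d. values, no group difference."""
    cols = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_control)]
    if layer == "expression":
        vals = 2.0 ** rng.normal(8, 1, size=(n_features, len(cols)))
    else:
        vals = rng.uniform(0.05, 0.95, size=(n_features, len(cols)))
    df = pd.DataFrame(vals, index=[f"f{i}" for i in range(n_features)], columns=cols)
    labels = pd.Series(["case"] * n_case + ["control"] * n_control, index=cols)
    return OmicsMatrix(df, labels, layer)


def random_graph_edges(rng, n_nodes, p):
    """Seeded Erdos-Renyi edge list on string node labels."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if rng.random() < p
    ]
    return nodes, edges
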