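import numpy as np
import pandas as pd
import pytest

from beebrains.phylo import PhyloTree, read_newick
from beebrains.simulate import simulate_tree


def random_tree(n_tips: int, seed: int, ultrametric: bool = True) -> PhyloTree:
    """Random tree; optionally with independently jittered branch lengths."""
    tree = simulate_tree(n_tips, seed=seed)
    if ultrametric:
        return tree
    rng = np.random.default_rng(seed + 1)
    dtree = tree.dendropy_tree
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is not None:
            nd.edge.length *= float(rng.uniform(0.2, 2.0))
    return read_newick(dtree.as_string(schema="newick").strip())


def covariance_by_path_enumeration(tree: PhyloTree):
    """Brute-force covariance oracle: intersect root-to-tip edge sets."""
    dtree = tree.dendropy_tree
    paths = {}
    for leaf in dtree.leaf_node_iter():
        edges = []
        nd = leaf
        while nd.parent_node is not None:
            edges.append((id(nd.edge), nd.edge.length or 0.0))
            nd = nd.parent_node
        paths[leaf.taxon.label] = dict(edges)
    labels = tree.tip_labels
    n = len(labels)
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = set(paths[a]) & set(paths[b])
            V[i, j] = sum(paths[a][e] for e in shared)
    return labels, V


@pytest.fixture
def toy_specimens() -> pd.DataFrame:
    e = float(np.e)
    return pd.DataFrame(
        {
            "species": ["A", "A", "B", "C", "C"],
            "brain_mg": [e, e, 1.0, 1.0, e**2],
            "itd_mm": [2.0, 2.0, 1.0, 1.0, 1.0],
            "region": ["US", "US", "EU", "both", "both"],
        }
    )


@pytest.fixture
def filter_toy_records() -> pd.DataFrame:
    """Twelve records spanning the year / decimal / min-records boundaries.

    Hand enumeration: rows 2, 3, 7, 8, 10, 11 survive the year (1990-2022,
    inclusive) and two-decimal filters; species A keeps 4 records, species
    B keeps 2, so a minimum of 3 records retains only A.
    """
    rows = [
        # species, year, lat_text, lon_text (None -> numeric fallback), lat, lon
        ("A", 1989, "40.123", "-75.10"),   # 0: year below window
        ("A", 2023, "40.123", "-75.10"),   # 1: year above window
        ("A", 1990, "40.10", "-75.10"),    # 2: keep (boundary year)
        ("A", 2022, "40.12", "-75.12"),    # 3: keep (boundary year)
        ("A", 2000, "40.1", "-75.123"),    # 4: lat has 1 decimal
        ("A", 2000, "40.123", "-75.1"),    # 5: lon has 1 decimal
        ("B", 2000, "40", "-75"),          # 6: integer coordinates
        ("A", 2000, "40.12", "-75.34"),    # 7: keep
        ("A", 2000, "40.1234", "-75.1000"),  # 8: keep (trailing zeros count)
        ("B", 2000, None, None),           # 9: numeric 40.12 / -75.3 -> lon 1 dec
        ("B", 2000, "40.125", "-75.125"),  # 10: keep
        ("B", 1991, "40.00", "-75.00"),    # 11: keep (zeros after the point)
    ]
    df = pd.DataFrame(rows, columns=["species", "year", "lat_text", "lon_text"])
    df["lat"] = df["lat_text"].astype(float)
    df["lon"] = df["lon_text"].astype(float)
    df.loc[9, "lat"] = 40.12
    df.loc[9, "lon"] = -75.3
    return df


FILTER_TOY_KEPT = [2, 3, 7, 8, 10, 11]
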