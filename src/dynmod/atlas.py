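"""Packaged 68-node functional atlas metadata.

The node table lists, for each of the 68 ROIs, its matrix position, name,
abbreviation, consensus-clustering module and final module assignment (the
final assignment additionally respects each node's network of origin).  The
five modules are SSM (somatic sensory-motor), TIL (temporal/insular/limbic),
TPN (task-positive), TNN (task-negative) and VIS (visual); the four DMN
sub-networks live inside TNN.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_node_table",
    "final_assignment",
    "clustering_assignment",
    "module_names",
    "dmn_subnetworks",
]

#: 1-based node ids of the four 4-node DMN sub-networks within the TNN module.
DMN_SUBNETWORK_NODES = {
    "pDMN": [42, 43, 44, 45],
    "dDMN": [46, 47, 48, 49],
    "vDMN": [50, 51, 52, 53],
    "aDMN": [54, 55, 56, 57],
}


def load_node_table() -> pd.DataFrame:
    """The packaged node table as a DataFrame, one row per ROI in matrix order."""
    with resources.files("dynmod").joinpath("data/node_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def final_assignment() -> np.ndarray:
    """Final 5-module labels (1..5) for the 68 nodes, in matrix order."""
    return load_node_table()["final_assignment"].to_numpy(dtype=int)


def clustering_assignment() -> np.ndarray:
    """Consensus-clustering module labels for the 68 nodes, in matrix order."""
    return load_node_table()["clustering_assignment"].to_numpy(dtype=int)


def module_names() -> dict:
    """Mapping from module label to module name (1 -> SSM, ..., 5 -> VIS)."""
    df = load_node_table()
    return {int(lab): name for name, lab in zip(df["module_name"], df["final_assignment"])}


def dmn_subnetworks() -> list:
    """The four DMN sub-network definitions (pDMN, dDMN, vDMN, aDMN)."""
    from .group_stats import SubnetworkDefinition

    return [SubnetworkDefinition(name=k, node_ids=v) for k, v in DMN_SUBNETWORK_NODES.items()]
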