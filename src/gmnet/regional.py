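"""Map cube nodes onto a labelled parcellation and average nodal metrics.

Whole-brain analyses use global means; local analyses average the nodal
parameters of the cubes falling inside each atlas region, which reduces the
number of local statistical tests from thousands of cubes to the region
count (90 for an AAL-style atlas).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .extract import CUBE_EDGE, NodeSet
from .volume import AtlasParcellation, GreyMatterVolume

__all__ = ["assign_nodes_to_regions", "aggregate_regional"]


def assign_nodes_to_regions(nodes: NodeSet, atlas: AtlasParcellation) -> np.ndarray:
    """Label each cube node by the majority label among its 27 voxels.

    Ties break toward the lowest label index; a cube whose majority label is
    background (0) is unassigned (label 0).  The atlas grid must match the
    grid the nodes were cut from.
    """
    if atlas.labels.shape != tuple(nodes.volume_shape):
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match volume grid {nodes.volume_shape}"
        )
    out = np.zeros(nodes.n_nodes, dtype=np.int64)
    for i, (x, y, z) in enumerate(nodes.cube_index_coords):
        sub = atlas.labels[x : x + CUBE_EDGE, y : y + CUBE_EDGE, z : z + CUBE_EDGE].ravel()
        counts = np.bincount(sub)
        out[i] = int(np.argmax(counts))  # first max -> lowest label on ties
    return out


def aggregate_regional(
    nodal: pd.DataFrame,
    node_labels: np.ndarray,
    volume: GreyMatterVolume,
    atlas: AtlasParcellation,
) -> pd.DataFrame:
    """Per-region unweighted means of nodal metrics plus local GM volume.

    Returns one row per atlas region with the mean of every nodal metric
    over the nodes assigned to that region, the node count, and the local
    grey matter volume in mL (sum of densities times voxel volume inside
    the region).  Regions containing no node get NaN metrics and are
    flagged ``missing``.
    """
    node_labels = np.asarray(node_labels)
    if len(node_labels) != len(nodal):
        raise ValueError("node_labels length must match the nodal metric table")
    if volume.shape != atlas.labels.shape:
        raise ValueError("volume and atlas grids differ")

    vox_ml = volume.voxel_volume_ml
    rows = []
    for region in range(1, atlas.n_regions + 1):
        in_region = node_labels == region
        n_nodes = int(in_region.sum())
        row = {
            "region": region,
            "region_name": atlas.region_names[region - 1],
            "n_nodes": n_nodes,
            "local_gm_volume_ml": float(volume.data[atlas.labels == region].sum()) * vox_ml,
            "missing": n_nodes == 0,
        }
        for col in nodal.columns:
            row[col] = float(nodal.loc[in_region, col].mean()) if n_nodes else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")
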