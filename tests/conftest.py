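"""Shared fixtures: tiny hand-checkable cohorts and spatial configurations."""

import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def six_tumor_spectra() -> pd.DataFrame:
    """Six tumors with hand-listed deletion lengths, pre-binned by hand.

    T1 [3,4]            -> (2,0,0,0) raw 0
    T2 [7,8,2]          -> (1,2,0,0) raw 2
    T3 [6,13,14,20]     -> (0,2,2,0) raw 4
    T4 [15,9,10,55]     -> (0,2,1,0)+overflow raw 3
    T5 [21,50,5]        -> (1,0,0,2) raw 0
    T6 [6,7,8,9,14]     -> (0,4,1,0) raw 5
    """
    return pd.DataFrame(
        {
            "tumor_id": ["T1", "T2", "T3", "T4", "T5", "T6"],
            "b1_5": [2, 1, 0, 0, 1, 0],
            "b6_13": [0, 1, 2, 2, 0, 4],
            "b14_20": [0, 0, 2, 1, 0, 1],
            "b21_50": [0, 0, 0, 0, 2, 0],
            "overflow_gt50": [0, 0, 0, 1, 0, 0],
        }
    )


SIX_TUMOR_LENGTHS = {
    "T1": [3, 4],
    "T2": [7, 8, 2],
    "T3": [6, 13, 14, 20],
    "T4": [15, 9, 10, 55],
    "T5": [21, 50, 5],
    "T6": [6, 7, 8, 9, 14],
}


@pytest.fixture
def enumerable_spatial() -> pd.DataFrame:
    """Three collinear macrophages, one APC-like at the origin, one CD8 cell
    5 um away: the label permutation space has exactly 3 outcomes {1, 0, 0},
    so the exact empirical p for the observed fraction 1 is 1/3."""
    return pd.DataFrame(
        {
            "cell_id": ["m1", "m2", "m3", "c1"],
            "sample_id": "S1",
            "x_um": [0.0, 100.0, 200.0, 5.0],
            "y_um": [0.0, 0.0, 0.0, 0.0],
            "cell_type": ["Macrophage", "Macrophage", "Macrophage", "CD8T"],
            "HLA-DRA": [1.0, 0.0, 0.0, 0.0],
            "CD74": [1.0, 0.0, 0.0, 0.0],
        }
    )


def make_spatial_frame(mac_xy, cd8_xy, apc_mask=None):
    """Build a spatial cell table from coordinate arrays; APC-like macrophages
    (all by default) get both genes positive."""
    mac_xy = np.asarray(mac_xy, dtype=float).reshape(-1, 2)
    cd8_xy = np.asarray(cd8_xy, dtype=float).reshape(-1, 2)
    if apc_mask is None:
        apc_mask = np.ones(len(mac_xy), dtype=bool)
    apc_mask = np.asarray(apc_mask, dtype=bool)
    mac = pd.DataFrame(
        {
            "cell_id": [f"m{i}" for i in range(len(mac_xy))],
            "sample_id": "S1",
            "x_um": mac_xy[:, 0],
            "y_um": mac_xy[:, 1],
            "cell_type": "Macrophage",
            "HLA-DRA": np.where(apc_mask, 1.0, 0.0),
            "CD74": np.where(apc_mask, 1.0, 0.0),
        }
    )
    cd8 = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(cd8_xy))],
            "sample_id": "S1",
            "x_um": cd8_xy[:, 0],
            "y_um": cd8_xy[:, 1],
            "cell_type": "CD8T",
            "HLA-DRA": 0.0,
            "CD74": 0.0,
        }
    )
    return pd.concat([mac, cd8], ignore_index=True)
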