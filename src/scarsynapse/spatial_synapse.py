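"""Spatial immune-synapse analysis: CD8 T-cell proximity to APC-like macrophages.

Antigen-presenting (APC-like) macrophages are macrophages co-expressing
HLA-DRA and CD74 (both strictly > 0 on the log1p scale). The synapse statistic
is the fraction of CD8 T cells lying within a radius (default 20 um) of at
least one APC-like macrophage, by Euclidean distance in micrometers. Its
significance is assessed against a geometry-preserving permutation null: the
APC-like labels are reshuffled uniformly among the macrophages (positions,
tissue geometry and density untouched) and the empirical p-value is the
proportion of permuted fractions greater than or equal to the observed one.

A second, orthogonal readout stratifies all macrophages into CD8-proximal
(<= threshold to the nearest CD8 cell) versus CD8-distal and compares
antigen-presentation gene expression between strata by two-sided Mann-Whitney
tests with a rank-biserial effect size.

All distances are double precision; the radius is inclusive (<=) for both the
proximity fraction and the stratification, and each sample is analyzed
independently. Expected coordinate columns are ``x_um``/``y_um``; cell types
``Macrophage`` and ``CD8T`` are recognized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_RADIUS_UM = 20.0
DEFAULT_N_PERM = 500
APC_GENES = ("HLA-DRA", "CD74")

MACROPHAGE = "Macrophage"
CD8 = "CD8T"


@dataclass
class ProximityResult:
    """Observed CD8-near-APC fraction with its permutation null."""

    sample_id: str
    observed_fraction: float
    n_cd8: int
    n_macrophage: int
    n_apc: int
    radius_um: float
    null_fractions: np.ndarray = field(repr=False)
    empirical_p: float
    seed: int

    def to_dict(self) -> dict:
        d = vars(self).copy()
        d["null_fractions"] = np.asarray(self.null_fractions).tolist()
        return d


def flag_apc_macrophages(cells: pd.DataFrame, genes=APC_GENES) -> np.ndarray:
    """Boolean APC-like indicator per row: macrophage with every gene in
    ``genes`` strictly positive. Missing gene columns are a hard error."""
    missing = [g for g in genes if g not in cells.columns]
    if missing:
        raise ValueError(f"missing expression column(s) for macrophages: {missing}")
    is_mac = (cells["cell_type"] == MACROPHAGE).to_numpy()
    flag = is_mac.copy()
    for g in genes:
        expr = cells[g].to_numpy(dtype=float)
        if np.isnan(expr[is_mac]).any():
            raise ValueError(f"macrophage rows have missing {g} expression")
        flag &= expr > 0
    return flag


def _coords(cells: pd.DataFrame, mask: np.ndarray) -> np.ndarray:
    xy = cells.loc[mask, ["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates")
    return xy


def cd8_proximity_fraction(
    cells: pd.DataFrame, radius_um: float = DEFAULT_RADIUS_UM
) -> float:
    """Fraction of CD8 T cells within ``radius_um`` (inclusive) of at least one
    APC-like macrophage, using a KD-tree nearest-neighbor query.

    Zero CD8 cells leave the fraction undefined and raise; zero APC-like
    macrophages yield 0.0 with a warning.
    """
    is_cd8 = (cells["cell_type"] == CD8).to_numpy()
    if not is_cd8.any():
        raise ValueError("no CD8 cells: proximity fraction is undefined")
    if not (cells["cell_type"] == MACROPHAGE).any():
        raise ValueError("no macrophages in sample")
    apc = flag_apc_macrophages(cells)
    cd8_xy = _coords(cells, is_cd8)
    if not apc.any():
        warnings.warn("no APC-like macrophages; fraction is 0", stacklevel=2)
        return 0.0
    tree = cKDTree(_coords(cells, apc))
    dist, _ = tree.query(cd8_xy, k=1)
    return float(np.mean(dist <= radius_um))


def permutation_null_test(
    cells: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    radius_um: float = DEFAULT_RADIUS_UM,
    sample_id: str | None = None,
    add_one: bool = False,
) -> ProximityResult:
    """Permutation test of CD8-to-APC-like-macrophage proximity.

    Each permutation draws a uniform random subset of size ``n_apc`` from all
    macrophages as the APC-like set (cell positions untouched) and recomputes
    the proximity fraction. The empirical p is the proportion of null fractions
    >= observed (ties count); with ``add_one`` the strictly positive
    (k+1)/(n+1) estimator is used instead.

    With every macrophage APC-like the permutation space is degenerate and
    p = 1 (warned). Zero APC-like macrophages are rejected.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    is_cd8 = (cells["cell_type"] == CD8).to_numpy()
    is_mac = (cells["cell_type"] == MACROPHAGE).to_numpy()
    if not is_cd8.any():
        raise ValueError("no CD8 cells: proximity fraction is undefined")
    apc = flag_apc_macrophages(cells)
    n_apc = int(apc.sum())
    n_mac = int(is_mac.sum())
    if n_apc == 0:
        raise ValueError("permutation test requires at least one APC-like macrophage")
    if n_apc == n_mac:
        warnings.warn(
            "all macrophages are APC-like; every permutation reproduces the "
            "observed configuration and p = 1",
            stacklevel=2,
        )

    cd8_xy = _coords(cells, is_cd8)
    mac_xy = _coords(cells, is_mac)
    # Boolean reachability matrix (cd8 x macrophage); observed and null
    # fractions both read from it so they share one distance computation.
    within = _within_radius(cd8_xy, mac_xy, radius_um)
    apc_idx_in_mac = np.flatnonzero(apc[is_mac])
    observed = float(within[:, apc_idx_in_mac].any(axis=1).mean())

    rng = np.random.default_rng(seed)
    null_fractions = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n_mac, size=n_apc, replace=False)
        null_fractions[i] = within[:, idx].any(axis=1).mean()

    k = int(np.sum(null_fractions >= observed))
    p = (k + 1) / (n_perm + 1) if add_one else k / n_perm
    if sample_id is None:
        sample_id = (
            str(cells["sample_id"].iloc[0]) if "sample_id" in cells.columns else ""
        )
    return ProximityResult(
        sample_id=sample_id,
        observed_fraction=observed,
        n_cd8=int(is_cd8.sum()),
        n_macrophage=n_mac,
        n_apc=n_apc,
        radius_um=radius_um,
        null_fractions=null_fractions,
        empirical_p=float(p),
        seed=seed,
    )


def _within_radius(a: np.ndarray, b: np.ndarray, radius: float) -> np.ndarray:
    """Boolean matrix of Euclidean distances <= radius between point sets,
    via a KD-tree sparse query (equals the brute-force all-pairs inclusion)."""
    tree_a = cKDTree(a)
    tree_b = cKDTree(b)
    mat = tree_a.sparse_distance_matrix(tree_b, radius, output_type="coo_matrix")
    out = np.zeros((len(a), len(b)), dtype=bool)
    out[mat.row, mat.col] = True
    return out


def stratify_and_compare_expression(
    cells: pd.DataFrame,
    threshold_um: float = DEFAULT_RADIUS_UM,
    genes=APC_GENES,
) -> pd.DataFrame:
    """Compare gene expression between CD8-proximal and CD8-distal macrophages.

    All macrophages (not only APC-like) are stratified by distance to the
    nearest CD8 T cell: proximal (<= threshold) versus distal (> threshold).
    Per gene, a two-sided Mann-Whitney test is run; the rank-biserial effect
    size 2U/(n1*n2) - 1 is reported (positive when proximal ranks higher). An
    empty stratum yields status "skipped" for every gene instead of a test.
    """
    from .immunogenomics import _mannwhitney

    is_cd8 = (cells["cell_type"] == CD8).to_numpy()
    is_mac = (cells["cell_type"] == MACROPHAGE).to_numpy()
    if not is_cd8.any():
        raise ValueError("no CD8 cells to stratify against")
    if not is_mac.any():
        raise ValueError("no macrophages to stratify")
    missing = [g for g in genes if g not in cells.columns]
    if missing:
        raise ValueError(f"missing expression column(s): {missing}")

    tree = cKDTree(_coords(cells, is_cd8))
    dist, _ = tree.query(_coords(cells, is_mac), k=1)
    proximal = dist <= threshold_um

    rows = []
    for g in genes:
        expr = cells.loc[is_mac, g].to_numpy(dtype=float)
        x, y = expr[proximal], expr[~proximal]
        if len(x) == 0 or len(y) == 0:
            rows.append(
                dict(gene=g, status="skipped", n_proximal=len(x), n_distal=len(y),
                     statistic=np.nan, pvalue=np.nan, median_proximal=np.nan,
                     median_distal=np.nan, rank_biserial=np.nan)
            )
            continue
        u, p = _mannwhitney(x, y)
        rows.append(
            dict(
                gene=g,
                status="ok",
                n_proximal=len(x),
                n_distal=len(y),
                statistic=u,
                pvalue=p,
                median_proximal=float(np.median(x)),
                median_distal=float(np.median(y)),
                rank_biserial=float(2.0 * u / (len(x) * len(y)) - 1.0),
            )
        )
    return pd.DataFrame(rows)
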