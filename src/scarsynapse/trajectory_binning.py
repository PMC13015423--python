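"""Neoantigen-gradient trajectory binning of pooled immune cells.

Immune cells pooled across tumors are ordered along a tumor-level neoantigen
gradient (cells sorted by their tumor's burden, ascending, with tumor id and
stable input order breaking ties) and split into ``n_bins`` contiguous,
near-equal-size bins. Each tumor contributes according to its cellular
composition; tumors are never reweighted. Per bin the module reports cell-type
proportions, Shannon entropy in bits, mean curated-program module scores, and
the mean tumor-level shifted MDF of the member cells — the summary used to
describe the transition from macrophage-predominant toward immune-diverse
states as burden rises.

The gradient here is the tumor-burden ordering itself, deliberately isolated in
:func:`order_and_bin` so that an alternative per-cell ordering (a diffusion
pseudotime, say) can be injected without touching the summaries.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 30


def order_and_bin(
    cells: pd.DataFrame,
    burden: Mapping[str, float],
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Assign each cell a 1-based trajectory bin along the neoantigen gradient.

    Cells are sorted by (tumor burden ascending, tumor_id, stable input order)
    and split into ``n_bins`` contiguous blocks; the first ``n_cells mod
    n_bins`` bins receive one extra cell. Every cell's tumor must have a burden.
    """
    n = len(cells)
    if not 1 <= n_bins <= n:
        raise ValueError("n_bins must be between 1 and the number of cells")
    tumor_ids = cells["tumor_id"].to_numpy()
    missing = set(tumor_ids) - set(burden)
    if missing:
        raise KeyError(f"no neoantigen burden for tumor(s): {sorted(missing)}")

    b = np.array([burden[t] for t in tumor_ids], dtype=float)
    order = np.lexsort((np.arange(n), tumor_ids.astype(str), b))  # last key primary

    base, extra = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:extra] += 1
    bin_of_rank = np.repeat(np.arange(1, n_bins + 1), sizes)

    assignment = np.empty(n, dtype=int)
    assignment[order] = bin_of_rank
    return assignment


def module_score(cells: pd.DataFrame, gene_set: Sequence[str]) -> np.ndarray:
    """Per-cell module score for a curated gene set.

    Each present gene is z-scored across all cells (sample sd; a zero-variance
    gene contributes 0) and the z-scores are averaged over the genes present.
    Genes absent from the table are dropped with a warning; an empty
    intersection is a hard error.
    """
    present = [g for g in gene_set if g in cells.columns]
    absent = [g for g in gene_set if g not in cells.columns]
    if absent:
        logger.warning("module_score: dropping absent gene(s) %s", absent)
    if not present:
        raise ValueError("no gene of the set is present in the expression table")
    expr = cells[present].to_numpy(dtype=float)
    mean = expr.mean(axis=0)
    sd = expr.std(axis=0, ddof=1) if len(expr) > 1 else np.zeros(expr.shape[1])
    z = np.zeros_like(expr)
    ok = sd > 0
    z[:, ok] = (expr[:, ok] - mean[ok]) / sd[ok]
    return z.mean(axis=1)


def shannon_entropy_bits(proportions: np.ndarray) -> float:
    """H = -sum p log2 p with 0*log0 = 0, exact on dyadic proportions."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def summarize_bins(
    cells: pd.DataFrame,
    assignment: np.ndarray,
    mdf: Mapping[str, float],
    programs: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Summarize each trajectory bin.

    Returns one row per bin with cell count, per-type composition proportions
    (columns ``prop_<type>``), Shannon entropy in bits, mean module score per
    program (columns ``score_<program>``), and the mean tumor-level shifted MDF
    over member cells.
    """
    if len(assignment) != len(cells):
        raise ValueError("assignment and cells must be matched")
    types = sorted(cells["cell_type"].unique())
    tumor_mdf = np.array([mdf[t] for t in cells["tumor_id"]], dtype=float)

    scores: dict[str, np.ndarray] = {}
    if programs:
        for name, genes in programs.items():
            scores[name] = module_score(cells, genes)

    rows = []
    for b in np.unique(assignment):
        in_bin = assignment == b
        sub = cells.loc[in_bin]
        n = int(in_bin.sum())
        props = sub["cell_type"].value_counts(normalize=True)
        row: dict[str, float] = {"bin_index": int(b), "n_cells": n}
        for t in types:
            row[f"prop_{t}"] = float(props.get(t, 0.0))
        row["entropy_bits"] = shannon_entropy_bits(
            np.array([props.get(t, 0.0) for t in types])
        )
        for name, s in scores.items():
            row[f"score_{name}"] = float(s[in_bin].mean())
        row["mean_mdf"] = float(tumor_mdf[in_bin].mean())
        rows.append(row)
    return pd.DataFrame(rows)
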