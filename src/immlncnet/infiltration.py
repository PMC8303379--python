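"""Single-sample GSEA scoring of immunocyte marker signatures.

For each sample, genes are ranked by expression (highest rank = most
expressed; ties broken deterministically by gene id). Walking down the
ranked list, the enrichment score of a signature G accumulates the
difference between the weighted in-set empirical distribution (rank values
to the power alpha) and the unweighted out-of-set one:

    ES(G, s) = sum_i [ P_in(i) - P_out(i) ]

over all N list positions. Raw scores are range-normalized over the whole
matrix to [0, 1] ("infiltration scores") and converted per sample to
fractions summing to one ("estimated cell proportions"). Because only
within-sample ranks enter, scores are invariant to any strictly monotone
per-sample transform of expression; log2-CPM is the conventional input.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .data import ImmLncError, SignatureSet


def ssgsea_scores(
    expr: pd.DataFrame, signatures: SignatureSet, alpha: float = 0.25
) -> pd.DataFrame:
    """Raw ssGSEA enrichment scores, cell types x samples.

    ``expr`` is a genes x samples real matrix (log2-CPM recommended).
    Each signature must overlap the matrix genes in at least one gene and
    must not cover all of them; violations raise, naming the set.
    """
    if expr.shape[0] < 2:
        raise ImmLncError("need >= 2 genes to rank")
    if len(signatures) == 0:
        raise ImmLncError("empty signature collection")
    # deterministic tie-breaking: pre-sort genes by id, then stable argsort
    expr = expr.sort_index(kind="stable")
    genes = expr.index
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    masks = {}
    for name, members in signatures.sets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        if not idx:
            raise ImmLncError(f"signature {name!r} has no overlap with the matrix")
        if len(idx) == n:
            raise ImmLncError(f"signature {name!r} covers every gene; ES undefined")
        m = np.zeros(n, dtype=bool)
        m[idx] = True
        masks[name] = m

    values = expr.to_numpy(dtype=float)
    scores = np.empty((len(masks), expr.shape[1]))
    for j, sample in enumerate(expr.columns):
        col = values[:, j]
        if np.ptp(col) == 0:
            raise ImmLncError(f"sample {sample!r} is constant; ranking undefined")
        order = np.argsort(-col, kind="stable")  # descending, ties by gene id
        ranks = np.arange(n, 0, -1, dtype=float)  # rank value N at the top
        w = ranks**alpha
        for i, (name, mask) in enumerate(masks.items()):
            in_set = mask[order]
            win = np.where(in_set, w, 0.0)
            p_in = np.cumsum(win) / win.sum()
            p_out = np.cumsum(~in_set) / (n - in_set.sum())
            scores[i, j] = float(np.sum(p_in - p_out))
    return pd.DataFrame(scores, index=list(masks), columns=expr.columns)


def normalize_scores(raw_es: pd.DataFrame) -> pd.DataFrame:
    """Range-normalize raw scores to [0, 1] with the global min / max."""
    arr = raw_es.to_numpy(dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ImmLncError("constant score matrix cannot be range-normalized")
    return (raw_es - lo) / (hi - lo)


def score_fractions(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractions: each column divided by its column sum."""
    arr = normalized.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ImmLncError("fractions require non-negative scores")
    colsum = arr.sum(axis=0)
    zero = normalized.columns[colsum == 0].tolist()
    if zero:
        raise ImmLncError(f"all-zero score column(s): {zero}")
    return normalized / colsum


def celltype_correlation(
    scores: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of cell-type scores across samples.

    Two-sided p-values come from t = r sqrt(n-2) / sqrt(1-r^2) on n-2
    degrees of freedom; the diagonal is fixed at r = 1, p = 0. Cell types
    with zero variance get NA with a warning.
    """
    n = scores.shape[1]
    if n < 3:
        raise ImmLncError("need >= 3 samples for correlation")
    arr = scores.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    degenerate = scores.index[sd == 0].tolist()
    if degenerate:
        warnings.warn(
            f"zero-variance cell type(s) excluded from correlation: {degenerate}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    for ct in degenerate:
        i = scores.index.get_loc(ct)
        r[i, :] = np.nan
        r[:, i] = np.nan
    r_clip = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r_clip * np.sqrt(n - 2) / np.sqrt(1.0 - r_clip**2)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r_clip), 1.0), 0.0, p)
    np.fill_diagonal(r_clip, 1.0)
    np.fill_diagonal(p, 0.0)
    for ct in degenerate:
        i = scores.index.get_loc(ct)
        r_clip[i, :] = np.nan
        r_clip[:, i] = np.nan
        p[i, :] = np.nan
        p[:, i] = np.nan
    idx = scores.index
    return (
        pd.DataFrame(r_clip, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def infiltration_long_table(normalized: pd.DataFrame, samples: Sequence) -> pd.DataFrame:
    """Tidy long format (celltype, sample, score) for heatmap plotting."""
    long = normalized.reset_index(names="celltype").melt(
        id_vars="celltype", var_name="sample_id", value_name="score"
    )
    return long
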