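"""The integration step: all-pairs negative correlation x target prediction.

Every deregulated miRNA is correlated with every deregulated mRNA across the
shared HSC samples (Pearson, two-sided p from the t distribution with n-2
degrees of freedom). The p-values of all pairs form a single family for
Benjamini-Hochberg adjustment, and a pair is called functional when it passes
all three filters: FDR < 0.05, Pearson r < 0, and a database prediction
p_database < 0.05. Pairs absent from the prediction table are kept in the
output with a missing p_database and selected = False, so database coverage
stays auditable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pearson_all_pairs",
    "bh_adjust",
    "add_fdr",
    "select_functional_pairs",
    "integrate",
]


def pearson_all_pairs(
    mirna_x: pd.DataFrame,
    gene_x: pd.DataFrame,
    samples: Sequence[str],
    mirna_ids: Sequence[str] | None = None,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson r and two-sided p for every miRNA x gene pair over ``samples``.

    Rows with zero variance or missing values over the correlation samples
    get a missing r and p (they are excluded from FDR adjustment downstream).
    Fewer than 3 shared samples is an error: r would have no degrees of
    freedom left for a test.
    """
    samples = list(samples)
    n = len(samples)
    if n < 3:
        raise ValueError(f"need at least 3 shared samples to correlate, got {n}")
    mirna_ids = list(mirna_ids) if mirna_ids is not None else list(mirna_x.index)
    gene_ids = list(gene_ids) if gene_ids is not None else list(gene_x.index)

    M = mirna_x.loc[mirna_ids, samples].to_numpy(dtype=float)
    G = gene_x.loc[gene_ids, samples].to_numpy(dtype=float)
    Mc = M - M.mean(axis=1, keepdims=True)
    Gc = G - G.mean(axis=1, keepdims=True)
    m_norm = np.sqrt((Mc**2).sum(axis=1))
    g_norm = np.sqrt((Gc**2).sum(axis=1))
    m_bad = (m_norm == 0) | np.isnan(M).any(axis=1)
    g_bad = (g_norm == 0) | np.isnan(G).any(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc @ Gc.T) / np.outer(m_norm, g_norm)
    r = np.clip(r, -1.0, 1.0)
    r[m_bad, :] = np.nan
    r[:, g_bad] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)

    return pd.DataFrame(
        {
            "mirna_id": np.repeat(mirna_ids, len(gene_ids)),
            "gene_id": np.tile(gene_ids, len(mirna_ids)),
            "pearson_r": r.ravel(),
            "cor_p": p.ravel(),
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving).

    Inputs must lie in [0, 1]; missing values pass through as missing and do
    not count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum() > 0:
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def add_fdr(pairs: pd.DataFrame) -> pd.DataFrame:
    """Attach a BH-adjusted ``fdr`` column; one family over all testable pairs."""
    pairs = pairs.copy()
    pairs["fdr"] = bh_adjust(pairs["cor_p"].to_numpy())
    return pairs


def select_functional_pairs(
    pairs: pd.DataFrame,
    predictions: pd.DataFrame,
    fdr_cut: float = 0.05,
    pdb_cut: float = 0.05,
) -> pd.DataFrame:
    """Flag pairs passing FDR < fdr_cut, r < 0 and p_database < pdb_cut.

    Merges the prediction table onto the pair table; pairs without a
    prediction keep a missing p_database and are never selected.
    """
    if "fdr" not in pairs.columns:
        raise ValueError("pair table has no fdr column; run add_fdr first")
    merged = pairs.merge(
        predictions[["mirna_id", "gene_id", "p_database"]],
        on=["mirna_id", "gene_id"],
        how="left",
    )
    merged["selected"] = (
        (merged["fdr"] < fdr_cut)
        & (merged["pearson_r"] < 0)
        & (merged["p_database"] < pdb_cut)
    ).fillna(False)
    return merged


def integrate(
    mirna_x: pd.DataFrame,
    gene_x: pd.DataFrame,
    de: pd.DataFrame,
    sheet: pd.DataFrame,
    predictions: pd.DataFrame,
    fdr_cut: float = 0.05,
    pdb_cut: float = 0.05,
) -> pd.DataFrame:
    """Full integration: deregulated cross-product -> r/p -> FDR -> selection.

    ``de`` is the combined differential table; only features labeled
    q_associated or a_associated enter the cross product. Correlation runs
    over the HSC samples shared by both matrices.
    """
    dereg = de[de["class_label"] != "unchanged"]
    mirna_ids = dereg.loc[dereg["feature_kind"] == "miRNA", "feature_id"]
    gene_ids = dereg.loc[dereg["feature_kind"] == "gene", "feature_id"]
    mirna_ids = [m for m in mirna_ids if m in mirna_x.index]
    gene_ids = [g for g in gene_ids if g in gene_x.index]
    hsc = sheet.loc[sheet["cell_type"] == "HSC", "sample_id"]
    samples = [s for s in hsc if s in mirna_x.columns and s in gene_x.columns]
    pairs = pearson_all_pairs(mirna_x, gene_x, samples, mirna_ids, gene_ids)
    pairs = add_fdr(pairs)
    return select_functional_pairs(pairs, predictions, fdr_cut=fdr_cut, pdb_cut=pdb_cut)
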