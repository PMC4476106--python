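"""Differential classification of miRNAs and genes between HSC states.

Features are labeled quiescence-associated (``q_associated``),
activation-associated (``a_associated``) or ``unchanged`` by fold-change
rules on group means plus a Student t-test on the quiescent/activated
contrast:

* genes, q_associated: at least 2-fold above both hepatocytes and LSECs in
  qHSCs (cell-type enrichment) and at least 1.5-fold down on activation;
* genes, a_associated: at least 2-fold above both reference cell types in
  aHSCs and significantly up-regulated from qHSC to aHSC (p <= 0.05);
* miRNAs, q_associated: at least 1.5-fold down on activation, p <= 0.05;
* miRNAs, a_associated: at least 2-fold up on activation, p <= 0.05.

Enrichment against the reference cell types is a fold-change-only filter;
significance applies only to the quiescent/activated contrast. Ties at a
threshold count as passing ("at least"). The two direction conditions are
mutually exclusive, so every feature gets exactly one label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import group_fold_change

__all__ = ["classify_genes", "classify_mirnas", "hsc_sample_groups"]


def hsc_sample_groups(sheet: pd.DataFrame, paired: bool = False):
    """(quiescent, activated) HSC sample id lists; donor-aligned if paired."""
    hsc = sheet[sheet["cell_type"] == "HSC"]
    if paired:
        hsc = hsc.sort_values("donor_id", kind="stable")
    q = hsc.loc[hsc["state"] == "quiescent", "sample_id"].tolist()
    a = hsc.loc[hsc["state"] == "activated", "sample_id"].tolist()
    for name, group in (("quiescent HSC", q), ("activated HSC", a)):
        if not group:
            raise ValueError(f"missing cell-type group: {name}")
    return q, a


def classify_mirnas(
    ndct: pd.DataFrame,
    sheet: pd.DataFrame,
    q_fc: float = 1.5,
    a_fc: float = 2.0,
    p_cut: float = 0.05,
    paired: bool = False,
) -> pd.DataFrame:
    """Label each miRNA by the quiescent-vs-activated contrast.

    ``ndct`` is the -dCt matrix restricted to expressed assays (detection
    filtering happens upstream). Returns a table with fc_q_vs_a (linear),
    fc_signed, p_value and class_label per miRNA.
    """
    q, a = hsc_sample_groups(sheet, paired=paired)
    stats = group_fold_change(ndct, q, a, paired=paired)
    fc = stats["fc_linear"]
    p = stats["p_value"]
    q_assoc = (fc >= q_fc) & (p <= p_cut)
    a_assoc = ((1.0 / fc) >= a_fc) & (p <= p_cut)
    label = np.where(q_assoc, "q_associated", np.where(a_assoc, "a_associated", "unchanged"))
    return pd.DataFrame(
        {
            "feature_id": ndct.index,
            "feature_kind": "miRNA",
            "fc_q_vs_a": fc.to_numpy(),
            "fc_signed": stats["fc_signed"].to_numpy(),
            "p_value": p.to_numpy(),
            "class_label": label,
        }
    ).reset_index(drop=True)


def classify_genes(
    expr: pd.DataFrame,
    sheet: pd.DataFrame,
    enrichment_fc: float = 2.0,
    q_down_fc: float = 1.5,
    p_cut: float = 0.05,
    paired: bool = False,
) -> pd.DataFrame:
    """Label each gene by cell-type enrichment plus the activation contrast.

    Requires qHSC, aHSC, hepatocyte and LSEC samples in the sheet. All
    intermediate fold changes are returned alongside the label.
    """
    q, a = hsc_sample_groups(sheet, paired=paired)
    hep = sheet.loc[sheet["cell_type"] == "hepatocyte", "sample_id"].tolist()
    lsec = sheet.loc[sheet["cell_type"] == "LSEC", "sample_id"].tolist()
    for name, group in (("hepatocyte", hep), ("LSEC", lsec)):
        if not group:
            raise ValueError(f"missing cell-type group: {name}")

    mean_q = expr[q].mean(axis=1)
    mean_a = expr[a].mean(axis=1)
    mean_hep = expr[hep].mean(axis=1)
    mean_lsec = expr[lsec].mean(axis=1)
    qa = group_fold_change(expr, q, a, paired=paired)
    fc_q_vs_a = qa["fc_linear"]
    p = qa["p_value"]

    fc_q_vs_hep = np.power(2.0, mean_q - mean_hep)
    fc_q_vs_lsec = np.power(2.0, mean_q - mean_lsec)
    fc_a_vs_hep = np.power(2.0, mean_a - mean_hep)
    fc_a_vs_lsec = np.power(2.0, mean_a - mean_lsec)

    q_assoc = (
        (fc_q_vs_hep >= enrichment_fc)
        & (fc_q_vs_lsec >= enrichment_fc)
        & (fc_q_vs_a >= q_down_fc)
    )
    a_assoc = (
        (fc_a_vs_hep >= enrichment_fc)
        & (fc_a_vs_lsec >= enrichment_fc)
        & (fc_q_vs_a < 1.0)  # up-regulated on activation
        & (p <= p_cut)
    )
    label = np.where(q_assoc, "q_associated", np.where(a_assoc, "a_associated", "unchanged"))
    return pd.DataFrame(
        {
            "feature_id": expr.index,
            "feature_kind": "gene",
            "fc_q_vs_a": fc_q_vs_a.to_numpy(),
            "fc_signed": qa["fc_signed"].to_numpy(),
            "p_value": p.to_numpy(),
            "fc_q_vs_hep": fc_q_vs_hep.to_numpy(),
            "fc_q_vs_lsec": fc_q_vs_lsec.to_numpy(),
            "fc_a_vs_hep": fc_a_vs_hep.to_numpy(),
            "fc_a_vs_lsec": fc_a_vs_lsec.to_numpy(),
            "class_label": label,
        }
    ).reset_index(drop=True)
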