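"""Network-level summaries of the selected miRNA-target pairs.

Covers the targets-per-miRNA distribution, the quiescence panel (miRNAs with
strictly more than ``panel_min`` functional targets), per-class target
statistics, the coverage of activation-induced genes by the panel, the
most-targeted gene, and class counts/percentages. Percentages are rounded
half-away-from-zero to integers.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "round_pct",
    "targets_per_mirna",
    "build_panel",
    "class_target_stats",
    "coverage_stats",
    "class_count_summary",
    "targets_histogram",
]


def round_pct(fraction: float) -> int:
    """Fraction -> integer percent, rounding half away from zero."""
    x = 100.0 * fraction
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def targets_per_mirna(pairs: pd.DataFrame, mirna_ids=None) -> pd.Series:
    """Selected-pair count per miRNA; miRNAs with none are reported as 0."""
    counts = (
        pairs[pairs["selected"]].groupby("mirna_id").size()
        if "selected" in pairs.columns
        else pairs.groupby("mirna_id").size()
    )
    ids = list(mirna_ids) if mirna_ids is not None else sorted(pairs["mirna_id"].unique())
    return counts.reindex(ids, fill_value=0).rename("n_targets").astype(int)


def build_panel(
    de: pd.DataFrame, counts: pd.Series, panel_min: int = 6, strict: bool = True
) -> pd.DataFrame:
    """Quiescence panel: q_associated miRNAs with n_targets above panel_min.

    The cut is strictly greater-than by default. Rows carry fc_q_vs_a and
    p_value from the differential table and are sorted by target count
    descending, then miRNA id.
    """
    q = de[(de["feature_kind"] == "miRNA") & (de["class_label"] == "q_associated")]
    q = q.set_index("feature_id")
    n = counts.reindex(q.index, fill_value=0)
    keep = n > panel_min if strict else n >= panel_min
    panel = pd.DataFrame(
        {
            "mirna_id": q.index[keep],
            "fc_q_vs_a": q.loc[keep, "fc_q_vs_a"].to_numpy(),
            "p_value": q.loc[keep, "p_value"].to_numpy(),
            "n_targets": n[keep].to_numpy(),
        }
    )
    return panel.sort_values(
        ["n_targets", "mirna_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def class_target_stats(
    de: pd.DataFrame, counts: pd.Series, panel_min: int = 6, strict: bool = True
) -> pd.DataFrame:
    """Mean/SD of targets per miRNA within each class, plus the panel fraction.

    SD is the n-1 sample standard deviation. ``pct_above_panel_min`` is the
    percentage of class members with a target count above ``panel_min``
    (strictly, by default), rounded to the nearest integer. Because the
    all-members denominator can be diluted by miRNAs with no selected target
    at all, the mean/SD restricted to members with >= 1 target are reported
    alongside. Empty classes get missing statistics.
    """
    rows = []
    mir = de[de["feature_kind"] == "miRNA"]
    for label in ("q_associated", "a_associated"):
        members = mir.loc[mir["class_label"] == label, "feature_id"]
        c = counts.reindex(members, fill_value=0).to_numpy(dtype=float)
        if c.size == 0:
            rows.append((label, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        above = (c > panel_min) if strict else (c >= panel_min)
        with_t = c[c >= 1]
        rows.append(
            (
                label,
                int(c.size),
                float(np.mean(c)),
                float(np.std(c, ddof=1)) if c.size > 1 else np.nan,
                float(np.mean(with_t)) if with_t.size else np.nan,
                float(np.std(with_t, ddof=1)) if with_t.size > 1 else np.nan,
                round_pct(above.mean()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "class_label",
            "n_mirnas",
            "mean_targets",
            "sd_targets",
            "mean_targets_nonzero",
            "sd_targets_nonzero",
            "pct_above_panel_min",
        ],
    )


def coverage_stats(pairs: pd.DataFrame, de: pd.DataFrame, panel: pd.DataFrame) -> dict:
    """Coverage of activation-induced genes by the panel, and the hub gene.

    coverage = |union of selected target genes of panel miRNAs| /
    |a_associated genes|. The most-targeted gene maximizes the number of
    distinct selected miRNAs targeting it; ties are all reported,
    alphabetically.
    """
    a_genes = de[(de["feature_kind"] == "gene") & (de["class_label"] == "a_associated")]
    n_a = len(a_genes)
    if n_a == 0:
        raise ValueError("no a_associated genes: coverage denominator is zero")
    sel = pairs[pairs["selected"]]
    panel_sel = sel[sel["mirna_id"].isin(panel["mirna_id"])]
    union = set(panel_sel["gene_id"])
    coverage = len(union) / n_a

    if len(sel):
        per_gene = sel.groupby("gene_id")["mirna_id"].nunique()
        top = int(per_gene.max())
        hubs = sorted(per_gene.index[per_gene == top])
    else:
        top, hubs = 0, []
    return {
        "n_panel_target_genes": len(union),
        "n_a_associated_genes": n_a,
        "coverage": coverage,
        "coverage_pct": round_pct(coverage),
        "most_targeted_genes": hubs,
        "most_targeted_n_mirnas": top,
    }


def class_count_summary(de: pd.DataFrame) -> pd.DataFrame:
    """Counts and integer percentages per class among deregulated features."""
    dereg = de[de["class_label"] != "unchanged"]
    total = len(dereg)
    rows = []
    for label in ("q_associated", "a_associated"):
        n = int((dereg["class_label"] == label).sum())
        pct = round_pct(n / total) if total else 0
        rows.append((label, n, pct))
    return pd.DataFrame(rows, columns=["class_label", "n_features", "pct_of_deregulated"])


def targets_histogram(counts: pd.Series) -> pd.DataFrame:
    """Target count -> number of miRNAs (histogram data table)."""
    h = counts.value_counts().sort_index()
    return pd.DataFrame({"n_targets": h.index.astype(int), "n_mirnas": h.to_numpy()})
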