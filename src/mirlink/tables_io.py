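"""Readers and writers for every table the pipeline touches.

All pipeline-native files are plain tab-separated text with decimal points.
The bundled quiescence-panel table is the one exception: it ships exactly as
printed in its source (decimal commas, centered-dot scientific notation such
as ``2.06·10–5``), and :func:`parse_panel_table` understands that dialect.
A pre-normalized copy is bundled alongside it.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_sample_sheet",
    "read_prediction_table",
    "write_prediction_table",
    "read_pair_table",
    "write_pair_table",
    "parse_panel_table",
    "parse_panel_number",
    "load_panel_fixture",
]

MISSING_TOKENS = ("", "NA")

CELL_TYPES = {"HSC", "hepatocyte", "LSEC", "KC", "whole_liver"}
STATES = {"quiescent", "activated", "n/a"}


# ---------------------------------------------------------------------------
# expression / Ct matrices


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a features-in-rows TSV matrix (first column = feature id).

    Empty cells and ``NA`` are preserved as missing. Duplicate feature ids or
    any other non-numeric cell raise ``ValueError`` naming the offender.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate feature id(s) in {path}: {dup}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for row, tok in df[col].items():
            tok = tok.strip()
            if tok in MISSING_TOKENS:
                out.loc[row, col] = np.nan
                continue
            try:
                out.loc[row, col] = float(tok)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {tok!r} at feature {row!r}, sample {col!r}"
                ) from None
    out.index.name = df.index.name or "feature_id"
    return out


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# sample sheets


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "cell_type", "state", "donor_id"]
    for col in required:
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample id(s): {dup}")
    bad_ct = set(sheet["cell_type"]) - CELL_TYPES
    if bad_ct:
        raise ValueError(f"unknown cell type(s): {sorted(bad_ct)}")
    bad_state = set(sheet["state"]) - STATES
    if bad_state:
        raise ValueError(f"unknown state(s): {sorted(bad_state)}")
    hsc = sheet[sheet["cell_type"] == "HSC"]
    if (hsc["state"] == "n/a").any():
        bad = hsc.loc[hsc["state"] == "n/a", "sample_id"].tolist()
        raise ValueError(f"HSC sample(s) without a state: {bad}")
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    # keep_default_na: the "n/a" state token is data, not a missing value
    return validate_sample_sheet(
        pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    )


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# prediction / pair tables


def read_prediction_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_prediction(df)
    return df


def _check_prediction(df: pd.DataFrame) -> None:
    for col in ("mirna_id", "gene_id", "p_database"):
        if col not in df.columns:
            raise ValueError(f"prediction table missing column {col!r}")
    if df.duplicated(["mirna_id", "gene_id"]).any():
        raise ValueError("prediction table has duplicate (mirna_id, gene_id) pairs")
    p = df["p_database"].to_numpy(dtype=float)
    if np.nanmin(p, initial=0.0) < 0.0 or np.nanmax(p, initial=0.0) > 1.0:
        raise ValueError("p_database outside [0, 1]")


def write_prediction_table(df: pd.DataFrame, path) -> None:
    _check_prediction(df)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "selected" in df.columns:
        df["selected"] = df["selected"].astype(bool)
    return df


def write_pair_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# the as-printed quiescence panel table

# mantissa [·x×] 10 [sign] exponent, e.g. "2.06·10–5"; the sign may be an
# ASCII hyphen, en/em dash or true minus, and the mantissa may use a comma.
_SCI_RE = re.compile(
    r"^(?P<mant>\d+[.,]?\d*)\s*[·×x]\s*10\^?\s*(?P<sign>[–—−+-]?)(?P<exp>\d+)$"
)


def parse_panel_number(token: str) -> float:
    """Parse one numeric token of the as-printed panel dialect.

    Handles decimal commas ("22,55" -> 22.55) and centered-dot scientific
    notation with dash-like minus signs ("2.06·10–5" -> 2.06e-5).
    """
    tok = token.strip()
    m = _SCI_RE.match(tok)
    if m:
        mant = float(m.group("mant").replace(",", "."))
        exp = int(m.group("exp"))
        if m.group("sign") not in ("", "+"):
            exp = -exp
        return mant * 10.0**exp
    try:
        return float(tok.replace(",", "."))
    except ValueError:
        raise ValueError(f"malformed numeric token {token!r}") from None


def parse_panel_table(path) -> pd.DataFrame:
    """Parse a panel table (miRNA, fold change, p-value, target count).

    Accepts the as-printed dialect or already-normalized numbers; a header
    line is skipped when its numeric fields do not parse as numbers. Target
    counts must be integers.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 4:
                raise ValueError(
                    f"line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            if lineno == 1:
                try:
                    parse_panel_number(fields[1])
                except ValueError:
                    continue  # header
            mirna, fc_tok, p_tok, n_tok = fields
            fc = parse_panel_number(fc_tok)
            p = parse_panel_number(p_tok)
            n = parse_panel_number(n_tok)
            if n != int(n):
                raise ValueError(f"malformed numeric token {n_tok!r} (target count)")
            rows.append((mirna, fc, p, int(n)))
    df = pd.DataFrame(rows, columns=["mirna_id", "fc_q_vs_a", "p_value", "n_targets"])
    if (df["fc_q_vs_a"] <= 0).any():
        raise ValueError("panel fold changes must be positive")
    if (df["n_targets"] < 0).any():
        raise ValueError("panel target counts must be non-negative")
    return df


def load_panel_fixture(normalized: bool = False) -> pd.DataFrame:
    """Load the bundled 31-miRNA quiescence panel table."""
    name = "table1_panel_normalized.tsv" if normalized else "table1_panel.tsv"
    ref = resources.files("mirlink.data").joinpath(name)
    with resources.as_file(ref) as path:
        if normalized:
            return pd.read_csv(path, sep="\t")
        return parse_panel_table(path)
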