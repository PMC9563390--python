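"""Readers and writers for the delimited-text interchange formats.

All tables are plain delimited text: tab-separated on output (fixed
column order and decimal formatting, so results files diff and
round-trip byte-identically), comma- or tab-separated on input with
case-insensitive header synonyms.

Results-table formatting: counts as integers, statistics to 2 decimals,
p-values in scientific notation with 4 significant digits, ORs and CI
bounds to 2 decimals, missing values as ``NA``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .multtest import PValueSet, harmonic_number
from .pipeline import RESULT_COLUMNS

__all__ = ["read_pvalue_table", "to_pvalue_set", "write_results_tsv",
           "read_results_tsv", "read_table", "fdr_plot_data",
           "write_fdr_plot", "read_config"]

# canonical name -> accepted case-insensitive synonyms
_SYNONYMS = {
    "code_group": {"code_group", "code", "icd10_code", "icd10", "group"},
    "mcnemar_stat": {"mcnemar_stat", "statistic", "stat", "mcnemar"},
    "p_value": {"p_value", "p", "pvalue", "p_val", "unadjusted_p"},
    "p_adjusted": {"p_adjusted", "adjusted_p", "p_adj", "padj"},
    "odds_ratio": {"odds_ratio", "or", "oddsratio"},
    "ci_lower": {"ci_lower", "lcl", "lower", "ci_low", "or_lcl"},
    "ci_upper": {"ci_upper", "ucl", "upper", "ci_high", "or_ucl"},
}

_INT_COLS = ["n_pairs", "n11", "n10", "n01", "n00", "significant", "relevant"]
_2DP_COLS = ["mcnemar_stat", "odds_ratio", "ci_lower", "ci_upper"]
_SCI_COLS = ["p_value", "p_adjusted"]


def _sep_for(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-separated table with a header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep=_sep_for(path))


def read_pvalue_table(path: str | Path) -> pd.DataFrame:
    """Read a per-code p-value table, e.g. a pre-aggregated screen output.

    Mandatory columns (case-insensitive synonyms accepted): the code
    group and the unadjusted p-value.  Optional: McNemar statistic, OR,
    CI bounds.  Rows with p outside [0, 1] are rejected with their
    1-based data row numbers.
    """
    df = read_table(path)
    if len(df) == 0:
        raise ValueError(f"empty p-value table: {path}")
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        for canon, names in _SYNONYMS.items():
            if key in names:
                rename[col] = canon
    df = df.rename(columns=rename)
    for required in ("code_group", "p_value"):
        if required not in df.columns:
            raise ValueError(f"missing mandatory column {required!r} in {path}")
    p = pd.to_numeric(df["p_value"], errors="coerce")
    bad = p.isna() | (p < 0) | (p > 1)
    if bad.any():
        rows = (np.where(bad)[0] + 1).tolist()
        raise ValueError(f"p-values outside [0, 1] (or non-numeric) at row(s) {rows[:10]}")
    df["p_value"] = p
    keep = [c for c in ["code_group", "mcnemar_stat", "p_value", "p_adjusted",
                        "odds_ratio", "ci_lower", "ci_upper"] if c in df.columns]
    return df[keep]


def to_pvalue_set(df: pd.DataFrame) -> PValueSet:
    return PValueSet(df["code_group"].astype(str).tolist(), df["p_value"].to_numpy())


def _fmt(value, col: str) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    if col in _INT_COLS:
        return str(int(value))
    if col in _2DP_COLS:
        return f"{float(value):.2f}"
    if col in _SCI_COLS:
        return f"{float(value):.3e}"
    return str(value)


def write_results_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results table in the canonical column order and formats."""
    cols = [c for c in RESULT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    lines = ["\t".join(cols)]
    for _, row in df.iterrows():
        lines.append("\t".join(_fmt(row[c], c) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df


def fdr_plot_data(pset: PValueSet, q: float = 0.05) -> pd.DataFrame:
    """Sorted p-values with their BY step-up threshold line.

    Columns rank, p_value, by_threshold (rank * q / (m * c(m))): the
    display underlying an FDR plot — every p-value at or below the
    threshold line up to the step-up crossing is significant.
    """
    p = np.sort(pset.p_values)
    m = p.size
    ranks = np.arange(1, m + 1)
    thresh = ranks * q / (m * harmonic_number(m))
    return pd.DataFrame({"rank": ranks, "p_value": p, "by_threshold": thresh})


def write_fdr_plot(data: pd.DataFrame, path: str | Path) -> None:
    """Render the FDR plot (sorted p-values vs the BY cutoff line)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.scatter(data["rank"], data["p_value"], s=4, label="sorted p-values")
    ax.plot(data["rank"], data["by_threshold"], color="black",
            label="BY step-up threshold")
    ax.set_xlabel("rank")
    ax.set_ylabel("p-value")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` configuration mirroring the CLI flags.

    Lines starting with ``#`` and blank lines are ignored; keys are
    lower-cased with ``-`` normalised to ``_``.
    """
    cfg: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {i} is not 'key = value': {line!r}")
        key, _, value = line.partition("=")
        cfg[key.strip().lower().replace("-", "_")] = value.strip()
    return cfg
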