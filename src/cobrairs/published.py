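"""Access to the packaged published summary tables and footnote p-values.

The original study deposited no raw densitometry; what survives are the
per-group mean/SD/n summaries of the pattern frequencies (one table per
assay) and the pairwise p-values reported in the table footnotes.  These
fixtures drive the summary-statistics checks and parameterize the default
synthetic study.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort_stats import SummaryStats

__all__ = ["load_summary_table", "load_footnotes", "summary_stats"]

_FILES = {"LINE1": "line1_summary.tsv", "ALU": "alu_summary.tsv"}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("cobrairs") / "fixtures" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_summary_table(assay: str, include_flagged: bool = False) -> pd.DataFrame:
    """Published group summaries for one assay.

    Columns: cell_type, group, n, metric, mean, sd, flag.  Rows whose
    ``flag`` marks a suspected typesetting error are dropped unless
    ``include_flagged`` is set.
    """
    if assay not in _FILES:
        raise ValueError(f"unknown assay {assay!r}")
    df = _read(_FILES[assay])
    if not include_flagged:
        df = df[df["flag"].isna()].reset_index(drop=True)
    return df


def load_footnotes() -> pd.DataFrame:
    """Published pairwise p-values with their comparison definitions."""
    return _read("footnotes.tsv")


def summary_stats(assay: str, cell_type: str, group: str, metric: str) -> SummaryStats:
    """One published group summary as a SummaryStats object."""
    df = load_summary_table(assay, include_flagged=True)
    row = df[
        (df["cell_type"] == cell_type) & (df["group"] == group) & (df["metric"] == metric)
    ]
    if len(row) != 1:
        raise KeyError(f"no unique summary for {assay}/{cell_type}/{group}/{metric}")
    r = row.iloc[0]
    return SummaryStats(mean=float(r["mean"]), sd=float(r["sd"]), n=int(r["n"]))
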