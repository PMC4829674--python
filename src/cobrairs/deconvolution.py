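"""Pattern-frequency deconvolution and inter-assay normalization.

Given the molar-scale band quantities of one lane, the frequency of each
joint methylation pattern is the quantity of that pattern's representative
band over the sum of all four representative quantities:

* LINE-1: mCmC <- C (50 bp), uCmC <- F (inferred 18 bp), mCuC <- A (92 bp),
  uCuC <- B (60 bp); overall %mC = 100 (A + 2C + F) / (2 (A + B + C + F)).
* Alu: mCmC <- F (32 bp), uCmC <- C (75 bp), mCuC <- D (90 bp),
  uCuC <- A (133 bp); overall %mC = 100 (2F + D + C) / (2 (A + C + D + F)).
  The redundant Alu bands B (58 bp) and E (43 bp) never enter the
  frequencies; they feed the consistency residuals instead.

The overall methylation percentage always satisfies
%mC = %mCmC + (%uCmC + %mCuC) / 2: each fully methylated locus contributes
two methylated CpGs, each partially methylated locus one out of two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .densitometry import (
    BandQuantities,
    EffectiveLengthTable,
    Lane,
    infer_f_line1,
    quantify_lane,
)

__all__ = [
    "PatternFrequencies",
    "ConsistencyResiduals",
    "line1_frequencies",
    "alu_frequencies",
    "pattern_frequencies",
    "lane_consistency",
    "deconvolve_lanes",
    "interassay_normalize",
    "FREQ_COLUMNS",
]

PATTERN_COLS = ["pct_mCmC", "pct_uCmC", "pct_mCuC", "pct_uCuC"]
FREQ_COLUMNS = [
    "sample_id",
    "assay",
    "cell_type",
    "group",
    "batch",
    *PATTERN_COLS,
    "pct_mC",
    "qc_flags",
]


@dataclass(frozen=True)
class PatternFrequencies:
    """Percent frequencies of the four patterns plus overall methylation."""

    pct_mCmC: float
    pct_uCmC: float
    pct_mCuC: float
    pct_uCuC: float
    pct_mC: float
    qc_flags: frozenset[str] = frozenset()

    def as_array(self) -> np.ndarray:
        return np.array([self.pct_mCmC, self.pct_uCmC, self.pct_mCuC, self.pct_uCuC])


@dataclass(frozen=True)
class ConsistencyResiduals:
    """Relative residuals of the redundant-band identities (QC)."""

    r1: float
    r2: float


def _frequencies(mm: float, um: float, mu: float, uu: float, assay: str) -> PatternFrequencies:
    s = mm + um + mu + uu
    if s <= 0:
        raise ValueError(f"no quantifiable {assay} signal (denominator is zero)")
    # divide before scaling: robust to subnormal totals
    return PatternFrequencies(
        pct_mCmC=100.0 * (mm / s),
        pct_uCmC=100.0 * (um / s),
        pct_mCuC=100.0 * (mu / s),
        pct_uCuC=100.0 * (uu / s),
        pct_mC=100.0 * ((2 * mm + um + mu) / s) / 2.0,
    )


def line1_frequencies(q: BandQuantities) -> PatternFrequencies:
    """Frequencies from LINE-1 quantities (F must be set, see infer_f_line1)."""
    if q.assay != "LINE1":
        raise ValueError("expected LINE-1 quantities")
    if q.f is None:
        raise ValueError("LINE-1 F is unset; run infer_f_line1 first")
    freq = _frequencies(mm=q.c, um=q.f, mu=q.a, uu=q.b, assay="LINE-1")
    return PatternFrequencies(**{**freq.__dict__, "qc_flags": q.flags})


def alu_frequencies(q: BandQuantities) -> PatternFrequencies:
    """Frequencies from Alu quantities (A, C, D, F; B and E are QC-only)."""
    if q.assay != "ALU":
        raise ValueError("expected Alu quantities")
    freq = _frequencies(mm=q.f, um=q.c, mu=q.d, uu=q.a, assay="Alu")
    return PatternFrequencies(**{**freq.__dict__, "qc_flags": q.flags})


def pattern_frequencies(q: BandQuantities) -> PatternFrequencies:
    return line1_frequencies(q) if q.assay == "LINE1" else alu_frequencies(q)


def lane_consistency(q: BandQuantities) -> ConsistencyResiduals:
    """Residuals of the redundant-band identities, relative to the lane total.

    Alu: the 58 bp band is produced by both uCmC and mCmC (B = C + F) and
    the 43 bp band by mCuC and mCmC (E = D + F).  LINE-1: the 42 bp band by
    mCmC and uCmC (D = C + F) and the 32 bp band by uCuC and uCmC
    (E = B + F).  Residuals vanish for exact, noise-free lanes.
    """
    f = q.f if q.f is not None else 0.0
    if q.assay == "ALU":
        raw1 = q.b - (q.c + f)
        raw2 = q.e - (q.d + f)
        total = q.a + q.c + q.d + f
    else:
        raw1 = q.d - (q.c + f)
        raw2 = q.e - (q.b + f)
        total = q.a + q.b + q.c + f
    if total <= 0:
        raise ValueError("no signal to scale residuals by")
    return ConsistencyResiduals(r1=raw1 / total, r2=raw2 / total)


def deconvolve_lanes(
    lanes: list[Lane],
    table: EffectiveLengthTable | None = None,
    f_variant: str = "algebraic",
) -> pd.DataFrame:
    """Quantify and deconvolve a list of lanes into a tidy frequency table."""
    table = table or EffectiveLengthTable.as_printed()
    rows = []
    for lane in lanes:
        q = quantify_lane(lane, table)
        if lane.assay == "LINE1":
            q = infer_f_line1(q, variant=f_variant)
        freq = pattern_frequencies(q)
        rows.append(
            {
                "sample_id": lane.sample_id,
                "assay": lane.assay,
                "cell_type": lane.cell_type,
                "group": lane.group,
                "batch": lane.batch,
                "pct_mCmC": freq.pct_mCmC,
                "pct_uCmC": freq.pct_uCmC,
                "pct_mCuC": freq.pct_mCuC,
                "pct_uCuC": freq.pct_uCuC,
                "pct_mC": freq.pct_mC,
                "qc_flags": ";".join(sorted(freq.qc_flags)),
            }
        )
    return pd.DataFrame(rows, columns=FREQ_COLUMNS)


def interassay_normalize(
    frequencies: pd.DataFrame, controls: pd.DataFrame
) -> pd.DataFrame:
    """Remove between-batch offsets using control cell-line measurements.

    Control DNA from fixed cell lines is run in every batch; the reference
    value of a control line is its grand mean across batches.  Per batch,
    assay and pattern, the mean deviation of that batch's controls from
    their references is subtracted from every sample measurement, the four
    patterns are renormalized to sum 100 (negative values clamped to 0
    first), and the overall %mC is recomputed.  Batches whose controls sit
    exactly at the reference are returned unchanged.

    Parameters
    ----------
    frequencies
        Sample frequency table (columns of :data:`FREQ_COLUMNS`).
    controls
        Control-lane frequency table with an additional ``control_line``
        column identifying the cell line.
    """
    if "control_line" not in controls.columns:
        raise ValueError("controls table needs a control_line column")
    out = frequencies.copy()
    for assay in out["assay"].unique():
        ctrl = controls[controls["assay"] == assay]
        batches = out.loc[out["assay"] == assay, "batch"].unique()
        missing = [b for b in batches if b not in set(ctrl["batch"])]
        if missing:
            raise ValueError(f"batches without {assay} control lanes: {missing}")
        reference = ctrl.groupby("control_line")[PATTERN_COLS].mean()
        for batch in batches:
            in_batch = ctrl[ctrl["batch"] == batch]
            deviation = (
                in_batch.set_index("control_line")[PATTERN_COLS] - reference
            ).dropna()
            correction = deviation.mean(axis=0).to_numpy()
            mask = (out["assay"] == assay) & (out["batch"] == batch)
            adj = out.loc[mask, PATTERN_COLS].to_numpy() - correction
            adj = np.clip(adj, 0.0, None)
            adj = 100.0 * adj / adj.sum(axis=1, keepdims=True)
            out.loc[mask, PATTERN_COLS] = adj
            out.loc[mask, "pct_mC"] = (
                adj[:, 0] + (adj[:, 1] + adj[:, 2]) / 2.0
            )
    return out
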