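"""Synthetic COBRA-IRS studies: cohorts, lanes, and ground truth.

No raw densitometry was deposited for the original cohorts, so testable
inputs are produced by simulation.  Per-sample pattern frequencies are
drawn around the published per-group means/SDs (truncated normals,
renormalized to the 100-simplex), then rendered into gel-lane band
intensities through the digestion forward model: a pattern present at molar
quantity q contributes q x effective_length to each of its fragment bands,
times an overall scale, a per-batch gain, and multiplicative lognormal
densitometry noise.  The invisible 18 bp LINE-1 band is omitted from
rendered lanes by default so that the downstream F-inference path is
exercised exactly as on real gels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .amplicon import PATTERNS
from .densitometry import ASSAY_MODELS, EffectiveLengthTable, Lane
from .deconvolution import PATTERN_COLS
from .published import load_summary_table

__all__ = [
    "CohortSpec",
    "GelNoiseModel",
    "StudyCohort",
    "StudyConfig",
    "StudyData",
    "sample_pattern_frequencies",
    "frequencies_to_lane",
    "generate_study",
    "DEFAULT_CONTROL_LINES",
]

# pattern order everywhere: (mCmC, uCmC, mCuC, uCuC)
_MEAN_SUM_TOL = 0.5


@dataclass(frozen=True)
class CohortSpec:
    """Target distribution of one cohort: per-pattern mean/SD in percent."""

    group: str
    n: int
    means: tuple[float, float, float, float]
    sds: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be at least 2")
        if any(m < 0 for m in self.means) or any(s < 0 for s in self.sds):
            raise ValueError("means and sds must be nonnegative")
        total = sum(self.means)
        if total <= 0:
            raise ValueError("infeasible spec: all pattern means are zero")
        if abs(total - 100.0) > _MEAN_SUM_TOL:
            raise ValueError(
                f"pattern means must sum to ~100 (got {total:.2f}) for group {self.group}"
            )


@dataclass(frozen=True)
class GelNoiseModel:
    """Multiplicative lognormal band noise plus per-batch distortions.

    ``sigma`` is the SD of the log-intensity noise per band.  ``batch_scale``
    models gel-to-gel gain differences (harmless: frequencies are
    scale-invariant).  ``batch_offset`` adds a per-batch shift to the
    frequency vector before rendering, emulating the inter-assay variation
    that the cell-line normalization is meant to remove; zero-sum offsets
    keep the shifted vector on the simplex.
    """

    sigma: float = 0.05
    batch_scale: Mapping[str, float] = field(default_factory=dict)
    batch_offset: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if any(s <= 0 for s in self.batch_scale.values()):
            raise ValueError("batch scale factors must be positive")


@dataclass(frozen=True)
class StudyCohort:
    assay: str
    cell_type: str
    spec: CohortSpec


# Fixed truth vectors standing in for the control cell-line DNA run in every
# batch; the original study reports no values for them.  Cancer cell lines
# are globally hypomethylated relative to blood, which these emulate.
DEFAULT_CONTROL_LINES: Mapping[str, Mapping[str, tuple[float, ...]]] = {
    "HeLa": {"LINE1": (62.0, 12.0, 18.0, 8.0), "ALU": (12.0, 30.0, 26.0, 32.0)},
    "Jurkat": {"LINE1": (70.0, 9.0, 15.0, 6.0), "ALU": (16.0, 31.0, 24.0, 29.0)},
    "Daudi": {"LINE1": (55.0, 15.0, 20.0, 10.0), "ALU": (10.0, 28.0, 27.0, 35.0)},
}


@dataclass(frozen=True)
class StudyConfig:
    """Complete recipe for one synthetic study."""

    cohorts: tuple[StudyCohort, ...]
    batches: tuple[str, ...] = ("b1", "b2", "b3")
    divisor_mode: str = "as_printed"
    noise: GelNoiseModel = GelNoiseModel()
    scale: float = 1000.0
    visible_18: bool = False
    control_lines: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=lambda: DEFAULT_CONTROL_LINES
    )

    @classmethod
    def default(cls, sigma: float = 0.05) -> "StudyConfig":
        """The study design of the original cohorts: control n=15, active
        n=12, inactive n=17, PBMC + neutrophils, both assays, published
        group means/SDs as simulation targets."""
        cohorts = []
        for assay in ("LINE1", "ALU"):
            table = load_summary_table(assay)
            for cell_type in ("PBMC", "NEUTROPHIL"):
                for group in ("control", "active", "inactive"):
                    cohorts.append(
                        StudyCohort(assay, cell_type, _spec_from_table(table, cell_type, group))
                    )
        return cls(cohorts=tuple(cohorts), noise=GelNoiseModel(sigma=sigma))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cohorts = tuple(
            StudyCohort(
                assay=c["assay"],
                cell_type=c["cell_type"],
                spec=CohortSpec(
                    group=c["group"],
                    n=int(c["n"]),
                    means=tuple(float(v) for v in c["means"]),
                    sds=tuple(float(v) for v in c["sds"]),
                ),
            )
            for c in d["cohorts"]
        )
        noise = d.get("noise", {})
        return cls(
            cohorts=cohorts,
            batches=tuple(d.get("batches", ("b1", "b2", "b3"))),
            divisor_mode=d.get("divisor_mode", "as_printed"),
            noise=GelNoiseModel(
                sigma=float(noise.get("sigma", 0.05)),
                batch_scale={k: float(v) for k, v in noise.get("batch_scale", {}).items()},
                batch_offset={
                    k: tuple(float(x) for x in v)
                    for k, v in noise.get("batch_offset", {}).items()
                },
            ),
            scale=float(d.get("scale", 1000.0)),
            visible_18=bool(d.get("visible_18", False)),
        )


def _spec_from_table(table: pd.DataFrame, cell_type: str, group: str) -> CohortSpec:
    sub = table[(table["cell_type"] == cell_type) & (table["group"] == group)]
    sub = sub.set_index("metric")
    n = int(sub["n"].iloc[0])
    means, sds = [], []
    present = {m for m in sub.index}
    pattern_metrics = ["pct_mCmC", "pct_uCmC", "pct_mCuC", "pct_uCuC"]
    for metric in pattern_metrics:
        if metric in present:
            means.append(float(sub.loc[metric, "mean"]))
            sds.append(float(sub.loc[metric, "sd"]))
        else:
            # a flagged (suspect) entry was dropped: complete the simplex and
            # reuse the median SD of the remaining patterns
            means.append(np.nan)
            sds.append(np.nan)
    means = np.array(means)
    sds = np.array(sds)
    if np.isnan(means).any():
        means[np.isnan(means)] = 100.0 - np.nansum(means)
        sds[np.isnan(sds)] = np.nanmedian(sds)
    return CohortSpec(group=group, n=n, means=tuple(means), sds=tuple(sds))


def _compensated_sds(means, sds) -> np.ndarray:
    """Pre-normalization SDs whose renormalized output hits the targets.

    Renormalizing independent draws to the 100-simplex mixes variance
    between patterns (delta method: var_out_j = (1-p_j)^2 v_j
    + p_j^2 sum_{k != j} v_k with p_j = mean_j / 100), so drawing at the
    target SDs directly would distort them.  This solves the fixed point
    for the pre-normalization variances; a target below the cross-talk
    floor contributed by the other patterns is clamped at zero variance
    (the output SD then sits at that floor -- a documented limitation).
    """
    p = np.asarray(means, dtype=float) / 100.0
    t2 = np.asarray(sds, dtype=float) ** 2
    v = t2.copy()
    for _ in range(500):
        total = v.sum()
        v_new = np.clip((t2 - p**2 * (total - v)) / (1.0 - p) ** 2, 0.0, None)
        if np.allclose(v_new, v, rtol=1e-12, atol=1e-15):
            v = v_new
            break
        v = v_new
    return np.sqrt(v)


def sample_pattern_frequencies(spec: CohortSpec, seed=None) -> np.ndarray:
    """Draw per-sample frequency vectors for one cohort.

    Each pattern value is drawn independently from a normal truncated at
    zero, then the four values are renormalized to sum 100.  The
    pre-normalization SDs are variance-compensated (see
    :func:`_compensated_sds`) so the renormalized output matches the spec's
    per-pattern means/SDs; residual distortion is measured by tests, not
    assumed away.

    Returns an (n, 4) array in pattern order (mCmC, uCmC, mCuC, uCuC).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = np.empty((spec.n, 4))
    pre_sds = _compensated_sds(spec.means, spec.sds)
    for j, (mean, sd) in enumerate(zip(spec.means, pre_sds)):
        if sd == 0:
            draws[:, j] = mean
        else:
            a = (0.0 - mean) / sd
            draws[:, j] = stats.truncnorm.rvs(
                a, np.inf, loc=mean, scale=sd, size=spec.n, random_state=rng
            )
    totals = draws.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("degenerate draw: all-zero frequency vector")
    return 100.0 * draws / totals[:, None]


def _render_bands(
    f: np.ndarray,
    assay: str,
    table: EffectiveLengthTable,
    scale: float,
    batch_scale: float,
    visible_18: bool,
) -> dict[int, float]:
    model = ASSAY_MODELS[assay]
    bands: dict[int, float] = {}
    from .amplicon import predict_fragments  # local import to avoid cycle at module load

    for q, pattern in zip(f, PATTERNS):
        if q <= 0:
            continue
        for frag in predict_fragments(model, pattern).fragments:
            if assay == "LINE1" and frag.length == 18 and not visible_18:
                continue
            intensity = q * table.divisor(assay, frag.length) * scale * batch_scale
            bands[frag.length] = bands.get(frag.length, 0.0) + intensity
    return bands


def frequencies_to_lane(
    f,
    assay: str,
    table: EffectiveLengthTable | None = None,
    scale: float = 1000.0,
    noise: GelNoiseModel | None = None,
    *,
    sample_id: str = "sample",
    cell_type: str = "PBMC",
    group: str = "control",
    batch: str = "b1",
    seed=None,
    visible_18: bool = False,
) -> Lane:
    """Render one frequency vector into a gel lane through the forward model.

    ``f`` is the (mCmC, uCmC, mCuC, uCuC) vector in percent.  Noise-free
    lanes (sigma = 0, no batch distortion) deconvolve back to ``f`` exactly
    when the same divisor table is used downstream.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (4,) or np.any(f < 0) or not np.isclose(f.sum(), 100.0, atol=1e-6):
        raise ValueError("frequency vector must be 4 nonnegative values summing to 100")
    table = table or EffectiveLengthTable.as_printed()
    noise = noise or GelNoiseModel(sigma=0.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    offset = np.array(noise.batch_offset.get(batch, (0.0, 0.0, 0.0, 0.0)))
    f_eff = np.clip(f + offset, 0.0, None)
    bands = _render_bands(
        f_eff, assay, table, scale, noise.batch_scale.get(batch, 1.0), visible_18
    )
    if noise.sigma > 0:
        for length in bands:
            bands[length] *= float(np.exp(rng.normal(0.0, noise.sigma)))
    return Lane(
        sample_id=sample_id, assay=assay, cell_type=cell_type, group=group,
        batch=batch, bands=bands,
    )


@dataclass
class StudyData:
    """Output bundle of generate_study."""

    lanes: list[Lane]
    truth: pd.DataFrame  # per-sample ground-truth frequencies
    control_lanes: list[Lane]
    control_truth: pd.DataFrame  # includes control_line column


def generate_study(config: StudyConfig, seed: int = 0) -> StudyData:
    """Generate a full synthetic study, deterministic per (config, seed).

    Emits sample lanes for every cohort, a ground-truth frequency table,
    and per-batch lanes of the fixed control cell lines (used by
    inter-assay normalization).  Subjects are assigned to batches round-
    robin within each cohort; measurements of the same subject in different
    assays or cell types are drawn independently.
    """
    rng = np.random.default_rng(seed)
    table = EffectiveLengthTable.from_mode(config.divisor_mode)
    lanes: list[Lane] = []
    truth_rows = []
    for cohort in config.cohorts:
        spec = cohort.spec
        freqs = sample_pattern_frequencies(spec, rng)
        for i in range(spec.n):
            sid = f"{spec.group}-{i + 1:02d}"
            batch = config.batches[i % len(config.batches)]
            lane = frequencies_to_lane(
                freqs[i], cohort.assay, table, config.scale, config.noise,
                sample_id=sid, cell_type=cohort.cell_type, group=spec.group,
                batch=batch, seed=rng, visible_18=config.visible_18,
            )
            lanes.append(lane)
            truth_rows.append(
                {
                    "sample_id": sid, "assay": cohort.assay,
                    "cell_type": cohort.cell_type, "group": spec.group,
                    "batch": batch,
                    **dict(zip(PATTERN_COLS, freqs[i])),
                    "pct_mC": freqs[i][0] + (freqs[i][1] + freqs[i][2]) / 2.0,
                }
            )

    study_assays = {c.assay for c in config.cohorts}
    control_lanes: list[Lane] = []
    control_rows = []
    for batch in config.batches:
        for line_name, per_assay in config.control_lines.items():
            for assay, vec in per_assay.items():
                if assay not in study_assays:
                    continue
                lane = frequencies_to_lane(
                    vec, assay, table, config.scale, config.noise,
                    sample_id=f"{line_name}_{batch}", cell_type="CELL_LINE",
                    group="cell_line", batch=batch, seed=rng,
                )
                control_lanes.append(lane)
                control_rows.append(
                    {
                        "sample_id": f"{line_name}_{batch}", "control_line": line_name,
                        "assay": assay, "cell_type": "CELL_LINE",
                        "group": "cell_line", "batch": batch,
                        **dict(zip(PATTERN_COLS, vec)),
                        "pct_mC": vec[0] + (vec[1] + vec[2]) / 2.0,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    control_truth = pd.DataFrame(control_rows)
    return StudyData(lanes=lanes, truth=truth, control_lanes=control_lanes,
                     control_truth=control_truth)
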