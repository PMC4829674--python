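"""Lane quantification: raw band intensities to length-normalized quantities.

Staining intensity of a gel band is proportional to the molar amount of the
fragment times its double-stranded length, so dividing each band's intensity
by an effective double-stranded length converts it to a molar-scale
quantity.  The effective length discounts the single-stranded 5' overhangs
left by the restriction enzymes (TaqI 2 nt, TasI 4 nt per cut end).

Quantities carry the conventional letters:

* LINE-1 (92 bp amplicon): A=92 bp band, B=60, C=50, D=42, E=32; F stands
  for the 18 bp band, which is too faint to quantify on the gel and is
  instead inferred from the redundant-band bookkeeping
  (see :func:`infer_f_line1`).
* Alu (133 bp amplicon): A=133, B=58, C=75, D=90, E=43, F=32.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .amplicon import (
    ALU_133,
    BLUNT,
    ENZYMES,
    LINE1_92,
    AmpliconModel,
    MethylationPattern,
    band_catalog,
    predict_fragments,
)

__all__ = [
    "ASSAYS",
    "ASSAY_MODELS",
    "BAND_LETTERS",
    "Lane",
    "EffectiveLengthTable",
    "BandQuantities",
    "effective_length",
    "quantify_lane",
    "infer_f_line1",
    "read_lanes_tsv",
    "write_lanes_tsv",
]

ASSAYS = ("LINE1", "ALU")
CELL_TYPES = ("PBMC", "NEUTROPHIL")
GROUPS = ("control", "active", "inactive")

ASSAY_MODELS: Mapping[str, AmpliconModel] = {"LINE1": LINE1_92, "ALU": ALU_133}

# Band length -> quantity letter, per assay.  LINE-1 has no direct F band:
# the 18 bp fragment is invisible on the gel and F is inferred.
BAND_LETTERS: Mapping[str, Mapping[int, str]] = {
    "LINE1": {92: "A", 60: "B", 50: "C", 42: "D", 32: "E"},
    "ALU": {133: "A", 58: "B", 75: "C", 90: "D", 43: "E", 32: "F"},
}

# Divisors exactly as used in the original analysis.  Two Alu entries (133
# and 32) differ from the overhang bookkeeping (133 vs 131, 28 vs 30); both
# are reproduced verbatim in this mode without interpretation.
AS_PRINTED_DIVISORS: Mapping[str, Mapping[int, float]] = {
    "LINE1": {92: 92, 60: 56, 50: 48, 42: 40, 32: 28},
    "ALU": {133: 131, 58: 56, 75: 73, 90: 88, 43: 41, 32: 30},
}


def _assay_catalog(assay: str) -> dict[int, set]:
    return band_catalog(ASSAY_MODELS[assay])


@dataclass
class Lane:
    """One gel lane: band lengths -> raw intensities, with sample metadata."""

    sample_id: str
    assay: str
    cell_type: str
    group: str
    batch: str
    bands: dict[int, float]

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        catalog = _assay_catalog(self.assay)
        for length, intensity in self.bands.items():
            if length not in catalog:
                raise ValueError(
                    f"lane {self.sample_id}: band length {length} not in the "
                    f"{self.assay} catalog {sorted(catalog)}"
                )
            if intensity < 0:
                raise ValueError(f"lane {self.sample_id}: negative intensity at {length} bp")
        if not any(v > 0 for v in self.bands.values()):
            raise ValueError(f"lane {self.sample_id}: empty lane (no nonzero band)")


def _fragment_ends(assay: str) -> dict[int, tuple[str, str]]:
    """End labels per band length; unique per length for the built-in models."""
    ends: dict[int, tuple[str, str]] = {}
    model = ASSAY_MODELS[assay]
    for pattern in MethylationPattern:
        for frag in predict_fragments(model, pattern).fragments:
            labels = (frag.left_end, frag.right_end)
            prev = ends.setdefault(frag.length, labels)
            assert prev == labels, "ambiguous end labels for a shared band length"
    return ends


def _geometric_divisor(length: int, ends: Iterable[str]) -> float:
    overhang = sum(ENZYMES[e].overhang_nt for e in ends if e != BLUNT)
    return float(length - overhang)


@dataclass(frozen=True)
class EffectiveLengthTable:
    """Per-assay band length -> double-stranded length divisor.

    ``as_printed`` reproduces the original arithmetic verbatim;
    ``geometric`` derives every divisor from the fragment end labels
    (length minus the summed overhangs of enzyme-cut ends).
    """

    mode: str
    divisors: Mapping[str, Mapping[int, float]]

    @classmethod
    def as_printed(cls) -> "EffectiveLengthTable":
        table = {a: dict(v) for a, v in AS_PRINTED_DIVISORS.items()}
        # the invisible 18 bp LINE-1 band has no printed divisor; the
        # geometric value (18 - 4 - 2 = 12) is used if it is ever quantified
        table["LINE1"][18] = _geometric_divisor(18, _fragment_ends("LINE1")[18])
        return cls("as_printed", table)

    @classmethod
    def geometric(cls) -> "EffectiveLengthTable":
        table = {
            assay: {
                length: _geometric_divisor(length, ends)
                for length, ends in _fragment_ends(assay).items()
            }
            for assay in ASSAYS
        }
        return cls("geometric", table)

    @classmethod
    def from_mode(cls, mode: str) -> "EffectiveLengthTable":
        if mode == "as_printed":
            return cls.as_printed()
        if mode == "geometric":
            return cls.geometric()
        raise ValueError(f"unknown divisor mode {mode!r}")

    def divisor(self, assay: str, length: int) -> float:
        try:
            return self.divisors[assay][length]
        except KeyError:
            raise ValueError(
                f"band length {length} has no {self.mode} divisor for assay {assay}"
            ) from None


def effective_length(
    length: int,
    ends: tuple[str, str] = (BLUNT, BLUNT),
    assay: str = "LINE1",
    mode: str = "geometric",
) -> float:
    """Effective double-stranded length divisor for one fragment.

    In geometric mode the divisor is the fragment length minus the 5'
    overhang of each enzyme-cut end (blunt PCR ends subtract nothing).  In
    as_printed mode the divisor is looked up from the fixed published table
    for the given assay.
    """
    if mode == "geometric":
        return _geometric_divisor(length, ends)
    if mode == "as_printed":
        return EffectiveLengthTable.as_printed().divisor(assay, length)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class BandQuantities:
    """Molar-scale quantities A..F for one lane (intensity per ds-bp)."""

    assay: str
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 0.0
    f: float | None = None
    flags: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float | None]:
        return {"A": self.a, "B": self.b, "C": self.c, "D": self.d, "E": self.e, "F": self.f}


def quantify_lane(lane: Lane, table: EffectiveLengthTable) -> BandQuantities:
    """Divide each band intensity by its effective-length divisor.

    Missing bands count as zero intensity.  For LINE-1, F is left unset; use
    :func:`infer_f_line1`.  The 18 bp LINE-1 band, when present in the input,
    does not enter A-E (F is always inferred from the redundant bands).
    """
    letters = BAND_LETTERS[lane.assay]
    values = {"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0, "E": 0.0, "F": 0.0}
    for length, intensity in lane.bands.items():
        letter = letters.get(length)
        if letter is None:
            continue  # LINE-1 18 bp: catalog-valid but not directly quantified
        values[letter] += intensity / table.divisor(lane.assay, length)
    f = values["F"] if lane.assay == "ALU" else None
    return BandQuantities(
        assay=lane.assay,
        a=values["A"],
        b=values["B"],
        c=values["C"],
        d=values["D"],
        e=values["E"],
        f=f,
    )


def infer_f_line1(q: BandQuantities, variant: str = "algebraic") -> BandQuantities:
    """Infer the invisible 18 bp LINE-1 quantity F from the redundant bands.

    The 42 bp band is shared by the mCmC and uCmC patterns (D = C + F) and
    the 32 bp band by uCuC and uCmC (E = B + F), so the band-sharing system
    has the unique solution F = ((D + E) - (B + C)) / 2 -- the ``algebraic``
    variant.  The ``as_printed`` variant applies the published formula
    F = ((D + E) - (B - C)) / 2 literally; it differs in the sign of C and
    is kept only for exact reproduction of the original arithmetic.

    A negative inferred F (routine under densitometry noise) is clamped to
    zero and flagged ``negative_F_clamped``.
    """
    if q.assay != "LINE1":
        raise ValueError("F inference applies to LINE-1 quantities only")
    if variant == "algebraic":
        f = ((q.d + q.e) - (q.b + q.c)) / 2.0
    elif variant == "as_printed":
        f = ((q.d + q.e) - (q.b - q.c)) / 2.0
    else:
        raise ValueError(f"unknown F variant {variant!r}")
    flags = set(q.flags)
    if f < 0:
        f = 0.0
        flags.add("negative_F_clamped")
    return replace(q, f=f, flags=frozenset(flags))


LANE_TSV_COLUMNS = [
    "sample_id",
    "assay",
    "cell_type",
    "group",
    "batch",
    "band_length",
    "intensity",
]


def read_lanes_tsv(path: str | Path) -> list[Lane]:
    """Read a lane table (one row per band) into validated Lane objects."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"batch": str, "sample_id": str})
    missing = [c for c in LANE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lane TSV {path} missing columns: {missing}")
    lanes = []
    keys = ["sample_id", "assay", "cell_type", "group", "batch"]
    for meta, sub in df.groupby(keys, sort=False):
        bands = {
            int(row.band_length): float(row.intensity) for row in sub.itertuples()
        }
        lanes.append(Lane(*meta, bands=bands))
    return lanes


def write_lanes_tsv(lanes: Iterable[Lane], path: str | Path, header_lines: Iterable[str] = ()) -> None:
    rows = []
    for lane in lanes:
        for length in sorted(lane.bands, reverse=True):
            rows.append(
                {
                    "sample_id": lane.sample_id,
                    "assay": lane.assay,
                    "cell_type": lane.cell_type,
                    "group": lane.group,
                    "batch": lane.batch,
                    "band_length": length,
                    "intensity": lane.bands[length],
                }
            )
    df = pd.DataFrame(rows, columns=LANE_TSV_COLUMNS)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
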