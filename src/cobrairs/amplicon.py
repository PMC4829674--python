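"""Restriction geometry of COBRA amplicons.

A COBRA amplicon interrogates two CpG dinucleotides inside a short PCR
product of bisulfite-converted DNA.  Methylation at a CpG decides whether a
restriction site survives conversion (TaqI, T^CGA: the site exists only if
the cytosine was methylated) or is created by it (TasI, ^AATT: the site
exists only if the cytosine was unmethylated and converted to T).  Each of
the four joint methylation patterns of the two sites therefore produces a
distinct fragment ladder on the gel, which is what this module predicts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Enzyme",
    "CpGCutSite",
    "MethylationPattern",
    "AmpliconModel",
    "Fragment",
    "FragmentSet",
    "TAQI",
    "TASI",
    "ENZYMES",
    "LINE1_92",
    "ALU_133",
    "BUILTIN_MODELS",
    "BLUNT",
    "METHYLATED",
    "UNMETHYLATED",
    "bisulfite_convert",
    "scan_sites",
    "predict_fragments",
    "band_catalog",
    "representative_bands",
]

BLUNT = "blunt"
METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"

_DNA_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with a 4-letter recognition motif.

    ``cut_offset`` is the distance in bases from the 5' end of the motif to
    the top-strand cut; ``overhang_nt`` is the length of the 5'
    single-stranded overhang left at each cut end.
    """

    name: str
    recognition: str
    cut_offset: int
    overhang_nt: int

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.recognition):
            raise ValueError(
                f"recognition motif must be A/C/G/T only: {self.recognition!r}"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the recognition motif")
        if not 0 <= self.overhang_nt <= len(self.recognition):
            raise ValueError("overhang_nt cannot exceed the motif length")


TAQI = Enzyme("TaqI", "TCGA", cut_offset=1, overhang_nt=2)
TASI = Enzyme("TasI", "AATT", cut_offset=0, overhang_nt=4)

ENZYMES: Mapping[str, Enzyme] = {e.name: e for e in (TAQI, TASI)}


@dataclass(frozen=True)
class CpGCutSite:
    """A methylation-dependent cut site inside an amplicon.

    ``position`` is the cut coordinate in bp from the amplicon 5' end: a cut
    at ``p`` splits the amplicon into fragments of length ``p`` and
    ``length - p``.  ``cut_when`` states the methylation state of the CpG
    under which the enzyme cuts.
    """

    position: int
    enzyme: Enzyme
    cut_when: str

    def __post_init__(self) -> None:
        if self.cut_when not in (METHYLATED, UNMETHYLATED):
            raise ValueError(f"cut_when must be methylated/unmethylated, got {self.cut_when!r}")
        if self.position <= 0:
            raise ValueError("cut position must be positive")


class MethylationPattern(str, Enum):
    """Joint methylation state of the two CpG sites, 5'-most site first."""

    MCMC = "mCmC"
    UCMC = "uCmC"
    MCUC = "mCuC"
    UCUC = "uCuC"

    @property
    def states(self) -> tuple[str, ...]:
        """Per-site states, 'm' or 'u', ordered 5' to 3'."""
        return (self.value[0], self.value[2])

    @classmethod
    def from_states(cls, states: Iterable[str]) -> "MethylationPattern":
        return cls("C".join(states) + "C")


PATTERNS: tuple[MethylationPattern, ...] = (
    MethylationPattern.MCMC,
    MethylationPattern.UCMC,
    MethylationPattern.MCUC,
    MethylationPattern.UCUC,
)


@dataclass(frozen=True)
class Fragment:
    """A digestion product; end labels record which enzyme cut each end."""

    length: int
    left_end: str = BLUNT
    right_end: str = BLUNT

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("fragment length must be >= 1")


@dataclass(frozen=True)
class FragmentSet:
    pattern: MethylationPattern
    fragments: tuple[Fragment, ...]

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(f.length for f in self.fragments)


@dataclass(frozen=True)
class AmpliconModel:
    """Geometric model of one COBRA amplicon: length plus ordered cut sites.

    Orientation convention: the first letter of a methylation pattern refers
    to the 5'-most site.  For the built-in Alu model the double-digest
    fragments read 43, 32, 58 from the 5' end -- the only ordering
    consistent with the mCuC pattern leaving a 90 bp band and uCmC a 75 bp
    band.
    """

    name: str
    length: int
    sites: tuple[CpGCutSite, ...]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("amplicon length must be positive")
        positions = [s.position for s in self.sites]
        if any(not 0 < p < self.length for p in positions):
            raise ValueError("cut positions must lie strictly inside the amplicon")
        if positions != sorted(set(positions)):
            raise ValueError("site positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AmpliconModel":
        sites = tuple(
            CpGCutSite(
                position=int(s["position"]),
                enzyme=ENZYMES[s["enzyme"]],
                cut_when=s["cut_when"],
            )
            for s in d["sites"]
        )
        return cls(name=d["name"], length=int(d["length"]), sites=sites)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "length": self.length,
            "sites": [
                {
                    "position": s.position,
                    "enzyme": s.enzyme.name,
                    "cut_when": s.cut_when,
                }
                for s in self.sites
            ],
        }


# 92 bp LINE-1 amplicon: TasI site (cuts when unmethylated) at coordinate 32,
# TaqI site (cuts when methylated) at 50.  These coordinates are the unique
# assignment reproducing all four representative bands, including the 18 bp
# middle fragment of the double digest.
LINE1_92 = AmpliconModel(
    "LINE1_92",
    92,
    (
        CpGCutSite(32, TASI, UNMETHYLATED),
        CpGCutSite(50, TAQI, METHYLATED),
    ),
)

# 133 bp Alu amplicon: two TaqI sites (cut when methylated) at 43 and 75,
# fixed by the single-cut fragment pairs {43, 90} and {75, 58}.
ALU_133 = AmpliconModel(
    "ALU_133",
    133,
    (
        CpGCutSite(43, TAQI, METHYLATED),
        CpGCutSite(75, TAQI, METHYLATED),
    ),
)

BUILTIN_MODELS: Mapping[str, AmpliconModel] = {
    "LINE1_92": LINE1_92,
    "ALU_133": ALU_133,
}


def bisulfite_convert(sequence: str, methylated_cpg_positions: Iterable[int] = ()) -> str:
    """Apply in-silico bisulfite conversion to the top strand.

    Every cytosine outside a CpG context converts to thymine; a CpG cytosine
    converts unless its index is listed in ``methylated_cpg_positions``
    (5-methylcytosine is protected).

    Parameters
    ----------
    sequence
        Top-strand DNA over A/C/G/T.
    methylated_cpg_positions
        0-based indices of methylated CpG cytosines.
    """
    if not _DNA_RE.match(sequence):
        raise ValueError("sequence must contain only A/C/G/T")
    methylated = set(methylated_cpg_positions)
    for i in methylated:
        if not (0 <= i < len(sequence) - 1 and sequence[i] == "C" and sequence[i + 1] == "G"):
            raise ValueError(f"position {i} is not a CpG cytosine")
    out = []
    for i, base in enumerate(sequence):
        if base != "C":
            out.append(base)
        elif i in methylated:
            out.append("C")
        elif i + 1 < len(sequence) and sequence[i + 1] == "G":
            out.append("T")  # unmethylated CpG converts too
        else:
            out.append("T")
    return "".join(out)


def scan_sites(duplex_top: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut coordinates for every motif occurrence, ascending."""
    if not _DNA_RE.match(duplex_top):
        raise ValueError("sequence must contain only A/C/G/T")
    cuts = []
    start = 0
    while True:
        i = duplex_top.find(enzyme.recognition, start)
        if i < 0:
            break
        cuts.append(i + enzyme.cut_offset)
        start = i + 1
    return cuts


def _site_is_cut(site: CpGCutSite, state: str) -> bool:
    return (state == "m") == (site.cut_when == METHYLATED)


def predict_fragments(model: AmpliconModel, pattern: MethylationPattern) -> FragmentSet:
    """Fragment ladder produced by digesting one methylation pattern.

    A site is cut iff its ``cut_when`` condition matches the pattern state at
    that site; fragments are the intervals between consecutive cuts and the
    amplicon ends, labeled with the cutting enzyme (or ``blunt`` for PCR
    ends).  Fragment lengths always sum to the amplicon length.
    """
    states = pattern.states
    if len(states) != model.n_sites:
        raise ValueError(
            f"pattern arity {len(states)} does not match model with {model.n_sites} sites"
        )
    cuts = [
        (site.position, site.enzyme.name)
        for site, state in zip(model.sites, states)
        if _site_is_cut(site, state)
    ]
    boundaries = [(0, BLUNT)] + cuts + [(model.length, BLUNT)]
    fragments = tuple(
        Fragment(right - left, left_end=left_lab, right_end=right_lab)
        for (left, left_lab), (right, right_lab) in zip(boundaries, boundaries[1:])
    )
    return FragmentSet(pattern=pattern, fragments=fragments)


def band_catalog(model: AmpliconModel) -> dict[int, set[MethylationPattern]]:
    """Map each band length to the set of patterns producing it.

    Lengths mapped to a single pattern are that pattern's representative
    band; shared lengths are redundant bands used for QC bookkeeping.
    Patterns are enumerated over all 2**n_sites joint states.
    """
    catalog: dict[int, set[MethylationPattern]] = {}
    for states in _all_states(model.n_sites):
        pattern = MethylationPattern.from_states(states) if model.n_sites == 2 else None
        fs = (
            predict_fragments(model, pattern)
            if pattern is not None
            else _predict_raw(model, states)
        )
        key = pattern if pattern is not None else states
        for length in (fs.lengths if pattern is not None else fs):
            catalog.setdefault(length, set()).add(key)
    return catalog


def _all_states(n: int):
    if n == 0:
        yield ()
        return
    for rest in _all_states(n - 1):
        for s in ("m", "u"):
            yield (s,) + rest


def _predict_raw(model: AmpliconModel, states: tuple[str, ...]) -> tuple[int, ...]:
    # generic path for toy models with != 2 sites
    cuts = [
        s.position for s, st in zip(model.sites, states) if _site_is_cut(s, st)
    ]
    bounds = [0] + cuts + [model.length]
    return tuple(b - a for a, b in zip(bounds, bounds[1:]))


def representative_bands(model: AmpliconModel) -> dict[MethylationPattern, int]:
    """The band length unique to each pattern (its representative band)."""
    reps: dict[MethylationPattern, int] = {}
    for length, patterns in band_catalog(model).items():
        if len(patterns) == 1:
            (p,) = patterns
            if isinstance(p, MethylationPattern):
                reps[p] = length
    return reps
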