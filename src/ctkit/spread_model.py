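"""Structural representation of painted metaphase spreads.

A spread is a list of chromosome objects; each chromosome is an ordered list
of segments carrying the paint color (one of the painted chromosome classes,
or ``unlabeled`` for pericentric heterochromatin the paints do not tile), a
physical length in Mb, a fluorescence intensity, and two quality attributes
used by junction calling: whether the segment colocalizes with the DNA stain
and whether it appears on both sister chromatids.  The structural form is the
contract consumed by the karyotype classifier, so rearrangement logic is
testable without any spot detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["Segment", "Chromosome", "MetaphaseSpread", "UNLABELED",
           "spreads_to_frame", "frame_to_spreads", "write_spreads_csv",
           "read_spreads_csv"]

UNLABELED = "unlabeled"


@dataclass(frozen=True)
class Segment:
    color: str  # painted chromosome class ("X", "2", "3") or UNLABELED
    length: float  # Mb
    intensity: float = 2.0  # a.u.
    dna_covered: bool = True
    on_both_chromatids: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment length must be > 0 Mb, got {self.length}")


@dataclass
class Chromosome:
    """One mitotic chromosome as an ordered run of segments.

    ``centromere_pos`` is the physical position (Mb from the start of the
    segment order) of the centromere / arm boundary; ``n_centromeres`` flags
    dicentric (2) or acentric (0) products.
    """

    segments: list[Segment]
    centromere_pos: float
    n_centromeres: int = 1
    chrom_id: str = ""

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.segments)

    def painted_length(self, color: str) -> float:
        return sum(s.length for s in self.segments if s.color == color)

    def colors(self) -> set[str]:
        return {s.color for s in self.segments if s.color != UNLABELED}

    def segment_starts(self) -> list[float]:
        starts, pos = [], 0.0
        for s in self.segments:
            starts.append(pos)
            pos += s.length
        return starts


@dataclass
class MetaphaseSpread:
    """A spread plus the reference painted totals of the normal karyotype.

    ``reference_painted_mb`` maps each paint color to the total painted Mb in
    a normal spread of the same cell; reciprocity of an exchange is judged by
    conservation against this reference.  ``truth`` optionally records the
    generator's plan (type, reciprocal flag, pairs) for validation.
    """

    chromosomes: list[Chromosome]
    spread_id: str = ""
    reference_painted_mb: dict[str, float] = field(default_factory=dict)
    truth: dict | None = None

    def painted_length(self, color: str) -> float:
        return sum(c.painted_length(color) for c in self.chromosomes)

    def colors(self) -> set[str]:
        out: set[str] = set()
        for c in self.chromosomes:
            out |= c.colors()
        return out


def spreads_to_frame(spreads: Iterable[MetaphaseSpread]) -> pd.DataFrame:
    """Flatten spreads to one row per chromosome segment."""
    rows = []
    for sp in spreads:
        for c in sp.chromosomes:
            for order, s in enumerate(c.segments):
                rows.append(
                    dict(
                        spread_id=sp.spread_id,
                        chrom_id=c.chrom_id,
                        order=order,
                        color=s.color,
                        length_Mb=s.length,
                        intensity=s.intensity,
                        dna=s.dna_covered,
                        both_chromatids=s.on_both_chromatids,
                        centromere_pos_Mb=c.centromere_pos,
                        n_centromeres=c.n_centromeres,
                    )
                )
    return pd.DataFrame(rows)


def frame_to_spreads(
    df: pd.DataFrame, reference_painted_mb: dict[str, float] | None = None
) -> list[MetaphaseSpread]:
    spreads = []
    for spread_id, sdf in df.groupby("spread_id", sort=True):
        chromosomes = []
        for chrom_id, cdf in sdf.groupby("chrom_id", sort=True):
            cdf = cdf.sort_values("order")
            segs = [
                Segment(
                    color=str(r.color),
                    length=float(r.length_Mb),
                    intensity=float(r.intensity),
                    dna_covered=bool(r.dna),
                    on_both_chromatids=bool(r.both_chromatids),
                )
                for r in cdf.itertuples()
            ]
            chromosomes.append(
                Chromosome(
                    segments=segs,
                    centromere_pos=float(cdf.centromere_pos_Mb.iloc[0]),
                    n_centromeres=int(cdf.n_centromeres.iloc[0]),
                    chrom_id=str(chrom_id),
                )
            )
        spreads.append(
            MetaphaseSpread(
                chromosomes=chromosomes,
                spread_id=str(spread_id),
                reference_painted_mb=dict(reference_painted_mb or {}),
            )
        )
    return spreads


def write_spreads_csv(spreads: Iterable[MetaphaseSpread], path: str | Path) -> None:
    spreads_to_frame(spreads).to_csv(path, index=False)


def read_spreads_csv(
    path: str | Path, reference_painted_mb: dict[str, float] | None = None
) -> list[MetaphaseSpread]:
    return frame_to_spreads(pd.read_csv(path), reference_painted_mb)
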