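"""Hi-C chromosome-pair averages and between-condition change.

Works on KR-normalized contact matrices at fixed resolution (5 kb by
default), one matrix per chromosome pair — *cis* when the two chromosomes are
the same, *trans* otherwise.  The change metric per pair is the relative
difference of the per-pair mean signal between a perturbed condition (KD) and
control (WT):

    relative_change = (KD average − WT average) / WT average

where each average runs over all bins of the stored matrix, excluding bins
flagged NA (unbalanceable rows/columns of the KR normalization).  Matrices
travel as tab-separated ``bin_i  bin_j  value`` triplets with ``NA`` literals
and ``#`` header lines recording chromosomes, lengths and resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrixPair",
    "HiCDelta",
    "pair_average",
    "relative_change",
    "genome_delta_table",
    "write_triplets",
    "read_triplets",
    "n_bins",
]


def n_bins(chrom_length: int, resolution: int) -> int:
    """Number of half-open fixed-width bins covering a chromosome."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return -(-int(chrom_length) // int(resolution))  # ceil division


@dataclass
class ContactMatrixPair:
    """One chromosome-pair contact matrix with an NA mask.

    ``values`` holds NaN at NA bins; ``pair`` is (chrom_a, chrom_b) with
    cis matrices having chrom_a == chrom_b.  Bins are 0-based, half-open,
    of width ``resolution`` bp.
    """

    pair: tuple[str, str]
    values: np.ndarray
    resolution: int = 5000
    lengths: tuple[int, int] | None = None  # bp, optional consistency check

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D matrix")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.lengths is not None:
            expect = (n_bins(self.lengths[0], self.resolution),
                      n_bins(self.lengths[1], self.resolution))
            if self.values.shape != expect:
                raise ValueError(
                    f"matrix shape {self.values.shape} inconsistent with "
                    f"lengths/resolution (expected {expect})"
                )

    @property
    def is_cis(self) -> bool:
        return self.pair[0] == self.pair[1]

    @property
    def na_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class HiCDelta:
    pair: tuple[str, str]
    wt_average: float
    kd_average: float

    @property
    def relative_change(self) -> float:
        return (self.kd_average - self.wt_average) / self.wt_average

    @property
    def kind(self) -> str:
        return "cis" if self.pair[0] == self.pair[1] else "trans"


def pair_average(matrix: ContactMatrixPair, cis_region: str = "full") -> float:
    """Mean signal over non-NA bins of one pair matrix.

    ``cis_region`` selects which bins of a cis matrix enter the average:
    ``"full"`` (default) uses the whole stored square including the diagonal;
    ``"upper"`` restricts to the upper triangle (i ≤ j).  Trans matrices
    always average over the full rectangle.
    """
    vals = matrix.values
    if matrix.is_cis and cis_region == "upper":
        vals = vals[np.triu_indices_from(vals)]
    elif cis_region not in ("full", "upper"):
        raise ValueError(f"cis_region must be 'full' or 'upper', got {cis_region!r}")
    finite = ~np.isnan(vals)
    if not finite.any():
        raise ValueError(f"all bins NA for pair {matrix.pair}; average undefined")
    return float(vals[finite].mean())


def relative_change(
    wt: ContactMatrixPair, kd: ContactMatrixPair, cis_region: str = "full"
) -> HiCDelta:
    """Relative change of the pair average between conditions (KD vs WT)."""
    if wt.pair != kd.pair:
        raise ValueError(f"condition matrices disagree on pair: {wt.pair} vs {kd.pair}")
    if wt.values.shape != kd.values.shape or wt.resolution != kd.resolution:
        raise ValueError(f"condition matrices for {wt.pair} disagree on shape/resolution")
    wt_avg = pair_average(wt, cis_region)
    kd_avg = pair_average(kd, cis_region)
    if wt_avg <= 0:
        raise ValueError(f"WT average for {wt.pair} is {wt_avg}; relative change undefined")
    return HiCDelta(pair=wt.pair, wt_average=wt_avg, kd_average=kd_avg)


def genome_delta_table(
    wt_set: Iterable[ContactMatrixPair],
    kd_set: Iterable[ContactMatrixPair],
    cis_region: str = "full",
) -> pd.DataFrame:
    """One relative-change row per chromosome pair across the genome.

    Columns: chrom_a, chrom_b, kind (cis|trans), wt_avg, kd_avg,
    relative_change.  Raises if the two condition sets cover different pairs.
    """
    wt_map = {m.pair: m for m in wt_set}
    kd_map = {m.pair: m for m in kd_set}
    missing = set(wt_map) ^ set(kd_map)
    if missing:
        raise ValueError(f"pairs present in only one condition: {sorted(missing)}")
    rows = []
    for pair in sorted(wt_map):
        d = relative_change(wt_map[pair], kd_map[pair], cis_region)
        rows.append(
            dict(
                chrom_a=pair[0],
                chrom_b=pair[1],
                kind=d.kind,
                wt_avg=d.wt_average,
                kd_avg=d.kd_average,
                relative_change=d.relative_change,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# triplet text I/O


def write_triplets(matrix: ContactMatrixPair, path: str | Path) -> None:
    """Write ``bin_i<TAB>bin_j<TAB>value`` triplets with ``#`` headers."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# chrom_a={matrix.pair[0]}\tchrom_b={matrix.pair[1]}\n")
        if matrix.lengths is not None:
            fh.write(f"# length_a={matrix.lengths[0]}\tlength_b={matrix.lengths[1]}\n")
        fh.write(f"# resolution={matrix.resolution}\n")
        vals = matrix.values
        for i in range(vals.shape[0]):
            for j in range(vals.shape[1]):
                v = vals[i, j]
                out = "NA" if math.isnan(v) else repr(float(v))
                fh.write(f"{i}\t{j}\t{out}\n")


def read_triplets(path: str | Path) -> ContactMatrixPair:
    path = Path(path)
    header: dict[str, str] = {}
    entries: list[tuple[int, int, float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split("\t"):
                    token = token.strip()
                    if "=" in token:
                        k, v = token.split("=", 1)
                        header[k.strip()] = v.strip()
                continue
            i_s, j_s, v_s = line.split("\t")
            v = math.nan if v_s == "NA" else float(v_s)
            entries.append((int(i_s), int(j_s), v))
    if "chrom_a" not in header or "chrom_b" not in header:
        raise ValueError(f"{path}: missing chromosome names in header")
    resolution = int(header.get("resolution", 5000))
    lengths = None
    if "length_a" in header and "length_b" in header:
        lengths = (int(header["length_a"]), int(header["length_b"]))
        shape = (n_bins(lengths[0], resolution), n_bins(lengths[1], resolution))
    else:
        shape = (max(e[0] for e in entries) + 1, max(e[1] for e in entries) + 1)
    values = np.full(shape, math.nan)
    for i, j, v in entries:
        values[i, j] = v
    return ContactMatrixPair(
        pair=(header["chrom_a"], header["chrom_b"]),
        values=values,
        resolution=resolution,
        lengths=lengths,
    )
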