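"""Junction detection and rearrangement classification on metaphase spreads.

A candidate junction is a boundary between two differently-colored painted
runs on one chromosome (runs may be separated by unlabeled pericentric
material; an unlabeled block between two same-color arms is a normal
centromeric gap, not a junction).  A candidate is accepted only if both
flanking painted segments pass three criteria: intensity above a multiple of
background, colocalization with the DNA stain, and presence on both sister
chromatids — the same filters a cytologist applies to reject hybridization
artifacts.

Accepted junctions are grouped into exchange events per chromosome pair and
the spread is classified:

* ``normal`` — no junctions;
* ``discrete`` — a single two-chromosome event whose junction lies strictly
  inside an arm (farther than δ from the arm boundary);
* ``compound`` — a single event whose junction sits at an arm boundary
  (within δ, or spanning the pericentric block): a whole-arm fusion;
* ``complex`` — more than two chromosomes involved, or ≥2 independent events.

An event is reciprocal when both derivative chromosomes are present and the
total painted length of each partner color is conserved (within a relative
tolerance ε) against the normal karyotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .spread_model import UNLABELED, Chromosome, MetaphaseSpread

__all__ = [
    "KaryotypeParams",
    "JunctionCall",
    "RearrangementCall",
    "detect_junctions",
    "classify_spread",
    "is_reciprocal",
    "summarize_karyotypes",
]


@dataclass(frozen=True)
class KaryotypeParams:
    """Tolerances of junction calling and classification."""

    k_background: float = 2.0  # intensity must exceed k × background
    background: float = 1.0  # a.u.
    delta_arm_fraction: float = 0.05  # δ: arm-boundary tolerance, fraction of arm
    epsilon_conservation: float = 0.05  # ε: per-color painted-length tolerance

    def validate(self) -> None:
        if self.background <= 0:
            raise ValueError("background must be > 0")
        if self.k_background <= 0:
            raise ValueError("k_background must be > 0")
        if not (0 <= self.delta_arm_fraction < 0.5):
            raise ValueError("delta_arm_fraction must lie in [0, 0.5)")
        if not (0 <= self.epsilon_conservation < 1):
            raise ValueError("epsilon_conservation must lie in [0, 1)")


@dataclass(frozen=True)
class JunctionCall:
    chrom_id: str
    colors: tuple[str, str]  # sorted pair of flanking paint colors
    position: float  # Mb from the chromosome's left end (gap midpoint)
    boundary_distance: float  # Mb to the nearest arm boundary (0 if gap-spanning)
    at_arm_boundary: bool
    accepted: bool
    reject_reasons: tuple[str, ...] = ()


@dataclass
class RearrangementCall:
    spread_id: str
    type: str  # normal | discrete | compound | complex
    chromosomes_involved: frozenset[str]
    reciprocal: bool
    n_junctions: int
    n_events: int
    pairs: frozenset[tuple[str, str]]
    flags: tuple[str, ...] = ()


def _painted_runs(chrom: Chromosome):
    """Contiguous same-color painted runs: (color, start, end, first_seg, last_seg)."""
    runs = []
    pos = 0.0
    for seg in chrom.segments:
        start, end = pos, pos + seg.length
        pos = end
        if seg.color == UNLABELED:
            continue
        if runs and runs[-1][0] == seg.color and abs(runs[-1][2] - start) < 1e-9:
            color, rstart, _rend, first, _last = runs[-1]
            runs[-1] = (color, rstart, end, first, seg)
        else:
            runs.append((seg.color, start, end, seg, seg))
    return runs


def detect_junctions(
    chrom: Chromosome, params: KaryotypeParams = KaryotypeParams()
) -> list[JunctionCall]:
    """All color junctions on one chromosome, accepted or annotated.

    The junction position is the midpoint of the gap between the two painted
    runs (their shared boundary when adjacent).  ``boundary_distance`` is the
    distance to the nearest painted-run edge abutting unlabeled material or a
    chromosome end — zero when the color change spans an unlabeled block,
    which is the signature of a whole-arm fusion.
    """
    params.validate()
    runs = _painted_runs(chrom)
    calls: list[JunctionCall] = []
    floor = params.k_background * params.background
    for left, right in zip(runs, runs[1:]):
        lcolor, _ls, lend, _lf, lseg = left
        rcolor, rstart, rend, rseg, _rl = right
        if lcolor == rcolor:
            continue  # same-color runs flanking a pericentric gap: no junction
        gap = rstart - lend
        position = 0.5 * (lend + rstart)
        if gap > 1e-9:
            boundary_distance = 0.0  # change spans unlabeled material
        else:
            # distance from the color change to the nearest run edge that
            # touches unlabeled material or a chromosome end
            boundary_distance = min(position - left[1], rend - position)
        arm_length = (left[2] - left[1]) + (right[2] - right[1])
        at_boundary = boundary_distance <= params.delta_arm_fraction * arm_length
        reasons = []
        for side, seg in (("left", lseg), ("right", rseg)):
            if seg.intensity <= floor:
                reasons.append(f"{side}-below-background")
            if not seg.dna_covered:
                reasons.append(f"{side}-no-dna")
            if not seg.on_both_chromatids:
                reasons.append(f"{side}-single-chromatid")
        calls.append(
            JunctionCall(
                chrom_id=chrom.chrom_id,
                colors=tuple(sorted((lcolor, rcolor))),
                position=position,
                boundary_distance=boundary_distance,
                at_arm_boundary=at_boundary,
                accepted=not reasons,
                reject_reasons=tuple(reasons),
            )
        )
    return calls


def is_reciprocal(
    spread: MetaphaseSpread,
    pair: tuple[str, str],
    junctions: Sequence[JunctionCall],
    params: KaryotypeParams = KaryotypeParams(),
) -> bool:
    """Both derivatives present and painted lengths of the pair conserved.

    ``junctions`` are the accepted junctions of this pair.  Conservation is
    judged per color against the spread's reference painted totals with
    relative tolerance ε.
    """
    if len(junctions) < 2 or len(junctions) % 2:
        return False
    if len({j.chrom_id for j in junctions}) < 2:
        return False
    ref = spread.reference_painted_mb
    for color in pair:
        expected = ref.get(color)
        if expected is None or expected <= 0:
            return False
        observed = spread.painted_length(color)
        if abs(observed - expected) > params.epsilon_conservation * expected:
            return False
    return True


def classify_spread(
    spread: MetaphaseSpread, params: KaryotypeParams = KaryotypeParams()
) -> RearrangementCall:
    """Classify one spread from its accepted junctions.

    Junctions are grouped by unordered color pair.  An even group whose
    colors are conserved reads as reciprocal events (two junctions each);
    otherwise each junction is an independent one-derivative event.  A
    single event between two chromosomes is discrete or compound by its
    junction position; anything larger is complex.
    """
    params.validate()
    accepted: list[JunctionCall] = []
    for chrom in spread.chromosomes:
        accepted += [j for j in detect_junctions(chrom, params) if j.accepted]
    if not accepted:
        return RearrangementCall(
            spread_id=spread.spread_id,
            type="normal",
            chromosomes_involved=frozenset(),
            reciprocal=False,
            n_junctions=0,
            n_events=0,
            pairs=frozenset(),
        )
    flags: list[str] = []
    by_pair: dict[tuple[str, str], list[JunctionCall]] = {}
    for j in accepted:
        by_pair.setdefault(j.colors, []).append(j)

    n_events = 0
    all_reciprocal = True
    for pair, js in by_pair.items():
        if is_reciprocal(spread, pair, js, params):
            n_events += len(js) // 2
        else:
            n_events += len(js)
            all_reciprocal = False

    colors_involved = frozenset(itertools.chain.from_iterable(by_pair))
    if n_events >= 2 or len(colors_involved) > 2:
        kind = "complex"
    else:
        at_boundary = [j.at_arm_boundary for j in accepted]
        if all(at_boundary):
            kind = "compound"
        elif any(at_boundary):
            kind = "compound"
            flags.append("mixed-boundary-junctions")
        else:
            kind = "discrete"
    return RearrangementCall(
        spread_id=spread.spread_id,
        type=kind,
        chromosomes_involved=colors_involved,
        reciprocal=all_reciprocal,
        n_junctions=len(accepted),
        n_events=n_events,
        pairs=frozenset(by_pair),
        flags=tuple(flags),
    )


def summarize_karyotypes(
    calls: Iterable[RearrangementCall], condition: str = ""
) -> dict:
    """Population summary: overall and per-pair translocation frequencies.

    A spread touching several pairs (complex events) increments each of its
    pairs once.  Returns a dict with n_spreads, n_with_translocation,
    frequency, per_pair (pair -> n, frequency), type_counts and condition.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no rearrangement calls to summarize")
    n = len(calls)
    rearranged = [c for c in calls if c.type != "normal"]
    per_pair_counts: dict[str, int] = {}
    for c in rearranged:
        for pair in c.pairs:
            key = "-".join(pair)
            per_pair_counts[key] = per_pair_counts.get(key, 0) + 1
    type_counts: dict[str, int] = {}
    for c in calls:
        type_counts[c.type] = type_counts.get(c.type, 0) + 1
    return dict(
        condition=condition,
        n_spreads=n,
        n_with_translocation=len(rearranged),
        frequency=len(rearranged) / n,
        per_pair={k: dict(n=v, frequency=v / n) for k, v in sorted(per_pair_counts.items())},
        type_counts=type_counts,
        n_reciprocal=sum(1 for c in rearranged if c.reciprocal),
    )


def summary_frame(summaries: Iterable[dict]) -> pd.DataFrame:
    """Tidy one-row-per-condition table from karyotype summaries."""
    rows = []
    for s in summaries:
        row = dict(
            condition=s["condition"],
            n_spreads=s["n_spreads"],
            n_with_translocation=s["n_with_translocation"],
            frequency=s["frequency"],
        )
        for pair, d in s["per_pair"].items():
            row[f"freq_{pair}"] = d["frequency"]
        rows.append(row)
    return pd.DataFrame(rows)
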