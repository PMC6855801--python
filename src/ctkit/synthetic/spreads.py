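"""Synthetic painted metaphase spreads with planned rearrangements.

The generator builds a normal karyotype from per-chromosome class specs
(paint color, arm lengths in Mb, an unlabeled pericentric block the paints do
not tile, and ploidy) and then applies a plan of exchange events.  Each event
breaks one chromosome of each of two paint classes and rejoins the pieces so
that every derivative carries exactly one centromere:

* ``discrete`` — both breaks strictly inside an arm; the derivative carries a
  mid-arm color junction.
* ``compound`` — both breaks at the centromere, i.e. a whole-arm fusion; the
  color junction spans the pericentric block, sitting at the arm boundary.

A ``reciprocal`` event keeps both derivatives, conserving the painted length
of each color exactly; a non-reciprocal event keeps one derivative plus the
truncated partner, losing the distal fragment of the broken chromosome (as
when the reciprocal product is not recovered).  The generator records the
plan as truth so classifier output can be scored against it.

Breakpoint fractions for non-reciprocal events are sampled away from the
telomere (≥25% of the arm) so the lost fragment exceeds the 5%-per-color
conservation tolerance used to call reciprocity; closer to the tip the loss
is cytologically invisible at that tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from ..spread_model import UNLABELED, Chromosome, MetaphaseSpread, Segment

__all__ = [
    "ChromosomeClassSpec",
    "RearrangementEvent",
    "SpreadSpec",
    "DM_MALE_KARYOTYPE",
    "generate_metaphase_spread",
    "random_plan",
    "generate_spread_cohort",
]


@dataclass(frozen=True)
class ChromosomeClassSpec:
    """One painted chromosome class of the karyotype."""

    color: str
    arm_lengths: tuple[float, float]  # (left, right) Mb; right may be 0 (telocentric)
    pericentric: float = 4.0  # unlabeled block spanning the centromere, Mb
    ploidy: int = 2

    def validate(self) -> None:
        if self.arm_lengths[0] <= 0 or self.arm_lengths[1] < 0:
            raise ValueError(f"bad arm lengths for {self.color}: {self.arm_lengths}")
        if self.pericentric <= 0 or self.ploidy < 1:
            raise ValueError(f"bad pericentric/ploidy for {self.color}")


#: Male diploid karyotype for the three painted chromosomes, dm3 arm lengths (Mb).
DM_MALE_KARYOTYPE: tuple[ChromosomeClassSpec, ...] = (
    ChromosomeClassSpec("X", (22.42, 0.0), pericentric=3.0, ploidy=1),
    ChromosomeClassSpec("2", (23.01, 21.15), pericentric=4.0, ploidy=2),
    ChromosomeClassSpec("3", (24.54, 27.91), pericentric=4.0, ploidy=2),
)


@dataclass(frozen=True)
class RearrangementEvent:
    """One two-chromosome exchange.

    ``arms`` names the broken arm of each partner ("L"/"R"); ``fractions``
    places each break as a fraction of that arm measured from the telomere
    (ignored for ``compound``, whose breaks sit at the centromere).
    """

    kind: str  # "discrete" | "compound"
    pair: tuple[str, str]
    arms: tuple[str, str] = ("L", "L")
    fractions: tuple[float, float] = (0.5, 0.5)
    reciprocal: bool = True

    def validate(self) -> None:
        if self.kind not in ("discrete", "compound"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.pair[0] == self.pair[1]:
            raise ValueError("exchange partners must be distinct paint classes")
        for a in self.arms:
            if a not in ("L", "R"):
                raise ValueError(f"arm must be 'L' or 'R', got {a!r}")
        if self.kind == "discrete":
            for f in self.fractions:
                if not (0.0 < f < 1.0):
                    raise ValueError(
                        f"discrete breakpoint fraction must lie strictly inside the arm, got {f}"
                    )


@dataclass
class SpreadSpec:
    classes: tuple[ChromosomeClassSpec, ...] = DM_MALE_KARYOTYPE
    plan: tuple[RearrangementEvent, ...] = ()
    intensity_background: float = 1.0
    paint_intensity: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        colors = [c.color for c in self.classes]
        if len(set(colors)) != len(colors):
            raise ValueError("duplicate paint color in karyotype")
        for c in self.classes:
            c.validate()
        for ev in self.plan:
            ev.validate()
            for color, arm, frac in zip(ev.pair, ev.arms, ev.fractions):
                cls = self.class_for(color)
                arm_len = cls.arm_lengths[0 if arm == "L" else 1]
                if arm_len <= 0:
                    raise ValueError(f"chromosome {color} has no {arm} arm to break")

    def class_for(self, color: str) -> ChromosomeClassSpec:
        for c in self.classes:
            if c.color == color:
                return c
        raise KeyError(f"no chromosome class painted {color!r}")

    def reference_painted_mb(self) -> dict[str, float]:
        return {
            c.color: c.ploidy * (c.arm_lengths[0] + c.arm_lengths[1])
            for c in self.classes
        }


# ---------------------------------------------------------------------------
# chromosome pieces


@dataclass
class _Piece:
    segments: list[Segment]
    cen_offset: float | None  # Mb from piece left end; None if acentric
    break_end: str  # "L" or "R": which end is the broken one

    @property
    def length(self) -> float:
        return sum(s.length for s in self.segments)

    def oriented(self, break_on: str) -> "_Piece":
        if self.break_end == break_on:
            return self
        segs = list(reversed(self.segments))
        cen = None if self.cen_offset is None else self.length - self.cen_offset
        return _Piece(segs, cen, break_on)


def _build_normal(cls: ChromosomeClassSpec, copy: int, intensity: float) -> Chromosome:
    segs = [Segment(cls.color, cls.arm_lengths[0], intensity=intensity)]
    segs.append(Segment(UNLABELED, cls.pericentric, intensity=1.0))
    cen = cls.arm_lengths[0] + cls.pericentric / 2.0
    if cls.arm_lengths[1] > 0:
        segs.append(Segment(cls.color, cls.arm_lengths[1], intensity=intensity))
    return Chromosome(
        segments=segs, centromere_pos=cen, chrom_id=f"{cls.color}.{copy}"
    )


def _split(chrom: Chromosome, pos: float) -> tuple[_Piece, _Piece]:
    """Split at ``pos`` Mb from the left end; centromere goes strictly left of pos."""
    if not (0.0 < pos < chrom.total_length):
        raise ValueError(
            f"breakpoint {pos} Mb outside chromosome {chrom.chrom_id} "
            f"(length {chrom.total_length} Mb)"
        )
    left: list[Segment] = []
    right: list[Segment] = []
    cursor = 0.0
    for s in chrom.segments:
        s_end = cursor + s.length
        if s_end <= pos + 1e-12:
            left.append(s)
        elif cursor >= pos - 1e-12:
            right.append(s)
        else:
            left.append(replace(s, length=pos - cursor))
            right.append(replace(s, length=s_end - pos))
        cursor = s_end
    cen_left = chrom.centromere_pos < pos
    return (
        _Piece(left, chrom.centromere_pos if cen_left else None, "R"),
        _Piece(right, None if cen_left else chrom.centromere_pos - pos, "L"),
    )


def _join(centric: _Piece, acentric: _Piece, chrom_id: str) -> Chromosome:
    a = centric.oriented("R")
    b = acentric.oriented("L")
    segs = _merge_runs(a.segments + b.segments)
    n_cen = (a.cen_offset is not None) + (b.cen_offset is not None)
    cen = a.cen_offset if a.cen_offset is not None else (
        a.length + b.cen_offset if b.cen_offset is not None else a.length
    )
    return Chromosome(segments=segs, centromere_pos=float(cen), n_centromeres=int(n_cen), chrom_id=chrom_id)


def _piece_to_chromosome(p: _Piece, chrom_id: str) -> Chromosome:
    q = p.oriented("R")
    return Chromosome(
        segments=_merge_runs(q.segments),
        centromere_pos=float(q.cen_offset if q.cen_offset is not None else q.length),
        n_centromeres=int(q.cen_offset is not None),
        chrom_id=chrom_id,
    )


def _merge_runs(segments: list[Segment]) -> list[Segment]:
    """Coalesce adjacent segments with identical color and attributes."""
    out: list[Segment] = []
    for s in segments:
        if out and (
            out[-1].color == s.color
            and out[-1].intensity == s.intensity
            and out[-1].dna_covered == s.dna_covered
            and out[-1].on_both_chromatids == s.on_both_chromatids
        ):
            out[-1] = replace(out[-1], length=out[-1].length + s.length)
        else:
            out.append(s)
    return out


def _break_position(chrom: Chromosome, cls: ChromosomeClassSpec, arm: str, frac: float, kind: str) -> float:
    if kind == "compound":
        return chrom.centromere_pos
    arm_len = cls.arm_lengths[0 if arm == "L" else 1]
    if arm == "L":
        return frac * arm_len  # measured from the left telomere
    return chrom.total_length - frac * arm_len  # from the right telomere


def _centric_acentric(chrom: Chromosome, pos: float) -> tuple[_Piece, _Piece]:
    left, right = _split(chrom, pos)
    if left.cen_offset is not None:
        return left, right
    return right, left


def generate_metaphase_spread(spec: SpreadSpec) -> MetaphaseSpread:
    """Realise the karyotype and apply the rearrangement plan.

    Each event consumes one still-normal copy of each partner class; an event
    that cannot find free copies raises.  Returns a spread whose ``truth``
    records the plan-level classification (see :func:`plan_truth`).
    """
    spec.validate()
    chromosomes: list[Chromosome] = []
    for cls in spec.classes:
        for copy in range(cls.ploidy):
            chromosomes.append(_build_normal(cls, copy, spec.paint_intensity))

    derivative_counter = itertools.count(1)
    for ev in spec.plan:
        picked: list[Chromosome] = []
        for color in ev.pair:
            free = [
                c
                for c in chromosomes
                if c.colors() == {color} and c not in picked
            ]
            if not free:
                raise ValueError(
                    f"no intact chromosome {color} left for event {ev}"
                )
            picked.append(free[0])
        a, b = picked
        cls_a, cls_b = (spec.class_for(c) for c in ev.pair)
        pos_a = _break_position(a, cls_a, ev.arms[0], ev.fractions[0], ev.kind)
        pos_b = _break_position(b, cls_b, ev.arms[1], ev.fractions[1], ev.kind)
        a_cen, a_ace = _centric_acentric(a, pos_a)
        b_cen, b_ace = _centric_acentric(b, pos_b)
        k = next(derivative_counter)
        new: list[Chromosome] = [_join(a_cen, b_ace, f"der{k}a")]
        if ev.reciprocal:
            new.append(_join(b_cen, a_ace, f"der{k}b"))
        else:
            new.append(_piece_to_chromosome(b_cen, f"trunc{k}"))
        chromosomes = [c for c in chromosomes if c not in picked] + new

    spread = MetaphaseSpread(
        chromosomes=chromosomes,
        spread_id=f"spread-{spec.seed}",
        reference_painted_mb=spec.reference_painted_mb(),
        truth=plan_truth(spec.plan),
    )
    return spread


def plan_truth(plan: tuple[RearrangementEvent, ...]) -> dict:
    """Spread-level classification implied by a plan.

    ``complex`` when the plan holds ≥2 events or >2 paint classes; otherwise
    the single event's kind.  The spread is reciprocal iff it has at least
    one event and every event is reciprocal.
    """
    if not plan:
        return {"type": "normal", "reciprocal": False, "pairs": set(), "n_events": 0}
    colors = set(itertools.chain.from_iterable(ev.pair for ev in plan))
    if len(plan) >= 2 or len(colors) > 2:
        kind = "complex"
    else:
        kind = plan[0].kind
    return {
        "type": kind,
        "reciprocal": all(ev.reciprocal for ev in plan),
        "pairs": {tuple(sorted(ev.pair)) for ev in plan},
        "n_events": len(plan),
    }


# ---------------------------------------------------------------------------
# random plans for cohort simulation


_PAIRS = (("X", "2"), ("X", "3"), ("2", "3"))


def _random_event(
    rng: np.random.Generator,
    spec_classes: tuple[ChromosomeClassSpec, ...],
    pair: tuple[str, str],
    kind: str,
    reciprocal: bool,
) -> RearrangementEvent:
    arms = []
    for color in pair:
        cls = next(c for c in spec_classes if c.color == color)
        choices = ["L"] + (["R"] if cls.arm_lengths[1] > 0 else [])
        arms.append(choices[rng.integers(len(choices))])
    if kind == "compound":
        fractions = (0.0, 0.0)
    elif reciprocal:
        fractions = tuple(rng.uniform(0.15, 0.85, size=2))
    else:
        # first partner loses its distal fragment; keep the loss detectable
        fractions = (rng.uniform(0.25, 0.85), rng.uniform(0.15, 0.85))
    return RearrangementEvent(
        kind=kind, pair=pair, arms=tuple(arms), fractions=tuple(fractions),
        reciprocal=reciprocal,
    )


def random_plan(
    rng: np.random.Generator,
    target_type: str,
    reciprocal: bool = False,
    classes: tuple[ChromosomeClassSpec, ...] = DM_MALE_KARYOTYPE,
) -> tuple[RearrangementEvent, ...]:
    """Sample a plan whose :func:`plan_truth` type equals ``target_type``."""
    if target_type == "normal":
        return ()
    if target_type in ("discrete", "compound"):
        pairs = _feasible_pairs(classes, target_type)
        pair = pairs[rng.integers(len(pairs))]
        return (_random_event(rng, classes, pair, target_type, reciprocal),)
    if target_type == "complex":
        ploidy = {c.color: c.ploidy for c in classes}
        if rng.random() < 0.5:
            # two events between distinct pairs; respect copy numbers (one X)
            while True:
                i, j = rng.choice(len(_PAIRS), size=2, replace=False)
                chosen = [_PAIRS[i], _PAIRS[j]]
                demand = list(itertools.chain.from_iterable(chosen))
                if all(demand.count(c) <= ploidy[c] for c in set(demand)):
                    break
        else:
            # two events on the same autosome pair (needs two copies of each)
            chosen = [("2", "3"), ("2", "3")]
        flags = [reciprocal, reciprocal] if reciprocal else [False, bool(rng.random() < 0.5)]
        if not reciprocal:
            flags[rng.integers(2)] = False  # ensure at least one non-reciprocal
        events = []
        compound_ok = {p for p in _feasible_pairs(classes, "compound")}
        for pair, flag in zip(chosen, flags):
            kind = "discrete"
            if tuple(sorted(pair)) in compound_ok and rng.random() < 0.3:
                kind = "compound"
            events.append(_random_event(rng, classes, pair, kind, flag))
        return tuple(events)
    raise ValueError(f"unknown target type {target_type!r}")


def _feasible_pairs(
    classes: tuple[ChromosomeClassSpec, ...], kind: str
) -> list[tuple[str, str]]:
    """Pairs an event of ``kind`` can use.

    Whole-arm fusions are restricted to metacentric partners: fusing at the
    centromere of a telocentric chromosome leaves a centric fragment with no
    painted material, so the event's junction count is cytologically
    degenerate.
    """
    by_color = {c.color: c for c in classes}
    out = []
    for pair in _PAIRS:
        if any(c not in by_color for c in pair):
            continue
        if kind == "compound" and any(by_color[c].arm_lengths[1] <= 0 for c in pair):
            continue
        out.append(pair)
    return out


def generate_spread_cohort(
    n_spreads: int,
    translocation_frequency: float,
    type_mixture: dict[str, float] | None = None,
    reciprocal_fraction: float = 0.33,
    seed: int = 0,
    classes: tuple[ChromosomeClassSpec, ...] = DM_MALE_KARYOTYPE,
) -> list[MetaphaseSpread]:
    """A population of spreads with translocations at a planned frequency.

    ``type_mixture`` gives the relative share of discrete/compound/complex
    among rearranged spreads (default: the 60.2/32/7.8 split observed after
    20 Gy); the planned number of rearranged spreads is ``round(n × f)``, so
    noiseless recovery of the planned count is exact.
    """
    mixture = type_mixture or {"discrete": 0.602, "compound": 0.32, "complex": 0.078}
    kinds = list(mixture)
    weights = np.array([mixture[k] for k in kinds], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    n_rearranged = int(round(n_spreads * translocation_frequency))
    flags = np.zeros(n_spreads, dtype=bool)
    flags[rng.choice(n_spreads, size=n_rearranged, replace=False)] = True
    spreads = []
    for i in range(n_spreads):
        if flags[i]:
            kind = kinds[rng.choice(len(kinds), p=weights)]
            recip = bool(rng.random() < reciprocal_fraction)
            plan = random_plan(rng, kind, recip, classes)
        else:
            plan = ()
        sp = generate_metaphase_spread(SpreadSpec(classes=classes, plan=plan, seed=i))
        sp.spread_id = f"spread-{seed}-{i}"
        spreads.append(sp)
    return spreads
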