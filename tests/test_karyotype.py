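"""Junction criteria, rearrangement classification and population summaries."""

import numpy as np
import pytest

from ctkit.karyotype import (
    KaryotypeParams,
    classify_spread,
    detect_junctions,
    summarize_karyotypes,
)
from ctkit.spread_model import UNLABELED, Chromosome, MetaphaseSpread, Segment
from ctkit.synthetic import (
    SpreadSpec,
    generate_metaphase_spread,
    generate_spread_cohort,
    random_plan,
)

REF = SpreadSpec().reference_painted_mb()


def _chrom(segs, cen=20.0, chrom_id="c"):
    return Chromosome(segments=segs, centromere_pos=cen, chrom_id=chrom_id)


def test_single_color_chromosome_has_no_junctions():
    c = _chrom([Segment("2", 23.0), Segment(UNLABELED, 4.0), Segment("2", 21.0)], cen=25.0)
    assert detect_junctions(c) == []


def test_three_criterion_rule_accepts_bright_dna_covered_both_chromatids():
    c = _chrom([Segment("2", 20.0, intensity=3.0), Segment("3", 15.0, intensity=3.0)])
    js = detect_junctions(c, KaryotypeParams(background=1.0, k_background=2.0))
    assert len(js) == 1 and js[0].accepted
    assert js[0].colors == ("2", "3")


@pytest.mark.parametrize(
    "kwargs,reason",
    [
        (dict(intensity=1.5), "below-background"),
        (dict(dna_covered=False), "no-dna"),
        (dict(on_both_chromatids=False), "single-chromatid"),
    ],
)
def test_junction_rejected_when_any_criterion_fails(kwargs, reason):
    bad = Segment("3", 15.0, intensity=kwargs.get("intensity", 3.0),
                  dna_covered=kwargs.get("dna_covered", True),
                  on_both_chromatids=kwargs.get("on_both_chromatids", True))
    c = _chrom([Segment("2", 20.0, intensity=3.0), bad])
    js = detect_junctions(c, KaryotypeParams(background=1.0, k_background=2.0))
    assert len(js) == 1 and not js[0].accepted
    assert any(reason in r for r in js[0].reject_reasons)


def test_pericentric_gap_between_same_color_arms_is_not_a_junction():
    c = _chrom([Segment("3", 24.0), Segment(UNLABELED, 4.0), Segment("3", 27.0)], cen=26.0)
    assert detect_junctions(c) == []


def test_raising_k_background_never_increases_junction_count():
    rng = np.random.default_rng(8)
    spreads = [
        generate_metaphase_spread(
            SpreadSpec(plan=random_plan(rng, t, bool(rng.random() < 0.5)), seed=i)
        )
        for i, t in enumerate(["discrete", "compound", "complex"] * 5)
    ]
    for sp in spreads:
        counts = []
        for k in (1.0, 2.0, 2.6):  # paint intensity is 2.5 x background
            params = KaryotypeParams(k_background=k)
            n = sum(
                sum(j.accepted for j in detect_junctions(c, params))
                for c in sp.chromosomes
            )
            counts.append(n)
        assert counts[0] >= counts[1] >= counts[2]


def test_zero_junction_spread_classified_normal():
    sp = generate_metaphase_spread(SpreadSpec())
    call = classify_spread(sp)
    assert call.type == "normal" and call.n_junctions == 0 and not call.reciprocal


def test_midarm_junction_classified_discrete_with_pair():
    rng = np.random.default_rng(3)
    plan = random_plan(rng, "discrete", reciprocal=False)
    sp = generate_metaphase_spread(SpreadSpec(plan=plan, seed=1))
    call = classify_spread(sp)
    assert call.type == "discrete"
    assert call.pairs == frozenset({tuple(sorted(plan[0].pair))})


def test_multi_event_spread_classified_complex():
    rng = np.random.default_rng(4)
    plan = random_plan(rng, "complex", reciprocal=False)
    sp = generate_metaphase_spread(SpreadSpec(plan=plan, seed=1))
    call = classify_spread(sp)
    assert call.type == "complex"
    assert call.n_events >= 2 or len(call.chromosomes_involved) > 2


def test_classification_matches_generator_plan_on_cohort():
    spreads = generate_spread_cohort(n_spreads=300, translocation_frequency=0.4, seed=6)
    for sp in spreads:
        call = classify_spread(sp)
        assert call.type == sp.truth["type"]
        assert call.reciprocal == sp.truth["reciprocal"]
        if call.type != "normal":
            assert call.pairs == frozenset(sp.truth["pairs"])


def test_summary_counts_and_frequencies():
    # three populations of the sizes scored in the source experiment
    sizes = {"0Gy": 592, "5Gy": 368, "20Gy": 442}
    freqs = {"0Gy": 0.017, "5Gy": 0.03, "20Gy": 0.148}
    summaries = []
    for cond, n in sizes.items():
        spreads = generate_spread_cohort(
            n_spreads=n, translocation_frequency=freqs[cond], seed=len(cond)
        )
        calls = [classify_spread(s) for s in spreads]
        summaries.append(summarize_karyotypes(calls, condition=cond))
    assert sum(s["n_spreads"] for s in summaries) == 1402
    for s, (cond, n) in zip(summaries, sizes.items()):
        assert s["n_with_translocation"] == round(n * freqs[cond])


def test_complex_spread_increments_each_pair_once():
    rng = np.random.default_rng(9)
    # force a two-pair complex plan
    while True:
        plan = random_plan(rng, "complex", reciprocal=False)
        pairs = {tuple(sorted(e.pair)) for e in plan}
        if len(pairs) == 2:
            break
    sp = generate_metaphase_spread(SpreadSpec(plan=plan, seed=0))
    summary = summarize_karyotypes([classify_spread(sp)], condition="x")
    assert set(summary["per_pair"]) == {"-".join(p) for p in pairs}
    assert all(d["n"] == 1 for d in summary["per_pair"].values())
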