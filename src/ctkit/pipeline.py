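"""Orchestration of the split-population experimental scheme.

One cell population is (virtually) split three ways: an interphase arm is
imaged and measured for CT contact and intermixing; an irradiated and an
unirradiated arm are karyotyped for translocations.  The run joins the
population contact summaries with translocation frequencies, fits the
contact→translocation regression, contrasts the ±IR arms by Fisher's exact
test, and writes every table plus a manifest (parameter snapshot, output
hashes, wall clock) so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .karyotype import KaryotypeParams, classify_spread, summarize_karyotypes
from .metrics import DEFAULT_CONTACT_THRESHOLD, measure_cell, summarize_population
from .segmentation import NUCLEUS_PARAMS, TERRITORY_PARAMS, SegmentationParams, segment_nucleus, segment_territories
from .stats import fisher_exact, linear_regression
from .synthetic import (
    CohortSpec,
    NucleusSpec,
    generate_cohort,
    generate_spread_cohort,
    simulate_translocation_cohort,
)

__all__ = ["RunConfig", "validate_config", "run_experiment_scheme"]


@dataclass
class RunConfig:
    """Everything one demo run needs, JSON-serialisable."""

    out_dir: str = "results/demo"
    seed: int = 0
    n_interphase_cells: int = 30
    interphase_contact_probability: float = 0.95
    n_spreads_control: int = 200
    n_spreads_ir: int = 200
    translocation_frequency_control: float = 0.017
    translocation_frequency_ir: float = 0.148
    contact_threshold_um3: float = DEFAULT_CONTACT_THRESHOLD
    cohort_q: float = 0.15
    cohort_contact_grid: tuple[float, ...] = tuple(np.round(np.arange(0.90, 1.0, 0.01), 2))
    cohort_n_cells: int = 2000
    nucleus_params: SegmentationParams = field(default_factory=lambda: NUCLEUS_PARAMS)
    territory_params: SegmentationParams = field(default_factory=lambda: TERRITORY_PARAMS)
    karyotype_params: KaryotypeParams = field(default_factory=KaryotypeParams)

    def to_json(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return dataclasses.asdict(v)
            if isinstance(v, tuple):
                return list(v)
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations found in a config (empty list = valid)."""
    v: list[str] = []
    if config.n_interphase_cells < 1:
        v.append("n_interphase_cells must be >= 1")
    for name in ("n_spreads_control", "n_spreads_ir", "cohort_n_cells"):
        if getattr(config, name) < 1:
            v.append(f"{name} must be >= 1")
    for name in (
        "interphase_contact_probability",
        "translocation_frequency_control",
        "translocation_frequency_ir",
        "cohort_q",
    ):
        val = getattr(config, name)
        if not (0.0 <= val <= 1.0):
            v.append(f"{name} must lie in [0, 1], got {val}")
    if config.contact_threshold_um3 < 0:
        v.append("contact_threshold_um3 must be >= 0")
    for label, params in (("nucleus_params", config.nucleus_params),
                          ("territory_params", config.territory_params)):
        try:
            params.validate()
        except ValueError as e:
            v.append(f"{label}: {e}")
    try:
        config.karyotype_params.validate()
    except ValueError as e:
        v.append(f"karyotype_params: {e}")
    if not config.cohort_contact_grid:
        v.append("cohort_contact_grid must be nonempty")
    return v


def _log(stage: str, **info) -> None:
    print(json.dumps({"stage": stage, **info}), file=sys.stderr)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment_scheme(config: RunConfig) -> dict:
    """Execute the full demo scheme; returns the manifest dict.

    Stages: simulate+segment+measure the interphase arm; simulate+karyotype
    the ±IR arms; simulate the contact→translocation cohort and regress;
    Fisher contrast of the ±IR arms.  Partial outputs are left in place if a
    stage fails (the failing stage is named in the raised error).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: list[str] = []
    written: list[Path] = []

    def stage(name):
        stages.append(name)
        _log(name, status="start")

    try:
        # --- interphase arm: simulate -> segment -> measure
        stage("interphase")
        spec = NucleusSpec(
            contact_probability=config.interphase_contact_probability,
            seed=config.seed,
        )
        overlap_records, truth_records = [], []
        for i, (stack, truth) in enumerate(
            generate_cohort(spec, config.n_interphase_cells, seed=config.seed)
        ):
            nucleus = segment_nucleus(stack.channels["dna"], stack.voxel_size, config.nucleus_params)
            masks = {
                name: segment_territories(
                    stack.channels[name], nucleus, stack.voxel_size,
                    config.territory_params, channel_name=name,
                )
                for name in spec.channel_names
            }
            _, overlaps = measure_cell(
                nucleus, masks, cell_id=f"cell{i}",
                contact_threshold=config.contact_threshold_um3,
            )
            overlap_records += overlaps
            for pair, ov in truth.true_pair_overlaps.items():
                truth_records.append(
                    dict(cell_id=f"cell{i}", pair="-".join(pair), true_overlap_um3=ov,
                         true_contact=truth.true_contacts[pair])
                )
        contact_summary = summarize_population(overlap_records, replicate_id="demo")
        p = out / "interphase_contact_summary.csv"
        contact_summary.to_csv(p, index=False)
        written.append(p)
        p = out / "interphase_truth.csv"
        pd.DataFrame(truth_records).to_csv(p, index=False)
        written.append(p)
        _log("interphase", status="done", n_cells=config.n_interphase_cells)

        # --- karyotype arms (±IR)
        stage("karyotype")
        summaries = []
        for label, n, freq in (
            ("control", config.n_spreads_control, config.translocation_frequency_control),
            ("20Gy", config.n_spreads_ir, config.translocation_frequency_ir),
        ):
            spreads = generate_spread_cohort(
                n_spreads=n, translocation_frequency=freq,
                seed=config.seed + zlib.crc32(label.encode()) % 10000,
            )
            calls = [classify_spread(s, config.karyotype_params) for s in spreads]
            summaries.append(summarize_karyotypes(calls, condition=label))
        kary = pd.DataFrame(
            [
                dict(condition=s["condition"], n_spreads=s["n_spreads"],
                     n_with_translocation=s["n_with_translocation"], frequency=s["frequency"])
                for s in summaries
            ]
        )
        p = out / "karyotype_summary.csv"
        kary.to_csv(p, index=False)
        written.append(p)
        _log("karyotype", status="done")

        # --- contact -> translocation cohort regression
        stage("cohort_regression")
        frames = [
            simulate_translocation_cohort(
                CohortSpec(pairs=(("2", "3"),), contact_freq=f, q=config.cohort_q,
                           n_cells=config.cohort_n_cells, seed=config.seed * 1000 + k)
            )
            for k, f in enumerate(config.cohort_contact_grid)
        ]
        cohort = pd.concat(frames, ignore_index=True)
        fit = linear_regression(
            100.0 * cohort.contact_freq.to_numpy(),
            100.0 * cohort.translocation_freq.to_numpy(),
        )
        p = out / "cohort_populations.csv"
        cohort.to_csv(p, index=False)
        written.append(p)
        regression = dict(slope=fit.m, intercept=fit.intercept, r_squared=fit.r_squared,
                          p_value=fit.p_value, stderr=fit.stderr, n_points=fit.n_points)
        _log("cohort_regression", status="done", slope=fit.m)

        # --- Fisher contrast of the ±IR arms
        stage("fisher")
        a = summaries[1]  # IR
        b = summaries[0]  # control
        table = [
            [a["n_with_translocation"], a["n_spreads"] - a["n_with_translocation"]],
            [b["n_with_translocation"], b["n_spreads"] - b["n_with_translocation"]],
        ]
        fisher_p = fisher_exact(table)
        results = dict(
            regression=regression,
            fisher_ir_vs_control_p=fisher_p,
            contingency=table,
            karyotype=[
                {k: s[k] for k in ("condition", "n_spreads", "n_with_translocation", "frequency")}
                for s in summaries
            ],
        )
        p = out / "stats.json"
        p.write_text(json.dumps(results, indent=2))
        written.append(p)
        _log("fisher", status="done", p=fisher_p)
    except Exception as e:  # noqa: BLE001 - name the failing stage for the caller
        raise RuntimeError(f"pipeline stage {stages[-1]!r} failed: {e}") from e

    manifest = dict(
        version=__version__,
        stages=stages,
        config=config.to_json(),
        outputs={str(p.relative_to(out)): _sha256(p) for p in written},
        wall_clock_s=round(time.time() - t0, 3),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
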