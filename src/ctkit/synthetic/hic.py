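"""Paired synthetic Hi-C matrices with known cis/trans condition effects.

Cis matrices follow a power-law distance decay ``amp·(1+|i−j|)^(−α)`` (the
canonical contact-probability falloff within a chromosome); trans matrices
are flat at a low mean level.  Both conditions share the same seeded base
signal; the perturbed condition (KD) multiplies cis bins by ``cis_scale`` and
trans bins by ``trans_scale``, and each condition then receives independent
multiplicative lognormal noise of a given coefficient of variation.  A fixed
fraction of bins is set NA identically in both conditions, mimicking
unbalanceable bins of KR normalization.  The true relative change is thus
``scale − 1`` exactly in the noiseless case.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..hic import ContactMatrixPair, n_bins

__all__ = ["HiCSimSpec", "generate_contact_matrix_pair", "generate_condition_set"]


@dataclass
class HiCSimSpec:
    """Parameters of the paired-condition Hi-C simulation."""

    chromosome_lengths: Mapping[str, int] = None  # type: ignore[assignment]
    resolution: int = 5000
    cis_decay: float = 1.0  # power-law exponent of the distance falloff
    cis_amplitude: float = 10.0  # cis signal at zero distance
    trans_level: float = 0.5  # flat mean of trans bins
    cis_scale: float = 1.0  # KD multiplier on cis bins
    trans_scale: float = 1.0  # KD multiplier on trans bins
    na_fraction: float = 0.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosome_lengths is None:
            # 3-chromosome toy genome, a few hundred bins per chromosome
            self.chromosome_lengths = {"X": 400_000, "2": 500_000, "3": 600_000}

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not (0.0 <= self.na_fraction < 1.0):
            raise ValueError("na_fraction must lie in [0, 1)")
        for name in ("cis_amplitude", "trans_level", "cis_scale", "trans_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for c, L in self.chromosome_lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")

    def pairs(self) -> list[tuple[str, str]]:
        chroms = list(self.chromosome_lengths)
        out = [(c, c) for c in chroms]
        out += [tuple(sorted(p)) for p in itertools.combinations(chroms, 2)]
        return out


def _pair_rngs(spec: HiCSimSpec, pair: tuple[str, str], condition: str):
    """Deterministic per-pair streams: base/NA shared, noise per condition."""
    chroms = list(spec.chromosome_lengths)
    idx = (chroms.index(pair[0]), chroms.index(pair[1]))
    base = np.random.default_rng(
        np.random.SeedSequence([spec.seed, idx[0], idx[1], 0])
    )
    cond_code = {"WT": 1, "KD": 2}[condition]
    noise = np.random.default_rng(
        np.random.SeedSequence([spec.seed, idx[0], idx[1], cond_code])
    )
    return base, noise


def generate_contact_matrix_pair(
    spec: HiCSimSpec, pair: tuple[str, str], condition: str
) -> ContactMatrixPair:
    """One pair matrix for one condition ("WT" or "KD").

    The noise-free base signal and the NA mask are drawn from a stream keyed
    by (seed, pair) only, so WT and KD share them; condition noise and the
    cis/trans scaling differ.  NA bins number exactly
    ``round(na_fraction × total_bins)``.
    """
    spec.validate()
    if condition not in ("WT", "KD"):
        raise ValueError(f"condition must be 'WT' or 'KD', got {condition!r}")
    la = int(spec.chromosome_lengths[pair[0]])
    lb = int(spec.chromosome_lengths[pair[1]])
    shape = (n_bins(la, spec.resolution), n_bins(lb, spec.resolution))
    base_rng, noise_rng = _pair_rngs(spec, pair, condition)

    if pair[0] == pair[1]:
        i = np.arange(shape[0])[:, None]
        j = np.arange(shape[1])[None, :]
        base = spec.cis_amplitude * (1.0 + np.abs(i - j)) ** (-spec.cis_decay)
        scale = spec.cis_scale
    else:
        base = np.full(shape, spec.trans_level)
        scale = spec.trans_scale
    if condition == "WT":
        scale = 1.0

    n_na = int(round(spec.na_fraction * base.size))
    na_flat = base_rng.choice(base.size, size=n_na, replace=False)

    values = base * scale
    if spec.noise_cv > 0:
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = noise_rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=shape)
        values = values * noise
    values = values.astype(float)
    values.flat[na_flat] = np.nan
    return ContactMatrixPair(
        pair=pair, values=values, resolution=spec.resolution, lengths=(la, lb)
    )


def generate_condition_set(spec: HiCSimSpec, condition: str) -> list[ContactMatrixPair]:
    """All cis and trans pair matrices of the toy genome for one condition."""
    return [generate_contact_matrix_pair(spec, p, condition) for p in spec.pairs()]
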