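"""Ground-truthed synthetic 3D nuclei with painted chromosome territories.

The generator emulates the observable that whole-chromosome FISH paints give:
a DNA-counterstained diploid nucleus containing a small number of chromosome
territories (CTs), each territory a compact, irregular, connected blob filling
a tunable fraction of the nuclear volume (no single chromosome exceeds 28% of
the nucleus in the cell line modelled here).  Pairwise CT contact is drawn per
cell as a Bernoulli event with tunable probability; for pairs in contact the
two blobs share an intermixing region whose expected volume is controlled, so
population contact frequency and median intermixing volume are calibrated
quantities rather than emergent accidents.

Territory shapes come from seeded region growth inside the nuclear ellipsoid
under a voxel budget: each step dilates the current blob, keeps the
admissible frontier (optionally a random subset of it), and respects
exclusion (pairs not in contact never share a voxel) and a per-pair overlap
quota (pairs in contact absorb partner voxels until the quota is met).  Truth masks are recorded before the
optical model (Gaussian PSF blur, Gaussian read noise, optional Poisson photon
noise) renders the intensity channels, so every downstream measurement can be
validated against exact voxel-level truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from ..imagestack import ImageStack, voxel_volume

__all__ = [
    "NucleusSpec",
    "GroundTruth",
    "InfeasibleGeometryError",
    "generate_nucleus_image",
    "generate_cohort",
    "PAINT_CHANNELS",
]

#: Channel order for painted chromosomes (after the DNA counterstain).
PAINT_CHANNELS = ("X", "2", "3")


class InfeasibleGeometryError(RuntimeError):
    """Requested territory geometry cannot be realised inside the nucleus."""


@dataclass
class NucleusSpec:
    """Parameters of one synthetic nucleus.

    Defaults model a diploid BG3-like nucleus of ~200 µm³ with three painted
    chromosomes, each occupying 18% of the nuclear volume, pairwise contact
    probability 0.95 and an expected intermixing volume of 5% of the nucleus
    for pairs in contact.
    """

    shape: tuple[int, int, int] = (24, 64, 64)
    voxel_size: tuple[float, float, float] = (0.3, 0.15, 0.15)
    nucleus_semiaxes: tuple[float, float, float] = (3.0, 4.0, 4.0)
    n_territories: int = 3
    target_volume_fraction: float | Sequence[float] = 0.18
    contact_probability: float | Mapping[tuple[int, int], float] = 0.95
    intermixing_target: float | None = None  # µm³; None -> 5% of nuclear volume
    psf_sigma: float = 0.1  # µm; effective blur of a deconvolved widefield stack
    gaussian_sd: float = 0.1  # additive read noise, fraction of signal amplitude
    poisson_scale: float = 0.0  # photons per unit intensity; 0 disables shot noise
    split_homologs: bool = False
    contact_threshold: float = 0.5  # µm³, used to derive truth contact booleans
    seed: int = 0

    def fractions(self) -> list[float]:
        if np.isscalar(self.target_volume_fraction):
            return [float(self.target_volume_fraction)] * self.n_territories
        fr = [float(f) for f in self.target_volume_fraction]  # type: ignore[union-attr]
        if len(fr) != self.n_territories:
            raise ValueError("one target_volume_fraction per territory required")
        return fr

    def pair_contact_probability(self, pair: tuple[int, int]) -> float:
        if isinstance(self.contact_probability, Mapping):
            key = tuple(sorted(pair))
            return float(self.contact_probability[key])  # type: ignore[index]
        return float(self.contact_probability)

    def validate(self) -> None:
        if self.n_territories < 1:
            raise ValueError("n_territories must be >= 1")
        fr = self.fractions()
        if any(not (0 < f <= 0.28) for f in fr):
            raise ValueError(
                "each territory volume fraction must lie in (0, 0.28]; "
                "no single chromosome occupies more than 28% of the nucleus"
            )
        if sum(fr) >= 1.0:
            raise ValueError("territory volume fractions must sum to < 1")
        for name in ("voxel_size", "nucleus_semiaxes"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be strictly positive")
        if self.psf_sigma < 0 or self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("psf_sigma, gaussian_sd and poisson_scale must be >= 0")
        for pair in itertools.combinations(range(self.n_territories), 2):
            p = self.pair_contact_probability(pair)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"contact probability for pair {pair} outside [0, 1]")
        if self.intermixing_target is not None and self.intermixing_target <= 0:
            raise ValueError("intermixing_target must be positive (or None)")

    @property
    def channel_names(self) -> list[str]:
        return list(PAINT_CHANNELS[: self.n_territories])


@dataclass
class GroundTruth:
    """Exact voxel-level truth for one synthetic nucleus."""

    nucleus_mask: np.ndarray
    territory_masks: dict[str, np.ndarray]  # channel -> labelled grid (objects 1..k)
    true_volumes: dict[str, float]  # µm³ per channel
    true_pair_overlaps: dict[tuple[str, str], float]  # µm³ per unordered pair
    true_contacts: dict[tuple[str, str], bool]
    voxel_size: tuple[float, float, float] = (0.3, 0.15, 0.15)

    def nucleus_volume(self) -> float:
        return float(self.nucleus_mask.sum()) * voxel_volume(self.voxel_size)


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
) -> np.ndarray:
    center = [(s - 1) / 2.0 * v for s, v in zip(shape, voxel_size)]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(
        ((g * v - c) / a) ** 2
        for g, v, c, a in zip(grids, voxel_size, center, semiaxes)
    )
    return q <= 1.0


def _place_seeds(
    rng: np.random.Generator,
    nucleus: np.ndarray,
    voxel_size: tuple[float, float, float],
    semiaxes: tuple[float, float, float],
    shape: tuple[int, int, int],
    radii: list[float],
    contact: dict[tuple[int, int], bool],
    n: int,
    tries: int = 600,
) -> list[tuple[int, int, int]]:
    """Choose seed voxel positions satisfying pairwise distance constraints.

    Pairs planned to be in contact want seeds closer than ~0.55 of the sum of
    their nominal blob radii (so growth naturally interpenetrates up to the
    overlap quota); pairs not in contact want seeds at least the radius sum
    apart (so neither blob is starved by the exclusion rule).  A randomised
    search keeps the best-scoring configuration.
    """
    center = np.array([(s - 1) / 2.0 * v for s, v in zip(shape, voxel_size)])
    best: list[np.ndarray] | None = None
    best_score = -np.inf
    for _ in range(tries):
        pts = []
        for _i in range(n):
            # rejection-sample a point in the inner ellipsoid (75% semiaxes)
            for _r in range(100):
                u = rng.uniform(-0.75, 0.75, size=3)
                if (u ** 2).sum() <= 0.75 ** 2:
                    break
            pts.append(center + u * np.array(semiaxes))
        score = 0.0
        ok = True
        for (i, j) in itertools.combinations(range(n), 2):
            d = float(np.linalg.norm(pts[i] - pts[j]))
            rsum = radii[i] + radii[j]
            if contact[(i, j)]:
                margin = 0.55 * rsum - d
            else:
                # exclusion during growth guarantees disjointness; the
                # distance floor only protects against growth starvation
                margin = d - 1.0 * rsum
            score += min(margin, 0.0)
            ok = ok and margin >= 0.0
        if score > best_score:
            best_score, best = score, [p.copy() for p in pts]
        if ok:
            best = pts
            break
    assert best is not None
    seeds = []
    for p in best:
        idx = tuple(
            int(np.clip(round(p[a] / voxel_size[a]), 0, shape[a] - 1)) for a in range(3)
        )
        if not nucleus[idx]:
            # snap to the nearest nuclear voxel
            nz = np.argwhere(nucleus)
            phys = nz * np.array(voxel_size)
            idx = tuple(int(c) for c in nz[np.argmin(((phys - p) ** 2).sum(axis=1))])
        seeds.append(idx)
    return seeds


_STRUCT26 = ndi.generate_binary_structure(3, 3)


def _grow_territory(
    rng: np.random.Generator,
    seed_voxels: list[tuple[int, int, int]],
    target_voxels: int,
    nucleus: np.ndarray,
    forbidden: np.ndarray,
    quota_masks: list[tuple[np.ndarray, int]],
    accept_p: float = 1.0,
) -> np.ndarray:
    """Stochastic 26-connected region growth under exclusion and overlap quotas.

    ``quota_masks`` lists (partner mask, remaining-overlap-voxel quota) pairs;
    frontier voxels inside a partner's mask are admitted only while that
    partner's quota lasts, so realised pairwise overlap equals its quota
    whenever the geometry reaches the partner at all.
    """
    mask = np.zeros_like(nucleus, dtype=bool)
    for sv in seed_voxels:
        mask[sv] = True
    quotas = [int(q) for _, q in quota_masks]
    size = int(mask.sum())
    while size < target_voxels:
        frontier = ndi.binary_dilation(mask, structure=_STRUCT26) & nucleus & ~mask & ~forbidden
        cand = np.argwhere(frontier)
        if cand.size == 0:
            raise InfeasibleGeometryError(
                f"territory growth starved at {size}/{target_voxels} voxels; "
                "requested volume fractions / contact layout do not fit the nucleus"
            )
        # cap this batch at each partner's remaining overlap quota
        keep = np.ones(len(cand), dtype=bool)
        in_partner = np.zeros(len(cand), dtype=bool)
        for k, (pmask, _q) in enumerate(quota_masks):
            inside = pmask[cand[:, 0], cand[:, 1], cand[:, 2]]
            over = int(inside.sum()) - quotas[k]
            if over > 0:
                drop_idx = np.flatnonzero(inside)
                rng.shuffle(drop_idx)
                keep[drop_idx[:over]] = False
                inside = inside & keep
            in_partner |= inside
        in_partner = in_partner[keep]
        cand = cand[keep]
        if len(cand) == 0:
            # everything on the frontier was quota-blocked; mark as forbidden
            forbidden = forbidden | frontier
            continue
        # partner voxels are absorbed greedily (until the quota is spent) so
        # the realised overlap meets its quota; elsewhere a random subset of
        # the frontier is taken, giving irregular but connected shapes
        take = in_partner | (rng.random(len(cand)) < accept_p)
        if not take.any():
            take[rng.integers(len(cand))] = True
        chosen = cand[take]
        chosen_in_partner = in_partner[take]
        room = target_voxels - size
        if len(chosen) > room:
            # trim the batch to the volume budget, keeping partner voxels
            # preferentially (the scarce resource for overlap calibration)
            order = np.concatenate(
                [np.flatnonzero(chosen_in_partner), np.flatnonzero(~chosen_in_partner)]
            )[:room]
            chosen = chosen[order]
        # spend quota only for voxels actually added
        for k, (pmask, _q) in enumerate(quota_masks):
            quotas[k] -= int(pmask[chosen[:, 0], chosen[:, 1], chosen[:, 2]].sum())
        mask[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
        size += len(chosen)
    # top-up: any unmet overlap quota is claimed from partner voxels adjacent
    # to the blob, so realised intermixing meets its quota whenever the
    # partner is reachable at all (the territory ends slightly over budget)
    for k, (pmask, _q) in enumerate(quota_masks):
        while quotas[k] > 0:
            frontier = (
                ndi.binary_dilation(mask, structure=_STRUCT26) & pmask & ~mask & ~forbidden
            )
            cand = np.argwhere(frontier)
            if len(cand) == 0:
                break
            if len(cand) > quotas[k]:
                cand = cand[rng.permutation(len(cand))[: quotas[k]]]
            mask[cand[:, 0], cand[:, 1], cand[:, 2]] = True
            quotas[k] -= len(cand)
    return mask


def _render_channel(
    rng: np.random.Generator,
    mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    psf_sigma: float,
    gaussian_sd: float,
    poisson_scale: float,
) -> np.ndarray:
    img = mask.astype(np.float32)
    if psf_sigma > 0:
        sigma_vox = [psf_sigma / v for v in voxel_size]
        img = ndi.gaussian_filter(img, sigma=sigma_vox)
    if poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * poisson_scale).astype(np.float32)
        img /= poisson_scale
    if gaussian_sd > 0:
        img = img + rng.normal(0.0, gaussian_sd, size=img.shape).astype(np.float32)
    return img.astype(np.float32)


def generate_nucleus_image(spec: NucleusSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic nucleus and its exact ground truth.

    Returns an :class:`ImageStack` with a DNA channel plus one paint channel
    per territory, and the :class:`GroundTruth` recorded before blur/noise.
    Identical spec + seed gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size
    vv = voxel_volume(vs)
    nucleus = _ellipsoid_mask(spec.shape, vs, spec.nucleus_semiaxes)
    nuc_voxels = int(nucleus.sum())
    if nuc_voxels == 0:
        raise InfeasibleGeometryError("nucleus ellipsoid does not intersect the grid")
    nuc_volume = nuc_voxels * vv

    n = spec.n_territories
    fractions = spec.fractions()
    names = spec.channel_names
    mix_target = (
        spec.intermixing_target
        if spec.intermixing_target is not None
        else 0.05 * nuc_volume
    )

    # per-cell contact plan
    pairs = list(itertools.combinations(range(n), 2))
    contact_plan = {
        p: bool(rng.random() < spec.pair_contact_probability(p)) for p in pairs
    }
    # per-pair overlap quota (µm³ -> voxels); drawn around the target so the
    # population median matches it; clipped above the contact threshold so a
    # planned contact always realises one.
    quota_um3 = {
        p: (
            max(2.0 * spec.contact_threshold, rng.normal(mix_target, 0.2 * mix_target))
            if contact_plan[p]
            else 0.0
        )
        for p in pairs
    }

    radii = [(3.0 * f * nuc_volume / (4.0 * np.pi)) ** (1.0 / 3.0) for f in fractions]

    # growth can occasionally starve when a territory gets boxed in by
    # exclusion masks; retry placement + growth (the contact plan and the
    # overlap quotas stay fixed, so population calibration is unaffected)
    masks: list[np.ndarray] = []
    for attempt in range(5):
        try:
            seeds = _place_seeds(
                rng, nucleus, vs, spec.nucleus_semiaxes, spec.shape, radii, contact_plan, n
            )
            masks = []
            for i in range(n):
                target = int(round(fractions[i] * nuc_voxels))
                forbidden = np.zeros_like(nucleus, dtype=bool)
                quota_masks: list[tuple[np.ndarray, int]] = []
                for j in range(i):
                    p = (j, i)
                    if contact_plan[p]:
                        quota_masks.append((masks[j], int(round(quota_um3[p] / vv))))
                    else:
                        forbidden |= masks[j]
                if spec.split_homologs:
                    # two half-size homolog blobs, mutually exclusive, per channel
                    s1 = seeds[i]
                    s2 = _offset_seed(rng, nucleus, s1, vs, radii[i])
                    m1 = _grow_territory(rng, [s1], target // 2, nucleus, forbidden, quota_masks)
                    m2 = _grow_territory(rng, [s2], target - target // 2, nucleus, forbidden | m1, quota_masks)
                    masks.append(m1 | m2)
                else:
                    masks.append(
                        _grow_territory(rng, [seeds[i]], target, nucleus, forbidden, quota_masks)
                    )
            break
        except InfeasibleGeometryError:
            if attempt == 4:
                raise

    # exact truth, before the optical model
    true_volumes = {names[i]: float(masks[i].sum()) * vv for i in range(n)}
    true_pair_overlaps: dict[tuple[str, str], float] = {}
    true_contacts: dict[tuple[str, str], bool] = {}
    for (i, j) in pairs:
        key = (names[i], names[j])
        ov = float((masks[i] & masks[j]).sum()) * vv
        true_pair_overlaps[key] = ov
        true_contacts[key] = ov > spec.contact_threshold

    territory_labels: dict[str, np.ndarray] = {}
    for i in range(n):
        lab, _ = ndi.label(masks[i], structure=_STRUCT26)
        territory_labels[names[i]] = lab.astype(np.int32)

    channels = {"dna": _render_channel(rng, nucleus, vs, spec.psf_sigma, spec.gaussian_sd, spec.poisson_scale)}
    for i in range(n):
        channels[names[i]] = _render_channel(
            rng, masks[i], vs, spec.psf_sigma, spec.gaussian_sd, spec.poisson_scale
        )

    stack = ImageStack(channels=channels, voxel_size=vs, cell_id=f"cell-{spec.seed}")
    truth = GroundTruth(
        nucleus_mask=nucleus,
        territory_masks=territory_labels,
        true_volumes=true_volumes,
        true_pair_overlaps=true_pair_overlaps,
        true_contacts=true_contacts,
        voxel_size=vs,
    )
    return stack, truth


def _offset_seed(rng, nucleus, seed, voxel_size, radius_um) -> tuple[int, int, int]:
    """A second homolog seed ~2.5 blob radii from the first, inside the nucleus."""
    nz = np.argwhere(nucleus)
    phys = nz * np.array(voxel_size)
    p0 = np.array(seed) * np.array(voxel_size)
    d = np.linalg.norm(phys - p0, axis=1)
    want = 2.5 * radius_um
    cand = nz[d >= want] if (d >= want).any() else nz[d >= d.max() * 0.9]
    return tuple(int(c) for c in cand[rng.integers(len(cand))])


def generate_cohort(
    base: NucleusSpec, n_cells: int, seed: int | None = None
) -> Iterator[tuple[ImageStack, GroundTruth]]:
    """Yield ``n_cells`` independent nuclei derived from one base spec.

    Per-cell seeds are spawned deterministically from ``seed`` (default: the
    base spec's seed), so the cohort is reproducible as a whole.
    """
    import dataclasses

    root = base.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    child_seeds = ss.generate_state(n_cells) % (2**31 - 1)
    for k in range(n_cells):
        spec = dataclasses.replace(base, seed=int(child_seeds[k]))
        yield generate_nucleus_image(spec)
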