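"""Synthetic stroke-lesion cohorts with a known lesion-behavior ground truth.

The generator emulates the statistical structure of an acute-stroke language
cohort: ~98 patients, ~30% with a deficit (score < 0), ~58% left-hemisphere
lesions, lesion volumes spanning orders of magnitude, and a noisy monotone
dependence of the behavioral score on how much of a fixed "language-eloquent"
region the lesion destroys.

Model
-----
Each patient has a binary lesion mask grown by random-walk dilation from a
centroid, and a score

    score = baseline - effect_size * overlap + noise,

where ``overlap`` is the eloquent-map weight mass covered by the lesion
(0 to 1), ``baseline`` is the cohort-level performance offset of unlesioned
tissue, and ``noise ~ N(0, noise_sd)``.  Deficit means score < 0.  Because the
behavioral score of real cohorts is a standardized battery composite rather
than a zero-centred residual, ``baseline`` is positive by default: patients
whose lesion spares the eloquent region score near ``baseline`` and are almost
never classified as having a deficit.

Deficit prevalence is met by calibrating how many left-hemisphere lesions are
*targeted* at the eloquent region versus placed uniformly in the hemisphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .exceptions import (
    CapacityError,
    ConfigurationError,
    CoordinateError,
    DegeneracyError,
    GridError,
    ValidationError,
)
from .imaging import GRID_SHAPE, MIDLINE_INDEX, N_VOXELS, CohortManifest, LesionImage

# 26-connected neighborhood offsets (3x3x3 cube minus the centre).
_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)

# Default eloquent-region geometry: a left perisylvian bump (~MNI -50,-20,+10)
# with a mirrored right-hemisphere bump carrying 10% of the mass.
_LEFT_PEAK = (13, 29, 33)
_RIGHT_PEAK = (47, 29, 33)
_DEFAULT_SIGMA_VOX = 3.0

# Interior placement margins (voxels) so lesions are not clipped at the faces.
_MARGIN = 2


@dataclass
class EloquentMap:
    """Voxelwise importance weights of the simulated language-eloquent region.

    ``weights`` is a non-negative volume on the lesion grid summing to 1; the
    score model is linear in the lesioned weight mass.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != GRID_SHAPE:
            raise GridError(f"eloquent map must have shape {GRID_SHAPE}, got {w.shape}")
        if (w < 0).any():
            raise ValidationError("eloquent map weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValidationError("eloquent map must have positive total weight")
        self.weights = w / total

    @property
    def lateralization(self) -> float:
        """Fraction of weight mass strictly left of the midline column."""
        return float(self.weights[:MIDLINE_INDEX].sum())


def default_eloquent_map(
    sigma: float = _DEFAULT_SIGMA_VOX,
    left_weight: float = 0.9,
    left_peak: tuple[int, int, int] = _LEFT_PEAK,
    right_peak: tuple[int, int, int] = _RIGHT_PEAK,
) -> EloquentMap:
    """Gaussian left perisylvian bump plus a weak mirrored right bump.

    ``left_weight`` sets the map lateralization (0.9 by default: language
    deficits after right-hemisphere stroke are rare but not impossible).
    """
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in GRID_SHAPE], indexing="ij")

    def bump(peak):
        d2 = sum((g - p) ** 2 for g, p in zip(grids, peak))
        return np.exp(-d2 / (2.0 * sigma**2))

    left = bump(left_peak)
    right = bump(right_peak)
    w = left_weight * left / left.sum() + (1.0 - left_weight) * right / right.sum()
    return EloquentMap(w)


@dataclass
class CohortConfig:
    """Generation parameters for a synthetic cohort.

    Parameters
    ----------
    n_patients : int
        Cohort size (default 98).
    deficit_prevalence_target : float
        Target fraction with score < 0 (default 29/98).
    left_hemisphere_fraction : float
        Fraction of lesions placed in the left hemisphere (default 57/98).
    lesion_volume_range : (int, int)
        Volumes are sampled log-uniformly in this range (voxels).
    noise_sd : float
        SD of the Gaussian score noise, in score units.
    effect_size : float
        Maximal score drop for full eloquent-region destruction (score units).
    baseline : float
        Cohort-level performance offset; patients with no eloquent damage
        score ~N(baseline, noise_sd).
    followup_fraction : float
        Fraction of patients with a 3-month follow-up score.
    followup_noise_sd : float or None
        SD of additional noise in the follow-up score (defaults to noise_sd).
    standardize_scores : bool
        If True, z-score acute scores cohort-wide (and apply the same affine
        transform to follow-up scores).
    seed : int
        Master seed; the cohort is a pure function of (config, map).
    """

    n_patients: int = 98
    deficit_prevalence_target: float = 29 / 98
    left_hemisphere_fraction: float = 57 / 98
    lesion_volume_range: tuple[int, int] = (5, 5000)
    noise_sd: float = 1.9
    effect_size: float = 15.0
    baseline: float = 2.0
    followup_fraction: float = 74 / 98
    followup_noise_sd: float | None = None
    standardize_scores: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if not 0 < self.deficit_prevalence_target < 1:
            raise ConfigurationError("deficit_prevalence_target must be in (0,1)")
        if not 0 < self.left_hemisphere_fraction < 1:
            raise ConfigurationError("left_hemisphere_fraction must be in (0,1)")
        vmin, vmax = self.lesion_volume_range
        if vmin < 1:
            raise ConfigurationError("minimum lesion volume must be >= 1")
        if vmax > N_VOXELS:
            raise ConfigurationError("maximum lesion volume exceeds grid capacity")
        if vmin > vmax:
            raise ConfigurationError("lesion_volume_range must be (min, max)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.followup_fraction <= 1:
            raise ConfigurationError("followup_fraction must be in [0,1]")


def _check_centroid(centroid) -> tuple[int, int, int]:
    c = tuple(int(v) for v in centroid)
    if len(c) != 3 or any(not 0 <= v < s for v, s in zip(c, GRID_SHAPE)):
        raise CoordinateError(f"centroid {centroid} outside grid {GRID_SHAPE}")
    return c


def _grow_lesion(rng: np.random.Generator, centroid, volume: int) -> np.ndarray:
    """Grow a single 26-connected blob of exactly ``volume`` voxels.

    Random-walk dilation: at each step a random batch of frontier voxels
    (26-neighbors of the current lesion) is absorbed.  Batching keeps the
    growth O(volume) in numpy while preserving irregular, compact shapes.
    """
    c = _check_centroid(centroid)
    if volume < 1:
        raise CapacityError("lesion volume must be >= 1")
    if volume > N_VOXELS:
        raise CapacityError(f"volume {volume} exceeds grid capacity {N_VOXELS}")

    lesion = np.zeros(GRID_SHAPE, dtype=bool)
    frontier = np.zeros(GRID_SHAPE, dtype=bool)
    lesion[c] = True
    count = 1

    def add_frontier(coords: np.ndarray) -> None:
        neigh = coords[:, None, :] + _OFFSETS[None, :, :]
        neigh = neigh.reshape(-1, 3)
        ok = ((neigh >= 0) & (neigh < np.array(GRID_SHAPE))).all(axis=1)
        neigh = neigh[ok]
        flat = np.ravel_multi_index(neigh.T, GRID_SHAPE)
        flat = flat[~lesion.reshape(-1)[flat]]
        frontier.reshape(-1)[flat] = True

    add_frontier(np.array([c]))
    while count < volume:
        candidates = np.flatnonzero(frontier.reshape(-1))
        if candidates.size == 0:  # pragma: no cover - only if lesion fills grid
            raise CapacityError("no room left to grow the lesion")
        need = volume - count
        take = min(need, max(1, int(round(0.35 * candidates.size))))
        chosen = rng.choice(candidates, size=take, replace=False)
        lesion.reshape(-1)[chosen] = True
        frontier.reshape(-1)[chosen] = False
        count += take
        coords = np.stack(np.unravel_index(chosen, GRID_SHAPE), axis=1)
        add_frontier(coords)
    return lesion


def generate_lesion(seed: int, centroid, volume: int) -> LesionImage:
    """Generate one lesion mask; deterministic given (seed, centroid, volume)."""
    rng = np.random.default_rng(seed)
    return LesionImage(_grow_lesion(rng, centroid, int(volume)).astype(np.uint8))


def eloquent_overlap(lesion: LesionImage | np.ndarray, emap: EloquentMap) -> float:
    """Eloquent weight mass covered by the lesion (0 to 1)."""
    mask = lesion.voxels if isinstance(lesion, LesionImage) else np.asarray(lesion)
    if mask.shape != GRID_SHAPE:
        raise GridError(f"lesion shape {mask.shape} does not match grid {GRID_SHAPE}")
    return float(emap.weights[mask.astype(bool)].sum())


def score_from_lesion(
    lesion: LesionImage,
    emap: EloquentMap,
    effect_size: float,
    noise_sd: float,
    seed: int,
    baseline: float = 0.0,
) -> float:
    """Behavioral score of one lesion under the linear overlap model."""
    overlap = eloquent_overlap(lesion, emap)
    noise = 0.0
    if noise_sd > 0:
        noise = float(np.random.default_rng(seed).normal(0.0, noise_sd))
    return float(baseline - effect_size * overlap + noise)


def _deficit_probability(overlap: np.ndarray, config: CohortConfig) -> np.ndarray:
    """P(score < 0) for given eloquent overlaps under the config's noise model."""
    signal = config.baseline - config.effect_size * np.asarray(overlap, dtype=float)
    if config.noise_sd == 0:
        return (signal < 0).astype(float)
    return special.ndtr(-signal / config.noise_sd)


def _ball_overlap(volume: np.ndarray, emap: EloquentMap, sigma: float) -> np.ndarray:
    """Approximate overlap of an eloquent-centred ball of the given volume.

    Used only to seed the prevalence calibration; the realized overlaps of the
    grown lesions are used for the final adjustment.
    """
    r = (3.0 * np.asarray(volume, dtype=float) / (4.0 * math.pi)) ** (1.0 / 3.0)
    mass = special.gammainc(1.5, r**2 / (2.0 * sigma**2))
    return emap.lateralization * mass


def _place_centroid(rng, targeted: bool, left: bool) -> tuple[int, int, int]:
    lo = np.array([_MARGIN] * 3)
    hi = np.array(GRID_SHAPE) - _MARGIN
    if targeted:
        jitter = rng.normal(0.0, 1.5, size=3)
        c = np.rint(np.array(_LEFT_PEAK) + jitter).astype(int)
        c = np.clip(c, lo, [MIDLINE_INDEX - 1, hi[1] - 1, hi[2] - 1])
        return tuple(int(v) for v in c)
    if left:
        x = rng.integers(_MARGIN, MIDLINE_INDEX)
    else:
        x = rng.integers(MIDLINE_INDEX + 1, hi[0])
    y = rng.integers(_MARGIN, hi[1])
    z = rng.integers(_MARGIN, hi[2])
    return (int(x), int(y), int(z))


def generate_cohort(
    config: CohortConfig, emap: EloquentMap | None = None
) -> tuple[list[LesionImage], CohortManifest]:
    """Generate a full synthetic cohort; bit-reproducible from (config, map).

    Left-hemisphere patients are split into eloquent-*targeted* lesions
    (centroid near the map peak) and uniformly placed ones; the targeted
    fraction is calibrated so the expected deficit prevalence matches
    ``config.deficit_prevalence_target``.  Raises ConfigurationError when the
    target is unreachable (expected prevalence off by more than 10 points even
    at the feasible extreme).
    """
    if emap is None:
        emap = default_eloquent_map()
    n = config.n_patients
    master = np.random.default_rng(config.seed)

    volumes = np.exp(
        master.uniform(
            math.log(config.lesion_volume_range[0]),
            math.log(config.lesion_volume_range[1] + 1),
            size=n,
        )
    ).astype(int)
    volumes = np.clip(volumes, config.lesion_volume_range[0], config.lesion_volume_range[1])

    n_left = int(round(n * config.left_hemisphere_fraction))
    is_left = np.zeros(n, dtype=bool)
    is_left[master.permutation(n)[:n_left]] = True

    # Seed the targeted fraction from the ball approximation, then refine on
    # the realized lesions.
    p_untargeted = float(_deficit_probability(np.zeros(1), config)[0])
    p_targeted = _deficit_probability(_ball_overlap(volumes, emap, _DEFAULT_SIGMA_VOX), config)
    gain = p_targeted - p_untargeted
    base = n * p_untargeted
    denom = float(gain[is_left].sum())
    want = config.deficit_prevalence_target * n - base
    t0 = 0.0 if denom <= 0 else float(np.clip(want / denom, 0.0, 1.0))

    left_idx = np.flatnonzero(is_left)
    n_targeted = int(round(t0 * n_left))
    targeted = np.zeros(n, dtype=bool)
    targeted[master.permutation(left_idx)[:n_targeted]] = True

    def build_patient(i: int, is_targeted: bool) -> tuple[np.ndarray, float]:
        rng = np.random.default_rng([config.seed, i, int(is_targeted)])
        centroid = _place_centroid(rng, is_targeted, bool(is_left[i]))
        mask = _grow_lesion(rng, centroid, int(volumes[i]))
        return mask, eloquent_overlap(mask, emap)

    masks: list[np.ndarray | None] = [None] * n
    overlaps = np.zeros(n)
    for i in range(n):
        masks[i], overlaps[i] = build_patient(i, bool(targeted[i]))

    # Greedy refinement: promote/demote left-hemisphere lesions until the
    # expected prevalence (under the noise model) is on target.
    target = config.deficit_prevalence_target
    tol = 0.02

    def expected_prevalence() -> float:
        return float(_deficit_probability(overlaps, config).mean())

    exp_prev = expected_prevalence()
    for _ in range(n_left):
        if exp_prev < target - tol:
            pool = [i for i in left_idx if not targeted[i]]
            if not pool:
                break
            i = max(pool, key=lambda j: (volumes[j], -j))  # biggest lesions first
            targeted[i] = True
        elif exp_prev > target + tol:
            pool = [i for i in left_idx if targeted[i]]
            if not pool:
                break
            i = min(pool, key=lambda j: (volumes[j], j))
            targeted[i] = False
        else:
            break
        masks[i], overlaps[i] = build_patient(i, bool(targeted[i]))
        new_prev = expected_prevalence()
        if abs(new_prev - target) >= abs(exp_prev - target):
            # Overshot: revert the flip and keep the closer configuration.
            targeted[i] = not targeted[i]
            masks[i], overlaps[i] = build_patient(i, bool(targeted[i]))
            break
        exp_prev = new_prev

    if abs(exp_prev - target) > 0.10:
        raise ConfigurationError(
            f"deficit prevalence target {target:.2f} unreachable "
            f"(expected prevalence {exp_prev:.2f} at the feasible extreme); "
            "adjust effect_size/baseline/volume range or the eloquent map"
        )

    noise = np.array(
        [np.random.default_rng([config.seed, i, 7]).normal(0.0, 1.0) for i in range(n)]
    )
    scores = config.baseline - config.effect_size * overlaps + config.noise_sd * noise

    fu_sd = config.noise_sd if config.followup_noise_sd is None else config.followup_noise_sd
    n_fu = int(round(n * config.followup_fraction))
    has_fu = np.zeros(n, dtype=bool)
    has_fu[master.permutation(n)[:n_fu]] = True
    fu_noise = np.array(
        [np.random.default_rng([config.seed, i, 11]).normal(0.0, 1.0) for i in range(n)]
    )
    followup = np.where(has_fu, scores + fu_sd * fu_noise, np.nan)

    if config.standardize_scores:
        mu, sd = scores.mean(), scores.std()
        if sd == 0:
            raise DegeneracyError("cannot standardize a zero-variance score vector")
        scores = (scores - mu) / sd
        followup = (followup - mu) / sd

    # Hemisphere label is recorded from the centroid side of each lesion.
    centroid_x = np.array([np.argwhere(m)[:, 0].mean() for m in masks])
    hemi = np.where(centroid_x <= MIDLINE_INDEX, "L", "R")

    ids = [f"P{i+1:03d}" for i in range(n)]
    images = [
        LesionImage(m.astype(np.uint8), patient_id=pid) for m, pid in zip(masks, ids)
    ]
    manifest = CohortManifest(
        pd.DataFrame(
            {
                "patient_id": ids,
                "score": scores,
                "score_followup": followup,
                "hemisphere": hemi,
                "lesion_volume_voxels": [int(m.sum()) for m in masks],
            }
        ),
        provenance=f"synthetic cohort, seed={config.seed}",
    )
    return images, manifest


def calibrate_noise_sd(
    config: CohortConfig,
    emap: EloquentMap | None = None,
    target_r2: float = 0.8,
) -> float:
    """Noise SD giving a generative signal-to-total variance ratio ``target_r2``.

    Generates the cohort noise-free, measures the variance of the deterministic
    score component, and returns sd = sd_signal * sqrt((1-R2)/R2).
    """
    if not 0 < target_r2 < 1:
        raise ConfigurationError("target_r2 must be in (0,1)")
    noise_free = replace(config, noise_sd=0.0)
    _, manifest = generate_cohort(noise_free, emap)
    sd_signal = float(np.std(manifest.scores))
    if sd_signal == 0:
        raise DegeneracyError("no signal variance; cannot calibrate noise")
    return sd_signal * math.sqrt((1.0 - target_r2) / target_r2)


def generate_clustered_cohort(
    n_clusters: int = 4,
    cluster_size: int = 8,
    n_singletons: int = 6,
    cluster_volume: int = 400,
    seed: int = 0,
    emap: EloquentMap | None = None,
    effect_size: float = 15.0,
    baseline: float = 2.0,
    noise_sd: float = 0.5,
) -> tuple[list[LesionImage], CohortManifest, np.ndarray]:
    """Cohort of tight lesion clusters plus unique singleton lesions.

    Cluster members share a centroid (small jitter) and volume (+-10%), so they
    are mutually redundant under centroid, topological and raw distances;
    singletons are placed far apart with volumes spanning an order of
    magnitude.  Scores follow the same linear overlap model as
    :func:`generate_cohort`.  Returns (images, manifest, is_cluster_member).
    """
    if emap is None:
        emap = default_eloquent_map()

    # Well-separated anchor positions (first on the eloquent peak, so cluster
    # scores span the deficit range) and distinct per-cluster volumes: members
    # of one cluster are mutually close under centroid, topological AND raw
    # distance, while clusters stay far from each other on every metric.
    all_anchors = [(13, 29, 33), (44, 22, 22), (22, 54, 24), (42, 50, 42), (30, 14, 44)]
    if n_clusters > len(all_anchors):
        raise ConfigurationError(f"at most {len(all_anchors)} clusters supported")
    anchors = [np.array(a) for a in all_anchors[:n_clusters]]
    cluster_volumes = np.unique(
        np.geomspace(0.6 * cluster_volume, 2.2 * cluster_volume, n_clusters).astype(int)
    )

    masks: list[np.ndarray] = []
    member: list[bool] = []

    def _perturb(template: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # Small random frontier dilation (single-connectedness preserved); the
        # dilation is resampled until the rounded centroid matches the
        # template's, so cluster members stay aligned after centroid centring.
        base = template.astype(bool)
        ref = np.floor(np.argwhere(base).mean(axis=0) + 0.5).astype(int)
        extra = max(1, int(0.03 * base.sum()))
        frontier = ndimage.binary_dilation(base, np.ones((3, 3, 3), bool)) & ~base
        idx = np.flatnonzero(frontier.reshape(-1))
        grown = base.copy()
        for _ in range(25):
            grown = base.copy()
            take = rng.choice(idx, size=min(extra, idx.size), replace=False)
            grown.reshape(-1)[take] = True
            cen = np.floor(np.argwhere(grown).mean(axis=0) + 0.5).astype(int)
            if (cen == ref).all():
                break
        return grown

    for k, (anchor, vol) in enumerate(zip(anchors, cluster_volumes)):
        template = _grow_lesion(
            np.random.default_rng([seed, k, 13]), tuple(anchor), int(vol)
        )
        for j in range(cluster_size):
            masks.append(_perturb(template, np.random.default_rng([seed, k, j, 17])))
            member.append(True)

    # Singletons near the grid centre: roughly equidistant from every cluster,
    # with unique volumes spanning nearly two orders of magnitude.
    centre = np.array([30, 36, 30])
    offsets = np.array(
        [(0, 0, 0), (3, 0, -2), (-3, 2, 2), (0, -4, 0), (2, 3, 3), (-2, -3, -3),
         (4, 4, -4), (-4, -4, 4)]
    )
    if n_singletons > len(offsets):
        raise ConfigurationError(f"at most {len(offsets)} singletons supported")
    # Singleton volumes sit above the largest cluster volume: a small lesion is
    # topologically near-subset of every larger one (distance ~ sqrt(volume
    # difference)), which would make it spuriously redundant with a cluster.
    singleton_volumes = np.geomspace(
        1.5 * cluster_volumes.max(), 5.5 * cluster_volumes.max(), max(n_singletons, 2)
    ).astype(int)
    for j in range(n_singletons):
        cen = tuple(int(v) for v in centre + offsets[j])
        masks.append(
            _grow_lesion(
                np.random.default_rng([seed, 99, j]), cen, int(singleton_volumes[j])
            )
        )
        member.append(False)

    n = len(masks)
    overlaps = np.array([eloquent_overlap(m, emap) for m in masks])
    noise = np.array(
        [np.random.default_rng([seed, i, 7]).normal(0.0, 1.0) for i in range(n)]
    )
    scores = baseline - effect_size * overlaps + noise_sd * noise
    ids = [f"C{i+1:03d}" for i in range(n)]
    images = [LesionImage(m.astype(np.uint8), patient_id=pid) for m, pid in zip(masks, ids)]
    centroid_x = np.array([np.argwhere(m)[:, 0].mean() for m in masks])
    manifest = CohortManifest(
        pd.DataFrame(
            {
                "patient_id": ids,
                "score": scores,
                "score_followup": np.nan,
                "hemisphere": np.where(centroid_x <= MIDLINE_INDEX, "L", "R"),
                "lesion_volume_voxels": [int(m.sum()) for m in masks],
            }
        ),
        provenance=f"clustered synthetic cohort, seed={seed}",
    )
    return images, manifest, np.array(member)


def connected_components(mask: np.ndarray) -> int:
    """Number of 26-connected components in a binary mask (diagnostic helper)."""
    _, num = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    return int(num)
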