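"""Synthetic life-span gray-matter datasets with planted covariance patterns.

The generator emulates the inputs of a grouped seed-PLS structural-covariance
study: N participants spanning ages 6-94 in six age bins, each with one 3-D
modulated gray-matter volume on a common grid.  Every volume is the sum of

* a constant gray-matter baseline inside a brain mask,
* a cohort-level global age decline (linear in the age-bin midpoint),
* one or more planted spatial covariance patterns, each a unit-norm sum of
  Gaussian blobs anchored at network seed coordinates, expressed per subject
  as ``amplitude * f(age) * (1 + c * eps)`` where ``f`` is the pattern's age
  trajectory (stable decline, inverted-U, or flat), ``c`` the subject
  variability fraction and ``eps`` standard normal,
* small scanner-field-strength and sex offsets, and
* i.i.d. Gaussian voxel noise,

followed by Gaussian smoothing.  The multiplicative subject term is what
creates *within-group* covariance between a pattern's seed regions and the
rest of its spatial map — the quantity the PLS analysis measures — and ties
its group-wise strength to the trajectory ``f``, so that planted trajectories
are recoverable from the latent-variable structure.

Ground truth (pattern maps, their smoothed counterparts, and every subject's
realized expression) is attached to the returned dataset for downstream
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dataset import GrayMatterDataset
from .errors import DegenerateDataError, InvalidConfigError
from .pls import DEFAULT_AGE_BINS
from .seeds import SeedTable, builtin_seed_table, mm_to_voxel

import pandas as pd

TRAJECTORY_KINDS = ("stable_decline", "inverted_u", "flat")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Probability of a 3T scan per age group, echoing the field-strength
#: imbalance typical of pooled open-access repositories (children and the
#: oldest cohorts mostly 1.5T, young adults mostly 3T) at moderate contrast;
#: because field strength tracks age group, scanner correction of brain
#: scores removes some genuine age signal, and stronger imbalance biases
#: fitted trajectory peaks (see the methods note).
DEFAULT_PROB_3T = (0.25, 0.45, 0.80, 0.55, 0.35, 0.20)

#: World coordinate (MNI mm) of the grid centre; chosen so the ventral
#: attention seed quadruple sits inside the default mask.
DEFAULT_CENTER_MM = (0.0, -10.0, 18.0)


def smooth_volume(volume, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Gaussian-smooth a 3-D volume to the given FWHM (mm).

    ``fwhm_mm == 0`` returns the input unchanged; the kernel is normalized so
    the total sum over an interior-supported image is preserved.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be nonnegative, got {fwhm_mm}")
    if voxel_size_mm <= 0:
        raise ValueError(f"voxel_size_mm must be positive, got {voxel_size_mm}")
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {volume.shape}")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(volume, sigma=sigma_vox, mode="constant", cval=0.0)


@dataclass(frozen=True)
class PatternSpec:
    """Configuration of one planted spatial covariance pattern.

    The spatial map is a unit-norm sum of Gaussian blobs at the four seeds of
    ``network`` (weight ``seed_weight``) plus optional extra blob centers;
    ``centers_mm`` overrides the seed lookup entirely (used on small test
    grids).  ``bipolar`` patterns are demeaned inside the mask so their total
    is zero — a contrast pattern orthogonal to global volume changes.
    """

    kind: str
    amplitude: float = 0.5
    network: str | None = "ventral_attention"
    centers_mm: tuple[tuple[float, float, float], ...] | None = None
    seed_weight: float = 1.0
    seed_weights: tuple[float, ...] | None = None   # per-seed, overrides seed_weight
    extra_centers_mm: tuple[tuple[float, float, float], ...] = ()
    extra_weight: float = 1.0
    extra_weights: tuple[float, ...] | None = None  # per-extra, may be negative
    blob_fwhm_mm: float = 12.0
    subject_sd_frac: float = 1.5
    # stable_decline parameters
    plateau_age: float = 70.0
    plateau_frac: float = 0.4
    decline_tau: float = 10.0
    # inverted_u parameters
    peak_age: float = 45.0
    halfwidth_years: float = 39.0
    bipolar: bool = False
    #: patterns sharing a factor id express the same per-subject latent factor
    #: (their expressions are correlated within groups, with the sign of the
    #: trajectory); None gives the pattern its own independent factor
    factor: int | None = None

    def __post_init__(self):
        if self.kind not in TRAJECTORY_KINDS:
            raise InvalidConfigError(
                f"trajectory kind must be one of {TRAJECTORY_KINDS}, got {self.kind!r}"
            )
        if self.amplitude < 0:
            raise InvalidConfigError("pattern amplitude must be nonnegative")
        if self.centers_mm is None and self.network is None:
            raise InvalidConfigError("pattern needs either a network or explicit centers")


def _softplus(x):
    return np.logaddexp(0.0, x)


def trajectory_mean(spec: PatternSpec, age) -> np.ndarray:
    """Expected (noise-free) expression shape f(age), unit scale at its maximum.

    * ``stable_decline``: softplus ramp that declines from 1 at age 6 and
      flattens toward ``plateau_frac`` around ``plateau_age``.
    * ``inverted_u``: concave quadratic with vertex at ``peak_age``, value 1
      at the vertex (may go slightly negative at the extremes of life).
    * ``flat``: constant 1.
    """
    age = np.asarray(age, dtype=float)
    if spec.kind == "stable_decline":
        ramp = _softplus((spec.plateau_age - age) / spec.decline_tau)
        ramp0 = _softplus((spec.plateau_age - 6.0) / spec.decline_tau)
        return spec.plateau_frac + (1.0 - spec.plateau_frac) * ramp / ramp0
    if spec.kind == "inverted_u":
        return 1.0 - ((age - spec.peak_age) / spec.halfwidth_years) ** 2
    return np.ones_like(age)


@dataclass
class PlantedPattern:
    """Ground truth for one planted pattern.

    ``spatial_map`` is the unit-norm masked map as planted (pre-smoothing);
    ``smoothed_map`` is the same map after the dataset's smoothing kernel —
    the version actually present in the data and the reference for recovery
    comparisons.  ``expression`` holds each subject's realized expression
    coefficient.
    """

    spec: PatternSpec
    spatial_map: np.ndarray
    smoothed_map: np.ndarray
    seed_support: tuple[tuple[float, float, float], ...]
    expression: np.ndarray

    def expression_fn(self, age):
        """Expected expression at a given age (years), finite on [6, 94]."""
        return self.spec.amplitude * trajectory_mean(self.spec, age)


@dataclass
class GroundTruth:
    patterns: list[PlantedPattern]
    mask_map_smoothed: np.ndarray  # smoothed uniform-in-mask map, masked vector

    @property
    def expression_matrix(self) -> np.ndarray:
        """N x K matrix of realized per-subject expressions."""
        if not self.patterns:
            return np.zeros((0, 0))
        return np.column_stack([p.expression for p in self.patterns])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic life-span dataset.

    Defaults describe the desk-scale study conditions: 6 age bins, a
    26x30x26 grid at 3 mm (~12k masked voxels) holding the ventral-attention
    seed quadruple, 8 mm smoothing, voxel noise 0.1 against a gray-matter
    baseline of 0.6, and planted amplitudes quoted as multiples of the voxel
    noise (signal-to-noise ratio ``amplitude / noise_sd``).
    """

    n_per_group: int = 50
    grid_shape: tuple[int, int, int] = (26, 30, 26)
    voxel_size_mm: float = 3.0
    center_mm: tuple[float, float, float] = DEFAULT_CENTER_MM
    patterns: tuple[PatternSpec, ...] = ()
    noise_sd: float = 0.1
    baseline: float = 0.6
    global_decline_slope: float = -0.0002
    scanner_effect: float = 0.001
    sex_effect: float = 0.0005
    smoothing_fwhm_mm: float = 8.0
    prob_3t_by_group: tuple[float, ...] = DEFAULT_PROB_3T
    age_bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS
    orthogonalize_patterns: bool = True
    mask_exponent: float = 3.0
    mask_semiaxis_frac: float = 0.98
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 3:
            raise InvalidConfigError(
                f"n_per_group must be >= 3 (within-group correlation needs it), "
                f"got {self.n_per_group}"
            )
        if len(self.grid_shape) != 3 or any(d < 4 for d in self.grid_shape):
            raise InvalidConfigError(
                f"grid_shape needs 3 dimensions each >= 4, got {self.grid_shape}"
            )
        if self.voxel_size_mm <= 0:
            raise InvalidConfigError("voxel_size_mm must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        if self.noise_sd == 0 and not self.patterns:
            raise DegenerateDataError(
                "zero noise with zero planted patterns would produce constant data"
            )
        if len(self.prob_3t_by_group) != len(self.age_bins):
            raise InvalidConfigError(
                "prob_3t_by_group must provide one probability per age bin"
            )
        if self.smoothing_fwhm_mm < 0:
            raise InvalidConfigError("smoothing_fwhm_mm must be nonnegative")

    @property
    def n_participants(self) -> int:
        return self.n_per_group * len(self.age_bins)


def make_affine(grid_shape, voxel_size_mm: float, center_mm=DEFAULT_CENTER_MM) -> np.ndarray:
    """RAS+ axis-aligned affine placing the grid centre at ``center_mm``."""
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size_mm
    half = (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0
    affine[:3, 3] = np.asarray(center_mm, dtype=float) - voxel_size_mm * half
    return affine


def make_mask(
    grid_shape,
    voxel_size_mm: float,
    center_mm=DEFAULT_CENTER_MM,
    exponent: float = 3.0,
    semiaxis_frac: float = 0.98,
) -> np.ndarray:
    """Superellipsoid brain mask inscribed in the grid.

    An exponent of 2 gives an ellipsoid; the default 3 is slightly boxier,
    which keeps lateral seed coordinates (e.g. anterior insula) inside the
    mask on a compact grid, as a real brain outline would.
    """
    shape = tuple(int(d) for d in grid_shape)
    half_mm = (np.asarray(shape, dtype=float) - 1.0) / 2.0 * voxel_size_mm
    semi = semiaxis_frac * half_mm
    coords = np.meshgrid(*[np.arange(d, dtype=float) for d in shape], indexing="ij")
    u = [
        np.abs((c - (d - 1) / 2.0) * voxel_size_mm) / s
        for c, d, s in zip(coords, shape, semi)
    ]
    return (u[0] ** exponent + u[1] ** exponent + u[2] ** exponent) <= 1.0


def _pattern_centers(spec: PatternSpec, seed_table: SeedTable):
    """(centers, weights, support) for a pattern's blobs.

    Support lists only the seed coordinates that carry nonzero loading.
    """
    centers: list[tuple[float, float, float]] = []
    weights: list[float] = []
    if spec.centers_mm is not None:
        anchor = [tuple(c) for c in spec.centers_mm]
    else:
        anchor = [s.coord_mm for s in seed_table.network_seeds(spec.network)]
    w_anchor = (
        list(spec.seed_weights)
        if spec.seed_weights is not None
        else [spec.seed_weight] * len(anchor)
    )
    if len(w_anchor) != len(anchor):
        raise InvalidConfigError(
            f"seed_weights has {len(w_anchor)} entries for {len(anchor)} seeds"
        )
    centers.extend(anchor)
    weights.extend(w_anchor)
    w_extra = (
        list(spec.extra_weights)
        if spec.extra_weights is not None
        else [spec.extra_weight] * len(spec.extra_centers_mm)
    )
    if len(w_extra) != len(spec.extra_centers_mm):
        raise InvalidConfigError(
            f"extra_weights has {len(w_extra)} entries for "
            f"{len(spec.extra_centers_mm)} extra centers"
        )
    for c in spec.extra_centers_mm:
        centers.append(tuple(c))
    weights.extend(w_extra)
    support = tuple(c for c, w in zip(anchor, w_anchor) if w != 0)
    return centers, weights, support


def _blob_map(mask, affine, voxel_size_mm, centers, weights, blob_fwhm_mm):
    """Unit-norm (over the mask) sum of Gaussian blobs at the given centers."""
    vol = np.zeros(mask.shape)
    for (x, y, z), w in zip(centers, weights):
        idx = mm_to_voxel(affine, (x, y, z), mask.shape)
        if not mask[idx]:
            raise InvalidConfigError(
                f"pattern blob center {(x, y, z)} mm falls outside the brain mask"
            )
        vol[idx] += w
    vol = smooth_volume(vol, blob_fwhm_mm, voxel_size_mm)
    vol[~mask] = 0.0
    norm = np.linalg.norm(vol[mask])
    if norm == 0:
        raise InvalidConfigError("pattern map is identically zero")
    return vol / norm


def build_patterns(config: SimulationConfig, seed_table: SeedTable | None = None):
    """Construct the planted spatial maps (3-D, unit norm over the mask)."""
    seed_table = seed_table or builtin_seed_table()
    affine = make_affine(config.grid_shape, config.voxel_size_mm, config.center_mm)
    mask = make_mask(
        config.grid_shape,
        config.voxel_size_mm,
        config.center_mm,
        config.mask_exponent,
        config.mask_semiaxis_frac,
    )
    maps, supports = [], []
    for spec in config.patterns:
        centers, weights, support = _pattern_centers(spec, seed_table)
        vol = _blob_map(
            mask, affine, config.voxel_size_mm, centers, weights, spec.blob_fwhm_mm
        )
        if spec.bipolar:
            # remove the pattern's global-volume component as it will appear
            # in the smoothed data: after dataset smoothing and masking the
            # planted map sums to ~zero, so the contrast is orthogonal to
            # whole-brain volume changes
            umask = mask.astype(float)
            sm_mask_sum = smooth_volume(
                umask, config.smoothing_fwhm_mm, config.voxel_size_mm
            )[mask].sum()
            sm_vol_sum = smooth_volume(
                vol, config.smoothing_fwhm_mm, config.voxel_size_mm
            )[mask].sum()
            if sm_mask_sum > 0:
                vol[mask] -= (sm_vol_sum / sm_mask_sum)
        if config.orthogonalize_patterns:
            for prev in maps:
                vol[mask] -= (vol[mask] @ prev[mask]) * prev[mask]
        norm = np.linalg.norm(vol[mask])
        if norm <= 1e-12:
            raise InvalidConfigError(
                "pattern map vanished after demeaning/orthogonalization"
            )
        vol = vol / norm
        maps.append(vol)
        supports.append(support)
    return mask, affine, maps, supports


def generate_dataset(
    config: SimulationConfig, seed_table: SeedTable | None = None
) -> GrayMatterDataset:
    """Generate a synthetic life-span dataset from a validated configuration.

    Deterministic: identical config (including ``rng_seed``) produces
    bit-identical output.  Ages are uniform within each bin; sex is balanced;
    scanner field strength follows the per-group 3T probabilities.
    """
    rng = np.random.default_rng(config.rng_seed)
    bins = config.age_bins
    G, n = len(bins), config.n_per_group
    N = G * n

    ages = np.concatenate([rng.uniform(lo, hi + 1.0, size=n) for lo, hi in bins])
    group_idx = np.repeat(np.arange(G), n)
    sex_male = rng.random(N) < 0.5
    p3t = np.asarray(config.prob_3t_by_group, dtype=float)
    scanner_3t = rng.random(N) < p3t[group_idx]

    mask, affine, maps, supports = build_patterns(config, seed_table)
    K = len(maps)

    # one latent factor per distinct factor id (drawn in id order for
    # determinism); patterns without an id get a private factor
    factor_ids = []
    for k, spec in enumerate(config.patterns):
        factor_ids.append(spec.factor if spec.factor is not None else ("own", k))
    factors = {fid: rng.standard_normal(N) for fid in dict.fromkeys(factor_ids)}

    expression = np.empty((N, K))
    for k, spec in enumerate(config.patterns):
        mean_k = spec.amplitude * trajectory_mean(spec, ages)
        expression[:, k] = mean_k * (
            1.0 + spec.subject_sd_frac * factors[factor_ids[k]]
        )

    mids = np.array([(lo + hi) / 2.0 for lo, hi in bins])
    cohort_decline = config.global_decline_slope * (mids - 6.0)

    fmask = mask.astype(float)
    volumes = np.empty((N,) + tuple(config.grid_shape))
    for i in range(N):
        vol = (config.baseline + cohort_decline[group_idx[i]]) * fmask
        for k in range(K):
            vol = vol + expression[i, k] * maps[k]
        if scanner_3t[i]:
            vol = vol + config.scanner_effect * fmask
        if sex_male[i]:
            vol = vol + config.sex_effect * fmask
        vol = vol + config.noise_sd * rng.standard_normal(config.grid_shape)
        volumes[i] = smooth_volume(vol, config.smoothing_fwhm_mm, config.voxel_size_mm)

    participants = pd.DataFrame(
        {
            "participant_id": [f"sub-{i:04d}" for i in range(N)],
            "age": ages,
            "sex": np.where(sex_male, "M", "F"),
            "scanner_tesla": np.where(scanner_3t, 3.0, 1.5),
        }
    )

    planted = [
        PlantedPattern(
            spec=spec,
            spatial_map=maps[k][mask],
            smoothed_map=smooth_volume(
                maps[k], config.smoothing_fwhm_mm, config.voxel_size_mm
            )[mask],
            seed_support=supports[k],
            expression=expression[:, k].copy(),
        )
        for k, spec in enumerate(config.patterns)
    ]
    truth = GroundTruth(
        patterns=planted,
        mask_map_smoothed=smooth_volume(
            fmask, config.smoothing_fwhm_mm, config.voxel_size_mm
        )[mask],
    )

    return GrayMatterDataset(
        volumes=volumes,
        mask=mask,
        affine=affine,
        participants=participants,
        ground_truth=truth,
    )


def two_pattern_config(
    n_per_group: int = 50,
    snr: float = 5.0,
    noise_sd: float = 0.1,
    rng_seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Reference two-pattern study: stable decline plus inverted-U.

    Both patterns load on the ventral-attention seed quadruple (the network
    whose seeds fit the default grid); the stable pattern carries extra
    midline/posterior blobs, while the age-dependent pattern is a bipolar
    contrast between anterior/insular and posterior blob sets, echoing the
    topography of the age-dependent latent variables reported for
    neurocognitive networks.
    """
    amp = snr * noise_sd
    patterns = (
        # Stable network pattern: anchored on the anterior cingulate pair with
        # weaker insular loading plus midline/posterior association blobs.
        # Its per-subject expression declines steeply before flattening.
        PatternSpec(
            kind="stable_decline",
            amplitude=amp,
            network="ventral_attention",
            seed_weights=(1.0, 1.0, 0.3, 0.3),
            extra_centers_mm=((0.0, -30.0, 28.0), (-14.0, -38.0, 2.0)),
            extra_weight=1.0,
            blob_fwhm_mm=12.0,
            subject_sd_frac=1.5,
            plateau_frac=0.25,
            decline_tau=8.0,
            factor=0,
        ),
        # Age-dependent contrast: a purely distal bipolar pattern expressing
        # the *same* subject factor with an inverted-U weight that crosses
        # zero near ages 21 and 69, so the seed regions covary positively
        # with these territories in mid-adulthood and negatively at both ends
        # of the life span (the covariance topography migrates with age).
        PatternSpec(
            kind="inverted_u",
            amplitude=amp,
            centers_mm=((18.0, -28.0, 6.0), (0.0, -10.0, 38.0), (-20.0, -20.0, 30.0)),
            seed_weights=(1.0, 1.0, -1.0),
            blob_fwhm_mm=12.0,
            subject_sd_frac=0.9,
            peak_age=45.0,
            halfwidth_years=24.0,
            bipolar=True,
            factor=0,
        ),
    )
    return SimulationConfig(
        n_per_group=n_per_group,
        patterns=patterns,
        noise_sd=noise_sd,
        rng_seed=rng_seed,
        **overrides,
    )
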