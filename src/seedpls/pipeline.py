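"""End-to-end pipeline: seed extraction -> grouped PLS -> scores -> trajectories.

Each requested network is analyzed independently (one seed-PLS per network,
no cross-network correction): the network's seed vector Y is extracted,
voxels that are constant within any age group are dropped from the mask with
a logged count, the grouped covariance stack is decomposed, LVs are assessed
by permutation and bootstrap, brain scores are computed from the raw voxel
data, corrected for scanner strength and sex, and their age trajectories
fitted.  A single top-level seed deterministically spawns independent RNG
streams per network and stage, so full runs are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as seedpls_io
from .dataset import GrayMatterDataset
from .errors import SeedPLSError
from .pls import (
    AgeGroupScheme,
    assign_groups,
    bootstrap_saliences,
    brain_scores,
    covariance_stack,
    decompose,
    group_correlations,
    group_normalize,
    permutation_test,
    select_lvs,
    threshold_pattern,
)
from .seeds import SeedTable, builtin_seed_table, network_seed_average
from .trajectory import correct_scores, fit_trajectory


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``n_perm`` / ``n_boot`` default to the reference resampling depths (5,000
    permutations, 1,000 bootstraps).  Values below 100 are refused unless
    ``allow_small_resampling`` is set (meant for tests and smoke runs only).
    """

    dataset_dir: str | None = None
    output_dir: str = "seedpls_out"
    networks: tuple[str, ...] = ()          # empty = all networks in the seed table
    seed_table_path: str | None = None      # None = built-in 24-seed table
    n_perm: int = 5000
    n_boot: int = 1000
    threshold_level: float = 0.95
    p_threshold: float = 0.001
    min_cov_explained: float = 5.0
    age_bins: tuple[tuple[int, int], ...] | None = None
    rng_seed: int = 0
    allow_small_resampling: bool = False
    write_nifti: bool = True

    def __post_init__(self):
        if not self.allow_small_resampling and (self.n_perm < 100 or self.n_boot < 100):
            raise ValueError(
                "n_perm and n_boot must be >= 100 for reportable runs "
                "(set allow_small_resampling for smoke tests)"
            )
        self.networks = tuple(self.networks)
        if self.age_bins is not None:
            self.age_bins = tuple(tuple(b) for b in self.age_bins)

    @property
    def scheme(self) -> AgeGroupScheme:
        return AgeGroupScheme(self.age_bins) if self.age_bins else AgeGroupScheme()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class NetworkResult:
    """All artifacts of one network's analysis."""

    network: str
    seed_values: np.ndarray
    groups: np.ndarray
    singular_values: np.ndarray
    cov_explained: np.ndarray
    p_perm: np.ndarray
    selected: np.ndarray
    u: np.ndarray
    v: np.ndarray                      # (V_kept, G)
    bsr: np.ndarray
    threshold_masks: np.ndarray        # bool (V_kept, G)
    scores: np.ndarray                 # (N, G) raw brain scores
    corrected_scores: np.ndarray
    group_r: np.ndarray
    group_r_ci: tuple[np.ndarray, np.ndarray]
    group_reliable: np.ndarray
    trajectories: list                  # TrajectoryFit per selected LV (None if skipped)
    kept_voxels: np.ndarray            # indices into the dataset mask vector
    n_dropped_voxels: int
    n_redrawn_perms: int
    n_zero_se: int
    covariate_coefficients: object = None


def screen_voxels(X: np.ndarray, groups) -> np.ndarray:
    """Indices of voxels with nonzero variance in every age group."""
    keep = np.ones(X.shape[1], dtype=bool)
    for g in np.unique(np.asarray(groups)):
        block = X[np.asarray(groups) == g]
        keep &= block.std(axis=0) > 1e-12
    return np.flatnonzero(keep)


def analyze_network(
    dataset: GrayMatterDataset,
    network: str,
    seed_table: SeedTable | None = None,
    scheme: AgeGroupScheme | None = None,
    n_perm: int = 5000,
    n_boot: int = 1000,
    threshold_level: float = 0.95,
    p_threshold: float = 0.001,
    min_cov_explained: float = 5.0,
    rng: np.random.Generator | None = None,
    fit_trajectories: bool = True,
) -> NetworkResult:
    """Run the full grouped seed-PLS analysis for one network."""
    seed_table = seed_table or builtin_seed_table()
    scheme = scheme or AgeGroupScheme()
    rng = rng if rng is not None else np.random.default_rng()

    groups = assign_groups(dataset.ages, scheme)
    Y = network_seed_average(dataset, seed_table, network).values

    X_full = dataset.voxel_matrix
    kept = screen_voxels(X_full, groups)
    n_dropped = X_full.shape[1] - kept.size
    X = X_full[:, kept]

    Xn, Yn = group_normalize(X, Y, groups)
    Z = covariance_stack(Xn, Yn, groups)
    lvset = decompose(Z)

    perm_rng, boot_rng = [np.random.default_rng(s) for s in rng.spawn(2)]
    p, n_redrawn = permutation_test(X, Y, groups, n_perm=n_perm, rng=perm_rng)
    lvset.p_perm = p
    lvset.selected = select_lvs(p, lvset.cov_explained, p_threshold, min_cov_explained)

    boot = bootstrap_saliences(X, Y, groups, n_boot=n_boot, rng=boot_rng, lvset=lvset)
    lvset.bootstrap_ratios = boot.bsr
    lvset.threshold_masks = threshold_pattern(boot.bsr, threshold_level)

    L = brain_scores(X, lvset.v)
    gcorr = group_correlations(L, Y, groups, r_resamples=boot.r_resamples)

    correction = correct_scores(
        L,
        dataset.participants["scanner_tesla"].to_numpy(),
        dataset.participants["sex"].to_numpy(),
    )

    trajectories = []
    if fit_trajectories:
        for j in range(lvset.n_lvs):
            if lvset.selected[j]:
                trajectories.append(
                    fit_trajectory(correction.corrected[:, j], dataset.ages, scheme=scheme)
                )
            else:
                trajectories.append(None)

    return NetworkResult(
        network=network,
        seed_values=Y,
        groups=groups,
        singular_values=lvset.singular_values,
        cov_explained=lvset.cov_explained,
        p_perm=p,
        selected=lvset.selected,
        u=lvset.u,
        v=lvset.v,
        bsr=boot.bsr,
        threshold_masks=lvset.threshold_masks,
        scores=L,
        corrected_scores=correction.corrected,
        group_r=gcorr.r,
        group_r_ci=(gcorr.ci_low, gcorr.ci_high),
        group_reliable=gcorr.reliable,
        trajectories=trajectories,
        kept_voxels=kept,
        n_dropped_voxels=n_dropped,
        n_redrawn_perms=n_redrawn,
        n_zero_se=boot.n_zero_se,
        covariate_coefficients=correction.coefficients,
    )


def _result_summary(res: NetworkResult, scheme: AgeGroupScheme) -> dict:
    """Machine-readable scalar summary of one network's analysis."""
    def _clean(a):
        return np.where(np.isfinite(a), a, np.nan)

    traj = []
    for j, fit in enumerate(res.trajectories or []):
        if fit is None:
            traj.append(None)
        else:
            traj.append(
                {
                    "lv": j + 1,
                    "degree": fit.degree,
                    "coefficients": fit.coefficients,
                    "aicc": fit.aicc,
                    "peak_age": fit.peak_age,
                    "age_range": list(fit.age_range),
                }
            )
    return {
        "network": res.network,
        "n_latent_variables": int(res.singular_values.size),
        "age_groups": scheme.labels(),
        "singular_values": res.singular_values,
        "cov_explained_percent": res.cov_explained,
        "p_perm": res.p_perm,
        "selected": res.selected,
        "group_saliences": res.u,
        "group_score_corr": res.group_r,
        "group_score_corr_ci_low": res.group_r_ci[0],
        "group_score_corr_ci_high": res.group_r_ci[1],
        "group_score_reliable": res.group_reliable,
        "n_voxels_analyzed": int(res.kept_voxels.size),
        "n_dropped_voxels": int(res.n_dropped_voxels),
        "n_redrawn_permutations": int(res.n_redrawn_perms),
        "n_zero_bootstrap_se": int(res.n_zero_se),
        "n_thresholded_voxels": res.threshold_masks.sum(axis=0).astype(int),
        "trajectories": traj,
    }


def run_pipeline(
    config: RunConfig,
    dataset: GrayMatterDataset | None = None,
) -> dict:
    """Run every requested network and write all artifacts.

    Returns the result bundle (also written as ``results.json``).  A failure
    in one network is recorded with its stage and reason; other networks
    still run.
    """
    if dataset is None:
        if config.dataset_dir is None:
            raise ValueError("config.dataset_dir is required when no dataset is passed")
        dataset = seedpls_io.read_dataset(config.dataset_dir)

    seed_table = (
        SeedTable.from_tsv(config.seed_table_path)
        if config.seed_table_path
        else builtin_seed_table()
    )
    networks = config.networks or seed_table.networks
    scheme = config.scheme
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root = np.random.default_rng(config.rng_seed)
    network_rngs = {
        net: np.random.default_rng(s) for net, s in zip(networks, root.spawn(len(networks)))
    }

    bundle: dict = {
        "rng_seed": config.rng_seed,
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
        "threshold_level": config.threshold_level,
        "n_participants": dataset.n_participants,
        "networks": {},
        "errors": {},
    }

    for net in networks:
        try:
            res = analyze_network(
                dataset,
                net,
                seed_table=seed_table,
                scheme=scheme,
                n_perm=config.n_perm,
                n_boot=config.n_boot,
                threshold_level=config.threshold_level,
                p_threshold=config.p_threshold,
                min_cov_explained=config.min_cov_explained,
                rng=network_rngs[net],
            )
        except (SeedPLSError, ValueError) as exc:
            bundle["errors"][net] = f"{type(exc).__name__}: {exc}"
            continue
        bundle["networks"][net] = _result_summary(res, scheme)
        if config.write_nifti:
            _write_network_maps(res, dataset, out_dir / net)
        _write_network_tables(res, dataset, out_dir / net)

    seedpls_io.save_json(bundle, out_dir / "results.json")
    return bundle


def _restore_map(dataset, kept, values):
    full = np.zeros(dataset.n_voxels)
    full[kept] = values
    return dataset.unmask(full)


def _write_network_maps(res: NetworkResult, dataset, net_dir: Path):
    net_dir.mkdir(parents=True, exist_ok=True)
    for j in range(res.singular_values.size):
        tag = f"lv{j + 1}"
        seedpls_io.save_nifti(
            _restore_map(dataset, res.kept_voxels, res.v[:, j]),
            dataset.affine,
            net_dir / f"{tag}_salience.nii",
        )
        bsr = np.nan_to_num(res.bsr[:, j], posinf=0.0, neginf=0.0)
        seedpls_io.save_nifti(
            _restore_map(dataset, res.kept_voxels, bsr),
            dataset.affine,
            net_dir / f"{tag}_bsr.nii",
        )
        seedpls_io.save_nifti(
            _restore_map(dataset, res.kept_voxels, res.threshold_masks[:, j].astype(float)),
            dataset.affine,
            net_dir / f"{tag}_thresholded.nii",
        )


def _write_network_tables(res: NetworkResult, dataset, net_dir: Path):
    import pandas as pd

    net_dir.mkdir(parents=True, exist_ok=True)
    n_lv = res.singular_values.size
    scores = pd.DataFrame(
        {
            "participant_id": dataset.participants["participant_id"],
            "age": dataset.ages,
            "group": res.groups,
            **{f"lv{j+1}_score": res.scores[:, j] for j in range(n_lv)},
            **{f"lv{j+1}_corrected": res.corrected_scores[:, j] for j in range(n_lv)},
        }
    )
    scores.to_csv(net_dir / "brain_scores.tsv", sep="\t", index=False)

    rows = []
    for j, fit in enumerate(res.trajectories or []):
        if fit is None:
            continue
        rows.append(
            {
                "lv": j + 1,
                "degree": fit.degree,
                "coefficients": ";".join(f"{c:.8g}" for c in fit.coefficients),
                "aicc": fit.aicc,
                "peak_age": "" if fit.peak_age is None else f"{fit.peak_age:.3f}",
            }
        )
    pd.DataFrame(rows).to_csv(net_dir / "trajectories.tsv", sep="\t", index=False)
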