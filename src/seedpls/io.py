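"""Readers and writers: NIfTI volumes, participant TSVs, ground truth, results.

Datasets are laid out one NIfTI volume per participant (``<id>_gm.nii``)
next to a ``participants.tsv``, a shared ``mask.nii`` and, for simulated
data, a ``ground_truth.json``.  Result serialization is canonical (sorted
keys, fixed float repr) so identical analyses produce byte-identical JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dataset import REQUIRED_PHENOTYPES, GrayMatterDataset
from .errors import DatasetError
from .simulate import GroundTruth, PatternSpec, PlantedPattern

_MANIFEST_NAME = "manifest.json"
_PARTICIPANTS_NAME = "participants.tsv"
_MASK_NAME = "mask.nii"
_TRUTH_NAME = "ground_truth.json"


def canonical_json(obj) -> str:
    """Deterministic JSON text (sorted keys, full float precision)."""
    return json.dumps(obj, sort_keys=True, indent=2, allow_nan=True)


def _to_jsonable(x):
    if isinstance(x, dict):
        return {k: _to_jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_to_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return [_to_jsonable(v) for v in x.tolist()]
    if isinstance(x, (np.floating, np.integer, np.bool_)):
        return x.item()
    return x


def save_json(obj, path) -> None:
    Path(path).write_text(canonical_json(_to_jsonable(obj)) + "\n")


def save_nifti(data, affine, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))


def write_dataset(dataset: GrayMatterDataset, directory) -> dict:
    """Write a dataset directory; returns the manifest (also saved as JSON).

    One float32 NIfTI per participant plus participants.tsv, mask.nii and,
    when ground truth is attached, ground_truth.json.  Round-trips through
    :func:`read_dataset` up to float32 storage precision.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DatasetError(f"cannot create dataset directory {directory}: {exc}") from exc

    ids = dataset.participants["participant_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise DatasetError("duplicate participant ids")
    volume_files = []
    for i, pid in enumerate(ids):
        fname = f"{pid}_gm.nii"
        save_nifti(dataset.volumes[i], dataset.affine, directory / fname)
        volume_files.append(fname)
    save_nifti(dataset.mask.astype(np.float32), dataset.affine, directory / _MASK_NAME)
    dataset.participants.to_csv(directory / _PARTICIPANTS_NAME, sep="\t", index=False)

    if dataset.ground_truth is not None:
        save_json(_truth_to_json(dataset.ground_truth), directory / _TRUTH_NAME)

    manifest = {
        "n_participants": dataset.n_participants,
        "grid_shape": list(dataset.grid_shape),
        "n_mask_voxels": dataset.n_voxels,
        "participants_tsv": _PARTICIPANTS_NAME,
        "mask": _MASK_NAME,
        "volumes": volume_files,
        "ground_truth": _TRUTH_NAME if dataset.ground_truth is not None else None,
    }
    save_json(manifest, directory / _MANIFEST_NAME)
    return manifest


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "mask_map_smoothed": truth.mask_map_smoothed,
        "patterns": [
            {
                "spec": {
                    "kind": p.spec.kind,
                    "amplitude": p.spec.amplitude,
                    "network": p.spec.network,
                    "centers_mm": p.spec.centers_mm,
                    "seed_weight": p.spec.seed_weight,
                    "extra_centers_mm": p.spec.extra_centers_mm,
                    "extra_weight": p.spec.extra_weight,
                    "blob_fwhm_mm": p.spec.blob_fwhm_mm,
                    "subject_sd_frac": p.spec.subject_sd_frac,
                    "plateau_age": p.spec.plateau_age,
                    "plateau_frac": p.spec.plateau_frac,
                    "decline_tau": p.spec.decline_tau,
                    "peak_age": p.spec.peak_age,
                    "halfwidth_years": p.spec.halfwidth_years,
                    "bipolar": p.spec.bipolar,
                },
                "spatial_map": p.spatial_map,
                "smoothed_map": p.smoothed_map,
                "seed_support": p.seed_support,
                "expression": p.expression,
            }
            for p in truth.patterns
        ],
    }


def _truth_from_json(payload: dict) -> GroundTruth:
    patterns = []
    for item in payload["patterns"]:
        spec_kw = dict(item["spec"])
        for key in ("centers_mm", "extra_centers_mm"):
            if spec_kw.get(key) is not None:
                spec_kw[key] = tuple(tuple(c) for c in spec_kw[key])
        patterns.append(
            PlantedPattern(
                spec=PatternSpec(**spec_kw),
                spatial_map=np.asarray(item["spatial_map"], dtype=float),
                smoothed_map=np.asarray(item["smoothed_map"], dtype=float),
                seed_support=tuple(tuple(c) for c in item["seed_support"]),
                expression=np.asarray(item["expression"], dtype=float),
            )
        )
    return GroundTruth(
        patterns=patterns,
        mask_map_smoothed=np.asarray(payload["mask_map_smoothed"], dtype=float),
    )


def read_dataset(directory, participants_tsv=None, mask=None) -> GrayMatterDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Participant ordering is canonicalized by id, so shuffled TSV rows load to
    the same dataset.  Missing volumes, duplicate ids and grid/affine
    mismatches raise :class:`DatasetError` naming the offender.
    """
    directory = Path(directory)
    tsv = Path(participants_tsv) if participants_tsv else directory / _PARTICIPANTS_NAME
    if not tsv.exists():
        raise DatasetError(f"participants table not found: {tsv}")
    participants = pd.read_csv(tsv, sep="\t")
    missing_cols = set(REQUIRED_PHENOTYPES) - set(participants.columns)
    if missing_cols:
        raise DatasetError(f"participants table missing columns {sorted(missing_cols)}")
    participants["participant_id"] = participants["participant_id"].astype(str)
    if participants["participant_id"].duplicated().any():
        dupes = participants.loc[
            participants["participant_id"].duplicated(), "participant_id"
        ].tolist()
        raise DatasetError(f"duplicate participant id(s): {dupes}")
    participants = participants.sort_values("participant_id").reset_index(drop=True)

    mask_path = Path(mask) if mask else directory / _MASK_NAME
    if not mask_path.exists():
        raise DatasetError(f"mask volume not found: {mask_path}")
    mask_img = nib.load(str(mask_path))
    mask_arr = np.asarray(mask_img.dataobj) > 0.5
    affine = mask_img.affine

    volumes = []
    for pid in participants["participant_id"]:
        vol_path = directory / f"{pid}_gm.nii"
        if not vol_path.exists():
            raise DatasetError(f"no volume for participant {pid!r} (expected {vol_path})")
        img = nib.load(str(vol_path))
        if img.shape != mask_arr.shape:
            raise DatasetError(
                f"volume for {pid!r} has grid {img.shape}, mask has {mask_arr.shape}"
            )
        if not np.allclose(img.affine, affine, atol=1e-4):
            raise DatasetError(f"volume for {pid!r} has a mismatched affine")
        volumes.append(np.asarray(img.dataobj, dtype=np.float64))

    truth = None
    truth_path = directory / _TRUTH_NAME
    if truth_path.exists():
        truth = _truth_from_json(json.loads(truth_path.read_text()))

    return GrayMatterDataset(
        volumes=np.stack(volumes),
        mask=mask_arr,
        affine=affine,
        participants=participants,
        ground_truth=truth,
    )
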