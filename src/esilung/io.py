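"""Readers and writers for curves, profiles, CT volumes and reports."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterResult, PatternProfile
from .curves import MEFVCurve, SpirometricIndices
from .densitometry import PairedCTStudy
from .exceptions import MalformedInputError
from .model import ESIResult

CURVE_HEADER = ("volume_l", "flow_l_s")


def read_curve(path, validate: bool = True) -> MEFVCurve:
    """Read an MEFV curve from a two-column CSV (``volume_l,flow_l_s``).

    Lines starting with ``#`` are comments.  Parse failures report the
    offending line number.
    """
    path = Path(path)
    volumes, flows = [], []
    header_seen = False
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if not header_seen:
                if tuple(c.strip() for c in row[:2]) != CURVE_HEADER:
                    raise MalformedInputError(
                        f"{path}:{lineno}: expected header 'volume_l,flow_l_s'"
                    )
                header_seen = True
                continue
            try:
                volumes.append(float(row[0]))
                flows.append(float(row[1]))
            except (ValueError, IndexError) as exc:
                raise MalformedInputError(f"{path}:{lineno}: {exc}") from exc
    if not header_seen:
        raise MalformedInputError(f"{path}: missing header line")
    if not volumes:
        raise MalformedInputError(f"{path}: no data rows")
    return MEFVCurve(volume_l=np.array(volumes), flow_l_s=np.array(flows),
                     validate=validate)


def write_curve(curve: MEFVCurve, path) -> None:
    """Write a curve as CSV at full double precision (round-trip exact)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CURVE_HEADER)
        for v, f in zip(curve.volume_l, curve.flow_l_s):
            writer.writerow([f"{v:.17g}", f"{f:.17g}"])


def write_report(result: ESIResult, spiro: SpirometricIndices, path) -> None:
    """Write the per-curve fit/score report as JSON."""
    payload = {
        "esi": result.esi,
        "theta_p": result.fit.theta_p,
        "theta_d": result.fit.theta_d,
        "u_star": result.fit.u_star,
        "w": result.fit.w,
        "sse": result.fit.sse,
        "single_phase": result.fit.single_phase,
        "fev1": spiro.fev1,
        "fvc": spiro.fvc,
        "pef": spiro.pef,
    }
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# pattern profiles

PROFILE_COLUMNS = ["id", "region", "normal", "mild_laa", "moderate_laa",
                   "severe_laa", "volume_weight"]


def write_profiles(profiles: dict[str, PatternProfile], path) -> None:
    """Write profiles as tidy CSV, one row per subject-region."""
    rows = []
    for sid, prof in profiles.items():
        for r, region in enumerate(prof.regions):
            rows.append([sid, region, *prof.fractions[r].tolist(),
                         prof.volume_weights[r]])
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_profiles(path) -> dict[str, PatternProfile]:
    """Read a tidy profiles CSV back into PatternProfile objects."""
    df = pd.read_csv(path, comment="#")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedInputError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for sid, sub in df.groupby("id", sort=False):
        out[str(sid)] = PatternProfile(
            regions=sub["region"].tolist(),
            fractions=sub[["normal", "mild_laa", "moderate_laa", "severe_laa"]].to_numpy(),
            volume_weights=sub["volume_weight"].to_numpy(),
        )
    return out


def write_clusters(ids: list[str], result: ClusterResult, path) -> None:
    df = pd.DataFrame({
        "id": ids,
        "cluster": result.labels,
        "is_exemplar": [int(i in set(result.exemplars)) for i in range(len(ids))],
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# NIfTI volumes

def load_paired_ct(insp_path, exp_path, mask_path) -> PairedCTStudy:
    """Load aligned inspiratory/expiratory volumes and lung mask from NIfTI."""
    import nibabel as nib

    insp = np.asanyarray(nib.load(str(insp_path)).dataobj, dtype=float)
    exp_ = np.asanyarray(nib.load(str(exp_path)).dataobj, dtype=float)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    return PairedCTStudy(insp_hu=insp, exp_hu=exp_, mask=mask)


def save_volume(data: np.ndarray, path, dtype=None) -> None:
    """Save a grid as NIfTI with an identity affine (synthetic volumes)."""
    import nibabel as nib

    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


def save_paired_ct(study: PairedCTStudy, insp_path, exp_path, mask_path) -> None:
    save_volume(study.insp_hu, insp_path, dtype=np.float32)
    save_volume(study.exp_hu, exp_path, dtype=np.float32)
    save_volume(study.mask.astype(np.uint8), mask_path)


def save_labels(labels: np.ndarray, path) -> None:
    """Save a PRM label map (codes 0-4) as integer NIfTI."""
    save_volume(labels.astype(np.uint8), path)
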