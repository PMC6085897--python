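"""Temporal preprocessing of labeled 4D BOLD-like data.

The chain, applied in fixed order, mirrors standard pediatric rs-fMRI
practice: truncate/trim volumes -> 0.01 Hz high-pass -> nuisance regression
(6 motion parameters + mean white-matter and CSF signals) -> motion
scrubbing at 0.5 mm relative RMS displacement (subjects with fewer than 125
surviving volumes are flagged for exclusion) -> 3x3x3 mask-aware spatial
median filter. ROI inclusion uses the brain-mask overlap rule: regions whose
mean overlap with the subject brain masks falls below 90%, or that appear on
a manual exclusion list, are dropped, and connectivity downstream uses only
ROI-mask intersection voxels.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import RegionAtlas, SUSCEPTIBILITY_EXCLUDED_NAMES

logger = logging.getLogger(__name__)

MOTION_COLUMNS = ["tx", "ty", "tz", "rx", "ry", "rz", "rel_disp"]

#: radius (mm) of the sphere used to convert rotations to arc length in the
#: fallback displacement formula — the common neuroimaging convention.
ROTATION_SPHERE_RADIUS_MM = 50.0


class PreprocessError(ValueError):
    pass


@dataclass
class LabeledVolume:
    """4D time series with an aligned label grid and brain mask.

    ``wm_series``/``csf_series`` optionally carry the mean white-matter and
    CSF nuisance signals alongside the data so they are trimmed and scrubbed
    in lockstep with the volumes.
    """

    data: np.ndarray          # (x, y, z, t) float
    labels: np.ndarray        # (x, y, z) int, 0 = background
    brain_mask: np.ndarray    # (x, y, z) bool
    tr: float                 # seconds
    voxel_dims: tuple[float, float, float]  # mm
    wm_series: np.ndarray | None = None
    csf_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise PreprocessError("data must be 4D (x, y, z, t)")
        if self.labels.shape != self.data.shape[:3]:
            raise PreprocessError("labels grid does not match data grid")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise PreprocessError("brain mask does not match data grid")
        if self.tr <= 0:
            raise PreprocessError("tr must be positive")
        if self.n_volumes < 1:
            raise PreprocessError("need at least one volume")
        self.brain_mask = self.brain_mask.astype(bool)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def replace(self, **kw) -> "LabeledVolume":
        return dataclasses.replace(self, **kw)


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters and relative displacement."""

    params: np.ndarray          # (t, 6): tx ty tz (mm), rx ry rz (rad)
    rel_displacement: np.ndarray  # (t,) mm, first volume 0

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.rel_displacement = np.asarray(self.rel_displacement, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise PreprocessError("motion params must be (t, 6)")
        if self.rel_displacement.shape != (self.params.shape[0],):
            raise PreprocessError("rel_displacement length must match params")
        if np.any(self.rel_displacement < 0):
            raise PreprocessError("rel_displacement must be nonnegative")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @classmethod
    def from_params(cls, params: np.ndarray) -> "MotionTrace":
        """Derive relative displacement from raw parameters.

        Translation Euclidean distance plus rotation arc length on a
        50 mm sphere, between consecutive volumes.
        """
        params = np.asarray(params, dtype=float)
        d = np.diff(params, axis=0)
        disp = np.zeros(params.shape[0])
        disp[1:] = (
            np.linalg.norm(d[:, :3], axis=1)
            + ROTATION_SPHERE_RADIUS_MM * np.linalg.norm(d[:, 3:], axis=1)
        )
        return cls(params, disp)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=MOTION_COLUMNS[:6])
        df["rel_disp"] = self.rel_displacement
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MotionTrace":
        params = df[MOTION_COLUMNS[:6]].to_numpy(dtype=float)
        if "rel_disp" in df.columns:
            return cls(params, df["rel_disp"].to_numpy(dtype=float))
        return cls.from_params(params)


@dataclass
class PreprocessReport:
    """Volume accounting for one subject through the preprocessing chain."""

    volumes_in: int
    volumes_trimmed: int = 0
    scrubbed_indices: list[int] = field(default_factory=list)
    excluded_subject: bool = False
    roi_overlap: dict[str, float] = field(default_factory=dict)

    @property
    def volumes_kept(self) -> int:
        return self.volumes_in - self.volumes_trimmed - len(self.scrubbed_indices)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["volumes_kept"] = self.volumes_kept
        return json.dumps(d, indent=1)


# ---------------------------------------------------------------------------
# operations


def trim_volumes(
    v: LabeledVolume,
    m: MotionTrace,
    max_volumes: int = 160,
    drop_first: int = 4,
) -> tuple[LabeledVolume, MotionTrace]:
    """Truncate to the first ``max_volumes`` volumes, then drop ``drop_first``.

    Acquisitions longer than ``max_volumes`` are cut so every series carries
    the same amount of information; the initial volumes are discarded to
    allow magnetization to reach steady state. The motion trace is trimmed
    in lockstep and the new first volume's relative displacement is reset
    to zero (it no longer has a predecessor).
    """
    t = v.n_volumes
    if m.n_volumes != t:
        raise PreprocessError("motion trace length does not match volume count")
    if t <= drop_first:
        raise PreprocessError(
            f"only {t} volumes; nothing remains after dropping the first {drop_first}"
        )
    stop = min(t, max_volumes)
    sl = slice(drop_first, stop)
    disp = m.rel_displacement[sl].copy()
    if disp.size:
        disp[0] = 0.0
    v2 = v.replace(
        data=v.data[..., sl],
        wm_series=None if v.wm_series is None else v.wm_series[sl],
        csf_series=None if v.csf_series is None else v.csf_series[sl],
    )
    return v2, MotionTrace(m.params[sl].copy(), disp)


def _dct_basis(t: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Intercept + DCT-II cosines with frequency below ``cutoff_hz``.

    Component k of a length-t DCT has frequency k / (2 t tr), so the basis
    spans exactly the sub-cutoff band.
    """
    k_max = int(np.floor(2 * t * tr * cutoff_hz))
    n = np.arange(t)
    cols = [np.ones(t)]
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * (n + 0.5) / t))
    return np.column_stack(cols)


def highpass_filter(v: LabeledVolume, cutoff_hz: float = 0.01) -> LabeledVolume:
    """Remove slow drifts below ``cutoff_hz`` from every voxel series.

    Implemented as regression against a discrete cosine drift basis
    (intercept plus all DCT components below the cutoff), so the series mean
    is removed exactly and there is no filter ringing.
    """
    t = v.n_volumes
    nyquist = 1.0 / (2.0 * v.tr)
    if cutoff_hz >= nyquist:
        raise PreprocessError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist {nyquist} Hz"
        )
    if t < 8:
        raise PreprocessError("need at least 8 volumes to high-pass filter")
    basis = _dct_basis(t, v.tr, cutoff_hz)
    flat = v.data.reshape(-1, t)
    coef, *_ = np.linalg.lstsq(basis, flat.T, rcond=None)
    resid = flat - (basis @ coef).T
    return v.replace(data=resid.reshape(v.data.shape))


def regress_confounds(
    v: LabeledVolume,
    m: MotionTrace,
    wm_series: np.ndarray | None = None,
    csf_series: np.ndarray | None = None,
) -> LabeledVolume:
    """Regress nuisance signals out of every voxel's time course.

    Design: intercept, the six motion parameters, mean white-matter signal,
    mean CSF signal. Each voxel series is replaced by its OLS residuals,
    which are exactly orthogonal to every retained regressor. Collinear
    columns are dropped with a warning rather than failing the fit.
    """
    t = v.n_volumes
    wm = v.wm_series if wm_series is None else np.asarray(wm_series, float)
    csf = v.csf_series if csf_series is None else np.asarray(csf_series, float)
    cols: list[np.ndarray] = [np.ones(t)]
    names = ["intercept"]
    if m.n_volumes != t:
        raise PreprocessError("motion trace length does not match volume count")
    for i in range(6):
        cols.append(m.params[:, i])
        names.append(MOTION_COLUMNS[i])
    for series, name in ((wm, "wm"), (csf, "csf")):
        if series is None:
            continue
        if series.shape != (t,):
            raise PreprocessError(f"{name} series length does not match volume count")
        cols.append(series)
        names.append(name)

    X = np.column_stack(cols)
    # drop collinear columns greedily, keeping earlier (protected) ones
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, keep + [j]])
        if r > rank:
            keep.append(j)
            rank = r
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        msg = f"dropping collinear confound columns: {dropped}"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        X = X[:, keep]

    flat = v.data.reshape(-1, t)
    coef, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    resid = flat - (X @ coef).T
    return v.replace(data=resid.reshape(v.data.shape))


def scrub(
    v: LabeledVolume,
    m: MotionTrace,
    threshold_mm: float = 0.5,
    min_volumes: int = 125,
) -> tuple[LabeledVolume, MotionTrace, PreprocessReport]:
    """Censor volumes whose relative displacement exceeds ``threshold_mm``.

    Surviving volumes are concatenated in their original order. A subject
    keeping fewer than ``min_volumes`` volumes is flagged for exclusion in
    the report (exclusion is an accounting decision, not an exception).
    """
    disp = m.rel_displacement
    keep = disp <= threshold_mm
    scrubbed = np.flatnonzero(~keep).tolist()
    disp_kept = disp[keep].copy()
    if disp_kept.size:
        disp_kept[0] = 0.0
    v2 = v.replace(
        data=v.data[..., keep],
        wm_series=None if v.wm_series is None else v.wm_series[keep],
        csf_series=None if v.csf_series is None else v.csf_series[keep],
    )
    m2 = MotionTrace(m.params[keep].copy(), disp_kept)
    report = PreprocessReport(
        volumes_in=v.n_volumes,
        scrubbed_indices=scrubbed,
        excluded_subject=int(keep.sum()) < min_volumes,
    )
    return v2, m2, report


def median_filter_3x3x3(v: LabeledVolume) -> LabeledVolume:
    """Mask-aware 3x3x3 spatial median filter, applied per volume.

    Each in-mask voxel is replaced by the median over its 3x3x3 neighborhood
    restricted to in-grid, in-mask voxels; out-of-mask voxels pass through
    untouched. At (3.4, 3.4, 4.0) mm voxels the full 27-voxel kernel covers
    about 1,248 mm^3.
    """
    mask = v.brain_mask
    nx, ny, nz, t = v.data.shape
    padded = np.full((nx + 2, ny + 2, nz + 2, t), np.nan)
    padded[1:-1, 1:-1, 1:-1, :] = np.where(mask[..., None], v.data, np.nan)
    stack = np.empty((27, nx, ny, nz, t))
    idx = 0
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                stack[idx] = padded[dx : dx + nx, dy : dy + ny, dz : dz + nz, :]
                idx += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighborhoods
        med = np.nanmedian(stack, axis=0)
    out = np.where(mask[..., None], med, v.data)
    return v.replace(data=out)


def kernel_volume_mm3(
    voxel_dims: Sequence[float] = (3.4, 3.4, 4.0), kernel_voxels: int = 27
) -> float:
    """Physical volume covered by the median-filter kernel."""
    dx, dy, dz = voxel_dims
    return float(kernel_voxels * dx * dy * dz)


def roi_overlap_filter(
    atlas: RegionAtlas,
    masks: Iterable[np.ndarray],
    mean_threshold: float = 0.90,
    manual_exclusions: Sequence[str] = SUSCEPTIBILITY_EXCLUDED_NAMES,
) -> tuple[list[str], dict[str, float]]:
    """Select regions by mean brain-mask overlap across subjects.

    For each subject, a region's overlap is |ROI ∩ mask| / |ROI|. Regions
    whose mean overlap across subjects falls below ``mean_threshold``, or
    whose name (or abbreviation) is listed in ``manual_exclusions``, are
    excluded. Returns (included region keys in atlas order, mean overlap per
    region key).
    """
    masks = [np.asarray(mk, dtype=bool) for mk in masks]
    if not masks:
        raise PreprocessError("need at least one subject brain mask")
    excluded_names = {s.lower() for s in manual_exclusions}
    overlaps: dict[str, float] = {}
    included: list[str] = []
    for region in atlas.regions:
        roi = atlas.label_volume == region.label
        n_roi = int(roi.sum())
        if n_roi == 0:
            raise PreprocessError(f"region {region.key} has no voxels")
        per_subject = [float((roi & mk).sum()) / n_roi for mk in masks]
        mean_ov = float(np.mean(per_subject))
        overlaps[region.key] = mean_ov
        manual = (
            region.name.lower() in excluded_names
            or region.abbreviation.lower() in excluded_names
        )
        if mean_ov >= mean_threshold and not manual:
            included.append(region.key)
    return included, overlaps


# ---------------------------------------------------------------------------
# file I/O


def save_labeled_volume(v: LabeledVolume, prefix: Path) -> dict[str, Path]:
    """Write data/labels/mask as NIfTI (and confounds TSV) under a prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*v.voxel_dims, 1.0])
    paths = {
        "data": prefix.with_suffix(".nii"),
        "labels": prefix.parent / (prefix.name + "_labels.nii"),
        "mask": prefix.parent / (prefix.name + "_mask.nii"),
    }
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), paths["data"])
    nib.save(nib.Nifti1Image(v.labels.astype(np.int32), affine), paths["labels"])
    nib.save(
        nib.Nifti1Image(v.brain_mask.astype(np.uint8), affine), paths["mask"]
    )
    if v.wm_series is not None:
        paths["confounds"] = prefix.parent / (prefix.name + "_confounds.tsv")
        pd.DataFrame({"wm": v.wm_series, "csf": v.csf_series}).to_csv(
            paths["confounds"], sep="\t", index=False
        )
    return paths


def load_labeled_volume(
    data_path: Path,
    labels_path: Path,
    mask_path: Path,
    tr: float,
    confounds_path: Path | None = None,
) -> LabeledVolume:
    img = nib.load(str(data_path))
    labels = np.asarray(nib.load(str(labels_path)).dataobj).astype(np.int32)
    mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
    zooms = img.header.get_zooms()[:3]
    wm = csf = None
    if confounds_path is not None and Path(confounds_path).exists():
        conf = pd.read_csv(confounds_path, sep="\t")
        wm = conf["wm"].to_numpy(float)
        csf = conf["csf"].to_numpy(float)
    return LabeledVolume(
        data=np.asarray(img.dataobj).astype(np.float64),
        labels=labels,
        brain_mask=mask,
        tr=tr,
        voxel_dims=tuple(float(z) for z in zooms),
        wm_series=wm,
        csf_series=csf,
    )


def save_motion(m: MotionTrace, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.to_frame().to_csv(path, sep="\t", index=False)


def load_motion(path: Path) -> MotionTrace:
    return MotionTrace.from_frame(pd.read_csv(path, sep="\t"))
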