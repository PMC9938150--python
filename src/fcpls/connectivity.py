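"""Motion QC, temporal filtering and seed-to-voxel Fisher-z connectivity.

Head motion is summarized per subject by Power-style framewise displacement
(sum of absolute backward differences of the six rigid-body parameters,
rotations converted to arc length on a 50 mm sphere).  Subjects are
excluded when mean FD exceeds 0.3 mm or any translation/rotation exceeds
3 mm / 3 degrees.  Time series are linearly detrended and band-passed to
0.01-0.08 Hz with a hard frequency-domain mask, then each seed's mean
series is correlated with every grey-matter voxel and the Pearson r is
Fisher z-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import GreyMatterMask, VoxelIndexMap

__all__ = [
    "BoldRun",
    "MotionSummary",
    "FCMapStack",
    "framewise_displacement",
    "motion_summary",
    "qc_filter",
    "bandpass",
    "fisher_z",
    "seed_fc_map",
    "stack_maps",
    "load_motion_params",
]

#: radius (mm) of the sphere used to convert rotations to displacements
DEFAULT_SPHERE_RADIUS_MM = 50.0
#: exclusion limits: mean FD (mm), max |translation| (mm), max |rotation| (deg)
FD_LIMIT_MM = 0.3
TRANSLATION_LIMIT_MM = 3.0
ROTATION_LIMIT_DEG = 3.0

R_CLIP = 1.0 - 1e-7  # keeps atanh finite for degenerate voxels


@dataclass
class BoldRun:
    """One subject's 4D BOLD-like run plus rigid-body motion parameters."""

    data: np.ndarray  # (x, y, z, t)
    tr_seconds: float
    motion_params: np.ndarray  # (t, 6): 3 translations mm, 3 rotations rad
    subject_id: str
    group: str = ""
    site: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.motion_params = np.asarray(self.motion_params, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.n_frames < 2:
            raise ValueError("a run needs at least 2 frames")
        if not np.isfinite(self.data).all():
            raise ValueError(f"non-finite values in BOLD data for {self.subject_id}")
        if self.motion_params.shape != (self.n_frames, 6):
            raise ValueError("motion parameters must be (n_frames, 6)")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_frames(self):
        return self.data.shape[-1]


@dataclass
class MotionSummary:
    subject_id: str
    fd_series: np.ndarray  # length t-1, mm
    mean_fd: float
    max_abs_translation_mm: float
    max_abs_rotation_deg: float
    excluded: bool
    reasons: list


def framewise_displacement(motion_params, sphere_radius_mm=DEFAULT_SPHERE_RADIUS_MM):
    """Power FD: FD_k = sum |d trans| + radius * sum |d rot| (mm), frame k vs k-1."""
    motion_params = np.asarray(motion_params, dtype=np.float64)
    if motion_params.ndim != 2 or motion_params.shape[1] != 6:
        raise ValueError("motion parameters must be (n_frames, 6)")
    if motion_params.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if sphere_radius_mm <= 0:
        raise ValueError("sphere radius must be positive")
    d = np.abs(np.diff(motion_params, axis=0))
    return d[:, :3].sum(axis=1) + sphere_radius_mm * d[:, 3:].sum(axis=1)


def motion_summary(run: BoldRun, *, fd_limit_mm=FD_LIMIT_MM,
                   translation_limit_mm=TRANSLATION_LIMIT_MM,
                   rotation_limit_deg=ROTATION_LIMIT_DEG,
                   sphere_radius_mm=DEFAULT_SPHERE_RADIUS_MM) -> MotionSummary:
    """Summarize motion and apply the exclusion rule (all comparisons strict >)."""
    fd = framewise_displacement(run.motion_params, sphere_radius_mm)
    mean_fd = float(fd.mean())
    max_trans = float(np.abs(run.motion_params[:, :3]).max())
    max_rot = float(np.degrees(np.abs(run.motion_params[:, 3:]).max()))
    reasons = []
    if mean_fd > fd_limit_mm:
        reasons.append(f"mean FD {mean_fd:.3f} mm > {fd_limit_mm} mm")
    if max_trans > translation_limit_mm:
        reasons.append(f"max translation {max_trans:.2f} mm > {translation_limit_mm} mm")
    if max_rot > rotation_limit_deg:
        reasons.append(f"max rotation {max_rot:.2f} deg > {rotation_limit_deg} deg")
    return MotionSummary(run.subject_id, fd, mean_fd, max_trans, max_rot,
                         excluded=bool(reasons), reasons=reasons)


def qc_filter(runs, **limits):
    """Split runs into kept and excluded; returns ``(kept, report)``.

    ``report`` is a list of dicts, one per subject, carrying the motion
    summary numbers and the triggered rules for excluded subjects.
    """
    if not runs:
        raise ValueError("qc_filter needs at least one run")
    kept, report = [], []
    for run in runs:
        ms = motion_summary(run, **limits)
        report.append({
            "subject_id": run.subject_id,
            "mean_fd_mm": ms.mean_fd,
            "max_abs_translation_mm": ms.max_abs_translation_mm,
            "max_abs_rotation_deg": ms.max_abs_rotation_deg,
            "excluded": ms.excluded,
            "reasons": ms.reasons,
        })
        if not ms.excluded:
            kept.append(run)
    return kept, report


def bandpass(ts, tr_seconds, f_low=0.01, f_high=0.08):
    """Linear detrend + ideal band-pass via the discrete Fourier transform.

    Operates along the last axis.  Frequency bins with ``f_low <= f <=
    f_high`` are kept (the zero-frequency bin never survives because the
    detrend removes the mean).  Constant series come back as zeros with a
    warning rather than an error so degenerate voxels flow through.
    """
    ts = np.asarray(ts, dtype=np.float64)
    t = ts.shape[-1]
    if t < 8:
        raise ValueError("need at least 8 frames to band-pass filter")
    nyquist = 0.5 / tr_seconds
    if not 0 < f_low < f_high < nyquist:
        raise ValueError(
            f"band [{f_low}, {f_high}] Hz must satisfy 0 < low < high < Nyquist ({nyquist:.3g} Hz)"
        )
    flat = np.ptp(ts, axis=-1) == 0
    if np.any(flat):
        warnings.warn("constant time series returned as zeros", stacklevel=2)
    from scipy.signal import detrend

    detrended = detrend(ts, axis=-1, type="linear")
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    keep = (freqs >= f_low) & (freqs <= f_high)
    spec = np.fft.rfft(detrended, axis=-1)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=-1)
    if np.any(flat):
        out[flat] = 0.0
    return out


def fisher_z(r):
    """Fisher r-to-z with |r| clipped to 1 - 1e-7 so z stays finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _correlate_with_seed(seed_ts, voxel_ts):
    """Pearson r of ``seed_ts`` (t,) against each row of ``voxel_ts`` (v, t)."""
    seed = seed_ts - seed_ts.mean()
    seed_norm = np.sqrt((seed**2).sum())
    if seed_norm == 0:
        raise ValueError("seed mean time series has zero variance")
    vox = voxel_ts - voxel_ts.mean(axis=-1, keepdims=True)
    vox_norm = np.sqrt((vox**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vox @ seed) / (vox_norm * seed_norm)
    r[~np.isfinite(r)] = 0.0  # zero-variance voxels -> r = 0
    return r


def seed_fc_map(run: BoldRun, seed_mask, gm: GreyMatterMask | VoxelIndexMap,
                *, filtered=None):
    """One subject's seed-to-voxel Fisher-z map over the grey-matter mask.

    ``filtered`` may carry the already band-passed (n_gm_voxels, t) series
    so several seeds can share one filtering pass; otherwise the raw run
    data are used as-is (filtering is the caller's responsibility).
    Returns a 1D vector ordered by the grey-matter index map.
    """
    index = gm if isinstance(gm, VoxelIndexMap) else VoxelIndexMap(gm.mask)
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != run.data.shape[:3]:
        raise ValueError("seed mask grid does not match the run")
    if not seed_mask.any():
        raise ValueError("seed mask is empty on this grid")
    seed_ts = run.data[seed_mask].mean(axis=0)
    voxel_ts = filtered if filtered is not None else index.vectorize(run.data)
    r = _correlate_with_seed(seed_ts, voxel_ts)
    return fisher_z(r)


@dataclass
class FCMapStack:
    """Subjects x in-mask-voxels Fisher-z values for one seed."""

    seed_name: str
    subjects: list
    values: np.ndarray  # (n_subjects, n_voxels)
    index_map: VoxelIndexMap
    site: np.ndarray
    group: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.site = np.asarray(self.site)
        self.group = np.asarray(self.group)
        n = len(self.subjects)
        if self.values.shape[0] != n or len(self.site) != n or len(self.group) != n:
            raise ValueError("row/label counts do not match the subject list")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite connectivity values in stack")

    @property
    def n_subjects(self):
        return len(self.subjects)

    @property
    def n_voxels(self):
        return self.values.shape[1]

    def rows_for_group(self, group):
        return self.values[self.group == group]

    def subset(self, row_mask):
        """New stack keeping only subjects where ``row_mask`` is True."""
        row_mask = np.asarray(row_mask, dtype=bool)
        return FCMapStack(self.seed_name,
                          [s for s, k in zip(self.subjects, row_mask) if k],
                          self.values[row_mask], self.index_map,
                          self.site[row_mask], self.group[row_mask])


def stack_maps(rows, subject_table: pd.DataFrame, index_map: VoxelIndexMap,
               seed_name="seed") -> FCMapStack:
    """Assemble per-subject map vectors into a stack ordered like the table.

    ``rows`` maps subject_id -> 1D Fisher-z vector.  The subject table must
    provide ``subject_id``, ``group`` and ``site`` columns with no
    duplicates or missing labels.
    """
    if subject_table["subject_id"].duplicated().any():
        raise ValueError("duplicate subject id in the subject table")
    for col in ("group", "site"):
        if subject_table[col].isna().any() or (subject_table[col] == "").any():
            raise ValueError(f"missing {col} label in the subject table")
    ordered = []
    for sid in subject_table["subject_id"]:
        if sid not in rows:
            raise ValueError(f"no connectivity map for subject {sid}")
        vec = np.asarray(rows[sid], dtype=np.float64)
        if vec.shape != (index_map.n_voxels,):
            raise ValueError(f"map for {sid} does not match the voxel index map")
        ordered.append(vec)
    return FCMapStack(seed_name=seed_name,
                      subjects=list(subject_table["subject_id"]),
                      values=np.vstack(ordered), index_map=index_map,
                      site=subject_table["site"].to_numpy(),
                      group=subject_table["group"].to_numpy())


def load_motion_params(path, n_frames=None):
    """Read whitespace-delimited motion parameters (t rows x 6 columns)."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion file must have 6 columns: {path}")
    if n_frames is not None and arr.shape[0] != n_frames:
        raise ValueError(f"motion file row count {arr.shape[0]} != n_frames {n_frames}: {path}")
    return arr
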