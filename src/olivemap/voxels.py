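"""Voxelwise analysis of volumetric response stacks.

Light-sheet style analysis: select labeled voxels with a brightness
threshold, compute per-stimulus repetition-averaged dF/F0 responses per
voxel, categorize voxels by selectivity with fixed response thresholds,
and build 2D projection count maps.

Category thresholds (dF/F0): forward-selective voxels need cos(PD) > 0
and a mean > 0.5 over the three forward-component stimuli; backward
needs cos(PD) < 0 and > 0.25 over the three backward stimuli (backward
responses are weaker); rotation-selective voxels respond > 0.75 to one
rotational direction and < 0.25 to the other; left/right selectivity
uses > 0.25 over the two stimuli with a left or right component, grouped
by the stronger side. All comparisons are strict.

Volumes are indexed (z, y, x) = (dorso-ventral, rostro-caudal,
left-right) in the registered frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .protocol import StimulusEpoch, TRANSLATION, ROTATION
from .tuning import vector_sum_dsi

__all__ = [
    "VoxelCategoryConfig",
    "ResponseVolume",
    "VoxelMaps",
    "label_voxels",
    "voxel_responses",
    "voxel_pd",
    "categorize_voxels",
    "project_map",
    "percentile_partition",
    "build_voxel_maps",
]

log = logging.getLogger(__name__)

FORWARD_DIRS = (315.0, 0.0, 45.0)     # the three forward-component stimuli
BACKWARD_DIRS = (135.0, 180.0, 225.0)
LEFT_DIRS = (270.0, 315.0)            # left and forward-left
RIGHT_DIRS = (90.0, 45.0)             # right and forward-right


@dataclass
class VoxelCategoryConfig:
    """Selectivity thresholds (dF/F0) and the brightness offset (gray values)."""

    forward_thresh: float = 0.5
    backward_thresh: float = 0.25
    rot_high: float = 0.75
    rot_low: float = 0.25
    lr_thresh: float = 0.25
    brightness_offset: float = 2.0

    def __post_init__(self) -> None:
        if self.rot_high <= self.rot_low:
            raise ValueError("rot_high must exceed rot_low")
        for name in ("forward_thresh", "backward_thresh", "rot_high",
                     "rot_low", "lr_thresh", "brightness_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ResponseVolume:
    """Per-stimulus, per-repetition response stacks plus raw brightness.

    ``responses`` has shape (n_stimuli, n_repetitions, nz, ny, nx) in
    dF/F0 units; ``brightness`` is the time-averaged raw volume (camera
    gray values). ``epochs`` carries one epoch per stimulus axis entry.
    ``origin_um`` is the physical coordinate (dv, rc, lr) of voxel
    (0, 0, 0); voxels are isotropic with pitch ``voxel_size_um``.
    """

    responses: np.ndarray
    brightness: np.ndarray
    epochs: list[StimulusEpoch]
    voxel_size_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.brightness = np.asarray(self.brightness, dtype=float)
        if self.responses.ndim != 5:
            raise ValueError("responses must be (n_stim, n_rep, nz, ny, nx)")
        if self.responses.shape[0] != len(self.epochs):
            raise ValueError("one epoch per stimulus axis entry required")
        if self.responses.shape[2:] != self.brightness.shape:
            raise ValueError("brightness grid must match response grid")

    def voxel_index(self, point_um) -> tuple[int, int, int]:
        """Nearest voxel index of a physical (rc, lr, dv) point."""
        rc, lr, dv = np.asarray(point_um, dtype=float)
        idx = np.round((np.array([dv, rc, lr]) - self.origin_um)
                       / self.voxel_size_um).astype(int)
        return tuple(idx)


def label_voxels(brightness: np.ndarray, background: float,
                 offset: float = 2.0) -> np.ndarray:
    """Mask of labeled voxels: mean brightness strictly above background + offset."""
    brightness = np.asarray(brightness, dtype=float)
    if not np.all(np.isfinite(brightness)):
        raise ValueError("brightness volume must be finite")
    return brightness > background + offset


def voxel_responses(data, epochs: list[StimulusEpoch] | None = None) -> np.ndarray:
    """Per-stimulus repetition-averaged dF/F0 volume.

    Accepts either per-stimulus/per-repetition response stacks
    (``ResponseVolume`` or an (n_stim, n_rep, ...) array; repetitions are
    averaged) or a raw 4D movie (t, nz, ny, nx) together with the epoch
    list, in which case per-stimulus responses are computed from the
    phase windows: F = mean over moving frames, F0 = mean over the
    initial stationary frames, response = (F - F0) / F0.
    """
    if isinstance(data, ResponseVolume):
        return data.responses.mean(axis=1)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 5:
        return arr.mean(axis=1)
    if arr.ndim != 4:
        raise ValueError("expected 5D stacks or a 4D movie")
    if epochs is None:
        raise ValueError("a 4D movie requires the epoch list")
    total = sum(e.n_frames for e in epochs)
    if arr.shape[0] < total:
        raise ValueError("stimulus windows extend beyond the recording")
    out, t = [], 0
    for e in epochs:
        f0 = arr[t:t + e.n_frames_pre].mean(axis=0)
        f = arr[t + e.n_frames_pre:t + e.n_frames_pre + e.n_frames_move].mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out.append((f - f0) / f0)
        t += e.n_frames
    return np.stack(out)


def _direction_mean(mean_responses: np.ndarray, epochs: list[StimulusEpoch],
                    directions) -> np.ndarray:
    idx = [i for i, e in enumerate(epochs)
           if e.kind == TRANSLATION and (e.direction_deg % 360.0) in
           {d % 360.0 for d in directions}]
    if not idx:
        raise ValueError(f"no stimuli at directions {directions}")
    return mean_responses[idx].mean(axis=0)


def voxel_pd(mean_responses: np.ndarray,
             epochs: list[StimulusEpoch]) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise DSI and PD by the rectified vector sum over the 8 directions."""
    idx = [i for i, e in enumerate(epochs) if e.kind == TRANSLATION]
    dirs = np.array([epochs[i].direction_deg for i in idx])
    stack = np.moveaxis(mean_responses[idx], 0, -1)  # (..., 8)
    return vector_sum_dsi(stack, dirs)


def _rotation_volume(mean_responses, epochs, label):
    for i, e in enumerate(epochs):
        if e.kind == ROTATION and e.rotation_label == label:
            return mean_responses[i]
    return None


def categorize_voxels(mean_responses: np.ndarray, epochs: list[StimulusEpoch],
                      mask: np.ndarray,
                      config: VoxelCategoryConfig | None = None,
                      pd_deg: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Boolean selectivity volumes {forward, backward, cw_rot, ccw_rot,
    leftward, rightward}, all restricted to the labeled-voxel mask."""
    config = config or VoxelCategoryConfig()
    if pd_deg is None:
        _, pd_deg = voxel_pd(mean_responses, epochs)
    cos_pd = np.cos(np.deg2rad(pd_deg))

    fwd = _direction_mean(mean_responses, epochs, FORWARD_DIRS)
    bwd = _direction_mean(mean_responses, epochs, BACKWARD_DIRS)
    out = {
        "forward": mask & (cos_pd > 0) & (fwd > config.forward_thresh),
        "backward": mask & (cos_pd < 0) & (bwd > config.backward_thresh),
    }

    cw = _rotation_volume(mean_responses, epochs, "CW")
    ccw = _rotation_volume(mean_responses, epochs, "CCW")
    zeros = np.zeros_like(mask, dtype=bool)
    if cw is not None and ccw is not None:
        out["cw_rot"] = mask & (cw > config.rot_high) & (ccw < config.rot_low)
        out["ccw_rot"] = mask & (ccw > config.rot_high) & (cw < config.rot_low)
    else:
        out["cw_rot"], out["ccw_rot"] = zeros.copy(), zeros.copy()

    lmean = _direction_mean(mean_responses, epochs, LEFT_DIRS)
    rmean = _direction_mean(mean_responses, epochs, RIGHT_DIRS)
    eligible = mask & ((lmean > config.lr_thresh) | (rmean > config.lr_thresh))
    out["leftward"] = eligible & (lmean > rmean)
    out["rightward"] = eligible & (rmean > lmean)
    n_tied = int((eligible & (lmean == rmean)).sum())
    if n_tied:
        log.info("categorize_voxels: %d voxels tied left/right, unassigned",
                 n_tied)
    return out


def project_map(volume: np.ndarray, axis: int = 0, split_halves: bool = False,
                split_index: int | None = None) -> np.ndarray:
    """Per-pixel count of category voxels along one axis.

    With ``split_halves`` the two halves of the image along its first
    axis (by default at the midline) are normalized independently to
    their own maxima; an all-zero half stays at zero. The anatomical
    split between projection (top) and soma (bottom) territory is
    configurable via ``split_index``.
    """
    volume = np.asarray(volume)
    if volume.size == 0:
        raise ValueError("empty volume")
    img = volume.sum(axis=axis).astype(float)
    if not split_halves:
        return img
    s = img.shape[0] // 2 if split_index is None else split_index
    out = img.copy()
    for half in (out[:s], out[s:]):
        m = half.max() if half.size else 0.0
        if m > 0:
            half /= m
    return out


def percentile_partition(values, cuts=(95.0, 99.0)) -> dict[str, np.ndarray]:
    """Split values into top 1%, next 4%, and the remaining 95%.

    Thresholds are the empirical percentiles at ``cuts`` computed with
    the Weibull plotting position (ranks i/(n+1)); membership is by
    strict exceedance, so ties at the threshold fall into the lower
    group. Returns boolean masks {"top", "middle", "rest"}.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    lo_cut, hi_cut = sorted(cuts)
    lo = np.quantile(values, lo_cut / 100.0, method="weibull")
    hi = np.quantile(values, hi_cut / 100.0, method="weibull")
    top = values > hi
    middle = (values > lo) & ~top
    return {"top": top, "middle": middle, "rest": ~(top | middle)}


@dataclass
class VoxelMaps:
    """Bundle of voxelwise analysis outputs."""

    mean_responses: np.ndarray
    mask: np.ndarray
    pd_deg: np.ndarray
    dsi: np.ndarray
    categories: dict[str, np.ndarray]
    projections: dict[str, np.ndarray]


def build_voxel_maps(volume: ResponseVolume,
                     config: VoxelCategoryConfig | None = None,
                     background: float | None = None,
                     split_halves: bool = True) -> VoxelMaps:
    """Full voxel chain: label, respond, categorize, project.

    ``background`` defaults to the median brightness of the volume (a
    robust stand-in for the manual background estimate).
    """
    config = config or VoxelCategoryConfig()
    if background is None:
        background = float(np.median(volume.brightness))
    mask = label_voxels(volume.brightness, background, config.brightness_offset)
    mean = voxel_responses(volume)
    dsi, pd_deg = voxel_pd(mean, volume.epochs)
    cats = categorize_voxels(mean, volume.epochs, mask, config, pd_deg=pd_deg)
    projections = {name: project_map(vol, axis=0, split_halves=split_halves)
                   for name, vol in cats.items()}
    return VoxelMaps(mean_responses=mean, mask=mask, pd_deg=pd_deg, dsi=dsi,
                     categories=cats, projections=projections)
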