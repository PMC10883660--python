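"""Direction selectivity: vector-sum DSI, shuffle test, rotation classes.

The direction selectivity index (DSI) of a neuron is the magnitude of the
vector sum of its mean responses to the eight translational directions,
divided by the scalar sum of those responses. A neuron responding to a
single direction has DSI 1; equal responses in all directions give DSI 0.
The preferred direction (PD) is the angle of the summed vector
(0 deg forward, 90 deg rightward, negative angles leftward).

Negative mean responses are rectified to zero before the vector sum; this
guarantees DSI in [0, 1] and the single-stimulus DSI = 1 anchor.

Significance is assessed with a label-shuffling test: direction labels are
permuted across individual presentations 1,000 times, the DSI recomputed
each time, and the neuron called direction selective when its observed DSI
strictly exceeds the 95th percentile of that null distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol, TRANSLATION
from .responses import NeuronRecord, ResponseTable, presentation_responses

__all__ = [
    "UndefinedTuningError",
    "TuningResult",
    "ShuffleTestResult",
    "compute_dsi",
    "shuffle_test",
    "classify_rotation",
    "pd_cosine_split",
    "tuning_analysis",
]

log = logging.getLogger(__name__)

ROTATION_CLASSES = ("DS", "DS+CW", "DS+CCW", "DS+CW+CCW", "none")


class UndefinedTuningError(ValueError):
    """All responses non-positive after rectification: DSI is undefined."""


def vector_sum_dsi(means: np.ndarray, directions_deg: np.ndarray):
    """Vectorized rectified vector-sum DSI and PD over the last axis.

    Entries whose rectified responses sum to zero yield NaN.
    """
    r = np.maximum(np.asarray(means, dtype=float), 0.0)
    th = np.deg2rad(np.asarray(directions_deg, dtype=float))
    fwd = (r * np.cos(th)).sum(axis=-1)
    rgt = (r * np.sin(th)).sum(axis=-1)
    tot = r.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dsi = np.where(tot > 0, np.hypot(fwd, rgt) / np.where(tot > 0, tot, 1.0),
                       np.nan)
    pd_deg = np.degrees(np.arctan2(rgt, fwd))
    pd_deg = np.where(tot > 0, pd_deg, np.nan)
    return dsi, pd_deg


def _check_eight_directions(directions_deg: np.ndarray) -> None:
    d = np.sort(np.asarray(directions_deg, dtype=float) % 360.0)
    if d.shape != (8,) or not np.allclose(d, np.arange(0.0, 360.0, 45.0)):
        raise ValueError("exactly 8 responses at 45-degree spacing required")


def compute_dsi(directions_deg, responses) -> tuple[float, float]:
    """DSI and preferred direction from 8 direction-labeled mean responses.

    Raises :class:`UndefinedTuningError` when every response is <= 0 after
    rectification (such neurons are excluded from the DS analysis).
    """
    directions_deg = np.asarray(directions_deg, dtype=float)
    responses = np.asarray(responses, dtype=float)
    _check_eight_directions(directions_deg)
    if responses.shape != (8,):
        raise ValueError("responses must have shape (8,)")
    dsi, pd_deg = vector_sum_dsi(responses, directions_deg)
    if np.isnan(dsi):
        raise UndefinedTuningError("all responses non-positive")
    return float(dsi), float(pd_deg)


@dataclass
class ShuffleTestResult:
    dsi: float
    pd_deg: float
    is_direction_selective: bool
    null_dsi: np.ndarray
    threshold: float


def shuffle_test(responses, direction_labels_deg, n_shuffles: int = 1000,
                 alpha: float = 0.05, seed=None) -> ShuffleTestResult:
    """Label-permutation test of direction selectivity.

    ``responses`` are per-presentation moving-period responses (one entry
    per repetition of each direction); ``direction_labels_deg`` are their
    direction labels. Each shuffle permutes the labels across all
    presentations, recomputes repetition means per direction, and
    recomputes the DSI. The verdict compares the observed DSI strictly
    against the empirical (1 - alpha) quantile of the null (linear
    interpolation). Deterministic given ``seed``.

    With fewer than two distinct response values the null is degenerate
    and the verdict is False with a warning.
    """
    responses = np.asarray(responses, dtype=float)
    labels = np.asarray(direction_labels_deg, dtype=float) % 360.0
    if responses.ndim != 1 or responses.shape != labels.shape:
        raise ValueError("responses and labels must be 1-D and equal length")
    uniq, inv, counts = np.unique(labels, return_inverse=True,
                                  return_counts=True)
    _check_eight_directions(uniq)
    if counts.min() < 1:
        raise ValueError("at least one presentation per direction required")

    # observed: repetition means per direction, then vector sum
    obs_means = np.bincount(inv, weights=responses) / counts
    obs_dsi, obs_pd = vector_sum_dsi(obs_means, uniq)
    if np.isnan(obs_dsi):
        raise UndefinedTuningError("all responses non-positive")

    if np.unique(responses).size < 2:
        warnings.warn("degenerate null: fewer than 2 distinct response values",
                      stacklevel=2)
        null = np.full(n_shuffles, float(obs_dsi))
        return ShuffleTestResult(float(obs_dsi), float(obs_pd), False, null,
                                 float(obs_dsi))

    rng = np.random.default_rng(seed)
    # permuting responses against a fixed label layout == permuting labels
    order = np.argsort(rng.random((n_shuffles, responses.size)), axis=1)
    shuffled = responses[order]
    # a uniformly random row permutation makes any contiguous split into
    # groups of the original sizes a uniformly random label assignment
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    null_means = np.add.reduceat(shuffled, starts, axis=1) / counts
    null_dsi, _ = vector_sum_dsi(null_means, uniq)
    # same multiset of responses in every shuffle: null defined iff observed is
    threshold = float(np.quantile(null_dsi, 1.0 - alpha))
    return ShuffleTestResult(float(obs_dsi), float(obs_pd),
                             bool(obs_dsi > threshold), null_dsi, threshold)


@dataclass
class TuningResult:
    """Per-neuron direction-tuning summary."""

    neuron_id: str
    dsi: float
    pd_deg: float
    is_direction_selective: bool
    rotation_class: str = "none"
    null_dsi: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self) -> None:
        if not (np.isnan(self.dsi) or 0.0 <= self.dsi <= 1.0 + 1e-12):
            raise ValueError("dsi must lie in [0, 1]")
        if self.rotation_class not in ROTATION_CLASSES:
            raise ValueError(f"unknown rotation class {self.rotation_class!r}")
        if self.rotation_class != "none" and not self.is_direction_selective:
            raise ValueError("rotation class requires direction selectivity")


def classify_rotation(is_direction_selective: bool, responding_cw: bool,
                      responding_ccw: bool) -> str:
    """Four rotation-response classes of direction-selective neurons."""
    if not is_direction_selective:
        return "none"
    if responding_cw and responding_ccw:
        return "DS+CW+CCW"
    if responding_cw:
        return "DS+CW"
    if responding_ccw:
        return "DS+CCW"
    return "DS"


def pd_cosine_split(pd_deg) -> dict[str, np.ndarray]:
    """Split direction-selective PDs into forward / backward by cos(PD) sign.

    cos(PD) == 0 (exactly sideways) belongs to neither group; such
    measure-zero cases are logged and dropped.
    """
    pd_deg = np.asarray(pd_deg, dtype=float)
    c = np.cos(np.deg2rad(pd_deg))
    boundary = np.isclose(c, 0.0)
    if boundary.any():
        log.info("pd_cosine_split: %d PD(s) exactly sideways, assigned to "
                 "neither group", int(boundary.sum()))
    return {"forward": np.flatnonzero((c > 0) & ~boundary),
            "backward": np.flatnonzero((c < 0) & ~boundary)}


def tuning_analysis(neurons: list[NeuronRecord], protocol: StimulusProtocol,
                    table: ResponseTable, eye: str = "both",
                    n_shuffles: int = 1000, alpha: float = 0.05,
                    seed=None) -> pd.DataFrame:
    """DSI, PD, shuffle verdict and rotation class for every active neuron.

    Returns one row per neuron with NaN tuning fields for neurons whose
    rectified responses are all zero (undefined tuning, logged).
    """
    rng = np.random.default_rng(seed)
    trans_idx = protocol.indices(eye=eye, kind=TRANSLATION)
    active = table.active(eye=eye)
    rows = []
    for neuron in neurons:
        if not bool(active.get(neuron.id, False)):
            rows.append(dict(neuron_id=neuron.id, active=False, dsi=np.nan,
                             pd_deg=np.nan, selective=False,
                             rotation_class="none"))
            continue
        resp, labels = [], []
        for si in trans_idx:
            pr = presentation_responses(neuron, protocol, si)
            resp.append(pr)
            labels.append(np.full(pr.size, protocol[si].direction_deg))
        resp = np.concatenate(resp)
        labels = np.concatenate(labels)
        try:
            res = shuffle_test(resp, labels, n_shuffles=n_shuffles,
                               alpha=alpha, seed=rng.integers(2**31))
        except UndefinedTuningError:
            log.info("neuron %s: undefined tuning, excluded from DS analysis",
                     neuron.id)
            rows.append(dict(neuron_id=neuron.id, active=True, dsi=np.nan,
                             pd_deg=np.nan, selective=False,
                             rotation_class="none"))
            continue
        flags = table.rotation_flags(neuron.id, eye=eye)
        rows.append(dict(
            neuron_id=neuron.id, active=True, dsi=res.dsi, pd_deg=res.pd_deg,
            selective=res.is_direction_selective,
            rotation_class=classify_rotation(res.is_direction_selective,
                                             flags.get("CW", False),
                                             flags.get("CCW", False))))
    return pd.DataFrame(rows)
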