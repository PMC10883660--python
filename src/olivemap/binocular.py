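"""Monocular input quantification and per-eye direction tuning.

The monocular index of a neuron is the difference between its responses
to contralateral-eye and ipsilateral-eye stimulation (averaged across
repetitions and the eight translational directions; rotation stimuli
carry no direction label and are excluded), divided by their sum:
-1 marks an ipsi-monocular neuron, 0 a balanced binocular one, +1 a
contra-monocular one.

Per-eye tuning applies the DSI/PD machinery and the shuffle test
independently to the left-eye, right-eye and binocular stimulation
blocks; a neuron may be direction selective in one block only. Neurons
selective in both monocular blocks are grouped by the quadrant of
(cos PD_left, cos PD_right) signs: same-sign quadrants hold neurons with
similar per-eye tuning, the two opposite-sign quadrants hold the
rotation-type neurons with opposing per-eye preferred directions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol, TRANSLATION
from .responses import NeuronRecord, ResponseTable, presentation_responses
from .tuning import UndefinedTuningError, shuffle_test

__all__ = [
    "MonocularResult",
    "monocular_index",
    "per_eye_tuning",
    "quadrant_group",
    "binocular_analysis",
]

log = logging.getLogger(__name__)

QUADRANT_GROUPS = ("both_forward", "both_backward",
                   "left_forward_right_backward",
                   "right_forward_left_backward", "unclassified")


@dataclass
class MonocularResult:
    """Per-neuron monocular integration summary.

    PD fields are NaN when the neuron is not direction selective in that
    block. ``opposing`` is True when the cosine signs of the two
    monocular PDs differ (both defined).
    """

    neuron_id: str
    monocular_index: float
    pd_left_deg: float
    pd_right_deg: float
    pd_binocular_deg: float
    selective_left: bool
    selective_right: bool
    selective_binocular: bool
    opposing: bool
    quadrant_group: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.monocular_index)
                or -1.0 <= self.monocular_index <= 1.0):
            raise ValueError("monocular_index must lie in [-1, 1]")
        if self.quadrant_group not in QUADRANT_GROUPS:
            raise ValueError(f"unknown quadrant group {self.quadrant_group!r}")


def monocular_index(contra_responses, ipsi_responses) -> float:
    """(mean_contra - mean_ipsi) / (mean_contra + mean_ipsi).

    Both inputs must cover the same stimulus subset. A zero denominator
    leaves the index undefined (NaN, logged); such neurons are excluded
    rather than assigned 0. Negative window means are kept as-is.
    """
    contra = np.asarray(contra_responses, dtype=float)
    ipsi = np.asarray(ipsi_responses, dtype=float)
    if contra.size == 0 or ipsi.size == 0:
        raise ValueError("both response sets must be non-empty")
    mc, mi = contra.mean(), ipsi.mean()
    denom = mc + mi
    if denom <= 0:
        # unresponsive to both eyes: the index is undefined, not 0
        log.info("monocular index undefined (non-positive denominator); "
                 "excluded")
        return float("nan")
    # a slightly negative noise-only mean can push the ratio past +-1;
    # clip back onto the index's defined range
    return float(np.clip((mc - mi) / denom, -1.0, 1.0))


def _cos_sign(pd_deg: float) -> int:
    c = math.cos(math.radians(pd_deg))
    if math.isclose(c, 0.0, abs_tol=1e-12):
        return 0
    return 1 if c > 0 else -1


def quadrant_group(pd_left_deg: float, pd_right_deg: float,
                   selective_left: bool = True,
                   selective_right: bool = True) -> str:
    """Group by signs of (cos PD_left, cos PD_right); opposite-sign
    quadrants hold the CW-type / CCW-type rotation-substrate neurons."""
    if not (selective_left and selective_right) or \
            np.isnan(pd_left_deg) or np.isnan(pd_right_deg):
        return "unclassified"
    sl, sr = _cos_sign(pd_left_deg), _cos_sign(pd_right_deg)
    if sl == 0 or sr == 0:
        return "unclassified"
    if sl > 0 and sr > 0:
        return "both_forward"
    if sl < 0 and sr < 0:
        return "both_backward"
    if sl > 0:
        return "left_forward_right_backward"   # CW-type
    return "right_forward_left_backward"       # CCW-type


def _block_tuning(neuron: NeuronRecord, protocol: StimulusProtocol, eye: str,
                  n_shuffles: int, alpha: float, seed):
    idx = protocol.indices(eye=eye, kind=TRANSLATION)
    if not idx:
        raise ValueError(f"protocol has no {eye!r} stimulation block")
    resp, labels = [], []
    for si in idx:
        pr = presentation_responses(neuron, protocol, si)
        resp.append(pr)
        labels.append(np.full(pr.size, protocol[si].direction_deg))
    resp, labels = np.concatenate(resp), np.concatenate(labels)
    try:
        res = shuffle_test(resp, labels, n_shuffles=n_shuffles, alpha=alpha,
                           seed=seed)
        return res.pd_deg, res.is_direction_selective, resp
    except UndefinedTuningError:
        return float("nan"), False, resp


def per_eye_tuning(neuron: NeuronRecord, protocol: StimulusProtocol,
                   n_shuffles: int = 1000, alpha: float = 0.05,
                   seed=None) -> MonocularResult:
    """Apply DSI + shuffle test independently per stimulation block and
    compute the monocular index from the two monocular blocks."""
    rng = np.random.default_rng(seed)
    out = {}
    responses = {}
    for eye in ("left", "right", "both"):
        pd_deg, sel, resp = _block_tuning(neuron, protocol, eye, n_shuffles,
                                          alpha, rng.integers(2**31))
        out[eye] = (pd_deg if sel else float("nan"), sel)
        responses[eye] = resp
    contra_eye = "right" if neuron.side == "left" else "left"
    ipsi_eye = "left" if contra_eye == "right" else "right"
    mi = monocular_index(responses[contra_eye], responses[ipsi_eye])
    pd_l, sel_l = out["left"]
    pd_r, sel_r = out["right"]
    pd_b, sel_b = out["both"]
    group = quadrant_group(pd_l, pd_r, sel_l, sel_r)
    opposing = group in ("left_forward_right_backward",
                         "right_forward_left_backward")
    return MonocularResult(
        neuron_id=neuron.id, monocular_index=mi,
        pd_left_deg=pd_l, pd_right_deg=pd_r, pd_binocular_deg=pd_b,
        selective_left=sel_l, selective_right=sel_r, selective_binocular=sel_b,
        opposing=opposing, quadrant_group=group)


def binocular_analysis(neurons: list[NeuronRecord],
                       protocol: StimulusProtocol, table: ResponseTable,
                       n_shuffles: int = 1000, alpha: float = 0.05,
                       seed=None) -> pd.DataFrame:
    """Monocular results for every neuron active in at least one block."""
    rng = np.random.default_rng(seed)
    per_block = [table.active(eye) for eye in ("left", "right", "both")]
    ids = sorted(set().union(*(s.index for s in per_block)))
    active_any = pd.Series(False, index=ids)
    for s in per_block:
        active_any |= s.reindex(ids, fill_value=False)
    rows = []
    for neuron in neurons:
        if not bool(active_any.get(neuron.id, False)):
            continue
        res = per_eye_tuning(neuron, protocol, n_shuffles=n_shuffles,
                             alpha=alpha, seed=rng.integers(2**31))
        rows.append(res.__dict__.copy())
    return pd.DataFrame(rows)
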