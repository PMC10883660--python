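"""Per-stimulus dF/F0 response extraction and response/activity criteria.

For every stimulus, each frame's fluorescence F is normalized by F0, the
mean signal over that stimulus's initial stationary period:
``dF/F0 = (F - F0) / F0``. The response to a stimulus is the mean dF/F0
over the moving period, averaged across repetitions. A neuron *responds*
to a stimulus when that response exceeds the baseline-period mean dF/F0
plus two standard deviations, and is *active* when it responds to at
least one stimulus of the set.

The 2-SD criterion is operationalized as follows: the baseline mean and
SD are computed over the per-frame baseline dF/F0 values pooled across
repetitions of that stimulus (frame-to-frame noise), and compared against
the repetition-averaged moving-phase mean. "Exceeds" is strict ``>``.

Missing frames (e.g. frames dropped during motion-artifact alignment) are
represented as NaN and skipped in all window means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import StimulusEpoch, StimulusProtocol

__all__ = [
    "NeuronRecord",
    "ResponseTable",
    "DegenerateBaselineError",
    "compute_dff",
    "stimulus_response",
    "baseline_stats",
    "is_responding",
    "is_active",
    "extract_responses",
]


class DegenerateBaselineError(ValueError):
    """Raised when the baseline fluorescence F0 is not positive."""


@dataclass
class NeuronRecord:
    """One ROI: centroid in the registered frame plus its raw traces.

    ``centroid_um`` is (rostro-caudal, left-right, dorso-ventral) in
    micrometres; the left-right coordinate is signed about the midline
    (negative = left). ``traces`` maps ``(stimulus_index, repetition)`` to a
    raw fluorescence trace whose length equals the epoch's frame count.
    ``side`` is the neuron's side relative to the midline.
    """

    id: str
    centroid_um: np.ndarray
    side: str
    traces: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroid_um = np.asarray(self.centroid_um, dtype=float)
        if self.centroid_um.shape != (3,):
            raise ValueError("centroid_um must be a 3-vector")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def repetitions(self, stimulus_index: int) -> list[int]:
        """Sorted repetition indices recorded for one stimulus."""
        return sorted(r for (s, r) in self.traces if s == stimulus_index)

    def traces_for(self, stimulus_index: int) -> list[np.ndarray]:
        return [self.traces[(stimulus_index, r)]
                for r in self.repetitions(stimulus_index)]

    def validate_against(self, protocol: StimulusProtocol) -> None:
        for (s, _), tr in self.traces.items():
            if len(tr) != protocol[s].n_frames:
                raise ValueError(
                    f"neuron {self.id}: trace for stimulus {s} has "
                    f"{len(tr)} frames, epoch spans {protocol[s].n_frames}")


def compute_dff(trace: np.ndarray, n_baseline_frames: int) -> np.ndarray:
    """dF/F0 of a raw trace; F0 is the mean of the first baseline frames.

    NaN frames are skipped when computing F0 and propagate elsewhere.
    Raises :class:`DegenerateBaselineError` when F0 <= 0 and ``ValueError``
    when the trace is shorter than the baseline window.
    """
    trace = np.asarray(trace, dtype=float)
    if n_baseline_frames < 1:
        raise ValueError("n_baseline_frames must be >= 1")
    if len(trace) <= n_baseline_frames:
        raise ValueError("trace shorter than the baseline window")
    window = trace[:n_baseline_frames]
    if np.all(np.isnan(window)):
        raise DegenerateBaselineError("baseline window contains no frames")
    f0 = np.nanmean(window)
    if f0 <= 0:
        raise DegenerateBaselineError(f"baseline F0 = {f0} is not positive")
    return (trace - f0) / f0


def stimulus_response(dff_traces: list[np.ndarray],
                      epoch: StimulusEpoch) -> float:
    """Mean moving-period dF/F0, averaged across repetitions.

    Repetition counts may differ between neurons; each neuron is averaged
    over whatever repetitions it has.
    """
    if len(dff_traces) == 0:
        raise ValueError("at least one repetition is required")
    lo = epoch.n_frames_pre
    hi = lo + epoch.n_frames_move
    per_rep = [np.nanmean(np.asarray(d, dtype=float)[lo:hi]) for d in dff_traces]
    return float(np.mean(per_rep))


def baseline_stats(dff_traces: list[np.ndarray],
                   epoch: StimulusEpoch) -> tuple[float, float]:
    """Mean and SD of per-frame baseline dF/F0 pooled across repetitions.

    The pooled mean is ~0 by construction of dF/F0; the SD captures
    frame-to-frame noise on the scale of the response unit.
    """
    if len(dff_traces) == 0:
        raise ValueError("at least one repetition is required")
    pooled = np.concatenate(
        [np.asarray(d, dtype=float)[:epoch.n_frames_pre] for d in dff_traces])
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size < 2:
        return float(pooled.mean()) if pooled.size else 0.0, 0.0
    return float(pooled.mean()), float(pooled.std(ddof=1))


def is_responding(response: float, baseline_mean: float,
                  baseline_sd: float) -> bool:
    """Strictly exceeds baseline mean + 2 SD."""
    if baseline_sd < 0:
        raise ValueError("baseline_sd must be non-negative")
    return response > baseline_mean + 2.0 * baseline_sd


def is_active(responding_flags) -> bool:
    """Responding to at least one stimulus of the set (logical OR)."""
    flags = list(responding_flags)
    if not flags:
        raise ValueError("empty stimulus set")
    return any(bool(f) for f in flags)


class ResponseTable:
    """Long-format table of per-neuron x per-stimulus responses and flags.

    One row per (neuron, stimulus): mean dF/F0 response, baseline mean/SD,
    repetition count, responding flag, plus the epoch metadata needed
    downstream (kind, direction, rotation label, eye condition).
    """

    COLUMNS = ["neuron_id", "stimulus", "eye", "kind", "direction_deg",
               "rotation_label", "response", "baseline_mean", "baseline_sd",
               "n_repetitions", "responding"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"response table missing columns {sorted(missing)}")
        self.df = df.reset_index(drop=True)

    def active(self, eye: str | None = None) -> pd.Series:
        """Per-neuron active flag; restrict to one eye-condition block if given."""
        df = self.df if eye is None else self.df[self.df["eye"] == eye]
        return df.groupby("neuron_id")["responding"].any()

    def responses(self, neuron_id: str, eye: str = "both",
                  kind: str | None = None) -> pd.DataFrame:
        m = (self.df["neuron_id"] == neuron_id) & (self.df["eye"] == eye)
        if kind is not None:
            m &= self.df["kind"] == kind
        return self.df[m]

    def rotation_flags(self, neuron_id: str, eye: str = "both") -> dict[str, bool]:
        """Responding flags keyed by rotation label for one neuron."""
        rows = self.responses(neuron_id, eye=eye, kind="rotation")
        return {r.rotation_label: bool(r.responding) for r in rows.itertuples()}

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["responding"] = out["responding"].astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseTable":
        df = pd.read_csv(path)
        df["responding"] = df["responding"].astype(bool)
        df["neuron_id"] = df["neuron_id"].astype(str)
        return cls(df)


def presentation_responses(neuron: NeuronRecord, protocol: StimulusProtocol,
                           stimulus_index: int) -> np.ndarray:
    """Per-repetition moving-period mean dF/F0 for one stimulus."""
    epoch = protocol[stimulus_index]
    lo, hi = epoch.n_frames_pre, epoch.n_frames_pre + epoch.n_frames_move
    out = []
    for tr in neuron.traces_for(stimulus_index):
        dff = compute_dff(tr, epoch.n_frames_pre)
        out.append(np.nanmean(dff[lo:hi]))
    return np.asarray(out, dtype=float)


def extract_responses(neurons: list[NeuronRecord],
                      protocol: StimulusProtocol) -> ResponseTable:
    """Build the response table for a population.

    Epochs flagged ``discard`` (duplicated first stimulus of a block) are
    dropped before any statistic.
    """
    rows = []
    for neuron in neurons:
        for si in protocol.indices(include_discard=False):
            epoch = protocol[si]
            raw = neuron.traces_for(si)
            if not raw:
                continue
            dffs = [compute_dff(tr, epoch.n_frames_pre) for tr in raw]
            resp = stimulus_response(dffs, epoch)
            bmean, bsd = baseline_stats(dffs, epoch)
            rows.append({
                "neuron_id": neuron.id,
                "stimulus": si,
                "eye": epoch.eye,
                "kind": epoch.kind,
                "direction_deg": epoch.direction_deg,
                "rotation_label": epoch.rotation_label,
                "response": resp,
                "baseline_mean": bmean,
                "baseline_sd": bsd,
                "n_repetitions": len(raw),
                "responding": is_responding(resp, bmean, bsd),
            })
    return ResponseTable(pd.DataFrame(rows, columns=ResponseTable.COLUMNS))
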