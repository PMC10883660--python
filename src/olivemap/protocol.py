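"""Visual stimulus protocols: translational gratings and rotating windmills.

A protocol is an ordered list of stimulus epochs. Each epoch has three
phases: a stationary pre period (used as the fluorescence baseline), a
moving period (used as the response window), and a stationary post period.
The standard epoch is 6 s stationary / 10 s moving / 5.4 s stationary;
at a 345.6 ms frame period this spans 62 imaging frames.

Direction convention throughout the package: 0 deg is forward motion,
90 deg rightward, 180 deg backward, -90 deg leftward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "StimulusEpoch",
    "StimulusProtocol",
    "generate_protocol",
    "TRANSLATION",
    "ROTATION",
    "ROTATION_LABELS",
]

TRANSLATION = "translation"
ROTATION = "rotation"
ROTATION_LABELS = ("CW", "CCW", "CONV", "DIV")

#: frame period of the plane-by-plane scanning used for soma imaging
DEFAULT_FRAME_PERIOD_S = 0.3456
#: stationary / moving / stationary phase durations in seconds
DEFAULT_PHASE_DURATIONS_S = (6.0, 10.0, 5.4)


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulus presentation: pre (stationary), move, post (stationary).

    ``direction_deg`` is set for translation epochs only, ``rotation_label``
    for rotation epochs only. ``eye`` says which visual field was stimulated
    ("left", "right" or "both"). ``discard`` flags the throwaway duplicate
    of the first stimulus of a block; flagged epochs are excluded from every
    downstream statistic.
    """

    kind: str
    eye: str
    n_frames_pre: int
    n_frames_move: int
    n_frames_post: int
    frame_period_s: float
    direction_deg: float | None = None
    rotation_label: str | None = None
    discard: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (TRANSLATION, ROTATION):
            raise ValueError(f"unknown epoch kind {self.kind!r}")
        if self.eye not in ("left", "right", "both"):
            raise ValueError(f"unknown eye condition {self.eye!r}")
        for name in ("n_frames_pre", "n_frames_move", "n_frames_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")
        if self.kind == TRANSLATION:
            if self.direction_deg is None:
                raise ValueError("translation epoch needs direction_deg")
            if self.rotation_label is not None:
                raise ValueError("translation epoch must not carry a rotation_label")
        else:
            if self.rotation_label not in ROTATION_LABELS:
                raise ValueError(f"rotation_label must be one of {ROTATION_LABELS}")
            if self.direction_deg is not None:
                raise ValueError("rotation epoch must not carry direction_deg")

    @property
    def n_frames(self) -> int:
        return self.n_frames_pre + self.n_frames_move + self.n_frames_post

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_period_s

    def label(self) -> str:
        """Short human-readable stimulus label, e.g. ``'T045'`` or ``'CW'``."""
        if self.kind == TRANSLATION:
            return f"T{int(round(self.direction_deg)) % 360:03d}"
        return self.rotation_label


@dataclass
class StimulusProtocol:
    """Ordered stimulus epochs plus the seed that produced the ordering."""

    epochs: list[StimulusEpoch] = field(default_factory=list)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i: int) -> StimulusEpoch:
        return self.epochs[i]

    @property
    def n_frames(self) -> int:
        """Total frame count over all epochs (epochs are contiguous)."""
        return sum(e.n_frames for e in self.epochs)

    def indices(self, eye: str | None = None, kind: str | None = None,
                include_discard: bool = False) -> list[int]:
        """Epoch indices filtered by eye condition and kind."""
        out = []
        for i, e in enumerate(self.epochs):
            if e.discard and not include_discard:
                continue
            if eye is not None and e.eye != eye:
                continue
            if kind is not None and e.kind != kind:
                continue
            out.append(i)
        return out

    def eyes(self) -> list[str]:
        """Eye conditions present, in block order of first appearance."""
        seen: list[str] = []
        for e in self.epochs:
            if e.eye not in seen:
                seen.append(e.eye)
        return seen

    def n_stimuli(self, eye: str) -> int:
        """Number of distinct stimuli in a block (discard duplicates excluded)."""
        return len(self.indices(eye=eye))

    def translation_directions(self, eye: str = "both") -> np.ndarray:
        """Directions (deg) of the translation epochs of a block, in order."""
        return np.array([self.epochs[i].direction_deg
                         for i in self.indices(eye=eye, kind=TRANSLATION)])

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed,
                           "epochs": [asdict(e) for e in self.epochs]}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        raw = json.loads(text)
        return cls(epochs=[StimulusEpoch(**e) for e in raw["epochs"]],
                   seed=raw["seed"])


def _phase_frames(phase_durations_s, frame_period_s) -> tuple[int, int, int]:
    frames = tuple(int(round(d / frame_period_s)) for d in phase_durations_s)
    if any(f <= 0 for f in frames):
        raise ValueError("phase durations too short for the frame period")
    return frames


def generate_protocol(
    n_directions: int = 8,
    include_rotations: bool = True,
    include_conv_div: bool = False,
    monocular_blocks: bool = False,
    frame_period_s: float = DEFAULT_FRAME_PERIOD_S,
    phase_durations_s: tuple[float, float, float] = DEFAULT_PHASE_DURATIONS_S,
    seed: int = 0,
) -> StimulusProtocol:
    """Build a randomized stimulus protocol.

    Each block presents gratings in ``n_directions`` evenly spaced
    directions in a seeded random order, followed by CW and CCW windmill
    rotation (and, in the binocular block only, converging/diverging
    rotation when ``include_conv_div`` is set). With ``monocular_blocks``
    three blocks are produced in the order left, right, binocular, and the
    first stimulus of each block is duplicated with the duplicate flagged
    ``discard`` (stimulus-onset transient control).
    """
    if any(d <= 0 for d in phase_durations_s):
        raise ValueError("phase durations must be positive")
    if n_directions <= 0 or 360 % n_directions != 0:
        raise ValueError("n_directions must be a positive divisor of 360")
    pre, move, post = _phase_frames(phase_durations_s, frame_period_s)
    rng = np.random.default_rng(seed)
    directions = np.arange(0.0, 360.0, 360.0 / n_directions)

    eyes = ["left", "right", "both"] if monocular_blocks else ["both"]
    epochs: list[StimulusEpoch] = []
    common = dict(n_frames_pre=pre, n_frames_move=move, n_frames_post=post,
                  frame_period_s=frame_period_s)
    for eye in eyes:
        block: list[StimulusEpoch] = []
        for d in rng.permutation(directions):
            block.append(StimulusEpoch(kind=TRANSLATION, eye=eye,
                                       direction_deg=float(d), **common))
        if include_rotations:
            labels = ["CW", "CCW"]
            if include_conv_div and eye == "both":
                labels += ["CONV", "DIV"]
            for lab in labels:
                block.append(StimulusEpoch(kind=ROTATION, eye=eye,
                                           rotation_label=lab, **common))
        if monocular_blocks:
            first = block[0]
            block.insert(0, StimulusEpoch(**{**asdict(first), "discard": True}))
        epochs.extend(block)
    return StimulusProtocol(epochs=epochs, seed=seed)
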