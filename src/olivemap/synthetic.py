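"""Synthetic populations of direction-tuned inferior-olive neurons.

The generator emulates the statistical structure the analysis chain
assumes: von Mises direction tuning, single-exponential calcium-indicator
kinetics, per-eye input weights with a contralateral bias, spatially
clustered functional classes (forward-rostral, backward-caudal, rotation
classes lateralized CW-right / CCW-left), two anatomical soma/terminal
classes (unipolar and multipolar), volumetric response stacks, and
skeletons whose leaves sit at requested axon-terminal points. Every
neuron carries ground-truth parameters for recovery tests.

All randomness flows through one seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import (StimulusEpoch, StimulusProtocol, TRANSLATION, ROTATION,
                       generate_protocol)
from .responses import NeuronRecord
from .voxels import ResponseVolume

__all__ = [
    "TuningParams",
    "ClassSpec",
    "AnatomyClassSpec",
    "PopulationSpec",
    "SyntheticDataset",
    "Skeleton",
    "simulate_trace",
    "expected_drive",
    "expected_response",
    "generate_population",
    "generate_voxel_volume",
    "generate_skeletons",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _wrap_deg(a):
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


@dataclass
class TuningParams:
    """Ground-truth response model of one neuron.

    The expected drive during the moving phase of a translation stimulus
    at direction theta is ``amplitude * exp(kappa * (cos(theta - pd) - 1))``
    per eye (peak-normalized von Mises; kappa = 0 gives a
    direction-uniform response). Per-eye preferred directions default to
    ``pd_deg`` but may oppose each other (the substrate of
    rotation-sensitive binocular neurons). Eye weights scale each eye's
    contribution; a binocular stimulus drives the weighted sum of the two
    eyes, so weights summing to 1 leave the binocular plateau at
    ``amplitude``. Rotation stimuli drive ``rot_gain_<label>`` per eye,
    weighted the same way. The drive is convolved with a causal
    exponential kernel (indicator kinetics) and Gaussian noise is added
    to the raw fluorescence around ``baseline_F``.
    """

    baseline_F: float = 100.0
    amplitude: float = 0.5
    pd_deg: float = 0.0
    kappa: float = 3.0
    rot_gain_cw: float = 0.0
    rot_gain_ccw: float = 0.0
    rot_gain_conv: float = 0.0
    rot_gain_div: float = 0.0
    w_contra: float = 0.65
    w_ipsi: float = 0.35
    tau_decay_s: float = 0.7
    noise_sd: float = 3.0
    pd_left_deg: float | None = None
    pd_right_deg: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_F <= 0:
            raise ValueError("baseline_F must be positive")
        if self.amplitude < 0 or self.kappa < 0 or self.noise_sd < 0:
            raise ValueError("amplitude, kappa and noise_sd must be >= 0")
        for g in ("rot_gain_cw", "rot_gain_ccw", "rot_gain_conv",
                  "rot_gain_div"):
            if getattr(self, g) < 0:
                raise ValueError(f"{g} must be >= 0")
        for w in ("w_contra", "w_ipsi"):
            if not 0.0 <= getattr(self, w) <= 1.0:
                raise ValueError(f"{w} must lie in [0, 1]")
        if self.tau_decay_s <= 0:
            raise ValueError("tau_decay_s must be positive")

    def eye_pd(self, eye: str) -> float:
        if eye == "left":
            return self.pd_deg if self.pd_left_deg is None else self.pd_left_deg
        return self.pd_deg if self.pd_right_deg is None else self.pd_right_deg

    def eye_weight(self, eye: str, side: str) -> float:
        """Weight of one eye's input for a neuron on ``side`` of the midline
        (the contralateral eye is the one on the opposite side)."""
        contra = eye != side
        return self.w_contra if contra else self.w_ipsi


def _von_mises(direction_deg: float, pd_deg: float, kappa: float) -> float:
    d = math.radians(direction_deg - pd_deg)
    return math.exp(kappa * (math.cos(d) - 1.0))


def expected_drive(params: TuningParams, epoch: StimulusEpoch,
                   side: str = "left") -> float:
    """Expected moving-phase drive (dF/F0 units) before indicator filtering."""
    eyes = ("left", "right") if epoch.eye == "both" else (epoch.eye,)
    drive = 0.0
    for eye in eyes:
        w = params.eye_weight(eye, side)
        if epoch.kind == TRANSLATION:
            drive += w * params.amplitude * _von_mises(
                epoch.direction_deg, params.eye_pd(eye), params.kappa)
        else:
            gain = getattr(params, f"rot_gain_{epoch.rotation_label.lower()}")
            drive += w * gain
    return drive


def _decay_kernel(tau_s: float, frame_period_s: float) -> np.ndarray:
    n = max(2, int(math.ceil(8.0 * tau_s / frame_period_s)))
    k = np.exp(-np.arange(n) * frame_period_s / tau_s)
    return k / k.sum()


def simulate_trace(params: TuningParams, epoch: StimulusEpoch,
                   n_repetitions: int = 1, seed=None,
                   side: str = "left") -> np.ndarray:
    """Simulated raw fluorescence traces, shape (n_repetitions, n_frames).

    The moving-phase drive is a step of height :func:`expected_drive`,
    convolved with a causal exponential kernel of constant
    ``tau_decay_s`` (normalized to unit sum, so a long plateau converges
    to the drive), scaled onto the baseline fluorescence, with i.i.d.
    Gaussian noise of SD ``noise_sd`` added to the raw signal.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    rng = _as_rng(seed)
    drive = np.zeros(epoch.n_frames)
    lo = epoch.n_frames_pre
    drive[lo:lo + epoch.n_frames_move] = expected_drive(params, epoch, side)
    kernel = _decay_kernel(params.tau_decay_s, epoch.frame_period_s)
    dff = np.convolve(drive, kernel)[:epoch.n_frames]
    clean = params.baseline_F * (1.0 + dff)
    noise = rng.normal(0.0, params.noise_sd,
                       size=(n_repetitions, epoch.n_frames))
    return clean[None, :] + noise


def expected_response(params: TuningParams, epoch: StimulusEpoch,
                      side: str = "left") -> float:
    """Noise-free moving-window mean dF/F0 (the generator's closed form)."""
    trace = simulate_trace(replace(params, noise_sd=0.0), epoch, 1, seed=0,
                           side=side)[0]
    dff = trace / params.baseline_F - 1.0
    lo = epoch.n_frames_pre
    return float(dff[lo:lo + epoch.n_frames_move].mean())


@dataclass
class ClassSpec:
    """One functional class: count, spatial cluster, tuning distribution.

    ``pd_mean_deg`` of None marks an untuned class (kappa forced to 0).
    ``opposing_eyes`` of "cw" gives left-forward / right-backward per-eye
    tuning (the CW-rotation substrate), "ccw" the mirror image.
    Optional ``terminal_*`` fields add a cerebellar terminal cluster for
    this functional class (used by the overlap analysis).
    """

    n: int
    center_um: tuple[float, float, float]
    spread_um: tuple[float, float, float]
    pd_mean_deg: float | None = 0.0
    pd_sd_deg: float = 25.0
    kappa_range: tuple[float, float] = (2.0, 4.0)
    amplitude_range: tuple[float, float] = (0.4, 0.8)
    rot_gain_cw_range: tuple[float, float] = (0.0, 0.0)
    rot_gain_ccw_range: tuple[float, float] = (0.0, 0.0)
    opposing_eyes: str | None = None
    w_contra: float = 0.65
    w_ipsi: float = 0.35
    n_terminals: int = 0
    terminal_center_um: tuple[float, float, float] | None = None
    terminal_spread_um: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("class counts must be >= 0")
        if any(s <= 0 for s in self.spread_um):
            raise ValueError("spreads must be positive")


@dataclass
class AnatomyClassSpec:
    """One anatomical class: soma and axon-terminal point clusters (um)."""

    n_somata: int
    soma_center_um: tuple[float, float, float]
    soma_spread_um: tuple[float, float, float]
    n_terminals: int
    terminal_center_um: tuple[float, float, float]
    terminal_spread_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.n_somata < 0 or self.n_terminals < 0:
            raise ValueError("point counts must be >= 0")
        if any(s <= 0 for s in self.soma_spread_um + self.terminal_spread_um):
            raise ValueError("spreads must be positive")


# Default study geometry (um, registered frame): the olive spans roughly
# 60 um rostro-caudally with the rostral pole at rc = 0; the cerebellar
# terminal fields sit rostral and dorsal of it (negative rc, high dv).
_IO_DV = 10.0
_CB_DV = 70.0
_UNI_TERM = ((-40.0, 5.0, _CB_DV), (9.0, 4.0, 5.0))    # medial projections
_MULTI_TERM = ((-40.0, 18.0, _CB_DV), (9.0, 5.0, 5.0))  # lateral projections


def _default_classes() -> dict[str, ClassSpec]:
    return {
        "forward": ClassSpec(
            n=40, center_um=(15.0, 0.0, _IO_DV), spread_um=(7.0, 6.0, 4.0),
            pd_mean_deg=0.0, n_terminals=40,
            terminal_center_um=_UNI_TERM[0], terminal_spread_um=_UNI_TERM[1]),
        "backward": ClassSpec(
            n=25, center_um=(45.0, 0.0, _IO_DV), spread_um=(7.0, 6.0, 4.0),
            pd_mean_deg=180.0, n_terminals=25,
            terminal_center_um=_MULTI_TERM[0], terminal_spread_um=_MULTI_TERM[1]),
        "cw_rotation": ClassSpec(
            n=12, center_um=(12.0, 9.0, _IO_DV), spread_um=(5.0, 4.0, 4.0),
            pd_mean_deg=0.0, pd_sd_deg=15.0, opposing_eyes="cw",
            rot_gain_cw_range=(0.4, 0.7), rot_gain_ccw_range=(0.0, 0.1)),
        "ccw_rotation": ClassSpec(
            n=12, center_um=(12.0, -9.0, _IO_DV), spread_um=(5.0, 4.0, 4.0),
            pd_mean_deg=0.0, pd_sd_deg=15.0, opposing_eyes="ccw",
            rot_gain_cw_range=(0.0, 0.1), rot_gain_ccw_range=(0.4, 0.7)),
        "nonselective": ClassSpec(
            n=20, center_um=(30.0, 0.0, _IO_DV), spread_um=(14.0, 7.0, 5.0),
            pd_mean_deg=None, amplitude_range=(0.2, 0.4)),
    }


def _default_anatomy() -> dict[str, AnatomyClassSpec]:
    return {
        "unipolar": AnatomyClassSpec(
            n_somata=16, soma_center_um=(12.0, 0.0, 6.0),
            soma_spread_um=(6.0, 5.0, 3.0),
            n_terminals=32, terminal_center_um=_UNI_TERM[0],
            terminal_spread_um=_UNI_TERM[1]),
        "multipolar": AnatomyClassSpec(
            n_somata=19, soma_center_um=(45.0, 0.0, 14.0),
            soma_spread_um=(7.0, 6.0, 3.0),
            n_terminals=38, terminal_center_um=_MULTI_TERM[0],
            terminal_spread_um=_MULTI_TERM[1]),
    }


@dataclass
class PopulationSpec:
    """Everything needed to synthesize one dataset."""

    classes: dict[str, ClassSpec] = field(default_factory=_default_classes)
    anatomy: dict[str, AnatomyClassSpec] = field(default_factory=_default_anatomy)
    n_repetitions: int = 3
    baseline_F: float = 100.0
    noise_sd: float = 3.0
    tau_decay_s: float = 0.7
    seed: int = 0


@dataclass
class SyntheticDataset:
    """Protocol, neuron records, ground truth and anatomical point sets.

    ``ground_truth`` holds one row per neuron (class label and
    :class:`TuningParams` fields); ``anatomy`` holds labeled soma and
    terminal points (columns rc_um, lr_um, dv_um, class_label, kind);
    ``function_terminals`` holds terminal points attributed to functional
    classes, for the function to anatomy overlap analysis.
    """

    protocol: StimulusProtocol
    neurons: list[NeuronRecord]
    ground_truth: pd.DataFrame
    anatomy: pd.DataFrame
    function_terminals: pd.DataFrame

    def points(self, class_label: str, kind: str = "soma",
               table: str = "anatomy") -> np.ndarray:
        df = self.anatomy if table == "anatomy" else self.function_terminals
        sel = df[(df["class_label"] == class_label) & (df["kind"] == kind)]
        return sel[["rc_um", "lr_um", "dv_um"]].to_numpy()

    def validate(self) -> None:
        for neuron in self.neurons:
            neuron.validate_against(self.protocol)
            for si in self.protocol.indices(include_discard=True):
                if not neuron.repetitions(si):
                    raise ValueError(
                        f"neuron {neuron.id} has no trace for stimulus {si}")


def _sample_pd(rng, mean_deg: float, sd_deg: float,
               half: str | None = None) -> float:
    """Wrapped-normal PD draw, optionally rejected into a cosine half-plane."""
    for _ in range(1000):
        pd_deg = float(_wrap_deg(rng.normal(mean_deg, sd_deg)))
        if half is None:
            return pd_deg
        c = math.cos(math.radians(pd_deg))
        if (half == "forward" and c > 0) or (half == "backward" and c < 0):
            return pd_deg
    raise RuntimeError("PD rejection sampling failed")


def _sample_params(rng, cls: ClassSpec, spec: PopulationSpec) -> TuningParams:
    if cls.pd_mean_deg is None:
        pd_deg, kappa = 0.0, 0.0
    else:
        half = ("forward" if math.cos(math.radians(cls.pd_mean_deg)) > 0
                else "backward")
        pd_deg = _sample_pd(rng, cls.pd_mean_deg, cls.pd_sd_deg, half=half)
        kappa = float(rng.uniform(*cls.kappa_range))
    pd_left = pd_right = None
    if cls.opposing_eyes == "cw":       # CW: forward on the left eye
        pd_left, pd_right = pd_deg, float(_wrap_deg(pd_deg + 180.0))
    elif cls.opposing_eyes == "ccw":
        pd_left, pd_right = float(_wrap_deg(pd_deg + 180.0)), pd_deg
    return TuningParams(
        baseline_F=spec.baseline_F,
        amplitude=float(rng.uniform(*cls.amplitude_range)),
        pd_deg=pd_deg, kappa=kappa,
        rot_gain_cw=float(rng.uniform(*cls.rot_gain_cw_range)),
        rot_gain_ccw=float(rng.uniform(*cls.rot_gain_ccw_range)),
        w_contra=cls.w_contra, w_ipsi=cls.w_ipsi,
        tau_decay_s=spec.tau_decay_s, noise_sd=spec.noise_sd,
        pd_left_deg=pd_left, pd_right_deg=pd_right)


def generate_population(spec: PopulationSpec,
                        protocol: StimulusProtocol | None = None
                        ) -> SyntheticDataset:
    """Draw a full synthetic dataset from a population specification.

    Neuron centroids are Gaussian about each class centre; every neuron
    gets ``spec.n_repetitions`` simulated traces for every protocol
    epoch. Deterministic given ``spec.seed``.
    """
    if sum(c.n for c in spec.classes.values()) == 0:
        raise ValueError("population spec contains zero neurons")
    rng = np.random.default_rng(spec.seed)
    if protocol is None:
        protocol = generate_protocol(seed=spec.seed)

    neurons: list[NeuronRecord] = []
    gt_rows = []
    fn_term_rows = []
    idx = 0
    for label, cls in spec.classes.items():
        for _ in range(cls.n):
            centroid = rng.normal(cls.center_um, cls.spread_um)
            side = "left" if centroid[1] < 0 else "right"
            params = _sample_params(rng, cls, spec)
            traces = {}
            for si in protocol.indices(include_discard=True):
                reps = simulate_trace(params, protocol[si],
                                      n_repetitions=spec.n_repetitions,
                                      seed=rng, side=side)
                for r in range(spec.n_repetitions):
                    traces[(si, r)] = reps[r]
            nid = f"n{idx:04d}"
            neurons.append(NeuronRecord(id=nid, centroid_um=centroid,
                                        side=side, traces=traces))
            gt_rows.append({
                "neuron_id": nid, "class_label": label, "side": side,
                "rc_um": centroid[0], "lr_um": centroid[1],
                "dv_um": centroid[2],
                "pd_deg": params.pd_deg, "kappa": params.kappa,
                "amplitude": params.amplitude,
                "rot_gain_cw": params.rot_gain_cw,
                "rot_gain_ccw": params.rot_gain_ccw,
                "w_contra": params.w_contra, "w_ipsi": params.w_ipsi,
                "pd_left_deg": (np.nan if params.pd_left_deg is None
                                else params.pd_left_deg),
                "pd_right_deg": (np.nan if params.pd_right_deg is None
                                 else params.pd_right_deg),
                "noise_sd": params.noise_sd, "baseline_F": params.baseline_F,
                "tau_decay_s": params.tau_decay_s,
            })
            idx += 1
        if cls.n_terminals and cls.terminal_center_um is not None:
            pts = rng.normal(cls.terminal_center_um, cls.terminal_spread_um,
                             size=(cls.n_terminals, 3))
            for p in pts:
                fn_term_rows.append({"rc_um": p[0], "lr_um": p[1],
                                     "dv_um": p[2], "class_label": label,
                                     "kind": "terminal"})

    an_rows = []
    for label, a in spec.anatomy.items():
        for p in rng.normal(a.soma_center_um, a.soma_spread_um,
                            size=(a.n_somata, 3)):
            an_rows.append({"rc_um": p[0], "lr_um": p[1], "dv_um": p[2],
                            "class_label": label, "kind": "soma"})
        for p in rng.normal(a.terminal_center_um, a.terminal_spread_um,
                            size=(a.n_terminals, 3)):
            an_rows.append({"rc_um": p[0], "lr_um": p[1], "dv_um": p[2],
                            "class_label": label, "kind": "terminal"})

    cols = ["rc_um", "lr_um", "dv_um", "class_label", "kind"]
    return SyntheticDataset(
        protocol=protocol, neurons=neurons,
        ground_truth=pd.DataFrame(gt_rows),
        anatomy=pd.DataFrame(an_rows, columns=cols),
        function_terminals=pd.DataFrame(fn_term_rows, columns=cols))


def generate_voxel_volume(dataset: SyntheticDataset, voxel_size_um: float = 2.0,
                          background_level: float = 10.0, seed=None,
                          blob_sd_um: float = 3.0, blob_height: float = 20.0,
                          n_repetitions: int = 5, noise_sd: float = 0.02,
                          brightness_noise_sd: float = 0.3,
                          pad_um: float = 8.0) -> ResponseVolume:
    """Render the population as Gaussian blobs into response stacks.

    Returns per-stimulus, per-repetition dF/F0 volumes (the noiseless
    expected window-mean response of each neuron, spread over an
    isotropic Gaussian blob, plus i.i.d. response noise per repetition)
    and a raw brightness volume with labeled voxels above
    ``background_level`` at blob locations.
    """
    if voxel_size_um <= 0:
        raise ValueError("voxel size must be positive")
    if not dataset.neurons:
        raise ValueError("dataset contains no neurons")
    rng = _as_rng(seed)
    cent = np.stack([n.centroid_um for n in dataset.neurons])  # (n, rc/lr/dv)
    # volume axes (z, y, x) = (dv, rc, lr)
    phys = cent[:, [2, 0, 1]]
    lo = phys.min(axis=0) - pad_um
    hi = phys.max(axis=0) + pad_um
    shape = np.ceil((hi - lo) / voxel_size_um).astype(int) + 1
    axes = [lo[d] + voxel_size_um * np.arange(shape[d]) for d in range(3)]

    stim_idx = dataset.protocol.indices(include_discard=False)
    epochs = [dataset.protocol[i] for i in stim_idx]
    weight_sum = np.zeros(tuple(shape))
    clean = np.zeros((len(epochs),) + tuple(shape))
    for neuron, p in zip(dataset.neurons, phys):
        gt = dataset.ground_truth
        row = gt[gt["neuron_id"] == neuron.id].iloc[0]
        params = TuningParams(
            baseline_F=row["baseline_F"], amplitude=row["amplitude"],
            pd_deg=row["pd_deg"], kappa=row["kappa"],
            rot_gain_cw=row["rot_gain_cw"], rot_gain_ccw=row["rot_gain_ccw"],
            w_contra=row["w_contra"], w_ipsi=row["w_ipsi"],
            tau_decay_s=row["tau_decay_s"], noise_sd=0.0,
            pd_left_deg=None if pd.isna(row["pd_left_deg"]) else row["pd_left_deg"],
            pd_right_deg=None if pd.isna(row["pd_right_deg"]) else row["pd_right_deg"])
        g = [np.exp(-0.5 * ((ax - p[d]) / blob_sd_um) ** 2)
             for d, ax in enumerate(axes)]
        w = g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
        weight_sum += w
        for k, epoch in enumerate(epochs):
            clean[k] += expected_response(params, epoch, side=neuron.side) * w

    responses = (clean[:, None] +
                 rng.normal(0.0, noise_sd,
                            size=(len(epochs), n_repetitions) + tuple(shape)))
    brightness = (background_level + blob_height * weight_sum +
                  rng.normal(0.0, brightness_noise_sd, size=tuple(shape)))
    return ResponseVolume(responses=responses, brightness=brightness,
                          epochs=epochs, voxel_size_um=voxel_size_um,
                          origin_um=lo)


@dataclass
class Skeleton:
    """A neurite skeleton: node coordinates (um) plus a parent pointer tree.

    Node ids are row indices; ``parents[i]`` is -1 for the root. Leaves
    of generated skeletons coincide exactly with the requested terminal
    points.
    """

    nodes_um: np.ndarray
    parents: np.ndarray

    def __post_init__(self) -> None:
        self.nodes_um = np.asarray(self.nodes_um, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        if self.nodes_um.ndim != 2 or self.nodes_um.shape[1] != 3:
            raise ValueError("nodes_um must be (n, 3)")
        if self.parents.shape != (len(self.nodes_um),):
            raise ValueError("one parent entry per node required")
        if (self.parents == -1).sum() != 1:
            raise ValueError("skeleton must have exactly one root")
        for i, p in enumerate(self.parents):
            if p >= i and p != -1:
                raise ValueError("parents must precede children")

    def leaves(self) -> np.ndarray:
        """Indices of nodes with no children."""
        has_child = np.zeros(len(self.parents), dtype=bool)
        has_child[self.parents[self.parents >= 0]] = True
        return np.flatnonzero(~has_child)

    def rasterize(self, axes: tuple[int, int] = (0, 2), scale_um: float = 1.0,
                  origin_um=None, shape=None) -> np.ndarray:
        """Project onto two coordinate axes and draw a 1-pixel mask.

        ``axes`` selects the (row, column) coordinates from
        (rc, lr, dv); the default (0, 2) is the lateral (rc x dv)
        projection. Each parent-child segment is drawn with a Bresenham
        line.
        """
        from skimage.draw import line
        pts = self.nodes_um[:, list(axes)]
        if origin_um is None:
            origin_um = pts.min(axis=0) - 2 * scale_um
        pix = np.round((pts - np.asarray(origin_um)) / scale_um).astype(int)
        if shape is None:
            shape = tuple(pix.max(axis=0) + 3)
        mask = np.zeros(shape, dtype=bool)
        for i, p in enumerate(self.parents):
            if p < 0:
                mask[pix[i, 0], pix[i, 1]] = True
                continue
            rr, cc = line(pix[p, 0], pix[p, 1], pix[i, 0], pix[i, 1])
            mask[rr, cc] = True
        return mask


def generate_skeletons(terminal_points: list[np.ndarray],
                       soma_points: np.ndarray, seed=None,
                       jitter_um: float = 1.5,
                       n_path_nodes: int = 3) -> list[Skeleton]:
    """One skeleton per soma: a jittered path to a branch point, then one
    branch per requested terminal, with leaves exactly at the terminals."""
    soma_points = np.asarray(soma_points, dtype=float)
    if len(terminal_points) != len(soma_points):
        raise ValueError("one terminal set per soma required")
    rng = _as_rng(seed)
    skeletons = []
    for soma, terms in zip(soma_points, terminal_points):
        terms = np.asarray(terms, dtype=float)
        if terms.ndim != 2 or len(terms) == 0:
            raise ValueError("each skeleton needs at least one terminal")
        nodes = [np.asarray(soma, dtype=float)]
        parents = [-1]
        branch_target = soma + 0.6 * (terms.mean(axis=0) - soma)
        prev = 0
        for i in range(1, n_path_nodes + 1):
            t = i / (n_path_nodes + 1)
            p = soma + t * (branch_target - soma)
            p = p + rng.normal(0.0, jitter_um, 3)
            nodes.append(p)
            parents.append(prev)
            prev = len(nodes) - 1
        nodes.append(branch_target)
        parents.append(prev)
        branch = len(nodes) - 1
        for term in terms:
            mid = branch_target + 0.5 * (term - branch_target)
            nodes.append(mid + rng.normal(0.0, jitter_um, 3))
            parents.append(branch)
            nodes.append(term.copy())
            parents.append(len(nodes) - 2)
        skeletons.append(Skeleton(nodes_um=np.stack(nodes),
                                  parents=np.array(parents)))
    return skeletons
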