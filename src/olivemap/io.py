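"""File formats: HDF5 datasets, SWC skeletons, TIFF volumes, CSV tables.

HDF5 layout of a synthetic dataset::

    /protocol            attribute "json": the protocol serialization
    /neurons/<id>        attrs: centroid_um, side
    /neurons/<id>/s<k>   float array (n_repetitions, n_frames) per stimulus
    /ground_truth, /anatomy, /function_terminals
                         one dataset per column (strings UTF-8 encoded)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol
from .responses import NeuronRecord
from .synthetic import Skeleton, SyntheticDataset


def _df_to_group(df: pd.DataFrame, group) -> None:
    group.attrs["columns"] = list(df.columns)
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object or str(data.dtype).startswith("str"):
            data = np.array(["" if v is None else str(v) for v in data],
                            dtype=bytes)
        group.create_dataset(col, data=data)


def _df_from_group(group) -> pd.DataFrame:
    out = {}
    for col in group.attrs["columns"]:
        data = group[col][()]
        if data.dtype.kind == "S":
            data = np.array([v.decode() for v in data], dtype=object)
        out[col] = data
    return pd.DataFrame(out)


def save_dataset(dataset: SyntheticDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["protocol_json"] = dataset.protocol.to_json()
        ng = f.create_group("neurons")
        for neuron in dataset.neurons:
            g = ng.create_group(neuron.id)
            g.attrs["centroid_um"] = neuron.centroid_um
            g.attrs["side"] = neuron.side
            by_stim: dict[int, list] = {}
            for (s, r), tr in sorted(neuron.traces.items()):
                by_stim.setdefault(s, []).append(tr)
            for s, trs in by_stim.items():
                g.create_dataset(f"s{s:03d}", data=np.stack(trs))
        _df_to_group(dataset.ground_truth, f.create_group("ground_truth"))
        _df_to_group(dataset.anatomy, f.create_group("anatomy"))
        _df_to_group(dataset.function_terminals,
                     f.create_group("function_terminals"))


def load_dataset(path) -> SyntheticDataset:
    import h5py

    with h5py.File(path, "r") as f:
        protocol = StimulusProtocol.from_json(f.attrs["protocol_json"])
        neurons = []
        for nid in sorted(f["neurons"]):
            g = f["neurons"][nid]
            traces = {}
            for name in sorted(g):
                s = int(name[1:])
                arr = g[name][()]
                for r in range(arr.shape[0]):
                    traces[(s, r)] = arr[r]
            neurons.append(NeuronRecord(
                id=nid, centroid_um=g.attrs["centroid_um"],
                side=str(g.attrs["side"]), traces=traces))
        gt = _df_from_group(f["ground_truth"])
        anatomy = _df_from_group(f["anatomy"])
        fn = _df_from_group(f["function_terminals"])
    return SyntheticDataset(protocol=protocol, neurons=neurons,
                            ground_truth=gt, anatomy=anatomy,
                            function_terminals=fn)


def save_swc(skeleton: Skeleton, path, node_type: int = 2,
             radius: float = 0.5) -> None:
    """Write a skeleton as SWC (1-based ids, parent -1 for the root).

    SWC stores coordinates as x y z; we map (rc, lr, dv) onto them.
    """
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i, (xyz, parent) in enumerate(zip(skeleton.nodes_um,
                                              skeleton.parents)):
            p = parent + 1 if parent >= 0 else -1
            fh.write(f"{i + 1} {node_type} {xyz[0]:.4f} {xyz[1]:.4f} "
                     f"{xyz[2]:.4f} {radius:.3f} {p}\n")


def load_swc(path) -> Skeleton:
    ids, coords, parents = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            ids.append(int(parts[0]))
            coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
            parents.append(int(parts[6]))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate node ids in SWC file")
    remap = {nid: i for i, nid in enumerate(ids)}
    par = np.array([remap[p] if p != -1 else -1 for p in parents])
    return Skeleton(nodes_um=np.array(coords), parents=par)


def save_volume_tiff(volume: np.ndarray, path) -> None:
    """Write a 3D volume (or boolean mask, stored as uint8) as multi-page TIFF."""
    import tifffile

    arr = np.asarray(volume)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")


def load_volume_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
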