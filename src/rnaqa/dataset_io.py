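"""HDF5 serialization of featurized training sets.

One file holds stacked raw grids, raw labels (Å) and per-sample provenance,
chunked per sample so training can stream without loading everything.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import h5py
import numpy as np

from .featurize import VoxelGrid


def save_training_set(
    samples: Iterable[tuple[VoxelGrid, float, tuple[str, str, int]]],
    path: Union[str, Path],
) -> int:
    """Write (grid, label, provenance) samples; returns the sample count."""
    grids, labels, provenance = [], [], []
    for grid, label, prov in samples:
        grids.append(np.asarray(grid.values, dtype=np.float32))
        labels.append(float(label))
        provenance.append("\t".join([prov[0], prov[1], str(prov[2])]))
    if not grids:
        raise ValueError("no samples to save")
    stack = np.stack(grids)
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("grids", data=stack, chunks=(1,) + stack.shape[1:])
        fh.create_dataset("labels", data=np.asarray(labels))
        fh.create_dataset("provenance",
                          data=np.array(provenance, dtype=h5py.string_dtype()))
    return len(grids)


def load_training_set(
    path: Union[str, Path],
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str, int]]]:
    """Read back (grids array, labels array, provenance list)."""
    with h5py.File(str(path), "r") as fh:
        grids = fh["grids"][...]
        labels = fh["labels"][...]
        raw = [p.decode() if isinstance(p, bytes) else p
               for p in fh["provenance"][...]]
    provenance = []
    for entry in raw:
        sid, chain, resnum = entry.split("\t")
        provenance.append((sid, chain, int(resnum)))
    return grids, labels, provenance
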