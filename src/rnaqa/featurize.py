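"""Per-nucleotide local frames and voxel-grid featurization.

Each nucleotide defines a body-fixed right-handed orthonormal frame:

* origin at C1',
* ``x`` the unit vector from C1' to the glycosidic nitrogen (N9 for purines,
  N1 for pyrimidines),
* ``z`` the unit vector along ``x × y_pre`` where ``y_pre`` points from C1'
  to the midpoint of O5' and C5',
* ``y = z × x``.

The cubic environment of half-width 16 Å around the origin (atoms whose
local ``|x|, |y|, |z|`` are all strictly below the threshold) is binned into
a 32x32x32 grid of 1 Å voxels with three accumulated channels: occupation
count, mass and charge. Channels (and RMSD-based labels) are min-max scaled
to [0, 1] with statistics fitted once over a training set and frozen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import DegenerateFrameError, FrameError, VoxelizationError
from .structure_io import Atom, Nucleotide, RnaStructure

logger = logging.getLogger(__name__)

CHANNELS = ("occupation", "mass", "charge")
_DEGENERACY_EPS = 1e-6  # Å, threshold on vector norms in the frame construction


@dataclass(frozen=True)
class FeaturizeConfig:
    half_width: float = 16.0  # Å
    grid_edge: int = 32  # voxels per axis
    exclude_self: bool = False

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.grid_edge <= 0:
            raise ValueError("half_width and grid_edge must be positive")

    @property
    def voxel_size(self) -> float:
        return 2.0 * self.half_width / self.grid_edge


@dataclass(frozen=True)
class LocalFrame:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """Rows are the axes: ``rotation @ (p - origin)`` gives local coords."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis])


@dataclass
class EnvironmentAtom:
    """An atom inside a nucleotide's cube, with its local coordinates."""

    atom: Atom
    local: np.ndarray  # (3,) Å in the nucleotide frame
    parent: Nucleotide


@dataclass
class VoxelGrid:
    values: np.ndarray  # (3, edge, edge, edge), channel order CHANNELS
    normalized: bool = False
    frame_provenance: tuple[str, str, int] | None = None  # (structure, chain, resnum)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4 or self.values.shape[0] != len(CHANNELS):
            raise ValueError(f"expected (3, e, e, e) grid, got {self.values.shape}")


@dataclass
class NormalizationStats:
    """Frozen dataset-wide min-max statistics for channels and labels."""

    channel_min: np.ndarray  # (3,)
    channel_max: np.ndarray  # (3,)
    label_min: float
    label_max: float

    def __post_init__(self) -> None:
        self.channel_min = np.asarray(self.channel_min, dtype=float)
        self.channel_max = np.asarray(self.channel_max, dtype=float)
        if np.any(self.channel_max < self.channel_min) or self.label_max < self.label_min:
            raise ValueError("max < min in normalization stats")

    @property
    def degenerate_channels(self) -> np.ndarray:
        return self.channel_max == self.channel_min

    def to_dict(self) -> dict:
        return {
            "channel_min": self.channel_min.tolist(),
            "channel_max": self.channel_max.tolist(),
            "label_min": float(self.label_min),
            "label_max": float(self.label_max),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            channel_min=np.array(d["channel_min"], dtype=float),
            channel_max=np.array(d["channel_max"], dtype=float),
            label_min=float(d["label_min"]),
            label_max=float(d["label_max"]),
        )


def compute_local_frame(nucleotide: Nucleotide) -> LocalFrame:
    """Build the body-fixed orthonormal frame of a nucleotide."""
    required = ["C1'", "O5'", "C5'", nucleotide.glycosidic_atom_name]
    positions = {}
    for name in required:
        atom = nucleotide.get_atom(name)
        if atom is None:
            raise FrameError(
                f"nucleotide {nucleotide.chain_id}{nucleotide.residue_number}: "
                f"missing frame atom {name!r}"
            )
        positions[name] = atom.position
    origin = positions["C1'"]
    x = positions[nucleotide.glycosidic_atom_name] - origin
    nx = np.linalg.norm(x)
    if nx < _DEGENERACY_EPS:
        raise DegenerateFrameError(
            f"nucleotide {nucleotide.chain_id}{nucleotide.residue_number}: "
            "glycosidic bond vector has near-zero length"
        )
    x = x / nx
    y_pre = 0.5 * (positions["O5'"] + positions["C5'"]) - origin
    z = np.cross(x, y_pre)
    nz = np.linalg.norm(z)
    if nz < _DEGENERACY_EPS:
        raise DegenerateFrameError(
            f"nucleotide {nucleotide.chain_id}{nucleotide.residue_number}: "
            "frame atoms are colinear"
        )
    z = z / nz
    y = np.cross(z, x)
    return LocalFrame(origin=origin.copy(), x_axis=x, y_axis=y, z_axis=z)


def to_local(frame: LocalFrame, atoms: Sequence[Atom]) -> list[tuple[Atom, np.ndarray]]:
    """Express atom positions in the local frame."""
    rot = frame.rotation
    return [(atom, rot @ (atom.position - frame.origin)) for atom in atoms]


def from_local(frame: LocalFrame, local: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_local` for a single coordinate vector."""
    return frame.rotation.T @ np.asarray(local) + frame.origin


def extract_environment(
    structure: RnaStructure,
    frame: LocalFrame,
    config: FeaturizeConfig | None = None,
    self_nucleotide: Nucleotide | None = None,
) -> list[EnvironmentAtom]:
    """Atoms of the structure strictly inside the frame-centered cube.

    The assessed nucleotide's own atoms are included unless
    ``config.exclude_self`` is set and ``self_nucleotide`` identifies it.
    """
    if config is None:
        config = FeaturizeConfig()
    pairs = [(nuc, atom) for nuc, atom in structure.iter_atoms()
             if not (config.exclude_self and nuc is self_nucleotide)]
    if not pairs:
        return []
    positions = np.array([atom.position for _, atom in pairs])
    local = (positions - frame.origin) @ frame.rotation.T
    inside = np.all(np.abs(local) < config.half_width, axis=1)
    return [
        EnvironmentAtom(atom=pairs[i][1], local=local[i], parent=pairs[i][0])
        for i in np.flatnonzero(inside)
    ]


def voxelize(
    environment: Sequence[EnvironmentAtom],
    config: FeaturizeConfig | None = None,
    frame_provenance: tuple[str, str, int] | None = None,
) -> VoxelGrid:
    """Accumulate occupation/mass/charge of environment atoms into the grid.

    Voxel cells are half-open: along each axis, cell ``i`` covers
    ``[i*s - half_width, (i+1)*s - half_width)`` Å with ``s`` the voxel size.
    """
    if config is None:
        config = FeaturizeConfig()
    edge = config.grid_edge
    values = np.zeros((len(CHANNELS), edge, edge, edge), dtype=float)
    for env in environment:
        if np.any(np.abs(env.local) >= config.half_width):
            raise VoxelizationError(
                f"atom {env.atom.name!r} at local {env.local} outside the cube"
            )
        if env.atom.mass is None or env.atom.charge is None:
            raise VoxelizationError(
                f"atom {env.atom.name!r} has unassigned mass/charge; "
                "run assign_properties first"
            )
        idx = np.floor((env.local + config.half_width) / config.voxel_size).astype(int)
        i, j, k = idx
        values[0, i, j, k] += 1.0
        values[1, i, j, k] += env.atom.mass
        values[2, i, j, k] += env.atom.charge
    return VoxelGrid(values=values, normalized=False, frame_provenance=frame_provenance)


def fit_normalization(
    grids: Iterable[VoxelGrid],
    labels: Iterable[float],
) -> NormalizationStats:
    """Global per-channel voxel extrema and label extrema over a training set."""
    cmin = np.full(len(CHANNELS), np.inf)
    cmax = np.full(len(CHANNELS), -np.inf)
    n_grids = 0
    for grid in grids:
        if grid.normalized:
            raise ValueError("fit_normalization expects raw grids")
        flat = grid.values.reshape(len(CHANNELS), -1)
        cmin = np.minimum(cmin, flat.min(axis=1))
        cmax = np.maximum(cmax, flat.max(axis=1))
        n_grids += 1
    label_arr = np.asarray(list(labels), dtype=float)
    if n_grids == 0 or label_arr.size == 0:
        raise ValueError("need at least one grid and one label")
    stats = NormalizationStats(
        channel_min=cmin, channel_max=cmax,
        label_min=float(label_arr.min()), label_max=float(label_arr.max()),
    )
    if np.any(stats.degenerate_channels):
        logger.warning("fit_normalization: degenerate (constant) channels %s",
                       [CHANNELS[i] for i in np.flatnonzero(stats.degenerate_channels)])
    return stats


def apply_normalization(
    grid_or_label: Union[VoxelGrid, float, np.ndarray],
    stats: NormalizationStats,
) -> Union[VoxelGrid, float, np.ndarray]:
    """Min-max scale a raw grid (per channel) or raw label(s) into [0, 1].

    Values outside the fitted range saturate at the interval ends; a channel
    that was constant during fitting maps to zero.
    """
    if isinstance(grid_or_label, VoxelGrid):
        grid = grid_or_label
        if grid.normalized:
            return grid
        span = np.where(stats.degenerate_channels, 1.0,
                        stats.channel_max - stats.channel_min)
        scaled = (grid.values - stats.channel_min[:, None, None, None]) \
            / span[:, None, None, None]
        scaled[stats.degenerate_channels] = 0.0
        return VoxelGrid(values=np.clip(scaled, 0.0, 1.0), normalized=True,
                         frame_provenance=grid.frame_provenance)
    span = stats.label_max - stats.label_min
    if span == 0:
        return np.zeros_like(np.asarray(grid_or_label, dtype=float)) \
            if np.ndim(grid_or_label) else 0.0
    scaled = (np.asarray(grid_or_label, dtype=float) - stats.label_min) / span
    clipped = np.clip(scaled, 0.0, 1.0)
    return float(clipped) if np.ndim(grid_or_label) == 0 else clipped


def invert_label_normalization(value, stats: NormalizationStats):
    """Map a normalized score back to the Å scale of the raw labels."""
    return np.asarray(value, dtype=float) * (stats.label_max - stats.label_min) \
        + stats.label_min


def featurize_nucleotide(
    structure: RnaStructure,
    nucleotide: Nucleotide,
    config: FeaturizeConfig | None = None,
) -> VoxelGrid:
    """Frame -> environment -> raw voxel grid for one nucleotide."""
    if config is None:
        config = FeaturizeConfig()
    frame = compute_local_frame(nucleotide)
    environment = extract_environment(structure, frame, config,
                                      self_nucleotide=nucleotide)
    provenance = (structure.structure_id, nucleotide.chain_id,
                  nucleotide.residue_number)
    return voxelize(environment, config, frame_provenance=provenance)
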