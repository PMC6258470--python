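"""End-to-end structure scoring and gradient saliency attribution.

A structure's global score is the sum of its per-nucleotide normalized
unfitness predictions; lower means better predicted quality. Saliency maps
are the exact gradient of the scalar network output with respect to every
input voxel; for near-native inputs, voxels with negative gradients are the
score-lowering (salient) ones. Gradients are mapped back to atoms by voxel
membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cnn_model import TrainedModel, predict
from .errors import AssessmentError, FrameError, ModelError
from .featurize import (
    EnvironmentAtom,
    FeaturizeConfig,
    VoxelGrid,
    apply_normalization,
    compute_local_frame,
    extract_environment,
    voxelize,
)
from .structure_io import Atom, RnaStructure

logger = logging.getLogger(__name__)


@dataclass
class StructureAssessment:
    structure_id: str
    per_nucleotide: list[tuple[tuple[str, int], float]]
    global_score: float
    skipped: list[tuple[tuple[str, int], str]] = field(default_factory=list)


@dataclass
class SaliencyMap:
    voxel_gradients: np.ndarray  # (3, edge, edge, edge) d(output)/d(input)
    atom_attributions: list[tuple[Atom, np.ndarray]] | None = None


def score_structure(
    model: TrainedModel,
    structure: RnaStructure,
    config: FeaturizeConfig | None = None,
) -> StructureAssessment:
    """Score every frame-ready nucleotide and sum into the global score.

    Nucleotides whose frame cannot be built are listed in ``skipped`` and
    excluded from the sum.
    """
    if model.normalization is None:
        raise AssessmentError("model carries no normalization statistics")
    if config is None:
        config = FeaturizeConfig(grid_edge=model.spec.grid_edge)
    for nuc, atom in structure.iter_atoms():
        if atom.mass is None:
            raise AssessmentError(
                "structure has unassigned atom properties; run assign_properties"
            )
        break

    keys: list[tuple[str, int]] = []
    grids: list[VoxelGrid] = []
    skipped: list[tuple[tuple[str, int], str]] = []
    for nuc in structure:
        try:
            frame = compute_local_frame(nuc)
        except FrameError as exc:
            skipped.append((nuc.key, str(exc)))
            continue
        env = extract_environment(structure, frame, config, self_nucleotide=nuc)
        grid = voxelize(env, config, frame_provenance=(
            structure.structure_id, nuc.chain_id, nuc.residue_number))
        grids.append(apply_normalization(grid, model.normalization))
        keys.append(nuc.key)
    if not grids:
        raise AssessmentError(
            f"structure {structure.structure_id!r}: no scoreable nucleotides "
            f"({len(skipped)} skipped)"
        )
    scores = predict(model, grids)
    per_nucleotide = [(key, float(s)) for key, s in zip(keys, scores)]
    if skipped:
        logger.info("score_structure(%s): skipped %d nucleotides",
                    structure.structure_id, len(skipped))
    return StructureAssessment(
        structure_id=structure.structure_id,
        per_nucleotide=per_nucleotide,
        global_score=float(sum(s for _, s in per_nucleotide)),
        skipped=skipped,
    )


def compute_saliency(model: TrainedModel, grid: VoxelGrid) -> SaliencyMap:
    """Exact gradient of the scalar output w.r.t. every input voxel value."""
    if not grid.normalized:
        raise ModelError("compute_saliency expects a normalized grid")
    gradients = model.network.input_gradient(grid.values[None])[0]
    return SaliencyMap(voxel_gradients=np.asarray(gradients, dtype=float))


def map_saliency_to_atoms(
    saliency: SaliencyMap,
    environment: list[EnvironmentAtom],
    config: FeaturizeConfig | None = None,
) -> SaliencyMap:
    """Attach to each environment atom the gradient of the voxel holding it.

    Atoms sharing a voxel share the attribution; atoms outside the cube are
    not part of the environment and receive none.
    """
    if config is None:
        config = FeaturizeConfig()
    edge = saliency.voxel_gradients.shape[1]
    attributions: list[tuple[Atom, np.ndarray]] = []
    for env in environment:
        idx = np.floor((env.local + config.half_width) / config.voxel_size).astype(int)
        if np.any(idx < 0) or np.any(idx >= edge):
            raise ModelError(
                f"atom {env.atom.name!r} maps to voxel {tuple(idx)} outside the grid"
            )
        i, j, k = idx
        attributions.append((env.atom, saliency.voxel_gradients[:, i, j, k].copy()))
    return SaliencyMap(voxel_gradients=saliency.voxel_gradients,
                       atom_attributions=attributions)
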