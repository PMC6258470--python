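"""RMSD-based unfitness labels via optimal rigid superposition.

The regression target for a nucleotide compares the assessed structure with
the native one: superpose the nucleotide's own atoms (Kabsch), then score

    raw = RMSD(surrounding atoms under that same transform) + RMSD(self).

A native structure labelled against itself scores exactly 0; the label is
invariant under any global rigid motion of either structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import LabelingError
from .featurize import FeaturizeConfig, compute_local_frame, extract_environment
from .structure_io import RnaStructure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper (det +1)
    translation: np.ndarray  # (3,)
    rmsd: float  # Å

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


@dataclass
class UnfitnessLabel:
    nucleotide_key: tuple[str, int]
    raw_score: float  # Å; surroundings RMSD + self RMSD
    self_rmsd: float
    surroundings_rmsd: float
    n_surrounding: int
    normalized: float | None = None  # filled in via NormalizationStats
    defined: bool = True


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Optimal proper rigid transform mapping point set P onto Q.

    Minimizes ``RMSD(R @ p + t, q)`` over rotations R (det +1) and
    translations t, with P and Q in correspondence.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise LabelingError(f"point sets must both be (n, 3); got {P.shape}, {Q.shape}")
    if len(P) < 3:
        raise LabelingError(f"need at least 3 points, got {len(P)}")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    deltas = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(deltas**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _matched_positions(native_nuc, assessed_nuc):
    names = [a.name for a in native_nuc.atoms
             if assessed_nuc.get_atom(a.name) is not None]
    P = np.array([assessed_nuc.get_atom(n).position for n in names])
    Q = np.array([native_nuc.get_atom(n).position for n in names])
    return names, P, Q


def nucleotide_unfitness(
    native: RnaStructure,
    assessed: RnaStructure,
    key: tuple[str, int],
    config: FeaturizeConfig | None = None,
) -> UnfitnessLabel:
    """Raw (Å-scale) unfitness label of one nucleotide of the assessed structure.

    Steps: (1) match the nucleotide's atoms by name between native and
    assessed; (2) Kabsch-superpose the assessed copy onto the native copy;
    (3) self-RMSD is that superposition RMSD; (4) the surroundings are the
    atoms inside the native nucleotide's cube (itself excluded), matched to
    assessed atoms by (chain, residue number, atom name); (5) surroundings
    RMSD is evaluated under the transform of step 2 without re-fitting;
    (6) raw = surroundings RMSD + self RMSD.
    """
    if config is None:
        config = FeaturizeConfig()
    chain_id, resnum = key
    native_nuc = native.get_nucleotide(chain_id, resnum)
    assessed_nuc = assessed.get_nucleotide(chain_id, resnum)
    if native_nuc is None or assessed_nuc is None:
        raise LabelingError(f"nucleotide {key} absent from native or assessed structure")

    names, P, Q = _matched_positions(native_nuc, assessed_nuc)
    if len(names) < 3:
        raise LabelingError(
            f"nucleotide {key}: only {len(names)} matched self atoms (need >= 3)"
        )
    sup = kabsch_superpose(P, Q)  # assessed -> native frame

    frame = compute_local_frame(native_nuc)
    env_cfg = FeaturizeConfig(half_width=config.half_width,
                              grid_edge=config.grid_edge, exclude_self=True)
    environment = extract_environment(native, frame, env_cfg,
                                      self_nucleotide=native_nuc)

    assessed_index = {
        (nuc.chain_id, nuc.residue_number, atom.name): atom.position
        for nuc, atom in assessed.iter_atoms()
    }
    native_pts, assessed_pts = [], []
    for env in environment:
        ref = (env.parent.chain_id, env.parent.residue_number, env.atom.name)
        pos = assessed_index.get(ref)
        if pos is not None:
            native_pts.append(env.atom.position)
            assessed_pts.append(pos)
    if environment and len(native_pts) < len(environment):
        logger.debug("nucleotide %s: matched %d/%d surrounding atoms",
                     key, len(native_pts), len(environment))
    if not native_pts:
        return UnfitnessLabel(nucleotide_key=key, raw_score=float("nan"),
                              self_rmsd=sup.rmsd, surroundings_rmsd=float("nan"),
                              n_surrounding=0, defined=False)

    moved = sup.apply(np.array(assessed_pts))
    deltas = moved - np.array(native_pts)
    surroundings_rmsd = float(np.sqrt(np.mean(np.sum(deltas**2, axis=1))))
    return UnfitnessLabel(
        nucleotide_key=key,
        raw_score=surroundings_rmsd + sup.rmsd,
        self_rmsd=sup.rmsd,
        surroundings_rmsd=surroundings_rmsd,
        n_surrounding=len(native_pts),
    )


def structure_rmsd(native: RnaStructure, assessed: RnaStructure) -> float:
    """All-matched-heavy-atom RMSD after one optimal global superposition."""
    native_index = {
        (nuc.chain_id, nuc.residue_number, atom.name): atom.position
        for nuc, atom in native.iter_atoms() if atom.element != "H"
    }
    P, Q = [], []
    for nuc, atom in assessed.iter_atoms():
        if atom.element == "H":
            continue
        pos = native_index.get((nuc.chain_id, nuc.residue_number, atom.name))
        if pos is not None:
            P.append(atom.position)
            Q.append(pos)
    if len(P) < 3:
        raise LabelingError(f"only {len(P)} matched heavy atoms between structures")
    return kabsch_superpose(np.array(P), np.array(Q)).rmsd
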