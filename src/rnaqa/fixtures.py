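"""Synthetic toy RNA structures and controlled decoy ensembles.

The generator builds a regular single-stranded parametric helix whose
nucleotides carry the frame-defining atoms (C1', O5', C5', N1/N9) plus a
fixed set of backbone/ribose/base placeholder atoms, all at offsets chosen
so the local-frame construction is well conditioned for every residue.
Decoys are produced by independent isotropic Gaussian displacement of every
atom, which gives a controlled, seed-reproducible deformation whose
RMSD-based labels grow monotonically with the perturbation width — the
structure a quality-assessment learner needs, without any physical realism
(no base pairing, sterics or torsional chemistry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .featurize import FeaturizeConfig, VoxelGrid, featurize_nucleotide
from .labeling import nucleotide_unfitness
from .structure_io import (
    Atom,
    AtomPropertyTable,
    Nucleotide,
    RnaStructure,
    assign_properties,
)

# Offsets (Å) of each atom from C1' in the per-residue triad
# (radial, tangential, helix-axis). "N" is the glycosidic nitrogen,
# "B1"/"B2" stand for two base ring atoms (named per base class below).
_ATOM_OFFSETS: dict[str, tuple[float, float, float]] = {
    "C1'": (0.0, 0.0, 0.0),
    "N": (-1.40, 0.30, 0.20),
    "O5'": (0.80, 1.20, -0.90),
    "C5'": (0.60, 1.40, 0.40),
    "C4'": (-0.40, -0.90, -1.40),
    "O4'": (-1.10, 0.20, -1.00),
    "C3'": (0.20, -1.60, -0.80),
    "O3'": (0.50, -2.60, -1.20),
    "C2'": (0.90, -1.00, 0.60),
    "O2'": (1.80, -1.50, 0.90),
    "P": (1.20, 2.00, -1.50),
    "B1": (-2.60, 0.90, 0.50),
    "B2": (-2.70, -0.40, 0.10),
}

# Base-ring placeholder names that exist in the default property table.
_BASE_ATOM_NAMES = {"purine": ("C8", "C4"), "pyrimidine": ("C2", "C6")}

_RESIDUE_CYCLE = ("A", "U", "G", "C")


@dataclass(frozen=True)
class DecoyGenConfig:
    n_nucleotides: int = 14
    perturbation_sigma: float = 1.0  # Å, per coordinate
    n_decoys: int = 5
    seed: int = 0
    rise_per_residue: float = 2.8  # Å
    twist_per_residue: float = 33.0  # degrees
    helix_radius: float = 9.0  # Å

    def __post_init__(self) -> None:
        if self.n_nucleotides < 1 or self.n_decoys < 1:
            raise ValueError("n_nucleotides and n_decoys must be >= 1")
        if self.perturbation_sigma < 0:
            raise ValueError("perturbation_sigma must be >= 0")


def make_toy_rna(config: DecoyGenConfig | None = None,
                 assign: bool = True) -> RnaStructure:
    """Build the parametric toy helix; every nucleotide is frame-ready.

    With ``assign`` (default) the default property table is applied so the
    structure can be featurized directly.
    """
    if config is None:
        config = DecoyGenConfig()
    twist = np.deg2rad(config.twist_per_residue)
    nucleotides = []
    for i in range(config.n_nucleotides):
        theta = i * twist
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangential = np.array([-np.sin(theta), np.cos(theta), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        c1 = config.helix_radius * radial + i * config.rise_per_residue * axial
        resname = _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
        base_class = "purine" if resname in ("A", "G") else "pyrimidine"
        atoms = []
        for name, (a, t, z) in _ATOM_OFFSETS.items():
            if name == "P" and i == 0:
                continue  # 5'-terminal residue has no phosphate
            if name == "N":
                real_name = "N9" if base_class == "purine" else "N1"
            elif name in ("B1", "B2"):
                real_name = _BASE_ATOM_NAMES[base_class][name == "B2"]
            else:
                real_name = name
            position = c1 + a * radial + t * tangential + z * axial
            element = real_name.lstrip("0123456789")[0]
            atoms.append(Atom(name=real_name, element=element, position=position))
        nucleotides.append(Nucleotide(residue_name=resname, chain_id="A",
                                      residue_number=i + 1, atoms=atoms))
    structure = RnaStructure(structure_id=f"toy_helix_n{config.n_nucleotides}",
                             nucleotides=nucleotides)
    if assign:
        structure = assign_properties(structure, AtomPropertyTable.default())
    return structure


def perturb(structure: RnaStructure, sigma: float, seed: int) -> RnaStructure:
    """Displace every atom by iid Gaussian noise (std ``sigma`` per coordinate)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    decoy = structure.copy()
    decoy.structure_id = f"{structure.structure_id}_decoy_s{sigma:g}_seed{seed}"
    if sigma > 0:
        for _, atom in decoy.iter_atoms():
            atom.position = atom.position + rng.normal(0.0, sigma, size=3)
    return decoy


def make_training_set(
    config: DecoyGenConfig | None = None,
    sigmas: Sequence[float] = (0.1, 0.5, 1.0),
    featurize_config: FeaturizeConfig | None = None,
) -> Iterator[tuple[VoxelGrid, float, tuple[str, str, int]]]:
    """Yield (raw grid, raw label Å, provenance) over all decoys and residues.

    For each sigma, ``config.n_decoys`` decoys are generated from the toy
    native with seeds derived deterministically from ``config.seed``; every
    frame-ready nucleotide of every decoy contributes one sample labelled
    against the native. Undefined labels (no matched surroundings) are
    skipped.
    """
    if config is None:
        config = DecoyGenConfig()
    if not sigmas:
        raise ValueError("need at least one sigma")
    if featurize_config is None:
        featurize_config = FeaturizeConfig()
    native = make_toy_rna(config)
    for s_index, sigma in enumerate(sigmas):
        for d_index in range(config.n_decoys):
            seed = config.seed + 1000 * s_index + d_index
            decoy = perturb(native, sigma, seed=seed)
            for nuc in decoy:
                label = nucleotide_unfitness(native, decoy, nuc.key,
                                             featurize_config)
                if not label.defined:
                    continue
                grid = featurize_nucleotide(decoy, nuc, featurize_config)
                yield grid, label.raw_score, (decoy.structure_id,
                                              nuc.chain_id, nuc.residue_number)
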