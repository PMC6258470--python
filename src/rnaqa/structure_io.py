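"""Reading, writing and property assignment for RNA structures.

PDB input is parsed with Biopython's :class:`Bio.PDB.PDBParser`; only RNA
residues (A/U/G/C plus a configurable set of modified-nucleotide aliases)
are retained. Per-atom masses and partial charges are attached from an
:class:`AtomPropertyTable`, by default the AMBER-style table shipped in
:mod:`rnaqa.atom_data`.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder
from Bio.PDB.PDBIO import PDBIO

from . import atom_data
from .errors import PdbParseError, PropertyError

logger = logging.getLogger(__name__)

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "U"})
CANONICAL_RESIDUES = PURINES | PYRIMIDINES


@dataclass
class Atom:
    """A single heavy (or hydrogen) atom with optional assigned properties."""

    name: str
    element: str
    position: np.ndarray  # (3,) in Å, global frame
    mass: float | None = None  # Da
    charge: float | None = None  # elementary charge units

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if self.mass is not None and self.mass < 0:
            raise ValueError(f"atom {self.name!r}: negative mass")


@dataclass
class Nucleotide:
    residue_name: str  # canonical A/U/G/C
    chain_id: str
    residue_number: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def base_class(self) -> str:
        return "purine" if self.residue_name in PURINES else "pyrimidine"

    @property
    def glycosidic_atom_name(self) -> str:
        return "N9" if self.base_class == "purine" else "N1"

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None


@dataclass
class RnaStructure:
    structure_id: str
    nucleotides: list[Nucleotide] = field(default_factory=list)
    model_number: int = 1

    def __iter__(self) -> Iterator[Nucleotide]:
        return iter(self.nucleotides)

    def __len__(self) -> int:
        return len(self.nucleotides)

    def get_nucleotide(self, chain_id: str, residue_number: int) -> Nucleotide | None:
        for nuc in self.nucleotides:
            if nuc.chain_id == chain_id and nuc.residue_number == residue_number:
                return nuc
        return None

    def iter_atoms(self) -> Iterator[tuple[Nucleotide, Atom]]:
        for nuc in self.nucleotides:
            for atom in nuc.atoms:
                yield nuc, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(n.atoms) for n in self.nucleotides)

    def copy(self) -> "RnaStructure":
        return RnaStructure(
            structure_id=self.structure_id,
            model_number=self.model_number,
            nucleotides=[
                Nucleotide(
                    residue_name=n.residue_name,
                    chain_id=n.chain_id,
                    residue_number=n.residue_number,
                    atoms=[
                        Atom(a.name, a.element, a.position.copy(), a.mass, a.charge)
                        for a in n.atoms
                    ],
                )
                for n in self.nucleotides
            ],
        )


@dataclass
class AtomPropertyTable:
    """Maps (residue_name, atom_name) to (mass Da, charge e).

    Atoms without a residue-specific entry fall back to their element mass
    and a charge of zero.
    """

    entries: dict[tuple[str, str], tuple[float, float]]
    element_masses: dict[str, float] = field(
        default_factory=lambda: dict(atom_data.ELEMENT_MASSES)
    )

    @classmethod
    def default(cls) -> "AtomPropertyTable":
        return cls(entries=atom_data.default_entries())

    def lookup(
        self, residue_name: str, atom_name: str, element: str
    ) -> tuple[float, float, bool]:
        """Return (mass, charge, found_in_table)."""
        entry = self.entries.get((residue_name, atom_name))
        if entry is not None:
            return entry[0], entry[1], True
        mass = self.element_masses.get(element.upper())
        if mass is None:
            raise PropertyError(
                f"no property entry for atom {atom_name!r} in residue "
                f"{residue_name!r} and unknown element {element!r}"
            )
        return mass, 0.0, False


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise PdbParseError(f"cannot infer element of atom {atom_name!r}")


def parse_pdb(
    source: Union[str, Path, TextIO],
    model_selection: int = 1,
    aliases: dict[str, str] | None = None,
    structure_id: str | None = None,
) -> RnaStructure:
    """Parse RNA residues of one model from PDB-format text.

    Parameters
    ----------
    source:
        A path, PDB-format string, or open text handle.
    model_selection:
        1-based model number (matching MODEL record serials where present).
    aliases:
        Modified-residue name -> canonical parent (default
        :data:`rnaqa.atom_data.MODIFIED_ALIASES`). Residues that are neither
        canonical nor aliased are skipped with a logged count.
    """
    if model_selection < 1:
        raise PdbParseError("model_selection must be >= 1")
    if aliases is None:
        aliases = atom_data.MODIFIED_ALIASES

    if isinstance(source, Path):
        text = source.read_text()
        sid = structure_id or source.stem
    elif isinstance(source, str):
        if "\n" not in source and Path(source).exists():
            path = Path(source)
            text = path.read_text()
            sid = structure_id or path.stem
        else:
            text = source
            sid = structure_id or "structure"
    else:
        text = source.read()
        sid = structure_id or "structure"

    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise PdbParseError("no ATOM/HETATM records found")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio_structure = parser.get_structure(sid, io.StringIO(text))

    models = list(bio_structure)
    if not models:
        raise PdbParseError("no models found")
    by_serial = {m.serial_num: m for m in models if m.serial_num}
    if model_selection in by_serial:
        model = by_serial[model_selection]
    elif model_selection <= len(models):
        model = models[model_selection - 1]
    else:
        available = sorted(by_serial) or list(range(1, len(models) + 1))
        raise PdbParseError(
            f"model {model_selection} not present; available models: {available}"
        )

    nucleotides: list[Nucleotide] = []
    n_skipped = 0
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            canonical = resname if resname in CANONICAL_RESIDUES else aliases.get(resname)
            if canonical is None:
                n_skipped += 1
                continue
            atoms = []
            for bio_atom in residue:  # disordered atoms yield highest occupancy
                name = bio_atom.get_name().strip()
                element = (bio_atom.element or "").strip() or _infer_element(name)
                atoms.append(Atom(name=name, element=element.upper(),
                                  position=np.array(bio_atom.get_coord(), dtype=float)))
            nucleotides.append(
                Nucleotide(
                    residue_name=canonical,
                    chain_id=chain.id,
                    residue_number=residue.id[1],
                    atoms=atoms,
                )
            )
    if n_skipped:
        logger.info("parse_pdb(%s): skipped %d non-RNA residues", sid, n_skipped)
    if not nucleotides:
        raise PdbParseError(f"no RNA residues found in {sid!r}")

    nucleotides.sort(key=lambda n: (n.chain_id, n.residue_number))
    return RnaStructure(structure_id=sid, nucleotides=nucleotides,
                        model_number=model_selection)


def write_pdb(structure: RnaStructure, destination: Union[str, Path, TextIO]) -> None:
    """Write a structure as a single-model PDB file via Biopython's PDBIO."""
    builder = StructureBuilder()
    builder.init_structure(structure.structure_id)
    builder.init_model(0)
    current_chain = None
    serial = 1
    for nuc in structure.nucleotides:
        if nuc.chain_id != current_chain:
            builder.init_chain(nuc.chain_id)
            current_chain = nuc.chain_id
        builder.init_seg("    ")
        builder.init_residue(nuc.residue_name, " ", nuc.residue_number, " ")
        for atom in nuc.atoms:
            fullname = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            builder.init_atom(
                atom.name, np.asarray(atom.position, dtype="f"), 0.0, 1.0, " ",
                fullname, serial, element=atom.element,
            )
            serial += 1
    pdb_io = PDBIO()
    pdb_io.set_structure(builder.get_structure())
    if isinstance(destination, (str, Path)):
        pdb_io.save(str(destination))
    else:
        pdb_io.save(destination)


def assign_properties(
    structure: RnaStructure,
    table: AtomPropertyTable | None = None,
    heavy_atoms_only: bool = True,
) -> RnaStructure:
    """Return a copy with masses/charges attached (and hydrogens dropped).

    Atoms missing from the table use the element-mass fallback with charge 0;
    their count is logged. Idempotent.
    """
    if table is None:
        table = AtomPropertyTable.default()
    result = structure.copy()
    n_fallback = 0
    n_hydrogens = 0
    for nuc in result.nucleotides:
        kept: list[Atom] = []
        for atom in nuc.atoms:
            is_hydrogen = atom.element == "H" or (
                not atom.element and atom.name.lstrip("0123456789").startswith("H")
            )
            if heavy_atoms_only and is_hydrogen:
                n_hydrogens += 1
                continue
            mass, charge, found = table.lookup(nuc.residue_name, atom.name, atom.element)
            if not found:
                n_fallback += 1
            atom.mass = mass
            atom.charge = charge
            kept.append(atom)
        nuc.atoms = kept
    if n_hydrogens:
        logger.info("assign_properties(%s): dropped %d hydrogens",
                    result.structure_id, n_hydrogens)
    if n_fallback:
        logger.info("assign_properties(%s): %d atoms used element-mass fallback",
                    result.structure_id, n_fallback)
    return result


def write_score_report(
    per_nucleotide_scores: Sequence[tuple],
    global_score: float,
    destination: Union[str, Path, TextIO],
) -> None:
    """Write a TSV report of per-nucleotide scores plus a global-score line.

    Rows are ``(chain_id, residue_number, score)`` or
    ``(chain_id, residue_number, residue_name, score)`` tuples. The global
    score must equal the sum of the rows to accumulation tolerance.
    """
    if not per_nucleotide_scores:
        raise ValueError("empty score list")
    rows = []
    for record in per_nucleotide_scores:
        if len(record) == 3:
            chain, resnum, score = record
            resname = "."
        elif len(record) == 4:
            chain, resnum, resname, score = record
        else:
            raise ValueError(f"bad score record: {record!r}")
        rows.append((chain, resnum, resname, float(score)))
    total = sum(r[3] for r in rows)
    if abs(total - global_score) > 1e-9 * max(1, len(rows)):
        raise ValueError(
            f"global score {global_score!r} does not match row sum {total!r}"
        )

    def _emit(handle: TextIO) -> None:
        handle.write("chain\tresnum\tresname\tunfitness_score\n")
        for chain, resnum, resname, score in rows:
            handle.write(f"{chain}\t{resnum}\t{resname}\t{score:.6f}\n")
        handle.write(f"GLOBAL\t.\t.\t{global_score:.6f}\n")

    if isinstance(destination, (str, Path)):
        with open(destination, "w") as handle:
            _emit(handle)
    else:
        _emit(destination)


def write_json_summary(
    structure_id: str,
    n_nucleotides: int,
    global_score: float,
    destination: Union[str, Path, TextIO],
) -> None:
    """Write the compact JSON summary of a structure assessment."""
    payload = {
        "structure_id": structure_id,
        "n_nucleotides": int(n_nucleotides),
        "global_score": float(global_score),
    }
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(json.dumps(payload, indent=2) + "\n")
    else:
        json.dump(payload, destination, indent=2)
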