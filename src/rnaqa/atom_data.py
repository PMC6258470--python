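"""Default per-atom masses and partial charges for RNA heavy atoms.

Masses are standard atomic masses in Da. Partial charges (in units of the
elementary charge e) follow the AMBER-family RNA point-charge conventions;
they are shipped as a self-contained default so that the charge channel of
the voxel featurization is populated without any external force-field
installation. The table covers every heavy atom of the four canonical
ribonucleotides A, U, G, C including the 5'-phosphate group.
"""

from __future__ import annotations

# Element -> mass in Da. Used as fallback when an atom has no residue-specific
# entry (channel 1) and to sanity-check parsed elements.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.01,
    "N": 14.01,
    "O": 16.00,
    "P": 30.97,
    "S": 32.06,
    "MG": 24.31,
    "K": 39.10,
    "NA": 22.99,
}

# Backbone + ribose charges shared by all four residues.
_BACKBONE_CHARGES: dict[str, float] = {
    "P": 1.1662,
    "OP1": -0.7760,
    "OP2": -0.7760,
    "O5'": -0.4989,
    "C5'": 0.0558,
    "C4'": 0.1065,
    "O4'": -0.3548,
    "C3'": 0.2022,
    "O3'": -0.5246,
    "C2'": 0.0670,
    "O2'": -0.6139,
    "C1'": 0.0394,
}

# Base charges per residue.
_BASE_CHARGES: dict[str, dict[str, float]] = {
    "A": {
        "N9": -0.0251, "C8": 0.2006, "N7": -0.6073, "C5": 0.0515,
        "C6": 0.7009, "N6": -0.9019, "N1": -0.7615, "C2": 0.5875,
        "N3": -0.6997, "C4": 0.3053,
    },
    "G": {
        "N9": 0.0492, "C8": 0.1374, "N7": -0.5709, "C5": 0.1744,
        "C6": 0.4770, "O6": -0.5597, "N1": -0.4787, "C2": 0.7657,
        "N2": -0.9672, "N3": -0.6323, "C4": 0.1222,
    },
    "C": {
        "N1": -0.0484, "C2": 0.7538, "O2": -0.6252, "N3": -0.7584,
        "C4": 0.8185, "N4": -0.9530, "C5": -0.5215, "C6": 0.0053,
    },
    "U": {
        "N1": 0.0418, "C2": 0.4687, "O2": -0.5477, "N3": -0.3549,
        "C4": 0.5952, "O4": -0.5761, "C5": -0.3635, "C6": -0.1126,
    },
}


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def default_entries() -> dict[tuple[str, str], tuple[float, float]]:
    """(residue_name, atom_name) -> (mass Da, charge e) for canonical RNA."""
    entries: dict[tuple[str, str], tuple[float, float]] = {}
    for res, base in _BASE_CHARGES.items():
        for name, q in {**_BACKBONE_CHARGES, **base}.items():
            entries[(res, name)] = (ELEMENT_MASSES[_element_of(name)], q)
    return entries


# Modified-nucleotide residue names mapped to their canonical parent.
MODIFIED_ALIASES: dict[str, str] = {
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "DHU": "U",
    "5MC": "C", "OMC": "C",
    "1MA": "A", "MIA": "A", "OMA": "A",
    "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "YG": "G",
}
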