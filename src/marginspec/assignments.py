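"""Static band-assignment lookup for PC loading interpretation.

Positions (cm^-1) and biochemical assignments of the vibrational bands of
soft tissue relevant to tumor/margin discrimination, compiled from the
standard FT-IR and Raman tissue literature.  Matching is nearest-entry
within a tolerance; anything farther is reported "unassigned".
"""

from __future__ import annotations

import numpy as np

from .core import Modality

__all__ = ["assign_band", "ASSIGNMENTS"]

# (wavenumber, class, description)
_FTIR = [
    (1047, "carbohydrate", "C-O stretch, glycogen/carbohydrates"),
    (1085, "nucleic_acid", "PO2- symmetric stretch"),
    (1165, "lipid", "C-O ester / CH bend"),
    (1240, "protein", "Amide III"),
    (1282, "protein", "Amide III"),
    (1340, "protein", "CH2 wag"),
    (1400, "protein", "COO- symmetric stretch"),
    (1455, "mixed", "CH2/CH3 bend, proteins and lipids"),
    (1466, "lipid", "CH2 scissoring"),
    (1547, "protein", "Amide II"),
    (1631, "protein", "Amide I, beta-sheet"),
    (1656, "protein", "Amide I, random coil/alpha"),
    (1669, "protein", "Amide I, anti-parallel beta-sheet"),
    (1746, "lipid", "ester C=O stretch (triacylglycerols)"),
    (2854, "lipid", "CH2 symmetric stretch"),
    (2874, "protein", "CH3 symmetric stretch"),
    (2924, "lipid", "CH2 asymmetric stretch"),
    (2960, "protein", "CH3 asymmetric stretch"),
    (3290, "protein", "Amide A (N-H stretch)"),
]

_RAMAN = [
    (621, "protein", "phenylalanine C-C twist"),
    (643, "protein", "tyrosine C-C twist"),
    (744, "nucleic_acid", "thymine ring breathing (DNA)"),
    (792, "nucleic_acid", "DNA backbone O-P-O"),
    (855, "protein", "tyrosine ring breathing / proline"),
    (939, "protein", "C-C backbone stretch (alpha-helix)"),
    (973, "lipid", "=CH bend"),
    (1003, "protein", "phenylalanine ring breathing"),
    (1032, "protein", "phenylalanine C-H in-plane"),
    (1066, "mixed", "C-C stretch, proteins and lipids"),
    (1082, "lipid", "C-C gauche stretch"),
    (1129, "mixed", "C-C trans stretch, proteins and lipids"),
    (1164, "protein", "C-C / C-N stretch"),
    (1209, "protein", "tryptophan/phenylalanine C-C6H5"),
    (1241, "protein", "Amide III"),
    (1275, "protein", "Amide III (alpha)"),
    (1302, "lipid", "CH2 twist"),
    (1339, "protein", "CH deformation"),
    (1366, "lipid", "CH3 symmetric bend"),
    (1438, "lipid", "CH2 scissoring"),
    (1621, "mixed", "C=C stretch"),
    (1655, "lipid", "C=C olefinic stretch (unsaturated TAG)"),
    (1676, "protein", "Amide I, beta-sheet"),
    (1748, "lipid", "ester C=O stretch"),
    (2853, "lipid", "CH2 symmetric stretch"),
    (2889, "lipid", "CH2 asymmetric stretch"),
    (2949, "protein", "CH3 stretch"),
    (2978, "protein", "CH3 asymmetric stretch"),
]

ASSIGNMENTS = {Modality.FTIR: _FTIR, Modality.RAMAN: _RAMAN}


def assign_band(
    wavenumber: float, modality: Modality | str, tol: float = 8.0
) -> tuple[str, str]:
    """Nearest-entry assignment within ``tol`` cm^-1.

    Returns ``(class, description)``; ``("unassigned", "")`` if no table
    entry is close enough.
    """
    table = ASSIGNMENTS[Modality.coerce(modality)]
    positions = np.array([row[0] for row in table], dtype=float)
    i = int(np.argmin(np.abs(positions - wavenumber)))
    if abs(positions[i] - wavenumber) > tol:
        return "unassigned", ""
    return table[i][1], table[i][2]
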