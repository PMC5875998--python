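"""Pinned atomic masses and natural isotope abundances.

Values are the IUPAC/CIAAW 2013 recommendations (monoisotopic masses in Da,
abundances as mole fractions). They are bundled as data, rather than taken
from an external library, so that mass arithmetic and simulated isotope
envelopes never drift with a dependency upgrade.

``ISOTOPES[element]`` lists ``(mass, abundance)`` pairs sorted by mass; the
first entry of ``MONOISOTOPIC`` is the mass of the *most abundant* isotope,
which defines the monoisotopic mass convention used throughout.
"""

from __future__ import annotations

# Mass of a bare proton (Da). Protonation/deprotonation adducts use this,
# not the hydrogen-atom mass: the electron stays behind.
PROTON_MASS = 1.00727646
# Hydrogen atom mass, used for hydrogen-rearrangement shifts in fragments.
H_ATOM_MASS = 1.0078250319
ELECTRON_MASS = 0.00054858

# element -> [(isotope mass, abundance), ...] sorted by increasing mass
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017780, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315000, 0.00038), (17.9991604000, 0.00205)],
    "F": [(18.9984031630, 1.0)],
    "Na": [(22.9897692800, 1.0)],
    "Mg": [(23.9850417000, 0.7899), (24.9858370200, 0.1000), (25.9825930400, 0.1101)],
    "Si": [(27.9769265327, 0.92223), (28.9764946530, 0.04685), (29.9737701710, 0.03092)],
    "P": [(30.9737615100, 1.0)],
    "S": [
        (31.9720706900, 0.9499),
        (32.9714585000, 0.0075),
        (33.9678668300, 0.0425),
        (35.9670808800, 0.0001),
    ],
    "Cl": [(34.9688527100, 0.7576), (36.9659026000, 0.2424)],
    "K": [(38.9637064900, 0.932581), (39.9639982000, 0.000117), (40.9618252600, 0.067302)],
    "Br": [(78.9183376000, 0.5069), (80.9162910000, 0.4931)],
    "I": [(126.9044680000, 1.0)],
}

#: element -> mass of its most abundant isotope (Da)
MONOISOTOPIC: dict[str, float] = {
    el: max(isos, key=lambda t: t[1])[0] for el, isos in ISOTOPES.items()
}

#: halogens, for ring-double-bond-equivalent arithmetic
HALOGENS = frozenset({"F", "Cl", "Br", "I"})

#: standard valence used by the RDBE plausibility filter
VALENCE: dict[str, int] = {
    "H": 1, "C": 4, "N": 3, "O": 2, "P": 3, "S": 2, "Si": 4,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "Na": 1, "K": 1, "Mg": 2,
}
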