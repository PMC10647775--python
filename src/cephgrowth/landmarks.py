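"""Landmark and measurement definitions for 2-D lateral cephalometry.

The package works with the 26 skeletal landmarks routinely traced on a
lateral cephalometric radiograph, plus the 13 linear (inter-landmark
distance) and 17 angular (inter-line angle) parameters built from them.
Coordinates live in a sella-centred frame: after normalization the sella is
the origin and the nasion lies on the positive x-axis (the anterior cranial
base, S–N, defines the horizontal). x increases anteriorly, y superiorly,
so most facial structures have negative y.
"""

from __future__ import annotations

# Canonical landmark order; every (26, 2) coordinate array follows it.
LANDMARKS: tuple[str, ...] = (
    "sella",
    "porion",
    "basion",
    "nasion",
    "orbitale",
    "A_point",
    "pogonion",
    "B_point",
    "PNS",
    "ANS",
    "R1",
    "R3",
    "articulare",
    "menton",
    "mx1_incisor_superius",
    "mx1_root",
    "md1_incisor_inferius",
    "md1_root",
    "occlusal_plane",
    "mx6_distal",
    "mx6_root",
    "md6_distal",
    "md6_root",
    "gnathion",
    "gonion",
    "condylion",
)

LANDMARK_INDEX: dict[str, int] = {name: i for i, name in enumerate(LANDMARKS)}

# Linear parameters: name -> (landmark, landmark); value = Euclidean distance (mm).
LINEAR_PARAMS: dict[str, tuple[str, str]] = {
    "N-S": ("nasion", "sella"),
    "N-Ba": ("nasion", "basion"),
    "S-Ba": ("sella", "basion"),
    "N-ANS": ("nasion", "ANS"),
    "S-Gn": ("sella", "gnathion"),
    "Ar-Go": ("articulare", "gonion"),
    "Ar-Me": ("articulare", "menton"),
    "Go-Me": ("gonion", "menton"),
    "N-Me": ("nasion", "menton"),
    "ANS-Me": ("ANS", "menton"),
    "Gn-Cd": ("gnathion", "condylion"),
    "Pog-Go": ("pogonion", "gonion"),
    "Cd-Go": ("condylion", "gonion"),
}

# Angular parameters: name -> ((from, to), (from, to)); value = unsigned angle
# in [0, 180] degrees between the two directed segments.
ANGULAR_PARAMS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "Convexity": (("nasion", "A_point"), ("A_point", "pogonion")),
    "A-B_plane": (("A_point", "B_point"), ("nasion", "pogonion")),
    "SNA": (("sella", "nasion"), ("nasion", "A_point")),
    "SNB": (("sella", "nasion"), ("nasion", "B_point")),
    "ANB": (("nasion", "A_point"), ("nasion", "B_point")),
    "N-Pog_to_SN": (("nasion", "pogonion"), ("sella", "nasion")),
    "Nasal_floor_to_SN": (("ANS", "PNS"), ("sella", "nasion")),
    "NSBa": (("nasion", "sella"), ("sella", "basion")),
    "NSAr": (("nasion", "sella"), ("sella", "articulare")),
    "NSGn": (("nasion", "sella"), ("sella", "gnathion")),
    "ArGoMe": (("articulare", "gonion"), ("menton", "gonion")),
    "Mandibular_pl_to_SN": (("gonion", "menton"), ("sella", "nasion")),
    "Gonial_angle": (("articulare", "gonion"), ("gonion", "menton")),
    "U1_to_SN": (("mx1_root", "mx1_incisor_superius"), ("sella", "nasion")),
    "L1_to_mandibular_pl": (("md1_root", "md1_incisor_inferius"), ("menton", "gonion")),
    "Interincisal_angle": (
        ("mx1_root", "mx1_incisor_superius"),
        ("md1_root", "md1_incisor_inferius"),
    ),
    "Occlusal_pl_to_SN": (("mx1_incisor_superius", "occlusal_plane"), ("sella", "nasion")),
}

LINEAR_NAMES: tuple[str, ...] = tuple(LINEAR_PARAMS)
ANGULAR_NAMES: tuple[str, ...] = tuple(ANGULAR_PARAMS)

#: Ages covered by one longitudinal series (annual films, mixed to early
#: permanent dentition period).
AGES: tuple[int, ...] = (6, 7, 8, 9, 10, 11, 12, 13)
INPUT_AGES: tuple[int, ...] = (6, 7, 8, 9, 10, 11, 12)
TARGET_AGE: int = 13
#: Ages that every subject must have on film (series are anchored at both ends).
REQUIRED_AGES: frozenset[int] = frozenset({6, 12, 13})
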