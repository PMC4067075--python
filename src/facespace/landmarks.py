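"""Facial landmark schemes.

Two ordered constellations are used throughout the package:

* ``C9`` -- the nine salient inner-face points returned by base face
  detectors: the medial and lateral canthi of both eyes, the left and
  right subnasale, the columella, and the lateral midpoints of the
  vermilion border (mouth corners).
* ``C36`` -- the full 36-point mesh covering the supra-orbital ridge
  (8 points), the eyes (8), the nose (7), the mouth (6) and the jaw
  line (7).

Coordinates are 0-based pixels, origin at the top-left corner, x
rightward and y downward.  "Left"/"right" refer to the image (viewer)
side, not the subject's anatomical side.

The canonical template below is expressed in template units (roughly
pixels for a face ~100 units tall) centred near the origin; renderers
position it inside an image through a pose transform.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# C36 scheme: names, anatomical groups, template coordinates
# ---------------------------------------------------------------------------

C36_NAMES: tuple[str, ...] = (
    # supra-orbital ridge (brows), left to right
    "brow_l_outer", "brow_l_upper", "brow_l_inner", "brow_l_end",
    "brow_r_end", "brow_r_inner", "brow_r_upper", "brow_r_outer",
    # eyes
    "eye_l_lateral_canthus", "eye_l_upper_lid", "eye_l_medial_canthus",
    "eye_l_lower_lid",
    "eye_r_medial_canthus", "eye_r_upper_lid", "eye_r_lateral_canthus",
    "eye_r_lower_lid",
    # nose
    "nasion", "nose_tip", "ala_l", "ala_r",
    "subnasale_l", "columella", "subnasale_r",
    # mouth
    "mouth_l_corner", "upper_lip_mid", "mouth_r_corner", "lower_lip_mid",
    "upper_vermilion_l", "upper_vermilion_r",
    # jaw
    "zygoma_l", "gonion_l", "mental_l", "chin_mid",
    "mental_r", "gonion_r", "zygoma_r",
)

#: anatomical groups as half-open index ranges into the C36 ordering
C36_GROUPS: dict[str, range] = {
    "supraorbital": range(0, 8),
    "eyes": range(8, 16),
    "nose": range(16, 23),
    "mouth": range(23, 29),
    "jaw": range(29, 36),
}

#: canonical 36-point layout (template units, y downward)
C36_TEMPLATE = np.array(
    [
        # supra-orbital ridge
        (-35.0, -32.0), (-25.0, -36.0), (-15.0, -36.0), (-7.0, -31.0),
        (7.0, -31.0), (15.0, -36.0), (25.0, -36.0), (35.0, -32.0),
        # eyes
        (-32.0, -18.0), (-23.0, -22.0), (-14.0, -18.0), (-23.0, -14.0),
        (14.0, -18.0), (23.0, -22.0), (32.0, -18.0), (23.0, -14.0),
        # nose
        (0.0, -16.0), (0.0, 6.0), (-11.0, 8.0), (11.0, 8.0),
        (-6.0, 12.0), (0.0, 13.0), (6.0, 12.0),
        # mouth
        (-16.0, 28.0), (0.0, 23.0), (16.0, 28.0), (0.0, 33.0),
        (-8.0, 25.0), (8.0, 25.0),
        # jaw
        (-42.0, -2.0), (-34.0, 26.0), (-18.0, 44.0), (0.0, 50.0),
        (18.0, 44.0), (34.0, 26.0), (42.0, -2.0),
    ]
)

#: left/right index swap under horizontal mirroring (C36, 0-based)
_C36_MIRROR_PAIRS = [
    (0, 7), (1, 6), (2, 5), (3, 4),
    (8, 14), (9, 13), (10, 12), (11, 15),
    (18, 19), (20, 22),
    (23, 25), (27, 28),
    (29, 35), (30, 34), (31, 33),
]

# ---------------------------------------------------------------------------
# C9 scheme
# ---------------------------------------------------------------------------

#: indices of the nine C9 points inside the C36 ordering
C9_IN_C36: tuple[int, ...] = (8, 10, 12, 14, 20, 21, 22, 23, 25)

C9_NAMES: tuple[str, ...] = tuple(C36_NAMES[i] for i in C9_IN_C36)

_C9_MIRROR_PAIRS = [(0, 3), (1, 2), (4, 6), (7, 8)]


def _swap_map(n: int, pairs: list[tuple[int, int]]) -> np.ndarray:
    m = np.arange(n)
    for a, b in pairs:
        m[a], m[b] = b, a
    return m


#: permutation applied to point indices when an image is mirrored
C36_MIRROR_MAP = _swap_map(36, _C36_MIRROR_PAIRS)
C9_MIRROR_MAP = _swap_map(9, _C9_MIRROR_PAIRS)

SCHEMES = {"C9": 9, "C36": 36}


def scheme_names(scheme: str) -> tuple[str, ...]:
    if scheme == "C9":
        return C9_NAMES
    if scheme == "C36":
        return C36_NAMES
    raise ValueError(f"unknown scheme {scheme!r}")


def mirror_map(scheme: str) -> np.ndarray:
    if scheme == "C9":
        return C9_MIRROR_MAP
    if scheme == "C36":
        return C36_MIRROR_MAP
    raise ValueError(f"unknown scheme {scheme!r}")
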