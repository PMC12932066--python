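"""Anatomical coordinate frames and block-face naming.

All meshes in this package live in a patient-anatomical Cartesian frame in
millimetres.  The default is LPS (+x left, +y posterior, +z superior), the
DICOM patient convention; RAS (+x right, +y anterior, +z superior) is also
accepted.  Anatomical face names of an axis-aligned block (``superior``,
``anterior``, ``left-lateral``, ...) resolve to ``(axis, sign)`` pairs through
the frame tag carried on every mesh, so the rest of the pipeline never
hard-codes an axis.
"""

from __future__ import annotations

# face -> (axis index, direction sign) for each supported frame tag.
_FACE_MAPS: dict[str, dict[str, tuple[int, int]]] = {
    "LPS": {
        "left-lateral": (0, +1),
        "right-lateral": (0, -1),
        "posterior": (1, +1),
        "anterior": (1, -1),
        "superior": (2, +1),
        "inferior": (2, -1),
    },
    "RAS": {
        "right-lateral": (0, +1),
        "left-lateral": (0, -1),
        "anterior": (1, +1),
        "posterior": (1, -1),
        "superior": (2, +1),
        "inferior": (2, -1),
    },
}

#: Deterministic priority used to break ties between equidistant approach
#: faces (closest-face ranking is otherwise purely geometric).
TIE_BREAK_ORDER = ("superior", "posterior", "left-lateral", "right-lateral")

FACE_NAMES = tuple(_FACE_MAPS["LPS"])


def face_axis(face: str, frame_label: str = "LPS") -> tuple[int, int]:
    """Return ``(axis, sign)`` of an anatomical face of an axis-aligned block.

    ``sign=+1`` means the face at the maximum coordinate along ``axis``.
    """
    try:
        faces = _FACE_MAPS[frame_label]
    except KeyError:
        raise ValueError(
            f"unknown frame label {frame_label!r}; supported: {sorted(_FACE_MAPS)}"
        ) from None
    try:
        return faces[face]
    except KeyError:
        raise ValueError(
            f"unknown anatomical face {face!r}; supported: {sorted(faces)}"
        ) from None


def inward_normal(face: str, frame_label: str = "LPS"):
    """Unit vector pointing from the named block face into the block."""
    import numpy as np

    axis, sign = face_axis(face, frame_label)
    n = np.zeros(3)
    n[axis] = -sign
    return n
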