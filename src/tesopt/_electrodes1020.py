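"""Idealized 10-20 electrode directions on a unit sphere.

Coordinate frame: +x right, +y anterior, +z superior, origin at the head
centre.  The ten outer-circumference electrodes (Fp1/2, F7/8, T7/8, P7/8,
O1/2) sit on the equator of the upper hemisphere at the standard 10% / 20%
arc spacings; midline and central electrodes sit on the sagittal and coronal
meridians; F3/F4 and P3/P4 are placed at the great-circle midpoints of their
neighbouring standard positions, which is the usual spherical-head
construction.
"""

from __future__ import annotations

import numpy as np

_S = np.sqrt(0.5)


def _equator(azimuth_deg: float) -> np.ndarray:
    a = np.deg2rad(azimuth_deg)
    return np.array([np.cos(a), np.sin(a), 0.0])


def _arc_mid(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    v = p + q
    return v / np.linalg.norm(v)


_FZ = np.array([0.0, _S, _S])
_PZ = np.array([0.0, -_S, _S])
_F7 = _equator(144.0)
_F8 = _equator(36.0)
_P7 = _equator(216.0)
_P8 = _equator(324.0)

# Canonical ordering used throughout the package (19 scalp positions,
# ground/reference excluded).
ELECTRODE_DIRECTIONS: dict[str, np.ndarray] = {
    "Fp1": _equator(108.0),
    "Fp2": _equator(72.0),
    "F7": _F7,
    "F3": _arc_mid(_FZ, _F7),
    "Fz": _FZ,
    "F4": _arc_mid(_FZ, _F8),
    "F8": _F8,
    "T7": _equator(180.0),
    "C3": np.array([-_S, 0.0, _S]),
    "Cz": np.array([0.0, 0.0, 1.0]),
    "C4": np.array([_S, 0.0, _S]),
    "T8": _equator(0.0),
    "P7": _P7,
    "P3": _arc_mid(_PZ, _P7),
    "Pz": _PZ,
    "P4": _arc_mid(_PZ, _P8),
    "P8": _P8,
    "O1": _equator(252.0),
    "O2": _equator(288.0),
}

ELECTRODE_NAMES: tuple[str, ...] = tuple(ELECTRODE_DIRECTIONS)

# Outer radius of the adult head the 3 cm sponge geometry refers to; sponge
# footprints on smaller phantoms are scaled by (outer radius / this) so the
# angular coverage of each electrode matches the physical device.
REFERENCE_HEAD_RADIUS_MM = 92.0
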