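"""Approximate extended 10-20 sensor layout on the unit sphere.

Head frame: +x right, +y anterior (nose), +z vertex. Each sensor is stored as
(name, inclination from vertex in degrees, azimuth from the nose in degrees,
positive toward the right ear). The angles approximate the 32-channel extended
international 10-20 montage; only the qualitative geometry matters for the
synthetic forward model.
"""

from __future__ import annotations

import numpy as np

# (name, inclination_deg, azimuth_deg)
SENSOR_ANGLES_32: list[tuple[str, float, float]] = [
    ("Fp1", 90, -18), ("Fp2", 90, 18),
    ("AF3", 74, -22), ("AF4", 74, 22),
    ("F7", 90, -54), ("F3", 62, -39), ("Fz", 45, 0), ("F4", 62, 39), ("F8", 90, 54),
    ("FC5", 72, -69), ("FC1", 32, -45), ("FC2", 32, 45), ("FC6", 72, 69),
    ("T7", 90, -90), ("C3", 45, -90), ("Cz", 0, 0), ("C4", 45, 90), ("T8", 90, 90),
    ("CP5", 72, -111), ("CP1", 32, -135), ("CP2", 32, 135), ("CP6", 72, 111),
    ("P7", 90, -126), ("P3", 62, -141), ("Pz", 45, 180), ("P4", 62, 141), ("P8", 90, 126),
    ("PO3", 74, -158), ("PO4", 74, 158),
    ("O1", 90, -162), ("Oz", 90, 180), ("O2", 90, 162),
]

SENSOR_NAMES_32: list[str] = [name for name, _, _ in SENSOR_ANGLES_32]


def sensor_positions(names_and_angles=None) -> tuple[list[str], np.ndarray]:
    """Unit-sphere Cartesian positions for the 32-channel layout.

    Returns ``(names, positions)`` with positions of shape (n_sensors, 3).
    """
    table = SENSOR_ANGLES_32 if names_and_angles is None else names_and_angles
    names = [t[0] for t in table]
    inc = np.radians([t[1] for t in table])
    azi = np.radians([t[2] for t in table])
    pos = np.column_stack(
        [np.sin(inc) * np.sin(azi), np.sin(inc) * np.cos(azi), np.cos(inc)]
    )
    return names, pos
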