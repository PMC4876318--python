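"""Scattering geometry, reciprocal-space frames and the Ewald intersection circle.

Coordinate conventions used throughout the package
--------------------------------------------------
Laboratory frame (right-handed):

* ``x_L`` along the incident beam,
* ``y_L`` vertical, up on the detector,
* ``z_L`` horizontal-transverse.

The detector azimuth ``chi`` is measured counterclockwise as seen from the
source looking downstream, with ``chi = 0`` along ``+z_L`` (horizontal) and
``chi = 90 deg`` along ``+y_L`` (vertical up).

Body (lamella) frame: the fibre lamella lies in the body ``x–z`` plane.  The
lamella is carried into the laboratory by ``R(alpha, beta) = R_x(-beta) ·
R_z(alpha)``: ``alpha`` tilts the lamella plane within the laboratory ``x–y``
plane (rotation about ``z_L``) and ``beta`` rotates it about the beam axis.
The signs are fixed by the observable behaviour of the azimuthal profile:
positive ``alpha`` strengthens the upper (``chi = 90 deg``) peak and positive
``beta`` shifts both peaks toward larger ``chi``.

All angles are degrees at public interfaces; radians are used internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GeometryError",
    "ScatteringGeometry",
    "wavenumber",
    "ewald_ring_point",
    "rotation_matrix",
    "body_to_lab",
    "lab_to_body",
]


class GeometryError(ValueError):
    """Raised for unphysical or incomplete scattering geometries."""


@dataclass(frozen=True)
class ScatteringGeometry:
    """Wavelength, reflection ring and (optional) flat-detector calibration.

    Parameters
    ----------
    wavelength : float
        X-ray wavelength in Angstrom.
    q_ring : float
        Magnitude of the scattering vector of the reflection being analysed,
        in inverse Angstrom (for alpha-chitin (110), ``2*pi/d_110``).
    detector_distance : float, optional
        Sample-to-detector distance in mm.
    beam_centre : tuple of float, optional
        Beam centre ``(x_px, y_px)`` in pixels; x is the horizontal
        (column) axis, y the vertical (row) axis with rows counted downward.
    pixel_size : float, optional
        Square pixel edge in mm.
    """

    wavelength: float
    q_ring: float
    detector_distance: float | None = None
    beam_centre: tuple[float, float] | None = None
    pixel_size: float | None = None

    def __post_init__(self):
        if not self.wavelength > 0:
            raise GeometryError(f"wavelength must be > 0, got {self.wavelength}")
        if not self.q_ring > 0:
            raise GeometryError(f"q_ring must be > 0, got {self.q_ring}")
        if self.q_ring >= 2.0 * self.k:
            raise GeometryError(
                f"q_ring = {self.q_ring} exceeds the 2k = {2 * self.k:.4f} limit: "
                "the reflection cannot intersect the Ewald sphere"
            )

    @property
    def k(self) -> float:
        """Wavenumber ``2*pi/wavelength`` in inverse Angstrom."""
        return 2.0 * np.pi / self.wavelength

    @property
    def has_detector(self) -> bool:
        return (
            self.detector_distance is not None
            and self.beam_centre is not None
            and self.pixel_size is not None
        )

    @classmethod
    def from_d_spacing(cls, wavelength: float, d_spacing: float, **kwargs):
        """Build a geometry from a lattice d-spacing (Angstrom)."""
        if not d_spacing > 0:
            raise GeometryError(f"d_spacing must be > 0, got {d_spacing}")
        return cls(wavelength=wavelength, q_ring=2.0 * np.pi / d_spacing, **kwargs)

    # -- flat key=value configuration files --------------------------------

    @classmethod
    def from_file(cls, path) -> "ScatteringGeometry":
        """Read a flat ``key = value`` geometry file.

        Recognised keys: ``wavelength_A``, ``q_ring_invA`` *or*
        ``d_spacing_A``, ``distance_mm``, ``beam_centre_x_px``,
        ``beam_centre_y_px``, ``pixel_size_mm``.
        """
        values: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = float(raw)
        if "wavelength_A" not in values:
            raise GeometryError(f"{path}: missing required key wavelength_A")
        if "q_ring_invA" in values:
            q_ring = values["q_ring_invA"]
        elif "d_spacing_A" in values:
            q_ring = 2.0 * np.pi / values["d_spacing_A"]
        else:
            raise GeometryError(f"{path}: need q_ring_invA or d_spacing_A")
        centre = None
        if "beam_centre_x_px" in values and "beam_centre_y_px" in values:
            centre = (values["beam_centre_x_px"], values["beam_centre_y_px"])
        return cls(
            wavelength=values["wavelength_A"],
            q_ring=q_ring,
            detector_distance=values.get("distance_mm"),
            beam_centre=centre,
            pixel_size=values.get("pixel_size_mm"),
        )

    def to_file(self, path) -> None:
        lines = [
            f"wavelength_A = {self.wavelength!r}",
            f"q_ring_invA = {self.q_ring!r}",
        ]
        if self.detector_distance is not None:
            lines.append(f"distance_mm = {self.detector_distance!r}")
        if self.beam_centre is not None:
            lines.append(f"beam_centre_x_px = {self.beam_centre[0]!r}")
            lines.append(f"beam_centre_y_px = {self.beam_centre[1]!r}")
        if self.pixel_size is not None:
            lines.append(f"pixel_size_mm = {self.pixel_size!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    def replace(self, **kwargs) -> "ScatteringGeometry":
        return replace(self, **kwargs)


def wavenumber(geometry: ScatteringGeometry) -> float:
    """Return ``k = 2*pi/wavelength`` (inverse Angstrom)."""
    return geometry.k


def ewald_ring_point(chi, geometry: ScatteringGeometry) -> np.ndarray:
    """Laboratory-frame q on the Ewald/reflection-sphere intersection circle.

    For elastic scattering the locus of measurable (110) scattering vectors
    is the circle where the Ewald sphere (radius ``k``, centred at ``-k``
    along the beam) cuts the reflection sphere of radius ``q_ring``.  Every
    point of that circle shares the beam-axis component

    ``qx_L = -q_ring**2 / (2 k)``

    (the Ewald curvature offset; it is what breaks the 180-degree symmetry
    of the azimuthal profile), while the transverse component of magnitude
    ``sqrt(q_ring**2 - qx_L**2)`` rotates with the detector azimuth.

    Parameters
    ----------
    chi : array_like
        Detector azimuth(s) in degrees; any real value, wrapped mod 360.
    geometry : ScatteringGeometry

    Returns
    -------
    ndarray, shape ``chi.shape + (3,)``
        Laboratory-frame ``(qx, qy, qz)`` with ``|q| = q_ring``.
    """
    q = geometry.q_ring
    qx = -q * q / (2.0 * geometry.k)  # strictly negative; chi-independent
    q_perp = np.sqrt(q * q - qx * qx)
    c = np.deg2rad(np.asarray(chi, dtype=float))
    return np.stack(
        [np.broadcast_to(qx, c.shape), q_perp * np.sin(c), q_perp * np.cos(c)],
        axis=-1,
    )


def rotation_matrix(alpha: float, beta: float) -> np.ndarray:
    """Body-to-laboratory rotation ``R = R_x(-beta) @ R_z(alpha)`` (degrees)."""
    a = np.deg2rad(alpha)
    b = np.deg2rad(-beta)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cb, -sb], [0.0, sb, cb]])
    return rx @ rz


def body_to_lab(q_body, alpha: float, beta: float) -> np.ndarray:
    """Rotate body-frame vector(s) ``(..., 3)`` into the laboratory frame."""
    r = rotation_matrix(alpha, beta)
    return np.asarray(q_body, dtype=float) @ r.T


def lab_to_body(q_lab, alpha: float, beta: float) -> np.ndarray:
    """Rotate laboratory-frame vector(s) ``(..., 3)`` into the body frame.

    Exact inverse of :func:`body_to_lab` (orthogonal transform).
    """
    r = rotation_matrix(alpha, beta)
    return np.asarray(q_lab, dtype=float) @ r
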