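"""Reference geometry and parameter sets for stomatopod telson cuticle.

The beamline geometry (0.6888 Angstrom microfocus beam, 262.3 mm
sample-to-detector distance, Pilatus-class pixels) and the fitted
two-family orientation parameters at four representative carina locations
(I: exocuticle centreline, II/III: flanks left/right of the centreline,
IV: endocuticle centre) are shipped as ready-made inputs for examples,
synthetic-data generation and self-tests.  ``lambda`` scales are stored as
fractions, so ``op.scale`` equals the out-of-plane volume-fraction proxy
``lambda2/(lambda1+lambda2)`` directly.
"""

from __future__ import annotations

from .geometry import ScatteringGeometry
from .model import FibreDistribution, LamellaModel, TwoFamilyModel

__all__ = [
    "CHITIN_D110_A",
    "default_geometry",
    "TELSON_CARINA",
]

#: Literature d-spacing of the alpha-chitin (110) reflection (Angstrom).
CHITIN_D110_A = 4.6


def default_geometry(
    d_spacing: float = CHITIN_D110_A,
    with_detector: bool = True,
) -> ScatteringGeometry:
    """Microfocus WAXD geometry used throughout the examples and tests."""
    kwargs = {}
    if with_detector:
        kwargs = dict(
            detector_distance=262.3,
            beam_centre=(309.0, 243.0),  # (x = column, y = row) pixels
            pixel_size=0.172,
        )
    return ScatteringGeometry.from_d_spacing(0.6888, d_spacing, **kwargs)


def _loc(ip, op):
    (a1, b1, g1, d1, l1), (a2, b2, g2, d2, l2) = ip, op
    return TwoFamilyModel(
        ip=LamellaModel(a1, b1, FibreDistribution(g1, d1), scale=l1),
        op=LamellaModel(a2, b2, FibreDistribution(g2, d2), scale=l2),
    )


#: Two-family orientation parameters at four carina locations
#: (alpha, beta, gamma0, dgamma0 in degrees; scale = lambda fraction).
TELSON_CARINA: dict[str, TwoFamilyModel] = {
    "I": _loc((0.4, 4.7, 20.0, 83.0, 0.82), (2.2, -87.2, 88.5, 10.0, 0.18)),
    "II": _loc((1.0, 15.1, -40.0, 75.0, 0.66), (-0.5, -81.0, 75.0, 10.1, 0.34)),
    "III": _loc((0.2, -17.5, -39.1, 89.3, 0.73), (8.5, 80.0, -55.0, 24.0, 0.27)),
    "IV": _loc((1.0, 3.4, -47.6, 50.0, 0.61), (-19.0, -86.8, 67.3, 10.2, 0.39)),
}
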