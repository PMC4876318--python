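"""Azimuthal intensity profiles and their plain-text serialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AzimuthalProfile", "read_profile", "write_profile"]


@dataclass
class AzimuthalProfile:
    """Sampled azimuthal intensity ``I(chi)`` around the (110) ring.

    ``chi`` in degrees, strictly increasing, spanning at most one full turn;
    ``intensity`` in detector counts (NaN marks bins with no pixels);
    ``sigma`` optional per-bin count uncertainties.
    """

    chi: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.chi = np.asarray(self.chi, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.chi.ndim != 1 or self.chi.shape != self.intensity.shape:
            raise ValueError("chi and intensity must be 1-D arrays of equal length")
        if self.chi.size >= 2:
            if np.any(np.diff(self.chi) <= 0):
                raise ValueError("chi must be strictly increasing")
            if self.chi[-1] - self.chi[0] > 360.0:
                raise ValueError("chi must span at most 360 degrees")
        finite = self.intensity[np.isfinite(self.intensity)]
        if finite.size and np.any(finite < 0):
            raise ValueError("intensity counts must be non-negative")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.chi.shape:
                raise ValueError("sigma must match chi in length")
            fin = self.sigma[np.isfinite(self.sigma)]
            if fin.size and np.any(fin <= 0):
                raise ValueError("sigma values must be positive")

    def __len__(self) -> int:
        return self.chi.size

    def dropna(self) -> "AzimuthalProfile":
        """Return a copy without the bins marked missing (NaN intensity)."""
        keep = np.isfinite(self.intensity)
        return AzimuthalProfile(
            self.chi[keep],
            self.intensity[keep],
            None if self.sigma is None else self.sigma[keep],
            list(self.warnings),
        )


def write_profile(profile: AzimuthalProfile, path) -> None:
    """Write a two- or three-column ``chi_deg intensity [sigma]`` text file."""
    cols = [profile.chi, profile.intensity]
    header = "chi_deg intensity"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        header += " sigma"
    np.savetxt(path, np.column_stack(cols), header=header)


def read_profile(path) -> AzimuthalProfile:
    data = np.loadtxt(Path(path), ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (chi, intensity)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return AzimuthalProfile(data[:, 0], data[:, 1], sigma)
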