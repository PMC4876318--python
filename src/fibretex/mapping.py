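"""Batch fitting of scan grids and export of fibre-orientation maps.

Each scan point is fitted independently (no spatial regularization, so the
map is an unbiased per-voxel readout; an optional neighbour-seeded warm
start is available for smooth fields).  The result is one table row per
grid point with the Table-style parameter columns, the out-of-plane volume
fraction and diagnostics; failed points are flagged, never dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitConfig, fit_profile
from .geometry import ScatteringGeometry, rotation_matrix
from .model import TwoFamilyModel
from .synthetic import ScanDataset, ScanPoint

__all__ = ["fit_scan", "export_map", "read_map", "lamella_glyphs"]

_MAP_COLUMNS = [
    "x_mm", "y_mm",
    "ip_alpha", "ip_beta", "ip_gamma0", "ip_dgamma0", "ip_lambda",
    "op_alpha", "op_beta", "op_gamma0", "op_dgamma0", "op_lambda",
    "ip_lambda_fraction", "op_lambda_fraction",
    "background", "rss", "redchi", "converged", "flags", "error",
]


def _point_profile(point: ScanPoint, geometry, regroup_kwargs):
    if point.profile is not None:
        return point.profile
    if point.image is not None:
        from .detector import azimuthal_regroup

        kwargs = dict(
            q_lo=geometry.q_ring - 0.05, q_hi=geometry.q_ring + 0.05, n_chi=360
        )
        kwargs.update(regroup_kwargs or {})
        return azimuthal_regroup(point.image, geometry, **kwargs)
    raise ValueError("scan point carries neither a profile nor an image")


def fit_scan(
    scan,
    geometry: ScatteringGeometry,
    config: FitConfig | None = None,
    n_families: int = 2,
    regroup_kwargs: dict | None = None,
    warm_start: bool = False,
) -> pd.DataFrame:
    """Fit every point of a scan; returns one row per point.

    ``scan`` is a :class:`~fibretex.synthetic.ScanDataset` or an iterable
    of ``(x_mm, y_mm, AzimuthalProfile)``.  With ``warm_start`` the
    previous point's solution seeds the next fit (off by default to keep
    points independent).
    """
    config = config or FitConfig()
    if isinstance(scan, ScanDataset):
        points = list(scan.points)
    else:
        points = [ScanPoint(x_mm=x, y_mm=y, profile=p) for x, y, p in scan]
    if not points:
        raise ValueError("scan has no points")
    rows = []
    n_failed = 0
    previous = None
    for point in points:
        row = {"x_mm": point.x_mm, "y_mm": point.y_mm, "error": ""}
        try:
            profile = _point_profile(point, geometry, regroup_kwargs)
            initial = None
            if warm_start and previous is not None:
                initial = TwoFamilyModel(
                    ip=previous.ip, op=previous.op, background=previous.background
                )
            result = fit_profile(profile, geometry, config, n_families, initial=initial)
            if warm_start:
                previous = result
            row.update(result.to_row())
        except Exception as exc:  # flagged, not dropped
            n_failed += 1
            row.update({c: np.nan for c in _MAP_COLUMNS if c not in row})
            row["converged"] = False
            row["flags"] = "failed"
            row["error"] = str(exc)
        rows.append(row)
    if n_failed == len(points):
        raise RuntimeError("every scan point failed to fit")
    return pd.DataFrame(rows, columns=_MAP_COLUMNS)


def lamella_glyphs(map_table: pd.DataFrame) -> pd.DataFrame:
    """Per-point lamella glyph descriptions for external 3D rendering.

    For each fitted point: the lamella centre, the unit plane normal
    implied by ``(alpha, beta)``, the in-plane principal fibre direction
    implied by ``gamma0``, and a glyph width proportional to ``dgamma0``.
    """
    rows = []
    for _, r in map_table.iterrows():
        if not np.isfinite(r.get("ip_alpha", np.nan)):
            continue
        rot = rotation_matrix(r.ip_alpha, r.ip_beta)
        normal = rot @ np.array([0.0, 1.0, 0.0])  # body y = lamella normal
        g = np.deg2rad(r.ip_gamma0)
        fibre = rot @ np.array([np.cos(g), 0.0, -np.sin(g)])
        rows.append(
            {
                "x_mm": r.x_mm, "y_mm": r.y_mm,
                "normal_x": normal[0], "normal_y": normal[1], "normal_z": normal[2],
                "fibre_x": fibre[0], "fibre_y": fibre[1], "fibre_z": fibre[2],
                "width": r.ip_dgamma0,
            }
        )
    return pd.DataFrame(rows)


_FORMATS = ("table", "glyphs")


def export_map(map_table: pd.DataFrame, path, format: str = "table") -> Path:
    """Write the orientation map as a delimited table or a glyph mesh file."""
    if map_table.empty:
        raise ValueError("refusing to export an empty map table")
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}: supported are {_FORMATS}")
    path = Path(path)
    if format == "table":
        map_table.to_csv(path, sep="\t", index=False, na_rep="nan")
    else:
        lamella_glyphs(map_table).to_csv(path, sep="\t", index=False)
    return path


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("flags", "error"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df
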