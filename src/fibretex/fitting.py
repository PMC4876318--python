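"""Estimation of two-family 3D orientation parameters from I(chi).

The measured azimuthal profile is fitted to
:func:`fibretex.model.two_family_profile` — eleven parameters: tilts
``alpha, beta``, distribution ``gamma0, dgamma0`` and scale ``lambda`` for
each of the in-plane and out-of-plane families, plus a constant background
— by bounded Levenberg-Marquardt-style least squares (trust-region
reflective through lmfit), with peak-based initialization and a multistart
over principal-direction seeds.  A brute-force grid search over the angular
parameters with scales solved linearly at each node is provided as a slow
cross-check oracle.

Identifiability conventions for reported parameters: ``gamma0`` in
``(-90, 90]`` (apolar fibrils make ``gamma0`` and ``gamma0 + 180``
identical); in-plane ``beta`` in ``[-45, 45]``; out-of-plane ``beta`` in
``[-90, -60] U [60, 90]``, fitted internally on the continuous interval
``[60, 120]`` and mapped back through the exact model symmetry
``(alpha, beta, gamma0) == (-alpha, beta - 180, -gamma0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy import signal

from .geometry import ScatteringGeometry
from .model import (
    FibreDistribution,
    LamellaModel,
    TwoFamilyModel,
    beta_smoothed_profile,
    two_family_profile,
)
from .profiles import AzimuthalProfile

__all__ = [
    "FitConfig",
    "FitResult",
    "Peak",
    "detect_peaks",
    "peak_separation",
    "halfmax_arc",
    "initialize",
    "fit_profile",
    "grid_fit",
    "op_volume_fraction",
]

MIN_SAMPLES = 36
NEAR_ISOTROPIC_DGAMMA0 = 85.0  # above this, gamma0 is weakly identifiable


@dataclass(frozen=True)
class Peak:
    position: float  # deg, sub-bin refined
    height: float
    width: float  # FWHM estimate, deg


@dataclass
class FitConfig:
    """Bounds, multistart and convergence settings for :func:`fit_profile`.

    ``op_beta`` bounds are given on the internal continuous interval
    ``[60, 120]`` equivalent to ``60 <= |beta| <= 90`` after
    canonicalization.
    """

    alpha_bounds: tuple[float, float] = (-30.0, 30.0)
    ip_beta_bounds: tuple[float, float] = (-45.0, 45.0)
    op_beta_bounds: tuple[float, float] = (60.0, 120.0)
    gamma0_bounds: tuple[float, float] = (-180.0, 180.0)
    dgamma0_bounds: tuple[float, float] = (3.0, 90.0)
    n_starts: int = 8
    n_hops: int = 6
    delta_beta_deg: float = 5.0
    n_kernel: int = 11
    seed: int = 0
    max_nfev: int = 4000
    explore_nfev: int = 300

    def __post_init__(self):
        for name in ("alpha", "ip_beta", "op_beta", "gamma0", "dgamma0"):
            lo, hi = getattr(self, f"{name}_bounds")
            if not lo < hi:
                raise ValueError(f"{name}_bounds: lower must be < upper")


@dataclass
class FitResult:
    """Recovered two-family parameters with fit diagnostics."""

    ip: LamellaModel
    op: LamellaModel
    background: float
    rss: float
    redchi: float
    stderr: dict[str, float | None]
    converged: bool
    flags: list[str] = field(default_factory=list)
    nfev: int = 0

    @property
    def op_volume_fraction(self) -> float:
        return op_volume_fraction(self)

    def to_row(self) -> dict:
        """Flat dict with the Table-style column names."""
        row = {}
        for prefix, fam in (("ip", self.ip), ("op", self.op)):
            row[f"{prefix}_alpha"] = fam.alpha
            row[f"{prefix}_beta"] = fam.beta
            row[f"{prefix}_gamma0"] = fam.distribution.gamma0
            row[f"{prefix}_dgamma0"] = fam.distribution.dgamma0
            row[f"{prefix}_lambda"] = fam.scale
        total = self.ip.scale + self.op.scale
        row["ip_lambda_fraction"] = self.ip.scale / total if total > 0 else np.nan
        row["op_lambda_fraction"] = self.op.scale / total if total > 0 else np.nan
        row["background"] = self.background
        row["rss"] = self.rss
        row["redchi"] = self.redchi
        row["converged"] = self.converged
        row["flags"] = ";".join(self.flags)
        return row


def op_volume_fraction(result: FitResult) -> float:
    """Out-of-plane volume-fraction proxy ``lambda2 / (lambda1 + lambda2)``."""
    total = result.ip.scale + result.op.scale
    if total <= 0:
        raise ValueError("both family scales are zero: fraction undefined")
    return result.op.scale / total


# --------------------------------------------------------------------------
# peak measurements


def _wrap180(x):
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def detect_peaks(profile: AzimuthalProfile, prominence_frac: float = 0.05):
    """Circular local-maxima detection, sorted by height (descending).

    Peaks must rise above ``prominence_frac`` of the intensity range; the
    0/360 seam is handled by tiling.  Positions are refined to sub-bin
    accuracy by a parabola through the three bins around each maximum.
    """
    prof = profile.dropna()
    y = prof.intensity
    if y.size < 3:
        return []
    rng = float(y.max() - y.min())
    if rng <= 0:
        return []
    step = float(np.mean(np.diff(prof.chi)))
    tiled = np.concatenate([y, y, y])
    idx, props = signal.find_peaks(tiled, prominence=prominence_frac * rng)
    widths = signal.peak_widths(tiled, idx, rel_height=0.5)[0] * step
    n = y.size
    peaks = []
    for i, w in zip(idx, widths):
        if not (n <= i < 2 * n):
            continue
        y0, y1, y2 = tiled[i - 1], tiled[i], tiled[i + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        pos = (prof.chi[i - n] + delta * step) % 360.0
        height = y1 - 0.25 * (y0 - y2) * delta
        peaks.append(Peak(float(pos), float(height), float(w)))
    peaks.sort(key=lambda p: -p.height)
    return peaks


def _antipodal_partner(peaks, p1: Peak, rel_tol: float = 1e-6):
    """Strongest peak in the half-circle opposite ``p1``.

    Ties within ``rel_tol`` relative height (a floating-point degeneracy of
    exactly symmetric profiles) are broken toward the antipode
    ``p1 + 180``, where the physically paired intersection lies.
    """
    candidates = [p for p in peaks if 90.0 < (p.position - p1.position) % 360.0 < 270.0]
    if not candidates:
        return None
    hmax = max(p.height for p in candidates)
    near = [p for p in candidates if p.height >= hmax * (1.0 - rel_tol)]
    return min(near, key=lambda p: abs(_wrap180(p.position - p1.position - 180.0)))


def peak_separation(chi, intensity, prominence_frac: float = 0.05) -> float:
    """Azimuthal separation (deg) between the two main profile maxima.

    Measured as the circular distance from the lower-chi peak to the
    higher-chi peak through increasing chi; exactly 180 for an untilted
    single family with ``gamma0 = 0``, below 180 for positive ``gamma0``.
    """
    prof = AzimuthalProfile(np.asarray(chi, float), np.asarray(intensity, float))
    peaks = detect_peaks(prof, prominence_frac)
    if len(peaks) < 2:
        raise ValueError("fewer than two peaks detected")
    p1 = peaks[0]
    p2 = _antipodal_partner(peaks, p1)
    if p2 is None:
        raise ValueError("no partner peak in the opposite half-circle")
    lo, hi = sorted((p1.position, p2.position))
    return hi - lo


def halfmax_arc(chi, intensity) -> float:
    """Total arc length (deg) where the profile is at or above half-maximum.

    Robust lobe-width measure: for a two-lobe profile half of this value is
    the full-width at half maximum of one lobe, and it remains well defined
    when the sharp-ring notch splits a lobe in two.
    """
    y = np.asarray(intensity, dtype=float)
    step = float(np.mean(np.diff(np.asarray(chi, dtype=float))))
    return float(np.count_nonzero(y >= y.max() / 2.0) * step)


# --------------------------------------------------------------------------
# initialization


def _family_pairs(peaks, max_pairs: int = 2):
    """Greedy pairing of peaks into fibre-family candidates.

    A family contributes two peaks separated by roughly 180 degrees with
    similar heights and widths; candidate pairs are scored by the weaker
    peak's height, down-weighted by width dissimilarity and by distance of
    the separation from 180 degrees.
    """
    scored = []
    for i, p in enumerate(peaks):
        for q in peaks[i + 1:]:
            sep = abs(_wrap180(q.position - p.position - 180.0))
            if sep > 45.0:
                continue
            wsim = min(p.width, q.width) / max(p.width, q.width)
            score = min(p.height, q.height) * wsim * np.exp(-((sep / 30.0) ** 2))
            scored.append((score, p, q))
    scored.sort(key=lambda t: -t[0])
    pairs = []
    for _, p, q in scored:
        if len(pairs) >= max_pairs:
            break
        used = [r for pair in pairs for r in pair]
        if any(abs(_wrap180(r.position - s.position)) < 15.0 for r in (p, q) for s in used):
            continue
        pairs.append((p, q))
    return pairs


_WIDTH_TABLES: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _width_table(geometry: ScatteringGeometry, delta_beta: float, n_kernel: int):
    """Lobe FWHM of the untilted single-family profile vs dgamma0 (cached)."""
    key = (round(geometry.wavelength, 6), round(geometry.q_ring, 6), delta_beta, n_kernel)
    if key not in _WIDTH_TABLES:
        chi = np.arange(0.0, 360.0, 0.5)
        dgammas = np.arange(5.0, 90.1, 2.5)
        widths = np.empty_like(dgammas)
        for i, dg in enumerate(dgammas):
            lam = LamellaModel(0.0, 0.0, FibreDistribution(0.0, dg))
            inten = beta_smoothed_profile(chi, lam, geometry, delta_beta, n_kernel)
            widths[i] = halfmax_arc(chi, inten) / 2.0
        _WIDTH_TABLES[key] = (dgammas, widths)
    return _WIDTH_TABLES[key]


def _dgamma0_from_width(width: float, geometry, delta_beta, n_kernel) -> float:
    dgammas, widths = _width_table(geometry, delta_beta, n_kernel)
    # widths decrease with dgamma0; invert on the reversed (increasing) axis
    val = np.interp(width, widths[::-1], dgammas[::-1])
    return float(np.clip(val, 3.0, 90.0))


def _gamma0_from_separation(sep: float, geometry: ScatteringGeometry) -> float:
    """Invert the untilted peak-separation relation for a gamma0 seed."""
    q = geometry.q_ring
    qx = -q * q / (2.0 * geometry.k)
    q_perp = np.sqrt(q * q - qx * qx)
    chi_up = np.deg2rad((360.0 - sep) / 2.0)
    g0 = np.degrees(np.arctan2(qx, q_perp * np.cos(chi_up)))
    return float((g0 + 90.0) % 180.0 - 90.0)


def _merge_lobes(peaks, radius: float = 30.0):
    """Cluster detected maxima into lobes.

    The sharp-ring notch can split one family lobe into two flanking
    sub-peaks (and, near the pole degeneracy, into a forest of spikes);
    peaks within ``radius`` degrees are merged into a single lobe whose
    position is the height-weighted circular mean of its members.
    """
    lobes: list[list[Peak]] = []
    for p in sorted(peaks, key=lambda p: -p.height):
        for members in lobes:
            centre = _cluster_position(members)
            if abs(_wrap180(p.position - centre)) <= radius:
                members.append(p)
                break
        else:
            lobes.append([p])
    merged = []
    for members in lobes:
        pos = _cluster_position(members)
        span = max(abs(_wrap180(m.position - pos)) for m in members)
        width = 2.0 * span + float(np.mean([m.width for m in members]))
        merged.append(Peak(pos, max(m.height for m in members), width))
    merged.sort(key=lambda p: -p.height)
    return merged


def _cluster_position(members) -> float:
    ang = np.deg2rad([m.position for m in members])
    w = np.array([m.height for m in members])
    return float(
        np.degrees(np.arctan2(np.sum(w * np.sin(ang)), np.sum(w * np.cos(ang)))) % 360.0
    )


def _pair_seed(pair, profile, geometry, config, is_op: bool):
    """Translate one antipodal lobe pair into family-parameter seeds."""
    lo, hi = sorted(pair, key=lambda p: p.position)
    beta = (lo.position + hi.position) / 2.0 - 180.0
    gamma0 = _gamma0_from_separation(hi.position - lo.position, geometry)
    # upper peak = nearer 90 + beta; its excess height signals positive alpha
    d_lo = abs(_wrap180(lo.position - (90.0 + beta)))
    d_hi = abs(_wrap180(hi.position - (90.0 + beta)))
    up, dn = (lo, hi) if d_lo <= d_hi else (hi, lo)
    alpha = 4.0 * (up.height - dn.height) / (up.height + dn.height)
    width = (lo.width + hi.width) / 2.0
    dgamma0 = _dgamma0_from_width(width, geometry, config.delta_beta_deg, config.n_kernel)
    alpha = float(np.clip(alpha, *config.alpha_bounds))
    if is_op:
        if beta < 0.0:  # map onto the internal [60, 120] branch
            beta, alpha, gamma0 = beta + 180.0, -alpha, -gamma0
        beta = float(np.clip(beta, *config.op_beta_bounds))
    else:
        beta = float(np.clip(beta, *config.ip_beta_bounds))
    dist = FibreDistribution(gamma0, dgamma0)
    return LamellaModel(alpha, beta, dist, scale=1.0), max(up.height, dn.height)


def _neutral_family(is_op: bool) -> LamellaModel:
    beta = 90.0 if is_op else 0.0
    return LamellaModel(0.0, beta, FibreDistribution(0.0, 45.0), scale=1.0)


def _scaled(fam: LamellaModel, target_height: float, geometry, config) -> LamellaModel:
    chi = np.arange(0.0, 360.0, 2.0)
    unit = beta_smoothed_profile(
        chi, fam.replace(scale=1.0), geometry, config.delta_beta_deg, config.n_kernel
    )
    peak = float(unit.max())
    return fam.replace(scale=target_height / peak if peak > 0 else 0.0)


def initialize(
    profile: AzimuthalProfile,
    geometry: ScatteringGeometry,
    config: FitConfig | None = None,
    n_families: int = 2,
) -> TwoFamilyModel:
    """Heuristic starting model from detected peak pairs.

    Antipodal peak pairs are assigned to families by width (broad pair ->
    in-plane, sharp pair -> out-of-plane); ``beta`` from the pair's mean
    position, ``gamma0`` from its separation, ``alpha`` from the height
    asymmetry and ``dgamma0`` by inverting the forward model's
    width-vs-dgamma0 relation.  Fewer than two peaks returns a neutral seed.
    """
    config = config or FitConfig()
    lobes = _merge_lobes(detect_peaks(profile)[:10])
    baseline = float(np.nanmin(profile.intensity)) if len(profile) else 0.0
    pairs = _family_pairs(lobes)
    if not pairs:
        ip = _scaled(
            _neutral_family(False), max(1.0, float(np.nanmax(profile.intensity, initial=1.0)) - baseline), geometry, config
        ) if len(profile) else _neutral_family(False)
        op = _neutral_family(True).replace(scale=ip.scale * 0.1)
        return TwoFamilyModel(ip=ip, op=op, background=max(baseline, 0.0))
    if len(pairs) == 2:
        # broader pair -> in-plane Bouligand stack
        w0 = sum(p.width for p in pairs[0])
        w1 = sum(p.width for p in pairs[1])
        ip_pair, op_pair = (pairs[0], pairs[1]) if w0 >= w1 else (pairs[1], pairs[0])
        ip, h_ip = _pair_seed(ip_pair, profile, geometry, config, is_op=False)
        op, h_op = _pair_seed(op_pair, profile, geometry, config, is_op=True)
    else:
        ip, h_ip = _pair_seed(pairs[0], profile, geometry, config, is_op=False)
        op, h_op = _neutral_family(True), 0.1 * h_ip
    ip = _scaled(ip, max(h_ip - baseline, 1e-12), geometry, config)
    op = _scaled(op, max(h_op - baseline, 1e-12), geometry, config)
    if n_families == 1:
        op = op.replace(scale=0.0)
    return TwoFamilyModel(ip=ip, op=op, background=max(baseline, 0.0))


# --------------------------------------------------------------------------
# nonlinear fit

_PARAM_NAMES = (
    "ip_alpha",
    "ip_beta",
    "ip_gamma0",
    "ip_dgamma0",
    "ip_scale",
    "op_alpha",
    "op_beta",
    "op_gamma0",
    "op_dgamma0",
    "op_scale",
    "background",
)


def _model_from_params(p) -> TwoFamilyModel:
    return TwoFamilyModel(
        ip=LamellaModel(
            p["ip_alpha"].value,
            p["ip_beta"].value,
            FibreDistribution(p["ip_gamma0"].value, p["ip_dgamma0"].value),
            scale=max(p["ip_scale"].value, 0.0),
        ),
        op=LamellaModel(
            p["op_alpha"].value,
            p["op_beta"].value,
            FibreDistribution(p["op_gamma0"].value, p["op_dgamma0"].value),
            scale=max(p["op_scale"].value, 0.0),
        ),
        background=max(p["background"].value, 0.0),
    )


def _make_params(seed: TwoFamilyModel, config: FitConfig, n_families: int):
    p = lmfit.Parameters()

    def clip(v, lo, hi):
        return float(np.clip(v, lo + 1e-9, hi - 1e-9))

    for prefix, fam, beta_bounds in (
        ("ip", seed.ip, config.ip_beta_bounds),
        ("op", seed.op, config.op_beta_bounds),
    ):
        if prefix == "op" and fam.beta < 0.0:
            # map the canonical negative-beta representation onto the
            # internal continuous branch via the exact model symmetry
            fam = LamellaModel(
                -fam.alpha,
                fam.beta + 180.0,
                FibreDistribution(
                    -fam.distribution.gamma0,
                    fam.distribution.dgamma0,
                    fam.distribution.wrapped,
                ),
                scale=fam.scale,
            )
        vary = prefix == "ip" or n_families == 2
        p.add(f"{prefix}_alpha", clip(fam.alpha, *config.alpha_bounds),
              min=config.alpha_bounds[0], max=config.alpha_bounds[1], vary=vary)
        p.add(f"{prefix}_beta", clip(fam.beta, *beta_bounds),
              min=beta_bounds[0], max=beta_bounds[1], vary=vary)
        p.add(f"{prefix}_gamma0", clip(fam.distribution.gamma0, *config.gamma0_bounds),
              min=config.gamma0_bounds[0], max=config.gamma0_bounds[1], vary=vary)
        p.add(f"{prefix}_dgamma0", clip(fam.distribution.dgamma0, *config.dgamma0_bounds),
              min=config.dgamma0_bounds[0], max=config.dgamma0_bounds[1], vary=vary)
        p.add(f"{prefix}_scale", max(fam.scale, 0.0), min=0.0,
              vary=vary)
    p.add("background", max(seed.background, 0.0), min=0.0)
    return p


def _canonical_family(alpha, beta, gamma0, dgamma0, scale, is_op: bool) -> LamellaModel:
    if is_op and beta > 90.0:
        alpha, beta, gamma0 = -alpha, beta - 180.0, -gamma0
    gamma0 = (gamma0 + 90.0) % 180.0 - 90.0
    return LamellaModel(alpha, beta, FibreDistribution(gamma0, dgamma0), scale=scale)


def fit_profile(
    profile: AzimuthalProfile,
    geometry: ScatteringGeometry,
    config: FitConfig | None = None,
    n_families: int = 2,
    initial: TwoFamilyModel | None = None,
) -> FitResult:
    """Weighted bounded least-squares fit of the two-family forward model.

    Uncertainties default to ``sqrt(max(I, 1))`` (Poisson counting).  The
    fit is restarted from ``config.n_starts`` principal-direction seeds in
    addition to the peak-based initialization (and ``initial``, if given);
    the best minimum is kept and the procedure is deterministic for a
    fixed ``config.seed``.
    """
    config = config or FitConfig()
    prof = profile.dropna()
    if len(prof) < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {len(prof)}")
    y = prof.intensity
    if float(np.ptp(y)) == 0.0:
        raise ValueError("degenerate profile: zero intensity variance")
    sigma = prof.sigma if prof.sigma is not None else np.sqrt(np.maximum(y, 1.0))
    chi = prof.chi

    def residual(params):
        model = _model_from_params(params)
        pred = two_family_profile(
            chi, model, geometry, config.delta_beta_deg, config.n_kernel
        )
        return (pred - y) / sigma

    seed_model = initialize(prof, geometry, config, n_families)
    rng = np.random.default_rng(config.seed)
    phase = rng.uniform(-90.0, 90.0, size=2)
    starts = [seed_model]
    if initial is not None:
        starts.insert(0, initial)
    for j in range(config.n_starts):
        g_ip = (phase[0] + j * 180.0 / config.n_starts + 90.0) % 180.0 - 90.0
        g_op = (phase[1] - j * 180.0 / config.n_starts + 90.0) % 180.0 - 90.0
        starts.append(
            TwoFamilyModel(
                ip=seed_model.ip.replace(
                    distribution=FibreDistribution(
                        g_ip, seed_model.ip.distribution.dgamma0
                    )
                ),
                op=seed_model.op.replace(
                    distribution=FibreDistribution(
                        g_op, seed_model.op.distribution.dgamma0
                    )
                ),
                background=seed_model.background,
            )
        )

    nfev = 0

    def run(params, max_nfev):
        nonlocal nfev
        res = lmfit.minimize(
            residual, params, method="least_squares", max_nfev=max_nfev
        )
        nfev += res.nfev
        return res

    perfect = 1e-6 * len(prof)  # only a noiseless profile reaches this
    families = ("ip", "op") if n_families == 2 else ("ip",)

    # stage 1: cheap exploratory runs from every seed
    best = None
    for start in starts:
        params = _make_params(start, config, n_families)
        try:
            res = run(params, config.explore_nfev)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    # stage 2: polish the best start to full tolerance
    res = run(best.params.copy(), config.max_nfev)
    if res.chisqr < best.chisqr:
        best = res

    # stage 3: block-coordinate family sweeps — re-seed one family's
    # principal direction (and, for the out-of-plane family, its tilt
    # branch) with the other family frozen, then polish jointly
    for _ in range(3):
        if best.chisqr <= perfect:
            break
        improved = False
        for prefix in families:
            frozen = [n for n in best.params if not n.startswith(prefix)]
            reseeds = [{"gamma0": g0} for g0 in np.arange(-78.75, 90.0, 22.5)]
            reseeds += [{"dgamma0": dg} for dg in (5.0, 15.0, 30.0, 60.0)]
            if prefix == "op":
                reseeds += [
                    {"gamma0": g0, "beta": b0}
                    for g0 in (-67.5, -22.5, 22.5, 67.5)
                    for b0 in (65.0, 85.0, 105.0)
                ]
            for reseed in reseeds:
                params = best.params.copy()
                for name in frozen:
                    params[name].vary = False
                for key, val in reseed.items():
                    par = params[f"{prefix}_{key}"]
                    par.value = float(np.clip(val, par.min + 1e-6, par.max - 1e-6))
                try:
                    res = run(params, 800)
                except Exception:
                    continue
                if res.chisqr < best.chisqr * 0.999:
                    joint = res.params.copy()
                    for name in joint:
                        joint[name].vary = best.params[name].vary
                    res = run(joint, config.max_nfev)
                    if res.chisqr < best.chisqr:
                        best = res
                        improved = True
        if not improved:
            break

    # stage 4: seeded perturbation restarts escape residual local minima of
    # the multimodal landscape around the Ewald-pole degeneracy
    hop_scale = {"alpha": 3.0, "beta": 8.0, "gamma0": 15.0, "dgamma0": 10.0}
    for _ in range(config.n_hops):
        if best.chisqr <= perfect:
            break
        params = best.params.copy()
        for prefix in families:
            for name, s in hop_scale.items():
                par = params[f"{prefix}_{name}"]
                par.value = float(
                    np.clip(par.value + rng.normal(0.0, s), par.min + 1e-6, par.max - 1e-6)
                )
        try:
            res = run(params, config.max_nfev)
        except Exception:
            continue
        if res.chisqr < best.chisqr:
            best = res

    p = best.params
    flags = []
    if not best.success:
        flags.append("not-converged")
    ip = _canonical_family(
        p["ip_alpha"].value, p["ip_beta"].value, p["ip_gamma0"].value,
        p["ip_dgamma0"].value, p["ip_scale"].value, is_op=False,
    )
    op = _canonical_family(
        p["op_alpha"].value, p["op_beta"].value, p["op_gamma0"].value,
        p["op_dgamma0"].value, p["op_scale"].value, is_op=True,
    )
    for prefix, fam in (("ip", ip), ("op", op)):
        if fam.distribution.dgamma0 > NEAR_ISOTROPIC_DGAMMA0:
            flags.append(f"{prefix}-near-isotropic")
    stderr = {name: p[name].stderr for name in _PARAM_NAMES}
    ndata = len(prof)
    nvar = sum(1 for name in _PARAM_NAMES if p[name].vary)
    redchi = best.chisqr / max(ndata - nvar, 1)
    return FitResult(
        ip=ip,
        op=op,
        background=max(p["background"].value, 0.0),
        rss=float(np.sum((two_family_profile(
            chi, _model_from_params(p), geometry, config.delta_beta_deg, config.n_kernel
        ) - y) ** 2)),
        redchi=float(redchi),
        stderr=stderr,
        converged=bool(best.success),
        flags=flags,
        nfev=nfev,
    )


# --------------------------------------------------------------------------
# brute-force grid oracle


def grid_fit(
    profile: AzimuthalProfile,
    geometry: ScatteringGeometry,
    grid_resolution: float,
    config: FitConfig | None = None,
    max_nodes: int = 10_000_000,
) -> FitResult:
    """Exhaustive single-family search over (alpha, beta, gamma0, dgamma0).

    At each node the scale and background are solved by weighted linear
    least squares (non-negativity enforced).  Intended as a slow oracle for
    :func:`fit_profile`; requests above ``max_nodes`` nodes are refused with
    a sizing message.  A two-family exhaustive search squares the node count
    and is always refused at useful resolutions — fit the dominant family
    or use :func:`fit_profile`.
    """
    if grid_resolution < 1.0:
        raise ValueError("grid_resolution must be >= 1 degree (coarse oracle)")
    config = config or FitConfig()
    prof = profile.dropna()
    if len(prof) < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {len(prof)}")
    res = grid_resolution
    alphas = np.arange(config.alpha_bounds[0], config.alpha_bounds[1] + 1e-9, res)
    betas = np.arange(config.ip_beta_bounds[0], config.ip_beta_bounds[1] + 1e-9, res)
    gamma0s = np.arange(-90.0 + res, 90.0 + 1e-9, res)
    dgamma0s = np.arange(max(config.dgamma0_bounds[0], res), config.dgamma0_bounds[1] + 1e-9, res)
    n_nodes = alphas.size * betas.size * gamma0s.size * dgamma0s.size
    if n_nodes == 0:
        raise ValueError("empty grid: no nodes within the requested bounds/resolution")
    if n_nodes > max_nodes:
        raise ValueError(
            f"grid of {n_nodes} nodes exceeds the {max_nodes} limit; "
            "coarsen the resolution or narrow the bounds"
        )

    y = prof.intensity
    sigma = prof.sigma if prof.sigma is not None else np.sqrt(np.maximum(y, 1.0))
    chi = prof.chi
    iw = y / sigma
    ow = 1.0 / sigma
    a22 = float(np.sum(ow * ow))
    b2 = float(np.sum(ow * iw))

    offsets = np.linspace(
        -2.5 * config.delta_beta_deg, 2.5 * config.delta_beta_deg, config.n_kernel
    )
    kw = np.exp(-((offsets / config.delta_beta_deg) ** 2))
    kw /= kw.sum()

    from .geometry import ewald_ring_point, lab_to_body

    q_lab = ewald_ring_point(chi, geometry)
    rad = 180.0 / np.pi
    best = dict(rss=np.inf)
    for a in alphas:
        for b in betas:
            # body-frame root angle and |g'| for each beta-kernel offset
            gamma_r = np.empty((config.n_kernel, chi.size))
            inv_a = np.empty_like(gamma_r)
            for k, off in enumerate(offsets):
                qb = lab_to_body(q_lab, a, b + off)
                gamma_r[k] = np.degrees(np.arctan2(qb[..., 0], qb[..., 2]))
                inv_a[k] = 1.0 / np.maximum(
                    np.hypot(qb[..., 0], qb[..., 2]), 1e-6 * geometry.q_ring
                )
            d = (gamma_r[None, :, :] - gamma0s[:, None, None] + 90.0) % 180.0 - 90.0
            for dg in dgamma0s:
                wsum = np.zeros_like(d)
                for n in range(-4, 5):
                    wsum += np.exp(-(((d + 180.0 * n) / dg) ** 2))
                wsum *= rad / (dg * np.sqrt(np.pi))
                shape = 2.0 * np.einsum("k,gkc,kc->gc", kw, wsum, inv_a)
                sw = shape / sigma
                a11 = np.sum(sw * sw, axis=1)
                a12 = sw @ ow
                b1 = sw @ iw
                det = a11 * a22 - a12 * a12
                with np.errstate(divide="ignore", invalid="ignore"):
                    lam = (a22 * b1 - a12 * b2) / det
                    bg = (a11 * b2 - a12 * b1) / det
                neg_l = lam < 0
                lam[neg_l] = 0.0
                bg[neg_l] = b2 / a22
                neg_b = bg < 0
                bg[neg_b] = 0.0
                lam[neg_b] = np.maximum(b1[neg_b] / a11[neg_b], 0.0)
                resid = iw[None, :] - lam[:, None] * sw - bg[:, None] * ow[None, :]
                rss = np.sum(resid * resid, axis=1)
                g = int(np.argmin(rss))
                if rss[g] < best["rss"]:
                    best = dict(
                        rss=float(rss[g]), alpha=float(a), beta=float(b),
                        gamma0=float(gamma0s[g]), dgamma0=float(dg),
                        scale=float(lam[g]), background=float(bg[g]),
                    )
    ip = _canonical_family(
        best["alpha"], best["beta"], best["gamma0"], best["dgamma0"], best["scale"],
        is_op=False,
    )
    op = LamellaModel(0.0, 90.0, FibreDistribution(0.0, 45.0), scale=0.0)
    pred = beta_smoothed_profile(
        chi, ip, geometry, config.delta_beta_deg, config.n_kernel
    ) + best["background"]
    rss_unweighted = float(np.sum((pred - y) ** 2))
    redchi = best["rss"] / max(len(prof) - 6, 1)
    return FitResult(
        ip=ip, op=op, background=best["background"], rss=rss_unweighted,
        redchi=float(redchi), stderr={}, converged=True, flags=["grid-search"],
    )
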