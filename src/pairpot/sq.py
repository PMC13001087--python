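"""Isotropic structure factors, S(0) extrapolation, and B22 from S(0) slopes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .coords import ParticleSet, InsufficientDataError
from .rdf import RadialDistribution

__all__ = [
    "StructureFactor",
    "default_q_grid",
    "structure_factor",
    "structure_factor_direct",
    "s_zero_from_kbi",
    "s_zero_extrapolate",
    "s_zero",
    "b22_from_s0_slope",
    "write_sq_tsv",
]


@dataclass
class StructureFactor:
    q: np.ndarray  # nm^-1, increasing
    S: np.ndarray
    density: float  # nm^-3
    q_min_reliable: float  # 2*pi / real-space cutoff
    window: str = "lorch"

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")

    @property
    def reliable(self) -> np.ndarray:
        return self.q >= self.q_min_reliable


def default_q_grid() -> np.ndarray:
    """120 log-spaced wavenumbers over 0.05-6 nm^-1."""
    return np.geomspace(0.05, 6.0, 120)


def _window(r: np.ndarray, R: float, kind: str) -> np.ndarray:
    if kind == "none":
        return np.ones_like(r)
    if kind == "lorch":
        x = np.pi * r / R
        return np.where(x > 0, np.sin(np.where(x > 0, x, 1.0)) / np.where(x > 0, x, 1.0), 1.0)
    raise ValueError(f"unknown window {kind!r}")


def structure_factor(
    rdf: RadialDistribution,
    q_grid: np.ndarray | None = None,
    density: float | None = None,
    window: str = "lorch",
) -> StructureFactor:
    """S(q) = 1 + 4*pi*rho * int (g-1) w(r) sinc(qr) r^2 dr over the rdf range.

    A Lorch window suppresses the truncation ripple from the finite cutoff R;
    q below 2*pi/R is reported but flagged unreliable.
    """
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise ValueError("empty q grid")
    if np.any(q <= 0):
        raise ValueError("q grid must be positive")
    rho = rdf.density if density is None else density
    R = rdf.r_max
    # extend to r=0 where g = 0 inside the (unsampled) core
    r = np.concatenate([[0.0], rdf.r_centers])
    h = np.concatenate([[-1.0], rdf.g - 1.0]) * _window(r, R, window)
    qr = q[:, None] * r[None, :]
    sinc = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
    integrand = h[None, :] * sinc * r[None, :] ** 2
    S = 1.0 + 4.0 * np.pi * rho * np.trapezoid(integrand, r, axis=1)
    return StructureFactor(q, S, rho, q_min_reliable=2.0 * np.pi / R, window=window)


def structure_factor_direct(
    ps: ParticleSet | list[ParticleSet],
    q_grid: np.ndarray | None = None,
    r_max: float | None = None,
    subtract_background: bool = True,
) -> StructureFactor:
    """Debye pair sum S(q) = 1 + (2/N) sum_{i<j} sinc(q r_ij).

    Used as the independent oracle for :func:`structure_factor` on small
    configurations; frames are ensemble-averaged when a list is given.
    Pair distances are minimum-image for periodic boxes and truncated at
    ``r_max`` (default: half the smallest extent) to bound the finite-sample
    low-q artefacts; truncation sets q_min_reliable.
    """
    frames = ps if isinstance(ps, list) else [ps]
    if not frames:
        raise ValueError("no frames")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    box = frames[0].box
    if r_max is None:
        r_max = float(box.extents.min()) / 2.0
    S_acc = np.zeros_like(q)
    for frame in frames:
        if frame.n < 2:
            raise InsufficientDataError("Debye sum needs at least 2 particles")
        coords = frame.coordinates
        if all(box.periodic):
            ext = box.extents
            shifted = np.mod(coords - box.origin, ext)
            tree = cKDTree(shifted, boxsize=ext)
            pairs = tree.query_pairs(r_max, output_type="ndarray")
            d = shifted[pairs[:, 0]] - shifted[pairs[:, 1]]
            d -= ext * np.round(d / ext)
            dist = np.linalg.norm(d, axis=1)
        else:
            tree = cKDTree(coords)
            pairs = tree.query_pairs(r_max, output_type="ndarray")
            dist = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        # ideal-gas background beyond the cutoff is subtracted analytically:
        # sum sinc over uniform pairs within r_max at the same density
        qr = q[:, None] * dist[None, :]
        pair_sum = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0).sum(axis=1)
        rho = frame.density
        # uniform-background Debye contribution over the truncation sphere
        qR = q * r_max
        # matches E[2 * pair_sum] for a uniform fluid: N*rho*int_0^R 4pi r^2 sinc
        bg = frame.n * rho * 4.0 * np.pi * (np.sin(qR) - qR * np.cos(qR)) / q**3
        if not subtract_background:
            bg = np.zeros_like(q)
        S_acc += 1.0 + (2.0 * pair_sum - bg) / frame.n
    S = S_acc / len(frames)
    return StructureFactor(
        q, S, float(np.mean([f.density for f in frames])),
        q_min_reliable=2.0 * np.pi / r_max, window="none",
    )


def s_zero_from_kbi(g_inf: float, density: float) -> float:
    """Compressibility route: S(0) = 1 + rho * G_inf."""
    return 1.0 + density * g_inf


def s_zero_extrapolate(sf: StructureFactor) -> float:
    """Linear extrapolation of S vs q^2 over [q_min_reliable, 2*q_min_reliable]."""
    lo, hi = sf.q_min_reliable, 2.0 * sf.q_min_reliable
    sel = (sf.q >= lo) & (sf.q <= hi)
    if sel.sum() < 2:
        raise ValueError("too few reliable q points for extrapolation")
    coef = np.polyfit(sf.q[sel] ** 2, sf.S[sel], 1)
    return float(coef[1])


def s_zero(
    sf: StructureFactor | None = None,
    g_inf: float | None = None,
    density: float | None = None,
) -> float:
    """S(0) via the KBI compressibility relation (when ``g_inf`` is given)
    or via low-q extrapolation of a StructureFactor."""
    if g_inf is not None:
        if density is None:
            if sf is None:
                raise ValueError("density required with g_inf")
            density = sf.density
        return s_zero_from_kbi(g_inf, density)
    if sf is None:
        raise ValueError("provide either a StructureFactor or g_inf")
    return s_zero_extrapolate(sf)


def b22_from_s0_slope(
    points: list[tuple[float, float]],
    fix_intercept: bool = True,
    s0_sigma: float | None = None,
) -> tuple[float, float]:
    """B22 (nm^3) from the dilute-limit relation S(0) = 1 - 2*B22*rho.

    Fits S0 = 1 + m*rho (intercept fixed at 1 by default) and returns
    (B22, standard error) with B22 = -m/2.  When the per-point noise
    ``s0_sigma`` is known it is used for the standard error instead of the
    residual estimate (which has very few degrees of freedom here).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (density, S0) points")
    rho, s0 = pts[:, 0], pts[:, 1]
    if np.ptp(rho) == 0:
        raise ValueError("densities are identical; slope fit is singular")
    if fix_intercept:
        m = float(np.sum(rho * (s0 - 1.0)) / np.sum(rho**2))
        if s0_sigma is not None:
            var_m = s0_sigma**2 / float(np.sum(rho**2))
        else:
            resid = s0 - 1.0 - m * rho
            dof = max(len(rho) - 1, 1)
            var_m = float(np.sum(resid**2) / dof / np.sum(rho**2))
    else:
        coef, cov = np.polyfit(rho, s0, 1, cov=True)
        m = float(coef[0])
        var_m = float(cov[0, 0])
    return -m / 2.0, np.sqrt(var_m) / 2.0


def write_sq_tsv(path, sf: StructureFactor) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("q_inv_nm\tS\treliable\n")
        for q, s, rel in zip(sf.q, sf.S, sf.reliable):
            fh.write(f"{float(q)!r}\t{float(s)!r}\t{int(rel)}\n")
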