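"""Kirkwood-Buff integrals three ways, and interconversion with B22.

* direct: running integral 4*pi int (g-1) r^2 dr of a measured RDF,
* sub-box: number fluctuations in sliding parallelepipeds, extrapolated to
  zero surface-to-volume ratio,
* from potentials: Mayer-function quadrature of U(r) or W(r).

The sub-box estimator G = V*(var N - mean N)/(mean N)^2 is a grand-canonical
statement; for frames drawn at fixed N an optional canonical finite-size
correction G_inf = (G_eff + p/rho) / (1 - p), p = V_sub/V_frame, removes the
leading closed-ensemble bias (exact for an ideal gas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coords import AVOGADRO, ParticleSet
from .rdf import PotentialCurve, RadialDistribution

__all__ = [
    "CumulativeKBI",
    "SubBoxScan",
    "KBIEstimate",
    "kbi_direct",
    "subbox_counts",
    "kbi_subbox",
    "kbi_subbox_estimate",
    "kbi_extrapolate",
    "b22_from_potential",
    "kbi_from_pmf",
    "b22_nm3_to_mol_ml_g2",
    "write_subbox_tsv",
]


@dataclass
class CumulativeKBI:
    r: np.ndarray
    G_of_r: np.ndarray  # nm^3, running integral; G_of_r[0] corresponds to r=0
    G_inf: float  # value at the cutoff
    cutoff: float


@dataclass
class SubBoxScan:
    L: np.ndarray  # square base side, nm, increasing
    stride: float
    H: float  # sub-box (slab) height
    G_eff: np.ndarray  # nm^3 per L
    SV: np.ndarray  # surface-to-volume ratio 2/H + 4/L, nm^-1
    n_subboxes: np.ndarray
    ensemble: str = "grand"

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        self.G_eff = np.asarray(self.G_eff, dtype=float)
        self.SV = np.asarray(self.SV, dtype=float)
        self.n_subboxes = np.asarray(self.n_subboxes, dtype=int)
        if np.any(np.diff(self.L) <= 0):
            raise ValueError("L must be strictly increasing")
        if np.any(self.n_subboxes < 1):
            raise ValueError("each L needs at least one sub-box position")


@dataclass
class KBIEstimate:
    G_inf: float  # nm^3
    stderr: float
    method: str  # direct | subbox | from_pmf
    fit: dict | None = None  # intercept/slope/r2/L_range for the subbox route

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")


# ---------------------------------------------------------------------------
# Direct RDF integration
# ---------------------------------------------------------------------------

def kbi_direct(rdf: RadialDistribution, cutoff: float | None = None) -> CumulativeKBI:
    """Trapezoidal running integral of 4*pi*(g-1)*r^2, read off at *cutoff*."""
    from scipy.integrate import cumulative_trapezoid

    if cutoff is None:
        cutoff = rdf.r_max
    if cutoff > rdf.r_max + 1e-9:
        raise ValueError(f"cutoff {cutoff} exceeds RDF range {rdf.r_max}")
    r = np.concatenate([[0.0], rdf.r_centers])
    integrand = 4.0 * np.pi * np.concatenate([[-1.0], rdf.g - 1.0]) * r**2
    G = cumulative_trapezoid(integrand, r, initial=0.0)
    G_inf = float(np.interp(cutoff, r, G))
    return CumulativeKBI(r=r, G_of_r=G, G_inf=G_inf, cutoff=float(cutoff))


# ---------------------------------------------------------------------------
# Sub-box fluctuation method
# ---------------------------------------------------------------------------

def subbox_counts(ps: ParticleSet, L: float, stride: float) -> np.ndarray:
    """Particle counts in all sliding L x L x H sub-boxes (half-open bounds).

    On laterally periodic boxes the sub-boxes wrap around the x/y boundaries,
    which makes the estimator exactly invariant under rigid translations by
    multiples of the stride.
    """
    box = ps.box
    Lx, Ly = float(box.extents[0]), float(box.extents[1])
    if L > min(Lx, Ly) + 1e-9:
        raise ValueError(f"sub-box side {L} exceeds lateral extents")
    wrap_x, wrap_y = box.periodic[0], box.periodic[1]
    x = ps.coordinates[:, 0] - box.origin[0]
    y = ps.coordinates[:, 1] - box.origin[1]
    if wrap_x:
        x = np.mod(x, Lx)
    if wrap_y:
        y = np.mod(y, Ly)
    x0s = np.arange(0.0, Lx if wrap_x else Lx - L + 1e-9, stride)
    y0s = np.arange(0.0, Ly if wrap_y else Ly - L + 1e-9, stride)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    counts = np.empty((len(x0s), len(y0s)), dtype=np.int64)
    for i, x0 in enumerate(x0s):
        a = np.searchsorted(xs, x0, side="left")
        end = x0 + L
        if end <= Lx or not wrap_x:
            b = np.searchsorted(xs, end, side="left")
            ysub = ys[a:b]
        else:
            b = np.searchsorted(xs, end - Lx, side="left")
            ysub = np.concatenate([ys[a:], ys[:b]])
        ysub = np.sort(ysub)
        lo = np.searchsorted(ysub, y0s, side="left")
        hi = np.searchsorted(ysub, y0s + L, side="left")
        row = hi - lo
        if wrap_y:
            over = y0s + L > Ly
            if over.any():
                hi_wrap = np.searchsorted(ysub, y0s[over] + L - Ly, side="left")
                row = row.copy()
                row[over] = (len(ysub) - lo[over]) + hi_wrap
        counts[i] = row
    return counts.ravel()


def _frame_moments(frames, L_list, stride):
    """Per-frame count moments (n_windows, sum, sum of squares) per L."""
    F, nL = len(frames), len(L_list)
    n_w = np.empty((F, nL), dtype=np.int64)
    s1 = np.empty((F, nL))
    s2 = np.empty((F, nL))
    for fi, frame in enumerate(frames):
        for k, L in enumerate(L_list):
            c = subbox_counts(frame, L, stride)
            n_w[fi, k] = len(c)
            s1[fi, k] = c.sum()
            s2[fi, k] = np.square(c, dtype=float).sum()
    return n_w, s1, s2


def _scan_from_moments(sel, n_w, s1, s2, frame_n, L_list, stride, H, V_frame, ensemble):
    n = n_w[sel].sum(axis=0)
    mean = s1[sel].sum(axis=0) / n
    var = s2[sel].sum(axis=0) / n - mean**2  # population variance, deliberately
    V_sub = L_list * L_list * H
    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.where(mean > 0, V_sub * (var - mean) / mean**2, np.nan)
    if ensemble == "canonical":
        p = V_sub / V_frame
        rho_bath = float(np.mean(frame_n[sel])) / V_frame
        G = (G + p / rho_bath) / (1.0 - p)
    return SubBoxScan(
        L=L_list, stride=stride, H=H, G_eff=G,
        SV=2.0 / H + 4.0 / L_list,
        n_subboxes=(n_w[sel].sum(axis=0) // max(sel.sum(), 1)),
        ensemble=ensemble,
    )


def _subbox_setup(frames, L_list, stride, ensemble):
    if stride <= 0:
        raise ValueError("stride must be positive")
    if ensemble not in ("grand", "canonical"):
        raise ValueError("ensemble must be 'grand' or 'canonical'")
    frames = frames if isinstance(frames, list) else [frames]
    if not frames:
        raise ValueError("no frames")
    box = frames[0].box
    if L_list is None:
        L_hi = float(min(box.extents[0], box.extents[1])) / 2.0
        L_list = np.arange(6.0, L_hi + 1e-9, 2.0)
    L_list = np.asarray(L_list, dtype=float)
    if L_list.size == 0:
        raise ValueError("empty L list")
    return frames, L_list, box


def kbi_subbox(
    frames: ParticleSet | list[ParticleSet],
    L_list: np.ndarray | None = None,
    stride: float = 3.0,
    ensemble: str = "grand",
) -> SubBoxScan:
    """Effective G(L) from pooled sub-box number fluctuations.

    Counts are pooled over sliding positions and over frames before the
    variance is taken (population variance: overlapping boxes are not
    independent samples).  ``ensemble='canonical'`` applies the fixed-N
    finite-size correction.
    """
    frames, L_list, box = _subbox_setup(frames, L_list, stride, ensemble)
    n_w, s1, s2 = _frame_moments(frames, L_list, stride)
    frame_n = np.array([f.n for f in frames], dtype=float)
    sel = np.ones(len(frames), dtype=bool)
    return _scan_from_moments(sel, n_w, s1, s2, frame_n, L_list, stride,
                              float(box.extents[2]), box.volume, ensemble)


def kbi_subbox_estimate(
    frames: ParticleSet | list[ParticleSet],
    L_list: np.ndarray | None = None,
    stride: float = 3.0,
    ensemble: str = "grand",
    L_max: float = 50.0,
    n_boot: int = 200,
    seed: int = 0,
) -> KBIEstimate:
    """Sub-box G_inf with an honest uncertainty.

    The point estimate is the S/V-extrapolation intercept on the pooled scan.
    Because sliding windows overlap heavily, the OLS standard error is far
    too small; with more than one frame the stderr is replaced by a bootstrap
    over frames, which captures the true variance of the pooled estimator.
    """
    frames, L_list, box = _subbox_setup(frames, L_list, stride, ensemble)
    H, V = float(box.extents[2]), box.volume
    n_w, s1, s2 = _frame_moments(frames, L_list, stride)
    frame_n = np.array([f.n for f in frames], dtype=float)
    all_sel = np.ones(len(frames), dtype=bool)
    scan = _scan_from_moments(all_sel, n_w, s1, s2, frame_n, L_list, stride, H, V, ensemble)
    est = kbi_extrapolate(scan, L_max=L_max)
    if len(frames) > 1 and n_boot > 0:
        rng = np.random.default_rng(seed)
        intercepts = []
        for _ in range(n_boot):
            pick = rng.integers(0, len(frames), len(frames))
            sel = np.bincount(pick, minlength=len(frames))
            # bincount weights: replicate frames by their multiplicity
            nb = n_w * sel[:, None]
            sb1 = s1 * sel[:, None]
            sb2 = s2 * sel[:, None]
            scan_b = _scan_from_moments(all_sel, nb, sb1, sb2,
                                        np.repeat(frame_n, sel),
                                        L_list, stride, H, V, ensemble)
            try:
                intercepts.append(kbi_extrapolate(scan_b, L_max=L_max).G_inf)
            except ValueError:
                continue
        if len(intercepts) >= 10:
            est = KBIEstimate(
                G_inf=est.G_inf,
                stderr=float(np.std(intercepts, ddof=1)),
                method="subbox",
                fit={**est.fit, "stderr_source": "frame_bootstrap",
                     "n_boot": len(intercepts)},
            )
    return est


def kbi_extrapolate(scan: SubBoxScan, L_max: float = 50.0) -> KBIEstimate:
    """OLS of G_eff against S/V for L <= L_max; the intercept is G_inf."""
    sel = scan.L <= L_max + 1e-9
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 L values <= {L_max}, have {int(sel.sum())}")
    x = scan.SV[sel]
    y = scan.G_eff[sel]
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept, slope = (float(c) for c in coef)
    yhat = X @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(n - 2, 1)
    sigma2 = ss_res / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    stderr = float(np.sqrt(cov[0, 0]))
    return KBIEstimate(
        G_inf=intercept,
        stderr=stderr,
        method="subbox",
        fit={
            "intercept": intercept,
            "slope": slope,
            "r_squared": r2,
            "L_range": (float(scan.L[sel].min()), float(scan.L[sel].max())),
            "n_points": n,
        },
    )


# ---------------------------------------------------------------------------
# Potential-route quadrature
# ---------------------------------------------------------------------------

def _mayer_integral(curve: PotentialCurve, cutoff: float) -> float:
    """int_0^cutoff (exp(-U) - 1) r^2 dr with hard repulsion below the first
    valid bin and linear interpolation of U across interior invalid bins."""
    r = curve.r
    if cutoff > r[-1] + 1e-9:
        raise ValueError(f"cutoff {cutoff} beyond potential grid end {r[-1]}")
    if not curve.valid.any():
        # entirely hard: f = -1 up to the cutoff
        return -(cutoff**3) / 3.0
    first = int(np.argmax(curve.valid))
    r_hc = r[first]
    hard = -(min(r_hc, cutoff) ** 3) / 3.0
    if cutoff <= r_hc:
        return hard
    sel = (r >= r_hc) & (r <= cutoff + 1e-12)
    rr = r[sel]
    vv = curve.valid[sel]
    u = np.interp(rr, rr[vv], curve.value[sel][vv])  # fill interior gaps
    f = np.exp(-u) - 1.0
    if not np.isclose(rr[-1], cutoff):
        u_c = float(np.interp(cutoff, rr, u))
        rr = np.append(rr, cutoff)
        f = np.append(f, np.exp(-u_c) - 1.0)
    return hard + float(np.trapezoid(f * rr**2, rr))


def b22_from_potential(curve: PotentialCurve, cutoff: float) -> float:
    """B22 = -2*pi int (exp(-U/kBT) - 1) r^2 dr, in nm^3 (U already in kB*T)."""
    return -2.0 * np.pi * _mayer_integral(curve, cutoff)


def kbi_from_pmf(curve: PotentialCurve, cutoff: float) -> float:
    """G_inf = 4*pi int (exp(-W/kBT) - 1) r^2 dr; exactly -2 x b22 route."""
    return 4.0 * np.pi * _mayer_integral(curve, cutoff)


def b22_nm3_to_mol_ml_g2(b22_nm3: float, molecular_weight: float) -> float:
    """Convert B22 from nm^3/molecule to the mol*mL/g^2 convention."""
    return b22_nm3 * 1e-21 * AVOGADRO / molecular_weight**2


def write_subbox_tsv(path, scan: SubBoxScan) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("L_nm\tSV_inv_nm\tG_eff_nm3\tn_subboxes\n")
        for L, sv, g, n in zip(scan.L, scan.SV, scan.G_eff, scan.n_subboxes):
            fh.write(f"{float(L)!r}\t{float(sv)!r}\t{float(g)!r}\t{int(n)}\n")
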