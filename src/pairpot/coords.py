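"""Particle coordinate handling: I/O, tilt correction, cropping, concentration.

All lengths are nanometres, all energies are kB*T, throughout the package.
Box membership is half-open, ``[lo, hi)`` on every axis, so that tiling a
volume with sub-boxes never double-counts a particle.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

import yaml

AVOGADRO = 6.02214076e23
NM3_PER_ML = 1e21  # 1 mL = 1e21 nm^3


class FormatError(ValueError):
    """A coordinate file violates its declared format."""


class InsufficientDataError(ValueError):
    """Too few particles for the requested operation."""


@dataclass(frozen=True)
class BoxGeometry:
    """Axis-aligned cuboid, optionally periodic per axis."""

    origin: np.ndarray
    extents: np.ndarray  # (Lx, Ly, H)
    periodic: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "extents", np.asarray(self.extents, dtype=float))
        if self.origin.shape != (3,) or self.extents.shape != (3,):
            raise ValueError("origin and extents must be 3-vectors")
        if not np.all(self.extents > 0):
            raise ValueError(f"box extents must be positive, got {self.extents}")

    @property
    def volume(self) -> float:
        return float(np.prod(self.extents))

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.extents

    def contains(self, xyz: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Half-open membership test per point (periodic axes always pass)."""
        xyz = np.atleast_2d(xyz)
        ok = np.ones(len(xyz), dtype=bool)
        for ax in range(3):
            if self.periodic[ax]:
                continue
            lo = self.origin[ax] - atol
            hi = self.origin[ax] + self.extents[ax] + atol
            ok &= (xyz[:, ax] >= lo) & (xyz[:, ax] < hi)
        return ok


@dataclass
class ParticleSet:
    """N x 3 particle centroids inside a box, plus sample metadata."""

    coordinates: np.ndarray
    box: BoxGeometry
    temperature: float = 293.15
    molecular_weight: float | None = None
    label: str = ""
    validate_bounds: bool = True

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be N x 3, got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates contain non-finite values")
        self.coordinates = coords
        if self.validate_bounds and len(coords):
            inside = self.box.contains(coords)
            if not inside.all():
                n_out = int((~inside).sum())
                raise ValueError(
                    f"{n_out} particle(s) outside the declared box "
                    f"(first offender index {int(np.argmax(~inside))})"
                )

    @property
    def n(self) -> int:
        return len(self.coordinates)

    @property
    def density(self) -> float:
        """Number density N/V in nm^-3."""
        return self.n / self.box.volume

    def mass_concentration(self) -> float:
        """Bulk mass concentration in mg/mL (requires molecular_weight)."""
        if self.molecular_weight is None:
            raise ValueError("molecular_weight not set")
        return self.density * self.molecular_weight / AVOGADRO * NM3_PER_ML * 1e3


@dataclass(frozen=True)
class TiltEstimate:
    """Least-squares plane fit z = a + b*x + c*y through the centroids."""

    angle_x: float  # degrees, slope of the slab mid-plane along x
    angle_y: float  # degrees, slope along y
    plane_coefficients: tuple[float, float, float]  # (a, b, c)
    residual_rms: float
    poor_fit: bool = False  # set when the cloud has no slab structure

    def __post_init__(self):
        if abs(self.angle_x) >= 45 or abs(self.angle_y) >= 45:
            raise ValueError("tilt angles must be below 45 degrees")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")


@dataclass(frozen=True)
class ConcentrationProfile:
    z_bin_centers: np.ndarray
    number_density: np.ndarray  # nm^-3 per bin
    mass_concentration: np.ndarray | None  # mg/mL per bin
    plateau_range: tuple[float, float]
    bin_width: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_particles(
    path,
    box: BoxGeometry,
    format: str | None = None,
    temperature: float = 293.15,
    molecular_weight: float | None = None,
    label: str = "",
    strict: bool = True,
) -> ParticleSet:
    """Read a CSV (``x_nm,y_nm,z_nm`` header) or XYZ coordinate file.

    With ``strict=True`` a record outside *box* raises; otherwise such
    records are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coordinate file not found: {path}")
    if format is None:
        format = "xyz" if path.suffix.lower() == ".xyz" else "csv"
    if format == "csv":
        coords = _read_csv(path)
    elif format == "xyz":
        coords = _read_xyz(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(coords) == 0:
        raise FormatError(f"{path}: no valid coordinate records")
    inside = box.contains(coords)
    if not inside.all():
        n_out = int((~inside).sum())
        if strict:
            raise FormatError(
                f"{path}: {n_out} record(s) fall outside the declared box"
            )
        warnings.warn(f"{path}: dropping {n_out} out-of-box record(s)")
        coords = coords[inside]
        if len(coords) == 0:
            raise FormatError(f"{path}: no records inside the declared box")
    return ParticleSet(
        coords,
        box,
        temperature=temperature,
        molecular_weight=molecular_weight,
        label=label or path.stem,
    )


def _read_csv(path: Path) -> np.ndarray:
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty file")
        cols = [h.strip().lower() for h in header]
        try:
            idx = [cols.index(c) for c in ("x_nm", "y_nm", "z_nm")]
        except ValueError:
            raise FormatError(
                f"{path}: header must contain columns x_nm,y_nm,z_nm, got {header}"
            ) from None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                xyz = [float(row[i]) for i in idx]
            except (ValueError, IndexError):
                raise FormatError(f"{path}, line {lineno}: unparseable record {row!r}")
            if not all(np.isfinite(xyz)):
                raise FormatError(f"{path}, line {lineno}: non-finite coordinate {row!r}")
            rows.append(xyz)
    return np.asarray(rows, dtype=float).reshape(-1, 3)


def _read_xyz(path: Path) -> np.ndarray:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated XYZ file")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise FormatError(f"{path}, line 1: expected particle count") from None
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) != count:
        raise FormatError(
            f"{path}: header declares {count} records but file has {len(records)}"
        )
    rows = []
    for lineno, ln in enumerate(records, start=3):
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path}, line {lineno}: expected 'element x y z'")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise FormatError(f"{path}, line {lineno}: unparseable coordinates")
        if not all(np.isfinite(xyz)):
            raise FormatError(f"{path}, line {lineno}: non-finite coordinate")
        rows.append(xyz)
    return np.asarray(rows, dtype=float).reshape(-1, 3)


def save_particles(ps: ParticleSet, path, format: str | None = None) -> None:
    """Write a ParticleSet in the CSV or XYZ dialect ``load_particles`` reads."""
    path = Path(path)
    if format is None:
        format = "xyz" if path.suffix.lower() == ".xyz" else "csv"
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write("x_nm,y_nm,z_nm\n")
            for x, y, z in ps.coordinates:
                fh.write(f"{float(x)!r},{float(y)!r},{float(z)!r}\n")
    elif format == "xyz":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{ps.n}\n{ps.label}\n")
            for x, y, z in ps.coordinates:
                fh.write(f"P {float(x)!r} {float(y)!r} {float(z)!r}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_metadata(path) -> dict:
    """Read a YAML/JSON sidecar with box extents, temperature_K, etc."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            meta = json.load(fh)
        else:
            meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise FormatError(f"{path}: sidecar must be a mapping")
    return meta


def box_from_metadata(meta: dict) -> BoxGeometry:
    extents = np.asarray(meta["box_extents_nm"], dtype=float)
    origin = np.asarray(meta.get("box_origin_nm", (0.0, 0.0, 0.0)), dtype=float)
    periodic = tuple(bool(b) for b in meta.get("periodic", (False, False, False)))
    return BoxGeometry(origin, extents, periodic)


# ---------------------------------------------------------------------------
# Tilt
# ---------------------------------------------------------------------------

def estimate_tilt(ps: ParticleSet) -> TiltEstimate:
    """Fit the plane z = a + b*x + c*y through all centroids by least squares.

    ``angle_x = atan(b)``, ``angle_y = atan(c)`` in degrees.  ``poor_fit`` is
    raised when the residual scatter is comparable to the lateral extent,
    i.e. the cloud carries no usable slab structure.
    """
    if ps.n < 10:
        raise InsufficientDataError(f"tilt estimation needs >= 10 particles, got {ps.n}")
    x, y, z = ps.coordinates.T
    design = np.column_stack([np.ones_like(x), x, y])
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    a, b, c = (float(v) for v in coef)
    resid = z - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    lateral = float(min(ps.box.extents[0], ps.box.extents[1]))
    return TiltEstimate(
        angle_x=float(np.degrees(np.arctan(b))),
        angle_y=float(np.degrees(np.arctan(c))),
        plane_coefficients=(a, b, c),
        residual_rms=rms,
        poor_fit=rms > 0.2 * lateral,
    )


def tilt_rotation(angle_x_deg: float, angle_y_deg: float) -> Rotation:
    """Rotation that tilts a flat slab so its fitted plane acquires the
    slopes ``tan(angle_x)`` along x and ``tan(angle_y)`` along y."""
    b = np.tan(np.radians(angle_x_deg))
    c = np.tan(np.radians(angle_y_deg))
    normal = np.array([-b, -c, 1.0])
    normal /= np.linalg.norm(normal)
    rot, _ = Rotation.align_vectors([normal], [[0.0, 0.0, 1.0]])
    return rot


def apply_tilt_correction(ps: ParticleSet, tilt: TiltEstimate) -> ParticleSet:
    """Rigidly rotate about the centroid so the fitted plane normal is +z."""
    _, b, c = tilt.plane_coefficients
    normal = np.array([-b, -c, 1.0])
    normal /= np.linalg.norm(normal)
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [normal])
    centroid = ps.coordinates.mean(axis=0)
    coords = rot.apply(ps.coordinates - centroid) + centroid
    return replace(ps, coordinates=coords, validate_bounds=False)


# ---------------------------------------------------------------------------
# Concentration profile and cropping
# ---------------------------------------------------------------------------

def concentration_profile(
    ps: ParticleSet, dz: float = 5.0, plateau_fraction: float = 0.2
) -> ConcentrationProfile:
    """Number density (and mg/mL if MW is known) in z-bins of width *dz*.

    The plateau is the widest contiguous run of bins whose density lies
    within ``plateau_fraction`` of the median bin density.
    """
    H = float(ps.box.extents[2])
    if dz <= 0:
        raise ValueError("dz must be positive")
    if dz > H:
        raise ValueError(f"dz = {dz} exceeds slab height H = {H}")
    z0 = float(ps.box.origin[2])
    n_bins = int(np.ceil(H / dz - 1e-12))
    idx = np.floor((ps.coordinates[:, 2] - z0) / dz).astype(int)
    # box membership is half-open, so idx is in [0, n_bins-1] up to rounding
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    bin_volume = float(ps.box.extents[0] * ps.box.extents[1] * dz)
    density = counts / bin_volume
    centers = z0 + (np.arange(n_bins) + 0.5) * dz

    med = float(np.median(density))
    ok = np.abs(density - med) <= plateau_fraction * med if med > 0 else density == 0
    lo, hi = _widest_run(ok)
    plateau = (z0 + lo * dz, z0 + hi * dz)

    mass = None
    if ps.molecular_weight is not None:
        mass = density * ps.molecular_weight / AVOGADRO * NM3_PER_ML * 1e3
    return ConcentrationProfile(centers, density, mass, plateau, dz)


def _widest_run(mask: np.ndarray) -> tuple[int, int]:
    """Indices [lo, hi) of the longest True run (whole range if none)."""
    best = (0, len(mask))
    cur_start, best_len = None, 0
    for i, v in enumerate(np.append(mask, False)):
        if v and cur_start is None:
            cur_start = i
        elif not v and cur_start is not None:
            if i - cur_start > best_len:
                best_len = i - cur_start
                best = (cur_start, i)
            cur_start = None
    return best if best_len else (0, len(mask))


def crop_central_slab(
    ps: ParticleSet,
    z_lo: float | None = None,
    z_hi: float | None = None,
    dz: float = 5.0,
    plateau_fraction: float = 0.2,
) -> ParticleSet:
    """Keep particles with z in ``[z_lo, z_hi)`` and shrink the box to match.

    With ``z_lo``/``z_hi`` omitted, the plateau of the concentration profile
    is used, shrunk by one extra bin on each side as a guard band against
    surface (AWI) layers.
    """
    if z_lo is None or z_hi is None:
        prof = concentration_profile(ps, dz=dz, plateau_fraction=plateau_fraction)
        auto_lo, auto_hi = prof.plateau_range
        z_lo = auto_lo + dz if z_lo is None else z_lo
        z_hi = auto_hi - dz if z_hi is None else z_hi
    box_lo = float(ps.box.origin[2])
    box_hi = box_lo + float(ps.box.extents[2])
    z_lo = max(z_lo, box_lo)
    z_hi = min(z_hi, box_hi)
    if not z_lo < z_hi:
        raise ValueError(f"invalid crop range [{z_lo}, {z_hi})")
    z = ps.coordinates[:, 2]
    keep = (z >= z_lo) & (z < z_hi)
    if keep.sum() < 2:
        raise InsufficientDataError("crop would leave fewer than 2 particles")
    origin = ps.box.origin.copy()
    extents = ps.box.extents.copy()
    origin[2] = z_lo
    extents[2] = z_hi - z_lo
    box = BoxGeometry(origin, extents, ps.box.periodic)
    return replace(ps, coordinates=ps.coordinates[keep], box=box)
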