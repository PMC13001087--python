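"""Synthetic particle configurations with known statistical structure.

Poisson gases (canonical and grand-canonical) and Metropolis Monte-Carlo
fluids with hard-sphere / square-well / Yukawa / tabulated pair potentials in
fully periodic orthorhombic boxes.  Every analysis stage in the package is
validated against configurations produced here, where the ground truth is
known exactly.  Energies are in kB*T throughout; the Yukawa form is
U(r) = eps * (sigma/r) * exp(-kappa*(r - sigma)) above a hard core at sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .coords import BoxGeometry, ParticleSet, tilt_rotation

__all__ = [
    "PotentialSpec",
    "SimulationConfig",
    "sample_poisson",
    "run_mc",
    "inject_artifacts",
]

_KIND_CODES = {"hard_sphere": 1, "square_well": 2, "yukawa": 3, "tabulated": 4}


@dataclass(frozen=True)
class PotentialSpec:
    """Pair potential for the MC sampler; sigma = 0 disables the hard core
    (an ideal gas when epsilon is also zero)."""

    kind: str
    sigma: float = 0.0  # hard-core diameter, nm
    epsilon: float = 0.0  # well depth / contact strength, kB*T
    kappa: float = 0.0  # Yukawa screening, nm^-1
    well_width: float = 0.0  # square-well width beyond sigma, nm
    table: tuple | None = None  # (r, U) arrays for kind="tabulated"
    r_cut: float | None = None  # interaction cutoff override, nm

    def __post_init__(self):
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown potential kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind == "tabulated":
            if self.table is None:
                raise ValueError("tabulated potential needs a table")
            r, u = (np.asarray(a, dtype=float) for a in self.table)
            if not np.all(np.isfinite(u)):
                raise ValueError("tabulated U must be finite on its grid")
            if np.any(np.diff(r) <= 0):
                raise ValueError("table r grid must be increasing")

    @property
    def cutoff(self) -> float:
        if self.r_cut is not None:
            return self.r_cut
        if self.kind == "hard_sphere":
            return max(self.sigma, 1e-9)
        if self.kind == "square_well":
            return self.sigma + self.well_width
        if self.kind == "yukawa":
            reach = 12.0 / self.kappa if self.kappa > 0 else 5.0 * max(self.sigma, 1.0)
            return self.sigma + reach
        return float(np.asarray(self.table[0], dtype=float)[-1])

    def beta_u(self, r: np.ndarray) -> np.ndarray:
        """Vectorised U(r)/kBT, +inf inside the hard core."""
        r = np.asarray(r, dtype=float)
        u = np.zeros_like(r)
        if self.kind == "hard_sphere":
            pass
        elif self.kind == "square_well":
            u = np.where(r < self.sigma + self.well_width, -self.epsilon, 0.0)
        elif self.kind == "yukawa":
            with np.errstate(divide="ignore", invalid="ignore"):
                safe = np.maximum(r, 1e-12)
                u = np.where(
                    r < self.cutoff,
                    self.epsilon * (self.sigma / safe) * np.exp(-self.kappa * (safe - self.sigma)),
                    0.0,
                )
        else:
            tr, tu = (np.asarray(a, dtype=float) for a in self.table)
            u = np.where(r <= tr[-1], np.interp(r, tr, tu), 0.0)
        return np.where(r < self.sigma, np.inf, u)


@dataclass(frozen=True)
class SimulationConfig:
    potential: PotentialSpec
    box: BoxGeometry
    n_particles: int
    temperature: float = 293.15
    n_sweeps_equil: int = 500
    n_sweeps_sample: int = 1000
    sample_every: int = 20
    max_displacement: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if min(self.n_sweeps_equil, self.n_sweeps_sample, self.sample_every) < 1:
            raise ValueError("sweep counts must be positive")
        if not all(self.box.periodic):
            raise ValueError("MC requires a fully periodic box")


# ---------------------------------------------------------------------------
# Poisson gases
# ---------------------------------------------------------------------------

def sample_poisson(
    box: BoxGeometry,
    n: int | None = None,
    density: float | None = None,
    seed: int = 0,
    ensemble: str = "canonical",
    n_frames: int = 1,
    temperature: float = 293.15,
    **metadata,
):
    """Uniform ideal-gas configurations.

    canonical: exactly *n* points per frame; grand: N ~ Poisson(rho*V) per
    frame.  Returns one ParticleSet (n_frames == 1) or a list of frames.
    """
    if (n is None) == (density is None):
        raise ValueError("give exactly one of n or density")
    rho = density if density is not None else n / box.volume
    if rho <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        if ensemble == "canonical":
            count = n if n is not None else int(round(rho * box.volume))
        elif ensemble == "grand":
            count = int(rng.poisson(rho * box.volume))
        else:
            raise ValueError("ensemble must be 'canonical' or 'grand'")
        pts = box.origin + rng.random((count, 3)) * box.extents
        frames.append(ParticleSet(pts, box, temperature=temperature, **metadata))
    return frames if n_frames > 1 else frames[0]


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

@njit(cache=True)
def _numba_seed(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _beta_u_r2(r2, kind, sigma, eps, kappa, ww, tr, tu, rc):
    """Pair energy in kB*T from squared distance; returns (u, overlap)."""
    if sigma > 0.0 and r2 < sigma * sigma:
        return 0.0, True
    r = np.sqrt(r2)
    if r >= rc:
        return 0.0, False
    if kind == 1:  # hard sphere
        return 0.0, False
    if kind == 2:  # square well
        if r < sigma + ww:
            return -eps, False
        return 0.0, False
    if kind == 3:  # yukawa
        if r <= 0.0:
            return 0.0, True
        return eps * (sigma / r) * np.exp(-kappa * (r - sigma)), False
    # tabulated, linear interpolation; hard below the table start
    if r < tr[0]:
        return 0.0, True
    if r >= tr[-1]:
        return 0.0, False
    j = np.searchsorted(tr, r) - 1
    if j < 0:
        j = 0
    w = (r - tr[j]) / (tr[j + 1] - tr[j])
    return tu[j] * (1.0 - w) + tu[j + 1] * w, False


@njit(cache=True)
def _cell_index(p, boxL, nc):
    ix = int(p[0] / boxL[0] * nc[0])
    iy = int(p[1] / boxL[1] * nc[1])
    iz = int(p[2] / boxL[2] * nc[2])
    if ix >= nc[0]:
        ix = nc[0] - 1
    if iy >= nc[1]:
        iy = nc[1] - 1
    if iz >= nc[2]:
        iz = nc[2] - 1
    return (ix * nc[1] + iy) * nc[2] + iz


@njit(cache=True)
def _particle_energy(i, p, pos, boxL, head, nxt, nc, use_cells,
                     kind, sigma, eps, kappa, ww, tr, tu, rc):
    """Energy of particle i at trial position p; (energy, overlap)."""
    e = 0.0
    if use_cells:
        ix = int(p[0] / boxL[0] * nc[0]) % nc[0]
        iy = int(p[1] / boxL[1] * nc[1]) % nc[1]
        iz = int(p[2] / boxL[2] * nc[2]) % nc[2]
        for dx in range(-1, 2):
            cx = (ix + dx) % nc[0]
            for dy in range(-1, 2):
                cy = (iy + dy) % nc[1]
                for dz in range(-1, 2):
                    cz = (iz + dz) % nc[2]
                    j = head[(cx * nc[1] + cy) * nc[2] + cz]
                    while j != -1:
                        if j != i:
                            r2 = 0.0
                            for d in range(3):
                                dd = p[d] - pos[j, d]
                                dd -= boxL[d] * np.round(dd / boxL[d])
                                r2 += dd * dd
                            u, ov = _beta_u_r2(r2, kind, sigma, eps, kappa, ww, tr, tu, rc)
                            if ov:
                                return 0.0, True
                            e += u
                        j = nxt[j]
    else:
        for j in range(pos.shape[0]):
            if j == i:
                continue
            r2 = 0.0
            for d in range(3):
                dd = p[d] - pos[j, d]
                dd -= boxL[d] * np.round(dd / boxL[d])
                r2 += dd * dd
            u, ov = _beta_u_r2(r2, kind, sigma, eps, kappa, ww, tr, tu, rc)
            if ov:
                return 0.0, True
            e += u
    return e, False


@njit(cache=True)
def _build_cells(pos, boxL, nc):
    head = -np.ones(nc[0] * nc[1] * nc[2], dtype=np.int64)
    nxt = -np.ones(pos.shape[0], dtype=np.int64)
    for i in range(pos.shape[0]):
        c = _cell_index(pos[i], boxL, nc)
        nxt[i] = head[c]
        head[c] = i
    return head, nxt


@njit(cache=True)
def _total_energy(pos, boxL, kind, sigma, eps, kappa, ww, tr, tu, rc):
    e = 0.0
    n = pos.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            r2 = 0.0
            for d in range(3):
                dd = pos[i, d] - pos[j, d]
                dd -= boxL[d] * np.round(dd / boxL[d])
                r2 += dd * dd
            u, ov = _beta_u_r2(r2, kind, sigma, eps, kappa, ww, tr, tu, rc)
            if ov:
                return np.inf
            e += u
    return e


@njit(cache=True)
def _mc_sweeps(pos, boxL, kind, sigma, eps, kappa, ww, tr, tu, rc,
               delta, n_sweeps, head, nxt, nc, use_cells):
    """Run n_sweeps Metropolis sweeps in place; returns (accepted, attempted,
    accumulated energy change)."""
    n = pos.shape[0]
    accepted = 0
    du_total = 0.0
    trial = np.empty(3)
    for _ in range(n_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            for d in range(3):
                trial[d] = pos[i, d] + (2.0 * np.random.random() - 1.0) * delta
                trial[d] -= boxL[d] * np.floor(trial[d] / boxL[d])
            e_new, overlap = _particle_energy(
                i, trial, pos, boxL, head, nxt, nc, use_cells,
                kind, sigma, eps, kappa, ww, tr, tu, rc)
            if overlap:
                continue
            e_old, _ = _particle_energy(
                i, pos[i], pos, boxL, head, nxt, nc, use_cells,
                kind, sigma, eps, kappa, ww, tr, tu, rc)
            du = e_new - e_old
            if du <= 0.0 or np.random.random() < np.exp(-du):
                if use_cells:
                    c_old = _cell_index(pos[i], boxL, nc)
                    c_new = _cell_index(trial, boxL, nc)
                    if c_old != c_new:
                        # unlink i from c_old
                        j = head[c_old]
                        if j == i:
                            head[c_old] = nxt[i]
                        else:
                            while nxt[j] != i:
                                j = nxt[j]
                            nxt[j] = nxt[i]
                        nxt[i] = head[c_new]
                        head[c_new] = i
                for d in range(3):
                    pos[i, d] = trial[d]
                accepted += 1
                du_total += du
    return accepted, n_sweeps * n, du_total


def _potential_args(pot: PotentialSpec):
    kind = _KIND_CODES[pot.kind]
    if pot.kind == "tabulated":
        tr, tu = (np.ascontiguousarray(a, dtype=float) for a in pot.table)
    else:
        tr = np.array([0.0, 1.0])
        tu = np.array([0.0, 0.0])
    return kind, pot.sigma, pot.epsilon, pot.kappa, pot.well_width, tr, tu, pot.cutoff


def _insert_initial(cfg: SimulationConfig, rng: np.random.Generator,
                    max_tries: int = 200) -> np.ndarray:
    """Random sequential insertion honouring the hard core."""
    pot = cfg.potential
    boxL = cfg.box.extents
    sigma = pot.sigma if pot.kind != "tabulated" else float(np.asarray(pot.table[0])[0])
    pos = np.empty((cfg.n_particles, 3))
    placed = 0
    for _ in range(max_tries * cfg.n_particles):
        if placed == cfg.n_particles:
            break
        trial = rng.random(3) * boxL
        if sigma > 0 and placed:
            d = pos[:placed] - trial
            d -= boxL * np.round(d / boxL)
            if np.min(np.einsum("ij,ij->i", d, d)) < sigma * sigma:
                continue
        pos[placed] = trial
        placed += 1
    if placed < cfg.n_particles:
        raise RuntimeError(
            f"could not insert {cfg.n_particles} hard cores (placed {placed}); "
            "lower the density"
        )
    return pos


def run_mc(cfg: SimulationConfig, energy_check_every: int = 1000):
    """Metropolis single-particle displacement sampling.

    The maximum displacement is tuned toward 30-50% acceptance during
    equilibration and frozen for the production sweeps (detailed balance).
    Returns (frames, info) where info carries acceptance_rate, the frozen
    step, and the worst incremental-vs-recomputed energy discrepancy.
    """
    rng = np.random.default_rng(cfg.seed)
    pos = _insert_initial(cfg, rng)
    boxL = np.ascontiguousarray(cfg.box.extents, dtype=float)
    args = _potential_args(cfg.potential)
    kind, sigma, eps, kappa, ww, tr, tu, rc = args

    nc = np.array([max(int(boxL[d] // max(rc, 1e-9)), 1) for d in range(3)], dtype=np.int64)
    use_cells = bool(nc.min() >= 3)
    if not use_cells:
        nc = np.array([1, 1, 1], dtype=np.int64)
    head, nxt = _build_cells(pos, boxL, nc)

    _numba_seed(cfg.seed & 0x7FFFFFFF)
    delta = float(cfg.max_displacement)
    delta_cap = float(boxL.min()) / 2.0

    # --- equilibration with step tuning ---
    block = 25
    done = 0
    while done < cfg.n_sweeps_equil:
        ns = min(block, cfg.n_sweeps_equil - done)
        acc, att, _ = _mc_sweeps(pos, boxL, *args, delta, ns, head, nxt, nc, use_cells)
        rate = acc / att
        if rate < 0.30:
            delta *= 0.9
        elif rate > 0.50:
            delta = min(delta * 1.1, delta_cap)
        done += ns

    # --- production ---
    energy = float(_total_energy(pos, boxL, *args))
    running = energy
    max_drift = 0.0
    frames = []
    accepted = attempted = 0
    n_frames = cfg.n_sweeps_sample // cfg.sample_every
    sweeps_done = 0
    for k in range(n_frames):
        acc, att, du = _mc_sweeps(pos, boxL, *args, delta, cfg.sample_every,
                                  head, nxt, nc, use_cells)
        accepted += acc
        attempted += att
        running += du
        sweeps_done += cfg.sample_every
        if sweeps_done % energy_check_every < cfg.sample_every or k == n_frames - 1:
            full = float(_total_energy(pos, boxL, *args))
            max_drift = max(max_drift, abs(full - running))
            running = full
        frames.append(
            ParticleSet(
                pos.copy() + cfg.box.origin,
                cfg.box,
                temperature=cfg.temperature,
                label=f"mc_frame_{k:04d}",
            )
        )
    info = {
        "acceptance_rate": accepted / attempted if attempted else 1.0,
        "max_displacement": delta,
        "energy_drift": max_drift,
        "n_frames": len(frames),
        "seed": cfg.seed,
    }
    return frames, info


# ---------------------------------------------------------------------------
# Tomogram-like artefacts
# ---------------------------------------------------------------------------

def inject_artifacts(
    ps: ParticleSet,
    tilt_x: float = 0.0,
    tilt_y: float = 0.0,
    enrichment_factor: float = 1.0,
    enrichment_depth: float = 10.0,
    seed: int = 0,
) -> ParticleSet:
    """Emulate slab tilt and surface (AWI) adsorption layers.

    Extra particles are Poisson-sampled into layers of ``enrichment_depth``
    at both z faces so their density reaches ``enrichment_factor`` times the
    bulk, then the whole cloud is rigidly rotated by the requested tilt.
    """
    if enrichment_factor < 1.0:
        raise ValueError("enrichment factor must be >= 1")
    rng = np.random.default_rng(seed)
    coords = ps.coordinates
    box = ps.box
    if enrichment_factor > 1.0:
        rho = ps.density
        area = box.extents[0] * box.extents[1]
        lam = (enrichment_factor - 1.0) * rho * area * enrichment_depth
        extras = []
        for face_lo in (True, False):
            n_extra = int(rng.poisson(lam))
            pts = box.origin + rng.random((n_extra, 3)) * box.extents
            if face_lo:
                pts[:, 2] = box.origin[2] + rng.random(n_extra) * enrichment_depth
            else:
                pts[:, 2] = box.upper[2] - rng.random(n_extra) * enrichment_depth
            extras.append(pts)
        coords = np.vstack([coords] + extras)
    if tilt_x or tilt_y:
        rot = tilt_rotation(tilt_x, tilt_y)
        centroid = coords.mean(axis=0)
        coords = rot.apply(coords - centroid) + centroid
    return ParticleSet(
        coords, box, temperature=ps.temperature,
        molecular_weight=ps.molecular_weight, label=ps.label,
        validate_bounds=False,
    )
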