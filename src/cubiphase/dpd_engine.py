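"""Dissipative particle dynamics engine for formulation microstructure runs.

Implements the standard Groot–Warren DPD scheme: soft conservative repulsion
``F_C = a_ij (1 - r/r_c) r̂`` for ``r < r_c``, a pairwise dissipative/random
thermostat ``F_D = -γ w(r)² (r̂·v_ij) r̂``, ``F_R = σ w(r) θ_ij r̂ / √dt``
with ``w(r) = 1 - r/r_c`` and ``σ² = 2 γ k_BT`` (fluctuation–dissipation),
plus harmonic bonds holding each GMO head bead (A) to its tail bead (B).
Integration uses the modified velocity-Verlet scheme with prediction factor
λ.  Reduced units throughout: ``r_c = 1``, ``k_BT = 1``, bead mass 1.

The per-pair thermostat noise θ_ij is counter-based — a hash of
(seed, step, pair) mapped to a zero-mean, unit-variance uniform variate — so
it is exactly symmetric in (i, j), independent of neighbor-list iteration
order, and bit-reproducible for a fixed seed.

Compositions are mapped to bead counts mole-proportionally, with GMO split
into one A and one B bead per molecule and one water bead representing
``waters_per_bead`` water molecules (default 3, the conventional DPD
coarse-graining degree).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from numba import njit

from .chi_params import SPECIES_IDS, Species, default_species_table

__all__ = [
    "Formulation",
    "DPDParams",
    "BeadSystem",
    "Trajectory",
    "map_composition",
    "box_for_counts",
    "init_system",
    "pair_forces",
    "run",
    "write_xyz",
    "read_xyz",
    "read_formulation_table",
    "pair_theta",
]

_SPECIES_INDEX = {s: i for i, s in enumerate(SPECIES_IDS)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Formulation:
    """A named mass-part composition of GMO / ethanol / water / drug."""

    name: str
    mass_parts: Mapping[str, float]

    _GROUPS = ("GMO", "ETHANOL", "WATER", "MET")

    def __post_init__(self) -> None:
        for g in self._GROUPS:
            if g not in self.mass_parts:
                raise ValueError(f"mass_parts must contain {g}")
            if self.mass_parts[g] < 0:
                raise ValueError(f"{g} mass parts must be non-negative")
        if self.total <= 0:
            raise ValueError("total mass parts must be positive")
        if self.mass_parts["GMO"] + self.mass_parts["WATER"] <= 0:
            raise ValueError("formulation needs GMO and/or water")

    @property
    def total(self) -> float:
        return float(sum(self.mass_parts[g] for g in self._GROUPS))

    def mass_fraction(self, group: str) -> float:
        return self.mass_parts[group] / self.total


@dataclass(frozen=True)
class DPDParams:
    """Simulation constants in DPD reduced units.

    Defaults are the Groot–Warren standard parameterization (ρ = 3,
    a_ii = 25 k_BT/r_c, γ = 4.5, σ = 3, dt = 0.04, λ = 0.65), consistent
    with the χ → a mapping coefficient 3.27.  ``sigma`` is derived from
    γ and kT when not given; fluctuation–dissipation (σ² = 2 γ kT) is
    enforced at construction.
    """

    rho: float = 3.0
    a_ii: float = 25.0
    gamma: float = 4.5
    sigma: float | None = None
    dt: float = 0.04
    lam: float = 0.65
    r_c: float = 1.0
    kT: float = 1.0
    bond_k: float = 100.0
    bond_r0: float = 0.7
    seed: int = 0
    n_steps: int = 15000
    equil_steps: int = 3000
    sample_every: int = 300

    def __post_init__(self) -> None:
        if self.sigma is None:
            object.__setattr__(self, "sigma", float(np.sqrt(2.0 * self.gamma * self.kT)))
        if abs(self.sigma**2 - 2.0 * self.gamma * self.kT) > 1e-9:
            raise ValueError(
                f"fluctuation-dissipation violated: sigma^2={self.sigma**2:.6g} "
                f"!= 2*gamma*kT={2 * self.gamma * self.kT:.6g}"
            )
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.rho > 0:
            raise ValueError("rho must be positive")
        if not 0 < self.lam <= 1:
            raise ValueError("lambda must be in (0, 1]")
        if self.r_c != 1.0:
            raise ValueError("r_c defines the length unit and must be 1")
        for name in ("n_steps", "equil_steps", "sample_every"):
            if getattr(self, name) < 0 or (name == "sample_every" and self.sample_every < 1):
                raise ValueError(f"{name} invalid")

    def digest(self) -> str:
        """Short provenance string of the numeric parameters."""
        items = [f"{k}={getattr(self, k)}" for k in (
            "rho", "a_ii", "gamma", "sigma", "dt", "lam", "bond_k", "bond_r0",
            "n_steps", "equil_steps", "sample_every")]
        return ",".join(items)


@dataclass
class BeadSystem:
    """Mesoscale particle state: periodic box, positions, velocities, bonds."""

    box: np.ndarray                # (3,) edge lengths
    positions: np.ndarray          # (N, 3), wrapped into the box
    velocities: np.ndarray         # (N, 3)
    types: np.ndarray              # (N,) int, index into SPECIES_IDS
    bonds: np.ndarray              # (M, 2) int, A-B dimer pairs
    unwrapped: np.ndarray | None = None  # (N, 3) for MSD bookkeeping

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=np.float64)
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        if self.unwrapped is None:
            self.unwrapped = self.positions.copy()
        if np.any(self.positions < -1e-9) or np.any(self.positions > self.box[None, :] + 1e-9):
            raise ValueError("positions must be wrapped into the box")
        a_idx = _SPECIES_INDEX["A"]
        b_idx = _SPECIES_INDEX["B"]
        a_beads = set(np.flatnonzero(self.types == a_idx).tolist())
        bonded_a = [int(i) for i, j in self.bonds]
        if sorted(bonded_a) != sorted(a_beads) or len(set(bonded_a)) != len(bonded_a):
            raise ValueError("every A bead must belong to exactly one bond")
        for i, j in self.bonds:
            if self.types[int(i)] != a_idx or self.types[int(j)] != b_idx:
                raise ValueError("bonds must pair an A bead with a B bead")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def species_count(self, species: str) -> int:
        return int(np.sum(self.types == _SPECIES_INDEX[species]))


@dataclass
class Trajectory:
    """Time-ordered snapshots plus per-frame thermodynamic scalars.

    Per-frame kinetic temperature and diagonal pressure-tensor components
    are means over the ``sample_every`` integration steps preceding each
    frame; the pressure includes the kinetic (ideal) part and the virial of
    the conservative and bond forces.
    """

    frames: np.ndarray             # (F, N, 3) wrapped positions
    unwrapped: np.ndarray          # (F, N, 3)
    velocities: np.ndarray | None  # (F, N, 3)
    times: np.ndarray              # (F,) DPD time
    types: np.ndarray              # (N,)
    box: np.ndarray                # (3,)
    params: DPDParams | None = None
    kinetic_T: np.ndarray | None = None      # (F,)
    pressure_diag: np.ndarray | None = None  # (F, 3): Pxx, Pyy, Pzz
    momentum: np.ndarray | None = None       # (F, 3)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if len(self.times) != len(self.frames):
            raise ValueError("times/frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def species_mask(self, species: str) -> np.ndarray:
        return self.types == _SPECIES_INDEX[species]


# ---------------------------------------------------------------------------
# composition -> beads
# ---------------------------------------------------------------------------

def map_composition(f: Formulation,
                    species: Mapping[str, Species] | None = None,
                    n_target: int = 3000,
                    waters_per_bead: int = 3) -> Tuple[Dict[str, int], Dict[str, float]]:
    """Convert mass parts to per-species bead counts near ``n_target``.

    Bead numbers are proportional to mole numbers (mass / molar mass); each
    GMO molecule contributes one A and one B bead (counts forced equal), and
    one water bead stands for ``waters_per_bead`` water molecules.

    Returns ``(counts, realized_mass_fractions)``.
    """
    if n_target < 100:
        raise ValueError("n_target must be at least 100")
    species = species or default_species_table()
    m_gmo = species["A"].molar_mass + species["B"].molar_mass
    moles = {
        "A": f.mass_parts["GMO"] / m_gmo,
        "B": f.mass_parts["GMO"] / m_gmo,
        "WATER": f.mass_parts["WATER"] / (species["WATER"].molar_mass * waters_per_bead),
        "ETHANOL": f.mass_parts["ETHANOL"] / species["ETHANOL"].molar_mass,
        "MET": f.mass_parts["MET"] / species["MET"].molar_mass,
    }
    total_moles = sum(moles.values())
    if total_moles <= 0:
        raise ValueError("composition maps to zero beads")
    counts: Dict[str, int] = {}
    n_ab = int(round(n_target * moles["A"] / total_moles))
    counts["A"] = counts["B"] = n_ab
    for sp in ("WATER", "ETHANOL", "MET"):
        counts[sp] = int(round(n_target * moles[sp] / total_moles))
    total = sum(counts.values())
    if total == 0:
        raise ValueError("composition maps to zero beads")
    if abs(total - n_target) > 0.05 * n_target:
        raise AssertionError(f"bead total {total} deviates >5% from target {n_target}")
    bead_mass = {
        "A": species["A"].molar_mass,
        "B": species["B"].molar_mass,
        "WATER": species["WATER"].molar_mass * waters_per_bead,
        "ETHANOL": species["ETHANOL"].molar_mass,
        "MET": species["MET"].molar_mass,
    }
    masses = {sp: counts[sp] * bead_mass[sp] for sp in counts}
    m_tot = sum(masses.values())
    fracs = {sp: (masses[sp] / m_tot if m_tot > 0 else 0.0) for sp in counts}
    return counts, fracs


def box_for_counts(counts: Mapping[str, int], rho: float = 3.0) -> np.ndarray:
    """Cubic box with volume N/ρ for the given bead counts."""
    n = sum(counts.values())
    edge = (n / rho) ** (1.0 / 3.0)
    return np.array([edge, edge, edge])


def init_system(counts: Mapping[str, int], box: Sequence[float],
                params: DPDParams, seed: int) -> BeadSystem:
    """Seeded random initial state.

    Positions uniform in the box (each B bead placed at bond_r0 from its A
    partner); velocities Maxwell–Boltzmann at kT, shifted to zero total
    momentum.
    """
    box = np.asarray(box, dtype=np.float64)
    n = int(sum(counts.values()))
    vol = float(np.prod(box))
    if abs(vol * params.rho - n) > 0.01 * n:
        raise ValueError(
            f"box volume {vol:.3f} x rho {params.rho} = {vol * params.rho:.1f} "
            f"inconsistent with {n} beads (>1% off)"
        )
    rng = np.random.default_rng(seed)
    types = []
    for sp in SPECIES_IDS:
        types.extend([_SPECIES_INDEX[sp]] * int(counts.get(sp, 0)))
    types = np.array(types, dtype=np.int64)
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box[None, :]
    a_ids = np.flatnonzero(types == _SPECIES_INDEX["A"])
    b_ids = np.flatnonzero(types == _SPECIES_INDEX["B"])
    if len(a_ids) != len(b_ids):
        raise ValueError("A and B bead counts must be equal")
    # place each B next to its A partner at the bond rest length
    for a, b in zip(a_ids, b_ids):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos[b] = (pos[a] + params.bond_r0 * u) % box
    bonds = np.column_stack([a_ids, b_ids]) if len(a_ids) else np.empty((0, 2), dtype=np.int64)
    vel = rng.normal(0.0, np.sqrt(params.kT), size=(n, 3))
    vel -= vel.mean(axis=0, keepdims=True)
    return BeadSystem(box=box, positions=pos % box, velocities=vel, types=types, bonds=bonds)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _splitmix64(z):
    z = np.uint64(z) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _theta(seed, step, i, j, n):
    """Zero-mean unit-variance uniform noise for pair (i, j) at a step."""
    if i > j:
        i, j = j, i
    p = np.uint64(i) * np.uint64(n) + np.uint64(j)
    z = _splitmix64(np.uint64(seed) ^ (np.uint64(step) * np.uint64(0xD1342543DE82EF95)))
    h = _splitmix64(z ^ _splitmix64(p))
    u = np.float64(h) / 18446744073709551616.0  # 2^64
    return 3.4641016151377544 * (u - 0.5)       # sqrt(12) -> unit variance


def pair_theta(seed: int, step: int, i: int, j: int, n: int) -> float:
    """Python-visible view of the kernel's pair-noise stream (for oracles)."""
    return float(_theta_py(seed, step, i, j, n))


def _theta_py(seed, step, i, j, n):
    mask = (1 << 64) - 1

    def sm(z):
        z = (z + 0x9E3779B97F4A7C15) & mask
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        return z ^ (z >> 31)

    if i > j:
        i, j = j, i
    p = (i * n + j) & mask
    z = sm((seed ^ ((step * 0xD1342543DE82EF95) & mask)) & mask)
    h = sm(z ^ sm(p))
    return np.sqrt(12.0) * (h / 2.0**64 - 0.5)


@njit(cache=True)
def _forces_kernel(pos, vel, types, bond_i, bond_j, box, a_mat,
                   gamma, sigma, inv_sqrt_dt, bond_k, bond_r0,
                   step, seed, use_random, use_dissipative,
                   forces, virial):
    """Cell-list pair loop (boxes < 3 r_c degenerate to a single all-pairs cell).

    ``virial`` (3,) accumulates the conservative + bond diagonal virial
    Σ F_d · r_d.  Forces are accumulated pairwise (Newton's third law exact).
    """
    n = pos.shape[0]
    forces[:] = 0.0
    virial[:] = 0.0
    ncx = int(box[0])
    ncy = int(box[1])
    ncz = int(box[2])
    if ncx < 3 or ncy < 3 or ncz < 3:
        ncx = ncy = ncz = 1          # all pairs in one cell
    ncell = ncx * ncy * ncz

    # counting sort of beads into cells (contiguous per-cell slices)
    cell_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        # clamp both ways: keeps the sort in-bounds even if a coordinate
        # degenerates (NaN/inf), letting the integrator's finiteness check
        # abort cleanly instead of corrupting memory
        cx = int(pos[i, 0] / box[0] * ncx)
        cy = int(pos[i, 1] / box[1] * ncy)
        cz = int(pos[i, 2] / box[2] * ncz)
        if cx >= ncx:
            cx = ncx - 1
        elif cx < 0:
            cx = 0
        if cy >= ncy:
            cy = ncy - 1
        elif cy < 0:
            cy = 0
        if cz >= ncz:
            cz = ncz - 1
        elif cz < 0:
            cz = 0
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        count[c + 1] += 1
    start = np.empty(ncell + 1, dtype=np.int64)
    start[0] = 0
    for c in range(ncell):
        start[c + 1] = start[c] + count[c + 1]
    cursor = start[:-1].copy()
    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = cell_of[i]
        order[cursor[c]] = i
        cursor[c] += 1

    # 13 half-neighbor cell ids per cell (none in the degenerate single cell)
    n_neigh = 13 if ncell > 1 else 0
    neigh = np.empty((ncell, 13), dtype=np.int64)
    if n_neigh > 0:
        for cx in range(ncx):
            for cy in range(ncy):
                for cz in range(ncz):
                    c = (cx * ncy + cy) * ncz + cz
                    k = 0
                    for ox, oy, oz in ((1, 0, 0), (0, 1, 0), (0, 0, 1),
                                       (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
                                       (0, 1, 1), (0, 1, -1),
                                       (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)):
                        nx = (cx + ox) % ncx
                        ny = (cy + oy) % ncy
                        nz = (cz + oz) % ncz
                        neigh[c, k] = (nx * ncy + ny) * ncz + nz
                        k += 1

    for c in range(ncell):
        s0 = start[c]
        s1 = start[c + 1]
        for ii in range(s0, s1):
            i = order[ii]
            for kk in range(n_neigh + 1):
                if kk == 0:
                    j0 = ii + 1      # same cell, i < j by sort order
                    j1 = s1
                else:
                    c2 = neigh[c, kk - 1]
                    j0 = start[c2]
                    j1 = start[c2 + 1]
                for jj in range(j0, j1):
                    j = order[jj]
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    dz = pos[i, 2] - pos[j, 2]
                    # minimum image: wrapped coordinates guarantee |d| < box
                    if dx > 0.5 * box[0]:
                        dx -= box[0]
                    elif dx < -0.5 * box[0]:
                        dx += box[0]
                    if dy > 0.5 * box[1]:
                        dy -= box[1]
                    elif dy < -0.5 * box[1]:
                        dy += box[1]
                    if dz > 0.5 * box[2]:
                        dz -= box[2]
                    elif dz < -0.5 * box[2]:
                        dz += box[2]
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 >= 1.0 or r2 < 1e-24:
                        continue
                    r = np.sqrt(r2)
                    w = 1.0 - r
                    ex = dx / r
                    ey = dy / r
                    ez = dz / r
                    fc = a_mat[types[i], types[j]] * w
                    # conservative part enters the virial
                    virial[0] += fc * ex * dx
                    virial[1] += fc * ey * dy
                    virial[2] += fc * ez * dz
                    fmag = fc
                    if use_dissipative:
                        vdote = ((vel[i, 0] - vel[j, 0]) * ex
                                 + (vel[i, 1] - vel[j, 1]) * ey
                                 + (vel[i, 2] - vel[j, 2]) * ez)
                        fmag -= gamma * w * w * vdote
                    if use_random:
                        fmag += sigma * w * _theta(seed, step, i, j, n) * inv_sqrt_dt
                    fx = fmag * ex
                    fy = fmag * ey
                    fz = fmag * ez
                    forces[i, 0] += fx
                    forces[i, 1] += fy
                    forces[i, 2] += fz
                    forces[j, 0] -= fx
                    forces[j, 1] -= fy
                    forces[j, 2] -= fz

    # harmonic A-B bonds (bonded pairs also feel the soft pair forces above)
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > 0.5 * box[0]:
            dx -= box[0]
        elif dx < -0.5 * box[0]:
            dx += box[0]
        if dy > 0.5 * box[1]:
            dy -= box[1]
        elif dy < -0.5 * box[1]:
            dy += box[1]
        if dz > 0.5 * box[2]:
            dz -= box[2]
        elif dz < -0.5 * box[2]:
            dz += box[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 1e-12:
            fmag = -bond_k * (r - bond_r0) / r
            fx = fmag * dx
            fy = fmag * dy
            fz = fmag * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            virial[0] += fx * dx
            virial[1] += fy * dy
            virial[2] += fz * dz


@njit(cache=True)
def _integrate(pos, unw, vel, types, bond_i, bond_j, box, a_mat,
               gamma, sigma, dt, lam, bond_k, bond_r0,
               n_total, equil, sample_every, seed,
               frames, frames_unw, frames_vel, frame_T, frame_P, frame_mom):
    """Modified velocity-Verlet main loop.  Returns (-1) or the step at which
    a non-finite coordinate appeared."""
    n = pos.shape[0]
    vol = box[0] * box[1] * box[2]
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    f = np.zeros((n, 3))
    f_new = np.zeros((n, 3))
    virial = np.zeros(3)
    _forces_kernel(pos, vel, types, bond_i, bond_j, box, a_mat, gamma, sigma,
                   inv_sqrt_dt, bond_k, bond_r0, 0, seed, True, True, f, virial)
    acc_T = 0.0
    acc_P = np.zeros(3)
    acc_n = 0
    frame = 0
    for step in range(1, n_total + 1):
        for i in range(n):
            for d in range(3):
                dr = dt * vel[i, d] + 0.5 * dt * dt * f[i, d]
                pos[i, d] += dr
                unw[i, d] += dr
                # wrap
                if pos[i, d] >= box[d]:
                    pos[i, d] -= box[d] * np.floor(pos[i, d] / box[d])
                elif pos[i, d] < 0.0:
                    pos[i, d] -= box[d] * np.floor(pos[i, d] / box[d])
        # predicted velocity for the force evaluation
        vtilde = vel + lam * dt * f
        _forces_kernel(pos, vtilde, types, bond_i, bond_j, box, a_mat, gamma, sigma,
                       inv_sqrt_dt, bond_k, bond_r0, step, seed, True, True,
                       f_new, virial)
        ke2 = 0.0
        kx = 0.0
        ky = 0.0
        kz = 0.0
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * (f[i, d] + f_new[i, d])
                f[i, d] = f_new[i, d]
            kx += vel[i, 0] * vel[i, 0]
            ky += vel[i, 1] * vel[i, 1]
            kz += vel[i, 2] * vel[i, 2]
        ke2 = kx + ky + kz
        acc_T += ke2 / (3.0 * n)
        acc_P[0] += (kx + virial[0]) / vol
        acc_P[1] += (ky + virial[1]) / vol
        acc_P[2] += (kz + virial[2]) / vol
        acc_n += 1
        if step > equil and (step - equil) % sample_every == 0:
            if not np.isfinite(pos).all():
                return step
            for i in range(n):
                for d in range(3):
                    frames[frame, i, d] = pos[i, d]
                    frames_unw[frame, i, d] = unw[i, d]
                    frames_vel[frame, i, d] = vel[i, d]
            frame_T[frame] = acc_T / acc_n
            frame_P[frame, 0] = acc_P[0] / acc_n
            frame_P[frame, 1] = acc_P[1] / acc_n
            frame_P[frame, 2] = acc_P[2] / acc_n
            for d in range(3):
                s = 0.0
                for i in range(n):
                    s += vel[i, d]
                frame_mom[frame, d] = s
            acc_T = 0.0
            acc_P[:] = 0.0
            acc_n = 0
            frame += 1
            if frame >= frames.shape[0]:
                break
    return -1


# ---------------------------------------------------------------------------
# public force / run API
# ---------------------------------------------------------------------------

def pair_forces(system: BeadSystem, params: DPDParams, a_mat: np.ndarray,
                step: int = 0, seed: int | None = None,
                include_random: bool = True,
                include_dissipative: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """Single force evaluation.

    Returns ``(forces, virial_diag)`` where the virial covers conservative
    and bond contributions (Σ F_d r_d per axis).
    """
    seed = params.seed if seed is None else seed
    n = system.n_beads
    forces = np.zeros((n, 3))
    virial = np.zeros(3)
    a_mat = np.ascontiguousarray(a_mat, dtype=np.float64)
    _forces_kernel(system.positions, system.velocities, system.types,
                   np.ascontiguousarray(system.bonds[:, 0]),
                   np.ascontiguousarray(system.bonds[:, 1]),
                   system.box, a_mat, params.gamma, params.sigma,
                   1.0 / np.sqrt(params.dt), params.bond_k, params.bond_r0,
                   step, seed, include_random, include_dissipative,
                   forces, virial)
    return forces, virial


def run(system: BeadSystem, params: DPDParams, a_mat: np.ndarray) -> Trajectory:
    """Integrate and sample a trajectory.

    Frames are recorded every ``sample_every`` steps after ``equil_steps``;
    per-frame temperature/pressure are block means over the preceding
    interval.  A fixed seed gives a bit-reproducible trajectory on one
    thread.  Raises ``FloatingPointError`` naming the step if a coordinate
    becomes non-finite.
    """
    pos = system.positions.copy()
    unw = (system.unwrapped if system.unwrapped is not None else pos).copy()
    vel = system.velocities.copy()
    n_frames = params.n_steps // params.sample_every
    if n_frames < 1:
        raise ValueError("n_steps must allow at least one sampled frame")
    n = system.n_beads
    frames = np.empty((n_frames, n, 3))
    frames_unw = np.empty((n_frames, n, 3))
    frames_vel = np.empty((n_frames, n, 3))
    frame_T = np.empty(n_frames)
    frame_P = np.empty((n_frames, 3))
    frame_mom = np.empty((n_frames, 3))
    a_mat = np.ascontiguousarray(a_mat, dtype=np.float64)
    bad = _integrate(pos, unw, vel, system.types,
                     np.ascontiguousarray(system.bonds[:, 0]),
                     np.ascontiguousarray(system.bonds[:, 1]),
                     system.box, a_mat, params.gamma, params.sigma, params.dt,
                     params.lam, params.bond_k, params.bond_r0,
                     params.equil_steps + params.n_steps, params.equil_steps,
                     params.sample_every, params.seed,
                     frames, frames_unw, frames_vel, frame_T, frame_P, frame_mom)
    if bad >= 0:
        raise FloatingPointError(f"non-finite coordinate at step {bad}")
    times = params.dt * (params.equil_steps
                         + params.sample_every * np.arange(1, n_frames + 1))
    return Trajectory(frames=frames, unwrapped=frames_unw, velocities=frames_vel,
                      times=times, types=system.types.copy(), box=system.box.copy(),
                      params=params, kinetic_T=frame_T, pressure_diag=frame_P,
                      momentum=frame_mom)


# ---------------------------------------------------------------------------
# I/O: extended XYZ and formulation tables
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path) -> None:
    """Write a trajectory as extended XYZ (species, wrapped and unwrapped
    coordinates; the comment line carries the box and frame time)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.frames.shape[1]}\n")
            bx, by, bz = traj.box
            fh.write(
                f'Lattice="{bx:.8f} 0.0 0.0 0.0 {by:.8f} 0.0 0.0 0.0 {bz:.8f}" '
                f'Properties=species:S:1:pos:R:3:unwrapped:R:3 Time={traj.times[f]:.8f}\n'
            )
            for i in range(traj.frames.shape[1]):
                sp = SPECIES_IDS[traj.types[i]]
                x, y, z = traj.frames[f, i]
                ux, uy, uz = traj.unwrapped[f, i]
                fh.write(f"{sp} {x:.8f} {y:.8f} {z:.8f} {ux:.8f} {uy:.8f} {uz:.8f}\n")


def read_xyz(path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_xyz`."""
    frames = []
    unwrapped = []
    times = []
    types = None
    box = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            lat = comment.split('Lattice="')[1].split('"')[0].split()
            box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
            t = float(comment.split("Time=")[1].split()[0])
            pos = np.empty((n, 3))
            unw = np.empty((n, 3))
            tps = np.empty(n, dtype=np.int64)
            for i in range(n):
                parts = fh.readline().split()
                tps[i] = _SPECIES_INDEX[parts[0]]
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                unw[i] = [float(parts[4]), float(parts[5]), float(parts[6])]
            frames.append(pos)
            unwrapped.append(unw)
            times.append(t)
            types = tps
    if not frames:
        raise ValueError(f"no frames in {path}")
    return Trajectory(frames=np.array(frames), unwrapped=np.array(unwrapped),
                      velocities=None, times=np.array(times), types=types, box=box)


def read_formulation_table(path) -> list[Formulation]:
    """Read a delimited formulation table (columns name, gmo, ethanol, water, met)."""
    import pandas as pd

    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    needed = {"name", "gmo", "ethanol", "water", "met"}
    if not needed <= set(df.columns):
        raise ValueError(f"formulation table needs columns {sorted(needed)}")
    out = []
    for _, row in df.iterrows():
        out.append(Formulation(str(row["name"]), {
            "GMO": float(row["gmo"]), "ETHANOL": float(row["ethanol"]),
            "WATER": float(row["water"]), "MET": float(row["met"]),
        }))
    return out
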