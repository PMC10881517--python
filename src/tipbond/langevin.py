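"""Coarse-grained Langevin dynamics of catch-bond-coupled semiflexible filaments.

Each filament is a 2D bead-spring chain of ``N`` beads (bond length
``sigma``) with harmonic stretching along the local tangent, a discrete
bending penalty on consecutive tangents, and WCA excluded volume between
all non-bonded bead pairs.  Two filaments are coupled by breakable
harmonic springs whose rupture rate is a catch-slip function of the
instantaneous spring load,

    omega_off(f) = omega0_1 exp(f / f_d1) + omega0_2 exp(-f / f_d2),

so bond lifetime is maximal at an intermediate load.  One filament of
each pair is tethered, the other pulled by a constant force; the
attachment lifetime is the time at which the last breakable bond ruptures.
Dimers can be combined into tetramers (two dimers pulled jointly), with
optional permanent cross-links between like filaments; cross-linking
flattens the catch region of the lifetime-force curve into an ideal-like
plateau.

All internals use reduced units (lengths in sigma, energies in kBT, time
in tau = alpha sigma^2 / kBT, unit mass and friction); ``to_physical``
maps results onto laboratory units.  Dynamics are underdamped Langevin
(BAOAB splitting) integrated with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "ReducedUnits",
    "LangevinParams",
    "FilamentSystem",
    "EnsembleResult",
    "stretching_energy",
    "bending_energy",
    "wca_energy",
    "catch_slip_rate",
    "optimal_bond_force",
    "to_physical",
    "build_arrangement",
    "compute_forces",
    "simulate_trajectory",
    "run_lifetime",
    "lifetime_vs_force",
]

ARRANGEMENTS = ("dimer", "tetramer_free", "tetramer_crosslinked")


@dataclass(frozen=True)
class ReducedUnits:
    """Mapping between reduced simulation units and laboratory units.

    Defaults: bond length 10 nm, ambient thermal energy 0.0042 pN*um, and
    drag alpha = 3 pi gamma sigma rounded to 0.1 pN*s/um (gamma = 1
    pN*s/um^2), giving a force unit of 0.42 pN and a time unit of about
    2.38 ms.
    """

    sigma_um: float = 0.01
    kBT_pN_um: float = 0.0042
    alpha_pN_s_per_um: float = 0.1

    @property
    def force_pN(self) -> float:
        return self.kBT_pN_um / self.sigma_um

    @property
    def time_s(self) -> float:
        return self.alpha_pN_s_per_um * self.sigma_um**2 / self.kBT_pN_um

    @property
    def length_nm(self) -> float:
        return self.sigma_um * 1000.0


def to_physical(value: float, quantity: str, units: ReducedUnits = ReducedUnits()):
    """Convert a reduced-unit value to physical units.

    Quantities and their physical units: ``length`` (nm), ``time`` (s),
    ``force`` (pN), ``rate`` (1/s), ``stiffness`` (pN/nm), ``bending``
    (pN*um^2), ``energy`` (pN*um).
    """
    factors = {
        "length": units.length_nm,
        "time": units.time_s,
        "force": units.force_pN,
        "rate": 1.0 / units.time_s,
        "stiffness": units.force_pN / units.length_nm,
        "bending": units.kBT_pN_um * units.sigma_um,
        "energy": units.kBT_pN_um,
    }
    if quantity not in factors:
        raise ValueError(
            f"unknown quantity {quantity!r}; expected one of {sorted(factors)}"
        )
    return value * factors[quantity]


@dataclass(frozen=True)
class LangevinParams:
    """Model parameters in reduced units.

    ``A`` is the stretching stiffness (kBT/sigma), ``kappa`` the bending
    rigidity (kBT*sigma) chosen so the rigidity parameter u = L/lambda =
    3.33 for N = 35, ``k_m`` the inter-filament spring stiffness
    (3e-3 A/sigma), and the four catch-slip constants set the bond
    detachment kinetics.
    """

    N: int = 35
    A: float = 5.0e3
    kappa: float = 5.1
    epsilon_wca: float = 1.0
    k_m: float = 15.0  # 3e-3 * A / sigma
    omega0_1: float = 4.0e-6
    omega0_2: float = 0.1
    f_d1: float = 5.0
    f_d2: float = 10.0
    dt: float = 0.001
    mass: float = 1.0
    friction: float = 1.0
    kBT: float = 1.0
    n_bonds: int = 10

    def __post_init__(self) -> None:
        for name in ("A", "kappa", "epsilon_wca", "k_m", "omega0_1",
                     "omega0_2", "f_d1", "f_d2", "dt", "mass", "friction",
                     "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt >= 0.1:
            raise ValueError("dt must be small compared to tau")


def catch_slip_rate(bond_force: float, params: LangevinParams) -> float:
    """Catch-slip detachment rate at a given spring load (1/tau)."""
    if bond_force < 0:
        raise ValueError("bond force magnitude must be >= 0")
    return params.omega0_1 * math.exp(bond_force / params.f_d1) + \
        params.omega0_2 * math.exp(-bond_force / params.f_d2)


def optimal_bond_force(params: LangevinParams) -> float:
    """Load at which the detachment rate is minimal (lifetime maximal)."""
    return math.log(
        params.omega0_2 * params.f_d1 / (params.omega0_1 * params.f_d2)
    ) / (1.0 / params.f_d1 + 1.0 / params.f_d2)


# --- reference (numpy) energies, used as oracles and by compute_forces ---

def stretching_energy(positions: np.ndarray, A: float, sigma: float = 1.0):
    """Harmonic stretching energy of one chain and its per-bead forces.

    ``eps_s = sum_i A/(2 sigma) |b_i - sigma t_i|^2`` with ``b_i`` the
    bond vector and ``t_i`` its unit tangent; equivalent to a spring of
    constant ``A/sigma`` on each bond length.
    """
    r = np.asarray(positions, dtype=float)
    if r.shape[0] < 2:
        raise ValueError("need at least 2 beads")
    b = np.diff(r, axis=0)
    d = np.linalg.norm(b, axis=1)
    if np.any(d == 0):
        raise ValueError("coincident consecutive beads: tangent undefined")
    t = b / d[:, None]
    energy = float(np.sum(A / (2 * sigma) * (d - sigma) ** 2))
    forces = np.zeros_like(r)
    fmag = (A / sigma) * (d - sigma)
    fvec = fmag[:, None] * t
    forces[:-1] += fvec
    forces[1:] -= fvec
    return energy, forces


def bending_energy(positions: np.ndarray, kappa: float, sigma: float = 1.0):
    """Discrete bending energy ``sum kappa/(2 sigma) |t_{i+1} - t_i|^2``.

    Zero for collinear tangents; forces are exact analytic gradients.
    """
    r = np.asarray(positions, dtype=float)
    if r.shape[0] < 3:
        raise ValueError("need at least 3 beads")
    b = np.diff(r, axis=0)
    d = np.linalg.norm(b, axis=1)
    if np.any(d == 0):
        raise ValueError("coincident consecutive beads: tangent undefined")
    t = b / d[:, None]
    dots = np.sum(t[1:] * t[:-1], axis=1)
    energy = float(np.sum(kappa / sigma * (1.0 - dots)))
    forces = np.zeros_like(r)
    pref = kappa / sigma
    for i in range(len(t) - 1):
        u, v = t[i], t[i + 1]
        uv = dots[i]
        # d(u.v)/d b_i and d(u.v)/d b_{i+1}
        g1 = (v - uv * u) / d[i]
        g2 = (u - uv * v) / d[i + 1]
        # E = pref (1 - u.v); dE/db = -pref * g
        forces[i] += -pref * g1
        forces[i + 1] += pref * (g1 - g2)
        forces[i + 2] += pref * g2
    return energy, forces


def wca_energy(
    positions: np.ndarray,
    epsilon: float,
    sigma: float = 1.0,
    exclude: set | None = None,
):
    """Shifted, purely repulsive Lennard-Jones (WCA) energy over all pairs.

    ``exclude`` is a set of (i, j) pairs (i < j) not subject to the
    repulsion (consecutive beads on the same filament).
    """
    r = np.asarray(positions, dtype=float)
    n = r.shape[0]
    cutoff = 2.0 ** (1.0 / 6.0) * sigma
    exclude = exclude or set()
    energy = 0.0
    forces = np.zeros_like(r)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if (i, j) in exclude:
                continue
            dvec = r[i] - r[j]
            dist = math.hypot(dvec[0], dvec[1]) if r.shape[1] == 2 else float(
                np.linalg.norm(dvec)
            )
            if dist == 0:
                raise ValueError(f"coincident beads {i}, {j}")
            if dist >= cutoff:
                continue
            sr6 = (sigma / dist) ** 6
            energy += 4 * epsilon * (sr6 * sr6 - sr6 + 0.25)
            fmag = 4 * epsilon * (12 * sr6 * sr6 - 6 * sr6) / dist
            fvec = fmag * dvec / dist
            forces[i] += fvec
            forces[j] -= fvec
    return float(energy), forces


@dataclass
class FilamentSystem:
    """Bead positions and connectivity of a filament arrangement."""

    positions: np.ndarray  # (n_beads, 2)
    n_filaments: int
    beads_per_filament: int
    breakable_bonds: np.ndarray  # (nb, 2) bead indices
    bond_rest: np.ndarray  # (nb,)
    permanent_links: np.ndarray  # (np, 2) bead indices
    link_rest: np.ndarray  # (np,)
    link_stiffness: np.ndarray  # (np,)
    tethered: np.ndarray  # bool mask (n_beads,)
    pull_force: np.ndarray  # (n_beads, 2) constant external force
    arrangement: str = "dimer"

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.breakable_bonds = np.ascontiguousarray(
            self.breakable_bonds.reshape(-1, 2), dtype=np.int64
        )
        self.permanent_links = np.ascontiguousarray(
            self.permanent_links.reshape(-1, 2), dtype=np.int64
        )
        for arr in (self.breakable_bonds, self.permanent_links):
            if arr.size and np.any(arr[:, 0] == arr[:, 1]):
                raise ValueError("a bond cannot connect a bead to itself")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


def build_arrangement(
    tag: str,
    params: LangevinParams = LangevinParams(),
    pull_force: float = 0.0,
) -> FilamentSystem:
    """Construct a dimer or tetramer geometry.

    ``dimer``: an anchored filament (first bead tethered) and a pulled
    filament whose first ``n_bonds`` beads overlap the anchored
    filament's last ``n_bonds`` beads, joined by breakable springs of
    rest length sigma; the pulled filament's far end carries the constant
    external force along +x.

    ``tetramer_free``: two dimers stacked mirror-symmetrically with the
    pulled filaments adjacent; their pulled ends are held together by a
    stiff permanent spring and each carries half the external force.

    ``tetramer_crosslinked``: tetramer_free plus three permanent
    cross-links of stiffness ``k_m``: two joining the anchored pair — near
    the anchor and adjacent to the bonded region, mimicking the PICA and
    EC3 lateral contacts of Pcdh15 — and one joining the pulled pair next
    to the bonded region, mimicking the EC1-EC1 contact of Cdh23.  Each
    filament pair is thus tied near both of its ends and moves as a unit.
    """
    if tag not in ARRANGEMENTS:
        raise ValueError(f"unknown arrangement {tag!r}; expected {ARRANGEMENTS}")
    N, nb = params.N, params.n_bonds
    if nb >= N:
        raise ValueError("n_bonds must be smaller than beads per filament")

    def chain(x0: float, y: float) -> np.ndarray:
        return np.column_stack([x0 + np.arange(N, dtype=float), np.full(N, y)])

    x_off = float(N - nb)
    if tag == "dimer":
        pos = np.vstack([chain(0.0, 0.0), chain(x_off, 1.0)])
        bonds = np.array([[N - nb + k, N + k] for k in range(nb)])
        perm = np.empty((0, 2), dtype=np.int64)
        link_rest = np.empty(0)
        link_k = np.empty(0)
        tether = np.zeros(2 * N, dtype=bool)
        tether[0] = True
        pull = np.zeros((2 * N, 2))
        pull[2 * N - 1] = (pull_force, 0.0)
    else:
        # filaments: 0 anchored A (y=0), 1 pulled A (y=1),
        #            2 pulled B (y=2), 3 anchored B (y=3)
        pos = np.vstack([
            chain(0.0, 0.0), chain(x_off, 1.0), chain(x_off, 2.0), chain(0.0, 3.0)
        ])
        bonds = np.array(
            [[N - nb + k, N + k] for k in range(nb)]
            + [[3 * N + N - nb + k, 2 * N + k] for k in range(nb)]
        )
        tether = np.zeros(4 * N, dtype=bool)
        tether[0] = True
        tether[3 * N] = True
        pull = np.zeros((4 * N, 2))
        end_a, end_b = 2 * N - 1, 3 * N - 1
        pull[end_a] = (pull_force / 2.0, 0.0)
        pull[end_b] = (pull_force / 2.0, 0.0)
        # pulled ends held together: stiff permanent spring
        perm_list = [(end_a, end_b)]
        rest_list = [float(np.linalg.norm(pos[end_a] - pos[end_b]))]
        k_list = [params.A]
        if tag == "tetramer_crosslinked":
            # PICA-like contact near the anchor; EC3-like contact adjacent
            # to the bonded region (three domains from the interface)
            for i in (2, N - nb - 1):
                a, b = i, 3 * N + i
                perm_list.append((a, b))
                rest_list.append(float(np.linalg.norm(pos[a] - pos[b])))
                k_list.append(params.k_m)
            a, b = N + nb, 2 * N + nb  # adjacent to the bonded region
            perm_list.append((a, b))
            rest_list.append(float(np.linalg.norm(pos[a] - pos[b])))
            k_list.append(params.k_m)
        perm = np.array(perm_list, dtype=np.int64)
        link_rest = np.array(rest_list)
        link_k = np.array(k_list)
    return FilamentSystem(
        positions=pos,
        n_filaments=2 if tag == "dimer" else 4,
        beads_per_filament=N,
        breakable_bonds=bonds,
        bond_rest=np.ones(len(bonds)),
        permanent_links=perm,
        link_rest=link_rest,
        link_stiffness=link_k,
        tethered=tether,
        pull_force=pull,
        arrangement=tag,
    )


# --- numba kernels -------------------------------------------------------

@njit(cache=True)
def _build_neighbours(pos, nfil, N, list_cut2):
    n = pos.shape[0]
    max_pairs = n * 24
    pairs = np.empty((max_pairs, 2), dtype=np.int64)
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if j == i + 1 and (i // N) == (j // N):
                continue  # consecutive beads on the same filament
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            if dx * dx + dy * dy < list_cut2:
                if count < max_pairs:
                    pairs[count, 0] = i
                    pairs[count, 1] = j
                count += 1
    return pairs[:count].copy()


@njit(cache=True)
def _forces_kernel(pos, F, nfil, N, A, kappa, eps, k_m, bonds, alive,
                   bond_rest, perm, perm_rest, perm_k, pull, pairs):
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = pull[i, 0]
        F[i, 1] = pull[i, 1]
    # stretching
    for f in range(nfil):
        base = f * N
        for i in range(N - 1):
            a = base + i
            b = a + 1
            dx = pos[b, 0] - pos[a, 0]
            dy = pos[b, 1] - pos[a, 1]
            d = math.sqrt(dx * dx + dy * dy)
            fmag = A * (d - 1.0) / d
            F[a, 0] += fmag * dx
            F[a, 1] += fmag * dy
            F[b, 0] -= fmag * dx
            F[b, 1] -= fmag * dy
    # bending
    for f in range(nfil):
        base = f * N
        for i in range(N - 2):
            a = base + i
            b = a + 1
            c = a + 2
            ux = pos[b, 0] - pos[a, 0]
            uy = pos[b, 1] - pos[a, 1]
            vx = pos[c, 0] - pos[b, 0]
            vy = pos[c, 1] - pos[b, 1]
            du = math.sqrt(ux * ux + uy * uy)
            dv = math.sqrt(vx * vx + vy * vy)
            ux /= du
            uy /= du
            vx /= dv
            vy /= dv
            uv = ux * vx + uy * vy
            g1x = (vx - uv * ux) / du
            g1y = (vy - uv * uy) / du
            g2x = (ux - uv * vx) / dv
            g2y = (uy - uv * vy) / dv
            F[a, 0] += -kappa * g1x
            F[a, 1] += -kappa * g1y
            F[b, 0] += kappa * (g1x - g2x)
            F[b, 1] += kappa * (g1y - g2y)
            F[c, 0] += kappa * g2x
            F[c, 1] += kappa * g2y
    # WCA over the neighbour list
    cutoff2 = 2.0 ** (1.0 / 3.0)
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r2 = dx * dx + dy * dy
        if r2 < cutoff2:
            inv2 = 1.0 / r2
            sr6 = inv2 * inv2 * inv2
            fmag = 4.0 * eps * (12.0 * sr6 * sr6 - 6.0 * sr6) * inv2
            F[i, 0] += fmag * dx
            F[i, 1] += fmag * dy
            F[j, 0] -= fmag * dx
            F[j, 1] -= fmag * dy
    # breakable inter-filament springs
    for bnd in range(bonds.shape[0]):
        if not alive[bnd]:
            continue
        a = bonds[bnd, 0]
        b = bonds[bnd, 1]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        d = math.sqrt(dx * dx + dy * dy)
        fmag = k_m * (d - bond_rest[bnd]) / d
        F[a, 0] += fmag * dx
        F[a, 1] += fmag * dy
        F[b, 0] -= fmag * dx
        F[b, 1] -= fmag * dy
    # permanent links
    for lk in range(perm.shape[0]):
        a = perm[lk, 0]
        b = perm[lk, 1]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        d = math.sqrt(dx * dx + dy * dy)
        fmag = perm_k[lk] * (d - perm_rest[lk]) / d
        F[a, 0] += fmag * dx
        F[a, 1] += fmag * dy
        F[b, 0] -= fmag * dx
        F[b, 1] -= fmag * dy


@njit(cache=True)
def _run_kernel(pos, vel, nfil, N, A, kappa, eps, k_m, bonds, alive,
                bond_rest, perm, perm_rest, perm_k, tethered, pull,
                dt, mass, friction, kBT, om1, om2, fd1, fd2,
                n_equil, n_max, seed, rupture_on,
                sample_every, samples_pos, samples_vel):
    np.random.seed(seed)
    n = pos.shape[0]
    F = np.zeros((n, 2))
    skin = 0.5
    list_cut2 = (2.0 ** (1.0 / 6.0) + skin) ** 2
    rebuild_every = 20
    c1 = math.exp(-friction * dt / mass)
    c2 = math.sqrt(kBT * (1.0 - c1 * c1) / mass)
    # Maxwell-Boltzmann start
    for i in range(n):
        if tethered[i]:
            vel[i, 0] = 0.0
            vel[i, 1] = 0.0
        else:
            vel[i, 0] = math.sqrt(kBT / mass) * np.random.normal()
            vel[i, 1] = math.sqrt(kBT / mass) * np.random.normal()
    pairs = _build_neighbours(pos, nfil, N, list_cut2)
    _forces_kernel(pos, F, nfil, N, A, kappa, eps, k_m, bonds, alive,
                   bond_rest, perm, perm_rest, perm_k, pull, pairs)
    n_alive = 0
    for bnd in range(alive.shape[0]):
        if alive[bnd]:
            n_alive += 1
    total = n_equil + n_max
    n_sampled = 0
    step_of_death = -1
    for step in range(total):
        if step % rebuild_every == 0:
            pairs = _build_neighbours(pos, nfil, N, list_cut2)
        # BAOAB
        for i in range(n):
            if tethered[i]:
                continue
            vel[i, 0] += 0.5 * dt * F[i, 0] / mass
            vel[i, 1] += 0.5 * dt * F[i, 1] / mass
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            vel[i, 0] = c1 * vel[i, 0] + c2 * np.random.normal()
            vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.normal()
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
        _forces_kernel(pos, F, nfil, N, A, kappa, eps, k_m, bonds, alive,
                       bond_rest, perm, perm_rest, perm_k, pull, pairs)
        for i in range(n):
            if tethered[i]:
                continue
            vel[i, 0] += 0.5 * dt * F[i, 0] / mass
            vel[i, 1] += 0.5 * dt * F[i, 1] / mass
            # blow-up guard
            if abs(vel[i, 0]) * dt > 1.0 or abs(vel[i, 1]) * dt > 1.0:
                return -2, n_sampled
        if rupture_on and step >= n_equil and n_alive > 0:
            for bnd in range(bonds.shape[0]):
                if not alive[bnd]:
                    continue
                a = bonds[bnd, 0]
                b = bonds[bnd, 1]
                dx = pos[b, 0] - pos[a, 0]
                dy = pos[b, 1] - pos[a, 1]
                d = math.sqrt(dx * dx + dy * dy)
                fload = k_m * abs(d - bond_rest[bnd])
                om = om1 * math.exp(fload / fd1) + om2 * math.exp(-fload / fd2)
                if np.random.random() < 1.0 - math.exp(-om * dt):
                    alive[bnd] = False
                    n_alive -= 1
            if n_alive == 0:
                step_of_death = step - n_equil + 1
                return step_of_death, n_sampled
        if sample_every > 0 and step >= n_equil and \
                (step - n_equil) % sample_every == 0:
            if n_sampled < samples_pos.shape[0]:
                for i in range(n):
                    samples_pos[n_sampled, i, 0] = pos[i, 0]
                    samples_pos[n_sampled, i, 1] = pos[i, 1]
                    samples_vel[n_sampled, i, 0] = vel[i, 0]
                    samples_vel[n_sampled, i, 1] = vel[i, 1]
                n_sampled += 1
    return -1, n_sampled  # censored / no rupture requested


def compute_forces(system: FilamentSystem, params: LangevinParams,
                   alive: np.ndarray | None = None) -> np.ndarray:
    """Total force on every bead for the current configuration.

    Exposed so the compiled kernel can be checked against the reference
    numpy energies.
    """
    pos = system.positions
    F = np.zeros_like(pos)
    if alive is None:
        alive = np.ones(len(system.breakable_bonds), dtype=np.bool_)
    skin = 0.5
    pairs = _build_neighbours(
        pos, system.n_filaments, system.beads_per_filament,
        (2.0 ** (1.0 / 6.0) + skin) ** 2,
    )
    _forces_kernel(
        pos, F, system.n_filaments, system.beads_per_filament,
        params.A, params.kappa, params.epsilon_wca, params.k_m,
        system.breakable_bonds, alive, system.bond_rest,
        system.permanent_links, system.link_rest, system.link_stiffness,
        system.pull_force, pairs,
    )
    return F


def _kernel_args(system: FilamentSystem, params: LangevinParams,
                 alive: np.ndarray):
    return (
        system.n_filaments, system.beads_per_filament,
        params.A, params.kappa, params.epsilon_wca, params.k_m,
        system.breakable_bonds, alive, system.bond_rest,
        system.permanent_links, system.link_rest, system.link_stiffness,
        system.tethered, system.pull_force,
        params.dt, params.mass, params.friction, params.kBT,
        params.omega0_1, params.omega0_2, params.f_d1, params.f_d2,
    )


def simulate_trajectory(
    system: FilamentSystem,
    params: LangevinParams,
    n_steps: int,
    sample_every: int,
    seed: int,
    n_equil: int = 0,
):
    """Integrate without bond rupture, returning sampled positions/velocities."""
    pos = system.positions.copy()
    vel = np.zeros_like(pos)
    alive = np.ones(len(system.breakable_bonds), dtype=np.bool_)
    n_samples = n_steps // sample_every + 1
    sp = np.zeros((n_samples, pos.shape[0], 2))
    sv = np.zeros_like(sp)
    status, n_sampled = _run_kernel(
        pos, vel, *_kernel_args(system, params, alive),
        n_equil, n_steps, seed, False, sample_every, sp, sv,
    )
    if status == -2:
        raise RuntimeError("numerical blow-up: displacement exceeded sigma per step")
    return sp[:n_sampled], sv[:n_sampled]


def run_lifetime(
    system: FilamentSystem,
    params: LangevinParams,
    seed: int,
    t_max: float = 3000.0,
    n_equil: int = 2000,
) -> tuple[float, bool]:
    """Attachment lifetime of one stochastic trajectory.

    Equilibrates with rupture disabled, then integrates until every
    breakable bond has ruptured (permanent cross-links are not part of
    the criterion).  Returns ``(lifetime_in_tau, censored)``; a lifetime
    capped at ``t_max`` is flagged censored.
    """
    if len(system.breakable_bonds) == 0:
        return 0.0, False
    pos = system.positions.copy()
    vel = np.zeros_like(pos)
    alive = np.ones(len(system.breakable_bonds), dtype=np.bool_)
    n_max = int(round(t_max / params.dt))
    dummy = np.zeros((1, pos.shape[0], 2))
    status, _ = _run_kernel(
        pos, vel, *_kernel_args(system, params, alive),
        n_equil, n_max, seed, True, 0, dummy, dummy.copy(),
    )
    if status == -2:
        raise RuntimeError(
            f"numerical blow-up (arrangement={system.arrangement}, seed={seed})"
        )
    if status == -1:
        return t_max, True
    return status * params.dt, False


@dataclass
class EnsembleResult:
    """Mean attachment lifetime vs pulling force over independent runs."""

    forces: np.ndarray
    mean_lifetimes: np.ndarray
    sem: np.ndarray
    n_runs: int
    n_censored: np.ndarray
    arrangement: str
    seed: int


def lifetime_vs_force(
    tag: str,
    forces: np.ndarray,
    n_runs: int,
    seed: int = 0,
    params: LangevinParams = LangevinParams(),
    t_max: float = 3000.0,
) -> EnsembleResult:
    """Ensemble mean attachment lifetime per pulling force."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 for a standard error")
    forces = np.asarray(forces, dtype=float)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_runs * forces.size) % 2**31
    means = np.empty(forces.size)
    sems = np.empty(forces.size)
    ncens = np.zeros(forces.size, dtype=int)
    for i, f in enumerate(forces):
        system = build_arrangement(tag, params, pull_force=f)
        taus = np.empty(n_runs)
        for r in range(n_runs):
            tau, cens = run_lifetime(
                system, params, int(seeds[i * n_runs + r]), t_max=t_max
            )
            taus[r] = tau
            ncens[i] += cens
        means[i] = taus.mean()
        sems[i] = taus.std(ddof=1) / np.sqrt(n_runs)
    return EnsembleResult(
        forces=forces, mean_lifetimes=means, sem=sems,
        n_runs=n_runs, n_censored=ncens, arrangement=tag, seed=seed,
    )
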