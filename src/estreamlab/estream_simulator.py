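"""Desk-scale Monte Carlo of secondary-electron streams in air.

This is the package's synthetic-data generator.  It reproduces the *structure*
of the phenomenon -- a single dominant hot spot on each panel whose magnitude
tracks the projected beam-footprint area -- not absolute dosimetry.  The chain
per photon history is:

1. a Co-60 photon (1.17 or 1.33 MeV line) is emitted from the source through
   a uniformly sampled point of the field square;
2. an exponential free path along the in-phantom chord decides whether and
   where it Compton-scatters (Compton is the only interaction modelled --
   it dominates at these energies in low-Z media);
3. the Compton electron energy and angle follow Klein-Nishina kinematics;
4. the electron is transported in a straight line under the continuous
   slowing-down approximation (CSDA); it escapes the phantom if the distance
   to the surface is below its residual range;
5. in air it follows an analytic helix along the 0.35 T field, losing energy
   along its path (CSDA in air), until it crosses a panel plane, re-enters
   the phantom, or runs out of range;
6. panel crossings deposit the electron's residual kinetic energy into the
   panel pixel grid; the dose maps are normalised so the Compton energy
   transferred in a 1 cm^3 voxel at the isocenter corresponds to the
   prescription dose.

Known biases are documented in the methods note: straight-line in-phantom
transport over-escapes, single scattering per photon, no electron return
effect.  All constants are frozen nominal values of standard tabulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .dosemap import DoseMap
from .geometry import BeamSetup, ExperimentCondition, PanelSetup, PhantomSetup

__all__ = [
    "PhysicsConfig",
    "SimConfig",
    "ElectronState",
    "SimResult",
    "klein_nishina_weight",
    "compton_kinematics",
    "sample_photons",
    "sample_interactions",
    "sample_compton",
    "propagate_electrons_to_surface",
    "helix_to_panel",
    "gyroradius_cm",
    "simulate_condition",
    "RangeTable",
]

ELECTRON_REST_MEV = 0.511
# r(cm) = pc(MeV) / (299.792458 * B(T)) * 100
_PC_TO_CM_PER_TESLA = 100.0 / 299.792458


@dataclass(frozen=True)
class RangeTable:
    """Log-log CSDA range table, MeV -> g/cm^2, divided by density to cm."""

    energies_mev: tuple[float, ...]
    ranges_gcm2: tuple[float, ...]
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        if len(self.energies_mev) != len(self.ranges_gcm2):
            raise ValueError("table columns must have equal length")
        if any(r <= 0 for r in self.ranges_gcm2) or self.density <= 0:
            raise ValueError("ranges and density must be positive")

    def range_cm(self, energy_mev: np.ndarray | float) -> np.ndarray:
        e = np.maximum(np.asarray(energy_mev, dtype=float), 1e-6)
        lr = np.interp(
            np.log(e), np.log(self.energies_mev), np.log(self.ranges_gcm2)
        )
        return np.exp(lr) / self.density

    def energy_from_range_cm(self, range_cm: np.ndarray | float) -> np.ndarray:
        r = np.maximum(np.asarray(range_cm, dtype=float) * self.density, 1e-12)
        le = np.interp(
            np.log(r), np.log(self.ranges_gcm2), np.log(self.energies_mev)
        )
        return np.exp(le)


# Frozen nominal CSDA tables (ESTAR-class values), g/cm^2.
PMMA_CSDA = RangeTable(
    energies_mev=(0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 1.5, 2.0),
    ranges_gcm2=(2.5e-4, 8.6e-4, 4.3e-3, 1.40e-2, 4.40e-2, 0.172, 0.428, 0.694, 0.963),
    density=1.18,
)
AIR_CSDA = RangeTable(
    energies_mev=(0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 1.5, 2.0),
    ranges_gcm2=(2.9e-4, 1.0e-3, 4.9e-3, 1.62e-2, 5.10e-2, 0.198, 0.491, 0.794, 1.10),
    density=1.205e-3,
)


@dataclass(frozen=True)
class PhysicsConfig:
    """Physics constants of the simulation (frozen nominal tabulations)."""

    photon_lines: tuple[tuple[float, float], ...] = ((1.17, 0.5), (1.33, 0.5))
    b_field: float = 0.35  # tesla, along +y
    electron_rest_energy: float = ELECTRON_REST_MEV
    # linear attenuation of PMMA (1/cm) at each line
    phantom_attenuation: tuple[float, ...] = (0.0753, 0.0701)
    phantom_csda: RangeTable = PMMA_CSDA
    air_csda: RangeTable = AIR_CSDA
    air_interactions: Literal["none", "csda"] = "csda"
    # ratio of straight-line penetration depth to true (scatter-lengthened)
    # path length for sub-MeV electrons in the phantom; the energy lost over
    # a geometric distance d is evaluated over d / detour_factor
    detour_factor: float = 0.6
    # Highland-type multiple-scattering spread applied at the exit surface;
    # radiation length of acrylic in cm (40.6 g/cm^2 / 1.18 g/cm^3)
    exit_scattering: bool = True
    phantom_radiation_length_cm: float = 34.4
    exit_scattering_max_rad: float = 1.4
    # diffusive-exit limit: redistribute each exit direction uniformly in
    # azimuth about the local face normal, keeping its polar angle to the
    # normal.  Sub-MeV electrons traversing >~1 mm of acrylic lose nearly all
    # azimuthal memory of the primary Compton kinematics, and the coherent
    # residue otherwise couples to the gyration sense and fabricates a large
    # spurious 30/330-gantry asymmetry.
    exit_azimuth_diffusion: bool = True
    # probability that an electron grazing back into the phantom surface
    # scatters out again instead of being absorbed (sub-MeV electrons have
    # large grazing-incidence backscatter coefficients)
    reentry_survival: float = 0.0

    def __post_init__(self) -> None:
        w = sum(w for _, w in self.photon_lines)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("photon line weights must sum to 1")
        if any(mu <= 0 for mu in self.phantom_attenuation):
            raise ValueError("attenuation coefficients must be positive")
        if len(self.phantom_attenuation) != len(self.photon_lines):
            raise ValueError("one attenuation coefficient per photon line")


@dataclass(frozen=True)
class SimConfig:
    condition: ExperimentCondition
    n_photons: int = 1_000_000
    seed: int = 0
    score: Literal["energy", "fluence"] = "energy"
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    reentry_check: bool = True
    # Gaussian response kernel applied to the binned maps (mm, 1 sigma).
    # Emulates the finite film/TPS spatial response and gives the maps the
    # smooth single-hot-spot structure the D_Rx analysis assumes; 0 disables.
    smoothing_sigma_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be at least 1")


@dataclass(frozen=True)
class ElectronState:
    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    kinetic_energy: float

    def __post_init__(self) -> None:
        if self.kinetic_energy <= 0:
            raise ValueError("kinetic energy must be positive")
        n = math.sqrt(sum(c * c for c in self.direction))
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")


@dataclass(frozen=True)
class SimResult:
    front_map: DoseMap
    end_map: DoseMap
    isocenter_score: float
    escaped_count: int
    panel_hit_counts: tuple[int, int]  # (front, end)
    n_photons: int
    compton_energy_total: float  # MeV, all Compton electrons generated
    panel_energy_total: float  # MeV scored on both panels (pre-normalisation)


# ---------------------------------------------------------------------------
# Sampling primitives (vectorised; each takes and advances a Generator)


def sample_photons(
    beam: BeamSetup, physics: PhysicsConfig, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample ``n`` photon origins (the source), unit directions and energies.

    Directions pass through uniform points of the field square drawn on the
    transverse isocenter plane (edges along x and y), matching the geometry
    module's calibrated field convention.
    """
    energies_w = np.array([w for _, w in physics.photon_lines])
    lines = np.array([e for e, _ in physics.photon_lines])
    idx = rng.choice(len(lines), size=n, p=energies_w)
    energy = lines[idx]
    h = beam.field_size / 2.0
    a = rng.uniform(-h, h, size=n)
    b = rng.uniform(-h, h, size=n)
    targets = np.column_stack([b, a, np.zeros(n)])  # e2 = x, e1 = y
    src = beam.source
    d = targets - src
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return np.broadcast_to(src, (n, 3)), d, energy


def _box_chord(
    phantom: PhantomSetup, origins: np.ndarray, directions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit parameters (t_in, t_out) of rays with the tilted box;
    t_out <= t_in means no intersection."""
    rot = phantom.rotation
    o = origins @ rot
    d = directions @ rot
    half = np.asarray(phantom.dimensions) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-half - o) / d
        t2 = (half - o) / d
    near = np.where(np.isfinite(t1), np.minimum(t1, t2), -np.inf)
    far = np.where(np.isfinite(t2), np.maximum(t1, t2), np.inf)
    # parallel-to-slab rays: inside the slab -> unconstrained, outside -> miss
    par = np.abs(d) < 1e-12
    inside = np.abs(o) <= half
    near = np.where(par, np.where(inside, -np.inf, np.inf), near)
    far = np.where(par, np.where(inside, np.inf, -np.inf), far)
    t_in = np.maximum(near.max(axis=1), 0.0)
    t_out = far.min(axis=1)
    return t_in, t_out


def sample_interactions(
    origins: np.ndarray,
    directions: np.ndarray,
    energies: np.ndarray,
    phantom: PhantomSetup,
    physics: PhysicsConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential free-path sampling along the in-phantom chord.

    Returns (interacted mask, interaction points).  Photons whose sampled
    free path exceeds the chord length pass through.
    """
    t_in, t_out = _box_chord(phantom, origins, directions)
    chord = np.maximum(t_out - t_in, 0.0)
    lines = np.array([e for e, _ in physics.photon_lines])
    mu = np.array(physics.phantom_attenuation)[
        np.argmin(np.abs(energies[:, None] - lines[None, :]), axis=1)
    ]
    path = rng.exponential(1.0, size=len(energies)) / mu
    interacted = (chord > 0) & (path < chord)
    t_hit = t_in + path
    points = origins + t_hit[:, None] * directions
    return interacted, points


def klein_nishina_weight(cos_theta: np.ndarray | float, alpha: float) -> np.ndarray:
    """Unnormalised Klein-Nishina angular weight d(sigma)/d(Omega) as a
    function of the photon scattering angle cosine (max value 2 at 0 deg)."""
    c = np.asarray(cos_theta, dtype=float)
    eps = 1.0 / (1.0 + alpha * (1.0 - c))
    return eps**2 * (eps + 1.0 / eps - (1.0 - c**2))


def compton_kinematics(
    energy_mev: np.ndarray | float, cos_theta: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Electron kinetic energy T and polar angle phi for a photon of energy E
    scattering by angle theta:  T = E a (1-cos t) / (1 + a (1-cos t)),
    cot(phi) = (1+a) tan(t/2), with a = E / m_e c^2."""
    e = np.asarray(energy_mev, dtype=float)
    c = np.asarray(cos_theta, dtype=float)
    alpha = e / ELECTRON_REST_MEV
    k = alpha * (1.0 - c)
    t_e = e * k / (1.0 + k)
    theta = np.arccos(np.clip(c, -1.0, 1.0))
    tan_half = np.tan(theta / 2.0)
    with np.errstate(divide="ignore"):
        phi = np.arctan2(1.0, (1.0 + alpha) * tan_half)
    return t_e, phi


def sample_compton(
    energies: np.ndarray, physics: PhysicsConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample photon scattering cosines from Klein-Nishina and
    return (cos_theta, electron kinetic energy, electron polar angle)."""
    e = np.asarray(energies, dtype=float)
    n = e.size
    cos_t = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        c = rng.uniform(-1.0, 1.0, size=todo.size)
        alpha = e[todo] / ELECTRON_REST_MEV
        eps = 1.0 / (1.0 + alpha * (1.0 - c))
        w = eps**2 * (eps + 1.0 / eps - (1.0 - c**2))
        accept = rng.uniform(0.0, 2.0, size=todo.size) < w
        cos_t[todo[accept]] = c[accept]
        todo = todo[~accept]
    t_e, phi = compton_kinematics(e, cos_t)
    return cos_t, t_e, phi


def _electron_directions(
    photon_dirs: np.ndarray, phi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Electron unit directions at polar angle phi from the photon direction,
    uniform azimuth."""
    d = photon_dirs
    # orthonormal frame around each photon direction
    helper = np.where(
        np.abs(d[:, 2:3]) < 0.9, np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
    )
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    psi = rng.uniform(0.0, 2.0 * np.pi, size=len(d))
    sp, cp = np.sin(phi), np.cos(phi)
    return (
        cp[:, None] * d
        + sp[:, None] * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2)
    )


def propagate_electrons_to_surface(
    points: np.ndarray,
    directions: np.ndarray,
    energies: np.ndarray,
    phantom: PhantomSetup,
    table: RangeTable,
    detour_factor: float = 0.6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Straight-line CSDA transport of electrons born inside the phantom.

    Returns (escaped mask, exit points, exit energies, path lengths).  An
    electron escapes if the path length needed to reach the surface -- the
    geometric distance divided by the detour factor, accounting for the
    scatter-lengthened true path -- is below the CSDA range at its energy;
    it exits with the residual-range energy.
    """
    _, t_out = _box_chord(phantom, points, directions)
    path = t_out / detour_factor
    rng_cm = table.range_cm(energies)
    escaped = (path < rng_cm) & (energies > 1e-4)
    residual = np.maximum(rng_cm - path, 0.0)
    exit_e = table.energy_from_range_cm(residual)
    exit_pts = points + t_out[:, None] * directions
    return escaped, exit_pts, np.where(escaped, exit_e, 0.0), path


def _outward_normals(phantom: PhantomSetup, surface_pts: np.ndarray) -> np.ndarray:
    """World-frame outward face normal at each surface point (nearest face)."""
    rot = phantom.rotation
    local = surface_pts @ rot
    half = np.asarray(phantom.dimensions) / 2.0
    # distance of each coordinate from its face plane; nearest face wins
    gap = half[None, :] - np.abs(local)
    face = np.argmin(gap, axis=1)
    signs = np.sign(local[np.arange(len(local)), face])
    signs[signs == 0] = 1.0
    normals_local = np.zeros_like(local)
    normals_local[np.arange(len(local)), face] = signs
    return normals_local @ rot.T


def apply_exit_scattering(
    exit_pts: np.ndarray,
    directions: np.ndarray,
    energies: np.ndarray,
    path_cm: np.ndarray,
    phantom: PhantomSetup,
    physics: PhysicsConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multiple-scattering kick at the exit surface (Highland formula).

    Straight-line CSDA transport keeps the Compton azimuthal memory of each
    electron all the way to the surface, which is unphysical for sub-MeV
    electrons: over even a millimetre of acrylic the Highland angle is tens
    of degrees.  A single condensed Gaussian kick drawn from the scattering
    accumulated over the in-phantom path restores the angular diffusion.
    Kicked directions that point back into the phantom are mirrored about the
    local face plane so every electron still exits.
    """
    t = np.maximum(energies, 1e-4)
    e_tot = t + ELECTRON_REST_MEV
    pc = np.sqrt(e_tot**2 - ELECTRON_REST_MEV**2)
    beta_pc = pc**2 / e_tot
    xr = np.maximum(path_cm, 1e-3) / physics.phantom_radiation_length_cm
    theta0 = 13.6 / beta_pc * np.sqrt(xr) * (1.0 + 0.038 * np.log(xr))
    theta0 = np.clip(theta0, 0.0, physics.exit_scattering_max_rad)
    kick = np.abs(rng.normal(0.0, theta0))
    psi = rng.uniform(0.0, 2.0 * np.pi, size=len(directions))
    d = directions
    helper = np.where(
        np.abs(d[:, 2:3]) < 0.9, np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
    )
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    new_d = (
        np.cos(kick)[:, None] * d
        + np.sin(kick)[:, None] * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2)
    )
    n_out = _outward_normals(phantom, exit_pts)
    comp = np.sum(new_d * n_out, axis=1)
    inward = comp < 0
    new_d[inward] -= 2.0 * comp[inward, None] * n_out[inward]
    new_d /= np.linalg.norm(new_d, axis=1, keepdims=True)
    if physics.exit_azimuth_diffusion:
        new_d = _randomize_azimuth(new_d, n_out, rng)
    return new_d


def _randomize_azimuth(
    directions: np.ndarray, normals: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly redistribute each direction's azimuth about its normal,
    preserving the polar angle to the normal."""
    cos_p = np.sum(directions * normals, axis=1)
    helper = np.where(
        np.abs(normals[:, 2:3]) < 0.9,
        np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 0.0, 0.0]),
    )
    e1 = np.cross(normals, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(normals, e1)
    sin_p = np.sqrt(np.clip(1.0 - cos_p**2, 0.0, 1.0))
    psi = rng.uniform(0.0, 2.0 * np.pi, size=len(directions))
    return (
        cos_p[:, None] * normals
        + sin_p[:, None]
        * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2)
    )


def gyroradius_cm(kinetic_energy_mev: np.ndarray | float, b_tesla: float,
                  sin_pitch: np.ndarray | float = 1.0) -> np.ndarray:
    """Gyroradius r = p_perp / (e B) for an electron, in cm."""
    t = np.asarray(kinetic_energy_mev, dtype=float)
    pc = np.sqrt((t + ELECTRON_REST_MEV) ** 2 - ELECTRON_REST_MEV**2)
    return pc * np.asarray(sin_pitch) * _PC_TO_CM_PER_TESLA / b_tesla


_REENTRY_SAMPLES_PER_TURN = 36
_REENTRY_MAX_SAMPLES = 720  # 20 turns; beyond that the phantom is out of reach
                            # for all but pathological pitch angles


def helix_to_panel(
    positions: np.ndarray,
    directions: np.ndarray,
    energies: np.ndarray,
    panel: PanelSetup,
    physics: PhysicsConfig,
    phantom: PhantomSetup | None = None,
    reentry_check: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic helical transport of escaped electrons to a panel plane.

    Returns (hit mask, (u, v) crossing coordinates, energy at crossing).
    Misses (distinct outcomes, not errors) are: axial velocity smaller than
    1e-9 of the speed, wrong sign for the requested panel, re-entry into the
    phantom box before crossing, or (with the "csda" air model) running out
    of residual range along the helical path.

    With ``b_field = 0`` the trajectory degenerates to a straight line.
    """
    pos = np.asarray(positions, dtype=float)
    d = np.asarray(directions, dtype=float)
    e = np.asarray(energies, dtype=float)
    y_panel = panel.y
    vy = d[:, 1]
    ok = np.abs(vy) >= 1e-9
    ok &= np.sign(vy) == np.sign(y_panel)
    dy = y_panel - pos[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        s_star = dy / vy  # arc length to crossing
    ok &= s_star > 0

    sin_a = np.sqrt(np.clip(d[:, 0] ** 2 + d[:, 2] ** 2, 0.0, 1.0))
    b = abs(physics.b_field)
    chirality = 1.0 if physics.b_field >= 0 else -1.0
    uv = np.zeros((len(pos), 2))

    if b > 0:
        r_g = gyroradius_cm(np.maximum(e, 1e-6), b, 1.0) * sin_a
        # circle centre in the x-z plane: centre = pos + chi * r * (dz, -dx)/sin_a
        with np.errstate(divide="ignore", invalid="ignore"):
            ex = np.where(sin_a > 0, d[:, 0] / sin_a, 0.0)
            ez = np.where(sin_a > 0, d[:, 2] / sin_a, 0.0)
        cx = pos[:, 0] + chirality * r_g * ez
        cz = pos[:, 2] - chirality * r_g * ex
        rho_x = pos[:, 0] - cx
        rho_z = pos[:, 2] - cz

        def xz_at(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            with np.errstate(divide="ignore", invalid="ignore"):
                theta = np.where(
                    r_g > 0, -chirality * sin_a * s / np.maximum(r_g, 1e-300), 0.0
                )
            ct, st = np.cos(theta), np.sin(theta)
            x = cx + ct * rho_x - st * rho_z
            z = cz + st * rho_x + ct * rho_z
            # sin_a == 0: pure axial motion, x-z frozen
            x = np.where(sin_a > 0, x, pos[:, 0])
            z = np.where(sin_a > 0, z, pos[:, 2])
            return x, z

    else:

        def xz_at(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            return pos[:, 0] + d[:, 0] * s, pos[:, 2] + d[:, 2] * s

    # air energy loss along the helical arc (scatter-lengthened by the same
    # detour factor as in the phantom)
    e_out = e.copy()
    if physics.air_interactions == "csda":
        res = physics.air_csda.range_cm(e) - np.abs(s_star) / physics.detour_factor
        alive = res > 0
        e_out = np.where(
            alive, physics.air_csda.energy_from_range_cm(np.maximum(res, 1e-12)), 0.0
        )
        ok &= alive

    if reentry_check and phantom is not None and b > 0:
        # sample the helix at 36 points per turn while still within the
        # y-band the box occupies (capped; documented approximation)
        half = np.asarray(phantom.dimensions) / 2.0
        y_band = abs(half[1] * phantom.rotation[1, 1]) + abs(
            half[2] * phantom.rotation[1, 2]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ds = np.where(
                sin_a > 1e-12,
                2.0 * np.pi * r_g / (_REENTRY_SAMPLES_PER_TURN * sin_a),
                np.inf,
            )
            s_band = (np.sign(vy) * y_band - pos[:, 1]) / vy
        s_lim = np.minimum(np.maximum(s_band, 0.0), s_star)
        n_samp = np.where(
            np.isfinite(ds) & (ds > 0),
            np.minimum(np.ceil(s_lim / np.maximum(ds, 1e-300)), _REENTRY_MAX_SAMPLES),
            0,
        ).astype(int)
        max_n = int(n_samp.max()) if len(n_samp) else 0
        reentered = np.zeros(len(pos), dtype=bool)
        in_prev = np.zeros(len(pos), dtype=bool)
        p_surv = physics.reentry_survival
        for k in range(1, max_n + 1):
            act = (n_samp >= k) & ok & ~reentered
            if not act.any():
                continue
            s_k = np.minimum(k * ds, s_lim)
            x_k, z_k = xz_at(s_k)
            y_k = pos[:, 1] + vy * s_k
            pts = np.column_stack([x_k, y_k, z_k])
            inside = phantom.contains(pts, pad=-1e-9)
            entering = act & inside & ~in_prev
            if p_surv > 0 and rng is not None and entering.any():
                spared = entering & (
                    rng.uniform(size=len(pos)) < p_surv
                )
                reentered |= entering & ~spared
            else:
                reentered |= entering
            in_prev = inside
        ok &= ~reentered

    x_c, z_c = xz_at(np.where(ok, s_star, 0.0))
    uv[:, 0] = x_c
    uv[:, 1] = z_c
    return ok, uv, np.where(ok, e_out, 0.0)


# ---------------------------------------------------------------------------
# Full chain


def _panel_grid(panel: PanelSetup) -> tuple[int, float]:
    px_cm = panel.pixel_size / 10.0
    n = int(panel.extent[0] // px_cm)
    return n, px_cm


def _bin_panel(
    uv: np.ndarray, weights: np.ndarray, panel: PanelSetup
) -> tuple[np.ndarray, float]:
    n, px_cm = _panel_grid(panel)
    half = n * px_cm / 2.0
    iu = np.floor((uv[:, 0] + half) / px_cm).astype(int)
    iv = np.floor((uv[:, 1] + half) / px_cm).astype(int)
    on = (iu >= 0) & (iu < n) & (iv >= 0) & (iv < n)
    grid = np.zeros((n, n))
    np.add.at(grid, (iv[on], iu[on]), weights[on])
    return grid, -half + px_cm / 2.0


def simulate_condition(cfg: SimConfig) -> SimResult:
    """Run the full photon -> Compton -> escape -> helix -> panel chain.

    Both panels of the condition's (distance, pixel grid) are scored in one
    pass; the returned maps are normalised so that the Compton energy
    transferred in a 1 cm^3 voxel at the isocenter equals the prescription
    dose (the package's own normalisation bridge, see the methods note).
    """
    cond = cfg.condition
    phys = cfg.physics
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_photons

    origins, dirs, energy = sample_photons(cond.beam, phys, rng, n)
    interacted, points = sample_interactions(
        origins, dirs, energy, cond.phantom, phys, rng
    )
    points = points[interacted]
    p_dirs = dirs[interacted]
    p_e = energy[interacted]

    _, t_e, phi = sample_compton(p_e, phys, rng)
    e_dirs = _electron_directions(p_dirs, phi, rng)
    live = t_e > 1e-4
    points, e_dirs, t_e = points[live], e_dirs[live], t_e[live]

    # isocenter normalisation voxel: 1 cm^3 cube at the origin
    in_voxel = np.all(np.abs(points) <= 0.5, axis=1)
    iso_score = float(t_e[in_voxel].sum())
    if iso_score <= 0:
        raise ValueError(
            "zero isocenter score: no Compton interactions in the isocenter "
            "voxel; increase n_photons"
        )
    compton_total = float(t_e.sum())

    escaped, exit_pts, exit_e, path_cm = propagate_electrons_to_surface(
        points, e_dirs, t_e, cond.phantom, phys.phantom_csda, phys.detour_factor
    )
    exit_pts = exit_pts[escaped]
    exit_dirs = e_dirs[escaped]
    exit_e = exit_e[escaped]
    if phys.exit_scattering:
        exit_dirs = apply_exit_scattering(
            exit_pts, exit_dirs, exit_e, path_cm[escaped], cond.phantom, phys, rng
        )

    maps = {}
    hits = {}
    e_panels = 0.0
    for side in ("front", "end"):
        panel = PanelSetup(
            side, cond.panel.distance, cond.panel.extent, cond.panel.pixel_size
        )
        ok, uv, e_at = helix_to_panel(
            exit_pts, exit_dirs, exit_e, panel, phys, cond.phantom,
            cfg.reentry_check, rng,
        )
        w = e_at[ok] if cfg.score == "energy" else np.ones(int(ok.sum()))
        grid, origin0 = _bin_panel(uv[ok], w, panel)
        if cfg.smoothing_sigma_mm > 0:
            from scipy.ndimage import gaussian_filter

            grid = gaussian_filter(
                grid, cfg.smoothing_sigma_mm / panel.pixel_size, mode="constant"
            )
        e_panels += float(e_at[ok].sum())
        scale = cond.prescription_dose / iso_score
        maps[side] = DoseMap(
            grid * scale,
            panel.pixel_size,
            (origin0, origin0),
            label=f"{cond.label()}::{side}",
        )
        hits[side] = int(ok.sum())

    return SimResult(
        front_map=maps["front"],
        end_map=maps["end"],
        isocenter_score=iso_score,
        escaped_count=int(escaped.sum()),
        panel_hit_counts=(hits["front"], hits["end"]),
        n_photons=n,
        compton_energy_total=compton_total,
        panel_energy_total=e_panels,
    )
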