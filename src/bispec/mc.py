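"""Particle-based stochastic reaction-diffusion simulator.

A cuboid reaction vessel with a square membrane patch (default 0.1 um^2)
as its bottom face stands in for a small piece of the 10 um spherical
cell.  Targets are seeded on the membrane at the cell-surface density and
diffuse laterally; a fixed number of antibody particles (default 605)
diffuse in the volume, whose height is chosen so that their number matches
the desired molarity.  Association happens when reactants come within a
reaction radius (the sum of their hydrodynamic radii) and then fire with a
per-encounter probability calibrated against the macroscopic rate
constant; dissociation is sampled as a per-step exponential.

Two regimes, two calibration strategies:

* volume-surface association (k1, k2 ~ 1e5 1/(M s)) is far below the 3D
  diffusion-limited encounter rate, so successive encounter samples are
  uncorrelated (the antibody rms step is ~10x the reaction radius) and the
  event rate is linear in p; calibration uses ghost counting.
* surface-surface association is diffusion-influenced (target rate 0.7
  um^2/(molecule s) vs a 2D encounter ceiling of order 4D = 0.4); here the
  encounter pairs persist across steps, the rate saturates as p -> 1, and
  calibration measures the pseudo-first-order decay of tracers at the
  operating density.  When the requested rate exceeds the ceiling the
  simulator reacts on contact (p = 1), i.e. runs the association fully
  diffusion-controlled -- the regime the model assumes anyway.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .ode import CurveResult, wash_correction, SurfaceState
from .params import AssayConfig, CellSurfaceModel, KineticConstants, ParameterError
from .rates import cuboid_height_for_concentration, cuboid_seed_count
from .units import N_A, UM2_PER_CM2

logger = logging.getLogger(__name__)

SPECIES = ("A", "T1", "T2", "AT1", "AT2", "AT1T2")


class CalibrationError(RuntimeError):
    """Requested macroscopic rate is unreachable at p = 1 for this geometry."""


@dataclass(frozen=True)
class MCBoxConfig:
    """Geometry, discretization and bookkeeping for one simulation box."""

    patch_area_um2: float = 0.1
    n_antibody: int = 605
    dt_s: float = 1e-6
    rng_seed: int = 0
    n_replicates: int = 3
    lateral_boundary: str = "periodic"   # "periodic" | "reflective"
    record_every_s: float = 1.0
    # hydrodynamic radii (nm); the reaction radius of a pair is their sum
    radius_antibody_nm: float = 5.5
    radius_target_nm: float = 2.5
    radius_complex_nm: float = 5.5
    placement_offset_nm: float = 0.1     # product separation beyond contact
    # mobility (cm^2/s); complexes move with the membrane anchor by default
    D_surface_cm2_s: float = 5e-10
    D_complex_cm2_s: float = 5e-10
    D_volume_cm2_s: float = 4e-7
    # far-field coarsening of the tall antibody column
    far_z_um: float = 1.0
    far_mult: int = 100

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ParameterError("dt must be > 0")
        if self.patch_area_um2 <= 0:
            raise ParameterError("patch area must be > 0")
        if self.lateral_boundary not in ("periodic", "reflective"):
            raise ParameterError(f"unknown boundary {self.lateral_boundary!r}")
        # guard: surface-pair diffusion must resolve the reaction radius
        rms = math.sqrt(2.0 * max(self.D_surface_cm2_s, self.D_complex_cm2_s)
                        * UM2_PER_CM2 * self.dt_s)
        if rms > self.r_surface_pair_um / 3.0:
            raise ParameterError(
                f"surface rms step {rms * 1e3:.3g} nm exceeds a third of the "
                f"surface reaction radius {self.r_surface_pair_um * 1e3:.3g} nm; "
                "reduce dt"
            )
        if self.patch_side_um < 2.0 * self.r_surface_pair_um:
            raise ParameterError("patch side must exceed twice the reaction radius")

    @property
    def patch_side_um(self) -> float:
        return math.sqrt(self.patch_area_um2)

    @property
    def r_volume_pair_um(self) -> float:
        """A-target contact distance (sum of hydrodynamic radii), um."""
        return (self.radius_antibody_nm + self.radius_target_nm) * 1e-3

    @property
    def r_surface_pair_um(self) -> float:
        """complex-target contact distance, um."""
        return (self.radius_complex_nm + self.radius_target_nm) * 1e-3


@dataclass
class ParticleWorld:
    """Mutable particle state: surface slot arrays plus volume antibodies."""

    L_um: float
    H_um: float
    ssp: np.ndarray       # int8 species codes per surface slot
    sx: np.ndarray
    sy: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    abound: np.ndarray    # bool: antibody currently inside a complex
    # persistent kernel counters (length-1 int64 arrays)
    _n_ab: np.ndarray = field(default=None)
    _n_sfree: np.ndarray = field(default=None)
    _n_near: np.ndarray = field(default=None)
    _abound_stack: np.ndarray = field(default=None)
    _sfree: np.ndarray = field(default=None)
    _near: np.ndarray = field(default=None)
    step: int = 0

    def __post_init__(self) -> None:
        cap = self.ssp.size
        nA = self.ax.size
        if self._sfree is None:
            free = np.nonzero(self.ssp == K.EMPTY)[0]
            self._sfree = np.zeros(cap, np.int64)
            self._sfree[: free.size] = free
            self._n_sfree = np.array([free.size], np.int64)
            bound = np.nonzero(self.abound)[0]
            self._abound_stack = np.zeros(max(nA, 1), np.int64)
            self._abound_stack[: bound.size] = bound
            self._n_ab = np.array([bound.size], np.int64)
            self._near = np.zeros(max(nA, 1), np.int64)
            self._n_near = np.array([0], np.int64)

    def counts(self) -> dict:
        c = {"A": int(self.ax.size - self._n_ab[0])}
        for code, name in ((K.T1, "T1"), (K.T2, "T2"), (K.AT1, "AT1"),
                           (K.AT2, "AT2"), (K.AT1T2, "AT1T2")):
            c[name] = int(np.count_nonzero(self.ssp == code))
        return c

    def copy(self) -> "ParticleWorld":
        w = ParticleWorld(
            self.L_um, self.H_um, self.ssp.copy(), self.sx.copy(),
            self.sy.copy(), self.ax.copy(), self.ay.copy(), self.az.copy(),
            self.abound.copy(),
        )
        w.step = self.step
        return w


@dataclass(frozen=True)
class ReactionChannel:
    """One elementary reaction with its macroscopic rate and, once
    calibrated, the per-encounter firing probability p."""

    kind: str              # "volume" | "surface" | "dissociation"
    name: str              # e.g. "A+T1->AT1"
    rate: float            # 1/(M s), um^2/(molecule s) or 1/s by kind
    p: float | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ParameterError("channel rate must be >= 0")
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise ParameterError("per-encounter probability must lie in [0, 1]")
        if self.kind == "dissociation" and self.p is not None:
            raise ParameterError("dissociation channels carry no p")


@dataclass
class MCResult:
    """Per-replicate species-count time series with ensemble summary."""

    times: np.ndarray                # s, shape (F,)
    counts: np.ndarray               # int64, shape (R, F, 6) in SPECIES order
    config: MCBoxConfig
    metadata: dict = field(default_factory=dict)

    @property
    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def std(self) -> np.ndarray:
        return self.counts.std(axis=0, ddof=1) if self.counts.shape[0] > 1 \
            else np.zeros_like(self.counts[0], dtype=float)

    def species(self, name: str) -> int:
        return SPECIES.index(name)

    def bound_mean(self) -> np.ndarray:
        return self.mean[:, 3:6].sum(axis=1)


# ---------------------------------------------------------------------------
# World construction and stepping


def build_box(
    cells: CellSurfaceModel,
    A_conc_M: float,
    cfg: MCBoxConfig | None = None,
    seed: int | None = None,
) -> tuple[MCBoxConfig, ParticleWorld]:
    """Seed a cuboid patch for one replicate.

    Targets are placed uniformly at random on the membrane at the derived
    per-patch counts; antibodies uniformly in the volume, whose height is
    set so that n_antibody particles realize ``A_conc_M``.
    """
    if A_conc_M <= 0:
        raise ParameterError("antibody concentration must be > 0")
    cfg = cfg or MCBoxConfig()
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)

    n1 = cuboid_seed_count(cells, "T1", cfg.patch_area_um2)
    n2 = cuboid_seed_count(cells, "T2", cfg.patch_area_um2)
    H = (cuboid_height_for_concentration(cfg.n_antibody, A_conc_M,
                                         cfg.patch_area_um2)
         if cfg.n_antibody > 0 else 1.0)
    if H < 2.0 * cfg.r_volume_pair_um:
        raise ParameterError(
            f"box height {H:.3g} um below twice the reaction radius; "
            "reduce n_antibody or concentration"
        )
    L = cfg.patch_side_um

    cap = n1 + n2
    ssp = np.zeros(max(cap, 1), np.int8)
    ssp[:n1] = K.T1
    ssp[n1:cap] = K.T2
    sx = rng.uniform(0.0, L, max(cap, 1))
    sy = rng.uniform(0.0, L, max(cap, 1))

    nA = cfg.n_antibody
    ax = rng.uniform(0.0, L, nA)
    ay = rng.uniform(0.0, L, nA)
    az = rng.uniform(0.0, H, nA)
    abound = np.zeros(nA, bool)

    world = ParticleWorld(L, H, ssp, sx, sy, ax, ay, az, abound)
    return cfg, world


def _sigmas(cfg: MCBoxConfig) -> tuple:
    dt = cfg.dt_s
    sT = math.sqrt(2.0 * cfg.D_surface_cm2_s * UM2_PER_CM2 * dt)
    sC = math.sqrt(2.0 * cfg.D_complex_cm2_s * UM2_PER_CM2 * dt)
    sA = math.sqrt(2.0 * cfg.D_volume_cm2_s * UM2_PER_CM2 * dt)
    sAf = math.sqrt(2.0 * cfg.D_volume_cm2_s * UM2_PER_CM2 * dt * cfg.far_mult)
    return sT, sT, sC, sA, sAf


def _step(world: ParticleWorld, cfg: MCBoxConfig, n_steps: int,
          probs: tuple, koffs: tuple, seed: int | None,
          counts_out=None, times_out=None, record_every: int = 1 << 62,
          frame0: int = 0) -> int:
    sT1, sT2, sC, sA, sAf = _sigmas(cfg)
    p1, p2, p3, p4 = probs
    km1, km2, km3, km4 = koffs
    dt = cfg.dt_s
    pd1 = -math.expm1(-km1 * dt)
    pd2 = -math.expm1(-km2 * dt)
    pd34 = -math.expm1(-(km3 + km4) * dt)
    br3 = km3 / (km3 + km4) if (km3 + km4) > 0 else 0.0
    if counts_out is None:
        counts_out = np.zeros((0, 6), np.int64)
        times_out = np.zeros(0, np.float64)
    if seed is not None:
        K.seed_rng(seed)
    frame = K.step_world(
        n_steps, world.step,
        world.L_um, world.H_um, dt, cfg.lateral_boundary == "periodic",
        world.ssp, world.sx, world.sy,
        world.ax, world.ay, world.az, world.abound,
        world._abound_stack, world._n_ab,
        world._sfree, world._n_sfree, world._near, world._n_near,
        sT1, sT2, sC, sA, sAf, cfg.far_z_um, cfg.far_mult,
        cfg.r_volume_pair_um, cfg.r_surface_pair_um,
        cfg.placement_offset_nm * 1e-3,
        p1, p2, p3, p4, pd1, pd2, pd34, br3,
        record_every, counts_out, times_out, frame0,
    )
    world.step += n_steps
    return frame


def diffuse_step(world: ParticleWorld, cfg: MCBoxConfig,
                 n_steps: int = 1, seed: int | None = None) -> ParticleWorld:
    """Advance diffusion only (all reaction channels off). In place."""
    _step(world, cfg, n_steps, (0.0, 0.0, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0), seed)
    return world


def react_step(world: ParticleWorld, channels: dict, cfg: MCBoxConfig,
               n_steps: int = 1, seed: int | None = None) -> ParticleWorld:
    """Advance reactions with diffusion frozen (sigma = 0). In place.

    ``channels`` maps "p1","p2","p3","p4" to per-encounter probabilities and
    "k_neg1".."k_neg4" to off-rates (missing keys default to 0).
    """
    frozen = replace(cfg, D_surface_cm2_s=0.0, D_complex_cm2_s=0.0,
                     D_volume_cm2_s=0.0)
    probs = tuple(channels.get(f"p{i}", 0.0) for i in (1, 2, 3, 4))
    koffs = tuple(channels.get(f"k_neg{i}", 0.0) for i in (1, 2, 3, 4))
    _step(world, frozen, n_steps, probs, koffs, seed)
    return world


def advance(world: ParticleWorld, cfg: MCBoxConfig, probs: tuple,
            koffs: tuple, n_steps: int, seed: int | None = None,
            record_every: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Advance one world with full dynamics, recording species counts.

    Returns (times, counts) with counts in SPECIES order, one row every
    ``record_every`` steps.  Mutates the world in place.
    """
    n_frames = n_steps // record_every
    counts_out = np.zeros((n_frames, 6), np.int64)
    times_out = np.zeros(n_frames)
    _step(world, cfg, n_steps, probs, koffs, seed,
          counts_out=counts_out, times_out=times_out,
          record_every=record_every, frame0=0)
    return times_out, counts_out


# ---------------------------------------------------------------------------
# Calibration


_CAL_CACHE: dict = {}


def _cal_key(kind, rate, D_sum, radius, dt, density):
    return (kind, round(rate, 12), round(D_sum, 16), round(radius, 9),
            round(dt, 12), None if density is None else round(density, 3))


def calibrate_channel(
    channel: ReactionChannel,
    cfg: MCBoxConfig,
    density_per_um2: float | None = None,
    seed: int = 20260922,
    rtol: float = 0.05,
) -> float:
    """Per-encounter probability p reproducing the macroscopic rate.

    Volume channels (rate in 1/(M s)): ghost-counted well-mixed run; the
    event rate is linear in p, solved by secant iteration.  Surface
    channels (rate in um^2/(molecule s)): pseudo-first-order tracer-decay
    run at ``density_per_um2`` (required), solved by bisection on p.
    Raises CalibrationError when even p = 1 cannot reach the target.
    Results are cached on (kind, rate, D sum, radius, dt, density).
    """
    if channel.kind == "dissociation":
        raise ParameterError("dissociation channels are sampled exactly; no p")
    if channel.rate == 0:
        return 0.0

    if channel.kind == "volume":
        D_sum = cfg.D_volume_cm2_s + cfg.D_surface_cm2_s
        key = _cal_key("volume", channel.rate, D_sum, cfg.r_volume_pair_um,
                       cfg.dt_s, None)
        if key in _CAL_CACHE:
            return _CAL_CACHE[key]
        p = _calibrate_volume(channel.rate, cfg, seed, rtol)
    elif channel.kind == "surface":
        if density_per_um2 is None or density_per_um2 <= 0:
            raise ParameterError(
                "surface-channel calibration needs the partner density "
                "(molecules/um^2) it will operate at"
            )
        D_sum = cfg.D_complex_cm2_s + cfg.D_surface_cm2_s
        key = _cal_key("surface", channel.rate, D_sum, cfg.r_surface_pair_um,
                       cfg.dt_s, density_per_um2)
        if key in _CAL_CACHE:
            return _CAL_CACHE[key]
        p = _calibrate_surface(channel.rate, cfg, density_per_um2, seed, rtol)
    else:
        raise ParameterError(f"unknown channel kind {channel.kind!r}")

    _CAL_CACHE[key] = p
    return p


def _volume_rate_per_molecule(rate_per_M_s: float) -> float:
    """1/(M s) -> um^3/(molecule s)."""
    return rate_per_M_s / N_A * 1e15


def _measure_volume_rate(p: float, cfg: MCBoxConfig, seed: int,
                         n_steps: int = 4000, n_targets: int = 800,
                         conc_M: float = 3e-5) -> float:
    """Ghost-counted association rate (um^3/(molecule s)) at trial p."""
    L = 1.0
    h = 0.3
    rng = np.random.default_rng(seed)
    tx = rng.uniform(0, L, n_targets)
    ty = rng.uniform(0, L, n_targets)
    nA = int(round(conc_M * N_A / 1e15 * L * L * h))
    ax = rng.uniform(0, L, nA)
    ay = rng.uniform(0, L, nA)
    az = rng.uniform(0, h, nA)
    sA = math.sqrt(2.0 * cfg.D_volume_cm2_s * UM2_PER_CM2 * cfg.dt_s)
    events = K.cal_volume_events(seed % (2**31), n_steps, L, h, cfg.dt_s,
                                 tx, ty, ax, ay, az, sA,
                                 cfg.r_volume_pair_um, p)
    c_num = nA / (L * L * h)  # molecules/um^3
    return events / (n_steps * cfg.dt_s * n_targets * c_num)


def _calibrate_volume(rate: float, cfg: MCBoxConfig, seed: int,
                      rtol: float) -> float:
    target = _volume_rate_per_molecule(rate)
    # analytic seed: rate = p * <n within radius of a membrane target>/dt,
    # with the half-sphere volume 2/3 pi r^3 at the reflecting membrane
    half_sphere = 2.0 / 3.0 * math.pi * cfg.r_volume_pair_um ** 3
    p = min(1.0, target * cfg.dt_s / half_sphere)
    for it in range(6):
        measured = _measure_volume_rate(p, cfg, seed + it)
        if measured <= 0:
            p = min(1.0, p * 4.0)
            continue
        scale = target / measured
        if abs(scale - 1.0) <= rtol:
            return p
        p_new = p * scale
        if p_new > 1.0:
            if measured < target * (1.0 - rtol) and p >= 1.0:
                raise CalibrationError(
                    f"volume rate {rate:.3g} 1/(M s) unreachable at p=1; "
                    "reduce dt or enlarge the reaction radius"
                )
            p_new = 1.0
        p = p_new
    return p


def _measure_surface_rate(p: float, cfg: MCBoxConfig, density: float,
                          k_target: float, seed: int,
                          n_tracers: int = 1200) -> float:
    """Tracer-decay 2D rate (um^2/(molecule s)) at trial p, measured over
    one mean lifetime at the target rate and the operating density."""
    L = 1.0
    nB = max(int(round(density * L * L)), 1)
    t_window = 1.0 / (k_target * density)
    n_steps = max(int(round(t_window / cfg.dt_s)), 10)
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0, L, nB)
    by = rng.uniform(0, L, nB)
    tx = rng.uniform(0, L, n_tracers)
    ty = rng.uniform(0, L, n_tracers)
    sig_b = math.sqrt(2.0 * cfg.D_surface_cm2_s * UM2_PER_CM2 * cfg.dt_s)
    sig_t = math.sqrt(2.0 * cfg.D_complex_cm2_s * UM2_PER_CM2 * cfg.dt_s)
    events, alive_steps = K.cal_surface_decay(
        seed % (2**31), n_steps, L, cfg.dt_s, bx, by, tx, ty,
        sig_b, sig_t, cfg.r_surface_pair_um, p)
    rho = nB / (L * L)
    if alive_steps == 0:
        return math.inf
    return events / (alive_steps * cfg.dt_s * rho)


def _calibrate_surface(rate: float, cfg: MCBoxConfig, density: float,
                       seed: int, rtol: float) -> float:
    at_one = _measure_surface_rate(1.0, cfg, density, rate, seed)
    if at_one < rate * (1.0 - rtol):
        raise CalibrationError(
            f"surface rate {rate:.3g} um^2/(molecule s) exceeds the "
            f"diffusion-limited ceiling {at_one:.3g} at density "
            f"{density:.3g}/um^2; reduce dt or enlarge the reaction radius"
        )
    if at_one <= rate * (1.0 + rtol):
        return 1.0
    lo, hi = 0.0, 1.0
    p = rate / at_one
    for it in range(20):
        measured = _measure_surface_rate(p, cfg, density, rate, seed + 1 + it)
        if abs(measured - rate) <= rtol * rate:
            return p
        if measured < rate:
            lo = p
        else:
            hi = p
        p = 0.5 * (lo + hi)
    return p


# ---------------------------------------------------------------------------
# Production runs


def make_channels(k: KineticConstants,
                  surface_rate_um2_per_molecule_s: float = 0.7) -> list[ReactionChannel]:
    """The four association channels and four dissociation channels of the
    binding scheme.  The surface chemical rate defaults to the CD2-CD58
    derived 0.7 um^2/(molecule s)."""
    s = surface_rate_um2_per_molecule_s
    return [
        ReactionChannel("volume", "A+T1->AT1", k.k1),
        ReactionChannel("volume", "A+T2->AT2", k.k2),
        ReactionChannel("surface", "AT1+T2->AT1T2", s),
        ReactionChannel("surface", "AT2+T1->AT1T2", s),
        ReactionChannel("dissociation", "AT1->A+T1", k.k_neg1),
        ReactionChannel("dissociation", "AT2->A+T2", k.k_neg2),
        ReactionChannel("dissociation", "AT1T2->AT1+T2", k.k_neg3),
        ReactionChannel("dissociation", "AT1T2->AT2+T1", k.k_neg4),
    ]


def _surface_p(channel: ReactionChannel, cfg: MCBoxConfig,
               density: float) -> float:
    try:
        return calibrate_channel(channel, cfg, density_per_um2=density)
    except CalibrationError as err:
        logger.warning(
            "surface channel %s: %s -- reacting on contact (p=1, "
            "diffusion-controlled)", channel.name, err)
        return 1.0


def run(
    cells: CellSurfaceModel,
    variant: KineticConstants,
    A_conc_M: float,
    t_end_s: float,
    cfg: MCBoxConfig | None = None,
    surface_rate_um2_per_molecule_s: float = 0.7,
) -> MCResult:
    """Simulate n_replicates independent boxes to t_end.

    Replicates are individually reproducible from (rng_seed, replicate):
    both the initial placement and the dynamics derive their seeds from
    them.  Emits a warning if the free-antibody pool depletes by more
    than 10%.
    """
    cfg = cfg or MCBoxConfig()
    if t_end_s <= 0:
        raise ParameterError("t_end must be > 0")
    n_steps = int(round(t_end_s / cfg.dt_s))
    record_every = max(int(round(cfg.record_every_s / cfg.dt_s)), 1)
    n_frames = n_steps // record_every

    dens1 = cells.n_T1_per_cell / cells.surface_area_um2
    dens2 = cells.n_T2_per_cell / cells.surface_area_um2
    channels = make_channels(variant, surface_rate_um2_per_molecule_s)
    p1 = calibrate_channel(channels[0], cfg) if dens1 > 0 and cfg.n_antibody else 0.0
    p2 = calibrate_channel(channels[1], cfg) if dens2 > 0 and cfg.n_antibody else 0.0
    p3 = _surface_p(channels[2], cfg, dens2) if dens1 > 0 and dens2 > 0 else 0.0
    p4 = _surface_p(channels[3], cfg, dens1) if dens1 > 0 and dens2 > 0 else 0.0
    probs = (p1, p2, p3, p4)
    koffs = (variant.k_neg1, variant.k_neg2, variant.k_neg3, variant.k_neg4)

    ss = np.random.SeedSequence(cfg.rng_seed)
    seeds = ss.generate_state(2 * cfg.n_replicates) & 0x7FFFFFFF

    all_counts = np.zeros((cfg.n_replicates, n_frames, 6), np.int64)
    times = np.zeros(n_frames)
    for r in range(cfg.n_replicates):
        _, world = build_box(cells, A_conc_M, cfg, seed=int(seeds[2 * r]))
        counts_out = np.zeros((n_frames, 6), np.int64)
        times_out = np.zeros(n_frames)
        _step(world, cfg, n_steps, probs, koffs, int(seeds[2 * r + 1]),
              counts_out=counts_out, times_out=times_out,
              record_every=record_every, frame0=0)
        all_counts[r] = counts_out
        times = times_out
        if cfg.n_antibody and counts_out[:, 0].min() < 0.9 * cfg.n_antibody:
            logger.warning(
                "replicate %d: free antibody depleted below 90%% "
                "(min %d of %d)", r, counts_out[:, 0].min(), cfg.n_antibody)

    return MCResult(
        times=times, counts=all_counts, config=cfg,
        metadata={"variant": variant.variant_name, "cell_type": cells.cell_type,
                  "A_conc_M": A_conc_M, "t_end_s": t_end_s,
                  "p": probs, "seeds": seeds.tolist(),
                  "surface_rate_um2": surface_rate_um2_per_molecule_s},
    )


def mc_binding_curve(
    cells: CellSurfaceModel,
    variant: KineticConstants,
    conc_grid,
    t_end_s: float,
    cfg: MCBoxConfig | None = None,
    assay: AssayConfig | None = None,
    apply_wash: bool = False,
) -> CurveResult:
    """Ensemble-mean bound species vs concentration, scaled patch -> cell.

    Counts are multiplied by (cell area / patch area) to give molecules per
    cell; the optional wash correction reuses the ODE model's first-order
    monovalent decay.
    """
    cfg = cfg or MCBoxConfig()
    assay = assay or AssayConfig()
    conc = np.asarray(conc_grid, dtype=float)
    if conc.size == 0:
        raise ParameterError("concentration grid is empty")
    scale = cells.surface_area_um2 / cfg.patch_area_um2

    out = np.zeros((3, conc.size))
    for i, A in enumerate(conc):
        res = run(cells, variant, A, t_end_s, cfg)
        final = res.mean[-1]  # species order: A,T1,T2,AT1,AT2,AT1T2
        b1, b2, b3 = final[3] * scale, final[4] * scale, final[5] * scale
        if apply_wash:
            b1 *= math.exp(-variant.k_neg1 * assay.wash_time_s)
            b2 *= math.exp(-variant.k_neg2 * assay.wash_time_s)
        out[:, i] = (b1, b2, b3)

    return CurveResult(
        x=conc, x_kind="concentration_M",
        bound_AT1=out[0], bound_AT2=out[1], bound_AT1T2=out[2],
        mfi_conversion=assay.mfi_conversion,
        metadata={"variant": variant.variant_name, "cell_type": cells.cell_type,
                  "engine": "mc", "t_end_s": t_end_s,
                  "apply_wash": apply_wash},
    )
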