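"""Overdamped Brownian-dynamics testbed for the binding protocols.

Mobile ligand beads diffuse in an orthorhombic cell above a static
receptor.  The physics is deliberately minimal: an overdamped Langevin
update (no inertia), a Gaussian attractive well at the binding-site
reference atom standing in for the all-atom binding pocket, a
reflective wall at the membrane surface z = 0 (and at the top of the
water slab), periodic wrapping in x and y, and an optional bias
controller from :mod:`bindsteer.biasing`.  The time unit is the
nominal ps of the diffusion coefficient — it is a toy clock for
comparing protocols, not an all-atom time scale.

Determinism: a single seeded generator drives each run; noise is drawn
in a fixed order (per step, then per particle, then per axis), so a
given config + seed reproduces the trajectory bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .biasing import (
    BiasReason,
    FlatBottomConfig,
    SteeringConfig,
    flat_bottom_forces,
    steering_forces,
)
from .geometry import PeriodicBox
from .model_io import AtomSelector, Structure, Trajectory, select_atom

logger = logging.getLogger(__name__)

__all__ = [
    "KB",
    "EngineError",
    "PackingError",
    "PotentialField",
    "EngineConfig",
    "SimulationResult",
    "step_update",
    "place_ligands_uniform",
    "run_simulation",
    "first_binding_time",
]

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹.
KB = 0.0019872


class EngineError(RuntimeError):
    pass


class PackingError(EngineError):
    pass


@dataclasses.dataclass(frozen=True)
class PotentialField:
    """Static receptor potential acting on each ligand bead.

    A Gaussian well U(r) = -well_depth · exp(-|r - r0|²/(2·well_sigma²))
    centred on the binding-site reference atom, with analytic gradient.
    Optional soft-sphere ligand–ligand repulsion (harmonic overlap
    penalty below ``repulsion_radius``); ligands are ideal (independent)
    by default.
    """

    well_depth: float = 5.0
    well_sigma: float = 2.0
    repulsion_radius: float | None = None
    repulsion_k: float = 1.0

    def __post_init__(self) -> None:
        if self.well_depth < 0 or not self.well_sigma > 0:
            raise ValueError("well depth must be >= 0 and width > 0")

    def well_forces(self, positions: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Force -∇U on (n, 3) positions, pointing toward the well centre."""
        delta = center - positions
        r2 = np.einsum("ij,ij->i", delta, delta)
        s2 = self.well_sigma**2
        mag = (self.well_depth / s2) * np.exp(-r2 / (2.0 * s2))
        return mag[:, None] * delta


@dataclasses.dataclass(frozen=True)
class EngineConfig:
    """Run configuration.

    dt in ps, temperature in K, diffusion coefficient in Ų/ps.  The
    default cell is the membrane-system geometry: 120 × 120 × 100 Å,
    periodic in x and y, bounded in z with reflective walls at z = 0
    (membrane surface) and z = Lz.  ``n_ligands`` is 1 for protocol
    runs and 76 for the high-concentration mode.
    """

    n_steps: int
    dt: float = 0.01
    temperature: float = 300.0
    diffusion: float = 0.6
    record_stride: int = 100
    seed: int = 0
    box: PeriodicBox = dataclasses.field(default_factory=PeriodicBox)
    n_ligands: int = 1
    potential: PotentialField = dataclasses.field(default_factory=PotentialField)
    reference: AtomSelector | str = "ARG:397:CZ"
    reference_position: tuple[float, float, float] | None = None
    initial_positions: tuple | None = None
    initial_distance: float | None = None
    min_separation: float = 6.0
    record_unwrapped: bool = False
    ligand_prefix: str = "LIG"

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if not (self.dt > 0 and self.diffusion > 0 and self.temperature > 0):
            raise ValueError("dt, diffusion and temperature must be positive")
        if self.n_ligands < 1:
            raise ValueError("need at least one ligand")
        if self.record_stride < 1:
            raise ValueError("record stride must be >= 1")

    @property
    def kBT(self) -> float:
        """Thermal energy in kcal/mol (kB = 0.0019872 kcal/mol/K)."""
        return KB * self.temperature

    @classmethod
    def from_dict(cls, d: dict) -> "EngineConfig":
        d = dict(d)
        if "box" in d and isinstance(d["box"], dict):
            b = d["box"]
            d["box"] = PeriodicBox(tuple(b.get("lengths", (120.0, 120.0, 100.0))),
                                   tuple(b.get("periodic", (True, True, False))))
        if "potential" in d and isinstance(d["potential"], dict):
            d["potential"] = PotentialField(**d["potential"])
        return cls(**d)


def step_update(positions: np.ndarray, forces: np.ndarray, cfg: EngineConfig,
                noise: np.ndarray) -> np.ndarray:
    """One overdamped Langevin step.

    x' = x + (D/kBT)·F·dt + sqrt(2·D·dt)·ξ per coordinate, with ξ the
    supplied standard-normal draws, followed by wall reflection on
    non-periodic axes (z mirrored at 0 and at Lz) and periodic wrapping
    in x, y.  Forces in kcal·mol⁻¹·Å⁻¹.  A deterministic drift larger
    than the well width per step logs a warning (dt too large).
    """
    pos = np.asarray(positions, dtype=float)
    F = np.asarray(forces, dtype=float)
    drift = (cfg.diffusion / cfg.kBT) * F * cfg.dt
    max_drift = float(np.max(np.abs(drift))) if drift.size else 0.0
    if max_drift > cfg.potential.well_sigma:
        logger.warning("per-step drift %.3g Å exceeds the well width %.3g Å: dt too large",
                       max_drift, cfg.potential.well_sigma)
    new = pos + drift + np.sqrt(2.0 * cfg.diffusion * cfg.dt) * np.asarray(noise, dtype=float)
    return _apply_boundaries(new, cfg.box)


def _apply_boundaries(pos: np.ndarray, box: PeriodicBox) -> np.ndarray:
    pos = np.array(pos, dtype=float, copy=True)
    L = box.lengths_array
    for ax in range(3):
        if box.periodic[ax]:
            pos[..., ax] = (pos[..., ax] + L[ax] / 2.0) % L[ax] - L[ax] / 2.0
        else:
            # reflective walls at 0 and L (displacements are << L per step)
            comp = np.abs(pos[..., ax])
            comp = np.where(comp > L[ax], 2.0 * L[ax] - comp, comp)
            pos[..., ax] = comp
    return pos


def place_ligands_uniform(n: int, box: PeriodicBox, min_separation: float = 6.0,
                          seed: int | np.random.Generator = 0, z_min: float = 0.0,
                          max_attempts_per_ligand: int = 200) -> np.ndarray:
    """Evenly distribute n ligand positions in the extracellular slab z > z_min.

    Uniform rejection sampling with a pairwise minimum separation;
    reproducible from the seed.  Raises PackingError if the slab cannot
    accommodate the request.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = box.lengths_array
    if z_min >= L[2]:
        raise PackingError("slab has zero height")
    placed = np.empty((n, 3))
    count = 0
    attempts = 0
    budget = max_attempts_per_ligand * n
    while count < n:
        if attempts >= budget:
            raise PackingError(
                f"could not place {n} ligands at separation {min_separation} Å after "
                f"{budget} attempts; reduce the separation or the count"
            )
        attempts += 1
        cand = np.array([
            rng.uniform(-L[0] / 2.0, L[0] / 2.0),
            rng.uniform(-L[1] / 2.0, L[1] / 2.0),
            rng.uniform(z_min, L[2]),
        ])
        if count and np.any(np.linalg.norm(box.minimum_image(placed[:count] - cand), axis=1) < min_separation):
            continue
        placed[count] = cand
        count += 1
    return placed


@dataclasses.dataclass
class SimulationResult:
    """Trajectory plus per-frame bias bookkeeping and summary statistics."""

    trajectory: Trajectory
    reasons: np.ndarray              # (n_frames, n_ligands) int8 BiasReason codes
    distances: np.ndarray            # (n_frames, n_ligands) ligand(CA)–reference distance, Å
    reference_position: np.ndarray
    config: EngineConfig
    bias_config: SteeringConfig | FlatBottomConfig | None
    events: list[dict]               # force on/off switches with step numbers
    unwrapped: np.ndarray | None = None

    @property
    def bias_fraction(self) -> float:
        """Fraction of recorded frames in which any ligand has an active bias force."""
        return float(np.mean(np.any(self.trajectory.flags, axis=1)))

    def bias_fraction_per_ligand(self) -> np.ndarray:
        return self.trajectory.flags.mean(axis=0)

    def first_binding_times(self, threshold: float = 7.0, dwell: int = 10) -> np.ndarray:
        return first_binding_time(self, threshold=threshold, dwell=dwell)


def _resolve_reference(structure: Structure | None, cfg: EngineConfig) -> np.ndarray:
    if cfg.reference_position is not None:
        return np.asarray(cfg.reference_position, dtype=float)
    if structure is None:
        raise EngineError("no structure supplied and no explicit reference position set")
    sel = cfg.reference if isinstance(cfg.reference, AtomSelector) else AtomSelector.parse(cfg.reference)
    return select_atom(structure, sel, mode="unique").position


def _initial_positions(cfg: EngineConfig, ref: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if cfg.initial_positions is not None:
        pos = np.array(cfg.initial_positions, dtype=float).reshape(cfg.n_ligands, 3)
        return pos
    if cfg.initial_distance is not None:
        start = ref + np.array([0.0, 0.0, float(cfg.initial_distance)])
        if start[2] <= 0 or start[2] >= cfg.box.lengths[2]:
            raise EngineError(
                f"initial distance {cfg.initial_distance} Å places the ligand at z={start[2]:.1f}, outside the box"
            )
        return np.tile(start, (cfg.n_ligands, 1))
    return place_ligands_uniform(cfg.n_ligands, cfg.box, cfg.min_separation, rng)


def _repulsion_forces(pos: np.ndarray, field: PotentialField, box: PeriodicBox) -> np.ndarray:
    """Pairwise harmonic overlap repulsion (O(n²); n is at most ~100 here)."""
    r0 = field.repulsion_radius
    n = pos.shape[0]
    F = np.zeros_like(pos)
    if r0 is None or n < 2:
        return F
    delta = box.minimum_image(pos[:, None, :] - pos[None, :, :])
    d = np.linalg.norm(delta, axis=2)
    np.fill_diagonal(d, np.inf)
    overlap = np.clip(r0 - d, 0.0, None)
    mag = field.repulsion_k * overlap / np.where(d > 0, d, 1.0)
    F += np.sum(mag[:, :, None] * delta, axis=1)
    return F


def run_simulation(structure: Structure | None, cfg: EngineConfig,
                   bias: SteeringConfig | FlatBottomConfig | None = None) -> SimulationResult:
    """Run the Brownian-dynamics testbed.

    Per step, in the order of the steering flowchart: evaluate the
    region/cut-off conditions for every ligand, apply the bias force or
    not, add the binding-well force, then propagate.  Frames are
    recorded every ``record_stride`` steps (the initial state is frame
    zero), with the bias decision made at the recorded positions, so
    the zero-bias-inside-cutoff guarantee can be asserted frame by
    frame from the output alone.
    """
    ref = _resolve_reference(structure, cfg)
    rng = np.random.default_rng(cfg.seed)
    pos = _apply_boundaries(_initial_positions(cfg, ref, rng), cfg.box)
    n = cfg.n_ligands

    n_rec = cfg.n_steps // cfg.record_stride + 1
    rec_times = np.empty(n_rec)
    rec_coords = np.empty((n_rec, n, 3))
    rec_flags = np.zeros((n_rec, n), dtype=bool)
    rec_reasons = np.full((n_rec, n), int(BiasReason.NONE), dtype=np.int8)
    rec_dist = np.empty((n_rec, n))
    rec_unwrapped = np.empty((n_rec, n, 3)) if cfg.record_unwrapped else None
    unwrapped = pos.copy()

    sqrt_noise = np.sqrt(2.0 * cfg.diffusion * cfg.dt)
    mobility_dt = (cfg.diffusion / cfg.kBT) * cfg.dt
    drift_warned = False
    events: list[dict] = []
    prev_active = np.zeros(n, dtype=bool)
    rec_i = 0

    def bias_eval(p: np.ndarray):
        if bias is None:
            return (np.zeros_like(p), np.zeros(n, dtype=bool),
                    np.full(n, int(BiasReason.NONE), dtype=np.int8))
        if isinstance(bias, SteeringConfig):
            return steering_forces(p, ref, bias)
        if isinstance(bias, FlatBottomConfig):
            return flat_bottom_forces(p, ref, bias)
        raise EngineError(f"unsupported bias config {type(bias).__name__}")

    for step in range(cfg.n_steps + 1):
        bias_F, active, reasons = bias_eval(pos)
        if isinstance(bias, SteeringConfig) and bias.update_period == 2 and step % 2 == 1:
            # off-cycle step: force withheld, direction will be recomputed next cycle
            bias_F = np.zeros_like(bias_F)
            active = np.zeros(n, dtype=bool)

        if np.any(active != prev_active):
            for idx in np.flatnonzero(active != prev_active):
                events.append({
                    "step": step,
                    "ligand": f"{cfg.ligand_prefix}{idx + 1}:CA",
                    "event": "force_on" if active[idx] else "force_off",
                    "reason": BiasReason(int(reasons[idx])).name.lower(),
                })
            prev_active = active.copy()

        if step % cfg.record_stride == 0:
            rec_times[rec_i] = step * cfg.dt
            rec_coords[rec_i] = pos
            rec_flags[rec_i] = active
            rec_reasons[rec_i] = reasons
            rec_dist[rec_i] = np.linalg.norm(ref - pos, axis=1)
            if rec_unwrapped is not None:
                rec_unwrapped[rec_i] = unwrapped
            rec_i += 1
        if step == cfg.n_steps:
            break

        F = bias_F + cfg.potential.well_forces(pos, ref)
        if cfg.potential.repulsion_radius is not None:
            F += _repulsion_forces(pos, cfg.potential, cfg.box)
        if not drift_warned:
            md = float(np.max(np.abs(F))) * mobility_dt
            if md > cfg.potential.well_sigma:
                logger.warning("per-step drift %.3g Å exceeds the well width: dt too large", md)
                drift_warned = True
        noise = rng.standard_normal((n, 3))
        disp = mobility_dt * F + sqrt_noise * noise
        unwrapped = unwrapped + disp
        pos = _apply_boundaries(pos + disp, cfg.box)
        if not np.all(np.isfinite(pos)):
            raise EngineError(f"non-finite position at step {step + 1}")

    # times must be strictly increasing; with n_steps == 0 there is one frame at t=0
    labels = [f"{cfg.ligand_prefix}{i + 1}:CA" for i in range(n)]
    traj = Trajectory(rec_times[:rec_i], rec_coords[:rec_i], labels, rec_flags[:rec_i], box=cfg.box)
    return SimulationResult(
        trajectory=traj,
        reasons=rec_reasons[:rec_i],
        distances=rec_dist[:rec_i],
        reference_position=ref,
        config=cfg,
        bias_config=bias,
        events=events,
        unwrapped=rec_unwrapped[:rec_i] if rec_unwrapped is not None else None,
    )


def first_binding_time(result, threshold: float = 7.0, dwell: int = 10) -> np.ndarray:
    """Earliest recorded time at which the binding distance stays below
    ``threshold`` for at least ``dwell`` consecutive recorded frames,
    per ligand; NaN where binding never happens.

    Accepts a SimulationResult or a (n_frames, n_ligands) distance
    array paired with times via the result object.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    dist = result.distances
    times = result.trajectory.times
    n_frames, n = dist.shape
    out = np.full(n, np.nan)
    below = dist < threshold
    for j in range(n):
        run = 0
        for i in range(n_frames):
            run = run + 1 if below[i, j] else 0
            if run >= dwell:
                out[j] = times[i - dwell + 1]
                break
    return out
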