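"""Bias protocols for accelerating spontaneous ligand binding.

Two controllers are implemented as pure decision functions:

* a region- and distance-gated constant-force steering protocol — a
  constant-magnitude force pushes the ligand toward a reference atom,
  but only while the ligand is inside an extracellular cone region and
  farther than a cut-off distance from the reference; within the
  cut-off the dynamics are completely unbiased, so the binding event
  itself is spontaneous;
* a flat-bottom harmonic restraint — zero potential within a cut-off
  distance of the reference and harmonic beyond it, which contains the
  ligand near the binding site without doing work on it while it is
  close.

Distances here are computed in the unwrapped extracellular frame (no
minimum-image wrapping): a steering force across the periodic boundary
would be meaningless, so the protocols are only defined on the
extracellular side of the cell.
"""

from __future__ import annotations

import dataclasses
import enum
import logging

import numpy as np

from .model_io import AtomSelector

logger = logging.getLogger(__name__)

__all__ = [
    "BiasReason",
    "BiasDecision",
    "ConeRegion",
    "SteeringConfig",
    "FlatBottomConfig",
    "cone_contains",
    "steering_decision",
    "steering_forces",
    "flat_bottom",
    "flat_bottom_decision",
    "flat_bottom_forces",
    "bias_from_dict",
]


class BiasReason(enum.IntEnum):
    """Why a bias decision came out the way it did."""

    OUTSIDE_REGION = 0
    WITHIN_CUTOFF = 1
    BEYOND_CUTOFF_IN_REGION = 2
    INSIDE_FLAT_REGION = 3
    IN_HARMONIC_REGION = 4
    DEGENERATE_ZERO = 5
    NONE = 6


@dataclasses.dataclass(frozen=True)
class BiasDecision:
    """Outcome of one controller evaluation for one ligand.

    ``active`` False implies the force vector is exactly zero.
    """

    active: bool
    force: np.ndarray
    reason: BiasReason

    def __post_init__(self) -> None:
        f = np.asarray(self.force, dtype=float)
        if f.shape != (3,):
            raise ValueError("force must be a 3-vector")
        if not self.active and np.any(f != 0.0):
            raise ValueError("inactive decision must carry an exactly zero force")
        object.__setattr__(self, "force", f)


@dataclasses.dataclass(frozen=True)
class ConeRegion:
    """Extracellular selection region: z > 0 and x² + y² < (z + a)^p.

    The printed membership rule compares Å² to Å when p = 1; the
    dimensionally consistent reading — a cone of 45° half-opening with
    its apex at z = -a on the pore axis, matching the drawn region — is
    p = 2, the default.  Both the apex offset and the exponent are
    exposed.
    """

    apex_offset: float = 15.0
    exponent: float = 2.0

    def __post_init__(self) -> None:
        if not self.apex_offset > 0:
            raise ValueError("apex offset must be positive")

    def contains(self, p) -> bool | np.ndarray:
        p = np.asarray(p, dtype=float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        radial2 = x * x + y * y
        zpos = z > 0.0
        if self.exponent == 2.0:
            za = z + self.apex_offset  # positive wherever zpos holds
            out = zpos & (radial2 < za * za)
        else:
            bound = np.where(zpos, np.power(np.clip(z + self.apex_offset, 0.0, None), self.exponent), 0.0)
            out = zpos & (radial2 < bound)
        return bool(out) if out.ndim == 0 else out


def cone_contains(p, region: ConeRegion) -> bool | np.ndarray:
    """Membership test for the force-application region (vectorised over leading axes)."""
    return region.contains(p)


@dataclasses.dataclass(frozen=True)
class SteeringConfig:
    """Constant-force steering protocol parameters.

    f0 : force magnitude in kcal·mol⁻¹·Å⁻¹ (default 5).  The protocol
        applies a constant-*magnitude* push toward the reference; the
        force direction is recomputed from the instantaneous
        ligand→reference vector on every evaluation.
    cutoff : switching distance in Å (default 7, 10 is a common
        alternative); at or below it the force is off.
    update_period : apply the force on every step (1) or every second
        step (2).
    """

    f0: float = 5.0
    cutoff: float = 7.0
    reference: AtomSelector = dataclasses.field(default_factory=lambda: AtomSelector.parse("ARG:397:CZ"))
    target_label: str = "CA"
    update_period: int = 1
    region: ConeRegion = dataclasses.field(default_factory=ConeRegion)

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise ValueError("force magnitude must be positive")
        if not self.cutoff > 0:
            raise ValueError("cut-off distance must be positive")
        if self.update_period not in (1, 2):
            raise ValueError("update period must be 1 or 2")


@dataclasses.dataclass(frozen=True)
class FlatBottomConfig:
    """Flat-bottom restraint: U = 0 for d ≤ cutoff, ½·k·(d−cutoff)² beyond.

    k in kcal·mol⁻¹·Å⁻² (default 0.1); cutoff in Å, typically 7, 10 or
    12 (default 12).  ``linear`` switches the outer branch to a
    constant-force wall of magnitude k instead of a harmonic.
    """

    k: float = 0.1
    cutoff: float = 12.0
    reference: AtomSelector = dataclasses.field(default_factory=lambda: AtomSelector.parse("ARG:397:CZ"))
    target_label: str = "CA"
    linear: bool = False

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("stiffness must be positive")
        if not self.cutoff > 0:
            raise ValueError("cut-off distance must be positive")


_ZERO = np.zeros(3)


def steering_decision(ligand_pos, ref_pos, cfg: SteeringConfig) -> BiasDecision:
    """One evaluation of the steering flow control for a single ligand.

    Order of decisions: outside the cone region -> inactive; within the
    cut-off distance of the reference -> inactive (binding proceeds
    unbiased); otherwise a force of magnitude f0 along the unit vector
    from ligand to reference.  A coincident ligand/reference pair is
    reported as a degenerate zero, never an exception.
    """
    lig = np.asarray(ligand_pos, dtype=float)
    ref = np.asarray(ref_pos, dtype=float)
    if not cone_contains(lig, cfg.region):
        return BiasDecision(False, _ZERO, BiasReason.OUTSIDE_REGION)
    delta = ref - lig
    d = float(np.linalg.norm(delta))
    if d == 0.0:
        logger.warning("ligand coincides with reference atom; steering force suppressed")
        return BiasDecision(False, _ZERO, BiasReason.DEGENERATE_ZERO)
    if d <= cfg.cutoff:
        return BiasDecision(False, _ZERO, BiasReason.WITHIN_CUTOFF)
    return BiasDecision(True, cfg.f0 * delta / d, BiasReason.BEYOND_CUTOFF_IN_REGION)


def steering_forces(positions: np.ndarray, ref_pos: np.ndarray, cfg: SteeringConfig):
    """Vectorised steering over (n, 3) ligand positions.

    Returns (forces (n,3), active (n,), reasons (n,) of BiasReason ints);
    agrees element-wise with :func:`steering_decision`.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    ref = np.asarray(ref_pos, dtype=float)
    delta = ref - pos
    d = np.sqrt(np.einsum("ij,ij->i", delta, delta))
    in_region = np.asarray(cone_contains(pos, cfg.region))
    reasons = np.full(pos.shape[0], int(BiasReason.OUTSIDE_REGION), dtype=np.int8)
    reasons[in_region & (d <= cfg.cutoff)] = int(BiasReason.WITHIN_CUTOFF)
    reasons[in_region & (d == 0.0)] = int(BiasReason.DEGENERATE_ZERO)
    active = in_region & (d > cfg.cutoff)
    reasons[active] = int(BiasReason.BEYOND_CUTOFF_IN_REGION)
    forces = np.zeros_like(pos)
    if np.any(active):
        forces[active] = cfg.f0 * delta[active] / d[active, None]
    return forces, active, reasons


def flat_bottom(d, cfg: FlatBottomConfig):
    """Energy (kcal/mol) and restoring-force magnitude (kcal/mol/Å) at distance d.

    Zero inside the cut-off; harmonic (or linear, if configured) beyond
    it.  Continuous and once-differentiable at the cut-off.  Accepts
    scalars or arrays; negative distances are rejected.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance must be non-negative")
    x = np.clip(d_arr - cfg.cutoff, 0.0, None)
    if cfg.linear:
        energy = cfg.k * x
        fmag = np.where(x > 0, cfg.k, 0.0)
    else:
        energy = 0.5 * cfg.k * x * x
        fmag = cfg.k * x
    if d_arr.ndim == 0:
        return float(energy), float(fmag)
    return energy, fmag


def flat_bottom_decision(ligand_pos, ref_pos, cfg: FlatBottomConfig) -> BiasDecision:
    """Restraint force on one ligand, directed toward the reference."""
    lig = np.asarray(ligand_pos, dtype=float)
    ref = np.asarray(ref_pos, dtype=float)
    delta = ref - lig
    d = float(np.linalg.norm(delta))
    if d <= cfg.cutoff:
        return BiasDecision(False, _ZERO, BiasReason.INSIDE_FLAT_REGION)
    _, fmag = flat_bottom(d, cfg)
    return BiasDecision(True, fmag * delta / d, BiasReason.IN_HARMONIC_REGION)


def flat_bottom_forces(positions: np.ndarray, ref_pos: np.ndarray, cfg: FlatBottomConfig):
    """Vectorised flat-bottom restraint over (n, 3) positions."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    ref = np.asarray(ref_pos, dtype=float)
    delta = ref - pos
    d = np.linalg.norm(delta, axis=1)
    _, fmag = flat_bottom(np.atleast_1d(d), cfg)
    active = d > cfg.cutoff
    reasons = np.full(pos.shape[0], int(BiasReason.INSIDE_FLAT_REGION), dtype=np.int8)
    reasons[active] = int(BiasReason.IN_HARMONIC_REGION)
    forces = np.zeros_like(pos)
    if np.any(active):
        forces[active] = (fmag[active] / d[active])[:, None] * delta[active]
    return forces, active, reasons


def bias_from_dict(cfg: dict | None):
    """Build a bias config from structured-text keys.

    Recognised keys: ``kind`` in {none, steer, flatbottom}, ``f0``,
    ``k``, ``cutoff``, ``update_period``, ``cone_apex_offset``,
    ``reference`` (selector string like "ARG:397:CZ"), ``target_label``,
    ``linear``.  Returns None, a SteeringConfig, or a FlatBottomConfig.
    """
    if not cfg:
        return None
    kind = str(cfg.get("kind", "none")).lower()
    if kind in ("none", ""):
        return None
    ref = cfg.get("reference", "ARG:397:CZ")
    ref_sel = AtomSelector.parse(ref) if isinstance(ref, str) else ref
    target = cfg.get("target_label", "CA")
    if kind == "steer":
        region = ConeRegion(apex_offset=float(cfg.get("cone_apex_offset", 15.0)))
        return SteeringConfig(
            f0=float(cfg.get("f0", 5.0)),
            cutoff=float(cfg.get("cutoff", 7.0)),
            reference=ref_sel,
            target_label=target,
            update_period=int(cfg.get("update_period", 1)),
            region=region,
        )
    if kind == "flatbottom":
        return FlatBottomConfig(
            k=float(cfg.get("k", 0.1)),
            cutoff=float(cfg.get("cutoff", 12.0)),
            reference=ref_sel,
            target_label=target,
            linear=bool(cfg.get("linear", False)),
        )
    raise ValueError(f"unknown bias kind {kind!r}: expected none, steer or flatbottom")
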