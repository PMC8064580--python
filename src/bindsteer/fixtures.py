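"""Synthetic test systems.

Builds a self-contained stand-in for the transporter binding-site
neighbourhood: a handful of named anchor atoms near the membrane
surface (the arginine reference residue, the two hairpin-loop tip
atoms whose separation reports gate openness, and the two conserved
aspartate anchors of the intermediate state), plus an aspartate-like
four-bead ligand (C, CA, CB, CG) so side-chain torsion analysis is
exercisable.  Anchor coordinates are synthetic — chosen, not copied
from any deposited structure — but the two distances the analysis
measures (gate tip-to-tip and reference-to-bound-ligand) are laid out
at the occluded-state crystal values, so the parse → select → measure
pipeline can be validated end to end without downloads.

Also provides a scheduled-torsion trajectory generator for conformer
analysis and a molarity helper for the high-concentration mode.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy.constants import Avogadro

from .engine import EngineConfig
from .geometry import PeriodicBox, place_fourth_atom
from .model_io import AtomRecord, Structure, Trajectory, write_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "DEFAULT_ANCHORS",
    "four_bead_ligand",
    "build_synthetic_system",
    "synth_dihedral_trajectory",
    "molarity",
]

#: Gate distance (hairpin tip CA to tip CA) in the substrate-bound,
#: occluded crystal state, Å.
CRYSTAL_GATE_DISTANCE = 5.6
#: Reference-arginine CZ to bound-substrate CA distance in the same state, Å.
CRYSTAL_BINDING_DISTANCE = 5.6

# (name, resname, resnum, chain, position); all anchors sit at z <= 5 Å,
# i.e. just above the membrane surface at z = 0.
DEFAULT_ANCHORS: tuple = (
    ("CZ", "ARG", 397, "A", (0.0, 0.0, 2.0)),
    ("CG", "ARG", 397, "A", (0.0, -2.9, 1.2)),
    ("CA", "SER", 277, "A", (-4.0, 3.0, 2.0)),
    ("CA", "PRO", 356, "A", (-4.0, 3.0 - CRYSTAL_GATE_DISTANCE, 2.0)),
    ("CG", "ASP", 390, "A", (3.0, 2.0, 1.0)),
    ("CG", "ASP", 394, "A", (-3.0, -2.0, 1.5)),
)

_REQUIRED_ANCHORS = {
    ("ARG", 397, "CZ"),
    ("ARG", 397, "CG"),
    ("SER", 277, "CA"),
    ("PRO", 356, "CA"),
    ("ASP", 390, "CG"),
    ("ASP", 394, "CG"),
}


def four_bead_ligand(ca_position, torsion_deg: float = 180.0, bond: float = 1.53,
                     bond_angle: float = 111.0) -> dict[str, np.ndarray]:
    """Coordinates of an aspartate-like four-bead ligand.

    The beads are C, CA, CB, CG with uniform bond lengths and tetrahedral-ish
    bond angles; the C-CA-CB-CG torsion is set exactly to ``torsion_deg``.
    """
    ca = np.asarray(ca_position, dtype=float)
    c = ca + bond * np.array([1.0, 0.0, 0.0])
    t = math.radians(bond_angle)
    cb = ca + bond * np.array([math.cos(t), math.sin(t), 0.0])
    cg = place_fourth_atom(c, ca, cb, bond, bond_angle, torsion_deg)
    return {"C": c, "CA": ca, "CB": cb, "CG": cg}


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """What the synthetic system should contain.

    initial_distance is where the mobile ligand starts, measured from
    the reference atom along +z; 18, 23 and 27 Å are the documented
    protocol placements (default 18).
    """

    anchors: tuple = DEFAULT_ANCHORS
    include_bound_ligand: bool = True
    bound_dihedral: float = 180.0
    bound_distance: float = CRYSTAL_BINDING_DISTANCE
    initial_distance: float = 18.0
    box: PeriodicBox = dataclasses.field(default_factory=PeriodicBox)
    n_steps: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        present = {(rn, num, name) for (name, rn, num, _c, _p) in self.anchors}
        missing = _REQUIRED_ANCHORS - present
        if missing:
            raise ValueError(f"anchor set is missing required atoms: {sorted(missing)}")
        for (name, rn, num, _c, pos) in self.anchors:
            if pos[2] > 5.0:
                raise ValueError(f"anchor {rn}{num}:{name} sits at z={pos[2]} > 5 Å (binding site must hug the membrane)")
        if not self.initial_distance > 0:
            raise ValueError("initial ligand distance must be positive")


def build_synthetic_system(spec: FixtureSpec | None = None) -> tuple[Structure, EngineConfig]:
    """Build the synthetic receptor structure and a draft engine config.

    The structure holds the anchor atoms (ATOM records, chain A) and,
    by default, a bound four-bead aspartate ligand (HETATM records,
    chain L, residue 500) whose CA bead sits at the crystal binding
    distance from the reference arginine CZ, with a prescribed
    side-chain torsion.  The draft config starts the mobile ligand at
    ``spec.initial_distance`` above the reference along +z.
    """
    spec = spec or FixtureSpec()
    ref_pos = None
    atoms: list[AtomRecord] = []
    serial = 1
    for (name, resname, resnum, chain, pos) in spec.anchors:
        atoms.append(AtomRecord(serial, name, resname, resnum=resnum, chain=chain,
                                position=np.asarray(pos, dtype=float), element=name[:1]))
        if (resname, resnum, name) == ("ARG", 397, "CZ"):
            ref_pos = np.asarray(pos, dtype=float)
        serial += 1
    assert ref_pos is not None
    if spec.include_bound_ligand:
        # bound CA placed in the z-plane of the reference, at the crystal distance
        offset = spec.bound_distance / math.sqrt(2.0)
        ca = ref_pos + np.array([offset, offset, 0.0])
        beads = four_bead_ligand(ca, spec.bound_dihedral)
        for name in ("C", "CA", "CB", "CG"):
            atoms.append(AtomRecord(serial, name, "ASP", resnum=500, chain="L",
                                    position=beads[name], element="C", het=True))
            serial += 1
    structure = Structure(atoms, box=spec.box)

    top = ref_pos[2] + spec.initial_distance
    if top >= spec.box.lengths[2] or top <= 0:
        raise ValueError(
            f"initial distance {spec.initial_distance} Å places the ligand at z={top:.1f}, outside the box"
        )
    cfg = EngineConfig(
        n_steps=spec.n_steps,
        seed=spec.seed,
        box=spec.box,
        reference="ARG:397:CZ",
        initial_distance=spec.initial_distance,
    )
    return structure, cfg


def write_fixture(spec: FixtureSpec | None, sink) -> Structure:
    """Build the synthetic system and write its structure as PDB."""
    structure, _ = build_synthetic_system(spec)
    write_pdb(structure, sink)
    return structure


def _normalize_angle(a: float) -> float:
    out = (a + 180.0) % 360.0 - 180.0
    if out == -180.0:
        out = 180.0
    return out


def synth_dihedral_trajectory(schedule, dt: float = 1.0, ca_position=(0.0, 0.0, 10.0),
                              bond: float = 1.53, bond_angle: float = 111.0) -> Trajectory:
    """Four-bead trajectory whose torsion follows a prescribed schedule.

    ``schedule`` is a list of (n_frames, angle_deg) segments; within each
    segment every frame's C-CA-CB-CG torsion equals the scheduled angle
    to within construction precision (~1e-6°).  Angles outside
    (-180, 180] are normalised with a log message.  Frame times are
    0, dt, 2·dt, ...
    """
    schedule = list(schedule)
    if not schedule:
        raise ValueError("schedule must contain at least one segment")
    angles: list[float] = []
    for n_frames, ang in schedule:
        n_frames = int(n_frames)
        if n_frames < 1:
            raise ValueError("each schedule segment needs at least one frame")
        norm = _normalize_angle(float(ang))
        if norm != float(ang):
            logger.info("normalised scheduled angle %s to %s deg", ang, norm)
        angles.extend([norm] * n_frames)
    base = four_bead_ligand(ca_position, angles[0], bond, bond_angle)
    labels = ["C", "CA", "CB", "CG"]
    coords = np.empty((len(angles), 4, 3))
    for i, ang in enumerate(angles):
        cg = place_fourth_atom(base["C"], base["CA"], base["CB"], bond, bond_angle, ang)
        coords[i] = [base["C"], base["CA"], base["CB"], cg]
    times = dt * np.arange(len(angles))
    return Trajectory(times, coords, labels)


def molarity(n: int, volume_A3: float) -> float:
    """Concentration in mol/L of n particles in a volume given in Å³.

    76 ligands in the default 120 × 120 × 100 Å cell come out at
    0.0876 M — the "about 0.1 M" regime of the high-concentration
    protocol (which quotes the concentration against the aqueous
    sub-volume; the value here is for whatever volume the caller
    supplies).
    """
    if n < 0:
        raise ValueError("particle count must be non-negative")
    if volume_A3 <= 0:
        raise ValueError("volume must be positive")
    return n / (Avogadro * volume_A3 * 1e-27)
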