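"""Trajectory observables for the binding protocols.

Distance time series between reference atoms and/or mobile particles,
radial distribution functions around a reference atom (with the
cumulative particle count), side-chain torsion classification into syn
and anti conformers, binding-event detection with hysteresis, and the
fraction of simulation time spent under an active bias force.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .geometry import DegenerateGeometryError, PeriodicBox, dihedral_angle
from .model_io import AtomSelector, SelectionError, Structure, Trajectory, select_atom

__all__ = [
    "DistanceSeries",
    "RDFResult",
    "ConformerSeries",
    "BindingEvent",
    "distance_series",
    "rdf",
    "conformer_classify",
    "detect_binding_events",
    "bias_fraction",
]


@dataclasses.dataclass
class DistanceSeries:
    """Per-frame distance between two endpoints (static atoms or particles)."""

    times: np.ndarray
    distances: np.ndarray
    endpoint_a: str
    endpoint_b: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "distance": self.distances})


@dataclasses.dataclass
class RDFResult:
    """Shell-normalised distance distribution g(r) and cumulative count N(r).

    g(r) is the count density per exact shell volume, normalised by the
    mean density within the analysis sphere of radius r_max (not the
    bulk density: the analysis is restricted to the neighbourhood of
    the reference).  N(r) is the mean number of particles within r per
    frame, so N(r_max) is the mean count inside the sphere.
    """

    edges: np.ndarray
    g: np.ndarray
    cumulative: np.ndarray
    r_max: float
    bin_width: float
    reference: str

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.centers, "g": self.g, "cumulative": self.cumulative})


@dataclasses.dataclass
class ConformerSeries:
    """Per-frame torsion angle and syn/anti label, plus occupancy fractions.

    Frames whose torsion is geometrically undefined are labelled
    "undefined" and excluded from the occupancy normalisation.
    """

    times: np.ndarray
    angles: np.ndarray
    states: list[str]
    occupancy: dict[str, float]
    boundary: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "dihedral": self.angles, "state": self.states})


@dataclasses.dataclass(frozen=True)
class BindingEvent:
    """One contiguous residency of a ligand in the bound state."""

    start: float
    end: float
    ligand: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end precedes start")

    @property
    def residency(self) -> float:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {"ligand": self.ligand, "start": self.start, "end": self.end, "residency": self.residency}


def _resolve_endpoint(traj: Trajectory, endpoint, structure: Structure | None):
    """An endpoint is a particle label, an AtomSelector (or its string form)
    resolved against the static structure, or an explicit coordinate."""
    if isinstance(endpoint, str) and endpoint in traj.labels:
        j = traj.particle_index(endpoint)
        return traj.coords[:, j, :], endpoint
    if isinstance(endpoint, (AtomSelector, str)):
        if structure is None:
            raise SelectionError(f"endpoint {endpoint!r} needs a structure to resolve against")
        atom = select_atom(structure, endpoint, mode="unique")
        name = f"{atom.resname}:{atom.resnum}:{atom.name}"
        return np.broadcast_to(atom.position, (traj.n_frames, 3)), name
    pos = np.asarray(endpoint, dtype=float)
    if pos.shape == (3,):
        return np.broadcast_to(pos, (traj.n_frames, 3)), "point"
    raise SelectionError(f"cannot interpret endpoint {endpoint!r}")


def distance_series(traj: Trajectory, endpoint_a, endpoint_b,
                    structure: Structure | None = None) -> DistanceSeries:
    """Per-frame minimum-image distance between two endpoints.

    Each endpoint may be a mobile-particle label from the trajectory, a
    selector (e.g. "SER:277:CA") resolved in the static structure, or a
    fixed coordinate.
    """
    a, name_a = _resolve_endpoint(traj, endpoint_a, structure)
    b, name_b = _resolve_endpoint(traj, endpoint_b, structure)
    delta = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if traj.box is not None:
        delta = traj.box.minimum_image(delta)
    return DistanceSeries(traj.times.copy(), np.linalg.norm(delta, axis=1), name_a, name_b)


def rdf(traj: Trajectory, reference, structure: Structure | None = None,
        r_max: float = 10.0, bin_width: float = 0.1,
        labels: list[str] | None = None) -> RDFResult:
    """Radial distribution of mobile particles around a reference atom.

    Distances use the minimum image when the trajectory carries a box.
    Shell volumes are exact (4π/3)(r₂³ − r₁³).  See :class:`RDFResult`
    for the normalisation convention.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    if not (0 < bin_width < r_max):
        raise ValueError("bin width must be positive and smaller than r_max")
    ref_pos, ref_name = _resolve_endpoint(traj, reference, structure)
    cols = ([traj.particle_index(l) for l in labels] if labels is not None
            else list(range(traj.n_particles)))
    coords = traj.coords[:, cols, :]
    delta = coords - np.asarray(ref_pos)[:, None, :]
    if traj.box is not None:
        delta = traj.box.minimum_image(delta)
    d = np.linalg.norm(delta, axis=2).ravel()
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    n_frames = traj.n_frames
    mean_counts = counts / n_frames
    shell_vol = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    cumulative = np.cumsum(mean_counts)
    total_in_sphere = float(np.sum(d <= r_max)) / n_frames
    sphere_vol = (4.0 / 3.0) * np.pi * r_max**3
    mean_density = total_in_sphere / sphere_vol
    if mean_density > 0:
        g = (mean_counts / shell_vol) / mean_density
    else:
        g = np.zeros_like(mean_counts)
    return RDFResult(edges, g, cumulative, r_max, bin_width, ref_name)


def conformer_classify(traj: Trajectory, atom_labels=("C", "CA", "CB", "CG"),
                       boundary: float = 120.0, three_state: bool = False,
                       window: float = 30.0) -> ConformerSeries:
    """Classify the side-chain torsion of a four-bead ligand per frame.

    The torsion is taken over the four labelled beads in order (C, CA,
    CB, CG for an aspartate-like ligand).  With the default two-state
    scheme a frame is *syn* when \\|angle\\| <= boundary (120°, the
    midpoint between the ~70° syn and ~180° anti modes) and *anti*
    otherwise.  ``three_state`` instead uses ±window bands around 70°
    and 180° with everything else labelled "other".  Occupancy
    fractions are over defined frames and sum to 1.
    """
    idx = [traj.particle_index(l) for l in atom_labels]
    if len(idx) != 4:
        raise SelectionError("need exactly four atom labels")
    angles = np.full(traj.n_frames, np.nan)
    states: list[str] = []
    for i in range(traj.n_frames):
        p = traj.coords[i]
        try:
            ang = dihedral_angle(p[idx[0]], p[idx[1]], p[idx[2]], p[idx[3]])
        except DegenerateGeometryError:
            states.append("undefined")
            continue
        angles[i] = ang
        if three_state:
            if abs(abs(ang) - 70.0) <= window:
                states.append("syn")
            elif abs(abs(ang) - 180.0) <= window:
                states.append("anti")
            else:
                states.append("other")
        else:
            states.append("syn" if abs(ang) <= boundary else "anti")
    defined = [s for s in states if s != "undefined"]
    occupancy: dict[str, float] = {}
    if defined:
        for label in ("syn", "anti") + (("other",) if three_state else ()):
            occupancy[label] = defined.count(label) / len(defined)
    return ConformerSeries(traj.times.copy(), angles, states, occupancy, boundary)


def detect_binding_events(ds: DistanceSeries, bind_threshold: float = 7.0,
                          unbind_threshold: float = 9.0, dwell: int = 10,
                          ligand: str | None = None) -> list[BindingEvent]:
    """Binding/unbinding events with hysteresis.

    An event opens when the distance stays below ``bind_threshold`` for
    at least ``dwell`` consecutive frames (the event start is the first
    such frame) and closes when the distance exceeds
    ``unbind_threshold``; an event still open at the end of the series
    closes at the final frame.  With unbind == bind and dwell == 1 this
    reduces to plain threshold crossing.
    """
    if unbind_threshold < bind_threshold:
        raise ValueError("unbind threshold must be >= bind threshold (hysteresis)")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    t = ds.times
    d = ds.distances
    label = ligand if ligand is not None else ds.endpoint_b
    events: list[BindingEvent] = []
    open_start: float | None = None
    run = 0
    for i in range(len(d)):
        if open_start is None:
            run = run + 1 if d[i] < bind_threshold else 0
            if run >= dwell:
                open_start = float(t[i - dwell + 1])
        else:
            if d[i] > unbind_threshold:
                events.append(BindingEvent(open_start, float(t[i]), label))
                open_start = None
                run = 0
    if open_start is not None:
        events.append(BindingEvent(open_start, float(t[-1]), label))
    return events


def bias_fraction(flags) -> float:
    """Fraction of frames with an active bias force.

    Accepts a SimulationResult, a 1-D boolean flag series, or a
    (n_frames, n_particles) flag array (a frame counts as biased when
    any particle is biased, matching the grey force-application bars of
    a single-ligand trajectory plot).
    """
    if hasattr(flags, "trajectory"):
        flags = flags.trajectory.flags
    arr = np.asarray(flags, dtype=bool)
    if arr.size == 0:
        raise ValueError("empty trajectory: bias fraction undefined")
    if arr.ndim == 2:
        arr = np.any(arr, axis=1)
    return float(np.mean(arr))
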