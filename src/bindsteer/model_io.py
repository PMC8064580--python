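"""Structure and trajectory I/O.

Reads a fixed-column PDB subset (ATOM/HETATM records only, author
residue numbering), resolves atom selections such as ``ARG:397:CZ``,
and round-trips particle trajectories through a text-based extended
XYZ format whose per-frame comment line carries the time stamp and the
per-particle bias-active flags.  Analysis tables go out as CSV with an
optional provenance comment header; event logs as JSON lines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import PeriodicBox, _as_vec

logger = logging.getLogger(__name__)

__all__ = [
    "ModelIOError",
    "PDBFormatError",
    "SelectionError",
    "TrajectoryFormatError",
    "AtomRecord",
    "Structure",
    "AtomSelector",
    "Trajectory",
    "read_pdb_subset",
    "write_pdb",
    "select_atom",
    "write_trajectory",
    "read_trajectory",
    "write_table_csv",
    "write_events_jsonl",
    "read_events_jsonl",
]


class ModelIOError(ValueError):
    pass


class PDBFormatError(ModelIOError):
    pass


class SelectionError(ModelIOError):
    pass


class TrajectoryFormatError(ModelIOError):
    pass


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One atom of a (static) structure, PDB author numbering, coordinates in Å."""

    serial: int
    name: str
    resname: str
    chain: str
    resnum: int
    position: np.ndarray
    element: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", _as_vec(self.position, "position"))

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.name)


class Structure:
    """Ordered collection of atoms with unique (chain, resnum, name) keys."""

    def __init__(self, atoms: Sequence[AtomRecord], box: PeriodicBox | None = None):
        atoms = list(atoms)
        if not atoms:
            raise ModelIOError("no atoms: a structure must contain at least one atom")
        index: dict[tuple[str, int, str], AtomRecord] = {}
        for a in atoms:
            if a.key in index:
                raise ModelIOError(f"duplicate atom {a.chain}:{a.resname}{a.resnum}:{a.name}")
            index[a.key] = a
        self.atoms = atoms
        self.box = box
        self._index = index

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclasses.dataclass(frozen=True)
class AtomSelector:
    """Match atoms by exact equality on any provided field.

    ``AtomSelector.parse("ARG:397:CZ")`` accepts the compact
    resname:resnum:atomname form used throughout configs (a leading
    chain id may be prepended: ``A:ARG:397:CZ``).
    """

    chain: str | None = None
    resnum: int | None = None
    resname: str | None = None
    name: str | None = None

    @classmethod
    def parse(cls, text: str) -> "AtomSelector":
        parts = [p.strip() for p in text.split(":")]
        if len(parts) == 3:
            resname, resnum, name = parts
            return cls(resname=resname or None, resnum=int(resnum), name=name or None)
        if len(parts) == 4:
            chain, resname, resnum, name = parts
            return cls(chain=chain or None, resname=resname or None, resnum=int(resnum), name=name or None)
        raise SelectionError(f"cannot parse selector {text!r}: expected RESNAME:RESNUM:ATOM")

    def matches(self, a: AtomRecord) -> bool:
        return (
            (self.chain is None or a.chain == self.chain)
            and (self.resnum is None or a.resnum == self.resnum)
            and (self.resname is None or a.resname == self.resname)
            and (self.name is None or a.name == self.name)
        )

    def __str__(self) -> str:
        fields = [self.chain, self.resname, None if self.resnum is None else str(self.resnum), self.name]
        return ":".join("" if f is None else f for f in fields if True).strip(":") or "<any>"


def select_atom(structure: Structure, sel: AtomSelector | str, mode: str = "unique"):
    """Resolve a selector against a structure.

    mode="unique" returns a single AtomRecord and raises if the match is
    not exactly one; mode="all" returns the (non-empty) list of matches.
    """
    if isinstance(sel, str):
        sel = AtomSelector.parse(sel)
    if mode not in ("unique", "all"):
        raise SelectionError(f"unknown selection mode {mode!r}")
    matches = [a for a in structure.atoms if sel.matches(a)]
    if not matches:
        near = sorted({a.resnum for a in structure.atoms}, key=lambda r: abs(r - (sel.resnum or 0)))[:5]
        raise SelectionError(f"no atom matches {sel}; closest residue numbers present: {near}")
    if mode == "unique":
        if len(matches) > 1:
            listing = ", ".join(f"{a.chain}:{a.resname}{a.resnum}:{a.name}" for a in matches[:8])
            raise SelectionError(f"selector {sel} is ambiguous ({len(matches)} matches): {listing}")
        return matches[0]
    return matches


# ---------------------------------------------------------------------------
# PDB subset reader / writer (fixed columns, ATOM/HETATM only)
# ---------------------------------------------------------------------------

def _open_maybe(source, mode: str):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode), True
    return source, False


def read_pdb_subset(source) -> Structure:
    """Parse ATOM/HETATM records from a fixed-column PDB stream or path.

    All other record types are ignored.  Alternate-location indicators
    other than blank or "A" are skipped with a log message.  Malformed
    fixed columns raise an error naming the offending line; duplicate
    (chain, resnum, atom name) combinations raise as well.
    """
    stream, close = _open_maybe(source, "r")
    atoms: list[AtomRecord] = []
    seen: set[tuple[str, int, str]] = set()
    try:
        for lineno, raw in enumerate(stream, start=1):
            rec = raw[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            line = raw.rstrip("\n")
            altloc = line[16:17] if len(line) > 16 else " "
            if altloc not in (" ", "", "A"):
                logger.warning("line %d: skipping alternate location %r for atom %r", lineno, altloc, line[12:16].strip())
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21:22].strip()
                resnum = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise PDBFormatError(f"malformed fixed-column PDB record on line {lineno}: {line!r}") from exc
            element = line[76:78].strip() if len(line) >= 77 else ""
            if not name:
                raise PDBFormatError(f"missing atom name on line {lineno}: {line!r}")
            key = (chain, resnum, name)
            if key in seen:
                raise PDBFormatError(f"duplicate atom {chain}:{resname}{resnum}:{name} on line {lineno}")
            seen.add(key)
            atoms.append(AtomRecord(serial, name, resname, chain, resnum, np.array([x, y, z]), element, het=(rec == "HETATM")))
    finally:
        if close:
            stream.close()
    if not atoms:
        raise PDBFormatError("no atoms: stream contained no ATOM/HETATM records")
    return Structure(atoms)


def _pdb_atom_name_field(name: str) -> str:
    # Names shorter than 4 characters start in column 14 by convention.
    return f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"


def write_pdb(structure: Structure, sink) -> None:
    """Write a Structure as fixed-column ATOM/HETATM records."""
    stream, close = _open_maybe(sink, "w")
    try:
        for a in structure.atoms:
            rec = "HETATM" if a.het else "ATOM"
            x, y, z = a.position
            stream.write(
                f"{rec:<6s}{a.serial:>5d} {_pdb_atom_name_field(a.name)} {a.resname:<3s} "
                f"{a.chain:1s}{a.resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
        stream.write("END\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Trajectory container and extended-XYZ round trip
# ---------------------------------------------------------------------------

class Trajectory:
    """Time-ordered frames of labelled mobile particles.

    Attributes
    ----------
    times : (n_frames,) float array, strictly increasing (ps or step index)
    coords : (n_frames, n_particles, 3) float array, Å
    labels : list of n_particles unique strings (no whitespace)
    flags : (n_frames, n_particles) bool array, bias-active per particle
    box : PeriodicBox or None
    """

    def __init__(self, times, coords, labels, flags=None, box: PeriodicBox | None = None):
        times = np.asarray(times, dtype=float)
        coords = np.asarray(coords, dtype=float)
        labels = list(labels)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ModelIOError(f"coords must be (n_frames, n_particles, 3), got {coords.shape}")
        if times.ndim != 1 or times.shape[0] != coords.shape[0]:
            raise ModelIOError("times and coords disagree on the number of frames")
        if times.size == 0:
            raise ModelIOError("a trajectory must contain at least one frame")
        if np.any(np.diff(times) <= 0):
            raise ModelIOError("frame times must be strictly increasing")
        if len(labels) != coords.shape[1]:
            raise ModelIOError("label count does not match particle count")
        if len(set(labels)) != len(labels):
            raise ModelIOError("particle labels must be unique")
        if any((" " in l) or ("\t" in l) or (not l) for l in labels):
            raise ModelIOError("labels must be non-empty and contain no whitespace")
        if flags is None:
            flags = np.zeros(coords.shape[:2], dtype=bool)
        flags = np.asarray(flags, dtype=bool)
        if flags.shape != coords.shape[:2]:
            raise ModelIOError("flags must be shaped (n_frames, n_particles)")
        self.times = times
        self.coords = coords
        self.labels = labels
        self.flags = flags
        self.box = box

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def particle_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise SelectionError(f"no particle labelled {label!r}; labels: {self.labels[:10]}") from None

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def write_trajectory(traj: Trajectory, sink) -> None:
    """Write as extended XYZ: per frame an atom-count line, a comment line
    ``time=<t> flags=<bitstring>``, then one ``label x y z`` line per particle."""
    stream, close = _open_maybe(sink, "w")
    try:
        m = traj.n_particles
        for i in range(traj.n_frames):
            bits = "".join("1" if f else "0" for f in traj.flags[i])
            stream.write(f"{m}\n")
            stream.write(f"time={traj.times[i]:.10g} flags={bits}\n")
            for j in range(m):
                x, y, z = traj.coords[i, j]
                stream.write(f"{traj.labels[j]} {x:.6f} {y:.6f} {z:.6f}\n")
    finally:
        if close:
            stream.close()


def read_trajectory(source, box: PeriodicBox | None = None) -> Trajectory:
    """Inverse of :func:`write_trajectory` (lossless to ≥1e-6 Å)."""
    stream, close = _open_maybe(source, "r")
    try:
        lines = stream.read().splitlines()
    finally:
        if close:
            stream.close()
    times: list[float] = []
    frames: list[np.ndarray] = []
    flag_rows: list[list[bool]] = []
    labels: list[str] | None = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            m = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(f"frame {frame_no}: expected an atom count, got {lines[i]!r}")
        if labels is not None and m != len(labels):
            raise TrajectoryFormatError(
                f"inconsistent atom count at frame {frame_no}: got {m}, expected {len(labels)}"
            )
        if i + 1 >= len(lines):
            raise TrajectoryFormatError(f"frame {frame_no}: missing comment line")
        comment = lines[i + 1]
        fields = dict(tok.split("=", 1) for tok in comment.split() if "=" in tok)
        if "time" not in fields:
            raise TrajectoryFormatError(f"frame {frame_no}: comment line lacks time=: {comment!r}")
        t = float(fields["time"])
        bits = fields.get("flags", "0" * m)
        if len(bits) != m or any(c not in "01" for c in bits):
            raise TrajectoryFormatError(f"frame {frame_no}: flags bitstring {bits!r} does not match {m} particles")
        frame_labels: list[str] = []
        coords = np.empty((m, 3))
        for j in range(m):
            row = lines[i + 2 + j].split()
            if len(row) != 4:
                raise TrajectoryFormatError(f"frame {frame_no}: bad particle line {lines[i + 2 + j]!r}")
            frame_labels.append(row[0])
            coords[j] = [float(v) for v in row[1:]]
        if labels is None:
            labels = frame_labels
        elif frame_labels != labels:
            raise TrajectoryFormatError(f"frame {frame_no}: particle labels changed")
        times.append(t)
        frames.append(coords)
        flag_rows.append([c == "1" for c in bits])
        i += 2 + m
    if not frames:
        raise TrajectoryFormatError("no frames found")
    return Trajectory(np.array(times), np.stack(frames), labels, np.array(flag_rows), box=box)


# ---------------------------------------------------------------------------
# Analysis outputs
# ---------------------------------------------------------------------------

def write_table_csv(df: pd.DataFrame, sink, provenance: dict | None = None) -> None:
    """CSV with a header row, preceded by '# key=value' provenance comments."""
    stream, close = _open_maybe(sink, "w")
    try:
        if provenance:
            for k, v in provenance.items():
                stream.write(f"# {k}={v}\n")
        df.to_csv(stream, index=False)
    finally:
        if close:
            stream.close()


def read_table_csv(source) -> pd.DataFrame:
    return pd.read_csv(source, comment="#")


def write_events_jsonl(events: Iterable[dict], sink) -> None:
    """One JSON object per line."""
    stream, close = _open_maybe(sink, "w")
    try:
        for ev in events:
            stream.write(json.dumps(ev) + "\n")
    finally:
        if close:
            stream.close()


def read_events_jsonl(source) -> list[dict]:
    stream, close = _open_maybe(source, "r")
    try:
        return [json.loads(line) for line in stream if line.strip()]
    finally:
        if close:
            stream.close()
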