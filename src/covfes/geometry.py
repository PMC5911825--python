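"""Coordinate snapshots and geometric descriptors.

Reads/writes fixed-column PDB ATOM records and computes the descriptors the
conformational analyses consume: interatomic distances (Å), proper dihedral
angles (degrees, IUPAC sign convention with cis = 0°, range (−180°, 180°]),
and difference-of-distance coordinates such as the proton-transfer
coordinate (H–S) − (H–O). Internally angles are radians; everything exposed
is degrees and Å.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Snapshot",
    "GeometricDescriptor",
    "read_pdb_snapshot",
    "write_pdb_snapshot",
    "distance",
    "dihedral",
    "difference_coordinate",
    "evaluate_descriptors",
    "make_toy_snapshots",
    "write_features",
    "read_features",
]


@dataclass(frozen=True)
class Atom:
    name: str
    res_name: str
    chain: str
    res_seq: int
    icode: str
    x: float
    y: float
    z: float
    element: str = ""

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Snapshot:
    """One coordinate frame: atoms plus time/replica provenance."""

    atoms: list[Atom]
    time: float = 0.0
    replica: int = 0

    def select(self, chain: str, res_seq: int, name: str) -> Atom:
        """The unique atom matching (chain, residue number, atom name)."""
        hits = [
            a
            for a in self.atoms
            if a.chain == chain and a.res_seq == res_seq and a.name == name
        ]
        if len(hits) != 1:
            raise KeyError(
                f"selector ({chain!r}, {res_seq}, {name!r}) matched "
                f"{len(hits)} atoms (need exactly 1)"
            )
        return hits[0]


def read_pdb_snapshot(source, time: float = 0.0, replica: int = 0) -> Snapshot:
    """Parse ATOM/HETATM records from PDB text, a path, or a stream.

    Only the first model of a multi-model file is read. Malformed coordinate
    fields raise with the offending line number; a file without any atom
    records raises an empty-input error.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    atoms: list[Atom] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            break  # first model only
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed coordinate field: {line!r}") from exc
        atoms.append(
            Atom(
                name=line[12:16].strip(),
                res_name=line[17:20].strip(),
                chain=line[21].strip() or "A",
                res_seq=int(line[22:26]),
                icode=line[26].strip(),
                x=x,
                y=y,
                z=z,
                element=line[76:78].strip() if len(line) >= 78 else "",
            )
        )
    if not atoms:
        raise ValueError("no ATOM/HETATM records found (empty input)")
    return Snapshot(atoms, time=time, replica=replica)


def write_pdb_snapshot(snapshot: Snapshot) -> str:
    """Serialize as standard fixed-column ATOM records (coordinates in Å)."""
    buf = io.StringIO()
    for i, a in enumerate(snapshot.atoms, start=1):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        buf.write(
            f"ATOM  {i:5d} {name:<4.4s} {a.res_name:<3.3s} {a.chain:1.1s}"
            f"{a.res_seq:4d}{a.icode:1.1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2.2s}\n"
        )
    buf.write("END\n")
    return buf.getvalue()


def distance(p1, p2) -> float:
    """Euclidean distance in Å."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(p2 - p1))


def dihedral(p1, p2, p3, p4) -> float:
    """Proper dihedral p1-p2-p3-p4 in degrees, IUPAC convention.

    cis (eclipsed) = 0°, trans = 180°; right-handed sign; range (−180, 180]
    with the boundary mapped to +180. Raises when three consecutive points
    are collinear (the dihedral is undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * (np.linalg.norm(b1) * b2n + 1e-300) or (
        np.linalg.norm(n2) < 1e-10 * (np.linalg.norm(b3) * b2n + 1e-300)
    ):
        raise ValueError("undefined dihedral: three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:  # boundary maps to +180
        ang += 360.0
    return ang


def difference_coordinate(d_ab: float, d_cd: float) -> float:
    """Difference-of-distances coordinate d(A–B) − d(C–D), Å."""
    if d_ab < 0 or d_cd < 0:
        raise ValueError("distances must be non-negative")
    return float(d_ab) - float(d_cd)


_KINDS = {"distance": 2, "dihedral": 4, "distance_difference": 4}


@dataclass(frozen=True)
class GeometricDescriptor:
    """A named geometric observable over 2–4 atom selectors.

    Selectors are (chain, residue number, atom name) triples. For
    ``distance_difference`` the four selectors pair as (A–B) − (C–D).
    """

    name: str
    kind: str
    selectors: tuple[tuple[str, int, str], ...]

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        object.__setattr__(self, "selectors", tuple(tuple(s) for s in self.selectors))
        if len(self.selectors) != _KINDS[self.kind]:
            raise ValueError(
                f"{self.kind} needs {_KINDS[self.kind]} selectors, got {len(self.selectors)}"
            )

    @property
    def units(self) -> str:
        return "degrees" if self.kind == "dihedral" else "angstrom"

    def evaluate(self, snapshot: Snapshot) -> float:
        try:
            pts = [snapshot.select(*s).position for s in self.selectors]
        except KeyError as exc:
            raise KeyError(
                f"descriptor {self.name!r}: {exc.args[0]} "
                f"(snapshot at t={snapshot.time})"
            ) from None
        if self.kind == "distance":
            return distance(pts[0], pts[1])
        if self.kind == "dihedral":
            return dihedral(*pts)
        return difference_coordinate(distance(pts[0], pts[1]), distance(pts[2], pts[3]))


def evaluate_descriptors(snapshots, descriptors) -> pd.DataFrame:
    """One row per snapshot, one column per descriptor (declaration order)."""
    cols = [d.name for d in descriptors]
    rows = []
    for snap in snapshots:
        row = {"time": snap.time, "replica": snap.replica}
        for d in descriptors:
            row[d.name] = d.evaluate(snap)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["time", "replica", *cols])
    if frame.empty:
        frame = pd.DataFrame(columns=["time", "replica", *cols])
    return frame


# ---------------------------------------------------------------------------
# Toy fixtures
# ---------------------------------------------------------------------------


def make_toy_snapshots(
    distance_target: float | None = None,
    dihedral_target: float | None = None,
) -> tuple[str, list[GeometricDescriptor]]:
    """Minimal PDB text whose descriptors equal the requested targets.

    Builds a two-atom pair at the requested separation and/or a four-atom
    chain with the requested dihedral; returns the PDB text together with
    matching descriptors so the round trip (parse → evaluate) can be checked
    to 10⁻³. Raises for unrealizable targets (negative distance).
    """
    atoms: list[Atom] = []
    descriptors: list[GeometricDescriptor] = []
    if distance_target is not None:
        if distance_target < 0:
            raise ValueError("distance target must be non-negative")
        atoms += [
            Atom("S1", "TOY", "A", 1, "", 0.0, 0.0, 0.0),
            Atom("C1", "TOY", "A", 1, "", float(distance_target), 0.0, 0.0),
        ]
        descriptors.append(
            GeometricDescriptor(
                "pair_distance", "distance", (("A", 1, "S1"), ("A", 1, "C1"))
            )
        )
    if dihedral_target is not None:
        if not np.isfinite(dihedral_target):
            raise ValueError("dihedral target must be finite")
        phi = math.radians(float(dihedral_target))
        # chain along x; p4 rotated about the central bond by phi from cis.
        # The long (40 A) arms keep the 0.001 A PDB coordinate quantization
        # below the 1e-3 degree target precision.
        r = 40.0
        atoms += [
            Atom("D1", "TOY", "B", 2, "", 0.0, r, 0.0),
            Atom("D2", "TOY", "B", 2, "", 0.0, 0.0, 0.0),
            Atom("D3", "TOY", "B", 2, "", 1.5, 0.0, 0.0),
            Atom("D4", "TOY", "B", 2, "", 1.5, r * math.cos(phi), r * math.sin(phi)),
        ]
        descriptors.append(
            GeometricDescriptor(
                "chain_dihedral",
                "dihedral",
                (("B", 2, "D1"), ("B", 2, "D2"), ("B", 2, "D3"), ("B", 2, "D4")),
            )
        )
    if not atoms:
        raise ValueError("no targets requested")
    snap = Snapshot(atoms)
    text = write_pdb_snapshot(snap)
    # verify the construction before handing it out
    parsed = read_pdb_snapshot(text)
    for d, target in zip(
        descriptors,
        [t for t in (distance_target, dihedral_target) if t is not None],
    ):
        got = d.evaluate(parsed)
        if abs(got - float(target)) > 1e-3:
            raise ValueError(
                f"toy construction failed for {d.name}: got {got}, want {target}"
            )
    return text, descriptors


# ---------------------------------------------------------------------------
# Feature-series tables
# ---------------------------------------------------------------------------


def write_features(frame: pd.DataFrame, path, comment: str | None = None) -> None:
    """Tab-separated feature table with a header line and '#' comments."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
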