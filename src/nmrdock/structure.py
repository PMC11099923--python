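"""Minimal protein structure model: PDB I/O, rigid transforms and geometry.

Coordinates are in Å throughout, residue numbering is 1-based and taken
verbatim from the source PDB (no renumbering).  The reader keeps the first
MODEL of an NMR ensemble, keeps altloc ' ' or 'A', skips waters and rejects
insertion codes.  Restraint evaluation downstream is heavy-atom based, so
hydrogens are retained when present but excluded from ``heavy``-flavoured
accessors.

Rotations are carried as scalar-first unit quaternions ``(w, x, y, z)``,
right-handed, acting actively on column vectors: ``y = R x + t``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DataError, NumericError, ParseError

log = logging.getLogger(__name__)

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}

#: three-letter -> one-letter amino-acid codes (subset used by the toy system
#: plus the standard twenty).
AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _infer_element(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            # Two-letter elements never occur in the atom vocabulary handled
            # here (protein heavy atoms + H); first alphabetic char suffices.
            return ch.upper()
    return "X"


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise DataError(f"atom {self.name!r}: coordinates must be 3 finite numbers")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.xyz.copy(), self.occupancy, self.bfactor)


@dataclass
class Residue:
    resid: int
    resname: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise DataError(f"residue {self.resname}{self.resid}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def copy(self) -> "Residue":
        return Residue(self.resid, self.resname, [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, resid: int) -> Residue:
        for r in self.residues:
            if r.resid == resid:
                return r
        raise DataError(f"chain {self.chain_id}: no residue {resid}")

    def has_residue(self, resid: int) -> bool:
        return any(r.resid == resid for r in self.residues)

    @property
    def resids(self) -> list[int]:
        return [r.resid for r in self.residues]

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


class Structure:
    """A set of chains; supports coordinate extraction and rigid motion."""

    def __init__(self, chains: Sequence[Chain]):
        self.chains = list(chains)
        self.validate()

    def validate(self) -> None:
        seen = set()
        for ch in self.chains:
            if ch.chain_id in seen:
                raise DataError(f"duplicate chain id {ch.chain_id!r}")
            seen.add(ch.chain_id)
            last = None
            for res in ch.residues:
                if last is not None and res.resid <= last:
                    raise DataError(
                        f"chain {ch.chain_id}: resids not strictly increasing at {res.resid}"
                    )
                last = res.resid

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise DataError(f"no chain {chain_id!r} in structure")

    def has_chain(self, chain_id: str) -> bool:
        return any(ch.chain_id == chain_id for ch in self.chains)

    def atoms(self, chain_id: str | None = None, heavy_only: bool = False) -> Iterator[tuple[Chain, Residue, Atom]]:
        for ch in self.chains:
            if chain_id is not None and ch.chain_id != chain_id:
                continue
            for res in ch.residues:
                for a in res.atoms:
                    if heavy_only and not a.is_heavy:
                        continue
                    yield ch, res, a

    def coords(self, chain_id: str | None = None, heavy_only: bool = False) -> np.ndarray:
        pts = [a.xyz for _, _, a in self.atoms(chain_id, heavy_only)]
        if not pts:
            return np.zeros((0, 3))
        return np.array(pts)

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "Structure":
        return Structure([ch.copy() for ch in self.chains])

    def subset(self, chain_ids: Iterable[str]) -> "Structure":
        wanted = list(chain_ids)
        return Structure([self.chain(c).copy() for c in wanted])


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rigid motion ``y = R x + t``.

    ``q`` is a scalar-first unit quaternion ``(w, x, y, z)``; the quaternion
    norm must be 1 within 1e-9.
    """

    q: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.q.shape != (4,) or self.t.shape != (3,):
            raise DataError("RigidTransform needs a 4-quaternion and a 3-translation")
        if abs(np.linalg.norm(self.q) - 1.0) > 1e-9:
            raise NumericError(
                f"quaternion norm {np.linalg.norm(self.q):.12f} deviates from 1 by more than 1e-9"
            )

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(3))

    @classmethod
    def from_rotation(cls, rot: Rotation, t: np.ndarray | None = None) -> "RigidTransform":
        q = rot.as_quat(scalar_first=True)
        q = q / np.linalg.norm(q)
        return cls(q, np.zeros(3) if t is None else np.asarray(t, dtype=float))

    @classmethod
    def from_quat(cls, q: np.ndarray, t: np.ndarray | None = None) -> "RigidTransform":
        q = np.asarray(q, dtype=float)
        return cls(q / np.linalg.norm(q), np.zeros(3) if t is None else np.asarray(t, dtype=float))

    # -- algebra ------------------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.q, scalar_first=True)

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equal to applying ``other`` first, then ``self``."""
        rot = self.rotation * other.rotation
        t = self.matrix @ other.t + self.t
        return RigidTransform.from_rotation(rot, t)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        return RigidTransform.from_rotation(rinv, -rinv.as_matrix() @ self.t)


def apply_transform(s: Structure, t: RigidTransform) -> Structure:
    """Return a copy of ``s`` with every atom moved by the rigid motion."""
    out = s.copy()
    for _, _, atom in out.atoms():
        atom.xyz = t.apply(atom.xyz)
    return out


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Parse ATOM/HETATM records (fixed columns) into a :class:`Structure`.

    Only MODEL 1 of a multi-model (NMR ensemble) file is kept; insertion
    codes are rejected; waters are skipped; altloc 'A' or blank is kept.
    """
    chains: dict[str, Chain] = {}
    order: list[str] = []
    model = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                model += 1
                continue
            if rec.startswith("ENDMDL"):
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if model > 1:
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}: line {lineno}: truncated coordinate record")
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            icode = line[26]
            if icode != " ":
                raise ParseError(f"{path}: line {lineno}: insertion codes are not supported")
            resname = line[17:20].strip()
            if resname in _WATER_RESNAMES:
                continue
            name = line[12:16].strip()
            chain_id = line[21]
            try:
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: malformed numeric field ({exc})") from None
            occ = 1.0
            bfac = 0.0
            try:
                if line[54:60].strip():
                    occ = float(line[54:60])
                if line[60:66].strip():
                    bfac = float(line[60:66])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: malformed numeric field ({exc})") from None
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(name)
            atom = Atom(name, element, np.array([x, y, z]), occ, bfac)
            if chain_id not in chains:
                chains[chain_id] = Chain(chain_id)
                order.append(chain_id)
            ch = chains[chain_id]
            if ch.residues and ch.residues[-1].resid == resid:
                ch.residues[-1].atoms.append(atom)
            else:
                ch.residues.append(Residue(resid, resname, [atom]))
    if not chains:
        raise DataError(f"{path}: no ATOM/HETATM records found")
    return Structure([chains[c] for c in order])


def _format_atom_line(serial: int, atom: Atom, res: Residue, chain_id: str) -> str:
    name = atom.name
    # PDB convention: atom names of <4 chars start in column 14.
    if len(name) < 4:
        name = " " + name
    return (
        f"ATOM  {serial:5d} {name:<4s} {res.resname:<3s} {chain_id}{res.resid:4d}    "
        f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
        f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          {atom.element:>2s}"
    )


def write_pdb(structures: Structure | Sequence[Structure], path, remarks: Sequence[str] = ()) -> None:
    """Write one structure, or several as a multi-MODEL file.

    ``remarks`` become REMARK records at the top (one per entry).
    """
    if isinstance(structures, Structure):
        models = [structures]
        multi = False
    else:
        models = list(structures)
        multi = len(models) > 1
    lines: list[str] = [f"REMARK   1 {r}" for r in remarks]
    for imodel, s in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        serial = 1
        for ch in s.chains:
            for res in ch.residues:
                for atom in res.atoms:
                    lines.append(_format_atom_line(serial, atom, res, ch.chain_id))
                    serial += 1
            lines.append(f"TER   {serial:5d}      {ch.residues[-1].resname:<3s} "
                         f"{ch.chain_id}{ch.residues[-1].resid:4d}")
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Superposition and geometry
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the optimal proper rigid transform (applied to ``mobile``) and
    the minimized RMSD in Å.  Requires >= 3 non-collinear points in each set.
    """
    mob = np.asarray(mobile, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if mob.shape != tgt.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise DataError("point sets must both have shape (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise DataError("superposition needs at least 3 points")
    cm, ct = mob.mean(axis=0), tgt.mean(axis=0)
    mc, tc = mob - cm, tgt - ct
    sv = np.linalg.svd(mc, compute_uv=False)
    if sv[1] < 1e-8 * max(1.0, sv[0]):
        raise DataError("superposition input is (near-)collinear")
    rot, rssd = Rotation.align_vectors(tc, mc)
    rmsd = float(rssd / math.sqrt(n))
    t = ct - rot.as_matrix() @ cm
    return RigidTransform.from_rotation(rot, t), rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no superposition)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("RMSD needs equally sized coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def interface_residues(
    complexe: Structure, chain_a: str, chain_b: str, cutoff: float = 5.0
) -> tuple[set[int], set[int]]:
    """Residues of each chain with any cross-chain heavy-atom pair < cutoff Å."""
    data = {}
    for cid in (chain_a, chain_b):
        ch = complexe.chain(cid)
        pts, rid = [], []
        for res in ch.residues:
            for a in res.heavy_atoms:
                pts.append(a.xyz)
                rid.append(res.resid)
        data[cid] = (np.array(pts), np.array(rid))
    pa, ra = data[chain_a]
    pb, rb = data[chain_b]
    out_a: set[int] = set()
    out_b: set[int] = set()
    if len(pa) == 0 or len(pb) == 0:
        return out_a, out_b
    tree = cKDTree(pb)
    neighbours = tree.query_ball_point(pa, cutoff)
    for i, nb in enumerate(neighbours):
        for j in nb:
            if np.linalg.norm(pa[i] - pb[j]) < cutoff:  # strict inequality
                out_a.add(int(ra[i]))
                out_b.add(int(rb[j]))
    return out_a, out_b


_ACIDIC_GROUPS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC_GROUPS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
_BASIC_GROUPS_HIS = {"HIS": ("ND1", "NE2")}


@dataclass(frozen=True)
class SaltBridge:
    acidic: tuple[str, int]   # (chain, resid)
    basic: tuple[str, int]
    distance: float


def salt_bridges(complexe: Structure, cutoff: float = 4.0, include_his: bool = False) -> list[SaltBridge]:
    """Acidic/basic residue pairs whose charged-group atoms come within cutoff.

    A pair is reported iff the minimum distance between carboxylate oxygens
    (Asp/Glu) and the basic nitrogen group (Lys NZ; Arg NH1/NH2/NE; His
    ND1/NE2 when enabled) is <= cutoff.  Residues lacking their side-chain
    atoms are skipped with a debug log entry.  Sorted by distance.
    """
    basic_groups = dict(_BASIC_GROUPS)
    if include_his:
        basic_groups.update(_BASIC_GROUPS_HIS)

    def _collect(groups):
        sites = []
        for ch in complexe.chains:
            for res in ch.residues:
                names = groups.get(res.resname)
                if names is None:
                    continue
                pts = [res.atom(n).xyz for n in names if res.has_atom(n)]
                if not pts:
                    log.debug("salt_bridges: %s %s%d lacks side-chain atoms, skipped",
                              ch.chain_id, res.resname, res.resid)
                    continue
                sites.append(((ch.chain_id, res.resid), np.array(pts)))
        return sites

    acidic = _collect(_ACIDIC_GROUPS)
    basic = _collect(basic_groups)
    found = []
    for aid, apts in acidic:
        for bid, bpts in basic:
            if aid == bid:
                continue
            d = float(np.min(np.linalg.norm(apts[:, None, :] - bpts[None, :, :], axis=-1)))
            if d <= cutoff:
                found.append(SaltBridge(aid, bid, round(d, 6)))
    found.sort(key=lambda sb: (sb.distance, sb.acidic, sb.basic))
    return found


def radius_of_gyration(coords: np.ndarray) -> float:
    c = np.asarray(coords, dtype=float)
    centred = c - c.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))
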