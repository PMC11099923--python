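"""Distance restraints: ambiguous interaction restraints (AIRs), effective
distances, violation energies and a CNS-style ``.tbl`` reader/writer.

An ambiguous restraint aggregates all cross pairs between its two atom
selections with the usual r⁻⁶ effective distance

    d_eff = ( Σ_i Σ_j d_ij⁻⁶ )^(−1/6)

so the shortest pair dominates; spin-label ambiguity (a probe on several
sites) instead uses plain minimum-distance semantics, selectable per
restraint via ``aggregate``.

Selections are tuples of ``(chain, resid, atom-name pattern)``.  Pattern
``"*"`` resolves to the residue's heavy atoms (restraints in this pipeline
are heavy-atom based); ``"H|N"`` is a priority list — the first name present
in the residue is used; a plain name matches exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError, ParseError
from .structure import Structure

Selection = tuple[tuple[str, int, str], ...]

#: default weights per restraint source; STD restraints are sparse and
#: high-confidence, hence the heavier weight.
DEFAULT_SOURCE_WEIGHTS = {"CSP": 1.0, "PRE": 1.0, "STD": 2.0, "manual": 1.0}


@dataclass(frozen=True)
class Restraint:
    kind: str                      # "ambiguous" | "unambiguous"
    selection_a: Selection | None
    selection_b: Selection | None
    d_target: float | None = None
    d_lower: float | None = None
    d_upper: float | None = None
    weight: float = 1.0
    source: str = "manual"         # CSP | PRE | STD | manual
    aggregate: str = "r6"          # "r6" | "min"

    def __post_init__(self):
        if self.kind not in ("ambiguous", "unambiguous"):
            raise DataError(f"unknown restraint kind {self.kind!r}")
        if self.aggregate not in ("r6", "min"):
            raise DataError(f"unknown aggregation {self.aggregate!r}")
        if self.d_lower is None and self.d_upper is None:
            raise DataError("restraint needs at least one bound")
        lo = self.d_lower if self.d_lower is not None else -np.inf
        hi = self.d_upper if self.d_upper is not None else np.inf
        tgt = self.d_target if self.d_target is not None else lo
        if not (lo <= (tgt if self.d_target is not None else hi) <= hi) or lo > hi:
            raise DataError("restraint bounds must satisfy d_lower <= d_target <= d_upper")
        if self.weight < 0:
            raise DataError("restraint weight must be >= 0")
        for sel in (self.selection_a, self.selection_b):
            if sel is not None and len(sel) == 0:
                raise DataError("restraint selections must be non-empty")
        if self.selection_a and self.selection_b:
            chains_a = {c for c, _, _ in self.selection_a}
            chains_b = {c for c, _, _ in self.selection_b}
            if chains_a & chains_b:
                raise DataError("restraint selections must be on different chains")

    @property
    def is_template(self) -> bool:
        """True for bound-only templates (e.g. straight from a PRE ratio)
        whose selections have not been attached yet."""
        return self.selection_a is None or self.selection_b is None

    def with_selections(self, sel_a: Selection, sel_b: Selection) -> "Restraint":
        return replace(self, selection_a=tuple(sel_a), selection_b=tuple(sel_b))


# ---------------------------------------------------------------------------
# Selection resolution and effective distances
# ---------------------------------------------------------------------------

def resolve_selection(structure: Structure, sel: Selection) -> np.ndarray:
    """Resolve a selection to an (n, 3) coordinate array."""
    if sel is None:
        raise DataError("cannot resolve a template restraint (no selections attached)")
    pts: list[np.ndarray] = []
    for chain_id, resid, pattern in sel:
        res = structure.chain(chain_id).residue(resid)
        if pattern == "*":
            pts.extend(a.xyz for a in res.heavy_atoms)
        elif "|" in pattern:
            for name in pattern.split("|"):
                if res.has_atom(name):
                    pts.append(res.atom(name).xyz)
                    break
        else:
            if res.has_atom(pattern):
                pts.append(res.atom(pattern).xyz)
    if not pts:
        raise DataError(f"selection resolved to zero atoms: {sel!r}")
    return np.array(pts)


def effective_distance_from_coords(a: np.ndarray, b: np.ndarray, aggregate: str = "r6") -> float:
    """Aggregate all cross pairs between coordinate sets ``a`` and ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    if aggregate == "min":
        return float(np.sqrt(d2.min()))
    return float(np.sum(d2 ** -3.0) ** (-1.0 / 6.0))


def effective_distance(structure: Structure, r: Restraint) -> float:
    """Effective distance of a restraint in the given (pose-resolved) structure."""
    a = resolve_selection(structure, r.selection_a)
    b = resolve_selection(structure, r.selection_b)
    return effective_distance_from_coords(a, b, r.aggregate)


def restraint_energy(d_eff: float, r: Restraint) -> tuple[float, float]:
    """Flat-bottom quadratic penalty; returns (energy, signed violation in Å)."""
    viol = 0.0
    if r.d_upper is not None and d_eff > r.d_upper:
        viol = d_eff - r.d_upper
    elif r.d_lower is not None and d_eff < r.d_lower:
        viol = r.d_lower - d_eff
    return r.weight * viol * viol, viol


def violation_energy(
    structure: Structure,
    restraints: list[Restraint],
    source_weights: dict[str, float] | None = None,
) -> tuple[float, list[tuple[Restraint, float, float, float]]]:
    """Total flat-bottom quadratic violation energy plus a per-restraint report.

    ``source_weights`` multiplies each restraint's own weight by a factor per
    provenance class.  The report rows are ``(restraint, d_eff, violation,
    energy)`` sorted by decreasing violation.
    """
    sw = source_weights or {}
    total = 0.0
    report = []
    for r in restraints:
        d_eff = effective_distance(structure, r)
        e, viol = restraint_energy(d_eff, r)
        e *= sw.get(r.source, 1.0)
        total += e
        report.append((r, d_eff, viol, e))
    report.sort(key=lambda row: -row[2])
    return total, report


# ---------------------------------------------------------------------------
# Ambiguous interaction restraints from active residue sets
# ---------------------------------------------------------------------------

def exposed_residues(structure: Structure, chain_id: str,
                     neighbor_radius: float = 10.0,
                     percentile: float = 60.0) -> set[int]:
    """Coarse solvent-exposure proxy.

    A residue counts as exposed when its heavy-atom neighbour count within
    ``neighbor_radius`` (excluding its own atoms, over the whole structure)
    falls below the given percentile of its chain.  This is deliberately a
    rough filter — only used to pick passive residues around an interface.
    """
    from scipy.spatial import cKDTree
    all_pts = structure.coords(heavy_only=True)
    tree = cKDTree(all_pts)
    ch = structure.chain(chain_id)
    counts = {}
    for res in ch.residues:
        own_pts = np.array([a.xyz for a in res.heavy_atoms])
        own_tree = cKDTree(own_pts)
        n = 0
        for p in own_pts:
            n += len(tree.query_ball_point(p, neighbor_radius))
            n -= len(own_tree.query_ball_point(p, neighbor_radius))  # exclude own residue
        counts[res.resid] = n
    thresh = float(np.percentile(list(counts.values()), percentile))
    return {rid for rid, n in counts.items() if n < thresh}


def build_air(
    active_a: set[int],
    active_b: set[int],
    structure_a: Structure,
    structure_b: Structure,
    chain_a: str = "A",
    chain_b: str = "B",
    passive_cutoff: float = 6.5,
    d_upper: float = 4.25,
    weight: float | None = None,
) -> list[Restraint]:
    """Ambiguous interaction restraints from active residue sets.

    One AIR per active residue: its heavy atoms against the union of heavy
    atoms of the partner's active plus passive residues, with an effective
    upper bound of ``d_upper`` Å; built symmetrically for both chains.
    Passive residues are exposed residues within ``passive_cutoff`` Å of any
    active residue of the same chain (set ``passive_cutoff=0`` to disable).

    The effective upper bound defaults to 4.25 Å rather than the 2 Å used
    with all-atom selections: with heavy-atom-only (backbone + CB) models
    the r⁻⁶ sum runs over far fewer pairs, and an active residue at the
    edge of a touching interface only reaches an effective distance of
    ~4.1 Å at this atom density.  4.25 Å is the tightest bound a correct
    pose is guaranteed to satisfy.
    """
    if not active_a or not active_b:
        raise DataError("build_air: both active sets must be non-empty")
    w = DEFAULT_SOURCE_WEIGHTS["CSP"] if weight is None else weight

    def _check(structure, chain_id, resids):
        ch = structure.chain(chain_id)
        missing = sorted(r for r in resids if not ch.has_residue(r))
        if missing:
            raise DataError(f"chain {chain_id}: active residues missing from structure: {missing}")

    _check(structure_a, chain_a, active_a)
    _check(structure_b, chain_b, active_b)

    def _passive(structure, chain_id, active):
        if passive_cutoff <= 0:
            return set()
        exposed = exposed_residues(structure, chain_id)
        ch = structure.chain(chain_id)
        act_pts = np.concatenate([
            [a.xyz for a in ch.residue(r).heavy_atoms] for r in sorted(active)
        ])
        passive = set()
        for res in ch.residues:
            if res.resid in active or res.resid not in exposed:
                continue
            pts = np.array([a.xyz for a in res.heavy_atoms])
            d = np.min(np.linalg.norm(pts[:, None, :] - act_pts[None, :, :], axis=-1))
            if d <= passive_cutoff:
                passive.add(res.resid)
        return passive

    passive_a = _passive(structure_a, chain_a, active_a)
    passive_b = _passive(structure_b, chain_b, active_b)
    sel_pool_a: Selection = tuple((chain_a, r, "*") for r in sorted(active_a | passive_a))
    sel_pool_b: Selection = tuple((chain_b, r, "*") for r in sorted(active_b | passive_b))

    airs = []
    for resid in sorted(active_a):
        airs.append(Restraint("ambiguous", ((chain_a, resid, "*"),), sel_pool_b,
                              d_upper=d_upper, weight=w, source="CSP"))
    for resid in sorted(active_b):
        airs.append(Restraint("ambiguous", sel_pool_a, ((chain_b, resid, "*"),),
                              d_upper=d_upper, weight=w, source="CSP"))
    return airs


# ---------------------------------------------------------------------------
# CNS-style .tbl dialect
# ---------------------------------------------------------------------------
#
# Each restraint is written as a metadata comment followed by one assign
# statement:
#
#   ! kind=ambiguous source=CSP weight=1.000 aggregate=r6
#   assign ((segid A and resid 12 and name *)) ((segid B and resid 3 and name *)
#       or (segid B and resid 5 and name *)) 2.000 2.000 0.000
#
# d/dminus/dplus encode target, target-lower and upper-target; bound-only
# restraints use d=bound with dminus=d (upper only) or dplus=9999 (lower
# only).  Distances are written with three decimals, so restraints built by
# this package (which round to 1e-3) round-trip exactly.

_LOWER_ONLY_SENTINEL = 9999.0


def _encode_bounds(r: Restraint) -> tuple[float, float, float]:
    if r.d_target is not None:
        lo = r.d_lower if r.d_lower is not None else r.d_target
        hi = r.d_upper if r.d_upper is not None else r.d_target
        return r.d_target, r.d_target - lo, hi - r.d_target
    if r.d_upper is not None and r.d_lower is None:
        return r.d_upper, r.d_upper, 0.0
    if r.d_lower is not None and r.d_upper is None:
        return r.d_lower, 0.0, _LOWER_ONLY_SENTINEL
    return r.d_upper, r.d_upper - r.d_lower, 0.0


def _decode_bounds(d: float, dminus: float, dplus: float):
    # returns (d_target, d_lower, d_upper)
    if dplus == _LOWER_ONLY_SENTINEL:
        return None, d, None
    if dminus == d and dplus == 0.0:
        return None, None, d
    if dminus == 0.0 and dplus == 0.0:
        return d, d, d
    return d, d - dminus, d + dplus


def _sel_to_cns(sel: Selection) -> str:
    parts = [f"(segid {c} and resid {r} and name {p})" for c, r, p in sel]
    return "(" + " or ".join(parts) + ")"


_SEL_ITEM_RE = re.compile(r"\(\s*segid\s+(\S+)\s+and\s+resid\s+(\d+)\s+and\s+name\s+(\S+?)\s*\)")
_META_RE = re.compile(r"^!\s*kind=(\S+)\s+source=(\S+)\s+weight=(\S+)\s+aggregate=(\S+)")


def write_tbl(restraints: list[Restraint], path) -> None:
    lines = []
    for r in restraints:
        if r.is_template:
            raise DataError("cannot write a template restraint (selections missing)")
        d, dminus, dplus = _encode_bounds(r)
        lines.append(f"! kind={r.kind} source={r.source} weight={r.weight:.3f} aggregate={r.aggregate}")
        lines.append(
            f"assign {_sel_to_cns(r.selection_a)} {_sel_to_cns(r.selection_b)} "
            f"{d:.3f} {dminus:.3f} {dplus:.3f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_tbl(path) -> list[Restraint]:
    restraints = []
    meta = {"kind": "unambiguous", "source": "manual", "weight": 1.0, "aggregate": "r6"}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = _META_RE.match(line)
            if m:
                meta = {"kind": m.group(1), "source": m.group(2),
                        "weight": float(m.group(3)), "aggregate": m.group(4)}
                continue
            if line.startswith("!"):
                continue
            if not line.startswith("assign"):
                raise ParseError(f"{path}: line {lineno}: expected an assign statement")
            body = line[len("assign"):].strip()
            # split the two top-level selection groups
            groups, depth, start = [], 0, None
            for i, ch in enumerate(body):
                if ch == "(":
                    if depth == 0:
                        start = i
                    depth += 1
                elif ch == ")":
                    depth -= 1
                    if depth == 0:
                        groups.append(body[start:i + 1])
                        if len(groups) == 2:
                            tail = body[i + 1:].split()
                            break
            if len(groups) != 2 or len(tail) < 3:
                raise ParseError(f"{path}: line {lineno}: malformed assign statement")
            try:
                d, dminus, dplus = (float(x) for x in tail[:3])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: malformed distances") from None
            sels = []
            for g in groups:
                items = _SEL_ITEM_RE.findall(g)
                if not items:
                    raise ParseError(f"{path}: line {lineno}: empty selection")
                sels.append(tuple((c, int(r), p) for c, r, p in items))
            d_target, d_lower, d_upper = _decode_bounds(d, dminus, dplus)
            restraints.append(Restraint(
                meta["kind"], sels[0], sels[1],
                d_target=d_target, d_lower=d_lower, d_upper=d_upper,
                weight=meta["weight"], source=meta["source"], aggregate=meta["aggregate"],
            ))
            meta = {"kind": "unambiguous", "source": "manual", "weight": 1.0, "aggregate": "r6"}
    return restraints


def write_restraints_json(restraints: list[Restraint], path) -> None:
    """Dump restraints as JSON (a transparent alternative to the .tbl dialect)."""
    import json
    payload = [{
        "kind": r.kind, "source": r.source, "weight": r.weight,
        "aggregate": r.aggregate,
        "selection_a": [list(s) for s in (r.selection_a or [])],
        "selection_b": [list(s) for s in (r.selection_b or [])],
        "d_target": r.d_target, "d_lower": r.d_lower, "d_upper": r.d_upper,
    } for r in restraints]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_restraints_json(path) -> list[Restraint]:
    import json
    with open(path) as fh:
        payload = json.load(fh)
    return [Restraint(
        kind=e["kind"], source=e["source"], weight=e["weight"],
        aggregate=e["aggregate"],
        selection_a=tuple((c, int(r), p) for c, r, p in e["selection_a"]) or None,
        selection_b=tuple((c, int(r), p) for c, r, p in e["selection_b"]) or None,
        d_target=e["d_target"], d_lower=e["d_lower"], d_upper=e["d_upper"],
    ) for e in payload]
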