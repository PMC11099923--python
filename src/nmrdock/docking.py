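"""Restraint-guided rigid-body docking with score/Z-score model selection.

This engine is a deliberately simplified, fully deterministic stand-in for
the large data-driven docking programs used in practice.  It keeps their
decision surface — restraint violation energies, a soft-sphere clash term,
a composite score, Z-scores over the generated ensemble, clustering and
ranked selection, and a configurable number of rigid-body minimisation
trials — and drops flexible refinement, solvation and molecular-dynamics
stages.  The receptor stays fixed in its own frame; only the ligand moves.

Stages:

1. uniform orientation sampling on SO(3) (Shoemake quaternions);
2. initial placement of the ligand centroid on a sphere around the
   receptor's restraint-active atoms;
3. per-pose derivative-free local minimisation of the score over the six
   rigid-body degrees of freedom, restarted from several jittered copies
   ("trials");
4. scoring, Z-scoring, single-linkage clustering on ligand RMSD, and
   deterministic ranked selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DataError, NumericError
from .restraints import Restraint
from .structure import RigidTransform, Structure, radius_of_gyration

#: van der Waals radii (Å) for the soft-sphere clash score.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8, "H": 1.1}
VDW_DEFAULT = 1.7
#: overlap softening factor: pairs only clash below 0.8 x (r_i + r_j).
CLASH_SOFTENING = 0.8


def _rotvec_matrix(rv: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrix for a rotation vector (cheap hot-loop path)."""
    theta = float(np.linalg.norm(rv))
    if theta < 1e-12:
        return np.eye(3)
    k = rv / theta
    K = np.array([[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]])
    return np.eye(3) + math.sin(theta) * K + (1.0 - math.cos(theta)) * (K @ K)


@dataclass(frozen=True)
class DockWeights:
    w_air: float = 1.0
    w_pre: float = 1.0
    w_std: float = 2.0
    w_clash: float = 0.01


@dataclass(frozen=True)
class DockParams:
    n_orient: int = 200
    trials: int = 10
    search_iters: int = 20
    refine_top: int = 20           # poses re-minimised with the fine schedule
    refine_iters: int = 60
    jitter_t: float = 2.0          # Å, trial-restart translation jitter
    jitter_rot_deg: float = 8.0    # deg, trial-restart rotation jitter
    placement_offset: float = 5.0  # Å added to the sum of radii of gyration
    cluster_cutoff: float = 5.0    # Å, single-linkage ligand-RMSD cutoff
    top_n: int = 10
    weights: DockWeights = field(default_factory=DockWeights)


@dataclass
class Pose:
    """A scored docked configuration of the ligand."""

    index: int
    transform: RigidTransform
    e_air: float = math.nan
    e_pre: float = math.nan
    e_std: float = math.nan
    e_clash: float = math.nan
    score: float = math.nan
    z_score: float | None = None
    cluster_id: int | None = None

    @property
    def energies(self) -> dict[str, float]:
        return {"e_air": self.e_air, "e_pre": self.e_pre,
                "e_std": self.e_std, "e_clash": self.e_clash}


# ---------------------------------------------------------------------------
# Orientation sampling
# ---------------------------------------------------------------------------

def sample_orientations(n: int, seed) -> np.ndarray:
    """``n`` unit quaternions (scalar-first) uniform on SO(3), Shoemake's map.

    ``seed`` may be an int or a ``numpy.random.Generator``; a fixed seed
    gives identical output.
    """
    if n < 1:
        raise DataError("sample_orientations: n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u1, u2, u3 = rng.random((3, n))
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    q = np.stack([
        b * np.cos(2 * np.pi * u3),   # w
        a * np.sin(2 * np.pi * u2),   # x
        a * np.cos(2 * np.pi * u2),   # y
        b * np.sin(2 * np.pi * u3),   # z
    ], axis=1)
    return q / np.linalg.norm(q, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Clash score
# ---------------------------------------------------------------------------

def _heavy_coords_radii(s: Structure, chain_id: str | None = None):
    pts, radii = [], []
    for _, _, a in s.atoms(chain_id, heavy_only=True):
        pts.append(a.xyz)
        radii.append(VDW_RADII.get(a.element, VDW_DEFAULT))
    return np.array(pts), np.array(radii)


def _clash_from_arrays(pa, ra, pb, rb, tree_a: cKDTree | None = None) -> float:
    if len(pa) == 0 or len(pb) == 0:
        return 0.0
    cutoff = CLASH_SOFTENING * (ra.max() + rb.max())
    tree = tree_a if tree_a is not None else cKDTree(pa)
    hits = tree.query_ball_point(pb, cutoff)
    e = 0.0
    for j, idx in enumerate(hits):
        if not idx:
            continue
        d = np.linalg.norm(pa[idx] - pb[j], axis=1)
        overlap = CLASH_SOFTENING * (ra[idx] + rb[j]) - d
        overlap[overlap < 0] = 0.0
        e += float(np.sum(overlap**2))
    return e


def clash_score(receptor: Structure, ligand: Structure) -> float:
    """Soft-sphere overlap energy between the heavy atoms of two structures."""
    pa, ra = _heavy_coords_radii(receptor)
    pb, rb = _heavy_coords_radii(ligand)
    return _clash_from_arrays(pa, ra, pb, rb)


def clash_score_bruteforce(receptor: Structure, ligand: Structure) -> float:
    """Reference double-loop implementation (test oracle for the tree version)."""
    pa, ra = _heavy_coords_radii(receptor)
    pb, rb = _heavy_coords_radii(ligand)
    e = 0.0
    for i in range(len(pa)):
        for j in range(len(pb)):
            d = float(np.linalg.norm(pa[i] - pb[j]))
            overlap = CLASH_SOFTENING * (ra[i] + rb[j]) - d
            if overlap > 0:
                e += overlap * overlap
    return e


# ---------------------------------------------------------------------------
# Engine: precompiled state for fast scoring
# ---------------------------------------------------------------------------

class DockingEngine:
    """Receptor, ligand and restraints compiled into flat arrays.

    The receptor chain is fixed at its input frame; poses transform the
    ligand's original coordinates.  Restraint selections are resolved to
    atom-index arrays once, so a score evaluation is a handful of small
    vectorised distance computations.
    """

    def __init__(self, receptor: Structure, ligand: Structure,
                 restraints: list[Restraint],
                 params: DockParams | None = None):
        if len(receptor.chains) != 1 or len(ligand.chains) != 1:
            raise DataError("DockingEngine expects single-chain receptor and ligand structures")
        self.receptor = receptor
        self.ligand = ligand
        self.params = params or DockParams()
        self.restraints = list(restraints)
        self.rec_chain = receptor.chains[0].chain_id
        self.lig_chain = ligand.chains[0].chain_id

        def _flatten(s: Structure):
            pts, names, radii, heavy = [], [], [], []
            lookup: dict[tuple[int, str], int] = {}
            residue_atoms: dict[int, list[int]] = {}
            resid_of = []
            for _, res, a in s.atoms():
                i = len(pts)
                pts.append(a.xyz)
                names.append(a.name)
                radii.append(VDW_RADII.get(a.element, VDW_DEFAULT))
                heavy.append(a.is_heavy)
                lookup[(res.resid, a.name)] = i
                residue_atoms.setdefault(res.resid, []).append(i)
                resid_of.append(res.resid)
            return (np.array(pts), names, np.array(radii), np.array(heavy),
                    lookup, residue_atoms, np.array(resid_of))

        (self.rec_xyz, self._rec_names, self.rec_radii, self.rec_heavy,
         self._rec_lookup, self._rec_res_atoms, self.rec_resid_of) = _flatten(receptor)
        (self.lig_xyz0, self._lig_names, self.lig_radii, self.lig_heavy,
         self._lig_lookup, self._lig_res_atoms, self.lig_resid_of) = _flatten(ligand)
        self._rec_tree_heavy = cKDTree(self.rec_xyz[self.rec_heavy])
        self._rec_radii_heavy = self.rec_radii[self.rec_heavy]
        self.lig_centroid0 = self.lig_xyz0[self.lig_heavy].mean(axis=0)

        self._compiled = [self._compile_restraint(r) for r in self.restraints]
        self._build_batches()
        self._clash_cutoff = CLASH_SOFTENING * (
            (self._rec_radii_heavy.max() if len(self._rec_radii_heavy) else 0.0)
            + (self.lig_radii[self.lig_heavy].max() if self.lig_heavy.any() else 0.0)
        )

    # -- compilation --------------------------------------------------------
    def _resolve_indices(self, s: Structure, lookup, res_atoms, heavy, sel):
        idx: list[int] = []
        for chain_id, resid, pattern in sel:
            if resid not in res_atoms:
                raise DataError(f"restraint references missing residue {chain_id}/{resid}")
            if pattern == "*":
                idx.extend(i for i in res_atoms[resid] if heavy[i])
            elif "|" in pattern:
                for name in pattern.split("|"):
                    if (resid, name) in lookup:
                        idx.append(lookup[(resid, name)])
                        break
            else:
                if (resid, pattern) in lookup:
                    idx.append(lookup[(resid, pattern)])
        if not idx:
            raise DataError(f"selection resolved to zero atoms: {sel!r}")
        return np.array(idx, dtype=np.intp)

    def _compile_restraint(self, r: Restraint):
        if r.is_template:
            raise DataError("docking received a template restraint without selections")
        chains_a = {c for c, _, _ in r.selection_a}
        if chains_a == {self.rec_chain}:
            sel_rec, sel_lig = r.selection_a, r.selection_b
        elif chains_a == {self.lig_chain}:
            sel_rec, sel_lig = r.selection_b, r.selection_a
        else:
            raise DataError(f"restraint selections do not match chains "
                            f"{self.rec_chain}/{self.lig_chain}: {r!r}")
        ri = self._resolve_indices(self.receptor, self._rec_lookup,
                                   self._rec_res_atoms, self.rec_heavy, sel_rec)
        li = self._resolve_indices(self.ligand, self._lig_lookup,
                                   self._lig_res_atoms, self.lig_heavy, sel_lig)
        lo = -np.inf if r.d_lower is None else r.d_lower
        hi = np.inf if r.d_upper is None else r.d_upper
        bucket = {"CSP": "e_air", "PRE": "e_pre", "STD": "e_std"}.get(r.source, "e_air")
        return (ri, li, r.aggregate, lo, hi, r.weight, bucket)

    def _build_batches(self) -> None:
        """Flatten all restraints into shared index arrays so one score
        evaluation is a single vectorised gather instead of a Python loop."""
        rp, lp, rid = [], [], []
        self._r_lo = np.empty(len(self._compiled))
        self._r_hi = np.empty(len(self._compiled))
        self._r_w = np.empty(len(self._compiled))
        self._r_is_min = np.zeros(len(self._compiled), dtype=bool)
        buckets = {"e_air": [], "e_pre": [], "e_std": []}
        for k, (ri, li, aggregate, lo, hi, w, bucket) in enumerate(self._compiled):
            pairs_r = np.repeat(ri, len(li))
            pairs_l = np.tile(li, len(ri))
            rp.append(pairs_r)
            lp.append(pairs_l)
            rid.append(np.full(len(pairs_r), k, dtype=np.intp))
            self._r_lo[k], self._r_hi[k], self._r_w[k] = lo, hi, w
            self._r_is_min[k] = aggregate == "min"
            buckets[bucket].append(k)
        self._pair_r = np.concatenate(rp) if rp else np.empty(0, dtype=np.intp)
        self._pair_l = np.concatenate(lp) if lp else np.empty(0, dtype=np.intp)
        self._pair_id = np.concatenate(rid) if rid else np.empty(0, dtype=np.intp)
        # pairs are laid out restraint-by-restraint: reduceat block starts
        counts = np.array([len(r) for r in rp], dtype=np.intp)
        self._block_starts = np.concatenate([[0], np.cumsum(counts)[:-1]]) if rp else np.empty(0, dtype=np.intp)
        self._bucket_masks = {}
        for name, ks in buckets.items():
            m = np.zeros(len(self._compiled), dtype=bool)
            m[ks] = True
            self._bucket_masks[name] = m
        self._rec_pair_xyz = self.rec_xyz[self._pair_r]

    # -- evaluation ---------------------------------------------------------
    def ligand_coords(self, transform: RigidTransform) -> np.ndarray:
        return self.lig_xyz0 @ transform.matrix.T + transform.t

    def _energies_from_coords(self, lig: np.ndarray) -> dict[str, float]:
        e = {"e_air": 0.0, "e_pre": 0.0, "e_std": 0.0, "e_clash": 0.0}
        n_r = len(self._compiled)
        if n_r:
            diff = self._rec_pair_xyz - lig[self._pair_l]
            d2 = np.einsum("ij,ij->i", diff, diff)
            inv = 1.0 / d2
            inv6 = np.add.reduceat(inv * inv * inv, self._block_starts)
            d_eff = inv6 ** (-1.0 / 6.0)
            if self._r_is_min.any():
                dmin2 = np.minimum.reduceat(d2, self._block_starts)
                d_eff = np.where(self._r_is_min, np.sqrt(dmin2), d_eff)
            viol = np.maximum(d_eff - self._r_hi, 0.0) + np.maximum(self._r_lo - d_eff, 0.0)
            energies = self._r_w * viol * viol
            for name, mask in self._bucket_masks.items():
                e[name] = float(energies[mask].sum())
        e["e_clash"] = self._clash(lig[self.lig_heavy])
        return e

    def _clash(self, lig_heavy: np.ndarray, k: int = 16) -> float:
        """Soft-sphere overlap vs the receptor; exact (falls back to an
        unbounded neighbour query for the rare atom with > k contacts)."""
        dist, idx = self._rec_tree_heavy.query(
            lig_heavy, k=k, distance_upper_bound=self._clash_cutoff)
        finite = np.isfinite(dist)
        if not finite.any():
            return 0.0
        ra = np.where(finite, self._rec_radii_heavy[np.where(finite, idx, 0)], 0.0)
        rb = self.lig_radii[self.lig_heavy][:, None]
        overlap = np.where(finite, CLASH_SOFTENING * (ra + rb) - dist, 0.0)
        overlap[overlap < 0.0] = 0.0
        ec = float(np.sum(overlap**2))
        truncated = np.flatnonzero(finite[:, k - 1])
        for j in truncated:  # k-th neighbour still in range: redo exactly
            hits = self._rec_tree_heavy.query_ball_point(lig_heavy[j], self._clash_cutoff)
            d = np.linalg.norm(self.rec_xyz[self.rec_heavy][hits] - lig_heavy[j], axis=1)
            ov = CLASH_SOFTENING * (self._rec_radii_heavy[hits]
                                    + self.lig_radii[self.lig_heavy][j]) - d
            ov[ov < 0] = 0.0
            ec += float(np.sum(ov**2)) - float(np.sum(overlap[j] ** 2))
        return ec

    def _score_from_energies(self, e: dict[str, float], w: DockWeights) -> float:
        return (w.w_air * e["e_air"] + w.w_pre * e["e_pre"]
                + w.w_std * e["e_std"] + w.w_clash * e["e_clash"])

    def score_pose(self, pose: Pose, weights: DockWeights | None = None) -> Pose:
        """Fill in the energy components and the composite score."""
        w = weights or self.params.weights
        e = self._energies_from_coords(self.ligand_coords(pose.transform))
        return replace(pose, score=self._score_from_energies(e, w), **e)

    def _objective(self, Rm: np.ndarray, t: np.ndarray, w: DockWeights) -> float:
        lig = self.lig_xyz0 @ Rm.T + t
        return self._score_from_energies(self._energies_from_coords(lig), w)

    def _make_fast_objective(self, w: DockWeights):
        """Scalar objective closure with bucket weights folded into one vector."""
        bucket_w = {"e_air": w.w_air, "e_pre": w.w_pre, "e_std": w.w_std}
        cw = self._r_w.copy()
        for name, mask in self._bucket_masks.items():
            cw[mask] *= bucket_w[name]
        starts, is_min = self._block_starts, self._r_is_min
        any_min = bool(is_min.any())
        rec_pair, pair_l = self._rec_pair_xyz, self._pair_l
        lo, hi, base = self._r_lo, self._r_hi, self.lig_xyz0
        heavy = self.lig_heavy
        w_clash = w.w_clash

        def objective(Rm: np.ndarray, t: np.ndarray) -> float:
            lig = base @ Rm.T + t
            diff = rec_pair - lig[pair_l]
            d2 = np.einsum("ij,ij->i", diff, diff)
            inv = 1.0 / d2
            d_eff = np.add.reduceat(inv * inv * inv, starts) ** (-1.0 / 6.0)
            if any_min:
                d_eff = np.where(is_min, np.sqrt(np.minimum.reduceat(d2, starts)), d_eff)
            viol = np.maximum(d_eff - hi, 0.0) + np.maximum(lo - d_eff, 0.0)
            s = float(cw @ (viol * viol))
            if w_clash:
                s += w_clash * self._clash(lig[heavy])
            return s

        return objective

    # -- placement ----------------------------------------------------------
    def restraint_center(self) -> np.ndarray:
        """Centroid of the receptor atoms referenced by any restraint."""
        idx = np.unique(np.concatenate([ri for ri, *_ in self._compiled]))
        return self.rec_xyz[idx].mean(axis=0)

    def initial_placements(self, n_orient: int | None = None, seed=0) -> list[Pose]:
        """One pose per sampled orientation, ligand centroid on a sphere of
        radius Rg(receptor) + Rg(ligand) + offset around the restraint center."""
        if not self._compiled:
            raise DataError("initial_placements: unguided docking is not supported "
                            "(no restraints)")
        n = n_orient if n_orient is not None else self.params.n_orient
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        quats = sample_orientations(n, rng)
        center = self.restraint_center()
        radius = (radius_of_gyration(self.rec_xyz[self.rec_heavy])
                  + radius_of_gyration(self.lig_xyz0[self.lig_heavy])
                  + self.params.placement_offset)
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        poses = []
        for i in range(n):
            Rm = Rotation.from_quat(quats[i], scalar_first=True).as_matrix()
            # back out along the placement direction until clash-free: the
            # receptor is rarely spherical, so a fixed radius can intersect it
            for extra in range(0, 40, 2):
                target = center + (radius + extra) * dirs[i]
                t = target - Rm @ self.lig_centroid0
                if self._clash((self.lig_xyz0 @ Rm.T + t)[self.lig_heavy]) == 0.0:
                    break
            poses.append(Pose(i, RigidTransform.from_quat(quats[i], t)))
        return poses

    # -- minimisation -------------------------------------------------------
    def minimize_pose(self, pose: Pose, trials: int | None = None, seed=0,
                      weights: DockWeights | None = None,
                      n_iter: int | None = None,
                      sig_t0: float = 2.0, sig_r0_deg: float = 12.0,
                      approach: bool = True) -> Pose:
        """Derivative-free local search over the six rigid-body DOF.

        A translation line search toward the restraint center is followed by
        ``trials`` greedy random-search restarts from jittered copies
        (2 Å / 8° by default); the best pose found is returned and is never
        worse than the input.
        """
        p = self.params
        w = weights or p.weights
        n_trials = trials if trials is not None else p.trials
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        obj = self._make_fast_objective(w)
        Rm0 = pose.transform.matrix
        t0 = pose.transform.t.copy()
        s0 = obj(Rm0, t0)
        if not np.isfinite(s0):
            raise NumericError("minimize_pose: non-finite score at the start pose")

        # stage 1: slide the ligand toward the restraint-active center
        best_t, best_s = t0, s0
        if approach:
            center = self.restraint_center()
            lig_c = Rm0 @ self.lig_centroid0 + t0
            step = center - lig_c
            for frac in np.linspace(0.0, 1.0, 9)[1:]:
                t_try = t0 + frac * step
                s_try = obj(Rm0, t_try)
                if s_try < best_s:
                    best_t, best_s = t_try, s_try
        start = (Rm0, best_t, best_s)

        jr = math.radians(p.jitter_rot_deg)
        n_iter = n_iter if n_iter is not None else p.search_iters
        decay = (0.05) ** (1.0 / max(n_iter - 1, 1))  # search scales shrink 20x
        sig_t = sig_t0 * decay ** np.arange(n_iter)
        sig_r = math.radians(sig_r0_deg) * decay ** np.arange(n_iter)
        overall = start
        for trial in range(max(n_trials, 1)):
            Rm, t, s = start
            if trial > 0:  # jittered restart
                rv = rng.normal(size=3)
                rv *= jr * abs(rng.normal()) / max(np.linalg.norm(rv), 1e-12)
                Rd = _rotvec_matrix(rv)
                c = Rm @ self.lig_centroid0 + t
                Rm = Rd @ Rm
                t = Rd @ (t - c) + c + rng.normal(scale=p.jitter_t, size=3)
                s = obj(Rm, t)
            rot_noise = rng.normal(size=(n_iter, 3)) * sig_r[:, None]
            tr_noise = rng.normal(size=(n_iter, 3)) * sig_t[:, None]
            for i in range(n_iter):
                Rd = _rotvec_matrix(rot_noise[i])
                c = Rm @ self.lig_centroid0 + t
                R_try = Rd @ Rm
                t_try = Rd @ (t - c) + c + tr_noise[i]
                s_try = obj(R_try, t_try)
                if s_try < s:
                    Rm, t, s = R_try, t_try, s_try
            if s < overall[2]:
                overall = (Rm, t, s)

        Rm, t, s = overall
        if s > s0:  # guard: never return worse than the input
            Rm, t, s = Rm0, t0, s0
        q = Rotation.from_matrix(Rm).as_quat(scalar_first=True)
        out = Pose(pose.index, RigidTransform.from_quat(q, t))
        return self.score_pose(out, w)

    # -- ranking ------------------------------------------------------------
    def ligand_rmsd(self, a: Pose | RigidTransform, b: Pose | RigidTransform,
                    atom_idx: np.ndarray | None = None) -> float:
        """RMSD between two poses of the ligand, in the fixed receptor frame."""
        ta = a.transform if isinstance(a, Pose) else a
        tb = b.transform if isinstance(b, Pose) else b
        idx = atom_idx if atom_idx is not None else np.flatnonzero(self.lig_heavy)
        ca = self.ligand_coords(ta)[idx]
        cb = self.ligand_coords(tb)[idx]
        return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))

    def interface_atom_idx(self, pose: Pose, cutoff: float = 10.0) -> np.ndarray:
        """Heavy-atom indices of ligand residues near the receptor in a pose."""
        lig = self.ligand_coords(pose.transform)
        heavy_idx = np.flatnonzero(self.lig_heavy)
        d, _ = self._rec_tree_heavy.query(lig[heavy_idx])
        resids = set(self.lig_resid_of[heavy_idx[d < cutoff]])
        if not resids:
            return heavy_idx
        mask = np.isin(self.lig_resid_of, list(resids)) & self.lig_heavy
        return np.flatnonzero(mask)

    def rank_select(self, poses: list[Pose], top_n: int | None = None) -> list[Pose]:
        """Z-score, cluster and rank an ensemble of scored poses.

        Z-scores standardise the composite score over the whole ensemble
        (sample standard deviation; all zero when scores are identical).
        Clustering is single linkage on pairwise ligand-interface RMSD at
        the configured cutoff, with the interface taken from the
        best-scoring pose.  The returned list is ordered by score ascending
        with deterministic tie-breaking (lower e_air, then lower index).
        """
        if len(poses) < 2:
            raise DataError("rank_select: need at least 2 scored poses")
        scores = np.array([p.score for p in poses])
        sd = scores.std(ddof=1)
        z = np.zeros_like(scores) if sd == 0 else (scores - scores.mean()) / sd

        best = poses[int(np.argmin(scores))]
        idx = self.interface_atom_idx(best)
        coords = np.stack([self.ligand_coords(p.transform)[idx] for p in poses])
        n = len(poses)
        condensed = []
        for i in range(n - 1):
            diff = coords[i + 1:] - coords[i]
            condensed.append(np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1)))
        labels = fcluster(linkage(np.concatenate(condensed), method="single"),
                          t=self.params.cluster_cutoff, criterion="distance")
        ranked = [replace(p, z_score=float(z[i]), cluster_id=int(labels[i]))
                  for i, p in enumerate(poses)]
        ranked.sort(key=lambda p: (p.score, p.e_air, p.index))
        k = top_n if top_n is not None else self.params.top_n
        return ranked[:k]


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass
class DockResult:
    ranked: list[Pose]          # top_n poses, best first
    all_poses: list[Pose]       # full minimised ensemble (scored, z, clusters)
    cluster_sizes: dict[int, int]
    engine: DockingEngine


def dock(receptor: Structure, ligand: Structure, restraints: list[Restraint],
         params: DockParams | None = None, seed: int = 0) -> DockResult:
    """Run the full docking protocol; fully deterministic for a fixed seed."""
    params = params or DockParams()
    engine = DockingEngine(receptor, ligand, restraints, params)
    ss = np.random.SeedSequence(seed)
    place_rng, *trial_seeds = ss.spawn(1 + params.n_orient + params.refine_top)
    poses = engine.initial_placements(params.n_orient, np.random.default_rng(place_rng))
    minimized = [
        engine.minimize_pose(pose, seed=np.random.default_rng(trial_seeds[i]))
        for i, pose in enumerate(poses)
    ]
    # second stage: polish the best-scoring poses with a finer schedule
    if params.refine_top > 0:
        order = sorted(range(len(minimized)), key=lambda i: minimized[i].score)
        for j, i in enumerate(order[:params.refine_top]):
            minimized[i] = engine.minimize_pose(
                minimized[i],
                seed=np.random.default_rng(trial_seeds[params.n_orient + j]),
                n_iter=params.refine_iters, sig_t0=1.0, sig_r0_deg=6.0,
                approach=False)
    ranked_all = engine.rank_select(minimized, top_n=len(minimized))
    sizes: dict[int, int] = {}
    for p in ranked_all:
        sizes[p.cluster_id] = sizes.get(p.cluster_id, 0) + 1
    return DockResult(ranked_all[:params.top_n], ranked_all, sizes, engine)


def rescore_by_clash(result: DockResult) -> list[Pose]:
    """Restraint-free control: rank the same minimised ensemble by the clash
    term alone (ties by pose index)."""
    w = DockWeights(w_air=0.0, w_pre=0.0, w_std=0.0, w_clash=1.0)
    rescored = [result.engine.score_pose(p, w) for p in result.all_poses]
    rescored.sort(key=lambda p: (p.score, p.index))
    return rescored
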