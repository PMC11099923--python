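"""Synthetic ground truth: a toy two-chain complex and simulated NMR data.

The generator stands in for the real receptor/adaptor system: a three-helix
bundle (receptor, chain A) presents one outward helix face to a small mixed
α/β domain (ligand, chain B) built from ideal secondary-structure
templates.  The bound pose is the construction itself, so the true
interface, an engineered Lys–Asp salt bridge, spin-label sites (Cys SG) and
a saturation-source amide are all known exactly, and every simulated
observable (CSP, PRE, STD peak lists) is generated by the same forward
models the analysis modules invert.

Only backbone atoms (N, CA, C, O) plus CB are built; side chains beyond CB
exist solely where the pipeline needs them (bridge NZ/OD1/OD2, labelled-Cys
SG).  Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GenerationError
from .peaklist import Peak, PeakList
from .pre import PREParameters, ratio_from_distance
from .structure import (AA3TO1, Atom, Chain, Residue, Structure,
                        interface_residues)

# ideal backbone internal coordinates
_BOND_N_CA, _BOND_CA_C, _BOND_C_N, _BOND_C_O, _BOND_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O, _ANG_N_CA_CB = 111.2, 116.2, 121.7, 120.5, 110.5
_HELIX_PHI_PSI = (-57.0, -47.0)
_STRAND_PHI_PSI = (-119.0, 113.0)


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement: position bonded to ``c`` with given internal coords."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang, dih = math.radians(angle_deg), math.radians(dihedral_deg)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(dih),
                  bond * math.sin(ang) * math.sin(dih)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(n_res: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry poly-residue backbone (N, CA, C, O, CB) at fixed φ/ψ."""
    res: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANG_N_CA_C)
    C = CA + _BOND_CA_C * np.array([math.cos(math.pi - ang),
                                    math.sin(math.pi - ang), 0.0])
    res.append({"N": N, "CA": CA, "C": C})
    for _ in range(1, n_res):
        prev = res[-1]
        Nn = _place_atom(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANG_CA_C_N, psi)
        CAn = _place_atom(prev["CA"], prev["C"], Nn, _BOND_N_CA, _ANG_C_N_CA, 180.0)
        Cn = _place_atom(prev["C"], Nn, CAn, _BOND_CA_C, _ANG_N_CA_C, phi)
        res.append({"N": Nn, "CA": CAn, "C": Cn})
    for i, r in enumerate(res):
        nxt_psi = psi
        r["O"] = _place_atom(r["N"], r["CA"], r["C"], _BOND_C_O, _ANG_CA_C_O, nxt_psi + 180.0)
        r["CB"] = _place_atom(r["C"], r["N"], r["CA"], _BOND_CA_CB, _ANG_N_CA_CB, 122.6)
    return res


def _principal_axis(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    axis = vt[0]
    # orient along increasing residue order
    if np.dot(points[-1] - points[0], axis) < 0:
        axis = -axis
    return axis


def _orient_along(template: list[dict], target_axis: np.ndarray) -> list[dict]:
    """Rotate a built segment so its CA principal axis matches target_axis,
    and centre it at the origin."""
    ca = np.array([r["CA"] for r in template])
    axis = _principal_axis(ca)
    rot, _ = Rotation.align_vectors(np.atleast_2d(target_axis), np.atleast_2d(axis))
    Rm = rot.as_matrix()
    centre = ca.mean(axis=0)
    return [{k: Rm @ (v - centre) for k, v in r.items()} for r in template]


def _segment_to_residues(segment, start_resid, resname="ALA") -> list[Residue]:
    out = []
    for i, r in enumerate(segment):
        atoms = [Atom(name, "C" if name.startswith("C") else name[0], xyz.copy())
                 for name, xyz in r.items()]
        out.append(Residue(start_resid + i, resname, atoms))
    return out


def _apply(residues: list[Residue], Rm: np.ndarray, t: np.ndarray) -> None:
    for res in residues:
        for a in res.atoms:
            a.xyz = Rm @ a.xyz + t


AA1TO3 = {v: k for k, v in AA3TO1.items()}


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """The toy complex in its true pose plus everything the tests need."""

    structure: Structure
    chain_receptor: str
    chain_ligand: str
    interface_receptor: set[int]
    interface_ligand: set[int]
    bridge: tuple[int, int]                       # (receptor LYS, ligand ASP)
    label_resids: tuple[int, ...]                 # ligand CYS resids carrying SG
    source_atom: tuple[str, int, str]             # saturation source selection
    min_dist_to_partner: dict[str, dict[int, float]]   # chain -> resid -> Å
    amide_to_labels: dict[int, float]             # receptor resid -> min Å to SG
    amide_to_source: dict[int, float]             # receptor resid -> Å to source
    params: dict = field(default_factory=dict)
    seed: int = 0

    def receptor(self) -> Structure:
        return self.structure.subset([self.chain_receptor])

    def ligand(self) -> Structure:
        return self.structure.subset([self.chain_ligand])

    def label_selections(self):
        return [(self.chain_ligand, r, "SG") for r in self.label_resids]

    def to_json(self, path) -> None:
        payload = {
            "chain_receptor": self.chain_receptor,
            "chain_ligand": self.chain_ligand,
            "interface_receptor": sorted(self.interface_receptor),
            "interface_ligand": sorted(self.interface_ligand),
            "bridge": list(self.bridge),
            "label_resids": list(self.label_resids),
            "source_atom": list(self.source_atom),
            "min_dist_to_partner": {c: {str(k): v for k, v in d.items()}
                                    for c, d in self.min_dist_to_partner.items()},
            "amide_to_labels": {str(k): v for k, v in self.amide_to_labels.items()},
            "amide_to_source": {str(k): v for k, v in self.amide_to_source.items()},
            "params": self.params,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Complex construction
# ---------------------------------------------------------------------------

def _min_cross_distance(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    from scipy.spatial import cKDTree
    d, _ = cKDTree(pts_a).query(pts_b)
    return float(d.min())


def make_toy_complex(seed: int = 0, receptor_helices: int = 3, helix_len: int = 25,
                     ligand_strands: int = 4, strand_len: int = 12,
                     ligand_helix_len: int = 8, gap: float = 3.0,
                     max_tries: int = 160) -> GroundTruth:
    """Build the toy complex in its bound pose.

    The receptor is an (anti)parallel ``receptor_helices``-helix bundle; the
    ligand is a ``ligand_strands``-stranded sheet with one short helix packed
    on its outer face.  The ligand is pressed onto the outward face of the
    first receptor helix until the closest inter-chain heavy-atom distance
    equals ``gap`` (Å), then accepted if the interface has at least 6
    residues per side at 5 Å, no inter-chain distance below 2.8 Å, and a
    cross-chain amide pair close enough (< 4.6 Å) to act as the
    saturation-transfer anchor.  Placement orientations are retried up to
    ``max_tries`` times before giving up.
    """
    if helix_len < 8:
        raise GenerationError("make_toy_complex: helix_len must be >= 8")
    rng = np.random.default_rng(seed)

    # ---- receptor: helix bundle, axes on a circle, antiparallel -----------
    helix_template = _build_backbone(helix_len, *_HELIX_PHI_PSI)
    bundle_r = 10.5 / math.sqrt(3.0) if receptor_helices == 3 else 10.5 / (
        2.0 * math.sin(math.pi / max(receptor_helices, 2)))
    rec_residues: list[Residue] = []
    helix0_axis_pos = None
    for h in range(receptor_helices):
        ang = math.pi / 2 + 2 * math.pi * h / receptor_helices
        axis_pos = np.array([bundle_r * math.cos(ang), bundle_r * math.sin(ang), 0.0])
        if h == 0:
            helix0_axis_pos = axis_pos
        direction = np.array([0.0, 0.0, 1.0 if h % 2 == 0 else -1.0])
        seg = _orient_along(helix_template, direction)
        residues = _segment_to_residues(seg, h * helix_len + 1)
        _apply(residues, np.eye(3), axis_pos)
        rec_residues.extend(residues)

    outward = helix0_axis_pos / np.linalg.norm(helix0_axis_pos)

    # ---- ligand: sheet + packed helix, built once, oriented per try -------
    strand_template = _build_backbone(strand_len, *_STRAND_PHI_PSI)
    lig_local: list[Residue] = []
    for s in range(ligand_strands):
        seg = _orient_along(strand_template, np.array([1.0, 0.0, 0.0]))
        residues = _segment_to_residues(seg, s * strand_len + 1)
        flip = Rotation.from_euler("z", 180 * (s % 2), degrees=True).as_matrix()
        _apply(residues, flip, np.array([0.0, 4.8 * s, 0.0]))
        lig_local.extend(residues)
    lig_helix = _orient_along(_build_backbone(ligand_helix_len, *_HELIX_PHI_PSI),
                              np.array([1.0, 0.0, 0.0]))
    helix_residues = _segment_to_residues(lig_helix, ligand_strands * strand_len + 1)
    _apply(helix_residues, np.eye(3),
           np.array([0.0, 4.8 * (ligand_strands - 1) / 2.0, 6.0]))
    lig_local.extend(helix_residues)
    sheet_centre = np.concatenate(
        [[a.xyz for a in r.atoms] for r in lig_local]).mean(axis=0)
    for res in lig_local:
        for a in res.atoms:
            a.xyz = a.xyz - sheet_centre

    rec_chain = Chain("A", rec_residues)
    rec_pts = np.array([a.xyz for r in rec_residues for a in r.atoms])

    # rotate ligand local +z (helix side) onto +outward, then spin randomly
    base_rot, _ = Rotation.align_vectors(np.atleast_2d(outward),
                                         np.atleast_2d([0.0, 0.0, 1.0]))

    last_reason = "no attempt"
    for attempt in range(max_tries):
        # stratified spin scan (with per-seed jitter) so every seed explores
        # the whole face of the helix rather than trusting luck
        spin_angle = 2 * math.pi * (attempt + rng.random()) / max_tries
        spin = Rotation.from_rotvec(outward * spin_angle)
        tilt_axis = np.cross(outward, np.array([0.0, 0.0, 1.0]))
        tilt_axis /= np.linalg.norm(tilt_axis)
        tilt = Rotation.from_rotvec(tilt_axis * rng.uniform(-0.35, 0.35))
        Rm = (tilt * spin * base_rot).as_matrix()
        z_shift = rng.uniform(-2.5, 2.5)

        lig_try = [r.copy() for r in lig_local]
        _apply(lig_try, Rm, np.zeros(3))
        lig_pts0 = np.array([a.xyz for r in lig_try for a in r.atoms])

        # slide along `outward` until the closest approach equals `gap`
        base_point = helix0_axis_pos + np.array([0.0, 0.0, z_shift])
        lo_off, hi_off = 0.0, 80.0
        for _ in range(48):
            mid = 0.5 * (lo_off + hi_off)
            d = _min_cross_distance(rec_pts, lig_pts0 + base_point + outward * mid)
            if d < gap:
                lo_off = mid
            else:
                hi_off = mid
        offset = hi_off
        shift = base_point + outward * offset
        _apply(lig_try, np.eye(3), shift)
        lig_pts = lig_pts0 + shift

        dmin = _min_cross_distance(rec_pts, lig_pts)
        if dmin < 2.8:
            last_reason = f"hard clash ({dmin:.2f} Å)"
            continue
        complexe = Structure([rec_chain.copy(), Chain("B", lig_try)])
        int_a, int_b = interface_residues(complexe, "A", "B", 5.0)
        if len(int_a) < 6 or len(int_b) < 6:
            last_reason = f"thin interface ({len(int_a)}/{len(int_b)} residues)"
            continue
        rec_n = {res.resid: res.atom("N").xyz for res in complexe.chain("A").residues}
        lig_n = {res.resid: res.atom("N").xyz for res in complexe.chain("B").residues}
        nn = [(float(np.linalg.norm(rec_n[i] - lig_n[j])), i, j)
              for i in rec_n for j in lig_n]
        nn_min, _, source_resid = min(nn)
        if nn_min > 5.0:
            last_reason = f"no amide pair close enough for STD ({nn_min:.2f} Å)"
            continue
        try:
            bridge = _engineer_salt_bridge(complexe, rng)
        except GenerationError as exc:
            last_reason = str(exc)
            continue
        break
    else:
        raise GenerationError(
            f"make_toy_complex: placement failed after {max_tries} tries "
            f"(last: {last_reason}); try another seed")

    # ---- spin-label cysteines on the ligand helix (away from interface) ---
    helix_start = ligand_strands * strand_len + 1
    label_resids = (helix_start + 2, helix_start + 4)
    chain_b = complexe.chain("B")
    for resid in label_resids:
        res = chain_b.residue(resid)
        res.resname = "CYS"
        cb, ca = res.atom("CB").xyz, res.atom("CA").xyz
        u = (cb - ca) / np.linalg.norm(cb - ca)
        res.atoms.append(Atom("SG", "S", cb + 1.808 * u))

    # ---- ground-truth bookkeeping -----------------------------------------
    int_a, int_b = interface_residues(complexe, "A", "B", 5.0)
    rec_pts_by_res = {res.resid: np.array([a.xyz for a in res.heavy_atoms])
                      for res in complexe.chain("A").residues}
    lig_pts_by_res = {res.resid: np.array([a.xyz for a in res.heavy_atoms])
                      for res in complexe.chain("B").residues}
    all_rec = np.concatenate(list(rec_pts_by_res.values()))
    all_lig = np.concatenate(list(lig_pts_by_res.values()))
    min_dist = {
        "A": {rid: _min_cross_distance(all_lig, pts)
              for rid, pts in rec_pts_by_res.items()},
        "B": {rid: _min_cross_distance(all_rec, pts)
              for rid, pts in lig_pts_by_res.items()},
    }
    sg_pts = np.array([complexe.chain("B").residue(r).atom("SG").xyz
                       for r in label_resids])
    src_pos = complexe.chain("B").residue(source_resid).atom("N").xyz
    amide_to_labels, amide_to_source = {}, {}
    for res in complexe.chain("A").residues:
        n_xyz = res.atom("N").xyz
        amide_to_labels[res.resid] = float(np.min(np.linalg.norm(sg_pts - n_xyz, axis=1)))
        amide_to_source[res.resid] = float(np.linalg.norm(src_pos - n_xyz))

    return GroundTruth(
        structure=complexe,
        chain_receptor="A", chain_ligand="B",
        interface_receptor=int_a, interface_ligand=int_b,
        bridge=bridge, label_resids=label_resids,
        source_atom=("B", source_resid, "N"),
        min_dist_to_partner=min_dist,
        amide_to_labels=amide_to_labels,
        amide_to_source=amide_to_source,
        params={"receptor_helices": receptor_helices, "helix_len": helix_len,
                "ligand_strands": ligand_strands, "strand_len": strand_len,
                "ligand_helix_len": ligand_helix_len, "gap": gap},
        seed=seed,
    )


def _engineer_salt_bridge(complexe: Structure, rng) -> tuple[int, int]:
    """Add a Lys NZ / Asp OD1+OD2 pair across the interface (<= 4 Å)."""
    rec, lig = complexe.chain("A"), complexe.chain("B")
    cands = []
    for ra in rec.residues:
        for rb in lig.residues:
            d = float(np.linalg.norm(ra.atom("CB").xyz - rb.atom("CB").xyz))
            if 5.5 <= d <= 9.5:
                cands.append((abs(d - 7.4), d, ra.resid, rb.resid))
    cands.sort()
    other_lig = complexe.coords("B", heavy_only=True)
    other_rec = complexe.coords("A", heavy_only=True)
    for _, d, rid_a, rid_b in cands[:20]:
        res_a, res_b = rec.residue(rid_a), lig.residue(rid_b)
        cb_a, cb_b = res_a.atom("CB").xyz, res_b.atom("CB").xyz
        u = (cb_b - cb_a) / np.linalg.norm(cb_b - cb_a)
        span = d - 3.4
        a_len = max(1.2, 0.63 * span)
        b_len = span - a_len
        if b_len < 0.8:
            continue
        nz = cb_a + a_len * u
        od1 = cb_b - b_len * u
        ref = np.array([0.0, 0.0, 1.0])
        v = np.cross(u, ref)
        if np.linalg.norm(v) < 1e-6:
            v = np.cross(u, np.array([1.0, 0.0, 0.0]))
        v /= np.linalg.norm(v)
        od2 = od1 + 2.2 * v
        # the new atoms must not collide with the partner chain
        d_nz_lig = np.min(np.linalg.norm(other_lig - nz, axis=1))
        d_od_rec = min(np.min(np.linalg.norm(other_rec - od1, axis=1)),
                       np.min(np.linalg.norm(other_rec - od2, axis=1)))
        if d_nz_lig < 2.6 or d_od_rec < 2.6:
            continue
        if np.linalg.norm(nz - od1) > 4.0:
            continue
        res_a.resname = "LYS"
        res_a.atoms.append(Atom("NZ", "N", nz))
        res_b.resname = "ASP"
        res_b.atoms.append(Atom("OD1", "O", od1))
        res_b.atoms.append(Atom("OD2", "O", od2))
        return (rid_a, rid_b)
    raise GenerationError("could not engineer a Lys-Asp bridge across the interface")


# ---------------------------------------------------------------------------
# Simulated observables
# ---------------------------------------------------------------------------

def _one_letter(res: Residue) -> str:
    return AA3TO1.get(res.resname, "A")


def _random_positions(residues, rng):
    return {res.resid: (float(rng.uniform(7.0, 10.0)), float(rng.uniform(105.0, 130.0)))
            for res in residues}


def simulate_csp(gt: GroundTruth, chain: str | None = None, A: float = 0.15,
                 lam: float = 4.0, noise_sd: float = 0.005,
                 drop_frac: float = 0.05, two_state_resids: tuple[int, ...] = (),
                 seed: int = 0) -> tuple[PeakList, PeakList]:
    """Free/bound peak-list pair with interface-dependent perturbations.

    Each residue's combined shift magnitude is A·exp(−d_min/λ) plus Gaussian
    noise, where d_min is its closest heavy-atom approach to the partner
    chain in the true pose; the direction is random, split between ¹H and
    ¹⁵N with the 1/5 nitrogen scaling applied consistently, so the combined
    CSP recovers the magnitude exactly.  A fraction of residues drops out of
    the bound list (weak signals); listed residues get a second, half-shifted
    bound peak with the alt flag (slow exchange).
    """
    chain = chain or gt.chain_receptor
    rng = np.random.default_rng(seed)
    residues = gt.structure.chain(chain).residues
    d_min = gt.min_dist_to_partner[chain]
    pos = _random_positions(residues, rng)
    free, bound = PeakList(), PeakList()
    shifts = {}
    for res in residues:
        h, n = pos[res.resid]
        inten = float(rng.lognormal(0.0, 0.2))
        free.add(Peak(res.resid, _one_letter(res), h, n, inten))
        m = max(0.0, A * math.exp(-d_min[res.resid] / lam) + rng.normal(0.0, noise_sd))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        shifts[res.resid] = (m * math.cos(phi), 5.0 * m * math.sin(phi))
    drop = {res.resid for res in residues if rng.random() < drop_frac}
    for res in residues:
        if res.resid in drop:
            continue
        h, n = pos[res.resid]
        dh, dn = shifts[res.resid]
        inten = float(rng.lognormal(0.0, 0.2))
        bound.add(Peak(res.resid, _one_letter(res), h + dh, n + dn, inten))
        if res.resid in two_state_resids:
            bound.add(Peak(res.resid, _one_letter(res), h + 0.5 * dh, n + 0.5 * dn,
                           0.5 * inten, alt_flag=True))
    return free, bound


def simulate_pre(gt: GroundTruth, params: PREParameters | None = None,
                 label_resids: tuple[int, ...] | None = None,
                 noise_sd: float = 0.03, seed: int = 0) -> tuple[PeakList, PeakList]:
    """Paramagnetic/diamagnetic peak-list pair for the receptor amides.

    Diamagnetic intensities are log-normal; the paramagnetic intensity is
    attenuated by the Solomon–Bloembergen forward ratio at the amide's
    minimum distance over the label sites, with multiplicative noise.
    """
    params = params or PREParameters()
    rng = np.random.default_rng(seed)
    chain = gt.chain_receptor
    residues = gt.structure.chain(chain).residues
    if label_resids is not None and tuple(label_resids) != tuple(gt.label_resids):
        sg = np.array([gt.structure.chain(gt.chain_ligand).residue(r).atom("SG").xyz
                       for r in label_resids])
        dist = {res.resid: float(np.min(np.linalg.norm(sg - res.atom("N").xyz, axis=1)))
                for res in residues}
    else:
        dist = gt.amide_to_labels
    pos = _random_positions(residues, rng)
    dia, para = PeakList(), PeakList()
    for res in residues:
        h, n = pos[res.resid]
        i_dia = float(rng.lognormal(0.0, 0.2))
        ratio = float(ratio_from_distance(dist[res.resid], params))
        i_para = max(0.0, i_dia * ratio * (1.0 + rng.normal(0.0, noise_sd)))
        letter = _one_letter(res)
        dia.add(Peak(res.resid, letter, h, n, i_dia))
        para.add(Peak(res.resid, letter, h, n, i_para))
    return para, dia


def simulate_std(gt: GroundTruth, source_atom: tuple[str, int, str] | None = None,
                 d_max: float = 6.0, atten: float = 0.5,
                 noise_sd: float = 0.01, seed: int = 0) -> tuple[PeakList, PeakList]:
    """Off/on saturation peak-list pair for the receptor amides.

    The transfer ramps linearly from ``atten`` at zero distance to nothing
    at ``d_max``, so only residues whose amide sits within ``d_max`` of the
    saturated source proton are attenuated.
    """
    rng = np.random.default_rng(seed)
    chain = gt.chain_receptor
    residues = gt.structure.chain(chain).residues
    if source_atom is None or tuple(source_atom) == tuple(gt.source_atom):
        dist = gt.amide_to_source
    else:
        c, rid, name = source_atom
        src = gt.structure.chain(c).residue(rid).atom(name).xyz
        dist = {res.resid: float(np.linalg.norm(src - res.atom("N").xyz))
                for res in residues}
    pos = _random_positions(residues, rng)
    off, on = PeakList(), PeakList()
    for res in residues:
        h, n = pos[res.resid]
        i_off = float(rng.lognormal(0.0, 0.2))
        ramp = atten * max(0.0, 1.0 - dist[res.resid] / d_max)
        i_on = max(0.0, i_off * (1.0 - ramp) * (1.0 + rng.normal(0.0, noise_sd)))
        letter = _one_letter(res)
        off.add(Peak(res.resid, letter, h, n, i_off))
        on.add(Peak(res.resid, letter, h, n, i_on))
    return off, on


# ---------------------------------------------------------------------------
# Noise-free restraints straight from the ground truth
# ---------------------------------------------------------------------------

def ground_truth_restraints(gt: GroundTruth, pre_params=None,
                            std_cut: float = 5.0, std_d_max: float = 6.0,
                            pre_margin: float = 4.0):
    """Restraints a perfect experiment would yield for this complex.

    Ambiguous interaction restraints from the true interface sets, one PRE
    restraint per receptor amide from its exact distance to the nearest
    label site, and STD upper bounds for every amide truly within
    ``std_cut`` of the saturation source.  Used for docking recovery
    experiments where the question is the engine's, not the data's, fidelity.
    """
    from .pre import PREParameters, distance_from_ratio, ratio_from_distance
    from .restraints import build_air
    from .std import std_restraints
    import pandas as pd

    params = pre_params or PREParameters()
    receptor, ligand = gt.receptor(), gt.ligand()
    airs = build_air(gt.interface_receptor, gt.interface_ligand,
                     receptor, ligand,
                     chain_a=gt.chain_receptor, chain_b=gt.chain_ligand)
    pres = []
    sites = tuple(gt.label_selections())
    for resid, d in sorted(gt.amide_to_labels.items()):
        tmpl = distance_from_ratio(float(ratio_from_distance(d, params)), params,
                                   margin=pre_margin)
        pres.append(tmpl.with_selections(
            ((gt.chain_receptor, resid, "H|HN|N"),), sites))
    rows = [{"resid": rid, "resname": "A", "I_off": 1.0,
             "I_on": 0.0, "attenuation": 1.0, "flagged": d <= std_cut}
            for rid, d in sorted(gt.amide_to_source.items())]
    stds = std_restraints(pd.DataFrame(rows), gt.source_atom, d_max=std_d_max,
                          observed_chain=gt.chain_receptor)
    return airs + pres + stds
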