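"""Paramagnetic relaxation enhancement (PRE) analysis.

The paramagnetic contribution of a nitroxide spin label to the transverse
relaxation of an amide proton at distance r follows the Solomon–Bloembergen
spectral-density form

    Γ₂(r) = (K / r⁶) · (4 τ_c + 3 τ_c / (1 + ω_H² τ_c²))

and the observed paramagnetic/diamagnetic intensity ratio combines the
steady-state line-broadening factor with the attenuation accumulated over
the transverse evolution period:

    I/I₀ = R₂,dia / (R₂,dia + Γ₂) · exp(−Γ₂ t_evol)

This composite is strictly increasing in r and therefore invertible, which
is what turns measured ratios into distance restraints.  The defaults
(K = 1.23e-32 cm⁶ s⁻², τ_c = 15 ns for a micelle-embedded complex,
R₂,dia = 50 s⁻¹, t_evol = 10 ms, ω_H for an 18.8 T magnet) are
literature-standard constants, surfaced explicitly in the parameter object
because the raw experiment does not pin them down.

A spin label on several attachment sites (e.g. the two native cysteines of
a PDZ domain) gives one ambiguous restraint with minimum-distance
semantics: the experiment cannot tell which label caused the attenuation,
so the restraint is satisfied if any site satisfies it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DataError, NumericError
from .peaklist import BACKBONE_LABEL, PeakList, pair_conditions
from .restraints import Restraint, Selection
from .structure import Structure

import pandas as pd

#: proton gyromagnetic ratio, rad s⁻¹ T⁻¹
GAMMA_H = 2.6752218744e8
#: Å⁶ per cm⁶
_CM6_TO_A6 = 1e48


@dataclass(frozen=True)
class PREParameters:
    """Constants of the Solomon–Bloembergen forward model (all > 0).

    ``K`` is in Å⁶ s⁻²; ``omega_H`` in rad/s; times in seconds.
    """

    tau_c: float = 15e-9
    omega_H: float = GAMMA_H * 18.8
    K: float = 1.23e-32 * _CM6_TO_A6
    R2_dia: float = 50.0
    t_evol: float = 0.010

    def __post_init__(self):
        for name in ("tau_c", "omega_H", "K", "R2_dia", "t_evol"):
            if getattr(self, name) <= 0:
                raise DataError(f"PREParameters.{name} must be strictly positive")

    @classmethod
    def from_field(cls, B0_tesla: float, **kwargs) -> "PREParameters":
        return cls(omega_H=GAMMA_H * B0_tesla, **kwargs)


def gamma2(r, p: PREParameters):
    """Paramagnetic transverse relaxation rate Γ₂ (s⁻¹); vectorised in r."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise NumericError("gamma2: distance must be > 0")
    j = 4.0 * p.tau_c + 3.0 * p.tau_c / (1.0 + (p.omega_H * p.tau_c) ** 2)
    out = p.K / r**6 * j
    return float(out) if out.ndim == 0 else out


def ratio_from_distance(r, p: PREParameters):
    """Expected I/I₀ at distance r; in (0, 1], strictly increasing in r."""
    g = gamma2(r, p)
    out = p.R2_dia / (p.R2_dia + g) * np.exp(-np.minimum(g * p.t_evol, 745.0))
    return float(out) if np.ndim(out) == 0 else out


def invert_ratio(ratio: float, p: PREParameters,
                 r_min: float = 1.0, r_max: float = 200.0, xtol: float = 1e-3) -> float:
    """Distance at which the forward model produces ``ratio`` (root bracketing)."""
    if not (0.0 < ratio < 1.0):
        raise NumericError(f"invert_ratio: ratio {ratio} outside (0, 1)")
    f = lambda r: ratio_from_distance(r, p) - ratio
    if f(r_min) > 0 or f(r_max) < 0:
        raise NumericError("invert_ratio: ratio outside the bracketable range")
    return float(brentq(f, r_min, r_max, xtol=xtol))


def distance_from_ratio(
    ratio: float,
    p: PREParameters | None = None,
    lo: float = 0.15,
    hi: float = 0.85,
    margin: float = 4.0,
    selection_a: Selection | None = None,
    selection_b: Selection | None = None,
    weight: float = 1.0,
) -> Restraint:
    """Turn one normalized I/I₀ into a distance restraint.

    * ratio < ``lo``  — the peak is essentially bleached; only an upper bound
      at r(lo) is known.
    * ratio > ``hi``  — no measurable enhancement; lower bound at r(hi).
    * otherwise       — invert the forward model and emit a range restraint
      target ± ``margin`` Å (standard PRE uncertainty).

    Without selections this returns a *template* restraint; attach atoms with
    :meth:`Restraint.with_selections`.  Distances are rounded to 1e-3 Å so the
    ``.tbl`` writer round-trips exactly.
    """
    p = p or PREParameters()
    if not np.isfinite(ratio) or ratio < 0:
        raise NumericError(f"distance_from_ratio: invalid ratio {ratio!r}")
    kw = dict(selection_a=selection_a, selection_b=selection_b,
              weight=weight, source="PRE", aggregate="min")
    if ratio < lo:
        bound = round(invert_ratio(lo, p), 3) if lo > 0 else None
        if bound is None:
            raise NumericError("distance_from_ratio: lo=0 leaves no upper bound to emit")
        return Restraint("ambiguous", d_upper=bound, **kw)
    if ratio > hi:
        bound = round(invert_ratio(hi, p), 3) if hi < 1 else None
        if bound is None:
            raise NumericError("distance_from_ratio: hi=1 leaves no lower bound to emit")
        return Restraint("ambiguous", d_lower=bound, **kw)
    target = round(invert_ratio(ratio, p), 3)
    return Restraint("ambiguous", d_target=target,
                     d_lower=round(max(target - margin, 0.0), 3),
                     d_upper=round(target + margin, 3), **kw)


# ---------------------------------------------------------------------------
# Intensity ratios from peak lists
# ---------------------------------------------------------------------------

def compute_ratios(para: PeakList, dia: PeakList, reference_set="auto",
                   strong_cut: float = 0.15, weak_cut: float = 0.85) -> pd.DataFrame:
    """Normalized PRE intensity ratios I_para/I_dia per residue.

    Raw ratios are divided by the median raw ratio of a reference set of
    residues assumed unaffected by the label; ``reference_set="auto"`` takes
    the top quartile of raw ratios.  Classes: ``strong`` (< ``strong_cut``),
    ``weak`` (> ``weak_cut``), ``intermediate`` otherwise, ``missing`` for
    residues absent from the paramagnetic list.
    """
    rep = pair_conditions(dia, para)
    rows = []
    for m in rep.matched:
        if m.atom_label != BACKBONE_LABEL:
            continue
        i_dia = m.a.intensity
        i_para = m.b[0].intensity
        if i_dia <= 0:
            raise DataError(f"compute_ratios: residue {m.resid}: diamagnetic intensity must be > 0")
        rows.append({"resid": m.resid, "resname": m.a.resname,
                     "I_para": i_para, "I_dia": i_dia, "ratio": i_para / i_dia})
    if not rows:
        raise DataError("compute_ratios: no matched backbone residues")
    table = pd.DataFrame(rows).sort_values("resid").reset_index(drop=True)
    raw = table["ratio"].to_numpy()
    if reference_set == "auto":
        q3 = np.quantile(raw, 0.75)
        ref_mask = raw >= q3
    else:
        ref_mask = table["resid"].isin(set(reference_set)).to_numpy()
    if not ref_mask.any():
        raise DataError("compute_ratios: empty normalization reference set")
    norm = float(np.median(raw[ref_mask]))
    if norm <= 0:
        raise DataError("compute_ratios: reference median ratio is not positive")
    ref_resids = sorted(int(r) for r in table.loc[ref_mask, "resid"])
    table["ratio"] = raw / norm
    table["class"] = np.select(
        [table["ratio"] < strong_cut, table["ratio"] > weak_cut],
        ["strong", "weak"], default="intermediate",
    )
    missing_rows = []
    for resid, label in rep.unmatched_a:
        if label != BACKBONE_LABEL:
            continue
        p = dia.get(resid, label)
        missing_rows.append({"resid": resid, "resname": p.resname,
                             "I_para": math.nan, "I_dia": p.intensity,
                             "ratio": math.nan, "class": "missing"})
    if missing_rows:
        table = pd.concat([table, pd.DataFrame(missing_rows)], ignore_index=True)
        table = table.sort_values("resid").reset_index(drop=True)
    table.attrs["normalization"] = norm
    table.attrs["reference_resids"] = ref_resids
    return table


def label_sites(structure: Structure, chain_id: str = "B",
                resids: tuple[int, ...] = (44, 46)) -> list[tuple[str, int, str]]:
    """SG atom selections of the configured spin-labelled cysteines."""
    ch = structure.chain(chain_id)
    sites = []
    for resid in resids:
        res = ch.residue(resid)
        if res.resname != "CYS":
            raise DataError(f"label_sites: residue {chain_id}/{resid} is {res.resname}, not CYS")
        if not res.has_atom("SG"):
            raise DataError(f"label_sites: residue {chain_id}/{resid} has no SG atom")
        sites.append((chain_id, resid, "SG"))
    return sites


def pre_restraints(
    table: pd.DataFrame,
    sites: list[tuple[str, int, str]],
    observed_chain: str = "A",
    p: PREParameters | None = None,
    lo: float = 0.15,
    hi: float = 0.85,
    margin: float = 4.0,
    weight: float = 1.0,
) -> list[Restraint]:
    """One ambiguous restraint per measured residue: amide (H, else N) to the
    union of label sites, min-distance semantics over sites."""
    out = []
    sel_sites: Selection = tuple(sites)
    for _, row in table.iterrows():
        if row["class"] == "missing" or not np.isfinite(row["ratio"]):
            continue
        tmpl = distance_from_ratio(float(row["ratio"]), p, lo=lo, hi=hi,
                                   margin=margin, weight=weight)
        out.append(tmpl.with_selections(
            ((observed_chain, int(row["resid"]), "H|HN|N"),), sel_sites))
    return out


def write_pre_csv(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        if "normalization" in table.attrs:
            fh.write(f"# normalization = {table.attrs['normalization']:.6f}\n")
        table.to_csv(fh, index=False, float_format="%.6f")
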