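"""Chemical-shift-perturbation (CSP) mapping.

The combined amide perturbation follows the standard ¹H/¹⁵N weighting

    Δδ_HN = sqrt(Δδ_H² + (Δδ_N / 5)²)

i.e. the ¹⁵N difference is scaled by exactly 1/5 to account for its larger
shift dispersion.  Residues are classified as *active* (significantly
perturbed, candidate interface) by an iterative trimmed-statistics cutoff:
outliers above μ + k_trim·σ are excluded until the mean and standard
deviation stabilise, and the final cutoff is μ + k_cut·σ.  The cutoff is
recorded in the table metadata so any published residue selection can be
reproduced by tuning ``k_trim``/``k_cut``.

Tables are pandas DataFrames with columns
``resid, resname, atom_label, delta_H, delta_N, delta_HN, two_state, class``
and metadata in ``DataFrame.attrs``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DataError
from .peaklist import BACKBONE_LABEL, PeakList, pair_conditions

N_SCALE = 5.0  # ¹⁵N shift-difference scale divisor


def combined_shift(delta_H, delta_N):
    """Combined amide CSP magnitude; accepts scalars or arrays."""
    dh = np.asarray(delta_H, dtype=float)
    dn = np.asarray(delta_N, dtype=float)
    return np.sqrt(dh**2 + (dn / N_SCALE) ** 2)


def combined_csp(free: PeakList, bound: PeakList) -> pd.DataFrame:
    """Per-residue Δδ_H, Δδ_N and Δδ_HN between two conditions.

    Differences are bound − free.  When the bound list carries two peaks for
    a residue (slow exchange), the farther peak is used and the row is
    flagged ``two_state``.  Free-list residues missing from the bound list
    get class ``missing``; bound-only residues are only counted in the
    metadata.
    """
    rep = pair_conditions(free, bound)
    if not rep.matched:
        raise DataError("combined_csp: the two peak lists share no assignments")
    rows = []
    for m in rep.matched:
        cands = []
        for pb in m.b:
            dh = pb.delta_H - m.a.delta_H
            dn = pb.delta_N - m.a.delta_N
            cands.append((float(combined_shift(dh, dn)), dh, dn))
        dhn, dh, dn = max(cands)  # farther peak wins for slow exchange
        rows.append({
            "resid": m.resid, "resname": m.a.resname, "atom_label": m.atom_label,
            "delta_H": dh, "delta_N": dn, "delta_HN": dhn,
            "two_state": m.two_state, "class": "unperturbed",
        })
    for resid, label in rep.unmatched_a:
        p = free.get(resid, label)
        rows.append({
            "resid": resid, "resname": p.resname, "atom_label": label,
            "delta_H": math.nan, "delta_N": math.nan, "delta_HN": math.nan,
            "two_state": False, "class": "missing",
        })
    table = pd.DataFrame(rows).sort_values(["resid", "atom_label"]).reset_index(drop=True)
    table.attrs["n_unmatched_free"] = len(rep.unmatched_a)
    table.attrs["n_unmatched_bound"] = len(rep.unmatched_b)
    return table


def classify_perturbed(
    table: pd.DataFrame,
    k_trim: float = 3.0,
    k_cut: float = 1.0,
    include_sidechain: bool = False,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Set the active/unperturbed classes by the iterative trimmed cutoff.

    Side-chain entries (e.g. tryptophan indoles) are classified against the
    same cutoff but excluded from the threshold statistics by default,
    because their shift dispersion differs from backbone amides.
    """
    out = table.copy()
    stat_mask = out["delta_HN"].notna()
    if not include_sidechain:
        stat_mask &= out["atom_label"] == BACKBONE_LABEL
    values = out.loc[stat_mask, "delta_HN"].to_numpy(dtype=float)
    if values.size < 10:
        raise DataError(
            f"classify_perturbed: need >= 10 usable residues, got {values.size}"
        )
    keep = np.ones(values.size, dtype=bool)
    for _ in range(max_iter):
        mu = values[keep].mean()
        sigma = values[keep].std(ddof=0)
        new_keep = values <= mu + k_trim * sigma
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
        if not keep.any():
            raise DataError("classify_perturbed: trimming removed every residue")
    mu = values[keep].mean()
    sigma = values[keep].std(ddof=0)
    cutoff = float(mu + k_cut * sigma)
    finite = out["delta_HN"].notna()
    out.loc[finite, "class"] = np.where(
        out.loc[finite, "delta_HN"] > cutoff, "active", "unperturbed"
    )
    out.loc[~finite, "class"] = "missing"
    out.attrs.update(table.attrs)
    out.attrs["cutoff"] = cutoff
    out.attrs["k_trim"] = k_trim
    out.attrs["k_cut"] = k_cut
    return out


def active_resids(table: pd.DataFrame) -> set[int]:
    """Backbone-amide residues classified active."""
    sel = (table["class"] == "active") & (table["atom_label"] == BACKBONE_LABEL)
    return set(table.loc[sel, "resid"].astype(int))


def titration_consistency(tables: list[pd.DataFrame], tolerance: float = 0.01) -> pd.DataFrame:
    """Flag residues whose Δδ_HN decreases along a titration series.

    Under fast exchange the combined shift grows monotonically with ligand
    concentration; a drop larger than ``tolerance`` (ppm) between successive
    concentrations is flagged.
    """
    if len(tables) < 2:
        raise DataError("titration_consistency: need at least 2 concentrations")
    series: dict[int, list[float]] = {}
    for t in tables:
        sub = t[t["atom_label"] == BACKBONE_LABEL]
        for resid, dhn in zip(sub["resid"], sub["delta_HN"]):
            series.setdefault(int(resid), []).append(float(dhn))
    rows = []
    n = len(tables)
    for resid in sorted(series):
        vals = series[resid]
        if len(vals) < n or any(math.isnan(v) for v in vals):
            continue
        drops = [vals[i] - vals[i + 1] for i in range(n - 1)]
        worst = max(drops)
        rows.append({"resid": resid, "consistent": worst <= tolerance, "max_drop": worst})
    out = pd.DataFrame(rows)
    out.attrs["tolerance"] = tolerance
    return out


# ---------------------------------------------------------------------------
# CSV serialization (cutoff carried in a metadata header line)
# ---------------------------------------------------------------------------

def write_csp_csv(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        if "cutoff" in table.attrs:
            fh.write(f"# cutoff = {table.attrs['cutoff']:.6f}\n")
        table.to_csv(fh, index=False, float_format="%.6f")


def read_csp_csv(path) -> pd.DataFrame:
    cutoff = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# cutoff"):
            cutoff = float(first.split("=")[1])
        else:
            fh.seek(0)
        table = pd.read_csv(fh)
    if cutoff is not None:
        table.attrs["cutoff"] = cutoff
    return table
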