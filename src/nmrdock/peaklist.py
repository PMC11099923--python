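"""Assigned 2D ¹H–¹⁵N peak lists: parsing, writing and cross-condition pairing.

Two on-disk dialects are supported:

* a Sparky-like whitespace table — ``Assignment  w1 (¹⁵N, ppm)  w2 (¹H, ppm)
  Height`` with assignment strings such as ``E437N-H`` or the tryptophan
  indole ``W438NE1-HE1``;
* a CSV dialect with explicit named columns
  (``resid,resname,atom_label,delta_N,delta_H,intensity[,alt_flag]``), which
  is the unambiguous interchange format because w1/w2 axis order varies
  between processing programs.

Peaks are keyed by ``(resid, atom_label, alt_flag)``; the ``alt_flag``
marks the second peak of a residue in slow exchange (two bound-state peaks).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParseError

BACKBONE_LABEL = "N-H"

_ASSIGNMENT_RE = re.compile(r"^([A-Z])(\d+)([A-Z][A-Z0-9]*)-([A-Z][A-Z0-9]*)(\*?)$")


@dataclass(frozen=True)
class Peak:
    resid: int
    resname: str          # 1-letter code
    delta_H: float        # ppm
    delta_N: float        # ppm
    intensity: float = 1.0
    atom_label: str = BACKBONE_LABEL   # e.g. "N-H" (backbone), "NE1-HE1" (indole)
    alt_flag: bool = False

    def __post_init__(self):
        if not np.isfinite(self.delta_H) or not np.isfinite(self.delta_N):
            raise DataError(f"peak {self.resname}{self.resid}: non-finite ppm value")
        if not np.isfinite(self.intensity) or self.intensity < 0:
            raise DataError(f"peak {self.resname}{self.resid}: intensity must be finite and >= 0")

    @property
    def key(self) -> tuple[int, str, bool]:
        return (self.resid, self.atom_label, self.alt_flag)

    @property
    def assignment(self) -> str:
        n_atom, h_atom = self.atom_label.split("-")
        star = "*" if self.alt_flag else ""
        return f"{self.resname}{self.resid}{n_atom}-{h_atom}{star}"


class PeakList:
    """An ordered collection of peaks with unique ``(resid, label, alt)`` keys."""

    def __init__(self, peaks=()):
        self.peaks: list[Peak] = []
        self._index: dict[tuple[int, str, bool], Peak] = {}
        for p in peaks:
            self.add(p)

    def add(self, peak: Peak) -> None:
        if peak.key in self._index:
            raise DataError(f"duplicate assignment {peak.assignment}")
        self.peaks.append(peak)
        self._index[peak.key] = peak

    def get(self, resid: int, atom_label: str = BACKBONE_LABEL, alt_flag: bool = False) -> Peak:
        return self._index[(resid, atom_label, alt_flag)]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakList) and self.peaks == other.peaks

    @property
    def resids(self) -> set[int]:
        return {p.resid for p in self.peaks}


def _parse_assignment(token: str, where: str) -> tuple[str, int, str, bool]:
    m = _ASSIGNMENT_RE.match(token)
    if not m:
        raise ParseError(f"{where}: unparsable assignment {token!r}")
    resname, resid, n_atom, h_atom, star = m.groups()
    return resname, int(resid), f"{n_atom}-{h_atom}", bool(star)


def read_peaklist(path) -> PeakList:
    """Read either dialect, auto-detected from the header line."""
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise DataError(f"{path}: empty peak list")
    if "," in lines[0]:
        return _read_csv(path, lines)
    return _read_sparky(path, text.splitlines())


def _read_sparky(path, raw_lines) -> PeakList:
    pl = PeakList()
    for lineno, line in enumerate(raw_lines, start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        fields = s.split()
        if fields[0].lower() in ("assignment",):
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected 'assignment w1 w2 [height]'")
        resname, resid, atom_label, alt = _parse_assignment(fields[0], f"{path}: line {lineno}")
        try:
            w1 = float(fields[1])   # ¹⁵N
            w2 = float(fields[2])   # ¹H
            height = float(fields[3]) if len(fields) > 3 else 1.0
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: malformed number ({exc})") from None
        try:
            pl.add(Peak(resid, resname, delta_H=w2, delta_N=w1, intensity=height,
                        atom_label=atom_label, alt_flag=alt))
        except DataError as exc:
            raise DataError(f"{path}: line {lineno}: {exc}") from None
    if len(pl) == 0:
        raise DataError(f"{path}: no peaks parsed")
    return pl


_CSV_COLUMNS = ["resid", "resname", "atom_label", "delta_N", "delta_H", "intensity", "alt_flag"]


def _read_csv(path, lines) -> PeakList:
    reader = csv.DictReader(lines)
    missing = [c for c in _CSV_COLUMNS[:-1] if c not in (reader.fieldnames or [])]
    if missing:
        raise ParseError(f"{path}: CSV dialect is missing columns {missing}")
    pl = PeakList()
    for lineno, row in enumerate(reader, start=2):
        try:
            pl.add(Peak(
                resid=int(row["resid"]),
                resname=row["resname"].strip(),
                atom_label=row["atom_label"].strip(),
                delta_N=float(row["delta_N"]),
                delta_H=float(row["delta_H"]),
                intensity=float(row["intensity"]),
                alt_flag=str(row.get("alt_flag", "0")).strip().lower() in ("1", "true", "yes"),
            ))
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        except DataError as exc:
            raise DataError(f"{path}: line {lineno}: {exc}") from None
    if len(pl) == 0:
        raise DataError(f"{path}: no peaks parsed")
    return pl


def write_peaklist(pl: PeakList, path, fmt: str = "sparky") -> None:
    if fmt == "sparky":
        with open(path, "w") as fh:
            fh.write(f"{'Assignment':>12s} {'w1':>9s} {'w2':>9s} {'Height':>14s}\n")
            for p in pl:
                fh.write(f"{p.assignment:>12s} {p.delta_N:9.3f} {p.delta_H:9.3f} {p.intensity:14.6e}\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_COLUMNS)
            for p in pl:
                w.writerow([p.resid, p.resname, p.atom_label,
                            f"{p.delta_N:.3f}", f"{p.delta_H:.3f}", f"{p.intensity:.6e}",
                            int(p.alt_flag)])
    else:
        raise DataError(f"unknown peak-list format {fmt!r}")


# ---------------------------------------------------------------------------
# Pairing peak lists across conditions
# ---------------------------------------------------------------------------

@dataclass
class MatchedEntry:
    resid: int
    atom_label: str
    a: Peak
    b: list[Peak]          # one peak, or two in slow exchange (alt_flag pair)

    @property
    def two_state(self) -> bool:
        return len(self.b) > 1


@dataclass
class PairReport:
    matched: list[MatchedEntry] = field(default_factory=list)
    unmatched_a: list[tuple[int, str]] = field(default_factory=list)
    unmatched_b: list[tuple[int, str]] = field(default_factory=list)


def pair_conditions(a: PeakList, b: PeakList) -> PairReport:
    """Match two lists on ``(resid, atom_label)``.

    A residue that shows two peaks in ``b`` (slow exchange, ``alt_flag``)
    matches as one entry carrying both ``b`` peaks; nothing is ever silently
    dropped — unmatched residues of either side are listed in the report.
    """
    if len(a) == 0 or len(b) == 0:
        raise DataError("pair_conditions: both peak lists must be non-empty")
    b_groups: dict[tuple[int, str], list[Peak]] = {}
    for p in b:
        b_groups.setdefault((p.resid, p.atom_label), []).append(p)
    report = PairReport()
    seen_b: set[tuple[int, str]] = set()
    a_main = [p for p in a if not p.alt_flag]
    for p in a_main:
        key = (p.resid, p.atom_label)
        if key in b_groups:
            bl = sorted(b_groups[key], key=lambda q: q.alt_flag)
            report.matched.append(MatchedEntry(p.resid, p.atom_label, p, bl))
            seen_b.add(key)
        else:
            report.unmatched_a.append(key)
    for key in b_groups:
        if key not in seen_b:
            report.unmatched_b.append(key)
    report.unmatched_a.sort()
    report.unmatched_b.sort()
    return report
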