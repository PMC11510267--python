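"""Elemental-formula arithmetic for small-molecule mass spectrometry.

Monoisotopic and average masses, ion m/z with electron-mass correction,
parts-per-million mass-error conventions, and aggregated isotope envelopes
(A, A+1, A+2, ...). Element masses and isotopic abundances come from the
NIST table embedded in :mod:`pyteomics.mass`; everything built on top of
them (ion m/z, ppm conventions, envelope aggregation) is implemented here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from pyteomics import mass as _ptmass

#: Electron rest mass in Da (CODATA). One electron is added per negative
#: charge and removed per positive charge when forming an ion.
ELECTRON_MASS = 0.000548579909

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


@dataclass(frozen=True)
class ElementalFormula(Mapping):
    """An elemental composition: element symbol -> positive atom count.

    Behaves as an immutable mapping. Equality is count-map equality;
    addition merges compositions.
    """

    counts: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        for sym, n in self.counts:
            if sym not in _ptmass.nist_mass:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if n < 1:
                raise FormulaError(f"element {sym} has non-positive count {n}")

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "ElementalFormula":
        return cls(tuple(sorted((s, int(n)) for s, n in counts.items())))

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> int:
        return dict(self.counts)[key]

    def __iter__(self) -> Iterator[str]:
        return iter(dict(self.counts))

    def __len__(self) -> int:
        return len(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts:
            merged[sym] = merged.get(sym, 0) + n
        return ElementalFormula.from_dict(merged)

    def hill(self) -> str:
        """Canonical Hill-order writer (C, H, then alphabetical)."""
        d = dict(self.counts)
        out = []
        for sym in ("C", "H"):
            if sym in d:
                n = d.pop(sym)
                out.append(sym + (str(n) if n > 1 else ""))
        for sym in sorted(d):
            n = d[sym]
            out.append(sym + (str(n) if n > 1 else ""))
        return "".join(out)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C15H11O4"``.

    Implicit counts of 1 are allowed (``"C5H10NO2"``); duplicate element
    tokens are summed. Charge decorations are not accepted here.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        if not m.group(0):
            break
        sym, digits = m.group(1), m.group(2)
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n == 0:
                raise FormulaError(f"zero count for element {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(text) or not counts:
        raise FormulaError(f"cannot parse formula {text!r}")
    return ElementalFormula.from_dict(counts)


@dataclass(frozen=True)
class IonSpec:
    """An ion written as its literal atom content plus a signed charge.

    ``formula`` holds the atoms of the ion as written, e.g. C15H11O4 for
    the [M-H]- ion of liquiritigenin (C15H12O4).
    """

    formula: ElementalFormula
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("ion charge must be non-zero")

    @property
    def polarity(self) -> str:
        return "+" if self.charge > 0 else "-"

    def __str__(self) -> str:
        z = abs(self.charge)
        return f"{self.formula.hill()}{'' if z == 1 else z}{self.polarity}"


def monoisotopic_mass(f: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da: sum of counts times the exact mass of each
    element's most abundant isotope (lightest for C/H/N/O/S/P)."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(n * _ptmass.nist_mass[sym][0][0] for sym, n in f.counts)


def average_mass(f: ElementalFormula | str) -> float:
    """Average (molecular-weight) mass in Da using isotopic abundances."""
    if isinstance(f, str):
        f = parse_formula(f)
    return _ptmass.calculate_mass(composition=_ptmass.Composition(dict(f.counts)),
                                  average=True)


def ion_mz(ion: IonSpec) -> float:
    """Theoretical m/z of an ion.

    The electron mass is added once per negative charge and subtracted once
    per positive charge; the result is divided by |z|.
    """
    z = ion.charge
    m = monoisotopic_mass(ion.formula) - z * ELECTRON_MASS
    return m / abs(z)


def truncate(x: float, ndigits: int = 4) -> float:
    """Truncate (not round) toward zero at ``ndigits`` decimals."""
    factor = 10.0 ** ndigits
    return math.trunc(x * factor) / factor


def ppm_error(observed: float, theoretical: float,
              convention: str = "theoretical_denominator") -> float:
    """Absolute mass error in parts per million.

    ``theoretical_denominator`` (standard practice) divides by the exact
    theoretical m/z. ``nominal_denominator`` divides by the integer part of
    the theoretical m/z, which is the convention the reference tabulation
    of this workflow used for its printed errors (its printed values also
    appear truncated, not rounded, at 4 decimals; see :func:`truncate`).
    """
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    if convention == "theoretical_denominator":
        denom = theoretical
    elif convention == "nominal_denominator":
        denom = float(math.floor(theoretical))
    else:
        raise ValueError(f"unknown ppm convention: {convention!r}")
    return abs(observed - theoretical) / denom * 1e6


def _element_offset_distribution(sym: str) -> np.ndarray:
    """Abundances of one element's isotopes indexed by nucleon offset from
    the most abundant isotope."""
    isotopes = {k: v for k, v in _ptmass.nist_mass[sym].items()
                if k != 0 and v[1] > 0}
    base = min(isotopes)  # lightest == most abundant for CHNOPS
    top = max(isotopes)
    dist = np.zeros(top - base + 1)
    for a, (_m, ab) in isotopes.items():
        dist[a - base] = ab
    return dist / dist.sum()


def isotope_envelope(ion: IonSpec | ElementalFormula | str,
                     n_peaks: int = 3) -> list[tuple[int, float]]:
    """Aggregated isotope envelope of a formula or ion.

    Returns ``[(offset, abundance), ...]`` for offsets 0..n_peaks-1 (the A,
    A+1, A+2, ... peaks), computed by convolving the per-element isotope
    distributions (polynomial expansion), truncated to ``n_peaks`` and
    renormalized to sum to 1. The charge state does not affect the envelope.
    """
    if n_peaks < 2:
        raise ValueError("n_peaks must be >= 2")
    f = ion.formula if isinstance(ion, IonSpec) else ion
    if isinstance(f, str):
        f = parse_formula(f)
    env = np.array([1.0])
    for sym, n in f.counts:
        d = _element_offset_distribution(sym)
        for _ in range(n):
            env = np.convolve(env, d)
            env = env[: n_peaks]  # higher offsets never fold back
    out = np.zeros(n_peaks)
    out[: len(env)] = env
    out = out / out.sum()
    return [(i, float(a)) for i, a in enumerate(out)]
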