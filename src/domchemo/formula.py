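"""Molecular formulae for FT-ICR MS dissolved organic matter analysis.

A molecular formula here is an elemental composition C/H/O/N/S/P assigned to
an exact-mass peak; no structural information is implied. This module owns
parsing, formatting, exact-mass computation and the validity rules that an
assigned formula must satisfy before it enters any downstream statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

ELEMENTS = ("C", "H", "O", "N", "S", "P")

# Monoisotopic atomic masses (u), CODATA/IUPAC values.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "O": 15.9949146221,
    "N": 14.0030740052,
    "S": 31.97207069,
    "P": 30.97376151,
}

# Allowed per-element count ranges for an assigned DOM formula.
ELEMENT_RANGES = {
    "C": (1, 40),
    "H": (1, 82),
    "O": (1, 40),
    "N": (0, 4),
    "S": (0, 1),
    "P": (0, 1),
}

# Allowed (N, S, P) signatures for formulae containing two or more distinct
# heteroatom elements. Formulae with zero or one heteroatom element are always
# allowed (subject to the count caps). Signatures implying S=2 are retained
# for completeness but are unreachable under the S <= 1 cap, which wins.
MULTI_HETEROATOM_WHITELIST = frozenset(
    {
        (1, 1, 1),  # N S P
        (2, 1, 0),  # N2 S
        (3, 1, 0),  # N3 S
        (4, 1, 0),  # N4 S
        (2, 0, 1),  # N2 P
        (3, 0, 1),  # N3 P
        (1, 2, 0),  # N S2
        (2, 2, 0),  # N2 S2
        (3, 2, 0),  # N3 S2
        (4, 2, 0),  # N4 S2
        (0, 2, 1),  # S2 P
    }
)


class FormulaError(ValueError):
    """Raised for malformed molecular-formula strings."""


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Elemental composition of a DOM compound.

    Absent elements have count zero. Instances are immutable, hashable and
    ordered lexicographically on (C, H, O, N, S, P), which gives a stable,
    platform-independent sort for anything keyed on formulae.
    """

    C: int = 0
    H: int = 0
    O: int = 0
    N: int = 0
    S: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            v = getattr(self, el)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise FormulaError(f"element count {el}={v!r} must be a non-negative integer")

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in u."""
        return sum(getattr(self, el) * MONOISOTOPIC_MASS[el] for el in ELEMENTS)

    def counts(self) -> dict[str, int]:
        return {el: int(getattr(self, el)) for el in ELEMENTS}

    def __str__(self) -> str:
        return format_formula(self)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse an element-count string such as ``"C10H12O5N1"``.

    Absent elements imply count zero; an element symbol without a digit
    implies count one ("C6H6"). Round-trips with :func:`format_formula`.

    Raises
    ------
    FormulaError
        On an empty string, an unknown element symbol, a repeated element,
        or malformed text.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at {s[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in ELEMENTS:
            raise FormulaError(f"unknown element {el!r} in formula {text!r}")
        if el in counts:
            raise FormulaError(f"element {el!r} repeated in formula {text!r}")
        counts[el] = int(digits) if digits else 1
        pos = m.end()
    return MolecularFormula(**counts)


def format_formula(f: MolecularFormula) -> str:
    """Serialize in fixed C-H-O-N-S-P order, omitting zero counts."""
    parts = [f"{el}{getattr(f, el)}" for el in ELEMENTS if getattr(f, el) > 0]
    if not parts:
        raise FormulaError("cannot format the empty formula")
    return "".join(parts)


def validate_formula(f: MolecularFormula) -> tuple[bool, list[str]]:
    """Apply the DOM formula-assignment validity rules.

    A formula is valid iff all of the following hold:

    * element counts within C 1-40, H 1-82, O 1-40, N 0-4, S 0-1, P 0-1;
    * O <= C;
    * 0.3*C <= H <= 2*C + 2;
    * O > 2*P + S;
    * when two or more distinct heteroatom elements (N, S, P) are present,
      the (N, S, P) count signature is on the multi-heteroatom whitelist.

    Returns ``(valid, reasons)`` where ``reasons`` lists every violated rule.
    The check is a pure function of the counts.
    """
    reasons: list[str] = []
    for el, (lo, hi) in ELEMENT_RANGES.items():
        v = getattr(f, el)
        if not lo <= v <= hi:
            reasons.append(f"{el}={v} outside [{lo}, {hi}]")
    if f.O > f.C:
        reasons.append(f"O > C ({f.O} > {f.C})")
    if not 0.3 * f.C <= f.H:
        reasons.append(f"H < 0.3*C ({f.H} < {0.3 * f.C:g})")
    if not f.H <= 2 * f.C + 2:
        reasons.append(f"H > 2*C+2 ({f.H} > {2 * f.C + 2})")
    if not f.O > 2 * f.P + f.S:
        reasons.append(f"O <= 2*P+S ({f.O} <= {2 * f.P + f.S})")
    n_hetero_elements = sum(1 for el in ("N", "S", "P") if getattr(f, el) > 0)
    if n_hetero_elements >= 2 and (f.N, f.S, f.P) not in MULTI_HETEROATOM_WHITELIST:
        reasons.append(f"heteroatom combination N{f.N}S{f.S}P{f.P} not whitelisted")
    return (not reasons, reasons)


def validate_counts(c, h, o, n, s, p) -> np.ndarray:
    """Vectorized validity mask over parallel count arrays.

    Same rules as :func:`validate_formula`, without reason strings; used by
    the synthetic-data generator to screen large candidate pools.
    """
    c, h, o, n, s, p = (np.asarray(a) for a in (c, h, o, n, s, p))
    ok = (
        (c >= 1) & (c <= 40)
        & (h >= 1) & (h <= 82)
        & (o >= 1) & (o <= 40)
        & (n >= 0) & (n <= 4)
        & (s >= 0) & (s <= 1)
        & (p >= 0) & (p <= 1)
        & (o <= c)
        & (0.3 * c <= h) & (h <= 2 * c + 2)
        & (o > 2 * p + s)
    )
    multi = ((n > 0).astype(int) + (s > 0).astype(int) + (p > 0).astype(int)) >= 2
    if np.any(multi):
        sig_ok = np.zeros_like(ok)
        for sn, ss, sp in MULTI_HETEROATOM_WHITELIST:
            sig_ok |= (n == sn) & (s == ss) & (p == sp)
        ok &= ~multi | sig_ok
    return ok


def formula_mass(c, h, o, n, s, p) -> np.ndarray:
    """Vectorized neutral monoisotopic mass over parallel count arrays."""
    m = MONOISOTOPIC_MASS
    return (
        np.asarray(c) * m["C"]
        + np.asarray(h) * m["H"]
        + np.asarray(o) * m["O"]
        + np.asarray(n) * m["N"]
        + np.asarray(s) * m["S"]
        + np.asarray(p) * m["P"]
    )
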