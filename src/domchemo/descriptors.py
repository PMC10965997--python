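"""Per-formula molecular descriptors and compound classification.

Implements the standard FT-ICR MS DOM descriptors — elemental ratios,
double-bond equivalents (DBE), the modified aromaticity index (AI_mod) and
the nominal oxidation state of carbon (NOSC) — together with the four broad
compound classes and the eight van Krevelen categories used for
chemodiversity and enrichment summaries.

All numeric functions accept scalars or numpy arrays.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .formula import MolecularFormula, format_formula, formula_mass

CLASS4 = ("saturated", "unsaturated", "highly_unsaturated", "aromatic")

CATEGORY8 = (
    "saturated fatty acids (CHO)",
    "saturated fatty acids (CHOX)",
    "oxygen-rich unsaturated aliphatic",
    "oxygen-poor unsaturated aliphatic",
    "oxygen-rich highly unsaturated",
    "oxygen-poor highly unsaturated",
    "polyphenols",
    "oxygen-poor polyphenols",
)

#: Default O/C ratio separating oxygen-rich from oxygen-poor categories.
OXYGEN_RICH_CUTOFF = 0.5


def compute_ai_mod(c, h, o, n=0, s=0, p=0):
    """Modified aromaticity index.

    AI_mod = (1 + C - 0.5*O - S - 0.5*H) / (C - 0.5*O - N - S - P),
    treating half the oxygen as carbonyl-like. Clamped to 0 when the
    denominator is non-positive or the numerator negative, so aliphatic,
    oxygen-saturated compositions score zero aromaticity.
    """
    c, h, o, n, s, p = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (c, h, o, n, s, p))
    )
    num = 1.0 + c - 0.5 * o - s - 0.5 * h
    den = c - 0.5 * o - n - s - p
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where((den > 0) & (num >= 0), num / np.where(den != 0, den, 1.0), 0.0)
    return ai if ai.ndim else float(ai)


def compute_dbe(c, h, n=0, p=0):
    """Double-bond equivalents: DBE = 1 + C - H/2 + N/2 + P/2.

    Rings plus pi bonds implied by the composition; may be half-integer for
    odd N+P-H parity.
    """
    c, h, n, p = (np.asarray(x, dtype=float) for x in (c, h, n, p))
    out = 1.0 + c - h / 2.0 + n / 2.0 + p / 2.0
    return out if out.ndim else float(out)


def compute_nosc(c, h, o, n=0, s=0, p=0):
    """Nominal oxidation state of carbon.

    NOSC = 4 - (4*C + H - 3*N - 2*O + 5*P - 2*S) / C, ranging from -4
    (fully reduced, CH4) through 0 (carbohydrate-like CH2O) to +4.
    """
    c, h, o, n, s, p = (np.asarray(x, dtype=float) for x in (c, h, o, n, s, p))
    out = 4.0 - (4.0 * c + h - 3.0 * n - 2.0 * o + 5.0 * p - 2.0 * s) / c
    return out if out.ndim else float(out)


def classify4(h_to_c, ai_mod):
    """Four broad compound classes from H/C and AI_mod.

    Precedence: H/C >= 2 -> saturated; else H/C >= 1.5 -> unsaturated; else
    AI_mod > 0.5 -> aromatic; else highly unsaturated. Total on any input;
    condensed aromatics (AI_mod > 0.67) fall in "aromatic" and are flagged
    separately by :func:`descriptor_table`.
    """
    h_to_c = np.asarray(h_to_c, dtype=float)
    ai_mod = np.asarray(ai_mod, dtype=float)
    out = np.select(
        [h_to_c >= 2.0, h_to_c >= 1.5, ai_mod > 0.5],
        ["saturated", "unsaturated", "aromatic"],
        default="highly_unsaturated",
    )
    return out if out.ndim else str(out)


def categorize8(class4, o_to_c, has_heteroatom, oxygen_rich_cutoff: float = OXYGEN_RICH_CUTOFF):
    """Eight van Krevelen categories refining the four classes.

    Saturated compounds split into CHO vs heteroatom-bearing (CHOX) fatty
    acids; unsaturated and highly unsaturated split into oxygen-rich vs
    oxygen-poor at ``oxygen_rich_cutoff`` on O/C; aromatics split into
    polyphenols (O/C >= cutoff) vs oxygen-poor polyphenols.
    """
    class4 = np.asarray(class4)
    o_to_c = np.asarray(o_to_c, dtype=float)
    het = np.asarray(has_heteroatom, dtype=bool)
    rich = o_to_c >= oxygen_rich_cutoff
    out = np.select(
        [
            (class4 == "saturated") & ~het,
            (class4 == "saturated") & het,
            (class4 == "unsaturated") & rich,
            (class4 == "unsaturated") & ~rich,
            (class4 == "highly_unsaturated") & rich,
            (class4 == "highly_unsaturated") & ~rich,
            (class4 == "aromatic") & rich,
        ],
        [
            "saturated fatty acids (CHO)",
            "saturated fatty acids (CHOX)",
            "oxygen-rich unsaturated aliphatic",
            "oxygen-poor unsaturated aliphatic",
            "oxygen-rich highly unsaturated",
            "oxygen-poor highly unsaturated",
            "polyphenols",
        ],
        default="oxygen-poor polyphenols",
    )
    return out if out.ndim else str(out)


def descriptor_table(
    formulae: Iterable[MolecularFormula],
    oxygen_rich_cutoff: float = OXYGEN_RICH_CUTOFF,
) -> pd.DataFrame:
    """Build the full descriptor table for a set of formulae.

    Returns a DataFrame indexed by the serialized formula string with columns
    ``c h o n s p mass o_to_c h_to_c dbe ai_mod nosc class4 category8
    contains_n contains_s contains_p condensed_aromatic``. Every formula
    receives exactly one class and one category.
    """
    formulae = list(formulae)
    if not formulae:
        raise ValueError("descriptor_table requires at least one formula")
    idx = [format_formula(f) for f in formulae]
    c = np.array([f.C for f in formulae], dtype=float)
    h = np.array([f.H for f in formulae], dtype=float)
    o = np.array([f.O for f in formulae], dtype=float)
    n = np.array([f.N for f in formulae], dtype=float)
    s = np.array([f.S for f in formulae], dtype=float)
    p = np.array([f.P for f in formulae], dtype=float)

    ai = compute_ai_mod(c, h, o, n, s, p)
    hc = h / c
    oc = o / c
    cls = classify4(hc, ai)
    het = (n > 0) | (s > 0) | (p > 0)
    cat = categorize8(cls, oc, het, oxygen_rich_cutoff)

    return pd.DataFrame(
        {
            "c": c.astype(int),
            "h": h.astype(int),
            "o": o.astype(int),
            "n": n.astype(int),
            "s": s.astype(int),
            "p": p.astype(int),
            "mass": formula_mass(c, h, o, n, s, p),
            "o_to_c": oc,
            "h_to_c": hc,
            "dbe": compute_dbe(c, h, n, p),
            "ai_mod": ai,
            "nosc": compute_nosc(c, h, o, n, s, p),
            "class4": cls,
            "category8": cat,
            "contains_n": n > 0,
            "contains_s": s > 0,
            "contains_p": p > 0,
            "condensed_aromatic": ai > 0.67,
        },
        index=pd.Index(idx, name="formula"),
    )
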