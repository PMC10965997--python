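"""Per-formula enrichment of soil-amended treatments relative to controls.

Enrichment of a formula is the percent change of its mean relative FT-ICR MS
intensity in a treatment versus the matching lake-water control:

    enrichment = (I_treatment - I_control) / I_control * 100

with the convention that a formula absent from the control but present in
the treatment ("new") is enriched at 100%. Summaries reproduce the standard
lake-characterization table: counts per compound class and heteroatom
element and mean descriptors over the enriched set.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import Dataset

#: Minimum enrichment (%) for a formula to count as enriched.
ENRICHED_THRESHOLD = 0.0


def compute_enrichment(i_treat: float, i_ctrl: float) -> float:
    """Percent enrichment of one formula from replicate-mean intensities.

    Returns 100.0 when the control intensity is zero but the treatment is
    detected (the "new compound" rule) and NaN (undefined, excluded
    downstream) when both are zero. Raises on negative input.
    """
    if i_treat < 0 or i_ctrl < 0:
        raise ValueError("intensities must be non-negative")
    if i_ctrl == 0:
        return 100.0 if i_treat > 0 else math.nan
    return (i_treat - i_ctrl) / i_ctrl * 100.0


def enriched_set(
    d: Dataset,
    lake: str,
    treatment: str,
    timepoint_h: float | None = None,
    threshold: float = ENRICHED_THRESHOLD,
) -> pd.DataFrame:
    """Per-formula enrichment records for one lake/treatment contrast.

    Intensities are replicate means of normalized relative intensities; when
    ``timepoint_h`` is None all timepoints are pooled into the means. One
    record is returned per formula detected in the treatment (mean > 0), with
    columns ``mean_treat, mean_ctrl, enrichment_pct, is_new, enriched`` and
    the contrast identifiers. ``is_new`` marks formulae present in the
    treatment but absent from the lake-water control.
    """
    if not d.normalized:
        raise ValueError("enrichment requires a normalized post-QC dataset")
    crit: dict = {"lake": lake, "role": "sample"}
    if timepoint_h is not None:
        crit["timepoint_h"] = timepoint_h
    treat_samples = [s.sample_id for s in d.select_samples(treatment=treatment, **crit)]
    ctrl_samples = [s.sample_id for s in d.select_samples(treatment="control", **crit)]
    if not ctrl_samples:
        raise ValueError(f"no control samples for lake={lake!r}, timepoint={timepoint_h!r}")
    if not treat_samples:
        raise ValueError(f"no samples for lake={lake!r}, treatment={treatment!r}")

    mean_treat = d.intensities[treat_samples].mean(axis=1)
    mean_ctrl = d.intensities[ctrl_samples].mean(axis=1)
    detected = mean_treat > 0
    mt = mean_treat[detected]
    mc = mean_ctrl[detected]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(mc > 0, (mt - mc) / mc.replace(0, np.nan) * 100.0, 100.0)
    records = pd.DataFrame(
        {
            "mean_treat": mt,
            "mean_ctrl": mc,
            "enrichment_pct": pct,
            "is_new": (mc == 0).to_numpy(),
            "enriched": pct > threshold,
            "lake": lake,
            "treatment": treatment,
            "timepoint_h": math.nan if timepoint_h is None else timepoint_h,
        }
    )
    records.index.name = "formula"
    return records


def novel_or_enriched_fraction(records: pd.DataFrame) -> float:
    """Fraction of novel-or-enriched formulae relative to the control pool.

    The denominator is the number of formulae detected in the lake-water
    control of the contrast; the numerator counts formulae with positive
    enrichment (which includes all new ones).
    """
    n_ctrl = int((records["mean_ctrl"] > 0).sum())
    if n_ctrl == 0:
        return math.nan
    return float(records["enriched"].sum()) / n_ctrl


def summarize_composition(descriptors: pd.DataFrame) -> pd.Series:
    """Class/heteroatom counts and mean descriptors over a formula set.

    Used both for the enriched set of a treatment and for all compounds
    detected in a lake-water control.
    """
    from .descriptors import CLASS4

    n = len(descriptors)
    out = {"n_compounds": n}
    for cls in CLASS4:
        out[f"n_{cls}"] = int((descriptors["class4"] == cls).sum()) if n else 0
    for el in ("n", "s", "p"):
        out[f"n_containing_{el}"] = int(descriptors[f"contains_{el}"].sum()) if n else 0
    for col in ("dbe", "o_to_c", "h_to_c", "ai_mod", "nosc"):
        out[f"mean_{col}"] = float(descriptors[col].mean()) if n else math.nan
    return pd.Series(out)


def summarize_enriched(records: pd.DataFrame, descriptors: pd.DataFrame) -> pd.Series:
    """Table-style summary of an enriched set.

    Counts of enriched compounds per broad class and per heteroatom element,
    plus unweighted means of DBE, O/C, H/C, AI_mod and NOSC over the enriched
    compounds. An empty enriched set yields zero counts and NaN means.
    """
    enriched = records.index[records["enriched"]]
    desc = descriptors.loc[descriptors.index.intersection(enriched)]
    out = summarize_composition(desc)
    out["n_enriched"] = int(records["enriched"].sum())
    out["n_new"] = int((records["is_new"] & records["enriched"]).sum())
    out["novel_or_enriched_fraction"] = novel_or_enriched_fraction(records)
    return out
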