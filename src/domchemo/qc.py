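"""Molecular-formula validity screening and the peak-filtering cascade.

The cascade that turns an assigned peak list into the analyzable intensity
matrix is order-fixed:

1. drop formulae failing the assignment validity rules,
2. drop formulae detected in blanks or on a contaminant list,
3. zero peaks below an intensity floor (default 0.01% of the sample sum),
4. zero peaks not present in enough replicates of their treatment group,
5. normalize each sample to relative intensities summing to 1.

Each stage is idempotent, never increases any intensity, and records itself
in the dataset provenance.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .formula import MolecularFormula, format_formula, parse_formula, validate_formula
from .io import Dataset

#: Fraction of the per-sample intensity sum below which a peak is zeroed.
INTENSITY_FLOOR_FRACTION = 1e-4

#: Minimum number of replicates a peak must appear in within its group.
REPLICATE_MIN = 2


def drop_invalid_formulae(d: Dataset) -> Dataset:
    """Remove rows whose formula fails the assignment validity rules."""
    keep, dropped = [], []
    for name in d.intensities.index:
        ok, _ = validate_formula(parse_formula(name))
        (keep if ok else dropped).append(name)
    out = d.intensities.loc[keep]
    return d.with_intensities(out, f"drop_invalid_formulae: removed {len(dropped)} invalid formulae")


def remove_blank_and_contaminant_peaks(
    d: Dataset, contaminant_list: Iterable[MolecularFormula] = ()
) -> Dataset:
    """Drop formulae detected in any blank sample or listed as contaminants.

    A formula counts as detected in a blank when its intensity there is > 0.
    Blank columns are consumed by this stage: they are removed from the
    returned dataset, having served their filtering purpose.
    """
    blanks = [s.sample_id for s in d.samples if s.role == "blank"]
    in_blank = (
        (d.intensities[blanks] > 0).any(axis=1)
        if blanks
        else pd.Series(False, index=d.intensities.index)
    )
    listed = {format_formula(f) for f in contaminant_list}
    in_list = d.intensities.index.isin(listed)
    drop_mask = in_blank.to_numpy() | in_list
    keep_samples = [s for s in d.samples if s.role != "blank"]
    out = d.intensities.loc[~drop_mask, [s.sample_id for s in keep_samples]]
    note = (
        f"remove_blank_and_contaminant_peaks: removed {int(in_blank.sum())} blank-detected, "
        f"{int(in_list.sum())} listed-contaminant formulae "
        f"({int(drop_mask.sum())} total); dropped {len(blanks)} blank columns"
    )
    return d.with_intensities(out, note, samples=keep_samples)


def apply_intensity_floor(d: Dataset, floor_fraction: float = INTENSITY_FLOOR_FRACTION) -> Dataset:
    """Zero peaks below ``floor_fraction`` of their sample's intensity sum.

    Column sums are computed once, before any zeroing (single pass); the
    comparison is strict, so a peak exactly at the floor is retained.
    """
    if d.normalized:
        raise ValueError("intensity floor must be applied before normalization")
    x = d.intensities.to_numpy(dtype=float, copy=True)
    sums = x.sum(axis=0)
    floor = floor_fraction * sums
    n_zeroed = int(((x > 0) & (x < floor)).sum())
    x[x < floor] = 0.0
    out = pd.DataFrame(x, index=d.intensities.index, columns=d.intensities.columns)
    return d.with_intensities(
        out, f"apply_intensity_floor({floor_fraction:g}): zeroed {n_zeroed} peaks"
    )


def replicate_presence_filter(
    d: Dataset, min_replicates: int = REPLICATE_MIN, *, allow_small_groups: bool = True
) -> Dataset:
    """Require presence in at least ``min_replicates`` replicates per group.

    Within each (lake, treatment, timepoint) replicate group, a formula
    present (intensity > 0, evaluated after flooring) in fewer than
    ``min(min_replicates, group size)`` replicates is zeroed in all
    replicates of that group. Rows left all-zero across the dataset are
    dropped. Groups smaller than ``min_replicates`` (a lost replicate) use
    their own size as the threshold unless ``allow_small_groups`` is False,
    in which case they raise.
    """
    x = d.intensities.to_numpy(dtype=float, copy=True)
    cols = {c: i for i, c in enumerate(d.intensities.columns)}
    n_zeroed = 0
    for key, members in d.replicate_groups(role="sample").items():
        idx = [cols[s.sample_id] for s in members]
        if len(idx) < min_replicates and not allow_small_groups:
            raise ValueError(
                f"group {key} has {len(idx)} replicates; cannot evaluate the "
                f">= {min_replicates}-replicate presence rule"
            )
        need = min(min_replicates, len(idx))
        present = (x[:, idx] > 0).sum(axis=1)
        fail = present < need
        n_zeroed += int((x[np.ix_(fail, idx)] > 0).sum())
        x[np.ix_(fail, idx)] = 0.0
    out = pd.DataFrame(x, index=d.intensities.index, columns=d.intensities.columns)
    all_zero = ~(out.to_numpy() > 0).any(axis=1)
    out = out.loc[~all_zero]
    note = (
        f"replicate_presence_filter(min={min_replicates}): zeroed {n_zeroed} peaks, "
        f"dropped {int(all_zero.sum())} all-zero rows"
    )
    return d.with_intensities(out, note)


def normalize(d: Dataset) -> Dataset:
    """Divide each sample column by its intensity sum (relative intensities).

    Idempotent; raises on an all-zero sample column, naming the sample.
    """
    x = d.intensities.to_numpy(dtype=float, copy=True)
    sums = x.sum(axis=0)
    dead = [c for c, s in zip(d.intensities.columns, sums) if s <= 0]
    if dead:
        raise ValueError(f"cannot normalize all-zero sample column(s): {dead}")
    x /= sums
    out = pd.DataFrame(x, index=d.intensities.index, columns=d.intensities.columns)
    return d.with_intensities(out, "normalize: columns scaled to unit sum", normalized=True)


def qc_pipeline(
    d: Dataset,
    contaminant_list: Iterable[MolecularFormula] = (),
    floor_fraction: float = INTENSITY_FLOOR_FRACTION,
    min_replicates: int = REPLICATE_MIN,
) -> Dataset:
    """Run the full order-fixed QC cascade and return the normalized matrix."""
    d = drop_invalid_formulae(d)
    d = remove_blank_and_contaminant_peaks(d, contaminant_list)
    d = apply_intensity_floor(d, floor_fraction)
    d = replicate_presence_filter(d, min_replicates)
    return normalize(d)
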