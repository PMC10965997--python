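"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops over dictionaries, so that agreement with the pipeline is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_qc_survivors(
    intensities: dict[str, dict[str, float]],
    sample_meta: dict[str, dict],
    contaminants: set[str],
    floor_fraction: float = 1e-4,
    min_replicates: int = 2,
) -> dict[str, dict[str, float]]:
    """Re-derive the QC cascade result with explicit loops.

    ``intensities``: {formula: {sample_id: value}}; ``sample_meta``:
    {sample_id: {"lake", "treatment", "timepoint_h", "role"}}. Returns the
    normalized surviving table in the same nested-dict form.
    """
    formulas = list(intensities)
    sample_ids = [sid for sid, m in sample_meta.items() if m["role"] == "sample"]
    blanks = [sid for sid, m in sample_meta.items() if m["role"] == "blank"]

    # 1) blank / contaminant removal
    kept = []
    for f in formulas:
        in_blank = any(intensities[f].get(b, 0.0) > 0 for b in blanks)
        if not in_blank and f not in contaminants:
            kept.append(f)

    table = {f: {sid: intensities[f].get(sid, 0.0) for sid in sample_ids} for f in kept}

    # 2) intensity floor, sums computed before zeroing
    for sid in sample_ids:
        total = sum(table[f][sid] for f in kept)
        for f in kept:
            if table[f][sid] < floor_fraction * total:
                table[f][sid] = 0.0

    # 3) replicate presence per (lake, treatment, timepoint) group
    groups: dict[tuple, list[str]] = {}
    for sid in sample_ids:
        m = sample_meta[sid]
        groups.setdefault((m["lake"], m["treatment"], m["timepoint_h"]), []).append(sid)
    for members in groups.values():
        need = min(min_replicates, len(members))
        for f in kept:
            n_present = sum(1 for sid in members if table[f][sid] > 0)
            if n_present < need:
                for sid in members:
                    table[f][sid] = 0.0
    table = {f: row for f, row in table.items() if any(v > 0 for v in row.values())}

    # 4) normalize columns
    for sid in sample_ids:
        total = sum(row[sid] for row in table.values())
        for f in table:
            table[f][sid] = table[f][sid] / total
    return table


def gower_oracle(rows: list[dict], numeric_vars: list[str], cat_var: str) -> np.ndarray:
    """Double-loop Gower distance over a list of descriptor dicts."""
    n = len(rows)
    ranges = {}
    for v in numeric_vars:
        vals = [r[v] for r in rows]
        ranges[v] = max(vals) - min(vals)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            total = 0.0
            m = 0
            for v in numeric_vars:
                if ranges[v] == 0:
                    continue
                total += abs(rows[i][v] - rows[j][v]) / ranges[v]
                m += 1
            total += 0.0 if rows[i][cat_var] == rows[j][cat_var] else 1.0
            m += 1
            d[i, j] = total / m
    return d


def rao_oracle(p: list[float], dist: np.ndarray) -> float:
    """Double-loop Rao's quadratic entropy."""
    q = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            q += dist[i][j] * p[i] * p[j]
    return q


def pathlength_oracle(linkage_matrix: np.ndarray, n_tips: int, tip_idx: set[int]) -> float:
    """Spanning-subtree pathlength by explicit edge enumeration.

    Walks every parent-child edge of the dendrogram, computes the tip set
    below each child by recursive descent, and sums the lengths of edges
    whose subtree contains some but not all selected tips.
    """
    children = {n_tips + i: (int(a), int(b)) for i, (a, b, *_r) in enumerate(linkage_matrix)}
    heights = {i: 0.0 for i in range(n_tips)}
    for i, row in enumerate(linkage_matrix):
        heights[n_tips + i] = float(row[2])

    def tips_below(node: int) -> set[int]:
        if node < n_tips:
            return {node}
        a, b = children[node]
        return tips_below(a) | tips_below(b)

    total = 0.0
    for parent, (a, b) in children.items():
        for child in (a, b):
            below = tips_below(child) & tip_idx
            if below and below != tip_idx:
                total += heights[parent] - heights[child]
    return total
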