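"""Dendrogram-pathlength chemodiversity of DOM molecular formulae.

Chemodiversity is measured in analogy to phylogenetic diversity: molecular
formulae are clustered on Gower's distance over mixed chemical descriptors
(O/C, H/C, molecular mass, AI_mod, DBE plus the eight-way compound
category), giving an ultrametric dendrogram of chemical similarity, and the
diversity of a sample is the total branch length of the minimal subtree
spanning the formulae present in it. Compounds chemically similar to ones
already present therefore add little diversity; chemically novel compounds
add long branches.

Because pathlength grows with the number of compounds, samples are first
rarefied by intensity to the lowest total signal and then repeatedly
subsampled to a fixed number of compounds; the per-iteration pathlengths are
the chemodiversity estimates. Rao's quadratic entropy is provided as the
intensity-weighted comparison index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import Dataset

#: Number of compounds drawn per chemodiversity iteration.
SUBSAMPLE_SIZE = 3000

#: Number of random subsampling iterations per sample.
N_ITERATIONS = 100

GOWER_NUMERIC_VARIABLES = ("o_to_c", "h_to_c", "mass", "ai_mod", "dbe")
GOWER_CATEGORICAL_VARIABLE = "category8"


def gower_distance(
    desc: pd.DataFrame,
    numeric_variables: tuple[str, ...] = GOWER_NUMERIC_VARIABLES,
    categorical_variable: str | None = GOWER_CATEGORICAL_VARIABLE,
) -> np.ndarray:
    """Pairwise Gower distance matrix over a descriptor table.

    Each numeric variable contributes |x_i - x_j| / range(variable); the
    categorical variable contributes 0 for a match and 1 otherwise; the
    distance is the unweighted mean over variables. Numeric variables with
    zero range are dropped with a warning. Result is symmetric with zero
    diagonal, entries in [0, 1], row/column order following ``desc.index``.
    """
    if len(desc) < 2:
        raise ValueError("gower_distance requires at least 2 formulae")
    total = np.zeros((len(desc), len(desc)))
    n_used = 0
    for var in numeric_variables:
        x = desc[var].to_numpy(dtype=float)
        if np.isnan(x).any():
            bad = desc.index[np.isnan(x)][0]
            raise ValueError(f"NaN descriptor {var!r} for formula {bad!r}")
        rng_ = x.max() - x.min()
        if rng_ == 0:
            warnings.warn(f"dropping constant Gower variable {var!r}", stacklevel=2)
            continue
        total += np.abs(x[:, None] - x[None, :]) / rng_
        n_used += 1
    if categorical_variable is not None:
        cat = desc[categorical_variable].to_numpy()
        total += (cat[:, None] != cat[None, :]).astype(float)
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable Gower variables")
    d = total / n_used
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ChemoTree:
    """Ultrametric dendrogram over molecular formulae.

    Built from a scipy linkage matrix. Tips are numbered 0..n-1 in the order
    of ``labels``; merge node i has id n+i and height ``linkage_matrix[i, 2]``
    (tips sit at height 0). The branch length of an edge is the height
    difference between parent and child.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    method: str = "average"
    _tip_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage_matrix.shape != (n - 1, 4):
            raise ValueError("linkage matrix inconsistent with label count")
        self._tip_index = {lab: i for i, lab in enumerate(self.labels)}
        self.children = self.linkage_matrix[:, :2].astype(np.intp)
        self.heights = np.concatenate([np.zeros(n), self.linkage_matrix[:, 2]])

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    def tip_indices(self, tips) -> np.ndarray:
        try:
            return np.array([self._tip_index[t] for t in tips], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"tip {e.args[0]!r} not in tree") from None

    def total_branch_length(self) -> float:
        n = self.n_tips
        parents = self.heights[n:]
        return float(
            sum(
                (parents[i] - self.heights[a]) + (parents[i] - self.heights[b])
                for i, (a, b) in enumerate(self.children)
            )
        )

    def subset_pathlengths(self, selection: np.ndarray) -> np.ndarray:
        """Spanning-subtree pathlength for each row of a tip-selection matrix.

        ``selection`` is boolean, shape (m, n_tips). For each row, an edge
        from child c to its parent is counted iff the subtree below c
        contains at least one but not all selected tips (edges at and above
        the most recent common ancestor are excluded). A single selected tip
        yields 0; selecting every tip yields the total branch length.
        """
        selection = np.atleast_2d(np.asarray(selection, dtype=bool))
        n = self.n_tips
        if selection.shape[1] != n:
            raise ValueError("selection width must equal the number of tips")
        m = selection.shape[0]
        counts = np.zeros((m, 2 * n - 1), dtype=np.int64)
        counts[:, :n] = selection
        k = selection.sum(axis=1)
        div = np.zeros(m)
        for i, (a, b) in enumerate(self.children):
            ca = counts[:, a]
            cb = counts[:, b]
            counts[:, n + i] = ca + cb
            h = self.heights[n + i]
            div += (h - self.heights[a]) * ((ca >= 1) & (ca < k))
            div += (h - self.heights[b]) * ((cb >= 1) & (cb < k))
        return div

    def cophenetic_matrix(self) -> np.ndarray:
        """Dense cophenetic distance matrix (merge height of each tip pair)."""
        if not hasattr(self, "_cophenetic"):
            from scipy.cluster.hierarchy import cophenet

            self._cophenetic = squareform(cophenet(self.linkage_matrix))
        return self._cophenetic

    def to_newick(self) -> str:
        """Newick serialization with branch lengths."""
        n = self.n_tips
        node = list(self.labels)
        for i, (a, b) in enumerate(self.children):
            h = self.heights[n + i]
            la = h - self.heights[a]
            lb = h - self.heights[b]
            node.append(f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})")
        return node[-1] + ";"


def build_dendrogram(dist: np.ndarray, labels: list[str], method: str = "average") -> ChemoTree:
    """Agglomerative dendrogram from a pairwise distance matrix.

    Average linkage (UPGMA) by default, which yields an ultrametric tree;
    ``complete`` and ``ward`` are accepted alternatives. Deterministic given
    the input order (scipy's tie-breaking is by earliest cluster index).
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if dist.shape[0] != len(labels):
        raise ValueError("labels inconsistent with distance matrix")
    if (dist < 0).any():
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    z = linkage(squareform(dist, checks=False), method=method)
    return ChemoTree(linkage_matrix=z, labels=list(labels), method=method)


def pathlength_diversity(tree: ChemoTree, tip_set) -> float:
    """Total branch length of the minimal subtree spanning ``tip_set``.

    Branches above the spanning subtree's most recent common ancestor are
    excluded; a single tip has diversity 0.
    """
    tips = list(tip_set)
    if len(tips) < 1:
        raise ValueError("tip_set must contain at least one tip")
    sel = np.zeros((1, tree.n_tips), dtype=bool)
    sel[0, tree.tip_indices(tips)] = True
    return float(tree.subset_pathlengths(sel)[0])


def mean_cophenetic_distance(tree: ChemoTree, tip_set) -> float:
    """Mean pairwise cophenetic distance among a tip set.

    Alternative diversity statistic to the spanning-subtree pathlength: the
    average dendrogram height at which two selected compounds merge. A single
    tip has diversity 0.
    """
    tips = list(tip_set)
    if len(tips) < 1:
        raise ValueError("tip_set must contain at least one tip")
    if len(tips) == 1:
        return 0.0
    idx = tree.tip_indices(tips)
    sub = tree.cophenetic_matrix()[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub.sum() / (n * (n - 1)))


def rarefy_by_intensity(d: Dataset, seed: int) -> dict[str, frozenset]:
    """Equalize total raw signal across samples by weighted subsampling.

    For each non-blank sample, compounds are drawn without replacement with
    probability proportional to raw intensity until the cumulative intensity
    first reaches the lowest per-sample total in the dataset (the draw that
    crosses the threshold is kept, so the target may be overshot by one
    compound). Samples already at the minimum keep all their compounds.
    Returns per-sample presence sets of formula strings.
    """
    if d.normalized:
        raise ValueError("rarefaction requires raw (pre-normalization) intensities")
    samples = [s for s in d.samples if s.role == "sample"]
    totals = {s.sample_id: float(d.intensities[s.sample_id].sum()) for s in samples}
    if min(totals.values()) <= 0:
        bad = [k for k, v in totals.items() if v <= 0]
        raise ValueError(f"non-positive total intensity in sample(s): {bad}")
    target = min(totals.values())
    out: dict[str, frozenset] = {}
    for j, s in enumerate(samples):
        col = d.intensities[s.sample_id].to_numpy(dtype=float)
        present = np.flatnonzero(col > 0)
        if totals[s.sample_id] <= target:
            out[s.sample_id] = frozenset(d.intensities.index[present])
            continue
        rng = np.random.default_rng([seed, j])
        w = col[present]
        # exponential-race keys give a weighted without-replacement order
        order = present[np.argsort(rng.exponential(size=len(present)) / w)]
        csum = np.cumsum(col[order])
        n_keep = int(np.searchsorted(csum, target, side="left")) + 1
        out[s.sample_id] = frozenset(d.intensities.index[order[:n_keep]])
    return out


@dataclass
class ChemodiversityEstimate:
    """Iterated pathlength-diversity estimates for one sample."""

    sample_id: str
    values: np.ndarray
    subsample_size: int
    n_iterations: int
    seed: int | tuple
    degenerate: bool = False  # presence set not larger than subsample_size

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_iterations:
            raise ValueError("values length must equal n_iterations")
        if (self.values < 0).any():
            raise ValueError("diversity values must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def estimate_chemodiversity(
    presence_set,
    tree: ChemoTree,
    subsample_size: int = SUBSAMPLE_SIZE,
    n_iterations: int = N_ITERATIONS,
    seed: int | tuple = 0,
    sample_id: str = "",
    statistic: str = "spanning",
) -> ChemodiversityEstimate:
    """Iterated fixed-size subsampling of a presence set on a shared tree.

    Per iteration, ``min(subsample_size, |presence_set|)`` compounds are
    drawn uniformly without replacement and the diversity statistic computed:
    ``"spanning"`` (default) is the spanning-subtree pathlength,
    ``"cophenetic"`` the mean pairwise cophenetic distance. The estimate
    deliberately ignores intensity: it reflects the presence or absence of
    chemically distinct moieties. If the presence set is not larger than the
    subsample size every iteration uses the whole set and the estimate has
    zero variance (flagged ``degenerate``).
    """
    if statistic not in ("spanning", "cophenetic"):
        raise ValueError("statistic must be 'spanning' or 'cophenetic'")
    tips = sorted(presence_set)
    if not tips:
        raise ValueError("empty presence set")
    idx = tree.tip_indices(tips)
    k = min(subsample_size, len(idx))
    rng = np.random.default_rng(seed)
    draws = [
        idx if k == len(idx) else rng.choice(idx, size=k, replace=False)
        for _ in range(n_iterations)
    ]
    if statistic == "spanning":
        sel = np.zeros((n_iterations, tree.n_tips), dtype=bool)
        for i, drawn in enumerate(draws):
            sel[i, drawn] = True
        values = tree.subset_pathlengths(sel)
    else:
        coph = tree.cophenetic_matrix()
        values = np.array(
            [coph[np.ix_(drawn, drawn)].sum() / (k * (k - 1)) if k > 1 else 0.0 for drawn in draws]
        )
    return ChemodiversityEstimate(
        sample_id=sample_id,
        values=values,
        subsample_size=subsample_size,
        n_iterations=n_iterations,
        seed=seed,
        degenerate=k == len(idx),
    )


def rao_q(p: np.ndarray, dist: np.ndarray) -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij p_i p_j.

    ``p`` are relative intensities over the compounds present (must sum to 1
    within 1e-6); ``dist`` is their pairwise Gower distance matrix. Q is the
    expected chemical distance between two randomly drawn intensity units.
    """
    p = np.asarray(p, dtype=float)
    dist = np.asarray(dist, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"relative intensities sum to {p.sum():.8f}, not 1")
    if dist.shape != (len(p), len(p)):
        raise ValueError("distance matrix shape inconsistent with p")
    return float(p @ dist @ p)


def chemodiversity_analysis(
    d: Dataset,
    descriptors: pd.DataFrame,
    subsample_size: int = SUBSAMPLE_SIZE,
    n_iterations: int = N_ITERATIONS,
    seed: int = 0,
    method: str = "average",
    rarefy: bool = True,
    statistic: str = "spanning",
) -> tuple[pd.DataFrame, ChemoTree]:
    """Full chemodiversity stage over a filtered (unnormalized) dataset.

    One dendrogram is built on the union of all formulae in the dataset and
    shared by every sample, so estimates live in a common metric space.
    Samples are rarefied by intensity, then each presence set is iterated.
    Returns a long-format table (sample_id, iteration, diversity) and the
    shared tree.
    """
    order = list(d.intensities.index)
    desc = descriptors.loc[order]
    dist = gower_distance(desc)
    tree = build_dendrogram(dist, order, method=method)
    if rarefy:
        presence = rarefy_by_intensity(d, seed=seed)
    else:
        presence = {
            s.sample_id: frozenset(d.intensities.index[d.intensities[s.sample_id] > 0])
            for s in d.samples
            if s.role == "sample"
        }
    rows = []
    for j, (sid, pres) in enumerate(sorted(presence.items())):
        est = estimate_chemodiversity(
            pres, tree, subsample_size, n_iterations, seed=[seed, 1, j], sample_id=sid,
            statistic=statistic,
        )
        rows.append(
            pd.DataFrame(
                {"sample_id": sid, "iteration": np.arange(n_iterations), "diversity": est.values}
            )
        )
    return pd.concat(rows, ignore_index=True), tree


def percent_change_vs_control(estimates: pd.DataFrame, samples) -> pd.DataFrame:
    """Percent change of mean chemodiversity in treatments versus controls.

    For each (lake, treatment, timepoint): 100 * (mean_D_treatment -
    mean_D_control) / mean_D_control, means taken over replicates and
    iterations. Also reports, per (lake, treatment), the average across
    timepoints and the temporal trend (percent change of the treatment's own
    estimates from the first to the last timepoint).
    """
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "lake": [s.lake for s in samples],
            "treatment": [s.treatment for s in samples],
            "timepoint_h": [s.timepoint_h for s in samples],
            "role": [s.role for s in samples],
        }
    )
    df = estimates.merge(meta, on="sample_id")
    df = df[df["role"] == "sample"]
    grp = df.groupby(["lake", "treatment", "timepoint_h"])["diversity"].mean()
    rows = []
    for (lake, treatment, tp), mean_treat in grp.items():
        if treatment == "control":
            continue
        try:
            mean_ctrl = grp.loc[(lake, "control", tp)]
        except KeyError:
            raise ValueError(f"missing control for lake={lake!r}, timepoint={tp!r}") from None
        rows.append(
            {
                "lake": lake,
                "treatment": treatment,
                "timepoint_h": tp,
                "mean_treatment": mean_treat,
                "mean_control": mean_ctrl,
                "pct_change": (mean_treat - mean_ctrl) / mean_ctrl * 100.0,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no treatment samples found")
    # temporal trend of the treatment's own estimates, first -> last timepoint
    trends = []
    for (lake, treatment), sub in df[df["treatment"] != "control"].groupby(["lake", "treatment"]):
        tps = sorted(sub["timepoint_h"].unique())
        first = sub.loc[sub["timepoint_h"] == tps[0], "diversity"].mean()
        last = sub.loc[sub["timepoint_h"] == tps[-1], "diversity"].mean()
        trends.append(
            {
                "lake": lake,
                "treatment": treatment,
                "temporal_trend_pct": (last - first) / first * 100.0,
            }
        )
    return out.merge(pd.DataFrame(trends), on=["lake", "treatment"])
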