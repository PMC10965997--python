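"""Synthetic FT-ICR MS experiments with known ground truth.

Emulates the statistical structure of a treeline soil-amendment experiment:
two lakes (alpine, subarctic), three treatments (control, S-Above, S-Below),
four in situ timepoints with triplicates, a large shared "ubiquitous"
formula pool, treatment-specific formula additions biased by compound
class, multiplicative log-normal replicate noise, blank/contaminant peaks,
per-compound exponential decay with Gamma-distributed rates, and long-term
bulk DOC decay curves.

The two amendments differ in how their added formulae relate to the lake
pool: S-Above (local soil, above the treeline) contributes mostly compounds
chemically *nested* within the existing pool — close neighbours of core
formulae in descriptor space — whereas S-Below (soil from below the
treeline) contributes chemically *novel* compounds drawn from categories the
lake pool underrepresents (polyphenolic and highly unsaturated moieties).
Every generated formula passes the assignment validity rules by
construction, and a ground-truth record (origin label, true decay rate,
true bulk RC parameters, true enrichment status) enables parameter-recovery
tests of every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .descriptors import CATEGORY8, descriptor_table
from .formula import MolecularFormula, format_formula, validate_counts
from .io import Dataset, SampleSpec

#: In situ incubation sampling times (hours).
TIMEPOINTS_INSITU_H = (0.0, 6.0, 24.0, 72.0)

#: Long-term laboratory incubation sampling times (days).
TIMEPOINTS_LONGTERM_D = (0.0, 0.5, 1.0, 3.0, 5.0, 7.0, 12.0, 22.0, 40.0, 58.0, 81.0)

#: Category composition of the lake-water core pool: dominated by highly
#: unsaturated material, as is typical for lake DOM.
CORE_CATEGORY_WEIGHTS = {
    "oxygen-poor highly unsaturated": 0.36,
    "oxygen-rich highly unsaturated": 0.30,
    "oxygen-poor unsaturated aliphatic": 0.12,
    "oxygen-rich unsaturated aliphatic": 0.10,
    "polyphenols": 0.015,
    "oxygen-poor polyphenols": 0.015,
    "saturated fatty acids (CHO)": 0.04,
    "saturated fatty acids (CHOX)": 0.04,
}

#: Added-formula category bias per treatment. S-Below is weighted to
#: polyphenolic / highly unsaturated compounds; S-Above to saturated /
#: unsaturated, heteroatom-rich material.
DEFAULT_CLASS_BIAS = {
    "s_above": {
        "saturated fatty acids (CHO)": 0.22,
        "saturated fatty acids (CHOX)": 0.22,
        "oxygen-poor unsaturated aliphatic": 0.22,
        "oxygen-rich unsaturated aliphatic": 0.22,
        "oxygen-poor highly unsaturated": 0.06,
        "oxygen-rich highly unsaturated": 0.06,
    },
    "s_below": {
        "polyphenols": 0.30,
        "oxygen-poor polyphenols": 0.30,
        "oxygen-poor highly unsaturated": 0.20,
        "oxygen-rich highly unsaturated": 0.20,
    },
}

#: Probability that an added formula is a nearest chemical neighbour of a
#: core formula (nested) rather than a class-bias draw (novel).
DEFAULT_NESTEDNESS = {"s_above": 0.85, "s_below": 0.10}


@dataclass
class SimConfig:
    """Study-design parameters of a synthetic amendment experiment.

    Defaults mirror the field conditions the analysis assumes: ~2500 core
    formulae shared between lake water and amendments, an 85-88% overlap of
    amended samples with the lake pool, triplicates at 0/6/24/72 h, and a
    Gamma(shape=nu, rate=alpha) reactivity continuum in units of 1/day.
    """

    n_core_formulae: int = 2500
    overlap_fraction: float = 0.865
    n_added_above: int | None = None
    n_added_below: int | None = None
    n_blank_contaminants: int = 25
    class_bias: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_BIAS.items()})
    nestedness: dict = field(default_factory=lambda: dict(DEFAULT_NESTEDNESS))
    noise_cv: float = 0.2
    decay_alpha: float = 5.0  # days
    decay_nu: float = 0.3
    fraction_accumulating: float = 0.1
    enriched_core_fraction: dict = field(
        default_factory=lambda: {"s_above": 0.08, "s_below": 0.28}
    )
    enrichment_boost: float = 2.5
    soil_intensity_scale: float = 1.5
    amended_intensity_excess: float = 0.10
    n_soil_clusters: int = 12
    timepoints_insitu: tuple = TIMEPOINTS_INSITU_H
    timepoints_longterm: tuple = TIMEPOINTS_LONGTERM_D
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.n_core_formulae <= 0 or self.n_blank_contaminants < 0:
            raise ValueError("counts must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (self.decay_alpha > 0 and self.decay_nu > 0):
            raise ValueError("decay_alpha and decay_nu must be positive")
        if not 0 <= self.fraction_accumulating < 1:
            raise ValueError("fraction_accumulating must be in [0, 1)")
        for tps in (self.timepoints_insitu, self.timepoints_longterm):
            if any(b <= a for a, b in zip(tps, tps[1:])):
                raise ValueError("timepoints must be strictly increasing")
        for trt, bias in self.class_bias.items():
            unknown = set(bias) - set(CATEGORY8)
            if unknown:
                raise ValueError(f"class_bias[{trt!r}] names unknown categories: {sorted(unknown)}")

    @property
    def n_added(self) -> dict[str, int]:
        """Added-formula counts per treatment, derived from the overlap.

        With amended samples containing core plus added formulae, the shared
        fraction is n_core / (n_core + n_added), so the default count is
        n_core * (1 - overlap) / overlap.
        """
        derived = round(self.n_core_formulae * (1 - self.overlap_fraction) / self.overlap_fraction)
        return {
            "s_above": self.n_added_above if self.n_added_above is not None else derived,
            "s_below": self.n_added_below if self.n_added_below is not None else derived,
        }


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests.

    ``table`` has one row per formula: origin label (core | soil_above |
    soil_below | blank_contaminant), the true in situ rate (d ln I / dt,
    1/day; negative = degradation), the long-term decay rate (1/day,
    positive) and the base intensity. ``rc_alpha``/``rc_nu`` are the bulk
    reactivity-continuum parameters; ``enrichment`` maps treatment to the
    set of formulae truly added or intensity-boosted in it.
    """

    table: pd.DataFrame
    rc_alpha: float
    rc_nu: float
    enrichment: dict[str, set]

    def origin(self, label: str) -> list[str]:
        return list(self.table.index[self.table["origin"] == label])


# ---------------------------------------------------------------------------
# formula universe
# ---------------------------------------------------------------------------


def _candidate_pool(n_draw: int, rng: np.random.Generator) -> pd.DataFrame:
    """Random valid CHONSP compositions with descriptors, deduplicated."""
    c = rng.integers(4, 41, size=n_draw)
    h_lo = np.ceil(0.3 * c).astype(int)
    h_hi = 2 * c + 2
    h = rng.integers(h_lo, np.minimum(h_hi, 82) + 1)
    o = rng.integers(1, np.minimum(c, 40) + 1)
    # heteroatom patterns: mostly CHO, some single-heteroatom, a few
    # whitelisted combinations
    pattern = rng.choice(6, size=n_draw, p=[0.55, 0.18, 0.08, 0.04, 0.1, 0.05])
    n = np.zeros(n_draw, dtype=int)
    s = np.zeros(n_draw, dtype=int)
    p = np.zeros(n_draw, dtype=int)
    n[pattern == 1] = rng.integers(1, 5, size=(pattern == 1).sum())
    s[pattern == 2] = 1
    p[pattern == 3] = 1
    n[pattern == 4] = rng.integers(2, 5, size=(pattern == 4).sum())  # Nx*S
    s[pattern == 4] = 1
    n[pattern == 5] = rng.integers(2, 4, size=(pattern == 5).sum())  # Nx*P
    p[pattern == 5] = 1
    ok = validate_counts(c, h, o, n, s, p)
    df = pd.DataFrame({"c": c[ok], "h": h[ok], "o": o[ok], "n": n[ok], "s": s[ok], "p": p[ok]})
    df = df.drop_duplicates()
    formulas = [
        MolecularFormula(C=int(r.c), H=int(r.h), O=int(r.o), N=int(r.n), S=int(r.s), P=int(r.p))
        for r in df.itertuples(index=False)
    ]
    desc = descriptor_table(formulas)
    return desc[~desc.index.duplicated()]


def generate_formula_pool(n: int, seed: int, category_weights: dict | None = None) -> pd.DataFrame:
    """Descriptor table of ``n`` distinct valid formulae spanning all classes.

    Candidates are rejection-sampled over the allowed element ranges, then
    ``n`` are drawn without replacement with per-formula probability
    proportional to ``category_weights[category] / category size``, so the
    realized category composition tracks the requested weights. One formula
    from every non-empty category is always included, which populates all
    eight van Krevelen categories for any reasonable ``n``.
    """
    rng = np.random.default_rng(seed)
    weights = dict(category_weights or CORE_CATEGORY_WEIGHTS)
    pool = _candidate_pool(max(40 * n, 20000), rng)
    if len(pool) < n:
        pool = pd.concat([pool, _candidate_pool(80 * n, rng)])
        pool = pool[~pool.index.duplicated()]
    if len(pool) < n:
        raise ValueError(f"cannot reach {n} distinct valid formulae (got {len(pool)})")
    cat = pool["category8"].to_numpy()
    counts = pd.Series(cat).value_counts()
    w = np.array([weights.get(c, 0.01) / counts[c] for c in cat], dtype=float)
    # guarantee each represented category appears at least once
    first_of_cat = pd.Series(np.arange(len(cat))).groupby(cat).first().to_numpy()
    chosen = set(first_of_cat[:n])
    w[list(chosen)] = 0.0
    if len(chosen) < n:
        extra = rng.choice(len(cat), size=n - len(chosen), replace=False, p=w / w.sum())
        chosen.update(extra.tolist())
    out = pool.iloc[sorted(chosen)]
    return out.iloc[rng.permutation(len(out))]


def generate_formula_universe(n: int, seed: int) -> list[MolecularFormula]:
    """``n`` distinct valid molecular formulae covering the van Krevelen plane."""
    desc = generate_formula_pool(n, seed)
    return [
        MolecularFormula(C=int(r.c), H=int(r.h), O=int(r.o), N=int(r.n), S=int(r.s), P=int(r.p))
        for r in desc.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# decay-rate draws
# ---------------------------------------------------------------------------


def draw_gamma_rates(
    n: int, alpha: float, nu: float, rng: np.random.Generator, stratified: bool = True
) -> np.ndarray:
    """Per-compound first-order rates from Gamma(shape=nu, rate=alpha).

    With ``stratified`` (default) the draws are the shuffled mid-probability
    quantiles of the Gamma distribution — a variance-reduced sample whose
    marginal is exact and whose mixture of exponentials converges to the
    closed-form bulk curve much faster than an i.i.d. sample.
    """
    if not (alpha > 0 and nu > 0):
        raise ValueError("alpha and nu must be positive")
    if stratified:
        q = (np.arange(n) + 0.5) / n
        k = stats.gamma.ppf(q, a=nu, scale=1.0 / alpha)
        return rng.permutation(k)
    return rng.gamma(shape=nu, scale=1.0 / alpha, size=n)


def _lognormal_factors(cv: float, shape, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative mean-1 log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(() if shape is None else shape)
    sigma2 = math.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=shape)


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------


def _select_additions(
    pool: pd.DataFrame,
    core_idx: np.ndarray,
    available: np.ndarray,
    n_add: int,
    bias: dict,
    nestedness: float,
    rng: np.random.Generator,
    n_clusters: int = 12,
) -> np.ndarray:
    """Pick added formulae: nested (near core) vs novel (class-biased) draws."""
    if n_add == 0:
        return np.array([], dtype=int)
    numeric = pool[["o_to_c", "h_to_c", "mass", "ai_mod", "dbe"]].to_numpy(dtype=float)
    scale = numeric.max(axis=0) - numeric.min(axis=0)
    scale[scale == 0] = 1.0
    z = numeric / scale
    n_nested = int(round(nestedness * n_add))
    chosen: list[int] = []
    avail_mask = np.zeros(len(pool), dtype=bool)
    avail_mask[available] = True
    if n_nested > 0:
        tree = cKDTree(z[available])
        # soil DOM is chemically coherent: nested additions pile up around a
        # handful of core anchor compounds rather than scattering uniformly
        centers = rng.choice(core_idx, size=min(n_clusters, len(core_idx)), replace=False)
        anchors = rng.choice(centers, size=n_nested, replace=True)
        taken = set()
        k = 1
        need = list(anchors)
        while need and k <= 64:
            _, nn = tree.query(z[need], k=k)
            nn = np.asarray(nn).reshape(len(need), k)
            still = []
            for row, a in zip(nn, need):
                cand = int(available[row[-1]])
                if cand not in taken:
                    taken.add(cand)
                    chosen.append(cand)
                else:
                    still.append(a)
            need = still
            k *= 2
        avail_mask[chosen] = False
    n_novel = n_add - len(chosen)
    if n_novel > 0:
        rem = np.flatnonzero(avail_mask)
        cat = pool["category8"].to_numpy()[rem]
        counts = pd.Series(cat).value_counts()
        w = np.array([bias.get(c, 0.0) / counts[c] for c in cat], dtype=float)
        if w.sum() == 0:
            w = np.ones(len(rem))
        novel = rng.choice(rem, size=n_novel, replace=False, p=w / w.sum())
        chosen.extend(novel.tolist())
    return np.array(chosen, dtype=int)


def generate_experiment(cfg: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate the full in situ amendment experiment.

    Returns the raw (unfiltered, unnormalized) peak table — 2 lakes x 3
    treatments x 4 timepoints x 3 replicates plus one blank per lake — and
    the ground truth. Control samples contain only core formulae; amended
    samples contain core plus treatment-specific additions; contaminant
    formulae are spiked into every sample including the blanks; replicate
    intensities are mean-1 log-normal perturbations of the sample mean.
    """
    rng = np.random.default_rng(cfg.seed)
    n_added = cfg.n_added
    n_total = cfg.n_core_formulae + sum(n_added.values()) + cfg.n_blank_contaminants
    pool = generate_formula_pool(
        max(int(1.8 * n_total), n_total + 500), seed=int(rng.integers(2**31))
    )

    # partition the pool: core first (by core category weights, already the
    # pool's sampling bias), then treatment additions, then contaminants
    core_idx = np.arange(cfg.n_core_formulae)
    available = np.arange(cfg.n_core_formulae, len(pool))
    added_idx: dict[str, np.ndarray] = {}
    for trt in ("s_above", "s_below"):
        sel = _select_additions(
            pool,
            core_idx,
            available,
            n_added[trt],
            cfg.class_bias.get(trt, {}),
            cfg.nestedness.get(trt, 0.0),
            rng,
            n_clusters=cfg.n_soil_clusters,
        )
        added_idx[trt] = sel
        available = np.setdiff1d(available, sel)
    contam_idx = rng.choice(available, size=cfg.n_blank_contaminants, replace=False)

    origin = pd.Series("unused", index=pool.index)
    origin.iloc[core_idx] = "core"
    origin.iloc[added_idx["s_above"]] = "soil_above"
    origin.iloc[added_idx["s_below"]] = "soil_below"
    origin.iloc[contam_idx] = "blank_contaminant"
    used = origin != "unused"
    pool = pool[used]
    origin = origin[used]
    names = list(pool.index)
    m = len(names)

    # true kinetics: gamma decay rates, a fraction accumulating instead
    k = draw_gamma_rates(m, cfg.decay_alpha, cfg.decay_nu, rng)
    sign = np.where(rng.random(m) < cfg.fraction_accumulating, 1.0, -1.0)
    rate_insitu = sign * k  # d ln I / dt, 1/day
    k_longterm = draw_gamma_rates(m, cfg.decay_alpha, cfg.decay_nu, rng)

    base = rng.lognormal(mean=math.log(1e6), sigma=1.0, size=m)
    soil_scale = np.where(
        np.isin(origin.to_numpy(), ["soil_above", "soil_below"]), cfg.soil_intensity_scale, 1.0
    )
    base = base * soil_scale

    truth_table = pd.DataFrame(
        {
            "origin": origin.to_numpy(),
            "true_rate_per_day": rate_insitu,
            "true_longterm_rate_per_day": k_longterm,
            "base_intensity": base,
        },
        index=pd.Index(names, name="formula"),
    )

    # treatment-specific intensity boosts of existing core compounds
    enrichment: dict[str, set] = {}
    boost = pd.DataFrame(1.0, index=truth_table.index, columns=["s_above", "s_below"])
    core_names = truth_table.index[truth_table["origin"] == "core"]
    for trt in ("s_above", "s_below"):
        n_boost = int(round(cfg.enriched_core_fraction.get(trt, 0.0) * len(core_names)))
        boosted = rng.choice(core_names, size=n_boost, replace=False)
        boost.loc[boosted, trt] = cfg.enrichment_boost
        added_names = truth_table.index[origin.to_numpy() == f"soil_{trt.split('_')[1]}"]
        enrichment[trt] = set(boosted) | set(added_names)

    # assemble sample columns
    lake_factor = {"alpine": 1.0, "subarctic": 1.2}
    samples: list[SampleSpec] = []
    columns: dict[str, np.ndarray] = {}
    is_origin = {
        "control": origin.isin(["core", "blank_contaminant"]).to_numpy(),
        "s_above": origin.isin(["core", "soil_above", "blank_contaminant"]).to_numpy(),
        "s_below": origin.isin(["core", "soil_below", "blank_contaminant"]).to_numpy(),
    }
    decay_day = truth_table["true_rate_per_day"].to_numpy()
    for lake in ("alpine", "subarctic"):
        for treatment in ("control", "s_above", "s_below"):
            present = is_origin[treatment]
            for tp in cfg.timepoints_insitu:
                mean = base * lake_factor[lake] * np.exp(decay_day * tp / 24.0)
                mean = mean * np.where(present, boost[treatment] if treatment != "control" else 1.0, 0.0)
                mean = np.where(present, mean, 0.0)
                for rep in (1, 2, 3):
                    sid = f"{lake}_{treatment}_t{int(tp)}_r{rep}"
                    noise = _lognormal_factors(cfg.noise_cv, m, rng)
                    col = np.asarray(mean * noise, dtype=float)
                    # rescale to a common injected-signal level: amended
                    # samples run slightly hot, exercising rarefaction
                    excess = 1.0 + (cfg.amended_intensity_excess if treatment != "control" else 0.0)
                    target = 1e9 * excess * float(_lognormal_factors(cfg.noise_cv / 4.0, None, rng))
                    columns[sid] = col * (target / col.sum())
                    samples.append(
                        SampleSpec(
                            sample_id=sid,
                            lake=lake,
                            treatment=treatment,
                            timepoint_h=float(tp),
                            replicate=rep,
                            role="sample",
                        )
                    )
        # one blank per lake: contaminants only
        sid = f"{lake}_blank"
        blank = np.where(origin.to_numpy() == "blank_contaminant", base * 0.5, 0.0)
        columns[sid] = blank * _lognormal_factors(cfg.noise_cv, m, rng)
        samples.append(
            SampleSpec(
                sample_id=sid, lake=lake, treatment="control", timepoint_h=0.0, replicate=1, role="blank"
            )
        )

    intens = pd.DataFrame(columns, index=pd.Index(names, name="formula"))
    d = Dataset(intensities=intens, samples=samples)
    d.log(
        f"generate_experiment(seed={cfg.seed}): {m} formulae, "
        f"{len(samples)} samples, overlap target {cfg.overlap_fraction}"
    )
    truth = GroundTruth(
        table=truth_table, rc_alpha=cfg.decay_alpha, rc_nu=cfg.decay_nu, enrichment=enrichment
    )
    return d, truth


def realized_overlap(d: Dataset, lake: str, treatment: str) -> float:
    """Fraction of amended-sample formulae also detected in the control.

    Computed from the generated intensities: formulae detected (> 0) in any
    sample of the treatment, intersected with those detected in any control
    sample of the same lake.
    """
    treat_ids = [s.sample_id for s in d.select_samples(lake=lake, treatment=treatment, role="sample")]
    ctrl_ids = [s.sample_id for s in d.select_samples(lake=lake, treatment="control", role="sample")]
    in_treat = (d.intensities[treat_ids] > 0).any(axis=1)
    in_ctrl = (d.intensities[ctrl_ids] > 0).any(axis=1)
    return float((in_treat & in_ctrl).sum() / in_treat.sum())


# ---------------------------------------------------------------------------
# long-term decay series
# ---------------------------------------------------------------------------


def generate_decay_series(
    truth: GroundTruth,
    timepoints_d=TIMEPOINTS_LONGTERM_D,
    seed: int = 0,
    noise_cv: float = 0.01,
    weights: str = "equal",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-term bulk DOC decay and the per-compound intensity series.

    Each compound decays as I_i(t) = I_i(0) * exp(-k_i t) with the
    ground-truth long-term rates (1/day, Gamma-distributed). The bulk curve
    is the weighted mixture sum; with ``weights='equal'`` (default: all
    compounds contribute equal initial carbon) it converges to the
    closed-form RC law (alpha/(alpha+t))**nu, while ``weights='intensity'``
    uses the ground-truth base intensities. Returns

    * a bulk table with columns ``t_d, doc_frac, doc_frac_observed`` (the
      latter with mean-1 log-normal observation noise), and
    * the per-compound series (formulae x timepoints), noiseless.
    """
    t = np.asarray(timepoints_d, dtype=float)
    if t[0] != 0:
        raise ValueError("timepoints must start at 0")
    rng = np.random.default_rng(seed)
    k = truth.table["true_longterm_rate_per_day"].to_numpy()
    if weights == "equal":
        w = np.ones(len(k))
    elif weights == "intensity":
        w = truth.table["base_intensity"].to_numpy()
    else:
        raise ValueError("weights must be 'equal' or 'intensity'")
    series = w[:, None] * np.exp(-np.outer(k, t))
    bulk = series.sum(axis=0) / w.sum()
    observed = bulk * _lognormal_factors(noise_cv, len(t), rng)
    observed[t == 0] = bulk[t == 0]  # the series is defined relative to t=0
    bulk_df = pd.DataFrame({"t_d": t, "doc_frac": bulk, "doc_frac_observed": observed})
    compound_df = pd.DataFrame(
        series, index=truth.table.index, columns=[f"t{tt:g}d" for tt in t]
    )
    return bulk_df, compound_df


# ---------------------------------------------------------------------------
# bacterial rates
# ---------------------------------------------------------------------------

#: Mean bacterial production (ug C L^-1 h^-1) per (lake, treatment); S-Above
#: sustains higher production and growth efficiency than S-Below.
BP_MEANS = {
    ("alpine", "control"): 0.05,
    ("alpine", "s_above"): 0.20,
    ("alpine", "s_below"): 0.08,
    ("subarctic", "control"): 0.15,
    ("subarctic", "s_above"): 0.60,
    ("subarctic", "s_below"): 0.25,
}
BR_MEANS = {
    ("alpine", "control"): 0.45,
    ("alpine", "s_above"): 1.00,
    ("alpine", "s_below"): 0.90,
    ("subarctic", "control"): 0.60,
    ("subarctic", "s_above"): 1.20,
    ("subarctic", "s_below"): 1.50,
}


def generate_bacterial_rates(cfg: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulated bacterial production/respiration for the in situ design."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for (lake, trt), bp_mean in BP_MEANS.items():
        br_mean = BR_MEANS[(lake, trt)]
        for tp in cfg.timepoints_insitu:
            for rep in (1, 2, 3):
                bp = bp_mean * _lognormal_factors(max(cfg.noise_cv, 0.05), None, rng)
                br = br_mean * _lognormal_factors(max(cfg.noise_cv, 0.05), None, rng)
                rows.append(
                    {
                        "lake": lake,
                        "treatment": trt,
                        "timepoint_h": tp,
                        "replicate": rep,
                        "bp": float(bp),
                        "br": float(br),
                    }
                )
    return pd.DataFrame(rows)
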