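"""Endpoint arithmetic and the two-branch group-comparison procedure.

Endpoint arithmetic: caliper tumor volume ``V = (π/6)·d1²·d2`` (d1 the
shortest diameter, d2 the longest), fibrous-scar/tumor-cell area ratio,
and actin-normalized densitometry.

Group comparison follows the study's branching rule: if the parametric
conditions hold (Shapiro–Wilk normality per group and Levene variance
homogeneity, both at α = 0.05), a one-way ANOVA is run and, when the
omnibus P < α, Tukey's HSD post hoc pairwise tests; otherwise a
Kruskal–Wallis test followed, when significant, by Dunn's rank-based
pairwise tests with Holm multiplicity adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


@dataclass
class TumorMeasurement:
    d1_mm: float
    d2_mm: float
    day: int = 0

    @property
    def volume_mm3(self) -> float:
        return tumor_volume(self.d1_mm, self.d2_mm)


@dataclass
class ScarRatio:
    fibrous_area: float
    tumor_cell_area: float
    ratio: float
    complete_response: bool = False


@dataclass
class PairResult:
    pair: tuple[str, str]
    adjusted_p: float
    significant: bool


@dataclass
class GroupComparison:
    branch: str  # "parametric" | "nonparametric"
    omnibus_stat: float
    omnibus_p: float
    posthoc: list[PairResult] = field(default_factory=list)
    alpha: float = 0.05
    normality_p: dict[str, float] = field(default_factory=dict)
    homogeneity_p: float = math.nan

    @property
    def significant_pairs(self) -> set[tuple[str, str]]:
        return {p.pair for p in self.posthoc if p.significant}


def tumor_volume(d1_mm: float, d2_mm: float) -> float:
    """Caliper volume ``(π/6)·d1²·d2`` (mm³); d1 shortest, d2 longest.

    Swapped diameters are auto-corrected with a warning.
    """
    if d1_mm < 0 or d2_mm < 0:
        raise ValueError("diameters must be non-negative")
    if d1_mm > d2_mm:
        warnings.warn("d1 > d2; swapping so d1 is the shortest diameter")
        d1_mm, d2_mm = d2_mm, d1_mm
    return (math.pi / 6.0) * d1_mm**2 * d2_mm


def scar_ratio(fibrous_area: float, tumor_cell_area: float) -> ScarRatio:
    """Fibrous-scar area over tumor-cell area (cellularity plus necrosis).

    A zero tumor-cell area is a complete response: the ratio is reported
    as NaN with the ``complete_response`` flag, never infinity.
    """
    if fibrous_area < 0 or tumor_cell_area < 0:
        raise ValueError("areas must be non-negative")
    if tumor_cell_area == 0:
        return ScarRatio(fibrous_area, tumor_cell_area, math.nan, complete_response=True)
    return ScarRatio(fibrous_area, tumor_cell_area, fibrous_area / tumor_cell_area)


def normalize_band(target: float, actin: float) -> float:
    """Densitometry band normalized to the actin loading control."""
    if actin <= 0:
        raise ValueError("actin band must be positive")
    if target < 0:
        raise ValueError("target band must be non-negative")
    return target / actin


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, pd.DataFrame):
        return {
            str(name): g["value"].to_numpy(dtype=float)
            for name, g in groups.groupby("group", sort=True)
        }
    return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}


def dunn_test(
    samples: dict[str, np.ndarray], adjust: str = "holm"
) -> list[tuple[tuple[str, str], float, float]]:
    """Dunn's rank-based pairwise z tests with tie correction.

    Pools all observations, ranks them (mid-ranks for ties), and for each
    pair computes ``z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j))``
    where ``T = Σ(t³−t) / (12(N−1))`` corrects for ties.  Two-sided normal
    p-values are multiplicity-adjusted (Holm by default).

    Returns ``[(pair, raw_p, adjusted_p), ...]``.
    """
    names = list(samples)
    pooled = np.concatenate([samples[n] for n in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for n in names:
        k = len(samples[n])
        mean_ranks[n] = float(ranks[start:start + k].mean())
        sizes[n] = k
        start += k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs, raw = [], []
    for a, b in combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        pairs.append((a, b))
        raw.append(min(1.0, p))
    adj = multipletests(raw, method=adjust)[1] if raw else []
    return [(pairs[i], raw[i], float(adj[i])) for i in range(len(pairs))]


def parametric_conditions_met(
    samples: dict[str, np.ndarray], screen_alpha: float = 0.05
) -> tuple[bool, dict[str, float], float]:
    """Shapiro–Wilk per group plus Levene homogeneity, both at ``screen_alpha``."""
    norm_p = {}
    for name, x in samples.items():
        if np.ptp(x) == 0:
            norm_p[name] = 0.0  # degenerate: treat as non-normal
            continue
        norm_p[name] = float(stats.shapiro(x).pvalue)
    arrays = list(samples.values())
    if all(np.ptp(x) == 0 for x in arrays):
        lev_p = math.nan
    else:
        lev_p = float(stats.levene(*arrays).pvalue)
    ok = all(p > screen_alpha for p in norm_p.values()) and (
        math.isnan(lev_p) or lev_p > screen_alpha
    )
    return ok, norm_p, lev_p


def compare_groups(
    groups,
    alpha: float = 0.05,
    branch: str = "auto",
) -> GroupComparison:
    """Two-branch omnibus + post hoc comparison of ≥2 groups.

    Parameters
    ----------
    groups
        Mapping ``name -> 1D samples`` or a tidy DataFrame with
        ``group, value`` columns; every group needs n ≥ 3.
    branch
        ``"auto"`` screens normality/homogeneity; ``"parametric"`` or
        ``"nonparametric"`` force a branch.

    Post hoc pairwise tests (Tukey HSD or Dunn/Holm) run only when the
    omnibus P < ``alpha``.
    """
    samples = _as_groups(groups)
    if len(samples) < 2:
        raise ValueError("at least 2 groups required")
    if any(len(x) < 3 for x in samples.values()):
        raise ValueError("every group needs n >= 3")
    if branch not in ("auto", "parametric", "nonparametric"):
        raise ValueError("branch must be auto|parametric|nonparametric")

    norm_p: dict[str, float] = {}
    lev_p = math.nan
    if branch == "auto":
        ok, norm_p, lev_p = parametric_conditions_met(samples)
        branch = "parametric" if ok else "nonparametric"

    arrays = list(samples.values())
    names = list(samples)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # constant data everywhere: no evidence of difference
        return GroupComparison(
            branch=branch, omnibus_stat=0.0, omnibus_p=1.0,
            alpha=alpha, normality_p=norm_p, homogeneity_p=lev_p,
        )

    if branch == "parametric":
        stat, p = stats.f_oneway(*arrays)
    else:
        stat, p = stats.kruskal(*arrays)
    result = GroupComparison(
        branch=branch, omnibus_stat=float(stat), omnibus_p=float(p),
        alpha=alpha, normality_p=norm_p, homogeneity_p=lev_p,
    )
    if result.omnibus_p >= alpha:
        return result

    if branch == "parametric":
        labels = np.concatenate([[n] * len(samples[n]) for n in names])
        tk = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
        for (a, b), padj, rej in zip(
            combinations(sorted(names), 2), tk.pvalues, tk.reject
        ):
            result.posthoc.append(PairResult((a, b), float(padj), bool(rej)))
    else:
        for pair, _, padj in dunn_test(samples):
            result.posthoc.append(PairResult(pair, padj, padj < alpha))
    return result


def growth_curve_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM tumor volume per day per arm from a tidy caliper table.

    ``table`` columns: ``subject, group, day, d1_mm, d2_mm`` (or a
    precomputed ``volume_mm3``).
    """
    df = table.copy()
    if "volume_mm3" not in df.columns:
        df["volume_mm3"] = [
            tumor_volume(r.d1_mm, r.d2_mm) for r in df.itertuples()
        ]
    g = df.groupby(["group", "day"])["volume_mm3"]
    out = g.agg(mean="mean", n="count", sd=lambda s: s.std(ddof=1)).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")
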