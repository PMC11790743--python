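"""Male-delayed expression detection from time-course slopes.

The detector asks whether a gene's expression change happens one age
interval later in males than in females.  Per gene and sex, group mean
normalized counts at each age are scaled to a joint maximum of one, slopes
over consecutive age intervals are corrected for interval length in days
(divide by 4 for 3->7, by 7 for 7->14), and each interval is classified as
flat (|slope| <= cutoff), rising (slope > cutoff) or dropping
(slope < -cutoff) with cutoff 0.05 by default.  Among genes differentially
expressed in both the female early interval (F3v7) and the male late
interval (M7v14), delayed upregulation is the pattern female =
(rising, flat) with male = (flat, rising); delayed downregulation is the
mirrored decreasing pattern.

Boundary choice: a corrected slope of exactly +/-cutoff is classified flat
(the conservative side: fewer delay calls).  An optional mode-gap estimator
can replace the fixed cutoff: a kernel density over pooled |corrected
slopes| with the cutoff at the minimum between the first two modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelmin

from .data_model import SEXES, SampleDesign
from .errors import ConfigError, EstimationError

DEFAULT_SLOPE_CUTOFF = 0.05

PATTERNS = {
    "up": {"F": ("rising", "flat"), "M": ("flat", "rising")},
    "down": {"F": ("dropping", "flat"), "M": ("flat", "dropping")},
}


@dataclass
class SlopeProfile:
    """Per-gene, per-sex trajectory summaries over the three ages."""

    gene_id: str
    ages: tuple[int, ...]
    means: dict[str, np.ndarray]            # sex -> mean normalized count per age
    max_normalized: dict[str, np.ndarray]   # sex -> means / joint (or per-sex) max
    raw_slopes: dict[str, np.ndarray]       # sex -> per-interval delta
    corrected_slopes: dict[str, np.ndarray]  # sex -> delta / interval days
    patterns: dict[str, tuple[str, ...]]    # sex -> per-interval class
    degenerate: bool = False                # all-zero gene


@dataclass
class DelayCall:
    gene_id: str
    direction: str                      # 'up' or 'down'
    in_f_early_degs: bool
    in_m_late_degs: bool
    female_pattern: tuple[str, ...]
    male_pattern: tuple[str, ...]
    called: bool


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# Profile construction


def group_mean_profiles(
    normalized: pd.DataFrame, design: SampleDesign
) -> dict[tuple[str, int], pd.Series]:
    """Arithmetic mean of normalized counts per (sex, age) group."""
    groups = design.groups()
    for sex in SEXES:
        for age in design.ages:
            if (sex, age) not in groups:
                raise EstimationError(f"missing sex-age group ({sex}, {age})")
    return {key: normalized[samples].mean(axis=1) for key, samples in groups.items()}


def build_profiles(
    normalized: pd.DataFrame,
    design: SampleDesign,
    cutoff: float = DEFAULT_SLOPE_CUTOFF,
    normalize_scope: str = "joint",
) -> dict[str, SlopeProfile]:
    """Max-normalize, compute day-corrected slopes and classify every gene.

    ``normalize_scope`` 'joint' scales both sexes by one shared maximum
    (default; the two sexes then share one scale); 'per-sex' scales each
    sex by its own maximum.
    """
    ages = tuple(design.ages)
    if len(ages) != 3:
        raise ConfigError("the two-interval delay template requires exactly 3 ages")
    means = group_mean_profiles(normalized, design)
    mean_arr = {
        sex: np.column_stack([means[(sex, age)].to_numpy() for age in ages])
        for sex in SEXES
    }
    gene_ids = list(normalized.index)
    profiles: dict[str, SlopeProfile] = {}
    for i, gene in enumerate(gene_ids):
        gene_means = {sex: mean_arr[sex][i] for sex in SEXES}
        profiles[gene] = _profile_for_gene(gene, ages, gene_means, cutoff, normalize_scope)
    return profiles


def max_normalize_profile(
    means: dict[str, np.ndarray], scope: str = "joint"
) -> tuple[dict[str, np.ndarray], bool]:
    """Scale trajectory means to a maximum of one.

    Returns the scaled means and a degenerate flag (True when every mean is
    zero, in which case the profile passes through as all-zero).
    """
    if any((m < 0).any() for m in means.values()):
        raise ConfigError("negative means cannot arise from counts")
    if scope == "joint":
        peak = max(float(m.max()) for m in means.values())
        if peak == 0.0:
            return {s: m.copy() for s, m in means.items()}, True
        return {s: m / peak for s, m in means.items()}, False
    if scope == "per-sex":
        out = {}
        degenerate = False
        for s, m in means.items():
            peak = float(m.max())
            if peak == 0.0:
                out[s] = m.copy()
                degenerate = True
            else:
                out[s] = m / peak
        return out, degenerate
    raise ConfigError(f"unknown normalize scope {scope!r}")


def compute_slopes(
    values: np.ndarray, ages: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (later - earlier) and day-corrected slopes over consecutive ages."""
    ages_arr = np.asarray(ages, dtype=float)
    if (np.diff(ages_arr) <= 0).any():
        raise ConfigError("ages must be strictly increasing and distinct")
    raw = np.diff(values)
    corrected = raw / np.diff(ages_arr)
    return raw, corrected


def classify_pattern(corrected_slope: float, cutoff: float = DEFAULT_SLOPE_CUTOFF) -> str:
    """flat / rising / dropping; the |slope| == cutoff boundary is flat."""
    if np.isnan(corrected_slope):
        return "flat"
    if corrected_slope > cutoff:
        return "rising"
    if corrected_slope < -cutoff:
        return "dropping"
    return "flat"


def _profile_for_gene(
    gene: str,
    ages: tuple[int, ...],
    means: dict[str, np.ndarray],
    cutoff: float,
    scope: str,
) -> SlopeProfile:
    scaled, degenerate = max_normalize_profile(means, scope)
    raw_slopes, corrected, patterns = {}, {}, {}
    for sex, vals in scaled.items():
        r, c = compute_slopes(vals, ages)
        raw_slopes[sex] = r
        corrected[sex] = c
        patterns[sex] = tuple(classify_pattern(ci, cutoff) for ci in c)
    return SlopeProfile(gene, ages, means, scaled, raw_slopes, corrected, patterns, degenerate)


# ---------------------------------------------------------------------------
# Mode-gap cutoff (optional alternative to the fixed 0.05)


def mode_gap_cutoff(profiles: dict[str, SlopeProfile], fallback: float = DEFAULT_SLOPE_CUTOFF) -> float:
    """Cutoff at the density minimum between the first two modes of |slope|.

    Pools all corrected slopes, fits a Gaussian KDE to their absolute
    values, and returns the location of the first local minimum that sits
    between two local maxima.  Falls back to the fixed cutoff when the
    pooled density is unimodal.
    """
    pooled = np.concatenate(
        [np.abs(p.corrected_slopes[sex]) for p in profiles.values() for sex in SEXES]
    )
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size < 10 or np.ptp(pooled) == 0:
        return fallback
    kde = stats.gaussian_kde(pooled)
    grid = np.linspace(0.0, float(np.quantile(pooled, 0.99)), 512)
    density = kde(grid)
    minima = argrelmin(density)[0]
    if minima.size == 0:
        return fallback
    return float(grid[minima[0]])


# ---------------------------------------------------------------------------
# Delay detection


def detect_delayed(
    profiles: dict[str, SlopeProfile],
    deg_f_early: set[str],
    deg_m_late: set[str],
    universe: str = "intersect",
) -> list[DelayCall]:
    """Call delayed genes from slope patterns within the DEG candidate set.

    The candidate universe is the intersection (default) or union of the
    female early-interval and male late-interval DEG sets.  A call requires
    membership in both sets and the direction's pattern template in both
    sexes; evidence is retained for non-called candidates.
    """
    if universe == "intersect":
        candidates = deg_f_early & deg_m_late
    elif universe == "union":
        candidates = deg_f_early | deg_m_late
    else:
        raise ConfigError(f"unknown universe mode {universe!r}")
    missing = candidates - set(profiles)
    if missing:
        raise EstimationError(f"profiles missing for {len(missing)} candidate genes")
    if not candidates:
        warnings.warn("empty delay candidate universe", stacklevel=2)
        return []
    calls = []
    for gene in sorted(candidates):
        prof = profiles[gene]
        fp, mp = prof.patterns["F"], prof.patterns["M"]
        in_both = gene in deg_f_early and gene in deg_m_late
        direction, called = _match_direction(fp, mp)
        calls.append(
            DelayCall(
                gene_id=gene,
                direction=direction,
                in_f_early_degs=gene in deg_f_early,
                in_m_late_degs=gene in deg_m_late,
                female_pattern=fp,
                male_pattern=mp,
                called=called and in_both,
            )
        )
    return calls


def _match_direction(fp: tuple[str, ...], mp: tuple[str, ...]) -> tuple[str, bool]:
    for direction, template in PATTERNS.items():
        if fp == template["F"] and mp == template["M"]:
            return direction, True
    return "none", False


def calls_frame(calls: list[DelayCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "direction": [c.direction for c in calls],
            "in_f_early_degs": [c.in_f_early_degs for c in calls],
            "in_m_late_degs": [c.in_m_late_degs for c in calls],
            "female_pattern": ["|".join(c.female_pattern) for c in calls],
            "male_pattern": ["|".join(c.male_pattern) for c in calls],
            "called": [c.called for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# Cross-comparison summaries


def lfc_correlation(result_a, result_b, genes) -> CorrelationResult:
    """Pearson correlation of per-gene LFCs between two comparisons."""
    genes = sorted(genes)
    a = result_a.table["lfc"].reindex(genes)
    b = result_b.table["lfc"].reindex(genes)
    mask = a.notna() & b.notna()
    if mask.sum() < 3:
        raise EstimationError("need >= 3 shared genes with finite LFCs")
    r, p = stats.pearsonr(a[mask], b[mask])
    return CorrelationResult(float(r), float(p), int(mask.sum()))


def overlap_stats(deg_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Venn-style exclusive-region counts and percentages for 2-3 sets."""
    names = list(deg_sets)
    if not 2 <= len(names) <= 3:
        raise ConfigError("overlap_stats handles 2 or 3 sets")
    union = set().union(*deg_sets.values())
    rows = []
    # every nonempty membership signature
    for signature in range(1, 2 ** len(names)):
        inside = [names[i] for i in range(len(names)) if signature >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set.intersection(*(deg_sets[n] for n in inside))
        for n in outside:
            region -= deg_sets[n]
        rows.append(
            {
                "region": "&".join(inside),
                "exclusive_count": len(region),
                "percent_of_union": 100.0 * len(region) / len(union) if union else 0.0,
            }
        )
    return pd.DataFrame(rows)


def direction_concordance(result_a, result_b, genes) -> dict[str, int]:
    """Counts of shared genes up in both, down in both, or discordant."""
    genes = sorted(genes)
    a = result_a.table["lfc"].reindex(genes)
    b = result_b.table["lfc"].reindex(genes)
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    return {
        "up_in_both": int(((a > 0) & (b > 0)).sum()),
        "down_in_both": int(((a < 0) & (b < 0)).sum()),
        "discordant": int((((a > 0) & (b < 0)) | ((a < 0) & (b > 0))).sum()),
    }
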