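"""Negative-binomial Wald differential expression with median-of-ratios
normalization, moment-based dispersion estimation, empirical-Bayes LFC
shrinkage and Benjamini-Hochberg adjustment.

Model
-----
Counts for gene g in sample j are modelled as NB with mean ``sf_j * q_gA``
(group A) or ``sf_j * q_gB`` (group B) and variance ``mean + alpha_g *
mean**2``.  The two-group log-link GLM with a group indicator decomposes
into two independent one-parameter fits, so each group's log-mean is
obtained by a vectorized Newton iteration on its own samples; the Wald
statistic is the log2 fold-change over its standard error from expected
Fisher information.

Fidelity caveats (deliberate simplifications of the reference tooling this
mirrors): dispersion shrinkage is moments-plus-trend rather than a full
Cox-Reid MAP fit; LFC shrinkage uses a single zero-centred normal prior
fitted by marginal maximum likelihood rather than a mixture prior;
independent filtering and outlier replacement are not replicated (an
optional mean-count filter, default off, stands in).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .data_model import ComparisonSpec, ExpressionMatrix, SampleDesign, comparison_battery
from .errors import BatteryError, ConfigError, EstimationError

_LN2 = np.log(2.0)
_MAX_IRLS_ITER = 25
_IRLS_TOL = 1e-8

RESULT_COLUMNS = ["base_mean", "lfc", "lfc_shrunk", "se", "wald_z", "p_raw", "p_adj"]


@dataclass
class DEResult:
    """Per-gene Wald test results for one named comparison.

    ``table`` is indexed by gene id with columns base_mean, lfc, lfc_shrunk,
    se, wald_z, p_raw, p_adj.  LFC is log2(group B / group A); the
    orientation string states which group is which.
    """

    comparison: str
    orientation: str
    group_a: tuple[str, int]
    group_b: tuple[str, int]
    table: pd.DataFrame
    prior_var: float | None = None  # shrinkage prior variance, once fitted

    def degs(
        self,
        alpha_raw: float | None = 0.05,
        alpha_adj: float | None = None,
        direction: str | None = None,
    ) -> set[str]:
        """Gene ids passing the threshold(s); either threshold suffices.

        ``direction`` 'up'/'down' filters on the sign of the (unshrunk) LFC.
        """
        t = self.table
        mask = pd.Series(False, index=t.index)
        if alpha_raw is not None:
            mask |= t["p_raw"] < alpha_raw
        if alpha_adj is not None:
            mask |= t["p_adj"] < alpha_adj
        if direction == "up":
            mask &= t["lfc"] > 0
        elif direction == "down":
            mask &= t["lfc"] < 0
        elif direction is not None:
            raise ConfigError(f"unknown direction {direction!r}")
        return set(t.index[mask.fillna(False)])


# ---------------------------------------------------------------------------
# Normalization


def size_factors_median_of_ratios(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    The reference per gene is its geometric mean across samples; genes with
    any zero count are excluded from the reference set.  A sample's factor
    is the median of its count/reference ratios over surviving genes.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise EstimationError(
            "no gene has positive counts in every sample; "
            "median-of-ratios needs an all-positive reference set "
            "(pseudo-reference fallback is disabled)"
        )
    log_counts = np.log(counts[all_positive])
    log_geomean = log_counts.mean(axis=1)
    factors = np.exp(np.median(log_counts - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def normalize(matrix: ExpressionMatrix, factors: pd.Series) -> pd.DataFrame:
    """Counts divided by each sample's size factor."""
    missing = [s for s in matrix.sample_ids if s not in factors.index]
    if missing:
        raise EstimationError(f"size factors missing for samples {missing}")
    if (factors <= 0).any():
        raise EstimationError("size factors must be strictly positive")
    return matrix.counts / factors.reindex(matrix.sample_ids)


# ---------------------------------------------------------------------------
# Dispersion


def estimate_dispersion(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    factors: pd.Series,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments with trend shrinkage.

    On normalized counts, the pooled within-group variance s2 and overall
    mean m give the raw estimate ``alpha_hat = max(0, (s2 - m) / m**2)``.
    A mean-dispersion trend ``alpha(m) = a0 + a1/m`` is fitted across genes
    and each gene is shrunk toward it by an adaptive weighted average: the
    trend weight is var_sampling / (var_sampling + var_signal), where
    var_sampling approximates the chi-square sampling variance of the
    per-gene moment estimate at the available degrees of freedom and
    var_signal is the (robustly estimated) excess between-gene variance of
    the raw estimates around the trend.  Genes with few replicates are thus
    pulled strongly toward the trend — the information sharing that keeps
    Wald tests calibrated at three replicates per group — while dispersions
    estimated from many replicates stay essentially unshrunk.
    """
    norm = normalize(matrix, factors)
    groups = design.groups()
    sizes = {g: len(s) for g, s in groups.items()}
    df_total = sum(n - 1 for n in sizes.values() if n >= 2)
    if df_total == 0:
        raise EstimationError("no sex-age group has >= 2 replicates")

    ss = np.zeros(matrix.n_genes)
    for g, samp in groups.items():
        if len(samp) < 2:
            continue
        sub = norm[samp].to_numpy()
        ss += sub.var(axis=1, ddof=1) * (len(samp) - 1)
    pooled_var = ss / df_total
    mean = norm[design.sample_ids].to_numpy().mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - mean) / np.square(mean)
    raw = np.where(mean > 0, np.maximum(raw, 0.0), 0.0)
    raw = np.nan_to_num(raw, nan=0.0, posinf=0.0)

    trend = _fit_dispersion_trend(mean, raw)
    # sampling variance of the moment estimate: var(s2) ~ 2 sigma^4 / df with
    # sigma^2 = m + alpha_trend m^2, so var(alpha_hat) ~ 2 (1/m + alpha_trend)^2 / df
    with np.errstate(divide="ignore"):
        inv_mean = np.where(mean > 0, 1.0 / mean, np.inf)
    var_sampling = 2.0 * np.square(inv_mean + trend) / df_total
    resid = raw - trend
    informative = np.isfinite(var_sampling) & (mean > 0)
    if informative.any():
        mad = np.median(np.abs(resid[informative] - np.median(resid[informative])))
        var_total = (1.4826 * mad) ** 2
        var_signal = max(var_total - float(np.median(var_sampling[informative])), 0.0)
    else:
        var_signal = 0.0
    w_trend = np.where(
        np.isfinite(var_sampling),
        var_sampling / (var_sampling + var_signal + 1e-300),
        1.0,
    )
    shrunk = w_trend * trend + (1.0 - w_trend) * raw
    return pd.Series(np.maximum(shrunk, 0.0), index=matrix.gene_ids, name="dispersion")


def _fit_dispersion_trend(mean: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Fit alpha(m) = a0 + a1/m over genes with informative raw estimates.

    One round of trimming discards gross outliers so a handful of wild
    moment estimates cannot drag the trend; the cut is deliberately loose
    (10x the median residual) because the raw estimates are right-skewed
    and an aggressive trim would bias the trend downward.  Falls back to
    the median raw dispersion when too few genes inform the fit.
    """
    use = (mean > 0) & (raw > 1e-8)
    if use.sum() < 10:
        return np.full_like(raw, float(np.median(raw)) if raw.size else 0.0)
    x = 1.0 / mean[use]
    y = raw[use]
    for _ in range(2):
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = np.abs(y - A @ coef)
        keep = resid <= 10.0 * np.median(resid) + 1e-12
        if keep.all():
            break
        x, y = x[keep], y[keep]
    a0, a1 = coef
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mean > 0, mean, np.inf)
    return np.clip(trend, 0.0, None)


# ---------------------------------------------------------------------------
# Wald test


def _fit_group_log_means(
    counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Newton fit of per-gene log group means under the NB GLM with offsets.

    Returns (eta, info): eta is the log of the group mean on the normalized
    scale, info the expected Fisher information of eta.  Genes whose group
    total is zero get eta = -inf and info = 0.
    """
    total = counts.sum(axis=1)
    with np.errstate(divide="ignore"):
        eta = np.log(total / sf.sum())
    ok = total > 0
    for _ in range(_MAX_IRLS_ITER):
        mu = sf[None, :] * np.exp(eta[:, None])
        denom = 1.0 + alpha[:, None] * mu
        score = ((counts - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(ok & (info > 0), score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -10.0, 10.0)
        eta = np.where(ok, eta + step, eta)
        if np.max(np.abs(step), initial=0.0) < _IRLS_TOL:
            break
    mu = sf[None, :] * np.exp(np.where(ok, eta, 0.0)[:, None])
    denom = 1.0 + alpha[:, None] * mu
    info = np.where(ok, (mu / denom).sum(axis=1), 0.0)
    return np.where(ok, eta, -np.inf), info


def wald_test(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    factors: pd.Series,
    dispersions: pd.Series,
    spec: ComparisonSpec,
) -> DEResult:
    """Two-group NB Wald test for one comparison.

    Per gene the two group log-means are fitted by Newton iteration with
    log size-factor offsets; lfc = (eta_B - eta_A)/ln 2, its standard error
    comes from the summed inverse Fisher informations, and p is the
    two-sided normal tail of lfc/se.  Genes with all-zero counts in both
    groups get NaN effect sentinels and p_raw = 1; genes with one all-zero
    group get NaN effect and NaN p (boundary estimate, no finite Wald
    statistic).
    """
    samples_a = design.samples_for(*spec.group_a)
    samples_b = design.samples_for(*spec.group_b)
    if not samples_a or not samples_b:
        raise BatteryError(
            f"comparison {spec.name!r}: empty group "
            f"{spec.group_a if not samples_a else spec.group_b}"
        )
    if set(samples_a) & set(samples_b):
        raise ConfigError(f"comparison {spec.name!r}: overlapping groups")

    alpha = dispersions.reindex(matrix.gene_ids).to_numpy(dtype=float)
    ca = matrix.counts[samples_a].to_numpy(dtype=float)
    cb = matrix.counts[samples_b].to_numpy(dtype=float)
    sfa = factors.reindex(samples_a).to_numpy(dtype=float)
    sfb = factors.reindex(samples_b).to_numpy(dtype=float)

    eta_a, info_a = _fit_group_log_means(ca, sfa, alpha)
    eta_b, info_b = _fit_group_log_means(cb, sfb, alpha)

    both_zero = np.isneginf(eta_a) & np.isneginf(eta_b)
    one_zero = np.isneginf(eta_a) ^ np.isneginf(eta_b)
    regular = ~(both_zero | one_zero)

    lfc = np.full(matrix.n_genes, np.nan)
    se = np.full(matrix.n_genes, np.nan)
    z = np.full(matrix.n_genes, np.nan)
    p = np.full(matrix.n_genes, np.nan)

    lfc[regular] = (eta_b[regular] - eta_a[regular]) / _LN2
    se[regular] = np.sqrt(1.0 / info_a[regular] + 1.0 / info_b[regular]) / _LN2
    with np.errstate(invalid="ignore"):
        z[regular] = lfc[regular] / se[regular]
    # exact two-group symmetry: identical data gives z == 0 -> p == 1
    p[regular] = 2.0 * stats.norm.sf(np.abs(z[regular]))
    p[both_zero] = 1.0

    norm_all = np.concatenate([ca / sfa[None, :], cb / sfb[None, :]], axis=1)
    table = pd.DataFrame(
        {
            "base_mean": norm_all.mean(axis=1),
            "lfc": lfc,
            "lfc_shrunk": np.nan,
            "se": se,
            "wald_z": z,
            "p_raw": p,
            "p_adj": np.nan,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    return DEResult(spec.name, spec.orientation, spec.group_a, spec.group_b, table)


# ---------------------------------------------------------------------------
# LFC shrinkage


def _fit_prior_variance(lfc: np.ndarray, se: np.ndarray) -> float:
    """Marginal ML estimate of the prior variance tau^2.

    Marginally lfc_g ~ N(0, tau^2 + se_g^2); the scalar likelihood is
    maximized over log tau^2 on a wide bracket.
    """
    var = np.square(se)

    def nll(log_tau2: float) -> float:
        t2 = np.exp(log_tau2)
        total = t2 + var
        return float(0.5 * np.sum(np.log(total) + np.square(lfc) / total))

    res = optimize.minimize_scalar(nll, bounds=(-20.0, 10.0), method="bounded")
    return float(np.exp(res.x))


def shrink_lfc(result: DEResult) -> DEResult:
    """Empirical-Bayes normal-prior shrinkage of the LFC estimates.

    Posterior mean is lfc * tau^2/(tau^2 + se^2), so |shrunk| <= |mle| and
    the sign is preserved (or zero).  When no gene has a finite (lfc, se)
    pair the step is skipped with a warning and lfc_shrunk = lfc.
    """
    t = result.table
    lfc = t["lfc"].to_numpy()
    se = t["se"].to_numpy()
    usable = np.isfinite(lfc) & np.isfinite(se) & (se > 0)
    if not usable.any():
        warnings.warn("no finite standard errors; LFC shrinkage skipped", stacklevel=2)
        t["lfc_shrunk"] = t["lfc"]
        return result
    tau2 = _fit_prior_variance(lfc[usable], se[usable])
    shrunk = np.where(usable, lfc * tau2 / (tau2 + np.square(se)), lfc)
    t["lfc_shrunk"] = shrunk
    result.prior_var = tau2
    return result


# ---------------------------------------------------------------------------
# Multiple testing


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity; NaNs propagate.

    Order-preserving: output[i] corresponds to input[i].  NaN entries
    (untested genes) are excluded from the ranking and returned as NaN.
    """
    p = np.asarray(p_raw, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        bad = p[finite][(p[finite] < 0) | (p[finite] > 1)][0]
        raise ConfigError(f"p-value {bad} outside [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Battery


def run_battery(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    factors: pd.Series,
    dispersions: pd.Series,
    ages=None,
    shrink: bool = True,
) -> dict[str, DEResult]:
    """All pairwise comparisons of the standard design (15 for three ages).

    Each comparison gets its own BH adjustment across genes.  Raises when a
    sex-age group required by the battery is absent.
    """
    ages = sorted(ages) if ages is not None else design.ages
    groups = design.groups()
    for sex in ("F", "M"):
        for age in ages:
            if (sex, age) not in groups:
                raise BatteryError(f"missing sex-age group ({sex}, {age})")
    results: dict[str, DEResult] = {}
    for spec in comparison_battery(ages):
        res = wald_test(matrix, design, factors, dispersions, spec)
        if shrink:
            res = shrink_lfc(res)
        res.table["p_adj"] = adjust_bh(res.table["p_raw"].to_numpy())
        results[spec.name] = res
    return results
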