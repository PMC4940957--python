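"""Expression quantification and differential-expression testing.

Implements the counting-side contracts of the pipeline: TPM
normalization, per-genotype detection and the three-set Venn partition,
meiocyte/somatic exclusivity, a Chao-type missing-gene estimate, TMM
library-size factors, a conditional negative-binomial exact test with a
single common dispersion estimated by conditional maximum likelihood,
Storey q-value FDR control, and the pooled two-proportion z-test used
by the comparative summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, special, stats
from statsmodels.stats.proportion import proportions_ztest

FDR_LEVEL = 0.01


# ---------------------------------------------------------------------------
# TPM, detection, Venn, exclusivity

def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: 1e6 * (c_g/l_g) / sum_h(c_h/l_h) per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    return rate.div(total.where(total > 0, 1.0), axis=1) * 1e6


def detect(counts: pd.DataFrame, groups: pd.Series,
           min_count: int = 1) -> pd.DataFrame:
    """Detection flag per gene x group: summed counts >= ``min_count``.

    ``groups`` maps sample name -> group label (e.g. genotype).
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    sums = counts.T.groupby(groups).sum().T
    return sums >= min_count


def venn_partition(detection: pd.DataFrame) -> pd.Series:
    """Counts of the 7 regions of a 3-set detection diagram.

    ``detection`` is gene x group boolean with exactly three columns.
    Region keys name the member groups joined by '&'. Genes detected
    nowhere are excluded (regions sum to the detected-anywhere total).
    """
    if detection.shape[1] != 3:
        raise ValueError("venn_partition needs exactly three groups")
    a, b, c = detection.columns
    regions = {}
    for ka in (False, True):
        for kb in (False, True):
            for kc in (False, True):
                if not (ka or kb or kc):
                    continue
                name = "&".join(n for n, k in ((a, ka), (b, kb), (c, kc)) if k)
                mask = ((detection[a] == ka) & (detection[b] == kb)
                        & (detection[c] == kc))
                regions[name] = int(mask.sum())
    return pd.Series(regions, name="genes")


def exclusivity(meiocyte_detected: pd.Series,
                somatic_detected: pd.Series) -> pd.Series:
    """Classify genes as meiocyte-exclusive, shared, or somatic-only."""
    idx = meiocyte_detected.index.union(somatic_detected.index)
    m = meiocyte_detected.reindex(idx, fill_value=False)
    s = somatic_detected.reindex(idx, fill_value=False)
    out = pd.Series("undetected", index=idx, name="exclusivity", dtype=object)
    out[m & ~s] = "meiocyte-exclusive"
    out[m & s] = "shared"
    out[~m & s] = "somatic-only"
    return out


# ---------------------------------------------------------------------------
# Missing-gene (unseen species) estimate

def estimate_missing_genes(counts: pd.DataFrame, n_boot: int = 1000,
                           seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Chao-type estimate of undetected genes with a bootstrap 95% CI.

    Pools counts over samples; with f1/f2 the numbers of genes seen with
    exactly one/two reads, the point estimate is f1^2 / (2 f2) (the
    bias-corrected f1(f1-1)/(2(f2+1)) when f2 = 0).  The CI comes from
    ``n_boot`` multinomial resamples of the pooled reads.  A coverage
    surrogate for parametric saturation estimators.
    """
    pooled = counts.sum(axis=1).to_numpy(int)
    total = int(pooled.sum())

    def chao(v: np.ndarray) -> float:
        f1 = int((v == 1).sum())
        f2 = int((v == 2).sum())
        if f1 == 0:
            return 0.0
        if f2 == 0:
            return f1 * (f1 - 1) / 2.0
        return f1 * f1 / (2.0 * f2)

    est = chao(pooled)
    if total == 0:
        return est, (0.0, 0.0)
    p = pooled / total
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = chao(rng.multinomial(total, p))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return est, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# TMM normalization

def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed mean of M-values normalization factors.

    Reference column = highest-depth sample; log-ratios trimmed 30%,
    absolute intensities 5%, weighted by asymptotic (delta-method)
    variances; factors are scaled to geometric mean 1.
    """
    lib = counts.sum(axis=0).astype(float)
    ref = lib.idxmax()
    yr = counts[ref].to_numpy(float)
    nr = lib[ref]
    factors = {}
    for col in counts.columns:
        yk = counts[col].to_numpy(float)
        nk = lib[col]
        ok = (yk > 0) & (yr > 0)
        if col == ref or not ok.any():
            factors[col] = 1.0
            continue
        m = np.log2((yk[ok] / nk) / (yr[ok] / nr))
        a = 0.5 * np.log2((yk[ok] / nk) * (yr[ok] / nr))
        w = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            factors[col] = 1.0
        else:
            factors[col] = 2.0 ** (np.sum(m[keep] / w[keep])
                                   / np.sum(1.0 / w[keep]))
    f = pd.Series(factors, name="tmm_factor")
    return f / np.exp(np.log(f).mean())


# ---------------------------------------------------------------------------
# Library-size equalization (quantile-adjusted pseudo-counts)

def _q2q_nbinom(x: np.ndarray, in_mean: np.ndarray, out_mean: np.ndarray,
                dispersion: float) -> np.ndarray:
    """Quantile-to-quantile NB transform (normal/gamma blend)."""
    x = np.asarray(x, float)
    in_mean = np.maximum(in_mean, 1e-8)
    out_mean = np.maximum(out_mean, 1e-8)
    ri = 1.0 + dispersion * in_mean
    ro = 1.0 + dispersion * out_mean
    vi = in_mean * ri
    vo = out_mean * ro
    # normal approximation
    q1 = out_mean + np.sqrt(vo / vi) * (x - in_mean)
    # gamma approximation (matched shape)
    shape_i = in_mean / ri
    shape_o = out_mean / ro
    with np.errstate(all="ignore"):
        p = stats.gamma.cdf(x, a=shape_i, scale=ri)
        q2 = stats.gamma.ppf(np.clip(p, 1e-300, 1 - 1e-12), a=shape_o, scale=ro)
    q2 = np.where(np.isfinite(q2), q2, q1)
    return np.maximum((q1 + q2) / 2.0, 0.0)


def equalize_lib_sizes(counts: pd.DataFrame, lib_sizes: pd.Series,
                       dispersion: float = 0.05) -> tuple[pd.DataFrame, float]:
    """Quantile-adjusted pseudo-counts at the common (geometric-mean)
    effective library size."""
    lib = lib_sizes.reindex(counts.columns).to_numpy(float)
    common = float(np.exp(np.mean(np.log(lib))))
    rel = counts.to_numpy(float).sum(axis=1) / lib.sum()
    pseudo = np.empty_like(counts.to_numpy(float))
    for j, s in enumerate(lib):
        pseudo[:, j] = _q2q_nbinom(counts.to_numpy(float)[:, j],
                                   rel * s, rel * common, dispersion)
    return pd.DataFrame(pseudo, index=counts.index,
                        columns=counts.columns), common


# ---------------------------------------------------------------------------
# Common dispersion by conditional maximum likelihood

def _cond_loglik(y: np.ndarray, r_per_rep: float) -> float:
    """Conditional log-likelihood of one gene's replicate vector given its
    sum, for NB with per-replicate size r."""
    n = len(y)
    s = y.sum()
    return float(np.sum(special.gammaln(y + r_per_rep))
                 - n * special.gammaln(r_per_rep)
                 + special.gammaln(n * r_per_rep)
                 - special.gammaln(s + n * r_per_rep))


def estimate_common_dispersion(counts: pd.DataFrame,
                               group_a: list[str], group_b: list[str],
                               bounds: tuple[float, float] = (1e-6, 5.0)
                               ) -> float:
    """Single common NB dispersion maximizing the conditional likelihood
    summed over genes and groups (rounded pseudo-counts)."""
    ya = np.round(counts[group_a].to_numpy(float))
    yb = np.round(counts[group_b].to_numpy(float))
    keep = (ya.sum(axis=1) + yb.sum(axis=1)) > 0
    ya, yb = ya[keep], yb[keep]
    if ya.size == 0:
        return bounds[0]

    def neg_ll(log_phi: float) -> float:
        r = 1.0 / math.exp(log_phi)
        tot = 0.0
        for y in (ya, yb):
            n = y.shape[1]
            s = y.sum(axis=1)
            tot += float(np.sum(special.gammaln(y + r))
                         - y.shape[0] * n * special.gammaln(r)
                         + y.shape[0] * special.gammaln(n * r)
                         - np.sum(special.gammaln(s + n * r)))
        return -tot

    res = optimize.minimize_scalar(neg_ll, bounds=(math.log(bounds[0]),
                                                   math.log(bounds[1])),
                                   method="bounded",
                                   options={"xatol": 1e-6})
    return float(math.exp(res.x))


# ---------------------------------------------------------------------------
# NB exact test

def nb_exact_test(y_a: int, y_b: int, dispersion: float,
                  n_a: int = 1, n_b: int = 1) -> float:
    """Conditional two-sided exact test for two NB group sums.

    Given the total s = y_a + y_b of two group sums with per-replicate
    dispersion ``dispersion`` and equalized per-replicate means, the
    conditional distribution of y_a is negative-hypergeometric with
    sizes (n_a/phi, n_b/phi) (binomial with p = n_a/(n_a+n_b) in the
    Poisson limit).  The p-value sums the probabilities of all outcomes
    no more likely than the observed one, capped at 1.
    """
    if y_a < 0 or y_b < 0:
        raise ValueError("counts must be non-negative")
    s = int(y_a) + int(y_b)
    if s == 0:
        return 1.0
    j = np.arange(s + 1)
    if dispersion <= 1e-12:
        logp = stats.binom.logpmf(j, s, n_a / (n_a + n_b))
    else:
        ra = n_a / dispersion
        rb = n_b / dispersion
        logp = (special.gammaln(j + ra) - special.gammaln(j + 1)
                - special.gammaln(ra)
                + special.gammaln(s - j + rb) - special.gammaln(s - j + 1)
                - special.gammaln(rb))
        logp -= special.logsumexp(logp)
    obs = logp[int(y_a)]
    # tolerance absorbs gammaln rounding so mirror-image outcomes with
    # theoretically equal probability are treated as ties
    p = float(np.exp(logp[logp <= obs + 1e-7]).sum())
    return min(p, 1.0)


@dataclass
class DEResult:
    """Per-gene differential-expression table with FDR flags."""

    table: pd.DataFrame  # gene_id x (log2_fold_change, p_value, q_value, de_flag)
    dispersion: float
    pi0: float


def exact_test_matrix(counts: pd.DataFrame, group_a: list[str],
                      group_b: list[str], dispersion: float | None = None,
                      normalize: bool = True) -> tuple[pd.Series, float]:
    """Exact-test p-values for all genes, group A vs group B.

    Library sizes are equalized with TMM-scaled effective sizes and
    quantile-adjusted pseudo-counts; a single common dispersion is
    estimated by conditional maximum likelihood unless supplied.
    Returns (p-values, dispersion used).
    """
    cols = list(group_a) + list(group_b)
    sub = counts[cols]
    if normalize:
        eff = sub.sum(axis=0) * tmm_factors(sub)
        pseudo, _ = equalize_lib_sizes(sub, eff)
    else:
        pseudo = sub.astype(float)
    if dispersion is None:
        dispersion = estimate_common_dispersion(pseudo, group_a, group_b)
    ya = np.round(pseudo[group_a].sum(axis=1)).astype(int)
    yb = np.round(pseudo[group_b].sum(axis=1)).astype(int)
    pvals = pd.Series(
        [nb_exact_test(a, b, dispersion, len(group_a), len(group_b))
         for a, b in zip(ya, yb)],
        index=counts.index, name="p_value")
    return pvals, float(dispersion)


def log2_fold_changes(counts: pd.DataFrame, group_a: list[str],
                      group_b: list[str], prior: float = 0.5) -> pd.Series:
    """Moderated log2 fold change (A over B) from CPM with a prior count."""
    lib = counts.sum(axis=0)
    cpm = counts.div(lib, axis=1) * 1e6
    a = cpm[group_a].mean(axis=1) + prior
    b = cpm[group_b].mean(axis=1) + prior
    return np.log2(a / b).rename("log2_fold_change")


# ---------------------------------------------------------------------------
# FDR control (Storey q-values, BH fallback)

def storey_pi0(pvals: np.ndarray) -> float:
    """Smoother estimate of the null proportion pi0.

    Cubic-spline fit of pi0(lambda) over lambda = 0.05..0.95 evaluated
    at the largest lambda.  Raises if the fit leaves (0, 1].
    """
    lam = np.arange(0.05, 0.96, 0.05)
    m = len(pvals)
    pi0_lam = np.array([(pvals > l).sum() / (m * (1.0 - l)) for l in lam])
    spline = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
    pi0 = float(spline(lam[-1]))
    if not 0.0 < pi0 <= 1.0:
        raise ValueError(f"pi0 estimate {pi0:.3f} outside (0, 1]")
    return pi0


def fdr_control(pvals: pd.Series, level: float = FDR_LEVEL) -> pd.DataFrame:
    """Storey q-values with smoother pi0; BH (pi0 = 1) fallback.

    The fallback applies when fewer than 100 p-values are supplied or
    the pi0 fit fails.  ``de_flag`` marks q <= level.
    """
    p = pvals.to_numpy(float)
    m = len(p)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m == 0:
        return pd.DataFrame(columns=["p_value", "q_value", "de_flag"])
    if m < 100:
        pi0 = 1.0
    else:
        try:
            pi0 = storey_pi0(p)
        except Exception:
            pi0 = 1.0
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qvals = np.empty(m)
    qvals[order] = q
    out = pd.DataFrame({"p_value": p, "q_value": qvals,
                        "de_flag": qvals <= level}, index=pvals.index)
    out.attrs["pi0"] = pi0
    return out


def differential_expression(counts: pd.DataFrame, group_a: list[str],
                            group_b: list[str], level: float = FDR_LEVEL,
                            dispersion: float | None = None) -> DEResult:
    """Full DE pipeline: TMM + equalization, common dispersion, exact
    test, Storey/BH FDR at ``level``."""
    pvals, disp = exact_test_matrix(counts, group_a, group_b, dispersion)
    table = fdr_control(pvals, level)
    table.insert(0, "log2_fold_change",
                 log2_fold_changes(counts, group_a, group_b))
    return DEResult(table=table, dispersion=disp,
                    pi0=table.attrs.get("pi0", 1.0))


# ---------------------------------------------------------------------------
# Two-proportion test

def proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Pooled two-tailed two-proportion z-test p-value."""
    for name, (x, n) in {"first": (x1, n1), "second": (x2, n2)}.items():
        if n <= 0 or not 0 <= x <= n:
            raise ValueError(f"invalid {name} sample: x={x}, n={n}")
    if x1 * n2 == x2 * n1:  # identical proportions, incl. degenerate pools
        return 1.0
    _, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(p)
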