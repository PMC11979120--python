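"""Differential-expression engine for bulk RNA-seq count matrices.

The chain implemented here is the standard weighted-linear-model route for
count data: counts-per-million (CPM), a low-expression filter, trimmed mean
of M-values (TMM) between-sample scaling, a classical-MDS sample check,
precision weights from a fitted mean-variance trend, gene-wise weighted
least squares for arbitrary group contrasts, empirical-Bayes moderation of
the residual variances, Holm or Benjamini-Hochberg p-value adjustment, and
DEG calling at a fold-change plus adjusted-p threshold.

All matrix-valued inputs and outputs are pandas DataFrames indexed by gene
id (rows) and sample id (columns); designs are sample x coefficient frames.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, TregsigError

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_STABLE = "stable"


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------


def compute_cpm(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    norm_factors: pd.Series | None = None,
    prior_count: float = 0.0,
    log: bool = False,
) -> pd.DataFrame:
    """Counts per million: ``(y + prior) / (N * f + 2 * prior) * 1e6``.

    ``norm_factors`` are TMM scaling factors (unit factors if ``None``).
    With ``log=True`` the base-2 logarithm is returned; a positive
    ``prior_count`` keeps zeros finite.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be >= 0")
    n = library_sizes.astype(float)
    if norm_factors is not None:
        n = n * norm_factors.reindex(n.index)
    eff = n + 2.0 * prior_count
    if (eff <= 0).any():
        bad = eff.index[eff <= 0][0]
        raise TregsigError(f"sample {bad!r} has zero effective library size")
    cpm = (counts + prior_count) / eff * 1e6
    if log:
        return np.log2(cpm)
    return cpm


def filter_low_expression(
    cm: CountMatrix,
    min_cpm: float = 1.0,
    max_low_libraries: int = 2,
    keep_genes: Iterable[str] = (),
) -> CountMatrix:
    """Drop genes below ``min_cpm`` in more than ``max_low_libraries`` samples.

    A gene is retained iff the number of samples in which its CPM (prior 0,
    unit factors) is below ``min_cpm`` is at most ``max_low_libraries``; a
    gene low in exactly ``max_low_libraries`` samples is kept.  Genes named
    in ``keep_genes`` (e.g. the private-gene reference) are exempt.
    """
    if min_cpm <= 0:
        raise ValueError("min_cpm must be > 0")
    cpm = compute_cpm(cm.counts, cm.library_sizes, prior_count=0.0)
    n_low = (cpm < min_cpm).sum(axis=1)
    keep = n_low <= max_low_libraries
    for g in keep_genes:
        if g in keep.index:
            keep[g] = True
    return cm.subset_genes(cm.gene_ids[keep])


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class NormFactors:
    """Geometric-mean-centred TMM scaling factors."""

    factors: pd.Series
    reference_sample: str


def _tmm_pair(
    yk: np.ndarray,
    nk: float,
    yr: np.ndarray,
    nr: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference sample.

    Only genes with nonzero counts in both libraries enter the M/A
    computation; trimming is two-sided on M (log-ratio) and A (average
    log-abundance), and the factor is ``2**(weighted mean of the surviving
    M-values)`` with inverse asymptotic-variance weights.  Trimming ranks
    break ties by gene order, so the result is deterministic.
    """
    ok = (yk > 0) & (yr > 0)
    yk = yk[ok].astype(float)
    yr = yr[ok].astype(float)
    n = yk.size
    if n == 0:
        return 1.0
    pk = yk / nk
    pr = yr / nr
    m = np.log2(pk / pr)
    a = 0.5 * np.log2(pk * pr)
    with np.errstate(divide="ignore"):
        var = 1.0 / yk - 1.0 / nk + 1.0 / yr - 1.0 / nr
    var = np.maximum(var, 1e-12)
    w = 1.0 / var
    if np.allclose(m, 0.0):
        return 1.0

    def ranks(x: np.ndarray) -> np.ndarray:
        order = np.lexsort((np.arange(x.size), x))  # stable; ties by gene order
        r = np.empty(x.size, dtype=np.int64)
        r[order] = np.arange(1, x.size + 1)
        return r

    rm = ranks(m)
    ra = ranks(a)
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        raise TregsigError(
            "TMM: no genes survive trimming; use smaller trim fractions "
            f"(trim_m={trim_m}, trim_a={trim_a})"
        )
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    return float(2.0**f)


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors for every sample.

    The reference is the sample whose 75th count percentile divided by its
    library size is closest to the mean of that statistic.  Factors are
    divided by their geometric mean so they multiply to one.
    """
    if cm.n_samples < 2:
        raise TregsigError("TMM requires at least 2 samples")
    y = cm.counts.to_numpy(dtype=float)
    if (y.sum(axis=0) == 0).any():
        raise TregsigError("TMM requires at least one nonzero count per sample")
    n = cm.library_sizes.to_numpy(dtype=float)
    f75 = np.quantile(y, 0.75, axis=0) / n
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = np.array(
        [
            _tmm_pair(y[:, k], n[k], y[:, ref], n[ref], trim_m, trim_a)
            if k != ref
            else 1.0
            for k in range(cm.n_samples)
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormFactors(
        factors=pd.Series(factors, index=cm.sample_ids),
        reference_sample=str(cm.sample_ids[ref]),
    )


# ---------------------------------------------------------------------------
# Classical MDS sample check
# ---------------------------------------------------------------------------


def mds_embedding(
    log2cpm: pd.DataFrame,
    top_n: int = 500,
    dims: int = 2,
) -> pd.DataFrame:
    """Classical (Torgerson) scaling of pairwise top-gene log-fold distances.

    The distance between two samples is the root mean square of the
    ``top_n`` largest absolute log2 differences for that pair (pair-specific
    gene selection).  Returns the ``dims`` leading coordinates per sample.
    """
    x = log2cpm.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 3:
        raise TregsigError("MDS requires at least 3 samples")
    if dims >= n:
        raise TregsigError(f"dims must be < number of samples ({n})")
    top = min(top_n, x.shape[0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sq = (x[:, i] - x[:, j]) ** 2
            largest = np.partition(sq, sq.size - top)[sq.size - top :]
            d[i, j] = d[j, i] = np.sqrt(largest.mean())
    d2 = d**2
    jmat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * jmat @ d2 @ jmat
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    # deterministic sign: largest-magnitude loading of each axis is positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return pd.DataFrame(
        coords, index=log2cpm.columns, columns=[f"dim{k + 1}" for k in range(dims)]
    )


# ---------------------------------------------------------------------------
# Precision weights (voom-style mean-variance trend)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class WeightedLogExpression:
    """log2-CPM with per-observation precision weights and the fitted trend.

    ``trend`` is the piecewise-linear mapping from mean log2 count to the
    fitted quarter-root standard deviation, stored as (x, y) node arrays;
    evaluation clamps outside the fitted range (constant extrapolation).
    """

    log2cpm: pd.DataFrame
    weights: pd.DataFrame
    trend_x: np.ndarray
    trend_y: np.ndarray

    def trend(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.trend_x, self.trend_y)


_TREND_FLOOR = 1e-2  # quarter-root SD floor so weights stay finite
_TREND_CEIL = 1e3


def design_matrix(samples: pd.DataFrame) -> pd.DataFrame:
    """Group-indicator design from (compartment, lineage) labels.

    One column per population label ``"<compartment>.<lineage>"`` present in
    the metadata, in sorted label order (a group-means parameterization).
    """
    groups = samples["compartment"] + "." + samples["lineage"]
    levels = sorted(groups.unique())
    x = pd.DataFrame(
        {g: (groups == g).astype(float) for g in levels}, index=samples.index
    )
    return x


def contrast_vector(design: pd.DataFrame, contrast: str) -> pd.Series:
    """Parse ``"groupA - groupB"`` into a coefficient vector for ``design``."""
    parts = [p.strip() for p in contrast.split("-")]
    if len(parts) != 2 or not all(parts):
        raise TregsigError(f"cannot parse contrast {contrast!r}; expected 'groupA - groupB'")
    vec = pd.Series(0.0, index=design.columns)
    for name, value in zip(parts, (1.0, -1.0)):
        if name not in vec.index:
            raise TregsigError(f"unknown group {name!r}; design has {list(vec.index)}")
        vec[name] = value
    return vec


def voom_weights(
    cm: CountMatrix,
    factors: NormFactors | None,
    design: pd.DataFrame,
    span: float = 0.5,
    iterations: int = 2,
) -> WeightedLogExpression:
    """Per-observation precision weights from the mean-variance trend.

    log2-CPM is computed with a prior count of 0.5 against the effective
    library size ``N * f + 1``.  An unweighted least-squares fit of the
    design per gene yields residual standard deviations; a lowess of their
    quarter roots against mean log2 count (span 0.5, 2 robustifying
    iterations) gives the trend, each observation's fitted log2 count is
    mapped through it, and the weight is the fitted value to the -4 power.
    """
    x = design.to_numpy(dtype=float)
    nsamp, ncoef = x.shape
    if nsamp <= ncoef:
        raise TregsigError(
            f"voom needs more samples ({nsamp}) than design columns ({ncoef})"
        )
    if np.linalg.matrix_rank(x) < ncoef:
        raise TregsigError("design matrix is not full rank")
    n = cm.library_sizes.to_numpy(dtype=float)
    if factors is not None:
        n = n * factors.factors.reindex(cm.sample_ids).to_numpy()
    lib = n + 1.0
    y = np.log2((cm.counts.to_numpy(dtype=float) + 0.5) / lib * 1e6)

    pinv = np.linalg.pinv(x)  # (p x n)
    beta = y @ pinv.T  # genes x p
    fitted = beta @ x.T  # genes x samples
    resid = y - fitted
    df = nsamp - ncoef
    sigma = np.sqrt((resid**2).sum(axis=1) / df)

    mean_log_count = y.mean(axis=1) + np.mean(np.log2(lib)) - np.log2(1e6)
    quarter_sd = np.sqrt(sigma)

    smooth = sm_lowess(
        quarter_sd, mean_log_count, frac=span, it=iterations, return_sorted=True
    )
    tx, ty = smooth[:, 0], smooth[:, 1]
    # collapse duplicate abscissae so np.interp sees a strictly valid grid
    tx, idx = np.unique(tx, return_index=True)
    ty = ty[idx]
    ty = np.clip(ty, _TREND_FLOOR, _TREND_CEIL)

    fitted_count = fitted + (np.log2(lib) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_count, tx, ty)
    weights = pred**-4.0

    return WeightedLogExpression(
        log2cpm=pd.DataFrame(y, index=cm.gene_ids, columns=cm.sample_ids),
        weights=pd.DataFrame(weights, index=cm.gene_ids, columns=cm.sample_ids),
        trend_x=tx,
        trend_y=ty,
    )


# ---------------------------------------------------------------------------
# Weighted linear-model fits
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GeneFits:
    """Per-gene weighted least-squares results for one design.

    ``coefficients`` holds the fitted group coefficients (genes x p);
    ``xtwx_inv`` the per-gene unscaled covariance ``(X'WX)^-1``;
    ``residual_var`` and ``residual_df`` the gene-wise variance estimates.
    Genes whose weighted normal equations are singular are dropped and
    listed in ``excluded``.
    """

    coefficients: pd.DataFrame
    xtwx_inv: np.ndarray
    residual_var: pd.Series
    residual_df: float
    design: pd.DataFrame
    excluded: list[str]


def fit_design(wle: WeightedLogExpression, design: pd.DataFrame) -> GeneFits:
    x = design.to_numpy(dtype=float)
    nsamp, ncoef = x.shape
    y = wle.log2cpm.to_numpy(dtype=float)
    w = wle.weights.to_numpy(dtype=float)
    genes = wle.log2cpm.index

    xtwx = np.einsum("gn,np,nq->gpq", w, x, x, optimize=True)
    xtwy = np.einsum("gn,np,gn->gp", w, x, y, optimize=True)

    ok = np.ones(len(genes), dtype=bool)
    try:
        inv = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        inv = np.empty_like(xtwx)
        for g in range(len(genes)):
            try:
                inv[g] = np.linalg.inv(xtwx[g])
            except np.linalg.LinAlgError:
                ok[g] = False
                inv[g] = np.nan
    if not ok.all():
        excluded = list(genes[~ok])
        warnings.warn(
            f"excluding {len(excluded)} gene(s) with singular weighted normal equations"
        )
    else:
        excluded = []

    beta = np.einsum("gpq,gq->gp", inv, xtwy)
    fitted = beta @ x.T
    resid = y - fitted
    df = nsamp - ncoef
    if df <= 0:
        raise TregsigError("no residual degrees of freedom")
    s2 = (w * resid**2).sum(axis=1) / df

    keep = ok
    return GeneFits(
        coefficients=pd.DataFrame(beta[keep], index=genes[keep], columns=design.columns),
        xtwx_inv=inv[keep],
        residual_var=pd.Series(s2[keep], index=genes[keep]),
        residual_df=float(df),
        design=design,
        excluded=excluded,
    )


def fit_contrast(
    wle: WeightedLogExpression,
    design: pd.DataFrame,
    contrast: pd.Series | Sequence[float],
    fits: GeneFits | None = None,
) -> pd.DataFrame:
    """Weighted least-squares estimate of one contrast for every gene.

    Returns a frame with the contrast estimate ``log2fc`` (= c'beta), the
    unscaled standard deviation ``u`` (= sqrt(c'(X'WX)^-1 c)), the residual
    variance ``s2`` and residual degrees of freedom ``df``.
    """
    c = np.asarray(contrast, dtype=float)
    if c.shape != (design.shape[1],):
        raise TregsigError(
            f"contrast length {c.size} does not match design columns {design.shape[1]}"
        )
    if fits is None:
        fits = fit_design(wle, design)
    coef = fits.coefficients.to_numpy() @ c
    u = np.sqrt(np.einsum("p,gpq,q->g", c, fits.xtwx_inv, c))
    return pd.DataFrame(
        {
            "log2fc": coef,
            "u": u,
            "s2": fits.residual_var.to_numpy(),
            "df": fits.residual_df,
        },
        index=fits.coefficients.index,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ModerationEstimates:
    prior_df: float  # d0, may be inf
    prior_var: float  # s0^2
    posterior_var: pd.Series  # per-gene shrunken variance


def _trigamma_inverse(x: float) -> float:
    """Solve ``trigamma(y) = x`` for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled F distribution.

    Returns ``(d0, s0^2)``.  The excess spread of ``log s^2`` beyond the
    chi-square sampling contribution ``trigamma(df/2)`` determines the prior
    degrees of freedom via trigamma inversion; no excess spread gives
    ``d0 = inf`` (all genes share one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise TregsigError("moderation needs at least 2 genes with positive variance")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess spread beyond chi-square sampling noise: one shared
        # variance, estimated by the arithmetic mean
        d0 = np.inf
        s02 = float(np.mean(s2[ok]))
    return float(d0), s02


def moderate_statistics(
    fit: pd.DataFrame,
    prior_df: float | None = None,
) -> tuple[ModerationEstimates, pd.DataFrame]:
    """Moderated t-statistics from per-gene fits.

    The posterior variance ``(d0*s0^2 + df*s^2) / (d0 + df)`` interpolates
    between the gene-wise and prior variances; the moderated t uses
    ``d0 + df`` degrees of freedom.  ``prior_df`` overrides the estimated
    d0 (0 recovers the ordinary t-statistic; ``inf`` pools completely).
    """
    if len(fit) < 2:
        raise TregsigError("moderation needs at least 2 genes")
    s2 = fit["s2"].to_numpy(dtype=float)
    df = float(fit["df"].iloc[0])
    if prior_df is None:
        d0, s02 = estimate_prior(s2, df)
    else:
        d0 = float(prior_df)
        if d0 > 0 and np.isfinite(d0):
            _, s02 = estimate_prior(s2, df)
        elif np.isinf(d0):
            s02 = float(np.mean(s2))  # complete pooling
        else:
            s02 = float(np.mean(s2))  # irrelevant when d0 == 0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = fit["log2fc"].to_numpy() / (np.sqrt(s2_post) * fit["u"].to_numpy())
    p = 2.0 * scipy.stats.t.sf(np.abs(tstat), df_total)
    est = ModerationEstimates(
        prior_df=d0,
        prior_var=s02,
        posterior_var=pd.Series(s2_post, index=fit.index),
    )
    result = fit.copy()
    result["moderated_t"] = tstat
    result["df_total"] = df_total
    result["p_raw"] = p
    return est, result


# ---------------------------------------------------------------------------
# Multiple testing and DEG calling
# ---------------------------------------------------------------------------


def adjust_pvalues(p: Sequence[float] | np.ndarray, method: str = "holm") -> np.ndarray:
    """Holm step-down or Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "holm":
        return multipletests(p, method="holm")[1]
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def call_degs(
    result: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign up/down/stable status from log2fc and adjusted p.

    ``up`` iff ``log2fc >= lfc_threshold`` and ``p_adj < alpha``; ``down``
    symmetrically; everything else ``stable``.
    """
    if "p_adj" not in result.columns:
        raise TregsigError("call_degs requires adjusted p-values (column 'p_adj')")
    out = result.copy()
    lfc = out["log2fc"].to_numpy()
    padj = out["p_adj"].to_numpy()
    status = np.full(len(out), STATUS_STABLE, dtype=object)
    status[(lfc >= lfc_threshold) & (padj < alpha)] = STATUS_UP
    status[(lfc <= -lfc_threshold) & (padj < alpha)] = STATUS_DOWN
    out["status"] = status
    return out


# ---------------------------------------------------------------------------
# Convenience: one full contrast analysis
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ContrastAnalysis:
    """Everything produced by one filter/normalize/fit/test run."""

    filtered: CountMatrix
    factors: NormFactors
    wle: WeightedLogExpression
    fits: GeneFits
    moderation: ModerationEstimates
    results: dict[str, pd.DataFrame]  # contrast name -> result table
    log2cpm: pd.DataFrame  # TMM-normalized log2-CPM (prior 0.5)


def run_contrasts(
    cm: CountMatrix,
    contrasts: dict[str, str],
    min_cpm: float = 1.0,
    max_low_libraries: int = 2,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    adjust_method: str = "bh",
    keep_genes: Iterable[str] = (),
    prior_df: float | None = None,
) -> ContrastAnalysis:
    """Filter, normalize, weight, fit and test a set of named contrasts.

    One joint group-means model is fitted over all samples present in
    ``cm``; each entry of ``contrasts`` ("name" -> "groupA - groupB") is
    tested against it with shared residual variances and one moderation
    step.
    """
    filtered = filter_low_expression(
        cm, min_cpm=min_cpm, max_low_libraries=max_low_libraries, keep_genes=keep_genes
    )
    factors = tmm_factors(filtered)
    design = design_matrix(filtered.samples)
    groups = filtered.group_labels()
    for g in design.columns:
        if (groups == g).sum() < 2:
            raise TregsigError(f"group {g!r} has fewer than 2 samples")
    wle = voom_weights(filtered, factors, design)
    fits = fit_design(wle, design)
    results: dict[str, pd.DataFrame] = {}
    moderation = None
    for name, expr in contrasts.items():
        vec = contrast_vector(design, expr)
        fit = fit_contrast(wle, design, vec, fits=fits)
        moderation, res = moderate_statistics(fit, prior_df=prior_df)
        res["p_adj"] = adjust_pvalues(res["p_raw"].to_numpy(), method=adjust_method)
        res = call_degs(res, lfc_threshold=lfc_threshold, alpha=alpha)
        results[name] = res
    log2cpm = compute_cpm(
        filtered.counts,
        filtered.library_sizes,
        norm_factors=factors.factors,
        prior_count=0.5,
        log=True,
    )
    return ContrastAnalysis(
        filtered=filtered,
        factors=factors,
        wle=wle,
        fits=fits,
        moderation=moderation,
        results=results,
        log2cpm=log2cpm,
    )
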