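"""Array-style differential methylation and region/CGI enrichment.

Senescence-associated CpGs are defined on beta-value matrices by a combined
rule: at least a 20% difference in mean methylation between early- and
late-passage groups AND a Benjamini-Hochberg adjusted p-value below 0.05
from a moderated two-sample t-test. The moderated test shrinks per-CpG
residual variances toward a pooled prior fitted by empirical Bayes
(method-of-moments fit of a scaled inverse-chi-square prior to the observed
variance distribution, after Smyth 2004), which stabilises inference at the
small group sizes typical of passage series. Differentially methylated CpGs
are then tested for enrichment or depletion within gene-region and
CpG-island annotation categories with exact hypergeometric tail
probabilities; in senescence the drift is characteristically depleted from
promoters and CpG islands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

DELTA_THRESHOLD = 0.20  # "at least 20%" mean difference, inclusive
ALPHA = 0.05

REFGENE_PRECEDENCE = ["TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR"]

__all__ = [
    "DMLResult",
    "EnrichmentResult",
    "test_differential",
    "bh_adjust",
    "classify_and_count",
    "overlap_sets",
    "hypergeometric_enrichment",
    "moderated_ttest",
    "fit_variance_prior",
    "resolve_refgene_annotation",
]


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 (Newton iteration, vectorised)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # good starting value for the relevant range
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * np.maximum(x, 1.0)):
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit the scaled inverse-chi-square prior (s0², d0) to residual variances.

    Method of moments on log variances: if s²·df/σ² ~ chi²(df) and
    1/σ² ~ chi²(d0)/(d0·s0²), then e = log(s²) - digamma(df/2) + log(df/2)
    has mean log(s0²) + digamma(d0/2) - log(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2). Returns ``(prior_var, prior_df)`` with
    ``prior_df = inf`` when the observed variances are no more dispersed
    than sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive variances to fit the prior")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2))
    if e_var <= 0:
        # no excess dispersion: variances are exchangeable, prior is a point mass
        return float(s2.mean()), float("inf")
    d0 = float(2 * _trigamma_inverse(np.array([e_var]))[0])
    s02 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return s02, d0


def moderated_ttest(
    delta: np.ndarray,
    s2: np.ndarray,
    df: np.ndarray,
    stdev_unscaled: np.ndarray,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics with empirical-Bayes variance shrinkage.

    ``delta`` are the group-mean differences, ``s2`` the per-feature pooled
    residual variances on ``df`` degrees of freedom, and ``stdev_unscaled``
    the design factor ``sqrt(1/n1 + 1/n2)``. The posterior variance is
    ``(d0*s0² + df*s²) / (d0 + df)`` and p-values use ``df + d0`` degrees of
    freedom. Pass ``prior_df=0`` to recover the ordinary pooled t-test.
    """
    delta = np.asarray(delta, float)
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    if prior_df is None:
        prior_var, prior_df = fit_variance_prior(s2, df)
    elif prior_df == 0:
        prior_var = 0.0
    elif prior_var is None:
        raise ValueError("prior_var required when prior_df is given and nonzero")
    if np.isinf(prior_df):
        s2_post = np.full_like(s2, prior_var)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (prior_df * prior_var + df * s2) / (prior_df + df)
        df_total = df + prior_df
    # cap total df at the pooled residual df: the prior cannot carry more
    # information than the whole dataset supplied
    df_total = np.minimum(df_total, df.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / (np.sqrt(s2_post) * stdev_unscaled)
    p = 2 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"t": t, "p": p, "s2_post": s2_post, "df_total": df_total}
    ).assign(prior_df=prior_df, prior_var=prior_var)


# ---------------------------------------------------------------------------
# differential methylation


def test_differential(
    betas: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    delta_threshold: float = DELTA_THRESHOLD,
    alpha: float = ALPHA,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Per-CpG moderated t-test of late versus early passage methylation.

    Parameters
    ----------
    betas : DataFrame CpG × sample, beta values in [0, 1], NaN allowed.
    groups : maps sample name to ``"early"`` or ``"late"``.
    delta_threshold, alpha : the combined call rule — ``hyper`` iff
        delta ≥ threshold and adjusted p < alpha; ``hypo`` iff delta ≤
        -threshold and adjusted p < alpha (thresholds inclusive on delta).
    prior_df, prior_var : override the empirical-Bayes prior (0 disables
        moderation, giving the ordinary pooled-variance t-test).

    Returns one row per tested CpG with means, ``delta`` (late - early),
    ``t``, ``p``, ``adjusted_p`` and ``call``. CpGs with fewer than two
    observations in a group or zero residual degrees of freedom are excluded
    (counted in ``df.attrs["n_excluded"]``). Raises if an entire group has
    fewer than two samples.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    early = [s for s in betas.columns if groups.get(s) == "early"]
    late = [s for s in betas.columns if groups.get(s) == "late"]
    if len(early) < 2 or len(late) < 2:
        raise ValueError(
            f"need >=2 samples per group, got early={len(early)} late={len(late)}"
        )
    e = betas[early].to_numpy(float)
    l = betas[late].to_numpy(float)
    n1 = np.sum(~np.isnan(e), axis=1)
    n2 = np.sum(~np.isnan(l), axis=1)
    with np.errstate(invalid="ignore"):
        mean_e = np.nanmean(np.where(np.isnan(e), np.nan, e), axis=1)
        mean_l = np.nanmean(np.where(np.isnan(l), np.nan, l), axis=1)
        var_e = _nanvar(e, n1)
        var_l = _nanvar(l, n2)
    df = n1 + n2 - 2
    usable = (n1 >= 2) & (n2 >= 2) & (df > 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.warning("test_differential: %d CpG(s) excluded (insufficient data)", n_excluded)

    idx = betas.index[usable]
    n1u, n2u, dfu = n1[usable], n2[usable], df[usable]
    s2 = ((n1u - 1) * var_e[usable] + (n2u - 1) * var_l[usable]) / dfu
    # guard exact-zero variances (constant rows): tiny floor keeps the EB fit finite
    s2 = np.maximum(s2, 1e-12)
    delta = mean_l[usable] - mean_e[usable]
    stdev_unscaled = np.sqrt(1.0 / n1u + 1.0 / n2u)
    mod = moderated_ttest(delta, s2, dfu, stdev_unscaled, prior_df, prior_var)
    adjusted = bh_adjust(mod["p"].to_numpy())

    call = np.full(len(idx), "none", dtype=object)
    call[(delta >= delta_threshold) & (adjusted < alpha)] = "hyper"
    call[(delta <= -delta_threshold) & (adjusted < alpha)] = "hypo"
    out = pd.DataFrame(
        {
            "mean_early": mean_e[usable],
            "mean_late": mean_l[usable],
            "delta": delta,
            "t_statistic": mod["t"].to_numpy(),
            "p": mod["p"].to_numpy(),
            "adjusted_p": adjusted,
            "call": call,
        },
        index=idx,
    )
    out.attrs["n_excluded"] = n_excluded
    out.attrs["prior_df"] = float(mod["prior_df"].iloc[0])
    out.attrs["prior_var"] = float(mod["prior_var"].iloc[0])
    return out


def _nanvar(a: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.nanvar(a, axis=1, ddof=1)
    return np.where(n >= 2, v, np.nan)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Adjusted value for the i-th smallest p is ``min_{j>=i} (m/j) * p_(j)``,
    capped at 1; adjusted >= raw and order-preserving. Rejecting adjusted <
    alpha reproduces the classical step-up rejection set.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def classify_and_count(results: pd.DataFrame) -> dict:
    """Count hyper-/hypomethylated calls and list their CpG ids."""
    hyper = results.index[results["call"] == "hyper"]
    hypo = results.index[results["call"] == "hypo"]
    return {
        "n_hyper": int(len(hyper)),
        "n_hypo": int(len(hypo)),
        "hyper_ids": list(hyper),
        "hypo_ids": list(hypo),
    }


def overlap_sets(dml_a: pd.DataFrame, dml_b: pd.DataFrame) -> pd.DataFrame:
    """Overlap of differentially methylated CpG sets between two analyses.

    Returns one row per call direction with counts unique to each analysis
    and shared (intersection on CpG ids) — the cross-cell-type comparison of
    senescence-associated sites.
    """
    rows = []
    for direction in ("hyper", "hypo"):
        a = set(dml_a.index[dml_a["call"] == direction])
        b = set(dml_b.index[dml_b["call"] == direction])
        rows.append(
            {
                "call": direction,
                "a_only": len(a - b),
                "b_only": len(b - a),
                "shared": len(a & b),
            }
        )
    return pd.DataFrame(rows).set_index("call")


# ---------------------------------------------------------------------------
# enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one annotation category among DML CpGs."""

    category: str
    k: int  # DML CpGs in the category
    n: int  # DML CpGs total
    K: int  # universe CpGs in the category
    N: int  # universe CpGs total
    fold: float
    p_enriched: float  # upper tail P(X >= k)
    p_depleted: float  # lower tail P(X <= k)


def hypergeometric_enrichment(
    dml_ids: Sequence[str],
    annotation: pd.Series,
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Category enrichment/depletion of DML CpGs by exact hypergeometric tails.

    ``annotation`` maps CpG id to a category (one axis at a time: gene-region
    group or CGI relation); ``universe`` defaults to all annotated CpGs and
    must contain ``dml_ids``. For each category both tails are reported:
    ``p_enriched`` = P(X >= k) and ``p_depleted`` = P(X <= k) for X
    hypergeometric(N, K, n). Fold is the ratio of observed to expected
    proportion.
    """
    universe = list(annotation.index if universe is None else universe)
    uni_set = set(universe)
    missing = [i for i in dml_ids if i not in uni_set]
    if missing:
        raise ValueError(f"{len(missing)} DML id(s) not in the universe, e.g. {missing[0]!r}")
    ann = annotation.reindex(universe)
    dml_ann = annotation.reindex(list(dml_ids))
    N = len(universe)
    n = len(dml_ids)
    rows = []
    for category, K in ann.value_counts().items():
        k = int((dml_ann == category).sum())
        K = int(K)
        expected = n * K / N
        fold = (k / expected) if expected > 0 else np.nan
        rv = stats.hypergeom(N, K, n)
        rows.append(
            EnrichmentResult(
                category=str(category),
                k=k, n=n, K=K, N=N,
                fold=float(fold),
                p_enriched=float(rv.sf(k - 1)),
                p_depleted=float(rv.cdf(k)),
            )
        )
    skipped = set(dml_ann.dropna().unique()) - set(ann.dropna().unique())
    for cat in skipped:
        logger.warning("category %r absent from universe annotation, skipped", cat)
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("category").sort_index()


def resolve_refgene_annotation(groups: Sequence[str] | str) -> str:
    """Resolve multi-mapping gene-region annotations to a single category.

    Array manifests list one group per overlapping transcript; precedence is
    TSS200 > TSS1500 > 5'UTR > 1stExon > Body > 3'UTR, with ``Intergenic``
    for CpGs with no annotation.
    """
    if isinstance(groups, str):
        groups = [g.strip() for g in groups.split(";") if g.strip()]
    for cat in REFGENE_PRECEDENCE:
        if cat in groups:
            return cat
    return "Intergenic"
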