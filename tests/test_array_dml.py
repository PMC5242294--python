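"""Differential methylation: moderated t, BH, hypergeometric enrichment, overlap."""

import shutil
import subprocess
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senmeth import simulate
from senmeth.array_dml import (
    bh_adjust,
    classify_and_count,
    hypergeometric_enrichment,
    overlap_sets,
    resolve_refgene_annotation,
)
from senmeth.array_dml import test_differential as run_dml


def _planted_matrix(seed=0, n_cpgs=1000, n_planted=100, n=4, effect=0.3, sd=0.02):
    rng = np.random.default_rng(seed)
    betas, annotation, truth = simulate.generate_beta_matrix(
        n_cpgs, n, n_planted / n_cpgs, rng, effect_size=effect, noise_sd=sd
    )
    groups = pd.Series({c: c.split("_")[0] for c in betas.columns})
    return betas, annotation, truth, groups


# ---------------------------------------------------------------------------
# moderated t


def test_identical_groups_give_no_calls():
    rng = np.random.default_rng(1)
    half = rng.uniform(0.1, 0.9, (200, 3))
    betas = pd.DataFrame(
        np.hstack([half, half]), columns=["early_0", "early_1", "early_2",
                                          "late_0", "late_1", "late_2"],
    )
    res = run_dml(betas + rng.normal(0, 1e-6, betas.shape),
                            {c: c.split("_")[0] for c in betas.columns})
    assert (res["delta"].abs() < 0.01).all()
    assert (res["call"] == "none").all()


def test_planted_effects_recovered_with_fdr_control():
    betas, _, truth, groups = _planted_matrix(seed=3)
    res = run_dml(betas, groups)
    called = res["call"] != "none"
    planted = truth["is_drifting"]
    sensitivity = (called & planted).sum() / planted.sum()
    false_calls = (called & ~planted).sum() / max(called.sum(), 1)
    assert sensitivity >= 0.95
    assert false_calls <= 0.05
    # direction of the call matches the planted direction
    hyper_called = res.index[res["call"] == "hyper"]
    assert (truth.loc[hyper_called, "direction"] == 1).all()


def test_prior_df_zero_recovers_ordinary_pooled_t():
    """Limiting case: no moderation equals the classical pooled-variance t."""
    from scipy import stats

    rng = np.random.default_rng(5)
    betas = pd.DataFrame(
        rng.uniform(0, 1, (50, 8)),
        columns=[f"early_{i}" for i in range(4)] + [f"late_{i}" for i in range(4)],
    )
    groups = {c: c.split("_")[0] for c in betas.columns}
    res = run_dml(betas, groups, prior_df=0)
    e, l = betas.iloc[:, :4].to_numpy(), betas.iloc[:, 4:].to_numpy()
    t_ref, p_ref = stats.ttest_ind(l, e, axis=1, equal_var=True)
    np.testing.assert_allclose(res["t_statistic"], t_ref, atol=1e-6)
    np.testing.assert_allclose(res["p"], p_ref, atol=1e-6)


def test_moderated_t_matches_limma_oracle(tmp_path):
    """Independent oracle: the empirical-Bayes moderated t agrees with
    R/limma's lmFit + eBayes on the same matrix."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the limma cross-check")
    rng = np.random.default_rng(7)
    n, k = 200, 3
    noise = rng.uniform(0.02, 0.3, n)[:, None]
    betas = pd.DataFrame(
        rng.uniform(0.1, 0.9, (n, 2 * k)) + rng.normal(0, 1, (n, 2 * k)) * noise,
        index=[f"cg{i}" for i in range(n)],
        columns=[f"early_{i}" for i in range(k)] + [f"late_{i}" for i in range(k)],
    )
    betas.iloc[:15, k:] += 0.3
    res = run_dml(betas, {c: c.split("_")[0] for c in betas.columns})
    betas.to_csv(tmp_path / "b.tsv", sep="\t")
    script = tmp_path / "limma.R"
    script.write_text(
        f"""
        suppressMessages(library(limma))
        b <- as.matrix(read.delim("{tmp_path / 'b.tsv'}", row.names=1))
        design <- cbind(Intercept=1, late=c(rep(0,{k}), rep(1,{k})))
        fit <- eBayes(lmFit(b, design))
        out <- data.frame(t=fit$t[,"late"], p=fit$p.value[,"late"],
                          adj=p.adjust(fit$p.value[,"late"], "BH"))
        write.table(out, "{tmp_path / 'limma.tsv'}", sep="\t", quote=FALSE)
        """
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True, timeout=300)
    lim = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
    np.testing.assert_allclose(res["t_statistic"], lim["t"], rtol=1e-8, atol=1e-10)
    np.testing.assert_allclose(res["p"], lim["p"], rtol=1e-6, atol=1e-12)
    np.testing.assert_allclose(res["adjusted_p"], lim["adj"], rtol=1e-6, atol=1e-12)


def test_group_size_precondition():
    betas = pd.DataFrame(np.zeros((5, 3)), columns=["early_0", "late_0", "late_1"])
    with pytest.raises(ValueError, match=">=2 samples"):
        run_dml(betas, {c: c.split("_")[0] for c in betas.columns})


def test_type_i_error_controlled_on_null_matrices():
    """BH 0.05 call rate on null matrices stays at/below nominal (50 seeds)."""
    rates = []
    for seed in range(50):
        betas, _, _, groups = _planted_matrix(seed=seed, n_planted=0, n_cpgs=400)
        res = run_dml(betas, groups)
        rates.append((res["adjusted_p"] < 0.05).mean())
    mean_rate = float(np.mean(rates))
    se = np.std(rates, ddof=1) / np.sqrt(len(rates))
    assert mean_rate <= 0.05 + 3 * se


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_hand_computed_and_edge_cases():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.04]), [0.04])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=80),
    st.floats(min_value=0.01, max_value=0.2),
)
def test_bh_matches_classical_step_up(p_values, alpha):
    """Rejecting adjusted < alpha equals the classical step-up rejection set,
    and adjusted values are >= raw and monotone in the ranks."""
    p = np.array(p_values)
    adjusted = bh_adjust(p)
    assert (adjusted >= p - 1e-15).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(adjusted[order]) >= -1e-15).all()
    # classical step-up: largest i with p_(i) <= i/m * alpha rejects p_(1..i)
    m = len(p)
    sorted_p = np.sort(p)
    below = np.flatnonzero(sorted_p <= np.arange(1, m + 1) / m * alpha)
    k = below[-1] + 1 if len(below) else 0
    classical = set(np.argsort(p, kind="stable")[:k])
    # ulp-scale guard: the equivalence is exact in exact arithmetic
    tol = 1e-9
    assert set(np.flatnonzero(adjusted < alpha * (1 - tol))) <= classical
    assert set(np.flatnonzero(adjusted <= alpha * (1 + tol))) >= classical


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(9)
    p = rng.uniform(size=500)
    np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# classification, overlap, enrichment


def test_classify_and_count_rule():
    res = pd.DataFrame(
        {
            "delta": [0.25, 0.25, -0.20, 0.10],
            "adjusted_p": [0.04, 0.06, 0.01, 0.001],
            "call": ["hyper", "none", "hypo", "none"],
        },
        index=list("abcd"),
    )
    counts = classify_and_count(res)
    assert counts["n_hyper"] == 1 and counts["hyper_ids"] == ["a"]
    assert counts["n_hypo"] == 1 and counts["hypo_ids"] == ["c"]


def test_boundary_delta_is_inclusive():
    """A mean difference exactly equal to the threshold is called ("at least").

    Binary-exact values keep the boundary comparison free of rounding: the
    shift and threshold are both 13/64.
    """
    threshold = 13 / 64  # exactly representable
    early = np.tile(np.full((50, 1), 0.25), 4)
    late = early + threshold
    betas = pd.DataFrame(
        np.hstack([early, late]),
        columns=[f"early_{i}" for i in range(4)] + [f"late_{i}" for i in range(4)],
    )
    res = run_dml(
        betas, {c: c.split("_")[0] for c in betas.columns}, delta_threshold=threshold
    )
    sig = res[res["adjusted_p"] < 0.05]
    assert len(sig) == 50
    assert (sig["call"] == "hyper").all()


def test_overlap_sets():
    def frame(calls):
        return pd.DataFrame({"call": calls}, index=[f"cg{i}" for i in range(len(calls))])

    a = frame(["hyper", "hyper", "hypo", "none"])
    b = frame(["hyper", "none", "hypo", "hypo"])
    out = overlap_sets(a, b)
    assert out.loc["hyper", "shared"] == 1
    assert out.loc["hyper", "a_only"] == 1
    assert out.loc["hypo", "shared"] == 1
    assert out.loc["hypo", "b_only"] == 1


def _exact_tails(N, K, n, k):
    total = comb(N, n)
    upper = sum(Fraction(comb(K, j) * comb(N - K, n - j), total)
                for j in range(k, min(K, n) + 1))
    lower = sum(Fraction(comb(K, j) * comb(N - K, n - j), total)
                for j in range(max(0, n - (N - K)), k + 1))
    return float(upper), float(lower)


def test_hypergeometric_worked_example():
    """N=10, K=4, n=5, k=4: P(X >= 4) = C(4,4) C(6,1) / C(10,5) = 6/252."""
    ids = [f"c{i}" for i in range(10)]
    ann = pd.Series(["in"] * 4 + ["out"] * 6, index=ids)
    dml = ids[:4] + [ids[5]]  # k=4 of the 4 'in', one 'out'
    res = hypergeometric_enrichment(dml, ann)
    assert res.loc["in", "p_enriched"] == pytest.approx(6 / 252, abs=1e-12)
    assert res.loc["in", "k"] == 4 and res.loc["in", "n"] == 5


def test_hypergeometric_tails_match_exhaustive_enumeration():
    """Exact-enumeration oracle over a grid of small parameter sets, plus the
    tail-complement identity P(X>=k) + P(X<=k-1) = 1."""
    from scipy import stats as sps

    rng = np.random.default_rng(13)
    for _ in range(300):
        N = int(rng.integers(2, 31))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, n + 1))
        upper, lower = _exact_tails(N, K, n, k)
        rv = sps.hypergeom(N, K, n)
        assert rv.sf(k - 1) == pytest.approx(upper, abs=1e-12)
        assert rv.cdf(k) == pytest.approx(lower, abs=1e-12)
        assert rv.sf(k - 1) + rv.cdf(k - 1) == pytest.approx(1.0, abs=1e-12)
        assert rv.sf(-1) == pytest.approx(1.0, abs=1e-12)


def test_fold_is_one_at_expectation():
    ids = [f"c{i}" for i in range(100)]
    ann = pd.Series(["in"] * 20 + ["out"] * 80, index=ids)
    dml = ids[:2] + ids[20:28]  # n=10, k=2, expectation 10*20/100 = 2
    res = hypergeometric_enrichment(dml, ann)
    assert res.loc["in", "fold"] == pytest.approx(1.0)


def test_enrichment_detects_planted_promoter_cgi_depletion():
    """Drifting CpGs planted away from promoters/CGIs: depletion tails are
    significant for Island and TSS200 at the planted effect size."""
    betas, annotation, truth, groups = _planted_matrix(
        seed=17, n_cpgs=4000, n_planted=400
    )
    res = run_dml(betas, groups)
    dml_ids = list(res.index[res["call"] != "none"])
    enr_cgi = hypergeometric_enrichment(dml_ids, annotation["cgi_relation"])
    enr_ref = hypergeometric_enrichment(dml_ids, annotation["refgene_group"])
    assert enr_cgi.loc["Island", "p_depleted"] < 0.01
    assert enr_ref.loc["TSS200", "p_depleted"] < 0.01


def test_dml_ids_must_be_subset_of_universe():
    ann = pd.Series({"a": "x", "b": "y"})
    with pytest.raises(ValueError, match="not in the universe"):
        hypergeometric_enrichment(["zz"], ann)


@pytest.mark.parametrize(
    "groups,expected",
    [
        ("TSS1500;Body", "TSS1500"),
        ("Body;TSS200", "TSS200"),
        (["3'UTR", "Body"], "Body"),
        ("", "Intergenic"),
    ],
)
def test_refgene_precedence(groups, expected):
    assert resolve_refgene_annotation(groups) == expected
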