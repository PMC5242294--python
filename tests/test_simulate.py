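"""Simulator unit and property tests: drift law, populations, reads, matrices."""

import numpy as np
import pandas as pd
import pytest

from senmeth import simulate
from senmeth.simulate import (
    CpGDriftParams,
    expected_methylation,
    generate_beta_matrix,
    generate_reads,
    sample_bulk,
    sample_clone,
)


@pytest.mark.parametrize(
    "p0,slope,t,expected",
    [
        (0.5, 0.0, 10, 0.5),      # zero slope is the identity
        (0.9, 0.05, 10, 1.0),     # clipped at 1
        (0.2, 0.03, 10, 0.5),     # plain arithmetic
        (0.3, -0.05, 10, 0.0),    # clipped at 0
    ],
)
def test_expected_methylation(p0, slope, t, expected):
    params = CpGDriftParams("c", p0, slope)
    assert expected_methylation(params, t) == pytest.approx(expected)


def test_expected_methylation_rejects_negative_passage():
    with pytest.raises(ValueError):
        expected_methylation(CpGDriftParams("c", 0.5, 0.0), -1)


def test_drift_params_validate_p0():
    with pytest.raises(ValueError):
        CpGDriftParams("c", 1.2, 0.0)


def test_bulk_degenerate_probabilities(rng):
    """p=1 with zero slope methylates every allele; p=0 none."""
    panel = simulate.default_panel()[:1]
    drift = {panel[0].name: [CpGDriftParams(f"c{i}", 1.0, 0.0) for i in range(panel[0].n_cpgs)]}
    cfg = simulate.SimulationConfig(amplicons=panel, drift=drift, n_cells_bulk=50)
    pop = sample_bulk(cfg, 5, rng)
    assert pop.alleles[panel[0].name].all()


def test_bulk_beta_converges_to_expected_probability():
    """Per-CpG bulk beta approaches p0 + slope*t within 3 binomial SEs at n=1e4."""
    cfg = simulate.default_config(seed=3, n_cells_bulk=10_000)
    rng = np.random.default_rng(3)
    pop = sample_bulk(cfg, 10, rng)
    for spec in cfg.amplicons:
        p = np.array([expected_methylation(d, 10) for d in cfg.drift[spec.name]])
        se = np.sqrt(p * (1 - p) / (2 * cfg.n_cells_bulk))
        assert np.all(np.abs(pop.beta(spec.name) - p) <= 3 * se + 1e-12)


def test_population_beta_is_exact_allele_fraction(config, rng):
    """Conservation: beta equals methylated alleles / (2 * n_cells) exactly."""
    pop = sample_bulk(config, 8, rng)
    arr = pop.alleles["CASR"]
    manual = arr.sum(axis=(0, 1)) / (2 * arr.shape[0])
    np.testing.assert_array_equal(pop.beta("CASR"), manual)


def test_bulk_determinism(config):
    pops = [sample_bulk(config, 6, np.random.default_rng(11)) for _ in range(2)]
    for name in pops[0].alleles:
        np.testing.assert_array_equal(pops[0].alleles[name], pops[1].alleles[name])


def test_zero_switch_clone_is_founder_copy(config, rng):
    pop = sample_bulk(config, 8, rng)
    clone = sample_clone(pop, 30, 0.0, rng)
    assert clone.provenance == "clone"
    for name, arr in clone.alleles.items():
        founder = clone.founder.alleles[name]
        assert (arr == founder[None]).all()
        betas = clone.beta(name)
        assert set(np.round(betas, 10)) <= {0.0, 0.5, 1.0}


def test_clone_mean_matches_bulk_within_3se(config):
    """Law of total expectation: mean clone beta over many clones ≈ bulk beta."""
    rng = np.random.default_rng(5)
    pop = sample_bulk(config, 10, rng)
    clones = [sample_clone(pop, 1, 0.0, rng) for _ in range(300)]
    for name in ("CASR", "GRM7"):
        bulk = pop.beta(name)
        clone_betas = np.array([c.beta(name) for c in clones])
        se = np.sqrt(bulk * (1 - bulk) / (2 * len(clones)))
        assert np.all(np.abs(clone_betas.mean(axis=0) - bulk) <= 3 * se + 1e-12)


def test_reads_pure_states_and_conversion(casr, config, rng):
    """Zero error rates: methylated -> C at CpGs, unmethylated -> T; non-CpG C -> T."""
    cfg = simulate.SimulationConfig(
        amplicons=config.amplicons,
        drift={s.name: [CpGDriftParams(f"c{i}", 1.0, 0.0) for i in range(s.n_cpgs)]
               for s in config.amplicons},
        n_cells_bulk=20,
        conversion_failure_rate=0.0, inappropriate_conversion_rate=0.0, seq_error_rate=0.0,
    )
    pop = sample_bulk(cfg, 0, rng)
    reads = generate_reads(pop, casr, cfg, rng, n_reads=50)
    for r in reads:
        assert all(r.sequence[o] == "C" for o in casr.cpg_offsets)
        assert all(r.sequence[o] == "T" for o in casr.non_cpg_c_offsets)
    # fully unmethylated: T everywhere a C was
    cfg0 = simulate.SimulationConfig(
        amplicons=cfg.amplicons,
        drift={s.name: [CpGDriftParams(f"c{i}", 0.0, 0.0) for i in range(s.n_cpgs)]
               for s in cfg.amplicons},
        n_cells_bulk=20,
        conversion_failure_rate=0.0, inappropriate_conversion_rate=0.0, seq_error_rate=0.0,
    )
    pop0 = sample_bulk(cfg0, 0, rng)
    for r in generate_reads(pop0, casr, cfg0, rng, n_reads=50):
        assert all(r.sequence[o] == "T" for o in casr.cpg_offsets)
        assert all(r.sequence[o] == "T" for o in casr.non_cpg_c_offsets)


def test_conversion_failure_rate_recovered(casr, rng):
    """Fraction of non-CpG C positions reading C matches the configured rate."""
    rate = 0.01
    cfg = simulate.default_config(
        seed=0, n_cells_bulk=50,
        conversion_failure_rate=rate, inappropriate_conversion_rate=0.0, seq_error_rate=0.0,
    )
    pop = sample_bulk(cfg, 5, rng)
    n_reads = 4000  # >= 1e5 non-CpG C observations
    reads = generate_reads(pop, casr, cfg, rng, n_reads=n_reads)
    sites = casr.non_cpg_c_offsets
    total = n_reads * len(sites)
    assert total >= 1e5
    retained = sum(r.sequence[o] == "C" for r in reads for o in sites)
    se = np.sqrt(rate * (1 - rate) / total)
    assert abs(retained / total - rate) <= 3 * se


def test_generate_reads_unknown_amplicon(config, rng):
    pop = sample_bulk(config, 5, rng)
    other = simulate.AmpliconSpec("other", "OTHER", "ACGT", (1,))
    with pytest.raises(KeyError):
        generate_reads(pop, other, config, rng, n_reads=5)


def test_stratified_reads_reproduce_allele_fractions(casr, rng):
    cfg = simulate.default_config(
        seed=2, n_cells_bulk=50,
        conversion_failure_rate=0.0, inappropriate_conversion_rate=0.0, seq_error_rate=0.0,
    )
    pop = sample_bulk(cfg, 8, rng)
    reads = generate_reads(pop, casr, cfg, rng, n_reads=200, coverage_mode="stratified")
    frac = np.mean([[s == "C" for s in (r.sequence[o] for o in casr.cpg_offsets)]
                    for r in reads], axis=0)
    np.testing.assert_allclose(frac, pop.beta("CASR"), atol=1e-12)


def test_simulated_run_determinism(tmp_path):
    cfg_kwargs = dict(seed=9, n_cells_bulk=100, reads_per_sample=120)
    outs = []
    for sub in ("a", "b"):
        cfg = simulate.default_config(**cfg_kwargs)
        simulate.simulate_bbaseq_run(cfg, tmp_path / sub, clones_per_passage=1, clone_cells=20)
        outs.append({p.name: p.read_bytes() for p in sorted((tmp_path / sub).iterdir())})
    assert outs[0] == outs[1]


def test_config_yaml_roundtrip(tmp_path, config):
    path = tmp_path / "cfg.yaml"
    config.to_yaml(path)
    loaded = simulate.SimulationConfig.from_yaml(path)
    assert loaded == config


# ---------------------------------------------------------------------------
# beta matrices


def test_beta_matrix_null_has_no_large_shifts(rng):
    """fraction_drifting=0: no CpG shows a mean shift beyond the Gaussian bound."""
    n, k = 2000, 6
    betas, _, truth = generate_beta_matrix(n, k, 0.0, rng, noise_sd=0.02)
    assert not truth["is_drifting"].any()
    early = betas.filter(like="early_").mean(axis=1)
    late = betas.filter(like="late_").mean(axis=1)
    # 4 sigma of the difference of two means of k samples, plus multiplicity head-room
    bound = 5 * 0.02 * np.sqrt(2 / k)
    assert (late - early).abs().max() < bound


def test_beta_matrix_planted_effect_and_annotation(rng):
    betas, annotation, truth = generate_beta_matrix(
        3000, 4, 0.05, rng, effect_size=0.3, noise_sd=0.02
    )
    assert ((betas.values >= 0) & (betas.values <= 1)).all()
    drift = truth["is_drifting"]
    assert drift.sum() == 150
    # planted shifts are ±effect_size in the right direction
    delta = betas.filter(like="late_").mean(axis=1) - betas.filter(like="early_").mean(axis=1)
    hyper = truth["direction"] == 1
    assert delta[hyper].min() > 0.2
    assert delta[truth["direction"] == -1].max() < -0.2
    # promoter/CGI depletion among drifting CpGs
    promoter = annotation["refgene_group"].isin(["TSS200", "TSS1500", "5'UTR", "1stExon"])
    assert promoter[drift].mean() < promoter.mean()
    island = annotation["cgi_relation"] == "Island"
    assert island[drift].mean() < island.mean()


def test_beta_matrix_determinism():
    mats = [
        generate_beta_matrix(200, 3, 0.1, np.random.default_rng(4))[0] for _ in range(2)
    ]
    pd.testing.assert_frame_equal(mats[0], mats[1])


def test_beta_matrix_rejects_bad_effect_size(rng):
    with pytest.raises(ValueError):
        generate_beta_matrix(10, 3, 0.1, rng, effect_size=1.5)
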