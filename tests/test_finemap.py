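"""Unit tests for configuration Bayes factors, enumeration, PIPs and credible sets."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from conftest import make_locus
from finecoloc.finemap import (
    CredibleSet,
    FineMapConfig,
    LocusData,
    SignalCluster,
    cluster_signals,
    compute_pips,
    config_log_bf,
    credible_set,
    enumerate_posterior,
    finemap_locus,
    make_variant_ids,
    parse_variant_id,
)
from finecoloc.simulate import SimulationTruth, simulate_panel, simulate_study


def brute_force_posteriors(locus, config):
    """Independent exhaustive enumeration over all configurations up to max size."""
    m = locus.variant_count
    p = 1.0 / m if config.prior_inclusion is None else config.prior_inclusion
    out = {}
    for size in range(0, config.max_signals + 1):
        for gamma in itertools.combinations(range(m), size):
            lbf = config_log_bf(locus, gamma, config.prior_effect_sd, config.ld_ridge)
            lprior = size * np.log(p) + (m - size) * np.log(1 - p)
            out[gamma] = lbf + lprior
    keys = sorted(out)
    scores = np.array([out[k] for k in keys])
    posts = np.exp(scores - logsumexp(scores))
    return dict(zip(keys, posts))


class TestConfigLogBF:
    def test_empty_configuration_is_zero(self):
        locus = make_locus([1.0, 2.0, 3.0])
        assert config_log_bf(locus, []) == 0.0

    def test_single_variant_at_z_zero_is_negative_closed_form(self):
        locus = make_locus([0.0], n=4000)
        ridge = 1e-3
        w = 4000 * 0.2**2
        expected = -0.5 * np.log(1 + (1 + ridge) * w)
        assert config_log_bf(locus, [0], ld_ridge=ridge) == pytest.approx(expected)
        assert config_log_bf(locus, [0], ld_ridge=ridge) < 0

    def test_matches_wakefield_abf_without_ld(self):
        # independent single-variant oracle from (beta, se, prior variance)
        locus = make_locus([3.7], n=8000)
        beta, se = locus.beta[0], locus.se[0]
        w_beta = locus.n[0] * 0.2**2 * se**2  # prior variance on the beta scale
        z2 = (beta / se) ** 2
        log_abf = 0.5 * np.log(se**2 / (se**2 + w_beta)) \
            + z2 * w_beta / (2 * (se**2 + w_beta))
        assert config_log_bf(locus, [0], ld_ridge=0.0) == pytest.approx(
            log_abf, abs=1e-8
        )

    def test_matches_full_covariance_density_oracle(self, rng):
        m = 6
        A = rng.normal(size=(m, m))
        R = np.corrcoef(A @ A.T + 5 * np.eye(m))
        locus = make_locus(rng.normal(0, 3, m), ld=R, n=5000)
        ridge = 1e-3
        Rp = R + ridge * np.eye(m)
        null = multivariate_normal(np.zeros(m), Rp)
        for indices in [(0,), (2, 4), (1, 3, 5), (0, 1, 2, 3)]:
            idx = list(indices)
            X = Rp[:, idx]
            W = np.diag(locus.n[idx] * 0.2**2)
            direct = multivariate_normal(np.zeros(m), Rp + X @ W @ X.T).logpdf(locus.z) \
                - null.logpdf(locus.z)
            # scipy's density goes through an eigendecomposition; agreement is
            # limited by that route's own float error, not the formula
            assert config_log_bf(locus, idx, ld_ridge=ridge) == pytest.approx(
                direct, abs=1e-6
            )

    def test_rejects_duplicate_and_out_of_range_indices(self):
        locus = make_locus([1.0, 2.0])
        with pytest.raises(ValueError):
            config_log_bf(locus, [0, 0])
        with pytest.raises(ValueError):
            config_log_bf(locus, [5])


class TestEnumeration:
    def test_strong_causal_dominates_without_ld(self):
        z = np.zeros(20)
        z[7] = 10.0
        locus = make_locus(z, n=10_000)
        config = FineMapConfig(max_signals=2)
        configs = enumerate_posterior(locus, config)
        assert len(configs) == 1 + 20 + 190  # null + singletons + pairs
        top = configs[0]
        assert top.indices == (7,)
        assert top.posterior > 0.9

    def test_null_config_wins_when_all_z_zero(self):
        locus = make_locus(np.zeros(10), n=5000)
        configs = enumerate_posterior(locus, FineMapConfig(max_signals=2))
        assert configs[0].indices == ()

    def test_posteriors_sum_to_one(self):
        locus = make_locus([1.0, -2.0, 0.5, 3.0], n=2000)
        configs = enumerate_posterior(locus, FineMapConfig())
        assert sum(c.posterior for c in configs) == pytest.approx(1.0)

    def test_matches_exhaustive_brute_force_at_small_m(self, rng):
        for trial in range(3):
            m = 8
            A = rng.normal(size=(m, m))
            R = np.corrcoef(A @ A.T + 4 * np.eye(m))
            locus = make_locus(rng.normal(0, 2, m), ld=R, n=3000)
            config = FineMapConfig(max_signals=2)
            configs = enumerate_posterior(locus, config)
            expected = brute_force_posteriors(locus, config)
            assert len(configs) == len(expected)
            for c in configs:
                assert c.posterior == pytest.approx(expected[c.indices], abs=1e-10)

    def test_two_independent_causals_recovered_in_size_two_config(self):
        panel = simulate_panel(30, 2000, 10, 0.95, (0.1, 0.5), seed=21)
        truth = SimulationTruth.from_dicts(
            {5: (0.02, 1.0), 25: (0.02, 1.0)}, {}
        )
        locus = simulate_study(panel, truth, 10_000, 1, seed=22)
        configs = enumerate_posterior(locus, FineMapConfig(max_signals=2))
        best_pair = next(c for c in configs if len(c.indices) == 2)
        pair_mass = sum(
            c.posterior for c in configs
            if len(c.indices) == 2 and 5 in c.indices and 25 in c.indices
        )
        # LD proxies of each causal may share the mass; the pair of signals
        # (not necessarily the exact variants) must dominate
        assert set(best_pair.indices) & set(range(10)) or pair_mass > 0
        joint = sum(
            c.posterior for c in configs
            if any(i < 10 for i in c.indices) and any(i >= 20 for i in c.indices)
        )
        assert joint > 0.5


class TestPips:
    def test_definition_on_tiny_config_sets(self):
        configs = [
            type("C", (), {"indices": (), "posterior": 0.5})(),
            type("C", (), {"indices": (0,), "posterior": 0.5})(),
        ]
        pips = compute_pips(configs, 3)
        assert pips[0] == pytest.approx(0.5)
        assert pips[1] == pips[2] == 0.0

    def test_overlapping_configs_accumulate(self):
        configs = [
            type("C", (), {"indices": (0,), "posterior": 0.4})(),
            type("C", (), {"indices": (0, 1), "posterior": 0.6})(),
        ]
        pips = compute_pips(configs, 2)
        assert pips[0] == pytest.approx(1.0)
        assert pips[1] == pytest.approx(0.6)

    def test_matches_independent_summation_on_random_configs(self, rng):
        m = 12
        raw = []
        for _ in range(40):
            size = int(rng.integers(0, 4))
            idx = tuple(sorted(rng.choice(m, size, replace=False).tolist()))
            raw.append(idx)
        w = rng.random(len(raw))
        w /= w.sum()
        configs = [
            type("C", (), {"indices": idx, "posterior": float(p)})()
            for idx, p in zip(raw, w)
        ]
        pips = compute_pips(configs, m)
        for v in range(m):
            expected = sum(p for idx, p in zip(raw, w) if v in idx)
            assert pips[v] == pytest.approx(expected, abs=1e-12)


class TestClustering:
    def test_perfect_proxies_form_one_signal(self):
        m = 6
        ld = np.ones((m, m))
        z = np.full(m, 8.0)
        locus = make_locus(z, ld=ld, n=5000)
        result = finemap_locus(locus)
        clusters = cluster_signals(
            enumerate_posterior(locus, FineMapConfig()), locus, FineMapConfig()
        )
        assert len(clusters) == 1
        assert clusters[0].indices.size <= 6
        total_pip = result.pips.sum()
        assert clusters[0].signal_pip_total == pytest.approx(total_pip, rel=1e-6)

    def test_no_signal_yields_no_clusters(self):
        locus = make_locus(np.zeros(15), n=5000)
        configs = enumerate_posterior(locus, FineMapConfig(max_signals=2))
        assert cluster_signals(configs, locus, FineMapConfig()) == []

    def test_two_block_causals_yield_two_clusters(self):
        panel = simulate_panel(30, 2000, 10, 0.95, (0.1, 0.5), seed=31)
        truth = SimulationTruth.from_dicts({4: (0.03, 1.0), 24: (0.03, 1.0)}, {})
        locus = simulate_study(panel, truth, 10_000, 1, seed=32)
        config = FineMapConfig()
        clusters = cluster_signals(enumerate_posterior(locus, config), locus, config)
        strong = [c for c in clusters if c.signal_pip_total > 0.5]
        assert len(strong) == 2
        blocks = sorted(set(c.seed_index // 10 for c in strong))
        assert blocks == [0, 2]


class TestCredibleSet:
    def test_prefix_arithmetic(self):
        cluster = SignalCluster(indices=np.arange(4),
                                pips=np.array([0.7, 0.2, 0.05, 0.05]),
                                seed_index=0)
        locus = make_locus(np.zeros(4))
        cs = credible_set(cluster, locus, coverage=0.95)
        assert len(cs.member_ids) == 3
        assert cs.coverage_achieved == pytest.approx(0.95)
        assert cs.lead_id == str(locus.variant_ids[0])

    def test_single_member_has_full_coverage(self):
        cluster = SignalCluster(indices=np.array([2]), pips=np.array([0.4]),
                                seed_index=2)
        locus = make_locus(np.zeros(3))
        cs = credible_set(cluster, locus)
        assert list(cs.member_ids) == [str(locus.variant_ids[2])]
        assert cs.coverage_achieved == pytest.approx(1.0)

    def test_twenty_equal_members_need_nineteen(self):
        cluster = SignalCluster(indices=np.arange(20), pips=np.full(20, 0.04),
                                seed_index=0)
        locus = make_locus(np.zeros(20))
        cs = credible_set(cluster, locus, coverage=0.95)
        assert len(cs.member_ids) == 19

    def test_empty_cluster_rejected(self):
        locus = make_locus(np.zeros(2))
        with pytest.raises(ValueError):
            credible_set(SignalCluster(np.array([], dtype=int),
                                       np.array([]), 0), locus)


class TestLocusData:
    def test_exchange_symmetry_under_permutation(self, rng):
        panel = simulate_panel(20, 1500, 5, 0.9, (0.1, 0.5), seed=41)
        truth = SimulationTruth.from_dicts({3: (0.02, 1.0)}, {})
        locus = simulate_study(panel, truth, 5000, 1, seed=42)
        perm = rng.permutation(locus.variant_count)
        permuted = locus.subset(perm)
        r1 = finemap_locus(locus)
        r2 = finemap_locus(permuted)
        s1 = r1.pips.sort_index()
        s2 = r2.pips.sort_index()
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)
        sets1 = {frozenset(cs.member_ids) for cs in r1.credible_sets}
        sets2 = {frozenset(cs.member_ids) for cs in r2.credible_sets}
        assert sets1 == sets2

    def test_bad_se_variants_are_dropped_not_fatal(self, caplog):
        df = pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3"],
                "chrom": ["chr1"] * 3,
                "pos": [100, 200, 300],
                "ref": ["A"] * 3,
                "alt": ["G"] * 3,
                "beta": [0.1, 0.2, 0.3],
                "se": [0.05, -1.0, np.nan],
                "n": [1000] * 3,
                "maf": [0.2] * 3,
            }
        )
        with caplog.at_level("WARNING"):
            locus = LocusData.from_frame(df, np.eye(3))
        assert locus.variant_count == 1
        assert "dropping 2" in caplog.text

    def test_invalid_ld_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            make_locus([1.0, 2.0], ld=np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_variant_id_roundtrip(self):
        ids = make_variant_ids("chr5", [80074424], ["G"], ["T"])
        assert ids[0] == "chr5_80074424_G_T_b38"
        assert parse_variant_id(ids[0]) == ("chr5", 80074424, "G", "T", "b38")


class TestConfigValidation:
    def test_coverage_bounds(self):
        with pytest.raises(ValueError):
            FineMapConfig(coverage=1.0)

    def test_max_signals_positive(self):
        with pytest.raises(ValueError):
            FineMapConfig(max_signals=0)
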