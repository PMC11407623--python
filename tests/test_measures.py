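"""Information measures against plug-in and closed-form oracles."""

import numpy as np
import pytest

from infodyn.measures import (
    average_over_living,
    decomposition_check,
    local_ais,
    local_apparent_te,
    local_collective_te,
    local_entropy,
    local_intrinsic_uncertainty,
)
from infodyn.community import CommunityTimeSeries, extinction_steps
from infodyn.oracles import (
    gaussian_te_closed_form,
    plugin_local_cond_entropy,
    plugin_local_entropy,
    plugin_local_cmi,
    plugin_series_measures,
)
from infodyn.tables import AnalysisConfig

from conftest import ar_coupled_pair

CFG = AnalysisConfig(n_estimation_runs=5, rng_seed=0)


class TestLocalEntropy:
    def test_uniform_alphabet_plugin_is_log8(self):
        series = np.tile(np.arange(8), 50)
        h = plugin_local_entropy(series)
        assert np.allclose(h, np.log(8))

    def test_constant_series_plugin_is_zero(self):
        assert np.allclose(plugin_local_entropy(np.full(40, 3)), 0.0)

    def test_mean_plugin_entropy_is_shannon_entropy(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, size=500)
        counts = np.bincount(x) / x.size
        shannon = -np.sum(counts * np.log(counts))
        assert np.isclose(plugin_local_entropy(x).mean(), shannon)

    def test_signal_alignment_and_validity(self):
        sig = local_entropy(np.arange(50), k=5, config=CFG)
        assert sig.steps()[0] == 6
        assert np.isnan(sig.values[:5]).all()


class TestLocalAIS:
    def test_iid_series_stores_nothing(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=2000)
        sig = local_ais(x, k=2, config=CFG)
        assert abs(sig.mean_value) < 0.03

    def test_alternating_series_stores_one_bit(self):
        x = np.arange(601) % 2  # odd length: both transition types equally often
        plug = plugin_series_measures(x, 0, 1, 1, 1)
        assert np.allclose(plug["ais"], np.log(2))  # exact for the plug-in
        sig = local_ais(x, k=1, config=AnalysisConfig(n_estimation_runs=10))
        assert abs(sig.mean_value - np.log(2)) < 0.1

    def test_sudden_change_after_plateau_is_misinformative(self):
        """Local AIS goes negative where a plateau breaks."""
        x = np.concatenate([np.full(60, 10), np.full(40, 50)])
        sig = local_ais(x, k=3, config=CFG)
        assert sig.values[60] < 0  # step 61, the jump

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            local_ais(np.arange(5), k=4, config=CFG)


class TestApparentTE:
    def test_independent_sources_transfer_nothing(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        sig = local_apparent_te(y, x, k=1, l=1, d=1, config=CFG)
        assert abs(sig.mean_value) < 0.03

    def test_copy_with_noise_matches_closed_form(self):
        """Y_{n+1} = X_{n-1} + eps has TE = 0.5 ln 2 at d = 2."""
        rng = np.random.default_rng(3)
        T = 5000
        x = rng.normal(size=T)
        y = np.zeros(T)
        y[2:] = x[:-2] + rng.normal(size=T - 2)
        sig = local_apparent_te(x, y, k=1, l=1, d=2, config=CFG)
        truth = gaussian_te_closed_form(1.0, 1.0)
        assert truth == pytest.approx(0.5 * np.log(2))
        assert abs(sig.mean_value - truth) < 0.05

    def test_source_equal_to_destination_rejected(self):
        x = np.arange(100, dtype=float)
        with pytest.raises(ValueError):
            local_apparent_te(x, x, k=1, config=CFG)


class TestCollectiveTE:
    def test_single_contributor_equals_apparent_te(self):
        x, y = ar_coupled_pair(400, seed=4)
        ab = np.column_stack([x, y])
        cte = local_collective_te(ab, 0, k=2, l=1, d=1, config=CFG, seed=9)
        te = local_apparent_te(y, x, k=2, l=1, d=1, config=CFG, seed=9)
        assert np.allclose(cte.values[cte.valid], te.values[te.valid])

    def test_plugin_cte_is_sum_of_incrementally_conditioned_tes(self):
        """CTE chains over sources, whatever their order, and is not the sum
        of apparent TEs."""
        rng = np.random.default_rng(5)
        ab = rng.integers(0, 2, size=(400, 3))
        ab[1:, 0] = (ab[:-1, 1] + ab[:-1, 2] + (rng.random(399) < 0.2)) % 2
        m = plugin_series_measures(ab, 0, 1, 1, 1)
        n_values = np.arange(1, 400)
        A = ab[n_values, 0]
        C = ab[n_values - 1, 0][:, None]
        V1 = ab[n_values - 1, 1][:, None]
        V2 = ab[n_values - 1, 2][:, None]
        for first, second in ((V1, V2), (V2, V1)):
            inc = (plugin_local_cmi(A, first, C)
                   + plugin_local_cmi(A, second, np.hstack([C, first])))
            assert np.allclose(m["cte"], inc)

    def test_uninformative_contributors_transfer_nothing(self):
        rng = np.random.default_rng(6)
        ab = rng.normal(size=(1500, 3))
        sig = local_collective_te(ab, 0, k=1, l=1, d=1, config=CFG)
        assert abs(sig.mean_value) < 0.05


class TestIntrinsicUncertainty:
    def test_deterministic_system_plugin_uncertainty_is_zero(self):
        x = np.arange(100) % 4
        cond = (np.arange(100) - 1) % 4
        u = plugin_local_cond_entropy(x[1:], cond[1:])
        assert np.allclose(u, 0.0)

    def test_balanced_coin_plugin_uncertainty_is_log2(self):
        """Every 1-step history is followed by both symbols equally often."""
        x = np.append(np.tile([0, 0, 1, 1], 100), 0)  # 100 of each transition
        m = plugin_series_measures(x, 0, 1, 1, 1)
        assert np.allclose(m["u"], np.log(2))

    def test_gaussian_uncertainty_is_positive(self):
        x, y = ar_coupled_pair(1500, seed=7)
        sig = local_intrinsic_uncertainty(
            np.column_stack([x, y]), 0, k=1, l=1, d=1, config=CFG
        )
        # h(X | past, sources) ~ 0.5 log(2 pi e sigma^2) > 0 for unit noise
        assert sig.mean_value > 0


class TestDecomposition:
    def test_plugin_identity_is_exact(self):
        rng = np.random.default_rng(8)
        ab = rng.integers(0, 3, size=(300, 2))
        m = plugin_series_measures(ab, 0, 2, 1, 1)
        residual = m["h"] - m["ais"] - m["cte"] - m["u"]
        assert np.allclose(residual, 0.0, atol=1e-12)

    def test_ksg_residual_small_on_gaussian_system(self):
        x, y = ar_coupled_pair(2500, seed=9)
        _, residual = decomposition_check(
            np.column_stack([x, y]), 0, k=1, l=1, d=1, config=CFG
        )
        assert abs(residual.mean()) < 0.05

    def test_no_contributors_reduces_to_h_equals_a_plus_u(self):
        x, _ = ar_coupled_pair(1500, seed=10)
        _, residual = decomposition_check(x, 0, k=1, l=1, d=1, config=CFG)
        assert abs(residual.mean()) < 0.05


class TestAverageOverLiving:
    def _ts(self, ab):
        return CommunityTimeSeries(
            species_names=[f"s{i}" for i in range(ab.shape[1])],
            abundance=ab,
            feeding_steps=[],
            extinction_step=extinction_steps(ab),
        )

    def _signal(self, values, species):
        from infodyn.measures import LocalSignal
        v = np.asarray(values, dtype=float)
        return LocalSignal(species, "AIS", 1, None, None, v, ~np.isnan(v))

    def test_all_alive_is_plain_mean(self):
        ab = np.ones((4, 2), dtype=np.int64)
        ts = self._ts(ab)
        s1 = self._signal([1, 2, 3, 4], "s0")
        s2 = self._signal([3, 4, 5, 6], "s1")
        avg = average_over_living([s1, s2], ts)
        assert np.allclose(avg.values, [2, 3, 4, 5])

    def test_extinct_species_drops_out(self):
        ab = np.array([[1, 1], [1, 1], [1, 0], [1, 0]], dtype=np.int64)
        ts = self._ts(ab)
        s1 = self._signal([1, 2, 3, 4], "s0")
        s2 = self._signal([3, 4, 5, 6], "s1")
        avg = average_over_living([s1, s2], ts)
        assert np.allclose(avg.values, [2, 3, 3, 4])

    def test_single_species_is_identity(self):
        ab = np.ones((3, 1), dtype=np.int64)
        s1 = self._signal([1.0, np.nan, 3.0], "s0")
        avg = average_over_living([s1], self._ts(ab))
        assert np.allclose(avg.values[[0, 2]], [1, 3])
        assert not avg.valid[1]
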