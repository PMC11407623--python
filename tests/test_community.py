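"""Simulator behaviour: growth phases, plateaus, extinctions, interventions."""

import numpy as np
import pytest

from infodyn.community import (
    CommunityConfig,
    crossfeeding_config,
    disturb_coherence,
    enforce_crossfeeding,
    simulate_base,
)


def longest_constant_run(col: np.ndarray) -> int:
    best = run = 1
    for i in range(1, col.size):
        run = run + 1 if (col[i] == col[i - 1] and col[i] > 0) else 1
        best = max(best, run)
    return best


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(growth_rate=(1.2,) * 7),
        dict(death_rate=(-0.1,) * 7),
        dict(feeding_steps=[35, 200], n_steps=184),
        dict(initial_abundance=-1),
        dict(uptake=(0.0,) * 7),
        dict(growth_rate=(0.5,) * 3),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_base(CommunityConfig(**bad))


class TestBaseScenario:
    def test_zero_growth_keeps_abundances_constant(self):
        cfg = CommunityConfig(growth_rate=(0.0,) * 7)
        ts = simulate_base(cfg)
        assert np.all(ts.abundance == cfg.initial_abundance)

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_base(CommunityConfig(rng_seed=11))
        b = simulate_base(CommunityConfig(rng_seed=11))
        assert np.array_equal(a.abundance, b.abundance)
        c = simulate_base(CommunityConfig(rng_seed=12))
        assert not np.array_equal(a.abundance, c.abundance)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_qualitative_phase_structure(self, seed):
        """Growth, long plateaus, extinctions, feeding recovery, lone survivor."""
        ts = simulate_base(CommunityConfig(rng_seed=seed))
        ab = ts.abundance
        T, S = ab.shape
        # initial nutrient-rich growth in every species
        assert all(ab[1:6, s].max() > ab[0, s] for s in range(S))
        # at least one extinction before the final step
        assert any(e is not None and e < T for e in ts.extinction_step)
        # at most one species alive at the end
        assert (ab[-1] > 0).sum() <= 1
        # renewed growth within 5 steps of each feeding for some survivor
        for f in ts.feeding_steps:
            assert any(
                ab[f + j, s] > ab[f + j - 1, s]
                for j in range(1, 6) for s in range(S) if ab[f - 1, s] > 0
            )
        # a plateau of >= 10 constant steps per surviving species between feedings
        bounds = [1] + list(ts.feeding_steps) + [T]
        for s in range(S):
            runs = [
                longest_constant_run(ab[b0 - 1:b1, s])
                for b0, b1 in zip(bounds[:-1], bounds[1:])
            ]
            assert max(runs) >= 10

    def test_series_passes_its_own_validation(self, base_ts):
        base_ts.validate()  # non-negative ints, absorbing extinction

    def test_resource_pool_only_refills_at_feedings(self, base_ts):
        """Pool decreases only by consumption; feedings add exactly the refill."""
        res = base_ts.resource
        refill = CommunityConfig().resource_refill
        for t in range(1, len(res)):
            step = t  # transition from step t to t+1
            added = refill if step in base_ts.feeding_steps else 0.0
            consumed = res[t - 1] + added - res[t]
            assert consumed >= -1e-9


class TestDisturbCoherence:
    def test_zero_jitter_is_identity(self, base_ts):
        out = disturb_coherence(base_ts, (109, 128), 0.0, seed=5)
        assert np.array_equal(out.abundance, base_ts.abundance)

    def test_outside_window_unchanged_and_extinction_absorbing(self, base_ts):
        out = disturb_coherence(base_ts, (109, 128), 0.3, seed=5)
        ab0, ab1 = base_ts.abundance, out.abundance
        assert np.array_equal(ab0[:108], ab1[:108])
        assert np.array_equal(ab0[128:], ab1[128:])
        out.validate()  # extinction stays absorbing
        dead = ab0[108:128] == 0
        assert np.all(ab1[108:128][dead] == 0)

    def test_most_living_cells_change(self, base_ts):
        out = disturb_coherence(base_ts, (109, 128), 0.3, seed=5)
        win0 = base_ts.abundance[108:128]
        win1 = out.abundance[108:128]
        living = win0 > 0
        frac = np.mean(win0[living] != win1[living])
        assert frac >= 0.8

    @pytest.mark.parametrize("window,jitter", [
        ((120, 110), 0.3), ((0, 10), 0.3), ((100, 300), 0.3), ((109, 128), -0.1),
    ])
    def test_bad_window_or_jitter_rejected(self, base_ts, window, jitter):
        with pytest.raises(ValueError):
            disturb_coherence(base_ts, window, jitter)


class TestEnforceCrossfeeding:
    def test_null_intervention_equals_plain_run(self):
        cfg = crossfeeding_config(rng_seed=3)
        plain = enforce_crossfeeding(cfg, n_injected=0, boost=0.0)
        again = enforce_crossfeeding(cfg, n_injected=0, boost=0.0)
        assert np.array_equal(plain.abundance, again.abundance)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_target_responds_exactly_two_steps_after_injection(self, seed):
        cfg = crossfeeding_config(rng_seed=seed)
        plain = enforce_crossfeeding(cfg, n_injected=0, boost=0.0)
        man = enforce_crossfeeding(cfg)
        prod, targ, inject = 4, 1, 28
        # injection visible in the producer column at the injection step
        assert man.abundance[inject - 1, prod] == plain.abundance[inject - 1, prod] + 20
        # target rises first at injection + 2, and was flat there without it
        assert man.abundance[inject + 1, targ] > man.abundance[inject, targ]
        assert man.abundance[inject, targ] == plain.abundance[inject, targ]
        assert plain.abundance[inject + 1, targ] == plain.abundance[inject, targ]

    def test_extinct_target_stays_extinct(self):
        cfg = crossfeeding_config(rng_seed=0)
        cfg.starvation_tolerance = (40, 2, 40, 40, 40, 40, 40)
        cfg.death_rate = (0.45, 1.0, 0.42, 0.40, 0.35, 0.10, 0.55)
        out = enforce_crossfeeding(cfg)
        assert out.extinction_step[1] is not None
        assert out.extinction_step[1] < 28
        assert np.all(out.abundance[27:, 1] == 0)

    @pytest.mark.parametrize("kwargs", [
        dict(producer=1, target=1),
        dict(n_injected=-5),
        dict(injection_step=37),
        dict(producer=9),
    ])
    def test_invalid_intervention_rejected(self, kwargs):
        with pytest.raises(ValueError):
            enforce_crossfeeding(crossfeeding_config(), **kwargs)
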