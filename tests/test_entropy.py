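import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import cycles_from_bounds
from oracles import brute_match_fractions, brute_sample_entropy
from pgme.embedding import embed
from pgme.entropy import (EntropyConfig, MatchCounts, count_matches,
                          pgme_epoch, pgme_subject, qlog, qsaen)
from pgme.exceptions import DataError
from pgme.synthetic import GaitSimParams, simulate_epoch


class TestQlog:
    def test_identities(self):
        grid = np.linspace(-1, 1, 21)
        np.testing.assert_array_equal(qlog(1.0, grid), np.zeros(21))
        assert qlog(0.5, 0.0) == -0.5
        assert qlog(np.e, 1.0) == pytest.approx(1.0, abs=1e-15)
        assert qlog(4.0, -1.0) == 7.5

    def test_continuity_at_q1(self):
        for n in (0.3, 0.9, 2.0, 7.7):
            assert qlog(n, 1.0 - 1e-10) == pytest.approx(np.log(n), rel=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(n=st.floats(min_value=0.01, max_value=100.0))
    def test_monotone_nonincreasing_in_q(self, n):
        # d/dq log_q(n) <= 0 for every n > 0 (equality only at n = 1)
        vals = qlog(n, np.linspace(-1, 1, 21))
        assert np.all(np.diff(vals) <= 1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            qlog(0.0, 0.5)
        with pytest.raises(ValueError):
            qlog(-1.0, 0.5)


class TestCountMatches:
    def test_constant_signal_all_match(self):
        X = np.zeros((20, 6))
        Y = np.zeros((20, 9))
        c = count_matches(X, Y, np.arange(20), r=0.1)
        assert c.n_x == 1.0 and c.n_y == 1.0

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            chans = rng.normal(size=(3, 60))
            pair = embed(chans, 3)
            idx = rng.choice(pair.X.shape[0], size=10, replace=False)
            r = 0.8
            for theiler in (0, 2):
                c = count_matches(pair.X, pair.Y, idx, r, theiler=theiler)
                nx, ny, npairs = brute_match_fractions(
                    pair.X, pair.Y, idx, r, theiler
                )
                assert c.n_x == nx
                assert c.n_y == ny
                assert c.pairs_evaluated == npairs

    def test_nested_inequality(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            chans = rng.normal(size=(3, 120))
            pair = embed(chans, 4)
            idx = rng.choice(pair.X.shape[0], size=30, replace=False)
            c = count_matches(pair.X, pair.Y, idx, r=0.5)
            assert 0.0 <= c.n_y <= c.n_x <= 1.0

    def test_order_free_pooling(self):
        rng = np.random.default_rng(8)
        chans = rng.normal(size=(3, 100))
        pair = embed(chans, 3)
        idx = np.arange(10, 40)
        c1 = count_matches(pair.X, pair.Y, idx, r=0.7)
        c2 = count_matches(pair.X, pair.Y, rng.permutation(idx), r=0.7)
        assert (c1.n_x, c1.n_y) == (c2.n_x, c2.n_y)

    def test_too_few_points(self):
        with pytest.raises(DataError):
            count_matches(np.zeros((5, 6)), np.zeros((5, 9)), [2], r=0.1)


class TestQsaen:
    def test_equal_counts_zero_entropy(self):
        c = MatchCounts(n_x=0.4, n_y=0.4, pairs_evaluated=100)
        grid = np.linspace(-1, 1, 21)
        np.testing.assert_allclose(qsaen(c, grid), 0.0, atol=1e-15)

    def test_closed_forms(self):
        c = MatchCounts(n_x=0.5, n_y=0.25, pairs_evaluated=100)
        assert qsaen(c, 1.0) == pytest.approx(np.log(2.0), abs=1e-12)
        assert qsaen(c, 0.0) == pytest.approx(0.25, abs=1e-15)

    def test_undefined_counts_propagate_nan(self):
        c = MatchCounts(n_x=0.1, n_y=0.0, pairs_evaluated=100)
        assert np.isnan(qsaen(c, 1.0))
        assert np.all(np.isnan(qsaen(c, np.array([-1.0, 0.0, 1.0]))))

    def test_grid_equals_per_q_recompute(self):
        c = MatchCounts(n_x=0.37, n_y=0.11, pairs_evaluated=50)
        grid = np.linspace(-1, 1, 21)
        batch = qsaen(c, grid)
        single = np.array([qsaen(c, q) for q in grid])
        np.testing.assert_array_equal(batch, single)


class TestSampleEntropyEquivalence:
    def test_q1_whole_epoch_matches_brute_force(self):
        """At q = 1, the entropy on a whole-epoch index set must equal an
        independently coded brute-force sample entropy to 1e-12."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            # random walks are smooth enough that matches always exist
            chans = np.cumsum(rng.normal(size=(3, 150)), axis=1)
            lag = 2
            pair = embed(chans, lag)
            r = 0.3 * float(np.mean(chans.std(axis=1)))
            idx = np.arange(pair.X.shape[0])
            c = count_matches(pair.X, pair.Y, idx, r)
            assert c.defined
            ref = brute_sample_entropy(chans, lag, r)
            assert qsaen(c, 1.0) == pytest.approx(ref, abs=1e-12)


class TestPGMEEpoch:
    def test_tensor_shape_and_meta(self, short_epoch, fast_entropy_cfg):
        ep, bounds = short_epoch
        tensor = pgme_epoch(ep, cycles_from_bounds(bounds), fast_entropy_cfg)
        assert tensor.values.shape == (3, 5, 5)
        assert tensor.meta["lag"] >= 1
        assert tensor.meta["r"] > 0
        assert tensor.level == "epoch"

    def test_full_grid_shape(self, short_epoch):
        ep, bounds = short_epoch
        cfg = EntropyConfig(n_dirs=8, ami_max_lag=40)
        tensor = pgme_epoch(ep, cycles_from_bounds(bounds), cfg)
        assert tensor.values.shape == (6, 5, 21)
        assert tensor.missing.shape == tensor.values.shape

    def test_defined_cells_nonnegative(self, short_epoch, fast_entropy_cfg):
        ep, bounds = short_epoch
        tensor = pgme_epoch(ep, cycles_from_bounds(bounds), fast_entropy_cfg)
        finite = tensor.values[np.isfinite(tensor.values)]
        assert len(finite) > 0
        assert np.all(finite >= -1e-12)

    def test_phase_localized_noise_raises_local_entropy(self):
        """Extra noise injected only in the 60% phase bin must raise the
        scale-1, q=1 entropy at 60% above the 0% phase in nearly all
        seeds.  The heel-strike transient is disabled so the 0% window is
        not irregular by construction, and the baseline noise is kept
        moderate so the 9-dim match counts stay defined."""
        cfg = EntropyConfig(scales=(1,), q_grid=np.array([1.0]),
                            n_dirs=8, ami_max_lag=40)
        wins = 0
        n = 40
        for seed in range(n):
            params = GaitSimParams(
                seed=seed, duration=20.0, impact_amp=0.0, noise_sigma=0.08,
                phase_noise_profile=np.array([1.0, 1.0, 1.0, 1.5, 1.0]),
            )
            ep, bounds = simulate_epoch(params)
            tensor = pgme_epoch(ep, cycles_from_bounds(bounds), cfg)
            v60 = tensor.cell(1, 60, 1.0)
            v0 = tensor.cell(1, 0, 1.0)
            if np.isfinite(v60) and np.isfinite(v0) and v60 > v0:
                wins += 1
        assert wins >= 0.95 * n

    def test_too_few_cycles_raises(self, short_epoch, fast_entropy_cfg):
        ep, bounds = short_epoch
        with pytest.raises(DataError, match="valid cycles"):
            pgme_epoch(ep, cycles_from_bounds(bounds[:4]), fast_entropy_cfg)


class TestPGMESubject:
    def _tensor(self, values, like):
        from pgme.entropy import PGMETensor
        return PGMETensor(values=values, scales=like.scales,
                          phases=like.phases, q_grid=like.q_grid)

    def test_single_epoch_identity(self, short_epoch, fast_entropy_cfg):
        ep, bounds = short_epoch
        t = pgme_epoch(ep, cycles_from_bounds(bounds), fast_entropy_cfg)
        agg = pgme_subject([t])
        np.testing.assert_array_equal(agg.values, t.values)
        assert agg.level == "subject"

    def test_median_and_bounds(self, short_epoch, fast_entropy_cfg):
        ep, bounds = short_epoch
        base = pgme_epoch(ep, cycles_from_bounds(bounds), fast_entropy_cfg)
        ts = [self._tensor(base.values * c, base) for c in (1.0, 2.0, 9.0)]
        agg = pgme_subject(ts)
        np.testing.assert_allclose(agg.values, base.values * 2.0)
        stack = np.stack([t.values for t in ts])
        ok = np.isfinite(agg.values)
        assert np.all(agg.values[ok] >= stack.min(axis=0)[ok])
        assert np.all(agg.values[ok] <= stack.max(axis=0)[ok])

    def test_missing_majority_rule(self, short_epoch, fast_entropy_cfg):
        ep, bounds = short_epoch
        base = pgme_epoch(ep, cycles_from_bounds(bounds), fast_entropy_cfg)
        v_nan = base.values.copy()
        v_nan[0, 0, 0] = np.nan
        ts = [self._tensor(v_nan, base), self._tensor(v_nan, base),
              self._tensor(base.values, base)]
        agg = pgme_subject(ts)
        assert np.isnan(agg.values[0, 0, 0])  # missing in 2/3 epochs
        with pytest.raises(DataError):
            pgme_subject([])

    def test_long_dataframe_roundtrip(self, short_epoch, fast_entropy_cfg):
        ep, bounds = short_epoch
        t = pgme_epoch(ep, cycles_from_bounds(bounds), fast_entropy_cfg)
        df = t.to_long_dataframe(subject="s1")
        assert len(df) == t.values.size
        assert set(df.columns) == {"subject", "scale", "phase", "q", "value",
                                   "missing"}
        assert df["missing"].sum() == int(t.missing.sum())
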