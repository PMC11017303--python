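import numpy as np
import pytest

from sihm.data_model import NoEventsError, StepCumHazard
from sihm.inner_solver import (
    _fixed_point,
    _make_workspace,
    _profile_fast,
    eta_bar,
    fit_inner,
    full_loglik,
    index_by_score,
    m1_update,
    m2_update,
    profile_loglik,
    squarem_accelerator,
)

from conftest import make_dataset, scenario2_dataset


def dataset_with_scores(z, events, times=None):
    """p=1 dataset whose index under beta=(1,) equals z."""
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    times = np.arange(1.0, n + 1) if times is None else np.asarray(times, float)
    return make_dataset(times, events, z[:, None])


class TestIndexByScore:
    def test_derived_block_structure(self):
        ds = dataset_with_scores([0.5, 0.2, 0.2, 0.9], [1, 0, 1, 0])
        idx = index_by_score(ds, np.array([1.0]))
        assert idx.knots == pytest.approx([0.2, 0.5])
        assert idx.md == pytest.approx([1, 1])
        assert list(idx.block_of) == [2, 1, 1, 3]

    def test_all_uncensored_distinct(self):
        z = np.array([0.3, -0.1, 0.8, 0.5])
        ds = dataset_with_scores(z, [1, 1, 1, 1])
        idx = index_by_score(ds, np.array([1.0]))
        assert idx.n_knots == 4
        assert idx.md == pytest.approx(np.ones(4))
        assert list(idx.block_of) == list(np.argsort(np.argsort(z)) + 1)

    def test_single_event_tail_censored(self):
        ds = dataset_with_scores([0.9, 0.1, 0.2], [1, 0, 0])
        idx = index_by_score(ds, np.array([1.0]))
        assert idx.n_knots == 1
        assert list(idx.block_of) == [1, 1, 1]

    def test_no_events_raises(self):
        ds = make_dataset([1.0, 2.0], [1, 0], [[0.1], [0.2]])
        broken = make_dataset([1.0, 2.0], [0, 0], [[0.1], [0.2]])
        index_by_score(ds, np.array([1.0]))
        with pytest.raises(NoEventsError):
            index_by_score(broken, np.array([1.0]))

    def test_near_ties_grouped(self):
        # dot products differing below 12 significant digits collapse to one knot
        z = np.array([0.1, 0.1 * (1 + 1e-14)])
        ds = dataset_with_scores(z, [1, 1])
        assert index_by_score(ds, np.array([1.0])).n_knots == 1


class TestEtaBar:
    def test_single_block_identity(self):
        ds = dataset_with_scores([0.0, 0.0], [1, 0], times=[2.0, 1.0])
        ch = StepCumHazard(jump_times=[2.0], jumps=[1.0], tau=2.0)
        idx = index_by_score(ds, np.array([1.0]))
        # block 1 holds both subjects: (Lambda(2) + Lambda(1)) / 1 event
        assert eta_bar(idx, ch, ds) == pytest.approx([1.0 + 0.0])

    def test_derived_two_block_example(self):
        ds = dataset_with_scores([0.5, 0.2, 0.2, 0.9], [1, 0, 1, 0])
        idx = index_by_score(ds, np.array([1.0]))
        lam = {1.0: 4.0, 2.0: 1.0, 3.0: 3.0, 4.0: 7.0}

        class FakeCumHaz:
            def __call__(self, t):
                return np.array([lam[v] for v in np.atleast_1d(t)])

        eta = eta_bar(idx, FakeCumHaz(), ds)
        # block 1: obs2 (Lambda=1, censored) + obs3 (Lambda=3) over 1 event
        assert eta == pytest.approx([4.0, 4.0])

    def test_zero_hazard_gives_zero(self):
        ds = dataset_with_scores([0.1, 0.4], [1, 1])

        class Zero:
            def __call__(self, t):
                return np.zeros(np.atleast_1d(t).shape)

        idx = index_by_score(ds, np.array([1.0]))
        assert eta_bar(idx, Zero(), ds) == pytest.approx([0.0, 0.0])


class TestM1M2:
    def test_m1_isotonic_example(self):
        # blocks with eta=[3,1,2], md=[2,1,1] -> pooled at 2.25
        ds = dataset_with_scores(
            [0.1, 0.1, 0.2, 0.3], [1, 1, 1, 1], times=[3.0, 3.0, 1.0, 2.0]
        )
        ch = StepCumHazard(jump_times=[1.0, 2.0, 3.0], jumps=[1.0, 1.0, 1.0], tau=3.0)
        idx = index_by_score(ds, np.array([1.0]))
        assert idx.md == pytest.approx([2, 1, 1])
        link = m1_update(idx, ch, ds)
        assert eta_bar(idx, ch, ds) == pytest.approx([3.0, 1.0, 2.0])
        assert link.values == pytest.approx([2.25, 2.25, 2.25])

    def test_m2_single_subject_normalizes(self):
        ds = make_dataset([1.0, 2.0], [1, 0], [[0.0], [0.0]], tau=1.0)
        ch = m2_update(ds, np.array([5.0, 5.0]))
        assert ch.jump_times == pytest.approx([1.0])
        assert ch(1.0) == pytest.approx(1.0)

    def test_m2_riskset_sums(self):
        ds = make_dataset([1.0, 2.0, 3.0], [1, 1, 0], np.zeros((3, 1)), tau=3.0)
        ch = m2_update(ds, np.ones(3))
        # Lambda* = 1/3 then 1/3 + 1/2 = 5/6; normalized jumps 0.4, 0.6
        assert ch.jumps == pytest.approx([0.4, 0.6])

    def test_m2_unequal_r(self):
        ds = make_dataset([1.0, 2.0], [1, 1], np.zeros((2, 1)), tau=2.0)
        ch = m2_update(ds, np.array([1.0, 2.0]))
        assert ch.jumps == pytest.approx([0.25, 0.75])
        assert ch(2.0) == pytest.approx(1.0)

    def test_m2_scale_invariance(self):
        rng = np.random.default_rng(0)
        ds = scenario2_dataset(50, seed=9)
        r = rng.uniform(0.5, 3, 50)
        a = m2_update(ds, r)
        b = m2_update(ds, 7.3 * r)
        assert a.jumps == pytest.approx(b.jumps, rel=1e-12)

    def test_m2_matches_nelson_aalen_with_unit_r(self):
        lifelines = pytest.importorskip("lifelines")
        ds = scenario2_dataset(80, seed=4)
        ch = m2_update(ds, np.ones(ds.n))
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(ds.times, event_observed=ds.events)
        na = naf.cumulative_hazard_.values.ravel()
        na_t = naf.cumulative_hazard_.index.values
        keep = na > 0
        # both are the same estimator up to the Lambda(tau)=1 rescaling
        ours = ch(na_t)[keep]
        ratio = na[keep] / ours
        assert ratio == pytest.approx(np.full(ratio.shape, ratio[0]), rel=1e-9)

    def test_m2_requires_positive_r(self):
        ds = make_dataset([1.0, 2.0], [1, 1], np.zeros((2, 1)))
        with pytest.raises(ValueError):
            m2_update(ds, np.array([1.0, 0.0]))


class TestFixedPoint:
    def two_point(self):
        return make_dataset([1.0, 2.0], [1, 1], [[0.3], [0.3]], tau=2.0)

    def test_hand_derived_fixed_point(self):
        res = fit_inner(self.two_point(), np.array([1.0]))
        assert res.converged
        assert res.link.values == pytest.approx([2.0 / 3.0])
        assert res.cumhaz.jumps == pytest.approx([1.0 / 3.0, 2.0 / 3.0])

    def test_profile_loglik_at_fixed_point(self):
        ll = profile_loglik(self.two_point(), np.array([1.0]))
        assert ll == pytest.approx(-np.log(2.0) - 2.0, abs=1e-9)

    def test_idempotent_at_fixed_point(self):
        res = fit_inner(self.two_point(), np.array([1.0]), r0=np.array([2.0 / 3.0]))
        assert res.converged and res.iterations == 1

    def test_infinite_tol_one_cycle(self):
        res = fit_inner(self.two_point(), np.array([1.0]), tol=np.inf)
        assert res.converged and res.iterations == 1

    def test_ascent_of_full_loglik_after_each_m1(self):
        for seed in (0, 1, 2, 3):
            ds = scenario2_dataset(120, seed=seed)
            beta = np.array([np.cos(0.7), np.sin(0.7)])
            res = fit_inner(ds, beta, return_history=True)
            hist = np.asarray(res.history)
            assert np.all(np.diff(hist) >= -1e-9), f"seed {seed}: {np.diff(hist).min()}"

    def test_lambda_tau_one_and_monotone_link_every_iterate(self):
        ds = scenario2_dataset(100, seed=6)
        res = fit_inner(ds, np.array([-0.6, 0.8]))
        assert res.cumhaz(ds.tau) == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.link.values) >= 0)

    def test_fast_path_matches_reference(self):
        for seed in (0, 5):
            ds = scenario2_dataset(90, seed=seed)
            beta = np.array([-0.8, 0.6])
            ref = fit_inner(ds, beta)
            ws = _make_workspace(ds)
            _, (r, jumps, iters, conv, ll) = _profile_fast(ws, ds, beta, 1e-8, 1000)
            assert r == pytest.approx(ref.link.values, rel=1e-6)
            assert jumps == pytest.approx(ref.cumhaz.jumps, rel=1e-6)
            idx = index_by_score(ds, beta)
            r_sub = ref.link.values[np.minimum(idx.block_of - 1, idx.n_knots - 1)]
            assert ll == pytest.approx(full_loglik(ds, r_sub, ref.cumhaz), abs=1e-6)

    def test_accelerator_reaches_same_fixed_point(self):
        ds = scenario2_dataset(80, seed=8)
        beta = np.array([-0.7, 0.7])
        plain = fit_inner(ds, beta)
        accel = fit_inner(ds, beta, accelerator=squarem_accelerator)
        assert accel.converged
        assert accel.link.values == pytest.approx(plain.link.values, abs=1e-6)
        assert accel.cumhaz.jumps == pytest.approx(plain.cumhaz.jumps, abs=1e-6)


class TestProfileLoglik:
    def test_depends_only_on_ordering(self):
        ds = scenario2_dataset(40, seed=2)
        b1 = np.array([np.cos(2.2), np.sin(2.2)])
        b2 = np.array([np.cos(2.2 + 1e-6), np.sin(2.2 + 1e-6)])
        z1 = ds.covariates @ b1
        z2 = ds.covariates @ b2
        assert np.array_equal(np.argsort(z1), np.argsort(z2))
        assert profile_loglik(ds, b1) == pytest.approx(profile_loglik(ds, b2), abs=1e-12)

    def test_single_event_dataset(self):
        ds = make_dataset([1.0, 2.0, 3.0], [1, 0, 0], [[0.5], [0.1], [0.9]], tau=3.0)
        res = fit_inner(ds, np.array([1.0]))
        assert res.cumhaz.jumps == pytest.approx([1.0])  # single normalized jump
        ll = profile_loglik(ds, np.array([1.0]))
        r = res.link.values
        idx = index_by_score(ds, np.array([1.0]))
        r_sub = r[np.minimum(idx.block_of - 1, idx.n_knots - 1)]
        lam = res.cumhaz(ds.times)
        expected = -np.log(r_sub[0]) - np.sum(lam / r_sub)
        assert ll == pytest.approx(expected, abs=1e-9)
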