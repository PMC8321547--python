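import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bovadapt import flk as F
from bovadapt.synthetic import SimTreeSpec, simulate_sites
from tests.conftest import make_table


class TestReynolds:
    def test_identical_populations(self):
        t = make_table({"x": [0.2, 0.8], "y": [0.2, 0.8]}, two_n=10)
        assert F.reynolds_distance(t, "x", "y") == 0.0

    def test_fixed_difference(self):
        t = make_table({"x": [0.0], "y": [1.0]}, two_n=10)
        assert F.reynolds_distance(t, "x", "y") == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        t = make_table({"x": [0.2, 0.8], "y": [0.4, 0.6]}, two_n=10)
        assert F.reynolds_distance(t, "x", "y") == pytest.approx(0.08 / 0.88)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        t = make_table({"x": [0.0, 0.5], "y": [1.0, 0.5]}, two_n=10)
        # per-site ratios would average (1 + 0)/2; ratio of sums differs
        num = 1.0
        den = 1.0 + (1 - 0.25 - 0.25)
        assert F.reynolds_distance(t, "x", "y") == pytest.approx(num / den)


class TestKinship:
    def test_two_population_closed_form(self):
        D = pd.DataFrame([[0, 0.3], [0.3, 0]], index=["a", "b"],
                         columns=["a", "b"])
        _, K = F.build_kinship(D)
        t = -np.log1p(-0.15)
        assert np.allclose(K, np.diag([t, t]))

    def test_star_distances_give_zero_shared_drift(self):
        D = pd.DataFrame(0.2 * (1 - np.eye(3)), index=list("abc"),
                         columns=list("abc"))
        _, K = F.build_kinship(D)
        off = np.asarray(K)[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)

    def test_zero_distances_give_zero_kinship(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("abc"),
                         columns=list("abc"))
        _, K = F.build_kinship(D)
        assert np.allclose(K, 0.0)

    def test_asymmetric_input_rejected(self):
        D = pd.DataFrame([[0, 0.1], [0.2, 0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError):
            F.build_kinship(D)

    def test_nested_tree_shares_drift(self):
        # a,b close; c distant -> F_ab > 0
        D = pd.DataFrame([[0, 0.05, 0.4], [0.05, 0, 0.4], [0.4, 0.4, 0]],
                         index=list("abc"), columns=list("abc"))
        _, K = F.build_kinship(D)
        assert K.loc["a", "b"] > 0.1
        assert K.loc["a", "c"] == pytest.approx(0.0, abs=1e-9)


class TestFlkStatistic:
    def test_equal_frequencies_give_zero(self):
        t = make_table({"a": [0.4], "b": [0.4], "c": [0.4]}, two_n=10)
        K = pd.DataFrame(np.diag([0.1, 0.1, 0.1]), index=list("abc"),
                         columns=list("abc"))
        assert F.flk(t, K).T[0] == pytest.approx(0.0)

    def test_diagonal_closed_form(self):
        t = make_table({"a": [0.9], "b": [0.1]}, two_n=10)
        K = pd.DataFrame(np.diag([0.1, 0.1]), index=["a", "b"],
                         columns=["a", "b"])
        r = F.flk(t, K)
        assert r.p0[0] == pytest.approx(0.5)
        assert r.T[0] == pytest.approx(12.8)

    def test_monomorphic_sites_excluded(self):
        t = make_table({"a": [0.0], "b": [0.0]}, two_n=10)
        K = pd.DataFrame(np.diag([0.1, 0.1]), index=["a", "b"],
                         columns=["a", "b"])
        r = F.flk(t, K)
        assert r.excluded[0]
        assert np.isnan(r.T[0])

    def test_chi2_null_mean(self):
        spec = SimTreeSpec.star([f"p{i}" for i in range(6)], F=0.01, n=5000,
                                seed=12)
        t = simulate_sites(spec, 20_000, genotypes=False)
        pops, K = spec.expected_kinship()
        r = F.flk(t, pd.DataFrame(K, index=pops, columns=pops))
        T = r.T[np.isfinite(r.T)]
        assert abs(T.mean() - r.dof) / r.dof < 0.05
        assert abs(T.var() - 2 * r.dof) / (2 * r.dof) < 0.1


class TestCalibrate:
    def test_normal_input_gives_uniform_p(self):
        rejections = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(5, 3, 10_000)
            scan = F.calibrate(x)
            if stats.kstest(scan.p, "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections == 0

    def test_outliers_flagged_and_location_robust(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 1, 10_000)
        idx = rng.choice(10_000, 100, replace=False)
        x[idx] += 8
        scan = F.calibrate(x)
        assert abs(scan.location - 10) / 10 < 0.02
        assert (scan.q[idx] < 0.01).mean() >= 0.95

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            F.calibrate(np.ones(500))

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError):
            F.calibrate(np.random.default_rng(0).normal(size=50))

    def test_chisq_transform_calibrates_flk_null(self):
        x = np.random.default_rng(1).chisquare(5, 20_000)
        scan = F.calibrate(x, transform="chisq", dof=5)
        # WH-transformed chi2 is near-normal: p roughly uniform
        assert stats.kstest(scan.p, "uniform").statistic < 0.02


class TestStoreyQvalues:
    def test_null_q_large(self):
        p = np.random.default_rng(0).uniform(size=5000)
        q = F.storey_qvalues(p)
        assert q.min() > 0.05

    def test_monotone_in_p(self):
        p = np.random.default_rng(1).uniform(size=1000)
        q = F.storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_signal_detected(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.uniform(size=5000), np.full(50, 1e-12)])
        q = F.storey_qvalues(p)
        assert (q[-50:] < 0.01).all()


def brute_force_intervals(pos, q, seed_q=0.01, boundary_q=0.1):
    """Reference interval caller: test every marker as a seed, expand."""
    chosen = set()
    for i, qi in enumerate(q):
        if not (qi < seed_q):
            continue
        lo = i
        while lo - 1 >= 0 and q[lo - 1] <= boundary_q:
            lo -= 1
        hi = i
        while hi + 1 < len(q) and q[hi + 1] <= boundary_q:
            hi += 1
        chosen.add((pos[lo], pos[hi]))
    return sorted(chosen)


class TestCallIntervals:
    def make_scan(self, q, pos=None):
        n = len(q)
        pos = pos or list(range(10, 10 * n + 1, 10))
        return F.CalibratedScan(
            sites=pd.DataFrame({"chrom": ["1"] * n, "pos": pos}),
            stat=np.zeros(n), z=np.zeros(n), p=np.zeros(n),
            q=np.asarray(q, dtype=float), location=0.0, scale=1.0)

    def test_worked_example(self):
        ivs = F.call_intervals(self.make_scan([0.5, 0.05, 0.005, 0.02, 0.5]))
        assert len(ivs) == 1
        assert (ivs[0].start, ivs[0].end, ivs[0].n_markers) == (20, 40, 3)

    def test_no_seed_no_intervals(self):
        assert F.call_intervals(self.make_scan([0.5, 0.05, 0.5])) == []

    def test_two_seeds_merge_without_separating_boundary(self):
        ivs = F.call_intervals(self.make_scan([0.5, 0.005, 0.05, 0.004, 0.5]))
        assert len(ivs) == 1
        assert ivs[0].n_markers == 3

    def test_unsorted_markers_rejected(self):
        scan = self.make_scan([0.5, 0.005, 0.5], pos=[30, 20, 10])
        with pytest.raises(ValueError):
            F.call_intervals(scan)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, q):
        scan = self.make_scan(q)
        got = [(iv.start, iv.end) for iv in F.call_intervals(scan)]
        pos = scan.sites["pos"].tolist()
        assert got == brute_force_intervals(pos, q)
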