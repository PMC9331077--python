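"""Binomial distance, NMDS, Mantel test, NSC, and the Gaussian discriminant."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import duplexmut as dm
from duplexmut.channels import CHANNELS_96
from duplexmut.classify import DistanceMatrix, nsc_train, pairwise_binomial


class TestBinomialDistance:
    def test_identity_is_zero(self):
        assert dm.binomial_distance([3, 1, 4], [3, 1, 4]) == 0.0

    def test_disjoint_two_channels(self):
        assert dm.binomial_distance([2, 0], [0, 2]) == pytest.approx(2 * math.log(2))

    def test_loop_oracle_and_symmetry(self):
        """Vectorized distance equals a naive per-channel loop to 1e-12."""

        def naive(x, y):
            total = 0.0
            for xi, yi in zip(x, y):
                ni = xi + yi
                if ni == 0:
                    continue
                mi = ni / 2
                t = 0.0
                if xi > 0:
                    t += xi * math.log(xi / mi)
                if yi > 0:
                    t += yi * math.log(yi / mi)
                total += t / ni
            return total

        rng = np.random.default_rng(3)
        for _ in range(100):
            x = rng.integers(0, 50, size=24)
            y = rng.integers(0, 50, size=24)
            d = dm.binomial_distance(x, y)
            assert d == pytest.approx(naive(x, y), abs=1e-12)
            assert d == pytest.approx(dm.binomial_distance(y, x), abs=1e-12)
            assert d >= -1e-12

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            dm.binomial_distance([1, -1], [0, 1])


class TestNmds:
    def _euclidean_matrix(self, n=10, k=2, seed=0):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, k))
        return DistanceMatrix([f"s{i}" for i in range(n)], squareform(pdist(X)))

    def test_perfect_fit_has_zero_stress(self):
        res = dm.nmds(self._euclidean_matrix(), k=2, n_restarts=3, seed=1)
        assert res.stress < 1e-4
        assert res.converged

    def test_stress_zero_when_fitted_equals_observed(self):
        """The stress formula vanishes when f(x) = d exactly."""
        from duplexmut.classify import _stress

        d = np.array([1.0, 2.0, 3.0])
        assert _stress(d, d.copy()) == 0.0

    def test_result_no_worse_than_metric_start(self):
        """Returned stress never exceeds that of the classical-scaling start."""
        from duplexmut.classify import _config_distances, _pcoa_init, _stress
        from sklearn.isotonic import IsotonicRegression

        dist = self._euclidean_matrix(n=12, k=4, seed=5)  # 4-d data forced into 2-d
        res = dm.nmds(dist, k=2, n_restarts=4, seed=2)
        X0 = _pcoa_init(dist, 2)
        delta = dist.upper()
        order = np.argsort(delta, kind="stable")
        d0 = _config_distances(X0)
        iso = IsotonicRegression(increasing=True)
        disp = np.empty_like(d0)
        disp[order] = iso.fit_transform(delta[order], d0[order])
        assert res.stress <= _stress(d0, disp) + 1e-12

    def test_deterministic_given_seed(self):
        dist = self._euclidean_matrix(n=9, k=3, seed=8)
        a = dm.nmds(dist, k=2, n_restarts=5, seed=3)
        b = dm.nmds(dist, k=2, n_restarts=5, seed=3)
        assert a.stress == b.stress
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            dm.nmds(DistanceMatrix(["a", "b"], np.zeros((2, 2))), k=2)

    def test_control_separates_from_high_dose(self, default_cohort, per_sample_percent):
        """Control and high-dose samples occupy distinct regions of the
        2-d embedding (between-group distances exceed within-group)."""
        P = per_sample_percent(default_cohort)
        dose_of = {m.sample_id: m.dose for m in default_cohort.metadata}
        keep = [s for s in P.index if dose_of[s] in (0.0, 50.0)]
        counts = P.loc[keep]
        res = dm.nmds(pairwise_binomial(counts), k=2, n_restarts=5, seed=4)
        lab = np.array([dose_of[s] for s in res.labels])
        from scipy.spatial.distance import cdist

        within = np.mean(
            [cdist(res.coords[lab == g], res.coords[lab == g]).mean() for g in (0.0, 50.0)]
        )
        between = cdist(res.coords[lab == 0.0], res.coords[lab == 50.0]).mean()
        assert between > within


class TestMantel:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix([f"s{i}" for i in range(8)], squareform(pdist(X)))
        r, p = dm.mantel_test(d, d, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_type_one_error_calibrated(self):
        """Under independent matrices the test rejects at ~alpha."""
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            d1 = squareform(pdist(rng.normal(size=(8, 3))))
            d2 = squareform(pdist(rng.normal(size=(8, 3))))
            labels = [f"s{j}" for j in range(8)]
            _, p = dm.mantel_test(
                DistanceMatrix(labels, d1), DistanceMatrix(labels, d2),
                n_perm=99, seed=i,
            )
            rejections += p <= 0.05
        assert rejections / n_rep <= 0.08  # 0.05 plus Monte Carlo slack

    def test_genic_intergenic_spectra_correlate(self, default_cohort, unique_mutations):
        """Genic and intergenic per-sample spectra from the same exposure
        process give a significantly positive Mantel correlation."""
        region = {t.name: t.region_class for t in default_cohort.panel}
        tables = {"genic": {}, "intergenic": {}}
        for m in unique_mutations:
            ch = m.channel()
            if ch is None:
                continue
            t = tables[region[m.target]].setdefault(m.sample_id, {})
            t[ch] = t.get(ch, 0) + 1
        ids = sorted(set(tables["genic"]) & set(tables["intergenic"]))
        mats = {
            k: pd.DataFrame(v).T.reindex(index=ids, columns=list(CHANNELS_96)).fillna(0)
            for k, v in tables.items()
        }
        r, p = dm.mantel_test(
            pairwise_binomial(mats["genic"]), pairwise_binomial(mats["intergenic"]),
            n_perm=999, seed=0,
        )
        assert r > 0.3
        assert p < 0.01

    def test_constant_matrix_rejected(self):
        labels = ["a", "b", "c"]
        d = DistanceMatrix(labels, np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError, match="constant"):
            dm.mantel_test(d, d, n_perm=99)


def _labelled_data(seed=0, n=6, p=20, shift=2.0, n_shifted=3):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(5.0, 1.0, size=(n, p))
    X1 = rng.normal(5.0, 1.0, size=(n, p))
    X1[:, :n_shifted] += shift
    X = pd.DataFrame(
        np.vstack([X0, X1]), columns=[f"ch{i}" for i in range(p)],
        index=[f"s{i}" for i in range(2 * n)],
    )
    y = ["control"] * n + ["exposed"] * n
    return X, y


class TestNsc:
    def test_delta_zero_equals_nearest_centroid(self):
        """At delta 0 predictions match the classical nearest-centroid rule
        computed independently in (s_i + s0)-standardized space."""
        X, y = _labelled_data(seed=1)
        model = nsc_train(X, y, delta_grid=np.array([0.0]), cv_folds=3, seed=0)
        rng = np.random.default_rng(2)
        Q = rng.normal(5.0, 2.0, size=(40, X.shape[1]))
        got = model.predict(Q)
        # independent oracle
        Xa = X.to_numpy()
        ya = np.asarray(y)
        classes = sorted(set(y))
        cents = np.vstack([Xa[ya == c].mean(axis=0) for c in classes])
        within = sum(((Xa[ya == c] - cents[k]) ** 2).sum(axis=0) for k, c in enumerate(classes))
        s = np.sqrt(within / (len(y) - 2))
        s_tot = s + np.median(s)
        expected = [
            classes[int(np.argmin([np.sum(((q - cents[k]) / s_tot) ** 2) for k in range(2)]))]
            for q in Q
        ]
        assert got.tolist() == expected

    def test_total_shrinkage_falls_back_to_priors(self):
        X, y = _labelled_data(seed=3)
        model = nsc_train(X, y, delta_grid=np.array([1e6]), cv_folds=3, seed=0)
        assert model.active_channels == []
        proba = model.predict_proba(X.to_numpy())
        np.testing.assert_allclose(proba, 0.5, atol=1e-12)

    def test_shrunken_differences_bounded(self):
        X, y = _labelled_data(seed=4)
        delta = 0.7
        model = nsc_train(X, y, delta_grid=np.array([delta]), cv_folds=3, seed=0)
        base = nsc_train(X, y, delta_grid=np.array([0.0]), cv_folds=3, seed=0)
        assert np.all(np.abs(model.shrunken_d) <= np.abs(base.shrunken_d) + 1e-12)

    def test_cv_selects_discriminative_channels(self):
        """With a strong shift on 3 channels, the CV-selected model keeps a
        nonempty subset of exactly those channels."""
        hits = 0
        for seed in range(10):
            X, y = _labelled_data(seed=seed, shift=4.0)
            model = nsc_train(X, y, cv_folds=6, seed=seed)
            active = set(model.active_channels)
            if active and active <= {"ch0", "ch1", "ch2"}:
                hits += 1
        assert hits >= 9

    def test_exposure_excess_channels_survive_on_cohorts(self, per_sample_percent):
        """Cohorts whose exposure spectrum exceeds background on exactly
        three channels yield NSC models active only on those channels."""
        base = dm.default_bap_config()
        lead = ["C[C>A]A", "C[C>A]C", "G[C>A]C"]
        excess = 0.15
        exposure = base.control_spectrum * (1 - 3 * excess)
        for ch in lead:
            exposure[CHANNELS_96.index(ch)] += excess
        hits = 0
        n_rep = 8
        for seed in range(n_rep):
            cfg = dataclasses.replace(
                dm.default_bap_config(seed=100 + seed), exposure_spectrum=exposure
            )
            cohort = dm.generate_cohort(cfg)
            P = per_sample_percent(cohort)
            dose_of = {m.sample_id: m.dose for m in cohort.metadata}
            keep = [s for s in P.index if dose_of[s] in (0.0, 50.0)]
            labels = ["exposed" if dose_of[s] == 50.0 else "control" for s in keep]
            model = nsc_train(P.loc[keep], labels, seed=seed)
            active = set(model.active_channels)
            if active and active <= set(lead):
                hits += 1
        assert hits >= n_rep - 1


class TestDiscriminant:
    def test_printed_centroids(self):
        params = dm.bap_reference_discriminant()
        p_exposed = dm.prob_exposed([4.23, 10.3, 4.00], params)
        p_control = dm.prob_exposed([1.38, 1.64, 0.80], params)
        assert p_exposed == pytest.approx(0.9921, abs=2e-4)
        assert p_control == pytest.approx(0.0079, abs=2e-4)
        # mirror symmetry of the two centroids
        assert p_exposed + p_control == pytest.approx(1.0, abs=1e-12)

    def test_complement_identity(self):
        params = dm.bap_reference_discriminant()
        rng = np.random.default_rng(0)
        for _ in range(25):
            x = rng.uniform(0, 15, size=3)
            assert dm.prob_exposed(x, params) + dm.prob_control(x, params) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_equidistant_point_is_even_odds(self):
        params = dm.bap_reference_discriminant()
        mid = (params.exposed_mean + params.control_mean) / 2
        assert dm.prob_exposed(mid, params) == pytest.approx(0.5, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            dm.prob_exposed([1.0, 2.0], dm.bap_reference_discriminant())
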