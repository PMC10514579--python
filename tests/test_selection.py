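"""SPA, CARS and union band selection against independent oracles."""

import numpy as np
import pytest

from seedspec import (
    CarsConfig,
    SelectionResult,
    SpectraTable,
    cars_select,
    edf_ratio,
    spa_projection_chain,
    spa_select,
    union_bands,
)


def brute_force_chain(X, start, k_max):
    """Reference SPA: explicit Gram-Schmidt residual norms each step."""
    X = np.asarray(X, dtype=float)
    chain = [start]
    for _ in range(1, k_max):
        basis = np.linalg.qr(X[:, chain], mode="reduced")[0]
        resid = X - basis @ (basis.T @ X)
        norms = np.linalg.norm(resid, axis=0)
        norms[chain] = -1
        chain.append(int(np.argmax(norms)))
    return chain


def _label_table(values, labels, wl=None):
    values = np.asarray(values, dtype=float)
    wl = wl if wl is not None else np.linspace(1000, 1000 + 5 * (values.shape[1] - 1), values.shape[1])
    return SpectraTable(values=values, wavelengths=wl, labels=np.asarray(labels, dtype=int))


class TestSpaChain:
    def test_hand_worked_projection(self):
        # residual norm of c2 after projecting out c1 is 1.0 > 0.707 for c3
        X = np.array([[1.0, 0.0, 0.707], [0.0, 1.0, 0.707]])
        assert spa_projection_chain(X, start=0, k_max=2) == [0, 1]

    def test_orthogonal_start_picks_largest_norm(self):
        X = np.array([[2.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 3.0]])
        assert spa_projection_chain(X, start=0, k_max=2) == [0, 2]

    def test_residual_norms_contract(self, rng):
        X = rng.normal(size=(15, 10))
        X -= X.mean(axis=0)
        chain = spa_projection_chain(X, 0, 6)
        resid = X.copy()
        for k in range(1, len(chain)):
            basis = np.linalg.qr(X[:, chain[:k]], mode="reduced")[0]
            resid = X - basis @ (basis.T @ X)
            picked = chain[k]
            assert np.linalg.norm(resid[:, picked]) <= np.linalg.norm(X[:, picked]) + 1e-9

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            X = rng.normal(size=(20, 12))
            X -= X.mean(axis=0)
            start = int(rng.integers(12))
            assert spa_projection_chain(X, start, 6) == brute_force_chain(X, start, 6)

    def test_residual_vectors_mutually_orthogonal(self, rng):
        X = rng.normal(size=(20, 12))
        X -= X.mean(axis=0)
        chain = spa_projection_chain(X, 3, 8)
        Q = np.linalg.qr(X[:, chain], mode="reduced")[0]
        gram = Q.T @ Q
        np.testing.assert_allclose(gram, np.eye(len(chain)), atol=1e-8)

    def test_never_selects_duplicated_column(self, rng):
        base = rng.normal(size=(10, 5))
        X = np.column_stack([base, base[:, 0]])  # column 5 duplicates column 0
        X -= X.mean(axis=0)
        chain = spa_projection_chain(X, 0, 2)
        assert 5 not in chain

    def test_infeasible_k_max_raises(self, rng):
        X = rng.normal(size=(4, 10))
        with pytest.raises(ValueError, match="k_max"):
            spa_projection_chain(X, 0, 5)


class TestSpaSelect:
    def test_recovers_planted_informative_bands(self, rng):
        # spectra-like design: a shared (collinear) baseline variation plus
        # two bands whose independent offsets encode the class
        n, b, (i, j) = 120, 30, (7, 21)
        baseline = rng.normal(size=(n, 1)) * np.ones((1, b))
        X = baseline + 0.01 * rng.normal(size=(n, b))
        y = rng.integers(0, 2, n)
        X[:, i] += 1.0 * y
        X[:, j] += 1.0 * (1 - y)
        tr = _label_table(X[:80], y[:80])
        va = _label_table(X[80:], y[80:])
        res = spa_select(tr, va, k_max=6)
        assert {i, j} <= set(res.selected_indices)
        # RMSE collapses once the informative bands enter the subset
        curve = dict(res.criterion_curve)
        assert curve[max(2, res.n_selected)] < 0.9 * curve[1]

    def test_k_max_one_equals_exhaustive_search(self, rng):
        n, b = 60, 12
        X = rng.normal(size=(n, b))
        y = rng.integers(0, 2, n)
        tr = _label_table(X[:40], y[:40])
        va = _label_table(X[40:], y[40:])
        res = spa_select(tr, va, k_max=1)
        # brute-force oracle: validation RMSE of every single band
        def rmse_of(band):
            A = np.column_stack([np.ones(40), X[:40, band]])
            Y = np.eye(2)[y[:40]]
            coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
            Av = np.column_stack([np.ones(20), X[40:, band]])
            return np.sqrt(np.mean((Av @ coef - np.eye(2)[y[40:]]) ** 2))

        best = min(range(b), key=rmse_of)
        assert list(res.selected_indices) == [best]

    def test_k_max_not_below_train_size(self, rng):
        X = rng.normal(size=(10, 8))
        t = _label_table(X, rng.integers(0, 2, 10))
        with pytest.raises(ValueError, match="k_max"):
            spa_select(t, t, k_max=10)


class TestEdf:
    def test_endpoints_exact(self):
        for N, p in ((50, 224), (10, 100), (5, 7)):
            assert edf_ratio(1, N, p) == pytest.approx(1.0, abs=1e-12)
            assert edf_ratio(N, N, p) == pytest.approx(2.0 / p, abs=1e-12)

    def test_closed_form_midpoint(self):
        assert edf_ratio(25, 50, 224) == pytest.approx(112 ** (-24 / 49), rel=1e-12)
        assert edf_ratio(25, 50, 224) == pytest.approx(0.0991, abs=5e-4)

    def test_monotone_decreasing(self):
        vals = [edf_ratio(i, 50, 224) for i in range(1, 51)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


@pytest.fixture(scope="module")
def cars_table():
    """140 samples, 60 bands; only bands 10 and 50 carry class signal."""
    rng = np.random.default_rng(42)
    n, b = 140, 60
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 1.0, size=(n, b))
    X[:, 10] += 2.0 * y
    X[:, 50] -= 2.0 * y
    return _label_table(X, y)


class TestCars:
    def test_winner_contains_signal_bands(self, cars_table):
        hits = 0
        for seed in range(5):
            res = cars_select(cars_table, CarsConfig(n_runs=30, seed=seed))
            if {10, 50} <= set(res.selected_indices):
                hits += 1
        assert hits >= 4

    def test_retained_counts_non_increasing(self, cars_table):
        res = cars_select(cars_table, CarsConfig(n_runs=25, seed=1))
        counts = [len(s) for s in res.subsets_per_step]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_fixed_seed_deterministic(self, cars_table):
        a = cars_select(cars_table, CarsConfig(n_runs=15, seed=3))
        b = cars_select(cars_table, CarsConfig(n_runs=15, seed=3))
        assert a.to_dict() == b.to_dict()

    def test_winner_not_worse_than_full_band_model(self, cars_table):
        res = cars_select(cars_table, CarsConfig(n_runs=25, seed=2))
        # run 1 retains every band, so its RMSECV is the full-band reference
        full_rmsecv = res.criterion_curve[0][1]
        win_rmsecv = res.criterion_curve[res.chosen_step][1]
        assert win_rmsecv <= full_rmsecv + 1e-12

    def test_selected_indices_match_chosen_subset(self, cars_table):
        res = cars_select(cars_table, CarsConfig(n_runs=15, seed=4))
        assert sorted(res.subsets_per_step[res.chosen_step]) == list(res.selected_indices)


class TestUnion:
    def _sel(self, idx, wl):
        return SelectionResult(method="spa", selected_indices=np.array(idx), grid_wavelengths=wl)

    def test_basic_union(self):
        wl = np.linspace(1000, 1100, 25)
        u = union_bands(self._sel([1, 5, 9], wl), self._sel([5, 20], wl))
        assert list(u.selected_indices) == [1, 5, 9, 20]

    def test_disjoint_sizes_add(self):
        wl = np.linspace(1000, 1100, 60)
        a = self._sel(list(range(5)), wl)
        b = self._sel(list(range(5, 57)), wl)
        assert union_bands(a, b).n_selected == 57

    def test_idempotent(self):
        wl = np.linspace(1000, 1100, 10)
        a = self._sel([2, 4], wl)
        assert list(union_bands(a, a).selected_indices) == [2, 4]

    def test_grid_mismatch_raises(self):
        a = self._sel([1], np.linspace(1000, 1100, 10))
        b = self._sel([1], np.linspace(1000, 1200, 10))
        with pytest.raises(ValueError, match="grid"):
            union_bands(a, b)

    def test_json_round_trip(self, tmp_path, cars_table):
        res = cars_select(cars_table, CarsConfig(n_runs=10, seed=5))
        res.to_json(tmp_path / "sel.json")
        back = SelectionResult.from_json(tmp_path / "sel.json")
        assert back.to_dict() == res.to_dict()
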