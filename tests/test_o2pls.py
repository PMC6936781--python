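import numpy as np
import pandas as pd
import pytest

from fermcore import cross_validate, fit_o2pls, generate_dataset, predict_y, vip_pred
from fermcore.o2pls import predict_x


def principal_angles(a, b):
    """Angles between the column spaces of a and b, in radians."""
    qa = np.linalg.qr(a)[0]
    qb = np.linalg.qr(b)[0]
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(s, -1, 1))


class TestExactRecovery:
    def test_zero_noise_model_data_is_fit_exactly(self):
        _, _, truth = generate_dataset(n_samples=40, noise_sd=0.0, seed=3)
        m = fit_o2pls(truth.X_latent, truth.Y_latent, K=truth.K, nx=truth.nx,
                      ny=truth.ny, scaling="center_only")
        assert m.r2y == pytest.approx(1.0, abs=1e-6)
        assert m.r2x == pytest.approx(1.0, abs=1e-6)
        angles = principal_angles(m.W, truth.W_true)
        assert angles.max() < 1e-6

    def test_zero_noise_prediction_reproduces_y_joint_part(self):
        _, _, truth = generate_dataset(n_samples=40, noise_sd=0.0, seed=4)
        m = fit_o2pls(truth.X_latent, truth.Y_latent, K=truth.K, nx=truth.nx,
                      ny=truth.ny, scaling="center_only")
        y_hat = predict_y(m, pd.DataFrame(truth.X_latent)).to_numpy()
        # prediction covers the joint part; the Y-orthogonal part is not
        # predictable from X by construction
        joint = truth.T_true @ truth.C_true.T
        assert np.allclose(y_hat - y_hat.mean(axis=0), joint - joint.mean(axis=0), atol=1e-8)


class TestSvdOracle:
    def test_k1_weights_equal_top_singular_vectors(self, rng):
        x = rng.standard_normal((20, 8))
        y = rng.standard_normal((20, 5))
        m = fit_o2pls(x, y, K=1, nx=0, ny=0, scaling="center_only")
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        u, _, vt = np.linalg.svd(xc.T @ yc)
        w_oracle = u[:, 0] * np.sign(u[np.argmax(np.abs(u[:, 0])), 0])
        c_oracle = vt[0] * np.sign(vt[0, np.argmax(np.abs(vt[0]))])
        assert np.allclose(m.W[:, 0], w_oracle, atol=1e-9)
        assert np.allclose(m.C[:, 0], c_oracle, atol=1e-9)

    def test_taxon_permutation_equivariance(self, rng):
        x = pd.DataFrame(rng.standard_normal((15, 6)),
                         columns=[f"g{i}" for i in range(6)])
        y = pd.DataFrame(rng.standard_normal((15, 4)))
        m1 = fit_o2pls(x, y, K=2, nx=1, ny=0)
        perm = rng.permutation(6)
        m2 = fit_o2pls(x[x.columns[perm]], y, K=2, nx=1, ny=0)
        assert np.allclose(m2.W, m1.W[perm], atol=1e-8)
        assert m2.r2y == pytest.approx(m1.r2y, abs=1e-10)


@pytest.fixture(scope="module")
def fitted():
    a, f, _ = generate_dataset(n_samples=30, seed=9)
    return fit_o2pls(a.data, f.data, K=2, nx=1, ny=1)


class TestModelInvariants:
    def test_joint_weight_columns_orthonormal(self, fitted):
        assert np.allclose(fitted.W.T @ fitted.W, np.eye(2), atol=1e-9)
        assert np.allclose(fitted.C.T @ fitted.C, np.eye(2), atol=1e-9)

    def test_within_block_orthogonality_is_exact(self, fitted):
        n = fitted.T.shape[0]
        assert np.abs(fitted.T_orth.T @ fitted.T).max() / n < 1e-10
        assert np.abs(fitted.U_orth.T @ fitted.U).max() / n < 1e-10

    def test_cross_block_orthogonality(self, fitted):
        # exact only at the component-extraction step; after the final joint
        # re-estimation it holds to O(noise^2) -> assert as a correlation
        def max_corr(a, b):
            r = np.corrcoef(np.hstack([a, b]).T)[: a.shape[1], a.shape[1]:]
            return np.abs(r).max()

        assert max_corr(fitted.T_orth, fitted.U) < 0.05
        assert max_corr(fitted.U_orth, fitted.T) < 0.05
        # and exactly at zero noise
        _, _, tr = generate_dataset(n_samples=30, noise_sd=0.0, seed=21)
        m0 = fit_o2pls(tr.X_latent, tr.Y_latent, K=tr.K, nx=tr.nx, ny=tr.ny,
                       scaling="center_only")
        assert np.abs(m0.T_orth.T @ m0.U).max() < 1e-8

    def test_inner_regression_near_diagonal(self, fitted):
        # diagnostic, not an invariant: SVD-paired components should give a
        # dominant diagonal in B_T
        b = np.abs(fitted.B_T)
        assert b.diagonal().min() > b[~np.eye(2, dtype=bool)].max()

    def test_r2y_nondecreasing_in_k(self):
        a, f, _ = generate_dataset(n_samples=30, seed=10)
        r2 = [
            fit_o2pls(a.data, f.data, K=k, nx=0, ny=0).r2y for k in (1, 2, 3)
        ]
        assert r2[0] <= r2[1] + 1e-10 and r2[1] <= r2[2] + 1e-10

    def test_rank_violation_rejected(self, rng):
        x = rng.standard_normal((6, 10))
        y = rng.standard_normal((6, 10))
        with pytest.raises(ValueError, match="rank"):
            fit_o2pls(x, y, K=4, nx=2, ny=0)

    def test_mismatched_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="sample"):
            fit_o2pls(rng.standard_normal((6, 4)), rng.standard_normal((5, 4)), K=1)


class TestVIP:
    def test_single_active_taxon_concentrates_vip(self):
        # X's single informative column drives Y: w = e_j, VIP_j = sqrt(p)
        rng = np.random.default_rng(5)
        t = rng.standard_normal(30)
        x = np.zeros((30, 4))
        x[:, 2] = t
        x[:, [0, 1, 3]] = rng.standard_normal((30, 3)) * 1e-8
        y = np.outer(t, rng.standard_normal(3))
        m = fit_o2pls(x, y, K=1, nx=0, ny=0, scaling="center_only")
        vip = vip_pred(m)
        assert vip.iloc[2] == pytest.approx(2.0, abs=1e-4)  # sqrt(p=4)
        assert vip.drop(vip.index[2]).max() < 1e-3

    def test_vip_normalisation_identity(self):
        for seed in (0, 1, 2):
            a, f, _ = generate_dataset(n_samples=25, seed=seed)
            m = fit_o2pls(a.data, f.data, K=2, nx=1, ny=1)
            vip = vip_pred(m)
            assert (vip**2).sum() == pytest.approx(len(vip), abs=1e-6)
            assert (vip >= 0).all()

    def test_planted_core_taxa_separate_from_background(self):
        aucs = []
        for seed in range(20):
            a, f, tr = generate_dataset(n_samples=60, seed=300 + seed)
            m = fit_o2pls(a.data, f.data, K=tr.K, nx=tr.nx, ny=tr.ny)
            vip = vip_pred(m)
            core = vip[tr.planted_core]
            rest = vip.drop(tr.planted_core)
            assert (core > 1.0).all()
            # rank-sum AUC of core vs non-core VIP
            auc = (core.to_numpy()[:, None] > rest.to_numpy()[None, :]).mean()
            aucs.append(auc)
        assert np.mean(aucs) > 0.95


class TestPrediction:
    def test_training_prediction_consistent_with_r2y_pred(self):
        a, f, _ = generate_dataset(n_samples=25, seed=6)
        m = fit_o2pls(a.data, f.data, K=2, nx=1, ny=1)
        y_hat = predict_y(m, a.data)
        resid = ((f.data - y_hat) / m.y_scale) ** 2
        y0 = ((f.data - m.y_mean) / m.y_scale) ** 2
        r2 = 1 - resid.to_numpy().sum() / y0.to_numpy().sum()
        assert r2 == pytest.approx(m.r2y_pred, abs=1e-10)

    def test_row_duplication_is_pointwise(self):
        a, f, _ = generate_dataset(n_samples=20, seed=7)
        m = fit_o2pls(a.data, f.data, K=2, nx=1, ny=1)
        single = predict_y(m, a.data.iloc[[3]])
        doubled = predict_y(m, pd.concat([a.data.iloc[[3]], a.data.iloc[[3]]]))
        assert np.allclose(doubled.to_numpy()[0], single.to_numpy()[0])
        assert np.allclose(doubled.to_numpy()[1], single.to_numpy()[0])

    def test_unknown_taxa_rejected(self):
        a, f, _ = generate_dataset(n_samples=20, seed=8)
        m = fit_o2pls(a.data, f.data, K=2, nx=1, ny=1)
        bad = a.data.rename(columns={a.data.columns[0]: "imposter"})
        with pytest.raises(ValueError, match="imposter"):
            predict_y(m, bad)


class TestCrossValidation:
    def test_selects_planted_ranks_as_mode(self):
        from collections import Counter

        picks = []
        for seed in range(20):
            a, f, tr = generate_dataset(n_samples=60, noise_sd=0.1, seed=500 + seed)
            _, best = cross_validate(a.data, f.data, seed=seed)
            picks.append(best)
        mode, _ = Counter(picks).most_common(1)[0]
        assert mode == (2, 1, 1)

    def test_null_data_has_low_q2(self):
        low = 0
        runs = 40
        for s in range(runs):
            rng = np.random.default_rng(2000 + s)
            x = rng.standard_normal((20, 15))
            y = rng.standard_normal((20, 10))
            table, _ = cross_validate(
                x, y, K_range=(1, 2), nx_range=(0, 1), ny_range=(0, 1), seed=s
            )
            low += table["Q2"].max() <= 0.1
        assert low >= runs * 0.9

    def test_q2_does_not_exceed_r2y_on_structured_data(self):
        a, f, _ = generate_dataset(n_samples=40, seed=12)
        table, (k, nx, ny) = cross_validate(a.data, f.data, seed=0)
        m = fit_o2pls(a.data, f.data, K=k, nx=nx, ny=ny)
        q2y = table.query("K == @k and nx == @nx and ny == @ny")["Q2_Y"].iloc[0]
        assert q2y <= m.r2y_pred + 0.05

    def test_infeasible_cells_are_nan_not_errors(self, rng):
        x = rng.standard_normal((8, 5))
        y = rng.standard_normal((8, 4))
        table, _ = cross_validate(x, y, K_range=(1, 5), nx_range=(0,), ny_range=(0,), seed=0)
        assert table["Q2"].isna().any()
        assert table["Q2"].notna().any()

    def test_predict_x_inverts_the_roles(self):
        a, f, tr = generate_dataset(n_samples=40, noise_sd=0.1, seed=13)
        m = fit_o2pls(a.data, f.data, K=2, nx=1, ny=1)
        x_hat = predict_x(m, f.data)
        core = tr.planted_core[0]
        r = np.corrcoef(x_hat[core], a.data[core])[0, 1]
        assert r > 0.9
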