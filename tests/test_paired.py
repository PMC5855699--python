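"""Paired GLS with unstructured covariance, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdelta.paired import (
    PairedDesign,
    adjust_fdr,
    build_paired_design,
    fit_paired_design,
    fit_paired_gls,
    run_all_probes,
)


def _design(y0, y1, c0=None, c1=None):
    y0 = np.atleast_2d(y0.T).T if y0.ndim == 1 else y0
    y1 = np.atleast_2d(y1.T).T if y1.ndim == 1 else y1
    n, p = y0.shape
    return PairedDesign(
        y0=y0, y1=y1,
        probe_ids=np.array([f"p{i}" for i in range(p)], object),
        subject_ids=np.array([f"u{i}" for i in range(n)], object),
        covariates0=c0, covariates1=c1,
    )


def _paired_data(rng, n=25, p=10, delta=0.0, subj_sd=1.0, noise_sd=0.5):
    subj = rng.normal(0, subj_sd, size=(n, p))
    y0 = subj + rng.normal(0, noise_sd, size=(n, p))
    y1 = subj + delta + rng.normal(0, noise_sd, size=(n, p))
    return y0, y1


class TestPairedGls:
    def test_matches_paired_t_in_spherical_limit(self, rng):
        """No covariates, exchangeable errors: the unstructured-GLS Wald
        test must coincide with the classical paired t-test."""
        y0, y1 = _paired_data(rng, n=20, p=8)
        res = fit_paired_design(_design(y0, y1))
        for j in range(8):
            t, p_ref = stats.ttest_rel(y1[:, j], y0[:, j])
            assert res["p_value"][j] == pytest.approx(p_ref, abs=1e-6)
            assert res["estimate"][j] == pytest.approx(
                (y1[:, j] - y0[:, j]).mean(), abs=1e-10
            )

    def test_closed_form_gls_oracle_with_covariates(self, rng):
        """Independent per-probe iterated-GLS oracle written directly from
        the estimating equations, looped per probe."""
        n = 30
        y0, y1 = _paired_data(rng, n=n, p=3)
        c0 = rng.normal(size=(n, 2))
        c1 = rng.normal(size=(n, 2))
        res = fit_paired_design(_design(y0, y1, c0, c1))
        x0 = np.hstack([np.ones((n, 1)), np.zeros((n, 1)), c0])
        x1 = np.hstack([np.ones((n, 1)), np.ones((n, 1)), c1])
        p_rank = x0.shape[1]
        for j in range(3):
            sigma = np.eye(2)
            beta = np.zeros(p_rank)
            for _ in range(200):
                w = np.linalg.inv(sigma)
                a = (w[0, 0] * x0.T @ x0 + w[0, 1] * x0.T @ x1
                     + w[1, 0] * x1.T @ x0 + w[1, 1] * x1.T @ x1)
                b = (w[0, 0] * x0.T @ y0[:, j] + w[0, 1] * x0.T @ y1[:, j]
                     + w[1, 0] * x1.T @ y0[:, j] + w[1, 1] * x1.T @ y1[:, j])
                beta = np.linalg.solve(a, b)
                e = np.column_stack([y0[:, j] - x0 @ beta, y1[:, j] - x1 @ beta])
                sigma_new = e.T @ e / (n - p_rank + 1)
                if np.abs(sigma_new - sigma).max() < 1e-12:
                    sigma = sigma_new
                    break
                sigma = sigma_new
            assert res["estimate"][j] == pytest.approx(beta[1], rel=1e-6)

    def test_type_one_error_calibrated(self, rng):
        y0, y1 = _paired_data(rng, n=39, p=5000)
        res = fit_paired_design(_design(y0, y1))
        rate = (res["p_value"] <= 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_label_swap_flips_sign_keeps_p(self, rng):
        y0, y1 = _paired_data(rng, n=20, p=6, delta=0.3)
        a = fit_paired_design(_design(y0, y1))
        b = fit_paired_design(_design(y1, y0))
        assert np.allclose(a["estimate"], -b["estimate"], atol=1e-10)
        assert np.allclose(a["p_value"], b["p_value"], atol=1e-10)

    def test_within_subject_shift_invariance(self, rng):
        y0, y1 = _paired_data(rng, n=18, p=4, delta=0.2)
        shift = rng.normal(0, 3, size=(18, 1))
        a = fit_paired_design(_design(y0, y1))
        b = fit_paired_design(_design(y0 + shift, y1 + shift))
        assert np.allclose(a["estimate"], b["estimate"], atol=1e-8)
        assert np.allclose(a["p_value"], b["p_value"], atol=1e-6)

    def test_degenerate_identical_data_reports_p_one(self, rng):
        y = rng.normal(size=(12, 3))
        res = fit_paired_design(_design(y, y.copy()))
        assert (res["p_value"] == 1.0).all()
        assert (res["estimate"] == 0.0).all()

    def test_constant_covariate_dropped_not_fatal(self, rng):
        y0, y1 = _paired_data(rng, n=15, p=2)
        c = np.full((15, 1), 0.3)
        res = fit_paired_design(_design(y0, y1, c, c.copy()))
        assert np.isfinite(res["p_value"]).all()

    def test_too_few_pairs_raises(self, rng):
        y0, y1 = _paired_data(rng, n=5, p=2)
        with pytest.raises(ValueError, match="pairs"):
            fit_paired_design(_design(y0, y1))

    def test_single_probe_wrapper(self, rng):
        y0, y1 = _paired_data(rng, n=12, p=1, delta=0.5)
        row = fit_paired_gls(_design(y0, y1))
        assert row["estimate"] == pytest.approx((y1 - y0).mean(), abs=1e-10)


def _pipeline_pieces(rng, n_probes=30):
    """Matched MethMatrix pair + sheet + proportions for run_all_probes."""
    from methdelta.core import MethMatrix

    subjects = [f"S{i:02d}" for i in range(15)]
    sheet = pd.DataFrame(
        [{"sample_id": f"{s}_a", "subject_id": s, "timepoint": "age18", "batch": 1}
         for s in subjects]
        + [{"sample_id": f"{s}_p", "subject_id": s, "timepoint": "preg_first",
            "batch": 1}
           for s in subjects]
    )
    probes = np.array([f"p{i}" for i in range(n_probes)], object)
    base = MethMatrix(rng.normal(size=(n_probes, 15)), probes,
                      np.array([f"{s}_a" for s in subjects], object), "m")
    preg = MethMatrix(base.values + rng.normal(0, 0.5, size=(n_probes, 15)),
                      probes, np.array([f"{s}_p" for s in subjects], object), "m")
    props = pd.DataFrame(
        rng.dirichlet(np.ones(7) * 15, size=30),
        index=list(base.sample_ids) + list(preg.sample_ids),
        columns=list("ABCDEFG"),
    )
    return base, preg, props, sheet


class TestRunAllProbes:
    def test_returns_one_row_per_probe(self, rng):
        base, preg, props, sheet = _pipeline_pieces(rng, n_probes=100)
        res = run_all_probes(base, preg, props, sheet, "first")
        assert len(res) == 100
        assert set(res["window"]) == {"first"}
        assert res["probe_id"].is_unique

    def test_deterministic(self, rng):
        base, preg, props, sheet = _pipeline_pieces(rng)
        a = run_all_probes(base, preg, props, sheet, "first")
        b = run_all_probes(base, preg, props, sheet, "first")
        pd.testing.assert_frame_equal(a, b)

    def test_no_overlapping_subjects_raises(self, rng):
        base, preg, props, sheet = _pipeline_pieces(rng)
        sheet2 = sheet.copy()
        sheet2.loc[sheet2["timepoint"] == "preg_first", "subject_id"] = [
            f"T{i}" for i in range(15)
        ]
        with pytest.raises(ValueError):
            build_paired_design(base, preg, props, sheet2, "first")


class TestAdjustFdr:
    def test_hand_step_up_example(self):
        res = pd.DataFrame({
            "probe_id": list("abcd"),
            "p_value": [0.01, 0.02, 0.03, 0.04],
        })
        out = adjust_fdr(res)
        assert np.allclose(out["q_value"], [0.04, 0.04, 0.04, 0.04])

    def test_single_test_q_equals_p(self):
        out = adjust_fdr(pd.DataFrame({"probe_id": ["a"], "p_value": [0.031]}))
        assert out["q_value"].iloc[0] == pytest.approx(0.031)

    def test_all_ones_stay_ones(self):
        out = adjust_fdr(pd.DataFrame({"probe_id": list("abc"),
                                       "p_value": [1.0, 1.0, 1.0]}))
        assert (out["q_value"] == 1.0).all()

    def test_matches_hand_implementation_on_random_vectors(self, rng):
        for _ in range(10):
            p = rng.uniform(size=rng.integers(3, 40))
            res = pd.DataFrame({
                "probe_id": [f"p{i}" for i in range(len(p))], "p_value": p,
            })
            out = adjust_fdr(res)
            # independent step-up oracle
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                q[i] = running
            assert np.allclose(out["q_value"].to_numpy(), q)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=25)
        ids = np.array([f"p{i}" for i in range(25)], object)
        res = pd.DataFrame({"probe_id": ids, "p_value": p})
        shuffled = res.sample(frac=1.0, random_state=1)
        a = adjust_fdr(res).set_index("probe_id")["q_value"]
        b = adjust_fdr(shuffled).set_index("probe_id")["q_value"]
        assert np.allclose(a.loc[ids], b.loc[ids])

    def test_scope_restricts_family(self, rng):
        res = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(10)],
            "p_value": np.linspace(0.001, 0.5, 10),
        })
        out = adjust_fdr(res, scope=["p0", "p1"])
        assert len(out) == 2
        assert out["q_value"].iloc[0] == pytest.approx(0.002)
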