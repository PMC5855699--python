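"""Transforms, probe filtering, quantile normalization, batch correction."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methdelta.combat import combat_adjust
from methdelta.core import MethMatrix
from methdelta.preprocess import (
    beta_to_m,
    clip_beta,
    filter_probes,
    intensity_to_beta,
    m_to_beta,
    quantile_normalize,
)


def _matrix(values, scale="m", prefix="p"):
    values = np.asarray(values, dtype=float)
    return MethMatrix(
        values,
        np.array([f"{prefix}{i}" for i in range(values.shape[0])], object),
        np.array([f"s{j}" for j in range(values.shape[1])], object),
        scale,
    )


class TestBetaTransforms:
    @pytest.mark.parametrize("meth,unmeth,c,expected", [
        (100, 100, 100, 1 / 3),
        (0, 500, 100, 0.0),
        (900, 0, 100, 0.9),
    ])
    def test_intensity_to_beta_arithmetic(self, meth, unmeth, c, expected):
        assert intensity_to_beta(meth, unmeth, c) == pytest.approx(expected)

    def test_intensity_to_beta_all_zero_raises(self):
        with pytest.raises(ZeroDivisionError):
            intensity_to_beta(0.0, 0.0, 0.0)

    def test_intensity_to_beta_rejects_negative(self):
        with pytest.raises(ValueError):
            intensity_to_beta(-1.0, 10.0, 100.0)

    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_logit_midpoint_and_log2_values(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)

    def test_round_trip_exact_to_1e12(self, rng):
        beta = rng.uniform(1e-5, 1 - 1e-5, size=1000)
        assert np.abs(m_to_beta(beta_to_m(beta)) - beta).max() < 1e-12

    def test_logit_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            beta_to_m(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            beta_to_m(1.0)

    def test_clip_keeps_values_loggable(self):
        m = beta_to_m(clip_beta(np.array([0.0, 1.0])))
        assert np.isfinite(m).all()


def _toy_manifest():
    return pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(5)],
        "chrom": ["1", "X", "2", "3", "4"],
        "pos": [100, 200, 300, 400, 500],
        "genes": [""] * 5,
        "region_groups": [""] * 5,
        "snp_maf_gt_1pct": [False, False, True, False, False],
    })


class TestFilterProbes:
    def test_hand_counted_toy(self, rng):
        mat = _matrix(rng.normal(size=(5, 3)))
        out, report = filter_probes(mat, _toy_manifest())
        assert out.n_probes == 3
        assert report.n_removed_snp == 1
        assert report.n_removed_sexchrom == 1
        assert report.n_output == 3
        assert list(out.probe_ids) == ["p0", "p3", "p4"]

    def test_identity_when_nothing_flagged(self, rng):
        man = _toy_manifest()
        man["chrom"] = "5"
        man["snp_maf_gt_1pct"] = False
        mat = _matrix(rng.normal(size=(5, 3)))
        out, report = filter_probes(mat, man)
        assert out.n_probes == 5
        assert report.n_removed_snp == 0 and report.n_removed_sexchrom == 0

    def test_double_flag_removed_once_counted_under_snp_rule(self, rng):
        man = _toy_manifest()
        man.loc[1, "snp_maf_gt_1pct"] = True  # p1 on chrX AND SNP-flagged
        mat = _matrix(rng.normal(size=(5, 3)))
        out, report = filter_probes(mat, man)
        # set-union oracle: removed = |snp OR sexchrom|
        removed = {"p1", "p2"}
        assert set(mat.probe_ids) - set(out.probe_ids) == removed
        assert report.n_removed_snp == 2  # both SNP-flagged
        assert report.n_removed_sexchrom == 0
        assert report.n_input - report.n_output == len(removed)

    def test_idempotent(self, rng):
        man = _toy_manifest()
        mat = _matrix(rng.normal(size=(5, 3)))
        once, _ = filter_probes(mat, man)
        twice, rep2 = filter_probes(once, man)
        assert np.array_equal(once.values, twice.values)
        assert rep2.n_input == rep2.n_output

    def test_missing_manifest_entry_raises(self, rng):
        mat = _matrix(rng.normal(size=(6, 3)))
        with pytest.raises(KeyError):
            filter_probes(mat, _toy_manifest())


class TestQuantileNormalize:
    def test_equal_columns_unchanged(self):
        col = np.array([0.3, 1.2, -0.5, 2.0])
        mat = _matrix(np.column_stack([col, col]))
        out = quantile_normalize(mat)
        assert np.allclose(out.values, mat.values)

    def test_hand_computed_reference(self):
        mat = _matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(mat)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out.values, expected)

    def test_columns_share_identical_sorted_values(self, rng):
        mat = _matrix(rng.normal(size=(50, 6)))
        out = quantile_normalize(mat)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 6):
            assert np.allclose(np.sort(out.values[:, j]), ref)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rank_order_preserved_within_columns(self, seed):
        x = np.random.default_rng(seed).normal(size=(30, 4))
        out = quantile_normalize(_matrix(x))
        for j in range(4):
            a = np.argsort(x[:, j], kind="stable")
            assert np.all(np.diff(out.values[a, j]) >= 0)

    def test_single_sample_warns_and_passes_through(self, rng):
        mat = _matrix(rng.normal(size=(10, 1)))
        with pytest.warns(UserWarning):
            out = quantile_normalize(mat)
        assert np.array_equal(out.values, mat.values)


def _batch_sheet(batches):
    n = len(batches)
    return pd.DataFrame({
        "sample_id": [f"s{j}" for j in range(n)],
        "subject_id": [f"u{j}" for j in range(n)],
        "timepoint": ["age18"] * n,
        "batch": batches,
    })


class TestCombat:
    def test_single_batch_identity(self, rng):
        mat = _matrix(rng.normal(size=(40, 8)))
        out = combat_adjust(mat, _batch_sheet([1] * 8))
        assert np.abs(out.values - mat.values).max() < 1e-10

    def test_singleton_batch_raises(self, rng):
        mat = _matrix(rng.normal(size=(10, 5)))
        with pytest.raises(ValueError, match="batch"):
            combat_adjust(mat, _batch_sheet([1, 1, 1, 1, 2]))

    def test_removes_injected_mean_shift(self, rng):
        n_per = 20
        x = rng.normal(size=(300, 2 * n_per))
        x[:, n_per:] += 1.0  # batch 2 shifted on every probe
        out = combat_adjust(_matrix(x), _batch_sheet([1] * n_per + [2] * n_per))
        gap = out.values[:, :n_per].mean(axis=1) - out.values[:, n_per:].mean(axis=1)
        # the systematic +1.0 shift is gone on average; what remains per
        # probe is shrunken sampling noise, far below the injected shift
        assert abs(gap.mean()) < 0.05
        assert np.abs(gap).mean() < 0.3

    def test_shrinks_injected_variance_inflation(self, rng):
        n_per = 25
        x = rng.normal(size=(400, 2 * n_per))
        x[:, n_per:] *= 2.0  # batch 2 variance x4
        out = combat_adjust(_matrix(x), _batch_sheet([1] * n_per + [2] * n_per))
        pooled = out.values.var(axis=1).mean()
        for cols in (slice(0, n_per), slice(n_per, None)):
            batch_var = out.values[:, cols].var(axis=1).mean()
            assert abs(batch_var - pooled) / pooled < 0.2

    def test_shift_equivariance(self, rng):
        x = rng.normal(size=(60, 12))
        sheet = _batch_sheet([1] * 6 + [2] * 6)
        a = combat_adjust(_matrix(x), sheet)
        b = combat_adjust(_matrix(x + 5.0), sheet)
        assert np.abs((b.values - a.values) - 5.0).max() < 1e-8

    def test_preserved_covariate_effect_survives(self, rng):
        n_per = 30
        grp = np.tile([0.0, 1.0], n_per)
        x = rng.normal(size=(200, 2 * n_per)) + 2.0 * grp[None, :]
        batches = [1] * n_per + [2] * n_per
        out = combat_adjust(_matrix(x), _batch_sheet(batches),
                            covariates_to_preserve=grp[:, None])
        effect = out.values[:, grp == 1].mean() - out.values[:, grp == 0].mean()
        assert effect == pytest.approx(2.0, abs=0.05)

    def test_matches_reference_r_implementation(self, rng, tmp_path):
        """Independent oracle: Bioconductor's empirical-Bayes adjustment."""
        x = rng.normal(size=(120, 24))
        batches = np.repeat([1, 2, 3], 8)
        x += np.array([0.0, 0.8, -0.6])[batches - 1][None, :]
        grp = np.tile([0.0, 1.0], 12)
        np.savetxt(tmp_path / "x.csv", x, delimiter=",")
        sheet = _batch_sheet(list(batches))
        ours = combat_adjust(_matrix(x), sheet, covariates_to_preserve=grp[:, None])
        script = textwrap.dedent(f"""
            suppressMessages(library(sva))
            x <- as.matrix(read.csv('{tmp_path}/x.csv', header=FALSE))
            batch <- rep(1:3, each=8)
            grp <- rep(c(0,1), 12)
            adj <- ComBat(dat=x, batch=batch, mod=model.matrix(~grp),
                          par.prior=TRUE)
            write.table(adj, '{tmp_path}/r.csv', sep=',', row.names=FALSE,
                        col.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True, timeout=300)
        theirs = np.loadtxt(tmp_path / "r.csv", delimiter=",")
        assert np.abs(ours.values - theirs).max() < 1e-3
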