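"""Empirical-Bayes batch correction: planted shifts, reference mode, protection."""

import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import epiclock as ec
from epiclock.batch import (apply_batch_model, batch_pca, correct_batches,
                            fit_batch_model, protect_with_predicted_age)

from conftest import two_batch_cohort


def fitted_age_slopes(bm, sheet):
    """Per-site OLS slope of beta on age (the biological signal of interest)."""
    age = sheet.aligned_to(bm).ages.to_numpy()
    ac = age - age.mean()
    Y = bm.values.to_numpy()
    return (Y - Y.mean(axis=1, keepdims=True)) @ ac / (ac @ ac)


class TestFitApply:
    def test_planted_shift_removed(self):
        # batch B is batch A plus a constant: the paired construction makes
        # a per-site mean-centering oracle exact, and the EB fit must match it
        rng = np.random.default_rng(0)
        n_sites, n = 60, 40
        A = rng.uniform(0.2, 0.7, (n_sites, n)) * 0.2 + rng.uniform(0.2, 0.6, (n_sites, 1))
        B = A + 0.1
        ids = [f"cg{i}" for i in range(n_sites)]
        cols = [f"a{j}" for j in range(n)] + [f"b{j}" for j in range(n)]
        bm = ec.BetaMatrix(pd.DataFrame(np.hstack([A, B]), index=ids, columns=cols))
        sheet = ec.SampleSheet(pd.DataFrame({
            "sample_id": cols, "age": rng.uniform(12, 25, 2 * n),
            "batch": ["A"] * n + ["B"] * n}))
        corrected = correct_batches(bm, sheet)
        cA = corrected.values.iloc[:, :n].mean(axis=1)
        cB = corrected.values.iloc[:, n:].mean(axis=1)
        # mean-centering oracle: both batches land on the pooled mean
        assert np.abs(cA - cB).max() < 0.01

    def test_no_batch_effect_limit(self):
        bm, sheet, _ = two_batch_cohort(seed=9, shift=0.0, n_per_batch=100)
        corrected = correct_batches(bm, sheet, protected=["age"])
        delta = np.abs(corrected.values.to_numpy() - bm.values.to_numpy())
        assert np.median(delta) < 0.01  # near-identity up to EB shrinkage noise

    def test_reference_batch_bit_identical(self):
        bm, sheet, _ = two_batch_cohort(seed=1)
        model = fit_batch_model(bm, sheet, protected=["age"], reference="A")
        corrected = apply_batch_model(bm, model, sheet)
        mask = (sheet.batches == "A").to_numpy()
        np.testing.assert_array_equal(
            corrected.values.to_numpy()[:, mask], bm.values.to_numpy()[:, mask])
        assert (model.gamma_star.loc["A"] == 0).all()
        assert (model.delta_star.loc["A"] == 1).all()

    def test_apply_consistent_with_fit(self):
        bm, sheet, _ = two_batch_cohort(seed=2)
        model = fit_batch_model(bm, sheet, protected=["age"])
        once = apply_batch_model(bm, model, sheet)
        again = apply_batch_model(bm, model, sheet)
        np.testing.assert_array_equal(once.values.to_numpy(), again.values.to_numpy())

    def test_unknown_batch_rejected(self):
        bm, sheet, _ = two_batch_cohort(seed=3)
        model = fit_batch_model(bm, sheet)
        tab = sheet.table.copy()
        tab["batch"] = "Z"
        with pytest.raises(ValueError, match="Z"):
            apply_batch_model(bm, model, ec.SampleSheet(tab.reset_index(drop=True)))

    def test_singleton_batch_rejected(self):
        bm, sheet, _ = two_batch_cohort(seed=4, n_per_batch=30)
        tab = sheet.table.copy()
        tab.loc[tab.index[0], "batch"] = "C"
        with pytest.raises(ValueError, match="singleton"):
            fit_batch_model(bm, ec.SampleSheet(tab.reset_index(drop=True)))

    def test_output_clipped_to_unit_interval(self):
        bm, sheet, _ = two_batch_cohort(seed=5, shift=0.25)
        corrected = correct_batches(bm, sheet, protected=["age"])
        vals = corrected.values.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestAgeProtection:
    def test_protected_age_slopes_preserved(self):
        # with age protected, the fitted age-beta slopes of planted
        # age-associated sites must survive the adjustment within 10%
        bm, sheet, _ = two_batch_cohort(seed=11, n_sites=60, n_per_batch=80,
                                        shift=0.08, slope_sd=0.02)
        before = fitted_age_slopes(bm, sheet)
        strong = np.abs(before) > 0.01
        prot = correct_batches(bm, sheet, protected=["age"])
        after = fitted_age_slopes(prot, sheet)
        rel = np.abs(after[strong] - before[strong]) / np.abs(before[strong])
        assert np.median(rel) < 0.10

    def test_unprotected_correction_degrades_confounded_age_signal(self):
        # batches with disjoint age ranges: unprotected adjustment absorbs
        # the between-batch age signal, protected adjustment keeps it --
        # the known failure mode of correcting without a protected variable
        bm, sheet, true_slopes = two_batch_cohort(
            seed=11, n_sites=60, n_per_batch=80, shift=0.08,
            age_by_batch={"A": (12, 18), "B": (19, 25)}, slope_sd=0.02)
        strong = np.abs(true_slopes) > 0.015
        unprot = fitted_age_slopes(correct_batches(bm, sheet, protected=[]), sheet)
        prot = fitted_age_slopes(correct_batches(bm, sheet, protected=["age"]), sheet)
        err_unprot = np.median(np.abs(unprot[strong] - true_slopes[strong])
                               / np.abs(true_slopes[strong]))
        err_prot = np.median(np.abs(prot[strong] - true_slopes[strong])
                             / np.abs(true_slopes[strong]))
        assert err_prot < 0.10
        assert err_unprot > 5 * err_prot

    def test_predicted_age_protection_close_to_true_age(self, default_fit,
                                                        default_cohort):
        _, bm, sheet, _ = default_cohort
        filtered, _, fit = default_fit
        sub_sites = fit.model.sites
        small = filtered.select_sites(sub_sites)
        with_true = correct_batches(small, sheet, protected=["age"], reference="study_A")
        with_pred = protect_with_predicted_age(small, sheet, fit.model, "study_A")
        gap = np.abs(with_true.values.to_numpy() - with_pred.values.to_numpy())
        assert gap.max() < 0.01  # small relative to noise sd 0.03

    def test_constant_prediction_degenerates_to_unprotected(self):
        # a clock whose sites the matrix lacks predicts a constant age
        # (imputed 0.5 everywhere); the constant covariate carries no signal
        # and the variant must reduce to plain reference-mode correction.
        # bm has a cg0... site naming scheme, so "cgabsent" is never present
        bm, sheet, _ = two_batch_cohort(seed=6)
        clock = ec.ClockModel(intercept=0.1,
                              coefficients={bm.site_ids[0]: 0.5, "cgabsent": 0.2},
                              transform_spec=ec.TransformSpec())
        constant_clock = ec.ClockModel(
            intercept=0.1, coefficients={"cgabsent": 0.5},
            transform_spec=ec.TransformSpec())
        with pytest.raises(ValueError):
            # zero model sites present is an error by contract
            protect_with_predicted_age(bm, sheet, constant_clock, "A")
        # one present site with zero-variance contribution: craft betas equal
        tab = bm.values.copy()
        tab.iloc[0, :] = 0.5
        flat_bm = ec.BetaMatrix(tab)
        out = protect_with_predicted_age(flat_bm, sheet, clock, "A")
        plain = correct_batches(flat_bm, sheet, protected=[], reference="A")
        np.testing.assert_allclose(out.values.to_numpy(),
                                   plain.values.to_numpy(), atol=1e-10)


class TestBatchPCA:
    def test_planted_shift_dominates_then_vanishes(self):
        bm, sheet, _ = two_batch_cohort(seed=21, shift=0.12, n_per_batch=60)
        diag_before = batch_pca(bm, sheet, n_components=4)
        corrected = correct_batches(bm, sheet, protected=["age"])
        diag_after = batch_pca(corrected, sheet, n_components=4)
        assert diag_before["batch_F"].max() > 10 * diag_after["batch_F"].max()

    def test_f_statistic_matches_hand_anova(self):
        bm, sheet, _ = two_batch_cohort(seed=22, shift=0.2, n_per_batch=30)
        diag = batch_pca(bm, sheet, n_components=2)
        scores = diag.attrs["scores"]["PC1"]
        g = sheet.batches
        # one-way ANOVA F recomputed from group means by hand
        grand = scores.mean()
        groups = [scores[(g == b).to_numpy()] for b in ("A", "B")]
        ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
        ssw = sum(((x - x.mean()) ** 2).sum() for x in groups)
        F = (ssb / 1) / (ssw / (len(scores) - 2))
        assert diag.loc[1, "batch_F"] == pytest.approx(F, rel=1e-9)

    def test_permuted_labels_near_null(self):
        bm, sheet, _ = two_batch_cohort(seed=23, shift=0.15, n_per_batch=60)
        rng = np.random.default_rng(0)
        tab = sheet.table.copy()
        tab["batch"] = rng.permutation(tab["batch"].to_numpy())
        permuted = ec.SampleSheet(tab.reset_index(drop=True))
        diag = batch_pca(bm, permuted, n_components=4)
        assert diag["batch_F"].mean() < 5  # F ~ 1 in expectation

    def test_single_batch_rejected(self):
        bm, sheet, _ = two_batch_cohort(seed=24)
        tab = sheet.table.copy()
        tab["batch"] = "A"
        with pytest.raises(ValueError, match="two batches"):
            batch_pca(bm, ec.SampleSheet(tab.reset_index(drop=True)), 2)


class TestAgainstReferenceImplementation:
    """Cross-check against the established R implementation on a tiny fixture."""

    def test_matches_sva_combat(self, tmp_path):
        rng = np.random.default_rng(7)
        n_sites, ns = 25, (18, 14, 20)
        base = rng.uniform(0.2, 0.8, (n_sites, 1))
        n = sum(ns)
        age = rng.uniform(12, 25, n)
        batch = np.repeat(["A", "B", "C"], ns)
        shift = {"A": 0.0, "B": 0.08, "C": -0.05}
        vals = np.clip(
            base + rng.normal(0, 0.01, (n_sites, 1)) * (age[None, :] - 18)
            + np.array([shift[b] for b in batch])[None, :]
            + rng.normal(0, 0.04, (n_sites, n)), 0.01, 0.99)
        ids = [f"cg{i}" for i in range(n_sites)]
        samp = [f"s{j}" for j in range(n)]
        pd.DataFrame(vals, index=ids, columns=samp).to_csv(tmp_path / "d.csv")
        pd.DataFrame({"sample_id": samp, "age": age, "batch": batch}).to_csv(
            tmp_path / "s.csv", index=False)
        rscript = (
            'suppressMessages(library(sva));'
            'd <- as.matrix(read.csv("d.csv", row.names=1, check.names=FALSE));'
            's <- read.csv("s.csv");'
            'mod <- model.matrix(~age, data=s);'
            'write.csv(ComBat(dat=d, batch=s$batch, mod=mod), "r_default.csv");'
            'write.csv(ComBat(dat=d, batch=s$batch, mod=mod, ref.batch="A"), "r_ref.csv")'
        )
        subprocess.run(["Rscript", "-e", rscript], cwd=tmp_path, check=True,
                       capture_output=True)
        bm = ec.BetaMatrix(pd.DataFrame(vals, index=ids, columns=samp))
        sheet = ec.SampleSheet(pd.DataFrame(
            {"sample_id": samp, "age": age, "batch": batch}))
        for ref, fname in ((None, "r_default.csv"), ("A", "r_ref.csv")):
            ours = correct_batches(bm, sheet, protected=["age"], reference=ref)
            theirs = pd.read_csv(tmp_path / fname, index_col=0)
            # we clip adjusted betas to [0, 1]; the R implementation does
            # not, and the two EB solvers stop at slightly different points
            np.testing.assert_allclose(ours.values.to_numpy(),
                                       np.clip(theirs.to_numpy(), 0, 1),
                                       atol=1e-6)
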