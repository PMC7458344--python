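import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoconcord.io import ExpressionMatrix, IHCRecord, log_transform
from immunoconcord.signature import (
    SignatureEnrichmentClassifier,
    assign_classes,
    classify_enriched,
    select_signature,
    signature_infiltrate_correlation,
    ttest_per_gene,
    zscore_vs_reference,
)
from immunoconcord.simulate import SimulationConfig, simulate_cohort

from oracles import pooled_t_by_hand


def rec(patient, cd3, cd8):
    return IHCRecord(patient, cd3, cd8, 100.0, 12.0, True)


class TestAssignClasses:
    def test_definitional_labels(self):
        # cd3 cutoff (p75 of 1..8) = 6.25; cd8 cutoff (median) = 4.5
        ihc = [rec(f"P{i}", float(i), float(i)) for i in range(1, 9)]
        labels = assign_classes(ihc)
        assert labels["P8"] == "HI"  # above both cutoffs
        assert labels["P1"] == "LOW"  # below both
        assert labels["P5"] == "excluded"  # above cd8 median, below cd3 p75

    def test_missing_density_excluded(self):
        ihc = [rec("P1", 5.0, 5.0), rec("P2", None, 5.0), rec("P3", 1.0, 1.0), rec("P4", 9.0, 9.0)]
        labels = assign_classes(ihc)
        assert labels["P2"] == "excluded"

    def test_independent_densities_hi_fraction(self):
        """With i.i.d. CD3/CD8 the expected HI share is ~0.25 x 0.5."""
        rng = np.random.default_rng(20)
        n = 4000
        ihc = [rec(f"P{i}", float(a), float(b)) for i, (a, b) in enumerate(zip(rng.random(n), rng.random(n)))]
        labels = assign_classes(ihc)
        assert (labels == "HI").mean() == pytest.approx(0.125, abs=0.02)


class TestTTestPerGene:
    def test_hand_computed_pooled_example(self):
        expr = ExpressionMatrix(
            pd.DataFrame(
                [[1.0, 2.0, 3.0, 4.0, 3.0, 4.0, 5.0, 6.0]],
                index=["g"],
                columns=[f"s{i}" for i in range(8)],
            ),
            transform="normalized_log",
        )
        labels = pd.Series(["HI"] * 4 + ["LOW"] * 4, index=expr.samples)
        sig = ttest_per_gene(expr, labels)
        assert sig.table.loc["g", "t"] == pytest.approx(-2.191, abs=1e-3)
        assert sig.table.loc["g", "p"] == pytest.approx(0.0707, abs=2e-3)
        assert sig.table.loc["g", "direction"] == "up_in_LOW"

    def test_identical_class_values_give_null(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["g"], columns=list("abcd")),
            transform="normalized_log",
        )
        labels = pd.Series(["HI", "HI", "LOW", "LOW"], index=expr.samples)
        sig = ttest_per_gene(expr, labels)
        assert sig.table.loc["g", "t"] == pytest.approx(0.0)
        assert sig.table.loc["g", "p"] == pytest.approx(1.0)

    def test_zero_variance_both_groups_missing_never_selected(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0, 2.0, 2.0]], index=["g"], columns=list("abcd")),
            transform="normalized_log",
        )
        labels = pd.Series(["HI", "HI", "LOW", "LOW"], index=expr.samples)
        sig = ttest_per_gene(expr, labels, alpha=1.0)
        assert np.isnan(sig.table.loc["g", "p"])
        assert not sig.table.loc["g", "selected"]

    def test_refuses_raw_tpm(self):
        expr = ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["g"], columns=list("abcd")))
        labels = pd.Series(["HI", "HI", "LOW", "LOW"], index=expr.samples)
        with pytest.raises(ValueError, match="log-scale"):
            ttest_per_gene(expr, labels)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        hi=st.lists(st.floats(-50, 50, allow_nan=False), min_size=3, max_size=10),
        low=st.lists(st.floats(-50, 50, allow_nan=False), min_size=3, max_size=10),
    )
    def test_matches_from_scratch_pooled_oracle(self, hi, low):
        """Pooled t equals the means/pooled-variance/t-CDF oracle."""
        vals = hi + low
        if np.std(hi) == 0 and np.std(low) == 0:
            return
        expr = ExpressionMatrix(
            pd.DataFrame([vals], index=["g"], columns=[f"s{i}" for i in range(len(vals))]),
            transform="normalized_log",
        )
        labels = pd.Series(["HI"] * len(hi) + ["LOW"] * len(low), index=expr.samples)
        sig = ttest_per_gene(expr, labels)
        t, p = pooled_t_by_hand(hi, low)
        assert sig.table.loc["g", "t"] == pytest.approx(t, rel=1e-10, abs=1e-12)
        assert sig.table.loc["g", "p"] == pytest.approx(p, rel=1e-10, abs=1e-12)

    def test_selection_monotone_in_alpha(self, signature_fixture):
        expr, classes = signature_fixture
        prev = -1
        for alpha in (1e-6, 1e-4, 1e-3, 1e-2, 0.1):
            n = int(ttest_per_gene(expr, classes, alpha=alpha).table["selected"].sum())
            assert n >= prev
            prev = n


class TestSelectSignature:
    def test_direction_filter_on_fixture(self, signature_fixture):
        expr, classes = signature_fixture
        sig = ttest_per_gene(expr, classes)
        down = select_signature(sig, "up_in_LOW")
        # genes enriched in poorly infiltrated tumors
        assert {"FAM3C", "NEBL", "HSP90AB1", "CSTB", "PDCD11"} <= set(down)
        both = select_signature(sig, "both")
        up = select_signature(sig, "up_in_HI")
        assert set(both) == set(up) | set(down)
        # stable ascending-p order
        ps = sig.table.loc[both, "p"]
        assert (ps.diff().dropna() >= 0).all()

    def test_alpha_zero_empty_with_warning(self, signature_fixture):
        expr, classes = signature_fixture
        sig = ttest_per_gene(expr, classes, alpha=0.0)
        with pytest.warns(RuntimeWarning, match="empty"):
            assert select_signature(sig) == []


class TestZScore:
    def test_reference_mean_gives_zero_and_standardization(self):
        rng = np.random.default_rng(21)
        expr = ExpressionMatrix(
            pd.DataFrame(rng.normal(5, 2, size=(4, 10)), index=list("abcd"), columns=[f"s{i}" for i in range(10)]),
            transform="normalized_log",
        )
        z = zscore_vs_reference(expr)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_documented_sd_conventions(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"], columns=list("abcd")),
            transform="normalized_log",
        )
        # default sample-sd convention: reference (1,2,3) has sd 1, z = (4-2)/1
        z = zscore_vs_reference(expr, reference_samples=["a", "b", "c"])
        assert z.loc["g", "d"] == pytest.approx(2.0)
        # population-sd alternative: sd = sqrt(2/3)
        z0 = zscore_vs_reference(expr, reference_samples=["a", "b", "c"], ddof=0)
        assert z0.loc["g", "d"] == pytest.approx(2.0 / np.sqrt(2.0 / 3.0))

    def test_zero_sd_gene_missing(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0, 1.0, 9.0]], index=["g"], columns=list("abcd")),
            transform="normalized_log",
        )
        z = zscore_vs_reference(expr, reference_samples=["a", "b", "c"])
        assert z.loc["g"].isna().all()


class TestClassifyEnriched:
    def z(self):
        return pd.DataFrame(
            [[2.5, 1.9, 1.0], [0.0, 1.9, 2.0]],
            index=["g1", "g2"],
            columns=["s1", "s2", "s3"],
        )

    def test_threshold_semantics(self):
        calls = {c.sample: c for c in classify_enriched(self.z(), ["g1", "g2"])}
        assert calls["s1"].enriched and calls["s1"].triggering_genes == {"g1": 2.5}
        assert not calls["s2"].enriched  # all genes at 1.9 < 2
        assert calls["s3"].enriched  # z == threshold counts

    def test_no_signature_gene_present_is_error(self):
        with pytest.raises(ValueError, match="no signature gene"):
            classify_enriched(self.z(), ["absent"])

    def test_monotone_in_z(self):
        z = self.z()
        base = {c.sample: c.enriched for c in classify_enriched(z, ["g1", "g2"])}
        z2 = z + 0.5
        up = {c.sample: c.enriched for c in classify_enriched(z2, ["g1", "g2"])}
        assert all(up[s] >= base[s] for s in base)

    def test_sklearn_classifier_agrees_with_function(self):
        rng = np.random.default_rng(22)
        ref = pd.DataFrame(rng.normal(size=(5, 30)), index=list("abcde"), columns=[f"r{i}" for i in range(30)])
        query = pd.DataFrame(rng.normal(size=(5, 8)), index=list("abcde"), columns=[f"q{i}" for i in range(8)])
        clf = SignatureEnrichmentClassifier(signature_genes=["a", "c"], threshold=2.0).fit(ref)
        pred = clf.predict(query)
        mean, sd = ref.loc[["a", "c"]].mean(axis=1), ref.loc[["a", "c"]].std(axis=1, ddof=1)
        zq = query.loc[["a", "c"]].sub(mean, axis=0).div(sd, axis=0)
        calls = classify_enriched(zq, ["a", "c"])
        assert list(pred) == [c.enriched for c in calls]

    def test_sensitivity_on_planted_validation_cohort(self):
        """Samples with several signature genes pushed >= 3 reference sds
        are nearly always called enriched; unshifted samples rarely are."""
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(20)]
        sig_genes = genes[:5]
        ref = pd.DataFrame(rng.normal(0, 1, size=(20, 50)), index=genes, columns=[f"r{i}" for i in range(50)])
        n_pos, n_neg = 40, 40
        pos = pd.DataFrame(rng.normal(0, 1, size=(20, n_pos)), index=genes, columns=[f"p{i}" for i in range(n_pos)])
        pos.loc[sig_genes[:3]] += 3.0
        neg = pd.DataFrame(rng.normal(0, 1, size=(20, n_neg)), index=genes, columns=[f"n{i}" for i in range(n_neg)])
        clf = SignatureEnrichmentClassifier(signature_genes=sig_genes, threshold=2.0).fit(ref)
        sens = clf.predict(pos).mean()
        assert sens >= 0.9


class TestLabelPermutationNull:
    def test_true_labels_beat_permuted_labels(self, signature_fixture):
        """Permuting HI/LOW labels almost always selects fewer genes than
        the true labeling."""
        expr, classes = signature_fixture
        true_n = int(ttest_per_gene(expr, classes).table["selected"].sum())
        rng = np.random.default_rng(24)
        fewer = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = pd.Series(rng.permutation(classes.to_numpy()), index=classes.index)
            n = int(ttest_per_gene(expr, perm).table["selected"].sum())
            fewer += n < true_n
        assert fewer / n_perm >= 0.95


class TestSignatureInfiltrateCorrelation:
    def test_shape_diagonal_and_planted_separation(self):
        cohort = simulate_cohort(SimulationConfig(n_patients=80, effect_size=2.0, seed=25))
        expr = log_transform(cohort.expression)
        infiltrates = pd.DataFrame(
            {"latent_cd3": cohort.truth["latent_cd3"], "latent_cd68": cohort.truth["latent_cd68"]}
        ).T
        planted = cohort.planted_genes[:10]
        background = [g for g in expr.genes if g not in set(cohort.planted_genes)][:10]
        corr, Z, order = signature_infiltrate_correlation(expr, planted + background, infiltrates)
        k = len(planted) + len(background) + 2
        assert corr.shape == (k, k)
        assert corr.loc[planted[0], planted[0]] == pytest.approx(1.0)
        assert set(order) == set(corr.index)
        r_planted = corr.loc[planted, "latent_cd3"].median()
        r_background = corr.loc[background, "latent_cd3"].median()
        assert r_planted - r_background > 0.3

    def test_too_few_shared_samples_is_error(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc")),
            transform="normalized_log",
        )
        infil = pd.DataFrame([[1.0, 2.0]], index=["T"], columns=["a", "b"])
        with pytest.raises(ValueError, match="shared samples"):
            signature_infiltrate_correlation(expr, ["g"], infil)
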