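"""Composition summaries and ANOVA/Tukey compact letters, checked against
hand arithmetic and the published group table's internal sums."""

import dataclasses
import itertools

import numpy as np
import pytest

from fameclass.summary_stats import (anova_tukey, anova_tukey_values,
                                     compact_letter_display,
                                     derived_quantities, summarize_groups)
from fameclass.synthetic_data import (GeneratorConfig, default_parameters,
                                      generate_dataset)


def _zero_variance_dataset():
    params = default_parameters()
    params = dataclasses.replace(
        params, sds=params.sds * 0.0,
        samples_per_group={0: 3, 1: 3, 2: 3, 3: 3})
    return generate_dataset(params, GeneratorConfig(
        replicate_cv=0.0, between_group_correlation=0.0,
        missing_instances=0, seed=0))


class TestDerivedQuantities:
    def test_sfa_sum_at_published_wild_means(self):
        """With zero variance, the wild profile is the closed mean vector,
        so SFA = (14:0 + 16:0 + 18:0) scaled by the closure factor:
        23.22 x 100/99.96 = 23.23, matching the published 23.25 within the
        rounding tolerance of a per-sample summation."""
        ds = _zero_variance_dataset()
        summary = summarize_groups(ds, with_letters=False)
        sfa_wild = summary.table.loc["SFA", (3, "mean")]
        assert sfa_wild == pytest.approx(23.229, abs=0.01)
        assert abs(sfa_wild - 23.25) < 0.1

    def test_component_sums_exact_per_sample(self, small_dataset):
        tab = small_dataset.sample_table()
        feats = list(small_dataset.feature_names)
        derived = derived_quantities(tab[feats])
        total = derived["SFA"] + derived["MUFA"] + derived["PUFA"]
        np.testing.assert_allclose(total, tab[feats].sum(axis=1), atol=1e-9)

    def test_coelution_conventions_differ(self, small_dataset):
        tab = small_dataset.sample_table()
        feats = list(small_dataset.feature_names)
        excl = derived_quantities(tab[feats], "exclude")["n3/n6"]
        half = derived_quantities(tab[feats], "half")["n3/n6"]
        assert not np.allclose(excl, half)
        with pytest.raises(ValueError, match="n3n6_coelution"):
            derived_quantities(tab[feats], "all_n3")


class TestAnovaTukey:
    def test_hand_computed_two_group_anova(self):
        """Groups {1,2,3} and {101,102,103}: group means 2 and 102, grand
        mean 52, so SSB = 2 * 3 * 50^2 = 15000 on 1 df and MSW = 4/4 = 1,
        giving F = 15000."""
        F, p, pw, letters = anova_tukey_values(
            [np.array([1.0, 2.0, 3.0]), np.array([101.0, 102.0, 103.0])])
        assert F == pytest.approx(15000.0)
        assert p < 1e-6
        assert letters[0] != letters[1]

    def test_identically_drawn_groups_share_a_letter(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 20) for _ in range(3)]
        _, _, _, letters = anova_tukey_values(groups)
        shared = set(letters[0]) & set(letters[1]) & set(letters[2])
        assert shared  # null case at a fixed, representative seed

    def test_zero_variance_ties_fully_significant_with_warning(self):
        with pytest.warns(UserWarning, match="zero within-group"):
            F, p, pw, letters = anova_tukey_values(
                [np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        assert letters[0] != letters[1]

    def test_linoleic_acid_group_pattern(self, default_dataset):
        """Linoleic acid (18:2n6c) separates wild from every farmed group
        and Canada-farmed from the other two farmed groups, as in the
        published letters.  (Whether Chile and Norway share a letter is
        borderline by design — their parameter means differ by 0.05 — and
        flips with the realized feed-factor shift, so it is not asserted.)"""
        F, p, pw, letters = anova_tukey(default_dataset, "18:2n6c")
        assert p < 1e-6
        # wild (3) shares no letter with any farmed group, lowest mean
        assert not set(letters[3]) & (set(letters[0]) | set(letters[1])
                                      | set(letters[2]))
        assert letters[3] == "a"
        # Canada farmed (2) distinct from Chile (1) and Norway (0)
        assert not set(letters[2]) & (set(letters[0]) | set(letters[1]))


class TestCompactLetterDisplay:
    def test_letters_encode_significance_exactly(self):
        """Property: groups share a letter iff non-significant, for every
        transitive-closure-free random significance pattern."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = rng.integers(2, 7)
            means = rng.normal(size=k)
            sig = np.zeros((k, k), dtype=bool)
            for i, j in itertools.combinations(range(k), 2):
                sig[i, j] = sig[j, i] = rng.random() < 0.4
            letters = compact_letter_display(sig, means)
            for i, j in itertools.combinations(range(k), 2):
                share = bool(set(letters[i]) & set(letters[j]))
                assert share != sig[i, j], (sig, letters)

    def test_alphabetical_from_lowest_mean(self):
        sig = np.array([[False, True], [True, False]])
        letters = compact_letter_display(sig, np.array([5.0, 1.0]))
        assert letters == ["b", "a"]


class TestSummarizeGroups:
    def test_replicates_averaged_before_statistics(self, default_dataset):
        """Group SDs are across fish, so they sit near the published
        between-specimen values (the coupled groups carry a sqrt(1 - rho)
        fish-level share, so only the uncoupled groups are compared)."""
        summary = summarize_groups(default_dataset, with_letters=False)
        assert summary.table.loc["16:0", (3, "n")] == 26
        sd = summary.table.loc["16:0", (3, "sd")]
        assert 0.5 * 1.70 < sd < 1.5 * 1.70

    def test_single_sample_group_warns_with_zero_sd(self, small_dataset):
        keep = [s for s in np.unique(small_dataset.sample_ids)
                if not s.startswith("G1") or s == "G1S000"]
        with pytest.warns(UserWarning, match="single sample"):
            summary = summarize_groups(small_dataset.subset_samples(keep),
                                       with_letters=False)
        assert summary.table.loc["16:0", (1, "sd")] == 0.0

    def test_formatted_table_shape(self, small_dataset):
        summary = summarize_groups(small_dataset)
        formatted = summary.formatted()
        assert list(formatted.index[:3]) == ["14:0", "16:0", "16:1"]
        assert list(formatted.index[-4:]) == ["SFA", "MUFA", "PUFA", "n3/n6"]
        assert formatted.shape[1] == 4
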