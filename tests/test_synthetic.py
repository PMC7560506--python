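"""Synthetic corpus and survey generators: determinism, exactness, calibration."""

from __future__ import annotations

import numpy as np
import pytest

from oneironet.corpus_io import Stratum
from oneironet.synthetic import (
    CorpusProfile,
    SurveyProfile,
    ThemeSpec,
    adjusted_rand_index,
    calibrate_copula,
    default_corpus_profile,
    default_survey_profile,
    default_theme_specs,
    generate_corpus,
    generate_paper_profile_corpus,
    generate_survey,
)


def corpus_stats(reports):
    def stratum(reports, s):
        return [r for r in reports if r.stratum == s]

    def tokens(rs):
        return sum(len(r.tokens) for r in rs)

    def types(rs):
        return len({t for r in rs for t in r.tokens})

    inc = stratum(reports, Stratum.INCREASED)
    ul = stratum(reports, Stratum.UNCHANGED_LOWERED)
    return {
        "total_tokens": tokens(reports), "total_types": types(reports),
        "tokens_increased": tokens(inc), "types_increased": types(inc),
        "tokens_unchanged_lowered": tokens(ul), "types_unchanged_lowered": types(ul),
    }


class TestThemeCorpus:
    def test_degenerate_full_theme_coverage(self):
        theme = ThemeSpec("only", ("w1", "w2", "w3"),
                          {"increased": 1.0, "unchanged_lowered": 1.0},
                          token_fraction=1.0)
        reports, planted = generate_corpus(
            [theme], reports_per_stratum=20, background_vocab_size=0, seed=0)
        assert all(set(r.tokens) <= {"w1", "w2", "w3"} for r in reports)
        assert planted == {"w1": "only", "w2": "only", "w3": "only"}

    def test_same_seed_identical_corpora(self):
        themes = default_theme_specs()
        a, _ = generate_corpus(themes, reports_per_stratum=30, seed=5)
        b, _ = generate_corpus(themes, reports_per_stratum=30, seed=5)
        assert a == b

    def test_different_seed_differs(self):
        themes = default_theme_specs()
        a, _ = generate_corpus(themes, reports_per_stratum=30, seed=5)
        b, _ = generate_corpus(themes, reports_per_stratum=30, seed=6)
        assert a != b

    def test_overlapping_theme_words_rejected(self):
        t1 = ThemeSpec("t1", ("shared", "x"), {"increased": 0.5})
        t2 = ThemeSpec("t2", ("shared", "y"), {"increased": 0.5})
        with pytest.raises(ValueError, match="overlap"):
            generate_corpus([t1, t2], reports_per_stratum=5, seed=0)

    def test_report_lengths_respect_distribution(self):
        reports, _ = generate_corpus(default_theme_specs(),
                                     reports_per_stratum=50,
                                     length_distribution=(3, 5), seed=2)
        assert all(3 <= len(r.tokens) <= 5 for r in reports)


class TestProfileCorpus:
    def test_default_profile_counts_are_exact(self):
        stats = corpus_stats(generate_paper_profile_corpus(seed=0))
        profile = default_corpus_profile()
        assert stats["total_tokens"] == profile.total_tokens == 4743
        assert stats["total_types"] == profile.total_types == 1095
        assert stats["tokens_increased"] == 3226
        assert stats["types_increased"] == 877
        assert stats["tokens_unchanged_lowered"] == 1514
        assert stats["types_unchanged_lowered"] == 589

    def test_seed_reproducibility(self):
        assert generate_paper_profile_corpus(seed=3) == generate_paper_profile_corpus(seed=3)

    def test_infeasible_profile_rejected(self):
        profile = CorpusProfile(tokens_increased=100, types_increased=200,
                                tokens_unchanged_lowered=1514,
                                total_tokens=100 + 1514 + 3)
        with pytest.raises(ValueError, match="types_increased"):
            generate_paper_profile_corpus(profile, seed=0)

    def test_shared_type_count_implied_by_totals(self):
        reports = generate_paper_profile_corpus(seed=1)
        inc_types = {t for r in reports if r.stratum == Stratum.INCREASED
                     for t in r.tokens}
        ul_types = {t for r in reports if r.stratum == Stratum.UNCHANGED_LOWERED
                    for t in r.tokens}
        assert len(inc_types & ul_types) == default_corpus_profile().shared_types == 371


class TestCopulaCalibration:
    STRESS = (0.221, 0.219, 0.380, 0.180)
    AWAKENINGS = (0.117, 0.597, 0.286)

    def test_target_zero_gives_latent_zero(self):
        assert calibrate_copula(0.0, self.STRESS, self.AWAKENINGS) == 0.0

    def test_latent_monotone_in_target(self):
        targets = [-0.4, -0.2, 0.1, 0.3, 0.5]
        latents = [calibrate_copula(t, self.STRESS, self.AWAKENINGS)
                   for t in targets]
        assert latents == sorted(latents)

    def test_unattainable_target_reports_range(self):
        with pytest.raises(ValueError, match="range"):
            calibrate_copula(0.999, self.STRESS, self.AWAKENINGS)


class TestSurveyGenerator:
    def test_same_seed_identical_records(self):
        a = generate_survey(seed=8)
        b = generate_survey(seed=8)
        assert a == b

    def test_independence_targets_give_near_zero_rho(self):
        """Zero targets: seed-averaged rho is within noise of zero."""
        from oneironet.group_stats import sleep_stress_associations

        profile = SurveyProfile(
            n=10_000,
            item_targets={k: 0.0 for k in default_survey_profile().item_targets},
        )
        rhos: dict[str, list[float]] = {}
        for seed in range(3):
            for assoc in sleep_stress_associations(generate_survey(profile, seed=seed)):
                rhos.setdefault(assoc.item, []).append(assoc.rho)
        for item, values in rhos.items():
            assert abs(np.mean(values)) < 0.03, item

    def test_marginals_converge_to_profile(self):
        """Seed-averaged category shares deviate < 1.5% from the profile."""
        profile = default_survey_profile()
        observed: dict[str, list[np.ndarray]] = {}
        for seed in range(5):
            records = generate_survey(profile, seed=seed)
            observed.setdefault("stress", []).append(
                np.bincount([r.stress_change for r in records], minlength=5)[1:]
                / len(records))
            for item in profile.item_marginals:
                observed.setdefault(item, []).append(
                    np.bincount([getattr(r, item) for r in records], minlength=4)[1:]
                    / len(records))
        for key, shares in observed.items():
            expected = np.asarray(profile.stress_marginals if key == "stress"
                                  else profile.item_marginals[key])
            expected = expected / expected.sum()
            assert np.abs(np.mean(shares, axis=0) - expected).max() < 0.015, key

    def test_ordinals_within_declared_ranges(self):
        records = generate_survey(SurveyProfile(n=500), seed=9)
        assert all(1 <= r.stress_change <= 4 for r in records)
        assert all(1 <= v <= 3 for r in records for v in r.sleep_items().values())


class TestAdjustedRandIndex:
    def test_identity_and_relabeling(self):
        p = {"a": 1, "b": 1, "c": 2, "d": 3}
        relabeled = {k: {1: "x", 2: "y", 3: "z"}[v] for k, v in p.items()}
        assert adjusted_rand_index(p, p) == 1.0
        assert adjusted_rand_index(p, relabeled) == 1.0

    def test_crossed_pairs_hand_value(self):
        a = {"a": 1, "b": 1, "c": 2, "d": 2}
        b = {"a": 1, "b": 2, "c": 1, "d": 2}
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5)

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index({"a": 1}, {"b": 1})

    def test_agrees_with_sklearn_on_random_partitions(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            nodes = [f"n{i}" for i in range(n)]
            pa = {v: int(rng.integers(0, 4)) for v in nodes}
            pb = {v: int(rng.integers(0, 4)) for v in nodes}
            if len(set(pa.values())) < 2 or len(set(pb.values())) < 2:
                continue
            expected = adjusted_rand_score([pa[v] for v in nodes],
                                           [pb[v] for v in nodes])
            assert adjusted_rand_index(pa, pb) == pytest.approx(expected, abs=1e-12)
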