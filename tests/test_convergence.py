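"""Signed-set overlap, PCA ordination and per-species activity tallies."""

import numpy as np
import pytest

from diapausemir import (
    CountSimConfig,
    SignedSet,
    ValidationError,
    pca_ordination,
    per_species_active_summary,
    signed_overlap,
    simulate_counts,
    size_factors,
)
from diapausemir.core import MatureArmCountMatrix, SampleMeta
from diapausemir.simulate import synthetic_catalog

from conftest import metadata_for_design


class TestSignedOverlap:
    def test_identical_sets_all_concordant(self):
        a = SignedSet("a", {"x", "y"}, {"z"})
        rep = signed_overlap(a, a, background=10)
        assert rep.n_concordant == 3 and rep.n_discordant == 0

    def test_opposed_sets_all_discordant(self):
        a = SignedSet("a", {"x", "y"}, set())
        b = SignedSet("b", set(), {"x", "y"})
        rep = signed_overlap(a, b, background=10)
        assert rep.n_concordant == 0 and rep.n_discordant == 2

    def test_counts_match_brute_force_and_symmetry(self):
        rng = np.random.default_rng(4)
        ids = [f"i{k}" for k in range(40)]
        for _ in range(10):
            pick = lambda: rng.choice(ids, size=rng.integers(0, 15), replace=False)
            au = set(pick()); ad = set(pick()) - au
            bu = set(pick()); bd = set(pick()) - bu
            a, b = SignedSet("a", au, ad), SignedSet("b", bu, bd)
            rep = signed_overlap(a, b, background=100)
            conc = len(au & bu) + len(ad & bd)
            disc = len(au & bd) + len(ad & bu)
            assert rep.n_concordant == conc and rep.n_discordant == disc
            rep2 = signed_overlap(b, a, background=100)
            assert rep2.n_concordant == conc and rep2.n_discordant == disc

    def test_small_background_rejected(self):
        a = SignedSet("a", {"x", "y"}, {"z"})
        with pytest.raises(ValidationError):
            signed_overlap(a, a, background=2)

    def test_up_down_must_be_disjoint(self):
        with pytest.raises(ValidationError):
            SignedSet("a", {"x"}, {"x"})


class TestPCA:
    def _counts(self, seed=0):
        cfg = CountSimConfig(n_loci=30, dispersion=0.05,
                             planted_dem_fraction=0.3, planted_lfc=2.5, seed=seed)
        return simulate_counts(cfg)

    def test_duplicated_sample_identical_scores(self):
        m, _, _ = self._counts()
        k = np.hstack([m.counts, m.counts[:, :1]])
        m2 = MatureArmCountMatrix(m.arm_ids, m.sample_ids + ["dup"], k)
        scores, _ = pca_ordination(m2, np.ones(k.shape[1]))
        np.testing.assert_allclose(
            scores.loc["dup"], scores.loc[m.sample_ids[0]], atol=1e-8
        )

    def test_variance_fractions_valid(self):
        m, _, _ = self._counts()
        _, var = pca_ordination(m, np.ones(len(m.sample_ids)))
        assert var.sum() <= 1 + 1e-9
        assert np.all(np.diff(var) <= 1e-12)

    def test_feature_permutation_invariance_up_to_sign(self):
        m, _, _ = self._counts()
        sf = np.ones(len(m.sample_ids))
        labels = m.row_labels()
        s1, _ = pca_ordination(m, sf, labels)
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(labels))
        s2, _ = pca_ordination(m, sf, perm)
        for k in range(2):
            col1, col2 = s1.iloc[:, k], s2.iloc[:, k]
            assert (np.allclose(col1, col2, atol=1e-8)
                    or np.allclose(col1, -col2, atol=1e-8))

    def test_planted_groups_separate(self):
        from sklearn.metrics import silhouette_score

        m, truth, design = self._counts(seed=42)
        sf = size_factors(m)
        dem = [f"{l}|{a}" for (l, a) in truth.dem_arm_ids]
        scores, _ = pca_ordination(m, sf, dem)
        labels = [1 if s in design.group_a else 0 for s in scores.index]
        sil = silhouette_score(scores.iloc[:, :2], labels)
        assert sil > 0.5

    def test_constant_matrix_rejected(self):
        m = MatureArmCountMatrix(
            [("l1", "5p"), ("l1", "3p")], ["s1", "s2"],
            np.array([[5, 5], [5, 5]]),
        )
        with pytest.raises(ValidationError):
            pca_ordination(m, np.ones(2))


class TestActiveSummary:
    def _setup(self):
        cat = synthetic_catalog(n_loci=6, seed=2)
        arm_ids = cat.arm_ids()
        meta = [
            SampleMeta("a1", "SpA", "africa_east", True, "diapause", 1),
            SampleMeta("a2", "SpA", "africa_east", True, "diapause", 2),
            SampleMeta("b1", "SpB", "africa_east", False, "normal_development", 1),
        ]
        return cat, arm_ids, meta

    def test_all_zero_counts_give_zero_summaries(self):
        cat, arm_ids, meta = self._setup()
        m = MatureArmCountMatrix(
            arm_ids, ["a1", "a2", "b1"],
            np.zeros((len(arm_ids), 3), dtype=int),
        )
        df = per_species_active_summary(m, meta, cat, np.ones(3))
        assert (df.active_total == 0).all()

    def test_species_specific_expression_tallied_once(self):
        cat, arm_ids, meta = self._setup()
        k = np.zeros((len(arm_ids), 3), dtype=int)
        k[0, 2] = 500  # only SpB expresses arm 0
        m = MatureArmCountMatrix(arm_ids, ["a1", "a2", "b1"], k)
        df = per_species_active_summary(m, meta, cat, np.ones(3)).set_index("species")
        assert df.loc["SpB", "active_total"] == 1
        assert df.loc["SpA", "active_total"] == 0

    def test_reference_difference_matches_set_arithmetic(self):
        cat, arm_ids, meta = self._setup()
        rng = np.random.default_rng(7)
        k = rng.integers(0, 60, size=(len(arm_ids), 3))
        m = MatureArmCountMatrix(arm_ids, ["a1", "a2", "b1"], k)
        sf = np.ones(3)
        df = per_species_active_summary(
            m, meta, cat, sf, reference_species="SpA"
        ).set_index("species")
        # brute force
        act_a = {i for i in range(len(arm_ids)) if k[i, :2].mean() > 10}
        act_b = {i for i in range(len(arm_ids)) if k[i, 2] > 10}
        assert df.loc["SpB", "active_not_in_reference"] == len(act_b - act_a)
        assert df.loc["SpB", "active_total"] == len(act_b)

    def test_unknown_reference_rejected(self):
        cat, arm_ids, meta = self._setup()
        m = MatureArmCountMatrix(
            arm_ids, ["a1", "a2", "b1"],
            np.zeros((len(arm_ids), 3), dtype=int),
        )
        with pytest.raises(ValidationError):
            per_species_active_summary(m, meta, cat, np.ones(3),
                                       reference_species="SpZ")
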