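import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicersite.io_formats import MatureAnnotation, SequenceRecord, ValidationError
from dicersite.pattern_engine import (
    CleavageSite,
    PatternConfig,
    PreMiRNA,
    build_dataset1,
    build_dataset2,
    cluster_redundancy,
    generate_patterns,
    infer_cleavage_sites,
    split_folds,
)
from tests.conftest import make_dataset


def hairpin(L, sites, seq_id="h"):
    rng = np.random.default_rng(L)
    seq = "".join(rng.choice(list("ACGU"), size=L))
    return PreMiRNA(seq_id, seq, "." * L,
                    sites=[CleavageSite(g, arm) for g, arm in sites])


def brute_force_patterns(L, s, sites):
    """Independent enumeration oracle: label every window directly."""
    out = []
    for a in range(1, L - s + 2):
        inside = [g for g in sites if a <= g <= a + s - 2]
        if len(inside) == 2:
            continue
        out.append((a, inside[0] - a + 1 if inside else 0))
    return out


class TestInferCleavageSites:
    def _hairpin(self, L=80):
        return hairpin(L, [])

    def test_let7a_geometry(self):
        p = self._hairpin(80)
        anns = [MatureAnnotation("h", "5p", 6, 27),
                MatureAnnotation("h", "3p", 50, 71)]
        sites = infer_cleavage_sites(p, anns)
        assert [(s.interval, s.arm) for s in sites] == [(27, "5p"), (49, "3p")]

    def test_5p_mature_ending_at_L_rejected(self):
        p = self._hairpin(60)
        anns = [MatureAnnotation("h", "5p", 39, 60),
                MatureAnnotation("h", "3p", 30, 50)]
        with pytest.raises(ValidationError):
            infer_cleavage_sites(p, anns)

    def test_coincident_sites_rejected(self):
        p = self._hairpin(60)
        anns = [MatureAnnotation("h", "5p", 1, 22),
                MatureAnnotation("h", "3p", 23, 44)]
        with pytest.raises(ValidationError, match="upstream"):
            infer_cleavage_sites(p, anns)

    def test_incomplete_annotation_rejected(self):
        p = self._hairpin(60)
        with pytest.raises(ValidationError, match="incomplete"):
            infer_cleavage_sites(p, [MatureAnnotation("h", "5p", 1, 22)])


class TestGeneratePatterns:
    def test_two_site_80nt_counts(self, two_site_hairpin):
        """The 80-nt fixture yields 67 windows, 26 of them positive."""
        pats = generate_patterns(two_site_hairpin, PatternConfig(s=14))
        labels = [p.label for p in pats]
        assert len(pats) == 67
        assert sum(1 for l in labels if l > 0) == 26

    def test_close_sites_drop_two_site_windows(self):
        p = hairpin(30, [(14, "5p"), (16, "3p")])
        pats = generate_patterns(p, PatternConfig(s=14))
        expected = brute_force_patterns(30, 14, [14, 16])
        assert len(pats) == 6  # 17 windows - 11 spanning both sites
        assert [(q.window_start, q.label) for q in pats] == expected

    def test_window_content_matches_parent(self, two_site_hairpin):
        for q in generate_patterns(two_site_hairpin, PatternConfig(s=14)):
            a = q.window_start
            assert q.pattern_seq == two_site_hairpin.sequence[a - 1:a + 13]
            assert q.pattern_struct == two_site_hairpin.structure[a - 1:a + 13]

    def test_label_reconstructs_site(self, two_site_hairpin):
        sites = {s.interval for s in two_site_hairpin.sites}
        for q in generate_patterns(two_site_hairpin, PatternConfig(s=14)):
            if q.label > 0:
                assert q.window_start + q.label - 1 in sites

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(30, 120), st.integers(4, 18), st.data())
    def test_agrees_with_bruteforce_oracle(self, L, s, data):
        g1 = data.draw(st.integers(1, L - 2))
        g2 = data.draw(st.integers(g1 + 1, L - 1))
        p = hairpin(L, [(g1, "5p"), (g2, "3p")])
        pats = generate_patterns(p, PatternConfig(s=s))
        assert [(q.window_start, q.label) for q in pats] == \
            brute_force_patterns(L, s, [g1, g2])

    def test_interior_single_site_positives(self):
        """One interior site yields s-1 = 13 positive 14-nt patterns."""
        p = hairpin(60, [(30, "5p")])
        pats = generate_patterns(p, PatternConfig(s=14))
        assert sum(1 for q in pats if q.label > 0) == 13
        assert len(pats) == 47  # no second site -> nothing removed


class TestDatasetConstruction:
    def _corpus(self, n=6):
        return [hairpin(80, [(27, "5p"), (49, "3p")], seq_id=f"h{i}")
                for i in range(n)]

    def test_dataset1_counts_and_determinism(self):
        corpus = self._corpus()
        cfg = PatternConfig(s=14)
        d1 = build_dataset1(corpus, cfg, n_neg=10, seed=7)
        labels = d1.labels
        assert (labels > 0).sum() == 26 * 6
        assert (labels == 0).sum() == 10
        d1b = build_dataset1(corpus, cfg, n_neg=10, seed=7)
        assert d1 == d1b

    def test_dataset1_seed_changes_sample(self):
        corpus = self._corpus()
        cfg = PatternConfig(s=14)
        ids = lambda d: {(p.premirna_id, p.window_start)
                         for p in d.samples if p.label == 0}
        assert ids(build_dataset1(corpus, cfg, n_neg=10, seed=1)) != \
            ids(build_dataset1(corpus, cfg, n_neg=10, seed=2))

    def test_dataset1_short_negatives_warns(self):
        corpus = self._corpus(1)
        with pytest.warns(UserWarning, match="negative"):
            d = build_dataset1(corpus, PatternConfig(s=14), n_neg=10**6, seed=0)
        assert (d.labels == 0).sum() == 67 - 26

    def test_dataset1_zero_negatives(self):
        d = build_dataset1(self._corpus(2), PatternConfig(s=14), n_neg=0, seed=0)
        assert (d.labels == 0).sum() == 0

    def test_dataset2_two_negatives_per_hairpin(self):
        corpus = self._corpus(3)
        d = build_dataset2(corpus, PatternConfig(s=14), seed=0)
        assert (d.labels == 0).sum() == 2 * 3
        assert (d.labels > 0).sum() == 26 * 3

    def test_dataset2_hairpin_without_enough_negatives_warns(self):
        # L=20, s=10, sites at 5 and 14: every window holds exactly one site
        p = hairpin(20, [(5, "5p"), (14, "3p")])
        only_pos = [q for q in generate_patterns(p, PatternConfig(s=10))]
        assert all(q.label > 0 for q in only_pos)
        with pytest.warns(UserWarning, match="negative"):
            d = build_dataset2([p], PatternConfig(s=10), seed=0)
        assert (d.labels == 0).sum() == 0


class TestSplitFolds:
    def test_equal_sizes(self):
        ds = make_dataset([0] * 10)
        out = split_folds(ds, k=5, seed=0)
        assert sorted(np.bincount(out.folds).tolist()) == [2] * 5

    def test_near_equal_sizes(self):
        ds = make_dataset([0] * 11)
        out = split_folds(ds, k=5, seed=0)
        assert sorted(np.bincount(out.folds).tolist()) == [2, 2, 2, 2, 3]

    def test_deterministic(self):
        ds = make_dataset([0] * 23)
        a = split_folds(ds, k=5, seed=9).folds
        b = split_folds(ds, k=5, seed=9).folds
        assert np.array_equal(a, b)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValidationError):
            split_folds(make_dataset([0] * 4), k=1, seed=0)

    def test_group_by_premirna_keeps_hairpins_together(self):
        ds = make_dataset([0] * 30, premirna_ids=[f"h{i % 6}" for i in range(30)])
        out = split_folds(ds, k=3, seed=0, group_by_premirna=True)
        for pid in {p.premirna_id for p in out.samples}:
            idx = [i for i, p in enumerate(out.samples) if p.premirna_id == pid]
            assert len({out.folds[i] for i in idx}) == 1


class TestClusterRedundancy:
    def test_identical_sequences_collapse(self):
        seq = "ACGUACGUACGUACGUACGU"
        recs = [SequenceRecord("a", seq), SequenceRecord("b", seq)]
        assert len(cluster_redundancy(recs)) == 1

    def test_disjoint_sequences_stay(self):
        recs = [SequenceRecord("a", "ACACACACACACACACAC"),
                SequenceRecord("b", "GUGUGUGUGUGUGUGUGU")]
        assert len(cluster_redundancy(recs, threshold=0.8)) == 2

    def test_near_duplicates_collapse(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGU"), size=80))
        variant = base[:70] + "A" * 10  # 70/80 shared prefix
        recs = [SequenceRecord("a", base), SequenceRecord("b", variant),
                SequenceRecord("c", "".join(rng.choice(list("ACGU"), size=80)))]
        reps = cluster_redundancy(recs, threshold=0.6)
        assert {r.id for r in reps} == {"a", "c"}

    def test_threshold_validated(self):
        with pytest.raises(ValidationError):
            cluster_redundancy([SequenceRecord("a", "ACGU" * 5)], threshold=0.3)

    def test_missing_external_tool_errors(self):
        with pytest.raises(ValidationError, match="not found"):
            cluster_redundancy([SequenceRecord("a", "ACGU" * 5)],
                               cdhit_path="definitely-not-a-binary")
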