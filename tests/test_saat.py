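"""SAAT family construction: tag similarity, single linkage, profiles."""

import numpy as np
import pandas as pd
import pytest

from deepsage.saat import (
    build_families,
    family_profile,
    import_similarity_pairs,
    similar_hit_histogram,
    tag_identity,
)

# published AGP-family tag sequences used as worked similarity examples
STCA_17544 = "CATGTAATGTAATATCGTTGTGATTT"
STCA_17547 = "CATGTAATGTAATATTGTTGAATGAA"
STCA_17548 = "CATGTAATGTAATATTGTTGTGAAAA"
STCA_17550 = "CATGTAATGTAATATTGTTGTGATTT"


class TestTagIdentity:
    def test_identical_tags(self):
        assert tag_identity(STCA_17548, STCA_17548) == 26

    def test_three_mismatches_meet_threshold(self):
        assert tag_identity(STCA_17548, STCA_17550) == 23

    def test_four_mismatches_fall_below_threshold(self):
        assert tag_identity(STCA_17547, STCA_17548) == 22

    def test_symmetry(self):
        assert tag_identity(STCA_17544, STCA_17550) == tag_identity(
            STCA_17550, STCA_17544
        )


def _mutate(tag: str, positions: dict[int, str]) -> str:
    chars = list(tag)
    for pos, base in positions.items():  # 1-based positions
        chars[pos - 1] = base
    return "".join(chars)


class TestBuildFamilies:
    def test_single_mismatch_pair_clusters(self):
        fams = build_families({"a": STCA_17544, "b": STCA_17550})
        assert tag_identity(STCA_17544, STCA_17550) == 25
        assert len(fams) == 1 and sorted(fams[0].members) == ["a", "b"]

    def test_identity_22_splits(self):
        fams = build_families({"a": STCA_17547, "b": STCA_17548})
        assert len(fams) == 2

    def test_single_linkage_chain(self):
        base = "CATG" + "ACGTTGCAACGTTGCAACGTTG"
        b = _mutate(base, {5: "G", 6: "A", 7: "A"})      # A-B identity 23
        c = _mutate(b, {10: "C", 11: "A", 12: "T"})      # B-C identity 23
        assert tag_identity(base, c) == 20               # A-C below threshold
        fams = build_families({"A": base, "B": b, "C": c})
        assert len(fams) == 1 and len(fams[0]) == 3

    def test_partition_covers_every_tag_once(self, small_scene):
        scene, _, _ = small_scene
        tags = {f"t{i}": s for i, s in enumerate(scene.truth.tags)}
        fams = build_families(tags)
        seen = [m for f in fams for m in f.members]
        assert sorted(seen) == sorted(tags)

    def test_partition_is_order_invariant(self):
        rng = np.random.default_rng(3)
        tags = {
            "a": STCA_17544, "b": STCA_17550, "c": STCA_17548,
            "d": STCA_17547, "e": "CATGCTTGTTATAGTTAGCCTTTCTC",
        }
        reference = {frozenset(f.members) for f in build_families(tags)}
        for _ in range(5):
            keys = list(tags)
            rng.shuffle(keys)
            shuffled = {k: tags[k] for k in keys}
            assert {frozenset(f.members) for f in build_families(shuffled)} == reference

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            build_families({"a": STCA_17548}, threshold_identity=0)
        with pytest.raises(ValueError):
            build_families({"a": STCA_17548}, threshold_identity=27)

    def test_snp_positions_exclude_anchor(self, small_scene):
        scene, _, _ = small_scene
        tags = {f"t{i}": s for i, s in enumerate(scene.truth.tags)}
        for fam in build_families(tags):
            assert all(5 <= p <= 26 for p in fam.snp_positions)

    def test_representative_prefers_abundance(self):
        tags = {"a": STCA_17544, "b": STCA_17550}
        fams = build_families(tags, abundance={"a": 1.0, "b": 50.0})
        assert fams[0].representative == "b"

    def test_similar_hit_histogram_percentages(self):
        fams = build_families(
            {"a": STCA_17544, "b": STCA_17550, "e": "CATGCTTGTTATAGTTAGCCTTTCTC"}
        )
        hist = similar_hit_histogram(fams)
        assert hist["n_unitags"].sum() == 3
        assert hist["percent"].sum() == pytest.approx(100.0)


class TestFamilyProfile:
    def _profile(self, sums):
        return pd.DataFrame({"lib": sums})

    def test_singleton_share_is_one(self):
        fams = build_families({"a": STCA_17548})
        summary = family_profile(fams[0], self._profile({"a": 42.0}))
        assert summary["representative_share"] == pytest.approx(1.0)

    def test_share_arithmetic(self):
        fams = build_families(
            {"a": STCA_17550, "b": STCA_17544, "c": _mutate(STCA_17550, {20: "A"})},
            abundance={"a": 100.0, "b": 10.0, "c": 5.0},
        )
        profile = self._profile({"a": 100.0, "b": 10.0, "c": 5.0})
        summary = family_profile(fams[0], profile)
        assert summary["representative"] == "a"
        assert summary["representative_share"] == pytest.approx(100 / 115)

    def test_dominant_isoform_recovered(self, small_scene, small_matrix):
        """The most abundant member of a planted family becomes its representative."""
        from deepsage.profiles import normalize

        scene, _, _ = small_scene
        profile = normalize(small_matrix)
        seq_to_uid = {s: u for u, s in small_matrix.sequences.items()}
        totals = profile.sum(axis=1)
        for members in scene.truth.families:
            uids = [seq_to_uid[m] for m in members if m in seq_to_uid]
            if len(uids) < 2:
                continue
            fams = build_families(
                {u: small_matrix.sequences[u] for u in uids},
                abundance=totals[uids].to_dict(),
            )
            top = max(uids, key=lambda u: (totals[u], small_matrix.sequences[u]))
            best = totals[uids].max()
            contenders = [u for u in uids if totals[u] == best]
            expected = min(contenders, key=lambda u: small_matrix.sequences[u])
            assert fams[0].representative == expected
            break


class TestImportSimilarityPairs:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert import_similarity_pairs(path) == set()

    def test_matched_bases_gate(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "t1\tt2\t96.15\t26\t1\t0\t1\t26\t1\t26\t1e-9\t50\n"  # 25 matched
            "t3\tt4\t84.6\t26\t4\t0\t1\t26\t1\t26\t1e-5\t40\n"   # 22 matched
        )
        links = import_similarity_pairs(path)
        assert links == {("t1", "t2")}

    def test_self_hit_discarded(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("t1\tt1\t100\t26\t0\t0\t1\t26\t1\t26\t1e-12\t52\n")
        assert import_similarity_pairs(path) == set()

    def test_malformed_rows_respect_error_budget(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(["bad row"] * 12) + "\n")
        with pytest.raises(ValueError):
            import_similarity_pairs(path, max_errors=5)


def test_planted_families_recovered(small_scene):
    """Single-linkage clustering recovers the generator's family partition."""
    scene, _, _ = small_scene
    tags = {s: s for s in scene.truth.tags}
    fams = build_families(tags)
    predicted = {frozenset(f.members) for f in fams if len(f) > 1}
    truth = {frozenset(m) for m in scene.truth.families if len(m) > 1}
    assert predicted == truth
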