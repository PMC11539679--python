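"""Periodic encoding generator, fusion, decoding, and dataset assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resuskit import (
    AnnotationRecord,
    Episode,
    allowed_values,
    build_dataset,
    decode_value,
    encode_episode,
    fuse,
    generator_code,
    project_to_allowed,
    summarize_dataset,
)
from resuskit.encoding import FusedMatrix


class TestGeneratorCode:
    @pytest.mark.parametrize(
        "i,expected", [(1, 1), (2, 3), (6, 63), (7, 127), (16, 65535)]
    )
    def test_values(self, i, expected):
        assert generator_code(i) == expected

    @pytest.mark.parametrize("i", [0, -1, 17])
    def test_out_of_range(self, i):
        with pytest.raises(ValueError):
            generator_code(i)

    def test_superincreasing(self):
        # each code strictly exceeds the sum of all smaller ones
        for i in range(2, 17):
            assert generator_code(i) > sum(generator_code(k) for k in range(1, i))


class TestEncodeEpisode:
    def test_worked_example_rows(self, table3_episode, sus4_profile):
        cm = encode_episode(table3_episode, sus4_profile, n_seconds=10)
        assert cm.values[0].tolist() == [1, 1, 1, 1, 1, 1, 1, 1, 1, 0]
        assert cm.values[1].tolist() == [3, 3, 3, 0, 0, 0, 0, 0, 0, 0]
        assert cm.values[2].tolist() == [0, 0, 0, 7, 7, 7, 7, 0, 0, 0]
        assert cm.values[3].tolist() == [0, 0, 0, 0, 15, 15, 15, 15, 15, 0]

    def test_empty_episode_is_all_zero(self, sus4_profile):
        cm = encode_episode(Episode("e", []), sus4_profile, n_seconds=10)
        assert not cm.values.any()

    def test_same_activity_overlap_collapses_to_presence(self, sus4_profile):
        ep = Episode(
            "ov",
            [
                AnnotationRecord("stimulation", 3000, 5000, 2000),
                AnnotationRecord("stimulation", 4000, 7000, 3000),
            ],
        )
        cm = encode_episode(ep, sus4_profile, n_seconds=10)
        assert cm.values[2, 4] == 7  # second 5: presence, never 14
        assert cm.values[2].tolist() == [0, 0, 0, 7, 7, 7, 7, 0, 0, 0]

    def test_partial_second_overlap_marks_whole_bin(self, sus4_profile):
        ep = Episode("p", [AnnotationRecord("drying", 1500, 1600, 100)])
        cm = encode_episode(ep, sus4_profile, n_seconds=3)
        assert cm.values[1].tolist() == [0, 3, 0]

    def test_truncation_and_origin_clipping(self, sus4_profile):
        ep = Episode("t", [AnnotationRecord("drying", 0, 20_000, 20_000)])
        cm = encode_episode(ep, sus4_profile, n_seconds=5, origin_ms=17_000)
        # origin shifts time zero: remaining 3 s of the record occupy bins 1-3
        assert cm.values[1].tolist() == [3, 3, 3, 0, 0]

    def test_invalid_horizon(self, table3_episode, sus4_profile):
        with pytest.raises(ValueError):
            encode_episode(table3_episode, sus4_profile, n_seconds=0)


class TestFuse:
    def test_worked_example_fusion(self, table3_fused):
        assert table3_fused.tolist() == [4, 4, 4, 8, 23, 23, 23, 16, 16, 0]

    def test_single_activity_fusion_is_identity(self, sus4_profile):
        ep = Episode("v", [AnnotationRecord("ventilation", 0, 4000, 4000)])
        cm = encode_episode(ep, sus4_profile, n_seconds=10)
        assert np.array_equal(fuse(cm), cm.values[3])

    def test_fuse_linear_over_rows(self, table3_episode, sus4_profile):
        cm = encode_episode(table3_episode, sus4_profile, n_seconds=10)
        assert np.array_equal(fuse(cm), cm.values.sum(axis=0))


class TestAllowedValues:
    @pytest.mark.parametrize(
        "H,expected",
        [(1, [0, 1]), (2, [0, 1, 3, 4])],
    )
    def test_small_sets(self, H, expected):
        assert allowed_values(H).tolist() == expected

    def test_h7_count_and_max(self):
        av = allowed_values(7)
        assert av.size == 128
        assert av[-1] == 247  # sum(2**i - 1, i=1..7) = 254 - 7 = 1+3+7+15+31+63+127

    @pytest.mark.parametrize("H", range(1, 11))
    def test_no_subset_sum_collisions(self, H):
        # independent brute-force enumeration over all 2**H subsets
        sums = [
            sum(c)
            for r in range(H + 1)
            for c in itertools.combinations([2**i - 1 for i in range(1, H + 1)], r)
        ]
        assert len(sums) == 2**H
        assert len(set(sums)) == 2**H
        assert sorted(sums) == allowed_values(H).tolist()


class TestDecodeValue:
    def test_worked_example_combination(self):
        # seconds 5-7 of the worked example: table + stimulation + ventilation
        assert decode_value(23, 6) == {1, 3, 4}

    def test_zero_decodes_to_empty_set(self):
        assert decode_value(0, 6) == frozenset()

    def test_decode_inverts_subset_sum_exhaustively(self):
        for v in allowed_values(7):
            members = decode_value(int(v), 7)
            assert sum(generator_code(i) for i in members) == v

    @pytest.mark.parametrize("v", [2, 5, 249, -1])
    def test_non_allowed_value_rejected(self, v):
        with pytest.raises(ValueError):
            decode_value(v, 7)


class TestProjectToAllowed:
    @pytest.mark.parametrize(
        "v,H,expected",
        [
            (23.4, 6, 23),
            (5.5, 4, 4),  # equidistant between 4 and 7: tie breaks downward
            (-2.0, 6, 0),
            (1e6, 6, 120),
        ],
    )
    def test_projection(self, v, H, expected):
        assert project_to_allowed(v, H) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-10, 300, allow_nan=False), st.integers(1, 8))
    def test_idempotent_and_identity_on_allowed(self, v, H):
        p = project_to_allowed(v, H)
        assert p in allowed_values(H)
        assert project_to_allowed(float(p), H) == p

    def test_vectorized_projection(self):
        out = project_to_allowed(np.array([[0.2, 22.6], [100.0, -3.0]]), 6)
        assert out.tolist() == [[0, 23], [101, 0]]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            project_to_allowed(float("nan"), 6)


class TestBuildDataset:
    def test_single_episode_padded(self, table3_episode, sus4_profile, table3_fused):
        tensor, fused = build_dataset([table3_episode], sus4_profile, n_seconds=720)
        assert tensor.values.shape == (4, 720, 1)
        assert fused.values.shape == (720, 1)
        assert fused.values[:10, 0].tolist() == table3_fused.tolist()
        assert not fused.values[10:, 0].any()

    def test_identical_episodes_identical_columns(self, table3_episode, sus4_profile):
        _, fused = build_dataset([table3_episode] * 3, sus4_profile, n_seconds=20)
        assert np.array_equal(fused.values[:, 0], fused.values[:, 1])
        assert np.array_equal(fused.values[:, 0], fused.values[:, 2])

    def test_all_entries_are_allowed_values(self, small_haydom_dataset):
        cfg, episodes, _, _ = small_haydom_dataset
        _, fused = build_dataset(episodes, cfg.profile, n_seconds=cfg.n_seconds)
        allowed = set(allowed_values(cfg.profile.H).tolist())
        assert set(np.unique(fused.values).tolist()) <= allowed

    def test_permuting_episodes_permutes_columns(self, small_haydom_dataset):
        cfg, episodes, _, _ = small_haydom_dataset
        _, fused = build_dataset(episodes, cfg.profile, n_seconds=cfg.n_seconds)
        perm = list(reversed(range(len(episodes))))
        _, fused_p = build_dataset(
            [episodes[i] for i in perm], cfg.profile, n_seconds=cfg.n_seconds
        )
        assert np.array_equal(fused_p.values, fused.values[:, perm])
        assert fused_p.episode_ids == [fused.episode_ids[i] for i in perm]

    def test_empty_dataset_rejected(self, sus4_profile):
        with pytest.raises(ValueError):
            build_dataset([], sus4_profile)

    def test_fused_matrix_csv_round_trip(self, small_haydom_dataset, tmp_path):
        cfg, episodes, _, _ = small_haydom_dataset
        _, fused = build_dataset(episodes, cfg.profile, n_seconds=cfg.n_seconds)
        fused.to_csv(tmp_path / "fused.csv")
        back = FusedMatrix.from_csv(tmp_path / "fused.csv", cfg.profile)
        assert np.array_equal(back.values, fused.values)
        assert back.episode_ids == fused.episode_ids


class TestSummarize:
    def test_worked_example_summary(self, table3_episode, sus4_profile):
        table = summarize_dataset([table3_episode], sus4_profile)
        row = table.set_index("activity")
        assert row.loc["stimulation", "n_records"] == 1
        assert row.loc["stimulation", "total_duration_s"] == 4
        assert row.loc["ventilation", "total_duration_s"] == 5
        assert table.attrs["n_files"] == 1

    def test_empty_dataset_all_zero(self, sus4_profile):
        table = summarize_dataset([], sus4_profile)
        assert (table["n_records"] == 0).all()
        assert table.attrs["total_duration_s"] == 0

    def test_summary_matches_generator_bookkeeping(self, small_haydom_dataset):
        cfg, episodes, _, bookkeeping = small_haydom_dataset
        table = summarize_dataset(episodes, cfg.profile).set_index("activity")
        for activity in cfg.profile.activities:
            n = sum(
                b["activities"].get(activity, {}).get("n_records", 0)
                for b in bookkeeping.values()
            )
            total_ms = sum(
                b["activities"].get(activity, {}).get("total_duration_ms", 0)
                for b in bookkeeping.values()
            )
            assert table.loc[activity, "n_records"] == n
            assert table.loc[activity, "total_duration_s"] == int(round(total_ms / 1000))
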