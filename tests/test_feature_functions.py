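import numpy as np
import pytest

from conftest import random_record
from naive_features import naive_feature
from x3dis.feature_functions import (
    FeatureFunctionSpec,
    compute_feature,
    compute_feature_block,
    enumerate_default_candidates,
    featurize,
    reduced_candidate_grid,
)
from x3dis.protein_model import ProteinRecord, one_hot_track


def spec_of(family, annotation=None, window=None):
    return FeatureFunctionSpec(family, annotation, window)


class TestSpec:
    def test_dimensionalities(self):
        cases = {
            spec_of("num_residues"): 1,
            spec_of("unnorm_global_hist"): 20,
            spec_of("labels_global_hist", "ss3"): 3,
            spec_of("labels_local_hist", "sa", 10): 3,
            spec_of("labels_local_window", "pssm", 5): 105,
            spec_of("separation_profile_window", "sa", 11): 22,
            spec_of("labeled_segments_window", "ss3", 5): 20,
            spec_of("dimeric_global_hist", "ss3"): 9,
            spec_of("dimeric_local_hist", "sa", 5): 4,
        }
        for spec, d in cases.items():
            assert spec.d == d, str(spec)

    def test_string_roundtrip(self):
        for spec in enumerate_default_candidates():
            assert FeatureFunctionSpec.parse(str(spec)) == spec

    def test_even_window_rejected_for_centred_families(self):
        with pytest.raises(ValueError, match="odd"):
            spec_of("labels_local_window", "sa", 4)
        # local histograms follow the published even-size grid
        spec_of("labels_local_hist", "sa", 10)

    def test_annotation_required_iff_annotation_family(self):
        with pytest.raises(ValueError):
            spec_of("num_residues", "sa")
        with pytest.raises(ValueError):
            spec_of("labels_global_hist")


class TestDefaultGrid:
    def test_grid_size_matches_candidate_count(self):
        grid = enumerate_default_candidates()
        assert len(grid) == 109  # 5 sequence-level + 4 annotations x 26

    def test_grid_slice_per_family(self):
        grid = enumerate_default_candidates()
        sep_sa = [
            s for s in grid
            if s.family == "separation_profile_window" and s.annotation == "sa"
        ]
        assert sorted(s.window for s in sep_sa) == [1, 5, 11, 15, 21]

    def test_segments_excluded_but_constructible(self):
        grid = enumerate_default_candidates()
        assert not any(s.family == "labeled_segments_window" for s in grid)
        assert spec_of("labeled_segments_window", "ss3", 5).d == 20

    def test_reduced_grid_size(self):
        assert len(reduced_candidate_grid()) == 20


class TestHandWorkedExamples:
    def test_sequence_scalars(self):
        rec = ProteinRecord(id="p", sequence="ACCDC")
        assert compute_feature(spec_of("num_cysteines"), rec, 2) == [3.0]
        rec100 = ProteinRecord(id="q", sequence="A" * 100)
        assert compute_feature(spec_of("position"), rec100, 1) == [1.0]
        assert compute_feature(spec_of("relative_position"), rec100, 1) == [0.01]

    def test_unnorm_global_hist(self):
        rec = ProteinRecord(id="p", sequence="AAG")
        v = compute_feature(spec_of("unnorm_global_hist"), rec, 1)
        assert v[0] == 2 and v[5] == 1 and v.sum() == 3

    def test_labels_global_hist_ss3(self):
        rec = ProteinRecord(id="p", sequence="AAAA")
        rec.tracks["ss3"] = one_hot_track("ss3", "HHEC")
        v = compute_feature(spec_of("labels_global_hist", "ss3"), rec, 1)
        np.testing.assert_allclose(v, [0.5, 0.25, 0.25])

    def test_labels_local_hist_interior_and_oob(self):
        rec = ProteinRecord(id="p", sequence="AAAAA")
        rec.tracks["ss3"] = one_hot_track("ss3", "CCCCC")
        v = compute_feature(spec_of("labels_local_hist", "ss3", 5), rec, 3)
        np.testing.assert_allclose(v, [0, 0, 1, 0])
        rec10 = ProteinRecord(id="q", sequence="A" * 10)
        rec10.tracks["ss3"] = one_hot_track("ss3", "C" * 10)
        v = compute_feature(spec_of("labels_local_hist", "ss3", 5), rec10, 1)
        assert v[-1] == pytest.approx(0.4)  # offsets -2, -1 out of bounds

    def test_labels_local_window_padding(self):
        rec = ProteinRecord(id="p", sequence="AAA")
        rec.tracks["ss3"] = one_hot_track("ss3", "HEC")
        v = compute_feature(spec_of("labels_local_window", "ss3", 3), rec, 2)
        np.testing.assert_allclose(v, [1, 0, 0, 0, 1, 0, 0, 0, 1])
        v = compute_feature(spec_of("labels_local_window", "ss3", 5), rec, 1)
        np.testing.assert_allclose(v[:6], 0)  # offsets -2, -1 padded with zeros

    def test_separation_profile_worked_example(self):
        rec = ProteinRecord(id="p", sequence="AAAAAAAAA")
        rec.tracks["sa"] = one_hot_track("sa", "EBBEEBEBB")
        v = compute_feature(spec_of("separation_profile_window", "sa", 5), rec, 5)
        np.testing.assert_allclose(v[:5], [3, 2, 1, 1, 3])  # label B block
        np.testing.assert_allclose(v[5:], [4, 1, 0, 2, 2])  # label E block

    def test_separation_profile_uniform_label(self):
        n, K = 15, 2
        rec = ProteinRecord(id="p", sequence="A" * n)
        rec.tracks["sa"] = one_hot_track("sa", "B" * n)
        v = compute_feature(spec_of("separation_profile_window", "sa", 5), rec, 8)
        np.testing.assert_allclose(v[:5], [K, K - 1, 0, 1, K])
        # E never occurs: all slots fall back to n
        np.testing.assert_allclose(v[5:], n)

    def test_labeled_segments_worked_example(self):
        rec = ProteinRecord(id="p", sequence="AAAAAAA")
        rec.tracks["ss3"] = one_hot_track("ss3", "HHHCCEE")
        v = compute_feature(spec_of("labeled_segments_window", "ss3", 3), rec, 4)
        np.testing.assert_allclose(
            v, [1, 0, 0, 3, 0, 0, 1, 2, 0, 1, 0, 2]
        )  # H-segment len 3, C-segment len 2, E-segment len 2

    def test_dimeric_global_hand_count(self):
        rec = ProteinRecord(id="p", sequence="AAAA")
        rec.tracks["sa"] = one_hot_track("sa", "EBEB")
        v = compute_feature(spec_of("dimeric_global_hist", "sa"), rec, 1)
        # pairs: EB, BE, EB -> freq(E,B)=2/3 at index (1,0), freq(B,E)=1/3
        np.testing.assert_allclose(v, [0, 1 / 3, 2 / 3, 0])

    def test_dimeric_local_boundary(self):
        rec = ProteinRecord(id="p", sequence="A" * 10)
        rec.tracks["sa"] = one_hot_track("sa", "B" * 10)
        v = compute_feature(spec_of("dimeric_local_hist", "sa", 5), rec, 1)
        # only pairs (1,2), (2,3) in bounds, denominator W-1 = 4
        np.testing.assert_allclose(v, [2 / 4, 0, 0, 0])
        v = compute_feature(spec_of("dimeric_local_hist", "sa", 1), rec, 5)
        np.testing.assert_allclose(v, 0)


ORACLE_SPECS = [
    spec_of("num_residues"),
    spec_of("num_cysteines"),
    spec_of("unnorm_global_hist"),
    spec_of("position"),
    spec_of("relative_position"),
] + [
    spec_of(fam, ann, W)
    for ann in ("aa", "pssm", "ss3", "sa")
    for fam, Ws in [
        ("labels_global_hist", [None]),
        ("labels_local_hist", [1, 5, 10, 30]),
        ("labels_local_window", [1, 5, 11]),
        ("separation_profile_window", [1, 5, 11]),
        ("labeled_segments_window", [1, 5, 11]),
        ("dimeric_global_hist", [None]),
        ("dimeric_local_hist", [1, 5, 11]),
    ]
    for W in Ws
]


ALL_FAMILIES = [
    ("num_residues", [None]),
    ("num_cysteines", [None]),
    ("unnorm_global_hist", [None]),
    ("position", [None]),
    ("relative_position", [None]),
    ("labels_global_hist", [None]),
    ("labels_local_hist", [1, 5, 10, 30]),
    ("labels_local_window", [1, 5, 11]),
    ("separation_profile_window", [1, 5, 11]),
    ("labeled_segments_window", [1, 5, 11]),
    ("dimeric_global_hist", [None]),
    ("dimeric_local_hist", [1, 5, 11]),
]


def test_all_families_match_naive_oracle(rng):
    """All 12 families agree exactly with a brute-force reference on >= 200
    random annotated (protein, position) pairs, rotating annotations and
    window sizes."""
    annotations = ("aa", "pssm", "ss3", "sa")
    pairs = 0
    for r in range(50):
        rec = random_record(rng)
        for i in rng.integers(1, rec.n + 1, size=4):
            i = int(i)
            for fam, windows in ALL_FAMILIES:
                W = windows[(pairs + r) % len(windows)]
                ann = (
                    None
                    if fam in ("num_residues", "num_cysteines",
                               "unnorm_global_hist", "position",
                               "relative_position")
                    else annotations[pairs % 4]
                )
                spec = FeatureFunctionSpec(fam, ann, W)
                expected = np.asarray(naive_feature(spec, rec, i), dtype=float)
                got = compute_feature(spec, rec, i)
                np.testing.assert_allclose(
                    got, expected, atol=1e-12, err_msg=f"{spec} at {i} (n={rec.n})"
                )
                np.testing.assert_allclose(
                    compute_feature_block(spec, rec)[i - 1], expected, atol=1e-12,
                    err_msg=f"block {spec} at {i} (n={rec.n})",
                )
            pairs += 1
    assert pairs >= 200


def test_translation_invariance_on_uniform_context(rng):
    """Windowed features are identical for all interior positions of a long
    uniform-label track."""
    n = 60
    rec = ProteinRecord(id="p", sequence="A" * n)
    rec.tracks["ss3"] = one_hot_track("ss3", "H" * n)
    for fam, W in [
        ("labels_local_hist", 5),
        ("labels_local_window", 5),
        ("separation_profile_window", 5),
        ("dimeric_local_hist", 5),
    ]:
        spec = spec_of(fam, "ss3", W)
        block = compute_feature_block(spec, rec)
        interior = block[20:40]
        assert (interior == interior[0]).all(), fam


def test_separation_profile_slot_bounds(rng):
    for _ in range(20):
        rec = random_record(rng)
        spec = spec_of("separation_profile_window", "sa", 11)
        block = compute_feature_block(spec, rec)
        assert block.min() >= 0 and block.max() <= rec.n
        # centre slot is zero iff residue carries that label
        lab = rec.tracks["sa"].argmax_labels()
        for l in range(2):
            centre = block[:, l * 11 + 5]
            np.testing.assert_array_equal(centre == 0, lab == l)


class TestFeaturize:
    def test_composition_example(self):
        rec = ProteinRecord(id="p", sequence="ACD")
        fm = featurize([rec], [spec_of("num_residues"), spec_of("relative_position")])
        np.testing.assert_allclose(
            fm.to_numpy(), [[3, 1 / 3], [3, 2 / 3], [3, 1]]
        )

    def test_column_count_and_order(self, rng):
        rec = random_record(rng, n=30)
        encoding = [
            spec_of("labels_local_window", "ss3", 5),
            spec_of("num_residues"),
            spec_of("dimeric_global_hist", "sa"),
        ]
        fm = featurize([rec], encoding)
        assert fm.shape == (30, sum(s.d for s in encoding))
        assert list(fm.columns[:2]) == [
            "labels_local_window(ss3,5):0",
            "labels_local_window(ss3,5):1",
        ]

    def test_rows_match_per_position_calls(self, rng):
        recs = [random_record(rng, n=20) for _ in range(3)]
        encoding = [
            spec_of("separation_profile_window", "sa", 5),
            spec_of("labels_local_hist", "pssm", 10),
        ]
        fm = featurize(recs, encoding)
        for _ in range(20):
            rec = recs[rng.integers(3)]
            i = int(rng.integers(1, 21))
            expected = np.concatenate(
                [compute_feature(s, rec, i) for s in encoding]
            )
            np.testing.assert_allclose(fm.loc[(rec.id, i)].to_numpy(), expected)

    def test_missing_track_reported(self):
        rec = ProteinRecord(id="naked", sequence="ACD")
        with pytest.raises(KeyError, match="naked.*ss3"):
            featurize([rec], [spec_of("labels_global_hist", "ss3")])

    def test_no_non_finite_values(self, rng):
        recs = [random_record(rng, n=int(rng.integers(1, 25))) for _ in range(5)]
        fm = featurize(recs, ORACLE_SPECS)
        assert np.isfinite(fm.to_numpy()).all()
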