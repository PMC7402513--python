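import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sidefx.io import Dataset, DrugProfile, ProteinAnnotation
from sidefx.similarity import (
    SimilarityMatrix,
    build_similarity_matrix,
    chem_similarity,
    go_similarity,
    integrate,
    substituent_similarity,
    target_similarity,
    therapeutic_similarity,
)
from sidefx.synthetic import GeneratorConfig, generate


# independent brute-force oracles -------------------------------------------

def tanimoto_oracle(a, b):
    both = sum(1 for x, y in zip(a, b) if x and y)
    either = sum(1 for x, y in zip(a, b) if x or y)
    return both / either if either else 0.0


def jaccard_oracle(a, b):
    a, b = set(a), set(b)
    if not a and not b:
        return 0.0
    inter = sum(1 for x in a if x in b)
    return inter / (len(a) + len(b) - inter)


class TestChem:
    @pytest.mark.parametrize(
        "fj,fk,expected",
        [
            ((1, 0, 1, 0), (1, 0, 1, 0), 1.0),
            ((1, 1, 0, 0), (0, 0, 1, 1), 0.0),
            ((1, 1, 0, 0), (1, 0, 1, 0), 1 / 3),
            ((0, 0, 0, 0), (0, 0, 0, 0), 0.0),
        ],
    )
    def test_examples(self, fj, fk, expected):
        assert chem_similarity(np.array(fj), np.array(fk)) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            chem_similarity(np.array([1, 0]), np.array([1, 0, 1]))


class TestSetChannels:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a", "b", "c"}, {"a", "b", "c"}, 1.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            (set(), {"a"}, 0.0),
            (set(), set(), 0.0),
        ],
    )
    def test_go_examples(self, a, b, expected):
        assert go_similarity(a, b) == pytest.approx(expected)

    def test_substituent_example(self):
        assert substituent_similarity(
            {"hydroxyl", "methyl"}, {"methyl", "amino", "nitro"}
        ) == pytest.approx(0.25)

    def test_target_similarity_cross_pair_mean(self):
        proteins = {
            "P1": ProteinAnnotation("P1", frozenset({"a"})),
            "P2": ProteinAnnotation("P2", frozenset({"a", "b"})),
            "P3": ProteinAnnotation("P3", frozenset({"a", "b", "c", "d"})),
        }
        assert go_similarity(proteins["P1"].go_terms, proteins["P2"].go_terms) == 0.5
        assert go_similarity(proteins["P1"].go_terms, proteins["P3"].go_terms) == 0.25
        dj = DrugProfile("D1", targets=frozenset({"P1"}))
        dk = DrugProfile("D2", targets=frozenset({"P2", "P3"}))
        assert target_similarity(dj, dk, proteins) == pytest.approx(0.375)

    def test_target_similarity_identical_single_target(self):
        proteins = {"P1": ProteinAnnotation("P1", frozenset({"x", "y"}))}
        d = DrugProfile("D1", targets=frozenset({"P1"}))
        assert target_similarity(d, d, proteins) == 1.0

    def test_target_without_targets_raises(self):
        with pytest.raises(ValueError):
            target_similarity(DrugProfile("D1"), DrugProfile("D2"), {})


class TestTherapeutic:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A01AB02"}, {"A01AB02"}, 1.0),
            ({"A01AB02"}, {"A01AC03"}, 0.6),
            ({"A01AB02"}, {"N02BA01"}, 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert therapeutic_similarity(a, b) == pytest.approx(expected)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            therapeutic_similarity(set(), {"A01AB02"})


class TestIntegrate:
    def test_examples(self):
        scores = (0.2, 0.4, 0.6, 0.8)
        assert integrate(scores, "max") == pytest.approx(0.8)
        assert integrate(scores, "mean") == pytest.approx(0.5)
        assert integrate(scores, "gm") == pytest.approx(0.0384 ** 0.25)

    def test_degenerate_consensus(self):
        for method in ("max", "mean", "gm"):
            assert integrate({"chem": 0.3, "tar": 0.3}, method) == pytest.approx(0.3)

    def test_gm_zero_channel_annihilates(self):
        assert integrate((0.5, 0.0, 0.9), "gm") == 0.0

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError, match="unknown integration"):
            integrate((0.5,), "median")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    a=st.sets(st.integers(0, 7), max_size=8),
    b=st.sets(st.integers(0, 7), max_size=8),
)
def test_set_similarity_matches_oracle_and_is_symmetric(a, b):
    assert substituent_similarity(a, b) == pytest.approx(jaccard_oracle(a, b))
    assert substituent_similarity(a, b) == substituent_similarity(b, a)
    assert 0.0 <= substituent_similarity(a, b) <= 1.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    fj=st.lists(st.integers(0, 1), min_size=16, max_size=16),
    fk=st.lists(st.integers(0, 1), min_size=16, max_size=16),
)
def test_tanimoto_matches_oracle_and_is_symmetric(fj, fk):
    a, b = np.array(fj), np.array(fk)
    assert chem_similarity(a, b) == pytest.approx(tanimoto_oracle(fj, fk))
    assert chem_similarity(a, b) == chem_similarity(b, a)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    a=st.sets(st.integers(0, 15), max_size=6),
    b=st.sets(st.integers(0, 15), max_size=6),
    extra=st.integers(100, 120),
)
def test_adding_shared_substituent_never_decreases_similarity(a, b, extra):
    before = substituent_similarity(a, b)
    after = substituent_similarity(a | {extra}, b | {extra})
    assert after >= before - 1e-12


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    scores=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=4)
)
def test_consensus_ordering_max_mean_gm(scores):
    s_max = integrate(scores, "max")
    s_mean = integrate(scores, "mean")
    s_gm = integrate(scores, "gm")
    assert s_max >= s_mean - 1e-12
    assert s_mean >= s_gm - 1e-12


class TestMatrix:
    def test_single_drug_matrix(self):
        ds = Dataset(
            drugs=[DrugProfile("D1", fingerprint=np.array([1, 0, 1, 0], dtype=np.uint8))],
            proteins={},
            labels=np.array([[1]], dtype=np.uint8),
            side_effect_ids=["SE0"],
        )
        S = build_similarity_matrix(ds, channels=("chem",), method="max")
        np.testing.assert_array_equal(S.values, [[1.0]])

    def test_matrix_is_symmetric_in_unit_range_unit_diagonal(self, bench_dataset):
        for method in ("max", "mean", "gm"):
            S = build_similarity_matrix(bench_dataset, method=method)
            assert np.array_equal(S.values, S.values.T)
            assert S.values.min() >= 0.0 and S.values.max() <= 1.0
            np.testing.assert_array_equal(np.diag(S.values), 1.0)

    def test_matrix_entries_match_scalar_channel_oracle(self):
        ds, _, _ = generate(
            GeneratorConfig(
                n_drugs=10, n_side_effects=4, n_clusters=2, fingerprint_length=32, seed=3
            )
        )
        for method in ("max", "mean", "gm"):
            S = build_similarity_matrix(ds, method=method)
            for j in range(ds.n_drugs):
                for k in range(ds.n_drugs):
                    if j == k:
                        continue
                    dj, dk = ds.drugs[j], ds.drugs[k]
                    per_channel = {
                        "chem": chem_similarity(dj.fingerprint, dk.fingerprint),
                        "tar": target_similarity(dj, dk, ds.proteins),
                        "sub": substituent_similarity(dj.substituents, dk.substituents),
                        "thera": therapeutic_similarity(dj.atc_codes, dk.atc_codes),
                    }
                    assert S.values[j, k] == pytest.approx(
                        integrate(per_channel, method), abs=1e-12
                    )

    def test_tsv_round_trip(self, bench_dataset, tmp_path):
        S = build_similarity_matrix(bench_dataset, channels=("chem", "sub"), method="mean")
        path = tmp_path / "S.tsv"
        S.to_tsv(path)
        back = SimilarityMatrix.from_tsv(path, channel=S.channel)
        assert back.drug_ids == S.drug_ids
        np.testing.assert_allclose(back.values, S.values, atol=1e-9)

    def test_mean_gm_divide_by_enabled_channel_count(self, bench_dataset):
        # two-channel mean must differ from four-channel mean on the same pair
        S2 = build_similarity_matrix(bench_dataset, channels=("chem", "tar"), method="mean")
        d0, d1 = bench_dataset.drugs[0], bench_dataset.drugs[1]
        expected = (
            chem_similarity(d0.fingerprint, d1.fingerprint)
            + target_similarity(d0, d1, bench_dataset.proteins)
        ) / 2.0
        assert S2.values[0, 1] == pytest.approx(expected, abs=1e-12)
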