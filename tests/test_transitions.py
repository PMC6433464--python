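"""Transition counting, normalization, flattening, cosine divergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cosine as scipy_cosine

from ethoseq import (
    average_matrices,
    baseline_divergence,
    cosine_distance,
    count_transitions,
    extract_label_sequence,
    flatten,
    normalize_transitions,
    segment_bouts,
)
from ethoseq.catalogue import NONE_LABEL
from ethoseq.ethogram import Bout, BoutSequence
from ethoseq.transitions import TransitionMatrix, read_matrix_tsv, write_matrix_tsv

from conftest import make_ethogram

AB = ("eating", "grooming")


def brute_force_counts(seq, alphabet):
    """Independent oracle: scan every index pair (k, k+1)."""
    n = len(alphabet)
    out = np.zeros((n, n), dtype=int)
    for k in range(len(seq) - 1):
        out[alphabet.index(seq[k]), alphabet.index(seq[k + 1])] += 1
    return out


class TestSequenceExtraction:
    def test_projection_discards_timing(self):
        bs = BoutSequence(
            bouts=(Bout(0, 2, "eating"), Bout(4, 5, "eating"), Bout(5, 6, "grooming"))
        )
        assert extract_label_sequence(bs) == ["eating", "eating", "grooming"]

    def test_empty_and_singleton(self):
        assert extract_label_sequence(BoutSequence(bouts=())) == []
        assert extract_label_sequence(BoutSequence(bouts=(Bout(0, 9, "eating"),))) == [
            "eating"
        ]


class TestCounting:
    def test_hand_enumeration(self):
        c = count_transitions(["eating", "eating", "grooming", "eating"], AB)
        assert c.total == 3
        assert c.counts.tolist() == [[1, 1], [1, 0]]

    @pytest.mark.parametrize("seq", [[], ["eating"]])
    def test_degenerate_sequences(self, seq):
        c = count_transitions(seq, AB)
        assert c.total == 0 and not c.counts.any()

    def test_label_outside_alphabet(self):
        with pytest.raises(ValueError, match="alphabet"):
            count_transitions(["flying"], AB)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from(AB), max_size=100))
    def test_matches_brute_force_oracle(self, seq):
        c = count_transitions(seq, AB)
        assert (c.counts == brute_force_counts(seq, AB)).all()
        assert c.total == max(len(seq) - 1, 0)


class TestNormalization:
    def test_conditional_row(self):
        c = count_transitions(
            ["eating"] * 4 + ["grooming"], AB
        )  # eat->eat x3, eat->groom x1
        m = normalize_transitions(c, "conditional")
        assert m.values[0].tolist() == [0.75, 0.25]
        assert not m.observed_rows[1] and not m.values[1].any()

    def test_global_mass(self):
        c = count_transitions(["eating"] * 4 + ["grooming"], AB)
        m = normalize_transitions(c, "global")
        assert m.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert m.values[0].tolist() == [0.75, 0.25]

    def test_zero_counts_flagged_undefined(self):
        m = normalize_transitions(count_transitions([], AB), "global")
        assert m.undefined and not m.values.any()

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(AB), min_size=2, max_size=100))
    def test_row_and_global_conservation(self, seq):
        c = count_transitions(seq, AB)
        cond = normalize_transitions(c, "conditional")
        glob = normalize_transitions(c, "global")
        for i in range(len(AB)):
            expected = 1.0 if cond.observed_rows[i] else 0.0
            assert cond.values[i].sum() == pytest.approx(expected, abs=1e-9)
        assert glob.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestAveraging:
    def _matrix(self, rows, mode="conditional"):
        values = np.asarray(rows, dtype=float)
        return TransitionMatrix(
            alphabet=AB,
            values=values,
            mode=mode,
            observed_rows=values.sum(axis=1) > 0,
            undefined=not values.any(),
        )

    def test_single_matrix_is_identity_of_mean(self):
        m = self._matrix([[0.5, 0.5], [1, 0]])
        avg = average_matrices([m])
        assert (avg.values == m.values).all()

    def test_hand_mean(self):
        a = self._matrix([[1, 0], [0, 1]])
        b = self._matrix([[0, 1], [1, 0]])
        avg = average_matrices([a, b])
        assert (avg.values == 0.5).all()

    def test_undefined_excluded_from_average(self):
        a = self._matrix([[1, 0], [0, 1]])
        z = self._matrix([[0, 0], [0, 0]])
        avg = average_matrices([a, z])
        assert (avg.values == a.values).all()
        with pytest.raises(ValueError, match="undefined"):
            average_matrices([z])

    def test_mixed_modes_rejected(self):
        a = self._matrix([[1, 0], [0, 1]], "conditional")
        b = self._matrix([[0.5, 0], [0, 0.5]], "global")
        with pytest.raises(ValueError, match="share"):
            average_matrices([a, b])


class TestFlattenAndCosine:
    def test_flatten_row_major(self):
        m = TransitionMatrix(
            alphabet=AB,
            values=np.array([[0.1, 0.9], [0.4, 0.6]]),
            mode="conditional",
            observed_rows=np.array([True, True]),
        )
        assert flatten(m).tolist() == [0.1, 0.9, 0.4, 0.6]

    @pytest.mark.parametrize("n_labels,expected", [(7, 49), (6, 36)])
    def test_flatten_length(self, n_labels, expected):
        labels = tuple(f"b{i}" for i in range(n_labels))
        m = TransitionMatrix(
            alphabet=labels,
            values=np.eye(n_labels),
            mode="conditional",
            observed_rows=np.ones(n_labels, bool),
        )
        assert flatten(m).size == expected

    def test_identity_orthogonality_and_hand_value(self):
        v = np.array([0.2, 0.5, 0.3])
        assert cosine_distance(v, v) == pytest.approx(0.0, abs=1e-12)
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        # 1 - 1/(sqrt(2)*sqrt(2)) = 0.5
        assert cosine_distance([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_distance([0, 0], [1, 0])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 10), min_size=4, max_size=4),
        st.lists(st.floats(0, 10), min_size=4, max_size=4),
        st.floats(0.01, 100),
    )
    def test_metric_like_properties_and_scipy_agreement(self, u, v, c):
        u, v = np.asarray(u), np.asarray(v)
        if u.sum() == 0 or v.sum() == 0:
            return
        d = cosine_distance(u, v)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(cosine_distance(v, u))
        assert cosine_distance(u, c * v) == pytest.approx(d, abs=1e-9)
        assert d == pytest.approx(scipy_cosine(u, v), abs=1e-9)


class TestBaselineDivergence:
    def _matrix(self, rows):
        values = np.asarray(rows, dtype=float)
        return TransitionMatrix(
            alphabet=AB,
            values=values,
            mode="conditional",
            observed_rows=values.sum(axis=1) > 0,
            undefined=not values.any(),
        )

    def test_identical_matrices_zero_distance(self):
        m = self._matrix([[0.5, 0.5], [1, 0]])
        per = {c: m for c in ("Fed", "Fasted18", "Fasted48")}
        results = baseline_divergence(per, "Fed")
        assert len(results) == 2
        assert all(r.distance == pytest.approx(0.0, abs=1e-12) for r in results)

    def test_five_conditions_four_results(self):
        m = self._matrix([[0.5, 0.5], [1, 0]])
        per = {c: m for c in ("Fed", "Fasted18", "Fasted48", "FedAgRP_CS", "FedAgRP_PS")}
        assert len(baseline_divergence(per, "Fed")) == 4

    def test_hand_angle(self):
        # Flattened vectors [0,1,1,0] vs [0,1,0,1]: cosine 1/2, distance 1/2.
        a = self._matrix([[0, 1], [1, 0]])
        b = self._matrix([[0, 1], [0, 1]])
        (r,) = baseline_divergence({"Fed": a, "Fasted48": b}, "Fed")
        assert r.distance == pytest.approx(0.5)

    def test_missing_baseline(self):
        m = self._matrix([[0.5, 0.5], [1, 0]])
        with pytest.raises(ValueError, match="baseline"):
            baseline_divergence({"Fasted18": m}, "Fed")

    def test_undefined_baseline_yields_no_results(self, caplog):
        z = self._matrix([[0, 0], [0, 0]])
        m = self._matrix([[0.5, 0.5], [1, 0]])
        assert baseline_divergence({"Fed": z, "Fasted18": m}, "Fed") == []


class TestMatrixIO:
    def test_tsv_roundtrip(self, tmp_path):
        values = np.array([[0.25, 0.75], [1.0, 0.0]])
        m = TransitionMatrix(
            alphabet=AB,
            values=values,
            mode="conditional",
            observed_rows=np.array([True, True]),
        )
        path = tmp_path / "m.tsv"
        write_matrix_tsv(m, path)
        back = read_matrix_tsv(path)
        assert back.alphabet == AB
        np.testing.assert_allclose(back.values, values)


def test_end_to_end_from_barcode(tiny_cat):
    """Barcode -> bouts -> sequence -> conditional matrix, by hand."""
    e = make_ethogram(
        ["eating", "eating", NONE_LABEL, "eating", NONE_LABEL, "grooming", "eating"],
        tiny_cat,
    )
    seq = extract_label_sequence(segment_bouts(e))
    assert seq == ["eating", "eating", "grooming", "eating"]
    m = normalize_transitions(count_transitions(seq, tiny_cat.labels))
    # eating row: eat->eat 1, eat->groom 1 of 2; grooming row: groom->eat 1.
    assert m.values.tolist() == [[0.5, 0.5], [1.0, 0.0]]
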