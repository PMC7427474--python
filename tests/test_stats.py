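"""Ae, informativeness, Weir-Cockerham FST, and marker geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microhap as mh
from _oracles import closest_gap_oracle, informativeness_oracle, wc_fst_oracle


def matrix_from_rows(rows, marker="mh01AA-1"):
    rows = np.asarray(rows, dtype=float)
    return mh.PopulationFrequencyMatrix(
        marker=marker,
        populations=[f"P{i}" for i in range(rows.shape[0])],
        haplotypes=[f"H{j}" for j in range(rows.shape[1])],
        p=rows,
    )


@st.composite
def frequency_rows(draw, k=None, n=None):
    k = k if k is not None else draw(st.integers(2, 5))
    n = n if n is not None else draw(st.integers(2, 6))
    raw = draw(
        st.lists(
            st.lists(st.floats(0.001, 1.0), min_size=n, max_size=n),
            min_size=k,
            max_size=k,
        )
    )
    rows = np.asarray(raw)
    return rows / rows.sum(axis=1, keepdims=True)


class TestEffectiveNumberOfAlleles:
    def test_single_haplotype_is_one(self):
        assert mh.effective_number_of_alleles([1.0]) == 1.0

    def test_equifrequent_haplotypes_reach_count(self):
        assert mh.effective_number_of_alleles([0.25] * 4) == pytest.approx(4.0)

    def test_hand_computed_value(self):
        # 1 / (0.25 + 0.09 + 0.04) = 1 / 0.38
        assert mh.effective_number_of_alleles([0.5, 0.3, 0.2]) == pytest.approx(
            1 / 0.38, abs=1e-12
        )

    @pytest.mark.parametrize("bad", [[], [0.0, 0.0]])
    def test_degenerate_vectors_rejected(self, bad):
        with pytest.raises(ValueError):
            mh.effective_number_of_alleles(bad)

    @given(frequency_rows(k=1))
    @settings(max_examples=50, derandomize=True)
    def test_bounds_and_label_permutation_invariance(self, rows):
        p = rows[0]
        ae = mh.effective_number_of_alleles(p)
        assert 1.0 - 1e-9 <= ae <= len(p) + 1e-9
        assert mh.effective_number_of_alleles(p[::-1]) == pytest.approx(ae)


class TestMeanAe:
    def test_identical_rows_mean_equals_row(self):
        matrix = matrix_from_rows([[0.5, 0.3, 0.2]] * 4)
        by_pop, mean = mh.mean_ae(matrix)
        assert mean == pytest.approx(1 / 0.38)
        assert all(v == pytest.approx(1 / 0.38) for v in by_pop.values())

    def test_fixed_plus_balanced_rows(self):
        # one population fixed (Ae=1), one maximally diverse (Ae=2)
        matrix = matrix_from_rows([[1.0, 0.0], [0.5, 0.5]])
        _, mean = mh.mean_ae(matrix)
        assert mean == pytest.approx(1.5)

    def test_single_population(self):
        matrix = matrix_from_rows([[0.5, 0.5]])
        by_pop, mean = mh.mean_ae(matrix)
        assert mean == by_pop["P0"] == pytest.approx(2.0)

    def test_row_scored_on_own_conditional_distribution(self):
        # zeros for haplotypes absent from the population do not dilute Ae
        matrix = matrix_from_rows([[0.5, 0.5, 0.0], [1 / 3, 1 / 3, 1 / 3]])
        by_pop, _ = mh.mean_ae(matrix)
        assert by_pop["P0"] == pytest.approx(2.0)
        assert by_pop["P1"] == pytest.approx(3.0)


class TestInformativeness:
    def test_identical_populations_zero(self):
        assert mh.informativeness(matrix_from_rows([[0.5, 0.3, 0.2]] * 2)) == 0.0

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_disjoint_fixed_populations_reach_log_k(self, k):
        rows = np.eye(k)
        assert mh.informativeness(matrix_from_rows(rows)) == pytest.approx(
            math.log(k), abs=1e-12
        )

    def test_hand_computed_value(self):
        value = mh.informativeness(matrix_from_rows([[0.8, 0.2], [0.2, 0.8]]))
        assert value == pytest.approx(0.1927447570, abs=1e-9)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError, match="two populations"):
            mh.informativeness(matrix_from_rows([[0.5, 0.5]]))

    @given(frequency_rows())
    @settings(max_examples=80, derandomize=True)
    def test_matches_term_by_term_oracle_within_bounds(self, rows):
        matrix = matrix_from_rows(rows)
        value = mh.informativeness(matrix)
        assert value == pytest.approx(
            informativeness_oracle(rows.tolist()), abs=1e-10
        )
        assert -1e-12 <= value <= math.log(rows.shape[0]) + 1e-9

    @given(frequency_rows())
    @settings(max_examples=40, derandomize=True)
    def test_simultaneous_permutation_invariance(self, rows):
        value = mh.informativeness(matrix_from_rows(rows))
        permuted = rows[::-1, ::-1]
        assert mh.informativeness(matrix_from_rows(permuted)) == pytest.approx(value)


def random_diplotypes(rng, n_pops=None, n_alleles=None):
    n_pops = n_pops or int(rng.integers(2, 5))
    n_alleles = n_alleles or int(rng.integers(2, 6))
    alleles = [f"H{j}" for j in range(n_alleles)]
    result = {}
    for i in range(n_pops):
        n_ind = int(rng.integers(5, 31))
        weights = rng.dirichlet(np.ones(n_alleles) * rng.uniform(0.2, 3.0))
        draws = rng.choice(n_alleles, size=(n_ind, 2), p=weights)
        result[f"P{i}"] = [(alleles[a], alleles[b]) for a, b in draws]
    return result


class TestWeirCockerhamFst:
    def test_complete_fixation_between_populations(self):
        diplotypes = {
            "P1": [("A", "A")] * 20,
            "P2": [("B", "B")] * 20,
        }
        assert mh.fst_weir_cockerham(diplotypes) == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_marker_undefined(self):
        diplotypes = {"P1": [("A", "A")] * 10, "P2": [("A", "A")] * 10}
        assert math.isnan(mh.fst_weir_cockerham(diplotypes))

    def test_single_population_undefined(self):
        assert math.isnan(mh.fst_weir_cockerham({"P1": [("A", "B")] * 10}))

    def test_haploid_individuals_excluded(self):
        diplotypes = {
            "P1": [("A", "A")] * 10 + [("A",)] * 5,
            "P2": [("B", "B")] * 10 + [("B",)] * 5,
        }
        assert mh.fst_weir_cockerham(diplotypes) == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_transcription(self, rng):
        for _ in range(50):
            diplotypes = random_diplotypes(rng)
            expected = wc_fst_oracle(list(diplotypes.values()))
            got = mh.fst_weir_cockerham(diplotypes)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_ratio_of_means_option(self, rng):
        for _ in range(20):
            diplotypes = random_diplotypes(rng)
            expected = wc_fst_oracle(
                list(diplotypes.values()), average="ratio_of_means"
            )
            got = mh.fst_weir_cockerham(diplotypes, average="ratio_of_means")
            assert got == pytest.approx(expected, abs=1e-10)

    def test_population_relabeling_invariance(self, rng):
        diplotypes = random_diplotypes(rng, n_pops=3)
        relabeled = dict(zip(["X", "Y", "Z"], diplotypes.values()))
        assert mh.fst_weir_cockerham(relabeled) == pytest.approx(
            mh.fst_weir_cockerham(diplotypes), abs=1e-12
        )


class TestMarkerGeometry:
    @pytest.mark.parametrize(
        "positions,length",
        [((100, 103), 4), ((100, 120, 449), 350), ((7, 8), 2)],
    )
    def test_core_length_spans_distal_variants_inclusive(self, positions, length):
        rsids = tuple(f"rs{i}" for i in range(len(positions)))
        marker = mh.MarkerDefinition("mh01AA-1", "chr1", positions, rsids)
        assert mh.marker_length(marker) == length

    def test_indel_reference_span(self):
        marker = mh.MarkerDefinition("mh01AA-1", "chr1", (100, 110), ("rs1", "rs2"))
        # 5-bp deletion reference allele at the last variant extends the span
        assert mh.marker_length(marker, ref_lengths=(1, 5)) == 15

    def test_gap_between_disjoint_spans(self):
        markers = [
            mh.MarkerDefinition("mh01AA-1", "chr1", (100, 200), ("rs1", "rs2")),
            mh.MarkerDefinition("mh01AA-2", "chr1", (350, 400), ("rs3", "rs4")),
        ]
        assert mh.closest_nonoverlapping_distance(markers) == {
            "mh01AA-1": 149,
            "mh01AA-2": 149,
        }

    def test_overlapping_neighbor_skipped(self):
        markers = [
            mh.MarkerDefinition("mh01AA-1", "chr1", (100, 200), ("rs1", "rs2")),
            mh.MarkerDefinition("mh01AA-2", "chr1", (150, 250), ("rs3", "rs4")),
            mh.MarkerDefinition("mh01AA-3", "chr1", (400, 500), ("rs5", "rs6")),
        ]
        distances = mh.closest_nonoverlapping_distance(markers)
        assert distances["mh01AA-1"] == 199  # measured to the third marker
        assert distances["mh01AA-2"] == 149

    def test_lone_marker_has_no_distance(self):
        markers = [
            mh.MarkerDefinition("mh01AA-1", "chr1", (100, 200), ("rs1", "rs2")),
            mh.MarkerDefinition("mh02AA-1", "chr2", (100, 200), ("rs3", "rs4")),
        ]
        distances = mh.closest_nonoverlapping_distance(markers)
        assert distances == {"mh01AA-1": None, "mh02AA-1": None}

    def test_abutting_spans_distance_zero(self):
        markers = [
            mh.MarkerDefinition("mh01AA-1", "chr1", (100, 200), ("rs1", "rs2")),
            mh.MarkerDefinition("mh01AA-2", "chr1", (201, 300), ("rs3", "rs4")),
        ]
        assert set(mh.closest_nonoverlapping_distance(markers).values()) == {0}

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(30):
            spans = []
            markers = []
            for i in range(int(rng.integers(1, 12))):
                start = int(rng.integers(1, 5000))
                end = start + int(rng.integers(1, 400))
                spans.append((start, end))
                markers.append(
                    mh.MarkerDefinition(
                        f"mh01AA-{i}", "chr1", (start, end), (f"rs{i}a", f"rs{i}b")
                    )
                )
            expected = closest_gap_oracle(spans)
            got = mh.closest_nonoverlapping_distance(markers)
            assert [got[m.name] for m in markers] == expected


class TestFilterMarkers:
    def test_x_and_long_markers_excludable(self):
        markers = [
            mh.MarkerDefinition("mh01AA-1", "chr1", (100, 150), ("rs1", "rs2")),
            mh.MarkerDefinition("mh0XAA-1", "chrX", (100, 150), ("rs3", "rs4")),
            mh.MarkerDefinition("mh01AA-2", "chr1", (100, 600), ("rs5", "rs6")),
        ]
        assert mh.filter_markers(markers) == markers
        kept = mh.filter_markers(markers, exclude_x=True, max_length=350)
        assert [m.name for m in kept] == ["mh01AA-1"]


class TestAnnotateStats:
    def test_marker_rows_gain_statistics(self, tiny_db):
        mh.annotate_stats(tiny_db)
        stats = tiny_db.stats["mh01KK-001"]
        assert stats["Ae"] is not None and stats["In"] is not None

    def test_marker_without_frequencies_keeps_missing_values(self, tiny_db):
        mh.annotate_stats(tiny_db)
        assert "mh02CP-010" not in tiny_db.stats
        assert tiny_db.marker("mh02CP-010") is not None

    def test_annotated_ae_is_mean_of_per_population_ae(self, tiny_db):
        mh.annotate_stats(tiny_db)
        afr = mh.population_ae(tiny_db, "mh01KK-001", "AFR")
        eur = mh.population_ae(tiny_db, "mh01KK-001", "EUR")
        assert tiny_db.stats["mh01KK-001"]["Ae"] == pytest.approx(
            (afr + eur) / 2, abs=1e-4
        )

    def test_per_population_ae_matches_row_statistic(self, tiny_db):
        # AFR frequencies 0.25/0.25/0.5 -> 1/(0.0625+0.0625+0.25)
        assert mh.population_ae(tiny_db, "mh01KK-001", "AFR") == pytest.approx(
            1 / 0.375
        )

    def test_single_population_marker_has_no_informativeness(self, tiny_db):
        mh.annotate_stats(tiny_db)
        assert tiny_db.stats["mh01KK-002"]["In"] is None

    def test_fst_column_from_panel_diplotypes(self, tiny_db):
        diplotypes = {
            "mh01KK-001": {
                "AFR": [("A,C,G", "G,C,T")] * 10,
                "EUR": [("A,C,G", "A,C,G")] * 10,
            }
        }
        mh.annotate_stats(tiny_db, diplotypes=diplotypes)
        expected = wc_fst_oracle(
            [[("A,C,G", "G,C,T")] * 10, [("A,C,G", "A,C,G")] * 10]
        )
        assert tiny_db.stats["mh01KK-001"]["Fst"] == pytest.approx(expected, abs=1e-4)
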