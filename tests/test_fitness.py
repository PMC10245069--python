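"""Mutational-cost landscapes, replicate averaging and residue selection."""

import numpy as np
import pytest

from mlascan.alphabet import AA_INDEX, AA_SYMBOLS, N_SYMBOLS
from mlascan.counting import normalize_cpm
from mlascan.fitness import (
    FitnessLandscape,
    GroupAnnotation,
    average_replicates,
    classify_groups,
    compute_fitness,
    landscape_from_scores_csv,
    parse_protein_variant,
    position_summary,
    select_functional_residues,
    write_scores_csv,
)
from mlascan.tables import CountTable, FrequencyTable


def _freq_table(variant_cpm, wt_cpm, wt_protein="M", condition="selected"):
    """One-position table; remaining mass is parked on a filler symbol."""
    cpm = np.zeros((1, N_SYMBOLS))
    for sym, v in variant_cpm.items():
        cpm[0, AA_INDEX[sym]] = v
    filler = 1e6 - cpm.sum() - wt_cpm
    assert filler >= 0
    cpm[0, AA_INDEX["C"]] += filler
    return FrequencyTable(
        positions=np.array([1]), wt_protein=wt_protein, cpm=cpm, wt_cpm=wt_cpm,
        condition=condition,
    )


def _landscape(delta_e, wt_protein, na_mask=None, replicate=1):
    delta_e = np.asarray(delta_e, dtype=float)
    na = np.zeros_like(delta_e, dtype=bool) if na_mask is None else na_mask
    return FitnessLandscape(
        positions=np.arange(1, delta_e.shape[0] + 1),
        wt_protein=wt_protein,
        delta_e=delta_e,
        na_mask=na,
        replicate=replicate,
    )


class TestComputeFitness:
    def test_wt_like_variant_scores_zero(self):
        sel = _freq_table({"A": 300}, wt_cpm=3000)
        unsel = _freq_table({"A": 100}, wt_cpm=1000, condition="unselected")
        land = compute_fitness(sel, unsel)
        assert land.score(1, "A") == pytest.approx(0.0, abs=1e-12)

    def test_direct_substitution_example(self):
        """sel 100 vs WT 1000, unsel 200 vs WT 500 -> ln(1/2) - ln 2 = -1.3863."""
        sel = _freq_table({"A": 100}, wt_cpm=1000)
        unsel = _freq_table({"A": 200}, wt_cpm=500, condition="unselected")
        land = compute_fitness(sel, unsel)
        assert land.score(1, "A") == pytest.approx(np.log(0.5) - np.log(2), abs=1e-4)
        assert land.score(1, "A") == pytest.approx(-1.3863, abs=1e-4)

    def test_wt_cells_are_exactly_zero_everywhere(self, small_library, small_truth):
        from mlascan.synthetic import preselection_frequencies, simulate_selection

        pre = preselection_frequencies(small_library, small_library.sublibraries[0])
        post = simulate_selection(pre, small_truth)
        land = compute_fitness(post, pre)
        assert (land.delta_e[land.wt_cells] == 0).all()

    def test_scaling_invariance_of_counts(self):
        """Multiplying one condition's counts by any c > 0 leaves dE unchanged."""
        rng = np.random.default_rng(0)
        wt_protein = "MAY"
        positions = np.arange(1, 4)

        def make_counts(low, high):
            c = rng.integers(low, high, size=(3, N_SYMBOLS))
            for r, aa in enumerate(wt_protein):
                c[r, AA_INDEX[aa]] = 0
            return c

        counts = make_counts(1, 500)
        base = CountTable(positions=positions, wt_protein=wt_protein,
                          counts=counts, wt_count=2000)
        scaled = CountTable(positions=positions, wt_protein=wt_protein,
                            counts=counts * 7, wt_count=2000 * 7)
        unsel = normalize_cpm(
            CountTable(positions=positions, wt_protein=wt_protein,
                       counts=make_counts(50, 51), wt_count=900),
            pseudocount=0,
        )
        l1 = compute_fitness(normalize_cpm(base, 0), unsel)
        l2 = compute_fitness(normalize_cpm(scaled, 0), unsel)
        keep = ~l1.na_mask
        np.testing.assert_allclose(l1.delta_e[keep], l2.delta_e[keep], atol=1e-12)

    def test_zero_wt_frequency_errors(self):
        sel = _freq_table({"A": 100}, wt_cpm=0)
        unsel = _freq_table({"A": 100}, wt_cpm=100, condition="unselected")
        with pytest.raises(ValueError, match="wild-type frequency"):
            compute_fitness(sel, unsel)

    def test_zero_unselected_frequency_masked_na(self):
        sel = _freq_table({"A": 100}, wt_cpm=1000)
        unsel = _freq_table({"A": 0}, wt_cpm=1000, condition="unselected")
        land = compute_fitness(sel, unsel)
        assert np.isnan(land.score(1, "A"))


class TestAverageReplicates:
    def test_two_replicates_average(self):
        a = _landscape([[0.0] + [-1.0] * 20], "A")
        b = _landscape([[0.0] + [-3.0] * 20], "A", replicate=2)
        mean = average_replicates([a, b])
        assert mean.delta_e[0, 1:] == pytest.approx(-2.0)

    def test_single_replicate_identity(self):
        a = _landscape([[0.0] + [-1.5] * 20], "A")
        mean = average_replicates([a])
        np.testing.assert_array_equal(mean.delta_e, a.delta_e)

    def test_partial_cells_flagged(self):
        na = np.zeros((1, N_SYMBOLS), dtype=bool)
        na[0, 5] = True
        a = _landscape([[0.0] + [-1.0] * 20], "A", na_mask=na)
        b = _landscape([[0.0] + [-3.0] * 20], "A", replicate=2)
        mean = average_replicates([a, b])
        assert mean.delta_e[0, 5] == pytest.approx(-3.0)  # only replicate 2 observed
        assert mean.partial_mask[0, 5] and not mean.na_mask[0, 5]

    def test_shape_mismatch_errors(self):
        a = _landscape([[0.0] + [-1.0] * 20], "A")
        b = _landscape([[0.0] + [-1.0] * 20, [-1.0] * 10 + [0.0] + [-1.0] * 10], "AM")
        with pytest.raises(ValueError):
            average_replicates([a, b])


class TestPositionSummary:
    def test_constant_and_zero_rows(self):
        land = _landscape([[0.0] + [-2.0] * 20, [0.0] * 21], "AA")
        means = position_summary(land)
        assert means.loc[1] == pytest.approx(-2.0)
        assert means.loc[2] == pytest.approx(0.0)

    def test_random_row_matches_brute_force(self, rng):
        row = rng.normal(size=N_SYMBOLS)
        wt_col = AA_INDEX["M"]
        row[wt_col] = 0.0
        land = _landscape([row], "M")
        brute = sum(v for i, v in enumerate(row) if i != wt_col) / 20
        assert position_summary(land).loc[1] == pytest.approx(brute, abs=1e-12)


class TestSelectionRule:
    def _toy_landscape(self):
        """3 positions x 20 mutations, six cells at -3 in position 2."""
        wt_protein = "MMM"
        de = np.zeros((3, N_SYMBOLS))
        cols = [i for i in range(N_SYMBOLS) if i != AA_INDEX["M"]]
        de[1, cols[:6]] = -3.0
        return _landscape(de, wt_protein)

    def test_hand_computed_oracle(self):
        """mu = -0.3, population sigma = 0.9, threshold -1.2 -> position 2 only."""
        sel = select_functional_residues(self._toy_landscape(), k=5, m=1.0)
        assert sel.mu == pytest.approx(-0.3)
        assert sel.sigma == pytest.approx(0.9)
        assert sel.selected_positions == {2}
        assert sel.qualifying_counts[2] == 6

    def test_all_neutral_with_tiny_noise_selects_nothing(self, rng):
        # balanced two-point noise: mu = 0 and sigma equals the amplitude, so
        # no cell falls strictly below mu - sigma and nothing is selected
        noise = np.array([-1e-6, 1e-6] * 10)
        de = np.zeros((4, N_SYMBOLS))
        wt_protein = "MMMM"
        cols = [i for i in range(N_SYMBOLS) if i != AA_INDEX["M"]]
        for r in range(4):
            de[r, cols] = rng.permutation(noise)
        sel = select_functional_residues(_landscape(de, wt_protein), k=5, m=1.0)
        assert sel.selected_positions == set()

    def test_degenerate_landscape_errors(self):
        de = np.zeros((2, N_SYMBOLS))
        with pytest.raises(ValueError, match="zero variance"):
            select_functional_residues(_landscape(de, "MM"), k=5, m=1.0)

    def test_two_sided_mode_counts_both_tails(self):
        de = np.zeros((2, N_SYMBOLS))
        cols = [i for i in range(N_SYMBOLS) if i != AA_INDEX["M"]]
        de[0, cols[:3]] = 5.0
        de[0, cols[3:6]] = -5.0
        land = _landscape(de, "MM")
        below = select_functional_residues(land, k=5, m=1.0, sided="below")
        two = select_functional_residues(land, k=5, m=1.0, sided="two_sided")
        assert below.selected_positions == set()
        assert two.selected_positions == {1}

    def test_relaxing_k_or_m_never_shrinks_selection(self, rng):
        de = rng.normal(-0.5, 1.0, size=(20, N_SYMBOLS))
        wt_protein = "M" * 20
        de[:, AA_INDEX["M"]] = 0.0
        land = _landscape(de, wt_protein)
        tight = select_functional_residues(land, k=6, m=1.5).selected_positions
        assert tight <= select_functional_residues(land, k=5, m=1.5).selected_positions
        assert tight <= select_functional_residues(land, k=6, m=1.0).selected_positions


class TestClassifyGroups:
    def test_signal_peptide_precedence(self):
        sel = select_functional_residues(TestSelectionRule()._toy_landscape(), k=5, m=1.0)
        sel.selected_positions = {2, 3}
        annot = GroupAnnotation(signal_peptide=(1, 2), pocket_positions={2, 3})
        groups = classify_groups(sel, annot)
        assert groups["signal_peptide"] == [2]
        assert groups["pocket"] == [3]

    def test_unannotated_goes_to_unclassified_with_warning(self):
        sel = select_functional_residues(TestSelectionRule()._toy_landscape(), k=5, m=1.0)
        sel.selected_positions = {50}
        with pytest.warns(UserWarning, match="lack annotation"):
            groups = classify_groups(sel, GroupAnnotation(signal_peptide=(1, 2)))
        assert groups["unclassified"] == [50]

    def test_empty_selection_empty_report(self):
        sel = select_functional_residues(TestSelectionRule()._toy_landscape(), k=5, m=1.0)
        sel.selected_positions = set()
        groups = classify_groups(sel, GroupAnnotation())
        assert all(v == [] for v in groups.values())


class TestScoreIO:
    @pytest.mark.parametrize(
        "s, expected",
        [
            ("A2G", ("A", 2, "G")),
            ("L123A", ("L", 123, "A")),
            ("Y7*", ("Y", 7, "*")),
            ("p.Ala2Gly", ("A", 2, "G")),
            ("p.Leu123Ter", ("L", 123, "*")),
            ("p.Ala2=", None),
            ("garbage", None),
        ],
    )
    def test_variant_string_parsing(self, s, expected):
        assert parse_protein_variant(s) == expected

    def test_scores_csv_round_trip(self, tmp_path, small_library, small_truth):
        from mlascan.synthetic import preselection_frequencies, simulate_selection

        pre = preselection_frequencies(small_library, small_library.sublibraries[0])
        post = simulate_selection(pre, small_truth)
        land = compute_fitness(post, pre)
        path = tmp_path / "scores.csv"
        write_scores_csv(path, land)
        loaded = landscape_from_scores_csv(path, wt_protein=small_library.wt_protein)
        keep = ~land.wt_cells & ~land.na_mask
        np.testing.assert_allclose(loaded.delta_e[keep], land.delta_e[keep], atol=1e-9)
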