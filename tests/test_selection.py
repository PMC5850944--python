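import numpy as np
import pandas as pd
import pytest

from _oracles import best_selection_bruteforce
from bnstratify.selection import (
    Couple,
    affinity,
    build_reduced_datasets,
    max_nonredundant_couples,
    readout_gap,
    select_proteins,
    sweep_k,
)
from conftest import make_processed, random_selection_instance


class TestAffinity:
    def test_agreement_on_k(self, make_proc):
        proc = make_proc([[1, 0]], [[1, 0]], [[0.1]], [[0.9]])
        assert affinity(proc.inputs, ["p1", "p2"], "CR1", "PR1") == 1

    def test_disagreement_on_k(self, make_proc):
        proc = make_proc([[1, 0]], [[1, 1]], [[0.1]], [[0.9]])
        assert affinity(proc.inputs, ["p1", "p2"], "CR1", "PR1") == 0
        assert affinity(proc.inputs, ["p1"], "CR1", "PR1") == 1

    def test_unknown_protein_is_an_error(self, make_proc):
        proc = make_proc([[1]], [[1]], [[0.1]], [[0.9]])
        with pytest.raises(ValueError, match="absent"):
            affinity(proc.inputs, ["nope"], "CR1", "PR1")


class TestMatching:
    def test_shared_cr_patient_limits_matching(self):
        pairs = [Couple("c1", "p1"), Couple("c1", "p2")]
        assert len(max_nonredundant_couples(pairs)) == 1

    def test_disjoint_pairs_all_match(self):
        pairs = [Couple("c1", "p1"), Couple("c2", "p2")]
        assert len(max_nonredundant_couples(pairs)) == 2

    def test_complete_bipartite_5x3(self):
        pairs = [Couple(f"c{i}", f"p{j}") for i in range(5) for j in range(3)]
        assert len(max_nonredundant_couples(pairs)) == 3

    def test_enumeration_lists_every_maximum_matching(self):
        pairs = [Couple(c, p) for c in ("c1", "c2") for p in ("p1", "p2")]
        matchings = max_nonredundant_couples(pairs, enumerate_all=True)
        assert len(matchings) == 2
        assert all(len(m) == 2 for m in matchings)


class TestReadoutGap:
    def test_identical_rows_give_zero(self, make_proc):
        proc = make_proc([[1]], [[1]], [[0.4, 0.6]], [[0.4, 0.6]])
        from bnstratify.preprocessing import split_by_class

        cr, pr = split_by_class(proc)
        assert readout_gap(cr.readouts, pr.readouts, [Couple("CR1", "PR1")]) == 0.0

    def test_opposite_boolean_rows(self, make_proc):
        proc = make_proc([[1]], [[1]], [[1.0, 1.0]], [[0.0, 0.0]])
        from bnstratify.preprocessing import split_by_class

        cr, pr = split_by_class(proc)
        assert readout_gap(cr.readouts, pr.readouts, [Couple("CR1", "PR1")]) == 2.0

    def test_invariant_under_couple_reordering(self, make_proc):
        proc = make_proc(
            [[1], [1]], [[1], [1]], [[0.9], [0.2]], [[0.1], [0.5]]
        )
        from bnstratify.preprocessing import split_by_class

        cr, pr = split_by_class(proc)
        couples = [Couple("CR1", "PR1"), Couple("CR2", "PR2")]
        assert readout_gap(cr.readouts, pr.readouts, couples) == pytest.approx(
            readout_gap(cr.readouts, pr.readouts, couples[::-1])
        )


class TestSelectProteins:
    def test_discriminating_protein_wins(self):
        """With CR=(1,0) and PR=(1,1): only protein 1 supports a couple at k=1."""
        proc = make_processed([[1, 0]], [[1, 1]], [[0.1]], [[0.9]])
        results = select_proteins(proc, k=1)
        top = results[0]
        assert top.proteins == ("p1",)
        assert top.couples == [Couple("CR1", "PR1")]

    def test_identical_matrices_pair_everyone(self):
        bits = [[1, 0], [0, 1], [1, 1]]
        proc = make_processed(bits, bits, [[0.0]] * 3, [[1.0]] * 3)
        results = select_proteins(proc, k=2)
        assert len(results[0].couples) == 3

    def test_k_too_large_is_an_error(self):
        proc = make_processed([[1]], [[1]], [[0.1]], [[0.9]])
        with pytest.raises(ValueError, match="k="):
            select_proteins(proc, k=2)

    def test_no_couple_returns_empty_with_warning(self, caplog):
        proc = make_processed([[1, 1]], [[0, 0]], [[0.1]], [[0.9]])
        with caplog.at_level("WARNING"):
            assert select_proteins(proc, k=2) == []

    def test_gap_tie_break_prefers_divergent_readouts(self):
        """Two CR patients share the input profile of one PR patient; the couple
        with the larger readout difference must be chosen."""
        proc = make_processed(
            [[1], [1]], [[1]], [[0.9], [0.5]], [[0.1]]
        )
        top = select_proteins(proc, k=1)[0]
        assert top.couples == [Couple("CR1", "PR1")]
        assert top.readout_gap == pytest.approx(0.8)
        assert top.affinity_count == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_oracle(self, seed):
        """Exhaustive selection equals DP brute force over subsets and matchings."""
        rng = np.random.default_rng(1000 + seed)
        bits_cr, bits_pr, r_cr, r_pr, k = random_selection_instance(rng)
        proc = make_processed(bits_cr, bits_pr, r_cr, r_pr)
        results = select_proteins(proc, k=k)
        count, gap, winners = best_selection_bruteforce(bits_cr, bits_pr, r_cr, r_pr, k)
        if count == 0:
            assert results == []
            return
        assert len(results[0].couples) == count
        assert results[0].readout_gap == pytest.approx(gap)
        assert len(results) == len(winners)

    def test_asp_backend_is_explicitly_unavailable(self):
        proc = make_processed([[1]], [[1]], [[0.1]], [[0.9]])
        with pytest.raises(ImportError, match="clingo"):
            select_proteins(proc, k=1, strategy="asp")


class TestSweepK:
    def test_identical_inputs_keep_couple_count_constant(self):
        bits = [[1, 1, 1]] * 3
        proc = make_processed(bits, bits, [[0.1]] * 3, [[0.9]] * 3)
        table = sweep_k(proc, [1, 2, 3])
        assert table["n_couples"].tolist() == [3, 3, 3]

    def test_redundant_pairs_shrink_with_k(self):
        """Profiles agree on p1 but split on p2/p3, so larger k leaves fewer
        redundant affinity pairs."""
        bits_cr = [[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]]
        bits_pr = [[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]]
        proc = make_processed(bits_cr, bits_pr, [[0.1]] * 4, [[0.9]] * 4)
        table = sweep_k(proc, [1, 2, 3])
        red = table["n_redundant"].tolist()
        assert red == sorted(red, reverse=True)
        assert red[-1] == 0

    def test_empty_range_gives_empty_table(self, make_proc):
        proc = make_proc([[1]], [[1]], [[0.1]], [[0.9]])
        assert len(sweep_k(proc, [])) == 0


class TestReducedDatasets:
    def test_input_bits_shared_row_wise(self):
        bits = [[1, 0], [0, 1]]
        proc = make_processed(bits, bits, [[0.9], [0.8]], [[0.1], [0.2]])
        sel = select_proteins(proc, k=2)[0]
        red_cr, red_pr = build_reduced_datasets(proc, sel)
        assert red_cr.inputs.values.tolist() == red_pr.inputs.values.tolist()
        assert len(red_cr.inputs) == len(sel.couples)
        assert (red_cr.readouts.values != red_pr.readouts.values).any()

    def test_experiments_carry_couple_observations(self):
        proc = make_processed([[1]], [[1]], [[0.75]], [[0.25]])
        sel = select_proteins(proc, k=1)[0]
        red_cr, red_pr = build_reduced_datasets(proc, sel)
        exp = red_cr.to_experiments()[0]
        assert exp.clamped == {"p1": 1}
        assert exp.observed == {"r1": 0.75}
        assert red_pr.to_experiments()[0].observed == {"r1": 0.25}

    def test_empty_selection_is_an_error(self):
        proc = make_processed([[1]], [[1]], [[0.1]], [[0.9]])
        sel = select_proteins(proc, k=1)[0]
        sel.couples = []
        with pytest.raises(ValueError, match="no couples"):
            build_reduced_datasets(proc, sel)
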