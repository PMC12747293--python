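import itertools
import math

import numpy as np
import pytest

from selscape.codon import (
    CODONS,
    N_CODONS,
    CodonAlignment,
    CodonModelParams,
    GeneFamilyEstimate,
    apply_retention_filters,
    build_codon_rate_matrix,
    count_mutations,
    estimate_dnds_ml,
    estimate_dnds_ng86,
    is_boundary,
    read_alignment,
    select_representative_paralog,
    simulate_alignment,
    subset_alignment,
    write_alignment,
)
from selscape.errors import EstimationDegenerateError, InvalidArgumentError
from selscape.synthetic import random_tree
from selscape.trees import Phylogeny

EQUAL_FREQS = np.full(N_CODONS, 1.0 / N_CODONS)

GENETIC_CODE = {  # independent copy of the standard code, sense codons only
    c: p
    for c, p in zip(
        CODONS,
        # translate via a hand-checked table independent of the package path
        [
            "K", "N", "K", "N", "T", "T", "T", "T", "R", "S", "R", "S",
            "I", "I", "M", "I", "Q", "H", "Q", "H", "P", "P", "P", "P",
            "R", "R", "R", "R", "L", "L", "L", "L", "E", "D", "E", "D",
            "A", "A", "A", "A", "G", "G", "G", "G", "V", "V", "V", "V",
            "Y", "Y", "S", "S", "S", "S", "C", "W", "C", "L", "F", "L",
            "F",
        ],
    )
}


def test_reference_code_table_is_consistent():
    from Bio.Seq import Seq

    for codon, aa in GENETIC_CODE.items():
        assert str(Seq(codon).translate()) == aa


class TestRateMatrix:
    def test_rows_sum_to_zero(self):
        q = build_codon_rate_matrix(CodonModelParams(0.3, 2.5))
        assert np.abs(q.sum(axis=1)).max() < 1e-10

    def test_neutral_symmetric_rates_equal(self):
        q = build_codon_rate_matrix(CodonModelParams(1.0, 1.0))
        off = q[~np.eye(N_CODONS, dtype=bool)]
        positive = off[off > 0]
        assert np.allclose(positive, positive[0])

    def test_omega_zero_kills_nonsynonymous(self):
        q = build_codon_rate_matrix(CodonModelParams(0.0, 2.0))
        for i, j in itertools.product(range(N_CODONS), repeat=2):
            if i == j:
                continue
            if GENETIC_CODE[CODONS[i]] != GENETIC_CODE[CODONS[j]]:
                assert q[i, j] == 0.0

    def test_multi_step_changes_zero(self):
        q = build_codon_rate_matrix(CodonModelParams(0.5, 2.0))
        for i, j in itertools.product(range(N_CODONS), repeat=2):
            diffs = sum(a != b for a, b in zip(CODONS[i], CODONS[j]))
            if diffs > 1:
                assert q[i, j] == 0.0

    def test_scaling_one_substitution_per_nt_site(self):
        for omega, kappa in [(0.1, 1.0), (1.0, 4.0), (2.0, 0.5)]:
            q = build_codon_rate_matrix(CodonModelParams(omega, kappa))
            assert -(EQUAL_FREQS @ np.diag(q)) == pytest.approx(3.0)

    def test_stationary_distribution_eigenvector_oracle(self):
        q = build_codon_rate_matrix(CodonModelParams(0.4, 3.0))
        # left null vector of Q is the stationary distribution
        eigvals, eigvecs = np.linalg.eig(q.T)
        k = np.argmin(np.abs(eigvals))
        pi = np.real(eigvecs[:, k])
        pi = pi / pi.sum()
        assert np.allclose(pi, EQUAL_FREQS, atol=1e-10)

    def test_detailed_balance_equal_frequencies(self):
        q = build_codon_rate_matrix(CodonModelParams(0.7, 2.0))
        assert np.allclose(
            EQUAL_FREQS[:, None] * q, (EQUAL_FREQS[:, None] * q).T, atol=1e-12
        )

    def test_invalid_params(self):
        with pytest.raises(InvalidArgumentError):
            CodonModelParams(0.5, -1.0)
        with pytest.raises(InvalidArgumentError):
            CodonModelParams(0.5, 2.0, np.full(N_CODONS, 1.0))


class TestSimulateAlignment:
    def test_zero_length_tree_identical_sequences(self):
        tree = Phylogeny.from_newick("((A:0,B:0)N1:0,C:0)R;")
        aln = simulate_alignment(tree, CodonModelParams(0.5, 2.0), 50, seed=1)
        assert len(set(aln.sequences)) == 1

    def test_omega_zero_preserves_protein(self):
        tree = random_tree(8, 2.0, 3)
        aln = simulate_alignment(tree, CodonModelParams(0.0, 2.0), 100, seed=2)
        proteins = set()
        for seq in aln.sequences:
            proteins.add(
                "".join(
                    GENETIC_CODE[seq[k : k + 3]] for k in range(0, len(seq), 3)
                )
            )
        assert len(proteins) == 1

    def test_event_count_poisson_oracle(self):
        tree = random_tree(10, 1.0, 11)
        _, events = simulate_alignment(
            tree,
            CodonModelParams(0.3, 2.0),
            1000,
            seed=5,
            return_events=True,
        )
        expected = 3.0 * 1000  # rate 3/codon site x tree length 1
        assert abs(events - expected) < 3 * math.sqrt(expected)

    def test_seed_determinism(self):
        tree = random_tree(5, 1.0, 0)
        params = CodonModelParams(0.4, 2.0)
        a = simulate_alignment(tree, params, 30, seed=9)
        b = simulate_alignment(tree, params, 30, seed=9)
        assert a.sequences == b.sequences

    def test_truncation(self):
        tree = random_tree(4, 1.0, 0)
        aln = simulate_alignment(tree, CodonModelParams(0.4, 2.0), 50, seed=1)
        short = aln.truncate_codons(20)
        assert short.length_codons == 20
        assert all(
            long.startswith(s) for long, s in zip(aln.sequences, short.sequences)
        )

    def test_invalid_codon_count(self):
        tree = random_tree(4, 1.0, 0)
        with pytest.raises(InvalidArgumentError):
            simulate_alignment(tree, CodonModelParams(0.4, 2.0), 0, seed=1)


class TestEstimateDndsMl:
    def test_recovers_omega_within_band(self):
        tree = random_tree(10, 1.0, 17)
        params = CodonModelParams(0.2, 2.0)
        aln = simulate_alignment(tree, params, 500, seed=23)
        est, loglik = estimate_dnds_ml(aln, tree)
        assert 0.15 <= est.omega <= 0.27
        assert 1.5 <= est.kappa <= 2.7
        assert not is_boundary(est)
        assert math.isfinite(loglik)

    def test_likelihood_at_truth_not_above_maximum(self):
        from selscape.codon import _log_likelihood, _pattern_table

        tree = random_tree(8, 1.0, 2)
        params = CodonModelParams(0.3, 2.0)
        aln = simulate_alignment(tree, params, 200, seed=3)
        est, maximized = estimate_dnds_ml(aln, tree)
        patterns, counts = _pattern_table(aln, tree.tip_labels)
        tip_index = {t: i for i, t in enumerate(tree.tip_labels)}
        at_truth = _log_likelihood(
            list(tree.postorder()), tip_index, patterns, counts, params
        )
        assert maximized >= at_truth - 1e-6

    def test_identical_sequences_degenerate(self):
        tree = Phylogeny.from_newick("((A:0.1,B:0.1)N1:0.1,C:0.1)R;")
        aln = CodonAlignment(("A", "B", "C"), ("ATGGCT",) * 3)
        with pytest.raises(EstimationDegenerateError):
            estimate_dnds_ml(aln, tree)

    def test_taxa_mismatch(self):
        tree = Phylogeny.from_newick("((A:0.1,B:0.1)N1:0.1,C:0.1)R;")
        aln = CodonAlignment(("A", "B", "X"), ("ATGGCT", "ATGGCA", "ATGGCC"))
        with pytest.raises(InvalidArgumentError):
            estimate_dnds_ml(aln, tree)


def oracle_ng86(seq_a: str, seq_b: str):
    """Independent Nei-Gojobori oracle: explicit per-codon enumeration."""

    def site_counts(codon):
        syn = nonsyn = 0.0
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if alt not in GENETIC_CODE:  # stop
                    continue
                if GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                    syn += 1.0 / 3.0
                else:
                    nonsyn += 1.0 / 3.0
        return syn, nonsyn

    def diff_counts(ca, cb):
        positions = [k for k in range(3) if ca[k] != cb[k]]
        if not positions:
            return 0.0, 0.0
        syn_counts = []
        for order in itertools.permutations(positions):
            current, syn = ca, 0
            ok = True
            for pos in order:
                nxt = current[:pos] + cb[pos] + current[pos + 1 :]
                if nxt not in GENETIC_CODE:
                    ok = False
                    break
                syn += GENETIC_CODE[current] == GENETIC_CODE[nxt]
                current = nxt
            if ok:
                syn_counts.append(syn)
        mean_syn = float(np.mean(syn_counts))
        return mean_syn, len(positions) - mean_syn

    S = N = sd = nd = 0.0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        sa, na = site_counts(ca)
        sb, nb = site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        d_s, d_n = diff_counts(ca, cb)
        sd += d_s
        nd += d_n

    def jc(p):
        return math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(nd / N), jc(sd / S)


class TestNg86:
    def test_identical_sequences(self):
        d_n, d_s, ratio = estimate_dnds_ng86("ATGGCT", "ATGGCT")
        assert d_n == 0.0 and d_s == 0.0 and ratio is None

    def test_single_synonymous_difference(self):
        d_n, d_s, ratio = estimate_dnds_ng86("TTT", "TTC")
        assert d_n == 0.0
        assert d_s > 0.0
        assert ratio == 0.0

    def test_unequal_lengths(self):
        with pytest.raises(InvalidArgumentError):
            estimate_dnds_ng86("ATG", "ATGGCT")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        tree = random_tree(2, 0.4, seed)
        aln = simulate_alignment(
            tree, CodonModelParams(0.5, 2.0), 100, seed=seed + 50
        )
        a, b = aln.sequences
        d_n, d_s, _ = estimate_dnds_ng86(a, b)
        o_n, o_s = oracle_ng86(a, b)
        assert d_n == pytest.approx(o_n, abs=1e-10)
        assert d_s == pytest.approx(o_s, abs=1e-10)

    def test_ml_ng86_rank_agreement(self):
        # pairwise alignments across an omega grid; the two estimators must
        # rank them consistently
        ml, ng = [], []
        k = 0
        for omega in (0.1, 0.5, 1.0):
            for rep in range(12):
                k += 1
                tree = random_tree(2, 0.5, k)
                aln = simulate_alignment(
                    tree, CodonModelParams(omega, 2.0), 500, seed=1000 + k
                )
                try:
                    est, _ = estimate_dnds_ml(aln, tree)
                except EstimationDegenerateError:
                    continue
                d_n, d_s, ratio = estimate_dnds_ng86(*aln.sequences)
                if ratio is None:
                    continue
                ml.append(est.omega)
                ng.append(ratio)
        from selscape.stats import spearman_rho

        assert len(ml) >= 30
        assert spearman_rho(np.array(ml), np.array(ng)) >= 0.9


class TestCountMutations:
    def test_values(self):
        assert count_mutations(0.2, 300) == 60.0
        assert count_mutations(0.0, 500) == 0.0
        assert count_mutations(0.1, 300) == 30.0  # fails the 32 threshold

    def test_negative_rejected(self):
        with pytest.raises(InvalidArgumentError):
            count_mutations(-0.1, 300)


def _estimate(lineage, gene, tree_length, n_sites=300, n_seqs=5):
    return GeneFamilyEstimate(
        lineage_id=lineage,
        gene_id=gene,
        dnds=0.3,
        kappa=2.0,
        n_sequences=n_seqs,
        n_sites_nt=n_sites,
        tree_length=tree_length,
        log_likelihood=-1000.0,
    )


class TestRetentionFilters:
    def test_seventy_percent_boundary_inclusive(self):
        ests = [_estimate("L1", f"g{i}", 0.2) for i in range(7)]  # 60 muts
        ests += [_estimate("L1", f"h{i}", 0.05) for i in range(3)]  # 15 muts
        result = apply_retention_filters(ests)
        assert result.lineages == ("L1",)
        assert len(result.families) == 7

    def test_below_seventy_percent_excluded(self):
        ests = [_estimate("L1", f"g{i}", 0.2) for i in range(6)]
        ests += [_estimate("L1", f"h{i}", 0.05) for i in range(4)]
        result = apply_retention_filters(ests)
        assert result.lineages == ()
        assert result.families == ()
        assert any(kind == "lineage" for kind, _, _ in result.exclusions)

    def test_exactly_32_mutations_retained(self):
        ests = [_estimate("L1", f"g{i}", 32 / 300) for i in range(10)]
        result = apply_retention_filters(ests)
        assert len(result.families) == 10

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ests = [
            _estimate(f"L{i % 4}", f"g{i}", float(rng.uniform(0.05, 0.3)))
            for i in range(40)
        ]
        once = apply_retention_filters(ests)
        twice = apply_retention_filters(once.families)
        assert twice.lineages == once.lineages
        assert twice.families == once.families

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            apply_retention_filters([])


class TestSelectRepresentativeParalog:
    def test_largest_wins(self):
        assert select_representative_paralog({"grp": {"famA": 10, "famB": 7}}) == {
            "grp": "famA"
        }

    def test_lexicographic_tie_break(self):
        assert select_representative_paralog({"grp": {"famB": 5, "famA": 5}}) == {
            "grp": "famA"
        }

    def test_single_member(self):
        assert select_representative_paralog({"grp": {"famZ": 1}}) == {
            "grp": "famZ"
        }

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            select_representative_paralog({"grp": {}})


class TestAlignmentIO:
    def test_fasta_roundtrip(self, tmp_path):
        tree = random_tree(5, 1.0, 0)
        aln = simulate_alignment(tree, CodonModelParams(0.4, 2.0), 40, seed=1)
        path = tmp_path / "aln.fna"
        write_alignment(aln, path)
        again = read_alignment(path)
        assert again.taxa == aln.taxa
        assert again.sequences == aln.sequences

    def test_subset(self):
        aln = CodonAlignment(("A", "B", "C"), ("ATGGCT", "ATGGCA", "ATGGCC"))
        sub = subset_alignment(aln, ["C", "A"])
        assert sub.taxa == ("C", "A")
        assert sub.sequences == ("ATGGCC", "ATGGCT")

    def test_stop_codon_rejected(self):
        with pytest.raises(InvalidArgumentError):
            CodonAlignment(("A", "B"), ("ATGTAA", "ATGGCA"))
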