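"""Nucleotide diversity, distance models, NG86 Ka/Ks and neighbor joining."""
import itertools
import math
import warnings

import numpy as np
import pytest

from mitocomp.divergence import (
    AlignmentError,
    AlignmentSet,
    CodingSequenceError,
    mean_pairwise,
    ng86_kaks,
    nj_tree,
    nucleotide_diversity,
    pairwise_distance,
    sliding_window_pi,
)


def _aln(seqs, gene="g", codon_aware=False):
    return AlignmentSet(gene, [f"t{i}" for i in range(len(seqs))], list(seqs),
                        codon_aware)


class TestPi:
    def test_identical_sequences(self):
        assert nucleotide_diversity(_aln(["ACGT" * 25] * 3)) == 0.0

    def test_two_sequences_one_difference(self):
        a = "A" * 100
        b = "A" * 99 + "C"
        assert nucleotide_diversity(_aln([a, b])) == pytest.approx(0.01)

    def test_three_sequences_enumerated_pairs(self):
        base = "A" * 100
        s1 = base
        s2 = "C" + base[1:]            # 1 diff to s1
        s3 = base[0] + "GG" + base[3:]  # 2 diffs to s1, 3 to s2
        # pairs: (s1,s2)=1, (s1,s3)=2, (s2,s3)=3 -> mean = 6/300 = 0.02
        assert nucleotide_diversity(_aln([s1, s2, s3])) == pytest.approx(0.02)

    def test_complete_deletion_drops_gapped_columns(self):
        a = "ACGTAC"
        b = "AC-TAC"
        c = "ACGTAT"
        pi = nucleotide_diversity(_aln([a, b, c]), deletion="complete")
        # column 2 removed for everyone: 5 sites, diffs (a,b)=0 (a,c)=1 (b,c)=1
        assert pi == pytest.approx((0 + 1 / 5 + 1 / 5) / 3)

    def test_pi_equals_mean_p_distance(self):
        """Oracle equivalence on random alignments (pairwise deletion)."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            n, L = int(rng.integers(2, 21)), int(rng.integers(50, 301))
            seqs = ["".join(rng.choice(list("ACGTN-"), size=L,
                                       p=[.22, .22, .22, .22, .06, .06]))
                    for _ in range(n)]
            aln = _aln(seqs)
            pi = nucleotide_diversity(aln, deletion="pairwise")
            mat = pairwise_distance(aln, "p")
            assert pi == pytest.approx(mean_pairwise(mat), rel=1e-12)

    def test_fewer_than_two_taxa_rejected(self):
        with pytest.raises(AlignmentError):
            nucleotide_diversity(_aln(["ACGT"]))


class TestSlidingWindow:
    def test_window_starts_at_stated_step(self):
        aln = _aln(["A" * 200, "A" * 200])
        wd = sliding_window_pi(aln, 100, 25)
        assert wd.starts == [0, 25, 50, 75, 100]
        assert not wd.tail_window

    def test_trailing_window_flagged(self):
        aln = _aln(["A" * 210, "A" * 210])
        wd = sliding_window_pi(aln, 100, 25)
        assert wd.starts[-1] == 110
        assert wd.tail_window

    def test_identical_rows_all_zero(self):
        aln = _aln(["ACGT" * 50] * 4)
        wd = sliding_window_pi(aln, 100, 25)
        assert all(v == 0.0 for v in wd.pi)
        assert wd.overall_pi == 0.0

    def test_bad_parameters(self):
        aln = _aln(["A" * 200] * 2)
        with pytest.raises(AlignmentError):
            sliding_window_pi(aln, 1, 25)
        with pytest.raises(AlignmentError):
            sliding_window_pi(aln, 100, 0)


def _pair_with_p(p, L=1000, seed=0):
    rng = np.random.default_rng(seed)
    a = "".join(rng.choice(list("ACGT"), size=L))
    k = int(round(p * L))
    sites = rng.choice(L, size=k, replace=False)
    b = list(a)
    for s in sites:
        b[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[s]]
    return a, "".join(b)


class TestDistances:
    def test_identical_pair_zero_under_every_model(self):
        a = "ACGT" * 100
        for model in ("p", "JC69", "K2P", "TN93", "MCL-composite"):
            mat = pairwise_distance(_aln([a, a]), model)
            assert mat.iloc[0, 1] == pytest.approx(0.0)

    def test_jc69_closed_form(self):
        a, b = _pair_with_p(0.3)
        d = pairwise_distance(_aln([a, b]), "JC69").iloc[0, 1]
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.3 / 3), abs=1e-9)
        assert d == pytest.approx(0.3831, abs=1e-4)

    def test_jc69_dominates_p(self):
        for p in (0.05, 0.2, 0.5, 0.7):
            a, b = _pair_with_p(p, seed=3)
            jc = pairwise_distance(_aln([a, b]), "JC69").iloc[0, 1]
            assert jc >= p - 1e-9

    def test_models_agree_to_first_order(self):
        a, b = _pair_with_p(0.01, L=10000, seed=5)
        values = [pairwise_distance(_aln([a, b]), m).iloc[0, 1]
                  for m in ("p", "JC69", "K2P", "TN93", "MCL-composite")]
        for v in values[1:]:
            assert v == pytest.approx(0.01, rel=0.01)

    def test_saturated_pair_flagged_not_clamped(self):
        a = "A" * 300
        b = "C" * 300
        d = pairwise_distance(_aln([a, b]), "JC69").iloc[0, 1]
        assert math.isnan(d)

    def test_mcl_composite_close_to_tn93(self, evolved_set):
        _, _, alns = evolved_set
        aln = alns["cox1"]
        tn = pairwise_distance(aln, "TN93")
        mcl = pairwise_distance(aln, "MCL-composite")
        assert np.allclose(tn.values, mcl.values, atol=0.01)


def _oracle_codon_sites(codon):
    """Independent per-codon site counter via Biopython translation."""
    from Bio.Seq import Seq

    def aa(c):
        return str(Seq(c).translate(table=5))

    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if aa(alt) == "*":
                continue
            tot += 1
            syn += aa(alt) == aa(codon)
        if tot:
            s += syn / tot
    return s, 3.0 - s


class TestNg86:
    def test_identical_pair(self):
        r = ng86_kaks("ATGGGA", "ATGGGA")
        assert (r.ka, r.ks, r.ratio) == (0.0, 0.0, None)

    def test_single_synonymous_change(self):
        # one Gly GGT->GGC swap in a ten-codon context: purely synonymous
        r = ng86_kaks("GGT" * 10, "GGC" + "GGT" * 9)
        assert r.ka == 0.0
        assert r.ks > 0.0
        assert r.s_diffs == 1.0 and r.n_diffs == 0.0

    def test_single_nonsynonymous_change(self):
        r = ng86_kaks("GGT", "GTT")  # Gly -> Val
        assert r.n_diffs == 1.0 and r.s_diffs == 0.0

    def test_site_conservation_s_plus_n(self):
        rng = np.random.default_rng(11)
        from mitocomp.codon_usage import genetic_code

        codons = sorted(genetic_code(5))
        seq = "".join(rng.choice(codons, size=200))
        r = ng86_kaks(seq, seq)
        assert r.s_sites + r.n_sites == pytest.approx(3 * 200)

    def test_site_counts_match_translation_oracle(self):
        from mitocomp.codon_usage import genetic_code

        for codon in sorted(genetic_code(5)):
            r = ng86_kaks(codon, codon)
            s, n = _oracle_codon_sites(codon)
            assert r.s_sites == pytest.approx(s)
            assert r.n_sites == pytest.approx(n)

    def test_multi_hit_codon_averages_pathways(self):
        # TTT (Phe) vs TTA (Leu) vs pathway-free check: CTT (Leu) vs TTA (Leu)
        # paths: CTT->TTT(F, non-syn)->TTA(L, non-syn) or CTT->CTA(L, syn)->TTA(L, syn)
        r = ng86_kaks("CTT", "TTA")
        assert r.s_diffs == pytest.approx(1.0)
        assert r.n_diffs == pytest.approx(1.0)

    def test_internal_stop_raises_with_position(self):
        with pytest.raises(CodingSequenceError, match="codon 2"):
            ng86_kaks("ATGTAAGGG", "ATGTAAGGG")

    def test_terminal_stop_tolerated(self):
        r = ng86_kaks("ATGGGATAA", "ATGGGGTAA")
        assert r.s_diffs == 1.0

    def test_agreement_with_biopython_ng86(self):
        """Cross-check Ka/Ks against the independent Biopython estimator.

        The two implementations differ only in how mutational paths through
        stop codons enter the site counts, so they agree to a few percent.
        """
        from Bio.Align import Alignment, analysis
        from Bio.Data import CodonTable

        from mitocomp.synthetic import evolve_codon_sequence, _codon_distribution, _AA_PROFILE_AT

        dist = _codon_distribution(_AA_PROFILE_AT, 0.15, 1.0, "J", -0.15, 0.36)
        codons, probs = list(dist), np.array(list(dist.values()))
        probs /= probs.sum()
        rng = np.random.default_rng(5)
        root = "".join(rng.choice(codons, size=500, p=probs))
        a = evolve_codon_sequence(root, 0.03, 0.3, 2.0, rng)
        b = evolve_codon_sequence(root, 0.03, 0.3, 2.0, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aln = Alignment([a, b], np.array([[0, len(a)], [0, len(b)]]))
            dn, ds = analysis.calculate_dn_ds(
                aln, method="NG86",
                codon_table=CodonTable.unambiguous_dna_by_id[5])
        r = ng86_kaks(a, b)
        assert r.ka == pytest.approx(dn, rel=0.05)
        assert r.ks == pytest.approx(ds, rel=0.05)

    def test_synonymous_only_divergence_gives_zero_ka(self):
        """Sequences differing only by synonymous third-position swaps."""
        pairs = {"TTT": "TTC", "GGA": "GGG", "CCT": "CCA", "ATT": "ATC"}
        spacer = "ATGATTAAAGGA" * 4  # identical context dilutes pS below 1
        a = "".join(c + spacer for c in pairs) * 10
        b = "".join(pairs[c] + spacer for c in pairs) * 10
        r = ng86_kaks(a, b)
        assert r.ka == 0.0
        assert r.ks > 0.0


class TestNeighborJoining:
    def _matrix(self, labels, d):
        import pandas as pd

        return pd.DataFrame(d, index=labels, columns=labels, dtype=float)

    def test_two_taxa_edge_length(self):
        import dendropy

        mat = self._matrix(["A", "B"], [[0, 0.4], [0.4, 0]])
        tree = dendropy.Tree.get(data=nj_tree(mat), schema="newick")
        assert sum(e.length or 0 for e in tree.edges()) == pytest.approx(0.4)

    def test_three_equidistant_taxa_star(self):
        import dendropy

        mat = self._matrix(["A", "B", "C"],
                           [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        tree = dendropy.Tree.get(data=nj_tree(mat), schema="newick")
        lengths = sorted(leaf.edge.length for leaf in tree.leaf_node_iter())
        assert lengths == pytest.approx([0.5, 0.5, 0.5])

    def test_additive_four_taxon_matrix_recovers_topology(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> path-length matrix
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        newick = nj_tree(self._matrix(list("ABCD"), d))
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.encode_bipartitions()
        splits = {frozenset(leaf.taxon.label for leaf in node.leaf_iter())
                  for node in tree if not node.is_leaf()}
        assert {"A", "B"} in splits or {"C", "D"} in splits

    def test_matches_scikit_bio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        import dendropy

        rng = np.random.default_rng(4)
        n = 6
        x = rng.random((n, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(n)]
        import io

        ours = nj_tree(self._matrix(labels, d))
        buf = io.StringIO()
        skbio_nj(DistanceMatrix(d, ids=labels)).write(buf)
        theirs = buf.getvalue()
        taxa = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=taxa)
        t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=taxa)
        rf = dendropy.calculate.treecompare.symmetric_difference(
            t1, t2, is_bipartitions_updated=False)
        assert rf == 0

    def test_asymmetric_matrix_rejected(self):
        mat = self._matrix(["A", "B"], [[0, 1], [2, 0]])
        with pytest.raises(AlignmentError):
            nj_tree(mat)


class TestAlignmentSet:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            _aln(["ACGT", "ACG"])

    def test_codon_aware_length_checked(self):
        with pytest.raises(AlignmentError):
            _aln(["ACGT", "ACGA"], codon_aware=True)
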