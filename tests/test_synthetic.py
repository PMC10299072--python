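"""The synthetic-genome generator: determinism, structure, and closure of
generated parameters under the package's own analyses."""
import numpy as np
import pytest

from mitocomp.codon_usage import bias_summary, count_codons, enc
from mitocomp.composition import base_composition
from mitocomp.divergence import ng86_kaks, nucleotide_diversity
from mitocomp.genome_io import extract_gene_sequence, write_genbank
from mitocomp.synthetic import (
    DivergenceSpec,
    RepeatSpec,
    SyntheticSpec,
    SyntheticSpecError,
    TdrlEvent,
    evolve_codon_sequence,
    evolve_set,
    expected_enc,
    generate_mitogenome,
    pooled_codon_distribution,
    profile_for_gc12,
)


class TestStructure:
    def test_gene_inventory(self, default_genome):
        assert default_genome.counts_by_type() == {
            "PCG": 13, "tRNA": 22, "rRNA": 2, "CR": 1}

    def test_strand_split_matches_salticid_layout(self, default_genome):
        pcg_n = {f.name for f in default_genome.features_of_type("PCG")
                 if f.strand == "N"}
        assert pcg_n == {"nad1", "nad4", "nad4L", "nad5"}
        assert all(f.strand == "N" for f in default_genome.features_of_type("rRNA"))
        trna_j = sum(f.strand == "J" for f in default_genome.features_of_type("tRNA"))
        assert trna_j == 13

    def test_cr_sits_between_trnq_and_trnm(self, default_genome):
        feats = sorted(default_genome.features, key=lambda f: f.start)
        names = [f.name for f in feats]
        i = names.index("CR")
        assert names[i - 1] == "trnQ"
        assert names[(i + 1) % len(names)] == "trnM"

    def test_genome_length_realistic(self, default_genome):
        assert 14000 <= len(default_genome) <= 15500


class TestDeterminism:
    def test_same_seed_same_genbank_bytes(self, tmp_path):
        spec = SyntheticSpec(seed=4)
        p1, p2 = tmp_path / "a.gb", tmp_path / "b.gb"
        write_genbank(generate_mitogenome(spec), p1)
        write_genbank(generate_mitogenome(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_different_sequence(self):
        a = generate_mitogenome(SyntheticSpec(seed=4))
        b = generate_mitogenome(SyntheticSpec(seed=5))
        assert a.sequence != b.sequence

    def test_evolve_set_deterministic(self):
        spec = SyntheticSpec(seed=6, divergence=DivergenceSpec(
            n_taxa=2, branch_length=0.02))
        root = generate_mitogenome(spec)
        g1, _ = evolve_set(root, spec)
        g2, _ = evolve_set(root, spec)
        assert [g.sequence for g in g1] == [g.sequence for g in g2]


class TestCompositionClosure:
    def test_stated_example_targets(self):
        g = generate_mitogenome(SyntheticSpec(seed=5, at_content=0.74,
                                              at_skew=-0.12))
        r = base_composition(g.sequence)
        assert r.at_content == pytest.approx(0.74, abs=0.01)
        assert r.at_skew == pytest.approx(-0.12, abs=0.01)

    def test_enc_tracks_usage_concentration(self):
        """Realized ENC within 1 of the analytic target implied by the
        codon-weight concentration, at >= 5000 pooled codons."""
        for conc in (1.0, 2.0):
            seqs = []
            for seed in (21, 22):  # two genomes -> ~7300 pooled codons
                g = generate_mitogenome(SyntheticSpec(
                    seed=seed, usage_concentration=conc))
                seqs += [extract_gene_sequence(g, f.name)
                         for f in g.features_of_type("PCG")]
            table = count_codons(seqs)
            assert table.total_codons >= 5000
            realized, _ = enc(table)
            from mitocomp.synthetic import _AA_PROFILE_AT

            target = expected_enc(pooled_codon_distribution(
                _AA_PROFILE_AT, 0.15, conc, -0.15, 0.36))
            assert realized == pytest.approx(target, abs=1.0)

    def test_gc12_targeting_is_exact_in_expectation(self):
        dist = pooled_codon_distribution(
            profile_for_gc12(0.12, 1.0, 0.31, -0.15, 0.36),
            0.12, 1.0, -0.15, 0.36)
        from mitocomp.synthetic import expected_positional_gc

        g1, g2, _ = expected_positional_gc(dist)
        assert (g1 + g2) / 2 == pytest.approx(0.31, abs=1e-9)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(SyntheticSpecError):
            SyntheticSpec(at_content=1.4)
        with pytest.raises(SyntheticSpecError):
            SyntheticSpec(at_skew=-2.0)
        with pytest.raises(SyntheticSpecError):
            SyntheticSpec(repeat=RepeatSpec(period=300, full_copies=5),
                          cr_length=800)
        with pytest.raises(SyntheticSpecError):
            DivergenceSpec(omega=-0.5)


class TestTdrlRoundTrip:
    def test_single_event_detected_by_order_analysis(self, shuffled_genome,
                                                     reference_order):
        from mitocomp.gene_order import compare_orders, extract_gene_order

        calls = compare_orders(extract_gene_order(shuffled_genome),
                               reference_order)
        assert [c.kind for c in calls] == ["tRNA-shuffle"]
        assert calls[0].tdrl_events == 1

    def test_event_application_is_window_local(self, reference_order):
        ev = TdrlEvent(2, 5, (True, False, True))
        out = ev.apply(reference_order)
        assert out.names[:2] == reference_order.names[:2]
        assert out.names[5:] == reference_order.names[5:]
        assert sorted(out.names[2:5]) == sorted(reference_order.names[2:5])

    def test_bad_keep_pattern_rejected(self, reference_order):
        with pytest.raises(SyntheticSpecError):
            TdrlEvent(0, 3, (True,)).apply(reference_order)


class TestDivergenceClosure:
    def test_zero_branch_length_keeps_sequences(self):
        spec = SyntheticSpec(seed=8, divergence=DivergenceSpec(
            n_taxa=3, branch_length=0.0))
        root = generate_mitogenome(spec)
        genomes, alns = evolve_set(root, spec)
        assert all(g.sequence == root.sequence for g in genomes)
        assert nucleotide_diversity(alns["cox1"]) == 0.0

    def test_pairwise_divergence_matches_branch_lengths(self):
        """Two tips at t=0.01 each: expected p-distance 0.02 +- 0.005."""
        spec = SyntheticSpec(seed=9, divergence=DivergenceSpec(
            n_taxa=2, branch_length=0.01, omega=1.0, kappa=1.0))
        root = generate_mitogenome(spec)
        _, alns = evolve_set(root, spec)
        a = "".join(alns[g].sequences[0] for g in sorted(alns))
        b = "".join(alns[g].sequences[1] for g in sorted(alns))
        assert len(a) >= 10000
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        assert p == pytest.approx(0.02, abs=0.005)

    def test_omega_zero_gives_zero_ka(self):
        rng = np.random.default_rng(10)
        root = "ATGATTAAAGGATTTCTT" * 300
        a = evolve_codon_sequence(root, 0.05, 0.0, 2.0, rng)
        b = evolve_codon_sequence(root, 0.05, 0.0, 2.0, rng)
        r = ng86_kaks(a, b)
        # multi-hit codons can route a pathway through a nonsynonymous
        # intermediate, so Ka is only asymptotically zero
        assert r.ka < 1e-3
        assert r.ratio is not None and r.ratio < 0.01
        assert r.ks > 0.0

    def test_neutral_omega_recovered(self):
        """Neutral simulation (omega=1, kappa=1) recovers Ka/Ks within 0.1."""
        rng = np.random.default_rng(12)
        from mitocomp.synthetic import _AA_PROFILE_AT, _codon_distribution

        dist = _codon_distribution(_AA_PROFILE_AT, 0.15, 1.0, "J", -0.15, 0.36)
        codons, probs = list(dist), np.array(list(dist.values()))
        probs /= probs.sum()
        root = "".join(rng.choice(codons, size=10000, p=probs))
        a = evolve_codon_sequence(root, 0.05, 1.0, 1.0, rng)
        b = evolve_codon_sequence(root, 0.05, 1.0, 1.0, rng)
        assert ng86_kaks(a, b).ratio == pytest.approx(1.0, abs=0.1)

    def test_alignments_are_codon_aware_and_gap_free(self, evolved_set):
        _, _, alns = evolved_set
        for aln in alns.values():
            assert aln.codon_aware
            assert aln.length % 3 == 0
            assert all("-" not in s and set(s) <= set("ACGT")
                       for s in aln.sequences)


class TestNeutralityGrid:
    def test_grid_recovers_coupling_slope(self):
        from mitocomp.codon_usage import neutrality_fit
        from mitocomp.synthetic import generate_genome_grid

        genomes = generate_genome_grid(seed=1, n=9, coupling=0.249)
        pts = []
        for g in genomes:
            seqs = [extract_gene_sequence(g, f.name)
                    for f in g.features_of_type("PCG")]
            s = bias_summary(seqs)
            pts.append((s.gc3, s.gc12))
        fit = neutrality_fit(pts)
        assert fit.slope == pytest.approx(0.249, abs=0.1)
        assert fit.r > 0.5
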