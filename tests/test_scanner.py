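from itertools import product

import numpy as np
import pytest

from argbox import scanner
from argbox.iimodel import build_model_from_sequences, consensus, ri_score
from argbox.scanner import (
    GeneAnnotation,
    ScanHit,
    assemble_sites,
    associate_genes,
    distance_to_start,
    pvalue,
    scan,
    score_distribution,
)
from argbox.seqio import ALPHABET, GenomicInterval, NucleotideSequence, reverse_complement

from conftest import toy_model

UNIFORM = np.full(4, 0.25)
GC72 = np.array([0.14, 0.36, 0.36, 0.14])


def brute_force_sf(weights, q, granularity):
    """Upper-tail probabilities from full enumeration (same binning)."""
    L = weights.shape[1]
    w_int = np.round(weights / granularity).astype(np.int64)
    scores, probs = {}, {}
    for kmer in product(range(4), repeat=L):
        s = int(sum(w_int[b, l] for l, b in enumerate(kmer)))
        p = float(np.prod([q[b] for b in kmer]))
        probs[s] = probs.get(s, 0.0) + p
    achievable = sorted(probs)
    sf = {}
    running = 0.0
    for s in reversed(achievable):
        running += probs[s]
        sf[s] = running
    return {s * granularity: v for s, v in sf.items()}


class TestScoreDistribution:
    def test_single_position_uniform_mass(self):
        w = np.array([[2.0], [0.0], [0.5], [-2.0]])
        dist = score_distribution(w, UNIFORM, granularity=0.001)
        assert np.isclose(dist.pmf.sum(), 1.0, atol=1e-12)
        nz = dist.pmf[dist.pmf > 0]
        assert np.allclose(nz, 0.25)

    @pytest.mark.parametrize("width", [3, 4, 5])
    @pytest.mark.parametrize("q", [UNIFORM, GC72], ids=["uniform", "gc72"])
    def test_dp_equals_enumeration_at_every_achievable_score(self, width, q):
        model = toy_model(width=width, n=9, seed=width)
        dist = score_distribution(model.weights, q, granularity=1e-3)
        oracle = brute_force_sf(model.weights, q, granularity=1e-3)
        for score, expected in oracle.items():
            assert pvalue(dist, score) == pytest.approx(expected, abs=1e-12)

    def test_pmf_sums_to_one(self):
        model = toy_model(width=6, n=11, seed=3)
        dist = score_distribution(model.weights, GC72)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_score_below_support_has_p_one(self):
        model = toy_model(width=4, n=5, seed=1)
        dist = score_distribution(model.weights, UNIFORM)
        assert pvalue(dist, dist.support_min - 1.0) == 1.0

    def test_consensus_pvalue_is_product_of_background(self):
        # unique per-column maxima guarantee a single top-scoring k-mer
        model = next(
            m
            for m in (toy_model(width=5, n=9, seed=s) for s in range(20))
            if all(
                np.sum(m.pfm.frequencies[:, l] == m.pfm.frequencies[:, l].max()) == 1
                for l in range(5)
            )
        )
        dist = score_distribution(model.weights, GC72, granularity=1e-3)
        cons = consensus(model)
        codes = [ALPHABET.index(c) for c in cons.residues]
        expected = float(np.prod([GC72[b] for b in codes]))
        assert pvalue(dist, ri_score(model, cons)) == pytest.approx(expected, abs=1e-12)

    def test_coarse_granularity_rejected(self):
        model = toy_model(width=3, n=5, seed=0)
        with pytest.raises(scanner.ResolutionError):
            score_distribution(model.weights, UNIFORM, granularity=1e3)


class TestScan:
    def test_consensus_genome_yields_its_own_hit(self, arg_model):
        cons = consensus(arg_model)
        genome = NucleotideSequence("g", cons.residues)
        hits = scan(genome, arg_model, background=UNIFORM)
        assert hits and {h.strand for h in hits} <= {"+", "-"}
        assert all((h.interval.left, h.interval.right) == (1, 20) for h in hits)
        assert hits[0].ri == pytest.approx(ri_score(arg_model, cons), abs=1e-9)

    def test_all_A_genome_has_no_hits(self, arg_model):
        genome = NucleotideSequence("g", "A" * 2000)
        assert scan(genome, arg_model, background=UNIFORM) == []

    def test_ambiguous_windows_skipped(self, arg_model):
        cons = consensus(arg_model).residues
        genome = NucleotideSequence("g", cons[:10] + "N" + cons[10:])
        # the only strong windows all contain the N and must be skipped
        hits = scan(genome, arg_model, background=UNIFORM)
        assert hits == []

    def test_reverse_complement_mirror(self, plain_model):
        """Scanning a sequence and its reverse complement gives mirrored hits."""
        rng = np.random.default_rng(5)
        residues = "".join(ALPHABET[b] for b in rng.integers(0, 4, 3000))
        cons = consensus(plain_model).residues
        residues = residues[:1000] + cons + residues[1000 + 20 :]
        g = NucleotideSequence("g", residues)
        g_rc = NucleotideSequence("g", reverse_complement(residues))
        fwd = scan(g, plain_model, p_max=1e-3, ri_min=5.0, background=UNIFORM)
        rev = scan(g_rc, plain_model, p_max=1e-3, ri_min=5.0, background=UNIFORM)
        n = len(residues)
        mirrored = sorted(
            (n - h.interval.right + 1, n - h.interval.left + 1,
             "+" if h.strand == "-" else "-", round(h.ri, 9))
            for h in rev
        )
        direct = sorted(
            (h.interval.left, h.interval.right, h.strand, round(h.ri, 9))
            for h in fwd
        )
        assert fwd and direct == mirrored

    def test_filter_monotonicity(self, arg_model):
        rng = np.random.default_rng(9)
        p = np.array([0.14, 0.36, 0.36, 0.14])
        residues = "".join(ALPHABET[b] for b in rng.choice(4, 100_000, p=p))
        g = NucleotideSequence("g", residues)
        loose = scan(g, arg_model, p_max=1e-3, ri_min=4.0)
        tighter_p = scan(g, arg_model, p_max=1e-4, ri_min=4.0)
        tighter_ri = scan(g, arg_model, p_max=1e-3, ri_min=8.0)
        assert len(tighter_p) <= len(loose)
        assert len(tighter_ri) <= len(loose)
        assert loose

    def test_background_hit_rate_matches_null(self):
        """Raw both-strand hit count on i.i.d. background tracks
        2*(G-L+1)*Pr(pass) within 3 SD over 20 seeds."""
        model = toy_model(width=6, n=12, seed=4)
        G = 20_000
        q = GC72
        dist = score_distribution(model.weights, q)
        # disable the Ri filter so the pass probability is exactly the
        # upper tail of the p-value statistic at the p_max cut
        p_max = 1e-3
        k = np.searchsorted(-dist.sf, -p_max, side="right")
        p_pass = float(dist.sf[k]) if k < len(dist.sf) else 0.0
        expected = 2 * (G - 6 + 1) * p_pass
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            residues = "".join(ALPHABET[b] for b in rng.choice(4, G, p=q))
            g = NucleotideSequence("g", residues)
            hits = scan(g, model, p_max=p_max, ri_min=-1e9, background=q)
            counts.append(len(hits))
        total, exp_total = sum(counts), 20 * expected
        assert abs(total - exp_total) <= 3 * np.sqrt(exp_total)


class TestAssembly:
    @staticmethod
    def _hit(left, ri=12.0, strand="+", chrom="c"):
        return ScanHit(GenomicInterval(chrom, left, left + 19), strand, ri, 1e-7)

    def test_gap0_pair_becomes_contiguous_tandem(self):
        sites = assemble_sites([self._hit(1), self._hit(21)])
        assert [s.architecture.kind for s in sites] == ["tandem_contiguous"]
        assert sites[0].combined_score == pytest.approx(24.0)

    def test_gap1_pair(self):
        sites = assemble_sites([self._hit(1), self._hit(22)])
        assert [s.architecture.kind for s in sites] == ["tandem_gap1"]

    def test_three_adjacent_greedy_leftmost_pair(self):
        sites = assemble_sites([self._hit(1), self._hit(21), self._hit(41)])
        assert [s.architecture.kind for s in sites] == [
            "tandem_contiguous",
            "single",
        ]

    def test_both_strand_duplicates_collapse(self):
        sites = assemble_sites([self._hit(1, strand="+"), self._hit(1, strand="-")])
        assert len(sites) == 1 and sites[0].architecture.kind == "single"

    def test_distant_hits_stay_single(self):
        sites = assemble_sites([self._hit(1), self._hit(100)])
        assert [s.architecture.kind for s in sites] == ["single", "single"]


class TestGeneAssociation:
    def test_distance_to_plus_strand_start(self):
        gene = GeneAnnotation("g1", "c", "+", start_codon=151, left=151, right=600)
        assert distance_to_start(GenomicInterval("c", 101, 120), gene) == 30

    def test_site_abutting_start_is_zero(self):
        gene = GeneAnnotation("g1", "c", "+", start_codon=121, left=121, right=400)
        assert distance_to_start(GenomicInterval("c", 101, 120), gene) == 0

    def test_overlapping_start_is_negative(self):
        # mirrors the pyrR case: box end 13 nt past the start codon
        gene = GeneAnnotation("g1", "c", "+", start_codon=1592077, left=1592077, right=1593000)
        site = GenomicInterval("c", 1592070, 1592089)
        assert distance_to_start(site, gene) == -13

    def test_minus_strand_distance(self):
        gene = GeneAnnotation("g1", "c", "-", start_codon=100, left=1, right=100)
        assert distance_to_start(GenomicInterval("c", 131, 150), gene) == 30

    def test_different_chromosome_rejected(self):
        gene = GeneAnnotation("g1", "c2", "+", start_codon=5, left=5, right=50)
        with pytest.raises(ValueError):
            distance_to_start(GenomicInterval("c1", 1, 10), gene)

    def test_nearest_and_next_gene_reported(self):
        genes = [
            GeneAnnotation("far", "c", "+", start_codon=500, left=500, right=900),
            GeneAnnotation("near", "c", "+", start_codon=151, left=151, right=400),
        ]
        [entries] = associate_genes([GenomicInterval("c", 101, 120)], genes)
        assert [(g, d, rel) for g, d, rel in entries] == [
            ("near", 30, "downstream"),
            ("far", 379, "next"),
        ]

    def test_site_past_all_genes_maps_to_nothing(self):
        genes = [GeneAnnotation("g", "c", "+", start_codon=10, left=10, right=90)]
        [entries] = associate_genes([GenomicInterval("c", 200, 219)], genes)
        assert entries == []

    def test_site_inside_gene_reports_it(self):
        genes = [
            GeneAnnotation("host", "c", "+", start_codon=10, left=10, right=900),
            GeneAnnotation("next_one", "c", "+", start_codon=1000, left=1000, right=1200),
        ]
        [entries] = associate_genes([GenomicInterval("c", 200, 219)], genes)
        assert ("host", distance_to_start(GenomicInterval("c", 200, 219), genes[0]), "contains") in entries

    def test_empty_annotation(self):
        assert associate_genes([GenomicInterval("c", 1, 20)], []) == [[]]
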