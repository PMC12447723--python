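import numpy as np
import pytest

from splicekit import training_data as td
from splicekit.formats_io import GeneModel, GenomeSequence


def _genome(seq: str, name: str = "c1") -> dict[str, str]:
    return {name: seq}


def _gene(strand: str, exons, chrom: str = "c1") -> GeneModel:
    return GeneModel(chrom, strand, exons[0][0], exons[-1][1], list(exons), "tx1", "g1")


def _seq_with(intron_start, intron_end, donor="GT", acceptor="AG", length=120):
    s = list("A" * length)
    s[intron_start : intron_start + 2] = donor
    s[intron_end - 2 : intron_end] = acceptor
    return "".join(s)


class TestAnnotatedSites:
    def test_plus_strand_canonical_intron(self):
        genome = _genome(_seq_with(30, 70))
        sites, dropped = td.extract_annotated_sites(
            [_gene("+", [(10, 30), (70, 100)])], genome
        )
        assert dropped == 0
        keys = {(s.pos, s.site_type, s.label) for s in sites}
        assert keys == {(30, td.DONOR, 1), (70, td.ACCEPTOR, 1)}

    def test_noncanonical_donor_dropped_acceptor_kept(self):
        genome = _genome(_seq_with(30, 70, donor="GC"))
        sites, dropped = td.extract_annotated_sites(
            [_gene("+", [(10, 30), (70, 100)])], genome
        )
        assert dropped == 1
        assert {(s.pos, s.site_type) for s in sites} == {(70, td.ACCEPTOR)}

    def test_minus_strand_roles_swap(self):
        # forward CT at intron start = AG on '-'; forward AC at end = GT on '-'
        genome = _genome(_seq_with(30, 70, donor="CT", acceptor="AC"))
        sites, dropped = td.extract_annotated_sites(
            [_gene("-", [(10, 30), (70, 100)])], genome
        )
        assert dropped == 0
        assert {(s.pos, s.strand, s.site_type) for s in sites} == {
            (70, "-", td.DONOR),
            (30, "-", td.ACCEPTOR),
        }

    def test_duplicate_sites_across_transcripts_deduplicated(self):
        genome = _genome(_seq_with(30, 70))
        g1 = _gene("+", [(10, 30), (70, 100)])
        g2 = GeneModel("c1", "+", 5, 100, [(5, 30), (70, 100)], "tx2", "g2")
        sites, _ = td.extract_annotated_sites([g1, g2], genome)
        assert len(sites) == 2


class TestNegativeSites:
    def test_opposite_strand_gt_becomes_minus_donor(self):
        seq = list("A" * 100)
        seq[50:52] = "AC"  # GT on the minus strand
        negs = td.extract_negative_sites([_gene("+", [(0, 100)])], _genome("".join(seq)))
        assert {(s.pos, s.strand, s.site_type) for s in negs} == {(52, "-", td.DONOR)}

    def test_same_strand_gt_never_negative(self):
        seq = list("A" * 100)
        seq[50:52] = "GT"  # same strand as the gene: not a negative
        negs = td.extract_negative_sites([_gene("+", [(0, 100)])], _genome("".join(seq)))
        assert negs == []

    def test_opposite_strand_overlap_region_excluded(self):
        seq = list("A" * 100)
        seq[50:52] = "AC"
        plus = _gene("+", [(0, 100)])
        minus = GeneModel("c1", "-", 40, 60, [(40, 60)], "tx2", "g2")
        negs = td.extract_negative_sites([plus, minus], _genome("".join(seq)))
        assert all(not (40 <= s.pos < 60) for s in negs)

    def test_annotated_site_never_negative(self):
        # '-' annotated intron inside a '+' gene body: its AC must not reappear
        seq = _seq_with(30, 70, donor="CT", acceptor="AC")
        minus = _gene("-", [(10, 30), (70, 100)])
        plus = GeneModel("c1", "+", 0, 110, [(0, 110)], "txp", "gp")
        negs = td.extract_negative_sites([plus, minus], _genome(seq))
        annotated, _ = td.extract_annotated_sites([minus], _genome(seq))
        assert {s.key for s in negs}.isdisjoint({s.key for s in annotated})


class TestDownsampling:
    def _sites(self, n, label):
        return [td.SpliceSite("c1", i, "+", td.DONOR, label) for i in range(n)]

    def test_exact_ratio(self):
        kept = td.downsample_negatives(self._sites(100, 1), self._sites(1000, 0), 3, 7)
        assert len(kept) == 300

    def test_capped_at_available(self):
        kept = td.downsample_negatives(self._sites(100, 1), self._sites(200, 0), 3, 7)
        assert len(kept) == 200

    def test_seed_determinism(self):
        a = td.downsample_negatives(self._sites(10, 1), self._sites(500, 0), 3, 42)
        b = td.downsample_negatives(self._sites(10, 1), self._sites(500, 0), 3, 42)
        assert a == b


class TestWindows:
    def test_default_window_width_is_202(self):
        genome = _genome(_seq_with(150, 200, length=400))
        site = td.SpliceSite("c1", 150, "+", td.DONOR, 1)
        w = td.make_window(site, genome, flank=100)
        assert w.shape == (4, 202)
        # central two columns are G,T
        assert w[:, 100].tolist() == [0, 0, 1, 0]
        assert w[:, 101].tolist() == [0, 0, 0, 1]

    def test_one_hot_first_column(self):
        m = td.one_hot("ACGTN")
        assert m[:, 0].tolist() == [1, 0, 0, 0]
        assert m[:, 4].tolist() == [0, 0, 0, 0]  # N column all zero

    def test_minus_window_is_reverse_complement_of_forward_slice(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 400))
        seq = seq[:198] + "AC" + seq[200:]  # '-' donor dinucleotide at 198
        genome = _genome(seq)
        site = td.SpliceSite("c1", 200, "-", td.DONOR, 1)
        w = td.make_window(site, genome, flank=100)
        # independent reverse-complement oracle on the raw string
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[c] for c in reversed(seq[98:300]))
        assert np.array_equal(w, td.one_hot(rc))
        assert rc[100:102] == "GT"

    def test_out_of_bounds_site_skipped(self):
        genome = _genome(_seq_with(30, 70))
        site = td.SpliceSite("c1", 30, "+", td.DONOR, 1)
        assert td.make_window(site, genome, flank=100) is None
        _, n_skipped = td.build_examples([site], genome, flank=100)
        assert n_skipped == 1


class TestSplit:
    def _examples(self, n_genes, chrom="c1", sites_per_gene=2):
        out = []
        for g in range(n_genes):
            for k in range(sites_per_gene):
                s = td.SpliceSite(chrom, 100 * g + k, "+", td.DONOR, 1, f"g{g}")
                out.append(td.SpliceSiteExample(s, np.zeros((4, 10), np.float32)))
        return out

    def test_gene_level_80_20(self):
        genomes = [GenomeSequence("c1", "A", 1), GenomeSequence("c2", "A", 2)]
        split = td.split_by_chromosome(self._examples(10), genomes, 0.8, seed=0)
        train_genes = {e.site.gene_id for e in split.train}
        val_genes = {e.site.gene_id for e in split.validation}
        assert len(train_genes) == 8 and len(val_genes) == 2
        assert train_genes.isdisjoint(val_genes)

    def test_all_sites_of_gene_share_split(self):
        genomes = [GenomeSequence("c1", "A", 1), GenomeSequence("c2", "A", 2)]
        split = td.split_by_chromosome(
            self._examples(5, sites_per_gene=10), genomes, 0.8, seed=1
        )
        assert {e.site.gene_id for e in split.train}.isdisjoint(
            {e.site.gene_id for e in split.validation}
        )

    def test_even_chromosomes_reserved_for_testing(self):
        genomes = [GenomeSequence("c1", "A", 1), GenomeSequence("c2", "A", 2)]
        examples = self._examples(4) + self._examples(4, chrom="c2")
        split = td.split_by_chromosome(examples, genomes, 0.8, seed=0)
        assert all(e.site.chrom == "c1" for e in split.train + split.validation)
        assert split.test_chromosomes == ["c2"]

    def test_single_chromosome_rejected(self):
        with pytest.raises(ValueError, match="2 chromosomes"):
            td.split_by_chromosome(
                self._examples(2), [GenomeSequence("c1", "A", 1)], 0.8, 0
            )


def test_generated_training_set_invariants(tiny_sim):
    """Exact 1:3 ratio, canonical window centers, no label conflicts."""
    genome = tiny_sim.genome_dict
    pos, dropped = td.extract_annotated_sites(tiny_sim.genes, genome)
    assert dropped == 0
    negs = td.extract_negative_sites(tiny_sim.genes, genome)
    kept = td.downsample_negatives(pos, negs, 3, seed=5)
    assert len(kept) == min(len(negs), 3 * len(pos))
    assert {s.key for s in pos}.isdisjoint({s.key for s in kept})
    examples, _ = td.build_examples(pos, genome, flank=100)
    for e in examples:
        center = np.argmax(e.window[:, 100:102], axis=0)
        if e.site.site_type == td.DONOR:
            assert center.tolist() == [2, 3]  # G, T
        else:
            assert center.tolist() == [0, 2]  # A, G
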