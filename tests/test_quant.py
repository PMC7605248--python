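"""Quantification: autonomy, LTR ratios, penetrance, splice motifs, and
isoform enumeration."""

import numpy as np
import pytest

from _oracles import brute_force_isoforms

from techimera import pipeline, quant, refprep, simdata
from techimera.quant import (
    MATCH_CONSENSUS,
    MATCH_GC,
    MATCH_NONE,
    AutonomyStats,
    enumerate_isoforms,
    scan_motifs,
)
from techimera.simdata import InsertionSpec


@pytest.fixture(scope="module")
def ltr_setup():
    """One gene with an exonic full-retention LTR insertion (read-through),
    shared by the autonomy and LTR-ratio scenarios."""
    base = simdata.simulate_genome(
        n_genes=2, n_te_subfamilies=1, genome_len=25_000, n_insertions=0,
        n_individuals=1, seed=7,
    )
    g = base.genes[0]
    te = base.te_library.entries[0]
    L = len(te.sequence)
    s, e = g.exons[1]
    spec = InsertionSpec(
        te.name, g.seqid, (s + e) // 2, "+", "exonic", 4, 1.0,
        donor_sites=(L,), acceptor_sites=(0,), splicing_fraction=1.0,
    )
    sim = simdata.simulate_genome(
        n_genes=2, n_te_subfamilies=1, genome_len=25_000,
        insertions=[spec], n_individuals=1, seed=7,
    )
    masked = refprep.mask_genome(sim.genome, sim.te_library)
    bundle = refprep.build_combined_reference(masked, sim.te_library)
    ann = refprep.build_annotation_index(sim.gff3_text, from_string=True)
    return sim, bundle, ann, g


class TestAutonomy:
    def test_per_nt_arithmetic(self):
        lib = refprep.TEConsensusLibrary([refprep.TEEntry("x", "A" * 5000)])
        stats = quant.autonomy_stats([], [], lib)
        assert stats[0].te_only_per_nt == 0.0
        s = AutonomyStats("x", 5000, 100, 100 / 5000, 0)
        assert s.te_only_per_nt == pytest.approx(0.02)

    def test_gene_driven_te_gene_exceeds_te_only(self, sim, bundle, annotation, cdna_result):
        """All TE transcripts are gene-driven spliced chimeras: spanning
        reads dominate length-normalized TE-only reads (the nonautonomous
        signature)."""
        stats = quant.autonomy_stats(
            cdna_result.alignments, cdna_result.clusters, sim.te_library
        )
        expressed = [s for s in stats if s.te_gene_reads > 0]
        assert expressed
        for s in expressed:
            assert s.te_gene_reads > s.te_only_per_nt * 100

    def test_autonomous_te_has_no_te_gene_reads(self, ltr_setup):
        sim, bundle, ann, g = ltr_setup
        pairs, _ = simdata.simulate_cdna_reads(
            sim, expression_levels={}, autonomous_te_levels={"TE1": 600}, seed=30
        )
        res = pipeline.detect_sample(pairs, bundle, mode="cdna", annotation=ann)
        (s,) = quant.autonomy_stats(res.alignments, res.clusters, sim.te_library)
        assert s.te_gene_reads == 0
        assert s.te_only_reads > 0


class TestLTRRatio:
    def test_autonomous_ratio_zero(self, ltr_setup):
        sim, bundle, ann, g = ltr_setup
        pairs, _ = simdata.simulate_cdna_reads(
            sim, expression_levels={}, autonomous_te_levels={"TE1": 600}, seed=31
        )
        res = pipeline.detect_sample(pairs, bundle, mode="cdna", annotation=ann)
        ratios, _ = quant.ltr_ratio(res.clusters, res.contigs, sim.te_library, bundle)
        for r in ratios:
            assert r.gene_ltr_reads == 0
            assert r.ltr_te_reads > 0
            assert r.raw_ratio == 0.0

    def test_gene_driven_ratio_near_one_capped(self, ltr_setup):
        sim, bundle, ann, g = ltr_setup
        pairs, _ = simdata.simulate_cdna_reads(
            sim, expression_levels={g.id: 800}, seed=32
        )
        res = pipeline.detect_sample(pairs, bundle, mode="cdna", annotation=ann)
        ratios, _ = quant.ltr_ratio(res.clusters, res.contigs, sim.te_library, bundle)
        assert len(ratios) == 2
        for r in ratios:
            assert r.raw_ratio >= 0.8
            assert r.ratio_percent <= 100.0

    def test_cap_arithmetic(self):
        r = quant.LTRRatio("x", "5'", 150, 100, 1.5, min(100.0, 150.0), True)
        assert r.ratio_percent == 100.0 and r.raw_ratio == 1.5

    def test_unannotated_te_listed(self):
        lib = refprep.TEConsensusLibrary([refprep.TEEntry("plain", "ACGGTT" * 100)])
        masked = refprep.MaskedGenome({"c": "TTGACA" * 100}, {"c": []})
        bundle = refprep.build_combined_reference(masked, lib)
        ratios, skipped = quant.ltr_ratio([], [], lib, bundle)
        assert ratios == [] and skipped == ["plain"]


class TestPenetrance:
    def test_arithmetic(self):
        jc = quant.JunctionCounts("g", "t", "c", 100, 200, 95, 5, 0, 0)
        assert jc.penetrance_upstream == pytest.approx(0.95)
        assert jc.penetrance_downstream is None
        jc2 = quant.JunctionCounts("g", "t", "c", 100, 200, 0, 50, 0, 0)
        assert jc2.penetrance_upstream == 0.0

    @pytest.mark.parametrize("fraction", [0.116, 0.5])
    def test_recovers_splicing_fraction(self, fraction):
        """Estimated penetrance sits within the binomial interval of the
        simulated splicing fraction."""
        sim = simdata.simulate_genome(
            n_genes=2, n_te_subfamilies=1, genome_len=25_000, n_insertions=1,
            n_individuals=1, seed=33, splicing_fraction=fraction,
            frequencies=(1.0,),
        )
        masked = refprep.mask_genome(sim.genome, sim.te_library)
        bundle = refprep.build_combined_reference(masked, sim.te_library)
        ann = refprep.build_annotation_index(sim.gff3_text, from_string=True)
        pairs, _ = simdata.simulate_cdna_reads(sim, mean_fragments_per_gene=3000, seed=34)
        res = pipeline.detect_sample(pairs, bundle, mode="cdna", annotation=ann)
        pens = quant.penetrance(res.clusters, res.contigs, ann, bundle)
        assert len(pens) == 1
        p = pens[0]
        n = (p.chimeric_upstream + p.canonical_upstream
             + p.chimeric_downstream + p.canonical_downstream)
        assert n > 300
        sd = np.sqrt(fraction * (1 - fraction) / n)
        assert p.penetrance == pytest.approx(fraction, abs=4 * sd + 0.01)


class TestMotifs:
    def _cluster(self, te_lib, te_bp, direction, te_strand="+"):
        from techimera.chimera import BreakpointCluster, ChimeraEvidence

        ev = ChimeraEvidence(
            "r", "r", "s1", "chr", 1000, (900, 1000), te_lib.names[0], te_bp,
            (te_bp, te_bp + 50), te_strand, direction, "exact", "+", 0, 300,
        )
        return BreakpointCluster("chr", te_lib.names[0], direction, "+", te_strand, [ev])

    def test_planted_consensus_donor(self):
        rng = np.random.default_rng(40)
        core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        seq = core[:200] + "CAG" + "GTAAGT" + core[200:]
        lib = refprep.TEConsensusLibrary([refprep.TEEntry("te", seq)])
        cl = self._cluster(lib, 203, "te_to_gene")  # exit right before GT
        (hit,) = scan_motifs(lib, [cl])
        assert hit.match_class == MATCH_CONSENSUS
        assert hit.site_class == "donor"

    def test_gc_donor_window_noncanonical(self):
        """The noncanonical donor context seen on antisense roo at its most
        used exit (GT read as GC) classifies as noncanonical_GC."""
        rng = np.random.default_rng(41)
        core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        seq = core[:200] + "TTTGGCAAGTT" + core[200:]
        lib = refprep.TEConsensusLibrary([refprep.TEEntry("te", seq)])
        cl = self._cluster(lib, 205, "te_to_gene")  # breakpoint inside the window
        (hit,) = scan_motifs(lib, [cl])
        assert hit.match_class == MATCH_GC

    def test_planted_acceptor(self):
        rng = np.random.default_rng(42)
        core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        seq = core[:200] + "TTTTTCTCAG" + "G" + core[200:]
        lib = refprep.TEConsensusLibrary([refprep.TEEntry("te", seq)])
        cl = self._cluster(lib, 210, "gene_to_te")
        (hit,) = scan_motifs(lib, [cl])
        assert hit.match_class == MATCH_CONSENSUS and hit.site_class == "acceptor"

    def test_random_windows_mostly_none(self):
        """Random breakpoints rarely score above the empirical null."""
        rng = np.random.default_rng(43)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        lib = refprep.TEConsensusLibrary([refprep.TEEntry("te", seq)])
        cls = [self._cluster(lib, int(b), "te_to_gene") for b in rng.integers(50, 2950, 100)]
        hits = scan_motifs(lib, cls)
        frac_hit = np.mean([h.match_class != MATCH_NONE for h in hits])
        assert frac_hit <= 0.1

    def test_planted_sites_recovered_in_bulk(self):
        """Planted GT donors classify consensus and planted GC donors
        noncanonical, at high specificity, across many random contexts."""
        rng = np.random.default_rng(44)
        n = 200
        ok = 0
        entries = []
        clusters = []
        for i in range(n):
            core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
            dinuc = "GT" if i % 2 == 0 else "GC"
            seq = core[:150] + "CAG" + dinuc + "AAGT" + core[150:]
            entries = [refprep.TEEntry("te", seq)]
            lib = refprep.TEConsensusLibrary(entries)
            cl = self._cluster(lib, 153, "te_to_gene")
            (hit,) = scan_motifs(lib, [cl])
            want = MATCH_CONSENSUS if dinuc == "GT" else MATCH_GC
            ok += hit.match_class == want
        assert ok / n == 1.0

    def test_truncated_window_flagged(self):
        lib = refprep.TEConsensusLibrary([refprep.TEEntry("te", "ACGTACGTAGGTAAGTACGT")])
        cl = self._cluster(lib, 2, "te_to_gene")
        (hit,) = scan_motifs(lib, [cl], threshold=0.0)
        assert hit.truncated

    def test_antisense_breakpoint_orientation(self):
        """For an antisense TE segment the scan runs on the reverse
        complement with the breakpoint mapped accordingly."""
        rng = np.random.default_rng(45)
        core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        sense = core[:200] + "CAG" + "GTAAGT" + core[200:]
        from techimera._seq import revcomp

        seq = revcomp(sense)  # consensus stores the reverse complement
        lib = refprep.TEConsensusLibrary([refprep.TEEntry("te", seq)])
        # oriented coordinate 203 -> consensus coordinate L - 203
        cl = self._cluster(lib, len(seq) - 203, "te_to_gene", te_strand="-")
        (hit,) = scan_motifs(lib, [cl])
        assert hit.match_class == MATCH_CONSENSUS


class TestIsoformEnumeration:
    def test_minimal_te_insertion_doubles_isoforms(self):
        cat = enumerate_isoforms([100], [500], [300], [200])
        assert cat.count == 2 and cat.baseline_count == 1

    def test_te_without_exit_donor_adds_nothing(self):
        cat = enumerate_isoforms([100], [500], [], [200])
        assert cat.count == 1

    def test_retention_counting_flag(self):
        cat = enumerate_isoforms([100], [500], [300], [200], count_retention=True)
        assert cat.count == 3

    def test_matches_brute_force_on_random_site_sets(self):
        """Chain enumeration equals exhaustive path enumeration on random
        site configurations of <= 12 sites."""
        rng = np.random.default_rng(46)
        for _ in range(25):
            pos = rng.choice(np.arange(10, 1000, 7), size=12, replace=False)
            host_d = sorted(int(x) for x in pos[:2])
            host_a = sorted(int(x) for x in pos[2:4])
            te_d = sorted(int(x) for x in pos[4:8])
            te_a = sorted(int(x) for x in pos[8:12])
            cat = enumerate_isoforms(host_d, host_a, te_d, te_a)
            oracle = brute_force_isoforms(host_d, host_a, te_d, te_a)
            assert set(cat.chains) == oracle
            assert cat.count == len(oracle)
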