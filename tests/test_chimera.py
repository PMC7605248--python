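"""Chimera detection: candidate filtering, breakpoint refinement,
deduplication, clustering, annotation, and germline insertion calling."""
import numpy as np
import pytest

from techimera import chimera, readproc, refprep
from techimera._seq import revcomp
from techimera.chimera import (
    ChimeraEvidence,
    cluster_breakpoints,
    deduplicate,
    find_candidate_pairs,
    refine_breakpoint,
)
from techimera.readproc import Contig, ReferenceIndex, align_pairs, make_insilico_pairs


def _rand(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(20)
    chr1 = _rand(rng, 6000)
    roo = _rand(rng, 2000)
    lib = refprep.TEConsensusLibrary([refprep.TEEntry("roo", roo)])
    masked = refprep.MaskedGenome({"chr1": chr1}, {"chr1": []})
    bundle = refprep.build_combined_reference(masked, lib)
    return bundle, ReferenceIndex(bundle)


def _evidence_for(contig_seq, bundle, index, mode="cdna", min_segment=20):
    c = Contig("c1", contig_seq, "c1", True, "+" if mode == "cdna" else None)
    pairs, _ = make_insilico_pairs([c])
    alns = align_pairs(pairs, index)
    cands, _ = find_candidate_pairs(alns)
    if not cands:
        return None
    return refine_breakpoint(cands[0], bundle, min_segment=min_segment, mode=mode)


class TestCandidates:
    def test_classification_filter(self, toy):
        bundle, index = toy
        chr1, roo = bundle.get("chr1"), bundle.get("roo")
        rng = np.random.default_rng(21)
        contigs = [
            Contig("a", chr1[100:250] + roo[500:700], "a", True),   # genome|te
            Contig("b", chr1[100:300], "b", True),                  # genome|genome
            Contig("c", _rand(rng, 120) + roo[100:300], "c", True), # unmapped|te
        ]
        pairs, _ = make_insilico_pairs(contigs)
        cands, stats = find_candidate_pairs(align_pairs(pairs, index))
        assert [c.id for c in cands] == ["a"]
        assert stats["excluded_other"] == 2


class TestRefine:
    def test_exact_breakpoints_by_construction(self, toy):
        bundle, index = toy
        chr1, roo = bundle.get("chr1"), bundle.get("roo")
        ev = _evidence_for(chr1[1000:1150] + roo[500:700], bundle, index)
        assert ev.resolution == "exact"
        assert ev.seqid == "chr1" and ev.genome_bp == 1150
        assert ev.te_name == "roo" and ev.te_bp == 500
        assert ev.direction == "gene_to_te" and ev.te_strand == "+"

    def test_te_first_contig_is_te_to_gene(self, toy):
        bundle, index = toy
        chr1, roo = bundle.get("chr1"), bundle.get("roo")
        ev = _evidence_for(roo[500:700] + chr1[3000:3150], bundle, index)
        assert ev.direction == "te_to_gene"
        assert ev.genome_bp == 3000 and ev.te_bp == 700

    def test_antisense_te_segment(self, toy):
        bundle, index = toy
        chr1, roo = bundle.get("chr1"), bundle.get("roo")
        ev = _evidence_for(chr1[1000:1150] + revcomp(roo[500:700]), bundle, index)
        assert ev.te_strand == "-" and ev.te_bp == 700

    def test_short_te_segment_dropped(self, toy):
        """A chimeric half below the minimum segment length is discarded."""
        bundle, index = toy
        chr1, roo = bundle.get("chr1"), bundle.get("roo")
        contig = chr1[1000:1185] + roo[500:515]  # te half 15 < 20
        c = Contig("c", contig, "c", True, "+")
        pairs, _ = make_insilico_pairs([c])
        cands, _ = find_candidate_pairs(align_pairs(pairs, index))
        # the te end cannot even align full-length; either no candidate or
        # refinement drops it
        if cands:
            assert refine_breakpoint(cands[0], bundle) is None

    def test_microhomology_assigned_genome_maximal(self, toy):
        """With k shared bases at the junction, every split in the ambiguous
        range is sequence-consistent (enumeration oracle); the reported
        breakpoint is the genome-maximal one and the homology is recorded."""
        bundle, index = toy
        chr1, roo = bundle.get("chr1"), bundle.get("roo")
        mh = roo[500:503]  # plant 3 nt of TE sequence at the genome edge
        genome_part = chr1[1000:1147] + mh
        contig = genome_part + roo[503:700]
        # enumeration oracle: consistent split points of the toy contig
        consistent = []
        for split in range(140, 160):
            g_ok = contig[:split] == (chr1[1000:1000 + split] if split <= 150
                                      else None)
            te_start = 503 - (150 - split)
            t_ok = 0 <= te_start and contig[split:] == roo[te_start:te_start + len(contig) - split]
            if g_ok and t_ok:
                consistent.append(split)
        assert consistent == [147, 148, 149, 150]
        ev = _evidence_for(contig, bundle, index)
        assert ev.microhomology == 3
        assert ev.genome_bp == 1000 + max(consistent)
        assert ev.te_bp == 503 - (150 - max(consistent))

    def test_gdna_reverse_contig_normalized(self, toy):
        """An unstranded gDNA contig read in reverse orientation yields the
        same call as its forward complement."""
        bundle, index = toy
        chr1, roo = bundle.get("chr1"), bundle.get("roo")
        # pick a junction with no chance homology across it
        cut = next(p for p in range(2150, 2300) if chr1[p] != roo[0])
        fwd = chr1[cut - 150 : cut] + roo[0:180]
        for seq in (fwd, revcomp(fwd)):
            ev = _evidence_for(seq, bundle, index, mode="gdna")
            assert ev.direction == "upstream"
            assert ev.genome_bp == cut and ev.te_bp == 0 and ev.te_strand == "+"


class TestDeduplicate:
    def _ev(self, read_id, bp=100, resolution="exact"):
        return ChimeraEvidence(
            read_id, read_id, "s1", "chr1", bp, (0, bp), "roo", 50, (50, 100),
            "+", "gene_to_te", resolution, "+", 0, 300,
        )

    def test_merged_and_unmerged_paths_collapse(self):
        evs = [self._ev("r1"), self._ev("r1", bp=105, resolution="estimated")]
        out = deduplicate(evs)
        assert len(out) == 1 and out[0].resolution == "exact"

    def test_distinct_reads_with_identical_breakpoints_kept(self):
        assert len(deduplicate([self._ev("r1"), self._ev("r2")])) == 2

    def test_empty(self):
        assert deduplicate([]) == []


class TestClustering:
    def _ev(self, bp, te="roo", direction="gene_to_te", i=[0]):
        i[0] += 1
        return ChimeraEvidence(
            f"r{i[0]}", f"r{i[0]}", "s1", "chr1", bp, (0, bp), te, 50,
            (50, 100), "+", direction, "exact", "+", 0, 300,
        )

    def test_window_joins_and_splits(self):
        cl = cluster_breakpoints([self._ev(1000), self._ev(1015)])
        assert len(cl) == 1
        cl = cluster_breakpoints([self._ev(1000), self._ev(1030)])
        assert len(cl) == 2

    def test_chained_single_linkage(self):
        cl = cluster_breakpoints([self._ev(1000), self._ev(1019), self._ev(1038)])
        assert len(cl) == 1 and cl[0].support == 3

    def test_agrees_with_transitive_closure_oracle(self):
        """Chaining equals brute-force transitive closure of the <=window
        relation on random breakpoint sets."""
        rng = np.random.default_rng(22)
        for _ in range(20):
            bps = sorted(int(x) for x in rng.integers(0, 2000, 40))
            evs = [self._ev(b) for b in bps]
            got = sorted(
                tuple(sorted(m.genome_bp for m in c.members))
                for c in cluster_breakpoints(evs, window=20)
            )
            # oracle: union-find over all pairs within the window
            parent = list(range(len(bps)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(bps)):
                for j in range(i + 1, len(bps)):
                    if abs(bps[i] - bps[j]) <= 20:
                        parent[find(i)] = find(j)
            groups = {}
            for i, b in enumerate(bps):
                groups.setdefault(find(i), []).append(b)
            oracle = sorted(tuple(sorted(v)) for v in groups.values())
            assert got == oracle

    def test_representative_is_modal_member(self):
        evs = [self._ev(b) for b in (1000, 1003, 1003, 1005)]
        cl = cluster_breakpoints(evs)[0]
        assert cl.rep_genome_bp == 1003
        evs = [self._ev(b) for b in (1000, 1000, 1003, 1003)]
        assert cluster_breakpoints(evs)[0].rep_genome_bp == 1000  # tie -> smallest

    def test_direction_and_te_separate_clusters(self):
        evs = [self._ev(1000), self._ev(1001, direction="te_to_gene"),
               self._ev(1002, te="blood")]
        assert len(cluster_breakpoints(evs)) == 3


class TestEndToEndGdna:
    def test_all_truth_insertions_called_exactly(self, sim, bundle, annotation, gdna_result):
        """Sensitivity: every planted insertion is called with exact
        breakpoints, TSD, orientation class and recovered frequency."""
        calls, sub = chimera.call_germline_insertions(
            gdna_result.clusters, bundle, annotation,
            n_individuals=sim.truth.n_individuals,
        )
        assert sub == []
        truth = {(i.te_name, i.downstream_bp): i for i in sim.truth.insertions}
        assert len(calls) == len(truth)
        for call in calls:
            ins = truth[(call.te_name, call.downstream_bp)]
            assert call.upstream_bp == ins.upstream_bp
            assert call.tsd_len == ins.spec.tsd_len
            assert call.tsd_seq == ins.tsd_seq
            assert call.te_orientation == ins.spec.orientation
            assert call.orientation_class == ins.orientation_class
            assert call.population_frequency == pytest.approx(
                ins.realized_frequency, abs=0.1
            )
            assert call.gene_id == ins.gene_id

    def test_no_calls_at_non_truth_loci(self, sim, bundle, annotation, gdna_result):
        calls, sub = chimera.call_germline_insertions(
            gdna_result.clusters, bundle, annotation,
            n_individuals=sim.truth.n_individuals, min_frequency=0.0,
        )
        truth_pts = {i.downstream_bp for i in sim.truth.insertions}
        for c in calls + sub:
            assert c.point in truth_pts

    def test_frequency_fallback_without_individual_tags(self, sim, bundle, annotation, gdna_result):
        """Stripping individual tags switches to the read-ratio estimator,
        which still separates fixed from 50% insertions."""
        import copy

        clusters = copy.deepcopy(gdna_result.clusters)
        for cl in clusters:
            for m in cl.members:
                m.read_id = m.read_id.replace(":i", ":x")
        calls, sub = chimera.call_germline_insertions(
            clusters, bundle, annotation, n_individuals=None,
            min_frequency=0.0, alignments=gdna_result.alignments,
        )
        truth = {(i.te_name, i.downstream_bp): i for i in sim.truth.insertions}
        for call in calls + sub:
            ins = truth[(call.te_name, call.downstream_bp)]
            assert call.population_frequency == pytest.approx(
                ins.realized_frequency, abs=0.25
            )


class TestEndToEndCdna:
    def test_direction_bookkeeping_matches_truth(self, sim, cdna_result):
        """gene_to_te clusters arise only at truth donor-side junctions and
        te_to_gene only at acceptor-side junctions."""
        truth = {}
        for ins in sim.truth.insertions:
            for j in ins.junctions:
                if ins.spec.splicing_fraction > 0:
                    truth[(j.te_name, j.genome_bp, j.direction)] = j
        assert cdna_result.clusters
        for cl in cdna_result.clusters:
            key = (cl.te_name, cl.rep_genome_bp, cl.direction)
            assert key in truth
            j = truth[key]
            assert cl.rep_te_bp == j.te_bp
            assert cl.te_strand == j.te_strand

    def test_annotation_context(self, sim, annotation, cdna_result):
        for cl in cdna_result.clusters:
            ins = next(
                i for i in sim.truth.insertions
                if i.te_name == cl.te_name and any(
                    j.genome_bp == cl.rep_genome_bp for j in i.junctions
                )
            )
            assert cl.gene_id == ins.gene_id
            assert cl.orientation_class == ins.orientation_class
            if ins.spec.placement == "intronic":
                # splice junctions sit exactly on annotated exon boundaries
                assert cl.splice_site_distance == 0

    def test_intergenic_annotation(self):
        ev = ChimeraEvidence(
            "r", "r", "s1", "chr1", 50, (0, 50), "roo", 10, (10, 60), "+",
            "gene_to_te", "exact", "+", 0, 300,
        )
        idx = refprep.AnnotationIndex([])
        (cl,) = chimera.annotate_clusters(cluster_breakpoints([ev]), idx)
        assert cl.gene_id is None and cl.feature == "intergenic"
        assert cl.orientation_class == "intergenic"
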