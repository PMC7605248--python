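"""Gene|TE junction detection, breakpoint refinement, clustering and
germline insertion calling.

Candidate chimeras are in-silico pairs with exactly one genome-class end and
one TE-class end. The parent contig is then re-aligned locally to both
references to place the junction at single-nucleotide resolution: the genome
and TE alignments are extended maximally towards each other, and any
microhomology at the junction is assigned to the genome side (deterministic,
and recorded so the choice is auditable).

Evidence is deduplicated per source read, clustered along the genome by
single-linkage chaining (window 20 nt, preserving single-nucleotide
breakpoint detail), annotated against gene features and splice sites, and —
for gDNA — upstream/downstream cluster pairs are joined into germline
insertion calls with TSD and population-frequency estimates.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._seq import revcomp
from .readproc import (
    CLS_GENOME,
    CLS_TE,
    Contig,
    PairAlignment,
)
from .refprep import AnnotationIndex, ReferenceBundle

_COMP = str.maketrans("ACGTN", "TGCAN")

DIR_GENE_TO_TE = "gene_to_te"
DIR_TE_TO_GENE = "te_to_gene"
DIR_UPSTREAM = "upstream"
DIR_DOWNSTREAM = "downstream"


@dataclass
class ChimeraEvidence:
    read_id: str
    contig_id: str
    sample: str
    seqid: str
    genome_bp: int  # junction boundary on the genome (0-based)
    genome_span: tuple[int, int]
    te_name: str
    te_bp: int  # junction boundary on the consensus (0-based)
    te_span: tuple[int, int]
    te_strand: str  # consensus strand of the TE segment
    direction: str
    resolution: str  # exact | estimated
    transcript_strand: Optional[str]  # cDNA only
    microhomology: int
    contig_len: int


@dataclass
class BreakpointCluster:
    seqid: str
    te_name: str
    direction: str
    transcript_strand: Optional[str]
    te_strand: str
    members: list[ChimeraEvidence]
    # annotation (filled by annotate_clusters)
    gene_id: Optional[str] = None
    gene_ids: list[str] = field(default_factory=list)
    feature: Optional[str] = None
    orientation_class: Optional[str] = None
    splice_site_kind: Optional[str] = None
    splice_site_distance: Optional[int] = None

    @property
    def start(self) -> int:
        return min(m.genome_bp for m in self.members)

    @property
    def end(self) -> int:
        return max(m.genome_bp for m in self.members)

    @property
    def support(self) -> int:
        return len(self.members)

    @property
    def rep_genome_bp(self) -> int:
        return _mode_min(m.genome_bp for m in self.members)

    @property
    def rep_te_bp(self) -> int:
        return _mode_min(m.te_bp for m in self.members)

    def sample_counts(self) -> dict[str, int]:
        return dict(Counter(m.sample for m in self.members))


def _mode_min(values: Iterable[int]) -> int:
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


# ---------------------------------------------------------------------------
# Candidate selection


def find_candidate_pairs(
    alignments: Iterable[PairAlignment],
) -> tuple[list[PairAlignment], dict]:
    """Pairs with exactly one genome-class end and one TE-class end."""
    out = []
    stats = {"candidate": 0, "excluded_multi": 0, "excluded_other": 0}
    for pa in alignments:
        classes = {pa.a1.cls, pa.a2.cls}
        if classes == {CLS_GENOME, CLS_TE}:
            out.append(pa)
            stats["candidate"] += 1
        elif "multi" in classes:
            stats["excluded_multi"] += 1
        else:
            stats["excluded_other"] += 1
    return out, stats


# ---------------------------------------------------------------------------
# Breakpoint refinement


class _Anchor:
    """Maps contig indices to reference coordinates for one aligned side."""

    def __init__(self, refseq: str, i0: int, r0: int, strand: str):
        self.seq = refseq
        self.i0 = i0
        self.r0 = r0
        self.dir = 1 if strand == "+" else -1
        self.strand = strand

    def refcoord(self, i: int) -> int:
        return self.r0 + self.dir * (i - self.i0)

    def matches(self, contig: str, i: int) -> bool:
        r = self.refcoord(i)
        if r < 0 or r >= len(self.seq):
            return False
        base = self.seq[r]
        if self.strand == "-":
            base = base.translate(_COMP)
        return contig[i] == base


def refine_breakpoint(
    candidate: PairAlignment,
    bundle: ReferenceBundle,
    min_segment: int = 20,
    mode: str = "cdna",
    sample: str = "s1",
) -> Optional[ChimeraEvidence]:
    """Resolve the junction of one candidate to single-nucleotide precision.

    Returns None when a side's segment is shorter than ``min_segment`` (the
    candidate is dropped, mirroring a minimum chimeric-segment filter).
    """
    contig_obj: Contig = candidate.pair.contig
    contig = contig_obj.sequence.upper()
    Lc = len(contig)
    L = len(candidate.pair.end1)

    ends = [candidate.a1, candidate.a2]
    genome_idx = 0 if ends[0].cls == CLS_GENOME else 1
    te_idx = 1 - genome_idx
    g_aln, t_aln = ends[genome_idx], ends[te_idx]

    # contig-forward strand of each end: end1 is the contig prefix as-is;
    # end2 is the revcomp of the contig suffix, so its strand flips.
    def _side(aln, is_end1):
        strand = aln.strand if is_end1 else ("-" if aln.strand == "+" else "+")
        i0 = 0 if is_end1 else Lc - L
        r0 = aln.pos if strand == "+" else aln.pos + L - 1
        return aln.ref, i0, r0, strand

    g_ref, g_i0, g_r0, g_strand = _side(g_aln, genome_idx == 0)
    t_ref, t_i0, t_r0, t_strand = _side(t_aln, te_idx == 0)
    genome_first = genome_idx == 0

    if mode == "gdna" and g_strand == "-":
        # gDNA is unstranded: normalize so the genome side reads along the
        # reference '+' strand. The aligned reference intervals [pos, pos+L)
        # are orientation-independent; only contig intervals/strands flip.
        contig = revcomp(contig)
        genome_first = not genome_first
        g_strand = "+"
        t_strand = "-" if t_strand == "+" else "+"
        g_i0 = 0 if genome_first else Lc - L
        t_i0 = Lc - L if genome_first else 0
        g_r0 = g_aln.pos
        t_r0 = t_aln.pos if t_strand == "+" else t_aln.pos + L - 1

    g_anchor = _Anchor(bundle.get(g_ref).upper(), g_i0, g_r0, g_strand)
    t_anchor = _Anchor(bundle.get(t_ref).upper(), t_i0, t_r0, t_strand)

    if genome_first:
        x = 0
        while x < Lc and g_anchor.matches(contig, x):
            x += 1
        y = Lc
        while y > 0 and t_anchor.matches(contig, y - 1):
            y -= 1
        microhomology = max(0, x - y)
        resolution = "exact" if x >= y else "estimated"
        split = x  # genome-maximal
        g_len, t_len = split, Lc - split
        if g_len < min_segment or t_len < min_segment:
            return None
        genome_bp = (
            g_anchor.refcoord(split - 1) + 1
            if g_strand == "+"
            else g_anchor.refcoord(split - 1)
        )
        te_bp = (
            t_anchor.refcoord(split)
            if t_strand == "+"
            else t_anchor.refcoord(split) + 1
        )
        g_span = tuple(sorted((g_anchor.refcoord(0), g_anchor.refcoord(split - 1))))
        t_span = tuple(sorted((t_anchor.refcoord(split), t_anchor.refcoord(Lc - 1))))
    else:
        y = Lc
        while y > 0 and g_anchor.matches(contig, y - 1):
            y -= 1
        x = 0
        while x < Lc and t_anchor.matches(contig, x):
            x += 1
        microhomology = max(0, x - y)
        resolution = "exact" if x >= y else "estimated"
        split = y  # genome-maximal: ambiguous bases stay with the genome
        g_len, t_len = Lc - split, split
        if g_len < min_segment or t_len < min_segment:
            return None
        genome_bp = (
            g_anchor.refcoord(split)
            if g_strand == "+"
            else g_anchor.refcoord(split) + 1
        )
        te_bp = (
            t_anchor.refcoord(split - 1) + 1
            if t_strand == "+"
            else t_anchor.refcoord(split - 1)
        )
        g_span = tuple(sorted((g_anchor.refcoord(split), g_anchor.refcoord(Lc - 1))))
        t_span = tuple(sorted((t_anchor.refcoord(0), t_anchor.refcoord(split - 1))))

    if mode == "cdna":
        direction = DIR_GENE_TO_TE if genome_first else DIR_TE_TO_GENE
        transcript_strand = g_strand
    else:
        direction = DIR_UPSTREAM if genome_first else DIR_DOWNSTREAM
        transcript_strand = None

    return ChimeraEvidence(
        read_id=contig_obj.read_id,
        contig_id=contig_obj.id,
        sample=sample,
        seqid=g_ref,
        genome_bp=genome_bp,
        genome_span=(g_span[0], g_span[1] + 1),
        te_name=t_ref,
        te_bp=te_bp,
        te_span=(t_span[0], t_span[1] + 1),
        te_strand=t_strand,
        direction=direction,
        resolution=resolution,
        transcript_strand=transcript_strand,
        microhomology=microhomology,
        contig_len=Lc,
    )


def detect_chimeras(
    alignments: Iterable[PairAlignment],
    bundle: ReferenceBundle,
    mode: str = "cdna",
    sample: str = "s1",
    min_segment: int = 20,
) -> tuple[list[ChimeraEvidence], dict]:
    """candidates -> refined evidence -> one record per source read."""
    candidates, stats = find_candidate_pairs(alignments)
    evidence = []
    dropped = 0
    for cand in candidates:
        ev = refine_breakpoint(cand, bundle, min_segment, mode, sample)
        if ev is None:
            dropped += 1
        else:
            evidence.append(ev)
    stats["dropped_short_segment"] = dropped
    evidence = deduplicate(evidence)
    stats["evidence"] = len(evidence)
    return evidence, stats


def deduplicate(evidence: list[ChimeraEvidence]) -> list[ChimeraEvidence]:
    """At most one evidence record per original read.

    Among duplicates (e.g. a read contributing via both merged and unmerged
    paths) the exact-resolution record wins, then the lowest genome
    coordinate. Distinct reads with identical breakpoints are kept: PCR
    duplicates are not collapsed.
    """
    best: dict[str, ChimeraEvidence] = {}
    for ev in evidence:
        cur = best.get(ev.read_id)
        if cur is None:
            best[ev.read_id] = ev
            continue
        key = (ev.resolution != "exact", ev.genome_bp)
        cur_key = (cur.resolution != "exact", cur.genome_bp)
        if key < cur_key:
            best[ev.read_id] = ev
    return list(best.values())


# ---------------------------------------------------------------------------
# Clustering


def cluster_breakpoints(
    evidence: Iterable[ChimeraEvidence], window: int = 20
) -> list[BreakpointCluster]:
    """Single-linkage chaining of genome breakpoints within ``window`` nt.

    Evidence is grouped by (sequence, TE, direction, transcript strand, TE
    strand); consecutive breakpoints <= window apart join one cluster. The
    representative breakpoint of a cluster is the modal member value (ties
    to the smallest).
    """
    groups: dict[tuple, list[ChimeraEvidence]] = {}
    for ev in evidence:
        key = (ev.seqid, ev.te_name, ev.direction, ev.transcript_strand, ev.te_strand)
        groups.setdefault(key, []).append(ev)
    clusters = []
    for key, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
        members.sort(key=lambda e: e.genome_bp)
        current = [members[0]]
        for ev in members[1:]:
            if ev.genome_bp - current[-1].genome_bp <= window:
                current.append(ev)
            else:
                clusters.append(
                    BreakpointCluster(key[0], key[1], key[2], key[3], key[4], current)
                )
                current = [ev]
        clusters.append(
            BreakpointCluster(key[0], key[1], key[2], key[3], key[4], current)
        )
    return clusters


def annotate_clusters(
    clusters: list[BreakpointCluster], index: AnnotationIndex
) -> list[BreakpointCluster]:
    """Label clusters with gene(s), feature class, nearest splice site and
    TE orientation relative to the gene."""
    for cl in clusters:
        bp = cl.rep_genome_bp
        hits = index.query(cl.seqid, bp)
        cl.gene_ids = [g.id for g, _ in hits]
        if hits:
            gene, feat = hits[0]
            if len(hits) > 1 and cl.transcript_strand is not None:
                same = [(g, f) for g, f in hits if g.strand == cl.transcript_strand]
                if same:
                    gene, feat = same[0]
            cl.gene_id = gene.id
            cl.feature = feat
            cl.orientation_class = (
                "sense" if cl.te_strand == gene.strand else "antisense"
            )
        else:
            cl.gene_id = None
            cl.feature = "intergenic"
            cl.orientation_class = "intergenic"
        near = index.nearest_splice_site(cl.seqid, bp)
        if near is not None:
            cl.splice_site_distance = near[0]
            cl.splice_site_kind = near[1].kind
    return clusters


# ---------------------------------------------------------------------------
# Germline insertion calling


@dataclass
class InsertionCall:
    seqid: str
    te_name: str
    te_orientation: str  # +/- on the genome
    orientation_class: str  # sense | antisense | intergenic | both
    upstream_bp: Optional[int]
    downstream_bp: Optional[int]
    tsd_len: Optional[int]
    tsd_seq: Optional[str]
    population_frequency: Optional[float]
    support_upstream: int
    support_downstream: int
    gene_id: Optional[str] = None
    one_sided: bool = False

    @property
    def point(self) -> Optional[int]:
        return self.downstream_bp if self.downstream_bp is not None else self.upstream_bp


_IND_RE = re.compile(r":i(\d+):")


def individuals_from_reads(members: Iterable[ChimeraEvidence]) -> Optional[set[int]]:
    inds = set()
    for m in members:
        hit = _IND_RE.search(m.read_id)
        if hit is None:
            return None
        inds.add(int(hit.group(1)))
    return inds


def _ref_spanning_reads(
    alignments: Iterable[PairAlignment], seqid: str, lo: int, hi: int, margin: int = 10
) -> int:
    n = 0
    for pa in alignments:
        for aln, end in ((pa.a1, pa.pair.end1), (pa.a2, pa.pair.end2)):
            if aln.cls != CLS_GENOME or aln.ref != seqid:
                continue
            if aln.pos + margin <= lo and aln.pos + len(end) >= hi + margin:
                n += 1
                break
    return n


def call_germline_insertions(
    clusters: list[BreakpointCluster],
    bundle: ReferenceBundle,
    annotation: Optional[AnnotationIndex] = None,
    n_individuals: Optional[int] = None,
    min_frequency: float = 0.5,
    pairing_window: int = 50,
    alignments: Optional[list[PairAlignment]] = None,
) -> tuple[list[InsertionCall], list[InsertionCall]]:
    """Join upstream/downstream gDNA clusters into insertion calls.

    The TSD is the genomic overlap between the upstream and downstream
    breakpoints. Population frequency is the fraction of individuals
    contributing at least one supporting read when read names carry
    individual tags; otherwise supporting / (supporting + reference-spanning
    reads at the locus). Calls below ``min_frequency`` go to the secondary
    list rather than being discarded.
    """
    ups = [c for c in clusters if c.direction == DIR_UPSTREAM]
    downs = [c for c in clusters if c.direction == DIR_DOWNSTREAM]
    used_down: set[int] = set()
    calls: list[InsertionCall] = []

    def _make_call(up, down):
        members = list(up.members if up else []) + list(down.members if down else [])
        anchor = up or down
        tsd_len = tsd_seq = None
        up_bp = up.rep_genome_bp if up else None
        down_bp = down.rep_genome_bp if down else None
        if up and down:
            tsd_len = up_bp - down_bp
            tsd_seq = bundle.get(anchor.seqid)[down_bp:up_bp].upper()
        freq = None
        inds = individuals_from_reads(members)
        if inds is not None and n_individuals:
            freq = len(inds) / n_individuals
        elif alignments is not None:
            lo = down_bp if down_bp is not None else up_bp
            hi = up_bp if up_bp is not None else down_bp
            ref_n = _ref_spanning_reads(alignments, anchor.seqid, lo, hi)
            freq = len(members) / (len(members) + ref_n) if members else 0.0
        orientation = anchor.te_strand
        gene_id = None
        ocls = "intergenic"
        if annotation is not None:
            pos = down_bp if down_bp is not None else up_bp
            genes = annotation.genes_at(anchor.seqid, pos)
            if genes:
                strands = {g.strand for g in genes}
                gene_id = genes[0].id
                if len(strands) > 1:
                    ocls = "both"
                else:
                    ocls = "sense" if orientation in strands else "antisense"
        return InsertionCall(
            seqid=anchor.seqid,
            te_name=anchor.te_name,
            te_orientation=orientation,
            orientation_class=ocls,
            upstream_bp=up_bp,
            downstream_bp=down_bp,
            tsd_len=tsd_len,
            tsd_seq=tsd_seq,
            population_frequency=freq,
            support_upstream=up.support if up else 0,
            support_downstream=down.support if down else 0,
            gene_id=gene_id,
            one_sided=not (up and down),
        )

    for up in sorted(ups, key=lambda c: (c.seqid, c.rep_genome_bp)):
        best = None
        for j, down in enumerate(downs):
            if j in used_down:
                continue
            if down.seqid != up.seqid or down.te_name != up.te_name:
                continue
            if down.te_strand != up.te_strand:
                continue
            gap = up.rep_genome_bp - down.rep_genome_bp
            if 0 <= gap <= pairing_window:
                if best is None or gap < best[0]:
                    best = (gap, j, down)
        if best is not None:
            used_down.add(best[1])
            calls.append(_make_call(up, best[2]))
        else:
            calls.append(_make_call(up, None))
    for j, down in enumerate(downs):
        if j not in used_down:
            calls.append(_make_call(None, down))

    primary = [c for c in calls if (c.population_frequency or 0) >= min_frequency]
    secondary = [c for c in calls if (c.population_frequency or 0) < min_frequency]
    return primary, secondary
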