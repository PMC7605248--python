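"""Quantification of chimera biology: autonomy, LTR junction ratios,
per-insertion penetrance, splice-motif context, and isoform-repertoire
expansion.

Read counting for penetrance and LTR ratios uses junction-window
containment: a 2x``window`` nt sequence spanning the junction is
reconstructed from the references and counted in the contig pool (both
orientations). Chimeric and canonical junctions are counted by the identical
mechanism, so their detection efficiencies cancel in ratios.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from ._seq import revcomp
from .chimera import DIR_GENE_TO_TE, DIR_TE_TO_GENE, BreakpointCluster
from .readproc import CLS_TE, Contig, PairAlignment
from .refprep import AnnotationIndex, ReferenceBundle, TEConsensusLibrary

# ---------------------------------------------------------------------------
# Junction windows


def _contig_corpus(contigs: Iterable[Contig]) -> str:
    return "#".join(c.sequence.upper() for c in contigs)


def count_window(corpus: str, window: str) -> int:
    """Occurrences of a junction window (either orientation) in the contigs."""
    if not window:
        return 0
    w = window.upper()
    return corpus.count(w) + corpus.count(revcomp(w))


def te_side_window(
    bundle: ReferenceBundle, te_name: str, te_bp: int, te_strand: str,
    direction: str, window: int,
) -> str:
    """Transcript-oriented TE sequence adjacent to the junction."""
    cons = bundle.get(te_name)
    if direction == DIR_GENE_TO_TE:
        # TE segment begins at the breakpoint
        if te_strand == "+":
            return cons[te_bp : te_bp + window]
        return revcomp(cons[max(0, te_bp - window) : te_bp])
    # TE segment ends at the breakpoint
    if te_strand == "+":
        return cons[max(0, te_bp - window) : te_bp]
    return revcomp(cons[te_bp : te_bp + window])


def genome_side_window(
    bundle: ReferenceBundle, seqid: str, bp: int, strand: str,
    direction: str, window: int,
) -> str:
    ref = bundle.get(seqid)
    if direction == DIR_GENE_TO_TE:  # genome provides the 5' transcript side
        if strand == "+":
            return ref[max(0, bp - window) : bp].upper()
        return revcomp(ref[bp : bp + window]).upper()
    if strand == "+":
        return ref[bp : bp + window].upper()
    return revcomp(ref[max(0, bp - window) : bp]).upper()


def chimeric_junction_window(
    cluster: BreakpointCluster, bundle: ReferenceBundle, window: int = 30
) -> str:
    strand = cluster.transcript_strand or "+"
    g = genome_side_window(
        bundle, cluster.seqid, cluster.rep_genome_bp, strand, cluster.direction, window
    )
    t = te_side_window(
        bundle, cluster.te_name, cluster.rep_te_bp, cluster.te_strand,
        cluster.direction, window,
    )
    return g + t if cluster.direction == DIR_GENE_TO_TE else t + g


def canonical_junction_window(
    cluster: BreakpointCluster,
    bundle: ReferenceBundle,
    annotation: AnnotationIndex,
    window: int = 30,
) -> str:
    """Canonical counterpart of a chimeric junction.

    If the genomic breakpoint coincides with an annotated splice site the
    canonical read is the spliced exon-exon junction across that site;
    otherwise (read-through into a UTR or exon) it is the contiguous genomic
    window across the breakpoint.
    """
    ref = bundle.get(cluster.seqid)
    bp = cluster.rep_genome_bp
    want = "donor" if cluster.direction == DIR_GENE_TO_TE else "acceptor"
    near = annotation.nearest_splice_site(cluster.seqid, bp, kind=want)
    if near is not None and near[0] == 0:
        partner = annotation.junction_partner(near[1])
        if partner is not None:
            # spliced exon-exon junction in genomic orientation (windows are
            # counted in both orientations, so strand does not matter here)
            j1, j2 = min(bp, partner), max(bp, partner)
            return (ref[max(0, j1 - window) : j1] + ref[j2 : j2 + window]).upper()
    return ref[max(0, bp - window) : bp + window].upper()


# ---------------------------------------------------------------------------
# Autonomy (TE-only vs TE-gene reads)


@dataclass
class AutonomyStats:
    te_name: str
    te_length: int
    te_only_reads: int
    te_only_per_nt: float
    te_gene_reads: int


def autonomy_stats(
    alignments: Iterable[PairAlignment],
    clusters: list[BreakpointCluster],
    te_library: TEConsensusLibrary,
) -> list[AutonomyStats]:
    """TE-only reads (both in-silico ends entirely on one consensus, per nt)
    versus TE-gene breakpoint-spanning reads per transposon."""
    te_only: dict[str, int] = {e.name: 0 for e in te_library}
    for pa in alignments:
        if (
            pa.a1.cls == CLS_TE
            and pa.a2.cls == CLS_TE
            and pa.a1.ref == pa.a2.ref
            and pa.a1.ref in te_only
        ):
            te_only[pa.a1.ref] += 1
    te_gene: dict[str, int] = {e.name: 0 for e in te_library}
    for cl in clusters:
        if cl.te_name in te_gene:
            te_gene[cl.te_name] += cl.support
    out = []
    for entry in te_library:
        L = len(entry.sequence)
        out.append(
            AutonomyStats(
                entry.name, L, te_only[entry.name], te_only[entry.name] / L,
                te_gene[entry.name],
            )
        )
    return out


# ---------------------------------------------------------------------------
# LTR junction ratios


@dataclass
class LTRRatio:
    te_name: str
    end: str  # 5' | 3'
    gene_ltr_reads: int
    ltr_te_reads: int
    raw_ratio: Optional[float]
    ratio_percent: Optional[float]  # capped at 100
    capped: bool


def _outward_gene(cluster: BreakpointCluster, end: str) -> bool:
    """True when the genomic sequence sits on the outward side of this
    consensus end (upstream of the 5' LTR / downstream of the 3' LTR)."""
    if end == "5'":
        return (cluster.direction == DIR_GENE_TO_TE and cluster.te_strand == "+") or (
            cluster.direction == DIR_TE_TO_GENE and cluster.te_strand == "-"
        )
    return (cluster.direction == DIR_TE_TO_GENE and cluster.te_strand == "+") or (
        cluster.direction == DIR_GENE_TO_TE and cluster.te_strand == "-"
    )


def ltr_ratio(
    clusters: list[BreakpointCluster],
    contigs: Iterable[Contig],
    te_library: TEConsensusLibrary,
    bundle: ReferenceBundle,
    window: int = 30,
) -> tuple[list[LTRRatio], list[str]]:
    """Ratio of gene-LTR to LTR-TE junction-spanning reads per LTR end.

    Autonomous LTR transcription initiates in the 5' LTR, so gene-LTR reads
    (genomic sequence outward of the LTR) should be absent; gene-driven
    read-through produces them at rates comparable to the LTR/core boundary
    (LTR-TE) reads. Reported percentages are capped at 100 with the raw
    ratio retained. TEs without LTR annotation are skipped and listed.
    """
    corpus = _contig_corpus(contigs)
    results, skipped = [], []
    for entry in te_library:
        if entry.ltr5 is None or entry.ltr3 is None:
            skipped.append(entry.name)
            continue
        cons = entry.sequence.upper()
        for end, ltr in (("5'", entry.ltr5), ("3'", entry.ltr3)):
            lo, hi = ltr
            boundary = hi if end == "5'" else lo  # LTR/core boundary
            ltr_te_win = cons[max(0, boundary - window) : boundary + window]
            ltr_te = count_window(corpus, ltr_te_win)
            gene_ltr = 0
            for cl in clusters:
                if cl.te_name != entry.name:
                    continue
                if not (lo <= cl.rep_te_bp <= hi):
                    continue
                if not _outward_gene(cl, end):
                    continue
                gene_ltr += count_window(
                    corpus, chimeric_junction_window(cl, bundle, window)
                )
            if ltr_te == 0:
                results.append(
                    LTRRatio(entry.name, end, gene_ltr, 0, None, None, False)
                )
            else:
                raw = gene_ltr / ltr_te
                results.append(
                    LTRRatio(
                        entry.name, end, gene_ltr, ltr_te, raw,
                        min(100.0, 100.0 * raw), raw > 1.0,
                    )
                )
    return results, skipped


# ---------------------------------------------------------------------------
# Penetrance


@dataclass
class JunctionCounts:
    gene_id: str
    te_name: str
    seqid: str
    upstream_bp: Optional[int]  # gene_to_te junction
    downstream_bp: Optional[int]  # te_to_gene junction
    chimeric_upstream: int = 0
    canonical_upstream: int = 0
    chimeric_downstream: int = 0
    canonical_downstream: int = 0
    per_replicate: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    def _pen(self, c: int, k: int) -> Optional[float]:
        return c / (c + k) if c + k > 0 else None

    @property
    def penetrance_upstream(self) -> Optional[float]:
        return self._pen(self.chimeric_upstream, self.canonical_upstream)

    @property
    def penetrance_downstream(self) -> Optional[float]:
        return self._pen(self.chimeric_downstream, self.canonical_downstream)

    @property
    def penetrance(self) -> Optional[float]:
        c = self.chimeric_upstream + self.chimeric_downstream
        k = self.canonical_upstream + self.canonical_downstream
        return self._pen(c, k)


def penetrance(
    clusters: list[BreakpointCluster],
    contigs,
    annotation: AnnotationIndex,
    bundle: ReferenceBundle,
    window: int = 30,
) -> list[JunctionCounts]:
    """Per-insertion chimeric penetrance.

    For every (gene, TE) chimera locus, counts reads spanning the chimeric
    junction and reads spanning the canonical junction crossing the same
    boundary; penetrance = chimeric / (chimeric + canonical) per side, with
    the combined value read-weighted. ``contigs`` may be a list (single
    sample) or a dict of sample -> contig list for per-replicate values.
    """
    by_sample = contigs if isinstance(contigs, dict) else {"pooled": list(contigs)}
    corpora = {s: _contig_corpus(cs) for s, cs in by_sample.items()}
    annotated = [c for c in clusters if c.gene_id is not None]
    loci: dict[tuple[str, str], list[BreakpointCluster]] = {}
    for cl in annotated:
        loci.setdefault((cl.gene_id, cl.te_name), []).append(cl)
    out = []
    for (gene_id, te_name), cls in sorted(loci.items()):
        jc = JunctionCounts(gene_id, te_name, cls[0].seqid, None, None)
        totals = {s: [0, 0, 0, 0] for s in corpora}
        for cl in cls:
            chim_w = chimeric_junction_window(cl, bundle, window)
            canon_w = canonical_junction_window(cl, bundle, annotation, window)
            for s, corpus in corpora.items():
                c = count_window(corpus, chim_w)
                k = count_window(corpus, canon_w)
                if cl.direction == DIR_GENE_TO_TE:
                    totals[s][0] += c
                    totals[s][1] += k
                else:
                    totals[s][2] += c
                    totals[s][3] += k
            if cl.direction == DIR_GENE_TO_TE:
                jc.upstream_bp = cl.rep_genome_bp
            else:
                jc.downstream_bp = cl.rep_genome_bp
        for s, (cu, ku, cd, kd) in totals.items():
            jc.per_replicate[s] = (cu, ku, cd, kd)
            jc.chimeric_upstream += cu
            jc.canonical_upstream += ku
            jc.chimeric_downstream += cd
            jc.canonical_downstream += kd
        out.append(jc)
    return out


# ---------------------------------------------------------------------------
# Splice-motif scanning


# Canonical splice-site position weight matrices (standard consensus
# MAG|GTRAGT donors and pyrimidine-rich ...NCAG|G acceptors). The invariant
# dinucleotide (GT/GC donors, AG acceptors) is classified separately and not
# scored.
DONOR_PWM = {
    -3: {"A": 0.33, "C": 0.37, "G": 0.18, "T": 0.12},
    -2: {"A": 0.60, "C": 0.13, "G": 0.14, "T": 0.13},
    -1: {"A": 0.08, "C": 0.04, "G": 0.81, "T": 0.07},
    3: {"A": 0.60, "C": 0.03, "G": 0.34, "T": 0.03},
    4: {"A": 0.70, "C": 0.08, "G": 0.12, "T": 0.10},
    5: {"A": 0.06, "C": 0.05, "G": 0.82, "T": 0.07},
    6: {"A": 0.17, "C": 0.19, "G": 0.14, "T": 0.50},
}
ACCEPTOR_PWM = {
    -8: {"A": 0.10, "C": 0.35, "G": 0.10, "T": 0.45},
    -7: {"A": 0.10, "C": 0.35, "G": 0.10, "T": 0.45},
    -6: {"A": 0.10, "C": 0.35, "G": 0.10, "T": 0.45},
    -5: {"A": 0.10, "C": 0.35, "G": 0.10, "T": 0.45},
    -3: {"A": 0.10, "C": 0.65, "G": 0.05, "T": 0.20},
    1: {"A": 0.25, "C": 0.13, "G": 0.49, "T": 0.13},
}

MATCH_CONSENSUS = "consensus"
MATCH_GC = "noncanonical_GC"
MATCH_NONE = "none"


@dataclass
class MotifHit:
    te_name: str
    te_bp: int
    site_class: str  # donor | acceptor
    window: str
    match_class: str
    score: Optional[float]  # bits
    frame_offset: int = 0
    truncated: bool = False


def _pwm_score(seq_at, pwm) -> Optional[float]:
    """Log-odds (bits) vs uniform background; None when out of range."""
    total = 0.0
    for rel, freqs in pwm.items():
        base = seq_at(rel)
        if base is None:
            return None
        total += math.log2(freqs.get(base, 0.02) / 0.25)
    return total


def _scan_frames(oriented: str, b: int, kind: str, search: int):
    """Best-scoring splice frame within +-search nt of the breakpoint.

    Returns (dinucleotide, score, offset) or None. For donors the
    dinucleotide is the first two intronic bases (GT consensus, GC
    noncanonical); for acceptors the last two (AG only).
    """
    best = None
    for off in range(-search, search + 1):
        p = b + off

        def at(rel, p=p):
            # rel > 0: intronic side for donors / exonic for acceptors
            i = p + (rel - 1) if rel > 0 else p + rel
            if 0 <= i < len(oriented):
                return oriented[i]
            return None

        if kind == "donor":
            dinuc = (at(1) or "") + (at(2) or "")
            if dinuc not in ("GT", "GC"):
                continue
            score = _pwm_score(at, DONOR_PWM)
        else:
            dinuc = (at(-2) or "") + (at(-1) or "")
            if dinuc != "AG":
                continue
            score = _pwm_score(at, ACCEPTOR_PWM)
        if score is None:
            continue
        if best is None or score > best[1] or (score == best[1] and abs(off) < abs(best[2])):
            best = (dinuc, score, off)
    return best


def empirical_threshold(
    windows: list[str], kind: str, search: int = 3, n_shuffles: int = 50,
    quantile: float = 99.0, seed: int = 0,
) -> float:
    """Null score threshold: 99th percentile of best-frame scores on
    shuffled copies of the scanned windows."""
    rng = np.random.default_rng(seed)
    scores = []
    for w in windows:
        chars = np.array(list(w))
        for _ in range(n_shuffles):
            rng.shuffle(chars)
            shuf = "".join(chars)
            hit = _scan_frames(shuf, len(shuf) // 2, kind, search)
            scores.append(hit[1] if hit is not None else -np.inf)
    finite = [s for s in scores if np.isfinite(s)]
    if not finite:
        return 0.0
    return float(np.percentile(finite, quantile))


def scan_motifs(
    te_library: TEConsensusLibrary,
    clusters: list[BreakpointCluster],
    flank: int = 11,
    search: int = 3,
    threshold: Optional[float] = None,
    null_seed: int = 0,
) -> list[MotifHit]:
    """Scan transposon sequence around cluster breakpoints for splice
    donor/acceptor consensus motifs.

    Scanning is strand-aware: the consensus is oriented as it appears in
    the transcript. A gene_to_te junction enters the TE, so its upstream TE
    context is screened for an acceptor; a te_to_gene junction exits the
    TE through a donor. Exact GT donors at or near (+-``search``) the
    breakpoint score as ``consensus``; GC donors with an otherwise strong
    context as ``noncanonical_GC``. When no threshold is given it is set to
    the 99th percentile of best-frame scores on shuffled windows.
    """
    jobs = []
    for cl in clusters:
        if cl.te_name not in te_library:
            continue
        cons = te_library[cl.te_name].sequence.upper()
        L = len(cons)
        oriented = cons if cl.te_strand == "+" else revcomp(cons)
        b = cl.rep_te_bp if cl.te_strand == "+" else L - cl.rep_te_bp
        kind = "acceptor" if cl.direction == DIR_GENE_TO_TE else "donor"
        half = flank // 2
        lo, hi = b - half, b + flank - half
        window = oriented[max(0, lo) : hi]
        truncated = lo < 0 or hi > L
        jobs.append((cl, oriented, b, kind, window, truncated))
    if threshold is None:
        thr = {
            kind: empirical_threshold(
                [j[4] for j in jobs if j[3] == kind] or ["A" * flank],
                kind, search, seed=null_seed,
            )
            for kind in ("donor", "acceptor")
        }
    else:
        thr = {"donor": threshold, "acceptor": threshold}
    hits = []
    for cl, oriented, b, kind, window, truncated in jobs:
        best = _scan_frames(oriented, b, kind, search)
        if best is None or best[1] < thr[kind]:
            match, score, off = MATCH_NONE, best[1] if best else None, 0
        else:
            dinuc, score, off = best
            match = MATCH_GC if (kind == "donor" and dinuc == "GC") else MATCH_CONSENSUS
        hits.append(
            MotifHit(cl.te_name, cl.rep_te_bp, kind, window, match, score, off, truncated)
        )
    return hits


# ---------------------------------------------------------------------------
# Isoform enumeration


@dataclass
class IsoformCatalog:
    count: int
    baseline_count: int
    chains: list[tuple[tuple[int, str, str], ...]]  # ((pos, origin, kind), ...)


def enumerate_isoforms(
    host_donors: list[int],
    host_acceptors: list[int],
    te_donors: list[int],
    te_acceptors: list[int],
    count_retention: bool = False,
) -> IsoformCatalog:
    """Count transcripts formed by donor->acceptor splice chains through an
    intronic insertion.

    A chain starts at a host donor, alternates donor -> acceptor with
    strictly increasing coordinates (sites from host or TE, no reuse), and
    terminates at the first host acceptor reached. The baseline count uses
    host sites only. Intron retention adds one isoform when requested.
    """
    donors = sorted(
        [(p, "host", "donor") for p in host_donors]
        + [(p, "te", "donor") for p in te_donors]
    )
    acceptors = sorted(
        [(p, "host", "acceptor") for p in host_acceptors]
        + [(p, "te", "acceptor") for p in te_acceptors]
    )

    def chains_from(restrict_host: bool):
        complete = []

        def step(chain, pos, need):
            pool = acceptors if need == "acceptor" else donors
            for site in pool:
                if site[0] <= pos:
                    continue
                if restrict_host and site[1] != "host":
                    continue
                nxt = chain + (site,)
                if need == "acceptor":
                    if site[1] == "host":
                        complete.append(nxt)
                    else:
                        step(nxt, site[0], "donor")
                else:
                    step(nxt, site[0], "acceptor")

        for d in donors:
            if d[1] != "host":
                continue
            step((d,), d[0], "acceptor")
        return complete

    chains = chains_from(False)
    baseline = len(chains_from(True))
    count = len(chains)
    if count_retention:
        count += 1
        baseline += 1
    return IsoformCatalog(count, baseline, chains)
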