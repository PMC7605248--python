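"""Amplification-artifact FDR control with immobile genetic elements (IGEs).

IGEs are ordinary single-copy exons matched to each transposon's expression
level. Because an exon cannot relocate, any chimera joining an IGE to another
gene is almost certainly an in-vitro amplification artifact; the IGE chimera
rate therefore calibrates a per-sample detection threshold. Decoy handling
mirrors TE consensus handling exactly — the exon sequence is appended as an
extra reference record and its genomic locus masked — so IGE and TE chimeras
flow through one code path.

The FDR at support threshold T is the mean over IGE sets of (IGE chimera
clusters with support >= T) divided by the total number of detected chimeric
clusters; the reported threshold is the smallest T meeting the target
(default 0.05%). Keeping the denominator at the unfiltered total makes the
FDR non-increasing in T by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chimera import BreakpointCluster
from .refprep import (
    AnnotationIndex,
    MaskedGenome,
    ReferenceBundle,
    TEConsensusLibrary,
    TEEntry,
)

IGE_PREFIX = "IGE|"


@dataclass
class IGEMember:
    exon_id: str
    seqid: str
    start: int
    end: int
    gene_id: str
    expression: float
    matched_te: str


@dataclass
class IGESet:
    set_id: int
    members: list[IGEMember]


@dataclass
class FDRReport:
    n_sets: int
    total_chimeras: int
    ige_counts_per_set: list[int]
    fdr: float  # at threshold 1 (pooled accounting)
    per_set_fdr: list[float]
    threshold: int
    fdr_at_threshold: float
    target: float
    target_reachable: bool
    fdr_by_threshold: dict[int, float] = field(default_factory=dict)
    expression_bin_rates: dict[str, float] = field(default_factory=dict)


def exon_expression_from_alignments(alignments, annotation: AnnotationIndex) -> dict[str, float]:
    """Read counts per exon from genome-class in-silico end alignments."""
    from .readproc import CLS_GENOME

    catalog = exon_catalog(annotation)
    counts = {c[0]: 0 for c in catalog}
    by_seq: dict[str, list] = {}
    for c in catalog:
        by_seq.setdefault(c[1], []).append(c)
    for pa in alignments:
        for aln, end in ((pa.a1, pa.pair.end1), (pa.a2, pa.pair.end2)):
            if aln.cls != CLS_GENOME:
                continue
            lo, hi = aln.pos, aln.pos + len(end)
            for exon_id, seqid, s, e, _gene in by_seq.get(aln.ref, ()):
                if s < hi and lo < e:
                    counts[exon_id] += 1
    return {k: float(v) for k, v in counts.items()}


def te_expression_from_alignments(alignments, te_names) -> dict[str, float]:
    """Read counts per transposon (any in-silico end on the consensus)."""
    from .readproc import CLS_TE

    counts = {n: 0 for n in te_names}
    for pa in alignments:
        for aln in (pa.a1, pa.a2):
            if aln.cls == CLS_TE and aln.ref in counts:
                counts[aln.ref] += 1
    return {k: float(v) for k, v in counts.items()}


def run_ige_detection(
    pairs,
    ige_bundle: ReferenceBundle,
    ige_sets: list[IGESet],
    annotation: AnnotationIndex,
    mode: str = "cdna",
    sample: str = "s1",
    **detect_kwargs,
):
    """Re-run the identical detection machinery against the IGE-decoy
    reference and split output into TE clusters and IGE artifact clusters."""
    from .pipeline import detect_sample

    result = detect_sample(
        pairs, ige_bundle, mode=mode, sample=sample, annotation=annotation,
        **detect_kwargs,
    )
    te_clusters, ige_clusters = split_ige_clusters(
        result.clusters, ige_sets, annotation
    )
    return result, te_clusters, ige_clusters


def exon_catalog(annotation: AnnotationIndex) -> list[tuple[str, str, int, int, str]]:
    """(exon_id, seqid, start, end, gene_id) for every distinct exon."""
    seen = set()
    out = []
    for g in annotation.genes:
        for t in g.transcripts:
            for i, (s, e) in enumerate(t.exons):
                key = (g.seqid, s, e)
                if key in seen:
                    continue
                seen.add(key)
                out.append((f"{g.id}:e{i + 1}", g.seqid, s, e, g.id))
    return out


def select_iges(
    annotation: AnnotationIndex,
    exon_expression: dict[str, float],
    te_expression: dict[str, float],
    n_sets: int = 10,
    seed: int = 0,
    masked_genome: Optional[MaskedGenome] = None,
    exclude_genes: Optional[set] = None,
) -> list[IGESet]:
    """For each TE, pick one expression-matched exon per set (sets disjoint).

    Matching is by 2-fold log bin around the TE's expression; an exhausted
    bin is widened once to 4-fold, after which selection fails. Exons
    overlapping masked intervals are excluded, as are exons of
    ``exclude_genes`` — genes already carrying transposon chimera loci are
    not clean immobile decoys, and masking their exons would erase the very
    junctions under study.
    """
    rng = np.random.default_rng(seed)
    catalog = exon_catalog(annotation)
    if masked_genome is not None:
        def clean(seqid, s, e):
            return not any(
                s < me and ms < e
                for ms, me in masked_genome.masked_intervals.get(seqid, [])
            )
        catalog = [c for c in catalog if clean(c[1], c[2], c[3])]
    if exclude_genes:
        catalog = [c for c in catalog if c[4] not in exclude_genes]
    used: set[str] = set()
    sets = []
    for set_id in range(1, n_sets + 1):
        members = []
        for te, level in sorted(te_expression.items()):
            if level <= 0:
                continue
            chosen = None
            for fold in (2.0, 4.0):
                pool = [
                    c for c in catalog
                    if c[0] not in used
                    and c[0] in exon_expression
                    and level / fold <= exon_expression[c[0]] <= level * fold
                ]
                if pool:
                    chosen = pool[int(rng.integers(0, len(pool)))]
                    break
            if chosen is None:
                raise ValueError(
                    f"no expression-matched exon left for TE {te!r} in set {set_id}"
                )
            used.add(chosen[0])
            members.append(
                IGEMember(chosen[0], chosen[1], chosen[2], chosen[3], chosen[4],
                          exon_expression[chosen[0]], te)
            )
        sets.append(IGESet(set_id, members))
    return sets


def build_ige_reference(
    bundle: ReferenceBundle, ige_sets: list[IGESet]
) -> ReferenceBundle:
    """Append each selected exon as a decoy reference record and mask its
    genomic locus, exactly mirroring TE consensus handling."""
    members = [m for s in ige_sets for m in s.members]
    genome = dict(bundle.masked_genome.sequences)
    intervals = {k: list(v) for k, v in bundle.masked_genome.masked_intervals.items()}
    entries = list(bundle.te_library.entries)
    for m in members:
        seq = genome[m.seqid]
        exon_seq = seq[m.start : m.end].upper()
        genome[m.seqid] = seq[: m.start] + seq[m.start : m.end].lower() + seq[m.end :]
        intervals.setdefault(m.seqid, []).append((m.start, m.end))
        entries.append(TEEntry(IGE_PREFIX + m.exon_id, exon_seq))
    for k in intervals:
        intervals[k] = sorted(intervals[k])
    return ReferenceBundle(
        MaskedGenome(genome, intervals, bundle.masked_genome.mode),
        TEConsensusLibrary(entries),
    )


def is_ige_cluster(cluster: BreakpointCluster) -> bool:
    return cluster.te_name.startswith(IGE_PREFIX)


def split_ige_clusters(
    clusters: list[BreakpointCluster],
    ige_sets: list[IGESet],
    annotation: AnnotationIndex,
    self_margin: int = 1000,
) -> tuple[list[BreakpointCluster], list[BreakpointCluster]]:
    """Split detection output into (TE clusters, IGE artifact clusters).

    IGE clusters whose genomic side lies within the decoy exon's own gene
    (plus a margin) are genuine splice junctions of that gene, not
    amplification artifacts, and are discarded.
    """
    member_gene = {IGE_PREFIX + m.exon_id: m for s in ige_sets for m in s.members}
    te_clusters, ige_clusters = [], []
    for cl in clusters:
        if not is_ige_cluster(cl):
            te_clusters.append(cl)
            continue
        m = member_gene[cl.te_name]
        gene = annotation.by_id[m.gene_id]
        bp = cl.rep_genome_bp
        if cl.seqid == gene.seqid and gene.start - self_margin <= bp < gene.end + self_margin:
            continue  # self-gene splice, not an artifact
        ige_clusters.append(cl)
    return te_clusters, ige_clusters


def _set_of(cluster: BreakpointCluster, ige_sets: list[IGESet]) -> int:
    name = cluster.te_name[len(IGE_PREFIX):]
    for s in ige_sets:
        if any(m.exon_id == name for m in s.members):
            return s.set_id
    raise KeyError(name)


def compute_fdr(
    te_clusters: list[BreakpointCluster],
    ige_clusters: list[BreakpointCluster],
    ige_sets: list[IGESet],
    target: float = 0.0005,
    expression_products: Optional[dict[str, float]] = None,
) -> FDRReport:
    """FDR per support threshold and the smallest threshold meeting target.

    fdr(T) = mean over sets of IGE clusters with support >= T, divided by
    the total number of chimeric clusters (TE + IGE) detected.
    """
    total = len(te_clusters) + len(ige_clusters)
    if total == 0:
        raise ValueError("no chimeric clusters detected")
    n_sets = len(ige_sets)
    per_set = {s.set_id: [] for s in ige_sets}
    for cl in ige_clusters:
        per_set[_set_of(cl, ige_sets)].append(cl.support)
    counts = [len(v) for v in per_set.values()]
    fdr1 = float(np.mean(counts)) / total

    max_t = max([c.support for c in ige_clusters], default=0) + 1
    fdr_by_t = {}
    threshold = None
    for t in range(1, max_t + 1):
        mean_ige = float(
            np.mean([sum(1 for s in v if s >= t) for v in per_set.values()])
        )
        fdr_by_t[t] = mean_ige / total
        if threshold is None and fdr_by_t[t] <= target:
            threshold = t
    reachable = threshold is not None
    if threshold is None:
        threshold = max_t  # fdr is 0 above the largest IGE support
        fdr_by_t[threshold] = 0.0
        reachable = fdr_by_t[threshold] <= target

    bins: dict[str, list[int]] = {}
    if expression_products:
        for cl in ige_clusters:
            prod = expression_products.get(cl.te_name)
            if prod is None or prod <= 0:
                continue
            b = f"2^{int(np.floor(np.log2(prod)))}"
            bins.setdefault(b, []).append(cl.support)
    return FDRReport(
        n_sets=n_sets,
        total_chimeras=total,
        ige_counts_per_set=counts,
        fdr=fdr1,
        per_set_fdr=[c / total for c in counts],
        threshold=threshold,
        fdr_at_threshold=fdr_by_t[threshold],
        target=target,
        target_reachable=reachable,
        fdr_by_threshold=fdr_by_t,
        expression_bin_rates={b: float(np.mean(v)) for b, v in bins.items()},
    )


def apply_threshold(
    clusters: list[BreakpointCluster], threshold: int
) -> list[BreakpointCluster]:
    return [c for c in clusters if c.support >= threshold]
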