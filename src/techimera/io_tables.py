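"""Tabular serialization of results (TSV; 1-based inclusive coordinates in
human-facing tables, BED stays 0-based half-open)."""
from __future__ import annotations

import pandas as pd

from .chimera import BreakpointCluster, ChimeraEvidence, InsertionCall


def evidence_to_frame(evidence: list[ChimeraEvidence]) -> pd.DataFrame:
    rows = []
    for e in evidence:
        rows.append(
            dict(
                read_id=e.read_id,
                sample=e.sample,
                seqid=e.seqid,
                genome_breakpoint=e.genome_bp + 1,
                te_name=e.te_name,
                te_breakpoint=e.te_bp + 1,
                te_strand=e.te_strand,
                direction=e.direction,
                resolution=e.resolution,
                transcript_strand=e.transcript_strand,
                microhomology=e.microhomology,
            )
        )
    return pd.DataFrame(rows)


def clusters_to_frame(clusters: list[BreakpointCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        row = dict(
            seqid=c.seqid,
            start=c.start + 1,
            end=c.end + 1,
            te_name=c.te_name,
            direction=c.direction,
            te_strand=c.te_strand,
            transcript_strand=c.transcript_strand,
            genome_breakpoint=c.rep_genome_bp + 1,
            te_breakpoint=c.rep_te_bp + 1,
            support=c.support,
            gene_id=c.gene_id,
            feature=c.feature,
            orientation=c.orientation_class,
            splice_site_kind=c.splice_site_kind,
            splice_site_distance=c.splice_site_distance,
        )
        for sample, n in sorted(c.sample_counts().items()):
            row[f"n_{sample}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def calls_to_frame(calls: list[InsertionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            dict(
                seqid=c.seqid,
                te_name=c.te_name,
                te_orientation=c.te_orientation,
                orientation=c.orientation_class,
                gene_id=c.gene_id,
                upstream_breakpoint=None if c.upstream_bp is None else c.upstream_bp + 1,
                downstream_breakpoint=None if c.downstream_bp is None else c.downstream_bp + 1,
                tsd_len=c.tsd_len,
                tsd_seq=c.tsd_seq,
                population_frequency=c.population_frequency,
                support_upstream=c.support_upstream,
                support_downstream=c.support_downstream,
                one_sided=c.one_sided,
            )
        )
    return pd.DataFrame(rows)


def calls_to_bed(calls: list[InsertionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        pos = c.point
        if pos is None:
            continue
        end = c.upstream_bp if c.upstream_bp is not None else pos
        rows.append(
            (c.seqid, pos, max(end, pos + 1), f"{c.te_name}({c.te_orientation})",
             c.support_upstream + c.support_downstream, c.te_orientation)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
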