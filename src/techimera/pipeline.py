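"""End-to-end convenience wrappers tying the modules together.

These are thin orchestration helpers: reads -> contigs -> in-silico pairs
-> alignment -> chimera evidence -> clusters (annotated), for one sample.
The CLI and the simulation-based analyses drive the same functions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import chimera as chi
from . import readproc as rp
from .refprep import AnnotationIndex, ReferenceBundle


@dataclass
class DetectionResult:
    contigs: list[rp.Contig]
    alignments: list[rp.PairAlignment]
    evidence: list[chi.ChimeraEvidence]
    clusters: list[chi.BreakpointCluster]
    stats: dict = field(default_factory=dict)


def detect_sample(
    pairs: Iterable[tuple[str, str, str]],
    bundle: ReferenceBundle,
    mode: str = "cdna",
    sample: str = "s1",
    annotation: Optional[AnnotationIndex] = None,
    index: Optional[rp.ReferenceIndex] = None,
    L_is: int = 100,
    window: int = 20,
    min_segment: int = 20,
    merged_only: bool = False,
) -> DetectionResult:
    """Run the full detection path for one sample's read pairs."""
    contigs, merge_stats = rp.contigs_from_pairs(
        pairs, stranded=(mode == "cdna"), merged_only=merged_only
    )
    isp, is_stats = rp.make_insilico_pairs(contigs, L_is)
    if index is None:
        index = rp.ReferenceIndex(bundle)
    alignments = rp.align_pairs(isp, index)
    evidence, det_stats = chi.detect_chimeras(
        alignments, bundle, mode=mode, sample=sample, min_segment=min_segment
    )
    clusters = chi.cluster_breakpoints(evidence, window=window)
    if annotation is not None:
        chi.annotate_clusters(clusters, annotation)
    return DetectionResult(
        contigs, alignments, evidence, clusters,
        {**merge_stats, **is_stats, **det_stats},
    )
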