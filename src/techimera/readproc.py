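"""Paired-read merging, in-silico read derivation, and alignment.

Paired reads are merged into contigs by best overlap (FLASH-style, default
maximum mismatch ratio 0.15, overlap range 10-170 nt). From every contig two
in-silico paired-end reads of length ``L_is`` (default 100 nt) are taken from
the contig ends; screening those against the combined reference finds
candidate gene|TE chimeras while the parent contig retains the full junction
sequence for single-nucleotide refinement.

The internal aligner is exact-seed (k=31) and extend with at most two
mismatches and no indels — sufficient for error-free synthetic data and for
classifying ends as genome/te/multi/unmapped. Soft-masked reference bases are
excluded from seeding, so reads from repeat copies can only anchor on the
appended consensus records. Real data can be imported as SAM from any
split-read-capable aligner via :func:`read_alignments_sam`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from ._seq import revcomp
from .refprep import ReferenceBundle

log = logging.getLogger(__name__)

CLS_GENOME = "genome"
CLS_TE = "te"
CLS_UNMAPPED = "unmapped"
CLS_MULTI = "multi"


# ---------------------------------------------------------------------------
# Merging


@dataclass
class Contig:
    id: str
    sequence: str
    read_id: str
    merged: bool
    strand_of_origin: Optional[str] = None  # transcript strand, cDNA only

    def __len__(self) -> int:
        return len(self.sequence)


def merge_read_pair(
    r1: str,
    r2: str,
    max_mismatch_ratio: float = 0.15,
    max_overlap: int = 170,
    min_overlap: int = 10,
) -> Optional[str]:
    """Merge a read pair by the best overlap of r1 with revcomp(r2).

    Returns the merged contig, or None when no overlap in
    ``[min_overlap, max_overlap]`` has mismatch ratio <= the maximum. The
    best overlap is the one with the lowest mismatch ratio (ties go to the
    longer overlap).
    """
    if not r1 or not r2:
        raise ValueError("reads must be non-empty")
    rc2 = revcomp(r2)
    hi = min(len(r1), len(rc2), max_overlap)
    if hi < min_overlap:
        return None
    # fast path: exact overlap (error-free data)
    probe = rc2[: min(16, min_overlap)]
    start = max(0, len(r1) - hi)
    while True:
        pos = r1.find(probe, start)
        if pos == -1:
            break
        o = len(r1) - pos
        if min_overlap <= o <= max_overlap and r1[pos:] == rc2[:o]:
            return r1 + rc2[o:]
        start = pos + 1
    # general path: score all overlaps
    a = np.frombuffer(r1.encode(), dtype=np.uint8)
    b = np.frombuffer(rc2.encode(), dtype=np.uint8)
    best = None  # (ratio, -overlap)
    for o in range(min_overlap, hi + 1):
        mm = int(np.count_nonzero(a[len(a) - o :] != b[:o]))
        ratio = mm / o
        if ratio <= max_mismatch_ratio and (best is None or (ratio, -o) < best[:2]):
            best = (ratio, -o, o)
    if best is None:
        return None
    o = best[2]
    merged = r1[: len(r1) - o]
    # consensus over the overlap: keep r1's call (constant qualities)
    merged += r1[len(r1) - o :] + rc2[o:]
    return merged


def contigs_from_pairs(
    pairs: Iterable[tuple[str, str, str]],
    stranded: bool = False,
    merged_only: bool = False,
    max_mismatch_ratio: float = 0.15,
    max_overlap: int = 170,
    min_overlap: int = 10,
) -> tuple[list[Contig], dict]:
    """Merge read pairs into contigs.

    For stranded (cDNA) input, mate 1 carries the transcript strand, so the
    merged contig is the transcript-sense sequence. Unmerged pairs pass
    through as two independent contigs (mate 2 reverse-complemented so both
    keep the mate-1 orientation) unless ``merged_only`` is set.
    """
    contigs = []
    stats = {"merged": 0, "unmerged": 0}
    for name, r1, r2 in pairs:
        m = merge_read_pair(r1, r2, max_mismatch_ratio, max_overlap, min_overlap)
        strand = "+" if stranded else None
        if m is not None:
            stats["merged"] += 1
            contigs.append(Contig(name, m, name, True, strand))
        else:
            stats["unmerged"] += 1
            if not merged_only:
                contigs.append(Contig(name + "/1", r1, name, False, strand))
                contigs.append(Contig(name + "/2", revcomp(r2), name, False, strand))
    return contigs, stats


# ---------------------------------------------------------------------------
# In-silico pairs


@dataclass
class InSilicoPair:
    contig: Contig
    end1: str
    end2: str  # reverse complement of the contig's last L_is bases

    @property
    def id(self) -> str:
        return self.contig.id


def make_insilico_pairs(
    contigs: Iterable[Contig], L_is: int = 100
) -> tuple[list[InSilicoPair], dict]:
    """Derive one in-silico read pair per contig (ends of length L_is)."""
    out = []
    skipped = 0
    for c in contigs:
        if len(c.sequence) < L_is:
            skipped += 1
            continue
        out.append(
            InSilicoPair(c, c.sequence[:L_is], revcomp(c.sequence[-L_is:]))
        )
    if skipped:
        log.info("skipped %d contigs shorter than L_is=%d", skipped, L_is)
    return out, {"skipped_short": skipped}


# ---------------------------------------------------------------------------
# Alignment


@dataclass
class EndAlignment:
    cls: str  # genome | te | unmapped | multi
    ref: Optional[str] = None
    pos: Optional[int] = None  # 0-based start of the aligned span
    strand: Optional[str] = None
    mismatches: int = 0
    n_hits: int = 0


@dataclass
class PairAlignment:
    pair: InSilicoPair
    a1: EndAlignment
    a2: EndAlignment

    @property
    def id(self) -> str:
        return self.pair.id


class ReferenceIndex:
    """Exact-seed index over the combined reference.

    Seeds (k-mers) overlapping soft-masked (lowercase) or N bases are not
    indexed; extension is case-insensitive so alignments may run into masked
    flanks.
    """

    def __init__(self, bundle: ReferenceBundle, k: int = 31):
        self.bundle = bundle
        self.k = k
        self._seqs_upper: dict[str, str] = {}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in bundle.sequences().items():
            up = seq.upper()
            self._seqs_upper[name] = up
            n = len(seq)
            if n < k:
                continue
            # positions whose k-window contains a masked/N base are skipped
            bad = np.frombuffer(seq.encode(), dtype=np.uint8)
            is_bad = (bad >= 97) | (bad == ord("N"))  # lowercase or N
            window_bad = np.convolve(is_bad.astype(np.int32), np.ones(k, int), "valid")
            for i in np.nonzero(window_bad == 0)[0]:
                self._index.setdefault(up[i : i + k], []).append((name, int(i)))

    def _extend(self, q: str, ref: str, start: int, max_mismatches: int):
        seq = self._seqs_upper[ref]
        if start < 0 or start + len(q) > len(seq):
            return None
        window = seq[start : start + len(q)]
        if window == q:
            return 0
        mm = sum(1 for a, b in zip(window, q) if a != b)
        return mm if mm <= max_mismatches else None

    def align(self, query: str, max_mismatches: int = 2) -> list[tuple[str, int, str, int]]:
        """All full-length hits of query: (ref, start, strand, mismatches)."""
        k = self.k
        if len(query) < k:
            return []
        hits: dict[tuple[str, int, str], int] = {}
        for strand, q in (("+", query.upper()), ("-", revcomp(query.upper()))):
            offsets = {0, len(q) - k, (len(q) - k) // 2}
            for off in offsets:
                for ref, pos in self._index.get(q[off : off + k], ()):
                    start = pos - off
                    key = (ref, start, strand)
                    if key in hits:
                        continue
                    mm = self._extend(q, ref, start, max_mismatches)
                    if mm is not None:
                        hits[key] = mm
        return [(r, p, s, m) for (r, p, s), m in sorted(hits.items())]

    def classify(self, query: str, max_mismatches: int = 2) -> EndAlignment:
        hits = self.align(query, max_mismatches)
        if not hits:
            return EndAlignment(CLS_UNMAPPED, n_hits=0)
        if len(hits) > 1:
            return EndAlignment(CLS_MULTI, n_hits=len(hits))
        ref, pos, strand, mm = hits[0]
        cls = CLS_TE if self.bundle.is_te(ref) else CLS_GENOME
        return EndAlignment(cls, ref, pos, strand, mm, 1)


def align_pairs(
    pairs: Iterable[InSilicoPair],
    index: ReferenceIndex,
    max_mismatches: int = 2,
) -> list[PairAlignment]:
    out = []
    for p in pairs:
        out.append(
            PairAlignment(
                p,
                index.classify(p.end1, max_mismatches),
                index.classify(p.end2, max_mismatches),
            )
        )
    return out


# ---------------------------------------------------------------------------
# SAM import / export (pysam)


def write_alignments_sam(alignments: list[PairAlignment], bundle: ReferenceBundle, path) -> None:
    import pysam

    seqs = bundle.sequences()
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in seqs.items()],
    }
    ref_id = {n: i for i, n in enumerate(seqs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for pa in alignments:
            for mate, (end, aln) in enumerate(
                ((pa.pair.end1, pa.a1), (pa.pair.end2, pa.a2))
            ):
                rec = pysam.AlignedSegment()
                rec.query_name = pa.id
                rec.query_sequence = end
                flag = 1 | (64 if mate == 0 else 128)
                if aln.cls in (CLS_UNMAPPED, CLS_MULTI):
                    flag |= 4
                else:
                    rec.reference_id = ref_id[aln.ref]
                    rec.reference_start = aln.pos
                    rec.cigarstring = f"{len(end)}M"
                    if aln.strand == "-":
                        flag |= 16
                rec.flag = flag
                rec.mapping_quality = 60 if aln.cls in (CLS_GENOME, CLS_TE) else 0
                fh.write(rec)


def read_alignments_sam(
    path, bundle: ReferenceBundle, contigs: dict[str, "Contig"]
) -> list[PairAlignment]:
    """Import externally produced SAM alignments of in-silico pairs.

    Records are matched back to contigs by query name; reference names must
    all exist in the bundle.
    """
    import pysam

    known = set(bundle.sequences())
    by_name: dict[str, dict[int, EndAlignment]] = {}
    ends: dict[str, dict[int, str]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for name in fh.references:
            if name not in known:
                raise ValueError(f"SAM reference {name!r} not in the bundle")
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = 1 if rec.is_read2 else 0
            if rec.is_unmapped:
                aln = EndAlignment(CLS_UNMAPPED)
            else:
                ref = rec.reference_name
                cls = CLS_TE if bundle.is_te(ref) else CLS_GENOME
                aln = EndAlignment(
                    cls, ref, rec.reference_start,
                    "-" if rec.is_reverse else "+", 0, 1,
                )
            by_name.setdefault(rec.query_name, {})[mate] = aln
            seq = rec.query_sequence or ""
            if rec.is_reverse:
                seq = revcomp(seq)
            ends.setdefault(rec.query_name, {})[mate] = seq
    out = []
    for name, pair_ends in by_name.items():
        if name not in contigs:
            continue
        e = ends.get(name, {})
        isp = InSilicoPair(contigs[name], e.get(0, ""), e.get(1, ""))
        out.append(
            PairAlignment(
                isp,
                pair_ends.get(0, EndAlignment(CLS_UNMAPPED)),
                pair_ends.get(1, EndAlignment(CLS_UNMAPPED)),
            )
        )
    return out
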