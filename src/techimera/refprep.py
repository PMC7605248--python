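"""Build the combined analysis reference and index gene annotation.

The analysis reference is the repeat-masked genome with one consensus copy of
each transposon subfamily appended as an extra named sequence, so downstream
alignment treats every subfamily as its own "chromosome". Masking is exact
seed-and-extend (default seed 25 nt, minimum reported match 50 nt, both
strands): every maximal genome segment sharing an exact match of at least
``min_match_len`` bases with any consensus is masked. A pre-masked FASTA can
be supplied instead for real data where sensitivity to diverged copies
matters.

Gene annotation (GFF3 primary; refFlat accepted) is indexed into exon /
intron / UTR / splice-site lookups used to annotate chimeric breakpoints.
Coordinates are 0-based half-open internally.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from ._seq import read_fasta, revcomp, write_fasta

log = logging.getLogger(__name__)

FEATURE_UTR5 = "5'UTR"
FEATURE_UTR3 = "3'UTR"
FEATURE_EXON = "exon"
FEATURE_INTRON = "intron"
FEATURE_INTERGENIC = "intergenic"


# ---------------------------------------------------------------------------
# Transposon consensus library


@dataclass
class TEEntry:
    name: str
    sequence: str
    ltr5: Optional[tuple[int, int]] = None  # 0-based half-open on consensus
    ltr3: Optional[tuple[int, int]] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TEConsensusLibrary:
    entries: list[TEEntry]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate name in TE library: {sorted(dup)}")
        for e in self.entries:
            if not e.sequence:
                raise ValueError(f"empty sequence for TE {e.name!r}")
            bad = set(e.sequence.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in TE {e.name!r}")
            for ltr in (e.ltr5, e.ltr3):
                if ltr is not None:
                    s, t = ltr
                    if not (0 <= s < t <= len(e.sequence)):
                        raise ValueError(f"LTR interval {ltr} outside TE {e.name!r}")
            if e.ltr5 and e.ltr3 and e.ltr5[1] > e.ltr3[0]:
                raise ValueError(f"overlapping LTR intervals on TE {e.name!r}")
        self._by_name = {e.name: e for e in self.entries}

    def __getitem__(self, name: str) -> TEEntry:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]


def load_te_library(fasta_path, ltr_table=None) -> TEConsensusLibrary:
    """Load transposon consensus sequences, optionally attaching LTR intervals.

    ``ltr_table`` is a TSV with columns te_name, ltr5_start, ltr5_end,
    ltr3_start, ltr3_end in 1-based inclusive coordinates.
    """
    seqs: dict[str, str] = {}
    from Bio import SeqIO

    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate name in TE library: {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    ltrs: dict[str, tuple] = {}
    if ltr_table is not None:
        tab = pd.read_csv(ltr_table, sep="\t")
        for row in tab.itertuples(index=False):
            ltrs[str(row.te_name)] = (
                (int(row.ltr5_start) - 1, int(row.ltr5_end)),
                (int(row.ltr3_start) - 1, int(row.ltr3_end)),
            )
    entries = []
    for name, seq in seqs.items():
        l5, l3 = ltrs.get(name, (None, None))
        entries.append(TEEntry(name, seq, l5, l3))
    return TEConsensusLibrary(entries)


# ---------------------------------------------------------------------------
# Masking


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


@dataclass
class MaskedGenome:
    sequences: dict[str, str]
    masked_intervals: dict[str, list[tuple[int, int]]]
    mode: str = "lowercase"

    def masked_bed(self) -> pd.DataFrame:
        rows = [
            (name, s, e)
            for name, ivs in self.masked_intervals.items()
            for s, e in ivs
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def mask_genome(
    genome: dict[str, str],
    te_library: TEConsensusLibrary,
    min_match_len: int = 50,
    seed_len: int = 25,
    mode: str = "lowercase",
) -> MaskedGenome:
    """Mask every genome segment sharing an exact match >= min_match_len with
    any consensus sequence (either strand). Overlapping hits are unioned.

    Seed-and-extend with exact ``seed_len``-mers; each seed hit is extended
    maximally along its diagonal, so the masked set equals the union of all
    maximal shared exact matches of length >= min_match_len.
    """
    if min_match_len < seed_len:
        raise ValueError("min_match_len must be >= seed_len")
    if mode not in ("lowercase", "hardmask"):
        raise ValueError(f"unknown masking mode {mode!r}")

    # k-mer index over both strands of every consensus
    index: dict[str, list[tuple[int, int]]] = {}
    te_seqs: list[str] = []
    for entry in te_library:
        for s in (entry.sequence.upper(), revcomp(entry.sequence.upper())):
            ti = len(te_seqs)
            te_seqs.append(s)
            for i in range(len(s) - seed_len + 1):
                kmer = s[i : i + seed_len]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((ti, i))

    out_seqs: dict[str, str] = {}
    out_ivs: dict[str, list[tuple[int, int]]] = {}
    for name, raw in genome.items():
        seq = raw.upper()
        n = len(seq)
        hits: list[tuple[int, int]] = []
        # farthest genome position already covered by an extension per diagonal
        done: dict[tuple[int, int], int] = {}
        for g in range(n - seed_len + 1):
            occ = index.get(seq[g : g + seed_len])
            if not occ:
                continue
            for ti, t in occ:
                diag = g - t
                if done.get((ti, diag), -1) >= g:
                    continue
                ts = te_seqs[ti]
                gl, tl = g, t
                while gl > 0 and tl > 0 and seq[gl - 1] == ts[tl - 1]:
                    gl -= 1
                    tl -= 1
                gr, tr = g + seed_len, t + seed_len
                m = len(ts)
                while gr < n and tr < m and seq[gr] == ts[tr]:
                    gr += 1
                    tr += 1
                done[(ti, diag)] = gr
                if gr - gl >= min_match_len:
                    hits.append((gl, gr))
        ivs = _merge_intervals(hits)
        chars = list(seq)
        for s, e in ivs:
            if mode == "lowercase":
                chars[s:e] = list(seq[s:e].lower())
            else:
                chars[s:e] = ["N"] * (e - s)
        out_seqs[name] = "".join(chars)
        out_ivs[name] = ivs
    return MaskedGenome(out_seqs, out_ivs, mode)


# ---------------------------------------------------------------------------
# Combined reference


@dataclass
class ReferenceBundle:
    masked_genome: MaskedGenome
    te_library: TEConsensusLibrary

    def __post_init__(self):
        collide = set(self.masked_genome.sequences) & set(self.te_library.names)
        if collide:
            raise ValueError(
                f"name collision between genome and TE library: {sorted(collide)}"
            )

    @property
    def genome_names(self) -> list[str]:
        return list(self.masked_genome.sequences)

    @property
    def te_names(self) -> list[str]:
        return self.te_library.names

    def sequences(self) -> dict[str, str]:
        """Combined reference: masked genome then one record per consensus."""
        out = dict(self.masked_genome.sequences)
        for entry in self.te_library:
            out[entry.name] = entry.sequence.upper()
        return out

    def get(self, name: str) -> str:
        if name in self.masked_genome.sequences:
            return self.masked_genome.sequences[name]
        return self.te_library[name].sequence.upper()

    def is_te(self, name: str) -> bool:
        return name in self.te_library

    def write_fasta(self, path) -> None:
        write_fasta(self.sequences(), path)


def build_combined_reference(
    masked_genome: MaskedGenome,
    te_library: TEConsensusLibrary,
    out_fasta=None,
) -> ReferenceBundle:
    bundle = ReferenceBundle(masked_genome, te_library)
    if out_fasta is not None:
        bundle.write_fasta(out_fasta)
    return bundle


def load_reference_bundle(fasta_path, te_names: list[str]) -> ReferenceBundle:
    """Round-trip a combined FASTA back into a ReferenceBundle."""
    seqs = read_fasta(fasta_path)
    missing = [n for n in te_names if n not in seqs]
    if missing:
        raise ValueError(f"TE records missing from combined FASTA: {missing}")
    te_entries = [TEEntry(n, seqs[n].upper()) for n in te_names]
    genome = {n: s for n, s in seqs.items() if n not in set(te_names)}
    ivs = {
        n: _merge_intervals(_lowercase_runs(s)) for n, s in genome.items()
    }
    return ReferenceBundle(MaskedGenome(genome, ivs), TEConsensusLibrary(te_entries))


def _lowercase_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c.islower() or c == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


# ---------------------------------------------------------------------------
# Annotation index


@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]]  # ordered by genomic coordinate
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Gene:
    id: str
    name: str
    seqid: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript]


@dataclass
class SpliceSite:
    seqid: str
    pos: int  # boundary coordinate (half-open exon edge)
    kind: str  # donor | acceptor
    strand: str
    gene_id: str
    transcript_id: str


class AnnotationIndex:
    """Point lookups of genes / feature classes and splice sites."""

    def __init__(self, genes: list[Gene], skipped: int = 0):
        self.genes = genes
        self.by_id = {g.id: g for g in genes}
        self.skipped_records = skipped
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self._trees.setdefault(g.seqid, IntervalTree()).addi(g.start, g.end, g)
        self.splice_sites: list[SpliceSite] = []
        for g in genes:
            for t in g.transcripts:
                exons = t.exons if g.strand == "+" else t.exons[::-1]
                for i, (s, e) in enumerate(exons):
                    is_last = i == len(exons) - 1
                    is_first = i == 0
                    if g.strand == "+":
                        if not is_last:
                            self.splice_sites.append(
                                SpliceSite(g.seqid, e, "donor", "+", g.id, t.id)
                            )
                        if not is_first:
                            self.splice_sites.append(
                                SpliceSite(g.seqid, s, "acceptor", "+", g.id, t.id)
                            )
                    else:
                        if not is_last:
                            self.splice_sites.append(
                                SpliceSite(g.seqid, s, "donor", "-", g.id, t.id)
                            )
                        if not is_first:
                            self.splice_sites.append(
                                SpliceSite(g.seqid, e, "acceptor", "-", g.id, t.id)
                            )

    # -- queries ---------------------------------------------------------

    def genes_at(self, seqid: str, pos: int) -> list[Gene]:
        tree = self._trees.get(seqid)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]), key=lambda g: g.id)

    def feature_class(self, gene: Gene, pos: int) -> str:
        in_exon = False
        for t in gene.transcripts:
            for s, e in t.utr5:
                if s <= pos < e:
                    return FEATURE_UTR5
            for s, e in t.utr3:
                if s <= pos < e:
                    return FEATURE_UTR3
            for s, e in t.exons:
                if s <= pos < e:
                    in_exon = True
        return FEATURE_EXON if in_exon else FEATURE_INTRON

    def query(self, seqid: str, pos: int) -> list[tuple[Gene, str]]:
        """All genes overlapping pos with the feature class at pos in each."""
        return [(g, self.feature_class(g, pos)) for g in self.genes_at(seqid, pos)]

    def nearest_splice_site(
        self, seqid: str, pos: int, kind: Optional[str] = None
    ) -> Optional[tuple[int, SpliceSite]]:
        best = None
        for ss in self.splice_sites:
            if ss.seqid != seqid:
                continue
            if kind is not None and ss.kind != kind:
                continue
            d = abs(ss.pos - pos)
            if best is None or d < best[0]:
                best = (d, ss)
        return best

    def junction_partner(self, site: SpliceSite) -> Optional[int]:
        """Boundary coordinate of the exon edge spliced to ``site`` in its
        own transcript (donor -> next acceptor, acceptor -> previous donor)."""
        gene = self.by_id[site.gene_id]
        for t in gene.transcripts:
            if t.id != site.transcript_id:
                continue
            exons = t.exons if gene.strand == "+" else t.exons[::-1]
            for i, (s, e) in enumerate(exons):
                d_pos = e if gene.strand == "+" else s
                a_pos = s if gene.strand == "+" else e
                if site.kind == "donor" and d_pos == site.pos and i + 1 < len(exons):
                    nxt = exons[i + 1]
                    return nxt[0] if gene.strand == "+" else nxt[1]
                if site.kind == "acceptor" and a_pos == site.pos and i > 0:
                    prv = exons[i - 1]
                    return prv[1] if gene.strand == "+" else prv[0]
        return None


def _parse_gff3(source: str, from_string: bool) -> tuple[list[Gene], int]:
    if from_string:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    clean_lines = []
    skipped = 0
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            clean_lines.append(line)
            continue
        parts = line.split("\t")
        ok = len(parts) == 9
        if ok:
            try:
                int(parts[3]), int(parts[4])
            except ValueError:
                ok = False
        if ok:
            clean_lines.append(line)
        else:
            skipped += 1
    if skipped:
        log.warning("skipped %d malformed GFF3 records", skipped)
    db = gffutils.create_db(
        "\n".join(clean_lines),
        ":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(t, featuretype="exon")
            )
            utr5 = sorted(
                (f.start - 1, f.end)
                for f in db.children(t, featuretype="five_prime_UTR")
            )
            utr3 = sorted(
                (f.start - 1, f.end)
                for f in db.children(t, featuretype="three_prime_UTR")
            )
            transcripts.append(Transcript(t.id, exons, utr5, utr3))
        name = g.attributes.get("Name", [g.id])[0]
        genes.append(
            Gene(g.id, name, g.seqid, g.strand, g.start - 1, g.end, transcripts)
        )
    return genes, skipped


_REFFLAT_COLS = [
    "geneName", "name", "chrom", "strand", "txStart", "txEnd",
    "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds",
]


def _parse_refflat(path) -> tuple[list[Gene], int]:
    tab = pd.read_csv(path, sep="\t", header=None, names=_REFFLAT_COLS, comment="#")
    genes: dict[str, Gene] = {}
    skipped = 0
    for row in tab.itertuples(index=False):
        try:
            starts = [int(x) for x in str(row.exonStarts).rstrip(",").split(",")]
            ends = [int(x) for x in str(row.exonEnds).rstrip(",").split(",")]
            cds_s, cds_e = int(row.cdsStart), int(row.cdsEnd)
        except (ValueError, AttributeError):
            skipped += 1
            continue
        if len(starts) != len(ends) or row.strand not in "+-":
            skipped += 1
            continue
        exons = sorted(zip(starts, ends))
        # UTRs from CDS bounds (refFlat convention)
        left = [(s, min(e, cds_s)) for s, e in exons if s < cds_s]
        right = [(max(s, cds_e), e) for s, e in exons if e > cds_e]
        utr5, utr3 = (left, right) if row.strand == "+" else (right, left)
        t = Transcript(str(row.name), exons, utr5, utr3)
        gid = str(row.geneName)
        if gid in genes:
            g = genes[gid]
            g.transcripts.append(t)
            g.start = min(g.start, int(row.txStart))
            g.end = max(g.end, int(row.txEnd))
        else:
            genes[gid] = Gene(
                gid, gid, str(row.chrom), str(row.strand),
                int(row.txStart), int(row.txEnd), [t],
            )
    if skipped:
        log.warning("skipped %d malformed refFlat records", skipped)
    return list(genes.values()), skipped


def build_annotation_index(
    source,
    dialect: str = "gff3",
    known_sequences=None,
    from_string: bool = False,
) -> AnnotationIndex:
    """Index gene annotation for point queries and splice-site lookups.

    ``known_sequences``, when given, is the set of valid sequence names; any
    annotated sequence outside it raises with the offending names listed.
    """
    if dialect == "gff3":
        genes, skipped = _parse_gff3(source, from_string)
    elif dialect == "refflat":
        genes, skipped = _parse_refflat(source)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if known_sequences is not None:
        bad = sorted({g.seqid for g in genes} - set(known_sequences))
        if bad:
            raise ValueError(f"annotation references unknown sequences: {bad}")
    for g in genes:
        for t in g.transcripts:
            for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
                if e1 > s2:
                    raise ValueError(
                        f"overlapping exons in transcript {t.id} of gene {g.id}"
                    )
    return AnnotationIndex(genes, skipped)
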