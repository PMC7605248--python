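"""Synthetic references, reads, and single-cell matrices with ground truth.

The generator emulates the study design the toolkit targets: an inbred fly
population carrying polymorphic germline transposon insertions.

* ``simulate_genome`` builds a random genome with multi-exon gene models, a
  consensus library of transposon subfamilies (optionally LTR-flanked), and a
  set of germline insertions. The emitted FASTA is the *reference* (insertion
  free); insertions exist on per-individual haplotypes, each flanked by a
  target-site duplication (TSD), and are carried by
  ``floor(freq * n_individuals + 0.5)`` individuals.
* ``simulate_gdna_reads`` draws unstranded paired-end fragments uniformly
  from each individual genome (defaults 250 nt reads, ~350 nt fragments,
  matching a TruSeq-style library).
* ``simulate_cdna_reads`` emits stranded mRNA fragments. Genes harbouring an
  insertion produce chimeric isoforms at their splicing fraction, through
  transposon-internal donor/acceptor sites; PCR-chimera artifacts are formed
  by ligating two random expressed fragments at a controlled rate.
* ``simulate_dge`` produces per-cell UMI matrices across replicates with
  planted transposon-gene co-expression.

Every emitted read name encodes its origin so downstream statistics have an
exact oracle. Base qualities are constant (Q37) and there is no sequencing
error by default: the simulations isolate pipeline logic, which is the
quantity under test, from error correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import revcomp, write_fasta, write_fastq
from .refprep import TEConsensusLibrary, TEEntry

QUAL_CHAR = chr(33 + 37)  # constant Q37

PLACEMENTS = ("intronic", "exonic", "5'UTR", "3'UTR", "intergenic")


# ---------------------------------------------------------------------------
# Specs and truth


@dataclass
class InsertionSpec:
    te_name: str
    seqid: str
    point: int  # 0-based insertion point on the reference
    orientation: str  # +/- relative to genome
    placement: str  # intronic | exonic | 5'UTR | 3'UTR | intergenic
    tsd_len: int = 4
    population_frequency: float = 1.0
    donor_sites: tuple[int, ...] = ()  # consensus coordinates
    acceptor_sites: tuple[int, ...] = ()
    splicing_fraction: float = 0.0

    def __post_init__(self):
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if not 0.0 <= self.population_frequency <= 1.0:
            raise ValueError("population_frequency must be in [0,1]")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if self.splicing_fraction > 0 and not (self.donor_sites or self.acceptor_sites):
            raise ValueError(
                "splicing_fraction > 0 requires at least one donor or acceptor site"
            )


@dataclass
class TruthJunction:
    gene_id: Optional[str]
    direction: str  # gene_to_te | te_to_gene
    genome_bp: int  # reference coordinate of the junction boundary
    te_name: str
    te_bp: int  # consensus coordinate of the junction boundary
    te_strand: str  # consensus strand as it appears in the transcript


@dataclass
class RealizedInsertion:
    id: str
    spec: InsertionSpec
    gene_id: Optional[str]
    orientation_class: str  # sense | antisense | intergenic
    upstream_bp: int  # reference coord: genome | TE junction (= point + tsd)
    downstream_bp: int  # reference coord: TE | genome junction (= point)
    tsd_seq: str
    carriers: list[int]
    realized_frequency: float
    junctions: list[TruthJunction] = field(default_factory=list)

    @property
    def te_name(self) -> str:
        return self.spec.te_name

    @property
    def seqid(self) -> str:
        return self.spec.seqid


@dataclass
class GeneModel:
    id: str
    seqid: str
    strand: str
    exons: list[tuple[int, int]]
    utr5: tuple[int, int]
    utr3: tuple[int, int]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]


@dataclass
class TruthTable:
    insertions: list[RealizedInsertion]
    n_individuals: int
    reference_copies: list[tuple[str, str, int, int]] = field(default_factory=list)

    def by_id(self, ins_id: str) -> RealizedInsertion:
        return next(i for i in self.insertions if i.id == ins_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ins in self.insertions:
            rows.append(
                dict(
                    id=ins.id,
                    te_name=ins.te_name,
                    seqid=ins.seqid,
                    point=ins.spec.point,
                    orientation=ins.spec.orientation,
                    placement=ins.spec.placement,
                    tsd_len=ins.spec.tsd_len,
                    tsd_seq=ins.tsd_seq,
                    upstream_bp=ins.upstream_bp,
                    downstream_bp=ins.downstream_bp,
                    gene_id=ins.gene_id,
                    orientation_class=ins.orientation_class,
                    population_frequency=ins.realized_frequency,
                    n_carriers=len(ins.carriers),
                )
            )
        return pd.DataFrame(rows)


@dataclass
class GenomeSim:
    genome: dict[str, str]  # reference, insertion free
    genes: list[GeneModel]
    te_library: TEConsensusLibrary
    truth: TruthTable
    gff3_text: str
    seed: int

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.id == gene_id)

    def individual_genome(self, individual: int) -> dict[str, str]:
        """Materialize one individual's genome with its insertions applied."""
        out = {}
        for seqid, seq in self.genome.items():
            todo = [
                ins
                for ins in self.truth.insertions
                if ins.seqid == seqid and individual in ins.carriers
            ]
            for ins in sorted(todo, key=lambda i: -i.spec.point):
                p, t = ins.spec.point, ins.spec.tsd_len
                te = self.te_library[ins.te_name].sequence
                if ins.spec.orientation == "-":
                    te = revcomp(te)
                seq = seq[: p + t] + te + seq[p:]
            out[seqid] = seq
        return out

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        write_fasta(
            {e.name: e.sequence for e in self.te_library},
            os.path.join(outdir, "te_library.fa"),
        )
        with open(os.path.join(outdir, "genes.gff3"), "w") as fh:
            fh.write(self.gff3_text)
        rows = []
        for e in self.te_library:
            if e.ltr5 and e.ltr3:
                rows.append(
                    (e.name, e.ltr5[0] + 1, e.ltr5[1], e.ltr3[0] + 1, e.ltr3[1])
                )
        if rows:
            pd.DataFrame(
                rows,
                columns=["te_name", "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end"],
            ).to_csv(os.path.join(outdir, "ltr_table.tsv"), sep="\t", index=False)
        self.truth.to_frame().to_csv(
            os.path.join(outdir, "truth_insertions.tsv"), sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Genome simulation


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _make_te_library(
    rng: np.random.Generator, n: int, with_ltr: bool, ltr_len: int
) -> TEConsensusLibrary:
    entries = []
    for i in range(n):
        core_len = int(rng.integers(1200, 2200))
        if with_ltr:
            ltr = _random_dna(rng, ltr_len)
            seq = ltr + _random_dna(rng, core_len) + ltr
            entries.append(
                TEEntry(
                    f"TE{i + 1}", seq, (0, ltr_len), (len(seq) - ltr_len, len(seq))
                )
            )
        else:
            entries.append(TEEntry(f"TE{i + 1}", _random_dna(rng, core_len)))
    return TEConsensusLibrary(entries)


def _make_gene(
    rng: np.random.Generator, gene_id: str, seqid: str, start: int
) -> GeneModel:
    # internal exons comfortably exceed the fragment length so junction
    # windows sit in fully covered transcript interior; a long last exon
    # keeps 3'UTR junctions clear of the transcript end
    n_exons = 4
    pos = start
    exons = []
    for i in range(n_exons):
        elen = int(rng.integers(360, 440)) if i < n_exons - 1 else int(rng.integers(700, 900))
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_exons - 1:
            pos += int(rng.integers(450, 900))
    utr5 = (exons[0][0], exons[0][0] + 120)
    utr3 = (exons[-1][1] - 500, exons[-1][1])
    return GeneModel(gene_id, seqid, "+", exons, utr5, utr3)


def _gff3_for_genes(genes: list[GeneModel], genome: dict[str, str]) -> str:
    lines = ["##gff-version 3"]
    for name, seq in genome.items():
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for g in genes:
        attrs = f"ID={g.id};Name={g.id}"
        lines.append(
            "\t".join(
                [g.seqid, "sim", "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", attrs]
            )
        )
        tid = f"{g.id}.t1"
        lines.append(
            "\t".join(
                [g.seqid, "sim", "mRNA", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", f"ID={tid};Parent={g.id}"]
            )
        )
        for j, (s, e) in enumerate(g.exons):
            lines.append(
                "\t".join(
                    [g.seqid, "sim", "exon", str(s + 1), str(e), ".", g.strand,
                     ".", f"ID={tid}.e{j + 1};Parent={tid}"]
                )
            )
        for kind, (s, e) in (
            ("five_prime_UTR", g.utr5),
            ("three_prime_UTR", g.utr3),
        ):
            lines.append(
                "\t".join(
                    [g.seqid, "sim", kind, str(s + 1), str(e), ".", g.strand,
                     ".", f"ID={tid}.{kind};Parent={tid}"]
                )
            )
    return "\n".join(lines) + "\n"


def carrier_count(freq: float, n_individuals: int) -> int:
    """Deterministic rounding rule: floor(freq * n + 0.5)."""
    return int(np.floor(freq * n_individuals + 0.5))


_COMP1 = str.maketrans("ACGTN", "TGCAN")


def _auto_insertion_specs(
    rng: np.random.Generator,
    genes: list[GeneModel],
    te_library: TEConsensusLibrary,
    n_insertions: int,
    genome: dict[str, str],
    tsd_range: tuple[int, int],
    frequencies: tuple[float, ...],
    splicing_fraction: float,
    placement_cycle: Optional[list[str]] = None,
) -> list[InsertionSpec]:
    """Draw insertion specs with unambiguous junctions.

    Insertion points and splice sites are nudged so no planted junction has
    chance sequence identity across it (zero microhomology); planted
    breakpoints are then recoverable exactly rather than up to the
    deterministic microhomology assignment rule.
    """
    placements = placement_cycle or ["intronic", "intronic", "exonic", "3'UTR", "intergenic"]
    specs: list[InsertionSpec] = []
    used_genes: set[str] = set()
    gene_pool = [g for g in genes]
    rng.shuffle(gene_pool)
    gi = 0
    for k in range(n_insertions):
        placement = placements[k % len(placements)]
        te = te_library.entries[k % len(te_library.entries)]
        orientation = "+" if k % 2 == 0 else "-"
        tsd = int(rng.integers(tsd_range[0], tsd_range[1] + 1))
        freq = frequencies[k % len(frequencies)]
        L = len(te.sequence)
        core_lo = (te.ltr5[1] if te.ltr5 else 0) + 60
        core_hi = (te.ltr3[0] if te.ltr3 else L) - 60
        a = int(rng.integers(core_lo, core_lo + (core_hi - core_lo) // 3))
        d = int(rng.integers(core_hi - (core_hi - core_lo) // 3, core_hi))
        if orientation == "-":
            a, d = d, a  # antisense: entry coordinate above exit coordinate
        seq = genome[genes[0].seqid]
        cons = te.sequence
        ote = cons if orientation == "+" else revcomp(cons)

        def fix_point(point: int) -> int:
            # avoid chance microhomology across the genome|TE junctions
            while seq[point + tsd] == ote[0] or seq[point - 1] == ote[-1]:
                point += 1
            return point

        if placement == "intergenic":
            seqid = genes[0].seqid
            spans = sorted((g.start, g.end) for g in genes)
            gaps = [
                (e1 + 800, s2 - 800) for (_, e1), (s2, _) in zip(spans, spans[1:])
                if s2 - e1 > 2000
            ]
            taken = [s.point for s in specs if s.placement == "intergenic"]
            for _ in range(100):
                lo, hi = gaps[int(rng.integers(0, len(gaps)))]
                point = int(rng.integers(lo, hi))
                if all(abs(point - q) > 600 for q in taken):
                    break
            specs.append(
                InsertionSpec(
                    te.name, seqid, fix_point(point), orientation, placement, tsd, freq
                )
            )
            continue
        while gi < len(gene_pool) and gene_pool[gi].id in used_genes:
            gi += 1
        if gi >= len(gene_pool):
            raise ValueError("not enough genes for requested insertions")
        g = gene_pool[gi]
        used_genes.add(g.id)
        if placement == "intronic":
            intron = g.introns()[int(rng.integers(0, len(g.introns())))]
            point = fix_point(int(rng.integers(intron[0] + 80, intron[1] - 80)))
            i0, i1 = intron
            if orientation == "+":
                while cons[a] == seq[i0]:
                    a += 1
                while cons[d - 1] == seq[i1 - 1]:
                    d -= 1
            else:  # antisense: segment is revcomp(cons[d:a])
                while cons[a - 1].translate(_COMP1) == seq[i0]:
                    a -= 1
                while cons[d].translate(_COMP1) == seq[i1 - 1]:
                    d += 1
            specs.append(
                InsertionSpec(
                    te.name, g.seqid, point, orientation, placement, tsd, freq,
                    (d,), (a,), splicing_fraction,
                )
            )
        elif placement == "exonic":
            s, e = g.exons[1]
            point = fix_point(int(rng.integers(s + 80, e - 80)))
            specs.append(
                InsertionSpec(
                    te.name, g.seqid, point, orientation, placement, tsd, freq,
                    (), (), 0.0,
                )
            )
        elif placement == "3'UTR":
            s, e = g.utr3
            point = fix_point(int(rng.integers(s + 60, e - 400)))
            if orientation == "+":
                while cons[a] == seq[point + tsd]:
                    a += 1
            else:  # tail is revcomp(cons[:a])
                while cons[a - 1].translate(_COMP1) == seq[point + tsd]:
                    a += 1
            specs.append(
                InsertionSpec(
                    te.name, g.seqid, point, orientation, placement, tsd, freq,
                    (), (a,), splicing_fraction,
                )
            )
        else:  # 5'UTR
            s, e = g.utr5
            point = fix_point(int(rng.integers(s + 30, e - 30)))
            if orientation == "+":
                while cons[d - 1] == seq[point - 1]:
                    d -= 1
            else:  # head is revcomp(cons[d:])
                while cons[d].translate(_COMP1) == seq[point - 1]:
                    d += 1
            specs.append(
                InsertionSpec(
                    te.name, g.seqid, point, orientation, placement, tsd, freq,
                    (d,), (), splicing_fraction,
                )
            )
    return specs


def simulate_genome(
    n_genes: int = 20,
    n_te_subfamilies: int = 4,
    genome_len: int = 200_000,
    insertions: Optional[list[InsertionSpec]] = None,
    n_insertions: int = 0,
    n_individuals: int = 10,
    seed: int = 0,
    chrom: str = "simchr",
    te_with_ltr: bool = True,
    ltr_len: int = 150,
    n_reference_te_copies: int = 0,
    tsd_range: tuple[int, int] = (2, 8),
    frequencies: tuple[float, ...] = (1.0, 0.5),
    splicing_fraction: float = 0.5,
    placement_cycle: Optional[list[str]] = None,
) -> GenomeSim:
    """Simulate a reference genome, gene annotation, TE library and germline
    insertions with full ground truth.

    Insertions are realized on individual haplotypes only; the returned
    FASTA genome is the insertion-free analysis reference. Each insertion
    duplicates the ``tsd_len`` bases at the insertion point so the emitted
    individual genome is ``ref[:p+t] + TE + ref[p:]``; the junction
    breakpoints on the reference are therefore ``p + t`` (upstream) and
    ``p`` (downstream), overlapping by the TSD.
    """
    rng = np.random.default_rng(seed)
    genome = {chrom: _random_dna(rng, genome_len)}
    te_library = _make_te_library(rng, n_te_subfamilies, te_with_ltr, ltr_len)

    slot = genome_len // (n_genes + 1) if n_genes else genome_len
    genes = []
    for i in range(n_genes):
        g = _make_gene(rng, f"gene{i + 1}", chrom, slot * i + slot // 3)
        if g.end > genome_len - 1000:
            raise ValueError("genes do not fit in requested genome size")
        genes.append(g)

    # optional reference-resident TE copies (overwrite intergenic sequence,
    # lengths preserved) used to exercise masking
    ref_copies: list[tuple[str, str, int, int]] = []
    if n_reference_te_copies:
        seq = genome[chrom]
        occupied = [(g.start - 500, g.end + 500) for g in genes]
        for i in range(n_reference_te_copies):
            te = te_library.entries[i % len(te_library.entries)]
            L = len(te.sequence)
            for _ in range(200):
                pos = int(rng.integers(0, genome_len - L))
                if not any(s < pos + L and pos < e for s, e in occupied):
                    break
            else:
                raise ValueError("no room for reference TE copies")
            strand = "+" if rng.random() < 0.5 else "-"
            copy = te.sequence if strand == "+" else revcomp(te.sequence)
            seq = seq[:pos] + copy + seq[pos + L:]
            occupied.append((pos - 100, pos + L + 100))
            ref_copies.append((te.name, strand, pos, pos + L))
        genome[chrom] = seq

    if insertions is None:
        insertions = _auto_insertion_specs(
            rng, genes, te_library, n_insertions, genome, tsd_range,
            frequencies, splicing_fraction, placement_cycle,
        )

    # realize insertions
    points = sorted((s.seqid, s.point) for s in insertions)
    for (c1, p1), (c2, p2) in zip(points, points[1:]):
        if c1 == c2 and p2 - p1 < 100:
            raise ValueError(f"overlapping requested insertions near {c1}:{p1}")

    realized = []
    for k, spec in enumerate(insertions):
        if not 0 <= spec.point < len(genome[spec.seqid]):
            raise ValueError(f"insertion point outside sequence: {spec}")
        n_carry = carrier_count(spec.population_frequency, n_individuals)
        carriers = sorted(int(x) for x in rng.permutation(n_individuals)[:n_carry])
        gene = next(
            (g for g in genes if g.seqid == spec.seqid and g.start <= spec.point < g.end),
            None,
        )
        if gene is None:
            ocls = "intergenic"
        else:
            ocls = "sense" if spec.orientation == gene.strand else "antisense"
        tsd_seq = genome[spec.seqid][spec.point : spec.point + spec.tsd_len]
        ins = RealizedInsertion(
            id=f"ins{k + 1}",
            spec=spec,
            gene_id=gene.id if gene else None,
            orientation_class=ocls,
            upstream_bp=spec.point + spec.tsd_len,
            downstream_bp=spec.point,
            tsd_seq=tsd_seq,
            carriers=carriers,
            realized_frequency=n_carry / n_individuals if n_individuals else 0.0,
        )
        realized.append(ins)

    sim = GenomeSim(
        genome=genome,
        genes=genes,
        te_library=te_library,
        truth=TruthTable(realized, n_individuals, ref_copies),
        gff3_text=_gff3_for_genes(genes, genome),
        seed=seed,
    )
    for ins in realized:
        ins.junctions = _expected_junctions(sim, ins)
    return sim


# ---------------------------------------------------------------------------
# Transcript models


def _spliced_up_to(gene: GeneModel, seq: str, pos: int) -> str:
    """Spliced (exonic) sequence of the gene up to genomic coordinate pos."""
    out = []
    for s, e in gene.exons:
        if e <= pos:
            out.append(seq[s:e])
        elif s < pos:
            out.append(seq[s:pos])
    return "".join(out)


def _spliced_from(gene: GeneModel, seq: str, pos: int) -> str:
    out = []
    for s, e in gene.exons:
        if s >= pos:
            out.append(seq[s:e])
        elif e > pos:
            out.append(seq[pos:e])
    return "".join(out)


def _oriented_te_segment(
    te: TEEntry, ins: RealizedInsertion
) -> tuple[str, int, int, str]:
    """Transcript-oriented TE segment for an internal splice chimera.

    Returns (segment, entry_bp, exit_bp, te_strand) where entry/exit are the
    consensus coordinates adjacent to the gene_to_te / te_to_gene junctions.
    """
    spec = ins.spec
    a = spec.acceptor_sites[0] if spec.acceptor_sites else None
    d = spec.donor_sites[0] if spec.donor_sites else None
    cons = te.sequence
    L = len(cons)
    sense = spec.orientation == "+"  # simulated genes are all '+' strand
    if sense:
        lo = a if a is not None else 0
        hi = d if d is not None else L
        seg = cons[lo:hi]
        return seg, lo, hi, "+"
    lo = d if d is not None else 0
    hi = a if a is not None else L
    seg = revcomp(cons[lo:hi])
    return seg, hi, lo, "-"


@dataclass
class Isoform:
    name: str
    gene_id: Optional[str]
    sequence: str
    kind: str  # canonical | chimeric | te
    junctions: list[TruthJunction] = field(default_factory=list)


def _expected_junctions(sim: GenomeSim, ins: RealizedInsertion) -> list[TruthJunction]:
    spec = ins.spec
    if spec.placement == "intergenic":
        return []
    te = sim.te_library[spec.te_name]
    gene_id = ins.gene_id
    out = []
    if spec.placement in ("intronic",):
        if spec.acceptor_sites and spec.donor_sites:
            _, entry, exit_, strand = _oriented_te_segment(te, ins)
            g = sim.gene(gene_id)
            intron = next(
                iv for iv in g.introns() if iv[0] <= spec.point < iv[1]
            )
            out.append(
                TruthJunction(gene_id, "gene_to_te", intron[0], spec.te_name, entry, strand)
            )
            out.append(
                TruthJunction(gene_id, "te_to_gene", intron[1], spec.te_name, exit_, strand)
            )
        elif spec.acceptor_sites:
            _, entry, _, strand = _oriented_te_segment(te, ins)
            g = sim.gene(gene_id)
            intron = next(iv for iv in g.introns() if iv[0] <= spec.point < iv[1])
            out.append(
                TruthJunction(gene_id, "gene_to_te", intron[0], spec.te_name, entry, strand)
            )
        elif spec.donor_sites:
            _, _, exit_, strand = _oriented_te_segment(te, ins)
            g = sim.gene(gene_id)
            intron = next(iv for iv in g.introns() if iv[0] <= spec.point < iv[1])
            out.append(
                TruthJunction(gene_id, "te_to_gene", intron[1], spec.te_name, exit_, strand)
            )
    elif spec.placement in ("exonic",):
        L = len(te.sequence)
        if spec.orientation == "+":
            out.append(
                TruthJunction(gene_id, "gene_to_te", ins.upstream_bp, spec.te_name, 0, "+")
            )
            out.append(
                TruthJunction(gene_id, "te_to_gene", ins.downstream_bp, spec.te_name, L, "+")
            )
        else:
            out.append(
                TruthJunction(gene_id, "gene_to_te", ins.upstream_bp, spec.te_name, L, "-")
            )
            out.append(
                TruthJunction(gene_id, "te_to_gene", ins.downstream_bp, spec.te_name, 0, "-")
            )
    elif spec.placement == "3'UTR":
        if spec.acceptor_sites:
            a = spec.acceptor_sites[0]
            strand = "+" if spec.orientation == "+" else "-"
            out.append(
                TruthJunction(gene_id, "gene_to_te", ins.upstream_bp, spec.te_name, a, strand)
            )
    elif spec.placement == "5'UTR":
        if spec.donor_sites:
            d = spec.donor_sites[0]
            strand = "+" if spec.orientation == "+" else "-"
            out.append(
                TruthJunction(gene_id, "te_to_gene", ins.downstream_bp, spec.te_name, d, strand)
            )
    return out


def _chimeric_isoform(sim: GenomeSim, ins: RealizedInsertion) -> Isoform:
    spec = ins.spec
    gene = sim.gene(ins.gene_id)
    seq = sim.genome[gene.seqid]
    te = sim.te_library[spec.te_name]
    cons = te.sequence
    L = len(cons)
    juncs = ins.junctions
    if spec.placement == "intronic" and spec.acceptor_sites and spec.donor_sites:
        seg, _, _, _ = _oriented_te_segment(te, ins)
        g2t = next(j for j in juncs if j.direction == "gene_to_te")
        t2g = next(j for j in juncs if j.direction == "te_to_gene")
        body = _spliced_up_to(gene, seq, g2t.genome_bp) + seg + _spliced_from(
            gene, seq, t2g.genome_bp
        )
        return Isoform(f"{gene.id}.chi", gene.id, body, "chimeric", juncs)
    if spec.placement == "intronic" and spec.acceptor_sites:
        seg, _, _, strand = _oriented_te_segment(te, ins)
        g2t = juncs[0]
        body = _spliced_up_to(gene, seq, g2t.genome_bp) + seg[:600]
        return Isoform(f"{gene.id}.chi", gene.id, body, "chimeric", juncs)
    if spec.placement == "intronic" and spec.donor_sites:
        seg, _, _, strand = _oriented_te_segment(te, ins)
        t2g = juncs[0]
        body = seg[-600:] + _spliced_from(gene, seq, t2g.genome_bp)
        return Isoform(f"{gene.id}.chi", gene.id, body, "chimeric", juncs)
    if spec.placement == "exonic":
        # full retention of the insertion allele within the exon
        te_seq = cons if spec.orientation == "+" else revcomp(cons)
        tsd = ins.tsd_seq
        body = (
            _spliced_up_to(gene, seq, spec.point) + tsd + te_seq
            + _spliced_from(gene, seq, spec.point)
        )
        return Isoform(f"{gene.id}.chi", gene.id, body, "chimeric", juncs)
    if spec.placement == "3'UTR":
        a = spec.acceptor_sites[0]
        tail = cons[a:] if spec.orientation == "+" else revcomp(cons[:a])
        body = _spliced_up_to(gene, seq, ins.upstream_bp) + tail[:800]
        return Isoform(f"{gene.id}.chi", gene.id, body, "chimeric", juncs)
    if spec.placement == "5'UTR":
        d = spec.donor_sites[0]
        head = cons[:d] if spec.orientation == "+" else revcomp(cons[d:])
        body = head[-800:] + _spliced_from(gene, seq, ins.downstream_bp)
        return Isoform(f"{gene.id}.chi", gene.id, body, "chimeric", juncs)
    raise ValueError(f"insertion {ins.id} has no chimeric isoform model")


def isoform_catalog(sim: GenomeSim) -> dict[str, list[tuple[Isoform, float]]]:
    """Per-gene isoforms with expected abundance fractions (sum to 1)."""
    ins_by_gene: dict[str, RealizedInsertion] = {}
    for ins in sim.truth.insertions:
        if ins.gene_id is None or ins.spec.splicing_fraction <= 0:
            continue
        if ins.gene_id in ins_by_gene:
            raise ValueError("one spliced insertion per gene is supported")
        ins_by_gene[ins.gene_id] = ins
    catalog = {}
    for gene in sim.genes:
        seq = sim.genome[gene.seqid]
        canonical = Isoform(
            f"{gene.id}.can", gene.id,
            "".join(seq[s:e] for s, e in gene.exons), "canonical",
        )
        if gene.id in ins_by_gene:
            ins = ins_by_gene[gene.id]
            f = ins.spec.splicing_fraction
            catalog[gene.id] = [
                (canonical, 1.0 - f),
                (_chimeric_isoform(sim, ins), f),
            ]
        else:
            catalog[gene.id] = [(canonical, 1.0)]
    return catalog


# ---------------------------------------------------------------------------
# Read simulation


def simulate_gdna_reads(
    sim: GenomeSim,
    coverage: float = 30.0,
    read_len: int = 250,
    fragment_len_mean: float = 350.0,
    fragment_len_sd: float = 20.0,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Unstranded paired gDNA reads from every individual genome.

    ``coverage`` is per-individual fragment coverage. Read names encode the
    individual and the fragment coordinates on that individual's genome:
    ``g:i<ind>:n<k>:<chrom>:<start>:<end>:<strand>``.
    """
    if fragment_len_mean < read_len:
        raise ValueError("fragment_len_mean must be >= read_len")
    rng = np.random.default_rng(seed)
    pairs = []
    k = 0
    for ind in range(sim.truth.n_individuals):
        g = sim.individual_genome(ind)
        for chrom, seq in g.items():
            n = rng.poisson(coverage * len(seq) / fragment_len_mean)
            lens = np.clip(
                np.rint(rng.normal(fragment_len_mean, fragment_len_sd, n)),
                read_len, 2 * read_len - 20,
            ).astype(int)
            starts = rng.integers(0, np.maximum(1, len(seq) - lens))
            flips = rng.random(n) < 0.5
            for L, s, flip in zip(lens, starts, flips):
                frag = seq[s : s + L]
                strand = "-" if flip else "+"
                if flip:
                    frag = revcomp(frag)
                r1, r2 = frag[:read_len], revcomp(frag[-read_len:])
                name = f"g:i{ind}:n{k}:{chrom}:{s}:{s + L}:{strand}"
                pairs.append((name, r1, r2))
                k += 1
    return pairs


@dataclass
class CDNATruth:
    catalog: dict[str, list[tuple[Isoform, float]]]
    artifact_names: list[str]
    fragment_origin: dict[str, tuple[str, int, int]]  # name -> (isoform, start, end)
    artifact_rate: float


def simulate_cdna_reads(
    sim: GenomeSim,
    expression_levels: Optional[dict[str, float]] = None,
    mean_fragments_per_gene: float = 300.0,
    artifact_rate: float = 0.0,
    read_len: int = 250,
    fragment_len_mean: float = 350.0,
    fragment_len_sd: float = 20.0,
    strand_protocol: str = "mate1-sense",
    autonomous_te_levels: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], CDNATruth]:
    """Stranded paired cDNA reads.

    Mate 1 carries the transcript (sense) strand per the default
    ``mate1-sense`` protocol. Each gene's transcripts are drawn from its
    isoform catalog (chimeric isoforms at the insertion's splicing
    fraction). Artifacts are ligations of two random expressed fragments at
    a uniformly chosen internal position, emitted at rate ``artifact_rate``
    relative to the real fragment count.
    """
    if strand_protocol not in ("mate1-sense", "mate2-sense"):
        raise ValueError(f"unknown strand protocol {strand_protocol!r}")
    if not 0.0 <= artifact_rate < 1.0:
        raise ValueError("artifact_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    catalog = isoform_catalog(sim)
    sources: list[tuple[Isoform, float]] = []
    for gene in sim.genes:
        level = (
            expression_levels.get(gene.id, 0.0)
            if expression_levels is not None
            else mean_fragments_per_gene
        )
        if level <= 0:
            continue
        # fragment yield scales with molar abundance x transcript length so
        # interior per-nt coverage tracks abundance; the length factor uses
        # the number of valid fragment start positions, which is what sets
        # coverage at an interior junction. ``level`` is the expected
        # fragment count at canonical length.
        def _eff(iso):
            return max(len(iso.sequence) - fragment_len_mean + 1.0, 1.0)

        eff_can = _eff(catalog[gene.id][0][0])
        for iso, frac in catalog[gene.id]:
            if frac > 0:
                sources.append((iso, level * frac * _eff(iso) / eff_can))
    for te_name, level in (autonomous_te_levels or {}).items():
        iso = Isoform(f"{te_name}.auto", None, sim.te_library[te_name].sequence, "te")
        sources.append((iso, level))

    pairs = []
    frag_pool: list[tuple[str, str]] = []  # (isoform name, fragment seq)
    origin = {}
    k = 0
    for iso, level in sources:
        n = rng.poisson(level)
        if len(iso.sequence) < read_len:
            continue
        lens = np.clip(
            np.rint(rng.normal(fragment_len_mean, fragment_len_sd, n)),
            read_len, 2 * read_len - 20,
        ).astype(int)
        lens = np.minimum(lens, len(iso.sequence))
        starts = rng.integers(0, np.maximum(1, len(iso.sequence) - lens + 1))
        for L, s in zip(lens, starts):
            frag = iso.sequence[s : s + L]
            name = f"c:{iso.name}:n{k}:{s}:{s + L}"
            r1, r2 = frag[:read_len], revcomp(frag[-read_len:])
            if strand_protocol == "mate2-sense":
                r1, r2 = r2, r1
            pairs.append((name, r1, r2))
            frag_pool.append((iso.name, frag))
            origin[name] = (iso.name, int(s), int(s + L))
            k += 1

    artifact_names = []
    if artifact_rate > 0 and len(frag_pool) >= 2:
        n_art = rng.poisson(artifact_rate * len(frag_pool))
        for j in range(n_art):
            ia, ib = rng.integers(0, len(frag_pool), 2)
            na, fa = frag_pool[ia]
            nb, fb = frag_pool[ib]
            u = int(rng.integers(60, max(61, min(len(fa), len(fb)) - 60)))
            frag = fa[:u] + fb[u:]
            name = f"c:art:{na}+{nb}:n{k}"
            r1, r2 = frag[:read_len], revcomp(frag[-read_len:])
            if strand_protocol == "mate2-sense":
                r1, r2 = r2, r1
            pairs.append((name, r1, r2))
            artifact_names.append(name)
            k += 1
    return pairs, CDNATruth(catalog, artifact_names, origin, artifact_rate)


def write_pairs_fastq(pairs, path1, path2) -> None:
    write_fastq(((n + "/1", s1, QUAL_CHAR * len(s1)) for n, s1, _ in pairs), path1)
    write_fastq(((n + "/2", s2, QUAL_CHAR * len(s2)) for n, _, s2 in pairs), path2)


# ---------------------------------------------------------------------------
# Single-cell DGE simulation


@dataclass
class DGESim:
    counts: pd.DataFrame  # features x cells
    cell_meta: pd.DataFrame  # cell, replicate
    planted: list[tuple[str, str, float, float, float]]
    baseline: dict[str, float]


def simulate_dge(
    n_cells: int = 2000,
    n_replicates: int = 8,
    features: Optional[dict[str, float] | list[str]] = None,
    planted_pairs: tuple[tuple[str, str, float, float, float], ...] = (),
    baseline_on: float = 0.3,
    umi_depth: float = 4.0,
    noise_rate: float = 0.05,
    seed: int = 0,
) -> DGESim:
    """Per-cell UMI counts across replicates with planted co-expression.

    ``planted_pairs`` entries are (feature_a, feature_x, p_a, p_x, p_both):
    in every replicate the pair is co-ON with probability ``p_both``
    (requires ``p_both <= min(p_a, p_x)`` and
    ``p_a + p_x - p_both <= 1``). OFF cells draw Poisson(``noise_rate``)
    background counts; ON cells draw ``1 + Poisson(umi_depth - 1)``.
    ``n_cells`` is the total, split evenly across replicates.
    """
    rng = np.random.default_rng(seed)
    if features is None:
        features = [f"feat{i + 1}" for i in range(20)]
    if isinstance(features, dict):
        baseline = dict(features)
        names = list(features)
    else:
        names = list(features)
        baseline = {n: baseline_on for n in names}
    planted_feats = set()
    for a, x, pa, px, pab in planted_pairs:
        if pab > min(pa, px) + 1e-12 or pa + px - pab > 1 + 1e-12:
            raise ValueError(f"inconsistent planted probabilities for ({a},{x})")
        if a in planted_feats or x in planted_feats:
            raise ValueError("a feature may appear in at most one planted pair")
        planted_feats |= {a, x}
        baseline[a], baseline[x] = pa, px
    idx = {n: i for i, n in enumerate(names)}
    per_rep = n_cells // n_replicates
    cols, reps = [], []
    blocks = []
    for r in range(n_replicates):
        nc = per_rep + (1 if r < n_cells % n_replicates else 0)
        p = np.array([baseline[n] for n in names])
        on = rng.random((len(names), nc)) < p[:, None]
        for a, x, pa, px, pab in planted_pairs:
            u = rng.random(nc)
            on[idx[a]] = u < pa
            on[idx[x]] = (u < pab) | ((u >= pa) & (u < pa + px - pab))
        counts = np.where(
            on,
            1 + rng.poisson(max(umi_depth - 1.0, 0.0), on.shape),
            rng.poisson(noise_rate, on.shape),
        )
        blocks.append(counts)
        cols += [f"r{r + 1}c{i + 1}" for i in range(nc)]
        reps += [f"rep{r + 1}"] * nc
    mat = pd.DataFrame(np.hstack(blocks), index=names, columns=cols)
    meta = pd.DataFrame({"cell": cols, "replicate": reps}).set_index("cell")
    return DGESim(mat, meta, list(planted_pairs), baseline)
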