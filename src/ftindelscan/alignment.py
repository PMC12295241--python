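"""Variant calling from gapped promoter alignments in a TSS-relative frame.

A multiple sequence alignment of a reference promoter/gene region against
genome-assembly contigs is the raw material for indel marker design.  This
module maps alignment columns onto reference coordinates, expresses reference
positions relative to the transcription start site (TSS, negative = upstream),
calls insertion/deletion and SNP variants of the contigs against the
reference, and exports the catalogue in VCF/BED/TSV form.

Coordinate conventions
----------------------
* Alignment columns and reference positions are 1-based inclusive.
* TSS-relative positions form a continuous signed integer axis that includes
  position 0 (the TSS itself); the inclusive length of the interval between
  two TSS-relative endpoints is therefore ``|a - b| + 1``.
* BED output converts to 0-based half-open; VCF records use the conventional
  left-anchored base for indels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

GAP = "-"
_VALID_CHARS = frozenset("ACGTN-")

FORWARD = "forward"
REVERSE = "reverse_complement"


class AlignmentFormatError(ValueError):
    """Malformed alignment (e.g. ragged sequence lengths)."""


class AlignmentInputError(ValueError):
    """Unusable input (empty file, too few sequences, bad characters)."""


@dataclass(frozen=True)
class ReferenceAnchor:
    """Frame for TSS-relative coordinates of one gene.

    ``tss_genomic`` is the 1-based genomic coordinate of the transcription
    start site on ``chromosome``.  For a ``reverse_complement`` gene,
    upstream of the TSS corresponds to *larger* genomic coordinates.

    ``region_start_genomic`` optionally records the genomic coordinate of the
    first base of the aligned reference sequence (in gene orientation), so
    that positions within an extracted region can be lifted to the genome.
    When it is ``None`` reference-sequence positions are taken to be genomic
    already.
    """

    gene_id: str
    chromosome: str
    tss_genomic: int
    strand: str
    region_start_genomic: int | None = None

    def __post_init__(self) -> None:
        if self.tss_genomic < 1:
            raise ValueError("tss_genomic must be >= 1")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be {FORWARD!r} or {REVERSE!r}")

    def to_genomic(self, ref_pos: int) -> int:
        """Lift a 1-based reference-sequence position to a genomic position."""
        if self.region_start_genomic is None:
            return ref_pos
        if self.strand == FORWARD:
            return self.region_start_genomic + ref_pos - 1
        return self.region_start_genomic - ref_pos + 1


def tss_relative(ref_pos: int, anchor: ReferenceAnchor) -> int:
    """Signed bp position of a genomic coordinate relative to the TSS.

    0 at the TSS, negative upstream of it.  For reverse-complement genes the
    sign convention flips so that upstream still comes out negative.
    """
    if ref_pos < 1:
        raise ValueError("ref_pos must be >= 1")
    if anchor.strand == FORWARD:
        return ref_pos - anchor.tss_genomic
    return anchor.tss_genomic - ref_pos


def span_length(tss_rel_a: int, tss_rel_b: int) -> int:
    """Inclusive bp length of the interval between two TSS-relative endpoints.

    Position 0 (the TSS) occupies one bp on the axis, so an interval crossing
    the TSS, e.g. (-511, 229), has length 229 - (-511) + 1 = 741.
    """
    return abs(tss_rel_a - tss_rel_b) + 1


@dataclass
class Alignment:
    """A gapped multiple sequence alignment over {A,C,G,T,N,-}."""

    sequences: dict[str, str]
    ref_id: str

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise AlignmentInputError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if self.ref_id not in self.sequences:
            raise AlignmentInputError(f"reference {self.ref_id!r} not in alignment")
        for sid, seq in self.sequences.items():
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise AlignmentInputError(
                    f"sequence {sid!r} contains unsupported characters {sorted(bad)}; "
                    "only A,C,G,T,N and '-' are accepted"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def ref_seq(self) -> str:
        return self.sequences[self.ref_id]

    def ungapped(self, seq_id: str) -> str:
        return self.sequences[seq_id].replace(GAP, "")


def read_alignment(path: str | Path, ref_id: str | None = None) -> Alignment:
    """Read an aligned multi-FASTA.  Sequences are upper-cased and validated.

    ``ref_id`` defaults to the first record.
    """
    path = Path(path)
    if not path.exists():
        raise AlignmentInputError(f"no such file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentInputError(f"no FASTA records in {path}")
    if len(records) < 2:
        raise AlignmentInputError(f"alignment {path} has only one sequence")
    seqs = {rec.id: str(rec.seq).upper() for rec in records}
    if len(seqs) != len(records):
        raise AlignmentInputError(f"duplicate sequence ids in {path}")
    return Alignment(sequences=seqs, ref_id=ref_id or records[0].id)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


class CoordMap:
    """Bijection between alignment columns and reference positions.

    Columns where the reference has a gap carry no reference position; they
    are reported as the position of the last preceding reference base (the
    usual "anchor" convention), with :meth:`is_ref_gap` distinguishing them.
    """

    def __init__(self, aln: Alignment) -> None:
        ref = aln.ref_seq
        col_to_ref: list[int] = []
        ref_to_col: list[int] = []
        pos = 0
        for col, base in enumerate(ref, start=1):
            if base != GAP:
                pos += 1
                ref_to_col.append(col)
            col_to_ref.append(pos)
        self._col_to_ref = col_to_ref
        self._ref_to_col = ref_to_col
        self._ref_gap = [base == GAP for base in ref]
        self.ref_length = pos

    def ref_pos(self, col: int) -> int:
        """Reference position of a column (anchor position on ref-gap columns)."""
        return self._col_to_ref[col - 1]

    def col(self, ref_pos: int) -> int:
        """Alignment column carrying reference position ``ref_pos``."""
        return self._ref_to_col[ref_pos - 1]

    def is_ref_gap(self, col: int) -> bool:
        return self._ref_gap[col - 1]


def build_coord_map(aln: Alignment) -> CoordMap:
    return CoordMap(aln)


@dataclass(frozen=True)
class IndelVariant:
    """An insertion or deletion of one or more contigs against the reference.

    ``ref_start``/``ref_end`` are 1-based inclusive reference positions; for
    insertions both equal the anchor position (the reference base immediately
    5' of the inserted material).  ``aln_start``/``aln_end`` are the alignment
    columns of the gap run, used for polymorphic-region queries.
    """

    kind: str  # "deletion" | "insertion"
    ref_start: int
    ref_end: int
    length: int
    carriers: frozenset[str]
    aln_start: int
    aln_end: int
    inserted_seq: str = ""
    tss_rel_start: int | None = None
    tss_rel_end: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind == "deletion" and self.ref_end - self.ref_start + 1 != self.length:
            raise ValueError("deletion length must equal its reference span")

    @property
    def label(self) -> str:
        return f"{self.kind[:3]}_{self.length}bp@{self.ref_start}"


@dataclass(frozen=True)
class SnpLocus:
    """A single-nucleotide mismatch locus against the reference."""

    ref_pos: int
    aln_col: int
    ref_base: str
    alts: Mapping[str, frozenset[str]]  # alt base -> carrier ids
    tss_rel: int | None = None

    def __post_init__(self) -> None:
        if self.ref_base in self.alts:
            raise ValueError("alt base equals reference base")


def aligned_span(seq: str) -> tuple[int, int] | None:
    """First and last non-gap columns (1-based) of a gapped sequence."""
    stripped = seq.strip(GAP)
    if not stripped:
        return None
    first = len(seq) - len(seq.lstrip(GAP)) + 1
    last = len(seq.rstrip(GAP))
    return first, last


def unaligned_ends(aln: Alignment) -> dict[str, tuple[int, int]]:
    """Leading/trailing gap lengths (columns) per contig.

    Terminal gap runs mean the contig simply does not extend over that part
    of the reference; they are missing data, never deletion calls.
    """
    out = {}
    for sid, seq in aln.sequences.items():
        if sid == aln.ref_id:
            continue
        span = aligned_span(seq)
        if span is None:
            out[sid] = (len(seq), 0)
        else:
            out[sid] = (span[0] - 1, len(seq) - span[1])
    return out


def _annotate_tss(
    indels: list[IndelVariant],
    snps: list[SnpLocus],
    anchor: ReferenceAnchor,
) -> tuple[list[IndelVariant], list[SnpLocus]]:
    def rel(ref_pos: int) -> int:
        return tss_relative(anchor.to_genomic(ref_pos), anchor)

    out_i = []
    for v in indels:
        a, b = rel(v.ref_start), rel(v.ref_end)
        out_i.append(replace(v, tss_rel_start=min(a, b), tss_rel_end=max(a, b)))
    out_s = [replace(s, tss_rel=rel(s.ref_pos)) for s in snps]
    return out_i, out_s


def call_variants(
    aln: Alignment, anchor: ReferenceAnchor | None = None
) -> tuple[list[IndelVariant], list[SnpLocus]]:
    """Call indels and SNP loci of every contig against the reference.

    Within each contig's aligned span (terminal gap runs are unaligned ends,
    not variants):

    * a maximal run of contig gaps over reference bases is a deletion;
    * a maximal run of contig bases over reference gaps is an insertion
      anchored at the last preceding reference base;
    * aligned base mismatches (both in {A,C,G,T}) are SNP loci.

    Gap runs occupying identical alignment-column intervals in several
    contigs are merged into a single variant with multiple carriers;
    partially overlapping runs remain distinct variants.
    """
    cmap = build_coord_map(aln)
    ref = aln.ref_seq
    ncol = aln.length

    # keyed by identifying coordinates -> carriers (and inserted seq)
    deletions: dict[tuple[int, int, int, int], set[str]] = {}
    insertions: dict[tuple[int, int, int], tuple[set[str], str]] = {}
    snp_alts: dict[int, dict[str, set[str]]] = {}

    for sid, seq in aln.sequences.items():
        if sid == aln.ref_id:
            continue
        span = aligned_span(seq)
        if span is None:
            continue
        first, last = span

        del_run: list[int] = []  # columns with ref base, contig gap
        ins_run: list[int] = []  # columns with ref gap, contig base

        def flush_del() -> None:
            if not del_run:
                return
            c0, c1 = del_run[0], del_run[-1]
            r0, r1 = cmap.ref_pos(c0), cmap.ref_pos(c1)
            deletions.setdefault((r0, r1, c0, c1), set()).add(sid)
            del_run.clear()

        def flush_ins() -> None:
            if not ins_run:
                return
            c0, c1 = ins_run[0], ins_run[-1]
            anchor_pos = cmap.ref_pos(c0)  # last ref base before the run
            seq_ins = "".join(seq[c - 1] for c in ins_run)
            key = (anchor_pos, c0, c1)
            if key in insertions:
                insertions[key][0].add(sid)
            else:
                insertions[key] = ({sid}, seq_ins)
            ins_run.clear()

        for col in range(first, last + 1):
            rbase = ref[col - 1]
            cbase = seq[col - 1]
            if rbase != GAP and cbase == GAP:
                flush_ins()
                del_run.append(col)
            elif rbase == GAP and cbase != GAP:
                flush_del()
                ins_run.append(col)
            elif rbase == GAP and cbase == GAP:
                # neither axis advances for the deletion; the contig is not
                # contiguous through the insertion block
                flush_ins()
            else:  # both bases present
                flush_del()
                flush_ins()
                if rbase != cbase and rbase != "N" and cbase != "N":
                    snp_alts.setdefault(col, {}).setdefault(cbase, set()).add(sid)
        flush_del()
        flush_ins()

    indels: list[IndelVariant] = []
    for (r0, r1, c0, c1), carriers in sorted(deletions.items()):
        indels.append(
            IndelVariant(
                kind="deletion",
                ref_start=r0,
                ref_end=r1,
                length=r1 - r0 + 1,
                carriers=frozenset(carriers),
                aln_start=c0,
                aln_end=c1,
            )
        )
    for (anchor_pos, c0, c1), (carriers, seq_ins) in sorted(insertions.items()):
        indels.append(
            IndelVariant(
                kind="insertion",
                ref_start=anchor_pos,
                ref_end=anchor_pos,
                length=len(seq_ins),
                carriers=frozenset(carriers),
                aln_start=c0,
                aln_end=c1,
                inserted_seq=seq_ins,
            )
        )
    indels.sort(key=lambda v: (v.ref_start, v.aln_start, v.kind))

    snps: list[SnpLocus] = []
    for col in sorted(snp_alts):
        snps.append(
            SnpLocus(
                ref_pos=cmap.ref_pos(col),
                aln_col=col,
                ref_base=ref[col - 1],
                alts={b: frozenset(c) for b, c in sorted(snp_alts[col].items())},
            )
        )

    if anchor is not None:
        indels, snps = _annotate_tss(indels, snps, anchor)
    return indels, snps


class PolymorphicRegions:
    """Union of indel column intervals and SNP columns, with containment
    and overlap queries in alignment coordinates."""

    def __init__(
        self, indels: Iterable[IndelVariant], snps: Iterable[SnpLocus]
    ) -> None:
        self._tree = IntervalTree()
        for v in indels:
            # IntervalTree is half-open; store [start, end+1)
            self._tree.addi(v.aln_start, v.aln_end + 1, v.label)
        for s in snps:
            self._tree.addi(s.aln_col, s.aln_col + 1, "SNP")

    def __contains__(self, col: int) -> bool:
        return bool(self._tree.overlap(col, col + 1))

    def overlaps(self, start_col: int, end_col: int) -> bool:
        """True if any bp of the inclusive column interval hits the set."""
        return bool(self._tree.overlap(start_col, end_col + 1))

    def labels(self, start_col: int, end_col: int) -> frozenset[str]:
        return frozenset(
            iv.data for iv in self._tree.overlap(start_col, end_col + 1)
        )

    def is_empty(self) -> bool:
        return len(self._tree) == 0


def polymorphic_region_set(
    indels: Iterable[IndelVariant], snps: Iterable[SnpLocus] = ()
) -> PolymorphicRegions:
    return PolymorphicRegions(indels, snps)


def compare_homolog_positions(
    list_a: Sequence[int], list_b: Sequence[int]
) -> list[tuple[int, int, int, int]]:
    """Pair each TSS-relative indel position in one species with the nearest
    one in another.

    Returns ``(pos_a, nearest_pos_b, signed_delta, abs_delta)`` tuples, where
    ``signed_delta = pos_a - nearest_pos_b``.  With an empty second list the
    pairing is empty.
    """
    if not list_b:
        return []
    out = []
    for a in list_a:
        b = min(list_b, key=lambda x: (abs(a - x), x))
        out.append((a, b, a - b, abs(a - b)))
    return out


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_variants(
    indels: Sequence[IndelVariant],
    snps: Sequence[SnpLocus],
    aln: Alignment,
    vcf_path: str | Path | None = None,
    bed_path: str | Path | None = None,
    contig_name: str | None = None,
) -> None:
    """Write the variant catalogue as VCF 4.2 and/or BED6.

    VCF indel records follow the left-anchored-base convention (REF includes
    the base before the event); coordinates are those of the ungapped
    reference sequence.  BED intervals are 0-based half-open.
    """
    ref = aln.ungapped(aln.ref_id)
    chrom = contig_name or aln.ref_id

    if vcf_path is not None:
        records = []
        for v in sorted(indels, key=lambda v: v.ref_start):
            if v.kind == "deletion":
                if v.ref_start < 2:
                    # no left anchor base; anchor on the right instead
                    pos = v.ref_start
                    refa = ref[v.ref_start - 1 : v.ref_end + 1]
                    alt = ref[v.ref_end]
                else:
                    pos = v.ref_start - 1
                    refa = ref[pos - 1 : v.ref_end]
                    alt = ref[pos - 1]
                info = f"SVTYPE=DEL;SVLEN=-{v.length}"
            else:
                pos = v.ref_start
                refa = ref[pos - 1]
                alt = refa + v.inserted_seq
                info = f"SVTYPE=INS;SVLEN={v.length}"
            carriers = ",".join(sorted(v.carriers))
            records.append((pos, refa, alt, f"{info};CARRIERS={carriers}"))
        for s in sorted(snps, key=lambda s: s.ref_pos):
            alts = ",".join(sorted(s.alts))
            carriers = "|".join(
                ",".join(sorted(s.alts[b])) for b in sorted(s.alts)
            )
            records.append(
                (s.ref_pos, s.ref_base, alts, f"SVTYPE=SNP;CARRIERS={carriers}")
            )
        records.sort(key=lambda r: r[0])
        with open(vcf_path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom},length={len(ref)}>\n")
            fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variant type">\n')
            fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed indel length">\n')
            fh.write('##INFO=<ID=CARRIERS,Number=1,Type=String,Description="Carrier sequence ids">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for pos, refa, alt, info in records:
                fh.write(f"{chrom}\t{pos}\t.\t{refa}\t{alt}\t.\t.\t{info}\n")

    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for v in sorted(indels, key=lambda v: v.ref_start):
                if v.kind == "deletion":
                    start0, end = v.ref_start - 1, v.ref_end
                else:
                    start0, end = v.ref_start - 1, v.ref_start
                fh.write(f"{chrom}\t{start0}\t{end}\t{v.label}\t0\t+\n")
            for s in sorted(snps, key=lambda s: s.ref_pos):
                fh.write(f"{chrom}\t{s.ref_pos - 1}\t{s.ref_pos}\tsnp_{s.ref_pos}\t0\t+\n")
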