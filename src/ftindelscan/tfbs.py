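"""Transcription-factor binding-site scanning over polymorphic promoter regions.

Promoter sequences extracted from a gapped alignment are scanned for motif
hits, either as IUPAC consensus strings (exact degenerate-code matching,
score 1) or as position-frequency matrices with a similarity threshold
(default 0.85).  Sites are reported in alignment-column coordinates so that
they can be intersected with the indel/SNP catalogue; a TF whose every
promoter site falls inside polymorphic regions is flagged "exclusive" — the
candidate whose binding is created or destroyed by the indel alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import GAP, PolymorphicRegions

logger = logging.getLogger(__name__)

BASES = "ACGT"
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_THRESHOLD = 0.85


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A TF binding model: IUPAC consensus or position-frequency matrix."""

    tf_id: str
    name: str
    kind: str  # "consensus" | "matrix"
    consensus: str | None = None
    matrix: tuple[tuple[float, float, float, float], ...] | None = None
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.kind == "consensus":
            if not self.consensus:
                raise ValueError("consensus model needs a pattern")
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC letters {sorted(bad)}")
        elif self.kind == "matrix":
            if not self.matrix:
                raise ValueError("matrix model needs frequencies")
            for row in self.matrix:
                if abs(sum(row) - 1.0) > 1e-6:
                    raise ValueError("matrix columns must sum to 1")
        else:
            raise ValueError(f"bad motif kind {self.kind!r}")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")

    @property
    def width(self) -> int:
        if self.kind == "consensus":
            return len(self.consensus)
        return len(self.matrix)

    def as_matrix(self) -> "MotifModel":
        """Equivalent matrix model: 0/1 frequencies spread over the allowed
        bases of each consensus position, threshold 1."""
        if self.kind == "matrix":
            return self
        rows = []
        for ch in self.consensus.upper():
            allowed = IUPAC[ch]
            rows.append(
                tuple(1.0 / len(allowed) if b in allowed else 0.0 for b in BASES)
            )
        return MotifModel(
            self.tf_id, self.name, "matrix", matrix=tuple(rows), threshold=1.0
        )


@dataclass(frozen=True)
class MotifSite:
    """One motif hit, located on the alignment-column axis.

    ``aln_start``/``aln_end`` are the 1-based alignment columns of the first
    and last base of the site window (gap columns inside the window are part
    of the interval); ``seq_start`` is the 1-based position on the ungapped
    sequence.  Strand is "+", "-", or "both" for palindromic dual-strand hits.
    """

    tf_id: str
    sequence_id: str
    aln_start: int
    aln_end: int
    seq_start: int
    strand: str
    score: float
    in_polymorphic_region: bool = False
    indel_labels: frozenset[str] = frozenset()


def degap(gapped: str) -> tuple[str, list[int]]:
    """Ungapped sequence and, per ungapped index, its 1-based alignment column."""
    seq = []
    cols = []
    for col, ch in enumerate(gapped, start=1):
        if ch != GAP:
            seq.append(ch)
            cols.append(col)
    return "".join(seq), cols


def _consensus_match(window: str, pattern: str) -> bool:
    return all(b in IUPAC[p] for b, p in zip(window, pattern.upper()))


def _matrix_score(window: str, matrix: Sequence[Sequence[float]]) -> float | None:
    """Matched-frequency sum over maximal-frequency sum; None on N bases."""
    num = 0.0
    den = 0.0
    for b, row in zip(window, matrix):
        idx = BASES.find(b)
        if idx < 0:
            return None
        num += row[idx]
        den += max(row)
    return num / den if den > 0 else 0.0


def _scan(
    sequence_id: str,
    gapped_seq: str,
    model: MotifModel,
    strands: str,
) -> list[MotifSite]:
    seq, cols = degap(gapped_seq.upper())
    w = model.width
    sites: list[MotifSite] = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        fwd_score: float | None = None
        rev_score: float | None = None
        if model.kind == "consensus":
            if "+" in strands and _consensus_match(window, model.consensus):
                fwd_score = 1.0
            if "-" in strands and _consensus_match(revcomp(window), model.consensus):
                rev_score = 1.0
        else:
            if "N" in window:
                logger.debug(
                    "skipping window with N at %s:%d", sequence_id, i + 1
                )
                continue
            if "+" in strands:
                s = _matrix_score(window, model.matrix)
                if s is not None and s >= model.threshold:
                    fwd_score = s
            if "-" in strands:
                s = _matrix_score(revcomp(window), model.matrix)
                if s is not None and s >= model.threshold:
                    rev_score = s
        if fwd_score is None and rev_score is None:
            continue
        if fwd_score is not None and rev_score is not None:
            strand, score = "both", max(fwd_score, rev_score)
        elif fwd_score is not None:
            strand, score = "+", fwd_score
        else:
            strand, score = "-", rev_score
        sites.append(
            MotifSite(
                tf_id=model.tf_id,
                sequence_id=sequence_id,
                aln_start=cols[i],
                aln_end=cols[i + w - 1],
                seq_start=i + 1,
                strand=strand,
                score=score,
            )
        )
    return sites


def scan_consensus(
    sequence_id: str, gapped_seq: str, model: MotifModel, strands: str = "+-"
) -> list[MotifSite]:
    """All windows whose bases are each compatible with the IUPAC code.

    The ungapped sequence is scanned (gaps removed) and positions mapped
    back to alignment columns; hits matching on both strands (palindromes)
    are reported once with strand "both"."""
    if model.kind != "consensus":
        raise ValueError("scan_consensus needs a consensus model")
    return _scan(sequence_id, gapped_seq, model, strands)


def scan_matrix(
    sequence_id: str, gapped_seq: str, model: MotifModel, strands: str = "+-"
) -> list[MotifSite]:
    """Windows whose similarity to the frequency matrix reaches the threshold.

    Similarity of a window is the sum of the matched base frequencies divided
    by the sum of the per-position maxima (1.0 for the consensus word).
    Windows containing N are skipped."""
    if model.kind != "matrix":
        raise ValueError("scan_matrix needs a matrix model")
    return _scan(sequence_id, gapped_seq, model, strands)


def scan(
    sequence_id: str, gapped_seq: str, model: MotifModel, strands: str = "+-"
) -> list[MotifSite]:
    if model.kind == "consensus":
        return scan_consensus(sequence_id, gapped_seq, model, strands)
    return scan_matrix(sequence_id, gapped_seq, model, strands)


def classify_sites(
    sites: Iterable[MotifSite],
    regions: PolymorphicRegions,
    all_or_nothing: bool = False,
) -> list[MotifSite]:
    """Flag each site by polymorphic-region membership and attach the labels
    of the overlapping indels (SNP-only overlaps are labelled "SNP").

    By default a site is "in" when >= 1 bp of its window overlaps the region
    set; ``all_or_nothing=True`` requires the whole window inside."""
    out = []
    for s in sites:
        if all_or_nothing:
            inside = all(
                col in regions for col in range(s.aln_start, s.aln_end + 1)
            )
        else:
            inside = regions.overlaps(s.aln_start, s.aln_end)
        labels = regions.labels(s.aln_start, s.aln_end) if inside else frozenset()
        out.append(replace(s, in_polymorphic_region=inside, indel_labels=labels))
    return out


@dataclass(frozen=True)
class TfVerdict:
    tf_id: str
    n_sites: int
    n_in_polymorphic: int
    exclusive: bool

    def __post_init__(self) -> None:
        if self.exclusive != (self.n_sites == self.n_in_polymorphic and self.n_sites >= 1):
            raise ValueError("inconsistent exclusivity verdict")


def exclusive_tfs(
    classified_sites: Iterable[MotifSite],
    scope: tuple[int, int],
) -> list[TfVerdict]:
    """Per-TF exclusivity over a promoter scope interval.

    ``scope`` is an inclusive alignment-column interval (e.g. everything
    upstream of the TSS column); only sites wholly within it are counted.
    A TF is exclusive when every one of its in-scope sites overlaps the
    polymorphic-region set; TFs with no in-scope site are omitted.
    """
    lo, hi = scope
    if hi < lo:
        raise ValueError("empty scope interval")
    counts: dict[str, list[int]] = {}
    for s in classified_sites:
        if s.aln_start < lo or s.aln_end > hi:
            continue
        n_tot, n_in = counts.setdefault(s.tf_id, [0, 0])
        counts[s.tf_id][0] = n_tot + 1
        counts[s.tf_id][1] = n_in + int(s.in_polymorphic_region)
    return [
        TfVerdict(tf, n_tot, n_in, exclusive=(n_tot == n_in and n_tot >= 1))
        for tf, (n_tot, n_in) in sorted(counts.items())
    ]


def per_indel_report(
    classified_sites: Iterable[MotifSite],
    verdicts: Iterable[TfVerdict],
    flowering_tfs: Mapping[str, str],
) -> pd.DataFrame:
    """Table of exclusive flowering-pathway TFs with their sites per indel.

    ``flowering_tfs`` maps tf_id -> display name; TFs outside the annotation
    list or not exclusive are dropped.  Rows sort by tf then position, so the
    output is byte-stable for identical inputs.
    """
    exclusive = {v.tf_id for v in verdicts if v.exclusive}
    rows = []
    for s in classified_sites:
        if s.tf_id not in exclusive or s.tf_id not in flowering_tfs:
            continue
        rows.append(
            {
                "tf_id": s.tf_id,
                "tf_name": flowering_tfs[s.tf_id],
                "sequence_id": s.sequence_id,
                "position": s.aln_start,
                "indel": ", ".join(sorted(s.indel_labels)) or "-",
                "strand": {"both": "+/-"}.get(s.strand, s.strand),
                "score": round(s.score, 2),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "tf_id", "tf_name", "sequence_id", "position", "indel", "strand", "score",
        ],
    )
    return df.sort_values(["tf_id", "position", "sequence_id"]).reset_index(drop=True)
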