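"""In-silico PCR marker model: product prediction, gel resolution, scoring.

A marker is a primer pair described by its two outer product endpoints on the
TSS-relative axis.  Against a haplotype's indel catalogue it predicts the
observable on a gel: a band of some length, or no product when a deletion
removes part of a primer binding site (a presence/absence variant, PAV).
Diploid genotypes are scored 0/1/2 from the predicted or observed band
patterns, minor allele frequencies are computed per marker, and markers are
screened by a MAF threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignment import IndelVariant, span_length

DEFAULT_PRIMER_LEN = 20
DEFAULT_RESOLVABILITY = 0.02  # standard agarose; relative length difference
HIGH_RES_RESOLVABILITY = 0.005  # high-resolution 3:1 agarose preset
NA = None  # genotype missing-call sentinel


class FrameMismatchError(ValueError):
    """Variants lack the TSS-relative coordinates the marker frame needs."""


@dataclass(frozen=True)
class ProductPattern:
    """Observable on a gel: a set of band lengths, or no product at all."""

    bands: frozenset[int] = frozenset()
    no_product: bool = False

    def __post_init__(self) -> None:
        if self.no_product and self.bands:
            raise ValueError("no_product implies an empty band set")

    @classmethod
    def of(cls, *bands: int) -> "ProductPattern":
        return cls(bands=frozenset(int(b) for b in bands))

    @classmethod
    def none(cls) -> "ProductPattern":
        return cls(no_product=True)


@dataclass(frozen=True)
class AllelePattern:
    """Acceptable observables for one scored allele of a marker.

    Markers over multi-allelic loci list several alternative observables for
    a single score (e.g. "2504 or 378 bp or no product"); any of the listed
    bands, and optionally absence of product, matches the allele.
    """

    bands: frozenset[int] = frozenset()
    allows_no_product: bool = False

    @classmethod
    def of(cls, *bands: int, no_product: bool = False) -> "AllelePattern":
        return cls(bands=frozenset(int(b) for b in bands), allows_no_product=no_product)


@dataclass
class MarkerDef:
    """A primer-pair assay in the TSS-relative frame.

    ``fwd_end_tss_rel`` / ``rev_end_tss_rel`` are the outer endpoints of the
    reference PCR product.  Primer binding windows extend ``primer_len_*`` bp
    inward from each endpoint; a deletion touching >= 1 bp of either window
    abolishes amplification.
    """

    marker_id: str
    gene_id: str
    fwd_end_tss_rel: int
    rev_end_tss_rel: int
    allele0: AllelePattern
    allele2: AllelePattern
    primer_len_f: int = DEFAULT_PRIMER_LEN
    primer_len_r: int = DEFAULT_PRIMER_LEN
    notes: str = ""

    def __post_init__(self) -> None:
        if self.fwd_end_tss_rel == self.rev_end_tss_rel:
            raise ValueError("marker endpoints must differ")
        if self.primer_len_f < 1 or self.primer_len_r < 1:
            raise ValueError("primer lengths must be >= 1")

    @property
    def span(self) -> tuple[int, int]:
        a, b = self.fwd_end_tss_rel, self.rev_end_tss_rel
        return (min(a, b), max(a, b))

    @property
    def reference_product(self) -> int:
        return span_length(self.fwd_end_tss_rel, self.rev_end_tss_rel)

    @property
    def primer_windows(self) -> tuple[tuple[int, int], tuple[int, int]]:
        lo, hi = self.span
        return (
            (lo, lo + self.primer_len_f - 1),
            (hi - self.primer_len_r + 1, hi),
        )


@dataclass(frozen=True)
class GenotypeCall:
    line_id: str
    marker_id: str
    score: int | None  # 0, 1, 2 or None (NA)

    def __post_init__(self) -> None:
        if self.score is not None and self.score not in (0, 1, 2):
            raise ValueError(f"score must be 0/1/2/None, got {self.score!r}")


@dataclass(frozen=True)
class MarkerSummary:
    marker_id: str
    maf_percent: float  # nan when no calls
    n_called: int
    is_monomorphic: bool


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Inclusive-interval overlap length (0 when disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def predict_products(
    marker: MarkerDef, haplotype_variants: Iterable[IndelVariant]
) -> ProductPattern:
    """Predict the gel observable of one haplotype for one marker.

    Product length = reference span length + inserted bp within the span
    - deleted bp within the span; a deletion covering any part of either
    primer window yields no product.  Variants must carry TSS-relative
    coordinates (the marker frame).
    """
    lo, hi = marker.span
    win_f, win_r = marker.primer_windows
    band = marker.reference_product
    for v in haplotype_variants:
        if v.tss_rel_start is None or v.tss_rel_end is None:
            raise FrameMismatchError(
                f"variant {v.label} lacks TSS-relative coordinates"
            )
        if v.kind == "deletion":
            iv = (v.tss_rel_start, v.tss_rel_end)
            if _overlap(iv, win_f) or _overlap(iv, win_r):
                return ProductPattern.none()
            band -= _overlap(iv, (lo, hi))
        else:  # insertion between anchor and anchor+1
            if lo <= v.tss_rel_start <= hi - 1:
                band += v.length
    if band <= 0:
        return ProductPattern.none()
    return ProductPattern.of(band)


def distinguishable(
    len_a: int, len_b: int, resolvability: float = DEFAULT_RESOLVABILITY
) -> bool:
    """Whether two band lengths separate on a gel of the given resolvability.

    Bands merge when their relative length difference |a-b|/max(a,b) falls
    below the threshold (default 2%, roughly standard agarose)."""
    if not 0 < resolvability < 1:
        raise ValueError("resolvability must be in (0, 1)")
    if len_a == len_b:
        return False
    return abs(len_a - len_b) / max(len_a, len_b) >= resolvability


def gel_resolve(
    patterns: Sequence[ProductPattern],
    resolvability: float = DEFAULT_RESOLVABILITY,
) -> list[list[int]]:
    """Group haplotype observables into gel-distinguishable classes.

    Returns index lists into ``patterns``.  Band classes are the transitive
    closure of pairwise indistinguishability over sorted lengths; no-product
    is always its own class.
    """
    none_idx = [i for i, p in enumerate(patterns) if p.no_product or not p.bands]
    banded = [(min(p.bands), i) for i, p in enumerate(patterns) if p.bands]
    banded.sort()
    classes: list[list[int]] = []
    if none_idx:
        classes.append(none_idx)
    current: list[int] = []
    prev_len: int | None = None
    for length, i in banded:
        if prev_len is not None and distinguishable(prev_len, length, resolvability):
            classes.append(current)
            current = []
        current.append(i)
        prev_len = length
    if current:
        classes.append(current)
    return classes


def _matches(observed: ProductPattern, allele: AllelePattern) -> bool:
    if observed.no_product or not observed.bands:
        return allele.allows_no_product
    return observed.bands <= allele.bands


def score_genotype(observed: ProductPattern, marker: MarkerDef) -> int | None:
    """Score a diploid gel observable against the marker's allele patterns.

    Match to the score-0 pattern -> 0, score-2 pattern -> 2, a band mixture
    drawing on both -> 1 (heterozygote), anything else -> NA (None).
    """
    if _matches(observed, marker.allele0):
        return 0
    if _matches(observed, marker.allele2):
        return 2
    if (
        observed.bands
        and observed.bands <= (marker.allele0.bands | marker.allele2.bands)
        and observed.bands & marker.allele0.bands
        and observed.bands & marker.allele2.bands
    ):
        return 1
    return NA


def genotype_line(
    marker: MarkerDef,
    hap1_variants: Iterable[IndelVariant],
    hap2_variants: Iterable[IndelVariant],
) -> int | None:
    """Virtual-PCR a diploid line: predict both haplotype observables,
    pool the bands on one gel lane and score."""
    p1 = predict_products(marker, hap1_variants)
    p2 = predict_products(marker, hap2_variants)
    bands = p1.bands | p2.bands
    if bands:
        observed = ProductPattern(bands=frozenset(bands))
    else:
        observed = ProductPattern.none()
    return score_genotype(observed, marker)


def maf(scores: Iterable[int | None]) -> float:
    """Allele-count minor allele frequency, in percent (always <= 50).

    Heterozygotes contribute one allele to each class:
    ``(2*n_minor_hom + n_het) / (2*n_called) * 100``.
    """
    n0 = n1 = n2 = 0
    for s in scores:
        if s == 0:
            n0 += 1
        elif s == 1:
            n1 += 1
        elif s == 2:
            n2 += 1
        elif s is not None and not (isinstance(s, float) and math.isnan(s)):
            raise ValueError(f"bad genotype score {s!r}")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("MAF undefined: no non-missing calls")
    f2 = (2 * n2 + n1) / (2 * n) * 100.0
    return min(f2, 100.0 - f2)


def summarize_marker(marker_id: str, scores: Sequence[int | None]) -> MarkerSummary:
    called = [s for s in scores if s in (0, 1, 2)]
    if not called:
        return MarkerSummary(marker_id, float("nan"), 0, True)
    value = maf(called)
    return MarkerSummary(marker_id, value, len(called), value == 0.0)


def filter_markers(
    summaries: Iterable[MarkerSummary], maf_min: float = 1.5
) -> list[MarkerSummary]:
    """Retain markers with MAF >= ``maf_min`` (inclusive boundary) that are
    not monomorphic; markers with undefined MAF are dropped."""
    out = []
    for s in summaries:
        if s.is_monomorphic or math.isnan(s.maf_percent):
            continue
        if s.maf_percent >= maf_min:
            out.append(s)
    return out


def discriminatory_accuracy(
    calls: Sequence[GenotypeCall], target_line_set: Iterable[str]
) -> float:
    """Percent of panel lines whose call agrees with a target-specific allele.

    A mismatch is a non-target line carrying the target-specific (score 2)
    allele in homozygous or heterozygous state, or a target line lacking it.
    Reported to one decimal, over the full panel size.
    """
    targets = set(target_line_set)
    if not calls:
        raise ValueError("empty panel")
    unknown = targets - {c.line_id for c in calls}
    if unknown:
        raise ValueError(f"target lines not in panel: {sorted(unknown)}")
    mismatches = 0
    for c in calls:
        if c.line_id in targets:
            if c.score == 0:
                mismatches += 1
        elif c.score in (1, 2):
            mismatches += 1
    return round((len(calls) - mismatches) / len(calls) * 100.0, 1)
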