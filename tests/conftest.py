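"""Shared fixtures: tiny hand-built alignments and worked-example markers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ftindelscan.alignment import Alignment, ReferenceAnchor
from ftindelscan.markers import AllelePattern, MarkerDef

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


def make_alignment(seqs: dict[str, str], ref_id: str | None = None) -> Alignment:
    return Alignment(sequences=dict(seqs), ref_id=ref_id or next(iter(seqs)))


@pytest.fixture
def fta1_anchor() -> ReferenceAnchor:
    """Forward-strand anchor of a promoter on chromosome 2."""
    return ReferenceAnchor(
        gene_id="FTa1", chromosome="Chr02", tss_genomic=14_996_788, strand="forward"
    )


@pytest.fixture
def fta2_anchor() -> ReferenceAnchor:
    """Reverse-complement anchor (upstream = larger genomic coordinate)."""
    return ReferenceAnchor(
        gene_id="FTa2", chromosome="Chr21", tss_genomic=12_758_313,
        strand="reverse_complement",
    )


@pytest.fixture
def pr09_marker() -> MarkerDef:
    """Promoter marker spanning a 90-bp deletion: 826-bp reference product,
    736-bp deletion product, heterozygote shows both bands."""
    return MarkerDef(
        marker_id="PR_09",
        gene_id="FTa1",
        fwd_end_tss_rel=-4161,
        rev_end_tss_rel=-3336,
        allele0=AllelePattern.of(826),
        allele2=AllelePattern.of(736),
    )


def random_gapped_alignment(rng: np.random.Generator, n_seqs=3, n_cols=80):
    """Fully random gapped alignment for oracle-equivalence tests.

    Column composition is drawn per sequence with a gap-opening bias so that
    realistic runs occur; the reference keeps enough bases to stay usable.
    """
    bases = np.array(list("ACGT"))
    ids = ["ref"] + [f"c{i}" for i in range(1, n_seqs)]
    cols = {sid: [] for sid in ids}
    gap_state = {sid: False for sid in ids}
    for _ in range(n_cols):
        for sid in ids:
            p_gap = 0.55 if gap_state[sid] else (0.08 if sid == "ref" else 0.18)
            if rng.random() < p_gap:
                cols[sid].append("-")
                gap_state[sid] = True
            else:
                cols[sid].append(bases[rng.integers(0, 4)])
                gap_state[sid] = False
    seqs = {sid: "".join(c) for sid, c in cols.items()}
    if seqs["ref"].count("-") == len(seqs["ref"]):  # all-gap reference
        seqs["ref"] = "A" * n_cols
    # drop sequences that vanished entirely
    for sid in list(seqs):
        if sid != "ref" and set(seqs[sid]) == {"-"}:
            seqs[sid] = ("A" * n_cols)[: len(seqs[sid])]
    return Alignment(sequences=seqs, ref_id="ref")
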