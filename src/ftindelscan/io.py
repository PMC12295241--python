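"""Tab-separated readers and writers for the pipeline's external interfaces.

All tables are plain TSV so that every artefact stays diff-able: anchors,
marker definitions, variant catalogues, genotype matrices, long phenotype
tables and motif models.  Band patterns serialise as comma-separated
lengths with the token ``no_product`` allowed (e.g. ``2504,378,no_product``);
matrix motifs serialise one position per ``;``-separated block of
``A:0.1,C:0.2,G:0.3,T:0.4`` entries.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alignment import IndelVariant, ReferenceAnchor, SnpLocus
from .markers import AllelePattern, GenotypeCall, MarkerDef
from .tfbs import BASES, MotifModel, MotifSite


# -- anchors ----------------------------------------------------------------

def read_anchors(path: str | Path) -> dict[str, ReferenceAnchor]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for _, row in df.iterrows():
        region = row.get("region_start_genomic")
        out[row["gene_id"]] = ReferenceAnchor(
            gene_id=row["gene_id"],
            chromosome=row["chromosome"],
            tss_genomic=int(row["tss_genomic"]),
            strand=row["strand"],
            region_start_genomic=(
                int(float(region)) if pd.notna(region) and region != "" else None
            ),
        )
    return out


def write_anchors(anchors: Iterable[ReferenceAnchor], path: str | Path) -> None:
    pd.DataFrame([asdict(a) for a in anchors]).to_csv(path, sep="\t", index=False)


# -- markers ----------------------------------------------------------------

def _parse_allele(text: str) -> AllelePattern:
    text = str(text).strip()
    if not text or text == "-":
        return AllelePattern()
    bands = []
    no_product = False
    for tok in text.split(","):
        tok = tok.strip()
        if tok == "no_product":
            no_product = True
        else:
            bands.append(int(tok))
    return AllelePattern(frozenset(bands), allows_no_product=no_product)


def _format_allele(a: AllelePattern) -> str:
    toks = [str(b) for b in sorted(a.bands)]
    if a.allows_no_product:
        toks.append("no_product")
    return ",".join(toks) if toks else "-"


def read_markers(path: str | Path) -> list[MarkerDef]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            MarkerDef(
                marker_id=row["marker_id"],
                gene_id=row["gene_id"],
                fwd_end_tss_rel=int(row["fwd_end_tss_rel"]),
                rev_end_tss_rel=int(row["rev_end_tss_rel"]),
                primer_len_f=int(row.get("primer_len_f", 20) or 20),
                primer_len_r=int(row.get("primer_len_r", 20) or 20),
                allele0=_parse_allele(row["allele0_bands"]),
                allele2=_parse_allele(row["allele2_bands"]),
                notes=str(row.get("notes", "") or ""),
            )
        )
    return out


def write_markers(markers: Iterable[MarkerDef], path: str | Path) -> None:
    rows = []
    for m in markers:
        rows.append(
            {
                "marker_id": m.marker_id,
                "gene_id": m.gene_id,
                "fwd_end_tss_rel": m.fwd_end_tss_rel,
                "rev_end_tss_rel": m.rev_end_tss_rel,
                "primer_len_f": m.primer_len_f,
                "primer_len_r": m.primer_len_r,
                "allele0_bands": _format_allele(m.allele0),
                "allele2_bands": _format_allele(m.allele2),
                "notes": m.notes,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- variants ---------------------------------------------------------------

def write_variants(
    indels: Sequence[IndelVariant], snps: Sequence[SnpLocus], path: str | Path
) -> None:
    rows = []
    for v in indels:
        rows.append(
            {
                "kind": v.kind,
                "ref_start": v.ref_start,
                "ref_end": v.ref_end,
                "length": v.length,
                "aln_start": v.aln_start,
                "aln_end": v.aln_end,
                "tss_rel_start": v.tss_rel_start,
                "tss_rel_end": v.tss_rel_end,
                "carriers": "|".join(sorted(v.carriers)),
                "inserted_seq": v.inserted_seq,
            }
        )
    for s in snps:
        for alt, carriers in s.alts.items():
            rows.append(
                {
                    "kind": "snp",
                    "ref_start": s.ref_pos,
                    "ref_end": s.ref_pos,
                    "length": 1,
                    "aln_start": s.aln_col,
                    "aln_end": s.aln_col,
                    "tss_rel_start": s.tss_rel,
                    "tss_rel_end": s.tss_rel,
                    "carriers": "|".join(sorted(carriers)),
                    "inserted_seq": f"{s.ref_base}>{alt}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_indels(path: str | Path) -> list[IndelVariant]:
    """Read back the indel rows of a variants TSV (SNP rows are skipped)."""
    df = pd.read_csv(path, sep="\t", dtype={"carriers": str, "inserted_seq": str})
    out = []
    for _, row in df.iterrows():
        if row["kind"] == "snp":
            continue
        def _opt(v):
            return None if pd.isna(v) else int(v)
        out.append(
            IndelVariant(
                kind=row["kind"],
                ref_start=int(row["ref_start"]),
                ref_end=int(row["ref_end"]),
                length=int(row["length"]),
                carriers=frozenset(str(row["carriers"]).split("|")),
                aln_start=int(row["aln_start"]),
                aln_end=int(row["aln_end"]),
                inserted_seq="" if pd.isna(row.get("inserted_seq")) else str(row["inserted_seq"]),
                tss_rel_start=_opt(row.get("tss_rel_start")),
                tss_rel_end=_opt(row.get("tss_rel_end")),
            )
        )
    return out


# -- genotypes & calls ------------------------------------------------------

def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Genotype matrix: lines x markers, cells 0/1/2 or NA."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df.astype(float)


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    out = genotypes.copy()
    out.index.name = "line_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def calls_to_frame(calls: Iterable[GenotypeCall]) -> pd.DataFrame:
    rows = [(c.line_id, c.marker_id, c.score) for c in calls]
    df = pd.DataFrame(rows, columns=["line_id", "marker_id", "score"])
    return df.pivot(index="line_id", columns="marker_id", values="score").astype(float)


# -- phenotypes -------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "trait": str, "year": str})
    required = {"line_id", "trait", "year", "replicate", "days"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


# -- motifs -----------------------------------------------------------------

def _parse_matrix(text: str) -> tuple[tuple[float, float, float, float], ...]:
    rows = []
    for block in text.strip().split(";"):
        freqs = dict(
            (kv.split(":")[0].strip().upper(), float(kv.split(":")[1]))
            for kv in block.split(",")
        )
        rows.append(tuple(freqs.get(b, 0.0) for b in BASES))
    return tuple(rows)


def _format_matrix(matrix) -> str:
    return ";".join(
        ",".join(f"{b}:{f:g}" for b, f in zip(BASES, row)) for row in matrix
    )


def read_motifs(path: str | Path) -> list[MotifModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        kind = row["kind"]
        thr = float(row.get("threshold") or 0.85)
        if kind == "consensus":
            out.append(
                MotifModel(row["tf_id"], row["name"], "consensus",
                           consensus=row["model"], threshold=thr)
            )
        else:
            out.append(
                MotifModel(row["tf_id"], row["name"], "matrix",
                           matrix=_parse_matrix(row["model"]), threshold=thr)
            )
    return out


def write_motifs(motifs: Iterable[MotifModel], path: str | Path) -> None:
    rows = []
    for m in motifs:
        rows.append(
            {
                "tf_id": m.tf_id,
                "name": m.name,
                "kind": m.kind,
                "model": m.consensus if m.kind == "consensus" else _format_matrix(m.matrix),
                "threshold": m.threshold,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- motif sites ------------------------------------------------------------

def write_sites(sites: Sequence[MotifSite], path: str | Path) -> None:
    rows = []
    for s in sites:
        rows.append(
            {
                "tf_id": s.tf_id,
                "sequence_id": s.sequence_id,
                "position": s.aln_start,
                "end": s.aln_end,
                "strand": {"both": "+/-"}.get(s.strand, s.strand),
                "score": round(s.score, 4),
                "in_polymorphic_region": int(s.in_polymorphic_region),
                "indel_labels": ",".join(sorted(s.indel_labels)) or "-",
            }
        )
    pd.DataFrame(
        rows,
        columns=["tf_id", "sequence_id", "position", "end", "strand", "score",
                 "in_polymorphic_region", "indel_labels"],
    ).to_csv(path, sep="\t", index=False)
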