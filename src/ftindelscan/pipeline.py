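"""End-to-end orchestration: simulate -> variants -> genotype -> MAF ->
association -> TFBS, with a machine-readable manifest.

Every stage writes plain-text outputs into one directory and never mutates
another stage's files; the manifest records the seed, all thresholds and a
SHA-256 hash of each output, so a rerun with the same config can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import alignment as al
from . import association as assoc
from . import io as fio
from . import markers as mk
from . import simulate as sim
from . import tfbs


@dataclass
class RunConfig:
    """Thresholds and inputs of one pipeline run.

    When ``alignment_path`` is ``None`` the run starts from the synthetic
    generator (``sim_*`` fields); otherwise alignment/anchors/genotypes/
    phenotypes must all be supplied.
    """

    out_dir: str | Path = "ftindelscan_run"
    seed: int = 0
    maf_min: float = 1.5
    similarity: float = 0.85
    alpha: float = 0.05
    resolvability: float = 0.02
    family: str = "all"
    alignment_path: str | Path | None = None
    ref_id: str | None = None
    anchors_path: str | Path | None = None
    genotypes_path: str | Path | None = None
    phenotypes_path: str | Path | None = None
    motifs_path: str | Path | None = None
    gene_id: str | None = None
    sim_alignment: sim.SimAlignmentConfig = field(default_factory=sim.SimAlignmentConfig)
    sim_panel: sim.SimPanelConfig = field(default_factory=sim.SimPanelConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 < self.similarity <= 1:
            raise ValueError("similarity must be in (0,1]")
        if self.maf_min < 0:
            raise ValueError("maf_min must be >= 0")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def demo_motifs() -> list[tfbs.MotifModel]:
    """A small bundled motif set for smoke runs and tests.

    The AGL15 CArG-type consensus (CARGNCAT) is the one literature-derived
    entry; the remaining matrices are synthetic stand-ins with realistic
    information content, not database motifs.
    """
    import numpy as np

    models = [
        tfbs.MotifModel("AT5G13790", "AGL15", "consensus", consensus="CARGNCAT")
    ]
    rng = np.random.default_rng(20240101)
    for i in range(1, 6):
        rows = []
        for _ in range(8):
            major = int(rng.integers(0, 4))
            row = [0.05, 0.05, 0.05, 0.05]
            row[major] = 0.85
            rows.append(tuple(row))
        models.append(
            tfbs.MotifModel(
                f"SYN{i:02d}", f"synthetic_tf_{i}", "matrix",
                matrix=tuple(rows), threshold=0.85,
            )
        )
    return models


def genotype_panel(
    markers: Sequence[mk.MarkerDef],
    indels: Sequence[al.IndelVariant],
    panel: pd.DataFrame,
) -> list[mk.GenotypeCall]:
    """Virtual-PCR genotyping of a diploid panel.

    ``panel`` maps each line to two haplotype sources (columns ``hap1``,
    ``hap2``), each naming a sequence whose carried variants define the
    haplotype; a source carrying nothing (e.g. the reference) amplifies the
    reference allele.
    """
    for col in ("hap1", "hap2"):
        if col not in panel.columns:
            raise ValueError(f"panel table lacks column {col!r}")
    by_source: dict[str, list[al.IndelVariant]] = {}
    for v in indels:
        for c in v.carriers:
            by_source.setdefault(c, []).append(v)
    calls = []
    for line_id, row in panel.iterrows():
        h1 = by_source.get(str(row["hap1"]), [])
        h2 = by_source.get(str(row["hap2"]), [])
        for m in markers:
            score = mk.genotype_line(m, h1, h2)
            calls.append(mk.GenotypeCall(str(line_id), m.marker_id, score))
    return calls


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    # -- stage: inputs ------------------------------------------------------
    try:
        if config.alignment_path is None:
            aln, aln_truth = sim.simulate_alignment(
                config.sim_alignment, seed=config.seed
            )
            al.write_alignment(aln, emit(out / "alignment.fasta"))
            tss_ref_pos = max(1, round(0.8 * config.sim_alignment.ref_length))
            anchor = al.ReferenceAnchor(
                gene_id=config.gene_id or "simFT",
                chromosome="chrSim",
                tss_genomic=tss_ref_pos,
                strand=al.FORWARD,
            )
            genotypes, pheno, panel_truth = sim.simulate_panel(
                config.sim_panel, seed=config.seed + 1
            )
            fio.write_genotypes(genotypes, emit(out / "genotypes.tsv"))
            fio.write_phenotypes(pheno, emit(out / "phenotypes.tsv"))
            truth_doc = {
                "indels": [
                    {"kind": v.kind, "ref_start": v.ref_start, "length": v.length,
                     "carriers": sorted(v.carriers)}
                    for v in aln_truth.indels
                ],
                "causal_effects": panel_truth.causal_effects,
                "seed": config.seed,
            }
            emit(out / "truth.json").write_text(
                json.dumps(truth_doc, indent=2, sort_keys=True) + "\n"
            )
        else:
            aln = al.read_alignment(config.alignment_path, ref_id=config.ref_id)
            anchors = fio.read_anchors(config.anchors_path)
            if config.gene_id:
                anchor = anchors[config.gene_id]
            else:
                anchor = next(iter(anchors.values()))
            if config.genotypes_path is None or config.phenotypes_path is None:
                raise FileNotFoundError(
                    "genotypes and phenotypes are required with an input alignment"
                )
            genotypes = fio.read_genotypes(config.genotypes_path)
            pheno = fio.read_phenotypes(config.phenotypes_path)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"input stage failed: {e}") from e

    # -- stage: variants ----------------------------------------------------
    try:
        indels, snps = al.call_variants(aln, anchor=anchor)
        fio.write_variants(indels, snps, emit(out / "variants.tsv"))
        al.export_variants(
            indels, snps, aln,
            vcf_path=emit(out / "variants.vcf"),
            bed_path=emit(out / "variants.bed"),
            contig_name=anchor.chromosome,
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(f"variant stage failed: {e}") from e

    # -- stage: MAF screening -----------------------------------------------
    try:
        summaries = [
            mk.summarize_marker(m, genotypes[m].tolist()) for m in genotypes.columns
        ]
        retained = {s.marker_id for s in mk.filter_markers(summaries, config.maf_min)}
        pd.DataFrame(
            [
                {
                    "marker_id": s.marker_id,
                    "maf_percent": round(s.maf_percent, 1),
                    "n_called": s.n_called,
                    "retained": int(s.marker_id in retained),
                }
                for s in summaries
            ]
        ).to_csv(emit(out / "maf_summary.tsv"), sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"MAF stage failed: {e}") from e

    # -- stage: association ---------------------------------------------------
    try:
        if config.phenotypes_path is None and config.alignment_path is not None:
            raise FileNotFoundError("phenotype file missing")
        kept = genotypes[[m for m in genotypes.columns if m in retained]]
        results = assoc.association_scan(
            kept, pheno, family=config.family, alpha=config.alpha
        )
        results.to_csv(emit(out / "associations.tsv"), sep="\t", index=False)
        year_corr = assoc.between_year_correlation(pheno)
        ks_rows = []
        means = assoc.trait_means(pheno)
        for trait, year in means.columns:
            ks = assoc.ks_normality(means[(trait, year)].dropna(), trait_id=trait)
            ks_rows.append(
                {"trait": trait, "year": year, "D": round(ks.statistic, 4),
                 "p": ks.p_value, "normal": int(ks.normal)}
            )
        pd.DataFrame(ks_rows).to_csv(emit(out / "ks_normality.tsv"), sep="\t", index=False)
        report = assoc.allele_phenotype_table(kept, pheno)
        report.to_csv(emit(out / "allele_by_phenotype.tsv"), sep="\t", na_rep="NA")
    except Exception as e:  # noqa: BLE001
        raise StageError(f"association stage failed: {e}") from e

    # -- stage: TFBS ----------------------------------------------------------
    try:
        motifs = (
            fio.read_motifs(config.motifs_path)
            if config.motifs_path
            else demo_motifs()
        )
        motifs = [
            tfbs.MotifModel(
                m.tf_id, m.name, m.kind, consensus=m.consensus, matrix=m.matrix,
                threshold=m.threshold if m.kind == "consensus" else config.similarity,
            )
            for m in motifs
        ]
        regions = al.polymorphic_region_set(indels, snps)
        cmap = al.build_coord_map(aln)
        tss_col = cmap.col(min(anchor.tss_genomic, cmap.ref_length))
        scope = (1, max(1, tss_col - 1))
        sites: list[tfbs.MotifSite] = []
        for sid, seq in aln.sequences.items():
            for model in motifs:
                sites.extend(tfbs.scan(sid, seq, model))
        sites = tfbs.classify_sites(sites, regions)
        fio.write_sites(sites, emit(out / "tfbs_sites.tsv"))
        verdicts = tfbs.exclusive_tfs(sites, scope)
        pd.DataFrame(
            [
                {"tf_id": v.tf_id, "n_sites": v.n_sites,
                 "n_in_polymorphic": v.n_in_polymorphic, "exclusive": int(v.exclusive)}
                for v in verdicts
            ]
        ).to_csv(emit(out / "tfbs_verdicts.tsv"), sep="\t", index=False)
        names = {m.tf_id: m.name for m in motifs}
        tfbs.per_indel_report(sites, verdicts, names).to_csv(
            emit(out / "tfbs_report.tsv"), sep="\t", index=False
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(f"TFBS stage failed: {e}") from e

    manifest = {
        "seed": config.seed,
        "thresholds": {
            "maf_min": config.maf_min,
            "similarity": config.similarity,
            "alpha": config.alpha,
            "resolvability": config.resolvability,
            "family": config.family,
        },
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
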