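# ftindelscan

Promoter **indel genotyping**, in-silico **PCR marker scoring** and
rank-based **marker–trait association** for flowering-time (*FT*-family)
genes in predominantly selfing crops such as lupins.

Structural variants (insertions/deletions of a few bp up to several kbp) in
the promoters of *FLOWERING LOCUS T* homologs are a recurring genetic basis
of flowering-time differences between spring and winter ecotypes.  The
standard desk workflow around such variants is: call indels and SNPs from a
gapped alignment of a reference promoter against assembly contigs; design
PCR markers whose product lengths (or product absence) distinguish the
alleles; genotype a diversity panel on gels as 0/1/2 scores; screen markers
by minor allele frequency; correlate phenology traits with the scores; and
scan transcription-factor binding motifs to ask which regulators lose or
gain binding sites inside the polymorphic regions.  `ftindelscan`
implements every one of those steps as a tested, reusable library with a
thin CLI, plus a synthetic-panel simulator so the whole pipeline can be
validated without any external download.

## The core quantities

* **TSS-relative geometry.**  Positions are signed bp relative to the
  transcription start site (0 at the TSS, negative upstream; the axis
  includes 0, so an interval's inclusive length is `|a − b| + 1`).
* **Virtual PCR.**  For a haplotype's variant set, the product is
  `span + Σ insertions − Σ deletions` within the amplicon; a deletion
  touching a primer window gives *no product* (a presence/absence variant).
  Bands merge on a gel when `|Δlen|/max(len)` is below the resolvability
  threshold (default 2 %).
* **MAF screening.**  Allele-count minor allele frequency
  `(2·n_minor_hom + n_het)/(2·n_called)`, markers kept at MAF ≥ 1.5 %.
* **Association.**  Correlation ρ of phenotype *average ranks* against raw
  marker scores 0/1/2, with `t = ρ·√((n−2)/(1−ρ²))` two-tailed on n−2 df
  and Bonferroni adjustment `min(1, m·p)` over the marker family.
* **TFBS exclusivity.**  Motif sites (IUPAC consensus or frequency-matrix
  similarity ≥ 0.85) intersected with indel/SNP regions; a TF whose every
  promoter site is polymorphic is flagged *exclusive*.

See `docs/methods.md` for the full model description and design decisions.

## Worked example

Simulate a 626-line panel with one causal marker sized to the ρ ≈ 0.35
regime typical of strongly associated promoter indels, then scan it:

```python
from ftindelscan.simulate import SimPanelConfig, simulate_panel, effect_size_for_rho
from ftindelscan.association import association_scan, between_year_correlation

cfg = SimPanelConfig(n_lines=626, allele_freqs={f"M{i:02d}": 0.3 for i in range(1, 11)})
cfg.effects = {"M01": effect_size_for_rho(0.35, 0.3, cfg)}   # 5.15 days per score unit
geno, pheno, truth = simulate_panel(cfg, seed=42)

res = association_scan(geno, pheno)
print(res[(res.trait == "BE") & (res.year == "Y1")].sort_values("p_adj").head(3))
```

which prints (floral bud emergence, first season):

```
marker_id       rho  n_used        p_raw  family_size        p_adj  significant
      M01  0.310094     626 2.028532e-15           10 2.028532e-14         True
      M02 -0.059465     626 1.372360e-01           10 1.000000e+00        False
      M03 -0.045052     626 2.603701e-01           10 1.000000e+00        False
```

The planted marker is recovered with ρ ≈ 0.31 (target 0.35, sampling noise
at n = 626), fifteen orders of magnitude clear of the null markers after
Bonferroni correction; the traits are grossly non-normal by construction
(KS D = 0.125, p ≈ 6e-09), which is why the scan is rank-based; and the
between-year repeatability comes out at 0.957/0.962/0.970 for the three
phenology stages against the configured 0.96.

The same stages run from the shell:

```bash
ftindelscan simulate --seed 42 --out-dir sim/
ftindelscan variants --alignment sim/alignment.fasta --out-prefix sim/var
ftindelscan maf --calls sim/genotypes.tsv
ftindelscan associate --calls sim/genotypes.tsv --phenotypes sim/phenotypes.tsv --out assoc.tsv
ftindelscan run-all --seed 42 --out-dir run/      # everything + manifest.json
```

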