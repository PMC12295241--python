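"""Synthetic diversity-panel simulator.

Generates every input the pipeline consumes, with the statistical structure
the analysis assumes:

* a gapped promoter alignment of a reference plus several contigs with
  planted deletions, insertions, SNPs, overlapping variants and terminal
  contig truncations, together with the ground-truth variant list;
* a mostly-selfing diploid genotype panel — heterozygote frequency
  2pq(1 - s) for selfing rate s — with markers drawn independently
  (a reasonable stand-in for a genome with very rapid LD decay);
* two-season phenology traits (BE <= SF <= EF per line) built from additive
  marker effects plus a line genetic value shared between years, with a
  bimodal early/late mixture that guarantees non-normality, an environmental
  year effect calibrated to a target between-year correlation, and 3-10
  replicates per observation.

Everything is driven by one ``numpy`` Generator per call, so identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment

DEFAULT_N_LINES = 626
DEFAULT_SELFING = 0.95
DEFAULT_REPEATABILITY = 0.96
TRAITS = ("BE", "SF", "EF")


# ---------------------------------------------------------------------------
# alignment simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedIndel:
    """A variant to plant: for deletions ``ref_start`` is the first deleted
    reference base; for insertions it is the anchor base (insert after it)."""

    kind: str  # "deletion" | "insertion"
    ref_start: int
    length: int
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass(frozen=True)
class PlantedSnp:
    ref_pos: int
    alt: str
    carriers: frozenset[str]


@dataclass
class SimAlignmentConfig:
    """Shape of the simulated promoter alignment.

    Defaults give a compact region with the variant-size spectrum of real
    promoter catalogues scaled down (deletions up to a few hundred bp rather
    than several kbp) so that tests stay fast."""

    ref_length: int = 5000
    n_contigs: int = 3
    n_deletions: int = 4
    n_insertions: int = 2
    n_snps: int = 10
    deletion_length_range: tuple[int, int] = (7, 400)
    insertion_length_range: tuple[int, int] = (8, 120)
    terminal_gap_contig: bool = True
    terminal_gap_length: int = 60
    max_retries: int = 500


@dataclass
class AlignmentTruth:
    indels: list[PlantedIndel]
    snps: list[PlantedSnp]
    truncations: dict[str, tuple[int, int]]  # contig -> (head bp, tail bp)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def simulate_alignment(
    config: SimAlignmentConfig | None = None,
    seed: int = 0,
    planted: Sequence[PlantedIndel] | None = None,
    planted_snps: Sequence[PlantedSnp] | None = None,
) -> tuple[Alignment, AlignmentTruth]:
    """Build a gapped alignment with planted variants and return the truth.

    Variants may be supplied explicitly (``planted`` / ``planted_snps``,
    carrier names ``contig_1`` ... ``contig_k``) or drawn at random per the
    config.  Per contig, planted events must not overlap each other (overlap
    *across* contigs is allowed and exercises the overlapping-variant path);
    insertion anchors are unique alignment-wide.  Placement collisions are
    retried up to ``config.max_retries`` times, then raise ``RuntimeError``.
    """
    cfg = config or SimAlignmentConfig()
    rng = np.random.default_rng(seed)
    contigs = [f"contig_{i + 1}" for i in range(cfg.n_contigs)]
    ref_id = "reference"
    L = cfg.ref_length

    truncations: dict[str, tuple[int, int]] = {}
    if cfg.terminal_gap_contig and contigs:
        truncations[contigs[-1]] = (cfg.terminal_gap_length, cfg.terminal_gap_length)

    def forbidden(contig: str) -> list[tuple[int, int]]:
        head, tail = truncations.get(contig, (0, 0))
        iv = []
        if head:
            iv.append((1, head + 2))
        if tail:
            iv.append((L - tail - 1, L))
        return iv

    if planted is not None:
        indels = list(planted)
        snps = list(planted_snps or [])
    else:
        indels = []
        taken: dict[str, list[tuple[int, int]]] = {c: forbidden(c) for c in contigs}
        anchors_used: set[int] = set()

        def clash(c: str, lo: int, hi: int) -> bool:
            return any(lo <= b + 1 and a - 1 <= hi for a, b in taken[c])

        tries = 0
        want = [("deletion", cfg.deletion_length_range)] * cfg.n_deletions + [
            ("insertion", cfg.insertion_length_range)
        ] * cfg.n_insertions
        for kind, (lmin, lmax) in want:
            while True:
                tries += 1
                if tries > cfg.max_retries:
                    raise RuntimeError("variant placement collision limit reached")
                c = contigs[rng.integers(0, len(contigs))]
                length = int(rng.integers(lmin, lmax + 1))
                if kind == "deletion":
                    start = int(rng.integers(2, L - length))
                    lo, hi = start, start + length - 1
                else:
                    start = int(rng.integers(2, L - 1))
                    if start in anchors_used:
                        continue
                    lo, hi = start, start + 1
                if clash(c, lo, hi):
                    continue
                taken[c].append((lo, hi))
                if kind == "insertion":
                    anchors_used.add(start)
                indels.append(
                    PlantedIndel(kind, start, length, frozenset({c}))
                )
                break

        snps = []
        snp_pos = set()
        tries = 0
        while len(snps) < cfg.n_snps:
            tries += 1
            if tries > cfg.max_retries * 4:
                raise RuntimeError("SNP placement collision limit reached")
            c = contigs[rng.integers(0, len(contigs))]
            pos = int(rng.integers(2, L))
            if pos in snp_pos or clash(c, pos, pos):
                continue
            snp_pos.add(pos)
            taken[c].append((pos, pos))
            snps.append(PlantedSnp(pos, "", frozenset({c})))

    ref_seq = _random_seq(rng, L)

    # resolve SNP alt bases now that the reference exists
    resolved_snps = []
    for s in snps:
        if s.alt:
            resolved_snps.append(s)
        else:
            choices = [b for b in "ACGT" if b != ref_seq[s.ref_pos - 1]]
            resolved_snps.append(
                PlantedSnp(s.ref_pos, choices[rng.integers(0, 3)], s.carriers)
            )
    snps = resolved_snps

    insertions = sorted(
        (v for v in indels if v.kind == "insertion"),
        key=lambda v: (v.ref_start, v.length),
    )
    anchor_counts: dict[int, int] = {}
    for v in insertions:
        anchor_counts[v.ref_start] = anchor_counts.get(v.ref_start, 0) + 1
    if any(n > 1 for n in anchor_counts.values()):
        raise RuntimeError("two insertion variants share an anchor position")
    ins_seqs = {v: _random_seq(rng, v.length) for v in insertions}
    ins_at = {v.ref_start: v for v in insertions}

    del_by_contig: dict[str, list[PlantedIndel]] = {c: [] for c in contigs}
    for v in indels:
        if v.kind == "deletion":
            if v.ref_start < 1 or v.ref_start + v.length - 1 > L:
                raise ValueError(f"deletion outside reference: {v}")
            for c in v.carriers:
                del_by_contig[c].append(v)
    snps_at: dict[tuple[str, int], str] = {}
    for s in snps:
        for c in s.carriers:
            snps_at[(c, s.ref_pos)] = s.alt

    rows: dict[str, list[str]] = {ref_id: []}
    for c in contigs:
        rows[c] = []

    deleted = {
        c: np.zeros(L + 1, dtype=bool) for c in contigs
    }
    for c, vs in del_by_contig.items():
        for v in vs:
            deleted[c][v.ref_start : v.ref_start + v.length] = True
    trunc_mask = {c: np.zeros(L + 1, dtype=bool) for c in contigs}
    for c, (head, tail) in truncations.items():
        if head:
            trunc_mask[c][1 : head + 1] = True
        if tail:
            trunc_mask[c][L - tail + 1 : L + 1] = True

    for pos in range(1, L + 1):
        rbase = ref_seq[pos - 1]
        rows[ref_id].append(rbase)
        for c in contigs:
            if trunc_mask[c][pos] or deleted[c][pos]:
                rows[c].append("-")
            else:
                rows[c].append(snps_at.get((c, pos), rbase))
        v = ins_at.get(pos)
        if v is not None:
            block = ins_seqs[v]
            rows[ref_id].append("-" * v.length)
            for c in contigs:
                if c in v.carriers and not trunc_mask[c][pos]:
                    rows[c].append(block)
                else:
                    rows[c].append("-" * v.length)

    seqs = {ref_id: "".join(rows[ref_id])}
    for c in contigs:
        seqs[c] = "".join(rows[c])
    aln = Alignment(sequences=seqs, ref_id=ref_id)
    truth = AlignmentTruth(indels=list(indels), snps=list(snps), truncations=truncations)
    return aln, truth


def truth_as_expected_calls(truth: AlignmentTruth) -> set[tuple]:
    """The (kind, ref interval, length, carriers) tuples the variant caller
    should recover — deletions planted with identical intervals in several
    contigs merge into one multi-carrier call."""
    merged: dict[tuple, set[str]] = {}
    for v in truth.indels:
        if v.kind == "deletion":
            key = ("deletion", v.ref_start, v.ref_start + v.length - 1, v.length)
        else:
            key = ("insertion", v.ref_start, v.ref_start, v.length)
        merged.setdefault(key, set()).update(v.carriers)
    return {key + (frozenset(c),) for key, c in merged.items()}


# ---------------------------------------------------------------------------
# genotype + phenotype panel simulation
# ---------------------------------------------------------------------------

@dataclass
class SimPanelConfig:
    """Study conditions of the simulated germplasm panel.

    ``n_lines`` and the replicate range mirror a two-season controlled-
    environment phenotyping of a 626-genotype collection with 3-10
    biological replicates; ``selfing_rate`` keeps heterozygotes rare
    (het frequency 2pq(1 - s)); the early/late mixture makes every trait
    clearly non-normal; ``year_repeatability`` is the target between-year
    trait correlation.
    """

    n_lines: int = DEFAULT_N_LINES
    allele_freqs: Mapping[str, float] = field(
        default_factory=lambda: {f"M{i:02d}": 0.3 for i in range(1, 11)}
    )
    effects: Mapping[str, float] = field(default_factory=dict)  # days per score unit
    selfing_rate: float = DEFAULT_SELFING
    year_repeatability: float = DEFAULT_REPEATABILITY
    years: tuple[str, str] = ("Y1", "Y2")
    be_baseline: float = 50.0
    sf_gap_range: tuple[float, float] = (4.0, 12.0)
    ef_gap_range: tuple[float, float] = (15.0, 35.0)
    late_fraction: float = 0.3
    late_shift: float = 30.0
    sd_early: float = 6.0
    sd_late: float = 8.0
    replicate_range: tuple[int, int] = (3, 10)
    replicate_sd: float = 2.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for m, q in self.allele_freqs.items():
            if not 0 < q < 1:
                raise ValueError(f"allele frequency of {m} must be in (0,1)")
        if not 0 <= self.selfing_rate <= 1:
            raise ValueError("selfing_rate must be in [0,1]")
        lo, hi = self.replicate_range
        if not (3 <= lo <= hi <= 10):
            raise ValueError("replicate_range must lie within [3, 10]")


@dataclass
class SimTruth:
    causal_effects: dict[str, float]
    allele_freqs: dict[str, float]
    genetic_values: pd.Series  # per-line shared signal (mixture + effects)


def genetic_mixture_variance(cfg: SimPanelConfig) -> float:
    """Analytic variance of the early/late genetic-value mixture."""
    w = cfg.late_fraction
    return (
        (1 - w) * cfg.sd_early**2
        + w * cfg.sd_late**2
        + w * (1 - w) * cfg.late_shift**2
    )


def score_variance(q: float, selfing_rate: float) -> float:
    """Variance of a 0/1/2 genotype score under inbreeding F = selfing rate."""
    p = 1 - q
    return 2 * p * q * (1 + selfing_rate)


# The generator targets the *rank* statistics the analysis reports (Spearman
# repeatability between years, rank-vs-score marker correlation); under the
# bimodal genetic value they have no convenient closed form, so noise and
# effect sizes are calibrated once by Monte-Carlo bisection with a fixed
# internal seed, independent of the run seed.
_CAL_SEED = 987_654_321
_CAL_N = 20_000


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    from scipy import stats

    return float(stats.spearmanr(a, b).statistic)


def _draw_mixture(cfg: SimPanelConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    late = rng.random(n) < cfg.late_fraction
    return np.where(
        late,
        cfg.late_shift + rng.normal(0, cfg.sd_late, n),
        rng.normal(0, cfg.sd_early, n),
    )


def _draw_scores(q: float, selfing: float, rng: np.random.Generator, n: int) -> np.ndarray:
    p = 1 - q
    probs = [p * p + selfing * p * q, 2 * p * q * (1 - selfing), q * q + selfing * p * q]
    return rng.choice([0.0, 1.0, 2.0], size=n, p=probs)


def calibrate_env_sd(
    signal: np.ndarray, repeatability: float, rng: np.random.Generator | None = None
) -> float:
    """Environmental-noise SD giving the target between-year Spearman
    correlation for a line signal shared between years (bisection on
    Spearman(signal + e1, signal + e2))."""
    if not 0 < repeatability < 1:
        raise ValueError("repeatability must be in (0,1)")
    rng = rng or np.random.default_rng(_CAL_SEED)
    sd_s = float(signal.std(ddof=1))
    lo, hi = 0.0, 4.0 * sd_s
    for _ in range(28):
        mid = (lo + hi) / 2
        e1 = rng.normal(0, mid, signal.size)
        e2 = rng.normal(0, mid, signal.size)
        if _spearman(signal + e1, signal + e2) > repeatability:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


_ENV_SD_CACHE: dict[tuple, float] = {}


def _cached_env_sd(cfg: SimPanelConfig) -> float:
    causal = tuple(
        sorted((m, cfg.effects[m], cfg.allele_freqs[m])
               for m in cfg.effects if cfg.effects[m] != 0.0)
    )
    key = (
        cfg.late_fraction, cfg.late_shift, cfg.sd_early, cfg.sd_late,
        cfg.selfing_rate, cfg.year_repeatability, causal,
    )
    if key not in _ENV_SD_CACHE:
        rng = np.random.default_rng(_CAL_SEED)
        signal = _draw_mixture(cfg, rng, _CAL_N)
        for _, b, q in causal:
            signal = signal + b * _draw_scores(q, cfg.selfing_rate, rng, _CAL_N)
        _ENV_SD_CACHE[key] = calibrate_env_sd(signal, cfg.year_repeatability, rng)
    return _ENV_SD_CACHE[key]


def effect_size_for_rho(
    target_rho: float, allele_freq: float, cfg: SimPanelConfig
) -> float:
    """Marker effect (days per score unit) that yields roughly the requested
    rank-vs-score correlation under the config's genetic and environmental
    noise structure.

    Calibrated by bisection on a large synthetic sample, so the returned
    effect matches the statistic the association scan actually computes
    (phenotype ranks against raw 0/1/2 scores), not the raw-scale Pearson
    coefficient."""
    if not 0 < abs(target_rho) < 0.9:
        raise ValueError("target rho must be in (0, 0.9)")
    from scipy import stats

    rng = np.random.default_rng(_CAL_SEED + 1)
    g = _draw_mixture(cfg, rng, _CAL_N)
    s = _draw_scores(allele_freq, cfg.selfing_rate, rng, _CAL_N)
    r = cfg.year_repeatability
    # env noise scales with the signal SD at (almost) fixed ratio for a given
    # repeatability target; pin the ratio once on the effect-free signal
    env_ratio = calibrate_env_sd(g, r, rng) / float(g.std(ddof=1))

    def realized(b: float) -> float:
        signal = g + b * s
        sd_env = float(signal.std(ddof=1)) * env_ratio
        y = signal + rng.normal(0, sd_env, _CAL_N)
        return float(np.corrcoef(stats.rankdata(y), s)[0, 1])

    lo, hi = 0.0, 10.0 * cfg.sd_late
    for _ in range(24):
        mid = (lo + hi) / 2
        if realized(mid) < abs(target_rho):
            lo = mid
        else:
            hi = mid
    return float(np.sign(target_rho) * (lo + hi) / 2)


def simulate_panel(
    config: SimPanelConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw genotypes and two-season replicated phenology for a panel.

    Returns ``(genotypes, phenotypes, truth)``: a lines x markers frame of
    0/1/2 scores (NaN where genotyping failed), a long phenotype table
    (line_id, trait, year, replicate, days) and the simulation truth.
    """
    cfg = config or SimPanelConfig()
    rng = np.random.default_rng(seed)
    lines = [f"L{i:04d}" for i in range(1, cfg.n_lines + 1)]
    markers = list(cfg.allele_freqs)
    unknown = set(cfg.effects) - set(markers)
    if unknown:
        raise ValueError(f"effects for unknown markers: {sorted(unknown)}")

    F = cfg.selfing_rate
    geno = np.empty((cfg.n_lines, len(markers)), dtype=float)
    for j, m in enumerate(markers):
        q = cfg.allele_freqs[m]
        p = 1 - q
        probs = [p * p + F * p * q, 2 * p * q * (1 - F), q * q + F * p * q]
        geno[:, j] = rng.choice([0, 1, 2], size=cfg.n_lines, p=probs)

    # shared-between-years line signal: bimodal genetic value + marker effects
    late = rng.random(cfg.n_lines) < cfg.late_fraction
    g = np.where(
        late,
        cfg.late_shift + rng.normal(0, cfg.sd_late, cfg.n_lines),
        rng.normal(0, cfg.sd_early, cfg.n_lines),
    )
    beta = np.array([cfg.effects.get(m, 0.0) for m in markers])
    signal = g + geno @ beta

    # environmental year noise sized so the between-year Spearman correlation
    # of line means matches the configured repeatability; calibrated on a
    # large mixture sample with a fixed internal seed (cached per config)
    sd_env = _cached_env_sd(cfg)

    # phase gaps (bud -> flowering -> end of flowering) belong to the line,
    # shared between years; BE <= SF <= EF holds by construction
    gap_sf = rng.uniform(*cfg.sf_gap_range, cfg.n_lines)
    gap_ef = rng.uniform(*cfg.ef_gap_range, cfg.n_lines)

    rows = []
    lo_rep, hi_rep = cfg.replicate_range
    for year in cfg.years:
        env = rng.normal(0, sd_env, cfg.n_lines)
        be = cfg.be_baseline + signal + env
        sf = be + gap_sf
        ef = sf + gap_ef
        by_trait = {"BE": be, "SF": sf, "EF": ef}
        for i, line in enumerate(lines):
            k = int(rng.integers(lo_rep, hi_rep + 1))
            for trait in TRAITS:
                reps = by_trait[trait][i] + rng.normal(0, cfg.replicate_sd, k)
                for rep_no, days in enumerate(reps, start=1):
                    rows.append((line, trait, year, rep_no, round(float(days), 1)))

    pheno = pd.DataFrame(
        rows, columns=["line_id", "trait", "year", "replicate", "days"]
    )
    genotypes = pd.DataFrame(geno, index=pd.Index(lines, name="line_id"), columns=markers)
    if cfg.missing_rate > 0:
        drop = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes = genotypes.mask(drop)

    truth = SimTruth(
        causal_effects={m: e for m, e in cfg.effects.items() if e != 0.0},
        allele_freqs=dict(cfg.allele_freqs),
        genetic_values=pd.Series(signal, index=genotypes.index, name="signal"),
    )
    return genotypes, pheno, truth
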