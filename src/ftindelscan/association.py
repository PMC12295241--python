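"""Rank-based marker-trait association with Bonferroni correction.

Phenology traits (days from sowing to floral bud emergence BE, start of
flowering SF, end of flowering EF) in diversity panels are typically far
from normal — early landraces and late winter ecotypes form separate modes —
so the analysis is rank-based throughout:

1. a one-sample Kolmogorov-Smirnov check documents the departure from
   normality,
2. phenotype values are converted to average ranks (ties get the mean of
   the ranks they span),
3. the correlation is computed between those ranks and the *raw* marker
   scores 0/1/2 (a both-ranked classical Spearman variant is available
   behind a flag),
4. significance comes from the two-tailed t-test on the correlation
   coefficient, Bonferroni-corrected by the marker family size.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = ("BE", "SF", "EF")
ALPHA = 0.05


@dataclass(frozen=True)
class KSResult:
    trait_id: str
    statistic: float
    p_value: float
    normal: bool  # not rejected at alpha = 0.05


class ZeroVarianceError(ValueError):
    """A correlation is undefined because one vector is constant."""


def rank_average(values: Sequence[float]) -> np.ndarray:
    """Average ranks of the non-missing values; NaN kept in place.

    Ties receive the mean of the ranks they span, so the rank sum over n
    non-missing values is always n(n+1)/2.
    """
    v = np.asarray(values, dtype=float)
    mask = ~np.isnan(v)
    if not mask.any():
        raise ValueError("all values missing")
    out = np.full(v.shape, np.nan)
    out[mask] = stats.rankdata(v[mask], method="average")
    return out


def marker_trait_correlation(
    ranks: Sequence[float],
    scores: Sequence[float],
    both_ranked: bool = False,
) -> tuple[float, int]:
    """Product-moment correlation of phenotype ranks against raw 0/1/2 scores.

    Pairwise-complete over non-missing entries; returns ``(rho, n_used)``.
    With ``both_ranked=True`` the scores are ranked too (classical Spearman).
    """
    r = np.asarray(ranks, dtype=float)
    s = np.asarray(scores, dtype=float)
    if r.shape != s.shape:
        raise ValueError("ranks and scores differ in length")
    mask = ~np.isnan(r) & ~np.isnan(s)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    rr, ss = r[mask], s[mask]
    if both_ranked:
        ss = stats.rankdata(ss, method="average")
    # re-rank the phenotype over the complete pairs so missing scores do not
    # leave holes in the rank scale
    rr = stats.rankdata(rr, method="average")
    if np.ptp(rr) == 0 or np.ptp(ss) == 0:
        raise ZeroVarianceError("constant ranks or scores")
    rho = float(np.corrcoef(rr, ss)[0, 1])
    return rho, n


def corr_pvalue(rho: float, n: int) -> float:
    """Two-tailed t-test p-value for a correlation coefficient.

    ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees of freedom.  A
    perfect |rho| = 1 is reported as the smallest positive normal float.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(rho) > 1 + 1e-12:
        raise ValueError("|rho| > 1")
    if abs(rho) >= 1:
        return sys.float_info.min
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: ``min(1, m * p_raw)``."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p_raw)


def ks_normality(values: Sequence[float], trait_id: str = "") -> KSResult:
    """One-sample KS test against a normal with the sample mean and SD.

    Because the parameters are estimated from the same data the asymptotic
    p-value is conservative (a Lilliefors-type correction would be more
    powerful); with the gross bimodality of phenology panels this is
    immaterial, and the conservative direction is documented.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 5:
        raise ValueError("need >= 5 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    d, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return KSResult(trait_id, float(d), float(p), normal=p > ALPHA)


# ---------------------------------------------------------------------------
# panel-level scans
# ---------------------------------------------------------------------------

def trait_means(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-line replicate means from a long phenotype table.

    Expects columns ``line_id, trait, year, replicate, days``; returns a
    frame indexed by line_id with one ``(trait, year)`` column per panel.
    """
    required = {"line_id", "trait", "year", "days"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    wide = pheno.pivot_table(
        index="line_id", columns=["trait", "year"], values="days", aggfunc="mean"
    )
    # round far below the recording precision (0.1 day) so that rank order is
    # independent of floating-point summation order
    return wide.round(6)


def association_scan(
    genotypes: pd.DataFrame,
    pheno: pd.DataFrame,
    family: str = "all",
    marker_genes: Mapping[str, str] | None = None,
    alpha: float = ALPHA,
    both_ranked: bool = False,
) -> pd.DataFrame:
    """Scan every marker x trait x year combination.

    ``genotypes``: lines x markers frame of 0/1/2/NaN scores.  ``pheno``:
    long table (line_id, trait, year, replicate, days).  ``family`` sets the
    Bonferroni family size: ``"all"`` counts every marker in the run,
    ``"per-gene"`` counts markers of the same gene (requires
    ``marker_genes``).  Returns a tidy frame with rho, n, raw and adjusted p
    and a significance flag at adjusted p <= alpha.
    """
    means = trait_means(pheno)
    shared = genotypes.index.intersection(means.index)
    if len(shared) == 0:
        raise ValueError("no overlapping lines between genotypes and phenotypes")
    geno = genotypes.loc[shared]
    means = means.loc[shared]

    if family == "all":
        fam_size = {m: genotypes.shape[1] for m in genotypes.columns}
    elif family == "per-gene":
        if marker_genes is None:
            raise ValueError("per-gene family needs a marker -> gene mapping")
        counts: dict[str, int] = {}
        for m in genotypes.columns:
            g = marker_genes[m]
            counts[g] = counts.get(g, 0) + 1
        fam_size = {m: counts[marker_genes[m]] for m in genotypes.columns}
    else:
        raise ValueError(f"unknown family policy {family!r}")

    rows = []
    for trait, year in means.columns:
        values = means[(trait, year)].to_numpy(dtype=float)
        ranks = np.full(values.shape, np.nan)
        ok = ~np.isnan(values)
        if ok.sum() >= 1:
            ranks[ok] = stats.rankdata(values[ok], method="average")
        for m in geno.columns:
            scores = geno[m].to_numpy(dtype=float)
            note = ""
            try:
                rho, n = marker_trait_correlation(ranks, scores, both_ranked)
                p_raw = corr_pvalue(rho, n)
            except ZeroVarianceError:
                rho, p_raw = np.nan, np.nan
                n = int((~np.isnan(ranks) & ~np.isnan(scores)).sum())
                note = "zero_variance"
            except ValueError:
                rho, p_raw, n = np.nan, np.nan, 0
                note = "insufficient_data"
            m_fam = fam_size[m]
            p_adj = bonferroni(p_raw, m_fam) if not np.isnan(p_raw) else np.nan
            rows.append(
                {
                    "marker_id": m,
                    "trait": trait,
                    "year": year,
                    "rho": rho,
                    "n_used": n,
                    "p_raw": p_raw,
                    "family_size": m_fam,
                    "p_adj": p_adj,
                    "significant": bool(p_adj <= alpha) if not np.isnan(p_raw) else False,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


def between_year_correlation(pheno: pd.DataFrame) -> dict[str, float]:
    """Spearman correlation of per-line trait means between two years."""
    means = trait_means(pheno)
    years = sorted({y for _, y in means.columns})
    if len(years) != 2:
        raise ValueError(f"expected exactly 2 years, found {years}")
    y1, y2 = years
    out = {}
    for trait in sorted({t for t, _ in means.columns}):
        a = means[(trait, y1)]
        b = means[(trait, y2)]
        mask = a.notna() & b.notna()
        if mask.sum() < 3:
            raise ValueError(f"trait {trait}: fewer than 3 shared lines")
        rho, _ = stats.spearmanr(a[mask], b[mask])
        out[trait] = float(rho)
    return out


def allele_phenotype_table(
    genotypes: pd.DataFrame,
    pheno: pd.DataFrame,
    trait: str = "BE",
    year: str | int | None = None,
) -> pd.DataFrame:
    """Lines sorted by a trait mean with their marker scores alongside — the
    plain-text analogue of an allele-by-phenotype heatmap."""
    means = trait_means(pheno)
    cols = [c for c in means.columns if c[0] == trait and (year is None or c[1] == year)]
    if not cols:
        raise ValueError(f"no phenotype panel for trait {trait!r} year {year!r}")
    order = means[cols].mean(axis=1).sort_values()
    out = genotypes.reindex(order.index).copy()
    out.insert(0, f"{trait}_mean_days", order.round(1))
    return out
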