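"""Diversity and differentiation statistics for survivor cohorts.

Per-sample observed/expected heterozygosity with rank-sum group
comparisons, windowed nucleotide diversity, rarefied allelic richness,
PCA on mean-imputed dosages, and the Weir-Cockerham (1984) two-population
FST estimator with a bootstrap-over-loci significance test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def _ranksum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (not ties and max(len(x), len(y)) <= 25) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------


def heterozygosity(
    gm: GenotypeMatrix,
    control_group: str,
    treatment_groups: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample Ho/He and per-pair rank-sum comparisons with BH adjustment.

    Ho is the heterozygous fraction of a sample's non-missing calls.  He is
    the mean of 2*p*(1-p) over that sample's non-missing loci, with p the
    alternate-allele frequency in the full cohort.  Samples with zero calls
    are flagged (NaN) and excluded from tests.
    """
    called = gm.dosage != MISSING
    n_called = called.sum(axis=0)
    het = (gm.dosage == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    p = gm.allele_freq()
    exp_het_site = 2 * p * (1 - p)
    he = np.array(
        [
            np.nanmean(exp_het_site[called[:, j]]) if n_called[j] else np.nan
            for j in range(gm.n_samples)
        ]
    )
    records = pd.DataFrame(
        {
            "sample": gm.samples,
            "group": gm.sample_groups(),
            "Ho": ho,
            "He": he,
            "n_called": n_called,
        }
    )
    rows = []
    for stat in ("Ho", "He"):
        ctrl = records.loc[records["group"] == control_group, stat].dropna()
        for grp in treatment_groups:
            trt = records.loc[records["group"] == grp, stat].dropna()
            rows.append(
                {
                    "statistic": stat,
                    "comparison": f"{grp}_vs_{control_group}",
                    "p": _ranksum(trt, ctrl),
                }
            )
    comparisons = pd.DataFrame(rows, columns=["statistic", "comparison", "p"])
    comparisons["fdr"] = np.nan
    for stat in ("Ho", "He"):
        mask = comparisons["statistic"] == stat
        if mask.any():
            comparisons.loc[mask, "fdr"] = multipletests(
                comparisons.loc[mask, "p"], method="fdr_bh"
            )[1]
    return records, comparisons


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def site_pi(gm: GenotypeMatrix, group: str | None = None) -> np.ndarray:
    """Per-site nucleotide diversity from allele counts.

    pi = c_ref * c_alt / C(c_total, 2): the mean pairwise difference over
    all haplotype pairs at the site.  NaN when fewer than two called
    alleles.
    """
    alt, total = gm.allele_counts(group)
    ref = total - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pairs = total * (total - 1) / 2
        return np.where(total >= 2, ref * alt / np.maximum(pairs, 1), np.nan)


def windowed_pi(
    gm: GenotypeMatrix,
    group: str | None = None,
    window_bp: int = 5000,
) -> pd.DataFrame:
    """Nucleotide diversity per bp in non-overlapping tiles.

    Window Pi = sum of site pi over the tile / window_bp.  Tiles with no
    variant are omitted (they carry no information to distinguish
    monomorphism from missing data in a variants-only input).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    pi = site_pi(gm, group)
    start = ((gm.pos - 1) // window_bp) * window_bp
    df = pd.DataFrame(
        {"chrom": gm.chrom, "start": start, "pi_site": pi, "defined": ~np.isnan(pi)}
    )
    grouped = df.groupby(["chrom", "start"], sort=True)
    out = grouped.agg(
        pi_sum=("pi_site", lambda v: np.nansum(v)),
        n_variants=("pi_site", "size"),
        n_defined=("defined", "sum"),
    ).reset_index()
    out["end"] = out["start"] + window_bp
    out["pi"] = out["pi_sum"] / window_bp
    return out[["chrom", "start", "end", "pi", "n_variants", "n_defined"]]


# ---------------------------------------------------------------------------
# allelic richness
# ---------------------------------------------------------------------------


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(gm: GenotypeMatrix, groups: list[str]) -> pd.DataFrame:
    """Rarefied allelic richness per group (El Mousadik & Petit rarefaction).

    At each locus the rarefaction depth g is the smallest non-missing allele
    count across groups; loci with g < 2 are skipped.  Per locus and group,
    Ar = sum over alleles of [1 - C(N - N_i, g) / C(N, g)]; the group value
    is the mean over usable loci.
    """
    counts = {}
    for grp in groups:
        alt, total = gm.allele_counts(grp)
        counts[grp] = (alt, total)
    totals = np.vstack([counts[g][1] for g in groups])
    g_depth = totals.min(axis=0)
    usable = g_depth >= 2
    if not usable.any():
        return pd.DataFrame({"group": groups, "Ar": np.nan, "n_loci": 0})
    rows = []
    gd = g_depth[usable].astype(float)
    for grp in groups:
        alt, total = counts[grp]
        alt = alt[usable].astype(float)
        total = total[usable].astype(float)
        ar = np.zeros(len(gd))
        for allele_count in (alt, total - alt):
            with np.errstate(invalid="ignore"):
                ratio = np.where(
                    total - allele_count >= gd,
                    np.exp(_log_comb(total - allele_count, gd) - _log_comb(total, gd)),
                    0.0,
                )
            ar += 1.0 - ratio
        rows.append({"group": grp, "Ar": float(np.mean(ar)), "n_loci": int(usable.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca(gm: GenotypeMatrix, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of mean-imputed, centered dosages (plain covariance, no scaling).

    Returns (coordinates with sample/group columns, explained-variance
    fractions).  All-missing variants are dropped with a warning.
    """
    if gm.n_samples < 2 or gm.n_variants < 2:
        raise ValueError("PCA requires at least 2 samples and 2 variants")
    dosage = gm.dosage.astype(float)
    dosage[gm.dosage == MISSING] = np.nan
    all_missing = np.isnan(dosage).all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d all-missing variants before PCA", all_missing.sum())
        dosage = dosage[~all_missing]
    mean = np.nanmean(dosage, axis=1, keepdims=True)
    centered = np.where(np.isnan(dosage), 0.0, dosage - mean)
    gram = centered.T @ centered
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    k = min(n_components, len(eigval))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    total = eigval.sum()
    explained = eigval[:k] / total if total > 0 else np.zeros(k)
    df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "group", gm.sample_groups())
    df.insert(0, "sample", gm.samples)
    return df, explained


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------


def wc_components(
    gm: GenotypeMatrix, group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components a, b, c.

    Two-population diploid estimator with heterozygosity terms; loci where
    either group has no called genotype get NaN components.
    """
    comps = []
    for grp in (group_a, group_b):
        dos = gm.dosage[:, gm.group_mask(grp)]
        called = dos != MISSING
        n = called.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, dos, 0).sum(axis=1) / np.maximum(2 * n, 1)
            h = (dos == 1).sum(axis=1) / np.maximum(n, 1)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def per_locus_fst(gm: GenotypeMatrix, group_a: str, group_b: str) -> np.ndarray:
    """Per-locus theta = a / (a+b+c); NaN where undefined (e.g. monomorphic)."""
    a, b, c = wc_components(gm, group_a, group_b)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.abs(denom) > 0, a / denom, np.nan)


@dataclass
class FstResult:
    pair: tuple[str, str]
    fst: float
    p: float
    n_boot: int
    n_loci: int
    boot_distribution: np.ndarray


def wc_fst(
    gm: GenotypeMatrix,
    group_a: str,
    group_b: str,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> FstResult:
    """Multi-locus Weir-Cockerham theta with bootstrap-over-loci significance.

    theta = sum(a) / sum(a+b+c) over loci with defined components; p is the
    fraction of bootstrap resamples (loci drawn with replacement) whose
    theta is <= 0, a one-sided test against "no differentiation".  Negative
    theta is reported as computed.
    """
    for grp in (group_a, group_b):
        if gm.group_mask(grp).sum() < 2:
            raise ValueError(f"group {grp} has fewer than 2 samples")
    a, b, c = wc_components(gm, group_a, group_b)
    ok = np.isfinite(a + b + c)
    a, bc = a[ok], (a + b + c)[ok]
    if len(a) == 0 or bc.sum() == 0:
        return FstResult((group_a, group_b), np.nan, np.nan, n_boot, 0, np.array([]))
    theta = float(a.sum() / bc.sum())
    rng = rng or np.random.default_rng()
    idx = rng.integers(0, len(a), size=(n_boot, len(a)))
    boot_num = a[idx].sum(axis=1)
    boot_den = bc[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        boot = np.where(boot_den != 0, boot_num / np.where(boot_den != 0, boot_den, 1), np.nan)
    p = float(np.mean(boot[~np.isnan(boot)] <= 0)) if np.isfinite(boot).any() else np.nan
    return FstResult((group_a, group_b), theta, p, n_boot, int(ok.sum()), boot)


def windowed_fst(
    gm: GenotypeMatrix,
    group_a: str,
    group_b: str,
    window_bp: int = 5000,
) -> pd.DataFrame:
    """Ratio-of-sums Weir-Cockerham theta in non-overlapping tiles."""
    a, b, c = wc_components(gm, group_a, group_b)
    denom = a + b + c
    start = ((gm.pos - 1) // window_bp) * window_bp
    df = pd.DataFrame(
        {
            "chrom": gm.chrom,
            "start": start,
            "a": np.where(np.isfinite(denom), a, 0.0),
            "abc": np.where(np.isfinite(denom), denom, 0.0),
            "defined": np.isfinite(denom),
        }
    )
    out = (
        df.groupby(["chrom", "start"], sort=True)
        .agg(a_sum=("a", "sum"), abc_sum=("abc", "sum"), n_defined=("defined", "sum"))
        .reset_index()
    )
    out["end"] = out["start"] + window_bp
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fst"] = np.where(
            (out["n_defined"] > 0) & (out["abc_sum"] != 0),
            out["a_sum"] / out["abc_sum"].where(out["abc_sum"] != 0, 1),
            np.nan,
        )
    return out[["chrom", "start", "end", "fst", "n_defined"]]
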