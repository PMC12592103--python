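"""Composite selection scan and dual-criteria focal-SNP designation.

Per treatment-vs-control comparison: windowed Weir-Cockerham FST is
Z-standardized across windows (ZFst) and plotted against the log2 ratio of
control to treatment nucleotide diversity; candidate intervals are windows
in the top tail of ZFst with a positive diversity ratio; intervals shared
by at least ``min_shared`` comparisons are robust.  Per-SNP FST outliers
(top tail of the empirical distribution) whose major-allele frequency
change falls outside the empirical 5th-95th percentile band of
fourfold-degenerate (neutral) sites, and which lie inside a robust
interval, are designated focal SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .popgen import per_locus_fst, windowed_fst, windowed_pi

logger = logging.getLogger(__name__)

WINDOW_BP = 5000


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------


def zfst_standardize(fst: np.ndarray) -> np.ndarray:
    """Z-scores of window FST: (fst - mean) / sample sd over defined windows.

    NaN windows stay NaN; a zero-variance vector maps to all zeros.
    """
    fst = np.asarray(fst, dtype=float)
    defined = np.isfinite(fst)
    if defined.sum() < 2:
        raise ValueError("ZFst needs at least 2 windows with defined FST")
    mean = fst[defined].mean()
    sd = fst[defined].std(ddof=1)
    z = np.full_like(fst, np.nan)
    z[defined] = 0.0 if sd == 0 else (fst[defined] - mean) / sd
    return z


def window_stats(
    gm: GenotypeMatrix,
    control_group: str,
    treatment_group: str,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Per-window FST, ZFst, per-group Pi and log2(Pi_control / Pi_treatment).

    Only windows where FST is defined and both groups have at least one
    variant with a defined Pi enter the volcano; excluded windows are kept
    with NaN statistics so callers can see what was dropped.
    """
    fst = windowed_fst(gm, control_group, treatment_group, window_bp)
    pi_c = windowed_pi(gm, control_group, window_bp).rename(columns={"pi": "pi_control"})
    pi_t = windowed_pi(gm, treatment_group, window_bp).rename(columns={"pi": "pi_treatment"})
    merged = fst.merge(
        pi_c[["chrom", "start", "pi_control", "n_defined"]].rename(
            columns={"n_defined": "n_pi_control"}
        ),
        on=["chrom", "start"],
        how="left",
    ).merge(
        pi_t[["chrom", "start", "pi_treatment", "n_defined"]].rename(
            columns={"n_defined": "n_pi_treatment"}
        ),
        on=["chrom", "start"],
        how="left",
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = merged["pi_control"] / merged["pi_treatment"]
        merged["log2_ratio"] = np.where(ratio > 0, np.log2(ratio.where(ratio > 0, 1)), np.nan)
    usable = (
        np.isfinite(merged["fst"])
        & (merged["n_pi_control"].fillna(0) > 0)
        & (merged["n_pi_treatment"].fillna(0) > 0)
        & np.isfinite(merged["log2_ratio"])
    )
    merged["included"] = usable.to_numpy()
    merged["zfst"] = np.nan
    if usable.sum() >= 2:
        merged.loc[usable, "zfst"] = zfst_standardize(
            merged.loc[usable, "fst"].to_numpy()
        )
    merged["comparison"] = treatment_group
    return merged


def css_outlier_intervals(
    windows: pd.DataFrame, top_fraction: float = 0.05
) -> pd.DataFrame:
    """Flag composite outlier windows for one comparison.

    ``outlier`` (selection in the treatment): ZFst at or above the
    (1 - top_fraction) empirical quantile AND log2_ratio > 0.  Ties at the
    quantile are included.  ``outlier_control`` marks the control-side
    analogue (top ZFst with negative ratio); it is reported for the volcano
    but never feeds focal designation.
    """
    out = windows.copy()
    included = out["included"].to_numpy(bool)
    out["outlier"] = False
    out["outlier_control"] = False
    if included.sum() == 0:
        logger.warning("no usable windows for CSS outlier detection")
        return out
    z = out.loc[included, "zfst"].to_numpy()
    threshold = np.quantile(z, 1 - top_fraction)
    top = included & (out["zfst"] >= threshold)
    out.loc[top & (out["log2_ratio"] > 0), "outlier"] = True
    out.loc[top & (out["log2_ratio"] < 0), "outlier_control"] = True
    return out


def shared_intervals(
    flagged: dict[str, pd.DataFrame], min_shared: int = 2
) -> pd.DataFrame:
    """Combine per-comparison outlier flags; keep windows shared >= min_shared.

    Returns one row per window that is an outlier in any comparison, with a
    boolean column per comparison, ``shared_count`` and ``robust``.
    """
    if len(flagged) < 2:
        raise ValueError("shared intervals need at least 2 comparisons")
    frames = []
    for name, df in flagged.items():
        sub = df.loc[df["outlier"], ["chrom", "start", "end"]].copy()
        sub[name] = True
        frames.append(sub.set_index(["chrom", "start", "end"]))
    merged = pd.concat(frames, axis=1)
    merged = merged.where(merged.notna(), False).astype(bool)
    merged["shared_count"] = merged.sum(axis=1)
    merged["robust"] = merged["shared_count"] >= min_shared
    return merged.reset_index()


# ---------------------------------------------------------------------------
# per-SNP criteria
# ---------------------------------------------------------------------------


def per_snp_fst_outliers(fst: np.ndarray, top_fraction: float = 0.05) -> tuple[np.ndarray, float]:
    """Mask of SNPs at or above the (1 - top_fraction) empirical FST quantile.

    NaN FST never qualifies.  Returns (mask, threshold).  With an all-equal
    FST vector every SNP ties at the threshold and all are selected (logged).
    """
    fst = np.asarray(fst, dtype=float)
    defined = np.isfinite(fst)
    if defined.sum() == 0:
        return np.zeros(len(fst), dtype=bool), np.nan
    threshold = float(np.quantile(fst[defined], 1 - top_fraction))
    mask = defined & (fst >= threshold)
    if mask.sum() == defined.sum() and defined.sum() > 1:
        logger.warning("all SNPs tie at the FST outlier threshold; all selected")
    return mask, threshold


def delta_af(
    gm: GenotypeMatrix, control_group: str, treatment_group: str
) -> np.ndarray:
    """Major-allele frequency change, treatment minus control.

    The major allele is fixed in the control survivors (ties at 0.5 resolve
    to the reference allele), so a decline of the control-major allele in
    the treatment yields a negative value.
    """
    f_control = gm.allele_freq(control_group)
    f_treatment = gm.allele_freq(treatment_group)
    sign = np.where(f_control > 0.5, 1.0, -1.0)  # +1 when ALT is control-major
    return sign * (f_treatment - f_control)


@dataclass
class NeutralNull:
    """Empirical drift null from fourfold-degenerate sites outside CSS intervals."""

    comparison: str
    delta: np.ndarray
    q05: float
    q95: float
    median: float
    n_sites: int

    @property
    def central_width(self) -> float:
        return self.q95 - self.q05


def build_neutral_null(
    delta: np.ndarray,
    is_4dtv: np.ndarray,
    in_css: np.ndarray,
    comparison: str = "",
) -> NeutralNull:
    """Null band of allele-frequency change at neutral sites.

    Qualifying sites are 4DTV variants outside CSS intervals with a defined
    frequency change; the 5th and 95th empirical percentiles of their delta
    distribution bound the band.  An empty CSS set leaves every 4DTV site
    qualifying.  Fewer than 50 qualifying sites triggers a warning
    (thresholds unstable).
    """
    qualifying = np.asarray(is_4dtv, bool) & ~np.asarray(in_css, bool) & np.isfinite(delta)
    values = np.asarray(delta, float)[qualifying]
    if len(values) < 50:
        logger.warning(
            "only %d qualifying 4DTV sites for %s; null thresholds unstable",
            len(values),
            comparison,
        )
    if len(values) == 0:
        return NeutralNull(comparison, values, np.nan, np.nan, np.nan, 0)
    return NeutralNull(
        comparison,
        values,
        float(np.quantile(values, 0.05)),
        float(np.quantile(values, 0.95)),
        float(np.median(values)),
        len(values),
    )


def snps_in_intervals(
    gm: GenotypeMatrix, intervals: pd.DataFrame, window_bp: int = WINDOW_BP
) -> np.ndarray:
    """Boolean mask of variants inside the given window intervals."""
    keys = set(zip(intervals["chrom"], intervals["start"]))
    start = ((gm.pos - 1) // window_bp) * window_bp
    return np.array(
        [(c, s) in keys for c, s in zip(gm.chrom, start)], dtype=bool
    )


def designate_focal(
    gm: GenotypeMatrix,
    control_group: str,
    treatment_group: str,
    fst: np.ndarray,
    null: NeutralNull,
    robust_mask: np.ndarray,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Apply the dual criteria plus interval membership for one comparison.

    focal = FST at or above the top-tail threshold AND delta outside the
    open null band (strict inequalities: a value exactly at a percentile is
    not "exceeding") AND position inside a robust CSS interval.
    """
    passes_fst, threshold = per_snp_fst_outliers(fst, top_fraction)
    delta = delta_af(gm, control_group, treatment_group)
    passes_null = np.isfinite(delta) & (
        (delta > null.q95) | (delta < null.q05)
    )
    with np.errstate(invalid="ignore"):
        ranks = pd.Series(fst).rank(pct=True).to_numpy()
    return pd.DataFrame(
        {
            "id": gm.ids,
            "chrom": gm.chrom,
            "pos": gm.pos,
            "comparison": treatment_group,
            "fst": fst,
            "fst_percentile": ranks,
            "fst_threshold": threshold,
            "delta_af": delta,
            "passes_fst": passes_fst,
            "passes_null": passes_null,
            "in_css_interval": np.asarray(robust_mask, bool),
            "focal": passes_fst & passes_null & np.asarray(robust_mask, bool),
        }
    )


# ---------------------------------------------------------------------------
# full scan across comparisons
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    windows: dict[str, pd.DataFrame]       # per comparison, with outlier flags
    shared: pd.DataFrame                   # interval sharing table
    nulls: dict[str, NeutralNull]
    snp_tables: dict[str, pd.DataFrame]    # per comparison designate_focal output
    focal: pd.DataFrame                    # union over comparisons (provenance kept)

    @property
    def focal_ids(self) -> set[str]:
        return set(self.focal["id"])


def run_scan(
    gm: GenotypeMatrix,
    control_group: str,
    treatment_groups: list[str],
    is_4dtv: np.ndarray,
    window_bp: int = WINDOW_BP,
    top_fraction: float = 0.05,
    min_shared: int = 2,
) -> ScanResult:
    """The composite scan end-to-end for one filtered cohort matrix."""
    windows: dict[str, pd.DataFrame] = {}
    for grp in treatment_groups:
        windows[grp] = css_outlier_intervals(
            window_stats(gm, control_group, grp, window_bp), top_fraction
        )
    shared = shared_intervals(windows, min_shared)
    robust = shared[shared["robust"]]
    robust_mask = snps_in_intervals(gm, robust, window_bp)
    nulls: dict[str, NeutralNull] = {}
    snp_tables: dict[str, pd.DataFrame] = {}
    for grp in treatment_groups:
        fst = per_locus_fst(gm, control_group, grp)
        delta = delta_af(gm, control_group, grp)
        css_mask = snps_in_intervals(
            gm, shared, window_bp
        )  # any flagged interval excludes a 4DTV site from the null
        nulls[grp] = build_neutral_null(delta, is_4dtv, css_mask, comparison=grp)
        snp_tables[grp] = designate_focal(
            gm, control_group, grp, fst, nulls[grp], robust_mask, top_fraction
        )
    focal_frames = [t[t["focal"]] for t in snp_tables.values()]
    focal = (
        pd.concat(focal_frames, ignore_index=True)
        if focal_frames
        else pd.DataFrame()
    )
    return ScanResult(windows, shared, nulls, snp_tables, focal)
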