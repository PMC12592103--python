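"""Post-calling variant filter chain and LD pruning.

Genotype-level masking (GQ, depth) is applied before site-level filters
(biallelic SNP, missingness, MAF), matching the order of the standard
VCFtools/PLINK toolchain where GQ and DP act per call.  LD pruning slides a
fixed-size variant window and greedily removes the lower-MAF member of any
dosage pair with squared Pearson correlation above the threshold
(indep-pairwise semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_ACGT = {"A", "C", "G", "T"}


@dataclass
class FilterConfig:
    maf_min: float = 0.05
    missing_max: float = 0.30
    gq_min: int = 10          # calls with GQ <= gq_min are masked
    depth_min: int = 10       # calls outside [depth_min, depth_max] are masked
    depth_max: int = 100
    ld_window: int = 50       # variants per pruning window
    ld_step: int = 10         # window advance, in variants
    ld_r2: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must not exceed depth_max")


def _is_biallelic_snp(ref: str, alt: str) -> bool:
    return ref in _ACGT and alt in _ACGT


def filter_variants(
    gm: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, dict[str, int], pd.DataFrame]:
    """Apply the QC chain; returns (filtered matrix, drop tally, sample report).

    Order: (1) mask calls failing GQ or depth bounds, (2) drop non-biallelic
    sites, (3) drop sites with missingness above ``missing_max`` (computed
    after masking), (4) drop sites with MAF below ``maf_min`` on the
    remaining calls.  The tally records the first rule that removed each
    site.  The sample report carries per-sample missingness for inspection
    (site-level missingness is the filter; the per-sample view is
    informational).
    """
    config = config or FilterConfig()
    dosage = gm.dosage.copy()
    if gm.gq is not None:
        dosage[gm.gq <= config.gq_min] = MISSING
    if gm.dp is not None:
        dosage[(gm.dp < config.depth_min) | (gm.dp > config.depth_max)] = MISSING

    n_var, n_samp = dosage.shape
    biallelic = np.array(
        [_is_biallelic_snp(r, a) for r, a in zip(gm.ref, gm.alt)], dtype=bool
    )
    called = dosage != MISSING
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        miss_rate = 1.0 - n_called / max(n_samp, 1)
        alt_count = np.where(called, dosage, 0).sum(axis=1)
        freq = np.where(n_called > 0, alt_count / np.maximum(2 * n_called, 1), np.nan)
    maf = np.minimum(freq, 1 - freq)

    drop_multi = ~biallelic
    drop_missing = biallelic & (miss_rate > config.missing_max)
    drop_maf = biallelic & ~drop_missing & ((maf < config.maf_min) | np.isnan(maf))
    keep = ~(drop_multi | drop_missing | drop_maf)

    tally = {
        "multiallelic": int(drop_multi.sum()),
        "missing": int(drop_missing.sum()),
        "maf": int(drop_maf.sum()),
        "retained": int(keep.sum()),
        "input": n_var,
    }

    out = GenotypeMatrix(
        samples=list(gm.samples),
        chrom=gm.chrom[keep],
        pos=gm.pos[keep],
        ref=gm.ref[keep],
        alt=gm.alt[keep],
        dosage=dosage[keep],
        groups=dict(gm.groups),
        gq=None if gm.gq is None else gm.gq[keep],
        dp=None if gm.dp is None else gm.dp[keep],
    )
    sample_report = pd.DataFrame(
        {
            "sample": gm.samples,
            "missing_rate": 1.0 - (dosage[keep] != MISSING).mean(axis=0)
            if keep.any()
            else np.ones(n_samp),
        }
    )
    return out, tally, sample_report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(dosage: np.ndarray, min_obs: int = 5) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation of dosage rows.

    Pairs with fewer than ``min_obs`` complete observations get NaN (skipped
    by the pruner).
    """
    valid = (dosage != MISSING).astype(np.float64)
    x = np.where(dosage == MISSING, 0, dosage).astype(np.float64)
    n = valid @ valid.T
    sx = x @ valid.T
    sxx = (x * x) @ valid.T
    sxy = x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        denom = varx * varx.T
        r2 = np.where(denom > 0, cov**2 / np.where(denom > 0, denom, 1), np.nan)
    r2[n < min_obs] = np.nan
    return r2


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """Greedy indep-pairwise pruning; returns a boolean keep mask.

    Windows of ``window`` variants advance by ``step`` within each
    chromosome.  Within a window, pairs are visited in position order; when
    both members are still retained and their r-squared exceeds the
    threshold, the lower-MAF member is removed (tie: the later position).
    Passes repeat with windows rebuilt over the surviving variants until no
    removal occurs, which makes pruning idempotent.
    """
    if window < step:
        raise ValueError("window must be at least step")
    keep = np.ones(gm.n_variants, dtype=bool)
    freq = gm.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    changed = True
    while changed:
        changed = False
        for chrom in pd.unique(gm.chrom):
            idx = np.nonzero((gm.chrom == chrom) & keep)[0]
            idx = idx[np.argsort(gm.pos[idx], kind="stable")]
            n = len(idx)
            starts = range(0, max(n - 1, 1), step) if n else []
            for start in starts:
                win = idx[start : start + window]
                win = win[keep[win]]
                if len(win) < 2:
                    continue
                r2 = _pairwise_r2(gm.dosage[win])
                exceed = np.triu(np.nan_to_num(r2, nan=0.0) > r2_threshold, k=1)
                if not exceed.any():
                    continue
                # row-major order over exceeding pairs = greedy position order
                for a, b in np.argwhere(exceed):
                    i, j = win[a], win[b]
                    if not (keep[i] and keep[j]):
                        continue
                    changed = True
                    if maf[i] < maf[j]:
                        keep[i] = False
                    else:  # equal MAF removes the later position
                        keep[j] = False
    return keep


def run_qc(
    gm: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, dict[str, int], pd.DataFrame]:
    """Filter chain followed by LD pruning; tally gains an ``ld_pruned`` entry."""
    config = config or FilterConfig()
    filtered, tally, sample_report = filter_variants(gm, config)
    keep = ld_prune(filtered, config.ld_window, config.ld_step, config.ld_r2)
    tally["ld_pruned"] = int((~keep).sum())
    tally["retained"] = int(keep.sum())
    return filtered.take_variants(np.nonzero(keep)[0]), tally, sample_report
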