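"""TPM normalization, differential expression, permutation null, genotype links.

The differential-expression decision rule is fold change > 2 together with
Benjamini-Hochberg adjusted p < 0.05, with the per-gene p from a two-sided
Wilcoxon rank-sum test on TPM (a deliberately simple, distribution-free
test; the experiment's inferential claim about the DEG count rests on the
label-permutation null, which is implemented exactly).  Fold change is
evaluated on group mean TPM with a pseudocount; medians are reported
alongside.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

PSEUDOCOUNT_TPM = 1.0


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-rate normalization to 1e6 per sample.

    ``counts`` is genes x samples; ``lengths`` gives effective gene length
    in bp.  A sample with zero total rate yields all-zero TPM (warned).
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all genes need a positive length")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    zero = total == 0
    if zero.any():
        logger.warning("samples with zero counts: %s", list(total.index[zero]))
        total = total.replace(0, np.nan)
    tpm = rate.div(total, axis=1) * 1e6
    return tpm.fillna(0.0)


def _ranksum_vector(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p for (genes x samples) blocks.

    Constant genes (all values identical across both groups) get p = 1.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = mannwhitneyu(x, y, alternative="two-sided", axis=1, method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.ptp(np.concatenate([x, y], axis=1), axis=1) == 0
    p[constant] = 1.0
    return np.clip(p, 0.0, 1.0)


def de_test(
    tpm: pd.DataFrame,
    groups: dict[str, str],
    control_group: str,
    treatment_group: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = PSEUDOCOUNT_TPM,
) -> pd.DataFrame:
    """Per-gene DE table between two groups of samples.

    log2fc = log2((mean TPM_treatment + pc) / (mean TPM_control + pc));
    significant requires |log2fc| > log2(fc_threshold) and BH-adjusted
    p < alpha.  Needs >= 3 samples per group.
    """
    labels = pd.Series({s: groups.get(s, "") for s in tpm.columns})
    ctrl_cols = labels.index[labels == control_group]
    trt_cols = labels.index[labels == treatment_group]
    if len(ctrl_cols) < 3 or len(trt_cols) < 3:
        raise ValueError("de_test needs at least 3 samples per group")
    ctrl = tpm[ctrl_cols].to_numpy(float)
    trt = tpm[trt_cols].to_numpy(float)
    p = _ranksum_vector(trt, ctrl)
    fdr = multipletests(p, method="fdr_bh")[1]
    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    significant = (np.abs(log2fc) > np.log2(fc_threshold)) & (fdr < alpha)
    return pd.DataFrame(
        {
            "gene_id": tpm.index,
            "mean_tpm_control": mean_c,
            "mean_tpm_treatment": mean_t,
            "median_tpm_control": np.median(ctrl, axis=1),
            "median_tpm_treatment": np.median(trt, axis=1),
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "significant": significant,
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    ).reset_index(drop=True)


def deg_count(
    tpm: pd.DataFrame,
    control_cols: np.ndarray,
    treatment_cols: np.ndarray,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = PSEUDOCOUNT_TPM,
) -> int:
    """DEG count under the decision rule for one column split (fast path)."""
    ctrl = tpm.to_numpy(float)[:, control_cols]
    trt = tpm.to_numpy(float)[:, treatment_cols]
    p = _ranksum_vector(trt, ctrl)
    fdr = multipletests(p, method="fdr_bh")[1]
    log2fc = np.log2((trt.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount))
    return int(((np.abs(log2fc) > np.log2(fc_threshold)) & (fdr < alpha)).sum())


def permutation_deg_null(
    tpm: pd.DataFrame,
    groups: dict[str, str],
    control_group: str,
    treatment_group: str,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> tuple[int, np.ndarray, float]:
    """Label-permutation null for the observed DEG count.

    Group labels are permuted preserving the (possibly unbalanced) group
    sizes; the DEG count is recomputed per permutation with the identical
    rule.  Returns (observed count, permuted counts, empirical p) with the
    add-one estimator p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = np.array([groups.get(s, "") for s in tpm.columns])
    cols = np.nonzero((labels == control_group) | (labels == treatment_group))[0]
    is_treatment = labels[cols] == treatment_group
    n_t = int(is_treatment.sum())
    observed = deg_count(tpm, cols[~is_treatment], cols[is_treatment], fc_threshold, alpha)
    perm_counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(cols)
        perm_counts[i] = deg_count(tpm, perm[n_t:], perm[:n_t], fc_threshold, alpha)
    p = (1 + int((perm_counts >= observed).sum())) / (n_perm + 1)
    return observed, perm_counts, float(p)


def link_genotype_expression(
    tpm: pd.DataFrame,
    gm: GenotypeMatrix,
    focal: pd.DataFrame,
    annotation: pd.DataFrame,
    control_group: str,
    treatment_groups: list[str],
    min_class_size: int = 3,
) -> pd.DataFrame:
    """Genotype-linked expression summaries for genes carrying focal SNPs.

    For each (focal SNP, assigned gene) pair: per-group frequencies of the
    control-major allele and of genotype classes, per-group median TPM, a
    rank-sum p comparing expression between pooled treatment and control,
    and a rank-sum p between the extreme genotype classes when both have at
    least ``min_class_size`` samples (otherwise skipped, group-level test
    still reported).
    """
    shared = [s for s in tpm.columns if s in gm.samples]
    if not shared:
        raise ValueError("expression and genotypes share no samples")
    sample_idx = {s: i for i, s in enumerate(gm.samples)}
    col = np.array([sample_idx[s] for s in shared])
    labels = np.array([gm.groups.get(s, "") for s in shared])
    gene_of = dict(zip(annotation["id"], annotation["gene_id"]))
    id_to_row = {vid: i for i, vid in enumerate(gm.ids)}
    is_ctrl = labels == control_group
    is_trt = np.isin(labels, treatment_groups)
    rows = []
    for vid in pd.unique(focal["id"]):
        gene = gene_of.get(vid)
        if gene is None or gene not in tpm.index:
            continue
        expr = tpm.loc[gene, shared].to_numpy(float)
        dos = gm.dosage[id_to_row[vid], col]
        called = dos != MISSING
        f_alt_ctrl = _af(dos[is_ctrl & called])
        major_is_alt = f_alt_ctrl > 0.5
        record = {
            "gene_id": gene,
            "snp_id": vid,
            "major_allele": "alt" if major_is_alt else "ref",
        }
        for name, mask in [("control", is_ctrl), ("treatment", is_trt)]:
            d = dos[mask & called]
            f_alt = _af(d)
            record[f"major_af_{name}"] = f_alt if major_is_alt else 1 - f_alt
            total = max(len(d), 1)
            for g in (0, 1, 2):
                record[f"geno{g}_freq_{name}"] = float((d == g).sum()) / total
            record[f"median_tpm_{name}"] = float(np.median(expr[mask]))
        record["group_p"] = float(
            mannwhitneyu(
                expr[is_trt], expr[is_ctrl], alternative="two-sided"
            ).pvalue
        )
        classes = [g for g in (0, 1, 2) if (called & (dos == g)).sum() >= min_class_size]
        if len(classes) >= 2:
            lo, hi = classes[0], classes[-1]
            record["genotype_p"] = float(
                mannwhitneyu(
                    expr[called & (dos == hi)],
                    expr[called & (dos == lo)],
                    alternative="two-sided",
                ).pvalue
            )
            record["genotype_classes"] = f"{lo}v{hi}"
        else:
            record["genotype_p"] = np.nan
            record["genotype_classes"] = ""
        rows.append(record)
    return pd.DataFrame(rows)


def _af(dosage: np.ndarray) -> float:
    return float(dosage.sum()) / (2 * len(dosage)) if len(dosage) else np.nan
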