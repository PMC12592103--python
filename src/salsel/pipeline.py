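"""End-to-end orchestration: QC -> diversity -> scan -> annotation -> expression.

Glues the stage modules together for one analysis cohort (control plus
treatment survivor groups), mirroring how the stages chain on real data:
the filtered, LD-pruned matrix feeds the diversity statistics and the
composite selection scan; focal SNPs are annotated against the gene models
and enrichment is run over the genes overlapping any analyzed SNP; the
expression stage links focal genotypes to TPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annotate, expression, popgen, scan
from .io import GeneModel, GenotypeMatrix
from .qc import FilterConfig, run_qc

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    matrix: GenotypeMatrix                  # analysis-ready (filtered, pruned)
    qc_tally: dict[str, int]
    sample_report: pd.DataFrame
    is_4dtv: np.ndarray
    scan: scan.ScanResult
    diversity: pd.DataFrame | None = None
    diversity_tests: pd.DataFrame | None = None
    allelic_richness: pd.DataFrame | None = None
    pca_coords: pd.DataFrame | None = None
    pca_explained: np.ndarray | None = None
    fst: pd.DataFrame | None = None
    focal_annotation: pd.DataFrame | None = None
    density: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    de: pd.DataFrame | None = None
    deg_observed: int | None = None
    deg_perm_p: float | None = None
    genotype_links: pd.DataFrame | None = None


def genes_with_snps(gm: GenotypeMatrix, genes: list[GeneModel]) -> set[str]:
    """Genes whose span overlaps at least one analyzed SNP."""
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom in pd.unique(gm.chrom):
        pos_by_chrom[chrom] = np.sort(gm.pos[gm.chrom == chrom])
    out = set()
    for g in genes:
        pos = pos_by_chrom.get(g.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, g.start + 1, side="left")
        if lo < len(pos) and pos[lo] <= g.end:
            out.add(g.id)
    return out


def run_pipeline(
    gm: GenotypeMatrix,
    genes: list[GeneModel],
    reference: dict[str, str],
    control_group: str = "CR",
    treatment_groups: list[str] | None = None,
    counts: pd.DataFrame | None = None,
    gene_lengths: pd.Series | None = None,
    gene2term: pd.DataFrame | None = None,
    filter_config: FilterConfig | None = None,
    window_bp: int = scan.WINDOW_BP,
    top_fraction: float = 0.05,
    min_shared: int = 2,
    n_boot: int = 1000,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    with_popgen: bool = True,
    with_annotation: bool = True,
    with_expression: bool = True,
) -> PipelineResult:
    """Run the analysis stages on one cohort matrix.

    ``gm`` may contain extra samples (e.g. the source population); only
    samples labeled with the control or a treatment group are analyzed.
    ``rng`` seeds the bootstrap and permutation draws.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    treatment_groups = treatment_groups or ["HC1", "HC2", "HC3"]
    analysis_groups = [control_group] + list(treatment_groups)
    in_analysis = np.isin(gm.sample_groups(), analysis_groups)
    cohort = gm.take_samples(in_analysis)

    filtered, tally, sample_report = run_qc(cohort, filter_config)
    four_sites = annotate.find_4dtv_sites(genes, reference)
    is_4dtv = annotate.fourfold_mask(filtered, four_sites)

    scan_result = scan.run_scan(
        filtered,
        control_group,
        list(treatment_groups),
        is_4dtv,
        window_bp=window_bp,
        top_fraction=top_fraction,
        min_shared=min_shared,
    )
    result = PipelineResult(
        matrix=filtered,
        qc_tally=tally,
        sample_report=sample_report,
        is_4dtv=is_4dtv,
        scan=scan_result,
    )

    if with_popgen:
        result.diversity, result.diversity_tests = popgen.heterozygosity(
            filtered, control_group, list(treatment_groups)
        )
        result.allelic_richness = popgen.allelic_richness(filtered, analysis_groups)
        result.pca_coords, result.pca_explained = popgen.pca(filtered)
        fst_rows = []
        for grp in treatment_groups:
            r = popgen.wc_fst(filtered, control_group, grp, n_boot=n_boot, rng=rng)
            fst_rows.append(
                {
                    "pair": f"{control_group}_vs_{grp}",
                    "fst": r.fst,
                    "p": r.p,
                    "n_boot": r.n_boot,
                    "n_loci": r.n_loci,
                }
            )
        result.fst = pd.DataFrame(fst_rows)

    if with_annotation:
        focal = scan_result.focal
        if len(focal):
            focal_ids = pd.unique(focal["id"])
            id_index = {vid: i for i, vid in enumerate(filtered.ids)}
            rows = np.array([id_index[v] for v in focal_ids])
            result.focal_annotation = annotate.annotate_snps(
                filtered.take_variants(rows), genes, reference
            )
            result.density = annotate.snp_density_report(result.focal_annotation)
            if gene2term is not None:
                universe = genes_with_snps(filtered, genes)
                focal_genes = {
                    g
                    for g in result.focal_annotation["gene_id"].dropna()
                    if g in universe
                }
                enr = annotate.enrich(focal_genes, universe, gene2term)
                if len(enr):
                    enr["salinity_keyword"] = annotate.keyword_filter(enr["term_name"])
                result.enrichment = enr
        else:
            result.focal_annotation = pd.DataFrame()
            result.density = pd.DataFrame()
            result.enrichment = pd.DataFrame()

    if with_expression and counts is not None and gene_lengths is not None:
        tpm = expression.tpm_normalize(counts, gene_lengths)
        pooled = {
            s: ("HC" if gm.groups.get(s) in treatment_groups else gm.groups.get(s, ""))
            for s in tpm.columns
        }
        result.de = expression.de_test(tpm, pooled, control_group, "HC")
        result.deg_observed, _, result.deg_perm_p = expression.permutation_deg_null(
            tpm, pooled, control_group, "HC", n_perm=n_perm, rng=rng
        )
        if (
            result.focal_annotation is not None
            and len(result.focal_annotation)
            and len(scan_result.focal)
        ):
            result.genotype_links = expression.link_genotype_expression(
                tpm,
                filtered,
                scan_result.focal,
                result.focal_annotation,
                control_group,
                list(treatment_groups),
            )
        else:
            result.genotype_links = pd.DataFrame()
    return result
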