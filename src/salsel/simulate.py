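"""Synthetic tank selection experiment: genotypes, mortality, expression.

Simulates the full study design end-to-end so every pipeline stage is
testable without external data: a single source population of diploid
individuals genotyped at biallelic SNPs (Hardy-Weinberg at sampled
ancestral frequencies), one control tank plus replicate treatment tanks,
genotype-dependent per-census mortality under a complementary-log-log
hazard, survivor sequencing cohorts, gene models on a multi-chromosome
reference with labeled fourfold-degenerate positions, and count-based
expression with genotype-linked mean shifts.

Truth (selected loci, their effects and expected survivor allele-frequency
shifts from a deterministic viability oracle, linked gene ids) is carried
alongside the outputs for recovery scoring.

A single seed drives everything through named substreams (genome /
population / experiment / expression / terms, spawned in that fixed order),
so identical seeds give byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import annotate
from .io import (
    MISSING,
    GeneModel,
    GenotypeMatrix,
    Transcript,
    write_counts_tsv,
    write_fasta,
    write_gene2term_tsv,
    write_gff3,
    write_groups_tsv,
    write_mortality_csv,
    write_truth_json,
    write_vcf,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def bell_hazard_shape(n_censuses: int = 10, peak: float = 5.5, width: float = 0.7) -> np.ndarray:
    """Unnormalized bell-shaped per-census hazard, peaking at ``peak`` (1-based).

    With 12-hour censuses the default peak between censuses 5 and 6 puts
    maximal mortality in the 48-72 h range; the narrow width keeps the
    early-census hazard negligible even for high-risk genotypes, so the
    realized mortality curve stays bell-shaped under strong selection.
    """
    t = np.arange(1, n_censuses + 1, dtype=float)
    return np.exp(-0.5 * ((t - peak) / width) ** 2)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the real design at desk scale: 200 individuals per tank,
    one control plus three treatment tanks, 12-hour censuses over 5 days,
    20,000 SNPs on 14 chromosomes, 20 loci with survival effects, and
    sequencing cohorts of 19 control / 10-11-10 treatment survivors.
    """

    n_tanks_treatment: int = 3
    n_per_tank: int = 200
    n_censuses: int = 10
    n_variants: int = 20_000
    n_selected: int = 20
    effect_size: float = 1.5           # log-hazard per alternate allele, all selected loci
    baseline_hazard: np.ndarray | None = None  # per-census rate; derived if None
    treatment_survival_target: float = 0.047   # calibrates baseline amplitude if derived
    control_hazard: float = 0.006      # per-census death probability in the control tank
    # genotype-independent transfer/handling mortality in the first treatment
    # censuses (acute stress shock); cancels out of the viability oracle
    shock_hazard: tuple[float, ...] = (0.05, 0.07)
    allele_freq_beta: tuple[float, float] = (0.6, 0.6)  # folded-spectrum shape
    allele_freq_bounds: tuple[float, float] = (0.05, 0.95)
    selected_freq_range: tuple[float, float] = (0.48, 0.52)
    frac_4dtv: float = 0.15
    n_genes: int = 200
    n_chromosomes: int = 14
    chrom_length: int = 800_000
    expr_effect: float = 2.0           # log2 mean shift per alternate allele, linked genes
    expr_dispersion: float = 0.2
    expr_base_mean_log: tuple[float, float] = (np.log(100.0), 1.0)
    libsize_range: tuple[float, float] = (0.5, 2.0)
    sample_noise_sd: float = 0.15      # log2-scale sd of gene-specific sample effects
    missing_rate: float = 0.01
    low_gq_rate: float = 0.03
    seq_cohort_control: int = 19
    seq_cohort_treatment: tuple[int, ...] = (10, 11, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_selected > self.n_variants:
            raise ValueError("n_selected cannot exceed n_variants")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if not 0 <= self.control_hazard <= 1:
            raise ValueError("control_hazard must be a probability")
        if self.baseline_hazard is not None:
            self.baseline_hazard = np.asarray(self.baseline_hazard, dtype=float)
            if len(self.baseline_hazard) != self.n_censuses:
                raise ValueError("baseline_hazard length must equal n_censuses")
            if (self.baseline_hazard < 0).any():
                raise ValueError("hazard rates must be non-negative")
        if len(self.seq_cohort_treatment) != self.n_tanks_treatment:
            raise ValueError("one sequencing cohort size per treatment tank")

    @property
    def n_individuals(self) -> int:
        return (1 + self.n_tanks_treatment) * self.n_per_tank

    @property
    def tank_names(self) -> list[str]:
        return ["CR"] + [f"HC{i + 1}" for i in range(self.n_tanks_treatment)]


@dataclass
class SimulatedTruth:
    selected: list[dict]            # id, beta, gene_id, ancestral_freq, expected_shift
    linked_genes: list[str]
    fourfold_ids: list[str]
    expected_treatment_survival: float

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "linked_genes": self.linked_genes,
            "fourfold_ids": self.fourfold_ids,
            "expected_treatment_survival": self.expected_treatment_survival,
        }

    @property
    def selected_ids(self) -> set[str]:
        return {s["id"] for s in self.selected}


# ---------------------------------------------------------------------------
# viability-selection oracles
# ---------------------------------------------------------------------------


def viability_recursion(
    p0: float, beta: float, hazard_rates: np.ndarray
) -> float:
    """Deterministic single-locus viability recursion; returns survivor freq.

    Genotype frequencies start at Hardy-Weinberg and are re-weighted each
    census by the genotype survival w_g = exp(-lambda_t * exp(beta * g));
    no mating occurs during the experiment so genotype (not allele)
    frequencies are propagated.
    """
    freqs = np.array([(1 - p0) ** 2, 2 * p0 * (1 - p0), p0**2])
    g = np.array([0.0, 1.0, 2.0])
    for lam in hazard_rates:
        w = np.exp(-lam * np.exp(beta * g))
        freqs = freqs * w
        freqs = freqs / freqs.sum()
    return float(freqs[2] + freqs[1] / 2)


def _burden_distribution(
    ps: np.ndarray, betas: np.ndarray, skip: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the log-hazard burden sum(beta * g) over loci.

    Dynamic programming over the three-point per-locus distributions; keys
    are rounded to collapse numerically identical sums (exact for a shared
    effect size, where the support is a lattice).
    """
    dist: dict[float, float] = {0.0: 1.0}
    for i, (p, b) in enumerate(zip(ps, betas)):
        if skip is not None and i == skip:
            continue
        probs = ((1 - p) ** 2, 2 * p * (1 - p), p**2)
        new: dict[float, float] = {}
        for x, px in dist.items():
            for g in range(3):
                key = round(x + b * g, 9)
                new[key] = new.get(key, 0.0) + px * probs[g]
        dist = new
    values = np.array(sorted(dist))
    return values, np.array([dist[v] for v in values])


def expected_survivor_shifts(
    ps: np.ndarray, betas: np.ndarray, total_hazard: float
) -> np.ndarray:
    """Expected survivor allele-frequency shift per selected locus.

    Whole-experiment survival given burden x is exp(-Lambda * e^x) with
    Lambda the summed per-census baseline; the marginal survivor frequency
    at locus l integrates over the exact background-burden distribution of
    the other loci.  Returns (survivor freq - ancestral freq), negative
    when the alternate allele raises the hazard.
    """
    shifts = np.empty(len(ps))
    for l, (p, b) in enumerate(zip(ps, betas)):
        bg_vals, bg_probs = _burden_distribution(ps, betas, skip=l)
        probs_g = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        surv_g = np.array(
            [
                float(np.sum(bg_probs * np.exp(-total_hazard * np.exp(b * g + bg_vals))))
                for g in range(3)
            ]
        )
        joint = probs_g * surv_g
        shifts[l] = (joint[2] + joint[1] / 2) / joint.sum() - p
    return shifts


def expected_survival(
    ps: np.ndarray, betas: np.ndarray, total_hazard: float
) -> float:
    vals, probs = _burden_distribution(ps, betas)
    return float(np.sum(probs * np.exp(-total_hazard * np.exp(vals))))


def calibrate_baseline(
    ps: np.ndarray,
    betas: np.ndarray,
    shape: np.ndarray,
    target_survival: float,
) -> np.ndarray:
    """Scale a hazard shape so expected whole-experiment survival hits target."""
    shape_sum = shape.sum()

    def f(log_scale: float) -> float:
        return expected_survival(ps, betas, np.exp(log_scale) * shape_sum) - target_survival

    log_scale = brentq(f, -60, 10, xtol=1e-10)
    return np.exp(log_scale) * shape


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------


_BASE_TRANSLATION = bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")


def _make_reference(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    return {
        f"chr{i + 1}": rng.integers(0, 4, size=cfg.chrom_length, dtype=np.uint8)
        .tobytes()
        .translate(_BASE_TRANSLATION)
        .decode()
        for i in range(cfg.n_chromosomes)
    }


def _make_gene(
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    rng: np.random.Generator,
) -> GeneModel:
    """Three-exon gene: exon1 = 5'UTR+CDS1, exon2 = CDS2, exon3 = CDS3+3'UTR."""
    utr5, utr3 = 150, 150
    cds_lens = [int(3 * rng.integers(100, 160)) for _ in range(3)]
    introns = [int(rng.integers(300, 800)) for _ in range(2)]
    # transcript-sense blocks: (kind, length)
    blocks = [
        ("utr5", utr5),
        ("cds", cds_lens[0]),
        ("intron", introns[0]),
        ("cds", cds_lens[1]),
        ("intron", introns[1]),
        ("cds", cds_lens[2]),
        ("utr3", utr3),
    ]
    if strand == "-":
        blocks = blocks[::-1]
    pos = start
    genomic: list[tuple[str, int, int]] = []
    for kind, length in blocks:
        genomic.append((kind, pos, pos + length))
        pos += length
    end = pos
    t = Transcript(f"{gene_id}.t1", gene_id, chrom, strand, start, end)
    cds_pieces = [(s, e) for kind, s, e in genomic if kind == "cds"]
    # phases attach in translation order
    order = cds_pieces if strand == "+" else cds_pieces[::-1]
    phases = {}
    cum = 0
    for s, e in order:
        phases[(s, e)] = (3 - cum % 3) % 3
        cum += e - s
    t.cds = sorted((s, e, phases[(s, e)]) for s, e in cds_pieces)
    t.utr5 = [(s, e) for kind, s, e in genomic if kind == "utr5"]
    t.utr3 = [(s, e) for kind, s, e in genomic if kind == "utr3"]
    # exons merge UTR with flanking CDS; introns split them
    exons: list[tuple[int, int]] = []
    for kind, s, e in genomic:
        if kind == "intron":
            continue
        if exons and exons[-1][1] == s:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))
    t.exons = exons
    return GeneModel(gene_id, chrom, strand, start, end, [t])


_MAX_GENE_SPAN = 3400  # 2x150 UTR + 3x477 CDS + 2x799 introns, rounded up


def _make_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    if per_chrom and cfg.chrom_length // per_chrom < _MAX_GENE_SPAN + 200:
        raise ValueError(
            f"chromosomes of {cfg.chrom_length} bp cannot hold {per_chrom} genes; "
            f"reduce n_genes or enlarge chrom_length"
        )
    idx = 0
    for c in range(cfg.n_chromosomes):
        n_here = min(per_chrom, cfg.n_genes - idx)
        if n_here <= 0:
            break
        slot = cfg.chrom_length // max(n_here, 1)
        for k in range(n_here):
            margin = slot - _MAX_GENE_SPAN
            offset = int(rng.integers(100, max(margin, 101)))
            genes.append(
                _make_gene(
                    f"g{idx + 1:04d}",
                    f"chr{c + 1}",
                    k * slot + offset,
                    "+" if rng.random() < 0.5 else "-",
                    rng,
                )
            )
            idx += 1
    return genes


# ---------------------------------------------------------------------------
# population genotypes
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: dict[str, str]
    genes: list[GeneModel]
    population: GenotypeMatrix          # observed calls, all individuals
    true_dosage: np.ndarray             # error-free genotypes (selection substrate)
    labels: np.ndarray                  # per-variant: neutral / selected / fourfold
    mortality: pd.DataFrame
    survivors: dict[str, np.ndarray]    # tank -> population column indices
    sequenced: GenotypeMatrix           # observed calls, sequencing cohorts
    sequenced_true: np.ndarray
    counts: pd.DataFrame
    gene_lengths: pd.Series
    gene2term: pd.DataFrame
    truth: SimulatedTruth


def simulate_population(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel], GenotypeMatrix, np.ndarray, np.ndarray, pd.DataFrame]:
    """Reference, gene models and Hardy-Weinberg population genotypes.

    Returns (reference, genes, observed population matrix, true dosages,
    per-variant labels, variant frame with ancestral frequencies and betas).
    Fourfold-labeled variants sit only at fourfold-degenerate codon
    positions of the emitted gene models; selected loci sit in first
    introns of distinct (expression-linked) genes.
    """
    reference = _make_reference(cfg, rng)
    genes = _make_genes(cfg, rng)

    if cfg.n_variants == 0:
        empty = GenotypeMatrix([], [], [], [], [], np.zeros((0, 0), np.int8))
        return reference, genes, empty, np.zeros((0, 0), np.int8), np.array([]), pd.DataFrame()

    four_sites = sorted(annotate.find_4dtv_sites(genes, reference))
    n_4dtv = min(int(round(cfg.frac_4dtv * cfg.n_variants)), len(four_sites))
    pick = rng.choice(len(four_sites), size=n_4dtv, replace=False)
    chosen_4dtv = [four_sites[i] for i in sorted(pick)]

    n_linked = min(cfg.n_selected, len(genes))
    linked_idx = rng.choice(len(genes), size=n_linked, replace=False)
    selected_pos: list[tuple[str, int]] = []
    for gi in linked_idx:
        g = genes[gi]
        t = g.transcripts[0]
        cds = sorted(t.cds)
        intron = (cds[0][1], cds[1][0])  # genomic gap between first two CDS pieces
        selected_pos.append((g.chrom, int(rng.integers(intron[0] + 1, intron[1])) + 1))

    used = set(chosen_4dtv) | set(selected_pos) | set(four_sites)
    n_rest = cfg.n_variants - n_4dtv - len(selected_pos)
    rest: list[tuple[str, int]] = []
    while len(rest) < n_rest:
        c = [f"chr{i + 1}" for i in rng.integers(0, cfg.n_chromosomes, size=2 * n_rest)]
        p = rng.integers(1, cfg.chrom_length + 1, size=2 * n_rest)
        for ci, pi in zip(c, p):
            key = (ci, int(pi))
            if key not in used:
                used.add(key)
                rest.append(key)
                if len(rest) == n_rest:
                    break

    records = (
        [(c, p, "fourfold") for c, p in chosen_4dtv]
        + [(c, p, "selected") for c, p in selected_pos]
        + [(c, p, "neutral") for c, p in rest]
    )
    frame = pd.DataFrame(records, columns=["chrom", "pos", "label"])
    frame["gene_id"] = ""
    frame.loc[frame["label"] == "selected", "gene_id"] = [
        genes[gi].id for gi in linked_idx
    ]
    lo, hi = cfg.allele_freq_bounds
    a, b = cfg.allele_freq_beta
    frame["freq"] = lo + (hi - lo) * rng.beta(a, b, size=len(frame))
    sel_mask = frame["label"] == "selected"
    frame.loc[sel_mask, "freq"] = rng.uniform(*cfg.selected_freq_range, size=sel_mask.sum())
    frame["beta"] = 0.0
    frame.loc[sel_mask, "beta"] = cfg.effect_size
    frame = frame.sort_values(["chrom", "pos"], ignore_index=True)

    ref_alleles = np.array(
        [reference[c][p - 1] for c, p in zip(frame["chrom"], frame["pos"])], dtype=object
    )
    alt_choice = rng.integers(0, 3, size=len(frame))
    alt_alleles = np.array(
        [
            [b for b in "ACGT" if b != r][k]
            for r, k in zip(ref_alleles, alt_choice)
        ],
        dtype=object,
    )

    n_ind = cfg.n_individuals
    true_dosage = rng.binomial(
        2, frame["freq"].to_numpy()[:, None], size=(len(frame), n_ind)
    ).astype(np.int8)

    observed = true_dosage.copy()
    observed[rng.random(observed.shape) < cfg.missing_rate] = MISSING
    gq = np.full(observed.shape, 99, dtype=np.int32)
    low = rng.random(observed.shape) < cfg.low_gq_rate
    gq[low] = rng.integers(0, 21, size=int(low.sum()))
    dp = rng.poisson(30, size=observed.shape).astype(np.int32) + 1
    high = rng.random(observed.shape) < 0.01
    dp[high] = rng.integers(100, 160, size=int(high.sum()))

    samples = [f"SRC_{i:04d}" for i in range(n_ind)]
    gm = GenotypeMatrix(
        samples=samples,
        chrom=frame["chrom"].to_numpy(object),
        pos=frame["pos"].to_numpy(np.int64),
        ref=ref_alleles,
        alt=alt_alleles,
        dosage=observed,
        groups={s: "SRC" for s in samples},
        gq=gq,
        dp=dp,
    )
    return reference, genes, gm, true_dosage, frame["label"].to_numpy(object), frame


def simulate_experiment(
    cfg: SimulationConfig,
    true_dosage: np.ndarray,
    betas: np.ndarray,
    baseline: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Tank assignment and per-census genotype-dependent mortality.

    Treatment-tank death probability per census for individual i is
    1 - (1 - shock_t) * exp(-baseline_t * exp(sum_selected beta * g_i)),
    where shock_t is the genotype-independent handling shock of the early
    censuses; the control tank dies at the constant genotype-independent
    ``control_hazard``.  Returns (mortality table, tank assignment,
    survivor indices per tank).
    """
    n_ind = cfg.n_individuals
    order = rng.permutation(n_ind)
    tanks = {
        name: order[k * cfg.n_per_tank : (k + 1) * cfg.n_per_tank]
        for k, name in enumerate(cfg.tank_names)
    }
    sel_rows = np.nonzero(betas != 0)[0]
    burden = (
        betas[sel_rows] @ true_dosage[sel_rows].astype(float)
        if len(sel_rows)
        else np.zeros(n_ind)
    )
    risk_mult = np.exp(burden)
    rows = []
    survivors: dict[str, np.ndarray] = {}
    for name, members in tanks.items():
        alive = members.copy()
        for t in range(cfg.n_censuses):
            if name == "CR":
                p_death = np.full(len(alive), cfg.control_hazard)
            else:
                shock = cfg.shock_hazard[t] if t < len(cfg.shock_hazard) else 0.0
                p_death = 1.0 - (1.0 - shock) * np.exp(-baseline[t] * risk_mult[alive])
            dies = rng.random(len(alive)) < p_death
            rows.append(
                {
                    "tank": name,
                    "census_hour": 12 * (t + 1),
                    "deaths": int(dies.sum()),
                    "alive_at_start": len(alive),
                }
            )
            alive = alive[~dies]
        survivors[name] = alive
        if len(alive) == 0:
            logger.warning("tank %s lost all individuals", name)
    return pd.DataFrame(rows), tanks, survivors


def _sequencing_cohorts(
    cfg: SimulationConfig,
    survivors: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    sizes = {"CR": cfg.seq_cohort_control}
    for i, n in enumerate(cfg.seq_cohort_treatment):
        sizes[f"HC{i + 1}"] = n
    cohorts = {}
    for tank, alive in survivors.items():
        n = min(sizes.get(tank, 0), len(alive))
        cohorts[tank] = np.sort(rng.choice(alive, size=n, replace=False))
    return cohorts


def simulate_expression(
    cfg: SimulationConfig,
    sequenced_true: np.ndarray,
    sample_names: list[str],
    genes: list[GeneModel],
    variant_gene: dict[str, int],
    variant_rows: dict[str, int],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts with genotype-linked log2 mean shifts.

    Library sizes vary at most fourfold; a mild gene-by-sample latent
    factor adds realistic correlated noise.  For a linked gene the log2
    mean shifts by ``expr_effect`` per alternate allele of its intronic
    selected locus.
    """
    n_genes = len(genes)
    n_samples = len(sample_names)
    if n_genes == 0:
        return pd.DataFrame(index=pd.Index([], name="gene_id")), pd.Series(dtype=int)
    mu_log, sigma_log = cfg.expr_base_mean_log
    base = rng.lognormal(mu_log, sigma_log, size=n_genes)
    lengths = pd.Series(
        {g.id: sum(e - s for s, e in g.transcripts[0].exons) for g in genes},
        name="length",
    )
    lib = rng.uniform(*cfg.libsize_range, size=n_samples)
    loadings = rng.normal(0.0, cfg.sample_noise_sd, size=n_genes)
    latent = rng.normal(0.0, 1.0, size=n_samples)
    log2_mu = np.log2(base)[:, None] + loadings[:, None] * latent[None, :]
    for vid, gi in variant_gene.items():
        row = variant_rows[vid]
        dos = np.clip(sequenced_true[row].astype(float), 0, 2)
        log2_mu[gi] = log2_mu[gi] + cfg.expr_effect * dos
    mu = np.exp2(log2_mu) * lib[None, :]
    shape = 1.0 / cfg.expr_dispersion
    lam = rng.gamma(shape, mu * cfg.expr_dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    df = pd.DataFrame(counts, index=pd.Index([g.id for g in genes], name="gene_id"), columns=sample_names)
    return df, lengths


# ---------------------------------------------------------------------------
# term map
# ---------------------------------------------------------------------------

SALINITY_TERMS = [
    "ion transport",
    "potassium channel activity",
    "chloride transmembrane transport",
    "water homeostasis",
    "ATP hydrolysis activity",
    "cellular ion homeostasis",
    "inorganic diphosphate transport",
    "divalent inorganic anion homeostasis",
    "urine volume regulation",
    "primary metabolic process",
]

GENERIC_TERMS = [
    "DNA binding",
    "cell adhesion",
    "immune response",
    "protein folding",
    "RNA splicing",
    "cytoskeleton organization",
    "signal transduction",
    "proteolysis",
    "translation",
    "DNA repair",
    "chromatin remodeling",
    "vesicle docking",
    "lipid binding",
    "microtubule motor activity",
    "cell cycle regulation",
]


def _make_gene2term(
    genes: list[GeneModel], linked: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    names = SALINITY_TERMS + GENERIC_TERMS
    term_ids = [f"T{i + 1:04d}" for i in range(len(names))]
    rows = []
    linked_set = set(linked)
    for g in genes:
        n_terms = int(rng.integers(1, 4))
        for t in rng.choice(len(names), size=n_terms, replace=False):
            rows.append((g.id, term_ids[t], names[t]))
        if g.id in linked_set and rng.random() < 0.8:
            t = int(rng.integers(0, len(SALINITY_TERMS)))
            rows.append((g.id, term_ids[t], names[t]))
    df = pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])
    return df.drop_duplicates(ignore_index=True)


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Run the full synthetic experiment for one seed."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_genome, rng_pop, rng_exp, rng_expr, rng_terms = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    reference, genes, gm, true_dosage, labels, frame = simulate_population(cfg, rng_genome)
    if cfg.n_variants == 0:
        truth = SimulatedTruth([], [], [], 1.0)
        empty_counts = pd.DataFrame(index=pd.Index([], name="gene_id"))
        return SimulationResult(
            cfg, reference, genes, gm, true_dosage, labels,
            pd.DataFrame(columns=["tank", "census_hour", "deaths", "alive_at_start"]),
            {}, gm, true_dosage, empty_counts, pd.Series(dtype=int),
            _make_gene2term(genes, [], rng_terms), truth,
        )

    sel = frame["label"].to_numpy() == "selected"
    betas = frame["beta"].to_numpy(float)
    ps = frame.loc[sel, "freq"].to_numpy(float)
    shape = bell_hazard_shape(cfg.n_censuses)
    shock_survival = float(np.prod([1 - s for s in cfg.shock_hazard]))
    bell_target = min(cfg.treatment_survival_target / shock_survival, 0.999)
    if cfg.baseline_hazard is not None:
        baseline = cfg.baseline_hazard
    elif sel.any():
        baseline = calibrate_baseline(ps, betas[sel], shape, bell_target)
    else:
        # no selected loci: uniform risk, amplitude straight from the target
        baseline = shape * (-np.log(bell_target) / shape.sum())

    mortality, tanks, survivors = simulate_experiment(
        cfg, true_dosage, betas, baseline, rng_exp
    )
    cohorts = _sequencing_cohorts(cfg, survivors, rng_exp)

    cols = np.concatenate([cohorts[t] for t in cfg.tank_names])
    col_tanks = np.concatenate(
        [[t] * len(cohorts[t]) for t in cfg.tank_names]
    )
    seq_names = [f"{t}_{i:04d}" for t, i in zip(col_tanks, cols)]
    sequenced = GenotypeMatrix(
        samples=seq_names,
        chrom=gm.chrom,
        pos=gm.pos,
        ref=gm.ref,
        alt=gm.alt,
        dosage=gm.dosage[:, cols],
        groups=dict(zip(seq_names, col_tanks)),
        gq=gm.gq[:, cols],
        dp=gm.dp[:, cols],
    )
    sequenced_true = true_dosage[:, cols]

    ids = gm.ids
    sel_rows = np.nonzero(sel)[0]
    gene_index = {g.id: i for i, g in enumerate(genes)}
    variant_gene = {
        ids[r]: gene_index[frame.loc[r, "gene_id"]] for r in sel_rows
    }
    variant_rows = {ids[r]: int(r) for r in sel_rows}
    counts, lengths = simulate_expression(
        cfg, sequenced_true, seq_names, genes, variant_gene, variant_rows, rng_expr
    )
    linked = [frame.loc[r, "gene_id"] for r in sel_rows]
    gene2term = _make_gene2term(genes, linked, rng_terms)

    total_hazard = float(np.sum(baseline))
    shifts = (
        expected_survivor_shifts(ps, betas[sel_rows], total_hazard)
        if len(sel_rows)
        else np.array([])
    )
    truth = SimulatedTruth(
        selected=[
            {
                "id": ids[r],
                "beta": float(betas[r]),
                "gene_id": frame.loc[r, "gene_id"],
                "ancestral_freq": float(frame.loc[r, "freq"]),
                "expected_shift": float(shifts[k]),
            }
            for k, r in enumerate(sel_rows)
        ],
        linked_genes=linked,
        fourfold_ids=[ids[r] for r in np.nonzero(labels == "fourfold")[0]],
        expected_treatment_survival=shock_survival
        * (
            expected_survival(ps, betas[sel_rows], total_hazard)
            if len(sel_rows)
            else float(np.exp(-total_hazard))
        ),
    )
    return SimulationResult(
        cfg, reference, genes, gm, true_dosage, labels, mortality, survivors,
        sequenced, sequenced_true, counts, lengths, gene2term, truth,
    )


def write_fixture_set(
    sim: SimulationResult, outdir, include_source: bool = True
) -> dict[str, Path]:
    """Write every standard-format input the pipeline consumes.

    The VCF carries the sequencing cohorts (tank in the sample name) and,
    by default, the full source population as additional SRC_* columns.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq = sim.sequenced
    if include_source and sim.population.n_samples:
        combined = GenotypeMatrix(
            samples=seq.samples + sim.population.samples,
            chrom=seq.chrom,
            pos=seq.pos,
            ref=seq.ref,
            alt=seq.alt,
            dosage=np.hstack([seq.dosage, sim.population.dosage]),
            groups={**seq.groups, **sim.population.groups},
            gq=np.hstack([seq.gq, sim.population.gq]) if seq.gq is not None else None,
            dp=np.hstack([seq.dp, sim.population.dp]) if seq.dp is not None else None,
        )
    else:
        combined = seq
    contigs = {c: len(s) for c, s in sim.reference.items()}
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "gff3": outdir / "genes.gff3",
        "fasta": outdir / "ref.fa",
        "counts": outdir / "counts.tsv",
        "mortality": outdir / "mortality.csv",
        "gene2term": outdir / "gene2term.tsv",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(paths["vcf"], combined, contig_lengths=contigs)
    write_gff3(paths["gff3"], sim.genes)
    write_fasta(paths["fasta"], sim.reference)
    write_counts_tsv(paths["counts"], sim.counts, sim.gene_lengths)
    write_mortality_csv(paths["mortality"], sim.mortality)
    write_gene2term_tsv(paths["gene2term"], sim.gene2term)
    write_groups_tsv(paths["groups"], combined.groups)
    write_truth_json(paths["truth"], sim.truth)
    return paths
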