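"""SNP functional annotation against gene models, enrichment, keyword filter.

Provides region classification (exonic / UTR / intronic / upstream /
downstream / intergenic), coding-effect calls (synonymous vs nonsynonymous
via strand-aware codon reconstruction), discovery of fourfold-degenerate
(4DTV) third-codon positions used as the neutral null, hypergeometric term
enrichment with Benjamini-Hochberg control, and the salinity keyword screen.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneModel, GenotypeMatrix, Transcript

logger = logging.getLogger(__name__)

REGION_PRIORITY = [
    "exonic",
    "5'UTR",
    "3'UTR",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
]

# GO-style keywords marking osmoregulation/salinity-relevant terms
DEFAULT_KEYWORDS = (
    "ion",
    "channel",
    "transport",
    "water",
    "chloride",
    "potassium",
    "homeostasis",
    "urine",
    "ATP",
    "metabolic",
)

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


from functools import lru_cache


@lru_cache(maxsize=256)
def _is_fourfold(codon: str, offset: int) -> bool:
    """True when every base at ``offset`` leaves the amino acid unchanged."""
    table = _codon_table()
    aas = {table[codon[:offset] + b + codon[offset + 1 :]] for b in _BASES}
    return len(aas) == 1


# ---------------------------------------------------------------------------
# coding coordinates
# ---------------------------------------------------------------------------


def _coding_positions(t: Transcript) -> np.ndarray:
    """Genomic 0-based positions of the transcript CDS in translation order.

    Respects strand and the GFF3 phase of the first coding piece (bases to
    skip before the first complete codon); the tail is trimmed to a multiple
    of three.
    """
    pieces = sorted(t.cds)
    if t.strand == "-":
        pieces = pieces[::-1]
    pos: list[np.ndarray] = []
    for s, e, _ in pieces:
        block = np.arange(s, e, dtype=np.int64)
        if t.strand == "-":
            block = block[::-1]
        pos.append(block)
    if not pos:
        return np.zeros(0, dtype=np.int64)
    arr = np.concatenate(pos)
    phase = pieces[0][2]
    arr = arr[phase:]
    return arr[: len(arr) - (len(arr) % 3)]


def _transcript_codons(t: Transcript, reference: dict[str, str]):
    """Return (positions, codon strings, offsets) in translation order."""
    pos = _coding_positions(t)
    if len(pos) == 0:
        return pos, np.zeros(0, dtype=object), np.zeros(0, dtype=np.int64)
    seq = reference[t.chrom]
    bases = "".join(seq[p] for p in pos)
    if t.strand == "-":
        bases = bases.translate(_COMP)
    codons = np.array(
        [bases[i : i + 3] for i in range(0, len(bases), 3)], dtype=object
    )
    offsets = np.arange(len(pos)) % 3
    return pos, codons, offsets


# ---------------------------------------------------------------------------
# 4DTV sites
# ---------------------------------------------------------------------------


def find_4dtv_sites(genes: list[GeneModel], reference: dict[str, str]) -> set[tuple[str, int]]:
    """Fourfold-degenerate coding positions as ``(chrom, pos)`` with 1-based pos.

    A position qualifies only if every codon containing it (across all
    transcripts of all genes) is fully degenerate at the position's offset
    within that codon, so positions in overlapping transcripts must be
    fourfold in all contexts.
    """
    verdict: dict[tuple[str, int], bool] = {}
    for g in genes:
        for t in g.transcripts:
            pos, codons, offsets = _transcript_codons(t, reference)
            for i, p in enumerate(pos):
                codon = codons[i // 3]
                ok = "N" not in codon and _is_fourfold(codon, int(offsets[i]))
                key = (t.chrom, int(p) + 1)
                verdict[key] = verdict.get(key, True) and ok
    return {k for k, ok in verdict.items() if ok}


def fourfold_mask(gm: GenotypeMatrix, sites: set[tuple[str, int]]) -> np.ndarray:
    return np.array(
        [(c, int(p)) in sites for c, p in zip(gm.chrom, gm.pos)], dtype=bool
    )


# ---------------------------------------------------------------------------
# region / effect classification
# ---------------------------------------------------------------------------


def _region_for_gene(pos0: int, g: GeneModel, flank_bp: int) -> tuple[str, int] | None:
    """Best (region, distance) of a position relative to one gene, else None."""
    if g.start <= pos0 < g.end:
        best = "intronic"
        for t in g.transcripts:
            if any(s <= pos0 < e for s, e, _ in t.cds):
                return "exonic", 0
            if any(s <= pos0 < e for s, e in t.utr5):
                best = _higher_priority(best, "5'UTR")
            elif any(s <= pos0 < e for s, e in t.utr3):
                best = _higher_priority(best, "3'UTR")
        return best, 0
    if pos0 < g.start:
        dist = g.start - pos0
        side = "upstream" if g.strand == "+" else "downstream"
    else:
        dist = pos0 - (g.end - 1)
        side = "downstream" if g.strand == "+" else "upstream"
    if dist <= flank_bp:
        return side, dist
    return None


def _higher_priority(a: str, b: str) -> str:
    return a if REGION_PRIORITY.index(a) <= REGION_PRIORITY.index(b) else b


def classify_region(
    chrom: str,
    pos: int,
    genes: list[GeneModel],
    flank_bp: int = 5000,
) -> tuple[str, str | None]:
    """Classify a 1-based position; returns (region, gene_id or None).

    Priority: exonic > 5'UTR > 3'UTR > intronic > upstream > downstream >
    intergenic; among genes offering the same label the nearest wins, then
    the lexicographically lower gene id.
    """
    pos0 = pos - 1
    candidates: list[tuple[int, int, str, str]] = []
    known_chrom = False
    for g in genes:
        if g.chrom != chrom:
            continue
        known_chrom = True
        hit = _region_for_gene(pos0, g, flank_bp)
        if hit is not None:
            region, dist = hit
            candidates.append((REGION_PRIORITY.index(region), dist, g.id, region))
    if not known_chrom:
        logger.warning("position %s:%d on unknown chromosome", chrom, pos)
        return "intergenic", None
    if not candidates:
        return "intergenic", None
    prio, _, gene_id, region = min(candidates)
    return region, gene_id


def nearest_gene(chrom: str, pos: int, genes: list[GeneModel]) -> str | None:
    """Nearest gene on the chromosome by distance to the gene span."""
    pos0 = pos - 1
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != chrom:
            continue
        dist = max(g.start - pos0, pos0 - (g.end - 1), 0)
        if best is None or (dist, g.id) < best:
            best = (dist, g.id)
    return None if best is None else best[1]


def classify_effect(
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    genes: list[GeneModel],
    reference: dict[str, str],
) -> str:
    """synonymous / nonsynonymous / noncoding for one SNP.

    The codon containing the site is rebuilt strand-aware with phase; with
    several containing transcripts the most severe effect is reported.
    Raises ``ValueError`` when the FASTA base at ``pos`` differs from the
    VCF REF allele.
    """
    pos0 = pos - 1
    actual = reference[chrom][pos0]
    if actual.upper() != ref_allele.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: FASTA has {actual}, VCF has {ref_allele}"
        )
    table = _codon_table()
    effects = []
    for g in genes:
        if g.chrom != chrom:
            continue
        for t in g.transcripts:
            cpos = _coding_positions(t)
            idx = np.nonzero(cpos == pos0)[0]
            if len(idx) == 0:
                continue
            i = int(idx[0])
            codon_pos = cpos[(i // 3) * 3 : (i // 3) * 3 + 3]
            bases = "".join(reference[chrom][p] for p in codon_pos)
            ref_b, alt_b = ref_allele, alt_allele
            if t.strand == "-":
                bases = bases.translate(_COMP)
                ref_b = ref_b.translate(_COMP)
                alt_b = alt_b.translate(_COMP)
            offset = i % 3
            assert bases[offset] == ref_b, "codon reconstruction inconsistent"
            mutated = bases[:offset] + alt_b + bases[offset + 1 :]
            effects.append(
                "synonymous" if table[bases] == table[mutated] else "nonsynonymous"
            )
    if not effects:
        return "noncoding"
    return "nonsynonymous" if "nonsynonymous" in effects else "synonymous"


def annotate_snps(
    gm: GenotypeMatrix,
    genes: list[GeneModel],
    reference: dict[str, str],
    flank_bp: int = 5000,
) -> pd.DataFrame:
    """Per-variant region, effect, gene assignment and 4DTV status.

    Intergenic SNPs are assigned their nearest gene (flagged by
    ``gene_assignment == 'nearest'``) so every variant can feed gene-level
    analyses; ``gene_id`` is None when the chromosome carries no gene.
    """
    sites = find_4dtv_sites(genes, reference)
    rows = []
    for c, p, r, a in zip(gm.chrom, gm.pos, gm.ref, gm.alt):
        region, gene_id = classify_region(c, int(p), genes, flank_bp)
        assignment = "overlap"
        if gene_id is None:
            gene_id = nearest_gene(c, int(p), genes)
            assignment = "nearest"
        if region == "exonic":
            effect = classify_effect(c, int(p), r, a, genes, reference)
        else:
            effect = "noncoding"
        rows.append(
            {
                "id": f"{c}:{p}",
                "chrom": c,
                "pos": int(p),
                "region": region,
                "effect": effect,
                "gene_id": gene_id,
                "gene_assignment": assignment,
                "is_4dtv": (c, int(p)) in sites,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "chrom",
            "pos",
            "region",
            "effect",
            "gene_id",
            "gene_assignment",
            "is_4dtv",
        ],
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def enrich(
    selected_genes: set[str],
    universe: set[str],
    term_map: pd.DataFrame,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH adjustment.

    ``term_map`` needs columns gene_id, term_id, term_name.  Terms with no
    selected gene are not tested.  Returns one row per tested term with
    k (selected in term), K (universe in term), n, N, p and fdr.
    """
    if not selected_genes <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    tm = term_map[term_map["gene_id"].isin(universe)]
    if not selected_genes or tm.empty:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p", "fdr"]
        )
    N, n = len(universe), len(selected_genes)
    rows = []
    for (term_id, term_name), sub in tm.groupby(["term_id", "term_name"]):
        members = set(sub["gene_id"])
        k = len(members & selected_genes)
        if k == 0:
            continue
        K = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term_id, "term_name": term_name, "k": k, "K": K, "n": n, "N": N, "p": p})
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p", "fdr"]
        )
    res = pd.DataFrame(rows)
    res["fdr"] = multipletests(res["p"], method="fdr_bh")[1]
    return res.sort_values("p", ignore_index=True)


def keyword_filter(
    term_names: pd.Series | list[str],
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
) -> np.ndarray:
    """Flag term names containing any keyword as a whole word (case-insensitive)."""
    pattern = re.compile(
        r"\b(?:" + "|".join(re.escape(k) for k in keywords) + r")\b", re.IGNORECASE
    )
    return np.array([bool(pattern.search(str(t))) for t in term_names], dtype=bool)


# ---------------------------------------------------------------------------
# density report
# ---------------------------------------------------------------------------


def snp_density_report(snps: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome focal-SNP count and mean successive inter-SNP distance.

    ``snps`` needs chrom and pos columns; chromosomes with a single SNP get
    a missing mean distance.
    """
    rows = []
    for chrom, sub in snps.groupby("chrom"):
        pos = np.sort(sub["pos"].to_numpy())
        dist = float(np.mean(np.diff(pos))) if len(pos) >= 2 else np.nan
        rows.append({"chrom": chrom, "n_snps": len(pos), "mean_distance": dist})
    return pd.DataFrame(rows, columns=["chrom", "n_snps", "mean_distance"])
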