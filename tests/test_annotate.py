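"""Region/effect classification, 4DTV discovery, enrichment, keywords."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from fractions import Fraction
from math import comb

from salsel.annotate import (
    classify_effect,
    classify_region,
    enrich,
    find_4dtv_sites,
    keyword_filter,
    snp_density_report,
)
from salsel.io import GeneModel, Transcript

_COMP = str.maketrans("ACGT", "TGCA")


def single_exon_gene(gene_id, chrom, strand, start, cds_seq_len, utr=10):
    """One-exon gene: [5'UTR][CDS][3'UTR] in transcript sense."""
    total = utr + cds_seq_len + utr
    end = start + total
    t = Transcript(f"{gene_id}.t", gene_id, chrom, strand, start, end)
    if strand == "+":
        u5 = (start, start + utr)
        cds = (start + utr, start + utr + cds_seq_len)
        u3 = (cds[1], end)
    else:
        u3 = (start, start + utr)
        cds = (start + utr, start + utr + cds_seq_len)
        u5 = (cds[1], end)
    t.utr5, t.utr3 = [u5], [u3]
    t.cds = [(cds[0], cds[1], 0)]
    t.exons = [(start, end)]
    return GeneModel(gene_id, chrom, strand, start, end, [t])


def brute_force_4dtv(genes, reference):
    """Mutate every CDS base to all alternatives and translate."""
    out = set()
    coverage = {}
    for g in genes:
        for t in g.transcripts:
            pieces = sorted(t.cds)
            order = pieces if t.strand == "+" else pieces[::-1]
            pos = []
            for s, e, _ in order:
                block = list(range(s, e))
                pos += block[::-1] if t.strand == "-" else block
            pos = pos[order[0][2] :]
            pos = pos[: len(pos) - len(pos) % 3]
            seq = "".join(reference[t.chrom][p] for p in pos)
            if t.strand == "-":
                seq = seq.translate(_COMP)
            for i, p in enumerate(pos):
                codon_i = i // 3
                codon = seq[codon_i * 3 : codon_i * 3 + 3]
                aa = str(Seq(codon).translate())
                ok = True
                for alt in "ACGT":
                    mutated = codon[: i % 3] + alt + codon[i % 3 + 1 :]
                    if str(Seq(mutated).translate()) != aa:
                        ok = False
                key = (t.chrom, p + 1)
                coverage[key] = coverage.get(key, True) and ok
    return {k for k, ok in coverage.items() if ok}


def hypergeom_oracle(N, K, n, k):
    """Exact upper-tail probability as a rational number."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


class TestClassifyRegion:
    def setup_method(self):
        self.gene = single_exon_gene("gA", "chr1", "+", 1000, 30)

    def test_cds_is_exonic(self):
        region, gid = classify_region("chr1", 1015, [self.gene])
        assert region == "exonic" and gid == "gA"

    def test_one_bp_past_gene_end_is_downstream(self):
        end = self.gene.end  # 0-based half-open; 1-based end = self.gene.end
        region, _ = classify_region("chr1", end + 1, [self.gene])
        assert region == "downstream"

    def test_utr_labels(self):
        assert classify_region("chr1", 1005, [self.gene])[0] == "5'UTR"
        assert classify_region("chr1", 1045, [self.gene])[0] == "3'UTR"

    def test_minus_strand_flanks(self):
        g = single_exon_gene("gB", "chr2", "-", 1000, 30)
        assert classify_region("chr2", 900, [g])[0] == "downstream"
        assert classify_region("chr2", 1200, [g])[0] == "upstream"

    def test_unknown_chromosome_warns_intergenic(self, caplog):
        with caplog.at_level("WARNING"):
            region, gid = classify_region("chrZ", 5, [self.gene])
        assert region == "intergenic" and gid is None

    def test_far_position_intergenic(self):
        assert classify_region("chr1", 50_000, [self.gene])[0] == "intergenic"

    def test_placed_snps_match_interval_oracle(self, tiny_sim):
        """Classification agrees with a direct interval-overlap scan."""
        rng = np.random.default_rng(0)
        genes = tiny_sim.genes[:6]
        chrom = genes[0].chrom
        positions = rng.integers(1, 60_000, size=30)
        for pos in positions:
            region, _ = classify_region(chrom, int(pos), genes, flank_bp=5000)
            pos0 = int(pos) - 1
            labels = []
            for g in genes:
                if g.chrom != chrom:
                    continue
                t = g.transcripts[0]
                if any(s <= pos0 < e for s, e, _ in t.cds):
                    labels.append("exonic")
                elif any(s <= pos0 < e for s, e in t.utr5):
                    labels.append("5'UTR")
                elif any(s <= pos0 < e for s, e in t.utr3):
                    labels.append("3'UTR")
                elif g.start <= pos0 < g.end:
                    labels.append("intronic")
                elif 0 < (g.start - pos0) <= 5000:
                    labels.append("upstream" if g.strand == "+" else "downstream")
                elif 0 < (pos0 - (g.end - 1)) <= 5000:
                    labels.append("downstream" if g.strand == "+" else "upstream")
            priority = ["exonic", "5'UTR", "3'UTR", "intronic", "upstream", "downstream"]
            expected = min(labels, key=priority.index) if labels else "intergenic"
            assert region == expected, pos


class TestClassifyEffect:
    def make_ref(self, cds):
        utr = "T" * 10
        return {"chr1": utr + cds + utr}

    def test_synonymous_third_position(self):
        # GCT (Ala) -> GCC (Ala)
        ref = self.make_ref("ATGGCTTAA")
        gene = single_exon_gene("g", "chr1", "+", 0, 9)
        assert classify_effect("chr1", 16, "T", "C", [gene], ref) == "synonymous"

    def test_nonsynonymous_first_position(self):
        # AAA (Lys) -> GAA (Glu)
        ref = self.make_ref("ATGAAATAA")
        gene = single_exon_gene("g", "chr1", "+", 0, 9)
        assert classify_effect("chr1", 14, "A", "G", [gene], ref) == "nonsynonymous"

    def test_minus_strand_matches_revcomp_oracle(self):
        rng = np.random.default_rng(1)
        cds_plus = "ATG" + "".join(rng.choice(list("ACGT"), 30)) + "TAA"
        # place it as the minus-strand CDS: genome carries the reverse complement
        genome_cds = cds_plus.translate(_COMP)[::-1]
        ref = {"chr1": "A" * 10 + genome_cds + "A" * 10}
        gene = single_exon_gene("g", "chr1", "-", 0, len(genome_cds))
        for pos0 in range(10, 10 + len(genome_cds)):
            base = ref["chr1"][pos0]
            for alt in "ACGT":
                if alt == base:
                    continue
                got = classify_effect("chr1", pos0 + 1, base, alt, [gene], ref)
                # oracle: mutate genome, rebuild transcript, translate both
                mutated = ref["chr1"][:pos0] + alt + ref["chr1"][pos0 + 1 :]
                tr_ref = str(Seq(genome_cds).reverse_complement().translate())
                tr_alt = str(
                    Seq(mutated[10 : 10 + len(genome_cds)]).reverse_complement().translate()
                )
                assert got == ("synonymous" if tr_ref == tr_alt else "nonsynonymous")

    def test_reference_mismatch_raises(self):
        ref = self.make_ref("ATGGCTTAA")
        gene = single_exon_gene("g", "chr1", "+", 0, 9)
        with pytest.raises(ValueError, match="chr1:16"):
            classify_effect("chr1", 16, "G", "C", [gene], ref)


class TestFind4dtv:
    def test_fourfold_and_nonfourfold_codons(self):
        # CDS = ATG GGA TAA: GGA third position (Gly) is 4-fold, ATG is not
        ref = {"chr1": "T" * 10 + "ATGGGATAA" + "T" * 10}
        gene = single_exon_gene("g", "chr1", "+", 0, 9)
        sites = find_4dtv_sites([gene], ref)
        assert ("chr1", 16) in sites       # third base of GGA
        assert ("chr1", 13) not in sites   # third base of ATG

    def test_toy_two_gene_set_matches_mutate_translate_oracle(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 400))
        ref = {"chr1": seq}
        g1 = single_exon_gene("g1", "chr1", "+", 20, 60)
        g2 = single_exon_gene("g2", "chr1", "-", 200, 90)
        sites = find_4dtv_sites([g1, g2], ref)
        assert sites == brute_force_4dtv([g1, g2], ref)

    def test_overlapping_transcripts_require_all_contexts(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 200))
        ref = {"chr1": seq}
        # same span, frames offset by one base: almost no site is 4-fold in both
        g1 = single_exon_gene("g1", "chr1", "+", 20, 60)
        g2 = single_exon_gene("g2", "chr1", "+", 21, 60)
        sites = find_4dtv_sites([g1, g2], ref)
        assert sites == brute_force_4dtv([g1, g2], ref)

    def test_sites_are_synonymous_under_every_substitution(self, tiny_sim):
        sites = sorted(find_4dtv_sites(tiny_sim.genes, tiny_sim.reference))[:40]
        for chrom, pos in sites:
            base = tiny_sim.reference[chrom][pos - 1]
            for alt in "ACGT":
                if alt == base:
                    continue
                effect = classify_effect(
                    chrom, pos, base, alt, tiny_sim.genes, tiny_sim.reference
                )
                assert effect == "synonymous"

    def test_strand_invariance(self):
        """Reverse-complementing the genome and flipping genes preserves calls."""
        rng = np.random.default_rng(4)
        L = 300
        seq = "".join(rng.choice(list("ACGT"), L))
        gene = single_exon_gene("g", "chr1", "+", 40, 90)
        sites = find_4dtv_sites([gene], {"chr1": seq})
        flipped_seq = seq.translate(_COMP)[::-1]
        fg_start = L - gene.end
        flipped = single_exon_gene("g", "chr1", "-", fg_start, 90)
        flipped_sites = find_4dtv_sites([flipped], {"chr1": flipped_seq})
        assert {(c, L - p + 1) for c, p in sites} == flipped_sites


class TestEnrich:
    def term_map(self, assignment):
        rows = [
            {"gene_id": g, "term_id": t, "term_name": t}
            for t, members in assignment.items()
            for g in members
        ]
        return pd.DataFrame(rows)

    def test_certain_term_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        tm = self.term_map({"everything": sorted(universe)})
        res = enrich({"g1", "g2"}, universe, tm)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_combinatorial_example(self):
        universe = {f"g{i}" for i in range(20)}
        term_genes = [f"g{i}" for i in range(5)]
        tm = self.term_map({"T": term_genes})
        selected = {"g0", "g1", "g2", "g10", "g11"}  # k=3 of K=5, n=5, N=20
        res = enrich(selected, universe, tm)
        assert res["p"].iloc[0] == pytest.approx(1126 / 15504)
        assert res["p"].iloc[0] == pytest.approx(hypergeom_oracle(20, 5, 5, 3))

    def test_bh_adjustment_forced(self):
        from statsmodels.stats.multitest import multipletests

        fdr = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert fdr == pytest.approx([0.03, 0.03, 0.03])

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 25))
        universe = {f"g{i}" for i in range(N)}
        assignment = {
            f"T{t}": list(rng.choice(sorted(universe), size=rng.integers(2, N), replace=False))
            for t in range(4)
        }
        selected = set(rng.choice(sorted(universe), size=rng.integers(2, N // 2 + 2), replace=False))
        res = enrich(selected, universe, self.term_map(assignment))
        for _, row in res.iterrows():
            assert row["p"] == pytest.approx(
                hypergeom_oracle(row["N"], row["K"], row["n"], row["k"]), rel=1e-9
            )

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich({"x"}, {"y"}, self.term_map({"T": ["y"]}))


class TestKeywordFilter:
    def test_paper_style_matches(self):
        flags = keyword_filter(
            ["inorganic diphosphate transport", "DNA binding", "cation channel activity"]
        )
        assert flags.tolist() == [True, False, True]

    def test_whole_word_only(self):
        # "cation" contains "ion" only as a substring, not a word
        assert not keyword_filter(["cation binding"]).any()
        assert keyword_filter(["ion binding"]).all()


class TestDensityReport:
    def test_arithmetic(self):
        df = pd.DataFrame({"chrom": ["c"] * 3, "pos": [100, 200, 400]})
        out = snp_density_report(df)
        assert out["mean_distance"].iloc[0] == pytest.approx(150.0)

    def test_single_snp_missing_distance(self):
        out = snp_density_report(pd.DataFrame({"chrom": ["c"], "pos": [5]}))
        assert np.isnan(out["mean_distance"].iloc[0])

    def test_sort_and_diff_oracle(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"chrom": rng.choice(["a", "b"], 40), "pos": rng.choice(10_000, 40, replace=False)}
        )
        out = snp_density_report(df).set_index("chrom")
        for chrom, sub in df.groupby("chrom"):
            pos = np.sort(sub["pos"])
            assert out.loc[chrom, "n_snps"] == len(pos)
            assert out.loc[chrom, "mean_distance"] == pytest.approx(np.diff(pos).mean())
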