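"""Containers and readers/writers for the pipeline's on-disk formats.

Everything downstream operates on two in-memory substrates: a
:class:`GenotypeMatrix` (samples x biallelic variants, diploid dosage codes
with missingness, plus group labels) and plain pandas DataFrames for
tabular inputs (mortality censuses, read counts, gene-to-term maps).
Gene models are held as lightweight dataclasses with 0-based half-open
coordinates; GFF3 files are converted on read/write.

VCF input goes through cyvcf2; VCF output is a plain VCF 4.2 writer
(GT, optionally GQ/DP) so that simulated fixtures round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1  # dosage code for a missing genotype call

# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes as an (n_variants, n_samples) dosage array.

    ``dosage`` holds the alternate-allele count per call: 0, 1, 2, or
    :data:`MISSING` (-1).  ``groups`` maps each sample name to a cohort label
    (e.g. ``CR``, ``HC1``); samples without a label map to ``""``.
    Optional ``gq``/``dp`` arrays (same shape as ``dosage``) carry per-call
    genotype quality and read depth for the QC stage.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    groups: dict[str, str] = field(default_factory=dict)
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.pos)} variants x {len(self.samples)} samples"
            )

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def ids(self) -> np.ndarray:
        """Variant identifiers ``chrom:pos`` (pos 1-based)."""
        return np.array(
            [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
        )

    def sample_groups(self) -> np.ndarray:
        return np.array([self.groups.get(s, "") for s in self.samples], dtype=object)

    def group_mask(self, group: str) -> np.ndarray:
        return self.sample_groups() == group

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[index],
            gq=None if self.gq is None else self.gq[index],
            dp=None if self.dp is None else self.dp[index],
        )

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            raise TypeError("take_samples expects a boolean mask")
        samples = [s for s, m in zip(self.samples, mask) if m]
        return replace(
            self,
            samples=samples,
            dosage=self.dosage[:, mask],
            gq=None if self.gq is None else self.gq[:, mask],
            dp=None if self.dp is None else self.dp[:, mask],
            groups={s: self.groups.get(s, "") for s in samples},
        )

    def subset_group(self, group: str) -> "GenotypeMatrix":
        return self.take_samples(self.group_mask(group))

    def allele_counts(self, group: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant (alt allele count, total called allele count)."""
        dos = self.dosage if group is None else self.dosage[:, self.group_mask(group)]
        called = dos != MISSING
        alt = np.where(called, dos, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)

    def allele_freq(self, group: str | None = None) -> np.ndarray:
        """Per-variant alternate-allele frequency (NaN when no calls)."""
        alt, total = self.allele_counts(group)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, alt / np.maximum(total, 1), np.nan)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """One mRNA with exon/CDS/UTR intervals in 0-based half-open coordinates.

    ``cds`` carries ``(start, end, phase)`` with GFF3 phase semantics (number
    of bases to skip at the 5' end of that CDS piece to reach a codon start).
    Intervals are stored sorted by genomic start regardless of strand.
    """

    id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)


@dataclass
class GeneModel:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, gm: GenotypeMatrix, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal standard VCF 4.2 with GT and, if present, GQ/DP."""
    has_fmt = gm.gq is not None and gm.dp is not None
    fmt = "GT:GQ:DP" if has_fmt else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_fmt:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gt_lookup = np.array(["./.", "0/0", "0/1", "1/1"], dtype=object)
        gt = gt_lookup[gm.dosage.astype(np.int64) + 1]
        if has_fmt:
            cells = (
                gt
                + ":"
                + gm.gq.astype(np.int64).astype(str).astype(object)
                + ":"
                + gm.dp.astype(np.int64).astype(str).astype(object)
            )
        else:
            cells = gt
        for i in range(gm.n_variants):
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t{gm.chrom[i]}:{gm.pos[i]}\t"
                f"{gm.ref[i]}\t{gm.alt[i]}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells[i])
                + "\n"
            )


def read_vcf(path, groups: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are kept (first ALT; dosage of calls carrying other
    alleles set to missing) so the QC stage can count and drop them; the
    per-variant alternate-allele count is recoverable from ``alt`` containing
    a comma.  When ``groups`` is not given, the cohort label is taken from
    the sample-name prefix before the last ``_`` (the simulator's naming).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows, gq_rows, dp_rows = [], [], [], [], [], [], []
    any_gq = False
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(",".join(v.ALT) if v.ALT else ".")
        dos = v.gt_types.astype(np.int8)
        dos[dos == 3] = MISSING
        rows.append(dos)
        gq = v.format("GQ")
        dp = v.format("DP")
        if gq is not None and dp is not None:
            any_gq = True
            gq_rows.append(gq.ravel().astype(np.int32))
            dp_rows.append(dp.ravel().astype(np.int32))
        else:
            gq_rows.append(None)
            dp_rows.append(None)
    vcf.close()
    n = len(pos)
    if groups is None:
        groups = {s: s.rsplit("_", 1)[0] for s in samples}
    gq_arr = dp_arr = None
    if any_gq and all(r is not None for r in gq_rows):
        gq_arr = np.vstack(gq_rows) if n else np.zeros((0, len(samples)), np.int32)
        dp_arr = np.vstack(dp_rows) if n else np.zeros((0, len(samples)), np.int32)
    dosage = (
        np.vstack(rows) if n else np.zeros((0, len(samples)), np.int8)
    )
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=dosage,
        groups=groups,
        gq=gq_arr,
        dp=dp_arr,
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        sequences[name] = "".join(parts)
    return sequences


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_FEATURE_ORDER = {"gene": 0, "mRNA": 1, "five_prime_UTR": 2, "exon": 3, "CDS": 4, "three_prime_UTR": 5}


def write_gff3(path, genes: list[GeneModel]) -> None:
    """Write gene models as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsalsel\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tsalsel\tmRNA\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
                    f"ID={t.id};Parent={g.id}\n"
                )
                for s, e in t.utr5:
                    fh.write(
                        f"{g.chrom}\tsalsel\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"Parent={t.id}\n"
                    )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\tsalsel\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"Parent={t.id}\n"
                    )
                for s, e, phase in t.cds:
                    fh.write(
                        f"{g.chrom}\tsalsel\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t{phase}\t"
                        f"Parent={t.id}\n"
                    )
                for s, e in t.utr3:
                    fh.write(
                        f"{g.chrom}\tsalsel\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"Parent={t.id}\n"
                    )


def _attr(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3(path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, phase, attrs = f[:9]
            start0, end0 = int(start) - 1, int(end)
            a = _attr(attrs)
            if ftype == "gene":
                genes[a["ID"]] = GeneModel(a["ID"], chrom, strand, start0, end0)
            elif ftype == "mRNA":
                t = Transcript(a["ID"], a["Parent"], chrom, strand, start0, end0)
                transcripts[a["ID"]] = t
                genes[a["Parent"]].transcripts.append(t)
            elif ftype == "exon":
                transcripts[a["Parent"]].exons.append((start0, end0))
            elif ftype == "CDS":
                transcripts[a["Parent"]].cds.append((start0, end0, int(phase)))
            elif ftype == "five_prime_UTR":
                transcripts[a["Parent"]].utr5.append((start0, end0))
            elif ftype == "three_prime_UTR":
                transcripts[a["Parent"]].utr3.append((start0, end0))
    for t in transcripts.values():
        t.exons.sort()
        t.cds.sort()
        t.utr5.sort()
        t.utr3.sort()
    return list(genes.values())


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_mortality_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_mortality_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"tank", "census_hour", "deaths", "alive_at_start"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mortality table missing columns: {sorted(missing)}")
    return df


def write_counts_tsv(path, counts: pd.DataFrame, lengths: pd.Series) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index).astype(int))
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df.pop("length")
    return df, lengths


def write_gene2term_tsv(path, mapping: pd.DataFrame) -> None:
    mapping.to_csv(path, sep="\t", index=False)


def read_gene2term_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "term_id", "term_name"}
    if required - set(df.columns):
        raise ValueError("gene2term table needs gene_id, term_id, term_name columns")
    return df


def write_groups_tsv(path, groups: dict[str, str]) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_groups_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["group"]))


def write_truth_json(path, truth) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict() if hasattr(truth, "to_dict") else truth, fh, indent=1)


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
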