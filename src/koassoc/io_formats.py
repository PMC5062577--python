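"""Readers and writers for the external formats the pipeline touches.

Genotypes come in as VCF (via :mod:`pysam`), gene models as BED12 or GFF3,
phenotypes/samples as TSV tables, and candidate-gene sets as plain text.
Everything is normalized into a small internal data model:

* genomic intervals are 0-based, half-open (VCF positions are converted on
  read and back on write);
* multi-allelic VCF records are split into one :class:`VariantSite` per ALT
  allele before any annotation;
* phase is preserved exactly as encoded (``|`` vs ``/``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: allele codes in :attr:`GenotypeMatrix.alleles`
MISSING = -1     # "." in the VCF GT field
HAPLOID = -2     # second slot of a haploid call (e.g. male X "1")


@dataclass(frozen=True, order=True)
class VariantSite:
    """A bi-allelic variant site (one ALT allele), VCF-style 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end0(self) -> int:
        """0-based, half-open end of the REF allele span."""
        return self.pos - 1 + len(self.ref)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class GenotypeMatrix:
    """Per-sample allele pairs for a list of bi-allelic variant sites.

    ``alleles`` has shape ``(n_variants, n_samples, 2)`` with values in
    {0, 1, MISSING, HAPLOID}; ``phased`` has shape ``(n_variants, n_samples)``.
    After multi-allelic splitting an allele value of 1 means "carries this
    site's ALT allele"; any other called allele (REF or another ALT of the
    original record) is stored as 0.
    """

    def __init__(self, variants: Sequence[VariantSite], samples: Sequence[str],
                 alleles: np.ndarray, phased: np.ndarray):
        self.variants = list(variants)
        self.samples = list(samples)
        self.alleles = np.asarray(alleles, dtype=np.int8)
        self.phased = np.asarray(phased, dtype=bool)
        n_v, n_s = len(self.variants), len(self.samples)
        if self.alleles.shape != (n_v, n_s, 2) or self.phased.shape != (n_v, n_s):
            raise ValueError("genotype array shapes inconsistent with variant/sample lists")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}

    def dosage(self, vi: int) -> np.ndarray:
        """ALT allele count per sample (haploid counts its single allele);
        NaN where the genotype is missing."""
        a = self.alleles[vi]
        d = (a == 1).sum(axis=1).astype(float)
        d[a[:, 0] == MISSING] = np.nan
        return d

    def called_allele_counts(self, vi: int, sample_mask: np.ndarray | None = None
                             ) -> tuple[int, int]:
        """(n_alt_alleles, n_called_alleles) over an optional sample subset."""
        a = self.alleles[vi]
        if sample_mask is not None:
            a = a[sample_mask]
        called = (a == 0) | (a == 1)
        return int((a == 1).sum()), int(called.sum())

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.variants == other.variants
                and self.samples == other.samples
                and np.array_equal(self.alleles, other.alleles)
                and np.array_equal(self.phased, other.phased))


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    """One transcript: exons in genomic order (0-based half-open) plus the
    genomic CDS span. Internal coordinates never depend on strand; the
    transcription order is derived from the parent gene's strand."""

    transcript_id: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_intervals(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals())


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


def validate_transcript(t: Transcript, gene_id: str = "?") -> None:
    """Raise ValueError if the transcript violates the structural invariants
    (unsorted/overlapping exons, CDS outside exons, inverted CDS)."""
    last = None
    for s, e in t.exons:
        if s >= e:
            raise ValueError(f"{gene_id}/{t.transcript_id}: empty exon [{s},{e})")
        if last is not None and s < last:
            raise ValueError(f"{gene_id}/{t.transcript_id}: exons overlap or are unsorted")
        last = e
    if not t.cds_start < t.cds_end:
        raise ValueError(f"{gene_id}/{t.transcript_id}: cds_start >= cds_end")
    span = t.span()
    if t.cds_start < span[0] or t.cds_end > span[1]:
        raise ValueError(f"{gene_id}/{t.transcript_id}: CDS outside transcript span")
    # every CDS interval must land inside an exon: cds_intervals() construction
    # guarantees containment, but the CDS bounds themselves must hit exons
    in_exon = any(s <= t.cds_start < e for s, e in t.exons)
    in_exon &= any(s < t.cds_end <= e for s, e in t.exons)
    if not in_exon:
        raise ValueError(f"{gene_id}/{t.transcript_id}: CDS boundary falls in an intron")


def _check_cds_multiple_of_3(model: GeneModel) -> GeneModel:
    """Drop coding transcripts whose CDS length is not a positive multiple of 3."""
    kept = []
    for t in model.transcripts:
        validate_transcript(t, model.gene_id)
        L = t.cds_length()
        if L <= 0 or L % 3 != 0:
            logger.warning("excluding %s/%s: CDS length %d not a positive multiple of 3",
                           model.gene_id, t.transcript_id, L)
            continue
        kept.append(t)
    return GeneModel(model.gene_id, model.chrom, model.strand, kept)


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED12 or GFF3 into internal 0-based half-open
    coordinates. ``fmt`` is inferred from the file extension when omitted.

    BED12 ``name`` fields use the ``gene_id|transcript_id`` convention; a name
    without ``|`` serves as both identifiers.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed12"
    if fmt == "bed12":
        models = _read_bed12(path)
    elif fmt == "gff3":
        models = _read_gff3(path)
    else:
        raise ValueError(f"unknown gene-model format: {fmt}")
    return [m for m in (_check_cds_multiple_of_3(g) for g in models) if m.transcripts]


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: blockCount does not match block lists")
            exons = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
            end = int(f[2])
            if exons[0][0] != start or exons[-1][1] != end:
                raise ValueError(f"{path}:{lineno}: exon outside transcript span")
            gene_id, _, tx_id = name.partition("|")
            tx_id = tx_id or gene_id
            t = Transcript(tx_id, exons, thick_start, thick_end)
            g = genes.setdefault(gene_id, GeneModel(gene_id, chrom, strand, []))
            if (g.chrom, g.strand) != (chrom, strand):
                raise ValueError(f"{path}:{lineno}: {gene_id} transcripts disagree on chrom/strand")
            g.transcripts.append(t)
    return list(genes.values())


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for gene in db.features_of_type("gene"):
        if gene.strand not in "+-":
            raise ValueError(f"{path}: gene {gene.id}: unknown strand {gene.strand!r}")
        gid = gene.attributes.get("Name", [gene.id])[0]
        model = GeneModel(gid, gene.seqid, gene.strand, [])
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = sorted((e.start - 1, e.end)
                           for e in db.children(mrna, featuretype="exon"))
            cds = sorted((c.start - 1, c.end)
                         for c in db.children(mrna, featuretype="CDS"))
            if not exons or not cds:
                continue
            span = (exons[0][0], exons[-1][1])
            for s, e in exons:
                if s < span[0] or e > span[1]:
                    raise ValueError(f"{path}: exon outside transcript span in {mrna.id}")
            model.transcripts.append(
                Transcript(mrna.id, exons, cds[0][0], cds[-1][1]))
        genes.append(model)
    return genes


def write_gene_models_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    """Serialize gene models as BED12, one line per transcript
    (name = ``gene_id|transcript_id``)."""
    with open(path, "w") as fh:
        for g in models:
            for t in g.transcripts:
                start, end = t.span()
                sizes = ",".join(str(e - s) for s, e in t.exons)
                offsets = ",".join(str(s - start) for s, _ in t.exons)
                fh.write("\t".join(map(str, [
                    g.chrom, start, end, f"{g.gene_id}|{t.transcript_id}", 0,
                    g.strand, t.cds_start, t.cds_end, 0, len(t.exons),
                    sizes, offsets])) + "\n")


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, rng = region.partition(":")
    if not rng:
        return chrom, 1, 2**31 - 1
    start, _, end = rng.partition("-")
    return chrom, int(start), int(end)


def read_genotypes(path: str | Path, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into one site per ALT; ``|`` separators
    yield ``phased=True``; ``.`` alleles become :data:`MISSING`; haploid calls
    put :data:`HAPLOID` in the second slot. ``region`` is ``chrom[:start-end]``,
    1-based inclusive.
    """
    want = _parse_region(region) if region else None
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    sites: list[VariantSite] = []
    all_rows: list[np.ndarray] = []
    phased_rows: list[np.ndarray] = []
    for rec in vf:
        if want is not None:
            if rec.chrom != want[0] or not (want[1] <= rec.pos <= want[2]):
                continue
        if rec.alts is None:
            continue
        if "GT" not in rec.format:
            raise ValueError(f"record {rec.chrom}:{rec.pos}: missing GT format field")
        gts = []
        phs = []
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or len(gt) == 0:
                raise ValueError(f"record {rec.chrom}:{rec.pos}: malformed GT for sample {s}")
            gts.append(gt)
            # a haploid call carries no phase information
            phs.append(call.phased and len(gt) > 1)
        for j, alt in enumerate(rec.alts, start=1):
            row = np.zeros((len(samples), 2), dtype=np.int8)
            for si, gt in enumerate(gts):
                for k in range(2):
                    if k >= len(gt):
                        row[si, k] = HAPLOID
                    elif gt[k] is None:
                        row[si, k] = MISSING
                    else:
                        row[si, k] = 1 if gt[k] == j else 0
                if row[si, 0] == MISSING:
                    row[si, 1] = MISSING if len(gt) > 1 else HAPLOID
            sites.append(VariantSite(rec.chrom, rec.pos, rec.ref, alt))
            all_rows.append(row)
            phased_rows.append(np.array(phs, dtype=bool))
    vf.close()
    n_v = len(sites)
    alleles = (np.stack(all_rows) if n_v else
               np.zeros((0, len(samples), 2), dtype=np.int8))
    phased = (np.stack(phased_rows) if n_v else
              np.zeros((0, len(samples)), dtype=bool))
    return GenotypeMatrix(sites, samples, alleles, phased)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only FORMAT. Deterministic: the same
    matrix always serializes to the same bytes, so read→write round-trips
    are bit-for-bit stable."""
    chroms = list(dict.fromkeys(v.chrom for v in gm.variants))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=koassoc\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for vi, v in enumerate(gm.variants):
            gts = []
            for si in range(gm.n_samples):
                a1, a2 = gm.alleles[vi, si]
                sep = "|" if gm.phased[vi, si] else "/"
                s1 = "." if a1 == MISSING else str(int(a1))
                if a2 == HAPLOID:
                    gts.append(s1)
                else:
                    s2 = "." if a2 == MISSING else str(int(a2))
                    gts.append(s1 + sep + s2)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# sample / phenotype tables, gene sets, result tables
# ---------------------------------------------------------------------------

def read_samples(path: str | Path) -> pd.DataFrame:
    """Read the sample table (TSV: sample_id, sex, stratum). Sexes are
    normalized to {male, female, unknown}; sample_ids must be unique and
    strata non-empty."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex", "stratum"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample table must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup}")
    if df["stratum"].isna().any() or (df["stratum"].str.len() == 0).any():
        raise ValueError("empty stratum label")
    sex = df["sex"].str.lower().map({"male": "male", "m": "male", "1": "male",
                                     "female": "female", "f": "female", "2": "female"})
    df["sex"] = sex.fillna("unknown")
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype/covariate table (TSV with a sample_id column).
    Missing values stay NaN — they are never silently zero-filled."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table must have a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValueError("phenotype table has duplicated sample_ids")
    return df


def read_gene_set(path: str | Path) -> set[str]:
    """Read a candidate-gene list: one symbol per line, ``#`` comments allowed,
    deduplicated, case preserved."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    if not out:
        logger.warning("gene set %s is empty", path)
    return out


def summarize_gene_set(gene_set: set[str], known_genes: Iterable[str]) -> dict:
    """Report how a gene set overlaps the annotation (symbols are matched as
    plain strings; no alias resolution)."""
    known = set(known_genes)
    unmatched = gene_set - known
    if unmatched:
        logger.info("%d gene-set symbols not present in the gene models", len(unmatched))
    return {"n_set": len(gene_set), "n_matched": len(gene_set & known),
            "n_unmatched": len(unmatched), "unmatched": sorted(unmatched)}


ASSOC_COLUMNS = ["gene", "trait", "stratum", "N_KO", "mean_SD", "mean_metric",
                 "count_le", "count_ge", "P_left", "P_right", "P_final", "n_perm"]


def write_association_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write association results as TSV at full float precision (the table
    round-trips losslessly through :func:`read_association_table`; any display
    rounding belongs to report formatting, not to this file)."""
    df = results.copy()
    for col in ASSOC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[ASSOC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_association_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
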