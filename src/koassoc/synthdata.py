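"""Fully synthetic cohorts for end-to-end testing of the KO pipeline.

The generator emits everything the pipeline consumes — a phased VCF, a
sample table, a phenotype/covariate table, BED12 gene models, a CDS sequence
table — plus a truth ledger recording every planted KO (sample, gene,
mechanism, cis/trans) and effect size.

What it emulates: rare LoF variants of the four consequence classes placed
in generated coding sequences; Hardy-Weinberg diploid genotypes from
stratum-specific allele frequencies (haplotypes drawn independently, so both
homozygous and compound-heterozygous KOs arise); male hemizygous X calls
outside the PAR; and normally distributed phenotypes built from a covariate
linear predictor plus per-gene KO mean shifts (applied on the raw-trait
scale, to individuals whose genotypes realize a KO under the trans rule)
plus Gaussian noise. What it does not model: linkage disequilibrium,
genotyping error, coverage heterogeneity, or admixture beyond per-stratum
allele frequencies.

Identical config (including seed) reproduces byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (GeneModel, GenotypeMatrix, Transcript, VariantSite,
                         HAPLOID, write_gene_models_bed12, write_genotypes)
from .lof_annotate import LofClass, revcomp

logger = logging.getLogger(__name__)

_SAFE_CODONS = sorted({a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
                      - {"TAA", "TAG", "TGA"})


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a sequencing-study stratum: a few thousand samples, a
    BMI-like trait (population mean ~27, SD ~4.5 raw units), genes of four
    40-codon exons, and rare LoF sites (per-stratum MAF uniform below 5%).
    ``effects`` maps gene_id -> KO mean shift in SD units; ``cis_fraction``
    forces the phase arrangement of two-het samples (None = natural 50/50);
    genes in ``force_cis_genes`` get every multi-het sample arranged in cis.
    """

    n_samples: int = 2000
    strata: dict[str, float] = field(default_factory=lambda: {"EA": 1.0})
    n_genes: int = 50
    exons_per_gene: int = 4
    codons_per_exon: int = 40
    lof_sites_per_gene: int = 3
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "nonsense": 0.4, "frameshift": 0.3, "splice_site": 0.2, "stop_loss": 0.1})
    maf_range: tuple[float, float] = (0.005, 0.045)
    maf_max: float = 0.05
    effects: dict[str, float] = field(default_factory=dict)
    cis_fraction: float | None = None
    force_cis_genes: tuple[str, ...] = ()
    n_x_genes: int = 0
    male_fraction: float = 0.5
    minus_strand_fraction: float = 0.3
    trait_name: str = "trait"
    trait_intercept: float = 27.0
    sex_effect: float = 1.5
    age_effect: float = 0.02
    age2_effect: float = 0.0
    pc_effects: tuple[float, ...] = (0.5, -0.3)
    noise_sd: float = 4.5
    seed: int = 0


@dataclass
class Cohort:
    """In-memory synthetic cohort plus ground truth."""

    config: SyntheticCohortConfig
    gm: GenotypeMatrix
    models: list[GeneModel]
    cds_seqs: dict[str, str]
    samples: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame                  # sample_id, gene, mechanism, effect_sd
    variant_truth: pd.DataFrame          # chrom, pos, ref, alt, gene, lof_class

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "samples": outdir / "samples.tsv",
            "phenotypes": outdir / "phenotypes.tsv",
            "gene_models": outdir / "gene_models.bed",
            "cds": outdir / "cds_sequences.tsv",
            "truth": outdir / "truth.tsv",
            "variant_truth": outdir / "variant_truth.tsv",
        }
        write_genotypes(self.gm, paths["vcf"])
        write_gene_models_bed12(self.models, paths["gene_models"])
        self.samples.to_csv(paths["samples"], sep="\t", index=False)
        self.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
        pd.DataFrame({"transcript_id": list(self.cds_seqs),
                      "cds_seq": list(self.cds_seqs.values())}
                     ).to_csv(paths["cds"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.variant_truth.to_csv(paths["variant_truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _build_gene(gid: str, chrom: str, start: int, strand: str,
                cfg: SyntheticCohortConfig, rng: np.random.Generator
                ) -> tuple[GeneModel, str]:
    exon_len = cfg.codons_per_exon * 3
    intron_len = 500
    exons = []
    pos = start
    for _ in range(cfg.exons_per_gene):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    t = Transcript(gid + ".t1", exons, exons[0][0], exons[-1][1])
    n_codons = cfg.exons_per_gene * cfg.codons_per_exon
    codons = list(rng.choice(_SAFE_CODONS, size=n_codons - 1))
    seq = "".join(codons) + "TAA"
    return GeneModel(gid, chrom, strand, [t]), seq


def _cds_genomic_positions(t: Transcript) -> np.ndarray:
    return np.concatenate([np.arange(s, e) for s, e in t.exons])


def _genome_base(seq: str, cds_pos: np.ndarray, strand: str, p: int) -> str:
    """Plus-strand genome base at CDS genomic position p."""
    rank = int(np.searchsorted(cds_pos, p))
    L = len(cds_pos)
    return seq[rank] if strand == "+" else revcomp(seq[L - 1 - rank])


def _plan_lof_sites(model: GeneModel, seq: str, cfg: SyntheticCohortConfig,
                    rng: np.random.Generator
                    ) -> tuple[list[VariantSite], list[str], str]:
    """Plant ``lof_sites_per_gene`` variants of the configured class mix.

    Returns (sites, classes, possibly edited CDS sequence). Nonsense sites
    overwrite their codon with CAA so a single C->T substitution creates TAA;
    stop-loss mutates the terminal TAA; splice sites sit on the first
    intronic base of a donor junction; frameshifts are 2-bp deletions inside
    an exon. Raises if the gene cannot host the requested number of sites.
    """
    t = model.transcripts[0]
    cds_pos = _cds_genomic_positions(t)
    L = len(cds_pos)
    n_codons = L // 3
    cpe = cfg.codons_per_exon
    strand = model.strand

    names = list(cfg.class_mix)
    w = np.array([cfg.class_mix[c] for c in names], dtype=float)
    draws = list(rng.choice(names, size=cfg.lof_sites_per_gene, p=w / w.sum()))
    # at most one stop-loss (there is one stop codon) and a limited number of
    # internal donor junctions
    n_donors = len(t.exons) - 1
    while draws.count("stop_loss") > 1:
        draws[draws.index("stop_loss")] = "nonsense"
    while draws.count("splice_site") > n_donors:
        draws[draws.index("splice_site")] = "nonsense"

    codon_pool = [c for c in range(1, n_codons - 1)]
    rng.shuffle(codon_pool)
    fs_pool = [c for c in codon_pool if c % cpe != 0]
    donor_pool = list(rng.permutation(n_donors))
    seq_list = list(seq)
    sites: list[VariantSite] = []
    classes: list[str] = []

    def tx_to_genomic(i: int) -> int:
        return int(cds_pos[i] if strand == "+" else cds_pos[L - 1 - i])

    for cls in draws:
        if cls == "nonsense":
            if not codon_pool:
                raise ValueError(f"{model.gene_id}: more LoF sites than codons")
            c = codon_pool.pop()
            if c in fs_pool:
                fs_pool.remove(c)
            seq_list[3 * c:3 * c + 3] = "CAA"
            gp = tx_to_genomic(3 * c)
            ref, alt = ("C", "T") if strand == "+" else ("G", "A")
            sites.append(VariantSite(model.chrom, gp + 1, ref, alt))
        elif cls == "stop_loss":
            gp = tx_to_genomic(L - 3)        # first base of the TAA stop
            ref, alt = ("T", "C") if strand == "+" else ("A", "G")
            sites.append(VariantSite(model.chrom, gp + 1, ref, alt))
        elif cls == "splice_site":
            j = donor_pool.pop()
            gp = t.exons[j][1]               # first intronic base 3' of exon j
            sites.append(VariantSite(model.chrom, gp + 1, "G", "T"))
        elif cls == "frameshift":
            if not fs_pool:
                raise ValueError(f"{model.gene_id}: no codon left for a frameshift")
            c = fs_pool.pop()
            codon_pool.remove(c)
            seq_now = "".join(seq_list)
            if strand == "+":
                d1 = int(cds_pos[3 * c])
            else:
                d1 = int(cds_pos[L - 1 - (3 * c + 2)])
            anchor = d1 - 1                  # previous CDS base, same exon
            bases = [_genome_base(seq_now, cds_pos, strand, p)
                     for p in (anchor, d1, d1 + 1)]
            sites.append(VariantSite(model.chrom, anchor + 1, "".join(bases), bases[0]))
        else:
            raise ValueError(f"unknown LoF class in mix: {cls}")
        classes.append(cls)
    return sites, classes, "".join(seq_list)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate a full synthetic cohort from ``config`` (seeded)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    for name, frac in cfg.strata.items():
        if not 0 < frac <= 1:
            raise ValueError(f"stratum fraction for {name} outside (0, 1]")

    # --- samples -----------------------------------------------------------
    n = cfg.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]
    strat_names = sorted(cfg.strata)
    fracs = np.array([cfg.strata[s] for s in strat_names], dtype=float)
    strata = rng.choice(strat_names, size=n, p=fracs / fracs.sum())
    male = rng.random(n) < cfg.male_fraction
    age = rng.uniform(21, 80, size=n)
    pcs = rng.standard_normal((n, len(cfg.pc_effects)))
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "sex": np.where(male, "male", "female"),
        "stratum": strata,
    })

    # --- genes, sequences, planted LoF sites -------------------------------
    models: list[GeneModel] = []
    cds_seqs: dict[str, str] = {}
    all_sites: list[VariantSite] = []
    site_gene: list[str] = []
    site_class: list[str] = []
    gene_site_idx: dict[str, list[int]] = {}
    n_auto = cfg.n_genes - cfg.n_x_genes
    if n_auto < 0:
        raise ValueError("n_x_genes exceeds n_genes")
    for gi in range(cfg.n_genes):
        gid = f"G{gi:04d}"
        on_x = gi >= n_auto
        if on_x:
            chrom = "X"
            start = 3_000_000 + (gi - n_auto) * 1_000_000   # outside PAR1
        else:
            chrom = str(gi % 22 + 1)
            start = 1_000_000 + (gi // 22) * 1_000_000
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        model, seq = _build_gene(gid, chrom, start, strand, cfg, rng)
        sites, classes, seq = _plan_lof_sites(model, seq, cfg, rng)
        models.append(model)
        cds_seqs[model.transcripts[0].transcript_id] = seq
        gene_site_idx[gid] = list(range(len(all_sites), len(all_sites) + len(sites)))
        all_sites.extend(sites)
        site_gene.extend([gid] * len(sites))
        site_class.extend(classes)

    # --- genotypes ---------------------------------------------------------
    n_var = len(all_sites)
    alleles = np.zeros((n_var, n, 2), dtype=np.int8)
    phased = np.ones((n_var, n), dtype=bool)
    stratum_of = pd.Series(strata).to_numpy()
    maf_rows = []
    for vi, site in enumerate(all_sites):
        on_x = site.chrom == "X"
        mafs = {s: rng.uniform(*cfg.maf_range) for s in strat_names}
        maf_rows.append(mafs)
        maf_vec = np.array([mafs[s] for s in stratum_of])
        hap = rng.random((n, 2)) < maf_vec[:, None]
        alleles[vi] = hap.astype(np.int8)
        if on_x:
            alleles[vi, male, 1] = HAPLOID
            phased[vi, male] = False

    _arrange_phase(cfg, rng, alleles, gene_site_idx, all_sites, male)

    gm = GenotypeMatrix(all_sites, sample_ids, alleles, phased)

    # --- ground-truth KO bookkeeping ---------------------------------------
    truth_rows = []
    ko_shift = np.zeros(n)
    for gid, vids in gene_site_idx.items():
        sub = alleles[vids]                            # (n_var, n, 2)
        on_x = all_sites[vids[0]].chrom == "X"
        is_alt = sub == 1
        for si in np.nonzero(is_alt.any(axis=(0, 2)))[0]:
            a = sub[:, si, :]
            if on_x and male[si]:
                mech = "hemizygous"
            elif ((a == 1).sum(axis=1) == 2).any():
                mech = "homozygous"
            else:
                het = (a == 1).sum(axis=1) == 1
                if het.sum() < 2:
                    continue
                on_h1 = (a[het, 0] == 1)
                mech = "compound_het" if (on_h1.any() and (~on_h1).any()) else "cis_pair"
            eff = cfg.effects.get(gid, 0.0)
            truth_rows.append({"sample_id": sample_ids[si], "gene": gid,
                               "mechanism": mech,
                               "effect_sd": eff if mech != "cis_pair" else 0.0})
            if mech != "cis_pair" and eff:
                ko_shift[si] += eff * cfg.noise_sd
    truth = pd.DataFrame(truth_rows,
                         columns=["sample_id", "gene", "mechanism", "effect_sd"])

    # --- phenotype ---------------------------------------------------------
    trait = (cfg.trait_intercept
             + cfg.sex_effect * male
             + cfg.age_effect * age
             + cfg.age2_effect * age ** 2
             + pcs @ np.array(cfg.pc_effects)
             + ko_shift
             + cfg.noise_sd * rng.standard_normal(n))
    pheno = pd.DataFrame({"sample_id": sample_ids, cfg.trait_name: trait,
                          "sex_code": male.astype(int), "age": age,
                          "age2": age ** 2})
    for j in range(len(cfg.pc_effects)):
        pheno[f"PC{j + 1}"] = pcs[:, j]

    variant_truth = pd.DataFrame({
        "chrom": [s.chrom for s in all_sites],
        "pos": [s.pos for s in all_sites],
        "ref": [s.ref for s in all_sites],
        "alt": [s.alt for s in all_sites],
        "gene": site_gene,
        "lof_class": site_class,
    })
    for s in strat_names:
        variant_truth[f"maf_{s}"] = [m[s] for m in maf_rows]

    return Cohort(cfg, gm, models, cds_seqs, samples, pheno, truth, variant_truth)


def _arrange_phase(cfg, rng, alleles, gene_site_idx, all_sites, male) -> None:
    """Rearrange haplotype assignment of heterozygous sites without touching
    genotypes: forced-cis genes put every het ALT on haplotype 1; elsewhere,
    samples het at exactly two sites follow ``cis_fraction`` when set."""
    force = set(cfg.force_cis_genes)
    if cfg.cis_fraction is None and not force:
        return
    for gid, vids in gene_site_idx.items():
        if all_sites[vids[0]].chrom == "X":
            continue
        sub = alleles[vids]
        het = (sub == 1).sum(axis=2) == 1              # (n_var, n)
        for si in np.nonzero(het.sum(axis=0) >= 2)[0]:
            rows = [v for k, v in enumerate(vids) if het[k, si]]
            if gid in force:
                for v in rows:
                    alleles[v, si] = (1, 0)
            elif cfg.cis_fraction is not None and len(rows) == 2:
                same = rng.random() < cfg.cis_fraction
                alleles[rows[0], si] = (1, 0)
                alleles[rows[1], si] = (1, 0) if same else (0, 1)


# ---------------------------------------------------------------------------
# phase stripping
# ---------------------------------------------------------------------------

def strip_phase(in_vcf: str | Path, out_vcf: str | Path) -> None:
    """Rewrite a phased VCF with phase removed: every ``|`` separator becomes
    ``/`` with the allele order canonicalized (REF allele first). Everything
    else is byte-identical; genotype dosages are unchanged."""
    with open(in_vcf) as fin, open(out_vcf, "w") as fout:
        for line in fin:
            if line.startswith("#"):
                fout.write(line)
                continue
            f = line.rstrip("\n").split("\t")
            fmt = f[8].split(":")
            gt_i = fmt.index("GT")
            for col in range(9, len(f)):
                parts = f[col].split(":")
                gt = parts[gt_i]
                if "|" in gt:
                    a = gt.split("|")
                    a.sort(key=lambda x: (x == ".", x))
                    parts[gt_i] = "/".join(a)
                    f[col] = ":".join(parts)
            fout.write("\t".join(f) + "\n")
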