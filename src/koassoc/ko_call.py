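"""Predicted gene-knockout calling.

An individual is a predicted KO for a gene when both gene copies carry a
loss-of-function allele:

* **homozygous** — both alleles ALT at a single LoF site;
* **compound heterozygous** — two different heterozygous LoF variants on
  opposite haplotypes (in *trans*). With phased genotypes the phase decides
  cis vs trans; without phase, rare LoF variants are assumed to be in trans
  (the exome-array convention), so any two heterozygous LoF sites qualify;
* **hemizygous** — males carrying a single LoF allele at an X-linked site
  outside the pseudoautosomal regions (PAR).

GRCh37 PAR coordinates ship with the package (``data/par_grch37.bed``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, VariantSite, MISSING, HAPLOID
from .lof_annotate import LofVariant

logger = logging.getLogger(__name__)

X_CHROM_NAMES = {"X", "chrX", "23"}


@dataclass
class KOCall:
    gene_id: str
    sample_id: str
    mechanism: str                        # homozygous | compound_het | hemizygous
    variants: list[VariantSite] = field(default_factory=list)


class KOMatrix:
    """gene_id -> {sample_id -> KOCall}; genes with zero KOs are absent."""

    def __init__(self):
        self.calls: dict[str, dict[str, KOCall]] = {}

    def add(self, call: KOCall) -> None:
        self.calls.setdefault(call.gene_id, {})[call.sample_id] = call

    @property
    def genes(self) -> list[str]:
        return sorted(self.calls)

    def ko_samples(self, gene_id: str) -> set[str]:
        return set(self.calls.get(gene_id, {}))

    def n_calls(self) -> int:
        return sum(len(v) for v in self.calls.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, "sample_id": s, "mechanism": c.mechanism,
                 "variants": ";".join(str(v) for v in c.variants)}
                for g in self.genes for s, c in sorted(self.calls[g].items())]
        return pd.DataFrame(rows, columns=["gene", "sample_id", "mechanism", "variants"])


def load_par_regions(path: str | Path | None = None) -> list[tuple[str, int, int]]:
    """PAR intervals as (chrom, start0, end0); defaults to the bundled GRCh37 file."""
    if path is None:
        with resources.files("koassoc.data").joinpath("par_grch37.bed").open() as fh:
            lines = fh.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    out = []
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        c, s, e = line.split("\t")[:3]
        out.append((c, int(s), int(e)))
    return out


def _in_par(site: VariantSite, par: list[tuple[str, int, int]]) -> bool:
    p0 = site.pos - 1
    return any(site.chrom == c and s <= p0 < e for c, s, e in par)


def call_gene_kos(gm: GenotypeMatrix, lof_variants: list[LofVariant],
                  samples: pd.DataFrame, phase_policy: str = "use_phase",
                  par_regions: list[tuple[str, int, int]] | None = None,
                  maf_threshold: float = 0.05,
                  x_het_policy: str = "carrier") -> KOMatrix:
    """Call predicted KOs for every gene with QC-passing LoF variants.

    ``phase_policy``:

    * ``use_phase`` — a compound het requires at least one pair of
      heterozygous LoF sites whose phased ALT alleles sit on opposite
      haplotypes; unphased heterozygous pairs cannot establish trans and do
      not qualify.
    * ``assume_trans_if_rare`` — any two distinct heterozygous LoF sites
      (each with stratum MAF below ``maf_threshold``) qualify, regardless of
      phase encoding.

    A variant only counts for a sample if it passed QC in that sample's
    stratum. Missing genotypes contribute nothing; the sample stays eligible
    as non-KO. ``x_het_policy`` controls heterozygous male calls at X
    non-PAR sites: ``carrier`` treats them as one LoF allele (KO, with a
    warning), ``missing`` ignores them.
    """
    if phase_policy not in ("use_phase", "assume_trans_if_rare"):
        raise ValueError(f"unknown phase policy: {phase_policy}")
    if x_het_policy not in ("carrier", "missing"):
        raise ValueError(f"unknown X het policy: {x_het_policy}")
    par = par_regions if par_regions is not None else load_par_regions()

    sidx = gm.sample_index()
    info = samples.set_index("sample_id")
    stratum = info["stratum"].to_dict()
    is_male = (info["sex"] == "male").to_dict()

    by_gene: dict[str, list[LofVariant]] = {}
    for lv in lof_variants:
        by_gene.setdefault(lv.gene_id, []).append(lv)

    kom = KOMatrix()
    for gene_id in sorted(by_gene):
        variants = sorted(by_gene[gene_id], key=lambda lv: (lv.site.chrom, lv.site.pos,
                                                            lv.site.ref, lv.site.alt))
        vi = np.array([lv.index for lv in variants])
        alle = gm.alleles[vi]                       # (n_var, n_samp, 2)
        carrier = (alle == 1).any(axis=0)           # any ALT in either slot
        for si in np.nonzero(carrier.any(axis=1))[0]:
            sid = gm.samples[si]
            if sid not in stratum:
                continue
            st = stratum[sid]
            male = bool(is_male.get(sid, False))
            call = _call_sample(gene_id, sid, st, male, variants, alle[:, si, :],
                                gm.phased[vi, si], phase_policy, par,
                                maf_threshold, x_het_policy)
            if call is not None:
                kom.add(call)
    return kom


def _call_sample(gene_id, sid, stratum, male, variants, alle, phased,
                 phase_policy, par, maf_threshold, x_het_policy) -> KOCall | None:
    hom_sites, het = [], []          # het: (variant, hap_assignment or None)
    hemi_sites = []
    for k, lv in enumerate(variants):
        if stratum not in lv.passing_strata:
            continue
        a1, a2 = int(alle[k, 0]), int(alle[k, 1])
        if a1 == MISSING:
            continue
        x_nonpar = lv.site.chrom in X_CHROM_NAMES and not _in_par(lv.site, par)
        if a2 == HAPLOID:
            if a1 == 1 and male and x_nonpar:
                hemi_sites.append(lv)
            continue
        if a2 == MISSING:
            continue
        n_alt = (a1 == 1) + (a2 == 1)
        if n_alt == 2:
            if male and x_nonpar:
                hemi_sites.append(lv)
            else:
                hom_sites.append(lv)
        elif n_alt == 1:
            if male and x_nonpar:
                if x_het_policy == "carrier":
                    logger.warning("heterozygous male call at X non-PAR site %s "
                                   "(sample %s): counted as carrier", lv.site, sid)
                    hemi_sites.append(lv)
                continue
            hap = (0 if a1 == 1 else 1) if phased[k] else None
            het.append((lv, hap))

    if hemi_sites:
        return KOCall(gene_id, sid, "hemizygous", [lv.site for lv in hemi_sites])
    if hom_sites:
        return KOCall(gene_id, sid, "homozygous", [hom_sites[0].site])
    if len(het) >= 2:
        if phase_policy == "assume_trans_if_rare":
            rare = [lv for lv, _ in het
                    if lv.maf_by_stratum.get(stratum, 1.0) < maf_threshold]
            if len(rare) >= 2:
                return KOCall(gene_id, sid, "compound_het", [lv.site for lv in rare])
        else:
            haps = [h for _, h in het]
            if 0 in haps and 1 in haps:        # some pair sits in trans
                sites = [lv.site for lv, h in het if h is not None]
                return KOCall(gene_id, sid, "compound_het", sites)
    return None


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def ko_summary(kom: KOMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum KO summary: mean gene KOs per individual, number of KO
    genes, counts of genes split by mechanism, and the gene-sharing histogram
    (how many genes are knocked out in exactly k individuals)."""
    info = samples.set_index("sample_id")
    strata = sorted(info["stratum"].unique())
    rows = []
    for st in strata:
        sids = set(info.index[info["stratum"] == st])
        n = len(sids)
        per_gene_counts: dict[str, int] = {}
        mech_genes = {"homozygous": set(), "compound_het": set(), "hemizygous": set()}
        total_calls = 0
        for g, calls in kom.calls.items():
            cnt = 0
            for sid, c in calls.items():
                if sid in sids:
                    cnt += 1
                    total_calls += 1
                    mech_genes[c.mechanism].add(g)
            if cnt:
                per_gene_counts[g] = cnt
        hist: dict[int, int] = {}
        for cnt in per_gene_counts.values():
            hist[cnt] = hist.get(cnt, 0) + 1
        rows.append({
            "stratum": st,
            "n_samples": n,
            "gene_kos_per_individual": total_calls / n if n else 0.0,
            "n_ko_genes": len(per_gene_counts),
            "n_genes_homozygous": len(mech_genes["homozygous"]),
            "n_genes_compound_het": len(mech_genes["compound_het"]),
            "n_genes_hemizygous": len(mech_genes["hemizygous"]),
            "sharing_hist": ";".join(f"{k}:{v}" for k, v in sorted(hist.items())),
        })
    return pd.DataFrame(rows)
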