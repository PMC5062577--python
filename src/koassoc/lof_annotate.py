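"""Loss-of-function consequence calling and variant QC.

A variant is classified against each transcript of a gene model into one of
four LoF classes — nonsense (stop gained), stop-loss, essential splice site,
frameshift indel — or ``not_lof``. Classification is strand-aware: codons are
read in transcription order and ALT alleles of minus-strand genes are
reverse-complemented before any codon logic.

Two splice-window conventions are supported:

* ``intronic2`` — the two intronic bases adjacent to each internal exon
  boundary (the classic "essential splice site");
* ``flank2`` — two bases on *both* sides of each internal boundary, the wider
  definition used for exome-array annotations.

QC follows the usual rare-variant filters: per-stratum call rate, exact
Hardy–Weinberg test, and a MAF ceiling (default 5%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import (GeneModel, GenotypeMatrix, Transcript, VariantSite,
                         MISSING, HAPLOID)

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class LofClass(str, Enum):
    nonsense = "nonsense"
    stop_loss = "stop_loss"
    splice_site = "splice_site"
    frameshift = "frameshift"
    not_lof = "not_lof"


#: most severe first; used by gene-level aggregation
SEVERITY = [LofClass.nonsense, LofClass.frameshift, LofClass.splice_site,
            LofClass.stop_loss]


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

def splice_windows(t: Transcript, mode: str = "intronic2") -> list[tuple[int, int]]:
    """Splice windows (0-based half-open) around *internal* exon boundaries.

    Transcript-terminal boundaries carry no splicing and get no window; a
    single-exon transcript therefore has none.
    """
    if mode not in ("intronic2", "flank2"):
        raise ValueError(f"unknown splice mode: {mode}")
    wins = []
    n = len(t.exons)
    for i, (s, e) in enumerate(t.exons):
        if i < n - 1:                      # boundary at the exon 3' end (genomic)
            wins.append((e, e + 2))
            if mode == "flank2":
                wins.append((e - 2, e))
        if i > 0:                          # boundary at the exon 5' start (genomic)
            wins.append((s - 2, s))
            if mode == "flank2":
                wins.append((s, s + 2))
    return wins


def _cds_positions(t: Transcript) -> np.ndarray:
    """Genomic positions (0-based, ascending) of the transcript's CDS bases."""
    parts = [np.arange(s, e) for s, e in t.cds_intervals()]
    return np.concatenate(parts) if parts else np.empty(0, dtype=int)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_variant(variant: VariantSite, model: GeneModel,
                     reference_cds: dict[str, str],
                     splice_mode: str = "intronic2") -> dict[str, LofClass]:
    """Classify ``variant`` against every transcript of ``model``.

    ``reference_cds`` maps transcript_id to the CDS sequence in transcription
    direction (including the stop codon); its length must equal the model's
    CDS length. Coding consequences (nonsense / stop-loss / frameshift) take
    precedence over splice-window hits when a variant qualifies for both.
    A variant that does not touch the gene is simply ``not_lof``.
    """
    out: dict[str, LofClass] = {}
    for t in model.transcripts:
        out[t.transcript_id] = _classify_one(variant, model, t,
                                             reference_cds[t.transcript_id],
                                             splice_mode)
    return out


def _classify_one(v: VariantSite, model: GeneModel, t: Transcript, seq: str,
                  splice_mode: str) -> LofClass:
    cds_pos = _cds_positions(t)
    L = len(cds_pos)
    if len(seq) != L:
        raise ValueError(f"{model.gene_id}/{t.transcript_id}: reference CDS length "
                         f"{len(seq)} != model CDS length {L}")
    pos0 = v.pos - 1
    minus = model.strand == "-"
    wins = splice_windows(t, splice_mode)

    if v.is_snv:
        hit = np.searchsorted(cds_pos, pos0)
        if hit < L and cds_pos[hit] == pos0:
            # index along the mRNA (transcription order)
            i = int(L - 1 - hit) if minus else int(hit)
            ref_b = revcomp(v.ref) if minus else v.ref
            alt_b = revcomp(v.alt) if minus else v.alt
            if seq[i].upper() != ref_b.upper():
                raise ValueError(
                    f"{model.gene_id}/{t.transcript_id}: reference CDS base "
                    f"{seq[i]!r} at CDS index {i} does not match variant REF {v.ref!r}")
            if ref_b.upper() == alt_b.upper():
                raise ValueError(f"variant {v}: ALT equals REF after strand normalization")
            ci = i // 3
            codon = seq[3 * ci:3 * ci + 3].upper()
            new = codon[:i % 3] + alt_b.upper() + codon[i % 3 + 1:]
            last = ci == L // 3 - 1
            if last and codon in STOP_CODONS and new not in STOP_CODONS:
                return LofClass.stop_loss
            if new in STOP_CODONS and codon not in STOP_CODONS and not last:
                return LofClass.nonsense
        if any(w[0] <= pos0 < w[1] for w in wins):
            return LofClass.splice_site
        return LofClass.not_lof

    # indel: the affected genomic interval is the deleted span (after the
    # anchor base) for deletions/substitutions, or the two bases flanking the
    # insertion point for pure insertions
    net = len(v.alt) - len(v.ref)
    if len(v.ref) > 1:
        interval = (pos0 + 1, pos0 + len(v.ref))
    else:
        interval = (pos0, pos0 + 2)
    touches_cds = any(_overlaps(interval, c) for c in t.cds_intervals())
    if touches_cds and net % 3 != 0:
        return LofClass.frameshift
    if any(_overlaps(interval, w) for w in wins):
        return LofClass.splice_site
    return LofClass.not_lof


def aggregate_gene_class(per_transcript: list[LofClass], mode: str = "any") -> LofClass:
    """Collapse per-transcript calls to one gene-level class.

    ``any``: the most severe LoF class over transcripts (LoF if any transcript
    is LoF). ``all``: LoF only if *every* transcript is LoF — the conservative
    all-transcripts sensitivity mode — reporting the first transcript's class.
    """
    if not per_transcript:
        raise ValueError("no transcript classifications to aggregate")
    if mode == "any":
        for cls in SEVERITY:
            if cls in per_transcript:
                return cls
        return LofClass.not_lof
    if mode == "all":
        if all(c != LofClass.not_lof for c in per_transcript):
            return per_transcript[0]
        return LofClass.not_lof
    raise ValueError(f"unknown transcript aggregation mode: {mode}")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed one
    (two-sided, no mid-p). Monomorphic sites return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom_alt + n_het          # minor allele count (either allele works)
    n_b = 2 * n_hom_ref + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het = h | n, allele counts) up to a shared constant:
    # multinomial over (hom_rare, het, hom_common) with 2^het phase factor
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = hets * np.log(2) - (gammaln(hets + 1) + gammaln(hom_rare + 1)
                               + gammaln(hom_common + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    maf_max: float = 0.05


@dataclass
class LofVariant:
    """A LoF-classified variant with per-stratum QC statistics.

    ``passing_strata`` lists the strata in which the variant survives all
    filters (call rate, HWE, 0 < MAF < maf_max); downstream KO calling only
    counts a variant for samples whose stratum is in that set.
    """

    site: VariantSite
    gene_id: str
    lof_class: LofClass
    index: int                             # row in the source GenotypeMatrix
    maf_by_stratum: dict[str, float] = field(default_factory=dict)
    call_rate_by_stratum: dict[str, float] = field(default_factory=dict)
    hwe_p_by_stratum: dict[str, float] = field(default_factory=dict)
    passing_strata: set[str] = field(default_factory=set)


def _stratum_masks(gm: GenotypeMatrix, samples: pd.DataFrame) -> dict[str, np.ndarray]:
    idx = gm.sample_index()
    unknown = set(samples["sample_id"]) - set(idx)
    strat = dict(zip(samples["sample_id"], samples["stratum"]))
    masks: dict[str, np.ndarray] = {}
    for s in sorted(samples["stratum"].unique()):
        mask = np.zeros(gm.n_samples, dtype=bool)
        for sid, st in strat.items():
            if st == s and sid in idx:
                mask[idx[sid]] = True
        masks[s] = mask
    missing = [s for s in gm.samples if s not in strat]
    if missing:
        raise ValueError(f"no stratum label for samples: {missing[:5]}")
    if unknown:
        logger.info("%d sample-table rows absent from the VCF", len(unknown))
    return masks


def variant_qc(gm: GenotypeMatrix, samples: pd.DataFrame,
               thresholds: QCThresholds | None = None,
               hwe_pooled: bool = False) -> pd.DataFrame:
    """Per-variant, per-stratum QC statistics and pass/fail with reasons.

    Call rate counts samples with a called genotype (haploid calls count).
    MAF is the folded frequency over called alleles only. The HWE test uses
    diploid genotypes only (haploid X calls are excluded); with
    ``hwe_pooled`` the test pools all strata but call rate and MAF stay
    stratified.
    """
    thr = thresholds or QCThresholds()
    masks = _stratum_masks(gm, samples)
    rows = []
    for vi in range(gm.n_variants):
        a = gm.alleles[vi]
        if hwe_pooled:
            pooled_hwe = _hwe_from_alleles(a, np.ones(gm.n_samples, dtype=bool))
        for stratum, mask in masks.items():
            sub = a[mask]
            called = sub[:, 0] != MISSING
            call_rate = called.mean() if mask.any() else np.nan
            n_alt = int((sub == 1).sum())
            n_called_alleles = int(((sub == 0) | (sub == 1)).sum())
            af = n_alt / n_called_alleles if n_called_alleles else np.nan
            maf = min(af, 1 - af) if n_called_alleles else np.nan
            hwe_p = pooled_hwe if hwe_pooled else _hwe_from_alleles(a, mask)
            reasons = []
            if not call_rate >= thr.call_rate_min:
                reasons.append("call_rate")
            if not hwe_p >= thr.hwe_p_min:
                reasons.append("hwe")
            if not (0 < maf < thr.maf_max):
                reasons.append("maf")
            rows.append({"variant_index": vi, "stratum": stratum,
                         "call_rate": call_rate, "maf": maf, "alt_af": af,
                         "hwe_p": hwe_p, "pass": not reasons,
                         "reasons": ",".join(reasons)})
    return pd.DataFrame(rows)


def _hwe_from_alleles(a: np.ndarray, mask: np.ndarray) -> float:
    sub = a[mask]
    diploid = (sub[:, 0] >= 0) & (sub[:, 1] >= 0)
    d = sub[diploid]
    if len(d) == 0:
        return 1.0
    alt = (d == 1).sum(axis=1)
    return hwe_exact_test(int((alt == 0).sum()), int((alt == 1).sum()),
                          int((alt == 2).sum()))


def qc_filter_variants(gm: GenotypeMatrix, classes: dict[int, tuple[str, LofClass]],
                       samples: pd.DataFrame,
                       thresholds: QCThresholds | None = None,
                       hwe_pooled: bool = False
                       ) -> tuple[list[LofVariant], pd.DataFrame]:
    """Apply QC to LoF-classified variants.

    ``classes`` maps GenotypeMatrix row index to (gene_id, LofClass). Returns
    the kept :class:`LofVariant` list (variants passing in at least one
    stratum; order follows the input matrix, so the result is independent of
    any caller-side ordering) and the full QC table including drop reasons.
    """
    qc = variant_qc(gm, samples, thresholds, hwe_pooled)
    kept: list[LofVariant] = []
    for vi, (gene_id, cls) in sorted(classes.items()):
        if cls == LofClass.not_lof:
            continue
        sub = qc[qc["variant_index"] == vi]
        lv = LofVariant(
            site=gm.variants[vi], gene_id=gene_id, lof_class=cls, index=vi,
            maf_by_stratum=dict(zip(sub["stratum"], sub["maf"])),
            call_rate_by_stratum=dict(zip(sub["stratum"], sub["call_rate"])),
            hwe_p_by_stratum=dict(zip(sub["stratum"], sub["hwe_p"])),
            passing_strata=set(sub.loc[sub["pass"], "stratum"]))
        if lv.passing_strata:
            kept.append(lv)
    return kept, qc


# ---------------------------------------------------------------------------
# cohort-level convenience
# ---------------------------------------------------------------------------

def annotate_cohort(gm: GenotypeMatrix, models: list[GeneModel],
                    reference_cds: dict[str, str], samples: pd.DataFrame,
                    splice_mode: str = "intronic2", transcript_mode: str = "any",
                    thresholds: QCThresholds | None = None,
                    hwe_pooled: bool = False
                    ) -> tuple[list[LofVariant], pd.DataFrame]:
    """Classify every variant against every overlapping gene and QC-filter.

    A variant overlapping several genes yields one candidate per gene. Only
    LoF variants enter the QC step. Returns (kept LoF variants, QC table).
    """
    classes: dict[int, tuple[str, LofClass]] = {}
    by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
    for g in models:
        spans = [t.span() for t in g.transcripts]
        lo = min(s for s, _ in spans) - 2
        hi = max(e for _, e in spans) + 2
        by_chrom.setdefault(g.chrom, []).append((lo, hi, g))
    for vi, v in enumerate(gm.variants):
        for lo, hi, g in by_chrom.get(v.chrom, []):
            if not (v.pos - 1 < hi and v.end0 > lo):
                continue
            per_tx = classify_variant(v, g, reference_cds, splice_mode)
            cls = aggregate_gene_class(list(per_tx.values()), transcript_mode)
            if cls != LofClass.not_lof:
                classes[vi] = (g.gene_id, cls)
    return qc_filter_variants(gm, classes, samples, thresholds, hwe_pooled)
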