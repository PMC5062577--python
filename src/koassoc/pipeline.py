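"""End-to-end orchestration: annotate -> QC -> KO calling -> phenotype
normalization -> per-stratum permutation scan -> cross-stratum combination."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import assoc_perm, ko_call, lof_annotate, meta_enrich, pheno_prep
from .synthdata import Cohort

logger = logging.getLogger(__name__)


@dataclass
class ScanOutput:
    per_stratum: dict[str, assoc_perm.ScanSummary]
    combined: pd.DataFrame | None        # meta-analysis across strata (>=2)
    komatrix: ko_call.KOMatrix
    qc: pd.DataFrame


def scan_cohort(cohort: Cohort, covariates: list[str] | None = None,
                splice_mode: str = "intronic2", transcript_mode: str = "any",
                phase_policy: str = "use_phase",
                thresholds: lof_annotate.QCThresholds | None = None,
                n_perm_initial: int = 10_000, n_perm_escalated: int = 100_000,
                escalate_below: float = 2e-4, min_n_ko: int = 1,
                seed: int = 0, alpha: float = 2e-5) -> ScanOutput:
    """Run the whole pipeline on an (in-memory) cohort.

    Covariates default to the generator's sex/age/age2/PC columns. Analyses
    are stratified throughout; with two or more strata a sample-size weighted
    Z meta-analysis combines the per-stratum results per gene.
    """
    cfg = cohort.config
    if covariates is None:
        covariates = (["sex_code", "age", "age2"]
                      + [f"PC{j + 1}" for j in range(len(cfg.pc_effects))])

    lof_vars, qc = lof_annotate.annotate_cohort(
        cohort.gm, cohort.models, cohort.cds_seqs, cohort.samples,
        splice_mode=splice_mode, transcript_mode=transcript_mode,
        thresholds=thresholds)
    logger.info("%d LoF variants pass QC in at least one stratum", len(lof_vars))

    thr = thresholds or lof_annotate.QCThresholds()
    kom = ko_call.call_gene_kos(cohort.gm, lof_vars, cohort.samples,
                                phase_policy=phase_policy,
                                maf_threshold=thr.maf_max)
    norm = pheno_prep.normalize_phenotype(cohort.phenotypes, cfg.trait_name,
                                          covariates, cohort.samples)
    per_stratum: dict[str, assoc_perm.ScanSummary] = {}
    for st, grp in norm.groupby("stratum", sort=True):
        try:
            per_stratum[st] = assoc_perm.genome_scan(
                kom, grp.reset_index(drop=True), trait=cfg.trait_name,
                n_perm_initial=n_perm_initial,
                n_perm_escalated=n_perm_escalated,
                escalate_below=escalate_below, min_n_ko=min_n_ko,
                seed=seed, alpha=alpha)
        except ValueError as exc:
            logger.warning("stratum %s not scanned: %s", st, exc)

    combined = None
    if len(per_stratum) >= 2:
        n_by_stratum = cohort.samples["stratum"].value_counts().to_dict()
        frames = []
        for st, summ in per_stratum.items():
            df = summ.to_frame()
            df["N_study"] = n_by_stratum[st]
            # meta-analysis needs P in (0, 1]: floor zero empirical Ps at the
            # permutation resolution
            df["P_final"] = df.apply(
                lambda r: max(r["P_final"], 1.0 / r["n_perm"]), axis=1)
            frames.append(df)
        combined = meta_enrich.combine_studies(pd.concat(frames, ignore_index=True))
    return ScanOutput(per_stratum, combined, kom, qc)
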