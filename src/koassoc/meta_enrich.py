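"""Cross-study combination and candidate-gene enrichment.

Two different weightings coexist deliberately:

* the combined **P value** uses the sample-size weighted Z-score scheme
  (METAL-style): Z_i = Phi^-1(1 - P_i/2) * sign(m_i), combined as
  sum(Z_i * sqrt(N_i)) / sqrt(sum N_i);
* the combined **effect display** is the N_KO-weighted mean of the per-study
  KO-group means (in SD units), optionally converted to metric units by a
  per-trait SD-to-unit factor. The metric value multiplies the *display
  rounded* (one decimal, half away from zero) SD value by the factor, which
  is the arithmetic that keeps SD and metric columns mutually consistent in
  reports; full-precision values are also returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import fisher_exact

from .assoc_perm import ScanSummary, qq_points

logger = logging.getLogger(__name__)


@dataclass
class MetaResult:
    gene_id: str
    z_combined: float
    p_combined: float
    weighted_mean_sd: float
    weighted_mean_metric: float | None
    n_ko_total: int
    n_studies: int


def round_display(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the display precision (1.35 -> 1.4)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def weighted_z_meta(studies: list[tuple[float, int, float]]
                    ) -> tuple[float, float]:
    """Sample-size weighted Z-score meta-analysis.

    ``studies`` is a list of (p_final, direction, n_study) with direction in
    {-1, 0, +1} (the sign of the KO-group mean; 0 — a degenerate exactly-zero
    mean — contributes Z = 0 with a warning). P must be in (0, 1]: a zero
    empirical P cannot be converted to a Z score — escalate the permutation
    test or configure a resolution floor first.
    """
    if not studies:
        raise ValueError("no studies to combine")
    zs, ws = [], []
    for p, direction, n_study in studies:
        if not 0 < p <= 1:
            raise ValueError(
                f"study P = {p!r} outside (0, 1]; escalate permutations or set a floor")
        if direction not in (-1, 0, 1):
            raise ValueError(f"direction must be -1, 0 or +1, got {direction}")
        if direction == 0:
            logger.warning("study with zero effect direction contributes Z = 0")
        zs.append(ndtri(1 - p / 2) * direction)
        ws.append(np.sqrt(n_study))
    zs, ws = np.array(zs), np.array(ws)
    z_comb = float((zs * ws).sum() / np.sqrt((ws ** 2).sum()))
    p_comb = float(2 * ndtr(-abs(z_comb)))
    return z_comb, p_comb


def weighted_ko_mean(strata: list[tuple[float, int]],
                     sd_conversion: float | None = None
                     ) -> tuple[float, float | None]:
    """N_KO-weighted mean of per-study KO-group means (SD units) and its
    metric conversion (display-rounded SD x units-per-SD), if configured."""
    if not strata:
        raise ValueError("no strata to combine")
    ms = np.array([m for m, _ in strata], dtype=float)
    ns = np.array([n for _, n in strata], dtype=float)
    if (ns < 1).any():
        raise ValueError("every stratum needs N_KO >= 1")
    wm = float((ms * ns).sum() / ns.sum())
    metric = round_display(wm) * sd_conversion if sd_conversion is not None else None
    return wm, metric


def combine_studies(per_study: pd.DataFrame, sd_conversion: float | None = None
                    ) -> pd.DataFrame:
    """Meta-analyze per-study association tables.

    ``per_study`` needs columns gene, N_study, N_KO, mean_SD, P_final (one
    row per gene per study). Genes present in a single study pass through
    with their own Z/P.
    """
    rows = []
    for gene, grp in per_study.groupby("gene", sort=True):
        studies = [(float(r.P_final), int(np.sign(r.mean_SD)), int(r.N_study))
                   for r in grp.itertuples()]
        z, p = weighted_z_meta(studies)
        wm, metric = weighted_ko_mean(
            [(float(r.mean_SD), int(r.N_KO)) for r in grp.itertuples()],
            sd_conversion)
        rows.append({"gene": gene, "Z_combined": z, "P_combined": p,
                     "weighted_mean_sd": wm, "weighted_mean_metric": metric,
                     "N_KO_total": int(grp["N_KO"].sum()),
                     "n_studies": len(grp)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# candidate-gene enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(gene_set: set[str], scan: ScanSummary, p_cut: float = 0.05
                      ) -> tuple[float, float, np.ndarray]:
    """Fisher's exact test of candidate-gene enrichment among nominally
    significant genes.

    The 2x2 table counts tested genes by {in set, not in set} x
    {P_final < p_cut, >= p_cut}. Degenerate tables (an empty margin, e.g. no
    tested gene in the set) are flagged and return (nan, 1.0, table).
    """
    if not scan.results:
        raise ValueError("empty scan")
    in_set = np.array([r.gene_id in gene_set for r in scan.results])
    signif = np.array([r.p_final < p_cut for r in scan.results])
    table = np.array([
        [int((in_set & signif).sum()), int((in_set & ~signif).sum())],
        [int((~in_set & signif).sum()), int((~in_set & ~signif).sum())],
    ])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        logger.warning("degenerate enrichment table %s; OR undefined", table.tolist())
        return float("nan"), 1.0, table
    odds, p = fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def stratified_qq(scan: ScanSummary, gene_sets: dict[str, set[str]]
                  ) -> dict[str, pd.DataFrame]:
    """Per-subset QQ tables for overlay plots: one table per candidate-gene
    set plus the all-genes background under the key ``all``. Subsets with no
    tested gene are skipped with a warning."""
    p_by_gene = {r.gene_id: r.p_final for r in scan.results}
    floor = 0.5 / max(r.n_perm for r in scan.results)
    out = {"all": qq_points(np.array([max(p, floor) for p in p_by_gene.values()]))}
    for name, genes in gene_sets.items():
        ps = [max(p_by_gene[g], floor) for g in genes if g in p_by_gene]
        if not ps:
            logger.warning("gene set %s has no tested genes; skipped", name)
            continue
        out[name] = qq_points(np.array(ps))
    return out
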