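"""Permutation test of the knockout-group phenotype mean.

For a gene with K predicted-KO individuals the statistic is the mean
normalized phenotype m over those K individuals. Each permutation draws K
phenotypes without replacement from the full vector and records its mean
m_i; with n permutations,

    P_left  = #{m_i <= m} / n,
    P_right = #{m_i >= m} / n,
    P_final = min(1, 2 * min(P_left, P_right)),

where ties count on both sides. Scans use an initial permutation budget and
escalate promising genes to a larger one (default 10,000 -> 100,000 below
P_final < 2e-4). A zero count is reported as P = 0 together with n; the
escalation stage is what refines such resolution-floor results.

The test assumes unrelated individuals and a symmetric phenotype
distribution (use :mod:`koassoc.pheno_prep` to produce the normalized input).
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .ko_call import KOMatrix

logger = logging.getLogger(__name__)

CHI2_1DF_MEDIAN = chi2.ppf(0.5, 1)          # 0.45493...


@dataclass
class AssocResult:
    gene_id: str
    stratum: str
    n_ko: int
    m: float
    count_le: int
    count_ge: int
    n_perm: int
    p_left: float
    p_right: float
    p_final: float


@dataclass
class ScanSummary:
    trait: str
    results: list[AssocResult]
    lambda_gc: float
    n_genes_tested: int
    alpha: float = 2e-5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "gene": r.gene_id, "trait": self.trait, "stratum": r.stratum,
            "N_KO": r.n_ko, "mean_SD": r.m, "count_le": r.count_le,
            "count_ge": r.count_ge, "P_left": r.p_left, "P_right": r.p_right,
            "P_final": r.p_final, "n_perm": r.n_perm}
            for r in self.results])


# ---------------------------------------------------------------------------
# subset sampling without replacement
# ---------------------------------------------------------------------------

def _draw_subsets(rng: np.random.Generator, n: int, k: int, n_draws: int
                  ) -> np.ndarray:
    """(n_draws, k) index arrays, each row a uniform k-subset of range(n).

    Rejection sampling on duplicate rows when k is small relative to sqrt(n)
    (duplicates are then rare); otherwise chunked partial argsort of random
    keys, which is uniform for any k.
    """
    if k == 1:
        return rng.integers(0, n, size=(n_draws, 1))
    if k * (k - 1) < n:          # duplicate probability < ~40%
        idx = rng.integers(0, n, size=(n_draws, k))
        while True:
            srt = np.sort(idx, axis=1)
            bad = (np.diff(srt, axis=1) == 0).any(axis=1)
            n_bad = int(bad.sum())
            if n_bad == 0:
                return idx
            idx[bad] = rng.integers(0, n, size=(n_bad, k))
    out = np.empty((n_draws, k), dtype=np.int64)
    chunk = max(1, int(2e7) // n)
    for lo in range(0, n_draws, chunk):
        hi = min(lo + chunk, n_draws)
        keys = rng.random((hi - lo, n))
        out[lo:hi] = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return out


def ko_mean_test(phenotype: np.ndarray, ko_indices: np.ndarray, n_perm: int,
                 rng: np.random.Generator | int | None = None,
                 method: str = "sample") -> AssocResult:
    """Permutation test of the KO-group mean for one gene.

    ``phenotype`` is the normalized phenotype vector for every tested sample;
    ``ko_indices`` selects the KO individuals (non-empty, proper subset).
    ``method='exhaustive'`` enumerates all C(N, K) equally likely KO-label
    assignments instead of sampling, making P_left/P_right exact (``n_perm``
    is then ignored and reported as C(N, K)).
    """
    y = np.asarray(phenotype, dtype=float)
    ko = np.asarray(ko_indices, dtype=int)
    n_samp, k = len(y), len(ko)
    if k == 0:
        raise ValueError("empty KO group")
    if len(np.unique(ko)) != k or ko.min() < 0 or ko.max() >= n_samp:
        raise ValueError("KO indices must be distinct valid sample indices")
    if k >= n_samp:
        raise ValueError("KO group covers every sample; no permutation null")
    m = float(y[ko].mean())

    if method == "exhaustive":
        from math import comb
        total = comb(n_samp, k)
        if total > 5_000_000:
            raise ValueError(f"C({n_samp},{k}) = {total} too large to enumerate")
        count_le = count_ge = 0
        for subset in itertools.combinations(range(n_samp), k):
            mi = y[list(subset)].mean()
            if mi <= m:
                count_le += 1
            if mi >= m:
                count_ge += 1
        n = total
    elif method == "sample":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        idx = _draw_subsets(rng, n_samp, k, n_perm)
        means = y[idx].mean(axis=1)
        count_le = int((means <= m).sum())
        count_ge = int((means >= m).sum())
        n = n_perm
    else:
        raise ValueError(f"unknown method: {method}")

    p_left = count_le / n
    p_right = count_ge / n
    p_final = min(1.0, 2.0 * min(p_left, p_right))
    return AssocResult("", "", k, m, count_le, count_ge, n, p_left, p_right, p_final)


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def _gene_rng(seed: int, gene_id: str, stage: int = 0) -> np.random.Generator:
    """Deterministic per-gene stream: seeds derive from (run seed, gene id,
    escalation stage) via a stable hash, so results are independent of gene
    order and reproducible across processes."""
    h = hashlib.blake2b(gene_id.encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed, int.from_bytes(h, "little"), stage]))


def genome_scan(kom: KOMatrix, phenotype: pd.DataFrame, trait: str = "trait",
                n_perm_initial: int = 10_000, n_perm_escalated: int = 100_000,
                escalate_below: float = 2e-4, min_n_ko: int = 1,
                seed: int = 0, alpha: float = 2e-5,
                escalate_on: str = "final") -> ScanSummary:
    """Test every gene of a KO matrix against one stratum's normalized
    phenotype (DataFrame with sample_id, z, stratum — a single stratum).

    Genes whose initial empirical P (``escalate_on``: the two-tailed
    ``final`` P or the smaller ``onesided`` P) falls below ``escalate_below``
    are re-run with ``n_perm_escalated`` permutations and the escalated
    result replaces the initial one. ``min_n_ko`` supports replication-style
    filtering (e.g. require at least two KO individuals).
    """
    strata = phenotype["stratum"].unique()
    if len(strata) != 1:
        raise ValueError("genome_scan expects one stratum; loop over strata upstream")
    stratum = str(strata[0])
    if escalate_on not in ("final", "onesided"):
        raise ValueError(f"unknown escalation criterion: {escalate_on}")
    if not kom.calls:
        raise ValueError("empty KO matrix")

    sample_pos = {s: i for i, s in enumerate(phenotype["sample_id"])}
    y = phenotype["z"].to_numpy(dtype=float)
    results: list[AssocResult] = []
    for gene in kom.genes:
        ko_ids = kom.ko_samples(gene)
        idx = np.array(sorted(sample_pos[s] for s in ko_ids if s in sample_pos))
        n_missing = len(ko_ids) - len(idx)
        if n_missing:
            logger.debug("%s: %d KO individuals lack phenotype", gene, n_missing)
        if len(idx) < min_n_ko or len(idx) == 0 or len(idx) >= len(y):
            continue
        r = ko_mean_test(y, idx, n_perm_initial, _gene_rng(seed, gene, 0))
        crit = r.p_final if escalate_on == "final" else min(r.p_left, r.p_right)
        if crit < escalate_below:
            r = ko_mean_test(y, idx, n_perm_escalated, _gene_rng(seed, gene, 1))
        r.gene_id, r.stratum = gene, stratum
        results.append(r)
    if not results:
        raise ValueError("no gene qualified for testing")
    lam = lambda_gc(np.array([max(r.p_final, 0.5 / r.n_perm) for r in results]))
    return ScanSummary(trait, results, lam, len(results), alpha)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def lambda_gc(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square quantile of the
    P values divided by the null median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.median(chi2.isf(p, 1)) / CHI2_1DF_MEDIAN)


def qq_points(p_values: np.ndarray) -> pd.DataFrame:
    """QQ-plot table on the -log10 scale with a 95% null band.

    Observed P values are sorted ascending; expected_i = (i - 0.5)/n; the
    band comes from the order-statistic law (the i-th of n uniforms is
    Beta(i, n - i + 1)), evaluated at the 2.5 and 97.5 percentiles.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    if n == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    i = np.arange(1, n + 1)
    expected = (i - 0.5) / n
    lower_p = beta_dist.ppf(0.975, i, n - i + 1)
    upper_p = beta_dist.ppf(0.025, i, n - i + 1)
    return pd.DataFrame({
        "expected": -np.log10(expected),
        "observed": -np.log10(p),
        "lower95": -np.log10(lower_p),
        "upper95": -np.log10(upper_p),
    })
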