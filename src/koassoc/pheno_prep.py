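"""Phenotype normalization: covariate residualization followed by rank-based
inverse normal transformation (INT), always within stratum.

The INT convention is z_i = Phi^-1((r_i - 0.5) / n) with ties given their
average rank — a simple, symmetric offset (no Blom-style constant).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


def residualize(trait: np.ndarray, covariates: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Ordinary least-squares residuals of ``trait`` on ``covariates`` plus an
    intercept. Residuals are orthogonal to every covariate column. Missing
    values must be removed upstream (listwise deletion); rank-deficient
    designs raise an error naming the collinear columns."""
    y = np.asarray(trait, dtype=float)
    names = None
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != len(X):
        raise ValueError("trait and covariate lengths differ")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values present; apply listwise deletion first")
    D = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        bad = _collinear_columns(D, names)
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return y - D @ beta


def _collinear_columns(D: np.ndarray, names: list[str] | None) -> list[str]:
    full = np.linalg.matrix_rank(D)
    bad = []
    for j in range(1, D.shape[1]):
        reduced = np.delete(D, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            label = names[j - 1] if names else f"col{j - 1}"
            bad.append(label)
    return bad or ["<unidentified>"]


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based INT: average ranks r, then Phi^-1((r - 0.5)/n).

    Requires at least two distinct values (the transform is undefined on a
    constant vector). The result is invariant to any strictly increasing
    transform of the input.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.isnan(x).any():
        raise ValueError("missing values present")
    if np.all(x == x[0]):
        raise ValueError("all values identical; INT undefined")
    r = rankdata(x, method="average")
    return ndtri((r - 0.5) / len(x))


def normalize_phenotype(phenotypes: pd.DataFrame, trait: str,
                        covariates: list[str], samples: pd.DataFrame
                        ) -> pd.DataFrame:
    """Full per-stratum normalization: listwise-delete missing rows,
    residualize the trait on the covariates, then INT the residuals.

    Returns a DataFrame (sample_id, z, stratum) covering the samples with
    complete data; deletions are logged.
    """
    merged = phenotypes.merge(samples[["sample_id", "stratum"]], on="sample_id")
    cols = [trait] + covariates
    out = []
    for st, grp in merged.groupby("stratum", sort=True):
        complete = grp.dropna(subset=cols)
        n_drop = len(grp) - len(complete)
        if n_drop:
            logger.info("stratum %s: dropped %d samples with missing %s/covariates",
                        st, n_drop, trait)
        if len(complete) < 2:
            logger.warning("stratum %s: fewer than 2 complete samples, skipped", st)
            continue
        resid = residualize(complete[trait].to_numpy(),
                            complete[covariates]) if covariates else (
            complete[trait].to_numpy() - complete[trait].mean())
        z = inverse_normal_transform(resid)
        out.append(pd.DataFrame({"sample_id": complete["sample_id"].to_numpy(),
                                 "z": z, "stratum": st}))
    if not out:
        raise ValueError("no stratum had enough complete data")
    return pd.concat(out, ignore_index=True)


def apply_trait_bounds(phenotypes: pd.DataFrame, trait: str,
                       lower: float | None = None, upper: float | None = None
                       ) -> pd.DataFrame:
    """Optional pre-filter utility masking trait values outside [lower, upper]
    (set to NaN, so they fall to listwise deletion). Bounds are configuration,
    not hard-coded science."""
    df = phenotypes.copy()
    vals = df[trait]
    mask = pd.Series(False, index=df.index)
    if lower is not None:
        mask |= vals < lower
    if upper is not None:
        mask |= vals > upper
    df.loc[mask, trait] = np.nan
    if mask.any():
        logger.info("masked %d %s values outside bounds", int(mask.sum()), trait)
    return df
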