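"""Sparseness, dynamic range, and dimensionality of response matrices.

Lifetime sparseness S_L summarizes how selectively one glomerulus responds
across the odorant panel; population sparseness S_P applies the same formula
across glomeruli for one odorant.  Both are normalized to [0, 1], with 1 for
a single nonzero response and 0 for a perfectly uniform response vector:

    S = (1 - (sum(r)/n)^2 / (sum(r^2)/n)) / (1 - 1/n)

Effective dimensionality (ED) is the participation ratio of the covariance
eigenvalues, ED = (sum(l))^2 / sum(l^2): the number of equal-variance
dimensions that would produce the same eigenvalue concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SparsenessResult:
    """Per-glomerulus S_L and per-odorant S_P for one OB, with the number of
    stimuli / glomeruli entering each measure.  Undefined entries (all-zero
    vectors) are NaN, never silently 0."""

    S_L: pd.Series
    S_P: pd.Series
    n_odorants: int
    n_glomeruli: int


def _sparseness(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("sparseness needs >= 2 responses")
    if (values < 0).any():
        raise ValueError("responses must be nonnegative")
    if not values.any():
        return np.nan
    mean_sq = (values.sum() / n) ** 2
    sq_mean = (values**2).sum() / n
    s = (1.0 - mean_sq / sq_mean) / (1.0 - 1.0 / n)
    # cancellation can push uniform vectors a few ulp outside [0, 1]
    return float(np.clip(s, 0.0, 1.0))


def lifetime_sparseness(responses: np.ndarray) -> float:
    """S_L of one glomerulus's responses across the odorant panel.

    Returns NaN (flagged undefined) for an all-zero vector.
    """
    out = _sparseness(responses)
    if np.isnan(out):
        logger.warning("lifetime sparseness undefined for all-zero response vector")
    return out


def population_sparseness(responses: np.ndarray) -> float:
    """S_P of one odorant's responses across glomeruli (same formula)."""
    out = _sparseness(responses)
    if np.isnan(out):
        logger.warning("population sparseness undefined: odorant evoked no response")
    return out


def sparseness_matrix(matrix: pd.DataFrame) -> SparsenessResult:
    """S_L per glomerulus (rows) and S_P per odorant (columns) of one OB."""
    S_L = matrix.apply(lambda r: _sparseness(r.to_numpy()), axis=1)
    S_P = matrix.apply(lambda c: _sparseness(c.to_numpy()), axis=0)
    return SparsenessResult(
        S_L=S_L, S_P=S_P, n_odorants=matrix.shape[1], n_glomeruli=matrix.shape[0]
    )


def dynamic_range(responses: np.ndarray) -> float:
    """Ratio between the strongest and weakest nonzero responses.

    NaN (flagged) when fewer than two nonzero responses exist.
    """
    nz = np.asarray(responses, dtype=float)
    nz = nz[nz > 0]
    if nz.size < 2:
        logger.warning("dynamic range undefined: fewer than 2 nonzero responses")
        return np.nan
    return float(nz.max() / nz.min())


def _normalized_covariance_eigenvalues(matrix: pd.DataFrame) -> np.ndarray:
    """Eigenvalues of the glomerulus-by-glomerulus covariance of a response
    matrix after normalizing each glomerulus's spectrum to its maximum.

    Glomeruli are the variables and odorants the observations, so the number
    of possible PCs is min(n_odorants - 1, n_glomeruli).  All-zero rows are
    dropped (logged) and columns are mean-centered.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 glomeruli and >= 2 odorants")
    values = matrix.to_numpy(dtype=float)
    keep = values.max(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d all-zero glomeruli before PCA", dropped)
    values = values[keep]
    if values.shape[0] < 2:
        raise ValueError("matrix rank too low: fewer than 2 responsive glomeruli")
    norm = values / values.max(axis=1, keepdims=True)
    data = norm.T  # odorants as observations, glomeruli as variables
    centered = data - data.mean(axis=0, keepdims=True)
    # eigenvalues of the covariance via SVD of the centered data
    svals = np.linalg.svd(centered, compute_uv=False)
    eig = svals**2 / (data.shape[0] - 1)
    if not eig.any():
        raise ValueError("rank-0 response matrix")
    return eig


def pca_variance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Variance fractions per PC of one OB's max-normalized response matrix.

    Returns a DataFrame with ``variance_fraction``, ``cumulative_fraction``
    and ``pc_fraction`` (PC index as a fraction of the number of possible
    PCs, which is bounded by the number of responsive glomeruli).
    """
    eig = _normalized_covariance_eigenvalues(matrix)
    n_possible = min(matrix.shape[1] - 1, int((matrix.to_numpy().max(axis=1) > 0).sum()))
    eig = eig[:n_possible]
    frac = eig / eig.sum()
    return pd.DataFrame(
        {
            "variance_fraction": frac,
            "cumulative_fraction": np.cumsum(frac),
            "pc_fraction": (np.arange(len(frac)) + 1) / n_possible,
        },
        index=pd.RangeIndex(1, len(frac) + 1, name="pc"),
    )


def effective_dimensionality(matrix: pd.DataFrame) -> float:
    """Participation ratio ED = (sum(l))^2 / sum(l^2) of the covariance
    eigenvalues of the max-normalized response matrix."""
    eig = _normalized_covariance_eigenvalues(matrix)
    return float(eig.sum() ** 2 / (eig**2).sum())


def tidy_metrics(dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-glomerulus (S_L, dynamic range) and per-odorant (S_P) tidy tables
    across all OBs of a dataset."""
    glom_rows, odor_rows = [], []
    for ob in dataset:
        res = sparseness_matrix(ob.responses)
        for g in ob.responses.index:
            glom_rows.append(
                {
                    "ob_id": ob.ob_id,
                    "glomerulus": g,
                    "S_L": res.S_L[g],
                    "dynamic_range": dynamic_range(ob.responses.loc[g].to_numpy()),
                    "n_effective": int((ob.responses.loc[g] > 0).sum()),
                }
            )
        for o in ob.responses.columns:
            odor_rows.append({"ob_id": ob.ob_id, "odorant": o, "S_P": res.S_P[o]})
    return pd.DataFrame(glom_rows), pd.DataFrame(odor_rows)
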