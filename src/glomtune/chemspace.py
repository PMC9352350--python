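"""Chemical-similarity spaces and prediction of glomerular co-tuning.

Two flavors of odorant chemical space are supported:

* continuous physicochemical descriptor matrices (consumed as input, never
  computed here), z-scored per descriptor and compared by cosine distance,
  optionally reduced to their leading principal components and compared by
  Euclidean distance; and
* binary substructure keysets compared by 1 - Dice similarity, including
  the shipped SMARTS42 set of 42 substructure patterns (functional groups,
  ring substitution motifs, terpenoid scaffolds, and explicit single-bond
  aliphatic chains of 6-11 carbons).

How well a space predicts a glomerulus's response spectrum is scored with a
ROC-derived enrichment metric from ligand-based virtual screening: the
non-query odorants are ranked by increasing distance from a query odorant,
the cumulative fraction of the glomerulus's responses recovered is plotted
against rank fraction, and

    P = 1 - 2 (AUC_response - AUC_model) / AUC_response

where AUC_response is the area under the best achievable curve (odorants
ranked by responsiveness itself) and AUC_model the area under the space's
curve.  P = 1 for a perfect ranking; the expectation under a uniformly
random ranking is 1/AUC_response - 1, which is ~0 for sparse spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_SMARTS42 = 42


class PatternError(ValueError):
    pass


def smarts42_patterns(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Load the SMARTS42 keyset as (pattern, label) pairs, validating that
    every pattern parses.  A substitute keyset file (one pattern per line,
    optional tab-separated label) can be supplied via ``path``."""
    from rdkit import Chem

    if path is None:
        text = (
            resources.files("glomtune").joinpath("data/smarts42.txt").read_text("utf-8")
        )
    else:
        text = Path(path).read_text("utf-8")
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pattern, _, label = line.partition("\t")
        pattern = pattern.strip()
        if Chem.MolFromSmarts(pattern) is None:
            raise PatternError(
                f"pattern {len(patterns) + 1} does not parse: {pattern!r}"
            )
        patterns.append((pattern, label.strip() or f"key{len(patterns) + 1}"))
    return patterns


def smarts42_fingerprints(
    smiles: list[str] | pd.Series,
    patterns: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Binary substructure fingerprints: bit k = 1 iff the molecule contains
    at least one match of pattern k (standard SMARTS semantics on
    aromaticity-perceived molecules).

    Rows for unparseable SMILES are NaN and logged.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    if patterns is None:
        patterns = smarts42_patterns()
    queries = [Chem.MolFromSmarts(p) for p, _ in patterns]
    labels = [lab for _, lab in patterns]
    if isinstance(smiles, pd.Series):
        index = smiles.index
        smi_list = list(smiles)
    else:
        index = pd.RangeIndex(len(smiles))
        smi_list = list(smiles)

    rows = np.full((len(smi_list), len(queries)), np.nan)
    RDLogger.DisableLog("rdApp.error")
    try:
        for i, smi in enumerate(smi_list):
            mol = Chem.MolFromSmiles(smi) if smi else None
            if mol is None:
                logger.warning("unparseable SMILES at %r; fingerprint row absent", index[i])
                continue
            rows[i] = [float(mol.HasSubstructMatch(q)) for q in queries]
    finally:
        RDLogger.EnableLog("rdApp.error")
    return pd.DataFrame(rows, index=index, columns=labels)


@dataclass
class ChemSpace:
    """An odorant x feature matrix with its induced odorant-odorant distances.

    ``metric`` is one of ``cosine`` (z-scored continuous descriptors),
    ``one-minus-dice`` (binary keys) or ``euclidean`` (PC-reduced spaces).
    """

    features: pd.DataFrame
    metric: str
    distance: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.distance = distance_matrix(self.features, self.metric)


def zscore_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Z-score each descriptor column; zero-variance columns are dropped
    with a logged count."""
    if raw.shape[0] < 2:
        raise ValueError("need >= 2 odorants to z-score")
    values = raw.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance descriptors", n_dropped)
    if not keep.any():
        raise ValueError("all descriptor columns are constant")
    z = (values[:, keep] - values[:, keep].mean(axis=0)) / sd[keep]
    return pd.DataFrame(z, index=raw.index, columns=raw.columns[keep])


def distance_matrix(features: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Symmetric odorant-odorant distance matrix.

    Cosine distance for continuous features, 1 - Dice similarity for binary
    keys, Euclidean for PC-reduced spaces.  Zero-norm rows under cosine (and
    all-zero fingerprints under Dice against themselves) yield NaN distances,
    flagged in the log.
    """
    from scipy.spatial.distance import pdist, squareform

    x = features.to_numpy(dtype=float)
    if metric == "cosine":
        norms = np.linalg.norm(x, axis=1)
        bad = norms == 0
        d = squareform(pdist(np.where(bad[:, None], np.nan, x), metric="cosine"))
        if bad.any():
            logger.warning(
                "cosine distance undefined for %d zero-norm odorants", int(bad.sum())
            )
            d[bad, :] = np.nan
            d[:, bad] = np.nan
    elif metric in ("one-minus-dice", "dice"):
        if not np.isin(x[~np.isnan(x)], (0.0, 1.0)).all():
            raise ValueError("Dice distance requires binary features")
        nanrows = np.isnan(x).any(axis=1)
        xb = np.where(nanrows[:, None], 0, x).astype(bool)
        d = squareform(pdist(xb, metric="dice"))
        # two all-zero fingerprints have undefined Dice similarity
        empty = ~xb.any(axis=1)
        if empty.any():
            d[np.ix_(empty, empty)] = np.nan
        if nanrows.any():
            d[nanrows, :] = np.nan
            d[:, nanrows] = np.nan
    elif metric == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, np.where(np.isnan(np.diag(d)), np.nan, 0.0))
    return pd.DataFrame(d, index=features.index, columns=features.index)


def pca_chemspace(
    library: pd.DataFrame,
    panel_ids: list[str] | None = None,
    n_pcs: int = 20,
) -> tuple[pd.DataFrame, pd.Series]:
    """Euclidean chemical space from the leading PCs of a descriptor library.

    The library (odorant x descriptor) is z-scored and eigendecomposed; the
    panel odorants (``panel_ids`` rows of the library; all rows by default)
    are projected onto the first ``n_pcs`` components.  Returns the
    projection and the cumulative variance fraction per PC.
    """
    if library.shape[0] < n_pcs:
        raise ValueError("library must have at least n_pcs rows")
    z = zscore_features(library)
    centered = z.to_numpy()
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum())
    if n_pcs > rank:
        logger.warning("n_pcs=%d exceeds rank %d; clipping", n_pcs, rank)
        n_pcs = rank
    var = s**2
    cumvar = pd.Series(
        np.cumsum(var) / var.sum(), index=pd.RangeIndex(1, len(var) + 1, name="pc")
    )
    scores = centered @ vt[:n_pcs].T
    scores = pd.DataFrame(
        scores, index=z.index, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )
    if panel_ids is not None:
        scores = scores.loc[panel_ids]
    return scores, cumvar


@dataclass
class PerformanceResult:
    P: float
    query: str
    auc_response: float
    auc_model: float
    #: (rank fraction, cumulative response fraction) of the model curve
    curve: tuple[np.ndarray, np.ndarray]


def _cumulative_auc(ordered_responses: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Trapezoidal AUC of the cumulative response fraction vs rank fraction,
    anchored at (0, 0)."""
    n = ordered_responses.size
    total = ordered_responses.sum()
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(ordered_responses)]) / total
    return float(np.trapezoid(y, x)), x, y


def performance_metric(
    responses: pd.Series,
    distance_row: pd.Series,
    query: str,
    mode: str = "binary",
) -> PerformanceResult:
    """Enrichment score P for predicting one glomerulus's responses from
    chemical distance to a query odorant.

    The query odorant is excluded from both curves.  In ``binary`` mode the
    curves accumulate the count of responsive odorants; in ``amplitude`` mode
    they accumulate summed response amplitudes.  Distance ties are broken by
    panel order (stable sort).  Returns NaN P (flagged) when no non-query
    odorant is responsive.
    """
    others = [o for o in responses.index if o != query]
    resp = responses.loc[others].to_numpy(dtype=float)
    if mode == "binary":
        resp = (resp > 0).astype(float)
    elif mode != "amplitude":
        raise ValueError(f"unknown mode {mode!r}")
    if resp.sum() == 0:
        logger.warning("performance metric undefined for query %r: no responses", query)
        return PerformanceResult(np.nan, query, np.nan, np.nan, (np.array([]), np.array([])))

    dist = distance_row.loc[others].to_numpy(dtype=float)
    if np.isnan(dist).any():
        logger.warning("query %r: NaN distances ranked last", query)
        dist = np.where(np.isnan(dist), np.inf, dist)
    if np.ptp(dist) == 0:
        logger.warning("query %r: constant distances; ranking degenerate to panel order", query)
    model_order = np.argsort(dist, kind="stable")
    response_order = np.argsort(-resp, kind="stable")

    auc_model, x, y = _cumulative_auc(resp[model_order])
    auc_response, _, _ = _cumulative_auc(resp[response_order])
    P = 1.0 - 2.0 * (auc_response - auc_model) / auc_response
    return PerformanceResult(P, query, auc_response, auc_model, (x, y))


def glomerulus_performance(
    matrix: pd.DataFrame,
    distance: pd.DataFrame,
    mode: str = "full",
    response_threshold: float = 0.1,
    primary: pd.Series | None = None,
) -> pd.Series:
    """Median performance metric per glomerulus.

    ``full`` mode mirrors a whole-dataset analysis: each glomerulus's
    spectrum is thresholded at ``response_threshold`` of its maximum
    (strictly greater), binarized, and restricted to glomeruli responding
    above threshold to more than one odorant; P is computed with every
    effective odorant as query and the median reported.  ``primary`` mode
    computes a single P per glomerulus using the supplied query odorant
    (e.g. the primary or strongest odorant).
    """
    out = {}
    for g in matrix.index:
        spec = matrix.loc[g].astype(float)
        peak = spec.max()
        if peak <= 0:
            continue
        effective = spec > response_threshold * peak
        binarized = effective.astype(float)
        if mode == "full":
            if effective.sum() < 2:
                continue
            ps = [
                performance_metric(binarized, distance.loc[q], q).P
                for q in spec.index[effective]
            ]
            out[g] = float(np.nanmedian(ps))
        elif mode == "primary":
            if primary is None:
                raise ValueError("primary mode needs a query odorant per glomerulus")
            q = primary[g]
            out[g] = performance_metric(binarized, distance.loc[q], q).P
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(out, dtype=float)


def expected_random_performance(auc_response: float) -> float:
    """Closed-form expectation of P under a uniformly random ranking: the
    random curve's expected AUC is 1/2, so E[P] = 1/AUC_response - 1."""
    return 1.0 / auc_response - 1.0
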