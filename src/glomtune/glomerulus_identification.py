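"""Functional identification of glomeruli across OBs via diagnostic odorants.

A *diagnostic* odorant singularly (or near-singularly) activates one
glomerulus at its delivered concentration, so the maximally-activated
glomerulus in each OB can be treated as the same functional unit across
animals.  The screen requires sparse activation (no more than two glomeruli
above 50% of the odorant's maximal response in every OB) and reliability
(a response in at least six of eight OBs and in every mouse; thresholds
scale proportionally for other OB counts).

Two statistics quantify how reliably an odorant tags the same glomerulus:

* the *error ratio* — over ordered pairs of responsive OBs (i, j), the
  fraction of comparisons in which the glomerulus of OB j whose full-panel
  spectrum best correlates (Pearson) with OB i's maximally-activated
  glomerulus is *not* OB j's own maximally-activated glomerulus;
* the *median ORS correlation* — the median over unordered OB pairs of the
  Pearson correlation between the full-panel spectra of the per-OB
  maximally-activated glomeruli.

Odorants with error ratio < 0.2 and median correlation > 0.8 are accepted
and grouped into unique glomeruli.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import ResponseDataset

logger = logging.getLogger(__name__)


@dataclass
class ConsensusGlomerulus:
    """A functionally-identified glomerulus and its cross-OB summary."""

    diagnostic_odorants: list[str]
    error_ratio: float
    median_ors_corr: float
    consensus_spectrum: pd.Series
    position_mean: tuple[float, float]
    position_sd: tuple[float, float]
    n_obs: int
    #: per-diagnostic-odorant (error ratio, median ORS correlation)
    odorant_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_ratio <= 1.0:
            raise ValueError("error ratio must lie in [0, 1]")
        peak = self.consensus_spectrum.max()
        if peak > 0 and not math.isclose(peak, 1.0, rel_tol=1e-9):
            raise ValueError("consensus spectrum must be max-normalized")


def _responsive_obs(dataset: ResponseDataset, odorant: str) -> list[int]:
    return [
        k for k, ob in enumerate(dataset) if (ob.responses[odorant] > 0).any()
    ]


def screen_diagnostic(
    dataset: ResponseDataset,
    cutoff: float = 0.5,
    min_ob_fraction: float = 6.0 / 8.0,
    max_strong: int = 2,
) -> list[str]:
    """Screen odorants for sparse, reliable singular activation.

    An odorant passes when (a) in every OB at most ``max_strong`` glomeruli
    respond above ``cutoff`` times that odorant's maximal response in that
    OB, and (b) it activates at least one glomerulus in at least
    ``min_ob_fraction`` of the OBs and in at least one OB of every mouse.
    """
    if len(dataset) < 2:
        raise ValueError("screen requires >= 2 OBs")
    if any(not ob.mouse_id for ob in dataset):
        raise ValueError("every OB needs a mouse id")
    mice = dataset.mouse_ids
    min_obs = math.ceil(min_ob_fraction * len(dataset))
    passed = []
    for odorant in dataset.odorants:
        sparse = True
        responsive_mice: set[str] = set()
        n_responsive = 0
        for ob in dataset:
            col = ob.responses[odorant].to_numpy()
            peak = col.max()
            if peak > 0:
                n_responsive += 1
                responsive_mice.add(ob.mouse_id)
                if (col > cutoff * peak).sum() > max_strong:
                    sparse = False
                    break
        if sparse and n_responsive >= min_obs and responsive_mice == set(mice):
            passed.append(odorant)
    return passed


def _zscore_rows(matrix: np.ndarray) -> np.ndarray:
    """Row-standardize so that correlation = dot product / n.  Zero-variance
    rows become all-zero (correlating to 0 with everything)."""
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / sd, 0.0)
    return z


def _max_glomerulus(ob, odorant: str) -> int:
    return int(np.argmax(ob.responses[odorant].to_numpy()))


def error_ratio(
    dataset: ResponseDataset, odorant: str, ordered: bool = True
) -> float:
    """Fraction of cross-OB comparisons where the maximally-activated
    glomerulus is not the best-spectrum-correlated glomerulus.

    Returns NaN (flagged) when the odorant is responsive in < 2 OBs.
    """
    resp = _responsive_obs(dataset, odorant)
    if len(resp) < 2:
        logger.warning("error ratio undefined for %r: responsive in < 2 OBs", odorant)
        return np.nan
    z = {k: _zscore_rows(dataset.obs[k].responses.to_numpy(dtype=float)) for k in resp}
    maxg = {k: _max_glomerulus(dataset.obs[k], odorant) for k in resp}
    n = dataset.obs[resp[0]].responses.shape[1]
    mismatches = 0
    comparisons = 0
    for i in resp:
        for j in resp:
            if j == i or (not ordered and j < i):
                continue
            corr = z[j] @ z[i][maxg[i]] / n
            if int(np.argmax(corr)) != maxg[j]:
                mismatches += 1
            comparisons += 1
    return mismatches / comparisons


def median_ors_correlation(dataset: ResponseDataset, odorant: str) -> float:
    """Median Pearson correlation, over unordered OB pairs, between the
    full-panel spectra of the per-OB maximally-activated glomeruli."""
    resp = _responsive_obs(dataset, odorant)
    if len(resp) < 2:
        logger.warning(
            "median ORS correlation undefined for %r: responsive in < 2 OBs", odorant
        )
        return np.nan
    spectra = {}
    for k in resp:
        ob = dataset.obs[k]
        spectra[k] = ob.responses.iloc[_max_glomerulus(ob, odorant)].to_numpy(dtype=float)
    corrs = []
    for i, j in combinations(resp, 2):
        si, sj = spectra[i], spectra[j]
        if si.std() == 0 or sj.std() == 0:
            logger.warning("skipping zero-variance spectrum pair (%s, %s)", i, j)
            continue
        corrs.append(float(np.corrcoef(si, sj)[0, 1]))
    return float(np.median(corrs)) if corrs else np.nan


def identify_glomeruli(
    dataset: ResponseDataset,
    r_min: float = 0.8,
    err_max: float = 0.2,
    cutoff: float = 0.5,
    min_ob_fraction: float = 6.0 / 8.0,
    ordered_pairs: bool = True,
) -> list[ConsensusGlomerulus]:
    """Identify unique glomeruli from diagnostic odorants.

    Screened odorants with median ORS correlation > ``r_min`` and error ratio
    < ``err_max`` are grouped: two odorants tag the same glomerulus when
    their per-OB maximally-activated glomeruli coincide in a majority of the
    OBs responsive to both.  The consensus spectrum is the per-odorant median
    across OBs of the tagged glomerulus's max-normalized spectrum; positions
    are summarized as mean +/- s.d. across OBs.
    """
    candidates = screen_diagnostic(dataset, cutoff=cutoff, min_ob_fraction=min_ob_fraction)
    stats: dict[str, tuple[float, float]] = {}
    accepted = []
    for odorant in candidates:
        err = error_ratio(dataset, odorant, ordered=ordered_pairs)
        med = median_ors_correlation(dataset, odorant)
        if np.isnan(err) or np.isnan(med):
            continue
        if med > r_min and err < err_max:
            stats[odorant] = (err, med)
            accepted.append(odorant)

    # per-odorant, per-OB index of the maximally-activated glomerulus
    maxg = {
        od: {
            k: _max_glomerulus(dataset.obs[k], od)
            for k in _responsive_obs(dataset, od)
        }
        for od in accepted
    }

    # group odorants whose max-activated glomeruli coincide in a majority of
    # the OBs responsive to both (connected components of the match graph)
    parent = {od: od for od in accepted}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(accepted, 2):
        common = sorted(set(maxg[a]) & set(maxg[b]))
        if not common:
            continue
        agree = sum(maxg[a][k] == maxg[b][k] for k in common)
        if agree > len(common) / 2:
            parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for od in accepted:
        groups.setdefault(find(od), []).append(od)

    out = []
    odorant_index = dataset.odorants
    for members in groups.values():
        members = sorted(members, key=odorant_index.index)
        lead = members[0]
        spectra, positions = [], []
        for k, g in maxg[lead].items():
            ob = dataset.obs[k]
            spec = ob.responses.iloc[g].to_numpy(dtype=float)
            peak = spec.max()
            spectra.append(spec / peak if peak > 0 else spec)
            positions.append(ob.positions.loc[ob.responses.index[g], ["ml_um", "ap_um"]])
        consensus = np.median(np.vstack(spectra), axis=0)
        peak = consensus.max()
        if peak > 0:
            consensus = consensus / peak
        pos = np.asarray(positions, dtype=float)
        out.append(
            ConsensusGlomerulus(
                diagnostic_odorants=members,
                error_ratio=stats[lead][0],
                median_ors_corr=stats[lead][1],
                odorant_stats={m: stats[m] for m in members},
                consensus_spectrum=pd.Series(consensus, index=odorant_index),
                position_mean=tuple(pos.mean(axis=0)),
                position_sd=tuple(pos.std(axis=0, ddof=1) if len(pos) > 1 else (0.0, 0.0)),
                n_obs=len(spectra),
            )
        )
    # stable output order: by first diagnostic odorant's panel position
    out.sort(key=lambda g: odorant_index.index(g.diagnostic_odorants[0]))
    return out


def consensus_table(glomeruli: list[ConsensusGlomerulus]) -> pd.DataFrame:
    """Tabular summary (one row per diagnostic odorant, grouped by glomerulus)."""
    rows = []
    for gi, g in enumerate(glomeruli, start=1):
        for od in g.diagnostic_odorants:
            err, med = g.odorant_stats.get(od, (g.error_ratio, g.median_ors_corr))
            rows.append(
                {
                    "glomerulus": gi,
                    "odorant": od,
                    "error_ratio": err,
                    "median_ors_corr": med,
                    "ml_um_mean": g.position_mean[0],
                    "ml_um_sd": g.position_sd[0],
                    "ap_um_mean": g.position_mean[1],
                    "ap_um_sd": g.position_sd[1],
                }
            )
    return pd.DataFrame(rows)
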