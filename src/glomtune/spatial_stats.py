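"""Spatial clustering of glomerular sensitivities via Ripley's K.

Glomerulus positions are grouped by the structural class of each
glomerulus's primary odorant (its lowest-concentration effective odorant)
and tested for spatial clustering against a Monte-Carlo null that resamples
the same number of positions, without replacement, from the OB's full
glomerular array.  Clustering is summarized by the *persistent radius*: the
smallest radius from which Ripley's K stays significantly above the null at
every larger radius on the grid.

Ripley's K for a point pattern of n points in a window W of area |W| is

    K(r) = |W| / (n (n - 1)) * sum_{i != j} e_ij * 1[d_ij <= r]

with isotropic (Ripley) edge-correction weights e_ij: the reciprocal of the
fraction of the circle of radius d_ij centered on point i that lies inside
the rectangular window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ResponseDataset
from .odorant_panel import MIXED, OdorantPanel

logger = logging.getLogger(__name__)


@dataclass
class PointPattern:
    """2-D points (um) with their rectangular observation window."""

    points: np.ndarray  # (n, 2)
    window: tuple[float, float, float, float]  # (x0, x1, y0, y1)
    group_label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        x0, x1, y0, y1 = self.window
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate window")
        inside = (
            (self.points[:, 0] >= x0) & (self.points[:, 0] <= x1)
            & (self.points[:, 1] >= y0) & (self.points[:, 1] <= y1)
        )
        if not inside.all():
            raise ValueError("all points must lie inside the window")

    @property
    def area(self) -> float:
        x0, x1, y0, y1 = self.window
        return (x1 - x0) * (y1 - y0)


def bounding_window(points: np.ndarray, pad: float = 0.0) -> tuple[float, float, float, float]:
    points = np.asarray(points, dtype=float)
    return (
        points[:, 0].min() - pad, points[:, 0].max() + pad,
        points[:, 1].min() - pad, points[:, 1].max() + pad,
    )


def assign_primary_class(
    dataset: ResponseDataset, panel: OdorantPanel
) -> dict[str, pd.Series]:
    """Per-OB mapping glomerulus -> structural class of its primary odorant.

    The primary odorant is the responsive odorant delivered at the lowest
    estimated concentration (ties and missing concentration metadata fall
    back to the strongest response, logged).  Glomeruli whose primary odorant
    is MIXED are excluded.
    """
    conc = pd.Series(
        {o.id: (np.nan if o.est_concentration is None else o.est_concentration)
         for o in panel}
    ).reindex(dataset.odorants)
    classes = panel.classes
    if conc.isna().all():
        logger.warning("no concentration metadata; primary = strongest response")
    out = {}
    for ob in dataset:
        labels = {}
        for g in ob.responses.index:
            spec = ob.responses.loc[g]
            effective = spec[spec > 0]
            if effective.empty:
                continue
            c = conc.loc[effective.index]
            if c.isna().all():
                primary = effective.idxmax()
            else:
                cmin = c.min()
                tied = c.index[c == cmin]
                primary = effective.loc[tied].idxmax() if len(tied) > 1 else tied[0]
            cls = classes.get(primary, MIXED)
            if cls == MIXED:
                continue
            labels[g] = cls
        out[ob.ob_id] = pd.Series(labels, dtype=object)
    return out


def _isotropic_weights(points: np.ndarray, d: np.ndarray,
                       window: tuple[float, float, float, float]) -> np.ndarray:
    """Ripley isotropic edge-correction weight for each (i, j) pair: 1 over
    the fraction of the circle of radius d_ij centered at point i inside the
    rectangular window."""
    x0, x1, y0, y1 = window
    dx1 = points[:, 0] - x0
    dx2 = x1 - points[:, 0]
    dy1 = points[:, 1] - y0
    dy2 = y1 - points[:, 1]
    r = d
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.zeros_like(r)
        for de in (dx1, dx2, dy1, dy2):
            ratio = np.clip(de[:, None] / r, -1.0, 1.0)
            out += 2.0 * np.arccos(ratio) * (de[:, None] < r)
        # overlapping arcs at the four corners
        for de1, de2 in ((dx1, dy1), (dx1, dy2), (dx2, dy1), (dx2, dy2)):
            both = (de1[:, None] ** 2 + de2[:, None] ** 2) < r**2
            overlap = np.arccos(np.clip(de1[:, None] / r, -1.0, 1.0)) - np.arcsin(
                np.clip(de2[:, None] / r, -1.0, 1.0)
            )
            out -= np.where(both, overlap, 0.0)
    frac_inside = 1.0 - out / (2.0 * np.pi)
    return 1.0 / np.clip(frac_inside, 1e-9, 1.0)


def ripleys_k(
    pattern: PointPattern,
    radii: np.ndarray | None = None,
    r_max: float = 400.0,
    n_steps: int = 512,
    edge_correction: str = "isotropic",
) -> pd.Series:
    """Ripley's K over a radius grid (default 512 uniform steps on
    [0, r_max]).  ``edge_correction``: ``isotropic`` or ``none``."""
    pts = pattern.points
    n = len(pts)
    if n < 3:
        raise ValueError("Ripley's K needs >= 3 points")
    if radii is None:
        radii = np.linspace(0.0, r_max, n_steps)
    radii = np.asarray(radii, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    if edge_correction == "isotropic":
        w = _isotropic_weights(pts, d, pattern.window)
    elif edge_correction == "none":
        w = np.ones_like(d)
    else:
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    iu = ~np.eye(n, dtype=bool)
    dvals = d[iu]
    wvals = w[iu]
    order = np.argsort(dvals)
    dvals, wvals = dvals[order], wvals[order]
    cum = np.concatenate([[0.0], np.cumsum(wvals)])
    idx = np.searchsorted(dvals, radii, side="right")
    k = pattern.area / (n * (n - 1)) * cum[idx]
    return pd.Series(k, index=pd.Index(radii, name="r_um"), name="K")


@dataclass
class ClusterTestResult:
    radii: np.ndarray
    k_observed: np.ndarray
    p_values: np.ndarray
    persistent_radius: float  # NaN when clustering never becomes persistent
    n_points: int
    alpha: float


def monte_carlo_cluster_test(
    group: PointPattern,
    universe: np.ndarray,
    n_iter: int = 10_000,
    alpha: float = 0.01,
    radii: np.ndarray | None = None,
    r_max: float = 400.0,
    n_steps: int = 512,
    rng: np.random.Generator | None = None,
    edge_correction: str = "isotropic",
) -> ClusterTestResult:
    """Upper-tail Monte-Carlo test of spatial clustering.

    The null resamples ``len(group)`` positions without replacement from the
    OB's full glomerular array ``universe`` (``n_iter`` times).  At each
    radius, p = (1 + #{K_sim >= K_obs}) / (1 + n_iter).  The persistent
    radius is the smallest grid radius from which p < alpha holds at every
    larger grid radius; NaN when no such radius exists.
    """
    rng = rng if rng is not None else np.random.default_rng()
    universe = np.asarray(universe, dtype=float)
    m = len(group.points)
    if m < 3:
        raise ValueError("need >= 3 group points")
    if m >= len(universe):
        raise ValueError("degenerate test: group is the whole glomerular array")
    if radii is None:
        radii = np.linspace(0.0, r_max, n_steps)
    radii = np.asarray(radii, dtype=float)

    window = group.window
    area = group.area

    # pair distances / weights precomputed once on the universe
    diff = universe[:, None, :] - universe[None, :, :]
    d_all = np.sqrt((diff**2).sum(axis=-1))
    if edge_correction == "isotropic":
        w_all = _isotropic_weights(universe, d_all, window)
    else:
        w_all = np.ones_like(d_all)

    k_obs = ripleys_k(group, radii=radii, edge_correction=edge_correction).to_numpy()

    factor = area / (m * (m - 1))
    exceed = np.zeros(radii.size)
    iu = ~np.eye(m, dtype=bool)
    for _ in range(n_iter):
        idx = rng.choice(len(universe), size=m, replace=False)
        d = d_all[np.ix_(idx, idx)][iu]
        w = w_all[np.ix_(idx, idx)][iu]
        order = np.argsort(d)
        cum = np.concatenate([[0.0], np.cumsum(w[order])])
        k_sim = factor * cum[np.searchsorted(d[order], radii, side="right")]
        exceed += k_sim >= k_obs
    p = (1.0 + exceed) / (1.0 + n_iter)

    sig = p < alpha
    # smallest grid radius from which significance holds at all larger radii
    holds_from = np.flip(np.logical_and.accumulate(np.flip(sig)))
    persistent = float(radii[int(np.argmax(holds_from))]) if holds_from.any() else np.nan
    return ClusterTestResult(
        radii=radii, k_observed=k_obs, p_values=p,
        persistent_radius=persistent, n_points=m, alpha=alpha,
    )


def cluster_classes(
    dataset: ResponseDataset,
    panel: OdorantPanel,
    n_iter: int = 1000,
    alpha: float = 0.01,
    min_group: int = 3,
    r_max: float = 400.0,
    n_steps: int = 512,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run the Monte-Carlo cluster test for every (OB, structural class) with
    at least ``min_group`` glomeruli.  Returns a tidy table with the
    persistent radius (NaN = no persistent clustering)."""
    rng = rng if rng is not None else np.random.default_rng()
    assignments = assign_primary_class(dataset, panel)
    rows = []
    for ob in dataset:
        labels = assignments[ob.ob_id]
        universe = ob.positions.loc[ob.responses.index, ["ml_um", "ap_um"]].to_numpy()
        window = bounding_window(universe, pad=1.0)
        for cls in panel.class_order:
            gids = labels.index[labels == cls]
            if len(gids) < min_group or len(gids) >= len(universe):
                continue
            pts = ob.positions.loc[gids, ["ml_um", "ap_um"]].to_numpy()
            res = monte_carlo_cluster_test(
                PointPattern(pts, window, group_label=cls),
                universe, n_iter=n_iter, alpha=alpha,
                r_max=r_max, n_steps=n_steps, rng=rng,
            )
            rows.append(
                {
                    "ob_id": ob.ob_id,
                    "structural_class": cls,
                    "n_points": res.n_points,
                    "persistent_radius_um": res.persistent_radius,
                    "significant": bool(np.isfinite(res.persistent_radius)),
                }
            )
    return pd.DataFrame(rows)
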