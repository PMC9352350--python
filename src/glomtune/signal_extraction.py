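"""From fluorescence frame stacks to glomerulus x odorant response matrices.

The stages mirror a widefield calcium-imaging workflow: trial-averaged dF
maps (post-onset minus pre-onset window means), a display rendering
(clipping, slight Gaussian smoothing, 2x bilinear upsampling), automated ROI
detection on the maximal dF projection across odorants, ROI trace
extraction normalized to baseline fluorescence, and a modified z-score
threshold that zeroes responses indistinguishable from a glomerulus's own
noise floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import OBResponse, ResponseDataset

logger = logging.getLogger(__name__)


@dataclass
class TrialStack:
    """Trial-resolved recording of one odorant presentation.

    ``frames`` is (trials, T, H, W) or an already trial-averaged (T, H, W).
    """

    frames: np.ndarray
    frame_rate: float
    odor_onset: float
    trial_count: int = 3

    def __post_init__(self) -> None:
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T,H,W) or (trials,T,H,W)")
        n_frames = self.frames.shape[-3]
        if not 0 < self.odor_onset < n_frames / self.frame_rate:
            raise ValueError("odor onset must fall within the recording")

    def trial_average(self) -> np.ndarray:
        return self.frames.mean(axis=0) if self.frames.ndim == 4 else self.frames


@dataclass
class ROI:
    pixels: np.ndarray  # (n, 2) array of (row, col) indices
    centroid: tuple[float, float]
    label: str


class WindowError(ValueError):
    pass


def compute_df_map(
    stack: TrialStack,
    pre_window_s: float = 1.0,
    post_window_s: tuple[float, float] = (2.0, 3.0),
) -> np.ndarray:
    """Pixelwise dF: mean over [onset+2 s, onset+3 s] minus mean over the
    1 s preceding odorant onset, on the trial-averaged stack."""
    frames = stack.trial_average()
    fr = stack.frame_rate
    onset = int(round(stack.odor_onset * fr))
    pre_lo = onset - int(round(pre_window_s * fr))
    post_lo = onset + int(round(post_window_s[0] * fr))
    post_hi = onset + int(round(post_window_s[1] * fr))
    if pre_lo < 0:
        raise WindowError("need >= 1 s of pre-onset frames")
    if post_hi > frames.shape[0]:
        raise WindowError("need >= 3 s of post-onset frames")
    pre = frames[pre_lo:onset].mean(axis=0)
    post = frames[post_lo:post_hi].mean(axis=0)
    return post - pre


def render_display_map(
    df: np.ndarray, top_n: int = 65, sigma: float = 0.75, upsample: int = 2
) -> np.ndarray:
    """Display rendering of a dF map: clip to [0, mean of the ``top_n``
    brightest pixels], smooth with a Gaussian kernel, bilinear-upsample."""
    if df.size == 0:
        raise ValueError("empty dF map")
    flat = np.sort(df, axis=None)
    ceiling = flat[-min(top_n, flat.size):].mean()
    clipped = np.clip(df, 0.0, ceiling if ceiling > 0 else None)
    smoothed = ndimage.gaussian_filter(clipped, sigma=sigma)
    if upsample == 1:
        return smoothed
    return ndimage.zoom(smoothed, upsample, order=1, grid_mode=True, mode="nearest")


def max_projection(df_maps: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Maximal dF projection across all odorants (raw, unsmoothed maps)."""
    return np.max(np.asarray(df_maps), axis=0)


def detect_rois(
    projection: np.ndarray,
    threshold: float | None = None,
    threshold_fraction: float = 0.2,
    diameter_range_px: tuple[float, float] = (4.0, 30.0),
    min_extent: float = 0.4,
) -> list[ROI]:
    """Segment approximately circular blobs from a maximal dF projection.

    The projection is thresholded (absolute ``threshold``, or
    ``threshold_fraction`` of its maximum), connected components are taken,
    and components are kept when their equivalent diameter lies within
    ``diameter_range_px`` and they fill at least ``min_extent`` of their
    bounding box (a cheap circularity proxy).  Components larger than the
    diameter ceiling are logged as possible merges of overlapping foci.
    """
    if threshold is None:
        peak = float(projection.max())
        if peak <= 0:
            return []
        threshold = threshold_fraction * peak
    logger.info("ROI detection threshold: %.4g", threshold)
    mask = projection > threshold
    labels, n = ndimage.label(mask)
    rois: list[ROI] = []
    lo, hi = diameter_range_px
    for lab in range(1, n + 1):
        pix = np.argwhere(labels == lab)
        area = len(pix)
        diameter = 2.0 * np.sqrt(area / np.pi)
        rows, cols = pix[:, 0], pix[:, 1]
        bbox_area = (rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1)
        extent = area / bbox_area
        if diameter > hi:
            logger.warning(
                "component %d (diameter %.1f px) exceeds maximum diameter; "
                "possible merged overlapping foci", lab, diameter
            )
            continue
        if diameter < lo or extent < min_extent:
            continue
        rois.append(ROI(pixels=pix, centroid=(rows.mean(), cols.mean()),
                        label=f"roi{len(rois):03d}"))
    return rois


def extract_responses(
    stacks: dict[str, TrialStack],
    rois: list[ROI],
    ob_id: str = "ob0",
    mouse_id: str = "m0",
    positions: pd.DataFrame | None = None,
) -> OBResponse:
    """Mean dF of each ROI's pixels per odorant, normalized to the ROI's
    baseline (pre-odorant) fluorescence to give dF/F."""
    odorants = list(stacks)
    shape = next(iter(stacks.values())).trial_average().shape[1:]
    for roi in rois:
        if (roi.pixels[:, 0] >= shape[0]).any() or (roi.pixels[:, 1] >= shape[1]).any():
            raise ValueError(f"ROI {roi.label} outside image geometry {shape}")

    baseline = np.zeros(len(rois))
    matrix = np.zeros((len(rois), len(odorants)))
    n_base = np.zeros(len(rois))
    for j, od in enumerate(odorants):
        stack = stacks[od]
        frames = stack.trial_average()
        onset = int(round(stack.odor_onset * stack.frame_rate))
        pre = frames[max(0, onset - int(round(stack.frame_rate))):onset].mean(axis=0)
        df = compute_df_map(stack)
        for i, roi in enumerate(rois):
            r, c = roi.pixels[:, 0], roi.pixels[:, 1]
            matrix[i, j] = df[r, c].mean()
            baseline[i] += pre[r, c].mean()
            n_base[i] += 1
    baseline /= np.maximum(n_base, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = matrix / baseline[:, None]
    labels = [roi.label for roi in rois]
    if positions is None:
        positions = pd.DataFrame(
            [roi.centroid for roi in rois], index=labels, columns=["ml_um", "ap_um"]
        )
    return OBResponse(
        responses=pd.DataFrame(dff, index=labels, columns=odorants),
        positions=positions,
        ob_id=ob_id,
        mouse_id=mouse_id,
        baseline_f=pd.Series(baseline, index=labels),
    )


def zero_misattributed(
    df_maps: dict[str, np.ndarray],
    rois: list[ROI],
    response: OBResponse,
    halo_px: int = 5,
) -> OBResponse:
    """Deterministic stand-in for visual response attribution: zero any
    ROI-odorant entry whose local dF peak lies outside the ROI.

    For each nonzero entry, the dF map's maximum within the ROI's bounding
    box expanded by ``halo_px`` is located; if that peak pixel is not one of
    the ROI's own pixels the response is attributed to a neighboring focus
    and zeroed.
    """
    matrix = response.responses.to_numpy().copy()
    for i, roi in enumerate(rois):
        rows, cols = roi.pixels[:, 0], roi.pixels[:, 1]
        pixset = {(int(r), int(c)) for r, c in roi.pixels}
        for j, od in enumerate(response.responses.columns):
            if matrix[i, j] == 0:
                continue
            df = df_maps[od]
            r0 = max(0, rows.min() - halo_px)
            r1 = min(df.shape[0], rows.max() + halo_px + 1)
            c0 = max(0, cols.min() - halo_px)
            c1 = min(df.shape[1], cols.max() + halo_px + 1)
            window = df[r0:r1, c0:c1]
            pr, pc = np.unravel_index(np.argmax(window), window.shape)
            if (pr + r0, pc + c0) not in pixset:
                matrix[i, j] = 0.0
    return OBResponse(
        responses=pd.DataFrame(
            matrix, index=response.responses.index, columns=response.responses.columns
        ),
        positions=response.positions,
        ob_id=response.ob_id,
        mouse_id=response.mouse_id,
        baseline_f=response.baseline_f,
    )


def _row_noise_sd(row: np.ndarray, upper_pct: float, lower_pct: float) -> float:
    """S.d. of a response row excluding its top ``upper_pct`` and bottom
    ``lower_pct`` percentiles (linear-interpolation percentiles)."""
    lo = np.percentile(row, lower_pct)
    hi = np.percentile(row, 100.0 - upper_pct)
    trimmed = row[(row >= lo) & (row <= hi)]
    if trimmed.size < 2:
        return 0.0
    return float(trimmed.std(ddof=0))


def threshold_modified_z(
    matrix: pd.DataFrame,
    z_cut: float = 9.0,
    upper_pct: float = 10.0,
    lower_pct: float = 5.0,
) -> pd.DataFrame:
    """Zero entries whose modified z-score falls below ``z_cut``.

    Per glomerulus (row), the noise s.d. is the s.d. of its dF/F values
    excluding the top 10th and bottom 5th percentiles; entries with
    value / s.d. < ``z_cut`` are set to zero.  Rows with zero trimmed s.d.
    fall back to the global trimmed s.d. of the matrix (logged).
    """
    if matrix.shape[1] < 20:
        raise ValueError("need >= 20 odorants for percentile-trimmed noise estimate")
    values = matrix.to_numpy(dtype=float).copy()
    global_sd = _row_noise_sd(values.ravel(), upper_pct, lower_pct)
    out = values.copy()
    for i, row in enumerate(values):
        if not row.any():
            continue
        sd = _row_noise_sd(row, upper_pct, lower_pct)
        if sd == 0.0:
            sd = global_sd
            logger.info(
                "row %s: zero trimmed s.d.; falling back to global noise floor %.3g",
                matrix.index[i], sd,
            )
        if sd == 0.0 or z_cut == 0.0:
            continue
        out[i, row / sd < z_cut] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def threshold_dataset(dataset: ResponseDataset, z_cut: float = 9.0) -> ResponseDataset:
    """Apply :func:`threshold_modified_z` to every OB of a dataset."""
    obs = [
        OBResponse(
            responses=threshold_modified_z(ob.responses, z_cut=z_cut),
            positions=ob.positions,
            ob_id=ob.ob_id,
            mouse_id=ob.mouse_id,
            baseline_f=ob.baseline_f,
        )
        for ob in dataset
    ]
    return ResponseDataset(obs)
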