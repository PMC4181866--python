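"""Detection-based and spectral quantification of reconstruction quality.

Small dark objects are detected with a per-slice grayscale bottom-hat
filter (morphological closing minus the image, 5×5 square structuring
element), thresholded at an intensity percentile of the bottom-hat map,
and grouped into 3D connected components.  Detections are matched
one-to-one against ground-truth objects by overlap; precision, recall and
F-score = 2PR/(P+R) summarize quality, optionally stratified by object
size or swept over thresholds to find the optimum.

Resolution is assessed independently of detection via the windowed
Fourier spectrum of a slice: more high-frequency energy (up to the
reconstruction Nyquist) indicates genuinely recovered detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateInputError
from .phantom import PhantomTruth

__all__ = [
    "DetectionParams",
    "DetectionResult",
    "SpectrumResult",
    "bottom_hat_detect",
    "bottom_hat_map",
    "score_detection",
    "threshold_sweep",
    "size_stratified_fscore",
    "windowed_spectrum",
    "fscore",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectionParams:
    """Bottom-hat spot-detection settings.

    The structuring element is a 2D square applied per transversal slice
    (``slice_axis`` indexes the through-slice axis); components are linked
    across slices with 3D 26-connectivity.  ``boundary_margin_vox`` erodes
    the evaluation mask so rim artifacts near the container boundary are
    disregarded.
    """

    se_size: int = 5
    percentile: float = 99.5
    percentiles: tuple[float, ...] = (
        90.0, 95.0, 97.5, 99.0, 99.5, 99.8, 99.9, 99.93, 99.95, 99.97, 99.99,
    )
    slice_axis: int = 1
    boundary_margin_vox: int = 3
    min_size_vox: int = 1

    def __post_init__(self) -> None:
        for p in (self.percentile, *self.percentiles):
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"percentile {p} outside [0, 100]")
        if self.boundary_margin_vox < 0:
            raise ValueError("boundary margin must be >= 0")
        if self.se_size < 1 or self.se_size % 2 == 0:
            raise ValueError("structuring element size must be odd and >= 1")


@dataclass
class DetectionResult:
    labels: np.ndarray
    precision: float
    recall: float
    f_score: float
    threshold_percentile: float
    tp_ids: list[int] = field(default_factory=list)
    fp_ids: list[int] = field(default_factory=list)
    fn_truth_ids: list[int] = field(default_factory=list)


@dataclass
class SpectrumResult:
    spectrum: np.ndarray
    freq_x: np.ndarray
    freq_y: np.ndarray
    hf_fraction: float
    cutoff_fraction: float


def fscore(precision: float, recall: float) -> float:
    """F = 2PR/(P+R); zero when both are zero."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _se_footprint(params: DetectionParams) -> np.ndarray:
    """5×5 square in the slice plane, extent 1 along the slice axis."""
    shape = [params.se_size] * 3
    shape[params.slice_axis] = 1
    return np.ones(shape, dtype=bool)


def bottom_hat_map(volume: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Grayscale bottom-hat (closing − image), per transversal slice."""
    volume = np.asarray(volume, dtype=float)
    closing = ndimage.grey_closing(volume, footprint=_se_footprint(params))
    return closing - volume


def _eval_mask(
    volume_shape: tuple[int, ...],
    params: DetectionParams,
    mask: np.ndarray | None,
) -> np.ndarray:
    if mask is None:
        m = np.ones(volume_shape, dtype=bool)
    else:
        m = np.asarray(mask).astype(bool)
    if params.boundary_margin_vox > 0:
        m = ndimage.binary_erosion(m, iterations=params.boundary_margin_vox)
    if not m.any():
        raise DegenerateInputError("evaluation mask is empty after erosion")
    return m


def bottom_hat_detect(
    volume: np.ndarray,
    params: DetectionParams,
    mask: np.ndarray | None = None,
    percentile: float | None = None,
    _bh: np.ndarray | None = None,
) -> np.ndarray:
    """Detect dark spots; returns a 3D label volume.

    Voxels whose bottom-hat response exceeds the given intensity
    percentile of the (masked) bottom-hat map are kept, restricted to the
    eroded evaluation mask, and labeled with 26-connectivity; components
    smaller than ``min_size_vox`` are dropped.
    """
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    pct = params.percentile if percentile is None else percentile
    bh = bottom_hat_map(volume, params) if _bh is None else _bh
    m = _eval_mask(np.shape(volume), params, mask)
    thr = np.percentile(bh[m], pct)
    cand = (bh > thr) & m
    labels, n = ndimage.label(cand, structure=_CONN26)
    if params.min_size_vox > 1 and n:
        sizes = np.bincount(labels.ravel())
        small = np.nonzero(sizes < params.min_size_vox)[0]
        labels[np.isin(labels, small)] = 0
        labels, _ = ndimage.label(labels > 0, structure=_CONN26)
    return labels


def _match(
    detected: np.ndarray, truth_labels: np.ndarray
) -> tuple[list[tuple[int, int, int]], list[int], list[int]]:
    """Greedy one-to-one matching by descending voxel overlap (≥1 voxel).

    Returns (matches [(det, truth, overlap)], unmatched detections,
    unmatched truth ids).
    """
    det_ids = np.unique(detected)
    det_ids = det_ids[det_ids > 0]
    tr_ids = np.unique(truth_labels)
    tr_ids = tr_ids[tr_ids > 0]
    both = (detected > 0) & (truth_labels > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        d = detected[both]
        t = truth_labels[both]
        uniq, counts = np.unique(np.stack([d, t]), axis=1, return_counts=True)
        for (di, ti), c in zip(uniq.T, counts):
            pairs[(int(di), int(ti))] = int(c)
    order = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for (di, ti), c in order:
        if di in used_d or ti in used_t:
            continue
        matches.append((di, ti, c))
        used_d.add(di)
        used_t.add(ti)
    fp = [int(i) for i in det_ids if i not in used_d]
    fn = [int(i) for i in tr_ids if i not in used_t]
    return matches, fp, fn


def score_detection(
    detected: np.ndarray,
    truth: PhantomTruth | np.ndarray,
    threshold_percentile: float = float("nan"),
) -> DetectionResult:
    """Match detections to truth objects and compute precision/recall/F.

    A detection is a true positive if it is greedily matched (≥1 voxel of
    overlap, one-to-one) to a truth object.  Empty detections give
    P = R = F = 0 when truth is nonempty.
    """
    truth_labels = truth.labels if isinstance(truth, PhantomTruth) else truth
    if np.shape(detected) != np.shape(truth_labels):
        raise ValueError(
            f"detected shape {np.shape(detected)} != truth shape "
            f"{np.shape(truth_labels)}"
        )
    matches, fp, fn = _match(detected, truth_labels)
    tp = len(matches)
    n_det = tp + len(fp)
    n_tr = tp + len(fn)
    precision = tp / n_det if n_det else 0.0
    recall = tp / n_tr if n_tr else 0.0
    return DetectionResult(
        labels=detected,
        precision=precision,
        recall=recall,
        f_score=fscore(precision, recall),
        threshold_percentile=threshold_percentile,
        tp_ids=[m[0] for m in matches],
        fp_ids=fp,
        fn_truth_ids=fn,
    )


def threshold_sweep(
    volume: np.ndarray,
    truth: PhantomTruth,
    params: DetectionParams,
    mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float, DetectionResult]:
    """F-score curve over the percentile grid; returns the optimum.

    The bottom-hat map is computed once and re-thresholded per percentile.
    Ties in F are broken toward the higher (more conservative) percentile.
    Returns ``(table, best_percentile, best_result)``.
    """
    if len(params.percentiles) < 1:
        raise ValueError("need at least one percentile")
    bh = bottom_hat_map(volume, params)
    rows = []
    best: tuple[float, float, DetectionResult] | None = None
    for pct in params.percentiles:
        labels = bottom_hat_detect(volume, params, mask, percentile=pct, _bh=bh)
        res = score_detection(labels, truth, threshold_percentile=pct)
        rows.append(
            {
                "percentile": pct,
                "precision": res.precision,
                "recall": res.recall,
                "f_score": res.f_score,
            }
        )
        if best is None or res.f_score >= best[0]:
            best = (res.f_score, pct, res)
    table = pd.DataFrame(rows)
    return table, best[1], best[2]


def size_stratified_fscore(
    volume: np.ndarray,
    truth: PhantomTruth,
    params: DetectionParams,
    size_cutoffs: list[int],
    mask: np.ndarray | None = None,
    detected: np.ndarray | None = None,
) -> pd.DataFrame:
    """F-score restricted to objects strictly larger than each cutoff.

    Detections are matched against the full truth once; then, per cutoff,
    scoring is restricted to truth objects with ``size_vox > cutoff``
    (a matched truth object counts as a true positive regardless of how
    many voxels its detection retained at the chosen threshold) and,
    symmetrically, unmatched detections (false-positive candidates) of at
    most ``cutoff`` voxels are excluded.  A cutoff at or beyond the
    largest truth object yields a missing value.  Cutoffs must ascend.
    """
    if any(b <= a for a, b in zip(size_cutoffs, size_cutoffs[1:])):
        raise ValueError("size cutoffs must be strictly ascending")
    if detected is None:
        detected = bottom_hat_detect(volume, params, mask)
    matches, fp_ids, _fn = _match(detected, truth.labels)
    matched_truth = {t for _d, t, _c in matches}
    det_sizes = np.bincount(detected.ravel()) if detected.max() > 0 else np.zeros(1, int)
    truth_sizes = dict(zip(truth.table["id"], truth.table["size_vox"]))
    rows = []
    for cutoff in size_cutoffs:
        keep_truth = {i for i, s in truth_sizes.items() if s > cutoff}
        if not keep_truth:
            rows.append({"cutoff": cutoff, "precision": np.nan, "recall": np.nan,
                         "f_score": np.nan})
            continue
        tp = len(keep_truth & matched_truth)
        fn = len(keep_truth) - tp
        fp = sum(1 for d in fp_ids if det_sizes[d] > cutoff)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        rows.append(
            {
                "cutoff": cutoff,
                "precision": precision,
                "recall": recall,
                "f_score": fscore(precision, recall),
            }
        )
    return pd.DataFrame(rows)


def windowed_spectrum(
    slice_2d: np.ndarray,
    spacing_mm: float,
    window: str = "hann",
    cutoff_fraction: float = 0.5,
) -> SpectrumResult:
    """Windowed 2D Fourier magnitude of a slice, up to the grid Nyquist.

    A tapering window suppresses FOV-edge leakage; the high-frequency
    energy fraction is the squared-magnitude mass at radial frequency
    above ``cutoff_fraction`` × Nyquist, DC-free (the mean is removed so
    bulk brightness does not dilute the fraction).
    """
    s = np.asarray(slice_2d, dtype=float)
    if s.ndim != 2 or min(s.shape) < 8:
        raise ValueError("slice must be 2D and at least 8×8")
    if window == "hann":
        w0 = np.hanning(s.shape[0])
        w1 = np.hanning(s.shape[1])
        win = np.outer(w0, w1)
    elif window == "none":
        win = np.ones(s.shape)
    else:
        raise ValueError(f"unknown window {window!r}")
    tapered = (s - s.mean()) * win
    spec = np.abs(np.fft.fftshift(np.fft.fft2(tapered)))
    fx = np.fft.fftshift(np.fft.fftfreq(s.shape[0], d=spacing_mm))
    fy = np.fft.fftshift(np.fft.fftfreq(s.shape[1], d=spacing_mm))
    nyquist = 0.5 / spacing_mm
    FX, FY = np.meshgrid(fx, fy, indexing="ij")
    radial = np.hypot(FX, FY)
    energy = spec**2
    total = energy.sum()
    hf = energy[radial > cutoff_fraction * nyquist].sum()
    frac = float(hf / total) if total > 0 else 0.0
    return SpectrumResult(
        spectrum=spec,
        freq_x=fx,
        freq_y=fy,
        hf_fraction=frac,
        cutoff_fraction=cutoff_fraction,
    )
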