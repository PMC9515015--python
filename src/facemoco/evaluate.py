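"""Quantitative readouts: SUVR tables, inferior-colliculus profile contrast,
test-retest agreement, exact Wilcoxon signed-rank test, motion summaries.

SUVR: mean uptake of each volume of interest divided by the cerebellar
mean — invariant under global intensity scaling, so reconstruction scale
never matters.  The inferior colliculus (paired ~6-mm midbrain nuclei) is
the small-structure benchmark: the peak-to-valley ratio of a profile line
through both nuclei, (peak1 + peak2)/2 / valley, measures whether the pair
is resolved.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import LABELS, SUVR_VOI_NAMES
from .transforms import motion_magnitude
from .volume import ImageVolume

__all__ = [
    "SuvrTable",
    "ProfileCurve",
    "NoStructureError",
    "compute_suvr",
    "profile_line_through_labels",
    "peak_to_valley",
    "test_retest",
    "wilcoxon_signed_rank",
    "motion_summary",
]


class NoStructureError(ValueError):
    """The profile shows no two peaks around a central valley (structure
    not visualized — the uncorrected-scan failure mode)."""


@dataclasses.dataclass
class SuvrTable:
    """Per-VOI means and cerebellar-normalized ratios."""

    voi_names: list
    means: np.ndarray
    suvr: np.ndarray
    missing: list

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"voi": self.voi_names, "mean": self.means, "suvr": self.suvr})

    def to_csv(self, path: str) -> None:
        self.as_dataframe().to_csv(path, index=False)

    def suvr_of(self, name: str) -> float:
        return float(self.suvr[self.voi_names.index(name)])


def compute_suvr(
    volume: ImageVolume,
    voi_labels: ImageVolume,
    voi_names: Sequence[str] = SUVR_VOI_NAMES,
    reference: str = "cerebellum",
) -> SuvrTable:
    """Mean VOI values normalized by the cerebellar mean.

    Labels must live on the same grid as the image (resample labels with
    nearest-neighbour first if needed).  Empty VOIs are flagged missing
    (NaN), never silently zero.
    """
    if not volume.same_grid(voi_labels):
        raise ValueError("image and label volumes are on different grids")
    vals = np.asarray(volume.values, dtype=float)
    lab = np.asarray(voi_labels.values)
    ref_mask = lab == LABELS[reference]
    if not ref_mask.any():
        raise ValueError(f"reference VOI '{reference}' is empty")
    ref_mean = float(vals[ref_mask].mean())
    means, missing = [], []
    for name in voi_names:
        m = lab == LABELS[name]
        if m.any():
            means.append(float(vals[m].mean()))
        else:
            means.append(np.nan)
            missing.append(name)
    means = np.array(means)
    return SuvrTable(list(voi_names), means, means / ref_mean, missing)


@dataclasses.dataclass
class ProfileCurve:
    positions_mm: np.ndarray
    values: np.ndarray

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"position_mm": self.positions_mm, "value": self.values}
        ).to_csv(path, index=False)


def profile_line_through_labels(
    labels: ImageVolume,
    label_a: str = "inferior_colliculus_left",
    label_b: str = "inferior_colliculus_right",
    extend_mm: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints of the profile line through two label centroids, extended
    ``extend_mm`` beyond each."""
    lab = np.asarray(labels.values)
    pts = []
    for name in (label_a, label_b):
        idx = np.argwhere(lab == LABELS[name])
        if len(idx) == 0:
            raise ValueError(f"label '{name}' is empty")
        pts.append(labels.index_to_world(idx.mean(axis=0)))
    a, b = pts
    d = (b - a) / np.linalg.norm(b - a)
    return a - extend_mm * d, b + extend_mm * d


def sample_profile(
    volume: ImageVolume, line: tuple[np.ndarray, np.ndarray], n_samples: int = 0
) -> ProfileCurve:
    a, b = (np.asarray(p, dtype=float) for p in line)
    length = float(np.linalg.norm(b - a))
    if n_samples <= 0:
        n_samples = max(5, int(round(length / 0.5)) + 1)  # 0.5-mm sampling
    pos = np.linspace(0.0, length, n_samples)
    pts = a + (pos / length)[:, None] * (b - a)
    return ProfileCurve(pos, volume.sample_world(pts))


def _local_extrema(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    interior = np.arange(1, len(y) - 1)
    maxima = interior[(y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])]
    minima = interior[(y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])]
    return maxima, minima


def peak_to_valley(
    volume: ImageVolume,
    line: tuple[np.ndarray, np.ndarray],
    n_samples: int = 0,
) -> tuple[float, ProfileCurve]:
    """Contrast of a bilateral structure on a profile line.

    Samples the image along the line (trilinear), finds the central local
    minimum (valley) and the highest local maximum on each side (peak1,
    peak2), and returns ((peak1 + peak2)/2) / valley together with the
    curve.  Raises :class:`NoStructureError` when two flanking peaks do not
    exist — the structure is not visualized.
    """
    curve = sample_profile(volume, line, n_samples)
    y = curve.values
    maxima, minima = _local_extrema(y)
    if len(maxima) < 2 or len(minima) < 1:
        raise NoStructureError("profile shows no two peaks around a valley")
    center = (len(y) - 1) / 2.0
    # central valley: the local minimum nearest the line midpoint that has
    # at least one local maximum on each side
    for v in sorted(minima, key=lambda i: abs(i - center)):
        left = maxima[maxima < v]
        right = maxima[maxima > v]
        if len(left) and len(right):
            p1 = y[left].max()
            p2 = y[right].max()
            valley = y[v]
            if valley <= 0:
                raise NoStructureError("non-positive valley value")
            return float((p1 + p2) / 2.0 / valley), curve
    raise NoStructureError("no valley flanked by peaks on both sides")


def peak_to_valley_or_flat(
    volume: ImageVolume, line: tuple[np.ndarray, np.ndarray], n_samples: int = 0
) -> float:
    """Like :func:`peak_to_valley` but maps 'not visualized' to ratio 1.0."""
    try:
        ratio, _ = peak_to_valley(volume, line, n_samples)
        return ratio
    except NoStructureError:
        return 1.0


def test_retest(suvr1: SuvrTable, suvr2: SuvrTable) -> tuple[float, float]:
    """Agreement of two SUVR tables: (OLS r^2, through-origin slope).

    r^2 is the squared Pearson correlation of the ordinary least-squares
    fit; the slope is fit separately through the origin (the y = a·x
    convention for reporting test-retest calibration agreement).
    """
    if suvr1.voi_names != suvr2.voi_names:
        raise KeyError("SUVR tables cover different VOI sets")
    x = np.asarray(suvr1.suvr, dtype=float)
    y = np.asarray(suvr2.suvr, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired VOIs")
    r = np.corrcoef(x, y)[0, 1]
    slope = float(x @ y / (x @ x))
    return float(r * r), slope


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon convention) and ties midranked.
    The null distribution of W+ is built by exact enumeration of all 2^n
    equally likely sign assignments, evaluated by convolution over doubled
    (hence integer) ranks; p = min(1, 2 min(P(W+ <= w), P(W+ >= w))).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have the same length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        import warnings

        warnings.warn("all differences are zero; p = 1")
        return 1.0
    if not 1 <= n <= 25:
        raise ValueError("exact enumeration supported for 1 <= n <= 25 nonzero pairs")
    ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
    r2 = np.round(2 * ranks).astype(int)  # doubled midranks are integers
    w_plus = int(r2[d > 0].sum())
    # distribution of doubled W+ over all sign assignments
    dist = np.zeros(r2.sum() + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = 0.5 * (dist + shifted)
    p_le = dist[: w_plus + 1].sum()
    p_ge = dist[w_plus:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def motion_summary(trajectory_or_tracking) -> dict:
    """Max/mean/min of the per-frame translation (mm) and rotation (deg)."""
    mags = trajectory_or_tracking.magnitudes()
    if len(mags) == 0:
        raise ValueError("empty trajectory")
    t, r = mags[:, 0], mags[:, 1]
    return {
        "translation_max_mm": float(t.max()),
        "translation_mean_mm": float(t.mean()),
        "translation_min_mm": float(t.min()),
        "rotation_max_deg": float(r.max()),
        "rotation_mean_deg": float(r.mean()),
        "rotation_min_deg": float(r.min()),
    }


def nrmse(image: ImageVolume, reference: ImageVolume) -> float:
    """Normalized root-mean-square error vs a reference image.

    Both images are mean-normalized over the reference support first, so
    absolute reconstruction scale (which list-mode EM does not fix) cancels.
    """
    a = np.asarray(image.values, dtype=float)
    b = np.asarray(reference.values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images on different grids")
    support = b > 0.05 * b.max()
    a = a / max(a[support].mean(), 1e-30)
    b = b / max(b[support].mean(), 1e-30)
    return float(np.sqrt(np.mean((a[support] - b[support]) ** 2)) / np.sqrt(np.mean(b[support] ** 2)))


def plot_suvr_comparison(tables: dict, path: str) -> None:
    """Grouped bar chart of SUVR tables (one group per VOI)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = next(iter(tables.values())).voi_names
    x = np.arange(len(names))
    width = 0.8 / len(tables)
    fig, ax = plt.subplots(figsize=(9, 4))
    for i, (label, tab) in enumerate(tables.items()):
        ax.bar(x + i * width, tab.suvr, width, label=label)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(names, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("SUVR (cerebellar-normalized)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profile(curves: dict, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        ax.plot(c.positions_mm, c.values, label=label)
    ax.set_xlabel("position along profile (mm)")
    ax.set_ylabel("image value")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def motion_summary_multi(trajectories) -> dict:
    """Across-scan motion statistics: max of maxima, mean of means, min of
    minima — the per-cohort figures reported alongside per-scan summaries."""
    per_scan = [motion_summary(t) for t in trajectories]
    if not per_scan:
        raise ValueError("no trajectories given")
    return {
        "translation_max_mm": max(s["translation_max_mm"] for s in per_scan),
        "translation_mean_mm": float(
            np.mean([s["translation_mean_mm"] for s in per_scan])
        ),
        "translation_min_mm": min(s["translation_min_mm"] for s in per_scan),
        "rotation_max_deg": max(s["rotation_max_deg"] for s in per_scan),
        "rotation_mean_deg": float(
            np.mean([s["rotation_mean_deg"] for s in per_scan])
        ),
        "rotation_min_deg": min(s["rotation_min_deg"] for s in per_scan),
        "n_scans": len(per_scan),
    }
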