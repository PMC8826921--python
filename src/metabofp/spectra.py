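"""Spectral feature extraction: fixed-width ppm bucketing, scaling, exploratory PCA.

A processed 1D serum spectrum over 0.2-10.0 ppm is integrated into 0.02-ppm
buckets; buckets touching the residual-water window (4.68-4.84 ppm) are
discarded whole. The retained bucket intensities form the multivariate data
matrix used by the discriminant and validation stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class CoverageError(ValueError):
    """Spectrum does not cover the requested bucketing range."""


class AlignmentError(ValueError):
    """Spectra and metadata cannot be aligned one-to-one."""


@dataclass
class Spectrum:
    """One processed 1D NMR trace on a ppm axis.

    ``ppm`` must be strictly monotone (ascending or descending); intensities
    finite and of equal length.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D and equally long")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def ascending(self) -> "Spectrum":
        if self.ppm[0] < self.ppm[-1]:
            return self
        return Spectrum(self.ppm[::-1].copy(), self.intensity[::-1].copy(), self.sample_id)


@dataclass(frozen=True)
class BucketSpec:
    """Bucketing geometry: half-open [low, low+width) tiles in descending-ppm
    output order, with exclusion windows dropped whole."""

    range_low_ppm: float = 0.2
    range_high_ppm: float = 10.0
    width_ppm: float = 0.02
    exclusions: tuple[tuple[float, float], ...] = ((4.68, 4.84),)

    def __post_init__(self) -> None:
        if not self.range_low_ppm < self.range_high_ppm:
            raise ValueError("range_low_ppm must be < range_high_ppm")
        if self.width_ppm <= 0:
            raise ValueError("width_ppm must be positive")
        for lo, hi in self.exclusions:
            if not (lo < hi):
                raise ValueError("exclusion interval must have low < high")
            if lo < self.range_low_ppm or hi > self.range_high_ppm:
                raise ValueError("exclusions must lie within the bucketing range")

    def edges(self) -> np.ndarray:
        """Ascending tile edges; the last tile may extend past range_high."""
        n = int(np.ceil(round((self.range_high_ppm - self.range_low_ppm) / self.width_ppm, 9)))
        return self.range_low_ppm + self.width_ppm * np.arange(n + 1)

    def retained_mask(self) -> np.ndarray:
        """Boolean mask (ascending tile order) of tiles kept after exclusion."""
        e = self.edges()
        lo, hi = e[:-1], e[1:]
        keep = np.ones(lo.size, dtype=bool)
        tol = 1e-9 * max(1.0, abs(self.range_high_ppm))  # guard float tiling edges
        for xlo, xhi in self.exclusions:
            keep &= ~((lo < xhi - tol) & (hi > xlo + tol))
        return keep

    def bucket_centers(self) -> np.ndarray:
        """Centers of retained buckets, descending ppm (NMR convention)."""
        e = self.edges()
        centers = (e[:-1] + e[1:]) / 2.0
        return centers[self.retained_mask()][::-1].copy()


@dataclass
class BucketMatrix:
    """Samples x retained-bucket intensities with aligned metadata."""

    values: np.ndarray
    bucket_centers_ppm: np.ndarray
    meta: list  # list[SampleMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.bucket_centers_ppm):
            raise ValueError("column count must match bucket centers")
        if self.values.shape[0] != len(self.meta):
            raise AlignmentError("row count must match metadata length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("bucket values must be finite")


def _piecewise_linear_cumint(ppm: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Integral of the piecewise-linear interpolant of (ppm, y) from ppm[0] to
    each query point x (exact, not a grid approximation)."""
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(ppm))))
    idx = np.clip(np.searchsorted(ppm, x, side="right") - 1, 0, ppm.size - 2)
    x0 = ppm[idx]
    dx = x - x0
    slope = (y[idx + 1] - y[idx]) / (ppm[idx + 1] - ppm[idx])
    return cum[idx] + y[idx] * dx + 0.5 * slope * dx * dx


def bucket_spectrum(s: Spectrum, spec: BucketSpec | None = None) -> np.ndarray:
    """Integrate one spectrum over the retained buckets.

    Bucket value is the trapezoidal (piecewise-linear) integral of intensity
    over the half-open tile; output follows the descending-ppm column order of
    ``spec.bucket_centers()``.
    """
    spec = spec or BucketSpec()
    s = s.ascending()
    if s.ppm[0] > spec.range_low_ppm + 1e-12 or s.ppm[-1] < spec.range_high_ppm - 1e-12:
        raise CoverageError(
            f"spectrum [{s.ppm[0]:.3f}, {s.ppm[-1]:.3f}] does not cover "
            f"[{spec.range_low_ppm}, {spec.range_high_ppm}] ppm"
        )
    edges = np.minimum(spec.edges(), s.ppm[-1])
    cints = _piecewise_linear_cumint(s.ppm, s.intensity, edges)
    vals = np.diff(cints)[spec.retained_mask()]
    return vals[::-1].copy()


def build_bucket_matrix(
    spectra: Sequence[Spectrum], meta: Sequence, spec: BucketSpec | None = None
) -> BucketMatrix:
    """Bucket every spectrum on an identical grid and align rows to metadata.

    Spectra are matched to metadata records by ``sample_id``; duplicate or
    missing ids raise :class:`AlignmentError`.
    """
    spec = spec or BucketSpec()
    if len(spectra) == 0:
        raise AlignmentError("no spectra given")
    if len(spectra) != len(meta):
        raise AlignmentError(f"{len(spectra)} spectra vs {len(meta)} metadata records")
    by_id: dict[str, Spectrum] = {}
    for s in spectra:
        if s.sample_id in by_id:
            raise AlignmentError(f"duplicate sample_id {s.sample_id!r}")
        by_id[s.sample_id] = s
    rows = []
    for m in meta:
        if m.sample_id not in by_id:
            raise AlignmentError(f"no spectrum for sample {m.sample_id!r}")
        rows.append(bucket_spectrum(by_id[m.sample_id], spec))
    return BucketMatrix(np.vstack(rows), spec.bucket_centers(), list(meta))


@dataclass
class ScalingParams:
    """Column centering/scaling state, reapplicable to new rows."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask over original columns

    def apply(self, m: np.ndarray) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        return (m[:, self.kept] - self.mean) / self.sd


def unit_variance_scale(m: np.ndarray) -> tuple[np.ndarray, ScalingParams]:
    """Center columns and scale to unit sample variance (ddof=1).

    Zero-variance columns are dropped with a warning; the returned params
    record which columns survive so the identical transform applies to new
    data.
    """
    m = np.asarray(m, dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate variance")
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    kept = sd > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} zero-variance column(s)", stacklevel=2
        )
    params = ScalingParams(mean=mean[kept], sd=sd[kept], kept=kept)
    return params.apply(m), params


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray  # columns are components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray = field(repr=False, default=None)


def pca(m: np.ndarray, n_components: int) -> PcaResult:
    """PCA by SVD of the column-centered matrix.

    Sign convention: within each loading vector the largest-magnitude element
    is made positive. Scores are the centered data projected on the loadings.
    """
    m = np.asarray(m, dtype=float)
    n, p = m.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(rows-1, cols)={min(n - 1, p)}")
    mean = m.mean(axis=0)
    xc = m - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    load = vt[:n_components].T
    flip = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    load = load * flip
    var = s**2 / max(n - 1, 1)
    total = var.sum()
    evr = var[:n_components] / total if total > 0 else np.zeros(n_components)
    return PcaResult(scores=xc @ load, loadings=load, explained_variance_ratio=evr, mean=mean)
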