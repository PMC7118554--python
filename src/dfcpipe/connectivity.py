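"""Sliding-window dynamic and static functional connectivity.

Per-subject region-of-interest (ROI) time series (T timepoints x N regions)
are turned into a stack of windowed Pearson correlation matrices — the
dynamic functional connectivity (DFC) tensor — or a single full-length
correlation matrix (static functional connectivity, SFC, the W=1 special
case).  Upper-triangle entries of every window are flattened, window-major,
into one feature row per subject; :class:`FeatureIndex` keeps the bijection
between feature columns and (window, region i, region j) triples.

Conventions: windows are half-open, 0-based ``[k*step, k*step + width)``
intervals with a rectangular (boxcar) taper; feature values are raw Pearson
r (an optional Fisher z-transform is available but off by default, since
classification consumes the correlations directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WindowScheme",
    "ConnectivityTensor",
    "FeatureIndex",
    "FeatureMatrix",
    "enumerate_windows",
    "windowed_connectivity",
    "static_connectivity",
    "vectorize",
    "build_feature_matrix",
]


@dataclass(frozen=True)
class WindowScheme:
    """Rectangular sliding-window scheme.

    Parameters
    ----------
    width : int
        Window width in timepoints.  With a TR of 2 s and a minimum signal
        frequency of 0.01 Hz the conventional choice is 1/f_min = 100 s,
        i.e. 50 timepoints.
    step : int
        Slide between consecutive window starts, in timepoints.
    n_timepoints : int
        Series length T the scheme will be applied to.
    """

    width: int
    step: int
    n_timepoints: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.step < 1:
            raise ValueError(
                f"width and step must be >= 1 (got width={self.width}, step={self.step})"
            )
        if self.width > self.n_timepoints:
            raise ValueError(
                f"window width {self.width} exceeds series length {self.n_timepoints}"
            )

    @property
    def n_windows(self) -> int:
        """W = floor((T - width) / step) + 1."""
        return (self.n_timepoints - self.width) // self.step + 1

    def bounds(self) -> list[tuple[int, int]]:
        return enumerate_windows(self)


def enumerate_windows(scheme: WindowScheme) -> list[tuple[int, int]]:
    """Half-open window intervals ``[k*step, k*step + width)``, k = 0..W-1."""
    return [
        (k * scheme.step, k * scheme.step + scheme.width)
        for k in range(scheme.n_windows)
    ]


@dataclass
class ConnectivityTensor:
    """W windowed N x N Pearson correlation matrices plus window bounds.

    ``values[w]`` is symmetric with unit diagonal; W = 1 for static
    connectivity.
    """

    values: np.ndarray  # (W, N, N)
    window_bounds: list[tuple[int, int]]

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def _window_correlation(seg: np.ndarray, where: str) -> np.ndarray:
    """Pearson correlation matrix of one window segment (rows = timepoints)."""
    sd = seg.std(axis=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ValueError(f"zero-variance region(s) {bad.tolist()} in {where}")
    c = np.corrcoef(seg, rowvar=False)
    # guard against tiny fp excursions outside [-1, 1]
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return c


def windowed_connectivity(ts: np.ndarray, scheme: WindowScheme) -> ConnectivityTensor:
    """Sliding-window Pearson connectivity of a T x N series.

    Slice ``w`` is the correlation matrix of rows ``[start_w, end_w)``.
    Raises if any region has zero variance inside any window, naming the
    (window, region) coordinates.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a T x N matrix")
    if ts.shape[0] != scheme.n_timepoints:
        raise ValueError(
            f"series has {ts.shape[0]} timepoints but scheme expects {scheme.n_timepoints}"
        )
    bounds = enumerate_windows(scheme)
    slices = np.empty((len(bounds), ts.shape[1], ts.shape[1]))
    for w, (a, b) in enumerate(bounds):
        slices[w] = _window_correlation(ts[a:b], where=f"window {w} [{a},{b})")
    return ConnectivityTensor(values=slices, window_bounds=bounds)


def static_connectivity(ts: np.ndarray) -> ConnectivityTensor:
    """Full-series Pearson connectivity: one N x N matrix (W = 1)."""
    ts = np.asarray(ts, dtype=float)
    scheme = WindowScheme(width=ts.shape[0], step=1, n_timepoints=ts.shape[0])
    return windowed_connectivity(ts, scheme)


@dataclass(frozen=True)
class FeatureIndex:
    """Bijection between feature columns and (window, region i, region j).

    Ordering is window-major, then row-major over the upper triangle
    (i < j), so column = w * N(N-1)/2 + pair_rank(i, j).
    """

    n_windows: int
    n_regions: int
    window_bounds: tuple[tuple[int, int], ...] = field(default=())

    @property
    def n_pairs(self) -> int:
        n = self.n_regions
        return n * (n - 1) // 2

    def __len__(self) -> int:
        return self.n_windows * self.n_pairs

    def to_triple(self, column: int) -> tuple[int, int, int]:
        """Decode a feature column into (window, i, j) with i < j."""
        if not 0 <= column < len(self):
            raise IndexError(f"column {column} out of range [0, {len(self)})")
        w, pair = divmod(column, self.n_pairs)
        n = self.n_regions
        # invert row-major upper-triangle rank
        i = 0
        row_len = n - 1
        while pair >= row_len:
            pair -= row_len
            i += 1
            row_len -= 1
        j = i + 1 + pair
        return w, i, j

    def to_column(self, w: int, i: int, j: int) -> int:
        """Encode (window, i, j), i < j, into a feature column."""
        n = self.n_regions
        if not (0 <= i < j < n):
            raise IndexError(f"invalid region pair ({i}, {j}) for N={n}")
        if not 0 <= w < self.n_windows:
            raise IndexError(f"window {w} out of range [0, {self.n_windows})")
        rank = i * n - i * (i + 1) // 2 + (j - i - 1)
        return w * self.n_pairs + rank

    def triples(self) -> np.ndarray:
        """All (window, i, j) triples in column order, shape (len, 3)."""
        iu, ju = np.triu_indices(self.n_regions, k=1)
        out = np.empty((len(self), 3), dtype=int)
        p = self.n_pairs
        for w in range(self.n_windows):
            out[w * p : (w + 1) * p, 0] = w
            out[w * p : (w + 1) * p, 1] = iu
            out[w * p : (w + 1) * p, 2] = ju
        return out


def vectorize(
    tensor: ConnectivityTensor, fisher_z: bool = False
) -> tuple[np.ndarray, FeatureIndex]:
    """Flatten a connectivity tensor into one feature row.

    Upper-triangle entries of every window, window-major; length
    W * N(N-1)/2.  ``fisher_z`` applies arctanh (with r clipped just inside
    (-1, 1)); default is raw Pearson r.
    """
    w, n, _ = tensor.values.shape
    iu, ju = np.triu_indices(n, k=1)
    row = tensor.values[:, iu, ju].ravel()
    if fisher_z:
        row = np.arctanh(np.clip(row, -1 + 1e-15, 1 - 1e-15))
    index = FeatureIndex(
        n_windows=w, n_regions=n, window_bounds=tuple(tensor.window_bounds)
    )
    return row, index


@dataclass
class FeatureMatrix:
    """Subjects x features table with its column index.

    ``feature_set`` tags the columns as DFC, SFC or their concatenation
    (DFC columns first).
    """

    values: np.ndarray  # (n_subjects, n_features)
    feature_index: FeatureIndex
    subject_ids: list[str]
    feature_set: str = "DFC"  # {"DFC", "SFC", "DFC+SFC"}
    sfc_index: FeatureIndex | None = None  # set for DFC+SFC

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def build_feature_matrix(
    series: list[np.ndarray],
    subject_ids: list[str],
    scheme: WindowScheme | None = None,
    mode: str = "dfc",
    fisher_z: bool = False,
) -> FeatureMatrix:
    """Extract a FeatureMatrix from per-subject T x N series.

    mode: 'dfc' (needs a scheme), 'sfc', or 'both' (DFC columns followed by
    SFC columns, matching the combined-feature protocol).
    """
    if mode not in {"dfc", "sfc", "both"}:
        raise ValueError(f"unknown mode {mode!r}")
    rows, index = [], None
    sfc_rows, sfc_index = [], None
    for ts in series:
        if mode in {"dfc", "both"}:
            if scheme is None:
                raise ValueError("DFC extraction requires a WindowScheme")
            row, index = vectorize(windowed_connectivity(ts, scheme), fisher_z)
            rows.append(row)
        if mode in {"sfc", "both"}:
            srow, sfc_index = vectorize(static_connectivity(ts), fisher_z)
            sfc_rows.append(srow)
    if mode == "dfc":
        return FeatureMatrix(np.vstack(rows), index, list(subject_ids), "DFC")
    if mode == "sfc":
        return FeatureMatrix(np.vstack(sfc_rows), sfc_index, list(subject_ids), "SFC")
    values = np.hstack([np.vstack(rows), np.vstack(sfc_rows)])
    return FeatureMatrix(values, index, list(subject_ids), "DFC+SFC", sfc_index)
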