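"""From parcellated BOLD time series to per-segment functional connectomes.

The experiment this package models acquires two consecutive fMRI runs per
participant: an 8-min resting scan (scan 1) and a 12:12-min scan (scan 2)
consisting of a 4-min stop signal task (SST), a 12-s announced transition,
and 8 min of rest.  Both scans are divided into five 4-min analysis segments
labeled R1.1, R1.2 (scan-1 rest), SST, R2.1, R2.2 (scan-2 task and rest).
The initial 7 s of each scan (scanner calibration volumes) and the 12-s
transition are discarded.

Functional connectivity for a segment is the region-by-region Pearson
correlation matrix of its time series.  When a segment has fewer time points
than regions the FC is rank-deficient (positive semidefinite only) and must
be regularized (see :mod:`tanrec.spd`) before any manifold operation.

Conventions: volume indices are 0-based half-open intervals; the calibration
exclusion is taken out of the *first* segment of each scan only, keeping the
later segment boundaries at the nominal 4-min marks so that the printed scan
totals are preserved (at TR = 1.2 s: 400 and 610 volumes, with R1.1 and SST
six volumes short of the nominal 200).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SEGMENTS",
    "SCAN_SEGMENTS",
    "BoldTimeSeries",
    "SegmentScheme",
    "FCMatrix",
    "nominal_scan_volumes",
    "default_scheme",
    "split_segments",
    "compute_fc",
    "vectorize",
    "unvectorize",
]

#: canonical segment order used everywhere downstream
SEGMENTS = ("R1.1", "R1.2", "SST", "R2.1", "R2.2")

#: which analysis segments live in which scan
SCAN_SEGMENTS = {"scan1": ("R1.1", "R1.2"), "scan2": ("SST", "R2.1", "R2.2")}

#: nominal protocol durations in seconds
SEGMENT_SECONDS = 240.0
CALIBRATION_SECONDS = 7.0
TRANSITION_SECONDS = 12.0


@dataclass
class BoldTimeSeries:
    """Parcellated BOLD data for one participant and one scan.

    ``data`` is T x p (rows = time points / volumes, columns = regions).
    Zero-variance columns are flagged at construction: FC is undefined for
    them and :func:`compute_fc` will refuse such a segment.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    scan_id: str = "scan1"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError(
                f"time series must be T x p with T >= 2, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.scan_id not in SCAN_SEGMENTS:
            raise ValueError(f"scan_id must be one of {sorted(SCAN_SEGMENTS)}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def zero_variance_regions(self) -> np.ndarray:
        """Indices of columns whose variance is zero (FC undefined)."""
        return np.flatnonzero(self.data.std(axis=0) == 0.0)


@dataclass
class SegmentScheme:
    """Volume layout of the five analysis segments plus discarded intervals.

    ``segments`` maps scan id to an ordered list of ``(label, start, stop)``
    half-open 0-based volume intervals; ``discarded`` lists
    ``(scan_id, label, start, stop)`` for calibration and transition volumes.
    """

    segments: dict
    discarded: list = field(default_factory=list)
    tr_seconds: float = 1.2

    def __post_init__(self):
        labels = [lab for scan in self.segments.values() for lab, _, _ in scan]
        if sorted(labels) != sorted(SEGMENTS):
            raise ValueError(
                f"analysis labels must be exactly {set(SEGMENTS)}, got {set(labels)}"
            )
        for scan_id, segs in self.segments.items():
            intervals = [(a, b) for _, a, b in segs] + [
                (a, b) for sid, _, a, b in self.discarded if sid == scan_id
            ]
            for a, b in intervals:
                if not (0 <= a < b):
                    raise ValueError(f"bad interval [{a}, {b}) in {scan_id}")
            for (a1, b1) in intervals:
                for (a2, b2) in intervals:
                    if (a1, b1) != (a2, b2) and a1 < b2 and a2 < b1:
                        raise ValueError(
                            f"overlapping intervals in {scan_id}: "
                            f"[{a1},{b1}) and [{a2},{b2})"
                        )

    def scan_volumes(self, scan_id: str) -> int:
        """Total volume count the scheme expects for ``scan_id``."""
        stops = [b for _, _, b in self.segments[scan_id]]
        stops += [b for sid, _, _, b in self.discarded if sid == scan_id]
        return max(stops)

    def segment_interval(self, label: str):
        for scan_id, segs in self.segments.items():
            for lab, a, b in segs:
                if lab == label:
                    return scan_id, a, b
        raise KeyError(label)


@dataclass
class FCMatrix:
    """A functional connectome: symmetric Pearson correlation matrix.

    Invariants checked at construction: unit diagonal, entries in [-1, 1],
    symmetry, positive semidefiniteness (correlation matrices are Gram
    matrices of standardized columns, so the smallest eigenvalue may only be
    negative by floating-point error).
    """

    values: np.ndarray
    subject_id: str = ""
    segment_label: str = ""

    def __post_init__(self):
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"FC must be square, got {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("FC contains non-finite entries")
        if np.abs(a - a.T).max() > 1e-10:
            raise ValueError("FC is not symmetric")
        a = 0.5 * (a + a.T)
        if np.abs(np.diag(a) - 1.0).max() > 1e-10:
            raise ValueError("FC diagonal must be 1")
        if a.min() < -1.0 - 1e-10 or a.max() > 1.0 + 1e-10:
            raise ValueError("FC entries must lie in [-1, 1]")
        w0 = float(np.linalg.eigvalsh(a)[0])
        if w0 < -1e-10:
            raise ValueError(f"FC is not positive semidefinite (eigenvalue {w0:.3e})")
        self.values = a

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def label(self) -> str:
        return f"{self.subject_id}:{self.segment_label}"


def nominal_scan_volumes(tr_seconds: float):
    """Volume counts implied by the protocol durations at a given TR.

    Scan 1 lasts 8:00 min of rest; scan 2 lasts 12:12 min (4-min task, 12-s
    transition, 8-min rest).  At TR = 1.2 s this gives (400, 610).
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    scan1 = 2 * SEGMENT_SECONDS
    scan2 = 3 * SEGMENT_SECONDS + TRANSITION_SECONDS
    v1, v2 = scan1 / tr_seconds, scan2 / tr_seconds
    if abs(v1 - round(v1)) > 1e-9 or abs(v2 - round(v2)) > 1e-9:
        raise ValueError(
            f"TR {tr_seconds} s does not tile the protocol into whole volumes"
        )
    return int(round(v1)), int(round(v2))


def default_scheme(
    tr_seconds: float, scan1_volumes: int, scan2_volumes: int
) -> SegmentScheme:
    """Build the five-segment layout for the two-scan rest/task/rest protocol.

    Segment boundaries sit at the nominal 4-min marks (240 s / TR volumes).
    The first ``ceil(7 / TR)`` calibration volumes of each scan are discarded
    from the first segment; ``12 / TR`` transition volumes are discarded
    between SST and R2.1.

    Raises if the supplied scan lengths are incompatible with the layout.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    seg = SEGMENT_SECONDS / tr_seconds
    trans = TRANSITION_SECONDS / tr_seconds
    if abs(seg - round(seg)) > 1e-9 or abs(trans - round(trans)) > 1e-9:
        raise ValueError(
            f"TR {tr_seconds} s does not tile 4-min segments / 12-s transition "
            "into whole volumes"
        )
    seg, trans = int(round(seg)), int(round(trans))
    calib = math.ceil(CALIBRATION_SECONDS / tr_seconds)
    want1, want2 = 2 * seg, 3 * seg + trans
    if scan1_volumes != want1 or scan2_volumes != want2:
        raise ValueError(
            f"scan lengths ({scan1_volumes}, {scan2_volumes}) incompatible with "
            f"the nominal layout ({want1}, {want2}) at TR {tr_seconds} s"
        )
    segments = {
        "scan1": [("R1.1", calib, seg), ("R1.2", seg, 2 * seg)],
        "scan2": [
            ("SST", calib, seg),
            ("R2.1", seg + trans, 2 * seg + trans),
            ("R2.2", 2 * seg + trans, 3 * seg + trans),
        ],
    }
    discarded = [
        ("scan1", "calibration", 0, calib),
        ("scan2", "calibration", 0, calib),
        ("scan2", "transition", seg, seg + trans),
    ]
    return SegmentScheme(segments=segments, discarded=discarded, tr_seconds=tr_seconds)


def split_segments(ts: BoldTimeSeries, scheme: SegmentScheme):
    """Slice one scan's time series into its labeled analysis segments.

    Returns ``[(label, BoldTimeSeries), ...]`` in scheme order; discarded
    intervals appear in no output.
    """
    segs = scheme.segments.get(ts.scan_id)
    if segs is None:
        raise ValueError(f"scheme has no scan {ts.scan_id!r}")
    expected = scheme.scan_volumes(ts.scan_id)
    if ts.n_volumes < expected:
        raise ValueError(
            f"{ts.subject_id}/{ts.scan_id}: {ts.n_volumes} volumes but the "
            f"scheme needs {expected}"
        )
    out = []
    for label, a, b in segs:
        out.append(
            (
                label,
                BoldTimeSeries(
                    ts.data[a:b],
                    tr_seconds=ts.tr_seconds,
                    subject_id=ts.subject_id,
                    scan_id=ts.scan_id,
                ),
            )
        )
    return out


def compute_fc(segment, subject_id: str = "", segment_label: str = "") -> FCMatrix:
    """Pearson-correlation FC of a T x p segment (T >= 3).

    A zero-variance column makes the correlation undefined; the error names
    the offending region(s).  The diagonal is set to exactly 1.
    """
    if isinstance(segment, BoldTimeSeries):
        subject_id = subject_id or segment.subject_id
        data = segment.data
    else:
        data = np.asarray(segment, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValueError(f"segment must be T x p with T >= 3, got {data.shape}")
    dead = np.flatnonzero(data.std(axis=0) == 0.0)
    if dead.size:
        raise ValueError(
            f"zero-variance region(s) {dead.tolist()} in "
            f"{subject_id or 'segment'} {segment_label}: correlation undefined"
        )
    r = np.corrcoef(data, rowvar=False)
    r = 0.5 * (r + r.T)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, subject_id=subject_id, segment_label=segment_label)


def vectorize(M, include_diagonal: bool = False) -> np.ndarray:
    """Row-major upper-triangle scan of a symmetric matrix.

    Length ``p(p-1)/2`` without the diagonal (the default: FC diagonals are
    identically 1 and tangent-FC diagonals are kept off for consistency), or
    ``p(p+1)/2`` with it.  The scan order is deterministic, so the map is
    injective on symmetric matrices.
    """
    a = np.asarray(M.values if hasattr(M, "values") else M, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"vectorize needs a square matrix, got {a.shape}")
    iu = np.triu_indices(a.shape[0], k=0 if include_diagonal else 1)
    return a[iu]


def unvectorize(v, p: int, include_diagonal: bool = False) -> np.ndarray:
    """Inverse of :func:`vectorize`; without-diagonal reconstruction fills the
    diagonal with zeros."""
    v = np.asarray(v, dtype=float)
    k = 0 if include_diagonal else 1
    iu = np.triu_indices(p, k=k)
    if v.shape != iu[0].shape:
        raise ValueError(f"expected length {iu[0].size} for p={p}, got {v.size}")
    out = np.zeros((p, p))
    out[iu] = v
    out = out + np.triu(out, k=1).T
    return out
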