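"""Identifiability matrices, fingerprinting rates, and reconfiguration vectors.

Tangent-FCs from two fMRI segments are compared across all participants with
the correlation distance ``1 - Pearson r`` of their vectorized upper
triangles, giving an n x n *identifiability matrix* (rows = participants in
segment A, columns = the same participants in segment B).  The 5 x 5 grid of
all segment-pair matrices is the *meta-identifiability matrix*.

Two summaries are derived from these matrices:

* the *identification rate* (fingerprinting): the percentage of participants
  whose own cross-segment tangent-FC is their nearest match, averaged over
  the row (A -> B) and column (B -> A) matching directions, with argmin ties
  counted as misidentification;
* the *reconfiguration vector*: the main diagonal of a cross-segment matrix,
  i.e., each participant's own distance between conditions — the quantity
  modeled against covariates downstream ("engaging" = R1.2 -> SST,
  "disengaging" = SST -> R2.1, "within-rest" = R2.1 -> R2.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import SEGMENTS, vectorize
from .spd import TangentMatrix

__all__ = [
    "IdentifiabilityMatrix",
    "MetaIdentifiabilityMatrix",
    "ReconfigurationVector",
    "PairedComparison",
    "correlation_distance",
    "identifiability_matrix",
    "meta_identifiability",
    "identification_rate",
    "reconfiguration_vector",
    "compare_reconfigurations",
]


@dataclass
class IdentifiabilityMatrix:
    """Pairwise correlation distances between two segments' tangent-FCs."""

    values: np.ndarray
    segment_pair: tuple
    subject_order: list

    def __post_init__(self):
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 2:
            raise ValueError("identifiability matrix must be 2-D")
        if a.min() < -1e-10 or a.max() > 2.0 + 1e-10:
            raise ValueError("correlation distances must lie in [0, 2]")
        self.values = np.clip(a, 0.0, 2.0)
        self.segment_pair = tuple(self.segment_pair)
        self.subject_order = list(self.subject_order)
        if len(self.subject_order) != a.shape[0]:
            raise ValueError("subject_order length does not match matrix rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def within_segment(self) -> bool:
        return self.segment_pair[0] == self.segment_pair[1]

    def off_diagonal(self) -> np.ndarray:
        """All off-diagonal entries, row-major."""
        mask = ~np.eye(self.values.shape[0], dtype=bool)
        return self.values[mask]


@dataclass
class MetaIdentifiabilityMatrix:
    """5 x 5 grid of identifiability matrices over the canonical segment order."""

    blocks: dict
    subject_order: list = field(default_factory=list)

    def __post_init__(self):
        for a in SEGMENTS:
            for b in SEGMENTS:
                if (a, b) not in self.blocks:
                    raise ValueError(f"missing block ({a}, {b})")
        for a in SEGMENTS:
            for b in SEGMENTS:
                fwd, back = self.blocks[(a, b)].values, self.blocks[(b, a)].values
                if np.abs(fwd - back.T).max() > 1e-12:
                    raise ValueError(f"block ({a},{b}) is not the transpose of ({b},{a})")
        if not self.subject_order:
            self.subject_order = list(self.blocks[(SEGMENTS[0], SEGMENTS[1])].subject_order)

    def block(self, a: str, b: str) -> IdentifiabilityMatrix:
        return self.blocks[(a, b)]

    def stacked(self) -> np.ndarray:
        """The full 5n x 5n matrix in canonical segment order."""
        return np.block(
            [[self.blocks[(a, b)].values for b in SEGMENTS] for a in SEGMENTS]
        )


@dataclass
class ReconfigurationVector:
    """Per-participant distance between their own tangent-FCs in two segments."""

    values: np.ndarray
    transition: tuple
    subject_order: list

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("reconfiguration vector must be 1-D")
        if v.min() < -1e-10 or v.max() > 2.0 + 1e-10:
            raise ValueError("reconfiguration values must lie in [0, 2]")
        self.values = np.clip(v, 0.0, 2.0)
        self.transition = tuple(self.transition)
        self.subject_order = list(self.subject_order)
        if len(self.subject_order) != v.size:
            raise ValueError("subject_order length does not match vector length")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class PairedComparison:
    """Paired t-test summary between two reconfiguration vectors."""

    t: float
    p: float
    mean_difference: float
    r: float
    n: int


def correlation_distance(x, y) -> float:
    """``1 - Pearson r(x, y)``; lies in [0, 2].

    Both vectors must have length >= 3 and be nonconstant (the correlation of
    a constant vector is undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must share length >= 3")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation distance undefined for a constant vector")
    r = float(np.dot(x - x.mean(), y - y.mean()) / (x.size * sx * sy))
    return float(min(max(1.0 - r, 0.0), 2.0))


def _vector_block(tfcs, include_diagonal: bool = False) -> np.ndarray:
    """Stack vectorized upper triangles into an (n, features) array."""
    return np.vstack([vectorize(t, include_diagonal=include_diagonal) for t in tfcs])


def _check_reference(tfcs):
    refs = {t.reference_id for t in tfcs if isinstance(t, TangentMatrix)}
    if len(refs) > 1:
        raise ValueError(
            f"tangent matrices mix references {sorted(refs)}; distances across "
            "references are meaningless"
        )


def identifiability_matrix(
    tfcs_A,
    tfcs_B,
    segment_pair=("A", "B"),
    subject_order=None,
    include_diagonal: bool = False,
) -> IdentifiabilityMatrix:
    """All-pairs correlation distances between two segments' matrices.

    ``values[i, j] = correlation_distance(vec(tfcs_A[i]), vec(tfcs_B[j]))``.
    Inputs are tangent matrices (mixed references are refused) or plain
    symmetric matrices (e.g., manifold FCs, for the pre-projection contrast).
    """
    if len(tfcs_A) != len(tfcs_B):
        raise ValueError("segment A and B must cover the same participants")
    _check_reference(list(tfcs_A) + list(tfcs_B))
    va = _vector_block(tfcs_A, include_diagonal)
    vb = _vector_block(tfcs_B, include_diagonal)
    sa, sb = va.std(axis=1), vb.std(axis=1)
    if np.any(sa == 0.0) or np.any(sb == 0.0):
        raise ValueError("constant vectorized matrix: correlation undefined")
    za = (va - va.mean(axis=1, keepdims=True)) / sa[:, None]
    zb = (vb - vb.mean(axis=1, keepdims=True)) / sb[:, None]
    r = za @ zb.T / va.shape[1]
    if subject_order is None:
        subject_order = [
            getattr(t, "label", "") or f"s{i}" for i, t in enumerate(tfcs_A)
        ]
    return IdentifiabilityMatrix(
        np.clip(1.0 - r, 0.0, 2.0), segment_pair=segment_pair, subject_order=subject_order
    )


def meta_identifiability(
    tfcs_by_segment: dict,
    subject_order=None,
    include_diagonal: bool = False,
) -> MetaIdentifiabilityMatrix:
    """All 25 segment-pair identifiability matrices in canonical order.

    Only the upper triangle of segment pairs is computed; the lower triangle
    is filled with exact transposes, so transpose consistency holds by
    construction.
    """
    missing = [s for s in SEGMENTS if s not in tfcs_by_segment]
    if missing:
        raise ValueError(f"missing segment(s) {missing}")
    n = len(tfcs_by_segment[SEGMENTS[0]])
    if any(len(tfcs_by_segment[s]) != n for s in SEGMENTS):
        raise ValueError("segments cover different participant counts")
    blocks = {}
    for i, a in enumerate(SEGMENTS):
        for j, b in enumerate(SEGMENTS):
            if j < i:
                continue
            idm = identifiability_matrix(
                tfcs_by_segment[a],
                tfcs_by_segment[b],
                segment_pair=(a, b),
                subject_order=subject_order,
                include_diagonal=include_diagonal,
            )
            if a == b:
                sym = 0.5 * (idm.values + idm.values.T)
                np.fill_diagonal(sym, 0.0)
                idm = IdentifiabilityMatrix(sym, (a, b), idm.subject_order)
            blocks[(a, b)] = idm
            if a != b:
                blocks[(b, a)] = IdentifiabilityMatrix(
                    idm.values.T.copy(), (b, a), idm.subject_order
                )
    return MetaIdentifiabilityMatrix(blocks=blocks)


def identification_rate(idm: IdentifiabilityMatrix) -> float:
    """Fingerprinting success percentage for a cross-segment block.

    A participant is identified in the row direction when the unique argmin
    of their row sits on the diagonal (their own tangent-FC is their nearest
    match in the other segment), and likewise per column; the two directions
    are averaged and scaled to percent.  Ties count as misidentification.
    Within-segment blocks are degenerate (zero diagonal) and refused.
    """
    if idm.within_segment:
        raise ValueError("identification rate is degenerate within a segment")
    v = idm.values
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    hits = 0
    for axis in (1, 0):
        m = v if axis == 1 else v.T
        row_min = m.min(axis=1)
        for i in range(n):
            if m[i, i] == row_min[i] and np.sum(m[i] == row_min[i]) == 1:
                hits += 1
    return 100.0 * hits / (2 * n)


def reconfiguration_vector(idm: IdentifiabilityMatrix) -> ReconfigurationVector:
    """Main diagonal of a cross-segment identifiability matrix."""
    v = idm.values
    if v.shape[0] != v.shape[1]:
        raise ValueError("reconfiguration vector needs a square matrix")
    if idm.within_segment:
        raise ValueError("within-segment diagonal is identically zero")
    return ReconfigurationVector(
        np.diag(v).copy(), transition=idm.segment_pair, subject_order=idm.subject_order
    )


def compare_reconfigurations(
    v1: ReconfigurationVector, v2: ReconfigurationVector
) -> PairedComparison:
    """Paired t test between two transitions' reconfiguration vectors.

    Returns the t statistic, two-sided p, mean difference (v1 - v2) and the
    Pearson correlation between the two vectors.  When every paired
    difference is identical the t statistic degenerates: 0 (p = 1) for a zero
    shift, signed infinity (p = 0) otherwise.
    """
    if v1.subject_order != v2.subject_order:
        raise ValueError("vectors cover different participants")
    if v1.n < 3:
        raise ValueError("need at least 3 participants for a paired test")
    d = v1.values - v2.values
    mean_d = float(d.mean())
    r = float(np.corrcoef(v1.values, v2.values)[0, 1])
    # an (up to float error) constant difference degenerates the t statistic
    if np.allclose(d, d[0], rtol=0.0, atol=1e-12 * max(1.0, float(np.abs(d).max()))):
        if mean_d == 0.0:
            return PairedComparison(0.0, 1.0, 0.0, r, v1.n)
        return PairedComparison(math.copysign(math.inf, mean_d), 0.0, mean_d, r, v1.n)
    t, p = stats.ttest_rel(v1.values, v2.values)
    return PairedComparison(float(t), float(p), mean_d, r, v1.n)
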