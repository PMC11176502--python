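"""Similarity matrices and the graphs the encoder consumes.

Four similarity sources feed the pipeline:

* microbe sequence similarity ``MSS`` — normalized Smith-Waterman local
  alignment scores (match +1, mismatch -1, linear gap cost 2);
* drug structural similarity ``DSS`` — an externally computed matrix;
* Gaussian interaction-profile (GIP) kernels ``MGS``/``DGS`` — radial
  kernels on the rows/columns of the association matrix, bandwidth
  normalized by the mean squared profile norm;
* fused matrices ``MS``/``DS`` — the arithmetic mean of the primary and
  GIP similarity where the primary is informative, the GIP kernel alone
  where it is zero.

The fused matrices are row-smoothed with a centered moving average,
symmetrized, and thresholded into the 0/1 adjacency of each entity
graph; the continuous fused rows concatenated with association profiles
form the node features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_data import AssociationMatrix, SequenceRecord

try:  # JIT-compiled DP kernel; falls back to pure python if unavailable
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

__all__ = [
    "SimilarityMatrix",
    "GipParams",
    "FeatureGraph",
    "local_align_score",
    "sequence_similarity",
    "sequence_similarity_matrix",
    "gip_bandwidth",
    "gip_similarity",
    "microbe_gip",
    "drug_gip",
    "fuse",
    "smooth_rows",
    "symmetrize",
    "binarize",
    "build_feature_graph",
    "build_entity_graphs",
]

_SYMMETRIC_TOL = 1e-8
_UNIT_DIAGONAL_KINDS = {"sequence", "gip", "fused"}


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0,1] with aligned ids.

    ``kind`` records provenance: sequence, structure, gip, fused,
    smoothed or binarized.  Smoothed matrices are exempt from the
    symmetry check (row smoothing breaks it; it is restored by averaging
    with the transpose before binarization).
    """

    values: np.ndarray
    ids: list[str]
    kind: str = "fused"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("id list does not match matrix size")
        if np.isnan(self.values).any():
            raise ValueError("similarity matrix contains NaN")
        if self.values.min() < -_SYMMETRIC_TOL or self.values.max() > 1 + _SYMMETRIC_TOL:
            raise ValueError("similarity values must lie in [0, 1]")
        if self.kind != "smoothed" and np.abs(self.values - self.values.T).max() > _SYMMETRIC_TOL:
            raise ValueError(f"{self.kind} similarity matrix is not symmetric")
        if self.kind == "binarized" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binarized matrix must be 0/1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GipParams:
    """Resolved GIP kernel bandwidth: gamma = gamma' / mean ||profile||^2."""

    gamma_prime: float
    gamma: float

    def __post_init__(self):
        if self.gamma_prime <= 0:
            raise ValueError("gamma_prime must be positive")
        if not np.isfinite(self.gamma):
            raise ValueError("resolved gamma must be finite")


@dataclass
class FeatureGraph:
    """Binarized adjacency plus continuous node features for one entity side."""

    adjacency: np.ndarray
    features: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if np.abs(self.adjacency - self.adjacency.T).max() > _SYMMETRIC_TOL:
            raise ValueError("adjacency must be symmetric")
        if self.features.shape[0] != n:
            raise ValueError("features must be row-aligned with adjacency")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


# ---------------------------------------------------------------------------
# local alignment


def _sw_python(a: np.ndarray, b: np.ndarray) -> int:
    best = 0
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for i in range(1, len(a) + 1):
        cur = np.zeros_like(prev)
        for j in range(1, len(b) + 1):
            s = 1 if a[i - 1] == b[j - 1] else -1
            h = max(prev[j - 1] + s, prev[j] - 2, cur[j - 1] - 2, 0)
            cur[j] = h
            if h > best:
                best = h
        prev = cur
    return int(best)


if njit is not None:

    @njit(cache=True)
    def _sw_numba(a, b):  # pragma: no cover - exercised via local_align_score
        best = 0
        prev = np.zeros(b.shape[0] + 1, dtype=np.int64)
        cur = np.zeros(b.shape[0] + 1, dtype=np.int64)
        for i in range(1, a.shape[0] + 1):
            cur[0] = 0
            for j in range(1, b.shape[0] + 1):
                s = 1 if a[i - 1] == b[j - 1] else -1
                h = prev[j - 1] + s
                if prev[j] - 2 > h:
                    h = prev[j] - 2
                if cur[j - 1] - 2 > h:
                    h = cur[j - 1] - 2
                if h < 0:
                    h = 0
                cur[j] = h
                if h > best:
                    best = h
            prev, cur = cur, prev
        return best

    _sw_kernel = _sw_numba
else:  # pragma: no cover
    _sw_kernel = _sw_python


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def local_align_score(seq_a: SequenceRecord, seq_b: SequenceRecord) -> int:
    """Smith-Waterman local alignment score.

    Dynamic program over H of shape (a+1) x (b+1) with zero first
    row/column; each cell is max(diagonal + score, up - 2, left - 2, 0)
    with match score +1 and mismatch -1; the returned value is the
    maximum over H, hence always >= 0.
    """
    if not seq_a.sequence or not seq_b.sequence:
        raise ValueError("cannot align an empty sequence")
    return int(_sw_kernel(_encode(seq_a.sequence), _encode(seq_b.sequence)))


def sequence_similarity(seq_a: SequenceRecord, seq_b: SequenceRecord) -> float:
    """Normalized local-alignment similarity in [0, 1].

    sw(A,B) / sqrt(sw(A,A) * sw(B,B)); self-similarity is exactly 1
    because the self score of a length-L sequence is L.
    """
    saa = local_align_score(seq_a, seq_a)
    sbb = local_align_score(seq_b, seq_b)
    if saa <= 0 or sbb <= 0:
        raise RuntimeError("self alignment score must be positive for non-empty sequences")
    return local_align_score(seq_a, seq_b) / float(np.sqrt(saa * sbb))


def sequence_similarity_matrix(records: list[SequenceRecord]) -> SimilarityMatrix:
    """All-pairs normalized alignment similarity ``MSS``."""
    n = len(records)
    encoded = [_encode(r.sequence) for r in records]
    self_scores = np.array([_sw_kernel(e, e) for e in encoded], dtype=np.float64)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = _sw_kernel(encoded[i], encoded[j])
            values[i, j] = values[j, i] = s / np.sqrt(self_scores[i] * self_scores[j])
    return SimilarityMatrix(values, [r.id for r in records], kind="sequence")


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernels


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> GipParams:
    """Resolve the GIP bandwidth: gamma' divided by the mean squared profile norm."""
    profiles = np.asarray(profiles, dtype=np.float64)
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("all interaction profiles are zero; GIP bandwidth undefined")
    return GipParams(gamma_prime=float(gamma_prime), gamma=float(gamma_prime) / mean_sq)


def gip_similarity(profiles: np.ndarray, params: GipParams, ids=None) -> SimilarityMatrix:
    """Radial kernel exp(-gamma * ||p_i - p_j||^2) over interaction profiles."""
    profiles = np.asarray(profiles, dtype=np.float64)
    sq = (profiles**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-params.gamma * d2)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    if ids is None:
        ids = [str(i) for i in range(profiles.shape[0])]
    return SimilarityMatrix(values, list(ids), kind="gip")


def microbe_gip(assoc: AssociationMatrix, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """``MGS``: GIP kernel over microbe profiles (rows of MD)."""
    profiles = assoc.values.astype(np.float64)
    return gip_similarity(profiles, gip_bandwidth(profiles, gamma_prime), assoc.microbe_ids)


def drug_gip(assoc: AssociationMatrix, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """``DGS``: GIP kernel over drug profiles (columns of MD)."""
    profiles = assoc.values.T.astype(np.float64)
    return gip_similarity(profiles, gip_bandwidth(profiles, gamma_prime), assoc.drug_ids)


# ---------------------------------------------------------------------------
# fusion, smoothing, binarization


def fuse(primary: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Average primary and GIP similarity; fall back to GIP where primary is 0."""
    if primary.ids != gip.ids:
        raise ValueError("cannot fuse matrices with different id orders")
    fused = np.where(primary.values != 0, (primary.values + gip.values) / 2.0, gip.values)
    return SimilarityMatrix(fused, list(primary.ids), kind="fused")


def smooth_rows(matrix: SimilarityMatrix, window: int = 5) -> SimilarityMatrix:
    """Centered moving average along each row, window truncated at edges.

    The window must be odd and positive; window=1 is the identity.  Edge
    cells average over however much of the window fits, so values stay
    inside the original [0,1] range.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    n = matrix.n
    if window > n:
        raise ValueError(f"window {window} exceeds matrix size {n}")
    half = window // 2
    padded = np.zeros((n, n + 1))
    padded[:, 1:] = np.cumsum(matrix.values, axis=1)
    out = np.empty_like(matrix.values)
    for j in range(n):
        lo, hi = max(0, j - half), min(n, j + half + 1)
        out[:, j] = (padded[:, hi] - padded[:, lo]) / (hi - lo)
    return SimilarityMatrix(out, list(matrix.ids), kind="smoothed")


def symmetrize(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Average a matrix with its transpose and restore the unit diagonal.

    Row smoothing mixes each diagonal entry with its neighbors; the
    diagonal is self-similarity, which is 1 by definition rather than a
    noisy measurement, so it is reset after smoothing.  A side effect is
    that binarization always keeps the self-edge of every node (1 is >=
    any admissible threshold), so entity graphs never have fully
    isolated nodes and the encoder's feature pathway survives even when
    the thresholds prune every off-diagonal edge.
    """
    values = (matrix.values + matrix.values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(matrix.ids), kind="fused")


def binarize(matrix: SimilarityMatrix, threshold: float) -> SimilarityMatrix:
    """Threshold to a 0/1 adjacency: 1 iff value >= threshold.

    Any residual asymmetry (e.g. from row smoothing) is resolved by a
    logical OR with the transpose so the result is a valid adjacency.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    binary = (matrix.values >= threshold).astype(np.float64)
    binary = np.maximum(binary, binary.T)
    return SimilarityMatrix(binary, list(matrix.ids), kind="binarized")


# ---------------------------------------------------------------------------
# graph assembly


def build_feature_graph(
    binarized: SimilarityMatrix,
    fused: SimilarityMatrix,
    associations: AssociationMatrix,
    side: str,
) -> FeatureGraph:
    """Assemble the encoder input for one entity side.

    Adjacency is the binarized similarity graph; node features are the
    continuous fused similarity row concatenated with the node's
    association profile (MD row for microbes, MD column for drugs), so
    the feature width is n_side + n_other.
    """
    if side not in ("microbe", "drug"):
        raise ValueError("side must be 'microbe' or 'drug'")
    expected_ids = associations.microbe_ids if side == "microbe" else associations.drug_ids
    if binarized.ids != expected_ids or fused.ids != expected_ids:
        raise ValueError(f"similarity ids do not match association {side} ids")
    profile = (
        associations.values if side == "microbe" else associations.values.T
    ).astype(np.float64)
    features = np.hstack([fused.values, profile])
    return FeatureGraph(binarized.values, features, list(expected_ids))


def build_entity_graphs(
    associations: AssociationMatrix,
    microbe_similarity: SimilarityMatrix,
    drug_similarity: SimilarityMatrix,
    *,
    window: int = 5,
    microbe_threshold: float = 0.8,
    drug_threshold: float = 0.7,
    gamma_prime: float = 1.0,
):
    """Full preprocessing: GIP, fusion, smoothing, binarization, graphs.

    ``associations`` should contain TRAINING-fold labels only when this
    is used inside cross-validation — the GIP kernels and feature
    profiles are derived from it, so feeding it test labels would leak
    them into the encoder input.

    Returns ``(microbe FeatureGraph, drug FeatureGraph, MS, DS)``.
    """
    mgs = microbe_gip(associations, gamma_prime)
    dgs = drug_gip(associations, gamma_prime)
    ms = fuse(microbe_similarity, mgs)
    ds = fuse(drug_similarity, dgs)
    graphs = []
    for fused_m, threshold, side in (
        (ms, microbe_threshold, "microbe"),
        (ds, drug_threshold, "drug"),
    ):
        smoothed = smooth_rows(fused_m, window)
        sym = symmetrize(smoothed)
        adj = binarize(sym, threshold)
        graphs.append(build_feature_graph(adj, fused_m, associations, side))
    return graphs[0], graphs[1], ms, ds
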