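"""DCT-II transform coding of singular-vector time courses.

Encephalopathic EEG has sparse spectral content, so the orthonormal DCT-II
compacts each singular vector's energy into few coefficients.  Magnitude
thresholding keeps the largest coefficients (energy-optimal for a fixed
count, by Parseval); the retained count is then tuned by a monotone
Newton/secant root search with bisection fallback until the byte-accurate
compression ratio of the serialized epoch hits the requested target —
the achieved CR depends on the zero-run structure seen by the run-length
encoder, so it is always measured from actual serialized bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, idct

from .edf_io import EpochMatrix
from .exceptions import InfeasibleTargetError, IterationError, ParameterError

MAX_RATE_ITERATIONS = 50


@dataclass
class SparseSpectrum:
    """DCT-II coefficients of one vector after magnitude thresholding."""

    coefficients: np.ndarray
    retained_count: int
    source_length: int

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.size != self.source_length:
            raise ParameterError("coefficient length must equal source_length")
        if np.count_nonzero(self.coefficients) > self.retained_count:
            raise ParameterError("more nonzeros than retained_count")


def dct2_forward(v) -> np.ndarray:
    """Orthonormal DCT-II. Parseval holds exactly: sum c^2 = sum v^2."""
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ParameterError("cannot transform an empty vector")
    return dct(v, type=2, norm="ortho", axis=-1)


def dct2_inverse(c) -> np.ndarray:
    """Inverse of :func:`dct2_forward` under the same normalization."""
    c = np.asarray(c, dtype=np.float64)
    if c.size == 0:
        raise ParameterError("cannot transform an empty vector")
    return idct(c, type=2, norm="ortho", axis=-1)


def threshold_coefficients(c, count: int) -> SparseSpectrum:
    """Keep the ``count`` largest-magnitude coefficients, zero the rest.

    Ties are broken toward the lower index.  Among all masks of equal
    cardinality this retains the maximum energy.
    """
    c = np.asarray(c, dtype=np.float64)
    if not (0 <= count <= c.size):
        raise ParameterError(f"count={count} outside [0, {c.size}]")
    out = np.zeros_like(c)
    if count:
        order = np.argsort(-np.abs(c), kind="stable")
        keep = order[:count]
        out[keep] = c[keep]
    return SparseSpectrum(out, retained_count=count, source_length=c.size)


def _pooled_mask(flat_abs: np.ndarray, order: np.ndarray, count: int) -> np.ndarray:
    mask = np.zeros(flat_abs.size, dtype=bool)
    mask[order[:count]] = True
    return mask


def fit_retained_count(
    epoch: EpochMatrix,
    k: int,
    target_cr: float,
    tol: float = 0.0,
    *,
    mode: str = "pooled",
    max_iter: int = MAX_RATE_ITERATIONS,
):
    """Find the retained-coefficient count that achieves ``target_cr``.

    The epoch is SVD-truncated to rank ``k`` and each time course DCT-
    transformed; a single magnitude ranking over all k*n coefficients
    ("pooled", the default) or an even per-vector split ("per_vector")
    selects which coefficients survive.  Because the serialized size after
    quantization + run-length coding is a non-increasing staircase in the
    retained count, the search is a secant (Newton-style) step on the count
    with a guaranteed bisection fallback; it returns the largest count
    whose byte-accurate achieved CR is still >= ``target_cr``, i.e. the
    achieved CR closest to the target from above within the reachable
    granularity.

    Returns
    -------
    counts : ndarray of int, shape (k,)
        Nonzero coefficients retained per singular vector.
    block : CompressedEpoch
        The fully serialized epoch at the fitted count.

    Raises
    ------
    InfeasibleTargetError
        ``target_cr`` exceeds the CR at zero retained coefficients (the
        payload has a fixed floor of factors and stream headers).
    IterationError
        The bracket failed to close within ``max_iter`` iterations; the
        best iterate found is attached.
    """
    from . import codec  # byte accounting lives in the codec
    from .svd_stage import svd_truncate

    if target_cr <= 1.0:
        raise ParameterError("target_cr must exceed 1")
    if mode not in ("pooled", "per_vector"):
        raise ParameterError(f"unknown thresholding mode {mode!r}")

    tsvd = svd_truncate(epoch, k)
    coeffs = dct2_forward(tsvd.vectors)  # (k, n)
    # modes with zero singular value contribute nothing to the epoch;
    # carrying their coefficients would only waste payload bytes
    coeffs = coeffs * (tsvd.singular_values[:, None] > 0)
    n = tsvd.n
    total = k * n
    flat_abs = np.abs(coeffs).ravel()
    order = np.argsort(-flat_abs, kind="stable")

    def sparse_at(count: int) -> np.ndarray:
        if mode == "pooled":
            mask = _pooled_mask(flat_abs, order, count).reshape(k, n)
            return np.where(mask, coeffs, 0.0)
        per = np.full(k, count // k)
        per[: count % k] += 1
        rows = [threshold_coefficients(coeffs[i], int(per[i])).coefficients
                for i in range(k)]
        return np.vstack(rows)

    def size_at(count: int) -> int:
        return codec.estimate_epoch_bytes(tsvd, sparse_at(count))

    raw = tsvd.m * n * 2
    target_bytes = raw / target_cr

    lo, hi = 0, total  # cr(lo) >= target > cr(hi) once bracketed
    size_lo = size_at(lo)
    if raw / size_lo < target_cr:
        raise InfeasibleTargetError(
            f"target CR {target_cr} unreachable: payload floor {size_lo} bytes "
            f"caps the CR at {raw / size_lo:.2f}"
        )
    size_hi = size_at(hi)
    if raw / size_hi >= target_cr:
        lo = hi  # even full retention meets the target
    iterations = 0
    while hi - lo > 1:
        if iterations >= max_iter:
            raise IterationError(
                f"rate search did not converge in {max_iter} iterations",
                best=lo,
            )
        iterations += 1
        # secant step on serialized size, clamped strictly inside the bracket
        if size_hi > size_lo:
            guess = lo + (target_bytes - size_lo) * (hi - lo) / (size_hi - size_lo)
        else:
            guess = (lo + hi) / 2
        mid = int(round(guess))
        mid = min(max(mid, lo + 1), hi - 1)
        size_mid = size_at(mid)
        if raw / size_mid >= target_cr:
            lo, size_lo = mid, size_mid
        else:
            hi, size_hi = mid, size_mid
        if tol > 0 and 0 <= raw / size_lo - target_cr <= tol:
            break
    # staircase plateaus can hide a slightly larger feasible count next door
    best = lo
    for cand in range(lo + 1, min(lo + 3, total) + 1):
        if raw / size_at(cand) >= target_cr:
            best = cand
    sparse = sparse_at(best)
    block = codec.assemble_epoch(tsvd, sparse)
    counts = np.count_nonzero(sparse, axis=1)
    return counts, block
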