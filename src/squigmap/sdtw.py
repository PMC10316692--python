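"""Subsequence dynamic time warping (sDTW) engines.

Given a query X (length M) and a reference Y (length N, M <= N), sDTW finds
the subsequence of Y that X warps onto at minimum accumulated cost:

    gamma(i, j) = |x_i - y_j| + min(gamma(i-1, j),      # insertion
                                    gamma(i-1, j-1),    # match
                                    gamma(i, j-1))      # deletion

with boundaries gamma(i, 0) = +inf for i >= 1 and gamma(0, j) = 0 (free
start anywhere in the reference).  The alignment ends at the minimum of the
last row; its score is that minimum.  The distance is Manhattan throughout.

Three interchangeable engines are provided:

``oracle``
    Full M x N matrix in float64 with backtracking: returns score, end,
    start and the warp path.  O(MN) time and space.
``linear``
    The end-position-only variant: a single (M+1)-length cost array swept
    across the reference.  Returns score and end (plus the second-best
    last-row minimum outside an exclusion window).  Identical floating-point
    values to the oracle — each cell is computed by the same expression from
    exact neighbor values, so (score, end) agree exactly.
``wavefront``
    A software model of a processing-element (PE) chain evaluating one
    anti-diagonal of the cost matrix per step in ``bits``-wide fixed-point
    integer arithmetic.  Cell (i, j) is computed at step t = i + j - 2 by
    PE i - 1, reading neighbors from two register arrays holding the
    previous and second-previous anti-diagonals; the full search takes
    exactly M + N - 1 steps.  Results are bit-identical to a sequential
    fixed-point sweep of the linear algorithm under the same word width and
    overflow policy (wraparound two's-complement or saturation).

In the fixed-point engines the "infinity" boundary is the maximum
representable word value; it is treated as a sticky sentinel (a cell whose
minimum neighbor is the sentinel stays at the sentinel instead of being
incremented past the representable range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ConfigError, SizeError
from .pore_model import FixedPointConfig

DEFAULT_EXCLUSION_FACTOR = 2  # exclusion window = 2 * M unless overridden

ENGINES = ("oracle", "linear", "wavefront")


# ---------------------------------------------------------------------------
# result type
# ---------------------------------------------------------------------------

@dataclass
class SdtwResult:
    """Outcome of one sDTW search.

    ``score``/``end`` are the last-row minimum and its 0-based reference
    index.  ``start``/``path`` are present only for the oracle engine.
    ``second_score``/``second_end`` give the best last-row minimum at
    distance > exclusion window from ``end`` (None when no such index
    exists).  ``steps`` and ``overflow_count`` are wavefront diagnostics.
    """

    score: float
    end: int
    engine: str
    start: int | None = None
    path: list[tuple[int, int]] | None = None
    second_score: float | None = None
    second_end: int | None = None
    steps: int | None = None
    overflow_count: int = 0


def _check_sizes(x: np.ndarray, y: np.ndarray) -> None:
    if x.size == 0 or y.size == 0:
        raise SizeError("query and reference must be non-empty")
    if x.size > y.size:
        raise SizeError(f"query length {x.size} exceeds reference length {y.size}")


# ---------------------------------------------------------------------------
# scalar distance / fixed-point primitives
# ---------------------------------------------------------------------------

def manhattan(a, b, fp: FixedPointConfig | None = None):
    """Manhattan distance |a - b|.

    With ``fp`` given, the subtraction and absolute value are evaluated in
    the configured word width under the configured overflow policy, exactly
    as the fixed-point engines compute it.
    """
    if fp is None:
        return abs(a - b)
    wrap = fp.overflow_policy == "wraparound"
    d, _ = _fixed_abs_diff(int(a), int(b), fp.min_value, fp.max_value,
                           1 << fp.bits, wrap)
    return d


@njit(cache=True, inline="always")
def _fixed_abs_diff(xi, yj, lo, hi, span, wrap):
    """|xi - yj| in word-width arithmetic; returns (value, overflow events)."""
    ovf = 0
    d = xi - yj
    if d > hi:
        ovf += 1
        d = d - span if wrap else hi
    elif d < lo:
        ovf += 1
        d = d + span if wrap else lo
    if d < 0:
        d = -d
        if d > hi:  # negating the minimum word value overflows
            ovf += 1
            d = d - span if wrap else hi
    return d, ovf


@njit(cache=True, inline="always")
def _fixed_cell(xi, yj, up, diag, left, lo, hi, span, wrap):
    """One recurrence cell in word-width arithmetic: (value, overflow events)."""
    d, ovf = _fixed_abs_diff(xi, yj, lo, hi, span, wrap)
    m = up
    if diag < m:
        m = diag
    if left < m:
        m = left
    if m == hi:  # sticky infinity sentinel: never incremented past range
        return hi, ovf
    v = d + m
    if v > hi:
        ovf += 1
        v = v - span if wrap else hi
    elif v < lo:
        ovf += 1
        v = v + span if wrap else lo
    return v, ovf


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _oracle_fill(x, y):
    """Full (M+1) x (N+1) cost matrix, float64."""
    M = x.size
    N = y.size
    g = np.empty((M + 1, N + 1), dtype=np.float64)
    for j in range(N + 1):
        g[0, j] = 0.0
    for i in range(1, M + 1):
        g[i, 0] = np.inf
    for j in range(1, N + 1):
        yj = y[j - 1]
        for i in range(1, M + 1):
            up = g[i - 1, j]
            diag = g[i - 1, j - 1]
            left = g[i, j - 1]
            m = up
            if diag < m:
                m = diag
            if left < m:
                m = left
            g[i, j] = abs(x[i - 1] - yj) + m
    return g


@njit(cache=True)
def _linear_float_kernel(x, y):
    """Last cost-matrix row via an (M+1)-length cost array, float64."""
    M = x.size
    N = y.size
    cost = np.empty(M + 1, dtype=np.float64)
    cost[0] = 0.0
    for i in range(1, M + 1):
        cost[i] = np.inf
    last = np.empty(N, dtype=np.float64)
    for j in range(1, N + 1):
        yj = y[j - 1]
        diag = cost[0]
        for i in range(1, M + 1):
            left = cost[i]
            up = cost[i - 1]
            m = up
            if diag < m:
                m = diag
            if left < m:
                m = left
            cost[i] = abs(x[i - 1] - yj) + m
            diag = left
        last[j - 1] = cost[M]
    return last


@njit(cache=True)
def _fixed_seq_kernel(x, y, lo, hi, span, wrap):
    """Sequential fixed-point sweep (the linear algorithm in integer words)."""
    M = x.size
    N = y.size
    cost = np.empty(M + 1, dtype=np.int64)
    cost[0] = 0
    for i in range(1, M + 1):
        cost[i] = hi
    last = np.empty(N, dtype=np.int64)
    ovf = 0
    for j in range(1, N + 1):
        yj = y[j - 1]
        diag = cost[0]
        for i in range(1, M + 1):
            left = cost[i]
            up = cost[i - 1]
            v, o = _fixed_cell(x[i - 1], yj, up, diag, left, lo, hi, span, wrap)
            cost[i] = v
            ovf += o
            diag = left
        last[j - 1] = cost[M]
    return last, ovf


@njit(cache=True)
def _wavefront_fixed_kernel(x, y, lo, hi, span, wrap):
    """PE-chain anti-diagonal schedule, bit-identical to the sequential sweep.

    Register arrays L1 (previous step) and L2 (second-previous step) hold
    the two most recent anti-diagonals, indexed by query row; index 0 is the
    free-start boundary row (always 0) and untouched entries are the
    infinity sentinel, which covers the gamma(i, 0) boundary column.
    """
    M = x.size
    N = y.size
    L1 = np.full(M + 1, hi, dtype=np.int64)
    L2 = np.full(M + 1, hi, dtype=np.int64)
    cur = np.full(M + 1, hi, dtype=np.int64)
    L1[0] = 0
    L2[0] = 0
    cur[0] = 0
    last = np.empty(N, dtype=np.int64)
    ovf = 0
    steps = 0
    for t in range(M + N - 1):
        steps += 1
        i_lo = t + 2 - N
        if i_lo < 1:
            i_lo = 1
        i_hi = t + 1
        if i_hi > M:
            i_hi = M
        for i in range(i_lo, i_hi + 1):  # PE i-1 computes cell (i, j)
            j = t - i + 2
            up = L1[i - 1]       # (i-1, j)   from step t-1
            diag = L2[i - 1]     # (i-1, j-1) from step t-2
            left = L1[i]         # (i, j-1)   from step t-1
            v, o = _fixed_cell(x[i - 1], y[j - 1], up, diag, left,
                               lo, hi, span, wrap)
            cur[i] = v
            ovf += o
            if i == M:
                last[j - 1] = v
        tmp = L2
        L2 = L1
        L1 = cur
        cur = tmp
    return last, steps, ovf


# ---------------------------------------------------------------------------
# best / second-best tracking
# ---------------------------------------------------------------------------

def best_and_second(last_row, exclusion_window: int):
    """Global minimum of a last-row stream, and the runner-up outside a window.

    ``best`` is (index, value) with the smallest index winning ties;
    ``second`` is the minimum over indices with |index - best_index| >
    exclusion_window, or None when no such index exists.
    """
    pairs = list(last_row) if not isinstance(last_row, np.ndarray) else None
    if pairs is not None:
        if len(pairs) == 0:
            raise SizeError("empty last-row stream")
        idx = np.array([p[0] for p in pairs], dtype=np.int64)
        val = np.array([p[1] for p in pairs], dtype=np.float64)
    else:
        if last_row.size == 0:
            raise SizeError("empty last-row stream")
        idx = np.arange(last_row.size, dtype=np.int64)
        val = last_row
    b = int(np.argmin(val))  # np.argmin returns the first minimum
    best = (int(idx[b]), val[b])
    mask = np.abs(idx - best[0]) > exclusion_window
    if not mask.any():
        return best, None
    masked = np.where(mask, val, np.inf)
    s = int(np.argmin(masked))
    return best, (int(idx[s]), val[s])


def _finalize(last_row, exclusion_window, M):
    if exclusion_window is None:
        exclusion_window = DEFAULT_EXCLUSION_FACTOR * M
    best, second = best_and_second(last_row, exclusion_window)
    return best, second


# ---------------------------------------------------------------------------
# public engines
# ---------------------------------------------------------------------------

def sdtw_oracle(x, y, exclusion_window: int | None = None) -> SdtwResult:
    """Full-matrix float engine with backtracking.

    Ties: the last-row argmin takes the smallest reference index; during
    backtracking the predecessor preference is diagonal, then left (j-1),
    then up (i-1).  The warp path is returned as 0-based (i, j) pairs from
    the start cell to (M-1, end).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    _check_sizes(x, y)
    g = _oracle_fill(x, y)
    M, N = x.size, y.size
    last = g[M, 1:]
    best, second = _finalize(last, exclusion_window, M)
    end = best[0]
    # backtracking in 1-based matrix coordinates from (M, end + 1)
    i, j = M, end + 1
    path = [(i - 1, j - 1)]
    while i > 1:
        diag = g[i - 1, j - 1]
        left = g[i, j - 1]
        up = g[i - 1, j]
        m = min(diag, left, up)
        if diag == m:
            i, j = i - 1, j - 1
        elif left == m:
            j = j - 1
        else:
            i = i - 1
        path.append((i - 1, j - 1))
    path.reverse()
    return SdtwResult(
        score=float(best[1]), end=end, engine="oracle",
        start=path[0][1], path=path,
        second_score=None if second is None else float(second[1]),
        second_end=None if second is None else second[0],
    )


def sdtw_linear(x, y, exclusion_window: int | None = None) -> SdtwResult:
    """Linear-space end-position engine (no start/path)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    _check_sizes(x, y)
    last = _linear_float_kernel(x, y)
    best, second = _finalize(last, exclusion_window, x.size)
    return SdtwResult(
        score=float(best[1]), end=best[0], engine="linear",
        second_score=None if second is None else float(second[1]),
        second_end=None if second is None else second[0],
    )


def _check_fixed_inputs(x, y, fp: FixedPointConfig):
    x = np.ascontiguousarray(x, dtype=np.int64)
    y = np.ascontiguousarray(y, dtype=np.int64)
    _check_sizes(x, y)
    for name, arr in (("query", x), ("reference", y)):
        if arr.size and (arr.min() < fp.min_value or arr.max() > fp.max_value):
            raise SizeError(
                f"{name} values outside the {fp.bits}-bit fixed-point range"
            )
    return x, y


def sdtw_fixed_sequential(
    x, y, fp: FixedPointConfig, exclusion_window: int | None = None
) -> SdtwResult:
    """Sequential fixed-point sweep — the arithmetic reference for the wavefront."""
    x, y = _check_fixed_inputs(x, y, fp)
    wrap = fp.overflow_policy == "wraparound"
    last, ovf = _fixed_seq_kernel(
        x, y, fp.min_value, fp.max_value, 1 << fp.bits, wrap
    )
    best, second = _finalize(last, exclusion_window, x.size)
    return SdtwResult(
        score=float(best[1]), end=best[0], engine="linear",
        second_score=None if second is None else float(second[1]),
        second_end=None if second is None else second[0],
        overflow_count=int(ovf),
    )


def sdtw_wavefront_fixed(
    x, y, fp: FixedPointConfig, exclusion_window: int | None = None
) -> SdtwResult:
    """Fixed-point PE-chain wavefront engine.

    Evaluates anti-diagonals of the cost matrix exactly as the hardware PE
    chain would, in ``fp.bits``-wide integer arithmetic under
    ``fp.overflow_policy``; reports the step count (always M + N - 1) and
    the number of overflow/clamp events.
    """
    x, y = _check_fixed_inputs(x, y, fp)
    wrap = fp.overflow_policy == "wraparound"
    last, steps, ovf = _wavefront_fixed_kernel(
        x, y, fp.min_value, fp.max_value, 1 << fp.bits, wrap
    )
    best, second = _finalize(last, exclusion_window, x.size)
    return SdtwResult(
        score=float(best[1]), end=best[0], engine="wavefront",
        second_score=None if second is None else float(second[1]),
        second_end=None if second is None else second[0],
        steps=int(steps), overflow_count=int(ovf),
    )


def run_engine(
    engine: str,
    x_float,
    y_float,
    x_quant=None,
    y_quant=None,
    fp: FixedPointConfig | None = None,
    exclusion_window: int | None = None,
) -> SdtwResult:
    """Dispatch to an engine by name ({oracle, linear, wavefront})."""
    if engine == "oracle":
        return sdtw_oracle(x_float, y_float, exclusion_window)
    if engine == "linear":
        return sdtw_linear(x_float, y_float, exclusion_window)
    if engine == "wavefront":
        if x_quant is None or y_quant is None or fp is None:
            raise ConfigError("wavefront engine requires quantized inputs and fp")
        return sdtw_wavefront_fixed(x_quant, y_quant, fp, exclusion_window)
    raise ConfigError(f"unknown engine {engine!r}; choose from {ENGINES}")
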