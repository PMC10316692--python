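"""Raw read input, event segmentation and query assembly.

A raw nanopore read is a stream of current samples.  Before alignment the
stream is compressed into *events* — maximal runs of approximately constant
level, nominally one per k-mer dwelling in the pore — summarized by their
mean.  The segmenter computes two sliding-window Welch t-statistics (a short
and a long window pair straddling each sample) and calls boundaries at
t-statistic peaks, using the classic two-detector hysteresis scheme: each
detector tracks a running peak and fires once the statistic has risen above
its threshold and fallen back by the peak-height margin; a firing short
detector masks the long detector over its window.

The first ``prefix_trim`` events (library adapter) are discarded and the
next ``query_size`` events become the query: their means are z-normalized
and quantized with the same fixed-point configuration as the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    FormatError,
    InsufficientEventsError,
    TooShortError,
)
from .pore_model import FixedPointConfig, quantize, znormalize

logger = logging.getLogger("squigmap")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawRead:
    """A raw signal read: current samples in instrument units."""

    read_id: str
    samples: np.ndarray
    sample_rate: float = 4000.0
    channel_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)


@dataclass(frozen=True)
class Event:
    """One segmented event: ``length`` samples starting at ``start``."""

    start: int
    length: int
    mean: float


@dataclass(frozen=True)
class EventQuery:
    """Fixed-length normalized + quantized event-mean query (the M side)."""

    read_id: str
    means_float: np.ndarray
    means_quant: np.ndarray
    fp: FixedPointConfig
    n_prefix_trimmed: int

    @property
    def size(self) -> int:
        return len(self.means_float)


@dataclass(frozen=True)
class EventDetectionParams:
    """Segmentation parameters (defaults follow open R9.4 DNA settings)."""

    window_short: int = 4
    window_long: int = 8
    threshold_short: float = 1.4
    threshold_long: float = 9.0
    peak_height: float = 0.2
    # candidate boundaries are re-tested with a Welch t over the two full
    # flanking events and merged away below this bar (None = threshold_long)
    prune_threshold: float | None = None

    def __post_init__(self):
        if not self.window_short < self.window_long:
            raise ValueError("window_short must be < window_long")
        if self.threshold_short <= 0 or self.threshold_long <= 0:
            raise ValueError("thresholds must be > 0")


DEFAULT_PREFIX_TRIM = 50
DEFAULT_QUERY_SIZE = 250


# ---------------------------------------------------------------------------
# raw read input
# ---------------------------------------------------------------------------

def read_raw_reads(path, format: str = "tsv"):
    """Yield :class:`RawRead` records from a signal file, in file order.

    Formats: ``tsv`` (one read per line, ``read_id<TAB>c1,c2,...``) or
    ``slow5``/``blow5`` via the pyslow5 library when installed.  Empty read
    records are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if format == "tsv":
        yield from _read_tsv(path)
    elif format in ("slow5", "blow5"):
        yield from _read_slow5(path)
    else:
        raise FormatError(f"unknown raw read format {format!r}")


def _read_tsv(path):
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'read_id<TAB>samples'"
                )
            read_id, payload = parts
            if not payload.strip():
                n_skipped += 1
                logger.warning("skipping empty read record %r", read_id)
                continue
            try:
                samples = np.array(payload.split(","), dtype=np.float64)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad sample value") from exc
            if samples.size == 0:
                n_skipped += 1
                logger.warning("skipping empty read record %r", read_id)
                continue
            if not np.all(np.isfinite(samples)):
                raise FormatError(f"{path}:{lineno}: non-finite sample values")
            yield RawRead(read_id=read_id, samples=samples)
    if n_skipped:
        logger.warning("%d empty read records skipped in %s", n_skipped, path)


def _read_slow5(path):
    try:
        import pyslow5  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "SLOW5/BLOW5 input requires the optional pyslow5 library "
            "(pip install pyslow5); use the TSV format otherwise"
        ) from exc
    s5 = pyslow5.Open(str(path), "r")  # pragma: no cover
    for rec in s5.seq_reads():  # pragma: no cover
        samples = np.asarray(rec["signal"], dtype=np.float64)
        if samples.size == 0:
            logger.warning("skipping empty read record %r", rec["read_id"])
            continue
        yield RawRead(
            read_id=rec["read_id"], samples=samples,
            sample_rate=float(rec.get("sampling_rate", 4000.0)),
        )


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def compute_tstat(samples: np.ndarray, w: int) -> np.ndarray:
    """Welch t-statistic between the ``w`` samples before and after each index.

    Position i compares samples[i-w:i] against samples[i:i+w]; positions
    closer than ``w`` to either edge are zero.  Zero-variance windows get a
    tiny variance floor so that an ideal step produces a large finite peak.
    """
    n = samples.size
    t = np.zeros(n, dtype=np.float64)
    if n < 2 * w:
        return t
    c1 = np.concatenate(([0.0], np.cumsum(samples)))
    c2 = np.concatenate(([0.0], np.cumsum(samples ** 2)))
    idx = np.arange(w, n - w + 1)
    s1 = c1[idx] - c1[idx - w]
    q1 = c2[idx] - c2[idx - w]
    s2 = c1[idx + w] - c1[idx]
    q2 = c2[idx + w] - c2[idx]
    m1 = s1 / w
    m2 = s2 / w
    v1 = np.maximum(q1 / w - m1 ** 2, 0.0)
    v2 = np.maximum(q2 / w - m2 ** 2, 0.0)
    eps = 1e-9
    denom = np.sqrt((v1 + v2) / w + eps)
    t[w:n - w + 1] = np.abs(m1 - m2) / denom
    return t


def _peak_detect(
    t_short: np.ndarray,
    t_long: np.ndarray,
    params: EventDetectionParams,
) -> list[int]:
    """Two-detector hysteresis peak calling on the t-statistic traces.

    Each detector waits for its statistic to rise ``peak_height`` above a
    running minimum, tracks the maximum, and fires a boundary at the peak
    position once the statistic has dropped ``peak_height`` below that
    maximum (and the maximum exceeded the detector threshold).  A firing
    short-window detector masks the long-window detector over one window,
    so a sharp boundary is not reported twice.
    """
    n = t_short.size
    DEF_POS = -1
    # per-detector state: [signal, threshold, window, masked_to,
    #                      peak_pos, peak_value, valid]
    short = {"sig": t_short, "thr": params.threshold_short,
             "win": params.window_short, "masked_to": -1,
             "pos": DEF_POS, "val": np.inf, "valid": False}
    longd = {"sig": t_long, "thr": params.threshold_long,
             "win": params.window_long, "masked_to": -1,
             "pos": DEF_POS, "val": np.inf, "valid": False}
    peaks: list[int] = []
    for i in range(n):
        for det in (short, longd):
            if det["masked_to"] >= i:
                continue
            cur = det["sig"][i]
            if det["pos"] == DEF_POS:
                # looking for a rise above the running minimum
                if cur < det["val"]:
                    det["val"] = cur
                elif cur - det["val"] > params.peak_height:
                    det["val"] = cur
                    det["pos"] = i
            else:
                # tracking a candidate peak
                if cur > det["val"]:
                    det["val"] = cur
                    det["pos"] = i
                if det is short and det["val"] > det["thr"]:
                    longd["masked_to"] = det["pos"] + params.window_long
                    longd["pos"] = DEF_POS
                    longd["val"] = np.inf
                    longd["valid"] = False
                if not det["valid"] and det["val"] - cur > params.peak_height:
                    det["valid"] = True
                if det["valid"] and i - det["pos"] > det["win"] // 2:
                    if det["val"] > det["thr"]:
                        peaks.append(det["pos"])
                    det["pos"] = DEF_POS
                    det["val"] = cur
                    det["valid"] = False
    return sorted(set(peaks))


def _prune_boundaries(samples: np.ndarray, edges: list[int], threshold: float):
    """Agglomerative pruning of weakly supported boundaries.

    The sliding short-window t-statistic uses only ``window_short`` samples
    per side, so at its threshold it fires freely on pure noise.  Each
    candidate boundary is therefore re-tested with a Welch t-statistic over
    the two *full* flanking events; the weakest boundary below ``threshold``
    is merged away and its neighbors re-tested, until all surviving
    boundaries are supported.  Genuine level steps exceed the bar by orders
    of magnitude, so this removes noise splits without eroding real events.
    """
    c1 = np.concatenate(([0.0], np.cumsum(samples)))
    c2 = np.concatenate(([0.0], np.cumsum(samples ** 2)))

    def stats(a, b):
        n = b - a
        m = (c1[b] - c1[a]) / n
        v = max((c2[b] - c2[a]) / n - m * m, 0.0)
        return m, v, n

    def tstat(left, right):
        m1, v1, n1 = stats(*left)
        m2, v2, n2 = stats(*right)
        return abs(m1 - m2) / np.sqrt(v1 / n1 + v2 / n2 + 1e-9)

    spans = [(a, b) for a, b in zip(edges[:-1], edges[1:])]
    ts = [tstat(spans[i], spans[i + 1]) for i in range(len(spans) - 1)]
    while ts:
        i = int(np.argmin(ts))
        if ts[i] >= threshold:
            break
        spans[i] = (spans[i][0], spans[i + 1][1])
        del spans[i + 1]
        del ts[i]
        if i > 0:
            ts[i - 1] = tstat(spans[i - 1], spans[i])
        if i < len(ts):
            ts[i] = tstat(spans[i], spans[i + 1])
    return [a for a, _ in spans] + [spans[-1][1]]


def detect_events(
    read: RawRead, params: EventDetectionParams | None = None
) -> list[Event]:
    """Segment a raw read into events.

    Boundaries are t-statistic peaks (see :func:`_peak_detect`) that survive
    the full-event significance pruning (see :func:`_prune_boundaries`);
    events are the spans between consecutive boundaries, covering the read
    from sample 0 to the last sample with no gaps or overlaps.  Each event's
    mean is the arithmetic mean of its samples.
    """
    if params is None:
        params = EventDetectionParams()
    samples = read.samples
    if samples.size <= 2 * params.window_long:
        raise TooShortError(
            f"read {read.read_id!r}: {samples.size} samples is too short "
            f"for event detection (need > {2 * params.window_long})"
        )
    t_short = compute_tstat(samples, params.window_short)
    t_long = compute_tstat(samples, params.window_long)
    boundaries = _peak_detect(t_short, t_long, params)
    edges = [0] + [b for b in boundaries if 0 < b < samples.size] + [samples.size]
    edges = sorted(set(edges))
    if len(edges) > 2:
        prune = params.prune_threshold
        if prune is None:
            prune = params.threshold_long
        edges = _prune_boundaries(samples, edges, prune)
    csum = np.concatenate(([0.0], np.cumsum(samples)))
    events = []
    for a, b in zip(edges[:-1], edges[1:]):
        events.append(Event(start=a, length=b - a,
                            mean=(csum[b] - csum[a]) / (b - a)))
    return events


# ---------------------------------------------------------------------------
# query assembly
# ---------------------------------------------------------------------------

def estimate_adapter_end(
    means: np.ndarray,
    query_size: int = DEFAULT_QUERY_SIZE,
    fallback: int = DEFAULT_PREFIX_TRIM,
    threshold: float = 9.0,
) -> int:
    """Estimate where the adapter prefix ends in a sequence of event means.

    The adapter/stall segment at the start of a read sits at systematically
    lower current than the genomic signal, so the boundary is located as the
    least-squares two-segment changepoint over the event means (maximizing
    the between-segment term n1*n2*(m1-m2)^2, the classic L2/CUSUM
    criterion).  Candidates leaving fewer than ``query_size`` events are not
    considered.  The chosen split must be supported by a Welch t-statistic
    of at least ``threshold`` between the two full segments, otherwise no
    adapter is deemed detectable and ``fallback`` is returned.
    """
    n = means.size
    c_max = n - query_size
    if c_max < 1:
        return min(fallback, max(0, c_max))
    c1 = np.concatenate(([0.0], np.cumsum(means)))
    c2 = np.concatenate(([0.0], np.cumsum(means ** 2)))
    c = np.arange(1, c_max + 1)
    n1 = c.astype(np.float64)
    n2 = (n - c).astype(np.float64)
    m1 = c1[c] / n1
    m2 = (c1[n] - c1[c]) / n2
    gain = n1 * n2 * (m1 - m2) ** 2
    best = int(np.argmax(gain))
    v1 = max(c2[c[best]] / n1[best] - m1[best] ** 2, 0.0)
    v2 = max((c2[n] - c2[c[best]]) / n2[best] - m2[best] ** 2, 0.0)
    t = abs(m1[best] - m2[best]) / np.sqrt(
        v1 / n1[best] + v2 / n2[best] + 1e-9
    )
    if t < threshold:
        return fallback
    return int(c[best])


def trim_and_select(
    events: list[Event],
    prefix_trim: int = DEFAULT_PREFIX_TRIM,
    query_size: int = DEFAULT_QUERY_SIZE,
) -> list[Event]:
    """Drop the adapter prefix and return the next ``query_size`` events."""
    if len(events) < prefix_trim + query_size:
        raise InsufficientEventsError(
            f"{len(events)} events < prefix_trim + query_size "
            f"({prefix_trim} + {query_size})"
        )
    return events[prefix_trim:prefix_trim + query_size]


def prepare_query(
    read: RawRead,
    params: EventDetectionParams | None = None,
    prefix_trim: int = DEFAULT_PREFIX_TRIM,
    query_size: int = DEFAULT_QUERY_SIZE,
    fp: FixedPointConfig | None = None,
    adapter_trim: str = "adaptive",
) -> EventQuery:
    """Full query preparation: detect, trim, normalize, quantize.

    The query is the ``query_size`` events following the adapter prefix.
    With ``adapter_trim='adaptive'`` (default) the adapter end is located by
    a mean-shift changepoint over the event means (see
    :func:`estimate_adapter_end`), falling back to ``prefix_trim`` when no
    adapter signature is detectable; ``adapter_trim='fixed'`` always trims
    exactly ``prefix_trim`` events.  Normalization happens over the selected
    query events only, mirroring the reference preparation; the same
    fixed-point scale is then applied.  The result is deterministic and
    independent of batch composition.
    """
    if fp is None:
        fp = FixedPointConfig()
    if adapter_trim not in ("adaptive", "fixed"):
        raise ValueError("adapter_trim must be 'adaptive' or 'fixed'")
    events = detect_events(read, params)
    if adapter_trim == "adaptive":
        all_means = np.array([e.mean for e in events], dtype=np.float64)
        trim = estimate_adapter_end(
            all_means, query_size=query_size, fallback=prefix_trim
        )
    else:
        trim = prefix_trim
    selected = trim_and_select(events, trim, query_size)
    means = np.array([e.mean for e in selected], dtype=np.float64)
    norm = znormalize(means)
    quant = quantize(norm, fp)
    return EventQuery(
        read_id=read.read_id,
        means_float=norm,
        means_quant=quant,
        fp=fp,
        n_prefix_trimmed=trim,
    )
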