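"""End-to-end mapping: strand search, coordinates, MAPQ, accept/reject.

A prepared event query is aligned against both strands of a reference index
with the selected sDTW engine; the strand with the lower best score wins
(forward wins exact ties).  The winning end position is converted from
signal coordinates to 1-based inclusive base coordinates on the forward
reference, and a mapping quality (MAPQ) is derived from the separation
between the best alignment and the best runner-up (the same-strand
second-best outside an exclusion window, or the other strand's best,
whichever is lower):

    mapq = 0                                        if second <= best
    mapq = 60                                       if no runner-up, or best = 0
    mapq = min(60, floor(60 * (second - best) / second))  otherwise

This MAPQ is this package's own operationalization — selective-sequencing
practice only requires *some* monotone confidence score — and is isolated
behind :func:`compute_mapq`.  The accept/reject decision then requires a
mapped read, MAPQ above a threshold, at least one base of overlap with a
target region, and optionally a per-event score ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError, FormatError, SquigmapError
from .pore_model import ReferenceIndex
from .sdtw import SdtwResult, run_engine
from .signal_prep import (
    DEFAULT_PREFIX_TRIM,
    DEFAULT_QUERY_SIZE,
    EventDetectionParams,
    EventQuery,
    prepare_query,
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MappingResult:
    """Outcome of mapping one read (PAF-like semantics).

    ``start_base``/``end_base`` are the 1-based inclusive forward-strand
    interval nominally covered by the query (start <= end on both strands;
    the strand flag carries orientation, so on the reverse strand the
    read-order alignment end is ``start_base``).  ``score`` is in engine
    units (fixed-point for the wavefront engine); ``score_float`` rescales
    it by the scaling factor for comparability.
    """

    read_id: str
    mapped: bool
    strand: str | None = None          # '+' or '-'
    ref_name: str | None = None
    score: float | None = None
    score_float: float | None = None
    end_event: int | None = None
    start_base: int | None = None
    end_base: int | None = None
    mapq: int | None = None
    decision: str = "unmapped"         # accept | reject | unmapped
    engine: str | None = None
    reason: str | None = None          # why unmapped
    second_score: float | None = None
    second_end: int | None = None
    overflow_count: int = 0
    query_size: int = 0

    @property
    def read_end_base(self) -> int | None:
        """Forward-strand base where the alignment ends in read order."""
        if not self.mapped:
            return None
        return self.end_base if self.strand == "+" else self.start_base


@dataclass
class SelectionPolicy:
    """Accept/reject thresholds for selective sequencing.

    ``target_regions`` is a list of (ref_name, start_base, end_base) in
    1-based inclusive coordinates (see :func:`read_bed` for BED input).  An
    empty list disables the region requirement.  ``score_max``, when set,
    caps the accepted mean per-event distance score / (scale * M).
    """

    target_regions: list[tuple[str, int, int]] = field(default_factory=list)
    mapq_min: int = 20
    score_max: float | None = None

    def __post_init__(self):
        if not 0 <= self.mapq_min <= 60:
            raise ConfigError(f"mapq_min must be in [0, 60], got {self.mapq_min}")


@dataclass
class BatchSummary:
    """Per-batch decision counts."""

    accept: int = 0
    reject: int = 0
    unmapped: dict = field(default_factory=dict)  # reason -> count

    @property
    def total(self) -> int:
        return self.accept + self.reject + sum(self.unmapped.values())


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def event_to_base_interval(
    end_event: int, strand: str, base_length: int, k: int, query_size: int
) -> tuple[int, int]:
    """Convert a strand signal end index to forward-strand base coordinates.

    Forward strand: signal index e covers bases [e+1, e+k]; the alignment
    end base is e + k and the nominal query footprint reaches back
    query_size + k - 1 bases (M k-mer windows cover M + k - 1 bases).
    Reverse strand: signal index e of the reverse-complement signal covers
    forward bases [L-e-k+1, L-e]; the alignment ends (in read order) at the
    interval's low edge and the footprint extends toward higher forward
    coordinates.  Intervals are clipped into [1, L].
    """
    L = base_length
    span = query_size + k - 1
    if strand == "+":
        end_base = end_event + k
        start_base = max(1, end_base - span + 1)
    elif strand == "-":
        start_base = max(1, L - end_event - k + 1)
        end_base = min(L, start_base + span - 1)
    else:
        raise ConfigError(f"strand must be '+' or '-', got {strand!r}")
    return start_base, end_base


# ---------------------------------------------------------------------------
# MAPQ and selection
# ---------------------------------------------------------------------------

def compute_mapq(best_score: float, second_score: float | None) -> int:
    """Mapping quality from best and runner-up alignment scores."""
    if best_score < 0 or (second_score is not None and second_score < 0):
        raise SquigmapError("alignment scores must be non-negative for MAPQ")
    if second_score is None:
        return 60
    if second_score <= best_score:
        return 0
    if best_score == 0:
        return 60
    return min(60, math.floor(60.0 * (second_score - best_score) / second_score))


def apply_selection(m: MappingResult, policy: SelectionPolicy) -> MappingResult:
    """Set the accept/reject decision on a finalized mapping result."""
    if not m.mapped:
        m.decision = "unmapped"
        return m
    ok = m.mapq >= policy.mapq_min
    if ok and policy.target_regions:
        ok = any(
            name == m.ref_name
            and m.start_base <= r_end
            and m.end_base >= r_start  # >= 1 base of overlap
            for name, r_start, r_end in policy.target_regions
        )
    if ok and policy.score_max is not None:
        per_event = m.score_float / max(1, m.query_size)
        ok = per_event <= policy.score_max
    m.decision = "accept" if ok else "reject"
    return m


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def _strand_result(
    q: EventQuery, idx: ReferenceIndex, strand: str, engine: str
) -> SdtwResult:
    sig = idx.forward if strand == "+" else idx.reverse
    return run_engine(
        engine,
        q.means_float, sig.float_signal,
        x_quant=q.means_quant, y_quant=sig.quant_signal, fp=idx.fp,
    )


def map_query(q: EventQuery, idx: ReferenceIndex, engine: str = "wavefront") -> MappingResult:
    """Map one event query against both strands of a reference index."""
    if q.fp != idx.fp:
        raise ConfigError(
            f"query fixed-point config {q.fp} does not match index {idx.fp}"
        )
    fwd = _strand_result(q, idx, "+", engine)
    rev = _strand_result(q, idx, "-", engine)
    if fwd.score <= rev.score:  # forward wins exact ties
        strand, win, lose = "+", fwd, rev
    else:
        strand, win, lose = "-", rev, fwd
    M = q.size
    start_base, end_base = event_to_base_interval(
        win.end, strand, idx.base_length, idx.k, M
    )
    # runner-up: same-strand second-best outside the window, or the losing
    # strand's best, whichever is lower
    candidates = [s for s in (win.second_score, lose.score) if s is not None]
    second = min(candidates) if candidates else None
    best = win.score
    if engine == "wavefront" and (best < 0 or (second is not None and second < 0)):
        # overflow wrapped a score negative: no meaningful confidence
        mapq = 0
    else:
        mapq = compute_mapq(best, second)
    scale = idx.fp.scale if engine == "wavefront" else 1.0
    return MappingResult(
        read_id=q.read_id,
        mapped=True,
        strand=strand,
        ref_name=idx.name,
        score=win.score,
        score_float=win.score / scale,
        end_event=win.end,
        start_base=start_base,
        end_base=end_base,
        mapq=mapq,
        engine=engine,
        second_score=second,
        second_end=win.second_end,
        overflow_count=win.overflow_count + lose.overflow_count,
        query_size=M,
    )


def search_space_size(idx: ReferenceIndex) -> int:
    """Two-strand search-space statistic, by the dataset-table convention.

    Reported as 2 x base_length (both strands counted in bases); the actual
    per-strand signal arrays hold L - k + 1 values each, available as
    ``idx.signal_length``.
    """
    return 2 * idx.base_length


def map_batch(
    reads,
    idx: ReferenceIndex,
    params: EventDetectionParams | None = None,
    policy: SelectionPolicy | None = None,
    engine: str = "wavefront",
    prefix_trim: int = DEFAULT_PREFIX_TRIM,
    query_size: int = DEFAULT_QUERY_SIZE,
):
    """Map a stream of raw reads; returns (results, summary).

    Per-read preparation failures become unmapped records with a reason and
    never abort the batch; output order equals input order.  The result is
    a pure function of (reads, index, params, policy, engine).
    """
    if policy is None:
        policy = SelectionPolicy()
    results: list[MappingResult] = []
    summary = BatchSummary()
    for read in reads:
        try:
            q = prepare_query(
                read, params, prefix_trim=prefix_trim,
                query_size=query_size, fp=idx.fp,
            )
        except SquigmapError as exc:
            reason = type(exc).__name__
            results.append(MappingResult(
                read_id=read.read_id, mapped=False,
                decision="unmapped", reason=reason, engine=engine,
            ))
            summary.unmapped[reason] = summary.unmapped.get(reason, 0) + 1
            continue
        m = apply_selection(map_query(q, idx, engine), policy)
        results.append(m)
        if m.decision == "accept":
            summary.accept += 1
        else:
            summary.reject += 1
    return results, summary


# ---------------------------------------------------------------------------
# quantization accuracy sweep
# ---------------------------------------------------------------------------

def scale_accuracy_sweep(
    ref_seq: str,
    model,
    reads,
    scales,
    bits: int = 16,
    overflow_policy: str = "wraparound",
    params: EventDetectionParams | None = None,
    prefix_trim: int = DEFAULT_PREFIX_TRIM,
    query_size: int = DEFAULT_QUERY_SIZE,
    match_tol: int = 0,
):
    """Fraction of reads whose fixed-point mapping matches the float mapping.

    For each scaling factor, every read is mapped with the wavefront engine
    and compared against the float linear engine on the same read: a match
    requires the same winning strand and an end position within
    ``match_tol`` signal positions (default 0: exact agreement, the
    strictest reading of position similarity).  Returns (dict scale ->
    fraction, n_reads_compared).  Reads that fail query preparation are
    excluded.
    """
    from .pore_model import FixedPointConfig, build_reference_index
    from .signal_prep import EventQuery

    float_idx = build_reference_index(ref_seq, model, FixedPointConfig(), "ref")
    queries = []
    for read in reads:
        try:
            q = prepare_query(read, params, prefix_trim=prefix_trim,
                              query_size=query_size, fp=float_idx.fp)
        except SquigmapError:
            continue
        baseline = map_query(q, float_idx, engine="linear")
        queries.append((q, baseline))
    fractions = {}
    for scale in scales:
        fp = FixedPointConfig(bits=bits, scale=scale,
                              overflow_policy=overflow_policy)
        idx = build_reference_index(ref_seq, model, fp, "ref")
        n_match = 0
        for q, baseline in queries:
            from .pore_model import quantize
            qq = EventQuery(
                read_id=q.read_id, means_float=q.means_float,
                means_quant=quantize(q.means_float, fp), fp=fp,
                n_prefix_trimmed=q.n_prefix_trimmed,
            )
            m = map_query(qq, idx, engine="wavefront")
            if (m.strand == baseline.strand
                    and abs(m.end_event - baseline.end_event) <= match_tol):
                n_match += 1
        fractions[scale] = n_match / len(queries) if queries else 0.0
    return fractions, len(queries)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED (0-based half-open) into 1-based inclusive regions."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad BED coordinates") from exc
            regions.append((fields[0], start + 1, end))
    return regions


PAF_HEADER = (
    "read_id\tquery_events\tqstart\tqend\tstrand\tref_name\tref_len\t"
    "start_base\tend_base\tscore\tmapq\ttags"
)


def format_paf_line(m: MappingResult, ref_len: int) -> str:
    """One PAF-like TSV row for a mapping result."""
    tags = f"dc:{m.decision}"
    if m.second_score is not None:
        tags += f"\tse:{m.second_score:g}"
    tags += f"\tov:{m.overflow_count}"
    if m.reason:
        tags += f"\trs:{m.reason}"
    if not m.mapped:
        return (f"{m.read_id}\t{m.query_size}\t0\t0\t*\t*\t{ref_len}\t"
                f"0\t0\t0\t0\t{tags}")
    return (
        f"{m.read_id}\t{m.query_size}\t0\t{m.query_size}\t{m.strand}\t"
        f"{m.ref_name}\t{ref_len}\t{m.start_base}\t{m.end_base}\t"
        f"{m.score:g}\t{m.mapq}\t{tags}"
    )


def write_paf(results, idx: ReferenceIndex, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(PAF_HEADER + "\n")
        for m in results:
            fh.write(format_paf_line(m, idx.base_length) + "\n")
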