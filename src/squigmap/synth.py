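"""Seeded synthetic squiggle generation with known ground truth.

The generator emulates what a selective-sequencing front end sees during
the first fraction of a second of a read: an adapter prefix of 50-300
events whose levels fall outside the typical genomic level range, followed
by a few hundred genomic events whose true levels come from a k-mer pore
model applied to a known strand and position of the reference.  Each event
emits a variable number of raw samples (geometric dwell, minimum 4 samples
so the default segmentation windows can resolve it) with Gaussian level
noise.  Everything is a pure function of the seed: a dataset RNG is split
per read by counter, so generation order or parallelism cannot change the
data.

The truth record keeps per-event levels and dwells (including the adapter),
so evaluations can map any raw-sample position back to the true reference
coordinate without assuming perfect segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SizeError
from .pore_model import (
    PoreModel,
    reverse_complement,
    sequence_to_signal,
    write_pore_model,
)
from .signal_prep import RawRead

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# parameters and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimParams:
    """Simulation conditions.

    noise_sigma : Gaussian level noise s.d., model units.
    dwell_mean / dwell_min : samples per event (geometric above the minimum,
        or fixed at ``dwell_mean`` with ``dwell_dist='fixed'``).
    adapter_events : inclusive count range of adapter-prefix events.
    read_events : genomic events per read.
    revcomp_prob : probability a read comes from the reverse strand.
    """

    noise_sigma: float = 0.5
    dwell_mean: int = 10
    dwell_dist: str = "geometric"  # or "fixed"
    dwell_min: int = 4
    adapter_events: tuple[int, int] = (50, 300)
    read_events: int = 400
    revcomp_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.dwell_mean < 4:
            raise ValueError("dwell_mean must be >= 4")
        if self.dwell_dist not in ("geometric", "fixed"):
            raise ValueError("dwell_dist must be 'geometric' or 'fixed'")
        if not 0 <= self.revcomp_prob <= 1:
            raise ValueError("revcomp_prob must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read.

    ``start_base``/``end_base`` bound the sequenced genomic span in 1-based
    inclusive forward-reference coordinates (start <= end on both strands).
    ``event_levels``/``event_lengths`` cover all events in emission order,
    adapter first.
    """

    read_id: str
    strand: str
    start_base: int
    end_base: int
    n_adapter_events: int
    event_levels: np.ndarray = field(repr=False)
    event_lengths: np.ndarray = field(repr=False)

    @property
    def n_events(self) -> int:
        return len(self.event_levels)

    def sample_to_event(self, sample_index: int) -> int:
        """True event index containing a raw sample position."""
        edges = np.cumsum(self.event_lengths)
        idx = int(np.searchsorted(edges, sample_index, side="right"))
        if idx >= len(edges):
            raise SizeError(f"sample {sample_index} beyond read end")
        return idx


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_pore_model(k: int, rng_seed: int) -> PoreModel:
    """Complete 4**k pore model with well-separated levels.

    Levels are uniform in 60-140 model units; a minimum pairwise gap of
    ``40 / 4**k`` units is enforced by rejection so no two k-mers share a
    level, keeping ideal step signals segmentable.  Deterministic per seed.
    """
    if not 1 <= k <= 8:
        raise SizeError(f"k must be in [1, 8], got {k}")
    rng = np.random.default_rng(rng_seed)
    n = 4 ** k
    min_gap = 40.0 / n
    levels: list[float] = []
    taken = np.empty(0)
    while len(levels) < n:
        cand = rng.uniform(60.0, 140.0, size=n)
        for c in cand:
            if len(levels) == n:
                break
            if taken.size == 0 or np.min(np.abs(taken - c)) >= min_gap:
                levels.append(float(c))
                taken = np.asarray(levels)
    kmers = _enumerate_kmers(k)
    return PoreModel(k=k, levels=dict(zip(kmers, levels)))


def _enumerate_kmers(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [km + b for km in kmers for b in "ACGT"]
    return kmers


def generate_reference(length_bases: int, rng_seed: int) -> str:
    """Uniform random ACGT string, deterministic per seed."""
    if length_bases < 1:
        raise SizeError(f"reference length must be >= 1, got {length_bases}")
    rng = np.random.default_rng(rng_seed)
    return "".join(_BASES[rng.integers(0, 4, size=length_bases)])


def _adapter_band(model: PoreModel) -> tuple[float, float]:
    """Low-current level band for adapter events, outside the model's
    central range.

    Adapter/stall segments sit at systematically lower current than genomic
    signal, so adapter levels are drawn uniformly from below the model's
    first level quartile, extending a quarter of the level range below the
    model minimum.
    """
    vals = np.asarray(list(model.levels.values()))
    lo, q25, hi = np.percentile(vals, [0, 25, 100])
    return float(lo - 0.25 * (hi - lo)), float(q25)


def _draw_dwells(rng, n: int, params: SimParams) -> np.ndarray:
    if params.dwell_dist == "fixed":
        return np.full(n, int(params.dwell_mean), dtype=np.int64)
    p = 1.0 / (params.dwell_mean - params.dwell_min + 1)
    return params.dwell_min + rng.geometric(p, size=n) - 1


def simulate_read(
    ref_seq: str,
    model: PoreModel,
    params: SimParams,
    rng: np.random.Generator,
    read_id: str = "read",
    strand_levels: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[RawRead, TruthRecord]:
    """Simulate one raw read from a known strand and position.

    ``strand_levels`` may pass precomputed (forward, reverse) model-level
    arrays for the reference to avoid recomputation across a dataset.
    """
    k = model.k
    E = params.read_events
    L = len(ref_seq)
    n_windows = L - k + 1
    if n_windows < E:
        raise SizeError(
            f"reference with {n_windows} windows too short for {E} events"
        )
    if strand_levels is None:
        fwd = sequence_to_signal(ref_seq, model)
        rev = sequence_to_signal(reverse_complement(ref_seq), model)
    else:
        fwd, rev = strand_levels

    strand = "-" if rng.random() < params.revcomp_prob else "+"
    w0 = int(rng.integers(0, n_windows - E + 1))
    if strand == "+":
        genomic_levels = fwd[w0:w0 + E]
        start_base, end_base = w0 + 1, w0 + E + k - 1
    else:
        genomic_levels = rev[w0:w0 + E]
        start_base, end_base = L - w0 - E - k + 2, L - w0

    a_lo, a_hi = params.adapter_events
    n_adapter = int(rng.integers(a_lo, a_hi + 1))
    band = _adapter_band(model)
    adapter_levels = rng.uniform(band[0], band[1], size=n_adapter)

    levels = np.concatenate([adapter_levels, genomic_levels])
    dwells = _draw_dwells(rng, levels.size, params)
    samples = np.repeat(levels, dwells)
    if params.noise_sigma > 0:
        samples = samples + rng.normal(0.0, params.noise_sigma, size=samples.size)

    read = RawRead(read_id=read_id, samples=samples)
    truth = TruthRecord(
        read_id=read_id, strand=strand,
        start_base=int(start_base), end_base=int(end_base),
        n_adapter_events=n_adapter,
        event_levels=levels, event_lengths=dwells,
    )
    return read, truth


def simulate_dataset(
    ref_seq: str,
    model: PoreModel,
    params: SimParams,
    n_reads: int,
    id_prefix: str = "read",
) -> tuple[list[RawRead], list[TruthRecord]]:
    """Simulate ``n_reads`` reads; per-read RNGs are split by counter."""
    fwd = sequence_to_signal(ref_seq, model)
    rev = sequence_to_signal(reverse_complement(ref_seq), model)
    reads, truths = [], []
    for i in range(n_reads):
        rng = np.random.default_rng([params.seed, i])
        read, truth = simulate_read(
            ref_seq, model, params, rng,
            read_id=f"{id_prefix}{i:05d}", strand_levels=(fwd, rev),
        )
        reads.append(read)
        truths.append(truth)
    return reads, truths


# ---------------------------------------------------------------------------
# fixture writers
# ---------------------------------------------------------------------------

def truth_sample_to_forward_base(
    truth: TruthRecord, sample_index: int, k: int, base_length: int
) -> int | None:
    """Forward-reference base (1-based) truly underlying a raw sample.

    Returns the read-order alignment end convention: the last base of the
    k-mer window on the forward strand, the first base of the window (in
    forward coordinates) on the reverse strand.  None when the sample falls
    inside the adapter prefix.
    """
    ev = truth.sample_to_event(sample_index)
    t = ev - truth.n_adapter_events
    if t < 0:
        return None
    if truth.strand == "+":
        w0 = truth.start_base - 1
        return w0 + t + k
    w0 = base_length - truth.end_base
    return base_length - (w0 + t) - k + 1


def write_fixtures(
    outdir,
    ref_seq: str,
    model: PoreModel,
    reads: list[RawRead],
    truths: list[TruthRecord],
    ref_name: str = "synthetic_ref",
) -> dict[str, Path]:
    """Write a dataset as plain-text fixture files.

    Layout: ``ref.fa``, ``model.tsv``, ``reads.tsv`` (one read per line,
    ``read_id<TAB>c1,c2,...``), ``truth.tsv`` (read_id, strand, start_base,
    end_base, n_adapter_events) and, when pyslow5 is installed,
    ``reads.blow5``.  Re-running with identical inputs reproduces identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["ref"] = outdir / "ref.fa"
    with open(paths["ref"], "w") as fh:
        fh.write(f">{ref_name}\n")
        for i in range(0, len(ref_seq), 70):
            fh.write(ref_seq[i:i + 70] + "\n")

    paths["model"] = outdir / "model.tsv"
    write_pore_model(model, paths["model"])

    paths["reads"] = outdir / "reads.tsv"
    with open(paths["reads"], "w") as fh:
        for read in reads:
            payload = ",".join(repr(float(v)) for v in read.samples)
            fh.write(f"{read.read_id}\t{payload}\n")

    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("read_id\tstrand\tstart_base\tend_base\tn_adapter_events\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.strand}\t{t.start_base}\t{t.end_base}\t"
                f"{t.n_adapter_events}\n"
            )

    try:
        import pyslow5  # type: ignore
    except ImportError:
        pass
    else:  # pragma: no cover - optional dependency
        paths["blow5"] = outdir / "reads.blow5"
        s5 = pyslow5.Open(str(paths["blow5"]), "w")
        header = s5.get_empty_header()
        header["run_id"] = "squigmap-synthetic"
        s5.write_header(header)
        for read in reads:
            rec, aux = s5.get_empty_record(aux=True)
            rec["read_id"] = read.read_id
            rec["read_group"] = 0
            rec["offset"] = 0.0
            rec["sampling_rate"] = read.sample_rate
            rec["len_raw_signal"] = len(read.samples)
            rec["signal"] = np.asarray(read.samples, dtype=np.int16)
            rec["digitisation"] = 8192.0
            rec["range"] = 1400.0
            s5.write_record(rec, aux)
        s5.close()
    return paths
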