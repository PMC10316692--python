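"""Pore models and synthetic signal reference construction.

A *pore model* maps each k-mer over {A,C,G,T} to the current level expected
while that k-mer dwells in the nanopore.  Sliding a k-base window over a base
reference and looking each window up in the model turns a DNA sequence into a
synthetic "squiggle" — the signal-domain reference against which raw reads
are aligned.  Because DNA is double stranded, both the forward sequence and
its reverse complement are synthesized.  Each strand's signal is z-score
normalized and then scaled into a narrow fixed-point integer representation
(16-bit words, scaling factor 32 by default) so that the alignment engines
can run entirely in small integer arithmetic.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    AlphabetError,
    ConfigError,
    DegenerateSignalError,
    FormatError,
    KmerLookupError,
    SizeError,
)

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANTGCAN")

INDEX_FORMAT_VERSION = "squigmap-index-v1"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PoreModel:
    """k-mer -> expected current level table.

    Parameters
    ----------
    k : int
        k-mer length in bases.
    levels : dict[str, float]
        Expected current level per k-mer (model units; dimensionless after
        normalization downstream).
    stdvs : dict[str, float] | None
        Optional per-k-mer level spread (not used by the mapper; carried for
        completeness of community model tables).
    """

    k: int
    levels: dict[str, float]
    stdvs: dict[str, float] | None = None
    _lut: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        for kmer, level in self.levels.items():
            if len(kmer) != self.k:
                raise FormatError(
                    f"k-mer {kmer!r} has length {len(kmer)}, expected {self.k}"
                )
            if any(b not in _BASE_CODE for b in kmer):
                raise FormatError(f"k-mer {kmer!r} contains non-ACGT characters")
            if not np.isfinite(level):
                raise FormatError(f"level for k-mer {kmer!r} is not finite")

    @property
    def complete(self) -> bool:
        """True when all 4**k k-mers are present."""
        return len(self.levels) == 4 ** self.k

    def level_table(self) -> np.ndarray:
        """Dense lookup table indexed by base-4 k-mer code (complete models).

        The code of a k-mer is ``sum(code(base_i) * 4**(k-1-i))`` with
        A=0, C=1, G=2, T=3.  Built lazily and cached.
        """
        if not self.complete:
            raise ConfigError("dense level table requires a complete model")
        if self._lut is None:
            lut = np.empty(4 ** self.k, dtype=np.float64)
            for kmer, level in self.levels.items():
                code = 0
                for b in kmer:
                    code = code * 4 + _BASE_CODE[b]
                lut[code] = level
            self._lut = lut
        return self._lut


@dataclass(frozen=True)
class FixedPointConfig:
    """Fixed-point representation used by the quantized alignment engines.

    ``scale`` multiplies z-normalized signal values before rounding to
    integers; ``bits`` is the word width of every value and accumulator in
    the fixed-point engines.  The defaults (16-bit words, scale 32) keep
    quantization error small while leaving enough headroom that accumulated
    alignment costs do not overflow on kilobase-scale references.
    """

    bits: int = 16
    scale: int = 32
    overflow_policy: str = "wraparound"  # or "saturate"

    def __post_init__(self):
        if self.bits < 8:
            raise ConfigError(f"bits must be >= 8, got {self.bits}")
        if self.scale < 1:
            raise ConfigError(f"scale must be >= 1, got {self.scale}")
        if self.overflow_policy not in ("wraparound", "saturate"):
            raise ConfigError(
                f"overflow_policy must be 'wraparound' or 'saturate', "
                f"got {self.overflow_policy!r}"
            )

    @property
    def min_value(self) -> int:
        return -(1 << (self.bits - 1))

    @property
    def max_value(self) -> int:
        return (1 << (self.bits - 1)) - 1


@dataclass(frozen=True)
class StrandSignal:
    """One strand of a reference index: float and quantized signal arrays."""

    float_signal: np.ndarray  # z-normalized, float64, length L - k + 1
    quant_signal: np.ndarray  # fixed-point int64 (values within word range)
    norm_mean: float          # mean removed during z-normalization
    norm_std: float           # population std divided out
    n_clamped: int            # values clamped during quantization


@dataclass(frozen=True)
class ReferenceIndex:
    """Per-strand normalized + quantized signal reference for one sequence."""

    name: str
    base_length: int
    k: int
    fp: FixedPointConfig
    forward: StrandSignal
    reverse: StrandSignal

    @property
    def signal_length(self) -> int:
        """Per-strand signal length, L - k + 1."""
        return self.base_length - self.k + 1


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_pore_model(path) -> PoreModel:
    """Load a k-mer pore model from a TSV file.

    The format follows community k-mer model tables: tab-separated rows of
    ``kmer<TAB>level_mean[<TAB>level_stdv ...]``, with an optional header
    line whose first field starts with ``kmer``.  k is inferred from the
    first row; inconsistent k-mer lengths, non-ACGT k-mers, duplicates and
    empty files are format errors.
    """
    path = Path(path)
    levels: dict[str, float] = {}
    stdvs: dict[str, float] = {}
    k = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower().startswith("kmer"):
                continue
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 2 tab-separated fields"
                )
            kmer = fields[0].strip().upper()
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise FormatError(
                    f"{path}:{lineno}: k-mer {kmer!r} has length {len(kmer)}, "
                    f"expected {k}"
                )
            if any(b not in _BASE_CODE for b in kmer):
                raise FormatError(
                    f"{path}:{lineno}: k-mer {kmer!r} contains non-ACGT characters"
                )
            if kmer in levels:
                raise FormatError(f"{path}:{lineno}: duplicate k-mer {kmer!r}")
            try:
                levels[kmer] = float(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad level {fields[1]!r}") from exc
            if len(fields) >= 3:
                try:
                    stdvs[kmer] = float(fields[2])
                except ValueError:
                    pass  # extra columns are ignored when not numeric
    if not levels:
        raise FormatError(f"{path}: empty pore model file")
    return PoreModel(k=k, levels=levels, stdvs=stdvs or None)


def write_pore_model(model: PoreModel, path) -> None:
    """Write a pore model as TSV (inverse of :func:`load_pore_model`)."""
    with open(path, "w") as fh:
        if model.stdvs:
            fh.write("kmer\tlevel_mean\tlevel_stdv\n")
            for kmer in sorted(model.levels):
                fh.write(f"{kmer}\t{model.levels[kmer]!r}\t{model.stdvs[kmer]!r}\n")
        else:
            fh.write("kmer\tlevel_mean\n")
            for kmer in sorted(model.levels):
                fh.write(f"{kmer}\t{model.levels[kmer]!r}\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (A<->T, C<->G, N fixed).

    Case-insensitive input, uppercase output; an involution.
    """
    up = seq.upper()
    bad = set(up) - set("ACGTN")
    if bad:
        raise AlphabetError(f"unexpected characters in sequence: {sorted(bad)}")
    return up.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise AlphabetError(
            f"non-ACGT character {seq[pos]!r} at position {pos}"
        )
    return codes


def sequence_to_signal(seq: str, model: PoreModel) -> np.ndarray:
    """Synthesize the expected signal for ``seq`` under ``model``.

    Slides a k-base window over the sequence; element i of the output is the
    model level of ``seq[i:i+k]``.  Output length is ``len(seq) - k + 1``.
    Complete models use a vectorized base-4 rolling-code lookup; incomplete
    models fall back to dictionary lookups and raise :class:`KmerLookupError`
    naming the first missing k-mer.
    """
    k = model.k
    seq = seq.upper()
    if len(seq) < k:
        raise SizeError(f"sequence length {len(seq)} < k={k}")
    if model.complete:
        codes = encode_bases(seq).astype(np.int64)
        # rolling base-4 code of each window via polynomial evaluation
        n_win = len(seq) - k + 1
        kmer_codes = np.zeros(n_win, dtype=np.int64)
        for offset in range(k):
            kmer_codes = kmer_codes * 4 + codes[offset:offset + n_win]
        return model.level_table()[kmer_codes]
    out = np.empty(len(seq) - k + 1, dtype=np.float64)
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        try:
            out[i] = model.levels[kmer]
        except KeyError:
            raise KmerLookupError(kmer, i) from None
    return out


def znormalize(x: np.ndarray) -> np.ndarray:
    """Z-score normalize using the population standard deviation.

    Output has mean 0 and population std 1.  Constant input (zero variance)
    raises :class:`DegenerateSignalError`; length < 2 raises
    :class:`SizeError`.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise SizeError(f"cannot z-normalize array of length {x.size}")
    mean = float(np.mean(x))
    std = float(np.std(x))  # population std (ddof=0)
    if std == 0.0:
        raise DegenerateSignalError("constant signal has zero variance")
    return (x - mean) / std


def znormalize_stats(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Like :func:`znormalize` but also returns (mean, population std)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise SizeError(f"cannot z-normalize array of length {x.size}")
    mean = float(np.mean(x))
    std = float(np.std(x))
    if std == 0.0:
        raise DegenerateSignalError("constant signal has zero variance")
    return (x - mean) / std, mean, std


def quantize(
    x: np.ndarray, fp: FixedPointConfig, return_clamp_count: bool = False
):
    """Scale and round a normalized signal into fixed-point integers.

    Each element is multiplied by ``fp.scale``, rounded to the nearest
    integer with ties away from zero, then clamped into the representable
    range ``[-2**(bits-1), 2**(bits-1) - 1]``.  Clamping is silent but
    counted; pass ``return_clamp_count=True`` to receive the count.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ConfigError("cannot quantize non-finite values")
    scaled = x * fp.scale
    # round half away from zero (np.round rounds half to even)
    rounded = np.where(
        scaled >= 0, np.floor(scaled + 0.5), np.ceil(scaled - 0.5)
    ).astype(np.int64)
    clamped = np.clip(rounded, fp.min_value, fp.max_value)
    n_clamped = int(np.count_nonzero(clamped != rounded))
    if return_clamp_count:
        return clamped, n_clamped
    return clamped


def _build_strand(signal_raw: np.ndarray, fp: FixedPointConfig) -> StrandSignal:
    norm, mean, std = znormalize_stats(signal_raw)
    quant, n_clamped = quantize(norm, fp, return_clamp_count=True)
    return StrandSignal(
        float_signal=norm, quant_signal=quant,
        norm_mean=mean, norm_std=std, n_clamped=n_clamped,
    )


def build_reference_index(
    seq: str,
    model: PoreModel,
    fp: FixedPointConfig | None = None,
    name: str = "ref",
) -> ReferenceIndex:
    """Build the two-strand signal reference index for one sequence.

    Forward strand: ``quantize(znormalize(sequence_to_signal(seq)))``.
    Reverse strand: the same pipeline on the reverse complement.  Each
    strand is normalized independently and its statistics recorded.
    Ambiguity codes (N) are rejected here with a clear error.
    """
    if fp is None:
        fp = FixedPointConfig()
    seq = seq.upper()
    bad = set(seq) - set(_BASES)
    if bad:
        raise AlphabetError(
            f"reference {name!r} contains unsupported characters {sorted(bad)}; "
            "ambiguity codes are not indexable"
        )
    fwd = _build_strand(sequence_to_signal(seq, model), fp)
    rev = _build_strand(sequence_to_signal(reverse_complement(seq), model), fp)
    return ReferenceIndex(
        name=name, base_length=len(seq), k=model.k, fp=fp,
        forward=fwd, reverse=rev,
    )


# ---------------------------------------------------------------------------
# index serialization
# ---------------------------------------------------------------------------
# One .npz container per file, holding any number of reference records.
# Arrays are stored with explicit little-endian dtypes ('<f8' / '<i8') and a
# JSON metadata entry carrying a version tag, so the container round-trips
# bit-exactly across platforms.

def save_index(indexes, path) -> None:
    """Save one or more :class:`ReferenceIndex` records into a container."""
    if isinstance(indexes, ReferenceIndex):
        indexes = [indexes]
    arrays: dict[str, np.ndarray] = {}
    meta = {"version": INDEX_FORMAT_VERSION, "records": []}
    for i, idx in enumerate(indexes):
        fp = idx.fp
        meta["records"].append({
            "name": idx.name,
            "base_length": idx.base_length,
            "k": idx.k,
            "fp": {"bits": fp.bits, "scale": fp.scale,
                   "overflow_policy": fp.overflow_policy},
            "norm": {
                "forward": [idx.forward.norm_mean, idx.forward.norm_std],
                "reverse": [idx.reverse.norm_mean, idx.reverse.norm_std],
            },
            "n_clamped": {"forward": idx.forward.n_clamped,
                          "reverse": idx.reverse.n_clamped},
        })
        for strand, sig in (("fwd", idx.forward), ("rev", idx.reverse)):
            arrays[f"r{i}_{strand}_float"] = sig.float_signal.astype("<f8")
            arrays[f"r{i}_{strand}_quant"] = sig.quant_signal.astype("<i8")
    arrays["meta"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_index(path) -> list[ReferenceIndex]:
    """Load reference indexes written by :func:`save_index`."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode("utf-8"))
            if meta.get("version") != INDEX_FORMAT_VERSION:
                raise FormatError(
                    f"{path}: unsupported index version {meta.get('version')!r}"
                )
            out = []
            for i, rec in enumerate(meta["records"]):
                fp = FixedPointConfig(**rec["fp"])
                strands = {}
                for strand, key in (("forward", "fwd"), ("reverse", "rev")):
                    mean, std = rec["norm"][strand]
                    strands[strand] = StrandSignal(
                        float_signal=data[f"r{i}_{key}_float"].astype(np.float64),
                        quant_signal=data[f"r{i}_{key}_quant"].astype(np.int64),
                        norm_mean=mean, norm_std=std,
                        n_clamped=rec["n_clamped"][strand],
                    )
                out.append(ReferenceIndex(
                    name=rec["name"], base_length=rec["base_length"],
                    k=rec["k"], fp=fp,
                    forward=strands["forward"], reverse=strands["reverse"],
                ))
            return out
    except (zipfile.BadZipFile, KeyError, ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a squigmap index container") from exc
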