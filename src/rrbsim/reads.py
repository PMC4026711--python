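"""Directional bisulfite read simulation, FASTQ I/O, trimming and end QC.

The simulator follows the directional (TruSeq-style) protocol: each sampled
molecule is the bisulfite-converted top or bottom original strand of an
insert (chosen 50/50). Read 1 is sequenced from the molecule's 5' end,
read 2 from the opposite end of the insert on the synthesised complementary
strand. When the insert is shorter than the read length, the sequencer reads
through into the adapter. Unmethylated cytosines are converted to T with
probability ``conversion_rate`` per molecule; methylated cytosines convert
with the (normally zero) ``inappropriate_conversion_rate``. Cytosines
introduced by MspI end repair (fragment ``fill_in_positions``) are always
unmethylated — the artifact RRBS-mode trimming removes.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fragments import Fragment
from .genome import Methylome, ReferenceGenome

__all__ = [
    "DEFAULT_ADAPTER",
    "ConversionParams",
    "QualityModel",
    "ReadPair",
    "TrimConfig",
    "bisulfite_convert",
    "generate_reads",
    "trim_read_pair",
    "trim_pairs",
    "end_composition",
    "write_fastq_pairs",
    "read_fastq_pairs",
]

# TruSeq adapter prefix; the exact sequence only matters for read-through
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

_A, _C, _G, _T = (ord(x) for x in "ACGT")
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ConversionParams:
    """Bisulfite conversion and sequencing-error model."""

    conversion_rate: float = 0.995
    inappropriate_conversion_rate: float = 0.0
    sequencing_error_rate: float = 0.001
    rng_seed: int = 0

    def validate(self) -> List[str]:
        errors = []
        for name in ("conversion_rate", "inappropriate_conversion_rate",
                     "sequencing_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                errors.append(f"{name}: must be in [0, 1]")
        return errors


@dataclass
class QualityModel:
    """Phred qualities along the read: constant, with an optional logistic
    3' decay (floor_quality set) to exercise quality trimming."""

    base_quality: int = 40
    floor_quality: Optional[int] = None
    decay_midpoint: float = 80.0
    decay_steepness: float = 0.15

    def qualities(self, length: int) -> str:
        if self.floor_quality is None:
            return chr(33 + self.base_quality) * length
        i = np.arange(length)
        q = self.floor_quality + (self.base_quality - self.floor_quality) / (
            1.0 + np.exp(self.decay_steepness * (i - self.decay_midpoint))
        )
        return "".join(chr(33 + int(round(v))) for v in q)


@dataclass(frozen=True)
class ReadPair:
    """A paired-end read with its recorded true origin (None once external)."""

    id: str
    read1: str
    qual1: str
    read2: str
    qual2: str
    origin: Optional[Tuple[str, int, int, str]] = None  # chrom, start, end, top|bottom

    def __post_init__(self) -> None:
        if len(self.read1) != len(self.qual1) or len(self.read2) != len(self.qual2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass
class TrimConfig:
    """Quality, adapter and RRBS-mode trimming parameters."""

    quality_cutoff: int = 20
    adapter_sequence: str = DEFAULT_ADAPTER
    rrbs_mode: bool = False
    min_length_after_trim: int = 20

    def validate(self) -> List[str]:
        errors = []
        if self.quality_cutoff < 0:
            errors.append("quality_cutoff: must be >= 0")
        if self.min_length_after_trim < 1:
            errors.append("min_length_after_trim: must be >= 1")
        return errors


# ---------------------------------------------------------------------------
# bisulfite conversion
# ---------------------------------------------------------------------------

def _convert_strand(
    seq_u8: np.ndarray,
    methylated: np.ndarray,
    params: ConversionParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Convert the cytosines of one strand (array is in that strand's 5'->3'
    orientation); returns a new array."""
    out = seq_u8.copy()
    c_mask = seq_u8 == _C
    n = int(c_mask.sum())
    if n == 0:
        return out
    u = rng.random(n)
    meth = methylated[c_mask]
    to_t = np.where(meth, u < params.inappropriate_conversion_rate,
                    u < params.conversion_rate)
    idx = np.flatnonzero(c_mask)[to_t]
    out[idx] = _T
    return out


def bisulfite_convert(
    insert_sequence: str,
    methylation_states: Dict[str, np.ndarray],
    params: ConversionParams,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[str, str]:
    """Convert one double-stranded insert; returns (top, bottom) sequences,
    each 5'->3' on its own strand.

    ``methylation_states`` maps "top" and "bottom" to boolean arrays of the
    insert length, indexed by *top-strand* position: ``top[i]`` applies to a
    top-strand C at i, ``bottom[i]`` to a bottom-strand C at i (a top-strand
    G). Entries at non-cytosine positions are ignored.
    """
    L = len(insert_sequence)
    for key in ("top", "bottom"):
        if len(methylation_states[key]) != L:
            raise ValueError(f"{key} state vector length != insert length")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    top_u8 = np.frombuffer(insert_sequence.encode(), dtype=np.uint8)
    bottom_u8 = np.frombuffer(_revcomp(insert_sequence).encode(), dtype=np.uint8)
    top = _convert_strand(top_u8, np.asarray(methylation_states["top"], dtype=bool),
                          params, rng)
    bottom = _convert_strand(
        bottom_u8, np.asarray(methylation_states["bottom"], dtype=bool)[::-1],
        params, rng)
    return top.tobytes().decode(), bottom.tobytes().decode()


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[_x] = _y


def _revcomp_u8(arr: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[arr[::-1]]


def _apply_errors(read: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return read
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    if len(hits) == 0:
        return read
    out = read.copy()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        alt = bases[bases != out[i]]
        out[i] = rng.choice(alt)
    return out


def generate_reads(
    fragments: Sequence[Fragment],
    genome: ReferenceGenome,
    methylome: Methylome,
    n_pairs: int,
    read_length: int = 100,
    params: Optional[ConversionParams] = None,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
    quality_model: Optional[QualityModel] = None,
) -> List[ReadPair]:
    """Sample molecules and emit 100 bp (by default) paired-end reads.

    Each molecule picks a fragment uniformly at random (no PCR bias), a top
    or bottom original strand with probability 0.5, per-cytosine Bernoulli
    methylation states from the methylome (fill-in positions forced
    unmethylated), bisulfite-converts the strand and sequences both ends.
    Deterministic for a fixed seed.
    """
    if not fragments:
        raise ValueError("no fragments to sequence")
    params = params or ConversionParams()
    quality_model = quality_model or QualityModel()
    rng = np.random.default_rng(seed)
    adapter_u8 = np.frombuffer(adapter.encode(), dtype=np.uint8)
    pairs: List[ReadPair] = []
    for i in range(n_pairs):
        frag = fragments[int(rng.integers(0, len(fragments)))]
        s, e = frag.insert_start, frag.insert_end
        top_strand = bool(rng.random() < 0.5)
        seq = genome.chrom_array(frag.chrom)[s:e]
        if top_strand:
            mol = seq.copy()
            probs = methylome.prob_fwd[frag.chrom][s:e]
            fill_local = [p - s for p in frag.fill_in_positions if seq[p - s] == _C]
        else:
            mol = _revcomp_u8(seq)
            probs = methylome.prob_rev[frag.chrom][s:e][::-1]
            fill_local = [(e - 1) - p for p in frag.fill_in_positions if seq[p - s] == _G]
        c_mask = mol == _C
        states = np.zeros(len(mol), dtype=bool)
        states[c_mask] = rng.random(int(c_mask.sum())) < probs[c_mask]
        if fill_local:
            states[np.asarray(fill_local, dtype=int)] = False
        conv = _convert_strand(mol, states, params, rng)

        def make_read(template: np.ndarray) -> str:
            if len(template) >= read_length:
                read = template[:read_length].copy()
            else:
                pad = read_length - len(template)
                tail = adapter_u8[:pad]
                if len(tail) < pad:
                    tail = np.concatenate(
                        [tail, np.full(pad - len(tail), _A, dtype=np.uint8)])
                read = np.concatenate([template, tail])
            return _apply_errors(read, params.sequencing_error_rate, rng).tobytes().decode()

        r1 = make_read(conv)
        r2 = make_read(_revcomp_u8(conv))  # complement strand, other insert end
        strand_name = "top" if top_strand else "bottom"
        pairs.append(
            ReadPair(
                id=f"sim{i}|{frag.chrom}:{s}-{e}/{strand_name}",
                read1=r1,
                qual1=quality_model.qualities(read_length),
                read2=r2,
                qual2=quality_model.qualities(read_length),
                origin=(frag.chrom, s, e, strand_name),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def _quality_trim_end(qual: str, cutoff: int) -> int:
    """New read length after removing the trailing run of bases below cutoff."""
    end = len(qual)
    while end > 0 and ord(qual[end - 1]) - 33 < cutoff:
        end -= 1
    return end


def _adapter_trim_pos(seq: str, adapter: str) -> Optional[int]:
    """Leftmost position where a suffix matches the adapter prefix with
    >= 1 base overlap and <= 10% mismatches; None if no match."""
    L, alen = len(seq), len(adapter)
    if L == 0 or alen == 0:
        return None
    read = np.frombuffer(seq.encode(), dtype=np.uint8)
    ad = np.frombuffer(adapter.encode(), dtype=np.uint8)
    padded = np.concatenate([read, np.zeros(alen, dtype=np.uint8)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, alen)[:L]
    mm_total = (windows != ad).sum(axis=1)
    overlap = np.minimum(alen, L - np.arange(L))
    mm_valid = mm_total - (alen - overlap)  # padding always mismatches
    ok = mm_valid <= (0.1 * overlap).astype(int)
    hits = np.flatnonzero(ok)
    return int(hits[0]) if len(hits) else None


def trim_read_pair(pair: ReadPair, config: TrimConfig) -> Optional[ReadPair]:
    """Quality- and adapter-trim one pair; None if either mate gets too short.

    3'-end quality trimming removes the trailing run of bases below the
    cutoff; adapter trimming removes the suffix matching the adapter prefix
    (>= 1 base overlap, <= 10% mismatches). In RRBS mode two extra bases are
    cut from the 3' end of any adapter-trimmed read, and the first two bases
    of read 2 are always clipped — together these excise the unmethylated
    fill-in cytosines of MspI end repair from both mates.
    """

    def trim_one(seq: str, qual: str) -> Tuple[str, str, bool]:
        end = _quality_trim_end(qual, config.quality_cutoff)
        seq, qual = seq[:end], qual[:end]
        pos = _adapter_trim_pos(seq, config.adapter_sequence)
        adapter_trimmed = pos is not None
        if adapter_trimmed:
            seq, qual = seq[:pos], qual[:pos]
        if config.rrbs_mode and adapter_trimmed:
            seq, qual = seq[:-2] if len(seq) >= 2 else "", qual[:-2] if len(qual) >= 2 else ""
        return seq, qual, adapter_trimmed

    r1, q1, _ = trim_one(pair.read1, pair.qual1)
    r2, q2, _ = trim_one(pair.read2, pair.qual2)
    if config.rrbs_mode:
        r2, q2 = r2[2:], q2[2:]
    if len(r1) < config.min_length_after_trim or len(r2) < config.min_length_after_trim:
        return None
    return replace(pair, read1=r1, qual1=q1, read2=r2, qual2=q2)


def trim_pairs(pairs: Iterable[ReadPair], config: TrimConfig) -> List[ReadPair]:
    """Trim a library, dropping rejected pairs. RRBS-mode read-2 clipping is
    recorded implicitly in the shorter mate lengths."""
    out = []
    for p in pairs:
        t = trim_read_pair(p, config)
        if t is not None:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# end-composition QC
# ---------------------------------------------------------------------------

def end_composition(pairs: Sequence[ReadPair], k: int = 3) -> pd.DataFrame:
    """Frequency table of the first k bases of read 1 and read 2.

    For MspI digest libraries the read-1 patterns collapse onto the
    methylated/unmethylated restriction-site end (CGG / TGG); sonication
    libraries show no dominant pattern.
    """
    rows = []
    for which in ("read1", "read2"):
        counts: Dict[str, int] = {}
        for p in pairs:
            pat = getattr(p, which)[:k]
            counts[pat] = counts.get(pat, 0) + 1
        total = sum(counts.values())
        for pat, n in sorted(counts.items(), key=lambda kv: -kv[1]):
            rows.append({"read": which, "pattern": pat, "count": n,
                         "fraction": n / total})
    return pd.DataFrame(rows, columns=["read", "pattern", "count", "fraction"])


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def _open(path: str | Path, mode: str):
    path = str(path)
    return gzip.open(path, mode + "t") if path.endswith(".gz") else open(path, mode)


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str | Path,
                      path2: str | Path) -> None:
    """Phred+33 four-line FASTQ, read id carrying the true origin."""
    with _open(path1, "w") as f1, _open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}\n{p.read1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}\n{p.read2}\n+\n{p.qual2}\n")


def _parse_origin(read_id: str) -> Optional[Tuple[str, int, int, str]]:
    try:
        _, locus, = read_id.split("|", 1)
        span, strand = locus.rsplit("/", 1)
        chrom, rest = span.rsplit(":", 1)
        start, end = rest.split("-")
        return chrom, int(start), int(end), strand
    except ValueError:
        return None


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> List[ReadPair]:
    pairs = []
    with _open(path1, "r") as f1, _open(path2, "r") as f2:
        while True:
            h1 = f1.readline().strip()
            if not h1:
                break
            r1 = f1.readline().strip(); f1.readline(); q1 = f1.readline().strip()
            h2 = f2.readline().strip()
            r2 = f2.readline().strip(); f2.readline(); q2 = f2.readline().strip()
            rid = h1[1:]
            if h2[1:] != rid:
                raise ValueError(f"unpaired FASTQ records: {rid} vs {h2[1:]}")
            pairs.append(ReadPair(rid, r1, q1, r2, q2, _parse_origin(rid)))
    return pairs
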