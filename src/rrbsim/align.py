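"""Simplified three-letter bisulfite-aware unique paired-end mapper.

Two converted references are kept: all C->T (for molecules derived from the
original top strand) and all G->A (original bottom strand). Reads are
converted the same way and scored entirely in converted space, so a
bisulfite T never counts as a mismatch against a reference C. Candidate
loci come from an exact-match lookup of the read's 5'-most seed plus every
single-substitution variant of that seed, which guarantees that any
full-read alignment within the one-mismatch budget is found; candidates are
then extended and scored over the full read. A pair is reported only when
exactly one concordant candidate exists: both mates within the mismatch
budget, opposite ends of the insert, correct relative orientation and an
insert length inside the configured window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genome import ReferenceGenome
from .reads import ReadPair

__all__ = [
    "MapperConfig",
    "Alignment",
    "BisulfiteIndex",
    "build_index",
    "map_pair",
    "map_pairs",
    "mapping_efficiency",
    "truth_alignments",
    "alignments_to_frame",
]

_CT = bytes.maketrans(b"C", b"T")
_GA = bytes.maketrans(b"G", b"A")
_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


def _rc(seq: bytes) -> bytes:
    return seq.translate(_RC)[::-1]


@dataclass
class MapperConfig:
    """Mapping contract: 50 bp seed, one mismatch, unique concordant pairs."""

    seed_length_bp: int = 50
    max_mismatches: int = 1
    insert_min_bp: int = 100
    insert_max_bp: int = 300
    require_unique: bool = True

    def validate(self) -> List[str]:
        errors = []
        if self.seed_length_bp < 1:
            errors.append("seed_length_bp: must be >= 1")
        if self.max_mismatches < 0:
            errors.append("max_mismatches: must be >= 0")
        if not 0 < self.insert_min_bp <= self.insert_max_bp:
            errors.append("insert window requires 0 < min <= max")
        return errors


@dataclass(frozen=True)
class Alignment:
    """Result of mapping one pair. Unique alignments carry the single locus."""

    pair_id: str
    status: str  # unique | ambiguous | unmapped | discordant
    chrom: Optional[str] = None
    insert_start: Optional[int] = None
    insert_end: Optional[int] = None
    strand: Optional[str] = None  # top | bottom (original strand)
    mismatches_read1: Optional[int] = None
    mismatches_read2: Optional[int] = None


class BisulfiteIndex:
    """C->T and G->A converted references plus exact seed-lookup tables."""

    def __init__(self, genome: ReferenceGenome, seed_length: int = 50):
        shortest = min(genome.lengths.values())
        if seed_length > shortest:
            raise ValueError(
                f"seed length {seed_length} exceeds shortest chromosome ({shortest} bp)")
        self.genome = genome
        self.seed_length = seed_length
        self.ct: Dict[str, bytes] = {}
        self.ga: Dict[str, bytes] = {}
        self.ct_arr: Dict[str, np.ndarray] = {}
        self.ga_arr: Dict[str, np.ndarray] = {}
        self.ct_seeds: Dict[bytes, List[Tuple[str, int]]] = {}
        self.ga_seeds: Dict[bytes, List[Tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            raw = seq.encode()
            ct, ga = raw.translate(_CT), raw.translate(_GA)
            self.ct[chrom], self.ga[chrom] = ct, ga
            self.ct_arr[chrom] = np.frombuffer(ct, dtype=np.uint8)
            self.ga_arr[chrom] = np.frombuffer(ga, dtype=np.uint8)
            for table, conv in ((self.ct_seeds, ct), (self.ga_seeds, ga)):
                for i in range(len(conv) - seed_length + 1):
                    table.setdefault(conv[i:i + seed_length], []).append((chrom, i))


def build_index(genome: ReferenceGenome, seed_length: int = 50) -> BisulfiteIndex:
    """Build the bisulfite index (both converted references + seed tables)."""
    return BisulfiteIndex(genome, seed_length)


def _seed_hits(table: Dict[bytes, List[Tuple[str, int]]], seed: bytes,
               max_mismatches: int) -> Set[Tuple[str, int]]:
    """Exact hits of the seed and of every <=max_mismatches-substitution
    variant (enumerated only for a budget of one)."""
    hits: Set[Tuple[str, int]] = set(table.get(seed, ()))
    if max_mismatches >= 1:
        b = bytearray(seed)
        for i in range(len(seed)):
            orig = b[i]
            for alt in b"ACGT":
                if alt == orig:
                    continue
                b[i] = alt
                hits.update(table.get(bytes(b), ()))
            b[i] = orig
    return hits


def _count_mm(ref: np.ndarray, start: int, read: np.ndarray) -> Optional[int]:
    if start < 0 or start + len(read) > len(ref):
        return None
    return int((ref[start:start + len(read)] != read).sum())


def _read_candidates(
    index: BisulfiteIndex,
    conv_read: bytes,
    mode: str,           # "ct" | "ga"
    anchor: str,         # "start": seed at read start; "end": seed at read end
    max_mm: int,
) -> List[Tuple[str, int, int]]:
    """(chrom, span_start, mismatches) of full-read hits in converted space."""
    k = index.seed_length
    table = index.ct_seeds if mode == "ct" else index.ga_seeds
    arrs = index.ct_arr if mode == "ct" else index.ga_arr
    seed = conv_read[:k] if anchor == "start" else conv_read[-k:]
    read_arr = np.frombuffer(conv_read, dtype=np.uint8)
    out = []
    for chrom, pos in _seed_hits(table, seed, max_mm):
        span_start = pos if anchor == "start" else pos + k - len(conv_read)
        mm = _count_mm(arrs[chrom], span_start, read_arr)
        if mm is not None and mm <= max_mm:
            out.append((chrom, span_start, mm))
    return out


def pair_candidates(
    pair: ReadPair, index: BisulfiteIndex, config: MapperConfig
) -> Tuple[List[Tuple], List[Tuple[str, int, int]], List[Tuple[str, int, int]]]:
    """Concordant candidate loci for a pair, plus the per-mate hit lists.

    Each concordant candidate is (chrom, insert_start, insert_end, strand,
    mm1, mm2). Used by :func:`map_pair`; exposed for the brute-force
    equivalence tests.
    """
    r1, r2 = pair.read1.encode(), pair.read2.encode()
    L1, L2 = len(r1), len(r2)
    mm = config.max_mismatches

    # original-top: read1 forward from insert start, read2 reverse at insert end
    top_r1 = _read_candidates(index, r1.translate(_CT), "ct", "start", mm)
    top_r2 = _read_candidates(index, _rc(r2).translate(_CT), "ct", "end", mm)
    # original-bottom: read1 reverse at insert end, read2 forward from start
    bot_r1 = _read_candidates(index, _rc(r1).translate(_GA), "ga", "end", mm)
    bot_r2 = _read_candidates(index, r2.translate(_GA), "ga", "start", mm)

    candidates = []
    for c1, p1, m1 in top_r1:
        for c2, p2, m2 in top_r2:
            if c1 != c2:
                continue
            s, e = p1, p2 + L2
            if (config.insert_min_bp <= e - s <= config.insert_max_bp
                    and e - s >= max(L1, L2)):
                candidates.append((c1, s, e, "top", m1, m2))
    for c1, p1, m1 in bot_r1:
        for c2, p2, m2 in bot_r2:
            if c1 != c2:
                continue
            s, e = p2, p1 + L1
            if (config.insert_min_bp <= e - s <= config.insert_max_bp
                    and e - s >= max(L1, L2)):
                candidates.append((c1, s, e, "bottom", m1, m2))
    read1_hits = top_r1 + bot_r1
    read2_hits = top_r2 + bot_r2
    return candidates, read1_hits, read2_hits


def map_pair(pair: ReadPair, index: BisulfiteIndex, config: MapperConfig) -> Alignment:
    """Map one pair; unique only if exactly one concordant candidate exists.

    A tie between original-top and original-bottom interpretations (even at
    the same locus) counts as ambiguity. Pairs with a mate shorter than the
    seed cannot be seeded and are unmapped.
    """
    if len(pair.read1) < index.seed_length or len(pair.read2) < index.seed_length:
        return Alignment(pair.id, "unmapped")
    candidates, r1_hits, r2_hits = pair_candidates(pair, index, config)
    distinct = sorted(set((c, s, e, st) for c, s, e, st, _, _ in candidates))
    if len(distinct) == 1:
        c, s, e, st = distinct[0]
        m1, m2 = next((m1, m2) for cc, ss, ee, sst, m1, m2 in candidates
                      if (cc, ss, ee, sst) == (c, s, e, st))
        return Alignment(pair.id, "unique", c, s, e, st, m1, m2)
    if len(distinct) > 1:
        if not config.require_unique:
            best = min(candidates, key=lambda t: t[4] + t[5])
            ties = [t for t in candidates if t[4] + t[5] == best[4] + best[5]]
            if len(set((t[0], t[1], t[2], t[3]) for t in ties)) == 1:
                c, s, e, st, m1, m2 = best
                return Alignment(pair.id, "unique", c, s, e, st, m1, m2)
        return Alignment(pair.id, "ambiguous")
    if r1_hits and r2_hits:
        return Alignment(pair.id, "discordant")
    return Alignment(pair.id, "unmapped")


def map_pairs(pairs: Iterable[ReadPair], index: BisulfiteIndex,
              config: MapperConfig) -> List[Alignment]:
    return [map_pair(p, index, config) for p in pairs]


def mapping_efficiency(alignments: Sequence[Alignment]) -> float:
    """100 x unique / total pairs, to one decimal."""
    if not alignments:
        raise ValueError("mapping efficiency undefined for an empty alignment set")
    unique = sum(1 for a in alignments if a.status == "unique")
    return round(100.0 * unique / len(alignments), 1)


def truth_alignments(pairs: Sequence[ReadPair]) -> List[Alignment]:
    """Perfect alignments reconstructed from the simulator's recorded
    origins (all unique) — the truth-tracking oracle path, used to study the
    effect of discarding ambiguous reads."""
    out = []
    for p in pairs:
        if p.origin is None:
            raise ValueError(f"{p.id}: no recorded origin")
        chrom, s, e, strand = p.origin
        out.append(Alignment(p.id, "unique", chrom, s, e, strand, 0, 0))
    return out


def alignments_to_frame(alignments: Sequence[Alignment]) -> pd.DataFrame:
    """SAM-like TSV-ready table (0-based half-open insert coordinates)."""
    return pd.DataFrame(
        [
            {
                "pair_id": a.pair_id,
                "status": a.status,
                "chrom": a.chrom if a.chrom is not None else ".",
                "insert_start": a.insert_start if a.insert_start is not None else -1,
                "insert_end": a.insert_end if a.insert_end is not None else -1,
                "strand": a.strand if a.strand is not None else ".",
                "mm1": a.mismatches_read1 if a.mismatches_read1 is not None else -1,
                "mm2": a.mismatches_read2 if a.mismatches_read2 is not None else -1,
            }
            for a in alignments
        ]
    )
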