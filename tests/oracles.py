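"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as direct enumeration / full scans,
independent of the code paths it checks.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from rrbsim.align import Alignment, MapperConfig
from rrbsim.genome import ReferenceGenome
from rrbsim.reads import ReadPair

_CT = bytes.maketrans(b"C", b"T")
_GA = bytes.maketrans(b"G", b"A")
_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


def brute_force_sites(sequence: str, recognition: str, cut_offset: int) -> List[int]:
    """Every cut coordinate by scanning all k-mers."""
    k = len(recognition)
    return [i + cut_offset for i in range(len(sequence) - k + 1)
            if sequence[i:i + k] == recognition]


def count_cpgs(sequence: str) -> int:
    """Dinucleotide scan."""
    return sum(1 for i in range(len(sequence) - 1) if sequence[i:i + 2] == "CG")


def cpg_positions(sequence: str) -> List[int]:
    return [i for i in range(len(sequence) - 1) if sequence[i:i + 2] == "CG"]


def cpgs_in_intervals(sequence: str, intervals: List[Tuple[int, int]]) -> set:
    """Distinct CpG positions whose dinucleotide lies fully inside any interval."""
    out = set()
    for p in cpg_positions(sequence):
        for s, e in intervals:
            if s <= p and p + 2 <= e:
                out.add(p)
                break
    return out


class BruteForceAligner:
    """All-positions paired-end bisulfite aligner (no seeding).

    Scores every genomic placement of each mate in converted space, then
    applies the same concordance / uniqueness contract as the seed-based
    mapper. Used only on small genomes.
    """

    def __init__(self, genome: ReferenceGenome, config: MapperConfig):
        self.config = config
        self.ct = {c: np.frombuffer(s.encode().translate(_CT), dtype=np.uint8)
                   for c, s in genome.sequences.items()}
        self.ga = {c: np.frombuffer(s.encode().translate(_GA), dtype=np.uint8)
                   for c, s in genome.sequences.items()}
        self._windows: Dict[Tuple[str, str, int], np.ndarray] = {}

    def _scan(self, mode: str, read: bytes) -> List[Tuple[str, int, int]]:
        """(chrom, span_start, mm) of every placement within the budget."""
        refs = self.ct if mode == "ct" else self.ga
        arr = np.frombuffer(read, dtype=np.uint8)
        L = len(arr)
        out = []
        for chrom, ref in refs.items():
            if L > len(ref):
                continue
            key = (mode, chrom, L)
            if key not in self._windows:
                self._windows[key] = np.lib.stride_tricks.sliding_window_view(ref, L)
            mm = (self._windows[key] != arr).sum(axis=1)
            for pos in np.flatnonzero(mm <= self.config.max_mismatches):
                out.append((chrom, int(pos), int(mm[pos])))
        return out

    def map_pair(self, pair: ReadPair, seed_length: int) -> Alignment:
        cfg = self.config
        if len(pair.read1) < seed_length or len(pair.read2) < seed_length:
            return Alignment(pair.id, "unmapped")
        r1, r2 = pair.read1.encode(), pair.read2.encode()
        rc1 = r1.translate(_RC)[::-1]
        rc2 = r2.translate(_RC)[::-1]
        L1, L2 = len(r1), len(r2)

        top_r1 = self._scan("ct", r1.translate(_CT))
        top_r2 = self._scan("ct", rc2.translate(_CT))
        bot_r1 = self._scan("ga", rc1.translate(_GA))
        bot_r2 = self._scan("ga", r2.translate(_GA))

        candidates = []
        for c1, p1, m1 in top_r1:
            for c2, p2, m2 in top_r2:
                if c1 != c2:
                    continue
                s, e = p1, p2 + L2
                if cfg.insert_min_bp <= e - s <= cfg.insert_max_bp and e - s >= max(L1, L2):
                    candidates.append((c1, s, e, "top", m1, m2))
        for c1, p1, m1 in bot_r1:
            for c2, p2, m2 in bot_r2:
                if c1 != c2:
                    continue
                s, e = p2, p1 + L1
                if cfg.insert_min_bp <= e - s <= cfg.insert_max_bp and e - s >= max(L1, L2):
                    candidates.append((c1, s, e, "bottom", m1, m2))

        distinct = sorted(set((c, s, e, st) for c, s, e, st, _, _ in candidates))
        if len(distinct) == 1:
            c, s, e, st = distinct[0]
            m1, m2 = next((m1, m2) for cc, ss, ee, sst, m1, m2 in candidates
                          if (cc, ss, ee, sst) == (c, s, e, st))
            return Alignment(pair.id, "unique", c, s, e, st, m1, m2)
        if len(distinct) > 1:
            return Alignment(pair.id, "ambiguous")
        if (top_r1 or bot_r1) and (top_r2 or bot_r2):
            return Alignment(pair.id, "discordant")
        return Alignment(pair.id, "unmapped")
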