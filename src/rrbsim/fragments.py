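"""In silico restriction digestion, sonication and fragment size selection.

MspI (C^CGG) cuts between the two cytosines of its site, leaving two-base
5' CG overhangs. After end repair the sequenced insert runs from the
upstream cut to two bases past the downstream cut, so both strands of an
internal fragment begin with the (methylated or bisulfite-converted) CpG of
a restriction site and every RRBS insert contains at least one CpG
dinucleotide. Repair regenerates one cytosine near each insert end — always
unmethylated, since the fill-in nucleotides carry no methylation; those
genomic positions are tracked per fragment so the read simulator can force
them unmethylated (the artifact that RRBS-mode trimming exists to remove).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import FeatureSet, Interval, ReferenceGenome, promoter_interval

_C_CODE, _G_CODE = ord("C"), ord("G")

__all__ = [
    "Enzyme",
    "MSPI",
    "Fragment",
    "SizeWindow",
    "find_sites",
    "digest",
    "rrbs_library",
    "size_select",
    "sonicate",
    "digest_summary",
    "fragments_to_bed",
]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with a top-strand cut offset inside its site."""

    name: str
    recognition_sequence: str
    cut_offset: int

    def __post_init__(self) -> None:
        if set(self.recognition_sequence) - set("ACGT"):
            raise ValueError(f"{self.name}: recognition sequence must be over A/C/G/T")
        if not 0 <= self.cut_offset <= len(self.recognition_sequence):
            raise ValueError(f"{self.name}: cut_offset outside recognition sequence")


MSPI = Enzyme("MspI", "CCGG", 1)


@dataclass(frozen=True)
class Fragment:
    """A sequenced insert: 0-based half-open genomic span plus bookkeeping.

    For digest fragments the insert is the *repaired* double-stranded span:
    it runs from the upstream cut to ``overhang`` bases past the downstream
    cut, because filling the 5' overhangs regenerates those bases on both
    strands (an MspI insert therefore starts and ends with a CpG, and reads
    from either strand begin at a restriction site). ``end_extension``
    records how many bases of the insert lie past the downstream cut, so
    that trimming the extension recovers the exact cut-to-cut partition of
    the chromosome. ``fill_in_positions`` holds the genomic positions of
    cytosines introduced by end repair (always unmethylated; empty for
    sonication fragments). ``terminal`` marks the pre-first-cut /
    post-last-cut chromosome pieces, which have only one ligatable end and
    are excluded from RRBS libraries.
    """

    chrom: str
    insert_start: int
    insert_end: int
    source: str = "digest"  # "digest" | "sonication"
    fill_in_positions: FrozenSet[int] = frozenset()
    terminal: bool = False
    end_extension: int = 0

    def __post_init__(self) -> None:
        if self.insert_start >= self.insert_end:
            raise ValueError("fragment insert must be non-empty")

    @property
    def length(self) -> int:
        return self.insert_end - self.insert_start


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive insert-length bounds of a size selection."""

    min_insert_bp: int
    max_insert_bp: int

    def __post_init__(self) -> None:
        if not 0 < self.min_insert_bp <= self.max_insert_bp:
            raise ValueError("size window requires 0 < min <= max")

    def contains(self, length: int) -> bool:
        return self.min_insert_bp <= length <= self.max_insert_bp


def find_sites(genome: ReferenceGenome, enzyme: Enzyme = MSPI) -> Dict[str, np.ndarray]:
    """All cut coordinates (occurrence start + cut_offset) per chromosome.

    Overlapping occurrences are all reported; the result is sorted and
    duplicate-free by construction.
    """
    pattern = re.compile(f"(?={re.escape(enzyme.recognition_sequence)})")
    return {
        chrom: np.array(
            [m.start() + enzyme.cut_offset for m in pattern.finditer(seq)], dtype=np.int64
        )
        for chrom, seq in genome.sequences.items()
    }


def digest(genome: ReferenceGenome, sites: Dict[str, np.ndarray],
           enzyme: Enzyme = MSPI) -> List[Fragment]:
    """Cut each chromosome at the given positions.

    Returns every piece in genomic order, terminal pieces flagged. The
    cut-to-cut spans (``insert_end - end_extension``) partition each
    chromosome exactly; internal inserts additionally carry the ``overhang``
    bases regenerated by end repair past the downstream cut (2 bp for MspI),
    with the cytosines among the repaired bases — the reverse-strand C at
    insert_start + 1 and the forward-strand C at insert_end - 2 for MspI —
    recorded as unmethylated fill-in positions.
    """
    overhang = max(0, len(enzyme.recognition_sequence) - 2 * enzyme.cut_offset)
    fragments: List[Fragment] = []
    for chrom, seq in genome.sequences.items():
        arr = genome.chrom_array(chrom)
        cuts = sites.get(chrom, np.array([], dtype=np.int64))
        bounds = [0, *[int(c) for c in cuts], len(seq)]
        for i in range(len(bounds) - 1):
            s, e = bounds[i], bounds[i + 1]
            if s == e:
                continue
            terminal = i == 0 or i == len(bounds) - 2
            has_left_cut = i > 0
            has_right_cut = i < len(bounds) - 2
            ext = overhang if has_right_cut else 0
            e_ins = min(e + ext, len(seq))
            ext = e_ins - e
            fill = set()
            if has_left_cut:  # bottom strand repaired over [s, s+overhang)
                fill.update(int(p) for p in range(s, min(s + overhang, len(seq)))
                            if arr[p] == _G_CODE)
            if has_right_cut:  # top strand repaired over [e_ins-ext, e_ins)
                fill.update(int(p) for p in range(e_ins - ext, e_ins)
                            if arr[p] == _C_CODE)
            fragments.append(
                Fragment(chrom, s, e_ins, "digest", frozenset(fill), terminal, ext))
    return fragments


def size_select(fragments: Iterable[Fragment], window: SizeWindow) -> List[Fragment]:
    """Keep fragments whose insert length lies in the window (inclusive)."""
    return [f for f in fragments if window.contains(f.length)]


def rrbs_library(genome: ReferenceGenome, window: SizeWindow,
                 enzyme: Enzyme = MSPI) -> List[Fragment]:
    """Digest, drop terminal pieces, size-select: the RRBS fragment pool."""
    frags = [f for f in digest(genome, find_sites(genome, enzyme), enzyme) if not f.terminal]
    return size_select(frags, window)


def sonicate(
    genome: ReferenceGenome,
    n_fragments: int,
    length_mean: float = 350.0,
    length_sd: float = 50.0,
    window: SizeWindow = SizeWindow(300, 400),
    seed: int = 0,
) -> List[Fragment]:
    """Random shearing with size selection: the WGBS fragment pool.

    Fragment lengths are Normal(length_mean, length_sd) truncated to the
    window; start positions are uniform over the genome (chromosome chosen
    proportionally to its length). No fill-in artifact positions.
    """
    if n_fragments < 0 or length_mean <= 0 or length_sd <= 0:
        raise ValueError("sonication parameters must be positive")
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    out: List[Fragment] = []
    while len(out) < n_fragments:
        length = int(round(rng.normal(length_mean, length_sd)))
        if not window.contains(length):
            continue
        ci = rng.choice(len(chroms), p=lens / lens.sum())
        chrom_len = int(lens[ci])
        if length > chrom_len:
            continue
        start = int(rng.integers(0, chrom_len - length + 1))
        out.append(Fragment(chroms[ci], start, start + length, "sonication"))
    return out


def _cpgs_in(genome: ReferenceGenome, frag: Fragment) -> np.ndarray:
    """Forward-strand CpG positions fully inside the insert."""
    cpg = genome.cpg_positions(frag.chrom)
    lo = np.searchsorted(cpg, frag.insert_start)
    hi = np.searchsorted(cpg, frag.insert_end - 1)
    return cpg[lo:hi]


def digest_summary(
    fragments: Sequence[Fragment],
    features: FeatureSet,
    genome: ReferenceGenome,
    windows: Sequence[SizeWindow],
    min_sites: int = 3,
    promoter_length_bp: int = 2_000,
) -> pd.DataFrame:
    """Coordinate-only prediction of per-window CpG and feature capture.

    For each window: fragment count, total insert bp, distinct CpG sites
    contained in selected fragments, and the number of genes / promoters
    holding at least ``min_sites`` captured CpGs. No reads are involved.
    """
    rows = []
    for window in windows:
        selected = size_select(fragments, window)
        captured: Dict[str, np.ndarray] = {}
        for chrom in genome.sequences:
            chunks = [_cpgs_in(genome, f) for f in selected if f.chrom == chrom]
            captured[chrom] = (
                np.unique(np.concatenate(chunks)) if chunks else np.array([], dtype=np.int64)
            )
        n_cpg = sum(len(v) for v in captured.values())

        def count_qualifying(intervals: Iterable[Optional[Interval]]) -> int:
            n = 0
            for iv in intervals:
                if iv is None:
                    continue
                pos = captured[iv.chrom]
                hits = np.searchsorted(pos, iv.end - 1) - np.searchsorted(pos, iv.start)
                if hits >= min_sites:
                    n += 1
            return n

        promoters = [
            promoter_interval(g, genome.lengths[g.chrom], promoter_length_bp)
            for g in features.genes
        ]
        rows.append(
            {
                "window": f"{window.min_insert_bp}-{window.max_insert_bp}",
                "n_fragments": len(selected),
                "total_insert_bp": sum(f.length for f in selected),
                "distinct_cpgs": n_cpg,
                "genes_ge_min_sites": count_qualifying(features.genes),
                "promoters_ge_min_sites": count_qualifying(promoters),
            }
        )
    return pd.DataFrame(rows)


def fragments_to_bed(fragments: Sequence[Fragment], path: str | Path) -> Path:
    """Export fragments as BED: chrom, start, end, name=source, score=length."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.insert_start}\t{f.insert_end}\t{f.source}\t{f.length}\n")
    return path
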