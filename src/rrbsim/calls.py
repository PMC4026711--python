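"""Per-cytosine methylation calling from unique alignments.

A read base over a reference cytosine is evidence: C = methylated,
T = unmethylated (on the cytosine's own strand; evidence from bottom-strand
molecules appears as G/A in forward orientation). Context (CpG vs non-CpG)
is taken from the reference, never from the read. Overlapping mate segments
are counted once, read 1 winning, to avoid pseudo-replication at short
inserts. Calls are kept per strand; coverage statistics use the
strand-merged CpG-dinucleotide view keyed by forward-strand position.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import Alignment
from .genome import ReferenceGenome
from .reads import ReadPair

__all__ = [
    "MethylationCallTable",
    "call_methylation",
    "conversion_qc",
    "mean_methylation",
]

_C, _G, _T, _A = (ord(x) for x in "CGTA")
_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


class MethylationCallTable:
    """Methylated / unmethylated counts per cytosine, per strand."""

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.meth_fwd = {c: np.zeros(l, dtype=np.int64) for c, l in genome.lengths.items()}
        self.unmeth_fwd = {c: np.zeros(l, dtype=np.int64) for c, l in genome.lengths.items()}
        self.meth_rev = {c: np.zeros(l, dtype=np.int64) for c, l in genome.lengths.items()}
        self.unmeth_rev = {c: np.zeros(l, dtype=np.int64) for c, l in genome.lengths.items()}

    # -- context masks ------------------------------------------------------
    def _cpg_fwd_mask(self, chrom: str) -> np.ndarray:
        a = self.genome.chrom_array(chrom)
        m = np.zeros(len(a), dtype=bool)
        m[:-1] = (a[:-1] == _C) & (a[1:] == _G)
        return m

    def _cpg_rev_mask(self, chrom: str) -> np.ndarray:
        a = self.genome.chrom_array(chrom)
        m = np.zeros(len(a), dtype=bool)
        m[1:] = (a[:-1] == _C) & (a[1:] == _G)
        return m

    # -- aggregate counts ---------------------------------------------------
    def total_calls(self) -> int:
        return int(sum(
            self.meth_fwd[c].sum() + self.unmeth_fwd[c].sum()
            + self.meth_rev[c].sum() + self.unmeth_rev[c].sum()
            for c in self.genome.sequences))

    def context_totals(self, context: str) -> Tuple[int, int]:
        """(methylated, unmethylated) totals over one context class."""
        meth = unmeth = 0
        for chrom in self.genome.sequences:
            fwd_cpg = self._cpg_fwd_mask(chrom)
            rev_cpg = self._cpg_rev_mask(chrom)
            if context == "CpG":
                fm, rm = fwd_cpg, rev_cpg
            else:
                fm, rm = ~fwd_cpg, ~rev_cpg
            meth += int(self.meth_fwd[chrom][fm].sum() + self.meth_rev[chrom][rm].sum())
            unmeth += int(self.unmeth_fwd[chrom][fm].sum() + self.unmeth_rev[chrom][rm].sum())
        return meth, unmeth

    # -- tabular views ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Covered cytosines: chrom, pos, strand, context, counts, level."""
        rows = []
        for chrom in self.genome.sequences:
            for strand, meth, unmeth, cpg in (
                ("+", self.meth_fwd[chrom], self.unmeth_fwd[chrom], self._cpg_fwd_mask(chrom)),
                ("-", self.meth_rev[chrom], self.unmeth_rev[chrom], self._cpg_rev_mask(chrom)),
            ):
                depth = meth + unmeth
                pos = np.flatnonzero(depth > 0)
                rows.append(pd.DataFrame({
                    "chrom": chrom,
                    "pos": pos,
                    "strand": strand,
                    "context": np.where(cpg[pos], "CpG", "non-CpG"),
                    "methylated": meth[pos],
                    "unmethylated": unmeth[pos],
                    "depth": depth[pos],
                    "level": meth[pos] / depth[pos],
                }))
        frame = pd.concat(rows, ignore_index=True)
        return frame.sort_values(["chrom", "pos", "strand"], ignore_index=True)

    def merged_cpg_frame(self, include_uncovered: bool = False) -> pd.DataFrame:
        """Strand-merged CpG dinucleotide sites keyed by forward position.

        Depth is the sum of forward-C and reverse-C (position + 1) evidence.
        """
        rows = []
        for chrom in self.genome.sequences:
            cpg = self.genome.cpg_positions(chrom)
            meth = self.meth_fwd[chrom][cpg] + self.meth_rev[chrom][cpg + 1]
            unmeth = self.unmeth_fwd[chrom][cpg] + self.unmeth_rev[chrom][cpg + 1]
            depth = meth + unmeth
            keep = np.ones(len(cpg), dtype=bool) if include_uncovered else depth > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                level = np.where(depth > 0, meth / np.maximum(depth, 1), np.nan)
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "pos": cpg[keep],
                "methylated": meth[keep],
                "unmethylated": unmeth[keep],
                "depth": depth[keep],
                "level": level[keep],
            }))
        frame = pd.concat(rows, ignore_index=True)
        return frame.sort_values(["chrom", "pos"], ignore_index=True)


def _add_evidence(
    table: MethylationCallTable,
    chrom: str,
    start: int,
    bases_fwd: np.ndarray,
    original_strand: str,
) -> None:
    """Record one forward-oriented read segment starting at ``start``."""
    ref = table.genome.chrom_array(chrom)[start:start + len(bases_fwd)]
    pos = np.arange(start, start + len(bases_fwd))
    if original_strand == "top":
        on_c = ref == _C
        meth = on_c & (bases_fwd == _C)
        unmeth = on_c & (bases_fwd == _T)
        np.add.at(table.meth_fwd[chrom], pos[meth], 1)
        np.add.at(table.unmeth_fwd[chrom], pos[unmeth], 1)
    else:
        # bottom-strand cytosines sit under forward-strand Gs; in forward
        # orientation their evidence reads G (methylated) / A (unmethylated)
        on_c = ref == _G
        meth = on_c & (bases_fwd == _G)
        unmeth = on_c & (bases_fwd == _A)
        np.add.at(table.meth_rev[chrom], pos[meth], 1)
        np.add.at(table.unmeth_rev[chrom], pos[unmeth], 1)


def call_methylation(
    alignments: Sequence[Alignment],
    pairs: Sequence[ReadPair] | Dict[str, ReadPair],
    genome: ReferenceGenome,
) -> MethylationCallTable:
    """Accumulate per-cytosine calls from uniquely aligned pairs.

    Read placement is derived from the alignment's insert span and the
    trimmed mate lengths: read 1 occupies the insert end it was sequenced
    from, read 2 the other; bases of read 2 overlapping read 1 are skipped.
    """
    by_id = pairs if isinstance(pairs, dict) else {p.id: p for p in pairs}
    table = MethylationCallTable(genome)
    for a in alignments:
        if a.status != "unique":
            continue
        if a.chrom not in genome.sequences:
            raise ValueError(f"{a.pair_id}: unknown chromosome {a.chrom}")
        pair = by_id[a.pair_id]
        r1 = np.frombuffer(pair.read1.encode(), dtype=np.uint8)
        r2 = np.frombuffer(pair.read2.encode(), dtype=np.uint8)
        s, e = a.insert_start, a.insert_end
        if a.strand == "top":
            _add_evidence(table, a.chrom, s, r1, "top")
            r2f = np.frombuffer(pair.read2.encode().translate(_RC)[::-1], dtype=np.uint8)
            eff_start = max(e - len(r2), s + len(r1))  # read 1 wins the overlap
            if eff_start < e:
                _add_evidence(table, a.chrom, eff_start,
                              r2f[eff_start - (e - len(r2)):], "top")
        else:
            r1f = np.frombuffer(pair.read1.encode().translate(_RC)[::-1], dtype=np.uint8)
            _add_evidence(table, a.chrom, e - len(r1), r1f, "bottom")
            eff_end = min(s + len(r2), e - len(r1))
            if eff_end > s:
                _add_evidence(table, a.chrom, s, r2[:eff_end - s], "bottom")
    return table


def conversion_qc(table: MethylationCallTable) -> Tuple[float, float]:
    """(non-CpG methylation %, implied conversion efficiency %).

    Residual methylation at non-CpG cytosines estimates the bisulfite
    conversion failure rate; efficiency is its complement to 100.
    """
    meth, unmeth = table.context_totals("non-CpG")
    depth = meth + unmeth
    if depth == 0:
        raise ValueError("no non-CpG calls: conversion QC undefined")
    non_cpg_pct = 100.0 * meth / depth
    return non_cpg_pct, 100.0 - non_cpg_pct


def mean_methylation(
    table: MethylationCallTable,
    min_depth: int = 1,
    weighted: bool = True,
) -> float:
    """Genome-wide CpG methylation % over merged CpG sites with
    depth >= min_depth, to one decimal.

    Depth-weighted by default (global count ratio); ``weighted=False`` gives
    the unweighted mean of per-site levels instead.
    """
    merged = table.merged_cpg_frame()
    merged = merged[merged["depth"] >= min_depth]
    if merged.empty:
        raise ValueError(f"no CpG sites at depth >= {min_depth}")
    if weighted:
        value = 100.0 * merged["methylated"].sum() / merged["depth"].sum()
    else:
        value = 100.0 * merged["level"].mean()
    return round(float(value), 1)
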