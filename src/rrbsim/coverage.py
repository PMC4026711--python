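"""CpG coverage statistics, feature-level coverage and saturation analysis.

The headline design question for an RRBS/WGBS experiment is how many CpG
sites remain usable as the amount of sequencing shrinks. This module counts
strand-merged CpG dinucleotide sites at per-depth thresholds (1x and >=10x
by default), applies the feature rule (a gene or promoter qualifies when it
holds at least three CpGs each covered >=10x), subsamples read pairs without
replacement, and assembles the saturation table of counts and percentages
relative to the full dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import BisulfiteIndex, MapperConfig, map_pairs
from .calls import call_methylation
from .genome import FeatureSet, Interval, ReferenceGenome, promoter_interval
from .reads import ReadPair

__all__ = [
    "CoverageThresholds",
    "count_cpg_coverage",
    "feature_coverage",
    "subsample_pairs",
    "relative_coverage",
    "saturation_analysis",
]


@dataclass
class CoverageThresholds:
    """Depth thresholds and the feature qualification rule."""

    depths: Tuple[int, ...] = (1, 10)
    feature_min_sites: int = 3
    feature_min_depth: int = 10
    promoter_length_bp: int = 2_000

    def validate(self) -> List[str]:
        errors = []
        if not self.depths or any(d <= 0 for d in self.depths):
            errors.append("depths: must be positive")
        if list(self.depths) != sorted(self.depths):
            errors.append("depths: must be sorted ascending")
        if self.feature_min_sites < 1:
            errors.append("feature_min_sites: must be >= 1")
        if self.feature_min_depth < 1:
            errors.append("feature_min_depth: must be >= 1")
        if self.promoter_length_bp <= 0:
            errors.append("promoter_length_bp: must be > 0")
        return errors


def count_cpg_coverage(
    merged_calls: pd.DataFrame, thresholds: CoverageThresholds = CoverageThresholds()
) -> Dict[int, int]:
    """Number of strand-merged CpG sites with combined depth >= d, per d."""
    depth = merged_calls["depth"].to_numpy() if len(merged_calls) else np.array([])
    return {d: int((depth >= d).sum()) for d in thresholds.depths}


def feature_coverage(
    merged_calls: pd.DataFrame,
    features: FeatureSet,
    genome: ReferenceGenome,
    thresholds: CoverageThresholds = CoverageThresholds(),
) -> Dict[str, int]:
    """Genes and promoters holding >= feature_min_sites CpG sites that each
    reach feature_min_depth. Promoters are derived from gene TSSs
    (strand-aware, clipped at chromosome ends)."""
    deep = merged_calls[merged_calls["depth"] >= thresholds.feature_min_depth]
    by_chrom = {
        chrom: np.sort(grp["pos"].to_numpy()) for chrom, grp in deep.groupby("chrom")
    }

    def qualifies(iv: Optional[Interval]) -> bool:
        if iv is None:
            return False
        pos = by_chrom.get(iv.chrom)
        if pos is None:
            return False
        n = np.searchsorted(pos, iv.end - 1) - np.searchsorted(pos, iv.start)
        return bool(n >= thresholds.feature_min_sites)

    promoters = [
        promoter_interval(g, genome.lengths[g.chrom], thresholds.promoter_length_bp)
        for g in features.genes
    ]
    return {
        "qualifying_genes": sum(qualifies(g) for g in features.genes),
        "qualifying_promoters": sum(qualifies(p) for p in promoters),
        "total_genes": len(features.genes),
        "total_promoters": sum(p is not None for p in promoters),
    }


def subsample_pairs(pairs: Sequence[ReadPair], fraction: float, seed: int = 0) -> List[ReadPair]:
    """Exact-count sampling without replacement of round(fraction x N) pairs.

    Implemented as a prefix of one seed-keyed permutation, so subsamples at
    decreasing fractions under the same seed are nested.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = int(round(fraction * len(pairs)))
    perm = np.random.default_rng(seed).permutation(len(pairs))
    return [pairs[i] for i in perm[:n]]


def relative_coverage(count: int, full_count: int) -> float:
    """100 x count / full_count to one decimal (round-half-even)."""
    if full_count <= 0:
        raise ValueError("full_count must be > 0")
    return round(100.0 * count / full_count, 1)


def saturation_analysis(
    pairs: Sequence[ReadPair],
    fractions: Sequence[float],
    genome: ReferenceGenome,
    index: BisulfiteIndex,
    mapper_config: MapperConfig,
    thresholds: CoverageThresholds = CoverageThresholds(),
    full_gb: float = 30.0,
    seed: int = 0,
    reuse_alignments: bool = False,
) -> pd.DataFrame:
    """CpG counts at 1x and >=10x for the full library and nested subsamples.

    ``pairs`` are trimmed read pairs. By default every subsample is
    re-mapped; with ``reuse_alignments`` the full-data alignments are
    computed once and subsampled by pair identity (mapping is per-pair, so
    the two modes agree). Percentages are relative to the full-data row;
    ``gb_equivalent`` converts fractions to the lane-size proxy.
    """
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must be in (0, 1]")
    d_lo, d_hi = thresholds.depths[0], thresholds.depths[-1]

    full_alignments = map_pairs(pairs, index, mapper_config)
    by_id = {p.id: p for p in pairs}

    def counts_for(sub_pairs: Sequence[ReadPair]) -> Tuple[int, int]:
        if reuse_alignments:
            ids = {p.id for p in sub_pairs}
            alignments = [a for a in full_alignments if a.pair_id in ids]
        else:
            alignments = map_pairs(sub_pairs, index, mapper_config)
        table = call_methylation(alignments, by_id, genome)
        cov = count_cpg_coverage(table.merged_cpg_frame(), thresholds)
        return cov[d_lo], cov[d_hi]

    def pct(count: int, full: int) -> float:
        # a full dataset with no qualifying sites makes the ratio undefined
        return relative_coverage(count, full) if full > 0 else float("nan")

    full_lo, full_hi = counts_for(pairs)
    rows = [{
        "fraction": 1.0,
        "gb_equivalent": full_gb,
        "n_pairs": len(pairs),
        f"total_cpgs_{d_lo}x": full_lo,
        f"cpgs_ge{d_hi}x": full_hi,
        f"pct_{d_lo}x_of_full": 100.0,
        f"pct_ge{d_hi}x_of_full": 100.0,
    }]
    for f in sorted(fractions, reverse=True):
        if f == 1.0:
            continue
        sub = subsample_pairs(pairs, f, seed)
        lo, hi = counts_for(sub)
        rows.append({
            "fraction": f,
            "gb_equivalent": round(f * full_gb, 3),
            "n_pairs": len(sub),
            f"total_cpgs_{d_lo}x": lo,
            f"cpgs_ge{d_hi}x": hi,
            f"pct_{d_lo}x_of_full": pct(lo, full_lo),
            f"pct_ge{d_hi}x_of_full": pct(hi, full_hi),
        })
    return pd.DataFrame(rows)
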