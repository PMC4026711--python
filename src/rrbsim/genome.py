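"""Synthetic reference genomes, feature annotation and compartment methylomes.

A synthetic mammalian-like genome is assembled from three compartments:

* **background** — i.i.d. sequence at a configurable GC content, in which CpG
  dinucleotides occur at the rate implied by base composition alone;
* **CpG islands** — short CpG-dense intervals, most of which are placed so
  that they overlap gene promoters (the 2 kb region upstream of the TSS);
* **tandem repeats** — loci carrying several byte-identical copies of a
  repeat unit, which defeat unique read mapping by construction.

The matching methylome assigns every genomic cytosine (both strands) a
methylation probability: each CpG dinucleotide draws one Beta variate from
its compartment's distribution (islands hypomethylated, background and
repeats hypermethylated), shared by the two symmetric cytosines of the
dinucleotide; non-CpG cytosines get a single small constant probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PlacementError",
    "Interval",
    "GenomeConfig",
    "ReferenceGenome",
    "FeatureSet",
    "MethylomeParams",
    "Methylome",
    "simulate_genome",
    "simulate_methylome",
    "write_reference",
    "read_reference",
    "promoter_interval",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(x) for x in "ACGT")


class PlacementError(ValueError):
    """Raised when a feature cannot be placed on a chromosome."""


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "+"
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.name}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeConfig:
    """Parameters of the synthetic genome.

    ``island_cpg_density`` is the number of CpG dinucleotides deliberately
    planted per 100 bp of island sequence (the island backbone is generated
    CpG-free so the planted density is also the realised density, up to
    boundary effects).
    """

    chromosome_lengths: Sequence[int] = (60_000, 40_000)
    background_gc: float = 0.42
    n_islands: int = 20
    island_length_bp: int = 600
    island_cpg_density: float = 10.0  # CpGs per 100 bp
    island_gc: float = 0.60
    n_genes: int = 20
    gene_length_bp: int = 2_000
    repeat_unit_length_bp: int = 400
    repeat_copy_number: int = 5
    n_repeat_loci: int = 3
    island_promoter_fraction: float = 0.8
    promoter_length_bp: int = 2_000
    rng_seed: int = 0

    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(len(self.chromosome_lengths))]

    def validate(self) -> List[str]:
        errors: List[str] = []
        if not self.chromosome_lengths:
            errors.append("chromosome_lengths: at least one chromosome required")
        if any(l <= 0 for l in self.chromosome_lengths):
            errors.append("chromosome_lengths: all lengths must be positive")
        for name in (
            "n_islands",
            "island_length_bp",
            "n_genes",
            "gene_length_bp",
            "repeat_unit_length_bp",
            "repeat_copy_number",
            "n_repeat_loci",
            "promoter_length_bp",
        ):
            if getattr(self, name) < 0:
                errors.append(f"{name}: must be >= 0")
        for name in ("background_gc", "island_gc", "island_promoter_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                errors.append(f"{name}: must be in [0, 1]")
        if self.island_cpg_density < 0 or self.island_cpg_density > 50:
            errors.append("island_cpg_density: must be in [0, 50] CpGs per 100 bp")
        return errors


class ReferenceGenome:
    """Chromosome sequences over the {A, C, G, T} alphabet."""

    def __init__(self, sequences: Dict[str, str]):
        for name, seq in sequences.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"{name}: characters outside A/C/G/T")
        self.sequences: Dict[str, str] = dict(sequences)
        self._arrays: Dict[str, np.ndarray] = {}
        self._cpg: Dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def chrom_array(self, chrom: str) -> np.ndarray:
        """Sequence as a uint8 array of ASCII codes (cached)."""
        if chrom not in self._arrays:
            self._arrays[chrom] = np.frombuffer(
                self.sequences[chrom].encode(), dtype=np.uint8
            )
        return self._arrays[chrom]

    def cpg_positions(self, chrom: str) -> np.ndarray:
        """Sorted forward-strand positions p with sequence[p:p+2] == 'CG'."""
        if chrom not in self._cpg:
            a = self.chrom_array(chrom)
            self._cpg[chrom] = np.flatnonzero((a[:-1] == _C) & (a[1:] == _G))
        return self._cpg[chrom]

    def n_cpg_sites(self) -> int:
        return sum(len(self.cpg_positions(c)) for c in self.sequences)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ReferenceGenome) and self.sequences == other.sequences

    def __repr__(self) -> str:
        return f"ReferenceGenome({self.lengths})"


@dataclass(frozen=True)
class FeatureSet:
    """Gene, CpG-island and repeat annotation (0-based half-open)."""

    genes: Tuple[Interval, ...] = ()
    islands: Tuple[Interval, ...] = ()
    repeats: Tuple[Interval, ...] = ()

    def validate_against(self, genome: ReferenceGenome) -> None:
        for iv in (*self.genes, *self.islands, *self.repeats):
            if iv.chrom not in genome.sequences:
                raise ValueError(f"{iv.name}: unknown chromosome {iv.chrom}")
            if iv.end > len(genome.sequences[iv.chrom]):
                raise ValueError(f"{iv.name}: extends past end of {iv.chrom}")


@dataclass
class MethylomeParams:
    """Per-compartment Beta parameters for CpG methylation probabilities.

    A ``*_fixed`` level, when given, replaces the Beta draw by that constant
    (the degenerate point-mass case; Beta shapes are ignored for that
    compartment). ``non_cpg_methylation`` is the constant probability given
    to every cytosine outside a CpG context.
    """

    island_beta_shape1: float = 1.0
    island_beta_shape2: float = 9.0
    background_beta_shape1: float = 6.0
    background_beta_shape2: float = 2.0
    repeat_beta_shape1: float = 9.0
    repeat_beta_shape2: float = 1.0
    non_cpg_methylation: float = 0.005
    island_fixed: Optional[float] = None
    background_fixed: Optional[float] = None
    repeat_fixed: Optional[float] = None
    rng_seed: int = 0

    def validate(self) -> List[str]:
        errors: List[str] = []
        for name in (
            "island_beta_shape1", "island_beta_shape2",
            "background_beta_shape1", "background_beta_shape2",
            "repeat_beta_shape1", "repeat_beta_shape2",
        ):
            if getattr(self, name) <= 0:
                errors.append(f"{name}: Beta shapes must be > 0")
        if not 0.0 <= self.non_cpg_methylation <= 1.0:
            errors.append("non_cpg_methylation: must be in [0, 1]")
        for name in ("island_fixed", "background_fixed", "repeat_fixed"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                errors.append(f"{name}: must be in [0, 1]")
        return errors

    def compartment_mean(self, compartment: str) -> float:
        """Analytic mean methylation probability of a compartment."""
        fixed = getattr(self, f"{compartment}_fixed")
        if fixed is not None:
            return fixed
        a = getattr(self, f"{compartment}_beta_shape1")
        b = getattr(self, f"{compartment}_beta_shape2")
        return a / (a + b)

    def compartment_var(self, compartment: str) -> float:
        fixed = getattr(self, f"{compartment}_fixed")
        if fixed is not None:
            return 0.0
        a = getattr(self, f"{compartment}_beta_shape1")
        b = getattr(self, f"{compartment}_beta_shape2")
        return a * b / ((a + b) ** 2 * (a + b + 1))


class Methylome:
    """Per-cytosine methylation probabilities on both strands.

    ``prob_fwd[chrom][p]`` is the probability for the forward-strand cytosine
    at position ``p`` (NaN where the forward base is not C); ``prob_rev`` is
    the same for reverse-strand cytosines, i.e. forward-strand G positions.
    The two cytosines of one CpG dinucleotide carry the same probability.
    """

    def __init__(
        self,
        genome: ReferenceGenome,
        prob_fwd: Dict[str, np.ndarray],
        prob_rev: Dict[str, np.ndarray],
    ):
        self.genome = genome
        self.prob_fwd = prob_fwd
        self.prob_rev = prob_rev

    def context_fwd(self, chrom: str) -> np.ndarray:
        """True where the forward-strand C at p is in CpG context."""
        a = self.genome.chrom_array(chrom)
        ctx = np.zeros(len(a), dtype=bool)
        ctx[:-1] = (a[:-1] == _C) & (a[1:] == _G)
        return ctx

    def context_rev(self, chrom: str) -> np.ndarray:
        """True where the reverse-strand C (forward G) at p is in CpG context."""
        a = self.genome.chrom_array(chrom)
        ctx = np.zeros(len(a), dtype=bool)
        ctx[1:] = (a[:-1] == _C) & (a[1:] == _G)
        return ctx

    def truth_frame(self) -> pd.DataFrame:
        """One row per genomic cytosine: chrom, pos, strand, context, probability."""
        rows = []
        for chrom in self.genome.sequences:
            a = self.genome.chrom_array(chrom)
            for strand, probs, ctx in (
                ("+", self.prob_fwd[chrom], self.context_fwd(chrom)),
                ("-", self.prob_rev[chrom], self.context_rev(chrom)),
            ):
                pos = np.flatnonzero(~np.isnan(probs))
                rows.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "strand": strand,
                            "context": np.where(ctx[pos], "CpG", "non-CpG"),
                            "probability": probs[pos],
                        }
                    )
                )
        frame = pd.concat(rows, ignore_index=True)
        return frame.sort_values(["chrom", "pos", "strand"], ignore_index=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Methylome) or self.genome != other.genome:
            return False
        return all(
            np.array_equal(self.prob_fwd[c], other.prob_fwd[c], equal_nan=True)
            and np.array_equal(self.prob_rev[c], other.prob_rev[c], equal_nan=True)
            for c in self.genome.sequences
        )


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    return _BASES[rng.choice(4, size=length, p=_base_probs(gc))]

def _cpg_free_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """i.i.d. sequence with every C->G adjacency broken (left-to-right pass)."""
    seq = _random_sequence(rng, length, gc)
    # replacing an offending G with A or T can never create a new CpG
    for i in range(1, length):
        if seq[i] == _G and seq[i - 1] == _C:
            seq[i] = _A if rng.random() < 0.5 else _T
    return seq

def _island_sequence(rng: np.random.Generator, length: int, gc: float,
                     cpg_density: float) -> np.ndarray:
    seq = _cpg_free_sequence(rng, length, gc)
    n_plant = int(round(length * cpg_density / 100.0))
    slots = np.arange(0, length - 1, 2)
    n_plant = min(n_plant, len(slots))
    if n_plant:
        for p in rng.choice(slots, size=n_plant, replace=False):
            seq[p] = _C
            seq[p + 1] = _G
    return seq

def _overlaps(start: int, end: int, occupied: List[Tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in occupied)

def _place(
    rng: np.random.Generator,
    chrom_len: int,
    length: int,
    occupied: List[Tuple[int, int]],
    chrom: str,
    what: str,
) -> int:
    """Uniform draw over every start position that fits in a free gap."""
    if length > chrom_len:
        raise PlacementError(f"cannot place {what} of {length} bp on {chrom} ({chrom_len} bp)")
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(occupied):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    starts: List[Tuple[int, int]] = []  # (first feasible start, count)
    prev = 0
    for s, e in merged + [(chrom_len, chrom_len)]:
        if s - prev >= length:
            starts.append((prev, s - prev - length + 1))
        prev = max(prev, e)
    total = sum(n for _, n in starts)
    if total == 0:
        raise PlacementError(f"no room left for {what} on {chrom}")
    pick = int(rng.integers(0, total))
    for first, n in starts:
        if pick < n:
            return first + pick
        pick -= n
    raise AssertionError("unreachable")


def simulate_genome(config: GenomeConfig) -> Tuple[ReferenceGenome, FeatureSet]:
    """Generate a reproducible synthetic genome and its feature annotation.

    Islands and repeat loci overwrite background sequence and never overlap
    each other; genes are pure annotation over whatever sequence underlies
    them. A fraction of islands is anchored to gene promoters (immediately
    upstream of the TSS, strand-aware).
    """
    errors = config.validate()
    if errors:
        raise ValueError("; ".join(errors))
    rng = np.random.default_rng(config.rng_seed)
    names = config.chrom_names()
    lengths = dict(zip(names, config.chromosome_lengths))
    weights = np.array(config.chromosome_lengths, dtype=float)
    weights /= weights.sum()

    seqs = {c: _random_sequence(rng, lengths[c], config.background_gc) for c in names}
    # occupied intervals that carry non-background sequence (islands, repeats)
    seq_occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in names}
    gene_occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in names}

    genes: List[Interval] = []
    for i in range(config.n_genes):
        chrom = names[rng.choice(len(names), p=weights)]
        start = _place(rng, lengths[chrom], config.gene_length_bp,
                       gene_occupied[chrom], chrom, f"gene_{i}")
        gene_occupied[chrom].append((start, start + config.gene_length_bp))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Interval(chrom, start, start + config.gene_length_bp,
                              f"gene_{i}", strand))

    islands: List[Interval] = []
    n_at_promoters = min(config.n_islands, config.n_genes,
                         int(round(config.island_promoter_fraction * config.n_genes)))
    ilen = config.island_length_bp
    promoter_genes = (
        rng.choice(len(genes), size=n_at_promoters, replace=False) if n_at_promoters else []
    )
    for gi in promoter_genes:
        g = genes[int(gi)]
        L = lengths[g.chrom]
        if g.strand == "+":
            start = max(0, g.start - ilen)
        else:
            start = min(L, g.end + ilen) - ilen
        start = min(max(start, 0), L - ilen)
        if _overlaps(start, start + ilen, seq_occupied[g.chrom]):
            continue  # replaced by a random island below
        seq_occupied[g.chrom].append((start, start + ilen))
        islands.append(Interval(g.chrom, start, start + ilen, f"island_{len(islands)}"))
    while len(islands) < config.n_islands:
        chrom = names[rng.choice(len(names), p=weights)]
        start = _place(rng, lengths[chrom], ilen, seq_occupied[chrom], chrom,
                       f"island_{len(islands)}")
        seq_occupied[chrom].append((start, start + ilen))
        islands.append(Interval(chrom, start, start + ilen, f"island_{len(islands)}"))
    for iv in islands:
        seqs[iv.chrom][iv.start:iv.end] = _island_sequence(
            rng, iv.length, config.island_gc, config.island_cpg_density)

    repeats: List[Interval] = []
    locus_len = config.repeat_unit_length_bp * config.repeat_copy_number
    for r in range(config.n_repeat_loci):
        if locus_len == 0:
            break
        chrom = names[rng.choice(len(names), p=weights)]
        start = _place(rng, lengths[chrom], locus_len, seq_occupied[chrom],
                       chrom, f"repeat locus {r}")
        seq_occupied[chrom].append((start, start + locus_len))
        unit = _random_sequence(rng, config.repeat_unit_length_bp, config.background_gc)
        for k in range(config.repeat_copy_number):
            s = start + k * config.repeat_unit_length_bp
            seqs[chrom][s:s + config.repeat_unit_length_bp] = unit
            repeats.append(Interval(chrom, s, s + config.repeat_unit_length_bp,
                                    f"repeat_{r}_{k}", group=f"repeat_{r}"))

    genome = ReferenceGenome({c: seqs[c].tobytes().decode() for c in names})
    features = FeatureSet(tuple(genes), tuple(islands), tuple(repeats))
    features.validate_against(genome)
    return genome, features


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def compartment_labels(genome: ReferenceGenome, features: FeatureSet) -> Dict[str, np.ndarray]:
    """Per-position compartment: 0 background, 1 repeat, 2 island.

    Precedence when features overlap: island > repeat > background.
    """
    labels = {c: np.zeros(l, dtype=np.int8) for c, l in genome.lengths.items()}
    for iv in features.repeats:
        labels[iv.chrom][iv.start:iv.end] = 1
    for iv in features.islands:
        labels[iv.chrom][iv.start:iv.end] = 2
    return labels

_COMPARTMENTS = {0: "background", 1: "repeat", 2: "island"}


def simulate_methylome(
    genome: ReferenceGenome, features: FeatureSet, params: MethylomeParams
) -> Methylome:
    """Draw a ground-truth methylome from the compartment model."""
    errors = params.validate()
    if errors:
        raise ValueError("; ".join(errors))
    features.validate_against(genome)
    rng = np.random.default_rng(params.rng_seed)
    labels = compartment_labels(genome, features)

    prob_fwd: Dict[str, np.ndarray] = {}
    prob_rev: Dict[str, np.ndarray] = {}
    for chrom, seq in genome.sequences.items():
        a = genome.chrom_array(chrom)
        pf = np.full(len(a), np.nan)
        pr = np.full(len(a), np.nan)
        pf[a == _C] = params.non_cpg_methylation
        pr[a == _G] = params.non_cpg_methylation
        cpg = genome.cpg_positions(chrom)
        comp = labels[chrom][cpg]
        draws = np.empty(len(cpg))
        for code, name in _COMPARTMENTS.items():
            mask = comp == code
            if not mask.any():
                continue
            fixed = getattr(params, f"{name}_fixed")
            if fixed is not None:
                draws[mask] = fixed
            else:
                draws[mask] = rng.beta(
                    getattr(params, f"{name}_beta_shape1"),
                    getattr(params, f"{name}_beta_shape2"),
                    size=int(mask.sum()),
                )
        pf[cpg] = draws          # forward-strand C of the dinucleotide
        pr[cpg + 1] = draws      # symmetric reverse-strand C (forward G)
        prob_fwd[chrom] = pf
        prob_rev[chrom] = pr
    return Methylome(genome, prob_fwd, prob_rev)


def promoter_interval(gene: Interval, chrom_length: int,
                      promoter_length_bp: int = 2_000) -> Optional[Interval]:
    """The promoter of a gene: promoter_length_bp immediately upstream of the
    TSS on the gene's strand, clipped at chromosome ends (None if empty)."""
    if gene.strand == "+":
        start, end = max(0, gene.start - promoter_length_bp), gene.start
    else:
        start, end = gene.end, min(chrom_length, gene.end + promoter_length_bp)
    if start >= end:
        return None
    return Interval(gene.chrom, start, end, f"{gene.name}_promoter", gene.strand)


# ---------------------------------------------------------------------------
# reference I/O (FASTA + BED + truth TSV)
# ---------------------------------------------------------------------------

_FASTA_WIDTH = 60


def write_reference(
    genome: ReferenceGenome,
    features: FeatureSet,
    methylome: Methylome,
    output_dir: str | Path,
) -> Dict[str, Path]:
    """Write genome FASTA, feature BED files and the methylome truth TSV.

    Round-trips losslessly through :func:`read_reference`.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "genes": out / "genes.bed",
        "islands": out / "islands.bed",
        "repeats": out / "repeats.bed",
        "methylome": out / "methylome_truth.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), _FASTA_WIDTH):
                fh.write(seq[i:i + _FASTA_WIDTH] + "\n")
    with open(paths["genes"], "w") as fh:
        for g in features.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
    with open(paths["islands"], "w") as fh:
        for iv in features.islands:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
    with open(paths["repeats"], "w") as fh:
        for iv in features.repeats:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t+\t{iv.group}\n")
    truth = methylome.truth_frame()
    with open(paths["methylome"], "w") as fh:
        fh.write("#chrom\tpos\tstrand\tcontext\tprobability\n")
        truth.to_csv(fh, sep="\t", header=False, index=False, float_format="%.17g")
    return paths


def read_reference(output_dir: str | Path) -> Tuple[ReferenceGenome, FeatureSet, Methylome]:
    """Read back what :func:`write_reference` wrote."""
    out = Path(output_dir)
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(out / "genome.fa"), "fasta")
    }
    genome = ReferenceGenome(sequences)

    genes, islands, repeats = [], [], []
    genes_path = out / "genes.bed"
    if genes_path.stat().st_size:
        for line in genes_path.read_text().splitlines():
            c, s, e, n, _score, strand = line.split("\t")
            genes.append(Interval(c, int(s), int(e), n, strand))
    islands_path = out / "islands.bed"
    if islands_path.stat().st_size:
        for line in islands_path.read_text().splitlines():
            c, s, e, n = line.split("\t")
            islands.append(Interval(c, int(s), int(e), n))
    repeats_path = out / "repeats.bed"
    if repeats_path.stat().st_size:
        for line in repeats_path.read_text().splitlines():
            c, s, e, n, _score, strand, group = line.split("\t")
            repeats.append(Interval(c, int(s), int(e), n, strand, group))
    features = FeatureSet(tuple(genes), tuple(islands), tuple(repeats))

    prob_fwd = {c: np.full(l, np.nan) for c, l in genome.lengths.items()}
    prob_rev = {c: np.full(l, np.nan) for c, l in genome.lengths.items()}
    truth = pd.read_csv(out / "methylome_truth.tsv", sep="\t", comment="#",
                        names=["chrom", "pos", "strand", "context", "probability"],
                        float_precision="round_trip")
    for (chrom, strand), grp in truth.groupby(["chrom", "strand"]):
        target = prob_fwd if strand == "+" else prob_rev
        target[chrom][grp["pos"].to_numpy()] = grp["probability"].to_numpy()
    return genome, features, Methylome(genome, prob_fwd, prob_rev)
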