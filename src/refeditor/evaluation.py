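"""Evaluation statistics for comparing read-mapping strategies.

Implements the metrics used to benchmark variant-aware mapping:
unique-mapping rate at a mismatch threshold, mean mapped depth
stratified by gold genotype class, genotype concordance on the gold
non-ref/ref subset, trio Mendelian inconsistency, SNP detection rate,
and minor-allele-frequency stratification.

Genotypes are handled as class labels over a biallelic model:
'ref/ref', 'het', 'alt/alt', plus 'no-call' / 'no-gold' for absent
entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AlignmentRecord, ReferenceGenome

logger = logging.getLogger(__name__)

GOLD_CLASSES = ("ref/ref", "het", "alt/alt", "no-gold")
CALL_CLASSES = ("ref/ref", "het", "alt/alt", "no-call")

Locus = tuple[str, int]


# ---------------------------------------------------------------------------
# Mapping rate
# ---------------------------------------------------------------------------


def mapping_rate(
    hits_per_read: list[list[int]], max_mm: int
) -> tuple[int, float]:
    """Unique-mapping rate: a read counts as successfully mapped iff it
    has exactly one placement with distance <= max_mm.

    ``hits_per_read`` holds, per read, the mismatch distances of its
    distinct candidate loci (from the oracle mapper or from a converted
    SAM's collapsed locus sets).
    """
    n_unique = sum(
        1 for hits in hits_per_read
        if sum(1 for d in hits if d <= max_mm) == 1
    )
    rate = n_unique / len(hits_per_read) if hits_per_read else 0.0
    return n_unique, rate


# ---------------------------------------------------------------------------
# Depth by genotype class
# ---------------------------------------------------------------------------


def depth_by_class(
    alignments: list[AlignmentRecord],
    gold_genotypes: dict[Locus, str],
    genome: ReferenceGenome,
) -> dict[str, float]:
    """Mean mapped depth (MAPQ > 0 reads) at loci of each gold class."""
    depth = {name: np.zeros(length, dtype=np.int32)
             for name, length in genome.lengths.items()}
    for rec in alignments:
        if rec.is_unmapped or rec.mapq <= 0 or rec.is_secondary:
            continue
        if rec.rname in depth:
            depth[rec.rname][rec.pos:rec.reference_end] += 1
    sums = {c: 0.0 for c in ("ref/ref", "het", "alt/alt")}
    counts = {c: 0 for c in sums}
    for (chrom, pos), cls in gold_genotypes.items():
        if cls not in sums or chrom not in depth:
            continue
        sums[cls] += int(depth[chrom][pos])
        counts[cls] += 1
    return {c: (sums[c] / counts[c] if counts[c] else 0.0) for c in sums}


# ---------------------------------------------------------------------------
# Genotype concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceBreakdown:
    """4x4 gold-class x called-class contingency table.

    The headline concordance follows the usual comparison-on-called-
    subset convention: among gold non-ref/ref loci at which the caller
    emitted *some* genotype, the fraction called identically.
    ``completeness`` reports the fraction of gold non-ref/ref loci that
    received any call, so a caller cannot look good by staying silent.
    """

    table: dict[tuple[str, str], int] = field(default_factory=dict)

    def count(self, gold: str, called: str) -> int:
        return self.table.get((gold, called), 0)

    def add(self, gold: str, called: str) -> None:
        self.table[(gold, called)] = self.table.get((gold, called), 0) + 1

    @property
    def total(self) -> int:
        return sum(self.table.values())

    @property
    def concordance(self) -> float:
        agree = self.count("het", "het") + self.count("alt/alt", "alt/alt")
        called = sum(
            self.count(g, c)
            for g in ("het", "alt/alt")
            for c in ("ref/ref", "het", "alt/alt")
        )
        return agree / called if called else 0.0

    @property
    def completeness(self) -> float:
        nonref = sum(self.count(g, c)
                     for g in ("het", "alt/alt") for c in CALL_CLASSES)
        called = sum(
            self.count(g, c)
            for g in ("het", "alt/alt")
            for c in ("ref/ref", "het", "alt/alt")
        )
        return called / nonref if nonref else 0.0


def concordance(
    calls: dict[Locus, str], gold: dict[Locus, str]
) -> ConcordanceBreakdown:
    """Tabulate called vs gold genotype classes over all gold loci and
    all additionally-called loci. Gold no-call loci cannot be scored and
    are excluded from every denominator."""
    breakdown = ConcordanceBreakdown()
    for locus, gold_class in gold.items():
        breakdown.add(gold_class, calls.get(locus, "no-call"))
    for locus, call_class in calls.items():
        if locus not in gold:
            breakdown.add("no-gold", call_class)
    return breakdown


def detection_rate(calls: dict[Locus, str], gold: dict[Locus, str]) -> float:
    """Of all gold non-ref/ref loci, the fraction where the call set
    also reports a non-ref/ref genotype."""
    nonref = [locus for locus, cls in gold.items()
              if cls in ("het", "alt/alt")]
    if not nonref:
        return 0.0
    found = sum(
        1 for locus in nonref if calls.get(locus) in ("het", "alt/alt"))
    return found / len(nonref)


# ---------------------------------------------------------------------------
# Mendelian inconsistency
# ---------------------------------------------------------------------------

_GT_ALLELES = {"ref/ref": (0, 0), "het": (0, 1), "alt/alt": (1, 1)}


@dataclass
class TrioCallSet:
    """Per-locus genotype classes for mother, father and child."""

    mother: dict[Locus, str]
    father: dict[Locus, str]
    child: dict[Locus, str]


def mendelian_inconsistency(trio: TrioCallSet) -> tuple[int, int, float]:
    """(n_assessed, n_errors, rate) over biallelic loci.

    Denominator: loci called in all three individuals where not all
    three genotypes are homozygous. A locus is an error iff no pairing
    of one maternal with one paternal allele reproduces the child's
    (unordered) genotype.
    """
    n_assessed = 0
    n_errors = 0
    shared = set(trio.mother) & set(trio.father) & set(trio.child)
    for locus in shared:
        gm = trio.mother[locus]
        gf = trio.father[locus]
        gc = trio.child[locus]
        if any(g not in _GT_ALLELES for g in (gm, gf, gc)):
            continue  # no-calls / multi-allelic excluded
        if all(g in ("ref/ref", "alt/alt") for g in (gm, gf, gc)):
            continue  # all-homozygous loci carry no phase information
        n_assessed += 1
        child_alleles = _GT_ALLELES[gc]
        possible = {
            tuple(sorted((a, b)))
            for a in _GT_ALLELES[gm]
            for b in _GT_ALLELES[gf]
        }
        if child_alleles not in possible:
            n_errors += 1
    rate = n_errors / n_assessed if n_assessed else 0.0
    return n_assessed, n_errors, rate


# ---------------------------------------------------------------------------
# MAF stratification
# ---------------------------------------------------------------------------


@dataclass
class MafBin:
    label: str
    loci: list[Locus] = field(default_factory=list)


MAF_BIN_EDGES = (
    ("MAF <= 1%", 0.0, 0.01),
    ("1% < MAF <= 5%", 0.01, 0.05),
    ("MAF > 5%", 0.05, 0.5),
)


def stratify_by_maf(
    loci: list[Locus], maf: dict[Locus, float]
) -> list[MafBin]:
    """Partition loci into the three conventional MAF bins, boundaries
    inclusive on the right: (0, 0.01], (0.01, 0.05], (0.05, 0.5]."""
    bins = [MafBin(label) for label, _, _ in MAF_BIN_EDGES]
    for locus in loci:
        if locus not in maf:
            continue
        f = maf[locus]
        if not 0 <= f <= 0.5:
            raise ValueError(f"MAF {f} outside [0, 0.5] at {locus}")
        for b, (_, low, high) in zip(bins, MAF_BIN_EDGES):
            if low < f <= high or (f == 0 and low == 0.0):
                b.loci.append(locus)
                break
    return bins
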