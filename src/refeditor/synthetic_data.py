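"""Synthetic genomes, diploid individuals, trios, reads and test oracles.

Everything the construct -> map -> convert -> call loop needs at desk
scale, with no external tools: a random genome generator, a diploid
individual sampler (SNPs and 1-3 bp indels, per-haplotype allele
assignment), Mendelian child sampling, an error-bearing read simulator
that records each read's true universal coordinate, an exhaustive
Hamming-distance mapper used as the mapping oracle, and a minimal
pileup genotype caller standing in for a production caller.

The oracle mapper is deliberately ungapped: exhaustive enumeration over
every position of both strands makes "unique mapping with at most t
mismatches" a provable property rather than an aligner heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    FLAG_REVERSE,
    FLAG_UNMAPPED,
    AlignmentRecord,
    ReferenceGenome,
    VariantRecord,
    XaHit,
    format_xa,
    revcomp,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Genome and individual generation
# ---------------------------------------------------------------------------


def generate_genome(
    n_chroms: int, lengths: list[int], gc: float = 0.5, seed: int = 0
) -> ReferenceGenome:
    """Random genome with i.i.d. bases; P(G) + P(C) = gc."""
    if len(lengths) != n_chroms:
        raise ValueError("lengths must have one entry per chromosome")
    if any(l < 1 for l in lengths):
        raise ValueError("chromosome lengths must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms = []
    for i, length in enumerate(lengths):
        draw = rng.choice(4, size=length, p=p)
        seq = "".join(_BASES[c] for c in draw)
        chroms.append((f"chr{i + 1}", seq))
    return ReferenceGenome(chroms)


@dataclass
class SimulatedIndividual:
    """A diploid individual: variants, phased haplotypes, truth tables.

    ``hap_alleles`` fixes which haplotype carries which allele at every
    variant locus; ``univ_of_hap`` maps each haplotype position to the
    universal coordinate of the reference base it aligns to (bases inside
    insertions map to the next reference-consuming position).
    """

    genome: ReferenceGenome
    variants: list[VariantRecord]
    hap_alleles: dict[tuple[str, int], tuple[int, int]]
    haplotypes: dict[str, tuple[str, str]] = field(default_factory=dict)
    univ_of_hap: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)

    def __post_init__(self):
        if not self.haplotypes:
            self._build_haplotypes()

    def _build_haplotypes(self) -> None:
        by_chrom: dict[str, list[VariantRecord]] = {}
        for v in self.variants:
            by_chrom.setdefault(v.chrom, []).append(v)
        for name, seq in self.genome.chromosomes:
            haps, maps = [], []
            for h in (0, 1):
                pieces: list[str] = []
                coords: list[np.ndarray] = []
                cursor = 0
                for v in sorted(by_chrom.get(name, []), key=lambda v: v.pos):
                    allele = self.hap_alleles[(name, v.pos)][h]
                    if allele == 0:
                        continue
                    alt = v.allele(allele)
                    pieces.append(seq[cursor:v.pos])
                    coords.append(np.arange(cursor, v.pos))
                    pieces.append(alt)
                    # alt bases map positionally onto the ref footprint;
                    # extra (inserted) bases map to the next ref position
                    span = np.minimum(
                        v.pos + np.arange(len(alt)), v.pos_end)
                    coords.append(span)
                    cursor = v.pos_end
                pieces.append(seq[cursor:])
                coords.append(np.arange(cursor, len(seq)))
                haps.append("".join(pieces))
                maps.append(np.concatenate(coords)
                            if coords else np.arange(len(seq)))
            self.haplotypes[name] = (haps[0], haps[1])
            self.univ_of_hap[name] = (maps[0], maps[1])

    @property
    def truth_genotypes(self) -> dict[tuple[str, int], str]:
        """Locus -> genotype class ('het' / 'alt/alt'; hom-ref loci are
        simply absent)."""
        out = {}
        for v in self.variants:
            if v.is_hom_ref:
                out[(v.chrom, v.pos)] = "ref/ref"
            elif v.is_het:
                out[(v.chrom, v.pos)] = "het"
            else:
                out[(v.chrom, v.pos)] = "alt/alt"
        return out

    @property
    def snp_truth_genotypes(self) -> dict[tuple[str, int], str]:
        """Truth classes at SNP loci only — the subset genotype-level
        evaluations score, since the pileup caller (like SNP-filtered
        production call sets) emits substitution genotypes."""
        snp_loci = {(v.chrom, v.pos) for v in self.variants if v.is_snp}
        return {k: v for k, v in self.truth_genotypes.items()
                if k in snp_loci}


def sample_individual(
    genome: ReferenceGenome,
    snp_rate: float = 0.01,
    indel_rate: float = 0.0,
    het_fraction: float = 0.6,
    seed: int = 0,
    min_spacing: int = 0,
) -> SimulatedIndividual:
    """Draw a diploid individual from the universal genome.

    Variant positions are Bernoulli draws per base (snp_rate for SNPs,
    indel_rate for 1-3 bp insertions/deletions); each variant is het
    with probability het_fraction and hom-alt otherwise. Variants never
    overlap; ``min_spacing`` optionally enforces a minimum distance
    between consecutive variant start positions.
    """
    for r in (snp_rate, indel_rate, het_fraction):
        if not 0 <= r <= 1:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    variants: list[VariantRecord] = []
    hap_alleles: dict[tuple[str, int], tuple[int, int]] = {}
    for name, seq in genome.chromosomes:
        length = len(seq)
        n_snps = rng.binomial(length, snp_rate)
        n_indels = rng.binomial(length, indel_rate)
        # leave room for deletion footprints and the VCF anchor base
        positions = rng.choice(max(1, length - 6), size=n_snps + n_indels,
                               replace=False)
        positions.sort()
        kinds = np.array([0] * n_snps + [1] * n_indels)
        rng.shuffle(kinds)
        occupied_until = -1
        for pos, kind in zip(positions, kinds):
            pos = int(pos)
            if pos <= occupied_until + min_spacing:
                continue
            ref_base = seq[pos]
            if ref_base == "N":
                continue
            if kind == 0:
                others = [b for b in _BASES if b != ref_base]
                alt = others[rng.integers(3)]
                ref = ref_base
            else:
                size = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # insertion after anchor base
                    ins = "".join(_BASES[rng.integers(4)]
                                  for _ in range(size))
                    ref, alt = ref_base, ref_base + ins
                else:  # deletion of `size` bases after anchor
                    ref = seq[pos:pos + 1 + size]
                    alt = ref_base
                    if len(ref) < 1 + size or "N" in ref:
                        continue
            is_het = rng.random() < het_fraction
            if is_het:
                alleles = (0, 1) if rng.random() < 0.5 else (1, 0)
                genotype = (0, 1)
            else:
                alleles = (1, 1)
                genotype = (1, 1)
            variants.append(VariantRecord(name, pos, ref, (alt,), genotype))
            hap_alleles[(name, pos)] = alleles
            occupied_until = pos + len(ref) - 1
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return SimulatedIndividual(genome, variants, hap_alleles)


def sample_child(
    mother: SimulatedIndividual, father: SimulatedIndividual, seed: int = 0
) -> SimulatedIndividual:
    """Mendelian child: one allele drawn uniformly from each parent's
    genotype at every variant locus of either parent.

    Loci private to one parent are treated as hom-ref in the other. The
    resulting trio is Mendelian-consistent by construction.
    """
    if mother.genome.chromosomes != father.genome.chromosomes:
        raise ValueError("parents must share a universal genome")
    rng = np.random.default_rng(seed)
    m_by = {(v.chrom, v.pos): v for v in mother.variants}
    f_by = {(v.chrom, v.pos): v for v in father.variants}
    loci = sorted(set(m_by) | set(f_by))
    variants: list[VariantRecord] = []
    hap_alleles: dict[tuple[str, int], tuple[int, int]] = {}
    occupied: dict[str, int] = {}
    for key in loci:
        chrom, pos = key
        mv, fv = m_by.get(key), f_by.get(key)
        template = mv or fv
        if mv and fv and (mv.ref_allele, mv.alt_alleles) != (
                fv.ref_allele, fv.alt_alleles):
            logger.warning("sample_child: allele conflict at %s:%d skipped",
                           chrom, pos)
            continue
        if pos <= occupied.get(chrom, -1):
            continue
        from_mother = (int(mv.genotype[rng.integers(2)]) if mv else 0)
        from_father = (int(fv.genotype[rng.integers(2)]) if fv else 0)
        genotype = tuple(sorted((from_mother, from_father)))
        variants.append(VariantRecord(
            chrom, pos, template.ref_allele, template.alt_alleles, genotype))
        hap_alleles[key] = (from_mother, from_father)
        occupied[chrom] = pos + len(template.ref_allele) - 1
    return SimulatedIndividual(mother.genome, variants, hap_alleles)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read plus its ground truth."""

    id: str
    sequence: str
    qualities: str
    chrom: str
    haplotype: int
    univ_start: int     # universal coordinate of the leftmost aligned base
    strand: str
    error_offsets: tuple[int, ...]   # offsets on the forward-strand segment


def simulate_reads(
    individual: SimulatedIndividual,
    k: int = 36,
    coverage: float = 4.0,
    error_rate: float = 0.0,
    rev_fraction: float = 0.5,
    seed: int = 0,
    base_quality: int = 30,
) -> list[SimulatedRead]:
    """Uniform single-end reads off both haplotypes.

    Read count = round(coverage * universal genome length / k). Each
    read picks a haplotype uniformly, a chromosome proportional to its
    haplotype length, and a uniform start. Substitution errors are
    i.i.d. per base at ``error_rate`` (never producing N); a
    ``rev_fraction`` share is reverse-complemented. The truth record
    keeps the universal coordinate of the read's leftmost aligned base.
    """
    rng = np.random.default_rng(seed)
    genome_len = individual.genome.total_length
    n_reads = int(round(coverage * genome_len / k))
    names = individual.genome.names
    qual_str = chr(base_quality + 33) * k
    reads: list[SimulatedRead] = []
    hap_lens = {
        name: (len(individual.haplotypes[name][0]),
               len(individual.haplotypes[name][1]))
        for name in names
    }
    for i in range(n_reads):
        hap = int(rng.integers(2))
        weights = np.array([hap_lens[n][hap] for n in names], dtype=float)
        chrom = names[rng.choice(len(names), p=weights / weights.sum())] \
            if len(names) > 1 else names[0]
        hap_seq = individual.haplotypes[chrom][hap]
        if len(hap_seq) < k:
            raise ValueError(f"read length {k} exceeds haplotype length")
        start = int(rng.integers(len(hap_seq) - k + 1))
        segment = hap_seq[start:start + k]
        errors = np.flatnonzero(rng.random(k) < error_rate)
        if len(errors):
            bases = list(segment)
            for off in errors:
                current = bases[off]
                choicepool = [b for b in _BASES if b != current]
                bases[off] = choicepool[rng.integers(3)]
            segment = "".join(bases)
        strand = "-" if rng.random() < rev_fraction else "+"
        seq = revcomp(segment) if strand == "-" else segment
        univ_start = int(individual.univ_of_hap[chrom][hap][start])
        reads.append(SimulatedRead(
            id=f"read{i}", sequence=seq, qualities=qual_str, chrom=chrom,
            haplotype=hap, univ_start=univ_start, strand=strand,
            error_offsets=tuple(int(e) for e in errors),
        ))
    return reads


# ---------------------------------------------------------------------------
# Oracle mapper
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OracleHit:
    chrom: str
    pos: int
    strand: str
    distance: int


class OracleMapper:
    """Exhaustive ungapped mapper: Hamming distance of the read against
    every position of both strands of every chromosome.

    N in the reference never matches any read base, so reads straddling
    the m+1-long N separators of an augmented genome cannot place there
    with <= m mismatches.
    """

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self._encoded = {name: _encode(seq)
                         for name, seq in genome.chromosomes}

    def map(self, read: str, max_mm: int) -> list[OracleHit]:
        read = read.upper()
        k = len(read)
        hits: list[OracleHit] = []
        n_code = ord("N")
        for strand, query in (("+", read), ("-", revcomp(read))):
            q = _encode(query)
            for name, arr in self._encoded.items():
                n_pos = len(arr) - k + 1
                if n_pos <= 0:
                    continue
                counts = np.zeros(n_pos, dtype=np.int32)
                for j in range(k):
                    window = arr[j:j + n_pos]
                    # reference N never matches anything, including N
                    counts += (window != q[j]) | (window == n_code)
                for pos in np.flatnonzero(counts <= max_mm):
                    hits.append(OracleHit(name, int(pos), strand,
                                          int(counts[pos])))
        hits.sort(key=lambda h: (h.distance, h.chrom, h.pos, h.strand))
        return hits


def oracle_map(read: str, genome: ReferenceGenome,
               max_mm: int) -> list[OracleHit]:
    """Convenience one-shot wrapper around :class:`OracleMapper`."""
    return OracleMapper(genome).map(read, max_mm)


def hits_to_sam_record(
    read_id: str, seq: str, qual: str, hits: list[OracleHit],
    unique_mapq: int = 37, max_xa: int = 20,
) -> AlignmentRecord:
    """Render oracle hits as one SAM record (best hit primary, others in
    XA), matching the reporting convention of short-read aligners."""
    k = len(seq)
    if not hits:
        return AlignmentRecord(
            qname=read_id, flag=FLAG_UNMAPPED, rname="*", pos=-1, mapq=0,
            cigar=[], seq=seq, qual=qual,
        )
    best = hits[0]
    flag = FLAG_REVERSE if best.strand == "-" else 0
    stored_seq = revcomp(seq) if best.strand == "-" else seq
    stored_qual = qual[::-1] if best.strand == "-" else qual
    mapq = unique_mapq if len(hits) == 1 else 0
    rec = AlignmentRecord(
        qname=read_id, flag=flag, rname=best.chrom, pos=best.pos, mapq=mapq,
        cigar=[("M", k)], seq=stored_seq, qual=stored_qual,
    )
    rec.set_tag("NM", "i", best.distance)
    if len(hits) > 1:
        rec.set_tag("XA", "Z", format_xa([
            XaHit(h.chrom, h.pos, h.strand, f"{k}M", h.distance)
            for h in hits[1:1 + max_xa]
        ]))
    return rec


# ---------------------------------------------------------------------------
# Naive pileup caller
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCall:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str | None
    genotype: str  # 'ref/ref' | 'het' | 'alt/alt'
    depth: int


def naive_call(
    records: list[AlignmentRecord],
    genome: ReferenceGenome,
    min_depth: int = 2,
    min_baseq: int = 13,
    het_band: float = 0.2,
) -> list[GenotypeCall]:
    """Minimal pileup genotyper over alignments in universal coordinates.

    Counts bases with quality >= min_baseq from reads with MAPQ > 0,
    walking each record's CIGAR. Positions with depth < min_depth are
    not called. With alt fraction f (top non-reference base over counted
    depth): f >= 1 - het_band -> alt/alt; het_band <= f < 1 - het_band
    -> het; otherwise ref/ref.
    """
    counts: dict[str, np.ndarray] = {
        name: np.zeros((4, length), dtype=np.int32)
        for name, length in genome.lengths.items()
    }
    for rec in records:
        if rec.is_unmapped or rec.mapq <= 0 or rec.is_secondary:
            continue
        if rec.rname not in counts:
            continue
        mat = counts[rec.rname]
        quals = rec.base_qualities()
        qpos, rpos = 0, rec.pos
        for op, n in rec.cigar:
            if op in "M=X":
                for i in range(n):
                    base = rec.seq[qpos + i]
                    if base in _BASE_TO_CODE and base != "N" \
                            and quals[qpos + i] >= min_baseq:
                        mat[_BASE_TO_CODE[base], rpos + i] += 1
                qpos += n
                rpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n
    calls: list[GenotypeCall] = []
    for name, seq in genome.chromosomes:
        mat = counts[name]
        depth = mat.sum(axis=0)
        for pos in np.flatnonzero(depth >= min_depth):
            pos = int(pos)
            ref_base = seq[pos]
            if ref_base == "N":
                continue
            ref_code = _BASE_TO_CODE[ref_base]
            col = mat[:, pos]
            alt_code = int(np.argmax(
                [c if i != ref_code else -1 for i, c in enumerate(col)]))
            total = int(depth[pos])
            f = col[alt_code] / total
            if f >= 1 - het_band:
                genotype, alt = "alt/alt", _BASES[alt_code]
            elif f >= het_band:
                genotype, alt = "het", _BASES[alt_code]
            else:
                genotype, alt = "ref/ref", None
            calls.append(GenotypeCall(name, pos, ref_base, alt, genotype,
                                      total))
    return calls
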