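"""Build a personalized diploid reference from a haploid genome + genotypes.

The construction follows four rules:

* homozygous-reference genotypes are ignored;
* homozygous-alternative SNPs are edited in place on the chromosome
  backbone (so backbone coordinates stay identical to the universal
  reference);
* heterozygous variants and all indels are represented as appended
  "mini chromosomes": short windows of the (edited) backbone carrying
  the alternative alleles, wide enough that any read of length k
  overlapping the variant fits entirely inside the window;
* nearby variants (reference distance < k + m, where m is the maximum
  indel length tolerated in mapping) are clustered and every non-reference
  haplotype combination over the cluster gets its own mini chromosome,
  since a single read can span several of them.

Minis are appended to their parent chromosome (keeping its name, so
paired-end mapping still sees one reference sequence per chromosome)
behind an N-run of length m + 1 which no read can cross with <= m
mismatches. An auxiliary map records every edit and mini placement for
the liftback step.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .io_formats import AuxMap, AuxMini, ReferenceGenome, VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BuildParameters:
    """Construction parameters.

    k        read length (bp)
    m        maximum allowed indel length during mapping
    w        mini-chromosome width; default 2k - 1 + 2m, the narrowest
             width that still captures every read overlapping the variant
             after up to m indel slippage (hard floor 2k - 1)
    sex      'female' drops chrY from the output genome
    max_cluster_hets  cap on per-cluster haplotype enumeration; denser
             clusters fall back to one mini per variant
    """

    k: int
    m: int = 0
    w: int | None = None
    sex: str = "unspecified"
    max_cluster_hets: int = 8

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("read length k must be >= 1")
        if self.m < 0:
            raise ValueError("max indel length m must be >= 0")
        if self.sex not in ("male", "female", "unspecified"):
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.w is None:
            object.__setattr__(self, "w", 2 * self.k - 1 + 2 * self.m)
        if self.w < 2 * self.k - 1:
            raise ValueError(f"w={self.w} below hard floor 2k-1={2*self.k-1}")

    @property
    def flank(self) -> int:
        """Bases of backbone context on each side of a cluster span."""
        return (self.w - 1) // 2

    @property
    def cluster_distance(self) -> int:
        """Variants closer than this (strict) share a cluster."""
        return self.k + self.m


@dataclass(frozen=True)
class VariantCluster:
    """Maximal run of mini-bound variants each < k+m from the next."""

    chrom: str
    variants: tuple[VariantRecord, ...]

    @property
    def span(self) -> tuple[int, int]:
        return self.variants[0].pos, self.variants[-1].pos_end


# A haplotype combination: one allele index per cluster variant.
HaplotypeCombo = tuple[int, ...]


@dataclass
class MiniChromosome:
    """One appended alt-allele segment, before/after placement."""

    parent_chrom: str
    univ_start: int
    univ_end: int
    combo: HaplotypeCombo
    sequence: str
    # (pos0, ref, alt) for each non-reference allele in the combo
    variant_edits: tuple[tuple[int, str, str], ...]
    aug_start: int = -1
    aug_end: int = -1

    def to_aux(self) -> AuxMini:
        return AuxMini(
            chrom=self.parent_chrom, aug_start=self.aug_start,
            aug_end=self.aug_end, univ_start=self.univ_start,
            variant_edits=self.variant_edits,
        )


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def classify_variants(
    variants: list[VariantRecord], params: BuildParameters
) -> tuple[list[VariantRecord], list[VariantRecord], list[VariantRecord]]:
    """Split genotyped variants into (skips, backbone_edits, mini_variants).

    Hom-ref genotypes need no action. Hom-alt SNPs become in-place
    backbone substitutions. Everything else that carries an alternative
    allele — het variants of any type, and all indels (a hom-alt indel
    edited in place would shift every downstream coordinate) — is routed
    to mini-chromosome construction.
    """
    skips: list[VariantRecord] = []
    backbone: list[VariantRecord] = []
    minis: list[VariantRecord] = []
    last_at: dict[tuple[str, int], VariantRecord] = {}
    for v in variants:
        key = (v.chrom, v.pos)
        if key in last_at:
            prev = last_at[key]
            if (prev.ref_allele, prev.alt_alleles, prev.genotype) != (
                    v.ref_allele, v.alt_alleles, v.genotype):
                raise ValueError(
                    f"conflicting variants at {v.chrom}:{v.pos}")
            continue
        last_at[key] = v
        if v.is_hom_ref:
            skips.append(v)
        elif v.is_hom_alt and v.is_snp:
            backbone.append(v)
        else:
            minis.append(v)
    logger.info(
        "classify_variants: %d skipped (hom-ref), %d backbone edits, "
        "%d mini-bound", len(skips), len(backbone), len(minis)
    )
    return skips, backbone, minis


def apply_backbone_edits(
    genome: ReferenceGenome, backbone_edits: list[VariantRecord]
) -> ReferenceGenome:
    """Substitute hom-alt SNP alleles in place; lengths are unchanged."""
    seqs = {name: seq for name, seq in genome.chromosomes}
    arrays: dict[str, list[str]] = {}
    for v in backbone_edits:
        alt = v.allele(v.genotype[0])
        if len(v.ref_allele) != 1 or len(alt) != 1:
            raise ValueError(
                f"backbone edit at {v.chrom}:{v.pos} is not a SNP")
        if v.chrom not in arrays:
            arrays[v.chrom] = list(seqs[v.chrom])
        if arrays[v.chrom][v.pos] != v.ref_allele:
            raise ValueError(
                f"ref mismatch at {v.chrom}:{v.pos}: expected "
                f"{v.ref_allele}, found {arrays[v.chrom][v.pos]}"
            )
        arrays[v.chrom][v.pos] = alt
    return ReferenceGenome([
        (name, "".join(arrays[name]) if name in arrays else seq)
        for name, seq in genome.chromosomes
    ])


def cluster_mini_variants(
    mini_variants: list[VariantRecord], params: BuildParameters
) -> list[VariantCluster]:
    """Single-linkage chaining: adjacent variants with reference-position
    distance < k + m join one cluster; clusters are maximal."""
    clusters: list[VariantCluster] = []
    current: list[VariantRecord] = []
    for v in sorted(mini_variants, key=lambda v: (v.chrom, v.pos)):
        if current and (
            v.chrom != current[-1].chrom
            or v.pos - current[-1].pos >= params.cluster_distance
        ):
            clusters.append(VariantCluster(current[0].chrom, tuple(current)))
            current = []
        current.append(v)
    if current:
        clusters.append(VariantCluster(current[0].chrom, tuple(current)))
    return clusters


def _allele_choices(v: VariantRecord) -> tuple[int, ...]:
    """Allele indices this variant can contribute to a haplotype."""
    return tuple(sorted(set(v.genotype)))


def enumerate_combos(
    cluster: VariantCluster, params: BuildParameters
) -> list[HaplotypeCombo]:
    """All per-cluster haplotype combinations carrying >= 1 alt allele.

    A het site contributes each of its genotype alleles; a hom-alt site
    always contributes its alt (it has no reference option); a 1/2 site
    contributes either alt but never ref. The all-reference combination
    is excluded — it is already present on the backbone. If enumeration
    would exceed 2^max_cluster_hets - 1 combos, fall back to one
    single-variant combo per variant.
    """
    choices = [_allele_choices(v) for v in cluster.variants]
    n_combos = 1
    for c in choices:
        n_combos *= len(c)
    if all(0 in c for c in choices):
        n_combos -= 1  # the all-reference combo is excluded
    cap = 2 ** params.max_cluster_hets - 1
    if n_combos > cap:
        logger.warning(
            "cluster at %s:%d: %d combos exceed cap %d; falling back to "
            "single-variant minis",
            cluster.chrom, cluster.variants[0].pos, n_combos, cap,
        )
        combos = []
        for i, v in enumerate(cluster.variants):
            for allele in _allele_choices(v):
                if allele == 0:
                    continue
                combo = tuple(
                    (allele if j == i else min(_allele_choices(u)))
                    for j, u in enumerate(cluster.variants)
                )
                combos.append(combo)
        return combos
    all_ref = tuple(0 for _ in choices)
    return [c for c in itertools.product(*choices) if c != all_ref]


def build_mini(
    backbone: ReferenceGenome,
    cluster: VariantCluster,
    combo: HaplotypeCombo,
    params: BuildParameters,
) -> MiniChromosome:
    """Cut the window around the cluster from the (hom-alt-edited)
    backbone and splice in the combo's alleles left-to-right.

    The window is [first.pos - flank, last.pos_end + flank), clipped to
    the chromosome; for a single unclipped SNP this is exactly w bases
    with the alternative allele at the middle index (w-1)/2.
    """
    chrom_len = backbone.length(cluster.chrom)
    start, end = cluster.span
    win_start = max(0, start - params.flank)
    win_end = min(chrom_len, end + params.flank)
    if win_end <= win_start:
        raise ValueError(
            f"degenerate mini window on {cluster.chrom} at {start}")
    seq = backbone.fetch(cluster.chrom, win_start, win_end)
    pieces: list[str] = []
    cursor = win_start
    edits: list[tuple[int, str, str]] = []
    for v, allele in zip(cluster.variants, combo):
        if allele == 0:
            continue
        alt = v.allele(allele)
        if v.pos < cursor:
            raise ValueError(
                f"overlapping variants in cluster at {v.chrom}:{v.pos}")
        pieces.append(seq[cursor - win_start:v.pos - win_start])
        pieces.append(alt)
        cursor = v.pos_end
        edits.append((v.pos, v.ref_allele, alt))
    pieces.append(seq[cursor - win_start:])
    return MiniChromosome(
        parent_chrom=cluster.chrom, univ_start=win_start, univ_end=win_end,
        combo=combo, sequence="".join(pieces), variant_edits=tuple(edits),
    )


def assemble(
    backbone: ReferenceGenome,
    minis: list[MiniChromosome],
    params: BuildParameters,
    edits: list[tuple[str, int, str, str]] | None = None,
) -> tuple[ReferenceGenome, AuxMap]:
    """Append minis behind N separators and record placements.

    Each augmented chromosome keeps its original name so both mates of a
    pair still map to a single reference sequence. Augmented length =
    backbone length + sum over minis of (len(mini) + m + 1).
    """
    separator = "N" * (params.m + 1)
    by_chrom: dict[str, list[MiniChromosome]] = {}
    for mini in minis:
        by_chrom.setdefault(mini.parent_chrom, []).append(mini)
    chromosomes: list[tuple[str, str]] = []
    placed: list[MiniChromosome] = []
    for name, seq in backbone.chromosomes:
        parts = [seq]
        offset = len(seq)
        for mini in by_chrom.get(name, []):
            parts.append(separator)
            offset += len(separator)
            mini.aug_start = offset
            mini.aug_end = offset + len(mini.sequence)
            parts.append(mini.sequence)
            offset = mini.aug_end
            placed.append(mini)
        chromosomes.append((name, "".join(parts)))
    aux = AuxMap(
        edits=list(edits or []),
        minis=[m.to_aux() for m in placed],
        k=params.k, m=params.m, w=params.w,
        universal_lengths=backbone.lengths,
    )
    return ReferenceGenome(chromosomes), aux


def build_reference(
    genome: ReferenceGenome,
    variants: list[VariantRecord],
    params: BuildParameters,
) -> tuple[ReferenceGenome, AuxMap]:
    """Full pipeline: classify -> edit -> cluster -> enumerate -> assemble.

    For female samples, chromosomes named Y/chrY (case-insensitive) are
    dropped from the output. Variants whose reference footprint (or its
    mini window) overlaps an N run are dropped with a logged count:
    edits inside undefined sequence are meaningless.
    """
    if params.sex == "female":
        kept = [
            (name, seq) for name, seq in genome.chromosomes
            if name.lower() not in ("y", "chry")
        ]
        if len(kept) != len(genome.chromosomes):
            logger.info("build_reference: excluded chrY (sex=female)")
        genome = ReferenceGenome(kept)
        variants = [v for v in variants if v.chrom in genome]

    variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
    ok: list[VariantRecord] = []
    n_on_n = 0
    for v in variants:
        v.validate_against(genome)
        if "N" in v.ref_allele:
            n_on_n += 1
            continue
        ok.append(v)
    if n_on_n:
        logger.warning(
            "build_reference: dropped %d variants overlapping N runs", n_on_n)

    skips, backbone_edits, mini_variants = classify_variants(ok, params)
    edited = apply_backbone_edits(genome, backbone_edits)
    clusters = cluster_mini_variants(mini_variants, params)
    minis: list[MiniChromosome] = []
    for cluster in clusters:
        for combo in enumerate_combos(cluster, params):
            minis.append(build_mini(edited, cluster, combo, params))
    edit_tuples = [
        (v.chrom, v.pos, v.ref_allele, v.allele(v.genotype[0]))
        for v in backbone_edits
    ]
    augmented, aux = assemble(edited, minis, params, edits=edit_tuples)
    logger.info(
        "build_reference: %d clusters -> %d mini chromosomes "
        "(%d backbone edits, %d hom-ref skipped)",
        len(clusters), len(minis), len(backbone_edits), len(skips),
    )
    return augmented, aux
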