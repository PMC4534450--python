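"""End-to-end strategy runners: simulate -> build -> map -> convert -> call.

These helpers wire the package's pieces into the two mapping strategies
being compared:

* ``universal``      — oracle-map reads to the universal haploid genome;
* ``personalized``   — build the personalized diploid reference from the
  individual's known genotypes, oracle-map to it, then lift alignments
  back to universal coordinates with the converter.

Both produce alignments in universal coordinates plus the per-read
distinct-locus mismatch profile used for unique-mapping rates, so the
evaluation metrics can score them identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .diploid_constructor import BuildParameters, build_reference
from .evaluation import (
    TrioCallSet,
    concordance,
    depth_by_class,
    detection_rate,
    mapping_rate,
    mendelian_inconsistency,
)
from .io_formats import AlignmentRecord, AuxMap, ReferenceGenome
from .mapping_converter import (
    AugmentedIndex,
    ConvertParameters,
    convert_records,
    translate,
)
from .synthetic_data import (
    GenotypeCall,
    OracleMapper,
    SimulatedIndividual,
    SimulatedRead,
    hits_to_sam_record,
    naive_call,
    simulate_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class StrategyResult:
    """Alignments (universal coordinates) and per-read locus profiles."""

    records: list[AlignmentRecord]
    # per read: mismatch distance of each distinct candidate locus
    locus_distances: list[list[int]]
    n_reads: int = 0

    def unique_rate(self, max_mm: int) -> float:
        return mapping_rate(self.locus_distances, max_mm)[1]


def run_universal(
    reads: list[SimulatedRead],
    genome: ReferenceGenome,
    max_mm: int = 2,
    unique_mapq: int = 37,
) -> StrategyResult:
    """Map reads straight to the universal genome with the oracle."""
    mapper = OracleMapper(genome)
    records: list[AlignmentRecord] = []
    profiles: list[list[int]] = []
    for read in reads:
        hits = mapper.map(read.sequence, max_mm)
        profiles.append([h.distance for h in hits])
        rec = hits_to_sam_record(read.id, read.sequence, read.qualities,
                                 hits, unique_mapq=unique_mapq)
        if len(hits) != 1:
            rec.mapq = 0 if hits else 0
        records.append(rec)
    return StrategyResult(records, profiles, n_reads=len(reads))


def run_personalized(
    reads: list[SimulatedRead],
    genome: ReferenceGenome,
    augmented: ReferenceGenome,
    aux: AuxMap,
    max_mm: int = 2,
    convert_params: ConvertParameters | None = None,
) -> StrategyResult:
    """Map reads to the augmented diploid reference, then lift back.

    The per-read locus profile is computed after liftback and collapse:
    placements on a mini and on its source backbone window count as ONE
    locus, at the smallest mismatch distance (vs the diploid reference)
    achieved there.
    """
    convert_params = convert_params or ConvertParameters()
    mapper = OracleMapper(augmented)
    index = AugmentedIndex(aux)
    raw_records: list[AlignmentRecord] = []
    profiles: list[list[int]] = []
    for read in reads:
        hits = mapper.map(read.sequence, max_mm)
        rec = hits_to_sam_record(read.id, read.sequence, read.qualities,
                                 hits, unique_mapq=convert_params.unique_mapq)
        raw_records.append(rec)
        loci: dict[tuple[str, int, str], int] = {}
        for hit in hits:
            probe = AlignmentRecord(
                qname=read.id, flag=0, rname=hit.chrom, pos=hit.pos,
                mapq=0, cigar=[("M", len(read.sequence))],
                seq=read.sequence, qual=read.qualities,
            )
            t = translate(probe, index, genome)
            if t.fail_reason is not None:
                continue
            key = (t.univ_chrom, t.univ_pos, hit.strand)
            if key not in loci or hit.distance < loci[key]:
                loci[key] = hit.distance
        profiles.append(sorted(loci.values()))
    converted = convert_records(raw_records, aux, genome, convert_params)
    return StrategyResult(converted, profiles, n_reads=len(reads))


def calls_to_classes(calls: list[GenotypeCall]) -> dict[tuple[str, int], str]:
    return {(c.chrom, c.pos): c.genotype for c in calls}


@dataclass
class ComparisonReport:
    """Universal-vs-personalized metric table for one individual."""

    metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, name: str, universal: float, personalized: float) -> None:
        self.metrics[name] = {
            "universal": universal, "personalized": personalized}

    def rows(self):
        for name, vals in self.metrics.items():
            yield name, vals["universal"], vals["personalized"]


def compare_strategies(
    individual: SimulatedIndividual,
    build_params: BuildParameters,
    coverage: float = 4.0,
    error_rate: float = 0.005,
    max_mm: int = 2,
    seed: int = 0,
    caller_kwargs: dict | None = None,
) -> tuple[ComparisonReport, StrategyResult, StrategyResult]:
    """Run both strategies on fresh reads from one individual and score
    them with every evaluation metric except trio MI."""
    genome = individual.genome
    reads = simulate_reads(
        individual, k=build_params.k, coverage=coverage,
        error_rate=error_rate, seed=seed,
    )
    augmented, aux = build_reference(genome, individual.variants,
                                     build_params)
    uni = run_universal(reads, genome, max_mm=max_mm)
    per = run_personalized(reads, genome, augmented, aux, max_mm=max_mm)

    # genotype-level metrics are scored on SNP loci only: the pileup
    # caller emits substitution genotypes, and indel loci would show up
    # as spurious no-calls/ref-calls for whichever strategy mapped them
    gold = individual.snp_truth_genotypes
    report = ComparisonReport()
    for t in range(max_mm + 1):
        report.add(f"unique_mapping_rate_mm{t}",
                   uni.unique_rate(t), per.unique_rate(t))
    kwargs = caller_kwargs or {}
    uni_calls = calls_to_classes(naive_call(uni.records, genome, **kwargs))
    per_calls = calls_to_classes(naive_call(per.records, genome, **kwargs))
    report.add("nonref_concordance",
               concordance(uni_calls, gold).concordance,
               concordance(per_calls, gold).concordance)
    report.add("snp_detection_rate",
               detection_rate(uni_calls, gold),
               detection_rate(per_calls, gold))
    uni_depth = depth_by_class(uni.records, gold, genome)
    per_depth = depth_by_class(per.records, gold, genome)
    for cls in ("ref/ref", "het", "alt/alt"):
        key = cls.replace("/", "_")
        report.add(f"mean_depth_{key}", uni_depth[cls], per_depth[cls])
    return report, uni, per


def trio_mi_comparison(
    trio: tuple[SimulatedIndividual, SimulatedIndividual,
                SimulatedIndividual],
    build_params: BuildParameters,
    coverage: float = 4.0,
    error_rate: float = 0.005,
    max_mm: int = 2,
    seed: int = 0,
    caller_kwargs: dict | None = None,
) -> dict[str, float]:
    """Mendelian-inconsistency rate for both strategies on a trio."""
    kwargs = caller_kwargs or {}
    calls = {"universal": [], "personalized": []}
    for i, individual in enumerate(trio):
        genome = individual.genome
        reads = simulate_reads(
            individual, k=build_params.k, coverage=coverage,
            error_rate=error_rate, seed=seed + 1000 * (i + 1),
        )
        augmented, aux = build_reference(genome, individual.variants,
                                         build_params)
        uni = run_universal(reads, genome, max_mm=max_mm)
        per = run_personalized(reads, genome, augmented, aux, max_mm=max_mm)
        calls["universal"].append(
            calls_to_classes(naive_call(uni.records, genome, **kwargs)))
        calls["personalized"].append(
            calls_to_classes(naive_call(per.records, genome, **kwargs)))
    out = {}
    for strategy, (m, f, c) in (
        ("universal", calls["universal"]),
        ("personalized", calls["personalized"]),
    ):
        n_assessed, n_errors, rate = mendelian_inconsistency(
            TrioCallSet(mother=m, father=f, child=c))
        out[f"mi_rate_{strategy}"] = rate
        out[f"mi_assessed_{strategy}"] = n_assessed
        out[f"mi_errors_{strategy}"] = n_errors
    return out
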