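"""Translate alignments on the augmented reference back to universal
coordinates, collapse artifactual multi-mappings, and reassign MAPQ.

A read aligned to a mini chromosome is really aligned to the genomic
window the mini copies; a read reported as "multi-mapped" because it
hits both the backbone and a mini of the same locus is really unique.
This module undoes both artifacts: every candidate placement (primary,
secondary, and XA alternative hits) is translated to universal
coordinates, placements that land on the same (chrom, pos, strand) are
collapsed, NM/MD are recomputed against the *universal* reference (so
alternative alleles surface as mismatches for downstream callers), and
the mapping quality of a read whose placements collapse to a single
locus is promoted to a unique-mapping score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .io_formats import (
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_REVERSE,
    FLAG_SECONDARY,
    FLAG_UNMAPPED,
    AlignmentRecord,
    AuxMap,
    AuxMini,
    ReferenceGenome,
    XaHit,
    cigar_reference_length,
    format_cigar,
    format_xa,
    revcomp,
)

logger = logging.getLogger(__name__)

MAIN = "MAIN"


@dataclass(frozen=True)
class ConvertParameters:
    """unique_mapq: score for reads collapsing to one locus (default 37,
    the conventional unique-hit score of short-read aligners); mapq_cap
    caps the Phred-scaled posterior; min_base_error floors per-base
    error probabilities so a handful of high-quality mismatches cannot
    drive likelihoods to exactly zero."""

    unique_mapq: int = 37
    mapq_cap: int = 60
    min_base_error: float = 1e-4

    def __post_init__(self):
        if not 0 <= self.unique_mapq <= self.mapq_cap <= 254:
            raise ValueError("require 0 <= unique_mapq <= mapq_cap <= 254")


@dataclass
class TranslatedAlignment:
    """One candidate placement expressed in universal coordinates."""

    univ_chrom: str
    univ_pos: int
    strand: str
    cigar: list[tuple[str, int]]
    nm: int                      # vs the UNIVERSAL reference
    md: str
    origin: str                  # MAIN or mini id "MINI:<aug_start>"
    mismatch_positions: list[int] = field(default_factory=list)
    mismatch_quals: list[int] = field(default_factory=list)
    source_nm: int = 0           # vs the reference actually mapped to
    seq: str = ""
    qual: str = ""
    fail_reason: str | None = None

    @property
    def locus(self) -> tuple[str, int, str]:
        return (self.univ_chrom, self.univ_pos, self.strand)


class _MiniAlignment:
    """Mini-local <-> universal walk derived from a mini's variant spec.

    Blocks are (op, length) with op M (positional match, incl. SNP
    substitutions), I (mini-only bases: combo insertions) or D
    (universal-only bases: combo deletions).
    """

    def __init__(self, mini: AuxMini):
        self.mini = mini
        blocks: list[tuple[str, int]] = []
        univ_cursor = mini.univ_start
        for pos, ref, alt in mini.variant_edits:
            if pos > univ_cursor:
                blocks.append(("M", pos - univ_cursor))
            prefix = 0
            while (prefix < len(ref) and prefix < len(alt)
                   and ref[prefix] == alt[prefix]):
                prefix += 1
            core = max(prefix, min(len(ref), len(alt)))
            if core:
                blocks.append(("M", core))
            if len(alt) > len(ref):
                blocks.append(("I", len(alt) - len(ref)))
            elif len(ref) > len(alt):
                blocks.append(("D", len(ref) - len(alt)))
            univ_cursor = pos + len(ref)
        if mini.univ_end > univ_cursor:
            blocks.append(("M", mini.univ_end - univ_cursor))
        self.blocks = blocks

    def project(self, local_start: int,
                local_len: int) -> tuple[int, list[tuple[str, int]]]:
        """Project a mini-local reference interval [local_start,
        local_start+local_len) onto the universal reference.

        Returns (univ_start, ops) where ops is the M/I/D profile of the
        interval vs the universal sequence. Leading/trailing insertions
        are reported as I and resolved by the caller.
        """
        ops: list[tuple[str, int]] = []
        univ = self.mini.univ_start
        local = 0
        remaining = local_len
        univ_start = None
        for op, n in self.blocks:
            if remaining <= 0:
                break
            if op == "D":
                # universal-only bases: emitted once the interval has begun
                if univ_start is not None:
                    ops.append(("D", n))
                univ += n
                continue
            # M and I both consume mini-local bases
            if local + n <= local_start:
                local += n
                if op == "M":
                    univ += n
                continue
            offset = max(0, local_start - local)
            take = min(n - offset, remaining)
            if op == "M":
                if univ_start is None:
                    univ_start = univ + offset
                ops.append(("M", take))
                univ += n
            else:
                ops.append(("I", take))
            local += n
            remaining -= take
        if remaining > 0:
            raise ValueError("interval extends past mini end")
        # trailing D blocks emitted above only when started; trim trailing D
        while ops and ops[-1][0] == "D":
            ops.pop()
        if univ_start is None:
            # interval entirely inside an insertion: anchor at next ref base
            univ_start = univ
        return univ_start, ops


class AugmentedIndex:
    """Fast lookup structures over an AuxMap for one conversion run."""

    def __init__(self, aux: AuxMap):
        self.aux = aux
        self._minis: dict[str, list[tuple[int, int, _MiniAlignment]]] = {}
        for mini in aux.minis:
            self._minis.setdefault(mini.chrom, []).append(
                (mini.aug_start, mini.aug_end, _MiniAlignment(mini)))
        for group in self._minis.values():
            group.sort()

    def find_mini(self, chrom: str, start: int,
                  end: int) -> _MiniAlignment | None:
        """The mini fully containing augmented interval [start, end)."""
        for aug_start, aug_end, aln in self._minis.get(chrom, []):
            if aug_start <= start and end <= aug_end:
                return aln
            if aug_start > start:
                break
        return None


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def compute_nm_md(
    seq: str, quals: list[int], genome: ReferenceGenome, chrom: str,
    pos: int, cigar: list[tuple[str, int]],
) -> tuple[int, str, list[int], list[int]]:
    """NM, MD, mismatch reference positions and their base qualities for
    an alignment laid out by ``cigar`` against the universal genome."""
    ref = genome.sequence(chrom)
    nm = 0
    md_parts: list[str] = []
    match_run = 0
    mismatch_positions: list[int] = []
    mismatch_quals: list[int] = []
    qpos, rpos = 0, pos
    for op, n in cigar:
        if op in "M=X":
            for i in range(n):
                if seq[qpos + i] == ref[rpos + i]:
                    match_run += 1
                else:
                    nm += 1
                    md_parts.append(f"{match_run}{ref[rpos + i]}")
                    match_run = 0
                    mismatch_positions.append(rpos + i)
                    mismatch_quals.append(quals[qpos + i])
            qpos += n
            rpos += n
        elif op in "IS":
            if op == "I":
                nm += n
            qpos += n
        elif op in "DN":
            if op == "D":
                nm += n
                md_parts.append(f"{match_run}^{ref[rpos:rpos + n]}")
                match_run = 0
            rpos += n
    md_parts.append(str(match_run))
    return nm, "".join(md_parts), mismatch_positions, mismatch_quals


def translate(
    record: AlignmentRecord,
    index: AugmentedIndex,
    universal_genome: ReferenceGenome,
) -> TranslatedAlignment:
    """Translate one mapped record from augmented to universal space.

    Backbone placements keep their coordinates; mini placements are
    shifted by the mini's offset and respliced through its indel
    profile so reads spanning a combo insertion/deletion regain I/D
    CIGAR ops. NM/MD always refer to the universal reference.
    Placements straddling an N separator or a mini boundary are flagged
    unalignable instead of being clipped.
    """
    aux = index.aux
    chrom = record.rname
    if chrom not in aux.universal_lengths:
        raise ValueError(f"chromosome {chrom!r} not in aux map")
    univ_len = aux.universal_lengths[chrom]
    span = cigar_reference_length(record.cigar)
    failed = TranslatedAlignment(
        univ_chrom=chrom, univ_pos=-1, strand=record.strand, cigar=[],
        nm=0, md="", origin="", fail_reason="separator_or_boundary",
    )
    if record.pos + span <= univ_len:
        univ_pos = record.pos
        new_cigar = list(record.cigar)
        origin = MAIN
    elif record.pos >= univ_len:
        aln = index.find_mini(chrom, record.pos, record.pos + span)
        if aln is None:
            return failed
        origin = f"MINI:{aln.mini.aug_start}"
        local = record.pos - aln.mini.aug_start
        # walk the record's CIGAR, projecting reference-consuming runs
        ops: list[tuple[str, int]] = []
        univ_pos = None
        cursor = local
        for op, n in record.cigar:
            if op in "M=X":
                start, projected = aln.project(cursor, n)
                if univ_pos is None:
                    univ_pos = start
                ops.extend(projected)
                cursor += n
            elif op in "IS":
                ops.append((op, n))
            elif op in "DN":
                start, projected = aln.project(cursor, n)
                univ_span = sum(ln for p, ln in projected if p == "M")
                ops.append(("D", univ_span))
                cursor += n
            else:
                ops.append((op, n))
        if univ_pos is None:
            return failed
        # a SAM alignment cannot begin or end with I: soft-clip instead
        ops = _merge_ops(ops)
        if ops and ops[0][0] == "I":
            ops[0] = ("S", ops[0][1])
        if ops and ops[-1][0] == "I":
            ops[-1] = ("S", ops[-1][1])
        new_cigar = _merge_ops(ops)
    else:
        return failed
    nm, md, mm_pos, mm_quals = compute_nm_md(
        record.seq, record.base_qualities(), universal_genome, chrom,
        univ_pos, new_cigar,
    )
    return TranslatedAlignment(
        univ_chrom=chrom, univ_pos=univ_pos, strand=record.strand,
        cigar=new_cigar, nm=nm, md=md, origin=origin,
        mismatch_positions=mm_pos, mismatch_quals=mm_quals,
        source_nm=int(record.get_tag("NM", 0)), seq=record.seq,
        qual=record.qual,
    )


def collapse(
    group: list[TranslatedAlignment],
) -> tuple[dict[tuple[str, int, str], TranslatedAlignment],
           TranslatedAlignment]:
    """Group candidates by translated locus and pick winners.

    Within a locus the candidate with minimal NM-vs-universal wins
    (ties: MAIN origin first, then lexicographically smallest origin).
    The overall chosen alignment is the locus winner with minimal NM
    (ties: leftmost (chrom, pos)).
    """
    if not group:
        raise ValueError("collapse called with empty group")
    loci: dict[tuple[str, int, str], TranslatedAlignment] = {}
    for cand in group:
        key = cand.locus
        best = loci.get(key)
        if best is None or _locus_rank(cand) < _locus_rank(best):
            loci[key] = cand
    chosen = min(
        loci.values(),
        key=lambda t: (t.nm, t.univ_chrom, t.univ_pos),
    )
    return loci, chosen


def _locus_rank(t: TranslatedAlignment):
    return (t.nm, 0 if t.origin == MAIN else 1, t.origin)


def _locus_likelihood(t: TranslatedAlignment,
                      params: ConvertParameters) -> float:
    p = 1.0
    for q in t.mismatch_quals:
        p *= max(10 ** (-q / 10), params.min_base_error)
    return p


def reassign_mapq(
    loci: dict[tuple[str, int, str], TranslatedAlignment],
    chosen: TranslatedAlignment,
    original_mapq: int,
    params: ConvertParameters,
    collapsed: bool = True,
) -> int:
    """Mapping quality after collapse.

    One distinct locus: promote to max(original, unique_mapq) — but only
    when the uniqueness was established by collapsing several candidate
    placements; a read that always had a single placement keeps its
    aligner score (never lowered). Multiple loci: Phred-scaled posterior
    of the best locus, each locus's likelihood being the product of its
    mismatch-site base error probabilities.
    """
    if len(loci) == 1:
        if collapsed:
            return max(original_mapq, params.unique_mapq)
        return original_mapq
    probs = {key: _locus_likelihood(t, params) for key, t in loci.items()}
    total = sum(probs.values())
    posterior = probs[chosen.locus] / total if total > 0 else 0.0
    complement = max(1 - posterior, 10 ** (-params.mapq_cap / 10))
    return min(params.mapq_cap, round(-10 * math.log10(complement)))


# ---------------------------------------------------------------------------
# Whole-file conversion
# ---------------------------------------------------------------------------


def _materialize_xa(primary: AlignmentRecord, hit: XaHit) -> AlignmentRecord:
    """Expand an XA alternative hit into a full record for translation."""
    same_strand = (hit.strand == primary.strand)
    seq = primary.seq if same_strand else revcomp(primary.seq)
    qual = primary.qual if same_strand or primary.qual == "*" \
        else primary.qual[::-1]
    flag = primary.flag & ~(FLAG_REVERSE | FLAG_SECONDARY)
    if hit.strand == "-":
        flag |= FLAG_REVERSE
    rec = AlignmentRecord(
        qname=primary.qname, flag=flag, rname=hit.chrom, pos=hit.pos,
        mapq=0, cigar=AlignmentRecord.from_sam_line(
            "\t".join(["x", "0", "*", "1", "0", hit.cigar, "*", "0", "0",
                       "*", "*"])).cigar,
        seq=seq, qual=qual,
    )
    rec.set_tag("NM", "i", hit.nm)
    return rec


def _emit_unmapped(primary: AlignmentRecord,
                   reason: str) -> AlignmentRecord:
    rec = AlignmentRecord(
        qname=primary.qname,
        flag=(primary.flag & ~FLAG_REVERSE & ~FLAG_SECONDARY) | FLAG_UNMAPPED,
        rname="*", pos=-1, mapq=0, cigar=[],
        seq=primary.seq if not primary.is_reverse else revcomp(primary.seq),
        qual=primary.qual if not primary.is_reverse or primary.qual == "*"
        else primary.qual[::-1],
    )
    rec.set_tag("ZF", "Z", reason)
    return rec


def convert_records(
    records: list[AlignmentRecord],
    aux: AuxMap,
    universal_genome: ReferenceGenome,
    params: ConvertParameters | None = None,
) -> list[AlignmentRecord]:
    """Convert a name-grouped record list; see :func:`convert_sam`."""
    params = params or ConvertParameters()
    index = AugmentedIndex(aux)

    groups: dict[tuple[str, int], list[AlignmentRecord]] = {}
    order: list[tuple[str, int]] = []
    for rec in records:
        key = (rec.qname, rec.mate_index)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    converted: dict[tuple[str, int], AlignmentRecord] = {}
    placements: dict[tuple[str, int], TranslatedAlignment | None] = {}
    for key in order:
        group = groups[key]
        primary = next((r for r in group if not r.is_secondary), group[0])
        if primary.is_unmapped:
            converted[key] = primary
            placements[key] = None
            continue
        candidates: list[AlignmentRecord] = [
            r for r in group if not r.is_unmapped]
        for rec in list(candidates):
            for hit in rec.xa_hits():
                candidates.append(_materialize_xa(rec, hit))
        translated: list[TranslatedAlignment] = []
        fail_reason = None
        for cand in candidates:
            t = translate(cand, index, universal_genome)
            if t.fail_reason is None:
                translated.append(t)
            else:
                fail_reason = t.fail_reason
        if not translated:
            converted[key] = _emit_unmapped(primary,
                                            fail_reason or "unalignable")
            placements[key] = None
            continue
        loci, chosen = collapse(translated)
        mapq = reassign_mapq(loci, chosen, primary.mapq, params,
                             collapsed=len(translated) > 1)
        out = AlignmentRecord(
            qname=primary.qname,
            flag=(primary.flag & ~FLAG_REVERSE)
            | (FLAG_REVERSE if chosen.strand == "-" else 0),
            rname=chosen.univ_chrom, pos=chosen.univ_pos, mapq=mapq,
            cigar=chosen.cigar, rnext=primary.rnext, pnext=primary.pnext,
            tlen=primary.tlen, seq=chosen.seq, qual=chosen.qual,
            tags=dict(primary.tags),
        )
        out.set_tag("NM", "i", chosen.nm)
        out.set_tag("MD", "Z", chosen.md)
        others = [t for k, t in sorted(loci.items()) if k != chosen.locus]
        if others:
            out.set_tag("XA", "Z", format_xa([
                XaHit(t.univ_chrom, t.univ_pos, t.strand,
                      format_cigar(t.cigar), t.nm)
                for t in others
            ]))
        elif "XA" in out.tags:
            del out.tags["XA"]
        if mapq != primary.mapq:
            out.set_tag("ZQ", "i", primary.mapq)
        if chosen.origin != MAIN:
            out.set_tag("ZR", "Z", chosen.origin)
        converted[key] = out
        placements[key] = chosen

    _repair_mates(converted, placements)
    return [converted[key] for key in order]


def _repair_mates(converted, placements) -> None:
    """Recompute RNEXT/PNEXT/TLEN and mate flags from converted mates."""
    for (qname, mate), rec in converted.items():
        if mate == 0:
            continue
        other_key = (qname, 3 - mate)
        if other_key not in converted:
            continue
        mate_rec = converted[other_key]
        if mate_rec.is_unmapped or rec.is_unmapped:
            rec.flag |= FLAG_MATE_UNMAPPED if mate_rec.is_unmapped else 0
            rec.rnext, rec.pnext, rec.tlen = "*", -1, 0
            continue
        rec.flag &= ~FLAG_MATE_UNMAPPED
        rec.flag = (rec.flag & ~FLAG_MATE_REVERSE) | (
            FLAG_MATE_REVERSE if mate_rec.is_reverse else 0)
        rec.rnext = "=" if mate_rec.rname == rec.rname else mate_rec.rname
        rec.pnext = mate_rec.pos
        if mate_rec.rname == rec.rname:
            left = min(rec.pos, mate_rec.pos)
            right = max(rec.reference_end, mate_rec.reference_end)
            span = right - left
            if rec.pos < mate_rec.pos or (
                    rec.pos == mate_rec.pos and mate == 1):
                rec.tlen = span
            else:
                rec.tlen = -span
        else:
            rec.tlen = 0


def convert_sam(
    in_path, aux: AuxMap, universal_genome: ReferenceGenome,
    out_path, params: ConvertParameters | None = None,
    header_extra: list[str] | None = None,
) -> None:
    """File-level conversion: validates the input header against the
    augmented lengths, rewrites @SQ lines to universal lengths, and
    converts every record (two-pass internal grouping, so the input
    need not be name-sorted)."""
    from .io_formats import read_sam, sam_header_for, write_sam

    header, records = read_sam(in_path)
    expected = aux.augmented_lengths
    for line in header:
        if line.startswith("@SQ"):
            fields = dict(
                item.split(":", 1) for item in line.split("\t")[1:])
            name, length = fields["SN"], int(fields["LN"])
            if name in expected and length != expected[name]:
                raise ValueError(
                    f"@SQ {name} length {length} != augmented "
                    f"{expected[name]}")
    out_records = convert_records(records, aux, universal_genome, params)
    out_header = ["@HD\tVN:1.6\tSO:unsorted"]
    out_header += [
        f"@SQ\tSN:{name}\tLN:{length}"
        for name, length in aux.universal_lengths.items()
    ]
    out_header += [line for line in header
                   if not line.startswith(("@HD", "@SQ"))]
    out_header.append("@PG\tID:refedit-convert\tPN:refedit")
    if header_extra:
        out_header += header_extra
    write_sam(out_records, out_header, out_path)
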