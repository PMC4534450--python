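"""Readers, writers and record types for the formats the pipeline touches.

FASTA is read and written through Biopython; VCF is read through pysam.
SAM is handled at the text-line level so that record round-trips are
byte-exact and records can exist independently of any file header (the
alignment model here carries bespoke tags — ``ZQ``, ``ZR``, ``ZF`` — and
structured ``XA`` alternative hits that the converter rewrites).

All coordinates are 0-based half-open internally; VCF and SAM positions
are shifted at the I/O boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_IN_PAIR = 0x40
FLAG_SECOND_IN_PAIR = 0x80
FLAG_SECONDARY = 0x100

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


class ReferenceGenome:
    """Ordered collection of named chromosome sequences.

    Sequences are stored uppercase over the alphabet {A, C, G, T, N};
    any other IUPAC character is coerced to N (with a logged warning).
    """

    def __init__(self, chromosomes: list[tuple[str, str]]):
        names = [n for n, _ in chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome")
        cleaned = []
        for name, seq in chromosomes:
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            seq = seq.upper()
            if not set(seq) <= _VALID_BASES:
                n_bad = sum(1 for c in seq if c not in _VALID_BASES)
                logger.warning(
                    "chromosome %s: %d non-ACGTN bases coerced to N", name, n_bad
                )
                seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
            cleaned.append((name, seq))
        self.chromosomes: list[tuple[str, str]] = cleaned
        self._by_name = dict(cleaned)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReferenceGenome)
            and self.chromosomes == other.chromosomes
        )

    def sequence(self, name: str) -> str:
        return self._by_name[name]

    def length(self, name: str) -> int:
        return len(self._by_name[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    def fetch(self, name: str, start: int, end: int) -> str:
        """Exact substring of chromosome ``name`` over [start, end)."""
        seq = self._by_name[name]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"interval [{start},{end}) out of bounds for {name}")
        return seq[start:end]


def read_fasta(path) -> ReferenceGenome:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return ReferenceGenome(records)


def write_fasta(genome: ReferenceGenome, path, wrap_width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A genotyped variant on the universal reference.

    ``genotype`` is an unordered pair of allele indices into
    [ref] + alt_alleles, stored sorted; phase is not tracked.
    """

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotype: tuple[int, int]

    def __post_init__(self):
        g = tuple(sorted(self.genotype))
        object.__setattr__(self, "genotype", g)
        object.__setattr__(self, "alt_alleles", tuple(self.alt_alleles))
        n_alleles = 1 + len(self.alt_alleles)
        if not all(0 <= a < n_alleles for a in g):
            raise ValueError(f"genotype {g} invalid for {n_alleles} alleles at "
                             f"{self.chrom}:{self.pos}")

    @property
    def pos_end(self) -> int:
        """End (exclusive) of the reference footprint."""
        return self.pos + len(self.ref_allele)

    def allele(self, index: int) -> str:
        return self.ref_allele if index == 0 else self.alt_alleles[index - 1]

    @property
    def is_hom_ref(self) -> bool:
        return self.genotype == (0, 0)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def is_hom_alt(self) -> bool:
        a, b = self.genotype
        return a == b and a != 0

    @property
    def is_snp(self) -> bool:
        carried = {self.allele(a) for a in self.genotype} | {self.ref_allele}
        return all(len(x) == 1 for x in carried)

    @property
    def is_indel(self) -> bool:
        return not self.is_snp

    def validate_against(self, genome: ReferenceGenome) -> None:
        observed = genome.fetch(self.chrom, self.pos, self.pos_end)
        if observed != self.ref_allele:
            raise ValueError(
                f"REF mismatch at {self.chrom}:{self.pos}: VCF says "
                f"{self.ref_allele!r}, reference has {observed!r}"
            )


def read_vcf(path, sample_name: str | None = None,
             genome: ReferenceGenome | None = None) -> list[VariantRecord]:
    """Parse genotyped variants for one sample from a VCF 4.x file.

    Missing genotypes (``./.``) are skipped with a logged count. When a
    genome is supplied every record's REF is validated against it and a
    single error lists all offending loci.
    """
    variants: list[VariantRecord] = []
    n_missing = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: no sample columns with GT data")
        if sample_name is None:
            sample_name = samples[0]
        elif sample_name not in samples:
            raise ValueError(f"sample {sample_name!r} not in {samples}")
        for rec in vcf:
            gt = rec.samples[sample_name].get("GT")
            if gt is None or any(a is None for a in gt):
                n_missing += 1
                continue
            variants.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref_allele=rec.ref.upper(),
                    alt_alleles=tuple(a.upper() for a in (rec.alts or ())),
                    genotype=(gt[0], gt[1]),
                )
            )
    if n_missing:
        logger.info("read_vcf: skipped %d records with missing GT", n_missing)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    if genome is not None:
        bad = []
        for v in variants:
            try:
                v.validate_against(genome)
            except ValueError as e:
                bad.append(str(e))
        if bad:
            raise ValueError("REF/reference disagreement:\n" + "\n".join(bad))
    return variants


def write_vcf(variants: list[VariantRecord], path,
              sample_name: str = "SAMPLE",
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write variants as a minimal single-sample VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_name}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            alts = ",".join(v.alt_alleles) if v.alt_alleles else "."
            gt = f"{v.genotype[0]}/{v.genotype[1]}"
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{alts}"
                     f"\t.\t.\t.\tGT\t{gt}\n")


# ---------------------------------------------------------------------------
# SAM records
# ---------------------------------------------------------------------------


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    if cigar == "*":
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if sum(len(m.group(0)) for m in _CIGAR_RE.finditer(cigar)) != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def format_cigar(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops) if ops else "*"


def cigar_query_length(ops: list[tuple[str, int]]) -> int:
    return sum(n for op, n in ops if op in _QUERY_OPS)


def cigar_reference_length(ops: list[tuple[str, int]]) -> int:
    return sum(n for op, n in ops if op in _REF_OPS)


@dataclass(frozen=True)
class XaHit:
    """One alternative hit from an ``XA:Z:`` tag (pos is 0-based here)."""

    chrom: str
    pos: int
    strand: str  # '+' or '-'
    cigar: str
    nm: int


def parse_xa(value: str) -> list[XaHit]:
    hits = []
    for item in value.strip(";").split(";"):
        if not item:
            continue
        chrom, signed_pos, cigar, nm = item.split(",")
        hits.append(XaHit(chrom, abs(int(signed_pos)) - 1,
                          "-" if signed_pos.startswith("-") else "+",
                          cigar, int(nm)))
    return hits


def format_xa(hits: list[XaHit]) -> str:
    return "".join(
        f"{h.chrom},{h.strand if h.strand == '-' else '+'}{h.pos + 1},"
        f"{h.cigar},{h.nm};"
        for h in hits
    )


@dataclass
class AlignmentRecord:
    """One SAM alignment line (pos and pnext 0-based internally).

    Tags are kept as an ordered mapping tag -> (type char, value);
    unknown tag types round-trip verbatim because their values stay
    strings.
    """

    qname: str
    flag: int
    rname: str
    pos: int  # 0-based; meaningless when unmapped
    mapq: int
    cigar: list[tuple[str, int]]
    rnext: str = "*"
    pnext: int = -1
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: dict[str, tuple[str, object]] = field(default_factory=dict)

    # -- flag helpers -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    @property
    def mate_index(self) -> int:
        """0 for unpaired, 1/2 for first/second in pair."""
        if self.flag & FLAG_FIRST_IN_PAIR:
            return 1
        if self.flag & FLAG_SECOND_IN_PAIR:
            return 2
        return 0

    @property
    def reference_end(self) -> int:
        return self.pos + cigar_reference_length(self.cigar)

    def base_qualities(self) -> list[int]:
        if self.qual == "*":
            return [30] * len(self.seq)
        return [ord(c) - 33 for c in self.qual]

    # -- tags ---------------------------------------------------------
    def get_tag(self, tag: str, default=None):
        if tag in self.tags:
            return self.tags[tag][1]
        return default

    def set_tag(self, tag: str, type_char: str, value) -> None:
        self.tags[tag] = (type_char, value)

    def xa_hits(self) -> list[XaHit]:
        raw = self.get_tag("XA")
        return parse_xa(raw) if raw else []

    # -- text form ----------------------------------------------------
    @classmethod
    def from_sam_line(cls, line: str) -> "AlignmentRecord":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise ValueError(f"SAM line has {len(fields)} fields: {line!r}")
        cigar = parse_cigar(fields[5])
        seq = fields[9]
        flag = int(fields[1])
        if cigar and seq != "*" and not (flag & FLAG_UNMAPPED):
            if cigar_query_length(cigar) != len(seq):
                raise ValueError(
                    f"{fields[0]}: CIGAR {fields[5]} does not span SEQ "
                    f"length {len(seq)}"
                )
        tags: dict[str, tuple[str, object]] = {}
        for raw in fields[11:]:
            tag, type_char, value = raw.split(":", 2)
            if type_char == "i":
                value = int(value)
            tags[tag] = (type_char, value)
        return cls(
            qname=fields[0], flag=flag, rname=fields[2],
            pos=int(fields[3]) - 1, mapq=int(fields[4]), cigar=cigar,
            rnext=fields[6], pnext=int(fields[7]) - 1, tlen=int(fields[8]),
            seq=seq, qual=fields[10], tags=tags,
        )

    def to_sam_line(self) -> str:
        fields = [
            self.qname, str(self.flag), self.rname, str(self.pos + 1),
            str(self.mapq), format_cigar(self.cigar), self.rnext,
            str(self.pnext + 1), str(self.tlen), self.seq, self.qual,
        ]
        for tag, (type_char, value) in self.tags.items():
            fields.append(f"{tag}:{type_char}:{value}")
        return "\t".join(fields)


def read_sam(path) -> tuple[list[str], list[AlignmentRecord]]:
    """Read a text SAM file into (header lines, alignment records)."""
    header: list[str] = []
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                header.append(line.rstrip("\n"))
            elif line.strip():
                records.append(AlignmentRecord.from_sam_line(line))
    return header, records


def write_sam(records: list[AlignmentRecord], header: list[str], path) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for rec in records:
            fh.write(rec.to_sam_line() + "\n")


def sam_header_for(genome: ReferenceGenome,
                   extra: list[str] | None = None) -> list[str]:
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    header += [f"@SQ\tSN:{name}\tLN:{len(seq)}"
               for name, seq in genome.chromosomes]
    if extra:
        header += extra
    return header


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    """Write (id, sequence, quality-string) triples as FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    return [(r.id, str(r.seq),
             "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"]))
            for r in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# Auxiliary liftback map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AuxMini:
    """Liftback descriptor for one appended alt-allele segment.

    ``variant_edits`` are the segment's non-reference alleles in
    universal coordinates, sorted by position: (pos0, ref, alt).
    """

    chrom: str            # parent == augmented chromosome name
    aug_start: int
    aug_end: int
    univ_start: int
    variant_edits: tuple[tuple[int, str, str], ...]

    @property
    def length(self) -> int:
        return self.aug_end - self.aug_start

    @property
    def univ_end(self) -> int:
        delta = sum(len(alt) - len(ref) for _, ref, alt in self.variant_edits)
        return self.univ_start + self.length - delta


def _format_variant_spec(edits) -> str:
    return ";".join(f"{pos}:{ref}>{alt}" for pos, ref, alt in edits) or "."


def _parse_variant_spec(spec: str):
    if spec == ".":
        return ()
    out = []
    for item in spec.split(";"):
        pos, change = item.split(":")
        ref, alt = change.split(">")
        out.append((int(pos), ref, alt))
    return tuple(out)


@dataclass
class AuxMap:
    """Index tying augmented-genome coordinates back to universal ones."""

    edits: list[tuple[str, int, str, str]]     # in-place hom-alt SNP edits
    minis: list[AuxMini]
    k: int
    m: int
    w: int
    universal_lengths: dict[str, int]

    def __post_init__(self):
        self._check_minis()

    def _check_minis(self) -> None:
        by_chrom: dict[str, list[AuxMini]] = {}
        for mini in self.minis:
            by_chrom.setdefault(mini.chrom, []).append(mini)
        for chrom, group in by_chrom.items():
            if chrom not in self.universal_lengths:
                raise ValueError(f"mini on unknown chromosome {chrom!r}")
            univ_len = self.universal_lengths[chrom]
            prev_end = univ_len
            for mini in group:
                if mini.aug_start < prev_end:
                    raise ValueError(
                        f"mini intervals on {chrom} unsorted or overlapping "
                        f"at {mini.aug_start}"
                    )
                prev_end = mini.aug_end

    def minis_for(self, chrom: str) -> list[AuxMini]:
        return [m for m in self.minis if m.chrom == chrom]

    @property
    def augmented_lengths(self) -> dict[str, int]:
        lengths = dict(self.universal_lengths)
        for mini in self.minis:
            lengths[mini.chrom] += mini.length + self.m + 1
        return lengths

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AuxMap)
            and self.edits == other.edits
            and self.minis == other.minis
            and (self.k, self.m, self.w) == (other.k, other.m, other.w)
            and self.universal_lengths == other.universal_lengths
        )


def write_aux_map(aux: AuxMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#refeditor-aux-map\tv1\n")
        fh.write(f"#params\tk={aux.k}\tm={aux.m}\tw={aux.w}\n")
        for name, length in aux.universal_lengths.items():
            fh.write(f"#univ\t{name}\t{length}\n")
        for chrom, pos, ref, alt in aux.edits:
            fh.write(f"EDIT\t{chrom}\t{pos}\t{ref}\t{alt}\n")
        for mini in aux.minis:
            spec = _format_variant_spec(mini.variant_edits)
            fh.write(f"MINI\t{mini.chrom}\t{mini.aug_start}\t{mini.aug_end}"
                     f"\t{mini.chrom}\t{mini.univ_start}\t{spec}\n")


def read_aux_map(path) -> AuxMap:
    params: dict[str, int] = {}
    universal_lengths: dict[str, int] = {}
    edits: list[tuple[str, int, str, str]] = []
    minis: list[AuxMini] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if line.startswith("#params"):
                for item in fields[1:]:
                    key, value = item.split("=")
                    params[key] = int(value)
            elif line.startswith("#univ"):
                universal_lengths[fields[1]] = int(fields[2])
            elif line.startswith("#"):
                continue
            elif fields[0] == "EDIT":
                edits.append((fields[1], int(fields[2]), fields[3], fields[4]))
            elif fields[0] == "MINI":
                if fields[1] != fields[4]:
                    raise ValueError(
                        f"MINI line maps across chromosomes: {line!r}")
                minis.append(AuxMini(
                    chrom=fields[1], aug_start=int(fields[2]),
                    aug_end=int(fields[3]), univ_start=int(fields[5]),
                    variant_edits=_parse_variant_spec(fields[6]),
                ))
            else:
                raise ValueError(f"unrecognized aux-map line: {line!r}")
    missing = {"k", "m", "w"} - set(params)
    if missing:
        raise ValueError(f"aux map missing parameters: {sorted(missing)}")
    return AuxMap(edits=edits, minis=minis, k=params["k"], m=params["m"],
                  w=params["w"], universal_lengths=universal_lengths)
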