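"""Readers/writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; the SAM/VCF boundary is
the single place 1-based coordinates appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALLOWED_CIGAR_OPS = frozenset("MIDS")

# pysam numeric CIGAR op -> character (subset we support)
_PYSAM_OPS = {0: "M", 1: "I", 2: "D", 4: "S"}


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass
class AlignmentRecord:
    """One read-to-ORF alignment (the subset of SAM the pipeline consumes)."""

    read_id: str
    orf_id: str
    pos: int  # 0-based start on the ORF
    cigar: list[tuple[str, int]]
    nm: int
    mapq: int = 60
    is_primary: bool = True
    is_reverse: bool = False
    seq: str | None = None

    def __post_init__(self) -> None:
        if self.nm < 0:
            raise FormatError(f"record {self.read_id}: NM must be >= 0")
        bad = {op for op, _ in self.cigar} - ALLOWED_CIGAR_OPS
        if bad:
            raise FormatError(f"record {self.read_id}: unsupported CIGAR ops {sorted(bad)}")

    @property
    def aligned_columns(self) -> int:
        """Number of aligned columns: total length of M, I and D operations."""
        return sum(n for op, n in self.cigar if op in "MID")

    @property
    def reference_span(self) -> int:
        """Bases of the reference consumed (M and D operations)."""
        return sum(n for op, n in self.cigar if op in "MD")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into (op, length) tuples (M/I/D/S subset)."""
    out: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise FormatError(f"bad CIGAR {cigar!r}")
            if ch not in ALLOWED_CIGAR_OPS:
                raise FormatError(f"unsupported CIGAR op {ch!r} in {cigar!r}")
            out.append((ch, int(num)))
            num = ""
    if num:
        raise FormatError(f"bad CIGAR {cigar!r}: trailing number")
    return out


def cigar_to_string(cigar: Iterable[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def read_sam(path: str | Path, on_missing_nm: str = "fail") -> list[AlignmentRecord]:
    """Read a SAM file into :class:`AlignmentRecord` objects.

    Unmapped records are dropped. A mapped record without an NM tag triggers an
    error by default (``on_missing_nm="skip"`` drops it instead).
    """
    if on_missing_nm not in ("fail", "skip"):
        raise ValueError("on_missing_nm must be 'fail' or 'skip'")
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if not aln.has_tag("NM"):
                if on_missing_nm == "fail":
                    raise FormatError(f"mapped record {aln.query_name!r} lacks an NM tag")
                continue
            cigar = []
            for op_code, n in aln.cigartuples or []:
                op = _PYSAM_OPS.get(op_code)
                if op is None:
                    raise FormatError(
                        f"record {aln.query_name!r}: unsupported CIGAR op code {op_code}"
                    )
                cigar.append((op, n))
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    orf_id=aln.reference_name,
                    pos=aln.reference_start,  # pysam is already 0-based
                    cigar=cigar,
                    nm=int(aln.get_tag("NM")),
                    mapq=aln.mapping_quality,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                    is_reverse=aln.is_reverse,
                    seq=aln.query_sequence,
                )
            )
    return records


def write_sam(
    records: Iterable[AlignmentRecord],
    references: dict[str, str],
    path: str | Path,
) -> None:
    """Write alignment records as headered SAM (FLAG 0/16, MAPQ, CIGAR, NM tag)."""
    names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(references[name])} for name in names],
    }
    tid = {name: i for i, name in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_id = tid[rec.orf_id]
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            a.cigarstring = cigar_to_string(rec.cigar)
            flag = 0
            if rec.is_reverse:
                flag |= 16
            if not rec.is_primary:
                flag |= 256
            a.flag = flag
            if rec.seq is not None:
                a.query_sequence = rec.seq
            a.set_tag("NM", rec.nm, value_type="i")
            out.write(a)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> sequence dict (wrapped lines tolerated)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write FASTA with 60-column line wrapping."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    """Write (read_id, sequence) pairs as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=EFF,Number=1,Type=String,Description="Coding effect: SYN, NONSYN or NA">
##INFO=<ID=CODON,Number=1,Type=String,Description="Reference codon > alternate codon">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
"""


def write_vcf(calls: Iterable, references: dict[str, str], path: str | Path,
              sample_names: list[str] | None = None) -> None:
    """Write SNV calls (see :class:`bloomshift.snv.SnvCall`) as VCF 4.2.

    CHROM is the ORF id and POS the 1-based position within the ORF. Raises if
    a call's ref allele disagrees with the reference sequence.
    """
    calls = list(calls)
    if sample_names is None:
        seen: list[str] = []
        for c in calls:
            for s in c.samples:
                if s not in seen:
                    seen.append(s)
        sample_names = seen
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, seq in references.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + sample_names) + "\n")
        for c in sorted(calls, key=lambda c: (c.orf_id, c.pos, c.alt_allele)):
            ref_seq = references.get(c.orf_id)
            if ref_seq is None:
                raise FormatError(f"call references unknown ORF {c.orf_id!r}")
            if ref_seq[c.pos - 1] != c.ref_allele:
                raise FormatError(
                    f"call at {c.orf_id}:{c.pos}: ref allele {c.ref_allele} disagrees "
                    f"with reference base {ref_seq[c.pos - 1]}"
                )
            info = f"EFF={c.effect}"
            if c.codon_change:
                info += f";CODON={c.codon_change}"
            fields = [c.orf_id, str(c.pos), ".", c.ref_allele, c.alt_allele, ".", "PASS",
                      info, "DP:AD:AF"]
            for s in sample_names:
                st = c.samples.get(s)
                if st is None:
                    fields.append(".:.:.")
                else:
                    depth, alt = st
                    af = alt / depth if depth else 0.0
                    fields.append(f"{depth}:{depth - alt},{alt}:{af:.6g}")
            fh.write("\t".join(fields) + "\n")


@dataclass
class VcfRecord:
    """A parsed VCF data line (round-trip checking and downstream joins)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    effect: str
    codon_change: str | None
    samples: dict[str, tuple[int, int]] = field(default_factory=dict)  # sample -> (depth, alt)


def read_vcf(path: str | Path) -> list[VcfRecord]:
    records: list[VcfRecord] = []
    sample_names: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                sample_names = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            info = dict(kv.split("=", 1) for kv in parts[7].split(";") if "=" in kv)
            samples: dict[str, tuple[int, int]] = {}
            for name, cell in zip(sample_names, parts[9:]):
                if cell.startswith("."):
                    continue
                dp, ad, _af = cell.split(":")
                samples[name] = (int(dp), int(ad.split(",")[1]))
            records.append(
                VcfRecord(
                    chrom=parts[0],
                    pos=int(parts[1]),
                    ref=parts[3],
                    alt=parts[4],
                    effect=info.get("EFF", "NA"),
                    codon_change=info.get("CODON"),
                    samples=samples,
                )
            )
    return records
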