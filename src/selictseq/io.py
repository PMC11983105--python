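"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
All internal coordinates are 0-based, half-open.  BED output is 0-based;
the human-readable TSV report additionally carries a 1-based position
column.  Single-end SAM input (as emitted by the read simulator) is
treated as proper-paired R1 by convention, so the same ingest filters
apply to both simulated and real paired-end data.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
import yaml
from Bio import SeqIO

logger = logging.getLogger("selictseq")

SAMPLE_LABELS = ("sgrna_pos_rep1", "sgrna_pos_rep2", "sgrna_neg", "untreated")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class ReferenceGenome:
    """Reference sequences keyed by contig name (uppercase A/C/G/T/N)."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.sequences[contig][max(start, 0) : end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences


@dataclass
class AlignedRead:
    """One mapped read in reference orientation.

    ``seq`` is stored as in SAM: reverse-complemented onto the reference
    plus strand for minus-strand alignments.  The read's 5' end in
    sequencing orientation is therefore the leftmost aligned base for
    plus-strand reads and the rightmost for minus-strand reads.
    """

    name: str
    contig: str
    start: int  # 0-based leftmost aligned reference position
    strand: str  # '+' or '-'
    mapq: int
    cigar: list[tuple[str, int]]  # ops in {M, I, D, S}
    seq: str
    is_r1: bool = True
    is_proper_pair: bool = True
    is_primary: bool = True
    is_duplicate: bool = False
    sample: str = "sgrna_pos_rep1"

    def query_length_from_cigar(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """0-based exclusive rightmost aligned reference position."""
        return self.start + self.reference_span()


@dataclass
class SiteExclusionList:
    """Known-variant positions to drop from candidate calling."""

    positions: set[tuple[str, int]] = field(default_factory=set)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.positions

    @classmethod
    def from_bed(cls, path: str | Path) -> "SiteExclusionList":
        positions = set()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 BED columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            positions.update((contig, p) for p in range(start, end))
        return cls(positions)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "SiteExclusionList":
        positions = set()
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                positions.add((rec.chrom, rec.pos - 1))
        return cls(positions)

    @classmethod
    def from_path(cls, path: str | Path) -> "SiteExclusionList":
        p = str(path)
        if p.endswith((".vcf", ".vcf.gz")):
            return cls.from_vcf(path)
        return cls.from_bed(path)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, pos in sorted(self.positions):
                fh.write(f"{contig}\t{pos}\t{pos + 1}\n")


@dataclass
class SgRNASpec:
    """20-nt protospacer (nontarget-strand, 5'->3', PAM-distal position 1)
    plus a 3-nt IUPAC PAM pattern and the deaminase editing window."""

    protospacer: str
    pam: str = "NGG"
    editing_window: tuple[int, int] = (3, 9)

    def __post_init__(self) -> None:
        self.protospacer = self.protospacer.upper()
        self.pam = self.pam.upper()
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3:
            raise ValueError("PAM pattern must be 3 nt")

    @property
    def target_with_pam(self) -> str:
        return self.protospacer + self.pam


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline.

    Defaults reproduce the published filter cascade, so an empty config
    file runs the standard pipeline.
    """

    # candidate-site filter cascade
    min_mapq: int = 5
    min_depth: int = 5
    min_mut_reads: int = 3
    min_mut_prop: float = 0.20
    max_background_reads: int = 1
    consec_window: int = 3
    consec_mut_rate: float = 0.20
    # Cas9-dependent classification
    min_score: float = 0.6
    min_edited_ratio: float = 0.2
    max_neg_reads: int = 1
    # binding-site search (alignment scores per position)
    window_flank: int = 100
    match: int = 5
    mismatch: int = -4
    gap_open: int = -24
    gap_extend: int = -8
    max_penalty: int = 70
    # Cas9-independent classification
    indep_min_neg_reads: int = 3
    # amplicon quantification
    amplicon_min_cov: int = 500
    umi_len: int = 5
    min_agreement: float = 0.6
    # feature extraction
    seed_region: tuple[int, int] = (11, 20)
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_mapq", "min_depth", "min_mut_reads",
                     "max_background_reads", "max_neg_reads", "window_flank",
                     "indep_min_neg_reads", "amplicon_min_cov", "umi_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("min_mut_prop", "min_score", "min_edited_ratio",
                     "min_agreement", "consec_mut_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("editing_window", "seed_region"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file into memory, uppercasing all sequences.

    Raises ``FormatError`` on an empty file, duplicate contig names, or
    characters outside A/C/G/T/N.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: contig {rec.id!r} has empty sequence")
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise FormatError(f"{path}: contig {rec.id!r} has non-DNA characters {bad}")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome(sequences)


_CIGAR_OPS = "MIDNSHP=X"


def _decode_cigar(rec: pysam.AlignedSegment) -> list[tuple[str, int]]:
    out = []
    for op, n in rec.cigartuples or []:
        c = _CIGAR_OPS[op]
        if c in "=X":
            c = "M"
        elif c == "H":
            continue  # hard clips consume nothing we track
        elif c not in "MIDS":
            raise FormatError(f"unsupported CIGAR op {c!r} in read {rec.query_name}")
        out.append((c, n))
    return out


def read_alignments(
    path: str | Path,
    sample_label: str,
    drop_filtered: bool = True,
) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM/BAM file.

    With ``drop_filtered`` (default), reads that are unmapped, secondary,
    supplementary, duplicate, not R1, or (for paired data) not in a
    proper pair are skipped — mirroring the upstream samtools/Picard
    contract.  Unpaired reads count as proper-paired R1 by convention.
    """
    save = pysam.set_verbosity(0)
    try:
        mode = "rb" if str(path).endswith(".bam") else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                if rec.reference_name is None:
                    raise FormatError(
                        f"{path}: read {rec.query_name} references unknown contig"
                    )
                paired = rec.is_paired
                read = AlignedRead(
                    name=rec.query_name or "",
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    cigar=_decode_cigar(rec),
                    seq=(rec.query_sequence or "").upper(),
                    is_r1=rec.is_read1 if paired else True,
                    is_proper_pair=rec.is_proper_pair if paired else True,
                    is_primary=not (rec.is_secondary or rec.is_supplementary),
                    is_duplicate=rec.is_duplicate,
                    sample=sample_label,
                )
                if drop_filtered and not (
                    read.is_r1
                    and read.is_proper_pair
                    and read.is_primary
                    and not read.is_duplicate
                ):
                    continue
                yield read
    finally:
        pysam.set_verbosity(save)


def write_sam(
    reads: Iterable[AlignedRead],
    genome: ReferenceGenome,
    path: str | Path,
) -> int:
    """Write reads as single-end SAM with a header from the genome."""
    contigs = list(genome.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome.sequences[c])} for c in contigs],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = read.name
            rec.reference_id = tid[read.contig]
            rec.reference_start = read.start
            rec.mapping_quality = read.mapq
            rec.cigarstring = "".join(f"{ln}{op}" for op, ln in read.cigar)
            rec.query_sequence = read.seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            flag = 0
            if read.strand == "-":
                flag |= 0x10
            if read.is_duplicate:
                flag |= 0x400
            if not read.is_primary:
                flag |= 0x100
            rec.flag = flag
            fh.write(rec)
            n += 1
    return n


# ---------------------------------------------------------------------------
# site call output

REPORT_COLUMNS = [
    "contig", "position", "position_1based", "strand", "classification",
    "selict_score", "edited_ratio",
    "rep1_depth", "rep1_mut_reads", "rep1_trunc_mut_reads",
    "rep2_depth", "rep2_mut_reads", "rep2_trunc_mut_reads",
    "neg_mut_reads", "untreated_mut_reads",
    "filter_i", "filter_ii", "filter_iii", "filter_iv", "filter_v",
    "filter_vi", "filter_vii", "passed",
    "binding_strand", "binding_start", "binding_end", "binding_penalty",
    "aligned_target", "aligned_window", "pam_observed", "pam_canonical",
    "protospacer_position", "in_editing_window", "in_protospacer",
    "out_of_protospacer", "edit_strand", "distance_to_protospacer",
]


def write_report_tsv(rows: Iterable[dict], path: str | Path) -> None:
    """Write the full audit report; one row per site, fixed column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(_format_cell(row.get(c)) for c in REPORT_COLUMNS) + "\n"
            )


def _format_cell(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_report_tsv(path: str | Path) -> list[dict]:
    """Read back a site report; numeric fields are restored exactly."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty report")
    header = lines[0].split("\t")
    int_cols = {
        "position", "position_1based",
        "rep1_depth", "rep1_mut_reads", "rep1_trunc_mut_reads",
        "rep2_depth", "rep2_mut_reads", "rep2_trunc_mut_reads",
        "neg_mut_reads", "untreated_mut_reads",
        "binding_start", "binding_end", "binding_penalty",
        "protospacer_position", "distance_to_protospacer",
    }
    float_cols = {"selict_score", "edited_ratio"}
    bool_cols = {c for c in header if c.startswith("filter_")} | {
        "passed", "pam_canonical", "in_editing_window", "in_protospacer",
        "out_of_protospacer",
    }
    rows = []
    for line in lines[1:]:
        cells = line.split("\t")
        row: dict = {}
        for col, cell in zip(header, cells):
            if cell == ".":
                row[col] = None
            elif col in int_cols:
                row[col] = int(cell)
            elif col in float_cols:
                row[col] = float(cell)
            elif col in bool_cols:
                row[col] = cell == "1"
            else:
                row[col] = cell
        rows.append(row)
    return rows


def write_sites_bed(rows: Iterable[dict], path: str | Path) -> None:
    """BED6 of called sites; score column = Selict-seq score x1000, clamped."""
    with open(path, "w") as fh:
        for row in rows:
            score = row.get("selict_score") or 0.0
            bed_score = int(min(max(round(score * 1000), 0), 1000))
            fh.write(
                f"{row['contig']}\t{row['position']}\t{row['position'] + 1}\t"
                f"{row.get('classification', 'candidate')}\t{bed_score}\t"
                f"{row['strand']}\n"
            )


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        force=True,
    )
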