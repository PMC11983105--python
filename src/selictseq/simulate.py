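"""Synthetic genomes, planted edit sites, and reads carrying the
truncated-read editing signature.

The simulator emits already-aligned single-end SAM records whose
positions are ground truth, so the whole caller/classifier stack is
testable without an external aligner.  Signal reads reproduce the
enrichment chemistry's operational signature: endonuclease V cleaves the
second phosphodiester bond 3' of a deoxyinosine, so a captured fragment
begins one base 5' of the edited adenosine and the edited base sits at
read position 2.  On plus-strand alignments this is an A->G call at the
second aligned base; on minus-strand alignments the read's 5' end is the
rightmost reference base and the signature appears as T->C on the
reference plus strand.

Truncated signal fragments are strongly enriched by the streptavidin /
EndoV capture relative to background coverage; ``signal_read_multiplier``
models that enrichment as extra trials in the per-site binomial draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._dna import revcomp
from .io import AlignedRead, ReferenceGenome, SAMPLE_LABELS, SgRNASpec, SiteExclusionList

SITE_CLASSES = ("on_target", "cas9_dependent", "cas9_independent",
                "endogenous_dI", "snp")

# which samples receive truncated signal reads for each site class
_SIGNAL_SAMPLES = {
    "on_target": {"sgrna_pos_rep1", "sgrna_pos_rep2"},
    "cas9_dependent": {"sgrna_pos_rep1", "sgrna_pos_rep2"},
    "cas9_independent": {"sgrna_pos_rep1", "sgrna_pos_rep2", "sgrna_neg"},
    "endogenous_dI": set(SAMPLE_LABELS),
    "snp": set(),
}

_SAMPLE_INDEX = {label: i for i, label in enumerate(SAMPLE_LABELS)}


@dataclass
class SiteSpec:
    """Request for one planted site.

    Protospacer coordinates are 1-based, position 1 PAM-distal.  For
    ``cas9_dependent``/``on_target`` sites, ``edit_position`` names the
    protospacer position of the edited adenosine; ``mismatches`` lists
    protospacer positions substituted in the genomic copy; ``dna_bulges``
    insert an extra genomic base after the named position; ``rna_bulges``
    delete the genomic base at the named position (leaving the sgRNA base
    unpaired).  ``pam`` may be a concrete 3-mer or an IUPAC pattern to
    instantiate.
    """

    site_class: str
    edit_fraction: float = 0.5
    strand: str | None = None  # '+', '-' or None = random
    edit_position: int = 5
    mismatches: tuple[int, ...] = ()
    dna_bulges: tuple[int, ...] = ()
    rna_bulges: tuple[int, ...] = ()
    pam: str = "NGG"

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if not 0.0 <= self.edit_fraction <= 1.0:
            raise ValueError("edit_fraction must be in [0, 1]")


@dataclass
class PlantedSite:
    """Ground truth for one planted locus."""

    contig: str
    position: int  # 0-based position of the edited base on the reference
    strand_of_edit: str  # strand whose adenosine is deaminated
    site_class: str
    edit_fraction: float
    # binding description (cas9_dependent / on_target only)
    binding_start: int | None = None  # half-open genomic interval of
    binding_end: int | None = None  # protospacer+PAM on the reference
    binding_strand: str | None = None
    mismatches: tuple[int, ...] = ()
    dna_bulges: tuple[int, ...] = ()
    rna_bulges: tuple[int, ...] = ()
    pam: str | None = None
    snp_alt: str | None = None


@dataclass
class SimulationParams:
    genome_length: int = 1_000_000
    gc_content: float = 0.41
    depth: float = 30.0
    read_length: int = 100
    signal_read_multiplier: float = 4.0
    sequencing_error_rate: float = 0.001
    mapq_values: tuple[int, ...] = (0, 2, 20, 40, 60)
    mapq_probs: tuple[float, ...] = (0.02, 0.02, 0.06, 0.10, 0.80)
    signal_mapq: int = 60
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.sequencing_error_rate <= 0.05:
            raise ValueError("sequencing_error_rate must be in [0, 0.05]")
        if abs(sum(self.mapq_probs) - 1.0) > 1e-9:
            raise ValueError("mapq_probs must sum to 1")


def make_genome(params: SimulationParams, contig: str = "chr_sim") -> ReferenceGenome:
    """Random genome at the requested GC content; deterministic per seed."""
    if params.genome_length < 1000:
        raise ValueError("genome_length must be >= 1 kb")
    rng = np.random.default_rng([params.seed, 101])
    gc = params.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=params.genome_length, p=probs)
    seq = codes.astype(np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return ReferenceGenome({contig: lut[seq].tobytes().decode("ascii")})


class PlacementError(RuntimeError):
    """A requested site could not be placed on the genome."""


def _instantiate_pam(pattern: str, rng: np.random.Generator) -> str:
    from ._dna import IUPAC

    return "".join(sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))] for c in pattern)


def _genomic_protospacer(
    spec: SiteSpec, sgrna: SgRNASpec, rng: np.random.Generator
) -> tuple[str, int]:
    """Build the genomic (protospacer-strand) sequence for a planted
    binding site and the offset of the edited A within it."""
    proto = list(sgrna.protospacer)
    if spec.edit_position in spec.mismatches or spec.edit_position in spec.rna_bulges:
        raise PlacementError(
            f"edit position {spec.edit_position} conflicts with requested "
            f"mismatches/bulges in {spec!r}"
        )
    if proto[spec.edit_position - 1] != "A":
        raise PlacementError(
            f"protospacer position {spec.edit_position} is "
            f"{proto[spec.edit_position - 1]}, not A; cannot plant edit"
        )
    for p in spec.mismatches:
        if not 1 <= p <= 20:
            raise PlacementError(f"mismatch position {p} outside protospacer")
        others = [b for b in "ACGT" if b != proto[p - 1]]
        proto[p - 1] = others[rng.integers(3)]
    # apply bulges right-to-left so earlier indices stay valid
    edits = [(p, "rna") for p in spec.rna_bulges] + [(p, "dna") for p in spec.dna_bulges]
    edit_offset = spec.edit_position - 1
    for p, kind in sorted(edits, reverse=True):
        if not 1 <= p <= 20:
            raise PlacementError(f"bulge position {p} outside protospacer")
        if kind == "rna":
            del proto[p - 1]
            if p - 1 < edit_offset:
                edit_offset -= 1
        else:
            proto.insert(p, "ACGT"[rng.integers(4)])
            if p <= edit_offset:
                edit_offset += 1
    pam = _instantiate_pam(spec.pam, rng)
    return "".join(proto) + pam, edit_offset


def plant_sites(
    genome: ReferenceGenome,
    sgrna: SgRNASpec,
    spec_list: Sequence[SiteSpec],
    seed: int,
    min_separation: int = 300,
) -> tuple[ReferenceGenome, list[PlantedSite]]:
    """Rewrite the genome so each requested site exists, returning the
    modified genome and the ground-truth site list.

    Sites are placed non-overlapping with ``min_separation`` bp between
    them so the 100-nt binding-site search windows never collide.
    """
    rng = np.random.default_rng([seed, 202])
    contig = next(iter(genome.sequences))
    seq = bytearray(genome.sequences[contig].encode("ascii"))
    occupied: list[tuple[int, int]] = []
    planted: list[PlantedSite] = []

    def reserve(start: int, end: int) -> bool:
        for s, e in occupied:
            if start < e + min_separation and s < end + min_separation:
                return False
        occupied.append((start, end))
        return True

    for spec in spec_list:
        strand = spec.strand or ("+" if rng.random() < 0.5 else "-")
        placed = False
        for _attempt in range(200):
            if spec.site_class in ("cas9_dependent", "on_target"):
                gseq, edit_offset = _genomic_protospacer(spec, sgrna, rng)
                L = len(gseq)
                start = int(rng.integers(200, len(seq) - 200 - L))
                if not reserve(start, start + L):
                    continue
                if strand == "+":
                    seq[start : start + L] = gseq.encode("ascii")
                    pos = start + edit_offset
                else:
                    seq[start : start + L] = revcomp(gseq).encode("ascii")
                    pos = start + L - 1 - edit_offset
                planted.append(
                    PlantedSite(
                        contig=contig,
                        position=pos,
                        strand_of_edit=strand,
                        site_class=spec.site_class,
                        edit_fraction=spec.edit_fraction,
                        binding_start=start,
                        binding_end=start + L,
                        binding_strand=strand,
                        mismatches=tuple(spec.mismatches),
                        dna_bulges=tuple(spec.dna_bulges),
                        rna_bulges=tuple(spec.rna_bulges),
                        pam=gseq[-3:],
                    )
                )
                placed = True
                break
            else:
                pos = int(rng.integers(200, len(seq) - 200))
                if not reserve(pos - 2, pos + 3):
                    continue
                if spec.site_class == "snp":
                    seq[pos] = ord("A")
                    planted.append(
                        PlantedSite(
                            contig=contig,
                            position=pos,
                            strand_of_edit="+",
                            site_class="snp",
                            edit_fraction=0.5,
                            snp_alt="G",
                        )
                    )
                else:
                    # TAT context centered on the edited A (on edit strand)
                    ctx = "TAT" if strand == "+" else "ATA"
                    seq[pos - 1 : pos + 2] = ctx.encode("ascii")
                    planted.append(
                        PlantedSite(
                            contig=contig,
                            position=pos,
                            strand_of_edit=strand,
                            site_class=spec.site_class,
                            edit_fraction=spec.edit_fraction,
                        )
                    )
                placed = True
                break
        if not placed:
            raise PlacementError(f"could not place site after retries: {spec!r}")

    new_genome = ReferenceGenome({contig: seq.decode("ascii")})
    _check_planted(new_genome, planted)
    return new_genome, planted


def _check_planted(genome: ReferenceGenome, planted: Iterable[PlantedSite]) -> None:
    for site in planted:
        ref = genome.sequences[site.contig][site.position]
        want = "A" if site.strand_of_edit == "+" else "T"
        if site.site_class != "snp" and ref != want:
            raise PlacementError(
                f"planted {site.site_class} at {site.contig}:{site.position} "
                f"has reference {ref}, expected {want}"
            )


def _inject_errors(seq: bytearray, rng: np.random.Generator, rate: float,
                   skip: int | None = None) -> None:
    if rate <= 0:
        return
    n_err = rng.binomial(len(seq), rate)
    for _ in range(n_err):
        i = int(rng.integers(len(seq)))
        if i == skip:
            continue
        alts = [b for b in b"ACGT" if b != seq[i]]
        seq[i] = alts[rng.integers(3)]


def simulate_reads(
    genome: ReferenceGenome,
    planted: Sequence[PlantedSite],
    params: SimulationParams,
    sample_label: str,
) -> Iterator[AlignedRead]:
    """Yield aligned reads for one sample.

    Background reads fragment the genome uniformly; truncated signal
    reads are added per planted site according to the site class's
    sample membership; SNP alleles appear as ordinary 50% variants in
    every sample.
    """
    if sample_label not in SAMPLE_LABELS:
        raise ValueError(f"unknown sample label {sample_label!r}")
    rng = np.random.default_rng([params.seed, 303, _SAMPLE_INDEX[sample_label]])
    contig = next(iter(genome.sequences))
    ref = genome.sequences[contig].encode("ascii")
    glen = len(ref)
    L = params.read_length
    err = params.sequencing_error_rate

    snps = sorted(
        (s.position, ord(s.snp_alt or "G")) for s in planted if s.site_class == "snp"
    )
    snp_pos = np.array([p for p, _ in snps], dtype=np.int64)

    n_background = int(round(params.depth * glen / L))
    starts = rng.integers(0, glen - L + 1, size=n_background)
    strands = rng.random(n_background) < 0.5
    mapqs = rng.choice(params.mapq_values, size=n_background, p=params.mapq_probs)

    counter = 0
    for k in range(n_background):
        s = int(starts[k])
        seq = bytearray(ref[s : s + L])
        if len(snp_pos):
            lo = np.searchsorted(snp_pos, s)
            hi = np.searchsorted(snp_pos, s + L)
            for idx in range(lo, hi):
                if rng.random() < 0.5:
                    seq[int(snp_pos[idx]) - s] = snps[idx][1]
        _inject_errors(seq, rng, err)
        strand = "-" if strands[k] else "+"
        counter += 1
        yield AlignedRead(
            name=f"{sample_label}_bg_{counter}",
            contig=contig,
            start=s,
            strand=strand,
            mapq=int(mapqs[k]),
            cigar=[("M", L)],
            seq=seq.decode("ascii"),
            sample=sample_label,
        )

    for site in planted:
        if sample_label not in _SIGNAL_SAMPLES[site.site_class]:
            continue
        n_trials = int(round(params.depth * params.signal_read_multiplier))
        n_signal = rng.binomial(n_trials, site.edit_fraction)
        for j in range(n_signal):
            if site.strand_of_edit == "+":
                s = site.position - 1
                e = min(s + L, glen)
                if s < 0:
                    continue
                seq = bytearray(ref[s:e])
                _inject_errors(seq, rng, err, skip=1)
                seq[1] = ord("G")  # edited A read as G at read position 2
                strand = "+"
            else:
                e = site.position + 2  # rightmost aligned base = position + 1
                s = max(e - L, 0)
                if e > glen:
                    continue
                seq = bytearray(ref[s:e])
                off = site.position - s
                _inject_errors(seq, rng, err, skip=off)
                seq[off] = ord("C")  # T->C on the plus strand
                strand = "-"
            yield AlignedRead(
                name=f"{sample_label}_sig_{site.position}_{j}",
                contig=contig,
                start=s,
                strand=strand,
                mapq=params.signal_mapq,
                cigar=[("M", len(seq))],
                seq=seq.decode("ascii"),
                sample=sample_label,
            )


def exclusion_list_from_truth(planted: Iterable[PlantedSite]) -> SiteExclusionList:
    """Known-variant list covering the planted SNP positions."""
    return SiteExclusionList(
        {(s.contig, s.position) for s in planted if s.site_class == "snp"}
    )


def write_truth_tsv(planted: Iterable[PlantedSite], path: str | Path) -> None:
    cols = ["contig", "position", "strand_of_edit", "site_class", "edit_fraction",
            "binding_start", "binding_end", "binding_strand", "mismatches",
            "dna_bulges", "rna_bulges", "pam", "snp_alt"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in planted:
            row = [s.contig, s.position, s.strand_of_edit, s.site_class,
                   s.edit_fraction,
                   s.binding_start, s.binding_end, s.binding_strand,
                   ",".join(map(str, s.mismatches)) or ".",
                   ",".join(map(str, s.dna_bulges)) or ".",
                   ",".join(map(str, s.rna_bulges)) or ".",
                   s.pam, s.snp_alt]
            fh.write("\t".join("." if v is None else str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# UMI-tagged amplicon simulation


@dataclass
class AmpliconTruth:
    reference: str
    edit_profile: dict[int, float]
    n_molecules: int


def simulate_amplicon(
    reference: str,
    edit_profile: dict[int, float],
    n_molecules: int,
    reads_per_molecule: int,
    umi_len: int = 5,
    error_rate: float = 0.001,
    seed: int = 0,
) -> Iterator[tuple[str, str, str]]:
    """Yield (name, R1, R2) for UMI-tagged amplicon read pairs.

    Each molecule draws a forward and reverse UMI and a fixed
    edited/unedited state per profiled position (A->G on the forward
    strand); its PCR duplicates share UMI and state and differ only by
    independent sequencing errors.  R1 = fwd UMI + amplicon; R2 = rev
    UMI + reverse-complemented amplicon.
    """
    rng = np.random.default_rng([seed, 404])
    bases = "ACGT"
    for off in edit_profile:
        if reference[off] != "A":
            raise ValueError(f"edit_profile offset {off} is not an A in the reference")
    for mol in range(n_molecules):
        umi_f = "".join(bases[rng.integers(4)] for _ in range(umi_len))
        umi_r = "".join(bases[rng.integers(4)] for _ in range(umi_len))
        mol_seq = bytearray(reference.encode("ascii"))
        for off, prob in edit_profile.items():
            if rng.random() < prob:
                mol_seq[off] = ord("G")
        fwd = mol_seq.decode("ascii")
        rev = revcomp(fwd)
        for dup in range(reads_per_molecule):
            # errors hit the payload only; UMI bases are kept error-free so
            # grouping stays exact (a UMI error would found a spurious group)
            b1 = bytearray(fwd.encode("ascii"))
            b2 = bytearray(rev.encode("ascii"))
            _inject_errors(b1, rng, error_rate)
            _inject_errors(b2, rng, error_rate)
            yield (
                f"mol{mol}_dup{dup}",
                umi_f + b1.decode("ascii"),
                umi_r + b2.decode("ascii"),
            )


def write_fastq_pair(
    pairs: Iterable[tuple[str, str, str]], r1_path: str | Path, r2_path: str | Path
) -> int:
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for name, r1, r2 in pairs:
            f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")
            n += 1
    return n
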