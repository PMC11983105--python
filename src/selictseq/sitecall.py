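"""Strand-resolved pileups and the candidate dA-to-dI filter cascade.

A deaminated adenosine is read as G, and the enrichment chemistry cleaves
two bases 3' of it, so a captured fragment aligns with the edited base at
read position 2 from its 5' end.  Candidates are therefore positions with
A->G calls on plus-strand reads (or T->C on minus-strand reads) at the
second aligned base, passed through seven filters:

  i    contributing reads have mapping quality >= ``min_mapq``
  ii   depth >= ``min_depth`` in each treated replicate
  iii  truncated-mutant reads >= ``min_mut_reads`` and a proportion
       >= ``min_mut_prop`` of strand depth, per replicate
  iv   <= ``max_background_reads`` mutant reads in the untreated sample
  v    filters ii+iii hold in both treated replicates
  vi   not inside a run of 3 consecutive positions with >20% mutation
       rate and >= 2 distinct substitution types (alignment artifacts)
  vii  not on the known-variant exclusion list
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from ._dna import BASES, seq_to_codes
from .io import AlignedRead, PipelineConfig, ReferenceGenome, SiteExclusionList

STRAND_INDEX = {"+": 0, "-": 1}
# mutant call observed on the reference plus strand, per edit strand
MUT_CALL = {"+": ("A", "G"), "-": ("T", "C")}
_CODE = {b: i for i, b in enumerate(BASES)}

TREATED_REPS = ("sgrna_pos_rep1", "sgrna_pos_rep2")


@dataclass
class StrandPileupColumn:
    """Per-position, per-strand tallies at one reference position."""

    contig: str
    position: int
    depth: dict[str, int]
    base_counts: dict[str, dict[str, int]]
    trunc_total_count: dict[str, int]
    trunc_mut_count: dict[str, int]


class SamplePileup:
    """Array-backed strand-separated pileup for one sample.

    Soft-clipped bases contribute nothing; reads below ``min_mapq`` are
    excluded entirely.  The "second aligned base" of a read is the second
    query base consuming reference counted from the read's 5' end in
    sequencing orientation — for minus-strand reads, the second base from
    the alignment's right edge.
    """

    def __init__(self, genome: ReferenceGenome, min_mapq: int = 5) -> None:
        self.genome = genome
        self.min_mapq = min_mapq
        self.n_reads = 0
        self._base: dict[str, np.ndarray] = {}
        self._trunc_total: dict[str, np.ndarray] = {}
        self._trunc_mut: dict[str, np.ndarray] = {}
        self._ref_codes: dict[str, np.ndarray] = {}
        for contig, seq in genome.sequences.items():
            L = len(seq)
            self._base[contig] = np.zeros((2, 5, L), dtype=np.uint32)
            self._trunc_total[contig] = np.zeros((2, L), dtype=np.uint32)
            self._trunc_mut[contig] = np.zeros((2, L), dtype=np.uint32)
            self._ref_codes[contig] = seq_to_codes(seq)

    def add_read(self, read: AlignedRead) -> None:
        if read.mapq < self.min_mapq:
            return
        if not (read.is_r1 and read.is_proper_pair and read.is_primary
                and not read.is_duplicate):
            return
        if read.contig not in self._base:
            raise KeyError(f"read {read.name} references unknown contig {read.contig}")
        base = self._base[read.contig]
        s = STRAND_INDEX[read.strand]
        codes = seq_to_codes(read.seq)

        blocks: list[tuple[int, int, int]] = []  # (query0, ref0, length)
        qpos, rpos = 0, read.start
        for op, n in read.cigar:
            if op == "M":
                blocks.append((qpos, rpos, n))
                qpos += n
                rpos += n
            elif op in ("I", "S"):
                qpos += n
            elif op == "D":
                rpos += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")
        if not blocks:
            return
        for q0, r0, n in blocks:
            np.add.at(base[s], (codes[q0 : q0 + n], np.arange(r0, r0 + n)), 1)

        n_aligned = sum(n for _, _, n in blocks)
        if n_aligned >= 2:
            idx = 1 if read.strand == "+" else n_aligned - 2
            acc = 0
            for q0, r0, n in blocks:
                if idx < acc + n:
                    q, r = q0 + (idx - acc), r0 + (idx - acc)
                    break
                acc += n
            self._trunc_total[read.contig][s, r] += 1
            ref_b, mut_b = MUT_CALL[read.strand]
            if (self._ref_codes[read.contig][r] == _CODE[ref_b]
                    and codes[q] == _CODE[mut_b]):
                self._trunc_mut[read.contig][s, r] += 1
        self.n_reads += 1

    def add_reads(self, reads: Iterable[AlignedRead]) -> "SamplePileup":
        for read in reads:
            self.add_read(read)
        return self

    # ---- accessors -------------------------------------------------------

    def column(self, contig: str, position: int) -> StrandPileupColumn:
        base = self._base[contig][:, :, position]
        return StrandPileupColumn(
            contig=contig,
            position=position,
            depth={"+": int(base[0].sum()), "-": int(base[1].sum())},
            base_counts={
                st: {b: int(base[i, j]) for j, b in enumerate(BASES + "N")}
                for st, i in STRAND_INDEX.items()
            },
            trunc_total_count={
                st: int(self._trunc_total[contig][i, position])
                for st, i in STRAND_INDEX.items()
            },
            trunc_mut_count={
                st: int(self._trunc_mut[contig][i, position])
                for st, i in STRAND_INDEX.items()
            },
        )

    def strand_depth(self, contig: str, position: int, edit_strand: str) -> int:
        s = STRAND_INDEX[edit_strand]
        return int(self._base[contig][s, :, position].sum())

    def mut_reads(self, contig: str, position: int, edit_strand: str) -> int:
        s = STRAND_INDEX[edit_strand]
        return int(self._base[contig][s, _CODE[MUT_CALL[edit_strand][1]], position])

    def trunc_mut(self, contig: str, position: int, edit_strand: str) -> int:
        s = STRAND_INDEX[edit_strand]
        return int(self._trunc_mut[contig][s, position])

    def candidate_positions(self, contig: str) -> list[tuple[int, str]]:
        """Positions with at least one truncated-mutant read, per strand."""
        out = []
        for strand, s in STRAND_INDEX.items():
            for p in np.nonzero(self._trunc_mut[contig][s])[0]:
                out.append((int(p), strand))
        return out


def build_pileup(
    reads: Iterable[AlignedRead], genome: ReferenceGenome, min_mapq: int = 5
) -> SamplePileup:
    """Accumulate one sample's reads into a strand-resolved pileup."""
    return SamplePileup(genome, min_mapq).add_reads(reads)


def selict_score(trunc_mut_reads: int, depth: int) -> float:
    """Fraction of covering reads on the edited strand that carry the
    truncated-mutant signature; the site-confidence score."""
    if depth <= 0:
        raise ZeroDivisionError("depth must be positive for a defined score")
    return min(max(trunc_mut_reads / depth, 0.0), 1.0)


@dataclass
class CandidateSite:
    """A putative dA-to-dI locus with its full filter audit trail."""

    contig: str
    position: int
    strand: str  # strand of the edited adenosine
    per_sample: dict[str, dict[str, int]]  # label -> depth/mut_reads/trunc_mut_reads
    edited_ratio: float = 0.0
    selict_score: float = 0.0
    filters: dict[str, bool] = field(default_factory=dict)
    replicate_presence: tuple[bool, bool] = (False, False)

    @property
    def passed(self) -> bool:
        return all(self.filters.values())


def _consecutive_artifact(
    pooled_base: np.ndarray,
    ref_codes: np.ndarray,
    position: int,
    window: int,
    rate_threshold: float,
) -> bool:
    """True if ``position`` falls in a run of ``window`` consecutive
    positions, each with mutation rate > ``rate_threshold``, carrying at
    least two distinct (modal) substitution types."""
    L = ref_codes.shape[0]
    for w0 in range(position - window + 1, position + 1):
        if w0 < 0 or w0 + window > L:
            continue
        types = set()
        ok = True
        for p in range(w0, w0 + window):
            ref = ref_codes[p]
            counts = pooled_base[:4, p].astype(np.int64)
            depth = int(counts.sum())
            if ref > 3 or depth == 0:
                ok = False
                break
            mut = depth - int(counts[ref])
            if mut / depth <= rate_threshold:
                ok = False
                break
            alt_counts = counts.copy()
            alt_counts[ref] = -1
            types.add((int(ref), int(alt_counts.argmax())))
        if ok and len(types) >= 2:
            return True
    return False


def call_candidates(
    pileups_by_sample: dict[str, SamplePileup],
    exclusion_list: SiteExclusionList,
    config: PipelineConfig,
) -> list[CandidateSite]:
    """Run the filter cascade over every position with truncated-mutant
    support in either treated replicate.

    Filters ii and iii are recorded as "passes in at least one treated
    replicate"; filter v requires both replicates, so a site seen in one
    replicate only is audited as failing v.
    """
    for label in TREATED_REPS + ("sgrna_neg", "untreated"):
        if label not in pileups_by_sample:
            raise ValueError(f"missing pileup for required sample {label!r}")
    reps = [pileups_by_sample[r] for r in TREATED_REPS]
    genome = reps[0].genome

    candidates: list[CandidateSite] = []
    for contig in genome.sequences:
        ref_codes = reps[0]._ref_codes[contig]
        pooled_base = sum(
            rep._base[contig].sum(axis=0, dtype=np.int64) for rep in reps
        )
        seen: set[tuple[int, str]] = set()
        for rep in reps:
            seen.update(rep.candidate_positions(contig))
        for position, strand in sorted(seen):
            per_sample = {}
            for label, pileup in pileups_by_sample.items():
                per_sample[label] = {
                    "depth": pileup.strand_depth(contig, position, strand),
                    "mut_reads": pileup.mut_reads(contig, position, strand),
                    "trunc_mut_reads": pileup.trunc_mut(contig, position, strand),
                }
            rep_stats = [per_sample[r] for r in TREATED_REPS]
            rep_depth_ok = [st["depth"] >= config.min_depth for st in rep_stats]
            rep_mut_ok = [
                st["trunc_mut_reads"] >= config.min_mut_reads
                and st["depth"] > 0
                and st["trunc_mut_reads"] / st["depth"] >= config.min_mut_prop
                for st in rep_stats
            ]
            presence = tuple(d and m for d, m in zip(rep_depth_ok, rep_mut_ok))
            filters = {
                "i": True,  # enforced at pileup construction
                "ii": any(rep_depth_ok),
                "iii": any(rep_mut_ok),
                "iv": per_sample["untreated"]["mut_reads"]
                <= config.max_background_reads,
                "v": all(presence),
                "vi": not _consecutive_artifact(
                    pooled_base, ref_codes, position,
                    config.consec_window, config.consec_mut_rate,
                ),
                "vii": (contig, position) not in exclusion_list,
            }
            pooled_depth = sum(st["depth"] for st in rep_stats)
            pooled_mut = sum(st["mut_reads"] for st in rep_stats)
            pooled_trunc = sum(st["trunc_mut_reads"] for st in rep_stats)
            site = CandidateSite(
                contig=contig,
                position=position,
                strand=strand,
                per_sample=per_sample,
                edited_ratio=(pooled_mut / pooled_depth) if pooled_depth else 0.0,
                selict_score=(
                    selict_score(pooled_trunc, pooled_depth) if pooled_depth else 0.0
                ),
                filters=filters,
                replicate_presence=presence,
            )
            candidates.append(site)
    return candidates
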