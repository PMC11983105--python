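"""sgRNA binding-site discovery around candidate edits and
Cas9-dependent / Cas9-independent / endogenous classification.

The on-target sequence (20-nt protospacer + 3-nt IUPAC PAM pattern) is
aligned semiglobally against the +/-100 nt window around each candidate,
on both strands.  A binding site is kept when its alignment penalty
(score shortfall from a perfect match, ``5 x target length - score``)
is below ``max_penalty``.

Classification:
  cas9_dependent    score >= 0.6, edited ratio >= 0.2, <= 1 mutant read
                    in the sgRNA(-) sample, and a binding site exists;
  cas9_independent  >= 3 mutant reads in sgRNA(-) and none in untreated;
  endogenous_dI     mutant reads in both sgRNA(-) and untreated (these
                    sites typically fail the untreated-background filter
                    of the candidate cascade, which is ignored here so
                    endogenous deoxyinosines can still be labelled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._dna import BASES, iupac_match, matches_pattern, revcomp
from .align import Alignment, AlignParams, semiglobal_align
from .io import PipelineConfig, ReferenceGenome, SgRNASpec
from .sitecall import CandidateSite

logger = logging.getLogger("selictseq")

CANONICAL_PAM = "NRG"
PROTOSPACER_LEN = 20


@dataclass
class BindingSite:
    """Best semiglobal alignment of the on-target sequence near a site."""

    contig: str
    ref_start: int
    ref_end: int  # half-open; reference span consumed by the alignment
    strand: str  # orientation of the protospacer on the reference
    aligned_target: str
    aligned_window: str
    score: int
    penalty: int
    pam_observed: str
    pam_canonical: bool
    mismatch_positions: tuple[int, ...]  # protospacer coords, 1 = PAM-distal
    target_bulges: tuple[int, ...]  # gap in window: sgRNA base unpaired
    dna_bulges: tuple[int, ...]  # gap in target: extra genomic base
    pam_mismatches: int
    # reference position -> (protospacer coord of the column, exact?);
    # "exact" is False for columns where the genomic base is a bulge
    ref_to_proto: dict[int, tuple[int, bool]]


@dataclass
class OffTargetCall:
    """A classified site with positional annotations."""

    site: CandidateSite
    classification: str
    binding: BindingSite | None = None
    protospacer_position: int | None = None
    in_editing_window: bool = False
    in_protospacer: bool = False
    out_of_protospacer: bool = False
    edit_strand: str | None = None  # nontarget_strand / target_strand
    distance_to_protospacer: int | None = None


def _binding_from_alignment(
    aln: Alignment,
    contig: str,
    strand: str,
    window_start_ref: int,
    window_end_ref: int,
    target_len: int,
    params: AlignParams,
) -> BindingSite:
    """Project an alignment's columns onto reference coordinates and
    protospacer positions, collecting mismatch/bulge features."""

    def ref_of(window_index: int) -> int:
        if strand == "+":
            return window_start_ref + window_index
        return window_end_ref - 1 - window_index

    mismatches: list[int] = []
    target_bulges: list[int] = []
    dna_bulges: list[int] = []
    pam_chars: list[str] = []
    pam_mismatches = 0
    ref_to_proto: dict[int, tuple[int, bool]] = {}
    ti = 0  # target chars consumed (1-based protospacer coord after ++)
    wi = aln.window_start
    ref_positions: list[int] = []
    for t_char, w_char in zip(aln.aligned_target, aln.aligned_window):
        if t_char != "-" and w_char != "-":
            ti += 1
            r = ref_of(wi)
            wi += 1
            ref_positions.append(r)
            ref_to_proto[r] = (ti, True)
            if ti > PROTOSPACER_LEN:
                pam_chars.append(w_char)
            if not iupac_match(t_char, w_char):
                if ti <= PROTOSPACER_LEN:
                    mismatches.append(ti)
                else:
                    pam_mismatches += 1
        elif w_char == "-":  # sgRNA base unpaired
            ti += 1
            target_bulges.append(min(ti, PROTOSPACER_LEN))
        else:  # extra genomic base
            r = ref_of(wi)
            wi += 1
            ref_positions.append(r)
            ref_to_proto[r] = (max(ti, 1), False)
            dna_bulges.append(max(ti, 1))
    pam_observed = "".join(pam_chars)
    return BindingSite(
        contig=contig,
        ref_start=min(ref_positions),
        ref_end=max(ref_positions) + 1,
        strand=strand,
        aligned_target=aln.aligned_target,
        aligned_window=aln.aligned_window,
        score=aln.score,
        penalty=params.match * target_len - aln.score,
        pam_observed=pam_observed,
        pam_canonical=(
            len(pam_observed) == 3 and matches_pattern(CANONICAL_PAM, pam_observed)
        ),
        mismatch_positions=tuple(mismatches),
        target_bulges=tuple(target_bulges),
        dna_bulges=tuple(dna_bulges),
        pam_mismatches=pam_mismatches,
        ref_to_proto=ref_to_proto,
    )


def find_binding_site(
    candidate: CandidateSite,
    sgrna: SgRNASpec,
    genome: ReferenceGenome,
    config: PipelineConfig | None = None,
) -> BindingSite | None:
    """Search both strands of the window around a candidate for the best
    sgRNA binding site; None if the penalty threshold is not met."""
    if config is None:
        config = PipelineConfig()
    params = AlignParams(config.match, config.mismatch, config.gap_open,
                         config.gap_extend)
    target = sgrna.target_with_pam
    contig_seq = genome.sequences[candidate.contig]
    ws = max(0, candidate.position - config.window_flank)
    we = min(len(contig_seq), candidate.position + config.window_flank + 1)
    window = contig_seq[ws:we]
    if len(window) < len(target):
        return None

    fwd = semiglobal_align(target, window, params)
    rev = semiglobal_align(target, revcomp(window), params)
    if rev.score > fwd.score:
        aln, strand = rev, "-"
    else:
        aln, strand = fwd, "+"
    binding = _binding_from_alignment(aln, candidate.contig, strand, ws, we,
                                      len(target), params)
    if binding.penalty >= config.max_penalty:
        return None
    return binding


def annotate_position(
    call: OffTargetCall, sgrna: SgRNASpec
) -> OffTargetCall:
    """Fill protospacer-coordinate, editing-window, strand and distance
    annotations from the call's binding site.

    Distances are signed in protospacer coordinates: 0 inside positions
    1-20, negative PAM-distal of position 1, positive PAM-proximal
    beyond position 20 (the PAM occupies distances 1-3).
    """
    binding = call.binding
    if binding is None:
        return call
    pos = call.site.position
    # the protospacer sits on the nontarget strand; the edit is on the
    # target strand when its adenosine lies on the opposite strand
    call.edit_strand = (
        "nontarget_strand" if call.site.strand == binding.strand else "target_strand"
    )
    if pos in binding.ref_to_proto:
        ti, _exact = binding.ref_to_proto[pos]
        if ti <= PROTOSPACER_LEN:
            call.protospacer_position = ti
            call.in_protospacer = True
            call.out_of_protospacer = False
            call.distance_to_protospacer = 0
            lo, hi = sgrna.editing_window
            call.in_editing_window = lo <= ti <= hi
        else:
            call.protospacer_position = None
            call.in_protospacer = False
            call.out_of_protospacer = True
            call.distance_to_protospacer = ti - PROTOSPACER_LEN
        return call
    # outside the aligned span: measure from the protospacer ends
    proto_refs = [r for r, (ti, exact) in binding.ref_to_proto.items()
                  if exact and ti <= PROTOSPACER_LEN]
    if binding.strand == "+":
        r1, r20 = min(proto_refs), max(proto_refs)
        distance = pos - r1 if pos < r1 else pos - r20
    else:
        r1, r20 = max(proto_refs), min(proto_refs)
        distance = r1 - pos if pos > r1 else r20 - pos
    call.protospacer_position = None
    call.in_protospacer = False
    call.out_of_protospacer = True
    call.distance_to_protospacer = int(distance)
    return call


def classify(
    candidates: Sequence[CandidateSite],
    sgrna: SgRNASpec,
    genome: ReferenceGenome,
    config: PipelineConfig | None = None,
) -> list[OffTargetCall]:
    """Classify candidate sites; sites matching no class are omitted."""
    if config is None:
        config = PipelineConfig()
    calls: list[OffTargetCall] = []
    for site in candidates:
        neg_mut = site.per_sample.get("sgrna_neg", {}).get("mut_reads", 0)
        unt_mut = site.per_sample.get("untreated", {}).get("mut_reads", 0)
        if site.passed:
            if (
                site.selict_score >= config.min_score
                and site.edited_ratio >= config.min_edited_ratio
                and neg_mut <= config.max_neg_reads
            ):
                binding = find_binding_site(site, sgrna, genome, config)
                if binding is not None:
                    call = OffTargetCall(site, "cas9_dependent", binding)
                    calls.append(annotate_position(call, sgrna))
                    continue
            if neg_mut >= config.indep_min_neg_reads and unt_mut == 0:
                calls.append(OffTargetCall(site, "cas9_independent"))
                continue
        else:
            # sites rejected only by the untreated-background filter can
            # still be labelled endogenous deoxyinosine
            other_filters = all(v for k, v in site.filters.items() if k != "iv")
            if other_filters and neg_mut >= 1 and unt_mut >= 1:
                calls.append(OffTargetCall(site, "endogenous_dI"))
    return calls


def motif_pfm(
    independent_calls: Sequence[OffTargetCall],
    genome: ReferenceGenome,
    flank: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Position frequency matrix of the sequence context around edited
    adenosines, with per-column information content.

    Contexts are oriented so the edited base is always A, at column
    ``flank + 1`` (position 3 of a 5-mer for the default flank of 2);
    minus-strand edits are reverse-complemented.  Returns the 4 x (2
    flank + 1) count matrix and the information content in bits.
    """
    if not independent_calls:
        raise ValueError("no calls supplied for motif construction")
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=np.int64)
    used = 0
    for call in independent_calls:
        site = call.site
        seq = genome.sequences[site.contig]
        lo, hi = site.position - flank, site.position + flank + 1
        if lo < 0 or hi > len(seq):
            logger.warning(
                "skipping site %s:%d: flank extends beyond contig",
                site.contig, site.position,
            )
            continue
        context = seq[lo:hi]
        if site.strand == "-":
            context = revcomp(context)
        for j, b in enumerate(context):
            if b in BASES:
                counts[BASES.index(b), j] += 1
        used += 1
    if used == 0:
        raise ValueError("all sites skipped; no motif contexts available")
    pfm = pd.DataFrame(counts, index=list(BASES),
                       columns=[str(i + 1) for i in range(width)])
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=0)
    return pfm, info
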