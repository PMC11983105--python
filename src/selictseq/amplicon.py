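"""UMI-based consensus editing-rate quantification for targeted
amplicon sequencing.

Read pairs carry a 5-nt UMI at the start of each mate; the combined
10-nt UMI identifies one input molecule.  Reads sharing a UMI are
collapsed to a per-position majority consensus (sequencing-error
correction + PCR deduplication in one step); ambiguous positions become
N and are excluded from rate denominators.  Editing rate per position is
(edited molecules)/(qualified molecules) x 100, background-subtracted
against a matched untreated control and gated at >= 500x consensus
coverage in both samples.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from ._dna import revcomp

logger = logging.getLogger("selictseq")


@dataclass
class UmiGroup:
    """All read pairs sharing one combined UMI, with their consensus."""

    combined_umi: str
    n_members: int
    consensus: str
    agreement: list[float]  # per-position fraction agreeing with the call


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str]]:
    """Stream (R1, R2) sequences from paired FASTQ files."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for rec1, rec2 in zip(f1, f2):
            yield rec1.sequence.upper(), rec2.sequence.upper()


def group_and_collapse(
    read_pairs: Iterable[tuple[str, str]],
    umi_len: int = 5,
    min_agreement: float = 0.6,
) -> list[UmiGroup]:
    """Group read pairs by exact combined UMI and build one consensus
    molecule per group.

    The molecule sequence is voted per position by all R1 payloads and
    reverse-complemented R2 payloads in the group; positions whose modal
    base falls below ``min_agreement`` are set to N.  Pairs whose UMI
    contains N are discarded (counted and logged).
    """
    groups: dict[str, list[tuple[str, str]]] = defaultdict(list)
    n_discarded = 0
    for r1, r2 in read_pairs:
        umi = r1[:umi_len] + r2[:umi_len]
        if "N" in umi or len(umi) < 2 * umi_len:
            n_discarded += 1
            continue
        groups[umi].append((r1[umi_len:], revcomp(r2[umi_len:])))
    if n_discarded:
        logger.info("discarded %d read pairs with ambiguous UMIs", n_discarded)

    out: list[UmiGroup] = []
    for umi, members in groups.items():
        length = max(len(s) for pair in members for s in pair)
        consensus = []
        agreement = []
        for i in range(length):
            votes = Counter()
            for fwd, rev in members:
                if i < len(fwd):
                    votes[fwd[i]] += 1
                if i < len(rev):
                    votes[rev[i]] += 1
            votes.pop("N", None)
            total = sum(votes.values())
            if total == 0:
                consensus.append("N")
                agreement.append(0.0)
                continue
            base, count = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            frac = count / total
            consensus.append(base if frac >= min_agreement else "N")
            agreement.append(frac)
        out.append(
            UmiGroup(
                combined_umi=umi,
                n_members=len(members),
                consensus="".join(consensus),
                agreement=agreement,
            )
        )
    return out


@dataclass
class PositionRate:
    """Per-position editing quantification with the coverage gate."""

    locus: str
    offset: int
    ref_base: str
    edited_reads: int
    total_qualified_reads: int
    control_edited: int
    control_total: int
    raw_rate: float  # percent
    control_rate: float  # percent
    net_rate: float  # percent, floored at 0
    passes_coverage: bool


def editing_rates(
    test_molecules: Sequence[UmiGroup],
    control_molecules: Sequence[UmiGroup],
    reference: str,
    min_cov: int = 500,
    locus: str = "amplicon",
) -> list[PositionRate]:
    """Per-position A->G editing rates from consensus molecules.

    Molecules are assumed aligned ungapped to the amplicon reference.
    Rates are computed at every reference adenosine; positions failing
    the coverage gate in either sample are reported but flagged.
    """
    reference = reference.upper()
    for group in list(test_molecules[:1]) + list(control_molecules[:1]):
        if len(group.consensus) != len(reference):
            raise ValueError(
                f"molecule length {len(group.consensus)} != reference "
                f"length {len(reference)}"
            )
    rates: list[PositionRate] = []
    for i, ref_base in enumerate(reference):
        if ref_base != "A":
            continue
        edited = total = 0
        for mol in test_molecules:
            b = mol.consensus[i]
            if b == "N":
                continue
            total += 1
            if b == "G":
                edited += 1
        c_edited = c_total = 0
        for mol in control_molecules:
            b = mol.consensus[i]
            if b == "N":
                continue
            c_total += 1
            if b == "G":
                c_edited += 1
        raw = 100.0 * edited / total if total else 0.0
        ctrl = 100.0 * c_edited / c_total if c_total else 0.0
        rates.append(
            PositionRate(
                locus=locus,
                offset=i,
                ref_base=ref_base,
                edited_reads=edited,
                total_qualified_reads=total,
                control_edited=c_edited,
                control_total=c_total,
                raw_rate=raw,
                control_rate=ctrl,
                net_rate=max(raw - ctrl, 0.0),
                passes_coverage=(total >= min_cov and c_total >= min_cov),
            )
        )
    return rates


def write_rates_tsv(rates: Sequence[PositionRate], path: str | Path) -> None:
    cols = ["locus", "offset", "ref_base", "edited_reads",
            "total_qualified_reads", "control_edited", "control_total",
            "raw_rate", "control_rate", "net_rate", "passes_coverage"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rates:
            fh.write(
                "\t".join(
                    str(int(v)) if isinstance(v, bool) else
                    (f"{v:.6g}" if isinstance(v, float) else str(v))
                    for v in (getattr(r, c) for c in cols)
                )
                + "\n"
            )
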