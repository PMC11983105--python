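"""End-to-end orchestration: simulate -> call -> classify -> features,
with a reproducibility manifest and truth-based scoring."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

from . import __version__
from .features import FEATURE_NAMES, feature_table, ridge_fit
from .io import (
    PipelineConfig,
    SAMPLE_LABELS,
    SgRNASpec,
    read_alignments,
    write_report_tsv,
    write_sam,
    write_sites_bed,
)
from .offtarget import OffTargetCall, motif_pfm
from .simulate import (
    PlantedSite,
    SimulationParams,
    SiteSpec,
    exclusion_list_from_truth,
    make_genome,
    plant_sites,
    simulate_reads,
    write_truth_tsv,
)
from .sitecall import CandidateSite, build_pileup, call_candidates

logger = logging.getLogger("selictseq")

DEFAULT_PROTOSPACER = "GCAATACGGATCAGTCAGCA"  # A at editing-window positions
DEFAULT_EDIT_POSITION = 6

_PAM_CYCLE = ("AGG", "TGG", "CGG", "GGG", "AGA")
_MISMATCH_PATTERNS = ((), (1,), (1, 3), (2, 9, 16), (1, 3, 11, 19))


def default_site_specs(
    n_dependent: int = 20,
    n_independent: int = 8,
    n_endogenous: int = 3,
    n_snp: int = 3,
    edit_fraction: float = 0.5,
    edit_position: int = DEFAULT_EDIT_POSITION,
    with_bulges: bool = True,
) -> list[SiteSpec]:
    """A representative planting mix: one perfect on-target, Cas9-dependent
    sites cycling 0-4 mismatches and PAM variants (plus DNA/RNA-bulge
    sites), TAT-context Cas9-independent sites, endogenous deoxyinosines
    and SNP confounders."""
    specs: list[SiteSpec] = [
        SiteSpec("on_target", edit_fraction=edit_fraction,
                 edit_position=edit_position, pam="AGG")
    ]
    for k in range(n_dependent):
        spec = SiteSpec(
            "cas9_dependent",
            edit_fraction=edit_fraction,
            edit_position=edit_position,
            mismatches=_MISMATCH_PATTERNS[k % len(_MISMATCH_PATTERNS)],
            pam=_PAM_CYCLE[k % len(_PAM_CYCLE)],
        )
        if with_bulges and k % 7 == 5:
            spec = dataclasses.replace(spec, dna_bulges=(12,), mismatches=())
        elif with_bulges and k % 7 == 6:
            spec = dataclasses.replace(spec, rna_bulges=(15,), mismatches=())
        specs.append(spec)
    specs += [SiteSpec("cas9_independent", edit_fraction=edit_fraction)
              for _ in range(n_independent)]
    specs += [SiteSpec("endogenous_dI", edit_fraction=edit_fraction)
              for _ in range(n_endogenous)]
    specs += [SiteSpec("snp") for _ in range(n_snp)]
    return specs


def candidate_report_rows(
    candidates: Sequence[CandidateSite],
    calls: Sequence[OffTargetCall] | None = None,
) -> list[dict]:
    """Flatten candidates (+ optional classifications) into report rows."""
    by_key: dict[tuple[str, int, str], OffTargetCall] = {}
    for call in calls or []:
        by_key[(call.site.contig, call.site.position, call.site.strand)] = call
    rows = []
    for site in candidates:
        call = by_key.get((site.contig, site.position, site.strand))
        row = {
            "contig": site.contig,
            "position": site.position,
            "position_1based": site.position + 1,
            "strand": site.strand,
            "classification": call.classification if call else None,
            "selict_score": site.selict_score,
            "edited_ratio": site.edited_ratio,
            "neg_mut_reads": site.per_sample["sgrna_neg"]["mut_reads"],
            "untreated_mut_reads": site.per_sample["untreated"]["mut_reads"],
            "passed": site.passed,
        }
        for i, rep in enumerate(("sgrna_pos_rep1", "sgrna_pos_rep2"), start=1):
            stats = site.per_sample[rep]
            row[f"rep{i}_depth"] = stats["depth"]
            row[f"rep{i}_mut_reads"] = stats["mut_reads"]
            row[f"rep{i}_trunc_mut_reads"] = stats["trunc_mut_reads"]
        for rule, ok in site.filters.items():
            row[f"filter_{rule}"] = ok
        if call and call.binding:
            b = call.binding
            row.update(
                binding_strand=b.strand,
                binding_start=b.ref_start,
                binding_end=b.ref_end,
                binding_penalty=b.penalty,
                aligned_target=b.aligned_target,
                aligned_window="".join(
                    w.lower() if t != "-" and w != "-" and w.lower() != t.lower()
                    else w
                    for t, w in zip(b.aligned_target, b.aligned_window)
                ),
                pam_observed=b.pam_observed,
                pam_canonical=b.pam_canonical,
                protospacer_position=call.protospacer_position,
                in_editing_window=call.in_editing_window,
                in_protospacer=call.in_protospacer,
                out_of_protospacer=call.out_of_protospacer,
                edit_strand=call.edit_strand,
                distance_to_protospacer=call.distance_to_protospacer,
            )
        rows.append(row)
    return rows


def score_against_truth(
    calls: Sequence[OffTargetCall], planted: Sequence[PlantedSite]
) -> dict:
    """Recall/precision of Cas9-dependent classification against the
    planted truth (exact-position matching)."""
    truth_dep = {
        (s.contig, s.position)
        for s in planted
        if s.site_class in ("cas9_dependent", "on_target")
    }
    called_dep = {
        (c.site.contig, c.site.position)
        for c in calls
        if c.classification == "cas9_dependent"
    }
    truth_indep = {
        (s.contig, s.position) for s in planted if s.site_class == "cas9_independent"
    }
    called_indep = {
        (c.site.contig, c.site.position)
        for c in calls
        if c.classification == "cas9_independent"
    }
    tp = len(truth_dep & called_dep)
    return {
        "n_planted_dependent": len(truth_dep),
        "n_called_dependent": len(called_dep),
        "dependent_recall": tp / len(truth_dep) if truth_dep else None,
        "dependent_precision": tp / len(called_dep) if called_dep else None,
        "false_dependent_calls": len(called_dep - truth_dep),
        "n_planted_independent": len(truth_indep),
        "n_called_independent": len(called_indep),
        "independent_recall": (
            len(truth_indep & called_indep) / len(truth_indep) if truth_indep else None
        ),
        "endogenous_misclassified": sum(
            1
            for c in calls
            if c.classification in ("cas9_dependent", "cas9_independent")
            and any(
                s.site_class == "endogenous_dI"
                and (s.contig, s.position) == (c.site.contig, c.site.position)
                for s in planted
            )
        ),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    outdir: str | Path,
    config: PipelineConfig | None = None,
    sim_params: SimulationParams | None = None,
    sgrna: SgRNASpec | None = None,
    site_specs: Sequence[SiteSpec] | None = None,
) -> dict:
    """Simulate a dataset, run the full caller/classifier/feature stack,
    and write all stage outputs plus a manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    sim_params = sim_params or SimulationParams(seed=config.seed)
    sgrna = sgrna or SgRNASpec(DEFAULT_PROTOSPACER)
    site_specs = list(site_specs) if site_specs is not None else default_site_specs()

    manifest: dict = {
        "version": __version__,
        "seed": sim_params.seed,
        "config": config.to_dict(),
        "sim_params": dataclasses.asdict(sim_params),
        "sgrna": dataclasses.asdict(sgrna),
        "stages": {},
    }

    # -- simulate ----------------------------------------------------------
    genome = make_genome(sim_params)
    genome, planted = plant_sites(genome, sgrna, site_specs, sim_params.seed)
    genome_path = outdir / "sim_genome.fasta"
    with open(genome_path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    truth_path = outdir / "sim_truth.tsv"
    write_truth_tsv(planted, truth_path)
    exclusion = exclusion_list_from_truth(planted)
    exclusion_path = outdir / "sim_exclusion.bed"
    exclusion.write_bed(exclusion_path)

    sam_paths = {}
    read_counts = {}
    for label in SAMPLE_LABELS:
        path = outdir / f"sim_{label}.sam"
        n = write_sam(simulate_reads(genome, planted, sim_params, label),
                      genome, path)
        sam_paths[label] = path
        read_counts[label] = n
    manifest["stages"]["simulate"] = {
        "n_planted_sites": len(planted),
        "reads": read_counts,
    }

    # -- call --------------------------------------------------------------
    pileups = {
        label: build_pileup(
            read_alignments(path, label), genome, config.min_mapq
        )
        for label, path in sam_paths.items()
    }
    candidates = call_candidates(pileups, exclusion, config)
    passing = [c for c in candidates if c.passed]
    manifest["stages"]["call"] = {
        "n_candidates": len(candidates),
        "n_passing": len(passing),
    }

    # -- classify ----------------------------------------------------------
    from .offtarget import classify

    calls = classify(candidates, sgrna, genome, config)
    rows = candidate_report_rows(candidates, calls)
    write_report_tsv(rows, outdir / "sites_report.tsv")
    write_sites_bed(
        [r for r in rows if r["passed"]], outdir / "sites_called.bed"
    )
    indep = [c for c in calls if c.classification == "cas9_independent"]
    if indep:
        pfm, info = motif_pfm(indep, genome)
        pfm_out = pfm.copy()
        pfm_out.loc["info_bits"] = info.round(4)
        pfm_out.to_csv(outdir / "independent_motif_pfm.tsv", sep="\t")
    by_class: dict[str, int] = {}
    for call in calls:
        by_class[call.classification] = by_class.get(call.classification, 0) + 1
    manifest["stages"]["classify"] = {"n_calls": len(calls), "by_class": by_class}

    # -- features ----------------------------------------------------------
    dep = [c for c in calls if c.classification == "cas9_dependent"]
    if len(dep) >= 2 * len(FEATURE_NAMES):
        table = feature_table(dep, config.seed_region)
        table.to_csv(outdir / "features.tsv", sep="\t", index=False)
        fit = ridge_fit(table[FEATURE_NAMES], table["outcome"].to_numpy())
        fit.summary().to_csv(outdir / "ridge_coefficients.tsv", sep="\t")
        manifest["stages"]["features"] = {
            "n_sites": len(table),
            "lambda": fit.lam,
            "dropped": fit.dropped,
        }
    else:
        manifest["stages"]["features"] = {
            "n_sites": len(dep),
            "skipped": "fewer sites than 2 x features",
        }

    manifest["truth_scoring"] = score_against_truth(calls, planted)
    manifest["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
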