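"""Per-patient orchestration: enumerate, predict, score, select, report.

The unit of work is a :class:`PatientBundle` (validated variants, expression
table, HLA alleles, shared reference proteome).  ``run_patient`` enumerates
candidate windows for both MHC classes, takes each peptide's best rank
across the patient's class-matched alleles, scores every candidate, keeps
those with a strictly positive priority score, and picks one vaccine long
peptide per variant for the top-ranked distinct variants.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .affinity import PredictorError, RankPredictor
from .io import (
    ExpressionTable,
    HLAAllele,
    MhcClass,
    PipelineConfig,
    Proteome,
    SomaticVariant,
    ValidationError,
)
from .peptides import LongPeptide, apply_variant, enumerate_windows, make_long_peptide
from .scoring import (
    ProteomeIndex,
    ScoredCandidate,
    compute_quartiles,
    score_candidate,
)

logger = logging.getLogger(__name__)


@dataclass
class PatientBundle:
    """All per-patient inputs, validated against one reference proteome."""

    patient_id: str
    proteome: Proteome
    variants: Sequence[SomaticVariant]
    expression: ExpressionTable
    alleles: Sequence[HLAAllele]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValidationError(f"patient {self.patient_id}: no HLA alleles")
        for v in self.variants:
            v.validate_against(self.proteome.protein_for(v))

    def alleles_of(self, mhc_class: MhcClass) -> list[HLAAllele]:
        return sorted(
            (a for a in self.alleles if a.mhc_class is mhc_class),
            key=lambda a: a.name,
        )


@dataclass
class SelectionReport:
    """Ranked scored candidates, the selected subset and the long peptides."""

    patient_id: str
    candidates: list[ScoredCandidate]  # every scored window, ranked
    selected: list[ScoredCandidate]    # score > threshold, same order
    long_peptides: list[LongPeptide]
    summary: dict
    config: PipelineConfig
    predictor_name: str


def _candidate_sort_key(c: ScoredCandidate):
    # score descending, then rank ascending, then sequence, then variant label
    return (-c.neoantigen_score, c.rank, c.peptide.sequence, c.peptide.source_variant.label)


def select_candidates(
    scored: Sequence[ScoredCandidate], config: PipelineConfig
) -> list[ScoredCandidate]:
    """Keep candidates with score strictly above the threshold, in the
    deterministic ranking order (score desc, rank asc, peptide, variant)."""
    kept = [c for c in scored if c.neoantigen_score > config.score_threshold]
    return sorted(kept, key=_candidate_sort_key)


def select_long_peptides(
    ranked: Sequence[ScoredCandidate],
    proteome: Proteome,
    config: PipelineConfig,
) -> list[LongPeptide]:
    """One long peptide per distinct variant, walking the candidate ranking.

    Class II candidates are excluded from the walk unless
    ``config.include_class2`` is set; with ``config.require_strong`` only
    variants carrying at least one strong-binder window are eligible.
    Selection stops after ``top_n_long_peptides`` distinct variants.
    """
    strong_variants = {
        c.peptide.source_variant.label
        for c in ranked
        if c.binder_class == "strong"
    }
    chosen: dict[str, LongPeptide] = {}
    for cand in ranked:
        if len(chosen) >= config.top_n_long_peptides:
            break
        if cand.peptide.mhc_class is MhcClass.II and not config.include_class2:
            continue
        variant = cand.peptide.source_variant
        if variant.label in chosen:
            continue
        if config.require_strong and variant.label not in strong_variants:
            continue
        protein = proteome.protein_for(variant)
        chosen[variant.label] = make_long_peptide(protein, variant, config)
    return list(chosen.values())


def run_patient(
    bundle: PatientBundle,
    predictor: RankPredictor,
    config: PipelineConfig | None = None,
) -> SelectionReport:
    """End-to-end prioritization for one patient.

    Every variant is enumerated for both MHC classes (a class with no
    patient allele is skipped with a warning); ranks are predicted once per
    unique (peptide, allele) pair; every window is scored; the report is
    fully deterministic for a deterministic predictor.
    """
    config = config or PipelineConfig()
    quartiles = compute_quartiles(bundle.expression)
    index = ProteomeIndex(bundle.proteome)

    # enumerate all candidate windows per class
    peptides_by_class: dict[MhcClass, list] = {MhcClass.I: [], MhcClass.II: []}
    for variant in bundle.variants:
        mutant = apply_variant(bundle.proteome.protein_for(variant), variant)
        for mhc_class in (MhcClass.I, MhcClass.II):
            if not bundle.alleles_of(mhc_class):
                continue
            peptides_by_class[mhc_class].extend(
                enumerate_windows(mutant, mhc_class, config)
            )
    for mhc_class in (MhcClass.I, MhcClass.II):
        if not bundle.alleles_of(mhc_class):
            logger.warning(
                "patient %s: no class %s allele; class skipped",
                bundle.patient_id, mhc_class.value,
            )

    # batch-predict unique peptides per class and reduce to the best allele
    best: dict[tuple[str, MhcClass], tuple[HLAAllele, float]] = {}
    for mhc_class, peps in peptides_by_class.items():
        unique = sorted({p.sequence for p in peps})
        if not unique:
            continue
        for allele in bundle.alleles_of(mhc_class):
            try:
                ranks = predictor.predict(unique, allele)
            except Exception as exc:
                raise PredictorError(
                    f"predictor {predictor.name!r} failed on {len(unique)} "
                    f"class {mhc_class.value} peptides for {allele}: {exc}"
                ) from exc
            if len(ranks) != len(unique):
                raise PredictorError(
                    f"predictor {predictor.name!r} returned {len(ranks)} ranks "
                    f"for {len(unique)} peptides ({allele})"
                )
            for seq, rank in zip(unique, ranks):
                key = (seq, mhc_class)
                if key not in best or rank < best[key][1]:
                    best[key] = (allele, rank)

    scored = [
        score_candidate(
            pep, *best[(pep.sequence, mhc_class)],
            bundle.expression, quartiles, index, config,
        )
        for mhc_class, peps in peptides_by_class.items()
        for pep in peps
    ]
    ranked = sorted(scored, key=_candidate_sort_key)
    selected = select_candidates(ranked, config)
    long_peptides = select_long_peptides(selected, bundle.proteome, config)

    summary = {
        "patient_id": bundle.patient_id,
        "n_mutations": len(bundle.variants),
        "n_mhc1_neoantigens": sum(
            1 for c in selected if c.peptide.mhc_class is MhcClass.I
        ),
        "n_mhc2_neoantigens": sum(
            1 for c in selected if c.peptide.mhc_class is MhcClass.II
        ),
        "n_strong": sum(1 for c in selected if c.binder_class == "strong"),
        "n_weak": sum(1 for c in selected if c.binder_class == "weak"),
        "n_long_peptides": len(long_peptides),
    }
    return SelectionReport(
        patient_id=bundle.patient_id,
        candidates=ranked,
        selected=selected,
        long_peptides=long_peptides,
        summary=summary,
        config=config,
        predictor_name=predictor.name,
    )


CANDIDATE_COLUMNS = [
    "gene", "variant", "mhc_class", "peptide", "wt_peptide", "allele", "rank",
    "binder_class", "affinity_score", "tpm", "expression_score", "vaf",
    "penalty", "mismatches", "neoantigen_score",
]


def candidates_frame(candidates: Sequence[ScoredCandidate]) -> pd.DataFrame:
    rows = [
        {
            "gene": c.peptide.source_variant.gene,
            "variant": c.peptide.source_variant.label,
            "mhc_class": c.peptide.mhc_class.value,
            "peptide": c.peptide.sequence,
            "wt_peptide": c.peptide.wt_sequence or "",
            "allele": c.allele.name,
            "rank": f"{c.rank:.6f}",
            "binder_class": c.binder_class,
            "affinity_score": f"{c.affinity_mutant_score:.6g}",
            "tpm": f"{c.tpm:.6f}",
            "expression_score": c.expression_score,
            "vaf": f"{c.vaf:.6f}",
            "penalty": c.normal_match_penalty,
            "mismatches": "" if c.self_similarity_mismatches is None
                          else c.self_similarity_mismatches,
            "neoantigen_score": f"{c.neoantigen_score:.6g}",
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def emit_reports(report: SelectionReport, outdir: str | Path) -> dict[str, Path]:
    """Write candidates TSV, long-peptide FASTA, summary JSON and a run log.

    Output is byte-stable: re-running with the same seed and inputs yields
    identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "candidates": outdir / f"{report.patient_id}.candidates.tsv",
        "long_peptides": outdir / f"{report.patient_id}.long_peptides.fasta",
        "summary": outdir / f"{report.patient_id}.summary.json",
        "log": outdir / f"{report.patient_id}.run.json",
    }
    candidates_frame(report.selected).to_csv(paths["candidates"], sep="\t", index=False)
    with open(paths["long_peptides"], "w") as fh:
        for lp in report.long_peptides:
            fh.write(f">{lp.source_variant.label} offset={lp.mutation_offset}\n")
            fh.write(lp.sequence + "\n")
    paths["summary"].write_text(json.dumps(report.summary, indent=2) + "\n")
    paths["log"].write_text(
        json.dumps(
            {
                "patient_id": report.patient_id,
                "predictor": report.predictor_name,
                "config": report.config.to_dict(),
            },
            indent=2,
        )
        + "\n"
    )
    return paths
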