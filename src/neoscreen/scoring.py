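"""The neoantigen priority score and its four factors.

Each candidate peptide p is scored as the exact product

    NeoantigenScore(p) = affinityMutantScore * ExpressionScore * VAF * penalty

where

* ``affinityMutantScore = 1 / (1 + exp(5 * (rank - 2)))`` — a logistic
  squash of the best (minimum) %rank across the patient's class-matched
  alleles; 0.5 at rank 2, near 1 for strong binders, near 0 beyond rank ~4;
* ``ExpressionScore`` is a quartile tier of the mutant gene's TPM against
  the patient's positive-TPM distribution: 1 above the upper quartile,
  0.5 between the quartiles, 0.25 at or below the lower quartile, and 0
  for an unexpressed gene (TPM = 0);
* ``VAF`` is the variant allele frequency in [0, 1];
* ``penalty`` (normal exact-match penalty) is 0 when the mutant peptide
  occurs verbatim anywhere in the reference proteome — such a peptide is a
  self peptide, not a neoantigen — and 1 otherwise.

The Hamming mismatch count between a mutant window and its wild-type
pairing ("similarity to self") is reported per candidate but is not a
factor of the product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.special import expit

from .affinity import classify_binder
from .io import (
    ExpressionTable,
    HLAAllele,
    PipelineConfig,
    Proteome,
    ValidationError,
)
from .peptides import MutantPeptide


@dataclass(frozen=True)
class ExpressionQuartiles:
    """25th/75th percentiles of a patient's strictly positive TPM values."""

    lower: float
    upper: float
    n_genes_used: int


def compute_quartiles(expression: ExpressionTable) -> ExpressionQuartiles:
    """Quartiles of the positive-TPM distribution (linear interpolation).

    Zeros are excluded: the TPM = 0 case is its own score tier, so the
    quartile thresholds describe only the expressed genes.
    """
    positive = expression.positive_values()
    if not positive:
        raise ValidationError("no gene with TPM > 0; quartiles undefined")
    lower, upper = np.percentile(positive, [25, 75], method="linear")
    return ExpressionQuartiles(lower=float(lower), upper=float(upper), n_genes_used=len(positive))


def expression_score(tpm: float, quartiles: ExpressionQuartiles) -> float:
    """Quartile tier of a TPM value: one of {1, 0.5, 0.25, 0}.

    Boundaries close downward (a TPM exactly at a quartile takes the lower
    tier) so the four tiers partition [0, inf).
    """
    if tpm < 0:
        raise ValidationError(f"negative TPM {tpm}")
    if tpm == 0:
        return 0.0
    if tpm <= quartiles.lower:
        return 0.25
    if tpm <= quartiles.upper:
        return 0.5
    return 1.0


def affinity_mutant_score(rank: float, config: PipelineConfig | None = None) -> float:
    """Logistic transform of a %rank: 1/(1 + exp(slope * (rank - center))).

    Computed via the numerically stable logistic sigmoid, so a rank of 100
    (exponent 490) saturates to 0 instead of overflowing.  Rank 0 is
    accepted — predictors round very strong ranks down to 0.00 — and maps
    to 1/(1+e^-10), just shy of 1.
    """
    if rank < 0:
        raise ValidationError(f"%rank must be non-negative, got {rank}")
    config = config or PipelineConfig()
    return float(expit(-config.sigmoid_slope * (rank - config.sigmoid_center)))


class ProteomeIndex:
    """Exact-substring index over a reference proteome.

    Sequences are concatenated with a separator outside the amino-acid
    alphabet, so one substring search answers "does this peptide occur
    verbatim in any reference protein".
    """

    def __init__(self, proteome: Proteome):
        self._haystack = "|" + "|".join(p.sequence for p in proteome) + "|"

    def contains(self, peptide: str) -> bool:
        if not peptide:
            raise ValidationError("empty peptide")
        return peptide in self._haystack


def normal_exact_match_penalty(peptide: str, index: ProteomeIndex) -> int:
    """0 if the mutant peptide matches any reference protein verbatim, else 1."""
    return 0 if index.contains(peptide) else 1


def self_similarity(mutant_seq: str, wt_seq: str) -> int:
    """Hamming distance between a mutant window and its wild-type pairing."""
    if len(mutant_seq) != len(wt_seq):
        raise ValidationError(
            f"length mismatch: {len(mutant_seq)} vs {len(wt_seq)}"
        )
    return sum(a != b for a, b in zip(mutant_seq, wt_seq))


def neoantigen_score(
    affinity_score: float, expr_score: float, vaf: float, penalty: int
) -> float:
    """The exact four-factor product, in [0, 1]."""
    if not 0 < affinity_score <= 1:
        raise ValidationError(f"affinity score {affinity_score} outside (0, 1]")
    if expr_score not in (0.0, 0.25, 0.5, 1.0):
        raise ValidationError(f"expression score {expr_score} not a tier value")
    if not 0 <= vaf <= 1:
        raise ValidationError(f"VAF {vaf} outside [0, 1]")
    if penalty not in (0, 1):
        raise ValidationError(f"penalty {penalty} not in {{0, 1}}")
    return affinity_score * expr_score * vaf * penalty


@dataclass(frozen=True)
class ScoredCandidate:
    """A mutant peptide with its winning allele, factors and final score."""

    peptide: MutantPeptide
    allele: HLAAllele
    rank: float
    binder_class: str
    affinity_mutant_score: float
    tpm: float
    expression_score: float
    vaf: float
    normal_match_penalty: int
    self_similarity_mismatches: Optional[int]
    neoantigen_score: float


def score_candidate(
    peptide: MutantPeptide,
    allele: HLAAllele,
    rank: float,
    expression: ExpressionTable,
    quartiles: ExpressionQuartiles,
    index: ProteomeIndex,
    config: PipelineConfig | None = None,
) -> ScoredCandidate:
    """Assemble the four factors and the final score for one peptide."""
    config = config or PipelineConfig()
    tpm = expression.tpm(peptide.source_variant.gene)
    aff = affinity_mutant_score(rank, config)
    expr = expression_score(tpm, quartiles)
    penalty = normal_exact_match_penalty(peptide.sequence, index)
    mismatches = (
        self_similarity(peptide.sequence, peptide.wt_sequence)
        if peptide.wt_sequence is not None
        else None
    )
    return ScoredCandidate(
        peptide=peptide,
        allele=allele,
        rank=rank,
        binder_class=classify_binder(rank, config),
        affinity_mutant_score=aff,
        tpm=tpm,
        expression_score=expr,
        vaf=peptide.source_variant.vaf,
        normal_match_penalty=penalty,
        self_similarity_mismatches=mismatches,
        neoantigen_score=neoantigen_score(aff, expr, peptide.source_variant.vaf, penalty),
    )
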