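# Methods

## Problem and model

`neoscreen` prioritizes tumor neoantigen candidates for personalized
vaccine design. The inputs are the downstream products of a WES/RNA-seq
tumor-normal workflow, taken at the protein level: a reference proteome
(FASTA), a table of non-synonymous somatic variants (SNVs, in-frame
insertions/deletions, frameshifts) with variant allele frequencies (VAF),
gene-level expression in TPM, and the patient's 4-digit HLA type. Variant
calling, consequence annotation, RNA quantification and HLA typing are out
of scope; frameshift variants must already carry their novel C-terminal
peptide, so no transcript model is needed.

For every variant the mutant protein is constructed and all full-length
peptide windows overlapping the mutated span are enumerated: 8–11-mers for
MHC class I and 12–15-mers for MHC class II. Windows truncated by a
protein terminus are dropped, not emitted short, because an under-length
peptide is not a valid ligand for its class. Each peptide's binding
percentile rank (%rank, lower = stronger) is obtained per allele from a
predictor behind a pluggable contract, reduced to the best (minimum) rank
across the patient's class-matched alleles (ties broken by allele name),
and classified: rank < 0.5 strong binder, 0.5 ≤ rank < 2 weak binder,
otherwise non-binder. The printed inequalities are strict on both
boundaries, so exactly 0.5 is weak and exactly 2 is non.

Each candidate peptide p receives the priority score

    NeoantigenScore(p) = affinityMutantScore · ExpressionScore · VAF · penalty

with

* `affinityMutantScore = 1 / (1 + exp(5·(rank − 2)))`, evaluated through
  the numerically stable logistic sigmoid (`scipy.special.expit`), so rank
  100 saturates to ~1e−213 instead of overflowing. Rank 0 — predictors
  round very strong ranks to 0.00 — is accepted and maps to 1/(1+e^−10).
* `ExpressionScore` ∈ {1, 0.5, 0.25, 0}: quartile tier of the mutant
  gene's TPM against the patient's *positive* TPM distribution
  (25th/75th percentiles, linear interpolation; zeros are excluded
  because TPM = 0 is its own tier). The tier boundaries close downward —
  TPM exactly at a quartile takes the lower tier — so the four tiers
  partition [0, ∞).
* `VAF` ∈ [0, 1] as reported by the variant caller.
* `penalty` ∈ {0, 1}: 0 iff the mutant peptide occurs verbatim as a
  substring of any reference protein (a self peptide, not a neoantigen).

The Hamming mismatch count between a mutant window and its wild-type
pairing ("similarity to self") is computed and reported per candidate but
is **not** a factor of the product. Candidates with score strictly
greater than 0 are selected and ranked (score descending, then rank
ascending, then peptide, then variant label — a total, deterministic
order). Finally one 27-aa vaccine long peptide per variant — the mutated
residue with up to 13 flanking residues on each side, truncated at the
termini — is taken for the top 10 distinct variants in ranking order.

## Design choices where the design was open

* **Wild-type pairing.** Only SNV windows carry a wild-type pairing (the
  equal-length aligned substring); indel and frameshift windows have no
  ungapped same-length alignment, so their pairing is absent and the
  mismatch count is not reported for them.
* **Mutated span for indels.** Insertions: the inserted segment.
  Deletions: the junction residue pair flanking the removed segment,
  clipped at the termini. Frameshifts: first novel residue to the
  C-terminus. Windows must overlap the span; the same rule is applied to
  both MHC classes.
* **Long-peptide geometry.** One rule for all variant kinds: a window of
  the mutant protein centered on the first mutated residue, ≤ 27 aa with
  the default flank of 13. This reproduces the published 13+1+13 27-mer
  geometry for interior substitutions and caps frameshift long peptides
  at 27 aa as well.
* **Class II handling.** The same rank cutoffs (0.5/2) and the same
  sigmoid (center 2, slope 5) are applied to class II ranks; both are
  configurable. Class II candidates are scored and reported but excluded
  from the long-peptide walk by default (`include_class2` restores them);
  "strong HLA affinity" in long-peptide selection is realized by the
  score ranking itself, with an optional `require_strong` flag that
  restricts eligibility to variants carrying ≥ 1 strong-binder window.
* **Deduplication.** Identical (sequence, class) windows are collapsed
  before prediction with all provenance kept — identical peptides have
  identical ranks. Predictions are made once per unique (peptide, allele).
* **Proteome index.** The exact-match penalty uses one substring search
  over the concatenated proteome with a separator character outside the
  amino-acid alphabet, cross-checked in tests against a naive per-protein
  scan.
* **Expression units.** Expression is standardized on TPM throughout;
  quartiles are computed per patient.

## Mock predictor

Real %ranks come from external neural-network predictors (NetMHCpan
family) that this package deliberately abstracts behind the
`RankPredictor` contract. The bundled `MockRankPredictor` makes the whole
pipeline runnable and testable offline: the rank for (peptide, allele) is
`100·u^0.75` with `u ∈ (0, 1]` taken from a SHA-256 hash of
(peptide, allele, seed) — bit-identical across platforms, no
floating-point accumulation, right-skewed so that most peptides are
non-binders and well under 5% fall below rank 0.5. A *spike table*
`{(peptide, allele): rank}` forces chosen pairs to chosen ranks, which is
how fixtures plant known strong binders with a predictable top candidate.
Mock ranks carry no biochemistry: absolute candidate counts from synthetic
runs characterize the pipeline's bookkeeping, not any allele's real
repertoire.

## Synthetic cohort generator

`neoscreen.simulate` emulates the statistical shape of an NSCLC patient
mutanome so every stage has realistic input sizes: variant count ~
Poisson(mean 184, the reported cohort average); kinds ~90% SNV, 5%
in-frame indel, 5% frameshift; positions uniform over a random proteome
(default 500 proteins of 100–600 aa, i.i.d. uniform residues); VAF ~
Beta(2, 5) (mean ≈ 0.29, a typical heterozygous tumor VAF under impurity);
TPM zero-inflated log-normal (zero fraction 0.30, log-scale μ = 1.0,
σ = 1.5); 3 class I plus 1–3 class II alleles drawn from a pool of common
types. All parameters are overridable on `CohortSpec`; all randomness
flows from the single seed and regenerating with the same seed yields
byte-identical files.

What the generator does **not** emulate: real amino-acid composition and
homology structure (so exact-match penalties fire less often than against
a real proteome), mutational signatures, expression–copy-number coupling,
and real binding motifs. Passing tests therefore demonstrate correctness
of the bookkeeping and formulas, not predictive performance on patients.

The published worked-example panel (30 printed 27-aa vaccine peptides
from three lung-cancer patients, `data/table1_peptides.tsv`) ships with
the package; each row reconstructs its wild-type 27-mer, and re-applying
the printed substitution recovers the printed mutant sequence exactly,
with Hamming distance 1 — the round-trip test for variant application and
long-peptide geometry. The panel's per-peptide predictor score column has
an unstated scale and is stored as an opaque annotation, never computed.

## Numerical and degenerate-input choices

Quartiles use NumPy's linear-interpolation percentile. Ranks must be
≥ 0 for the sigmoid and > 0 for binder classification. Proteins shorter
than the smallest window legitimately yield zero candidates; a patient
whose every mutant gene is unexpressed yields a valid empty report. A
class with no patient allele is skipped with a warning rather than an
error; `best_rank` called directly with no class-matched allele raises.
An expression table with no positive TPM has undefined quartiles and is
rejected.

## Problem sizes used in the test suite

Unit and property tests run on 60–200-aa proteins and 20–60-variant
patients; the end-to-end determinism check uses one full-size
(~184-variant, 500-protein) patient, which completes in a few seconds
with the mock predictor. The oracle-equivalence checks use 200
hypothesis cases (enumeration) and 1,000 query peptides against a
50 × 200-aa proteome (penalty).
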