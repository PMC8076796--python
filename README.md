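# neoscreen

Neoantigen candidate generation and prioritization from a tumor mutanome.

Somatic mutations create tumor-specific peptides ("neoantigens") that can
be presented on MHC molecules and recognized by T cells; selecting which
of a patient's hundreds of mutations to put into a personalized vaccine
is a ranking problem. `neoscreen` implements that ranking for
protein-level inputs: it enumerates mutant peptide windows from somatic
variants (SNVs, in-frame indels, frameshifts), obtains MHC binding
percentile ranks (%rank) through a pluggable predictor contract,
classifies strong (%rank < 0.5) and weak (0.5 < %rank < 2) binders, and
scores every candidate with the multiplicative priority score

    NeoantigenScore(p) = affinityMutantScore · ExpressionScore · VAF · penalty

where `affinityMutantScore = 1/(1 + exp(5·(rank − 2)))`,
`ExpressionScore ∈ {1, 0.5, 0.25, 0}` is the quartile tier of the mutant
gene's TPM among the patient's expressed genes, `VAF` is the variant
allele frequency, and `penalty` is 0 for any peptide occurring verbatim
in the reference proteome (a self peptide) and 1 otherwise. Candidates
with score > 0 are selected, and one 27-aa vaccine long peptide (mutated
residue ± 13 flanking residues) is designed for each of the top 10
variants. A seeded synthetic-cohort generator and a deterministic mock
rank predictor make the whole pipeline runnable and testable offline;
real predictions plug in behind the `RankPredictor` contract. See
`docs/methods.md` for the model details and design choices.

Audience: immunoinformatics developers and computational biologists who
have already run variant calling, expression quantification and HLA
typing, and need a tested, reproducible prioritization stage.

## Worked example

```python
import neoscreen as ns

protein = ns.ProteinRecord(id="ACAD8_toy", gene="ACAD8",
                           sequence="QTDVGGSGLSRLDTSVIFEALATGCTS")
variant = ns.SomaticVariant(gene="ACAD8", protein_id="ACAD8_toy",
                            kind=ns.VariantKind.SNV, position=14,
                            wt="T", alt="I", vaf=0.31)
mutant = ns.apply_variant(protein, variant)
print("mutant protein:", mutant.sequence)
windows = ns.enumerate_windows(mutant, ns.MhcClass.I)
print("class I windows:", len(windows))
print("one 9-mer:", sorted(w.sequence for w in windows if w.length == 9)[0])
print("affinity score at rank 0.3:", round(ns.affinity_mutant_score(0.3), 6))
q = ns.ExpressionQuartiles(lower=2.0, upper=20.0, n_genes_used=100)
print("expression tier for TPM 35.0:", ns.expression_score(35.0, q))
score = ns.neoantigen_score(ns.affinity_mutant_score(0.3), 1.0, 0.31, 1)
print("NeoantigenScore:", round(score, 6))
lp = ns.make_long_peptide(protein, variant)
print("long peptide:", lp.sequence, "offset", lp.mutation_offset)
```

prints

```
mutant protein: QTDVGGSGLSRLDISVIFEALATGCTS
class I windows: 38
one 9-mer: DISVIFEAL
affinity score at rank 0.3: 0.999797
expression tier for TPM 35.0: 1.0
NeoantigenScore: 0.309937
long peptide: QTDVGGSGLSRLDISVIFEALATGCTS offset 14
```

The T→I substitution at position 14 yields 38 class I windows (all 8–11-mers
covering the site), a strong-binder affinity score near 1 at %rank 0.3, the
top expression tier for a TPM above the upper quartile, a final score equal
to the product of the four factors (here dominated by the VAF of 0.31), and
a long peptide with the mutated residue at offset 14. The same sequence is
one of the 30 published 27-mer vaccine peptides shipped as a worked-example
panel in `neoscreen.simulate.load_vaccine_panel()`.

From the shell, a full synthetic patient:

```sh
$ neoscreen simulate --seed 3 --n-patients 1 --out sim/
SIM00: 23 variants -> sim/SIM00.variants.tsv
$ neoscreen run --proteome sim/proteome.fasta \
    --variants sim/SIM00.variants.tsv --expression sim/SIM00.expression.tsv \
    --alleles sim/SIM00.alleles.txt --seed 3 --patient-id SIM00 --out out/
SIM00: 676 class I + 898 class II candidates, 3 strong / 14 weak binders,
10 long peptides -> out
```

(`--n-variants-mean 25` was used above for a quick run; the default mean
is 184 variants per patient.) `out/` then contains the ranked candidate
TSV, the long-peptide FASTA, a JSON summary of per-class and binder
counts, and a run log with the configuration and seed; re-running with
the same seed reproduces every file byte-for-byte.

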