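"""Seeded synthetic patients with the statistical shape of an NSCLC mutanome.

Real inputs to this pipeline are a reference proteome plus per-patient
somatic variants (protein-level), RNA-seq TPMs and HLA types.  The
generator emulates that structure so every stage runs offline: ~184
non-synonymous variants per patient (Poisson), ~90% SNVs with small
in-frame indel and frameshift fractions, zero-inflated log-normal TPMs,
Beta-distributed VAFs and 4-6 HLA alleles drawn from a pool of common
class I and class II types.  All randomness flows from one seed and output
files are byte-identical across runs.

The module also ships the published vaccine long-peptide panel (30 printed
27-mers from three lung-cancer patients) as ``data/table1_peptides.tsv``,
usable as worked-example variants against toy proteomes that embed the
reconstructed wild-type 27-mers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS,
    ExpressionTable,
    HLAAllele,
    MhcClass,
    Proteome,
    ProteinRecord,
    SomaticVariant,
    VariantKind,
    parse_hla_allele,
    write_expression_table,
    write_proteome_fasta,
    write_variants_table,
)
from .pipeline import PatientBundle

CLASS_I_POOL = (
    "HLA-A*02:01", "HLA-A*02:06", "HLA-A*02:07", "HLA-A*33:03",
    "HLA-B*15:01", "HLA-B*15:02", "HLA-B*58:01", "HLA-B*81:01",
)
CLASS_II_POOL = (
    "HLA-DRB1*11:01", "HLA-DQA1*03:01", "HLA-DQA1*04:01",
    "HLA-DQA1*05:01", "HLA-DPA1*02:02",
)


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``tpm_zero_fraction``/``tpm_mu``/``tpm_sigma`` parameterize the
    zero-inflated log-normal TPM model (natural-log scale);
    ``vaf_alpha``/``vaf_beta`` the Beta VAF model.  ``spike_ranks`` plants
    one known strong binder per entry: a dedicated SNV on a highly
    expressed gene whose first 9-mer window is forced to the given %rank
    on the patient's first class I allele.
    """

    n_patients: int = 3
    n_variants_mean: float = 184.0
    n_proteins: int = 500
    protein_length_range: tuple[int, int] = (100, 600)
    tpm_zero_fraction: float = 0.30
    tpm_mu: float = 1.0
    tpm_sigma: float = 1.5
    vaf_alpha: float = 2.0
    vaf_beta: float = 5.0
    allele_pool: tuple[str, ...] = CLASS_I_POOL + CLASS_II_POOL
    spike_ranks: tuple[float, ...] = ()
    seed: int = 0


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_proteome(spec: CohortSpec) -> Proteome:
    """Random reference proteome: i.i.d. uniform residues, seeded."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.protein_length_range
    records = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            ProteinRecord(
                id=f"SYNP{i:04d}",
                gene=f"GENE{i:04d}",
                sequence=_random_peptide(rng, length),
            )
        )
    return Proteome(records)


def _gen_variant(rng: np.random.Generator, protein: ProteinRecord, vaf: float) -> SomaticVariant:
    L = len(protein)
    kinds = (VariantKind.SNV, VariantKind.INFRAME_INS, VariantKind.INFRAME_DEL,
             VariantKind.FRAMESHIFT)
    kind = kinds[int(rng.choice(4, p=[0.90, 0.025, 0.025, 0.05]))]
    common = dict(gene=protein.gene, protein_id=protein.id, vaf=vaf)
    if kind is VariantKind.SNV:
        pos = int(rng.integers(1, L + 1))
        wt = protein.residue(pos)
        alt = rng.choice([a for a in AMINO_ACIDS if a != wt])
        return SomaticVariant(kind=kind, position=pos, wt=wt, alt=str(alt), **common)
    if kind is VariantKind.INFRAME_INS:
        pos = int(rng.integers(1, L + 1))
        seg = _random_peptide(rng, int(rng.integers(1, 4)))
        return SomaticVariant(kind=kind, position=pos, wt="", alt=seg, **common)
    if kind is VariantKind.INFRAME_DEL:
        seg_len = int(rng.integers(1, 4))
        pos = int(rng.integers(1, L - seg_len + 1))  # keep mutant non-empty
        seg = protein.sequence[pos - 1 : pos - 1 + seg_len]
        return SomaticVariant(kind=kind, position=pos, wt=seg, alt="", **common)
    pos = int(rng.integers(2, L + 1))  # frameshift keeps >= 1 prefix residue
    tail = _random_peptide(rng, int(rng.integers(8, 31)))
    return SomaticVariant(kind=kind, position=pos, wt="", alt=tail, **common)


def gen_patient(
    spec: CohortSpec, proteome: Proteome, patient_index: int = 0
) -> tuple[PatientBundle, dict[tuple[str, str], float]]:
    """One synthetic patient bundle plus the spike table for the mock predictor.

    Variant count ~ Poisson(n_variants_mean); VAFs ~ Beta; TPMs cover every
    proteome gene from the zero-inflated log-normal.  Returns the bundle
    and a ``{(peptide, allele_name): rank}`` dict realizing ``spike_ranks``.
    """
    rng = np.random.default_rng([spec.seed, 7919, patient_index])
    proteins = sorted(proteome, key=lambda p: p.id)

    # expression over the whole proteome gene set
    tpm = {}
    for protein in proteins:
        if rng.random() < spec.tpm_zero_fraction:
            tpm[protein.gene] = 0.0
        else:
            tpm[protein.gene] = round(float(rng.lognormal(spec.tpm_mu, spec.tpm_sigma)), 6)

    n_variants = max(1, int(rng.poisson(spec.n_variants_mean)))
    variants = []
    for _ in range(n_variants):
        protein = proteins[int(rng.integers(len(proteins)))]
        vaf = round(float(rng.beta(spec.vaf_alpha, spec.vaf_beta)), 6)
        variants.append(_gen_variant(rng, protein, vaf))

    class1 = [str(a) for a in rng.choice(CLASS_I_POOL, size=3, replace=False)]
    n_class2 = int(rng.integers(1, 4))
    class2 = [str(a) for a in rng.choice(CLASS_II_POOL, size=n_class2, replace=False)]
    alleles = [parse_hla_allele(a) for a in class1 + class2]

    # planted strong binders: SNV on a strongly expressed gene, high VAF,
    # first 9-mer window pinned to the requested rank on the first allele
    spikes: dict[tuple[str, str], float] = {}
    if spec.spike_ranks:
        from .peptides import apply_variant, enumerate_windows

        spike_allele = sorted(
            a.name for a in alleles if a.mhc_class is MhcClass.I
        )[0]
        top_tpm = max(tpm.values()) * 2 + 1
        for i, target_rank in enumerate(spec.spike_ranks):
            protein = proteins[(patient_index * 31 + i * 17) % len(proteins)]
            pos = len(protein) // 2
            wt = protein.residue(pos)
            alt = next(a for a in AMINO_ACIDS if a != wt)
            variant = SomaticVariant(
                gene=protein.gene, protein_id=protein.id, kind=VariantKind.SNV,
                position=pos, wt=wt, alt=alt, vaf=0.9,
            )
            tpm[protein.gene] = top_tpm
            variants.append(variant)
            windows = enumerate_windows(apply_variant(protein, variant), MhcClass.I)
            nine_mers = sorted(w.sequence for w in windows if w.length == 9)
            spikes[(nine_mers[0], spike_allele)] = float(target_rank)

    bundle = PatientBundle(
        patient_id=f"SIM{patient_index:02d}",
        proteome=proteome,
        variants=variants,
        expression=ExpressionTable(tpm),
        alleles=alleles,
    )
    return bundle, spikes


def write_bundle(bundle: PatientBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle in the exact formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.fasta",
        "variants": outdir / f"{bundle.patient_id}.variants.tsv",
        "expression": outdir / f"{bundle.patient_id}.expression.tsv",
        "alleles": outdir / f"{bundle.patient_id}.alleles.txt",
    }
    write_proteome_fasta(bundle.proteome, paths["proteome"])
    write_variants_table(bundle.variants, paths["variants"])
    write_expression_table(bundle.expression, paths["expression"])
    paths["alleles"].write_text("".join(a.name + "\n" for a in bundle.alleles))
    return paths


# ---------------------------------------------------------------------------
# published worked-example panel
# ---------------------------------------------------------------------------

def load_vaccine_panel() -> pd.DataFrame:
    """The published 30-row panel of 27-aa vaccine peptides (3 patients).

    Columns: patient, gene, hla, mutated_sequence (27-mer, mutant residue
    at offset 14), wt_residue, position (original protein coordinate),
    mut_residue, hla_score (predictor score as printed; opaque scale).
    """
    with resources.files("neoscreen.data").joinpath("table1_peptides.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"position": int, "hla_score": int})


def panel_wildtype_27mer(row) -> str:
    """Reconstruct the wild-type 27-mer by undoing the printed substitution."""
    seq = row.mutated_sequence
    return seq[:13] + row.wt_residue + seq[14:]


def panel_bundle(patient_id: str) -> PatientBundle:
    """A worked-example bundle for one published patient (P01/P02/P03).

    Each panel row becomes a toy protein (the reconstructed wild-type
    27-mer) carrying its printed substitution at position 14.  TPM and VAF
    are not printed in the panel; neutral placeholders (TPM 10, VAF 0.5)
    are used so the bundle exercises enumeration, not scoring claims.
    """
    panel = load_vaccine_panel()
    rows = panel[panel.patient == patient_id]
    if rows.empty:
        raise ValueError(f"unknown panel patient {patient_id!r}")
    records, variants, tpm = [], [], {}
    for row in rows.itertuples(index=False):
        records.append(
            ProteinRecord(
                id=f"{patient_id}_{row.gene}",
                gene=row.gene,
                sequence=panel_wildtype_27mer(row),
            )
        )
        variants.append(
            SomaticVariant(
                gene=row.gene, protein_id=f"{patient_id}_{row.gene}",
                kind=VariantKind.SNV, position=14,
                wt=row.wt_residue, alt=row.mut_residue, vaf=0.5,
            )
        )
        tpm[row.gene] = 10.0
    alleles = sorted(
        {parse_hla_allele(h) for h in rows.hla}, key=lambda a: a.name
    )
    return PatientBundle(
        patient_id=patient_id,
        proteome=Proteome(records),
        variants=variants,
        expression=ExpressionTable(tpm),
        alleles=alleles,
    )
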