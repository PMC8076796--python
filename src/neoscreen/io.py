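"""Input data model and readers for proteome, variant, expression and HLA inputs.

Somatic variants are accepted at the protein level (HGVS-p-like coordinates:
1-based, closed intervals, "T105I" style), not as genomic VCF.  Genomic
variant calling, consequence annotation and HLA typing from reads are
upstream of this package; frameshift variants must therefore carry their
novel C-terminal peptide (``alt_tail``) explicitly — no transcript
translation happens here.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 proteinogenic residues plus X (unknown).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

CLASS_I_LOCI = frozenset({"A", "B", "C"})
CLASS_II_LOCI = frozenset({"DRB1", "DQA1", "DQB1", "DPA1", "DPB1"})


class ValidationError(ValueError):
    """An input file or record failed validation."""


class MhcClass(str, enum.Enum):
    I = "I"
    II = "II"


class VariantKind(str, enum.Enum):
    SNV = "snv"
    INFRAME_INS = "inframe_ins"
    INFRAME_DEL = "inframe_del"
    FRAMESHIFT = "frameshift"


@dataclass(frozen=True)
class ProteinRecord:
    """One reference protein: FASTA id, owning gene, uppercase AA sequence."""

    id: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise ValidationError(
                f"protein {self.id!r}: position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SomaticVariant:
    """A protein-level non-synonymous somatic mutation with its VAF.

    ``position`` is 1-based.  Field use by kind:

    * snv — ``wt`` is the reference residue, ``alt`` the mutant residue;
    * inframe_ins — ``alt`` is the segment inserted *after* ``position``;
    * inframe_del — ``wt`` is the deleted segment starting at ``position``;
    * frameshift — ``alt`` is the novel stop-free C-terminal tail replacing
      everything from ``position`` onward.
    """

    gene: str
    protein_id: str
    kind: VariantKind
    position: int
    wt: str
    alt: str
    vaf: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"{self.label}: position must be >= 1")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"{self.label}: vaf {self.vaf} outside [0, 1]")
        if self.kind is VariantKind.SNV:
            if len(self.wt) != 1 or len(self.alt) != 1:
                raise ValidationError(f"{self.label}: snv needs single wt/alt residues")
            if self.wt == self.alt:
                raise ValidationError(f"{self.label}: synonymous (wt == alt)")
        elif self.kind is VariantKind.INFRAME_INS and not self.alt:
            raise ValidationError(f"{self.label}: insertion needs alt segment")
        elif self.kind is VariantKind.INFRAME_DEL and not self.wt:
            raise ValidationError(f"{self.label}: deletion needs wt segment")
        elif self.kind is VariantKind.FRAMESHIFT and not self.alt:
            raise ValidationError(f"{self.label}: frameshift needs alt tail")

    @property
    def label(self) -> str:
        """Short human-readable identifier, e.g. ``ACAD8:T105I``."""
        if self.kind is VariantKind.SNV:
            return f"{self.gene}:{self.wt}{self.position}{self.alt}"
        return f"{self.gene}:{self.kind.value}@{self.position}"

    def validate_against(self, protein: ProteinRecord) -> None:
        """Check coordinates and reference residues against the proteome."""
        if self.position > len(protein):
            raise ValidationError(
                f"{self.label}: position {self.position} beyond protein "
                f"{protein.id!r} length {len(protein)}"
            )
        if self.kind is VariantKind.SNV:
            found = protein.residue(self.position)
            if found != self.wt:
                raise ValidationError(
                    f"{self.label}: expected wt residue {self.wt!r} at position "
                    f"{self.position} of {protein.id!r}, found {found!r}"
                )
        elif self.kind is VariantKind.INFRAME_DEL:
            end = self.position + len(self.wt) - 1
            if end > len(protein):
                raise ValidationError(
                    f"{self.label}: deleted segment runs past protein end ({end} > {len(protein)})"
                )
            found = protein.sequence[self.position - 1 : end]
            if found != self.wt:
                raise ValidationError(
                    f"{self.label}: expected segment {self.wt!r} at "
                    f"{self.position}..{end} of {protein.id!r}, found {found!r}"
                )


class Proteome:
    """A collection of reference proteins indexed by protein id and by gene.

    One canonical protein per gene: when a gene appears more than once the
    longest sequence wins and a warning is logged.
    """

    def __init__(self, records: Iterable[ProteinRecord]):
        self.by_id: dict[str, ProteinRecord] = {}
        self.by_gene: dict[str, ProteinRecord] = {}
        for rec in records:
            if rec.id in self.by_id:
                raise ValidationError(f"duplicate protein id {rec.id!r}")
            self.by_id[rec.id] = rec
            prev = self.by_gene.get(rec.gene)
            if prev is None or len(rec) > len(prev):
                if prev is not None:
                    logger.warning(
                        "gene %s has multiple proteins; keeping longest (%s)",
                        rec.gene, rec.id,
                    )
                self.by_gene[rec.gene] = rec
            else:
                logger.warning(
                    "gene %s has multiple proteins; keeping longest (%s)",
                    rec.gene, prev.id,
                )

    def __len__(self) -> int:
        return len(self.by_id)

    def __iter__(self):
        return iter(self.by_id.values())

    def protein_for(self, variant: SomaticVariant) -> ProteinRecord:
        rec = self.by_id.get(variant.protein_id) or self.by_gene.get(variant.gene)
        if rec is None:
            raise ValidationError(
                f"{variant.label}: no protein {variant.protein_id!r} / gene "
                f"{variant.gene!r} in proteome"
            )
        return rec


@dataclass(frozen=True)
class HLAAllele:
    """A 4-digit HLA allele, normalized as ``HLA-<locus>*<group>:<protein>``."""

    name: str
    mhc_class: MhcClass

    def __str__(self) -> str:
        return self.name


def parse_hla_allele(text: str) -> HLAAllele:
    """Parse and normalize an HLA allele name.

    Accepts ``A*0201``, ``HLA-A*02:01``, ``drb1*1101`` etc.; class is
    inferred from the locus (A/B/C -> I, DRB1/DQA1/DQB1/DPA1/DPB1 -> II).
    Normalization is idempotent and case-insensitive.
    """
    raw = text.strip().upper()
    body = raw[4:] if raw.startswith("HLA-") else raw
    if "*" not in body:
        raise ValidationError(f"cannot parse HLA allele {text!r}: missing '*'")
    locus, _, digits = body.partition("*")
    locus = locus.strip()
    digits = digits.replace(":", "").strip()
    if not digits.isdigit() or len(digits) != 4:
        raise ValidationError(f"cannot parse HLA allele {text!r}: expected 4-digit form")
    if locus in CLASS_I_LOCI:
        cls = MhcClass.I
    elif locus in CLASS_II_LOCI:
        cls = MhcClass.II
    else:
        raise ValidationError(f"unknown HLA locus {locus!r} in {text!r}")
    return HLAAllele(name=f"HLA-{locus}*{digits[:2]}:{digits[2:]}", mhc_class=cls)


def parse_hla_alleles(text_or_lines: str | Iterable[str]) -> list[HLAAllele]:
    """Parse a comma-separated string or an iterable of allele names."""
    if isinstance(text_or_lines, str):
        items = text_or_lines.split(",")
    else:
        items = list(text_or_lines)
    alleles = [parse_hla_allele(t) for t in items if t.strip()]
    if not alleles:
        raise ValidationError("no HLA alleles given")
    return alleles


def read_alleles_file(path: str | Path) -> list[HLAAllele]:
    lines = Path(path).read_text().splitlines()
    return parse_hla_alleles(lines)


class ExpressionTable:
    """Gene -> TPM mapping.  Zeros are preserved: TPM=0 zeroes the score."""

    def __init__(self, tpm: Mapping[str, float]):
        for gene, value in tpm.items():
            if value < 0:
                raise ValidationError(f"gene {gene!r}: negative TPM {value}")
        self._tpm = dict(tpm)

    def __len__(self) -> int:
        return len(self._tpm)

    def __contains__(self, gene: str) -> bool:
        return gene in self._tpm

    def items(self):
        return self._tpm.items()

    def tpm(self, gene: str, default: float = 0.0) -> float:
        """TPM for a gene; genes absent from the table count as unexpressed."""
        return self._tpm.get(gene, default)

    def positive_values(self) -> list[float]:
        return [v for v in self._tpm.values() if v > 0]


@dataclass
class PipelineConfig:
    """Tunables of the prioritization pipeline.

    Defaults reflect the study design: 8-11-mer windows for MHC I and
    12-15-mer windows for MHC II, 13-residue flanks around the mutated
    residue for 27-aa vaccine long peptides, %rank cutoffs 0.5 (strong) and
    2 (weak), the rank sigmoid 1/(1+exp(slope*(rank-center))) with slope 5
    and center 2, selection of candidates with score strictly above 0, and
    ten long peptides per patient.
    """

    mhc1_lengths: tuple[int, ...] = (8, 9, 10, 11)
    mhc2_lengths: tuple[int, ...] = (12, 13, 14, 15)
    long_peptide_flank: int = 13
    strong_rank_cutoff: float = 0.5
    weak_rank_cutoff: float = 2.0
    sigmoid_slope: float = 5.0
    sigmoid_center: float = 2.0
    score_threshold: float = 0.0
    top_n_long_peptides: int = 10
    require_strong: bool = False
    include_class2: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for lengths in (self.mhc1_lengths, self.mhc2_lengths):
            lengths = tuple(lengths)
            if not lengths or list(lengths) != sorted(set(lengths)):
                raise ValidationError("peptide lengths must be non-empty ascending")
        self.mhc1_lengths = tuple(self.mhc1_lengths)
        self.mhc2_lengths = tuple(self.mhc2_lengths)
        if not 0 < self.strong_rank_cutoff < self.weak_rank_cutoff:
            raise ValidationError("need 0 < strong_rank_cutoff < weak_rank_cutoff")

    def lengths_for(self, mhc_class: MhcClass) -> tuple[int, ...]:
        return self.mhc1_lengths if mhc_class is MhcClass.I else self.mhc2_lengths

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("mhc1_lengths", "mhc2_lengths"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "mhc1_lengths": list(self.mhc1_lengths),
            "mhc2_lengths": list(self.mhc2_lengths),
            "long_peptide_flank": self.long_peptide_flank,
            "strong_rank_cutoff": self.strong_rank_cutoff,
            "weak_rank_cutoff": self.weak_rank_cutoff,
            "sigmoid_slope": self.sigmoid_slope,
            "sigmoid_center": self.sigmoid_center,
            "score_threshold": self.score_threshold,
            "top_n_long_peptides": self.top_n_long_peptides,
            "require_strong": self.require_strong,
            "include_class2": self.include_class2,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _gene_from_description(record) -> str:
    # FASTA headers carry the gene as a "gene=NAME" token when written by this
    # package; otherwise the gene defaults to the record id.
    for token in record.description.split():
        if token.startswith("gene="):
            return token[5:]
    return record.id


def read_proteome_fasta(path: str | Path) -> Proteome:
    """Read a reference proteome FASTA into an indexed :class:`Proteome`.

    Sequences are uppercased; records with characters outside the 21-letter
    amino-acid alphabet are rejected with the offending record named.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            records.append(ProteinRecord(id=rec.id, gene=_gene_from_description(rec), sequence=seq))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return Proteome(records)


def write_proteome_fasta(proteome: Proteome, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.id, description=f"gene={p.gene}")
        for p in proteome
    ]
    SeqIO.write(recs, str(path), "fasta")


VARIANT_COLUMNS = ["gene", "protein_id", "kind", "position", "wt", "alt", "vaf"]


def read_variants_table(path: str | Path, proteome: Proteome) -> list[SomaticVariant]:
    """Read the variant TSV and validate every row against the proteome."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing variant columns {sorted(missing)}")
    variants = []
    for row in df.itertuples(index=False):
        variant = SomaticVariant(
            gene=row.gene,
            protein_id=row.protein_id,
            kind=VariantKind(row.kind),
            position=int(row.position),
            wt=row.wt,
            alt=row.alt,
            vaf=float(row.vaf),
        )
        variant.validate_against(proteome.protein_for(variant))
        variants.append(variant)
    return variants


def write_variants_table(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    rows = [
        {
            "gene": v.gene, "protein_id": v.protein_id, "kind": v.kind.value,
            "position": v.position, "wt": v.wt, "alt": v.alt,
            "vaf": f"{v.vaf:.6f}",
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read the gene/tpm TSV; zeros retained, duplicates and negatives rejected."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "tpm"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns gene, tpm")
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValidationError(f"{path}: duplicate gene rows {dupes}")
    if (df["tpm"] < 0).any():
        bad = df.loc[df["tpm"] < 0, "gene"].tolist()
        raise ValidationError(f"{path}: negative TPM for {bad}")
    return ExpressionTable(dict(zip(df["gene"], df["tpm"].astype(float))))


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    rows = [{"gene": g, "tpm": f"{v:.6f}"} for g, v in table.items()]
    pd.DataFrame(rows, columns=["gene", "tpm"]).to_csv(path, sep="\t", index=False)
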