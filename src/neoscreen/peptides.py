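"""Variant application and mutant peptide window enumeration.

A somatic variant applied to its reference protein yields a
:class:`MutantProtein` with a *mutated span* — the 1-based closed interval
of mutant-protein positions that changed.  Candidate peptides are exactly
the full-length windows of the configured per-class lengths (8-11 for MHC I,
12-15 for MHC II) that overlap the span; windows truncated by a protein
terminus are dropped, never emitted short, because an under-length peptide
is not a valid ligand for its class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io import (
    MhcClass,
    PipelineConfig,
    ProteinRecord,
    SomaticVariant,
    ValidationError,
    VariantKind,
)


@dataclass(frozen=True)
class MutantProtein:
    """A protein sequence after variant application.

    ``mutated_span`` is the closed 1-based interval of positions that differ
    from (or are absent in) the wild type; for a frameshift it runs from the
    first novel residue to the C-terminus.
    """

    sequence: str
    mutated_span: tuple[int, int]
    source_variant: SomaticVariant
    wt_sequence: str

    def __post_init__(self) -> None:
        a, b = self.mutated_span
        if not (1 <= a <= b <= len(self.sequence)):
            raise ValidationError(
                f"{self.source_variant.label}: mutated span {self.mutated_span} "
                f"outside 1..{len(self.sequence)}"
            )


@dataclass(frozen=True)
class WindowProvenance:
    """Where a peptide window came from in the mutant protein."""

    start: int  # 1-based start in the mutant protein
    length: int


@dataclass(frozen=True)
class MutantPeptide:
    """A candidate mutant peptide window with its wild-type pairing.

    ``mutation_offset`` holds the 1-based offsets of mutated residues within
    the window.  ``wt_sequence`` is the aligned equal-length wild-type
    substring for substitution windows and ``None`` where no ungapped
    alignment exists (indel and frameshift windows).
    """

    sequence: str
    mhc_class: MhcClass
    mutation_offset: tuple[int, ...]
    wt_sequence: Optional[str]
    source_variant: SomaticVariant
    provenance: tuple[WindowProvenance, ...] = field(default=(), compare=False)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LongPeptide:
    """A vaccine long peptide: the mutated residue with up to ``flank``
    (default 13) residues on each side, truncated — never padded — at the
    protein termini.  With the default flank every interior substitution
    yields a 27-mer with the mutant residue at offset 14."""

    sequence: str
    mutation_offset: int
    source_variant: SomaticVariant


def apply_variant(protein: ProteinRecord, variant: SomaticVariant) -> MutantProtein:
    """Apply a validated somatic variant to its reference protein."""
    variant.validate_against(protein)
    seq = protein.sequence
    pos = variant.position
    if variant.kind is VariantKind.SNV:
        mutant = seq[: pos - 1] + variant.alt + seq[pos:]
        span = (pos, pos)
    elif variant.kind is VariantKind.INFRAME_INS:
        # alt segment inserted after `position`
        mutant = seq[:pos] + variant.alt + seq[pos:]
        span = (pos + 1, pos + len(variant.alt))
    elif variant.kind is VariantKind.INFRAME_DEL:
        mutant = seq[: pos - 1] + seq[pos - 1 + len(variant.wt):]
        if not mutant:
            raise ValidationError(f"{variant.label}: deletion removes entire protein")
        # junction residue pair flanking the deleted segment, clipped at termini
        span = (max(1, pos - 1), min(len(mutant), pos))
    elif variant.kind is VariantKind.FRAMESHIFT:
        mutant = seq[: pos - 1] + variant.alt
        span = (pos, len(mutant))
    else:  # pragma: no cover - enum is exhaustive
        raise ValidationError(f"unknown variant kind {variant.kind}")
    return MutantProtein(
        sequence=mutant, mutated_span=span, source_variant=variant, wt_sequence=seq
    )


def pair_wildtype(mutant: MutantProtein, start: int, length: int) -> Optional[str]:
    """Aligned wild-type substring for a mutant window, or ``None``.

    Only substitutions (SNVs) preserve coordinates, so only their windows
    have an ungapped equal-length wild-type pairing.  Indel and frameshift
    windows return ``None``.
    """
    if mutant.source_variant.kind is not VariantKind.SNV:
        return None
    return mutant.wt_sequence[start - 1 : start - 1 + length]


def enumerate_windows(
    mutant: MutantProtein, mhc_class: MhcClass, config: PipelineConfig | None = None
) -> list[MutantPeptide]:
    """All full-length windows of the class's lengths overlapping the span.

    Duplicate sequences (same peptide arising from several start/length
    combinations) are collapsed, keeping every provenance record.  The empty
    list is a valid result for proteins shorter than the smallest window.
    """
    config = config or PipelineConfig()
    a, b = mutant.mutated_span
    L = len(mutant.sequence)
    windows: dict[str, dict] = {}
    for length in config.lengths_for(mhc_class):
        # starts where the window [s, s+length-1] fits and overlaps [a, b]
        for start in range(max(1, a - length + 1), min(b, L - length + 1) + 1):
            seq = mutant.sequence[start - 1 : start - 1 + length]
            offsets = tuple(
                p - start + 1 for p in range(max(a, start), min(b, start + length - 1) + 1)
            )
            wt = pair_wildtype(mutant, start, length)
            if wt == seq:
                # defensive: a window identical to self is not a neoantigen
                continue
            entry = windows.setdefault(
                seq, {"offsets": offsets, "wt": wt, "prov": []}
            )
            entry["prov"].append(WindowProvenance(start=start, length=length))
    return [
        MutantPeptide(
            sequence=seq,
            mhc_class=mhc_class,
            mutation_offset=entry["offsets"],
            wt_sequence=entry["wt"],
            source_variant=mutant.source_variant,
            provenance=tuple(entry["prov"]),
        )
        for seq, entry in windows.items()
    ]


def make_long_peptide(
    protein: ProteinRecord, variant: SomaticVariant, config: PipelineConfig | None = None
) -> LongPeptide:
    """Build the vaccine long peptide for a variant.

    The window is cut from the *mutant* protein, centered on the first
    mutated residue with ``long_peptide_flank`` residues on each side and
    truncated at the termini, so the default flank of 13 gives a 27-mer
    with the mutated residue at offset 14 whenever the protein allows.
    """
    config = config or PipelineConfig()
    flank = config.long_peptide_flank
    mutant = apply_variant(protein, variant)
    center = mutant.mutated_span[0]
    L = len(mutant.sequence)
    start = max(1, center - flank)
    end = min(L, center + flank)
    return LongPeptide(
        sequence=mutant.sequence[start - 1 : end],
        mutation_offset=center - start + 1,
        source_variant=variant,
    )
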