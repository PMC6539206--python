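"""Mutant-library accounting for random-mutagenesis MAPPIT screens.

An error-prone-PCR library is characterised by Sanger sequencing a sample of
clones per PCR condition.  This module calls nucleotide variants in each clone
against the reference construct, derives the protein-level consequence per
codon, classifies each clone (wildtype, single missense, multi missense,
silent only, nonsense, indel, ambiguous), summarises the substitution spectrum
and library coverage, and picks the PCR condition that yielded the most single
missense mutants — the clones that are carried forward to screening.

Only single-substitution Sanger clones of a fixed-length insert are expected,
so comparison is positional (equal length); any length difference routes the
clone to the ``indel`` class without breakpoint resolution.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = ("A", "C", "G", "T")

#: The 12 ordered nucleotide substitution types, e.g. ``"A>C"``.
SUBSTITUTION_TYPES = tuple(
    f"{a}>{b}" for a in NUCLEOTIDES for b in NUCLEOTIDES if a != b
)

STOP = "*"


class LibraryError(ValueError):
    """Base class for mutant-library errors."""


class FrameError(LibraryError):
    """CDS length is not a multiple of three."""


class AlphabetError(LibraryError):
    """Sequence contains characters outside the expected alphabet."""


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    Stop codons translate to ``"*"``; internal stops are permitted because
    mutant clones may carry nonsense substitutions.

    Raises
    ------
    FrameError
        If ``len(cds)`` is not divisible by 3.
    AlphabetError
        If the sequence contains characters other than A/C/G/T.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    bad = set(cds) - set(NUCLEOTIDES)
    if bad:
        raise AlphabetError(f"invalid nucleotide(s) {sorted(bad)} in CDS")
    return str(Seq(cds).translate())


@dataclass(frozen=True)
class ReferenceConstruct:
    """The mutagenised insert: CDS, translated protein and residue numbering.

    ``residue_offset`` is the residue number, in the numbering of the
    full-length protein (and of the structure used for mapping), of the
    construct's first codon.  Codon ``i`` (1-based) of the construct is
    residue ``i + residue_offset - 1`` of the full-length protein.
    """

    construct_id: str
    cds: str
    residue_offset: int = 1
    protein: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", self.cds.upper())
        protein = translate_cds(self.cds)
        if STOP in protein[:-1]:
            raise LibraryError("reference CDS contains an internal stop codon")
        if self.residue_offset < 1:
            raise LibraryError("residue_offset must be >= 1")
        object.__setattr__(self, "protein", protein)

    @property
    def n_codons(self) -> int:
        """Number of amino-acid-coding codons (trailing stop excluded)."""
        return len(self.protein.rstrip(STOP))

    def residue_number(self, codon_index: int) -> int:
        """Full-length-protein residue number of a 1-based codon index."""
        return codon_index + self.residue_offset - 1


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced mutant clone (one Sanger-sequenced colony)."""

    clone_id: str
    sequence: str
    source_well: str = ""
    pcr_condition: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise LibraryError(f"clone {self.clone_id}: empty sequence")
        bad = set(self.sequence) - set(NUCLEOTIDES) - {"N"}
        if bad:
            raise AlphabetError(
                f"clone {self.clone_id}: invalid character(s) {sorted(bad)}"
            )


class Consequence(str, enum.Enum):
    SILENT = "silent"
    MISSENSE = "missense"
    NONSENSE = "nonsense"


@dataclass(frozen=True)
class VariantCall:
    """A single-nucleotide substitution and its codon-level consequence.

    When several substitutions fall in one codon the amino-acid consequence is
    computed from the fully mutated codon, so all calls in that codon share
    ``ref_aa``/``alt_aa``/``consequence``.
    """

    nt_pos: int  # 1-based position in the CDS
    ref_base: str
    alt_base: str
    codon_index: int  # 1-based
    ref_aa: str
    alt_aa: str
    consequence: Consequence

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise LibraryError("ref_base and alt_base must differ")
        if self.codon_index != ceil(self.nt_pos / 3):
            raise LibraryError("codon_index inconsistent with nt_pos")

    @property
    def substitution_type(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"


class CloneClass(str, enum.Enum):
    """Library class of a sequenced clone."""

    WILDTYPE = "wildtype"
    SINGLE_MISSENSE = "single_missense"
    MULTI_MISSENSE = "multi_missense"
    SILENT_ONLY = "silent_only"
    NONSENSE = "nonsense"
    INDEL = "indel"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CloneCalls:
    """Variant calls for one clone plus the flags that drive classification."""

    calls: tuple[VariantCall, ...]
    indel: bool = False
    ambiguous: bool = False  # clone contains N bases

    @property
    def missense_codons(self) -> tuple[int, ...]:
        """Distinct codon indices with a missense consequence (one event per
        codon, even if two substitutions in the codon produced it)."""
        seen: dict[int, None] = {}
        for c in self.calls:
            if c.consequence is Consequence.MISSENSE:
                seen.setdefault(c.codon_index, None)
        return tuple(seen)

    @property
    def has_nonsense(self) -> bool:
        return any(c.consequence is Consequence.NONSENSE for c in self.calls)


def call_variants(clone: CloneRecord, ref: ReferenceConstruct) -> CloneCalls:
    """Call substitutions in a clone against the reference CDS.

    Comparison is positional.  A clone whose length differs from the reference
    is flagged ``indel`` with an empty call list.  N bases are non-calls: a
    codon containing an N produces no calls, and the clone is flagged
    ``ambiguous`` because the N may hide a mutation.
    """
    seq = clone.sequence
    if len(seq) != len(ref.cds):
        return CloneCalls(calls=(), indel=True)
    ambiguous = "N" in seq
    calls: list[VariantCall] = []
    for codon_start in range(0, len(seq), 3):
        ref_codon = ref.cds[codon_start : codon_start + 3]
        alt_codon = seq[codon_start : codon_start + 3]
        if alt_codon == ref_codon or "N" in alt_codon:
            continue
        codon_index = codon_start // 3 + 1
        ref_aa = ref.protein[codon_index - 1]
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == STOP and ref_aa != STOP:
            consequence = Consequence.NONSENSE
        elif alt_aa == ref_aa:
            consequence = Consequence.SILENT
        else:
            consequence = Consequence.MISSENSE
        for k in range(3):
            if alt_codon[k] != ref_codon[k]:
                calls.append(
                    VariantCall(
                        nt_pos=codon_start + k + 1,
                        ref_base=ref_codon[k],
                        alt_base=alt_codon[k],
                        codon_index=codon_index,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        consequence=consequence,
                    )
                )
    return CloneCalls(calls=tuple(calls), ambiguous=ambiguous)


def classify_clone(calls: CloneCalls) -> CloneClass:
    """Classify a clone from its variant calls.

    Precedence: indel > ambiguous (N bases) > nonsense, then by the number of
    distinct missense codons.  Silent co-mutations never disqualify a single
    missense clone: classification is at the protein level.
    """
    if calls.indel:
        return CloneClass.INDEL
    if calls.ambiguous:
        return CloneClass.AMBIGUOUS
    if not calls.calls:
        return CloneClass.WILDTYPE
    if calls.has_nonsense:
        return CloneClass.NONSENSE
    n_missense = len(calls.missense_codons)
    if n_missense == 1:
        return CloneClass.SINGLE_MISSENSE
    if n_missense > 1:
        return CloneClass.MULTI_MISSENSE
    return CloneClass.SILENT_ONLY


@dataclass(frozen=True)
class ClassifiedClone:
    """A clone together with its calls and library class."""

    clone: CloneRecord
    calls: CloneCalls
    classification: CloneClass

    @property
    def missense_substitution(self) -> tuple[int, str, str] | None:
        """``(codon_index, ref_aa, alt_aa)`` for a single-missense clone."""
        if self.classification is not CloneClass.SINGLE_MISSENSE:
            return None
        codon = self.calls.missense_codons[0]
        call = next(c for c in self.calls.calls if c.codon_index == codon)
        return (codon, call.ref_aa, call.alt_aa)

    def substitution_label(self, ref: ReferenceConstruct) -> str | None:
        """Label like ``"P163L"`` in full-length-protein numbering."""
        sub = self.missense_substitution
        if sub is None:
            return None
        codon, ref_aa, alt_aa = sub
        return f"{ref_aa}{ref.residue_number(codon)}{alt_aa}"


def classify_library(
    clones: Iterable[CloneRecord], ref: ReferenceConstruct
) -> list[ClassifiedClone]:
    """Call variants and classify every clone of a library."""
    out = []
    for clone in clones:
        calls = call_variants(clone, ref)
        out.append(ClassifiedClone(clone, calls, classify_clone(calls)))
    return out


@dataclass(frozen=True)
class LibrarySummary:
    """Class counts, substitution spectrum and coverage for a set of clones.

    ``coverage`` is the fraction of construct codons hit by at least one
    single-missense mutant; ``n_unique_missense`` deduplicates single-missense
    clones by amino-acid change (codon index + alternate residue).
    """

    n_clones: int
    class_counts: Mapping[str, int]
    spectrum: Mapping[str, int]
    n_unique_missense: int
    coverage: float

    @property
    def single_missense_fraction(self) -> float:
        return self.class_counts.get(CloneClass.SINGLE_MISSENSE.value, 0) / self.n_clones


def summarize_library(
    classified: Sequence[ClassifiedClone], ref: ReferenceConstruct
) -> LibrarySummary:
    """Summarise a classified clone set (one PCR condition, or the pool)."""
    if not classified:
        raise LibraryError("cannot summarise an empty clone set")
    class_counts = Counter(c.classification.value for c in classified)
    spectrum = Counter({t: 0 for t in SUBSTITUTION_TYPES})
    for c in classified:
        for call in c.calls.calls:
            spectrum[call.substitution_type] += 1
    unique = {
        (sub[0], sub[2])
        for c in classified
        if (sub := c.missense_substitution) is not None
    }
    covered_codons = {codon for codon, _alt in unique}
    return LibrarySummary(
        n_clones=len(classified),
        class_counts=dict(class_counts),
        spectrum=dict(spectrum),
        n_unique_missense=len(unique),
        coverage=len(covered_codons) / ref.n_codons,
    )


def summarize_by_condition(
    classified: Sequence[ClassifiedClone], ref: ReferenceConstruct
) -> dict[str, LibrarySummary]:
    """One LibrarySummary per PCR condition label."""
    by_cond: dict[str, list[ClassifiedClone]] = {}
    for c in classified:
        by_cond.setdefault(c.clone.pcr_condition, []).append(c)
    return {cond: summarize_library(cs, ref) for cond, cs in sorted(by_cond.items())}


def select_pcr_condition(summaries: Mapping[str, LibrarySummary]) -> str:
    """Pick the PCR condition with the most single-missense mutants.

    Ties are broken by the higher single-missense fraction, then by
    lexicographic label (for determinism).
    """
    if not summaries:
        raise LibraryError("no PCR conditions to select from")

    def count(s: LibrarySummary) -> int:
        return s.class_counts.get(CloneClass.SINGLE_MISSENSE.value, 0)

    return min(
        summaries,
        key=lambda cond: (
            -count(summaries[cond]),
            -summaries[cond].single_missense_fraction,
            cond,
        ),
    )


# ---------------------------------------------------------------------------
# File interfaces: FASTA in, CSV out
# ---------------------------------------------------------------------------

_WELL_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[A-P]\d{1,2})$")


def read_reference_fasta(path, residue_offset: int = 1) -> ReferenceConstruct:
    """Read the reference CDS (first record of a FASTA file)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceConstruct(
        construct_id=record.id, cds=str(record.seq), residue_offset=residue_offset
    )


def read_clones_fasta(path, pcr_condition: str = "") -> list[CloneRecord]:
    """Read clone sequences; record IDs of the form ``plateID_wellID`` carry
    the colony-plate provenance into ``source_well``."""
    clones = []
    for record in SeqIO.parse(str(path), "fasta"):
        m = _WELL_RE.match(record.id)
        source_well = record.id if m else ""
        cond = pcr_condition or (record.description.split()[1] if len(record.description.split()) > 1 else "")
        clones.append(
            CloneRecord(
                clone_id=record.id,
                sequence=str(record.seq),
                source_well=source_well,
                pcr_condition=cond,
            )
        )
    return clones


def write_clones_fasta(clones: Iterable[CloneRecord], path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.clone_id, description=c.pcr_condition)
        for c in clones
    ]
    SeqIO.write(records, str(path), "fasta")


def summaries_to_frame(summaries: Mapping[str, LibrarySummary]) -> pd.DataFrame:
    """One row per PCR condition with class counts, yield and coverage."""
    rows = []
    for cond, s in summaries.items():
        row = {"pcr_condition": cond, "n_clones": s.n_clones}
        for cls in CloneClass:
            row[cls.value] = s.class_counts.get(cls.value, 0)
        row["single_missense_fraction"] = s.single_missense_fraction
        row["n_unique_missense"] = s.n_unique_missense
        row["coverage"] = s.coverage
        rows.append(row)
    return pd.DataFrame(rows)


def spectrum_to_frame(summaries: Mapping[str, LibrarySummary]) -> pd.DataFrame:
    """Substitution-spectrum table: one row per condition, one column per
    ordered nucleotide change."""
    rows = []
    for cond, s in summaries.items():
        row = {"pcr_condition": cond}
        row.update({t: s.spectrum.get(t, 0) for t in SUBSTITUTION_TYPES})
        rows.append(row)
    return pd.DataFrame(rows)
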