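"""Data model and coordinate logic for non-frameshifting protein indels.

A non-frameshifting insertion/deletion variant adds and/or removes whole
amino-acid residues from a protein sequence without disrupting the reading
frame.  Three kinds are distinguished: pure insertions, pure deletions, and
complex indels (delins), where a deletion and an insertion occur in tandem
at one locus.

Coordinate conventions
----------------------
Residue positions are 1-based and inclusive everywhere.  A deletion or
complex indel spans ``start..end`` on the wildtype sequence.  A pure
insertion is anchored "after residue p": ``start == end == p`` with
``p in [0, L]``, where ``p = 0`` denotes an N-terminal insertion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Letters accepted in protein sequences: the 20 standard amino acids plus X.
VALID_SEQUENCE_LETTERS = frozenset(AA_ALPHABET + "X")

LABELS = ("pathogenic", "neutral", "unlabeled")


class VariantError(ValueError):
    """Base class for variant construction/validation failures."""


class VariantParseError(VariantError):
    """Malformed HGVS-like p. notation."""


class ReferenceMismatchError(VariantError):
    """Stated residues disagree with the wildtype sequence."""


@dataclass(frozen=True)
class IndelVariant:
    """One non-frameshifting insertion/deletion/complex event on a protein.

    Parameters
    ----------
    protein_id : str
        Identifier of the protein the variant lies on.
    start, end : int
        1-based inclusive span on the wildtype sequence.  For pure
        insertions ``start == end`` and denotes the residue immediately
        preceding the insertion point (0 for an N-terminal insertion).
    deleted_seq : str
        Wildtype residues removed (empty for pure insertions).
    inserted_seq : str
        Residues added (empty for pure deletions).
    label : str
        One of ``pathogenic``, ``neutral``, ``unlabeled``.
    allele_count : int, optional
        Population allele count (AC); used by quality filters.
    recurrence_count : int, optional
        Number of times the variant's residue is hit in a somatic
        catalogue; used for recurrence stratification.
    """

    protein_id: str
    start: int
    end: int
    deleted_seq: str = ""
    inserted_seq: str = ""
    label: str = "unlabeled"
    allele_count: Optional[int] = None
    recurrence_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.deleted_seq and not self.inserted_seq:
            raise VariantError("variant must delete and/or insert residues")
        if self.label not in LABELS:
            raise VariantError(f"unknown label {self.label!r}")
        for name in ("deleted_seq", "inserted_seq"):
            seq = getattr(self, name)
            bad = set(seq) - VALID_SEQUENCE_LETTERS
            if bad:
                raise VariantError(f"illegal letters in {name}: {sorted(bad)}")
        if self.deleted_seq:
            if self.start < 1 or self.start > self.end:
                raise VariantError(
                    f"bad span {self.start}..{self.end} for deletion/complex"
                )
            if self.end - self.start + 1 != len(self.deleted_seq):
                raise VariantError(
                    "deleted_seq length does not match span "
                    f"{self.start}..{self.end}"
                )
        else:  # pure insertion, anchored after residue start
            if self.start != self.end:
                raise VariantError("pure insertion requires start == end")
            if self.start < 0:
                raise VariantError("insertion anchor must be >= 0")
        if self.allele_count is not None and self.allele_count < 0:
            raise VariantError("allele_count must be nonnegative")
        if self.recurrence_count is not None and self.recurrence_count < 0:
            raise VariantError("recurrence_count must be nonnegative")

    @property
    def kind(self) -> str:
        return variant_kind(self)

    @property
    def size(self) -> int:
        """Event size: max of residues inserted and deleted."""
        return max(len(self.deleted_seq), len(self.inserted_seq))

    def key(self) -> tuple:
        """Deduplication key (one event per protein locus)."""
        return (self.protein_id, self.start, self.end,
                self.deleted_seq, self.inserted_seq)

    def validate_against(self, sequence: str) -> None:
        """Check coordinates and deleted residues against *sequence*."""
        L = len(sequence)
        if self.deleted_seq:
            if self.end > L:
                raise ReferenceMismatchError(
                    f"span {self.start}..{self.end} exceeds length {L}")
            ref = sequence[self.start - 1:self.end]
            if ref != self.deleted_seq:
                raise ReferenceMismatchError(
                    f"deleted_seq {self.deleted_seq!r} != wildtype {ref!r} "
                    f"at {self.start}..{self.end} of {self.protein_id}")
        elif self.start > L:
            raise ReferenceMismatchError(
                f"insertion anchor {self.start} exceeds length {L}")


@dataclass
class ProteinRecord:
    """A protein sequence with its attached per-residue evidence.

    ``tracks`` maps mechanism name -> :class:`~indelfx.features.PropertyTrack`
    (per-residue scores with a confident threshold); ``conservation`` maps
    alignment/index name -> per-position conservation vector.  Gene-level
    function scores and homolog identity lists are optional.
    """

    protein_id: str
    sequence: str
    canonical: bool = True
    tracks: dict = field(default_factory=dict)
    conservation: dict = field(default_factory=dict)
    gene_scores: Optional[object] = None  # 1-D array-like
    homolog_identities_human: list = field(default_factory=list)
    homolog_identities_mouse: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_SEQUENCE_LETTERS
        if bad:
            raise VariantError(
                f"illegal letters in sequence of {self.protein_id}: {sorted(bad)}")
        for name, track in self.tracks.items():
            if len(track.scores) != len(self.sequence):
                raise VariantError(
                    f"track {name!r} length != sequence length for {self.protein_id}")
        for name, vec in self.conservation.items():
            if len(vec) != len(self.sequence):
                raise VariantError(
                    f"conservation {name!r} length != sequence length "
                    f"for {self.protein_id}")

    def __len__(self) -> int:
        return len(self.sequence)


def variant_kind(v: IndelVariant) -> str:
    """Classify *v* as ``insertion``, ``deletion`` or ``complex``.

    The kind is a pure function of the two sequences: insertion iff nothing
    is deleted, deletion iff nothing is inserted, complex otherwise.
    """
    if not v.deleted_seq:
        return "insertion"
    if not v.inserted_seq:
        return "deletion"
    return "complex"


_DEL_RE = re.compile(
    r"^p\.([A-Z])(\d+)(?:_([A-Z])(\d+))?del(?:ins([A-Z]+))?$")
_INS_RE = re.compile(r"^p\.([A-Z])(\d+)_([A-Z])(\d+)ins([A-Z]+)$")


def parse_variant_notation(text: str, protein: ProteinRecord,
                           **kwargs) -> IndelVariant:
    """Parse HGVS-like protein notation into a validated :class:`IndelVariant`.

    Supported grammars: ``p.K3del``, ``p.K3_L4del``, ``p.A2_K3insQ`` (the
    two anchors must be consecutive; insertion goes after the first),
    ``p.K3delinsWW``, ``p.K3_G5delinsWW``.  Extra keyword arguments (label,
    allele_count, ...) are forwarded to the variant.
    """
    text = text.strip()
    seq = protein.sequence
    m = _INS_RE.match(text)
    if m:
        aa1, p1, aa2, p2, ins = m.group(1), int(m.group(2)), m.group(3), \
            int(m.group(4)), m.group(5)
        if p2 != p1 + 1:
            raise VariantParseError(
                f"{text}: insertion anchors must be consecutive residues")
        for aa, pos in ((aa1, p1), (aa2, p2)):
            if pos < 1 or pos > len(seq):
                raise ReferenceMismatchError(f"{text}: residue {pos} out of range")
            if seq[pos - 1] != aa:
                raise ReferenceMismatchError(
                    f"{text}: expected {aa} at {pos}, sequence has {seq[pos - 1]}")
        v = IndelVariant(protein.protein_id, p1, p1, "", ins, **kwargs)
        v.validate_against(seq)
        return v
    m = _DEL_RE.match(text)
    if m:
        aa1, p1 = m.group(1), int(m.group(2))
        if m.group(3) is not None:
            aa2, p2 = m.group(3), int(m.group(4))
        else:
            aa2, p2 = aa1, p1
        ins = m.group(5) or ""
        if p2 < p1:
            raise VariantParseError(f"{text}: end before start")
        for aa, pos in ((aa1, p1), (aa2, p2)):
            if pos < 1 or pos > len(seq):
                raise ReferenceMismatchError(f"{text}: residue {pos} out of range")
            if seq[pos - 1] != aa:
                raise ReferenceMismatchError(
                    f"{text}: expected {aa} at {pos}, sequence has {seq[pos - 1]}")
        v = IndelVariant(protein.protein_id, p1, p2, seq[p1 - 1:p2], ins, **kwargs)
        v.validate_against(seq)
        return v
    raise VariantParseError(f"unrecognized variant notation: {text!r}")


def apply_variant(seq: str, v: IndelVariant) -> str:
    """Return the mutant sequence produced by applying *v* to *seq*."""
    v.validate_against(seq)
    if v.deleted_seq:
        return seq[:v.start - 1] + v.inserted_seq + seq[v.end:]
    p = v.start  # insert after residue p (0 = N-terminal)
    return seq[:p] + v.inserted_seq + seq[p:]


def impacted_residues(v: IndelVariant, L: int, mode: str) -> tuple:
    """Wildtype residue positions considered impacted by *v*.

    ``mode="impact"`` (per-variant functional-impact statistics): the
    deleted range plus three flanking residues on each side; for pure
    insertions, three residues on each side of the insertion boundary.

    ``mode="enrichment"`` (cohort enrichment): the deleted range for
    deletions and complex indels; for insertions, the two residues on
    either side of the insertion point.

    Positions are clipped to ``[1, L]``; terminal truncation is silent.
    """
    if mode not in ("impact", "enrichment"):
        raise ValueError(f"unknown mode {mode!r}")
    if v.deleted_seq:
        if mode == "impact":
            lo, hi = v.start - 3, v.end + 3
        else:
            lo, hi = v.start, v.end
    else:
        p = v.start  # insertion between p and p+1
        if mode == "impact":
            lo, hi = p - 2, p + 3
        else:
            lo, hi = p - 1, p + 2
    return tuple(range(max(1, lo), min(L, hi) + 1))
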