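"""Variant identity and normalization.

All set algebra in this package operates on :class:`VariantKey` — a normalized
``(chrom, pos, ref, alt)`` tuple. Genotypes are deliberately not part of
identity: pooled call sets are compared on variant *detection* only
(squash-ploidy semantics). Multi-allelic records are split into one key per
alternate allele before keys exist, and indels are left-aligned to their
leftmost parsimonious representation against a reference window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "SNV",
    "INDEL",
    "VariantKey",
    "AnnotatedCall",
    "ReferenceWindow",
    "NormalizationError",
    "ReferenceMismatchError",
    "OutOfWindowError",
    "UnsupportedAlleleError",
    "normalize_record",
    "classify",
]

SNV = "SNV"
INDEL = "INDEL"

_VALID_BASES = frozenset("ACGTN")


class NormalizationError(ValueError):
    """Base class for variant normalization failures."""


class ReferenceMismatchError(NormalizationError):
    """REF allele disagrees with the reference sequence at its position."""


class OutOfWindowError(NormalizationError):
    """Left-shifting exited the provided reference window."""


class UnsupportedAlleleError(NormalizationError):
    """Symbolic, breakend or spanning-deletion alleles are out of scope."""


def _validate_allele(allele: str, what: str) -> None:
    if not allele:
        raise UnsupportedAlleleError(f"empty {what} allele")
    if allele == "*" or allele.startswith("<") or "[" in allele or "]" in allele:
        raise UnsupportedAlleleError(
            f"unsupported {what} allele {allele!r}: symbolic/breakend/spanning "
            "alleles are outside the scope of SNV and small-indel analysis"
        )
    bad = set(allele) - _VALID_BASES
    if bad:
        raise UnsupportedAlleleError(
            f"{what} allele {allele!r} contains non-ACGTN characters {sorted(bad)}"
        )


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized variant identity: ``(chrom, pos, ref, alt)``.

    ``pos`` is the 1-based position of the first reference base. Exactly one
    alternate allele per key. Equality and hashing use the four coordinate
    fields only; the variant-type label is derived.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        _validate_allele(self.ref, "ref")
        _validate_allele(self.alt, "alt")

    @property
    def vtype(self) -> str:
        """``SNV`` iff both alleles are single bases, else ``INDEL``."""
        return SNV if len(self.ref) == 1 and len(self.alt) == 1 else INDEL

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def classify(key: VariantKey) -> str:
    """Return the variant-type label (``SNV`` or ``INDEL``) of a key."""
    return key.vtype


@dataclass
class AnnotatedCall:
    """A called variant with its technical annotations.

    ``annotations`` maps caller-namespace names (QD, FS, MQ, DP, AF,
    MQRankSum, ...) to numeric values. Missing values are explicit ``None``,
    never silently zero; unknown annotation names are preserved.
    """

    key: VariantKey
    annotations: dict[str, Optional[float]] = field(default_factory=dict)
    source_pool: str = ""

    def annotation(self, name: str) -> Optional[float]:
        return self.annotations.get(name)


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence: ``chrom``, 1-based inclusive ``start``, ``seq``."""

    chrom: str
    start: int
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError("reference window must contain at least one base")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + len(self.seq) - 1

    def base(self, pos: int) -> str:
        if not self.start <= pos <= self.end:
            raise OutOfWindowError(
                f"position {pos} outside window {self.chrom}:{self.start}-{self.end}"
            )
        return self.seq[pos - self.start]

    def fetch(self, pos: int, length: int) -> str:
        if pos < self.start or pos + length - 1 > self.end:
            raise OutOfWindowError(
                f"span {pos}+{length} outside window {self.chrom}:{self.start}-{self.end}"
            )
        off = pos - self.start
        return self.seq[off : off + length]

    def apply(self, pos: int, ref: str, alt: str) -> str:
        """Haplotype produced by substituting ``alt`` for ``ref`` at ``pos``."""
        if self.fetch(pos, len(ref)) != ref:
            raise ReferenceMismatchError(
                f"ref {ref!r} does not match window at {self.chrom}:{pos}"
            )
        off = pos - self.start
        return self.seq[:off] + alt + self.seq[off + len(ref) :]


def _left_align(pos: int, ref: str, alt: str, window: ReferenceWindow) -> tuple[int, str, str]:
    # Trim shared trailing bases, re-anchoring with the preceding reference
    # base whenever an allele would empty; then trim shared leading bases.
    # This is the standard leftmost-parsimonious canonicalization.
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                anchor_pos = pos - 1
                anchor = window.base(anchor_pos)  # raises OutOfWindowError
                pos = anchor_pos
                ref, alt = anchor + ref, anchor + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_record(
    chrom: str,
    pos: int,
    ref: str,
    alts: Iterable[str],
    reference: ReferenceWindow,
) -> list[VariantKey]:
    """Split a (possibly multi-allelic) record and left-align each allele.

    Returns one :class:`VariantKey` per alternate allele, in input order, each
    in canonical leftmost-parsimonious form. Raises
    :class:`ReferenceMismatchError` when ``ref`` disagrees with the window and
    :class:`OutOfWindowError` when left-shifting would exit the window.
    """
    ref = ref.upper()
    alts = [a.upper() for a in alts]
    if not alts:
        raise NormalizationError(f"record {chrom}:{pos} has no alternate alleles")
    _validate_allele(ref, "ref")
    for a in alts:
        _validate_allele(a, "alt")
    if reference.chrom != chrom:
        raise ReferenceMismatchError(
            f"window is for {reference.chrom}, record is on {chrom}"
        )
    if reference.fetch(pos, len(ref)) != ref:
        raise ReferenceMismatchError(
            f"ref {ref!r} does not match reference at {chrom}:{pos} "
            f"(window has {reference.fetch(pos, len(ref))!r})"
        )
    keys = []
    for alt in alts:
        if alt == ref:
            raise NormalizationError(f"alt equals ref at {chrom}:{pos}: {alt!r}")
        p, r, a = _left_align(pos, ref, alt, reference)
        keys.append(VariantKey(chrom, p, r, a))
    return keys
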