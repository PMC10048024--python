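"""Core variant-locus model, allele normalization, and genotype container.

A :class:`VariantLocus` is one short insertion/deletion site in the anchored
VCF representation: 1-based position, a reference allele and one or more
alternative alleles of unequal length.  Loci with exactly one alternative
allele are *diallelic*; loci with two or more are *multiallelic*
(microsatellite-like expanded repeats, typically).

Normalization puts every allele pair into the left-aligned, parsimonious
form used as the matching key everywhere downstream (integration across
samples, registered-variant lookup, population database queries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import numpy as np

ALLELE_ALPHABET = frozenset("ACGTN")

#: sentinel allele index for a missing call
MISSING = -1


class MalformedVariantError(ValueError):
    """Raised when a record violates the locus invariants."""


@dataclass(frozen=True, order=True)
class VariantLocus:
    """One normalized INDEL site.

    Attributes
    ----------
    chrom : str
        Chromosome name as spelled in the source file.
    pos : int
        1-based position of the anchor base (VCF convention).
    ref : str
        Reference allele, including the anchor base.
    alts : tuple of str
        Ordered alternative alleles.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MalformedVariantError(f"position must be 1-based, got {self.pos}")
        for allele in (self.ref, *self.alts):
            if not allele or set(allele) - ALLELE_ALPHABET:
                raise MalformedVariantError(f"bad allele {allele!r} at {self.chrom}:{self.pos}")
        if any(alt == self.ref for alt in self.alts):
            raise MalformedVariantError(f"Ref == Alt at {self.chrom}:{self.pos}")
        if len(self.alts) == 0:
            raise MalformedVariantError(f"no Alt allele at {self.chrom}:{self.pos}")

    @property
    def allelicity(self) -> str:
        return "diallelic" if len(self.alts) == 1 else "multiallelic"

    @property
    def is_diallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def size_deltas(self) -> tuple[int, ...]:
        """Alt length minus Ref length, per alternative allele."""
        return tuple(len(a) - len(self.ref) for a in self.alts)

    @property
    def size_delta(self) -> int:
        """Size delta of a diallelic locus (bp; negative = deletion)."""
        if not self.is_diallelic:
            raise ValueError("size_delta is defined for diallelic loci only")
        return len(self.alts[0]) - len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, tuple[str, ...]]:
        return (self.chrom, self.pos, self.ref, self.alts)

    def pair_keys(self) -> list[tuple]:
        """Normalized event keys, one per Ref/Alt pair (see :func:`event_key`)."""
        out = []
        for alt in self.alts:
            pos, ref, (a,) = normalize_alleles(self.pos, self.ref, (alt,))
            out.append(event_key(self.chrom, pos, ref, a))
        return out


def is_indel_pair(ref: str, alt: str) -> bool:
    """True when a Ref/Alt pair is an insertion or deletion (unequal lengths).

    Equal-length pairs (SNVs and multi-base substitutions) are not INDELs.
    """
    return len(ref) != len(alt)


def normalize_alleles(
    pos: int,
    ref: str,
    alts: Sequence[str],
    reference: Optional[str] = None,
) -> tuple[int, str, tuple[str, ...]]:
    """Left-align and make parsimonious an allele set at one site.

    The shared suffix is trimmed while every allele keeps at least one base;
    the shared prefix is trimmed down to a single anchor base, advancing the
    position.  When ``reference`` (the full chromosome sequence, 0-indexed)
    is supplied, alleles ending in a common base are shifted left through
    the reference, which left-aligns repeats; without reference context the
    function can only trim.

    Idempotent: normalizing a normalized site is the identity.
    """
    alleles = [ref, *alts]
    changed = True
    while changed:
        changed = False
        # trim shared trailing base (parsimony), all alleles keep >= 1 base
        while (
            all(len(a) > 1 for a in alleles)
            and len({a[-1] for a in alleles}) == 1
        ):
            alleles = [a[:-1] for a in alleles]
            changed = True
        # left extension: if some allele is exhausted down to its last base
        # and all alleles still share that trailing base, prepend the
        # reference base before pos and retry the trim (classic vt loop)
        if (
            reference is not None
            and pos > 1
            and len({a[-1] for a in alleles}) == 1
            and any(len(a) == 1 for a in alleles)
        ):
            prev = reference[pos - 2]
            alleles = [prev + a[:-1] for a in alleles]
            pos -= 1
            changed = True
    # trim shared leading bases down to one anchor
    while all(len(a) > 1 for a in alleles) and len({a[0] for a in alleles}) == 1 and len({a[1] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    return pos, alleles[0], tuple(alleles[1:])


def normalize_locus(locus: VariantLocus, reference: Optional[str] = None) -> VariantLocus:
    pos, ref, alts = normalize_alleles(locus.pos, locus.ref, locus.alts, reference)
    return VariantLocus(locus.chrom, pos, ref, alts)


def event_key(chrom: str, pos: int, ref: str, alt: str) -> tuple:
    """Anchor-free identity of one normalized Ref/Alt pair.

    Pure insertions and deletions are keyed by the inserted/deleted bases
    and the 1-based position of the first affected base, so the same event
    compares equal whether it came from an anchored VCF record or from an
    anchor-free GVF line.  Complex (length-changing substitution) pairs
    keep the anchored representation.
    """
    if len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
        return ("ins", chrom, pos + 1, alt[1:])
    if len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
        return ("del", chrom, pos + 1, ref[1:])
    return ("cx", chrom, pos, ref, alt)


@dataclass
class GenotypeMatrix:
    """Loci-by-samples diploid genotype calls.

    ``calls`` has shape (n_loci, n_samples, 2) holding allele indices
    (0 = Ref, 1.. = Alts in locus order) with :data:`MISSING` for no-calls.
    Allele pairs are unordered and stored sorted.
    """

    loci: list[VariantLocus]
    samples: list[str]
    calls: np.ndarray
    info: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.loci), len(self.samples), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")
        if not self.info:
            self.info = [{} for _ in self.loci]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Row-subset by boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            [self.loci[i] for i in idx],
            list(self.samples),
            self.calls[idx],
            [self.info[i] for i in idx],
        )

    def validate_indices(self) -> None:
        for i, locus in enumerate(self.loci):
            mx = int(self.calls[i].max(initial=MISSING))
            if mx > len(locus.alts):
                raise ValueError(f"allele index {mx} out of range at {locus.chrom}:{locus.pos}")


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero at a fixed number of decimals.

    Report-level rounding; avoids banker's rounding so printed counts and
    percentages are stable across platforms.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: float, whole: float, decimals: int = 1) -> float:
    """100*part/whole rounded half away from zero."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * part / whole, decimals)


def chromosome_compartment(chrom: str) -> str:
    """Map a chromosome name to {autosomes, X, MT, other}.

    Accepts plain ("12", "X", "MT") and prefixed ("chr12") spellings.
    """
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.upper() in {"X"}:
        return "X"
    if name.upper() in {"MT", "M"}:
        return "MT"
    if name.isdigit():
        return "autosomes"
    return "other"


def sort_loci_order(loci: Iterable[VariantLocus], chrom_order: Sequence[str]) -> list[int]:
    """Indices that sort loci by chromosome-table order, then position."""
    rank = {c: i for i, c in enumerate(chrom_order)}
    items = list(loci)
    return sorted(
        range(len(items)),
        key=lambda i: (rank.get(items[i].chrom, len(rank)), items[i].chrom, items[i].pos, items[i].ref, items[i].alts),
    )
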