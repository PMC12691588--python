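"""Core types and algorithms for inverted-repeat-flanked invertible loci.

An invertible locus is a genomic segment bracketed by a pair of inverted
repeats (IRs): the right repeat is the reverse complement of the left one.
Site-specific recombination between the repeats flips the intervening
spacer, toggling the locus between a *forward* and an *inverted* orientation
state.  Because the right IR is the reverse complement of the left, reverse
complementing the whole IR-to-IR segment leaves the repeats in place and
only reverses the spacer, so the two states differ exclusively inside it.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AmbiguousPlacementError, ConfigError, DataError, DNAAlphabetError
from .align import find_infix_matches, global_identity

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def validate_dna(seq: str, context: str = "") -> str:
    """Uppercase ``seq`` and reject characters outside {A,C,G,T,N}."""
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in DNA_ALPHABET:
            raise DNAAlphabetError(c, i, context)
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    seq = validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ConfigError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class GenomeSequence:
    """A single DNA record (contig, assembly, amplicon or read)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.seq:
            raise DataError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", validate_dna(self.seq, context=self.id))

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(self.id, reverse_complement(self.seq), self.description)


@dataclass(frozen=True)
class InvertedRepeatPair:
    """A left/right inverted-repeat pair on a parent sequence.

    The right repeat equals the reverse complement of the left repeat up to
    ``mismatches`` substitutions.  Coordinates are 0-based half-open on the
    parent sequence.
    """

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    repeat_len: int
    mismatches: int = 0

    def __post_init__(self):
        if self.left_end - self.left_start != self.repeat_len:
            raise ConfigError("left repeat length inconsistent with repeat_len")
        if self.right_end - self.right_start != self.repeat_len:
            raise ConfigError("right repeat length inconsistent with repeat_len")
        if self.left_end > self.right_start:
            raise ConfigError("left repeat must end at or before right repeat start")
        if self.mismatches < 0:
            raise ConfigError("mismatches must be non-negative")

    @property
    def spacer_len(self) -> int:
        return self.right_start - self.left_end

    @property
    def segment_len(self) -> int:
        """IR-to-IR length, repeats included."""
        return self.right_end - self.left_start


def build_orientation_states(
    reference_segment: str, ir: InvertedRepeatPair
) -> tuple[str, str]:
    """Return (forward_state, inverted_state) for a locus segment.

    The inverted state reverse-complements the full IR-to-IR stretch
    ``[ir.left_start, ir.right_end)`` in place.  Sequence outside that
    stretch is untouched, and applying the operation twice restores the
    input (involution).
    """
    seg = validate_dna(reference_segment)
    if ir.left_start < 0 or ir.right_end > len(seg):
        raise DataError(
            f"IR coordinates [{ir.left_start}, {ir.right_end}) outside "
            f"segment of length {len(seg)}"
        )
    middle = seg[ir.left_start : ir.right_end]
    inverted = seg[: ir.left_start] + reverse_complement(middle) + seg[ir.right_end :]
    return seg, inverted


@dataclass(frozen=True)
class InvertibleLocus:
    """A reference invertible locus with both orientation-state sequences.

    ``ir`` coordinates are relative to ``forward_state``.  ``left_anchor``
    and ``right_anchor`` are the segments flanking the IR pair, used to
    localize the locus in other genomes (they are orientation-invariant).
    """

    name: str
    reference_id: str
    ir: InvertedRepeatPair
    left_anchor: str
    right_anchor: str
    forward_state: str
    inverted_state: str
    spacer_len: int = field(default=-1)

    def __post_init__(self):
        object.__setattr__(self, "left_anchor", validate_dna(self.left_anchor))
        object.__setattr__(self, "right_anchor", validate_dna(self.right_anchor))
        object.__setattr__(self, "forward_state", validate_dna(self.forward_state))
        object.__setattr__(self, "inverted_state", validate_dna(self.inverted_state))
        if self.spacer_len < 0:
            object.__setattr__(self, "spacer_len", self.ir.spacer_len)
        if self.spacer_len != self.ir.spacer_len:
            raise ConfigError("spacer_len inconsistent with IR coordinates")
        _, expect_inv = build_orientation_states(self.forward_state, self.ir)
        if expect_inv != self.inverted_state:
            raise DataError(
                f"locus {self.name!r}: inverted_state is not the IR-to-IR "
                "reverse complement of forward_state"
            )
        left = self.forward_state[self.ir.left_start : self.ir.left_end]
        right = self.forward_state[self.ir.right_start : self.ir.right_end]
        if hamming(left, reverse_complement(right)) > self.ir.mismatches:
            raise DataError(
                f"locus {self.name!r}: repeats are not inverted within the "
                f"declared mismatch budget ({self.ir.mismatches})"
            )

    @classmethod
    def from_segment(
        cls,
        name: str,
        reference_id: str,
        segment: str,
        ir: InvertedRepeatPair,
    ) -> "InvertibleLocus":
        """Build a locus from a reference-orientation segment and IR coordinates."""
        fwd, inv = build_orientation_states(segment, ir)
        return cls(
            name=name,
            reference_id=reference_id,
            ir=ir,
            left_anchor=fwd[: ir.left_start],
            right_anchor=fwd[ir.right_end :],
            forward_state=fwd,
            inverted_state=inv,
        )

    @property
    def segment_len(self) -> int:
        """IR-to-IR inversion length, repeats included (spacer_len excludes them)."""
        return self.ir.segment_len


@dataclass(frozen=True)
class LocusHit:
    """Placement of a locus on a genome, found by anchor homology."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    anchor_identity_left: float
    anchor_identity_right: float

    def __post_init__(self):
        if not self.start < self.end:
            raise DataError("LocusHit requires start < end")
        if self.strand not in "+-":
            raise DataError("strand must be '+' or '-'")
        for v in (self.anchor_identity_left, self.anchor_identity_right):
            if not 0.0 <= v <= 1.0:
                raise DataError("anchor identities must lie in [0, 1]")


def find_inverted_repeat_pairs(
    seq: str,
    min_repeat: int,
    max_repeat: int | None = None,
    min_spacer: int = 0,
    max_spacer: int | None = None,
    max_mismatches: int = 0,
) -> list[InvertedRepeatPair]:
    """Find all maximal inverted-repeat pairs in ``seq``.

    A pair (left repeat at ``[i, i+L)``, right repeat at ``[j, j+L)``) is
    valid when the left repeat equals the reverse complement of the right
    repeat up to ``max_mismatches`` substitutions, ``min_repeat <= L <=
    max_repeat`` and the spacer ``j - (i+L)`` lies in ``[min_spacer,
    max_spacer]``.  Only maximal pairs are reported: a pair is suppressed if
    it can be grown by one base on both repeats — inward (spacer shrinks by
    two) or outward (spacer unchanged) — and remain valid.

    Positions containing N never match.  Results are sorted by ``left_start``
    then ``repeat_len`` descending.

    Implementation note: a pair with right-repeat end ``e = j + L`` satisfies
    ``i + e = s`` for a fixed anti-diagonal ``s``; base ``p`` of the left
    repeat pairs with base ``s - 1 - p`` of the right one, and both one-base
    extensions stay on the same anti-diagonal.  Each anti-diagonal is scanned
    once with a mismatch prefix sum, so candidates and their extensions are
    checked in O(1).
    """
    seq = validate_dna(seq)
    n = len(seq)
    if n == 0:
        return []
    if max_repeat is None:
        max_repeat = max(min_repeat, n // 2)
    if max_spacer is None:
        max_spacer = n
    if not (0 < min_repeat <= max_repeat):
        raise ConfigError("require 0 < min_repeat <= max_repeat")
    if not (0 <= min_spacer <= max_spacer):
        raise ConfigError("require 0 <= min_spacer <= max_spacer")
    if max_mismatches < 0:
        raise ConfigError("max_mismatches must be non-negative")
    if n == 0 or 2 * min_repeat + min_spacer > n:
        return []

    comp = seq.translate(_COMPLEMENT)
    pairs: list[InvertedRepeatPair] = []

    # s = left_start + right_end ranges over [2*min_repeat + min_spacer, 2n].
    for s in range(2 * min_repeat + min_spacer, 2 * n + 1):
        p_lo = max(0, s - n)
        p_hi = (s - 2) // 2  # largest p with p < s-1-p
        if p_hi < p_lo:
            continue
        width = p_hi - p_lo + 1
        # mis[t] = 1 if base p_lo+t does not pair with base s-1-(p_lo+t)
        pref = [0] * (width + 1)
        acc = 0
        for t in range(width):
            p = p_lo + t
            q = s - 1 - p
            a = seq[p]
            if a == "N" or a != comp[q]:
                acc += 1
            pref[t + 1] = acc

        def mis(i: int, length: int) -> int:
            return pref[i + length - p_lo] - pref[i - p_lo]

        # For fixed (s, i) the spacer is s - 2i - 2L, so L and spacer are
        # interchangeable; only the largest valid L is non-extendable inward.
        for i in range(p_lo, p_hi + 1):
            # L bounds from the spacer window (floor/ceil division)
            l_hi = min(max_repeat, (s - 2 * i - min_spacer) // 2, p_hi + 1 - i)
            l_lo = max(min_repeat, -((-(s - 2 * i - max_spacer)) // 2))
            if l_hi < l_lo:
                continue
            # mismatches are monotone in L: take the largest L within budget
            l_top = l_hi
            while l_top >= l_lo and mis(i, l_top) > max_mismatches:
                l_top -= 1
            if l_top < l_lo:
                continue
            L = l_top
            spacer = s - 2 * i - 2 * L
            # inward extension (i, L+1), spacer-2: only possible if L was
            # capped by the mismatch budget or parameter bounds
            inward_ok = (
                L + 1 <= max_repeat
                and spacer - 2 >= min_spacer
                and i + L <= p_hi
                and mis(i, L + 1) <= max_mismatches
            )
            if inward_ok:
                continue
            # outward extension (i-1, L+1), same spacer
            outward_ok = (
                L + 1 <= max_repeat
                and i - 1 >= max(0, s - n)
                and mis(i - 1, L + 1) <= max_mismatches
            )
            if outward_ok:
                continue
            j = s - i - L
            pairs.append(
                InvertedRepeatPair(
                    left_start=i,
                    left_end=i + L,
                    right_start=j,
                    right_end=j + L,
                    repeat_len=L,
                    mismatches=mis(i, L),
                )
            )

    pairs.sort(key=lambda p: (p.left_start, -p.repeat_len))
    return pairs


def locate_locus_by_anchors(
    genome: GenomeSequence,
    locus: InvertibleLocus,
    min_anchor_identity: float = 0.8,
) -> LocusHit | None:
    """Localize a locus on a genome via its two flanking anchors.

    Both anchors are searched against the genome and its reverse complement.
    A qualifying placement needs both anchors at identity >=
    ``min_anchor_identity``, collinear (left before right) and an implied
    interval no longer than 3x the reference locus.  The best placement (by
    summed anchor identity) is returned with plus-strand genome coordinates;
    ``None`` means the locus was not localized.

    Raises :class:`AmbiguousPlacementError` when several non-overlapping
    placements qualify.
    """
    if len(locus.left_anchor) < 30 or len(locus.right_anchor) < 30:
        raise ConfigError("anchors must be at least 30 nt")
    if not 0.5 < min_anchor_identity <= 1.0:
        raise ConfigError("min_anchor_identity must lie in (0.5, 1]")
    n = len(genome.seq)
    max_span = 3 * len(locus.forward_state)

    candidates: list[tuple[int, int, str, float, float]] = []
    for strand, target in (("+", genome.seq), ("-", reverse_complement(genome.seq))):
        lefts = find_infix_matches(locus.left_anchor, target, min_anchor_identity)
        rights = find_infix_matches(locus.right_anchor, target, min_anchor_identity)
        for lm in lefts:
            for rm in rights:
                if lm.end <= rm.start and (rm.end - lm.start) <= max_span:
                    if strand == "+":
                        start, end = lm.start, rm.end
                    else:
                        start, end = n - rm.end, n - lm.start
                    candidates.append((start, end, strand, lm.identity, rm.identity))

    if not candidates:
        return None
    candidates.sort(key=lambda c: (-(c[3] + c[4]), c[0]))
    best = candidates[0]
    for other in candidates[1:]:
        if other[1] <= best[0] or other[0] >= best[1]:  # non-overlapping
            raise AmbiguousPlacementError(
                locus.name,
                [(genome.id, c[0], c[1], c[2]) for c in (best, other)],
            )
    return LocusHit(
        genome_id=genome.id,
        contig_id=genome.id,
        start=best[0],
        end=best[1],
        strand=best[2],
        anchor_identity_left=best[3],
        anchor_identity_right=best[4],
    )


def extract_locus_sequence(genome: GenomeSequence, hit: LocusHit) -> str:
    """Locus sequence implied by a hit, canonicalized to the reference strand."""
    sub = genome.seq[hit.start : hit.end]
    return sub if hit.strand == "+" else reverse_complement(sub)
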