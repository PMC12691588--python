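"""Inversion-frequency estimation from mixed-population sequencing.

Two estimators for the fraction of a population carrying the inverted
orientation of a locus:

* the amplicon path — denoised amplicon sequence variants (ASVs) are
  classified against labeled (strain, orientation) reference sequences by
  best global-alignment identity with a minimum-identity floor, and
  per-sample counts are pooled per strain;
* the junction path — whole-genome reads are assigned to an orientation
  when they contain an exact diagnostic junction (IR/spacer boundary with a
  window of flanking bases on each side) of exactly one orientation state.

Both report exact (Clopper-Pearson) binomial 95% intervals, appropriate for
small per-sample counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from scipy.stats import beta

from .align import global_identity
from .errors import ConfigError, DataError
from .locus import GenomeSequence, InvertibleLocus, reverse_complement, validate_dna

ORIENTATIONS = ("forward", "inverted")


@dataclass(frozen=True)
class ASVRecord:
    """An amplicon sequence variant with per-sample read counts."""

    asv_id: str
    seq: str
    counts: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "seq", validate_dna(self.seq, context=self.asv_id))
        if not self.seq:
            raise DataError(f"ASV {self.asv_id!r} has an empty sequence")
        for sample, c in self.counts.items():
            if c < 0:
                raise DataError(f"ASV {self.asv_id!r} has negative count in {sample!r}")


@dataclass(frozen=True)
class AmpliconReferenceSet:
    """Labeled amplicon references: (strain_id, orientation) -> sequence."""

    references: Mapping[tuple[str, str], str]

    def __post_init__(self):
        refs = {}
        for (strain, orient), seq in self.references.items():
            if orient not in ORIENTATIONS:
                raise ConfigError(f"orientation must be one of {ORIENTATIONS}")
            refs[(strain, orient)] = validate_dna(seq, context=f"{strain}/{orient}")
        object.__setattr__(self, "references", refs)

    @classmethod
    def from_loci(cls, loci: Mapping[str, InvertibleLocus]) -> "AmpliconReferenceSet":
        """Build the 2-strains x 2-orientations set from per-strain loci."""
        refs = {}
        for strain, locus in loci.items():
            refs[(strain, "forward")] = locus.forward_state
            refs[(strain, "inverted")] = locus.inverted_state
        return cls(refs)

    @property
    def strains(self) -> list[str]:
        return sorted({s for s, _ in self.references})


class ClassifiedASV(NamedTuple):
    asv_id: str
    label: tuple[str, str] | str  # (strain, orientation) | 'unclassified' | 'ambiguous'
    identity: float


def classify_asv(
    asv: ASVRecord,
    refs: AmpliconReferenceSet,
    min_identity: float = 0.97,
    tie_epsilon: float = 0.01,
) -> ClassifiedASV:
    """Classify an ASV by best global-alignment identity to the references.

    ``unclassified`` when the best identity is below ``min_identity`` (the
    assay's floor, default 97%); ``ambiguous`` when the top two labels are
    within ``tie_epsilon`` of each other.
    """
    if not refs.references:
        raise ConfigError("empty amplicon reference set")
    scored = sorted(
        ((global_identity(asv.seq, seq), label) for label, seq in refs.references.items()),
        key=lambda t: (-t[0], t[1]),
    )
    best_id, best_label = scored[0]
    if best_id < min_identity:
        return ClassifiedASV(asv.asv_id, "unclassified", best_id)
    if len(scored) > 1 and best_id - scored[1][0] < tie_epsilon:
        return ClassifiedASV(asv.asv_id, "ambiguous", best_id)
    return ClassifiedASV(asv.asv_id, best_label, best_id)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) two-sided confidence interval."""
    if not 0 <= k <= n:
        raise ConfigError("require 0 <= k <= n")
    if n == 0:
        return (float("nan"), float("nan"))
    low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


@dataclass
class AmpliconInversionResult:
    """Per strain x sample inversion frequencies plus audit counts."""

    frequencies: pd.DataFrame  # strain_id, sample_id, n_forward, n_inverted, ...
    sample_summary: pd.DataFrame  # sample_id, n_classified, n_ambiguous, n_unclassified, n_total
    classifications: list[ClassifiedASV] = field(default_factory=list)


def inversion_rate_from_asv_table(
    asvs: Iterable[ASVRecord],
    refs: AmpliconReferenceSet,
    min_identity: float = 0.97,
    tie_epsilon: float = 0.01,
) -> AmpliconInversionResult:
    """Estimate per-strain, per-sample inversion fractions from an ASV table.

    Every ASV is classified once; counts are pooled by (strain, orientation,
    sample).  Ambiguous and unclassified reads are excluded from the
    denominator but reported per sample so the accounting can be audited:
    classified + ambiguous + unclassified equals the sample's total reads.
    Strain x sample cells with zero classifiable reads report NaN fractions.
    """
    asvs = list(asvs)
    classifications = [classify_asv(a, refs, min_identity, tie_epsilon) for a in asvs]
    samples = sorted({s for a in asvs for s in a.counts})
    strains = refs.strains

    pooled: dict[tuple[str, str, str], int] = {}
    audit: dict[str, dict[str, int]] = {
        s: {"n_classified": 0, "n_ambiguous": 0, "n_unclassified": 0, "n_total": 0}
        for s in samples
    }
    for asv, cls in zip(asvs, classifications):
        for sample, count in asv.counts.items():
            audit[sample]["n_total"] += count
            if isinstance(cls.label, tuple):
                strain, orient = cls.label
                key = (strain, orient, sample)
                pooled[key] = pooled.get(key, 0) + count
                audit[sample]["n_classified"] += count
            elif cls.label == "ambiguous":
                audit[sample]["n_ambiguous"] += count
            else:
                audit[sample]["n_unclassified"] += count

    rows = []
    for strain in strains:
        for sample in samples:
            n_fwd = pooled.get((strain, "forward", sample), 0)
            n_inv = pooled.get((strain, "inverted", sample), 0)
            n = n_fwd + n_inv
            if n:
                frac = n_inv / n
                lo, hi = clopper_pearson(n_inv, n)
            else:
                frac, lo, hi = float("nan"), float("nan"), float("nan")
            rows.append(
                {
                    "strain_id": strain,
                    "sample_id": sample,
                    "n_forward": n_fwd,
                    "n_inverted": n_inv,
                    "fraction_inverted": frac,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    freq = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [{"sample_id": s, **audit[s]} for s in samples]
    )
    return AmpliconInversionResult(freq, summary, classifications)


@dataclass(frozen=True)
class JunctionInversionResult:
    n_forward: int
    n_inverted: int
    n_both: int  # matched junctions of both states; discarded
    n_neither: int  # spanned no diagnostic junction; discarded
    fraction_inverted: float
    ci_low: float
    ci_high: float


def diagnostic_junctions(
    locus: InvertibleLocus, min_anchor: int = 20
) -> dict[str, list[str]]:
    """Diagnostic junction windows (2 repeats x 2 states) for a locus.

    Each window spans one full repeat plus ``min_anchor`` flanking bases on
    each side (flank into spacer).  Crossing the *whole* repeat is essential:
    because the right repeat is the reverse complement of the left one, a
    window that touches only one repeat edge reads, on the opposite strand,
    exactly like the other state's window at the other repeat, and
    strand-agnostic matching could not tell the two orientations apart.
    Anchoring in the unique flank on one side and the spacer on the other
    makes each window state-specific.  Windows shared verbatim between the
    two states (orientation-symmetric spacers) are removed from both.
    """
    if locus.spacer_len < min_anchor:
        raise ConfigError(
            f"locus {locus.name!r}: spacer ({locus.spacer_len} nt) shorter than "
            f"min_anchor ({min_anchor} nt); junctions are not diagnostic"
        )
    ir = locus.ir
    out: dict[str, list[str]] = {}
    for state, seq in (("forward", locus.forward_state), ("inverted", locus.inverted_state)):
        wins = []
        for rep_start, rep_end in ((ir.left_start, ir.left_end),
                                   (ir.right_start, ir.right_end)):
            lo, hi = rep_start - min_anchor, rep_end + min_anchor
            if lo < 0 or hi > len(seq):
                raise ConfigError(
                    f"locus {locus.name!r}: junction window [{lo}, {hi}) exceeds the "
                    "locus sequence; shrink min_anchor or extend the anchors"
                )
            wins.append(seq[lo:hi])
        out[state] = wins
    shared = set(out["forward"]) & set(out["inverted"])
    for state in out:
        out[state] = [w for w in out[state] if w not in shared]
    if not out["forward"] or not out["inverted"]:
        raise ConfigError(
            f"locus {locus.name!r}: no diagnostic junctions remain (orientation-"
            "symmetric spacer)"
        )
    return out


def inversion_rate_from_junction_reads(
    reads: Iterable[str | GenomeSequence],
    locus: InvertibleLocus,
    min_anchor: int = 20,
) -> JunctionInversionResult:
    """Estimate the inversion fraction from junction-spanning reads.

    A read supports an orientation when it (or its reverse complement)
    contains a diagnostic junction window of that state as an exact
    substring, guaranteeing ``min_anchor`` matched bases on both sides of the
    boundary.  Reads matching both states or neither are discarded but
    counted, so assigned + discarded equals the input total.
    """
    junctions = diagnostic_junctions(locus, min_anchor)
    window_len = locus.ir.repeat_len + 2 * min_anchor
    n_fwd = n_inv = n_both = n_neither = 0
    for read in reads:
        seq = read.seq if isinstance(read, GenomeSequence) else validate_dna(read)
        if len(seq) < window_len:
            raise ConfigError(
                f"read shorter than a junction window ({window_len} nt: repeat + "
                f"2 x min_anchor) cannot span a junction"
            )
        rc = reverse_complement(seq)
        hit_f = any(w in seq or w in rc for w in junctions["forward"])
        hit_i = any(w in seq or w in rc for w in junctions["inverted"])
        if hit_f and hit_i:
            n_both += 1
        elif hit_f:
            n_fwd += 1
        elif hit_i:
            n_inv += 1
        else:
            n_neither += 1
    n = n_fwd + n_inv
    if n:
        frac = n_inv / n
        lo, hi = clopper_pearson(n_inv, n)
    else:
        frac, lo, hi = float("nan"), float("nan"), float("nan")
    return JunctionInversionResult(n_fwd, n_inv, n_both, n_neither, frac, lo, hi)
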