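"""Per-genome orientation calling and collection-level inversion-rate surveys.

Given a set of reference invertible loci and a collection of assemblies or
MAGs, each genome is scanned for each locus (anchor homology), the extracted
segment is typed against the locus's two orientation-state sequences, and
per-locus inversion rates are aggregated.  The percent inverted is computed
over unambiguously typed loci only:

    pct_inverted = 100 * n_inverted / (n_forward + n_inverted)

and is reported as missing when no locus was typed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import global_identity
from .errors import AmbiguousPlacementError, ConfigError, DataError
from .locus import (
    GenomeSequence,
    InvertibleLocus,
    extract_locus_sequence,
    locate_locus_by_anchors,
)

logger = logging.getLogger(__name__)

STATES = ("forward", "inverted", "ambiguous", "absent")


@dataclass(frozen=True)
class OrientationCall:
    """Orientation state of one locus in one genome."""

    genome_id: str
    locus_name: str
    state: str
    identity_forward: float
    identity_inverted: float

    def __post_init__(self):
        if self.state not in STATES:
            raise DataError(f"unknown orientation state {self.state!r}")

    @property
    def margin(self) -> float:
        return self.identity_forward - self.identity_inverted


def call_orientation(
    extracted_locus_seq: str,
    locus: InvertibleLocus,
    min_identity: float = 0.90,
    tie_epsilon: float = 0.01,
    genome_id: str = "",
) -> OrientationCall:
    """Type an extracted locus sequence as forward / inverted / ambiguous / absent.

    The sequence (already canonicalized to the reference strand) is globally
    aligned against both orientation states; the better identity wins when it
    clears ``min_identity`` and beats the other state by at least
    ``tie_epsilon``.  Near-ties are flagged ambiguous rather than guessed.
    """
    if not 0.0 < min_identity <= 1.0:
        raise ConfigError("min_identity must lie in (0, 1]")
    if tie_epsilon < 0:
        raise ConfigError("tie_epsilon must be non-negative")
    if not extracted_locus_seq:
        return OrientationCall(genome_id, locus.name, "absent", 0.0, 0.0)
    id_f = global_identity(extracted_locus_seq, locus.forward_state)
    id_i = global_identity(extracted_locus_seq, locus.inverted_state)
    if max(id_f, id_i) < min_identity:
        state = "absent"
    elif abs(id_f - id_i) < tie_epsilon:
        state = "ambiguous"
    else:
        state = "forward" if id_f > id_i else "inverted"
    return OrientationCall(genome_id, locus.name, state, id_f, id_i)


GenomeInput = GenomeSequence | tuple[str, Sequence[GenomeSequence]]


def _normalize_genomes(
    genomes: Iterable[GenomeInput],
) -> list[tuple[str, list[GenomeSequence]]]:
    out = []
    for g in genomes:
        if isinstance(g, GenomeSequence):
            out.append((g.id, [g]))
        else:
            gid, contigs = g
            out.append((gid, list(contigs)))
    return out


def call_genome_locus(
    genome_id: str,
    contigs: Sequence[GenomeSequence],
    locus: InvertibleLocus,
    min_anchor_identity: float = 0.80,
    min_identity: float = 0.90,
    tie_epsilon: float = 0.01,
) -> OrientationCall:
    """Locate and type one locus on one (possibly multi-contig) genome.

    One locus per genome: hits on more than one contig, or several
    non-overlapping placements on one contig, yield an ambiguous call rather
    than a double count.  Genomes where the locus cannot be localized (or a
    contig fails to parse) are called absent.
    """
    hits = []
    for contig in contigs:
        try:
            hit = locate_locus_by_anchors(contig, locus, min_anchor_identity)
        except AmbiguousPlacementError:
            return OrientationCall(genome_id, locus.name, "ambiguous", 0.0, 0.0)
        except DataError as exc:
            logger.warning("genome %s contig %s unreadable: %s", genome_id, contig.id, exc)
            continue
        if hit is not None:
            hits.append((contig, hit))
    if not hits:
        return OrientationCall(genome_id, locus.name, "absent", 0.0, 0.0)
    if len(hits) > 1:
        return OrientationCall(genome_id, locus.name, "ambiguous", 0.0, 0.0)
    contig, hit = hits[0]
    extracted = extract_locus_sequence(contig, hit)
    call = call_orientation(extracted, locus, min_identity, tie_epsilon, genome_id)
    return call


def survey_inversion_rates(
    genomes: Iterable[GenomeInput],
    loci: Sequence[InvertibleLocus],
    min_anchor_identity: float = 0.80,
    min_identity: float = 0.90,
    tie_epsilon: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survey locus orientations across a genome collection.

    Returns ``(summary, calls)``: ``calls`` has one row per genome x locus
    (genome_id, locus, state, identity_forward, identity_inverted, margin);
    ``summary`` has one row per locus with counts and ``pct_inverted``
    (NaN when nothing was typed).  Deterministic for fixed inputs.
    """
    norm = _normalize_genomes(genomes)
    if not norm or not loci:
        raise ConfigError("survey requires at least one genome and one locus")
    rows = []
    for gid, contigs in norm:
        for locus in loci:
            c = call_genome_locus(
                gid, contigs, locus, min_anchor_identity, min_identity, tie_epsilon
            )
            rows.append(
                {
                    "genome_id": gid,
                    "locus": locus.name,
                    "state": c.state,
                    "identity_forward": c.identity_forward,
                    "identity_inverted": c.identity_inverted,
                    "margin": c.margin,
                }
            )
    calls = pd.DataFrame(rows)
    summary_rows = []
    for locus in loci:
        sub = calls[calls["locus"] == locus.name]
        n_fwd = int((sub["state"] == "forward").sum())
        n_inv = int((sub["state"] == "inverted").sum())
        n_amb = int((sub["state"] == "ambiguous").sum())
        denom = n_fwd + n_inv
        summary_rows.append(
            {
                "locus": locus.name,
                "n_genomes_queried": len(norm),
                "n_identified": n_fwd + n_inv + n_amb,
                "n_forward": n_fwd,
                "n_inverted": n_inv,
                "n_ambiguous": n_amb,
                "pct_inverted": (100.0 * n_inv / denom) if denom else float("nan"),
            }
        )
    summary = pd.DataFrame(summary_rows)
    return summary, calls
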