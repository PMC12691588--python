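"""Seeded generators for every input the pipeline consumes, with planted truth.

Each generator draws all randomness from one explicit seed
(``numpy.random.default_rng``) and returns the planted truth alongside the
data, so every downstream stage has a round-trip test that reads only
generated artifacts.  Defaults mirror the biological system the package
models: a 27-nt inverted-repeat pair around a 174-nt invertible spacer,
three such loci per genome, and a 38-strain defined community.

Background base composition defaults to GC 0.45 (Bacteroidetes-like); the
generators make no claim of realism beyond exercising the algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import global_identity
from .community import StrainReferenceDB, group_row_name
from .errors import ConfigError
from .frequency import AmpliconReferenceSet, ASVRecord
from .locus import (
    GenomeSequence,
    InvertedRepeatPair,
    InvertibleLocus,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))
_COMP_OF = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Apply ``n_sub`` substitutions at distinct positions."""
    if n_sub == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n_sub, len(chars)), replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def _non_pairing_base(rng: np.random.Generator, partner: str) -> str:
    """A base that does not complement ``partner`` (blocks IR extension)."""
    forbidden = _COMP_OF[partner]
    choices = [b for b in "ACGT" if b != forbidden]
    return choices[rng.integers(3)]


@dataclass
class SyntheticGenome:
    """A genome with planted invertible loci plus the planted truth."""

    genome: GenomeSequence
    loci: list[InvertibleLocus]
    truth: dict


def _build_locus(
    rng: np.random.Generator,
    name: str,
    ir_len: int,
    spacer_len: int,
    anchor_len: int,
    gc: float,
    ir_seq: str | None = None,
    existing_anchors: Sequence[str] = (),
    max_tries: int = 50,
) -> InvertibleLocus:
    """One reference locus; anchors rejected until non-homologous (< 0.6 identity)."""
    ir = ir_seq if ir_seq is not None else _random_dna(rng, ir_len)
    if len(ir) != ir_len:
        raise ConfigError("ir_seq length must equal ir_len")
    for _ in range(max_tries):
        left = list(_random_dna(rng, anchor_len, gc))
        right = list(_random_dna(rng, anchor_len, gc))
        spacer = list(_random_dna(rng, spacer_len, gc))
        # block one-base extension of the planted pair so its geometry is
        # exactly maximal: inward (spacer ends) and outward (anchor boundary)
        if spacer_len >= 2:
            spacer[0] = _non_pairing_base(rng, spacer[-1])
        left[-1] = _non_pairing_base(rng, right[0])
        left_s, right_s, spacer_s = "".join(left), "".join(right), "".join(spacer)
        ok = all(
            global_identity(left_s, prev) < 0.6 and global_identity(right_s, prev) < 0.6
            for prev in existing_anchors
        )
        if ok:
            segment = left_s + ir + spacer_s + reverse_complement(ir) + right_s
            pair = InvertedRepeatPair(
                left_start=anchor_len,
                left_end=anchor_len + ir_len,
                right_start=anchor_len + ir_len + spacer_len,
                right_end=anchor_len + 2 * ir_len + spacer_len,
                repeat_len=ir_len,
            )
            return InvertibleLocus.from_segment(name, "synthetic_ref", segment, pair)
    raise ConfigError(f"could not place non-homologous anchors for locus {name!r}")


def make_reference_loci(
    seed: int,
    n_loci: int = 3,
    ir_len: int = 27,
    spacer_len: int = 174,
    anchor_len: int = 300,
    gc: float = 0.45,
    ir_seqs: Sequence[str] | None = None,
) -> list[InvertibleLocus]:
    """Mutually non-homologous reference loci named locus_1..locus_n."""
    rng = np.random.default_rng(seed)
    loci: list[InvertibleLocus] = []
    anchors: list[str] = []
    for i in range(n_loci):
        ir_seq = ir_seqs[i] if ir_seqs else None
        locus = _build_locus(
            rng, f"locus_{i + 1}", ir_len, spacer_len, anchor_len, gc,
            ir_seq=ir_seq, existing_anchors=anchors,
        )
        loci.append(locus)
        anchors.extend([locus.left_anchor, locus.right_anchor])
    return loci


def make_invertible_genome(
    seed: int,
    ir_len: int = 27,
    spacer_len: int = 174,
    n_loci: int = 3,
    orientations: Sequence[str] | None = None,
    genome_len: int | None = None,
    anchor_len: int = 300,
    gc: float = 0.45,
    ir_seqs: Sequence[str] | None = None,
) -> SyntheticGenome:
    """A single genome carrying ``n_loci`` planted IR-flanked invertible loci.

    ``orientations`` gives the planted state per locus ('forward' or
    'inverted'; default all forward).  ``genome_len`` (optional) pads the
    genome with random background to at least that length; loci are placed
    with background gaps and never overlap.
    """
    if orientations is None:
        orientations = ["forward"] * n_loci
    if len(orientations) != n_loci:
        raise ConfigError("need one orientation per locus")
    rng = np.random.default_rng(seed)
    loci = make_reference_loci(
        int(rng.integers(2**31)), n_loci, ir_len, spacer_len, anchor_len, gc, ir_seqs
    )
    gap = 150
    parts = [_random_dna(rng, gap, gc)]
    coords = []
    pos = gap
    for locus, orient in zip(loci, orientations):
        if orient not in ("forward", "inverted"):
            raise ConfigError(f"unknown orientation {orient!r}")
        seg = locus.forward_state if orient == "forward" else locus.inverted_state
        parts.append(seg)
        coords.append({"locus": locus.name, "start": pos, "end": pos + len(seg),
                       "orientation": orient})
        pos += len(seg)
        parts.append(_random_dna(rng, gap, gc))
        pos += gap
    seq = "".join(parts)
    if genome_len is not None:
        if genome_len < len(seq):
            raise ConfigError(
                f"genome_len {genome_len} too small for {n_loci} loci "
                f"({len(seq)} nt required)"
            )
        seq += _random_dna(rng, genome_len - len(seq), gc)
    genome = GenomeSequence("synthetic_genome", seq)
    truth = {
        "scenario": "genome",
        "seed": seed,
        "ir_len": ir_len,
        "spacer_len": spacer_len,
        "gc": gc,
        "loci": coords,
    }
    return SyntheticGenome(genome, loci, truth)


@dataclass
class SyntheticMAGCollection:
    """A genome collection with per-genome planted locus states."""

    genomes: list[tuple[str, list[GenomeSequence]]]
    loci: list[InvertibleLocus]
    truth: pd.DataFrame  # genome_id, locus, planted_state


def simulate_mag_collection(
    seed: int,
    n_genomes: int,
    per_locus_inversion_prob: float | Mapping[str, float] = 0.1,
    dropout_prob: float = 0.0,
    fragmentation_prob: float = 0.0,
    loci: Sequence[InvertibleLocus] | None = None,
    n_loci: int = 1,
    flank_len: int = 150,
    gc: float = 0.45,
) -> SyntheticMAGCollection:
    """A collection of genomes/MAGs with independently drawn locus states.

    Per genome and locus: the locus is dropped with ``dropout_prob``
    (planted_state 'absent'), split across two contigs through the spacer
    with ``fragmentation_prob`` ('fragmented'), otherwise planted intact and
    inverted with its per-locus probability.  The truth table records every
    draw.  Reference locus sequences are shared across genomes; flanking
    background is drawn fresh per genome.
    """
    rng = np.random.default_rng(seed)
    if loci is None:
        loci = make_reference_loci(int(rng.integers(2**31)), n_loci=n_loci, gc=gc)
    probs = (
        {lc.name: float(per_locus_inversion_prob) for lc in loci}
        if isinstance(per_locus_inversion_prob, (int, float))
        else dict(per_locus_inversion_prob)
    )
    genomes = []
    rows = []
    for g in range(n_genomes):
        gid = f"genome_{g + 1:05d}"
        main_parts = [_random_dna(rng, flank_len, gc)]
        contigs: list[GenomeSequence] = []
        n_extra = 0
        for locus in loci:
            u = rng.random()
            if u < dropout_prob:
                state = "absent"
            elif u < dropout_prob + fragmentation_prob:
                state = "fragmented"
            else:
                state = "inverted" if rng.random() < probs[locus.name] else "forward"
            seg = locus.inverted_state if state == "inverted" else locus.forward_state
            if state == "absent":
                pass
            elif state == "fragmented":
                cut = locus.ir.left_end + locus.spacer_len // 2
                n_extra += 1
                contigs.append(
                    GenomeSequence(f"{gid}_frag{n_extra}a",
                                   _random_dna(rng, flank_len, gc) + seg[:cut])
                )
                contigs.append(
                    GenomeSequence(f"{gid}_frag{n_extra}b",
                                   seg[cut:] + _random_dna(rng, flank_len, gc))
                )
            else:
                main_parts.append(seg)
                main_parts.append(_random_dna(rng, flank_len, gc))
            rows.append({"genome_id": gid, "locus": locus.name, "planted_state": state})
        contigs.insert(0, GenomeSequence(f"{gid}_c1", "".join(main_parts)))
        genomes.append((gid, contigs))
    truth = pd.DataFrame(rows)
    return SyntheticMAGCollection(genomes, list(loci), truth)


@dataclass
class SyntheticAmpliconData:
    asvs: list[ASVRecord]
    refs: AmpliconReferenceSet
    truth: dict


def simulate_amplicon_reads(
    seed: int,
    refs: AmpliconReferenceSet,
    fraction_inverted: Mapping[str, float] | Mapping[str, Mapping[str, float]],
    n_reads: int = 10_000,
    substitution_error: float = 0.001,
    strain_mix: Mapping[str, float] | None = None,
) -> SyntheticAmpliconData:
    """Mixed-population amplicon reads collapsed to unique sequences.

    ``fraction_inverted`` is either strain -> fraction (one sample, 'S1') or
    sample -> (strain -> fraction).  Reads are drawn multinomially over
    (strain, orientation) classes — strains mixed per ``strain_mix``
    (default equal) — then per-base substitution noise is applied and
    identical sequences are collapsed to ASV records with per-sample counts.
    The truth records the realized (post-multinomial) class counts.
    """
    rng = np.random.default_rng(seed)
    first = next(iter(fraction_inverted.values()))
    per_sample: Mapping[str, Mapping[str, float]]
    if isinstance(first, Mapping):
        per_sample = fraction_inverted  # type: ignore[assignment]
    else:
        per_sample = {"S1": fraction_inverted}  # type: ignore[dict-item]
    strains = refs.strains
    if strain_mix is None:
        strain_mix = {s: 1.0 / len(strains) for s in strains}

    seq_counts: dict[str, dict[str, int]] = {}
    realized: dict[str, dict[str, dict[str, int]]] = {}
    for sample, fracs in per_sample.items():
        classes = []
        probs = []
        for strain in strains:
            f = float(fracs.get(strain, 0.0))
            if not 0.0 <= f <= 1.0:
                raise ConfigError("fraction_inverted must lie in [0, 1]")
            classes.append((strain, "forward"))
            probs.append(strain_mix[strain] * (1 - f))
            classes.append((strain, "inverted"))
            probs.append(strain_mix[strain] * f)
        probs = np.asarray(probs) / np.sum(probs)
        counts = rng.multinomial(n_reads, probs)
        realized[sample] = {
            strain: {
                "forward": int(counts[2 * i]),
                "inverted": int(counts[2 * i + 1]),
            }
            for i, strain in enumerate(strains)
        }
        for cls, count in zip(classes, counts):
            template = refs.references[cls]
            n_errors = rng.binomial(len(template), substitution_error, size=count)
            for n_err in n_errors:
                read = _mutate(rng, template, int(n_err)) if n_err else template
                seq_counts.setdefault(read, {})[sample] = (
                    seq_counts.get(read, {}).get(sample, 0) + 1
                )
    ordered = sorted(seq_counts, key=lambda s: (-sum(seq_counts[s].values()), s))
    asvs = [
        ASVRecord(f"asv_{i + 1:05d}", seq, seq_counts[seq])
        for i, seq in enumerate(ordered)
    ]
    truth = {
        "scenario": "amplicon",
        "seed": seed,
        "n_reads": n_reads,
        "substitution_error": substitution_error,
        "planted_fraction_inverted": {s: dict(f) for s, f in per_sample.items()},
        "realized_counts": realized,
    }
    return SyntheticAmpliconData(asvs, refs, truth)


@dataclass
class SyntheticJunctionReads:
    reads: list[str]
    truth: dict


def simulate_junction_reads(
    seed: int,
    locus: InvertibleLocus,
    fraction_inverted: float,
    n_reads: int = 5_000,
    read_len: int = 150,
    substitution_error: float = 0.0,
) -> SyntheticJunctionReads:
    """Error-prone reads guaranteed to span one repeat junction.

    Each read's orientation is Bernoulli(``fraction_inverted``); a repeat
    (left or right) and an offset are drawn so the read covers the full
    repeat with at least ``window_margin`` = 20 bases of flank/spacer on each
    side, and half the reads are reverse-complemented.  The realized
    orientation counts are the truth.
    """
    if not 0.0 <= fraction_inverted <= 1.0:
        raise ConfigError("fraction_inverted must lie in [0, 1]")
    margin = 20
    rng = np.random.default_rng(seed)
    ir = locus.ir
    if read_len < ir.repeat_len + 2 * margin:
        raise ConfigError(
            "read_len must cover a full repeat plus 20 bases on each side"
        )
    reads = []
    n_inverted = int(rng.binomial(n_reads, fraction_inverted))
    states = ["inverted"] * n_inverted + ["forward"] * (n_reads - n_inverted)
    for state in states:
        seq = locus.inverted_state if state == "inverted" else locus.forward_state
        rep_start, rep_end = (
            (ir.left_start, ir.left_end)
            if rng.random() < 0.5
            else (ir.right_start, ir.right_end)
        )
        lo = max(0, rep_end + margin - read_len)
        hi = min(len(seq) - read_len, rep_start - margin)
        if hi < lo:
            raise ConfigError("locus too short for the requested read length")
        start = int(rng.integers(lo, hi + 1))
        read = seq[start : start + read_len]
        if substitution_error:
            read = _mutate(rng, read, int(rng.binomial(read_len, substitution_error)))
        if rng.random() < 0.5:
            read = reverse_complement(read)
        reads.append(read)
    truth = {
        "scenario": "junction",
        "seed": seed,
        "n_reads": n_reads,
        "planted_fraction_inverted": fraction_inverted,
        "realized_n_inverted": n_inverted,
        "realized_n_forward": n_reads - n_inverted,
    }
    return SyntheticJunctionReads(reads, truth)


@dataclass
class SyntheticCommunity:
    db: StrainReferenceDB
    asvs: list[ASVRecord]
    abundance: pd.DataFrame  # strain x sample, wpFUKM-like unit
    ko_copies: pd.DataFrame  # strain x KO
    pathways: dict[str, list[str]]
    groups: dict[str, str]  # sample -> 'A' | 'B'
    truth: dict


def simulate_community_profiles(
    seed: int,
    n_strains: int = 38,
    n_samples_per_group: int = 4,
    n_kos: int = 300,
    n_planted: int = 10,
    fold_change: float = 4.0,
    noise_sd_log2: float = 0.2,
    identical_16s_pairs: int = 1,
    n_pathways: int = 20,
    amplicon_depth: int = 50_000,
    region_len: int = 250,
) -> SyntheticCommunity:
    """A defined community with planted group effects on KO abundances.

    Strain abundances are lognormal (per-sample Gaussian noise with
    ``noise_sd_log2`` on the log2 scale).  Each planted KO lives on a
    dedicated carrier strain (single copy, no other KOs on that strain)
    whose abundance is multiplied by ``fold_change`` in group B, so the
    community-KO fold change is exact by construction.  Null KO copy
    numbers are drawn over the remaining strains.  The last
    ``identical_16s_pairs`` pairs of strains share identical 16S regions to
    exercise ambiguity groups.  Pathways are contiguous KO chunks, so the
    planted KOs concentrate in the first pathway(s).
    """
    if n_planted > n_strains // 2:
        raise ConfigError("too many planted KOs for the community size")
    rng = np.random.default_rng(seed)
    strains = [f"S{i + 1:02d}" for i in range(n_strains)]
    samples = [f"A{i + 1}" for i in range(n_samples_per_group)] + [
        f"B{i + 1}" for i in range(n_samples_per_group)
    ]
    groups = {s: s[0] for s in samples}

    # 16S regions; trailing pairs share sequences
    seqs = {}
    for i, sid in enumerate(strains):
        seqs[sid] = _random_dna(rng, region_len)
    for p in range(identical_16s_pairs):
        a, b = strains[-2 * p - 2], strains[-2 * p - 1]
        seqs[b] = seqs[a]
    db = StrainReferenceDB(seqs)

    carriers = strains[:n_planted]
    planted_kos = [f"K{90000 + i:05d}" for i in range(n_planted)]
    null_kos = [f"K{10000 + i:05d}" for i in range(n_kos - n_planted)]
    kos = planted_kos + null_kos

    copies = pd.DataFrame(0, index=strains, columns=kos, dtype=int)
    for ko, carrier in zip(planted_kos, carriers):
        copies.loc[carrier, ko] = 1
    non_carriers = strains[n_planted:]
    for ko in null_kos:
        # each null KO present in a random subset of non-carrier strains
        n_members = int(rng.integers(1, max(2, len(non_carriers) // 3)))
        members = rng.choice(non_carriers, size=n_members, replace=False)
        for m in members:
            copies.loc[m, ko] = int(rng.integers(1, 4))

    base_log2 = rng.uniform(2.0, 8.0, size=n_strains)
    abund = pd.DataFrame(index=strains, columns=samples, dtype=float)
    shift = np.log2(fold_change)
    for j, sample in enumerate(samples):
        noise = rng.normal(0.0, noise_sd_log2, size=n_strains)
        vals = base_log2 + noise
        if groups[sample] == "B":
            vals = vals + np.where(np.isin(strains, carriers), shift, 0.0)
        abund[sample] = 2.0**vals
    abund.attrs["unit"] = "wpFUKM"

    # amplicon counts proportional to abundance (single 16S copy per strain)
    uniq_seqs = sorted(set(seqs.values()), key=lambda s: min(k for k, v in seqs.items() if v == s))
    asvs = []
    for i, seq in enumerate(uniq_seqs):
        members = [sid for sid in strains if seqs[sid] == seq]
        counts = {}
        for sample in samples:
            frac = abund.loc[members, sample].sum() / abund[sample].sum()
            counts[sample] = int(rng.binomial(amplicon_depth, frac))
        asvs.append(ASVRecord(f"asv_{i + 1:03d}", seq, counts))

    chunk = max(1, n_kos // n_pathways)
    pathways = {
        f"path_{i + 1:02d}": kos[i * chunk : (i + 1) * chunk]
        for i in range(n_pathways)
        if kos[i * chunk : (i + 1) * chunk]
    }
    truth = {
        "scenario": "community",
        "seed": seed,
        "planted_kos": planted_kos,
        "carrier_strains": carriers,
        "fold_change": fold_change,
        "noise_sd_log2": noise_sd_log2,
        "groups": groups,
        "identical_16s_groups": [
            group_row_name([a, b])
            for p in range(identical_16s_pairs)
            for a, b in [(strains[-2 * p - 2], strains[-2 * p - 1])]
        ],
    }
    return SyntheticCommunity(db, asvs, abund, copies, pathways, groups, truth)
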