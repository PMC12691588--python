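# Methods

## Locus model

An invertible locus is modeled as `left_anchor + IR + spacer + IR' +
right_anchor`, where `IR'` is the reverse complement of `IR` up to a
configurable substitution budget (default 0, since the motivating repeats
are exact 27-mers). Coordinates are 0-based half-open everywhere and are
stated as such in every serialized table. The *inverted state*
reverse-complements the full IR-to-IR segment in place; because `IR'` =
revcomp(`IR`), the repeats are invariant and only the spacer flips, and the
operation is an involution. Two lengths are exposed deliberately:
`spacer_len` (between the repeats) and `segment_len` (IR-to-IR inclusive),
since "inversion length" is ambiguous between the two conventions.

### Inverted-repeat pair detection

A pair (left repeat at `[i, i+L)`, right end `e = j+L`) lies on the
anti-diagonal `s = i + e`; base `p` of the left repeat pairs with base
`s-1-p` of the right, and both one-base extensions of a pair — *inward*
(into the spacer, spacer−2) and *outward* (into the flanks, spacer
unchanged) — stay on the same anti-diagonal. The detector scans each
anti-diagonal once with a mismatch prefix sum; for a fixed `(s, i)` the
mismatch count is monotone in `L`, so only the largest valid `L` can be
maximal and candidates plus their extensions are checked in O(1). **A pair
is reported iff neither extension satisfies all constraints** (mismatch
budget, length and spacer ranges, sequence bounds); this suppresses the
combinatorial cloud of shrinkable sub-pairs while keeping every maximal
pair. `N` never matches anything. The test suite checks equality against an
independent brute-force enumeration of all `(i, j, L)` triples on hundreds
of seeded sequences up to 300 nt.

### Alignment and localization

All pairwise alignment is edit-distance based (edlib), with one identity
convention package-wide: `identity = matches / alignment columns`, gap
columns counted as mismatches (equivalently `(columns − editDistance) /
columns`). Anchors are located in infix mode on both strands; a placement
qualifies when both anchors reach `min_anchor_identity` (default 0.80),
are collinear, and the implied interval is at most 3× the reference locus
length. Several non-overlapping qualifying placements raise an
ambiguous-placement error, which the survey layer converts into an
`ambiguous` call rather than double-counting a genome. Anchor-based
localization with these defaults is this package's reconstruction of an
unspecified homology search; thresholds are configurable.

## Orientation survey

The extracted locus sequence (canonicalized to the reference strand) is
globally aligned to both state sequences. The call is the better state when
its identity is at least `min_identity` (default 0.90) and it beats the
other by at least `tie_epsilon` (default 0.01); near-ties are `ambiguous`,
sub-threshold maxima `absent`. Defaults were chosen so exact-state
sequences are always called and near-ties are flagged, and are
configurable. `pct_inverted` uses only unambiguously typed loci in the
denominator (ambiguous counts are reported alongside), a choice documented
in the output metadata since published rates rarely state their treatment
of ambiguity. Calls are strand-invariant, and fragmentation through the
locus yields `absent`, never a wrong orientation — both are property
tests.

## Mixed-population frequency estimators

**Amplicon path.** ASVs are classified by best global-alignment identity
against the labeled (strain × orientation) references with a 97% floor;
the top-two labels within `tie_epsilon` (default 0.01) make an ASV
`ambiguous`. "Best-scoring" is deliberately defined as best *identity*
(not raw alignment score) so the floor and the ranking use one scale.
Ambiguous and unclassified reads are excluded from denominators but
reported per sample, so classified + ambiguous + unclassified always equals
the input total. Intervals are exact Clopper–Pearson, appropriate for the
small per-sample counts the assay can produce.

**Junction path.** Each orientation state contributes two diagnostic
windows, one per repeat, spanning the *full* repeat plus `min_anchor`
(default 20) bases on each side. Spanning the whole repeat is essential,
not cosmetic: since the right repeat is the reverse complement of the left,
a window touching only one repeat edge is — read on the opposite strand —
identical to the other state's window at the other repeat, and
strand-agnostic matching could never assign a read. With full-repeat
windows, one side sits in unique flank and the other in the spacer, making
each window state-specific. Reads (searched on both strands) are counted
when they contain exactly one state's window as an exact substring;
matching both states or neither discards the read but keeps it in the
accounting. Exact matching is conservative and fast at the substitution
rates modeled; a spacer shorter than `min_anchor` is rejected as
non-diagnostic. Windows shared verbatim by both states
(orientation-symmetric spacers) are removed from both.

## Community quantification

ASV-to-strain matching uses global edit distance with a one-mismatch
default tolerance; indels count as mismatches (the looser reading of a
"one mismatch" rule — the stricter substitution-only reading is obtained
by construction when references are length-matched). Strains matched by
the same ASV form first-class ambiguity-group rows named by sorted member
ids joined with `+`; they are never silently dropped. Community KO
abundance is exact linear propagation of strain abundance (wpFUKM or any
linear unit) through integer copy numbers — no normalization — and is
linear and additive over strain partitions by construction (property
tests). Welch's *t* with Satterthwaite degrees of freedom is applied to
`log2(x + pseudocount)`; the pseudocount defaults to half the smallest
nonzero value in the table and is only added when zeros are present, and
is recorded in the output metadata. Zero-variance features with equal
means get `t = 0, p = 1`. Z-score inputs (e.g. metabolite panels) skip the
transform via `log2_transform=False`. Over-representation uses the
upper-tail hypergeometric probability with the background defaulting to
all KOs present in at least one strain; BH adjustment runs across exactly
the pathways tested (those with at least one background member), with 0.1
as the default reporting threshold.

## Synthetic data

Generators draw every random quantity from one explicit
`numpy.random.default_rng(seed)`; regeneration with the same seed is
byte-identical, and each generator returns a machine-readable truth object
recording every draw. Background composition is GC 0.45
(Bacteroidetes-like). Defaults mirror the modeled system: 27-nt repeats,
174-nt spacer, three loci per genome, 300-nt anchors, a 38-strain
community with 4 vs 4 samples, lognormal abundances with sd 0.2 on the
log2 scale, ten planted 4-fold KO shifts, and substitution-only read error
(denoised amplicons make indel noise a property of the upstream denoiser,
which is out of scope here).

Two generator details matter for interpretation. First, the genome builder
pins the bases immediately inside and outside the planted repeats so the
planted pair is *exactly* maximal — otherwise a 1-in-4 boundary coincidence
would make the detector (correctly) report a longer repeat than planted
and the truth would be ill-defined. Second, each planted differential KO
lives on a dedicated carrier strain whose abundance is shifted by the
fold-change in one group, so the planted community-KO fold change is exact
by construction and the null KOs (on non-carrier strains) stay null.

What the generators do **not** emulate: real MAG contamination and
chimerism, read-quality profiles, chimeric amplicons, taxonomic
mis-binning, compositional coupling between strains, or phage population
dynamics. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated error model, not robustness to every artifact
of real sequencing data.

## Problem sizes and determinism

The acceptance script simulates at the scales the estimators are meant
for: a 6,001-genome collection surveyed at locus-wise inversion rates of
9.16% / 8.74% / 37.4%, amplicon samples of 20,000 reads at inverted
fractions of 4.918% and 5.385% with 0.1% substitution error, 5,000
junction-spanning reads at 19.5%, and the default community scenario. The
test suite uses smaller collections (40–1,000 genomes, 400–10,000 reads)
chosen so planted-draw confidence intervals are tight enough to be
informative. All stochastic assertions compare estimates against the
*realized* draw (recorded in the truth), not the nominal parameter, so
they hold exactly under the generators' error model. Hypothesis-based
property tests run derandomized.

## Known limitations

* Anchor localization assumes the flanks of a locus are unique in the
  genome; paralogous loci surface as ambiguous calls rather than being
  resolved.
* The junction estimator requires exact window matches; at substitution
  rates well above ~1% it discards an increasing share of reads (biasing
  precision, not the point estimate).
* Orientation calling is pairwise against exactly two states; loci with
  more than one invertible segment need one locus object per segment.
* The Welch test treats samples as independent; repeated measures or
  paired designs are out of scope.
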