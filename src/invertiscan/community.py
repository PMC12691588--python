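"""Defined-community quantification and statistics.

Covers the analytic steps downstream of strain-resolved sequencing of a
defined (synthetic) gut community:

* matching 16S ASVs to community members by global alignment with a
  one-mismatch tolerance (indistinguishable strains form ambiguity groups);
* relative-abundance tables from ASV counts;
* community KEGG-ortholog (KO) abundance as the strain-abundance-weighted
  sum of per-genome KO copy numbers (abundances in wpFUKM, the
  strain-resolved quantification unit: weighted percentile fragments per
  thousand unique k-mers per million reads mapped);
* Welch's t-test on log2-transformed abundances for differential features;
* hypergeometric over-representation analysis with Benjamini-Hochberg
  control for pathway enrichment;
* a detection-prevalence helper.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import edit_distance
from .errors import ConfigError, DataError
from .frequency import ASVRecord
from .locus import validate_dna

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrainReferenceDB:
    """Per-strain 16S target-region sequences (plus optional KO copy table)."""

    sequences: Mapping[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise ConfigError("empty strain reference database")
        object.__setattr__(
            self,
            "sequences",
            {sid: validate_dna(seq, context=sid) for sid, seq in self.sequences.items()},
        )


class StrainMatch(NamedTuple):
    asv_id: str
    matched_strains: frozenset[str]
    status: str  # 'unique' | 'ambiguous_group' | 'unassigned'


def match_asv_to_strains(
    asv: ASVRecord, db: StrainReferenceDB, max_mismatches: int = 1
) -> StrainMatch:
    """Match an ASV to community members, tolerating ``max_mismatches`` edits.

    Distance is global-alignment edit distance (substitutions and indels each
    cost 1).  All strains within the tolerance are kept: more than one match
    makes an ambiguity group; none makes the ASV unassigned.
    """
    matched = frozenset(
        sid
        for sid, ref in db.sequences.items()
        if edit_distance(asv.seq, ref) <= max_mismatches
    )
    if len(matched) == 1:
        status = "unique"
    elif matched:
        status = "ambiguous_group"
    else:
        status = "unassigned"
    return StrainMatch(asv.asv_id, matched, status)


def group_row_name(strains: Iterable[str]) -> str:
    return "+".join(sorted(strains))


def relative_abundance_table(
    asvs: Sequence[ASVRecord], matches: Sequence[StrainMatch]
) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate ASV counts into a relative-abundance table.

    Rows are strain ids (unique matches) or ambiguity-group ids (member ids
    sorted, joined with '+'); columns are samples; values are fractions of
    the sample's total reads.  Returns ``(table, unmapped)`` where
    ``unmapped`` holds the per-sample unassigned fraction, so each column of
    the table sums to ``1 - unmapped``.  Zero-read samples yield NaN columns.
    """
    if len(asvs) != len(matches):
        raise DataError("need exactly one match record per ASV")
    by_id = {m.asv_id: m for m in matches}
    samples = sorted({s for a in asvs for s in a.counts})
    counts: dict[str, dict[str, float]] = {}
    unmapped = {s: 0 for s in samples}
    totals = {s: 0 for s in samples}
    for asv in asvs:
        m = by_id.get(asv.asv_id)
        if m is None:
            raise DataError(f"no match record for ASV {asv.asv_id!r}")
        row = group_row_name(m.matched_strains) if m.matched_strains else None
        for sample, c in asv.counts.items():
            totals[sample] += c
            if row is None:
                unmapped[sample] += c
            else:
                counts.setdefault(row, {s: 0 for s in samples})[sample] += c
    for sample, total in totals.items():
        if total == 0:
            logger.warning("sample %s has zero reads; reporting missing values", sample)
    table = pd.DataFrame.from_dict(counts, orient="index").reindex(columns=samples)
    table = table.fillna(0.0).sort_index()
    denom = pd.Series(totals, dtype=float).replace(0, np.nan)
    table = table.div(denom, axis=1)
    unmapped_frac = pd.Series(unmapped, dtype=float) / denom
    table.attrs["unit"] = "relative_fraction"
    return table, unmapped_frac


def community_ko_abundance(
    abundance: pd.DataFrame, ko_copies: pd.DataFrame
) -> pd.DataFrame:
    """Community KO abundances: sum over strains of abundance x copy number.

    ``abundance`` is strain x sample (wpFUKM or any linear unit);
    ``ko_copies`` is strain x KO with non-negative integer copy numbers.
    Exact linear propagation, no normalization:

        value(KO, sample) = sum_strains abundance(strain, sample) * copies(strain, KO)

    Strains missing from either table are reported and skipped; fully
    disjoint strain sets are a configuration error.
    """
    shared = abundance.index.intersection(ko_copies.index)
    if shared.empty:
        raise ConfigError("abundance and KO tables share no strains")
    skipped = abundance.index.symmetric_difference(ko_copies.index)
    if len(skipped):
        logger.warning("strains without both tables skipped: %s", ", ".join(skipped))
    if (ko_copies < 0).any().any():
        raise DataError("KO copy numbers must be non-negative")
    result = ko_copies.loc[shared].T @ abundance.loc[shared]
    result.index.name = "ko_id"
    return result


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Satterthwaite df and two-sided p for two samples."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        # zero variance in both groups: equal means are a non-effect
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return math.inf * math.copysign(1, a.mean() - b.mean()), float(na + nb - 2), 0.0
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def differential_features(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    log2_transform: bool = True,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Welch's t-test per feature between two sample groups.

    ``table`` is feature x sample; ``groups`` maps sample -> group label
    (exactly two labels, each with >= 2 samples).  In abundance mode values
    are log2(x + pseudocount) first (pseudocount defaults to half the
    smallest nonzero value in the table, only added when zeros are present);
    pass ``log2_transform=False`` for already-normalized input such as
    metabolite Z-scores.  Features with zero variance in both groups and
    equal means get t = 0, p = 1.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ConfigError(f"need exactly two groups, got {labels}")
    ga = [s for s in table.columns if groups.get(s) == labels[0]]
    gb = [s for s in table.columns if groups.get(s) == labels[1]]
    for name, cols in zip(labels, (ga, gb)):
        if len(cols) < 2:
            raise ConfigError(f"group {name!r} has fewer than 2 samples")
    values = table[ga + gb].astype(float)
    if log2_transform:
        if (values < 0).any().any():
            raise DataError("negative abundances cannot be log2-transformed")
        if pseudocount is None:
            nonzero = values.values[values.values > 0]
            has_zero = (values.values == 0).any()
            pseudocount = (nonzero.min() / 2.0) if (has_zero and nonzero.size) else 0.0
        values = np.log2(values + pseudocount)
    rows = []
    for feature, row in values.iterrows():
        a = row[ga].to_numpy(dtype=float)
        b = row[gb].to_numpy(dtype=float)
        t, df, p = _welch(a, b)
        rows.append(
            {
                "feature_id": feature,
                f"mean_log2_{labels[0]}": a.mean(),
                f"mean_log2_{labels[1]}": b.mean(),
                "t_statistic": t,
                "df": df,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    out.attrs["alpha"] = alpha
    out.attrs["pseudocount"] = pseudocount if log2_transform else None
    return out


def ora_enrichment(
    significant: Iterable[str],
    background: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis with BH correction.

    For each pathway with at least one background member, the upper-tail
    hypergeometric probability P[X >= k] is computed with N background
    features, K of them in the pathway and n significant draws.  q-values
    are Benjamini-Hochberg adjusted across exactly the tested pathways;
    ``enriched`` flags q < ``fdr`` (default reporting threshold 0.1).
    """
    sig = set(significant)
    bg = set(background)
    if not sig <= bg:
        raise DataError(
            f"significant set contains features outside the background: "
            f"{sorted(sig - bg)[:5]}"
        )
    N, n = len(bg), len(sig)
    rows = []
    for pathway, members in sorted(pathways.items()):
        members_bg = set(members) & bg
        K = len(members_bg)
        if K == 0:
            continue
        k = len(members_bg & sig)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway_id": pathway, "k": k, "n": n, "K": K, "N": N, "p_value": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["enriched"] = out["q_value"] < fdr
    return out.set_index("pathway_id")


def detection_prevalence(n_detected: int, n_total: int) -> tuple[float, int]:
    """Prevalence as (raw percent, nearest-integer percent)."""
    if n_total <= 0:
        raise ConfigError("n_total must be positive")
    if not 0 <= n_detected <= n_total:
        raise ConfigError("require 0 <= n_detected <= n_total")
    pct = 100.0 * n_detected / n_total
    return pct, int(math.floor(pct + 0.5))
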