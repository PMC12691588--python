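"""End-to-end synthetic pipeline: simulate -> survey -> frequency -> KO stats.

Used by the ``invertiscan pipeline`` subcommand and as a smoke-testable
library entry point.  All outputs are plain text (TSV/JSON/FASTA) and are
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .community import community_ko_abundance, differential_features, ora_enrichment
from .frequency import inversion_rate_from_asv_table, inversion_rate_from_junction_reads
from .io import RunConfig, write_json, write_loci, write_table
from .simulate import (
    make_reference_loci,
    simulate_amplicon_reads,
    simulate_community_profiles,
    simulate_junction_reads,
    simulate_mag_collection,
)
from .survey import survey_inversion_rates
from .frequency import AmpliconReferenceSet

logger = logging.getLogger(__name__)


def _stage(name: str):
    logger.info("stage=%s wall=%s", name, time.strftime("%Y-%m-%dT%H:%M:%S"))


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:12]


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    n_genomes: int = 200,
    inversion_prob: float = 0.374,
    amplicon_fraction: float = 0.05,
    junction_fraction: float = 0.195,
    n_amplicon_reads: int = 5_000,
    n_junction_reads: int = 2_000,
) -> dict[str, Path]:
    """Run the full synthetic pipeline and write all result tables.

    Returns a mapping from stage name to the main output file of the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = RunConfig(
        command="pipeline",
        seed=seed,
        params={
            "n_genomes": n_genomes,
            "inversion_prob": inversion_prob,
            "amplicon_fraction": amplicon_fraction,
            "junction_fraction": junction_fraction,
            "n_amplicon_reads": n_amplicon_reads,
            "n_junction_reads": n_junction_reads,
        },
    )
    config.write(outdir)
    outputs: dict[str, Path] = {}

    _stage("simulate-mags")
    mags = simulate_mag_collection(
        seed, n_genomes=n_genomes, per_locus_inversion_prob=inversion_prob, n_loci=1
    )
    write_loci(mags.loci, outdir / "loci.json")

    _stage("survey")
    summary, calls = survey_inversion_rates(mags.genomes, mags.loci)
    write_table(calls, outdir / "calls.tsv", {"pct_denominator": "forward+inverted"})
    write_table(summary, outdir / "summary.tsv",
                {"pct_denominator": "forward+inverted", "input_hash": _hash_df(calls)})
    outputs["survey"] = outdir / "summary.tsv"

    _stage("amplicon-inversion")
    strain_loci = {
        "strainA": mags.loci[0],
        "strainB": make_reference_loci(seed + 1, n_loci=1)[0],
    }
    refs = AmpliconReferenceSet.from_loci(strain_loci)
    amp = simulate_amplicon_reads(
        seed + 2, refs,
        {"strainA": amplicon_fraction, "strainB": amplicon_fraction},
        n_reads=n_amplicon_reads,
    )
    amp_res = inversion_rate_from_asv_table(amp.asvs, refs)
    write_table(amp_res.frequencies, outdir / "amplicon_inversion_rates.tsv")
    outputs["amplicon"] = outdir / "amplicon_inversion_rates.tsv"

    _stage("junction-inversion")
    jr = simulate_junction_reads(
        seed + 3, mags.loci[0], junction_fraction, n_reads=n_junction_reads
    )
    j = inversion_rate_from_junction_reads(jr.reads, mags.loci[0])
    write_table(
        pd.DataFrame([j.__dict__]), outdir / "junction_inversion_rates.tsv"
    )
    outputs["junction"] = outdir / "junction_inversion_rates.tsv"

    _stage("community-ko")
    com = simulate_community_profiles(seed + 4)
    ko = community_ko_abundance(com.abundance, com.ko_copies)
    write_table(ko, outdir / "community_ko.tsv", {"unit": "wpFUKM x copies"}, index=True)
    outputs["ko_profile"] = outdir / "community_ko.tsv"

    _stage("differential")
    diff = differential_features(ko, com.groups)
    write_table(diff, outdir / "differential_kos.tsv",
                {"test": "Welch t on log2", "alpha": "0.05"}, index=True)
    outputs["diff"] = outdir / "differential_kos.tsv"

    _stage("enrichment")
    significant = diff.index[diff["significant"]]
    enr = ora_enrichment(significant, ko.index, com.pathways)
    write_table(enr, outdir / "pathway_enrichment.tsv",
                {"correction": "Benjamini-Hochberg", "fdr": "0.1"}, index=True)
    outputs["enrich"] = outdir / "pathway_enrichment.tsv"

    write_json(
        {"version": __version__, "seed": seed,
         "truths": {"mags": "planted in memory", "community": com.truth}},
        outdir / "pipeline_truth.json",
    )
    _stage("done")
    return outputs
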