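"""File formats: FASTA/FASTQ records, metadata-carrying TSV tables, locus JSON.

Tables are TSV with a header row preceded by ``#``-prefixed metadata lines
(units, parameters, package version); floats are written with 6 significant
digits, and the format is recorded in the metadata so round-trips are
well-defined.  FASTA input is gzip-transparent.
"""

from __future__ import annotations

import dataclasses
import gzip
import io as _io
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from . import __version__
from .errors import ConfigError, DataError
from .locus import GenomeSequence, InvertedRepeatPair, InvertibleLocus

FLOAT_FORMAT = "%.6g"


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (possibly gzipped) multi-record FASTA into GenomeSequence records.

    Record order is preserved, lowercase is normalized to uppercase, non-DNA
    characters raise a position-addressed error, and duplicate ids are
    rejected.
    """
    records = []
    seen: dict[str, int] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seen[rec.id] = seen.get(rec.id, 0) + 1
            records.append(GenomeSequence(rec.id, str(rec.seq), rec.description))
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise DataError(f"duplicate record ids in {path}: {', '.join(dupes)}")
    if not records:
        raise DataError(f"no FASTA records found in {path}")
    return records


def read_reads(path: str | Path) -> list[GenomeSequence]:
    """Read FASTA or FASTQ reads (format by extension; qualities ignored)."""
    path = Path(path)
    name = path.name.removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        records = [GenomeSequence(r.id, str(r.seq), r.description)
                   for r in SeqIO.parse(fh, fmt)]
    if not records:
        raise DataError(f"no {fmt.upper()} records found in {path}")
    return records


def write_fasta(records, path: str | Path, width: int = 80) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, str] | None = None,
    index: bool = False,
) -> None:
    """Write a TSV table with ``#`` metadata lines before the header."""
    meta = {"invertiscan_version": __version__, "float_format": FLOAT_FORMAT}
    meta.update(metadata or {})
    with open(path, "wt") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`; metadata lands in ``df.attrs``."""
    meta = {}
    buf = _io.StringIO()
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition(":")
                meta[key.strip()] = value.strip()
            else:
                buf.write(line)
    buf.seek(0)
    try:
        df = pd.read_csv(buf, sep="\t", index_col=index_col)
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed table {path}: {exc}") from exc
    df.attrs["metadata"] = meta
    return df


def loci_to_json(loci) -> str:
    payload = []
    for lc in loci:
        payload.append(
            {
                "name": lc.name,
                "reference_id": lc.reference_id,
                "ir": dataclasses.asdict(lc.ir),
                "spacer_len": lc.spacer_len,
                "anchors": {"left": lc.left_anchor, "right": lc.right_anchor},
                "forward_state": lc.forward_state,
                "inverted_state": lc.inverted_state,
            }
        )
    return json.dumps({"coordinate_system": "0-based half-open", "loci": payload}, indent=1)


def write_loci(loci, path: str | Path) -> None:
    Path(path).write_text(loci_to_json(loci))


def read_loci(path: str | Path) -> list[InvertibleLocus]:
    data = json.loads(Path(path).read_text())
    out = []
    for entry in data["loci"]:
        ir = InvertedRepeatPair(**entry["ir"])
        out.append(
            InvertibleLocus(
                name=entry["name"],
                reference_id=entry["reference_id"],
                ir=ir,
                left_anchor=entry["anchors"]["left"],
                right_anchor=entry["anchors"]["right"],
                forward_state=entry["forward_state"],
                inverted_state=entry["inverted_state"],
                spacer_len=entry.get("spacer_len", -1),
            )
        )
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=str))


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of a run, serialized into every output directory."""

    command: str
    params: dict
    seed: int | None = None
    version: str = __version__

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "run_config.json"
        write_json(dataclasses.asdict(self), path)
        return path
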