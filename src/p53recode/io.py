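"""Readers and writers for the formats the pipeline touches.

FASTA in/out goes through Biopython; tabular data are TSV with a header
row, optional ``#``-prefixed ``key=value`` metadata lines on top, UTF-8
and ``.`` decimal separator.  Site reports are written BED6-style
(0-based half-open, per the BED standard).  All writers are deterministic:
stable column order and 6-significant-digit float formatting.
"""

from __future__ import annotations

import importlib.resources
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import IUPAC, SiteMatch

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "sites_to_bed",
    "sites_to_records",
    "load_main_text_res",
]

_FLOAT_FORMAT = "%.6g"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse a (possibly wrapped) FASTA file into an ordered name -> sequence map.

    Sequences are uppercased and validated against the IUPAC nucleotide
    alphabet; a non-IUPAC character raises with the record name and
    offset, and duplicate record names raise listing the duplicates.
    """
    path = Path(path)
    out: dict[str, str] = {}
    dupes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in IUPAC:
                raise ValueError(
                    f"record {rec.id!r}: non-IUPAC character {ch!r} at offset {i}"
                )
        if rec.id in out:
            dupes.append(rec.id)
        out[rec.id] = seq
    if dupes:
        raise ValueError(f"duplicate record names: {sorted(set(dupes))}")
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_table(
    path: str | Path,
    schema: Mapping[str, type] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV with header, returning (frame, metadata).

    Leading ``# key=value`` lines are captured into the metadata dict.
    With a ``schema`` (column -> type), missing columns raise naming the
    column, and cells that fail numeric coercion raise with their 1-based
    data row number.  An empty file is an error, not an empty frame.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            body_lines.append(line)
    body = "\n".join(body_lines).strip()
    if not body:
        raise ValueError(f"{path}: empty table")
    df = pd.read_csv(StringIO(body), sep="\t", dtype=str)
    if schema:
        missing = set(schema) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        for col, typ in schema.items():
            if typ in (float, int):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    row = int(bad.idxmax()) + 1
                    raise ValueError(
                        f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                        f"in column {col!r}, data row {row}"
                    )
                df[col] = coerced.astype(typ)
    return df, meta


def write_table(df: pd.DataFrame, path: str | Path,
                metadata: Mapping[str, object] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def sites_to_bed(sites: Iterable[SiteMatch], seqid: str) -> pd.DataFrame:
    """BED6-style frame: seqid, start, end, name, mismatches, strand."""
    rows = []
    for i, s in enumerate(sites):
        rows.append(
            {
                "seqid": seqid,
                "start": s.start,
                "end": s.end,
                "name": f"{s.architecture}_{i}",
                "score": s.mismatches,
                "strand": s.strand,
            }
        )
    return pd.DataFrame(
        rows, columns=["seqid", "start", "end", "name", "score", "strand"]
    )


def sites_to_records(sites: Iterable[SiteMatch], seqid: str) -> list[dict]:
    """JSON-ready per-site report with architecture, spacer and site sequence."""
    return [
        {
            "seqid": seqid,
            "architecture": s.architecture,
            "start": s.start,
            "end": s.end,
            "strand": s.strand,
            "spacer": s.spacer,
            "mismatches": s.mismatches,
            "site_seq": s.re20,
        }
        for s in sites
    ]


def load_main_text_res() -> pd.DataFrame:
    """Packaged table of the REs whose sequences are printed in full.

    Columns ``name  sequence  spacer  provenance``; includes the GGGCA /
    GAACA half- and full-site probes and the ConE consensus permutation
    series (ConP and later steps reconstructed from the described edit
    path — see the file's comment lines).
    """
    ref = importlib.resources.files("p53recode") / "data" / "main_text_res.tsv"
    with importlib.resources.as_file(ref) as p:
        df, _ = read_table(p, schema={"name": str, "sequence": str,
                                      "spacer": int, "provenance": str})
    return df
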