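"""File format helpers.

All genomic coordinates are 0-based half-open in memory.  Conversion to and
from the 1-based inclusive conventions of VCF and GTF happens here and only
here; the analysis modules never see on-disk coordinates.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

_GTF_COLUMNS = [
    "chrom", "source", "feature", "start", "end",
    "score", "strand", "frame", "attributes",
]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-case sequences."""
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _parse_attributes(attrs: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attrs))


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Parse a GTF file into a DataFrame with 0-based half-open coordinates.

    ``gene_id`` and ``transcript_id`` are pulled out of the attribute column;
    the raw attribute string is preserved verbatim so a round trip through
    :func:`write_gtf` does not rewrite annotations.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            rows.append(parts)
    df = pd.DataFrame(rows, columns=_GTF_COLUMNS)
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    attrs = df["attributes"].map(_parse_attributes)
    df["gene_id"] = attrs.map(lambda a: a.get("gene_id", ""))
    df["transcript_id"] = attrs.map(lambda a: a.get("transcript_id", ""))
    return df


def write_gtf(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1  # back to 1-based inclusive
    out["end"] = out["end"].astype(int)
    out[_GTF_COLUMNS].to_csv(path, sep="\t", header=False, index=False,
                             quoting=3)  # QUOTE_NONE


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file (already 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if 3 in df.columns:
        df = df.rename(columns={3: "name"})
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand")
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
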