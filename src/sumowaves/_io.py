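"""Small text-format helpers: BED6, plain VCF position masks, FASTA writing.

Coordinates are 0-based half-open internally; BED round-trips without shifting.
"""

from __future__ import annotations

import textwrap
from pathlib import Path
from typing import Iterable

import pandas as pd

from ._errors import ValidationError

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (3-6 columns; extra columns kept as bed7, bed8, ...)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append(line.split("\t"))
    if not rows:
        return pd.DataFrame(columns=BED6_COLUMNS)
    ncol = len(rows[0])
    names = BED6_COLUMNS[:ncol] + [f"bed{i + 1}" for i in range(6, ncol)]
    df = pd.DataFrame(rows, columns=names)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValidationError(
            f"malformed BED interval {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, width)) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif line and name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_vcf_mask(positions: Iterable[tuple[str, int]], path: str | Path) -> None:
    """Write genomic positions (chrom, 0-based pos) as a minimal VCF (1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos in sorted(positions):
            fh.write(f"{chrom}\t{pos + 1}\t.\tN\tN\t.\t.\t.\n")


def read_vcf_mask(path: str | Path) -> set[tuple[str, int]]:
    """Read CHROM/POS from a plain-text VCF into 0-based (chrom, pos) pairs."""
    mask = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split("\t")
            mask.add((fields[0], int(fields[1]) - 1))
    return mask
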