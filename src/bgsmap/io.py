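"""Readers and writers shared by the pipeline stages.

Tables are TSV with ``#``-prefixed header comments recording the model id and
package version; B tracks are BedGraph-compatible (chrom, start, end, value)
so genome browsers can load them.  Floats are written with round-trip
precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bgs import BLandscape

__all__ = [
    "write_table",
    "read_table",
    "write_b_track",
    "read_b_track",
    "write_fasta_alignment",
    "read_fasta_alignment",
]


def _header(model_id: str | None) -> str:
    lines = [f"# bgsmap_version={__version__}"]
    if model_id:
        lines.append(f"# model_id={model_id}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, model_id: str | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(model_id))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_b_track(landscape: BLandscape, path) -> Path:
    """BedGraph-compatible TSV of per-window B values."""
    return write_table(landscape.to_frame(), path, model_id=landscape.model_id)


def read_b_track(path) -> BLandscape:
    df = read_table(path)
    starts = df["start"].to_numpy(dtype=np.int64)
    window_size = int(df["end"].iloc[0] - df["start"].iloc[0])
    b = df["B"].to_numpy(dtype=float)
    return BLandscape(
        model_id=str(df["model_id"].iloc[0]),
        chromosome=str(df["chrom"].iloc[0]),
        window_size=window_size,
        window_starts=starts,
        b=b,
        exponent=-np.log(b),
    )


def write_fasta_alignment(matrix: np.ndarray, path, name_prefix: str = "hap") -> Path:
    """Write a haplotype byte matrix as a FASTA multiple alignment."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, row in enumerate(matrix):
            fh.write(f">{name_prefix}{i:03d}\n")
            seq = row.tobytes().decode()
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")
    return path


def read_fasta_alignment(path) -> np.ndarray:
    """Read a FASTA multiple alignment into a haplotype byte matrix."""
    from Bio import SeqIO

    from .diversity import alignment_to_matrix

    return alignment_to_matrix(SeqIO.parse(str(path), "fasta"))
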