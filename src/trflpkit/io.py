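"""Readers and writers for the plain-text formats used across the pipeline.

FASTA via Biopython; peak tables, fingerprint matrices, resemblance matrices,
abundance tables and metadata as CSV (comma-separated, UTF-8, header row
mandatory, floats written with 12 significant digits); dendrograms as Newick.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structure import Dendrogram, ResemblanceMatrix
from .trflp import FingerprintMatrix, PeakProfile

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peak_table",
    "write_peak_table",
    "read_fingerprint_matrix",
    "write_fingerprint_matrix",
    "read_resemblance_matrix",
    "write_resemblance_matrix",
    "write_newick",
]

_FLOAT_FMT = "%.12g"
_VALID_RESIDUES = set("ACGTRYSWKMBDHVN-.")


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Read FASTA records, preserving order; residues are uppercased and
    validated against the IUPAC DNA alphabet (gaps allowed)."""
    path = Path(path)
    records: Dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{path}: record {i + 1} ({rec.id!r}) contains invalid "
                f"residues {sorted(bad)}"
            )
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = seq
    if not records:
        warnings.warn(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Dict[str, str], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_peak_table(profiles: Sequence[PeakProfile], path: Union[str, Path]) -> None:
    rows = [
        {"sample": p.sample_id, "channel": p.channel, "size_bp": s, "height": h}
        for p in profiles
        for s, h in p.peaks
    ]
    pd.DataFrame(rows, columns=["sample", "channel", "size_bp", "height"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_peak_table(path: Union[str, Path]) -> List[PeakProfile]:
    df = pd.read_csv(path)
    required = {"sample", "channel", "size_bp", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("size_bp", "height"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: column {col!r} must be numeric")
    if (df["height"] < 0).any():
        raise ValueError(f"{path}: negative peak heights")
    profiles = []
    for (sample, channel), grp in df.groupby(["sample", "channel"], sort=False):
        grp = grp.sort_values("size_bp")
        profiles.append(
            PeakProfile(
                sample_id=str(sample),
                channel=str(channel),
                peaks=[(float(s), float(h)) for s, h in zip(grp["size_bp"], grp["height"])],
            )
        )
    return profiles


def write_fingerprint_matrix(m: FingerprintMatrix, path: Union[str, Path]) -> None:
    m.to_frame().to_csv(path, index_label="sample", float_format=_FLOAT_FMT)


def read_fingerprint_matrix(path: Union[str, Path]) -> FingerprintMatrix:
    df = pd.read_csv(path, index_col=0)
    try:
        df.columns = [float(c) for c in df.columns]
    except ValueError as e:
        raise ValueError(f"{path}: bin headers must be numeric sizes: {e}")
    widths = np.diff(sorted(df.columns))
    bin_width = float(np.min(widths)) if len(widths) else 1.0
    return FingerprintMatrix.from_frame(df, bin_width=bin_width)


def write_resemblance_matrix(m: ResemblanceMatrix, path: Union[str, Path]) -> None:
    m.to_frame().to_csv(path, index_label="sample", float_format=_FLOAT_FMT)


def read_resemblance_matrix(
    path: Union[str, Path], kind: str = "similarity-percent", metric: str = "bray-curtis"
) -> ResemblanceMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column sample ids differ")
    v = df.to_numpy(dtype=float)
    if not np.allclose(v, v.T, atol=1e-9):
        raise ValueError(f"{path}: matrix is asymmetric beyond 1e-9")
    return ResemblanceMatrix(
        sample_ids=[str(i) for i in df.index], values=v, kind=kind, metric=metric
    )


def write_newick(dendrogram: Dendrogram, path: Union[str, Path]) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n")
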