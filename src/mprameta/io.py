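"""Readers and writers for the pipeline's interchange formats.

All tabular artifacts are tab-separated with a header row, UTF-8, and "." for
missing values. Sequences travel as FASTA, intervals as BED3+ with a
track-metadata TSV, and motifs in MEME minimal format (via Bio.motifs).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .featurize import PWM

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_bed",
    "read_fasta",
    "write_fasta",
    "read_meme",
    "write_meme",
    "read_activity_table",
    "write_activity_table",
    "read_feature_matrix",
    "write_feature_matrix",
    "config_hash",
]

NA_REP = "."


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=True, **kwargs)


def _write_tsv(df: pd.DataFrame, path, index: bool) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_REP, index=index)


def read_count_table(path) -> pd.DataFrame:
    """Read and validate a barcode-level count table TSV."""
    df = _read_tsv(path)
    required = ["region_id", "barcode_id", "dna", "rna"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} is missing columns: {missing}")
    if "batch" not in df.columns:
        df["batch"] = "b1"
    if "is_control" not in df.columns:
        df["is_control"] = False
    df["is_control"] = df["is_control"].astype(bool)
    for col in ("dna", "rna"):
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, vals.round()):
                rows = vals.index[vals != vals.round()][:5].tolist()
                raise ValueError(f"non-integer {col} counts at rows {rows}")
            df[col] = vals.astype(np.int64)
        if (df[col] < 0).any():
            rows = df.index[df[col] < 0][:5].tolist()
            raise ValueError(f"negative {col} counts at rows {rows}")
    dup = df.duplicated(subset=["region_id", "barcode_id", "batch"])
    if dup.any():
        raise ValueError(
            f"duplicate (region, barcode, batch) rows at {df.index[dup][:5].tolist()}"
        )
    return df


def write_count_table(df: pd.DataFrame, path) -> None:
    _write_tsv(df, path, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file (0-based half-open); rejects end <= start."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from e
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            rows.append({"chrom": parts[0], "start": start, "end": end})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    SeqIO.write(
        [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in items],
        str(path),
        "fasta",
    )


def read_meme(path) -> list[PWM]:
    """Read PWMs from a MEME minimal-format motif file."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        mat = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        bg = np.array([m.background[b] for b in "ACGT"]) if m.background else None
        out.append(PWM(m.name or m.consensus, mat, background=bg))
    return out


def write_meme(pwms: list[PWM], path) -> None:
    """Write PWMs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                # large nsites so parsers that reconstruct counts keep precision
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_activity_table(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col="region_id")
    if "alpha" not in df.columns:
        raise ValueError(f"activity table {path} lacks an 'alpha' column")
    return df


def write_activity_table(df: pd.DataFrame, path) -> None:
    _write_tsv(df, path, index=True)


def read_feature_matrix(path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read a FeatureMatrix TSV and, if present, its sidecar category map."""
    matrix = _read_tsv(path, index_col="region_id")
    sidecar = Path(str(path) + ".categories")
    category_map = None
    if sidecar.exists():
        cm = _read_tsv(sidecar, index_col="feature")
        category_map = cm["category"]
    return matrix, category_map


def write_feature_matrix(
    matrix: pd.DataFrame, path, category_map: pd.Series | None = None
) -> None:
    out = matrix.copy()
    out.index.name = "region_id"
    _write_tsv(out, path, index=True)
    if category_map is not None:
        cm = category_map.rename("category").to_frame()
        cm.index.name = "feature"
        _write_tsv(cm, Path(str(path) + ".categories"), index=True)


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
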