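"""FASTA / CSV / JSON plumbing shared by the CLI and the experiment layer."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from . import __version__
from .core import Sequence

__all__ = ["read_fasta", "write_fasta", "write_csv", "read_csv", "write_manifest"]


def read_fasta(path) -> list[Sequence]:
    return [Sequence(str(rec.seq).upper(), rec.id) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: list[Sequence], path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(records)


def write_csv(frame: pd.DataFrame, path, meta: dict | None = None) -> None:
    """CSV with ``# key=value`` header comments carrying seed and version."""
    meta = {"version": __version__, **(meta or {})}
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_manifest(manifest: dict, path) -> None:
    payload = {"version": __version__, **manifest}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
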