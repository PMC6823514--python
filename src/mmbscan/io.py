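"""Plain-text format plumbing: FASTA, TSV with provenance headers, config."""

from __future__ import annotations

import hashlib
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict:
    """FASTA file -> {record id: uppercase sequence string}."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(sequences: dict, path):
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")


def read_config(path) -> dict:
    """Plain key = value configuration; '#' starts a comment."""
    cfg = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        cfg[key] = value
    return cfg


def config_hash(cfg: dict) -> str:
    payload = "\n".join(f"{k}={cfg[k]}" for k in sorted(cfg))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_header(seed, cfg: dict | None = None) -> str:
    from . import __version__
    lines = [f"# mmbscan {__version__}", f"# seed: {seed}"]
    if cfg:
        lines.append(f"# config: {config_hash(cfg)}")
    return "\n".join(lines) + "\n"


def write_table(text: str, path, seed, cfg: dict | None = None):
    Path(path).write_text(provenance_header(seed, cfg) + text)
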