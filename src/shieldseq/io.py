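"""Readers and writers for the package's plain-text formats.

All tables carry ``#``-prefixed metadata headers documenting the schema
and coordinate convention (1-based, closed intervals), so outputs are
self-describing.
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd
from Bio import SeqIO

from .errors import InvalidInputError
from .geometry import AmpliconRef


def read_amplicons(path: str, anchors: dict[str, tuple[int, int, int]] | None = None) -> list[AmpliconRef]:
    """Read reference amplicons from FASTA.

    ``anchors`` maps record id to a CDS anchor ``(position, residue,
    frame_offset)``; records without an anchor default to ``(1, 1, 0)``
    (numbering from the amplicon start).
    """
    anchors = anchors or {}
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        out.append(
            AmpliconRef(
                name=rec.id,
                sequence=str(rec.seq).upper(),
                cds_anchor=anchors.get(rec.id, (1, 1, 0)),
            )
        )
    if not out:
        raise InvalidInputError(f"no FASTA records in {path}")
    return out


def read_guides(path: str) -> dict[str, str]:
    """Read a two-column TSV of guides: name, 20-nt sequence."""
    guides: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InvalidInputError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name, seq = parts
            guides[name] = seq.upper()
    if not guides:
        raise InvalidInputError(f"no guides in {path}")
    return guides


def write_table(df: pd.DataFrame, path: str, meta: dict | None = None, sep: str = ",") -> None:
    """Write a table with ``#`` metadata lines (coordinates are 1-based, closed)."""
    with open(path, "w") as fh:
        fh.write("# shieldseq table; coordinates 1-based, closed intervals\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(path_or_buf=fh, sep=sep, index=False)


def read_table(path: str, sep: str = ",") -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    return pd.read_csv(path, sep=sep, comment="#")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (for run provenance)."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
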