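"""Reading and writing motif matrix files.

Three plain-text dialects are supported:

* ``jaspar`` — one ``>id name`` header followed by four labelled rows of
  bracketed integer counts (``A  [ 3  0 17 ]``).
* ``transfac`` — TRANSFAC-style blocks: ``ID``/``DE`` headers, a ``P0``
  (or ``PO``) column-header line, numbered count rows, ``//`` terminator.
* ``sites-fasta`` — a FASTA file of equal-length binding sites; the whole
  file is tallied into a single motif named after the file.

Writers mirror the readers so that write(read(x)) round-trips byte-for-byte
on files this package wrote.
"""

from __future__ import annotations

import logging
import os
import re
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .motifs import BASES, Motif

__all__ = ["read_motifs", "write_motifs", "MotifParseError"]

log = logging.getLogger(__name__)

FORMATS = ("jaspar", "transfac", "sites-fasta")


class MotifParseError(ValueError):
    """Raised when a motif file does not conform to its dialect."""


def read_motifs(path: str | os.PathLike, format: str = "jaspar") -> list[Motif]:
    """Read all motifs from ``path`` in the named dialect.

    An empty file yields an empty list with a warning.  Malformed numeric
    cells raise :class:`MotifParseError` naming the offending line.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown motif format {format!r}; expected one of {FORMATS}")
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        log.warning("motif file %s is empty", path)
        return []
    if format == "jaspar":
        return _parse_jaspar(text)
    if format == "transfac":
        return _parse_transfac(text)
    return [_parse_sites_fasta(path)]


def write_motifs(motifs: Iterable[Motif], path: str | os.PathLike,
                 format: str = "jaspar") -> None:
    motifs = list(motifs)
    if format == "jaspar":
        blocks = [_format_jaspar(m) for m in motifs]
    elif format == "transfac":
        blocks = [_format_transfac(m) for m in motifs]
    elif format == "sites-fasta":
        if len(motifs) != 1:
            raise ValueError("sites-fasta holds exactly one motif per file")
        if motifs[0].sites is None:
            raise ValueError("sites-fasta output requires a motif with sites attached")
        blocks = [_format_sites_fasta(motifs[0])]
    else:
        raise ValueError(f"unknown motif format {format!r}; expected one of {FORMATS}")
    with open(path, "w") as fh:
        fh.write("".join(blocks))


# --- JASPAR ---------------------------------------------------------------

_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[?\s*([^\[\]]*?)\s*\]?\s*$")


def _parse_jaspar(text: str) -> list[Motif]:
    motifs: list[Motif] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise MotifParseError(f"line {i + 1}: expected '>' header, got {line!r}")
        head = line[1:].split(None, 1)
        motif_id = head[0] if head else f"motif{len(motifs) + 1}"
        tf_name = head[1].strip() if len(head) > 1 else None
        rows: dict[str, list[int]] = {}
        i += 1
        for base in BASES:
            if i >= len(lines):
                raise MotifParseError(f"line {i + 1}: truncated record for {motif_id!r}")
            m = _JASPAR_ROW.match(lines[i].strip())
            if not m or m.group(1) != base:
                raise MotifParseError(
                    f"line {i + 1}: expected a {base!r} count row for {motif_id!r}"
                )
            rows[base] = _parse_counts(m.group(2), i + 1)
            i += 1
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise MotifParseError(f"record {motif_id!r}: rows have unequal lengths {lengths}")
        counts = np.array([rows[b] for b in BASES], dtype=np.int64)
        motifs.append(Motif(id=motif_id, counts=counts, tf_name=tf_name))
    return motifs


def _parse_counts(cells: str, lineno: int) -> list[int]:
    out = []
    for tok in cells.split():
        try:
            val = int(tok)
        except ValueError:
            raise MotifParseError(f"line {lineno}: non-integer matrix cell {tok!r}") from None
        if val < 0:
            raise MotifParseError(f"line {lineno}: negative matrix cell {tok!r}")
        out.append(val)
    if not out:
        raise MotifParseError(f"line {lineno}: empty count row")
    return out


def _format_jaspar(m: Motif) -> str:
    header = f">{m.id}" + (f" {m.tf_name}" if m.tf_name else "") + "\n"
    width = max(len(str(int(v))) for v in m.counts.ravel())
    body = ""
    for bi, base in enumerate(BASES):
        cells = " ".join(f"{int(v):>{width}d}" for v in m.counts[bi])
        body += f"{base}  [ {cells} ]\n"
    return header + body


# --- TRANSFAC -------------------------------------------------------------

def _parse_transfac(text: str) -> list[Motif]:
    motifs: list[Motif] = []
    motif_id: str | None = None
    tf_name: str | None = None
    rows: list[list[int]] = []
    in_matrix = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tag = line.split(None, 1)[0]
        if tag in ("ID", "AC"):
            motif_id = line.split(None, 1)[1].strip() if " " in line else None
        elif tag in ("DE", "NA", "BF"):
            tf_name = line.split(None, 1)[1].strip() if " " in line else None
        elif tag in ("P0", "PO"):
            in_matrix = True
            rows = []
        elif tag == "XX":
            continue
        elif tag == "//":
            if motif_id is None and tf_name is None and not rows:
                continue
            motifs.append(_finish_transfac(motif_id, tf_name, rows, len(motifs), lineno))
            motif_id, tf_name, rows, in_matrix = None, None, [], False
        elif in_matrix and tag[0].isdigit():
            toks = line.split()
            cells = toks[1:5]
            if len(cells) != 4:
                raise MotifParseError(f"line {lineno}: expected 4 counts, got {len(cells)}")
            row = []
            for tok in cells:
                try:
                    val = int(float(tok))
                except ValueError:
                    raise MotifParseError(
                        f"line {lineno}: non-numeric matrix cell {tok!r}") from None
                if val < 0:
                    raise MotifParseError(f"line {lineno}: negative matrix cell {tok!r}")
                row.append(val)
            rows.append(row)
        # anything else outside a matrix block is ignored (TRANSFAC is annotation-rich)
    if rows or motif_id is not None:
        motifs.append(_finish_transfac(motif_id, tf_name, rows, len(motifs), lineno))
    return motifs


def _finish_transfac(motif_id, tf_name, rows, index, lineno) -> Motif:
    if not rows:
        raise MotifParseError(f"line {lineno}: TRANSFAC record without a count matrix")
    counts = np.array(rows, dtype=np.int64).T  # rows are positions, columns A C G T
    return Motif(id=motif_id or f"motif{index + 1}", counts=counts, tf_name=tf_name)


def _format_transfac(m: Motif) -> str:
    out = [f"ID {m.id}"]
    if m.tf_name:
        out.append(f"DE {m.tf_name}")
    out.append("P0      A      C      G      T")
    for j in range(m.length):
        cells = "".join(f"{int(m.counts[b, j]):>7d}" for b in range(4))
        out.append(f"{j + 1:02d}{cells}")
    out.append("XX")
    out.append("//")
    return "\n".join(out) + "\n"


# --- sites FASTA ----------------------------------------------------------

def _parse_sites_fasta(path: str | os.PathLike) -> Motif:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MotifParseError(f"{path}: no FASTA records")
    sites = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in sites}
    if len(lengths) != 1:
        raise MotifParseError(f"{path}: ragged site lengths {sorted(lengths)}")
    for s in sites:
        bad = set(s) - set(BASES)
        if bad:
            raise MotifParseError(
                f"{path}: ambiguous or non-ACGT letters {sorted(bad)}; "
                "the model is strictly 4-letter"
            )
    stem = os.path.splitext(os.path.basename(str(path)))[0]
    return Motif.from_sites(id=stem, sites=sites)


def _format_sites_fasta(m: Motif) -> str:
    return "".join(f">{m.id}_site{i + 1}\n{s}\n" for i, s in enumerate(m.sites))
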