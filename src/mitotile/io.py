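"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython.  GFF3 is written/read directly: features
live in memory as 0-based half-open intervals and on disk as 1-based
closed intervals with a ``##gff-version 3`` header.  A feature that
wraps the circular origin is emitted as two part lines sharing an ID
attribute, per GFF3's linear coordinate model.
"""

from __future__ import annotations

import json
from pathlib import Path
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import FEATURE_CATEGORIES, AnnotatedGenome, Feature

SOURCE = "mitotile"


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> AnnotatedGenome:
    """Read a single-record FASTA into a (sequence-only) genome.

    The pipeline operates on one molecule at a time; a multi-record file
    is rejected with the record count in the message.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ParseError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ParseError(
            f"{path}: expected a single record, found {len(records)} "
            "(this is a single-molecule tool)"
        )
    rec = records[0]
    return AnnotatedGenome(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(genome: AnnotatedGenome, path, width: int = 70) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    # Biopython wraps at 60 by default; the width argument is accepted for
    # interface stability but the default wrap is fine for every consumer.
    _ = width


# ---------------------------------------------------------------------------
# GFF3


def _fmt_attributes(attrs: dict) -> str:
    if not attrs:
        return "."
    parts = []
    for k, v in attrs.items():
        parts.append(f"{quote(str(k), safe='')}={quote(str(v), safe=', ')}")
    return ";".join(parts)


def _parse_attributes(text: str) -> dict:
    attrs: dict = {}
    if text in (".", ""):
        return attrs
    for item in text.split(";"):
        if not item:
            continue
        k, _, v = item.partition("=")
        attrs[unquote(k)] = unquote(v)
    return attrs


def write_gff3(features, path, seqid: str, genome_length: int | None = None,
               ftype: str = "region") -> None:
    """Write features (or any objects with start/end/strand/id) as GFF3.

    ``genome_length`` is required to split origin-wrapping features into
    their two linear parts.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genome_length is not None:
            fh.write(f"##sequence-region {seqid} 1 {genome_length}\n")
        for f in features:
            attrs = {"ID": f.id}
            if getattr(f, "category", None):
                attrs["category"] = f.category
            attrs.update(getattr(f, "attributes", {}) or {})
            score = attrs.pop("score", ".")
            if getattr(f, "wraps", False):
                if genome_length is None:
                    raise ValueError("genome_length required for wrapped features")
                parts = [(f.start, genome_length), (0, f.end - genome_length)]
                attrs["wraps"] = "true"
            else:
                parts = [(f.start, f.end)]
            for start, end in parts:
                fh.write(
                    "\t".join(
                        [
                            seqid,
                            SOURCE,
                            ftype,
                            str(start + 1),  # 1-based closed on disk
                            str(end),
                            str(score),
                            f.strand,
                            ".",
                            _fmt_attributes(attrs),
                        ]
                    )
                    + "\n"
                )


def read_gff3(path) -> list[Feature]:
    """Read features back; two part-lines sharing an ID are re-joined."""
    raw: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            start1, end1 = int(cols[3]), int(cols[4])
            if end1 < start1:
                raise ParseError(
                    f"{path}:{lineno}: end < start ({end1} < {start1}) without wrap"
                )
            attrs = _parse_attributes(cols[8])
            fid = attrs.get("ID", f"feature_{lineno}")
            if cols[5] != ".":
                attrs["score"] = cols[5]
            entry = (start1 - 1, end1, cols[6], attrs)
            raw.setdefault(fid, []).append(entry)
            if len(raw[fid]) == 1:
                order.append(fid)
    features = []
    for fid in order:
        parts = raw[fid]
        start, end, strand, attrs = parts[0]
        wraps = attrs.pop("wraps", "false") == "true"
        category = attrs.pop("category", "iorf")
        if category not in FEATURE_CATEGORIES:
            # TU/ORF class vocabularies round-trip as a plain attribute;
            # the generic reader always yields genome Features
            attrs["feature_class"] = category
            category = "iorf"
        attrs.pop("ID", None)
        if wraps and len(parts) == 2:
            # first part runs to the origin; second gives the wrapped tail
            tail = parts[1]
            end = end + (tail[1] - tail[0])
        features.append(
            Feature(id=fid, start=start, end=end, strand=strand,
                    category=category, wraps=wraps, attributes=attrs)
        )
    return features


# ---------------------------------------------------------------------------
# Provenance sidecars


def write_provenance(path, stage: str, **params) -> None:
    """Record the producing stage and its parameters next to an output file."""
    side = Path(str(path) + ".provenance.json")
    side.write_text(json.dumps({"stage": stage, "params": params}, indent=2,
                               sort_keys=True, default=str) + "\n")


__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_provenance",
]
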