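"""FASTA input and hit output."""

from __future__ import annotations

import logging
from typing import Iterator, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser

from . import __version__
from .descriptor import Descriptor
from .engine import Occurrence, reverse_complement

__all__ = ["read_fasta", "write_hits"]

logger = logging.getLogger("rnarobo")

_VALID = set("ACGTN")


def read_fasta(stream: TextIO) -> Iterator[tuple[str, str]]:
    """Read a multi-record FASTA stream into (id, normalized sequence) pairs.

    The record id is the first whitespace-delimited token of the header.
    Sequences are uppercased, U becomes T, and any other non-ACGTN
    character becomes N (counted and warned once per record).  Records with
    empty sequences are skipped with a warning; a stream with no records
    at all is an error.
    """
    n_records = 0
    for header, seq in SimpleFastaParser(stream):
        n_records += 1
        seq_id = header.split()[0] if header.split() else header
        seq = seq.upper().replace("U", "T")
        if not seq:
            logger.warning("record %s has an empty sequence; skipped", seq_id)
            continue
        bad = sum(1 for c in seq if c not in _VALID)
        if bad:
            logger.warning(
                "record %s: %d non-ACGTN characters replaced by N", seq_id, bad
            )
            seq = "".join(c if c in _VALID else "N" for c in seq)
        yield seq_id, seq
    if n_records == 0:
        raise ValueError("no FASTA records found")


def _fmt_interval(start: int, end: int) -> str:
    """0-based half-open -> 1-based inclusive (empty prints start..start-1)."""
    return f"{start + 1}..{end}"


def _occ_columns(
    occ: Occurrence, descriptor: Descriptor, sequences: dict[str, str]
) -> list[str]:
    seq = sequences[occ.seq_id]
    cols = []
    for tag, (s, e) in zip(descriptor.map.occurrences, occ.intervals):
        sub = seq[s:e]
        if occ.strand == "-":
            sub = reverse_complement(sub)
        cols.append(f"{tag}={_fmt_interval(s, e)}/{sub}")
    return cols


def write_hits(
    occurrences: list[Occurrence],
    descriptor: Descriptor,
    stream: TextIO,
    sequences: dict[str, str],
    order: tuple[str, ...] | None = None,
    seed: int | None = None,
    fmt: str = "tsv",
) -> None:
    """Write occurrences as TSV (or an aligned text block).

    One row per occurrence: seq_id, strand, 1-based inclusive span, then
    one ``tag=start..end/substring`` column per map occurrence (the
    substring is the motif-sense sequence; '-' hits carry forward-axis
    coordinates).  Header lines carry the descriptor name, search order,
    seed and version, so identical (input, seed, config) runs produce
    byte-identical output.
    """
    stream.write(f"# rnarobo {__version__}\n")
    stream.write(f"# descriptor: {descriptor.name}\n")
    if order is not None:
        stream.write(f"# order: {' '.join(order)}\n")
    if seed is not None:
        stream.write(f"# seed: {seed}\n")
    if fmt == "tsv":
        cols = "\t".join(descriptor.map.occurrences)
        stream.write(f"#seq_id\tstrand\tspan_start\tspan_end\t{cols}\n")
        for occ in occurrences:
            lo, hi = occ.span
            fields = [occ.seq_id, occ.strand, str(lo + 1), str(hi)]
            fields += _occ_columns(occ, descriptor, sequences)
            stream.write("\t".join(fields) + "\n")
    elif fmt == "text":
        for occ in occurrences:
            lo, hi = occ.span
            stream.write(
                f">{occ.seq_id}:{lo + 1}..{hi}({occ.strand})\n"
            )
            for col in _occ_columns(occ, descriptor, sequences):
                tag, _, rest = col.partition("=")
                iv, _, sub = rest.partition("/")
                stream.write(f"  {tag:>6s}  {iv:>12s}  {sub}\n")
    else:
        raise ValueError(f"unknown output format {fmt!r}")
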