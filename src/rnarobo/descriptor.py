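"""Motif descriptor language: parsing, validation and length bounds.

A descriptor specifies an RNA structural motif as an ordered list of
structural elements (the *motif map*, written 5'->3'), one specification
line per element, and an optional fixed search order.  Single-stranded
elements are degenerate-nucleotide patterns; paired (helical) elements are
two column-aligned strands whose columns must form allowed base pairs.
Helices appear twice in the map -- once per strand, the 3' strand marked
with a prime (``h1'``) -- and the map order is otherwise unrestricted, so
arbitrary pseudoknots can be expressed.

File format (UTF-8 text, ``#`` starts a comment)::

    # optional name line
    name: my-motif
    # motif map: one line, element occurrences 5'->3'
    s1 h1 s2 h2 h1' s3 h2'
    # element specifications, one line each
    s1 0:0 YNGCTAA            # tag  mismatches:insertions  pattern
    s2 1:0 NN***
    h1 0:0:1 NNNNN:NNNNN AT,TA,CG,GC,GT,TG
    h2 0:1:0 SSSS:SSSS        # tag  mismatches:mispairs:insertions  5':3'
    # optional fixed search order (helices listed once, unprimed)
    order: s1 h2 h1 s2 s3

Patterns use the IUPAC degenerate alphabet plus ``*`` (wildcard: one
arbitrary nucleotide or the empty string).  The 3' strand of a helix is
written 3'->5' so that column *j* of the two strands pair with each other.
The pair list defaults to Watson-Crick (``AT,TA,CG,GC``).  Trailing
distortion fields may be omitted and default to 0.  Variable helix length
is expressed through wildcard columns (wildcard on *both* strands) and
bulge insertions; there is no separate min:max length syntax.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Union

__all__ = [
    "IUPAC_BASES",
    "WATSON_CRICK",
    "DescriptorError",
    "SingleStrandSpec",
    "HelixSpec",
    "MotifMap",
    "Descriptor",
    "parse_descriptor",
    "serialize_descriptor",
    "length_bounds",
    "flexibility",
]

#: IUPAC degenerate nucleotide codes mapped to their DNA base sets.
#: U is an input alias of T; patterns and sequences are normalised to T.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

WILDCARD = "*"

#: Canonical Watson-Crick pairs as (5'-base, 3'-base) two-character strings.
WATSON_CRICK: frozenset[str] = frozenset({"AT", "TA", "CG", "GC"})

_SINGLE_TAG = re.compile(r"^s\d+$")
_HELIX_TAG = re.compile(r"^h\d+$")
_HELIX_OCC = re.compile(r"^h\d+'?$")


class DescriptorError(ValueError):
    """Raised for syntax or semantic errors in a descriptor file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _check_tokens(tokens: str, tag: str, line: int | None) -> tuple[str, ...]:
    out = []
    for ch in tokens.upper():
        if ch == WILDCARD:
            out.append(WILDCARD)
        elif ch in IUPAC_BASES:
            # normalise U -> T
            out.append("T" if ch == "U" else ch)
        else:
            raise DescriptorError(
                f"element {tag}: invalid pattern character {ch!r}", line
            )
    if not out:
        raise DescriptorError(f"element {tag}: empty pattern", line)
    return tuple(out)


def _wildcard_blocks(tokens: tuple[str, ...]) -> list[int]:
    """Lengths of maximal runs of consecutive wildcard tokens."""
    blocks, run = [], 0
    for t in tokens:
        if t == WILDCARD:
            run += 1
        elif run:
            blocks.append(run)
            run = 0
    if run:
        blocks.append(run)
    return blocks


@dataclass(frozen=True)
class SingleStrandSpec:
    """A single-stranded element: IUPAC/wildcard pattern with distortion budgets.

    ``max_mismatch`` bounds the number of non-wildcard positions whose text
    base falls outside its class; ``max_insert`` bounds extra text bases
    consumed between two pattern tokens (insertions are internal only).
    """

    tag: str
    tokens: tuple[str, ...]
    max_mismatch: int = 0
    max_insert: int = 0

    is_helix = False

    def __post_init__(self):
        if self.max_mismatch < 0 or self.max_insert < 0:
            raise DescriptorError(f"element {self.tag}: negative distortion count")

    @cached_property
    def base_sets(self) -> tuple[frozenset[str] | None, ...]:
        """Per-token base set; ``None`` marks a wildcard."""
        return tuple(
            None if t == WILDCARD else IUPAC_BASES[t] for t in self.tokens
        )

    @property
    def min_len(self) -> int:
        return sum(1 for t in self.tokens if t != WILDCARD)

    @property
    def max_len(self) -> int:
        return len(self.tokens) + self.max_insert

    @property
    def wildcard_blocks(self) -> list[int]:
        return _wildcard_blocks(self.tokens)

    def pattern_str(self) -> str:
        return "".join(self.tokens)


@dataclass(frozen=True)
class HelixSpec:
    """A paired (helical) element: two column-aligned strands.

    ``tokens3`` is stored 3'->5', so column *j* of ``tokens5`` pairs with
    column *j* of ``tokens3``.  A column is optional (matchable by nothing)
    only when *both* tokens are wildcards; mixed wildcard columns are a
    parse error.  ``max_mispair`` bounds aligned columns whose base pair is
    outside ``allowed_pairs``; ``max_insert`` bounds single-base bulges on
    either strand, never adjacent to another insertion.
    """

    tag: str
    tokens5: tuple[str, ...]
    tokens3: tuple[str, ...]
    allowed_pairs: frozenset[str] = WATSON_CRICK
    max_mismatch: int = 0
    max_mispair: int = 0
    max_insert: int = 0

    is_helix = True

    def __post_init__(self):
        if len(self.tokens5) != len(self.tokens3):
            raise DescriptorError(
                f"element {self.tag}: strand patterns differ in length "
                f"({len(self.tokens5)} vs {len(self.tokens3)})"
            )
        if min(self.max_mismatch, self.max_mispair, self.max_insert) < 0:
            raise DescriptorError(f"element {self.tag}: negative distortion count")
        if not self.allowed_pairs:
            raise DescriptorError(f"element {self.tag}: empty base-pair set")
        for j, (a, b) in enumerate(zip(self.tokens5, self.tokens3)):
            if (a == WILDCARD) != (b == WILDCARD):
                raise DescriptorError(
                    f"element {self.tag}: column {j + 1} mixes a wildcard with "
                    "a base class (wildcard columns must be '*' on both strands)"
                )

    @cached_property
    def base_sets5(self) -> tuple[frozenset[str] | None, ...]:
        return tuple(None if t == WILDCARD else IUPAC_BASES[t] for t in self.tokens5)

    @cached_property
    def base_sets3(self) -> tuple[frozenset[str] | None, ...]:
        return tuple(None if t == WILDCARD else IUPAC_BASES[t] for t in self.tokens3)

    @cached_property
    def pair_counts(self) -> tuple[int, ...]:
        """P[j]: number of allowed base pairs compatible with column j's classes."""
        out = []
        for s5, s3 in zip(self.base_sets5, self.base_sets3):
            c5 = s5 if s5 is not None else IUPAC_BASES["N"]
            c3 = s3 if s3 is not None else IUPAC_BASES["N"]
            out.append(sum(1 for p in self.allowed_pairs if p[0] in c5 and p[1] in c3))
        return tuple(out)

    @property
    def n_columns(self) -> int:
        return len(self.tokens5)

    @property
    def min_len(self) -> int:
        """Minimum length of either strand (mandatory columns)."""
        return sum(1 for t in self.tokens5 if t != WILDCARD)

    @property
    def max_len(self) -> int:
        """Maximum length of one strand (all columns plus all bulges on it)."""
        return self.n_columns + self.max_insert

    @property
    def wildcard_blocks(self) -> list[int]:
        return _wildcard_blocks(self.tokens5)

    def validate_matchable(self) -> None:
        if self.max_mispair == 0:
            for j, (p, t) in enumerate(zip(self.pair_counts, self.tokens5)):
                if t != WILDCARD and p == 0:
                    raise DescriptorError(
                        f"element {self.tag}: column {j + 1} admits no allowed "
                        "base pair and no mispairs are permitted"
                    )

    def pattern_str(self) -> str:
        return "".join(self.tokens5) + ":" + "".join(self.tokens3)


ElementSpec = Union[SingleStrandSpec, HelixSpec]


@dataclass(frozen=True)
class MotifMap:
    """The 5'->3' list of element occurrences.

    Each single-strand tag appears once; each helix tag appears twice, as
    ``h<k>`` (5' strand) and later ``h<k>'`` (3' strand).  No other order
    restriction: interleaved helices (``h1 h2 h1' h2'``) are pseudoknots.
    """

    occurrences: tuple[str, ...]

    def __post_init__(self):
        seen: dict[str, int] = {}
        for occ in self.occurrences:
            if _SINGLE_TAG.match(occ):
                if occ in seen:
                    raise DescriptorError(f"duplicate occurrence of {occ} in map")
                seen[occ] = 1
            elif _HELIX_OCC.match(occ):
                base = occ.rstrip("'")
                primed = occ.endswith("'")
                if primed:
                    if seen.get(base) != 1:
                        raise DescriptorError(
                            f"3' strand {occ} appears before 5' strand {base}"
                            if base not in seen
                            else f"duplicate occurrence of {occ} in map"
                        )
                    seen[base] = 2
                else:
                    if base in seen:
                        raise DescriptorError(f"duplicate occurrence of {base} in map")
                    seen[base] = 1
            else:
                raise DescriptorError(f"malformed element tag {occ!r} in map")
        for tag, state in seen.items():
            if _HELIX_TAG.match(tag) and state != 2:
                raise DescriptorError(f"helix {tag} is missing its 3' strand {tag}'")
        if not self.occurrences:
            raise DescriptorError("empty motif map")

    @cached_property
    def element_tags(self) -> tuple[str, ...]:
        """Distinct element tags in order of first occurrence (helices unprimed)."""
        out, seen = [], set()
        for occ in self.occurrences:
            base = occ.rstrip("'")
            if base not in seen:
                seen.add(base)
                out.append(base)
        return tuple(out)

    def index_of(self, occ: str) -> int:
        return self.occurrences.index(occ)


def _occ_spec(desc: "Descriptor", occ: str) -> ElementSpec:
    return desc.specs[occ.rstrip("'")]


@dataclass(frozen=True)
class Descriptor:
    """A validated motif descriptor."""

    map: MotifMap
    specs: dict[str, ElementSpec] = field(hash=False)
    user_order: tuple[str, ...] | None = None
    name: str = "motif"

    def __post_init__(self):
        tags = set(self.map.element_tags)
        for occ in tags:
            if occ not in self.specs:
                raise DescriptorError(f"map element {occ} has no specification")
        for tag in self.specs:
            if tag not in tags:
                raise DescriptorError(f"specified element {tag} is not in the map")
            spec = self.specs[tag]
            if spec.tag != tag:
                raise DescriptorError(f"spec tag {spec.tag} filed under {tag}")
            if bool(_HELIX_TAG.match(tag)) != bool(spec.is_helix):
                raise DescriptorError(
                    f"element {tag}: tag kind does not match specification kind"
                )
            if spec.is_helix:
                spec.validate_matchable()
        if self.user_order is not None:
            if sorted(self.user_order) != sorted(tags):
                raise DescriptorError(
                    "search order must list every element exactly once"
                )

    def occ_spec(self, occ: str) -> ElementSpec:
        """Specification of a map occurrence (primed or not)."""
        return self.specs[occ.rstrip("'")]

    def occ_bounds(self, occ: str) -> tuple[int, int]:
        """(min, max) length of the given map occurrence."""
        spec = self.occ_spec(occ)
        return spec.min_len, spec.max_len

    @cached_property
    def L(self) -> int:
        """Maximum total length of a motif occurrence (sum of strand maxima)."""
        return sum(self.occ_spec(occ).max_len for occ in self.map.occurrences)

    @cached_property
    def min_span(self) -> int:
        return sum(self.occ_spec(occ).min_len for occ in self.map.occurrences)


def length_bounds(spec: ElementSpec) -> tuple[int, int]:
    """(min, max) match length of one strand of an element.

    The minimum counts mandatory (non-wildcard) tokens; the maximum adds
    every wildcard and every permitted insertion.
    """
    return spec.min_len, spec.max_len


def flexibility(spec: ElementSpec) -> int:
    """Length slack of one strand: max_len - min_len."""
    return spec.max_len - spec.min_len


def _parse_counts(fieldstr: str, tag: str, n: int, line: int) -> list[int]:
    parts = fieldstr.split(":")
    if len(parts) > n:
        raise DescriptorError(
            f"element {tag}: expected at most {n} ':'-separated distortion "
            f"counts, got {fieldstr!r}", line
        )
    out = []
    for p in parts:
        if not p.isdigit():
            raise DescriptorError(
                f"element {tag}: malformed distortion count {p!r}", line
            )
        out.append(int(p))
    out.extend([0] * (n - len(out)))
    return out


def _parse_pairs(fieldstr: str, tag: str, line: int) -> frozenset[str]:
    pairs = set()
    for item in fieldstr.split(","):
        item = item.strip().upper().replace("U", "T")
        if len(item) != 2 or any(b not in "ACGT" for b in item):
            raise DescriptorError(f"element {tag}: malformed base pair {item!r}", line)
        pairs.add(item)
    return frozenset(pairs)


def parse_descriptor(text: str, name: str | None = None) -> Descriptor:
    """Parse and validate a descriptor file's content.

    Raises :class:`DescriptorError` with the offending line number on any
    syntax or consistency error.
    """
    map_line: tuple[str, ...] | None = None
    order: tuple[str, ...] | None = None
    specs: dict[str, ElementSpec] = {}
    parsed_name = name

    for lineno, raw in enumerate(text.splitlines(), start=1):
        content = raw.split("#", 1)[0].strip()
        if not content:
            continue
        if content.lower().startswith("name:"):
            parsed_name = content[5:].strip()
            continue
        if content.lower().startswith("order:"):
            if order is not None:
                raise DescriptorError("duplicate order line", lineno)
            order = tuple(content[6:].split())
            continue
        fields = content.split()
        if map_line is None:
            map_line = tuple(fields)
            continue
        # specification line: tag counts pattern [pairs]
        if len(fields) < 3:
            raise DescriptorError(
                f"expected 'tag counts pattern [pairs]', got {content!r}", lineno
            )
        tag = fields[0]
        if tag in specs:
            raise DescriptorError(f"duplicate specification for {tag}", lineno)
        if _SINGLE_TAG.match(tag):
            if len(fields) > 3:
                raise DescriptorError(
                    f"element {tag}: unexpected trailing fields", lineno
                )
            m, i = _parse_counts(fields[1], tag, 2, lineno)
            specs[tag] = SingleStrandSpec(
                tag, _check_tokens(fields[2], tag, lineno), m, i
            )
        elif _HELIX_TAG.match(tag):
            if len(fields) > 4:
                raise DescriptorError(
                    f"element {tag}: unexpected trailing fields", lineno
                )
            m, r, i = _parse_counts(fields[1], tag, 3, lineno)
            if ":" not in fields[2]:
                raise DescriptorError(
                    f"element {tag}: helix pattern must be 5':3'", lineno
                )
            p5, _, p3 = fields[2].partition(":")
            pairs = WATSON_CRICK if len(fields) < 4 else _parse_pairs(
                fields[3], tag, lineno
            )
            try:
                specs[tag] = HelixSpec(
                    tag,
                    _check_tokens(p5, tag, lineno),
                    _check_tokens(p3, tag, lineno),
                    pairs,
                    m,
                    r,
                    i,
                )
            except DescriptorError as exc:
                raise DescriptorError(str(exc), lineno) from None
        else:
            raise DescriptorError(f"malformed element tag {tag!r}", lineno)

    if map_line is None:
        raise DescriptorError("descriptor has no motif map line")
    return Descriptor(
        MotifMap(map_line), specs, order, parsed_name if parsed_name else "motif"
    )


def serialize_descriptor(desc: Descriptor) -> str:
    """Render a descriptor back to its file format (reparses identically)."""
    lines = [f"name: {desc.name}", " ".join(desc.map.occurrences)]
    for tag in desc.map.element_tags:
        spec = desc.specs[tag]
        if spec.is_helix:
            counts = f"{spec.max_mismatch}:{spec.max_mispair}:{spec.max_insert}"
            pairs = ",".join(sorted(spec.allowed_pairs))
            lines.append(f"{tag} {counts} {spec.pattern_str()} {pairs}")
        else:
            counts = f"{spec.max_mismatch}:{spec.max_insert}"
            lines.append(f"{tag} {counts} {spec.pattern_str()}")
    if desc.user_order is not None:
        lines.append("order: " + " ".join(desc.user_order))
    return "\n".join(lines) + "\n"
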