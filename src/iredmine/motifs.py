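"""PROSITE-style motif patterns: parsing, scanning and instantiation.

The dialect covers the notation used for the two IRED-specific motifs
(the NADPH cofactor-binding motif and the active-site motif):

* an uppercase letter is an exact residue;
* ``x`` is a wildcard, ``xN`` means exactly N consecutive wildcards;
* ``[DE]`` matches any residue in the set;
* ``{K}`` matches any residue **not** in the set.

Matching is ungapped and case-insensitive. A per-scan mismatch budget
(default 0) may allow a limited number of bracketed positions (choice or
negation elements) to deviate; exact and wildcard elements never deviate.
The ambiguity code ``X`` in a subject sequence fails exact/choice/negation
elements and, under the default lenient policy, satisfies wildcards.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .records import AA_SET, AMBIGUOUS, AMINO_ACIDS


class PatternError(ValueError):
    """Malformed pattern text; the message names the offending offset."""


@dataclass(frozen=True)
class PatternElement:
    """One token of a pattern.

    ``kind`` is one of ``exact``, ``choice``, ``negation``, ``wildcard``.
    ``residues`` is the residue set the token refers to (empty for
    wildcards); ``repeat`` > 1 only for wildcards.
    """

    kind: str
    residues: frozenset
    repeat: int = 1

    def __post_init__(self) -> None:
        if self.kind not in {"exact", "choice", "negation", "wildcard"}:
            raise PatternError(f"unknown element kind {self.kind!r}")
        if self.repeat < 1:
            raise PatternError("repeat must be >= 1")
        if self.repeat > 1 and self.kind != "wildcard":
            raise PatternError("repeat is only allowed on wildcards")
        if not self.residues <= AA_SET:
            bad = sorted(set(self.residues) - AA_SET)
            raise PatternError(f"non-canonical residues {bad} in element")
        if self.kind == "exact" and len(self.residues) != 1:
            raise PatternError("exact element needs exactly one residue")
        if self.kind in {"choice", "negation"} and not self.residues:
            raise PatternError(f"{self.kind} set must be non-empty")
        if self.kind == "negation" and self.residues >= AA_SET:
            raise PatternError("negation set must be a proper subset of the alphabet")

    def matches(self, ch: str, x_in_wildcard: bool = True) -> bool:
        """Whether subject character ``ch`` satisfies this element (one site)."""
        if ch == AMBIGUOUS:
            return self.kind == "wildcard" and x_in_wildcard
        if self.kind == "wildcard":
            return ch in AA_SET
        if self.kind == "negation":
            return ch in AA_SET and ch not in self.residues
        return ch in self.residues

    def canonical(self) -> str:
        if self.kind == "exact":
            return next(iter(self.residues))
        if self.kind == "wildcard":
            return "x" if self.repeat == 1 else f"x{self.repeat}"
        inner = "".join(sorted(self.residues))
        return f"[{inner}]" if self.kind == "choice" else f"{{{inner}}}"


@dataclass(frozen=True)
class Pattern:
    """A named, compiled motif pattern."""

    name: str
    elements: tuple
    source_text: str = ""

    @property
    def span(self) -> int:
        """Fixed match length: the sum of element repeats."""
        return sum(e.repeat for e in self.elements)

    def canonical_text(self) -> str:
        return "".join(e.canonical() for e in self.elements)

    def site_elements(self):
        """Elements expanded to one per matched site (wildcards unrolled)."""
        out = []
        for e in self.elements:
            out.extend([e] * e.repeat)
        return out


@dataclass(frozen=True)
class MotifHit:
    """An occurrence of a pattern in a sequence (1-based inclusive)."""

    pattern_name: str
    start: int
    end: int
    matched: str
    mismatches: int = 0


def parse_pattern(text: str, name: str = "") -> Pattern:
    """Compile pattern ``text`` into a :class:`Pattern`.

    Raises :class:`PatternError` naming the 0-based offset of the first
    offending character.
    """
    if not text:
        raise PatternError("empty pattern at offset 0")
    elements = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "x":
            j = i + 1
            while j < n and text[j].isdigit():
                j += 1
            repeat = int(text[i + 1 : j]) if j > i + 1 else 1
            if repeat < 1:
                raise PatternError(f"zero repeat at offset {i}")
            elements.append(PatternElement("wildcard", frozenset(), repeat))
            i = j
        elif ch in ("[", "{"):
            close = "]" if ch == "[" else "}"
            j = text.find(close, i + 1)
            if j < 0:
                raise PatternError(f"unclosed {ch!r} at offset {i}")
            inner = text[i + 1 : j]
            if not inner:
                raise PatternError(f"empty bracket at offset {i}")
            for k, c in enumerate(inner):
                if c not in AA_SET:
                    raise PatternError(
                        f"invalid residue {c!r} inside bracket at offset {i + 1 + k}"
                    )
            kind = "choice" if ch == "[" else "negation"
            elements.append(PatternElement(kind, frozenset(inner)))
            i = j + 1
        elif ch in AA_SET:
            elements.append(PatternElement("exact", frozenset(ch)))
            i += 1
        elif ch.isdigit():
            raise PatternError(f"repeat on a non-wildcard token at offset {i}")
        else:
            raise PatternError(f"unknown character {ch!r} at offset {i}")
    return Pattern(name or text, tuple(elements), text)


def match_at(
    sequence: str,
    pos: int,
    pattern: Pattern,
    mismatch_budget: int = 0,
    x_in_wildcard: bool = True,
):
    """Try to match ``pattern`` at 0-based offset ``pos``.

    Returns the number of bracketed-position mismatches used, or ``None``
    if the pattern does not match within the budget.
    """
    sites = pattern.site_elements()
    if pos + len(sites) > len(sequence):
        return None
    used = 0
    for k, elem in enumerate(sites):
        ch = sequence[pos + k]
        if elem.matches(ch, x_in_wildcard):
            continue
        # only choice/negation elements may consume the budget
        if elem.kind in {"choice", "negation"} and ch in AA_SET and used < mismatch_budget:
            used += 1
            continue
        return None
    return used


def scan(
    sequence: str,
    pattern: Pattern,
    mismatch_budget: int = 0,
    x_in_wildcard: bool = True,
) -> list:
    """All (possibly overlapping) occurrences of ``pattern`` in ``sequence``.

    Hits are returned in ascending start order with 1-based inclusive
    coordinates. An empty sequence, or a pattern longer than the sequence,
    yields an empty list.
    """
    if not 0 <= mismatch_budget <= 2:
        raise ValueError("mismatch_budget must be in 0..2")
    seq = sequence.upper()
    span = pattern.span
    hits = []
    for pos in range(0, len(seq) - span + 1):
        used = match_at(seq, pos, pattern, mismatch_budget, x_in_wildcard)
        if used is not None:
            hits.append(
                MotifHit(pattern.name, pos + 1, pos + span, seq[pos : pos + span], used)
            )
    return hits


def instantiate(pattern: Pattern, seed: int) -> str:
    """A concrete sequence of the pattern's span that the pattern matches.

    Choices are drawn reproducibly from ``seed``; negations draw from the
    complement of the excluded set.
    """
    rng = random.Random(seed)
    return instantiate_with(pattern, rng)


def instantiate_with(pattern: Pattern, rng: random.Random) -> str:
    """Like :func:`instantiate` but drawing from an existing RNG stream."""
    out = []
    for elem in pattern.site_elements():
        if elem.kind == "exact":
            out.append(next(iter(elem.residues)))
        elif elem.kind == "wildcard":
            out.append(rng.choice(AMINO_ACIDS))
        elif elem.kind == "choice":
            out.append(rng.choice(sorted(elem.residues)))
        else:  # negation
            out.append(rng.choice(sorted(AA_SET - elem.residues)))
    return "".join(out)


def load_patterns(path: str | Path) -> list:
    """Load patterns from a TSV config (one per line: name TAB pattern)."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, text = line.partition("\t")
        if not text:
            raise PatternError(f"malformed pattern line (need name TAB pattern): {line!r}")
        patterns.append(parse_pattern(text.strip(), name.strip()))
    return patterns


COFACTOR_MOTIF = "cofactor_binding"
ACTIVE_SITE_MOTIF = "active_site"


def default_patterns() -> list:
    """The two IRED-specific motifs shipped with the package."""
    ref = resources.files("iredmine.data") / "motifs.tsv"
    with resources.as_file(ref) as p:
        return load_patterns(p)
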