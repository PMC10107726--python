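"""Motif dialect: parsing, scanning, instantiation."""

import random

import pytest

from iredmine.motifs import (
    MotifHit,
    Pattern,
    PatternError,
    instantiate,
    parse_pattern,
    scan,
)
from iredmine.records import AA_SET, AMINO_ACIDS

COFACTOR = "GLGxMGx5[ATS]x4Gx4[VIL]WNR[TS]x2[KR]"
ACTIVE_SITE = "Gx[DE]x[GDA]x[APS]x3{K}x[ASL]x[LMVIAG]"


class TestParse:
    def test_simple_tokens(self):
        p = parse_pattern("Gx[DE]")
        kinds = [(e.kind, set(e.residues), e.repeat) for e in p.elements]
        assert kinds == [
            ("exact", {"G"}, 1),
            ("wildcard", set(), 1),
            ("choice", {"D", "E"}, 1),
        ]
        assert p.span == 3

    def test_wildcard_repeat_and_negation(self):
        p = parse_pattern("x3{K}")
        assert [e.kind for e in p.elements] == ["wildcard", "negation"]
        assert p.elements[0].repeat == 3
        assert set(p.elements[1].residues) == {"K"}
        assert p.span == 4

    def test_family_motif_spans(self):
        # sum of token repeats, hand-counted independently
        assert parse_pattern(COFACTOR).span == 29
        assert parse_pattern(ACTIVE_SITE).span == 15

    @pytest.mark.parametrize(
        "text,offset",
        [
            ("G[DE", 1),  # unclosed bracket
            ("G[]x", 1),  # empty bracket
            ("G3x", 1),  # repeat on a non-wildcard token
            ("Gx[D1]", 4),  # bad residue inside bracket
            ("G?x", 1),  # unknown character
        ],
    )
    def test_errors_name_offset(self, text, offset):
        with pytest.raises(PatternError, match=f"offset {offset}"):
            parse_pattern(text)

    def test_canonical_round_trip(self):
        for text in (COFACTOR, ACTIVE_SITE, "Gx[ED]x2{KR}A"):
            p = parse_pattern(text)
            again = parse_pattern(p.canonical_text())
            assert again.elements == p.elements


class TestScan:
    def test_single_hit(self):
        hits = scan("GAD", parse_pattern("Gx[DE]"))
        assert hits == [MotifHit("Gx[DE]", 1, 3, "GAD")]

    def test_negation_rejects(self):
        assert scan("AAAK", parse_pattern("x3{K}")) == []

    def test_empty_sequence_and_short_sequence(self):
        p = parse_pattern("Gx[DE]")
        assert scan("", p) == []
        assert scan("GA", p) == []

    def test_overlapping_hits_all_reported(self):
        hits = scan("GGGA", parse_pattern("Gx"))
        assert [h.start for h in hits] == [1, 2, 3]

    def test_case_insensitive(self):
        assert scan("gad", parse_pattern("Gx[DE]"))

    def test_x_fails_brackets_matches_wildcard(self):
        p = parse_pattern("Gx[DE]")
        assert scan("GXD", p)  # X on the wildcard site
        assert scan("GAX", p) == []  # X on the choice site
        assert scan("GXD", p, x_in_wildcard=False) == []

    def test_mismatch_budget_applies_to_bracketed_only(self):
        p = parse_pattern("Gx[DE]")
        assert scan("GAY", p) == []
        hits = scan("GAY", p, mismatch_budget=1)
        assert hits and hits[0].mismatches == 1
        # exact position never consumes the budget
        assert scan("AAD", p, mismatch_budget=2) == []


def _random_pattern(rng):
    elements = []
    for _ in range(rng.randint(1, 6)):
        kind = rng.choice(["exact", "choice", "negation", "wildcard", "wildcard_n"])
        if kind == "exact":
            elements.append(rng.choice(AMINO_ACIDS))
        elif kind == "choice":
            k = rng.randint(1, 4)
            elements.append("[" + "".join(rng.sample(AMINO_ACIDS, k)) + "]")
        elif kind == "negation":
            k = rng.randint(1, 4)
            elements.append("{" + "".join(rng.sample(AMINO_ACIDS, k)) + "}")
        elif kind == "wildcard":
            elements.append("x")
        else:
            elements.append(f"x{rng.randint(2, 5)}")
    return parse_pattern("".join(elements))


def _oracle_scan(seq, pattern, budget=0, x_in_wildcard=True):
    """Independent per-offset check via precomputed allowed-residue sets."""
    seq = seq.upper()
    sites = []
    for e in pattern.elements:
        if e.kind == "exact":
            allowed = set(e.residues)
        elif e.kind == "choice":
            allowed = set(e.residues)
        elif e.kind == "negation":
            allowed = AA_SET - set(e.residues)
        else:
            allowed = set(AA_SET) | ({"X"} if x_in_wildcard else set())
        bracketed = e.kind in ("choice", "negation")
        sites.extend([(allowed, bracketed)] * e.repeat)
    hits = []
    for off in range(len(seq) - len(sites) + 1):
        used = 0
        ok = True
        for k, (allowed, bracketed) in enumerate(sites):
            ch = seq[off + k]
            if ch in allowed:
                continue
            if bracketed and ch in AA_SET and used < budget:
                used += 1
                continue
            ok = False
            break
        if ok:
            hits.append((off + 1, used))
    return hits


def test_scanner_equals_bruteforce_oracle():
    """Scan output matches a per-offset set-membership oracle exactly."""
    rng = random.Random(42)
    for _ in range(60):
        pattern = _random_pattern(rng)
        length = rng.randint(0, 200)
        seq = "".join(rng.choice(AMINO_ACIDS + "X") for _ in range(length))
        budget = rng.randint(0, 2)
        got = [(h.start, h.mismatches) for h in scan(seq, pattern, budget)]
        assert got == _oracle_scan(seq, pattern, budget)


def test_shift_equivariance():
    """Prepending non-matching residues shifts every hit start by k."""
    rng = random.Random(7)
    p = parse_pattern("WNR[TS]")
    seq = "".join(rng.choice("ACDEG") for _ in range(50)) + "WNRT" + "AAAA"
    base = scan(seq, p)
    for k in (1, 3, 10):
        shifted = scan("A" * k + seq, p)
        assert [h.start for h in shifted] == [h.start + k for h in base]


class TestInstantiate:
    def test_respects_element_sets(self):
        for seed in range(10):
            s = instantiate(parse_pattern("Gx[DE]"), seed)
            assert s[0] == "G" and s[2] in "DE" and len(s) == 3

    def test_negation_never_emits_excluded(self):
        for seed in range(50):
            assert instantiate(parse_pattern("{K}"), seed) != "K"

    def test_scan_closure_on_family_motifs(self):
        for text in (COFACTOR, ACTIVE_SITE):
            p = parse_pattern(text)
            for seed in range(100):
                s = instantiate(p, seed)
                assert any(h.start == 1 for h in scan(s, p))

    def test_deterministic_under_seed(self):
        p = parse_pattern(COFACTOR)
        assert instantiate(p, 5) == instantiate(p, 5)
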