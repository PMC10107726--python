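"""IRED calling and sequence-based classification.

A candidate imine reductase must carry both family motifs (the
cofactor-binding and active-site motifs), must not carry Asn at reference
position 191 (the discriminator against beta-hydroxyacid dehydrogenases),
and — optionally, on by default — must carry the conserved Arg at
reference position 50.

Classification reads the key-residue profile: the residue-187/196 pair
defines the subgroup; Asp187 and Tyr187 are the canonical markers of
(R)- and (S)-stereoselectivity respectively; Glu187 and Asn187 mark
NADH-capable enzymes. These rules are heuristics learned from sequence
panels, not ground truth — one documented panel member (D187 with P139 and
C194) inverts the stereoselectivity rule, which is why predictions carry a
caveat flag when residue 139 is Pro or residue 194 is not Met/Phe.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .motifs import ACTIVE_SITE_MOTIF, COFACTOR_MOTIF, MotifHit, Pattern, scan
from .records import GAP, ProteinRecord
from .refmap import (
    AlignmentParams,
    KeyResidueProfile,
    ReferenceMap,
    align_global,
    key_residue_profile,
)

#: Exclusion rule identifiers.
MISSING_COFACTOR = "missing_cofactor_motif"
MISSING_ACTIVE_SITE = "missing_active_site_motif"
N191 = "N191"
MISSING_R50 = "missing_R50"
LOW_IDENTITY = "low_identity"

#: The eight subgroups of the characterised panel, keyed by (r187, r196).
NAMED_SUBGROUPS = {
    ("D", "G"),
    ("Y", "T"),
    ("Y", "G"),
    ("E", "P"),
    ("D", "T"),
    ("N", "A"),
    ("D", "A"),
    ("D", "S"),
}


@dataclass(frozen=True)
class IREDCall:
    """Mining verdict for one sequence."""

    query_id: str
    is_candidate: bool
    evidence: dict  # pattern name -> list of MotifHit (primary first)
    exclusions: tuple
    profile: KeyResidueProfile
    identity_to_ref: float


@dataclass(frozen=True)
class Classification:
    """Subgroup label and heuristic property predictions for one profile."""

    query_id: str
    subgroup: str  # "<r187>187-<r196>196" or "unassigned"
    novel: bool  # subgroup pair not among the eight named ones
    stereo_prediction: str  # "R" | "S" | "unknown"
    cofactor_prediction: str  # "NADPH" | "NADH-capable" | "unknown"
    caveat: bool = False
    provenance: str = "heuristic"


@dataclass(frozen=True)
class MiningOptions:
    """Knobs for :func:`call_ired` / :func:`mine_proteome`."""

    mismatch_budget: int = 0
    require_r50: bool = True
    #: optional identity prefilter standing in for the original similarity
    #: search against the reference; ``None`` disables it.
    min_identity: float | None = None
    params: AlignmentParams = field(default_factory=AlignmentParams)


def _order_hits(
    hits: list, refmap: ReferenceMap, reference_hit_start: int | None
) -> list:
    """Primary hit first: the one mapping nearest the reference motif locus."""
    if len(hits) <= 1 or reference_hit_start is None:
        return list(hits)
    query_to_ref = {q: r for q, r in refmap.pairs}

    def mapped_distance(hit: MotifHit) -> float:
        ref_pos = query_to_ref.get(hit.start)
        if ref_pos is None:
            return float("inf")
        return abs(ref_pos - reference_hit_start)

    return sorted(hits, key=lambda h: (mapped_distance(h), h.start))


def call_ired(
    record: ProteinRecord,
    patterns: list,
    reference: ProteinRecord,
    options: MiningOptions | None = None,
) -> IREDCall:
    """Apply the motif and key-residue rules to one sequence.

    ``patterns`` must include both default motifs (by name). Degenerate
    sequences never raise; they come back non-candidate with the triggered
    exclusions listed.
    """
    options = options or MiningOptions()
    by_name = {p.name: p for p in patterns}
    for required in (COFACTOR_MOTIF, ACTIVE_SITE_MOTIF):
        if required not in by_name:
            raise ValueError(f"patterns must include {required!r}")

    refmap = align_global(record, reference, options.params)
    profile = key_residue_profile(refmap, record)

    evidence = {}
    for name in (COFACTOR_MOTIF, ACTIVE_SITE_MOTIF):
        pattern = by_name[name]
        hits = scan(record.seq, pattern, mismatch_budget=options.mismatch_budget)
        ref_hits = scan(reference.seq, pattern)
        ref_start = ref_hits[0].start if ref_hits else None
        evidence[name] = _order_hits(hits, refmap, ref_start)

    exclusions = []
    if not evidence[COFACTOR_MOTIF]:
        exclusions.append(MISSING_COFACTOR)
    if not evidence[ACTIVE_SITE_MOTIF]:
        exclusions.append(MISSING_ACTIVE_SITE)
    # residue rules follow motif confirmation: a sequence without the family
    # motifs is already rejected, and its alignment-mapped key residues are
    # not meaningful evidence
    if not exclusions:
        if profile[191] == "N":
            exclusions.append(N191)
        if options.require_r50 and profile[50] != "R":
            exclusions.append(MISSING_R50)
    if options.min_identity is not None and refmap.identity < options.min_identity:
        exclusions.append(LOW_IDENTITY)

    return IREDCall(
        query_id=record.id,
        is_candidate=not exclusions,
        evidence=evidence,
        exclusions=tuple(exclusions),
        profile=profile,
        identity_to_ref=refmap.identity,
    )


def mine_proteome(
    records: list,
    patterns: list,
    reference: ProteinRecord,
    options: MiningOptions | None = None,
):
    """One :class:`IREDCall` per record plus summary counts.

    Returns ``(calls, summary)`` where ``summary`` has the candidate count
    and per-rule exclusion tallies.
    """
    calls = [call_ired(rec, patterns, reference, options) for rec in records]
    tally = Counter()
    for call in calls:
        tally.update(call.exclusions)
    summary = {
        "n_records": len(calls),
        "n_candidates": sum(c.is_candidate for c in calls),
        "exclusions": dict(tally),
    }
    return calls, summary


def assign_subgroup(profile: KeyResidueProfile) -> Classification:
    """Subgroup from the (187, 196) residue pair; total on any profile."""
    r187, r196 = profile[187], profile[196]
    if r187 == GAP or r196 == GAP:
        subgroup, novel = "unassigned", False
    else:
        subgroup = f"{r187}187-{r196}196"
        novel = (r187, r196) not in NAMED_SUBGROUPS
    stereo, cofactor, caveat = _predict(profile)
    return Classification(
        query_id=profile.query_id,
        subgroup=subgroup,
        novel=novel,
        stereo_prediction=stereo,
        cofactor_prediction=cofactor,
        caveat=caveat,
    )


def _predict(profile: KeyResidueProfile):
    r187 = profile[187]
    if r187 == "D":
        stereo = "R"
    elif r187 == "Y":
        stereo = "S"
    else:
        stereo = "unknown"
    if r187 in {"E", "N"}:
        cofactor = "NADH-capable"
    elif r187 in {"D", "Y"}:
        cofactor = "NADPH"
    else:
        cofactor = "unknown"
    # residues known to modulate stereoselectivity beyond 187
    caveat = profile[139] == "P" or profile[194] not in {"M", "F"}
    return stereo, cofactor, caveat


def predict_properties(profile: KeyResidueProfile) -> Classification:
    """Heuristic stereoselectivity / cofactor-preference prediction."""
    return assign_subgroup(profile)


def summarize_panel(classifications: list) -> dict:
    """Count table by subgroup and by residue-187 class."""
    by_subgroup = Counter(c.subgroup for c in classifications if c.subgroup != "unassigned")
    by_r187 = Counter(
        c.subgroup[0] for c in classifications if c.subgroup != "unassigned"
    )
    return {
        "n_members": len(classifications),
        "n_unassigned": sum(c.subgroup == "unassigned" for c in classifications),
        "by_subgroup": dict(by_subgroup),
        "by_r187": dict(by_r187),
        "n_subgroups": len(by_subgroup),
        "n_r187_classes": len(by_r187),
    }
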