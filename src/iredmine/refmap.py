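"""Mapping candidate sequences onto reference residue numbering.

All residue positions used for IRED classification (50, 54, 108, 139, 187,
191, 194, 195, 196) are expressed in the coordinate system of the
*S. kanamyceticus* IRED reference. A candidate is mapped onto that
coordinate system by optimal global pairwise alignment (BLOSUM62, affine
gaps), and the residues aligned to the key positions are read out.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .records import GAP, ProteinRecord

#: Reference positions read out for classification.
KEY_POSITIONS = (50, 54, 108, 139, 187, 191, 194, 195, 196)


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring parameters.

    ``gap_open`` is the cost of the first gapped residue and ``gap_extend``
    the cost of each additional one, in substitution-matrix units.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class ReferenceMap:
    """Aligned (query, reference) position pairs plus alignment summary.

    ``pairs`` lists 1-based positions for aligned non-gap columns, strictly
    increasing in both coordinates. ``identity`` is the fraction of
    identical residues over aligned columns.
    """

    query_id: str
    pairs: tuple
    score: float
    identity: float

    def reference_to_query(self) -> dict:
        return {r: q for q, r in self.pairs}


@dataclass(frozen=True)
class KeyResidueProfile:
    """Query residues observed at the nine reference key positions.

    ``residue_at`` maps each position in :data:`KEY_POSITIONS` to a single
    amino-acid letter, or to ``"-"`` when the alignment leaves the position
    uncovered.
    """

    query_id: str
    residue_at: dict

    def __post_init__(self) -> None:
        if set(self.residue_at) != set(KEY_POSITIONS):
            raise ValueError("profile must cover exactly the nine key positions")

    def __getitem__(self, pos: int) -> str:
        return self.residue_at[pos]


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_global(
    query: ProteinRecord,
    reference: ProteinRecord,
    params: AlignmentParams | None = None,
) -> ReferenceMap:
    """Optimal global alignment of ``query`` against ``reference``.

    Deterministic: of co-optimal alignments the aligner's first enumerated
    alignment is taken, so identical inputs give identical maps.
    """
    params = params or AlignmentParams()
    if not query.seq or not reference.seq:
        raise ValueError("both sequences must be non-empty")
    query.validate()
    reference.validate()
    aligner = _make_aligner(params)
    aln = aligner.align(query.seq, reference.seq)[0]
    pairs = []
    matches = 0
    qblocks, rblocks = aln.aligned
    for (qs, qe), (rs, re_) in zip(qblocks, rblocks):
        for qi, ri in zip(range(qs, qe), range(rs, re_)):
            pairs.append((qi + 1, ri + 1))
            if query.seq[qi] == reference.seq[ri]:
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    return ReferenceMap(query.id, tuple(pairs), float(aln.score), identity)


def percent_identity(
    a: ProteinRecord, b: ProteinRecord, params: AlignmentParams | None = None
) -> float:
    """Pairwise global-alignment identity, symmetric in its arguments.

    Symmetry is guaranteed by aligning the pair in a canonical order
    (lexicographic by sequence) so tie-breaking among co-optimal alignments
    cannot depend on argument order.
    """
    first, second = (a, b) if (a.seq, a.id) <= (b.seq, b.id) else (b, a)
    return align_global(first, second, params).identity


def key_residue_profile(
    refmap: ReferenceMap, query: ProteinRecord
) -> KeyResidueProfile:
    """Read out the query residues aligned to the nine key positions."""
    ref_to_query = refmap.reference_to_query()
    residue_at = {}
    for pos in KEY_POSITIONS:
        qpos = ref_to_query.get(pos)
        residue_at[pos] = query.seq[qpos - 1] if qpos is not None else GAP
    return KeyResidueProfile(refmap.query_id, residue_at)


def profile_sequence(
    query: ProteinRecord,
    reference: ProteinRecord,
    params: AlignmentParams | None = None,
) -> KeyResidueProfile:
    """Convenience: align then read the key-residue profile."""
    return key_residue_profile(align_global(query, reference, params), query)
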