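"""Cross-species SAV extraction from global protein alignments.

Human/ortholog pairs are aligned globally (Needleman-Wunsch with affine
gaps, BLOSUM62, open 10 / extend 0.5, terminal gaps free — the defaults of
the EMBOSS ``needle`` tool).  Pairs below 70% identity over gap-free columns
(PIDE) are discarded.  Every mismatching gap-free column then yields one
cross-species SAV under the back-mutation convention: the non-human residue
is introduced into the human sequence (the *context*), and the variant
scored is the substitution back to the human residue.  E.g. human L at
position 42 vs ortholog V gives the SAV ``V42L`` evaluated on the human
sequence carrying V at 42.

When several candidate orthologs exist for one human protein, the alignment
with the highest ungapped sequence identity is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .variant_model import (
    AMINO_ACID_SET,
    SAV,
    ProteinRecord,
    VariantModelError,
)

logger = logging.getLogger("savkit")


class AlignmentError(VariantModelError):
    pass


class PideBelowThresholdError(AlignmentError):
    """Alignment identity below the configured minimum."""

    def __init__(self, message: str, pide: float):
        super().__init__(message)
        self.pide = pide


class NoOrthologPassesError(AlignmentError):
    """Every candidate ortholog failed the identity filter."""

    def __init__(self, message: str, pide_by_candidate: Mapping[str, float]):
        super().__init__(message)
        self.pide_by_candidate = dict(pide_by_candidate)


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap global alignment parameters (EMBOSS needle defaults).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``; terminal
    gaps are free unless ``penalize_end_gaps`` is set.  ``min_pide`` is the
    identity-over-gap-free-columns threshold below which a pair is
    discarded.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    min_pide: float = 0.70
    penalize_end_gaps: bool = False

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend > 0:
            raise AlignmentError(
                f"need gap_open >= gap_extend > 0, got "
                f"{self.gap_open} / {self.gap_extend}"
            )
        if not 0.0 <= self.min_pide <= 1.0:
            raise AlignmentError(f"min_pide {self.min_pide} outside [0, 1]")


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment with its identity measures.

    ``pide_nogap`` = identical columns / gap-free columns (the filter
    quantity); ``ungapped_identity`` = identical columns / length of the
    shorter sequence (the ortholog-selection quantity).
    """

    aligned_a: str
    aligned_b: str
    score: float
    pide_nogap: Optional[float]
    ungapped_identity: float

    @property
    def n_identical(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )


def _check_sequence(seq: str, name: str) -> None:
    for i, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACID_SET:
            raise AlignmentError(
                f"sequence {name!r}: non-standard residue {ch!r} at position {i}"
            )


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # Biopython charges open_gap_score for the first gapped column and
    # extend_gap_score for each further one — exactly the needle convention
    # gap_open + (k-1)*gap_extend.
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if not params.penalize_end_gaps:
        try:
            aligner.open_end_gap_score = 0.0
            aligner.extend_end_gap_score = 0.0
        except AttributeError:  # biopython < 1.86 naming
            aligner.end_open_gap_score = 0.0
            aligner.end_extend_gap_score = 0.0
    return aligner


def identity_measures(aligned_a: str, aligned_b: str) -> tuple[Optional[float], float]:
    """(pide_nogap, ungapped_identity) for a pair of gapped rows.

    ``pide_nogap`` is None when the alignment has no gap-free column (the
    undefined case is signalled explicitly, never silently 0).
    """
    if len(aligned_a) != len(aligned_b):
        raise AlignmentError("aligned rows differ in length")
    n_gapfree = 0
    n_ident = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            raise AlignmentError("column gapped in both rows")
        if x != "-" and y != "-":
            n_gapfree += 1
            if x == y:
                n_ident += 1
    len_a = len(aligned_a.replace("-", ""))
    len_b = len(aligned_b.replace("-", ""))
    pide_nogap = None if n_gapfree == 0 else n_ident / n_gapfree
    ungapped_identity = n_ident / min(len_a, len_b)
    return pide_nogap, ungapped_identity


def pide_measures(aln: AlignmentResult) -> tuple[Optional[float], float]:
    """Recompute (pide_nogap, ungapped_identity) from an alignment."""
    return identity_measures(aln.aligned_a, aln.aligned_b)


def global_align_affine(
    a: str, b: str, params: AlignmentParams = AlignmentParams()
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences under affine gap
    scoring; deterministic (first alignment of the ordered optimal set)."""
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    _check_sequence(a, "a")
    _check_sequence(b, "b")
    aligner = _make_aligner(params)
    alignment = next(iter(aligner.align(a, b)))
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    pide_nogap, ungapped = identity_measures(aligned_a, aligned_b)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        pide_nogap=pide_nogap,
        ungapped_identity=ungapped,
    )


def select_best_ortholog(
    human: ProteinRecord,
    candidates: Iterable[ProteinRecord],
    params: AlignmentParams = AlignmentParams(),
) -> tuple[ProteinRecord, AlignmentResult]:
    """Among candidate orthologs passing ``min_pide``, pick the one whose
    alignment has the highest ungapped identity (ties: smallest id)."""
    candidates = list(candidates)
    if not candidates:
        raise AlignmentError(f"no ortholog candidates for {human.id!r}")
    passing: list[tuple[ProteinRecord, AlignmentResult]] = []
    pides: dict[str, float] = {}
    for cand in candidates:
        aln = global_align_affine(human.sequence, cand.sequence, params)
        pides[cand.id] = -1.0 if aln.pide_nogap is None else aln.pide_nogap
        if aln.pide_nogap is not None and aln.pide_nogap >= params.min_pide:
            passing.append((cand, aln))
    if not passing:
        raise NoOrthologPassesError(
            f"{human.id!r}: no candidate reaches PIDE >= {params.min_pide:.2f} "
            f"({', '.join(f'{k}={v:.3f}' for k, v in pides.items())})",
            pides,
        )
    passing.sort(key=lambda item: (-item[1].ungapped_identity, item[0].id))
    return passing[0]


@dataclass(frozen=True)
class ContextSAV:
    """A cross-species SAV together with its back-mutated context sequence
    (the human sequence carrying the ortholog residue at the SAV position).
    Applying ``sav.alt_aa`` at ``sav.position`` on the context reproduces
    the human sequence exactly."""

    sav: SAV
    context_sequence: str


def extract_cross_species_savs(
    human: ProteinRecord,
    ortholog: ProteinRecord,
    params: AlignmentParams = AlignmentParams(),
    set_label: str = "cross_species",
    alignment: Optional[AlignmentResult] = None,
) -> list[ContextSAV]:
    """Extract one SAV per mismatching gap-free alignment column under the
    back-mutation convention (ref = ortholog residue, alt = human residue,
    position in human coordinates).

    Raises :class:`PideBelowThresholdError` when the pair aligns below
    ``min_pide``.  Masked human positions are skipped with a warning.
    """
    aln = alignment or global_align_affine(human.sequence, ortholog.sequence, params)
    if aln.pide_nogap is None or aln.pide_nogap < params.min_pide:
        shown = "undefined" if aln.pide_nogap is None else f"{aln.pide_nogap:.3f}"
        raise PideBelowThresholdError(
            f"{human.id!r} vs {ortholog.id!r}: PIDE {shown} "
            f"below minimum {params.min_pide:.2f}",
            -1.0 if aln.pide_nogap is None else aln.pide_nogap,
        )
    masked = human.masked_positions
    out: list[ContextSAV] = []
    human_pos = 0
    seen_positions: set[int] = set()
    for h, o in zip(aln.aligned_a, aln.aligned_b):
        if h != "-":
            human_pos += 1
        if h == "-" or o == "-" or h == o:
            continue
        assert human_pos not in seen_positions  # one column per human coordinate
        seen_positions.add(human_pos)
        if human_pos in masked:
            logger.warning(
                "%s: masked position %d skipped in cross-species extraction",
                human.id, human_pos,
            )
            continue
        if o not in AMINO_ACID_SET:
            continue
        context = (
            human.sequence[: human_pos - 1] + o + human.sequence[human_pos:]
        )
        sav = SAV(human.id, human_pos, ref_aa=o, alt_aa=h, set_label=set_label)
        out.append(ContextSAV(sav=sav, context_sequence=context))
    return out


def housekeeping_subset(
    per_species_savs: Mapping[str, list[SAV]],
    within_human_savs: list[SAV],
) -> tuple[dict[str, list[SAV]], list[SAV]]:
    """Restrict every SAV set to proteins shared by all species' ortholog
    sets and the within-human set, each contributing at least one SAV.

    Returns the restricted per-species map and the restricted within-human
    list.  An empty intersection yields empty outputs (logged).
    """
    protein_sets = [
        {s.protein_id for s in savs} for savs in per_species_savs.values()
    ]
    protein_sets.append({s.protein_id for s in within_human_savs})
    shared = set.intersection(*protein_sets) if protein_sets else set()
    logger.info("housekeeping subset: %d shared proteins", len(shared))
    restricted = {
        species: [s for s in savs if s.protein_id in shared]
        for species, savs in per_species_savs.items()
    }
    human_restricted = [s for s in within_human_savs if s.protein_id in shared]
    return restricted, human_restricted
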