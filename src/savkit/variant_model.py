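"""Domain types and input readers for single-amino-acid-variant (SAV) analysis.

A SAV is a one-residue substitution in a protein, the protein-level
consequence of a non-synonymous single-nucleotide variant (SNV).  This module
defines the core containers (:class:`ProteinRecord`, :class:`SAV`,
:class:`ScoredSAV`), the allele-frequency classification into rare / uncommon
/ common, and readers and filters for the plain-text interchange formats
(FASTA, tab-separated SAV and score tables, VCF with a VEP-style CSQ field).

All coordinates are 1-based: position ``p`` refers to sequence character
``p``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("savkit")

#: The 20 standard amino acids, one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)

#: Ambiguity / non-standard codes tolerated in FASTA input.  Positions
#: carrying one of these are *masked*: no SAV may be enumerated or accepted
#: there.
MASKED_RESIDUES = frozenset("XBZU")

#: Default maximum protein length (residues); longer proteins are excluded
#: from analysis.
MAX_PROTEIN_LENGTH = 6000


class VariantModelError(ValueError):
    """Base class for domain-validation errors."""


class InvalidFrequencyError(VariantModelError):
    """Allele frequency outside [0, 1] or missing where required."""


class InvalidResidueError(VariantModelError):
    """Sequence character outside the tolerated alphabet."""


class FrequencyClass(str, Enum):
    """Allele-frequency class of a within-population SAV.

    The three classes partition [0, 1]: rare (< 1%), uncommon (1% <= f < 5%)
    and common (>= 5%).
    """

    RARE = "rare"
    UNCOMMON = "uncommon"
    COMMON = "common"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_frequency(ldaf: float) -> FrequencyClass:
    """Classify an allele frequency into rare / uncommon / common.

    Parameters
    ----------
    ldaf:
        Allele-frequency estimate in [0, 1].  The boundaries are
        rare < 0.01 <= uncommon < 0.05 <= common (inclusive on the common
        side).

    Raises
    ------
    InvalidFrequencyError
        If ``ldaf`` is None, NaN or outside [0, 1].
    """
    if ldaf is None or ldaf != ldaf:
        raise InvalidFrequencyError("allele frequency is missing; cannot classify")
    if not 0.0 <= ldaf <= 1.0:
        raise InvalidFrequencyError(f"allele frequency {ldaf!r} outside [0, 1]")
    if ldaf < 0.01:
        return FrequencyClass.RARE
    if ldaf < 0.05:
        return FrequencyClass.UNCOMMON
    return FrequencyClass.COMMON


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with a stable identifier.

    Non-standard residues (X, B, Z, U) are tolerated but their positions are
    masked; any other character raises :class:`InvalidResidueError`.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise VariantModelError(f"protein {self.id!r}: empty sequence")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in AMINO_ACID_SET and ch not in MASKED_RESIDUES:
                raise InvalidResidueError(
                    f"protein {self.id!r}: invalid residue {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def masked_positions(self) -> frozenset[int]:
        """1-based positions carrying a non-standard residue."""
        return frozenset(
            i for i, ch in enumerate(self.sequence, start=1) if ch in MASKED_RESIDUES
        )

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise VariantModelError(
                f"position {position} outside 1..{len(self.sequence)} "
                f"for protein {self.id!r}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SAV:
    """One amino-acid substitution: ``ref_aa`` at ``position`` replaced by
    ``alt_aa`` in protein ``protein_id``.

    ``ldaf`` is the allele frequency when the SAV comes from a population
    set; cross-species / random / disease SAVs carry ``None`` and
    classifying them raises rather than silently defaulting.
    """

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    ldaf: Optional[float] = None
    set_label: str = ""

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise VariantModelError(
                f"{self.protein_id}:{self.notation}: ref and alt are identical"
            )
        if self.position < 1:
            raise VariantModelError(f"position {self.position} is not 1-based")
        for aa, role in ((self.ref_aa, "ref"), (self.alt_aa, "alt")):
            if aa not in AMINO_ACID_SET:
                raise InvalidResidueError(
                    f"{self.protein_id}: {role} residue {aa!r} is not a "
                    "standard amino acid"
                )
        if self.ldaf is not None and not 0.0 <= self.ldaf <= 1.0:
            raise InvalidFrequencyError(
                f"{self.protein_id}:{self.notation}: ldaf {self.ldaf} outside [0, 1]"
            )

    @property
    def notation(self) -> str:
        """``<ref><position><alt>`` text form, e.g. ``V42L``."""
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def frequency_class(self) -> FrequencyClass:
        return classify_frequency(self.ldaf)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the substitution (protein, position, ref, alt)."""
        return (self.protein_id, self.position, self.ref_aa, self.alt_aa)


def parse_sav_notation(protein_id: str, text: str, **kwargs) -> SAV:
    """Parse ``<ref><position><alt>`` notation (e.g. ``V42L``) into a SAV."""
    if len(text) < 3 or text[0] not in AMINO_ACID_SET or text[-1] not in AMINO_ACID_SET:
        raise VariantModelError(f"malformed SAV notation {text!r}")
    try:
        position = int(text[1:-1])
    except ValueError as exc:
        raise VariantModelError(f"malformed SAV notation {text!r}") from exc
    return SAV(protein_id, position, text[0], text[-1], **kwargs)


@dataclass(frozen=True)
class ScoredSAV:
    """A SAV with per-method raw effect scores.

    Score conventions: SNAP2 on [-100, 100] (negative = neutral, positive =
    effect); SIFT on [0, 1] (low = deleterious); CADD an unbounded raw
    score; PolyPhen-2 a category label or probability.
    """

    sav: SAV
    scores: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        snap2 = self.scores.get("SNAP2")
        if snap2 is not None and not -100.0 <= float(snap2) <= 100.0:
            raise VariantModelError(
                f"{self.sav.protein_id}:{self.sav.notation}: SNAP2 score "
                f"{snap2} outside [-100, 100]"
            )
        sift = self.scores.get("SIFT")
        if isinstance(sift, (int, float)) and not 0.0 <= sift <= 1.0:
            raise VariantModelError(
                f"{self.sav.protein_id}:{self.sav.notation}: SIFT score "
                f"{sift} outside [0, 1]"
            )

    def score(self, method: str):
        try:
            return self.scores[method]
        except KeyError:
            raise MissingScoreError(
                f"{self.sav.protein_id}:{self.sav.notation}: no {method} score"
            ) from None


class MissingScoreError(VariantModelError):
    """A required per-method score is absent on a SAV."""


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def unique_savs(savs: Iterable[SAV]) -> list[SAV]:
    """Collapse duplicate substitutions (same protein, position, ref, alt)
    to one record each, keeping the first occurrence; order preserved."""
    seen: set[tuple] = set()
    out: list[SAV] = []
    for sav in savs:
        if sav.key not in seen:
            seen.add(sav.key)
            out.append(sav)
    return out


def filter_protein_length(
    proteins: Iterable[ProteinRecord], max_len: int = MAX_PROTEIN_LENGTH
) -> tuple[list[ProteinRecord], int]:
    """Drop proteins longer than ``max_len`` residues (default 6000).

    Proteins of length exactly ``max_len`` are retained.  Returns the kept
    records and the number removed.
    """
    if max_len < 1:
        raise VariantModelError(f"max_len must be >= 1, got {max_len}")
    pool = list(proteins)
    kept = [p for p in pool if len(p) <= max_len]
    n_removed = len(pool) - len(kept)
    if n_removed:
        logger.info("length filter (> %d residues): %d proteins removed",
                    max_len, n_removed)
    return kept, n_removed


@dataclass
class MissenseFilterStats:
    """Tally of records seen / kept / dropped by the missense-SNV filter."""

    n_in: int = 0
    n_kept: int = 0
    n_no_csq: int = 0
    n_not_missense_snv: int = 0
    n_unparseable: int = 0


def _is_snv(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(ref) == 1
        and ref in "ACGT"
        and len(alts) >= 1
        and all(len(a) == 1 and a in "ACGT" for a in alts)
    )


def filter_missense_snv(
    records: Iterable,
    csq_fields: Sequence[str],
    csq_key: str = "CSQ",
    stats: Optional[MissenseFilterStats] = None,
) -> list[SAV]:
    """Keep exactly the variant records that are missense single-nucleotide
    substitutions, converted to SAVs in protein coordinates.

    ``records`` are cyvcf2 ``Variant`` objects (or any object exposing
    ``INFO``-mapping, ``REF`` and ``ALT``).  ``csq_fields`` names the
    '|'-separated fields of each CSQ block (taken from the VCF header);
    blocks are ','-separated and consequence terms within a block are
    '&'-separated.  Any block containing ``missense_variant`` qualifies.

    Records lacking the CSQ key are skipped with a logged warning and
    counted in ``stats.n_no_csq``.  Output order follows input order.
    """
    stats = stats if stats is not None else MissenseFilterStats()
    idx = {name: i for i, name in enumerate(csq_fields)}
    for required in ("Consequence", "Protein_position", "Amino_acids"):
        if required not in idx:
            raise VariantModelError(
                f"CSQ format lacks required field {required!r}: {list(csq_fields)}"
            )
    protein_field = next(
        (f for f in ("ENSP", "Protein", "Feature", "Gene") if f in idx), None
    )
    if protein_field is None:
        raise VariantModelError(
            "CSQ format lacks a protein identifier field (ENSP/Protein/Feature/Gene)"
        )

    out: list[SAV] = []
    for rec in records:
        stats.n_in += 1
        try:
            csq = rec.INFO.get(csq_key)
        except (AttributeError, KeyError):
            csq = None
        if csq is None:
            stats.n_no_csq += 1
            logger.warning("variant record without %s field skipped", csq_key)
            continue
        if not _is_snv(rec.REF, rec.ALT):
            stats.n_not_missense_snv += 1
            continue
        emitted = False
        for block in str(csq).split(","):
            parts = block.split("|")
            if len(parts) != len(csq_fields):
                continue
            terms = parts[idx["Consequence"]].split("&")
            if "missense_variant" not in terms:
                continue
            aa_change = parts[idx["Amino_acids"]]
            pos_text = parts[idx["Protein_position"]]
            pid = parts[idx[protein_field]]
            if "/" not in aa_change or not pid:
                stats.n_unparseable += 1
                continue
            ref_aa, alt_aa = aa_change.split("/", 1)
            try:
                sav = SAV(pid, int(pos_text), ref_aa, alt_aa)
            except (ValueError, VariantModelError):
                stats.n_unparseable += 1
                continue
            out.append(sav)
            emitted = True
            break  # one SAV per record: first missense block
        if emitted:
            stats.n_kept += 1
        else:
            stats.n_not_missense_snv += 1
    return out


def read_missense_savs(
    vcf_path: str | Path, csq_key: str = "CSQ",
    stats: Optional[MissenseFilterStats] = None,
) -> list[SAV]:
    """Read a VCF and return its missense-SNV records as SAVs.

    The CSQ block layout is parsed from the header line's
    ``Format: A|B|...`` description, VEP-style.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    desc = None
    for h in vcf.header_iter():
        info = h.info()
        if info.get("ID") == csq_key:
            desc = info.get("Description", "")
            break
    if desc is None:
        raise VariantModelError(f"VCF header does not define INFO key {csq_key!r}")
    if "Format:" not in desc:
        raise VariantModelError(f"{csq_key} header lacks a 'Format:' description")
    fields = desc.split("Format:", 1)[1].strip().strip('"').split("|")
    return filter_missense_snv(vcf, [f.strip() for f in fields], csq_key, stats)


# ---------------------------------------------------------------------------
# Plain-text IO
# ---------------------------------------------------------------------------

SAV_TABLE_COLUMNS = ["protein_id", "position", "ref_aa", "alt_aa", "ldaf", "set_label"]
SCORE_TABLE_COLUMNS = ["protein_id", "position", "ref_aa", "alt_aa", "method", "score"]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load protein records from FASTA (first whitespace-delimited token of
    the header is the identifier)."""
    return [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins
    ]
    handle = path if hasattr(path, "write") else str(path)
    SeqIO.write(records, handle, "fasta")


def read_sav_table(path: str | Path) -> list[SAV]:
    """Read the tab-separated SAV table ('.' marks a missing ldaf)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAV_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise VariantModelError(f"SAV table {path} lacks columns {missing}")
    savs = []
    for row in df.itertuples(index=False):
        ldaf = None if row.ldaf in (".", "") else float(row.ldaf)
        savs.append(
            SAV(row.protein_id, int(row.position), row.ref_aa, row.alt_aa,
                ldaf, row.set_label)
        )
    return savs


def write_sav_table(savs: Iterable[SAV], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": s.protein_id,
                "position": s.position,
                "ref_aa": s.ref_aa,
                "alt_aa": s.alt_aa,
                "ldaf": "." if s.ldaf is None else repr(s.ldaf),
                "set_label": s.set_label,
            }
            for s in savs
        ],
        columns=SAV_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> list[ScoredSAV]:
    """Read the long-form score table and collapse it to one ScoredSAV per
    substitution with a method -> score mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SCORE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise VariantModelError(f"score table {path} lacks columns {missing}")
    grouped: dict[tuple, dict[str, object]] = {}
    order: list[tuple] = []
    for row in df.itertuples(index=False):
        key = (row.protein_id, int(row.position), row.ref_aa, row.alt_aa)
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
        try:
            value: object = float(row.score)
        except ValueError:
            value = row.score  # categorical (PolyPhen-2 / SIFT labels)
        grouped[key][row.method] = value
    return [
        ScoredSAV(SAV(k[0], k[1], k[2], k[3]), grouped[k]) for k in order
    ]


def write_score_table(scored: Iterable[ScoredSAV], path: str | Path) -> None:
    rows = []
    for s in scored:
        for method, value in s.scores.items():
            rows.append(
                {
                    "protein_id": s.sav.protein_id,
                    "position": s.sav.position,
                    "ref_aa": s.sav.ref_aa,
                    "alt_aa": s.sav.alt_aa,
                    "method": method,
                    "score": value,
                }
            )
    pd.DataFrame(rows, columns=SCORE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_localization_labels(path: str | Path) -> dict[str, str]:
    """Read tab-separated (protein_id, category) localization labels."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"protein_id", "category"} <= set(df.columns):
        raise VariantModelError(f"localization table {path} needs protein_id, category")
    return dict(zip(df["protein_id"], df["category"]))
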