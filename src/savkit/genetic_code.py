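"""SNV reachability over amino acids and random SAV background generators.

Not every amino-acid substitution can arise from a single nucleotide change:
the genetic code connects residue pairs only where some pair of sense codons
differs at exactly one position.  This module derives that reachability
relation from a codon table and uses it to build the two random mutational
backgrounds used as null references for observed variation:

* ``all19`` — every position mutated to each of the 19 non-native residues;
* ``snv_possible`` — the subset of those substitutions reachable by one
  nucleotide change (codon-agnostic: existential over all codons of the
  reference residue).

Stop codons never participate in reachability.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional

import numpy as np

from .variant_model import AMINO_ACID_SET, SAV, ProteinRecord, VariantModelError

NUCLEOTIDES = "ACGT"


class GeneticCodeError(VariantModelError):
    """Malformed codon table."""


class InsufficientPoolError(VariantModelError):
    """Requested sample larger than the candidate pool."""


def load_codon_table(path: Optional[str | Path] = None) -> dict[str, str]:
    """Load a codon -> amino-acid table from a two-column TSV.

    Stop codons are marked ``*``.  Defaults to the packaged standard genetic
    code.  The table must cover all 64 codons, map exactly 61 to the 20
    standard amino acids, and mark 3 stops.
    """
    if path is None:
        source = resources.files("savkit").joinpath(
            "data/standard_genetic_code.tsv"
        )
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    for line in text.strip().splitlines()[1:]:
        codon, aa = line.split("\t")
        codon = codon.upper().replace("U", "T")
        if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
            raise GeneticCodeError(f"malformed codon {codon!r}")
        if aa != "*" and aa not in AMINO_ACID_SET:
            raise GeneticCodeError(f"codon {codon} maps to invalid residue {aa!r}")
        table[codon] = aa
    if len(table) != 64:
        raise GeneticCodeError(f"codon table has {len(table)} codons, expected 64")
    n_stop = sum(1 for aa in table.values() if aa == "*")
    if n_stop != 3:
        raise GeneticCodeError(f"codon table has {n_stop} stop codons, expected 3")
    if set(table.values()) - {"*"} != AMINO_ACID_SET:
        raise GeneticCodeError("codon table does not cover the 20 amino acids")
    return table


def _single_nucleotide_neighbors(codon: str) -> Iterable[str]:
    for i in range(3):
        for b in NUCLEOTIDES:
            if b != codon[i]:
                yield codon[:i] + b + codon[i + 1 :]


@dataclass(frozen=True)
class SubstitutionReachability:
    """Symmetric, irreflexive relation over ordered amino-acid pairs:
    ``(a, b)`` is reachable iff some sense codon of ``a`` differs from some
    sense codon of ``b`` at exactly one nucleotide."""

    pairs: frozenset[tuple[str, str]]

    def reachable(self, a: str, b: str) -> bool:
        return (a, b) in self.pairs

    def neighbors(self, a: str) -> frozenset[str]:
        """Residues reachable from ``a`` by one nucleotide change."""
        return frozenset(y for x, y in self.pairs if x == a)


def build_snv_reachability(
    codon_table: Optional[Mapping[str, str]] = None,
) -> SubstitutionReachability:
    """Derive the SNV-reachability relation from a codon table.

    Reachability is codon-agnostic: ``(a, b)`` holds when *any* sense codon
    of ``a`` has a single-nucleotide neighbour encoding ``b``.
    """
    if codon_table is None:
        codon_table = load_codon_table()
    sense = {c: aa for c, aa in codon_table.items() if aa != "*"}
    if len(sense) != 61:
        raise GeneticCodeError(f"{len(sense)} sense codons, expected 61")
    pairs: set[tuple[str, str]] = set()
    for codon, aa in sense.items():
        for nb in _single_nucleotide_neighbors(codon):
            other = sense.get(nb)  # stop neighbours drop out here
            if other is not None and other != aa:
                pairs.add((aa, other))
    return SubstitutionReachability(frozenset(pairs))


Mode = Literal["all19", "snv_possible"]


def enumerate_candidate_savs(
    protein: ProteinRecord,
    mode: Mode,
    reach: Optional[SubstitutionReachability] = None,
) -> list[SAV]:
    """Enumerate candidate SAVs over all unmasked positions of a protein.

    ``all19`` yields the 19 non-native substitutions at every position;
    ``snv_possible`` restricts to substitutions reachable by one nucleotide
    change.  Output order is deterministic: position-major, alphabetical
    alternate residue.
    """
    if mode not in ("all19", "snv_possible"):
        raise VariantModelError(f"unknown enumeration mode {mode!r}")
    if mode == "snv_possible" and reach is None:
        reach = build_snv_reachability()
    masked = protein.masked_positions
    out: list[SAV] = []
    for pos, ref in enumerate(protein.sequence, start=1):
        if pos in masked:
            continue
        for alt in sorted(AMINO_ACID_SET):
            if alt == ref:
                continue
            if mode == "snv_possible" and not reach.reachable(ref, alt):
                continue
            out.append(SAV(protein.id, pos, ref, alt, set_label=mode))
    return out


def sample_random_savs(
    proteins: Iterable[ProteinRecord],
    mode: Mode,
    n: int,
    seed: int,
    reach: Optional[SubstitutionReachability] = None,
) -> list[SAV]:
    """Draw ``n`` distinct SAVs uniformly without replacement from the
    pooled candidate supersets of all proteins.

    Long proteins contribute proportionally more candidates.  Identical
    (proteins, mode, n, seed) reproduce the identical set.
    """
    if n < 0:
        raise VariantModelError(f"sample size must be >= 0, got {n}")
    if mode == "snv_possible" and reach is None:
        reach = build_snv_reachability()
    pool: list[SAV] = []
    for protein in proteins:
        pool.extend(enumerate_candidate_savs(protein, mode, reach))
    if n > len(pool):
        raise InsufficientPoolError(
            f"requested {n} SAVs from a candidate pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    chosen = sorted(idx.tolist())
    return [pool[i] for i in chosen]
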