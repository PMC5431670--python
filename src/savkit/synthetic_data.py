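"""Synthetic proteomes, variant sets, scores and ortholog pairs with known
ground truth.

Real inputs to this kind of analysis — exome-consortium variant calls and
proprietary predictor scores over them — are huge and external.  The
generators here emulate their statistical structure at desk scale so that
every pipeline stage is testable end to end:

* a proteome of uniform-random amino-acid sequences;
* variant sets with class-specific allele-frequency ranges whose
  composition mirrors the exome data (rare dominates: by default the
  printed rare/uncommon/common counts scaled by 1e-3);
* class-conditional effect scores on [-100, 100] as a two-component
  effect/neutral Gaussian mixture with configurable effect fraction —
  widely separated components (means -+50, sd 15) so the component weight
  is, to ~1e-3, the score mass above 0 (the effect AUC);
* diverged ortholog sequences: per-position substitutions at a configurable
  rate, no indels, so alignment recovers exactly the substituted positions.

Every generator is a pure function of (config, seed); sub-seeds are derived
per protein / per set by stable CRC-32 hashing of identifiers so that adding
records does not reshuffle existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .genetic_code import InsufficientPoolError
from .variant_model import (
    AMINO_ACIDS,
    FrequencyClass,
    SAV,
    ProteinRecord,
    ScoredSAV,
    VariantModelError,
)


class SyntheticConfigError(VariantModelError):
    pass


def _sub_rng(seed: int, *tags: str) -> np.random.Generator:
    """Deterministic per-entity generator: seed combined with stable
    CRC-32 hashes of the tags."""
    keys = [seed] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass(frozen=True)
class MixtureParams:
    """Two-component effect/neutral score mixture on the [-100, 100] scale.

    ``effect_fraction`` is the probability a SAV belongs to the effect
    component; scores are normal with the component mean and the shared sd,
    truncated to [-100, 100] by resampling (no boundary atoms).
    """

    effect_fraction: float
    neutral_mean: float = -50.0
    effect_mean: float = 50.0
    sd: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise SyntheticConfigError(
                f"effect_fraction {self.effect_fraction} outside [0, 1]"
            )
        for mean in (self.neutral_mean, self.effect_mean):
            if not -100.0 <= mean <= 100.0:
                raise SyntheticConfigError(f"mean {mean} outside [-100, 100]")
        if self.sd <= 0:
            raise SyntheticConfigError(f"sd must be positive, got {self.sd}")


#: Allele-frequency sampling ranges per class; each range stays strictly
#: inside its class boundaries so classification always round-trips.
DEFAULT_LDAF_RANGES: dict[FrequencyClass, tuple[float, float]] = {
    FrequencyClass.RARE: (1e-4, 0.0099),
    FrequencyClass.UNCOMMON: (0.01, 0.0499),
    FrequencyClass.COMMON: (0.05, 0.5),
}

#: Class composition of the default synthetic exome set: the printed
#: rare/uncommon/common counts (7,530,337 / 28,789 / 40,446) scaled by 1e-3,
#: preserving rare dominance at desk scale.
DEFAULT_CLASS_COUNTS: dict[FrequencyClass, int] = {
    FrequencyClass.RARE: 7530,
    FrequencyClass.UNCOMMON: 29,
    FrequencyClass.COMMON: 40,
}

#: Effect mass per class: common SAVs carry more effect mass (0.61) than
#: rare (0.48) — the headline contrast the pipeline is built to detect;
#: uncommon sits between.
DEFAULT_SCORE_MIXTURES: dict[str, MixtureParams] = {
    "common": MixtureParams(effect_fraction=0.61),
    "uncommon": MixtureParams(effect_fraction=0.55),
    "rare": MixtureParams(effect_fraction=0.48),
}

#: Per-residue substitution probabilities for synthetic ortholog pairs,
#: ordered by evolutionary distance; all stay above the 70% identity filter.
DEFAULT_DIVERGENCE_RATES: dict[str, float] = {
    "denisovan": 0.001,
    "chimp": 0.01,
    "mouse": 0.10,
    "fly": 0.25,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark."""

    n_proteins: int = 60
    length_range: tuple[int, int] = (100, 400)
    class_counts: Mapping[FrequencyClass, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    ldaf_ranges: Mapping[FrequencyClass, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LDAF_RANGES)
    )
    score_mixtures: Mapping[str, MixtureParams] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_MIXTURES)
    )
    divergence_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVERGENCE_RATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SyntheticConfigError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise SyntheticConfigError(f"invalid length_range {self.length_range}")
        from .variant_model import classify_frequency

        for cls, (low, high) in self.ldaf_ranges.items():
            if not (classify_frequency(low) == cls == classify_frequency(high)):
                raise SyntheticConfigError(
                    f"ldaf range {low}..{high} leaves class {cls}"
                )


def generate_proteome(config: SyntheticConfig) -> list[ProteinRecord]:
    """Uniform-random proteome: ``n_proteins`` sequences over the 20-letter
    alphabet with lengths uniform on ``length_range``."""
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    proteins = []
    for i in range(config.n_proteins):
        pid = f"SYNP{i + 1:05d}"
        rng = _sub_rng(config.seed, "proteome", pid)
        lo, hi = config.length_range
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(alphabet, size=length)
        proteins.append(ProteinRecord(pid, b"".join(seq).decode()))
    return proteins


def generate_variant_sets(
    proteome: Sequence[ProteinRecord], config: SyntheticConfig
) -> dict[FrequencyClass, list[SAV]]:
    """Sample SAVs without replacement across (protein, position, alt)
    triples, one set per frequency class, with LDAFs uniform on the class
    range (classification always recovers the assigned class)."""
    triples: list[tuple[str, int, str]] = []
    residues: dict[tuple[str, int], str] = {}
    for protein in proteome:
        masked = protein.masked_positions
        for pos, ref in enumerate(protein.sequence, start=1):
            if pos in masked:
                continue
            residues[(protein.id, pos)] = ref
            triples.append((protein.id, pos, ref))
    n_total = sum(config.class_counts.values())
    capacity = len(triples) * 19
    if n_total > capacity:
        raise InsufficientPoolError(
            f"requested {n_total} SAVs but the proteome supports {capacity}"
        )
    rng = _sub_rng(config.seed, "variants")
    # sample flat indices into the (position, alt) product space
    flat = rng.choice(capacity, size=n_total, replace=False)
    order = sorted(AMINO_ACIDS)
    out: dict[FrequencyClass, list[SAV]] = {}
    cursor = 0
    for cls, count in config.class_counts.items():
        low, high = config.ldaf_ranges[cls]
        savs = []
        for flat_idx in flat[cursor : cursor + count]:
            t_idx, a_idx = divmod(int(flat_idx), 19)
            pid, pos, ref = triples[t_idx]
            alts = [a for a in order if a != ref]
            ldaf = float(rng.uniform(low, high))
            savs.append(SAV(pid, pos, ref, alts[a_idx], ldaf, cls.value))
        out[cls] = savs
        cursor += count
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int,
    low: float = -100.0, high: float = 100.0,
) -> np.ndarray:
    """Normal draws truncated to [low, high] by resampling (rejection), so
    the boundaries carry no atoms."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def generate_scores(
    savs: Sequence[SAV],
    mixture: MixtureParams,
    seed: int,
    method: str = "SNAP2",
) -> tuple[list[ScoredSAV], list[str]]:
    """Attach mixture scores to SAVs; returns the scored SAVs and the
    parallel ground-truth component labels ("effect" / "neutral")."""
    rng = _sub_rng(seed, "scores", method)
    n = len(savs)
    is_effect = rng.random(n) < mixture.effect_fraction
    scores = np.where(
        is_effect,
        _truncated_normal(rng, mixture.effect_mean, mixture.sd, n),
        _truncated_normal(rng, mixture.neutral_mean, mixture.sd, n),
    )
    scored = [
        ScoredSAV(sav, {method: float(s)}) for sav, s in zip(savs, scores)
    ]
    labels = ["effect" if e else "neutral" for e in is_effect]
    return scored, labels


def generate_correlated_scores(
    scored: Sequence[ScoredSAV],
    method: str,
    rho: float,
    seed: int,
    base_method: str = "SNAP2",
) -> list[ScoredSAV]:
    """Add a second method's scores correlated (population rho) with an
    existing method's, for exercising the correlation machinery."""
    if not -1.0 < rho < 1.0:
        raise SyntheticConfigError(f"rho {rho} outside (-1, 1)")
    rng = _sub_rng(seed, "corr", method)
    base = np.array([float(s.score(base_method)) for s in scored])
    z = (base - base.mean()) / (base.std() or 1.0)
    noise = rng.normal(size=base.size)
    new = rho * z + np.sqrt(1.0 - rho * rho) * noise
    return [
        ScoredSAV(s.sav, {**s.scores, method: float(v)})
        for s, v in zip(scored, new)
    ]


def generate_ortholog_pair(
    protein: ProteinRecord, rate: float, seed: int, ortholog_id: Optional[str] = None
) -> ProteinRecord:
    """Diverged copy of a protein: each position independently substituted
    with probability ``rate`` to a uniformly chosen different residue; no
    indels."""
    if not 0.0 <= rate < 1.0:
        raise SyntheticConfigError(f"substitution rate {rate} outside [0, 1)")
    rng = _sub_rng(seed, "ortholog", protein.id)
    seq = list(protein.sequence)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        ref = seq[i]
        others = [a for a in AMINO_ACIDS if a != ref]
        seq[i] = others[int(rng.integers(len(others)))]
    return ProteinRecord(ortholog_id or f"{protein.id}_ortho", "".join(seq))


def generate_labeled_reference(
    n_effect: int,
    n_neutral: int,
    mixture: MixtureParams,
    seed: int,
) -> list[tuple[float, str]]:
    """Labelled score list for accuracy curves: ``n_effect`` draws from the
    effect component and ``n_neutral`` from the neutral component."""
    if n_effect < 1 or n_neutral < 1:
        raise SyntheticConfigError(
            "need at least one score of each label "
            f"(got effect={n_effect}, neutral={n_neutral})"
        )
    rng = _sub_rng(seed, "reference")
    eff = _truncated_normal(rng, mixture.effect_mean, mixture.sd, n_effect)
    neu = _truncated_normal(rng, mixture.neutral_mean, mixture.sd, n_neutral)
    return [(float(s), "effect") for s in eff] + [
        (float(s), "neutral") for s in neu
    ]
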