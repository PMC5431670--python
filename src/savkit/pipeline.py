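"""Orchestration: wire the stages into the three headline comparisons.

``run_comparison`` executes load/simulate -> classify -> curves/statistics
-> enrichment and writes a machine-readable JSON report plus tab-separated
tables.  The three comparisons it is built around:

1. within-human frequency classes (rare vs uncommon vs common);
2. cross-species SAVs vs within-human SAVs (more neutral with distance);
3. observed variation vs random mutational backgrounds (all19 /
   snv_possible).

Every number in the report is recomputable from the persisted per-set score
tables; ``verify_report`` re-derives them and checks agreement to 1e-9.
The report carries a provenance block (config hash, seed, package versions)
and a filter-count log such that records_in = records_out + per-reason
drops for every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import EnrichmentFilterSpec, filter_enriched_proteins, localization_fold
from .genetic_code import build_snv_reachability, sample_random_savs
from .ortholog_alignment import AlignmentParams, extract_cross_species_savs
from .score_statistics import (
    DEFAULT_FNR,
    DEFAULT_FPR,
    METHOD_DEFAULTS,
    MethodConfig,
    classify_binary,
    cumulative_effect_curve,
    error_correct_fractions,
    grouped_distribution_summary,
    normalize_for_correlation,
    pearson_with_se,
)
from .synthetic_data import (
    MixtureParams,
    SyntheticConfig,
    _sub_rng,
    generate_correlated_scores,
    generate_ortholog_pair,
    generate_proteome,
    generate_scores,
    generate_variant_sets,
)
from .variant_model import (
    FrequencyClass,
    ProteinRecord,
    ScoredSAV,
    VariantModelError,
    filter_protein_length,
    read_fasta,
    read_localization_labels,
    read_score_table,
    write_sav_table,
    write_score_table,
)

logger = logging.getLogger("savkit")

#: Mixture effect fractions for the synthetic set labels beyond the
#: frequency classes: random backgrounds sit near rare (snv_possible 0.50,
#: the unconstrained all19 slightly higher), cross-species sets are more
#: neutral the larger the evolutionary distance.
EXTRA_SET_MIXTURES: dict[str, MixtureParams] = {
    "random_snv_possible": MixtureParams(effect_fraction=0.50),
    "random_all19": MixtureParams(effect_fraction=0.53),
    "denisovan": MixtureParams(effect_fraction=0.40),
    "chimp": MixtureParams(effect_fraction=0.35),
    "mouse": MixtureParams(effect_fraction=0.30),
    "fly": MixtureParams(effect_fraction=0.25),
}

#: Background localization composition for the synthetic proteome
#: (category -> probability): roughly the published proteome-wide split.
SYNTHETIC_LOCALIZATION = {"nuclear": 0.28, "secreted+membrane": 0.23, "other": 0.49}


class PipelineError(VariantModelError):
    pass


@dataclass
class AnalysisReport:
    """All computed outputs of one comparison run."""

    sets: dict[str, dict[str, Any]] = field(default_factory=dict)
    ks: list[dict[str, Any]] = field(default_factory=list)
    correlations: dict[str, dict[str, Any]] = field(default_factory=dict)
    enrichment: dict[str, Any] = field(default_factory=dict)
    filters: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "sets": self.sets,
            "ks": self.ks,
            "correlations": self.correlations,
            "enrichment": self.enrichment,
            "filters": self.filters,
            "provenance": self.provenance,
        }


def _load_config(config: str | Path | Mapping[str, Any]) -> tuple[dict, str]:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        return yaml.safe_load(text) or {}, hashlib.sha256(text.encode()).hexdigest()
    canonical = json.dumps(config, sort_keys=True, default=str)
    return dict(config), hashlib.sha256(canonical.encode()).hexdigest()


def _synthetic_sets(
    cfg: dict, seed: int, filters: dict
) -> tuple[dict[str, list[ScoredSAV]], dict[str, list[str]], list[ProteinRecord]]:
    """Build the labelled score sets of the three comparisons from the
    synthetic generators."""
    syn_cfg = dict(cfg)
    mixtures = {
        label: MixtureParams(**params) if isinstance(params, dict) else params
        for label, params in (syn_cfg.pop("score_mixtures", {}) or {}).items()
    }
    random_n = int(syn_cfg.pop("random_n", 500))
    class_counts = syn_cfg.pop("class_counts", None)
    if class_counts is not None:
        syn_cfg["class_counts"] = {
            FrequencyClass(k): int(v) for k, v in class_counts.items()
        }
    if "length_range" in syn_cfg:
        syn_cfg["length_range"] = tuple(syn_cfg["length_range"])
    if "divergence_rates" in syn_cfg:
        syn_cfg["divergence_rates"] = dict(syn_cfg["divergence_rates"])
    config = SyntheticConfig(seed=seed, **syn_cfg)

    proteome = generate_proteome(config)
    proteome, n_long = filter_protein_length(proteome)
    filters["proteome"] = {
        "records_in": config.n_proteins,
        "records_out": len(proteome),
        "dropped_by_length": n_long,
    }

    all_mixtures: dict[str, MixtureParams] = {}
    all_mixtures.update(config.score_mixtures)
    all_mixtures.update(EXTRA_SET_MIXTURES)
    all_mixtures.update(mixtures)

    sets: dict[str, list[ScoredSAV]] = {}
    labels: dict[str, list[str]] = {}

    def score_set(label: str, savs) -> None:
        mixture = all_mixtures.get(label)
        if mixture is None:
            raise PipelineError(f"no score mixture configured for set {label!r}")
        scored, truth = generate_scores(savs, mixture, seed)
        sets[label] = scored
        labels[label] = truth

    # 1. within-human frequency classes
    variant_sets = generate_variant_sets(proteome, config)
    for cls, savs in variant_sets.items():
        score_set(cls.value, savs)

    # 2. random mutational backgrounds
    reach = build_snv_reachability()
    for label, mode in (("random_snv_possible", "snv_possible"),
                        ("random_all19", "all19")):
        savs = sample_random_savs(proteome, mode, random_n, seed, reach)
        score_set(label, savs)

    # 3. cross-species sets (back-mutated ortholog differences)
    params = AlignmentParams()
    n_pairs_rejected = 0
    for species, rate in config.divergence_rates.items():
        xs_savs = []
        for protein in proteome:
            ortholog = generate_ortholog_pair(protein, rate, seed)
            try:
                ctx = extract_cross_species_savs(
                    protein, ortholog, params, set_label=species
                )
            except VariantModelError:
                n_pairs_rejected += 1
                continue
            xs_savs.extend(c.sav for c in ctx)
        score_set(species, xs_savs)
    filters["ortholog_pairs"] = {
        "records_in": len(proteome) * len(config.divergence_rates),
        "records_out": len(proteome) * len(config.divergence_rates)
        - n_pairs_rejected,
        "dropped_by_pide": n_pairs_rejected,
    }
    return sets, labels, proteome


def _loaded_sets(cfg: dict, filters: dict) -> tuple[dict[str, list[ScoredSAV]], list[ProteinRecord]]:
    proteins: list[ProteinRecord] = []
    if cfg.get("fasta"):
        proteins = read_fasta(cfg["fasta"])
        proteins, n_long = filter_protein_length(
            proteins, int(cfg.get("max_protein_length", 6000))
        )
        filters["proteome"] = {
            "records_in": len(proteins) + n_long,
            "records_out": len(proteins),
            "dropped_by_length": n_long,
        }
    sets = {
        label: read_score_table(path)
        for label, path in (cfg.get("score_tables") or {}).items()
    }
    if not sets:
        raise PipelineError("config names neither a synthetic block nor score_tables")
    return sets, proteins


def run_comparison(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path,
    seed: Optional[int] = None,
) -> AnalysisReport:
    """Execute the full comparison described by a config (YAML path or
    mapping) and write report.json plus per-set tables under ``out_dir``."""
    cfg, cfg_hash = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    n_boot = int(cfg.get("n_boot", 100))
    method = cfg.get("method", "SNAP2")

    report = AnalysisReport()
    filters: dict[str, Any] = {}

    proteome: list[ProteinRecord] = []
    if "synthetic" in cfg:
        sets, truth_labels, proteome = _synthetic_sets(
            cfg["synthetic"] or {}, seed, filters
        )
    else:
        sets, proteome = _loaded_sets(cfg.get("inputs", {}), filters)
        truth_labels = {}

    # optional correlated second method on the frequency-class sets
    corr_cfg = cfg.get("correlated_method")
    if corr_cfg:
        name = corr_cfg.get("name", "CADD-like")
        rho = float(corr_cfg.get("rho", 0.6))
        for label in list(sets):
            if label in ("rare", "uncommon", "common"):
                sets[label] = generate_correlated_scores(
                    sets[label], name, rho, seed
                )

    # ----- statistics ------------------------------------------------------
    scores_by_set = {
        label: np.array([float(s.score(method)) for s in scored])
        for label, scored in sets.items()
        if scored
    }
    empty = sorted(set(sets) - set(scores_by_set))
    if empty:
        logger.warning("empty sets skipped: %s", empty)
    summaries, pairwise = grouped_distribution_summary(
        scores_by_set, n_boot=n_boot, seed=seed
    )

    fpr = float(cfg.get("fpr", DEFAULT_FPR))
    fnr = float(cfg.get("fnr", DEFAULT_FNR))
    method_cfg = METHOD_DEFAULTS.get(method, MethodConfig(method, threshold=0.0))

    curves = {}
    for label, arr in scores_by_set.items():
        curve = cumulative_effect_curve(arr, n_boot=n_boot, seed=seed)
        curves[label] = curve
        n_effect = sum(
            1 for s in sets[label] if classify_binary(s, method_cfg) == "effect"
        )
        neff_raw = n_effect / len(sets[label])
        corrected = error_correct_fractions(neff_raw, 1.0 - neff_raw, fpr, fnr)
        band_low, band_high = curve.band_curves()
        curve_file = f"curve_{label}.tsv"
        pd.DataFrame(
            {
                "threshold": curve.thresholds,
                "fraction": curve.fraction,
                "sem_low": band_low,
                "sem_high": band_high,
            }
        ).to_csv(out / curve_file, sep="\t", index=False)
        table_file = f"scores_{label}.tsv"
        write_score_table(sets[label], out / table_file)
        write_sav_table((s.sav for s in sets[label]), out / f"savs_{label}.tsv")
        summary = summaries[label]
        report.sets[label] = {
            "n": summary.n,
            "mean": summary.mean,
            "sem": curve.sem,
            "effect_auc": summary.effect_auc,
            "neff_raw": corrected.neff_raw,
            "nneu_raw": corrected.nneu_raw,
            "neff_star": corrected.neff_star,
            "nneu_star": corrected.nneu_star,
            "curve_file": curve_file,
            "score_table": table_file,
            "bootstrap": {"n_boot": n_boot, "seed": seed},
        }
        if label in truth_labels:
            report.sets[label]["true_effect_fraction"] = (
                truth_labels[label].count("effect") / len(truth_labels[label])
                if truth_labels[label] else None
            )

    for (a, b), ks in sorted(pairwise.items()):
        entry = {
            "a": a, "b": b, "D": ks.D, "p": ks.p, "p_text": ks.p_text,
            "n": ks.n, "n_prime": ks.n_prime,
        }
        # stochastic-dominance flag on the effect side of the grid
        fa, fb = curves[a].fraction, curves[b].fraction
        mask = (curves[a].thresholds > 0) & (fa > 0) & (fb > 0)
        if mask.any():
            entry["a_above_b_on_effect_side"] = bool(np.all(fa[mask] >= fb[mask]))
        report.ks.append(entry)

    # pairwise method correlations within each set carrying >= 2 methods
    for label, scored in sets.items():
        if not scored:
            continue
        methods = sorted({m for s in scored for m in s.scores})
        if len(methods) < 2:
            continue
        entry = {}
        for i, ma in enumerate(methods):
            for mb in methods[i + 1:]:
                cfg_a = METHOD_DEFAULTS.get(ma, MethodConfig(ma, threshold=0.0))
                cfg_b = METHOD_DEFAULTS.get(mb, MethodConfig(mb, threshold=0.0))
                xs, ys = [], []
                for s in scored:
                    if ma in s.scores and mb in s.scores:
                        xs.append(normalize_for_correlation(s, cfg_a))
                        ys.append(normalize_for_correlation(s, cfg_b))
                try:
                    res = pearson_with_se(xs, ys)
                except VariantModelError:
                    continue
                entry[f"{ma}|{mb}"] = {"r": res.r, "se_r": res.se_r, "n": res.n}
        if entry:
            report.correlations[label] = entry

    # ----- enrichment ------------------------------------------------------
    enr_cfg = cfg.get("enrichment", {}) or {}
    if enr_cfg.get("enabled", True) and any(
        label in sets for label in ("common", "rare")
    ):
        spec_common = EnrichmentFilterSpec(
            frequency_class="any",
            min_count=int(enr_cfg.get("min_count", 2)),
            score_threshold=float(enr_cfg.get("score_threshold", 50.0)),
            min_fraction=float(enr_cfg.get("min_fraction", 0.5)),
            fraction_strict=bool(enr_cfg.get("fraction_strict", True)),
            method=method,
        )
        spec_rare = EnrichmentFilterSpec(
            frequency_class="any",
            min_count=spec_common.min_count,
            score_threshold=spec_common.score_threshold,
            min_fraction=spec_common.min_fraction,
            fraction_strict=False,
            method=method,
        )
        enriched: dict[str, list[str]] = {}
        if "common" in sets and sets["common"]:
            enriched["common"] = filter_enriched_proteins(sets["common"], spec_common)
        if "rare" in sets and sets["rare"]:
            enriched["rare"] = filter_enriched_proteins(sets["rare"], spec_rare)
        report.enrichment["enriched_proteins"] = {
            k: {"n": len(v), "ids": v} for k, v in enriched.items()
        }

        # localization folds against all SAV-bearing proteins
        loc_labels: Optional[dict[str, str]] = None
        if cfg.get("localization"):
            loc_labels = read_localization_labels(cfg["localization"])
        elif proteome and "synthetic" in cfg:
            rng = _sub_rng(seed, "localization")
            cats = list(SYNTHETIC_LOCALIZATION)
            probs = list(SYNTHETIC_LOCALIZATION.values())
            loc_labels = {
                p.id: cats[int(rng.choice(len(cats), p=probs))] for p in proteome
            }
        if loc_labels:
            background = sorted(
                {
                    s.sav.protein_id
                    for scored in sets.values()
                    for s in scored
                    if s.sav.protein_id in loc_labels
                }
            )
            folds = {}
            for label, ids in enriched.items():
                ids = [p for p in ids if p in loc_labels]
                folds[label] = [
                    asdict(e)
                    for e in localization_fold(loc_labels, ids, background)
                ]
            report.enrichment["localization"] = folds
            pd.DataFrame(
                [
                    {"subset": label, **row}
                    for label, rows in folds.items()
                    for row in rows
                ]
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # ----- provenance and output ------------------------------------------
    import Bio
    import scipy

    report.filters = filters
    report.provenance = {
        "config_sha256": cfg_hash,
        "seed": seed,
        "n_boot": n_boot,
        "method": method,
        "versions": {
            "savkit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "biopython": Bio.__version__,
        },
    }
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return report


def verify_report(out_dir: str | Path, tol: float = 1e-9) -> bool:
    """Recompute every per-set statistic from the persisted score tables
    and check agreement with report.json within ``tol``.

    Raises :class:`PipelineError` on any discrepancy; True otherwise.
    """
    from .score_statistics import bootstrap_sem, effect_auc, ks_two_sample

    out = Path(out_dir)
    report = json.loads((out / "report.json").read_text())
    method = report["provenance"]["method"]
    arrays: dict[str, np.ndarray] = {}
    for label, entry in report["sets"].items():
        scored = read_score_table(out / entry["score_table"])
        arr = np.array([float(s.score(method)) for s in scored])
        arrays[label] = arr
        boot = entry["bootstrap"]
        recomputed = {
            "n": len(arr),
            "mean": float(arr.mean()),
            "effect_auc": effect_auc(arr),
            "sem": bootstrap_sem(arr, boot["n_boot"], boot["seed"])
            if boot["n_boot"] else 0.0,
        }
        for key, value in recomputed.items():
            if abs(value - entry[key]) > tol:
                raise PipelineError(
                    f"set {label!r}: {key} mismatch "
                    f"(report {entry[key]}, recomputed {value})"
                )
    for entry in report["ks"]:
        ks = ks_two_sample(arrays[entry["a"]], arrays[entry["b"]])
        if abs(ks.D - entry["D"]) > tol:
            raise PipelineError(
                f"KS {entry['a']} vs {entry['b']}: D mismatch "
                f"(report {entry['D']}, recomputed {ks.D})"
            )
    return True
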