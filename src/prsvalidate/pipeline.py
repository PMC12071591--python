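"""End-to-end orchestration: simulate|ingest -> qc -> score -> pca -> assoc -> concord.

One YAML/dict config drives the whole analysis.  The stage order is fixed
— exclusions happen before any statistics, so association models never see
pruned samples — and every run emits a JSON manifest (config hash, seeds,
input digests, per-stage row counts, output paths) that makes reruns
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association_stats import (
    auc_cv,
    auc_holdout,
    bonferroni,
    make_bins,
    or_per_sd,
    staircase,
    two_by_two_or,
)
from .cohort_qc import (
    HIGH_PENETRANCE_GENES,
    assign_ancestry_groups,
    build_ledger,
    exclude_carriers,
    prune_related,
)
from .concordance import compare_scores
from .covariates_pca import compute_pcs, zscore_pcs
from .formats_io import GenotypeMatrix, read_bed, read_genotypes, read_scoring_file, read_tables
from .score_engine import compute_scores, filter_scoring_variants, match_alleles
from .synthetic_data import SimulationConfig, add_imputation_noise, simulate_cohort


class ConfigError(ValueError):
    pass


_SCHEMA = {
    "seed": None,
    "out_dir": None,
    "simulate": {f.name for f in dc_fields(SimulationConfig)} | {"write_vcf"},
    "inputs": {"scoring_file", "vcf", "metadata", "kinship", "ancestry",
               "targets_bed", "prefer_dosage", "scoring_dialect"},
    "qc": {"carrier_genes", "remove_missing_inputs", "remove_low_quality"},
    "score": {"max_distance_bp", "maf_min", "exclude_ids", "allow_ambiguous"},
    "pca": {"k", "maf_min"},
    "assoc": {"bins", "boundary_source", "test_fraction", "folds", "bonferroni_m"},
    "concord": {"enabled"},
}


def validate_config(config: dict) -> dict:
    """Schema check: unknown keys are rejected by name."""
    for key, val in config.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config key {key!r}")
        allowed = _SCHEMA[key]
        if allowed is not None and isinstance(val, dict):
            for sub in val:
                if sub not in allowed:
                    raise ConfigError(f"unknown config key {key}.{sub!r}")
    if "seed" not in config:
        raise ConfigError("config requires a seed")
    if ("simulate" in config) == ("inputs" in config):
        raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
    return config


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def record(self, event: str) -> None:
        self.log.append(event)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash, "seed": self.seed,
            "version": self.version, "input_digests": self.input_digests,
            "stage_counts": self.stage_counts, "outputs": self.outputs,
            "log": self.log,
        }


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: dict, write_outputs: bool = True) -> tuple[RunManifest, dict]:
    """Execute the full analysis; returns (manifest, results).

    ``results`` holds the in-memory objects: scores, ledger, groups, pcs,
    association tables and the optional concordance report.
    """
    config = validate_config(config)
    seed = int(config["seed"])
    out_dir = Path(config.get("out_dir", "prsvalidate_run"))
    manifest = RunManifest(config_hash=_config_hash(config), seed=seed,
                           version=__version__)
    results: dict = {}

    # ---- input / simulate ------------------------------------------------
    stage = "input"
    try:
        targets = None
        cohort = None
        if "simulate" in config:
            sim_kwargs = {k: v for k, v in (config["simulate"] or {}).items()
                          if k != "write_vcf"}
            if "carrier_spec" in sim_kwargs:
                sim_kwargs["carrier_spec"] = {
                    g: tuple(v) for g, v in sim_kwargs["carrier_spec"].items()}
            sim_cfg = SimulationConfig(**sim_kwargs)
            cohort = simulate_cohort(sim_cfg, seed=seed)
            scoring = cohort.scoring
            genotypes = cohort.genotypes
            metadata_df = cohort.metadata
            records, pairs = _records_from_frames(cohort.metadata, cohort.kinship,
                                                  cohort.ancestry)
            manifest.record(f"simulated cohort: {genotypes.n_samples} samples, "
                            f"{genotypes.n_sites} variants, seed {seed}")
            if config["simulate"].get("write_vcf") and write_outputs:
                paths = cohort.write(out_dir / "simulated")
                manifest.outputs.update({f"simulated_{k}": v for k, v in paths.items()})
        else:
            inp = config["inputs"]
            scoring = read_scoring_file(inp["scoring_file"],
                                        dialect=inp.get("scoring_dialect", "pgs_catalog"))
            genotypes = read_genotypes(inp["vcf"], scoring,
                                       prefer_dosage=bool(inp.get("prefer_dosage", False)))
            records, pairs = read_tables(inp["metadata"], inp.get("kinship"),
                                         inp.get("ancestry"))
            metadata_df = pd.read_csv(inp["metadata"], sep="\t",
                                      dtype={"sample_id": str})
            if inp.get("targets_bed"):
                targets = read_bed(inp["targets_bed"])
            for key in ("scoring_file", "vcf", "metadata", "kinship", "ancestry",
                        "targets_bed"):
                if inp.get(key):
                    manifest.input_digests[key] = _digest(inp[key])
        manifest.stage_counts["input_samples"] = len(records)
        manifest.stage_counts["input_scoring_variants"] = len(scoring)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- qc --------------------------------------------------------------
    stage = "qc"
    try:
        qc_cfg = config.get("qc", {}) or {}
        genes = frozenset(qc_cfg.get("carrier_genes", HIGH_PENETRANCE_GENES))
        all_ids = [r.sample_id for r in records]
        kept_ids, removed_rel = prune_related(all_ids, pairs, seed=seed)
        manifest.record(f"relatedness pruning removed {len(removed_rel)} samples "
                        f"(seed {seed})")
        rec_by_id = {r.sample_id: r for r in records}
        removed_missing = [s for s in qc_cfg.get("remove_missing_inputs", [])
                           if s in set(kept_ids)]
        removed_lowq = [s for s in qc_cfg.get("remove_low_quality", [])
                        if s in set(kept_ids) and s not in set(removed_missing)]
        dropped = set(removed_missing) | set(removed_lowq)
        kept_ids = [s for s in kept_ids if s not in dropped]
        kept_records, removed_carrier_recs = exclude_carriers(
            [rec_by_id[s] for s in kept_ids], genes)
        manifest.record(f"carrier exclusion ({sorted(genes)}) removed "
                        f"{len(removed_carrier_recs)} samples")
        groups, unassigned = assign_ancestry_groups(kept_records)
        n_case = sum(r.is_case for r in kept_records)
        ledger = build_ledger(
            initial_n=len(records),
            removed_relatedness=removed_rel,
            removed_missing_inputs=removed_missing,
            removed_low_quality=removed_lowq,
            removed_carriers=[r.sample_id for r in removed_carrier_recs],
            final_cases=n_case,
            final_controls=len(kept_records) - n_case,
        )
        results["ledger"] = ledger
        results["groups"] = groups
        manifest.stage_counts["qc_final_n"] = ledger.final_n
        manifest.stage_counts["qc_final_cases"] = ledger.final_cases
        manifest.stage_counts["qc_final_controls"] = ledger.final_controls
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # subset genotypes to the analysis cohort, in kept order
    kept_order = [r.sample_id for r in kept_records]
    sample_pos = {s: i for i, s in enumerate(genotypes.samples)}
    missing_geno = [s for s in kept_order if s not in sample_pos]
    if missing_geno:
        raise StageError("qc", ValueError(
            f"{len(missing_geno)} kept samples missing from the VCF, "
            f"e.g. {missing_geno[:3]}"))
    rows = np.array([sample_pos[s] for s in kept_order])
    genotypes = GenotypeMatrix(samples=kept_order, sites=genotypes.sites,
                               dosages=genotypes.dosages[rows],
                               not_found=genotypes.not_found)
    status = np.array(["case" if rec_by_id[s].is_case else "control"
                       for s in kept_order])

    # ---- score -----------------------------------------------------------
    stage = "score"
    try:
        sc = config.get("score", {}) or {}
        maf_map = _cohort_maf(scoring, genotypes)
        filtered, drops = filter_scoring_variants(
            scoring, targets=targets,
            max_distance_bp=int(sc.get("max_distance_bp", 200)),
            maf=maf_map, maf_min=float(sc.get("maf_min", 0.001)),
            exclusion_ids=set(sc.get("exclude_ids", [])))
        matched = match_alleles(filtered, genotypes,
                                allow_ambiguous=bool(sc.get("allow_ambiguous", False)))
        controls = {s for s, st in zip(kept_order, status) if st == "control"}
        scores = compute_scores(matched, filtered, genotypes, controls)
        results["scores"] = scores
        results["drop_ledger"] = drops
        manifest.record(f"scoring drops: {drops}")
        manifest.stage_counts["score_variants_used"] = scores.n_variants_used
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- pca -------------------------------------------------------------
    stage = "pca"
    try:
        pc_cfg = config.get("pca", {}) or {}
        pcs = zscore_pcs(compute_pcs(genotypes,
                                     maf_min=float(pc_cfg.get("maf_min", 0.01)),
                                     k=int(pc_cfg.get("k", 10)), seed=seed))
        results["pcs"] = pcs
        manifest.stage_counts["pca_k"] = pcs.k
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- assoc -----------------------------------------------------------
    stage = "assoc"
    try:
        as_cfg = config.get("assoc", {}) or {}
        kind = as_cfg.get("bins", "decile")
        boundary_source = as_cfg.get("boundary_source", "control-only")
        assoc_rows = []
        overall = or_per_sd(scores.standardized, status, pcs, contrast="per-SD:all")
        assoc_rows.append(overall)
        group_results = []
        id_pos = {s: i for i, s in enumerate(kept_order)}
        for grp in results["groups"]:
            idx = np.array([id_pos[s] for s in grp.member_ids], dtype=int)
            if len(idx) < 40 or len(set(status[idx])) < 2:
                manifest.record(f"group {grp.label}: too small for a per-SD fit "
                                f"(n={len(idx)})")
                continue
            sub_pcs = None
            if pcs is not None:
                from .covariates_pca import PCSet
                sub_pcs = PCSet(sample_ids=[kept_order[i] for i in idx],
                                pcs=pcs.pcs[idx],
                                explained_variance=pcs.explained_variance,
                                zscored=pcs.zscored)
            group_results.append(or_per_sd(scores.standardized[idx], status[idx],
                                           sub_pcs, contrast=f"per-SD:{grp.label}"))
        m_corr = as_cfg.get("bonferroni_m") or len(group_results)
        adj = bonferroni([g.p_value for g in group_results], m_corr) \
            if group_results else []
        assoc_rows.extend(group_results)

        partition = make_bins(scores.standardized, kind=kind,
                              boundary_source=boundary_source, status=status)
        stair = staircase(partition, status, pcs)
        assoc_rows.extend(stair)

        carrier_rows = []
        meta_kept = metadata_df.set_index("sample_id").loc[kept_order]
        for gene in [c for c in meta_kept.columns
                     if c in {"BRCA1", "BRCA2", "TP53", "PALB2", "PTEN",
                              "ATM", "CHEK2", "TP53_R337H"}]:
            exposed = meta_kept[gene].astype(int).to_numpy().astype(bool)
            if exposed.sum() == 0:
                continue
            carrier_rows.append(two_by_two_or(exposed, status, contrast=f"gene:{gene}"))
        assoc_rows.extend(carrier_rows)

        auc = auc_holdout(scores.standardized, status,
                          test_fraction=float(as_cfg.get("test_fraction", 0.25)),
                          seed=seed)
        auc_mean, auc_folds = auc_cv(scores.standardized, status,
                                     folds=int(as_cfg.get("folds", 10)), seed=seed)
        results["assoc"] = assoc_rows
        results["staircase"] = stair
        results["partition"] = partition
        results["group_or"] = group_results
        results["group_p_adjusted"] = list(map(float, adj))
        results["auc_holdout"] = auc
        results["auc_cv"] = {"mean": auc_mean, "per_fold": auc_folds.tolist()}
        manifest.record(f"assoc: OR/SD={overall.or_:.3f} "
                        f"CI=({overall.ci_low:.3f},{overall.ci_high:.3f}), "
                        f"AUC holdout={auc:.3f}, CV={auc_mean:.3f} "
                        f"(bins={kind}, boundaries={boundary_source}, "
                        f"m_bonferroni={m_corr})")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- concord (simulate mode only: clean vs imputation-noise scores) --
    stage = "concord"
    try:
        conc_cfg = config.get("concord", {}) or {}
        want = conc_cfg.get("enabled", "simulate" in config)
        sim_cfg = cohort.config if cohort is not None else None
        if want and cohort is not None and (
                sim_cfg.target_rho is not None or sim_cfg.noise_epsilon is not None):
            noisy, eps, rho = add_imputation_noise(
                genotypes, cohort.truth.site_afs()[rows], scoring=filtered,
                epsilon=sim_cfg.noise_epsilon, target_rho=sim_cfg.target_rho,
                seed=seed + 1)
            noisy_scores = compute_scores(matched, filtered, noisy, controls)
            report = compare_scores(scores.normalized, noisy_scores.normalized)
            results["concordance"] = report
            results["noise_epsilon"] = eps
            manifest.record(f"concordance: rho={report.spearman_rho:.3f} at "
                            f"epsilon={eps:.4f}, extreme overlap "
                            f"{report.extreme_overlap_pct:.1f}%")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    if write_outputs:
        _write_outputs(out_dir, manifest, results, status, kept_order)
    return manifest, results


def _records_from_frames(metadata: pd.DataFrame, kinship: pd.DataFrame,
                         ancestry: pd.DataFrame):
    """Build SampleRecord/KinshipPair lists from in-memory simulated tables."""
    import io

    meta_buf = io.StringIO()
    metadata.to_csv(meta_buf, sep="\t", index=False)
    kin_buf = io.StringIO()
    kinship.to_csv(kin_buf, sep="\t", index=False)
    anc_buf = io.StringIO()
    ancestry.to_csv(anc_buf, sep="\t", index=False)
    meta_buf.seek(0), kin_buf.seek(0), anc_buf.seek(0)
    return read_tables(meta_buf, kin_buf if len(kinship) else None, anc_buf)


def _cohort_maf(scoring, genotypes) -> dict:
    """variant_id -> cohort MAF for scoring variants present in the matrix."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(genotypes.dosages, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    site_maf = {(s.chrom, s.pos, frozenset((s.ref, s.alt))): float(maf[j])
                for j, s in enumerate(genotypes.sites)}
    return {v.variant_id: site_maf[v.key] for v in scoring.variants
            if v.key in site_maf}


def _write_outputs(out_dir: Path, manifest: RunManifest, results: dict,
                   status, kept_order) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    scores_df = results["scores"].to_frame()
    scores_df["status"] = status
    scores_path = out_dir / "scores.tsv"
    scores_df.to_csv(scores_path, sep="\t", index=False)
    manifest.outputs["scores"] = str(scores_path)

    pcs_path = out_dir / "pcs.tsv"
    results["pcs"].to_frame().to_csv(pcs_path, sep="\t", index=False)
    manifest.outputs["pcs"] = str(pcs_path)

    assoc_path = out_dir / "assoc.tsv"
    pd.DataFrame([r.to_dict() for r in results["assoc"]]).to_csv(
        assoc_path, sep="\t", index=False)
    manifest.outputs["assoc"] = str(assoc_path)

    report = {
        "ledger": results["ledger"].to_dict(),
        "drop_ledger": results["drop_ledger"],
        "groups": {g.label: len(g.member_ids) for g in results["groups"]},
        "auc_holdout": results["auc_holdout"],
        "auc_cv": results["auc_cv"],
        "group_p_adjusted": results["group_p_adjusted"],
    }
    if "concordance" in results:
        report["concordance"] = results["concordance"].to_dict()
        report["noise_epsilon"] = results["noise_epsilon"]
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest.outputs["report"] = str(report_path)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    manifest.outputs["manifest"] = str(manifest_path)
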