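"""Pipeline orchestration: validated config, staged execution, manifest.

The pipeline runs the full synthetic study end to end: fixture generation,
nascent-RNA quantification and cross-normalization, SUMO peptide filtering
through density and equilibrium, the union-peak differential ChIP landscape,
and stage-module clustering with cross-dataset correlation.  Every stage's
outputs are checksummed into a manifest so a rerun with the same config is
verifiably identical for deterministic stages.  All randomness flows from
the config seed; no wall-clock or PID entropy enters anywhere.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ConfigurationError
from ._io import read_fasta
from . import chip, modules, proteomics, simulate, slam

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1

_TOP_LEVEL_KEYS = {
    "version", "seed", "outdir", "simulate", "thresholds", "stage_map",
    "clustering", "windows", "min_base_quality", "input_mg",
}
_REQUIRED_THRESHOLDS = ("loc_prob", "delta", "padj", "fc", "deg_padj", "treatment_deg_padj")
_SIMULATE_KEYS = {
    "n_genes", "n_replicates", "time_points", "depth", "labeled_fraction",
    "conversion_rate", "seq_error_rate", "n_snps", "nb_dispersion", "read_length",
}


def default_config(seed: int = 0, outdir: str = "pipeline_out") -> dict[str, Any]:
    """The packaged demo configuration (synthetic study conditions)."""
    return {
        "version": CONFIG_VERSION,
        "seed": seed,
        "outdir": outdir,
        "simulate": {
            "n_genes": 60,
            "n_replicates": 3,
            "depth": 100.0,
            "labeled_fraction": 0.3,
            "conversion_rate": 0.02,
            "seq_error_rate": 0.001,
            "n_snps": 20,
        },
        "thresholds": {
            "loc_prob": 0.75,
            "delta": 40.0,
            "padj": 0.05,
            "fc": 1.5,
            "deg_padj": 0.01,
            "treatment_deg_padj": 0.1,
        },
        "stage_map": dict(modules.DEFAULT_STAGE_MAP),
        "clustering": {"k": 3},
        "windows": {"promoter": [-1000, 100], "distant_promoter": [-10000, -1000]},
        "min_base_quality": 27,
        "input_mg": 2.0,
    }


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Schema check; unknown keys and missing threshold keys are errors."""
    unknown = set(config) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("version", "seed", "outdir", "thresholds"):
        if key not in config:
            raise ConfigurationError(f"missing required config key: {key}")
    if config["version"] != CONFIG_VERSION:
        raise ConfigurationError(
            f"config version {config['version']} != supported {CONFIG_VERSION}"
        )
    thresholds = config["thresholds"]
    for key in _REQUIRED_THRESHOLDS:
        if key not in thresholds:
            raise ConfigurationError(f"missing required threshold key: {key}")
    unknown_thr = set(thresholds) - set(_REQUIRED_THRESHOLDS)
    if unknown_thr:
        raise ConfigurationError(f"unknown threshold keys: {sorted(unknown_thr)}")
    sim = config.get("simulate", {})
    unknown_sim = set(sim) - _SIMULATE_KEYS
    if unknown_sim:
        raise ConfigurationError(f"unknown simulate keys: {sorted(unknown_sim)}")
    return dict(config)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Any]:
    """Run all stages in dependency order; returns the manifest dict."""
    config = validate_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    thresholds = config["thresholds"]
    stage_map = config.get("stage_map", dict(modules.DEFAULT_STAGE_MAP))
    min_bq = int(config.get("min_base_quality", slam.DEFAULT_MIN_BASE_QUALITY))

    sim_kwargs = dict(config.get("simulate", {}))
    if "time_points" in sim_kwargs:
        sim_kwargs["time_points"] = tuple(sim_kwargs["time_points"])
    cfg = simulate.SimConfig(seed=seed, **sim_kwargs)

    manifest: dict[str, Any] = {
        "tool": "sumowaves",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
        "outputs": {},
        "inputs": {},
    }

    # --- stage: simulate -------------------------------------------------
    fixtures = simulate.write_fixture_bundle(cfg, outdir / "fixtures")
    manifest["inputs"] = {k: _sha256(p) for k, p in sorted(fixtures.items())}
    manifest["stages"]["simulate"] = {"n_files": len(fixtures)}
    logger.info("simulate: wrote %d fixture files", len(fixtures))

    def _save(name: str, df: pd.DataFrame, index: bool = False) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        manifest["outputs"][name] = _sha256(path)
        return path

    # --- stage: slam quantification --------------------------------------
    utr_bed = pd.read_csv(
        fixtures["utrs_bed"], sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    snp_mask = {
        (r.chrom, r.pos0)
        for r in pd.read_csv(
            fixtures["snp_mask_vcf"], sep="\t", comment="#", header=None,
            names=["chrom", "pos", "id", "ref", "alt", "qual", "filter", "info"],
        ).assign(pos0=lambda d: d["pos"] - 1).itertuples()
    } if fixtures["snp_mask_vcf"].stat().st_size > 60 else set()
    tidy = slam.quantify(
        str(fixtures["slam_sam"]), utr_bed, snp_mask=snp_mask, min_base_quality=min_bq
    )
    _save("slam_counts.tsv", tidy)
    totals = slam.conversion_matrix(tidy, "total_reads")
    labeled = slam.conversion_matrix(tidy, "labeled_reads")
    factors = slam.size_factors(totals)
    normalized_labeled = slam.cross_normalize(labeled, factors)
    _save("size_factors.tsv", factors.rename_axis("sample_id").to_frame(), index=True)
    _save("normalized_labeled.tsv", normalized_labeled, index=True)
    manifest["stages"]["slam"] = {
        "n_genes": int(totals.shape[0]), "n_samples": int(totals.shape[1]),
    }
    logger.info("slam: %d genes x %d samples", *totals.shape)

    # --- stage: proteomics ------------------------------------------------
    peptides = pd.read_csv(fixtures["peptides_tsv"], sep="\t")
    proteins = read_fasta(fixtures["proteins_fasta"])
    records = proteomics.records_from_table(peptides)
    accepted, rejected = proteomics.filter_peptides(
        records, proteins,
        loc_prob=float(thresholds["loc_prob"]), delta=float(thresholds["delta"]),
    )
    resolved = proteomics.resolve_multiply_sumoylated(accepted)
    site_table, targets = proteomics.map_sites(
        [r for r in resolved if r.sumo_mods], proteins
    )
    _save("sumo_sites.tsv", site_table)
    _save(
        "sumo_rejections.tsv",
        pd.DataFrame(
            [{"record_id": r.record_id, "reason": reason} for r, reason in rejected]
        ),
    )
    mg = config.get("input_mg", 2.0)
    input_mg = (
        dict(mg) if isinstance(mg, Mapping)
        else {s: float(mg) for s in cfg.samples}
    )
    density = proteomics.sumo_density(site_table, input_mg)
    _save("sumo_density.tsv", density)
    equilibrium = proteomics.classify_equilibrium(resolved, cfg.time_points)
    _save("sumo_equilibrium.tsv", equilibrium)
    site_matrix = site_table.set_index(
        site_table["protein_id"] + ":" + site_table["residue_position"].astype(str)
    )[[c for c in site_table.columns if c.startswith("intensity_")]]
    site_matrix.columns = [c[len("intensity_"):] for c in site_matrix.columns]
    site_z = proteomics.lfq_summarize(site_matrix, seed=seed)
    _save("sumo_site_zscores.tsv", site_z, index=True)
    manifest["stages"]["proteomics"] = {
        "n_records": len(records), "n_accepted": len(accepted),
        "n_sites": int(site_table.shape[0]), "n_targets": len(targets),
    }
    logger.info(
        "proteomics: %d records -> %d sites on %d targets",
        len(records), site_table.shape[0], len(targets),
    )

    # --- stage: chip landscape --------------------------------------------
    peak_frames = [
        pd.read_csv(
            fixtures[f"peaks_{tp}"], sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        for tp in cfg.time_points
    ]
    union = chip.union_peaks(peak_frames)
    _save("union_peaks.tsv", union)
    counts = chip.count_in_union(str(fixtures["chip_sam"]), union)
    normalized, chip_factors = chip.normalize_union_counts(counts)
    _save("union_counts.tsv", counts, index=True)
    groups = {c: c.rsplit("_", 1)[0] for c in counts.columns}
    diff = chip.differential_regions(
        normalized, groups,
        padj_threshold=float(thresholds["padj"]),
        fc_threshold=float(thresholds["fc"]),
        counts=counts,
    )
    _save("differential_regions.tsv", diff)
    gene_models = chip.gene_models_from_table(
        pd.read_csv(fixtures["gene_models_tsv"], sep="\t")
    )
    windows = config.get("windows", {})
    annotations = chip.annotate_peaks(
        union, gene_models,
        promoter_window=tuple(windows.get("promoter", chip.PROMOTER_WINDOW)),
        distant_window=tuple(windows.get("distant_promoter", chip.DISTANT_PROMOTER_WINDOW)),
    )
    _save("peak_annotations.tsv", annotations)
    manifest["stages"]["chip"] = {
        "n_union_peaks": int(union.shape[0]),
        "n_flagged": int(diff["flagged"].sum()),
    }
    logger.info("chip: %d union peaks, %d flagged", union.shape[0], int(diff["flagged"].sum()))

    # --- stage: modules ----------------------------------------------------
    counts_matrix = pd.read_csv(fixtures["counts_tsv"], sep="\t", index_col=0)
    count_factors = slam.size_factors(counts_matrix)
    normed = slam.normalize_counts(counts_matrix, count_factors)
    averaged = slam.replicate_average(normed)[list(cfg.time_points)]
    log2 = np.log2(averaged + 1.0)
    z = modules.zscore_rows(log2)
    clustering = config.get("clustering", {"k": 3})
    k = clustering.get("k")
    if k in (None, "scan"):
        k = modules.choose_k(
            z, range(int(clustering.get("k_min", 4)), int(clustering.get("k_max", 15)) + 1),
            seed=seed,
        )
    assignment = modules.assign_stages(
        modules.cluster_modules(z, int(k), seed=seed), stage_map
    )
    module_report = {
        "k": int(k),
        "modules": [
            {
                "module": int(m),
                "stage": assignment.stages[int(m)],
                "n_members": int((assignment.labels == m).sum()),
                "centroid": {
                    tp: round(float(v), 6)
                    for tp, v in assignment.centroids.loc[m].items()
                },
            }
            for m in assignment.centroids.index
        ],
    }
    report_path = outdir / "module_report.json"
    report_path.write_text(json.dumps(module_report, indent=2, sort_keys=True))
    manifest["outputs"]["module_report.json"] = _sha256(report_path)
    _save(
        "module_assignment.tsv",
        assignment.labels.rename("module").rename_axis("gene_id").to_frame().assign(
            stage=[assignment.stages[int(m)] for m in assignment.labels]
        ),
        index=True,
    )

    # cross-dataset correlation: nascent (labeled) vs steady-state counts
    nascent_avg = slam.replicate_average(normalized_labeled)[list(cfg.time_points)]
    shared = nascent_avg.index.intersection(averaged.index)
    corr = modules.profile_correlation(nascent_avg.loc[shared], averaged.loc[shared])
    _save("profile_correlation.tsv", corr)
    bins = modules.correlation_bins(corr["r"])
    _save(
        "correlation_bins.tsv",
        pd.DataFrame({"bin": range(1, 11), "count": bins}),
    )
    manifest["stages"]["modules"] = {
        "k": int(k),
        "n_clustered": int(assignment.labels.size),
        "n_correlated": int(corr["defined"].sum()),
    }
    logger.info("modules: k=%d over %d genes", int(k), assignment.labels.size)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


__all__ = ["default_config", "validate_config", "load_config", "run_pipeline", "CONFIG_VERSION"]
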