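"""End-to-end orchestration: identify -> group -> quantify -> diffexpr.

Each stage writes its artifact (filtered PSM table, group report,
intensity matrix + imputation mask, normalization report, differential
report) so the stages are independently inspectable and re-runnable, plus
a machine-readable run manifest with the seed, the echoed configuration
and per-stage counts.  Outputs are pure functions of (inputs, config,
seed).
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import __version__
from .diffexpr import call_differential, results_to_frame, run_differential
from .grouping import group_proteins, retained_protein_list, write_group_report
from .identifications import (
    assemble_proteins,
    estimate_fdr,
    filter_psms,
    parse_psm_table,
    read_fasta_database,
    write_psm_table,
)
from .ms1io import read_ms1
from .quant import estimate_noise, quantify_proteins

log = logging.getLogger("lfqpipe")


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass
class PipelineConfig:
    database_fasta: str = ""
    psm_table: str = ""
    ms1_dir: str = ""
    out_dir: str = "lfqpipe_out"
    condition_a: str = "A"
    condition_b: str = "B"
    e_value_threshold: float = 0.05
    min_distinct_peptides: int = 2
    alpha: float = 0.05
    channel_halfwidth: float = 0.5
    max_extent: int = 250
    noise_quantile: float = 0.05
    dedupe_tolerance: float = 0.01
    n_iterations: int = 1_000_000
    seed: int = 0
    bounds: str = "per-protein"
    mode_bin_width: float = 0.1
    preferred_species: str = "Gossypium hirsutum"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("database_fasta", "psm_table"):
            p = getattr(self, name)
            if not p or not os.path.exists(p):
                raise ConfigError(f"{name} does not exist: {p!r}")
        if not self.ms1_dir or not os.path.isdir(self.ms1_dir):
            raise ConfigError(f"ms1_dir does not exist: {self.ms1_dir!r}")
        if not 0 < self.e_value_threshold:
            raise ConfigError("e_value_threshold must be > 0")
        if self.min_distinct_peptides < 1:
            raise ConfigError("min_distinct_peptides must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 < self.noise_quantile < 1:
            raise ConfigError("noise_quantile must be in (0, 1)")
        if self.channel_halfwidth <= 0 or self.dedupe_tolerance < 0:
            raise ConfigError("channel_halfwidth must be > 0 and dedupe_tolerance >= 0")
        if self.max_extent < 1 or self.n_iterations < 1:
            raise ConfigError("max_extent and n_iterations must be >= 1")
        if self.bounds not in ("per-protein", "global"):
            raise ConfigError(f"bounds must be per-protein or global, got {self.bounds!r}")
        if self.mode_bin_width <= 0:
            raise ConfigError("mode_bin_width must be > 0")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    counts: dict[str, int] = {}

    # --- identify ---------------------------------------------------------
    psms = parse_psm_table(config.psm_table)
    counts["psms_in"] = len(psms)
    kept = filter_psms(psms, config.e_value_threshold)
    counts["psms_passing_evalue"] = len(kept)
    database = read_fasta_database(config.database_fasta)
    proteins = assemble_proteins(kept, database, config.min_distinct_peptides)
    targets = [p for p in proteins if not p.is_decoy]
    decoys = [p for p in proteins if p.is_decoy]
    counts["proteins_identified"] = len(targets)
    counts["decoy_proteins_passing"] = len(decoys)
    fdr = estimate_fdr(targets, decoys)
    log.info("identify: %d PSMs -> %d pass E-value; %d target proteins, FDR %.4f",
             counts["psms_in"], counts["psms_passing_evalue"], len(targets), fdr)
    filtered_path = os.path.join(config.out_dir, "filtered_psms.tsv")
    write_psm_table([p for prot in targets for p in prot.psms], filtered_path)

    # --- group ------------------------------------------------------------
    groups = group_proteins(targets, config.preferred_species)
    retained = retained_protein_list(groups, targets)
    counts["groups_formed"] = len(groups)
    counts["proteins_retained"] = len(retained)
    group_path = os.path.join(config.out_dir, "protein_groups.tsv")
    write_group_report(groups, group_path)
    log.info("group: %d groups, %d proteins retained", len(groups), len(retained))

    # --- quantify ---------------------------------------------------------
    ms1_files = sorted(glob.glob(os.path.join(config.ms1_dir, "*.ms1")))
    if not ms1_files:
        raise ConfigError(f"no .ms1 files in {config.ms1_dir!r}")
    runs = {}
    for path in ms1_files:
        run = read_ms1(path)
        runs[run.replicate_id] = run
    conditions = {}
    for psm in kept:
        conditions[psm.replicate_id] = psm.condition_id
    missing = set(conditions) - set(runs)
    if missing:
        raise ConfigError(f"PSM table references replicate(s) with no MS1 run: {sorted(missing)}")
    noise = {r: estimate_noise(runs[r], config.noise_quantile) for r in runs}
    matrix = quantify_proteins(
        runs, retained, conditions, noise,
        halfwidth=config.channel_halfwidth,
        max_extent=config.max_extent,
        dedupe_tolerance=config.dedupe_tolerance,
    )
    matrix.to_tsv(
        os.path.join(config.out_dir, "intensity_matrix.tsv"),
        os.path.join(config.out_dir, "imputation_mask.tsv"),
    )
    counts["replicates"] = len(runs)
    counts["cells_imputed"] = int(matrix.imputed.values.sum())
    log.info("quantify: %d x %d matrix, %d imputed cells",
             len(matrix.proteins), len(runs), counts["cells_imputed"])

    # --- diffexpr ---------------------------------------------------------
    results, report = run_differential(
        matrix, config.condition_a, config.condition_b,
        n_iterations=config.n_iterations, seed=config.seed,
        alpha=config.alpha, bin_width=config.mode_bin_width,
        bounds=config.bounds,
    )
    up, down, unchanged = call_differential(results, config.alpha)
    counts["proteins_significant"] = len(up) + len(down)
    counts["proteins_up"] = len(up)
    counts["proteins_down"] = len(down)
    diff_path = os.path.join(config.out_dir, "differential_report.tsv")
    results_to_frame(results).to_csv(diff_path, sep="\t", index=False)
    norm_path = os.path.join(config.out_dir, "normalization_report.tsv")
    pd.DataFrame(
        {"replicate_id": list(report.mode_value),
         "mode_value": list(report.mode_value.values())}
    ).to_csv(norm_path, sep="\t", index=False)
    log.info("diffexpr: %d significant (%d up, %d down) of %d",
             counts["proteins_significant"], len(up), len(down), len(results))

    artifacts = {
        "filtered_psms": filtered_path,
        "protein_groups": group_path,
        "intensity_matrix": os.path.join(config.out_dir, "intensity_matrix.tsv"),
        "imputation_mask": os.path.join(config.out_dir, "imputation_mask.tsv"),
        "normalization_report": norm_path,
        "differential_report": diff_path,
    }
    manifest = {
        "lfqpipe_version": __version__,
        "seed": config.seed,
        "protein_fdr": fdr,
        "config": asdict(config),
        "counts": counts,
        "artifacts": {k: _sha256(v) for k, v in artifacts.items()},
    }
    with open(os.path.join(config.out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def compare_catalogs(catalogs: dict[str, list[str]]) -> pd.DataFrame:
    """Numeric overlap report for >= 2 named protein lists.

    Rows: per-list sizes, all pairwise intersection/unique-to counts, and
    the intersection and union of all lists.
    """
    if len(catalogs) < 2:
        raise ValueError("need at least two protein lists to compare")
    sets = {name: set(v) for name, v in catalogs.items()}
    rows = []
    names = list(sets)
    for name in names:
        rows.append({"comparison": f"size:{name}", "count": len(sets[name])})
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = sets[a] & sets[b]
            rows.append({"comparison": f"intersection:{a}&{b}", "count": len(inter)})
            rows.append({"comparison": f"only:{a}-{b}", "count": len(sets[a] - sets[b])})
            rows.append({"comparison": f"only:{b}-{a}", "count": len(sets[b] - sets[a])})
    common = set.intersection(*sets.values())
    total = set.union(*sets.values())
    rows.append({"comparison": "intersection:all", "count": len(common)})
    rows.append({"comparison": "union:all", "count": len(total)})
    return pd.DataFrame(rows)
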