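"""End-to-end orchestration: curate -> landscape -> scan -> peaks -> coloc.

A single YAML (or dict) config drives the whole analysis; every stage can
also be re-run independently from the intermediate files it writes.  The
run ends with a manifest recording the config snapshot, input digests,
seeds and an inventory of outputs, so any output is traceable to its
inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import GenomeLayout, default_oat_layout
from . import colocation as coloc
from . import curation, landscape, markers, qtl, simulate

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration schema violation, reported with its field path."""


def _require(cfg: dict, path: str):
    cur = cfg
    for part in path.split("."):
        if not isinstance(cur, dict) or part not in cur:
            raise ConfigError(f"missing required config field: {path}")
        cur = cur[part]
    return cur


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _load_layout(cfg: dict) -> GenomeLayout:
    spec = cfg.get("layout")
    if spec is None:
        return default_oat_layout()
    if isinstance(spec, str):
        path = Path(spec)
        if not path.exists():
            raise ConfigError(f"layout: file not found: {spec}")
        if path.suffix in (".gff", ".gff3"):
            return GenomeLayout.from_gff3(path)
        return GenomeLayout.from_tsv(path)
    if isinstance(spec, dict):
        return GenomeLayout(list(spec.items()))
    raise ConfigError("layout: expected path or mapping of name -> length_bp")


def run_pipeline(config, out_dir=None) -> RunManifest:
    """Execute all configured stages; returns the manifest (written last).

    A failure in one trait/environment combination is recorded and does
    not abort the remaining combinations.
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg.get("out", "rilmap_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)
    layout = _load_layout(cfg)

    geno_path = _require(cfg, "genotypes")
    pheno_path = cfg.get("phenotypes")
    for label, p in (("genotypes", geno_path), ("phenotypes", pheno_path)):
        if p is not None:
            if not Path(p).exists():
                raise ConfigError(f"{label}: file not found: {p}")
            manifest.input_digests[str(p)] = _sha256(p)

    table = markers.read_genotypes(geno_path,
                                   cfg.get("genotype_dialect", "char"))

    # -- curation ------------------------------------------------------------
    cur_cfg = cfg.get("curation", {})
    parents = cfg.get("parents")
    curated, reports = curation.curate(
        table,
        parent_a=parents[0] if parents else None,
        parent_b=parents[1] if parents else None,
        max_missing=cur_cfg.get("max_missing", 0.50),
        min_maf=cur_cfg.get("min_maf", 0.30),
        max_het=cur_cfg.get("max_het", 0.10),
        uncertainty_zone=cur_cfg.get("uncertainty_zone", 1),
        chrom_order=[s.name for s in layout.spans
                     if s.name in set(table.markers["chromosome"])] or None,
    )
    markers.write_genotypes(curated, out / "genotypes.curated.tsv")
    with open(out / "curation_report.json", "w") as fh:
        json.dump({k: r.as_dict() for k, r in reports.items()}, fh, indent=2)
    manifest.outputs["curated_genotypes"] = str(out / "genotypes.curated.tsv")
    manifest.outputs["curation_report"] = str(out / "curation_report.json")

    distortion = landscape.distortion_profile(curated)
    distortion.to_csv(out / "distortion.tsv", sep="\t", index=False)
    manifest.outputs["distortion"] = str(out / "distortion.tsv")

    # -- recombination landscape ----------------------------------------------
    land_cfg = cfg.get("landscape", {})
    if land_cfg.get("enabled", True):
        matrix = landscape.recombination_matrix(
            curated, layout,
            window=land_cfg.get("window", 16.0),
            step=land_cfg.get("step", 10.0),
            min_informative=land_cfg.get("min_informative", 10),
        )
        matrix.to_tsv(out / "recombination_matrix.tsv")
        anomalies = landscape.detect_anomalies(
            matrix,
            linkage_threshold=land_cfg.get("linkage_threshold", 0.2),
            min_block=land_cfg.get("min_block", 2),
        )
        landscape.anomalies_to_gff(anomalies, out / "anomalies.gff3")
        manifest.outputs["recombination_matrix"] = \
            str(out / "recombination_matrix.tsv")
        manifest.outputs["anomalies"] = str(out / "anomalies.gff3")
        if land_cfg.get("heatmap", False):
            landscape.render_heatmap(matrix, out / "recombination_heatmap.png")
            manifest.outputs["heatmap"] = str(out / "recombination_heatmap.png")

    # -- QTL scans -----------------------------------------------------------
    all_peaks: list[qtl.QtlPeak] = []
    scan_cfg = cfg.get("scan")
    if scan_cfg is not None and pheno_path is not None:
        pheno = markers.read_phenotypes(pheno_path)
        traits = scan_cfg.get("traits", "all")
        if traits == "all":
            traits = sorted(pheno["trait"].unique())
        population = cfg.get("population", "pop")
        for trait in traits:
            try:
                values = qtl.prepare_trait_values(
                    pheno, trait, scan_cfg.get("environments", "means")
                )
                profile = qtl.genome_scan(
                    curated, values,
                    covariate_marker=scan_cfg.get("covariate"),
                    min_lines=scan_cfg.get("min_lines", 20),
                    trait=trait,
                )
                thresholds = qtl.permutation_thresholds(
                    curated, values,
                    n_perm=scan_cfg.get("n_perm", 1000),
                    seed=seed,
                    min_lines=scan_cfg.get("min_lines", 20),
                )
                alpha = scan_cfg.get("alpha", 0.05)
                peaks = qtl.call_peaks(
                    profile, thresholds.ts(alpha),
                    falloff=scan_cfg.get("falloff", 0.80),
                    exclusion_mbp=scan_cfg.get("exclusion_mbp", 75.0),
                    population=population,
                )
                profile.to_tsv(out / f"scan.{trait}.tsv")
                thresholds.to_frame().to_csv(
                    out / f"thresholds.{trait}.tsv", sep="\t", index=False
                )
                qtl.peaks_to_frame(peaks).to_csv(
                    out / f"peaks.{trait}.tsv", sep="\t", index=False
                )
                manifest.outputs[f"scan.{trait}"] = str(out / f"scan.{trait}.tsv")
                all_peaks.extend(peaks)
            except Exception as exc:  # isolate per-trait failures
                logger.exception("scan failed for trait %s", trait)
                manifest.errors[f"scan.{trait}"] = str(exc)
        qtl.export_gff(all_peaks, out / "peaks.gff3")
        manifest.outputs["peaks_gff"] = str(out / "peaks.gff3")

    # -- co-location ---------------------------------------------------------
    coloc_cfg = cfg.get("colocation")
    if coloc_cfg is not None:
        genes = coloc.read_genes_tsv(_require(cfg, "colocation.genes"))
        intervals = [p.interval for p in all_peaks]
        if not intervals and coloc_cfg.get("intervals"):
            intervals = coloc.read_intervals_tsv(coloc_cfg["intervals"])
        if intervals:
            test = coloc.colocation_test(
                trait=coloc_cfg.get("trait", "all"),
                genes=genes, intervals=intervals, layout=layout,
                widen=coloc_cfg.get("widen", 0),
                n_boot=coloc_cfg.get("n_boot", 0),
                min_sep=coloc_cfg.get("min_sep", 100),
                seed=seed,
            )
            test.to_frame().to_csv(out / "colocation.tsv", sep="\t",
                                   index=False)
            manifest.outputs["colocation"] = str(out / "colocation.tsv")
        else:
            manifest.errors["colocation"] = "no QTL intervals available"

    for key, path in manifest.outputs.items():
        manifest.input_digests.setdefault(path, _sha256(path))
    manifest.write(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest


def simulate_to_files(cfg: simulate.SimConfig, out_dir) -> dict[str, str]:
    """Run the simulator and write genotypes (observed + truth), phenotypes
    and truth records; returns the output inventory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = simulate.simulate_population(cfg)
    markers.write_genotypes(res.observed, out / "genotypes.observed.tsv")
    markers.write_genotypes(res.truth, out / "genotypes.truth.tsv")
    markers.write_phenotypes(res.phenotypes, out / "phenotypes.tsv")
    res.pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
    cfg.layout.to_tsv(out / "layout.tsv")
    truth_records = {
        "seed": cfg.seed,
        "generations": cfg.generations,
        "qtls": [q.__dict__ for q in cfg.qtls],
        "translocations": [t.__dict__ for t in cfg.translocations],
        "inversions": [i.__dict__ for i in cfg.inversions],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_records, fh, indent=2, default=str)
    return {p.name: str(p) for p in sorted(out.iterdir())}
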