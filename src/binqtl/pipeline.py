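"""End-to-end pipeline: simulate -> bin map -> QTL scan -> fine-map.

Every stage writes its artifacts into the output directory and a
``manifest.json`` stamps each run with the configuration hash and master
seed; per-stage counts (lines and bins in/out of every filter) are logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .binmap import BinMapper
from .config import PipelineConfig, config_hash
from .finemap import (
    classify_recombinant,
    constraint_from_test,
    intersect_assignments,
    progeny_test,
)
from .qtl import CIMScanner
from .sim import (
    line_means,
    simulate_gbs_observations,
    simulate_parent_snps,
    simulate_phenotypes,
    simulate_progeny_subfamily,
    simulate_ril_population,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Run the configured stages, returning the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest: dict = {"config_hash": config_hash(cfg), "seed": cfg.seed, "stages": {}}

    try:
        snps, truth, raw, phenotypes, pheno_truth = _stage_simulate(cfg, outdir, manifest)
        binmap = _stage_binmap(cfg, raw, outdir, manifest)
        scanner = _stage_scan(cfg, binmap, phenotypes, outdir, manifest)
        if cfg.finemap is not None and len(scanner.qtls_):
            _stage_finemap(cfg, truth, scanner, outdir, manifest)
    except Exception as exc:
        manifest["error"] = str(exc)
        _write_manifest(outdir, manifest)
        raise
    _write_manifest(outdir, manifest)
    return outdir


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def _stage_simulate(cfg: PipelineConfig, outdir: Path, manifest: dict):
    s = cfg.sim
    logger.info("simulate: %d SNPs, %d lines", s.n_snps, s.n_lines)
    snps = simulate_parent_snps(s.n_snps, s.chrom_lengths, s.cm_per_mb, cfg.seed)
    truth = simulate_ril_population(snps, s.n_lines, s.n_selfing_generations, cfg.seed)
    raw = simulate_gbs_observations(truth, s.mean_depth, s.error_rate, cfg.seed)
    spec = s.phenotype_spec()
    phenotypes, pheno_truth = simulate_phenotypes(truth, spec, cfg.seed)
    bio.write_snp_table(snps, outdir / "snps.tsv")
    bio.write_genotype_matrix(raw, outdir / "genotypes.tsv")
    bio.write_phenotypes(phenotypes, outdir / "phenotypes.csv")
    bio.write_truth(
        truth,
        outdir / "truth.json",
        extra={
            "qtls": [vars(q) for q in spec.qtls],
            "planted_pve": pheno_truth.planted_pve,
            "planted_h2": pheno_truth.planted_h2,
        },
    )
    manifest["stages"]["simulate"] = {
        "n_snps": snps.n_snps,
        "n_lines": truth.n_lines,
        "missing_fraction": float((raw.calls == -1).mean()),
    }
    return snps, truth, raw, phenotypes, pheno_truth


def _stage_binmap(cfg: PipelineConfig, raw, outdir: Path, manifest: dict):
    mapper = BinMapper(**cfg.qc.model_dump())
    binmap = mapper.fit_transform(raw)
    bio.write_binmap(binmap, outdir / "binmap.tsv")
    bio.write_genetic_map(binmap, outdir / "genetic_map.tsv")
    manifest["stages"]["binmap"] = {
        "lines_in": raw.n_lines,
        "lines_kept": int(mapper.kept_lines_.sum()),
        "bins_before_filter": mapper.unfiltered_binmap_.n_bins,
        "bins_kept": binmap.n_bins,
        "map_length_cm": mapper.genetic_map_length_,
    }
    logger.info(
        "binmap: kept %d/%d lines, %d bins, %.1f cM",
        int(mapper.kept_lines_.sum()), raw.n_lines, binmap.n_bins,
        mapper.genetic_map_length_,
    )
    return binmap


def _stage_scan(cfg: PipelineConfig, binmap, phenotypes, outdir: Path, manifest: dict):
    y = line_means(phenotypes, cfg.scan.location, cfg.scan.year)
    missing = [lid for lid in binmap.line_ids if lid not in y.index]
    if missing:
        raise ValueError(f"scan: phenotypes missing for lines {missing[:5]} ...")
    scanner = CIMScanner(
        n_cofactors=cfg.scan.n_cofactors,
        window_cm=cfg.scan.window_cm,
        n_permutations=cfg.scan.n_permutations,
        alpha=cfg.scan.alpha,
        lod_drop=cfg.scan.lod_drop,
        random_state=cfg.seed,
    )
    scanner.fit(binmap, y)
    scanner.scan_.to_csv(outdir / "scan.tsv", sep="\t", index=False)
    qtls = scanner.qtls_.copy()
    qtls.to_csv(outdir / "qtl_table.tsv", sep="\t", index=False)
    manifest["stages"]["scan"] = {
        "threshold": scanner.threshold_,
        "n_qtls": int(len(qtls)),
        "cofactors": scanner.cofactors_.tolist(),
    }
    logger.info("scan: threshold %.2f, %d QTLs", scanner.threshold_, len(qtls))
    return scanner


def _stage_finemap(cfg: PipelineConfig, truth, scanner, outdir: Path, manifest: dict):
    """Progeny-test fine-mapping of the top QTL on simulated subfamilies."""
    fm = cfg.finemap
    top = scanner.qtls_.sort_values("lod", ascending=False).iloc[0]
    chrom = top["chrom"]
    qtl_bp = int(top["peak_bp"])
    lo = max(0, qtl_bp - fm.region_halfwidth_bp)
    hi = qtl_bp + fm.region_halfwidth_bp
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99]))
    marker_pos = np.sort(rng.integers(lo, hi, size=20))
    markers = [(f"M{p}", int(p)) for p in marker_pos]
    constraints = []
    tests = []
    for i in range(fm.n_recombinants):
        bp = int(rng.integers(lo, hi))
        het_side = "left" if rng.integers(0, 2) == 0 else "right"
        genotypes = [
            ("het" if (p < bp) == (het_side == "left") else "homB")
            for _, p in markers
        ]
        try:
            rec = classify_recombinant(f"R{i + 1}", markers, genotypes)
        except ValueError:
            continue
        qtl_in_het = (qtl_bp < bp) == (het_side == "left")
        fam = simulate_progeny_subfamily(
            fm.n_progeny_per_class, fm.effect, fm.sd, qtl_in_het, rng
        )
        test = progeny_test(fam, rec.recombinant_id, fm.alpha)
        tests.append(test)
        constraints.append(constraint_from_test(rec, test))
    if not constraints:
        logger.warning("finemap: no usable recombinants")
        return
    result = intersect_assignments(constraints, chrom, lo, hi, on_conflict="drop-weakest")
    payload = {
        "chrom": result.chrom,
        "start_bp": result.start_bp,
        "end_bp": result.end_bp,
        "length_bp": result.length_bp,
        "true_qtl_bp": qtl_bp,
        "supporting": result.supporting,
        "consistent": result.consistent,
        "inconsistent": [vars(c) for c in result.inconsistent],
    }
    with open(outdir / "finemap.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    pd.DataFrame([vars(t) for t in tests]).to_csv(
        outdir / "progeny_tests.tsv", sep="\t", index=False
    )
    manifest["stages"]["finemap"] = {
        "interval_bp": [result.start_bp, result.end_bp],
        "n_subfamilies": len(tests),
        "n_inconsistent": len(result.inconsistent),
    }
    logger.info(
        "finemap: interval %s:%d-%d (%.1f kb)",
        result.chrom, result.start_bp, result.end_bp, result.length_bp / 1e3,
    )
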