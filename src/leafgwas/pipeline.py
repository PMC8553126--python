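"""End-to-end pipeline: simulate -> qc -> gwas -> report."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import qc, scan, simulate
from .io import RunConfig, output_header


def end_to_end(config: RunConfig, outdir) -> dict:
    """Run every stage on synthetic data and write the report bundle.

    Produces genotype (VCF + TSV), phenotype (CSV), QC (TSV + JSON), scan
    (TSV + regions + QQ/Manhattan CSVs) outputs and a provenance manifest
    with the config hash, seeds and per-stage record counts.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = {"config": json.loads(config.to_json()), "config_digest": config.digest(),
                "stages": {}}

    # --- simulate
    cross_cfg = simulate.CrossConfig(
        n_clones=config.n_clones,
        n_chromosomes=config.n_chromosomes,
        snps_per_chromosome=config.snps_per_chromosome,
        chromosome_length=config.chromosome_length,
        missing_rate=config.missing_rate,
        seed=config.seed,
    )
    cross = simulate.simulate_cross(cross_cfg)
    t = config.n_traits
    vg, ve = simulate.default_radius_covariances(t, h2=config.heritability)
    trial = simulate.TrialConfig(
        V_G=vg,
        V_E=ve,
        n_blocks=config.n_blocks,
        cuttings_per_plot=config.cuttings_per_plot,
        trait_means=simulate.default_radius_means(t),
        block_effects=np.outer(np.linspace(-2, 2, config.n_blocks), np.ones(t)),
        survival_rate=config.survival_rate,
        seed=config.seed + 1,
    )
    phen = simulate.simulate_rcbd_phenotypes(trial, cross.true_classes,
                                             clone_ids=cross.clone_ids)
    simulate.write_vcf(cross, out / "genotypes.vcf")
    simulate.write_genotype_tsv(cross, out / "genotypes.tsv")
    simulate.write_phenotype_csv(phen, out / "phenotypes.csv", seed=config.seed)
    manifest["stages"]["simulate"] = {
        "n_snps": int(cross.n_snps),
        "n_clones": int(cross.n_clones),
        "n_trees": int(len(phen)),
        "seed": config.seed,
    }

    # --- qc
    records = qc.build_records(cross.snps, cross.classes,
                               seg_p=config.seg_p, max_missing=config.max_missing)
    keep, per_type = qc.filter_snps(records)
    rep = qc.records_table(records)
    with open(out / "qc_report.tsv", "w") as fh:
        fh.write(output_header("qc", config))
        rep.to_csv(fh, sep="\t", index=False)
    snps_pass = cross.snps.iloc[keep].reset_index(drop=True)
    classes_pass = cross.classes[:, keep]
    codes_pass = simulate.encode_classes(classes_pass, snps_pass["seg_type"])
    pruned = qc.ld_prune(snps_pass, codes_pass,
                         window=config.prune_window, step=config.prune_step,
                         r2_threshold=config.prune_r2)
    (out / "pruned_snps.txt").write_text("\n".join(pruned.kept_snp_ids) + "\n")
    summary = qc.qc_summary(records, keep, pruned)
    (out / "qc_summary.json").write_text(json.dumps(summary, indent=2))
    manifest["stages"]["qc"] = summary

    # --- gwas
    class_codes = np.full(classes_pass.shape, -1, dtype=np.int64)
    finite = ~np.isnan(codes_pass)
    class_codes[finite] = codes_pass[finite].astype(np.int64)
    result = scan.run_scan(
        phen, snps_pass, class_codes,
        m_independent=max(pruned.n_independent, 1),
        alpha=config.alpha, mode=config.mode, clone_ids=cross.clone_ids,
    )
    with open(out / "scan.tsv", "w") as fh:
        fh.write(output_header("gwas", config))
        result.table.to_csv(fh, sep="\t", index=False)
    scan.regions_table(result).to_csv(out / "regions.tsv", sep="\t", index=False)
    scan.qq_table(result.table["p_raw"]).to_csv(out / "qq.csv", index=False)
    scan.manhattan_table(result).to_csv(out / "manhattan.csv", index=False)
    (out / "scan_summary.json").write_text(json.dumps(result.summary(), indent=2))
    manifest["stages"]["gwas"] = result.summary()

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
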