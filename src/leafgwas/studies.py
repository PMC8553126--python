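"""Simulation studies: calibration, power, parameter recovery, geometry.

Each study is a self-contained experiment on synthetic data at desk scale,
mirroring the design of the field trial (150 clones, 3 blocks, 6 cuttings
per plot, ~76.5% tree survival, 11 right-side polar radii):

* :func:`null_calibration_study` — per-test calibration of the multivariate
  scan on unlinked null markers (independent markers so the binomial /
  chi-square-median reference distributions apply; linkage only correlates
  tests, it does not change per-test calibration).
* :func:`power_study` — the multivariate radius test against every
  univariate single-radius test on pleiotropic QTL datasets at a matched
  family-wise significance level.
* :func:`univariate_recovery_study`, :func:`multivariate_recovery_study` —
  REML recovery of known variance components.
* :func:`geometry_validation_study` — the pixel measurement pipeline
  against closed-form leaf geometry.
"""

from __future__ import annotations

import numpy as np

from . import simulate as sim
from .leafgen import LeafShapeParams, render_leaf
from .lmm import (
    MultiVarComp,
    RCBDDesign,
    heritability,
    MixedModelScanner,
    reml_multivariate,
    reml_univariate,
)
from .phenotype import measure_image
from .scan import bonferroni_threshold, run_scan
from .reference import N_INDEPENDENT

RD11_T = 11


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _rd11_trial(vg, ve, seed, qtl=()):
    t = vg.shape[0]
    return sim.TrialConfig(
        V_G=vg, V_E=ve,
        trait_means=sim.default_radius_means(t),
        block_effects=np.outer(np.linspace(-2.0, 2.0, 3), np.ones(t)),
        qtl_spec=tuple(qtl),
        survival_rate=0.765,
        seed=seed,
    )


def null_calibration_study(
    seed: int,
    n_snps: int = 2000,
    n_clones: int = 150,
    n_traits: int = RD11_T,
    alpha: float = 0.05,
) -> dict:
    """Null scan of unlinked SNPs: lambda_GC, type-I error, significance.

    Phenotypes carry block, polygenic and residual effects but no SNP
    effects; each SNP segregates independently (one per chromosome) so the
    exact binomial reference applies to the empirical rejection rate.
    """
    s_cross, s_trial = _child_seeds(seed, 2)
    cross = sim.simulate_cross(
        sim.CrossConfig(
            n_clones=n_clones, n_chromosomes=n_snps, snps_per_chromosome=1,
            missing_rate=0.03, seed=s_cross,
        )
    )
    vg, ve = sim.default_radius_covariances(n_traits)
    phen = sim.simulate_rcbd_phenotypes(
        _rd11_trial(vg, ve, s_trial), cross.true_classes, clone_ids=cross.clone_ids
    )
    codes = _to_codes(cross)
    result = run_scan(phen, cross.snps, codes, m_independent=n_snps,
                      clone_ids=cross.clone_ids)
    p = result.table["p_raw"].to_numpy()
    return {
        "lambda_gc": result.lambda_gc,
        "type_i_error": float((p < alpha).mean()),
        "n_tests": int(len(p)),
        "n_significant": result.n_significant,
        "alpha": alpha,
    }


def _to_codes(cross) -> np.ndarray:
    vals = sim.encode_classes(cross.classes, cross.snps["seg_type"])
    codes = np.full(vals.shape, -1, dtype=np.int64)
    ok = ~np.isnan(vals)
    codes[ok] = vals[ok].astype(np.int64)
    return codes


def power_study(
    seed: int,
    n_datasets: int = 200,
    n_clones: int = 150,
    n_traits: int = RD11_T,
    effect_mm: float = 6.0,
    m_independent: int = N_INDEPENDENT,
    alpha: float = 0.05,
) -> dict:
    """Multivariate vs univariate power on pleiotropic QTL datasets.

    Each dataset has one 1:1-segregating QTL whose heterozygote shifts the
    radius profile by ``effect_mm * cos(theta)`` (the leaf widens without
    lengthening — an effect spread over several radii).  The multivariate
    test runs at the Bonferroni threshold alpha/m; each univariate radius
    test runs at alpha/(m*t) so the family-wise level is matched.
    Returns per-test rejection rates over the datasets.
    """
    t = n_traits
    theta = np.linspace(-np.pi / 2, np.pi / 2, t)
    pattern = np.cos(theta)
    vg, ve = sim.default_radius_covariances(t)
    thr_mv, _ = bonferroni_threshold(m_independent, alpha)
    thr_uni = thr_mv / t
    seeds = _child_seeds(seed, 2 * n_datasets)
    rej_mv = 0
    rej_uni = np.zeros(t, dtype=int)
    for d in range(n_datasets):
        cross = sim.simulate_cross(
            sim.CrossConfig(
                n_clones=n_clones, n_chromosomes=1, snps_per_chromosome=1,
                segregation_mix={"aaxab": 1.0}, missing_rate=0.0,
                seed=seeds[2 * d],
            )
        )
        qtl = sim.QTL(snp_index=0, effects={"ab": effect_mm * pattern})
        phen = sim.simulate_rcbd_phenotypes(
            _rd11_trial(vg, ve, seeds[2 * d + 1], qtl=[qtl]),
            cross.true_classes, clone_ids=cross.clone_ids,
        )
        design = RCBDDesign.from_table(phen)
        X0 = design.base_design_matrix()
        cols = [f"trait_{i+1}" for i in range(t)]
        Y = phen[cols].to_numpy()
        codes = _to_codes(cross)[:, 0]
        vc = reml_multivariate(Y, X0, design.clone)
        res = MixedModelScanner(Y, design, vc).test_snp(codes)
        rej_mv += int(res.p_value < thr_mv)
        for l in range(t):
            u = reml_univariate(Y[:, l], X0, design.clone)
            vcl = MultiVarComp(np.array([[u.sigma_g2]]), np.array([[u.sigma_e2]]),
                               u.log_restricted_likelihood, 0, u.converged)
            ru = MixedModelScanner(Y[:, l : l + 1], design, vcl).test_snp(codes)
            rej_uni[l] += int(ru.p_value < thr_uni)
    return {
        "power_multivariate": rej_mv / n_datasets,
        "power_univariate": (rej_uni / n_datasets).tolist(),
        "power_univariate_best": float(rej_uni.max() / n_datasets),
        "n_datasets": n_datasets,
        "threshold_multivariate": thr_mv,
        "threshold_univariate": thr_uni,
    }


def univariate_recovery_study(
    seed: int,
    n_replicates: int = 100,
    n_clones: int = 150,
    cuttings: int = 5,
    sigma_g2: float = 1.0,
    sigma_e2: float = 1.0,
) -> dict:
    """REML recovery of (sigma_g^2, sigma_e^2) and h^2 over replicates."""
    seeds = _child_seeds(seed, n_replicates)
    sg, se, h2 = [], [], []
    for s in seeds:
        trial = sim.TrialConfig(
            V_G=np.array([[sigma_g2]]), V_E=np.array([[sigma_e2]]),
            n_blocks=3, cuttings_per_plot=cuttings, survival_rate=1.0, seed=s,
        )
        phen = sim.simulate_rcbd_phenotypes(trial, n_clones=n_clones)
        design = RCBDDesign.from_table(phen)
        vc = reml_univariate(
            phen["trait_1"].to_numpy(), design.base_design_matrix(), design.clone
        )
        sg.append(vc.sigma_g2)
        se.append(vc.sigma_e2)
        h2.append(heritability(vc.sigma_g2, vc.sigma_e2))
    sg, se, h2 = np.array(sg), np.array(se), np.array(h2)
    root_n = np.sqrt(n_replicates)
    return {
        "sigma_g2_mean": float(sg.mean()), "sigma_g2_se": float(sg.std(ddof=1) / root_n),
        "sigma_e2_mean": float(se.mean()), "sigma_e2_se": float(se.std(ddof=1) / root_n),
        "h2_mean": float(h2.mean()), "h2_se": float(h2.std(ddof=1) / root_n),
        "sigma_g2_true": sigma_g2, "sigma_e2_true": sigma_e2,
        "h2_true": sigma_g2 / (sigma_g2 + sigma_e2),
        "n_replicates": n_replicates,
    }


def multivariate_recovery_study(
    seed: int,
    n_replicates: int = 100,
    n_clones: int = 150,
    cuttings: int = 5,
) -> dict:
    """Entrywise REML recovery of V_G = diag(1, 2), V_E = I_2."""
    vg_true = np.diag([1.0, 2.0])
    ve_true = np.eye(2)
    seeds = _child_seeds(seed, n_replicates)
    vgs, ves = [], []
    for s in seeds:
        trial = sim.TrialConfig(V_G=vg_true, V_E=ve_true, n_blocks=3,
                                cuttings_per_plot=cuttings, survival_rate=1.0, seed=s)
        phen = sim.simulate_rcbd_phenotypes(trial, n_clones=n_clones)
        design = RCBDDesign.from_table(phen)
        Y = phen[["trait_1", "trait_2"]].to_numpy()
        vc = reml_multivariate(Y, design.base_design_matrix(), design.clone)
        vgs.append(vc.V_G)
        ves.append(vc.V_E)
    vgs, ves = np.array(vgs), np.array(ves)
    root_n = np.sqrt(n_replicates)
    return {
        "V_G_mean": vgs.mean(axis=0).tolist(),
        "V_G_se": (vgs.std(axis=0, ddof=1) / root_n).tolist(),
        "V_E_mean": ves.mean(axis=0).tolist(),
        "V_E_se": (ves.std(axis=0, ddof=1) / root_n).tolist(),
        "V_G_true": vg_true.tolist(),
        "V_E_true": ve_true.tolist(),
        "n_replicates": n_replicates,
    }


def geometry_validation_study(seed: int, n_leaves: int = 100) -> dict:
    """Pixel pipeline vs closed-form geometry on random synthetic leaves.

    Returns mean relative differences (%) in length, maximum width and
    area, plus the worst relative radius error on the ellipse subset.
    """
    rng = np.random.default_rng(seed)
    rel = {"L": [], "W": [], "A": []}
    radius_err = []
    for i in range(n_leaves):
        family = ["ellipse", "parametric-leaf"][i % 2]
        a = rng.uniform(45.0, 75.0)
        b = a * rng.uniform(0.55, 0.85)
        params = LeafShapeParams(
            family=family, a=a, b=b,
            tip_taper=rng.uniform(0.2, 0.7), base_taper=rng.uniform(0.0, 0.3),
            # ellipses stay upright so their radii can be checked against the
            # closed form; the tapered leaves exercise tilt + normalization
            rotation_deg=0.0 if family == "ellipse" else rng.uniform(-30.0, 30.0),
            seed=int(rng.integers(2**31)),
        )
        leaf = render_leaf(params)
        res = measure_image(leaf.image, scale=leaf.pixels_per_mm,
                            radius_kinds=("RD360",))
        m, truth = res["traits"], leaf.truth
        rel["L"].append(abs(m.L - truth.L) / truth.L)
        rel["W"].append(abs(m.W - truth.W) / truth.W)
        rel["A"].append(abs(m.A - truth.A) / truth.A)
        if family == "ellipse" and abs(params.rotation_deg) < 1e-9:
            prof = res["profiles"]["RD360"]
            th = prof.angles
            exact = a * b / np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2)
            radius_err.append(float(np.abs(prof.radii / exact - 1.0).max()))
    out = {f"rel_diff_{k}_pct": float(100 * np.mean(v)) for k, v in rel.items()}
    out["n_leaves"] = n_leaves
    if radius_err:
        out["max_radius_rel_err_pct"] = float(100 * max(radius_err))
    return out
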