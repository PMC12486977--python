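"""Calibration and recovery experiments on simulated data.

Each function runs one self-contained experiment against ground truth from
the synthetic-data module: null-GWAS calibration, REML heritability
recovery, LD estimator oracles, Fisher-pooling distributional checks, MDS
cluster recovery, and the end-to-end disjoint-architecture run that maps a
planted variance-indicator QTL.  They are used by the acceptance script
and the test suite; all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from resilind import gwas as gw
from resilind import popstruct as ps
from resilind.config import SimConfig
from resilind.genetics import compute_grm_vanraden, condition_grm, fit_single_record_model
from resilind.indicators import compute_indicators, transform_indicators
from resilind.pipeline import attach_covariates, disjoint_architecture_config, evaluate_group
from resilind.preprocessing import MIN_COVERAGE_DAYS, WINDOW, build_lactation_series
from resilind.simulate import (simulate_genotypes, simulate_indicator_trait,
                               simulate_phenotypes)


def lambda_gc_denominator() -> float:
    """Theoretical median of the 1-df chi-square used as the lambda_GC denominator."""
    return gw.CHI2_1DF_MEDIAN


def coverage_threshold_days(window: tuple[int, int] = WINDOW) -> int:
    """Minimum retained-day count implied by 50% coverage of the window."""
    lo, hi = window
    n_days = hi - lo + 1
    threshold = int(np.ceil(0.5 * n_days))
    assert threshold == MIN_COVERAGE_DAYS
    return threshold


def null_gwas_calibration(
    seed: int,
    n_individuals: int = 2000,
    n_chrom: int = 5,
    n_snp_per_chrom: int = 1000,
    variants: tuple[str, ...] = gw.MODEL_VARIANTS,
) -> dict[str, dict[str, float]]:
    """Type-I error and lambda_GC of every model variant on a null panel.

    The panel has no causal loci and no stratification (one population,
    F_ST = 0); the phenotype is standard normal noise.
    """
    cfg = SimConfig(n_per_breed=(n_individuals,), n_breeds=1, n_chrom=n_chrom,
                    n_snp_per_chrom=n_snp_per_chrom, n_farms=4, fst=0.0,
                    seed=seed)
    panel = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    y = rng.standard_normal(panel.n_individuals)
    out = {}
    for variant in variants:
        res = gw.mlma_scan(y, panel, variant)
        p = res.table["p"].dropna().to_numpy()
        out[variant] = {
            "lambda_gc": res.lambda_gc,
            "type1_at_05": float((p < 0.05).mean()),
            "n_tests": int(p.size),
        }
    return out


def h2_recovery(
    seeds: tuple[int, ...],
    h2: float = 0.15,
    n_individuals: int = 2000,
    n_chrom: int = 4,
    n_snp_per_chrom: int = 500,
) -> dict[str, float]:
    """REML heritability estimates for a simulated log-variance trait."""
    ests = []
    for seed in seeds:
        cfg = SimConfig(n_per_breed=(n_individuals,), n_breeds=1, n_chrom=n_chrom,
                        n_snp_per_chrom=n_snp_per_chrom, n_farms=4, fst=0.0,
                        seed=seed)
        panel = simulate_genotypes(cfg)
        y, _ = simulate_indicator_trait(panel, h2=h2, rng=seed)
        grm, _ = compute_grm_vanraden(panel)
        vc, _ = fit_single_record_model(
            y, np.ones((panel.n_individuals, 1)), condition_grm(grm),
            compute_reliability=False)
        ests.append(vc.h2)
    return {"h2_true": h2, "h2_mean": float(np.mean(ests)),
            "h2_by_seed": [float(v) for v in ests]}


def ld_phase_oracle(seed: int, n_pairs: int = 1000) -> dict[str, float]:
    """Phase-aware r^2 against a brute-force haplotype-counting oracle.

    Also evaluates the printed-formula example p_A1B1 = 0.4,
    p_A1 = p_B1 = 0.5 (r^2 = 0.36).
    """
    cfg = SimConfig(n_per_breed=(300,), n_breeds=1, n_chrom=2,
                    n_snp_per_chrom=400, n_farms=2, fst=0.0, seed=seed)
    panel = simulate_genotypes(cfg)
    rec = ps.ld_r2_pairs(panel)
    rec = rec.iloc[:n_pairs]
    hap = panel.phased_haplotypes.astype(float)
    col = {s: j for j, s in enumerate(panel.snp_map["snp"])}
    max_diff = 0.0
    for _, row in rec.iterrows():
        a, b = hap[:, col[row["snp_a"]]], hap[:, col[row["snp_b"]]]
        pa, pb, pab = a.mean(), b.mean(), (a * b).mean()
        oracle = (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))
        max_diff = max(max_diff, abs(float(row["r2"]) - oracle))
    example = (0.4 - 0.25) ** 2 / (0.5 ** 4)
    return {"n_pairs": int(len(rec)), "max_abs_diff": float(max_diff),
            "formula_example_r2": float(example)}


def fisher_calibration(seed: int, n_snps: int = 50_000) -> dict[str, float]:
    """Unit example and distributional null of Fisher pooling."""
    unit = gw.fisher_pool(pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]}))
    rng = np.random.default_rng(seed)
    p = pd.DataFrame(rng.uniform(size=(n_snps, 3)), columns=["a", "b", "c"])
    pooled = gw.fisher_pool(p)
    ks = stats.kstest(pooled["p_pooled"], "uniform")
    return {"pooled_p_for_unit_inputs": float(unit.loc[0, "p_pooled"]),
            "ks_pvalue_uniform_null": float(ks.pvalue)}


def mds_cluster_recovery(seed: int, fst: float = 0.10) -> dict[str, float]:
    """Adjusted Rand index of k-means(3) on 2 MDS coordinates vs breed labels."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    cfg = SimConfig(n_per_breed=(200, 200, 200), n_chrom=2, n_snp_per_chrom=1000,
                    n_farms=3, fst=fst, seed=seed)
    panel = simulate_genotypes(cfg)
    coords, _ = ps.classical_mds(ps.ibs_distance(panel), k=2)
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit_predict(coords)
    truth = pd.Categorical(panel.breed_label).codes
    return {"adjusted_rand": float(adjusted_rand_score(truth, km)), "fst": fst}


def disjoint_architecture_run(seed: int) -> dict:
    """Full pipeline on the disjoint-architecture scenario for one seed.

    Simulates milking data in which one QTL drives disturbance
    susceptibility (hence ln v_d) and the autocorrelation channel is
    purely polygenic, runs preprocessing, indicator computation,
    repeated-records genetic evaluation and per-breed mixed-model GWAS,
    pools p-values across the three breeds, and reports whether the
    variance-indicator QTL reaches the genome-wide tier (at the QTL or a
    SNP in r^2 > 0.8 with it) and whether the autocorrelation scan stays
    free of genome-wide hits.
    """
    cfg = disjoint_architecture_config(seed)
    panel = simulate_genotypes(cfg)
    milkings, calvings, truth = simulate_phenotypes(panel, cfg)
    qtl = truth.qtl_positions["vd"][0]
    series, _ = build_lactation_series(milkings, calvings)
    ind, _ = transform_indicators(compute_indicators(series))
    ind = attach_covariates(ind, calvings)

    pooled_p = {}
    for trait in ("vd", "rauto"):
        p_cols = {}
        for breed in pd.unique(panel.breed_label):
            sub = panel.subset(individuals=panel.breed_label == breed)
            breed_ind = ind[ind["animal_id"].isin(sub.samples["iid"])]
            _, dereg = evaluate_group(breed_ind, sub, trait, "M")
            d = dereg.set_index("animal_id")
            iidx = pd.Index(sub.samples["iid"])
            common = iidx[iidx.isin(d.index)]
            sub_t = sub.subset(individuals=iidx.get_indexer(common))
            res = gw.mlma_scan(d.loc[common, "pseudo_phenotype"].to_numpy(),
                               sub_t, "mlma")
            p_cols[breed] = res.table.set_index("snp")["p"]
        pooled_p[trait] = gw.fisher_pool(pd.DataFrame(p_cols))["p_pooled"]

    n_tests = int(pooled_p["vd"].notna().sum())
    gw_thr, _ = gw.significance_thresholds(n_tests)

    # SNPs in strong LD with the QTL (genotype-correlation proxy)
    g = panel.dosages()
    gq = g[:, qtl] - g[:, qtl].mean()
    gc = g - g.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (gc.T @ gq) ** 2 / ((gc ** 2).sum(axis=0) * (gq ** 2).sum())
    proxy = set(panel.snp_map["snp"][np.nan_to_num(r2) > 0.8])

    vd_hits = set(pooled_p["vd"].index[pooled_p["vd"] <= gw_thr])
    rauto_hits = set(pooled_p["rauto"].index[pooled_p["rauto"] <= gw_thr])
    return {
        "seed": seed,
        "genome_wide_threshold": gw_thr,
        "vd_qtl_detected": bool(vd_hits & proxy),
        "n_vd_genome_wide": len(vd_hits),
        "n_rauto_genome_wide": len(rauto_hits),
        "rauto_clean": len(rauto_hits) == 0,
        "min_p_vd": float(pooled_p["vd"].min()),
        "min_p_rauto": float(pooled_p["rauto"].min()),
    }
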