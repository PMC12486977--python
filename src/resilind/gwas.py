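"""Mixed-linear-model GWAS with inflation-controlled model selection.

Each SNP is tested as a fixed effect in ``y = mu + Xb + Zu + e`` with a
polygenic random effect ``u ~ N(0, G sigma2_u)`` built from standardized
genotypes (Yang estimator).  Variance components are estimated once per
scan under the null model and fixed for the per-SNP generalized
least-squares tests (the usual MLMA approximation).  Three variants:

* ``mlma`` — whole-genome GRM;
* ``loco`` — leave-one-chromosome-out: the GRM excludes the chromosome of
  the tested SNP (null components re-estimated per left-out chromosome);
* ``loco-pc`` — LOCO plus a fixed-effect covariate of the top principal
  components of the whole-genome GRM, to absorb population stratification.

Scan calibration is summarized by the genomic inflation factor, the ratio
of the median observed 1-df chi-square to the theoretical median 0.455;
model selection picks the variant whose inflation factor is closest to 1,
rejecting strongly inflated candidates.  Evidence is pooled across breeds
per SNP with Fisher's method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from resilind.genetics import _profile_reml
from resilind.plink import GenotypePanel

log = logging.getLogger(__name__)

#: theoretical median of the 1-df chi-square distribution (lambda_GC denominator)
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))
#: candidates with lambda_GC above this are rejected during model selection
LAMBDA_GUARD = 1.5
SUGGESTIVE_P = 5e-5
MODEL_VARIANTS = ("mlma", "loco", "loco-pc")


@dataclass
class AssocResult:
    """Per-SNP association statistics for one scan."""

    table: pd.DataFrame  # snp, chrom, pos, a1, effect, se, chi2, p
    variant: str
    lambda_gc: float
    varcomp: dict = field(default_factory=dict)


def compute_grm_yang(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """GRM from standardized genotypes with the Yang et al. diagonal.

    Off-diagonals average ``z_i z_j`` over SNPs with
    ``z = (g - 2p) / sqrt(2p(1-p))``; diagonals use
    ``1 + (g^2 - (1+2p) g + 2 p^2) / (2p(1-p))`` averaged over SNPs.
    Monomorphic SNPs are excluded.  Returns ``(G, used_mask)``.
    """
    g = panel.dosages()
    p = g.mean(axis=0) / 2.0
    used = (p > 0) & (p < 1)
    g, p = g[:, used], p[used]
    het = 2.0 * p * (1.0 - p)
    z = (g - 2.0 * p) / np.sqrt(het)
    m = g.shape[1]
    G = z @ z.T / m
    diag = 1.0 + np.mean((g * g - (1.0 + 2.0 * p) * g + 2.0 * p * p) / het, axis=1)
    np.fill_diagonal(G, diag)
    return G, used


def genomic_inflation(chi2: np.ndarray | None = None, pvalues: np.ndarray | None = None) -> float:
    """lambda_GC = median observed chi-square / 0.455 (1-df theoretical median)."""
    if chi2 is None:
        if pvalues is None:
            raise ValueError("provide chi2 statistics or p-values")
        pvalues = np.asarray(pvalues, dtype=float)
        if pvalues.size == 0:
            raise ValueError("empty p-value input")
        chi2 = stats.chi2.isf(pvalues, df=1)
    chi2 = np.asarray(chi2, dtype=float)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size == 0:
        raise ValueError("no finite test statistics")
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def _scan_block(y, covar, G, snps):
    """GLS single-SNP tests with variance components from the null model.

    Eigendecomposes ``V = sigma2_u G + sigma2_e I`` once, whitens response,
    covariates and SNPs, and runs per-SNP OLS on the whitened data.
    Returns (effect, se, chi2, p, sigma2_u, sigma2_e).
    """
    n = y.size
    d, U = np.linalg.eigh(G)
    d = np.clip(d, 0.0, None)
    Uty, UtX = U.T @ y, U.T @ covar
    kappa, sigma2_e, _, _ = _profile_reml(y, covar, np.clip(d, 1e-10, None), Uty, UtX)
    w = 1.0 / (kappa * d + 1.0)
    sw = np.sqrt(w)
    ys = sw * Uty
    Xs = sw[:, None] * UtX
    Gs = sw[:, None] * (U.T @ snps)
    Q, _ = np.linalg.qr(Xs)
    y_r = ys - Q @ (Q.T @ ys)
    G_r_sq = np.einsum("ij,ij->j", Gs, Gs) - np.einsum("ij,ij->j", Q.T @ Gs, Q.T @ Gs)
    xty = Gs.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = xty / G_r_sq
        se = np.sqrt(sigma2_e / G_r_sq)
        chi2 = (effect / se) ** 2
    bad = ~(G_r_sq > 1e-10)
    effect[bad] = se[bad] = chi2[bad] = np.nan
    p = stats.chi2.sf(chi2, df=1)
    return effect, se, chi2, p, kappa * sigma2_e, sigma2_e


def mlma_scan(
    y: np.ndarray,
    panel: GenotypePanel,
    variant: str = "mlma",
    covariates: np.ndarray | None = None,
    n_pcs: int = 20,
) -> AssocResult:
    """Scan every SNP of the panel against ``y`` under the chosen variant.

    ``y`` should be the de-regressed, standardized pseudo-phenotypes (or
    any quantitative response), aligned with the panel's individuals.
    Zero-variance SNPs are skipped (NaN statistics).
    """
    if variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {MODEL_VARIANTS}")
    y = np.asarray(y, dtype=float)
    if y.size != panel.n_individuals:
        raise ValueError("phenotype length does not match the panel")
    dosages = panel.dosages()
    chroms = panel.snp_map["chrom"].to_numpy()
    uniq_chroms = pd.unique(chroms)
    if variant in ("loco", "loco-pc") and uniq_chroms.size < 2:
        raise ValueError("leave-one-chromosome-out undefined on a single-chromosome panel")

    covar = np.ones((y.size, 1))
    if covariates is not None:
        covar = np.column_stack([covar, covariates])

    # per-chromosome Yang GRM pieces (sum of zz' and SNP counts)
    p_all = dosages.mean(axis=0) / 2.0
    poly = (p_all > 0) & (p_all < 1)
    if variant == "loco-pc":
        G_full, _ = compute_grm_yang(panel)
        vals, vecs = np.linalg.eigh(G_full)
        pcs = vecs[:, ::-1][:, :n_pcs]
        covar = np.column_stack([covar, pcs])

    m = panel.n_snps
    effect = np.full(m, np.nan)
    se = np.full(m, np.nan)
    chi2 = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    varcomp: dict = {"variant": variant}

    if variant == "mlma":
        G, _ = compute_grm_yang(panel)
        eff, s, c2, p, s2u, s2e = _scan_block(y, covar, G, dosages)
        effect, se, chi2, pval = eff, s, c2, p
        varcomp.update(sigma2_u=s2u, sigma2_e=s2e)
    else:
        z = np.zeros_like(dosages)
        het = 2.0 * p_all[poly] * (1.0 - p_all[poly])
        z[:, poly] = (dosages[:, poly] - 2.0 * p_all[poly]) / np.sqrt(het)
        for c in uniq_chroms:
            on_c = chroms == c
            off_c = poly & ~on_c
            m_off = int(off_c.sum())
            if m_off == 0:
                raise ValueError(f"no polymorphic SNPs outside chromosome {c}")
            G_loco = z[:, off_c] @ z[:, off_c].T / m_off
            g_off = dosages[:, off_c]
            p_off = p_all[off_c]
            het_off = 2.0 * p_off * (1.0 - p_off)
            diag = 1.0 + np.mean(
                (g_off * g_off - (1.0 + 2.0 * p_off) * g_off + 2.0 * p_off ** 2) / het_off,
                axis=1,
            )
            np.fill_diagonal(G_loco, diag)
            eff, s, c2, p, s2u, s2e = _scan_block(y, covar, G_loco, dosages[:, on_c])
            effect[on_c], se[on_c], chi2[on_c], pval[on_c] = eff, s, c2, p
            varcomp[f"sigma2_u_chr{c}"] = s2u
            varcomp[f"sigma2_e_chr{c}"] = s2e

    mono = ~poly
    effect[mono] = se[mono] = chi2[mono] = pval[mono] = np.nan
    table = pd.DataFrame({
        "snp": panel.snp_map["snp"],
        "chrom": chroms,
        "pos": panel.snp_map["pos"],
        "a1": panel.snp_map["a1"],
        "effect": effect,
        "se": se,
        "chi2": chi2,
        "p": pval,
    })
    lam = genomic_inflation(chi2=chi2[np.isfinite(chi2)])
    return AssocResult(table=table, variant=variant, lambda_gc=lam, varcomp=varcomp)


def select_model(
    scans: dict[str, AssocResult] | dict[str, float],
    lambda_guard: float = LAMBDA_GUARD,
) -> tuple[str, pd.DataFrame]:
    """Pick the variant whose lambda_GC is closest to 1.

    Candidates with ``lambda_GC > lambda_guard`` (strong inflation of
    false positives) are rejected outright.  Raises if every candidate is
    rejected, reporting the full candidate table.
    """
    if len(scans) < 2:
        raise ValueError("model selection needs at least two candidate variants")
    lam = {k: (v.lambda_gc if isinstance(v, AssocResult) else float(v))
           for k, v in scans.items()}
    report = pd.DataFrame({
        "variant": list(lam),
        "lambda_gc": list(lam.values()),
        "rejected": [v > lambda_guard for v in lam.values()],
    })
    report["dist_to_1"] = (report["lambda_gc"] - 1.0).abs()
    ok = report.loc[~report["rejected"]]
    if ok.empty:
        raise ValueError(f"all candidate models rejected (lambda_GC > {lambda_guard}):\n{report}")
    chosen = ok.sort_values("dist_to_1", kind="mergesort").iloc[0]["variant"]
    return str(chosen), report.drop(columns="dist_to_1")


def fisher_pool(p_by_breed: pd.DataFrame) -> pd.DataFrame:
    """Fisher's method across breeds: ``X2 = -2 sum ln(p_i)``, df ``2k``.

    ``p_by_breed`` has one column of p-values per breed, indexed by SNP;
    SNPs missing in any breed are dropped (counted in the ``n_dropped``
    attribute of the result).  Zero p-values are clamped to the smallest
    positive float with an audit log entry.
    """
    complete = p_by_breed.dropna()
    n_dropped = len(p_by_breed) - len(complete)
    if n_dropped:
        log.info("fisher_pool: %d SNPs absent in at least one breed dropped", n_dropped)
    k = complete.shape[1]
    if k < 2:
        raise ValueError("pooling needs p-values from at least two breeds")
    vals = complete.to_numpy(dtype=float)
    n_zero = int((vals == 0).sum())
    if n_zero:
        log.warning("fisher_pool: clamping %d zero p-values to the smallest positive float", n_zero)
        vals = np.maximum(vals, np.nextafter(0.0, 1.0))
    x2 = -2.0 * np.log(vals).sum(axis=1)
    pooled = pd.DataFrame({
        "fisher_x2": x2,
        "df": 2 * k,
        "p_pooled": stats.chi2.sf(x2, df=2 * k),
    }, index=complete.index)
    pooled.attrs["n_dropped"] = n_dropped
    pooled.attrs["n_zero_clamped"] = n_zero
    return pooled


def pooled_inflation(p_pooled: np.ndarray) -> float:
    """lambda_GC of a pooled scan: pooled p converted to 1-df chi-squares."""
    return genomic_inflation(pvalues=np.asarray(p_pooled, dtype=float))


def significance_thresholds(n_snps: int) -> tuple[float, float]:
    """(genome-wide, suggestive) p-value thresholds.

    Genome-wide is the Bonferroni level ``0.05 / n_snps``; the suggestive
    level is fixed at 5e-5.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be at least 1")
    return 0.05 / n_snps, SUGGESTIVE_P


def manhattan_table(
    results: pd.DataFrame, thresholds: tuple[float, float] | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate a per-SNP result table with significance tiers and positions.

    ``results`` needs ``snp, chrom, pos`` and a ``p`` (or ``p_pooled``)
    column.  Adds a ``tier`` column (``none | suggestive | genome-wide``)
    and a genome-cumulative position for plotting; unmapped SNPs are
    excluded with a warning.  Returns the annotated table and per-tier
    counts.
    """
    pcol = "p" if "p" in results.columns else "p_pooled"
    df = results.copy()
    mapped = df["chrom"].notna() & df["pos"].notna()
    if not mapped.all():
        log.warning("manhattan_table: excluding %d unmapped SNPs", int((~mapped).sum()))
        df = df.loc[mapped]
    if thresholds is None:
        thresholds = significance_thresholds(int(df[pcol].notna().sum()))
    genome_wide, suggestive = thresholds
    p = df[pcol].to_numpy(dtype=float)
    tier = np.where(p <= genome_wide, "genome-wide",
                    np.where(p < suggestive, "suggestive", "none"))
    tier = np.where(np.isnan(p), "none", tier)
    df["tier"] = tier
    offset, cum = 0, np.zeros(len(df))
    pos = df["pos"].to_numpy(dtype=float)
    chrom_order = pd.unique(df["chrom"])
    for c in chrom_order:
        on_c = (df["chrom"] == c).to_numpy()
        cum[on_c] = pos[on_c] + offset
        offset += pos[on_c].max() if on_c.any() else 0
    df["cum_pos"] = cum
    counts = {
        "genome-wide": int((df["tier"] == "genome-wide").sum()),
        "suggestive": int((df["tier"] == "suggestive").sum()),
        "none": int((df["tier"] == "none").sum()),
    }
    return df.reset_index(drop=True), counts
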