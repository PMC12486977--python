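"""Population structure (classical MDS on IBS distances) and LD decay.

LD between two loci is the squared correlation of allelic states,

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1-p_A) p_B (1-p_B)),

with the haplotype frequency ``p_AB`` taken from phase when available and
otherwise estimated by expectation-maximization over double heterozygotes.
Pairs are restricted to the same chromosome within a window of at most
1,000 intervening SNPs and 3,000 kb.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from resilind.plink import GenotypePanel

MAX_SNP_SEP = 1000
MAX_BP_SEP = 3_000_000
EM_ITER = 50
EM_TOL = 1e-10


def ibs_distance(panel: GenotypePanel) -> np.ndarray:
    """Pairwise 1 - IBS distance matrix.

    ``IBS_ij`` is the mean over SNPs of ``(2 - |g_i - g_j|) / 2``; missing
    calls are mean-imputed.  Identical genotypes give distance 0, opposite
    homozygotes at every SNP give 1.
    """
    g = panel.dosages()
    if np.isnan(g).any():
        raise ValueError("pair with no jointly called SNPs")
    d = squareform(pdist(g, metric="cityblock")) / (2.0 * g.shape[1])
    np.fill_diagonal(d, 0.0)
    return d


def classical_mds(distance: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a symmetric zero-diagonal distance matrix.

    Double-centers ``-D^2 / 2``, eigendecomposes, and returns the top-``k``
    coordinates scaled by the square root of their eigenvalues, plus the
    full eigenvalue spectrum in decreasing order.
    """
    D = np.asarray(distance, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int(np.sum(vals > 1e-10 * max(vals.max(), 1.0)))
    if k > n_pos:
        raise ValueError(f"requested {k} dimensions but only {n_pos} positive eigenvalues")
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    return coords, vals


def _pair_index(snp_map: pd.DataFrame, max_snp_sep: int, max_bp_sep: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Same-chromosome pair indices within the SNP-count AND bp windows."""
    ii, jj = [], []
    for _, grp in snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        m = idx.size
        for off in range(1, min(max_snp_sep, m - 1) + 1):
            ok = (pos[off:] - pos[:-off]) <= max_bp_sep
            ii.append(idx[:-off][ok])
            jj.append(idx[off:][ok])
    if not ii:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(ii), np.concatenate(jj)


def _r2_phased(hap: np.ndarray, ii: np.ndarray, jj: np.ndarray,
               chunk: int = 100_000) -> np.ndarray:
    ht = np.ascontiguousarray(hap.T, dtype=np.float64)  # (snps, haplotypes)
    n_hap = ht.shape[1]
    freq = ht.mean(axis=1)
    out = np.empty(ii.size)
    for s in range(0, ii.size, chunk):
        sl = slice(s, min(s + chunk, ii.size))
        pa, pb = freq[ii[sl]], freq[jj[sl]]
        pab = np.einsum("ij,ij->i", ht[ii[sl]], ht[jj[sl]]) / n_hap
        den = pa * (1 - pa) * pb * (1 - pb)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[sl] = np.where(den > 0, (pab - pa * pb) ** 2 / den, np.nan)
    return out


def em_haplotype_r2(ga: np.ndarray, gb: np.ndarray,
                    n_iter: int = EM_ITER, tol: float = EM_TOL) -> np.ndarray:
    """r^2 for unphased genotype column pairs via EM haplotype frequencies.

    ``ga, gb`` are (individuals, pairs) allele-count matrices.  Only the
    double-heterozygote cell is phase-ambiguous; its expected split between
    the cis and trans haplotype configurations is iterated to convergence.
    Monomorphic pairs return NaN.
    """
    ga = np.asarray(ga, dtype=np.int64)
    gb = np.asarray(gb, dtype=np.int64)
    n = ga.shape[0]
    counts = {}
    for va in (0, 1, 2):
        for vb in (0, 1, 2):
            counts[va, vb] = ((ga == va) & (gb == vb)).sum(axis=0).astype(float)
    # haplotype codes: allele counted is A1 (genotype = # of A1 alleles)
    c11 = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    c12 = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    c21 = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    c22 = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    dh = counts[1, 1]  # double heterozygotes: A1B1/A2B2 or A1B2/A2B1
    total = 2.0 * n
    pa = ga.mean(axis=0) / 2.0
    pb = gb.mean(axis=0) / 2.0
    f11 = pa * pb
    for _ in range(n_iter):
        f12 = np.clip(pa - f11, 1e-12, None)
        f21 = np.clip(pb - f11, 1e-12, None)
        f22 = np.clip(1 - pa - pb + f11, 1e-12, None)
        cis = f11 * f22
        trans = f12 * f21
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_cis = np.where(cis + trans > 0, cis / (cis + trans), 0.5)
        f11_new = (c11 + dh * frac_cis) / total
        if np.all(np.abs(f11_new - f11) < tol):
            f11 = f11_new
            break
        f11 = f11_new
    den = pa * (1 - pa) * pb * (1 - pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(den > 0, (f11 - pa * pb) ** 2 / den, np.nan)
    return r2


def ld_r2_pairs(
    panel: GenotypePanel,
    max_snp_sep: int = MAX_SNP_SEP,
    max_bp_sep: int = MAX_BP_SEP,
    use_phase: bool | None = None,
) -> pd.DataFrame:
    """Per-pair LD records within the window constraints.

    Returns a frame with ``snp_a, snp_b, chrom, distance_bp, r2``; pairs
    with a monomorphic member are skipped.  ``use_phase`` defaults to
    using phased haplotypes when the panel carries them.
    """
    snp_map = panel.snp_map.reset_index(drop=True)
    ii, jj = _pair_index(snp_map, max_snp_sep, max_bp_sep)
    if ii.size == 0:
        return pd.DataFrame(columns=["snp_a", "snp_b", "chrom", "distance_bp", "r2"])
    if use_phase is None:
        use_phase = panel.phased_haplotypes is not None
    if use_phase:
        if panel.phased_haplotypes is None:
            raise ValueError("panel has no phased haplotypes")
        r2 = _r2_phased(panel.phased_haplotypes, ii, jj)
    else:
        g = panel.genotypes
        r2 = np.empty(ii.size)
        chunk = 200_000
        for s in range(0, ii.size, chunk):
            sl = slice(s, min(s + chunk, ii.size))
            r2[sl] = em_haplotype_r2(g[:, ii[sl]], g[:, jj[sl]])
    out = pd.DataFrame({
        "snp_a": snp_map["snp"].to_numpy()[ii],
        "snp_b": snp_map["snp"].to_numpy()[jj],
        "chrom": snp_map["chrom"].to_numpy()[ii],
        "distance_bp": snp_map["pos"].to_numpy()[jj] - snp_map["pos"].to_numpy()[ii],
        "r2": r2,
    })
    return out.dropna(subset=["r2"]).reset_index(drop=True)


def ld_decay_curve(records: pd.DataFrame, bin_width_bp: int = 100_000) -> pd.DataFrame:
    """Mean r^2 per physical-distance bin, with pair counts.

    Bins without pairs are reported with NaN mean (missing, not zero).
    """
    if records.empty:
        raise ValueError("no LD records to bin")
    edges = np.arange(0, records["distance_bp"].max() + bin_width_bp, bin_width_bp)
    binned = pd.cut(records["distance_bp"], edges, right=True)
    g = records.groupby(binned, observed=False)["r2"]
    out = pd.DataFrame({
        "bin_start_bp": edges[:-1],
        "bin_end_bp": edges[1:],
        "mean_r2": g.mean().to_numpy(),
        "n_pairs": g.size().to_numpy(),
    })
    return out
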