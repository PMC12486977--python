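"""Animal-model genetic evaluation with a genomic relationship matrix.

Two univariate animal models are supported:

* ``P`` (first lactation, one record per animal): ``y = Xb + Zu + e``
* ``M`` (repeated records): ``y = Xb + Zu + Wpe + e`` with a
  permanent-environment term sharing the animal incidence

with ``u ~ N(0, G sigma2_u)``, ``pe ~ N(0, I sigma2_pe)`` and
``e ~ N(0, I sigma2_e)``; ``G`` is the VanRaden genomic relationship
matrix.  Variance components are REML estimates: a profiled
eigendecomposition search for the single-record model, a direct restricted
log-likelihood optimization for the repeated-records model.  GEBVs are
BLUPs from the mixed-model equations, reliabilities come from prediction
error variances, ``r2_i = 1 - PEV_i / (g_ii sigma2_u)``, and de-regressed
pseudo-phenotypes are ``u_i / r2_i`` standardized within group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from resilind.plink import GenotypePanel

log = logging.getLogger(__name__)

#: minimum number of distinct animals per fixed-effect level
MIN_LEVEL_SIZE = 6
#: GRM conditioning weight: G* = 0.99 G + 0.01 I
GRM_BLEND = 0.99
#: variance floor, as a fraction of the phenotypic variance
VAR_FLOOR_FRAC = 1e-8

SEASONS = {3: "spring", 4: "spring", 5: "spring", 6: "summer", 7: "summer",
           8: "summer", 9: "autumn", 10: "autumn", 11: "autumn",
           12: "winter", 1: "winter", 2: "winter"}

COMPLETENESS_BINS = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0 + 1e-9]
COMPLETENESS_LABELS = ["50-<60", "60-<70", "70-<80", "80-<90", ">=90"]


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    sigma2_pe: float = 0.0
    converged: bool = True
    boundary: bool = False
    loglik: float = float("nan")

    @property
    def total(self) -> float:
        return self.sigma2_u + self.sigma2_pe + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_u / self.total

    @property
    def repeatability(self) -> float:
        return (self.sigma2_u + self.sigma2_pe) / self.total


def compute_grm_vanraden(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """VanRaden GRM ``G = ZZ' / (2 sum p(1-p))`` with ``Z = genotypes - 2p``.

    Monomorphic SNPs are excluded with a warning.  Returns ``(G, used)``
    where ``used`` is the boolean mask of SNPs that entered the matrix.
    """
    g = panel.dosages()
    p = g.mean(axis=0) / 2.0
    used = (p > 0) & (p < 1)
    if not used.all():
        warnings.warn(f"excluding {int((~used).sum())} monomorphic SNPs from the GRM")
    z = g[:, used] - 2.0 * p[used]
    denom = 2.0 * np.sum(p[used] * (1.0 - p[used]))
    return z @ z.T / denom, used


def condition_grm(grm: np.ndarray, blend: float = GRM_BLEND) -> np.ndarray:
    """Blend with the identity, ``G* = w G + (1-w) I``, to ensure invertibility."""
    return blend * grm + (1.0 - blend) * np.eye(grm.shape[0])


def season_class(month: int) -> str:
    return SEASONS[int(month)]


def completeness_class(coverage: float) -> str:
    """Lactation-data completeness class from the covered fraction of the window."""
    idx = np.digitize([coverage], COMPLETENESS_BINS)[0] - 1
    if idx < 0:
        return "<50"
    return COMPLETENESS_LABELS[min(idx, len(COMPLETENESS_LABELS) - 1)]


def build_design(
    pheno: pd.DataFrame,
    covariates: tuple[str, ...] = ("age_first_calving_months",),
    factors: tuple[str, ...] = ("hys", "completeness_class"),
    min_level_size: int = MIN_LEVEL_SIZE,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Fixed-effect design matrix with rare-level filtering.

    Levels of any factor with fewer than ``min_level_size`` distinct
    animals are excluded (their records dropped), repeated until stable.
    Returns ``(X, retained_pheno)``; ``X`` has an intercept, centered
    covariates and treatment-coded factor dummies.
    """
    df = pheno.copy()
    while True:
        n0 = len(df)
        for f in factors:
            sizes = df.groupby(f)["animal_id"].nunique()
            ok_levels = sizes.index[sizes >= min_level_size]
            df = df[df[f].isin(ok_levels)]
        if len(df) == n0:
            break
    if df.empty:
        raise ValueError("no records remain after rare-level filtering")
    cols = [np.ones(len(df))]
    for c in covariates:
        v = df[c].to_numpy(dtype=float)
        cols.append(v - v.mean())
    X = np.column_stack(cols)
    for f in factors:
        d = pd.get_dummies(df[f], drop_first=True, dtype=float)
        if d.shape[1]:
            X = np.column_stack([X, d.to_numpy()])
    # drop linearly dependent columns
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * np.abs(np.diag(r)).max()
    return X[:, keep], df.reset_index(drop=True)


def _profile_reml(y: np.ndarray, X: np.ndarray, d: np.ndarray, Uty: np.ndarray,
                  UtX: np.ndarray) -> tuple[float, float, float, bool]:
    """REML for y = Xb + u + e with eigendecomposed G* = U diag(d) U'.

    Profiles out sigma2_e and maximizes over the variance ratio
    kappa = sigma2_u / sigma2_e.  Returns (kappa, sigma2_e, loglik, boundary).
    """
    n, p = X.shape

    def neg_rll(log_kappa: float) -> float:
        kappa = np.exp(log_kappa)
        w = 1.0 / (kappa * d + 1.0)
        XtWX = UtX.T @ (UtX * w[:, None])
        XtWy = UtX.T @ (w * Uty)
        b = np.linalg.solve(XtWX, XtWy)
        r = Uty - UtX @ b
        rss = float(np.sum(w * r * r))
        sign, logdet_x = np.linalg.slogdet(XtWX)
        return 0.5 * ((n - p) * np.log(rss / (n - p))
                      + np.sum(np.log(kappa * d + 1.0)) + logdet_x)

    res = optimize.minimize_scalar(neg_rll, bounds=(-14.0, 14.0), method="bounded",
                                   options={"xatol": 1e-8})
    log_kappa = float(res.x)
    kappa = np.exp(log_kappa)
    w = 1.0 / (kappa * d + 1.0)
    XtWX = UtX.T @ (UtX * w[:, None])
    b = np.linalg.solve(XtWX, UtX.T @ (w * Uty))
    r = Uty - UtX @ b
    sigma2_e = float(np.sum(w * r * r)) / (n - p)
    boundary = log_kappa < -13.0 or log_kappa > 13.0
    return kappa, sigma2_e, -float(res.fun), boundary


def fit_single_record_model(
    y: np.ndarray, X: np.ndarray, grm_star: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    compute_reliability: bool = True,
) -> tuple[VarianceComponents, pd.DataFrame]:
    """Model P: one record per animal, no permanent-environment term."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if eig is None:
        d, U = np.linalg.eigh(grm_star)
    else:
        d, U = eig
    d = np.clip(d, 1e-10, None)
    Uty, UtX = U.T @ y, U.T @ X
    kappa, sigma2_e, ll, boundary = _profile_reml(y, X, d, Uty, UtX)
    sigma2_u = kappa * sigma2_e
    vc = VarianceComponents(sigma2_u=sigma2_u, sigma2_e=sigma2_e, loglik=ll,
                            boundary=boundary)
    # BLUP: u_hat = kappa * U diag(d) W (Uty - UtX b)
    w = 1.0 / (kappa * d + 1.0)
    XtWX = UtX.T @ (UtX * w[:, None])
    b = np.linalg.solve(XtWX, UtX.T @ (w * Uty))
    u_hat = U @ (kappa * d * w * (Uty - UtX @ b))
    result = pd.DataFrame({"gebv": u_hat})
    if compute_reliability:
        # MME coefficient matrix; C^{uu} * sigma2_e = PEV
        p = X.shape[1]
        alpha = 1.0 / max(kappa, 1e-12)
        Ginv = (U * (1.0 / d)) @ U.T
        C = np.zeros((p + n, p + n))
        C[:p, :p] = X.T @ X
        C[:p, p:] = X.T
        C[p:, :p] = X
        C[p:, p:] = np.eye(n) + alpha * Ginv
        Cinv = np.linalg.inv(C)
        pev = np.diag(Cinv)[p:] * sigma2_e
        g_ii = np.diag(grm_star)
        rel = np.clip(1.0 - pev / (g_ii * max(sigma2_u, 1e-12)), 0.0, 1.0)
        result["pev"] = pev
        result["reliability"] = rel
    return vc, result


def _neg_rll_general(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                     ZGZt: np.ndarray, ZZt: np.ndarray) -> float:
    s2u, s2pe, s2e = np.exp(theta)
    n, p = X.shape
    V = s2u * ZGZt + s2pe * ZZt + s2e * np.eye(n)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e30
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = np.linalg.solve(L.T, np.linalg.solve(L, y))
    Vi_X = np.linalg.solve(L.T, np.linalg.solve(L, X))
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e30
    b = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ b)
    return 0.5 * (logdet_v + logdet_x + yPy)


def fit_repeated_records_model(
    y: np.ndarray, X: np.ndarray, Z: np.ndarray, grm_star: np.ndarray,
    compute_reliability: bool = True,
) -> tuple[VarianceComponents, pd.DataFrame]:
    """Model M: repeated records with a permanent-environment term.

    ``Z`` is the (records x animals) incidence matrix shared by the
    additive-genetic and permanent-environment effects.
    """
    y = np.asarray(y, dtype=float)
    n_rec = y.size
    n_animal = Z.shape[1]
    ZGZt = Z @ grm_star @ Z.T
    ZZt = Z @ Z.T
    var_y = float(np.var(y))
    x0 = np.log(np.array([0.2, 0.2, 0.6]) * var_y)
    res = optimize.minimize(
        _neg_rll_general, x0, args=(y, X, ZGZt, ZZt), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 600},
    )
    s2u, s2pe, s2e = np.exp(res.x)
    floor = VAR_FLOOR_FRAC * var_y
    boundary = bool(min(s2u, s2pe, s2e) < floor)
    s2u, s2pe, s2e = (max(v, floor) for v in (s2u, s2pe, s2e))
    vc = VarianceComponents(sigma2_u=s2u, sigma2_e=s2e, sigma2_pe=s2pe,
                            converged=bool(res.success), boundary=boundary,
                            loglik=-float(res.fun))
    if not res.success:
        log.warning("repeated-records REML did not fully converge: %s", res.message)

    # MME with R = I sigma2_e
    p = X.shape[1]
    Ginv = np.linalg.inv(grm_star)
    ZtZ = Z.T @ Z
    C = np.zeros((p + 2 * n_animal, p + 2 * n_animal))
    C[:p, :p] = X.T @ X
    C[:p, p:p + n_animal] = X.T @ Z
    C[:p, p + n_animal:] = X.T @ Z
    C[p:p + n_animal, :p] = Z.T @ X
    C[p + n_animal:, :p] = Z.T @ X
    C[p:p + n_animal, p:p + n_animal] = ZtZ + (s2e / s2u) * Ginv
    C[p:p + n_animal, p + n_animal:] = ZtZ
    C[p + n_animal:, p:p + n_animal] = ZtZ
    C[p + n_animal:, p + n_animal:] = ZtZ + (s2e / s2pe) * np.eye(n_animal)
    rhs = np.concatenate([X.T @ y, Z.T @ y, Z.T @ y])
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    u_hat = sol[p:p + n_animal]
    result = pd.DataFrame({"gebv": u_hat})
    if compute_reliability:
        pev = np.diag(Cinv)[p:p + n_animal] * s2e
        g_ii = np.diag(grm_star)
        result["pev"] = pev
        result["reliability"] = np.clip(1.0 - pev / (g_ii * s2u), 0.0, 1.0)
    return vc, result


def fit_animal_model(
    pheno: pd.DataFrame,
    grm: np.ndarray,
    animal_ids: pd.Index | np.ndarray,
    response: str,
    repeated: bool = False,
    covariates: tuple[str, ...] = ("age_first_calving_months",),
    factors: tuple[str, ...] = ("hys", "completeness_class"),
) -> tuple[VarianceComponents, pd.DataFrame]:
    """Fit the P (``repeated=False``) or M (``repeated=True``) animal model.

    ``pheno`` holds one row per record with the response and the fixed-
    effect columns; ``animal_ids`` orders the GRM.  For M, a first-versus-
    higher lactation factor is added automatically when a ``lactation``
    column is present.  Returns the variance components and a per-animal
    table (``animal_id, gebv, pev, reliability``).
    """
    if repeated and "lactation" in pheno.columns:
        pheno = pheno.copy()
        pheno["lactation_class"] = np.where(pheno["lactation"] == 1, "first", "higher")
        if pheno["lactation_class"].nunique() > 1:
            factors = tuple(factors) + ("lactation_class",)
    X, df = build_design(pheno, covariates=covariates, factors=factors)
    y = df[response].to_numpy(dtype=float)
    animal_ids = pd.Index(animal_ids)
    used_animals = pd.Index(pd.unique(df["animal_id"]))
    used_animals = animal_ids[animal_ids.isin(used_animals)]
    idx = animal_ids.get_indexer(used_animals)
    G = condition_grm(grm[np.ix_(idx, idx)])
    row = used_animals.get_indexer(df["animal_id"])
    if not repeated:
        if df["animal_id"].duplicated().any():
            raise ValueError("model P requires one record per animal")
        order = np.argsort(row)
        vc, res = fit_single_record_model(y[order], X[order], G)
    else:
        Z = np.zeros((len(df), len(used_animals)))
        Z[np.arange(len(df)), row] = 1.0
        vc, res = fit_repeated_records_model(y, X, Z, G)
    res.insert(0, "animal_id", used_animals.to_numpy())
    return vc, res


def deregress_and_standardize(
    result: pd.DataFrame, group: np.ndarray | pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """De-regress GEBVs by their reliabilities and z-standardize per group.

    ``deregressed = gebv / reliability``; standardization (mean 0, SD 1) is
    within each level of ``group`` (a single group when omitted).  Animals
    with non-positive or undefined reliability are excluded and returned
    in the audit frame.
    """
    df = result.copy()
    if group is None:
        df["group"] = "all"
    else:
        df["group"] = np.asarray(group)
    ok = df["reliability"].notna() & (df["reliability"] > 0)
    audit = df.loc[~ok].assign(reason="non_positive_reliability")
    df = df.loc[ok].copy()
    df["deregressed"] = df["gebv"] / df["reliability"]
    z = df.groupby("group")["deregressed"].transform(
        lambda v: (v - v.mean()) / v.std(ddof=1)
    )
    df["pseudo_phenotype"] = z
    return df.reset_index(drop=True), audit.reset_index(drop=True)
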