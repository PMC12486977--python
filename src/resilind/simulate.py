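"""Synthetic multi-breed genotypes and longitudinal milking data.

Genotype model
--------------
Ancestral allele frequencies are drawn uniformly on (0.1, 0.9); each breed's
frequency is Beta-distributed around the ancestral value with the configured
fixation index F_ST (a Balding-Nichols-style model).  Haplotypes come from a
latent Gaussian AR(1) process along each chromosome, thresholded at the
breed-specific frequency quantile: marginals are exactly Bernoulli(p) while
adjacent markers stay correlated, so r^2 decays geometrically with marker
separation at a rate set by ``ld_persistence``.

Phenotype model
---------------
Each cow-lactation is a Wood gamma curve ``a * t^b * exp(-c t)`` minus
disturbance events (Poisson onsets, half-normal depths, exponential recovery
with the configured half-life) plus AR(1) daily noise.  Two cow-level
parameters carry additive-genetic signal built from the genotypes:

* log disturbance susceptibility (scales event depths) — drives the
  variance-type resilience indicators;
* the AR(1) persistence of the daily residual — drives the lag-1
  autocorrelation indicator.

The two traits use disjoint causal loci (QTL for susceptibility, a purely
polygenic architecture for persistence by default), so their indicator
traits have separate genetic backgrounds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from resilind.config import ConfigError, SimConfig
from resilind.plink import GenotypePanel


@dataclass
class TruthRecord:
    """Ground truth attached to a simulated data set."""

    true_breeding_value: pd.DataFrame  # per-animal columns: one per trait
    qtl_positions: dict[str, np.ndarray]  # trait -> SNP column indices
    realized_h2: dict[str, float]


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Simulate a phased multi-breed SNP panel with LD and F_ST structure."""
    rng = _spawn(config.seed, 0)
    m_raw = config.n_chrom * config.n_snp_per_chrom
    p_anc = rng.uniform(0.1, 0.9, size=m_raw)
    fst = float(config.fst)
    if fst > 0:
        shape = (1.0 - fst) / fst
        p_breed = rng.beta(
            p_anc * shape, (1.0 - p_anc) * shape, size=(config.n_breeds, m_raw)
        )
        p_breed = np.clip(p_breed, 1e-4, 1 - 1e-4)
    else:
        p_breed = np.tile(p_anc, (config.n_breeds, 1))

    a = float(config.ld_persistence)
    innov_sd = np.sqrt(max(1.0 - a * a, 0.0))
    n_total = config.n_individuals
    haplos = np.empty((2 * n_total, m_raw), dtype=np.uint8)
    thresholds = stats.norm.ppf(p_breed)  # allele = 1 iff latent < threshold

    row = 0
    for b, n_b in enumerate(config.n_per_breed):
        n_hap = 2 * n_b
        latent = np.empty((n_hap, config.n_snp_per_chrom))
        for c in range(config.n_chrom):
            sl = slice(c * config.n_snp_per_chrom, (c + 1) * config.n_snp_per_chrom)
            eps = rng.standard_normal((n_hap, config.n_snp_per_chrom))
            latent[:, 0] = eps[:, 0]
            for j in range(1, config.n_snp_per_chrom):
                latent[:, j] = a * latent[:, j - 1] + innov_sd * eps[:, j]
            haplos[row : row + n_hap, sl] = latent < thresholds[b, sl]
        row += n_hap

    genotypes = (haplos[0::2] + haplos[1::2]).astype(np.int8)

    # map: strictly increasing positions from positive gaps
    mean_gap = max(config.chrom_length_bp // (config.n_snp_per_chrom + 1), 2)
    chroms, positions = [], []
    for c in range(config.n_chrom):
        gaps = rng.integers(1, 2 * mean_gap, size=config.n_snp_per_chrom)
        positions.append(np.cumsum(gaps))
        chroms.append(np.full(config.n_snp_per_chrom, c + 1))
    snp_map = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms).astype(str),
            "snp": [f"snp{c}_{i}" for c in range(1, config.n_chrom + 1)
                    for i in range(1, config.n_snp_per_chrom + 1)],
            "cm": 0.0,
            "pos": np.concatenate(positions),
            "a1": "A",
            "a2": "B",
        }
    )

    breed_names = np.repeat(config.breed_names, config.n_per_breed)
    iids = [f"{b}_{i:05d}" for b in config.breed_names for i in range(1, dict(zip(config.breed_names, config.n_per_breed))[b] + 1)]
    samples = pd.DataFrame({"fid": breed_names, "iid": iids})

    panel = GenotypePanel(
        genotypes=genotypes,
        snp_map=snp_map,
        samples=samples,
        breed_label=np.asarray(breed_names),
        phased_haplotypes=haplos,
    )
    freq = panel.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= config.maf_floor
    if not keep.all():
        panel = panel.subset(snps=keep)
    return panel


def simulate_breeding_values(
    panel: GenotypePanel,
    rng: np.random.Generator,
    n_qtl: int = 0,
    qtl_effect_sd: float = 0.7,
    causal_snps: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive breeding values from standardized genotypes.

    Background effects are iid normal over the causal pool (scaled to unit
    polygenic variance); ``n_qtl`` loci additionally receive large effects
    of magnitude ``qtl_effect_sd`` (random sign) on the standardized
    genotype scale.  Returns the breeding-value vector standardized to zero
    mean and unit sample variance, plus the QTL column indices.
    """
    pool = np.arange(panel.n_snps) if causal_snps is None else np.asarray(causal_snps)
    g = panel.dosages()[:, pool]
    p = g.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    ok = sd > 0
    z = (g[:, ok] - 2.0 * p[ok]) / sd[ok]
    pool = pool[ok]
    beta = rng.standard_normal(z.shape[1]) / np.sqrt(z.shape[1])
    u = z @ beta
    u = (u - u.mean()) / u.std()
    qtl_idx = np.array([], dtype=int)
    if n_qtl > 0:
        which = rng.choice(z.shape[1], size=n_qtl, replace=False)
        qtl_idx = pool[which]
        gamma = qtl_effect_sd * rng.choice([-1.0, 1.0], size=n_qtl)
        u = u + z[:, which] @ gamma
    u = (u - u.mean()) / u.std()
    return u, qtl_idx


def simulate_indicator_trait(
    panel: GenotypePanel,
    h2: float,
    rng: np.random.Generator | int | None = None,
    n_qtl: int = 0,
    qtl_effect_sd: float = 0.7,
    causal_snps: np.ndarray | None = None,
) -> tuple[np.ndarray, TruthRecord]:
    """A single quantitative trait ``y = g + e`` with exact heritability.

    The additive and environmental parts are both standardized in-sample,
    so ``var(g)/var(y) == h2`` up to the (small) sampling covariance between
    the two parts.  This is the clean architecture used for REML
    parameter-recovery checks of log-variance indicator traits.
    """
    if not 0.0 <= h2 < 1.0:
        raise ConfigError(f"h2 must lie in [0, 1), got {h2}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = panel.n_individuals
    if h2 == 0.0:
        y = rng.standard_normal(n)
        truth = TruthRecord(
            true_breeding_value=pd.DataFrame({"trait": np.zeros(n)}, index=panel.samples["iid"]),
            qtl_positions={"trait": np.array([], dtype=int)},
            realized_h2={"trait": 0.0},
        )
        return y, truth
    u, qtl = simulate_breeding_values(panel, rng, n_qtl, qtl_effect_sd, causal_snps)
    e = rng.standard_normal(n)
    e = (e - e.mean()) / e.std()
    y = np.sqrt(h2) * u + np.sqrt(1.0 - h2) * e
    realized = float(h2 * np.var(u) / np.var(y))
    truth = TruthRecord(
        true_breeding_value=pd.DataFrame({"trait": np.sqrt(h2) * u}, index=panel.samples["iid"]),
        qtl_positions={"trait": qtl},
        realized_h2={"trait": realized},
    )
    return y, truth


def _wood_curve(t: np.ndarray, scale: np.ndarray, b: float = 0.10, c: float = 0.0022) -> np.ndarray:
    """Wood gamma lactation curve, broadcast over (lactations, days)."""
    return scale[:, None] * np.power(t, b)[None, :] * np.exp(-c * t)[None, :]


def simulate_phenotypes(
    panel: GenotypePanel, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate milking-event records for every cow in the panel.

    Returns ``(milkings, calvings, truth)``:

    * ``milkings`` — long table with ``animal_id, farm_id, timestamp,
      yield_kg`` (2-3 timed milking events per retained cow-day);
    * ``calvings`` — one row per cow-lactation with calving date and the
      age-at-first-calving covariate (months);
    * ``truth`` — per-cow breeding values for the susceptibility (``vd``)
      and persistence (``rauto``) channels, QTL positions and realized
      heritabilities of the two simulated cow parameters.
    """
    for trait, h2 in dict(config.h2_target).items():
        if not 0.0 <= float(h2) < 1.0:
            raise ConfigError(f"h2_target[{trait!r}] out of range")
    rng = _spawn(config.seed, 1)
    n = panel.n_individuals
    iid = panel.samples["iid"].to_numpy()
    breed = panel.breed_label if panel.breed_label is not None else np.repeat("B1", n)

    # disjoint causal pools: odd columns feed susceptibility, even feed persistence
    pool_vd = np.arange(1, panel.n_snps, 2)
    pool_r = np.arange(0, panel.n_snps, 2)
    h2_vd = float(dict(config.h2_target).get("vd", 0.15))
    h2_r = float(dict(config.h2_target).get("rauto", 0.05))
    u_vd, qtl_vd = simulate_breeding_values(panel, rng, config.n_qtl, config.qtl_effect_sd, pool_vd)
    u_r, qtl_r = simulate_breeding_values(panel, rng, 0, 0.0, pool_r)

    e_vd = rng.standard_normal(n)
    e_vd = (e_vd - e_vd.mean()) / e_vd.std()
    log_susc = config.log_susceptibility_sd * (np.sqrt(h2_vd) * u_vd + np.sqrt(1 - h2_vd) * e_vd)
    susceptibility = np.exp(log_susc)
    e_r = rng.standard_normal(n)
    e_r = (e_r - e_r.mean()) / e_r.std()
    persistence = np.clip(
        config.persistence_mean + config.persistence_sd * (np.sqrt(h2_r) * u_r + np.sqrt(1 - h2_r) * e_r),
        0.02, 0.90,
    )

    realized_h2 = {
        "vd": float(np.var(np.sqrt(h2_vd) * u_vd) / np.var(log_susc / config.log_susceptibility_sd))
        if config.log_susceptibility_sd > 0 else float("nan"),
        "rauto": float(np.var(np.sqrt(h2_r) * u_r)
                       / np.var(np.sqrt(h2_r) * u_r + np.sqrt(1 - h2_r) * e_r)),
    }

    # farms partitioned within breed so every farm is single-breed
    farm_ids = np.array([f"F{k:03d}" for k in range(1, config.n_farms + 1)])
    farm_breed = np.repeat(
        np.arange(config.n_breeds),
        np.maximum(np.round(np.asarray(config.n_per_breed) / n * config.n_farms).astype(int), 1),
    )[: config.n_farms]
    if farm_breed.size < config.n_farms:
        farm_breed = np.concatenate([farm_breed, np.full(config.n_farms - farm_breed.size, config.n_breeds - 1)])
    cow_farm = np.empty(n, dtype=object)
    breed_names = config.breed_names
    for b in range(config.n_breeds):
        cows_b = np.flatnonzero(breed == breed_names[b])
        farms_b = farm_ids[farm_breed == b]
        if farms_b.size == 0:
            farms_b = farm_ids[:1]
        cow_farm[cows_b] = rng.choice(farms_b, size=cows_b.size)

    # lactation roster
    n_lact = rng.integers(1, config.n_lactations_max + 1, size=n)
    afc_months = np.round(rng.normal(26.0, 2.0, size=n), 1)
    start = pd.Timestamp(config.study_start)
    first_calving = start + pd.to_timedelta(rng.integers(0, 365, size=n), unit="D")

    rows = []
    for l in range(1, config.n_lactations_max + 1):
        has = n_lact >= l
        offs = (l - 1) * 370 + rng.integers(-15, 16, size=n)
        rows.append(pd.DataFrame({
            "animal_id": iid[has],
            "farm_id": cow_farm[has],
            "lactation": l,
            "calving_date": (first_calving + pd.to_timedelta(offs, unit="D"))[has],
            "age_first_calving_months": afc_months[has],
        }))
    calvings = pd.concat(rows, ignore_index=True).sort_values(["animal_id", "lactation"]).reset_index(drop=True)

    lo, hi = config.lactation_days
    days = np.arange(lo, hi + 1)
    L = len(calvings)
    cow_index = pd.Series(np.arange(n), index=iid)
    lact_cow = cow_index[calvings["animal_id"]].to_numpy()

    parity_scale = np.where(calvings["lactation"].to_numpy() == 1, 1.0, 1.12)
    wood_scale = rng.normal(20.0, 2.0, size=n)[lact_cow] * parity_scale
    yields = _wood_curve(days.astype(float), wood_scale)

    # disturbance events with exponential recovery
    n_events = rng.poisson(config.disturbance_rate, size=L)
    perturbation = np.zeros_like(yields)
    for i in np.flatnonzero(n_events):
        s_i = susceptibility[lact_cow[i]]
        for _ in range(n_events[i]):
            onset = rng.integers(lo, hi - 10)
            depth = abs(rng.normal(0.0, config.disturbance_depth_sd)) * s_i
            mask = days >= onset
            perturbation[i, mask] -= depth * np.exp(-np.log(2.0) * (days[mask] - onset) / config.recovery_halflife_days)

    # AR(1) daily noise, per-cow persistence; susceptibility scales the whole
    # deviation process (event depths above and residual noise here), so the
    # lag-1 autocorrelation of the deviations stays invariant to it — the
    # variance and autocorrelation channels stay genetically separable
    if config.noise_sd > 0:
        phi = persistence[lact_cow]
        noise = np.empty((L, days.size))
        eps = rng.standard_normal((L, days.size)) * config.noise_sd
        noise[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - phi * phi)
        for j in range(1, days.size):
            noise[:, j] = phi * noise[:, j - 1] + scale * eps[:, j]
        perturbation += susceptibility[lact_cow][:, None] * noise

    # perturbations act multiplicatively (base * exp(pert/base) ~ base + pert
    # for small perturbations): yields stay positive without hard clipping,
    # which would otherwise create flat runs with spurious autocorrelation
    yields = yields * np.exp(perturbation / yields)

    # retention masks: cow-day missing + whole-farm outage days
    keep = rng.random((L, days.size)) >= config.missing_day_prob
    calving_ord = calvings["calving_date"].to_numpy().astype("datetime64[D]").astype(int)
    dates_ord = calving_ord[:, None] + days[None, :]
    farm_codes = pd.Categorical(calvings["farm_id"]).codes
    if config.farm_outage_prob > 0:
        all_dates = np.unique(dates_ord)
        date_pos = {d: k for k, d in enumerate(all_dates)}
        outage = rng.random((farm_codes.max() + 1, all_dates.size)) < config.farm_outage_prob
        pos = np.vectorize(date_pos.get)(dates_ord)
        keep &= ~outage[farm_codes[:, None], pos]

    # milking-event decomposition: milk is secreted at each day's rate
    # (daily yield / 24 h) and each milking collects the milk accumulated
    # since the previous one, so the overnight milking carries the previous
    # evening's production — the proportional day-splitting rule applied
    # downstream then reconstructs daily production consistently.  Milking
    # clock times are jittered per day; the same jittered times drive the
    # secretion split and the recorded timestamps.
    n_milk = rng.choice([2, 3], size=n, p=[0.45, 0.55])
    schedules = {2: np.array([5.5, 17.0]), 3: np.array([5.0, 13.0, 21.0])}
    out = []
    for nm, sched in schedules.items():
        li = np.flatnonzero(n_milk[lact_cow] == nm)
        if li.size == 0:
            continue
        D = days.size
        times = sched[None, None, :] + rng.uniform(-0.5, 0.5, size=(li.size, D, nm))
        rate = yields[li] / 24.0  # kg per hour, constant within a day
        amounts = np.empty((li.size, D, nm))
        # within-day collections: interval fully inside the day
        for k in range(1, nm):
            amounts[:, :, k] = rate * (times[:, :, k] - times[:, :, k - 1])
        # first milking: previous day's tail (its rate) plus today's morning
        prev_last = np.empty((li.size, D))
        prev_last[:, 1:] = times[:, :-1, nm - 1]
        prev_last[:, 0] = sched[-1]  # phantom pre-series evening milking
        prev_rate = np.empty((li.size, D))
        prev_rate[:, 1:] = rate[:, :-1]
        prev_rate[:, 0] = rate[:, 0]
        amounts[:, :, 0] = prev_rate * (24.0 - prev_last) + rate * times[:, :, 0]
        sub_keep = keep[li]
        lac_idx, day_idx = np.nonzero(sub_keep)
        if lac_idx.size == 0:
            continue
        lrows = li[lac_idx]
        base_ord = dates_ord[lrows, day_idx]
        for k in range(nm):
            ts = (base_ord.astype("datetime64[D]").astype("datetime64[s]")
                  + (times[lac_idx, day_idx, k] * 3600).astype("timedelta64[s]"))
            out.append(pd.DataFrame({
                "animal_id": calvings["animal_id"].to_numpy()[lrows],
                "farm_id": calvings["farm_id"].to_numpy()[lrows],
                "timestamp": ts,
                "yield_kg": np.round(amounts[lac_idx, day_idx, k], 3),
            }))
    milkings = pd.concat(out, ignore_index=True)
    milkings = milkings.sort_values(["animal_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    truth = TruthRecord(
        true_breeding_value=pd.DataFrame(
            {"vd": np.sqrt(h2_vd) * u_vd, "rauto": np.sqrt(h2_r) * u_r,
             "log_susceptibility": log_susc, "persistence": persistence},
            index=pd.Index(iid, name="animal_id"),
        ),
        qtl_positions={"vd": qtl_vd, "rauto": qtl_r},
        realized_h2=realized_h2,
    )
    return milkings, calvings, truth
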