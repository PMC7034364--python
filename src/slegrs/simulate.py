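"""Synthetic case/control cohorts with GRS-structured phenotypes.

Generates the three layers every downstream stage needs without real
data: (1) biallelic genotypes in Hardy-Weinberg proportions with
log-normal per-SNP true odds ratios, (2) case status from a logistic
disease model on the true weighted score, and (3) case phenotypes —
GRS-dependent age at diagnosis, ordinal organ damage (SDI), binary
subphenotypes/serology, and right-censored event ages (first damage,
cardiovascular/arterial/venous events, end-stage renal disease, death)
with exponential hazards log-linear in the GRS.

All draws are reproducible from ``SimConfig.seed``; per-stage substreams
are spawned deterministically from that one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .genotypes import GenotypeMatrix
from .panel import RiskPanel
from .scores import ScoreSet, compute_scores

# Baseline prevalences and log-odds-per-GRS-unit effects of the binary
# case subphenotypes (ACR-82 criteria and antiphospholipid serology).
DEFAULT_BINARY_OUTCOMES: dict[str, tuple[float, float]] = {
    # name: (baseline prevalence among cases, log-odds per GRS unit)
    "malar_rash": (0.56, -0.06),
    "discoid_rash": (0.24, -0.06),
    "photosensitivity": (0.68, -0.13),
    "oral_ulcers": (0.25, 0.02),
    "arthritis": (0.80, -0.09),
    "serositis": (0.45, -0.05),
    "renal_disorder": (0.34, 0.255),
    "neurological_disorder": (0.10, 0.09),
    "haematological_disorder": (0.62, 0.05),
    "immunological_disorder": (0.69, 0.255),
    "ana": (0.98, 0.31),
    "dsdna": (0.62, 0.27),
    "sm": (0.13, 0.10),
    "la": (0.22, 0.19),
    "acl_igg": (0.27, 0.13),
    "acl_igm": (0.13, 0.12),
    "ab2gpi_igg": (0.18, 0.28),
    "ab2gpi_igm": (0.11, -0.09),
}

SEROLOGY = ("dsdna", "sm", "la", "acl_igg", "acl_igm",
            "ab2gpi_igg", "ab2gpi_igm")

# Per-year baseline hazards of post-diagnosis events at the cohort-mean
# GRS, chosen to yield realistic lifetime event fractions under ~30-60
# years of follow-up (damage in most patients, ESRD rare).
DEFAULT_EVENT_HAZARDS: dict[str, float] = {
    "first_sdi": 0.030,
    "first_cve": 0.010,
    "first_ae": 0.006,
    "first_vte": 0.005,
    "esrd": 0.0012,
    "death": 0.010,
}

EVENT_NAMES = tuple(DEFAULT_EVENT_HAZARDS)


@dataclass
class SimConfig:
    """Generator parameters; ``seed`` is mandatory.

    ``or_distribution`` is the (location, scale) of ln(OR) for per-SNP
    true odds ratios; ``event_log_hr_per_grs_unit`` scales every event
    hazard multiplicatively in the centred GRS.
    """

    seed: int
    n_individuals: int = 3803
    n_snps: int = 57
    risk_allele_freq_range: tuple[float, float] = (0.05, 0.95)
    or_distribution: tuple[float, float] = (np.log(1.15), 0.15)
    baseline_prevalence: float = 1001 / 3803
    onset_log_hazard_per_grs_unit: float = 0.13
    onset_baseline_hazard: float = 1 / 36
    event_log_hr_per_grs_unit: dict[str, float] = field(
        default_factory=lambda: {"first_sdi": 0.15, "first_cve": 0.18,
                                 "first_ae": 0.28, "first_vte": 0.10,
                                 "esrd": 0.55, "death": 0.26})
    subphenotype_effects: dict[str, float] = field(
        default_factory=lambda: {k: v for k, (_, v)
                                 in DEFAULT_BINARY_OUTCOMES.items()})
    sdi_log_or_per_grs_unit: float = 0.12
    event_baseline_hazards: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_HAZARDS))
    admin_censor_age: float = 85.0
    serology_missing_rate: float = 0.2

    def __post_init__(self) -> None:
        lo, hi = self.risk_allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("risk_allele_freq_range must lie in open (0,1)")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0,1)")
        if any(h < 0 for h in self.event_baseline_hazards.values()):
            raise ValueError("hazards must be >= 0")
        unknown = set(self.event_baseline_hazards) - set(EVENT_NAMES)
        if unknown:
            raise ValueError(f"unknown event name: {sorted(unknown)[0]!r}")
        unknown = set(self.subphenotype_effects) - set(DEFAULT_BINARY_OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcome name: {sorted(unknown)[0]!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def null_effects(self) -> "SimConfig":
        """Copy with every GRS effect set to zero (null calibration runs)."""
        cfg = asdict(self)
        cfg["onset_log_hazard_per_grs_unit"] = 0.0
        cfg["sdi_log_or_per_grs_unit"] = 0.0
        cfg["event_log_hr_per_grs_unit"] = {k: 0.0 for k in EVENT_NAMES}
        cfg["subphenotype_effects"] = {k: 0.0 for k in self.subphenotype_effects}
        for key in ("risk_allele_freq_range", "or_distribution"):
            cfg[key] = tuple(cfg[key])
        return SimConfig(**cfg)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(config: SimConfig) -> tuple[RiskPanel, GenotypeMatrix]:
    """Draw a true-OR panel and HWE genotypes.

    Risk-allele frequencies are uniform over the configured range and
    dosages binomial(2, p_j), independent across SNPs and individuals.
    """
    rng_p, rng_or, rng_g = _streams(config.seed, 3)
    lo, hi = config.risk_allele_freq_range
    freqs = rng_p.uniform(lo, hi, config.n_snps)
    loc, scale = config.or_distribution
    ors = np.exp(rng_or.normal(loc, scale, config.n_snps))
    # the risk allele is by definition the one with OR >= 1: re-orient
    # any draw below 1 (OR -> 1/OR, frequency -> 1 - p)
    flip = ors < 1
    ors[flip] = 1 / ors[flip]
    freqs[flip] = 1 - freqs[flip]
    alleles = np.array([["A", "G"]] * config.n_snps)
    panel = RiskPanel.from_frame(pd.DataFrame({
        "snp_id": [f"rs{1000 + j}" for j in range(config.n_snps)],
        "chrom": [str(1 + j % 22) for j in range(config.n_snps)],
        "pos": 10_000 + 100 * np.arange(config.n_snps),
        "risk_allele": alleles[:, 0],
        "other_allele": alleles[:, 1],
        "odds_ratio": ors,
    }))
    dosage = rng_g.binomial(
        2, freqs, size=(config.n_individuals, config.n_snps)).astype(float)
    ids = [f"ind{i:06d}" for i in range(config.n_individuals)]
    return panel, GenotypeMatrix(ids, panel.snp_ids, dosage)


def assign_case_status(
    genotypes: GenotypeMatrix,
    panel: RiskPanel,
    config: SimConfig,
) -> np.ndarray:
    """Logistic disease model on the true weighted score.

    P(case_i) = expit(alpha + GRS_i) with the intercept solved so the
    expected prevalence over the sampled genotypes equals
    ``baseline_prevalence``.
    """
    grs = genotypes.dosage @ panel.weights
    target = config.baseline_prevalence

    def mean_prev(alpha: float) -> float:
        return expit(alpha + grs).mean() - target

    lo = -float(grs.max()) - 50.0
    hi = -float(grs.min()) + 50.0
    if mean_prev(lo) > 0 or mean_prev(hi) < 0:
        raise RuntimeError("could not bracket the disease-model intercept")
    alpha = brentq(mean_prev, lo, hi, xtol=1e-10)
    (rng,) = _streams(config.seed + 1_000_003, 1)
    return rng.random(len(grs)) < expit(alpha + grs)


def _truncated_exponential(rng, rate: np.ndarray, upper: float) -> np.ndarray:
    """Inverse-CDF draw from Exp(rate) truncated to (0, upper]."""
    u = rng.random(len(rate))
    return -np.log1p(-u * (1 - np.exp(-rate * upper))) / rate


def simulate_outcomes(
    case_ids: list[str],
    case_grs: np.ndarray,
    config: SimConfig,
) -> pd.DataFrame:
    """Phenotype table for the case rows of the cohort.

    Age at diagnosis is a truncated-exponential proportional-hazards
    draw with log-hazard linear in the centred GRS (positive effect =
    earlier onset); each event age is diagnosis plus an exponential
    residual with its own GRS effect, right-censored at the
    administrative age and at death.  Binary subphenotypes are logistic
    in the GRS with intercepts solved to hit their baseline prevalences.
    Every table invariant (event age <= follow-up age, ESRD => CKD stage
    5, deceased => death age = follow-up age) holds by construction.
    """
    grs = np.asarray(case_grs, float)
    n = len(grs)
    centred = grs - grs.mean()
    streams = _streams(config.seed + 2_000_029, 6 + len(EVENT_NAMES))
    rng_onset, rng_bin, rng_sdi, rng_ckd, rng_biopsy, rng_miss = streams[:6]
    event_rngs = dict(zip(EVENT_NAMES, streams[6:]))

    out = pd.DataFrame({"individual_id": case_ids, "is_case": True,
                        "grs": grs})
    T = config.admin_censor_age
    if T <= 0:  # degenerate: everything administratively censored at birth
        out["age_at_diagnosis"] = 0.0
        out["age_last_followup"] = 0.0
        out["deceased"] = False
        out["age_at_death"] = np.nan
        out["sdi"] = 0
        for name, (_, _) in DEFAULT_BINARY_OUTCOMES.items():
            out[name] = False
        for ev in EVENT_NAMES:
            if ev != "death":
                out[f"age_{ev}"] = np.nan
                out[f"{ev}_observed"] = False
        out["esrd"] = False
        out["age_at_esrd"] = np.nan
        out["ckd_stage"] = 0
        out["biopsy_class"] = "none"
        out["age_nephritis"] = np.nan
        out["nephritis_observed"] = False
        return out

    onset_rate = config.onset_baseline_hazard * np.exp(
        config.onset_log_hazard_per_grs_unit * centred)
    onset = _truncated_exponential(rng_onset, onset_rate, T)

    death_rate = config.event_baseline_hazards["death"] * np.exp(
        config.event_log_hr_per_grs_unit.get("death", 0.0) * centred)
    with np.errstate(divide="ignore"):
        death_age = onset + rng_onset.exponential(
            np.where(death_rate > 0, 1 / death_rate, np.inf))
    deceased = death_age <= T
    followup = np.minimum(death_age, T)

    out["age_at_diagnosis"] = onset
    out["age_last_followup"] = followup
    out["deceased"] = deceased
    out["age_at_death"] = np.where(deceased, death_age, np.nan)

    # post-diagnosis events, censored at end of follow-up
    for ev in EVENT_NAMES:
        if ev == "death":
            continue
        base = config.event_baseline_hazards[ev]
        rate = base * np.exp(
            config.event_log_hr_per_grs_unit.get(ev, 0.0) * centred)
        with np.errstate(divide="ignore"):
            cand = onset + event_rngs[ev].exponential(
                np.where(rate > 0, 1 / rate, np.inf))
        observed = cand <= followup
        out[f"age_{ev}"] = np.where(observed, cand, np.nan)
        out[f"{ev}_observed"] = observed

    # binary subphenotypes: logistic in the GRS, intercept solved to hit
    # the configured baseline prevalence
    for name, (prev, _) in DEFAULT_BINARY_OUTCOMES.items():
        eff = config.subphenotype_effects.get(name, 0.0)
        if eff == 0.0:
            alpha = logit(prev)
        else:
            alpha = brentq(lambda a: expit(a + eff * centred).mean() - prev,
                           -30, 30, xtol=1e-10)
        out[name] = rng_bin.random(n) < expit(alpha + eff * centred)

    miss = rng_miss.random((n, len(SEROLOGY))) < config.serology_missing_rate
    for k, name in enumerate(SEROLOGY):
        col = out[name].astype(object)
        col[miss[:, k]] = pd.NA
        out[name] = col

    # SDI: 0 unless a first-damage event was observed; affected draw an
    # ordinal level 1..4 ("4" stands for >=4) with proportional odds in GRS
    sdi = np.zeros(n, int)
    damaged = out["first_sdi_observed"].to_numpy()
    eta = config.sdi_log_or_per_grs_unit * centred[damaged]
    cuts = logit(np.array([0.45, 0.75, 0.90]))  # P(SDI<=k | damaged) at mean
    cum = expit(cuts[None, :] - eta[:, None])   # ascending in k
    u = rng_sdi.random(damaged.sum())
    sdi[damaged] = 1 + (u[:, None] > cum).sum(axis=1)
    out["sdi"] = sdi

    # renal staging: ESRD is driven by the event process (=> stage 5);
    # other renal-disorder patients draw CKD stage 0-4
    esrd = out["esrd_observed"].to_numpy()
    out["esrd"] = esrd
    out["age_at_esrd"] = out["age_esrd"]
    ckd = np.zeros(n, int)
    renal = out["renal_disorder"].to_numpy(bool)
    stage_p = np.array([0.55, 0.20, 0.13, 0.08, 0.04])  # stages 0..4
    ckd[renal] = rng_ckd.choice(5, size=int(renal.sum()), p=stage_p)
    ckd[esrd] = 5
    out["ckd_stage"] = ckd

    # renal biopsy classes among renal-disorder patients; proliferative
    # nephritis (III-IV) log-odds increase with GRS
    classes = np.array(["I-II", "III-IV", "V", "other"])
    base_p = np.array([0.14, 0.60, 0.14, 0.12])
    biopsy = np.full(n, "none", object)
    if renal.any():
        sc = np.log(base_p)[None, :] + np.outer(
            0.31 * centred[renal], [0, 1, 0, 0])
        p = np.exp(sc)
        p /= p.sum(axis=1, keepdims=True)
        u = rng_biopsy.random((int(renal.sum()), 1))
        biopsy[renal] = classes[(u > p.cumsum(axis=1)).sum(axis=1)]
    out["biopsy_class"] = biopsy

    # nephritis debut: renal-disorder patients develop nephritis shortly
    # after diagnosis; only debuts inside follow-up carry a known age
    neph_rate = 0.15 * np.exp(
        config.onset_log_hazard_per_grs_unit * 2.0 * centred)
    cand = onset + rng_ckd.exponential(1 / neph_rate)
    neph_obs = renal & (cand <= followup)
    out["age_nephritis"] = np.where(neph_obs, cand, np.nan)
    out["nephritis_observed"] = neph_obs
    return out


def simulate_cohort(
    config: SimConfig,
) -> tuple[RiskPanel, GenotypeMatrix, np.ndarray, ScoreSet, pd.DataFrame]:
    """Full generator: genotypes -> case status -> true-score ScoreSet ->
    case phenotype table.  Returns (panel, genotypes, status, scores,
    cohort)."""
    panel, genotypes = simulate_genotypes(config)
    status = assign_case_status(genotypes, panel, config)
    scores = compute_scores(genotypes, panel)
    case_idx = np.flatnonzero(status)
    cohort = simulate_outcomes(
        [genotypes.individual_ids[i] for i in case_idx],
        scores.grs[case_idx], config)
    return panel, genotypes, status, scores, cohort


def binormal_scores(
    n_cases: int = 1001,
    n_controls: int = 2802,
    case_mean: float = 8.52,
    control_mean: float = 7.45,
    sd: float = 1.20,
    seed: int = 0,
) -> tuple[ScoreSet, np.ndarray]:
    """GRS draws matching a two-Gaussian case/control summary.

    Defaults reproduce the discovery-cohort moments (case GRS
    N(8.52, 1.2^2) vs control N(7.45, 1.2^2), 1001 cases / 2802
    controls).  RAC is filled with the GRS rescaled by ln 2 (rank
    equivalent) since only score ranks matter for these checks.
    """
    rng = np.random.default_rng(seed)
    grs = np.concatenate([rng.normal(case_mean, sd, n_cases),
                          rng.normal(control_mean, sd, n_controls)])
    status = np.zeros(n_cases + n_controls, bool)
    status[:n_cases] = True
    ids = [f"ind{i:06d}" for i in range(len(grs))]
    scores = ScoreSet(ids, np.rint(grs / np.log(2)).astype(int), grs)
    return scores, status
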