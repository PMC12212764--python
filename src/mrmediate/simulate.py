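"""Synthetic GWAS summary statistics with known causal truth.

Generates three non-overlapping-cohort summary-statistics sets (continuous
exposure, continuous mediator, binary outcome) under the structural model

    X -> M -> Y   with direct effect X -> Y and optional per-variant
                  direct (pleiotropic) effects on Y

at the summary level: per-variant true marginal effects are computed from the
structural coefficients and observed effects are the truth plus normal noise
with the analytic GWAS standard error.  This is exact for the SEs and fast,
at the cost of not modeling genotype-level phenomena (LD is optional and
block-wise, sample overlap and winner's curse are absent).

Default cohort sizes mirror the study setting this package targets: a
50,000-sample continuous exposure GWAS, an 8299-sample metabolite GWAS and a
case-control outcome GWAS of 6435 cases / 446,419 controls.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError
from .sumstats import CANONICAL_COLUMNS, TraitSumStats

import pandas as pd

#: outcome GWAS defaults (ulcerative colitis case-control scale)
N_OUTCOME_DEFAULT = 6435 + 446419
PREVALENCE_DEFAULT = 6435 / N_OUTCOME_DEFAULT

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_SPACING_BP = 10_001_000  # > the default 10,000 kb clump window


@dataclass(frozen=True)
class Pleiotropy:
    """Per-variant direct-effect (alpha) model for the outcome.

    kind: "none", "balanced" (mean-zero N(0, sd) on all variants),
    "directional" (N(mean, sd) on a random fraction ``frac`` of variants),
    or "inside_violating" (alpha correlated with instrument strength with
    correlation ``corr``, breaking the InSIDE assumption).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    frac: float = 1.0
    corr: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional",
                             "inside_violating"):
            raise ConfigurationError(f"unknown pleiotropy kind {self.kind!r}")
        if not (0.0 <= self.frac <= 1.0):
            raise ConfigurationError("pleiotropy frac must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults encode the study conditions.

    ``m`` variants in total: the first ``m - m_mediator - m_outcome``
    instrument the exposure (gamma effects), the next ``m_mediator`` directly
    instrument the mediator (delta effects), and the last ``m_outcome`` are
    outcome-specific susceptibility loci (eta effects) with no exposure or
    mediator association — these are what reverse MR instruments on.
    ``h2_x``/``h2_m``/``h2_y`` are the variances explained by the respective
    instrument sets.  ``beta_reverse`` switches to a reverse-causation world
    where the variants instrument the outcome liability and the exposure is
    downstream.
    """

    m: int = 30
    m_mediator: int = 0
    m_outcome: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_x: float = 0.1
    h2_m: float = 0.0
    h2_y: float = 0.0
    beta1_true: float = 0.0
    beta2_true: float = 0.0
    theta_direct: float = 0.0
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    n_exp: int = 50_000
    n_med: int = 8_299
    n_out: int = N_OUTCOME_DEFAULT
    outcome_prevalence: float = PREVALENCE_DEFAULT
    beta_reverse: float = 0.0
    gamma_signs: str = "random"  # "random" | "positive"
    ld_block_size: int = 1
    ld_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for h2 in (self.h2_x, self.h2_m, self.h2_y):
            if not (0.0 <= h2 < 1.0):
                raise ConfigurationError("heritabilities must be in [0, 1)")
        if min(self.n_exp, self.n_med, self.n_out) < 100:
            raise ConfigurationError("all sample sizes must be >= 100")
        if not (0.0 < self.outcome_prevalence < 1.0):
            raise ConfigurationError("outcome_prevalence must be in (0, 1)")
        if self.m_mediator + self.m_outcome > self.m:
            raise ConfigurationError("m_mediator + m_outcome cannot exceed m")
        if self.h2_x > 0 and self.m - self.m_mediator - self.m_outcome < 1:
            raise ConfigurationError("h2_x > 0 requires exposure instruments")
        if self.h2_m > 0 and self.m_mediator < 1:
            raise ConfigurationError("h2_m > 0 requires mediator instruments")
        if self.h2_y > 0 and self.m_outcome < 1:
            raise ConfigurationError("h2_y > 0 requires outcome loci")
        if self.gamma_signs not in ("random", "positive"):
            raise ConfigurationError("gamma_signs must be 'random' or 'positive'")

    @property
    def beta_all_true(self) -> float:
        return self.theta_direct + self.beta1_true * self.beta2_true


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset."""

    gamma: np.ndarray
    delta: np.ndarray
    alpha: np.ndarray
    eta: np.ndarray
    maf: np.ndarray
    beta1_true: float
    beta2_true: float
    theta_direct: float
    beta_all_true: float
    proportion_true: float | None
    pleiotropy_mean: float
    ld_r2_lookup: dict | None = None

    def to_json(self) -> str:
        d = {
            "gamma": list(map(float, self.gamma)),
            "delta": list(map(float, self.delta)),
            "alpha": list(map(float, self.alpha)),
            "eta": list(map(float, self.eta)),
            "maf": list(map(float, self.maf)),
            "beta1_true": self.beta1_true,
            "beta2_true": self.beta2_true,
            "theta_direct": self.theta_direct,
            "beta_all_true": self.beta_all_true,
            "proportion_true": self.proportion_true,
            "pleiotropy_mean": self.pleiotropy_mean,
        }
        return json.dumps(d, indent=1)


def _scaled_effects(rng: np.random.Generator, maf: np.ndarray, h2: float,
                    signs: str) -> np.ndarray:
    """Draw effects and rescale so sum 2 maf (1-maf) beta^2 equals h2."""
    raw = rng.standard_normal(len(maf))
    if signs == "positive":
        raw = np.abs(raw)
    var = 2.0 * maf * (1.0 - maf)
    total = float(np.sum(var * raw ** 2))
    if total <= 0:
        raise ConfigurationError("degenerate instrument effects")
    return raw * np.sqrt(h2 / total)


def _trait_table(rng: np.random.Generator, ids, chrom, pos, ea, oa, maf,
                 truth: np.ndarray, se: np.ndarray, n: int) -> pd.DataFrame:
    beta = truth + rng.normal(0.0, se)
    z = np.abs(beta / se)
    pval = np.maximum(2.0 * sps.norm.sf(z), 5e-324)
    return pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": maf,
        "beta": beta, "se": se, "pval": pval, "n": float(n),
    }, columns=CANONICAL_COLUMNS)


def simulate_sumstats(cfg: SimConfig) -> tuple[TraitSumStats, TraitSumStats,
                                               TraitSumStats, SimTruth]:
    """Generate (exposure, mediator, outcome, truth) for one replicate.

    A single seed drives four independent child streams (structure, and one
    noise stream per trait) via numpy's SeedSequence spawning, so the three
    cohorts are non-overlapping by construction and the output is
    bit-reproducible for a given config.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_e, rng_m, rng_o = (np.random.default_rng(s)
                                       for s in ss.spawn(4))
    m, m_med, m_out = cfg.m, cfg.m_mediator, cfg.m_outcome
    m_x = m - m_med - m_out
    maf = rng_struct.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)

    gamma = np.zeros(m)
    delta = np.zeros(m)
    eta = np.zeros(m)
    med_sl = slice(m_x, m_x + m_med)
    out_sl = slice(m_x + m_med, m)
    if cfg.h2_x > 0:
        gamma[:m_x] = _scaled_effects(rng_struct, maf[:m_x], cfg.h2_x,
                                      cfg.gamma_signs)
    if cfg.h2_m > 0:
        delta[med_sl] = _scaled_effects(rng_struct, maf[med_sl], cfg.h2_m,
                                        cfg.gamma_signs)
    if cfg.h2_y > 0:
        eta[out_sl] = _scaled_effects(rng_struct, maf[out_sl], cfg.h2_y,
                                      cfg.gamma_signs)

    pl = cfg.pleiotropy
    alpha = np.zeros(m)
    pleiotropy_mean = 0.0
    if pl.kind == "balanced":
        alpha = rng_struct.normal(0.0, pl.sd, size=m)
    elif pl.kind == "directional":
        n_inv = int(round(pl.frac * m))
        idx = rng_struct.choice(m, size=n_inv, replace=False)
        alpha[idx] = rng_struct.normal(pl.mean, pl.sd, size=n_inv)
        pleiotropy_mean = pl.frac * pl.mean
    elif pl.kind == "inside_violating":
        noise = rng_struct.standard_normal(m) * pl.sd
        g_sd = float(np.std(gamma)) or 1.0
        alpha = pl.corr * (pl.sd / g_sd) * gamma + np.sqrt(1 - pl.corr ** 2) * noise
        pleiotropy_mean = float(np.mean(alpha))

    if cfg.beta_reverse != 0.0:
        # reverse-causation world: the variants instrument the outcome
        # liability (gamma) and the exposure sits downstream of it
        truth_out = gamma.copy()
        truth_exp = cfg.beta_reverse * gamma
        truth_med = np.zeros(m)
    else:
        truth_exp = gamma.copy()
        truth_med = cfg.beta1_true * gamma + delta
        truth_out = (cfg.beta_all_true * gamma + cfg.beta2_true * delta
                     + eta + alpha)

    ids = np.array([f"rs{j + 1:06d}" for j in range(m)], dtype=object)
    if cfg.ld_block_size > 1:
        block = np.arange(m) // cfg.ld_block_size
        within = np.arange(m) % cfg.ld_block_size
        pos = block * _SPACING_BP + within * 1000 + 1
        lookup = {}
        for b in np.unique(block):
            members = ids[block == b]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    lookup[(members[i], members[j])] = cfg.ld_r2
    else:
        pos = np.arange(m) * _SPACING_BP + 1
        lookup = None
    chrom = np.full(m, "1", dtype=object)
    pair_idx = rng_struct.integers(0, len(_NONPALINDROMIC), size=m)
    ea = np.array([_NONPALINDROMIC[i][0] for i in pair_idx], dtype=object)
    oa = np.array([_NONPALINDROMIC[i][1] for i in pair_idx], dtype=object)

    var = 2.0 * maf * (1.0 - maf)
    se_exp = 1.0 / np.sqrt(var * cfg.n_exp)
    se_med = 1.0 / np.sqrt(var * cfg.n_med)
    prev = cfg.outcome_prevalence
    se_out = 1.0 / np.sqrt(var * cfg.n_out * prev * (1.0 - prev))

    exposure = TraitSumStats(
        "exposure", "continuous", "per_SD",
        _trait_table(rng_e, ids, chrom, pos, ea, oa, maf, truth_exp, se_exp,
                     cfg.n_exp))
    mediator = TraitSumStats(
        "mediator", "continuous", "per_SD",
        _trait_table(rng_m, ids, chrom, pos, ea, oa, maf, truth_med, se_med,
                     cfg.n_med))
    outcome = TraitSumStats(
        "outcome", "binary", "logOR",
        _trait_table(rng_o, ids, chrom, pos, ea, oa, maf, truth_out, se_out,
                     cfg.n_out))

    beta_all = cfg.beta_all_true
    proportion = (cfg.beta1_true * cfg.beta2_true / beta_all
                  if beta_all != 0 else None)
    truth = SimTruth(gamma=gamma, delta=delta, alpha=alpha, eta=eta, maf=maf,
                     beta1_true=cfg.beta1_true, beta2_true=cfg.beta2_true,
                     theta_direct=cfg.theta_direct, beta_all_true=beta_all,
                     proportion_true=proportion,
                     pleiotropy_mean=pleiotropy_mean, ld_r2_lookup=lookup)
    return exposure, mediator, outcome, truth


def plant_outlier(stats: TraitSumStats, variant_id: str,
                  displacement_in_se: float) -> TraitSumStats:
    """Shift one variant's beta by ``displacement_in_se`` standard errors.

    Returns a copy; the p-value of the shifted row is recomputed so the table
    stays internally consistent.
    """
    table = stats.table.copy()
    mask = table["variant_id"] == variant_id
    if not mask.any():
        raise KeyError(f"unknown variant {variant_id!r}")
    i = table.index[mask][0]
    se = table.at[i, "se"]
    table.at[i, "beta"] = table.at[i, "beta"] + displacement_in_se * se
    z = abs(table.at[i, "beta"] / se)
    table.at[i, "pval"] = max(2.0 * sps.norm.sf(z), 5e-324)
    return TraitSumStats(stats.trait_id, stats.trait_type, stats.effect_units,
                         table)


def scenario_library() -> dict[str, SimConfig]:
    """Named presets covering the designs the package is validated against.

    - ``valid_instruments``: 30 strong, valid instruments; total effect 0.3.
    - ``balanced_pleiotropy``: mean-zero direct effects inflate heterogeneity
      without biasing IVW.
    - ``directional_pleiotropy``: 30% invalid instruments with positive-mean
      direct effects (instruments oriented positive so the bias does not
      cancel); mean direct effect over all instruments 0.015.
    - ``inside_violation``: direct effects correlated with instrument
      strength (InSIDE broken).
    - ``reverse_causation``: the outcome drives the exposure; forward MR on
      the exposure's apparent instruments is spurious.
    - ``full_mediation``: X->M->Y with beta1=0.3, beta2=0.4, direct 0.1;
      true mediated proportion 0.12/0.22 = 0.545...; the outcome also carries
      15 susceptibility loci of its own so reverse MR has instruments.
    - ``partial_mediation_negative``: indirect effect opposite in sign to the
      total effect, yielding a negative mediated proportion (-0.176).
    """
    mediation_kw = dict(m=55, m_mediator=20, m_outcome=15, h2_x=0.15,
                        h2_m=0.15, h2_y=0.2, n_exp=50_000, n_med=8_299)
    return {
        "valid_instruments": SimConfig(m=30, h2_x=0.1, theta_direct=0.3),
        "balanced_pleiotropy": SimConfig(
            m=30, h2_x=0.1, theta_direct=0.3,
            pleiotropy=Pleiotropy(kind="balanced", sd=0.02)),
        "directional_pleiotropy": SimConfig(
            m=30, h2_x=0.1, theta_direct=0.3, gamma_signs="positive",
            pleiotropy=Pleiotropy(kind="directional", mean=0.05, sd=0.01,
                                  frac=0.3)),
        "inside_violation": SimConfig(
            m=30, h2_x=0.1, theta_direct=0.3, gamma_signs="positive",
            pleiotropy=Pleiotropy(kind="inside_violating", corr=0.5,
                                  sd=0.02)),
        "reverse_causation": SimConfig(m=15, h2_x=0.1, beta_reverse=0.5),
        "full_mediation": SimConfig(beta1_true=0.3, beta2_true=0.4,
                                    theta_direct=0.1, **mediation_kw),
        "partial_mediation_negative": SimConfig(beta1_true=0.2,
                                                beta2_true=-0.3,
                                                theta_direct=0.4,
                                                **mediation_kw),
    }


def scenario(name: str, seed: int | None = None, **overrides) -> SimConfig:
    """Fetch a preset, optionally re-seeded or with field overrides."""
    lib = scenario_library()
    if name not in lib:
        raise ConfigurationError(
            f"unknown scenario {name!r}; choose from {sorted(lib)}")
    cfg = lib[name]
    if seed is not None:
        overrides["seed"] = seed
    return dataclasses.replace(cfg, **overrides) if overrides else cfg
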