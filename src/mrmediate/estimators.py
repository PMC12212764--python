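"""Causal-effect estimators on harmonized instrument sets.

All estimators consume a :class:`~mrmediate.sumstats.HarmonizedInstruments`
set of (beta_exp, se_exp, beta_out, se_out) pairs and return an
:class:`MREstimate` carrying the log-scale effect, its standard error and the
odds-ratio reporting (exp(beta) with a 95% Wald interval).  When the outcome is
binary the effect is the log-odds of outcome per SD of exposure.

Implemented methods: per-variant Wald ratio, inverse-variance weighted (IVW;
fixed or multiplicative random effects), MR-Egger regression, weighted median,
and simple/weighted mode.  The IVW point estimate is the weighted regression of
beta_out on beta_exp through the origin with weights 1/se_out^2; the robust
estimators trade efficiency for validity under partial instrument invalidity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInstrumentError, InsufficientInstrumentsError
from .sumstats import HarmonizedInstruments

Z95 = float(sps.norm.ppf(0.975))  # 1.959963984540054


@dataclass(frozen=True)
class MREstimate:
    """One method's causal-effect estimate with OR/CI reporting."""

    method: str
    nsnp: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.nsnp < 1:
            raise ValueError("nsnp must be >= 1")


@dataclass(frozen=True)
class EggerIntercept:
    """MR-Egger intercept: the average directional pleiotropy estimate."""

    intercept: float
    se: float
    pval: float


def to_or(beta: float, se: float) -> tuple[float, float, float, float]:
    """Odds-ratio reporting: (OR, CI low, CI high, two-sided normal p)."""
    if se <= 0:
        raise ValueError("se must be > 0")
    or_ = float(np.exp(beta))
    ci_low = float(np.exp(beta - Z95 * se))
    ci_high = float(np.exp(beta + Z95 * se))
    pval = float(2.0 * sps.norm.sf(abs(beta) / se))
    return or_, ci_low, ci_high, pval


def _finish(method: str, nsnp: int, beta: float, se: float,
            pval: float | None = None) -> MREstimate:
    or_, lo, hi, p_norm = to_or(beta, se)
    return MREstimate(method, nsnp, float(beta), float(se),
                      float(pval if pval is not None else p_norm), or_, lo, hi)


def _arrays(pairs: HarmonizedInstruments):
    return (pairs.beta_exp, pairs.se_exp, pairs.beta_out, pairs.se_out)


def wald_ratio(pairs: HarmonizedInstruments, second_order: bool = False) -> MREstimate:
    """Single-instrument ratio estimate beta_out/beta_exp.

    First-order delta SE ``se_out/|beta_exp|`` by default; ``second_order``
    adds the exposure-noise term
    sqrt(se_out^2/beta_exp^2 + beta_out^2 se_exp^2/beta_exp^4).
    """
    if len(pairs) != 1:
        raise InsufficientInstrumentsError("wald_ratio takes exactly one instrument")
    bx, sx, by, sy = (a[0] for a in _arrays(pairs))
    if bx == 0:
        raise DegenerateInstrumentError("beta_exp is zero")
    beta = by / bx
    if second_order:
        se = float(np.sqrt(sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4))
    else:
        se = sy / abs(bx)
    return _finish("wald_ratio", 1, beta, se)


def ivw(pairs: HarmonizedInstruments,
        model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate (the primary method).

    Weighted regression through the origin with weights 1/se_out^2.  With
    ``model="multiplicative_random"`` the fixed-effect SE is inflated by
    max(1, sqrt(Q/(k-1))) for k >= 2; ``model="fixed"`` leaves it unscaled.
    """
    if len(pairs) < 1:
        raise InsufficientInstrumentsError("ivw needs >= 1 instrument")
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, _, by, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise DegenerateInstrumentError("beta_exp contains zeros")
    w = 1.0 / sy ** 2
    denom = float(np.sum(bx ** 2 * w))
    beta = float(np.sum(bx * by * w)) / denom
    se = float(np.sqrt(1.0 / denom))
    k = len(pairs)
    if model == "multiplicative_random" and k >= 2:
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return _finish("ivw", k, beta, se)


def egger(pairs: HarmonizedInstruments) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger: weighted regression with an intercept.

    Instruments are first oriented so beta_exp >= 0 (both betas negated where
    beta_exp < 0).  The slope is the pleiotropy-adjusted causal estimate; the
    intercept estimates average directional pleiotropy.  SEs use the residual
    dispersion floored at 1 (multiplicative random effects); p-values come from
    the t distribution with k-2 df.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError(f"egger needs >= 3 instruments, got {k}")
    bx, _, by, sy = _arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy ** 2
    # weighted normal equations for by ~ a + b*bx
    sw, swx = w.sum(), (w * bx).sum()
    swxx, swy, swxy = (w * bx * bx).sum(), (w * by).sum(), (w * bx * by).sum()
    det = sw * swxx - swx ** 2
    if det <= 0:
        raise DegenerateInstrumentError(
            "no variation in exposure effects; Egger regression undefined")
    slope = (sw * swxy - swx * swy) / det
    inter = (swxx * swy - swx * swxy) / det
    resid = by - inter - slope * bx
    sigma2 = float(np.sum(w * resid ** 2)) / (k - 2)
    infl = max(1.0, sigma2)
    se_slope = float(np.sqrt(infl * sw / det))
    se_inter = float(np.sqrt(infl * swxx / det))
    p_slope = float(2.0 * sps.t.sf(abs(slope) / se_slope, df=k - 2))
    p_inter = float(2.0 * sps.t.sf(abs(inter) / se_inter, df=k - 2))
    est = _finish("egger", k, slope, se_slope, pval=p_slope)
    return est, EggerIntercept(float(inter), se_inter, p_inter)


def _ratios_weights(pairs: HarmonizedInstruments,
                    weighted: bool = True) -> tuple[np.ndarray, np.ndarray]:
    bx, _, by, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise DegenerateInstrumentError("beta_exp contains zeros")
    r = by / bx
    if weighted:
        w = (bx / sy) ** 2  # 1/Var(r) to first order
    else:
        w = np.ones_like(r)
    return r, w / w.sum()


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="stable")
    r, w = r[order], w[order]
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


def _bootstrap_se(pairs: HarmonizedInstruments, point_fn, n_boot: int,
                  seed: int | None, weighted: bool) -> float:
    """Parametric bootstrap: resample betas from their normal sampling
    distributions and take the SD of re-estimates.  Inputs are already in
    canonical (variant_id-sorted) order, so a fixed seed is reproducible."""
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = _arrays(pairs)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).tiny
        r = bys / bxs
        w = (bxs / sy) ** 2 if weighted else np.ones_like(r)
        ests[b] = point_fn(r, w / w.sum())
    return float(np.std(ests, ddof=1))


def weighted_median(pairs: HarmonizedInstruments, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted median of per-variant ratios (consistent if >=50% of weight is
    on valid instruments).

    Ratios are sorted; with normalized inverse-variance weights w_j and
    cumulative sums S_j, the percentile points are p_j = S_j - w_j/2 and the
    estimate linearly interpolates the ratio at p = 0.5.  SE by parametric
    bootstrap (``n_boot=0`` skips it and reports NaN).
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("weighted_median needs >= 3 instruments")
    r, w = _ratios_weights(pairs, weighted=True)
    beta = _weighted_median_point(r, w)
    if n_boot > 0:
        se = _bootstrap_se(pairs, _weighted_median_point, n_boot, seed, True)
        se = max(se, np.finfo(float).tiny)
    else:
        se = float("nan")
    pval = 2.0 * sps.norm.sf(abs(beta) / se) if np.isfinite(se) else float("nan")
    if not np.isfinite(se):
        # reporting interval undefined without an SE; use a tiny placeholder
        return MREstimate("weighted_median", len(pairs), float(beta), se,
                          float("nan"), float(np.exp(beta)), float("nan"),
                          float("nan"))
    return _finish("weighted_median", len(pairs), beta, se, pval=float(pval))


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    k = len(r)
    s = float(np.std(r, ddof=1))
    mad = float(np.median(np.abs(r - np.median(r)))) * 1.4826
    spread = min(x for x in (s, mad) if x > 0) if (s > 0 or mad > 0) else 0.0
    h = phi * 0.9 * spread * k ** (-1.0 / 5.0)
    if h == 0.0:
        return float(r[0])  # all ratios identical
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 2048)
    z = (grid[:, None] - r[None, :]) / h
    dens = (w[None, :] * np.exp(-0.5 * z * z)).sum(axis=1)
    best = dens.max()
    ties = np.flatnonzero(dens >= best * (1.0 - 1e-12))
    if len(ties) > 1:
        wm = _weighted_median_point(r, w)
        return float(grid[ties[np.argmin(np.abs(grid[ties] - wm))]])
    return float(grid[ties[0]])


def mode_estimate(pairs: HarmonizedInstruments, weighted: bool = False,
                  phi: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None) -> MREstimate:
    """Mode-based estimate: the peak of a Gaussian kernel density of ratios.

    ``weighted=False`` gives the simple mode (uniform weights),
    ``weighted=True`` the weighted mode (inverse-variance weights).  Bandwidth
    h = phi * 0.9 * min(sd, 1.4826*mad) * k^(-1/5), falling back to whichever
    spread measure is nonzero when the other degenerates to zero; density
    evaluated on a 2048-point grid
    spanning [min-3h, max+3h], ties broken toward the weighted median.
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("mode_estimate needs >= 3 instruments")
    r, w = _ratios_weights(pairs, weighted=weighted)
    beta = _mode_point(r, w, phi)
    method = "weighted_mode" if weighted else "simple_mode"
    if n_boot > 0:
        se = _bootstrap_se(pairs, lambda rr, ww: _mode_point(rr, ww, phi),
                           n_boot, seed, weighted)
        se = max(se, np.finfo(float).tiny)
        pval = float(2.0 * sps.norm.sf(abs(beta) / se))
        return _finish(method, len(pairs), beta, se, pval=pval)
    return MREstimate(method, len(pairs), float(beta), float("nan"),
                      float("nan"), float(np.exp(beta)), float("nan"),
                      float("nan"))


def all_estimates(pairs: HarmonizedInstruments, n_boot: int = 1000,
                  seed: int | None = None,
                  ivw_model: str = "multiplicative_random",
                  ) -> tuple[dict[str, MREstimate], EggerIntercept | None]:
    """Run IVW plus every complementary method the instrument count allows."""
    out: dict[str, MREstimate] = {"ivw": ivw(pairs, model=ivw_model)}
    intercept = None
    if len(pairs) >= 3:
        est, intercept = egger(pairs)
        out["egger"] = est
        out["weighted_median"] = weighted_median(pairs, n_boot=n_boot, seed=seed)
        out["simple_mode"] = mode_estimate(pairs, weighted=False,
                                           n_boot=n_boot, seed=seed)
        out["weighted_mode"] = mode_estimate(pairs, weighted=True,
                                             n_boot=n_boot, seed=seed)
    return out, intercept
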