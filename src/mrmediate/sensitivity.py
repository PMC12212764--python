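"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

For one exposure-outcome instrument set this module provides Cochran's Q (with
I^2), the MR-PRESSO residual-sum-of-squares global/outlier/distortion tests,
leave-one-out influence analysis, and the scatter/funnel diagnostic tables.
:func:`sensitivity_report` bundles everything that the instrument count allows
into a single JSON-serializable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientInstrumentsError
from .estimators import EggerIntercept, MREstimate, egger, ivw
from .sumstats import HarmonizedInstruments


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran Q heterogeneity test; I^2 = max(0, (Q - df)/Q)."""

    Q: float
    df: int
    pval: float
    i2: float


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results.

    ``beta_corrected``/``distortion_pval`` are None when no outliers are
    flagged.  Empirical p-values use +1 smoothing, so the smallest attainable
    p is 1/(n_sim+1).
    """

    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: list[str]
    beta_raw: float
    beta_corrected: float | None = None
    distortion_pval: float | None = None


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure-outcome analysis."""

    heterogeneity: HeterogeneityResult | None = None
    egger_intercept: EggerIntercept | None = None
    presso: PressoResult | None = None
    loo: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d: dict = {}
        if self.heterogeneity is not None:
            h = self.heterogeneity
            d["heterogeneity"] = {"Q": h.Q, "df": h.df, "pval": h.pval, "i2": h.i2}
        if self.egger_intercept is not None:
            e = self.egger_intercept
            d["egger_intercept"] = {"intercept": e.intercept, "se": e.se,
                                    "pval": e.pval}
        if self.presso is not None:
            p = self.presso
            d["mr_presso"] = {
                "rss_obs": p.rss_obs, "global_pval": p.global_pval,
                "outlier_pvals": p.outlier_pvals, "outliers": p.outliers,
                "beta_raw": p.beta_raw, "beta_corrected": p.beta_corrected,
                "distortion_pval": p.distortion_pval,
            }
        if self.loo is not None:
            d["leave_one_out"] = self.loo.to_dict(orient="records")
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def cochran_q(pairs: HarmonizedInstruments) -> HeterogeneityResult:
    """Cochran's Q over per-variant ratios against the fixed-effect IVW mean.

    Q = sum_j w_j (r_j - beta_fixed)^2 with r_j = beta_out/beta_exp and
    w_j = beta_exp^2/se_out^2 (first-order inverse ratio variances);
    df = k - 1; upper-tail chi-square p.
    """
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError("cochran_q needs >= 2 instruments")
    r = pairs.beta_out / pairs.beta_exp
    w = (pairs.beta_exp / pairs.se_out) ** 2
    beta_fixed = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta_fixed) ** 2))
    df = k - 1
    pval = float(sps.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q, df, max(pval, np.finfo(float).tiny), i2)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized.

    Supports batched input: arrays of shape (..., k)."""
    num = (bx * by * w).sum(axis=-1, keepdims=True)
    den = (bx * bx * w).sum(axis=-1, keepdims=True)
    return (num - bx * by * w) / (den - bx * bx * w)


def mr_presso(pairs: HarmonizedInstruments, n_sim: int = 1000,
              seed: int | None = None,
              sig_threshold: float = 0.05) -> PressoResult:
    """MR-PRESSO: residual-sum-of-squares pleiotropy and outlier test.

    Each variant's outcome effect is predicted from the leave-one-out IVW
    slope; the observed weighted RSS is compared with the RSS distribution of
    ``n_sim`` parametric replicates drawn under the no-pleiotropy model
    (beta_out*_j ~ N(loo-prediction, se_out), beta_exp*_j ~ N(beta_exp,
    se_exp)).  Per-variant outlier p-values come from each variant's simulated
    weighted-residual distribution and are flagged at the Bonferroni threshold
    sig_threshold/k.  When outliers are flagged, IVW is recomputed without them
    and the raw-vs-corrected difference is tested against the distribution of
    differences obtained by removing equally many random variants from the
    simulated outlier-free sets.
    """
    k = len(pairs)
    if k < 4:
        raise InsufficientInstrumentsError(f"mr_presso needs >= 4 instruments, got {k}")
    bx, sx, by, sy = (pairs.beta_exp, pairs.se_exp, pairs.beta_out, pairs.se_out)
    w = 1.0 / sy ** 2
    b_loo = _loo_slopes(bx, by, w)
    expected = b_loo * bx
    res_obs = w * (by - expected) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, k))
    by_s = rng.normal(expected, sy, size=(n_sim, k))
    b_loo_s = _loo_slopes(bx_s, by_s, w)
    res_s = w * (by_s - b_loo_s * bx_s) ** 2
    rss_s = res_s.sum(axis=1)
    global_pval = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))

    out_p = (1 + (res_s >= res_obs).sum(axis=0)) / (n_sim + 1)
    ids = [str(v) for v in pairs.variant_id]
    outlier_pvals = dict(zip(ids, map(float, out_p)))
    flagged = [ids[j] for j in range(k) if out_p[j] < sig_threshold / k]

    beta_raw = ivw(pairs).beta
    beta_corrected = distortion_pval = None
    if flagged and len(flagged) < k:
        keep = ~np.isin(pairs.variant_id.astype(str), flagged)
        beta_corrected = ivw(pairs.subset(keep)).beta
        obs_diff = beta_raw - beta_corrected
        n_out = len(flagged)
        num_s = (bx_s * by_s * w).sum(axis=1)
        den_s = (bx_s * bx_s * w).sum(axis=1)
        diffs = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            num_d = num_s[s] - (bx_s[s, drop] * by_s[s, drop] * w[drop]).sum()
            den_d = den_s[s] - (bx_s[s, drop] ** 2 * w[drop]).sum()
            diffs[s] = num_s[s] / den_s[s] - num_d / den_d
        distortion_pval = float(
            (1 + np.sum(np.abs(diffs) >= abs(obs_diff))) / (n_sim + 1))
    return PressoResult(rss_obs, global_pval, outlier_pvals, flagged,
                        float(beta_raw), beta_corrected, distortion_pval)


def leave_one_out(pairs: HarmonizedInstruments,
                  model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimated with each instrument dropped in turn.

    Returns one row per dropped variant with columns
    (dropped_variant, nsnp, beta, se, pval).
    """
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError("leave_one_out needs >= 2 instruments")
    rows = []
    for j in range(k):
        keep = np.ones(k, dtype=bool)
        keep[j] = False
        est = ivw(pairs.subset(keep), model=model)
        rows.append((str(pairs.variant_id[j]), est.nsnp, est.beta, est.se,
                     est.pval))
    return pd.DataFrame(rows, columns=["dropped_variant", "nsnp", "beta",
                                       "se", "pval"])


def diagnostics_export(
    pairs: HarmonizedInstruments,
    estimates: dict[str, MREstimate],
    egger_intercept: EggerIntercept | None = None,
) -> dict[str, pd.DataFrame]:
    """Scatter and funnel tables underlying the standard MR diagnostic plots.

    The scatter table holds the (beta_exp, beta_out) points with SEs; the
    lines table one fitted line per method (Egger with its intercept, all
    others through the origin).  The funnel table plots each Wald ratio
    against its precision 1/se(ratio).
    """
    scatter = pairs.to_frame()
    lines = pd.DataFrame(
        [(m, e.beta,
          egger_intercept.intercept if (m == "egger" and egger_intercept) else 0.0)
         for m, e in estimates.items()],
        columns=["method", "slope", "intercept"])
    ratio = pairs.beta_out / pairs.beta_exp
    se_ratio = pairs.se_out / np.abs(pairs.beta_exp)
    funnel = pd.DataFrame({
        "variant_id": pairs.variant_id, "ratio": ratio,
        "precision": 1.0 / se_ratio,
    })
    return {"scatter": scatter, "lines": lines, "funnel": funnel}


def plot_diagnostics(tables: dict[str, pd.DataFrame], scatter_path=None,
                     funnel_path=None) -> None:
    """Render the scatter/funnel tables to image files (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if scatter_path is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        s = tables["scatter"]
        ax.errorbar(s["beta_exp"], s["beta_out"], xerr=s["se_exp"],
                    yerr=s["se_out"], fmt="o", ms=3, lw=0.7, color="k")
        xs = np.linspace(0, s["beta_exp"].abs().max() * 1.05, 50)
        for _, row in tables["lines"].iterrows():
            ax.plot(xs, row["intercept"] + row["slope"] * xs, label=row["method"])
        ax.set_xlabel("SNP effect on exposure")
        ax.set_ylabel("SNP effect on outcome")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(scatter_path, dpi=150)
        plt.close(fig)
    if funnel_path is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        f = tables["funnel"]
        ax.plot(f["ratio"], f["precision"], "ko", ms=3)
        ax.set_xlabel("Wald ratio")
        ax.set_ylabel("1 / SE(ratio)")
        fig.tight_layout()
        fig.savefig(funnel_path, dpi=150)
        plt.close(fig)


def sensitivity_report(pairs: HarmonizedInstruments, n_sim: int = 1000,
                       seed: int | None = None,
                       ivw_model: str = "multiplicative_random",
                       ) -> SensitivityReport:
    """Run every diagnostic the instrument count permits."""
    rep = SensitivityReport()
    k = len(pairs)
    if k >= 2:
        rep.heterogeneity = cochran_q(pairs)
        rep.loo = leave_one_out(pairs, model=ivw_model)
    if k >= 3:
        _, rep.egger_intercept = egger(pairs)
    if k >= 4:
        rep.presso = mr_presso(pairs, n_sim=n_sim, seed=seed)
    return rep
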