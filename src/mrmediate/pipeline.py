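"""Two-step MR orchestration: forward screen, reverse-MR exclusion,
exposure->mediator linkage and mediated-proportion computation.

The design mirrors the standard two-step mediation workflow on summary data:

1. screen every exposure (and every candidate mediator) against the outcome
   with IVW as the primary method and the complementary estimators plus the
   sensitivity suite alongside;
2. exclude exposures that show a reverse (outcome->exposure) IVW signal;
3. estimate exposure->mediator effects for the retained exposures against the
   screened mediators (mediator classes such as metabolite ratios and unknown
   metabolites are excluded at this stage);
4. for each nominally significant exposure->mediator link, combine
   beta1 (exposure->mediator), beta2 (the mediator's total effect on the
   outcome from its own screen) and beta_all (the exposure's total effect)
   into the mediated proportion.

beta2 is a univariable (total) mediator->outcome effect, which is what
two-sample summary data supports; no multivariable adjustment is attempted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InputError
from .estimators import MREstimate, all_estimates, ivw
from .mediation import MediationEstimate, mediation_proportion
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import (HarmonizedInstruments, SelectionConfig, TraitSumStats,
                       harmonize, read_sumstats, select_instruments)

logger = logging.getLogger(__name__)

ESTIMATE_COLUMNS = ["exposure", "outcome", "method", "nsnp", "beta", "se",
                    "pval", "or", "ci_low", "ci_high"]


@dataclass
class PipelineConfig:
    """Thresholds and switches for the whole two-step analysis.

    ``alpha`` is the nominal screening threshold (the source analyses use
    nominal p < .05 throughout; Benjamini-Hochberg columns are reported
    alongside when ``bh_adjust`` is set, never silently substituted).
    """

    alpha: float = 0.05
    exposure_selection: SelectionConfig = field(
        default_factory=lambda: SelectionConfig(p_threshold=1e-5))
    outcome_selection: SelectionConfig = field(
        default_factory=lambda: SelectionConfig(p_threshold=5e-8))
    ivw_model: str = "multiplicative_random"
    seed: int = 0
    n_boot: int = 1000
    n_sim_presso: int = 1000
    mediator_exclusion: tuple[str, ...] = ("ratio", "unknown")
    run_complementary: bool = True
    run_sensitivity: bool = True
    bh_adjust: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")


def derive_seed(base_seed: int, *labels: str) -> int:
    """Stable per-analysis seed (< 2^31) from the run seed and analysis labels."""
    tag = "|".join(labels).encode()
    return (zlib.crc32(tag) ^ (base_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


@dataclass
class MRResult:
    """One exposure-outcome analysis: estimates plus diagnostics."""

    exposure: str
    outcome: str
    nsnp: int
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    egger_intercept: object | None = None
    sensitivity: SensitivityReport | None = None
    instruments: HarmonizedInstruments | None = None
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None

    def rows(self) -> list[list]:
        return [[self.exposure, self.outcome, m, e.nsnp, e.beta, e.se, e.pval,
                 e.or_, e.ci_low, e.ci_high] for m, e in self.estimates.items()]


def analyze_pair(exposure: TraitSumStats, outcome: TraitSumStats,
                 cfg: PipelineConfig, selection: SelectionConfig | None = None,
                 ld=None) -> MRResult:
    """Select instruments, harmonize and estimate one exposure-outcome pair."""
    selection = selection or cfg.exposure_selection
    instruments = select_instruments(exposure, selection, ld=ld)
    if not instruments:
        logger.info("%s -> %s: no instruments at p < %g, skipped",
                    exposure.trait_id, outcome.trait_id, selection.p_threshold)
        return MRResult(exposure.trait_id, outcome.trait_id, 0,
                        skipped_reason="no instruments after selection")
    pairs = harmonize(instruments, outcome)
    if len(pairs) == 0:
        return MRResult(exposure.trait_id, outcome.trait_id, 0,
                        skipped_reason="no instruments after harmonization")
    seed = derive_seed(cfg.seed, exposure.trait_id, outcome.trait_id)
    if cfg.run_complementary:
        estimates, intercept = all_estimates(pairs, n_boot=cfg.n_boot,
                                             seed=seed, ivw_model=cfg.ivw_model)
    else:
        estimates, intercept = {"ivw": ivw(pairs, model=cfg.ivw_model)}, None
    sens = None
    if cfg.run_sensitivity:
        sens = sensitivity_report(pairs, n_sim=cfg.n_sim_presso,
                                  seed=derive_seed(cfg.seed, exposure.trait_id,
                                                   outcome.trait_id, "presso"),
                                  ivw_model=cfg.ivw_model)
        if intercept is None and sens.egger_intercept is not None:
            intercept = sens.egger_intercept
    return MRResult(exposure.trait_id, outcome.trait_id, len(pairs),
                    estimates, intercept, sens, pairs)


@dataclass
class ScreenResult:
    """One exposure's forward-screen outcome against the study outcome."""

    exposure_id: str
    primary: MREstimate | None
    complementary: dict[str, MREstimate]
    sensitivity: SensitivityReport | None
    selected: bool
    skipped_reason: str | None = None
    mr: MRResult | None = None


def forward_screen(exposures: list[TraitSumStats], outcome: TraitSumStats,
                   cfg: PipelineConfig, ld=None) -> list[ScreenResult]:
    """Screen each exposure against the outcome; selected = IVW p < alpha.

    Exposures with no usable instruments are reported as skipped, not errors.
    """
    if outcome is None:
        raise InputError("outcome trait is required")
    results = []
    for exp in exposures:
        mr = analyze_pair(exp, outcome, cfg, cfg.exposure_selection, ld=ld)
        if mr.skipped:
            results.append(ScreenResult(exp.trait_id, None, {}, None, False,
                                        mr.skipped_reason, mr))
            continue
        primary = mr.estimates["ivw"]
        comp = {m: e for m, e in mr.estimates.items() if m != "ivw"}
        results.append(ScreenResult(exp.trait_id, primary, comp,
                                    mr.sensitivity,
                                    primary.pval < cfg.alpha, None, mr))
    return results


@dataclass
class ReverseFilterResult:
    retained: list[str]
    table: pd.DataFrame
    no_outcome_instruments: bool = False


def reverse_mr_filter(outcome: TraitSumStats,
                      selected_exposures: list[TraitSumStats],
                      cfg: PipelineConfig) -> ReverseFilterResult:
    """Drop exposures with a reverse (outcome->exposure) IVW signal.

    The outcome's instruments are selected at the genome-wide threshold
    (``cfg.outcome_selection``).  If none reach it, all exposures are retained
    and the result is flagged rather than erroring.
    """
    rows = []
    if not selected_exposures:
        return ReverseFilterResult([], pd.DataFrame(
            columns=["exposure", "reverse_beta", "reverse_pval", "nsnp",
                     "retained"]))
    out_instruments = select_instruments(outcome, cfg.outcome_selection)
    if not out_instruments:
        logger.warning("reverse MR: no genome-wide-significant outcome "
                       "instruments; retaining all exposures (flagged)")
        table = pd.DataFrame(
            [[t.trait_id, np.nan, np.nan, 0, True] for t in selected_exposures],
            columns=["exposure", "reverse_beta", "reverse_pval", "nsnp",
                     "retained"])
        return ReverseFilterResult([t.trait_id for t in selected_exposures],
                                   table, no_outcome_instruments=True)
    retained = []
    for exp in selected_exposures:
        pairs = harmonize(out_instruments, exp)
        if len(pairs) == 0:
            rows.append([exp.trait_id, np.nan, np.nan, 0, True])
            retained.append(exp.trait_id)
            continue
        est = ivw(pairs, model=cfg.ivw_model)
        keep = est.pval >= cfg.alpha
        rows.append([exp.trait_id, est.beta, est.pval, est.nsnp, keep])
        if keep:
            retained.append(exp.trait_id)
    table = pd.DataFrame(rows, columns=["exposure", "reverse_beta",
                                        "reverse_pval", "nsnp", "retained"])
    return ReverseFilterResult(retained, table)


def is_excluded_mediator(trait_id: str, rules: tuple[str, ...]) -> bool:
    """Mediator-class exclusion: substring rules plus the X- unknown prefix."""
    low = trait_id.lower()
    if any(r.lower() in low for r in rules):
        return True
    return low.startswith("x-")


@dataclass
class LinkResult:
    table: pd.DataFrame
    results: dict[tuple[str, str], MRResult]
    candidates: list[tuple[str, str]]
    excluded_mediators: list[str]


def link_exposure_mediator(exposures: list[TraitSumStats],
                           mediators: list[TraitSumStats],
                           cfg: PipelineConfig, ld=None) -> LinkResult:
    """All exposure x mediator MR analyses; IVW p < alpha flags candidates."""
    excluded = [m.trait_id for m in mediators
                if is_excluded_mediator(m.trait_id, cfg.mediator_exclusion)]
    mediators = [m for m in mediators if m.trait_id not in excluded]
    if excluded:
        logger.info("mediator exclusion dropped: %s", ", ".join(excluded))
    rows, results, candidates = [], {}, []
    for exp in exposures:
        for med in mediators:
            mr = analyze_pair(exp, med, cfg, cfg.exposure_selection, ld=ld)
            results[(exp.trait_id, med.trait_id)] = mr
            if mr.skipped:
                continue
            rows.extend(mr.rows())
            if mr.estimates["ivw"].pval < cfg.alpha:
                candidates.append((exp.trait_id, med.trait_id))
    table = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
    return LinkResult(table, results, candidates, excluded)


@dataclass
class TwoStepResult:
    """Everything the two-step pipeline produces, in memory."""

    exposure_screen: list[ScreenResult]
    mediator_screen: list[ScreenResult]
    reverse: ReverseFilterResult
    link: LinkResult
    mediation: pd.DataFrame
    mediation_estimates: dict[tuple[str, str], MediationEstimate]
    config: PipelineConfig

    def estimates_table(self) -> pd.DataFrame:
        rows = []
        for screen in (self.exposure_screen, self.mediator_screen):
            for s in screen:
                if s.mr is not None and not s.mr.skipped:
                    rows.extend(s.mr.rows())
        df = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
        return pd.concat([df, self.link.table], ignore_index=True)


def _bh(pvals: pd.Series) -> pd.Series:
    from statsmodels.stats.multitest import multipletests
    if pvals.empty:
        return pvals
    return pd.Series(multipletests(pvals.to_numpy(), method="fdr_bh")[1],
                     index=pvals.index)


def run_two_step(exposures: list[TraitSumStats],
                 mediators: list[TraitSumStats],
                 outcome: TraitSumStats,
                 cfg: PipelineConfig | None = None, ld=None,
                 through: str = "mediate") -> TwoStepResult:
    """Run the two-step mediation workflow in memory.

    Outputs are a pure function of (inputs, config, seed): all stochastic
    steps derive their seeds from ``cfg.seed`` and the analysis labels.
    ``through`` can stop the run early ("screen" or "reverse").
    """
    cfg = cfg or PipelineConfig()
    empty_link = LinkResult(pd.DataFrame(columns=ESTIMATE_COLUMNS), {}, [], [])
    exp_screen = forward_screen(exposures, outcome, cfg, ld=ld)
    med_screen = forward_screen(mediators, outcome, cfg, ld=ld)
    if through == "screen":
        return TwoStepResult(exp_screen, med_screen,
                             ReverseFilterResult([], pd.DataFrame()),
                             empty_link, _empty_mediation_table(), {}, cfg)

    selected_exp = [t for t, s in zip(exposures, exp_screen) if s.selected]
    reverse = reverse_mr_filter(outcome, selected_exp, cfg)
    retained_exp = [t for t in selected_exp if t.trait_id in reverse.retained]
    if through == "reverse":
        return TwoStepResult(exp_screen, med_screen, reverse, empty_link,
                             _empty_mediation_table(), {}, cfg)

    selected_med = [t for t, s in zip(mediators, med_screen) if s.selected]
    link = link_exposure_mediator(retained_exp, selected_med, cfg, ld=ld)

    med_by_id = {s.exposure_id: s for s in med_screen}
    exp_by_id = {s.exposure_id: s for s in exp_screen}
    rows, estimates = [], {}
    for (eid, mid) in link.candidates:
        b_all = exp_by_id[eid].primary
        b1 = link.results[(eid, mid)].estimates["ivw"]
        b2 = med_by_id[mid].primary
        if b_all is None or b2 is None or b_all.beta == 0:
            continue
        est = mediation_proportion(b_all.beta, b_all.se, b1.beta, b1.se,
                                   b2.beta, b2.se)
        estimates[(eid, mid)] = est
        rows.append([eid, mid, est.beta_all, est.beta1, est.beta2,
                     est.indirect, est.proportion, est.se_proportion,
                     est.ci_low, est.ci_high])
    mediation = pd.DataFrame(rows, columns=_MEDIATION_COLUMNS)
    return TwoStepResult(exp_screen, med_screen, reverse, link, mediation,
                         estimates, cfg)


_MEDIATION_COLUMNS = ["exposure", "mediator", "beta_all", "beta1", "beta2",
                      "indirect", "proportion", "se_proportion", "ci_low",
                      "ci_high"]


def _empty_mediation_table() -> pd.DataFrame:
    return pd.DataFrame(columns=_MEDIATION_COLUMNS)


# ---------------------------------------------------------------------------
# manifest-driven entry point


def _load_trait(entry, default_type: str) -> TraitSumStats:
    if isinstance(entry, str):
        entry = {"path": entry}
    return read_sumstats(entry["path"],
                         column_map=entry.get("column_map"),
                         trait_id=entry.get("id"),
                         trait_type=entry.get("trait_type", default_type))


def config_from_manifest(manifest: dict) -> PipelineConfig:
    c = manifest.get("config", {})
    exp_sel = SelectionConfig(
        p_threshold=float(c.get("p_exposure", 1e-5)),
        clump_window_kb=int(c.get("clump_window_kb", 10_000)),
        clump_r2_max=float(c.get("clump_r2", 0.001)))
    out_sel = dataclasses.replace(exp_sel,
                                  p_threshold=float(c.get("p_outcome", 5e-8)))
    return PipelineConfig(
        alpha=float(c.get("alpha", 0.05)),
        exposure_selection=exp_sel, outcome_selection=out_sel,
        ivw_model=c.get("ivw_model", "multiplicative_random"),
        seed=int(c.get("seed", 0)),
        n_boot=int(c.get("n_boot", 1000)),
        n_sim_presso=int(c.get("n_sim_presso", 1000)),
        mediator_exclusion=tuple(c.get("mediator_exclusion",
                                       ("ratio", "unknown"))),
    )


def run_pipeline(manifest, out_dir=None, stage: str = "report",
                 cfg: PipelineConfig | None = None) -> TwoStepResult:
    """Manifest-driven pipeline run with on-disk outputs.

    ``manifest`` is a dict or a path to a YAML file with keys ``exposures``,
    ``mediators``, ``outcome`` (file paths or {id, path, column_map} entries)
    and an optional ``config`` block.  ``stage`` limits how far the run goes
    (screen < reverse < mediate = report); the report stage also writes the
    sensitivity JSONs.  Partial results are written even when later stages
    produce nothing.
    """
    if not isinstance(manifest, dict):
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    if "outcome" not in manifest:
        raise InputError("manifest must name an outcome trait")
    cfg = cfg or config_from_manifest(manifest)
    exposures = [_load_trait(e, "continuous")
                 for e in manifest.get("exposures", [])]
    mediators = [_load_trait(e, "continuous")
                 for e in manifest.get("mediators", [])]
    outcome = _load_trait(manifest["outcome"], "binary")

    stages = ("screen", "reverse", "mediate", "report")
    if stage not in stages:
        raise ConfigurationError(f"stage must be one of {stages}")
    through = stage if stage in ("screen", "reverse") else "mediate"
    result = run_two_step(exposures, mediators, outcome, cfg, through=through)

    if out_dir is not None:
        write_outputs(result, out_dir, full=(stage == "report"))
    return result


def write_outputs(result: TwoStepResult, out_dir, full: bool = True) -> None:
    """Write the estimate/mediation tables, audits and provenance log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    est = result.estimates_table()
    if result.config.bh_adjust and not est.empty:
        mask = est["method"] == "ivw"
        est["pval_bh"] = np.nan
        est.loc[mask, "pval_bh"] = _bh(est.loc[mask, "pval"])
    est.to_csv(out / "estimates.tsv", sep="\t", index=False,
               float_format="%.10g")
    if not result.reverse.table.empty:
        result.reverse.table.to_csv(out / "reverse_mr.tsv", sep="\t",
                                    index=False, float_format="%.10g")
    result.mediation.to_csv(out / "mediation.tsv", sep="\t", index=False,
                            float_format="%.10g")
    screen_rows = []
    for label, screen in (("exposure", result.exposure_screen),
                          ("mediator", result.mediator_screen)):
        for s in screen:
            screen_rows.append([
                label, s.exposure_id, s.selected,
                s.primary.pval if s.primary else np.nan,
                s.skipped_reason or ""])
    pd.DataFrame(screen_rows, columns=["role", "trait", "selected",
                                       "ivw_pval", "skipped_reason"]).to_csv(
        out / "screen.tsv", sep="\t", index=False, float_format="%.10g")
    if full:
        sens_dir = out / "sensitivity"
        sens_dir.mkdir(exist_ok=True)
        audits = []
        for s in result.exposure_screen + result.mediator_screen:
            mr = s.mr
            if mr is None or mr.skipped:
                continue
            if mr.sensitivity is not None:
                path = sens_dir / f"{mr.exposure}__{mr.outcome}.json"
                path.write_text(mr.sensitivity.to_json(indent=1))
            if mr.instruments is not None:
                a = mr.instruments.audit.copy()
                a.insert(0, "exposure", mr.exposure)
                a.insert(1, "outcome", mr.outcome)
                audits.append(a)
        if audits:
            pd.concat(audits, ignore_index=True).to_csv(
                out / "harmonization_audit.tsv", sep="\t", index=False)
    provenance = {
        "package": "mrmediate",
        "version": __version__,
        "seed": result.config.seed,
        "alpha": result.config.alpha,
        "p_exposure": result.config.exposure_selection.p_threshold,
        "p_outcome": result.config.outcome_selection.p_threshold,
        "clump_window_kb": result.config.exposure_selection.clump_window_kb,
        "clump_r2_max": result.config.exposure_selection.clump_r2_max,
        "ivw_model": result.config.ivw_model,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1,
                                                    sort_keys=True))
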