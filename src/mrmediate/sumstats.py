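"""GWAS summary statistics: containers, file I/O, instrument selection, harmonization.

The atoms of every analysis are per-variant association records (one SNP, one
trait).  A :class:`TraitSumStats` wraps a validated pandas table of such records;
:func:`select_instruments` applies the p-value threshold and greedy LD clumping;
:func:`harmonize` aligns effect alleles between an exposure's instruments and a
second trait's records, producing the (beta_exp, beta_out) pairs every causal
estimator consumes.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: canonical column order of the summary-statistics TSV dialect
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_MANDATORY = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pval"]

#: complementary base pairs whose alleles are strand-ambiguous
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class VariantAssociation:
    """Summary statistics of one variant for one trait.

    ``beta`` is in per-SD units for continuous traits and log-odds for binary
    traits.  ``eaf`` is the effect-allele frequency and may be missing (NaN).
    Positions are 1-based.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not np.isnan(self.eaf) and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf outside [0, 1]")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical alleles")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.variant_id}: pval outside (0, 1]")

    @property
    def palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in _PALINDROMIC_PAIRS

    @property
    def f_statistic(self) -> float:
        return f_statistic(self.beta, self.se)


@dataclass
class TraitSumStats:
    """A trait's full set of variant associations, keyed by ``variant_id``.

    ``trait_type`` is ``continuous`` or ``binary``; binary traits must carry
    log-odds effects (``effect_units == "logOR"``).
    """

    trait_id: str
    trait_type: str
    effect_units: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")
        if self.effect_units not in ("per_SD", "logOR"):
            raise ConfigurationError(f"unknown effect_units {self.effect_units!r}")
        if self.trait_type == "binary" and self.effect_units != "logOR":
            raise ConfigurationError("binary traits must use logOR effect units")
        if self.table["variant_id"].duplicated().any():
            dups = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"]
            raise InputError(f"duplicate variant_id in {self.trait_id}: {list(dups[:3])}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def get(self, variant_id: str) -> VariantAssociation:
        row = self.table.loc[self.table["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        return _row_to_record(row.iloc[0])

    @property
    def records(self) -> list[VariantAssociation]:
        return [_row_to_record(r) for _, r in self.table.iterrows()]

    @classmethod
    def from_records(cls, trait_id: str, trait_type: str, effect_units: str,
                     records: Sequence[VariantAssociation]) -> "TraitSumStats":
        table = pd.DataFrame(
            [[v.variant_id, v.chrom, v.pos, v.effect_allele, v.other_allele,
              v.eaf, v.beta, v.se, v.pval, v.n] for v in records],
            columns=CANONICAL_COLUMNS,
        )
        return cls(trait_id, trait_type, effect_units, table)


@dataclass(frozen=True)
class SelectionConfig:
    """Instrument selection thresholds.

    Defaults follow common two-sample MR practice for non-genome-wide exposures:
    p < 1e-5 with 10,000 kb / r^2 < 0.001 clumping; an outcome used as exposure
    in reverse MR should use ``p_threshold=5e-8``.  ``f_min`` is the weak
    instrument flag threshold.
    """

    p_threshold: float = 1e-5
    clump_window_kb: int = 10_000
    clump_r2_max: float = 0.001
    f_min: float = 10.0
    f_formula: str = "z2"  # "z2" -> (beta/se)^2, "r2" -> (n-2) R^2/(1-R^2)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if not (0.0 <= self.clump_r2_max <= 1.0):
            raise ConfigurationError("clump_r2_max must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ConfigurationError("clump_window_kb must be > 0")
        if self.f_formula not in ("z2", "r2"):
            raise ConfigurationError("f_formula must be 'z2' or 'r2'")


def _row_to_record(row: pd.Series) -> VariantAssociation:
    return VariantAssociation(
        variant_id=str(row["variant_id"]), chrom=str(row["chrom"]),
        pos=int(row["pos"]), effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        eaf=float(row["eaf"]) if pd.notna(row["eaf"]) else float("nan"),
        beta=float(row["beta"]), se=float(row["se"]), pval=float(row["pval"]),
        n=float(row["n"]) if pd.notna(row["n"]) else float("nan"),
    )


def f_statistic(beta: float, se: float) -> float:
    """Single-variant instrument-strength F statistic, ``(beta/se)**2``."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def f_statistic_r2(beta: float, eaf: float, n: float) -> float:
    """Alternative F from variance explained: R^2 = 2*eaf*(1-eaf)*beta^2."""
    r2 = 2.0 * eaf * (1.0 - eaf) * beta ** 2
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"variance explained {r2} outside [0, 1)")
    return (n - 2.0) * r2 / (1.0 - r2)


def _validate_table(df: pd.DataFrame, trait_id: str) -> pd.DataFrame:
    """Drop rows violating hard invariants (logged); flag soft inconsistencies."""
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    ok = (
        (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["effect_allele"] != df["other_allele"])
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
        & df["beta"].notna() & df["se"].notna() & df["pval"].notna()
    )
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning("%s: dropped %d row(s) failing validation", trait_id, n_drop)
    df = df.loc[ok].reset_index(drop=True)
    # p-value vs z-score consistency: flag (never drop) >2-fold discrepancies
    with np.errstate(divide="ignore"):
        expected = 2.0 * sps.norm.sf(np.abs(df["beta"] / df["se"]))
    ratio = np.where(expected > 0, df["pval"] / np.maximum(expected, 1e-300), np.inf)
    flagged = (ratio > 2.0) | (ratio < 0.5)
    df["pval_flagged"] = flagged
    n_flag = int(flagged.sum())
    if n_flag:
        logger.info("%s: flagged %d row(s) with p inconsistent with beta/se", trait_id, n_flag)
    return df


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "continuous",
    effect_units: str | None = None,
    sep: str = "\t",
) -> TraitSumStats:
    """Read a delimited summary-statistics table into a validated TraitSumStats.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"variant_id": "SNP", "pval": "p"}``.  Mandatory columns: variant_id,
    effect_allele, other_allele, beta, se, pval.  Missing optional columns are
    filled (eaf/n -> NaN, chrom -> "1", pos -> row order).  Rows failing hard
    invariants are dropped with a logged count; alleles are upper-cased.
    """
    df = pd.read_csv(path, sep=sep, na_values=["NA", "NaN", ""],
                     float_precision="round_trip")
    if df.empty:
        raise InputError(f"{path}: empty summary-statistics file")
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    for col in _MANDATORY:
        if col not in df.columns:
            raise ConfigurationError(
                f"{path}: mandatory column {col!r} not found "
                f"(available: {list(df.columns)})")
    if "chrom" not in df.columns:
        df["chrom"] = "1"
    if "pos" not in df.columns:
        df["pos"] = np.arange(len(df))
    for col in ("eaf", "n"):
        if col not in df.columns:
            df[col] = np.nan
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    df = df[CANONICAL_COLUMNS]
    if effect_units is None:
        effect_units = "logOR" if trait_type == "binary" else "per_SD"
    df = _validate_table(df, trait_id or str(path))
    return TraitSumStats(trait_id or str(path), trait_type, effect_units,
                         df.drop(columns=["pval_flagged"]))


def write_sumstats(stats: TraitSumStats, path) -> None:
    """Write the canonical TSV dialect (missing values encoded as ``NA``)."""
    out = stats.table[CANONICAL_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA",
               float_format="%.17g")  # full float64 round-trip precision


LDLookup = Callable[[str, str], float] | Mapping


def _pair_r2(ld: LDLookup | None, a: str, b: str) -> float:
    if ld is None:
        return 1.0  # no LD information: treat in-window pairs as correlated
    if callable(ld):
        return float(ld(a, b))
    try:
        return float(ld.get((a, b), ld.get((b, a), 0.0)))
    except AttributeError as exc:  # pragma: no cover
        raise ConfigurationError("ld lookup must be callable or a mapping") from exc


def select_instruments(
    stats: TraitSumStats,
    cfg: SelectionConfig | None = None,
    ld: LDLookup | None = None,
) -> list[VariantAssociation]:
    """Threshold on p-value then greedily clump, best p first.

    Survivors are sorted by ascending p (variant_id breaks ties, so the result
    is invariant to input row order); the best is kept and every other survivor
    on the same chromosome within ``clump_window_kb`` whose r^2 with it is
    >= ``clump_r2_max`` is removed.  Without an ``ld`` lookup all in-window
    pairs are treated as correlated (pure distance pruning).  The retained set
    is returned sorted by (chrom, pos).
    """
    cfg = cfg or SelectionConfig()
    df = stats.table.loc[stats.table["pval"] < cfg.p_threshold]
    if df.empty:
        return []
    df = df.sort_values(["pval", "variant_id"], kind="mergesort").reset_index(drop=True)
    window_bp = cfg.clump_window_kb * 1000
    alive = np.ones(len(df), dtype=bool)
    kept_idx: list[int] = []
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    vid = df["variant_id"].to_numpy()
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept_idx.append(i)
        for j in range(i + 1, len(df)):
            if not alive[j] or chrom[j] != chrom[i]:
                continue
            if abs(int(pos[j]) - int(pos[i])) <= window_bp:
                if _pair_r2(ld, vid[i], vid[j]) >= cfg.clump_r2_max:
                    alive[j] = False
    kept = df.iloc[kept_idx].sort_values(["chrom", "pos"], kind="mergesort")
    return [_row_to_record(r) for _, r in kept.iterrows()]


@dataclass
class HarmonizedInstruments:
    """Allele-aligned exposure/outcome effect pairs, canonically sorted by id.

    ``audit`` records one row per input instrument with the ``action_taken``
    (unchanged, allele_flip, dropped_palindromic, dropped_incompatible,
    dropped_missing) and whether the variant is palindromic.
    """

    variant_id: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        order = np.argsort(self.variant_id.astype(str), kind="stable")
        for name in ("variant_id", "beta_exp", "se_exp", "beta_out", "se_out"):
            setattr(self, name, getattr(self, name)[order])
        if self.audit.empty:
            self.audit = pd.DataFrame({
                "variant_id": self.variant_id,
                "action_taken": "unchanged",
                "palindromic": False,
            })

    def __len__(self) -> int:
        return len(self.variant_id)

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out,
                    variant_id=None) -> "HarmonizedInstruments":
        beta_exp = np.asarray(beta_exp, dtype=float)
        if variant_id is None:
            variant_id = np.array([f"v{i:06d}" for i in range(len(beta_exp))],
                                  dtype=object)
        return cls(variant_id, beta_exp, se_exp, beta_out, se_out)

    def subset(self, mask) -> "HarmonizedInstruments":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            sel = np.zeros(len(self), dtype=bool)
            sel[mask] = True
            mask = sel
        return HarmonizedInstruments(
            self.variant_id[mask], self.beta_exp[mask], self.se_exp[mask],
            self.beta_out[mask], self.se_out[mask],
            self.audit.loc[self.audit["variant_id"].isin(self.variant_id[mask])]
            .reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant_id": self.variant_id, "beta_exp": self.beta_exp,
            "se_exp": self.se_exp, "beta_out": self.beta_out,
            "se_out": self.se_out,
        })


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC_PAIRS


def harmonize(
    exp_instruments: Sequence[VariantAssociation],
    out_stats: TraitSumStats,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedInstruments:
    """Align the outcome trait's alleles to the exposure instruments.

    Matching allele pairs are kept as-is; swapped pairs flip the outcome beta's
    sign (and eaf -> 1-eaf).  Palindromic variants (A/T, C/G) are oriented by
    allele frequency when both traits' eaf are available and far from 0.5
    (outside ``palindrome_eaf_window``), otherwise dropped.  Incompatible
    allele pairs and variants absent from the outcome are dropped.  Every
    exclusion is recorded in the audit.
    """
    out_idx = out_stats.table.set_index("variant_id")
    ids, bx, sx, by, sy = [], [], [], [], []
    audit_rows = []

    for v in exp_instruments:
        pal = v.palindromic
        if v.variant_id not in out_idx.index:
            audit_rows.append((v.variant_id, "dropped_missing", pal))
            continue
        o = out_idx.loc[v.variant_id]
        o_ea, o_oa = str(o["effect_allele"]), str(o["other_allele"])
        o_beta, o_se = float(o["beta"]), float(o["se"])
        o_eaf = float(o["eaf"]) if pd.notna(o["eaf"]) else float("nan")

        same = (o_ea == v.effect_allele and o_oa == v.other_allele)
        swapped = (o_ea == v.other_allele and o_oa == v.effect_allele)
        if not (same or swapped):
            audit_rows.append((v.variant_id, "dropped_incompatible", pal))
            continue

        if pal:
            ambiguous = (
                np.isnan(v.eaf) or np.isnan(o_eaf)
                or abs(v.eaf - 0.5) <= palindrome_eaf_window
                or abs(o_eaf - 0.5) <= palindrome_eaf_window
            )
            if ambiguous:
                audit_rows.append((v.variant_id, "dropped_palindromic", True))
                continue
            # orient by frequency: the labels are strand-ambiguous, so alignment
            # is decided by whether both eafs sit on the same side of 0.5
            aligned = (v.eaf < 0.5) == (o_eaf < 0.5)
            action = "unchanged" if aligned else "allele_flip"
            out_beta = o_beta if aligned else -o_beta
        else:
            action = "unchanged" if same else "allele_flip"
            out_beta = o_beta if same else -o_beta

        ids.append(v.variant_id)
        bx.append(v.beta)
        sx.append(v.se)
        by.append(out_beta)
        sy.append(o_se)
        audit_rows.append((v.variant_id, action, pal))

    audit = pd.DataFrame(audit_rows,
                         columns=["variant_id", "action_taken", "palindromic"])
    n_drop = int(audit["action_taken"].str.startswith("dropped").sum())
    if n_drop:
        logger.info("harmonize: dropped %d of %d instrument(s)",
                    n_drop, len(exp_instruments))
    return HarmonizedInstruments(
        np.array(ids, dtype=object), np.array(bx), np.array(sx),
        np.array(by), np.array(sy), audit)
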