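"""Shared fixtures and simulation helpers for the test suite."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import mrmediate as mm


@pytest.fixture
def toy_pairs():
    """3-instrument toy set: (beta_exp, se_exp, beta_out, se_out) rows."""
    return mm.HarmonizedInstruments.from_arrays(
        beta_exp=[0.1, 0.2, 0.15], se_exp=[0.02, 0.02, 0.02],
        beta_out=[0.05, 0.09, 0.08], se_out=[0.01, 0.01, 0.01])


@pytest.fixture
def noisy_pairs():
    """7-instrument set with visible heterogeneity, fixed draw."""
    rng = np.random.default_rng(42)
    bx = rng.uniform(0.05, 0.3, 7)
    by = 0.4 * bx + rng.normal(0, 0.02, 7)
    return mm.HarmonizedInstruments.from_arrays(
        beta_exp=bx, se_exp=np.full(7, 0.01), beta_out=by,
        se_out=np.full(7, 0.02))


def make_trait(records, trait_id="trait", trait_type="continuous"):
    units = "logOR" if trait_type == "binary" else "per_SD"
    return mm.TraitSumStats.from_records(trait_id, trait_type, units, records)


def variant(vid, chrom="1", pos=1, ea="A", oa="G", eaf=0.3, beta=0.1,
            se=0.02, pval=None, n=10000.0):
    if pval is None:
        if se > 0:
            from scipy import stats as sps
            pval = max(float(2 * sps.norm.sf(abs(beta / se))), 5e-324)
        else:
            pval = 0.5
    return mm.VariantAssociation(vid, chrom, pos, ea, oa, eaf, beta, se,
                                 pval, n)


def ivw_leg(exposure, outcome, seed, model="multiplicative_random"):
    """One selection->harmonization->IVW leg, as the pipeline runs it."""
    cfg = mm.PipelineConfig(run_complementary=False, run_sensitivity=False,
                            seed=seed, ivw_model=model)
    res = mm.analyze_pair(exposure, outcome, cfg)
    return None if res.skipped else res.estimates["ivw"]


def relabel_trait(stats, prefix, trait_id=None):
    t = stats.table.copy()
    t["variant_id"] = prefix + t["variant_id"]
    return mm.TraitSumStats(trait_id or stats.trait_id, stats.trait_type,
                            stats.effect_units, t)


def composite_study(seed):
    """3 exposures / 2 mediators / 1 outcome with one true mediated path.

    Exposure E1 acts on the outcome partly through mediator M1 (true mediated
    proportion 0.545...); E2, E3, M2 come from all-null worlds.  Each
    simulated world contributes its variants (disjoint ids) to the shared
    outcome trait, which also carries outcome-specific loci so reverse MR has
    instruments.
    """
    strong = dataclasses.replace(mm.scenario("full_mediation"),
                                 h2_x=0.3, h2_m=0.3)
    null = dataclasses.replace(strong, beta1_true=0.0, beta2_true=0.0,
                               theta_direct=0.0)
    traits, y_parts, truth1 = {}, [], None
    for i, cfg in enumerate((strong, null, null), start=1):
        e, m, y, truth = mm.simulate_sumstats(
            dataclasses.replace(cfg, seed=seed + i))
        traits[f"E{i}"] = relabel_trait(e, f"s{i}", f"E{i}")
        if i <= 2:
            traits[f"M{i}"] = relabel_trait(m, f"s{i}", f"M{i}")
        y_parts.append(relabel_trait(y, f"s{i}").table)
        if i == 1:
            truth1 = truth
    outcome = mm.TraitSumStats("UC", "binary", "logOR",
                               pd.concat(y_parts, ignore_index=True))
    return traits, outcome, truth1
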