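"""Synthetic cohort generator: determinism, composition, planted truth."""
import math

import numpy as np
import pytest

from nmdx.config import CohortConfig, default_config
from nmdx.simulate import (breakpoint_touch_probability, generate_cohort,
                           generate_dmd_cohort, generate_variants,
                           simulate_cohort, truth_fit_flags)
from nmdx.types import ValidationError


def test_degenerate_category_weights():
    cfg = default_config(n_probands=5, seed=1)
    cfg.category_weights = {"LGMD": 1.0}
    cfg.validate()
    probands, truths = generate_cohort(cfg)
    assert len(probands) == 5
    assert all(p.diagnostic_category == "LGMD" for p in probands)


def test_invalid_weights_name_offending_map():
    cfg = default_config(n_probands=5)
    cfg.category_weights = {"LGMD": 0.6, "PN": 0.6}
    with pytest.raises(ValidationError, match="category_weights"):
        cfg.validate()
    cfg2 = default_config()
    cfg2.dmd_breakpoint_weights = {45: 0.7, 50: 0.7}
    with pytest.raises(ValidationError, match="dmd_breakpoint_weights"):
        cfg2.validate()


def test_determinism_and_prefix_stability():
    cfg_a = default_config(n_probands=40, seed=3)
    cfg_b = default_config(n_probands=40, seed=3)
    pa, ta = generate_cohort(cfg_a)
    pb, tb = generate_cohort(cfg_b)
    assert pa == pb and ta == tb
    # growing the cohort must not reshuffle earlier probands
    cfg_c = default_config(n_probands=80, seed=3)
    pc, tc = generate_cohort(cfg_c)
    assert pc[:40] == pa and tc[:40] == ta


def test_composition_recovery():
    """Configured proportions recovered within 4 binomial standard errors."""
    n = 20000
    probands, _ = generate_cohort(default_config(n_probands=n, seed=12))
    cats = [p.diagnostic_category for p in probands]
    for cat, p_true in (("LGMD", 0.181), ("PN", 0.155), ("CM_CMD", 0.094),
                        ("DMD_BMD", 0.086)):
        share = cats.count(cat) / n
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(share - p_true) <= 4 * se, cat
    male = sum(p.sex == "male" for p in probands) / n
    assert abs(male - 0.65) <= 4 * math.sqrt(0.65 * 0.35 / n)
    ages = np.array([p.age_years for p in probands])
    assert abs(np.median(ages) - 26) < 1.5
    assert abs((ages <= 18).mean() - 0.35) <= 4 * math.sqrt(0.35 * 0.65 / n)


def test_probands_carry_category_consistent_hpo_terms():
    from nmdx.simulate import hpo_vocab

    vocab = hpo_vocab()
    probands, _ = generate_cohort(default_config(n_probands=50, seed=9))
    for p in probands:
        assert len(p.hpo_positive) >= 1
        assert p.hpo_positive <= set(vocab[p.diagnostic_category])
        assert not (p.hpo_positive & p.hpo_negative)


def test_planted_variants_respect_truth(small_cohort):
    cfg = small_cohort.config
    for proband in small_cohort.probands:
        truth = small_cohort.truth_of(proband.id)
        variants = small_cohort.variants[proband.id]
        ids = {v.id for v in variants}
        # consistency: every causal id resolves to a generated variant
        assert set(truth.causal_variant_ids) <= ids
        causal = [v for v in variants if v.id in truth.causal_variant_ids]
        if truth.outcome == "solved" and truth.mode == "AR":
            assert (any(v.zygosity == "hom" for v in causal)
                    or len(causal) >= 2)
        if truth.outcome == "possibly_solved":
            assert all(v.max_af < 1e-4 for v in causal)
        if truth.outcome == "unsolved":
            assert causal == []
            assert len(variants) == cfg.noise_variants_per_proband


def test_decoy_frequencies_straddle_both_thresholds(small_cohort):
    decoys = [v for vs in small_cohort.variants.values() for v in vs
              if "noise" in v.id]
    afs = np.array([v.max_af for v in decoys])
    assert (afs > 0.01).any() and (afs < 0.001).any()
    assert afs.min() >= 1e-6 and afs.max() <= 0.05


def test_generate_variants_truth_mismatch():
    cfg = default_config(n_probands=2, seed=0)
    probands, truths = generate_cohort(cfg)
    with pytest.raises(ValidationError, match="does not belong"):
        generate_variants(probands[0], truths[1], cfg)


def test_truth_fit_flags():
    _, truths = generate_cohort(default_config(n_probands=30, seed=2))
    for t in truths:
        flags = truth_fit_flags(t)
        assert flags == ({t.causal_gene: True} if t.causal_gene else {})


# ---------------------------------------------------------------------------
# Dystrophin structural-variant generator
# ---------------------------------------------------------------------------

def test_india_has_no_duplications():
    cfg = default_config()
    svs = generate_dmd_cohort(cfg, n=400, seed=5,
                              country_weights={"India": 1.0})
    assert len(svs) == 400
    assert all(sv.country == "India" for sv in svs)
    assert not any(sv.kind == "duplication" for sv in svs)


def test_degenerate_breakpoint_weights_pin_intron_45():
    cfg = default_config()
    cfg.dmd_country_type_mix = {"India": {"deletion": 1.0}}
    cfg.dmd_breakpoint_weights = {j: (1.0 if j == 45 else 0.0)
                                  for j in range(80)}
    cfg.validate()
    svs = generate_dmd_cohort(cfg, n=1, seed=0, country_weights={"India": 1.0})
    from nmdx.dmd import breakpoints
    assert svs[0].kind == "deletion"
    assert 45 in breakpoints(svs[0])


def test_missing_country_raises():
    cfg = default_config()
    with pytest.raises(ValidationError, match="Zambia"):
        generate_dmd_cohort(cfg, n=5, seed=0, country_weights={"Zambia": 1.0})


def test_breakpoint_hotspot_fraction_matches_analytic():
    """Empirical intron 45-48 touch fraction tracks the analytic mixture."""
    from nmdx.dmd import hotspot_summary

    cfg = default_config()
    svs = generate_dmd_cohort(cfg, n=4000, seed=8)
    res = hotspot_summary(svs)
    p_analytic = breakpoint_touch_probability(cfg.dmd_breakpoint_weights,
                                              range(45, 49))
    se = math.sqrt(p_analytic * (1 - p_analytic) / res["n"])
    assert abs(res["hotspot_fraction"] - p_analytic) <= 4 * se
    # the defaults put the reported hotspot mass in the right place
    assert 0.5 < p_analytic < 0.7


def test_simulate_cohort_bundle(small_cohort):
    assert len(small_cohort.probands) == len(small_cohort.truths) == 120
    assert set(small_cohort.variants) == {p.id for p in small_cohort.probands}
    names = {c.name for c in small_cohort.catalogs}
    assert {"gnomad", "clinvar"} <= names


def test_novel_causal_variants_absent_from_all_catalogs(small_cohort):
    from nmdx.acmg import is_novel

    for truth in small_cohort.truths:
        if truth.outcome == "unsolved":
            continue
        causal = [v for v in small_cohort.variants[truth.proband_id]
                  if v.id in truth.causal_variant_ids]
        for v in causal:
            assert is_novel(v, small_cohort.catalogs) == truth.novel


def test_config_yaml_roundtrip(tmp_path):
    cfg = default_config(n_probands=17, seed=4)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = CohortConfig.from_yaml(path)
    assert back.to_dict() == cfg.to_dict()
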