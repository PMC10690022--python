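"""ACMG evidence combination, outcome rules and novelty determination."""
import itertools

import pytest
import yaml
from importlib import resources

from nmdx.acmg import (VALID_CODES, CatalogFixture, assign_frequency_evidence,
                       classify_outcome, combine_acmg, is_novel)
from nmdx.types import (CandidateGroup, ProbandRecord, ValidationError,
                        VariantObservation)

PATH_ORDER = {"Benign": -2, "Likely benign": -1, "VUS": 0,
              "Likely pathogenic": 1, "Pathogenic": 2}


def make_variant(vid="v1", zyg="hom", af=None, ev=(), insilico=True,
                 gene="DYSF", consequence="missense"):
    return VariantObservation(
        id=vid, gene=gene, transcript="TX", hgvs_c="c.100A>G",
        consequence=consequence, zygosity=zyg,
        afs={} if af is None else {"gnomad": af},
        insilico_support=insilico, acmg_evidence=frozenset(ev), position=100)


def proband(sex="female"):
    return ProbandRecord(id="P1", diagnostic_category="LGMD", sex=sex,
                         age_years=30, hpo_positive={"HP:0003701"})


# ---------------------------------------------------------------------------
# Combining rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("codes,expected", [
    ({"PVS1", "PS1"}, "Pathogenic"),
    ({"PS1", "PS3"}, "Pathogenic"),
    ({"PVS1", "PM2"}, "Likely pathogenic"),
    ({"PS1", "PM2"}, "Likely pathogenic"),
    ({"PM1", "PM2", "PM4"}, "Likely pathogenic"),
    (set(), "VUS"),
    ({"PM2"}, "VUS"),
    ({"BA1"}, "Benign"),
    ({"BS1", "BS2"}, "Benign"),
    ({"BS1", "BP4"}, "Likely benign"),
    ({"BP4", "BP7"}, "Likely benign"),
    ({"PVS1", "PS1", "BA1"}, "VUS"),  # conflicting evidence
])
def test_combine_acmg_rule_table(codes, expected):
    assert combine_acmg(codes) == expected


def test_combine_acmg_rejects_unknown_codes():
    with pytest.raises(ValidationError):
        combine_acmg({"PVS1", "XX9"})


_RAW_RULES = yaml.safe_load(
    resources.files("nmdx.data").joinpath("acmg_rules.yaml").read_text())


def oracle_combine(codes, raw=_RAW_RULES):
    """Independent combiner: literal re-reading of the packaged rule table."""
    counts = {"PVS": 0, "PS": 0, "PM": 0, "PP": 0, "BA": 0, "BS": 0, "BP": 0}
    for code in codes:
        for bucket in counts:
            if code == "PVS1" and bucket == "PVS":
                counts["PVS"] += 1
                break
            if code == "BA1" and bucket == "BA":
                counts["BA"] += 1
                break
            if code.startswith(bucket) and code not in ("PVS1", "BA1"):
                counts[bucket] += 1
                break
    def hit(rules):
        return any(all(counts[k] >= v for k, v in rule.items()) for rule in rules)
    p = "Pathogenic" if hit(raw["pathogenic"]) else \
        "Likely pathogenic" if hit(raw["likely_pathogenic"]) else None
    b = "Benign" if hit(raw["benign"]) else \
        "Likely benign" if hit(raw["likely_benign"]) else None
    if p and b:
        return "VUS"
    return p or b or "VUS"


def test_combine_acmg_matches_enumeration_oracle():
    """Exhaustive agreement with an independent oracle, all sets of size <= 3."""
    codes = sorted(VALID_CODES)
    for size in (0, 1, 2, 3):
        for combo in itertools.combinations(codes, size):
            assert combine_acmg(combo) == oracle_combine(combo), combo


def test_adding_pathogenic_code_never_moves_toward_benign():
    rng_sets = [set(), {"PM2"}, {"PS1"}, {"PVS1"}, {"PM1", "PM2"},
                {"BS1"}, {"BP4", "BP7"}, {"PS1", "PM2"}]
    for base in rng_sets:
        before = PATH_ORDER[combine_acmg(base)]
        for code in ("PVS1", "PS2", "PM3", "PP1"):
            if code in base:
                continue
            after = PATH_ORDER[combine_acmg(base | {code})]
            assert after >= before, (base, code)


# ---------------------------------------------------------------------------
# Frequency evidence and novelty
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("af,expected", [
    (None, {"PM2"}),      # unobserved everywhere
    (5e-5, {"PM2"}),
    (0.001, set()),       # between the cutoffs
    (0.02, {"BS1"}),
    (0.06, {"BS1", "BA1"}),
])
def test_assign_frequency_evidence(af, expected):
    v = make_variant(af=af)
    assert set(assign_frequency_evidence(v, [])) == expected


def test_is_novel_against_catalogs():
    v = make_variant()
    known = CatalogFixture("clinvar", known_variants={v.key})
    other = CatalogFixture("gnomad")
    assert not is_novel(v, [known, other])
    assert is_novel(v, [other])
    with pytest.warns(UserWarning):
        assert is_novel(v, [])


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------

def test_hom_lp_variant_fitting_phenotype_is_solved():
    v = make_variant(ev=("PVS1", "PM2"), af=1e-5)
    group = CandidateGroup("DYSF", "AR", (v,))
    rec = classify_outcome(proband(), [group], {"DYSF": True})
    assert rec.outcome == "solved"
    assert rec.causal_gene == "DYSF"
    assert rec.variant_classes == ("Likely pathogenic",)


def test_single_het_vus_in_ar_gene_is_unsolved():
    v = make_variant(zyg="het", ev=("PM2", "PP3"), af=5e-5)
    group = CandidateGroup("DYSF", "AR", (v,))
    rec = classify_outcome(proband(), [group], {"DYSF": True})
    assert rec.outcome == "unsolved"
    assert rec.causal_variant_ids == ()


def test_hom_ultrarare_supported_vus_is_possibly_solved():
    v = make_variant(zyg="hom", ev=("PM2", "PP3"), af=5e-5)
    group = CandidateGroup("DYSF", "AR", (v,))
    rec = classify_outcome(proband(), [group], {"DYSF": True})
    assert rec.outcome == "possibly_solved"


def test_vus_above_frequency_ceiling_not_possibly_solved():
    v = make_variant(zyg="hom", ev=("PP3",), af=5e-4)  # > 0.01% ceiling
    group = CandidateGroup("DYSF", "AR", (v,))
    rec = classify_outcome(proband(), [group], {"DYSF": True})
    assert rec.outcome == "unsolved"


def test_phenotype_fit_required():
    v = make_variant(ev=("PVS1", "PS3"))
    group = CandidateGroup("DYSF", "AR", (v,))
    rec = classify_outcome(proband(), [group], {"DYSF": False})
    assert rec.outcome == "unsolved"


def test_plp_group_ranks_before_vus_group():
    solved_v = make_variant(vid="a", ev=("PVS1", "PS3"), gene="SGCB")
    vus_v = make_variant(vid="b", zyg="hom", ev=("PM2", "PP3"), af=1e-5,
                         gene="ANO5")
    groups = [CandidateGroup("ANO5", "AR", (vus_v,)),
              CandidateGroup("SGCB", "AR", (solved_v,))]
    rec = classify_outcome(proband(), groups,
                           {"ANO5": True, "SGCB": True})
    assert rec.outcome == "solved"
    assert rec.causal_gene == "SGCB"
    assert "ANO5" in rec.notes


def test_outcome_invariants_on_synthetic_run(medium_cohort):
    """OutcomeRecord invariants hold over a 500-proband classified cohort."""
    from nmdx.pipeline import classify_cohort

    outcomes = classify_cohort(medium_cohort)
    for o in outcomes:
        if o.outcome == "solved":
            assert o.causal_variant_ids
            assert all(c in ("Pathogenic", "Likely pathogenic")
                       for c in o.variant_classes)
        elif o.outcome == "possibly_solved":
            assert "VUS" in o.variant_classes
        else:
            assert not o.causal_variant_ids
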