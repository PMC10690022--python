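"""ACMG evidence combination, diagnostic-outcome rules and novelty.

The evidence-combining algebra is shipped as data (``data/acmg_rules.yaml``)
so tests can enumerate it exhaustively. Outcomes follow the study rules:
*solved* requires pathogenic/likely-pathogenic variant(s) fitting the
phenotype (biallelic for recessive genes); *possibly solved* requires a
strong VUS candidate — every variant ultra-rare (max catalog frequency below
0.01%), supported in silico and fitting the phenotype; anything else is
*unsolved*. A variant is *novel* when its (gene, HGVS.c) key is absent from
every reference catalog.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import yaml

from .types import (CandidateGroup, OutcomeRecord, ValidationError,
                    VariantObservation)

VALID_CODES = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
    | {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)

CLASSES = ("Pathogenic", "Likely pathogenic", "VUS", "Likely benign", "Benign")

#: Frequency-evidence cutoffs (max AF across catalogs).
PM2_MAX_AF = 1e-4      # ultra-rare (or unobserved) supports pathogenicity
BS1_MIN_AF = 0.01      # too common for a rare-disease allele
BA1_MIN_AF = 0.05      # stand-alone benign

#: "Strong candidate" frequency ceiling for possibly-solved (<0.01%).
POSSIBLY_SOLVED_MAX_AF = 1e-4


def validate_codes(codes: Iterable[str]) -> frozenset:
    codes = frozenset(codes)
    unknown = codes - VALID_CODES
    if unknown:
        raise ValidationError(f"unknown ACMG evidence codes: {sorted(unknown)}")
    return codes


def _bucket(code: str) -> str:
    if code == "PVS1":
        return "PVS"
    if code == "BA1":
        return "BA"
    return code[:2]


@dataclass
class CombiningRules:
    """The packaged evidence-combining rule table."""

    version: str
    pathogenic: list
    likely_pathogenic: list
    benign: list
    likely_benign: list

    @classmethod
    def load(cls) -> "CombiningRules":
        path = resources.files("nmdx.data").joinpath("acmg_rules.yaml")
        with resources.as_file(path) as p, open(p) as fh:
            raw = yaml.safe_load(fh)
        return cls(version=raw["version"], pathogenic=raw["pathogenic"],
                   likely_pathogenic=raw["likely_pathogenic"],
                   benign=raw["benign"], likely_benign=raw["likely_benign"])


_RULES: Optional[CombiningRules] = None


def _rules() -> CombiningRules:
    global _RULES
    if _RULES is None:
        _RULES = CombiningRules.load()
    return _RULES


def _matches(buckets: dict, rule: dict) -> bool:
    return all(buckets.get(b, 0) >= need for b, need in rule.items())


def combine_acmg(codes: Iterable[str], rules: Optional[CombiningRules] = None) -> str:
    """Combine evidence codes into one of the five classes.

    The pathogenic and benign rule sides are evaluated independently;
    meeting both yields VUS (conflicting evidence), as does meeting neither.
    """
    codes = validate_codes(codes)
    rules = rules or _rules()
    buckets: dict = {}
    for code in codes:
        b = _bucket(code)
        buckets[b] = buckets.get(b, 0) + 1
    path_class = None
    if any(_matches(buckets, r) for r in rules.pathogenic):
        path_class = "Pathogenic"
    elif any(_matches(buckets, r) for r in rules.likely_pathogenic):
        path_class = "Likely pathogenic"
    benign_class = None
    if any(_matches(buckets, r) for r in rules.benign):
        benign_class = "Benign"
    elif any(_matches(buckets, r) for r in rules.likely_benign):
        benign_class = "Likely benign"
    if path_class and benign_class:
        return "VUS"
    return path_class or benign_class or "VUS"


# ---------------------------------------------------------------------------
# Frequency evidence
# ---------------------------------------------------------------------------

@dataclass
class CatalogFixture:
    """A reference catalog: known variant keys and their frequencies."""

    name: str
    known_variants: set = field(default_factory=set)
    afs: dict = field(default_factory=dict)


def assign_frequency_evidence(variant: VariantObservation,
                              catalogs: Iterable[CatalogFixture]) -> frozenset:
    """Frequency-derived evidence delta for a variant.

    PM2 when the variant is ultra-rare (max AF < 1e-4) or unobserved in every
    catalog; BS1 when max AF > 1%; BA1 additionally when max AF > 5%.
    """
    afs = [cat.afs[variant.key] for cat in catalogs if variant.key in cat.afs]
    afs.append(variant.max_af)
    top = max(afs)
    delta = set()
    if top < PM2_MAX_AF:
        delta.add("PM2")
    if top > BS1_MIN_AF:
        delta.add("BS1")
    if top > BA1_MIN_AF:
        delta.add("BA1")
    return frozenset(delta)


def is_novel(variant: VariantObservation,
             catalogs: Iterable[CatalogFixture]) -> bool:
    """True iff the variant key is absent from every catalog."""
    catalogs = list(catalogs)
    if not catalogs:
        warnings.warn("is_novel: no catalogs loaded; absence is vacuous")
        return True
    return all(variant.key not in cat.known_variants for cat in catalogs)


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------

def _biallelic_ok(group: CandidateGroup) -> bool:
    """Recessive groups must be homozygous or carry two (or more) variants."""
    if group.mode != "AR":
        return True
    return any(v.zygosity == "hom" for v in group.variants) or len(group.variants) >= 2


def classify_group(group: CandidateGroup,
                   rules: Optional[CombiningRules] = None) -> tuple:
    """ACMG classes of each variant in a candidate group."""
    return tuple(combine_acmg(v.acmg_evidence, rules) for v in group.variants)


def classify_outcome(proband, groups: list, phenotype_fit: dict,
                     modality: str = "WES",
                     rules: Optional[CombiningRules] = None,
                     catalogs: Iterable[CatalogFixture] = ()) -> OutcomeRecord:
    """Apply the solved / possibly-solved / unsolved rules to one proband.

    ``groups`` are zygosity-consistent CandidateGroups from prioritization;
    ``phenotype_fit`` maps gene -> bool (expert judgement arrives as input).
    When several groups qualify, P/LP groups rank before VUS groups and the
    first group (by gene symbol) is reported as primary; the rest are noted.
    """
    catalogs = list(catalogs)
    qualifying = []  # (rank, gene, group, classes)
    for group in groups:
        classes = classify_group(group, rules)
        if len(classes) != len(group.variants):
            raise ValidationError("every candidate variant needs a class")
        fit = phenotype_fit.get(group.gene, False)
        if not fit or not _biallelic_ok(group):
            continue
        if all(c in ("Pathogenic", "Likely pathogenic") for c in classes):
            qualifying.append((0, group.gene, group, classes))
        elif ("VUS" in classes
              and all(c not in ("Benign", "Likely benign") for c in classes)
              and all(v.max_af < POSSIBLY_SOLVED_MAX_AF for v in group.variants)
              and all(v.insilico_support for v in group.variants)):
            qualifying.append((1, group.gene, group, classes))
    qualifying.sort(key=lambda q: (q[0], q[1]))
    if not qualifying:
        return OutcomeRecord(
            proband_id=proband.id, outcome="unsolved", modality=modality,
            category=proband.diagnostic_category, country=proband.country)
    rank, gene, group, classes = qualifying[0]
    outcome = "solved" if rank == 0 else "possibly_solved"
    novel = tuple(is_novel(v, catalogs) if catalogs else False
                  for v in group.variants)
    notes = ""
    if len(qualifying) > 1:
        others = ", ".join(g for _, g, _, _ in qualifying[1:])
        notes = f"additional qualifying gene(s): {others}"
    if group.phase_unconfirmed:
        notes = (notes + "; " if notes else "") + "phase unconfirmed"
    mechanism = None
    if any(v.consequence == "exonic_duplication" for v in group.variants):
        mechanism = "dup"
    elif any(v.consequence == "exonic_deletion" for v in group.variants):
        mechanism = "del"
    return OutcomeRecord(
        proband_id=proband.id, outcome=outcome,
        causal_variant_ids=tuple(v.id for v in group.variants),
        variant_classes=classes, causal_gene=gene, mechanism=mechanism,
        mode=group.mode,
        modality=modality, novel_flags=novel,
        category=proband.diagnostic_category, country=proband.country,
        notes=notes)
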