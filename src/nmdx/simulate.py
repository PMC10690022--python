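"""Synthetic neuromuscular-disease cohort generation with planted truth.

Because the study's participant-level data are not yet publicly deposited,
the simulator emulates the reported statistical structure of the cohort —
category mix, sex ratio, age distribution, per-category diagnostic yields
and causal-gene mixtures, dystrophin variant-type mixes per country and
intron breakpoint hotspots — and plants ground-truth diagnoses so that the
downstream prioritization, classification and statistics stages can be
tested end to end without any download.

Randomness uses one master seed with per-proband substreams derived from
(seed, proband index), so growing the cohort never reshuffles earlier
probands.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .acmg import CatalogFixture
from .config import CohortConfig, GeneMixEntry
from .dmd import DmdStructuralVariant
from .types import (PlantedTruth, ProbandRecord, Relative, ValidationError,
                    VariantObservation)

#: Evidence templates for planted causal variants, per target class.
_PATHOGENIC_TEMPLATES = (("PVS1", "PS3", "PM2"), ("PS1", "PS3", "PM2"))
_LP_TEMPLATES = (("PVS1", "PM2"), ("PS4", "PM2"))
_VUS_TEMPLATE = ("PM2", "PP3")

#: Genes used for decoy (noise) variants; none appear in any packaged panel.
DECOY_GENES = ("MUC16", "OBSCN", "AHNAK2", "FLG", "PLIN4", "ZNF717",
               "HYDIN", "PCLO", "CSMD1", "LRP1B")

#: Country weights for the dystrophinopathy structural-variant cohort
#: (proportional to the solved counts per country: 64 / 40 / 2).
DMD_COUNTRY_WEIGHTS = {"India": 64 / 106, "South Africa": 40 / 106,
                       "Brazil": 2 / 106}


def _load_hpo_vocab() -> dict:
    path = resources.files("nmdx.data").joinpath("hpo_vocab.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return {cat: list(sub["hpo_id"]) for cat, sub in df.groupby("category")}


_HPO_VOCAB: dict = {}


def hpo_vocab() -> dict:
    if not _HPO_VOCAB:
        _HPO_VOCAB.update(_load_hpo_vocab())
    return _HPO_VOCAB


def _proband_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, index, stream])


def _choice(rng, items, weights):
    return items[rng.choice(len(items), p=weights)]


def _draw_age(rng, age_model: dict) -> float:
    if rng.random() < age_model["p_paediatric"]:
        return float(rng.uniform(0.0, age_model["paediatric_max"]))
    age = age_model["paediatric_max"] + rng.exponential(age_model["adult_mean_excess"])
    return float(min(age, age_model.get("adult_age_cap", 90.0)))


# ---------------------------------------------------------------------------
# Probands and truth
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig):
    """Generate probands and their planted diagnoses.

    Returns (probands, truths), one of each per proband, deterministically
    for a fixed (config, seed).
    """
    config.validate()
    vocab = hpo_vocab()
    cats = sorted(config.category_weights)
    cat_w = np.array([config.category_weights[c] for c in cats])
    cat_w = cat_w / cat_w.sum()
    countries = sorted(config.country_weights)
    country_w = np.array([config.country_weights[c] for c in countries])
    country_w = country_w / country_w.sum()

    probands, truths = [], []
    for i in range(config.n_probands):
        rng = _proband_rng(config.seed, i)
        pid = f"P{i:06d}"
        category = _choice(rng, cats, cat_w)
        country = _choice(rng, countries, country_w)
        sex = "male" if rng.random() < config.male_fraction else "female"
        age = _draw_age(rng, config.age_model)

        terms = vocab[category]
        k = int(rng.integers(2, min(3, len(terms)) + 1))
        hpo_pos = frozenset(rng.choice(terms, size=k, replace=False))
        other_terms = [t for c, ts in vocab.items() if c != category for t in ts]
        n_neg = int(rng.integers(0, 3))
        hpo_neg = frozenset(rng.choice(other_terms, size=n_neg, replace=False)) \
            if n_neg else frozenset()

        n_rel = int(rng.integers(0, 4))
        relatives = tuple(
            Relative(relation=str(rng.choice(["mother", "father", "sibling"])),
                     affected=bool(rng.random() < 0.15))
            for _ in range(n_rel))

        proband = ProbandRecord(
            id=pid, diagnostic_category=category, sex=sex, age_years=age,
            hpo_positive=hpo_pos, hpo_negative=hpo_neg, country=country,
            relatives=relatives)

        p_solved, p_possibly = config.per_category_yield.get(category, (0.0, 0.0))
        u = rng.random()
        if u < p_solved:
            outcome = "solved"
        elif u < p_solved + p_possibly:
            outcome = "possibly_solved"
        else:
            outcome = "unsolved"

        if outcome == "unsolved":
            truth = PlantedTruth(proband_id=pid, outcome="unsolved")
        else:
            mix = config.per_category_gene_mix[category]
            weights = np.array([e.weight for e in mix])
            entry: GeneMixEntry = mix[int(rng.choice(len(mix), p=weights))]
            novel = bool(rng.random() < config.novel_fraction)
            n_vars = _planted_variant_count(rng, entry, proband.sex)
            vids = tuple(f"{pid}_causal{k}" for k in range(n_vars))
            truth = PlantedTruth(
                proband_id=pid, outcome=outcome, causal_variant_ids=vids,
                causal_gene=entry.gene, mechanism=entry.mechanism,
                mode=entry.mode, novel=novel)
        probands.append(proband)
        truths.append(truth)
    return probands, truths


def _planted_variant_count(rng, entry: GeneMixEntry, sex: str) -> int:
    if entry.mode == "AR":
        # homozygous or compound heterozygous, equally likely
        return 1 if rng.random() < 0.5 else 2
    return 1


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def generate_variants(proband: ProbandRecord, truth: PlantedTruth,
                      config: CohortConfig) -> list:
    """Generate the observed variant list for one proband.

    Solved probands receive pathogenic/likely-pathogenic-evidence variant(s)
    in their causal gene with zygosity matching the inheritance mode (two
    variants or homozygous for recessive genes); possibly-solved probands
    receive an ultra-rare VUS-evidence candidate; every proband additionally
    receives decoy variants with frequencies straddling both filter
    thresholds (log-uniform over [1e-6, 0.05]).
    """
    if truth.proband_id != proband.id:
        raise ValidationError(
            f"truth {truth.proband_id} does not belong to proband {proband.id}")
    index = int(proband.id[1:])
    rng = _proband_rng(config.seed, index, stream=1)
    variants: list = []

    if truth.outcome != "unsolved":
        variants.extend(_planted_variants(rng, proband, truth))

    causal_gene = truth.causal_gene
    for k in range(config.noise_variants_per_proband):
        gene = DECOY_GENES[int(rng.integers(0, len(DECOY_GENES)))]
        # some decoys land in real panel genes (never the causal gene) so the
        # panel restriction and MAF thresholds are both exercised
        if rng.random() < 0.3:
            mix = config.per_category_gene_mix[proband.diagnostic_category]
            panel_genes = [e.gene for e in mix if e.gene != causal_gene]
            if panel_genes:
                gene = panel_genes[int(rng.integers(0, len(panel_genes)))]
        af = float(10 ** rng.uniform(-6, np.log10(0.05)))
        pos = int(rng.integers(1, 300000))
        variants.append(VariantObservation(
            id=f"{proband.id}_noise{k}", gene=gene, transcript=f"TX_{gene}",
            hgvs_c=f"c.{pos}A>G", consequence="missense", zygosity="het",
            afs={"gnomad": af}, insilico_support=False,
            acmg_evidence=frozenset(), position=pos))
    return variants


def _planted_variants(rng, proband: ProbandRecord, truth: PlantedTruth) -> list:
    n = len(truth.causal_variant_ids)
    gene, mode = truth.causal_gene, truth.mode
    if mode == "XL":
        zygosities = ["hemi" if proband.sex == "male" else "het"] * n
    elif mode == "AR":
        zygosities = ["hom"] if n == 1 else ["het"] * n
    else:
        zygosities = ["het"] * n
    if truth.outcome == "solved":
        templates = (_PATHOGENIC_TEMPLATES if rng.random() < 0.5
                     else _LP_TEMPLATES)
        evidence = [templates[int(rng.integers(0, len(templates)))]
                    for _ in range(n)]
    else:
        evidence = [_VUS_TEMPLATE] * n
    consequence_pool = ("missense", "nonsense", "frameshift", "splice")
    out = []
    for vid, zyg, ev in zip(truth.causal_variant_ids, zygosities, evidence):
        pos = int(rng.integers(1, 300000))
        if truth.mechanism == "dup":
            consequence = "exonic_duplication"
            hgvs = f"c.{pos}_{pos + 500}dup"
        elif truth.mechanism == "del":
            consequence = "exonic_deletion"
            hgvs = f"c.{pos}_{pos + 500}del"
        else:
            consequence = consequence_pool[int(rng.integers(0, 4))]
            hgvs = f"c.{pos}G>T"
        # ultra-rare: unobserved, or below the 0.01% candidate ceiling
        afs = {} if (truth.novel or rng.random() < 0.4) \
            else {"gnomad": float(10 ** rng.uniform(-6, np.log10(9e-5)))}
        out.append(VariantObservation(
            id=vid, gene=gene, transcript=f"TX_{gene}", hgvs_c=hgvs,
            consequence=consequence, zygosity=zyg, afs=afs,
            insilico_support=True, acmg_evidence=frozenset(ev), position=pos))
    return out


def truth_fit_flags(truth: PlantedTruth) -> dict:
    """Phenotype-fit flags implied by the planted truth (causal gene fits)."""
    return {truth.causal_gene: True} if truth.causal_gene else {}


def generate_catalogs(variants_by_proband: dict, truths: list) -> list:
    """Build reference-catalog fixtures consistent with the planted novelty.

    Non-novel causal variants are inserted into the variant catalogs (and
    into the frequency catalog when they carry a frequency); decoy variants
    are always known to the frequency catalog. Novel causal variants are
    absent everywhere.
    """
    truth_by_id = {t.proband_id: t for t in truths}
    gnomad = CatalogFixture("gnomad")
    clinvar = CatalogFixture("clinvar")
    local = CatalogFixture("local")
    for pid, variants in variants_by_proband.items():
        truth = truth_by_id.get(pid)
        causal_ids = set(truth.causal_variant_ids) if truth else set()
        for v in variants:
            if v.id in causal_ids:
                if not truth.novel:
                    clinvar.known_variants.add(v.key)
                    if v.afs:
                        gnomad.known_variants.add(v.key)
                        gnomad.afs[v.key] = v.max_af
            else:
                gnomad.known_variants.add(v.key)
                gnomad.afs[v.key] = v.max_af
    return [gnomad, clinvar, local]


# ---------------------------------------------------------------------------
# Dystrophin structural-variant cohort
# ---------------------------------------------------------------------------

_DMD_TYPES = ("deletion", "duplication", "nonsense", "splice")


def generate_dmd_cohort(config: CohortConfig, n: int, seed: int,
                        country_weights: dict = None) -> list:
    """Simulate n dystrophinopathy causal variants with country labels.

    Variant types follow the per-country mixes; deletion/duplication
    breakpoints are drawn (without replacement) from the intron hotspot
    weights, so mass concentrates in introns 45-48 and the proximal 5'
    region. Returns a list of DmdStructuralVariant (country on the record).
    """
    config.validate()
    if n <= 0:
        raise ValidationError("n must be positive")
    weights = dict(country_weights or DMD_COUNTRY_WEIGHTS)
    for country in weights:
        if country not in config.dmd_country_type_mix:
            raise ValidationError(
                f"country {country!r} missing from dmd_country_type_mix")
    countries = sorted(weights)
    cw = np.array([weights[c] for c in countries], dtype=float)
    cw = cw / cw.sum()
    junctions = sorted(config.dmd_breakpoint_weights)
    jw = np.array([config.dmd_breakpoint_weights[j] for j in junctions])
    jw = jw / jw.sum()
    records = []
    for k in range(n):
        rng = _proband_rng(seed, k, stream=2)
        country = _choice(rng, countries, cw)
        mix = config.dmd_country_type_mix[country]
        tw = np.array([mix.get(t, 0.0) for t in _DMD_TYPES])
        kind = _choice(rng, _DMD_TYPES, tw / tw.sum())
        sid = f"DMD{k:05d}"
        if kind in ("deletion", "duplication"):
            i = int(rng.choice(len(junctions), p=jw))
            rest = jw.copy()
            rest[i] = 0.0
            if rest.sum() > 0:
                j = int(rng.choice(len(junctions), p=rest / rest.sum()))
            else:  # degenerate weights: second junction uniform over the rest
                others = [k for k in range(len(junctions)) if k != i]
                j = others[int(rng.integers(0, len(others)))]
            a, b = sorted((junctions[i], junctions[j]))
            records.append(DmdStructuralVariant(
                kind=kind, first_exon=a + 1, last_exon=b,
                sample_id=sid, country=country))
        else:
            locus = int(rng.integers(4, 73))  # spread across exons 4..72
            records.append(DmdStructuralVariant(
                kind=kind, locus=locus, sample_id=sid, country=country))
    return records


def breakpoint_touch_probability(weights: dict, introns) -> float:
    """Analytic P(a deletion/duplication touches any intron in ``introns``).

    Breakpoints are two distinct junctions drawn sequentially without
    replacement from ``weights``; the complement sums over ordered pairs
    avoiding the target set.
    """
    target = set(introns)
    total = sum(weights.values())
    w = {j: v / total for j, v in weights.items()}
    outside = {j: v for j, v in w.items() if j not in target}
    p_miss = 0.0
    for i, wi in outside.items():
        denom = 1.0 - wi
        p_miss += wi * sum(wj for j, wj in outside.items() if j != i) / denom
    return 1.0 - p_miss


# ---------------------------------------------------------------------------
# Bundled cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: CohortConfig
    probands: list
    truths: list
    variants: dict  # proband id -> list of VariantObservation
    catalogs: list = field(default_factory=list)

    def truth_of(self, proband_id: str) -> PlantedTruth:
        if not hasattr(self, "_truth_idx"):
            self._truth_idx = {t.proband_id: t for t in self.truths}
        return self._truth_idx[proband_id]


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full simulation: probands, truths, variants and catalog fixtures."""
    probands, truths = generate_cohort(config)
    variants = {p.id: generate_variants(p, t, config)
                for p, t in zip(probands, truths)}
    catalogs = generate_catalogs(variants, truths)
    return SyntheticCohort(config=config, probands=probands, truths=truths,
                           variants=variants, catalogs=catalogs)


def expected_combined_yield(config: CohortConfig) -> float:
    """Configured expectation of P(solved or possibly solved) per proband."""
    total = sum(config.category_weights.values())
    return sum(w / total * sum(config.per_category_yield.get(cat, (0, 0)))
               for cat, w in config.category_weights.items())
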