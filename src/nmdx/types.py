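"""Core domain records shared across the pipeline stages.

All records are plain dataclasses with light validation on construction.
Frequencies are absolute allele frequencies in [0, 1]; an absent catalog entry
means the variant was not observed there and is treated as frequency zero by
the filters.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Controlled diagnostic-category vocabulary. The four most-recruited
#: categories are first; the remainder are the smaller clinic categories plus
#: a catch-all.
CATEGORIES = (
    "LGMD", "PN", "CM_CMD", "DMD_BMD",
    "MITO", "SMA", "FSHD", "MYOTONIC", "CMS", "MND", "OTHER",
)

INHERITANCE_MODES = ("AR", "AD", "XL")

CONSEQUENCES = (
    "missense", "nonsense", "frameshift", "splice", "inframe_indel",
    "exonic_deletion", "exonic_duplication", "other",
)

ZYGOSITIES = ("het", "hom", "hemi")

OUTCOMES = ("solved", "possibly_solved", "unsolved")

MODALITIES = ("SGT", "WES", "MLPA")


class ValidationError(ValueError):
    """Raised when a record or configuration violates its invariants."""


@dataclass
class Relative:
    relation: str
    affected: bool


@dataclass
class ProbandRecord:
    """One participant's phenotype record.

    The mandatory entries are id, diagnostic category, sex, age and the
    positive/negative HPO term sets; everything else is optional.
    """

    id: str
    diagnostic_category: str
    sex: str
    age_years: float
    hpo_positive: frozenset = frozenset()
    hpo_negative: frozenset = frozenset()
    country: str = ""
    relatives: tuple = ()
    prior_test: Optional[str] = None

    def __post_init__(self):
        if self.diagnostic_category not in CATEGORIES:
            raise ValidationError(
                f"unknown diagnostic category {self.diagnostic_category!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        if self.age_years < 0:
            raise ValidationError("age_years must be nonnegative")
        self.hpo_positive = frozenset(self.hpo_positive)
        self.hpo_negative = frozenset(self.hpo_negative)
        overlap = self.hpo_positive & self.hpo_negative
        if overlap:
            raise ValidationError(
                f"HPO terms cannot be both positive and negative: {sorted(overlap)}")


@dataclass
class VariantObservation:
    """One observed small variant in one proband."""

    id: str
    gene: str
    transcript: str
    hgvs_c: str
    consequence: str
    zygosity: str
    afs: dict = field(default_factory=dict)
    insilico_support: bool = False
    acmg_evidence: frozenset = frozenset()
    position: int = 0  # 1-based position used only for deterministic ordering

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValidationError(f"unknown zygosity {self.zygosity!r}")
        for catalog, af in self.afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValidationError(
                    f"allele frequency for catalog {catalog!r} outside [0,1]: {af}")
        self.acmg_evidence = frozenset(self.acmg_evidence)

    @property
    def max_af(self) -> float:
        """Maximum frequency across catalogs; 0.0 when unobserved everywhere."""
        return max(self.afs.values(), default=0.0)

    @property
    def key(self) -> tuple:
        """Novelty/catalog key: (gene symbol, whitespace-stripped HGVS.c)."""
        return (self.gene, "".join(self.hgvs_c.split()))


@dataclass
class GenePanel:
    """An expert gene panel: genes with inheritance modes plus HPO anchors."""

    id: str
    name: str
    entries: tuple  # of (gene, mode)
    hpo_terms: frozenset = frozenset()
    category: str = ""

    def __post_init__(self):
        genes = [g for g, _ in self.entries]
        if len(genes) != len(set(genes)):
            raise ValidationError(f"panel {self.id}: duplicate genes")
        for g, m in self.entries:
            if m not in INHERITANCE_MODES:
                raise ValidationError(f"panel {self.id}: bad mode {m!r} for {g}")
        self.hpo_terms = frozenset(self.hpo_terms)

    def mode_of(self, gene: str) -> str:
        for g, m in self.entries:
            if g == gene:
                return m
        raise KeyError(gene)

    @property
    def genes(self) -> tuple:
        return tuple(g for g, _ in self.entries)


@dataclass
class PlantedTruth:
    """Ground truth attached to every simulated proband."""

    proband_id: str
    outcome: str
    causal_variant_ids: tuple = ()
    causal_gene: Optional[str] = None
    mechanism: Optional[str] = None  # e.g. PMP22 dup vs point, mirrored in reports
    mode: Optional[str] = None
    novel: bool = False

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if (self.outcome == "unsolved") != (len(self.causal_variant_ids) == 0):
            raise ValidationError(
                "causal variants must be present iff outcome is not unsolved")


@dataclass
class CandidateGroup:
    """A zygosity-consistent set of candidate variants in one gene."""

    gene: str
    mode: str
    variants: tuple
    phase_unconfirmed: bool = False  # unphased compound hets assumed in trans


@dataclass
class OutcomeRecord:
    """Final per-proband diagnostic outcome."""

    proband_id: str
    outcome: str
    causal_variant_ids: tuple = ()
    variant_classes: tuple = ()
    causal_gene: Optional[str] = None
    mechanism: Optional[str] = None
    mode: Optional[str] = None
    modality: str = "WES"
    novel_flags: tuple = ()
    category: str = ""
    country: str = ""
    notes: str = ""

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.outcome == "solved":
            if not self.causal_variant_ids or any(
                    c not in ("Pathogenic", "Likely pathogenic")
                    for c in self.variant_classes):
                raise ValidationError(
                    "solved outcome requires causal variants all classed P/LP")
        elif self.outcome == "possibly_solved":
            if "VUS" not in self.variant_classes:
                raise ValidationError(
                    "possibly_solved outcome requires at least one VUS")
        else:
            if self.causal_variant_ids:
                raise ValidationError("unsolved outcome must have no causal variants")
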