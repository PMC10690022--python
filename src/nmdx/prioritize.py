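"""Variant prioritization: panel matching, frequency filters, zygosity rules.

The analysis keeps variants that lie in genes of panels aligned to the
proband's HPO terms and phenotype, that pass the inheritance-specific minor
allele frequency thresholds (<0.01 for autosomal recessive, <0.001 for
autosomal dominant; X-linked uses the dominant threshold), and that form a
zygosity-consistent group for the gene's inheritance mode (two variants or
homozygous in recessive disorders). An empty candidate list flags the
proband for extended analyses.
"""
from __future__ import annotations

from dataclasses import dataclass

from .types import (CandidateGroup, GenePanel, ProbandRecord, ValidationError,
                    VariantObservation)


@dataclass(frozen=True)
class MafThresholds:
    """Strict upper bounds on the maximum catalog allele frequency."""

    ar: float = 0.01
    ad: float = 0.001

    def for_mode(self, mode: str) -> float:
        if mode == "AR":
            return self.ar
        if mode in ("AD", "XL"):  # X-linked filtered at the dominant threshold
            return self.ad
        raise ValidationError(f"unknown inheritance mode {mode!r}")


DEFAULT_THRESHOLDS = MafThresholds()

#: Fallback mapping when no panel overlaps the proband's HPO terms.
CATEGORY_PANEL = {
    "LGMD": "P_LGMD", "PN": "P_PN", "CM_CMD": "P_CM_CMD", "DMD_BMD": "P_DMD_BMD",
    "MITO": "P_MITO", "SMA": "P_SMA", "FSHD": "P_FSHD", "MYOTONIC": "P_MYOTONIC",
    "CMS": "P_CMS", "MND": "P_MND", "OTHER": "P_OTHER",
}


def match_panels(proband: ProbandRecord, panels: list) -> list:
    """Panels aligned to the proband, best HPO overlap first.

    Ordering is descending overlap count, ties broken by panel id. With no
    overlapping panel the category-mapped panel is the fallback.
    """
    if not panels:
        raise ValidationError("match_panels requires at least one panel")
    scored = [(len(p.hpo_terms & proband.hpo_positive), p) for p in panels]
    hits = [(n, p) for n, p in scored if n > 0]
    if hits:
        hits.sort(key=lambda np_: (-np_[0], np_[1].id))
        return [p for _, p in hits]
    fallback_id = CATEGORY_PANEL.get(proband.diagnostic_category)
    for p in panels:
        if p.id == fallback_id or p.category == proband.diagnostic_category:
            return [p]
    raise ValidationError(
        f"no panel resolvable for proband {proband.id}: no HPO overlap and "
        f"no panel for category {proband.diagnostic_category!r}")


def maf_pass(variant: VariantObservation, mode: str,
             thresholds: MafThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Strict frequency filter on the max frequency across catalogs.

    Frequencies absent from every catalog count as zero (pass). The bound is
    strict: a frequency exactly at the threshold fails.
    """
    for catalog, af in variant.afs.items():
        if not (0.0 <= af <= 1.0):
            raise ValidationError(
                f"variant {variant.id}: frequency for {catalog!r} outside [0,1]")
    return variant.max_af < thresholds.for_mode(mode)


def zygosity_consistent(variants: list, mode: str, sex: str) -> bool:
    """Zygosity rule for one gene's variants under an inheritance mode.

    AR needs one homozygote or at least two heterozygous variants; AD needs
    any variant; XL needs a hemizygous variant in males, and follows the AD
    rule in females. An empty list is simply inconsistent, not an error.
    """
    if not variants:
        return False
    genes = {v.gene for v in variants}
    if len(genes) > 1:
        raise ValidationError(f"variants span multiple genes: {sorted(genes)}")
    if mode == "AR":
        return any(v.zygosity == "hom" for v in variants) or len(variants) >= 2
    if mode == "AD":
        return True
    if mode == "XL":
        if sex == "male":
            return any(v.zygosity in ("hemi", "hom") for v in variants)
        return True  # females: AD rule
    raise ValidationError(f"unknown inheritance mode {mode!r}")


def prioritize(proband: ProbandRecord, variants: list, panels: list,
               thresholds: MafThresholds = DEFAULT_THRESHOLDS) -> list:
    """Reduce a proband's variants to candidate groups.

    Returns CandidateGroups (gene, inheritance mode, variants) for genes in
    the matched panels whose surviving variants are zygosity-consistent.
    Deterministic ordering: gene symbol, then position within gene. An empty
    result is valid and routes the proband to extended analyses.
    """
    matched = match_panels(proband, panels)
    # first matched panel naming a gene governs its inheritance mode
    gene_mode: dict = {}
    for panel in matched:
        for gene, mode in panel.entries:
            gene_mode.setdefault(gene, mode)
    by_gene: dict = {}
    for v in variants:
        mode = gene_mode.get(v.gene)
        if mode is None:
            continue
        if not maf_pass(v, mode, thresholds):
            continue
        by_gene.setdefault(v.gene, []).append(v)
    groups = []
    for gene in sorted(by_gene):
        mode = gene_mode[gene]
        vs = sorted(by_gene[gene], key=lambda v: (v.position, v.id))
        if not zygosity_consistent(vs, mode, proband.sex):
            continue
        phase_unconfirmed = (mode == "AR"
                             and not any(v.zygosity == "hom" for v in vs)
                             and len(vs) >= 2)
        groups.append(CandidateGroup(gene=gene, mode=mode, variants=tuple(vs),
                                     phase_unconfirmed=phase_unconfirmed))
    return groups


def flag_extended_analysis(proband: ProbandRecord, groups: list) -> bool:
    """True iff prioritization produced no candidates.

    Probands flagged here would continue to the extended pipeline analyses;
    of those, only dystrophin exon-interval records are modelled (dmd
    module) — the flag itself is recorded in reports either way.
    """
    return len(groups) == 0
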