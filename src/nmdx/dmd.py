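"""Dystrophin (DMD) structural-variant analysis.

Implements the reading-frame rule over the 79-exon muscle transcript
(Dp427m): a deletion or duplication whose combined coding length is a
multiple of 3 preserves the reading frame (typically the milder Becker
phenotype), otherwise it shifts the frame (typically Duchenne). Variants
touching the initial or terminal exon are not frame-assessable. Built on the
frame rule are severity prediction, single-exon antisense-oligonucleotide
skipping amenability for the licensed (45, 51, 53) and trial (44) target
exons, intron breakpoint attribution and hotspot summaries, and the
per-country variant-type contingency table.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .types import ValidationError

LICENSED_SKIP_EXONS = frozenset({45, 51, 53})
TRIAL_SKIP_EXONS = frozenset({44})

SV_KINDS = ("deletion", "duplication")
POINT_KINDS = ("nonsense", "splice", "small_frameshift")

#: Sentinels returned by :func:`breakpoints` for boundaries at the gene ends.
FIVE_PRIME = "5prime"
THREE_PRIME = "3prime"


class DmdExonModel:
    """The 79-exon coding model of the full-length muscle transcript."""

    def __init__(self, lengths: dict, source: str):
        exons = sorted(lengths)
        if exons != list(range(1, 80)):
            raise ValidationError("exon model must cover exons 1..79 exactly")
        if any(lengths[e] <= 0 for e in exons):
            raise ValidationError("all exon coding lengths must be positive")
        if sum(lengths.values()) % 3 != 0:
            raise ValidationError("total coding length must be a multiple of 3")
        self.lengths = dict(lengths)
        self.source = source

    @classmethod
    def load(cls) -> "DmdExonModel":
        path = resources.files("nmdx.data").joinpath("dmd_exons.tsv")
        with resources.as_file(path) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
        return cls(dict(zip(df["exon"], df["coding_length"])), "NM_004006.2")

    def span_length(self, first: int, last: int) -> int:
        return sum(self.lengths[e] for e in range(first, last + 1))


@dataclass(frozen=True)
class DmdStructuralVariant:
    """An exon-interval deletion/duplication, or a point variant.

    For deletions/duplications ``first_exon``/``last_exon`` are 1-based
    inclusive exon numbers. Point variants carry their exon (or intron, for
    splice variants) in ``locus``.
    """

    kind: str
    first_exon: Optional[int] = None
    last_exon: Optional[int] = None
    locus: Optional[int] = None
    sample_id: str = ""
    country: str = ""

    def __post_init__(self):
        if self.kind in SV_KINDS:
            f, l = self.first_exon, self.last_exon
            if f is None or l is None or not (1 <= f <= l <= 79):
                raise ValidationError(
                    f"exon interval must satisfy 1 <= first <= last <= 79, "
                    f"got {f}..{l}")
        elif self.kind in POINT_KINDS:
            if self.locus is not None and not (1 <= self.locus <= 79):
                raise ValidationError(f"point-variant locus out of range: {self.locus}")
        else:
            raise ValidationError(f"unknown DMD variant kind {self.kind!r}")

    @property
    def is_interval(self) -> bool:
        return self.kind in SV_KINDS


def frame_status(sv: DmdStructuralVariant, model: DmdExonModel) -> str:
    """Reading-frame status of an exon-interval deletion or duplication.

    Returns ``in_frame``, ``out_of_frame``, or ``inapplicable`` when the
    interval touches exon 1 or exon 79 (duplications are assumed tandem, so
    the same divisibility rule applies to both kinds).
    """
    if not sv.is_interval:
        raise ValidationError("frame_status applies to deletions/duplications only")
    if sv.first_exon == 1 or sv.last_exon == 79:
        return "inapplicable"
    return "in_frame" if model.span_length(sv.first_exon, sv.last_exon) % 3 == 0 \
        else "out_of_frame"


def predict_severity(sv: DmdStructuralVariant, model: DmdExonModel) -> str:
    """DMD-like (Duchenne), BMD-like (Becker) or indeterminate.

    Frame-preserving intervals predict the milder Becker phenotype;
    frameshifting intervals and truncating point variants predict Duchenne.
    """
    if not sv.is_interval:
        if sv.kind in ("nonsense", "small_frameshift"):
            return "DMD_like"
        return "indeterminate"  # splice effect not predictable at exon level
    status = frame_status(sv, model)
    return {"in_frame": "BMD_like",
            "out_of_frame": "DMD_like",
            "inapplicable": "indeterminate"}[status]


def skip_amenable(deletion: DmdStructuralVariant, exon: int,
                  model: DmdExonModel) -> bool:
    """Whether skipping ``exon`` restores the frame across ``deletion``.

    True iff the deletion is out of frame, the exon is immediately adjacent
    to it, the enlarged interval stays clear of the initial/terminal exons,
    and the enlarged interval is frame-preserving.
    """
    if not (1 <= exon <= 79):
        raise ValidationError(f"exon out of range: {exon}")
    if not deletion.is_interval:
        return False
    if frame_status(deletion, model) != "out_of_frame":
        return False  # in-frame or boundary deletions: not amenable by definition
    if exon == deletion.first_exon - 1:
        first, last = exon, deletion.last_exon
    elif exon == deletion.last_exon + 1:
        first, last = deletion.first_exon, exon
    else:
        return False
    if first == 1 or last == 79:
        return False
    return model.span_length(first, last) % 3 == 0


def amenable_therapy_exons(deletion: DmdStructuralVariant, model: DmdExonModel,
                           licensed: Iterable[int] = LICENSED_SKIP_EXONS,
                           trial: Iterable[int] = TRIAL_SKIP_EXONS):
    """Licensed and trial skip-target exons applicable to a deletion."""
    lic = tuple(sorted(e for e in licensed if skip_amenable(deletion, e, model)))
    tri = tuple(sorted(e for e in trial if skip_amenable(deletion, e, model)))
    return lic, tri


def breakpoints(sv: DmdStructuralVariant):
    """Flanking-intron breakpoints of an exon-interval variant.

    Intron ``i`` lies between exons ``i`` and ``i+1``; a boundary at the gene
    start or end yields the ``5prime``/``3prime`` sentinel instead.
    """
    if not sv.is_interval:
        raise ValidationError("breakpoints apply to deletions/duplications only")
    left = FIVE_PRIME if sv.first_exon == 1 else sv.first_exon - 1
    right = THREE_PRIME if sv.last_exon == 79 else sv.last_exon
    return {left, right}


def hotspot_summary(cohort: Iterable[DmdStructuralVariant],
                    hotspot_introns=range(45, 49)) -> dict:
    """Per-intron breakpoint counts/proportions over deletions/duplications.

    Each variant counts once per intron it touches; the hotspot fraction
    counts a variant once if at least one of its breakpoints falls in the
    hotspot introns (45-48 by default). Returns a dict with a per-intron
    table (DataFrame), the denominator, and the hotspot fraction.
    """
    intervals = [sv for sv in cohort if sv.is_interval]
    n = len(intervals)
    if n == 0:
        import warnings
        warnings.warn("hotspot_summary: no deletion/duplication records")
        return {"table": pd.DataFrame(columns=["intron", "count", "proportion"]),
                "n": 0, "hotspot_fraction": float("nan")}
    counts: dict = {}
    hot = set(hotspot_introns)
    n_hot = 0
    for sv in intervals:
        bps = breakpoints(sv)
        for b in bps:
            counts[b] = counts.get(b, 0) + 1
        if any(isinstance(b, int) and b in hot for b in bps):
            n_hot += 1

    def _sort_key(b):
        if b == FIVE_PRIME:
            return (-1,)
        if b == THREE_PRIME:
            return (80,)
        return (b,)

    table = pd.DataFrame(
        [(b, c, c / n) for b, c in sorted(counts.items(), key=lambda kv: _sort_key(kv[0]))],
        columns=["intron", "count", "proportion"])
    table["percent_display"] = (table["proportion"] * 100).map(_round_half_up)
    return {"table": table, "n": n, "hotspot_fraction": n_hot / n}


def variant_type_table(cohort: Iterable[DmdStructuralVariant]):
    """Country x variant-type contingency table (ContingencyTable)."""
    from .stats import ContingencyTable

    cols = ["deletion", "nonsense", "duplication", "splice"]
    counts: dict = {}
    for sv in cohort:
        kind = "nonsense" if sv.kind == "small_frameshift" else sv.kind
        if kind not in cols:
            raise ValidationError(f"unknown variant type {sv.kind!r}")
        row = counts.setdefault(sv.country, dict.fromkeys(cols, 0))
        row[kind] += 1
    rows = sorted(counts)
    import numpy as np
    data = np.array([[counts[r][c] for c in cols] for r in rows],
                    dtype=np.int64).reshape(len(rows), len(cols))
    return ContingencyTable(rows=rows, cols=cols, counts=data)


def _round_half_up(x: float) -> int:
    import math
    return int(math.floor(x + 0.5))
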