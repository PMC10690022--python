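"""Readers and writers for the interchange formats, packaged fixtures, and
run manifests.

Conventions (stated in file headers where applicable): variant files follow
VCF (1-based, REF/ALT); phenotype and panel files are 1-based human-readable
TSV; dystrophin exon intervals are 1-based inclusive. All writers round-trip
losslessly with their readers for the supported fields.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .acmg import CatalogFixture
from .dmd import DmdStructuralVariant
from .types import (GenePanel, OutcomeRecord, PlantedTruth, ProbandRecord,
                    Relative, ValidationError, VariantObservation)


class FormatError(ValueError):
    """Raised for unparseable or schema-violating input files."""


# ---------------------------------------------------------------------------
# Variants: minimal VCF and TSV
# ---------------------------------------------------------------------------

_VCF_INFO_KEYS = ("PROBAND", "GENE", "TRANSCRIPT", "HGVSC", "CSQ", "ZYG",
                  "INSILICO", "ACMG_EV")

_VCF_HEADER = """##fileformat=VCFv4.2
##source=nmdx
##INFO=<ID=PROBAND,Number=1,Type=String,Description="Proband identifier">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript identifier">
##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS.c description">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity: het/hom/hemi">
##INFO=<ID=INSILICO,Number=0,Type=Flag,Description="In-silico support">
##INFO=<ID=ACMG_EV,Number=.,Type=String,Description="ACMG evidence codes">
{af_lines}##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(path, variants_by_proband: dict) -> None:
    """Write all probands' variants to one minimal VCF (INFO-encoded)."""
    catalogs = sorted({name for vs in variants_by_proband.values()
                       for v in vs for name in v.afs})
    af_lines = "".join(
        f'##INFO=<ID=AF_{c.upper()},Number=1,Type=Float,'
        f'Description="Allele frequency in {c}">\n'
        for c in catalogs)
    rows = []
    for pid in sorted(variants_by_proband):
        for v in sorted(variants_by_proband[pid], key=lambda v: (v.position, v.id)):
            info = [f"PROBAND={pid}", f"GENE={v.gene}",
                    f"TRANSCRIPT={v.transcript}",
                    f"HGVSC={''.join(v.hgvs_c.split())}",
                    f"CSQ={v.consequence}", f"ZYG={v.zygosity}"]
            for cat in sorted(v.afs):
                info.append(f"AF_{cat.upper()}={v.afs[cat]:.10g}")
            if v.insilico_support:
                info.append("INSILICO")
            if v.acmg_evidence:
                info.append("ACMG_EV=" + ",".join(sorted(v.acmg_evidence)))
            rows.append(f"1\t{max(v.position, 1)}\t{v.id}\tA\tG\t.\t.\t"
                        + ";".join(info))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(af_lines=af_lines))
        fh.write("\n".join(rows) + ("\n" if rows else ""))


def read_variants_vcf(path) -> dict:
    """Read a minimal VCF back into {proband id: [VariantObservation]}."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    header_ids = {h.info().get("ID") for h in vcf.header_iter()
                  if h.type == "INFO"}
    if "GENE" not in header_ids:
        raise FormatError(f"{path}: VCF lacks the mandatory GENE INFO key")
    af_keys = sorted(k for k in header_ids if k and k.startswith("AF_"))
    out: dict = {}
    errors = []
    for i, rec in enumerate(vcf):
        pid = rec.INFO.get("PROBAND")
        gene = rec.INFO.get("GENE")
        if pid is None or gene is None:
            errors.append((i + 1, "missing PROBAND/GENE"))
            continue
        afs = {}
        for key in af_keys:
            val = rec.INFO.get(key)
            if val is not None:
                afs[key[3:].lower()] = float(val)
        ev = rec.INFO.get("ACMG_EV")
        try:
            v = VariantObservation(
                id=rec.ID, gene=gene, transcript=rec.INFO.get("TRANSCRIPT", ""),
                hgvs_c=rec.INFO.get("HGVSC", ""),
                consequence=rec.INFO.get("CSQ", "other"),
                zygosity=rec.INFO.get("ZYG", "het"), afs=afs,
                insilico_support=bool(rec.INFO.get("INSILICO", False)),
                acmg_evidence=frozenset(ev.split(",")) if ev else frozenset(),
                position=rec.POS)
        except ValidationError as exc:
            errors.append((i + 1, str(exc)))
            continue
        out.setdefault(pid, []).append(v)
    if errors:
        lines = "; ".join(f"record {ln}: {msg}" for ln, msg in errors)
        raise FormatError(f"{path}: malformed records — {lines}")
    return out


_VARIANT_TSV_COLUMNS = ["proband_id", "variant_id", "gene", "transcript",
                        "hgvs_c", "consequence", "zygosity", "position",
                        "afs", "insilico_support", "acmg_evidence"]


def write_variants_tsv(path, variants_by_proband: dict) -> None:
    rows = []
    for pid in sorted(variants_by_proband):
        for v in sorted(variants_by_proband[pid], key=lambda v: (v.position, v.id)):
            rows.append({
                "proband_id": pid, "variant_id": v.id, "gene": v.gene,
                "transcript": v.transcript, "hgvs_c": v.hgvs_c,
                "consequence": v.consequence, "zygosity": v.zygosity,
                "position": v.position,
                "afs": ";".join(f"{c}:{v.afs[c]:.10g}" for c in sorted(v.afs)),
                "insilico_support": int(v.insilico_support),
                "acmg_evidence": ";".join(sorted(v.acmg_evidence)),
            })
    pd.DataFrame(rows, columns=_VARIANT_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_variants_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#",
                     keep_default_na=False, dtype=str)
    missing = [c for c in _VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    out: dict = {}
    errors = []
    for i, row in df.iterrows():
        afs = {}
        try:
            if row["afs"]:
                for part in row["afs"].split(";"):
                    cat, val = part.split(":")
                    afs[cat] = float(val)
            ev = frozenset(row["acmg_evidence"].split(";")) \
                if row["acmg_evidence"] else frozenset()
            v = VariantObservation(
                id=row["variant_id"], gene=row["gene"],
                transcript=row["transcript"], hgvs_c=row["hgvs_c"],
                consequence=row["consequence"], zygosity=row["zygosity"],
                afs=afs, insilico_support=bool(int(row["insilico_support"])),
                acmg_evidence=ev, position=int(row["position"]))
        except (ValueError, ValidationError) as exc:
            errors.append((i + 2, str(exc)))  # +2: header + 1-based
            continue
        out.setdefault(row["proband_id"], []).append(v)
    if errors:
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in errors)
        raise ValidationError(f"{path}: invalid rows — {lines}")
    return out


def read_variants(path, format: str = "vcf") -> dict:
    if format == "vcf":
        return read_variants_vcf(path)
    if format == "tsv":
        return read_variants_tsv(path)
    raise FormatError(f"unknown variant format {format!r}")


# ---------------------------------------------------------------------------
# Phenotypes, truth, panels, catalogs, outcomes, DMD SVs
# ---------------------------------------------------------------------------

def write_phenotypes(path, probands: list) -> None:
    rows = [{
        "proband_id": p.id, "country": p.country,
        "category": p.diagnostic_category, "sex": p.sex,
        "age": round(p.age_years, 2),
        "hpo_pos": ";".join(sorted(p.hpo_positive)),
        "hpo_neg": ";".join(sorted(p.hpo_negative)),
        "relatives": ";".join(f"{r.relation}:{int(r.affected)}"
                              for r in p.relatives),
    } for p in probands]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#",
                     keep_default_na=False, dtype=str)
    needed = ["proband_id", "category", "sex", "age", "hpo_pos", "hpo_neg"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        relatives = tuple(
            Relative(relation=part.split(":")[0],
                     affected=bool(int(part.split(":")[1])))
            for part in row.get("relatives", "").split(";") if part)
        out.append(ProbandRecord(
            id=row["proband_id"], diagnostic_category=row["category"],
            sex=row["sex"], age_years=float(row["age"]),
            hpo_positive=frozenset(t for t in row["hpo_pos"].split(";") if t),
            hpo_negative=frozenset(t for t in row["hpo_neg"].split(";") if t),
            country=row.get("country", ""), relatives=relatives))
    return out


def write_truth(path, truths: list) -> None:
    with open(path, "w") as fh:
        json.dump([dataclasses.asdict(t) for t in truths], fh, indent=1)


def read_truth(path) -> list:
    with open(path) as fh:
        raw = json.load(fh)
    return [PlantedTruth(**{**d, "causal_variant_ids":
                            tuple(d["causal_variant_ids"])}) for d in raw]


def load_panels(path=None) -> list:
    """Load gene panels from a TSV (default: the packaged panel set)."""
    if path is None:
        res = resources.files("nmdx.data").joinpath("panels.tsv")
        with resources.as_file(res) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    panels = []
    for pid, sub in df.groupby("panel_id", sort=True):
        first = sub.iloc[0]
        panels.append(GenePanel(
            id=pid, name=first["panel_name"], category=first["category"],
            entries=tuple(zip(sub["gene"], sub["mode"])),
            hpo_terms=frozenset(first["hpo_terms"].split(";"))))
    return panels


def write_catalogs(path, catalogs: list) -> None:
    rows = []
    for cat in catalogs:
        keys = set(cat.known_variants) | set(cat.afs)
        for gene, hgvs in sorted(keys):
            af = cat.afs.get((gene, hgvs))
            rows.append({"catalog": cat.name, "gene": gene, "hgvs_c": hgvs,
                         "af": "" if af is None else f"{af:.10g}"})
    pd.DataFrame(rows, columns=["catalog", "gene", "hgvs_c", "af"]).to_csv(
        path, sep="\t", index=False)


def read_catalogs(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#",
                     keep_default_na=False, dtype=str)
    out: dict = {}
    for _, row in df.iterrows():
        cat = out.setdefault(row["catalog"], CatalogFixture(row["catalog"]))
        key = (row["gene"], row["hgvs_c"])
        cat.known_variants.add(key)
        if row["af"]:
            cat.afs[key] = float(row["af"])
    return [out[name] for name in sorted(out)]


def write_outcomes(path, outcomes: list) -> None:
    with open(path, "w") as fh:
        for o in outcomes:
            fh.write(json.dumps(dataclasses.asdict(o)) + "\n")


def read_outcomes(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            for key in ("causal_variant_ids", "variant_classes", "novel_flags"):
                d[key] = tuple(d[key])
            out.append(OutcomeRecord(**d))
    return out


def write_dmd_svs(path, records: list) -> None:
    rows = [{
        "sample_id": sv.sample_id, "country": sv.country, "kind": sv.kind,
        "first_exon": "" if sv.first_exon is None else sv.first_exon,
        "last_exon": "" if sv.last_exon is None else sv.last_exon,
        "locus": "" if sv.locus is None else sv.locus,
    } for sv in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dmd_svs(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#",
                     keep_default_na=False, dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(DmdStructuralVariant(
            kind=row["kind"],
            first_exon=int(row["first_exon"]) if row["first_exon"] else None,
            last_exon=int(row["last_exon"]) if row["last_exon"] else None,
            locus=int(row["locus"]) if row.get("locus") else None,
            sample_id=row["sample_id"], country=row["country"]))
    return out


# ---------------------------------------------------------------------------
# Packaged cohort-report table fixtures
# ---------------------------------------------------------------------------

@dataclass
class PaperTableFixture:
    table_id: str
    frame: pd.DataFrame


_FIXTURE_FILES = {
    "T1": "t1_neuropathy_novel.tsv",
    "T2": "t2_cm_cmd_novel.tsv",
    "T3": "t3_lgmd_dmd_novel.tsv",
    "dmd_counts": "dmd_counts.tsv",
}

_FIXTURE_SHA256 = {
    "T1": "841efb1877e7843dd301412a448e87e0e9cc66f52776c0dfbdbe147d3e183f6a",
    "T2": "a7b31df883708ce605cb04756692895eb5e7b65f1cffb885bec247a9d4254dbb",
    "T3": "b9686ad4c3c04ef43f90d99bca70d57e6b0a5559ae662824048e4343b15e5dbb",
    "dmd_counts": "dc9fbad1c3eb3775348cc20bb243704b55a53f8486b969ca959630e061e578a5",
}


def _fixture_bytes(table_id: str) -> bytes:
    fname = _FIXTURE_FILES[table_id]
    res = resources.files("nmdx.data").joinpath(f"paper_tables/{fname}")
    return res.read_bytes()


def load_fixture(table_id: str) -> PaperTableFixture:
    """Load a transcribed cohort-report table and verify its invariants."""
    if table_id not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {table_id!r}; "
                       f"choose from {sorted(_FIXTURE_FILES)}")
    raw = _fixture_bytes(table_id)
    digest = hashlib.sha256(raw).hexdigest()
    expected = _FIXTURE_SHA256.get(table_id)
    if expected is not None and digest != expected:
        raise FormatError(f"fixture {table_id}: checksum mismatch "
                          f"({digest} != {expected})")
    from io import BytesIO
    df = pd.read_csv(BytesIO(raw), sep="\t", comment="#",
                     keep_default_na=False)
    counts = {"T1": 22, "T2": 21, "T3": 17}
    if table_id in counts and len(df) != counts[table_id]:
        raise FormatError(
            f"fixture {table_id}: expected {counts[table_id]} rows, got {len(df)}")
    if table_id == "dmd_counts":
        sums = df.set_index("country").sum(axis=1)
        if int(sums.get("India", 0)) != 64 or int(sums.get("South Africa", 0)) != 40:
            raise FormatError("fixture dmd_counts: row sums must be 64 and 40")
    return PaperTableFixture(table_id=table_id, frame=df)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config, outputs: list, extra: dict = None) -> dict:
    """Emit one manifest per run: config hash, seeds, output checksums."""
    from . import __version__

    cfg_dict = config.to_dict()
    manifest = {
        "tool": "nmdx",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "config": cfg_dict,
        "outputs": {str(Path(p).name): sha256_file(p) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
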