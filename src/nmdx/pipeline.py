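"""End-to-end orchestration: simulate -> prioritize -> classify -> dmd -> stats.

Each stage logs record counts in/out so a run's accounting can be audited,
and a run manifest with config hash and output checksums is emitted at the
end. Fixed seeds reproduce every deterministic artifact byte-identically.
"""
from __future__ import annotations

import logging
from pathlib import Path

from . import io as nio
from .acmg import classify_outcome
from .config import CohortConfig
from .dmd import DmdExonModel, amenable_therapy_exons, frame_status, \
    hotspot_summary, predict_severity, variant_type_table
from .prioritize import flag_extended_analysis, prioritize
from .simulate import generate_dmd_cohort, simulate_cohort, truth_fit_flags
from .stats import fisher_exact, gene_frequency, novel_fraction, yield_table

log = logging.getLogger("nmdx")


def classify_cohort(cohort, panels=None, modality: str = "WES") -> list:
    """Prioritize and classify every proband of a synthetic cohort.

    Phenotype-fit flags come from the planted truth (standing in for the
    expert review the study performed); returns one OutcomeRecord per
    proband.
    """
    panels = panels or nio.load_panels()
    outcomes = []
    n_flagged = 0
    for proband in cohort.probands:
        truth = cohort.truth_of(proband.id)
        groups = prioritize(proband, cohort.variants[proband.id], panels)
        if flag_extended_analysis(proband, groups):
            n_flagged += 1
        outcome = classify_outcome(
            proband, groups, truth_fit_flags(truth), modality=modality,
            catalogs=cohort.catalogs)
        outcomes.append(outcome)
    log.info("classified %d probands (%d flagged for extended analysis)",
             len(outcomes), n_flagged)
    return outcomes


def run_all(config: CohortConfig, outdir, n_dmd: int = 106) -> dict:
    """Run the full pipeline on synthetic data and write the output tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    stage = "simulate"
    try:
        cohort = simulate_cohort(config)
        vcf = outdir / "variants.vcf"
        nio.write_variants_vcf(vcf, cohort.variants)
        pheno = outdir / "phenotypes.tsv"
        nio.write_phenotypes(pheno, cohort.probands)
        truth = outdir / "truth.json"
        nio.write_truth(truth, cohort.truths)
        cats = outdir / "catalogs.tsv"
        nio.write_catalogs(cats, cohort.catalogs)
        outputs += [vcf, pheno, truth, cats]
        log.info("simulated %d probands, %d variants", len(cohort.probands),
                 sum(len(v) for v in cohort.variants.values()))

        stage = "classify"
        outcomes = classify_cohort(cohort)
        ojl = outdir / "outcomes.jsonl"
        nio.write_outcomes(ojl, outcomes)
        outputs.append(ojl)

        stage = "dmd"
        model = DmdExonModel.load()
        svs = generate_dmd_cohort(config, n=n_dmd, seed=config.seed + 1)
        svtsv = outdir / "dmd_svs.tsv"
        nio.write_dmd_svs(svtsv, svs)
        outputs.append(svtsv)
        reports = []
        for sv in svs:
            if sv.is_interval:
                lic, tri = ([], []) if frame_status(sv, model) != "out_of_frame" \
                    else amenable_therapy_exons(sv, model)
                reports.append({
                    "sample_id": sv.sample_id, "country": sv.country,
                    "kind": sv.kind, "frame": frame_status(sv, model),
                    "severity": predict_severity(sv, model),
                    "licensed_skip_exons": list(lic),
                    "trial_skip_exons": list(tri)})
            else:
                reports.append({
                    "sample_id": sv.sample_id, "country": sv.country,
                    "kind": sv.kind, "frame": "inapplicable",
                    "severity": predict_severity(sv, model),
                    "licensed_skip_exons": [], "trial_skip_exons": []})
        import json
        dmd_report = outdir / "dmd_report.json"
        with open(dmd_report, "w") as fh:
            json.dump(reports, fh, indent=1)
        outputs.append(dmd_report)
        hs = hotspot_summary(svs)
        hstsv = outdir / "dmd_hotspots.tsv"
        hs["table"].to_csv(hstsv, sep="\t", index=False)
        outputs.append(hstsv)
        ct = variant_type_table(svs)
        p_types = fisher_exact(ct, method="montecarlo", seed=config.seed) \
            if ct.total > 200 else fisher_exact(ct)

        stage = "stats"
        yt = yield_table(outcomes, by=("category",))
        yt_path = outdir / "yield_by_category.tsv"
        yt.to_csv(yt_path, sep="\t", index=False)
        overall = yield_table(outcomes)
        ov_path = outdir / "yield_overall.tsv"
        overall.to_csv(ov_path, sep="\t", index=False)
        gf = gene_frequency(outcomes)
        gf_path = outdir / "gene_frequency.tsv"
        gf.to_csv(gf_path, sep="\t", index=False)
        nf = novel_fraction(outcomes)
        summary = {
            "n_probands": len(cohort.probands),
            "combined_solved_possibly_pct":
                float(overall["pct_combined"].iloc[0]),
            "novel_fraction": nf["fraction"],
            "dmd_hotspot_fraction_introns_45_48": hs["hotspot_fraction"],
            "dmd_variant_type_fisher_p": p_types,
        }
        summ_path = outdir / "summary.json"
        with open(summ_path, "w") as fh:
            json.dump(summary, fh, indent=1)
        outputs += [yt_path, ov_path, gf_path, summ_path]

        manifest = nio.write_manifest(outdir / "manifest.json", config, outputs)
        return {"manifest": manifest, "summary": summary, "outdir": str(outdir)}
    except Exception:
        # abort with stage name and a partial-output manifest
        nio.write_manifest(outdir / "manifest.partial.json", config,
                           [p for p in outputs if Path(p).exists()],
                           extra={"failed_stage": stage})
        log.exception("pipeline aborted during stage %s", stage)
        raise
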