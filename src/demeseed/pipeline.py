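"""Full pipeline: filter -> collapse -> cluster/classify -> co-occurrence
-> MLE correction -> founder fits -> statistics, with one JSON report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cooccur, founder, haplocall, io, popstats
from .config import RunConfig
from .core import DemeseedError

__all__ = ["run_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("demeseed")


def _stage(name: str):
    log.info("stage %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on the configured inputs and write the report.

    Returns the report dict; also writes ``report.json`` plus the catalog,
    assignment, curve and spectrum TSVs into ``config.output_dir``. Every
    stochastic stage records its seed in the report so results are
    reproducible from the report alone.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": config.to_dict(),
    }

    _stage("read")
    matrix = io.read_genotypes(config.genotypes, config.genotype_format)
    frame = io.read_sample_frame(config.samples, config.individuals)
    report["input"] = {
        "n_individuals": matrix.n_individuals,
        "n_sites_raw": matrix.n_sites,
        "n_samples": frame.n_samples,
    }

    _stage("filter")
    matrix = haplocall.filter_sites(
        matrix, config.min_call_rate, config.max_het_fraction
    )
    report["filter"] = {"n_sites_after_filter": matrix.n_sites}

    _stage("collapse")
    matrix = haplocall.collapse_in_phase(matrix)
    report["collapse"] = {"n_sites_after_collapse": matrix.n_sites}

    _stage("cluster")
    catalog, assignments = haplocall.call_haplotypes(
        matrix,
        minor_variant_max_diff=config.minor_variant_max_diff,
        min_overlap=config.min_overlap,
        f1_min_het_fraction=config.f1_min_het_fraction,
        min_block_sites=config.min_block_sites,
        location_code=config.location_code,
    )
    assignments.to_csv(out / "assignments.tsv", sep="\t", index=False, na_rep="NA")
    catalog.to_frame(matrix.site_labels()).to_csv(
        out / "catalog.tsv", sep="\t", index=False
    )
    report["haplotypes"] = {
        "n_major": len(catalog.majors),
        "n_entries": len(catalog),
        "class_counts": assignments["kind"].value_counts().to_dict(),
    }

    _stage("cooccurrence")
    excludes = set(config.substrate_excludes)
    curves = []
    for min_n in config.min_n_list:
        curve = cooccur.cooccurrence_curve(
            assignments, frame, config.thresholds_m, min_n, excludes
        )
        df = curve.to_frame()
        curves.append(df)
    curve_table = pd.concat(curves, ignore_index=True)
    curve_table.to_csv(out / "cooccurrence.tsv", sep="\t", index=False, na_rep="NA")
    report["cooccurrence"] = json.loads(
        curve_table.to_json(orient="records")
    )

    _stage("mle_correction")
    try:
        observed = cooccur.observed_multi_proportion(
            assignments, frame, min_n=min(config.min_n_list),
            substrate_excludes=excludes, radius=config.mixing_radius_m,
        )
        mle = cooccur.mle_true_multi_proportion(
            observed, n_replicates=config.mle_replicates,
            seed=config.seed, n_draws=config.mle_draws,
        )
        report["multi_proportion"] = {
            "observed": observed.fraction,
            "k": observed.k,
            "m": observed.m,
            "mle": mle.summary(),
        }
        p_multi = config.p_multi if config.p_multi is not None else mle.theta_hat
    except DemeseedError as exc:
        log.warning("mle_correction skipped: %s", exc)
        report["multi_proportion"] = {"error": str(exc)}
        p_multi = config.p_multi
    if p_multi is None or not (0.0 < p_multi < 1.0):
        raise DemeseedError(
            "no usable multi-genotype proportion for the founder model; "
            "set p_multi explicitly"
        )

    _stage("founders")
    founder_results = {}
    for spec_text in config.priors:
        prior = founder.FrequencyPrior.parse(spec_text)
        if prior.kind == "fixed":
            lam, clipped = founder.fit_lambda(p_multi, prior.f, full_output=True)
            founder_results[spec_text] = {
                "lambda": lam,
                "lambda_1dp": round(lam, 1),
                "clipped": clipped,
            }
        else:
            fit = founder.fit_lambda_mc(
                p_multi, prior, n_trials=config.founder_trials, seed=config.seed
            )
            founder_results[spec_text] = fit.summary()
    report["founders"] = {"p_multi": p_multi, "fits": founder_results}

    _stage("stats")
    spectrum = popstats.haplotype_spectrum(assignments, frame, by="individuals")
    spectrum.to_csv(out / "spectrum_individuals.tsv", sep="\t", index=False)
    report["spectrum_individuals"] = json.loads(spectrum.to_json(orient="records"))
    try:
        sample_of = frame.sample_of()
        fst = popstats.weir_cockerham_fst(
            matrix, [sample_of[i] for i in matrix.individuals]
        )
        report["fst_samples"] = fst.summary()
    except DemeseedError as exc:
        report["fst_samples"] = {"error": str(exc)}
    divergence, mean_div = popstats.pairwise_divergence(catalog)
    report["divergence"] = {
        "mean_substitutions_per_bp": mean_div,
        "surveyed_bp": popstats.DEFAULT_SURVEYED_BP,
    }
    divergence.to_csv(out / "divergence.tsv", sep="\t")

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=_jsonable))
    log.info("report written to %s", report_path)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
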