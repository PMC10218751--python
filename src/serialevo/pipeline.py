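"""Configuration-driven orchestration of the analysis stages.

``run_pipeline`` composes the stages in dependency order — simulate (or
ingest) barcode counts in two conditions, infer fitness, classify adaptive
loci, build the mutation spectrum — writing every intermediate artifact as
TSV/JSON so each stage is independently inspectable and re-runnable, plus a
``report.json`` manifest with provenance (config hash, master seed, package
version).  Identical configuration and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import adaptive_classifier, fitness_inference, popsim, spectrum_stats

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("serialevo")

_SIM_KEYS = {f.name for f in dataclasses.fields(popsim.SimConfig)}
_CLASSIFY_KEYS = {f.name for f in dataclasses.fields(adaptive_classifier.ClassifierConfig)}
_FIT_DEFAULTS = {
    "generations_per_transfer": 8.0,
    "pseudocount": 0.5,
    "threshold": 0.01,
}
_TOP_KEYS = {"stages", "out_dir", "seed", "log_level", "sim", "fit", "classify", "cohort"}
_COHORT_DEFAULTS = {
    "adaptive_loci": {f"ADP{i}": 4 for i in range(1, 7)},
    "effect_range": [0.03, 0.08],
    "passenger_rate": 0.3,
    "n_passenger_loci": 6000,
    "diploid_fraction": 0.0,
}


@dataclass
class RunConfig:
    stages: tuple[str, ...] = ("simulate", "fit", "classify", "stats")
    out_dir: str = "serialevo_out"
    seed: int = 0
    log_level: str = "INFO"
    sim: popsim.SimConfig = field(default_factory=popsim.SimConfig)
    fit: dict = field(default_factory=lambda: dict(_FIT_DEFAULTS))
    classify: adaptive_classifier.ClassifierConfig = field(
        default_factory=adaptive_classifier.ClassifierConfig
    )
    cohort: dict = field(default_factory=lambda: json.loads(json.dumps(_COHORT_DEFAULTS)))
    raw: dict = field(default_factory=dict)


def validate_config(document: dict) -> RunConfig:
    """Range-check and fully default a raw configuration document.

    Unknown keys anywhere are rejected; out-of-range parameters raise with
    the offending key and bound named.
    """
    unknown = set(document) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")

    sim_doc = dict(document.get("sim", {}))
    unknown = set(sim_doc) - _SIM_KEYS
    if unknown:
        raise ValueError(f"unknown sim key(s): {sorted(unknown)}")
    sim = popsim.SimConfig(**sim_doc)  # dataclass validates ranges

    fit_doc = dict(_FIT_DEFAULTS, **document.get("fit", {}))
    unknown = set(fit_doc) - set(_FIT_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown fit key(s): {sorted(unknown)}")
    if fit_doc["generations_per_transfer"] <= 0:
        raise ValueError("fit.generations_per_transfer must be > 0")
    if fit_doc["pseudocount"] < 0:
        raise ValueError("fit.pseudocount must be >= 0")
    if fit_doc["threshold"] < 0:
        raise ValueError("fit.threshold must be >= 0")

    cls_doc = dict(document.get("classify", {}))
    unknown = set(cls_doc) - _CLASSIFY_KEYS
    if unknown:
        raise ValueError(f"unknown classify key(s): {sorted(unknown)}")
    classify = adaptive_classifier.ClassifierConfig(**cls_doc)

    cohort_doc = json.loads(json.dumps(_COHORT_DEFAULTS))
    cohort_doc.update(document.get("cohort", {}))
    unknown = set(cohort_doc) - set(_COHORT_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown cohort key(s): {sorted(unknown)}")

    stages = tuple(document.get("stages", ("simulate", "fit", "classify", "stats")))
    known_stages = {"simulate", "fit", "classify", "stats"}
    bad = set(stages) - known_stages
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")

    return RunConfig(
        stages=stages,
        out_dir=str(document.get("out_dir", "serialevo_out")),
        seed=int(document.get("seed", 0)),
        log_level=str(document.get("log_level", "INFO")),
        sim=sim,
        fit=fit_doc,
        classify=classify,
        cohort=cohort_doc,
        raw=document,
    )


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "stages": list(config.stages),
            "seed": config.seed,
            "sim": dataclasses.asdict(config.sim),
            "fit": config.fit,
            "classify": dataclasses.asdict(config.classify),
            "cohort": config.cohort,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Simulates an evolved cohort, remeasures it in the nitrogen and glucose
    conditions, infers fitness, classifies loci and builds the spectrum.
    Returns the report manifest (also written to ``report.json``).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
        },
        "files": {},
        "stages_run": [],
    }
    files = manifest["files"]

    def finish(stage: str | None = None) -> dict:
        if stage is not None:
            manifest["stages_run"].append(stage)
        with open(out / "report.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest

    rng = np.random.default_rng(config.seed)
    conditions = ("nitrogen", "glucose")

    counts: dict[str, pd.DataFrame] = {}
    mutations = None
    lineages = None
    try:
        if "simulate" in config.stages:
            log.info("stage simulate: seed=%s", config.seed)
            sim = config.sim.replace(seed=config.seed)
            cohort = config.cohort
            lineages, mutations = popsim.simulate_evolved_cohort(
                sim,
                adaptive_loci=dict(cohort["adaptive_loci"]),
                effect_range=tuple(cohort["effect_range"]),
                passenger_rate=cohort["passenger_rate"],
                n_passenger_loci=cohort["n_passenger_loci"],
                diploid_fraction=cohort["diploid_fraction"],
                rng=rng,
            )
            for cond in conditions:
                cond_lineages = lineages
                if cond == "glucose":
                    cond_lineages = [
                        dataclasses.replace(ln, true_s=0.0, mutations=list(ln.mutations))
                        for ln in lineages
                    ]
                _, traj = popsim.simulate_serial_transfer(
                    sim, cond_lineages, rng=np.random.default_rng(rng.integers(2**31))
                )
                reads = popsim.sample_barcode_reads(
                    traj, sim.read_depth, seed=int(rng.integers(2**31))
                )
                path = out / f"counts_{cond}.tsv"
                popsim.write_count_table(reads, path)
                files[f"counts_{cond}"] = path.name
                counts[cond] = reads
                log.info("stage simulate: %s counts written (%d rows)", cond, len(reads))
            mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
            files["mutations"] = "mutations.tsv"
            popsim.write_truth(lineages, out / "truth.tsv", out / "truth_mutations.json")
            files["truth"] = "truth.tsv"
            finish("simulate")

        fitness: dict[str, pd.DataFrame] = {}
        if "fit" in config.stages:
            for cond in conditions:
                if cond not in counts:
                    path = out / f"counts_{cond}.tsv"
                    if not path.exists():
                        raise FileNotFoundError(f"fit stage needs {path}")
                    counts[cond] = popsim.read_count_table(path)
                neutral = [
                    b for b in counts[cond]["barcode"].unique() if b.startswith("neutral_")
                ]
                fitness[cond] = fitness_inference.infer_fitness(
                    counts[cond],
                    neutral,
                    generations_per_transfer=config.fit["generations_per_transfer"],
                    pseudocount=config.fit["pseudocount"],
                    threshold=config.fit["threshold"],
                )
                path = out / f"fitness_{cond}.tsv"
                fitness_inference.write_fitness_table(fitness[cond], path)
                files[f"fitness_{cond}"] = path.name
            finish("fit")

        if "classify" in config.stages:
            if mutations is None:
                mutations = pd.read_csv(out / "mutations.tsv", sep="\t")
            if not fitness:
                fitness = {
                    c: fitness_inference.read_fitness_table(out / f"fitness_{c}.tsv")
                    for c in conditions
                }
            summaries = adaptive_classifier.summarize_by_locus(
                mutations, fitness, fitness_threshold=config.classify.fitness_threshold
            )
            labelled = adaptive_classifier.classify_loci(summaries, config.classify)
            adaptive_classifier.write_locus_table(labelled, out / "loci.tsv")
            files["loci"] = "loci.tsv"
            ploidy = mutations.drop_duplicates("barcode").set_index("barcode")["ploidy"]
            all_barcodes = fitness["nitrogen"]["barcode"]
            ploidy = ploidy.reindex(all_barcodes).fillna("haploid")
            report = adaptive_classifier.summarize_cohort(
                labelled, mutations, fitness["nitrogen"], ploidy,
                threshold=config.classify.fitness_threshold,
            )
            adaptive_classifier.write_cohort_report(report, out / "cohort.json")
            files["cohort"] = "cohort.json"
            manifest["nitrogen_adaptive_loci"] = report["nitrogen_adaptive_loci"]
            finish("classify")

        if "stats" in config.stages:
            if mutations is None:
                mutations = pd.read_csv(out / "mutations.tsv", sep="\t")
            spectrum = spectrum_stats.build_spectrum_table(mutations)
            spectrum.to_frame().to_csv(out / "spectrum.tsv", sep="\t")
            files["spectrum"] = "spectrum.tsv"
            finish("stats")
    except Exception as exc:  # annotate which stage died, then re-raise
        done = manifest["stages_run"]
        raise RuntimeError(
            f"pipeline failed after stages {done}: {exc}"
        ) from exc

    return finish()
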