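"""End-to-end orchestration: simulate -> clean -> count -> bin -> neighbors
-> recovery/compare, driven by one YAML/JSON config, with a machine-readable
run manifest (checksums, row counts, seed, version) so runs are
self-describing and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .frequency import bin_abundances, count_peptides, diversity, top_n
from .neighbors import remove_neighbors
from .panning import SangerTable, TiterSeries, compare_sanger_ngs, recovery_efficiency
from .reads import cleaned_peptides, extract_and_translate, filter_report, write_fastq
from .synthetic import (
    CloneSpec,
    LibraryModel,
    PanningConfig,
    build_library,
    emit_reads,
    simulate_panning,
    write_provenance,
)

log = logging.getLogger("phagepan")

DEFAULT_CONFIG = {
    "seed": 0,
    "library": {"n_clones": 1000, "abundance_law": "uniform"},
    "spike_ins": [],
    "panning": {},
    "analysis": {
        "amber_policy": "stop",
        "reference": None,
        "remove_neighbors": False,
        "collapse_into_reference": False,
        "also_remove_reference": False,
    },
    "titers_csv": None,
    "sanger_csv": None,
}


class ConfigError(ValueError):
    """Raised when the run config fails validation (CLI exit code 2)."""


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    return merge_config(raw)


def merge_config(raw: dict) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in raw.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, outdir) -> dict:
    """Execute the configured stages and write tables, reports and manifest.

    Returns the manifest dict.  Stage order: simulate (library + rounds +
    read emission), process (clean/translate + filter report), freqs, bins,
    neighbors (optional), recovery and Sanger comparison (if inputs given).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}

    try:
        model = LibraryModel(seed=seed, **config["library"])
        spikes = [CloneSpec(**s) for s in config["spike_ins"]]
        pan = PanningConfig(**config["panning"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"stage=simulate: {exc}") from exc

    log.info("stage=simulate n_clones=%d n_rounds=%d", model.n_clones, pan.n_rounds)
    library = build_library(model, spikes)
    freqs = simulate_panning(library, pan, seed=seed)

    samples = {"naive": freqs[0]}
    if pan.n_rounds > 0:
        samples[f"round{pan.n_rounds}_eluate"] = freqs[-1]

    offset = len(pan.flank5)
    analysis = config["analysis"]
    results: dict[str, dict] = {}
    for label, fvec in samples.items():
        batch, prov = emit_reads(fvec, library, pan, seed=seed, sample_label=label)
        fq = outdir / f"{label}.fastq"
        write_fastq(batch, fq)
        write_provenance(prov, outdir / f"{label}.provenance.tsv")
        outputs[f"{label}.fastq"] = fq
        outputs[f"{label}.provenance.tsv"] = outdir / f"{label}.provenance.tsv"
        counts[f"{label}.reads"] = len(batch)

        translated = extract_and_translate(
            batch, offset=offset, amber_policy=analysis["amber_policy"]
        )
        report = filter_report(translated)
        (outdir / f"{label}.filter_report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        outputs[f"{label}.filter_report.json"] = outdir / f"{label}.filter_report.json"
        log.info(
            "stage=process sample=%s total=%d cleaned=%d removed=%d",
            label, report.total_reads, report.cleaned_reads, report.removed_reads,
        )

        table = count_peptides(cleaned_peptides(translated), sample_label=label)
        if analysis["reference"] and analysis["remove_neighbors"]:
            table, nreport = remove_neighbors(
                table,
                analysis["reference"],
                also_remove_reference=analysis["also_remove_reference"],
                collapse_into_reference=analysis["collapse_into_reference"],
            )
            nreport.matches.to_csv(outdir / f"{label}.neighbors.csv", index=False)
            outputs[f"{label}.neighbors.csv"] = outdir / f"{label}.neighbors.csv"
            counts[f"{label}.neighbors_matched"] = nreport.n_matched_unique
            log.info(
                "stage=neighbors sample=%s matched_unique=%d matched_reads=%d",
                label, nreport.n_matched_unique, nreport.matched_read_total,
            )
        table.to_csv(outdir / f"{label}.freqs.csv")
        outputs[f"{label}.freqs.csv"] = outdir / f"{label}.freqs.csv"
        counts[f"{label}.distinct_peptides"] = len(table)

        bins = bin_abundances(table)
        bins.to_csv(outdir / f"{label}.bins.csv", index=False)
        outputs[f"{label}.bins.csv"] = outdir / f"{label}.bins.csv"
        div = diversity(table)
        results[label] = {
            "diversity": div.to_dict(),
            "top10": top_n(table, 10).to_dict(orient="records"),
        }

    if config["titers_csv"]:
        titers = TiterSeries.read_csv(config["titers_csv"])
        rec = recovery_efficiency(titers)
        rec.to_csv(outdir / "recovery.csv", index=False)
        outputs["recovery.csv"] = outdir / "recovery.csv"
        results["recovery"] = rec.to_dict(orient="records")
        log.info("stage=recovery rounds=%d", len(rec))

    if config["sanger_csv"]:
        sanger = SangerTable.read_csv(config["sanger_csv"])
        eluate_label = f"round{pan.n_rounds}_eluate" if pan.n_rounds else "naive"
        from .frequency import PeptideFrequencyTable

        ngs = PeptideFrequencyTable.read_csv(
            outdir / f"{eluate_label}.freqs.csv", sample_label=eluate_label
        )
        cmp_report = compare_sanger_ngs(sanger, ngs)
        cmp_report.per_peptide.to_csv(outdir / "sanger_ngs.csv", index=False)
        outputs["sanger_ngs.csv"] = outdir / "sanger_ngs.csv"
        results["sanger_ngs"] = {
            "n_absent_from_top100": cmp_report.n_absent_from_top100,
            "n_absent_from_top1000": cmp_report.n_absent_from_top1000,
            "n_not_found": cmp_report.n_not_found,
        }
        log.info("stage=compare n_not_found=%d", cmp_report.n_not_found)

    (outdir / "summary.json").write_text(json.dumps(results, indent=2, default=str))
    outputs["summary.json"] = outdir / "summary.json"

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "row_counts": counts,
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
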