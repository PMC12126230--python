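"""End-to-end orchestration plus run manifests.

Each stage writes a plain TSV that the next stage can re-read, so any
stage is independently runnable and testable; ``run_all`` chains them and
drops a machine-readable manifest (config echo, package/library versions,
input checksums) next to the results.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .annotation import extract_3utrs, read_gene_models, write_utr_table
from .breakpoint import pdui_table, write_pdui_table
from .coverage import read_sample_sheet
from .diffapa import (
    APACallConfig, run_differential, summarize_direction, write_apa_results,
)
from .integration import intersect_binding, overlap_test, read_bed6


@dataclass
class PipelineConfig:
    """All knobs for a full run; serialised into the run manifest."""

    annotation: str
    samples: str
    outdir: str
    binding: str | None = None
    gmt: str | None = None
    ref_group: str = "control"
    alt_group: str = "knockdown"
    margin: int = 100
    stride: int = 1
    min_mean_coverage: float = 15.0
    min_utr_length: int = 150
    delta_threshold: float = 0.1
    alpha: float = 0.05
    p_mode: str = "fdr"
    universe: int | None = None
    seed: int = 0

    def call_config(self) -> APACallConfig:
        return APACallConfig(self.delta_threshold, self.alpha, self.p_mode)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: PipelineConfig, outputs: dict[str, str]) -> str:
    import scipy

    inputs = {}
    for key in ("annotation", "samples", "binding", "gmt"):
        path = getattr(config, key)
        if path and os.path.exists(path):
            inputs[key] = {"path": path, "sha256": _sha256(path)}
    manifest = {
        "config": asdict(config),
        "versions": {
            "apakit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "inputs": inputs,
        "outputs": outputs,
    }
    path = os.path.join(config.outdir, "run_manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_all(config: PipelineConfig) -> dict[str, str]:
    """Annotation -> coverage -> PDUI -> differential APA -> integration.

    Returns the map of output names to file paths; raises with a clear
    message when inputs are missing or a stage produces nothing.
    """
    for key in ("annotation", "samples"):
        path = getattr(config, key)
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing input: {key} file {path!r}")
    os.makedirs(config.outdir, exist_ok=True)
    outputs: dict[str, str] = {}

    models = read_gene_models(config.annotation)
    utrs = extract_3utrs(models, min_utr_length=config.min_utr_length)
    utr_path = os.path.join(config.outdir, "utr_annotation.tsv")
    write_utr_table(utrs, utr_path)
    outputs["utr_annotation"] = utr_path

    samples = read_sample_sheet(config.samples)
    groups = sorted({s.group for s in samples})
    if len(groups) < 2:
        raise ValueError("two groups required in the sample sheet")
    for g in (config.ref_group, config.alt_group):
        if g not in groups:
            raise ValueError(f"group {g!r} not present in sample sheet {groups}")

    table, fits = pdui_table(
        utrs, samples,
        margin=config.margin, stride=config.stride,
        min_mean_coverage=config.min_mean_coverage,
    )
    pdui_path = os.path.join(config.outdir, "pdui.tsv")
    write_pdui_table(table, fits, utrs, pdui_path)
    outputs["pdui"] = pdui_path

    results = run_differential(
        table, config.ref_group, config.alt_group,
        config.call_config(), fits=fits,
    )
    apa_path = os.path.join(config.outdir, "apa_results.tsv")
    write_apa_results(results, apa_path)
    outputs["apa_results"] = apa_path

    if results["significant"].any():
        summary = summarize_direction(results)
        sum_path = os.path.join(config.outdir, "direction_summary.json")
        with open(sum_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs["direction_summary"] = sum_path

    if config.binding:
        sites = read_bed6(config.binding)
        sig_genes = results.loc[results["significant"], "gene_id"].tolist()
        gene_bodies = {}
        for m in models:
            iv = gene_bodies.get(m.gene_id)
            if iv is None or len(m.interval) > len(iv):
                gene_bodies[m.gene_id] = m.interval
        annotations, bind_summary = intersect_binding(
            sig_genes, utrs, gene_bodies, sites
        )
        bind_path = os.path.join(config.outdir, "binding_annotation.tsv")
        with open(bind_path, "w") as fh:
            fh.write("gene_id\tcategory\tmin_distance_to_pas\tproximal_to_pas\n")
            for a in annotations:
                dist = "NA" if a.min_distance_to_pas is None else a.min_distance_to_pas
                fh.write(f"{a.gene_id}\t{a.category}\t{dist}\t{int(a.proximal_to_pas)}\n")
        outputs["binding_annotation"] = bind_path
        if config.universe:
            bound = [a.gene_id for a in annotations if a.category != "none"]
            ov = overlap_test(sig_genes, bound or sig_genes, config.universe)
            bind_summary["overlap_p_value"] = ov.p_value
        bsum_path = os.path.join(config.outdir, "binding_summary.json")
        with open(bsum_path, "w") as fh:
            json.dump(bind_summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs["binding_summary"] = bsum_path

    outputs["manifest"] = write_manifest(config, dict(outputs))
    return outputs
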