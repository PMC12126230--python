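"""Synthetic two-isoform 3'UTR datasets with known ground truth.

Each simulated gene expresses a short isoform ending at the proximal PAS
(offset ``P_true`` from the UTR 5' end) and a long isoform spanning the
full UTR, mixed at a per-condition true PDUI.  Reads of fixed length are
placed uniformly along each isoform (with an upstream flank, so coverage
at the UTR 5' end is at full height); read counts are Poisson, or negative
binomial when a dispersion is set.  Coverage is the per-base read pileup,
so the drop at ``P_true`` is a realistic ramp over ~read_length bases, not
an ideal step.

One global seed expands into per-gene substreams keyed by a stable hash of
the gene id, so any subset of genes reproduces identically regardless of
iteration order.  All outputs are plain text (BED12, bedGraph, BED6, TSV);
the generator can also hand back in-memory coverage tables so the whole
pipeline runs without touching disk.

Library sizes are written as exactly one million reads per sample, so the
per-million depth factor is 1 and synthetic coverage is already in
normalised units.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field

import numpy as np

from .annotation import GenomicInterval, UTRRegion
from .coverage import SampleInfo, write_bedgraph

CDS_FLANK = 300          # upstream CDS length in the synthetic gene models
GENE_SPACING = 1000      # intergenic gap on the synthetic chromosome
SIM_LIBRARY_SIZE = 1_000_000


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    utr_length: int
    P_true: int
    pdui_true: dict  # condition label -> true PDUI in [0, 1]
    depth: float
    read_length: int
    dispersion: float
    seed: int
    effect: str = "null"  # null | lengthened | shortened

    def __post_init__(self):
        if not (0 < self.P_true < self.utr_length):
            raise ValueError(f"{self.gene_id}: P_true outside UTR")
        for cond, v in self.pdui_true.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{self.gene_id}: pdui_true[{cond}] outside [0,1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study design for a synthetic dataset.

    Defaults mirror the analysis conditions the pipeline targets: 3 vs 3
    replicates at 100x 5'-end coverage with 100-nt reads; a 60/30/10
    mixture of null, lengthened (ΔPDUI = +0.3) and shortened (−0.3) genes;
    half of the lengthened genes carry a binding site within 75 nt
    upstream of the distal PAS (the repressive-binding geometry).
    """

    n_genes: int = 200
    n_replicates: int = 3
    frac_null: float = 0.6
    frac_lengthened: float = 0.3
    frac_shortened: float = 0.1
    effect_size: float = 0.3
    depth: float = 100.0
    read_length: int = 100
    dispersion: float = 0.0
    binding_fraction: float = 0.5
    utr_length_range: tuple[int, int] = (800, 2000)
    breakpoint_margin: int = 200  # keep P_true this far from both UTR ends
    ref_group: str = "control"
    alt_group: str = "knockdown"
    seed: int = 0

    def __post_init__(self):
        total = self.frac_null + self.frac_lengthened + self.frac_shortened
        if abs(total - 1.0) > 1e-9:
            raise ValueError("effect fractions must sum to 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _gene_stream(seed: int, gene_id: str, *extra: int) -> np.random.Generator:
    """Per-gene RNG substream: stable across iteration order and subsets."""
    tag = zlib.crc32(gene_id.encode())
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence([seed, tag, *extra]))
    )


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    size = 1.0 / dispersion
    return int(rng.negative_binomial(size, size / (size + mean)))


def _isoform_pileup(
    rng: np.random.Generator, n_reads: int, iso_len: int, read_length: int
) -> np.ndarray:
    """Pileup over [0, iso_len) from reads starting uniformly along the isoform.

    Start positions range over iso_len slots from −(read_length−1) (in the
    upstream flank) to iso_len − read_length, so interior coverage is flat
    at n·read_length/iso_len, full at base 0, and ramps down over the final
    read_length−1 bases (the fragment must end before the cleavage site).
    """
    if n_reads == 0 or iso_len <= 0:
        return np.zeros(iso_len)
    idx = rng.integers(0, iso_len, size=n_reads)  # start + read_length − 1
    hist = np.bincount(idx, minlength=iso_len + read_length - 1)
    csum = np.concatenate(([0], np.cumsum(hist)))
    b = np.arange(iso_len)
    return (csum[np.minimum(b + read_length, len(hist))] - csum[b]).astype(float)


def simulate_gene(
    truth: SimTruth, condition: str, replicate_index: int
) -> np.ndarray:
    """Per-base coverage (5'→3' orientation) for one gene/condition/replicate."""
    rng = _gene_stream(
        truth.seed, truth.gene_id,
        zlib.crc32(condition.encode()), replicate_index,
    )
    pdui = truth.pdui_true[condition]
    L, P, rl = truth.utr_length, truth.P_true, truth.read_length
    n_short = _draw_count(rng, (1.0 - pdui) * truth.depth * P / rl,
                          truth.dispersion)
    n_long = _draw_count(rng, pdui * truth.depth * L / rl, truth.dispersion)
    cov = _isoform_pileup(rng, n_long, L, rl)
    cov[:P] += _isoform_pileup(rng, n_short, P, rl)
    return cov


def simulate_truths(config: SimConfig) -> list[SimTruth]:
    """Draw per-gene ground truth (UTR geometry, PDUIs, effect classes).

    Effect classes are assigned in exact proportions via a seeded
    permutation; baseline PDUIs are drawn so that adding the effect never
    needs clipping (true ΔPDUI is exactly ±effect_size for non-null genes).
    """
    n = config.n_genes
    n_len = int(round(n * config.frac_lengthened))
    n_short = int(round(n * config.frac_shortened))
    labels = (["lengthened"] * n_len + ["shortened"] * n_short
              + ["null"] * (n - n_len - n_short))
    perm = np.random.Generator(
        np.random.Philox(np.random.SeedSequence([config.seed, 0xA9A]))
    ).permutation(n)
    truths = []
    width = len(str(n - 1)) if n > 1 else 1
    for i in range(n):
        gene_id = f"gene{i:0{width}d}"
        effect = labels[perm[i]]
        rng = _gene_stream(config.seed, gene_id, 0xFACE)
        L = int(rng.integers(config.utr_length_range[0],
                             config.utr_length_range[1] + 1))
        m = config.breakpoint_margin
        P = int(rng.integers(m, L - m + 1))
        d = config.effect_size
        if effect == "lengthened":
            base = float(rng.uniform(0.15, 0.95 - d))
            pduis = {config.ref_group: base, config.alt_group: base + d}
        elif effect == "shortened":
            base = float(rng.uniform(0.05 + d, 0.85))
            pduis = {config.ref_group: base, config.alt_group: base - d}
        else:
            base = float(rng.uniform(0.15, 0.85))
            pduis = {config.ref_group: base, config.alt_group: base}
        truths.append(SimTruth(
            gene_id=gene_id, utr_length=L, P_true=P, pdui_true=pduis,
            depth=config.depth, read_length=config.read_length,
            dispersion=config.dispersion, seed=config.seed, effect=effect,
        ))
    return truths


def _layout(truths: list[SimTruth]) -> dict[str, UTRRegion]:
    """Place genes along a synthetic chromosome, alternating strands."""
    regions: dict[str, UTRRegion] = {}
    offset = GENE_SPACING
    for i, t in enumerate(sorted(truths, key=lambda t: t.gene_id)):
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start = offset + CDS_FLANK
            end = start + t.utr_length
            distal = end
        else:
            start = offset
            end = start + t.utr_length
            distal = start
        regions[t.gene_id] = UTRRegion(
            t.gene_id, GenomicInterval("chrS", start, end, strand),
            distal, (f"{t.gene_id}.t1",),
        )
        offset = end + (CDS_FLANK if strand == "-" else 0) + GENE_SPACING
    return regions


def _sample_plan(config: SimConfig) -> list[tuple[str, str, int]]:
    plan = []
    for group in (config.ref_group, config.alt_group):
        for r in range(1, config.n_replicates + 1):
            plan.append((f"{group}_{r}", group, r))
    return plan


def simulate_coverage_tables(config: SimConfig):
    """In-memory dataset: (utrs, samples, coverage_maps, truths).

    ``coverage_maps`` is {sample_id: {UTRRegion: oriented array}} ready for
    :func:`apakit.breakpoint.pdui_table`.
    """
    truths = simulate_truths(config)
    regions = _layout(truths)
    utrs = [regions[t.gene_id] for t in truths]
    samples = [
        SampleInfo(sid, group, SIM_LIBRARY_SIZE, f"<memory:{sid}>")
        for sid, group, _ in _sample_plan(config)
    ]
    coverage_maps: dict[str, dict[UTRRegion, np.ndarray]] = {}
    for sid, group, rep in _sample_plan(config):
        cov_map = {}
        for t in truths:
            cov_map[regions[t.gene_id]] = simulate_gene(t, group, rep)
        coverage_maps[sid] = cov_map
    return utrs, samples, coverage_maps, truths


def simulate_dataset(config: SimConfig, outdir) -> dict[str, str]:
    """Write the full synthetic dataset to ``outdir``; returns file paths.

    Files: annotation.bed12, <sample>.bedgraph per sample, samples.tsv,
    truth.tsv, binding.bed.  Byte-identical for identical config and seed.
    """
    os.makedirs(outdir, exist_ok=True)
    truths = simulate_truths(config)
    regions = _layout(truths)
    paths = {
        "annotation": os.path.join(outdir, "annotation.bed12"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "binding": os.path.join(outdir, "binding.bed"),
    }

    with open(paths["annotation"], "w") as fh:
        for t in sorted(truths, key=lambda t: t.gene_id):
            r = regions[t.gene_id].region
            if r.strand == "+":
                tx_start, tx_end = r.start - CDS_FLANK, r.end
                thick_start, thick_end = tx_start, r.start
            else:
                tx_start, tx_end = r.start, r.end + CDS_FLANK
                thick_start, thick_end = r.end, tx_end
            size = tx_end - tx_start
            fh.write(
                f"{r.chrom}\t{tx_start}\t{tx_end}\t{t.gene_id}|{t.gene_id}.t1"
                f"\t0\t{r.strand}\t{thick_start}\t{thick_end}\t0\t1\t{size},\t0,\n"
            )

    sample_rows = []
    for sid, group, rep in _sample_plan(config):
        bg_path = os.path.join(outdir, f"{sid}.bedgraph")
        open(bg_path, "w").close()
        for t in sorted(truths, key=lambda t: t.gene_id):
            reg = regions[t.gene_id]
            cov = simulate_gene(t, group, rep)
            genomic = cov[::-1] if reg.region.strand == "-" else cov
            write_bedgraph(bg_path, reg.region.chrom, reg.region.start, genomic)
        sample_rows.append((sid, group, bg_path))
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\tgroup\ttotal_mapped_reads\tcoverage_path\n")
        for sid, group, bg_path in sample_rows:
            # basename keeps the sheet portable (and byte-stable across
            # output directories); the reader resolves it relative to the
            # sheet's own location
            fh.write(
                f"{sid}\t{group}\t{SIM_LIBRARY_SIZE}\t"
                f"{os.path.basename(bg_path)}\n"
            )

    with open(paths["truth"], "w") as fh:
        ref, alt = config.ref_group, config.alt_group
        fh.write(
            "gene_id\tchrom\tstrand\tutr_start\tutr_end\tutr_length\tP_true\t"
            f"pdui_{ref}\tpdui_{alt}\tdelta_pdui_true\teffect\tdepth\t"
            "read_length\tdispersion\tseed\n"
        )
        for t in sorted(truths, key=lambda t: t.gene_id):
            r = regions[t.gene_id].region
            fh.write(
                f"{t.gene_id}\t{r.chrom}\t{r.strand}\t{r.start}\t{r.end}\t"
                f"{t.utr_length}\t{t.P_true}\t{t.pdui_true[ref]:.6f}\t"
                f"{t.pdui_true[alt]:.6f}\t"
                f"{t.pdui_true[alt] - t.pdui_true[ref]:.6f}\t{t.effect}\t"
                f"{t.depth:g}\t{t.read_length}\t{t.dispersion:g}\t{t.seed}\n"
            )

    with open(paths["binding"], "w") as fh:
        for t in sorted(truths, key=lambda t: t.gene_id):
            if t.effect != "lengthened":
                continue
            rng = _gene_stream(config.seed, t.gene_id, 0xB1D)
            if rng.random() >= config.binding_fraction:
                continue
            utr = regions[t.gene_id]
            gap = int(rng.integers(5, 56))  # site edge 5–55 nt upstream of PAS
            width = 20
            if utr.region.strand == "+":
                pas = utr.distal_end - 1
                start, end = pas - gap - width + 1, pas - gap + 1
            else:
                pas = utr.distal_end
                start, end = pas + gap, pas + gap + width
            fh.write(
                f"{utr.region.chrom}\t{start}\t{end}\t{t.gene_id}_site\t100\t"
                f"{utr.region.strand}\n"
            )
    return paths
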