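"""Per-base coverage loading, transcript orientation, depth normalisation.

Coverage arrives as bedGraph (4-column) or wiggle (fixedStep /
variableStep) tracks, one file per sample.  Arrays are oriented 5'→3' of
the transcript: minus-strand regions are reversed so index 0 is always the
UTR's 5' end, which is the orientation the breakpoint model assumes.

Depth normalisation scales coverage to reads-per-million using the
externally supplied total mapped-read count (the ``samtools flagstat``
number in a real pipeline).  PDUI is a within-sample ratio and is invariant
to this scaling; the normalised values feed only the expression filter and
reporting.
"""

from __future__ import annotations

import csv
import os
import logging
from dataclasses import dataclass, replace

import numpy as np

from .annotation import GenomicInterval, ParseError, UTRRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleInfo:
    """One sequencing sample: condition label, library size, coverage path."""

    sample_id: str
    group: str
    total_mapped_reads: int
    coverage_path: str

    def __post_init__(self):
        if self.total_mapped_reads <= 0:
            raise ValueError(f"{self.sample_id}: total_mapped_reads must be > 0")
        if not self.group:
            raise ValueError(f"{self.sample_id}: empty group label")

    @property
    def depth_factor(self) -> float:
        return 1e6 / self.total_mapped_reads


@dataclass(frozen=True)
class UTRCoverage:
    """Per-base coverage over one UTR for one sample, oriented 5'→3'."""

    gene_id: str
    sample_id: str
    values: np.ndarray
    depth_factor: float = 1.0

    def __post_init__(self):
        if self.depth_factor <= 0:
            raise ValueError("depth_factor must be > 0")
        if np.any(self.values < 0):
            raise ValueError("negative coverage values")


def read_sample_sheet(path) -> list[SampleInfo]:
    """Read the TSV sample sheet: sample_id, group, total_mapped_reads, coverage_path."""
    samples = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "group", "total_mapped_reads", "coverage_path"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: sample sheet must have columns {sorted(required)}"
            )
        sheet_dir = os.path.dirname(os.path.abspath(path))
        for row in reader:
            cov_path = row["coverage_path"]
            if not os.path.isabs(cov_path):  # resolve relative to the sheet
                cov_path = os.path.join(sheet_dir, cov_path)
            samples.append(
                SampleInfo(
                    row["sample_id"],
                    row["group"],
                    int(row["total_mapped_reads"]),
                    cov_path,
                )
            )
    if not samples:
        raise ParseError(f"{path}: empty sample sheet")
    return samples


def _fill_regions(
    regions: list[UTRRegion],
) -> tuple[dict[str, list[UTRRegion]], dict[UTRRegion, np.ndarray], dict[UTRRegion, np.ndarray]]:
    by_chrom: dict[str, list[UTRRegion]] = {}
    arrays: dict[UTRRegion, np.ndarray] = {}
    filled: dict[UTRRegion, np.ndarray] = {}
    for r in regions:
        by_chrom.setdefault(r.region.chrom, []).append(r)
        arrays[r] = np.zeros(len(r), dtype=float)
        filled[r] = np.zeros(len(r), dtype=bool)
    return by_chrom, arrays, filled


def _add_interval(
    region: UTRRegion,
    arr: np.ndarray,
    mask: np.ndarray,
    start: int,
    end: int,
    value: float,
    context: str,
) -> None:
    lo = max(start, region.region.start)
    hi = min(end, region.region.end)
    if lo >= hi:
        return
    i0, i1 = lo - region.region.start, hi - region.region.start
    if mask[i0:i1].any():
        raise ParseError(
            f"{context}: overlapping coverage intervals over "
            f"{region.region.chrom}:{lo}-{hi} (ambiguous coverage)"
        )
    arr[i0:i1] += value
    mask[i0:i1] = True


def _orient(regions, arrays) -> dict[UTRRegion, np.ndarray]:
    # reverse minus-strand arrays so index 0 is the transcript 5' end
    return {
        r: (arrays[r][::-1].copy() if r.region.strand == "-" else arrays[r])
        for r in regions
    }


def read_bedgraph(path, regions: list[UTRRegion]) -> dict[UTRRegion, np.ndarray]:
    """Read a bedGraph file into per-base arrays over the given UTR regions.

    Bases not covered by any interval are 0.  Overlapping intervals within a
    region raise (coverage would be ambiguous); negative values raise.
    Minus-strand arrays are returned reversed (transcript orientation).
    """
    by_chrom, arrays, filled = _fill_regions(regions)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if value < 0:
                raise ParseError(f"{path}: line {lineno}: negative coverage {value}")
            for region in by_chrom.get(chrom, ()):
                _add_interval(
                    region, arrays[region], filled[region],
                    start, end, value, f"{path}: line {lineno}",
                )
    return _orient(regions, arrays)


def read_wiggle(path, regions: list[UTRRegion]) -> dict[UTRRegion, np.ndarray]:
    """Read a wiggle file (fixedStep/variableStep, 1-based) over UTR regions."""
    by_chrom, arrays, filled = _fill_regions(regions)
    mode = None
    chrom = None
    pos = step = span = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                parts = dict(
                    kv.split("=") for kv in line.split()[1:] if "=" in kv
                )
                mode = line.split()[0]
                chrom = parts.get("chrom")
                span = int(parts.get("span", 1))
                step = int(parts.get("step", 1))
                pos = int(parts.get("start", 1)) - 1  # wiggle is 1-based
                if chrom is None:
                    raise ParseError(f"{path}: line {lineno}: missing chrom=")
                continue
            if mode is None:
                raise ParseError(f"{path}: line {lineno}: data before header")
            if mode == "fixedStep":
                value = float(line)
                start = pos
                pos += step
            else:
                f = line.split()
                if len(f) != 2:
                    raise ParseError(
                        f"{path}: line {lineno}: variableStep needs 2 fields"
                    )
                start = int(f[0]) - 1
                value = float(f[1])
            if value < 0:
                raise ParseError(f"{path}: line {lineno}: negative coverage")
            for region in by_chrom.get(chrom, ()):
                _add_interval(
                    region, arrays[region], filled[region],
                    start, start + span, value, f"{path}: line {lineno}",
                )
    return _orient(regions, arrays)


def normalize_depth(cov: UTRCoverage) -> UTRCoverage:
    """Scale coverage to per-million-mapped-reads units.

    PDUI is unchanged by this scaling (it is a within-sample ratio); the
    normalised track is used by the expression filter and in reports.
    """
    return replace(
        cov, values=cov.values * cov.depth_factor, depth_factor=1.0
    )


def expression_filter(
    covs: list[UTRCoverage], min_mean_coverage: float = 15.0
) -> bool:
    """Pass iff mean *normalised* coverage >= threshold in every sample.

    The boundary is inclusive.  Requiring the threshold per sample (rather
    than on the mean of means) guards against fitting a breakpoint to a
    sample with no signal.
    """
    if not covs:
        raise ValueError("expression_filter needs >= 1 sample")
    return all(
        float(np.mean(c.values * c.depth_factor)) >= min_mean_coverage
        for c in covs
    )


def write_bedgraph(path, chrom: str, start: int, values: np.ndarray) -> None:
    """Write a per-base array as run-length-encoded bedGraph (genomic order).

    Zero runs are omitted, matching the sparse convention of real tracks.
    """
    values = np.asarray(values)
    with open(path, "a") as fh:
        if len(values) == 0:
            return
        edges = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], edges))
        ends = np.concatenate((edges, [len(values)]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v == 0:
                continue
            fh.write(f"{chrom}\t{start + s}\t{start + e}\t{v:g}\n")
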