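"""De novo proximal poly(A) site inference and PDUI computation.

The model: each gene expresses a short and a long 3'UTR isoform that share
a proximal segment.  At a candidate breakpoint P (the de novo proximal
PAS), expected coverage in sample s is

    w_short[s] + w_long[s]   on bases [0, P)   (both isoforms)
    w_long[s]                on bases [P, L)   (long isoform only)

Per candidate the least-squares weights are closed-form segment means:
w_long = mean(values[P:L]) and w_short = max(0, mean(values[0:P]) − w_long)
— the clamp forbids negative abundances, and when it binds residuals are
recomputed with w_short = 0.  One breakpoint is fitted *jointly* across all
samples (both conditions) by minimising the summed squared residual, so
per-sample PDUIs are comparable; ties in the residual are broken toward the
most proximal P.

PDUI (Percentage of Distal poly(A) site Usage Index) per sample is then
w_long / (w_long + w_short): the fraction of transcripts using the distal
site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import UTRRegion
from .coverage import SampleInfo, UTRCoverage, expression_filter, read_bedgraph

logger = logging.getLogger(__name__)

DEFAULT_MARGIN = 100
DEFAULT_STRIDE = 1


@dataclass(frozen=True)
class BreakpointFit:
    """A fitted proximal PAS: offset P from the UTR 5' end plus weights.

    ``w_long`` / ``w_short`` are per-sample isoform abundances in coverage
    units (arrays aligned with ``sample_ids``); ``rss`` is the total
    residual sum of squares over all samples at the chosen P.
    """

    gene_id: str
    P: int
    utr_length: int
    sample_ids: tuple[str, ...]
    w_long: np.ndarray
    w_short: np.ndarray
    rss: float

    def __post_init__(self):
        if np.any(self.w_long < 0) or np.any(self.w_short < 0):
            raise ValueError("negative isoform abundance")
        if self.rss < -1e-9:
            raise ValueError("negative rss")


def _candidate_stats(values: np.ndarray, candidates: np.ndarray):
    """Closed-form per-candidate weights and RSS for one sample.

    Uses prefix sums so the full candidate sweep is O(L).
    """
    L = values.shape[0]
    c = np.concatenate(([0.0], np.cumsum(values)))        # c[P] = sum(values[:P])
    cs = np.concatenate(([0.0], np.cumsum(values ** 2)))  # sum of squares
    P = candidates.astype(float)
    n2 = L - candidates
    m1 = c[candidates] / P
    m2 = (c[L] - c[candidates]) / n2
    rss2 = (cs[L] - cs[candidates]) - n2 * m2 ** 2
    # unclamped: first-segment level is its own mean
    rss1_free = cs[candidates] - P * m1 ** 2
    # clamped (mean short < 0): w_short = 0, first segment fitted at w_long = m2
    rss1_clamp = cs[candidates] - 2.0 * m2 * c[candidates] + P * m2 ** 2
    clamp = m1 < m2
    rss1 = np.where(clamp, rss1_clamp, rss1_free)
    w_long = m2
    w_short = np.where(clamp, 0.0, m1 - m2)
    rss = np.maximum(rss1, 0.0) + np.maximum(rss2, 0.0)
    return w_long, w_short, rss


def fit_breakpoint(
    covs: list[UTRCoverage],
    margin: int = DEFAULT_MARGIN,
    stride: int = DEFAULT_STRIDE,
) -> BreakpointFit:
    """Fit the shared two-segment breakpoint jointly across samples.

    Candidate offsets run from ``margin`` to ``L − margin`` (inclusive
    bounds, step ``stride``); the margin prevents degenerate one-base
    segments.  Raises ``ValueError`` for UTRs too short to search
    (L <= 2·margin) and for genes with all-zero coverage in every sample.
    """
    if not covs:
        raise ValueError("fit_breakpoint needs >= 1 sample")
    arrays = [np.asarray(c.values, dtype=float) for c in covs]
    L = arrays[0].shape[0]
    if any(a.shape[0] != L for a in arrays):
        raise ValueError("coverage arrays differ in length")
    if L <= 2 * margin:
        raise ValueError(
            f"{covs[0].gene_id}: UTR length {L} <= 2*margin ({2 * margin}); skipped"
        )
    if all(not a.any() for a in arrays):
        raise ValueError(f"{covs[0].gene_id}: all-zero coverage in every sample")

    candidates = np.arange(margin, L - margin + 1, stride)
    total_rss = np.zeros(candidates.shape[0])
    per_sample = []
    for a in arrays:
        wl, ws, rss = _candidate_stats(a, candidates)
        per_sample.append((wl, ws))
        total_rss += rss
    best = int(np.argmin(total_rss))  # first minimum -> most proximal P on ties
    P = int(candidates[best])
    w_long = np.array([wl[best] for wl, _ in per_sample])
    w_short = np.array([ws[best] for _, ws in per_sample])
    return BreakpointFit(
        gene_id=covs[0].gene_id,
        P=P,
        utr_length=L,
        sample_ids=tuple(c.sample_id for c in covs),
        w_long=w_long,
        w_short=np.maximum(w_short, 0.0),
        rss=max(float(total_rss[best]), 0.0),
    )


def compute_pdui(fit: BreakpointFit) -> dict[str, float]:
    """Per-sample PDUI = w_long / (w_long + w_short).

    Samples where both weights are 0 have undefined PDUI and are dropped
    (logged).
    """
    out: dict[str, float] = {}
    for sid, wl, ws in zip(fit.sample_ids, fit.w_long, fit.w_short):
        denom = wl + ws
        if denom == 0:
            logger.info("%s / %s: zero abundance, PDUI undefined; dropped",
                        fit.gene_id, sid)
            continue
        out[sid] = float(wl / denom)
    return out


def pdui_table(
    utrs: list[UTRRegion],
    samples: list[SampleInfo],
    margin: int = DEFAULT_MARGIN,
    stride: int = DEFAULT_STRIDE,
    min_mean_coverage: float = 15.0,
    end_trim: int | None = None,
    coverage_maps: dict[str, dict[UTRRegion, np.ndarray]] | None = None,
) -> tuple[pd.DataFrame, dict[str, BreakpointFit]]:
    """Run breakpoint fitting + PDUI over all genes passing the filter.

    Parameters
    ----------
    end_trim
        Bases excluded from the 3' end of each UTR before fitting (default:
        ``margin``).  Coverage there decays over the final fragment length
        as reads run out of transcript before the cleavage site; the
        two-segment model has no step at the distal terminus to absorb that
        ramp, so leaving it in drags the breakpoint toward the UTR end and
        biases PDUI toward 0.5 for near-uniform genes.  Trimming is capped
        so at least ``2*margin + 1`` bases remain.
    coverage_maps
        Optional pre-loaded {sample_id: {UTRRegion: oriented array}}; when
        absent each sample's bedGraph is read from its ``coverage_path``.

    Returns
    -------
    (table, fits)
        ``table`` is a tidy DataFrame with columns gene_id, sample_id,
        group, pdui, w_long, w_short; ``fits`` maps gene_id to its
        :class:`BreakpointFit`.  Raises if no gene passes the filters.
    """
    if coverage_maps is None:
        coverage_maps = {
            s.sample_id: read_bedgraph(s.coverage_path, utrs) for s in samples
        }
    group_of = {s.sample_id: s.group for s in samples}
    factor_of = {s.sample_id: s.depth_factor for s in samples}

    if end_trim is None:
        end_trim = margin

    rows = []
    fits: dict[str, BreakpointFit] = {}
    for utr in utrs:
        L_full = len(utr)
        trim = min(end_trim, max(0, L_full - (2 * margin + 1)))
        covs = [
            UTRCoverage(utr.gene_id, s.sample_id,
                        coverage_maps[s.sample_id][utr][:L_full - trim],
                        factor_of[s.sample_id])
            for s in samples
        ]
        if not expression_filter(covs, min_mean_coverage):
            logger.info("%s: failed expression filter; skipped", utr.gene_id)
            continue
        try:
            fit = fit_breakpoint(covs, margin=margin, stride=stride)
        except ValueError as exc:
            logger.info("%s", exc)
            continue
        fits[utr.gene_id] = fit
        pduis = compute_pdui(fit)
        for i, sid in enumerate(fit.sample_ids):
            if sid not in pduis:
                continue
            rows.append({
                "gene_id": utr.gene_id,
                "sample_id": sid,
                "group": group_of[sid],
                "pdui": pduis[sid],
                "w_long": float(fit.w_long[i]),
                "w_short": float(fit.w_short[i]),
            })
    if not rows:
        raise ValueError("no genes passed filters")
    return pd.DataFrame(rows), fits


def write_pdui_table(
    table: pd.DataFrame,
    fits: dict[str, BreakpointFit],
    utrs: list[UTRRegion],
    path,
) -> None:
    """Write the wide PDUI TSV: coordinates, genomic breakpoint, per-sample PDUI."""
    utr_by_gene = {u.gene_id: u for u in utrs}
    sample_ids = sorted(table["sample_id"].unique())
    wide = table.pivot(index="gene_id", columns="sample_id", values="pdui")
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tutr_start\tutr_end\tbreakpoint_coord")
        for sid in sample_ids:
            fh.write(f"\tPDUI_{sid}")
        fh.write("\n")
        for gene_id in wide.index:
            u = utr_by_gene[gene_id]
            fit = fits[gene_id]
            if u.region.strand == "+":
                bp = u.region.start + fit.P
            else:
                bp = u.region.end - fit.P
            fh.write(
                f"{gene_id}\t{u.region.chrom}\t{u.region.strand}\t"
                f"{u.region.start}\t{u.region.end}\t{bp}"
            )
            for sid in sample_ids:
                v = wide.loc[gene_id, sid]
                fh.write("\tNA" if pd.isna(v) else f"\t{v:.4f}")
            fh.write("\n")
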