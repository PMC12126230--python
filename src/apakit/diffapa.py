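"""Differential APA calls: ΔPDUI, per-gene tests, BH-FDR, direction.

ΔPDUI for a gene is mean(PDUI in the perturbed group) − mean(PDUI in the
reference group); positive ΔPDUI means relatively more long-3'UTR
transcript under perturbation (3'UTR lengthening), negative means
shortening.  A gene is called significant when the (FDR-adjusted, by
default) p-value is below alpha AND |ΔPDUI| reaches the effect threshold —
the dual-threshold regime used throughout this style of analysis
(FDR adj P < 0.05, |ΔPDUI| >= 0.1; a raw-p regime is available for small
designs).

The per-gene test is Welch's two-sample t on per-sample PDUIs when both
groups are replicated; with a single replicate in either group it falls
back to a two-sided Fisher exact test on pooled long/short read mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class APACallConfig:
    """Thresholds for the significance call.

    delta_threshold is inclusive (|ΔPDUI| >= threshold); p_mode selects
    between BH-adjusted q (``fdr``) and raw p (``raw``).
    """

    delta_threshold: float = 0.1
    alpha: float = 0.05
    p_mode: str = "fdr"

    def __post_init__(self):
        if not 0 < self.delta_threshold < 1:
            raise ValueError("delta_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.p_mode not in ("fdr", "raw"):
            raise ValueError("p_mode must be 'fdr' or 'raw'")


def delta_pdui(
    table: pd.DataFrame, ref_group: str, alt_group: str
) -> pd.DataFrame:
    """Per-gene group means and ΔPDUI = mean(alt) − mean(ref).

    Genes with PDUI values in only one group are dropped (logged).
    Replicate averaging is an unweighted mean over samples.
    """
    for g in (ref_group, alt_group):
        if g not in set(table["group"]):
            raise ValueError(f"group {g!r} absent from PDUI table")
    sub = table[table["group"].isin([ref_group, alt_group])]
    rows = []
    for gene_id, gdf in sub.groupby("gene_id", sort=True):
        ref = gdf.loc[gdf["group"] == ref_group, "pdui"].to_numpy()
        alt = gdf.loc[gdf["group"] == alt_group, "pdui"].to_numpy()
        if len(ref) == 0 or len(alt) == 0:
            logger.info("%s: PDUI present in only one group; dropped", gene_id)
            continue
        rows.append({
            "gene_id": gene_id,
            "mean_pdui_ref": float(np.mean(ref)),
            "mean_pdui_alt": float(np.mean(alt)),
            "delta_pdui": float(np.mean(alt) - np.mean(ref)),
            "n_ref": len(ref),
            "n_alt": len(alt),
        })
    return pd.DataFrame(
        rows, columns=["gene_id", "mean_pdui_ref", "mean_pdui_alt",
                       "delta_pdui", "n_ref", "n_alt"],
    )


def test_gene(
    pduis_ref,
    pduis_alt,
    mass_ref: tuple[float, float] | None = None,
    mass_alt: tuple[float, float] | None = None,
) -> float:
    """Two-sided p-value for a PDUI difference between two groups.

    Replicated groups (>= 2 each): Welch two-sample t-test on the PDUIs;
    identical zero-variance groups give p = 1.  With a single replicate in
    either group, a Welch test is undefined, so a two-sided Fisher exact
    test is run on the 2x2 table of rounded long/short read mass
    (w · segment length) pooled per group — pass those masses as
    ``mass_ref`` / ``mass_alt`` = (long_mass, short_mass).
    """
    ref = np.asarray(pduis_ref, dtype=float)
    alt = np.asarray(pduis_alt, dtype=float)
    if len(ref) < 1 or len(alt) < 1:
        raise ValueError("each group needs >= 1 PDUI value")
    if len(ref) >= 2 and len(alt) >= 2:
        if np.ptp(ref) == 0 and np.ptp(alt) == 0:
            return 1.0 if ref[0] == alt[0] else 0.0
        p = stats.ttest_ind(ref, alt, equal_var=False).pvalue
        return float(p)
    if mass_ref is None or mass_alt is None:
        raise ValueError(
            "single-replicate groups need pooled long/short read mass for "
            "the Fisher fallback"
        )
    table = np.rint([
        [mass_ref[0], mass_ref[1]],
        [mass_alt[0], mass_alt[1]],
    ]).astype(int)
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved.

    q_(i) = min over ranks j >= i of p_(j) · m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.shape[0]
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify(results: pd.DataFrame, config: APACallConfig) -> pd.DataFrame:
    """Set q_value, direction and the significance flag on a results frame.

    ``results`` needs columns delta_pdui and p_value.  Direction is
    lengthened when ΔPDUI >= +threshold, shortened when <= −threshold, else
    none; significant requires both the (q or raw) p below alpha and the
    effect threshold.
    """
    out = results.copy()
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    crit_p = out["q_value"] if config.p_mode == "fdr" else out["p_value"]
    delta = out["delta_pdui"]
    out["direction"] = np.select(
        [delta >= config.delta_threshold, delta <= -config.delta_threshold],
        ["lengthened", "shortened"],
        default="none",
    )
    out["significant"] = (crit_p < config.alpha) & (
        delta.abs() >= config.delta_threshold
    )
    return out


def _percent(count: int, total: int) -> float:
    """Percentage rounded half-away-from-zero to 1 decimal (51.25 -> 51.3)."""
    if total == 0:
        raise ValueError("total must be > 0")
    pct = Decimal(count) / Decimal(total) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_direction(results: pd.DataFrame) -> dict:
    """Counts and percentages of lengthened/shortened among significant genes."""
    sig = results[results["significant"]]
    n = len(sig)
    if n == 0:
        raise ValueError("no significant genes to summarise")
    n_len = int((sig["direction"] == "lengthened").sum())
    n_short = int((sig["direction"] == "shortened").sum())
    return {
        "n_significant": n,
        "n_lengthened": n_len,
        "n_shortened": n_short,
        "pct_lengthened": _percent(n_len, n),
        "pct_shortened": _percent(n_short, n),
    }


def direction_percent(count: int, total: int) -> float:
    """Public helper: percentage with the package's reporting rounding."""
    return _percent(count, total)


def run_differential(
    table: pd.DataFrame,
    ref_group: str,
    alt_group: str,
    config: APACallConfig | None = None,
    fits=None,
) -> pd.DataFrame:
    """Full differential pipeline: ΔPDUI + per-gene test + BH + classify.

    ``fits`` (gene_id -> BreakpointFit) is only needed for single-replicate
    designs, where the Fisher fallback pools long/short read mass per group.
    """
    config = config or APACallConfig()
    deltas = delta_pdui(table, ref_group, alt_group)
    if deltas.empty:
        raise ValueError("no genes testable in both groups")
    pvals = []
    for _, row in deltas.iterrows():
        gdf = table[table["gene_id"] == row["gene_id"]]
        ref = gdf.loc[gdf["group"] == ref_group, "pdui"].to_numpy()
        alt = gdf.loc[gdf["group"] == alt_group, "pdui"].to_numpy()
        if len(ref) >= 2 and len(alt) >= 2:
            pvals.append(test_gene(ref, alt))
        else:
            if fits is None or row["gene_id"] not in fits:
                raise ValueError(
                    f"{row['gene_id']}: single-replicate design needs "
                    "breakpoint fits for the Fisher fallback"
                )
            fit = fits[row["gene_id"]]
            # read-mass proxy: w x segment length, pooled within each group
            seg_short, seg_long = fit.P, fit.utr_length - fit.P
            masses = {}
            for grp in (ref_group, alt_group):
                sids = set(gdf.loc[gdf["group"] == grp, "sample_id"])
                idx = [i for i, s in enumerate(fit.sample_ids) if s in sids]
                masses[grp] = (
                    sum(fit.w_long[i] for i in idx) * seg_long,
                    sum(fit.w_short[i] for i in idx) * seg_short,
                )
            pvals.append(
                test_gene(ref, alt, masses[ref_group], masses[alt_group])
            )
    deltas["p_value"] = pvals
    return classify(deltas, config)


def write_apa_results(results: pd.DataFrame, path) -> None:
    """Volcano-ready APA results TSV with fixed column order/formatting."""
    cols = ["gene_id", "mean_pdui_ref", "mean_pdui_alt", "delta_pdui",
            "p_value", "q_value", "direction", "significant"]
    out = results[cols].copy()
    for c in ("mean_pdui_ref", "mean_pdui_alt", "delta_pdui"):
        out[c] = out[c].map(lambda v: f"{v:.4f}")
    for c in ("p_value", "q_value"):
        out[c] = out[c].map(lambda v: f"{v:.6g}")
    out["significant"] = out["significant"].astype(int)
    out.to_csv(path, sep="\t", index=False)
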