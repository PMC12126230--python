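"""Cross-referencing APA calls with binding sites and gene sets.

Three related capabilities:

* assign each APA gene a binding category — a site inside its 3'UTR
  (``utr3``), elsewhere in the gene body (``other_region``), or ``none`` —
  and summarise the bound fractions;
* the signed distance from a binding site to a poly(A) site, with the
  75-nt proximity flag (binding within 75 nt of a PAS is the repressive
  zone for position-dependent RBP regulation);
* exact hypergeometric upper-tail tests for gene-set overlaps (Venn
  significance) and generic over-representation against GMT collections.

The test universe is always supplied explicitly (e.g. all genes passing
the expression filter): defaulting it silently would fabricate
significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from intervaltree import IntervalTree
from scipy import stats

from .annotation import GenomicInterval, ParseError, UTRRegion
from .diffapa import bh_fdr

logger = logging.getLogger(__name__)

PAS_PROXIMAL_NT = 75


@dataclass(frozen=True)
class BindingSite:
    """One RBP binding-site interval (an eCLIP-style peak), optional score."""

    interval: GenomicInterval
    score: float | None = None
    name: str = "."


@dataclass(frozen=True)
class BindingAnnotation:
    """Binding category for one gene, plus PAS-proximity of the nearest site.

    ``min_distance_to_pas`` is signed: negative = transcript-5' (upstream)
    of the PAS; None when the gene has no 3'UTR site.
    """

    gene_id: str
    category: str  # utr3 | other_region | none
    min_distance_to_pas: int | None = None
    proximal_to_pas: bool = False


@dataclass(frozen=True)
class OverlapResult:
    """A hypergeometric overlap test between two gene sets in a universe."""

    size_a: int
    size_b: int
    overlap: int
    universe: int
    p_value: float

    def __post_init__(self):
        if not (self.overlap <= min(self.size_a, self.size_b) <= self.universe):
            raise ValueError("inconsistent overlap counts")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value out of (0, 1]")


def read_bed6(path) -> list[BindingSite]:
    """Read binding sites from a BED6 (or BED4+) file."""
    sites = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED fields")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "+"
            score = None
            if len(f) >= 5 and f[4] not in (".", ""):
                score = float(f[4])
            name = f[3] if len(f) >= 4 else "."
            sites.append(
                BindingSite(GenomicInterval(f[0], int(f[1]), int(f[2]), strand),
                            score, name)
            )
    return sites


def read_gmt(path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set file: name, description, members per line."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs name, description, members"
                )
            members = frozenset(g for g in f[2:] if g)
            if not members:
                raise ParseError(f"{path}: line {lineno}: empty gene set {f[0]!r}")
            sets[f[0]] = members
    return sets


def pas_distance(
    site: BindingSite, pas_coord: int, strand: str
) -> tuple[int, bool]:
    """Signed nearest-edge distance (nt) from a binding site to a PAS base.

    0 when the site overlaps the PAS base; negative when the site lies
    transcript-5' (upstream) of the PAS.  The proximal flag is
    |distance| <= 75 nt — the repressive window for PAS-proximal binding.
    """
    iv = site.interval
    if iv.start <= pas_coord < iv.end:
        return 0, True
    if strand == "+":
        if iv.end <= pas_coord:       # site upstream (5') of the PAS
            d = -(pas_coord - (iv.end - 1))
        else:                          # site downstream
            d = iv.start - pas_coord
    else:
        if iv.start > pas_coord:      # genomically right = transcript-5'
            d = -(iv.start - pas_coord)
        else:
            d = pas_coord - (iv.end - 1)
    return d, abs(d) <= PAS_PROXIMAL_NT


def intersect_binding(
    apa_genes,
    utrs: list[UTRRegion],
    gene_bodies: dict[str, GenomicInterval],
    sites: list[BindingSite],
) -> tuple[list[BindingAnnotation], dict]:
    """Assign each APA gene its most specific binding category + summary.

    Overlap means >= 1 shared base; ``utr3`` beats ``other_region`` beats
    ``none``.  Sites on chromosomes absent from the annotation are ignored
    with a warning.  The summary reports the percent of APA genes bound
    anywhere and percent bound in the 3'UTR (rounded half-away-from-zero
    to 1 decimal).
    """
    apa_genes = list(apa_genes)
    utr_by_gene = {u.gene_id: u for u in utrs}
    known_chroms = {u.region.chrom for u in utrs} | {
        iv.chrom for iv in gene_bodies.values()
    }
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        if s.interval.chrom not in known_chroms:
            logger.warning("binding site on unknown chromosome %s ignored",
                           s.interval.chrom)
            continue
        trees.setdefault(s.interval.chrom, IntervalTree()).addi(
            s.interval.start, s.interval.end, s
        )

    annotations = []
    for gene in apa_genes:
        utr = utr_by_gene.get(gene)
        body = gene_bodies.get(gene)
        category = "none"
        min_dist: int | None = None
        proximal = False
        if utr is not None:
            tree = trees.get(utr.region.chrom)
            hits = (
                sorted(tree.overlap(utr.region.start, utr.region.end),
                       key=lambda h: (h.begin, h.end))
                if tree else []
            )
            if hits:
                category = "utr3"
                dists = [
                    pas_distance(h.data, _pas_base(utr), utr.region.strand)
                    for h in hits
                ]
                min_dist, proximal = min(dists, key=lambda dp: abs(dp[0]))
        if category == "none" and body is not None:
            tree = trees.get(body.chrom)
            if tree and tree.overlap(body.start, body.end):
                category = "other_region"
        annotations.append(
            BindingAnnotation(gene, category, min_dist, proximal)
        )

    n = len(apa_genes)
    n_bound = sum(a.category != "none" for a in annotations)
    n_utr3 = sum(a.category == "utr3" for a in annotations)
    summary = {
        "n_genes": n,
        "n_bound": n_bound,
        "n_utr3": n_utr3,
        "pct_bound": _pct(n_bound, n),
        "pct_utr3": _pct(n_utr3, n),
    }
    return annotations, summary


def _pas_base(utr: UTRRegion) -> int:
    """Genomic coordinate of the distal PAS base (last transcribed base)."""
    return utr.distal_end - 1 if utr.region.strand == "+" else utr.distal_end


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    pct = Decimal(count) / Decimal(total) * 100
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def overlap_test(set_a, set_b, universe: int) -> OverlapResult:
    """Exact hypergeometric upper-tail test for the overlap of two gene sets.

    p = P[X >= |A∩B|] for X ~ Hypergeometric(universe, |A|, |B|): the
    chance of at least the observed overlap when B is drawn at random from
    the universe.  Computed with scipy's log-space survival function.
    """
    a, b = frozenset(set_a), frozenset(set_b)
    if universe < len(a | b):
        raise ValueError(
            f"universe {universe} smaller than |A ∪ B| = {len(a | b)}"
        )
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe, len(a), len(b)))
    p = min(max(p, 5e-324), 1.0)  # upper tail is strictly positive
    return OverlapResult(len(a), len(b), k, universe, p)


def gene_set_enrichment(
    query,
    collections: dict[str, frozenset[str]],
    universe,
) -> "pd.DataFrame":
    """Hypergeometric over-representation of a query set in GMT collections.

    ``universe`` may be an integer count or an explicit gene set (then the
    query and every collection are intersected with it first).  One
    upper-tail test per set, BH across sets, sorted by q then p.
    """
    import pandas as pd

    query = frozenset(query)
    if not query:
        raise ValueError("empty query gene set")
    if isinstance(universe, int):
        n_universe = universe
        clip = None
    else:
        clip = frozenset(universe)
        n_universe = len(clip)
        query = query & clip

    rows = []
    for name, members in collections.items():
        mem = members if clip is None else members & clip
        if not mem:
            continue
        res = overlap_test(query, mem, n_universe)
        rows.append({
            "set_name": name,
            "set_size": res.size_b,
            "query_size": res.size_a,
            "overlap": res.overlap,
            "universe": n_universe,
            "p_value": res.p_value,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    return df.sort_values(["q_value", "p_value", "set_name"]).reset_index(drop=True)
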