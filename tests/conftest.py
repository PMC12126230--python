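import numpy as np
import pytest

from apakit.annotation import GenomicInterval, UTRRegion
from apakit.coverage import SampleInfo, UTRCoverage


@pytest.fixture
def plus_utr():
    """A 300-nt + strand UTR at chr1:700-1000."""
    return UTRRegion("geneA", GenomicInterval("chr1", 700, 1000, "+"), 1000, ("txA",))


@pytest.fixture
def minus_utr():
    """A 200-nt − strand UTR at chr1:100-300 (distal end = 100)."""
    return UTRRegion("geneB", GenomicInterval("chr1", 100, 300, "-"), 100, ("txB",))


@pytest.fixture
def bed12_file(tmp_path):
    """Small BED12 with one + and one − strand transcript."""
    path = tmp_path / "models.bed12"
    path.write_text(
        "chr1\t100\t1000\tgeneA|txA\t0\t+\t100\t700\t0\t1\t900,\t0,\n"
        "chr2\t100\t1000\tgeneB|txB\t0\t-\t300\t1000\t0\t1\t900,\t0,\n"
    )
    return str(path)


def step_coverage(gene_id, sample_id, a, b, P, L, depth_factor=1.0):
    """Noiseless two-segment coverage: a+b on [0, P), b on [P, L)."""
    values = np.full(L, float(b))
    values[:P] += a
    return UTRCoverage(gene_id, sample_id, values, depth_factor)


def brute_force_fit(arrays, margin, stride=1):
    """Independent exhaustive breakpoint search (the oracle).

    Evaluates every candidate P directly from segment means and explicit
    residuals; ties broken to the smallest P by strict improvement.
    """
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    L = arrays[0].shape[0]
    best = None
    for P in range(margin, L - margin + 1, stride):
        total = 0.0
        wl_list, ws_list = [], []
        for a in arrays:
            wl = a[P:].mean()
            ws = max(0.0, a[:P].mean() - wl)
            pred = np.empty(L)
            pred[:P] = ws + wl
            pred[P:] = wl
            total += float(((a - pred) ** 2).sum())
            wl_list.append(wl)
            ws_list.append(ws)
        if best is None or total < best[0]:
            best = (total, P, wl_list, ws_list)
    return best  # (rss, P, w_long, w_short)


def make_samples(n_per_group, groups=("control", "knockdown"), library=1_000_000):
    samples = []
    for g in groups:
        for i in range(1, n_per_group + 1):
            samples.append(SampleInfo(f"{g}_{i}", g, library, f"<memory:{g}_{i}>"))
    return samples
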