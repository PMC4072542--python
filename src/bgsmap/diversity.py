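"""Silent nucleotide diversity and normalized Tajima's D from masked
population alignments.

Input is an N-masked multiple alignment (one row per sampled haplotype;
heterozygous, low-quality or admixed bases already replaced by N upstream).
Per-site pairwise diversity uses only non-N alleles, requires a minimum
number of covered sequences (10 by default), and applies the n/(n-1)
sample-size correction with the site's own non-N count.  Silent diversity
pi_sil averages per-site values over intronic + intergenic sites of a
window; windows with too few analyzable silent sites (<= 500 for 1-kb,
<= 1,000 for 10-kb windows) are flagged excluded.

Tajima's D is reported normalized by the magnitude of its theoretical
minimum for the same sample size and number of segregating sites (D with
every variant a singleton), so D/|Dmin| is -1 when all variants are
singletons and positive when intermediate frequencies are in excess.  Sites
containing any N are excluded from the D computation so that the sample
size is constant within a window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import INTERGENIC, INTRON

__all__ = [
    "WindowDiversity",
    "alignment_to_matrix",
    "per_site_pi",
    "site_pi_profile",
    "window_diversity",
    "tajima_d",
    "tajima_d_normalized",
]

MIN_COVERAGE_DEFAULT = 10

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class WindowDiversity:
    """Diversity summaries for one window."""

    chromosome: str
    start: int
    end: int
    pi_sil: float
    pi_intron: float
    pi_intergenic: float
    n_silent_sites: int
    n_seg_sites: int
    tajima_d_norm: float
    included: bool


def alignment_to_matrix(records) -> np.ndarray:
    """Byte matrix (n_seq x L, uint8 of ACGTN) from SeqRecords or strings."""
    rows = []
    for rec in records:
        seq = str(getattr(rec, "seq", rec)).upper()
        rows.append(np.frombuffer(seq.encode(), dtype=np.uint8))
    mat = np.vstack(rows)
    if len({r.size for r in rows}) != 1:
        raise ValueError("alignment rows have unequal length")
    return mat


def _allele_counts(matrix: np.ndarray) -> np.ndarray:
    """(4 x L) counts of A, C, G, T per column."""
    return np.stack([(matrix == b).sum(axis=0) for b in _BASES])


def per_site_pi(alleles, min_coverage: int = MIN_COVERAGE_DEFAULT) -> float:
    """Unbiased pairwise diversity at one site, or NaN when fewer than
    ``min_coverage`` non-N alleles are present.

    Equals the average number of differences over all pairs of non-N alleles:
    (m/(m-1)) * (1 - sum_a p_a^2) with m the non-N count.
    """
    arr = np.frombuffer("".join(alleles).upper().encode(), dtype=np.uint8)
    counts = np.array([(arr == b).sum() for b in _BASES], dtype=float)
    m = counts.sum()
    if m < min_coverage or m < 2:
        return float("nan")
    p = counts / m
    return float(m / (m - 1.0) * (1.0 - np.sum(p**2)))


def site_pi_profile(
    matrix: np.ndarray, min_coverage: int = MIN_COVERAGE_DEFAULT
) -> np.ndarray:
    """Vectorized per-site pi over all columns of an alignment matrix
    (NaN where coverage is insufficient)."""
    counts = _allele_counts(matrix).astype(float)
    m = counts.sum(axis=0)
    ok = (m >= max(min_coverage, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p2 = np.where(m > 0, (counts**2).sum(axis=0) / np.maximum(m, 1) ** 2, 1.0)
        pi = m / np.maximum(m - 1.0, 1.0) * (1.0 - p2)
    return np.where(ok, pi, np.nan)


def _min_silent_sites(window_size: int) -> int:
    if window_size <= 1000:
        return 500
    if window_size <= 10_000:
        return 1000
    return 0


def window_diversity(
    matrix: np.ndarray,
    labels: np.ndarray,
    *,
    chromosome: str = "chr1",
    window_size: int = 1000,
    min_coverage: int = MIN_COVERAGE_DEFAULT,
    min_silent_sites: int | None = None,
) -> pd.DataFrame:
    """Per-window silent diversity and normalized Tajima's D.

    ``labels`` are per-bp site-class codes aligned to the alignment columns;
    silent sites are intron plus intergenic.  Windows with
    <= ``min_silent_sites`` analyzable silent sites (threshold by window size
    when None: 500 for 1-kb, 1,000 for 10-kb, none for larger) are flagged
    ``included = False`` with summaries still reported where computable.
    """
    n_seq, length = matrix.shape
    if len(labels) != length:
        raise ValueError("labels and alignment length differ")
    if min_silent_sites is None:
        min_silent_sites = _min_silent_sites(window_size)
    pi = site_pi_profile(matrix, min_coverage)
    silent = (labels == INTRON) | (labels == INTERGENIC)
    intron = labels == INTRON
    rows = []
    for start in range(0, length, window_size):
        end = min(start + window_size, length)
        sl = slice(start, end)
        sil_mask = silent[sl]
        pi_win = pi[sl]
        analyzable = sil_mask & ~np.isnan(pi_win)
        n_sil = int(analyzable.sum())
        pi_sil = float(np.mean(pi_win[analyzable])) if n_sil else float("nan")
        intr = analyzable & intron[sl]
        interg = analyzable & ~intron[sl]
        pi_intron = float(np.mean(pi_win[intr])) if intr.any() else float("nan")
        pi_interg = float(np.mean(pi_win[interg])) if interg.any() else float("nan")
        d_norm, n_seg = tajima_d_normalized(
            matrix[:, sl][:, sil_mask], return_n_seg=True
        )
        rows.append(
            WindowDiversity(
                chromosome=chromosome,
                start=start,
                end=end,
                pi_sil=pi_sil,
                pi_intron=pi_intron,
                pi_intergenic=pi_interg,
                n_silent_sites=n_sil,
                n_seg_sites=n_seg,
                tajima_d_norm=d_norm,
                included=n_sil > min_silent_sites,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def _tajima_constants(n: int):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajima_d(n: int, n_seg: int, mean_pairwise_diff: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences (per window, unnormalized)."""
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    if n_seg < 1:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * n_seg + e2 * n_seg * (n_seg - 1)
    return (mean_pairwise_diff - n_seg / a1) / np.sqrt(var)


def tajima_d_normalized(window_matrix: np.ndarray, return_n_seg: bool = False):
    """D/|Dmin| for an alignment window (sign of D preserved).

    Dmin is D for the same n and S with every variant a singleton, the most
    negative configuration; an all-singleton window therefore scores -1.
    Columns containing any N are excluded; returns NaN with no segregating
    sites.
    """
    n, _ = window_matrix.shape
    complete = ~np.any(window_matrix == ord("N"), axis=0)
    sub = window_matrix[:, complete]
    counts = _allele_counts(sub)
    present = counts > 0
    seg = present.sum(axis=0) > 1
    n_seg = int(seg.sum())
    if n_seg == 0 or n < 4:
        return (float("nan"), n_seg) if return_n_seg else float("nan")
    m = counts[:, seg].astype(float)
    tot = m.sum(axis=0)
    # mean pairwise differences summed over segregating sites
    k = float(np.sum(tot / (tot - 1.0) * (1.0 - (m**2).sum(axis=0) / tot**2)))
    d = tajima_d(n, n_seg, k)
    k_min = 2.0 * n_seg / n  # all singletons: per site 2/n after correction
    d_min = tajima_d(n, n_seg, k_min)
    val = float(d / abs(d_min))
    return (val, n_seg) if return_n_seg else val
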