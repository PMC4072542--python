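"""Synthetic genomes, polymorphism and gene tables for pipeline testing.

The generator emulates the statistical structure the analysis assumes, not
population-genetic dynamics: a compact genome with one 4-kb gene per 10-kb
unit (1,000 bp 5'UTR, 300 + 600 + 600 bp coding exons separated by 1,000 and
200 bp introns, a 300 bp 3'UTR, intergenic sequence filling the rest), a
windowed crossover map, and an N-masked haplotype alignment in which the
expected silent diversity of a window equals theta0 x B (its background-
selection baseline) times any planted multiplier.  Planted sweep regions
(multiplier < 1) carry singleton-tilted site frequencies; planted balanced
regions (multiplier > 1) carry intermediate-frequency tilts, so both the
residual scan and the Tajima's D concordance have known signs.

Variant placement draws, per silent site, a segregating configuration from a
tilted neutral site-frequency spectrum scaled so the unbiased pairwise
estimator is exactly calibrated: E[pi_site] = theta0 * B * multiplier.
Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .annotation import INTERGENIC, INTRON
from .bgs import BLandscape
from .recmap import RecombinationMap, SEX_FACTOR_AUTOSOME

__all__ = [
    "SyntheticSpec",
    "PlantedFeature",
    "GenomeFiles",
    "generate_genome",
    "generate_polymorphism",
    "generate_gene_table",
    "GENE_GEOMETRY",
]

#: (feature kind, length bp) of the standard gene, 5' to 3'.
GENE_GEOMETRY = (
    ("five_prime_UTR", 1000),
    ("CDS", 300),
    ("intron", 1000),
    ("CDS", 600),
    ("intron", 200),
    ("CDS", 600),
    ("three_prime_UTR", 300),
)
GENE_LENGTH = sum(l for _, l in GENE_GEOMETRY)

_PROFILES = {
    # cM/Mb per female meiosis, cycling over 100-kb windows.  "chromosome"
    # emulates an arm with reduced sub-telomeric/sub-centromeric crossover
    # rates at the ends and variable rates (~0.3-4 cM/Mb, median ~1.8, the
    # range typical of experimentally mapped *Drosophila* arms) in between.
    "chromosome": (0.3, 1.5, 3.0, 4.0, 2.0, 1.0, 2.5, 3.5, 1.2, 0.4),
    "constant": (2.0,),
    "piecewise": (0.5, 1.5, 3.0, 2.0, 1.0),
    "hot-cold": (0.05, 3.5),
}


class SyntheticSpecError(ValueError):
    """Inconsistent synthetic-data specification."""


@dataclass(frozen=True)
class PlantedFeature:
    """A diversity anomaly spanning ``span`` bp from ``start``."""

    start: int
    span: int
    kind: str  # "sweep" | "balanced"
    multiplier: float

    def __post_init__(self) -> None:
        if self.kind not in ("sweep", "balanced"):
            raise SyntheticSpecError("kind must be 'sweep' or 'balanced'")
        if self.multiplier <= 0 or self.span <= 0:
            raise SyntheticSpecError("multiplier and span must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic chromosome."""

    seed: int = 0
    chromosome: str = "chrS"
    chromosome_length: int = 1_000_000
    n_genes: int = 100
    gene_spacing: int = 10_000
    crossover_profile: str = "chromosome"
    recmap_window: int = 100_000
    n_tes: int = 10
    te_length: int = 500
    theta0: float = 0.01
    n_haplotypes: int = 15
    mask_rate: float = 0.02
    planted_features: tuple = ()

    def __post_init__(self) -> None:
        if self.theta0 < 0 or self.chromosome_length <= 0:
            raise SyntheticSpecError("theta0 >= 0 and positive length required")
        if self.n_genes * self.gene_spacing > self.chromosome_length:
            raise SyntheticSpecError("gene layout exceeds chromosome length")
        if self.gene_spacing < GENE_LENGTH and self.n_genes > 0:
            raise SyntheticSpecError("gene_spacing shorter than the gene model")
        for f in self.planted_features:
            if f.start < 0 or f.start + f.span > self.chromosome_length:
                raise SyntheticSpecError("planted feature outside chromosome")
            if self.theta0 * f.multiplier > 0.5:
                raise SyntheticSpecError(
                    "theta0 x multiplier exceeds the per-bp diversity bound 0.5"
                )


class GenomeFiles(NamedTuple):
    gff3: Path
    te_bed: Path
    recmap_tsv: Path


def crossover_rates(spec: SyntheticSpec) -> np.ndarray:
    """Per-100-kb crossover rates (cM/Mb) for the chromosome."""
    n_win = -(-spec.chromosome_length // spec.recmap_window)
    if isinstance(spec.crossover_profile, str):
        if spec.crossover_profile not in _PROFILES:
            raise SyntheticSpecError(
                f"unknown crossover profile {spec.crossover_profile!r}"
            )
        pattern = np.array(_PROFILES[spec.crossover_profile])
        return np.resize(pattern, n_win)
    rates = np.asarray(spec.crossover_profile, dtype=float)
    if len(rates) != n_win:
        raise SyntheticSpecError("explicit crossover profile has wrong length")
    return rates


def build_recmap(spec: SyntheticSpec, sex_factor: float = SEX_FACTOR_AUTOSOME) -> RecombinationMap:
    rates = crossover_rates(spec)
    n_win = len(rates)
    starts = np.arange(n_win, dtype=np.int64) * spec.recmap_window
    ends = np.minimum(starts + spec.recmap_window, spec.chromosome_length)
    return RecombinationMap(
        spec.chromosome, starts, ends, rates, sex_factor=sex_factor
    )


def _gene_features(gene_index: int, start: int, chromosome: str) -> list[str]:
    """GFF3 lines for one plus-strand gene starting at ``start`` (0-based)."""
    gid = f"gene{gene_index:04d}"
    lines = []
    pos = start
    exons = []  # merged exon blocks: UTR+CDS runs
    blocks = []
    for kind, length in GENE_GEOMETRY:
        blocks.append((kind, pos, pos + length))
        pos = pos + length
    gene_end = pos
    # exon blocks = maximal runs of non-intron features
    run_start = None
    for kind, s, e in blocks + [("intron", pos, pos)]:
        if kind == "intron":
            if run_start is not None:
                exons.append((run_start, prev_end))
                run_start = None
        else:
            if run_start is None:
                run_start = s
            prev_end = e

    def row(ftype, s, e, attr):
        # GFF3 is 1-based closed
        return f"{chromosome}\tbgsmap\t{ftype}\t{s + 1}\t{e}\t.\t+\t.\t{attr}"

    lines.append(row("gene", start, gene_end, f"ID={gid}"))
    lines.append(row("mRNA", start, gene_end, f"ID={gid}.t1;Parent={gid}"))
    for i, (s, e) in enumerate(exons, 1):
        lines.append(row("exon", s, e, f"ID={gid}.e{i};Parent={gid}.t1"))
    for kind, s, e in blocks:
        if kind == "intron":
            continue
        lines.append(row(kind, s, e, f"ID={gid}.{kind}.{s};Parent={gid}.t1"))
    return lines


def generate_genome(spec: SyntheticSpec, outdir) -> GenomeFiles:
    """Write the GFF3 annotation, TE BED track and crossover-map TSV.

    Genes sit at the start of every ``gene_spacing`` unit; TEs are placed
    deterministically (seeded) inside intergenic spacers so they never
    overlap gene models.  Output is byte-identical for identical specs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    gff_lines = ["##gff-version 3"]
    for i in range(spec.n_genes):
        gff_lines.append(f"###")
        gff_lines.extend(_gene_features(i, i * spec.gene_spacing, spec.chromosome))
    gff3 = outdir / "annotation.gff3"
    gff3.write_text("\n".join(gff_lines) + "\n")

    # TEs in intergenic spacers (after the gene, before the next unit)
    te_rows = []
    if spec.n_genes > 0 and spec.n_tes > 0:
        units = rng.choice(spec.n_genes, size=min(spec.n_tes, spec.n_genes), replace=False)
        for u in sorted(units):
            lo = u * spec.gene_spacing + GENE_LENGTH + 100
            hi = (u + 1) * spec.gene_spacing - spec.te_length - 100
            if hi <= lo:
                continue
            s = int(rng.integers(lo, hi))
            te_rows.append((spec.chromosome, s, s + spec.te_length))
    te_bed = outdir / "tes.bed"
    te_bed.write_text(
        "".join(f"{c}\t{s}\t{e}\n" for c, s, e in te_rows)
    )

    rates = crossover_rates(spec)
    recmap_tsv = outdir / "recmap.tsv"
    with open(recmap_tsv, "w") as fh:
        fh.write("chrom\tstart\tend\tc_cM_per_Mb\n")
        for i, rate in enumerate(rates):
            s = i * spec.recmap_window
            e = min(s + spec.recmap_window, spec.chromosome_length)
            fh.write(f"{spec.chromosome}\t{s}\t{e}\t{rate:.17g}\n")
    return GenomeFiles(gff3=gff3, te_bed=te_bed, recmap_tsv=recmap_tsv)


def _sfs_weights(kind: str, n: int) -> np.ndarray:
    k = np.arange(1, n)
    if kind == "neutral":
        w = 1.0 / k
    elif kind == "sweep":
        w = 1.0 / k**2.5  # singleton-tilted
    elif kind == "balanced":
        w = np.exp(-0.5 * ((k - n / 2.0) / (n / 6.0)) ** 2)  # intermediate-tilted
    else:
        raise SyntheticSpecError(f"unknown SFS kind {kind!r}")
    return w / w.sum()


def _het(k: np.ndarray, n: int) -> np.ndarray:
    """Expected value of the unbiased per-site pi estimator given k derived
    copies among n sampled haplotypes."""
    return 2.0 * k * (n - k) / (n * (n - 1.0))


def generate_polymorphism(
    landscape: BLandscape,
    spec: SyntheticSpec,
    labels: np.ndarray,
    seed_offset: int = 1,
) -> np.ndarray:
    """N-masked haplotype matrix whose window diversity is calibrated to B.

    Variants are placed only at silent (intron/intergenic) sites; every
    other base is monomorphic.  Per silent site the probability of
    segregating and the derived-allele count are drawn from a (possibly
    tilted) SFS scaled so E[pi_site] = theta0 * B(window) * multiplier.
    Bases are then masked to N independently at ``mask_rate``.
    """
    n = spec.n_haplotypes
    length = spec.chromosome_length
    if len(labels) != length:
        raise SyntheticSpecError("labels length does not match chromosome")
    rng = np.random.default_rng((spec.seed, seed_offset))
    mult = np.ones(length)
    kind = np.zeros(length, dtype=np.uint8)  # 0 neutral, 1 sweep, 2 balanced
    for f in spec.planted_features:
        mult[f.start : f.start + f.span] = f.multiplier
        kind[f.start : f.start + f.span] = 1 if f.kind == "sweep" else 2
    b_per_bp = landscape.b[
        np.minimum(np.arange(length) // landscape.window_size, len(landscape.b) - 1)
    ]
    theta = spec.theta0 * b_per_bp * mult

    silent = (labels == INTRON) | (labels == INTERGENIC)
    sil_idx = np.flatnonzero(silent)

    matrix = np.full((n, length), ord("A"), dtype=np.uint8)
    kinds = ("neutral", "sweep", "balanced")
    weights = {kn: _sfs_weights(kn, n) for kn in kinds}
    hbar = {kn: float(weights[kn] @ _het(np.arange(1, n), n)) for kn in kinds}

    u = rng.random(sil_idx.size)
    lam = np.empty(sil_idx.size)
    site_kind = kind[sil_idx]
    for code, kn in enumerate(kinds):
        sel = site_kind == code
        lam[sel] = theta[sil_idx[sel]] / hbar[kn]
    if np.any(lam > 1):
        raise SyntheticSpecError("theta too high for the SFS scaling (lambda > 1)")
    seg_sites = sil_idx[u < lam]
    seg_kind = kind[seg_sites]
    for code, kn in enumerate(kinds):
        sites = seg_sites[seg_kind == code]
        if sites.size == 0:
            continue
        ks = rng.choice(np.arange(1, n), size=sites.size, p=weights[kn])
        for pos, k in zip(sites, ks):
            carriers = rng.choice(n, size=int(k), replace=False)
            matrix[carriers, pos] = ord("C")

    if spec.mask_rate > 0:
        mask = rng.random(matrix.shape) < spec.mask_rate
        matrix[mask] = ord("N")
    return matrix


def generate_gene_table(
    landscape: BLandscape,
    spec: SyntheticSpec,
    effect_size: float,
    n_genes: int | None = None,
    violation_rate: float = 0.0,
    slope_ds: float = 0.5,
    omega_baseline: float = 0.15,
    noise_sd: float = 0.02,
    seed_offset: int = 2,
) -> pd.DataFrame:
    """Per-gene molecular-evolution table with a planted omega_R ~ -B effect.

    omega = baseline + slope_ds * dS - effect_size * B(midpoint) + noise, so
    after regressing out dS the residual omega_R anticorrelates with B with
    strength ``effect_size``.  A ``violation_rate`` fraction of genes is
    planted with one filter-rule violation each (column
    ``planted_violation``).  Deterministic given the spec seed.
    """
    if effect_size < 0:
        raise SyntheticSpecError("effect_size must be nonnegative")
    rng = np.random.default_rng((spec.seed, seed_offset))
    if n_genes is None:
        n_genes = spec.n_genes
        midpoints = np.arange(n_genes) * spec.gene_spacing + GENE_LENGTH // 2
    else:
        midpoints = rng.integers(0, spec.chromosome_length, size=n_genes)
    win = np.minimum(midpoints // landscape.window_size, len(landscape.b) - 1)
    b = landscape.b[win.astype(int)]
    ds = rng.gamma(shape=4.0, scale=0.025, size=n_genes)
    omega = (
        omega_baseline
        + slope_ds * ds
        - effect_size * b
        + rng.normal(0.0, noise_sd, size=n_genes)
    )
    omega = np.clip(omega, 1e-4, None)
    df = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": spec.chromosome,
            "chrom_group": "autosome",
            "midpoint": midpoints,
            "cds_length_bp": 1500,
            "aligned_aa": 450,
            "dN": omega * ds,
            "dS": ds,
            "omega": omega,
            "premature_stop": False,
            "positive_selection_q": np.round(rng.uniform(0.05, 1.0, size=n_genes), 6),
            "planted_violation": False,
        }
    )
    if violation_rate > 0:
        n_bad = int(round(violation_rate * n_genes))
        bad = rng.choice(n_genes, size=n_bad, replace=False)
        rules = rng.integers(0, 5, size=n_bad)
        for idx, rule in zip(bad, rules):
            if rule == 0:
                df.loc[idx, "cds_length_bp"] = 300
            elif rule == 1:
                df.loc[idx, "aligned_aa"] = 50
            elif rule == 2:
                df.loc[idx, "premature_stop"] = True
            elif rule == 3:
                df.loc[idx, "positive_selection_q"] = 0.001
            else:
                df.loc[idx, "omega"] = 0.8 + float(rng.random()) * 0.2
        df.loc[bad, "planted_violation"] = True
    return df
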