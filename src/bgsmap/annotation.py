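"""Site classification and per-window constrained-site counts.

Every base of a chromosome is assigned exactly one of five labels:

* ``coding``      — inside a CDS of any isoform;
* ``utr``         — inside an annotated 5'/3' UTR (and not coding);
* ``intron``      — inside a gene model but overlapping no other annotation
                    (no exon of any isoform, no UTR, no TE/repeat);
* ``intergenic``  — between gene models, outside TEs/repeats;
* ``masked``      — TE/repeat bases, plus exonic bases that are neither CDS
                    nor UTR (ambiguous under overlapping isoforms; excluded
                    from every downstream count).

Masked takes precedence over all genic labels; coding beats UTR beats intron.

The BGS models need, per 1-kb window, the number of sites at which a mutation
is deleterious.  Following the constraint-fraction approach, the count of
nonsynonymous sites under selection is Naa = coding_bp × 0.75 × cs_nonsyn
(0.75 = fraction of coding positions that change the protein, cs_nonsyn ~0.92
the constrained fraction), while UTR, intron and intergenic bases contribute
with their own constrained fractions (0.81, 0.56, ~0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteClassConfig",
    "SelectedSiteTrack",
    "LABELS",
    "classify_sites",
    "count_selected_sites",
    "per_bp_selected_weights",
    "read_bed_intervals",
]

# label codes (uint8)
INTERGENIC, INTRON, UTR, CODING, MASKED = 0, 1, 2, 3, 4
LABELS = {
    "intergenic": INTERGENIC,
    "intron": INTRON,
    "utr": UTR,
    "coding": CODING,
    "masked": MASKED,
}

_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}


class AnnotationError(ValueError):
    """Inconsistent gene models or unusable annotation input."""


@dataclass(frozen=True)
class SiteClassConfig:
    """Constrained-site fractions per class (defaults for *D. melanogaster*)."""

    cs_nonsyn: float = 0.92
    cs_utr: float = 0.81
    cs_intron: float = 0.56
    cs_intergenic: float = 0.5
    coding_nonsyn_fraction: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "cs_nonsyn",
            "cs_utr",
            "cs_intron",
            "cs_intergenic",
            "coding_nonsyn_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AnnotationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SelectedSiteTrack:
    """Per-1-kb counts of BGS-relevant (constrained) sites for one chromosome.

    ``naa``, ``nutr_ss`` and ``nnc_ss`` are the nonsynonymous, untranslated-
    genic (UTR + intron) and intergenic sites possibly under strong selection
    per window; ``n_silent_candidate`` counts intron+intergenic bases usable
    for diversity estimation.
    """

    chromosome: str
    window_size: int
    window_starts: np.ndarray
    coding_bp: np.ndarray
    utr_bp: np.ndarray
    intron_bp: np.ndarray
    intergenic_bp: np.ndarray
    masked_bp: np.ndarray
    config: SiteClassConfig = field(default_factory=SiteClassConfig)
    #: optional per-bp class weight arrays ({"aa","utr","nc"} -> float array
    #: over the chromosome); used for exact near-field integration in the B
    #: computation when present.
    per_bp_weights: dict | None = field(default=None, repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_starts + self.window_size // 2

    @property
    def naa(self) -> np.ndarray:
        return self.coding_bp * self.config.coding_nonsyn_fraction * self.config.cs_nonsyn

    @property
    def nutr_ss(self) -> np.ndarray:
        return self.utr_bp * self.config.cs_utr + self.intron_bp * self.config.cs_intron

    @property
    def nnc_ss(self) -> np.ndarray:
        return self.intergenic_bp * self.config.cs_intergenic

    @property
    def n_silent_candidate(self) -> np.ndarray:
        return self.intron_bp + self.intergenic_bp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosome,
                "start": self.window_starts,
                "end": self.window_starts + self.window_size,
                "coding_bp": self.coding_bp,
                "utr_bp": self.utr_bp,
                "intron_bp": self.intron_bp,
                "intergenic_bp": self.intergenic_bp,
                "masked_bp": self.masked_bp,
                "naa": self.naa,
                "nutr_ss": self.nutr_ss,
                "nnc_ss": self.nnc_ss,
                "n_silent_candidate": self.n_silent_candidate,
            }
        )


def per_bp_selected_weights(
    labels: np.ndarray, config: SiteClassConfig | None = None
) -> dict:
    """Per-bp selected-site weights by class from per-bp labels.

    A coding bp carries weight 0.75 × cs_nonsyn in class ``aa``; UTR and
    intron bases carry their constrained fractions in class ``utr``;
    intergenic bases cs_intergenic in class ``nc``.  Masked bases carry no
    weight anywhere.
    """
    config = config or SiteClassConfig()
    n = len(labels)
    w = {c: np.zeros(n) for c in ("aa", "utr", "nc")}
    w["aa"][labels == CODING] = config.coding_nonsyn_fraction * config.cs_nonsyn
    w["utr"][labels == UTR] = config.cs_utr
    w["utr"][labels == INTRON] = config.cs_intron
    w["nc"][labels == INTERGENIC] = config.cs_intergenic
    return w


def read_bed_intervals(path) -> pd.DataFrame:
    """Read a (chrom, start, end[, ...]) BED file; returns empty frame for
    an empty file."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return df


def _paint(labels: np.ndarray, start: int, end: int, code: int) -> None:
    lo = max(0, int(start))
    hi = min(len(labels), int(end))
    if hi > lo:
        labels[lo:hi] = code


def classify_sites(
    gene_models,
    te_track=None,
    repeat_track=None,
    *,
    chromosome: str,
    chromosome_length: int,
) -> np.ndarray:
    """Per-bp site-class labels (uint8 codes, see :data:`LABELS`).

    ``gene_models`` is a GFF3 path or an open :mod:`gffutils` database;
    ``te_track``/``repeat_track`` are BED paths or (chrom, start, end)
    DataFrames.  GFF3 coordinates (1-based closed) are converted to 0-based
    half-open internally.  Strand-inconsistent gene models (a child feature on
    the opposite strand from its gene) raise :class:`AnnotationError`.
    """
    import gffutils

    if isinstance(gene_models, gffutils.FeatureDB):
        db = gene_models
    else:
        try:
            db = gffutils.create_db(
                str(gene_models),
                ":memory:",
                merge_strategy="create_unique",
                keep_order=True,
            )
        except gffutils.exceptions.EmptyInputError:
            db = None  # featureless annotation: everything intergenic

    labels = np.full(chromosome_length, INTERGENIC, dtype=np.uint8)

    genes = (
        [g for g in db.features_of_type("gene") if g.seqid == chromosome]
        if db is not None
        else []
    )
    # paint in increasing precedence: intron (gene body) < exon placeholder
    # (masked) < utr < coding; TE/repeat masking last wins over everything.
    for gene in genes:
        for child in db.children(gene.id):
            if child.strand != gene.strand and child.strand != "." and gene.strand != ".":
                raise AnnotationError(
                    f"feature {child.id!r} on strand {child.strand} contradicts "
                    f"gene {gene.id!r} on strand {gene.strand}"
                )
        _paint(labels, gene.start - 1, gene.end, INTRON)
    if db is not None:
        for feat in db.features_of_type("exon"):
            if feat.seqid == chromosome:
                _paint(labels, feat.start - 1, feat.end, MASKED)
        for utr_type in _UTR_TYPES:
            for feat in db.features_of_type(utr_type):
                if feat.seqid == chromosome:
                    _paint(labels, feat.start - 1, feat.end, UTR)
        for feat in db.features_of_type("CDS"):
            if feat.seqid == chromosome:
                _paint(labels, feat.start - 1, feat.end, CODING)

    for track in (te_track, repeat_track):
        if track is None:
            continue
        df = track if isinstance(track, pd.DataFrame) else read_bed_intervals(track)
        for _, row in df[df["chrom"] == chromosome].iterrows():
            _paint(labels, row["start"], row["end"], MASKED)

    return labels


def count_selected_sites(
    labels: np.ndarray,
    config: SiteClassConfig | None = None,
    *,
    chromosome: str = "chr1",
    window_size: int = 1000,
    keep_per_bp: bool = True,
) -> SelectedSiteTrack:
    """Aggregate per-bp labels into per-window class counts.

    The trailing partial window (if chromosome length is not a multiple of
    ``window_size``) is kept with its actual base counts.  With
    ``keep_per_bp`` the track also retains per-bp class weights so the B
    computation can integrate its near field exactly; disable to save memory
    on very long chromosomes.
    """
    config = config or SiteClassConfig()
    n = len(labels)
    n_windows = -(-n // window_size)
    window_starts = np.arange(n_windows, dtype=np.int64) * window_size
    window_idx = np.arange(n) // window_size

    def per_window(code: int) -> np.ndarray:
        return np.bincount(window_idx[labels == code], minlength=n_windows).astype(float)

    return SelectedSiteTrack(
        chromosome=chromosome,
        window_size=window_size,
        window_starts=window_starts,
        coding_bp=per_window(CODING),
        utr_bp=per_window(UTR),
        intron_bp=per_window(INTRON),
        intergenic_bp=per_window(INTERGENIC),
        masked_bp=per_window(MASKED),
        config=config,
        per_bp_weights=per_bp_selected_weights(labels, config) if keep_per_bp else None,
    )
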