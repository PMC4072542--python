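"""Windowed crossover maps, gene conversion, and pairwise recombination.

Crossover rates come as per-window rates (cM/Mb per female meiosis, typically
at 100-kb resolution).  Recombination between two sites combines the
piecewise-constant crossover distance with a gene-conversion term and is then
sex-averaged: *Drosophila* males do not recombine, so only 0.5 of autosomal
meioses (0.66 for the X, which spends more time in females) are recombining.

The gene-conversion contribution to the recombination frequency between two
sites at distance d uses the tract-overlap form

    gc(d) = gamma · L_GC · (1 − exp(−d / L_GC))

which rises linearly (≈ gamma·d) for d << L_GC and plateaus at gamma·L_GC for
d >> L_GC.  The function is pluggable so an alternative form can be swapped
without touching callers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "RecombinationMap",
    "TrimBoundaries",
    "read_recmap",
    "genetic_distance",
    "pairwise_r",
    "trim_chromosome",
    "tract_overlap_gc",
    "R_FLOOR",
]

#: Recombination frequencies below this are treated as exactly 0.
R_FLOOR = 1e-10

#: Default gene-conversion parameters (per bp per female meiosis; bp).
GAMMA_GC_DEFAULT = 1.25e-7
L_GC_DEFAULT = 518.0

SEX_FACTOR_AUTOSOME = 0.5
SEX_FACTOR_X = 0.66


class RecmapFormatError(ValueError):
    """Malformed recombination-map input."""


class MapRangeError(ValueError):
    """Position outside the mapped extent."""


class TrimError(ValueError):
    """No region satisfies the crossover-rate trimming rule."""


def tract_overlap_gc(d, gamma: float, l_gc: float):
    """Gene-conversion recombination between sites d bp apart."""
    d = np.asarray(d, dtype=float)
    return gamma * l_gc * -np.expm1(-d / l_gc)


@dataclass
class RecombinationMap:
    """Piecewise-constant crossover map for one chromosome.

    windows are contiguous, sorted, non-overlapping [start, end) intervals in
    bp with rates in cM/Mb per female meiosis.
    """

    chromosome: str
    starts: np.ndarray  # bp, 0-based half-open
    ends: np.ndarray
    rates_cm_per_mb: np.ndarray
    gamma_gc: float = GAMMA_GC_DEFAULT
    l_gc: float = L_GC_DEFAULT
    sex_factor: float = SEX_FACTOR_AUTOSOME
    gc_function: Callable = field(default=tract_overlap_gc, repr=False)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.rates_cm_per_mb = np.asarray(self.rates_cm_per_mb, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.rates_cm_per_mb)):
            raise RecmapFormatError("starts, ends, rates must have equal length")
        if len(self.starts) == 0:
            raise RecmapFormatError("empty recombination map")
        if np.any(self.ends <= self.starts):
            raise RecmapFormatError("windows must have positive length")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise RecmapFormatError("windows must be contiguous and sorted")
        if np.any(self.rates_cm_per_mb < 0):
            raise RecmapFormatError("crossover rates must be nonnegative")
        if self.gamma_gc < 0 or self.l_gc <= 0:
            raise RecmapFormatError("gamma_gc >= 0 and l_gc > 0 required")
        # cumulative genetic position (Morgans per female meiosis) at window starts
        lengths_bp = (self.ends - self.starts).astype(float)
        morgans_per_bp = self.rates_cm_per_mb * 1e-8  # cM/Mb -> M/bp
        self._cum_morgans = np.concatenate([[0.0], np.cumsum(lengths_bp * morgans_per_bp)])
        self._morgans_per_bp = morgans_per_bp

    @property
    def span(self) -> tuple[int, int]:
        return int(self.starts[0]), int(self.ends[-1])

    def genetic_position(self, pos):
        """Cumulative genetic position (Morgans/female meiosis) at bp ``pos``."""
        pos_arr = np.asarray(pos, dtype=np.int64)
        lo, hi = self.span
        if np.any(pos_arr < lo) or np.any(pos_arr > hi):
            raise MapRangeError(
                f"position outside mapped extent [{lo}, {hi}] of {self.chromosome}"
            )
        idx = np.clip(np.searchsorted(self.starts, pos_arr, side="right") - 1, 0, None)
        g = self._cum_morgans[idx] + (pos_arr - self.starts[idx]) * self._morgans_per_bp[idx]
        return g if g.shape else float(g)


@dataclass(frozen=True)
class TrimBoundaries:
    """Retained [keep_start, keep_end) extent after removing low-crossover
    chromosome ends; boundaries lie on map-window edges."""

    chromosome: str
    keep_start: int
    keep_end: int

    def __post_init__(self) -> None:
        if self.keep_start >= self.keep_end:
            raise TrimError("keep_start must be < keep_end")


def read_recmap(
    path,
    chromosome: str | None = None,
    window_size: int = 100_000,
    **map_kwargs,
) -> RecombinationMap:
    """Read a TSV crossover map (columns: chrom, start, [end,] c_cM_per_Mb).

    Windows must be sorted and non-overlapping; gaps are filled with c = 0
    (with a warning).  Extra keyword arguments (gamma_gc, l_gc, sex_factor)
    are forwarded to :class:`RecombinationMap`.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    required = {"chrom", "start"}
    if not required.issubset(cols):
        raise RecmapFormatError(f"recombination map needs columns {sorted(required)}")
    rate_col = next((c for c in cols if c.startswith("c") and c != "chrom"), None)
    if rate_col is None:
        raise RecmapFormatError("no crossover-rate column found")
    if chromosome is None:
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise RecmapFormatError("multiple chromosomes in file; pass chromosome=")
        chromosome = str(chroms[0])
    sub = df[df["chrom"] == chromosome].sort_values("start").reset_index(drop=True)
    if sub.empty:
        raise RecmapFormatError(f"chromosome {chromosome!r} not present in map")
    starts = sub["start"].to_numpy(dtype=np.int64)
    ends = (
        sub["end"].to_numpy(dtype=np.int64)
        if "end" in cols
        else starts + window_size
    )
    rates = sub[rate_col].to_numpy(dtype=float)
    if np.any(starts[1:] < ends[:-1]):
        raise RecmapFormatError("overlapping or unsorted windows in recombination map")
    # fill gaps with c = 0
    gap_mask = starts[1:] > ends[:-1]
    if np.any(gap_mask):
        warnings.warn(
            f"{int(gap_mask.sum())} gap(s) in recombination map for {chromosome}; "
            "filled with c = 0",
            stacklevel=2,
        )
        new_s, new_e, new_r = [], [], []
        for i in range(len(starts)):
            if i > 0 and starts[i] > ends[i - 1]:
                new_s.append(ends[i - 1])
                new_e.append(starts[i])
                new_r.append(0.0)
            new_s.append(starts[i])
            new_e.append(ends[i])
            new_r.append(rates[i])
        starts, ends, rates = (
            np.array(new_s, dtype=np.int64),
            np.array(new_e, dtype=np.int64),
            np.array(new_r),
        )
    return RecombinationMap(chromosome, starts, ends, rates, **map_kwargs)


def genetic_distance(recmap: RecombinationMap, pos1, pos2):
    """Genetic distance in Morgans per female meiosis between two positions
    (piecewise-constant integral of the windowed crossover rate)."""
    return np.abs(recmap.genetic_position(pos1) - recmap.genetic_position(pos2))


def pairwise_r(
    recmap: RecombinationMap, pos1, pos2, include_gc: bool = True
):
    """Sex-averaged recombination frequency per generation between two sites.

    r = sex_factor × [crossover genetic distance + gc(d)], floored to 0 below
    1e-10 and capped at 1.  Accepts scalars or broadcastable arrays.
    """
    d = np.abs(np.asarray(pos1, dtype=np.int64) - np.asarray(pos2, dtype=np.int64))
    r = genetic_distance(recmap, pos1, pos2)
    if include_gc:
        r = r + recmap.gc_function(d, recmap.gamma_gc, recmap.l_gc)
    r = recmap.sex_factor * r
    r = np.where(r < R_FLOOR, 0.0, np.minimum(r, 1.0))
    return r if r.shape else float(r)


def trim_chromosome(
    recmap: RecombinationMap, min_rate_cm_per_mb: float = 1.0, run_length: int = 3
) -> TrimBoundaries:
    """Remove low-crossover chromosome ends.

    Scanning inward from each end, the retained region starts at the first
    window of the first run of >= ``run_length`` consecutive windows with
    crossover rate > ``min_rate_cm_per_mb`` (and symmetrically from the other
    end).  Raises :class:`TrimError` when no such run exists.
    """
    if len(recmap.starts) < run_length:
        raise TrimError(f"map has fewer than {run_length} windows")
    ok = recmap.rates_cm_per_mb > min_rate_cm_per_mb
    runs = np.convolve(ok.astype(int), np.ones(run_length, dtype=int), mode="valid")
    qualifying = np.flatnonzero(runs == run_length)  # run start indices
    if qualifying.size == 0:
        raise TrimError(
            f"no run of {run_length} consecutive windows with "
            f"c > {min_rate_cm_per_mb} cM/Mb on {recmap.chromosome}"
        )
    first = qualifying[0]
    last_end = qualifying[-1] + run_length - 1  # last window of last qualifying run
    return TrimBoundaries(
        chromosome=recmap.chromosome,
        keep_start=int(recmap.starts[first]),
        keep_end=int(recmap.ends[last_end]),
    )
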