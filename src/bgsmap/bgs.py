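"""Background-selection landscapes (B) at 1-kb resolution.

B = pi/pi0 is the expected neutral diversity relative to free recombination.
Under the classical structured-coalescent result for purifying selection at
many partially linked sites,

    B_j = exp( - sum_i u_i * K(r_ji) ),
    K(r) = integral over the truncated DDFE of
           phi(s) * s*h / (s*h + r*(1 - s*h))**2 ds,

where u_i is the per-site deleterious mutation rate at selected site i, h the
dominance coefficient, and r_ji the recombination frequency between the focal
site j and site i.  At r = 0 the kernel reduces to E[1/(s*h)] and the whole
exponent to the classical U/(2*s*h) of fully linked mutational load.

Computing B at every 1-kb window of a chromosome is made tractable by
(1) precomputing K on a log-spaced grid of r in [1e-10, 1] (one adaptive
quadrature per grid point) and interpolating log-log between points, and
(2) treating all sites within a 1-kb window as equidistant from all sites of
any other window (recombination measured center-to-center).  Both shortcuts
are validated against :func:`oracle_B`, a brute-force per-bp evaluation with
no r-grid and no windowing.

The DDFE is truncated at the effectively-neutral threshold s_T (conditioning
the density on s >= s_T; the matching rate reduction is applied through
``MutationRates.effective_fraction``), and mass above s = 1 — lethals, present
under the heavy-tailed log-normal — is clamped to s = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

from .annotation import SelectedSiteTrack, per_bp_selected_weights
from .ddfe import DDFESpec, MutationRates, NeutralThreshold
from .recmap import RecombinationMap, pairwise_r

__all__ = [
    "ExponentKernel",
    "BLandscape",
    "DBProfile",
    "build_kernel",
    "compute_B",
    "oracle_B",
    "per_bp_selected_weights",
    "db_quantiles",
    "xa_summary",
]

SITE_CLASSES = ("aa", "utr", "nc")

#: Upper clamp for selection coefficients (homozygous lethality).
S_CLAMP = 1.0


class KernelError(ArithmeticError):
    """Quadrature failure while building an exponent kernel."""


def _coalescent_factor(s, h, r):
    """sh / (sh + r(1-sh))^2 — per-mutation contribution to the BGS exponent."""
    t = s * h
    return t / (t + r * (1.0 - t)) ** 2


@dataclass
class ExponentKernel:
    """Inner DDFE integral K(r) tabulated on a log-spaced r grid.

    ``value_at_zero`` holds K(0) = E[1/(s h)] over the truncated DDFE, used
    for fully linked pairs (r below the 1e-10 floor).  Interpolation between
    grid points is linear in (ln r, ln K).
    """

    r_grid: np.ndarray
    values: np.ndarray
    value_at_zero: float
    ddfe: DDFESpec
    threshold: NeutralThreshold

    def __post_init__(self) -> None:
        if np.any(self.values <= 0) or self.value_at_zero <= 0:
            raise KernelError("kernel values must be positive")
        if np.any(np.diff(self.values) > 1e-9 * self.values[:-1]):
            raise KernelError("kernel must be nonincreasing in r")
        self._log_r = np.log(self.r_grid)
        self._log_v = np.log(self.values)

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        rc = np.clip(r, self.r_grid[0], self.r_grid[-1])
        out = np.exp(np.interp(np.log(rc), self._log_r, self._log_v))
        out = np.where(r == 0.0, self.value_at_zero, out)
        return out if out.shape else float(out)


def _truncated_parts(ddfe: DDFESpec, threshold: NeutralThreshold):
    """Normalization mass, continuous range and lethal clamp mass of the
    truncated DDFE.  Returns (surviving_mass, s_lo, s_hi, lethal_mass) where
    masses are unconditional (divide by surviving_mass to condition)."""
    s_t = threshold.s_T
    if ddfe.family == "point_mass":
        s0 = min(ddfe.point_value, S_CLAMP)
        if ddfe.point_value < s_t:
            return 0.0, s0, s0, 0.0
        return 1.0, s0, s0, 1.0  # all mass is "clamp" mass at s0
    dist = ddfe.distribution
    surviving = float(1.0 - dist.cdf(s_t))
    lethal = float(dist.sf(S_CLAMP))
    return surviving, s_t, S_CLAMP, lethal


def kernel_value(ddfe: DDFESpec, threshold: NeutralThreshold, r: float) -> float:
    """K(r) by adaptive quadrature over the truncated, renormalized DDFE."""
    h = ddfe.dominance_h
    surviving, s_lo, s_hi, lethal = _truncated_parts(ddfe, threshold)
    if surviving == 0.0:
        return 0.0
    if ddfe.family == "point_mass":
        return float(_coalescent_factor(s_lo, h, r))
    dist = ddfe.distribution

    def integrand(y):  # y = ln s
        s = np.exp(y)
        return dist.pdf(s) * s * _coalescent_factor(s, h, r)

    if s_hi > s_lo:
        val, err = integrate.quad(
            integrand, np.log(s_lo), np.log(s_hi), limit=400, epsabs=0, epsrel=1e-10
        )
        if not np.isfinite(val):
            raise KernelError(f"quadrature failed at r = {r}")
    else:
        val = 0.0
    val += lethal * _coalescent_factor(S_CLAMP, h, r)
    return val / surviving


def build_kernel(
    ddfe: DDFESpec,
    threshold: NeutralThreshold,
    n_grid: int = 512,
    r_min: float = 1e-10,
    r_max: float = 1.0,
) -> ExponentKernel:
    """Tabulate K(r) on ``n_grid`` log-spaced points spanning [r_min, r_max]."""
    if n_grid < 200:
        raise ValueError("r grid needs at least 200 points")
    r_grid = np.geomspace(r_min, r_max, n_grid)
    values = np.array([kernel_value(ddfe, threshold, r) for r in r_grid])
    v0 = kernel_value(ddfe, threshold, 0.0)
    return ExponentKernel(r_grid, values, v0, ddfe, threshold)


@dataclass
class BLandscape:
    """Per-1-kb B values for one chromosome under one model."""

    model_id: str
    chromosome: str
    window_size: int
    window_starts: np.ndarray
    b: np.ndarray
    exponent: np.ndarray  # E_j = -ln B_j

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_starts + self.window_size // 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosome,
                "start": self.window_starts,
                "end": self.window_starts + self.window_size,
                "B": self.b,
                "model_id": self.model_id,
            }
        )


def _normalize_per_class(obj) -> dict:
    if isinstance(obj, dict):
        missing = set(SITE_CLASSES) - set(obj)
        if missing:
            raise ValueError(f"missing site classes {sorted(missing)}")
        return {c: obj[c] for c in SITE_CLASSES}
    return {c: obj for c in SITE_CLASSES}


def _class_weights(track: SelectedSiteTrack) -> dict:
    return {"aa": track.naa, "utr": track.nutr_ss, "nc": track.nnc_ss}


#: Windows on each side of the focal window whose kernel is averaged over
#: exact per-bp distances rather than evaluated at the center distance.  K(r)
#: varies steeply for r within ~1e-4 of zero (weakly selected mass near the
#: truncation threshold), so center-to-center distances are only safe once
#: the kernel flattens; in the near field sites are integrated as uniformly
#: spread within their window.
NEAR_FIELD_WINDOWS = 3


def _near_field_corrections(
    track: SelectedSiteTrack,
    recmap: RecombinationMap,
    kernels: dict,
    rate_by_class: dict,
    include_gc: bool,
    n_near: int = NEAR_FIELD_WINDOWS,
) -> np.ndarray:
    """Exponent corrections replacing the center-distance kernel by the exact
    per-bp near-field integral for the 2·n_near+1 windows around each focus.

    Returns array (n_windows, 2·n_near+1): column ``d`` holds, for focal
    window j, the correction attributable to source window j + d - n_near
    (0 out of range), already multiplied by class weights and effective
    rates.  When the track carries per-bp weights they are used exactly;
    otherwise each class is assumed uniformly spread within its window.
    """
    centers = track.window_centers
    starts = track.window_starts
    weights = _class_weights(track)
    n = len(centers)
    w = track.window_size
    chrom_end = min(int(starts[-1]) + w, recmap.span[1])
    per_bp = track.per_bp_weights
    corr = np.zeros((n, 2 * n_near + 1))
    offs = np.arange(w)
    for d in range(-n_near, n_near + 1):
        j = np.arange(max(0, -d), min(n, n - d))
        if j.size == 0:
            continue
        src = j + d
        pos = starts[src][:, None] + offs[None, :]
        valid = pos < chrom_end
        pos_c = np.minimum(pos, chrom_end - 1)
        r_exact = pairwise_r(recmap, centers[j][:, None], pos_c, include_gc)
        r_center = pairwise_r(recmap, centers[j], centers[src], include_gc)
        kv_cache: dict[int, np.ndarray] = {}
        kc_cache: dict[int, np.ndarray] = {}
        for cls in SITE_CLASSES:
            k = kernels[cls]
            key = id(k)
            if key not in kv_cache:
                kv_cache[key] = np.where(valid, k(r_exact), 0.0)
                kc_cache[key] = k(r_center)
            u = rate_by_class[cls].u_effective
            if per_bp is not None:
                wb = np.where(valid, per_bp[cls][pos_c], 0.0)
                exact = (kv_cache[key] * wb).sum(axis=1)
            else:
                n_valid = np.maximum(valid.sum(axis=1), 1)
                exact = kv_cache[key].sum(axis=1) / n_valid * weights[cls][src]
            corr[j, d + n_near] += u * (exact - kc_cache[key] * weights[cls][src])
    return corr


def compute_B(
    track: SelectedSiteTrack,
    recmap: RecombinationMap,
    kernel,
    rates,
    include_gc: bool = True,
    model_id: str = "custom",
    chunk_size: int = 512,
    n_near: int = NEAR_FIELD_WINDOWS,
) -> BLandscape:
    """B at the center of every 1-kb window of a chromosome.

    ``kernel`` and ``rates`` may be a single :class:`ExponentKernel` /
    :class:`~bgsmap.ddfe.MutationRates` (applied to all three site classes)
    or dicts keyed by ``{"aa", "utr", "nc"}`` for two-DDFE hybrid models.
    The exponent at focal window j sums the class counts of every window i of
    the chromosome (including i = j) times the per-class effective rate times
    the kernel.  Far windows use the center-to-center recombination
    frequency; the ``n_near`` windows on each side (and the focal window
    itself, whose sites would otherwise count as fully linked) average the
    kernel over exact per-bp distances, treating sites as uniformly spread
    within their 1-kb window.
    """
    lo, hi = recmap.span
    if track.window_starts[0] < lo or track.window_starts[-1] + track.window_size > hi:
        raise ValueError(
            f"selected-site track [{track.window_starts[0]}, "
            f"{track.window_starts[-1] + track.window_size}) not covered by "
            f"recombination map [{lo}, {hi})"
        )
    kernels = _normalize_per_class(kernel)
    rate_by_class = _normalize_per_class(rates)
    weights = _class_weights(track)
    centers = track.window_centers
    n = len(centers)
    exponent = np.zeros(n)
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        r = pairwise_r(recmap, centers[sl][:, None], centers[None, :], include_gc)
        seen: dict[int, np.ndarray] = {}
        for cls in SITE_CLASSES:
            k = kernels[cls]
            key = id(k)
            if key not in seen:
                seen[key] = k(r)
            exponent[sl] += seen[key] @ (weights[cls] * rate_by_class[cls].u_effective)
    # near-field correction: exact per-bp distance integrals around the focus
    corr = _near_field_corrections(
        track, recmap, kernels, rate_by_class, include_gc, n_near
    )
    exponent += corr.sum(axis=1)
    return BLandscape(
        model_id=model_id,
        chromosome=track.chromosome,
        window_size=track.window_size,
        window_starts=track.window_starts.copy(),
        b=np.exp(-exponent),
        exponent=exponent,
    )


# ---------------------------------------------------------------------------
# brute-force oracle




class _TrapezoidDDFE:
    """Fixed-node trapezoid quadrature of the truncated, clamped DDFE in
    ln s — independent of the adaptive-quadrature path used by kernels."""

    def __init__(self, ddfe: DDFESpec, threshold: NeutralThreshold, n_nodes: int = 512):
        self.h = ddfe.dominance_h
        surviving, s_lo, s_hi, lethal = _truncated_parts(ddfe, threshold)
        self.surviving = surviving
        if ddfe.family == "point_mass" or surviving == 0.0:
            self.point = s_lo if surviving else None
            self.nodes = self.mass = None
            return
        self.point = None
        y = np.linspace(np.log(s_lo), np.log(s_hi), n_nodes)
        s = np.exp(y)
        dens = ddfe.distribution.pdf(s) * s  # density in ln s
        wts = np.full(n_nodes, y[1] - y[0])
        wts[[0, -1]] *= 0.5
        self.nodes = s
        self.mass = dens * wts
        self.lethal = lethal

    def kernel(self, r: np.ndarray) -> np.ndarray:
        """K(r) for a vector of recombination frequencies."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        if self.surviving == 0.0:
            return np.zeros_like(r)
        if self.point is not None:
            return _coalescent_factor(self.point, self.h, r)
        out = np.empty_like(r)
        chunk = max(1, 4_000_000 // len(self.nodes))
        for i in range(0, len(r), chunk):
            rr = r[i : i + chunk]
            f = _coalescent_factor(self.nodes[:, None], self.h, rr[None, :])
            out[i : i + chunk] = self.mass @ f
        out += self.lethal * _coalescent_factor(S_CLAMP, self.h, r)
        return out / self.surviving


def oracle_B(
    per_bp_weights: dict,
    recmap: RecombinationMap,
    ddfe,
    threshold: NeutralThreshold,
    rates,
    focal_positions: np.ndarray,
    include_gc: bool = True,
    n_quad_nodes: int = 512,
    max_length: int = 200_000,
) -> np.ndarray:
    """Brute-force B with no 1-kb windowing and no r-grid interpolation.

    Sums over every selected bp individually, with exact per-pair
    recombination frequencies and a fixed-node trapezoid quadrature of the
    DDFE per pair.  Quadratic cost — refuses chromosomes over ``max_length``.
    ``ddfe`` and ``rates`` may be single objects or per-class dicts.
    """
    length = max(len(w) for w in per_bp_weights.values())
    if length > max_length:
        raise ValueError(f"oracle limited to {max_length} bp, got {length}")
    ddfe_by_class = _normalize_per_class(ddfe)
    rate_by_class = _normalize_per_class(rates)
    quads = {}
    for cls in SITE_CLASSES:
        key = id(ddfe_by_class[cls])
        if key not in quads:
            quads[key] = _TrapezoidDDFE(ddfe_by_class[cls], threshold, n_quad_nodes)
    focal_positions = np.asarray(focal_positions, dtype=np.int64)
    exponent = np.zeros(len(focal_positions))
    for cls in SITE_CLASSES:
        w = per_bp_weights[cls]
        sel = np.flatnonzero(w)
        if sel.size == 0:
            continue
        quad = quads[id(ddfe_by_class[cls])]
        u = rate_by_class[cls].u_effective
        w_sel = w[sel] * u
        for k, p in enumerate(focal_positions):
            r = pairwise_r(recmap, sel, p, include_gc)
            exponent[k] += w_sel @ quad.kernel(np.atleast_1d(r))
    return np.exp(-exponent)


# ---------------------------------------------------------------------------
# spatial scale of BGS


@dataclass(frozen=True)
class DBProfile:
    """Genomic region sizes around a focal window generating 50/75/90% of its
    total BGS exponent, in physical (kb) and genetic (cM per female meiosis)
    units."""

    chromosome: str
    focal_start: int
    sizes: dict  # fraction -> (kb, cM)

    def __getitem__(self, fraction: float) -> tuple:
        return self.sizes[fraction]


def db_quantiles(
    track: SelectedSiteTrack,
    recmap: RecombinationMap,
    kernel,
    rates,
    focal_index: int,
    fractions=(0.5, 0.75, 0.9),
    include_gc: bool = True,
) -> DBProfile:
    """Size of the region around a focal window needed to generate the given
    fractions of the full-chromosome BGS exponent.

    The interval grows symmetrically in physical distance, one 1-kb window
    per side per step (truncated at chromosome ends), until its summed
    exponent reaches fraction × E_total.  Genetic size is the crossover map
    distance between interval ends, in cM per female meiosis.
    """
    kernels = _normalize_per_class(kernel)
    rate_by_class = _normalize_per_class(rates)
    weights = _class_weights(track)
    centers = track.window_centers
    n = len(centers)
    if not 0 <= focal_index < n:
        raise IndexError("focal_index outside track")
    r = pairwise_r(recmap, centers[focal_index], centers, include_gc)
    contrib = np.zeros(n)
    seen: dict[int, np.ndarray] = {}
    for cls in SITE_CLASSES:
        k = kernels[cls]
        if id(k) not in seen:
            seen[id(k)] = k(r)
        contrib += seen[id(k)] * weights[cls] * rate_by_class[cls].u_effective
    # near-field per-bp integration, consistent with compute_B
    corr = _near_field_corrections(track, recmap, kernels, rate_by_class, include_gc)
    for d in range(-NEAR_FIELD_WINDOWS, NEAR_FIELD_WINDOWS + 1):
        i = focal_index + d
        if 0 <= i < n:
            contrib[i] += corr[focal_index, d + NEAR_FIELD_WINDOWS]
    total = contrib.sum()
    if total <= 0:
        raise ArithmeticError("focal window has zero BGS exponent; D_B undefined")
    sizes = {}
    remaining = sorted(fractions)
    acc = contrib[focal_index]
    lo = hi = focal_index
    step = 0
    while remaining:
        frac = remaining[0]
        if acc >= frac * total - 1e-12 * total:
            n_windows = hi - lo + 1
            kb = n_windows * track.window_size / 1000.0
            g_lo = recmap.genetic_position(track.window_starts[lo])
            g_hi = recmap.genetic_position(
                min(track.window_starts[hi] + track.window_size, recmap.span[1])
            )
            sizes[frac] = (kb, (g_hi - g_lo) * 100.0)  # Morgans -> cM
            remaining.pop(0)
            continue
        if lo == 0 and hi == n - 1:
            raise ArithmeticError("exponent never reaches requested fraction")
        step += 1
        if lo > 0:
            lo -= 1
            acc += contrib[lo]
        if hi < n - 1:
            hi += 1
            acc += contrib[hi]
    return DBProfile(
        chromosome=track.chromosome,
        focal_start=int(track.window_starts[focal_index]),
        sizes=sizes,
    )


def xa_summary(autosomal, x: BLandscape) -> dict:
    """Median B per chromosome group and the predicted X/A diversity ratio
    0.75 × median(B_X) / median(B_A)."""
    if isinstance(autosomal, BLandscape):
        autosomal = [autosomal]
    if not autosomal or x is None or len(x.b) == 0:
        raise ValueError("need non-empty autosomal and X landscapes")
    b_a = np.concatenate([l.b for l in autosomal])
    if len(b_a) == 0:
        raise ValueError("empty autosomal landscape")
    median_a = float(np.median(b_a))
    median_x = float(np.median(x.b))
    return {
        "median_B_autosome": median_a,
        "median_B_X": median_x,
        "xa_predicted_ratio": 0.75 * median_x / median_a,
    }
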