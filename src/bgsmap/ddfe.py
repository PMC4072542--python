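"""Distributions of deleterious fitness effects (DDFEs).

Background selection (BGS) removes linked neutral variation at a rate set by
the deleterious mutation rate and by how deleterious the removed mutations
are.  Both quantities depend on the distribution of selection coefficients
``s`` of new mutations.  This module represents the two parameterizations in
common use for *Drosophila* — a log-normal (median s = 2.31e-4, standard
deviation of ln s = 5.308) and a gamma (shape k = 0.3, mean s = 2.5e-3) — plus
a degenerate point mass used for closed-form checks.

Mutations with ``s`` below the effectively-neutral threshold ``s_T ~ 1/Ne``
drift as if neutral and contribute no BGS; the DDFE used inside BGS integrals
is therefore truncated at ``s_T`` and the deleterious mutation rate is scaled
by the surviving mass.  X-linked selection acts on ``s_X = (2/3)·s_A`` (genic
selection, equal sex ratio) while X-linked drift has ``N_eX = 0.75·Ne``, so
both the distribution scale and the threshold differ from autosomes.
"""

from __future__ import annotations


from dataclasses import dataclass, replace
from typing import NamedTuple

from scipy import stats

__all__ = [
    "DDFESpec",
    "MutationRates",
    "NeutralThreshold",
    "make_ddfe",
    "neutral_fraction",
    "effective_deleterious_rate",
    "te_insertion_rate",
]

_FAMILIES = ("lognormal", "gamma", "point_mass")

#: Fraction of X-linked meioses that see selection on a hemizygous/genic scale
#: relative to autosomes (s_X = 2/3 s_A under h = 0.5 and equal sex numbers).
X_SELECTION_SCALE = 2.0 / 3.0

#: X effective population size relative to autosomes.
X_NE_FACTOR = 0.75


class ParameterError(ValueError):
    """A DDFE or rate parameter is missing, of the wrong sign, or unknown."""


@dataclass(frozen=True)
class DDFESpec:
    """A validated distribution of deleterious fitness effects.

    ``chromosome_scale`` multiplies every selection coefficient: 1 for
    autosomes, 2/3 for the X chromosome.  ``dominance_h`` is the dominance
    coefficient of deleterious mutations (0.5 throughout the default models).
    Mass above s = 1 (possible under the heavy-tailed log-normal, representing
    lethals) is clamped to s = 1 inside BGS integrals; see :mod:`bgsmap.bgs`.
    """

    family: str
    median_s: float | None = None
    sd_log: float | None = None
    shape_k: float | None = None
    mean_s: float | None = None
    dominance_h: float = 0.5
    chromosome_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(
                f"unknown DDFE family {self.family!r}; expected one of {_FAMILIES}"
            )
        if not 0.0 <= self.dominance_h <= 1.0:
            raise ParameterError("dominance_h must lie in [0, 1]")
        if self.chromosome_scale <= 0:
            raise ParameterError("chromosome_scale must be positive")
        if self.family == "lognormal":
            if not (self.median_s and self.median_s > 0 and self.sd_log and self.sd_log > 0):
                raise ParameterError("lognormal DDFE needs median_s > 0 and sd_log > 0")
        elif self.family == "gamma":
            if not (self.shape_k and self.shape_k > 0 and self.mean_s and self.mean_s > 0):
                raise ParameterError("gamma DDFE needs shape_k > 0 and mean_s > 0")
        else:  # point_mass
            if not (self.mean_s and self.mean_s > 0):
                raise ParameterError("point_mass DDFE needs mean_s > 0")

    @property
    def distribution(self):
        """Frozen scipy distribution of ``s`` on the scale selection acts
        (i.e. already multiplied by ``chromosome_scale``)."""
        if self.family == "lognormal":
            return stats.lognorm(s=self.sd_log, scale=self.median_s * self.chromosome_scale)
        if self.family == "gamma":
            return stats.gamma(
                a=self.shape_k,
                scale=self.mean_s / self.shape_k * self.chromosome_scale,
            )
        raise ParameterError("point_mass DDFE has no continuous distribution")

    @property
    def point_value(self) -> float:
        """Location of the point mass (scaled), for the degenerate family."""
        if self.family != "point_mass":
            raise ParameterError("point_value only defined for point_mass DDFE")
        return self.mean_s * self.chromosome_scale

    def cdf(self, s: float) -> float:
        """P(selection coefficient < s) on the acting scale."""
        if s <= 0:
            return 0.0
        if self.family == "point_mass":
            return float(s > self.point_value)
        return float(self.distribution.cdf(s))

    def for_x_chromosome(self) -> "DDFESpec":
        """The same DDFE with selection coefficients scaled by 2/3."""
        return replace(self, chromosome_scale=X_SELECTION_SCALE)


@dataclass(frozen=True)
class NeutralThreshold:
    """Effectively-neutral cutoff s_T below which mutations add no BGS.

    The autosomal threshold is 1/Ne.  On the X chromosome drift is governed by
    N_eX = 0.75·Ne, so the cutoff satisfying N_eX·s_X ≈ 1 is 1/(0.75·Ne) on
    the (already 2/3-scaled) X selection scale.
    """

    Ne: float
    s_T: float

    def __post_init__(self) -> None:
        if self.Ne <= 0 or self.s_T < 0:
            raise ParameterError("Ne must be positive and s_T nonnegative")

    @classmethod
    def autosomal(cls, Ne: float) -> "NeutralThreshold":
        return cls(Ne=Ne, s_T=1.0 / Ne)

    @classmethod
    def x_linked(cls, Ne: float) -> "NeutralThreshold":
        return cls(Ne=Ne, s_T=1.0 / (X_NE_FACTOR * Ne))


@dataclass(frozen=True)
class MutationRates:
    """Deleterious mutation rates entering the BGS exponent.

    u_per_bp is per bp per haploid genome copy per generation, so the diploid
    genome-wide rate is U = 2 · u_per_bp · (deleterious target size).
    ``effective_fraction`` is the share of deleterious mutations with
    s >= s_T, i.e. the complement of the neutral fraction.
    """

    u_per_bp: float
    U_diploid_genomewide: float = 0.0
    u_te_per_bp: float = 0.0
    effective_fraction: float = 1.0

    def __post_init__(self) -> None:
        if min(self.u_per_bp, self.U_diploid_genomewide, self.u_te_per_bp) < 0:
            raise ParameterError("mutation rates must be nonnegative")
        if not 0.0 <= self.effective_fraction <= 1.0:
            raise ParameterError("effective_fraction must lie in [0, 1]")

    @property
    def u_effective(self) -> float:
        """Per-bp deleterious rate relevant for BGS (truncation applied)."""
        return (self.u_per_bp + self.u_te_per_bp) * self.effective_fraction


def make_ddfe(
    family: str,
    *,
    median_s: float | None = None,
    sd_log: float | None = None,
    shape_k: float | None = None,
    mean_s: float | None = None,
    dominance_h: float = 0.5,
    chromosome_scale: float = 1.0,
) -> DDFESpec:
    """Build and validate a :class:`DDFESpec`.

    >>> make_ddfe("lognormal", median_s=2.31e-4, sd_log=5.308).median_s
    0.000231
    """
    return DDFESpec(
        family=family,
        median_s=median_s,
        sd_log=sd_log,
        shape_k=shape_k,
        mean_s=mean_s,
        dominance_h=dominance_h,
        chromosome_scale=chromosome_scale,
    )


def neutral_fraction(ddfe: DDFESpec, threshold: NeutralThreshold) -> float:
    """Fraction of deleterious mutations that are effectively neutral.

    Evaluates the DDFE's cumulative probability below ``threshold.s_T`` on the
    scale at which selection acts; for an X-scaled spec pass the X-linked
    threshold (``NeutralThreshold.x_linked``).  Monotone nondecreasing in s_T.
    """
    return ddfe.cdf(threshold.s_T)


def effective_deleterious_rate(
    u_total: float, ddfe: DDFESpec, threshold: NeutralThreshold
) -> float:
    """Deleterious mutation rate after removing effectively-neutral mass:
    ``u_total × (1 − neutral_fraction)``."""
    if u_total < 0:
        raise ParameterError("u_total must be nonnegative")
    return u_total * (1.0 - neutral_fraction(ddfe, threshold))


class TEInsertionRate(NamedTuple):
    p_seg_per_bp: float
    q_frequency: float
    u_te_per_bp: float


def te_insertion_rate(
    n_exonic_tes: int,
    exonic_bp: int,
    n_chromosomes_sampled: int,
    s_h: float,
) -> TEInsertionRate:
    """Deleterious TE insertion rate from mutation–selection balance.

    For non-recessive strongly deleterious insertions segregating at
    equilibrium frequency q, the probability of observing a segregating TE at
    a bp across n sampled chromosomes is P_seg = n·q, so q = P_seg/n and the
    insertion rate is u_TE = q·s_h.
    """
    if exonic_bp <= 0 or n_chromosomes_sampled <= 0:
        raise ParameterError("exonic_bp and n_chromosomes_sampled must be positive")
    if n_exonic_tes < 0 or s_h <= 0:
        raise ParameterError("n_exonic_tes must be >= 0 and s_h > 0")
    p_seg = n_exonic_tes / exonic_bp
    q = p_seg / n_chromosomes_sampled
    return TEInsertionRate(p_seg_per_bp=p_seg, q_frequency=q, u_te_per_bp=q * s_h)
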