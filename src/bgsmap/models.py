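"""BGS model identifiers and resolved parameter bundles.

A model id has the form ``M_{DDFE},{Mut},{Rec}``:

* DDFE: ``LN`` (log-normal), ``G`` (gamma), or the two-DDFE hybrids ``LN/G``
  / ``G/LN`` (first token applies to nonsynonymous sites, second to
  deleterious noncoding sites);
* Mut: ``StdMut`` (U = 1.2, u = 8.4e-9/bp/generation, includes the TE
  contribution) or ``LowMut`` (U = 0.6, u = 4.2e-9, point mutations and small
  indels only);
* Rec: ``CO+GC`` (crossover plus gene conversion) or ``CO`` (crossover only).

The default model is ``M_LN,StdMut,CO+GC``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


from .annotation import SiteClassConfig
from .ddfe import DDFESpec, MutationRates, NeutralThreshold, make_ddfe, neutral_fraction
from .recmap import GAMMA_GC_DEFAULT, L_GC_DEFAULT

__all__ = ["ModelConfig", "parse_model_id", "VALID_MODEL_IDS", "DEFAULT_MODEL_ID"]

# canonical parameter values
LOGNORMAL_MEDIAN_S = 2.31e-4
LOGNORMAL_SD_LOG = 5.308
GAMMA_SHAPE = 0.3
GAMMA_MEAN_S = 2.5e-3
DOMINANCE_H = 0.5
NE_DEFAULT = 1_000_000.0
U_STD, U_LOW = 1.2, 0.6
U_BP_STD, U_BP_LOW = 8.4e-9, 4.2e-9

DEFAULT_MODEL_ID = "M_LN,StdMut,CO+GC"

_DDFE_TOKENS = ("LN", "G", "LN/G", "G/LN")
_MUT_TOKENS = {"StdMut": (U_STD, U_BP_STD), "LowMut": (U_LOW, U_BP_LOW)}
_REC_TOKENS = {"CO+GC": True, "CO": False}

VALID_MODEL_IDS = tuple(
    f"M_{d},{m},{r}" for d in _DDFE_TOKENS for m in _MUT_TOKENS for r in _REC_TOKENS
)


class ModelUsageError(ValueError):
    """Unparseable model id."""


#: Published full-genome reference values for *D. melanogaster* (FlyBase
#: r5.47 annotation + experimentally derived crossover/gene-conversion maps
#: + DPGP2 Rwanda polymorphism).  These require the external datasets and are
#: recorded for users reproducing the genome-scale analysis; none of them is
#: checked by the desk-scale test suite.
FULL_GENOME_REFERENCE = {
    "median_B_default_model": {"value": 0.591, "desk_scale": False},
    "median_B_trimmed_arms": {"value": 0.643, "desk_scale": False},
    "fraction_1kb_windows_B_below_0.25": {"value": 0.19, "desk_scale": False},
    "xa_predicted_ratio_complete": {"value": 0.99, "desk_scale": False},
    "xa_predicted_ratio_trimmed": {"value": 0.92, "desk_scale": False},
    "median_B_gamma_model": {"value": 0.428, "desk_scale": False},
    "median_genetic_DB90_cM": {"value": 5.5, "desk_scale": False},
}


def _base_ddfe(token: str) -> DDFESpec:
    if token == "LN":
        return make_ddfe(
            "lognormal",
            median_s=LOGNORMAL_MEDIAN_S,
            sd_log=LOGNORMAL_SD_LOG,
            dominance_h=DOMINANCE_H,
        )
    return make_ddfe(
        "gamma", shape_k=GAMMA_SHAPE, mean_s=GAMMA_MEAN_S, dominance_h=DOMINANCE_H
    )


@dataclass(frozen=True)
class ModelConfig:
    """Fully resolved BGS model parameters.

    ``ddfe_aa`` applies to nonsynonymous sites, ``ddfe_nc`` to deleterious
    noncoding (UTR/intron/intergenic) sites; they coincide except for the
    two-DDFE hybrid models.
    """

    model_id: str
    ddfe_aa: DDFESpec
    ddfe_nc: DDFESpec
    U_diploid: float
    u_per_bp: float
    include_gc: bool
    Ne: float = NE_DEFAULT
    gamma_gc: float = GAMMA_GC_DEFAULT
    l_gc: float = L_GC_DEFAULT
    site_classes: SiteClassConfig = field(default_factory=SiteClassConfig)

    def threshold(self, chromosome: str = "autosome") -> NeutralThreshold:
        if chromosome.upper() in ("X", "CHRX"):
            return NeutralThreshold.x_linked(self.Ne)
        return NeutralThreshold.autosomal(self.Ne)

    def ddfe_by_class(self, chromosome: str = "autosome") -> dict:
        """Per-site-class DDFEs, X-scaled when requested."""
        aa, nc = self.ddfe_aa, self.ddfe_nc
        if chromosome.upper() in ("X", "CHRX"):
            aa, nc = aa.for_x_chromosome(), nc.for_x_chromosome()
        return {"aa": aa, "utr": nc, "nc": nc}

    def rates_by_class(self, chromosome: str = "autosome") -> dict:
        """Per-class effective mutation rates (truncation applied)."""
        thr = self.threshold(chromosome)
        specs = self.ddfe_by_class(chromosome)
        return {
            cls: MutationRates(
                u_per_bp=self.u_per_bp,
                U_diploid_genomewide=self.U_diploid,
                effective_fraction=1.0 - neutral_fraction(spec, thr),
            )
            for cls, spec in specs.items()
        }


def parse_model_id(model_id: str) -> ModelConfig:
    """Resolve a model id string into a :class:`ModelConfig`.

    >>> parse_model_id("M_G,LowMut,CO").U_diploid
    0.6
    """
    if not model_id.startswith("M_"):
        raise ModelUsageError(
            f"bad model id {model_id!r}; valid ids: {', '.join(VALID_MODEL_IDS)}"
        )
    parts = model_id[2:].split(",")
    if len(parts) != 3:
        raise ModelUsageError(
            f"bad model id {model_id!r}; expected M_<DDFE>,<Mut>,<Rec>, "
            f"e.g. {', '.join(VALID_MODEL_IDS[:2])}, ... {VALID_MODEL_IDS[-1]}"
        )
    dtok, mtok, rtok = parts
    if dtok not in _DDFE_TOKENS:
        raise ModelUsageError(
            f"unknown DDFE token {dtok!r}; valid: {', '.join(_DDFE_TOKENS)}"
        )
    if mtok not in _MUT_TOKENS:
        raise ModelUsageError(
            f"unknown mutation token {mtok!r}; valid: {', '.join(_MUT_TOKENS)}"
        )
    if rtok not in _REC_TOKENS:
        raise ModelUsageError(
            f"unknown recombination token {rtok!r}; valid: {', '.join(_REC_TOKENS)}"
        )
    aa_tok, nc_tok = (dtok.split("/") + [dtok])[:2] if "/" in dtok else (dtok, dtok)
    U, u_bp = _MUT_TOKENS[mtok]
    return ModelConfig(
        model_id=model_id,
        ddfe_aa=_base_ddfe(aa_tok),
        ddfe_nc=_base_ddfe(nc_tok),
        U_diploid=U,
        u_per_bp=u_bp,
        include_gc=_REC_TOKENS[rtok],
    )
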