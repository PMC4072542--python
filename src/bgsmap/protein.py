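"""Efficacy-of-selection readouts from per-gene molecular evolution tables.

Input is a precomputed table of lineage-specific dN, dS and omega = dN/dS per
gene (e.g. from codeml branch models), plus a BH-corrected q value from an
M1a-vs-M2a positive-selection test.  Genes likely to violate the
nearly-neutral assumption are removed (short CDS, sparse alignment,
premature stops, positive selection, omega > 0.75), omega is regressed on dS
separately for autosomes and the X (omega_R: residual efficacy of purifying
selection after controlling for mutation/coalescent-time variation through
dS), and omega_R is correlated with the local strength of background
selection B.  A negative rank correlation indicates reduced efficacy of
selection where linked selection depresses effective population size
(Hill-Robertson interference).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .bgs import BLandscape

__all__ = ["filter_genes", "omega_residuals", "correlate_b_omega", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = (
    "gene_id",
    "chrom",
    "midpoint",
    "cds_length_bp",
    "aligned_aa",
    "dN",
    "dS",
    "omega",
    "premature_stop",
    "positive_selection_q",
)

MIN_CDS_LENGTH = 450
MIN_ALIGNED_AA = 100
MAX_OMEGA = 0.75
POSITIVE_SELECTION_Q = 0.05


class GeneTableError(ValueError):
    """Missing columns or degenerate gene table."""


def filter_genes(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the gene filters in order; returns (retained, removal audit).

    Rules (a gene is counted under the first rule it violates):
    cds_length_bp < 450; aligned_aa < 100; premature_stop; positive-selection
    q < 0.05; omega > 0.75.
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise GeneTableError(f"gene table missing columns {sorted(missing)}")
    df = records.copy()
    audit: dict[str, int] = {}
    rules = [
        ("cds_length", df["cds_length_bp"] < MIN_CDS_LENGTH),
        ("aligned_aa", df["aligned_aa"] < MIN_ALIGNED_AA),
        ("premature_stop", df["premature_stop"].astype(bool)),
        ("positive_selection", df["positive_selection_q"] < POSITIVE_SELECTION_Q),
        ("high_omega", df["omega"] > MAX_OMEGA),
    ]
    removed = np.zeros(len(df), dtype=bool)
    for name, mask in rules:
        new = mask.to_numpy() & ~removed
        audit[name] = int(new.sum())
        removed |= new
    audit["retained"] = int((~removed).sum())
    return df[~removed].reset_index(drop=True), audit


def omega_residuals(records: pd.DataFrame, group_column: str = "chrom_group") -> pd.DataFrame:
    """Add ``omega_R``: least-squares residuals of omega on dS, fitted per
    chromosome group (autosome / X) separately.

    When ``group_column`` is absent, a single fit over all genes is used.
    """
    df = records.copy()
    groups = (
        df.groupby(group_column, group_keys=False)
        if group_column in df.columns
        else [(None, df)]
    )
    df["omega_R"] = np.nan
    iterable = groups if isinstance(groups, list) else list(groups)
    for _, sub in iterable:
        if len(sub) < 10:
            raise GeneTableError("need >= 10 genes per group for omega_R")
        if np.ptp(sub["dS"].to_numpy()) == 0:
            raise GeneTableError("dS constant within group; fit degenerate")
        res = sm.OLS(sub["omega"], sm.add_constant(sub["dS"])).fit()
        df.loc[sub.index, "omega_R"] = res.resid
    return df


def correlate_b_omega(
    records: pd.DataFrame,
    landscape: BLandscape,
    aggregation: str = "gene",
    window_size: int = 100_000,
) -> dict:
    """Spearman correlation between omega_R and B.

    ``gene`` aggregation looks B up at each gene's midpoint window; ``100kb``
    first averages omega_R and B within 100-kb windows.  Genes whose midpoint
    falls outside the landscape are excluded (count reported).
    """
    if "omega_R" not in records.columns:
        raise GeneTableError("run omega_residuals first")
    df = records[records["chrom"] == landscape.chromosome].copy()
    span_end = landscape.window_starts[-1] + landscape.window_size
    inside = (df["midpoint"] >= landscape.window_starts[0]) & (df["midpoint"] < span_end)
    n_unmapped = int((~inside).sum())
    df = df[inside]
    idx = (
        (df["midpoint"].to_numpy() - landscape.window_starts[0])
        // landscape.window_size
    ).astype(int)
    df["B"] = landscape.b[idx]
    if aggregation == "100kb":
        df["win"] = df["midpoint"] // window_size
        agg = df.groupby("win")[["omega_R", "B"]].mean()
        x, y = agg["B"].to_numpy(), agg["omega_R"].to_numpy()
    elif aggregation == "gene":
        x, y = df["B"].to_numpy(), df["omega_R"].to_numpy()
    else:
        raise ValueError("aggregation must be 'gene' or '100kb'")
    if len(x) < 5:
        raise GeneTableError("too few mapped genes for correlation")
    rho, p = stats.spearmanr(x, y)
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(p),
        "n": int(len(x)),
        "n_unmapped": n_unmapped,
        "aggregation": aggregation,
    }
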