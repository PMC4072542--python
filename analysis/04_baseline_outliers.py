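#!/usr/bin/env python
"""Fit the B baseline to observed diversity and flag outlier windows.

Regresses window silent diversity on B (OLS; the slope estimates theta0),
computes externally studentized residuals (pi_sil-R) with two-sided t
probabilities, checks residual normality with a 24-bin chi-square, applies
Benjamini-Hochberg FDR at q = 0.10, and reports the concordance between
pi_sil-R and Tajima's D/Dmin.
"""

import argparse
from pathlib import Path

from bgsmap import io
from bgsmap.outliers import concordance, fit_baseline, normality_check, outlier_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--diversity", type=Path,
                    default=Path("results/diversity/window_diversity_1kb.tsv"))
    ap.add_argument("--b-track", type=Path,
                    default=Path("results/b_tracks/B_M_LN,StdMut,CO+GC.tsv"))
    ap.add_argument("--fdr", type=float, default=0.10)
    ap.add_argument("--outdir", type=Path, default=Path("results/outliers"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    landscape = io.read_b_track(args.b_track)
    div = io.read_table(args.diversity)
    div = div[div["included"]].reset_index(drop=True)
    div["B"] = landscape.b[(div["start"] // landscape.window_size).astype(int)]

    fit = fit_baseline(div["pi_sil"].to_numpy(), div["B"].to_numpy())
    print(f"baseline fit over {fit.n} windows: pi_sil = "
          f"{fit.intercept:.5f} + {fit.slope:.5f} x B "
          f"(slope se {fit.slope_se:.5f})")
    tab = outlier_table(div, fit, q_level=args.fdr)
    io.write_table(tab, args.outdir / "outlier_table_1kb.tsv",
                   model_id=landscape.model_id)

    chi2, dof, p = normality_check(tab["pi_sil_R"].to_numpy())
    print(f"residual normality: chi2 = {chi2:.1f}, d.f. = {dof}, P = {p:.3f}")
    n_def = int((tab["flag"] == "deficit").sum())
    n_exc = int((tab["flag"] == "excess").sum())
    n_q = int(tab["q_pass"].sum())
    print(f"outliers at nominal P<0.05: {n_def} deficit, {n_exc} excess; "
          f"{n_q} pass BH q<{args.fdr}")
    print("windows passing FDR:")
    cols = ["start", "pi_sil", "B", "pi_sil_R", "P", "q", "flag"]
    print(tab.loc[tab["q_pass"], cols].to_string(index=False))
    conc = concordance(tab["pi_sil_R"].to_numpy(), tab["tajima_d_norm"].to_numpy(),
                       tab["flag"].to_numpy())
    print(f"rho(pi_sil-R, D/Dmin) = {conc['spearman_rho']:.3f} "
          f"(P = {conc['spearman_p']:.2e})")


if __name__ == "__main__":
    main()
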