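"""Mutation-versus-selection diagnostics for codon usage.

Three classic genome-level reads on what drives codon bias:

* **Neutrality plot** — per-gene GC12 regressed on GC3.  A slope near 1
  with a significant correlation says directional mutation pressure moves
  all three codon positions together; a slope near 0 says selection (or
  any position-specific force) decouples the third position.
* **ENC-GC3s plot** — observed ENC against Wright's expectation under
  mutation alone, ENC_exp = 2 + s + 29 / (s^2 + (1 - s)^2); genes falling
  on the curve are compatible with pure compositional bias, genes well
  below it show selected codon preferences.  ENC_ratio quantifies the
  per-gene deficit: (ENC_exp - ENC_obs) / ENC_exp.
* **PR2-bias plot** — A3/(A3+T3) versus G3/(G3+C3); under strand-symmetric
  mutation and no selection both should sit at 0.5.

The functions report coordinates and fits; interpretation stays with the
analyst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CORR_INDICES = ["cai", "cbi", "fop", "gravy", "aromo", "enc",
                "gc1", "gc2", "gc3", "gc3s", "gc"]


@dataclass
class NeutralityFit:
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n_genes: int


def neutrality_fit(table: pd.DataFrame) -> NeutralityFit:
    """OLS of GC12 on GC3 across the genes of one genome."""
    sub = table[["gc12", "gc3"]].dropna()
    if len(sub) < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    if np.isclose(sub["gc3"].var(ddof=0), 0.0):
        raise ValueError("GC3 is constant; regression on GC3 is degenerate")
    if np.isclose(sub["gc12"].var(ddof=0), 0.0):
        # constant response: flat fit, no correlation
        return NeutralityFit(
            slope=0.0, intercept=float(sub["gc12"].mean()),
            r=0.0, r_squared=0.0, p_value=1.0, n_genes=len(sub),
        )
    res = stats.linregress(sub["gc3"], sub["gc12"])
    return NeutralityFit(
        slope=res.slope,
        intercept=res.intercept,
        r=res.rvalue,
        r_squared=res.rvalue ** 2,
        p_value=res.pvalue,
        n_genes=len(sub),
    )


def enc_expected(gc3s: float | np.ndarray) -> float | np.ndarray:
    """Wright's expected ENC under mutation bias alone at silent-site G+C s."""
    s = np.asarray(gc3s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("GC3s must lie in [0, 1]")
    out = 2.0 + s + 29.0 / (s ** 2 + (1.0 - s) ** 2)
    return float(out) if np.isscalar(gc3s) else out


def enc_ratio(enc_obs: float | np.ndarray, gc3s: float | np.ndarray):
    """(ENC_exp - ENC_obs) / ENC_exp; positive = fewer codons used than expected."""
    exp = enc_expected(gc3s)
    return (exp - np.asarray(enc_obs, dtype=float)) / exp


def enc_curve_points(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene GC3s, observed ENC, expected ENC and ENC_ratio."""
    out = table[["gc3s", "enc"]].rename(columns={"enc": "enc_obs"}).copy()
    valid = out["gc3s"].notna()
    out["enc_exp"] = np.nan
    out.loc[valid, "enc_exp"] = enc_expected(out.loc[valid, "gc3s"].to_numpy())
    out["enc_ratio"] = (out["enc_exp"] - out["enc_obs"]) / out["enc_exp"]
    return out


def pr2_points(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """PR2-bias coordinates per gene plus quadrant occupancy fractions.

    Genes with a zero denominator are flagged (``valid == False``) and
    excluded from the quadrant summary.
    """
    at = table["a3"] + table["t3"]
    gc = table["g3"] + table["c3"]
    out = pd.DataFrame(index=table.index)
    out["x"] = np.where(gc > 0, table["g3"] / gc.replace(0, np.nan), np.nan)
    out["y"] = np.where(at > 0, table["a3"] / at.replace(0, np.nan), np.nan)
    out["valid"] = (at > 0) & (gc > 0)

    def quadrant(row):
        if not row["valid"]:
            return "undefined"
        return ("G" if row["x"] > 0.5 else "C") + ("A" if row["y"] > 0.5 else "T")

    out["quadrant"] = out.apply(quadrant, axis=1)
    occ = (
        out.loc[out["valid"], "quadrant"].value_counts(normalize=True)
        .reindex(["GA", "GT", "CA", "CT"], fill_value=0.0)
    )
    return out, occ


def index_correlations(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations among the CUB indices, long format.

    Emits r, the two-sided p, significance flags at 0.05 and 0.01, and a
    Benjamini-Hochberg adjusted q per pair.  Zero-variance columns (AROMO
    can be near-constant) yield NaN rows rather than errors.
    """
    cols = [c for c in (columns or CORR_INDICES) if c in table.columns]
    if len(table) < 3:
        raise ValueError("correlation matrix needs at least 3 genes")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = table[[a, b]].dropna()
            if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(sub[a], sub[b])
            rows.append({"index_a": a, "index_b": b, "r": r, "p": p})
    df = pd.DataFrame(rows)
    mask = df["p"].notna()
    df["q_bh"] = np.nan
    if mask.any():
        df.loc[mask, "q_bh"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    df["sig_05"] = df["p"] < 0.05
    df["sig_01"] = df["p"] < 0.01
    return df
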