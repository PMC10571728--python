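"""One-vs-rest differential abundance at the peptide level.

Each cancer's patients are tested against all other patients (restricted
to the relevant sex for sex-specific cancers) with a two-sided t test on
log2 concentrations — Welch by default, pooled-variance behind a flag.
P values are Bonferroni-adjusted within each comparison and a peptide is
significant iff the adjusted p falls below alpha (default 0.0005).
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import SEX_RESTRICTED_CANCERS

DE_COLUMNS = [
    "comparison", "peptide", "protein", "n_case", "n_rest",
    "mean_case", "mean_rest", "log2_fc", "t_stat", "df",
    "p_raw", "p_adj", "significant",
]


def one_vs_rest(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    alpha: float = 0.0005,
    sex_restriction: Optional[Dict[str, str]] = None,
    welch: bool = True,
    peptide_protein: Optional[pd.Series] = None,
    family: str = "per_comparison",
) -> pd.DataFrame:
    """Run every one-vs-rest comparison.

    Parameters
    ----------
    matrix:
        Samples x peptides concentrations (linear scale, pmol/uL); values
        are log2-transformed internally.  Pools are excluded via the
        manifest.
    sex_restriction:
        cancer -> sex map; for those cancers both case and rest groups are
        restricted to that sex.  Defaults to the standard map (prostate
        male; breast/ovarian/endometrial/cervical female).
    family:
        ``per_comparison`` (default) multiplies p by the number of peptides
        tested within the comparison; ``global`` by the total number of
        tests across all comparisons.
    """
    if sex_restriction is None:
        sex_restriction = dict(SEX_RESTRICTED_CANCERS)
    if family not in ("per_comparison", "global"):
        raise ValueError(f"unknown Bonferroni family {family!r}")

    mani = manifest.set_index("sample_id")
    patients = [s for s in matrix.index
                if s in mani.index and mani.loc[s, "sample_type"] == "patient"]
    data = np.log2(matrix.loc[patients])
    cancer = mani.loc[patients, "cancer"]
    sex = mani.loc[patients, "sex"]

    results: List[dict] = []
    for c in sorted(cancer.unique()):
        restrict = sex_restriction.get(c)
        eligible = np.ones(len(patients), dtype=bool)
        if restrict is not None:
            eligible = (sex == restrict).to_numpy()
        is_case = (cancer == c).to_numpy() & eligible
        is_rest = (cancer != c).to_numpy() & eligible
        case = data.loc[is_case]
        rest = data.loc[is_rest]
        if is_case.sum() == 0 or is_rest.sum() == 0:
            continue

        for pep in data.columns:
            a = case[pep].dropna().to_numpy()
            b = rest[pep].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            res = stats.ttest_ind(a, b, equal_var=not welch)
            results.append({
                "comparison": c,
                "peptide": pep,
                "protein": peptide_protein.get(pep, "") if peptide_protein is not None else "",
                "n_case": len(a),
                "n_rest": len(b),
                "mean_case": float(a.mean()),
                "mean_rest": float(b.mean()),
                "log2_fc": float(a.mean() - b.mean()),
                "t_stat": float(res.statistic),
                "df": float(res.df),
                "p_raw": float(res.pvalue),
            })

    de = pd.DataFrame(results)
    if de.empty:
        return pd.DataFrame(columns=DE_COLUMNS)

    if family == "per_comparison":
        m = de.groupby("comparison")["peptide"].transform("size")
    else:
        m = len(de)
    de["p_adj"] = np.minimum(de["p_raw"] * m, 1.0)
    de["significant"] = de["p_adj"] < alpha
    return de[DE_COLUMNS]


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot input: log2 fold change vs -log10 adjusted p."""
    out = results[["comparison", "peptide", "protein", "log2_fc",
                   "p_adj", "significant"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p_adj"] = -np.log10(out["p_adj"])
    return out


def network_edge_table(results: pd.DataFrame) -> pd.DataFrame:
    """One edge per (cancer, protein) with at least one significant
    peptide; direction is the sign of the fold change, and the number of
    supporting peptides is retained."""
    sig = results.loc[results["significant"]]
    if sig.empty:
        return pd.DataFrame(columns=["cancer", "protein", "direction", "n_peptides"])
    edges = (
        sig.groupby(["comparison", "protein"], observed=True)
        .agg(n_peptides=("peptide", "size"), mean_fc=("log2_fc", "mean"))
        .reset_index()
        .rename(columns={"comparison": "cancer"})
    )
    edges["direction"] = np.where(edges["mean_fc"] > 0, "up", "down")
    return edges[["cancer", "protein", "direction", "n_peptides"]]
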