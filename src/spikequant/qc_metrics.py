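"""Assay-performance statistics from pool replicates and patient spread.

Three statistics summarise the run: the intra-assay coefficient of
variation of the pool injections (per plate and across all plates), the
pairwise Pearson correlation of pool injections on log10 concentrations,
and the normalized inter-individual IQR of patient concentrations.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd


def _pool_ids(matrix: pd.DataFrame, manifest: pd.DataFrame) -> List[str]:
    mani = manifest.set_index("sample_id")
    return [s for s in matrix.index
            if s in mani.index and mani.loc[s, "sample_type"] == "pool"]


def _cv_percent(values: pd.DataFrame) -> pd.Series:
    """Per-column CV = sd/mean * 100 (sample sd, ddof=1), NaN-aware.
    Columns with <2 observations give NaN."""
    n = values.notna().sum(axis=0)
    mean = values.mean(axis=0, skipna=True)
    sd = values.std(axis=0, ddof=1, skipna=True)
    cv = sd / mean * 100.0
    return cv.where(n >= 2)


def intra_assay_cv(
    matrix: pd.DataFrame, manifest: pd.DataFrame
) -> Dict[str, object]:
    """Pool-replicate CV summaries.

    Per plate: CV of each peptide over that plate's pool injections, then
    the median across peptides.  Overall: CV of each peptide over ALL pool
    injections pooled across plates, then the median — deliberately a
    cross-plate statistic, which is why it exceeds every per-plate median
    when plate effects are present.
    """
    pool_ids = _pool_ids(matrix, manifest)
    pools = matrix.loc[pool_ids]
    mani = manifest.set_index("sample_id")

    per_plate: Dict[str, float] = {}
    for plate, grp in pools.groupby(mani.loc[pool_ids, "plate"].to_numpy()):
        if len(grp) < 2:
            warnings.warn(f"plate {plate}: fewer than 2 pool injections, skipped")
            continue
        per_plate[str(plate)] = float(_cv_percent(grp).median(skipna=True))

    overall = float(_cv_percent(pools).median(skipna=True)) if len(pools) >= 2 else np.nan
    return {
        "per_plate_median_cv": per_plate,
        "median_of_plate_medians": float(np.median(list(per_plate.values())))
        if per_plate else np.nan,
        "overall_median_cv": overall,
        "n_pool_injections": len(pools),
    }


def pool_correlation(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    min_shared: int = 3,
) -> Dict[str, object]:
    """Pearson correlation between every pair of pool injections over the
    log10 concentrations of their shared quantified peptides."""
    pool_ids = _pool_ids(matrix, manifest)
    if len(pool_ids) < 2:
        raise ValueError("pool_correlation needs at least 2 pool injections")
    logs = np.log10(matrix.loc[pool_ids])

    pairs: List[Tuple[str, str, float]] = []
    arr = logs.to_numpy()
    for i in range(len(pool_ids)):
        for j in range(i + 1, len(pool_ids)):
            shared = np.isfinite(arr[i]) & np.isfinite(arr[j])
            if shared.sum() < min_shared:
                warnings.warn(
                    f"pool pair ({pool_ids[i]}, {pool_ids[j]}): "
                    f"<{min_shared} shared peptides, skipped")
                continue
            r = float(np.corrcoef(arr[i, shared], arr[j, shared])[0, 1])
            pairs.append((pool_ids[i], pool_ids[j], r))
    rs = [r for _, _, r in pairs]
    return {
        "pairwise": pairs,
        "median_r": float(np.median(rs)) if rs else np.nan,
        "n_pairs": len(pairs),
    }


def normalized_iqr(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    method: str = "ratio",
    min_values: int = 4,
) -> Dict[str, object]:
    """Per-protein dispersion of patient concentrations.

    ``method="ratio"`` (default) defines nIQR = Q3/Q1, a fold-change-scale
    statistic with nIQR >= 1; ``method="diff"`` uses (Q3-Q1)/median.
    Quartiles use linear interpolation between order statistics.  Pools
    are excluded; proteins with fewer than ``min_values`` patient values
    are skipped.
    """
    if method not in ("ratio", "diff"):
        raise ValueError(f"unknown nIQR method {method!r}")
    mani = manifest.set_index("sample_id")
    patients = [s for s in matrix.index
                if s in mani.index and mani.loc[s, "sample_type"] == "patient"]
    data = matrix.loc[patients]

    per_protein: Dict[str, float] = {}
    for col in data.columns:
        vals = data[col].dropna().to_numpy()
        if len(vals) < min_values:
            warnings.warn(f"{col}: <{min_values} patient values, skipped")
            continue
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        if method == "ratio":
            per_protein[col] = float(q3 / q1) if q1 > 0 else np.nan
        else:
            per_protein[col] = float((q3 - q1) / med) if med != 0 else np.nan
    vals = [v for v in per_protein.values() if np.isfinite(v)]
    return {
        "per_protein": per_protein,
        "median_niqr": float(np.median(vals)) if vals else np.nan,
        "method": method,
        "n_proteins": len(per_protein),
    }


def qc_report(
    peptide_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    sample_qc: pd.DataFrame | None = None,
    niqr_method: str = "ratio",
) -> Dict[str, object]:
    """Assemble the full QC report dictionary (JSON-serialisable)."""
    cv = intra_assay_cv(peptide_matrix, manifest)
    corr = pool_correlation(peptide_matrix, manifest)
    niqr = normalized_iqr(protein_matrix, manifest, method=niqr_method)
    report = {
        "intra_assay_cv": cv,
        "pool_correlation": {
            "median_r": corr["median_r"],
            "n_pairs": corr["n_pairs"],
        },
        "normalized_iqr": {
            "median_niqr": niqr["median_niqr"],
            "method": niqr["method"],
            "n_proteins": niqr["n_proteins"],
            "per_protein": niqr["per_protein"],
        },
    }
    if sample_qc is not None:
        failed = sample_qc.loc[~sample_qc["passed"]]
        report["excluded_samples"] = dict(zip(failed["sample_id"], failed["reasons"]))
    return report
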