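"""Spike-in quantification core.

Pairs light/heavy transitions, computes summed-area ratios to standard,
recomputes the ratio dot product, applies the score/ratio filters, runs the
anchor-peptide retention-time regression and sample-level QC, converts
ratios to absolute concentrations via the spiked amounts, applies the
peptide quantification-rate filter and pool-based median normalization,
and rolls peptides up to proteins.

Every stage logs how many records it removed and why; the per-stage counts
are additive so the full provenance can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats


class QuantError(ValueError):
    pass


@dataclass
class FilterThresholds:
    """Peptide-level acceptance thresholds; all comparisons are strict."""

    min_rdotp: float = 0.7
    min_dotp: float = 0.5
    ratio_low: float = 0.01
    ratio_high: float = 1000.0


@dataclass
class QuantParams:
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    min_proteins: int = 120
    min_irt_r2: float = 0.99
    min_anchors: int = 6
    min_quant_rate: float = 0.5
    normalize: bool = True


@dataclass
class QuantResult:
    quants: pd.DataFrame                 # per sample x peptide with status
    peptide_matrix: pd.DataFrame         # normalized, samples x peptides
    peptide_matrix_raw: pd.DataFrame     # pre-normalization
    protein_matrix: pd.DataFrame
    irt_fits: pd.DataFrame
    sample_qc: pd.DataFrame              # sample_id, passed, reasons
    normalization_factors: Optional[pd.DataFrame]
    peptide_protein: pd.Series           # peptide -> protein
    provenance: Dict


# ----------------------------------------------------------------------
# Pairing and per-peptide summaries
# ----------------------------------------------------------------------

_PAIR_KEY = ["sample_id", "protein", "peptide", "precursor_charge",
             "fragment", "product_charge"]


def pair_transitions(records: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Keep transitions whose (fragment, product charge) has a present,
    positive area in BOTH channels of the same sample x peptide.

    Returns
    -------
    paired:
        One row per kept transition with ``light_area`` and ``heavy_area``.
    dropped:
        Input rows that did not pair, with a ``drop_reason`` column
        (``missing_area``, ``zero_area`` or ``unpaired``).
    """
    rec = records.copy()
    usable = rec["area"].notna() & (rec["area"] > 0)
    reason = np.where(rec["area"].isna(), "missing_area", "zero_area")

    wide = (
        rec.loc[usable]
        .pivot_table(index=_PAIR_KEY, columns="label", values="area",
                     aggfunc="first", observed=True)
    )
    for ch in ("light", "heavy"):
        if ch not in wide.columns:
            wide[ch] = np.nan
    both = wide["light"].notna() & wide["heavy"].notna()
    paired = wide.loc[both, ["light", "heavy"]].reset_index()
    paired.columns = _PAIR_KEY + ["light_area", "heavy_area"]

    paired_keys = set(map(tuple, paired[_PAIR_KEY].itertuples(index=False)))
    key_tuples = map(tuple, rec[_PAIR_KEY].itertuples(index=False))
    in_pair = np.fromiter((k in paired_keys for k in key_tuples),
                          dtype=bool, count=len(rec))
    is_paired = in_pair & usable.to_numpy()
    drop_reason = np.where(usable.to_numpy(), "unpaired", reason)
    dropped = rec.loc[~is_paired].copy()
    dropped["drop_reason"] = drop_reason[~is_paired]
    return paired, dropped


def compute_ratio(light: np.ndarray, heavy: np.ndarray) -> Tuple[float, float, float]:
    """Summed-area ratio over paired transitions: L, H and r = L/H."""
    light = np.asarray(light, dtype=float)
    heavy = np.asarray(heavy, dtype=float)
    if light.size == 0:
        raise QuantError("compute_ratio needs at least one paired transition")
    L = float(light.sum())
    H = float(heavy.sum())
    if H == 0:
        raise QuantError("undefined ratio: summed heavy area is 0")
    return L, H, L / H


def compute_rdotp(light: np.ndarray, heavy: np.ndarray) -> float:
    """Cosine similarity between the paired light and heavy area vectors."""
    light = np.asarray(light, dtype=float)
    heavy = np.asarray(heavy, dtype=float)
    norm = np.linalg.norm(light) * np.linalg.norm(heavy)
    if norm == 0:
        return 0.0
    return float(np.dot(light, heavy) / norm)


def summarize_peptides(records: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per sample x peptide summary: paired counts, summed areas, ratio,
    recomputed rdotp and the input (light-channel) dotp.

    Anchor-only or entirely unpaired peptides appear with zero pairs so the
    downstream filter can reject them with reason ``no_pairs``.

    Returns (quants, dropped_transitions).
    """
    paired, dropped = pair_transitions(records)

    group_cols = ["sample_id", "protein", "peptide"]
    if len(paired):
        g = paired.assign(
            lh=paired["light_area"] * paired["heavy_area"],
            l2=paired["light_area"] ** 2,
            h2=paired["heavy_area"] ** 2,
        ).groupby(group_cols, observed=True)
        agg = g.agg(
            n_pairs=("light_area", "size"),
            light_sum=("light_area", "sum"),
            heavy_sum=("heavy_area", "sum"),
            lh=("lh", "sum"), l2=("l2", "sum"), h2=("h2", "sum"),
        ).reset_index()
        denom = np.sqrt(agg["l2"] * agg["h2"])
        agg["rdotp"] = np.where(denom > 0, agg["lh"] / denom, 0.0)
        agg["ratio"] = np.where(agg["heavy_sum"] > 0,
                                agg["light_sum"] / agg["heavy_sum"], np.nan)
        agg = agg.drop(columns=["lh", "l2", "h2"])
    else:
        agg = pd.DataFrame(columns=group_cols + [
            "n_pairs", "light_sum", "heavy_sum", "rdotp", "ratio"])

    # Every sample x peptide seen in the input, paired or not.
    universe = records[group_cols].drop_duplicates()
    quants = universe.merge(agg, on=group_cols, how="left")
    quants["n_pairs"] = quants["n_pairs"].fillna(0).astype(int)
    for c in ("light_sum", "heavy_sum"):
        quants[c] = quants[c].fillna(0.0)

    light_dotp = (
        records.loc[records["label"] == "light"]
        .groupby(group_cols, observed=True)["dotp"].median()
        .rename("dotp").reset_index()
    )
    quants = quants.merge(light_dotp, on=group_cols, how="left")
    return quants, dropped


# ----------------------------------------------------------------------
# Filters
# ----------------------------------------------------------------------

def filter_peptides(
    quants: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
) -> pd.DataFrame:
    """Set status to ``quantified`` iff rdotp > min_rdotp AND
    dotp > min_dotp AND ratio_low < r < ratio_high (strict inequalities);
    rejected rows carry their reason code(s), semicolon-joined."""
    t = thresholds or FilterThresholds()
    q = quants.copy()

    no_pairs = (q["n_pairs"] == 0) | q["ratio"].isna()
    low_rdotp = ~no_pairs & ~(q["rdotp"] > t.min_rdotp)
    low_dotp = ~(q["dotp"] > t.min_dotp)  # NaN dotp fails the strict test
    out_of_bounds = ~no_pairs & ~((q["ratio"] > t.ratio_low) & (q["ratio"] < t.ratio_high))

    reasons = []
    for np_, lr, ld, ob in zip(no_pairs, low_rdotp, low_dotp, out_of_bounds):
        codes = []
        if np_:
            codes.append("no_pairs")
        if lr:
            codes.append("low_rdotp")
        if ld:
            codes.append("low_dotp")
        if ob:
            codes.append("ratio_out_of_bounds")
        reasons.append(";".join(codes))
    q["reasons"] = reasons
    q["status"] = np.where(q["reasons"] == "", "quantified", "rejected")
    return q


def fit_irt_regression(
    records: pd.DataFrame,
    anchor_peptides: Optional[List[str]] = None,
) -> pd.DataFrame:
    """Per-sample OLS of measured retention time on reference iRT over the
    detected anchor peptides.

    Anchors default to every peptide with a non-null ``irt_ref``.  Samples
    with fewer than 2 detected anchors get NaN slope/R2 (regression
    undefined).  Returns columns
    ``sample_id, slope, intercept, r2, n_anchors``.
    """
    anchors = records.loc[records["irt_ref"].notna() & records["rt_min"].notna()]
    if anchor_peptides is not None:
        anchors = anchors.loc[anchors["peptide"].isin(anchor_peptides)]
    anchors = anchors.loc[anchors["label"] == "light"]

    rows = []
    for sid, grp in anchors.groupby("sample_id", observed=True):
        x = grp["irt_ref"].to_numpy(dtype=float)
        y = grp["rt_min"].to_numpy(dtype=float)
        n = len(x)
        if n < 2 or np.ptp(x) == 0:
            rows.append({"sample_id": sid, "slope": np.nan, "intercept": np.nan,
                         "r2": np.nan, "n_anchors": n})
            continue
        fit = stats.linregress(x, y)
        rows.append({"sample_id": sid, "slope": fit.slope,
                     "intercept": fit.intercept, "r2": fit.rvalue ** 2,
                     "n_anchors": n})
    return pd.DataFrame(rows, columns=["sample_id", "slope", "intercept",
                                       "r2", "n_anchors"])


def qc_samples(
    quants: pd.DataFrame,
    manifest: pd.DataFrame,
    irt_fits: pd.DataFrame,
    min_proteins: int = 120,
    min_r2: float = 0.99,
    min_anchors: int = 6,
) -> pd.DataFrame:
    """Sample-level QC: a sample fails iff its anchor regression fails
    (R2 below threshold or too few anchors) or it has fewer than
    ``min_proteins`` distinct quantified proteins.

    If the dataset carries no anchor information at all the iRT criterion
    is disabled.  Returns columns ``sample_id, passed, n_proteins, reasons``.
    """
    quantified = quants.loc[quants["status"] == "quantified"]
    prot_counts = quantified.groupby("sample_id", observed=True)["protein"].nunique()

    have_irt = len(irt_fits) > 0
    irt = irt_fits.set_index("sample_id") if have_irt else None

    rows = []
    for sid in manifest["sample_id"]:
        reasons = []
        n_prot = int(prot_counts.get(sid, 0))
        if have_irt:
            if sid not in irt.index:
                reasons.append("irt_no_anchors")
            else:
                r = irt.loc[sid]
                if r["n_anchors"] < min_anchors:
                    reasons.append("irt_too_few_anchors")
                elif not (r["r2"] >= min_r2):
                    reasons.append("irt_poor_fit")
        if n_prot < min_proteins:
            reasons.append("too_few_proteins")
        rows.append({"sample_id": sid, "passed": not reasons,
                     "n_proteins": n_prot, "reasons": ";".join(reasons)})
    return pd.DataFrame(rows)


def filter_by_quant_rate(matrix: pd.DataFrame, min_rate: float = 0.5) -> pd.DataFrame:
    """Drop peptides quantified in less than ``min_rate`` of the retained
    samples (strict: a rate exactly at the threshold is kept)."""
    if len(matrix) == 0:
        return matrix
    rate = matrix.notna().mean(axis=0)
    return matrix.loc[:, rate >= min_rate]


# ----------------------------------------------------------------------
# Absolute concentrations and normalization
# ----------------------------------------------------------------------

def to_absolute(
    quants: pd.DataFrame, panel: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.Series]:
    """Convert ratios to concentrations C = r * S_p and pivot to a wide
    samples x peptides matrix.  Only ``quantified`` rows contribute;
    a quantified peptide missing from the panel is a configuration error.

    Returns (matrix, peptide -> protein map).
    """
    q = quants.loc[quants["status"] == "quantified"].copy()
    spike = panel.set_index("peptide")["spike_conc_pmol_per_ul"]
    unknown = set(q["peptide"]) - set(spike.index)
    if unknown:
        raise QuantError(
            f"quantified peptide(s) absent from the spike panel: "
            f"{sorted(unknown)[:5]}")
    q["conc"] = q["ratio"].to_numpy() * spike.loc[q["peptide"]].to_numpy()
    matrix = q.pivot_table(index="sample_id", columns="peptide", values="conc",
                           aggfunc="first", observed=True)
    matrix.columns.name = None
    pep_prot = panel.set_index("peptide")["protein"]
    return matrix, pep_prot


def median_normalize(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    return_factors: bool = False,
):
    """Pool-based per-peptide, per-plate median normalization.

    For each peptide and plate the factor is (global median over ALL pool
    injections) / (median over that plate's pool injections); every value
    of the peptide on that plate is multiplied by it.  Peptides with no
    usable pool median on a plate get factor 1.
    """
    mani = manifest.set_index("sample_id")
    pool_ids = [s for s in matrix.index if mani.loc[s, "sample_type"] == "pool"]
    if not pool_ids:
        raise QuantError("median_normalize requires pool samples in the matrix")

    pools = matrix.loc[pool_ids]
    global_median = pools.median(axis=0, skipna=True)

    plates = mani.loc[matrix.index, "plate"]
    out = matrix.copy()
    factor_rows = []
    for plate, idx in matrix.groupby(plates.to_numpy()).groups.items():
        plate_pools = [s for s in idx if s in pools.index]
        if plate_pools:
            plate_median = matrix.loc[plate_pools].median(axis=0, skipna=True)
            factor = global_median / plate_median
        else:
            factor = pd.Series(np.nan, index=matrix.columns)
        factor = factor.where(np.isfinite(factor) & (factor > 0), 1.0)
        out.loc[idx] = matrix.loc[idx] * factor
        factor_rows.append(pd.Series(factor, name=plate))
    factors = pd.DataFrame(factor_rows)
    factors.index.name = "plate"
    if return_factors:
        return out, factors
    return out


def rollup_protein(matrix: pd.DataFrame, peptide_protein: pd.Series) -> pd.DataFrame:
    """Protein concentration per sample = median over the protein's
    quantified peptides (NaN when none)."""
    prot_of = peptide_protein.loc[[p for p in matrix.columns
                                   if p in peptide_protein.index]]
    out = matrix[prot_of.index].T.groupby(prot_of).median().T
    out.columns.name = None
    return out


# ----------------------------------------------------------------------
# Pipeline
# ----------------------------------------------------------------------

def run_quantification(
    records: pd.DataFrame,
    panel: pd.DataFrame,
    manifest: pd.DataFrame,
    params: QuantParams | None = None,
) -> QuantResult:
    """Run the full post-processing chain on a transition report."""
    params = params or QuantParams()

    quants, dropped = summarize_peptides(records)
    quants = filter_peptides(quants, params.thresholds)

    irt_fits = fit_irt_regression(records)
    sample_qc = qc_samples(
        quants, manifest, irt_fits,
        min_proteins=params.min_proteins,
        min_r2=params.min_irt_r2,
        min_anchors=params.min_anchors,
    )
    passed = sample_qc.loc[sample_qc["passed"], "sample_id"]

    matrix_all, pep_prot = to_absolute(quants, panel)
    matrix = matrix_all.loc[matrix_all.index.intersection(passed)]
    n_pep_before_rate = matrix.shape[1]
    matrix = filter_by_quant_rate(matrix, params.min_quant_rate)

    factors = None
    if params.normalize:
        normalized, factors = median_normalize(matrix, manifest, return_factors=True)
    else:
        normalized = matrix

    protein_matrix = rollup_protein(normalized, pep_prot)

    reason_counts = (
        quants.loc[quants["status"] == "rejected", "reasons"]
        .str.split(";").explode().value_counts().to_dict()
    )
    provenance = {
        "n_transitions_in": int(len(records)),
        "n_transitions_paired": int(quants["n_pairs"].sum() * 2),
        "n_transitions_dropped": int(len(dropped)),
        "transition_drop_reasons": dropped["drop_reason"].value_counts().to_dict()
        if len(dropped) else {},
        "n_peptide_observations": int(len(quants)),
        "n_quantified": int((quants["status"] == "quantified").sum()),
        "n_rejected": int((quants["status"] == "rejected").sum()),
        "rejection_reason_counts": reason_counts,
        "n_samples_in": int(len(manifest)),
        "n_samples_passed": int(sample_qc["passed"].sum()),
        "n_samples_failed": int((~sample_qc["passed"]).sum()),
        "n_peptides_before_rate_filter": int(n_pep_before_rate),
        "n_peptides_after_rate_filter": int(matrix.shape[1]),
        "thresholds": vars(params.thresholds),
        "min_proteins": params.min_proteins,
        "min_irt_r2": params.min_irt_r2,
        "min_anchors": params.min_anchors,
        "min_quant_rate": params.min_quant_rate,
        "normalized": params.normalize,
    }

    return QuantResult(
        quants=quants,
        peptide_matrix=normalized,
        peptide_matrix_raw=matrix,
        protein_matrix=protein_matrix,
        irt_fits=irt_fits,
        sample_qc=sample_qc,
        normalization_factors=factors,
        peptide_protein=pep_prot,
        provenance=provenance,
    )
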