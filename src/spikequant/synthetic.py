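"""Ground-truthed synthetic study generator.

Produces a sample manifest (plates, wells, pools), true protein
concentrations with planted biology, a spike-in panel, and a
transition-level quantification report with multiplicative lognormal noise,
missingness, corrupted library scores and designed QC-failing samples.

The generator starts at integrated peak areas: no spectra or chromatograms
are simulated.  Everything is deterministic given the config's master seed.
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import (
    ANCHOR_PROTEIN,
    CORE_PROTEINS,
    SEX_RESTRICTED_CANCERS,
    CohortConfig,
    ConfigError,
)

_AMINO_ACIDS = np.array(list("ADEFGHILNPQSTVWY"))

# Stream indices for the master SeedSequence; one independent stream per
# generation stage keeps byte-identical determinism under a single seed.
_STREAM_MANIFEST = 1
_STREAM_TRUTH = 2
_STREAM_EMIT = 3


def protein_names(n: int) -> List[str]:
    """Core panel proteins first, then numbered fillers."""
    if n < len(CORE_PROTEINS):
        raise ConfigError(f"need at least {len(CORE_PROTEINS)} proteins")
    fillers = [f"PROT{i:03d}" for i in range(1, n - len(CORE_PROTEINS) + 1)]
    return list(CORE_PROTEINS) + fillers


def _random_peptides(rng: np.random.Generator, n: int) -> List[str]:
    """Unique pseudo-tryptic sequences (end in K or R)."""
    seen: set = set()
    out: List[str] = []
    while len(out) < n:
        length = int(rng.integers(8, 14))
        body = "".join(rng.choice(_AMINO_ACIDS, size=length))
        seq = body + ("K" if rng.random() < 0.5 else "R")
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def _well_label(index: int, wells_per_plate: int) -> str:
    ncols = 12 if wells_per_plate % 12 == 0 else max(1, int(math.sqrt(wells_per_plate)))
    row, col = divmod(index, ncols)
    letters = string.ascii_uppercase
    prefix = letters[row] if row < 26 else letters[row // 26 - 1] + letters[row % 26]
    return f"{prefix}{col + 1:02d}"


# ----------------------------------------------------------------------
# Manifest
# ----------------------------------------------------------------------

def build_manifest(config: CohortConfig) -> pd.DataFrame:
    """Assign patients and pool replicates to plates and wells.

    Patients are permuted with the seeded generator and dealt onto plates
    in order; each plate additionally carries exactly
    ``config.pool_replicates`` pool wells at evenly spaced positions.
    Sexes follow the cancer when it is sex-specific, otherwise ~1:1.

    Returns a DataFrame with columns
    ``sample_id, plate, well, sample_type, cancer, sex``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_MANIFEST]))

    cancers: List[str] = []
    sexes: List[str] = []
    for cancer in sorted(config.cancer_counts):
        n = config.cancer_counts[cancer]
        cancers.extend([cancer] * n)
        restricted = SEX_RESTRICTED_CANCERS.get(cancer)
        if restricted is not None:
            sexes.extend([restricted] * n)
        else:
            sexes.extend(np.where(rng.random(n) < 0.5, "female", "male").tolist())

    n_pat = len(cancers)
    n_plates = config.required_plates()
    capacity = config.plate_capacity
    if n_pat > n_plates * capacity:
        raise ConfigError(
            f"{n_pat} patients + {n_plates * config.pool_replicates} pool wells "
            f"exceed {n_plates} plates x {config.wells_per_plate} wells")

    order = rng.permutation(n_pat)

    pool_positions = sorted(
        {int(round(x)) for x in
         np.linspace(0, config.wells_per_plate - 1, config.pool_replicates)}
    ) if config.pool_replicates else []

    rows = []
    patient_counter = 0
    for plate_idx in range(n_plates):
        plate = f"P{plate_idx + 1:02d}"
        for rep, pos in enumerate(pool_positions, start=1):
            rows.append({
                "sample_id": f"POOL-{plate}-{rep}",
                "plate": plate,
                "well": _well_label(pos, config.wells_per_plate),
                "sample_type": "pool",
                "cancer": "",
                "sex": "",
            })
        patient_wells = [w for w in range(config.wells_per_plate)
                         if w not in pool_positions]
        for w in patient_wells:
            if patient_counter >= n_pat:
                break
            src = order[patient_counter]
            rows.append({
                "sample_id": f"S{patient_counter + 1:04d}",
                "plate": plate,
                "well": _well_label(w, config.wells_per_plate),
                "sample_type": "patient",
                "cancer": cancers[src],
                "sex": sexes[src],
            })
            patient_counter += 1

    manifest = pd.DataFrame(
        rows, columns=["sample_id", "plate", "well", "sample_type", "cancer", "sex"])
    return manifest


# ----------------------------------------------------------------------
# Ground truth
# ----------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    concentrations: pd.DataFrame        # samples x proteins, pmol/uL
    baselines: pd.Series                # protein -> baseline pmol/uL
    peptides: pd.DataFrame              # columns: protein, peptide
    kappa: pd.Series                    # peptide -> response factor
    fragment_profiles: pd.DataFrame     # peptides x transitions, rows sum to 1
    panel: pd.DataFrame                 # protein, peptide, standard_id, spike_conc
    anchor_peptides: pd.Series          # anchor peptide -> reference iRT
    qc_fail_samples: Dict[str, str]     # sample_id -> "irt" | "low_yield"
    seed: int

    def peptide_truth(self) -> pd.DataFrame:
        """Samples x peptides matrix of true concentrations (protein value
        broadcast to each of its peptides)."""
        prot_of = self.peptides.set_index("peptide")["protein"]
        data = {pep: self.concentrations[prot] for pep, prot in prot_of.items()}
        return pd.DataFrame(data, index=self.concentrations.index)


def draw_true_concentrations(
    config: CohortConfig,
    manifest: pd.DataFrame,
    seed: Optional[int] = None,
) -> GroundTruth:
    """Draw baselines, per-sample true concentrations and assay constants.

    Protein baselines are log-uniform over ``dynamic_range_decades``.
    A patient's value is ``baseline * 2**(eps_bio + effect[cancer, protein])
    * sexfactor`` with ``eps_bio ~ Normal(0, sigma_bio)``; sex-affected
    proteins multiply female samples by the configured female/male fold.
    Pool samples share one fixed value per protein: the mean of five donor
    profiles (3 male, 2 female) drawn once, identical across plates.
    """
    config.validate()
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([master, _STREAM_TRUTH]))

    proteins = protein_names(config.n_proteins)
    n_prot = len(proteins)

    log10_base = config.log10_min_conc + config.dynamic_range_decades * rng.random(n_prot)
    baselines = pd.Series(10.0 ** log10_base, index=proteins, name="baseline")

    sex_factor = pd.Series(1.0, index=proteins)
    for prot, fold in config.sex_effects.items():
        if prot in sex_factor.index:
            sex_factor[prot] = float(fold)

    # Fixed pool blend: 3 male + 2 female donor profiles, no cancer effects.
    donor_sexes = ["male", "male", "male", "female", "female"]
    donor = np.empty((len(donor_sexes), n_prot))
    for i, sex in enumerate(donor_sexes):
        eps = rng.normal(0.0, config.sigma_bio, n_prot)
        fac = np.where(sex == "female", sex_factor.to_numpy(), 1.0)
        donor[i] = baselines.to_numpy() * np.exp2(eps) * fac
    pool_values = donor.mean(axis=0)

    effect = np.zeros((len(manifest), n_prot))
    prot_index = {p: j for j, p in enumerate(proteins)}
    for i, (cancer, stype) in enumerate(zip(manifest["cancer"], manifest["sample_type"])):
        if stype != "patient":
            continue
        for prot, lfc in config.effect_table.get(cancer, {}).items():
            j = prot_index.get(prot)
            if j is not None:
                effect[i, j] = lfc

    is_patient = (manifest["sample_type"] == "patient").to_numpy()
    is_female = (manifest["sex"] == "female").to_numpy()
    eps_bio = rng.normal(0.0, config.sigma_bio, (len(manifest), n_prot))

    conc = np.where(
        is_patient[:, None],
        baselines.to_numpy()[None, :] * np.exp2(eps_bio + effect)
        * np.where(is_female[:, None], sex_factor.to_numpy()[None, :], 1.0),
        pool_values[None, :],
    )
    concentrations = pd.DataFrame(
        conc, index=manifest["sample_id"].to_numpy(), columns=proteins)
    concentrations.index.name = "sample_id"

    # Peptides, response factors, fragment profiles.
    n_pep = config.n_peptides
    seqs = _random_peptides(rng, n_pep + config.n_anchor_peptides)
    pep_rows = []
    k = 0
    for prot in proteins:
        for _ in range(config.peptides_per_protein):
            pep_rows.append({"protein": prot, "peptide": seqs[k]})
            k += 1
    peptides = pd.DataFrame(pep_rows)

    kappa = pd.Series(
        10.0 ** rng.uniform(4.0, 6.0, n_pep),
        index=peptides["peptide"].to_numpy(), name="kappa")

    profiles = rng.dirichlet(
        np.full(config.transitions_per_peptide, 2.0), size=n_pep)
    fragment_profiles = pd.DataFrame(
        profiles, index=peptides["peptide"].to_numpy(),
        columns=[f"y{t + 3}" for t in range(config.transitions_per_peptide)])

    # Spike panel: one standard per protein at close-to-baseline level.
    spike_per_protein = {
        prot: baselines[prot] * float(np.exp2(rng.uniform(-1.0, 1.0)))
        for prot in proteins
    }
    panel = peptides.copy()
    panel["standard_id"] = ["STD" + f"{prot_index[p] + 1:03d}" for p in panel["protein"]]
    panel["spike_conc_pmol_per_ul"] = [spike_per_protein[p] for p in panel["protein"]]

    anchor_names = seqs[n_pep:]
    anchor_peptides = pd.Series(
        np.linspace(5.0, 105.0, config.n_anchor_peptides),
        index=anchor_names, name="irt_ref")

    # Designed QC failures among patients, alternating failure modes.
    patients = manifest.loc[manifest["sample_type"] == "patient", "sample_id"]
    n_fail = int(round(config.qc_fail_fraction * len(patients)))
    qc_fail: Dict[str, str] = {}
    if n_fail:
        chosen = rng.choice(patients.to_numpy(), size=n_fail, replace=False)
        for i, sid in enumerate(sorted(chosen)):
            qc_fail[sid] = "irt" if i % 2 == 0 else "low_yield"

    return GroundTruth(
        concentrations=concentrations,
        baselines=baselines,
        peptides=peptides,
        kappa=kappa,
        fragment_profiles=fragment_profiles,
        panel=panel,
        anchor_peptides=anchor_peptides,
        qc_fail_samples=qc_fail,
        seed=master,
    )


# ----------------------------------------------------------------------
# Transition report
# ----------------------------------------------------------------------

def emit_transition_report(
    truth: GroundTruth,
    manifest: pd.DataFrame,
    panel: pd.DataFrame,
    config: CohortConfig,
) -> pd.DataFrame:
    """Expand ground truth into a transition-level report.

    For peptide p in sample s the total light area is
    ``kappa_p * C_true(s, protein(p)) * exp(eta + delta_plate)`` with
    ``eta ~ Normal(0, sigma_intra)`` per sample x peptide and a per-plate
    factor ``delta ~ Normal(0, sigma_plate)``; the heavy total is
    ``kappa_p * spike_conc(p) * exp(eta_h)`` with ``eta_h`` controlled by
    ``sigma_heavy`` (0 by default, so all injection noise lands on the
    ratio).  Totals are split across transitions by the fragment profile,
    then channel- and transition-level dropout is applied.  Anchor-peptide
    rows carry reference iRTs and retention times on the configured line;
    designed "irt" failures get their anchor RTs scrambled and designed
    "low_yield" failures lose most peptides in both channels.
    """
    missing = set(panel["peptide"]) - set(truth.peptides["peptide"])
    if missing:
        raise ConfigError(f"panel peptides absent from ground truth: {sorted(missing)[:5]}")

    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, _STREAM_EMIT]))

    samples = manifest["sample_id"].to_numpy()
    plates = manifest["plate"].to_numpy()
    n_s = len(samples)
    peptides = truth.peptides["peptide"].to_numpy()
    prots = truth.peptides["protein"].to_numpy()
    n_p = len(peptides)
    n_t = config.transitions_per_peptide
    frag_names = truth.fragment_profiles.columns.to_numpy()

    pep_truth = truth.peptide_truth().loc[samples, peptides].to_numpy()
    kappa = truth.kappa.loc[peptides].to_numpy()
    spike = panel.set_index("peptide")["spike_conc_pmol_per_ul"].loc[peptides].to_numpy()
    weights = truth.fragment_profiles.loc[peptides].to_numpy()

    unique_plates = pd.unique(plates)
    delta = dict(zip(unique_plates, rng.normal(0.0, config.sigma_plate, len(unique_plates))))
    plate_factor = np.exp([delta[p] for p in plates])

    eta = rng.normal(0.0, config.sigma_intra, (n_s, n_p))
    eta_h = rng.normal(0.0, config.sigma_heavy, (n_s, n_p)) if config.sigma_heavy > 0 \
        else np.zeros((n_s, n_p))

    light_total = kappa[None, :] * pep_truth * np.exp(eta) * plate_factor[:, None]
    heavy_total = kappa[None, :] * spike[None, :] * np.exp(eta_h)

    # dotp per sample x peptide: near 1 for clean rows, planted low for a
    # corrupted fraction so the score filter has something to reject.
    dotp = np.clip(1.0 - np.abs(rng.normal(0.0, 0.02, (n_s, n_p))), 0.0, 1.0)
    corrupted = rng.random((n_s, n_p)) < config.corrupted_fraction
    dotp = np.where(corrupted, rng.uniform(0.05, 0.45, (n_s, n_p)), dotp)

    chan_drop = rng.random((n_s, n_p, 2)) < config.channel_dropout
    trans_drop = rng.random((n_s, n_p, n_t, 2)) < config.transition_dropout

    # Designed low-yield samples: keep only a small peptide subset.
    low_yield_mask = np.zeros((n_s, n_p), dtype=bool)
    sample_pos = {s: i for i, s in enumerate(samples)}
    keep_n = max(1, int(round(config.low_yield_keep_fraction * n_p)))
    for sid, mode in truth.qc_fail_samples.items():
        if mode != "low_yield" or sid not in sample_pos:
            continue
        keep = rng.choice(n_p, size=keep_n, replace=False)
        mask = np.ones(n_p, dtype=bool)
        mask[keep] = False
        low_yield_mask[sample_pos[sid]] = mask

    # Per-peptide nominal retention time (no iRT reference for non-anchors).
    pep_rt = rng.uniform(5.0, 45.0, n_p)

    frames: List[pd.DataFrame] = []
    for ch_idx, label in enumerate(("light", "heavy")):
        total = light_total if label == "light" else heavy_total
        areas = total[:, :, None] * weights[None, :, :]          # (S, P, T)
        keep = ~(chan_drop[:, :, ch_idx][:, :, None] | trans_drop[:, :, :, ch_idx])
        keep &= ~low_yield_mask[:, :, None]
        s_idx, p_idx, t_idx = np.nonzero(keep)
        rt = pep_rt[p_idx] + (rng.normal(0.0, config.rt_noise_sd, len(p_idx))
                              if config.rt_noise_sd > 0 else 0.0)
        frames.append(pd.DataFrame({
            "sample_id": samples[s_idx],
            "plate": plates[s_idx],
            "well": manifest["well"].to_numpy()[s_idx],
            "protein": prots[p_idx],
            "peptide": peptides[p_idx],
            "precursor_charge": 2,
            "fragment": frag_names[t_idx],
            "product_charge": 1,
            "label": label,
            "area": areas[s_idx, p_idx, t_idx],
            "rt_min": rt,
            "irt_ref": np.nan,
            "dotp": dotp[s_idx, p_idx] if label == "light" else np.nan,
        }))

    # Anchor rows: light-only, with reference iRT, RT on the line
    # a*iRT + b (+ noise), scrambled for designed iRT failures.
    irt = truth.anchor_peptides.to_numpy()
    n_a = len(irt)
    base_rt = config.rt_slope * irt + config.rt_intercept
    anchor_frames = []
    for i, sid in enumerate(samples):
        rt = base_rt + (rng.normal(0.0, config.rt_noise_sd, n_a)
                        if config.rt_noise_sd > 0 else 0.0)
        if truth.qc_fail_samples.get(sid) == "irt":
            rt = rng.permutation(rt)
        anchor_frames.append(pd.DataFrame({
            "sample_id": sid,
            "plate": plates[i],
            "well": manifest["well"].to_numpy()[i],
            "protein": ANCHOR_PROTEIN,
            "peptide": truth.anchor_peptides.index.to_numpy(),
            "precursor_charge": 2,
            "fragment": "y1",
            "product_charge": 1,
            "label": "light",
            "area": 1.0e6,
            "rt_min": rt,
            "irt_ref": irt,
            "dotp": np.nan,
        }))

    report = pd.concat(frames + anchor_frames, ignore_index=True)
    report = report.sort_values(
        ["sample_id", "protein", "peptide", "fragment", "label"],
        kind="mergesort").reset_index(drop=True)
    return report


def peptide_observation_matrix(
    truth: GroundTruth,
    manifest: pd.DataFrame,
    config: CohortConfig,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Observed peptide concentrations without the transition round trip.

    Applies the same ratio-level noise model (injection + plate lognormal
    factors on the light channel) directly to the true peptide
    concentrations.  Useful for statistical experiments that do not need
    the full report emission + quantification path.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, _STREAM_EMIT, 7]))
    samples = manifest["sample_id"].to_numpy()
    pep_truth = truth.peptide_truth().loc[samples]
    plates = manifest["plate"].to_numpy()
    unique_plates = pd.unique(plates)
    delta = dict(zip(unique_plates, rng.normal(0.0, config.sigma_plate, len(unique_plates))))
    plate_factor = np.exp([delta[p] for p in plates])
    eta = rng.normal(0.0, config.sigma_intra, pep_truth.shape)
    return pep_truth * np.exp(eta) * plate_factor[:, None]


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------

@dataclass
class Simulation:
    config: CohortConfig
    manifest: pd.DataFrame
    truth: GroundTruth
    report: pd.DataFrame

    @property
    def panel(self) -> pd.DataFrame:
        return self.truth.panel


def simulate(config: CohortConfig) -> Simulation:
    """Run the full generator: manifest -> ground truth -> report."""
    manifest = build_manifest(config)
    truth = draw_true_concentrations(config, manifest)
    report = emit_transition_report(truth, manifest, truth.panel, config)
    return Simulation(config=config, manifest=manifest, truth=truth, report=report)


def write_simulation(sim: Simulation, outdir: str | Path) -> Dict[str, str]:
    """Write the three pipeline inputs plus ground truth and provenance."""
    from . import formats_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": str(outdir / "transition_report.csv"),
        "panel": str(outdir / "panel.csv"),
        "manifest": str(outdir / "manifest.csv"),
        "ground_truth": str(outdir / "ground_truth.csv"),
        "provenance": str(outdir / "simulation_provenance.json"),
    }
    formats_io.write_transition_report(paths["report"], sim.report)
    formats_io.write_panel(paths["panel"], sim.panel)
    formats_io.write_manifest(paths["manifest"], sim.manifest)
    gt = sim.truth.concentrations.stack().rename("true_conc_pmol_per_ul").reset_index()
    gt.columns = ["sample_id", "protein", "true_conc_pmol_per_ul"]
    gt.to_csv(paths["ground_truth"], index=False)
    prov = {
        "seed": sim.config.seed,
        "n_patients": sim.config.n_patients,
        "n_plates": sim.config.required_plates(),
        "n_proteins": sim.config.n_proteins,
        "n_peptides": sim.config.n_peptides,
        "qc_fail_samples": sim.truth.qc_fail_samples,
        "config": {k: v for k, v in vars(sim.config).items()
                   if not isinstance(v, dict)},
        "effect_table": sim.config.effect_table,
        "sex_effects": sim.config.sex_effects,
        "cancer_counts": sim.config.cancer_counts,
    }
    with open(paths["provenance"], "w") as fh:
        json.dump(prov, fh, indent=2, default=str)
    return paths
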