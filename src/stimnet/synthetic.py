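"""Synthetic paired-stimulation cohorts with planted, recoverable structure.

The generator emulates the shape of a monocyte LPS-stimulation study: a
genes × patients pair of log2 expression matrices (baseline and stimulated),
a 14-covariate clinical table whose moments match a real coronary-artery-
disease cohort, and ground truth for every downstream inference stage:

* co-expressed response modules driven by patient-level latent factors, one
  of which is coupled to diastolic blood pressure (DBP);
* transcription-factor regulons with signed modes of regulation, whose
  targets follow the TF's latent per-patient activity;
* a module → trait dependency for Bayesian-network recovery;
* a drug-signature library containing one signature that mirrors and one
  that reverses the planted trait-module response.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ClinicalTable, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_drug_library",
    "simulate_negative_controls",
    "MYELOID_CELL_LINES",
]

#: Cell lines treated as myeloid-relevant in the drug library.
MYELOID_CELL_LINES = ("HL60", "THP1", "NOMO1", "SKM1", "PL21", "U266", "HS27A")
_OTHER_CELL_LINES = ("HEPG2", "MCF7", "A549")

#: Clinical covariate moments used for generation (cohort of 38 CAD patients).
CLINICAL_MOMENTS = {
    "age": (66.68, 8.65),
    "bmi": (27.13, 4.14),
    "heart_rate": (63.29, 10.32),
    "dbp": (74.78, 11.88),
    "sbp": (137.68, 21.35),
    "glucose": (6.41, 1.15),
    "triglyceride": (1.55, 0.8),
    "creatinine": (87.45, 21.3),
    "hdl": (1.11, 0.3),
    "ldl": (2.64, 0.91),
}
BINARY_RATES = {"sex": 20 / 38, "renal_failure": 3 / 38, "smoker": 7 / 38, "diabetes": 7 / 38}


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    ``within_module_cor`` is the pairwise response correlation between genes
    of the same module; ``trait_effect`` is the correlation between the
    trait-linked module's latent response factor and generated DBP;
    ``noise_sd`` scales the residual noise on TF-target coupling (targets are
    MoR × activity + noise, so small values mean tight regulons).
    """

    n_genes: int = 2000
    n_patients: int = 38
    n_modules: int = 6
    module_sizes: Sequence[int] = (150, 120, 100, 80, 70, 60)
    within_module_cor: float = 0.7
    trait_effect: float = 0.6
    n_tfs: int = 40
    targets_per_tf: int = 25
    repressor_fraction: float = 0.3
    noise_sd: float = 0.15
    response_scale: float = 0.8
    noise_gene_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError(
                f"module_sizes has {len(self.module_sizes)} entries for "
                f"{self.n_modules} modules"
            )
        if any(s < 2 for s in self.module_sizes):
            raise ConfigError("every module needs at least 2 genes")
        needed = sum(self.module_sizes) + self.n_tfs * (1 + self.targets_per_tf)
        if needed > self.n_genes:
            raise ConfigError(
                f"planted structure needs {needed} genes but n_genes={self.n_genes}"
            )
        if not (-1 < self.trait_effect < 1):
            raise ConfigError("trait_effect must lie in (-1, 1)")
        if not (0 <= self.within_module_cor < 1):
            raise ConfigError("within_module_cor must lie in [0, 1)")
        if min(self.n_genes, self.n_patients, self.n_modules) <= 0:
            raise ConfigError("counts must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    module_labels: dict[str, str]  # gene -> module id or "unassigned"
    trait_module: str
    regulons: dict[str, dict[str, float]]  # TF -> {target: signed MoR}
    tf_activity: pd.DataFrame  # TFs × patients
    dag_edges: set[tuple[str, str]]
    response_means: pd.Series  # planted expected log2FC per gene
    reversal_drug: str | None = None
    mimic_drug: str | None = None
    latent_factors: pd.DataFrame | None = None  # modules × patients

    def to_json(self, path) -> None:
        payload = {
            "module_labels": self.module_labels,
            "trait_module": self.trait_module,
            "regulons": self.regulons,
            "tf_activity": {
                tf: [float(x) for x in row]
                for tf, row in self.tf_activity.iterrows()
            },
            "patients": list(self.tf_activity.columns),
            "dag_edges": sorted(list(e) for e in self.dag_edges),
            "response_means": {g: float(v) for g, v in self.response_means.items()},
            "reversal_drug": self.reversal_drug,
            "mimic_drug": self.mimic_drug,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        act = pd.DataFrame(
            {tf: vals for tf, vals in payload["tf_activity"].items()},
        ).T
        act.columns = payload["patients"]
        return cls(
            module_labels=payload["module_labels"],
            trait_module=payload["trait_module"],
            regulons={tf: dict(t) for tf, t in payload["regulons"].items()},
            tf_activity=act,
            dag_edges={tuple(e) for e in payload["dag_edges"]},
            response_means=pd.Series(payload["response_means"]),
            reversal_drug=payload["reversal_drug"],
            mimic_drug=payload["mimic_drug"],
        )


def _truncated_normal(rng, mean, sd, low, high, size):
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= low) & (draw <= high)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def _simulate_clinical(cfg: SimulationConfig, rng: np.random.Generator,
                       patients: list[str], dbp: np.ndarray) -> ClinicalTable:
    n = cfg.n_patients
    data: dict[str, np.ndarray] = {"dbp": np.round(dbp, 1)}
    # SBP rides on DBP with a positive offset; offset sd chosen so the SBP
    # marginal sd matches the cohort table while keeping corr(SBP, DBP) > 0.
    offset_sd = np.sqrt(max(CLINICAL_MOMENTS["sbp"][1] ** 2 - CLINICAL_MOMENTS["dbp"][1] ** 2, 25.0))
    offset_mean = CLINICAL_MOMENTS["sbp"][0] - CLINICAL_MOMENTS["dbp"][0]
    data["sbp"] = np.round(dbp + _truncated_normal(rng, offset_mean, offset_sd, 10, 150, n), 1)
    for name, (mean, sd) in CLINICAL_MOMENTS.items():
        if name in ("dbp", "sbp"):
            continue
        low = 0.05 * mean  # strictly positive physiology
        data[name] = np.round(_truncated_normal(rng, mean, sd, low, mean + 6 * sd, n), 2)
    for name, rate in BINARY_RATES.items():
        data[name] = (rng.random(n) < rate).astype(float)
    df = pd.DataFrame(data, index=patients)
    df.index.name = "patient_id"
    return ClinicalTable(df)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Generate a paired baseline/stimulated cohort with planted structure.

    Returns baseline and stimulated expression matrices (log2-intensity
    scale, gene means in ~6-14), the clinical table, and the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n_g, n_p = cfg.n_genes, cfg.n_patients
    genes = [f"G{i:05d}" for i in range(n_g)]
    patients = [f"P{i:03d}" for i in range(n_p)]

    # --- clinical covariates; DBP drives the trait-linked module -----------
    dbp = _truncated_normal(rng, *CLINICAL_MOMENTS["dbp"], 40.0, 130.0, n_p)
    clin = _simulate_clinical(cfg, rng, patients, dbp)
    dbp_z = (dbp - dbp.mean()) / dbp.std()

    # --- gene pools --------------------------------------------------------
    module_ids = [f"M{i + 1}" for i in range(cfg.n_modules)]
    trait_module = module_ids[0]
    labels: dict[str, str] = {}
    cursor = 0
    module_genes: dict[str, list[str]] = {}
    for mid, size in zip(module_ids, cfg.module_sizes):
        module_genes[mid] = genes[cursor:cursor + size]
        for g in module_genes[mid]:
            labels[g] = mid
        cursor += size
    tf_genes = genes[cursor:cursor + cfg.n_tfs]
    cursor += cfg.n_tfs
    target_genes = genes[cursor:cursor + cfg.n_tfs * cfg.targets_per_tf]
    cursor += len(target_genes)
    noise_genes = genes[cursor:]
    for g in tf_genes + target_genes + noise_genes:
        labels[g] = "unassigned"

    # --- latent structure --------------------------------------------------
    factors = rng.standard_normal((cfg.n_modules, n_p))
    te = cfg.trait_effect
    factors[0] = te * dbp_z + np.sqrt(1 - te ** 2) * rng.standard_normal(n_p)
    latent = pd.DataFrame(factors, index=module_ids, columns=patients)

    tf_activity = rng.standard_normal((cfg.n_tfs, n_p))
    n_repressors = int(round(cfg.repressor_fraction * cfg.n_tfs))
    is_repressor = np.zeros(cfg.n_tfs, dtype=bool)
    is_repressor[:n_repressors] = True

    # --- planted per-gene mean responses -----------------------------------
    response_mean = np.zeros(n_g)
    gene_pos = {g: i for i, g in enumerate(genes)}
    module_sign = {mid: (-1 if i % 2 == 0 else 1) for i, mid in enumerate(module_ids)}

    # per-gene module loadings: heterogeneous around within_module_cor, so
    # modules have a core-periphery structure; the mean pairwise response
    # correlation stays ~ within_module_cor
    w = cfg.within_module_cor
    gene_w: dict[str, np.ndarray] = {}
    for mid in module_ids:
        size = len(module_genes[mid])
        if w == 0:
            gene_w[mid] = np.zeros(size)
        else:
            lo, hi = max(w - 0.2, 0.05), min(w + 0.2, 0.98)
            gene_w[mid] = rng.uniform(lo, hi, size)

    for mid in module_ids:
        idx = [gene_pos[g] for g in module_genes[mid]]
        wg = gene_w[mid]
        u = (np.argsort(np.argsort(wg)) + 0.5) / len(wg)  # loading rank in (0,1)
        # amplitude grows with loading: core (hub) genes respond strongest;
        # the trait module mirrors the study's dampened-downregulation story
        if mid == trait_module:
            response_mean[idx] = -(1.2 + 1.0 * u)
        else:
            response_mean[idx] = module_sign[mid] * (0.8 + 1.0 * u)
    response_mean[[gene_pos[g] for g in noise_genes]] = rng.normal(0, 0.2, len(noise_genes))

    # --- responses ----------------------------------------------------------
    resp = np.zeros((n_g, n_p))
    scale = cfg.response_scale
    for mid in module_ids:
        idx = np.array([gene_pos[g] for g in module_genes[mid]])
        shared = latent.loc[mid].to_numpy()
        eps = rng.standard_normal((len(idx), n_p))
        lam = np.sqrt(gene_w[mid])[:, None]
        resp[idx] = scale * (lam * shared + np.sqrt(1.0 - lam ** 2) * eps)

    regulons: dict[str, dict[str, float]] = {}
    for t, tf in enumerate(tf_genes):
        resp[gene_pos[tf]] = tf_activity[t] + 0.1 * rng.standard_normal(n_p)
        mor = -1.0 if is_repressor[t] else 1.0
        targets = target_genes[t * cfg.targets_per_tf:(t + 1) * cfg.targets_per_tf]
        regulons[tf] = {g: mor for g in targets}
        for g in targets:
            resp[gene_pos[g]] = mor * tf_activity[t] + cfg.noise_sd * rng.standard_normal(n_p)

    idx = np.array([gene_pos[g] for g in noise_genes])
    if idx.size:
        resp[idx] = cfg.noise_gene_sd * rng.standard_normal((idx.size, n_p))
    resp += response_mean[:, None]

    # --- assemble matrices --------------------------------------------------
    gene_means = rng.uniform(6.0, 14.0, n_g)
    baseline_vals = gene_means[:, None] + 0.4 * rng.standard_normal((n_g, n_p))
    base_cols = [f"{p}_baseline" for p in patients]
    stim_cols = [f"{p}_stimulated" for p in patients]
    baseline = ExpressionMatrix(
        pd.DataFrame(baseline_vals, index=genes, columns=base_cols),
        {c: "baseline" for c in base_cols},
        {c: p for c, p in zip(base_cols, patients)},
    )
    stimulated = ExpressionMatrix(
        pd.DataFrame(baseline_vals + resp, index=genes, columns=stim_cols),
        {c: "stimulated" for c in stim_cols},
        {c: p for c, p in zip(stim_cols, patients)},
    )

    truth = GroundTruth(
        module_labels=labels,
        trait_module=trait_module,
        regulons=regulons,
        tf_activity=pd.DataFrame(tf_activity, index=tf_genes, columns=patients),
        dag_edges={(trait_module, "dbp")},
        response_means=pd.Series(response_mean, index=genes),
        latent_factors=latent,
    )
    return baseline, stimulated, clin, truth


def simulate_negative_controls(
    n_probes: int = 200, n_samples: int = 1, seed: int = 0,
    mean: float = 5.0, sd: float = 0.5,
) -> np.ndarray:
    """Negative-control probe intensities (log2 scale) for detection calls."""
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sd, (n_probes, n_samples))


def simulate_gene_sets(
    truth: GroundTruth,
    n_random_sets: int = 20,
    member_fraction: float = 0.8,
    random_set_size: int = 50,
    seed: int = 0,
):
    """Gene-set collection with one set per planted module plus random sets.

    Each module-linked set contains ``member_fraction`` of the module's genes
    plus a few background genes, so over-representation tests have a planted
    positive per module; random sets calibrate the null.
    """
    from .io_formats import GeneSetCollection

    rng = np.random.default_rng(seed)
    genes = list(truth.response_means.index)
    sets: dict[str, set[str]] = {}
    modules = sorted({m for m in truth.module_labels.values() if m != "unassigned"})
    for mid in modules:
        members = [g for g, m in truth.module_labels.items() if m == mid]
        take = max(2, int(round(member_fraction * len(members))))
        chosen = list(rng.choice(members, size=take, replace=False))
        padding = list(rng.choice(genes, size=max(2, take // 10), replace=False))
        sets[f"PLANTED_{mid}"] = set(chosen) | set(padding)
    for i in range(n_random_sets):
        sets[f"RANDOM_{i + 1:02d}"] = set(
            rng.choice(genes, size=random_set_size, replace=False)
        )
    return GeneSetCollection(sets, source="synthetic")


def simulate_drug_library(
    cfg: SimulationConfig,
    truth: GroundTruth,
    n_drugs: int = 50,
    n_landmark: int = 978,
    seed: int | None = None,
) -> pd.DataFrame:
    """Drug-by-gene differential-signature library with planted extremes.

    The landmark panel defaults to 978 genes (the size of a standard
    landmark-gene panel) and always contains the trait module. The planted
    ``mimic`` drug's signature equals the trait module's expected
    response over the landmark genes (it pushes those genes the way the
    stimulus does); the ``reversal`` drug is its exact negative. The rest are
    standard-normal noise. A ``cell_line`` column supports myeloid-subset
    filtering. ``truth`` is updated in place with the two drug ids.
    """
    if n_landmark > cfg.n_genes:
        raise ConfigError(f"n_landmark={n_landmark} exceeds n_genes={cfg.n_genes}")
    if n_drugs < 2:
        raise ConfigError("need at least 2 drugs (mimic and reversal)")
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    module_members = [g for g, m in truth.module_labels.items() if m == truth.trait_module]
    if len(module_members) > n_landmark:
        raise ConfigError("n_landmark smaller than the trait module")
    others = [g for g in truth.response_means.index if g not in set(module_members)]
    extra = list(rng.choice(others, size=n_landmark - len(module_members), replace=False))
    landmarks = sorted(module_members + extra)

    planted = truth.response_means.loc[landmarks].to_numpy().copy()
    off_module = np.array([g not in set(module_members) for g in landmarks])
    # off-module landmarks carry moderate noise (drugs perturb many genes a
    # little), giving the planted signatures a full, realistic ranking;
    # reversal = -mimic keeps their correlation exactly -1
    planted[off_module] = 0.5 * rng.standard_normal(off_module.sum())

    drugs = [f"drug{1:03d}", f"drug{2:03d}"] + [f"drug{i:03d}" for i in range(3, n_drugs + 1)]
    sig = rng.standard_normal((n_drugs, len(landmarks)))
    sig[0] = planted          # mimic
    sig[1] = -planted         # reversal
    lines = [
        MYELOID_CELL_LINES[i % len(MYELOID_CELL_LINES)]
        if i % 5 != 4 else _OTHER_CELL_LINES[i % len(_OTHER_CELL_LINES)]
        for i in range(n_drugs)
    ]
    lines[0] = lines[1] = MYELOID_CELL_LINES[0]
    library = pd.DataFrame(sig, index=drugs, columns=landmarks)
    library.insert(0, "cell_line", lines)
    library.index.name = "drug_id"
    truth.mimic_drug = drugs[0]
    truth.reversal_drug = drugs[1]
    return library
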