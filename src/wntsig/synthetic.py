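"""Synthetic datasets with the statistical structure the analyses assume.

Three generators emulate the three data sources of the study design:

* :func:`gen_anchor_correlated_matrix` — a small brain-metastasis-like
  expression matrix (default n = 19 samples) in which planted WNT-target
  genes track a latent anchor signal at a prescribed correlation rho, and
  null genes are independent noise.  This is the substrate for signature
  derivation.
* :func:`gen_clustered_cohort` — a primary-tumour cohort (default n = 58)
  with two latent sample clusters: signature probes are shifted upward in
  cluster 1, and survival is proportional-hazards with cluster 1 at the
  higher hazard (default true HR 3.125, i.e. 0.32 for cluster 2 vs 1).
* :func:`gen_ihc_cohort` — an ordinally scored IHC cohort (default n = 25)
  whose marker prevalences follow the study's baseline table and whose
  survival follows a proportional-hazards model with planted per-marker
  hazard ratios.

Every generator is a pure function of its parameters and seed.  Expression
noise is Gaussian on the log2 scale; survival times are Weibull with unit
shape (exponential) by default; censoring is uniform on (0, u) with u
calibrated to the requested censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "SyntheticTruth",
    "gen_anchor_correlated_matrix",
    "gen_clustered_cohort",
    "gen_ihc_cohort",
    "TABLE1_PREVALENCES",
    "TABLE1_HAZARD_RATIOS",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset; fixed by the parameters + seed."""

    seed: int
    planted_genes: dict[str, float] = field(default_factory=dict)  # gene -> rho
    anchor_genes: list[str] = field(default_factory=list)
    annotation: pd.Series | None = None  # probe_id -> gene_symbol
    panel_probes: dict[str, list[str]] = field(default_factory=dict)
    cluster_labels: dict[str, int] = field(default_factory=dict)
    hr_true: float | None = None
    de_probes: dict[str, float] = field(default_factory=dict)  # probe -> shift
    marker_hr: dict[str, float] = field(default_factory=dict)


def _to_log2_scale(z: np.ndarray, center: float = 8.0, scale: float = 1.5) -> np.ndarray:
    # affine map of standardized signals onto a microarray-like log2 range;
    # correlations are unaffected
    return center + scale * z


def gen_anchor_correlated_matrix(
    n_samples: int = 19,
    n_null_genes: int = 200,
    planted: list[tuple[str, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    anchor_genes: list[str] = ("LEF1", "TCF4"),
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression matrix with genes planted at correlation rho to an anchor.

    A latent standard-normal anchor signal is drawn per sample; each anchor
    gene contributes one probe carrying that signal.  A planted gene's probe
    is ``rho * A + sqrt(1 - rho^2) * eps`` with the standardized anchor A, so
    its population correlation to every anchor probe is exactly rho.  Null
    genes are independent Gaussian noise.  All rows are mapped onto a
    log2-like range (center 8, spread 1.5).
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    planted = list(planted or [])
    for gene, rho in planted:
        if not abs(rho) < 1:
            raise ValueError(f"{gene}: |rho| must be < 1, got {rho}")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n_samples)
    a_std = (latent - latent.mean()) / latent.std()

    probe_ids: list[str] = []
    gene_of_probe: list[str] = []
    rows: list[np.ndarray] = []
    for gene in anchor_genes:
        probe_ids.append(f"{gene}_s_at")
        gene_of_probe.append(gene)
        rows.append(_to_log2_scale(latent))
    for gene, rho in planted:
        eps = rng.standard_normal(n_samples) * noise_sd
        eps = (eps - eps.mean()) / eps.std()
        sig = rho * a_std + np.sqrt(1.0 - rho**2) * eps
        probe_ids.append(f"{gene}_s_at")
        gene_of_probe.append(gene)
        rows.append(_to_log2_scale(sig))
    for i in range(n_null_genes):
        gene = f"NULL{i:04d}"
        probe_ids.append(f"{gene}_s_at")
        gene_of_probe.append(gene)
        rows.append(_to_log2_scale(rng.standard_normal(n_samples) * noise_sd))

    samples = [f"S{i:03d}" for i in range(n_samples)]
    matrix = ExpressionMatrix(
        pd.DataFrame(np.array(rows), index=probe_ids, columns=samples),
        is_log2=True,
    )
    annotation = pd.Series(gene_of_probe, index=probe_ids)
    panel_probes = {
        g: [p] for g, p in zip(gene_of_probe, probe_ids)
        if g not in anchor_genes
    }
    truth = SyntheticTruth(
        seed=seed,
        planted_genes={g: r for g, r in planted},
        anchor_genes=list(anchor_genes),
        annotation=annotation,
        panel_probes=panel_probes,
    )
    return matrix, truth


def _calibrated_censor_times(
    t_event: np.ndarray, censor_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform(0, u) censoring with u chosen so E[fraction censored] matches.

    Given realized event times t_i and C ~ U(0, u), P(censored_i) =
    min(t_i / u, 1); u is found by bisection on the mean of that quantity.
    """
    if not 0 < censor_frac < 1:
        raise ValueError("censor_frac must be in (0,1)")

    def frac(u: float) -> float:
        return float(np.minimum(t_event / u, 1.0).mean())

    lo, hi = t_event.min() * 1e-3 + 1e-9, t_event.max() * 100 + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > censor_frac:
            lo = mid
        else:
            hi = mid
    u = 0.5 * (lo + hi)
    return rng.uniform(0.0, u, size=t_event.size)


def gen_clustered_cohort(
    n_samples: int = 58,
    signature_probes: list[str] | None = None,
    shift_delta: float = 2.0,
    hr_true: float = 3.125,
    censor_frac: float = 0.3,
    seed: int = 0,
    n_null_probes: int = 200,
    split_frac: float = 0.5,
    noise_sd: float = 1.0,
    baseline_median_months: float = 20.0,
    weibull_shape: float = 1.0,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Two-cluster cohort with cluster-dependent hazard.

    Samples split into two latent clusters (cluster 1 gets
    ``round(n * split_frac)`` members).  Signature probes are shifted by
    ``shift_delta`` log2 units in cluster 1; survival is Weibull
    proportional-hazards with cluster 1 at hazard lambda and cluster 2 at
    lambda / hr_true, so cluster 1 is the poor-prognosis group.  Returns the
    matrix, a survival frame (sample_id, time_months, event) and the truth.
    """
    if hr_true <= 0:
        raise ValueError("hr_true must be > 0")
    if signature_probes is None:
        signature_probes = [f"SIG{i:03d}_s_at" for i in range(10)]
    rng = np.random.default_rng(seed)
    n1 = int(round(n_samples * split_frac))
    if n1 == 0 or n1 == n_samples:
        raise ValueError("split_frac leaves an empty cluster")
    labels = np.array([1] * n1 + [2] * (n_samples - n1))
    rng.shuffle(labels)

    samples = [f"P{i:03d}" for i in range(n_samples)]
    probe_ids = list(signature_probes) + [
        f"NULLP{i:04d}_s_at" for i in range(n_null_probes)
    ]
    values = 8.0 + noise_sd * rng.standard_normal((len(probe_ids), n_samples))
    values[: len(signature_probes), labels == 1] += shift_delta
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=samples), is_log2=True
    )

    lam = np.log(2.0) / baseline_median_months  # cluster-1 hazard scale
    hazard = np.where(labels == 1, lam, lam / hr_true)
    e = rng.exponential(1.0, size=n_samples)
    t_event = (e / hazard) ** (1.0 / weibull_shape)
    c = _calibrated_censor_times(t_event, censor_frac, rng)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    surv = pd.DataFrame(
        {"sample_id": samples, "time_months": time, "event": event}
    )
    truth = SyntheticTruth(
        seed=seed,
        cluster_labels=dict(zip(samples, (int(l) for l in labels))),
        hr_true=hr_true,
        de_probes={p: shift_delta for p in signature_probes},
    )
    return matrix, surv, truth


# Marker prevalences and univariate hazard ratios of the 25-patient
# brain-metastasis cohort's baseline table; generator defaults.
TABLE1_PREVALENCES: dict[str, float] = {
    "male": 0.64,
    "present_at_diagnosis": 0.72,
    "multiple_metastases": 0.40,
    "secondary_organ_metastasis": 0.56,
    "ct_before_surgery": 0.167,
    "radiotherapy": 0.875,
    "ct_after_surgery": 0.667,
    "ttf1_positive": 0.68,
    "ki67_high": 0.68,
    "lef1_positive": 0.36,
    "tcf4_top": 0.28,
    "beta_catenin_positive": 0.36,
}

TABLE1_HAZARD_RATIOS: dict[str, float] = {
    "male": 2.36,
    "present_at_diagnosis": 1.03,
    "multiple_metastases": 0.65,
    "secondary_organ_metastasis": 3.03,
    "ct_before_surgery": 1.50,
    "radiotherapy": 0.13,
    "ct_after_surgery": 0.22,
    "ttf1_positive": 0.57,
    "ki67_high": 3.27,
    "lef1_tcf4_combined": 4.69,
}

_CLINICAL_BINARIES = [
    "male", "present_at_diagnosis", "multiple_metastases",
    "secondary_organ_metastasis", "ct_before_surgery", "radiotherapy",
    "ct_after_surgery",
]


def gen_ihc_cohort(
    n_patients: int = 25,
    prevalence: dict[str, float] | None = None,
    planted_hr: dict[str, float] | None = None,
    seed: int = 0,
    baseline_median_months: float = 12.0,
    censor_frac: float = 0.2,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Ordinally scored IHC cohort with planted per-marker hazards.

    Binary marker states are Bernoulli draws at the requested prevalences and
    are then expressed as ordinal scores consistent with the study's grading
    bins (e.g. LEF1-positive patients are mostly 1+; TCF4 non-top patients
    are 2+ or 3+; Ki67 spans 3-40 %).  Survival follows an exponential
    proportional-hazards model whose log-hazard is the sum of the planted
    log hazard ratios over the patient's positive markers.
    """
    prev = dict(TABLE1_PREVALENCES)
    prev.update(prevalence or {})
    hrs = dict(TABLE1_HAZARD_RATIOS)
    hrs.update(planted_hr or {})
    for name, pr in prev.items():
        if not 0 < pr < 1:
            raise ValueError(f"prevalence for {name} must be in (0,1)")
    rng = np.random.default_rng(seed)

    flags = {
        name: rng.random(n_patients) < pr for name, pr in prev.items()
    }
    df = pd.DataFrame({"patient_id": [f"BM{i:03d}" for i in range(n_patients)]})

    # ordinal scores realizing the dichotomized states
    lef1 = np.where(flags["lef1_positive"],
                    rng.choice([1, 2], size=n_patients, p=[0.9, 0.1]), 0)
    tcf4 = np.where(flags["tcf4_top"], 4,
                    rng.choice([2, 3], size=n_patients, p=[3 / 18, 15 / 18]))
    bcat = np.where(flags["beta_catenin_positive"],
                    rng.choice([1, 2, 3], size=n_patients,
                               p=[7 / 9, 1 / 9, 1 / 9]), 0)
    ki67 = np.where(flags["ki67_high"],
                    rng.uniform(10.0, 40.0, n_patients),
                    rng.uniform(3.0, 10.0 - 1e-9, n_patients))
    ttf1 = np.where(flags["ttf1_positive"],
                    rng.integers(4, 9, n_patients),
                    rng.integers(0, 4, n_patients))
    df["lef1"] = lef1
    df["tcf4"] = tcf4
    df["beta_catenin"] = bcat
    df["ki67_percent"] = np.round(ki67, 1)
    df["ttf1_score"] = ttf1.astype(float)
    df["age"] = np.clip(np.round(rng.normal(61.0, 10.0, n_patients)), 35, 85)
    for name in _CLINICAL_BINARIES:
        df[name] = flags[name].astype(int)

    combined = flags["lef1_positive"] & (tcf4 == 4)
    state = {**{k: flags[k] for k in hrs if k in flags},
             "lef1_tcf4_combined": combined}
    log_hr = np.zeros(n_patients)
    for name, hr in hrs.items():
        if name in state:
            log_hr += np.log(hr) * state[name].astype(float)
    lam = np.log(2.0) / baseline_median_months
    t_event = rng.exponential(1.0, n_patients) / (lam * np.exp(log_hr))
    c = _calibrated_censor_times(t_event, censor_frac, rng)
    df["time_months"] = np.round(np.minimum(t_event, c), 2)
    df["event"] = (t_event <= c).astype(int)

    truth = SyntheticTruth(seed=seed, marker_hr=dict(hrs))
    return df, truth
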