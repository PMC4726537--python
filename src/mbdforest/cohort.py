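"""Synthetic hemodialysis cohort generator.

Emulates monthly CKD-MBD laboratory records: serum calcium (Ca, mg/dL),
phosphate (P, mg/dL), parathyroid hormone (PTH, pg/mL), alkaline
phosphatase (AP, IU/L) and potassium (K, mmol/L), together with
demographics (age, gender, dialysis vintage) and eight binary drug-exposure
flags (drug taken within the 30 days before the blood draw).

The generator encodes the qualitative physiology of secondary
hyperparathyroidism as a fixed structural recipe:

1. demographics per patient (gender, baseline age, vintage from a gamma
   law to honour its skew), advanced month by month;
2. phosphate, declining with age, with a patient-level random intercept;
3. PTH as a *saturating, nonlinear* function of phosphate (tanh response on
   the log scale), depressed by high baseline calcium, rising with vintage,
   with a patient intercept and lognormal-style noise so the marginal PTH
   distribution is right-skewed (mean 317, SD of the same order);
4. alkaline phosphatase tracking log-PTH (bone turnover);
5. calcium = latent baseline + positive PTH feedback + noise;
6. potassium as an independent nuisance variable (a known-null feature for
   importance analysis);
7. drug flags assigned *by indication*: each drug has a trigger variable
   and threshold; records beyond the threshold receive the drug with the
   configured (high) probability, and the below-threshold probability is
   solved so that the marginal prevalence matches its target.  This builds
   confounding by indication into the cohort (e.g. calcimimetic users have
   systematically higher PTH);
8. calcimimetic exposure then pulls calcium partway toward 9.0 mg/dL and
   calcitriol toward 9.8 mg/dL (partial corrective shifts).

PTH and AP are normalised multiplicatively against the sample mean of the
exponentiated log-deviation, so their sample means land on the configured
targets without an analytic lognormal correction; with all couplings and
noise at zero every biochemical variable degenerates to its target mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# -- table schema ---------------------------------------------------------

DRUGS = [
    "vitamin_d",
    "calcitriol",
    "paricalcitol",
    "calcimimetic",
    "ca_binder",
    "mg_binder",
    "sevelamer",
    "lanthanum",
]
DRUG_COLUMNS = ["drug_" + d for d in DRUGS]
BIOCHEM = ["ca", "p", "pth", "alk_phos", "potassium"]
COLUMNS = (
    ["patient_id", "month_index", "age", "gender", "vintage"]
    + BIOCHEM
    + DRUG_COLUMNS
)
#: Fields that must be present for a record to count as complete.
REQUIRED_FIELDS = ["ca", "p", "pth", "age", "gender", "vintage"] + DRUG_COLUMNS

#: Mean serum Ca (mg/dL) toward which each drug pulls exposed records.
CA_PULL_TARGETS = {"calcimimetic": 9.0, "calcitriol": 9.8}

_DAYS_PER_MONTH = 30.44

#: The phosphate drive on PTH is amplified in long-vintage patients (more
#: severe secondary hyperparathyroidism), creating a P-by-vintage
#: interaction in the structural response.
VINTAGE_SEVERITY = 0.35


@dataclass(frozen=True)
class TreatmentRule:
    """Indication rule: exposure probability jumps when the trigger
    variable exceeds the threshold."""

    trigger: str  # one of "pth", "p", "ca"
    threshold: float  # clinical units of the trigger variable
    probability: float  # exposure probability above the threshold


def _default_marginals() -> Dict[str, Tuple[float, float]]:
    return {
        "ca": (9.4, 0.9),
        "p": (4.7, 1.4),
        "pth": (317.0, 320.0),
        "alk_phos": (142.0, 126.0),
        "potassium": (5.3, 0.9),
        "age": (59.8, 16.6),
        "vintage": (3300.0, 2560.0),
    }


def _default_prevalence() -> Dict[str, float]:
    return {
        "vitamin_d": 0.014,
        "calcitriol": 0.156,
        "paricalcitol": 0.131,
        "calcimimetic": 0.155,
        "ca_binder": 0.424,
        "mg_binder": 0.006,
        "sevelamer": 0.418,
        "lanthanum": 0.106,
    }


def _default_coupling() -> Dict[str, float]:
    # log-PTH units unless stated; calibrated once against the marginal
    # targets and the qualitative association pattern, then frozen.
    return {
        "p_to_pth": 0.65,  # amplitude of the saturating tanh response
        "ca_to_pth": -0.75,  # per mg/dL of baseline-Ca deviation
        "vintage_to_pth": 0.55,  # per saturated SD of vintage
        "age_to_p": -0.35,  # mg/dL of P per SD of age
        "pth_to_ap": 1.00,  # log-AP per unit of saturated centered log-PTH
        "pth_to_ca": 0.65,  # mg/dL of Ca per unit of saturated centered log-PTH
        "age_to_ca": -0.35,  # mg/dL of Ca per SD of age
        "vintage_to_ca": 1.0,  # mg/dL amplitude of the non-monotone vintage bump
        "treatment_to_ca": 0.6,  # fractional pull toward the drug's Ca target
    }


def _default_noise() -> Dict[str, float]:
    return {
        "p": 1.25,  # mg/dL
        "pth": 0.30,  # log scale
        "ca": 0.60,  # mg/dL, residual
        "ca_baseline": 0.70,  # mg/dL, latent baseline spread
        "alk_phos": 0.55,  # log scale
        "potassium": 0.9,  # mmol/L
    }


def _default_patient_sd() -> Dict[str, float]:
    return {"p": 0.55, "pth": 0.33}


def _default_rules() -> Dict[str, TreatmentRule]:
    return {
        "vitamin_d": TreatmentRule("pth", 300.0, 0.03),
        "calcitriol": TreatmentRule("pth", 300.0, 0.30),
        "paricalcitol": TreatmentRule("pth", 300.0, 0.25),
        "calcimimetic": TreatmentRule("pth", 500.0, 0.60),
        "ca_binder": TreatmentRule("p", 5.5, 0.80),
        "mg_binder": TreatmentRule("p", 5.5, 0.012),
        "sevelamer": TreatmentRule("p", 5.5, 0.80),
        "lanthanum": TreatmentRule("p", 5.5, 0.25),
    }


@dataclass
class CohortConfig:
    """Generative parameters of the synthetic cohort.

    The default marginal targets reproduce the study population this
    package is aimed at: 1758 patients followed monthly (~46,000 records),
    Ca 9.4 (0.9) mg/dL, P 4.7 (1.4) mg/dL, PTH 317 (320) pg/mL, AP 142
    (126) IU/L, K 5.3 (0.9) mmol/L, age 59.8 (16.6) y, vintage 3300 (2560)
    days, 59.2% male, and the eight drug prevalences between 0.6% and 42%.
    """

    n_patients: int = 1758
    months_per_patient: int = 26
    seed: int = 0
    male_fraction: float = 0.592
    marginal_targets: Dict[str, Tuple[float, float]] = field(default_factory=_default_marginals)
    drug_prevalence_targets: Dict[str, float] = field(default_factory=_default_prevalence)
    coupling: Dict[str, float] = field(default_factory=_default_coupling)
    noise_sd: Dict[str, float] = field(default_factory=_default_noise)
    patient_sd: Dict[str, float] = field(default_factory=_default_patient_sd)
    treatment_rules: Dict[str, TreatmentRule] = field(default_factory=_default_rules)

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.months_per_patient <= 0:
            raise ValueError("n_patients and months_per_patient must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        for var, (mean, sd) in self.marginal_targets.items():
            if sd < 0:
                raise ValueError(f"negative SD for marginal target {var!r}")
        for d, frac in self.drug_prevalence_targets.items():
            if d not in DRUGS:
                raise ValueError(f"unknown drug {d!r} in prevalence targets")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"prevalence for {d!r} outside [0, 1]")
        for var, sd in {**self.noise_sd, **self.patient_sd}.items():
            if sd < 0:
                raise ValueError(f"negative SD for {var!r}")
        for d, rule in self.treatment_rules.items():
            if d not in DRUGS:
                raise ValueError(f"unknown drug {d!r} in treatment rules")
            if rule.trigger not in ("pth", "p", "ca"):
                raise ValueError(f"unknown trigger variable {rule.trigger!r}")
            if not 0.0 <= rule.probability <= 1.0:
                raise ValueError(f"rule probability for {d!r} outside [0, 1]")

    def with_coupling(self, **updates: float) -> "CohortConfig":
        """Copy of the config with some coupling coefficients replaced."""
        coupling = dict(self.coupling)
        for k, v in updates.items():
            if k not in coupling:
                raise KeyError(f"unknown coupling {k!r}")
            coupling[k] = v
        return replace(self, coupling=coupling)


# -- structural pieces ----------------------------------------------------

def phosphate_response(p: np.ndarray, config: Optional[CohortConfig] = None) -> np.ndarray:
    """Noiseless structural log-PTH contribution of phosphate.

    A saturating tanh in standardized phosphate: steep through the normal
    range, flattening at the extremes (parathyroid stimulation saturates).
    Deliberately non-affine: its second difference over any three phosphate
    levels spanning the bend is nonzero.
    """
    config = config or CohortConfig()
    mean, sd = config.marginal_targets["p"]
    u = (np.asarray(p, dtype=float) - mean) / sd
    return config.coupling["p_to_pth"] * np.tanh(0.9 * u)


def structural_pth(
    p: np.ndarray,
    ca_dev: np.ndarray | float = 0.0,
    vintage: np.ndarray | float | None = None,
    config: Optional[CohortConfig] = None,
) -> np.ndarray:
    """Noiseless PTH (pg/mL) implied by the structural equations, before
    the in-sample mean normalisation.  Used to probe the generator's true
    response surface (e.g. its nonlinearity)."""
    config = config or CohortConfig()
    pth_mean, _ = config.marginal_targets["pth"]
    v_mean, v_sd = config.marginal_targets["vintage"]
    z_vint = 0.0 if vintage is None else (np.asarray(vintage, dtype=float) - v_mean) / v_sd
    h = (
        phosphate_response(p, config) * (1.0 + VINTAGE_SEVERITY * np.tanh(z_vint))
        + config.coupling["ca_to_pth"] * np.asarray(ca_dev, dtype=float)
        + config.coupling["vintage_to_pth"] * np.tanh(z_vint)
    )
    return pth_mean * np.exp(h)


def _clip_positive(x: np.ndarray, floor: float, name: str, clip_log: Dict[str, int]) -> np.ndarray:
    n_clip = int(np.sum(x < floor))
    if n_clip:
        clip_log[name] = clip_log.get(name, 0) + n_clip
        logger.info("clipped %d %s values at %.3g", n_clip, name, floor)
    return np.maximum(x, floor)


# -- generation -----------------------------------------------------------

def generate_cohort(config: Optional[CohortConfig] = None) -> pd.DataFrame:
    """Generate one synthetic cohort; deterministic given ``config.seed``.

    Returns a record table with one row per (patient, month) and the
    documented column set; counts of values clipped to positive support are
    stored in ``table.attrs["clipped"]``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n_pat = config.n_patients
    months = config.months_per_patient
    n = n_pat * months
    tgt = config.marginal_targets
    cpl = config.coupling
    noise = config.noise_sd
    clip_log: Dict[str, int] = {}

    # demographics: stratified inverse-CDF draws (one jittered quantile per
    # patient) keep the cohort-level mean tight even with few patients, and
    # baseline values are adjusted so the record-level mean over the
    # follow-up months lands on the configured target
    from scipy import stats as _st

    n_male = int(round(config.male_fraction * n_pat))
    gender = np.zeros(n_pat, dtype=np.int64)
    gender[rng.permutation(n_pat)[:n_male]] = 1
    age_mean, age_sd = tgt["age"]
    u_age = (rng.permutation(n_pat) + rng.random(n_pat)) / n_pat
    age0 = age_mean - (months - 1) / 24.0 + age_sd * _st.norm.ppf(u_age)
    v_mean, v_sd = tgt["vintage"]
    v0_mean = max(v_mean - _DAYS_PER_MONTH * (months - 1) / 2.0, 1.0)
    if v_sd > 0:
        shape = (v0_mean / v_sd) ** 2
        scale = v_sd**2 / v0_mean
        u_v = (rng.permutation(n_pat) + rng.random(n_pat)) / n_pat
        vintage0 = _st.gamma.ppf(u_v, shape, scale=scale)
    else:
        vintage0 = np.full(n_pat, v0_mean)

    b_p = rng.normal(0.0, config.patient_sd.get("p", 0.0), n_pat)
    b_pth = rng.normal(0.0, config.patient_sd.get("pth", 0.0), n_pat)

    pat = np.repeat(np.arange(n_pat), months)
    month = np.tile(np.arange(months), n_pat)
    age = np.clip(age0[pat] + month / 12.0, 18.01, 109.99)
    vintage = vintage0[pat] + _DAYS_PER_MONTH * month

    # phosphate: declines with age, patient intercept, Gaussian noise
    p_mean, p_sd = tgt["p"]
    z_age = (age - age_mean) / age_sd if age_sd > 0 else np.zeros(n)
    p = (
        p_mean
        + cpl["age_to_p"] * z_age
        + b_p[pat]
        + rng.normal(0.0, noise["p"], n)
    )
    p = _clip_positive(p, 0.5, "p", clip_log)

    # latent baseline calcium deviation (mg/dL around the Ca target)
    ca_dev = rng.normal(0.0, noise["ca_baseline"], n)

    # PTH: saturating phosphate drive, calcium suppression, vintage drift,
    # patient intercept, lognormal-style noise; normalised to the target mean
    z_vint = (vintage - v_mean) / v_sd if v_sd > 0 else np.zeros(n)
    h = (
        phosphate_response(p, config) * (1.0 + VINTAGE_SEVERITY * np.tanh(z_vint))
        + cpl["ca_to_pth"] * ca_dev
        + cpl["vintage_to_pth"] * np.tanh(z_vint)
        + b_pth[pat]
        + rng.normal(0.0, noise["pth"], n)
    )
    pth_mean, _ = tgt["pth"]
    eh = np.exp(h)
    pth = pth_mean * eh / eh.mean()
    hc = h - h.mean()  # centered log-PTH deviation, reused downstream

    # alkaline phosphatase tracks log-PTH with a saturating response
    ap_mean, _ = tgt["alk_phos"]
    h_ap = cpl["pth_to_ap"] * np.tanh(hc) + rng.normal(0.0, noise["alk_phos"], n)
    eap = np.exp(h_ap)
    alk_phos = ap_mean * eap / eap.mean()

    # calcium: baseline + saturating positive PTH feedback + a declining
    # age effect + a non-monotone vintage effect (rises early, falls after
    # ~8 years on dialysis as patients age), + residual noise
    ca_mean, _ = tgt["ca"]
    bump = np.exp(-(((vintage - 2920.0) / 2200.0) ** 2))
    ca = (
        ca_mean
        + ca_dev
        + cpl["pth_to_ca"] * np.tanh(1.5 * hc)
        + cpl["age_to_ca"] * z_age
        + cpl["vintage_to_ca"] * (bump - bump.mean())
        + rng.normal(0.0, noise["ca"], n)
    )
    ca = _clip_positive(ca, 4.0, "ca", clip_log)

    # potassium: independent nuisance (known-null feature)
    k_mean, _ = tgt["potassium"]
    potassium = _clip_positive(
        k_mean + rng.normal(0.0, noise["potassium"], n), 0.5, "potassium", clip_log
    )

    # drug flags by indication; below-threshold probability is solved so the
    # marginal prevalence hits its target
    trigger_values = {"pth": pth, "p": p, "ca": ca}
    flags: Dict[str, np.ndarray] = {}
    for drug in DRUGS:
        target = config.drug_prevalence_targets.get(drug, 0.0)
        rule = config.treatment_rules.get(drug)
        u = rng.random(n)
        if rule is None:
            flags[drug] = (u < target).astype(np.int64)
            continue
        above = trigger_values[rule.trigger] > rule.threshold
        q = float(above.mean())
        p_above = rule.probability
        if q >= 1.0:
            p_below = 0.0
            p_above = target
        else:
            p_below = float(np.clip((target - p_above * q) / (1.0 - q), 0.0, 1.0))
        prob = np.where(above, p_above, p_below)
        flags[drug] = (u < prob).astype(np.int64)

    # partial corrective calcium shifts for PTH-lowering / vitamin-D drugs
    w = cpl["treatment_to_ca"]
    for drug, ca_target in CA_PULL_TARGETS.items():
        mask = flags[drug] == 1
        ca = np.where(mask, ca + w * (ca_target - ca), ca)

    table = pd.DataFrame(
        {
            "patient_id": pat + 1,
            "month_index": month,
            "age": age,
            "gender": gender[pat],
            "vintage": vintage,
            "ca": ca,
            "p": p,
            "pth": pth,
            "alk_phos": alk_phos,
            "potassium": potassium,
            **{"drug_" + d: flags[d] for d in DRUGS},
        },
        columns=COLUMNS,
    )
    table.attrs["clipped"] = clip_log
    return table


def summarize_cohort(table: pd.DataFrame) -> Dict[str, object]:
    """Per-variable sample mean/SD and per-drug prevalence of a cohort.

    SDs use the population convention (ddof=0) so a single-record table
    reports SD 0 rather than NaN.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty table")
    numeric = BIOCHEM + ["age", "vintage"]
    means = {v: float(table[v].mean()) for v in numeric}
    sds = {v: float(table[v].std(ddof=0)) for v in numeric}
    prevalence = {d: float(table["drug_" + d].mean()) for d in DRUGS}
    return {
        "n_records": int(len(table)),
        "n_patients": int(table["patient_id"].nunique()),
        "male_fraction": float(table["gender"].mean()),
        "means": means,
        "sds": sds,
        "drug_prevalence": prevalence,
    }


# -- external interfaces --------------------------------------------------

def write_records(table: pd.DataFrame, path) -> None:
    """Write a record table as CSV in the documented dialect."""
    out = table.copy()
    for c in DRUG_COLUMNS + ["gender"]:
        out[c] = out[c].astype("Int64")
    out.to_csv(path, index=False, columns=COLUMNS)


def _flatten(d: dict, prefix: str = "") -> dict:
    flat = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            flat.update(_flatten(v, key + "."))
        else:
            flat[key] = v
    return flat


def config_to_yaml(config: CohortConfig, path=None) -> str:
    """Serialize a config as a flat dotted-key YAML document."""
    nested = {
        "n_patients": config.n_patients,
        "months_per_patient": config.months_per_patient,
        "seed": config.seed,
        "male_fraction": config.male_fraction,
        "marginal_targets": {
            k: {"mean": float(m), "sd": float(s)}
            for k, (m, s) in config.marginal_targets.items()
        },
        "drug_prevalence_targets": dict(config.drug_prevalence_targets),
        "coupling": dict(config.coupling),
        "noise_sd": dict(config.noise_sd),
        "patient_sd": dict(config.patient_sd),
        "treatment_rules": {
            d: {"trigger": r.trigger, "threshold": r.threshold, "probability": r.probability}
            for d, r in config.treatment_rules.items()
        },
    }
    text = yaml.safe_dump(_flatten(nested), sort_keys=True, default_flow_style=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_from_yaml(source) -> CohortConfig:
    """Read a config written by :func:`config_to_yaml` (path or text)."""
    if hasattr(source, "read"):
        flat = yaml.safe_load(source.read())
    elif isinstance(source, str) and "\n" in source:
        flat = yaml.safe_load(source)
    else:
        with open(source) as fh:
            flat = yaml.safe_load(fh)
    nested: dict = {}
    for key, value in flat.items():
        parts = key.split(".")
        d = nested
        for part in parts[:-1]:
            d = d.setdefault(part, {})
        d[parts[-1]] = value
    marginals = {
        k: (float(v["mean"]), float(v["sd"]))
        for k, v in nested.get("marginal_targets", {}).items()
    }
    rules = {
        d: TreatmentRule(r["trigger"], float(r["threshold"]), float(r["probability"]))
        for d, r in nested.get("treatment_rules", {}).items()
    }
    return CohortConfig(
        n_patients=int(nested["n_patients"]),
        months_per_patient=int(nested["months_per_patient"]),
        seed=int(nested["seed"]),
        male_fraction=float(nested["male_fraction"]),
        marginal_targets=marginals,
        drug_prevalence_targets={
            k: float(v) for k, v in nested.get("drug_prevalence_targets", {}).items()
        },
        coupling={k: float(v) for k, v in nested.get("coupling", {}).items()},
        noise_sd={k: float(v) for k, v in nested.get("noise_sd", {}).items()},
        patient_sd={k: float(v) for k, v in nested.get("patient_sd", {}).items()},
        treatment_rules=rules,
    )
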