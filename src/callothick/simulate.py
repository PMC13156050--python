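"""Synthetic cohorts with a planted crossover group x age effect.

The generator emulates the structure of a first-episode schizophrenia /
healthy control morphometry study: per-subject demographics (age, sex,
education years, total intracranial volume), 100-node callosal thickness
profiles in which the patient-vs-control difference changes sign at a
planted crossover age on a chosen set of nodes, and PANSS-style symptom
scores for patients that share a planted rank-1 latent covariance with the
thickness x age interaction.  Everything is driven by a single seed, so
identical configurations reproduce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "baseline_profile",
    "simulate_cohort",
    "PANSS_ITEMS",
    "SYMPTOM_FACTORS",
]

#: PANSS-style item columns: 7 positive, 7 negative, 16 general items
PANSS_ITEMS: tuple[str, ...] = tuple(
    [f"P{i}" for i in range(1, 8)]
    + [f"N{i}" for i in range(1, 8)]
    + [f"G{i}" for i in range(1, 17)]
)

#: four-factor model: uniform-weight means of the item groups.  The factor
#: composition follows the usual positive / negative / affective
#: (depression-anxiety) / cognitive (disorganisation) split of PANSS items.
SYMPTOM_FACTORS: dict[str, tuple[str, ...]] = {
    "positive": ("P1", "P3", "P5", "P6", "G9", "G12"),
    "negative": ("N1", "N2", "N3", "N4", "N6", "G7", "G16"),
    "affective": ("G1", "G2", "G3", "G4", "G6", "P4"),
    "cognitive": ("P2", "N5", "N7", "G5", "G10", "G11", "G13", "G15"),
}

# Table-1-like demographic marginals (per group): education years and total
# intracranial volume (cm^3)
_EDU = {"patient": (11.27, 2.81), "control": (15.09, 3.17)}
_TIV = {"patient": (1449.59, 127.23), "control": (1446.47, 123.79)}
# reference values at which covariate effects are zero (close to the
# pooled means, fixed so the baseline profile does not drift with n)
_EDU_REF = 13.0
_TIV_REF = 1448.0


@dataclass
class SyntheticCohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the reference study's sample (151 patients, 278
    controls, ages 11-42) with a planted crossover at 25 years on the
    splenium window (nodes 13-23).
    """

    n_patients: int = 151
    n_controls: int = 278
    age_range: tuple[float, float] = (11.0, 42.0)
    crossover_age: float = 25.0
    effect_slope: float = 0.05  # mm of group difference per year of age
    affected_nodes: tuple[int, ...] = tuple(range(13, 24))
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.15, "education": 0.02, "tiv": 0.001}
    )
    noise_sd: float = 0.5  # mm, per node
    symptom_latent_strength: float = 0.5  # corr(latent, interaction) in [0, 1]
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.age_range
        if not lo < self.crossover_age < hi:
            raise ValueError(
                f"crossover age {self.crossover_age} must lie strictly inside "
                f"the age range {self.age_range}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.symptom_latent_strength <= 1:
            raise ValueError("symptom_latent_strength must be in [0, 1]")
        nodes = np.asarray(self.affected_nodes)
        if len(nodes) == 0 or nodes.min() < 0 or nodes.max() > 99:
            raise ValueError("affected_nodes must be a non-empty subset of 0..99")
        min_n = len(self.covariate_effects) + 3
        if self.n_patients < min_n or self.n_controls < min_n:
            raise ValueError(
                f"need at least {min_n} subjects per group for an identifiable model"
            )


@dataclass
class SyntheticTruth:
    """Ground truth planted in a simulated cohort."""

    crossover_age: float
    effect_slope: float
    affected_nodes: np.ndarray
    baseline: np.ndarray  # (100,) mm
    design_salience: np.ndarray  # unit vector over [thickness, age, interaction]
    item_salience: np.ndarray  # unit vector over the 30 PANSS items
    latent_strength: float
    singular_value: float  # population singular value of the item-level R

    def theta_true(self, age, node: int) -> np.ndarray:
        """Planted group effect (patient - control, mm) at ``age`` and node."""
        age = np.asarray(age, dtype=float)
        if node in set(int(i) for i in self.affected_nodes):
            return self.effect_slope * (age - self.crossover_age)
        return np.zeros_like(age)


def baseline_profile(n_nodes: int = 100) -> np.ndarray:
    """Smooth positive thickness template (mm), node 0 posterior.

    Thick splenium (posterior hump) and genu (anterior hump), a thinner
    isthmus dip around nodes 25-35, and a moderate body in between; values
    range roughly 4-9 mm, comparable to adult midsagittal profiles.
    """
    i = np.arange(n_nodes)
    return (
        5.0
        + 3.0 * np.exp(-0.5 * ((i - 10.0) / 9.0) ** 2)
        + 3.5 * np.exp(-0.5 * ((i - 90.0) / 8.0) ** 2)
        - 1.5 * np.exp(-0.5 * ((i - 30.0) / 7.0) ** 2)
    )


# item-salience template: symptom burden loads on negative and general
# items, none on positive items (fixed, unit-normalised below)
_ITEM_LOADINGS = {"P": 0.0, "N": 1.0, "G": 0.6}
_ITEM_SIGNAL = 1.0  # item-score units per latent-score unit
_ITEM_NOISE = 0.8  # independent item noise SD


def _item_salience() -> np.ndarray:
    v = np.array([_ITEM_LOADINGS[name[0]] for name in PANSS_ITEMS], dtype=float)
    return v / np.linalg.norm(v)


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1)
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def simulate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (cohort, thickness profiles, patient symptoms, truth).

    Thickness per node j:  baseline_j + covariate effects + group *
    effect_slope * (age - crossover) on affected nodes + N(0, noise_sd^2).
    Patient symptom items:  item_salience * latent + independent noise,
    where the latent correlates with the z(region thickness) * z(age)
    interaction at exactly ``symptom_latent_strength``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_demo, rng_noise, rng_sym = (np.random.default_rng(s) for s in ss.spawn(3))

    n = config.n_patients + config.n_controls
    group = np.array([1] * config.n_patients + [0] * config.n_controls)
    labels = np.where(group == 1, "patient", "control")
    lo, hi = config.age_range
    age = rng_demo.uniform(lo, hi, n)
    sex = rng_demo.binomial(1, 0.5, n)  # 1 = male
    edu = np.empty(n)
    tiv = np.empty(n)
    for lab in ("patient", "control"):
        m = labels == lab
        edu[m] = rng_demo.normal(*_EDU[lab], m.sum())
        tiv[m] = rng_demo.normal(*_TIV[lab], m.sum())
    edu = np.clip(edu, 1.0, None)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "group": labels,
            "age": np.round(age, 2),
            "sex": sex,
            "education": np.round(edu, 2),
            "tiv": np.round(tiv, 2),
        }
    )

    base = baseline_profile()
    nodes = np.arange(100)
    affected = np.isin(nodes, np.asarray(config.affected_nodes))
    eff = config.covariate_effects
    subject_shift = (
        eff.get("sex", 0.0) * sex
        + eff.get("education", 0.0) * (edu - _EDU_REF)
        + eff.get("tiv", 0.0) * (tiv - _TIV_REF)
    )
    planted = (
        group[:, None]
        * config.effect_slope
        * (cohort["age"].to_numpy() - config.crossover_age)[:, None]
        * affected[None, :]
    )
    thick = (
        base[None, :]
        + subject_shift[:, None]
        + planted
        + rng_noise.normal(0.0, config.noise_sd, (n, 100))
    )
    profiles = pd.DataFrame(
        thick, columns=[f"node_{j:02d}" for j in nodes], index=cohort.index
    )

    # --- symptoms (patients only), rank-1 latent coupled to interaction ---
    pat = group == 1
    region_mean = thick[pat][:, affected].mean(axis=1)
    inter = _zscore(_zscore(region_mean) * _zscore(cohort.loc[pat, "age"].to_numpy()))
    s = config.symptom_latent_strength
    latent = s * inter + np.sqrt(1 - s**2) * rng_sym.normal(0, 1, pat.sum())
    v = _item_salience()
    items = (
        3.5
        + _ITEM_SIGNAL * latent[:, None] * v[None, :]
        + rng_sym.normal(0.0, _ITEM_NOISE, (pat.sum(), len(PANSS_ITEMS)))
    )
    items = np.clip(items, 1.0, 7.0)
    symptoms = pd.DataFrame(items, columns=list(PANSS_ITEMS))
    symptoms.insert(0, "subject_id", cohort.loc[pat, "subject_id"].to_numpy())
    for fac, members in SYMPTOM_FACTORS.items():
        symptoms[fac] = symptoms[list(members)].mean(axis=1)

    # population singular value of the item-level cross-block matrix
    # R = corr(interaction, item_j): s * signal * v_j / sd(item_j)
    sd_items = np.sqrt(_ITEM_SIGNAL**2 * v**2 + _ITEM_NOISE**2)
    sv = float(np.linalg.norm(s * _ITEM_SIGNAL * v / sd_items))

    truth = SyntheticTruth(
        crossover_age=config.crossover_age,
        effect_slope=config.effect_slope,
        affected_nodes=nodes[affected],
        baseline=base,
        design_salience=np.array([0.0, 0.0, 1.0]),
        item_salience=v,
        latent_strength=s,
        singular_value=sv,
    )
    return cohort, profiles, symptoms, truth


def write_tables(
    out_dir: str | Path,
    cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    symptoms: pd.DataFrame,
) -> dict[str, Path]:
    """Write the three cohort tables as UTF-8 CSV with headers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "profiles": out / "thickness_profiles.csv",
        "symptoms": out / "symptoms.csv",
    }
    cohort.to_csv(paths["cohort"], index=False)
    profiles.to_csv(paths["profiles"], index=False)
    symptoms.to_csv(paths["symptoms"], index=False)
    return paths
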