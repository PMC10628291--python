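"""Synthetic study generator.

Emulates the statistical structure of a multi-compound rat study: compounds
with fixed-length descriptor vectors, conditions = compound x {3,7,14,28}
days x {low,mid,high} dose, several animals per condition plus time-matched
vehicle controls, and a smooth ground-truth condition -> profile map with
per-animal measurement noise.

The ground-truth effect is linear in a low-dimensional projection of the
descriptors and multiplicative in relative dose and log time, so it is
learnable at desk scale yet varies non-trivially across conditions. The
white-blood-cell differential is generated on a simplex scaled to 100, so
per-animal noise places sums near 100 and occasionally past the 105 validity
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DOSE_VALUES, TIME_POINTS, StudyDataset, TreatmentCondition
from .panel import EndpointPanel, WBC_CODES, default_panel

#: plausible healthy-rat baseline for the default 38-endpoint panel,
#: in the panel's natural units (panel order)
_BASELINE = {
    "ALP": 250.0, "ALT": 40.0, "AST": 80.0, "DBIL": 0.05, "GTP": 1.0,
    "LDH": 300.0, "TBIL": 0.10, "BUN": 15.0, "Ca": 10.0, "Cl": 105.0,
    "CRE": 0.35, "IP": 7.0, "K": 4.5, "Na": 142.0, "A/G": 1.5,
    "GLC": 130.0, "PL": 120.0, "RALB": 4.2, "TC": 70.0, "TG": 60.0,
    "TP": 6.0, "APTT": 18.0, "Bas": 0.5, "Eos": 1.5, "Fbg": 220.0,
    "Hb": 15.0, "Ht": 45.0, "Lym": 78.0, "MCH": 19.0, "MCHC": 33.0,
    "MCV": 55.0, "Mono": 2.0, "Neu": 18.0, "Plat": 100.0, "PT": 15.0,
    "RBC": 8.0, "Ret": 3.0, "WBC": 80.0,
}

#: endpoints with a built-in monotone dose/time response and the maximal
#: fold-change of their shift at (high dose, 28 days, fully susceptible
#: compound); hepatotoxicity and nephrotoxicity markers
_TOXIC_EFFECTS = {
    "ALT": 2.5, "AST": 2.0, "LDH": 1.5, "ALP": 0.8, "GTP": 1.2,
    "TBIL": 3.0, "DBIL": 3.0, "BUN": 0.8, "CRE": 0.6,
}

#: relative shift of the neutrophil share at maximal effect (inflammation)
_NEU_SHIFT = 1.5


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic fixture."""

    n_compounds: int = 20
    descriptor_dim: int = 8
    n_animals_per_condition: int = 5
    n_controls_per_time: int = 10
    noise_cv: float = 0.05  # per-endpoint noise sd as a fraction of baseline
    times: tuple[int, ...] = TIME_POINTS
    dose_levels: tuple[str, ...] = ("low", "mid", "high")
    seed: int = 0

    def __post_init__(self):
        if min(self.n_compounds, self.descriptor_dim, self.n_animals_per_condition,
               self.n_controls_per_time) < 1:
            raise ValueError("all fixture counts must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class GroundTruthModel:
    """Noiseless condition -> profile map underlying a fixture."""

    panel: EndpointPanel
    baseline: np.ndarray
    noise_sd: np.ndarray
    projection: np.ndarray  # (D, 2) descriptor projection
    susceptibility_w: np.ndarray  # (2,) weights of the susceptibility score
    effect_scale: np.ndarray  # (|panel|,) maximal relative shift per endpoint
    max_dose: float = 10.0
    max_time: float = 28.0
    _wbc_idx: np.ndarray = field(init=False)

    def __post_init__(self):
        self._wbc_idx = np.array([self.panel.index(c) for c in WBC_CODES])

    def susceptibility(self, s: np.ndarray) -> float:
        """Compound susceptibility in (0, 1): sigmoid of a linear score on
        the projected descriptors."""
        u = np.asarray(s, dtype=float) @ self.projection
        return float(1.0 / (1.0 + np.exp(-(u @ self.susceptibility_w))))

    def intensity(self, s: np.ndarray, dose_value: float, time_days: float) -> float:
        """Effect intensity in [0, 1]; monotone non-decreasing in dose and time."""
        return (
            self.susceptibility(s)
            * (dose_value / self.max_dose)
            * (np.log1p(time_days) / np.log1p(self.max_time))
        )

    def profile(self, s: np.ndarray, dose_value: float, time_days: float) -> np.ndarray:
        """Noiseless treated profile; WBC differential renormalized to 100."""
        a = self.intensity(s, dose_value, time_days)
        prof = self.baseline * (1.0 + self.effect_scale * a)
        w = prof[self._wbc_idx]
        prof[self._wbc_idx] = 100.0 * w / w.sum()
        return prof

    def control_profile(self) -> np.ndarray:
        prof = self.baseline.copy()
        w = prof[self._wbc_idx]
        prof[self._wbc_idx] = 100.0 * w / w.sum()
        return prof


def _default_baseline(panel: EndpointPanel) -> np.ndarray:
    return np.array([_BASELINE[c] for c in panel.codes])


def _default_effect_scale(panel: EndpointPanel) -> np.ndarray:
    scale = np.zeros(len(panel))
    for code, s in _TOXIC_EFFECTS.items():
        scale[panel.index(code)] = s
    scale[panel.index("Neu")] = _NEU_SHIFT
    return scale


def make_fixture(
    config: FixtureConfig | None = None, panel: EndpointPanel | None = None
) -> tuple[StudyDataset, GroundTruthModel, np.ndarray]:
    """Build a synthetic study: (dataset, ground truth, descriptor matrix).

    Deterministic given ``config.seed``. Descriptors are standard normal;
    treated animals are ground-truth profile + N(0, noise_sd); controls are
    baseline + noise, time-matched, with no compound.
    """
    config = config or FixtureConfig()
    panel = panel or default_panel()
    rng = np.random.default_rng(config.seed)

    D = config.descriptor_dim
    descriptors = rng.standard_normal((config.n_compounds, D))
    compound_ids = [f"C{i:03d}" for i in range(config.n_compounds)]

    baseline = _default_baseline(panel)
    gt = GroundTruthModel(
        panel=panel,
        baseline=baseline,
        noise_sd=config.noise_cv * baseline,
        projection=rng.standard_normal((D, 2)) / np.sqrt(D),
        susceptibility_w=rng.standard_normal(2) + np.array([1.0, 0.0]),
        effect_scale=_default_effect_scale(panel),
    )

    rows = []
    animal = 0
    for ci, cid in enumerate(compound_ids):
        for t in config.times:
            for level in config.dose_levels:
                prof = gt.profile(descriptors[ci], DOSE_VALUES[level], t)
                for _ in range(config.n_animals_per_condition):
                    vals = prof + rng.normal(0.0, gt.noise_sd)
                    vals = np.maximum(vals, 0.0)
                    rows.append(
                        [f"A{animal:05d}", cid, "treated", level, t] + list(vals)
                    )
                    animal += 1
    ctrl = gt.control_profile()
    for t in config.times:
        for _ in range(config.n_controls_per_time):
            vals = np.maximum(ctrl + rng.normal(0.0, gt.noise_sd), 0.0)
            rows.append([f"A{animal:05d}", "", "control", "", t] + list(vals))
            animal += 1

    records = pd.DataFrame(
        rows, columns=["animal_id", "compound_id", "group", "dose_level", "time_days"] + panel.codes
    )
    compounds = pd.DataFrame({"compound_id": compound_ids})
    dataset = StudyDataset(panel=panel, records=records, compounds=compounds)
    return dataset, gt, descriptors


def oracle_condition_profile(gt: GroundTruthModel, condition: TreatmentCondition,
                             descriptors: np.ndarray) -> np.ndarray:
    """Noiseless target profile for a condition — the recovery target for
    trained models."""
    return gt.profile(np.asarray(descriptors, dtype=float),
                      condition.dose_value, condition.time_days)


def make_population_controls(gt: GroundTruthModel, n_animals: int, seed: int = 0) -> np.ndarray:
    """Vehicle-control population (animals x panel): baseline + noise."""
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rng = np.random.default_rng(seed)
    ctrl = gt.control_profile()
    return np.maximum(ctrl + rng.normal(0.0, gt.noise_sd, size=(n_animals, len(gt.panel))), 0.0)
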