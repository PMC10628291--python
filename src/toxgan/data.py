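"""Study-table containers and I/O, [-1, 1] feature scaling, and the
harmonization filters used before cross-dataset comparison.

A study table is one row per animal: identifiers, group (treated/control),
dose level, time point, and one column per endpoint code. Treated animals
belong to a treatment condition — a (compound, dose level, time) triple; the
dose levels low/mid/high stand in ratio 1:3:10 anchored at the maximum
tolerated dose. Control animals are vehicle-treated and time-matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import EndpointPanel, default_panel

logger = logging.getLogger(__name__)

#: relative numeric dose for each dose-level token (low:mid:high = 1:3:10)
DOSE_VALUES = {"low": 1.0, "mid": 3.0, "high": 10.0}
TIME_POINTS = (3, 7, 14, 28)

ID_COLUMNS = ["animal_id", "compound_id", "group", "dose_level", "time_days"]


class SchemaError(ValueError):
    """The study table does not match the expected column schema."""


@dataclass(frozen=True)
class TreatmentCondition:
    """One (compound, dose level, time point) combination."""

    compound_id: str
    dose_level: str
    time_days: int
    descriptors: np.ndarray | None = None

    def __post_init__(self):
        if self.dose_level not in DOSE_VALUES:
            raise ValueError(f"unknown dose level {self.dose_level!r}")

    @property
    def dose_value(self) -> float:
        return DOSE_VALUES[self.dose_level]

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.compound_id, self.dose_level, int(self.time_days))

    def condition_vector(self, descriptors: np.ndarray | None = None) -> np.ndarray:
        """c = concat(s, d, t) in natural units."""
        s = descriptors if descriptors is not None else self.descriptors
        if s is None:
            raise ValueError(f"no descriptors available for {self.compound_id}")
        return np.concatenate([np.asarray(s, dtype=float), [self.dose_value, float(self.time_days)]])


@dataclass(frozen=True)
class PathologyRecord:
    """One animal's endpoint measurement vector with its metadata."""

    animal_id: str
    group: str  # "treated" | "control"
    values: np.ndarray
    compound_id: str | None = None
    dose_level: str | None = None
    time_days: int = 0

    def __post_init__(self):
        if self.group not in ("treated", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("record values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def condition_key(self):
        if self.group != "treated":
            return None
        return (self.compound_id, self.dose_level, int(self.time_days))


@dataclass
class StudyDataset:
    """A panel, per-animal records, the treated conditions, and compounds.

    Records are stored as a DataFrame (one row per animal: id columns plus
    one column per endpoint code), which is also the on-disk CSV layout.
    """

    panel: EndpointPanel
    records: pd.DataFrame
    compounds: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["compound_id"]))

    def __post_init__(self):
        missing = [c for c in ID_COLUMNS + self.panel.codes if c not in self.records.columns]
        if missing:
            raise SchemaError(f"study table missing columns: {missing}")
        self.validate()

    # -- accessors -----------------------------------------------------------
    @property
    def conditions(self) -> list[TreatmentCondition]:
        t = self.records[self.records["group"] == "treated"]
        keys = (
            t[["compound_id", "dose_level", "time_days"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        return [
            TreatmentCondition(str(k.compound_id), str(k.dose_level), int(k.time_days))
            for k in keys
        ]

    def treated_values(self, condition: TreatmentCondition) -> np.ndarray:
        """Matrix (animals x panel) of the condition's treated records."""
        m = (
            (self.records["group"] == "treated")
            & (self.records["compound_id"] == condition.compound_id)
            & (self.records["dose_level"] == condition.dose_level)
            & (self.records["time_days"] == condition.time_days)
        )
        return self.records.loc[m, self.panel.codes].to_numpy(dtype=float)

    def control_values(self, time_days: int | None = None) -> np.ndarray:
        """Time-matched control matrix; all controls when time is None."""
        m = self.records["group"] == "control"
        if time_days is not None:
            m &= self.records["time_days"] == time_days
        return self.records.loc[m, self.panel.codes].to_numpy(dtype=float)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def endpoint_matrix(self, group: str | None = None) -> np.ndarray:
        df = self.records if group is None else self.records[self.records["group"] == group]
        return df[self.panel.codes].to_numpy(dtype=float)

    def iter_records(self) -> Iterable[PathologyRecord]:
        for _, r in self.records.iterrows():
            yield PathologyRecord(
                animal_id=str(r["animal_id"]),
                group=str(r["group"]),
                values=r[self.panel.codes].to_numpy(dtype=float),
                compound_id=None if r["group"] == "control" else str(r["compound_id"]),
                dose_level=None if r["group"] == "control" else str(r["dose_level"]),
                time_days=int(r["time_days"]),
            )

    # -- invariants ----------------------------------------------------------
    def validate(self) -> None:
        vals = self.records[self.panel.codes].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("study table contains non-finite endpoint values")
        bad_group = set(self.records["group"]) - {"treated", "control"}
        if bad_group:
            raise SchemaError(f"unknown group tokens: {sorted(bad_group)}")
        treated = self.records[self.records["group"] == "treated"]
        bad_dose = set(treated["dose_level"]) - set(DOSE_VALUES)
        if bad_dose:
            raise SchemaError(f"unknown dose-level tokens: {sorted(bad_dose)}")


# ---------------------------------------------------------------------------
# study-table I/O
# ---------------------------------------------------------------------------

def load_study_table(path, panel: EndpointPanel | None = None) -> StudyDataset:
    """Read a study CSV; rows with any non-finite endpoint value are dropped
    (and counted in the log), mirroring how incomplete lab reports are
    handled.
    """
    panel = panel or default_panel()
    df = pd.read_csv(path, keep_default_na=True, na_values=[""], float_precision="round_trip")
    missing = [c for c in ID_COLUMNS + panel.codes if c not in df.columns]
    if missing:
        raise SchemaError(f"study table at {path!r} missing columns: {missing}")

    vals = df[panel.codes].apply(pd.to_numeric, errors="coerce")
    ok = np.isfinite(vals.to_numpy(dtype=float)).all(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("load_study_table: dropped %d rows with non-finite endpoint values", n_drop)
    df = df.loc[ok].copy()
    df[panel.codes] = vals.loc[ok]

    treated = df["group"] == "treated"
    bad_dose = ~df.loc[treated, "dose_level"].isin(DOSE_VALUES)
    if bad_dose.any():
        row = df.loc[treated].index[bad_dose.to_numpy()][0]
        raise SchemaError(f"unknown dose-level token at row {row}: "
                          f"{df.loc[row, 'dose_level']!r}")
    try:
        df["time_days"] = df["time_days"].astype(int)
    except (TypeError, ValueError) as e:
        raise SchemaError(f"unparseable time_days column: {e}") from e
    df["animal_id"] = df["animal_id"].astype(str)
    return StudyDataset(panel=panel, records=df.reset_index(drop=True))


def write_study_table(dataset: StudyDataset, path) -> None:
    cols = ID_COLUMNS + dataset.panel.codes
    # 17 significant digits: float64 values round-trip bitwise
    dataset.records[cols].to_csv(path, index=False, float_format="%.17g")


def load_compound_table(path) -> pd.DataFrame:
    """Compound CSV: compound_id, smiles, optional atc_level1 /
    approval_year / drug_like columns."""
    df = pd.read_csv(path, keep_default_na=True, na_values=[""])
    if "compound_id" not in df.columns:
        raise SchemaError("compound table needs a compound_id column")
    return df


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalerState:
    """Per-feature min-max state mapping natural units onto [-1, 1].

    Constant features map to 0; out-of-range inputs are clipped at the
    bounds on the forward pass (inference conditions may fall outside the
    training envelope).
    """

    feature_min: np.ndarray
    feature_max: np.ndarray

    def __post_init__(self):
        self.feature_min = np.asarray(self.feature_min, dtype=float)
        self.feature_max = np.asarray(self.feature_max, dtype=float)
        if self.feature_min.shape != self.feature_max.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.feature_min > self.feature_max):
            raise ValueError("feature_min must be <= feature_max")

    @property
    def n_features(self) -> int:
        return self.feature_min.size

    @property
    def _span(self) -> np.ndarray:
        return self.feature_max - self.feature_min

    @classmethod
    def fit(cls, X: np.ndarray) -> "ScalerState":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("fit expects a non-empty 2-D matrix")
        return cls(feature_min=X.min(axis=0), feature_max=X.max(axis=0))

    def transform(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.shape[-1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {v.shape[-1]}")
        span = self._span
        out = np.zeros_like(v, dtype=float)
        nz = span > 0
        out[..., nz] = 2.0 * (v[..., nz] - self.feature_min[nz]) / span[nz] - 1.0
        return np.clip(out, -1.0, 1.0)

    def inverse_transform(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if u.shape[-1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {u.shape[-1]}")
        span = self._span
        out = np.empty_like(u, dtype=float)
        nz = span > 0
        out[..., nz] = (u[..., nz] + 1.0) / 2.0 * span[nz] + self.feature_min[nz]
        # constant features: any network-space value maps back to the constant
        out[..., ~nz] = self.feature_min[~nz]
        return out


@dataclass
class StudyScalers:
    """Paired scalers for the two vector spaces the networks see:
    ``condition`` covers (descriptors, dose, time); ``profile`` covers the
    endpoint panel."""

    condition: ScalerState
    profile: ScalerState


def fit_scaler(
    dataset: StudyDataset,
    descriptor_matrix: np.ndarray,
    compound_ids: Sequence[str] | None = None,
) -> StudyScalers:
    """Fit per-feature min-max scalers on the (training) dataset.

    ``descriptor_matrix`` is row-aligned to ``compound_ids`` (defaults to the
    dataset's compound table order). Non-finite descriptor entries are
    replaced by 0 before fitting, with a logged count — 3-D descriptor
    computations routinely fail for some molecules.
    """
    if dataset.n_records == 0:
        raise ValueError("cannot fit a scaler on an empty dataset")
    S = np.asarray(descriptor_matrix, dtype=float)
    n_bad = int((~np.isfinite(S)).sum())
    if n_bad:
        logger.info("fit_scaler: imputed %d non-finite descriptor entries with 0", n_bad)
        S = np.where(np.isfinite(S), S, 0.0)
    if compound_ids is None:
        compound_ids = list(dataset.compounds["compound_id"])
    if len(compound_ids) != S.shape[0]:
        raise ValueError("descriptor matrix not row-aligned to compounds")

    conds = dataset.conditions
    idx = {str(c): i for i, c in enumerate(compound_ids)}
    cond_rows = np.stack(
        [
            np.concatenate([S[idx[c.compound_id]], [c.dose_value, float(c.time_days)]])
            for c in conds
        ]
    )
    cond_state = ScalerState.fit(cond_rows)
    prof_state = ScalerState.fit(dataset.endpoint_matrix())
    return StudyScalers(condition=cond_state, profile=prof_state)


def apply_scaler(v: np.ndarray, state: ScalerState, direction: str = "forward") -> np.ndarray:
    if direction == "forward":
        return state.transform(v)
    if direction == "inverse":
        return state.inverse_transform(v)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# per-condition summaries & harmonization
# ---------------------------------------------------------------------------

def condition_mean_profile(dataset: StudyDataset, condition: TreatmentCondition) -> np.ndarray:
    """Element-wise mean profile over the condition's treated animals
    (natural units) — the real-side mean R-bar entering the similarity
    metrics."""
    vals = dataset.treated_values(condition)
    if vals.shape[0] == 0:
        raise KeyError(f"no treated records for condition {condition.key}")
    return vals.mean(axis=0)


#: exclusion rules applied before cross-dataset comparison
EXCLUSION_RULES = ("no_matched_control", "route_mismatch", "lab_mismatch", "female")


def filter_external_records(
    dataset: StudyDataset, metadata: pd.DataFrame
) -> tuple[StudyDataset, dict[str, int]]:
    """Drop records failing any harmonization rule.

    ``metadata`` is indexed (or keyed by an ``animal_id`` column) per record
    with boolean columns ``has_matched_vehicle_control``, ``same_route``,
    ``same_lab`` and a ``sex`` column ('M'/'F'). A record failing several
    rules is dropped once but increments every matching rule counter.
    """
    md = metadata.set_index("animal_id") if "animal_id" in metadata.columns else metadata
    md = md.loc[[str(a) for a in dataset.records["animal_id"]]]

    fails = {
        "no_matched_control": ~md["has_matched_vehicle_control"].to_numpy(bool),
        "route_mismatch": ~md["same_route"].to_numpy(bool),
        "lab_mismatch": ~md["same_lab"].to_numpy(bool),
        "female": md["sex"].astype(str).str.upper().eq("F").to_numpy(),
    }
    counts = {rule: int(m.sum()) for rule, m in fails.items()}
    drop = np.logical_or.reduce(list(fails.values()))
    kept = dataset.records.loc[~drop].reset_index(drop=True)
    if len(kept) == 0:
        logger.warning("filter_external_records: all records excluded")
    out = StudyDataset(panel=dataset.panel, records=kept, compounds=dataset.compounds)
    return out, counts


def map_common_endpoints(
    panel_a: EndpointPanel,
    panel_b: EndpointPanel,
    alias_table: Mapping[str, str] | None = None,
) -> EndpointPanel:
    """Intersection panel (panel_a order) across two naming dialects.

    ``alias_table`` maps panel_b codes to panel_a codes. Two panel_b codes
    mapping onto the same panel_a code is an error.
    """
    alias_table = dict(alias_table or {})
    translated = [alias_table.get(c, c) for c in panel_b.codes]
    seen: dict[str, str] = {}
    for orig, tr in zip(panel_b.codes, translated):
        if tr in seen and seen[tr] != orig:
            raise ValueError(f"alias collision: {seen[tr]!r} and {orig!r} both map to {tr!r}")
        seen[tr] = orig
    common = [c for c in panel_a.codes if c in set(translated)]
    if not common:
        logger.warning("map_common_endpoints: panels share no endpoints")
    return panel_a.subset(common)
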