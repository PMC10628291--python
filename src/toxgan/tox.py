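"""Toxicity assessment: treated-vs-control significance calls, the
per-endpoint consistency between synthetic-based and real-based calls,
upper-limit-of-normal (ULN) derivation, and Hy's-law counting over virtual
cohorts.

A toxicity call for one endpoint under one condition compares the treated
group to its time-matched vehicle controls: when both groups look normal
(Shapiro-Wilk screen at alpha = 0.05) an unpaired pooled-variance t-test is
used; otherwise a two-sided Mann-Whitney U test. p < 0.05 flags the call
significant. Consistency per endpoint is the fraction of conditions whose
real-based and synthetic-based flags agree.

Hy's-law screening counts cohort subjects whose ALT or AST exceeds its ULN
while TBIL also exceeds its ULN — the classic combination of hepatocellular
injury with loss of bilirubin clearance. The ULN of an endpoint is the
maximum over a designated vehicle-control population; exceedance is strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import StudyScalers, StudyDataset, TreatmentCondition
from .generation import ProfileModel, generate_condition_profile
from .panel import EndpointPanel

#: endpoint groups conventionally read together in organ-toxicity review
HEPATOTOXICITY_PANEL = ("ALT", "AST", "LDH", "ALP", "GTP", "TBIL", "DBIL")
NEPHROTOXICITY_PANEL = ("BUN", "CRE", "Na", "K", "Cl", "Ca", "IP")


@dataclass(frozen=True)
class ToxicityCall:
    condition_key: tuple
    endpoint: str
    source: str  # "real" | "synthetic"
    p_value: float
    significant: bool
    test_used: str  # "pooled_t" | "mann_whitney"


def significance_call(
    treated: np.ndarray,
    controls: np.ndarray,
    endpoint: str = "",
    condition_key: tuple = (),
    source: str = "real",
    alpha: float = 0.05,
) -> ToxicityCall:
    """Treated-vs-control call for a single endpoint.

    Both groups are screened for normality (Shapiro-Wilk, alpha 0.05); if
    both pass, an unpaired two-sided pooled-variance t-test (equal within-
    group variances assumed), else a two-sided Mann-Whitney U test.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(controls, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("need >= 2 values per group")
    if np.ptp(t) == 0 and np.ptp(c) == 0 and t[0] == c[0]:
        # identical constant groups: no evidence of any difference
        return ToxicityCall(tuple(condition_key), endpoint, source, 1.0, False, "pooled_t")

    def _normalish(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False  # constant sample: Shapiro undefined, not "normal"
        return stats.shapiro(x).pvalue >= 0.05

    if _normalish(t) and _normalish(c):
        res = stats.ttest_ind(t, c, equal_var=True)
        test = "pooled_t"
    else:
        res = stats.mannwhitneyu(t, c, alternative="two-sided")
        test = "mann_whitney"
    p = float(res.pvalue)
    return ToxicityCall(tuple(condition_key), endpoint, source, p, p < alpha, test)


@dataclass
class ConsistencyReport:
    per_endpoint: pd.DataFrame  # code, n_conditions, n_agreeing, consistency

    def rollup(self, codes: Sequence[str]) -> tuple[float, float]:
        """(min, max) consistency across an endpoint group."""
        sub = self.per_endpoint[self.per_endpoint["code"].isin(codes)]
        return float(sub["consistency"].min()), float(sub["consistency"].max())

    @property
    def hepatotoxicity_range(self) -> tuple[float, float]:
        return self.rollup(HEPATOTOXICITY_PANEL)

    @property
    def nephrotoxicity_range(self) -> tuple[float, float]:
        return self.rollup(NEPHROTOXICITY_PANEL)

    @property
    def overall(self) -> float:
        pe = self.per_endpoint
        return float(pe["n_agreeing"].sum() / pe["n_conditions"].sum())


def consistency(
    calls_real: Sequence[ToxicityCall], calls_synth: Sequence[ToxicityCall]
) -> ConsistencyReport:
    """Per endpoint: (#conditions where the significance flags agree) /
    (#conditions). The call sets must align on (condition, endpoint)."""
    real = {(c.condition_key, c.endpoint): c.significant for c in calls_real}
    synth = {(c.condition_key, c.endpoint): c.significant for c in calls_synth}
    if set(real) != set(synth):
        missing = set(real) ^ set(synth)
        raise ValueError(f"misaligned call sets; unmatched pairs: {sorted(missing)[:5]}")
    rows: dict[str, list[int]] = {}
    for key, flag in real.items():
        code = key[1]
        agree = int(flag == synth[key])
        rows.setdefault(code, []).append(agree)
    per_endpoint = pd.DataFrame(
        {
            "code": list(rows),
            "n_conditions": [len(v) for v in rows.values()],
            "n_agreeing": [int(np.sum(v)) for v in rows.values()],
        }
    )
    per_endpoint["consistency"] = per_endpoint["n_agreeing"] / per_endpoint["n_conditions"]
    return ConsistencyReport(per_endpoint=per_endpoint)


# ---------------------------------------------------------------------------
# ULN and Hy's law
# ---------------------------------------------------------------------------

@dataclass
class ULNTable:
    """Upper limit of normal per endpoint: the maximum over the designated
    control population (e.g. 28-day vehicle-treated rats)."""

    values: pd.Series  # indexed by endpoint code

    def __getitem__(self, code: str) -> float:
        return float(self.values[code])


def compute_uln(controls: np.ndarray, panel: EndpointPanel) -> ULNTable:
    controls = np.asarray(controls, dtype=float)
    if controls.ndim != 2 or controls.shape[0] == 0:
        raise ValueError("need a non-empty (animals x panel) control matrix")
    if controls.shape[1] != len(panel):
        raise ValueError("control matrix width must equal panel size")
    return ULNTable(values=pd.Series(controls.max(axis=0), index=panel.codes))


def hys_law_counts(
    cohort: np.ndarray, uln: ULNTable, panel: EndpointPanel
) -> dict[str, int]:
    """Strict-exceedance counts over a cohort: per-marker elevations and the
    Hy's-law combination (ALT > ULN or AST > ULN) and TBIL > ULN."""
    cohort = np.atleast_2d(np.asarray(cohort, dtype=float))
    if cohort.size and cohort.shape[1] != len(panel):
        raise ValueError("cohort width must equal panel size")
    for code in ("ALT", "AST", "TBIL"):
        if code not in uln.values.index:
            raise KeyError(f"ULN missing for required endpoint {code}")
    if cohort.size == 0:
        return {"n_alt": 0, "n_ast": 0, "n_tbil": 0, "n_hys": 0}
    alt = cohort[:, panel.index("ALT")] > uln["ALT"]
    ast = cohort[:, panel.index("AST")] > uln["AST"]
    tbil = cohort[:, panel.index("TBIL")] > uln["TBIL"]
    return {
        "n_alt": int(alt.sum()),
        "n_ast": int(ast.sum()),
        "n_tbil": int(tbil.sum()),
        "n_hys": int(((alt | ast) & tbil).sum()),
    }


# ---------------------------------------------------------------------------
# paired condition assessment
# ---------------------------------------------------------------------------

def assess_condition(
    model: ProfileModel,
    condition: TreatmentCondition,
    real_treated: np.ndarray,
    matched_controls: np.ndarray,
    scalers: StudyScalers,
    panel: EndpointPanel,
    seed: int = 0,
    descriptors: np.ndarray | None = None,
    n_draws: int = 100,
    alpha: float = 0.05,
) -> tuple[list[ToxicityCall], list[ToxicityCall]]:
    """Paired real/synthetic toxicity calls per endpoint for one condition.

    The synthetic side tests the ``n_draws`` individually valid generated
    profiles against the real matched controls; the real side tests the real
    treated animals against the same controls. Deterministic given seed.
    """
    res = generate_condition_profile(
        model, condition, scalers, n_target=n_draws, seed=seed,
        descriptors=descriptors, panel=panel,
    )
    synth_group = res.candidates[res.valid][:n_draws]
    real_calls, synth_calls = [], []
    for i, ep in enumerate(panel):
        real_calls.append(
            significance_call(
                real_treated[:, i], matched_controls[:, i],
                endpoint=ep.code, condition_key=condition.key, source="real", alpha=alpha,
            )
        )
        synth_calls.append(
            significance_call(
                synth_group[:, i], matched_controls[:, i],
                endpoint=ep.code, condition_key=condition.key, source="synthetic", alpha=alpha,
            )
        )
    return real_calls, synth_calls


def assess_dataset(
    model: ProfileModel,
    dataset: StudyDataset,
    scalers: StudyScalers,
    descriptors_by_id: Mapping[str, np.ndarray],
    seed: int = 0,
    n_draws: int = 100,
    alpha: float = 0.05,
    conditions: Sequence[TreatmentCondition] | None = None,
) -> ConsistencyReport:
    """Consistency of synthetic vs real toxicity calls over a dataset's
    conditions (time-matched controls per condition)."""
    conds = list(conditions) if conditions is not None else dataset.conditions
    all_real: list[ToxicityCall] = []
    all_synth: list[ToxicityCall] = []
    for k, cond in enumerate(conds):
        controls = dataset.control_values(cond.time_days)
        treated = dataset.treated_values(cond)
        r, s = assess_condition(
            model, cond, treated, controls, scalers, dataset.panel,
            seed=(seed * 9973 + k) % (2**31),
            descriptors=descriptors_by_id[cond.compound_id],
            n_draws=n_draws, alpha=alpha,
        )
        all_real.extend(r)
        all_synth.extend(s)
    return consistency(all_real, all_synth)
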