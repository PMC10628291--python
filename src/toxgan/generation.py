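"""Sampling synthetic profiles for a condition.

Candidate draws are rejected with a blood-cell-count plausibility check:
the five white-blood-cell differential percentages may not exceed a 105%
total (bench counting and rounding justify the 5% headroom). A condition's
reported profile is the mean of the first ``n_target`` (default 100) valid
draws; virtual cohorts keep each accepted draw as one subject, enforcing
validity per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .data import StudyScalers, TreatmentCondition
from .panel import EndpointPanel

#: maximal plausible WBC-differential total, percent
WBC_SUM_LIMIT = 105.0

#: noise draws per generator call while rejection sampling; fixed so that
#: results are independent of any external chunking of the output
_BLOCK = 512


class ProfileModel(Protocol):
    """What generation needs from a trained model."""

    @property
    def noise_dim(self) -> int: ...

    def infer(self, x: np.ndarray) -> np.ndarray: ...


@dataclass
class GenerationResult:
    condition: TreatmentCondition
    candidates: np.ndarray  # (n_attempted, |panel|), natural units
    valid: np.ndarray  # boolean per candidate
    mean_profile: np.ndarray | None  # mean of first n_target valid draws
    n_valid: int
    n_attempted: int
    seed: int


def wbc_validity_check(profile: np.ndarray, panel: EndpointPanel) -> bool:
    """True iff Neu + Eos + Bas + Mono + Lym <= 105 (percent, natural
    units); totals strictly above the limit are implausible cell counts."""
    idx = panel.wbc_indices
    if len(idx) != 5:
        raise ValueError(f"panel must flag exactly 5 WBC components, found {len(idx)}")
    return float(np.asarray(profile, dtype=float)[..., idx].sum()) <= WBC_SUM_LIMIT


def _wbc_valid_mask(profiles: np.ndarray, panel: EndpointPanel) -> np.ndarray:
    idx = panel.wbc_indices
    if len(idx) != 5:
        raise ValueError(f"panel must flag exactly 5 WBC components, found {len(idx)}")
    return profiles[:, idx].sum(axis=1) <= WBC_SUM_LIMIT


def _draw_batch(
    model: ProfileModel,
    cond_scaled: np.ndarray,
    scalers: StudyScalers,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    noise = rng.standard_normal((n, model.noise_dim))
    x = np.concatenate([np.tile(cond_scaled, (n, 1)), noise], axis=1)
    return scalers.profile.inverse_transform(model.infer(x))


def generate_condition_profile(
    model: ProfileModel,
    condition: TreatmentCondition,
    scalers: StudyScalers,
    n_target: int = 100,
    max_attempts_factor: int = 10,
    seed: int = 0,
    descriptors: np.ndarray | None = None,
    panel: EndpointPanel | None = None,
    strict: bool = True,
) -> GenerationResult:
    """Draw until ``n_target`` valid profiles are accumulated; the reported
    profile G-bar is their element-wise mean in natural units.

    Deterministic given ``seed``. If fewer than ``n_target`` draws pass the
    check within ``max_attempts_factor * n_target`` attempts, raise (or,
    with ``strict=False``, return a result whose mean_profile is None).
    """
    from .panel import default_panel

    panel = panel or default_panel()
    cond_scaled = scalers.condition.transform(condition.condition_vector(descriptors))
    rng = np.random.default_rng(seed)

    chunks: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    n_valid = 0
    n_attempted = 0
    max_attempts = max_attempts_factor * n_target
    while n_valid < n_target and n_attempted < max_attempts:
        n = min(_BLOCK, n_target - n_valid, max_attempts - n_attempted)
        batch = _draw_batch(model, cond_scaled, scalers, n, rng)
        ok = _wbc_valid_mask(batch, panel)
        chunks.append(batch)
        flags.append(ok)
        n_valid += int(ok.sum())
        n_attempted += n

    candidates = np.concatenate(chunks) if chunks else np.empty((0, len(panel)))
    valid = np.concatenate(flags) if flags else np.zeros(0, bool)
    if n_valid < n_target:
        if strict:
            raise RuntimeError(
                f"condition {condition.key}: only {n_valid}/{n_target} valid draws in "
                f"{n_attempted} attempts (validity rate {n_valid / max(n_attempted, 1):.3f})"
            )
        mean_profile = None
    else:
        mean_profile = candidates[valid][:n_target].mean(axis=0)
    return GenerationResult(
        condition=condition,
        candidates=candidates,
        valid=valid,
        mean_profile=mean_profile,
        n_valid=n_valid,
        n_attempted=n_attempted,
        seed=seed,
    )


def generate_cohort(
    model: ProfileModel,
    condition: TreatmentCondition,
    n_subjects: int,
    scalers: StudyScalers,
    seed: int = 0,
    descriptors: np.ndarray | None = None,
    panel: EndpointPanel | None = None,
    max_attempts_factor: int = 10,
) -> np.ndarray:
    """A virtual cohort: ``n_subjects`` individually valid profiles
    (invalid draws are rejected and redrawn), natural units.

    Noise is consumed in fixed-size internal blocks, so the result for a
    given seed does not depend on how the caller chunks or streams the
    output. Aborts if the observed validity rate drops below
    1 / max_attempts_factor.
    """
    from .panel import default_panel

    panel = panel or default_panel()
    cond_scaled = scalers.condition.transform(condition.condition_vector(descriptors))
    rng = np.random.default_rng(seed)

    rows: list[np.ndarray] = []
    n_have = 0
    n_attempted = 0
    min_rate = 1.0 / max_attempts_factor
    while n_have < n_subjects:
        batch = _draw_batch(model, cond_scaled, scalers, _BLOCK, rng)
        ok = _wbc_valid_mask(batch, panel)
        accepted = batch[ok]
        rows.append(accepted)
        n_have += accepted.shape[0]
        n_attempted += _BLOCK
        if n_attempted >= 10 * _BLOCK and n_have / n_attempted < min_rate:
            raise RuntimeError(
                f"validity rate {n_have / n_attempted:.3f} below {min_rate:.3f}; aborting cohort"
            )
    return np.concatenate(rows)[:n_subjects]
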