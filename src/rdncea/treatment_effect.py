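"""Mapping an office-SBP reduction to endpoint-specific relative risks.

Meta-regressions of blood-pressure-lowering trials report standardized
relative risks per reference mmHg of office systolic BP reduction.  The
mapping is log-linear in the achieved reduction:

    RR(delta) = exp(ln(RR_ref) * delta / delta_ref)

so ``RR(0) = 1`` exactly and the configured anchor ``(RR_ref, delta_ref)``
is reproduced exactly at ``delta = delta_ref``.  The relative risk is applied
to baseline per-cycle event probabilities in the treated arm, by default as a
hazard ratio on the rate scale (``1 - (1-p)**RR``), with a probability-scale
fallback (``p * RR``) selectable for reproducibility against other
conventions; the two agree to first order for small p.

The effect size is assumed to be maintained over the cohort's lifetime; an
exponential-waning hook (half-life in years) exists for exploration and is
off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rdncea.errors import ConfigurationError
from rdncea.risk_equations import ENDPOINTS


@dataclass
class TreatmentEffect:
    """An office-SBP reduction and its meta-regression anchors.

    ``delta_osbp`` is the reduction vs. the comparator arm in mmHg (positive
    = reduction).  ``anchors`` maps endpoints to ``(RR_ref, delta_ref_mmHg)``
    pairs.  Endpoints without an anchor (configured ``None``) fall back to
    RR = 1.
    """

    delta_osbp: float = 4.9
    anchors: dict[str, tuple[float, float]] = field(default_factory=dict)
    hazard_scale: bool = True
    waning_half_life_years: float | None = None

    def __post_init__(self) -> None:
        for endpoint, anchor in self.anchors.items():
            if anchor is None:
                continue
            rr_ref, delta_ref = anchor
            if not (0.0 < rr_ref <= 1.0):
                raise ConfigurationError(
                    f"anchor RR for {endpoint!r} must be in (0, 1], got {rr_ref}"
                )
            if delta_ref <= 0:
                raise ConfigurationError(
                    f"anchor delta for {endpoint!r} must be > 0, got {delta_ref}"
                )

    def effective_delta(self, time_years: float = 0.0) -> float:
        if self.waning_half_life_years is None:
            return self.delta_osbp
        return self.delta_osbp * 0.5 ** (time_years / self.waning_half_life_years)


def rr_for_endpoint(
    effect: TreatmentEffect, endpoint: str, time_years: float = 0.0
) -> float:
    """Relative risk for one endpoint at the configured effect size."""
    if endpoint not in effect.anchors:
        raise ConfigurationError(
            f"no meta-regression anchor configured for endpoint {endpoint!r}"
        )
    anchor = effect.anchors[endpoint]
    if anchor is None:
        return 1.0
    rr_ref, delta_ref = anchor
    delta = effect.effective_delta(time_years)
    if delta == 0.0:
        return 1.0
    if delta == delta_ref:
        return rr_ref  # anchor reproduced exactly, no round-trip error
    return math.exp(math.log(rr_ref) * delta / delta_ref)


def apply_effect(
    p_baseline: float | np.ndarray, rr: float, hazard_scale: bool = True
) -> float | np.ndarray:
    """Apply a relative risk to a baseline per-cycle probability."""
    if rr <= 0:
        raise ConfigurationError(f"relative risk must be > 0, got {rr}")
    p = np.asarray(p_baseline, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ConfigurationError("p_baseline must lie in [0, 1]")
    if rr == 1.0:  # exact identity: null effect must be bitwise null
        return p_baseline if np.ndim(p_baseline) else float(p)
    if hazard_scale:
        out = -np.expm1(rr * np.log1p(-p))
    else:
        out = p * rr
    if np.ndim(p_baseline) == 0:
        return float(out)
    return out


def all_rrs(effect: TreatmentEffect) -> dict[str, float]:
    """Relative risks for every endpoint with a configured anchor."""
    return {
        e: (rr_for_endpoint(effect, e) if e in effect.anchors else 1.0)
        for e in ENDPOINTS
    }
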