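"""From a 4-class probability profile to PoD, predicted class and confidence.

The network's output for a substance is a probability profile
(p_NS, p_weak, p_moderate, p_strong/extreme).  Three derived quantities make
it usable in risk assessment:

* a continuous point of departure, the EC3-anchored weighted sum

      PoD_BN [%] = p_NS*100 + p_weak*10 + p_moderate*2 + p_strong*0.2,

  bounded in [0.2, 100] by construction;

* the most likely class (argmax; ties broken toward the more potent class,
  the conservative choice for risk assessment), with its class lower-bound
  PoD (100 / 10 / 2 / 0.2);

* a weight-of-evidence confidence level.  Each class's Generalized Bayes
  Factor is the posterior odds over the prior odds,
  GBF_k = [p_k/(1-p_k)] / [pi_k/(1-pi_k)] with pi the training-set class
  frequencies, transformed to decibans W_k = 10*log10(GBF_k).  Following a
  Jeffreys-style rule on the maximum W: |W| below 5 decibans is "low"
  confidence, 5 to 10 "moderate", 10 and above "high" (boundary values go to
  the higher-confidence bin; the maximum W is never negative since some
  p_k >= pi_k whenever both vectors sum to one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import PoDWeights, PotencyClass, ValidationError

__all__ = [
    "ProbabilityProfile",
    "ConfidenceResult",
    "pod_bn",
    "predicted_class",
    "class_pod_lower_bound",
    "gbf",
    "weight_of_evidence",
    "confidence_level",
    "confidence",
]

#: Tolerance on sum(profile) == 1.  Looser than the 1e-9 the network's own
#: posteriors satisfy, so that externally reported profiles rounded to four
#: decimals (which can sum to e.g. 1.0001) remain valid inputs.
PROFILE_SUM_TOL = 1e-3

_CLAMP_EPS = 1e-12  # keeps odds, hence GBF, finite at p in {0, 1}


@dataclass(frozen=True)
class ProbabilityProfile:
    """Posterior probabilities over the four potency classes."""

    p_ns: float
    p_weak: float
    p_moderate: float
    p_strong: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValidationError(f"profile entries must lie in [0, 1]: {arr}")
        if abs(arr.sum() - 1.0) > PROFILE_SUM_TOL:
            raise ValidationError(
                f"profile must sum to 1 within {PROFILE_SUM_TOL}: sum={arr.sum()}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.p_ns, self.p_weak, self.p_moderate, self.p_strong])

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ProbabilityProfile":
        arr = np.asarray(values, dtype=float)
        if arr.shape != (4,):
            raise ValidationError("profile needs exactly four probabilities")
        return cls(*(float(v) for v in arr))


@dataclass(frozen=True)
class ConfidenceResult:
    """Per-class GBF and W (deciban) values with the derived confidence."""

    gbf: tuple[float, float, float, float]
    w: tuple[float, float, float, float]
    max_w: float
    level: str


def pod_bn(profile: ProbabilityProfile, weights: PoDWeights = PoDWeights()) -> float:
    """Continuous point of departure: the weighted probability sum, in %."""
    return float(profile.as_array() @ weights.as_array())


def predicted_class(profile: ProbabilityProfile) -> PotencyClass:
    """Most likely class; ties go to the more potent class."""
    arr = profile.as_array()
    tied = np.flatnonzero(arr == arr.max())
    return PotencyClass(int(tied.max()))


def class_pod_lower_bound(
    potency: PotencyClass, weights: PoDWeights = PoDWeights()
) -> float:
    """Lower-bound PoD of a predicted class (its EC3-scale anchor, in %)."""
    return float(weights.as_array()[PotencyClass(potency)])


def _validated_priors(priors: Sequence[float]) -> np.ndarray:
    pi = np.asarray(priors, dtype=float)
    if pi.shape != (4,):
        raise ValidationError("need exactly four class priors")
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValidationError("priors must lie strictly inside (0, 1)")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValidationError(f"priors must sum to 1, got {pi.sum()}")
    return pi


def gbf(profile: ProbabilityProfile, priors: Sequence[float]) -> np.ndarray:
    """Generalized Bayes Factor per class: posterior odds / prior odds.

    Posterior probabilities are clamped to [1e-12, 1 - 1e-12] before the
    odds so the GBF stays finite at degenerate profiles.
    """
    pi = _validated_priors(priors)
    p = np.clip(profile.as_array(), _CLAMP_EPS, 1.0 - _CLAMP_EPS)
    return (p / (1.0 - p)) / (pi / (1.0 - pi))


def weight_of_evidence(gbf_values: Sequence[float]) -> np.ndarray:
    """W = 10 * log10(GBF), in decibans."""
    arr = np.asarray(gbf_values, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("GBF values must be finite and strictly positive")
    return 10.0 * np.log10(arr)


def confidence_level(w: Sequence[float]) -> str:
    """Jeffreys-style confidence from the maximum W across classes."""
    max_w = float(np.max(np.asarray(w, dtype=float)))
    magnitude = abs(max_w)
    if magnitude < 5.0:
        return "low"
    if magnitude < 10.0:
        return "moderate"
    return "high"


def confidence(
    profile: ProbabilityProfile, priors: Sequence[float]
) -> ConfidenceResult:
    """Full confidence assessment of a profile against training priors."""
    g = gbf(profile, priors)
    w = weight_of_evidence(g)
    return ConfidenceResult(
        gbf=tuple(float(v) for v in g),
        w=tuple(float(v) for v in w),
        max_w=float(w.max()),
        level=confidence_level(w),
    )
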