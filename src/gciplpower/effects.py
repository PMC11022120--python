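"""Effect-size model: translating a protective effect into a mean difference.

The trial compares a glucocorticoid-only control arm ("GC arm", whose
means and SDs come from the pilot cohort) against a GC + neuroprotective
test-drug arm.  A "protective effect of X%" means the test drug prevents
X% of the control arm's mean loss from baseline, so the between-arm mean
difference is

    delta = effect_size * (mean_baseline - mean_followup_gc)

With follow-up values as the endpoint (Method A) the test arm's mean is
the control follow-up mean plus delta; with change-from-baseline scores
(Method B) the test arm's mean change is (1 - effect_size) times the
control mean loss.  Both phrasings yield the identical between-arm
difference, which is all the two-sample machinery consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import InvalidEffectError

METHODS = ("A", "B")


@dataclass(frozen=True)
class EffectSpec:
    """A protective effect applied to a deteriorating OCT endpoint.

    Parameters
    ----------
    effect_size
        Fraction of the control-arm mean loss prevented, in (0, 1].
    mean_baseline, mean_followup_gc
        Control-arm means at baseline and at the follow-up visit, in the
        metric's units (µm or mm³).
    method
        ``"A"`` (follow-up values) or ``"B"`` (change from baseline).
    """

    effect_size: float
    mean_baseline: float
    mean_followup_gc: float
    method: str = "A"

    def __post_init__(self) -> None:
        if not 0 < self.effect_size <= 1:
            raise InvalidEffectError(
                f"effect_size must be in (0, 1], got {self.effect_size}"
            )
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")


def mean_loss(mean_baseline: float, mean_followup_gc: float) -> float:
    """Control-arm mean loss from baseline (baseline minus follow-up).

    Negative loss (an improving endpoint) is permitted but warned about,
    since the design formulas then size a trial to detect improvement.
    """
    loss = mean_baseline - mean_followup_gc
    if loss < 0:
        warnings.warn(
            f"improving endpoint: follow-up mean {mean_followup_gc} exceeds "
            f"baseline mean {mean_baseline}",
            UserWarning,
            stacklevel=2,
        )
    return loss


def delta(spec: EffectSpec) -> float:
    """Between-arm mean difference implied by the protective effect.

    Identical for Methods A and B: the mean of paired change scores is the
    difference of the visit means.
    """
    return spec.effect_size * mean_loss(spec.mean_baseline, spec.mean_followup_gc)


def test_drug_mean(spec: EffectSpec) -> float:
    """Assumed test-arm mean under the protective effect.

    Method A: the test arm retains more tissue, ``mean_followup_gc + delta``.
    Method B: the test arm's mean change score, ``(1 - effect) * mean loss``.
    """
    d = delta(spec)
    if spec.method == "A":
        return spec.mean_followup_gc + d
    return mean_loss(spec.mean_baseline, spec.mean_followup_gc) - d
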