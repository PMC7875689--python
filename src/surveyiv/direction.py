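"""Four-way causal-direction verdict from the Test A / Test B pair."""
from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = ["DirectionVerdict", "decide_direction", "VERDICTS"]

VERDICTS = (
    "treatment_causes_outcome",
    "outcome_causes_treatment",
    "inconclusive",
    "both_rejected",
)

_NARRATIVES = {
    "treatment_causes_outcome": (
        "Test A retained and Test B rejected: the instrument carries "
        "information about the outcome only through the treatment, consistent "
        "with the treatment causing the outcome."
    ),
    "outcome_causes_treatment": (
        "Test A rejected and Test B retained: conditioning on the treatment "
        "(a collider between instrument and outcome) induces dependence, "
        "consistent with the outcome causing the treatment."
    ),
    "inconclusive": (
        "Neither test rejected: the data cannot distinguish the causal "
        "direction at this significance level."
    ),
    "both_rejected": (
        "Both tests rejected: inconsistent with either single-direction "
        "model; possible unobserved confounding of treatment and outcome "
        "(the treatment is a collider once such confounding exists)."
    ),
}


@dataclass(frozen=True)
class DirectionVerdict:
    """The verdict plus the p-values that produced it."""

    verdict: str
    p_A: float
    p_B: float
    alpha: float
    outcome: str | None = None

    @property
    def narrative(self) -> str:
        return _NARRATIVES[self.verdict]

    def to_dict(self) -> dict:
        out = asdict(self)
        out["narrative"] = self.narrative
        return out


def decide_direction(p_A: float, p_B: float, alpha: float = 0.05,
                     outcome: str | None = None) -> DirectionVerdict:
    """Map the (Test A, Test B) p-values to a causal-direction verdict.

    The verdict is a pure function of which tests reject at ``alpha``:

    ========  ========  ==========================
    A rejects  B rejects  verdict
    ========  ========  ==========================
    no         yes        treatment_causes_outcome
    yes        no         outcome_causes_treatment
    no         no         inconclusive
    yes        yes        both_rejected
    ========  ========  ==========================
    """
    for name, p in (("p_A", p_A), ("p_B", p_B)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rej_a, rej_b = p_A < alpha, p_B < alpha
    if not rej_a and rej_b:
        verdict = "treatment_causes_outcome"
    elif rej_a and not rej_b:
        verdict = "outcome_causes_treatment"
    elif not rej_a and not rej_b:
        verdict = "inconclusive"
    else:
        verdict = "both_rejected"
    return DirectionVerdict(verdict, float(p_A), float(p_B), float(alpha), outcome)
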