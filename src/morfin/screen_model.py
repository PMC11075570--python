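"""Expected-frequency arithmetic for the fluorescent-colony plate screen.

The probability that a screened colony carries a fluorescent in-frame
fusion is modelled as the product of four factors:

``p_single``
    fraction of plasmids carrying exactly one insertion (manufacturer's
    guidance for the 1:1 molar-ratio reaction, about 1 in 200);
``orf_len / plasmid_len``
    probability that the insertion lands in the target ORF;
``orientation_factor``
    probability of the correct donor orientation (1/2, orientation is
    random);
``frame_factor``
    probability that the cut falls between codons rather than within one
    (1/3).

For the elongation-factor-G expression plasmid used as the worked example
(ORF 2,109 bp on a 6,837 bp plasmid) the reciprocal of the product rounds
to 3,890 colonies screened per expected positive.  Expression level and
target domain structure also shape the observed rate but cannot be
assigned numbers; the model deliberately excludes them, which is why
observed bench frequencies can exceed the prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .seq_core import ParameterError
from .fusion_classifier import LibrarySummary

__all__ = [
    "ScreenModelParams",
    "positive_frequency",
    "screening_burden",
    "BurdenPlan",
    "empirical_vs_expected",
    "ModelComparison",
]


@dataclass(frozen=True)
class ScreenModelParams:
    """The four frequency factors plus the plating density."""

    orf_len: int
    plasmid_len: int
    p_single: float = 1 / 200
    orientation_factor: float = 0.5
    frame_factor: float = 1 / 3
    colonies_per_plate: int = 500

    def __post_init__(self) -> None:
        for name in ("p_single", "orientation_factor", "frame_factor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must be in (0, 1], got {v}")
        if self.orf_len <= 0 or self.plasmid_len <= 0:
            raise ParameterError("orf_len and plasmid_len must be positive integers")
        if self.orf_len > self.plasmid_len:
            raise ParameterError(
                f"orf_len ({self.orf_len}) cannot exceed plasmid_len ({self.plasmid_len})"
            )
        if self.colonies_per_plate <= 0:
            raise ParameterError("colonies_per_plate must be positive")

    def with_(self, **kwargs) -> "ScreenModelParams":
        return replace(self, **kwargs)


def positive_frequency(params: ScreenModelParams) -> float:
    """Probability per colony of a fluorescent in-frame fusion."""
    return (
        params.p_single
        * (params.orf_len / params.plasmid_len)
        * params.orientation_factor
        * params.frame_factor
    )


@dataclass(frozen=True)
class BurdenPlan:
    colonies_per_positive: int
    k_expected_positives: int
    plates: int
    colonies_per_plate: int
    positive_frequency: float


def screening_burden(params: ScreenModelParams, k: int = 1) -> BurdenPlan:
    """Colonies per expected positive and plates needed for ``k`` positives.

    The reciprocal frequency is rounded to the nearest integer (the worked
    example's raw value ~3890.2 prints as 3890); plates are a ceiling at
    the configured plating density.
    """
    if k < 0:
        raise ParameterError(f"k must be >= 0, got {k}")
    freq = positive_frequency(params)
    colonies = int(round(1 / freq))
    plates = math.ceil(k * colonies / params.colonies_per_plate)
    return BurdenPlan(
        colonies_per_positive=colonies,
        k_expected_positives=k,
        plates=plates,
        colonies_per_plate=params.colonies_per_plate,
        positive_frequency=freq,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Simulated in-frame yield versus the factor-product model."""

    expected_frequency: float
    observed_frequency: float
    observed_ci_low: float
    observed_ci_high: float
    n_events: int
    n_in_frame: int
    agrees: bool


def empirical_vs_expected(
    summary: LibrarySummary, params: ScreenModelParams
) -> ModelComparison:
    """Compare a simulated library's in-frame fraction with the model.

    The simulated fraction conditions on a single insertion having
    happened, so it is multiplied by ``p_single`` before comparison.  The
    model value is checked against the exact binomial interval of the
    simulated fraction (scaled the same way); ``agrees`` is False when the
    model falls outside it.
    """
    if summary.n_events == 0:
        raise ParameterError("cannot compare an empty library summary")
    expected = positive_frequency(params)
    observed = params.p_single * summary.in_frame_fraction
    lo = params.p_single * summary.ci_low
    hi = params.p_single * summary.ci_high
    return ModelComparison(
        expected_frequency=expected,
        observed_frequency=observed,
        observed_ci_low=lo,
        observed_ci_high=hi,
        n_events=summary.n_events,
        n_in_frame=summary.n_in_frame,
        agrees=lo <= expected <= hi,
    )
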