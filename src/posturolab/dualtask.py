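"""Dual-task costs on balance metrics and on the concurrent counting task.

The cognitive load is a serial-7 subtraction task performed while standing.
Balance dual-task cost (DTC) is the percent change of a balance metric from
single-task to dual-task performance::

    DTC = 100 * (single_task - dual_task) / single_task

so a metric inflated by the added task yields a *negative* cost. The
cognitive costs (C-DTC) apply the same formula to correct-counting rates
(counts/min) across contexts: reference (seated/standing baseline) versus
sway, reference versus perturbation, and sway versus perturbation. The
three cognitive costs are algebraically linked: with r = reference, s =
sway and p = perturbation rates,

    1 - cdtc(s, p)/100 = (1 - cdtc(r, p)/100) / (1 - cdtc(r, s)/100).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UndefinedCostError

COUNTING_CONTEXTS = ("reference", "sway", "perturbation")


@dataclass(frozen=True)
class CountingRecord:
    """Correct serial-subtraction tally over one timed context."""

    n_correct_counts: int
    duration_s: float
    context: str

    def __post_init__(self):
        if self.n_correct_counts < 0:
            raise ValueError("count must be non-negative")
        if not self.duration_s > 0:
            raise ValueError("duration must be positive")
        if self.context not in COUNTING_CONTEXTS:
            raise ValueError(f"context must be one of {COUNTING_CONTEXTS}")


@dataclass(frozen=True)
class DTCResult:
    """A named dual-task cost with the two scores it derives from."""

    metric_name: str
    single_task: float
    dual_task: float
    dtc_percent: float


def dtc(single: float, dual: float, metric_name: str = "") -> float:
    """Percent dual-task cost of a balance metric.

    Negative when the dual-task value exceeds the single-task value.
    Undefined (raises) for a zero single-task score.
    """
    if single == 0:
        raise UndefinedCostError(
            f"dual-task cost undefined for zero single-task score"
            f"{' (' + metric_name + ')' if metric_name else ''}")
    return 100.0 * (single - dual) / single


def dtc_result(single: float, dual: float, metric_name: str) -> DTCResult:
    return DTCResult(metric_name, float(single), float(dual),
                     dtc(single, dual, metric_name))


def counting_rate(rec: CountingRecord) -> float:
    """Correct-counting rate in counts per minute."""
    return 60.0 * rec.n_correct_counts / rec.duration_s


def cognitive_dtc(cr_a: float, cr_b: float, name: str = "") -> float:
    """Percent cognitive dual-task cost between two counting rates.

    Applied as (reference, sway), (reference, perturbation) and
    (sway, perturbation); same arithmetic and sign convention as
    :func:`dtc`.
    """
    if cr_a == 0:
        raise UndefinedCostError(
            f"cognitive cost undefined for zero baseline rate"
            f"{' (' + name + ')' if name else ''}")
    return 100.0 * (cr_a - cr_b) / cr_a


def cognitive_dtc_set(reference: float, sway: float,
                      perturbation: float) -> dict:
    """All three cognitive costs from the three context counting rates."""
    return {
        "cdtc_sway": cognitive_dtc(reference, sway, "reference vs sway"),
        "cdtc_pert": cognitive_dtc(reference, perturbation,
                                   "reference vs perturbation"),
        "cdtc_sway_vs_pert": cognitive_dtc(sway, perturbation,
                                           "sway vs perturbation"),
    }
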