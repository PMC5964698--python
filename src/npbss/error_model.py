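"""Quality-value -> error-probability models and error-type partition.

Two models map an integer quality value q to a per-base error probability:

- theoretical (Phred definition):   P_th(q)    = 10^(-q/10)
- empirical CLR model:              P_error(q) = a * 10^(-q/10) + b

with default coefficients a = 0.3942, b = 0.0041 fitted on real PacBio CLR
data.  The empirical model sits below the theoretical one at low QV and
levels off at the additive floor b, reflecting that raw CLR base calls are
somewhat better than their nominal QV suggests while never becoming
error-free.

Users specify target *average* substitution/insertion/deletion rates; a
single multiplicative calibration factor reconciles those averages with the
QV-driven per-base probabilities, preserving the error-rate-vs-QV shape.
Each base's total error probability is then split among the three error
types proportionally to the configured rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .qv_model import QVTable

log = logging.getLogger(__name__)

DEFAULT_MODEL_A = 0.3942
DEFAULT_MODEL_B = 0.0041
DEFAULT_SUB_RATE = 0.06
DEFAULT_INS_RATE = 0.03
DEFAULT_DEL_RATE = 0.06
MAX_PER_BASE_PROB = 0.999  # per-base clamp; p = 1 would degenerate generation


@dataclass(frozen=True)
class EmpiricalErrorModel:
    """P_error(q) = a * 10^(-q/10) + b."""

    a: float = DEFAULT_MODEL_A
    b: float = DEFAULT_MODEL_B

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if not (0 <= self.b < 1):
            raise ValueError(f"b must be in [0, 1), got {self.b}")
        if self.a + self.b > 1:
            raise ValueError(
                f"a + b = {self.a + self.b} > 1: probability at QV 0 exceeds 1"
            )

    def error_prob(self, qv):
        """Vectorised P_error; accepts a scalar or array of QVs >= 0."""
        q = np.asarray(qv, dtype=float)
        if np.any(q < 0):
            raise ValueError("QV must be non-negative")
        out = self.a * np.power(10.0, -q / 10.0) + self.b
        return float(out) if np.isscalar(qv) else out


def theoretical_error_prob(qv):
    """Phred-defined error probability 10^(-qv/10)."""
    q = np.asarray(qv, dtype=float)
    if np.any(q < 0):
        raise ValueError("QV must be non-negative")
    out = np.power(10.0, -q / 10.0)
    return float(out) if np.isscalar(qv) else out


def empirical_error_prob(model: EmpiricalErrorModel, qv):
    """Empirical per-base error probability under ``model``."""
    return model.error_prob(qv)


def calibrate_scale(
    table: QVTable, model: EmpiricalErrorModel, target_total: float
) -> float:
    """Multiplier s with E_q[s * P_error(q)] = target_total over the table.

    s = target_total / sum_q proportion(q) * P_error(q).  A warning is
    logged when the scaled probability at any table QV would exceed the
    per-base clamp (the generator clamps at use).
    """
    if not (0 < target_total < 1):
        raise ValueError(f"target_total must be in (0, 1), got {target_total}")
    qv = np.asarray(table.qvs, dtype=float)
    props = np.asarray(table.proportions, dtype=float)
    mean_p = float(np.sum(props * model.error_prob(qv)))
    if mean_p <= 0:
        raise ValueError("table-averaged error probability is zero")
    scale = target_total / mean_p
    if scale * float(model.error_prob(qv).max()) > MAX_PER_BASE_PROB:
        log.warning(
            "calibration scale %.4g pushes some per-base probabilities above "
            "%.3f; they will be clamped",
            scale,
            MAX_PER_BASE_PROB,
        )
    return scale


@dataclass(frozen=True)
class ErrorConfig:
    """Target average error rates plus the QV->probability model.

    ``calibration_scale`` multiplies the model output so that the expected
    per-base error probability over a QV table equals
    sub_rate + ins_rate + del_rate; see :meth:`calibrated_against`.
    """

    sub_rate: float = DEFAULT_SUB_RATE
    ins_rate: float = DEFAULT_INS_RATE
    del_rate: float = DEFAULT_DEL_RATE
    model: EmpiricalErrorModel = field(default_factory=EmpiricalErrorModel)
    calibration_scale: float = 1.0

    def __post_init__(self) -> None:
        for name, r in (
            ("sub_rate", self.sub_rate),
            ("ins_rate", self.ins_rate),
            ("del_rate", self.del_rate),
        ):
            if not (0 <= r < 1):
                raise ValueError(f"{name} must be in [0, 1), got {r}")
        if self.total_rate >= 1:
            raise ValueError(f"rates sum to {self.total_rate} >= 1")
        if not self.calibration_scale > 0:
            raise ValueError("calibration_scale must be > 0")

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    def calibrated_against(self, table: QVTable) -> "ErrorConfig":
        """Return a copy whose calibration_scale targets ``total_rate``."""
        if self.total_rate == 0:
            # no errors requested; scale is irrelevant but must stay positive
            return replace(self, calibration_scale=1.0)
        return replace(
            self,
            calibration_scale=calibrate_scale(table, self.model, self.total_rate),
        )

    def per_base_error_prob(self, qv):
        """Calibrated, clamped per-base total error probability at ``qv``."""
        if self.total_rate == 0:
            q = np.asarray(qv, dtype=float)
            return 0.0 if np.isscalar(qv) else np.zeros_like(q)
        p = self.calibration_scale * self.model.error_prob(qv)
        return (
            float(min(p, MAX_PER_BASE_PROB))
            if np.isscalar(qv)
            else np.minimum(p, MAX_PER_BASE_PROB)
        )


def partition_error(p_error: float, cfg: ErrorConfig) -> tuple[float, float, float]:
    """Split a total per-base error probability into (sub, ins, del).

    The split is proportional to the configured rates, so the three parts
    sum to ``p_error`` exactly and genome-average rates come out in the
    configured ratio.
    """
    if not (0 <= p_error < 1):
        raise ValueError(f"p_error must be in [0, 1), got {p_error}")
    if p_error == 0:
        return (0.0, 0.0, 0.0)
    total = cfg.total_rate
    if total == 0:
        raise ConfigError("cannot partition a positive p_error with all-zero rates")
    return (
        p_error * cfg.sub_rate / total,
        p_error * cfg.ins_rate / total,
        p_error * cfg.del_rate / total,
    )
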