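"""Model-qualification statistics: fold error, AFE, AAFE, and the
3-fold / AFE < 2 / AAFE < 2 acceptance rule.

For each observed point the fold error is FE_i = Predicted_i / Observed_i.
The average fold error AFE = 10^(mean(log10 FE)) is the geometric mean fold
error and shows systematic under-/over-prediction; the absolute average
fold error AAFE = 10^(mean(|log10 FE|)) measures absolute spread and is
always >= 1.  A simulation qualifies when every FE lies within [0.3, 3]
(3-fold error) and both AFE and AAFE are below 2.

Predicted curves are interpolated log-linearly in concentration onto the
observed sampling times, so observed data need not coincide with the solver
grid.  Observed zeros or below-limit values are excluded before FE is
formed (the ratio is undefined there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ObservedProfile",
    "ValidationReport",
    "fold_errors",
    "afe",
    "aafe",
    "acceptance_check",
    "interpolate_loglinear",
]

THREEFOLD_LOW, THREEFOLD_HIGH = 0.3, 3.0
AFE_LIMIT = AAFE_LIMIT = 2.0


@dataclass(frozen=True)
class ObservedProfile:
    """An observed concentration–time profile (times h, conc ug/mL)."""

    times: np.ndarray
    concentrations: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size == 0:
            raise ValueError("empty observed profile")
        if t.shape != c.shape:
            raise ValueError("times and concentrations differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("observed times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    @property
    def n(self) -> int:
        return int(self.times.size)

    def positive_only(self) -> "ObservedProfile":
        """Drop non-positive observations (fold error undefined there)."""
        mask = self.concentrations > 0
        if not mask.all():
            warnings.warn(
                f"{(~mask).sum()} non-positive observed value(s) excluded "
                f"from fold-error statistics ({self.label or 'profile'})",
                stacklevel=2,
            )
        if not mask.any():
            raise ValueError("no positive observed concentrations")
        return ObservedProfile(
            self.times[mask], self.concentrations[mask], self.label
        )

    # -- CSV dialect: header time_h, conc_ug_per_ml ------------------------

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_h": self.times, "conc_ug_per_ml": self.concentrations}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "ObservedProfile":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["time_h"].to_numpy(float),
            df["conc_ug_per_ml"].to_numpy(float),
            label or str(path),
        )


@dataclass(frozen=True)
class ValidationReport:
    """Per-point fold errors and the qualification verdict."""

    fold_errors: np.ndarray
    afe: float
    aafe: float
    within_3fold: bool
    within_2fold_fraction: float
    outlier_indices: tuple[int, ...]
    passed: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "fold_error": self.fold_errors,
                "outlier_3fold": [
                    i in self.outlier_indices for i in range(len(self.fold_errors))
                ],
            }
        )


def interpolate_loglinear(
    pred_times: np.ndarray, pred_conc: np.ndarray, obs_times: np.ndarray
) -> np.ndarray:
    """Interpolate a predicted curve onto observed times, linearly in
    log-concentration (exponential segments), falling back to linear where
    the curve touches zero."""
    pred_times = np.asarray(pred_times, float)
    pred_conc = np.asarray(pred_conc, float)
    obs_times = np.asarray(obs_times, float)
    if obs_times.min() < pred_times.min() or obs_times.max() > pred_times.max():
        raise ValueError("observed times outside the simulated window")
    if np.all(pred_conc > 0):
        return np.exp(np.interp(obs_times, pred_times, np.log(pred_conc)))
    return np.interp(obs_times, pred_times, pred_conc)


def fold_errors(predicted, observed: ObservedProfile) -> np.ndarray:
    """FE_i = Predicted_i / Observed_i on the observed sampling times.

    ``predicted`` is either a :class:`cefapbpk.engine.SimResult` (its plasma
    curve is used) or a (times, concentrations) pair.
    """
    from .engine import SimResult

    observed = observed.positive_only()
    if isinstance(predicted, SimResult):
        pt, pc = predicted.time, predicted.plasma
    else:
        pt, pc = (np.asarray(x, float) for x in predicted)
    pred = interpolate_loglinear(pt, pc, observed.times)
    return pred / observed.concentrations


def afe(fe: Sequence[float]) -> float:
    """Average fold error, 10^(mean log10 |FE|) — geometric mean fold error."""
    fe = np.asarray(fe, dtype=float)
    if fe.size == 0:
        raise ValueError("empty fold-error list")
    return float(10 ** np.mean(np.log10(np.abs(fe))))


def aafe(fe: Sequence[float]) -> float:
    """Absolute average fold error, 10^(mean |log10 FE|); always >= 1."""
    fe = np.asarray(fe, dtype=float)
    if fe.size == 0:
        raise ValueError("empty fold-error list")
    return float(10 ** np.mean(np.abs(np.log10(np.abs(fe)))))


def acceptance_check(fe: Sequence[float]) -> ValidationReport:
    """Apply the qualification rule: all FE within [0.3, 3] and both AFE and
    AAFE below 2.  Also reports the fraction of points within 2-fold."""
    fe = np.asarray(fe, dtype=float)
    if fe.size == 0:
        raise ValueError("empty fold-error list")
    outliers = tuple(
        int(i)
        for i in np.nonzero((fe < THREEFOLD_LOW) | (fe > THREEFOLD_HIGH))[0]
    )
    a, aa = afe(fe), aafe(fe)
    within3 = len(outliers) == 0
    within2 = float(np.mean((fe >= 0.5) & (fe <= 2.0)))
    return ValidationReport(
        fold_errors=fe,
        afe=a,
        aafe=aa,
        within_3fold=within3,
        within_2fold_fraction=within2,
        outlier_indices=outliers,
        passed=within3 and a < AFE_LIMIT and aa < AAFE_LIMIT,
    )


def validate_profile(predicted, observed: ObservedProfile) -> ValidationReport:
    """Convenience: fold errors then the acceptance rule in one call."""
    return acceptance_check(fold_errors(predicted, observed))
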