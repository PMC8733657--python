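"""Synthetic observed-style datasets.

Stands in for the literature plasma and tissue measurements the models are
validated against: a forward simulation sampled on a literature-like time
grid and corrupted by multiplicative lognormal assay noise,
``C_obs = C_true * exp(eps)`` with ``eps ~ N(0, sigma^2)`` and
``sigma = sqrt(ln(1 + CV^2))`` so the coefficient of variation of the noise
equals the nominal CV.  All randomness flows through one seeded generator,
so a fixed seed reproduces every dataset bit for bit.

Default sampling schedules mirror the reported designs: nine points to
120 min after an IV bolus in mouse, eight nonzero points to 240 min in rat,
and twelve nonzero points to 480 min after an oral dose in human.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import simulate
from .gut import GutModel
from .params import DoseEvent, TISSUE_NAMES
from .systemic import DispositionModel
from .validation import ObservedProfile

__all__ = [
    "NoiseModel",
    "MOUSE_SCHEDULE_H",
    "RAT_SCHEDULE_H",
    "HUMAN_SCHEDULE_H",
    "generate_observed_profile",
    "generate_tissue_timepoints",
]

MOUSE_SCHEDULE_H = tuple(m / 60.0 for m in (1, 2.5, 5, 10, 20, 30, 45, 90, 120))
RAT_SCHEDULE_H = tuple(m / 60.0 for m in (5, 15, 30, 60, 90, 120, 180, 240))
HUMAN_SCHEDULE_H = tuple(
    m / 60.0 for m in (10, 20, 30, 45, 60, 75, 90, 120, 180, 240, 360, 480)
)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal assay noise with a given CV and seed."""

    cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.cv**2)))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.asarray(values, dtype=float).copy()
        eps = rng.normal(0.0, self.sigma, size=np.shape(values))
        return np.asarray(values, dtype=float) * np.exp(eps)


def generate_observed_profile(
    model: DispositionModel,
    gut: GutModel | None,
    dose: DoseEvent,
    sample_times: Sequence[float],
    noise: NoiseModel,
    label: str = "",
    **sim_kwargs,
) -> ObservedProfile:
    """Simulate the true plasma profile, sample it at the given times, and
    apply one draw of lognormal noise per point."""
    times = np.asarray(sample_times, dtype=float)
    t_end = sim_kwargs.pop("t_end", max(float(times.max()), 1.0))
    if times.max() > t_end:
        raise ValueError("sample times extend beyond the simulation horizon")
    res = simulate(model, gut, dose, t_end=t_end, **sim_kwargs)
    truth = np.interp(times, res.time, res.plasma)
    noisy = noise.apply(truth, noise.rng())
    return ObservedProfile(
        times, noisy, label or f"{model.physiology.species}-{dose.route}"
    )


def generate_tissue_timepoints(
    model: DispositionModel,
    dose: DoseEvent,
    tissues: Sequence[str],
    times: Sequence[float] = (1.0, 3.0),
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
    gut: GutModel | None = None,
    **sim_kwargs,
):
    """Sparse tissue-concentration table (tissue x time x replicate), the
    design of sacrificial tissue-sampling studies."""
    import pandas as pd

    unknown = set(tissues) - set(TISSUE_NAMES)
    if unknown:
        raise ValueError(f"unknown tissue(s): {sorted(unknown)}")
    times = np.asarray(times, dtype=float)
    if len(tissues) == 0:
        return pd.DataFrame(
            columns=["tissue", "time_h", "replicate", "conc_ug_per_g"]
        )
    t_end = sim_kwargs.pop("t_end", max(float(times.max()) * 2, 6.0))
    res = simulate(model, gut, dose, t_end=t_end, **sim_kwargs)
    rng = noise.rng()
    rows = []
    for tissue in tissues:
        truth = np.interp(times, res.time, res.tissue(tissue))
        for t, c in zip(times, truth):
            for rep in range(n_replicates):
                rows.append(
                    {
                        "tissue": tissue,
                        "time_h": float(t),
                        "replicate": rep + 1,
                        "conc_ug_per_g": float(noise.apply(np.array(c), rng)),
                    }
                )
    return pd.DataFrame(rows)
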