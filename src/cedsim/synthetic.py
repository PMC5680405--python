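"""Synthetic inputs with the statistical structure the analysis assumes.

The elimination-rate stage of the pipeline was originally calibrated
against an unpublished rat striatal GDNF concentration-time study: two CED
doses (15 and 3 ug) with whole-striatum amounts measured 3, 7, 14, 21 and
28 days post-infusion, declining biexponentially under two-compartment
kinetics. :func:`generate_pk_dataset` emulates exactly that design so the
fitting stage is testable end-to-end without any external data; defaults
reproduce the study conditions (rate constants k10 = 3.72e-2, k12 =
7.12e-4, k21 = 3.81e-3 per hour; both doses; the five sampling days).

Measurement noise defaults to mean-preserving lognormal proportional error
with a 10% coefficient of variation — the conventional model for
ELISA-type assays, whose published error structure is unavailable.

:func:`generate_square_profile` builds the ideal square (convection-only)
concentration profile used as a fixture for the distribution metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .pk import PKDataset, TwoCompartmentParams, simulate_two_compartment
from .solver import ConcentrationProfile

__all__ = ["PkSimConfig", "generate_pk_dataset", "generate_square_profile"]

#: Rate constants of the reference striatal GDNF fit, h^-1.
DEFAULT_TRUE_PARAMS = TwoCompartmentParams(k10=3.72e-2, k12=7.12e-4, k21=3.81e-3)
DEFAULT_DOSES_UG = (15.0, 3.0)
DEFAULT_SAMPLE_DAYS = (3.0, 7.0, 14.0, 21.0, 28.0)


@dataclass(frozen=True)
class PkSimConfig:
    """Design of a simulated striatal PK study.

    true_params : generating two-compartment rate constants (h^-1)
    doses : bolus amounts per group, ug
    sample_times_days : post-infusion sampling days (strictly positive)
    noise_model : "proportional" (lognormal, mean-preserving), "additive"
        (Gaussian, sd = noise_cv * mean amount), or "none"
    noise_cv : fractional coefficient of variation
    replicates : independent animals per (dose, time) point
    seed : RNG seed; identical seeds give identical datasets
    """

    true_params: TwoCompartmentParams = field(default_factory=lambda: DEFAULT_TRUE_PARAMS)
    doses: tuple[float, ...] = DEFAULT_DOSES_UG
    sample_times_days: tuple[float, ...] = DEFAULT_SAMPLE_DAYS
    noise_model: str = "proportional"
    noise_cv: float = 0.10
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("proportional", "additive", "none"):
            raise ParameterError(f"unknown noise_model {self.noise_model!r}")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if any(t <= 0 for t in self.sample_times_days):
            raise ParameterError("sample times must be strictly positive")
        if any(d <= 0 for d in self.doses):
            raise ParameterError("doses must be positive")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")


def generate_pk_dataset(config: PkSimConfig) -> PKDataset:
    """Simulate a striatal amount-time dataset from the design in ``config``.

    Noise-free values equal the closed-form two-compartment solution
    exactly. Proportional noise multiplies each amount by
    exp(sigma Z - sigma^2/2) with sigma^2 = ln(1 + CV^2), so the noisy
    values keep the model mean and have sample CV ~ noise_cv.
    """
    rng = np.random.default_rng(config.seed)
    times_h = np.asarray(config.sample_times_days, dtype=float) * 24.0
    rows = []
    for dose in config.doses:
        clean = simulate_two_compartment(config.true_params, times_h, initial_amount=dose)
        for _ in range(config.replicates):
            if config.noise_model == "none" or config.noise_cv == 0:
                amounts = clean.copy()
            elif config.noise_model == "proportional":
                sigma = np.sqrt(np.log1p(config.noise_cv**2))
                z = rng.standard_normal(times_h.size)
                amounts = clean * np.exp(sigma * z - 0.5 * sigma**2)
            else:  # additive
                amounts = clean + config.noise_cv * clean.mean() * rng.standard_normal(
                    times_h.size
                )
                amounts = np.maximum(amounts, 0.0)
            rows.append(
                pd.DataFrame(
                    {"time_h": times_h, "amount_ug": amounts, "dose_ug": dose}
                )
            )
    data = pd.concat(rows, ignore_index=True)
    return PKDataset(
        data,
        metadata={
            "synthetic": True,
            "noise_model": config.noise_model,
            "noise_cv": config.noise_cv,
            "seed": config.seed,
            "true_params": {
                "k10": config.true_params.k10,
                "k12": config.true_params.k12,
                "k21": config.true_params.k21,
            },
        },
    )


def generate_square_profile(
    front_radius: float,
    radii: np.ndarray | None = None,
    r_inner: float = 0.2,
    r_max: float = 3.0,
    n: int = 1200,
    amplitude: float = 1.0,
) -> ConcentrationProfile:
    """Ideal convection-only square profile: C = amplitude inside the front.

    The step is linear over the single grid cell containing
    ``front_radius`` so that threshold-crossing interpolation is exercised.
    Pass explicit ``radii`` to match a solver grid, otherwise a uniform
    grid on [r_inner, r_max] is built.
    """
    if radii is None:
        faces = np.linspace(r_inner, r_max, n + 1)
        radii = 0.5 * (faces[:-1] + faces[1:])
    radii = np.asarray(radii, dtype=float)
    if not radii[0] < front_radius < radii[-1]:
        raise ParameterError(
            f"front_radius {front_radius} must lie inside the grid "
            f"[{radii[0]:.3g}, {radii[-1]:.3g}]"
        )
    dr = radii[1] - radii[0]
    # half-amplitude exactly at front_radius, linear over one cell width
    c = amplitude * np.clip(0.5 + (front_radius - radii) / dr, 0.0, 1.0)
    return ConcentrationProfile(
        radii=radii,
        times=np.array([0.0]),
        values=c[None, :],
        phases=["infusion"],
        meta={"synthetic": True, "front_radius": front_radius},
    )
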