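"""Molecular transport parameters.

A diffusing species is described by its free-medium diffusion coefficient
``D`` (cm^2/s) and the tortuosity ``lambda`` of the tissue it moves through;
the effective interstitial diffusivity is ``D / lambda**2``. Free diffusivity
scales with molecular weight as MW^(-1/3) under the Stokes-Einstein relation
for spherical molecules, which is how the small MRI tracer Gd-DTPA is
parameterised from the GDNF value.

Built-in presets carry the values used throughout the putamen infusion
analysis:

* ``r-metHuGDNF`` — 30.4 kDa homodimer, D = 1.3e-6 cm^2/s, lambda = 2.2;
* ``Gd-DTPA``     — 938 Da contrast agent, D = 4.1e-6 cm^2/s, lambda = 1.6.

The Gd-DTPA preset stores the conventional rounded diffusivity (4.1e-6)
rather than the raw cube-root-scaled number (4.14e-6).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

# Tortuosity conventionally measured for small molecules in brain ISF
# falls in 1.5-1.6; the upper value is the default here.
SMALL_MOLECULE_TORTUOSITY = 1.6


@dataclass(frozen=True)
class Molecule:
    """A diffusing species.

    Parameters
    ----------
    name : str
        Display name.
    molecular_weight : float
        Molecular weight in daltons; must be positive.
    d_free : float
        Free-medium diffusion coefficient, cm^2/s; must be positive.
    tortuosity : float
        Dimensionless hindrance factor lambda >= 1.
    """

    name: str
    molecular_weight: float
    d_free: float
    tortuosity: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ParameterError(f"molecular_weight must be > 0, got {self.molecular_weight}")
        if self.d_free <= 0:
            raise ParameterError(f"d_free must be > 0, got {self.d_free}")
        if self.tortuosity < 1:
            raise ParameterError(f"tortuosity must be >= 1, got {self.tortuosity}")

    @property
    def effective_diffusivity(self) -> float:
        """Effective interstitial diffusivity D/lambda^2, cm^2/s."""
        return self.d_free / self.tortuosity**2


def effective_diffusivity(molecule: Molecule) -> float:
    """Effective diffusivity in tissue, ``D_free / lambda**2`` (cm^2/s).

    Tortuosity only hinders: the result never exceeds ``D_free``, with
    equality at ``lambda == 1``.
    """
    return molecule.effective_diffusivity


def scale_diffusivity_by_mw(d_ref: float, mw_ref: float, mw_target: float) -> float:
    """Scale a free diffusivity to another molecular weight.

    Uses the inverse one-third-power dependence of diffusivity on molecular
    weight implied by Stokes-Einstein drag on a sphere whose volume is
    proportional to its mass:

        D_target = D_ref * (mw_ref / mw_target)**(1/3)

    Parameters are a reference diffusivity (cm^2/s) and the two molecular
    weights (daltons, any consistent unit). The operation composes
    multiplicatively: scaling A->B then B->C equals scaling A->C.
    """
    if d_ref <= 0 or mw_ref <= 0 or mw_target <= 0:
        raise ParameterError(
            f"scale_diffusivity_by_mw requires positive arguments, got "
            f"(d_ref={d_ref}, mw_ref={mw_ref}, mw_target={mw_target})"
        )
    return d_ref * (mw_ref / mw_target) ** (1.0 / 3.0)


#: Built-in species presets (values as used in the putamen CED analysis).
PRESETS: dict[str, Molecule] = {
    "r-metHuGDNF": Molecule(
        name="r-metHuGDNF", molecular_weight=30400.0, d_free=1.3e-6, tortuosity=2.2
    ),
    "Gd-DTPA": Molecule(
        name="Gd-DTPA",
        molecular_weight=938.0,
        d_free=4.1e-6,
        tortuosity=SMALL_MOLECULE_TORTUOSITY,
    ),
}


def get_molecule(name: str) -> Molecule:
    """Look up a preset molecule by name (case-sensitive)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown molecule preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
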