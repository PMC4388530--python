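"""Sample dilution to the imaging optical density, with gravimetric check.

Before imaging, a fermentation sample is diluted with demineralized water
to a target OD600 (default 1.15, the density at which 5-10 bacteria per
field of view are typically observed).  OD is assumed linear in cell
concentration over the working range, so the dilution factor is simply
od_measured / od_target; a sample already below target cannot be
concentrated and is flagged instead.  The executed dilution is verified by
weighing: with density ~1 g/ml for both sample and diluent the final mass
must equal sample_mass * factor within a relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

#: imaging optical density the automated unit dilutes to
DEFAULT_TARGET_OD = 1.15


@dataclass
class DilutionPlan:
    od_measured: float
    od_target: float
    dilution_factor: float      # >= 1
    sample_mass: float          # g
    water_mass_to_add: float    # g
    below_target: bool = False  # sample thinner than target; not diluted

    @property
    def expected_total_mass(self) -> float:
        return self.sample_mass * self.dilution_factor


def plan_dilution(od_measured: float, sample_mass: float,
                  od_target: float = DEFAULT_TARGET_OD,
                  density_g_ml: float = 1.0) -> DilutionPlan:
    """Water mass to add to reach the target OD.

    factor = od_measured / od_target, clipped to >= 1 (a thin sample is
    left undiluted and flagged); water to add = sample_mass * (factor - 1)
    at equal densities for sample and diluent.
    """
    if od_measured <= 0 or sample_mass <= 0 or od_target <= 0:
        raise ValueError("od_measured, sample_mass, od_target must be > 0")
    if density_g_ml <= 0:
        raise ValueError("density must be positive")
    factor = od_measured / od_target
    below = factor < 1.0
    factor = max(factor, 1.0)
    water = sample_mass * (factor - 1.0)
    return DilutionPlan(od_measured=od_measured, od_target=od_target,
                        dilution_factor=factor, sample_mass=sample_mass,
                        water_mass_to_add=water, below_target=below)


def verify_dilution(plan: DilutionPlan, measured_total_mass: float,
                    tolerance_pct: float = 2.0) -> bool:
    """Gravimetric check of an executed dilution.

    Passes iff the measured total mass deviates from the expected
    sample_mass * factor by at most tolerance_pct percent (symmetric).
    """
    if tolerance_pct <= 0:
        raise ValueError("tolerance_pct must be positive")
    expected = plan.expected_total_mass
    return abs(measured_total_mass - expected) <= tolerance_pct / 100.0 * expected
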