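"""Neutral-diffusion expectations for cline width in a tension zone.

In the absence of selection, a cline formed at secondary contact widens by
dispersal alone as

    w = 2.51 * sigma * sqrt(T)

with w the cline width (km), sigma the average lifetime dispersal distance
(km per generation) and T the number of generations since contact.  An
observed width narrower than this expectation for a plausible contact age is
evidence that selection (a tension zone) keeps the cline sharp.  The
inversion T = (w / (2.51 sigma))^2 gives the time unrestricted diffusion
would need to reach an observed width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError

DIFFUSION_COEF = 2.51


def per_generation_dispersal(per_year_distance: float, generation_time: float) -> float:
    """Lifetime dispersal sigma (km/generation) from a per-year distance and
    a generation time in years."""
    if per_year_distance <= 0 or generation_time <= 0:
        raise ParameterError("dispersal distance and generation time must be > 0")
    return per_year_distance * generation_time


def neutral_width(sigma: float, t_generations: float) -> float:
    """Expected neutral cline width (km) after T generations: 2.51 sigma sqrt(T)."""
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    if t_generations < 0:
        raise ParameterError("T must be >= 0")
    return DIFFUSION_COEF * sigma * math.sqrt(t_generations)


@dataclass
class DiffusionTime:
    """Time for unrestricted diffusion to reach an observed cline width."""

    width_km: float
    sigma: float
    generation_time_years: float
    generations: float
    years_raw: float
    years_rounded: int

    def to_dict(self) -> dict:
        return {
            "width_km": self.width_km, "sigma_km_per_gen": self.sigma,
            "generation_time_years": self.generation_time_years,
            "generations": self.generations, "years_raw": self.years_raw,
            "years_rounded": self.years_rounded,
        }


def time_to_width(width: float, sigma: float, generation_time: float) -> DiffusionTime:
    """Invert the diffusion approximation: T = (w / (2.51 sigma))^2.

    Years are reported both raw and rounded half-up to the nearest integer.
    """
    if width <= 0 or sigma <= 0 or generation_time <= 0:
        raise ParameterError("width, sigma and generation time must all be > 0")
    t_gen = (width / (DIFFUSION_COEF * sigma)) ** 2
    years = t_gen * generation_time
    return DiffusionTime(width, sigma, generation_time, t_gen, years,
                         int(math.floor(years + 0.5)))
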