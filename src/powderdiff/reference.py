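"""Published benchmark measurements of 18 milk-protein-concentrate particles.

One row per particle from a published confocal rehydration study of MPC
powder (the dataset this package's workflow automates): segmented area,
equivalent diameter, relative dye intensity at the first capture and at
340 s, and the Crank-model effective diffusion coefficient.  The table is
used as an internal consistency benchmark: the package's morphology and
summary operations must reproduce the printed diameters and ensemble
statistics from the printed areas.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceParticle", "REFERENCE_PARTICLES", "reference_summary"]


@dataclass(frozen=True)
class ReferenceParticle:
    particle_id: int
    area_um2: float
    diameter_um: float
    rel_intensity_initial: float
    rel_intensity_340s: float
    deff_m2_s: float

    @property
    def area_m2(self) -> float:
        return self.area_um2 * 1e-12

    @property
    def diameter_m(self) -> float:
        return self.diameter_um * 1e-6


REFERENCE_PARTICLES: tuple[ReferenceParticle, ...] = tuple(
    ReferenceParticle(*row)
    for row in [
        (1, 850.13, 32.90, 0.324, 0.869, 8.25e-14),
        (2, 696.65, 29.78, 0.372, 0.784, 7.00e-14),
        (3, 290.77, 19.24, 0.310, 0.795, 2.13e-14),
        (4, 52.01, 8.14, 0.487, 0.761, 3.67e-15),
        (5, 59.40, 8.70, 0.547, 0.835, 4.14e-15),
        (6, 63.33, 8.98, 0.551, 0.684, 4.14e-15),
        (7, 311.11, 19.90, 0.391, 0.702, 1.81e-14),
        (8, 509.43, 25.47, 0.318, 0.805, 4.50e-14),
        (9, 638.87, 28.52, 0.382, 0.805, 7.63e-14),
        (10, 162.72, 14.39, 0.461, 0.842, 2.00e-14),
        (11, 22.65, 5.37, 0.427, 0.736, 1.76e-15),
        (12, 969.63, 35.14, 0.314, 0.804, 6.88e-14),
        (13, 104.01, 11.51, 0.493, 0.724, 5.94e-15),
        (14, 1410.64, 42.38, 0.306, 0.730, 1.43e-13),
        (15, 47.15, 7.75, 0.546, 0.730, 3.40e-15),
        (16, 64.26, 9.05, 0.558, 0.789, 5.63e-15),
        (17, 338.16, 20.75, 0.268, 0.682, 2.06e-14),
        (18, 266.73, 18.43, 0.295, 0.746, 1.66e-14),
    ]
)


def reference_summary() -> dict:
    """Ensemble statistics of the benchmark table, computed by the package's
    own summary operation (not hard-coded)."""
    from .estimation import ensemble_stats

    stats = ensemble_stats(
        [p.deff_m2_s for p in REFERENCE_PARTICLES],
        [p.diameter_m for p in REFERENCE_PARTICLES],
        areas_m2=[p.area_m2 for p in REFERENCE_PARTICLES],
    )
    n = len(REFERENCE_PARTICLES)
    stats["mean_rel_intensity_initial"] = (
        sum(p.rel_intensity_initial for p in REFERENCE_PARTICLES) / n
    )
    stats["mean_rel_intensity_340s"] = (
        sum(p.rel_intensity_340s for p in REFERENCE_PARTICLES) / n
    )
    return stats
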