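"""Population simulation: heterogeneous ipRGCs sharing one photocycle.

Pigment-pool fractions evolve identically for every cell of a genotype (the
photocycle is linear in the pool), so the deterministic trajectory is
integrated once; cells differ by a lognormal pigment scaling of the drive
and a lognormal scaling of the firing threshold, then by independent spike
noise.  All randomness derives from a single root seed through
``numpy.random.SeedSequence`` spawning, making every cell reproducible from
(seed, cell index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (GenotypeConfig, PhotocycleParams, PopulationConfig,
                     TransductionParams)
from .photocycle import PhotocycleResult, simulate_photocycle
from .protocols import LightProtocol
from .transduction import SpikeTrain, drive_to_rate, generate_spikes


def _lognormal_scales(cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean lognormal draws with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


@dataclass
class PopulationResult:
    trains: list[SpikeTrain]
    photocycle: PhotocycleResult
    pigment_scales: np.ndarray
    thresholds: np.ndarray
    genotype: GenotypeConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.trains)

    def cell_rate(self, i: int, tp: TransductionParams) -> np.ndarray:
        """Deterministic firing-rate series of cell ``i``."""
        drive = self.pigment_scales[i] * self.photocycle.drive
        return drive_to_rate(drive, self.photocycle.dt, tp,
                             theta=self.thresholds[i])


def simulate_population(
    protocol: LightProtocol,
    params: PhotocycleParams | None = None,
    genotype: GenotypeConfig | None = None,
    pop: PopulationConfig | None = None,
    tp: TransductionParams | None = None,
    dt: float = 1e-3,
    dt_out: float = 0.01,
    cell_prefix: str | None = None,
) -> PopulationResult:
    """Simulate spike trains for a heterogeneous population of one genotype."""
    params = params or PhotocycleParams()
    genotype = genotype or GenotypeConfig()
    pop = pop or PopulationConfig()
    tp = tp or TransductionParams()
    prefix = cell_prefix if cell_prefix is not None else genotype.name

    pc = simulate_photocycle(protocol, params, genotype, dt=dt, dt_out=dt_out, tp=tp)

    root = np.random.SeedSequence(pop.seed)
    hetero_ss, spikes_ss = root.spawn(2)
    hetero_rng = np.random.default_rng(hetero_ss)
    scales = _lognormal_scales(pop.cv_pigment, pop.n_cells, hetero_rng)
    theta_scales = _lognormal_scales(pop.cv_threshold, pop.n_cells, hetero_rng)
    thresholds = tp.theta * theta_scales

    cell_seeds = spikes_ss.spawn(pop.n_cells)
    trains = []
    for i in range(pop.n_cells):
        rate = drive_to_rate(scales[i] * pc.drive, dt_out, tp, theta=thresholds[i])
        rng = np.random.default_rng(cell_seeds[i])
        trains.append(generate_spikes(rate, dt_out, tp, seed=rng,
                                      cell_id=f"{prefix}_{i:03d}"))
    return PopulationResult(
        trains=trains, photocycle=pc, pigment_scales=scales,
        thresholds=thresholds, genotype=genotype,
        meta={"pop": pop.to_dict(), "protocol": protocol.to_dict()},
    )
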