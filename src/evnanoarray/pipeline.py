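"""High-level workflows chaining leveling, detection, classification and
population comparison — the programmatic face of the package; the CLI is
a thin wrapper around these functions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import (DetectionParams, Particle, assign_to_spots,
                     detect_particles, measure_particles)
from .image import HeightMap, LevelReport, line_level, plane_level
from .morphometry import ClassThresholds, FitResult, classify_particles, fit_ar_model, \
    occupancy_fraction
from .stats import PopulationSummary, TestResult, student_t_test, summarize

__all__ = ["ProcessResult", "process_height_map", "analyze_populations"]


@dataclass
class ProcessResult:
    """Everything produced by one scan's processing pass."""

    particles: list[Particle]
    leveled: HeightMap
    level_report: LevelReport
    occupancy: pd.DataFrame | None = None

    @property
    def occupancy_fraction(self) -> float:
        if self.occupancy is None:
            raise ValueError("no layout was supplied; occupancy unavailable")
        return occupancy_fraction(self.occupancy)

    def by_class(self, klass: str) -> list[Particle]:
        return [p for p in self.particles if p.klass == klass]


def process_height_map(
    hmap: HeightMap,
    params: DetectionParams = DetectionParams(),
    thresholds: ClassThresholds = ClassThresholds(),
    layout=None,
    level_order: int = 1,
) -> ProcessResult:
    """Level -> detect -> measure -> classify (-> assign to spots).

    The raw map is plane-leveled (background-masked polynomial of
    ``level_order``), scan-row offsets are removed, particles are
    detected and measured, classified by the morphological thresholds,
    and — when a spot layout is given — assigned to their nearest spot
    to produce the occupancy table.
    """
    leveled, report = plane_level(hmap, order=level_order)
    leveled = line_level(leveled)
    regions = detect_particles(leveled, params)
    particles = measure_particles(regions, leveled, params)
    classify_particles(particles, thresholds)
    occupancy = None
    if layout is not None:
        particles, occupancy = assign_to_spots(particles, layout, params)
    return ProcessResult(particles, leveled, report, occupancy)


def analyze_populations(
    populations: dict[str, list[Particle]],
    occupancies: dict[str, float] | None = None,
    through_origin: bool = True,
    run_test: bool | None = None,
) -> tuple[list[PopulationSummary], dict[str, FitResult], TestResult | None]:
    """Summaries, AR ~ c*d^-3 fits per population, and — for exactly two
    populations — the pooled two-sample t-test on the aspect ratios.

    Populations with no EV-class particles are skipped with a warning.
    ``run_test=True`` with fewer than two usable populations is an error;
    the default runs the test whenever two populations are available.
    """
    occupancies = occupancies or {}
    summaries: list[PopulationSummary] = []
    fits: dict[str, FitResult] = {}
    ar_samples: dict[str, np.ndarray] = {}
    for label, particles in populations.items():
        evs = [p for p in particles if p.klass == "EV" and not p.border]
        if not evs:
            warnings.warn(f"population '{label}' has no EV-class particles; skipped",
                          stacklevel=2)
            continue
        summaries.append(summarize(particles, occupancies.get(label), label))
        fits[label] = fit_ar_model(evs, through_origin=through_origin)
        ar_samples[label] = np.array([p.ar for p in evs])

    test = None
    want_test = run_test if run_test is not None else len(ar_samples) == 2
    if want_test:
        if len(ar_samples) != 2:
            raise ValueError(
                f"t-test needs exactly two populations with EVs, have {len(ar_samples)}"
            )
        a, b = ar_samples.values()
        test = student_t_test(a, b)
    return summaries, fits, test
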