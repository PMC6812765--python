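"""Population statistics: per-cell-line summaries, the two-sample
Student's t comparison of mean aspect ratio, the drag-vs-adhesion
capture toy model, and report generation.

The t-test is the pooled-variance two-sample Student's t (the single
comparison performed between cell lines, two-sided at alpha = 0.05). It
is implemented in closed form so the degenerate zero-variance cases have
defined behaviour, and is cross-checked against scipy in the test suite.

The capture model formalises the size selectivity of the tethering
process: Stokes drag on a sphere in shear flow grows as D^2, while the
hydrophobic anchoring force is size-independent, so vesicles above a
critical diameter D* = sqrt(F_resist / (c_drag * v)) are swept away
before tethering. Only the scaling laws are meaningful — the
coefficients are dimensionless knobs.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .detect import Particle
from .morphometry import FitResult

__all__ = [
    "PopulationSummary",
    "TestResult",
    "CaptureModel",
    "summarize",
    "student_t_test",
    "capture_predicate",
    "apply_capture_filter",
    "make_report",
    "coefficient_of_variation",
]


def coefficient_of_variation(mean: float, sd: float) -> float:
    """sd/mean as a percentage (e.g. 11/229 -> 4.8)."""
    if mean == 0:
        raise ValueError("mean must be nonzero")
    return 100.0 * sd / mean


@dataclass(frozen=True)
class PopulationSummary:
    """Mean/sample-sd morphometry of one EV population."""

    label: str
    n: int
    mean_d_nm: float
    sd_d_nm: float
    mean_h_nm: float
    sd_h_nm: float
    mean_ar: float
    sd_ar: float
    mean_D_nm: float
    sd_D_nm: float
    occupancy: float | None = None


@dataclass(frozen=True)
class TestResult:
    """Pooled two-sample Student's t-test outcome."""

    t_statistic: float
    degrees_of_freedom: int
    p_two_sided: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.alpha


@dataclass(frozen=True)
class CaptureModel:
    """Dimensionless drag-vs-adhesion capture threshold model."""

    drag_coefficient: float = 1.0
    resistance_force: float = 1.0
    flow_velocity: float = 1.0

    def __post_init__(self) -> None:
        if min(self.drag_coefficient, self.resistance_force, self.flow_velocity) < 0:
            raise ValueError("model coefficients must be >= 0")

    @property
    def critical_diameter(self) -> float:
        """D* above which drag exceeds the anchoring force."""
        denom = self.drag_coefficient * self.flow_velocity
        return float(np.sqrt(self.resistance_force / denom)) if denom > 0 else np.inf


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def summarize(
    particles: list[Particle],
    occupancy: float | None = None,
    label: str = "",
    include_border: bool = False,
) -> PopulationSummary:
    """Mean and sample sd (n-1) of d, h, AR and D over EV-class
    particles; border-touching particles are excluded by default."""
    sel = [p for p in particles
           if p.klass == "EV" and (include_border or not p.border)]
    if not sel:
        raise ValueError("no EV-class particles to summarize")
    d = np.array([p.d_nm for p in sel])
    h = np.array([p.h_nm for p in sel])
    ar = np.array([p.ar for p in sel])
    D = np.array([p.D_nm for p in sel])
    (md, sdd), (mh, sdh), (mar, sdar), (mD, sdD) = map(_mean_sd, (d, h, ar, D))
    return PopulationSummary(label, len(sel), md, sdd, mh, sdh, mar, sdar, mD, sdD,
                             occupancy)


def student_t_test(a, b, alpha: float = 0.05) -> TestResult:
    """Pooled-variance two-sample Student's t-test, two-sided.

    t = (mean_a - mean_b) / (s_p * sqrt(1/n_a + 1/n_b)), with the pooled
    variance s_p^2 on df = n_a + n_b - 2 degrees of freedom. Degenerate
    zero-variance input: equal means give t = 0, p = 1; unequal means
    give p = 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        if diff == 0:
            return TestResult(0.0, df, 1.0, alpha)
        warnings.warn("zero pooled variance with unequal means: p = 0", stacklevel=2)
        return TestResult(np.inf if diff > 0 else -np.inf, df, 0.0, alpha)
    t = diff / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(float(t), df, min(p, 1.0), alpha)


def capture_predicate(D_nm: float, model: CaptureModel) -> bool:
    """A vesicle is captured iff drag c*v*D^2 does not exceed the
    anchoring resistance force."""
    drag = model.drag_coefficient * model.flow_velocity * D_nm ** 2
    return bool(drag <= model.resistance_force)


def apply_capture_filter(D_values, model: CaptureModel) -> tuple[np.ndarray, dict]:
    """Filter a suspension population by the capture predicate.

    Returns the captured subpopulation and a summary with the mean
    before/after, the captured fraction and D*. Whenever D* is interior
    to the population's support the captured mean is below the overall
    mean (truncation from above).
    """
    D = np.asarray(D_values, dtype=float)
    if D.size == 0:
        raise ValueError("empty population")
    captured = D[D ** 2 * model.drag_coefficient * model.flow_velocity
                 <= model.resistance_force]
    summary = {
        "critical_diameter_nm": model.critical_diameter,
        "n_total": int(D.size),
        "n_captured": int(captured.size),
        "captured_fraction": float(captured.size / D.size),
        "mean_D_before_nm": float(D.mean()),
        "mean_D_after_nm": float(captured.mean()) if captured.size else None,
    }
    return captured, summary


# ---------------------------------------------------------------------------
# Reports

def _round_sig(x, digits: int = 4):
    if isinstance(x, bool) or x is None:
        return x
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        if not np.isfinite(x):
            return None if np.isnan(x) else ("inf" if x > 0 else "-inf")
        return float(f"{float(x):.{digits}g}")
    if isinstance(x, dict):
        return {k: _round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_round_sig(v, digits) for v in x]
    return x


def make_report(
    summaries: list[PopulationSummary],
    fits: dict[str, FitResult] | None,
    test: TestResult | None,
    config: dict | None,
    out_dir: str | Path,
    capture: dict | None = None,
    plots: bool = False,
) -> Path:
    """Write the machine-readable summary JSON (and CSV; optionally the
    AR-vs-d scatter with fitted curves and D histograms).

    The JSON has stable key order and 4-significant-digit floats, so
    regenerating from identical inputs is byte-identical. Missing
    sections are serialized as null, never omitted.
    """
    if not summaries:
        raise ValueError("at least one population summary is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    doc = {
        "populations": [_round_sig(asdict(s)) for s in summaries],
        "ar_fits": (
            {label: _round_sig(asdict(f)) for label, f in fits.items()} if fits else None
        ),
        "t_test": (
            _round_sig({**asdict(test), "significant": test.significant}) if test else None
        ),
        "capture_model": _round_sig(capture) if capture else None,
        "provenance": _round_sig(config or {}),
    }
    json_path = out_dir / "summary.json"
    json_path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    csv_path = out_dir / "populations.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(asdict(summaries[0])))
        writer.writeheader()
        for s in summaries:
            writer.writerow(_round_sig(asdict(s)))

    if plots:
        _write_plots(summaries, fits, out_dir)
    return json_path


def _write_plots(summaries, fits, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    d_grid = np.linspace(30, 90, 200)
    if fits:
        for label, fit in fits.items():
            ax.plot(d_grid, fit.predict(d_grid), label=f"{label}: AR = {fit.c:.3g} d$^{{-3}}$")
    ax.set_xlabel("footprint diameter d (nm)")
    ax.set_ylabel("aspect ratio h/d")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "ar_vs_d.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for s in summaries:
        ax.errorbar([s.label], [s.mean_D_nm], yerr=[s.sd_D_nm], fmt="o", capsize=4)
    ax.set_ylabel("suspension diameter D (nm)")
    fig.tight_layout()
    fig.savefig(out_dir / "d_summary.png", dpi=150)
    plt.close(fig)
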