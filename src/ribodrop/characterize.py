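"""Post-screen analytics for individually assayed riboswitch candidates.

Covers the arithmetic applied after a screen:

* expression normalization — GFP divided by ROX (transcription
  reference), further divided by the no-riboswitch positive control;
* nonspecific-effect correction — the ligand can mildly activate the
  control construct itself, so fold changes are corrected as a
  ratio-of-ratios at each concentration;
* Hill dose-response fitting (EC50, Hill coefficient) for activation or
  repression;
* sorting efficiency / purity / enrichment metrics for gated and sorted
  droplet populations (the mock-sorting readouts);
* restriction-digest band-intensity arithmetic to estimate two-template
  composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

if TYPE_CHECKING:  # pragma: no cover
    from .droplet_sim import DropletEvents


@dataclass(frozen=True)
class ExpressionMeasurement:
    """One bulk CFPS measurement: GFP and ROX signals under a condition."""

    gfp: float
    rox: float
    ligand_conc: float = 0.0
    construct: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.gfp < 0 or self.rox < 0:
            raise ValueError("signals must be >= 0")


def normalize_expression(
    m: ExpressionMeasurement, control: ExpressionMeasurement
) -> float:
    """GFP/ROX of a sample divided by GFP/ROX of the no-riboswitch control."""
    if m.rox <= 0 or control.rox <= 0:
        raise ValueError("ROX signal must be > 0 for normalization")
    if control.gfp <= 0:
        raise ValueError("control GFP must be > 0 for normalization")
    return (m.gfp / m.rox) / (control.gfp / control.rox)


def corrected_fold_change(
    variant_at_conc: float,
    variant_at_zero: float,
    control_at_conc: float,
    control_at_zero: float,
) -> float:
    """Fold change corrected for nonspecific ligand effects on the control.

    ``(variant_c / variant_0) / (control_c / control_0)`` — the control
    construct lacks the aptamer, so any response it shows to the ligand
    is nonspecific and is divided out at each concentration.
    """
    for name, value in (
        ("variant_at_conc", variant_at_conc),
        ("variant_at_zero", variant_at_zero),
        ("control_at_conc", control_at_conc),
        ("control_at_zero", control_at_zero),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be > 0")
    return (variant_at_conc / variant_at_zero) / (control_at_conc / control_at_zero)


def correct_dose_series(
    concs: Sequence[float],
    variant_levels: Sequence[float],
    control_levels: Sequence[float],
) -> np.ndarray:
    """Corrected fold change at every concentration of a dose series.

    Both series must include concentration 0, which anchors the
    respective denominators.
    """
    concs = np.asarray(concs, dtype=float)
    variant = np.asarray(variant_levels, dtype=float)
    control = np.asarray(control_levels, dtype=float)
    if not (concs.shape == variant.shape == control.shape):
        raise ValueError("series must have equal lengths")
    zero = np.flatnonzero(concs == 0)
    if zero.size == 0:
        raise ValueError("dose series must include concentration 0")
    v0 = variant[zero].mean()
    c0 = control[zero].mean()
    return np.array(
        [
            corrected_fold_change(v, v0, c, c0)
            for v, c in zip(variant, control)
        ]
    )


FitMode = Literal["activation", "repression"]


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted Hill dose response.

    ``baseline`` is the zero-ligand asymptote and ``max_response`` the
    saturating-ligand asymptote (below the baseline for repression).
    """

    baseline: float
    max_response: float
    ec50: float
    hill: float
    mode: FitMode
    residual_norm: float

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return _hill(c, self.baseline, self.max_response, self.ec50, self.hill)

    @property
    def dynamic_ratio(self) -> float:
        """Ratio of the larger to the smaller asymptote."""
        lo, hi = sorted((self.baseline, self.max_response))
        return np.inf if lo == 0 else hi / lo

    def fold_change(self, conc) -> np.ndarray:
        """Predicted response relative to the zero-ligand baseline."""
        return self.predict(conc) / self.baseline


def _hill(c, y0, ymax, ec50, hill):
    c = np.asarray(c, dtype=float)
    ch = np.power(np.maximum(c, 0.0), hill)
    return y0 + (ymax - y0) * ch / (ec50**hill + ch)


class DegenerateFitError(ValueError):
    """The response carries no dose information (constant series)."""


def fit_dose_response(
    concs: Sequence[float],
    responses: Sequence[float],
    mode: FitMode = "activation",
) -> DoseResponseFit:
    """Least-squares Hill fit of (corrected) responses against ligand dose.

    Requires at least 4 distinct concentrations including 0.  Replicates
    are passed as repeated (conc, response) pairs.  ``mode`` declares the
    expected direction; a fit whose asymptotes contradict it raises.
    """
    c = np.asarray(concs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concs and responses must have equal lengths")
    distinct = np.unique(c)
    if distinct.size < 4 or 0.0 not in distinct:
        raise ValueError("need >= 4 distinct concentrations including 0")
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        raise DegenerateFitError("constant response: no dose dependence to fit")
    low = float(y[c == c.min()].mean())
    high = float(y[c == c.max()].mean())
    if mode == "repression" and high > low:
        raise ValueError("responses increase with dose; mode='repression' mismatch")
    if mode == "activation" and high < low:
        raise ValueError("responses decrease with dose; mode='activation' mismatch")
    positive = distinct[distinct > 0]
    ec50_guess = float(np.median(positive))
    p0 = [low, high, ec50_guess, 1.0]
    bounds = ([0.0, 0.0, 1e-12, 1e-3], [np.inf, np.inf, np.inf, 100.0])
    try:
        popt, _ = curve_fit(_hill, c, y, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError as exc:  # pragma: no cover - depends on data
        raise RuntimeError(
            f"Hill fit failed to converge (mode={mode}, start={p0}): {exc}"
        ) from exc
    y0, ymax, ec50, hill = (float(v) for v in popt)
    residual = float(np.linalg.norm(_hill(c, *popt) - y))
    return DoseResponseFit(
        baseline=y0,
        max_response=ymax,
        ec50=ec50,
        hill=hill,
        mode=mode,
        residual_norm=residual,
    )


@dataclass(frozen=True)
class SortMetrics:
    """Sorting efficiency, purity and fold enrichments of one sort.

    efficiency
        100 x (sorted desired droplets) / (droplets detected within the
        gate) — a gate-conditional recovery rate, exactly as reported by
        the droplet sorter's own statistics.
    purity
        100 x (desired droplets among all sorted droplets).
    droplet_enrichment_fold
        Desired-droplet fraction after / before, both over ALL droplets
        (empties included).
    template_enrichment_fold
        Desired-template fraction in the regenerated pool over the
        fraction in the input pool.
    """

    efficiency: float
    purity: float
    droplet_enrichment_fold: float
    template_enrichment_fold: float

    def to_dict(self) -> dict:
        return {
            "efficiency_percent": self.efficiency,
            "purity_percent": self.purity,
            "droplet_enrichment_fold": self.droplet_enrichment_fold,
            "template_enrichment_fold": self.template_enrichment_fold,
        }


def sort_metrics(
    events: "DropletEvents",
    desired,
    template_fraction_before: float = np.nan,
    template_fraction_after: float = np.nan,
) -> SortMetrics:
    """Compute sorting metrics from a gated/sorted droplet population.

    ``desired`` is a per-droplet boolean mask of the droplets carrying
    the sought output (e.g. droplets containing the minor mock
    template).  Template-level fractions are optional; without them the
    template enrichment is NaN.
    """
    desired = np.asarray(desired, dtype=bool)
    if desired.shape[0] != len(events):
        raise ValueError("desired mask must have one entry per droplet")
    n_gate = int(events.in_gate.sum())
    if n_gate == 0:
        raise ValueError("empty gate: no droplets detected within the gate")
    n_sorted = int(events.sorted_flag.sum())
    if n_sorted == 0:
        raise ValueError("no droplets sorted")
    desired_sorted = int((desired & events.sorted_flag).sum())
    before = float(desired.mean())
    after = desired_sorted / n_sorted
    return SortMetrics(
        efficiency=100.0 * desired_sorted / n_gate,
        purity=100.0 * after,
        droplet_enrichment_fold=after / before if before > 0 else np.inf,
        template_enrichment_fold=float(template_fraction_after)
        / float(template_fraction_before)
        if template_fraction_before and not np.isnan(template_fraction_before)
        else np.nan,
    )


def digest_ratio(
    cut_band_a: float,
    uncut_a: float,
    cut_band_b: float,
    uncut_b: float,
) -> tuple[float, float]:
    """Two-template composition from restriction-digest band intensities.

    Each template carries a distinct restriction site, so its cut-band
    intensity is proportional to its share of the mixture.  Background
    subtraction is the caller's responsibility (image analysis is out of
    scope); this is pure arithmetic on supplied intensities.
    Returns ``(fraction_a, fraction_b)`` summing to 1.
    """
    for name, value in (
        ("cut_band_a", cut_band_a),
        ("uncut_a", uncut_a),
        ("cut_band_b", cut_band_b),
        ("uncut_b", uncut_b),
    ):
        if value < 0:
            raise ValueError(f"{name} must be >= 0")
    if cut_band_a + uncut_a == 0 or cut_band_b + uncut_b == 0:
        raise ValueError("each digest lane needs at least one positive band")
    total_cut = cut_band_a + cut_band_b
    if total_cut == 0:
        raise ValueError("no cut-band signal in either lane")
    fraction_a = cut_band_a / total_cut
    return fraction_a, 1.0 - fraction_a
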