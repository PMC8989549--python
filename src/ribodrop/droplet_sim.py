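"""Synthetic sorting-campaign generator.

Simulates full fluorescence-activated droplet sorting screens of a
riboswitch library expressed in a cell-free protein synthesis system:

* ground-truth dose-response phenotypes for every library variant
  (a small planted fraction of true switches among leaky and repressed
  variants),
* Poisson (optionally clumped) bead encapsulation,
* ROX (transcription beacon) and split-GFP (riboswitch output) droplet
  signals with lognormal noise and a reporter saturation ceiling,
* quantile gate construction anchored on the empty-droplet cluster,
* sorting with miss / false-sort errors, and
* pool regeneration by PCR for the next round.

Alternating ON (with ligand, keep high GFP) and OFF (no ligand, keep low
GFP) rounds enrich variants that express only in the presence of ligand.
The two-template mock experiment (constitutive "strong-RBS" vs
"weak-RBS" templates mixed 5:95) is also provided; with bead clumping it
reproduces the dilution of template-level enrichment relative to
droplet-level enrichment.

Expression is in units of the no-riboswitch control construct (1.0 =
fully active promoter + RBS with no inhibitory structure).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .encapsulation import (
    LoadingModel,
    bead_pgf,
    lambda_for_occupancy,
    sample_bead_counts,
)
from .library_design import (
    ENUMERATION_CAP,
    LibraryDesign,
    normalize_pool,
    variant_ids,
)

Pool = dict[str, float]

#: Per-round seed stride used to derive round seeds from a campaign seed.
ROUND_SEED_STRIDE = 100_003


class EmptyPoolError(RuntimeError):
    """No beads were recovered from a sorting round; the campaign halts."""


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Phenotypes
# --------------------------------------------------------------------------

ClassLabel = Literal["on_switch", "off_switch", "constitutive", "dead"]


@dataclass(frozen=True)
class SwitchPhenotype:
    """Ground-truth dose response of one variant (Hill parameterization).

    ``off_level`` is the expression with no ligand, ``on_level`` at
    saturating ligand; both in units of the no-riboswitch control.
    """

    off_level: float
    on_level: float
    ec50: float = 1.6
    hill: float = 1.0
    class_label: ClassLabel = "constitutive"

    def __post_init__(self) -> None:
        if self.off_level < 0 or self.on_level < 0:
            raise ValueError("expression levels must be >= 0")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be > 0")

    @property
    def dynamic_ratio(self) -> float:
        """ON/OFF ratio at saturation (inverted for off-switches)."""
        lo, hi = sorted((self.off_level, self.on_level))
        return math.inf if lo == 0 else hi / lo


def expression_level(ph: SwitchPhenotype, conc: float) -> float:
    """Hill dose response: ``off + (on - off) c^h / (ec50^h + c^h)``."""
    if conc < 0:
        raise ValueError("ligand concentration must be >= 0")
    if conc == 0:
        return ph.off_level
    ch = conc**ph.hill
    return ph.off_level + (ph.on_level - ph.off_level) * ch / (ph.ec50**ph.hill + ch)


@dataclass(frozen=True)
class EffectParams:
    """Ranges used to draw planted-switch and background phenotypes.

    Defaults reflect a library built around an inhibitory stem-loop:
    most variants stay repressed ("dead", a few percent of control),
    a minority is constitutively leaky near the control level, and
    planted switches span 5-20x activation (covering the strongest
    observed responses, ~19.7x) around a millimolar EC50.
    """

    ratio_range: tuple[float, float] = (5.0, 20.0)
    off_level_range: tuple[float, float] = (0.02, 0.15)
    constitutive_level_range: tuple[float, float] = (0.6, 1.4)
    # Repressed variants leak at the same level as a switch's OFF state:
    # the inhibitory stem, common to both, sets the basal expression.
    dead_level_range: tuple[float, float] = (0.02, 0.15)
    ec50_log_mean: float = math.log(1.6)
    ec50_log_sd: float = 0.5
    hill: float = 1.0
    constitutive_fraction: float = 0.1


def assign_phenotypes(
    design: LibraryDesign,
    planted_fraction: float = 0.01,
    effect_params: EffectParams = EffectParams(),
    seed: int | np.random.Generator | None = None,
    switch_class: ClassLabel = "on_switch",
    cap: int = ENUMERATION_CAP,
) -> dict[str, SwitchPhenotype]:
    """Assign a ground-truth phenotype to every variant of a design.

    A random ``planted_fraction`` of variants become true switches with
    ON/OFF ratios drawn from ``effect_params.ratio_range``; the remainder
    is split between constitutive (leaky) and dead (repressed) variants.
    Deterministic given the seed.
    """
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = _rng(seed)
    ids = variant_ids(design, cap=cap)
    n = len(ids)
    n_planted = int(round(planted_fraction * n))
    planted = set(rng.choice(n, size=n_planted, replace=False).tolist())
    ep = effect_params
    phenotypes: dict[str, SwitchPhenotype] = {}
    for i, vid in enumerate(ids):
        if i in planted:
            off = rng.uniform(*ep.off_level_range)
            ratio = rng.uniform(*ep.ratio_range)
            on = off * ratio
            if switch_class == "off_switch":
                off, on = on, off
            phenotypes[vid] = SwitchPhenotype(
                off_level=off,
                on_level=on,
                ec50=float(rng.lognormal(ep.ec50_log_mean, ep.ec50_log_sd)),
                hill=ep.hill,
                class_label=switch_class,
            )
        elif rng.random() < ep.constitutive_fraction:
            level = rng.uniform(*ep.constitutive_level_range)
            phenotypes[vid] = SwitchPhenotype(level, level, class_label="constitutive")
        else:
            level = rng.uniform(*ep.dead_level_range)
            phenotypes[vid] = SwitchPhenotype(level, level, class_label="dead")
    return phenotypes


# --------------------------------------------------------------------------
# Optics and droplet events
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticsModel:
    """Signal model for the two fluorescence channels.

    ``gfp_cap`` is the split-GFP saturation ceiling in expression units:
    the detector fragment is present at a fixed concentration, so summed
    reporter output above the ceiling reads as the ceiling.  ROX reports
    transcription generally, so it is modeled as a bead-presence
    indicator scaled by ``rox_scale``.  All signals carry multiplicative
    lognormal noise of coefficient of variation ``noise_cv``.
    """

    gfp_cap: float = 1.2
    gfp_scale: float = 20.0
    rox_scale: float = 20.0
    noise_cv: float = 0.25
    gfp_baseline: float = 1.0
    rox_baseline: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gfp_cap", "gfp_scale", "rox_scale", "gfp_baseline", "rox_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.noise_cv < 1.0:
            raise ValueError("noise_cv must be in [0, 1)")


DEFAULT_OPTICS = OpticsModel()


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


@dataclass(frozen=True)
class DropletEvent:
    """One droplet: bead content, condition, signals and sort flags."""

    bead_count: int
    variant_ids: tuple[str, ...]
    ligand_conc: float
    rox: float
    gfp: float
    in_gate: bool
    sorted_flag: bool


@dataclass
class DropletEvents:
    """A simulated droplet population (structure-of-arrays container).

    ``bead_droplet`` and ``bead_variant`` map each bead to its droplet
    index and to an index into ``variant_ids``.
    """

    ligand_conc: float
    bead_count: np.ndarray
    rox: np.ndarray
    gfp: np.ndarray
    in_gate: np.ndarray
    sorted_flag: np.ndarray
    bead_droplet: np.ndarray
    bead_variant: np.ndarray
    variant_ids: list[str]

    def __len__(self) -> int:
        return self.bead_count.shape[0]

    def event(self, i: int) -> DropletEvent:
        beads = self.bead_variant[self.bead_droplet == i]
        return DropletEvent(
            bead_count=int(self.bead_count[i]),
            variant_ids=tuple(self.variant_ids[j] for j in beads),
            ligand_conc=self.ligand_conc,
            rox=float(self.rox[i]),
            gfp=float(self.gfp[i]),
            in_gate=bool(self.in_gate[i]),
            sorted_flag=bool(self.sorted_flag[i]),
        )

    def droplets_containing(self, variant_id: str) -> np.ndarray:
        """Boolean mask of droplets holding >= 1 bead of the given variant."""
        idx = self.variant_ids.index(variant_id)
        mask = np.zeros(len(self), dtype=bool)
        beads = self.bead_droplet[self.bead_variant == idx]
        mask[beads] = True
        return mask


def droplet_signals(
    variant_ids_in_droplet: Sequence[str],
    phenotypes: Mapping[str, SwitchPhenotype],
    conc: float,
    optics: OpticsModel = DEFAULT_OPTICS,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Signals of a single droplet given its bead content.

    Empty droplets show only (noisy) channel baselines.  Occupied
    droplets add the ROX presence signal and the summed, cap-limited
    expression of all beads on the GFP channel — multi-bead droplets
    share one fluorescence readout and hence one sorting fate.
    """
    rng = _rng(seed)
    total = sum(expression_level(phenotypes[v], conc) for v in variant_ids_in_droplet)
    has_bead = len(variant_ids_in_droplet) > 0
    rox = optics.rox_baseline * float(_lognoise(rng, optics.noise_cv, ()))
    gfp = optics.gfp_baseline * float(_lognoise(rng, optics.noise_cv, ()))
    if has_bead:
        rox += optics.rox_scale * float(_lognoise(rng, optics.noise_cv, ()))
        capped = min(total, optics.gfp_cap)
        gfp += optics.gfp_scale * capped * float(_lognoise(rng, optics.noise_cv, ()))
    return rox, gfp


def generate_events(
    pool: Mapping[str, float],
    n_droplets: int,
    loading: LoadingModel,
    phenotypes: Mapping[str, SwitchPhenotype],
    optics: OpticsModel,
    ligand_conc: float,
    seed: int | np.random.Generator | None = None,
) -> DropletEvents:
    """Encapsulate a pool and measure every droplet (vectorized)."""
    rng = _rng(seed)
    abund = normalize_pool(pool)
    ids = list(abund.keys())
    probs = np.asarray(list(abund.values()))
    counts = sample_bead_counts(n_droplets, loading, seed=rng)
    n_beads = int(counts.sum())
    bead_variant = rng.choice(len(ids), size=n_beads, p=probs)
    bead_droplet = np.repeat(np.arange(n_droplets), counts)
    expr_per_variant = np.array(
        [expression_level(phenotypes[v], ligand_conc) for v in ids]
    )
    total_expr = np.bincount(
        bead_droplet, weights=expr_per_variant[bead_variant], minlength=n_droplets
    )
    occupied = counts > 0
    rox = optics.rox_baseline * _lognoise(rng, optics.noise_cv, n_droplets)
    gfp = optics.gfp_baseline * _lognoise(rng, optics.noise_cv, n_droplets)
    rox += occupied * optics.rox_scale * _lognoise(rng, optics.noise_cv, n_droplets)
    capped = np.minimum(total_expr, optics.gfp_cap)
    gfp += optics.gfp_scale * capped * _lognoise(rng, optics.noise_cv, n_droplets)
    return DropletEvents(
        ligand_conc=ligand_conc,
        bead_count=counts,
        rox=rox,
        gfp=gfp,
        in_gate=np.zeros(n_droplets, dtype=bool),
        sorted_flag=np.zeros(n_droplets, dtype=bool),
        bead_droplet=bead_droplet,
        bead_variant=bead_variant,
        variant_ids=ids,
    )


# --------------------------------------------------------------------------
# Gating and sorting
# --------------------------------------------------------------------------

GateMode = Literal["high_gfp", "low_gfp"]


@dataclass(frozen=True)
class Gate:
    """A sorting gate: ROX positivity floor plus one GFP threshold."""

    rox_min: float
    gfp_bound: float
    mode: GateMode
    cap_fraction: float

    def membership(self, events: DropletEvents) -> np.ndarray:
        positive = events.rox > self.rox_min
        if self.mode == "high_gfp":
            return positive & (events.gfp >= self.gfp_bound)
        return positive & (events.gfp <= self.gfp_bound)


def build_gate(
    events: DropletEvents, mode: GateMode, cap_fraction: float = 0.03
) -> Gate:
    """Construct a gate from the droplet population itself.

    The ROX floor is the 99.9% quantile of the dominant low-ROX cluster
    (the empty droplets, identified as values within 4x the population
    median).  The GFP bound is then the quantile of GFP among
    ROX-positive droplets such that the gate holds at most
    ``cap_fraction`` of ALL droplets — mirroring gates drawn on the
    extreme-GFP tail of the transcriptionally active population,
    capped at 10% of all events.
    """
    n = len(events)
    if n < 1000:
        raise ValueError("need >= 1000 droplets for meaningful quantile gates")
    if not 0.0 < cap_fraction <= 0.10:
        raise ValueError("cap_fraction must be in (0, 0.10]")
    if mode not in ("high_gfp", "low_gfp"):
        raise ValueError(f"unknown gate mode {mode!r}")
    rox = events.rox
    med = float(np.median(rox))
    empty_cluster = rox[rox <= 4.0 * med]
    rox_min = float(np.quantile(empty_cluster, 0.999))
    positive = rox > rox_min
    n_pos = int(positive.sum())
    # A genuine occupied cluster sits well above the empty-cluster tail;
    # bare quantile exceedances of the empty cluster do not.
    if n_pos == 0 or float(np.median(rox[positive])) < 2.0 * rox_min:
        raise ValueError("no ROX-positive droplet cluster found (all empty?)")
    k = int(math.floor(cap_fraction * n))
    if k < 1:
        raise ValueError("cap_fraction too small for this population")
    gfp_pos = events.gfp[positive]
    if mode == "high_gfp":
        order = np.sort(gfp_pos)[::-1]
        if n_pos <= k:
            bound = float(order[-1])
        else:
            bound = float(order[k - 1])
            if int(np.count_nonzero(gfp_pos >= bound)) > k:
                higher = gfp_pos[gfp_pos > bound]
                bound = float(higher.min()) if higher.size else float("inf")
    else:
        order = np.sort(gfp_pos)
        if n_pos <= k:
            bound = float(order[-1])
        else:
            bound = float(order[k - 1])
            if int(np.count_nonzero(gfp_pos <= bound)) > k:
                lower = gfp_pos[gfp_pos < bound]
                bound = float(lower.max()) if lower.size else float("-inf")
    return Gate(rox_min=rox_min, gfp_bound=bound, mode=mode, cap_fraction=cap_fraction)


def sort_droplets(
    events: DropletEvents,
    gate: Gate,
    false_sort: float = 0.003,
    miss: float = 0.02,
    seed: int | np.random.Generator | None = None,
) -> DropletEvents:
    """Apply the sorter to a gated population, recording per-event flags.

    In-gate droplets are dispensed with probability ``1 - miss``;
    out-of-gate droplets slip through with probability ``false_sort``
    (droplet trains and satellite droplets make the real sorter
    imperfect in both directions).
    """
    if not (0.0 <= false_sort < 1.0 and 0.0 <= miss <= 1.0):
        raise ValueError("sorter error rates must be fractions")
    rng = _rng(seed)
    member = gate.membership(events)
    u = rng.random(len(events))
    events.in_gate = member
    events.sorted_flag = np.where(member, u >= miss, u < false_sort)
    return events


def regenerate_pool(
    events: DropletEvents,
    pcr_bias_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Pool:
    """Recover templates from sorted droplets and amplify into a new pool.

    Every bead inside a sorted droplet contributes one template lineage;
    relative abundances are bead counts times lognormal(mean 1,
    CV ``pcr_bias_cv``) amplification factors, normalized to sum to 1.
    """
    rng = _rng(seed)
    sorted_beads = events.sorted_flag[events.bead_droplet]
    counts = np.bincount(
        events.bead_variant[sorted_beads], minlength=len(events.variant_ids)
    ).astype(float)
    if counts.sum() == 0:
        raise EmptyPoolError("no beads recovered from the sorted droplets")
    if pcr_bias_cv > 0:
        counts = counts * _lognoise(rng, pcr_bias_cv, counts.shape[0])
    abund = counts / counts.sum()
    return {
        vid: float(a)
        for vid, a in zip(events.variant_ids, abund)
        if a > 0
    }


# --------------------------------------------------------------------------
# Rounds and screens
# --------------------------------------------------------------------------


def _default_loading() -> LoadingModel:
    return LoadingModel(lam=lambda_for_occupancy(0.30))


@dataclass(frozen=True)
class RoundSpec:
    """One sorting round: target, ligand condition and sorter settings.

    Defaults follow the screening protocol scaled to desk size: 5 x 10^5
    droplets per round (roughly 90x coverage of a ~5000-variant library,
    comparable to the 10-40x the protocol targets), 30% occupancy
    (>= 70% empty), a 3% gate cap and small sorter error rates.
    """

    sort_target: Literal["ON", "OFF"]
    ligand_conc: float
    n_droplets: int = 500_000
    loading: LoadingModel = field(default_factory=_default_loading)
    gate_cap: float = 0.03
    sorter_false_sort: float = 0.003
    sorter_miss: float = 0.02
    pcr_bias_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.sort_target not in ("ON", "OFF"):
            raise ValueError("sort_target must be 'ON' or 'OFF'")
        if self.n_droplets < 1000:
            raise ValueError("need >= 1000 droplets per round")

    @property
    def gate_mode(self) -> GateMode:
        return "high_gfp" if self.sort_target == "ON" else "low_gfp"


def alternating_schedule(
    n_rounds: int = 4,
    on_conc: float = 5.0,
    start_with: Literal["ON", "OFF"] = "ON",
    **round_kwargs,
) -> list[RoundSpec]:
    """ON/OFF alternating schedule (ligand present only in ON rounds)."""
    first_on = start_with == "ON"
    specs = []
    for i in range(n_rounds):
        on = (i % 2 == 0) == first_on
        specs.append(
            RoundSpec(
                sort_target="ON" if on else "OFF",
                ligand_conc=on_conc if on else 0.0,
                **round_kwargs,
            )
        )
    return specs


@dataclass(frozen=True)
class RoundMetrics:
    """Summary of one simulated round."""

    n_droplets: int
    occupied_fraction: float
    in_gate_fraction: float
    n_sorted: int
    n_variants_out: int

    def to_dict(self) -> dict:
        return {
            "n_droplets": self.n_droplets,
            "occupied_fraction": self.occupied_fraction,
            "in_gate_fraction": self.in_gate_fraction,
            "n_sorted": self.n_sorted,
            "n_variants_out": self.n_variants_out,
        }


@dataclass
class RoundResult:
    pool: Pool
    events: DropletEvents
    metrics: RoundMetrics


def simulate_round(
    pool: Mapping[str, float],
    spec: RoundSpec,
    phenotypes: Mapping[str, SwitchPhenotype],
    optics: OpticsModel = DEFAULT_OPTICS,
    seed: int | np.random.Generator | None = None,
) -> RoundResult:
    """Encapsulate, measure, gate, sort and regenerate one round."""
    rng = _rng(seed)
    events = generate_events(
        pool, spec.n_droplets, spec.loading, phenotypes, optics, spec.ligand_conc, rng
    )
    gate = build_gate(events, spec.gate_mode, spec.gate_cap)
    sort_droplets(events, gate, spec.sorter_false_sort, spec.sorter_miss, rng)
    next_pool = regenerate_pool(events, spec.pcr_bias_cv, rng)
    metrics = RoundMetrics(
        n_droplets=len(events),
        occupied_fraction=float((events.bead_count > 0).mean()),
        in_gate_fraction=float(events.in_gate.mean()),
        n_sorted=int(events.sorted_flag.sum()),
        n_variants_out=len(next_pool),
    )
    return RoundResult(pool=next_pool, events=events, metrics=metrics)


@dataclass
class ScreenHistory:
    """Every intermediate pool of a campaign (these become the
    sequencing cycles: index 0 is the unsorted input library)."""

    pools: list[Pool]
    metrics: list[RoundMetrics]
    schedule: list[RoundSpec]
    halted: bool = False
    halted_at: int | None = None

    @property
    def n_cycles(self) -> int:
        return len(self.pools)

    def abundance_frame(self) -> pd.DataFrame:
        """Variant x cycle percentage abundances (columns 0..C)."""
        ids = sorted({v for pool in self.pools for v in pool}, key=lambda s: (len(s), s))
        frame = pd.DataFrame(
            {c: [100.0 * pool.get(v, 0.0) for v in ids] for c, pool in enumerate(self.pools)},
            index=pd.Index(ids, name="variant_id"),
        )
        return frame

    def export(self, directory) -> None:
        """Write per-cycle pools as TSV plus a JSON metrics summary."""
        from pathlib import Path

        from .library_design import write_pool_tsv

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        for c, pool in enumerate(self.pools):
            write_pool_tsv(pool, out / f"cycle_{c}.tsv")
        summary = {
            "n_cycles": self.n_cycles,
            "halted": self.halted,
            "halted_at": self.halted_at,
            "rounds": [m.to_dict() for m in self.metrics],
        }
        (out / "metrics.json").write_text(json.dumps(summary, indent=2))


def simulate_screen(
    initial_pool: Mapping[str, float],
    schedule: Sequence[RoundSpec],
    phenotypes: Mapping[str, SwitchPhenotype],
    optics: OpticsModel = DEFAULT_OPTICS,
    seed: int = 0,
) -> ScreenHistory:
    """Run sequential sorting rounds, recording every intermediate pool.

    Per-round seeds are derived from the campaign seed by a fixed
    stride, so individual rounds can be reproduced in isolation.  An
    empty sorted pool halts the campaign; remaining rounds are skipped
    and the halt is recorded.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one round")
    pool = normalize_pool(initial_pool)
    history = ScreenHistory(pools=[pool], metrics=[], schedule=list(schedule))
    for i, spec in enumerate(schedule):
        round_seed = (seed + (i + 1) * ROUND_SEED_STRIDE) % 2**31
        try:
            result = simulate_round(pool, spec, phenotypes, optics, round_seed)
        except EmptyPoolError:
            history.halted = True
            history.halted_at = i
            break
        pool = result.pool
        history.pools.append(pool)
        history.metrics.append(result.metrics)
    return history


# --------------------------------------------------------------------------
# Mock sorting (two-template validation experiment)
# --------------------------------------------------------------------------

MOCK_ON_ID = "PT7-RBS-GFP11"
MOCK_OFF_ID = "PT7-wRBS-GFP11"

#: Strong-RBS template: constitutive expression at the control level.
MOCK_ON_PHENOTYPE = SwitchPhenotype(1.0, 1.0, class_label="constitutive")
#: Weak-RBS template: low constitutive expression.
MOCK_OFF_PHENOTYPE = SwitchPhenotype(0.05, 0.05, class_label="dead")


@dataclass(frozen=True)
class MockReport:
    """Before/after composition of a mock sort at droplet and template level."""

    sort_for: str
    droplet_fraction_before: float
    droplet_fraction_after: float
    template_fraction_before: float
    template_fraction_after: float
    efficiency: float
    purity: float

    @property
    def droplet_enrichment_fold(self) -> float:
        return self.droplet_fraction_after / self.droplet_fraction_before

    @property
    def template_enrichment_fold(self) -> float:
        return self.template_fraction_after / self.template_fraction_before


def simulate_mock(
    minor_fraction: float = 0.05,
    sort_for: Literal["ON", "OFF"] = "ON",
    n_droplets: int = 100_000,
    loading: LoadingModel | None = None,
    optics: OpticsModel = DEFAULT_OPTICS,
    gate_cap: float | None = None,
    false_sort: float = 0.003,
    miss: float = 0.02,
    pcr_bias_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> MockReport:
    """One sorting round on a two-template 5:95-style mixture.

    The pool mixes a strong-RBS (constitutively bright) and a weak-RBS
    (dim) template, with the sorted-for species at ``minor_fraction``.
    A droplet counts as ON if it holds at least one strong-RBS bead
    (multi-bead droplets fluoresce if any bead is bright); an OFF
    droplet is occupied with no strong-RBS bead.  The default loading
    includes bead clumping (clump_p = 0.3), which is what makes the
    template-level enrichment fall short of the droplet-level one.

    With ``gate_cap=None`` the gate cap is set just inside the expected
    minor-droplet cluster (85% of its closed-form population fraction),
    mirroring how an operator draws the gate around the visible minor
    cluster rather than at a fixed percentage.
    """
    if not 0.0 < minor_fraction < 1.0:
        raise ValueError("minor_fraction must be in (0, 1)")
    if sort_for not in ("ON", "OFF"):
        raise ValueError("sort_for must be 'ON' or 'OFF'")
    rng = _rng(seed)
    if loading is None:
        loading = LoadingModel(lam=lambda_for_occupancy(0.30), clump_p=0.3)
    if gate_cap is None:
        if sort_for == "ON":
            expected = 1.0 - bead_pgf(loading, 1.0 - minor_fraction)
        else:
            expected = bead_pgf(loading, minor_fraction) - bead_pgf(loading, 0.0)
        gate_cap = min(0.10, max(1e-3, 0.85 * expected))
    desired_id = MOCK_ON_ID if sort_for == "ON" else MOCK_OFF_ID
    pool = {
        MOCK_ON_ID: minor_fraction if sort_for == "ON" else 1.0 - minor_fraction,
        MOCK_OFF_ID: 1.0 - minor_fraction if sort_for == "ON" else minor_fraction,
    }
    phenotypes = {MOCK_ON_ID: MOCK_ON_PHENOTYPE, MOCK_OFF_ID: MOCK_OFF_PHENOTYPE}
    events = generate_events(pool, n_droplets, loading, phenotypes, optics, 0.0, rng)
    mode: GateMode = "high_gfp" if sort_for == "ON" else "low_gfp"
    gate = build_gate(events, mode, gate_cap)
    sort_droplets(events, gate, false_sort, miss, rng)
    pool_after = regenerate_pool(events, pcr_bias_cv, rng)

    has_on = events.droplets_containing(MOCK_ON_ID)
    occupied = events.bead_count > 0
    desired = has_on if sort_for == "ON" else (occupied & ~has_on)
    n_sorted = int(events.sorted_flag.sum())
    if n_sorted == 0:
        raise EmptyPoolError("no droplets sorted in mock experiment")
    droplet_before = float(desired.mean())
    droplet_after = float((desired & events.sorted_flag).sum()) / n_sorted
    in_gate_n = int(events.in_gate.sum())
    efficiency = 100.0 * float((desired & events.sorted_flag).sum()) / in_gate_n
    purity = 100.0 * droplet_after
    return MockReport(
        sort_for=sort_for,
        droplet_fraction_before=droplet_before,
        droplet_fraction_after=droplet_after,
        template_fraction_before=minor_fraction,
        template_fraction_after=float(pool_after.get(desired_id, 0.0)),
        efficiency=efficiency,
        purity=purity,
    )
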