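"""Synthetic choline-rescue lipidome time courses.

Emulates the lipidomic structure of a choline-rescue experiment in a yeast
strain whose PC synthesis depends entirely on exogenous choline (the 3Δ
cho2Δ opi3Δ pct1Δ background rescued by a plasmid-borne enzyme): under
choline starvation (t = 0) PC is nearly absent, PE is strongly elevated, PS
slightly decreased and TAG elevated; after adding 1 mM choline PC rises and
the others relax, with saturating single-exponential kinetics.  Within PE
and PS, the saturated 32:1 species sits near 30 mol% of its class at t = 0
and falls as di-unsaturated 34:2 rises to compensate; DAG stays flat.

The generator returns both the noisy replicate samples and the noise-free
expected compositions (ground truth), so every downstream stage can be
tested against known truth.  Measurement noise is multiplicative lognormal
(amounts are positive and spread grows with the mean), CV 0.15 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import LipidClass, LipidSpecies, LipidomeSample, parse_species
from .psce import PsceParams, compute_w, classify
from .quantify import PEAK_COLUMNS, StandardConfig, default_standard_config


class ScenarioError(ValueError):
    """A scenario whose targets violate the generator invariants."""


@dataclass(frozen=True)
class ClassTrajectory:
    start_mol_pct: float
    end_mol_pct: float
    half_time_h: float = 4.0

    def at(self, t: float) -> float:
        # single-exponential approach to the post-choline steady state
        f = 1.0 - 0.5 ** (t / self.half_time_h)
        return self.start_mol_pct + (self.end_mol_pct - self.start_mol_pct) * f


def _default_class_trajectories() -> dict[LipidClass, ClassTrajectory]:
    return {
        LipidClass.PC: ClassTrajectory(2.0, 40.0),
        LipidClass.PE: ClassTrajectory(45.0, 22.0),
        LipidClass.PS: ClassTrajectory(8.0, 12.0),
        LipidClass.PI: ClassTrajectory(12.0, 12.0),
        LipidClass.PA: ClassTrajectory(4.0, 4.0),
        LipidClass.DAG: ClassTrajectory(4.0, 4.0),
        LipidClass.TAG: ClassTrajectory(25.0, 6.0),
    }


def _default_acyl_trajectories() -> dict[LipidClass, dict[str, tuple[float, float]]]:
    # within-class mol%: (start, end); PE/PS encode the 32:1 -> 34:2 swap
    return {
        LipidClass.PC: {"32:1": (30, 25), "34:1": (40, 40), "32:2": (10, 10), "34:2": (20, 25)},
        LipidClass.PE: {"32:1": (30, 8), "34:1": (50, 42), "32:2": (5, 10), "34:2": (15, 40)},
        LipidClass.PS: {"32:1": (30, 10), "34:1": (45, 40), "32:2": (5, 15), "34:2": (20, 35)},
        LipidClass.PI: {"34:1": (60, 60), "34:2": (40, 40)},
        LipidClass.PA: {"34:1": (60, 60), "34:2": (40, 40)},
        LipidClass.DAG: {"32:1": (50, 50), "34:2": (50, 50)},
        LipidClass.TAG: {"48:1": (40, 40), "48:2": (30, 30), "50:2": (30, 30)},
    }


@dataclass
class RescueScenario:
    """Targets and noise model for one synthetic rescue experiment."""

    time_points_h: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 24.0)
    n_replicates: int = 3
    class_trajectories: dict[LipidClass, ClassTrajectory] = field(
        default_factory=_default_class_trajectories
    )
    acyl_trajectories: dict[LipidClass, dict[str, tuple[float, float]]] = field(
        default_factory=_default_acyl_trajectories
    )
    noise_cv: float = 0.15
    total_lipid_nmol: float = 200.0  # per 50 mg biomass
    condition: str = "WT-Pct1-GFP"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ScenarioError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ScenarioError("noise_cv must be >= 0")
        if self.total_lipid_nmol <= 0:
            raise ScenarioError("total_lipid_nmol must be > 0")
        for label, getter in (("start", lambda tr: tr.start_mol_pct),
                              ("end", lambda tr: tr.end_mol_pct)):
            s = sum(getter(tr) for tr in self.class_trajectories.values())
            if abs(s - 100.0) > 1e-6:
                raise ScenarioError(f"class {label} mol% targets sum to {s}, not 100")
        for cls, acyl in self.acyl_trajectories.items():
            if cls not in self.class_trajectories:
                raise ScenarioError(f"acyl targets for {cls.value} lack a class trajectory")
            for i, label in enumerate(("start", "end")):
                s = sum(v[i] for v in acyl.values())
                if abs(s - 100.0) > 1e-6:
                    raise ScenarioError(
                        f"{cls.value} within-class {label} targets sum to {s}, not 100"
                    )
        missing = set(self.class_trajectories) - set(self.acyl_trajectories)
        if missing:
            raise ScenarioError(
                f"classes without acyl targets: {sorted(c.value for c in missing)}"
            )

    def expected_composition(self, t: float) -> dict[LipidSpecies, float]:
        """Noise-free expected amounts (nmol) at time ``t``.

        Class mol% values are renormalised to 100 at each time point so that
        differing half-times cannot break the composition invariant (with
        the default single half-time the renormalisation is a no-op).
        """
        cls_pct = {c: tr.at(t) for c, tr in self.class_trajectories.items()}
        norm = sum(cls_pct.values())
        out: dict[LipidSpecies, float] = {}
        for cls, pct in cls_pct.items():
            cls_nmol = self.total_lipid_nmol * pct / norm
            acyl = self.acyl_trajectories[cls]
            half = self.class_trajectories[cls].half_time_h
            f = 1.0 - 0.5 ** (t / half)
            shares = {k: s + (e - s) * f for k, (s, e) in acyl.items()}
            share_norm = sum(shares.values())
            for comp, share in shares.items():
                sp = parse_species(f"{cls.value} {comp}")
                out[sp] = cls_nmol * share / share_norm
        return out


@dataclass
class TimecourseTruth:
    """Noise-free expectations aligned with the generated samples."""

    scenario: RescueScenario
    expected_amounts: dict[float, dict[LipidSpecies, float]]  # time -> composition

    def expected_class_mol_pct(self, t: float) -> dict[LipidClass, float]:
        comp = self.expected_amounts[t]
        totals: dict[LipidClass, float] = {}
        for sp, a in comp.items():
            totals[sp.lipid_class] = totals.get(sp.lipid_class, 0.0) + a
        grand = sum(totals.values())
        return {c: 100.0 * v / grand for c, v in totals.items()}

    def expected_fa_mol_pct(self, t: float, cls: LipidClass) -> dict[str, float]:
        comp = self.expected_amounts[t]
        pool = {sp: a for sp, a in comp.items() if sp.lipid_class == cls}
        tot = sum(pool.values())
        return {sp.sum_composition: 100.0 * a / tot for sp, a in pool.items()}


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)  # mean 1


def generate_timecourse(
    scenario: Optional[RescueScenario] = None,
    seed: Optional[int] = None,
) -> tuple[list[LipidomeSample], TimecourseTruth]:
    """Generate noisy replicate lipidomes for every (time, replicate).

    Each species amount is the expected amount times an independent
    mean-one lognormal factor of the scenario's CV.  Reproducible for a
    fixed seed (``seed`` overrides ``scenario.seed``).
    """
    scenario = scenario if scenario is not None else RescueScenario()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    samples: list[LipidomeSample] = []
    expected: dict[float, dict[LipidSpecies, float]] = {}
    for t in scenario.time_points_h:
        comp = scenario.expected_composition(t)
        expected[t] = comp
        species = list(comp)
        for rep in range(1, scenario.n_replicates + 1):
            factors = _lognormal_factors(rng, scenario.noise_cv, len(species))
            amounts = {sp: comp[sp] * f for sp, f in zip(species, factors)}
            samples.append(
                LipidomeSample(
                    sample_id=f"{scenario.condition}_t{t:g}h_r{rep}",
                    condition=scenario.condition,
                    time_h=t,
                    replicate=rep,
                    amounts=amounts,
                )
            )
    return samples, TimecourseTruth(scenario, expected)


# ---------------------------------------------------------------------------
# raw peak tables


def generate_peak_table(
    samples: Sequence[LipidomeSample],
    standards: Optional[StandardConfig] = None,
    response_noise_cv: float = 0.0,
    seed: int = 0,
    response_factors: Optional[Mapping[LipidClass, float]] = None,
) -> pd.DataFrame:
    """Simulate integrated peak areas for a set of lipidomes.

    area(analyte) = amount * response factor * lognormal noise, with the
    response factor taken per quantification group (the class of the
    internal standard that quantifies the analyte) so that the standard
    ratio cancels it, as in the single-point response model.  Standard rows
    (area = spiked amount * factor, no noise: the spike is the reference)
    are appended per sample.
    """
    standards = standards if standards is not None else default_standard_config()
    present = {sp.lipid_class for s in samples for sp in s.biological_amounts()}
    if not standards.covers(present):
        missing = [c.value for c in present
                   if not standards.covers([c])]
        raise ScenarioError(f"no standard coverage for classes: {sorted(missing)}")
    if response_factors is None:
        # deterministic spread of instrument response across standard groups
        response_factors = {
            cls: 0.5 + 0.25 * i
            for i, cls in enumerate(sorted(standards.standards, key=lambda c: c.value))
        }
    rng = np.random.default_rng(seed)
    rows = []
    for s in samples:
        bio = s.biological_amounts()
        species = list(bio)
        factors = _lognormal_factors(rng, response_noise_cv, len(species))
        used_std_classes = set()
        for sp, f in zip(species, factors):
            std_class = standards.resolve(sp.lipid_class)
            used_std_classes.add(std_class)
            rf = response_factors[std_class]
            rows.append(
                dict(sample_id=s.sample_id, condition=s.condition, time_h=s.time_h,
                     replicate=s.replicate, species=str(sp),
                     area=bio[sp] * rf * f)
            )
        for std_class in sorted(used_std_classes, key=lambda c: c.value):
            std_sp, spiked = standards.standards[std_class]
            rows.append(
                dict(sample_id=s.sample_id, condition=s.condition, time_h=s.time_h,
                     replicate=s.replicate, species=str(std_sp),
                     area=spiked * response_factors[std_class])
            )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


# ---------------------------------------------------------------------------
# calibration fixtures


def generate_calibration_populations(
    params: PsceParams,
    n_populations: int = 8,
    noise_cv: float = 0.01,
    seed: int = 0,
) -> list[dict[LipidSpecies, float]]:
    """Asynchronous populations whose P_SCE is constant under ``params``.

    Construction: the type II pool trades PE 34:2 against DAG 32:1 and the
    type 0 pool trades PC 34:1 against PC 32:0, in each case keeping the
    w-weighted (respectively g(w)-weighted) sum fixed under the true
    coefficients; the unsaturation-sensitive species of the two pools are
    traded in opposite directions so a misweighted increment moves
    numerator and denominator oppositely.  Any other unsaturation increment
    therefore scatters P_SCE across populations, and the variance is
    minimised at the generating coefficients — the property
    ``calibrate_w`` exploits.
    """
    if n_populations < 3:
        raise ValueError("need >= 3 populations")
    pe342 = parse_species("PE 34:2")
    dag321 = parse_species("DAG 32:1")
    pc341 = parse_species("PC 34:1")
    pc320 = parse_species("PC 32:0")
    pe341 = parse_species("PE 34:1")
    for sp in (pe342, dag321):
        if classify(sp, params) != "type_II":
            raise ValueError(f"{sp} must be type II under the generating params")
    w = {sp: compute_w(sp, params) for sp in (pe342, dag321, pc341, pc320)}
    inv = params.denominator_mode == "inverse_weight"
    g = (lambda x: 1.0 / x) if inv else (lambda x: x)
    # weighted pool totals held fixed under the true params
    num_total = 40.0
    den_total = 120.0
    rng = np.random.default_rng(seed)
    pops = []
    ts = np.linspace(0.25, 0.75, n_populations)
    for k, t in enumerate(ts):
        a = num_total * t / w[pe342]          # PE 34:2 amount
        d = num_total * (1 - t) / w[dag321]   # DAG 32:1 amount
        b = den_total * t / g(w[pc341])        # PC 34:1 amount
        e = den_total * (1 - t) / g(w[pc320])  # PC 32:0 amount
        amounts = {pe342: a, dag321: d, pc341: b, pc320: e,
                   pe341: 30.0}  # pivot-class ballast, type 0, constant
        noise = _lognormal_factors(rng, noise_cv, len(amounts))
        pops.append({sp: v * f for (sp, v), f in zip(amounts.items(), noise)})
    return pops
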