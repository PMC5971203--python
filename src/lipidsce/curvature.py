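"""Lipid contribution to membrane stored curvature elastic (SCE) stress.

A lipid monolayer forced flat while its unstressed state is curved stores
torque stress.  To first order this stress is

    tau = -2 * K_M * C0_mix        [N]

where ``K_M`` is the monolayer bending modulus (J) and ``C0_mix`` the
spontaneous curvature (1/m) of the mixture, obtained from the component
lipids' spontaneous curvatures by ideal additive mixing:

    C0_mix = sum_i x_i * C0_i

with ``x_i`` the mole fractions over the included lipid classes.  Type II
lipids (PE, PA, DAG) have strongly negative C0, so their accumulation makes
C0_mix more negative and tau larger (more stored stress).

C0 values come from a provenance-annotated parameter table.  When a species
is absent, the matching fallback picks the same-class entry with the same
per-chain double-bond multiset and the nearest total carbon count; as a last
resort a class-level speculative default may be allowed (used for PI, which
has no measured C0 in the literature).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .core import (
    ChainAssignmentTable,
    LipidClass,
    LipidSpecies,
    LipidomeSample,
    assign_chains,
    parse_species,
)


class MissingParameterError(KeyError):
    """No C0 entry (exact, fallback, or allowed speculative) for a species."""


class UndefinedCompositionError(ValueError):
    """All included amounts are zero (or the inclusion set is empty)."""


@dataclass(frozen=True)
class C0Entry:
    lipid_class: LipidClass
    chains: tuple[tuple[int, int], ...]  # (carbons, double_bonds) per chain
    c0_per_m: float
    provenance: str
    speculative: bool = False

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("C0 entry requires a provenance note")
        if self.c0_per_m != self.c0_per_m or abs(self.c0_per_m) == float("inf"):
            raise ValueError("C0 must be finite")

    @property
    def total_carbons(self) -> int:
        return sum(c for c, _ in self.chains)

    def db_multiset(self) -> tuple[int, ...]:
        return tuple(sorted(d for _, d in self.chains))


@dataclass
class CurvatureParams:
    """C0 table plus bending modulus.

    ``class_defaults`` hold speculative class-level C0 values used only when
    a lookup explicitly allows them.
    """

    entries: list[C0Entry]
    class_defaults: dict[LipidClass, C0Entry] = field(default_factory=dict)
    k_m: float = 5.0e-20  # J; average monolayer bending modulus

    def __post_init__(self) -> None:
        if self.k_m <= 0:
            raise ValueError(f"K_M must be > 0, got {self.k_m}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path, None] = None) -> "CurvatureParams":
        """Load a C0 table; ``None`` loads the shipped default file."""
        if path is None:
            text = (
                resources.files("lipidsce").joinpath("params/c0_table.yaml").read_text()
            )
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        scale = 1e9 if raw.get("unit", "per_m") == "per_nm" else 1.0
        entries = []
        for row in raw["entries"]:
            chains = tuple(
                (int(p.split(":")[0]), int(p.split(":")[1]))
                for p in str(row["chains"]).split("/")
            )
            entries.append(
                C0Entry(
                    LipidClass(row["class"]),
                    chains,
                    float(row["c0"]) * scale,
                    str(row["provenance"]),
                    bool(row.get("speculative", False)),
                )
            )
        defaults = {}
        for code, row in (raw.get("class_defaults") or {}).items():
            cls_ = LipidClass(code)
            defaults[cls_] = C0Entry(
                cls_, ((0, 0),), float(row["c0"]) * scale, str(row["provenance"]),
                speculative=True,
            )
        return cls(entries=entries, class_defaults=defaults,
                   k_m=float(raw.get("bending_modulus_J", 5.0e-20)))


@dataclass(frozen=True)
class SceVariant:
    """Named class-inclusion variant for the tau estimate.

    The default includes {PC, PE, PS, PA, PG}: PI is left out for lack of
    measured C0 values, DAG and TAG because they partition into lipid
    droplets rather than the bilayer.  Alternates re-admit PI (with
    speculative C0) or DAG for sensitivity analysis.
    """

    name: str
    included_classes: frozenset[LipidClass]
    allow_speculative_c0: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "included_classes", frozenset(self.included_classes))
        if not self.included_classes:
            raise ValueError("variant must include at least one class")


DEFAULT_VARIANT = SceVariant(
    "default",
    frozenset({LipidClass.PC, LipidClass.PE, LipidClass.PS, LipidClass.PA,
               LipidClass.PG}),
)
WITH_PI_VARIANT = SceVariant(
    "with_pi_speculative",
    DEFAULT_VARIANT.included_classes | {LipidClass.PI},
    allow_speculative_c0=True,
)
WITH_DAG_VARIANT = SceVariant(
    "with_dag",
    DEFAULT_VARIANT.included_classes | {LipidClass.DAG},
)


@dataclass
class TauResult:
    c0_mix: float  # 1/m
    tau: float  # N
    mole_fractions: dict[LipidSpecies, float]
    lookups: dict[LipidSpecies, tuple[float, str]]  # species -> (C0 used, match kind)
    variant: SceVariant
    k_m: float

    @property
    def r0_mix(self) -> float:
        """Radius of curvature 1/C0_mix of the mixture (m)."""
        if self.c0_mix == 0:
            return float("inf")
        return 1.0 / self.c0_mix


def lookup_c0(
    species: LipidSpecies,
    params: CurvatureParams,
    allow_speculative: bool = False,
) -> tuple[float, str]:
    """Resolve C0 for one species; returns ``(c0_per_m, match_kind)``.

    match_kind is ``exact`` (class + chain multiset + carbons),
    ``fallback`` (same class, same per-chain double-bond multiset, minimal
    |delta total carbons|, ties broken toward the shorter chain), or
    ``speculative`` (class-level default, only when allowed).
    """
    if species.chains is None:
        raise ValueError(f"{species} needs an acyl-chain assignment before C0 lookup")
    db = species.chain_double_bond_multiset()
    carbons = species.total_carbons
    chain_multiset = tuple(sorted((c.carbons, c.double_bonds) for c in species.chains))
    same_class = [e for e in params.entries if e.lipid_class == species.lipid_class]
    exact = [e for e in same_class if tuple(sorted(e.chains)) == chain_multiset]
    if exact:
        return exact[0].c0_per_m, "exact"
    candidates = [e for e in same_class if e.db_multiset() == db]
    if candidates:
        best = min(candidates, key=lambda e: (abs(e.total_carbons - carbons),
                                              e.total_carbons))
        return best.c0_per_m, "fallback"
    if allow_speculative and species.lipid_class in params.class_defaults:
        return params.class_defaults[species.lipid_class].c0_per_m, "speculative"
    raise MissingParameterError(
        f"no C0 for {species} (per-chain unsaturation {db}); "
        f"speculative defaults {'absent' if allow_speculative else 'not allowed'}"
    )


def mix_c0(
    composition: Union[LipidomeSample, Mapping[LipidSpecies, float]],
    params: CurvatureParams,
    variant: SceVariant = DEFAULT_VARIANT,
    chain_table: Optional[ChainAssignmentTable] = None,
) -> TauResult:
    """Ideal-additive-mixing estimate of C0_mix and tau for one composition.

    Mole fractions are taken over the variant's included classes only;
    internal standards are excluded.  Species lacking chain assignments are
    resolved through ``chain_table`` (default yeast table).
    """
    if isinstance(composition, LipidomeSample):
        amounts = composition.biological_amounts()
    else:
        amounts = {s: a for s, a in composition.items() if not s.is_internal_standard}
    included = {
        s: a for s, a in amounts.items()
        if s.lipid_class in variant.included_classes and a > 0
    }
    total = sum(included.values())
    if total <= 0:
        raise UndefinedCompositionError(
            f"no positive amounts in classes {sorted(c.value for c in variant.included_classes)}"
        )
    fractions: dict[LipidSpecies, float] = {}
    lookups: dict[LipidSpecies, tuple[float, str]] = {}
    c0_mix = 0.0
    for sp, amt in included.items():
        sp_ch = assign_chains(sp, chain_table)
        c0, kind = lookup_c0(sp_ch, params, variant.allow_speculative_c0)
        x = amt / total
        fractions[sp] = x
        lookups[sp] = (c0, kind)
        c0_mix += x * c0
    tau = -2.0 * params.k_m * c0_mix
    return TauResult(c0_mix, tau, fractions, lookups, variant, params.k_m)


@dataclass
class SensitivityReport:
    base_variant: str
    times: list[float]
    tau_by_variant: dict[str, list[float]]  # variant name -> tau per time point
    trend_preserved: dict[str, bool]

    def deltas(self, name: str) -> list[float]:
        base = self.tau_by_variant[self.base_variant]
        return [t - b for t, b in zip(self.tau_by_variant[name], base)]


def sensitivity_analysis(
    samples: Sequence[LipidomeSample],
    params: CurvatureParams,
    base: SceVariant = DEFAULT_VARIANT,
    alternates: Iterable[SceVariant] = (WITH_PI_VARIANT, WITH_DAG_VARIANT),
    chain_table: Optional[ChainAssignmentTable] = None,
) -> SensitivityReport:
    """Recompute the tau series under alternative class-inclusion variants.

    Samples are averaged per time point; a variant preserves the trend when
    the signs of all successive differences of its mean-tau series match the
    base variant's.
    """
    if len({s.key for s in samples}) < 2:
        raise ValueError("sensitivity analysis needs at least two samples")
    times = sorted({s.time_h for s in samples})
    if len(times) < 2:
        raise ValueError("sensitivity analysis needs at least two time points")

    def mean_tau_series(variant: SceVariant) -> list[float]:
        out = []
        for t in times:
            taus = [
                mix_c0(s, params, variant, chain_table).tau
                for s in samples if s.time_h == t
            ]
            out.append(sum(taus) / len(taus))
        return out

    tau_by_variant = {base.name: mean_tau_series(base)}
    trend = {base.name: True}
    base_signs = _diff_signs(tau_by_variant[base.name])
    for v in alternates:
        series = mean_tau_series(v)
        tau_by_variant[v.name] = series
        trend[v.name] = _diff_signs(series) == base_signs
    return SensitivityReport(base.name, times, tau_by_variant, trend)


def _diff_signs(series: Sequence[float]) -> tuple[int, ...]:
    return tuple(
        (0 if b == a else (1 if b > a else -1))
        for a, b in zip(series, series[1:])
    )
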