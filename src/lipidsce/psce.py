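"""P_SCE: ratio-control proxy for total membrane SCE stress.

Each lipid gets a coarse-grained weight

    w = head_term(class) + unsat_increment * (number of double bonds,
                                              summed over acyl chains)

expressing how strongly it promotes stored curvature elastic stress.
Species are partitioned against the pivot lipid PE(34:1): w above the
pivot's weight w_Lp marks a type II (stress-raising) lipid, w at or below
w_Lp a type 0 lipid (the pivot itself is type 0).  The metric is the
weighted ratio

    P_SCE = sum_{n in type II} w_n [L_n]  /  sum_{m in type 0} g(w_m) [L_m]

with g(w) = 1/w by default (``inverse_weight``); ``direct_weight`` (g(w)=w)
is retained as a switch because the printed form of the denominator is
ambiguous.  P_SCE is invariant to uniform scaling of the amounts, so nmol
and mol% inputs are equivalent.

Unlike the purely lipid-based tau estimate, the w weights were conceived to
absorb protein contributions in a coarse-grained way: a cell holding P_SCE
in a narrow band while its lipidome swings is reading out active SCE-stress
homeostasis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .core import (
    ChainAssignmentTable,
    LipidClass,
    LipidSpecies,
    LipidomeSample,
    assign_chains,
    parse_species,
)
from .curvature import MissingParameterError, UndefinedCompositionError


@dataclass(frozen=True)
class WModel:
    """Coefficients of the coarse-grained w weight."""

    head_terms: Mapping[LipidClass, float]
    unsat_increment: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "head_terms", dict(self.head_terms))
        for cls, h in self.head_terms.items():
            if not h > 0 or h != h:
                raise ValueError(f"head term for {cls} must be finite and > 0")


@dataclass
class PsceParams:
    w_model: WModel
    pivot_species: LipidSpecies
    included_classes: frozenset[LipidClass]
    denominator_mode: str = "inverse_weight"  # or "direct_weight"

    def __post_init__(self) -> None:
        self.included_classes = frozenset(self.included_classes)
        if self.denominator_mode not in ("inverse_weight", "direct_weight"):
            raise ValueError(f"unknown denominator_mode {self.denominator_mode!r}")
        if self.pivot_species.lipid_class not in self.w_model.head_terms:
            raise MissingParameterError(
                f"pivot {self.pivot_species} not resolvable by the w model"
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path, None] = None) -> "PsceParams":
        """Load w-model coefficients; ``None`` loads the shipped defaults.

        Default inclusion set is {PC, PE, PS, PA, PI, DAG}; TAG is excluded
        (lipid-droplet lipid, not bilayer) and PG is excluded (no
        parameters available for it in the source model).
        """
        if path is None:
            text = (
                resources.files("lipidsce").joinpath("params/w_model.yaml").read_text()
            )
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        head = {LipidClass(k): float(v) for k, v in raw["head_terms"].items()}
        return cls(
            w_model=WModel(head, float(raw["unsat_increment"])),
            pivot_species=parse_species(str(raw["pivot"])),
            included_classes=frozenset(LipidClass(c) for c in raw["included_classes"]),
            denominator_mode=str(raw.get("denominator_mode", "inverse_weight")),
        )

    @property
    def pivot_w(self) -> float:
        return compute_w(self.pivot_species, self)


@dataclass
class PsceResult:
    p_sce: float
    numerator: float
    denominator: float
    classification: dict[LipidSpecies, str]  # "type_II" | "type_0"
    weights: dict[LipidSpecies, float]
    params_used: PsceParams


def compute_w(
    species: LipidSpecies,
    params: PsceParams,
    chain_table: Optional[ChainAssignmentTable] = None,
) -> float:
    """w for one species; additive over chains, so the per-chain sum of
    double bonds equals the sum-composition total and a chain assignment
    never changes the value — it is resolved anyway so that the record is
    explicit about chain structure."""
    if species.lipid_class not in params.w_model.head_terms:
        raise MissingParameterError(
            f"no head term for class {species.lipid_class.value}"
        )
    sp = assign_chains(species, chain_table)
    n_db = sum(c.double_bonds for c in sp.chains)
    return params.w_model.head_terms[sp.lipid_class] + params.w_model.unsat_increment * n_db


def classify(
    species: LipidSpecies,
    params: PsceParams,
    chain_table: Optional[ChainAssignmentTable] = None,
) -> str:
    """``type_II`` iff w(species) > w(pivot); equality is type 0."""
    return (
        "type_II"
        if compute_w(species, params, chain_table) > params.pivot_w
        else "type_0"
    )


def psce(
    sample: Union[LipidomeSample, Mapping[LipidSpecies, float]],
    params: PsceParams,
    chain_table: Optional[ChainAssignmentTable] = None,
) -> PsceResult:
    """Compute P_SCE for one lipidome."""
    if isinstance(sample, LipidomeSample):
        amounts = sample.biological_amounts()
    else:
        amounts = {s: a for s, a in sample.items() if not s.is_internal_standard}
    included = {
        s: a for s, a in amounts.items() if s.lipid_class in params.included_classes
    }
    if not included or all(a == 0 for a in included.values()):
        raise UndefinedCompositionError("no positive included amounts")
    pivot_w = params.pivot_w
    weights: dict[LipidSpecies, float] = {}
    classification: dict[LipidSpecies, str] = {}
    num = 0.0
    den = 0.0
    for sp, amt in included.items():
        w = compute_w(sp, params, chain_table)
        weights[sp] = w
        if w > pivot_w:
            classification[sp] = "type_II"
            num += w * amt
        else:
            classification[sp] = "type_0"
            g = (1.0 / w) if params.denominator_mode == "inverse_weight" else w
            den += g * amt
    if den <= 0:
        raise UndefinedCompositionError(
            "P_SCE denominator is zero: no type 0 lipid with positive amount"
        )
    return PsceResult(num / den, num, den, classification, weights, params)


# ---------------------------------------------------------------------------
# w calibration


def w_model_grid(
    head_terms: Mapping[LipidClass, float],
    unsat_increments: Iterable[float],
    dag_head_terms: Optional[Iterable[float]] = None,
) -> list[WModel]:
    """Cartesian grid of candidate w models varying the unsaturation
    increment (and optionally the DAG head term) around fixed head terms."""
    out = []
    dag_opts = list(dag_head_terms) if dag_head_terms is not None else [None]
    for u in unsat_increments:
        for dag in dag_opts:
            terms = dict(head_terms)
            if dag is not None:
                terms[LipidClass.DAG] = dag
            out.append(WModel(terms, u))
    return out


def calibrate_w(
    datasets: Sequence[Union[LipidomeSample, Mapping[LipidSpecies, float]]],
    params: PsceParams,
    search_space: Sequence[WModel],
    chain_table: Optional[ChainAssignmentTable] = None,
) -> PsceParams:
    """Select the w model minimising the variance of P_SCE across datasets.

    The rationale: across asynchronous populations that are each holding
    membrane stress steady, the true weighting should make P_SCE nearly
    constant; coefficients that scatter P_SCE are misweighted.  Ties go to
    the first candidate in the grid order (deterministic).
    """
    if len(datasets) < 3:
        raise ValueError(f"calibration needs >= 3 datasets, got {len(datasets)}")
    candidates = list(search_space)
    if not candidates:
        raise ValueError("empty search space")
    best: Optional[tuple[float, int]] = None
    for i, wm in enumerate(candidates):
        cand = replace(params, w_model=wm)
        values = [psce(d, cand, chain_table).p_sce for d in datasets]
        var = float(np.var(values))
        if best is None or var < best[0]:
            best = (var, i)
    return replace(params, w_model=candidates[best[1]])
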