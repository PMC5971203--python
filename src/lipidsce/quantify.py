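"""Internal-standard quantification and composition summaries.

Integrated LC-MS peak areas become absolute amounts through a single-point,
one-standard-per-class response model: each analyte's area is divided by the
area of the class-matched internal standard in the same sample and scaled by
the spiked amount.  Classes without a spiked standard (PS, PI, PA, DAG in a
typical yeast panel) are quantified against a configurable surrogate
standard; the mapping used is recorded on the output.

Downstream summaries are the composition quantities reported for lipidome
time courses: class mol% of total lipid, within-class fatty-acid mol%, and
the PC/PE ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .core import (
    LipidClass,
    LipidSpecies,
    LipidomeSample,
    parse_species,
)
from .curvature import UndefinedCompositionError

#: fixed column schema for delimited peak/amount tables
PEAK_COLUMNS = ["sample_id", "condition", "time_h", "replicate", "species", "area"]
AMOUNT_COLUMNS = ["sample_id", "condition", "time_h", "replicate", "species", "amount_nmol"]


class QuantificationError(ValueError):
    """Missing or zero internal-standard area for a (sample, class)."""


@dataclass
class StandardConfig:
    """Internal-standard panel: class -> (standard species, spiked nmol).

    ``surrogate_map`` routes classes without their own spiked standard to
    the nearest chemically similar standard class.  The spiked amount in
    nmol is a required configuration value (vendor sheets state standards
    as mass concentrations; the molar conversion depends on the exact
    species and is not hard-coded here).
    """

    standards: dict[LipidClass, tuple[LipidSpecies, float]]
    surrogate_map: dict[LipidClass, LipidClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, (sp, nmol) in self.standards.items():
            if nmol <= 0:
                raise ValueError(f"spiked amount for {cls.value} must be > 0")
            if not sp.is_internal_standard:
                raise ValueError(f"standard for {cls.value} is not isotope-labelled: {sp}")

    def resolve(self, lipid_class: LipidClass) -> LipidClass:
        """Class whose spiked standard quantifies ``lipid_class``."""
        if lipid_class in self.standards:
            return lipid_class
        if lipid_class in self.surrogate_map:
            target = self.surrogate_map[lipid_class]
            if target in self.standards:
                return target
        raise QuantificationError(
            f"no internal standard (direct or surrogate) for class {lipid_class.value}"
        )

    def covers(self, classes: Iterable[LipidClass]) -> bool:
        try:
            for c in classes:
                self.resolve(c)
        except QuantificationError:
            return False
        return True


def default_standard_config(spiked_nmol: float = 1.0) -> StandardConfig:
    """A typical deuterated panel (CE, LPC, PC, PE, SM, TAG standards) with
    PC as surrogate for the other glycerophospholipids and TAG for DAG."""
    panel = {
        LipidClass.CE: "CE(C18:0-d6)",
        LipidClass.LPC: "LPC(C14:0-d42)",
        LipidClass.PC: "PC(C16:0-d31/C18:1)",
        LipidClass.PE: "PE(C16:0-d31/C18:1)",
        LipidClass.SM: "SM(C16:0-d31/C18:1)",
        LipidClass.TAG: "TAG(C16:0-d31/C16:0-d31/C16:0-d31)",
    }
    return StandardConfig(
        standards={c: (parse_species(s), spiked_nmol) for c, s in panel.items()},
        surrogate_map={
            LipidClass.PS: LipidClass.PC,
            LipidClass.PI: LipidClass.PC,
            LipidClass.PA: LipidClass.PC,
            LipidClass.PG: LipidClass.PC,
            LipidClass.DAG: LipidClass.TAG,
        },
    )


# ---------------------------------------------------------------------------
# peak table I/O


def read_peak_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a delimited peak table (comma-separated, header row)."""
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df


def write_samples(samples: Sequence[LipidomeSample], path: Union[str, Path]) -> None:
    rows = []
    for s in samples:
        for sp, amt in s.amounts.items():
            rows.append(
                dict(sample_id=s.sample_id, condition=s.condition, time_h=s.time_h,
                     replicate=s.replicate, species=str(sp), amount_nmol=amt)
            )
    pd.DataFrame(rows, columns=AMOUNT_COLUMNS).to_csv(path, index=False)


def read_samples(path: Union[str, Path]) -> list[LipidomeSample]:
    df = pd.read_csv(path)
    out = []
    for (sid, cond, t, rep), grp in df.groupby(
        ["sample_id", "condition", "time_h", "replicate"], sort=False
    ):
        amounts = {
            parse_species(r.species): float(r.amount_nmol) for r in grp.itertuples()
        }
        out.append(LipidomeSample(str(sid), str(cond), float(t), int(rep), amounts))
    return out


# ---------------------------------------------------------------------------
# quantification


def areas_to_amounts(
    peaks: pd.DataFrame, standards: StandardConfig
) -> list[LipidomeSample]:
    """Convert a peak table to absolute amounts.

    amount(analyte) = area(analyte) / area(class standard) * spiked nmol.
    Internal-standard rows are consumed as references and excluded from the
    output amounts.  Raises :class:`QuantificationError` when a needed
    standard is absent or has zero area in a sample.
    """
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    samples: list[LipidomeSample] = []
    for (sid, cond, t, rep), grp in peaks.groupby(
        ["sample_id", "condition", "time_h", "replicate"], sort=False
    ):
        parsed = [(parse_species(str(r.species)), float(r.area)) for r in grp.itertuples()]
        std_areas: dict[LipidClass, float] = {}
        for sp, area in parsed:
            if sp.is_internal_standard:
                std_areas[sp.lipid_class] = area
        amounts: dict[LipidSpecies, float] = {}
        for sp, area in parsed:
            if sp.is_internal_standard:
                continue
            if area < 0:
                raise ValueError(f"negative area for {sp} in sample {sid}")
            std_class = standards.resolve(sp.lipid_class)
            _, spiked = standards.standards[std_class]
            std_area = std_areas.get(std_class, 0.0)
            if std_area <= 0:
                raise QuantificationError(
                    f"sample {sid}: missing or zero {std_class.value} standard area "
                    f"needed for class {sp.lipid_class.value}"
                )
            amounts[sp] = area / std_area * spiked
        samples.append(LipidomeSample(str(sid), str(cond), float(t), int(rep), amounts))
    return samples


# ---------------------------------------------------------------------------
# composition summaries


def class_mol_percent(
    sample: LipidomeSample,
    included_classes: Optional[Iterable[LipidClass]] = None,
) -> dict[LipidClass, float]:
    """Head-group composition as mol% of total included lipid."""
    totals = sample.class_totals()
    if included_classes is not None:
        included = frozenset(included_classes)
        if not included:
            raise UndefinedCompositionError("empty class inclusion set")
        totals = {c: totals.get(c, 0.0) for c in included}
    grand = sum(totals.values())
    if grand <= 0:
        raise UndefinedCompositionError("all included amounts are zero")
    return {c: 100.0 * v / grand for c, v in totals.items()}


def fa_mol_percent(
    sample: LipidomeSample, lipid_class: LipidClass
) -> dict[str, float]:
    """Within-class fatty-acid composition, keyed by sum composition
    (e.g. ``"32:1"``), as mol% of the class total."""
    pool = {
        sp: a for sp, a in sample.biological_amounts().items()
        if sp.lipid_class == lipid_class
    }
    total = sum(pool.values())
    if total <= 0:
        raise UndefinedCompositionError(
            f"class {lipid_class.value} absent or all-zero in sample {sample.sample_id}"
        )
    out: dict[str, float] = {}
    for sp, a in pool.items():
        key = sp.sum_composition
        out[key] = out.get(key, 0.0) + 100.0 * a / total
    return out


def pc_pe_ratio(sample: LipidomeSample) -> float:
    """Total PC amount over total PE amount (dimensionless)."""
    totals = sample.class_totals()
    pe = totals.get(LipidClass.PE, 0.0)
    if pe <= 0:
        raise ZeroDivisionError(
            f"sample {sample.sample_id}: total PE is zero, PC/PE undefined"
        )
    return totals.get(LipidClass.PC, 0.0) / pe
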