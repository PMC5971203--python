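"""Domain types and lipid shorthand nomenclature.

Lipid species are annotated either at sum-composition level ("PE 34:1":
total acyl carbons and double bonds) or with explicit acyl chains
("PC(C16:0-d31/C18:1)").  Most LC-MS lipidomics reports only the sum
composition, while the biophysical models downstream (spontaneous-curvature
lookup, coarse-grained w weights) are formulated per chain, so this module
also carries the machinery to resolve a sum composition into a deterministic
per-chain split.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence


class ParseError(ValueError):
    """A lipid name that does not conform to the accepted grammar."""


class UnresolvedAssignmentError(KeyError):
    """A sum-composition species whose acyl chains cannot be resolved."""


class LipidClass(str, enum.Enum):
    """Closed enumeration of head-group classes handled by the pipeline.

    Unknown class codes fail loudly at parse time rather than being
    silently dropped, because a dropped species would bias every mol%
    denominator computed later.
    """

    PC = "PC"
    PE = "PE"
    PS = "PS"
    PI = "PI"
    PA = "PA"
    PG = "PG"
    DAG = "DAG"
    TAG = "TAG"
    CE = "CE"
    LPC = "LPC"
    SM = "SM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: number of acyl chains carried by each class
N_CHAINS: dict[LipidClass, int] = {
    LipidClass.PC: 2,
    LipidClass.PE: 2,
    LipidClass.PS: 2,
    LipidClass.PI: 2,
    LipidClass.PA: 2,
    LipidClass.PG: 2,
    LipidClass.DAG: 2,
    LipidClass.SM: 2,
    LipidClass.TAG: 3,
    LipidClass.CE: 1,
    LipidClass.LPC: 1,
}


class AcylChain(NamedTuple):
    carbons: int
    double_bonds: int
    isotope_label: Optional[str] = None  # e.g. "d31" for a deuterated chain

    def __str__(self) -> str:
        s = f"C{self.carbons}:{self.double_bonds}"
        if self.isotope_label:
            s += f"-{self.isotope_label}"
        return s


@dataclass(frozen=True)
class LipidSpecies:
    """One annotated lipid species.

    ``chains`` is ``None`` for a sum-composition annotation.  A species is
    an internal standard when any of its chains carries an isotope label;
    such species are quantification references only and are excluded from
    every biology-facing composition.
    """

    lipid_class: LipidClass
    total_carbons: int
    total_double_bonds: int
    chains: Optional[tuple[AcylChain, ...]] = None
    is_internal_standard: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.lipid_class, LipidClass):
            raise ParseError(f"unknown lipid class: {self.lipid_class!r}")
        if self.total_carbons <= 0:
            raise ValueError(f"total_carbons must be > 0, got {self.total_carbons}")
        if self.total_double_bonds < 0:
            raise ValueError(
                f"total_double_bonds must be >= 0, got {self.total_double_bonds}"
            )
        if self.chains is not None:
            object.__setattr__(self, "chains", tuple(AcylChain(*c) for c in self.chains))
            c_sum = sum(c.carbons for c in self.chains)
            d_sum = sum(c.double_bonds for c in self.chains)
            if c_sum != self.total_carbons or d_sum != self.total_double_bonds:
                raise ValueError(
                    f"chain sums ({c_sum}:{d_sum}) do not match totals "
                    f"({self.total_carbons}:{self.total_double_bonds})"
                )
            if any(c.isotope_label for c in self.chains) and not self.is_internal_standard:
                object.__setattr__(self, "is_internal_standard", True)

    # -- accessors ---------------------------------------------------------

    @property
    def sum_composition(self) -> str:
        """The ``C:D`` sum-composition string, e.g. ``"34:1"``."""
        return f"{self.total_carbons}:{self.total_double_bonds}"

    def without_chains(self) -> "LipidSpecies":
        return LipidSpecies(
            self.lipid_class,
            self.total_carbons,
            self.total_double_bonds,
            chains=None,
            is_internal_standard=self.is_internal_standard,
        )

    def chain_double_bond_multiset(self) -> tuple[int, ...]:
        """Sorted per-chain double-bond counts; requires chains."""
        if self.chains is None:
            raise ValueError(f"{self} has no chain assignment")
        return tuple(sorted(c.double_bonds for c in self.chains))

    def __str__(self) -> str:
        return format_species(self)


def format_species(species: LipidSpecies) -> str:
    """Inverse of :func:`parse_species`."""
    cls = species.lipid_class.value
    if species.chains is None:
        return f"{cls} {species.sum_composition}"
    return f"{cls}({'/'.join(str(c) for c in species.chains)})"


_SUM_RE = re.compile(
    r"^(?P<cls>[A-Za-z]+)\s*[\s(]\s*(?P<c>\d+):(?P<d>\d+)\s*\)?$"
)
_CHAIN_RE = re.compile(
    r"^C?(?P<c>\d+):(?P<d>\d+)(?:-(?P<label>d\d+))?$"
)


def parse_species(text: str) -> LipidSpecies:
    """Parse a shorthand lipid name.

    Accepted forms::

        PE 32:1            sum composition
        PE(32:1)           sum composition
        PC(C16:0-d31/C18:1)    explicit chains, optional isotope suffix
        TAG(16:0/16:1/18:1)    explicit chains, three for TAG

    A single ``C:D`` pair inside parentheses is read as a sum composition
    unless it is written with a leading ``C`` or carries an isotope suffix
    (then it is an explicit single chain, as for LPC/CE standards).
    """
    text = text.strip()
    m = re.match(r"^(?P<cls>[A-Za-z]+)\s*\(\s*(?P<body>[^)]+)\s*\)$", text)
    if m and ("/" in m.group("body") or m.group("body").lstrip().startswith("C")
              or "-d" in m.group("body")):
        cls = _parse_class(m.group("cls"), text)
        chains = []
        for part in m.group("body").split("/"):
            cm = _CHAIN_RE.match(part.strip())
            if not cm:
                raise ParseError(f"cannot parse acyl chain {part.strip()!r} in {text!r}")
            chains.append(
                AcylChain(int(cm.group("c")), int(cm.group("d")), cm.group("label"))
            )
        expected = N_CHAINS[cls]
        if len(chains) != expected:
            raise ParseError(
                f"{cls.value} requires {expected} chains, got {len(chains)} in {text!r}"
            )
        return LipidSpecies(
            cls,
            sum(c.carbons for c in chains),
            sum(c.double_bonds for c in chains),
            chains=tuple(chains),
        )
    m = _SUM_RE.match(text)
    if not m:
        raise ParseError(f"cannot parse lipid name {text!r}")
    cls = _parse_class(m.group("cls"), text)
    return LipidSpecies(cls, int(m.group("c")), int(m.group("d")))


def _parse_class(code: str, context: str) -> LipidClass:
    try:
        return LipidClass(code.upper())
    except ValueError:
        raise ParseError(f"unknown lipid class {code!r} in {context!r}") from None


# ---------------------------------------------------------------------------
# chain assignment


@dataclass
class ChainAssignmentTable:
    """Maps (class, total carbons, total double bonds) to a per-chain split.

    Measured species are sum compositions; the curvature and w models need
    per-chain unsaturation.  Explicit entries take precedence; a deterministic
    default rule covers the rest: carbons are split as evenly as possible in
    steps of two (two chains: 32 -> 16/16, 34 -> 16/18; three chains for TAG),
    and double bonds are distributed as evenly as possible with the remainder
    on the longer chain (34:1 -> 16:0/18:1, 32:2 -> 16:1/16:1).  The shipped
    default favours the common yeast acyls 16:0, 16:1, 18:0, 18:1.
    """

    entries: dict[tuple[LipidClass, int, int], tuple[tuple[int, int], ...]] = field(
        default_factory=dict
    )
    use_default_rule: bool = True

    def __post_init__(self) -> None:
        for (cls, c, d), chains in self.entries.items():
            if sum(x[0] for x in chains) != c or sum(x[1] for x in chains) != d:
                raise ValueError(
                    f"assignment for {cls.value} {c}:{d} sums to "
                    f"{sum(x[0] for x in chains)}:{sum(x[1] for x in chains)}"
                )

    def lookup(self, species: LipidSpecies) -> tuple[tuple[int, int], ...]:
        key = (species.lipid_class, species.total_carbons, species.total_double_bonds)
        if key in self.entries:
            return self.entries[key]
        if self.use_default_rule:
            return _default_split(
                N_CHAINS[species.lipid_class],
                species.total_carbons,
                species.total_double_bonds,
            )
        raise UnresolvedAssignmentError(
            f"no chain assignment for {species} and default rule disabled"
        )


def _default_split(n_chains: int, carbons: int, double_bonds: int) -> tuple[tuple[int, int], ...]:
    # carbons: near-even split in steps of 2, shorter chains first
    base = carbons // n_chains
    if base % 2:
        base -= 1
    cs = [base] * n_chains
    i = n_chains - 1
    while sum(cs) + 2 <= carbons:
        cs[i] += 2
        i = (i - 1) if i > 0 else n_chains - 1
    cs[0] += carbons - sum(cs)  # odd-carbon remainder, rare
    cs.sort()
    # double bonds: even split, remainder to the longest chains
    ds = [double_bonds // n_chains] * n_chains
    for j in range(double_bonds % n_chains):
        ds[n_chains - 1 - j] += 1
    return tuple(zip(cs, ds))


def assign_chains(
    species: LipidSpecies, table: Optional[ChainAssignmentTable] = None
) -> LipidSpecies:
    """Return ``species`` with chains populated; identity if already assigned."""
    if species.chains is not None:
        return species
    table = table if table is not None else DEFAULT_CHAIN_TABLE
    split = table.lookup(species)
    return LipidSpecies(
        species.lipid_class,
        species.total_carbons,
        species.total_double_bonds,
        chains=tuple(AcylChain(c, d) for c, d in split),
        is_internal_standard=species.is_internal_standard,
    )


#: default yeast-oriented table; the default rule already produces the common
#: pairs (32:1 -> 16:0/16:1, 34:2 -> 16:1/18:1), explicit entries pin the
#: conventional reading where the rule is ambiguous in principle.
DEFAULT_CHAIN_TABLE = ChainAssignmentTable(
    entries={
        (LipidClass.PE, 34, 1): ((16, 0), (18, 1)),
        (LipidClass.PC, 34, 1): ((16, 0), (18, 1)),
        (LipidClass.PS, 34, 1): ((16, 0), (18, 1)),
    }
)


# ---------------------------------------------------------------------------
# samples


@dataclass
class LipidomeSample:
    """Per-sample absolute lipid amounts plus acquisition metadata.

    Amounts are nmol per 50 mg biomass (relative to class-matched internal
    standards).  ``(condition, time_h, replicate)`` identifies a sample
    within a dataset.
    """

    sample_id: str
    condition: str
    time_h: float
    replicate: int
    amounts: dict[LipidSpecies, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"time_h must be >= 0, got {self.time_h}")
        for sp, amt in self.amounts.items():
            if not (amt >= 0) or amt != amt or amt in (float("inf"),):
                raise ValueError(f"amount for {sp} must be finite and >= 0, got {amt}")

    def biological_amounts(self) -> dict[LipidSpecies, float]:
        """Amounts excluding internal-standard species."""
        return {
            sp: a for sp, a in self.amounts.items() if not sp.is_internal_standard
        }

    def class_totals(self) -> dict[LipidClass, float]:
        out: dict[LipidClass, float] = {}
        for sp, a in self.biological_amounts().items():
            out[sp.lipid_class] = out.get(sp.lipid_class, 0.0) + a
        return out

    @property
    def key(self) -> tuple[str, float, int]:
        return (self.condition, self.time_h, self.replicate)


def check_unique_samples(samples: Iterable[LipidomeSample]) -> None:
    seen: set[tuple[str, float, int]] = set()
    for s in samples:
        if s.key in seen:
            raise ValueError(f"duplicate sample key {s.key}")
        seen.add(s.key)
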