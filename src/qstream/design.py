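"""Breeding designs and stocking plans for multi-population common-garden experiments.

Two designs are supported, mirroring the two standard salmonid breeding
schemes used in stream-stocking experiments:

* **Unique-pair full-sib design** (experiment 1): each dam is mated to a
  unique sire from the same population, so every parent appears in exactly
  one cross and family variance contains half the additive variance plus
  non-additive and maternal terms.
* **Incomplete 2x2 diallel** (experiment 2): blocks of two dams crossed with
  the same two sires (four full-sib families per block), which lets sire and
  dam variance components be separated downstream.  Irregular blocks (extra
  unique-pair families appended after the complete matrices) are declared
  explicitly in the population spec rather than inferred.

Eggs from each cross are then allocated to one or more rearing streams by a
:class:`StockingPlan`; a cross may be excluded from individual streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PopulationSpec",
    "Cross",
    "BreedingDesign",
    "StockingPlan",
    "build_design",
    "build_stocking",
    "attach_parents",
    "experiment1_populations",
    "experiment2_populations",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Breeding-effort specification for one source population.

    Exactly one of ``n_pairs`` (unique-pair design) or ``n_diallel_matrices``
    (2x2 diallel design) is used, depending on the experiment.
    ``n_extra_pairs`` appends irregular unique-pair families after the
    complete diallel matrices (e.g. a population where only four complete
    matrices plus two extra maternal families could be produced).
    """

    name: str
    n_pairs: int = 0
    n_diallel_matrices: int = 0
    n_extra_pairs: int = 0
    origin_class: str = "wild"

    def __post_init__(self) -> None:
        if min(self.n_pairs, self.n_diallel_matrices, self.n_extra_pairs) < 0:
            raise ValueError(f"negative count in population spec {self.name!r}")
        if self.origin_class not in ("hatchery", "wild"):
            raise ValueError(
                f"origin_class must be 'hatchery' or 'wild', got {self.origin_class!r}"
            )


@dataclass(frozen=True)
class Cross:
    """A single full-sib family: one dam fertilized by one sire.

    Matings are strictly within population; the constructor enforces that the
    parent labels carry the same population prefix as the cross.
    """

    cross_id: str
    sire_id: str
    dam_id: str
    population: str


@dataclass(frozen=True)
class BreedingDesign:
    """All crosses of one experiment, with their population specifications."""

    experiment: int
    populations: tuple[PopulationSpec, ...]
    crosses: tuple[Cross, ...]

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    def cross_ids(self) -> list[str]:
        return [c.cross_id for c in self.crosses]

    def parents_of(self, cross_id: str) -> tuple[str, str]:
        """Return ``(sire_id, dam_id)`` for a cross."""
        for c in self.crosses:
            if c.cross_id == cross_id:
                return c.sire_id, c.dam_id
        raise KeyError(cross_id)


@dataclass(frozen=True)
class StockingPlan:
    """Egg allocations: which cross goes into which stream, and how many eggs."""

    entries: tuple[tuple[str, str, int], ...]  # (cross_id, stream, n_eggs)

    @property
    def streams(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, stream, _ in self.entries:
            seen.setdefault(stream)
        return list(seen)

    def total_eggs(self, stream: str | None = None) -> int:
        return sum(n for _, s, n in self.entries if stream is None or s == stream)

    def entries_for(self, stream: str) -> list[tuple[str, int]]:
        return [(cid, n) for cid, s, n in self.entries if s == stream]


def _label(pop: str, kind: str, i: int) -> str:
    return f"{pop}-{kind}{i:02d}"


def build_design(
    population_specs: list[PopulationSpec] | tuple[PopulationSpec, ...],
    experiment: int,
    seed: int = 0,
) -> BreedingDesign:
    """Construct the full set of crosses implied by per-population specs.

    Experiment 1 interprets ``n_pairs``: each pair is one dam mated to one
    unique sire, so total crosses equal the sum of pair counts.  Experiment 2
    interprets ``n_diallel_matrices``: each complete 2x2 matrix contributes
    two sires x two dams = four crosses, each parent appearing exactly twice;
    ``n_extra_pairs`` adds irregular unique-pair crosses with fresh parents.

    Labels are deterministic functions of the spec (``POP-S01`` sires,
    ``POP-D01`` dams, ``POP-X01`` crosses); ``seed`` is accepted for interface
    stability but the construction is fully deterministic.
    """
    if experiment not in (1, 2):
        raise ValueError(f"experiment must be 1 or 2, got {experiment}")
    names = [p.name for p in population_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate population names in design spec")

    crosses: list[Cross] = []
    for spec in population_specs:
        pop = spec.name
        x = 0  # cross counter within population
        if experiment == 1:
            for i in range(1, spec.n_pairs + 1):
                x += 1
                crosses.append(
                    Cross(
                        cross_id=_label(pop, "X", x),
                        sire_id=_label(pop, "S", i),
                        dam_id=_label(pop, "D", i),
                        population=pop,
                    )
                )
        else:
            parent = 0
            for _block in range(spec.n_diallel_matrices):
                sires = [_label(pop, "S", parent + 1), _label(pop, "S", parent + 2)]
                dams = [_label(pop, "D", parent + 1), _label(pop, "D", parent + 2)]
                parent += 2
                for s in sires:
                    for d in dams:
                        x += 1
                        crosses.append(Cross(_label(pop, "X", x), s, d, pop))
            for _ in range(spec.n_extra_pairs):
                parent += 1
                x += 1
                crosses.append(
                    Cross(
                        _label(pop, "X", x),
                        _label(pop, "S", parent),
                        _label(pop, "D", parent),
                        pop,
                    )
                )
    return BreedingDesign(
        experiment=experiment,
        populations=tuple(population_specs),
        crosses=tuple(crosses),
    )


def build_stocking(
    design: BreedingDesign,
    allocation: dict[str, int | dict[str, int]],
    exclude: dict[str, list[str]] | None = None,
) -> StockingPlan:
    """Allocate eggs from each cross to each stream.

    ``allocation`` maps stream name to either a constant eggs-per-cross count
    or an explicit ``{cross_id: n_eggs}`` table (crosses absent from an
    explicit table are simply not stocked there).  ``exclude`` lists crosses
    to drop per stream, e.g. families whose egg counts were too low to stock
    everywhere.
    """
    exclude = exclude or {}
    known = set(design.cross_ids())
    for stream, dropped in exclude.items():
        if stream not in allocation:
            raise KeyError(f"exclusion references unknown stream {stream!r}")
        for cid in dropped:
            if cid not in known:
                raise KeyError(f"exclusion references unknown cross {cid!r}")

    entries: list[tuple[str, str, int]] = []
    for stream, rule in allocation.items():
        dropped = set(exclude.get(stream, []))
        if isinstance(rule, dict):
            for cid, n in rule.items():
                if cid not in known:
                    raise KeyError(f"allocation references unknown cross {cid!r}")
                if n < 0:
                    raise ValueError(f"negative egg count for cross {cid!r}")
                if cid not in dropped:
                    entries.append((cid, stream, int(n)))
        else:
            if rule < 0:
                raise ValueError(f"negative egg count for stream {stream!r}")
            for cid in design.cross_ids():
                if cid not in dropped:
                    entries.append((cid, stream, int(rule)))
    return StockingPlan(entries=tuple(entries))


def attach_parents(table, design: BreedingDesign):
    """Add ``sire_id`` and ``dam_id`` columns to a phenotype table.

    Needed for diallel (sire/dam) mixed models, where parent identity is a
    random-effect factor but phenotype records only carry the cross label.
    Returns a copy; unknown cross ids raise ``KeyError``.
    """
    mapping = {c.cross_id: (c.sire_id, c.dam_id) for c in design.crosses}
    unknown = set(table["cross_id"]) - set(mapping)
    if unknown:
        raise KeyError(f"crosses absent from design: {sorted(unknown)[:5]}")
    out = table.copy()
    out["sire_id"] = [mapping[c][0] for c in table["cross_id"]]
    out["dam_id"] = [mapping[c][1] for c in table["cross_id"]]
    return out


def experiment1_populations() -> list[PopulationSpec]:
    """The five-population unique-pair breeding effort of the first year.

    Two hatchery lines and one wild population contributed 12 pairs each,
    the remaining two wild-caught efforts 11 and 10 pairs (57 families).
    """
    return [
        PopulationSpec("DAL2", n_pairs=12, origin_class="hatchery"),
        PopulationSpec("DAL8", n_pairs=12, origin_class="hatchery"),
        PopulationSpec("NOR", n_pairs=12, origin_class="wild"),
        PopulationSpec("AVA", n_pairs=11, origin_class="hatchery"),
        PopulationSpec("JOR", n_pairs=10, origin_class="wild"),
    ]


def experiment2_populations() -> list[PopulationSpec]:
    """The four-population incomplete-diallel effort of the second year.

    Six complete 2x2 matrices per population (24 crosses), except one
    population with four complete matrices plus two irregular maternal
    families (18 crosses), for 90 families in total.
    """
    return [
        PopulationSpec("DAL8", n_diallel_matrices=6, origin_class="hatchery"),
        PopulationSpec("AVA", n_diallel_matrices=6, origin_class="hatchery"),
        PopulationSpec("JOR", n_diallel_matrices=6, origin_class="wild"),
        PopulationSpec("KAV", n_diallel_matrices=4, n_extra_pairs=2, origin_class="wild"),
    ]
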