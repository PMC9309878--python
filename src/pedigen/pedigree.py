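"""Pedigree data model for inbred crop breeding programs.

A breeding program is represented as a directed acyclic graph of cultivars.
Every cultivar is either a *terminal ancestor* (a landrace or line whose own
parentage cannot be traced further) or carries exactly one breeding event:
a cross between two distinct parents, or a single-source derivation
(pure-line selection or mutation).  All lines are assumed homozygous and
homogeneous, so a pedigree edge transmits whole (inbred) genomes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "Ecoregion",
    "Period",
    "BreedingMethod",
    "CultivarRecord",
    "PedigreeGraph",
    "PedigreeError",
    "PedigreeSchemaError",
    "PedigreeStructureError",
    "read_pedigree",
    "write_pedigree",
    "write_edge_list",
]

MISSING = "."  # placeholder for an absent parent in the TSV dialect

PEDIGREE_COLUMNS = ("id", "name", "method", "female_or_source", "male", "ecoregion", "period")


class PedigreeError(Exception):
    """Base class for pedigree validation problems."""


class PedigreeSchemaError(PedigreeError):
    """A row violates the declared file schema (bad method, parent slots...)."""


class PedigreeStructureError(PedigreeError):
    """The assembled graph is structurally invalid (cycle, dangling id)."""


class Ecoregion(str, enum.Enum):
    NNC = "NNC"  # Northeast & Northwest China, single-cropping spring soybean
    HHH = "HHH"  # Huang-Huai-Hai valleys, double-cropping
    SC = "SC"  # Southern China, multi-cropping
    FOREIGN = "FOREIGN"
    UNKNOWN = "UNKNOWN"


class Period(str, enum.Enum):
    P1923_2005 = "P1923_2005"
    P2006_2015 = "P2006_2015"
    UNKNOWN = "UNKNOWN"


class BreedingMethod(str, enum.Enum):
    CROSS = "CROSS"
    SELECTION = "SELECTION"
    MUTATION = "MUTATION"
    TERMINAL = "TERMINAL"


# raw method strings accepted in files; "introduction" carries full-weight
# single-source transmission, so it maps onto SELECTION for all computations
_METHOD_ALIASES = {
    "cross": BreedingMethod.CROSS,
    "selection": BreedingMethod.SELECTION,
    "mutation": BreedingMethod.MUTATION,
    "terminal": BreedingMethod.TERMINAL,
    "introduction": BreedingMethod.SELECTION,
}


@dataclass(frozen=True)
class CultivarRecord:
    """One cultivar/line with its breeding event and passport metadata."""

    id: str
    name: str = ""
    method: BreedingMethod = BreedingMethod.TERMINAL
    female_or_source: str | None = None
    male: str | None = None
    ecoregion: Ecoregion = Ecoregion.UNKNOWN
    period: Period = Period.UNKNOWN
    # file-level label, e.g. "introduction"; presentation only, not identity
    raw_method: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        # accept plain strings for the enum-valued fields
        for attr, cls in (
            ("method", BreedingMethod),
            ("ecoregion", Ecoregion),
            ("period", Period),
        ):
            v = getattr(self, attr)
            if not isinstance(v, cls):
                object.__setattr__(self, attr, cls(str(v).upper()))
        if not self.id:
            raise PedigreeSchemaError("cultivar id must be nonempty")
        m = self.method
        if m is BreedingMethod.CROSS:
            if not (self.female_or_source and self.male):
                raise PedigreeSchemaError(
                    f"{self.id!r}: a cross needs both a female and a male parent"
                )
            if self.female_or_source == self.male:
                raise PedigreeSchemaError(
                    f"{self.id!r}: selfing of a single line is not a breeding event"
                )
        elif m in (BreedingMethod.SELECTION, BreedingMethod.MUTATION):
            if not self.female_or_source or self.male:
                raise PedigreeSchemaError(
                    f"{self.id!r}: {m.value} needs exactly one source parent"
                )
        else:  # TERMINAL
            if self.female_or_source or self.male:
                raise PedigreeSchemaError(f"{self.id!r}: a terminal record has no parents")

    @property
    def parents(self) -> tuple[str, ...]:
        if self.method is BreedingMethod.CROSS:
            return (self.female_or_source, self.male)  # type: ignore[return-value]
        if self.female_or_source:
            return (self.female_or_source,)
        return ()

    @property
    def is_terminal(self) -> bool:
        return self.method is BreedingMethod.TERMINAL


class PedigreeGraph:
    """Directed acyclic graph of cultivars (edges run parent -> child)."""

    def __init__(self, records: Iterable[CultivarRecord] = ()) -> None:
        self._records: dict[str, CultivarRecord] = {}
        self._g = nx.DiGraph()
        self._invalidate_caches()
        for rec in records:
            self.add_record(rec, validate=False)
        self.validate()

    # -- construction -------------------------------------------------

    def add_record(self, rec: CultivarRecord, validate: bool = True) -> None:
        if rec.id in self._records:
            raise PedigreeSchemaError(f"duplicate cultivar id {rec.id!r}")
        self._records[rec.id] = rec
        self._g.add_node(rec.id)
        for p in rec.parents:
            self._g.add_edge(p, rec.id)
        self._invalidate_caches()
        if validate:
            self.validate()

    def validate(self) -> None:
        for node in self._g.nodes:
            if node not in self._records:
                raise PedigreeStructureError(f"parent id {node!r} has no record")
        try:
            cycle = nx.find_cycle(self._g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise PedigreeStructureError(f"pedigree contains a cycle: {path}")

    def _invalidate_caches(self) -> None:
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._term_cache: dict[str, frozenset[str]] = {}

    # -- basic queries -------------------------------------------------

    def __contains__(self, cultivar: str) -> bool:
        return cultivar in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PedigreeGraph):
            return NotImplemented
        return self._records == other._records

    def record(self, cultivar: str) -> CultivarRecord:
        try:
            return self._records[cultivar]
        except KeyError:
            raise KeyError(f"unknown cultivar id {cultivar!r}") from None

    @property
    def records(self) -> Mapping[str, CultivarRecord]:
        return dict(self._records)

    def parents(self, cultivar: str) -> tuple[str, ...]:
        return self.record(cultivar).parents

    def children(self, cultivar: str) -> tuple[str, ...]:
        self.record(cultivar)
        return tuple(sorted(self._g.successors(cultivar)))

    def is_terminal(self, cultivar: str) -> bool:
        return self.record(cultivar).is_terminal

    def terminal_records(self) -> list[str]:
        return sorted(i for i, r in self._records.items() if r.is_terminal)

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._g))

    # -- traversal -----------------------------------------------------

    def ancestors(self, cultivar: str) -> frozenset[str]:
        """All strict ancestors of ``cultivar`` (excluding itself)."""
        if cultivar not in self._anc_cache:
            self.record(cultivar)
            acc: set[str] = set()
            for p in self.parents(cultivar):
                acc.add(p)
                acc |= self.ancestors(p)
            self._anc_cache[cultivar] = frozenset(acc)
        return self._anc_cache[cultivar]

    def terminal_ancestors(self, cultivar: str) -> frozenset[str]:
        """Parentless records reachable upward; a terminal maps to itself."""
        if cultivar not in self._term_cache:
            rec = self.record(cultivar)
            if rec.is_terminal:
                out = frozenset({cultivar})
            else:
                out = frozenset().union(
                    *(self.terminal_ancestors(p) for p in rec.parents)
                )
            self._term_cache[cultivar] = out
        return self._term_cache[cultivar]

    def derived_cultivars(self, ancestor: str, universe: Iterable[str]) -> frozenset[str]:
        """Members of ``universe`` whose terminal-ancestor set contains ``ancestor``."""
        self.record(ancestor)
        return frozenset(c for c in universe if ancestor in self.terminal_ancestors(c))

    def breeding_cycles(self, ancestor: str, cultivar: str) -> int:
        """Maximum number of crosses on any pedigree path ancestor -> cultivar.

        Selection and mutation edges are traversed but add no cycle: a cycle
        is one round of recombination.  The maximum over routes is used since
        an ancestor can reach a cultivar through several paths.
        """
        self.record(ancestor)
        if ancestor != cultivar and ancestor not in self.ancestors(cultivar):
            raise ValueError(f"{ancestor!r} is not an ancestor of {cultivar!r}")

        memo: dict[str, int] = {}

        def best(node: str) -> int:
            # max crosses from `ancestor` down to `node`; -1 if unreachable
            if node == ancestor:
                return 0
            if node in memo:
                return memo[node]
            rec = self._records[node]
            step = 1 if rec.method is BreedingMethod.CROSS else 0
            cands = [
                best(p) + step
                for p in rec.parents
                if p == ancestor or ancestor in self.ancestors(p)
            ]
            memo[node] = max(cands) if cands else -1
            return memo[node]

        return best(cultivar)


# ---------------------------------------------------------------------------
# file I/O — UTF-8, tab-separated, header row, "." marks an absent parent
# ---------------------------------------------------------------------------


def _parse_enum(cls, value: str, default):
    value = value.strip()
    if not value or value == MISSING:
        return default
    try:
        return cls(value.upper())
    except ValueError:
        raise PedigreeSchemaError(f"unknown {cls.__name__} value {value!r}") from None


def read_pedigree(path: str | Path) -> PedigreeGraph:
    """Read a pedigree TSV into a validated :class:`PedigreeGraph`.

    Columns (in order): id, name, method, female_or_source, male, ecoregion,
    period.  Parents referenced but never declared are auto-created as
    terminal records with UNKNOWN metadata.
    """
    path = Path(path)
    records: list[CultivarRecord] = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise PedigreeSchemaError(f"{path}: empty file, header row required")
        cols = tuple(header.rstrip("\n").split("\t"))
        if cols != PEDIGREE_COLUMNS:
            raise PedigreeSchemaError(
                f"{path}: header {cols!r} does not match {PEDIGREE_COLUMNS!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(PEDIGREE_COLUMNS):
                raise PedigreeSchemaError(
                    f"{path}:{lineno}: expected {len(PEDIGREE_COLUMNS)} fields, got {len(parts)}"
                )
            cid, name, method_s, female, male, eco_s, period_s = (p.strip() for p in parts)
            try:
                method = _METHOD_ALIASES[method_s.lower()]
            except KeyError:
                raise PedigreeSchemaError(
                    f"{path}:{lineno}: unknown breeding method {method_s!r}"
                ) from None
            try:
                rec = CultivarRecord(
                    id=cid,
                    name=name or cid,
                    method=method,
                    female_or_source=None if female in ("", MISSING) else female,
                    male=None if male in ("", MISSING) else male,
                    ecoregion=_parse_enum(Ecoregion, eco_s, Ecoregion.UNKNOWN),
                    period=_parse_enum(Period, period_s, Period.UNKNOWN),
                    raw_method=method_s,
                )
            except PedigreeSchemaError as err:
                raise PedigreeSchemaError(f"{path}:{lineno}: {err}") from None
            records.append(rec)

    declared = {r.id for r in records}
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise PedigreeSchemaError(f"{path}: duplicate child id {rec.id!r}")
        seen.add(rec.id)
    # referenced-but-undeclared parents become anonymous terminal ancestors
    auto = sorted(
        {p for r in records for p in r.parents if p not in declared}
    )
    records.extend(CultivarRecord(id=p, name=p) for p in auto)
    return PedigreeGraph(records)


def write_pedigree(graph: PedigreeGraph, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(PEDIGREE_COLUMNS) + "\n")
        for cid in sorted(graph.records):
            r = graph.record(cid)
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.name,
                        (r.raw_method or r.method.value).lower(),
                        r.female_or_source or MISSING,
                        r.male or MISSING,
                        r.ecoregion.value,
                        r.period.value,
                    ]
                )
                + "\n"
            )


def write_edge_list(graph: PedigreeGraph, path: str | Path) -> None:
    """Parent->child edge list TSV for visualization tools."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("parent\tchild\trole\tmethod\n")
        for cid in sorted(graph.records):
            r = graph.record(cid)
            if r.method is BreedingMethod.CROSS:
                fh.write(f"{r.female_or_source}\t{cid}\tfemale\tcross\n")
                fh.write(f"{r.male}\t{cid}\tmale\tcross\n")
            elif r.female_or_source:
                fh.write(f"{r.female_or_source}\t{cid}\tsource\t{r.method.value.lower()}\n")
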