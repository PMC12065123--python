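"""Ontological character dependencies: annotation parsing, graph building,
automated scoring enforcement, and xlinks-style command emission.

The model is the negative downstream dependency (DSD): when a controlling
character shows a non-enabling state, its dependents are inapplicable (or, for
single-state dependencies, the listed dependent states become unavailable).
A character with several controllers is applicable only when ALL of them are
enabling (nested encaptic structure).  Serial-homologue blocks mark runs of
positionally ordered characters that may transform jointly at a discounted
combined step cost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .matrix_io import (
    INAPPLICABLE,
    MISSING,
    CellValue,
    Character,
    CharacterMatrix,
)


@dataclass(frozen=True)
class DependencyLink:
    """controller state(s) enable the dependent; otherwise the dependent (or
    just ``dependent_states`` when given) is unavailable."""

    controller: int
    enabling_states: FrozenSet[int]
    dependent: int
    dependent_states: Optional[FrozenSet[int]] = None  # None == whole character

    def __post_init__(self) -> None:
        if self.controller == self.dependent:
            raise ValueError("a character cannot control itself")
        if not self.enabling_states:
            raise ValueError("enabling state set must be non-empty")


@dataclass(frozen=True)
class SerialBlock:
    """An anterior-to-posterior ordered run of serially homologous characters.

    ``concurrency_discount`` is the per-extra-position cost factor for
    simultaneous homomorph transformations (default 1/10, matching a ten-fold
    upweighted matrix where each extra concurrent change costs one raw step).
    ``streak_constrained`` restricts reconstructions to contiguous runs.
    """

    members: Tuple[int, ...]
    streak_constrained: bool = False
    concurrency_discount: Fraction = Fraction(1, 10)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("serial block members must be pairwise distinct")
        if not (0 < self.concurrency_discount <= 1):
            raise ValueError("concurrency discount must be in (0, 1]")


class DependencyCycleError(ValueError):
    def __init__(self, cycle: Sequence[int]) -> None:
        self.cycle = list(cycle)
        super().__init__(
            "dependency cycle: " + " -> ".join(str(c + 1) for c in self.cycle)
        )


@dataclass
class DependencyGraph:
    links: List[DependencyLink] = field(default_factory=list)
    serial_blocks: List[SerialBlock] = field(default_factory=list)

    def controllers_of(self, dependent: int) -> List[DependencyLink]:
        return [l for l in self.links if l.dependent == dependent]

    def full_controllers_of(self, dependent: int) -> List[DependencyLink]:
        return [
            l
            for l in self.links
            if l.dependent == dependent and l.dependent_states is None
        ]

    def participating_characters(self) -> Set[int]:
        out: Set[int] = set()
        for l in self.links:
            out.add(l.controller)
            out.add(l.dependent)
        for b in self.serial_blocks:
            out.update(b.members)
        return out

    def validate(self, characters: Optional[Sequence[Character]] = None) -> None:
        g = nx.DiGraph()
        for l in self.links:
            g.add_edge(l.controller, l.dependent)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise DependencyCycleError([u for u, _ in cycle])
        if characters is not None:
            n = len(characters)
            for l in self.links:
                for idx in (l.controller, l.dependent):
                    if not 0 <= idx < n:
                        raise ValueError(
                            f"link references character {idx + 1} outside the matrix"
                        )
                bad = l.enabling_states - set(characters[l.controller].state_codes)
                if bad:
                    raise ValueError(
                        f"enabling states {sorted(bad)} not valid for character"
                        f" {l.controller + 1}"
                    )
            for b in self.serial_blocks:
                codes = {characters[i].state_codes for i in b.members}
                if len(codes) != 1:
                    raise ValueError(
                        "serial block members must share one state-code set: "
                        f"{[i + 1 for i in b.members]}"
                    )
        # overlapping blocks sharing a member must agree on that member's role
        seen: Dict[int, SerialBlock] = {}
        for b in self.serial_blocks:
            for i in b.members:
                if i in seen and characters is not None:
                    if characters[i].state_codes not in {
                        characters[j].state_codes for j in seen[i].members
                    }:
                        raise ValueError(
                            f"character {i + 1} shared by serial blocks with"
                            " conflicting state sets"
                        )
                seen[i] = b


# ---------------------------------------------------------------------------
# Annotation grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationGrammar:
    """Configurable grammar for dependency prefixes on character statements.

    The default token is ``[C.S>this]``: this character is applicable only
    when (1-based) character C shows one of the comma-separated states S.  A
    single-state dependency adds the restricted dependent states after
    ``this``: ``[C.S>this.D]``.  Several tokens may be stacked; all must
    enable for the character to apply.
    """

    token_pattern: str = (
        r"\[\s*(?P<ctrl>\d+)\s*\.\s*(?P<states>\d+(?:\s*,\s*\d+)*)\s*>\s*this"
        r"(?:\s*\.\s*(?P<dstates>\d+(?:\s*,\s*\d+)*))?\s*\]"
    )
    token_template: str = "[{controller}.{states}>this{dsuffix}]"

    def compiled(self) -> "re.Pattern[str]":
        return re.compile(self.token_pattern)


DEFAULT_GRAMMAR = AnnotationGrammar()


def parse_dependency_annotation(
    statement: str,
    dependent: int,
    grammar: AnnotationGrammar = DEFAULT_GRAMMAR,
    characters: Optional[Sequence[Character]] = None,
) -> List[DependencyLink]:
    """Extract the dependency links declared at the start of a statement.

    Character numbers in annotations are 1-based; returned links are 0-based.
    A statement with no leading annotation yields an empty list.
    """
    pat = grammar.compiled()
    links: List[DependencyLink] = []
    pos = 0
    text = statement.lstrip()
    offset = len(statement) - len(text)
    while True:
        m = pat.match(text, pos)
        if not m:
            leftover = text[pos:].lstrip()
            if leftover.startswith("["):
                token = leftover.split("]", 1)[0] + "]"
                raise ValueError(
                    f"malformed dependency annotation {token!r} in statement for"
                    f" character {dependent + 1}"
                )
            break
        ctrl = int(m.group("ctrl")) - 1
        states = frozenset(int(s) for s in m.group("states").split(","))
        dstates = (
            frozenset(int(s) for s in m.group("dstates").split(","))
            if m.group("dstates")
            else None
        )
        if characters is not None:
            if not 0 <= ctrl < len(characters):
                raise ValueError(
                    f"annotation on character {dependent + 1} references"
                    f" nonexistent character {ctrl + 1}"
                )
            bad = states - set(characters[ctrl].state_codes)
            if bad:
                raise ValueError(
                    f"annotation on character {dependent + 1} references"
                    f" state(s) {sorted(bad)} not valid for character {ctrl + 1}"
                )
        links.append(
            DependencyLink(
                controller=ctrl,
                enabling_states=states,
                dependent=dependent,
                dependent_states=dstates,
            )
        )
        pos = m.end()
        while pos < len(text) and text[pos].isspace():
            pos += 1
    del offset
    return links


def render_dependency_annotation(
    links: Sequence[DependencyLink],
    grammar: AnnotationGrammar = DEFAULT_GRAMMAR,
) -> str:
    """Inverse of :func:`parse_dependency_annotation` (parse o render = id)."""
    tokens = []
    for l in links:
        dsuffix = (
            "." + ",".join(str(s) for s in sorted(l.dependent_states))
            if l.dependent_states is not None
            else ""
        )
        tokens.append(
            grammar.token_template.format(
                controller=l.controller + 1,
                states=",".join(str(s) for s in sorted(l.enabling_states)),
                dsuffix=dsuffix,
            )
        )
    return " ".join(tokens)


def build_dependency_graph(
    matrix: CharacterMatrix,
    extra_links: Iterable[DependencyLink] = (),
    serial_blocks: Iterable[SerialBlock] = (),
    grammar: AnnotationGrammar = DEFAULT_GRAMMAR,
) -> DependencyGraph:
    """Parse every character statement, merge manually supplied single-state
    links and serial blocks, and validate the result (acyclicity, index and
    state ranges, serial-block consistency)."""
    links: List[DependencyLink] = []
    for ch in matrix.characters:
        links.extend(
            parse_dependency_annotation(
                ch.statement, ch.index, grammar, matrix.characters
            )
        )
    links.extend(extra_links)
    graph = DependencyGraph(links=links, serial_blocks=list(serial_blocks))
    graph.validate(matrix.characters)
    return graph


# ---------------------------------------------------------------------------
# Scoring validation / enforcement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringViolation:
    taxon: str
    character: int  # 0-based
    kind: str  # "dependent-scored" | "unexpected-inapplicable" | "forbidden-state"
    detail: str

    def __str__(self) -> str:
        return f"{self.taxon} / char {self.character + 1}: {self.kind} ({self.detail})"


def _definitely_non_enabling(cell: CellValue, enabling: FrozenSet[int]) -> bool:
    if cell is MISSING:
        return False
    if cell is INAPPLICABLE:
        return True
    if isinstance(cell, frozenset):
        return not (cell & enabling)
    return cell not in enabling


def _definitely_enabling(cell: CellValue, enabling: FrozenSet[int]) -> bool:
    if cell is MISSING or cell is INAPPLICABLE:
        return False
    if isinstance(cell, frozenset):
        return cell <= enabling
    return cell in enabling


def validate_and_autoscore(
    matrix: CharacterMatrix,
    graph: DependencyGraph,
    mode: str = "report",
):
    """Check (or enforce) dependency-consistent scoring.

    In ``report`` mode, return the list of violations: a dependent scored with
    an actual state while some controller is definitely non-enabling; a
    dependent scored inapplicable while all its controllers are definitely
    enabling; or a single-state-restricted state scored while its controller
    is definitely non-enabling.  In ``enforce`` mode, return a corrected copy:
    dependents are rewritten to INAPPLICABLE (or restricted states removed)
    when a controller is scored a definite non-enabling state; MISSING
    controllers never trigger a rewrite.  Enforcement is idempotent and never
    touches controller cells or characters outside the graph.
    """
    if mode not in ("report", "enforce"):
        raise ValueError("mode must be 'report' or 'enforce'")
    violations: List[ScoringViolation] = []
    corrected = matrix.copy() if mode == "enforce" else None
    source = corrected if corrected is not None else matrix
    ti = {t: i for i, t in enumerate(matrix.taxon_labels)}
    # process in dependency order so enforced inapplicability cascades
    dg = nx.DiGraph()
    dg.add_nodes_from(l.dependent for l in graph.links)
    dg.add_nodes_from(l.controller for l in graph.links)
    dg.add_edges_from((l.controller, l.dependent) for l in graph.links)
    dep_set = {l.dependent for l in graph.links}
    deps = [d for d in nx.topological_sort(dg) if d in dep_set]
    for d in deps:
        full = graph.full_controllers_of(d)
        partial = [l for l in graph.controllers_of(d) if l.dependent_states is not None]
        for taxon, i in ti.items():
            cell = source.cells[i][d]
            blocked = any(
                _definitely_non_enabling(source.cells[i][l.controller], l.enabling_states)
                for l in full
            )
            if blocked and cell is not INAPPLICABLE and cell is not MISSING:
                violations.append(
                    ScoringViolation(
                        taxon, d, "dependent-scored",
                        f"scored {cell!r} while a controller is non-enabling",
                    )
                )
                if corrected is not None:
                    corrected.cells[i][d] = INAPPLICABLE
            if (
                full
                and cell is INAPPLICABLE
                and all(
                    _definitely_enabling(
                        source.cells[i][l.controller], l.enabling_states
                    )
                    for l in full
                )
            ):
                violations.append(
                    ScoringViolation(
                        taxon, d, "unexpected-inapplicable",
                        "all controllers enabling but cell is inapplicable",
                    )
                )
            if blocked:
                continue
            for l in partial:
                if _definitely_non_enabling(
                    source.cells[i][l.controller], l.enabling_states
                ):
                    forb = l.dependent_states or frozenset()
                    if isinstance(cell, int) and cell in forb:
                        violations.append(
                            ScoringViolation(
                                taxon, d, "forbidden-state",
                                f"state {cell} unavailable under controller"
                                f" {l.controller + 1}",
                            )
                        )
                        if corrected is not None:
                            corrected.cells[i][d] = INAPPLICABLE
                    elif isinstance(cell, frozenset) and cell & forb:
                        keep = cell - forb
                        if corrected is not None:
                            corrected.cells[i][d] = (
                                keep if len(keep) >= 2
                                else (next(iter(keep)) if keep else INAPPLICABLE)
                            )
                        violations.append(
                            ScoringViolation(
                                taxon, d, "forbidden-state",
                                f"polymorphism overlaps unavailable states {sorted(forb)}",
                            )
                        )
    if mode == "enforce":
        return corrected
    return violations


# ---------------------------------------------------------------------------
# Command emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommandTemplate:
    """Template for xlinks-style command text (default modelled on the TNT 1.6
    documentation; the exact spelling is configurable)."""

    link_template: str = "xlinks = {controller}.{states} > {dependents};"
    single_state_template: str = (
        "xlinks = {controller}.{states} > {dependent}.{dstates};"
    )
    serial_template: str = "xlinks* {flags}= {members};"
    one_based: bool = True


def emit_xlink_commands(
    graph: DependencyGraph,
    template: CommandTemplate = CommandTemplate(),
) -> List[str]:
    """Render the graph as deterministic command text: one command per
    (controller, enabling-states) group of whole-character links, one per
    single-state link, and one starred command per serial block."""
    off = 1 if template.one_based else 0
    out: List[str] = []
    groups: Dict[Tuple[int, FrozenSet[int]], List[int]] = {}
    singles: List[DependencyLink] = []
    for l in graph.links:
        if l.dependent_states is None:
            groups.setdefault((l.controller, l.enabling_states), []).append(l.dependent)
        else:
            singles.append(l)
    for (ctrl, states) in sorted(groups, key=lambda k: (k[0], sorted(k[1]))):
        deps = sorted(groups[(ctrl, states)])
        out.append(
            template.link_template.format(
                controller=ctrl + off,
                states=",".join(str(s) for s in sorted(states)),
                dependents=" ".join(str(d + off) for d in deps),
            )
        )
    for l in sorted(singles, key=lambda l: (l.controller, l.dependent)):
        out.append(
            template.single_state_template.format(
                controller=l.controller + off,
                states=",".join(str(s) for s in sorted(l.enabling_states)),
                dependent=l.dependent + off,
                dstates=",".join(str(s) for s in sorted(l.dependent_states)),
            )
        )
    for b in graph.serial_blocks:
        flags = "streak " if b.streak_constrained else ""
        out.append(
            template.serial_template.format(
                flags=flags,
                members=" ".join(str(m + off) for m in b.members),
            )
        )
    return out
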