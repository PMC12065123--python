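"""Dependency annotations, graph validation, autoscoring, command emission."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from depclad import (
    Character,
    CharacterMatrix,
    DependencyCycleError,
    DependencyGraph,
    DependencyLink,
    INAPPLICABLE,
    MISSING,
    SerialBlock,
    build_dependency_graph,
    emit_xlink_commands,
    parse_dependency_annotation,
    render_dependency_annotation,
    validate_and_autoscore,
)


def _chars(n, codes=(0, 1)):
    return [Character(i, state_codes=codes) for i in range(n)]


class TestAnnotationParsing:
    def test_single_link(self):
        chars = _chars(120)
        links = parse_dependency_annotation(
            "[98.1>this] Pleopod 1, endopod shape", 98, characters=chars
        )
        assert links == [
            DependencyLink(controller=97, enabling_states=frozenset({1}),
                           dependent=98)
        ]

    def test_plain_statement_yields_nothing(self):
        assert parse_dependency_annotation(
            "Carapace: (0) absent, (1) present", 5
        ) == []

    def test_stacked_tokens_and_single_state(self):
        links = parse_dependency_annotation(
            "[1.1>this] [2.0,1>this.2] Some statement", 4
        )
        assert len(links) == 2
        assert links[0].dependent_states is None
        assert links[1].enabling_states == frozenset({0, 1})
        assert links[1].dependent_states == frozenset({2})

    def test_reference_out_of_range(self):
        with pytest.raises(ValueError, match="999"):
            parse_dependency_annotation(
                "[999.1>this] x", 3, characters=_chars(207)
            )

    def test_malformed_token(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_dependency_annotation("[abc>this] x", 3)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.tuples(
            st.integers(0, 30),
            st.sets(st.integers(0, 3), min_size=1, max_size=3),
            st.one_of(st.none(), st.sets(st.integers(0, 3), min_size=1,
                                         max_size=2)),
        ),
        max_size=4,
    ))
    def test_render_parse_identity(self, raw):
        links = [
            DependencyLink(c, frozenset(es), 99,
                           frozenset(ds) if ds is not None else None)
            for c, es, ds in raw
            if c != 99
        ]
        text = render_dependency_annotation(links)
        assert parse_dependency_annotation(text, 99) == links


class TestGraphBuilding:
    def test_chain_counts_participants(self):
        chars = [
            Character(0, "Base: (0) absent, (1) present", "neomorphic"),
            Character(1, "[1.1>this] Mid: (0) absent, (1) present",
                      "neomorphic"),
            Character(2, "[2.1>this] Tip shape: (0) round, (1) flat"),
        ]
        m = CharacterMatrix(["a", "b"], chars, [[1, 1, 0], [0, INAPPLICABLE,
                                                            INAPPLICABLE]])
        g = build_dependency_graph(m)
        assert g.participating_characters() == {0, 1, 2}

    def test_cycle_detected(self):
        g = DependencyGraph(links=[
            DependencyLink(0, frozenset({1}), 1),
            DependencyLink(1, frozenset({1}), 0),
        ])
        with pytest.raises(DependencyCycleError):
            g.validate()

    def test_generator_bookkeeping_matches_graph(self):
        from depclad import SimulationConfig, simulate_matrix

        matrix, graph, ledger = simulate_matrix(
            SimulationConfig(n_taxa=8, n_characters=30, rng_seed=42)
        )
        assert graph.participating_characters() == ledger.participating

    def test_serial_block_conflicting_states_rejected(self):
        chars = [Character(0, state_codes=(0, 1)),
                 Character(1, state_codes=(0, 1, 2))]
        m = CharacterMatrix(["a", "b"], chars, [[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="state-code set"):
            build_dependency_graph(m, serial_blocks=[SerialBlock((0, 1))])


class TestAutoscoring:
    @pytest.fixture
    def small(self):
        chars = [
            Character(0, "Tail: (0) absent, (1) present", "neomorphic"),
            Character(1, "[1.1>this] Tail colour: (0) red, (1) blue"),
        ]
        return chars

    def _matrix(self, chars, rows):
        return CharacterMatrix([f"t{i}" for i in range(len(rows))], chars, rows)

    def test_dependent_scored_is_violation_and_enforced(self, small):
        m = self._matrix(small, [[0, 1], [1, 0]])
        g = build_dependency_graph(m)
        report = validate_and_autoscore(m, g, "report")
        assert len(report) == 1 and report[0].kind == "dependent-scored"
        fixed = validate_and_autoscore(m, g, "enforce")
        assert fixed.cell("t0", 1) is INAPPLICABLE
        assert validate_and_autoscore(fixed, g, "report") == []

    def test_missing_controller_is_not_decided(self, small):
        m = self._matrix(small, [[MISSING, 1]])
        g = build_dependency_graph(m)
        assert validate_and_autoscore(m, g, "report") == []
        fixed = validate_and_autoscore(m, g, "enforce")
        assert fixed.cell("t0", 1) == 1

    def test_unexpected_inapplicable_reported(self, small):
        m = self._matrix(small, [[1, INAPPLICABLE]])
        g = build_dependency_graph(m)
        report = validate_and_autoscore(m, g, "report")
        assert [v.kind for v in report] == ["unexpected-inapplicable"]

    def test_enforce_is_idempotent_and_leaves_controllers(self):
        from depclad import SimulationConfig, simulate_matrix

        matrix, graph, _ = simulate_matrix(
            SimulationConfig(n_taxa=6, n_characters=20, rng_seed=7,
                             missing_fraction=0.0)
        )
        # inject violations: score dependents wherever controller disables
        broken = matrix.copy()
        for i in range(broken.n_taxa):
            for c in range(broken.n_characters):
                if broken.cells[i][c] is INAPPLICABLE:
                    broken.cells[i][c] = 1
        once = validate_and_autoscore(broken, graph, "enforce")
        twice = validate_and_autoscore(once, graph, "enforce")
        assert once.cells == twice.cells
        assert validate_and_autoscore(once, graph, "report") == []
        controllers = {l.controller for l in graph.links}
        dependents = {l.dependent for l in graph.links}
        untouched = (set(range(matrix.n_characters)) - dependents)
        for i in range(broken.n_taxa):
            for c in untouched:
                assert once.cells[i][c] == broken.cells[i][c]

    def test_consistent_synthetic_matrix_reports_empty(self):
        from depclad import SimulationConfig, simulate_matrix

        for seed in (1, 2, 3):
            matrix, graph, _ = simulate_matrix(
                SimulationConfig(n_taxa=8, n_characters=25, rng_seed=seed)
            )
            assert validate_and_autoscore(matrix, graph, "report") == []


class TestCommandEmission:
    def test_single_link_command(self):
        g = DependencyGraph(links=[DependencyLink(0, frozenset({1}), 4)])
        assert emit_xlink_commands(g) == ["xlinks = 1.1 > 5;"]

    def test_empty_graph(self):
        assert emit_xlink_commands(DependencyGraph()) == []

    def test_grouping_and_counts(self):
        links = [
            DependencyLink(0, frozenset({1}), 2),
            DependencyLink(0, frozenset({1}), 3),
            DependencyLink(5, frozenset({1}), 6),
            DependencyLink(7, frozenset({1}), 8, frozenset({2})),  # single-state
        ]
        blocks = [SerialBlock((10, 11, 12), streak_constrained=True)]
        g = DependencyGraph(links=links, serial_blocks=blocks)
        cmds = emit_xlink_commands(g)
        # grouped whole-character links + single-state + starred serial
        assert len(cmds) == 2 + 1 + 1
        assert cmds[0] == "xlinks = 1.1 > 3 4;"
        assert any(c.startswith("xlinks*") for c in cmds)
        assert emit_xlink_commands(g) == cmds  # deterministic
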