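"""From in-statement dependency annotations to xlinks-style commands.

Character statements carry a prefix such as ``[1.1>this]``, meaning "this
character applies only while character 1 (1-based) shows state 1".  The
toolkit parses these into a dependency graph, audits the matrix for scoring
inconsistencies, enforces them automatically, and renders the graph as
command text that can be appended to a TNT-dialect matrix file.
"""

from depclad import (
    Character,
    CharacterMatrix,
    INAPPLICABLE,
    SerialBlock,
    build_dependency_graph,
    emit_xlink_commands,
    validate_and_autoscore,
    write_tnt_matrix,
)

chars = [
    Character(0, "Carapace: (0) absent, (1) present", "neomorphic", (0, 1)),
    Character(1, "[1.1>this] Carapace, posterior margin: (0) smooth, (1) serrate"),
    Character(2, "[1.1>this] Carapace, cervical groove: (0) absent, (1) present",
              "neomorphic", (0, 1)),
    Character(3, "Thoracopod exopod position 1: (0) absent, (1) present",
              "neomorphic", (0, 1)),
    Character(4, "Thoracopod exopod position 2: (0) absent, (1) present",
              "neomorphic", (0, 1)),
    Character(5, "Thoracopod exopod position 3: (0) absent, (1) present",
              "neomorphic", (0, 1)),
]
cells = [
    [1, 0, 1, 1, 1, 0],
    [1, 1, 0, 0, 1, 1],
    [0, INAPPLICABLE, INAPPLICABLE, 1, 0, 0],
    [0, 1, INAPPLICABLE, 0, 0, 0],  # violation: margin scored, carapace absent
]
matrix = CharacterMatrix(["alpha", "beta", "gamma", "delta"], chars, cells)
serial = SerialBlock((3, 4, 5), streak_constrained=True)
graph = build_dependency_graph(matrix, serial_blocks=[serial])

print("violations before enforcement:")
for v in validate_and_autoscore(matrix, graph, "report"):
    print("  ", v)
fixed = validate_and_autoscore(matrix, graph, "enforce")
print("violations after enforcement:",
      validate_and_autoscore(fixed, graph, "report"))
print()
print("emitted commands (1-based character numbers):")
for cmd in emit_xlink_commands(graph):
    print("  ", cmd)
print()
print("matrix file with commands:")
print(write_tnt_matrix(fixed))
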