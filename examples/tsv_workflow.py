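"""File-based workflow: dump a graph as TSV, reload it, write a ranking.

The same edge-list format feeds the command-line interface
(``netprio prioritize|benchmark|simulate``); this script drives it through
the library API instead.
"""

import tempfile
from pathlib import Path

from netprio import FixtureSpec, PropagationParams, dump_fixture, generate_hetnet, prioritize
from netprio.io import load_global_graph, write_ranking_tsv

spec = FixtureSpec(sizes=(20, 14, 16), planted_pairs=2, seed=8)
graph, pairs = generate_hetnet(spec)

with tempfile.TemporaryDirectory() as tmp:
    manifest = dump_fixture(graph, tmp)
    print("wrote", len(manifest["networks"]), "network files and",
          len(manifest["relations"]), "relation files")

    reloaded = load_global_graph(
        manifest["networks"],
        [(r["a"], r["b"], r["file"]) for r in manifest["relations"]],
        manifest["node_files"],
    )
    query, true_target = pairs[0]
    ranking = prioritize(
        reloaded, {query}, "d0", "d2", PropagationParams(gamma=0.1)
    )
    out = Path(tmp) / "ranking.tsv"
    write_ranking_tsv(ranking, str(out))
    print(f"query {query}: planted target {true_target} ranked",
          ranking.rank_of(true_target))
    print("first lines of the ranking file:")
    print("\n".join(out.read_text().splitlines()[:4]))
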