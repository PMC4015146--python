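"""Rank disease candidates for a small hand-built gene query.

Builds a three-domain global graph (genes, protein domains, diseases) in
memory, then ranks every disease by the correlation between the propagated
query evidence and each disease's own diffusion profile.  Two paths carry
evidence: gene->disease directly and gene->domain->disease.
"""

from netprio import PropagationParams, build_global_graph, enumerate_paths, prioritize

graph = build_global_graph(
    domain_specs=[
        ("gene", ["BRCA1", "RAD51", "TP53", "INS"],
         [("BRCA1", "RAD51", 0.9), ("BRCA1", "TP53", 0.4)]),
        ("domain", ["PF00533", "PF00870"],
         [("PF00533", "PF00870", 0.5)]),
        ("disease", ["breast_cancer", "li_fraumeni", "diabetes"],
         [("breast_cancer", "li_fraumeni", 0.3)]),
    ],
    relation_specs=[
        ("gene", "domain", [("BRCA1", "PF00533", 1.0), ("TP53", "PF00870", 0.8)]),
        ("domain", "disease", [("PF00533", "breast_cancer", 1.0),
                               ("PF00870", "li_fraumeni", 0.7)]),
        ("gene", "disease", [("RAD51", "breast_cancer", 0.9),
                             ("TP53", "li_fraumeni", 0.8),
                             ("INS", "diabetes", 1.0)]),
    ],
)

params = PropagationParams(alpha=0.9, gamma=0.5)
paths = enumerate_paths(graph, "gene", "disease")
print("evidence paths:", [" -> ".join(p.sequence) for p in paths])

ranking = prioritize(graph, {"BRCA1"}, "gene", "disease", params)
print("\nrank  disease          score")
for name, score, rank in ranking.entries:
    print(f"{rank:>4}  {name:<15}  {score:+.4f}")

print(
    "\nThe score is the Pearson correlation between the query evidence "
    "projected\nonto diseases and each candidate's own diffusion profile; "
    "diseases tied to\nBRCA1's network neighborhood rank first."
)
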