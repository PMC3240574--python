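"""Simulated-patient experiment: does exact significance help diagnosis?

Simulates patient queries from each disease's own annotations — optionally
corrupted by term exchange (NOISE) or generalisation to parent terms
(IMPRECISION) — and compares how well rankings by raw score, sampled
P-value and exact P-value recover the true disease (mean rank; 1 is best).
"""

import warnings

from ontosim import corpus_ic, diagnosis_experiment, random_corpus, random_dag
from ontosim.simulate import corpus_database

ontology = random_dag(80, extra_edge_prob=0.02, seed=11)
# leaf-coverage warnings are expected: every term must receive a finite IC
warnings.filterwarnings("ignore", message="covering")
corpus = random_corpus(ontology, 25, terms_per_item=(2, 5), seed=12, popularity=1.0)
ic = corpus_ic(ontology, corpus)
database = corpus_database(corpus)

frame = diagnosis_experiment(
    ontology,
    ic,
    database,
    scenarios=("NONE", "NOISE", "IMPRECISION"),
    methods=("score", "sampled:1000", "exact"),
    seed=7,
)

table = frame.pivot_table(index="scenario", columns="method", values="true_rank")
print("mean rank of the true disease (lower is better):\n")
print(table.round(3).to_string())
print("\n-> on clean (NONE) and generalised (IMPRECISION) queries, P-value")
print("   rankings beat raw scores. A single run this small cannot separate")
print("   exact from sampled P-values; the paired multi-seed benchmark in")
print("   the test suite shows the exact computation's consistent edge.")
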