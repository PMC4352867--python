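"""End-to-end static-structure analysis on a synthetic corpus.

Generates a corpus of glycosylated and carbohydrate-free PDB files with
a known combinatorial truth (including a redundant chain and a
too-short chain to exercise the filters), runs the full pipeline
(annotate -> filter -> pair -> score -> cluster -> histogram), and
compares the stage counts against the truth manifest.
"""

import tempfile
from pathlib import Path

from glycodelta import RunConfig, run_structure_analysis
from glycodelta.synthetic_data import (
    CorpusSequenceSpec,
    SiteSpec,
    generate_pair_corpus,
)

specs = [
    CorpusSequenceSpec(name="SQA", n_residues=60, n_glyco=1, n_deglyco=3,
                       sites=[SiteSpec(20, 2)]),
    CorpusSequenceSpec(name="SQB", n_residues=55, n_glyco=2, n_deglyco=2,
                       sites=[SiteSpec(15, 1)], n_redundant_chains=1),
    CorpusSequenceSpec(name="SQS", n_residues=49, n_glyco=1, n_deglyco=2),
]

with tempfile.TemporaryDirectory() as tmp:
    truth = generate_pair_corpus(specs, seed=5, out_dir=tmp)
    cfg = RunConfig(glyco_dir=Path(tmp) / "glyco",
                    deglyco_dir=Path(tmp) / "deglyco",
                    out_dir=Path(tmp) / "out")
    bundle = run_structure_analysis(cfg)

print("expected:", truth["expected"])
print("measured:", bundle["counts"])
print()
pairs = bundle["pairs"]
print(pairs[["pair_id", "class", "rmsd", "tm_score"]].to_string(index=False))
print()
hist = bundle["histograms"]
at_15 = hist[(hist.metric == "rmsd") & (hist.threshold == 1.5)]
print("fraction of clusters with RMSD <= 1.5 A:")
print(at_15[["class", "fraction"]].to_string(index=False))

# The measured filter-stage and pair counts equal the combinatorial
# truth exactly (n_glyco x n_deglyco GP/P pairs and C(n_deglyco, 2) P/P
# pairs per retained sequence); with only crystal-noise between forms,
# every cluster mean lands below the 1.5 A threshold.
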