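"""Compare similarity-based annotation against the classifier's labels.

Builds a small BLAST tabular file by hand, derives per-transcript best-hit
class labels (lowest e-value, ties by bitscore), and cross-classifies them
against a set of pipeline labels.  Off-diagonal counts are transcripts the
two approaches annotate differently — the interesting cases.
"""

import tempfile
from pathlib import Path

import toxcascade as tc

tab = Path(tempfile.mkdtemp()) / "hits.tsv"
tab.write_text(
    "t1\tNaTx_ref\t92.0\t60\t4\t0\t1\t60\t1\t60\t1e-40\t200.0\n"
    "t1\tKTx_ref\t55.0\t60\t25\t1\t1\t60\t1\t60\t1e-12\t80.0\n"
    "t2\tKTx_ref\t88.0\t45\t5\t0\t1\t45\t1\t45\t1e-30\t160.0\n"
    "t3\tNaTx_ref\t88.0\t60\t6\t0\t1\t60\t1\t60\t1e-35\t180.0\n"
    "t4\tICK_ref\t97.0\t40\t1\t0\t1\t40\t1\t40\t1e-50\t210.0\n"
)
hits = tc.parse_blast_tab(tab)
subject_classes = {"NaTx_ref": "NaTx", "KTx_ref": "KTx", "ICK_ref": "ICK"}
blast_labels = tc.best_hit_labels(hits, subject_classes, max_evalue=1e-10)
print("BLAST best-hit labels:", blast_labels)

# labels the cascade produced for the same transcripts (one reannotation)
pipeline_labels = {"t1": "NaTx", "t2": "KTx", "t3": "KTx", "t4": "ICK"}
cm, extras = tc.cross_classification(blast_labels, pipeline_labels)
print("cross-classification (rows: BLAST, columns: pipeline):")
print(cm.to_dataframe())
print("ids in only one mapping:", extras)
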