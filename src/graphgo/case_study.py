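"""Worked example: BPO term sets for the human protein Q9BQD7.

Q9BQD7 is a *difficult* no-knowledge benchmark protein (no training homolog at
e-value 0.001), for which the predicted biological-process term sets of several
function predictors are available alongside its 22 experimentally derived BPO
terms (root GO:0008150 omitted throughout). These sets make a compact reference
case for the set-level F1 metric: the homology k-NN predicts nothing, the
network k-NN over-predicts broadly, and the graph-convolutional predictor gets
the best precision/recall balance.
"""

from __future__ import annotations

#: 22 true BPO terms of Q9BQD7 (root omitted).
Q9BQD7_TRUTH = frozenset({
    "GO:0044238", "GO:0006479", "GO:0032259", "GO:0044237", "GO:0018193",
    "GO:0036211", "GO:0008152", "GO:0009987", "GO:0008213", "GO:0043414",
    "GO:0043412", "GO:0006807", "GO:0018205", "GO:0006464", "GO:0044267",
    "GO:0071704", "GO:0019538", "GO:1901564", "GO:0044260", "GO:0043170",
    "GO:0018022", "GO:0018023",
})

#: Predicted BPO term sets per method for Q9BQD7.
Q9BQD7_PREDICTIONS = {
    "BLAST-KNN": frozenset(),
    "LR-InterPro": frozenset({
        "GO:0006139", "GO:0006725", "GO:0006807", "GO:0008152", "GO:0009987",
        "GO:0032259", "GO:0034641", "GO:0043170", "GO:0043412", "GO:0043414",
        "GO:0044237", "GO:0044238", "GO:0044260", "GO:0046483", "GO:0065007",
        "GO:0071704", "GO:0090304", "GO:1901360", "GO:1901564",
    }),
    "Net-KNN": frozenset({
        "GO:0006139", "GO:0006412", "GO:0006464", "GO:0006479", "GO:0006518",
        "GO:0006725", "GO:0006807", "GO:0008152", "GO:0008213", "GO:0009058",
        "GO:0009059", "GO:0009987", "GO:0010467", "GO:0010468", "GO:0016070",
        "GO:0019222", "GO:0019538", "GO:0032259", "GO:0034641", "GO:0034645",
        "GO:0036211", "GO:0043043", "GO:0043170", "GO:0043412", "GO:0043414",
        "GO:0043603", "GO:0043604", "GO:0044237", "GO:0044238", "GO:0044249",
        "GO:0044260", "GO:0044267", "GO:0044271", "GO:0046483", "GO:0048519",
        "GO:0050789", "GO:0050794", "GO:0060255", "GO:0065007", "GO:0071704",
        "GO:0090304", "GO:1901360", "GO:1901564", "GO:1901566", "GO:1901576",
    }),
    "DeepGOCNN": frozenset({
        "GO:0044238", "GO:1901564", "GO:0008152", "GO:0043170", "GO:0044237",
        "GO:0006807", "GO:0009987", "GO:0071704", "GO:0050896", "GO:0050794",
        "GO:0050789", "GO:0031323", "GO:0048519", "GO:0065007", "GO:0019222",
        "GO:0080090", "GO:0060255", "GO:1901576", "GO:0009058", "GO:0044249",
    }),
    "DeepGOPlus": frozenset({
        "GO:0009987", "GO:0008152", "GO:0071704", "GO:0044237", "GO:0065007",
    }),
    "DeepGraphGO": frozenset({
        "GO:0006464", "GO:0006479", "GO:0006807", "GO:0008152", "GO:0008213",
        "GO:0009058", "GO:0009987", "GO:0019538", "GO:0032259", "GO:0034641",
        "GO:0036211", "GO:0043170", "GO:0043412", "GO:0043414", "GO:0044237",
        "GO:0044238", "GO:0044249", "GO:0044260", "GO:0044267", "GO:0050789",
        "GO:0065007", "GO:0071704", "GO:0071840", "GO:1901564", "GO:1901576",
    }),
}


def case_study_f1(method: str) -> float:
    """Set-level F1 of one method's Q9BQD7 term set, rounded to 3 decimals."""
    from .evaluation import f1_set

    return round(f1_set(Q9BQD7_PREDICTIONS[method], Q9BQD7_TRUTH), 3)
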