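"""Published external-testing performance of the original clinical system.

These are printed results from the original multicenter study, carried as
*inputs* (the patient cohorts themselves are not redistributable).  They are
used to recompute derived quantities — e.g. the percent C-index improvement
of the multimodal fusion (MMF) score over its comparators — and as context
when reporting desk-scale synthetic results.
"""

from __future__ import annotations

#: External testing cohort (n = 209) C-indexes per model and endpoint.
EXTERNAL_TEST_CINDEX = {
    "OS": {
        "mrecist": 0.57,
        "radiomics": 0.58,
        "net1": 0.65,
        "net2": 0.64,
        "net3": 0.68,
        "benchmark": 0.67,
        "ensemble_dl": 0.69,
        "mmf": 0.74,
    },
    "PFS": {
        "mrecist": 0.58,
        "radiomics": 0.58,
        "net1": 0.61,
        "net2": 0.60,
        "net3": 0.64,
        "benchmark": 0.65,
        "ensemble_dl": 0.66,
        "mmf": 0.69,
    },
}

EXTERNAL_TEST_N = 209


def relative_improvement_pct(c_model: float, c_reference: float) -> float:
    """Percent C-index improvement of a model over a reference."""
    return 100.0 * (c_model - c_reference) / c_reference
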