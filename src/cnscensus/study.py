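"""The published whole-CNS census summary tables, as pipeline inputs.

These are the printed per-line nucleus-count summaries of the larval
*Drosophila* CNS study this package reimplements: mean count, coefficient
of variation (percent) and number of animals per genetic line and sex.
Lines *brp*, *Syt1* and *nSyb* label synapse-forming (functional) neurons;
*repo* labels glia; *Sh*, *Shal*, *Shab* and *Shaw* report voltage-gated
potassium channel (Kv family) gene expression and were quantified in
males only.

The printed pooled neuron means (female 10,312, n=16; male 9,396, n=15)
were computed from raw per-animal counts; the sample-size-weighted mean
of the printed male line means differs from the printed male pooled value
by under one count (9395.33 vs 9396) because the line means are
themselves rounded.  The printed pooled values are therefore carried as
explicit inputs for the sex-difference and expression-fraction
arithmetic.
"""

from __future__ import annotations

from .core import CensusLineSummary, Sex
from .stats import CensusTable, build_census_report

__all__ = [
    "SYNAPTIC_LINE_SUMMARIES",
    "GLIA_LINE_SUMMARIES",
    "KV_LINE_SUMMARIES",
    "PRINTED_POOLED_NEURONS",
    "CONCORDANCE_BRP",
    "study_census_report",
]

SYNAPTIC_LINE_SUMMARIES = [
    CensusLineSummary("brp", Sex.FEMALE, 10776.0, 2.65, 6),
    CensusLineSummary("Syt1", Sex.FEMALE, 10097.0, 5.96, 5),
    CensusLineSummary("nSyb", Sex.FEMALE, 9971.0, 1.35, 5),
    CensusLineSummary("brp", Sex.MALE, 9888.0, 3.15, 5),
    CensusLineSummary("Syt1", Sex.MALE, 9012.0, 3.8, 5),
    CensusLineSummary("nSyb", Sex.MALE, 9286.0, 5.38, 5),
]

GLIA_LINE_SUMMARIES = [
    CensusLineSummary("repo", Sex.FEMALE, 3860.0, 3.37, 7),
    CensusLineSummary("repo", Sex.MALE, 4015.0, 1.98, 6),
]

KV_LINE_SUMMARIES = [
    CensusLineSummary("Sh", Sex.MALE, 8204.0, 5.67, 10),
    CensusLineSummary("Shal", Sex.MALE, 8261.0, 3.1, 5),
    CensusLineSummary("Shab", Sex.MALE, 3057.0, 8.21, 10),
    CensusLineSummary("Shaw", Sex.MALE, 1737.0, 4.3, 11),
]

# Printed pooled means, computed in the study from raw per-animal counts.
PRINTED_POOLED_NEURONS = {"female": 10312.0, "male": 9396.0}

# Manual vs automated count of one densely labelled brp CNS.
CONCORDANCE_BRP = {"manual": 9430, "automated": 9444}


def study_census_report() -> CensusTable:
    """Full derived report for the synaptic + glia census tables.

    Kv expression is summarised separately (fractions and percent
    differences against the printed male pooled neuron mean) and merged
    into the same ``derived`` dict under ``male_<gene>_*`` keys.
    """
    table = build_census_report(
        SYNAPTIC_LINE_SUMMARIES + GLIA_LINE_SUMMARIES,
        glia_line="repo", pooled_override=PRINTED_POOLED_NEURONS)
    male_ref = PRINTED_POOLED_NEURONS["male"]
    kv = build_census_report(
        KV_LINE_SUMMARIES, glia_line="repo",
        pooled_override={"male": male_ref})
    for key, value in kv.derived.items():
        if key.endswith(("_fraction_pct", "_vs_pooled_pct")):
            table.derived[key] = value
    table.rows = table.rows + KV_LINE_SUMMARIES
    return table
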