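"""Census arithmetic: line summaries, pooled means, percent conventions.

Counts are reported in the Results convention "mean (+-CV%, n)" with the
coefficient of variation based on the sample (n-1) standard deviation.
Pooling across lines weights each line's mean by its number of animals.

Two distinct percent-difference conventions coexist in the source
arithmetic and are deliberately exposed as two named functions so they
cannot be confused:

* :func:`pct_diff_line` — line (or gene) vs a reference line,
  ``100 * (a - b) / b`` (the comparison line is the denominator);
* :func:`pct_diff_sex` — male vs female, ``100 * (male - female) / male``
  (the male mean is the denominator; negative = fewer in males).

Rounding is half-even and applied only at report time; internal values
stay unrounded.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .core import CensusLineSummary, ParameterError, Sex

__all__ = [
    "CensusTable",
    "line_summary",
    "weighted_mean",
    "pct_diff_line",
    "pct_diff_sex",
    "fraction_of_reference",
    "anova_tukey",
    "unpaired_ttest",
    "build_census_report",
]


from dataclasses import dataclass, field


@dataclass
class CensusTable:
    """Per-line summaries plus every derived quantity of the report."""

    rows: list[CensusLineSummary]
    derived: dict = field(default_factory=dict)


def line_summary(counts, line: str = "", sex: Sex = Sex.UNKNOWN
                 ) -> CensusLineSummary:
    """Mean, CV% (sample SD), and n for one line's per-animal counts."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ParameterError("line_summary needs at least one animal")
    mean = float(arr.mean())
    if arr.size == 1:
        cv = 0.0  # degenerate by convention; flagged via n_animals == 1
    else:
        sd = float(arr.std(ddof=1))
        cv = 100.0 * sd / mean if mean else 0.0
    return CensusLineSummary(line=line, sex=sex, mean_count=mean,
                             cv_percent=cv, n_animals=int(arr.size))


def weighted_mean(summaries) -> float:
    """Sample-size-weighted pooled mean across same-sex line summaries."""
    summaries = list(summaries)
    if not summaries:
        raise ParameterError("weighted_mean needs at least one summary")
    sexes = {s.sex for s in summaries}
    if len(sexes) != 1:
        raise ParameterError(f"refusing to pool across sexes: {sexes}")
    total_n = sum(s.n_animals for s in summaries)
    return float(sum(s.mean_count * s.n_animals for s in summaries) / total_n)


def pct_diff_line(a: float, b: float) -> float:
    """Percent difference of ``a`` vs reference ``b``: 100 * (a - b) / b."""
    if b <= 0:
        raise ParameterError("reference value must be > 0")
    return 100.0 * (a - b) / b


def pct_diff_sex(male: float, female: float) -> float:
    """Sex difference with the male mean as denominator.

    ``100 * (male - female) / male``; negative means fewer in males.
    """
    if male <= 0:
        raise ParameterError("male mean must be > 0")
    return 100.0 * (male - female) / male


def fraction_of_reference(a: float, ref: float, decimals: int | None = None
                          ) -> float:
    """``100 * a / ref`` percent, optionally rounded (half-even)."""
    if ref <= 0:
        raise ParameterError("reference must be > 0")
    value = 100.0 * a / ref
    if decimals is not None:
        value = float(np.round(value, decimals))
        if decimals == 0:
            value = float(int(value))
    return value


def anova_tukey(groups, labels=None):
    """Ordinary one-way ANOVA followed by Tukey's HSD.

    Returns ``(F, p, pairwise)`` where ``pairwise`` is a DataFrame of
    adjusted p-values for all group pairs.
    """
    import pandas as pd
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ParameterError("ANOVA needs >= 2 groups with n >= 2 each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    f_stat, p_value = sps.f_oneway(*groups)
    values = np.concatenate(groups)
    group_col = np.concatenate([[lab] * g.size
                                for lab, g in zip(labels, groups)])
    if np.ptp(values) == 0:
        # All observations identical: F = 0, p = 1, nothing to adjust.
        pairs = [(a, b) for i, a in enumerate(labels)
                 for b in labels[i + 1:]]
        pairwise = pd.DataFrame(pairs, columns=["group1", "group2"])
        pairwise["p_adj"] = 1.0
        return 0.0, 1.0, pairwise
    tukey = pairwise_tukeyhsd(values, group_col)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )[["group1", "group2", "p-adj"]].rename(columns={"p-adj": "p_adj"})
    return float(f_stat), float(p_value), pairwise


def unpaired_ttest(a, b) -> tuple[float, float]:
    """Two-sided unpaired Student t-test (equal variances)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("t-test needs n >= 2 per group")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        # Zero pooled variance: identical constant groups.
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ParameterError("degenerate zero-variance input")
    return float(t), float(p)


def build_census_report(summaries, glia_line: str = "repo",
                        pooled_override: dict | None = None) -> CensusTable:
    """Derive the full census report from per-line summaries.

    Lines named ``glia_line`` count as glia; all others as neurons.
    Derived values: per-sex pooled neuron means (sample-size weighted),
    line-vs-line percent differences within sex, per-line and pooled sex
    differences (male-denominator convention), glia sex difference, and
    each line's count as a fraction of its sex's pooled neuron mean.

    ``pooled_override`` maps ``"female"``/``"male"`` to externally supplied
    pooled neuron means (e.g. values computed from raw per-animal data
    rather than from the summary table); overridden values become the
    reference for sex differences and fractions.
    """
    rows = list(summaries)
    derived: dict = {}
    neurons = {s: [r for r in rows
                   if r.sex == s and r.line != glia_line]
               for s in (Sex.FEMALE, Sex.MALE)}
    glia = {s: [r for r in rows if r.sex == s and r.line == glia_line]
            for s in (Sex.FEMALE, Sex.MALE)}

    pooled: dict = {}
    for s in (Sex.FEMALE, Sex.MALE):
        if neurons[s]:
            value = weighted_mean(neurons[s])
            derived[f"{s.value}_neurons_pooled_from_lines"] = value
            pooled[s.value] = value
    if pooled_override:
        pooled.update(pooled_override)
    for sex_name, value in pooled.items():
        derived[f"{sex_name}_neurons_pooled"] = value

    for s in (Sex.FEMALE, Sex.MALE):
        for i, a in enumerate(neurons[s]):
            for b in neurons[s]:
                if a.line != b.line:
                    derived[f"{s.value}_{a.line}_vs_{b.line}_pct"] = (
                        pct_diff_line(a.mean_count, b.mean_count))

    by_line_f = {r.line: r for r in neurons[Sex.FEMALE]}
    by_line_m = {r.line: r for r in neurons[Sex.MALE]}
    for line in by_line_f.keys() & by_line_m.keys():
        derived[f"sex_diff_{line}_pct"] = pct_diff_sex(
            by_line_m[line].mean_count, by_line_f[line].mean_count)
    if "female" in pooled and "male" in pooled:
        derived["sex_diff_neurons_pct"] = pct_diff_sex(
            pooled["male"], pooled["female"])
    if glia[Sex.FEMALE] and glia[Sex.MALE]:
        derived["sex_diff_glia_pct"] = pct_diff_sex(
            glia[Sex.MALE][0].mean_count, glia[Sex.FEMALE][0].mean_count)

    for s in (Sex.FEMALE, Sex.MALE):
        ref = pooled.get(s.value)
        if ref is None:
            continue
        if glia[s]:
            derived[f"{s.value}_glia_fraction_pct"] = fraction_of_reference(
                glia[s][0].mean_count, ref)
        for r in neurons[s]:
            derived[f"{s.value}_{r.line}_fraction_pct"] = (
                fraction_of_reference(r.mean_count, ref))
            derived[f"{s.value}_{r.line}_vs_pooled_pct"] = pct_diff_line(
                r.mean_count, ref)
    return CensusTable(rows=rows, derived=derived)
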