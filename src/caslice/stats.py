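"""Condition comparisons and summary statistics.

The statistical unit is the slice: per-cell statistics are averaged within
slice before any test, matching the reported n = slices.  Paired
comparisons use Student's t-test; multi-factor designs use full-factorial
ANOVA.  Significance is p < 0.05 with no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .traces import analyze_recording
from .types import ASTROCYTE, NEURON, Pge2Timecourse, SliceRecording

ALPHA = 0.05

#: Fold-ratio ceiling under which a stimulus response counts as "blunted"
#: (together with a non-significant paired test); an interpretation, since
#: the term is qualitative in the source literature.
BLUNTED_RATIO_MAX = 1.2


@dataclass
class ConditionSummary:
    region: str
    genotype: str
    cell_class: str  # astrocyte | neuron | network
    epoch: str
    n_slices: int
    mean: float
    sd: float  # NaN for a single slice


@dataclass
class FoldChangeResult:
    ratio: float  # post/pre
    sd: float  # sd of per-slice ratios (NaN when unpaired or n=1)
    p_value: float
    test: str  # "t" | "anova"
    n_slices: int
    blunted: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("fold ratio must be positive")


def slice_means(
    cell_table: pd.DataFrame,
    value: str = "frequency_cpm",
    active_only: bool = True,
    label: Optional[str] = None,
    epoch: Optional[str] = None,
) -> pd.DataFrame:
    """Per-slice means of a per-cell statistic.

    Filters to active cells (classified on the control epoch) and optionally
    one cell class and epoch; returns one row per (slice_id, epoch).
    """
    df = cell_table
    if df.empty:
        raise ValueError("empty group after filtering")
    if active_only:
        df = df[df["active"]]
    if label is not None:
        df = df[df["label"] == label]
    if epoch is not None:
        df = df[df["epoch"] == epoch]
    if df.empty:
        raise ValueError("empty group after filtering")
    out = (df.groupby(["slice_id", "epoch"])[value]
             .mean().rename("mean_value").reset_index())
    return out


def summarize(
    cell_table: pd.DataFrame,
    region: str = "",
    genotype: str = "",
    cell_class: str = "",
    epoch: Optional[str] = None,
    value: str = "frequency_cpm",
    active_only: bool = True,
) -> ConditionSummary:
    """Group mean ± SD over per-slice means (slice = statistical unit)."""
    label = cell_class if cell_class in (ASTROCYTE, NEURON) else None
    per_slice = slice_means(cell_table, value, active_only, label, epoch)
    vals = per_slice["mean_value"].to_numpy()
    return ConditionSummary(
        region=region, genotype=genotype, cell_class=cell_class or "network",
        epoch=epoch or "all", n_slices=vals.size,
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
    )


def fold_change(
    pre: Sequence[float],
    post: Sequence[float],
    paired: bool = True,
) -> FoldChangeResult:
    """Post/pre frequency fold change over matched slices.

    ``pre`` and ``post`` are per-slice mean values.  Paired inputs must be
    matched by slice; the ratio is the mean of per-slice ratios and the
    attached p-value is a paired t-test of post vs pre.  Unpaired inputs
    use the ratio of group means and Welch's t-test.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if paired:
        if pre.size != post.size:
            raise ValueError("paired fold change requires matched slices")
        if np.any(pre <= 0):
            raise ValueError("non-positive pre-epoch means")
        ratios = post / pre
        ratio = float(np.mean(ratios))
        sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else float("nan")
        diffs = post - pre
        if np.allclose(diffs, 0.0):
            p = 1.0
        elif pre.size < 2:
            p = float("nan")
        elif np.isclose(np.std(diffs), 0.0):
            # constant non-zero shift: zero within-pair variance
            p = 0.0
        else:
            p = float(sps.ttest_rel(post, pre).pvalue)
    else:
        ratio = float(np.mean(post) / np.mean(pre))
        sd = float("nan")
        p = float(sps.ttest_ind(post, pre, equal_var=False).pvalue)
    return FoldChangeResult(ratio=ratio, sd=sd, p_value=p, test="t",
                            n_slices=int(pre.size))


def stimulus_fold_change(
    recordings: Sequence[SliceRecording],
    cell_class: str,
    value: str = "frequency_cpm",
) -> FoldChangeResult:
    """Control→stimulus fold change of one cell class across slices.

    Runs the trace pipeline on each recording, averages the statistic over
    active cells of the class per slice and epoch, and forms the paired
    per-slice ratio.
    """
    pre, post = [], []
    for rec in recordings:
        if rec.protocol.kind == "none":
            raise ValueError("recording has no stimulus epoch")
        table = analyze_recording(rec)
        sub = table[table["active"] & (table["label"] == cell_class)]
        ctl = sub[sub["epoch"] == "control"]["frequency_cpm"].mean()
        stim = sub[sub["epoch"] == rec.protocol.kind][value].mean()
        pre.append(ctl)
        post.append(stim)
    return fold_change(pre, post, paired=True)


def hypercapnia_response(
    recordings: Sequence[SliceRecording],
    cell_class: str = ASTROCYTE,
) -> FoldChangeResult:
    """Frequency fold change across a hypercapnic challenge.

    Reported for the astrocytic population by default: astrocytes are the
    CO₂-sensing elements, and their rate response stays inside the
    0.01–0.15 Hz analysis band, whereas doubled neuronal rates (>0.18 Hz)
    fall outside it and cannot be counted.  Returns the paired
    control→hypercapnia fold with a ``blunted`` flag: ratio ≤ 1.2 and a
    non-significant paired test.
    """
    for rec in recordings:
        if rec.protocol.kind != "hypercapnia":
            raise ValueError("recordings must carry a hypercapnia protocol")
    result = stimulus_fold_change(recordings, cell_class)
    result.blunted = bool(result.ratio <= BLUNTED_RATIO_MAX
                          and not (result.p_value < ALPHA))
    return result


def pge2_transient(
    timecourse: Pge2Timecourse,
    onset_min: Optional[float] = None,
) -> FoldChangeResult:
    """Peak fold change of a PGE2 timecourse over its pre-onset baseline.

    ratio = max post-onset concentration / baseline mean.  The response
    counts as a transient when the level clearly exceeded baseline and the
    final sample has returned to within two baseline SDs.  Requires at
    least three baseline samples.
    """
    if onset_min is None:
        onset_min = timecourse.stimulus_onset_min
    t = timecourse.times_min
    c = timecourse.concentration
    base = c[t < onset_min]
    if base.size < 3:
        raise ValueError("need at least three baseline samples")
    base_mean = float(np.mean(base))
    base_sd = float(np.std(base, ddof=1))
    if base_mean <= 0:
        raise ValueError("degenerate baseline")
    post = c[t >= onset_min]
    i_peak = int(np.argmax(post))
    ratio = float(post[i_peak] / base_mean)
    margin = 2.0 * base_sd
    exceeded = bool(post[i_peak] > base_mean + max(margin, 1e-12 * base_mean))
    after_peak = post[i_peak + 1:]
    returned = bool(after_peak.size and np.any(
        np.abs(after_peak - base_mean) <= max(margin, 1e-9 * base_mean)))
    transient = exceeded and returned
    if post.size <= 2:
        p = float("nan")
    elif np.allclose(post, base_mean):
        p = 1.0
    else:
        p = float(sps.ttest_1samp(post, base_mean).pvalue)
    res = FoldChangeResult(ratio=ratio, sd=base_sd, p_value=p, test="t",
                           n_slices=1)
    res.blunted = not transient  # reused flag: no transient detected
    res.transient = transient  # type: ignore[attr-defined]
    return res


def run_tests(dataset: pd.DataFrame, design: dict) -> pd.DataFrame:
    """Student's t-test or full-factorial ANOVA per the given design.

    ``design`` keys: ``value`` (response column), either ``group`` (a
    two-level factor → two-sided t-test; add ``paired: True`` for paired
    data sorted by a ``by`` column) or ``factors`` (list of factor columns →
    full-factorial ANOVA via OLS).  Returns a table with (comparison,
    statistic, df, p, significant); significance at p < 0.05, uncorrected.
    """
    value = design["value"]
    rows = []
    if "group" in design:
        factor = design["group"]
        levels = sorted(dataset[factor].dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"t-test needs exactly 2 levels of {factor!r}")
        a = dataset[dataset[factor] == levels[0]]
        b = dataset[dataset[factor] == levels[1]]
        if design.get("paired"):
            key = design.get("by", "slice_id")
            a = a.sort_values(key)[value].to_numpy()
            b = b.sort_values(key)[value].to_numpy()
            if a.size != b.size:
                raise ValueError("paired design requires matched rows")
            if np.allclose(a - b, 0.0):
                stat, p, dof = 0.0, 1.0, a.size - 1
            else:
                res = sps.ttest_rel(a, b)
                stat, p, dof = float(res.statistic), float(res.pvalue), a.size - 1
            name = f"{levels[0]} vs {levels[1]} (paired)"
        else:
            av, bv = a[value].to_numpy(), b[value].to_numpy()
            if np.allclose(np.concatenate([av, bv]) - np.mean(av), 0.0):
                stat, p = 0.0, 1.0
            else:
                res = sps.ttest_ind(av, bv)
                stat, p = float(res.statistic), float(res.pvalue)
            dof = av.size + bv.size - 2
            name = f"{levels[0]} vs {levels[1]}"
        rows.append({"comparison": name, "statistic": stat, "df": dof, "p": p})
    elif "factors" in design:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        factors = design["factors"]
        data = dataset.rename(columns={value: "_y"})
        terms = " * ".join(f"C({f})" for f in factors)
        model = ols(f"_y ~ {terms}", data=data).fit()
        table = sm.stats.anova_lm(model, typ=2)
        for term, row in table.iterrows():
            if term == "Residual":
                continue
            rows.append({"comparison": term.replace("C(", "").replace(")", ""),
                         "statistic": float(row["F"]),
                         "df": float(row["df"]),
                         "p": float(row["PR(>F)"])})
    else:
        raise ValueError("design must name either 'group' or 'factors'")
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < ALPHA
    return out
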