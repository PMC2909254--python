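"""Two-group one-way ANOVA per soil chemistry parameter.

Accepts either raw replicate values or printed mean/sd/n summaries; with
two groups the classic equal-variance F statistic is t^2 of the pooled
t-test and is computable exactly from summaries.  Welch's variant is
available behind a flag; no multiple-testing correction is applied by
default (Holm optional).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from ecmcomm.errors import FormatError, ValidationError


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 2:
            raise ValidationError("each group needs n >= 2")


@dataclass
class SoilSummary:
    parameter: str
    group_a: GroupSummary
    group_b: GroupSummary
    units: str = ""

    @classmethod
    def from_raw(
        cls, parameter: str, values_a: list[float], values_b: list[float], units: str = ""
    ) -> "SoilSummary":
        a, b = np.asarray(values_a, float), np.asarray(values_b, float)
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(f"{parameter}: each group needs >= 2 replicates")
        return cls(
            parameter=parameter,
            group_a=GroupSummary(float(a.mean()), float(a.std(ddof=1)), len(a)),
            group_b=GroupSummary(float(b.mean()), float(b.std(ddof=1)), len(b)),
            units=units,
        )


@dataclass
class AnovaResult:
    parameter: str
    f: float
    df1: int
    df2: int
    p: float
    significant: bool
    welch: bool = False
    p_adjusted: float | None = None


def anova_two_group(
    summary: SoilSummary, alpha: float = 0.05, welch: bool = False
) -> AnovaResult:
    """One-way ANOVA for two groups from summary statistics."""
    a, b = summary.group_a, summary.group_b
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            # degenerate: zero variance everywhere, F undefined
            return AnovaResult(summary.parameter, 0.0, 1, a.n + b.n - 2, 1.0, False, welch)
        return AnovaResult(
            summary.parameter, float("inf"), 1, a.n + b.n - 2, 0.0, True, welch
        )
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        t2 = (a.mean - b.mean) ** 2 / (va + vb)
        df2 = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        p = float(stats.f.sf(t2, 1, df2))
        return AnovaResult(summary.parameter, float(t2), 1, int(round(df2)), p, p < alpha, True)
    df2 = a.n + b.n - 2
    ms_within = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df2
    grand = (a.n * a.mean + b.n * b.mean) / (a.n + b.n)
    ms_between = a.n * (a.mean - grand) ** 2 + b.n * (b.mean - grand) ** 2
    if ms_within == 0:
        return AnovaResult(summary.parameter, float("inf"), 1, df2, 0.0, True, False)
    f = ms_between / ms_within
    p = float(stats.f.sf(f, 1, df2))
    return AnovaResult(summary.parameter, float(f), 1, df2, p, p < alpha, False)


def compare_soils(
    summaries: list[SoilSummary], alpha: float = 0.05, welch: bool = False,
    holm: bool = False,
) -> list[AnovaResult]:
    """ANOVA per parameter; optional Holm step-down adjustment."""
    if not summaries:
        raise ValidationError("no soil parameters to compare")
    results = [anova_two_group(s, alpha=alpha, welch=welch) for s in summaries]
    if holm:
        order = sorted(range(len(results)), key=lambda i: results[i].p)
        m = len(results)
        prev = 0.0
        for rank, i in enumerate(order):
            adj = min(1.0, max(prev, (m - rank) * results[i].p))
            prev = adj
            results[i].p_adjusted = adj
            results[i].significant = adj < alpha
    return results


# -- on-disk formats -------------------------------------------------------


def read_soil_summaries(path: str | Path) -> list[SoilSummary]:
    """TSV with columns parameter, mean1, sd1, n1, mean2, sd2, n2 [, units]."""
    path = Path(path)
    out: list[SoilSummary] = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"parameter", "mean1", "sd1", "n1", "mean2", "sd2", "n2"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: summary table needs columns {sorted(required)}")
        for row in reader:
            out.append(
                SoilSummary(
                    parameter=row["parameter"].strip(),
                    group_a=GroupSummary(float(row["mean1"]), float(row["sd1"]), int(row["n1"])),
                    group_b=GroupSummary(float(row["mean2"]), float(row["sd2"]), int(row["n2"])),
                    units=(row.get("units") or "").strip(),
                )
            )
    if not out:
        raise FormatError(f"{path}: no soil parameters found")
    return out


def read_soil_raw(path: str | Path) -> list[SoilSummary]:
    """TSV with columns parameter, group, value (two groups per parameter)."""
    path = Path(path)
    by_param: dict[str, dict[str, list[float]]] = {}
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"parameter", "group", "value"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: raw table needs columns {sorted(required)}")
        for row in reader:
            by_param.setdefault(row["parameter"].strip(), {}).setdefault(
                row["group"].strip(), []
            ).append(float(row["value"]))
    out: list[SoilSummary] = []
    for param, groups in by_param.items():
        if len(groups) != 2:
            raise ValidationError(
                f"{param}: expected exactly 2 groups, got {sorted(groups)}"
            )
        (ga, va), (gb, vb) = sorted(groups.items(), reverse=True)
        out.append(SoilSummary.from_raw(param, va, vb))
    if not out:
        raise FormatError(f"{path}: no soil measurements found")
    return out


def write_anova_results(results: list[AnovaResult], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("parameter\tF\tdf1\tdf2\tp\tsignificant\twelch\tp_adjusted\n")
        for r in results:
            padj = "" if r.p_adjusted is None else repr(r.p_adjusted)
            fh.write(
                f"{r.parameter}\t{r.f!r}\t{r.df1}\t{r.df2}\t{r.p!r}\t"
                f"{int(r.significant)}\t{int(r.welch)}\t{padj}\n"
            )
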