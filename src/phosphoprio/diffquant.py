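"""Differential-phosphorylation calling from replicate isotope ratios.

Phosphoisoforms are compared between a test genotype and a control using
their per-replicate light/heavy (e.g. 14N/15N) ratios.  The caller follows
a robust two-tier "flexible filter":

1. Replicate-level ratios are median-normalized per technical replicate.
2. For each isoform with at least ``min_quant`` measurements in the test
   genotype, a control vector is assembled: the control genotype's own
   measurements if it has at least three (control-1), otherwise the pooled
   measurements of the control plus auxiliary genotypes (control-2).
3. The log2 fold change is log2(median test ratio / median control ratio).
4. The population spread of all eligible log2 fold changes is summarized
   robustly: NIQ = 0.7413 x (Q3 - Q1), a consistent estimate of the
   standard deviation for Gaussian data (0.7413 ~ 1/(2 z_0.75)).
5. An isoform is called hyper- or hypo-phosphorylated if either
   (a) its log2 fold change lies outside median +/- 1.5 x NIQ with
   one-tailed Wilcoxon rank-sum p < alpha, or
   (b) outside median +/- 1.0 x NIQ with two-tailed p < alpha.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import IsoformQuant

NIQ_FACTOR = 0.7413  # 1 / (2 * Phi^-1(0.75)); robust sigma from the IQR

#: above this total sample size the Wilcoxon test switches to the
#: tie- and continuity-corrected normal approximation
EXACT_WILCOXON_THRESHOLD = 20


@dataclass(frozen=True)
class SpreadStats:
    """Robust location/spread of a log2-fold-change distribution."""

    median: float
    q1: float
    q3: float

    @property
    def iq(self) -> float:
        return self.q3 - self.q1

    @property
    def niq(self) -> float:
        return NIQ_FACTOR * self.iq


@dataclass
class DiffCall:
    """Differential call for one phosphoisoform."""

    isoform_id: str
    log2fc: float
    p_two_sided: float
    p_one_sided: float
    direction: Literal["hyper", "hypo", "none"]
    control_tier: Literal["control-1", "control-2"]
    n_test: int
    n_control: int


class InsufficientControlError(ValueError):
    """No control measurements available for an isoform after merging."""


def normalize_replicate_ratios(ratios: Sequence[float]) -> np.ndarray:
    """Divide one technical replicate's ratio vector by its own median.

    Applied across all quantified peptides of a replicate so the replicate's
    median ratio becomes exactly 1, removing per-run mixing-ratio offsets.
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.size == 0:
        raise ValueError("empty ratio vector")
    if np.any(arr <= 0):
        raise ValueError("ratios must be positive")
    return arr / np.median(arr)


def normalize_quant_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Median-normalize a long-format quant table per (genotype, replicate).

    Each technical replicate is one MS run; its ratios across all isoforms
    are divided by their median.
    """
    out = df.copy()
    out["ratio"] = df.groupby(["genotype", "replicate"])["ratio"].transform(
        lambda v: normalize_replicate_ratios(v.to_numpy())
    )
    return out


def build_control(
    isoform: IsoformQuant,
    control_genotype: str,
    auxiliary_genotypes: Sequence[str],
    min_primary: int = 3,
) -> tuple[list[float], str]:
    """Assemble the control ratio vector for one isoform.

    Returns (ratios, tier).  If the control genotype has at least
    ``min_primary`` measurements they are used alone (control-1); if it has
    fewer, its measurements are pooled with the auxiliary genotypes'
    (control-2).  Zero measurements after pooling is an error: the isoform
    must be excluded explicitly, never silently dropped.
    """
    primary = list(isoform.ratios.get(control_genotype, []))
    if len(primary) >= min_primary:
        return primary, "control-1"
    merged = list(primary)
    for genotype in auxiliary_genotypes:
        merged.extend(isoform.ratios.get(genotype, []))
    if not merged:
        raise InsufficientControlError(
            f"{isoform.isoform_id}: no control measurements in "
            f"{control_genotype} or auxiliaries {list(auxiliary_genotypes)}"
        )
    return merged, "control-2"


def robust_spread(log2fc_values: Sequence[float]) -> SpreadStats:
    """Median, quartiles and NIQ of the log2-fold-change distribution.

    Quantiles use linear interpolation between order statistics.
    Requires at least 4 values for the quartiles to be meaningful.
    """
    arr = np.asarray(log2fc_values, dtype=float)
    if arr.size < 4:
        raise ValueError(f"need >= 4 values to estimate spread, got {arr.size}")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return SpreadStats(median=float(med), q1=float(q1), q3=float(q3))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney U) p-value for x vs y.

    Exact by enumeration over rank assignments when the pooled sample is
    small (<= EXACT_WILCOXON_THRESHOLD) and tie-free; otherwise the normal
    approximation with tie correction and continuity correction.  The
    ``greater`` alternative is that x is stochastically larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_WILCOXON_THRESHOLD and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method, use_continuity=True)
    return float(res.pvalue)


def call_regulated(
    isoform_id: str,
    log2fc: float,
    p_two_sided: float,
    p_greater: float,
    p_less: float,
    spread: SpreadStats,
    alpha: float = 0.05,
    control_tier: str = "control-1",
    n_test: int = 0,
    n_control: int = 0,
) -> DiffCall:
    """Apply the two-tier flexible filter to one isoform.

    Tier 1: |log2fc - median| beyond 1.5 x NIQ with one-tailed p < alpha in
    the matching direction.  Tier 2: beyond 1.0 x NIQ with two-tailed
    p < alpha.  Either tier suffices; insufficient evidence yields
    direction "none" rather than an error.
    """
    med, niq = spread.median, spread.niq
    direction: str = "none"
    if log2fc > med:
        if (log2fc > med + 1.5 * niq and p_greater < alpha) or (
            log2fc > med + niq and p_two_sided < alpha
        ):
            direction = "hyper"
        p_one = p_greater
    elif log2fc < med:
        if (log2fc < med - 1.5 * niq and p_less < alpha) or (
            log2fc < med - niq and p_two_sided < alpha
        ):
            direction = "hypo"
        p_one = p_less
    else:
        p_one = min(p_greater, p_less)
    return DiffCall(
        isoform_id=isoform_id,
        log2fc=log2fc,
        p_two_sided=p_two_sided,
        p_one_sided=p_one,
        direction=direction,  # type: ignore[arg-type]
        control_tier=control_tier,  # type: ignore[arg-type]
        n_test=n_test,
        n_control=n_control,
    )


def call_differential(
    isoforms: Iterable[IsoformQuant],
    test_genotype: str,
    control_genotype: str,
    auxiliary_genotypes: Sequence[str] = (),
    min_quant: int = 3,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, SpreadStats]:
    """Run the full differential-calling stage over a set of isoforms.

    Isoforms quantified fewer than ``min_quant`` times in the test genotype,
    or lacking any control measurement, are excluded (the returned frame
    contains only eligible isoforms).  Returns the per-isoform call table
    and the population spread statistics used for the thresholds.
    """
    eligible = []
    for iso in isoforms:
        test = iso.ratios.get(test_genotype, [])
        if len(test) < min_quant:
            continue
        try:
            control, tier = build_control(
                iso, control_genotype, auxiliary_genotypes, min_primary=3
            )
        except InsufficientControlError:
            continue
        log2fc = math.log2(np.median(test) / np.median(control))
        eligible.append((iso.isoform_id, test, control, tier, log2fc))

    if len(eligible) < 4:
        raise ValueError(
            f"only {len(eligible)} isoforms eligible; need >= 4 to estimate spread"
        )
    spread = robust_spread([e[4] for e in eligible])

    calls = []
    for isoform_id, test, control, tier, log2fc in eligible:
        p_two = wilcoxon_rank_sum(test, control, "two-sided")
        p_gt = wilcoxon_rank_sum(test, control, "greater")
        p_lt = wilcoxon_rank_sum(test, control, "less")
        calls.append(
            call_regulated(
                isoform_id,
                log2fc,
                p_two,
                p_gt,
                p_lt,
                spread,
                alpha=alpha,
                control_tier=tier,
                n_test=len(test),
                n_control=len(control),
            )
        )
    df = pd.DataFrame(
        {
            "isoform_id": [c.isoform_id for c in calls],
            "log2fc": [c.log2fc for c in calls],
            "p_two_sided": [c.p_two_sided for c in calls],
            "p_one_sided": [c.p_one_sided for c in calls],
            "direction": [c.direction for c in calls],
            "control_tier": [c.control_tier for c in calls],
            "n_test": [c.n_test for c in calls],
            "n_control": [c.n_control for c in calls],
        }
    )
    return df, spread


def expand_to_sites(calls: pd.DataFrame) -> pd.DataFrame:
    """Expand isoform-level calls to site-level regulated calls.

    A site is regulated if any isoform containing it is regulated.  A site
    regulated in opposite directions by different isoforms is reported once
    per direction with ``conflict`` set on both rows.
    """
    rows: dict[tuple[str, str], dict] = {}
    for row in calls.itertuples(index=False):
        if row.direction == "none":
            continue
        acc, sites = row.isoform_id.split(":", 1)
        for s in sites.split("+"):
            key = (f"{acc}:{s}", row.direction)
            prev = rows.get(key)
            # keep the most extreme supporting isoform per (site, direction)
            if prev is None or abs(row.log2fc) > abs(prev["log2fc"]):
                rows[key] = {
                    "site_id": key[0],
                    "direction": row.direction,
                    "log2fc": row.log2fc,
                    "isoform_id": row.isoform_id,
                }
    df = pd.DataFrame(rows.values(), columns=["site_id", "direction", "log2fc", "isoform_id"])
    if df.empty:
        df["conflict"] = pd.Series(dtype=bool)
        return df
    counts = df.groupby("site_id")["direction"].transform("nunique")
    df["conflict"] = counts > 1
    return df.sort_values(["site_id", "direction"]).reset_index(drop=True)


def exact_rank_sum_p(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> float:
    """Brute-force exact rank-sum p by enumerating all label assignments.

    Enumeration oracle over all C(n+m, n) ways to assign the pooled ranks to
    the first sample; intended for validation at small n, not routine use.
    Requires tie-free data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size < pooled.size:
        raise ValueError("enumeration oracle requires tie-free data")
    ranks = stats.rankdata(pooled)
    n = x.size
    observed = ranks[:n].sum()
    sums = [sum(combo) for combo in itertools.combinations(ranks, n)]
    total = len(sums)
    p_ge = sum(s >= observed for s in sums) / total
    p_le = sum(s <= observed for s in sums) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))
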