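"""Ancestor-descendant change metrics on individual branches.

For every branch of the phylogeny (terminals included), with parent and
child trait values taken from an ancestral reconstruction, three metrics
are computed:

1. change  = final - initial value (trait units),
2. absolute change = |change|,
3. rate in darwins = |ln(final/initial)| / branch duration (My).

Darwins require strictly positive initial and final values and a positive
duration; otherwise the record is flagged undefined (not zero).  SSD
(male minus female length) can be negative, so it is analysed via
arithmetic change only.

A qualitative coding turns each branch into +/-/= per sex and for SSD:
a sex-specific change below 5% of the initial value is "within
experimental error" (coded '='), and an SSD change below 5% of the total
observed SSD range is likewise coded '='.  An "all changes" mode codes
every branch +/- with no '=' category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ancestral import AncestralReconstruction
from .trees import Phylogeny, branches

__all__ = [
    "BranchChangeRecord",
    "BranchCode",
    "branch_changes",
    "ssd_range_from_reconstructions",
    "code_branches",
    "crosstab",
    "sign_binomial_test",
    "rate_difference_regression",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BranchChangeRecord:
    branch: str            # child node id identifies the branch
    trait: str
    initial: float
    final: float
    change: float
    abs_change: float
    darwins: float | None  # None when undefined (non-positive values or zero duration)
    duration: float


@dataclass(frozen=True)
class BranchCode:
    branch: str
    code_male: str
    code_female: str
    code_ssd: str
    size_threshold: float
    ssd_threshold: float  # absolute threshold in mm (fraction x SSD range)


def branch_changes(tree: Phylogeny, node_values: AncestralReconstruction) -> list[BranchChangeRecord]:
    """One change record per branch from reconstructed node values."""
    est = node_values.estimates
    missing = sorted(set(tree.node_ids) - set(est))
    if missing:
        raise ValueError(f"missing node values for: {missing}")
    out = []
    for br in branches(tree):
        x0 = float(est[br.parent])
        x1 = float(est[br.child])
        if x0 > 0 and x1 > 0 and br.duration > 0:
            dw = abs(math.log(x1 / x0)) / br.duration
        else:
            dw = None
        out.append(
            BranchChangeRecord(
                branch=br.child,
                trait=node_values.trait,
                initial=x0,
                final=x1,
                change=x1 - x0,
                abs_change=abs(x1 - x0),
                darwins=dw,
                duration=br.duration,
            )
        )
    return out


def ssd_range_from_reconstructions(
    male: AncestralReconstruction,
    female: AncestralReconstruction,
    tips_only: bool = False,
    tip_labels: list[str] | None = None,
) -> float:
    """Total range (max - min) of SSD = male - female over reconstruction nodes.

    Default uses all nodes (tips plus ancestors), the set over which the
    branch-change coding is applied; ``tips_only`` restricts to observed
    species values.
    """
    keys = set(male.estimates) & set(female.estimates)
    if tips_only:
        if tip_labels is None:
            raise ValueError("tips_only requires tip_labels")
        keys &= set(tip_labels)
    ssd = [male.estimates[k] - female.estimates[k] for k in keys]
    return float(max(ssd) - min(ssd))


def _align(records_male, records_female):
    fm = {r.branch: r for r in records_female}
    if set(fm) != {r.branch: r for r in records_male}.keys():
        raise ValueError("male and female records cover different branch sets")
    return [(m, fm[m.branch]) for m in records_male]


def code_branches(
    records_male: list[BranchChangeRecord],
    records_female: list[BranchChangeRecord],
    ssd_range: float,
    size_threshold: float = 0.05,
    ssd_threshold_fraction: float = 0.05,
    all_changes: bool = False,
) -> list[BranchCode]:
    """Qualitative +/-/= coding of each branch for male, female and SSD.

    With ``all_changes`` every branch is coded by the raw sign of its
    change (ties coded '=' only for an exactly zero change).  A zero
    ``ssd_range`` (SSD constant over all nodes) codes every SSD change
    '=' — there is no dimorphism evolution to classify.
    """
    if ssd_range < 0:
        raise ValueError("ssd_range must be non-negative")
    ssd_thr = ssd_threshold_fraction * ssd_range
    out = []
    for m, f in _align(records_male, records_female):
        d_ssd = (m.final - f.final) - (m.initial - f.initial)
        if all_changes:
            cm = "+" if m.change > 0 else ("-" if m.change < 0 else "=")
            cf = "+" if f.change > 0 else ("-" if f.change < 0 else "=")
            cs = "+" if d_ssd > 0 else ("-" if d_ssd < 0 else "=")
        else:
            cm = _code_rel(m.change, m.initial, size_threshold)
            cf = _code_rel(f.change, f.initial, size_threshold)
            if ssd_range == 0 or abs(d_ssd) < ssd_thr:
                cs = "="
            else:
                cs = "+" if d_ssd > 0 else "-"
        out.append(
            BranchCode(
                branch=m.branch,
                code_male=cm,
                code_female=cf,
                code_ssd=cs,
                size_threshold=size_threshold,
                ssd_threshold=ssd_thr,
            )
        )
    return out


def _code_rel(change: float, initial: float, threshold: float) -> str:
    if initial == 0:
        return "+" if change > 0 else ("-" if change < 0 else "=")
    if abs(change) / abs(initial) < threshold:
        return "="
    return "+" if change > 0 else "-"


def crosstab(codes: list[BranchCode]) -> pd.DataFrame:
    """Counts of branches per (female, male, SSD) code combination."""
    df = pd.DataFrame(
        {
            "lf": [c.code_female for c in codes],
            "lm": [c.code_male for c in codes],
            "ssd": [c.code_ssd for c in codes],
        }
    )
    out = (
        df.value_counts(["lf", "lm", "ssd"])
        .rename("count")
        .reset_index()
        .sort_values(["lf", "lm", "ssd"], ignore_index=True)
    )
    return out


def single_sex_ssd_counts(codes: list[BranchCode]) -> tuple[int, int]:
    """Branches where SSD changed (>threshold) driven by exactly one sex.

    Returns (male-only, female-only) counts: SSD code is +/- and exactly
    one of the sex codes is +/-.
    """
    male_only = sum(
        1
        for c in codes
        if c.code_ssd != "=" and c.code_male != "=" and c.code_female == "="
    )
    female_only = sum(
        1
        for c in codes
        if c.code_ssd != "=" and c.code_female != "=" and c.code_male == "="
    )
    return male_only, female_only


def sign_binomial_test(n_male_only: int, n_female_only: int) -> float:
    """Exact two-sided binomial p-value for equal probability of the two classes."""
    if n_male_only < 0 or n_female_only < 0:
        raise ValueError("counts must be non-negative")
    n = n_male_only + n_female_only
    if n == 0:
        raise ValueError("both counts are zero")
    return float(stats.binomtest(n_male_only, n, 0.5, alternative="two-sided").pvalue)


def rate_difference_regression(
    records_male: list[BranchChangeRecord],
    records_female: list[BranchChangeRecord],
    metric: str = "darwins",
) -> pd.DataFrame:
    """OLS of (male - female) rate difference on each sex's own rate.

    ``metric`` is ``"darwins"`` or ``"absolute"`` (absolute phenotypic
    change).  Branches with undefined darwins are dropped with a logged
    count.  Returns one row per predictor (male, female) with slope, R^2
    and p.
    """
    if metric not in ("darwins", "absolute"):
        raise ValueError(f"unknown metric {metric!r}")
    pairs = _align(records_male, records_female)
    mv, fv = [], []
    dropped = 0
    for m, f in pairs:
        if metric == "darwins":
            if m.darwins is None or f.darwins is None:
                dropped += 1
                continue
            mv.append(m.darwins)
            fv.append(f.darwins)
        else:
            mv.append(m.abs_change)
            fv.append(f.abs_change)
    if dropped:
        logger.info("rate_difference_regression: dropped %d branches with undefined darwins", dropped)
    mv = np.asarray(mv)
    fv = np.asarray(fv)
    if len(mv) < 3:
        raise ValueError("fewer than 3 usable branches")
    diff = mv - fv
    rows = []
    for name, x in (("male", mv), ("female", fv)):
        if np.ptp(x) == 0:  # degenerate predictor: fit undefined
            slope, r2, p = np.nan, np.nan, np.nan
        elif np.ptp(diff) == 0:  # constant response: flat fit
            slope, r2, p = 0.0, 0.0, 1.0
        else:
            fit = stats.linregress(x, diff)
            slope, r2, p = fit.slope, fit.rvalue**2, fit.pvalue
        rows.append(
            {
                "metric": metric,
                "predictor": name,
                "n": len(x),
                "slope": slope,
                "r2": r2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
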