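"""Normality-gated group comparisons for chip-level metrics.

The workflow mirrors common practice in the organ-on-chip literature:
each group is checked for normality (Shapiro–Wilk at α = 0.05); if every
group passes, a one-way ANOVA with Dunnett's control-vs-each post hoc is
used, otherwise a Kruskal–Wallis test with Dunn's post hoc (Holm-adjusted
by default).  Two-group comparisons use the two-tailed unpaired Student's
t-test.  The branch taken is always recorded so analyses are auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .calcium import InvalidParameterError

__all__ = ["ComparisonResult", "compare_to_control", "two_group_test", "dunn_test"]


@dataclass
class ComparisonResult:
    test_name: str
    global_p: float
    comparisons: dict[str, float]  # group label -> adjusted p vs control
    normality_passed: dict[str, bool]
    alpha: float = 0.05
    flags: list[str] = field(default_factory=list)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def dunn_test(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    adjust: str = "holm",
) -> dict[str, float]:
    """Dunn's rank-based post hoc, control vs every other group.

    Uses pooled mid-ranks with the standard tie correction
    Σ(tᵏ³ − tᵏ)/(12(N−1)) and two-sided normal p-values, multiplicity
    adjusted (Holm by default).
    """
    g = _as_groups(groups)
    labels = list(g)
    pooled = np.concatenate([g[k] for k in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for k in labels:
        n = g[k].size
        mean_ranks[k] = ranks[i : i + n].mean()
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    others = [k for k in labels if k != control_label]
    raw = []
    for k in others:
        se = np.sqrt(var_base * (1.0 / g[control_label].size + 1.0 / g[k].size))
        z = (mean_ranks[k] - mean_ranks[control_label]) / se
        raw.append(2.0 * sps.norm.sf(abs(z)))
    if adjust is None or adjust == "none":
        adj = raw
    else:
        adj = multipletests(raw, method=adjust)[1]
    return dict(zip(others, map(float, adj)))


def compare_to_control(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Normality-gated multi-group comparison against a control group.

    All groups normal (Shapiro–Wilk, α = 0.05) → one-way ANOVA with
    Dunnett's post hoc; any group non-normal → Kruskal–Wallis with Dunn's
    post hoc (Holm-adjusted).
    """
    g = _as_groups(groups)
    if control_label not in g:
        raise InvalidParameterError(f"control label {control_label!r} not among groups")
    if len(g) < 2:
        raise InvalidParameterError("need at least two groups")
    for k, v in g.items():
        if v.size < 3:
            raise InvalidParameterError(f"group {k!r} has n < 3")

    normality: dict[str, bool] = {}
    flags: list[str] = []
    for k, v in g.items():
        if np.ptp(v) == 0:
            normality[k] = False
            flags.append(f"group {k!r} is constant; treated as non-normal")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality[k] = bool(sps.shapiro(v).pvalue > 0.05)

    others = [k for k in g if k != control_label]
    samples = [g[k] for k in others]
    if all(normality.values()):
        global_p = float(sps.f_oneway(*g.values()).pvalue)
        # fixed random_state: Dunnett's p-values come from Monte-Carlo
        # integration of the multivariate t; seeding makes reruns identical
        res = sps.dunnett(
            *samples, control=g[control_label], random_state=np.random.default_rng(0)
        )
        comparisons = dict(zip(others, map(float, np.atleast_1d(res.pvalue))))
        name = "one-way ANOVA + Dunnett"
    else:
        global_p = float(sps.kruskal(*g.values()).pvalue)
        comparisons = dunn_test(g, control_label, adjust="holm")
        name = "Kruskal-Wallis + Dunn (Holm)"
    return ComparisonResult(
        test_name=name,
        global_p=global_p,
        comparisons=comparisons,
        normality_passed=normality,
        alpha=alpha,
        flags=flags,
    )


def two_group_test(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-tailed unpaired Student's t-test (pooled variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each group needs n >= 2")
    flags: list[str] = []
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        flags.append("zero variance in both groups with equal means; p = 1 by convention")
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(
        test_name="two-tailed unpaired t-test",
        global_p=float(p),
        comparisons={"b_vs_a": float(p)},
        normality_passed={},
        flags=flags,
    )
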