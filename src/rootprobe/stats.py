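"""Statistical reporting: one-way ANOVA with Fisher LSD letters, pooled
two-sample t-test, and TPM expression summaries.

Group comparisons follow the classical agronomy workflow: a one-way ANOVA
with a pooled within-group mean square, followed by Fisher's least
significant difference (LSD) pairwise t-tests on the pooled error, displayed
as compact letters — two groups share a letter iff their pairwise comparison
is non-significant at α.  The LSD is *protected* by default (pairwise
differences are only declared when the omnibus F-test rejects), since that is
the conservative convention; the unprotected variant and an optional Holm
correction are switchable.  Letters are assigned in ascending-mean order
starting at "a" via the insert-absorb algorithm.

Normality screening (Shapiro–Wilk) is reported alongside but never blocks an
analysis: it is a gatekeeping diagnostic, not part of the inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSamples",
    "AnovaLsdResult",
    "anova_fisher_lsd",
    "compact_letter_display",
    "two_sample_t",
    "tpm",
]


@dataclass(frozen=True)
class GroupSamples:
    """One labelled sample group (n ≥ 2 finite values)."""

    group_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError(f"group {self.group_label!r} needs ≥ 2 values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.group_label!r} has non-finite values")


@dataclass
class AnovaLsdResult:
    """Omnibus ANOVA + Fisher LSD pairwise comparisons + letter display."""

    F: float
    p_omnibus: float
    df_between: int
    df_within: int
    mse: float
    means: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float
    protected: bool
    shapiro_p: dict[str, float] = field(default_factory=dict)


def _one_way_anova(groups: list[GroupSamples]) -> tuple[float, float, int, int, float]:
    """Omnibus F from sums of squares with the pooled within-group MSE."""
    all_vals = np.concatenate([g.values for g in groups])
    grand = all_vals.mean()
    ss_between = sum(g.values.size * (g.values.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g.values - g.values.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    mse = ss_within / df_w
    if mse == 0.0:
        # all groups internally constant; F is 0 (identical means) or infinite
        f = 0.0 if ss_between == 0 else np.inf
    else:
        f = (ss_between / df_b) / mse
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return float(f), p, df_b, df_w, float(mse)


def _lsd_pairwise_p(a: GroupSamples, b: GroupSamples, mse: float, df_w: int) -> float:
    """Two-sided p of the LSD t-test on the pooled error."""
    se = np.sqrt(mse * (1.0 / a.values.size + 1.0 / b.values.size))
    diff = a.values.mean() - b.values.mean()
    if se == 0.0:
        return 1.0 if diff == 0 else 0.0
    t = diff / se
    return float(2.0 * sps.t.sf(abs(t), df_w))


def compact_letter_display(
    labels: list[str],
    means: dict[str, float],
    significant: dict[tuple[str, str], bool],
) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Produces, for each group, a string of letters such that two groups share
    a letter iff their pairwise difference is **not** significant.  Letters
    are issued in ascending-mean order starting at "a".
    """
    order = sorted(labels, key=lambda g: means[g])

    def is_sig(a: str, b: str) -> bool:
        return significant.get((a, b), significant.get((b, a), False))

    # letter groups are maximal sets of mutually non-different groups
    letter_sets: list[set[str]] = [set(order)]
    for a, b in itertools.combinations(order, 2):
        if not is_sig(a, b):
            continue
        split: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                split.extend((s - {a}, s - {b}))
            else:
                split.append(s)
        # absorb: drop empties, duplicates, and sets contained in another
        letter_sets = []
        for s in split:
            if not s or any(s <= t for t in letter_sets):
                continue
            letter_sets = [t for t in letter_sets if not t < s]
            letter_sets.append(s)
    # order letters by the smallest mean they cover
    letter_sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in labels}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in labels}


def anova_fisher_lsd(
    groups: list[GroupSamples],
    alpha: float = 0.05,
    protected: bool = True,
    holm: bool = False,
) -> AnovaLsdResult:
    """One-way ANOVA with Fisher LSD pairwise comparisons and letters.

    With ``protected=True`` (default) pairwise differences are only declared
    when the omnibus test rejects at α; otherwise every pairwise LSD test is
    interpreted directly.  ``holm=True`` applies a Holm step-down correction
    to the pairwise p-values before letter assignment (off by default — plain
    LSD applies no multiplicity correction beyond the omnibus protection).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs ≥ 2 groups")
    labels = [g.group_label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")

    f, p_omni, df_b, df_w, mse = _one_way_anova(groups)
    means = {g.group_label: float(g.values.mean()) for g in groups}
    by_label = {g.group_label: g for g in groups}

    pairwise: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(labels, 2):
        pairwise[(a, b)] = _lsd_pairwise_p(by_label[a], by_label[b], mse, df_w)

    p_adj = dict(pairwise)
    if holm:
        items = sorted(pairwise.items(), key=lambda kv: kv[1])
        m = len(items)
        running = 0.0
        for i, (pair, p) in enumerate(items):
            running = max(running, min(1.0, (m - i) * p))
            p_adj[pair] = running

    omnibus_rejects = p_omni <= alpha
    significant = {
        pair: (p <= alpha) and (omnibus_rejects or not protected)
        for pair, p in p_adj.items()
    }
    letters = compact_letter_display(labels, means, significant)

    shapiro = {}
    for g in groups:
        if np.ptp(g.values) > 0 and g.values.size >= 3:
            shapiro[g.group_label] = float(sps.shapiro(g.values).pvalue)
        else:
            shapiro[g.group_label] = float("nan")

    return AnovaLsdResult(
        F=f, p_omnibus=p_omni, df_between=df_b, df_within=df_w, mse=mse,
        means=means, pairwise_p=p_adj, letters=letters, alpha=alpha,
        protected=protected, shapiro_p=shapiro,
    )


def two_sample_t(a, b, alpha: float = 0.05) -> tuple[float, int, float, str]:
    """Pooled-variance two-sided two-sample t-test.

    Returns (t, df, p, verdict) with verdict "significant" or
    "not significant" at α.  Two identical constant samples give t = 0,
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n ≥ 2")
    df = a.size + b.size - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if sp2 == 0.0:
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
        t = float((a.mean() - b.mean()) / se)
        p = float(2.0 * sps.t.sf(abs(t), df))
    verdict = "significant" if p <= alpha else "not significant"
    return float(t), int(df), p, verdict


def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million from read counts and transcript lengths.

    TPM_i = 10⁶ · (c_i/l_i) / Σ_j (c_j/l_j).  Length-normalised within-sample
    abundances that always sum to 10⁶.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must align")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("TPM undefined: all counts are zero")
    return 1e6 * rate / total
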