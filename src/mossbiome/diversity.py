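"""Alpha-diversity indices and pairwise group tests with letter displays.

Diversity is summarized by the inverse Simpson index (effective number of
equally abundant OTUs) and OTU richness. Group contrasts use pairwise
Mann-Whitney-Wilcoxon rank-sum tests (diversity indices) or pairwise
t-tests with a pooled standard deviation (environmental variables), with
Holm adjustment by default, and are rendered as a compact letter display:
groups that share no letter differ at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupTestResult",
    "inverse_simpson",
    "richness",
    "diversity_frame",
    "pairwise_wilcoxon",
    "pairwise_ttest",
    "compact_letter_display",
]


@dataclass
class GroupTestResult:
    """Pairwise p-value matrix over groups plus a compact letter display."""

    groups: tuple[str, ...]
    p_matrix: np.ndarray  # symmetric, NaN diagonal, adjusted p-values
    raw_p_matrix: np.ndarray
    adjustment: str
    letters: dict[str, str]
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_matrix, index=self.groups, columns=self.groups)


def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum(p_i^2) of one sample's counts.

    Equals k for k equally abundant OTUs and 1 for a single-OTU sample.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no defined diversity")
    p = c / total
    return float(1.0 / np.sum(p**2))


def richness(counts) -> int:
    """Number of OTUs with a strictly positive count."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def diversity_frame(table) -> pd.DataFrame:
    """Per-sample inverse Simpson and richness for an OtuTable."""
    rows = {
        s: {
            "inverse_simpson": inverse_simpson(table.counts[:, j]),
            "richness": richness(table.counts[:, j]),
        }
        for j, s in enumerate(table.sample_ids)
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def _split_groups(values, group_labels, min_n: int = 2):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if len(values) != len(labels):
        raise ValueError("values and group_labels differ in length")
    groups = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: values[labels == g] for g in groups}
    for g, v in data.items():
        if len(v) < min_n:
            raise ValueError(f"group {g!r} has fewer than {min_n} observations")
    return groups, data


def _adjust(raw: np.ndarray, k: int, method: str) -> np.ndarray:
    iu = np.triu_indices(k, 1)
    flat = raw[iu]
    if method == "holm":
        adj = multipletests(flat, method="holm")[1]
    elif method == "none":
        adj = flat
    else:
        raise ValueError(f"unknown adjustment: {method!r}")
    out = np.full((k, k), np.nan)
    out[iu] = adj
    out.T[iu] = adj
    return out


def pairwise_wilcoxon(
    values, group_labels, adjust: str = "holm", alpha: float = 0.05
) -> GroupTestResult:
    """Pairwise two-sided Mann-Whitney-Wilcoxon rank-sum tests.

    Each pair uses the exact null distribution when both groups have at
    most 50 observations and the pooled values contain no ties, and the
    normal approximation with tie correction (and continuity correction)
    otherwise.
    """
    groups, data = _split_groups(values, group_labels)
    k = len(groups)
    raw = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = data[groups[i]], data[groups[j]]
            has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            if len(a) <= 50 and len(b) <= 50 and not has_ties:
                method = "exact"
            else:
                method = "asymptotic"
            raw[i, j] = raw[j, i] = stats.mannwhitneyu(
                a, b, alternative="two-sided", method=method
            ).pvalue
    adj = _adjust(raw, k, adjust)
    letters = compact_letter_display(adj, alpha=alpha, groups=groups)
    return GroupTestResult(tuple(groups), adj, raw, adjust, letters, alpha)


def pairwise_ttest(
    values,
    group_labels,
    adjust: str = "holm",
    pooled_sd: bool = True,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Pairwise two-sided t-tests.

    With ``pooled_sd=True`` (default) the standard deviation is pooled
    across *all* groups and every comparison uses N - k degrees of
    freedom; otherwise each pair is tested with Welch's t.
    """
    groups, data = _split_groups(values, group_labels)
    k = len(groups)
    raw = np.full((k, k), np.nan)
    if pooled_sd:
        ns = np.array([len(data[g]) for g in groups])
        means = np.array([np.mean(data[g]) for g in groups])
        ss = sum(np.sum((data[g] - means[i]) ** 2) for i, g in enumerate(groups))
        df = int(ns.sum() - k)
        if df <= 0 or ss <= 0:
            raise ValueError("zero pooled variance")
        sp = np.sqrt(ss / df)
        for i in range(k):
            for j in range(i + 1, k):
                se = sp * np.sqrt(1 / ns[i] + 1 / ns[j])
                t = (means[i] - means[j]) / se
                raw[i, j] = raw[j, i] = 2 * stats.t.sf(abs(t), df)
    else:
        for i in range(k):
            for j in range(i + 1, k):
                raw[i, j] = raw[j, i] = stats.ttest_ind(
                    data[groups[i]], data[groups[j]], equal_var=False
                ).pvalue
    adj = _adjust(raw, k, adjust)
    letters = compact_letter_display(adj, alpha=alpha, groups=groups)
    return GroupTestResult(tuple(groups), adj, raw, adjust, letters, alpha)


def compact_letter_display(
    p_matrix, alpha: float = 0.05, groups=None
) -> dict[str, str]:
    """Assign letters so groups sharing a letter are *not* significantly
    different (p >= alpha) and groups sharing no letter are (p < alpha).

    Greedy insert-absorb: letters are introduced per significant pair and
    redundant letters absorbed. The assignment is consistent but not
    guaranteed minimal in the number of letters.
    """
    p = np.asarray(p_matrix, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("p_matrix must be square")
    off = ~np.eye(p.shape[0], dtype=bool)
    if not np.allclose(
        np.where(np.isnan(p), -1.0, p), np.where(np.isnan(p.T), -1.0, p.T)
    ):
        raise ValueError("p_matrix must be symmetric")
    k = p.shape[0]
    if groups is None:
        groups = [str(i) for i in range(k)]
    sig = (p < alpha) & off & ~np.isnan(p)

    # letter sets: each is a frozenset of group indices forming a
    # "no significant difference" clique; start with one letter for all
    letter_sets: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_sets: list[set[int]] = []
            for s in letter_sets:
                if i in s and j in s:
                    new_sets.append(s - {j})
                    new_sets.append(s - {i})
                else:
                    new_sets.append(s)
            # absorb duplicates / subsets
            letter_sets = []
            for s in sorted(new_sets, key=len, reverse=True):
                if s and not any(s <= t for t in letter_sets):
                    letter_sets.append(s)
    # groups that lost every letter (isolated) get their own
    for i in range(k):
        if not any(i in s for s in letter_sets):
            letter_sets.append({i})
    # deterministic ordering by smallest member
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for li, s in enumerate(letter_sets):
        ch = alphabet[li % 26] * (li // 26 + 1)
        for i in sorted(s):
            out[groups[i]] += ch
    return out
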