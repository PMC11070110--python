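"""Differential expression between polarization states.

Two contrasts are run, M0-vs-M1 and M2-vs-M1, each reporting a log2
fold change oriented so that positive means "higher in M1" (the sign
convention under which TNF, IL6 and IL1B come out up-regulated), a
Welch unequal-variance t statistic on log2 intensities, and
Benjamini-Hochberg adjusted p-values.  A gene is called a hit when its
adjusted p falls below alpha in *both* contrasts and, by default, the
two fold changes agree in direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientSamplesError, ValidationError
from .expression import ExpressionMatrix

log = logging.getLogger(__name__)

CONTRASTS = {"M0_vs_M1": "M0", "M2_vs_M1": "M2"}  # contrast name -> reference condition


def compute_logfc(
    expr: ExpressionMatrix,
    numerator_condition: str,
    reference_condition: str,
    pseudocount: float | None = None,
) -> pd.Series:
    """Per-gene log2 fold change of linear-scale group means.

    logFC = log2((mean_num + eps) / (mean_ref + eps)) with a small
    pseudocount eps (default 1e-9 x global mean intensity) that keeps
    the ratio finite for all-zero genes.  Swapping the two conditions
    negates the result.
    """
    linear = expr.linear_values()
    mean_num = linear[expr.samples_for(numerator_condition)].mean(axis=1)
    mean_ref = linear[expr.samples_for(reference_condition)].mean(axis=1)
    if pseudocount is None:
        pseudocount = 1e-9 * float(linear.to_numpy().mean())
    if pseudocount == 0 and ((mean_num == 0) | (mean_ref == 0)).any():
        raise ValidationError("all-zero gene with zero pseudocount gives infinite logFC")
    out = np.log2(mean_num + pseudocount) - np.log2(mean_ref + pseudocount)
    out.name = "logFC"
    return out


def two_sample_test(
    expr: ExpressionMatrix, condition_a: str, condition_b: str
) -> pd.DataFrame:
    """Welch two-sided t-test per gene on log2 values (a minus b).

    Returns a frame with columns ``t``, ``p`` and ``degenerate``.
    Degenerate genes are those where both groups have zero variance:
    equal means give t = 0, p = 1; unequal means give an infinite t and
    the smallest positive p, flagged so downstream users can see them.
    """
    values = expr.log2_values()
    a = values[expr.samples_for(condition_a)].to_numpy(dtype=float)
    b = values[expr.samples_for(condition_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise InsufficientSamplesError(
            f"need >= 2 samples per group ({condition_a}: {a.shape[1]}, "
            f"{condition_b}: {b.shape[1]})"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    diff = a.mean(axis=1) - b.mean(axis=1)
    both_flat = (var_a == 0) & (var_b == 0)
    flat_equal = both_flat & (diff == 0)
    flat_unequal = both_flat & (diff != 0)
    t = np.where(flat_equal, 0.0, t)
    p = np.where(flat_equal, 1.0, p)
    t = np.where(flat_unequal, np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(flat_unequal, np.nextafter(0.0, 1.0), p)
    if flat_unequal.any():
        log.warning(
            "%d gene(s) with zero variance in both groups but unequal means",
            int(flat_unequal.sum()),
        )
    return pd.DataFrame(
        {"t": t, "p": p, "degenerate": both_flat}, index=values.index
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order
    statistics, capped at 1 and mapped back to the input order.  The
    output is monotone in the p-value ranks and never below the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and within [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    # floor at the raw p: mathematically implied by the step-up formula
    # (m/j >= 1 for j <= m) but lost to rounding in m*p/j for j = m
    q_sorted = np.maximum(q_sorted, p[order])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


@dataclass
class DegResult:
    """Outcome of the two-contrast differential-expression stage."""

    tables: dict[str, pd.DataFrame]
    intersection: frozenset[str]
    alpha: float
    discordant: frozenset[str] = field(default_factory=frozenset)

    def significant(self, contrast: str) -> frozenset[str]:
        table = self.tables[contrast]
        return frozenset(table.index[table["significant"]])

    def combined_frame(self) -> pd.DataFrame:
        """All contrasts stacked in the on-disk DegTable layout."""
        frames = []
        for contrast, table in sorted(self.tables.items()):
            frame = table.reset_index()
            frame.insert(1, "contrast", contrast)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


def run_contrasts(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    direction_concordance: bool = True,
    pseudocount: float | None = None,
) -> DegResult:
    """Run both polarization contrasts and intersect the hit lists.

    Each contrast has M1 in the numerator/first group, so logFC and t
    are both positive for genes up in M1.  The intersection contains
    genes significant (p_adj < alpha) in both contrasts; with
    ``direction_concordance`` (default) genes whose fold changes
    disagree in sign between the contrasts are additionally excluded.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    tables: dict[str, pd.DataFrame] = {}
    for contrast, reference in CONTRASTS.items():
        logfc = compute_logfc(expr, "M1", reference, pseudocount=pseudocount)
        test = two_sample_test(expr, "M1", reference)
        p_adj = bh_adjust(test["p"].to_numpy())
        tables[contrast] = pd.DataFrame(
            {
                "logFC": logfc,
                "t": test["t"],
                "p_raw": test["p"],
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            },
            index=expr.genes,
        )
    sig_sets = [frozenset(t.index[t["significant"]]) for t in tables.values()]
    common = frozenset.intersection(*sig_sets)
    discordant: frozenset[str] = frozenset()
    if direction_concordance:
        signs = {
            c: np.sign(tables[c].loc[sorted(common), "logFC"]) for c in tables
        }
        agree = signs["M0_vs_M1"] * signs["M2_vs_M1"] > 0
        discordant = frozenset(agree.index[~agree])
        common = frozenset(agree.index[agree])
        if discordant:
            log.warning("%d gene(s) dropped for discordant fold-change signs", len(discordant))
    if not common:
        log.warning("empty DEG intersection; downstream stages will see no mRNA support")
    return DegResult(tables=tables, intersection=common, alpha=alpha, discordant=discordant)
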