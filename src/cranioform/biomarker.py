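"""Small-sample expression and proliferation statistics.

Covers the statistical side of a ddPCR expression comparison between
trisomic and euploid littermates and of EdU/PH3/Hoechst cell-count assays:

* a test-selection cascade — Shapiro-Wilk normality on each group, then an
  F-test for variance equality choosing between the pooled two-tailed
  unpaired t-test and Welch's t-test, with a Mann-Whitney U fallback when
  normality is rejected;
* the trisomic/euploid mean expression ratio (1.5 is the naive three-copy
  dosage expectation);
* the proliferation index (% EdU-positive of Hoechst-labeled total) and
  the mitotic ratio between EdU- and PH3-positive counts, whose
  orientation must be chosen explicitly.

Droplet-level ddPCR processing and image segmentation are upstream of this
module; inputs are per-animal concentration ratios and per-section counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TESTS = ("t_test", "welch", "mann_whitney")
MITOTIC_CONVENTIONS = ("ph3_over_edu", "edu_over_ph3")


class BiomarkerError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionSample:
    """Per-animal target/housekeeping concentration ratios for one gene."""

    gene: str
    group: str  # "euploid" or "trisomic"
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise BiomarkerError(f"{self.gene}/{self.group}: values must be finite and > 0")


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the test-selection cascade for one two-group comparison."""

    test_used: str
    p_value: float
    normality_p: tuple[float, float]  # (reference group, test group)
    variance_p: float | None
    alpha: float
    group_means: tuple[float, float]
    ratio: float  # test-group mean / reference-group mean

    def replay_branch(self) -> str:
        """Re-derive the branch from the recorded p-values (audit helper)."""
        if min(self.normality_p) < self.alpha:
            return "mann_whitney"
        assert self.variance_p is not None
        return "t_test" if self.variance_p >= self.alpha else "welch"


@dataclass(frozen=True)
class CellCounts:
    """EdU / PH3 / Hoechst counts for one section or region."""

    edu_pos: int
    ph3_pos: int
    hoechst_total: int
    region: str = ""

    def __post_init__(self) -> None:
        if self.hoechst_total <= 0:
            raise BiomarkerError("hoechst_total must be > 0")
        if not (0 <= self.edu_pos <= self.hoechst_total):
            raise BiomarkerError("edu_pos must be in [0, hoechst_total]")
        if not (0 <= self.ph3_pos <= self.hoechst_total):
            raise BiomarkerError("ph3_pos must be in [0, hoechst_total]")


def _f_test_equal_variance(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test of equal variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va <= 0 and vb <= 0:
        return 1.0
    if vb <= 0 or va <= 0:
        return 0.0
    f = va / vb
    p = stats.f.sf(f, len(a) - 1, len(b) - 1)
    return float(min(1.0, 2.0 * min(p, 1.0 - p)))


def select_and_test(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> ComparisonResult:
    """Two-group location comparison with the pre-test cascade.

    ``a`` is the reference (euploid) group and ``b`` the test (trisomic)
    group. Shapiro-Wilk is run on each group at ``alpha``; if both pass,
    an F-test for variance equality selects the pooled two-tailed unpaired
    t-test (equal variances) or Welch's t-test; if either group fails
    normality, a two-sided Mann-Whitney U test is used instead and flagged
    in ``test_used``. All intermediate p-values are recorded so the branch
    choice can be replayed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise BiomarkerError(
            f"insufficient sample: need n >= 3 per group, got {len(a)} and {len(b)}"
        )
    norm_a = float(stats.shapiro(a).pvalue)
    norm_b = float(stats.shapiro(b).pvalue)
    variance_p: float | None = None
    if norm_a >= alpha and norm_b >= alpha:
        variance_p = _f_test_equal_variance(a, b)
        if variance_p >= alpha:
            test_used = "t_test"
            p_value = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        else:
            test_used = "welch"
            p_value = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        test_used = "mann_whitney"
        p_value = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if np.isnan(p_value):  # zero variance in both groups with equal means
        p_value = 1.0 if np.mean(a) == np.mean(b) else 0.0
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    return ComparisonResult(
        test_used=test_used,
        p_value=p_value,
        normality_p=(norm_a, norm_b),
        variance_p=variance_p,
        alpha=alpha,
        group_means=(mean_a, mean_b),
        ratio=mean_b / mean_a,
    )


def expression_ratio(trisomic: Sequence[float], euploid: Sequence[float]) -> float:
    """Relative expression: mean(trisomic) / mean(euploid)."""
    trisomic = np.asarray(trisomic, dtype=float)
    euploid = np.asarray(euploid, dtype=float)
    if trisomic.size == 0 or euploid.size == 0:
        raise BiomarkerError("both groups must be non-empty")
    return float(trisomic.mean() / euploid.mean())


def proliferation_index(counts: CellCounts) -> float:
    """Percentage of EdU-positive cells among Hoechst-labeled cells."""
    return 100.0 * counts.edu_pos / counts.hoechst_total


def mitotic_index(counts: CellCounts, convention: str) -> float:
    """Ratio between EdU- and PH3-positive counts (S-phase vs G2/M progression).

    The orientation is ambiguous in common usage, so ``convention`` is
    mandatory: ``"ph3_over_edu"`` or ``"edu_over_ph3"``.
    """
    if convention not in MITOTIC_CONVENTIONS:
        raise BiomarkerError(
            f"convention must be one of {MITOTIC_CONVENTIONS}, got {convention!r}"
        )
    num, den = (
        (counts.ph3_pos, counts.edu_pos)
        if convention == "ph3_over_edu"
        else (counts.edu_pos, counts.ph3_pos)
    )
    if den == 0:
        raise BiomarkerError(f"zero denominator under convention {convention!r}")
    return num / den


def compare_expression_table(
    df: pd.DataFrame,
    alpha: float = 0.05,
    reference_group: str = "euploid",
    holm: bool = False,
) -> pd.DataFrame:
    """Per-gene cascade comparison from a tidy table.

    Expects columns ``gene, group, value`` (extra columns ignored); the
    non-reference group is treated as the test (trisomic) group. With
    ``holm=True`` a Holm step-down adjustment across genes is appended
    (off by default; per-gene significance is reported as-is otherwise).
    """
    required = {"gene", "group", "value"}
    if not required.issubset(df.columns):
        raise BiomarkerError(f"table must have columns {sorted(required)}")
    rows = []
    for gene, sub in df.groupby("gene", sort=False):
        groups = sub["group"].unique()
        test_groups = [g for g in groups if g != reference_group]
        if reference_group not in groups or len(test_groups) != 1:
            raise BiomarkerError(
                f"gene {gene!r}: need exactly reference {reference_group!r} plus one test group"
            )
        a = sub.loc[sub["group"] == reference_group, "value"].to_numpy(float)
        b = sub.loc[sub["group"] == test_groups[0], "value"].to_numpy(float)
        res = select_and_test(a, b, alpha=alpha)
        rows.append(
            {
                "gene": gene,
                "test_used": res.test_used,
                "p_value": res.p_value,
                "normality_p_reference": res.normality_p[0],
                "normality_p_test": res.normality_p[1],
                "variance_p": res.variance_p,
                "mean_reference": res.group_means[0],
                "mean_test": res.group_means[1],
                "ratio": res.ratio,
            }
        )
    out = pd.DataFrame(rows)
    if holm:
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adjusted[idx] = min(1.0, running)
        out["p_holm"] = adjusted
    return out
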