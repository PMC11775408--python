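"""Paired cohort statistics: median/IQR, Wilcoxon signed-rank, Bland-Altman.

The cohort design is paired: every subject contributes one lesion measured
under two acquisition conditions ("highquality" vs "clinical"). Differences
are taken as ``highquality - clinical`` throughout. All tests are
two-sided, markers are tested at a common significance level without
multiple-testing correction (five markers), and the ten-cm³ sensitivity
analysis drops a subject when EITHER condition falls below threshold so the
paired design stays intact.

The Wilcoxon signed-rank implementation drops zero differences (classical
treatment), uses mid-ranks for ties, reports ``W = min(W+, W-)`` and an
exact two-sided p-value by full enumeration of the 2^n sign assignments
(via a rank-sum convolution, identical result) for n_eff <= 25; beyond
that a normal approximation with tie and continuity correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import (
    CohortError,
    DegenerateDifferencesError,
    StatsDomainError,
)
from .markers import MARKER_NAMES

EXACT_LIMIT = 25
MIN_PAIRS_FOR_P = 5


# -- elementary summaries ---------------------------------------------------


def median_iqr(values: Iterable[float]) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile) by linear interpolation.

    The inclusive linear-interpolation convention is used (numpy default);
    IQR endpoints differ across conventions at small n, so the choice is
    fixed here and recorded in report metadata.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise StatsDomainError("median of an empty sample")
    if not np.all(np.isfinite(v)):
        raise StatsDomainError("non-finite values in sample")
    med, q25, q75 = np.percentile(v, [50, 25, 75])
    return float(med), float(q25), float(q75)


# -- Wilcoxon signed-rank ---------------------------------------------------


@dataclass
class WilcoxonResult:
    statistic: float          # W = min(W+, W-)
    pvalue: float | None      # None when too few non-zero differences
    n_effective: int
    w_plus: float
    w_minus: float
    method: str               # "exact" | "normal-approx" | "too-few-pairs"


def _exact_two_sided_p(ranks: np.ndarray, w_min: float) -> float:
    """P(min(W+, W-) <= w_min) under random signs, by convolution.

    Ranks may be mid-ranks (k + 0.5); doubling makes them integers so the
    distribution of 2*W+ lives on an integer lattice. The convolution
    enumerates all 2^n sign assignments exactly. The null distribution of
    W+ is symmetric about T/2 even under ties, so the two-sided p is
    2 * P(W+ <= w_min), capped at 1.
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist += shifted
    dist /= 2.0 ** len(r2)
    w2 = int(np.floor(round(2 * w_min, 6) + 1e-9))
    return float(min(1.0, 2.0 * dist[: w2 + 1].sum()))


def _approx_two_sided_p(ranks: np.ndarray, w_min: float) -> float:
    """Normal approximation with tie variance and continuity correction."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise DegenerateDifferencesError("zero variance: all ranks tied away")
    z = (w_min - mu + 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.cdf(z)))


def wilcoxon_signed_rank(a, b=None) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Parameters
    ----------
    a, b
        Either two equal-length sequences of paired measurements, or a
        single (n, 2) array of pairs. Differences are ``a - b``.

    Raises
    ------
    DegenerateDifferencesError
        If every difference is exactly zero.
    """
    if b is None:
        pairs = np.asarray(a, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise StatsDomainError("pairs must be an (n, 2) array")
        a, b = pairs[:, 0], pairs[:, 1]
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise StatsDomainError("paired samples must be equal-length vectors")
    d = a - b
    d = d[d != 0]
    n_eff = int(d.size)
    if n_eff == 0:
        raise DegenerateDifferencesError(
            "all paired differences are zero"
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n_eff < MIN_PAIRS_FOR_P:
        return WilcoxonResult(w, None, n_eff, w_plus, w_minus,
                              "too-few-pairs")
    if n_eff <= EXACT_LIMIT:
        p = _exact_two_sided_p(ranks, w)
        method = "exact"
    else:
        p = _approx_two_sided_p(ranks, w)
        method = "normal-approx"
    return WilcoxonResult(w, p, n_eff, w_plus, w_minus, method)


# -- Bland-Altman -----------------------------------------------------------


@dataclass
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def bland_altman(a, b=None) -> BlandAltman:
    """Agreement statistics: mean difference and ±1.96 SD limits.

    The limits of agreement bracket the range most differences fall into;
    the standard deviation uses the n-1 denominator.
    """
    if b is None:
        pairs = np.asarray(a, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise StatsDomainError("pairs must be an (n, 2) array")
        a, b = pairs[:, 0], pairs[:, 1]
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if d.size < 2:
        raise StatsDomainError("Bland-Altman needs at least 2 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean, mean - 1.96 * sd, mean + 1.96 * sd, sd,
                       int(d.size))


# -- cohort tables ----------------------------------------------------------

PAIRED_COLUMNS = ("subject_id", "marker", "value_highquality",
                  "value_clinical")


def validate_paired_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format paired cohort table invariants."""
    missing = set(PAIRED_COLUMNS) - set(table.columns)
    if missing:
        raise CohortError(f"paired table missing columns {sorted(missing)}")
    if table.duplicated(["subject_id", "marker"]).any():
        raise CohortError("duplicate subject x marker rows")
    vals = table[["value_highquality", "value_clinical"]].to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise CohortError("non-finite marker values in paired table")
    return table


def paired_table_from_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Long paired table from a wide per-subject x condition marker frame.

    ``markers`` must have columns ``subject_id``, ``condition`` (values
    ``highquality`` / ``clinical``) and one column per marker name.
    Subjects lacking either condition are dropped.
    """
    required = {"subject_id", "condition"}
    if not required <= set(markers.columns):
        raise CohortError("marker frame needs subject_id and condition")
    rows = []
    present = [m for m in MARKER_NAMES if m in markers.columns]
    for sid, grp in markers.groupby("subject_id", sort=True):
        conds = set(grp["condition"])
        if not {"highquality", "clinical"} <= conds:
            continue
        hq = grp[grp["condition"] == "highquality"].iloc[0]
        cl = grp[grp["condition"] == "clinical"].iloc[0]
        for m in present:
            if pd.notna(hq[m]) and pd.notna(cl[m]):
                rows.append((sid, m, float(hq[m]), float(cl[m])))
    table = pd.DataFrame(rows, columns=list(PAIRED_COLUMNS))
    return validate_paired_table(table)


def sensitivity_filter(table: pd.DataFrame,
                       threshold_cm3: float) -> pd.DataFrame:
    """Drop subjects whose lesion volume is below threshold in EITHER arm.

    Small lesions carry few voxels and unstable shape markers; the filter
    removes the whole subject (all markers) so the paired design survives.
    A threshold of 0 is a no-op.
    """
    validate_paired_table(table)
    vol = table[table["marker"] == "volume_ml"]
    subjects = set(table["subject_id"])
    if set(vol["subject_id"]) != subjects:
        raise CohortError("every subject needs a volume_ml row")
    if threshold_cm3 <= 0:
        return table.copy()
    below = vol[
        (vol["value_highquality"] < threshold_cm3)
        | (vol["value_clinical"] < threshold_cm3)
    ]["subject_id"]
    keep = ~table["subject_id"].isin(set(below))
    return table[keep].reset_index(drop=True)


# -- cohort comparison ------------------------------------------------------


@dataclass
class ComparisonReport:
    """Per-marker cohort comparison shaped like a summary table.

    ``table`` has one row per marker: medians and IQRs per condition, the
    Wilcoxon W and p, significance at ``alpha``, and Bland-Altman mean
    difference / limits of agreement for ``highquality - clinical``.
    """

    table: pd.DataFrame
    alpha: float
    n_subjects: int
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def bland_altman_frame(self, source: pd.DataFrame,
                           marker: str) -> pd.DataFrame:
        """Per-subject (mean, difference) rows for one marker's BA plot."""
        rows = source[source["marker"] == marker]
        out = pd.DataFrame({
            "subject_id": rows["subject_id"],
            "mean": (rows["value_highquality"]
                     + rows["value_clinical"]) / 2.0,
            "difference": rows["value_highquality"] - rows["value_clinical"],
        })
        return out.reset_index(drop=True)


def compare_cohort(table: pd.DataFrame, alpha: float = 0.05,
                   markers: Sequence[str] | None = None) -> ComparisonReport:
    """Full paired comparison of a cohort table.

    For each marker: median (IQR) per condition, two-sided Wilcoxon
    signed-rank test, Bland-Altman agreement, and a significance flag at
    ``alpha``. When all differences are zero the test is degenerate and
    reported with p = 1 (no evidence of a difference). Output is invariant
    to subject ordering.
    """
    validate_paired_table(table)
    if not 0.0 <= alpha <= 1.0:
        raise StatsDomainError("alpha must lie in [0, 1]")
    marker_list = list(markers) if markers is not None else [
        m for m in MARKER_NAMES if m in set(table["marker"])
    ]
    n_subjects = table["subject_id"].nunique()
    if n_subjects < MIN_PAIRS_FOR_P:
        raise StatsDomainError(
            f"need >= {MIN_PAIRS_FOR_P} subjects, got {n_subjects}"
        )
    rows = []
    for m in marker_list:
        sub = table[table["marker"] == m].sort_values("subject_id")
        if sub.empty:
            raise CohortError(f"no rows for marker {m}")
        hq = sub["value_highquality"].to_numpy(float)
        cl = sub["value_clinical"].to_numpy(float)
        med_h, q25_h, q75_h = median_iqr(hq)
        med_c, q25_c, q75_c = median_iqr(cl)
        try:
            wres = wilcoxon_signed_rank(hq, cl)
            w, p, n_eff, method = (wres.statistic, wres.pvalue,
                                   wres.n_effective, wres.method)
        except DegenerateDifferencesError:
            w, p, n_eff, method = 0.0, 1.0, 0, "degenerate-all-zero"
        ba = bland_altman(hq, cl)
        significant = bool(p is not None and p <= alpha and alpha > 0)
        rows.append({
            "marker": m, "n": len(sub),
            "median_highquality": med_h,
            "q25_highquality": q25_h, "q75_highquality": q75_h,
            "median_clinical": med_c,
            "q25_clinical": q25_c, "q75_clinical": q75_c,
            "wilcoxon_w": w,
            "p_value": p if p is not None else np.nan,
            "n_effective": n_eff, "method": method,
            "significant": significant,
            "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high,
        })
    report = ComparisonReport(
        table=pd.DataFrame(rows),
        alpha=alpha,
        n_subjects=int(n_subjects),
        metadata={
            "zero_differences": "dropped before ranking",
            "p_value_sides": "two-sided",
            "exact_p_limit": EXACT_LIMIT,
            "percentiles": "linear interpolation (inclusive)",
            "multiple_testing": "none (markers tested individually)",
        },
    )
    return report
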