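"""Panel-level statistics: positivity calling, frequency tables, Fisher and
Mann-Whitney tests, summed-PMR panel scores, and ROC/AUC.

The positivity threshold is calibrated as the control-sample maximum PMR
rounded up to the next integer percent. AUC is computed via the midrank
Mann-Whitney identity AUC = U / (n_pos * n_neg) and cross-checked internally
against trapezoidal integration of the empirical ROC step curve.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bisulfite_scoring import round_percent
from .errors import ConfigError, ValidationError

#: cohort groups regarded as non-lymphoma by default (benign controls + FH)
NON_LYMPHOMA_GROUPS = ("control:Bcell", "control:PBMC", "control:tonsil", "FH")
LYMPHOMA_GROUPS = ("BL", "ABC", "GCB", "FL", "PMBL")
CONTROL_GROUPS = ("control:Bcell", "control:PBMC", "control:tonsil")

DEFAULT_PANEL_GENES = ("LRP12", "CDH1", "BMPER", "DUSP4", "BMP7")


@dataclass
class PanelConfig:
    """Positivity threshold and gene panel for positivity calling/scoring."""

    threshold: float = 4.0
    genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    combine: str = "sum"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigError("threshold must be >= 0")
        if self.combine != "sum":
            raise ConfigError("only combine='sum' is supported")


def lymphoma_class(group: str) -> str:
    """Map a cohort group label to its lymphoma / non-lymphoma class."""
    if group in NON_LYMPHOMA_GROUPS or group.startswith("control"):
        return "non-lymphoma"
    if group in LYMPHOMA_GROUPS:
        return "lymphoma"
    raise ValidationError(f"unknown cohort group {group!r}")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table (``sample``, ``group``, ``series``) and attach the
    derived ``class`` column."""
    for col in ("sample", "group", "series"):
        if col not in cohort.columns:
            raise ValidationError(f"cohort table missing column {col!r}")
    if cohort["sample"].duplicated().any():
        dupes = sorted(cohort.loc[cohort["sample"].duplicated(), "sample"])
        raise ValidationError(f"duplicate cohort samples: {dupes}")
    out = cohort.copy()
    out["class"] = out["group"].map(lymphoma_class)
    return out


def calibrate_threshold(control_pmrs: Sequence[float]) -> int:
    """Positivity threshold: the maximum control PMR rounded up to the next
    integer percent (e.g. control range 0-3.7 gives 4)."""
    values = np.asarray(list(control_pmrs), dtype=float)
    if values.size == 0:
        raise ValidationError("cannot calibrate threshold from zero control samples")
    if (values < 0).any():
        raise ValidationError("control PMR values must be >= 0")
    return int(math.ceil(values.max()))


def call_positive(pmr: float, cfg: PanelConfig | float) -> bool:
    """Methylation-positive iff PMR >= threshold."""
    threshold = cfg.threshold if isinstance(cfg, PanelConfig) else float(cfg)
    if pmr < 0:
        raise ValidationError("PMR must be >= 0")
    return pmr >= threshold


def frequency_table(calls: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Methylation frequencies per gene x group x series, with pooled rows.

    ``calls`` has one row per sample x gene with a boolean ``positive``
    column. Output rows carry ``methylated``/``analyzed`` counts and
    nearest-integer ``percent``; pooled rows use ``group="all"`` (per-series
    pool over lymphoma groups) and ``series="all"`` (pool over series).
    Controls get per-group rows but are excluded from lymphoma pools.
    """
    cohort = validate_cohort(cohort)
    orphans = sorted(set(calls["sample"]) - set(cohort["sample"]))
    if orphans:
        raise ValidationError(f"call samples absent from cohort table: {orphans}")
    df = calls.merge(cohort, on="sample", how="left")

    rows = []
    for gene, gsub in df.groupby("gene", sort=True):
        overall_m = overall_n = 0
        for series, ssub in gsub.groupby("series", sort=True):
            pooled_m = pooled_n = 0
            for group, sub in ssub.groupby("group", sort=True):
                m = int(sub["positive"].sum())
                n = len(sub)
                rows.append(
                    {"gene": gene, "series": series, "group": group,
                     "methylated": m, "analyzed": n,
                     "percent": round_percent(m, n)}
                )
                if lymphoma_class(group) == "lymphoma":
                    pooled_m += m
                    pooled_n += n
            if pooled_n:
                rows.append(
                    {"gene": gene, "series": series, "group": "all",
                     "methylated": pooled_m, "analyzed": pooled_n,
                     "percent": round_percent(pooled_m, pooled_n)}
                )
            overall_m += pooled_m
            overall_n += pooled_n
        if overall_n:
            rows.append(
                {"gene": gene, "series": "all", "group": "all",
                 "methylated": overall_m, "analyzed": overall_n,
                 "percent": round_percent(overall_m, overall_n)}
            )
    return pd.DataFrame(rows)


def pooled_percent(counts: Iterable[tuple[int, int]]) -> int:
    """Pool (methylated, analyzed) count pairs and return the nearest-integer
    percentage."""
    pairs = list(counts)
    num = sum(k for k, _ in pairs)
    den = sum(n for _, n in pairs)
    return round_percent(num, den)


# ---------------------------------------------------------------------------
# significance tests


def fisher_exact(a: int, b: int, c: int, d: int, *, convention: str = "mass") -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    ``convention="mass"`` (default) sums hypergeometric probabilities not
    exceeding the observed table's probability; ``"double"`` doubles the
    smaller one-sided tail (capped at 1).
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValidationError("Fisher table entries must be non-negative integers")
    a, b, c, d = (int(x) for x in counts)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0  # degenerate margin: only one table possible
    dist = stats.hypergeom(n, c1, r1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    if convention == "mass":
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif convention == "double":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ConfigError("convention must be 'mass' or 'double'")
    return min(p, 1.0)


def _exact_mw_p(all_values: np.ndarray, n_a: int, u_obs: float) -> float:
    """Exact two-sided Mann-Whitney p conditional on the observed tie
    pattern: P(|U - mu| >= |u_obs - mu|) over all equally likely group
    assignments, via a subset-sum DP on integer doubled midranks."""
    n = len(all_values)
    n_b = n - n_a
    ranks2 = np.rint(2 * stats.rankdata(all_values)).astype(int)
    # dp[k] maps doubled rank sum -> number of size-k subsets attaining it
    dp: list[dict[int, int]] = [defaultdict(int) for _ in range(n_a + 1)]
    dp[0][0] = 1
    for w in ranks2:
        for k in range(min(n_a, n) - 1, -1, -1):
            if not dp[k]:
                continue
            target = dp[k + 1]
            for s, cnt in dp[k].items():
                target[s + int(w)] += cnt
    total = math.comb(n, n_a)
    mu2 = n_a * n_b  # doubled U mean
    d_obs = abs(2 * u_obs - mu2)
    hits = 0
    offset = n_a * (n_a + 1)  # 2U = 2R_a - n_a(n_a+1)
    for s2, cnt in dp[n_a].items():
        if abs(s2 - offset - mu2) >= d_obs - 1e-9:
            hits += cnt
    return hits / total


def mann_whitney(
    values_a: Sequence[float], values_b: Sequence[float], *, method: str = "auto"
) -> tuple[float, float]:
    """Midrank Mann-Whitney U for group A versus group B and two-sided p.

    ``method="exact"`` enumerates the permutation distribution conditional on
    ties (used automatically when ``n_a * n_b <= 400``); otherwise the normal
    approximation with tie correction is used.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    if method not in ("auto", "exact", "normal"):
        raise ConfigError("method must be 'auto', 'exact' or 'normal'")
    exact = method == "exact" or (method == "auto" and n_a * n_b <= 400)
    if exact:
        return u, _exact_mw_p(pooled, n_a, u)

    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0  # all observations tied
    z = (u - mu) / math.sqrt(var)
    return u, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# panel score and ROC


def panel_score(
    pmrs: pd.DataFrame,
    cfg: PanelConfig | None = None,
    *,
    mode: str = "available",
) -> pd.DataFrame:
    """Summed-PMR panel score per sample.

    ``pmrs`` has columns ``sample``, ``gene``, ``pmr``. With
    ``mode="available"`` (default) missing panel genes are skipped and
    flagged; ``mode="strict"`` raises if any sample lacks a panel gene.
    """
    cfg = cfg or PanelConfig()
    if mode not in ("available", "strict"):
        raise ConfigError("mode must be 'available' or 'strict'")
    panel = pmrs[pmrs["gene"].isin(cfg.genes)]
    rows = []
    for sample, sub in panel.groupby("sample", sort=True):
        present = sorted(sub["gene"].unique())
        missing = sorted(set(cfg.genes) - set(present))
        if len(present) == 0:
            raise ValidationError(f"sample {sample!r} has no panel gene measured")
        if missing and mode == "strict":
            raise ValidationError(
                f"sample {sample!r} missing panel genes {missing} in strict mode"
            )
        rows.append(
            {"sample": sample, "score": float(sub["pmr"].sum()),
             "n_genes": len(present),
             "missing_genes": ";".join(missing)}
        )
    if not rows:
        raise ValidationError("no samples with any panel gene measured")
    return pd.DataFrame(rows)


@dataclass
class RocResult:
    """Empirical ROC curve and its midrank AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC points over all score thresholds and the AUC.

    *labels* are truthy for the positive (lymphoma) class; higher scores are
    assumed more positive. AUC uses the midrank Mann-Whitney identity
    ``U / (n_pos * n_neg)`` and is verified against trapezoidal integration
    of the step curve.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=bool)
    if s.shape != y.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for ROC analysis")

    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))

    order = np.argsort(-s, kind="mergesort")
    sorted_y = y[order]
    sorted_s = s[order]
    tp = np.cumsum(sorted_y)
    fp = np.cumsum(~sorted_y)
    # keep the last point of each tied-score block
    keep = np.r_[sorted_s[1:] != sorted_s[:-1], True]
    tpr = np.r_[0.0, tp[keep] / n_pos]
    fpr = np.r_[0.0, fp[keep] / n_neg]
    thresholds = np.r_[np.inf, sorted_s[keep]]

    auc_trap = float(np.trapezoid(tpr, fpr))
    if not math.isclose(auc, auc_trap, rel_tol=0, abs_tol=1e-9):
        raise AssertionError(
            f"midrank AUC {auc} disagrees with trapezoidal AUC {auc_trap}"
        )
    return RocResult(thresholds, fpr, tpr, auc, n_pos, n_neg)
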