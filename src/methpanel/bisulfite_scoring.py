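"""Bisulfite-trace scoring and MSP-style methylation calls.

Per-CpG methylation is the cytosine fraction of the sequencing signal,
``r = C / (C + T)``, bucketed into unmethylated / partially methylated /
fully methylated classes at the 0.20 and 0.80 cutoffs. MSP band patterns are
merged across duplicate runs and summarised into per-gene cell-line
methylation frequency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import UnscorableSiteError, ValidationError

#: class boundaries for the C/(C+T) ratio
RATIO_CUTOFF_LOW = 0.20
RATIO_CUTOFF_HIGH = 0.80

UNMETHYLATED = "unmethylated"
PARTIAL = "partial"
FULL = "full"
DISCORDANT = "discordant"

#: classes counted as methylated in frequency tables
_METHYLATED_CLASSES = frozenset({PARTIAL, FULL})


def round_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer, halves away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def cpg_ratio(peak_c: float, peak_t: float) -> float:
    """Cytosine signal fraction ``C / (C + T)`` of one trace site."""
    if peak_c < 0 or peak_t < 0:
        raise ValidationError("peak heights must be non-negative")
    total = peak_c + peak_t
    if total == 0:
        raise UnscorableSiteError("both C and T peaks are zero; site unscorable")
    return peak_c / total


def classify_cpg(r: float) -> str:
    """Bucket a ratio into unmethylated (<=0.20), partial ((0.20, 0.80]) or
    full (>0.80)."""
    if not 0.0 <= r <= 1.0:
        raise ValidationError(f"ratio {r} outside [0, 1]")
    if r <= RATIO_CUTOFF_LOW:
        return UNMETHYLATED
    if r <= RATIO_CUTOFF_HIGH:
        return PARTIAL
    return FULL


def score_traces(traces: pd.DataFrame) -> pd.DataFrame:
    """Score a trace table into per-CpG calls.

    Expects columns ``gene``, ``sample``, ``position``, ``peak_C``,
    ``peak_T`` and optionally ``site_type`` (rows other than ``cpg`` are used
    only for the conversion check and excluded from calls). Returns a call
    table with ``ratio`` and ``call`` columns.
    """
    df = traces.copy()
    if "site_type" in df.columns:
        cpg = df[df["site_type"] == "cpg"].copy()
    else:
        cpg = df
    ratios = [cpg_ratio(c, t) for c, t in zip(cpg["peak_C"], cpg["peak_T"])]
    cpg["ratio"] = ratios
    cpg["call"] = [classify_cpg(r) for r in ratios]
    return cpg[["gene", "sample", "position", "ratio", "call"]].reset_index(drop=True)


def conversion_rate(traces: pd.DataFrame) -> float:
    """Fraction of non-CpG cytosine sites read as fully converted (ratio <=
    the unmethylated cutoff). 1.0 indicates complete bisulfite conversion."""
    if "site_type" not in traces.columns:
        raise ValidationError("trace table has no site_type column")
    non_cpg = traces[traces["site_type"] == "non_cpg_c"]
    if non_cpg.empty:
        raise ValidationError("no non-CpG cytosine sites to assess conversion")
    r = non_cpg["peak_C"] / (non_cpg["peak_C"] + non_cpg["peak_T"])
    return float((r <= RATIO_CUTOFF_LOW).mean())


@dataclass(frozen=True)
class MSPCall:
    """One MSP run for a gene x sample: band presence in the methylated and
    unmethylated reactions."""

    gene: str
    sample: str
    run: int
    methylated_band: bool
    unmethylated_band: bool

    @property
    def run_class(self) -> str:
        if self.methylated_band and self.unmethylated_band:
            return PARTIAL
        if self.methylated_band:
            return FULL
        if self.unmethylated_band:
            return UNMETHYLATED
        raise ValidationError(
            f"MSP run {self.gene}/{self.sample}#{self.run} has no band in "
            "either reaction"
        )


_CLASS_ORDER = {UNMETHYLATED: 0, PARTIAL: 1, FULL: 2}


def consensus_msp(calls: Sequence[MSPCall]) -> str:
    """Merge duplicate MSP runs for one gene x sample.

    Runs agreeing on methylated-band presence yield the more-methylated
    per-run class; disagreement on methylated-band presence is flagged
    ``discordant`` (repeat required).
    """
    if len(calls) == 0:
        raise ValidationError("consensus_msp requires at least one run")
    m_flags = {c.methylated_band for c in calls}
    if len(m_flags) > 1:
        return DISCORDANT
    return max((c.run_class for c in calls), key=_CLASS_ORDER.__getitem__)


def msp_consensus_table(bands: pd.DataFrame) -> pd.DataFrame:
    """Collapse an MSP band table (``gene``, ``sample``, ``run``,
    ``methylated_band``, ``unmethylated_band``) to one consensus per
    gene x sample."""
    rows = []
    for (gene, sample), sub in bands.groupby(["gene", "sample"], sort=True):
        calls = [
            MSPCall(gene, sample, int(r.run), bool(r.methylated_band),
                    bool(r.unmethylated_band))
            for r in sub.itertuples()
        ]
        rows.append({"gene": gene, "sample": sample,
                     "consensus": consensus_msp(calls)})
    return pd.DataFrame(rows)


def cellline_frequency_table(
    consensus: pd.DataFrame, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene methylation frequencies across grouped cell lines.

    ``consensus`` holds one row per gene x cell line (``sample`` column is the
    cell-line id) with a ``consensus`` class; *grouping* maps cell line to
    lymphoma type. A line counts as methylated when partially or fully
    methylated; discordant/missing calls are excluded from denominators.
    Output: one row per gene x type plus a ``combined`` row pooling all
    lines, with raw counts and nearest-integer percentages.
    """
    unknown = sorted(set(consensus["sample"]) - set(grouping))
    if unknown:
        raise ValidationError(f"cell lines with no type assignment: {unknown}")
    df = consensus.copy()
    df["type"] = df["sample"].map(grouping)
    df = df[df["consensus"] != DISCORDANT]
    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        total_m = total_n = 0
        for lym_type, tsub in sub.groupby("type", sort=True):
            n = len(tsub)
            m = int(tsub["consensus"].isin(_METHYLATED_CLASSES).sum())
            total_m += m
            total_n += n
            rows.append(
                {"gene": gene, "type": lym_type, "methylated": m,
                 "analyzed": n, "percent": round_percent(m, n)}
            )
        rows.append(
            {"gene": gene, "type": "combined", "methylated": total_m,
             "analyzed": total_n,
             "percent": round_percent(total_m, total_n) if total_n else None}
        )
    return pd.DataFrame(rows)
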