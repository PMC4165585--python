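"""Three-criteria screen for epigenetically silenced candidate genes.

A gene is a candidate for a given lymphoma type when, simultaneously:

1. its expression in patients of that type is at least ``patient_down_threshold``
   -fold below the average of patients of the remaining types;
2. its mean response to demethylating treatment in cell lines of that type is
   at least ``response_up_threshold``;
3. that mean response exceeds the mean response in cell lines of the remaining
   types by at least ``response_contrast_threshold``.

All arithmetic is on log2 expression values. The ``scale`` switch controls how
the response thresholds of criteria 2 and 3 are interpreted (see
:class:`SelectionConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

LYMPHOMA_TYPES = ("BL", "ABC", "GCB", "FL")

META_COLUMNS = ("sample", "lymphoma_type", "origin", "cell_line", "treatment")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) plus per-sample metadata.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``meta``: one row per sample with columns ``sample``, ``lymphoma_type``,
    ``origin`` (``cell_line``/``patient``), ``cell_line`` (id or ``n/a``) and
    ``treatment`` (``treated``/``untreated``/``n/a``).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"sample metadata missing columns: {missing}")
        meta_samples = set(self.meta["sample"])
        if meta_samples != set(self.values.columns):
            raise ValidationError(
                "sample ids in metadata and expression matrix differ"
            )
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValidationError(
                f"expression matrix contains missing values in samples {bad}; "
                "impute or drop before loading"
            )
        cl = self.meta[self.meta["origin"] == "cell_line"]
        by_line = cl.groupby("cell_line")["treatment"].apply(set)
        orphans = sorted(
            line
            for line, arms in by_line.items()
            if "treated" in arms and "untreated" not in arms
        )
        if orphans:
            raise ValidationError(
                f"treated cell-line samples without untreated mates: {orphans}"
            )

    def patients(self, lymphoma_type: str | None = None) -> pd.DataFrame:
        mask = self.meta["origin"] == "patient"
        if lymphoma_type is not None:
            mask &= self.meta["lymphoma_type"] == lymphoma_type
        return self.values[self.meta.loc[mask, "sample"]]

    @property
    def types(self) -> list[str]:
        return sorted(self.meta["lymphoma_type"].dropna().unique())


@dataclass
class SelectionConfig:
    """Thresholds for the three selection criteria.

    ``patient_down_threshold`` is a linear fold (2.0 means patients of the
    type are at least 2-fold below the others, i.e. log2 contrast <= -1).
    With ``scale="log2"`` (default) the two response thresholds are log2-unit
    differences (a value of 0.5 means +0.5 log2). With ``scale="linear"`` they
    are literal fractional increases (0.5 means the linear ratio must be at
    least 1.5).
    """

    patient_down_threshold: float = 2.0
    response_up_threshold: float = 0.5
    response_contrast_threshold: float = 0.5
    scale: str = "log2"

    def __post_init__(self) -> None:
        for name in (
            "patient_down_threshold",
            "response_up_threshold",
            "response_contrast_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.scale not in ("log2", "linear"):
            raise ConfigError("scale must be 'log2' or 'linear'")


def patient_type_contrast(expr: ExpressionMatrix, lymphoma_type: str) -> pd.Series:
    """Per-gene mean log2 expression of *lymphoma_type* patients minus the
    mean over all other types' patients."""
    in_type = expr.patients(lymphoma_type)
    meta = expr.meta
    out_mask = (meta["origin"] == "patient") & (meta["lymphoma_type"] != lymphoma_type)
    out_type = expr.values[meta.loc[out_mask, "sample"]]
    if in_type.shape[1] == 0:
        raise ValidationError(f"no patient samples for type {lymphoma_type!r}")
    if out_type.shape[1] == 0:
        raise ValidationError(
            f"no patient samples outside type {lymphoma_type!r} to contrast against"
        )
    contrast = in_type.mean(axis=1) - out_type.mean(axis=1)
    contrast.name = f"contrast_{lymphoma_type}"
    return contrast


def treatment_response(expr: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment-induced log2 change per (gene, cell line), and per-type means.

    Returns ``(per_line, per_type)``: *per_line* has one column per cell line
    (treated minus untreated log2 values), *per_type* averages those columns
    within each lymphoma type.
    """
    meta = expr.meta
    cl = meta[meta["origin"] == "cell_line"]
    if cl.empty:
        raise ValidationError("no cell-line samples in expression matrix")
    responses: dict[str, pd.Series] = {}
    line_type: dict[str, str] = {}
    for line, sub in cl.groupby("cell_line"):
        arms = sub.set_index("treatment")["sample"]
        if "treated" not in arms.index:
            continue  # untreated-only lines carry no response information
        treated = expr.values[arms["treated"]]
        untreated = expr.values[arms["untreated"]]
        responses[line] = treated - untreated
        line_type[line] = sub["lymphoma_type"].iloc[0]
    per_line = pd.DataFrame(responses)
    per_type = per_line.T.groupby(pd.Series(line_type)).mean().T
    return per_line, per_type


def select_candidates(
    expr: ExpressionMatrix, cfg: SelectionConfig | None = None
) -> pd.DataFrame:
    """Evaluate the three criteria for every (gene, lymphoma type) pair.

    Returns a report with one row per pair: the contrast and response
    statistics, the three per-criterion booleans, ``selected`` (their
    conjunction) and margin columns used for ranking. Rows are sorted by
    descending criterion-3 margin, then criterion-1 margin, then gene id.
    """
    cfg = cfg or SelectionConfig()
    types = sorted(
        expr.meta.loc[expr.meta["origin"] == "patient", "lymphoma_type"].unique()
    )
    if len(types) < 2:
        raise ValidationError("need patient samples for at least 2 lymphoma types")
    _, per_type_resp = treatment_response(expr)

    down_cut = -np.log2(cfg.patient_down_threshold)
    rows = []
    for lym_type in types:
        contrast = patient_type_contrast(expr, lym_type)
        if lym_type in per_type_resp.columns:
            resp_in = per_type_resp[lym_type]
            others = per_type_resp.drop(columns=lym_type)
        else:
            raise ValidationError(f"no cell lines for type {lym_type!r}")
        resp_out = others.mean(axis=1)

        if cfg.scale == "log2":
            pass2 = resp_in >= cfg.response_up_threshold
            margin3 = resp_in - resp_out
            pass3 = margin3 >= cfg.response_contrast_threshold
        else:  # literal linear-ratio reading
            pass2 = 2.0**resp_in >= 1.0 + cfg.response_up_threshold
            margin3 = 2.0**resp_in / 2.0**resp_out
            pass3 = margin3 >= 1.0 + cfg.response_contrast_threshold
        pass1 = contrast <= down_cut

        frame = pd.DataFrame(
            {
                "gene": contrast.index,
                "lymphoma_type": lym_type,
                "patient_contrast": contrast.values,
                "mean_response_type": resp_in.values,
                "mean_response_other": resp_out.values,
                "pass_patient_down": pass1.values,
                "pass_response_up": pass2.values,
                "pass_response_contrast": pass3.values,
                "margin_contrast": (down_cut - contrast).values,
                "margin_response": (margin3 - (
                    cfg.response_contrast_threshold
                    if cfg.scale == "log2"
                    else 1.0 + cfg.response_contrast_threshold
                )).values,
            }
        )
        rows.append(frame)
    report = pd.concat(rows, ignore_index=True)
    report["selected"] = (
        report["pass_patient_down"]
        & report["pass_response_up"]
        & report["pass_response_contrast"]
    )
    report = report.sort_values(
        ["margin_response", "margin_contrast", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return report


def top_candidates(report: pd.DataFrame, k: int | None = None) -> pd.DataFrame:
    """Selected rows of a report, optionally truncated to the top *k*."""
    sel = report[report["selected"]]
    return sel if k is None else sel.head(k)
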