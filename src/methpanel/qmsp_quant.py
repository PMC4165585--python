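"""qMSP quantification: standard curves, Ct interpolation and PMR.

Quantities are interpolated from per-assay standard curves
(``Ct = slope * log10(quantity) + intercept``), replicates are averaged on
the quantity scale, the gene quantity is normalised to the ALU-C4 reference
for DNA input, and the sample gene/reference ratio is expressed as a percent
of the same ratio in the fully methylated calibrator DNA:

    PMR = 100 * (gene/ref)_sample / (gene/ref)_calibrator
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CurveQualityError,
    InsufficientStandardsError,
    NonQuantifiableError,
    ValidationError,
)

REFERENCE_ASSAY = "ALU-C4"
CALIBRATOR_ID = "calibrator"

#: flag strings attached to PMR records
FLAG_PARTIAL_DETECTION = "partial_detection"
FLAG_NO_AMPLIFICATION = "no_amplification"
FLAG_ABOVE_100 = "above_100"
FLAG_HIGH_CV = "high_cv"

DEFAULT_CV_THRESHOLD = 0.5


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of Ct against log10 input quantity."""

    assay: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency implied by the slope
        (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class PMRRecord:
    """Percent-methylated-reference for one sample x gene."""

    sample: str
    gene: str
    pmr: float
    gene_quantity: float
    reference_quantity: float
    replicate_cv: float
    flags: list[str] = field(default_factory=list)


def fit_standard_curve(standards: pd.DataFrame, assay: str | None = None) -> StandardCurve:
    """Fit ``Ct = slope * log10(quantity) + intercept`` to dilution-series wells.

    *standards* needs ``ct`` and ``known_quantity`` columns (one assay's
    rows). Requires at least three distinct dilution levels with determined
    Ct; a non-negative fitted slope is rejected.
    """
    df = standards.dropna(subset=["ct"])
    df = df[df["known_quantity"] > 0]
    levels = df["known_quantity"].nunique()
    if levels < 3:
        raise InsufficientStandardsError(
            f"standard curve needs >=3 distinct dilution levels, got {levels}"
        )
    x = np.log10(df["known_quantity"].to_numpy(float))
    y = df["ct"].to_numpy(float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if slope >= 0:
        raise CurveQualityError(
            f"fitted slope {slope:.3f} is non-negative; Ct must decrease with quantity"
        )
    name = assay if assay is not None else (
        str(df["assay"].iloc[0]) if "assay" in df.columns else "assay"
    )
    return StandardCurve(name, float(slope), float(intercept), r2, len(df))


def interpolate_quantity(curve: StandardCurve, ct: float) -> float:
    """Quantity ``10**((ct - intercept) / slope)``; undetermined (NaN) Ct
    maps to quantity 0 (no amplification)."""
    if ct is None or (isinstance(ct, float) and np.isnan(ct)):
        return 0.0
    if ct <= 0:
        raise ValidationError(f"determined Ct must be positive, got {ct}")
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def _replicate_quantity(
    wells: pd.DataFrame, curve: StandardCurve
) -> tuple[float, float, int]:
    """Mean quantity over replicate wells, replicate CV (sd/mean on the
    quantity scale) and count of undetermined wells."""
    cts = wells["ct"].to_numpy(float)
    q = np.array([interpolate_quantity(curve, ct) for ct in cts])
    mean = float(q.mean())
    cv = float(q.std(ddof=1) / mean) if len(q) > 1 and mean > 0 else float("nan")
    return mean, cv, int(np.isnan(cts).sum())


def compute_pmr(
    sample_wells: pd.DataFrame,
    calibrator_wells: pd.DataFrame,
    gene_curve: StandardCurve,
    reference_curve: StandardCurve,
    *,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> PMRRecord:
    """PMR for one sample from its gene and reference replicate wells.

    Both well tables need ``assay``, ``replicate`` and ``ct`` columns and must
    contain rows for the gene assay and the reference assay. Undetermined
    gene Cts contribute quantity 0 (flagged); an undetermined or zero-quantity
    reference invalidates the sample.
    """
    if calibrator_wells.empty:
        raise ValidationError("calibrator wells missing; PMR is undefined")
    gene = gene_curve.assay
    ref = reference_curve.assay
    sample_id = str(sample_wells["sample"].iloc[0]) if "sample" in sample_wells else "?"

    def split(wells: pd.DataFrame, who: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        g = wells[wells["assay"] == gene]
        r = wells[wells["assay"] == ref]
        if g.empty or r.empty:
            raise ValidationError(
                f"{who} wells must cover both assay {gene!r} and reference {ref!r}"
            )
        return g, r

    sg, sr = split(sample_wells, "sample")
    cg, cr = split(calibrator_wells, "calibrator")

    gene_q, gene_cv, n_undet = _replicate_quantity(sg, gene_curve)
    ref_q, _, ref_undet = _replicate_quantity(sr, reference_curve)
    cal_gene_q, _, _ = _replicate_quantity(cg, gene_curve)
    cal_ref_q, _, _ = _replicate_quantity(cr, reference_curve)

    if ref_q <= 0 or ref_undet == len(sr):
        raise NonQuantifiableError(
            f"reference assay yielded zero quantity for sample {sample_id}"
        )
    if cal_gene_q <= 0 or cal_ref_q <= 0:
        raise NonQuantifiableError("calibrator quantities must be positive")

    pmr = 100.0 * (gene_q / ref_q) / (cal_gene_q / cal_ref_q)
    flags: list[str] = []
    if n_undet == len(sg):
        flags.append(FLAG_NO_AMPLIFICATION)
    elif n_undet > 0:
        flags.append(FLAG_PARTIAL_DETECTION)
    if pmr > 100.0:
        flags.append(FLAG_ABOVE_100)
    if np.isfinite(gene_cv) and gene_cv > cv_threshold:
        flags.append(FLAG_HIGH_CV)
    return PMRRecord(sample_id, gene, pmr, gene_q, ref_q, gene_cv, flags)


def fit_plate_curves(plate: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per assay from the plate's ``standard`` rows."""
    standards = plate[plate["role"] == "standard"]
    if standards.empty:
        raise ValidationError("plate has no standard-curve wells")
    return {
        assay: fit_standard_curve(sub, assay=assay)
        for assay, sub in standards.groupby("assay")
    }


def quantify_plate(
    plate: pd.DataFrame,
    *,
    reference_assay: str = REFERENCE_ASSAY,
    calibrator_id: str = CALIBRATOR_ID,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> pd.DataFrame:
    """Quantify a whole qMSP plate into a PMR table.

    The plate table needs columns ``sample``, ``assay``, ``replicate``,
    ``ct``, ``role`` (``sample``/``standard``/``calibrator``) and
    ``known_quantity`` for standards. Returns one row per sample x gene with
    ``pmr``, quantities, replicate CV and semicolon-joined flags.
    """
    curves = fit_plate_curves(plate)
    if reference_assay not in curves:
        raise ValidationError(f"no standard curve for reference assay {reference_assay!r}")

    wells = plate[plate["role"].isin(["sample", "calibrator"])].copy()
    slopes = wells["assay"].map({a: c.slope for a, c in curves.items()})
    intercepts = wells["assay"].map({a: c.intercept for a, c in curves.items()})
    if slopes.isna().any():
        missing = sorted(wells.loc[slopes.isna(), "assay"].unique())
        raise ValidationError(f"no standard curve for assays: {missing}")
    ct = wells["ct"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        q = 10.0 ** ((ct - intercepts.to_numpy(float)) / slopes.to_numpy(float))
    q[np.isnan(ct)] = 0.0
    wells["quantity"] = q

    agg = (
        wells.groupby(["sample", "assay"])["quantity"]
        .agg(["mean", "std", "count"])
        .join(wells.groupby(["sample", "assay"])["ct"].agg(n_undet=lambda s: s.isna().sum()))
    )

    cal = agg.loc[calibrator_id] if calibrator_id in agg.index.get_level_values(0) else None
    if cal is None:
        raise ValidationError(f"calibrator sample {calibrator_id!r} not on plate")
    cal_ref_q = cal.loc[reference_assay, "mean"]

    records = []
    genes = sorted(a for a in wells["assay"].unique() if a != reference_assay)
    samples = sorted(s for s in wells["sample"].unique() if s != calibrator_id)
    for sample in samples:
        sub = agg.loc[sample]
        if reference_assay not in sub.index:
            raise ValidationError(f"sample {sample!r} lacks reference assay wells")
        ref_q = sub.loc[reference_assay, "mean"]
        if ref_q <= 0:
            raise NonQuantifiableError(
                f"reference assay yielded zero quantity for sample {sample}"
            )
        for gene in genes:
            if gene not in sub.index:
                continue  # gene not assayed for this sample
            if gene not in cal.index:
                raise ValidationError(f"calibrator lacks wells for assay {gene!r}")
            cal_gene_q = cal.loc[gene, "mean"]
            if cal_gene_q <= 0 or cal_ref_q <= 0:
                raise NonQuantifiableError("calibrator quantities must be positive")
            gene_q = sub.loc[gene, "mean"]
            n = int(sub.loc[gene, "count"])
            n_undet = int(sub.loc[gene, "n_undet"])
            cv = sub.loc[gene, "std"] / gene_q if n > 1 and gene_q > 0 else float("nan")
            pmr = 100.0 * (gene_q / ref_q) / (cal_gene_q / cal_ref_q)
            flags = []
            if n_undet == n:
                flags.append(FLAG_NO_AMPLIFICATION)
            elif n_undet > 0:
                flags.append(FLAG_PARTIAL_DETECTION)
            if pmr > 100.0:
                flags.append(FLAG_ABOVE_100)
            if np.isfinite(cv) and cv > cv_threshold:
                flags.append(FLAG_HIGH_CV)
            records.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "pmr": pmr,
                    "gene_quantity": gene_q,
                    "reference_quantity": ref_q,
                    "replicate_cv": cv,
                    "flags": ";".join(flags),
                }
            )
    return pd.DataFrame(records)
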