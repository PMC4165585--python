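"""Seeded synthetic data for the full methylation-panel pipeline.

Generates the four input tables the pipeline consumes — a log2 expression
matrix with treated/untreated cell-line pairs and patient samples, a qMSP
plate with triplicate Cts plus dilution-series standards, a bisulfite-trace
peak table, and a cohort table — together with ground-truth tables, so that
selection, quantification and frequency recovery are all testable without
external data.

Determinism contract: identical (seed, config) produce byte-identical tables.
Each output table draws from its own RNG stream derived from the master seed,
so generating one table never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .candidate_selection import ExpressionMatrix, LYMPHOMA_TYPES
from .errors import ConfigError
from .qmsp_quant import CALIBRATOR_ID, REFERENCE_ASSAY

# fixed spawn keys: one stream per table
_STREAM_EXPRESSION = 0
_STREAM_QMSP = 1
_STREAM_TRACES = 2

#: cohort shaped like a two-series lymphoma study with benign controls
DEFAULT_GROUPS = (
    ("control:Bcell", 20, "test"),
    ("control:PBMC", 10, "test"),
    ("control:tonsil", 10, "test"),
    ("FH", 9, "test"),
    ("BL", 7, "test"),
    ("ABC", 10, "test"),
    ("GCB", 10, "test"),
    ("FL", 10, "test"),
    ("ABC", 8, "validation"),
    ("GCB", 6, "validation"),
    ("FL", 2, "validation"),
    ("PMBL", 6, "validation"),
)

DEFAULT_FREQUENCIES: dict[str, dict[str, float]] = {
    "GENE%02d" % i: {"BL": 0.6, "ABC": 0.6, "GCB": 0.6, "FL": 0.6, "PMBL": 0.6}
    for i in range(1, 6)
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic generators.

    ``methylation_frequency`` maps gene -> group -> probability that a sample
    of that group is methylated at that gene; absent groups default to 0
    (controls are never listed). A ``"series:group"`` key (e.g.
    ``"validation:ABC"``) overrides the plain group key for that series. PMR of methylated samples is drawn from a
    Gaussian (``pmr_positive_mean``/``pmr_positive_sd``) floored at 0;
    unmethylated and control samples draw uniform on [0, control_pmr_max].
    The PMR placeholders are conventions, not estimates of any real cohort.
    """

    seed: int = 0
    n_genes: int = 40
    n_candidate_genes: int = 5
    groups: tuple[tuple[str, int, str], ...] = DEFAULT_GROUPS
    methylation_frequency: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_FREQUENCIES.items()}
    )
    pmr_positive_mean: float = 40.0
    pmr_positive_sd: float = 20.0
    control_pmr_max: float = 3.7
    treatment_effect_log2: float = 2.0
    patient_downregulation_log2: float = 2.0
    expression_noise_sd: float = 0.2
    expression_baseline_mean: float = 8.0
    expression_baseline_sd: float = 1.0
    n_celllines_per_type: int = 3
    n_patients_per_type: int = 5
    ct_replicate_sd: float = 0.1
    curve_slope: float = -1.0 / math.log10(2.0)  # perfect doubling: ~ -3.3219
    curve_intercept: float = 38.0
    n_replicates: int = 3
    standard_quantities: tuple[float, ...] = (1e1, 1e2, 1e3, 1e4, 1e5)
    calibrator_ref_quantity: float = 1e4
    calibrator_ratio: float = 1.0
    ref_quantity_range: tuple[float, float] = (1e3, 1e4)
    n_cpg_sites: int = 10
    n_non_cpg_sites: int = 4
    trace_noise: float = 0.02
    trace_peak_height: float = 1000.0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not 0 <= self.n_candidate_genes <= self.n_genes:
            raise ConfigError("n_candidate_genes must be in [0, n_genes]")
        for gene, by_group in self.methylation_frequency.items():
            for group, freq in by_group.items():
                if not 0.0 <= freq <= 1.0:
                    raise ConfigError(
                        f"methylation_frequency[{gene}][{group}] = {freq} "
                        "outside [0, 1]"
                    )
        for label, n, series in self.groups:
            if n < 1:
                raise ConfigError(f"groups: n must be >= 1 for {label}/{series}")
        if self.ct_replicate_sd < 0:
            raise ConfigError("ct_replicate_sd must be >= 0")
        if self.curve_slope >= 0:
            raise ConfigError("curve_slope must be < 0")
        if self.control_pmr_max < 0:
            raise ConfigError("control_pmr_max must be >= 0")
        if self.expression_noise_sd < 0:
            raise ConfigError("expression_noise_sd must be >= 0")
        if not 0 <= self.trace_noise < 0.5:
            raise ConfigError("trace_noise must be in [0, 0.5)")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )

    @property
    def panel_genes(self) -> list[str]:
        return sorted(self.methylation_frequency)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = [list(g) for g in self.groups]
        d["methylation_frequency"] = {
            g: dict(v) for g, v in self.methylation_frequency.items()
        }
        d["standard_quantities"] = list(self.standard_quantities)
        d["ref_quantity_range"] = list(self.ref_quantity_range)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        kwargs = dict(data)
        if "groups" in kwargs:
            kwargs["groups"] = tuple(tuple(g) for g in kwargs["groups"])
        for key in ("standard_quantities", "ref_quantity_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown simulation config fields: {sorted(unknown)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Synthetic log2 expression matrix plus candidate ground truth.

    Cell lines come in treated/untreated pairs (``n_celllines_per_type`` per
    lymphoma type); patients are unpaired. Each planted candidate gene is
    assigned a target type round-robin: treated cell lines of that type gain
    ``treatment_effect_log2`` and patients of that type lose
    ``patient_downregulation_log2``. Everything else is baseline + Gaussian
    noise. Returns ``(matrix, truth)`` where *truth* has one row per gene
    with ``is_candidate`` and ``target_type``.
    """
    config.validate()
    rng = config.rng(_STREAM_EXPRESSION)
    genes = [f"GENE{i:02d}" for i in range(1, config.n_genes + 1)]
    types = list(LYMPHOMA_TYPES)

    meta_rows = []
    for lym_type in types:
        for i in range(1, config.n_celllines_per_type + 1):
            line = f"{lym_type}_cl{i}"
            for arm in ("untreated", "treated"):
                meta_rows.append(
                    {"sample": f"{line}_{arm}", "lymphoma_type": lym_type,
                     "origin": "cell_line", "cell_line": line, "treatment": arm}
                )
        for i in range(1, config.n_patients_per_type + 1):
            meta_rows.append(
                {"sample": f"{lym_type}_pt{i:02d}", "lymphoma_type": lym_type,
                 "origin": "patient", "cell_line": "n/a", "treatment": "n/a"}
            )
    meta = pd.DataFrame(meta_rows)

    baseline = rng.normal(
        config.expression_baseline_mean, config.expression_baseline_sd,
        size=config.n_genes,
    )
    target_types = {
        genes[i]: types[i % len(types)] for i in range(config.n_candidate_genes)
    }

    values = np.empty((config.n_genes, len(meta)))
    for j, row in enumerate(meta.itertuples()):
        mu = baseline.copy()
        for gi, gene in enumerate(genes[: config.n_candidate_genes]):
            if row.lymphoma_type == target_types[gene]:
                if row.origin == "cell_line" and row.treatment == "treated":
                    mu[gi] += config.treatment_effect_log2
                elif row.origin == "patient":
                    mu[gi] -= config.patient_downregulation_log2
        values[:, j] = mu
    values += rng.normal(0.0, config.expression_noise_sd, size=values.shape)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=meta["sample"].tolist()), meta
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_candidate": [g in target_types for g in genes],
            "target_type": [target_types.get(g, "n/a") for g in genes],
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# qMSP cohort


def _cohort_samples(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for label, n, series in config.groups:
        tag = label.replace(":", "_")
        for i in range(1, n + 1):
            rows.append(
                {"sample": f"{series}_{tag}_{i:02d}", "group": label,
                 "series": series}
            )
    return pd.DataFrame(rows)


def simulate_qmsp_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic qMSP plate, cohort table and ground truth.

    For every sample x panel gene a true PMR is drawn (methylated with the
    configured per-group frequency -> truncated-Gaussian PMR; otherwise
    uniform background on [0, control_pmr_max]) and inverted through the
    quantification model into triplicate Cts for the gene and the reference
    assay, plus a dilution series per assay and calibrator wells. A planted
    PMR of exactly 0 yields undetermined gene Cts.
    """
    config.validate()
    rng = config.rng(_STREAM_QMSP)
    cohort = _cohort_samples(config)
    genes = config.panel_genes
    slope, intercept = config.curve_slope, config.curve_intercept

    def ct_of(quantity: float) -> float:
        if quantity <= 0:
            return np.nan
        ct = slope * np.log10(quantity) + intercept
        if config.ct_replicate_sd > 0:
            ct += rng.normal(0.0, config.ct_replicate_sd)
        return float(ct)

    plate_rows = []
    # dilution-series standards per assay (gene assays + reference)
    for assay in genes + [REFERENCE_ASSAY]:
        for level, quantity in enumerate(config.standard_quantities, start=1):
            for rep in range(1, config.n_replicates + 1):
                plate_rows.append(
                    {"sample": f"std_{assay}_L{level}", "assay": assay,
                     "replicate": rep, "ct": ct_of(quantity),
                     "role": "standard", "known_quantity": quantity}
                )
    # calibrator: fully methylated reference material
    cal_ref_q = config.calibrator_ref_quantity
    cal_gene_q = config.calibrator_ratio * cal_ref_q
    for assay, quantity in [(REFERENCE_ASSAY, cal_ref_q)] + [
        (g, cal_gene_q) for g in genes
    ]:
        for rep in range(1, config.n_replicates + 1):
            plate_rows.append(
                {"sample": CALIBRATOR_ID, "assay": assay, "replicate": rep,
                 "ct": ct_of(quantity), "role": "calibrator",
                 "known_quantity": np.nan}
            )

    truth_rows = []
    lo, hi = config.ref_quantity_range
    for row in cohort.itertuples():
        ref_q = float(rng.uniform(lo, hi))
        for gene in genes:
            by_group = config.methylation_frequency[gene]
            freq = float(
                by_group.get(f"{row.series}:{row.group}",
                             by_group.get(row.group, 0.0))
            )
            methylated = bool(rng.random() < freq)
            if methylated:
                pmr = max(
                    0.0,
                    float(rng.normal(config.pmr_positive_mean,
                                     config.pmr_positive_sd)),
                )
            else:
                pmr = float(rng.uniform(0.0, config.control_pmr_max))
            gene_q = pmr / 100.0 * config.calibrator_ratio * ref_q
            for rep in range(1, config.n_replicates + 1):
                plate_rows.append(
                    {"sample": row.sample, "assay": gene, "replicate": rep,
                     "ct": ct_of(gene_q), "role": "sample",
                     "known_quantity": np.nan}
                )
            truth_rows.append(
                {"sample": row.sample, "gene": gene, "group": row.group,
                 "series": row.series, "true_pmr": pmr,
                 "methylated": methylated}
            )
        for rep in range(1, config.n_replicates + 1):
            plate_rows.append(
                {"sample": row.sample, "assay": REFERENCE_ASSAY,
                 "replicate": rep, "ct": ct_of(ref_q), "role": "sample",
                 "known_quantity": np.nan}
            )

    return pd.DataFrame(plate_rows), cohort, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# bisulfite traces


def simulate_traces(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic bisulfite-trace peak table plus planted levels.

    One trace per panel gene x cell-line sample. Each gene x sample gets a
    planted methylation level drawn from {0, 0.5, 1.0}; every CpG site's
    C fraction is the level plus bounded noise (clipped to [0, 1]). Non-CpG
    cytosine rows are emitted fully converted (T-only) as conversion
    controls. Returns ``(traces, truth)``.
    """
    config.validate()
    rng = config.rng(_STREAM_TRACES)
    samples = [
        f"{t}_cl{i}"
        for t in LYMPHOMA_TYPES
        for i in range(1, config.n_celllines_per_type + 1)
    ]
    levels = (0.0, 0.5, 1.0)
    trace_rows = []
    truth_rows = []
    for gene in config.panel_genes:
        for sample in samples:
            level = float(levels[rng.integers(len(levels))])
            truth_rows.append({"gene": gene, "sample": sample,
                               "planted_level": level})
            positions = -np.sort(rng.choice(np.arange(10, 400), size=(
                config.n_cpg_sites + config.n_non_cpg_sites), replace=False))
            site_types = ["cpg"] * config.n_cpg_sites + (
                ["non_cpg_c"] * config.n_non_cpg_sites)
            rng.shuffle(site_types)
            for pos, site_type in zip(positions, site_types):
                height = config.trace_peak_height * float(rng.uniform(0.5, 1.5))
                if site_type == "cpg":
                    frac = level
                    if config.trace_noise > 0:
                        frac += float(rng.uniform(-config.trace_noise,
                                                  config.trace_noise))
                    frac = float(np.clip(frac, 0.0, 1.0))
                else:
                    frac = 0.0  # complete bisulfite conversion
                peak_c = round(height * frac, 3)
                peak_t = round(height - peak_c, 3)
                trace_rows.append(
                    {"gene": gene, "sample": sample, "position": int(pos),
                     "site_type": site_type, "peak_C": peak_c,
                     "peak_T": peak_t}
                )
    return pd.DataFrame(trace_rows), pd.DataFrame(truth_rows)
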