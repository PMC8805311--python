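"""Per-case orchestration, cohort summaries and the statistical comparisons.

One *case* is: a ground-truth structure set, a test (auto-segmented)
structure set, and two dose grids — the reference plan optimized on the
ground-truth contours and the test plan optimized on the test contours.
Geometric metrics compare the structure sets; DVH parameters are always
evaluated on the *ground-truth* structures, once per dose grid, so they
measure the dosimetric consequence of planning on the wrong contour, not
the contour difference itself. The rectum's slice restriction is applied
before its geometric metrics.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import dosimetry, geometry
from .dosimetry import MarginSpec, cumulative_dvh, dvh_D, dvh_V
from .gamma import GammaCriteria, gamma_index
from .grids import BinaryMask3D, DoseGrid

__all__ = [
    "EvalConfig",
    "CaseMetrics",
    "evaluate_case",
    "evaluate_cohort",
    "dvh_differences",
    "wilcoxon_signed_rank",
    "pearson_r",
    "plan_consistency_check",
    "summarize_cohort",
    "cases_to_frame",
    "ingest_printed_tables",
    "correlation_report",
]

#: DVH parameters evaluated per structure: (kind, value); kind "D" takes a
#: volume-percent and returns Gy, kind "V" a Gy threshold (or % of
#: prescription when suffixed "%") and returns percent volume.
DEFAULT_DVH_PARAMS: dict[str, list[str]] = {
    "prostate": ["D98", "D2", "V95%"],
    "ctv": ["D98", "D2", "V95%"],  # prostate + 3 mm surrogate-CTV expansion
    "rectum": ["V50", "V65", "V70"],
    "bladder": ["V60", "V65", "V70"],
}


@dataclasses.dataclass
class EvalConfig:
    """Everything the per-case evaluation needs beyond the data itself."""

    prescription: float = 74.0
    fractions: int = 37
    ptv_margins: MarginSpec = dataclasses.field(default_factory=MarginSpec)
    ctv_margin_mm: float = 3.0
    isodose_pct: float = 95.0  # prescription isodose defining the Paddick PIV
    gamma_dose_pct: float = 3.0
    gamma_distance_mm: float = 3.0
    gamma_cutoff_pct: float = 10.0
    dvh_bin_width: float = 0.01
    dvh_params: dict[str, list[str]] = dataclasses.field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_DVH_PARAMS.items()}
    )
    slice_restricted: tuple[str, ...] = ("rectum",)

    @property
    def gamma_criteria(self) -> GammaCriteria:
        return GammaCriteria(
            prescription=self.prescription,
            dose_tolerance_pct=self.gamma_dose_pct,
            distance_tolerance_mm=self.gamma_distance_mm,
            cutoff_pct=self.gamma_cutoff_pct,
        )


@dataclasses.dataclass
class CaseMetrics:
    """All geometric and dosimetric metrics of one case."""

    case_id: str
    dsc: dict[str, float]
    hd_avg: dict[str, float]
    hd95: dict[str, float]
    dvh_ref: dict[str, float]  # parameter -> value under the reference plan
    dvh_test: dict[str, float]  # parameter -> value under the test plan
    ci_ref: float
    ci_test: float
    gamma_pass_pct: float
    missing: list[str] = dataclasses.field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return bool(self.missing)


def _dvh_param(curve, token: str, prescription: float) -> float:
    kind, spec_ = token[0], token[1:]
    if kind == "D":
        return dvh_D(curve, float(spec_))
    if kind == "V":
        if spec_.endswith("%"):
            return dvh_V(curve, float(spec_[:-1]), percent_of=prescription)
        return dvh_V(curve, float(spec_))
    raise ValueError(f"unknown DVH parameter {token!r}")


def evaluate_case(
    gt_structs: dict[str, BinaryMask3D],
    test_structs: dict[str, BinaryMask3D],
    dose_ref: DoseGrid,
    dose_test: DoseGrid,
    config: EvalConfig | None = None,
    case_id: str = "case",
) -> CaseMetrics:
    """Compute every configured metric for one case.

    Structures missing from the test set are recorded in ``missing`` and
    their geometric metrics set to NaN; the case is flagged, not dropped.
    """
    config = config or EvalConfig()
    dsc_d: dict[str, float] = {}
    hda: dict[str, float] = {}
    hd95: dict[str, float] = {}
    missing: list[str] = []
    for name, gt in gt_structs.items():
        test = test_structs.get(name)
        if test is None or test.is_empty():
            missing.append(name)
            dsc_d[name] = hda[name] = hd95[name] = float("nan")
            continue
        if name in config.slice_restricted:
            test = geometry.restrict_to_reference_slices(test, gt)
        dsc_d[name] = geometry.dsc(gt, test)
        hda[name] = geometry.hd_avg(gt, test)
        hd95[name] = geometry.hd_percentile(gt, test, 95)

    prostate = gt_structs["prostate"]
    eval_structs = dict(gt_structs)
    if "ctv" in config.dvh_params and "ctv" not in eval_structs:
        eval_structs["ctv"] = dosimetry.expand_margin(
            prostate, MarginSpec.isotropic(config.ctv_margin_mm)
        )
    dvh_ref: dict[str, float] = {}
    dvh_test: dict[str, float] = {}
    for sname, tokens in config.dvh_params.items():
        struct = eval_structs.get(sname)
        if struct is None or struct.is_empty():
            continue
        c_ref = cumulative_dvh(dose_ref, struct, config.dvh_bin_width)
        c_test = cumulative_dvh(dose_test, struct, config.dvh_bin_width)
        for token in tokens:
            dvh_ref[f"{sname}_{token}"] = _dvh_param(c_ref, token, config.prescription)
            dvh_test[f"{sname}_{token}"] = _dvh_param(c_test, token, config.prescription)

    ptv = dosimetry.expand_margin(prostate, config.ptv_margins)
    ci_ref = dosimetry.paddick_ci(ptv, dose_ref, config.prescription, config.isodose_pct)
    ci_test = dosimetry.paddick_ci(ptv, dose_test, config.prescription, config.isodose_pct)
    gamma = gamma_index(dose_ref, dose_test, config.gamma_criteria)

    return CaseMetrics(
        case_id=case_id,
        dsc=dsc_d,
        hd_avg=hda,
        hd95=hd95,
        dvh_ref=dvh_ref,
        dvh_test=dvh_test,
        ci_ref=ci_ref,
        ci_test=ci_test,
        gamma_pass_pct=gamma.pass_rate_pct,
        missing=missing,
    )


def evaluate_cohort(cases, config: EvalConfig | None = None) -> list[CaseMetrics]:
    """Evaluate a list of simulated cases (see :mod:`rtsegeval.phantom`)."""
    return [
        evaluate_case(
            c.gt_masks, c.pred_masks, c.dose_ref, c.dose_test, config, c.case_id
        )
        for c in cases
    ]


def dvh_differences(case: CaseMetrics) -> dict[str, float]:
    """Signed test-minus-reference DVH parameter differences.

    Gy for D-parameters, percentage points for V-parameters.
    """
    return {k: case.dvh_test[k] - case.dvh_ref[k] for k in case.dvh_ref}


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int
    significant: bool
    note: str = ""


def wilcoxon_signed_rank(
    x, y=None, alpha: float = 0.05
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    ``x`` may be the paired differences directly, or the first sample with
    ``y`` the second. Zero differences are discarded (Wilcoxon's original
    rule); the exact null distribution is used for n <= 25 effective pairs
    and the normal approximation above. With fewer than 5 non-zero pairs a
    warning is issued and no p-value is reported; all-zero differences give
    the defined "no evidence" result (p = 1).
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, False, "all differences zero")
    if n < 5:
        warnings.warn(
            f"only {n} non-zero pairs; Wilcoxon p-value not reported"
        )
        return WilcoxonResult(float("nan"), float("nan"), n, False, "n < 5")
    method = "exact" if n <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, zero_method="wilcox", method=method)
    except ValueError:
        res = stats.wilcoxon(d, zero_method="wilcox", method="approx")
    p = float(res.pvalue)
    return WilcoxonResult(float(res.statistic), p, n, p < alpha)


@dataclasses.dataclass
class PearsonResult:
    r: float
    p_value: float
    n: int
    significant: bool


def pearson_r(x, y, alpha: float = 0.05) -> PearsonResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs two equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; correlation undefined")
        return PearsonResult(float("nan"), float("nan"), x.size, False)
    res = stats.pearsonr(x, y)
    return PearsonResult(
        float(res.statistic), float(res.pvalue), x.size, res.pvalue < alpha
    )


def plan_consistency_check(
    params_a: dict[str, float],
    params_b: dict[str, float],
    tolerance_pct: float = 2.0,
) -> pd.DataFrame:
    """Flag DVH parameters whose relative deviation exceeds the tolerance.

    Used to validate that re-planning after a contour format round trip
    reproduces the original plan's DVH parameters within +/- 2%.
    """
    if set(params_a) != set(params_b):
        raise ValueError(
            f"mismatched parameter sets: {sorted(set(params_a) ^ set(params_b))}"
        )
    rows = []
    for k in params_a:
        a, b = params_a[k], params_b[k]
        denom = abs(a) if a != 0 else 1.0
        dev = 100.0 * abs(b - a) / denom
        rows.append({"parameter": k, "a": a, "b": b,
                     "deviation_pct": dev, "within_tolerance": dev <= tolerance_pct})
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


def cases_to_frame(cases: list[CaseMetrics]) -> pd.DataFrame:
    """One row per case: DSC/HD per structure, DVH pairs and differences,
    CI and gamma pass rate."""
    rows = []
    for c in cases:
        row: dict[str, float | str] = {"case_id": c.case_id}
        for name in c.dsc:
            row[f"dsc_{name}"] = c.dsc[name]
            row[f"hdavg_{name}"] = c.hd_avg[name]
            row[f"hd95_{name}"] = c.hd95[name]
        for k, v in c.dvh_ref.items():
            row[f"ref_{k}"] = v
        for k, v in c.dvh_test.items():
            row[f"test_{k}"] = v
        for k, v in dvh_differences(c).items():
            row[f"diff_{k}"] = v
        row["ci_manual"] = c.ci_ref
        row["ci_unet"] = c.ci_test
        row["gamma_pct"] = c.gamma_pass_pct
        row["flagged"] = c.flagged
        rows.append(row)
    return pd.DataFrame(rows).set_index("case_id")


#: decimals used when reporting, matching common clinical table precision
REPORT_PRECISION = {"dsc": 2, "ci": 2, "hdavg": 1, "hd95": 1, "gamma": 0}


def _column_precision(col: str) -> int | None:
    for prefix, dec in REPORT_PRECISION.items():
        if col.startswith(prefix):
            return dec
    return None


def summarize_cohort(frame: pd.DataFrame, round_for_report: bool = False) -> pd.DataFrame:
    """Per-metric mean and sample standard deviation (ddof = 1).

    With ``round_for_report`` the summary is rounded to the reporting
    precision per metric family (2 decimals for DSC/CI, 1 for HD, whole
    percent for gamma); raw values are what the unrounded call returns.
    """
    num = frame.select_dtypes(include=[np.number])
    out = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)}).T
    if round_for_report:
        for col in out.columns:
            dec = _column_precision(col)
            if dec is not None:
                out[col] = out[col].round(dec)
    return out


def ingest_printed_tables(path: str | Path | None = None) -> pd.DataFrame:
    """Load the bundled 11-patient clinical reference cohort.

    The fixture holds transcribed per-patient DSC, HD, conformity-index and
    gamma values from a published clinical evaluation; it is reference data,
    not something this package computes.
    """
    if path is None:
        path = importlib.resources.files("rtsegeval") / "data" / "clinical_tables.csv"
    df = pd.read_csv(path, comment="#")
    expected = {
        "patient", "dsc_prostate", "dsc_bladder", "dsc_rectum",
        "hdavg_prostate", "hd95_prostate", "hdavg_bladder", "hd95_bladder",
        "hdavg_rectum", "hd95_rectum", "ci_manual", "ci_unet", "gamma_pct",
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"malformed cohort table, missing columns {sorted(missing)}")
    if df.isna().any().any():
        raise ValueError("malformed cohort table: missing values")
    return df.set_index("patient")


def correlation_report(frame: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """The three geometric-vs-dosimetric correlation families.

    (1) prostate DSC vs gamma pass rate; (2) mean organ DSC vs gamma pass
    rate; (3) prostate DSC vs each DVH-difference parameter present in the
    frame. Constant columns yield NaN correlations (reported, not dropped).
    """
    if len(frame) < 3:
        raise ValueError("correlation_report needs at least 3 cases")
    dsc_cols = [c for c in frame.columns if c.startswith("dsc_")]
    pairs: list[tuple[str, pd.Series, pd.Series]] = [
        ("dsc_prostate vs gamma_pct", frame["dsc_prostate"], frame["gamma_pct"]),
        (
            "mean_dsc vs gamma_pct",
            frame[dsc_cols].mean(axis=1),
            frame["gamma_pct"],
        ),
    ]
    for col in frame.columns:
        if col.startswith("diff_"):
            pairs.append((f"dsc_prostate vs {col}", frame["dsc_prostate"], frame[col]))
    rows = []
    for name, x, y in pairs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pearson_r(x.to_numpy(), y.to_numpy(), alpha)
        rows.append(
            {"pair": name, "r": res.r, "p_value": res.p_value,
             "n": res.n, "significant": res.significant}
        )
    return pd.DataFrame(rows).set_index("pair")
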