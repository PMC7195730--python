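"""End-to-end study pipeline: simulate -> cohort -> coverage -> ITS.

Runs the whole analysis on a generated (or previously written) population:
build the quarterly cohort under the administrative or EMR algorithm, score
per-quarter medication coverage for each analysis class, fit the segmented
regression, and emit the study-shaped tables — quarterly patient
characteristics, quarterly coverage rates, and the four ITS parameters per
class.  A per-stage structured log records counts in/out so cohort
attrition is auditable.

Segment bookkeeping: the default window 2010Q1-2016Q4 contains 28 quarters
with the intervention at index 13 (2013Q2), i.e. 13 pre- and 15
post-intervention quarters.  The source analyses used 13 and 14; the
pipeline therefore drops the final quarter by default (``keep_last_quarter``
restores it), which reproduces the 13 + 14 segment lengths.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohorts, coverage, its
from .quarters import QuarterId, StudyWindow, quarter_of
from .synthetic import PatientBundle, SimConfig, generate_population, read_bundle

logger = logging.getLogger("rxcoverage")

ADMIN_DEFAULT_CLASSES = ("STATIN", "ACEI_OR_ARB", "ANTIPLATELET", "PPI")
EMR_DEFAULT_CLASSES = ("STATIN", "ACEI", "ARB", "ACEI_OR_ARB", "ANTIPLATELET", "PPI")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StudyConfig:
    """One full study run."""

    sim: SimConfig | None = None
    input_dir: str | Path | None = None
    algorithm: str = "admin"  # "admin" or "emr"
    classes: tuple[str, ...] | None = None  # default depends on algorithm
    intervention_quarter: QuarterId | None = None  # default: simulation's
    exclude_no_encounter: bool = False  # sensitivity analysis (EMR only)
    output_dir: str | Path | None = None
    error_model: str = "iid"
    weighted: bool = False
    keep_last_quarter: bool = False
    fixed_90_day_quarters: bool = False
    make_figures: bool = False

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("provide exactly one of sim config or input_dir")
        if self.algorithm not in ("admin", "emr"):
            raise ValueError(f"algorithm must be 'admin' or 'emr', got {self.algorithm!r}")
        if self.classes is not None and len(self.classes) == 0:
            raise ValueError("classes must be non-empty")
        if self.exclude_no_encounter and self.algorithm != "emr":
            raise ValueError("exclude_no_encounter sensitivity applies to the EMR algorithm only")


def default_classes(algorithm: str) -> tuple[str, ...]:
    return EMR_DEFAULT_CLASSES if algorithm == "emr" else ADMIN_DEFAULT_CLASSES


def sensitivity_exclude_no_encounter(
    bundle: PatientBundle, cohort: cohorts.CohortQuarters
) -> cohorts.CohortQuarters:
    """Restrict an EMR cohort to patients with at least one EMR encounter."""
    if cohort.algorithm != "emr":
        raise ValueError("sensitivity analysis requires an EMR-algorithm cohort")
    with_enc = np.isin(cohort.patient_ids, bundle.encounters["patient_id"].unique())
    eligible = cohort.eligible & with_enc[:, np.newaxis]
    logger.info(
        "sensitivity exclude-no-encounter: %d of %d patients retained",
        int(with_enc.sum()), len(with_enc),
    )
    return cohorts.CohortQuarters(
        patient_ids=cohort.patient_ids,
        eligible=eligible,
        window=cohort.window,
        algorithm=cohort.algorithm,
        reasons=cohort.reasons,
    )


def characteristics_table(
    bundle: PatientBundle, cohort: cohorts.CohortQuarters
) -> pd.DataFrame:
    """Quarterly cohort description: size, age, sex, AMI history, enrollment."""
    window = cohort.window
    patients = bundle.patients.set_index("patient_id").reindex(cohort.patient_ids)
    birth = pd.to_datetime(patients["birth_date"]).to_numpy(dtype="datetime64[D]")
    female = (patients["sex"] == "F").to_numpy()
    ami = pd.to_datetime(patients["ami_history_date"]).to_numpy(dtype="datetime64[D]")
    enroll = bundle.enrollment_spells
    rows = []
    for j, label in enumerate(window.labels):
        mask = cohort.eligible[:, j]
        n = int(mask.sum())
        row: dict = {"label": label, "t": j, "n": n}
        if n:
            age_days = (window.starts[j] - birth[mask]).astype(int)
            age = age_days / 365.25
            virt = _virtual_at(enroll, cohort.patient_ids[mask], window.starts[j])
            row.update(
                age_mean=float(age.mean()),
                age_median=float(np.median(age)),
                pct_female=100.0 * float(female[mask].mean()),
                pct_ami_history=100.0
                * float((~np.isnat(ami[mask]) & (ami[mask] < window.ends[j])).mean()),
                pct_virtual_enrolled=100.0 * float(virt.mean()) if virt is not None else np.nan,
            )
        else:
            row.update(
                age_mean=np.nan, age_median=np.nan, pct_female=np.nan,
                pct_ami_history=np.nan, pct_virtual_enrolled=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _virtual_at(enrollment: pd.DataFrame, pids: np.ndarray, on: np.datetime64):
    if "virtual" not in enrollment.columns or enrollment.empty:
        return None
    sp = enrollment[
        (enrollment["start_date"].to_numpy(dtype="datetime64[D]") <= on)
        & (enrollment["end_date"].to_numpy(dtype="datetime64[D]") > on)
    ]
    virt = sp.groupby("patient_id")["virtual"].any()
    return virt.reindex(pids).fillna(False).to_numpy(dtype=bool)


def _study_window(bundle: PatientBundle, cfg: StudyConfig) -> StudyWindow:
    sim = bundle.config
    if sim is None:
        raise ValueError("bundle carries no config; cannot derive the study window")
    window = sim.window()
    if cfg.fixed_90_day_quarters:
        n = len(window)
        iq = cfg.intervention_quarter or sim.intervention_quarter
        t0 = int(
            window.period_index(np.array([iq.start], dtype="datetime64[D]"))[0]
        )
        return StudyWindow.fixed_90_day(sim.study_start, n, t0)
    if cfg.intervention_quarter is not None:
        first = quarter_of(sim.study_start)
        return StudyWindow.calendar_quarters(
            first, quarter_of(sim.study_end), cfg.intervention_quarter
        )
    return window


def run_study(cfg: StudyConfig) -> dict:
    """Run simulate -> cohort -> coverage -> ITS and return all tables.

    Returns a dict with keys ``bundle``, ``cohort``, ``characteristics``,
    ``rates``, ``its``, ``fits``; writes CSVs (and optional figures) to
    ``cfg.output_dir`` when set.  Deterministic given the configuration.
    """
    # --- stage: input -------------------------------------------------
    try:
        bundle = generate_population(cfg.sim) if cfg.sim is not None else read_bundle(cfg.input_dir)
    except Exception as exc:
        raise StageError("simulate/read", exc) from exc
    window = _study_window(bundle, cfg)
    logger.info("input: %d patients, %d dispensings", len(bundle.patients), len(bundle.dispensings))

    # --- stage: cohort ------------------------------------------------
    try:
        cohort = cohorts.eligibility_matrix(bundle, cfg.algorithm, window)
        if cfg.exclude_no_encounter:
            cohort = sensitivity_exclude_no_encounter(bundle, cohort)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("cohort", exc) from exc
    logger.info(
        "cohort (%s): quarterly n %d..%d",
        cfg.algorithm, int(cohort.eligible.sum(axis=0).min()), int(cohort.eligible.sum(axis=0).max()),
    )

    # --- stage: coverage ----------------------------------------------
    classes = cfg.classes or default_classes(cfg.algorithm)
    rates_frames = []
    try:
        for cls in classes:
            series = coverage.class_series(bundle, cohort, cls, window)
            rates_frames.append(series.table)
    except Exception as exc:
        raise StageError("coverage", exc) from exc
    rates = pd.concat(rates_frames, ignore_index=True)

    # --- stage: its ---------------------------------------------------
    t0 = window.intervention_index
    n_q = len(window)
    fit_rates = rates if cfg.keep_last_quarter else rates[rates["t"] < n_q - 1]
    fits: dict[str, its.ITSFit] = {}
    its_frames = []
    try:
        for cls in classes:
            sub = fit_rates[fit_rates["class"] == cls]
            fit = its.fit_segmented(sub, t0, error_model=cfg.error_model, weighted=cfg.weighted)
            fits[cls] = fit
            its_frames.append(fit.to_frame(cls))
    except Exception as exc:
        raise StageError("its", exc) from exc
    its_table = pd.concat(its_frames, ignore_index=True)
    chars = characteristics_table(bundle, cohort)

    result = {
        "bundle": bundle,
        "cohort": cohort,
        "characteristics": chars,
        "rates": rates,
        "its": its_table,
        "fits": fits,
    }
    if cfg.output_dir is not None:
        _write_outputs(result, cfg, window)
    return result


def _write_outputs(result: dict, cfg: StudyConfig, window: StudyWindow) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["characteristics"].to_csv(out / "characteristics.csv", index=False)
    rates = result["rates"].copy()
    rates.to_csv(out / "rates.csv", index=False, float_format="%.6f")
    result["its"].to_csv(out / "its.csv", index=False, float_format="%.8g")
    result["cohort"].to_table().to_csv(out / "cohort.csv", index=False)
    if cfg.make_figures:
        for cls, fit in result["fits"].items():
            sub = result["rates"][result["rates"]["class"] == cls]
            plot_series(sub, fit, window, out / f"its_{cls}.png")


def plot_series(rates: pd.DataFrame, fit: its.ITSFit, window: StudyWindow, path) -> None:
    """Observed quarterly points, fitted segments, dashed counterfactual."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = rates["t"].to_numpy(dtype=float)
    y = rates["rate_percent"].to_numpy(dtype=float)
    t0 = fit.t0
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(t, y, "o", ms=3, color="k", label="observed")
    pre = np.linspace(t.min(), t0 - 1, 50)
    post = np.linspace(t0, t.max(), 50)
    ax.plot(pre, its.predict(fit, pre), "-", color="C0", label="fitted")
    ax.plot(post, its.predict(fit, post), "-", color="C0")
    ax.plot(post, its.counterfactual(fit, post), "--", color="C1", label="counterfactual")
    ax.axvline(t0 - 0.5, color="grey", lw=0.8)
    ax.set_xlabel("quarter index")
    ax.set_ylabel("coverage (%)")
    ax.set_title(str(rates["class"].iloc[0]))
    ax.legend(frameon=False, fontsize=8)
    step = max(len(window.labels) // 7, 1)
    ticks = np.arange(0, len(window.labels), step)
    ax.set_xticks(ticks)
    ax.set_xticklabels([window.labels[i] for i in ticks], rotation=45, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
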