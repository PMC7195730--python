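"""Synthetic claims-data generator with known ground truth.

Generates the raw record tables an administrative pharmacoepidemiology
study consumes — patients, pharmacy dispensings, physician billing claims,
hospital discharges, insurance-eligibility and primary-care-enrollment
spells, and EMR encounter dates — for a closed population of older adults,
most of whom have diabetes.

The generator's central contract is *known truth*: each drug class follows
a piecewise-linear coverage trajectory (baseline level, pre-intervention
slope, level change at the intervention quarter, slope change after it).
Every (patient, quarter, class) cell is drawn covered/uncovered with the
trajectory's probability, and dispensing sequences are then constructed so
that the coverage engine reproduces those labels exactly: covered runs are
tiled with <=90-day supplies (refilled a few days early, exercising the
carryover rule), uncovered quarters receive at most a short supply well
below the 75% threshold.  Diabetes case status is likewise generated by
inverting the administrative case definition, so the classifier's output
agrees with the latent truth by construction.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quarters import QuarterId, StudyWindow, quarter_of

DRUG_CLASSES = ("STATIN", "ACEI", "ARB", "ANTIPLATELET", "PPI")

#: classes whose per-quarter coverage indicators are mutually exclusive
#: (a patient takes an ACE inhibitor or an ARB in a quarter, rarely both;
#: this makes the combined-class rate the sum of the two, matching the
#: near-additive pattern seen in real dispensing data).
EXCLUSIVE_GROUPS = (("ACEI", "ARB"),)


class TrajectoryError(ValueError):
    pass


class BundleIOError(ValueError):
    pass


@dataclass(frozen=True)
class CoverageTrajectory:
    """Piecewise-linear true coverage path, in percent.

    value(t) = baseline + pre_slope*t                      for t < t0
             = ... + level_change + slope_change*(t - t0)  for t >= t0
    """

    baseline_level: float
    pre_slope: float
    level_change: float
    slope_change: float

    def value(self, t, t0: int):
        t = np.asarray(t, dtype=float)
        post = t >= t0
        return (
            self.baseline_level
            + self.pre_slope * t
            + post * (self.level_change + self.slope_change * (t - t0))
        )


# Default trajectories: magnitudes of the four segmented-regression
# parameters observed for each class in province-wide dispensing data
# (statins slowly rising, ACEI falling with ARBs replacing them,
# antiplatelets declining, PPIs rising), ACEI + ARB summing to the
# combined-class path.
DEFAULT_TRAJECTORIES: dict[str, CoverageTrajectory] = {
    "STATIN": CoverageTrajectory(60.99, 0.20, -0.26, -0.12),
    "ACEI": CoverageTrajectory(41.50, -0.15, 0.11, 0.01),
    "ARB": CoverageTrajectory(20.66, 0.02, 0.10, -0.01),
    "ANTIPLATELET": CoverageTrajectory(10.46, -0.12, -0.09, -0.03),
    "PPI": CoverageTrajectory(22.67, 0.22, 0.09, -0.11),
}

DEFAULT_HAZARDS: dict[str, float] = {
    # annual event hazards; exponential waiting times, earliest event wins
    "death": 0.045,
    "eligibility_loss": 0.005,
    "disenrollment": 0.010,
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic population."""

    n_patients: int
    study_start: dt.date = dt.date(2010, 1, 1)
    study_end: dt.date = dt.date(2016, 12, 31)  # inclusive
    intervention_quarter: QuarterId = QuarterId(2013, 2)
    age_range_at_start: tuple[int, int] = (66, 90)
    trajectories: dict[str, CoverageTrajectory] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES)
    )
    diabetes_prevalence_admin: float = 0.85
    diabetes_prevalence_emr_flag: float = 0.80
    annual_hazards: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    ami_history_prob: float = 0.083
    rng_seed: int = 0
    # secondary generator knobs
    prevalent_fraction: float = 0.9  # diabetic before study start
    no_encounter_prob: float = 0.10  # EMR presence without visit dates
    virtual_enrollment_prob: float = 0.05
    near_miss_claim_prob: float = 0.15  # single diabetes claim, non-case
    gestational_negative_prob: float = 0.05  # claims inside a pregnancy window
    noise_dispensing_prob: float = 0.08  # short supply in an uncovered quarter
    refill_jitter_days: int = 7

    # -- derived ------------------------------------------------------
    def window(self) -> StudyWindow:
        return StudyWindow.calendar_quarters(
            quarter_of(self.study_start), quarter_of(self.study_end), self.intervention_quarter
        )

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not self.study_start < self.study_end:
            raise ValueError("study_start must precede study_end")
        first, last = quarter_of(self.study_start), quarter_of(self.study_end)
        t0 = self.intervention_quarter.index(first)
        if not (0 < t0 < last.index(first)):
            raise ValueError("intervention_quarter must lie strictly inside the study window")
        for name, p in (
            ("diabetes_prevalence_admin", self.diabetes_prevalence_admin),
            ("diabetes_prevalence_emr_flag", self.diabetes_prevalence_emr_flag),
            ("ami_history_prob", self.ami_history_prob),
            ("prevalent_fraction", self.prevalent_fraction),
            ("no_encounter_prob", self.no_encounter_prob),
            ("virtual_enrollment_prob", self.virtual_enrollment_prob),
            ("near_miss_claim_prob", self.near_miss_claim_prob),
            ("gestational_negative_prob", self.gestational_negative_prob),
            ("noise_dispensing_prob", self.noise_dispensing_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.diabetes_prevalence_emr_flag > self.diabetes_prevalence_admin:
            raise ValueError(
                "diabetes_prevalence_emr_flag cannot exceed diabetes_prevalence_admin "
                "(every EMR-flagged patient is also an administrative case)"
            )
        if self.age_range_at_start[0] > self.age_range_at_start[1]:
            raise ValueError("age_range_at_start must be (low, high)")
        self._validate_trajectories()

    def _validate_trajectories(self) -> None:
        window = self.window()
        t = np.arange(len(window))
        t0 = window.intervention_index
        for cls, traj in self.trajectories.items():
            vals = traj.value(t, t0)
            bad = np.nonzero((vals < 0) | (vals > 100))[0]
            if len(bad):
                raise TrajectoryError(
                    f"trajectory for {cls} leaves [0, 100] at quarter "
                    f"{window.labels[bad[0]]} (value {vals[bad[0]]:.2f})"
                )
        for group in EXCLUSIVE_GROUPS:
            present = [c for c in group if c in self.trajectories]
            if len(present) > 1:
                total = sum(self.trajectories[c].value(t, t0) for c in present)
                bad = np.nonzero(total > 100)[0]
                if len(bad):
                    raise TrajectoryError(
                        f"combined trajectory for {'+'.join(present)} exceeds 100% at "
                        f"quarter {window.labels[bad[0]]}"
                    )

    # -- (de)serialization -------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["intervention_quarter"] = str(self.intervention_quarter)
        d["age_range_at_start"] = list(self.age_range_at_start)
        d["trajectories"] = {
            c: dataclasses.asdict(t) for c, t in self.trajectories.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "study_start" in d:
            d["study_start"] = dt.date.fromisoformat(str(d["study_start"]))
        if "study_end" in d:
            d["study_end"] = dt.date.fromisoformat(str(d["study_end"]))
        if "intervention_quarter" in d:
            iq = d["intervention_quarter"]
            d["intervention_quarter"] = (
                iq if isinstance(iq, QuarterId) else QuarterId.from_label(str(iq))
            )
        if "age_range_at_start" in d:
            d["age_range_at_start"] = tuple(d["age_range_at_start"])
        if "trajectories" in d:
            d["trajectories"] = {
                c: t if isinstance(t, CoverageTrajectory) else CoverageTrajectory(**t)
                for c, t in d["trajectories"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


TABLE_SCHEMAS: dict[str, dict] = {
    "patients": {
        "columns": [
            "patient_id", "birth_date", "sex", "death_date",
            "emr_diabetes_flag", "emr_flag_date", "ami_history_date",
        ],
        "dates": ["birth_date", "death_date", "emr_flag_date", "ami_history_date"],
        "bools": ["emr_diabetes_flag"],
        "strings": ["sex"],
    },
    "dispensings": {
        "columns": ["patient_id", "dispense_date", "drug_class", "days_supplied"],
        "dates": ["dispense_date"],
        "bools": [],
        "strings": ["drug_class"],
    },
    "claims": {
        "columns": ["patient_id", "service_date", "diagnosis_code"],
        "dates": ["service_date"],
        "bools": [],
        "strings": ["diagnosis_code"],
    },
    "discharges": {
        "columns": ["patient_id", "discharge_date", "diagnosis_code", "pregnancy_delivery"],
        "dates": ["discharge_date"],
        "bools": ["pregnancy_delivery"],
        "strings": ["diagnosis_code"],
    },
    "eligibility": {
        "columns": ["patient_id", "start_date", "end_date"],
        "dates": ["start_date", "end_date"],
        "bools": [],
    },
    "enrollment": {
        "columns": ["patient_id", "start_date", "end_date", "virtual"],
        "dates": ["start_date", "end_date"],
        "bools": ["virtual"],
    },
    "encounters": {
        "columns": ["patient_id", "encounter_date"],
        "dates": ["encounter_date"],
        "bools": [],
    },
}

_TABLE_ATTRS = {
    "patients": "patients",
    "dispensings": "dispensings",
    "claims": "claims",
    "discharges": "discharges",
    "eligibility": "eligibility_spells",
    "enrollment": "enrollment_spells",
    "encounters": "encounters",
}


@dataclass
class PatientBundle:
    """All raw records for one synthetic population, plus latent truth."""

    patients: pd.DataFrame
    dispensings: pd.DataFrame
    claims: pd.DataFrame
    discharges: pd.DataFrame
    eligibility_spells: pd.DataFrame
    enrollment_spells: pd.DataFrame
    encounters: pd.DataFrame
    config: SimConfig | None = None
    truth_diabetes: np.ndarray | None = None  # by sorted patient_id
    truth_coverage: dict[str, np.ndarray] | None = None  # class -> (n, n_q) bool

    @property
    def window(self) -> StudyWindow:
        if self.config is not None:
            return self.config.window()
        raise ValueError("bundle has no config; pass a StudyWindow explicitly")

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, attr) for name, attr in _TABLE_ATTRS.items()}

    def tables_equal(self, other: "PatientBundle") -> bool:
        for name, attr in _TABLE_ATTRS.items():
            a = getattr(self, attr).reset_index(drop=True).copy()
            b = getattr(other, attr).reset_index(drop=True).copy()
            for col in TABLE_SCHEMAS[name]["dates"]:
                a[col] = pd.to_datetime(a[col]).astype("datetime64[ns]")
                b[col] = pd.to_datetime(b[col]).astype("datetime64[ns]")
            try:
                pd.testing.assert_frame_equal(a, b, check_dtype=False)
            except AssertionError:
                return False
        return True


# ---------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------

def _empty_tables() -> dict[str, pd.DataFrame]:
    out = {}
    for name, schema in TABLE_SCHEMAS.items():
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in schema["columns"]})
        df["patient_id"] = df["patient_id"].astype(np.int64)
        for c in schema["dates"]:
            df[c] = pd.to_datetime(df[c])
        for c in schema["bools"]:
            df[c] = df[c].astype(bool)
        if "days_supplied" in df.columns:
            df["days_supplied"] = df["days_supplied"].astype(np.int64)
        out[name] = df
    return out


def _birth_dates(start: dt.date, ages: np.ndarray, offsets: np.ndarray) -> pd.Series:
    day = min(start.day, 28)  # sidestep Feb-29 anniversaries
    anniv = pd.to_datetime(
        {"year": start.year - ages, "month": start.month, "day": day}
    )
    return anniv - pd.to_timedelta(offsets, unit="D")


def _runs_to_dispensings(
    truth: np.ndarray, day_offs: np.ndarray, rng: np.random.Generator, jitter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dispensing events realizing a boolean coverage matrix exactly.

    Each maximal run of covered quarters is tiled with 90-day supplies,
    refills arriving up to ``jitter`` days early (carryover absorbs the
    overlap), the final supply truncated so the covered span ends exactly
    at the run's last quarter boundary.
    Returns (patient_row, day_offset, days_supplied).
    """
    n, n_q = truth.shape
    if n == 0 or not truth.any():
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    pad = np.zeros((n, 1), dtype=bool)
    t = np.hstack([pad, truth, pad]).astype(np.int8)
    d = t[:, 1:] - t[:, :-1]
    rows_s, q_start = np.nonzero(d == 1)
    rows_e, q_end = np.nonzero(d == -1)  # row-major order pairs with starts
    start_day = day_offs[q_start]
    end_day = day_offs[q_end]
    span = end_day - start_day
    k = (span + 89) // 90
    total = int(k.sum())
    run_of = np.repeat(np.arange(len(k)), k)
    j = np.arange(total) - np.repeat(np.cumsum(k) - k, k)
    last = j == k[run_of] - 1
    supply = np.where(last, span[run_of] - 90 * (k[run_of] - 1), 90).astype(np.int64)
    jit = rng.integers(0, jitter + 1, size=total)
    jit[j == 0] = 0
    dates = start_day[run_of] + 90 * j - jit
    return rows_s[run_of], dates, supply


def _noise_dispensings(
    truth: np.ndarray,
    active: np.ndarray,
    day_offs: np.ndarray,
    q_len: np.ndarray,
    prob: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short, sub-threshold supplies inside isolated uncovered quarters.

    Restricted to quarters whose neighbours are also uncovered so the noise
    can neither merge with a covered run nor push any quarter past the 75%
    threshold (max 21 + 21 spill-free days << 67).
    """
    n, n_q = truth.shape
    if n == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    pad = np.zeros((n, 1), dtype=bool)
    left = np.hstack([pad, truth[:, :-1]])
    right = np.hstack([truth[:, 1:], pad])
    candidate = active & ~truth & ~left & ~right
    pick = candidate & (rng.random(truth.shape) < prob)
    rows, qs = np.nonzero(pick)
    if len(rows) == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    offset = rng.integers(0, q_len[qs] - 25)
    supply = rng.integers(7, 22, size=len(rows))
    return rows, day_offs[qs] + offset, supply


def generate_population(config: SimConfig) -> PatientBundle:
    """Generate one synthetic population. Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    window = config.window()
    n = config.n_patients
    n_q = len(window)
    origin = np.datetime64(config.study_start, "D")
    total_days = int((window.ends[-1] - origin).astype(int))
    day_offs = window.day_offsets()
    q_len = window.n_days
    t0 = window.intervention_index

    if n == 0:
        tables = _empty_tables()
        return PatientBundle(
            patients=tables["patients"],
            dispensings=tables["dispensings"],
            claims=tables["claims"],
            discharges=tables["discharges"],
            eligibility_spells=tables["eligibility"],
            enrollment_spells=tables["enrollment"],
            encounters=tables["encounters"],
            config=config,
            truth_diabetes=np.zeros(0, dtype=bool),
            truth_coverage={c: np.zeros((0, n_q), dtype=bool) for c in config.trajectories},
        )

    pids = np.arange(1, n + 1, dtype=np.int64)
    lo, hi = config.age_range_at_start
    ages = rng.integers(lo, hi + 1, size=n)
    birth = _birth_dates(config.study_start, ages, rng.integers(0, 365, size=n))
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    # --- censoring events (independent exponential waiting times) ----
    event_day = {}
    for name, hazard in config.annual_hazards.items():
        if hazard > 0:
            t_years = rng.exponential(1.0 / hazard, size=n)
        else:
            t_years = np.full(n, np.inf)
        event_day[name] = np.where(
            t_years * 365.25 < total_days, (t_years * 365.25).astype(np.int64), np.iinfo(np.int64).max
        )
    death_day = event_day.get("death", np.full(n, np.iinfo(np.int64).max))
    elig_loss_day = event_day.get("eligibility_loss", np.full(n, np.iinfo(np.int64).max))
    disenroll_day = event_day.get("disenrollment", np.full(n, np.iinfo(np.int64).max))

    censor_day = np.minimum(np.minimum(death_day, elig_loss_day), disenroll_day)
    censor_q = np.where(
        censor_day < total_days,
        window.period_index(origin + np.minimum(censor_day, total_days - 1)),
        n_q,
    ).astype(np.int64)

    # --- diabetes truth and case-defining records --------------------
    u = rng.random(n)
    diab = u < config.diabetes_prevalence_admin
    emr_flag = diab & (u < config.diabetes_prevalence_emr_flag)  # nested: EMR subset of admin
    prevalent = rng.random(n) < config.prevalent_fraction
    index_day = np.where(
        prevalent,
        -rng.integers(1, 5 * 365, size=n),
        rng.integers(0, total_days, size=n),
    )
    # the EMR problem-list flag is recorded at or shortly after the
    # administrative index, so the EMR cohort nests inside the admin cohort
    emr_flag_day = index_day + rng.integers(0, 181, size=n)

    claims_parts, discharge_parts = [], []
    hosp_basis = diab & (rng.random(n) < 0.25)
    claim_basis = diab & ~hosp_basis
    # claims pair: second claim on the index date, first 1..730 days earlier
    cb = np.nonzero(claim_basis)[0]
    first_off = index_day[cb] - rng.integers(1, 731, size=len(cb))
    claims_parts.append((pids[cb], index_day[cb], "250"))
    claims_parts.append((pids[cb], first_off, "250"))
    hb = np.nonzero(hosp_basis)[0]
    discharge_parts.append((pids[hb], index_day[hb], "250", False))

    # non-case near-misses: a single claim, or a claim pair inside the
    # gestational exclusion window of a pregnancy/delivery discharge
    nd = np.nonzero(~diab)[0]
    style = rng.random(len(nd))
    near = nd[style < config.near_miss_claim_prob]
    claims_parts.append(
        (pids[near], rng.integers(-2 * 365, total_days, size=len(near)), "250")
    )
    gest = nd[
        (style >= config.near_miss_claim_prob)
        & (style < config.near_miss_claim_prob + config.gestational_negative_prob)
    ]
    g_day = rng.integers(-2 * 365, total_days, size=len(gest))
    discharge_parts.append((pids[gest], g_day, "650", True))
    claims_parts.append((pids[gest], g_day + rng.integers(-120, 181, size=len(gest)), "250"))
    claims_parts.append((pids[gest], g_day + rng.integers(-120, 181, size=len(gest)), "250"))

    # routine billing contacts every ~180 days until death or study end
    contact_end = np.minimum(death_day, total_days)
    first_contact = -rng.integers(0, 180, size=n)
    n_contacts = np.maximum((contact_end - first_contact) // 180, 0) + 1
    rep = np.repeat(np.arange(n), n_contacts)
    seq = np.arange(n_contacts.sum()) - np.repeat(np.cumsum(n_contacts) - n_contacts, n_contacts)
    contact_days = first_contact[rep] + 180 * seq
    keep = contact_days <= contact_end[rep]
    claims_parts.append((pids[rep[keep]], contact_days[keep], "780"))

    claims = pd.DataFrame(
        {
            "patient_id": np.concatenate([p for p, _, _ in claims_parts]),
            "service_date": pd.to_datetime(
                origin + np.concatenate([d for _, d, _ in claims_parts])
            ),
            "diagnosis_code": np.concatenate(
                [np.full(len(p), code, dtype=object) for p, _, code in claims_parts]
            ),
        }
    )
    discharges = pd.DataFrame(
        {
            "patient_id": np.concatenate([p for p, _, _, _ in discharge_parts]),
            "discharge_date": pd.to_datetime(
                origin + np.concatenate([d for _, d, _, _ in discharge_parts])
            ),
            "diagnosis_code": np.concatenate(
                [np.full(len(p), code, dtype=object) for p, _, code, _ in discharge_parts]
            ),
            "pregnancy_delivery": np.concatenate(
                [np.full(len(p), flag, dtype=bool) for p, _, _, flag in discharge_parts]
            ),
        }
    )

    # --- EMR encounters ----------------------------------------------
    has_enc = rng.random(n) >= config.no_encounter_prob
    early_first = rng.random(n) < 0.8
    first_enc = np.where(
        early_first, -rng.integers(0, 3 * 365, size=n), rng.integers(0, total_days // 2, size=n)
    )
    enc_end = np.minimum(death_day, total_days)
    n_enc = np.where(has_enc, np.maximum((enc_end - first_enc) // 180, 0) + 1, 0)
    rep = np.repeat(np.arange(n), n_enc)
    seq = np.arange(n_enc.sum()) - np.repeat(np.cumsum(n_enc) - n_enc, n_enc)
    enc_days = first_enc[rep] + 180 * seq
    keep = enc_days <= enc_end[rep]
    encounters = pd.DataFrame(
        {
            "patient_id": pids[rep[keep]],
            "encounter_date": pd.to_datetime(origin + enc_days[keep]),
        }
    )

    # --- spells -------------------------------------------------------
    hist_start = origin - np.int64(10 * 365)
    window_end = np.datetime64(window.study_end, "D")
    elig_end = np.where(
        elig_loss_day < total_days,
        origin + np.minimum(elig_loss_day, total_days),
        window_end,
    ).astype("datetime64[D]")
    enroll_end = np.where(
        disenroll_day < total_days,
        origin + np.minimum(disenroll_day, total_days),
        window_end,
    ).astype("datetime64[D]")
    eligibility = pd.DataFrame(
        {
            "patient_id": pids,
            "start_date": pd.to_datetime(np.full(n, hist_start)),
            "end_date": pd.to_datetime(elig_end),
        }
    )
    enrollment = pd.DataFrame(
        {
            "patient_id": pids,
            "start_date": pd.to_datetime(np.full(n, hist_start)),
            "end_date": pd.to_datetime(enroll_end),
            "virtual": rng.random(n) < config.virtual_enrollment_prob,
        }
    )

    # --- AMI history --------------------------------------------------
    ami = rng.random(n) < config.ami_history_prob
    ami_day = -rng.integers(1, 10 * 365, size=n)

    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "birth_date": birth,
            "sex": sex,
            "death_date": pd.to_datetime(
                np.where(
                    death_day < total_days,
                    origin + np.minimum(death_day, total_days - 1),
                    np.datetime64("NaT"),
                )
            ),
            "emr_diabetes_flag": emr_flag,
            "emr_flag_date": pd.to_datetime(
                np.where(emr_flag, origin + emr_flag_day, np.datetime64("NaT"))
            ),
            "ami_history_date": pd.to_datetime(
                np.where(ami, origin + ami_day, np.datetime64("NaT"))
            ),
        }
    )

    # --- per-class coverage truth and dispensings ---------------------
    t = np.arange(n_q)
    active = diab[:, np.newaxis] & (t[np.newaxis, :] < censor_q[:, np.newaxis])
    truth_coverage: dict[str, np.ndarray] = {}
    handled: set[str] = set()
    disp_rows, disp_days, disp_supply, disp_class = [], [], [], []

    def _emit(cls: str, truth: np.ndarray) -> None:
        truth_coverage[cls] = truth
        r, d, s = _runs_to_dispensings(truth, day_offs, rng, config.refill_jitter_days)
        nr, ndy, ns = _noise_dispensings(
            truth, active, day_offs, q_len, config.noise_dispensing_prob, rng
        )
        rows = np.concatenate([r, nr])
        disp_rows.append(rows)
        disp_days.append(np.concatenate([d, ndy]))
        disp_supply.append(np.concatenate([s, ns]))
        disp_class.append(np.full(len(rows), cls, dtype=object))

    for group in EXCLUSIVE_GROUPS:
        present = [c for c in group if c in config.trajectories]
        if len(present) > 1:
            probs = np.vstack(
                [config.trajectories[c].value(t, t0) / 100.0 for c in present]
            )  # (g, n_q)
            cum = np.cumsum(probs, axis=0)
            ug = rng.random((n, n_q))
            prev = np.zeros(n_q)
            for gi, cls in enumerate(present):
                truth = active & (ug >= prev) & (ug < cum[gi])
                _emit(cls, truth)
                prev = cum[gi]
            handled.update(present)

    for cls, traj in config.trajectories.items():
        if cls in handled:
            continue
        p = traj.value(t, t0) / 100.0
        truth = active & (rng.random((n, n_q)) < p[np.newaxis, :])
        _emit(cls, truth)

    if disp_rows:
        rows = np.concatenate(disp_rows)
        dispensings = pd.DataFrame(
            {
                "patient_id": pids[rows],
                "dispense_date": pd.to_datetime(origin + np.concatenate(disp_days)),
                "drug_class": np.concatenate(disp_class),
                "days_supplied": np.concatenate(disp_supply),
            }
        )
    else:
        dispensings = _empty_tables()["dispensings"]

    # stable, reproducible ordering
    claims = claims.sort_values(["patient_id", "service_date", "diagnosis_code"]).reset_index(drop=True)
    discharges = discharges.sort_values(["patient_id", "discharge_date"]).reset_index(drop=True)
    dispensings = dispensings.sort_values(
        ["patient_id", "drug_class", "dispense_date"]
    ).reset_index(drop=True)
    encounters = encounters.sort_values(["patient_id", "encounter_date"]).reset_index(drop=True)

    return PatientBundle(
        patients=patients,
        dispensings=dispensings,
        claims=claims,
        discharges=discharges,
        eligibility_spells=eligibility,
        enrollment_spells=enrollment,
        encounters=encounters,
        config=config,
        truth_diabetes=diab,
        truth_coverage=truth_coverage,
    )


def generate_diabetes_history(
    patient: dict,
    truth: bool,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    style: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case-defining records for one patient (inverse of the case rule).

    ``truth=True`` emits records that satisfy the administrative
    classifier with an index date before the study window's first eligible
    quarter; ``truth=False`` emits guaranteed negatives (``style`` one of
    "none", "near-miss", "gestational"; random when omitted).
    """
    rng = rng or np.random.default_rng(config.rng_seed)
    pid = patient["patient_id"]
    origin = np.datetime64(config.study_start, "D")
    claims_rows, disch_rows = [], []
    if truth:
        index_day = -int(rng.integers(1, 5 * 365))
        if rng.random() < 0.25:
            disch_rows.append((pid, index_day, "250", False))
        else:
            claims_rows.append((pid, index_day - int(rng.integers(1, 731)), "250"))
            claims_rows.append((pid, index_day, "250"))
    else:
        style = style or rng.choice(["none", "near-miss", "gestational"])
        if style == "near-miss":
            claims_rows.append((pid, int(rng.integers(-2 * 365, 365)), "250"))
        elif style == "gestational":
            g = int(rng.integers(-2 * 365, 365))
            disch_rows.append((pid, g, "650", True))
            claims_rows.append((pid, g + int(rng.integers(-120, 181)), "250"))
            claims_rows.append((pid, g + int(rng.integers(-120, 181)), "250"))
        elif style != "none":
            raise ValueError(f"unknown style {style!r}")
    claims = pd.DataFrame(
        claims_rows, columns=["patient_id", "service_date", "diagnosis_code"]
    )
    claims["service_date"] = pd.to_datetime(origin) + pd.to_timedelta(
        claims["service_date"], unit="D"
    )
    discharges = pd.DataFrame(
        disch_rows,
        columns=["patient_id", "discharge_date", "diagnosis_code", "pregnancy_delivery"],
    )
    discharges["discharge_date"] = pd.to_datetime(origin) + pd.to_timedelta(
        discharges["discharge_date"], unit="D"
    )
    return claims, discharges


# ---------------------------------------------------------------------
# Bundle IO (one CSV per record table, ISO-8601 dates, UTF-8)
# ---------------------------------------------------------------------

def write_bundle(bundle: PatientBundle, directory, include_truth: bool = True) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        out = df.copy()
        for col in TABLE_SCHEMAS[name]["dates"]:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out.to_csv(directory / f"{name}.csv", index=False)
    if bundle.config is not None:
        bundle.config.to_yaml(directory / "config.yaml")
    if include_truth and bundle.truth_coverage is not None:
        sorted_pids = np.sort(bundle.patients["patient_id"].to_numpy())
        rows = []
        for cls, m in bundle.truth_coverage.items():
            r, q = np.nonzero(m)
            rows.append(
                pd.DataFrame({"patient_id": sorted_pids[r], "drug_class": cls, "t": q})
            )
        truth = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["patient_id", "drug_class", "t"])
        )
        truth.to_csv(directory / "truth_coverage.csv", index=False)
        if bundle.truth_diabetes is not None:
            pd.DataFrame(
                {"patient_id": sorted_pids, "diabetes": bundle.truth_diabetes}
            ).to_csv(directory / "truth_patients.csv", index=False)


def _read_table(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise BundleIOError(f"missing table file: {path.name}")
    schema = TABLE_SCHEMAS[name]
    df = pd.read_csv(path, dtype={c: str for c in schema.get("strings", [])})
    unknown = set(df.columns) - set(schema["columns"])
    if unknown:
        raise BundleIOError(f"{path.name}: unknown column(s) {sorted(unknown)}")
    missing = set(schema["columns"]) - set(df.columns)
    if missing:
        raise BundleIOError(f"{path.name}: missing column(s) {sorted(missing)}")
    df = df[schema["columns"]]
    for col in schema["dates"]:
        raw = df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise BundleIOError(
                f"{path.name}: row {row}, column {col!r}: cannot parse date {raw.iloc[row]!r}"
            )
        df[col] = parsed
    for col in schema["bools"]:
        df[col] = df[col].astype(bool)
    df["patient_id"] = df["patient_id"].astype(np.int64)
    if "days_supplied" in df.columns:
        df["days_supplied"] = df["days_supplied"].astype(np.int64)
    return df


def read_bundle(directory) -> PatientBundle:
    """Read a bundle written by :func:`write_bundle`; strict about schema."""
    directory = Path(directory)
    frames = {name: _read_table(directory / f"{name}.csv", name) for name in TABLE_SCHEMAS}
    config = None
    cfg_path = directory / "config.yaml"
    if cfg_path.exists():
        config = SimConfig.from_yaml(cfg_path)
    truth_cov = None
    truth_diab = None
    tc_path = directory / "truth_coverage.csv"
    if tc_path.exists() and config is not None:
        n_q = len(config.window())
        sorted_pids = np.sort(frames["patients"]["patient_id"].to_numpy())
        row_of = pd.Series(np.arange(len(sorted_pids)), index=sorted_pids)
        tc = pd.read_csv(tc_path)
        truth_cov = {}
        for cls in config.trajectories:
            m = np.zeros((len(sorted_pids), n_q), dtype=bool)
            sub = tc[tc["drug_class"] == cls]
            if len(sub):
                m[row_of[sub["patient_id"]].to_numpy(), sub["t"].to_numpy()] = True
            truth_cov[cls] = m
        tp_path = directory / "truth_patients.csv"
        if tp_path.exists():
            tp = pd.read_csv(tp_path).set_index("patient_id")["diabetes"]
            truth_diab = tp.reindex(sorted_pids).fillna(False).to_numpy(dtype=bool)
    return PatientBundle(
        patients=frames["patients"],
        dispensings=frames["dispensings"],
        claims=frames["claims"],
        discharges=frames["discharges"],
        eligibility_spells=frames["eligibility"],
        enrollment_spells=frames["enrollment"],
        encounters=frames["encounters"],
        config=config,
        truth_diabetes=truth_diab,
        truth_coverage=truth_cov,
    )
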