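"""Diabetes case classification and quarterly cohort eligibility.

Two case definitions are supported:

* the administrative rule (the Ontario Diabetes Database algorithm): two
  physician billing claims coded ICD-9 250 within 2 years, or a single
  hospital discharge with a diabetes code — after removing any claim or
  discharge falling 120 days before to 180 days after a pregnancy/delivery
  hospital record (gestational diabetes exclusion);
* the EMR rule: a validated diabetes flag carried on the patient record
  (the flag itself is an input attribute, not recomputed here), with cohort
  entry at the quarter of the patient's first EMR encounter.

A patient contributes to a quarter when they are 66 or older at the quarter
start, case-positive strictly before the quarter start, and not yet
censored.  Censoring removes the quarter of the event itself and all later
quarters; the four censoring rules are death, last healthcare encounter
long before study end, loss of insurance eligibility, and loss of
primary-care enrollment (including virtual enrollment).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .quarters import QuarterId, StudyWindow, quarter_of

DIABETES_CODE_PREFIX = "250"
CLAIM_PAIR_WINDOW_DAYS = 730  # "within 2 years", inclusive
GESTATIONAL_BEFORE_DAYS = 120
GESTATIONAL_AFTER_DAYS = 180
DEFAULT_LOOK_AHEAD_QUARTERS = 1

AGE_FLOOR = 66

CENSOR_REASONS = (
    "censored-death",
    "censored-last-encounter",
    "censored-eligibility-loss",
    "censored-disenrollment",
)


@dataclass(frozen=True)
class DiabetesStatus:
    positive: bool
    index_date: dt.date | None = None
    basis: Literal["claims-pair", "hospitalization", "emr-flag"] | None = None


@dataclass(frozen=True)
class CensorEvent:
    quarter: QuarterId
    reason: str  # one of CENSOR_REASONS


@dataclass(frozen=True)
class EligibilityDecision:
    eligible: bool
    reason_if_not: str | None = None


@dataclass
class CohortQuarters:
    """Per-patient, per-quarter eligibility for one algorithm."""

    patient_ids: np.ndarray
    eligible: np.ndarray  # (n_patients, n_quarters) bool
    window: StudyWindow
    algorithm: str
    reasons: np.ndarray | None = field(default=None, repr=False)  # int codes, -1 = eligible

    _REASON_LABELS = (
        "too-young",
        "no-diabetes-yet",
        "pre-entry",
    ) + CENSOR_REASONS

    def to_table(self) -> pd.DataFrame:
        """Long table: one row per (patient, quarter, eligible, reason)."""
        n, n_q = self.eligible.shape
        out = pd.DataFrame(
            {
                "patient_id": np.repeat(self.patient_ids, n_q),
                "label": np.tile(np.asarray(self.window.labels, dtype=object), n),
                "t": np.tile(np.arange(n_q), n),
                "eligible": self.eligible.ravel(),
            }
        )
        if self.reasons is not None:
            labels = np.asarray(("",) + self._REASON_LABELS, dtype=object)
            out["reason"] = labels[self.reasons.ravel() + 1]
        return out


# ---------------------------------------------------------------------
# Administrative (ODD) classification
# ---------------------------------------------------------------------

def _is_diabetes_code(codes: pd.Series) -> pd.Series:
    return codes.astype(str).str.startswith(DIABETES_CODE_PREFIX)


def _gestational_excluded(dates: np.ndarray, pregnancy_dates: np.ndarray) -> np.ndarray:
    """Mask of record dates inside any [preg-120, preg+180] window."""
    if len(pregnancy_dates) == 0 or len(dates) == 0:
        return np.zeros(len(dates), dtype=bool)
    d = np.asarray(dates, dtype="datetime64[D]")[:, np.newaxis]
    g = np.asarray(pregnancy_dates, dtype="datetime64[D]")[np.newaxis, :]
    delta = (d - g).astype(int)
    return ((delta >= -GESTATIONAL_BEFORE_DAYS) & (delta <= GESTATIONAL_AFTER_DAYS)).any(axis=1)


def odd_classify(
    claims: pd.DataFrame | Sequence,
    discharges: pd.DataFrame | Sequence,
    pair_window_days: int = CLAIM_PAIR_WINDOW_DAYS,
) -> DiabetesStatus:
    """Administrative diabetes classification for a single patient.

    ``claims`` needs ``service_date``/``diagnosis_code`` columns;
    ``discharges`` needs ``discharge_date``/``diagnosis_code`` and a boolean
    ``pregnancy_delivery`` column.  Gestationally excluded records are
    removed first; the patient is positive if any diabetes-coded discharge
    remains, or any two remaining 250-claims fall within ``pair_window_days``
    of each other.  The index date is the earliest date at which the
    definition is satisfied (the discharge date, or the second claim of the
    earliest qualifying pair).
    """
    claims = _coerce_event_frame(claims, "service_date")
    discharges = _coerce_event_frame(discharges, "discharge_date", pregnancy=True)

    preg_dates = discharges.loc[
        discharges["pregnancy_delivery"].astype(bool), "discharge_date"
    ].to_numpy(dtype="datetime64[D]")

    dia_claims = claims.loc[_is_diabetes_code(claims["diagnosis_code"])]
    claim_dates = np.sort(dia_claims["service_date"].to_numpy(dtype="datetime64[D]"))
    claim_dates = claim_dates[~_gestational_excluded(claim_dates, preg_dates)]

    dia_disch = discharges.loc[
        _is_diabetes_code(discharges["diagnosis_code"])
        & ~discharges["pregnancy_delivery"].astype(bool)
    ]
    disch_dates = np.sort(dia_disch["discharge_date"].to_numpy(dtype="datetime64[D]"))
    disch_dates = disch_dates[~_gestational_excluded(disch_dates, preg_dates)]

    best_date: np.datetime64 | None = None
    basis: str | None = None
    if len(disch_dates):
        best_date = disch_dates[0]
        basis = "hospitalization"
    if len(claim_dates) >= 2:
        gaps = (claim_dates[1:] - claim_dates[:-1]).astype(int)
        ok = np.nonzero(gaps <= pair_window_days)[0]
        if len(ok):
            pair_date = claim_dates[ok[0] + 1]
            if best_date is None or pair_date < best_date:
                best_date = pair_date
                basis = "claims-pair"
    if best_date is None:
        return DiabetesStatus(positive=False)
    return DiabetesStatus(positive=True, index_date=best_date.astype(dt.date), basis=basis)


def _coerce_event_frame(records, date_col: str, pregnancy: bool = False) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    cols = {date_col: [], "diagnosis_code": []}
    if pregnancy:
        cols["pregnancy_delivery"] = []
    for rec in records:
        cols[date_col].append(rec[0])
        cols["diagnosis_code"].append(rec[1])
        if pregnancy:
            cols["pregnancy_delivery"].append(rec[2] if len(rec) > 2 else False)
    out = pd.DataFrame(cols)
    out[date_col] = pd.to_datetime(out[date_col])
    return out


def odd_classify_bulk(claims: pd.DataFrame, discharges: pd.DataFrame) -> pd.DataFrame:
    """Vectorized ODD classification for a whole population.

    Returns a frame indexed by patient_id with columns ``positive``,
    ``index_date`` (NaT when negative) and ``basis``.
    """
    preg = discharges.loc[discharges["pregnancy_delivery"].astype(bool),
                          ["patient_id", "discharge_date"]]

    def _filter_gestational(df: pd.DataFrame, date_col: str) -> pd.DataFrame:
        if preg.empty or df.empty:
            return df
        affected = df["patient_id"].isin(preg["patient_id"])
        keep = df.loc[~affected]
        cand = df.loc[affected].reset_index(drop=True)
        if cand.empty:
            return keep
        merged = cand.reset_index().merge(
            preg.rename(columns={"discharge_date": "_preg_date"}), on="patient_id"
        )
        delta = (merged[date_col] - merged["_preg_date"]).dt.days
        hit = merged.loc[
            (delta >= -GESTATIONAL_BEFORE_DAYS) & (delta <= GESTATIONAL_AFTER_DAYS), "index"
        ].unique()
        return pd.concat([keep, cand.drop(index=hit)], ignore_index=True)

    dia_claims = claims.loc[_is_diabetes_code(claims["diagnosis_code"]),
                            ["patient_id", "service_date"]]
    dia_claims = _filter_gestational(dia_claims, "service_date")
    dia_disch = discharges.loc[
        _is_diabetes_code(discharges["diagnosis_code"])
        & ~discharges["pregnancy_delivery"].astype(bool),
        ["patient_id", "discharge_date"],
    ]
    dia_disch = _filter_gestational(dia_disch, "discharge_date")

    # earliest qualifying claim pair: with dates sorted per patient, some
    # earlier claim lies within the window of claim j iff its immediate
    # predecessor does.
    pair_index = pd.Series(dtype="datetime64[ns]")
    if not dia_claims.empty:
        c = dia_claims.sort_values(["patient_id", "service_date"])
        same = c["patient_id"].to_numpy()[1:] == c["patient_id"].to_numpy()[:-1]
        gap = c["service_date"].diff().dt.days.to_numpy()[1:]
        qual = np.concatenate([[False], same & (gap <= CLAIM_PAIR_WINDOW_DAYS)])
        hits = c.loc[qual]
        pair_index = hits.groupby("patient_id")["service_date"].min()

    disch_index = pd.Series(dtype="datetime64[ns]")
    if not dia_disch.empty:
        disch_index = dia_disch.groupby("patient_id")["discharge_date"].min()

    idx = pd.DataFrame({"claims-pair": pair_index, "hospitalization": disch_index})
    if idx.empty:
        return pd.DataFrame(
            columns=["positive", "index_date", "basis"]
        ).rename_axis("patient_id")
    out = pd.DataFrame(index=idx.index)
    out["index_date"] = idx.min(axis=1)
    out["basis"] = idx.idxmin(axis=1)
    out["positive"] = True
    return out[["positive", "index_date", "basis"]].rename_axis("patient_id")


# ---------------------------------------------------------------------
# Censoring
# ---------------------------------------------------------------------

def _merge_spells(spells: pd.DataFrame) -> list[tuple[dt.date, dt.date]]:
    ivs = sorted(
        zip(spells["start_date"].dt.date, spells["end_date"].dt.date), key=lambda x: x[0]
    )
    merged: list[list] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _first_uncovered(spells: pd.DataFrame, from_date: dt.date) -> dt.date:
    """First date >= from_date not covered by any spell."""
    cur = from_date
    for s, e in _merge_spells(spells):
        if s <= cur < e:
            cur = e
        elif s > cur:
            break
    return cur


def _check_enrollment_consistency(spells: pd.DataFrame) -> None:
    if "virtual" not in spells.columns or len(spells) < 2:
        return
    sp = spells.sort_values("start_date")
    starts = sp["start_date"].to_numpy()[1:]
    ends = sp["end_date"].to_numpy()[:-1]
    virt = sp["virtual"].to_numpy()
    overlap = starts < ends
    contradictory = overlap & (virt[1:] != virt[:-1])
    if contradictory.any():
        raise ValueError("overlapping enrollment spells with contradictory virtual flags")


def censor_quarter(
    patient,
    encounters,
    eligibility_spells: pd.DataFrame,
    enrollment_spells: pd.DataFrame,
    window: StudyWindow,
    look_ahead: int = DEFAULT_LOOK_AHEAD_QUARTERS,
) -> CensorEvent | None:
    """Earliest censoring event for one patient, or None.

    ``patient`` carries ``death_date``; ``encounters`` is every recorded
    healthcare contact date (billing claims, discharges, dispensings, EMR
    encounters).  The last-encounter rule censors in the quarter after the
    final contact when that contact precedes the study end by more than
    ``look_ahead`` quarters — the rule is applied with full-window
    knowledge, as a retrospective analysis must.
    """
    _check_enrollment_consistency(enrollment_spells)
    n_q = len(window)
    study_start = window.study_start
    candidates: list[tuple[int, int]] = []  # (quarter index, reason rank)

    death = patient.get("death_date") if hasattr(patient, "get") else patient["death_date"]
    if death is not None and not pd.isna(death):
        death = pd.Timestamp(death).date()
        if death < window.study_end:
            qd = max(quarter_of(death).index(quarter_of(study_start)), 0) if death >= study_start else 0
            candidates.append((qd, 0))

    contact_dates = [pd.Timestamp(d).date() for d in encounters if not pd.isna(d)]
    if not contact_dates:
        candidates.append((0, 1))
    else:
        last = max(contact_dates)
        q_last = int(window.period_index(np.array([last], dtype="datetime64[D]"))[0])
        if (n_q - 1) - q_last > look_ahead:
            candidates.append((max(q_last + 1, 0), 1))

    for spells, rank in ((eligibility_spells, 2), (enrollment_spells, 3)):
        lost = _first_uncovered(spells, study_start)
        if lost < window.study_end:
            q_lost = int(window.period_index(np.array([lost], dtype="datetime64[D]"))[0])
            candidates.append((max(q_lost, 0), rank))

    if not candidates:
        return None
    q_idx, rank = min(candidates)
    quarters = window.quarters
    q = quarters[q_idx] if quarters is not None else quarter_of(
        window.starts[q_idx].astype(dt.date)
    )
    return CensorEvent(quarter=q, reason=CENSOR_REASONS[rank])


# ---------------------------------------------------------------------
# Per-quarter eligibility
# ---------------------------------------------------------------------

def _completed_years(birth: dt.date, on: dt.date) -> int:
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def eligible(
    patient,
    q: QuarterId,
    algorithm: Literal["admin", "emr"],
    bundle,
    look_ahead: int = DEFAULT_LOOK_AHEAD_QUARTERS,
) -> EligibilityDecision:
    """Eligibility decision for one patient and one quarter.

    Checks, in order of reporting precedence: age 66+ at quarter start,
    diabetes-positive strictly before quarter start (administrative rule, or
    EMR flag date for the EMR algorithm), EMR cohort entry (first-encounter
    quarter), then censoring.
    """
    window = bundle.window
    pid = patient["patient_id"]
    birth = pd.Timestamp(patient["birth_date"]).date()
    if _completed_years(birth, q.start) < AGE_FLOOR:
        return EligibilityDecision(False, "too-young")

    claims = bundle.claims[bundle.claims["patient_id"] == pid]
    discharges = bundle.discharges[bundle.discharges["patient_id"] == pid]
    if algorithm == "admin":
        status = odd_classify(claims, discharges)
        if not status.positive or status.index_date >= q.start:
            return EligibilityDecision(False, "no-diabetes-yet")
    elif algorithm == "emr":
        flag = bool(patient["emr_diabetes_flag"])
        flag_date = patient["emr_flag_date"]
        if not flag or pd.isna(flag_date) or pd.Timestamp(flag_date).date() >= q.start:
            return EligibilityDecision(False, "no-diabetes-yet")
        enc = bundle.encounters[bundle.encounters["patient_id"] == pid]
        if len(enc):
            first_enc = pd.Timestamp(enc["encounter_date"].min()).date()
            entry_q = quarter_of(max(first_enc, window.study_start))
            if q < entry_q:
                return EligibilityDecision(False, "pre-entry")
        # no encounter records: present in the EMR with no visit dates;
        # entry defaults to the study start
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    disp = bundle.dispensings[bundle.dispensings["patient_id"] == pid]
    enc = bundle.encounters[bundle.encounters["patient_id"] == pid]
    contacts = (
        list(claims["service_date"])
        + list(discharges["discharge_date"])
        + list(disp["dispense_date"])
        + list(enc["encounter_date"])
    )
    event = censor_quarter(
        patient,
        contacts,
        bundle.eligibility_spells[bundle.eligibility_spells["patient_id"] == pid],
        bundle.enrollment_spells[bundle.enrollment_spells["patient_id"] == pid],
        window,
        look_ahead=look_ahead,
    )
    if event is not None and not (q < event.quarter):
        return EligibilityDecision(False, event.reason)
    return EligibilityDecision(True)


def eligibility_matrix(
    bundle,
    algorithm: Literal["admin", "emr"],
    window: StudyWindow | None = None,
    look_ahead: int = DEFAULT_LOOK_AHEAD_QUARTERS,
    with_reasons: bool = False,
) -> CohortQuarters:
    """Vectorized per-quarter eligibility for a whole population.

    Same rules as :func:`eligible`, computed columnwise over quarters.
    Insurance/enrollment losses and the censoring rules are folded into a
    single per-patient censor quarter (monotone exit); entry is monotone
    through the diabetes index date.
    """
    window = window or bundle.window
    n_q = len(window)
    patients = bundle.patients.sort_values("patient_id").reset_index(drop=True)
    pids = patients["patient_id"].to_numpy()
    n = len(pids)
    pid_to_row = pd.Series(np.arange(n), index=pids)

    birth = pd.to_datetime(patients["birth_date"])
    birth_year = birth.dt.year.to_numpy()
    birth_md = (birth.dt.month * 100 + birth.dt.day).to_numpy()

    # --- diabetes entry quarter ------------------------------------
    if algorithm == "admin":
        odd = odd_classify_bulk(bundle.claims, bundle.discharges)
        index_date = odd["index_date"].reindex(pids).to_numpy(dtype="datetime64[D]")
    elif algorithm == "emr":
        flag = patients["emr_diabetes_flag"].astype(bool).to_numpy()
        index_date = pd.to_datetime(patients["emr_flag_date"]).to_numpy(dtype="datetime64[D]")
        index_date[~flag] = np.datetime64("NaT")
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    # --- censor quarter per patient --------------------------------
    censor_q, censor_rank = _censor_bulk(bundle, patients, pid_to_row, window, look_ahead)

    # --- EMR entry quarter ------------------------------------------
    if algorithm == "emr":
        first_enc = bundle.encounters.groupby("patient_id")["encounter_date"].min()
        fe = first_enc.reindex(pids).to_numpy(dtype="datetime64[D]")
        entry_q = np.where(np.isnat(fe), 0, np.clip(window.period_index(fe), 0, n_q))
    else:
        entry_q = np.zeros(n, dtype=int)

    eligible_m = np.zeros((n, n_q), dtype=bool)
    reasons = np.full((n, n_q), -1, dtype=np.int8) if with_reasons else None
    quarters = window.quarters
    for j in range(n_q):
        qstart = window.starts[j].astype(dt.date)
        q_md = qstart.month * 100 + qstart.day
        age = qstart.year - birth_year - (q_md < birth_md)
        age_ok = age >= AGE_FLOOR
        diab_ok = ~np.isnat(index_date) & (index_date < window.starts[j])
        not_censored = j < censor_q
        entered = j >= entry_q
        ok = age_ok & diab_ok & not_censored & entered
        eligible_m[:, j] = ok
        if with_reasons:
            # precedence: too-young, no-diabetes-yet, pre-entry, censored-*
            r = reasons[:, j]
            r[~ok] = 3 + censor_rank[~ok]  # censor reasons (rank 0..3)
            r[~ok & ~entered] = 2
            r[~ok & ~diab_ok] = 1
            r[~ok & ~age_ok] = 0
            reasons[:, j] = r
    return CohortQuarters(
        patient_ids=pids, eligible=eligible_m, window=window,
        algorithm=algorithm, reasons=reasons,
    )


def _censor_bulk(bundle, patients, pid_to_row, window, look_ahead):
    """Per-patient censor quarter index (n_q = none) and reason rank."""
    n = len(patients)
    n_q = len(window)
    BIG = n_q + 1
    cand = np.full((4, n), BIG, dtype=np.int64)

    death = pd.to_datetime(patients["death_date"]).to_numpy(dtype="datetime64[D]")
    has_death = ~np.isnat(death) & (death < np.datetime64(window.study_end, "D"))
    dq = np.clip(window.period_index(np.where(np.isnat(death), window.starts[0], death)), 0, n_q)
    cand[0, has_death] = dq[has_death]

    # last healthcare contact of any kind
    contact_frames = [
        bundle.claims[["patient_id", "service_date"]].rename(columns={"service_date": "d"}),
        bundle.discharges[["patient_id", "discharge_date"]].rename(columns={"discharge_date": "d"}),
        bundle.dispensings[["patient_id", "dispense_date"]].rename(columns={"dispense_date": "d"}),
        bundle.encounters[["patient_id", "encounter_date"]].rename(columns={"encounter_date": "d"}),
    ]
    contacts = pd.concat(contact_frames, ignore_index=True)
    last = contacts.groupby("patient_id")["d"].max().reindex(patients["patient_id"])
    last_np = last.to_numpy(dtype="datetime64[D]")
    no_contact = np.isnat(last_np)
    q_last = window.period_index(np.where(no_contact, window.starts[0], last_np))
    early = (n_q - 1) - q_last > look_ahead
    lq = np.clip(q_last + 1, 0, n_q)
    cand[1, early] = lq[early]
    cand[1, no_contact] = 0

    for row, spells in ((2, bundle.eligibility_spells), (3, bundle.enrollment_spells)):
        loss = _first_uncovered_bulk(spells, patients["patient_id"].to_numpy(), window)
        lost = loss < np.datetime64(window.study_end, "D")
        q_loss = np.clip(window.period_index(np.where(lost, loss, window.starts[0])), 0, n_q)
        cand[row, lost] = q_loss[lost]

    censor_q = cand.min(axis=0)
    censor_rank = cand.argmin(axis=0)
    return np.minimum(censor_q, n_q), censor_rank


def _first_uncovered_bulk(spells: pd.DataFrame, pids: np.ndarray, window: StudyWindow) -> np.ndarray:
    """Vectorized first-uncovered-date >= study start per patient.

    Spells are merged per patient (sort, running max of ends); the result is
    the end of the merged spell containing the study start, the study start
    itself when uncovered then, or study end when coverage persists.
    """
    s0 = np.datetime64(window.study_start, "D")
    s_end = np.datetime64(window.study_end, "D")
    out = np.full(len(pids), s0, dtype="datetime64[D]")  # default: uncovered at start
    if spells.empty:
        return out
    sp = spells.sort_values(["patient_id", "start_date"]).reset_index(drop=True)
    pid = sp["patient_id"].to_numpy()
    start = sp["start_date"].to_numpy(dtype="datetime64[D]")
    end = sp["end_date"].to_numpy(dtype="datetime64[D]")
    new_patient = np.concatenate([[True], pid[1:] != pid[:-1]])
    # running max of spell ends within patient -> merged coverage frontier
    grp = np.cumsum(new_patient) - 1
    frontier = _running_max_by_group(end.astype(np.int64), grp)
    gap_start = np.concatenate([[True], start.astype(np.int64)[1:] > frontier[:-1]])
    gap_start |= new_patient
    merged_id = np.cumsum(gap_start) - 1
    merged = pd.DataFrame(
        {
            "patient_id": pid,
            "mstart": start.astype(np.int64),
            "mend": frontier,
            "mid": merged_id,
        }
    ).groupby("mid").agg(
        patient_id=("patient_id", "first"), mstart=("mstart", "min"), mend=("mend", "max")
    )
    s0i = s0.astype(np.int64)
    covering = merged[(merged["mstart"] <= s0i) & (merged["mend"] > s0i)]
    per_pid = covering.groupby("patient_id")["mend"].max()
    rows = pd.Series(np.arange(len(pids)), index=pids)
    idx = rows.reindex(per_pid.index).to_numpy()
    out[idx.astype(int)] = per_pid.to_numpy().astype("datetime64[D]")
    return np.minimum(out, s_end)


def _running_max_by_group(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Cumulative max restarting at each group change (groups sorted)."""
    return pd.Series(values).groupby(pd.Series(groups)).cummax().to_numpy()
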