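"""Per-quarter medication coverage from pharmacy dispensing events.

A patient is *covered* for a drug class in a quarter when their dispensed
supply overlaps at least 75% of the quarter's days (67 days of a 90-day
quarter).  Supply carries over between refills: when a refill arrives before
the previous supply runs out, the leftover is added to the new supply, but
the leftover is capped (default 100 days, the formulary's maximum supply).
The supply did not have to be dispensed inside the quarter it covers.

The engine maintains a running supply-end ``E``: a dispensing of ``s`` days
at date ``d`` sets ``E = d + s + min(max(0, E - d), cap)``.  Days covered
are the union of the resulting half-open intervals: a 90-day supply
dispensed on day 0 covers days 0-89.

Two implementations are provided: a scalar one (`supply_intervals`,
`coverage_call`) that is the reference API, and numba kernels used by
`covered_days_matrix` / `class_series` to score whole populations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .quarters import QuarterId, StudyWindow

DEFAULT_CARRYOVER_CAP = 100
MAX_DAYS_SUPPLIED = 100
COVERAGE_FRACTION = 0.75

#: Analysis drug classes: members that count toward the class, and whether
#: patients with a myocardial-infarction history are excluded from the
#: denominator (antiplatelets are indicated for secondary prevention only,
#: so AMI patients leave that denominator).
CLASS_SPECS: dict[str, dict] = {
    "STATIN": {"members": ("STATIN",), "exclude_ami": False},
    "ACEI": {"members": ("ACEI",), "exclude_ami": False},
    "ARB": {"members": ("ARB",), "exclude_ami": False},
    "ACEI_OR_ARB": {"members": ("ACEI", "ARB"), "exclude_ami": False},
    "ANTIPLATELET": {"members": ("ANTIPLATELET",), "exclude_ami": True},
    "PPI": {"members": ("PPI",), "exclude_ami": False},
}


class DispensingValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SupplyInterval:
    """Half-open covered span: [start, end)."""

    start: dt.date
    end: dt.date

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days


@dataclass(frozen=True)
class CoverageCall:
    patient_id: int
    drug_class: str
    quarter: QuarterId
    covered_days: int
    covered: bool


@dataclass
class CoverageSeries:
    """Quarterly denominator/numerator/rate for one drug class."""

    drug_class: str
    table: pd.DataFrame = field(repr=False)  # columns: label, year, quarter, t, n, k, rate_percent


def threshold_days(q: QuarterId | int, fraction: float = COVERAGE_FRACTION) -> int:
    """Minimum covered days for a quarter to count as covered.

    ``floor(fraction * days-in-quarter)``: 67 days for a 90-day quarter.
    Accepts a QuarterId or a plain day count.
    """
    n_days = q if isinstance(q, int) else q.n_days
    return int(np.floor(fraction * n_days))


def _as_events(dispensings) -> list[tuple[dt.date, int]]:
    if isinstance(dispensings, pd.DataFrame):
        dates = pd.to_datetime(dispensings["dispense_date"]).dt.date
        return list(zip(dates, dispensings["days_supplied"].astype(int)))
    return [(d, int(s)) for d, s in dispensings]


def supply_intervals(
    dispensings,
    carryover_cap: int = DEFAULT_CARRYOVER_CAP,
    on_invalid: str = "raise",
) -> list[SupplyInterval]:
    """Merged covered intervals for one patient and one drug class.

    Parameters
    ----------
    dispensings : DataFrame with ``dispense_date``/``days_supplied`` or an
        iterable of ``(date, days_supplied)`` pairs; sorted internally.
    carryover_cap : leftover supply retained at refill time is truncated to
        this many days (the formulary's 100-day maximum by default).
    on_invalid : "raise" rejects days_supplied outside [1, 100];
        "clip" clamps into range instead.
    """
    events = _as_events(dispensings)
    cleaned: list[tuple[dt.date, int]] = []
    for d, s in events:
        if s < 1 or s > MAX_DAYS_SUPPLIED:
            if on_invalid == "clip":
                s = min(max(s, 1), MAX_DAYS_SUPPLIED)
            else:
                raise DispensingValidationError(
                    f"days_supplied must be in [1, {MAX_DAYS_SUPPLIED}], got {s} on {d}"
                )
        cleaned.append((d, s))
    cleaned.sort(key=lambda e: e[0])

    intervals: list[SupplyInterval] = []
    cur_start: dt.date | None = None
    E: dt.date | None = None  # running supply end, exclusive
    for d, s in cleaned:
        if E is None or d > E:
            if cur_start is not None:
                intervals.append(SupplyInterval(cur_start, E))
            cur_start = d
            E = d + dt.timedelta(days=s)
        else:
            leftover = min((E - d).days, carryover_cap)
            E = d + dt.timedelta(days=s + leftover)
    if cur_start is not None:
        intervals.append(SupplyInterval(cur_start, E))
    return intervals


def coverage_call(
    intervals: Sequence[SupplyInterval],
    q: QuarterId,
    patient_id: int = -1,
    drug_class: str = "",
    fraction: float = COVERAGE_FRACTION,
) -> CoverageCall:
    """Covered days and covered/uncovered call for one quarter."""
    qs, qe = q.start, q.end
    days = 0
    for iv in intervals:
        lo = max(iv.start, qs)
        hi = min(iv.end, qe)
        if hi > lo:
            days += (hi - lo).days
    return CoverageCall(
        patient_id=patient_id,
        drug_class=drug_class,
        quarter=q,
        covered_days=days,
        covered=days >= threshold_days(q, fraction),
    )


# ---------------------------------------------------------------------
# Bulk engine (numba kernels over day-offset integer arrays)
# ---------------------------------------------------------------------

@njit(cache=True)
def _carryover_kernel(dates, supplies, group_start, cap, out_start, out_end, out_group):
    """Carryover scan per group; emits merged intervals. Returns count."""
    m = 0
    for g in range(group_start.shape[0] - 1):
        lo = group_start[g]
        hi = group_start[g + 1]
        if hi == lo:
            continue
        cur = dates[lo]
        E = dates[lo] + supplies[lo]
        for i in range(lo + 1, hi):
            d = dates[i]
            s = supplies[i]
            if d > E:
                out_start[m] = cur
                out_end[m] = E
                out_group[m] = g
                m += 1
                cur = d
                E = d + s
            else:
                leftover = E - d
                if leftover > cap:
                    leftover = cap
                E = d + s + leftover
        out_start[m] = cur
        out_end[m] = E
        out_group[m] = g
        m += 1
    return m


@njit(cache=True)
def _merge_kernel(starts, ends, group_start, out_start, out_end, out_group):
    """Plain union-merge of per-group sorted intervals. Returns count."""
    m = 0
    for g in range(group_start.shape[0] - 1):
        lo = group_start[g]
        hi = group_start[g + 1]
        if hi == lo:
            continue
        cur_s = starts[lo]
        cur_e = ends[lo]
        for i in range(lo + 1, hi):
            if starts[i] > cur_e:
                out_start[m] = cur_s
                out_end[m] = cur_e
                out_group[m] = g
                m += 1
                cur_s = starts[i]
                cur_e = ends[i]
            elif ends[i] > cur_e:
                cur_e = ends[i]
        out_start[m] = cur_s
        out_end[m] = cur_e
        out_group[m] = g
        m += 1
    return m


def _group_bounds(sorted_keys: np.ndarray, n_groups: int) -> np.ndarray:
    """Index bounds of each group in a sorted key array (length n_groups+1)."""
    return np.searchsorted(sorted_keys, np.arange(n_groups + 1))


def merged_intervals_bulk(
    patient_index: np.ndarray,
    day_offsets: np.ndarray,
    supplies: np.ndarray,
    n_patients: int,
    carryover_cap: int = DEFAULT_CARRYOVER_CAP,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Carryover scan for one drug class across a population.

    Inputs are parallel arrays of dispensings; ``patient_index`` is a dense
    0-based patient row index and ``day_offsets`` days since an arbitrary
    origin.  Returns ``(starts, ends, patient_index)`` of merged intervals.
    """
    if day_offsets.size == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    order = np.lexsort((day_offsets, patient_index))
    pid = patient_index[order].astype(np.int64)
    dd = day_offsets[order].astype(np.int64)
    ss = supplies[order].astype(np.int64)
    bounds = _group_bounds(pid, n_patients)
    out_s = np.empty(dd.size, dtype=np.int64)
    out_e = np.empty(dd.size, dtype=np.int64)
    out_g = np.empty(dd.size, dtype=np.int64)
    m = _carryover_kernel(dd, ss, bounds, carryover_cap, out_s, out_e, out_g)
    return out_s[:m], out_e[:m], out_g[:m]


def union_intervals_bulk(
    starts: np.ndarray, ends: np.ndarray, patient_index: np.ndarray, n_patients: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Union-merge intervals per patient (no carryover across classes)."""
    if starts.size == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    order = np.lexsort((starts, patient_index))
    pid = patient_index[order].astype(np.int64)
    ss = starts[order].astype(np.int64)
    ee = ends[order].astype(np.int64)
    bounds = _group_bounds(pid, n_patients)
    out_s = np.empty(ss.size, dtype=np.int64)
    out_e = np.empty(ss.size, dtype=np.int64)
    out_g = np.empty(ss.size, dtype=np.int64)
    m = _merge_kernel(ss, ee, bounds, out_s, out_e, out_g)
    return out_s[:m], out_e[:m], out_g[:m]


def covered_days_matrix(
    starts: np.ndarray,
    ends: np.ndarray,
    patient_index: np.ndarray,
    n_patients: int,
    window: StudyWindow,
) -> np.ndarray:
    """(n_patients, n_periods) covered-day counts from merged intervals."""
    offs = window.day_offsets()
    n_q = len(window)
    out = np.zeros((n_patients, n_q), dtype=np.int64)
    if starts.size == 0:
        return out
    for q in range(n_q):
        lo = np.maximum(starts, offs[q])
        hi = np.minimum(ends, offs[q + 1])
        ov = hi - lo
        mask = ov > 0
        if mask.any():
            np.add.at(out[:, q], patient_index[mask], ov[mask])
    return out


def covered_matrix_for_class(
    dispensings: pd.DataFrame,
    patient_ids: np.ndarray,
    members: Sequence[str],
    window: StudyWindow,
    carryover_cap: int = DEFAULT_CARRYOVER_CAP,
    fraction: float = COVERAGE_FRACTION,
    on_invalid: str = "raise",
) -> np.ndarray:
    """Boolean (n_patients, n_periods) covered matrix for a drug class.

    Carryover runs within each member class; member coverage is then
    unioned (a quarter half-covered by an ACEI and half by an ARB counts
    for the combined class).
    """
    n = len(patient_ids)
    disp = dispensings[dispensings["drug_class"].isin(list(members))]
    bad = ~disp["days_supplied"].between(1, MAX_DAYS_SUPPLIED)
    if bad.any():
        if on_invalid == "clip":
            disp = disp.assign(days_supplied=disp["days_supplied"].clip(1, MAX_DAYS_SUPPLIED))
        else:
            row = disp.index[bad][0]
            raise DispensingValidationError(
                f"days_supplied out of [1, {MAX_DAYS_SUPPLIED}] at dispensings row {row}"
            )
    pid_to_row = pd.Series(np.arange(n), index=patient_ids)
    rows = pid_to_row.reindex(disp["patient_id"]).to_numpy()
    known = ~np.isnan(rows)
    disp = disp.loc[known]
    rows = rows[known].astype(np.int64)
    origin = np.datetime64(window.study_start, "D")
    days = (disp["dispense_date"].to_numpy().astype("datetime64[D]") - origin).astype(np.int64)
    supplies = disp["days_supplied"].to_numpy(np.int64)

    all_s, all_e, all_p = [], [], []
    for mem in members:
        sel = (disp["drug_class"] == mem).to_numpy()
        s, e, p = merged_intervals_bulk(rows[sel], days[sel], supplies[sel], n, carryover_cap)
        all_s.append(s)
        all_e.append(e)
        all_p.append(p)
    s = np.concatenate(all_s) if all_s else np.empty(0, dtype=np.int64)
    e = np.concatenate(all_e) if all_e else np.empty(0, dtype=np.int64)
    p = np.concatenate(all_p) if all_p else np.empty(0, dtype=np.int64)
    if len(members) > 1:
        s, e, p = union_intervals_bulk(s, e, p, n)
    cd = covered_days_matrix(s, e, p, n, window)
    thresh = np.floor(fraction * window.n_days).astype(np.int64)
    return cd >= thresh[np.newaxis, :]


def class_series(
    bundle,
    cohort,
    class_spec: str,
    window: StudyWindow | None = None,
    carryover_cap: int = DEFAULT_CARRYOVER_CAP,
    fraction: float = COVERAGE_FRACTION,
) -> CoverageSeries:
    """Quarterly coverage rates for one analysis class over a cohort.

    Parameters
    ----------
    bundle : PatientBundle (needs ``dispensings`` and ``patients`` tables).
    cohort : CohortQuarters from :mod:`rxcoverage.cohorts` — per-patient,
        per-quarter eligibility.
    class_spec : key of :data:`CLASS_SPECS` ("STATIN", "ACEI_OR_ARB", ...).
    window : study window; defaults to the cohort's.

    The denominator in each quarter is the eligible patients, minus those
    with an AMI-history date before the quarter's end for the antiplatelet
    class; the numerator is the denominator members called covered.
    """
    if class_spec not in CLASS_SPECS:
        raise KeyError(
            f"unknown drug class {class_spec!r}; expected one of {sorted(CLASS_SPECS)}"
        )
    spec = CLASS_SPECS[class_spec]
    window = window or cohort.window
    eligible = cohort.eligible.copy()
    if spec["exclude_ami"]:
        patients = bundle.patients.set_index("patient_id").reindex(cohort.patient_ids)
        ami = patients["ami_history_date"].to_numpy().astype("datetime64[D]")
        has_ami_by_q = ami[:, np.newaxis] < window.ends[np.newaxis, :]
        has_ami_by_q &= ~np.isnat(ami)[:, np.newaxis]
        eligible &= ~has_ami_by_q
    covered = covered_matrix_for_class(
        bundle.dispensings, cohort.patient_ids, spec["members"], window,
        carryover_cap=carryover_cap, fraction=fraction,
    )
    n = eligible.sum(axis=0)
    k = (eligible & covered).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n > 0, 100.0 * k / np.maximum(n, 1), np.nan)
    labels = window.labels
    years = [int(lbl[:4]) if "Q" in lbl else -1 for lbl in labels]
    qnums = [int(lbl.split("Q")[1]) if "Q" in lbl else -1 for lbl in labels]
    table = pd.DataFrame(
        {
            "class": class_spec,
            "label": labels,
            "year": years,
            "quarter": qnums,
            "t": np.arange(len(labels)),
            "n": n,
            "k": k,
            "rate_percent": rate,
        }
    )
    return CoverageSeries(drug_class=class_spec, table=table)
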