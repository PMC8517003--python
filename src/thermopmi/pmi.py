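"""Cooling-curve inversion: reconstructed PMIs, case aggregation, error stats.

A simulated site-specific cooling curve acts as a look-up table from time
since death to skin temperature.  The time whose simulated temperature
best approximates a measured skin temperature is the reconstructed PMI.
Per case, reconstructed PMIs from all body sites are pooled into a median
PMI with a median-absolute-deviation (MAD) spread, mapped through the
measurement clock times into an estimated time-of-death interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import BODY_SITES
from .thermo import CoolingCurve

#: Best-case uncertainty of the standard (nomogram) method, hours; the
#: benchmark threshold for the |dPMI| <= 2.8 h fraction.
HENSSGE_BEST_UNCERTAINTY_H = 2.8

DEFAULT_TOLERANCE_C = 0.5
#: Bracketing-segment slope magnitudes below this (deg C / h) flag an
#: estimate as near thermal equilibrium.
DEFAULT_SLOPE_FLOOR_C_PER_H = 0.05

STATUS_OK = "ok"
STATUS_NEAR_EQUILIBRIUM = "near_equilibrium"
STATUS_OUT_OF_RANGE = "out_of_range"


class ReconstructionError(ValueError):
    """No usable PMI estimates could be produced for a case."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One measured skin temperature with clock time and ambient reading."""

    site: str
    clock_time: pd.Timestamp
    skin_temp_C: float
    ambient_temp_C: float
    source: str = "logger"

    def __post_init__(self):
        if self.site not in BODY_SITES:
            raise ValueError(f"site {self.site!r} is not one of {BODY_SITES}")
        if self.source not in ("logger", "camera"):
            raise ValueError("source must be 'logger' or 'camera'")
        if not (np.isfinite(self.skin_temp_C)
                and np.isfinite(self.ambient_temp_C)):
            raise ValueError("temperatures must be finite")
        object.__setattr__(self, "clock_time", pd.Timestamp(self.clock_time))

    @property
    def delta_t_C(self) -> float:
        return self.skin_temp_C - self.ambient_temp_C


@dataclass
class PMIEstimate:
    """Reconstructed PMI for one measurement."""

    pmi_h: float
    min_residual_C: float
    status: str
    slope_C_per_h: float = np.nan
    site: str = ""


def reconstruct_pmi(curve: CoolingCurve, measured_C: float,
                    tolerance_C: float = DEFAULT_TOLERANCE_C,
                    slope_floor: float = DEFAULT_SLOPE_FLOOR_C_PER_H) -> PMIEstimate:
    """Invert one cooling curve for one measured temperature.

    The PMI is the curve time whose temperature best approximates the
    measurement, refined by linear interpolation on the bracketing segment;
    exact crossings tie-break to the earliest time.  Estimates whose best
    residual exceeds ``tolerance_C`` are flagged ``out_of_range``; estimates
    on segments flatter than ``slope_floor`` are flagged
    ``near_equilibrium`` (close to thermal equilibrium, little time
    information).
    """
    if tolerance_C <= 0:
        raise ValueError("tolerance must be positive")
    t = curve.times_h
    temp = curve.temps_C
    if len(t) == 0:
        raise ValueError("empty cooling curve")
    diff = temp - float(measured_C)

    pmi = None
    slope = np.nan
    residual = None
    exact = np.flatnonzero(diff == 0.0)
    crossing = np.flatnonzero(diff[:-1] * diff[1:] < 0.0)
    first_exact = exact[0] if exact.size else np.inf
    first_cross = crossing[0] if crossing.size else np.inf
    if first_exact <= first_cross and exact.size:
        i = int(first_exact)
        pmi = float(t[i])
        residual = 0.0
        seg = i if i + 1 < len(t) else i - 1
        if 0 <= seg < len(t) - 1:
            slope = (temp[seg + 1] - temp[seg]) / (t[seg + 1] - t[seg])
    elif crossing.size:
        i = int(first_cross)
        frac = diff[i] / (diff[i] - diff[i + 1])
        pmi = float(t[i] + frac * (t[i + 1] - t[i]))
        residual = 0.0
        slope = (temp[i + 1] - temp[i]) / (t[i + 1] - t[i])
    else:
        i = int(np.argmin(np.abs(diff)))
        pmi = float(t[i])
        residual = float(abs(diff[i]))
        seg = i if i + 1 < len(t) else i - 1
        if 0 <= seg < len(t) - 1:
            slope = (temp[seg + 1] - temp[seg]) / (t[seg + 1] - t[seg])

    if residual > tolerance_C:
        status = STATUS_OUT_OF_RANGE
    elif np.isnan(slope) or abs(slope) < slope_floor:
        status = STATUS_NEAR_EQUILIBRIUM
    else:
        status = STATUS_OK
    return PMIEstimate(pmi, residual, status, float(slope), curve.site)


@dataclass
class CaseResult:
    """Per-case aggregate: median PMI, MAD, and time-of-death interval."""

    estimates: list                  # PMIEstimate per record, record order
    records: list                    # the MeasurementRecord inputs
    median_pmi_h: float              # relative to the latest record clock
    mad_h: float
    reference_time: pd.Timestamp     # latest record clock time
    time_of_death: pd.Timestamp
    earliest: pd.Timestamp
    latest: pd.Timestamp

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec, est in zip(self.records, self.estimates):
            rows.append({
                "site": rec.site, "clock_time": rec.clock_time,
                "skin_temp_C": rec.skin_temp_C,
                "ambient_temp_C": rec.ambient_temp_C, "source": rec.source,
                "pmi_h": est.pmi_h, "min_residual_C": est.min_residual_C,
                "status": est.status,
            })
        return pd.DataFrame(rows)


def reconstruct_case(curves: Mapping[str, CoolingCurve],
                     records: Sequence[MeasurementRecord],
                     tolerance_C: float = DEFAULT_TOLERANCE_C,
                     slope_floor: float = DEFAULT_SLOPE_FLOOR_C_PER_H) -> CaseResult:
    """Invert every record and aggregate into a case-level PMI.

    Each record's clock time is referenced to the latest record: a record
    at clock c_k with reconstructed PMI p_k implies a time of death
    c_k - p_k, i.e. a PMI of (c_last - c_k) + p_k relative to the latest
    measurement.  Median and MAD are taken over ok-status estimates only.
    """
    if not records:
        raise ReconstructionError("no measurement records")
    missing = sorted({r.site for r in records} - set(curves))
    if missing:
        raise ReconstructionError(f"no cooling curve for sites: {missing}")
    estimates = [reconstruct_pmi(curves[r.site], r.skin_temp_C, tolerance_C,
                                 slope_floor) for r in records]
    ref = max(r.clock_time for r in records)
    rel = np.array([
        est.pmi_h + (ref - rec.clock_time).total_seconds() / 3600.0
        for rec, est in zip(records, estimates)])
    ok = np.array([est.status == STATUS_OK for est in estimates])
    usable = ok if ok.any() else np.array(
        [est.status != STATUS_OUT_OF_RANGE for est in estimates])
    if not usable.any():
        raise ReconstructionError(
            "all records are out of range of their cooling curves")
    median = float(np.median(rel[usable]))
    mad = float(np.median(np.abs(rel[usable] - median)))
    tod = ref - pd.Timedelta(hours=median)
    return CaseResult(
        estimates=estimates, records=list(records), median_pmi_h=median,
        mad_h=mad, reference_time=ref, time_of_death=tod,
        earliest=ref - pd.Timedelta(hours=median + mad),
        latest=ref - pd.Timedelta(hours=median - mad))


@dataclass
class ErrorSummary:
    """Per-site and pooled dPMI (reconstructed - true) statistics."""

    table: pd.DataFrame  # site, mean_dpmi_h, sd_dpmi_h, n, frac_within_2p8h
    pooled_mean_h: float
    pooled_sd_h: float
    pooled_fraction_within_2p8h: float


def summarize_errors(estimates: Iterable[tuple]) -> ErrorSummary:
    """Summarise (site, reconstructed_pmi_h, true_pmi_h) triples.

    Reports per-site and pooled mean +/- sample sd of dPMI and the fraction
    of reconstructions within the standard method's best-case +/-2.8 h.
    """
    df = pd.DataFrame(list(estimates),
                      columns=["site", "reconstructed_h", "true_h"])
    if df.empty:
        raise ValueError("no estimates to summarise")
    df["dpmi_h"] = df["reconstructed_h"] - df["true_h"]
    rows = []
    for site, sub in df.groupby("site", sort=False):
        d = sub["dpmi_h"].to_numpy()
        rows.append({
            "site": site, "mean_dpmi_h": float(d.mean()),
            "sd_dpmi_h": float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
            "n": len(d),
            "frac_within_2p8h": float(
                (np.abs(d) <= HENSSGE_BEST_UNCERTAINTY_H).mean()),
        })
    d = df["dpmi_h"].to_numpy()
    return ErrorSummary(
        table=pd.DataFrame(rows),
        pooled_mean_h=float(d.mean()),
        pooled_sd_h=float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
        pooled_fraction_within_2p8h=float(
            (np.abs(d) <= HENSSGE_BEST_UNCERTAINTY_H).mean()))


@dataclass
class DeltaTBin:
    """dPMI statistics within one half-open [lo, hi) band of dT."""

    lo_C: float
    hi_C: float
    mean_dpmi_h: float
    sd_dpmi_h: float
    n: int
    members_h: np.ndarray = field(repr=False, default=None)


def bin_by_delta_t(estimates: Iterable[tuple], bin_width_C: float) -> list:
    """Group (delta_t_C, dpmi_h) pairs into half-open dT bins.

    dT is the measured body-ambient temperature difference (proximity to
    thermal equilibrium).  A value exactly on a bin edge belongs to the
    upper bin.
    """
    if bin_width_C <= 0:
        raise ValueError("bin_width must be positive")
    data = np.asarray(list(estimates), dtype=float)
    if data.size == 0:
        return []
    dt, dpmi = data[:, 0], data[:, 1]
    first = np.floor(dt.min() / bin_width_C)
    idx = np.floor(dt / bin_width_C).astype(int)
    bins = []
    for b in range(int(first), int(idx.max()) + 1):
        sel = idx == b
        if not sel.any():
            continue
        members = dpmi[sel]
        bins.append(DeltaTBin(
            lo_C=b * bin_width_C, hi_C=(b + 1) * bin_width_C,
            mean_dpmi_h=float(members.mean()),
            sd_dpmi_h=float(np.std(members, ddof=1)) if len(members) > 1 else 0.0,
            n=int(sel.sum()), members_h=members))
    return bins


def load_measurements(path) -> list:
    """Read measurement records from CSV.

    Columns: site, iso_timestamp, skin_temp_C, ambient_temp_C, source.
    """
    df = pd.read_csv(path)
    return [MeasurementRecord(str(r.site), pd.Timestamp(r.iso_timestamp),
                              float(r.skin_temp_C), float(r.ambient_temp_C),
                              str(r.source))
            for r in df.itertuples()]


def save_measurements(records, path) -> None:
    pd.DataFrame([{
        "site": r.site, "iso_timestamp": r.clock_time.isoformat(),
        "skin_temp_C": r.skin_temp_C, "ambient_temp_C": r.ambient_temp_C,
        "source": r.source} for r in records]).to_csv(path, index=False)
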