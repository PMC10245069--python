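"""Biolayer-interferometry 1:1 Langmuir kinetics: forward model, global
fitting grouped by sensor, and binding-call classification.

Model
-----
With analyte concentration C, association rate kon (M^-1 s^-1), dissociation
rate koff (s^-1) and sensor capacity Rmax (nm):

    association:  R(t) = Req * (1 - exp(-(kon*C + koff) * (t - t0)))
                  Req  = Rmax * C / (C + KD),   KD = koff / kon
    dissociation: R(t) = R_end * exp(-koff * (t - t1))

where t0/t1 are the association/dissociation phase starts and R_end is the
model signal at the end of association (continuity at the phase boundary).
kon, koff and Rmax are shared across all traces of a sensor; the fit is a
joint nonlinear least squares over the association and dissociation samples
of every trace, with a 3x3 multi-start grid over (kon, koff) in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

PHASES = ("baseline", "association", "dissociation")

DEFAULT_KON_BOUNDS = (1e2, 1e8)    # M^-1 s^-1
DEFAULT_KOFF_BOUNDS = (1e-5, 10.0)  # s^-1


@dataclass
class Sensorgram:
    """One binding trace: signal (nm) vs time (s) with phase annotations."""

    time: np.ndarray          # (n,) s, strictly increasing
    signal: np.ndarray        # (n,) nm
    phase: np.ndarray         # (n,) unicode, in PHASES
    analyte_conc: float       # M
    sensor_id: str = "sensor1"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.phase = np.asarray(self.phase)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing within a trace")
        if self.analyte_conc <= 0:
            raise ValueError("analyte concentration must be positive")

    def phase_mask(self, name: str) -> np.ndarray:
        return self.phase == name


@dataclass
class KineticsParams:
    """Globally fitted 1:1 parameters for one sensor."""

    kon: float                # M^-1 s^-1
    koff: float               # s^-1
    rmax: float               # nm
    residual_sum: float       # sum of squared residuals
    per_trace_residuals: list[float] = field(default_factory=list)
    sensor_id: str = ""
    unfittable: bool = False
    unfittable_reason: str = ""

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant, koff/kon (M)."""
        return self.koff / self.kon


@dataclass
class BindingCall:
    category: str             # wt_like | diminished | none
    max_conc_tested: float    # M
    fold_change: float | None  # KD fold change vs reference (None if no fit)


# ---------------------------------------------------------------------------
# forward model

def response_1to1(
    time: np.ndarray,
    phase: np.ndarray,
    conc: float,
    kon: float,
    koff: float,
    rmax: float,
) -> np.ndarray:
    """Noise-free 1:1 model response over a phased time grid.

    Baseline samples are 0; association rises toward Req; dissociation decays
    from the model value at the end of the association window.
    """
    time = np.asarray(time, dtype=np.float64)
    out = np.zeros_like(time)
    kd = koff / kon
    req = rmax * conc / (conc + kd)
    kobs = kon * conc + koff
    assoc = phase == "association"
    dissoc = phase == "dissociation"
    if assoc.any():
        t0 = time[assoc][0]
        out[assoc] = req * (1.0 - np.exp(-kobs * (time[assoc] - t0)))
        t_end = time[assoc][-1]
        r_end = req * (1.0 - np.exp(-kobs * (t_end - t0)))
    else:
        r_end = 0.0
    if dissoc.any():
        t1 = time[dissoc][0]
        out[dissoc] = r_end * np.exp(-koff * (time[dissoc] - t1))
    return out


# ---------------------------------------------------------------------------
# fitting

def _baseline_subtract(trace: Sensorgram, tail_s: float = 10.0) -> tuple[np.ndarray, float]:
    """Signal with the mean of the final baseline seconds removed.

    Returns the corrected signal and the baseline noise SD (for the
    detection threshold); traces without a baseline phase pass through.
    """
    base = trace.phase_mask("baseline")
    if not base.any():
        return trace.signal.copy(), 0.0
    t_base = trace.time[base]
    tail = base & (trace.time >= t_base[-1] - tail_s)
    level = float(trace.signal[tail].mean())
    noise = float(trace.signal[tail].std())
    return trace.signal - level, noise


def _multistart_grid(
    kon_bounds: tuple[float, float],
    koff_bounds: tuple[float, float],
    n: int = 3,
) -> list[tuple[float, float]]:
    kons = np.logspace(np.log10(kon_bounds[0]) + 0.5, np.log10(kon_bounds[1]) - 0.5, n)
    koffs = np.logspace(np.log10(koff_bounds[0]) + 0.5, np.log10(koff_bounds[1]) - 0.5, n)
    return [(ko, kf) for ko in kons for kf in koffs]


def fit_1to1(
    traces: list[Sensorgram],
    kon_bounds: tuple[float, float] = DEFAULT_KON_BOUNDS,
    koff_bounds: tuple[float, float] = DEFAULT_KOFF_BOUNDS,
    detection_factor: float = 3.0,
    shared_rmax: bool = True,
) -> KineticsParams:
    """Global 1:1 fit over all traces of one sensor.

    kon, koff (and, by default, Rmax) are shared across traces; association
    and dissociation phases are fitted jointly with continuity at the phase
    boundary. If the peak baseline-subtracted association signal is below
    ``detection_factor`` times the baseline noise SD the result is flagged
    unfittable instead of fitted.
    """
    if not traces:
        raise ValueError("no traces to fit")
    sensor_ids = {t.sensor_id for t in traces}
    if len(sensor_ids) > 1:
        raise ValueError(f"traces span multiple sensors: {sorted(sensor_ids)}; fit per sensor")
    sensor_id = traces[0].sensor_id

    corrected, noises, peaks = [], [], []
    for tr in traces:
        sig, noise = _baseline_subtract(tr)
        corrected.append(sig)
        noises.append(noise)
        mask = tr.phase_mask("association")
        if mask.any():
            # detection level: mean over the final 20% of the association
            # window — robust to single-sample noise spikes, and equal to the
            # near-plateau response for fast binders
            assoc = sig[mask]
            tail = assoc[-max(5, len(assoc) // 5):]
            peaks.append(float(abs(tail.mean())))
        else:
            peaks.append(0.0)
    noise_floor = max(noises)
    if noise_floor > 0 and max(peaks) < detection_factor * noise_floor:
        return KineticsParams(
            kon=float("nan"), koff=float("nan"), rmax=float("nan"),
            residual_sum=float("nan"), sensor_id=sensor_id,
            unfittable=True,
            unfittable_reason=(
                f"peak association signal {max(peaks):.3g} nm below "
                f"{detection_factor} x baseline noise SD ({noise_floor:.3g} nm)"
            ),
        )
    if max(peaks) <= 0:
        return KineticsParams(
            kon=float("nan"), koff=float("nan"), rmax=float("nan"),
            residual_sum=float("nan"), sensor_id=sensor_id,
            unfittable=True, unfittable_reason="no association signal",
        )

    fit_masks = [tr.phase_mask("association") | tr.phase_mask("dissociation") for tr in traces]
    y_obs = [sig[m] for sig, m in zip(corrected, fit_masks)]
    rmax0 = max(peaks) * 1.5
    n_rmax = 1 if shared_rmax else len(traces)

    def residuals(theta: np.ndarray) -> np.ndarray:
        kon, koff = 10.0 ** theta[0], 10.0 ** theta[1]
        rmaxes = theta[2:]
        out = []
        for i, (tr, m) in enumerate(zip(traces, fit_masks)):
            rm = rmaxes[0] if shared_rmax else rmaxes[i]
            pred = response_1to1(tr.time, tr.phase, tr.analyte_conc, kon, koff, rm)
            out.append(pred[m] - y_obs[i])
        return np.concatenate(out)

    lo = np.array([np.log10(kon_bounds[0]), np.log10(koff_bounds[0])] + [0.0] * n_rmax)
    hi = np.array([np.log10(kon_bounds[1]), np.log10(koff_bounds[1])] + [np.inf] * n_rmax)
    best = None
    for kon0, koff0 in _multistart_grid(kon_bounds, koff_bounds):
        x0 = np.array([np.log10(kon0), np.log10(koff0)] + [rmax0] * n_rmax)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            f"1:1 fit failed to converge from all {len(_multistart_grid(kon_bounds, koff_bounds))} starts"
        )

    kon, koff = 10.0 ** best.x[0], 10.0 ** best.x[1]
    rmax = float(best.x[2])
    per_trace = []
    start = 0
    for y in y_obs:
        seg = best.fun[start : start + len(y)]
        per_trace.append(float(np.sum(seg**2)))
        start += len(y)
    return KineticsParams(
        kon=float(kon),
        koff=float(koff),
        rmax=rmax,
        residual_sum=float(2.0 * best.cost),
        per_trace_residuals=per_trace,
        sensor_id=sensor_id,
    )


def classify_binding(
    fit: KineticsParams | None,
    reference: KineticsParams,
    max_conc: float,
    diminished_fold: float = 3.0,
) -> BindingCall:
    """WT-like / diminished / no-binding call against a reference fit.

    ``none``: no fit or unfittable signal at the highest tested concentration;
    ``diminished``: KD fold-change above ``diminished_fold``; else ``wt_like``.
    """
    if reference is None or reference.unfittable:
        raise ValueError("a valid reference fit is required")
    if fit is None or fit.unfittable:
        return BindingCall(category="none", max_conc_tested=max_conc, fold_change=None)
    fold = fit.kd / reference.kd
    category = "diminished" if fold > diminished_fold else "wt_like"
    return BindingCall(category=category, max_conc_tested=max_conc, fold_change=float(fold))


# ---------------------------------------------------------------------------
# IO

def write_sensorgrams_csv(path: str | Path, traces: list[Sensorgram]) -> None:
    """Columns: time_s, signal_nm, phase, conc_M, sensor_id."""
    frames = [
        pd.DataFrame(
            {
                "time_s": tr.time,
                "signal_nm": tr.signal,
                "phase": tr.phase,
                "conc_M": tr.analyte_conc,
                "sensor_id": tr.sensor_id,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgrams_csv(path: str | Path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    traces = []
    for (sensor, conc), grp in df.groupby(["sensor_id", "conc_M"], sort=False):
        grp = grp.sort_values("time_s")
        traces.append(
            Sensorgram(
                time=grp["time_s"].to_numpy(),
                signal=grp["signal_nm"].to_numpy(),
                phase=grp["phase"].to_numpy(),
                analyte_conc=float(conc),
                sensor_id=str(sensor),
            )
        )
    return traces


def write_fit_json(path: str | Path, fit: KineticsParams, call: BindingCall | None = None) -> None:
    import json

    payload = {
        "sensor_id": fit.sensor_id,
        "kon_per_M_per_s": fit.kon,
        "koff_per_s": fit.koff,
        "KD_M": fit.kd if not fit.unfittable else None,
        "Rmax_nm": fit.rmax,
        "residual_sum": fit.residual_sum,
        "per_trace_residuals": fit.per_trace_residuals,
        "unfittable": fit.unfittable,
        "unfittable_reason": fit.unfittable_reason,
    }
    if call is not None:
        payload["binding_call"] = {
            "category": call.category,
            "max_conc_tested_M": call.max_conc_tested,
            "fold_change": call.fold_change,
        }
    Path(path).write_text(json.dumps(payload, indent=2))
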