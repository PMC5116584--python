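"""Real-time RCA fluorescence simulation and RRR quantification.

This module doubles as the package's synthetic-data generator.  The signal
model is deliberately simple — the quantification pipeline only ever uses
the linear part of a curve, so anything richer than "lag, then a line,
then saturation" would be unconstrained:

``F(t) = baseline + R_total * max(0, t - lag) + noise``, clipped at the
plateau, with i.i.d. Gaussian noise on each sample.

Template rates: an active template contributes the full polymerase rate
``k_full``; a repressed template contributes ``k_full`` times the largest
leak fraction among its occupied sites (the leak through the weakest
repressor on the circle).  Contributions add across templates but the total
is capped at ``k_full * enzyme_capacity`` (default one template-equivalent):
the polymerase, not the template pool, is limiting, so one running template
out of two reads the same as two — which is why a half-active OR gate still
scores as output 1.

Quantification follows the experimental pipeline: the RCA rate is the
best-fitting slope over the linear part of each curve; rates are normalized
to the maximum within the experiment — always including a repressor-free
control condition so that all-off gates still have a positive reference —
giving the relative RCA rate (RRR); RRR above 0.5 reads as output 1,
otherwise 0 (exactly 0.5 is conservatively read as 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ReactionSystem,
    SpeciesRegistry,
    SpeciesState,
    occupied_sites,
    resolve_state,
    template_active,
)
from .logic import TruthTable

__all__ = [
    "KineticParams",
    "FluorescenceCurve",
    "RateEstimate",
    "RRRResult",
    "QuantificationReport",
    "DegenerateExperiment",
    "simulate_curve",
    "estimate_rate",
    "quantify_experiment",
    "quantify_curves",
    "curves_to_frame",
    "curves_from_frame",
    "read_curves_csv",
    "write_curves_csv",
]

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class KineticParams:
    """Synthetic kinetic conditions (fluorescence in arbitrary RFU).

    Defaults emulate a 15-minute SYBR-green RCA run sampled every 30 s with
    a 1-minute lag and noise at 5% of the full rate.
    """

    baseline_rfu: float = 50.0
    k_full: float = 100.0  # RFU/min per fully active template
    duration_min: float = 15.0
    sample_interval_min: float = 0.5
    lag_min: float = 1.0
    noise_sd: float = 5.0
    plateau_rfu: float = 2000.0
    enzyme_capacity: float = 1.0  # cap on total rate, in template-equivalents
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_min > self.lag_min >= 0:
            raise ValueError("need duration > lag >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.k_full <= 0:
            raise ValueError("k_full must be > 0")
        if self.sample_interval_min <= 0:
            raise ValueError("sample_interval_min must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(
            0.0, self.duration_min + 1e-9, self.sample_interval_min
        )


@dataclass(frozen=True)
class FluorescenceCurve:
    """One condition's real-time signal."""

    label: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be equal-length vectors")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class RateEstimate:
    slope: float  # RFU/min
    window: tuple  # (start, stop) sample indices, half-open
    r_squared: float


@dataclass(frozen=True)
class RRRResult:
    """Slope-normalized binary readout of one condition."""

    condition: str
    raw_slope: float
    window: tuple
    rrr: float
    output_bit: int
    threshold: float = DEFAULT_THRESHOLD


class DegenerateExperiment(RuntimeError):
    """All conditions (including the control) produced non-positive rates."""


@dataclass(frozen=True)
class QuantificationReport:
    """Empirical truth table plus per-condition RRR results."""

    system_name: str
    truth_table: TruthTable
    results: tuple
    control: RRRResult
    threshold: float
    params: KineticParams

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": r.condition,
                "raw_slope_rfu_per_min": r.raw_slope,
                "rrr": r.rrr,
                "output": r.output_bit,
            }
            for r in (*self.results, self.control)
        ]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        return self.to_frame().to_string(index=False)


# ---------------------------------------------------------------------------
# Simulation


def _state_rate(
    templates: Sequence, registry: SpeciesRegistry, state: SpeciesState, params: KineticParams
) -> float:
    total = 0.0
    for template in templates:
        if template_active(template, registry, state):
            total += params.k_full
        else:
            bound = occupied_sites(template, registry, state)
            leak = max(
                (registry.repressor(s.cognate_repressor).leak for s in bound),
                default=0.0,
            )
            total += params.k_full * leak
    return min(total, params.k_full * params.enzyme_capacity)


def _simulate_rate(
    label: str,
    rate: float,
    params: KineticParams,
    rng: np.random.Generator,
) -> FluorescenceCurve:
    t = params.times
    values = params.baseline_rfu + rate * np.clip(t - params.lag_min, 0.0, None)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=t.shape)
    values = np.minimum(values, params.plateau_rfu)
    return FluorescenceCurve(label=label, times=t, values=values)


def _condition_label(assignment: Mapping[str, int], names: Sequence[str]) -> str:
    return "".join(str(assignment[n]) for n in names)


def simulate_curve(
    system: ReactionSystem,
    assignment: Mapping[str, int],
    params: KineticParams,
    rng: Optional[np.random.Generator] = None,
) -> FluorescenceCurve:
    """Simulate one condition's fluorescence curve under seeded noise."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    state = resolve_state(system, assignment)
    rate = _state_rate(system.templates, system.registry, state, params)
    return _simulate_rate(
        _condition_label(assignment, system.input_names), rate, params, rng
    )


# ---------------------------------------------------------------------------
# Rate estimation


def estimate_rate(
    curve: FluorescenceCurve,
    min_fraction: float = 0.4,
    r2_floor: float = 0.9,
) -> RateEstimate:
    """Slope of the linear part of a curve.

    Considers every contiguous window spanning at least ``min_fraction`` of
    the samples and picks the steepest one whose least-squares fit quality
    (R^2) reaches ``r2_floor``; ties prefer longer, then earlier windows.
    If no window reaches the floor the best-fitting window wins.  The choice
    is deterministic given the curve.  Windows of zero signal variance are
    perfect fits (R^2 = 1), so flat baselines yield slope 0, not an error.
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.values, dtype=float)
    n = len(t)
    if n < 6:
        raise ValueError(f"need at least 6 samples, got {n}")
    min_len = max(int(np.ceil(min_fraction * n)), 3)

    ct = np.concatenate(([0.0], np.cumsum(t)))
    ctt = np.concatenate(([0.0], np.cumsum(t * t)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))
    cty = np.concatenate(([0.0], np.cumsum(t * y)))

    slopes, r2s, starts, lengths = [], [], [], []
    for length in range(min_len, n + 1):
        idx = np.arange(0, n - length + 1)
        st = ct[idx + length] - ct[idx]
        stt = ctt[idx + length] - ctt[idx]
        sy = cy[idx + length] - cy[idx]
        syy = cyy[idx + length] - cyy[idx]
        sty = cty[idx + length] - cty[idx]
        sxx = stt - st * st / length
        sxy = sty - st * sy / length
        svv = syy - sy * sy / length
        slope = sxy / sxx
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(svv > 1e-12, (sxy * sxy) / (sxx * svv), 1.0)
        slopes.append(slope)
        r2s.append(r2)
        starts.append(idx)
        lengths.append(np.full(idx.shape, length))
    slope_arr = np.concatenate(slopes)
    r2_arr = np.concatenate(r2s)
    start_arr = np.concatenate(starts)
    len_arr = np.concatenate(lengths)

    qualifying = r2_arr >= r2_floor - 1e-12
    if not np.any(qualifying):
        pick = int(
            np.lexsort((start_arr, -len_arr, -r2_arr))[0]
        )
    else:
        idxs = np.nonzero(qualifying)[0]
        order = np.lexsort(
            (start_arr[idxs], -len_arr[idxs], -slope_arr[idxs])
        )
        pick = int(idxs[order[0]])
    start = int(start_arr[pick])
    stop = start + int(len_arr[pick])
    return RateEstimate(
        slope=float(slope_arr[pick]),
        window=(start, stop),
        r_squared=float(r2_arr[pick]),
    )


# ---------------------------------------------------------------------------
# Quantification


def _binarize(
    slopes: Mapping[str, RateEstimate],
    max_rate: float,
    threshold: float,
) -> dict:
    out = {}
    for label, est in slopes.items():
        rrr = max(est.slope, 0.0) / max_rate
        out[label] = RRRResult(
            condition=label,
            raw_slope=est.slope,
            window=est.window,
            rrr=rrr,
            output_bit=int(rrr > threshold),
            threshold=threshold,
        )
    return out


def quantify_experiment(
    system: ReactionSystem,
    params: Optional[KineticParams] = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_fraction: float = 0.4,
    r2_floor: float = 0.9,
) -> QuantificationReport:
    """Simulate all conditions, estimate rates, normalize, threshold.

    All 2^n input assignments are simulated from one seeded generator, plus
    a repressor-free control of the same templates that pins the
    normalization reference for gates whose every condition is off.  The
    empirical truth table holds each condition's thresholded RRR.
    """
    params = params or KineticParams()
    names = system.input_names
    n = len(names)
    if 2**n < 2:
        raise ValueError("need at least 2 conditions for normalization")
    rng = np.random.default_rng(params.seed)

    estimates: dict = {}
    for row in range(2**n):
        assignment = {
            name: (row >> (n - 1 - i)) & 1 for i, name in enumerate(names)
        }
        curve = simulate_curve(system, assignment, params, rng)
        estimates[curve.label] = estimate_rate(curve, min_fraction, r2_floor)

    control_rate = _state_rate(
        system.templates, system.registry, SpeciesState(), params
    )
    control_curve = _simulate_rate("control", control_rate, params, rng)
    control_est = estimate_rate(control_curve, min_fraction, r2_floor)

    max_rate = max(
        max(e.slope for e in estimates.values()), control_est.slope
    )
    if max_rate <= 0:
        raise DegenerateExperiment(
            f"system {system.name!r}: no condition (nor the repressor-free "
            "control) produced a positive RCA rate"
        )
    results = _binarize(estimates, max_rate, threshold)
    control = _binarize({"control": control_est}, max_rate, threshold)["control"]
    outputs = tuple(
        results[format(row, f"0{n}b")].output_bit for row in range(2**n)
    )
    return QuantificationReport(
        system_name=system.name,
        truth_table=TruthTable(names, outputs),
        results=tuple(results[format(row, f"0{n}b")] for row in range(2**n)),
        control=control,
        threshold=threshold,
        params=params,
    )


def quantify_curves(
    curves: Sequence[FluorescenceCurve],
    threshold: float = DEFAULT_THRESHOLD,
    min_fraction: float = 0.4,
    r2_floor: float = 0.9,
) -> list:
    """RRR pipeline over imported curves (e.g. re-analysis of plate-reader CSV).

    Normalizes against the maximum rate within the supplied condition set.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 conditions for normalization")
    estimates = {
        c.label: estimate_rate(c, min_fraction, r2_floor) for c in curves
    }
    max_rate = max(e.slope for e in estimates.values())
    if max_rate <= 0:
        raise DegenerateExperiment("no curve has a positive rate")
    results = _binarize(estimates, max_rate, threshold)
    return [results[c.label] for c in curves]


# ---------------------------------------------------------------------------
# Tidy CSV import/export


def curves_to_frame(curves: Iterable[FluorescenceCurve]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {"condition": c.label, "time_min": c.times, "rfu": c.values}
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)


def curves_from_frame(frame: pd.DataFrame) -> list:
    required = {"condition", "time_min", "rfu"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"curve table missing columns {sorted(missing)}")
    curves = []
    for label, group in frame.groupby("condition", sort=False):
        group = group.sort_values("time_min")
        curves.append(
            FluorescenceCurve(
                label=str(label),
                times=group["time_min"].to_numpy(dtype=float),
                values=group["rfu"].to_numpy(dtype=float),
            )
        )
    return curves


def write_curves_csv(curves: Iterable[FluorescenceCurve], path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def read_curves_csv(path) -> list:
    # condition labels are bit strings: keep leading zeros
    return curves_from_frame(pd.read_csv(path, dtype={"condition": str}))
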