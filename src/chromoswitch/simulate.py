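"""Coupled photochemistry–pharmacology virtual experiments.

Couples the piecewise-analytic isomer kinetics (:mod:`.photochem`) to the
competitive-occupancy response model (:mod:`.pharm`) under quasi-equilibrium
binding: ligand (re)binding is treated as instantaneous relative to
photoswitching and readout, so E*(t) = response(occupancy(c_tot, f_Z(t))).

Two readout idealisations are supported: an ``instantaneous`` readout
(patch-clamp-like, linear in channel current) and a ``first_order_lag``
readout (plate-reader-like Ca2+ indicator with a delayed, low-pass
response).  Gaussian readout noise is optional and fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .photochem import (
    DEFAULT_FLUX,
    IlluminationProtocol,
    IsomerSpectrumPair,
    PhotoswitchPhotophysics,
    compute_pss,
    simulate_isomerization,
    switching_rate,
)
from .pharm import IsomerPharmacology, competitive_occupancy, response

__all__ = [
    "ReadoutModel",
    "ResponseTrace",
    "CycleStats",
    "ActionSpectrumSet",
    "run_experiment",
    "cycle_stats",
    "wavelength_scan",
    "dose_wavelength_surface",
]


@dataclass(frozen=True)
class ReadoutModel:
    """Instrument model applied to the instantaneous effect.

    ``first_order_lag`` convolves E*(t) with an RC low-pass of time constant
    ``lag_tau`` (s), emulating a delayed fluorometric reporter; ``noise_sd``
    adds seeded additive Gaussian noise as a fraction of system maximum.
    """

    mode: Literal["instantaneous", "first_order_lag"] = "instantaneous"
    lag_tau: float = 2.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("instantaneous", "first_order_lag"):
            raise ValueError(f"unknown readout mode {self.mode!r}")
        if self.mode == "first_order_lag" and not self.lag_tau > 0:
            raise ValueError("lag_tau must be > 0 for first_order_lag readout")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: FLIPR-like readout: 2-s first-order reporter lag (the true lag of the
#: source assay is unpublished; 2 s encodes "delayed and attenuated").
FLIPR_READOUT = ReadoutModel(mode="first_order_lag", lag_tau=2.0)
#: Electrophysiology-like readout: linear and effectively instantaneous.
EPHYS_READOUT = ReadoutModel(mode="instantaneous")


@dataclass
class ResponseTrace:
    """Aligned time series of Z fraction and biological effect."""

    time: np.ndarray
    effect: np.ndarray
    fz: np.ndarray
    segment_id: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("effect", "fz", "segment_id"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace columns must have equal length")
        if np.any((self.effect < 0) | (self.effect > 1)):
            raise ValueError("effect must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "fz": self.fz,
                "effect": self.effect,
                "segment_id": self.segment_id.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResponseTrace":
        return cls(
            time=frame["time_s"].to_numpy(float),
            effect=frame["effect"].to_numpy(float),
            fz=frame["fz"].to_numpy(float),
            segment_id=frame["segment_id"].to_numpy(int),
        )


@dataclass(frozen=True)
class CycleStats:
    """Per-cycle extrema and reproducibility summary of a cycling trace.

    ``fatigue_slope`` is the slope of ln(amplitude) versus cycle index —
    the fractional amplitude change per cycle (0 for a fatigue-free switch).
    ``reversibility`` is the mean fraction of the peak-minus-baseline
    excursion recovered at the trough (1 = full return to baseline).
    """

    peaks: np.ndarray
    troughs: np.ndarray
    amplitudes: np.ndarray
    amplitude_cv: float
    fatigue_slope: float
    reversibility: float

    @property
    def n_cycles(self) -> int:
        return len(self.amplitudes)


@dataclass
class ActionSpectrumSet:
    """Tidy action-spectrum table: ``wavelength_nm``, ``bioactivity``, ``conc_M``."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"wavelength_nm", "bioactivity", "conc_M"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"action-spectrum table missing columns {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("action-spectrum table must be non-empty")


# ---------------------------------------------------------------------------


def run_experiment(
    protocol: IlluminationProtocol,
    spectra: IsomerSpectrumPair,
    phot: PhotoswitchPhotophysics,
    pharm: IsomerPharmacology,
    c_tot: float,
    readout: ReadoutModel | None = None,
    fz0: float = 0.0,
    samples_per_segment: int = 200,
    seed: int | None = None,
) -> ResponseTrace:
    """Simulate one photoswitching experiment.

    Propagates f_Z(t) analytically through the protocol, maps it to E*(t)
    via quasi-equilibrium competitive occupancy at total concentration
    ``c_tot``, then applies the readout model.  Deterministic whenever
    ``readout.noise_sd == 0``; otherwise reproducible from ``seed``.
    """
    if c_tot < 0:
        raise ValueError("c_tot must be >= 0")
    readout = readout or ReadoutModel()
    for seg in protocol:
        spectra.eps_at(seg.wavelength)  # raises on protocol/spectrum mismatch

    iso = simulate_isomerization(
        protocol, spectra, phot, fz0=fz0, samples_per_segment=samples_per_segment
    )
    occ = competitive_occupancy(np.full_like(iso.fz, c_tot), iso.fz, pharm)
    effect = np.asarray(response(occ, pharm), dtype=float)

    if readout.mode == "first_order_lag":
        effect = _first_order_filter(iso.time, effect, readout.lag_tau)

    if readout.noise_sd > 0:
        rng = np.random.default_rng(seed)
        effect = effect + rng.normal(0.0, readout.noise_sd, size=effect.shape)

    return ResponseTrace(
        time=iso.time,
        effect=np.clip(effect, 0.0, 1.0),
        fz=iso.fz,
        segment_id=iso.segment_id,
    )


def _first_order_filter(time: np.ndarray, x: np.ndarray, tau: float) -> np.ndarray:
    """Exact exponential-hold RC filter y' = (x - y) / tau, y(0) = x(0)."""
    y = np.empty_like(x)
    y[0] = x[0]
    dt = np.diff(time)
    decay = np.exp(-np.maximum(dt, 0.0) / tau)
    for i in range(1, len(x)):
        y[i] = x[i] + (y[i - 1] - x[i]) * decay[i - 1]
    return y


def cycle_stats(
    trace: ResponseTrace, protocol: IlluminationProtocol | None = None
) -> CycleStats:
    """Per-cycle peak/trough statistics of an alternating on/off trace.

    Consecutive segment pairs (0,1), (2,3), ... are treated as cycles; the
    peak is the maximum and the trough the minimum effect within the pair.
    The amplitude CV uses the population standard deviation (0 for a single
    cycle by convention).
    """
    seg_ids = np.unique(trace.segment_id)
    if protocol is not None and len(protocol) != len(seg_ids):
        raise ValueError(
            f"trace has {len(seg_ids)} segments but protocol has {len(protocol)}"
        )
    n_cycles = len(seg_ids) // 2
    if n_cycles < 1:
        raise ValueError("trace must contain at least one on/off cycle (2 segments)")

    peaks, troughs = [], []
    for k in range(n_cycles):
        mask = (trace.segment_id == seg_ids[2 * k]) | (
            trace.segment_id == seg_ids[2 * k + 1]
        )
        window = trace.effect[mask]
        peaks.append(float(window.max()))
        troughs.append(float(window.min()))
    peaks = np.array(peaks)
    troughs = np.array(troughs)
    amplitudes = peaks - troughs

    mean_amp = float(amplitudes.mean())
    cv = float(amplitudes.std() / mean_amp) if mean_amp > 0 else 0.0
    if n_cycles >= 2 and np.all(amplitudes > 0):
        slope = float(np.polyfit(np.arange(n_cycles), np.log(amplitudes), 1)[0])
    else:
        slope = 0.0

    baseline = float(trace.effect[0])
    denom = peaks - baseline
    with np.errstate(divide="ignore", invalid="ignore"):
        rev = np.where(denom > 1e-12, 1.0 - (troughs - baseline) / denom, 1.0)
    reversibility = float(np.clip(rev, 0.0, 1.0).mean())

    return CycleStats(
        peaks=peaks,
        troughs=troughs,
        amplitudes=amplitudes,
        amplitude_cv=cv,
        fatigue_slope=slope,
        reversibility=reversibility,
    )


def wavelength_scan(
    scan_lambdas: Sequence[float],
    fixed_lambda: float,
    spectra: IsomerSpectrumPair,
    phot: PhotoswitchPhotophysics,
    pharm: IsomerPharmacology,
    c_tot: float,
    scan_role: Literal["on", "off"] = "on",
    flux: float = DEFAULT_FLUX,
    n_cycles: int = 3,
    samples_per_segment: int = 50,
    readout: ReadoutModel | None = None,
) -> ActionSpectrumSet:
    """Cycle each scan wavelength against a fixed counter-wavelength.

    ``scan_role="on"`` scans the activating wavelength (cycles of
    lambda_scan / fixed); ``"off"`` scans the deactivating one (fixed /
    lambda_scan).  The bioactivity reported per wavelength is the plateau
    effect at the end of the final scan segment, after ``n_cycles``
    equilibration cycles of >= 10 / k_obs each.
    """
    rows = []
    for lam in scan_lambdas:
        lam = float(lam)
        if scan_role == "on":
            lam_on, lam_off = lam, fixed_lambda
        elif scan_role == "off":
            lam_on, lam_off = fixed_lambda, lam
        else:
            raise ValueError("scan_role must be 'on' or 'off'")
        d_on = 10.0 / switching_rate(spectra, phot, lam_on, flux)
        d_off = 10.0 / switching_rate(spectra, phot, lam_off, flux)
        protocol = IlluminationProtocol.cycles(
            lam_on, lam_off, n_cycles, d_on, d_off, flux
        )
        fz0 = compute_pss(spectra, phot, lam_off, flux)
        trace = run_experiment(
            protocol, spectra, phot, pharm, c_tot,
            readout=readout, fz0=fz0, samples_per_segment=samples_per_segment,
        )
        # plateau at the end of the last segment in the scanned role
        last_scan_seg = 2 * (n_cycles - 1) if scan_role == "on" else 2 * n_cycles - 1
        plateau = float(trace.effect[trace.segment_id == last_scan_seg][-1])
        rows.append({"wavelength_nm": lam, "bioactivity": plateau, "conc_M": c_tot})
    return ActionSpectrumSet(
        table=pd.DataFrame(rows),
        meta={"scan_role": scan_role, "fixed_lambda": fixed_lambda},
    )


def dose_wavelength_surface(
    c_grid,
    lambda_grid,
    spectra: IsomerSpectrumPair,
    phot: PhotoswitchPhotophysics,
    pharm: IsomerPharmacology,
    flux: float = DEFAULT_FLUX,
) -> pd.DataFrame:
    """Steady-state effect surface E*(c, lambda).

    Rows are concentrations (index, M), columns wavelengths (nm).  Each cell
    is the PSS-plateau response at that wavelength and total concentration.
    For an ideal efficacy switch the rows above the saturation threshold are
    constant across concentration; for an affinity switch they are not.
    """
    c = np.asarray(c_grid, dtype=float)
    lams = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(c) <= 0) or np.any(np.diff(lams) <= 0):
        raise ValueError("grids must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    surface = np.empty((c.size, lams.size))
    for j, lam in enumerate(lams):
        phi = compute_pss(spectra, phot, float(lam), flux)
        occ = competitive_occupancy(c, np.full_like(c, phi), pharm)
        surface[:, j] = np.asarray(response(occ, pharm))
    return pd.DataFrame(surface, index=c, columns=lams)
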