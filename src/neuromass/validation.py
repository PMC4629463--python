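"""Amplitude / frequency / phase validation of simulated BOLD.

Simulated signals are compared with empirical-style signals on three
descriptive axes: amplitude (global range and mean of per-region means),
frequency (one-sided FFT power at fs = 1/TR, topping out at 0.25 Hz for
TR = 2 s), and phase (functional connectivity — pairwise Pearson
correlation matrices — compared via the correlation of their strict
upper triangles, with significance from the Fisher Z transform).

Amplitude and frequency are reported side by side without a hard
pass/fail rule; a configurable relative-difference warning (default
±50%) flags gross mismatches only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulator import BOLDSeries

logger = logging.getLogger("neuromass")

__all__ = [
    "ValidationReport",
    "amplitude_stats",
    "frequency_profile",
    "functional_connectivity",
    "group_mean_fc",
    "fc_similarity",
    "validate_subject",
]

#: relative difference beyond which amplitude/frequency mismatch is flagged
MISMATCH_WARN_FRACTION = 0.5


def amplitude_stats(b: BOLDSeries) -> tuple[tuple[float, float], float]:
    """(global min, global max) over all regions and times, and the mean
    over regions of per-region temporal means."""
    if b.data.size == 0:
        raise ValueError("empty BOLD series")
    rng = (float(b.data.min()), float(b.data.max()))
    overall_mean = float(b.data.mean(axis=1).mean())
    return rng, overall_mean


def frequency_profile(b: BOLDSeries):
    """One-sided FFT power spectra after per-region mean removal.

    Returns ``(frequencies, power, peak_hz)`` where ``frequencies`` spans
    0 to fs/2 (0.25 Hz at TR = 2 s), ``power`` is per-region
    ``|FFT|^2``, and ``peak_hz`` the frequency of maximal mean power,
    excluding the 0 Hz bin.
    """
    if b.n_timepoints < 4:
        raise ValueError("frequency profile needs at least 4 time points")
    x = b.data - b.data.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(x, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(b.n_timepoints, d=b.tr_s)
    mean_power = power.mean(axis=0)
    peak_hz = float(freqs[1:][np.argmax(mean_power[1:])])
    return freqs, power, peak_hz


def functional_connectivity(b: BOLDSeries) -> np.ndarray:
    """Pairwise Pearson correlation matrix of the regional series.

    Zero-variance (silent) regions get correlation 0 with every other
    region, with a logged warning, so lesioned nodes do not break the
    pipeline; their diagonal stays 1.
    """
    if b.n_timepoints < 3:
        raise ValueError("functional connectivity needs at least 3 time points")
    sd = b.data.std(axis=1)
    silent = sd == 0
    if silent.any():
        logger.warning(
            "%d zero-variance region(s) in %s; correlations set to 0",
            int(silent.sum()), b.subject_id,
        )
    fc = np.zeros((b.n_regions, b.n_regions))
    live = ~silent
    if live.sum() >= 1:
        sub = np.atleast_2d(np.corrcoef(b.data[live]))
        fc[np.ix_(live, live)] = sub
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def group_mean_fc(fcs: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of equally shaped FC matrices."""
    if not fcs:
        raise ValueError("no matrices given")
    shape = fcs[0].shape
    for m in fcs:
        if m.shape != shape:
            raise ValueError("FC matrices differ in shape")
    return np.mean(np.stack(fcs), axis=0)


def fc_similarity(fc_a: np.ndarray, fc_b: np.ndarray):
    """Similarity of two FC matrices over strict upper triangles.

    Returns ``(r, fisher_z, p)``: the Pearson correlation of the
    vectorized strict upper triangles, its Fisher Z transform atanh(r),
    and a two-sided normal-approximation p-value with standard error
    1/sqrt(m - 3), m = number of upper-triangle entries (entries treated
    as independent — a documented simplification).
    """
    fc_a = np.asarray(fc_a, dtype=float)
    fc_b = np.asarray(fc_b, dtype=float)
    if fc_a.shape != fc_b.shape:
        raise ValueError("FC matrices differ in shape")
    n = fc_a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 regions")
    iu = np.triu_indices(n, k=1)
    a, b = fc_a[iu], fc_b[iu]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant upper triangle; correlation undefined")
    # explicitly symmetric form so fc_similarity(a, b) == fc_similarity(b, a)
    da, db = a - a.mean(), b - b.mean()
    r = float((da * db).sum() / np.sqrt((da * da).sum() * (db * db).sum()))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        z = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        z = float(np.arctanh(r))
        se = 1.0 / np.sqrt(len(a) - 3)
        p = float(2.0 * stats.norm.sf(abs(z) / se))
    return r, z, p


@dataclass
class ValidationReport:
    """Side-by-side amplitude/frequency/phase comparison."""

    subject_id: str
    amplitude_range_sim: tuple
    amplitude_range_emp: tuple
    amplitude_mean_sim: float
    amplitude_mean_emp: float
    peak_frequency_sim: float
    peak_frequency_emp: float
    fc_similarity_r: float
    fisher_z: float
    p_value: float
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "amplitude_range_sim": list(self.amplitude_range_sim),
            "amplitude_range_emp": list(self.amplitude_range_emp),
            "amplitude_mean_sim": self.amplitude_mean_sim,
            "amplitude_mean_emp": self.amplitude_mean_emp,
            "peak_frequency_sim": self.peak_frequency_sim,
            "peak_frequency_emp": self.peak_frequency_emp,
            "fc_similarity_r": self.fc_similarity_r,
            "fisher_z": self.fisher_z,
            "p_value": self.p_value,
            "warnings": list(self.warnings),
        }


def _relative_mismatch(a: float, b: float) -> float:
    denom = max(abs(a), abs(b), 1e-12)
    return abs(a - b) / denom


def validate_subject(
    sim: BOLDSeries, emp_group_fc: np.ndarray, emp_reference: BOLDSeries
) -> ValidationReport:
    """Full three-part validation of one simulated series against a group
    empirical FC matrix and a reference empirical series (for amplitude
    and frequency descriptives)."""
    rng_s, mean_s = amplitude_stats(sim)
    rng_e, mean_e = amplitude_stats(emp_reference)
    _, _, peak_s = frequency_profile(sim)
    _, _, peak_e = frequency_profile(emp_reference)
    fc_s = functional_connectivity(sim)
    r, z, p = fc_similarity(fc_s, emp_group_fc)
    warnings = []
    if _relative_mismatch(mean_s, mean_e) > MISMATCH_WARN_FRACTION:
        warnings.append("amplitude mean mismatch beyond warning threshold")
    if _relative_mismatch(peak_s, peak_e) > MISMATCH_WARN_FRACTION:
        warnings.append("peak frequency mismatch beyond warning threshold")
    for w in warnings:
        logger.warning("%s: %s", sim.subject_id, w)
    return ValidationReport(
        subject_id=sim.subject_id,
        amplitude_range_sim=rng_s,
        amplitude_range_emp=rng_e,
        amplitude_mean_sim=mean_s,
        amplitude_mean_emp=mean_e,
        peak_frequency_sim=peak_s,
        peak_frequency_emp=peak_e,
        fc_similarity_r=r,
        fisher_z=z,
        p_value=p,
    )
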