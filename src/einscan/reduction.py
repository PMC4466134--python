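"""Reduction of raw elastic fixed-window scans to normalised S(Q, T) matrices.

A raw scan is a counts matrix over a (temperature, Q) grid with counting
errors. Reduction follows the standard elastic-scan protocol:

1. subtract the empty-cell contribution scaled by the sample transmission,
2. normalise every detector column to its value at the lowest-temperature
   scan (reference 20 K), which cancels detector efficiency and geometry,
3. bin in temperature (5-K steps by default) with inverse-variance weights.

The summed elastic intensity over a Q window, renormalised to 1 at the
reference temperature, is a model-free monitor of dynamics: it decreases
linearly in T while motions are harmonic, and each activation of a new class
of motion (methyl-group activation; the ~240 K dynamical transition) shows up
as a change of slope. ``detect_slope_changes`` makes that visual criterion
reproducible with a BIC-selected continuous piecewise-linear fit.

Scan files are plain text tables with columns Q, T, I, dI (comma, tab or
whitespace separated) and optional ``# key: value`` metadata header lines.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .models import PiecewiseLinearModel

__all__ = [
    "RawScan",
    "ElasticScan",
    "SummedIntensitySeries",
    "TransitionReport",
    "read_scan",
    "write_scan",
    "subtract_empty_cell",
    "normalize_to_reference",
    "bin_by_temperature",
    "summed_intensity",
    "detect_slope_changes",
]

logger = logging.getLogger("einscan")


def _validate_grid(q, t, i, di):
    q = np.asarray(q, dtype=float)
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    di = np.asarray(di, dtype=float)
    if q.ndim != 1 or t.ndim != 1:
        raise ValueError("q_values and temperatures must be 1-D")
    if i.shape != (t.size, q.size) or di.shape != i.shape:
        raise ValueError(
            f"intensity matrix shape {i.shape} does not match grid "
            f"({t.size} temperatures x {q.size} Q)"
        )
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    if np.any(i < 0):
        raise ValueError("negative intensities")
    if np.any(di < 0):
        raise ValueError("negative errors")
    return q, t, i, di


@dataclass
class RawScan:
    """Counts matrix S(Q, T) before normalisation, with counting errors.

    ``intensities`` and ``errors`` have shape (n_temperatures, n_q).
    ``metadata`` carries instrument name, sample label, hydration, and — for
    generated scans — the embedded ground truth.
    """

    q_values: np.ndarray
    temperatures: np.ndarray
    intensities: np.ndarray
    errors: np.ndarray
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.q_values, self.temperatures, self.intensities, self.errors = (
            _validate_grid(self.q_values, self.temperatures, self.intensities, self.errors)
        )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.intensities.shape

    def row_at(self, temperature: float, tol: Optional[float] = None) -> int:
        """Index of the temperature row nearest ``temperature`` within ``tol``.

        Default tolerance is half the median temperature step.
        """
        t = self.temperatures
        if tol is None:
            steps = np.diff(t)
            tol = 0.5 * float(np.median(steps)) if steps.size else 0.5
        idx = int(np.argmin(np.abs(t - temperature)))
        if abs(t[idx] - temperature) > tol + 1e-9:
            raise ValueError(
                f"no scan row within {tol:g} K of T = {temperature:g} K"
            )
        return idx


@dataclass
class ElasticScan(RawScan):
    """Scan normalised to the reference-temperature row (values ~1 there)."""

    reference_temperature: float = 20.0


@dataclass
class SummedIntensitySeries:
    """Summed normalised elastic intensity vs temperature over a Q window."""

    temperatures: np.ndarray
    values: np.ndarray
    errors: np.ndarray
    q_window: Tuple[float, float]

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if not (self.temperatures.size == self.values.size == self.errors.size):
            raise ValueError("mismatched series lengths")
        if np.any(self.values <= 0):
            raise ValueError("summed intensities must be positive")


@dataclass
class TransitionReport:
    """Slope-change transitions located in a summed-intensity series."""

    breakpoints: List[float]
    segment_slopes: List[float]
    model_score: float
    n_points: int
    t_min: float

    def to_dict(self) -> dict:
        return {
            "breakpoints_K": self.breakpoints,
            "segment_slopes_per_K": self.segment_slopes,
            "bic": self.model_score,
            "n_points": self.n_points,
            "t_min_K": self.t_min,
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["Q", "T", "I", "dI"]


def read_scan(source) -> RawScan:
    """Read a long-format scan table (columns Q, T, I, dI) into a RawScan.

    ``source`` is a path or an open text handle. Lines starting with ``#`` are
    metadata (``# key: value``; a ``# truth: {...}`` line holds embedded JSON).
    The (Q, T) grid must be complete; a ragged grid is an error.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()

    meta: Dict = {}
    data_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key, val = key.strip(), val.strip()
                if key == "truth":
                    meta[key] = json.loads(val)
                else:
                    meta[key] = val
            continue
        data_lines.append(stripped)
    if not data_lines:
        raise ValueError("no data rows found")

    sep = "," if "," in data_lines[0] else r"\s+"
    df = pd.read_csv(io.StringIO("\n".join(data_lines)), sep=sep)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}; header must name Q, T, I, dI")

    if df[["Q", "T"]].duplicated().any():
        raise ValueError("duplicate (Q, T) cells")
    pivot_i = df.pivot(index="T", columns="Q", values="I")
    pivot_e = df.pivot(index="T", columns="Q", values="dI")
    if pivot_i.isna().any().any():
        n_missing = int(pivot_i.isna().sum().sum())
        raise ValueError(f"ragged grid: {n_missing} missing (Q, T) cells")

    return RawScan(
        q_values=pivot_i.columns.to_numpy(dtype=float),
        temperatures=pivot_i.index.to_numpy(dtype=float),
        intensities=pivot_i.to_numpy(dtype=float),
        errors=pivot_e.to_numpy(dtype=float),
        metadata=meta,
    )


def write_scan(scan: RawScan, target) -> None:
    """Write a scan in the long-format table read back by :func:`read_scan`."""
    own = not hasattr(target, "write")
    fh = open(target, "w") if own else target
    try:
        for key, val in scan.metadata.items():
            if isinstance(val, (dict, list)):
                fh.write(f"# {key}: {json.dumps(val)}\n")
            else:
                fh.write(f"# {key}: {val}\n")
        fh.write("Q,T,I,dI\n")
        for it, t in enumerate(scan.temperatures):
            for iq, q in enumerate(scan.q_values):
                fh.write(
                    f"{q:.10g},{t:.10g},{scan.intensities[it, iq]:.10g},"
                    f"{scan.errors[it, iq]:.10g}\n"
                )
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# corrections and normalisation
# ---------------------------------------------------------------------------

def subtract_empty_cell(
    sample: RawScan, empty: RawScan, transmission: float = 0.95
) -> RawScan:
    """Subtract the transmission-scaled empty-cell signal, clipping at zero.

    Errors combine in quadrature. Negative differences are clipped to zero
    (counting data) and the number of clipped cells is logged and recorded in
    the metadata.
    """
    if not (
        np.allclose(sample.q_values, empty.q_values)
        and np.allclose(sample.temperatures, empty.temperatures)
    ):
        raise ValueError("sample and empty-cell scans must share the (Q, T) grid")
    if not 0 < transmission <= 1:
        raise ValueError("transmission must be in (0, 1]")

    diff = sample.intensities - transmission * empty.intensities
    n_clipped = int(np.sum(diff < 0))
    if n_clipped:
        logger.warning("empty-cell subtraction clipped %d negative cells", n_clipped)
    err = np.hypot(sample.errors, transmission * empty.errors)
    meta = dict(sample.metadata)
    meta["empty_cell_transmission"] = transmission
    meta["clipped_negative_cells"] = n_clipped
    return RawScan(
        q_values=sample.q_values.copy(),
        temperatures=sample.temperatures.copy(),
        intensities=np.clip(diff, 0.0, None),
        errors=err,
        metadata=meta,
    )


def normalize_to_reference(
    raw: RawScan, reference_temperature: float = 20.0
) -> ElasticScan:
    """Divide each detector column by its reference-temperature value.

    The reference row must exist within half a temperature bin; propagation is
    by quadrature of relative errors. Idempotent up to error inflation.
    """
    idx = raw.row_at(reference_temperature)
    ref = raw.intensities[idx]
    ref_err = raw.errors[idx]
    if np.any(ref <= 0):
        raise ValueError("reference-temperature intensities must be positive")

    vals = raw.intensities / ref
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(
            np.where(raw.intensities > 0, (raw.errors / np.maximum(raw.intensities, 1e-300)) ** 2, 0.0)
            + (ref_err / ref) ** 2
        )
    errs = vals * rel
    meta = dict(raw.metadata)
    meta["reference_temperature_K"] = float(raw.temperatures[idx])
    return ElasticScan(
        q_values=raw.q_values.copy(),
        temperatures=raw.temperatures.copy(),
        intensities=vals,
        errors=errs,
        metadata=meta,
        reference_temperature=float(raw.temperatures[idx]),
    )


def bin_by_temperature(scan: ElasticScan, width: float = 5.0) -> ElasticScan:
    """Average rows into consecutive [T0, T0 + width) bins.

    Bins are anchored greedily: each bin starts at the first not-yet-binned
    temperature and collects every row within ``width`` of it. Intensities are
    combined with inverse-variance weights (plain means when errors are
    absent); the reported bin temperature is the mean of the contributing
    temperatures, so a scan already on a ``width`` grid is returned unchanged.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    t = scan.temperatures
    idx = np.empty(t.size, dtype=int)
    bin_id = -1
    t_start = -np.inf
    for j, tj in enumerate(t):
        if tj >= t_start + width:
            bin_id += 1
            t_start = tj
        idx[j] = bin_id
    new_t, new_i, new_e = [], [], []
    for b in np.unique(idx):
        sel = idx == b
        ii = scan.intensities[sel]
        ee = scan.errors[sel]
        if np.all(ee > 0):
            w = 1.0 / ee**2
            wi = (w * ii).sum(axis=0) / w.sum(axis=0)
            we = 1.0 / np.sqrt(w.sum(axis=0))
        else:
            wi = ii.mean(axis=0)
            we = np.sqrt((ee**2).sum(axis=0)) / sel.sum()
        new_t.append(float(t[sel].mean()))
        new_i.append(wi)
        new_e.append(we)
    meta = dict(scan.metadata)
    meta["temperature_bin_width_K"] = width
    return ElasticScan(
        q_values=scan.q_values.copy(),
        temperatures=np.asarray(new_t),
        intensities=np.asarray(new_i),
        errors=np.asarray(new_e),
        metadata=meta,
        reference_temperature=scan.reference_temperature,
    )


# ---------------------------------------------------------------------------
# summed intensity and transition detection
# ---------------------------------------------------------------------------

def summed_intensity(
    scan: ElasticScan, q_window: Optional[Tuple[float, float]] = None
) -> SummedIntensitySeries:
    """Sum normalised intensities over Q in ``q_window``; renormalise to 1 at T_ref.

    The window is an open interval (q_lo, q_hi); default (0.2, 2.0).
    """
    if q_window is None:
        q_window = (0.2, 2.0)
    q_lo, q_hi = q_window
    sel = (scan.q_values > q_lo) & (scan.q_values < q_hi)
    if not np.any(sel):
        raise ValueError(f"no Q values inside window ({q_lo}, {q_hi})")
    vals = scan.intensities[:, sel].sum(axis=1)
    errs = np.sqrt((scan.errors[:, sel] ** 2).sum(axis=1))
    idx = scan.row_at(scan.reference_temperature)
    ref = vals[idx]
    return SummedIntensitySeries(
        temperatures=scan.temperatures.copy(),
        values=vals / ref,
        errors=errs / ref,
        q_window=(float(q_lo), float(q_hi)),
    )


def detect_slope_changes(
    series: SummedIntensitySeries,
    max_breakpoints: int = 2,
    t_min: float = 100.0,
) -> TransitionReport:
    """Locate slope-change transitions above ``t_min`` by piecewise-linear BIC fit.

    The fit is performed on ln(summed intensity): the elastic intensity decays
    exponentially with the MSD, so on the log scale a piecewise-linear MSD law
    gives near-linear segments and a slope change cleanly marks the activation
    of a new motion (methyl-group activation, the dynamical transition).
    Below ~100 K the quantum saturation of harmonic motion curves the series,
    hence the search is restricted to T >= t_min. Reported segment slopes are
    d ln(sum)/dT in 1/K.
    """
    sel = series.temperatures >= t_min
    if sel.sum() < 8:
        raise ValueError("need at least 8 points above t_min")
    t = series.temperatures[sel]
    y = np.log(series.values[sel])
    e = series.errors[sel]
    # sigma_ln = sigma / value
    w = (series.values[sel] / e) ** 2 if np.all(e > 0) else None

    model = PiecewiseLinearModel(max_breakpoints=max_breakpoints).fit(
        t[:, None], y, sample_weight=w
    )
    return TransitionReport(
        breakpoints=model.breakpoints_,
        segment_slopes=model.segment_slopes_,
        model_score=model.bic_,
        n_points=int(t.size),
        t_min=float(t_min),
    )
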