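"""Extracted-ion-chromatogram quantification of centroided LC-MS runs.

Workflow: read a centroided run (mzML or a plain rt/mz/intensity peak
table), extract an EIC per library species and charge state within a ppm
window, locate the apex, integrate the peak above a window-minimum
baseline, and normalise integrated areas to molar percentages under an
equimolar-response assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .murolib import MuropeptideRecord


@dataclass
class CentroidedRun:
    """A centroided LC-MS acquisition.

    Stored internally as flat arrays sorted by m/z for fast EIC slicing:
    ``times`` (minutes, strictly increasing, one entry per spectrum) and the
    peak triplets (spectrum index, m/z, intensity).
    """

    times: np.ndarray
    _mz: np.ndarray = field(repr=False)
    _intensity: np.ndarray = field(repr=False)
    _scan: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size == 0:
            raise ValueError("run contains no spectra")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self._intensity < 0):
            raise ValueError("peak intensities must be non-negative")

    @property
    def n_spectra(self) -> int:
        return self.times.size

    @classmethod
    def from_arrays(
        cls, times: np.ndarray, scan_idx: np.ndarray, mz: np.ndarray, intensity: np.ndarray
    ) -> "CentroidedRun":
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        scan_idx = np.asarray(scan_idx, dtype=np.intp)
        order = np.argsort(mz, kind="stable")
        return cls(np.asarray(times, dtype=float), mz[order], intensity[order], scan_idx[order])

    @classmethod
    def from_spectra(
        cls, spectra: Sequence[tuple[float, np.ndarray, np.ndarray]]
    ) -> "CentroidedRun":
        """Build from ``[(rt_min, mz_array, intensity_array), ...]``."""
        if not spectra:
            raise ValueError("run contains no spectra")
        times = np.array([s[0] for s in spectra], dtype=float)
        mz = np.concatenate([np.asarray(s[1], dtype=float) for s in spectra]) if spectra else np.array([])
        inten = np.concatenate([np.asarray(s[2], dtype=float) for s in spectra])
        scan = np.concatenate(
            [np.full(len(s[1]), i, dtype=np.intp) for i, s in enumerate(spectra)]
        )
        return cls.from_arrays(times, scan, mz, inten)

    @classmethod
    def from_peak_table(cls, df: pd.DataFrame) -> "CentroidedRun":
        """Build from a long table with columns rt_min, mz, intensity."""
        required = {"rt_min", "mz", "intensity"}
        if not required.issubset(df.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        rts = np.asarray(df["rt_min"], dtype=float)
        times, scan_idx = np.unique(rts, return_inverse=True)
        return cls.from_arrays(times, scan_idx, df["mz"].to_numpy(), df["intensity"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "CentroidedRun":
        return cls.from_peak_table(pd.read_csv(path))

    @classmethod
    def from_mzml(cls, path) -> "CentroidedRun":
        """Read a centroided mzML file (profile-mode spectra are rejected)."""
        spectra = _read_mzml_spectra(path)
        spectra.sort(key=lambda s: s[0])
        return cls.from_spectra(spectra)

    def spectra(self):
        """Iterate ``(rt_min, mz_array, intensity_array)`` per spectrum."""
        order = np.argsort(self._scan, kind="stable")
        scan, mz, inten = self._scan[order], self._mz[order], self._intensity[order]
        bounds = np.searchsorted(scan, np.arange(self.n_spectra + 1))
        for i in range(self.n_spectra):
            sl = slice(bounds[i], bounds[i + 1])
            o = np.argsort(mz[sl])
            yield self.times[i], mz[sl][o], inten[sl][o]


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _decode_binary_array(elem) -> np.ndarray:
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in elem.iter(_MZML_NS + "cvParam")
    }
    binary = elem.find(_MZML_NS + "binary")
    raw = base64.b64decode((binary.text or "").strip())
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml_spectra(path) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Minimal mzML reader: MS1 centroided spectra with rt/mz/intensity.

    Self-contained (ElementTree + base64) rather than delegating to a
    heavier mzML stack; handles 32/64-bit float arrays, optional zlib
    compression, and scan start times in minutes or seconds.
    """
    import xml.etree.ElementTree as ET

    spectra: list[tuple[float, np.ndarray, np.ndarray]] = []
    for _event, spec in ET.iterparse(str(path)):
        if spec.tag != _MZML_NS + "spectrum":
            continue
        params = {
            cv.get("accession"): cv for cv in spec.iter(_MZML_NS + "cvParam")
        }
        level = params.get(_ACC_MS_LEVEL)
        if level is not None and int(level.get("value", "1")) != 1:
            spec.clear()
            continue
        if _ACC_PROFILE in params:
            raise ValueError(
                "profile-mode spectra are not supported; centroid the data first"
            )
        rt_param = params.get(_ACC_SCAN_START)
        if rt_param is None:
            raise ValueError("spectrum without a scan start time")
        rt = float(rt_param.get("value"))
        if rt_param.get("unitName", "minute") in ("second", "s"):
            rt /= 60.0
        mz = intensity = None
        for arr in spec.iter(_MZML_NS + "binaryDataArray"):
            arr_params = {cv.get("accession") for cv in arr.iter(_MZML_NS + "cvParam")}
            if _ACC_MZ_ARRAY in arr_params:
                mz = _decode_binary_array(arr)
            elif _ACC_INT_ARRAY in arr_params:
                intensity = _decode_binary_array(arr)
        if mz is None or intensity is None:
            raise ValueError("spectrum missing m/z or intensity array")
        spectra.append((rt, mz, intensity))
        spec.clear()
    if not spectra:
        raise ValueError("no MS1 spectra found in mzML file")
    return spectra


@dataclass
class EICTrace:
    """Extracted ion chromatogram: summed intensity per spectrum in a ppm window."""

    target_mz: float
    tolerance_ppm: float
    times: np.ndarray
    intensities: np.ndarray


@dataclass
class Identification:
    """A library species matched and integrated in a run."""

    record: MuropeptideRecord
    charge: int
    apex_rt: float
    rt_window: tuple[float, float]
    area: float
    matched_mz: float
    mass_error_ppm: float

    @property
    def name(self) -> str:
        return self.record.name


def extract_eic(run: CentroidedRun, target_mz: float, tolerance_ppm: float) -> EICTrace:
    """Sum peak intensities within ``target_mz * (1 +/- ppm*1e-6)`` per spectrum."""
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    lo = target_mz * (1 - tolerance_ppm * 1e-6)
    hi = target_mz * (1 + tolerance_ppm * 1e-6)
    i0, i1 = np.searchsorted(run._mz, [lo, hi])
    intensities = np.bincount(
        run._scan[i0:i1], weights=run._intensity[i0:i1], minlength=run.n_spectra
    )
    return EICTrace(target_mz, tolerance_ppm, run.times, intensities)


def integrate_peak(trace: EICTrace, rt_window: tuple[float, float]) -> float:
    """Trapezoidal area in the window after subtracting the window-minimum baseline."""
    start, end = rt_window
    if start >= end:
        raise ValueError("rt_window start must precede end")
    if start > trace.times[-1] or end < trace.times[0]:
        raise ValueError("rt_window lies outside the trace RT range")
    sel = (trace.times >= start) & (trace.times <= end)
    if not np.any(sel):
        raise ValueError("rt_window contains no samples")
    t = trace.times[sel]
    y = trace.intensities[sel]
    if t.size < 2:
        return 0.0
    baseline = float(y.min())
    return float(np.trapezoid(y - baseline, t))


def _smooth(y: np.ndarray, window: int = 5) -> np.ndarray:
    window = min(window, y.size)
    if window < 2:
        return y.astype(float)
    return np.convolve(y, np.ones(window) / window, mode="same")


def _peak_window(y_smooth: np.ndarray, apex: int, frac: float = 0.05) -> tuple[int, int]:
    """Peak boundaries: contiguous region around the apex above ``frac`` of the
    apex on the smoothed trace, then extended downhill to the local minima.

    Boundary detection runs on a lightly smoothed copy so that isolated
    centroid dropouts (zero-intensity scans from m/z jitter leaving the ppm
    window) do not truncate the peak."""
    thr = frac * y_smooth[apex]
    i0 = apex
    while i0 > 0 and y_smooth[i0 - 1] >= thr:
        i0 -= 1
    while i0 > 0 and y_smooth[i0 - 1] < y_smooth[i0]:
        i0 -= 1
    i1 = apex
    while i1 < y_smooth.size - 1 and y_smooth[i1 + 1] >= thr:
        i1 += 1
    while i1 < y_smooth.size - 1 and y_smooth[i1 + 1] < y_smooth[i1]:
        i1 += 1
    return i0, i1


def _integrate_segment(t: np.ndarray, y: np.ndarray) -> float:
    """Baseline-subtracted trapezoidal area over the nonzero samples.

    Zero-intensity scans inside the window are centroid dropouts; skipping
    them lets the trapezoid bridge the gap instead of dipping to zero."""
    nz = y > 0
    if nz.sum() < 2:
        return 0.0
    tt, yy = t[nz], y[nz]
    return float(np.trapezoid(yy - yy.min(), tt))


def match_run(
    run: CentroidedRun,
    library: Sequence[MuropeptideRecord],
    tolerance_ppm: float = 10.0,
    min_area: float = 0.0,
    rt_tolerance_min: float = 0.5,
) -> list[Identification]:
    """Match every library record against the run.

    Per record and charge state: extract the EIC, take the global intensity
    maximum as the apex (restricted to +/- ``rt_tolerance_min`` of the library
    retention time when one is present), define the peak window as the
    contiguous region above 5% of the apex, and integrate. Per record only the
    best charge state by area is kept; identifications below ``min_area`` are
    dropped. Each record yields at most one identification.
    """
    if not library:
        raise ValueError("library must be non-empty")
    identifications: list[Identification] = []
    for record in library:
        best: Identification | None = None
        for z, target in sorted(record.mz_by_charge.items()):
            trace = extract_eic(run, target, tolerance_ppm)
            y = trace.intensities
            if record.retention_time is not None:
                region = np.abs(trace.times - record.retention_time) <= rt_tolerance_min
                if not np.any(region) or not np.any(y[region] > 0):
                    continue
                apex = int(np.flatnonzero(region)[np.argmax(y[region])])
            else:
                if not np.any(y > 0):
                    continue
                apex = int(np.argmax(y))
            y_smooth = _smooth(y)
            i0, i1 = _peak_window(y_smooth, apex)
            if i1 <= i0:
                continue
            t = trace.times[i0 : i1 + 1]
            seg = y[i0 : i1 + 1]
            area = _integrate_segment(t, seg)
            if area <= 0 or area < min_area:
                continue
            matched_mz = _matched_mz_at_apex(run, apex, target, tolerance_ppm)
            ident = Identification(
                record=record,
                charge=z,
                apex_rt=float(trace.times[apex]),
                rt_window=(float(t[0]), float(t[-1])),
                area=area,
                matched_mz=matched_mz,
                mass_error_ppm=(matched_mz - target) / target * 1e6,
            )
            if best is None or ident.area > best.area:
                best = ident
        if best is not None:
            identifications.append(best)
    identifications.sort(key=lambda i: i.name)
    return identifications


def _matched_mz_at_apex(
    run: CentroidedRun, apex_scan: int, target_mz: float, tolerance_ppm: float
) -> float:
    lo = target_mz * (1 - tolerance_ppm * 1e-6)
    hi = target_mz * (1 + tolerance_ppm * 1e-6)
    i0, i1 = np.searchsorted(run._mz, [lo, hi])
    in_scan = run._scan[i0:i1] == apex_scan
    if not np.any(in_scan):
        return target_mz
    mzs = run._mz[i0:i1][in_scan]
    ints = run._intensity[i0:i1][in_scan]
    return float(mzs[np.argmax(ints)])


def identifications_to_frame(identifications: Sequence[Identification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [i.name for i in identifications],
            "charge": [i.charge for i in identifications],
            "apex_rt": [i.apex_rt for i in identifications],
            "rt_start": [i.rt_window[0] for i in identifications],
            "rt_end": [i.rt_window[1] for i in identifications],
            "area": [i.area for i in identifications],
            "matched_mz": [i.matched_mz for i in identifications],
            "mass_error_ppm": [i.mass_error_ppm for i in identifications],
        }
    )


def normalize_molar(identifications: Sequence[Identification] | pd.DataFrame) -> pd.DataFrame:
    """Convert integrated areas to molar percentages (equimolar response).

    Returns a quant table with columns ``name``, ``area``, ``molar_percent``,
    sorted by name; percentages sum to 100.
    """
    if isinstance(identifications, pd.DataFrame):
        df = identifications[["name", "area"]].copy()
    else:
        df = pd.DataFrame(
            {"name": [i.name for i in identifications], "area": [i.area for i in identifications]}
        )
    if df.empty:
        raise ValueError("no identifications to normalise")
    total = df["area"].sum()
    if total <= 0:
        raise ValueError("all areas are zero; molar normalisation undefined")
    df["molar_percent"] = 100.0 * df["area"] / total
    return df.sort_values("name", ignore_index=True)
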