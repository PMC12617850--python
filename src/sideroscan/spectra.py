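"""MS/MS spectra: container, MGF I/O and peak hygiene.

Hygiene follows the networking preprocessing of the method: a ubiquitous
contaminant product ion (m/z 202.080, instrument-borne, present in every
spectrum regardless of precursor) is deleted, then each spectrum is
reduced to the top five most abundant ions within a sliding 50 Da window
and ions below 0.1% of the base peak are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mgf as _mgf

__all__ = [
    "FragmentSpectrum",
    "CONTAMINANT_MZ",
    "read_mgf",
    "write_mgf",
    "remove_contaminant",
    "filter_peaks",
]

#: m/z of the ubiquitous contaminant product ion removed computationally.
CONTAMINANT_MZ = 202.080


@dataclass
class FragmentSpectrum:
    """A centroided MS/MS spectrum linked to an MS1 feature.

    Peaks are kept sorted ascending in m/z; intensities must be positive.
    """

    spectrum_id: str
    precursor_mz: float
    precursor_rt: float
    mz: np.ndarray
    intensity: np.ndarray
    feature_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity <= 0):
            raise ValueError(f"spectrum {self.spectrum_id}: intensities must be > 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.mz.size else 0.0

    def peaks(self) -> List[Tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def with_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "FragmentSpectrum":
        return FragmentSpectrum(
            spectrum_id=self.spectrum_id,
            precursor_mz=self.precursor_mz,
            precursor_rt=self.precursor_rt,
            mz=mz,
            intensity=intensity,
            feature_id=self.feature_id,
        )


def read_mgf(path: str | Path) -> List[FragmentSpectrum]:
    """Read an MGF file; TITLE carries the feature id, RTINSECONDS the RT."""
    out: List[FragmentSpectrum] = []
    with _mgf.read(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"spectrum_{i}"))
            pepmass = params.get("pepmass", (0.0,))
            rt_s = params.get("rtinseconds", 0.0)
            mz = np.asarray(entry.get("m/z array", []), dtype=float)
            inten = np.asarray(entry.get("intensity array", []), dtype=float)
            keep = inten > 0
            out.append(
                FragmentSpectrum(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0]),
                    precursor_rt=float(rt_s) / 60.0,
                    mz=mz[keep],
                    intensity=inten[keep],
                    feature_id=title,
                )
            )
    return out


def write_mgf(spectra: Sequence[FragmentSpectrum], path: str | Path) -> None:
    """Write spectra to MGF (TITLE = feature id, PEPMASS, RTINSECONDS)."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.feature_id or s.spectrum_id,
                    "pepmass": s.precursor_mz,
                    "rtinseconds": s.precursor_rt * 60.0,
                    "charge": "1+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def remove_contaminant(
    s: FragmentSpectrum,
    contaminant_mz: float = CONTAMINANT_MZ,
    tol_da: float = 0.003,
) -> FragmentSpectrum:
    """Delete all product ions within ``tol_da`` of the contaminant m/z."""
    keep = np.abs(s.mz - contaminant_mz) > tol_da
    return s.with_peaks(s.mz[keep], s.intensity[keep])


def filter_peaks(
    s: FragmentSpectrum,
    top_k: int = 5,
    window_da: float = 50.0,
    min_rel_intensity: float = 0.001,
) -> FragmentSpectrum:
    """Window-ranked peak reduction.

    A peak survives iff it ranks among the ``top_k`` most intense peaks
    within the ``window_da`` window centred on it (+-window/2, sliding,
    to avoid bin-edge artifacts) AND its intensity is at least
    ``min_rel_intensity`` of the base peak.  The operation is idempotent.
    """
    if top_k <= 0 or window_da <= 0 or min_rel_intensity < 0:
        raise ValueError("filter parameters must be positive")
    if s.n_peaks == 0:
        return s
    base = s.base_peak_intensity
    half = window_da / 2.0
    keep = np.zeros(s.n_peaks, dtype=bool)
    for i in range(s.n_peaks):
        if s.intensity[i] < min_rel_intensity * base:
            continue
        in_win = np.abs(s.mz - s.mz[i]) <= half
        rank = int(np.sum(s.intensity[in_win] > s.intensity[i]))
        if rank < top_k:
            keep[i] = True
    return s.with_peaks(s.mz[keep], s.intensity[keep])
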