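"""MS1 feature tables: containers, CSV I/O, cross-run matching and blank
subtraction.

A *feature* is a deconvoluted MS1 ion defined by its m/z, retention time
and peak area, optionally carrying an isotopologue envelope (list of
(m/z, relative intensity) pairs with the monoisotopic peak at 1.0).
Tables are plain CSV with columns ``feature_id, mz, rt_min, area,
polarity``; envelopes travel in a separate long-format CSV
``feature_id, iso_mz, rel_intensity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "MS1Feature",
    "SCAN_RANGE",
    "read_feature_table",
    "write_feature_table",
    "match_features",
    "blank_filter",
]

#: Default instrument scan range (m/z) for full-scan acquisition.
SCAN_RANGE: Tuple[float, float] = (80.0, 1500.0)

FEATURE_COLUMNS = ["feature_id", "mz", "rt_min", "area", "polarity"]
ENVELOPE_COLUMNS = ["feature_id", "iso_mz", "rel_intensity"]


@dataclass
class MS1Feature:
    """A single aligned MS1 feature (singly charged assumption)."""

    feature_id: str
    mz: float
    rt: float
    area: float
    polarity: str = "positive"
    envelope: Optional[List[Tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"feature {self.feature_id}: area must be > 0")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: rt must be >= 0")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(
                f"feature {self.feature_id}: polarity must be positive|negative"
            )
        if self.envelope is not None:
            self.envelope = sorted((float(m), float(i)) for m, i in self.envelope)


def read_feature_table(
    path: str | Path,
    envelope_path: str | Path | None = None,
    scan_range: Tuple[float, float] = SCAN_RANGE,
) -> List[MS1Feature]:
    """Load a feature CSV (and optional envelope CSV) into features.

    Features outside the scan range are rejected with a ``ValueError``;
    missing required columns raise as a schema error.
    """
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    envelopes: Dict[str, List[Tuple[float, float]]] = {}
    if envelope_path is not None and Path(envelope_path).exists():
        env = pd.read_csv(envelope_path)
        emissing = [c for c in ENVELOPE_COLUMNS if c not in env.columns]
        if emissing:
            raise ValueError(f"{envelope_path}: missing envelope columns {emissing}")
        for fid, grp in env.groupby("feature_id"):
            envelopes[str(fid)] = list(
                zip(grp["iso_mz"].astype(float), grp["rel_intensity"].astype(float))
            )
    out: List[MS1Feature] = []
    lo, hi = scan_range
    for row in df.itertuples(index=False):
        mz = float(row.mz)
        if not (lo <= mz <= hi):
            raise ValueError(
                f"feature {row.feature_id}: m/z {mz} outside scan range {scan_range}"
            )
        out.append(
            MS1Feature(
                feature_id=str(row.feature_id),
                mz=mz,
                rt=float(row.rt_min),
                area=float(row.area),
                polarity=str(row.polarity),
                envelope=envelopes.get(str(row.feature_id)),
            )
        )
    return out


def write_feature_table(
    features: Sequence[MS1Feature],
    path: str | Path,
    envelope_path: str | Path | None = None,
) -> None:
    """Write features (and, if requested, their envelopes) to CSV."""
    df = pd.DataFrame(
        [
            {
                "feature_id": f.feature_id,
                "mz": f.mz,
                "rt_min": f.rt,
                "area": f.area,
                "polarity": f.polarity,
            }
            for f in features
        ],
        columns=FEATURE_COLUMNS,
    )
    df.to_csv(path, index=False)
    if envelope_path is not None:
        rows = []
        for f in features:
            for iso_mz, rel in f.envelope or []:
                rows.append(
                    {"feature_id": f.feature_id, "iso_mz": iso_mz, "rel_intensity": rel}
                )
        pd.DataFrame(rows, columns=ENVELOPE_COLUMNS).to_csv(envelope_path, index=False)


def match_features(
    a: Sequence[MS1Feature],
    b: Sequence[MS1Feature],
    mz_tol_ppm: float = 5.0,
    rt_tol: float = 0.2,
) -> List[Tuple[str, str]]:
    """Greedy nearest-match of features across two runs.

    Candidate pairs lie within ``mz_tol_ppm`` in m/z and ``rt_tol`` minutes
    in retention time; pairs are consumed in order of (|dmz in ppm|, |drt|)
    and each feature participates in at most one match.
    """
    if mz_tol_ppm <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    cands: List[Tuple[float, float, str, str]] = []
    for fa in a:
        for fb in b:
            dppm = abs(fa.mz - fb.mz) / fa.mz * 1e6
            drt = abs(fa.rt - fb.rt)
            if dppm <= mz_tol_ppm and drt <= rt_tol:
                cands.append((dppm, drt, fa.feature_id, fb.feature_id))
    cands.sort()
    used_a: set = set()
    used_b: set = set()
    matches: List[Tuple[str, str]] = []
    for _, _, ida, idb in cands:
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        matches.append((ida, idb))
    return matches


def blank_filter(
    sample: Sequence[MS1Feature],
    control: Sequence[MS1Feature],
    threshold_fraction: float = 1e-4,
    mz_tol_ppm: float = 5.0,
    rt_tol: float = 0.2,
) -> List[MS1Feature]:
    """Remove features attributable to the blank/control run.

    A sample feature is dropped iff a matched control feature has peak
    area greater than ``threshold_fraction`` (default 0.01%) of the
    sample feature's area.  Sample features with no control partner are
    always retained.
    """
    matches = dict(
        match_features(sample, control, mz_tol_ppm=mz_tol_ppm, rt_tol=rt_tol)
    )
    control_area = {f.feature_id: f.area for f in control}
    retained: List[MS1Feature] = []
    for f in sample:
        partner = matches.get(f.feature_id)
        if partner is not None and control_area[partner] > threshold_fraction * f.area:
            continue
        retained.append(f)
    return retained
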