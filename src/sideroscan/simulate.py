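"""Synthetic LC-MS scenarios with planted siderophore families.

The generator emits what the screen consumes: an MS1 feature table for a
sample run and a blank/control run, MS/MS spectra, and a ground-truth
map.  The default scenario plants five tris-hydroxamate siderophore
families around the base neutral formula C33H62N6O13, related by +CH2
and +O offsets (members 1/2, 3/4, 4/5 differ by CH2; 1/3, 2/4 by O).
Each family appears as an apo [M+H]+ feature and a ferric-complex
[M-3H+Fe+H]+ feature with the 54Fe satellite in its isotopologue
envelope, the ferric complex carrying the major share of the peak area
and a shifted retention time.  Decoys (plain organics, Cl-like isotope
patterns, correct-spacing/wrong-ratio patterns, near-miss mass pairs),
blank-shared features and a ubiquitous MS/MS contaminant ion complete
the scenario.

Noise model: Gaussian m/z error (sigma 1 ppm), log-normal peak-area
error (sigma 0.1), multiplicative Gaussian error on envelope relative
intensities — Orbitrap-class accuracy.  A fixed seed makes every output
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    ElementalFormula,
    ferric_complex_mz,
    monoisotopic_mass,
    parse_formula,
    protonated_mz,
    FE54_FE56_SPACING,
    FE_MINUS_3H,
    MASS,
)
from .features import MS1Feature, write_feature_table
from .spectra import CONTAMINANT_MZ, FragmentSpectrum, write_mgf

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "ScenarioResult",
    "generate_scenario",
    "simulate_isotope_envelope",
    "simulate_msms",
]

_C13_DELTA = 1.00335484  # 13C - 12C


@dataclass
class ScenarioConfig:
    """Everything that defines a synthetic run.

    The defaults are the study conditions the rest of the package is
    tested against: five planted families, ferric complex dominant
    (``apo_fraction`` 0.25), gradient window 1.5-8 min with the ferric
    complex eluting 0.2-0.5 min later, 24 decoys, 6 blank-shared
    features and the m/z 202.080 contaminant ion in every spectrum.
    """

    seed: int = 1
    base_formula: str = "C33H62N6O13"
    # (n_CH2, n_O) offsets; order defines family ids 1..5
    family_offsets: Tuple[Tuple[int, int], ...] = ((0, 0), (1, 0), (0, 1), (1, 1), (2, 1))
    apo_fraction: float = 0.25
    family_area: float = 1.0e7
    rt_window: Tuple[float, float] = (1.5, 8.0)
    holo_rt_shift: Tuple[float, float] = (0.2, 0.5)
    n_plain_decoys: int = 12
    n_wrong_ratio_decoys: int = 4
    n_cl_decoys: int = 4
    n_near_pair_decoys: int = 2
    n_blank_shared: int = 6
    n_control_only: int = 8
    mz_noise_ppm: float = 1.0
    area_noise_sigma: float = 0.1
    envelope_rel_noise: float = 0.05
    envelope_mz_noise_da: float = 0.0005
    contaminant: bool = True
    include_fe_peaks: bool = True
    include_apo: bool = True
    include_holo: bool = True
    msms_noise_peaks: int = 6
    scan_range: Tuple[float, float] = (80.0, 1500.0)

    def family_formulas(self) -> List[ElementalFormula]:
        base = parse_formula(self.base_formula)
        out = []
        for n_ch2, n_o in self.family_offsets:
            counts = base.as_dict()
            counts["C"] = counts.get("C", 0) + n_ch2
            counts["H"] = counts.get("H", 0) + 2 * n_ch2
            counts["O"] = counts.get("O", 0) + n_o
            out.append(ElementalFormula(counts))
        return out

    def validate(self) -> None:
        lo, hi = self.scan_range
        for f in self.family_formulas():
            apo = protonated_mz(monoisotopic_mass(f))
            holo = ferric_complex_mz(monoisotopic_mass(f))
            if not (lo <= apo <= hi and lo <= holo <= hi):
                raise ValueError(
                    f"planted ion m/z outside scan range {self.scan_range}: "
                    f"{f.hill()} (apo {apo:.4f}, holo {holo:.4f})"
                )
        if not (0.0 < self.apo_fraction < 1.0):
            raise ValueError("apo_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted role of every emitted feature."""

    entries: Dict[str, dict] = field(default_factory=dict)

    def add(self, feature_id: str, role: str, family: Optional[int] = None,
            formula: Optional[str] = None) -> None:
        self.entries[feature_id] = {"role": role, "family": family, "formula": formula}

    def ids_with_role(self, role: str) -> List[str]:
        return sorted(k for k, v in self.entries.items() if v["role"] == role)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(entries=json.load(fh))


@dataclass
class ScenarioResult:
    sample: List[MS1Feature]
    control: List[MS1Feature]
    spectra: List[FragmentSpectrum]
    truth: GroundTruth
    config: ScenarioConfig


def simulate_isotope_envelope(
    f: ElementalFormula, include_fe: Optional[bool] = None
) -> List[Tuple[float, float]]:
    """Deterministic (noise-free) isotopologue envelope of a formula.

    Returns (mass, relative intensity) with the monoisotopic peak at 1.0,
    a 13C A+1 peak at ``n_C * 0.0107`` (binomial approximation), and —
    when the formula contains iron (or ``include_fe`` forces it) — the
    54Fe A-2 peak at the natural 54/56 abundance ratio 0.0637.
    """
    if include_fe is None:
        include_fe = f.get("Fe", 0) > 0
    m = monoisotopic_mass(f)
    peaks: List[Tuple[float, float]] = []
    if include_fe:
        peaks.append((m - FE54_FE56_SPACING, MASS.fe_ratio))
    peaks.append((m, 1.0))
    n_c = f.get("C", 0)
    if n_c:
        peaks.append((m + _C13_DELTA, n_c * MASS.c13_abundance))
    return peaks


def _ion_envelope(
    ion_mz: float,
    n_c: int,
    fe: bool,
    rng: np.random.Generator,
    cfg: ScenarioConfig,
    a2_spacing: float = FE54_FE56_SPACING,
    a2_ratio: Optional[float] = None,
    a2_sign: int = -1,
) -> List[Tuple[float, float]]:
    """Noisy envelope around an observed ion m/z.

    ``a2_ratio``/``a2_spacing``/``a2_sign`` let decoy generators plant
    wrong-ratio or Cl-like (+2) satellite peaks.
    """
    peaks = [(ion_mz, 1.0)]
    if n_c:
        rel = n_c * MASS.c13_abundance * (1.0 + rng.normal(0.0, cfg.envelope_rel_noise))
        peaks.append((ion_mz + _C13_DELTA, max(rel, 1e-4)))
    if fe or a2_ratio is not None:
        ratio = MASS.fe_ratio if a2_ratio is None else a2_ratio
        rel = ratio * (1.0 + rng.normal(0.0, cfg.envelope_rel_noise))
        peaks.append((ion_mz + a2_sign * a2_spacing, max(rel, 1e-4)))
    return sorted(
        (m + rng.normal(0.0, cfg.envelope_mz_noise_da), i) for m, i in peaks
    )


_MSMS_TEMPLATE_FRAGMENTS: Tuple[Tuple[float, float], ...] = (
    # (m/z, intensity): conserved monomer fragment ions of the family
    (86.06004, 100.0),   # C4H7NO + H
    (115.07536, 55.0),   # hexanoyl C6H10O2 + H
    (131.08150, 70.0),   # N5-hydroxyornithine + H
    (157.06077, 40.0),   # N5-formyl-N5-hydroxyornithine + H
    (241.11830, 20.0),   # internal dipeptide-like fragment (invented)
    (198.08720, 15.0),   # internal fragment (invented)
)
_MSMS_TEMPLATE_LOSSES: Tuple[Tuple[float, float], ...] = (
    # (neutral-loss mass, intensity): peaks at precursor - loss
    (114.06808, 45.0),   # C6H10O2
    (130.07423, 35.0),   # C5H10N2O2
    (158.06914, 25.0),   # C6H10N2O3
)
_SUBTHRESHOLD_PEAK = (333.3333, 0.05)  # 0.05% of base peak: below the floor


def simulate_msms(
    precursor_mz: float,
    precursor_rt: float = 0.0,
    spectrum_id: str = "spectrum",
    feature_id: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
    noise_peaks: int = 0,
    mz_noise_da: float = 0.0,
    contaminant: bool = False,
) -> FragmentSpectrum:
    """Template MS/MS spectrum of a planted hydroxamate siderophore.

    Conserved monomer fragments sit at fixed m/z across a family while
    loss peaks ride at ``precursor - loss``, so analog spectra align
    under the modified cosine via the precursor-shifted condition.  With
    ``noise_peaks=0`` and ``mz_noise_da=0`` the peak list is exactly the
    deterministic template.
    """
    mzs: List[float] = [m for m, _ in _MSMS_TEMPLATE_FRAGMENTS]
    ints: List[float] = [i for _, i in _MSMS_TEMPLATE_FRAGMENTS]
    for loss, inten in _MSMS_TEMPLATE_LOSSES:
        mzs.append(precursor_mz - loss)
        ints.append(inten)
    mzs.append(_SUBTHRESHOLD_PEAK[0])
    ints.append(_SUBTHRESHOLD_PEAK[1])
    if contaminant:
        mzs.append(CONTAMINANT_MZ)
        ints.append(30.0)
    if noise_peaks and rng is not None:
        lo, hi = 90.0, max(precursor_mz - 20.0, 120.0)
        for _ in range(noise_peaks):
            mzs.append(float(rng.uniform(lo, hi)))
            ints.append(float(rng.uniform(0.2, 2.0)))
    mz = np.asarray(mzs)
    if mz_noise_da and rng is not None:
        mz = mz + rng.normal(0.0, mz_noise_da, size=mz.size)
    return FragmentSpectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz,
        precursor_rt=precursor_rt,
        mz=mz,
        intensity=np.asarray(ints),
        feature_id=feature_id or spectrum_id,
    )


def _decoy_msms(
    precursor_mz: float,
    precursor_rt: float,
    feature_id: str,
    rng: np.random.Generator,
    contaminant: bool,
) -> FragmentSpectrum:
    n = int(rng.integers(6, 12))
    mzs = list(rng.uniform(90.0, max(precursor_mz - 10.0, 120.0), size=n))
    ints = list(rng.uniform(5.0, 100.0, size=n))
    if contaminant:
        mzs.append(CONTAMINANT_MZ)
        ints.append(30.0)
    return FragmentSpectrum(
        spectrum_id=feature_id,
        precursor_mz=precursor_mz,
        precursor_rt=precursor_rt,
        mz=np.asarray(mzs),
        intensity=np.asarray(ints),
        feature_id=feature_id,
    )


def _noisy_mz(mz: float, rng: np.random.Generator, cfg: ScenarioConfig) -> float:
    return mz * (1.0 + rng.normal(0.0, cfg.mz_noise_ppm * 1e-6))


def _noisy_area(area: float, rng: np.random.Generator, cfg: ScenarioConfig) -> float:
    return area * float(np.exp(rng.normal(0.0, cfg.area_noise_sigma)))


def _random_mz(
    rng: np.random.Generator,
    avoid: Sequence[float],
    lo: float = 100.0,
    hi: float = 1200.0,
    margin: float = 0.05,
) -> float:
    """Uniform random m/z avoiding windows around reserved masses.

    Keeps ground truth unambiguous: no decoy can collide by chance with
    a planted ion, its ferric/apo counterpart or a +-CH2/+-O analog slot.
    """
    offsets = (0.0, FE_MINUS_3H, -FE_MINUS_3H, 14.01565, -14.01565, 15.99491, -15.99491)
    for _ in range(1000):
        mz = float(rng.uniform(lo, hi))
        if all(abs(mz - a - off) > margin for a in avoid for off in offsets):
            return mz
    raise RuntimeError("could not place a decoy m/z away from reserved windows")


def generate_scenario(
    cfg: Optional[ScenarioConfig] = None, outdir: str | Path | None = None
) -> ScenarioResult:
    """Generate the full synthetic scenario (and optionally write files).

    Files written to ``outdir``: ``sample.csv`` + ``sample_envelopes.csv``,
    ``control.csv``, ``spectra.mgf``, ``truth.json``.
    """
    cfg = cfg or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    sample: List[MS1Feature] = []
    control: List[MS1Feature] = []
    spectra: List[FragmentSpectrum] = []

    formulas = cfg.family_formulas()
    planted_mz: List[float] = []
    apo_features: List[Tuple[MS1Feature, int]] = []
    for fam_idx, f in enumerate(formulas, start=1):
        neutral = monoisotopic_mass(f)
        apo_ion = protonated_mz(neutral)
        holo_ion = ferric_complex_mz(neutral)
        planted_mz += [apo_ion, holo_ion]
        rt_apo = float(rng.uniform(*cfg.rt_window))
        rt_holo = rt_apo + float(rng.uniform(*cfg.holo_rt_shift))
        total = _noisy_area(cfg.family_area, rng, cfg)
        n_c = f.get("C", 0)
        if cfg.include_apo:
            apo_obs = _noisy_mz(apo_ion, rng, cfg)
            feat = MS1Feature(
                feature_id=f"sid{fam_idx}_apo",
                mz=apo_obs,
                rt=rt_apo,
                area=total * cfg.apo_fraction,
                envelope=_ion_envelope(apo_obs, n_c, fe=False, rng=rng, cfg=cfg),
            )
            sample.append(feat)
            apo_features.append((feat, fam_idx))
            truth.add(feat.feature_id, "apo", family=fam_idx, formula=f.hill())
        if cfg.include_holo:
            holo_counts = f.as_dict()
            holo_counts["H"] -= 3
            holo_counts["Fe"] = 1
            holo_f = ElementalFormula(holo_counts)
            holo_obs = _noisy_mz(holo_ion, rng, cfg)
            feat = MS1Feature(
                feature_id=f"sid{fam_idx}_holo",
                mz=holo_obs,
                rt=rt_holo,
                area=total * (1.0 - cfg.apo_fraction),
                envelope=_ion_envelope(
                    holo_obs, n_c, fe=cfg.include_fe_peaks, rng=rng, cfg=cfg
                ),
            )
            sample.append(feat)
            truth.add(feat.feature_id, "holo", family=fam_idx, formula=holo_f.hill())

    # --- decoys -----------------------------------------------------------
    decoy_idx = 0

    def _rt() -> float:
        return float(rng.uniform(*cfg.rt_window))

    for _ in range(cfg.n_plain_decoys):
        decoy_idx += 1
        mz = _random_mz(rng, planted_mz)
        feat = MS1Feature(
            feature_id=f"decoy{decoy_idx}_plain",
            mz=mz,
            rt=_rt(),
            area=_noisy_area(2e6, rng, cfg),
            envelope=_ion_envelope(mz, int(mz / 20), fe=False, rng=rng, cfg=cfg),
        )
        sample.append(feat)
        truth.add(feat.feature_id, "decoy", formula=None)
    for _ in range(cfg.n_wrong_ratio_decoys):
        decoy_idx += 1
        mz = _random_mz(rng, planted_mz)
        feat = MS1Feature(
            feature_id=f"decoy{decoy_idx}_ratio",
            mz=mz,
            rt=_rt(),
            area=_noisy_area(2e6, rng, cfg),
            # correct 54Fe-56Fe spacing but a 0.5 abundance ratio
            envelope=_ion_envelope(
                mz, int(mz / 20), fe=False, rng=rng, cfg=cfg, a2_ratio=0.5
            ),
        )
        sample.append(feat)
        truth.add(feat.feature_id, "decoy", formula=None)
    for _ in range(cfg.n_cl_decoys):
        decoy_idx += 1
        mz = _random_mz(rng, planted_mz)
        feat = MS1Feature(
            feature_id=f"decoy{decoy_idx}_cl",
            mz=mz,
            rt=_rt(),
            area=_noisy_area(2e6, rng, cfg),
            # Cl-like: A+2 satellite at +1.99705 and ~32% relative intensity
            envelope=_ion_envelope(
                mz, int(mz / 20), fe=False, rng=rng, cfg=cfg,
                a2_spacing=1.99705, a2_ratio=0.32, a2_sign=+1,
            ),
        )
        sample.append(feat)
        truth.add(feat.feature_id, "decoy", formula=None)
    for _ in range(cfg.n_near_pair_decoys):
        decoy_idx += 1
        light = _random_mz(rng, planted_mz, lo=300.0, hi=700.0)
        heavy = light + FE_MINUS_3H + 0.05  # 50 mDa off the ferric shift
        rt = _rt()
        for tag, mz in (("a", light), ("b", heavy)):
            feat = MS1Feature(
                feature_id=f"decoy{decoy_idx}_pair{tag}",
                mz=mz,
                rt=rt + (0.3 if tag == "b" else 0.0),
                area=_noisy_area(2e6, rng, cfg),
                envelope=_ion_envelope(
                    mz, int(mz / 20), fe=False, rng=rng, cfg=cfg,
                    a2_ratio=0.5 if tag == "b" else None,
                ),
            )
            sample.append(feat)
            truth.add(feat.feature_id, "decoy", formula=None)

    # --- blank-shared and control-only features ---------------------------
    for i in range(cfg.n_blank_shared):
        mz = _random_mz(rng, planted_mz)
        rt = _rt()
        area = _noisy_area(5e6, rng, cfg)
        fid = f"blank{i + 1}"
        sample.append(MS1Feature(feature_id=fid, mz=mz, rt=rt, area=area,
                                 envelope=_ion_envelope(mz, int(mz / 20), fe=False,
                                                        rng=rng, cfg=cfg)))
        control.append(
            MS1Feature(
                feature_id=fid,
                mz=_noisy_mz(mz, rng, cfg),
                rt=rt + float(rng.normal(0.0, 0.02)),
                area=area * float(rng.uniform(0.5, 1.5)),
            )
        )
        truth.add(fid, "blank-shared", formula=None)
    for i in range(cfg.n_control_only):
        mz = _random_mz(rng, planted_mz)
        fid = f"ctrl{i + 1}"
        control.append(
            MS1Feature(feature_id=fid, mz=mz, rt=_rt(), area=_noisy_area(3e6, rng, cfg))
        )
        truth.add(fid, "control-only", formula=None)

    # --- MS/MS ------------------------------------------------------------
    for feat, fam_idx in apo_features:
        spectra.append(
            simulate_msms(
                precursor_mz=feat.mz,
                precursor_rt=feat.rt,
                spectrum_id=feat.feature_id,
                feature_id=feat.feature_id,
                rng=rng,
                noise_peaks=cfg.msms_noise_peaks,
                mz_noise_da=cfg.envelope_mz_noise_da,
                contaminant=cfg.contaminant,
            )
        )
    for feat in sample:
        if truth.entries[feat.feature_id]["role"] == "decoy" and feat.feature_id.endswith(
            ("_plain",)
        ):
            spectra.append(
                _decoy_msms(feat.mz, feat.rt, feat.feature_id, rng, cfg.contaminant)
            )

    result = ScenarioResult(
        sample=sample, control=control, spectra=spectra, truth=truth, config=cfg
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_feature_table(
            sample, outdir / "sample.csv", outdir / "sample_envelopes.csv"
        )
        write_feature_table(control, outdir / "control.csv")
        write_mgf(spectra, outdir / "spectra.mgf")
        truth.to_json(outdir / "truth.json")
        with open(outdir / "scenario.json", "w") as fh:
            json.dump(dataclasses.asdict(cfg), fh, indent=1, sort_keys=True)
    return result
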