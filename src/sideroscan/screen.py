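"""Three-criterion MS1 screen for iron-siderophore complexes.

Criteria, applied to a blank-filtered feature table:

1. the 54Fe/56Fe natural isotope pattern on the ferric-complex ion —
   a satellite peak 1.99533 Da below the monoisotopic peak at ~6.4%
   relative intensity;
2. the exact m/z difference of 52.91146 Da between the apo [M+H]+ and
   ferric-complex [M-3H+Fe+H]+ ions of the same neutral, at a shifted
   retention time;
3. (delegated to :mod:`sideroscan.annotate`) siderophore-specific MS/MS
   fragments and neutral losses.

The screen also decomposes the apo neutral mass into candidate elemental
formulas and annotates +-CH2 / +-O analog relations among the accepted
apo masses, the signature of a biosynthetic family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import chem
from .chem import (
    CH2_MASS,
    FE54_FE56_SPACING,
    FE_MINUS_3H,
    O_MASS,
    DecompositionCandidate,
    decompose_mass,
    neutral_from_protonated,
)
from .features import MS1Feature, blank_filter

__all__ = [
    "IronPatternHit",
    "ApoHoloPair",
    "FamilyLink",
    "SiderophoreCandidate",
    "ScreenConfig",
    "find_iron_pattern_hits",
    "pair_apo_holo",
    "screen_siderophores",
]


@dataclass(frozen=True)
class IronPatternHit:
    """A feature whose envelope shows the 54Fe satellite peak."""

    feature_id: str
    partner_mz: float
    spacing_error_mda: float
    abundance_ratio: float


@dataclass(frozen=True)
class ApoHoloPair:
    """Linked apo and ferric-complex features of one neutral."""

    apo_feature_id: str
    holo_feature_id: str
    mass_error_ppm: float
    rt_shift: float
    apo_fraction: float


@dataclass(frozen=True)
class FamilyLink:
    """A +-CH2 or +-O analog relation between two apo features."""

    apo_a: str
    apo_b: str
    kind: str  # "CH2" | "O"
    delta_mz: float


@dataclass
class SiderophoreCandidate:
    """A feature (pair) passing the MS1 criteria, with formula candidates."""

    apo_feature_id: Optional[str]
    holo_feature_id: str
    pair: Optional[ApoHoloPair]
    iron_hit: IronPatternHit
    apo_mz: float
    holo_mz: float
    apo_neutral_mass: float
    formulas: List[DecompositionCandidate] = field(default_factory=list)
    family_links: List[FamilyLink] = field(default_factory=list)
    msms_evidence: Optional[dict] = None


@dataclass
class ScreenConfig:
    """Tunable thresholds of the MS1 screen (defaults follow the method)."""

    blank_threshold_fraction: float = 1e-4  # 0.01% of sample area
    match_mz_tol_ppm: float = 5.0
    match_rt_tol: float = 0.2
    fe_spacing_tol_mda: float = 5.0
    fe_ratio_window: Tuple[float, float] = (0.02, 0.15)
    pair_mz_tol_ppm: float = 5.0
    pair_mz_tol_da: float = 0.003
    pair_rt_window: float = 2.0
    coelute_rt_tol: float = 0.05
    require_apo: bool = True  # both apo and holo required by default
    formula_tol_ppm: float = 5.0
    family_link_tol_da: float = 0.005
    decompose: bool = True


def _pair_tol_da(mz: float, tol_ppm: float, tol_da: float) -> float:
    """The matching rule 'dm/z = 5 p.p.m. or 0.003 Da', whichever is larger."""
    return max(tol_ppm * 1e-6 * mz, tol_da)


def find_iron_pattern_hits(
    features: Sequence[MS1Feature],
    spacing_tol_mda: float = 5.0,
    ratio_window: Tuple[float, float] = (0.02, 0.15),
    coelute_rt_tol: float = 0.05,
) -> List[IronPatternHit]:
    """Find features showing the 54Fe-56Fe isotope pattern.

    For each feature, look for a satellite peak ``FE54_FE56_SPACING``
    below the monoisotopic m/z whose relative intensity falls inside
    ``ratio_window`` (default 0.02-0.15, bracketing the natural 0.0637).
    The satellite is searched first in the feature's own isotopologue
    envelope; failing that, among co-eluting features in the table, using
    peak areas as intensities.  57Fe/58Fe satellites are ignored.
    """
    tol_da = spacing_tol_mda * 1e-3
    hits: List[IronPatternHit] = []
    by_id = {f.feature_id: f for f in features}
    for f in features:
        target = f.mz - FE54_FE56_SPACING
        hit: Optional[IronPatternHit] = None
        if f.envelope:
            # reference intensity: envelope entry at the feature m/z itself
            ref = min(
                (abs(m - f.mz), i) for m, i in f.envelope
            )
            ref_int = ref[1] if ref[0] <= tol_da else None
            if ref_int:
                best = None
                for m, i in f.envelope:
                    err = abs(m - target)
                    if err <= tol_da and (best is None or err < best[0]):
                        best = (err, m, i)
                if best is not None:
                    ratio = best[2] / ref_int
                    if ratio_window[0] <= ratio <= ratio_window[1]:
                        spacing = f.mz - best[1]
                        hit = IronPatternHit(
                            feature_id=f.feature_id,
                            partner_mz=best[1],
                            spacing_error_mda=(spacing - FE54_FE56_SPACING) * 1e3,
                            abundance_ratio=ratio,
                        )
        if hit is None and not f.envelope:
            # fall back to co-eluting features acting as the A-2 peak
            best = None
            for g in features:
                if g.feature_id == f.feature_id:
                    continue
                if abs(g.rt - f.rt) > coelute_rt_tol:
                    continue
                err = abs(g.mz - target)
                if err <= tol_da and (best is None or err < best[0]):
                    best = (err, g)
            if best is not None:
                g = best[1]
                ratio = g.area / f.area
                if ratio_window[0] <= ratio <= ratio_window[1]:
                    hit = IronPatternHit(
                        feature_id=f.feature_id,
                        partner_mz=g.mz,
                        spacing_error_mda=(f.mz - g.mz - FE54_FE56_SPACING) * 1e3,
                        abundance_ratio=ratio,
                    )
        if hit is not None:
            hits.append(hit)
    return hits


def pair_apo_holo(
    features: Sequence[MS1Feature],
    mz_tol_ppm: float = 5.0,
    mz_tol_da: float = 0.003,
    rt_window: float = 2.0,
) -> List[ApoHoloPair]:
    """All (apo, holo) feature pairs separated by the ferric-complex shift.

    Two features pair when the heavier m/z minus the lighter equals
    ``FE_MINUS_3H`` (52.91146 Da) within max(``mz_tol_ppm``,
    ``mz_tol_da``) evaluated at the holo m/z, and their retention times
    differ by at most ``rt_window`` minutes.  Pairs are returned sorted
    by absolute mass error, then ids; the reported ppm error is relative
    to the holo m/z.
    """
    out: List[ApoHoloPair] = []
    feats = sorted(features, key=lambda f: (f.mz, f.feature_id))
    for i, apo in enumerate(feats):
        for holo in feats[i + 1 :]:
            delta = holo.mz - apo.mz
            tol = _pair_tol_da(holo.mz, mz_tol_ppm, mz_tol_da)
            if delta > FE_MINUS_3H + tol:
                break
            if abs(delta - FE_MINUS_3H) > tol:
                continue
            if abs(holo.rt - apo.rt) > rt_window:
                continue
            out.append(
                ApoHoloPair(
                    apo_feature_id=apo.feature_id,
                    holo_feature_id=holo.feature_id,
                    mass_error_ppm=(delta - FE_MINUS_3H) / holo.mz * 1e6,
                    rt_shift=holo.rt - apo.rt,
                    apo_fraction=apo.area / (apo.area + holo.area),
                )
            )
    out.sort(
        key=lambda p: (abs(p.mass_error_ppm), p.apo_feature_id, p.holo_feature_id)
    )
    return out


def _annotate_family_links(
    candidates: List[SiderophoreCandidate], tol_da: float
) -> None:
    """Record +-CH2 (14.0157) and +-O (15.9949) relations among apo masses."""
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if a.apo_mz is None or b.apo_mz is None:
                continue
            delta = abs(b.apo_mz - a.apo_mz)
            kind = None
            if abs(delta - CH2_MASS) <= tol_da:
                kind = "CH2"
            elif abs(delta - O_MASS) <= tol_da:
                kind = "O"
            if kind is None:
                continue
            ida = a.apo_feature_id or a.holo_feature_id
            idb = b.apo_feature_id or b.holo_feature_id
            link = FamilyLink(apo_a=ida, apo_b=idb, kind=kind, delta_mz=delta)
            a.family_links.append(link)
            b.family_links.append(link)


def screen_siderophores(
    sample: Sequence[MS1Feature],
    control: Sequence[MS1Feature],
    config: Optional[ScreenConfig] = None,
) -> List[SiderophoreCandidate]:
    """Run the MS1 stages of the siderophore screen.

    Blank subtraction, then Fe-isotope-pattern detection, then apo/holo
    pairing; candidates must satisfy both MS1 criteria unless
    ``config.require_apo`` is off, in which case a ferric-complex feature
    with a clean Fe pattern qualifies alone.  Each feature enters at most
    one candidate (pairs are consumed in order of mass error).  Apo
    neutral masses are decomposed into elemental formulas, and +-CH2/+-O
    family relations among accepted candidates are annotated.

    The result is sorted by apo neutral mass and is invariant under
    permutation of the input feature order.
    """
    cfg = config or ScreenConfig()
    retained = blank_filter(
        sample,
        control,
        threshold_fraction=cfg.blank_threshold_fraction,
        mz_tol_ppm=cfg.match_mz_tol_ppm,
        rt_tol=cfg.match_rt_tol,
    )
    hits = find_iron_pattern_hits(
        retained,
        spacing_tol_mda=cfg.fe_spacing_tol_mda,
        ratio_window=cfg.fe_ratio_window,
        coelute_rt_tol=cfg.coelute_rt_tol,
    )
    hit_by_id = {h.feature_id: h for h in hits}
    pairs = pair_apo_holo(
        retained,
        mz_tol_ppm=cfg.pair_mz_tol_ppm,
        mz_tol_da=cfg.pair_mz_tol_da,
        rt_window=cfg.pair_rt_window,
    )
    mz_by_id = {f.feature_id: f.mz for f in retained}

    candidates: List[SiderophoreCandidate] = []
    used: set = set()
    for p in pairs:  # already sorted by |mass error|
        if p.apo_feature_id in used or p.holo_feature_id in used:
            continue
        iron = hit_by_id.get(p.holo_feature_id)
        if iron is None:
            continue
        apo_mz = mz_by_id[p.apo_feature_id]
        holo_mz = mz_by_id[p.holo_feature_id]
        used.add(p.apo_feature_id)
        used.add(p.holo_feature_id)
        candidates.append(
            SiderophoreCandidate(
                apo_feature_id=p.apo_feature_id,
                holo_feature_id=p.holo_feature_id,
                pair=p,
                iron_hit=iron,
                apo_mz=apo_mz,
                holo_mz=holo_mz,
                apo_neutral_mass=neutral_from_protonated(apo_mz),
            )
        )
    if not cfg.require_apo:
        for h in hits:
            if h.feature_id in used:
                continue
            holo_mz = mz_by_id[h.feature_id]
            apo_mz = holo_mz - FE_MINUS_3H
            used.add(h.feature_id)
            candidates.append(
                SiderophoreCandidate(
                    apo_feature_id=None,
                    holo_feature_id=h.feature_id,
                    pair=None,
                    iron_hit=h,
                    apo_mz=apo_mz,
                    holo_mz=holo_mz,
                    apo_neutral_mass=neutral_from_protonated(apo_mz),
                )
            )
    if cfg.decompose:
        for c in candidates:
            c.formulas = decompose_mass(
                c.apo_neutral_mass, tol_ppm=cfg.formula_tol_ppm
            )
    candidates.sort(key=lambda c: (c.apo_neutral_mass, c.holo_feature_id))
    _annotate_family_links(candidates, tol_da=cfg.family_link_tol_da)
    return candidates
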