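"""Hydroxamate building-block annotation of MS/MS spectra.

Tris-hydroxamate (ferrichrome-family) siderophores are peptides built
from N5-hydroxyornithine residues whose side-chain nitrogens carry
N-acyl groups (formyl, acetyl, hexanoyl, ...).  Collision-induced
dissociation releases characteristic monomer fragment ions and neutral
losses; matching a spectrum against a small library of these building
blocks is the third criterion of the siderophore screen.

Theoretical masses in the default library are computed from the block
formulas with :mod:`sideroscan.chem`; entries whose elemental formula is
inferred from the measured fragment mass alone (rather than an
established structure) carry ``provenance="inferred"``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .chem import ElementalFormula, monoisotopic_mass, parse_formula, protonated_mz
from .spectra import FragmentSpectrum

__all__ = [
    "BuildingBlock",
    "AnnotationHit",
    "EvidenceReport",
    "default_library",
    "load_library",
    "annotate_spectrum",
    "score_hydroxamate_evidence",
]


@dataclass(frozen=True)
class BuildingBlock:
    """A monomer whose fragment ion and/or neutral loss marks a siderophore.

    ``fragment_formula`` is the neutral formula B of the [B+H]+ fragment
    cation; ``loss_formula`` the formula of the neutral loss (often B or
    B+H2, depending on the hydrogen rearrangement of the cleavage).
    """

    name: str
    fragment_formula: Optional[ElementalFormula] = None
    loss_formula: Optional[ElementalFormula] = None
    provenance: str = "established"

    @property
    def fragment_mz(self) -> Optional[float]:
        if self.fragment_formula is None:
            return None
        return protonated_mz(monoisotopic_mass(self.fragment_formula))

    @property
    def loss_mass(self) -> Optional[float]:
        if self.loss_formula is None:
            return None
        return monoisotopic_mass(self.loss_formula)


@dataclass(frozen=True)
class AnnotationHit:
    """One matched fragment ion or neutral loss in a spectrum."""

    spectrum_id: str
    kind: str  # "fragment" | "neutral_loss"
    block: str
    observed: float  # matched peak m/z, or observed loss mass
    theoretical: float
    error_ppm: float


@dataclass
class EvidenceReport:
    """Summary of building-block evidence for one candidate spectrum."""

    spectrum_id: str
    n_hits: int
    blocks_hit: List[str]
    hydroxamate_consistent: bool
    unexplained_major_peaks: List[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "spectrum_id": self.spectrum_id,
            "n_hits": self.n_hits,
            "blocks_hit": list(self.blocks_hit),
            "hydroxamate_consistent": self.hydroxamate_consistent,
            "unexplained_major_peaks": list(self.unexplained_major_peaks),
        }


def default_library() -> List[BuildingBlock]:
    """Hydroxamate building blocks of ferrichrome-type siderophores.

    Fragment/loss masses (theory vs measured, Da):

    ========================  ==========  ========  ========
    block                     quantity    theory    measured
    ========================  ==========  ========  ========
    N5-hydroxyornithine       [B+H]+      131.0815  131.0816
    (C5H10N2O2, inferred)     loss        130.0742  130.0731
    N5-formyl-N5-hydroxy-     [B+H]+      157.0608  157.0609
    ornithine (C6H8N2O3,      loss        158.0691  158.0686
    inferred; loss C6H10N2O3)
    hexanoyl unit C6H10O2     [B+H]+      115.0754  115.0759
                              loss        114.0681  114.0681
    dehydrated C4H7NO unit    [B+H]+       86.0600   86.0601
    ========================  ==========  ========  ========

    All agree with the measured values within the matching tolerance
    max(5 ppm, 0.003 Da).
    """
    return [
        BuildingBlock(
            name="N5-hydroxyornithine",
            fragment_formula=parse_formula("C5H10N2O2"),
            loss_formula=parse_formula("C5H10N2O2"),
            provenance="inferred",
        ),
        BuildingBlock(
            name="N5-formyl-N5-hydroxyornithine",
            fragment_formula=parse_formula("C6H8N2O3"),
            loss_formula=parse_formula("C6H10N2O3"),
            provenance="inferred",
        ),
        BuildingBlock(
            name="hexanoyl-C6H10O2",
            fragment_formula=parse_formula("C6H10O2"),
            loss_formula=parse_formula("C6H10O2"),
            provenance="established",
        ),
        BuildingBlock(
            name="C4H7NO",
            fragment_formula=parse_formula("C4H7NO"),
            loss_formula=None,
            provenance="established",
        ),
    ]


def load_library(path: str | Path) -> List[BuildingBlock]:
    """Read a building-block library from CSV.

    Columns: ``name, fragment_formula, loss_formula, provenance`` (the
    formula columns may be empty).
    """
    blocks: List[BuildingBlock] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            frag = row.get("fragment_formula", "").strip()
            loss = row.get("loss_formula", "").strip()
            blocks.append(
                BuildingBlock(
                    name=row["name"].strip(),
                    fragment_formula=parse_formula(frag) if frag else None,
                    loss_formula=parse_formula(loss) if loss else None,
                    provenance=(row.get("provenance") or "established").strip(),
                )
            )
    return blocks


def _tol_da(mz: float, tol_ppm: float, tol_da: float) -> float:
    return max(tol_ppm * 1e-6 * mz, tol_da)


def annotate_spectrum(
    s: FragmentSpectrum,
    library: Optional[Sequence[BuildingBlock]] = None,
    tol_ppm: float = 5.0,
    tol_da: float = 0.003,
) -> List[AnnotationHit]:
    """Match every peak and neutral loss against the block library.

    Fragment matches compare peak m/z with the block's [B+H]+ m/z;
    neutral-loss matches compare ``precursor_mz - peak m/z`` with the
    block's loss mass.  The tolerance is max(``tol_ppm``, ``tol_da``) at
    the theoretical value.  Every match is reported with its signed ppm
    error.
    """
    lib = default_library() if library is None else list(library)
    hits: List[AnnotationHit] = []
    for block in lib:
        fmz = block.fragment_mz
        if fmz is not None:
            tol = _tol_da(fmz, tol_ppm, tol_da)
            for mz in s.mz[np.abs(s.mz - fmz) <= tol]:
                hits.append(
                    AnnotationHit(
                        spectrum_id=s.spectrum_id,
                        kind="fragment",
                        block=block.name,
                        observed=float(mz),
                        theoretical=fmz,
                        error_ppm=(float(mz) - fmz) / fmz * 1e6,
                    )
                )
        lmass = block.loss_mass
        if lmass is not None and s.precursor_mz > 0:
            losses = s.precursor_mz - s.mz
            tol = _tol_da(lmass, tol_ppm, tol_da)
            for loss in losses[np.abs(losses - lmass) <= tol]:
                hits.append(
                    AnnotationHit(
                        spectrum_id=s.spectrum_id,
                        kind="neutral_loss",
                        block=block.name,
                        observed=float(loss),
                        theoretical=lmass,
                        error_ppm=(float(loss) - lmass) / lmass * 1e6,
                    )
                )
    return hits


def score_hydroxamate_evidence(
    spectrum: FragmentSpectrum,
    hits: Sequence[AnnotationHit],
    min_distinct_blocks: int = 2,
    major_peak_rel: float = 0.10,
) -> EvidenceReport:
    """Summarise block evidence and flag hydroxamate-consistent spectra.

    A candidate is flagged consistent when hits cover at least
    ``min_distinct_blocks`` distinct building blocks.  Peaks above
    ``major_peak_rel`` of the base peak with no hit are listed as
    unexplained.
    """
    blocks = sorted({h.block for h in hits})
    matched_mz = {round(h.observed, 4) for h in hits if h.kind == "fragment"}
    loss_matched_mz = {
        round(spectrum.precursor_mz - h.observed, 4)
        for h in hits
        if h.kind == "neutral_loss"
    }
    base = spectrum.base_peak_intensity
    unexplained = [
        float(mz)
        for mz, inten in zip(spectrum.mz, spectrum.intensity)
        if inten >= major_peak_rel * base
        and round(float(mz), 4) not in matched_mz
        and round(float(mz), 4) not in loss_matched_mz
    ]
    return EvidenceReport(
        spectrum_id=spectrum.spectrum_id,
        n_hits=len(hits),
        blocks_hit=blocks,
        hydroxamate_consistent=len(blocks) >= min_distinct_blocks,
        unexplained_major_peaks=unexplained,
    )
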