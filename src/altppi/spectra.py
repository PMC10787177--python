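"""Spectral correlation between experimental and synthetic-peptide spectra.

Fragment peaks of two MS/MS spectra are matched greedily by m/z within a
tolerance (default 0.02 Da, appropriate for high-resolution Orbitrap data);
unmatched peaks contribute a zero intensity to the partner vector. The
similarity statistic is the Pearson correlation of the square-root-transformed
matched intensity vectors (variance-stabilized, as in the Toprak-style
spectral contrast family), with the normalized spectral contrast angle
reported as a secondary statistic. A coefficient above 0.6 flags the pair as
a confirmed fragmentation match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from pyteomics import mgf as _mgf

DEFAULT_TOLERANCE_DA = 0.02
CORRELATION_CUTOFF = 0.6


@dataclass
class PeakList:
    """A centroided MS/MS spectrum: (m/z, intensity) peaks plus precursor info."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    charge: Optional[int] = None
    peptide: Optional[str] = None
    title: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size != self.intensity.size:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size and (np.any(self.mz <= 0) or np.any(~np.isfinite(self.intensity))):
            raise ValueError("peaks must have positive m/z and finite intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)


def read_mgf(path: str | Path) -> list[PeakList]:
    spectra = []
    with _mgf.read(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            charge = params.get("charge")
            spectra.append(
                PeakList(
                    mz=spec["m/z array"],
                    intensity=spec["intensity array"],
                    precursor_mz=float(params["pepmass"][0]) if "pepmass" in params else None,
                    charge=int(charge[0]) if charge else None,
                    peptide=params.get("seq"),
                    title=params.get("title", ""),
                )
            )
    return spectra


def write_mgf(spectra: list[PeakList], path: str | Path) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.title}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.charge is not None:
            params["charge"] = s.charge
        if s.peptide:
            params["seq"] = s.peptide
        entries.append({"m/z array": s.mz, "intensity array": s.intensity, "params": params})
    _mgf.write(entries, str(path), file_mode="w")


def match_peaks(a: PeakList, b: PeakList, tol_da: float = DEFAULT_TOLERANCE_DA) -> list[tuple[float, float]]:
    """Greedy nearest-neighbor peak matching within ``tol_da``.

    Each peak is used at most once; candidate matches are taken in order of
    increasing m/z difference (ties toward lower m/z); unmatched peaks are
    paired with intensity 0.
    """
    if tol_da <= 0:
        raise ValueError("tolerance must be positive")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty peak list")
    candidates = []
    for i, mza in enumerate(a.mz):
        for j, mzb in enumerate(b.mz):
            delta = abs(mza - mzb)
            if delta <= tol_da:
                candidates.append((delta, min(mza, mzb), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[float, float]] = []
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((float(a.intensity[i]), float(b.intensity[j])))
    for i in range(len(a)):
        if i not in used_a:
            pairs.append((float(a.intensity[i]), 0.0))
    for j in range(len(b)):
        if j not in used_b:
            pairs.append((0.0, float(b.intensity[j])))
    return pairs


@dataclass
class SpectralComparison:
    coefficient: float
    contrast_angle: float
    n_matched: int
    above_cutoff: bool = field(init=False)

    def __post_init__(self) -> None:
        self.above_cutoff = self.coefficient > CORRELATION_CUTOFF


def spectral_correlation(
    a: PeakList, b: PeakList, tol_da: float = DEFAULT_TOLERANCE_DA
) -> SpectralComparison:
    """Pearson correlation of sqrt-transformed matched intensities.

    Raises on zero-variance intensity vectors (the coefficient is undefined).
    Also reports the normalized spectral contrast angle
    ``1 - 2 * arccos(cos_theta) / pi`` of the sqrt-transformed vectors.
    """
    pairs = match_peaks(a, b, tol_da)
    x = np.sqrt([p[0] for p in pairs])
    y = np.sqrt([p[1] for p in pairs])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance intensity vector; correlation undefined")
    coeff = float(np.corrcoef(x, y)[0, 1])
    cos_theta = float(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)))
    angle = 1.0 - 2.0 * np.arccos(np.clip(cos_theta, -1.0, 1.0)) / np.pi
    n_matched = sum(1 for px, py in pairs if px > 0 and py > 0)
    return SpectralComparison(coeff, float(angle), n_matched)
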