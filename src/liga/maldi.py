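"""MALDI-TOF quantification of phage coat-protein (pVIII) modification.

A phage preparation gives a spectrum with peaks for unmodified pVIII, the
alkyne-functionalised DBCO-pVIII, and the glycoconjugate product(s).  The
fraction of pVIII carrying a modification, times the ~2700 available copies
per virion, is the mean glycan display density.  Two analysis artifacts are
handled explicitly:

* "ghost" satellites — in-source loss of sialic acid (-291.0954 Da per
  Neu5Ac) creates peaks at the parent mass minus k sialic residues that do
  not correspond to real species; their area is reassigned to the parent.
* sialylation suppresses ionization, so density is best estimated at the
  DBCO stage (pVIII vs DBCO-pVIII), before sialylated conjugates appear.

Peak areas come from least-squares Gaussian fits in windows around the
predicted species masses; overlapping windows are fitted jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit.models import ConstantModel, GaussianModel

from .dictionary import GlycanStructure

__all__ = [
    "Spectrum",
    "SpeciesModel",
    "PeakFit",
    "DensityEstimate",
    "ConversionTimecourse",
    "read_spectrum",
    "preprocess",
    "predict_species_masses",
    "fit_peaks",
    "quantify_species",
    "estimate_density",
    "conversion_timecourse",
    "RESIDUE_MASSES",
    "NEU5AC_RESIDUE",
    "DEFAULT_PVIII_MASS",
    "DEFAULT_DBCO_ADDUCT",
    "DEFAULT_LINKER_MASS",
]

#: Monoisotopic residue masses (Da) of the monosaccharide classes.
RESIDUE_MASSES = {
    "Hex": 162.0528,
    "HexNAc": 203.0794,
    "Neu5Ac": 291.0954,
    "dHex": 146.0579,
}
NEU5AC_RESIDUE = RESIDUE_MASSES["Neu5Ac"]

# Configuration constants for the M13 system: average mass of mature wild-type
# pVIII and the masses added by the DBCO handle and the triazole linker.
# Exact values depend on the conjugation chemistry batch; override per run.
DEFAULT_PVIII_MASS = 5238.4
DEFAULT_DBCO_ADDUCT = 427.2
DEFAULT_LINKER_MASS = 129.1


@dataclass
class Spectrum:
    """A MALDI trace: ascending m/z (Da) and non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""
    time: float | None = None  # hours, for timecourses

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")

    def slice(self, lo: float, hi: float) -> "Spectrum":
        m = (self.mz >= lo) & (self.mz <= hi)
        return Spectrum(self.mz[m], self.intensity[m], self.label, self.time)


def read_spectrum(path: str | Path, label: str = "") -> Spectrum:
    """Read a two-column text spectrum (whitespace/tab delimited, '#' comments)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        rows.append((float(parts[0]), float(parts[1])))
    arr = np.array(rows)
    order = np.argsort(arr[:, 0])
    return Spectrum(arr[order, 0], arr[order, 1], label=label or Path(path).stem)


@dataclass(frozen=True)
class SpeciesModel:
    """One expected species: a named mass, its class and sialic-acid count."""

    name: str
    expected_mass: float
    species_class: str = "conjugate"  # pviii | dbco_pviii | conjugate
    sialic_count: int = 0
    ghost_parent: str | None = None

    def __post_init__(self) -> None:
        if self.expected_mass <= 0:
            raise ValueError("expected_mass must be positive")


@dataclass
class PeakFit:
    """Gaussian fit of one species: area = amplitude * sigma * sqrt(2 pi)."""

    species: SpeciesModel
    center: float
    sigma: float
    amplitude: float
    area: float
    residual: float

    def __post_init__(self) -> None:
        if self.area > 0 and self.sigma <= 0:
            raise ValueError("sigma must be positive for a fitted peak")


@dataclass
class DensityEstimate:
    modified_fraction: float
    mean_density: int
    available_pviii: int = 2700


@dataclass
class ConversionTimecourse:
    """Species composition (%) over reaction time; rows sum to 100."""

    table: pd.DataFrame  # index: time (h); columns: species names; values: %

    def __post_init__(self) -> None:
        sums = self.table.sum(axis=1).to_numpy()
        if np.any(np.abs(sums - 100.0) > 0.1):
            raise ValueError("species percentages must sum to 100 per timepoint")


# ---------------------------------------------------------------------------
# preprocessing

def _rolling(arr: np.ndarray, window: int, fn) -> np.ndarray:
    """Edge-padded rolling statistic with an odd integer window."""
    w = max(1, int(window))
    if w % 2 == 0:
        w += 1
    half = w // 2
    padded = np.pad(arr, half, mode="edge")
    strided = np.lib.stride_tricks.sliding_window_view(padded, w)
    return fn(strided, axis=1)


def preprocess(
    spec: Spectrum, baseline_window: float = 200.0, smooth_window: int = 5
) -> Spectrum:
    """Baseline-subtract and smooth a spectrum (deterministic).

    Baseline = rolling minimum followed by a rolling mean of the same window
    (``baseline_window`` in Da, converted via the median m/z spacing);
    subtracted and clipped at zero, then moving-average smoothed over
    ``smooth_window`` points.
    """
    if baseline_window <= 0 or smooth_window <= 0:
        raise ValueError("windows must be positive")
    span = spec.mz[-1] - spec.mz[0]
    if baseline_window > span:
        raise ValueError(
            f"baseline window {baseline_window} Da exceeds spectrum span {span:.1f} Da"
        )
    spacing = float(np.median(np.diff(spec.mz)))
    w = max(3, int(round(baseline_window / spacing)))
    baseline = _rolling(_rolling(spec.intensity, w, np.min), w, np.mean)
    cleaned = np.clip(spec.intensity - baseline, 0.0, None)
    smoothed = _rolling(cleaned, smooth_window, np.mean)
    return Spectrum(spec.mz.copy(), smoothed, spec.label, spec.time)


# ---------------------------------------------------------------------------
# species prediction

def predict_species_masses(
    glycan: GlycanStructure | None,
    *,
    pviii_base: float = DEFAULT_PVIII_MASS,
    dbco_adduct: float = DEFAULT_DBCO_ADDUCT,
    linker_mass: float = DEFAULT_LINKER_MASS,
    max_ghosts: int | None = None,
) -> list[SpeciesModel]:
    """Predict the species ladder for a conjugation experiment.

    Emits unmodified pVIII, DBCO-pVIII, and (if a glycan is given) the
    conjugate at ``base + DBCO + linker + sum(residue masses)``; every
    species carrying ``sialic_count >= 1`` gets ghost companions at
    -291.0954*k Da flagged with its name.
    """
    species = [
        SpeciesModel("pVIII", pviii_base, "pviii"),
        SpeciesModel("DBCO-pVIII", pviii_base + dbco_adduct, "dbco_pviii"),
    ]
    if glycan is not None:
        unknown = set(glycan.composition) - set(RESIDUE_MASSES)
        if unknown:
            raise KeyError(f"unknown monosaccharide class(es): {sorted(unknown)}")
        residue_sum = sum(
            RESIDUE_MASSES[m] * n for m, n in glycan.composition.items()
        )
        sia = int(glycan.composition.get("Neu5Ac", 0))
        conj_mass = pviii_base + dbco_adduct + linker_mass + residue_sum
        conj = SpeciesModel(
            f"pVIII+{glycan.structure_id}", conj_mass, "conjugate", sialic_count=sia
        )
        species.append(conj)
    out = []
    for sp in species:
        out.append(sp)
        n_ghost = sp.sialic_count if max_ghosts is None else min(
            sp.sialic_count, max_ghosts
        )
        for k in range(1, n_ghost + 1):
            out.append(
                SpeciesModel(
                    f"{sp.name}-{k}Neu5Ac(ghost)",
                    sp.expected_mass - k * NEU5AC_RESIDUE,
                    sp.species_class,
                    sialic_count=sp.sialic_count - k,
                    ghost_parent=sp.name,
                )
            )
    return out


# ---------------------------------------------------------------------------
# peak fitting

def _noise_sigma(intensity: np.ndarray) -> float:
    """High-frequency noise estimate: std of first differences / sqrt(2)."""
    d = np.diff(intensity)
    if d.size == 0:
        return 0.0
    return float(np.std(d) / np.sqrt(2.0))


def _merge_windows(windows: list[tuple[float, float, int]]):
    """Merge overlapping (lo, hi, species-index) windows into joint groups."""
    windows = sorted(windows)
    groups: list[list] = []
    for lo, hi, idx in windows:
        if groups and lo <= groups[-1][1]:
            groups[-1][1] = max(groups[-1][1], hi)
            groups[-1][2].append(idx)
        else:
            groups.append([lo, hi, [idx]])
    return groups


def fit_peaks(
    spec: Spectrum,
    species: list[SpeciesModel],
    tolerance: float = 15.0,
    *,
    noise_multiple: float = 8.0,
    sigma_bounds: tuple[float, float] = (0.5, 20.0),
) -> list[PeakFit]:
    """Fit a Gaussian per species in windows expected_mass +/- tolerance.

    Overlapping windows are fitted jointly as a sum of Gaussians.  A species
    whose local maximum intensity is below ``noise_multiple`` times the
    high-frequency noise level gets area 0 (no peak).  Gaussian sigma is
    free within ``sigma_bounds`` (Da).
    """
    if not np.isfinite(spec.intensity).all():
        raise ValueError("non-finite intensities")
    for sp in species:
        if not (spec.mz[0] <= sp.expected_mass <= spec.mz[-1]):
            raise ValueError(
                f"species {sp.name!r} mass {sp.expected_mass} outside "
                f"spectrum range [{spec.mz[0]}, {spec.mz[-1]}]"
            )
    threshold = noise_multiple * _noise_sigma(spec.intensity)
    windows = [
        (sp.expected_mass - tolerance, sp.expected_mass + tolerance, i)
        for i, sp in enumerate(species)
    ]
    fits: dict[int, PeakFit] = {}
    for lo, hi, idxs in _merge_windows(windows):
        sub = spec.slice(lo, hi)
        active = []
        for i in idxs:
            sp = species[i]
            local = sub.slice(sp.expected_mass - tolerance,
                              sp.expected_mass + tolerance)
            # height above the local pedestal, so a residual baseline offset
            # does not count as signal
            height = (local.intensity.max() - np.median(local.intensity)
                      if local.intensity.size else 0.0)
            if local.intensity.size == 0 or height <= threshold:
                fits[i] = PeakFit(sp, sp.expected_mass, 0.0, 0.0, 0.0, 0.0)
            else:
                active.append(i)
        if not active:
            continue
        pedestal = float(np.median(sub.intensity))
        model = ConstantModel(prefix="bg_")
        params = model.make_params(c=dict(value=pedestal, min=0.0))
        for i in active:
            sp = species[i]
            g = GaussianModel(prefix=f"g{i}_")
            local = sub.slice(sp.expected_mass - tolerance,
                              sp.expected_mass + tolerance)
            amp0 = max(float(local.intensity.max()) - pedestal, threshold, 1e-12)
            sigma0 = float(np.clip(3.0, *sigma_bounds))
            p = g.make_params(
                center=dict(value=sp.expected_mass,
                            min=sp.expected_mass - tolerance,
                            max=sp.expected_mass + tolerance),
                sigma=dict(value=sigma0, min=sigma_bounds[0], max=sigma_bounds[1]),
                amplitude=dict(value=amp0 * sigma0 * np.sqrt(2 * np.pi), min=0.0),
            )
            model = model + g
            params.update(p)
        result = model.fit(sub.intensity, params, x=sub.mz)
        resid = float(np.sqrt(np.mean(result.residual**2)))
        for i in active:
            sp = species[i]
            pref = f"g{i}_"
            area = float(result.params[pref + "amplitude"].value)
            fits[i] = PeakFit(
                species=sp,
                center=float(result.params[pref + "center"].value),
                sigma=float(result.params[pref + "sigma"].value),
                amplitude=area / (
                    float(result.params[pref + "sigma"].value) * np.sqrt(2 * np.pi)
                ),
                area=max(area, 0.0),
                residual=resid,
            )
    return [fits[i] for i in range(len(species))]


# ---------------------------------------------------------------------------
# quantification

def quantify_species(
    fits: list[PeakFit], ghost_correct: bool = True
) -> dict[str, float]:
    """Species fractions from fitted areas, summing to 1.

    With ``ghost_correct``, each ghost satellite's area is reassigned to its
    parent species before normalising, so correction changes attribution
    but never the total area.
    """
    areas: dict[str, float] = {}
    for f in fits:
        name = f.species.name
        if ghost_correct and f.species.ghost_parent is not None:
            name = f.species.ghost_parent
        areas[name] = areas.get(name, 0.0) + f.area
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("all fitted areas are zero; nothing to quantify")
    return {k: v / total for k, v in areas.items()}


def estimate_density(
    fractions: dict[str, float],
    species: list[SpeciesModel] | None = None,
    available: int = 2700,
) -> DensityEstimate:
    """Mean glycans/virion from the modified pVIII fraction.

    Species named 'pVIII' (class ``pviii``) count as unmodified; everything
    else (DBCO-pVIII, conjugates) counts as modified.  Best applied at the
    DBCO stage, before sialylation biases ionization.
    """
    vals = np.array(list(fractions.values()), float)
    if (vals < 0).any():
        raise ValueError("negative fraction")
    if abs(vals.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    classes = {sp.name: sp.species_class for sp in species or []}
    modified = sum(
        frac
        for name, frac in fractions.items()
        if classes.get(name, "pviii" if name == "pVIII" else "conjugate") != "pviii"
    )
    return DensityEstimate(
        modified_fraction=float(modified),
        mean_density=int(round(modified * available)),
        available_pviii=available,
    )


def conversion_timecourse(
    spectra: list[tuple[float, Spectrum]],
    species: list[SpeciesModel],
    tolerance: float = 15.0,
    *,
    ghost_correct: bool = True,
    **fit_kwargs,
) -> ConversionTimecourse:
    """Track species composition (%) across an enzymatic reaction timecourse."""
    if len(spectra) < 2:
        raise ValueError("need at least two timepoints")
    times = [t for t, _ in spectra]
    if np.any(np.diff(times) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    rows = {}
    for t, spec in spectra:
        fits = fit_peaks(spec, species, tolerance, **fit_kwargs)
        fr = quantify_species(fits, ghost_correct=ghost_correct)
        rows[t] = {k: 100.0 * v for k, v in fr.items()}
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    table.index.name = "time_h"
    return ConversionTimecourse(table=table)
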