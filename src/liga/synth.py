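"""Seeded generators for every input of the pipeline, with ground truth.

Each generator is a deterministic function of its mandatory seed and writes
(or returns) a truth sidecar sufficient to score any downstream stage:

* counts — negative-binomial barcode counts with log-normal baselines
  (phage mixtures are never uniform even when mixed by titer), per-sample
  library-size factors, and known fold changes; invariant blank clones have
  fold change 1 by construction;
* FASTQ — 2x75 bp paired reads embedding flank+barcode regions with a
  per-base substitution error rate;
* spectra — Gaussian species peaks with baseline drift, noise, sialic-acid
  ghost satellites and sialylation ionization suppression;
* titrations — 1:1 binding curves with multiplicative noise on R.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import TitrationSeries, fraction_bound
from .demux import AmpliconDesign, CountMatrix, SdbRegion
from .dictionary import LigaDictionary
from .maldi import NEU5AC_RESIDUE, SpeciesModel, Spectrum

__all__ = [
    "SimTruth",
    "default_design",
    "simulate_counts",
    "simulate_fastq",
    "simulate_spectrum",
    "simulate_titration",
]


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, serializable next to the data."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "seed": self.seed,
            "params": self.params,
            "tables": {
                k: df.to_dict(orient="index") for k, df in self.tables.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str) + "\n")


def default_design(sample_index_map: dict | None = None) -> AmpliconDesign:
    """Synthetic 2x75 amplicon layout: two 15-nt SDBs with 8-nt flanks."""
    return AmpliconDesign(
        regions=(
            SdbRegion("ACGGTCTG", "TGACCAGT", 15),
            SdbRegion("CCATAGTC", "GTTCAGGA", 15),
        ),
        read_length=75,
        sample_index_map=sample_index_map,
    )


# ---------------------------------------------------------------------------
# counts

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB with var = mu + dispersion * mu^2 (Poisson when dispersion = 0)."""
    mean = np.asarray(mean, float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    dictionary: LigaDictionary,
    n_test: int = 3,
    n_control: int = 3,
    *,
    baseline_log_mean: float = np.log(300.0),
    baseline_log_sd: float = 1.0,
    fc_map: dict[str, float] | None = None,
    dispersion: float = 0.1,
    libsize_range: tuple[float, float] = (0.5, 2.0),
    seed: int,
) -> tuple[CountMatrix, SimTruth]:
    """NB count matrix over the dictionary with known per-entry fold changes.

    ``fc_map`` maps entry_id -> true fold change in the test group (default
    1 everywhere); invariant (blank) clones always get fold change 1.
    Per-sample library-size factors are drawn log-uniformly from
    ``libsize_range``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    entry_ids = [e.entry_id for e in dictionary.entries]
    fc = pd.Series(1.0, index=entry_ids)
    for eid, v in (fc_map or {}).items():
        fc[eid] = v
    for e in dictionary.invariant_entries:
        fc[e.entry_id] = 1.0
    baseline = pd.Series(
        rng.lognormal(baseline_log_mean, baseline_log_sd, len(entry_ids)),
        index=entry_ids,
    )
    samples = [f"T{i + 1}" for i in range(n_test)] + [
        f"C{i + 1}" for i in range(n_control)
    ]
    lib = pd.Series(
        np.exp(rng.uniform(np.log(libsize_range[0]), np.log(libsize_range[1]),
                           len(samples))),
        index=samples,
    )
    counts = {}
    for j, s in enumerate(samples):
        group_fc = fc.to_numpy() if j < n_test else 1.0
        mu = baseline.to_numpy() * group_fc * lib[s]
        counts[s] = _nb_draw(rng, mu, dispersion)
    df = pd.DataFrame(counts, index=entry_ids)
    truth = SimTruth(
        kind="counts",
        seed=seed,
        params={
            "n_test": n_test,
            "n_control": n_control,
            "dispersion": dispersion,
            "baseline_log_mean": baseline_log_mean,
            "baseline_log_sd": baseline_log_sd,
        },
        tables={
            "entries": pd.DataFrame(
                {"true_fc": fc, "true_baseline": baseline}
            ),
            "samples": pd.DataFrame({"libsize_factor": lib}),
        },
    )
    return CountMatrix(counts=df, totals=pd.DataFrame(
        {"total": df.sum(), "mapped": df.sum(), "unmapped": 0,
         "unassigned_index": 0}
    )), truth


# ---------------------------------------------------------------------------
# FASTQ

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    arr = np.array(list(seq))
    hits = np.where(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return "".join(arr)


def simulate_fastq(
    dictionary: LigaDictionary,
    design: AmpliconDesign,
    reads_per_sample: dict[str, dict[str, int]],
    out_dir: str | Path,
    *,
    error_rate: float = 0.0,
    seed: int,
) -> tuple[dict[str, tuple[Path, Path]], SimTruth]:
    """Write paired FASTQ files embedding flanked barcodes, plus truth counts.

    ``reads_per_sample`` maps sample -> {entry_id: n_reads}.  The forward
    read carries ``flank1 + SDB1 + flank1' ... flank2 + SDB2 + flank2'``
    padded with random bases to the design read length; the mate is random
    filler (the barcode regions live on the forward read).  Substitution
    errors are applied per base at ``error_rate``.
    """
    if not 0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entry_by_id = {e.entry_id: e for e in dictionary.entries}
    paths: dict[str, tuple[Path, Path]] = {}
    truth_rows = {}
    for sample, alloc in reads_per_sample.items():
        r1_path = out_dir / f"{sample}_R1.fastq"
        r2_path = out_dir / f"{sample}_R2.fastq"
        records = []
        for eid, n in alloc.items():
            for _ in range(int(n)):
                records.append(eid)
        order = rng.permutation(len(records))
        with r1_path.open("w") as f1, r2_path.open("w") as f2:
            for ridx, k in enumerate(order):
                eid = records[k]
                e = entry_by_id[eid]
                core = "".join(
                    reg.upstream_flank + sdb + reg.downstream_flank
                    for reg, sdb in zip(design.regions, e.sdb_sequences)
                )
                pad = design.read_length - len(core)
                if pad < 0:
                    raise ValueError("amplicon core longer than read length")
                fwd = core + _random_seq(rng, pad)
                fwd = _mutate(rng, fwd, error_rate)
                rev = _mutate(rng, _random_seq(rng, design.read_length),
                              error_rate)
                q = "I" * design.read_length
                name = f"{sample}.{ridx} entry={eid}"
                f1.write(f"@{name}/1\n{fwd}\n+\n{q}\n")
                f2.write(f"@{name}/2\n{rev}\n+\n{q}\n")
        paths[sample] = (r1_path, r2_path)
        truth_rows[sample] = dict(alloc)
    truth = SimTruth(
        kind="fastq",
        seed=seed,
        params={"error_rate": error_rate,
                "read_length": design.read_length},
        tables={"counts": pd.DataFrame(truth_rows).fillna(0).astype(int)},
    )
    return paths, truth


# ---------------------------------------------------------------------------
# spectra

def simulate_spectrum(
    fractions: dict[str, float],
    species: list[SpeciesModel],
    *,
    sigma: float = 3.0,
    total_area: float = 1e5,
    noise_sd: float = 0.0,
    baseline_slope: float = 0.0,
    baseline_offset: float = 0.0,
    ghost_fraction: float = 0.0,
    sialyl_suppression: float = 1.0,
    mz_range: tuple[float, float] | None = None,
    n_points: int = 4000,
    seed: int,
) -> tuple[Spectrum, SimTruth]:
    """Sum-of-Gaussians spectrum with the analysis artifacts of real MALDI.

    Species areas are proportional to ``fractions`` times the ionization
    suppression factor (applied once per sialic-acid residue); each species
    with ``sialic_count >= 1`` sheds ``ghost_fraction`` of its area into a
    satellite at -291.0954 Da.  Linear baseline drift and Gaussian noise
    are added on top.
    """
    vals = np.array(list(fractions.values()), float)
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    by_name = {sp.name: sp for sp in species}
    masses, areas = [], []
    true_areas: dict[str, float] = {}
    for name, frac in fractions.items():
        sp = by_name[name]
        area = total_area * frac * (sialyl_suppression ** sp.sialic_count)
        ghost = area * ghost_fraction if sp.sialic_count >= 1 else 0.0
        masses.append(sp.expected_mass)
        areas.append(area - ghost)
        true_areas[name] = area
        if ghost > 0:
            masses.append(sp.expected_mass - NEU5AC_RESIDUE)
            areas.append(ghost)
    if mz_range is None:
        lo = min(masses) - 40 * sigma
        hi = max(masses) + 40 * sigma
    else:
        lo, hi = mz_range
    mz = np.linspace(lo, hi, n_points)
    intensity = np.zeros_like(mz)
    for m, a in zip(masses, areas):
        intensity += a / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((mz - m) / sigma) ** 2
        )
    intensity += baseline_offset + baseline_slope * (mz - mz[0])
    if noise_sd > 0:
        intensity += rng.normal(0.0, noise_sd, mz.size)
    truth = SimTruth(
        kind="spectrum",
        seed=seed,
        params={
            "fractions": dict(fractions),
            "sigma": sigma,
            "noise_sd": noise_sd,
            "ghost_fraction": ghost_fraction,
            "sialyl_suppression": sialyl_suppression,
        },
        tables={"areas": pd.DataFrame({"true_area": true_areas})},
    )
    return Spectrum(mz, intensity), truth


# ---------------------------------------------------------------------------
# titrations

def simulate_titration(
    p0: float,
    kd: float,
    l0_grid,
    *,
    noise_sd: float = 0.0,
    seed: int,
) -> tuple[TitrationSeries, SimTruth]:
    """Titration series from the 1:1 binding curve, multiplicative noise on R."""
    rng = np.random.default_rng(seed)
    l0 = np.asarray(l0_grid, float)
    f = np.asarray(fraction_bound(p0, l0, kd), float)
    clipped = f >= 1.0 - 1e-12
    f = np.where(clipped, 1.0 - 1e-12, f)
    r = f / (1.0 - f)
    if noise_sd > 0:
        r = r * np.exp(rng.normal(0.0, noise_sd, r.size))
    series = TitrationSeries(p0=p0, l0=l0, r=r)
    truth = SimTruth(
        kind="titration",
        seed=seed,
        params={"p0": p0, "kd": kd, "noise_sd": noise_sd,
                "clipped_points": int(clipped.sum())},
        tables={"points": pd.DataFrame({"l0": l0, "true_fraction": f})},
    )
    return series, truth
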