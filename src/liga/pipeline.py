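"""End-to-end pipeline runner: validated config in, artifact directory out.

The run config is a YAML file validated before any stage executes; each run
writes its outputs, a copy of the exact config used, the package version,
and per-sample mapped/unmapped totals into the output directory, so reruns
with the same inputs and seeds are reproducible.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, affinity, demux, dictionary, enrichment, maldi

log = logging.getLogger("liga.pipeline")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any stage executes)."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    mode: str  # enrich | maldi | kd
    out_dir: Path
    source_path: Path | None = None  # original YAML, echoed into out_dir
    # enrich mode
    dictionary_path: Path | None = None
    design_path: Path | None = None
    fastq_by_sample: dict[str, tuple] = field(default_factory=dict)
    counts_path: Path | None = None
    test_samples: list[str] = field(default_factory=list)
    control_samples: list[str] = field(default_factory=list)
    normalization: str = "invariant_set"
    alpha: float = 0.05
    max_mismatch: int = 0
    max_flank_mismatch: int = 0
    # maldi mode
    spectrum_paths: list[Path] = field(default_factory=list)
    species: list[dict] = field(default_factory=list)
    tolerance: float = 15.0
    available_pviii: int = 2700
    # kd mode
    titration_path: Path | None = None
    p0: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        cfg = cls(
            mode=raw.get("mode", "enrich"),
            out_dir=Path(raw.get("out_dir", "liga-run")),
            source_path=path,
            dictionary_path=_opt_path(raw, "dictionary"),
            design_path=_opt_path(raw, "design"),
            fastq_by_sample={
                k: tuple(v) if isinstance(v, list) else (v,)
                for k, v in (raw.get("fastq") or {}).items()
            },
            counts_path=_opt_path(raw, "counts"),
            test_samples=list(raw.get("test_samples", [])),
            control_samples=list(raw.get("control_samples", [])),
            normalization=raw.get("normalization", "invariant_set"),
            alpha=float(raw.get("alpha", 0.05)),
            max_mismatch=int(raw.get("max_mismatch", 0)),
            max_flank_mismatch=int(raw.get("max_flank_mismatch", 0)),
            spectrum_paths=[Path(p) for p in raw.get("spectra", [])],
            species=list(raw.get("species", [])),
            tolerance=float(raw.get("tolerance", 15.0)),
            available_pviii=int(raw.get("available_pviii", 2700)),
            titration_path=_opt_path(raw, "titration"),
            p0=raw.get("p0"),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("enrich", "maldi", "kd"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_mismatch < 0 or self.max_flank_mismatch < 0:
            raise ConfigError("mismatch limits must be >= 0")
        if self.mode == "enrich":
            if self.dictionary_path is None:
                raise ConfigError("enrich mode needs 'dictionary'")
            if self.counts_path is None and not self.fastq_by_sample:
                raise ConfigError("enrich mode needs 'counts' or 'fastq'")
            if self.fastq_by_sample and self.design_path is None:
                raise ConfigError("demultiplexing needs 'design'")
            if not self.test_samples or not self.control_samples:
                raise ConfigError("enrich mode needs test and control samples")
            if set(self.test_samples) & set(self.control_samples):
                raise ConfigError("test and control samples must be disjoint")
            if self.normalization not in ("invariant_set", "tmm",
                                          "naive_composition"):
                raise ConfigError(
                    f"unknown normalization {self.normalization!r}"
                )
        elif self.mode == "maldi":
            if not self.spectrum_paths or not self.species:
                raise ConfigError("maldi mode needs 'spectra' and 'species'")
        elif self.mode == "kd":
            if self.titration_path is None or self.p0 is None:
                raise ConfigError("kd mode needs 'titration' and 'p0'")


def _opt_path(raw: dict, key: str) -> Path | None:
    return Path(raw[key]) if raw.get(key) else None


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured flow; returns the artifact directory.

    Any stage error aborts with a stage-tagged RuntimeError.  Inputs are
    never mutated; the output directory receives the exact config used and
    the package version.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "version.txt").write_text(__version__ + "\n")
    if cfg.source_path is not None:
        shutil.copy(cfg.source_path, out / "config.yaml")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise RuntimeError(f"[stage:{name}] {exc}") from exc

    if cfg.mode == "enrich":
        d = stage("dictionary",
                  lambda: dictionary.read_dictionary(cfg.dictionary_path))
        if cfg.counts_path is not None:
            cm = stage("counts",
                       lambda: demux.CountMatrix.from_tsv(cfg.counts_path))
        else:
            design = stage("design",
                           lambda: demux.AmpliconDesign.from_yaml(cfg.design_path))
            cm = stage("demux", lambda: demux.count_reads(
                cfg.fastq_by_sample, design, d,
                max_flank_mismatch=cfg.max_flank_mismatch,
                max_mismatch=cfg.max_mismatch,
            ))
            cm.to_tsv(out / "counts.tsv", out / "counts.totals.json")
            for s in cm.samples:
                log.info("%s: mapped %d / unmapped %d", s,
                         cm.totals.loc[s, "mapped"],
                         cm.totals.loc[s, "unmapped"])
        contrast = enrichment.ContrastSpec(
            tuple(cfg.test_samples), tuple(cfg.control_samples),
            label="test vs control",
        )
        res = stage("enrich", lambda: enrichment.run_enrichment(
            cm, d, contrast, normalization=cfg.normalization, alpha=cfg.alpha
        ))
        res.to_tsv(out / "results.tsv")
        res.heatmap_frame().to_csv(out / "heatmap.tsv", sep="\t")
    elif cfg.mode == "maldi":
        species = [
            maldi.SpeciesModel(
                name=s["name"], expected_mass=float(s["expected_mass"]),
                species_class=s.get("species_class", "conjugate"),
                sialic_count=int(s.get("sialic_count", 0)),
                ghost_parent=s.get("ghost_parent"),
            )
            for s in cfg.species
        ]
        rows = []
        for p in cfg.spectrum_paths:
            spec = stage("read", lambda p=p: maldi.read_spectrum(p))
            spec = stage("preprocess", lambda s=spec: maldi.preprocess(s))
            fits = stage("fit", lambda s=spec: maldi.fit_peaks(
                s, species, cfg.tolerance))
            fr = stage("quantify", lambda f=fits: maldi.quantify_species(f))
            dens = maldi.estimate_density(fr, species, cfg.available_pviii)
            rows.append({"spectrum": str(p), **fr,
                         "mean_density": dens.mean_density})
        (out / "maldi.json").write_text(json.dumps(rows, indent=1) + "\n")
    else:  # kd
        series = stage("titration", lambda: affinity.TitrationSeries.from_csv(
            cfg.titration_path, p0=cfg.p0))
        res = stage("fit_kd", lambda: affinity.fit_kd(series))
        (out / "kd.json").write_text(json.dumps({
            "Kd_uM": res.kd, "SE_uM": res.kd_se, "RSS": res.rss,
            "converged": res.converged,
        }, indent=1) + "\n")
    return out
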