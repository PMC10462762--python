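"""Demultiplexing: paired-end amplicon reads -> counts per dictionary entry.

Reads carry the two silent-barcode regions embedded between fixed flanking
sequences on the forward read.  Extraction locates each flank (exact scan
first, then a bounded-Hamming scan), pulls the fixed-length barcode after
the upstream flank, and looks the concatenated pair up in the dictionary.
Reads whose barcodes match no dictionary entry are discarded but counted,
so ``mapped + unmapped`` always equals the total number of barcode-bearing
reads per sample.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dictionary import LigaDictionary

__all__ = [
    "AmpliconDesign",
    "SdbRegion",
    "CountMatrix",
    "extract_sdb",
    "map_entry",
    "count_reads",
    "read_fastq",
    "FastqFormatError",
]


class FastqFormatError(ValueError):
    """Malformed FASTQ record, reported with its record index."""


@dataclass(frozen=True)
class SdbRegion:
    """One barcode region: fixed flanks around a fixed-length variable core."""

    upstream_flank: str
    downstream_flank: str
    sdb_length: int

    def __post_init__(self) -> None:
        if not self.upstream_flank or not self.downstream_flank:
            raise ValueError("flanks must be non-empty")
        if self.sdb_length <= 0:
            raise ValueError("sdb_length must be positive")


@dataclass(frozen=True)
class AmpliconDesign:
    """Layout of the sequencing amplicon (2x75 bp paired-end by default)."""

    regions: tuple[SdbRegion, ...]
    read_length: int = 75
    sample_index_map: dict[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AmpliconDesign":
        cfg = yaml.safe_load(Path(path).read_text())
        regions = tuple(
            SdbRegion(r["upstream_flank"], r["downstream_flank"], r["sdb_length"])
            for r in cfg["regions"]
        )
        return cls(
            regions=regions,
            read_length=cfg.get("read_length", 75),
            sample_index_map=cfg.get("sample_index_map"),
        )

    def to_yaml(self, path: str | Path) -> None:
        cfg = {
            "regions": [
                {
                    "upstream_flank": r.upstream_flank,
                    "downstream_flank": r.downstream_flank,
                    "sdb_length": r.sdb_length,
                }
                for r in self.regions
            ],
            "read_length": self.read_length,
        }
        if self.sample_index_map:
            cfg["sample_index_map"] = dict(self.sample_index_map)
        Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


@dataclass
class CountMatrix:
    """Integer reads per dictionary entry per sample, with discard bookkeeping.

    ``counts`` is entries x samples; ``totals`` holds per-sample mapped /
    unmapped / unassigned_index tallies.  Conservation invariant:
    mapped + unmapped = total barcode-bearing reads in every sample.
    """

    counts: pd.DataFrame
    totals: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def entry_ids(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, counts_path: str | Path, totals_path: str | Path | None = None):
        self.counts.to_csv(counts_path, sep="\t", index_label="entry_id")
        if totals_path is not None:
            Path(totals_path).write_text(
                json.dumps(self.totals.to_dict(orient="index"), indent=1) + "\n"
            )

    @classmethod
    def from_tsv(cls, counts_path: str | Path, totals_path=None) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="entry_id")
        totals = pd.DataFrame()
        if totals_path is not None:
            totals = pd.DataFrame.from_dict(
                json.loads(Path(totals_path).read_text()), orient="index"
            )
        return cls(counts=counts, totals=totals)


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(path: str | Path):
    """Yield (name, sequence, quality) from a FASTQ file, gzip-transparent."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise FastqFormatError(f"{path}: malformed record at index {idx}")
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path}: sequence/quality length mismatch at index {idx}"
                )
            yield header[1:].strip(), seq, qual
            idx += 1


# ---------------------------------------------------------------------------
# barcode extraction and mapping

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_flank(read: str, flank: str, max_mismatch: int, start: int = 0) -> int:
    """Leftmost occurrence of ``flank`` at Hamming distance <= max_mismatch.

    Exact scan first; only if that fails, a per-position mismatch scan.
    Returns -1 if absent.
    """
    pos = read.find(flank, start)
    if pos >= 0 or max_mismatch == 0:
        return pos
    k = len(flank)
    for i in range(start, len(read) - k + 1):
        if _hamming(read[i:i + k], flank) <= max_mismatch:
            return i
    return -1


def extract_sdb(
    read: str,
    design: AmpliconDesign,
    max_flank_mismatch: int = 0,
) -> tuple[str, ...] | None:
    """Extract the barcode from each region of the forward read.

    Returns the tuple of barcodes (one per region, in design order), or
    ``None`` if any flank is missing or a barcode would run off the read.
    Failures are data, not exceptions.
    """
    barcodes = []
    cursor = 0
    for region in design.regions:
        up = _find_flank(read, region.upstream_flank, max_flank_mismatch, cursor)
        if up < 0:
            return None
        bc_start = up + len(region.upstream_flank)
        bc_end = bc_start + region.sdb_length
        down_end = bc_end + len(region.downstream_flank)
        if down_end > len(read):
            return None
        if _hamming(read[bc_end:down_end], region.downstream_flank) > max_flank_mismatch:
            return None
        barcodes.append(read[bc_start:bc_end])
        cursor = down_end
    return tuple(barcodes)


def map_entry(
    barcodes: tuple[str, ...],
    dictionary: LigaDictionary,
    max_mismatch: int = 0,
    *,
    _index: dict[str, str] | None = None,
) -> str | None:
    """Map a barcode tuple to an entry_id, or None if unmapped.

    Exact match on the concatenated barcode wins; with ``max_mismatch=1`` a
    unique Hamming-1 neighbour rescues the read, ties stay unmapped.
    """
    if len(dictionary) == 0:
        raise ValueError("dictionary is empty")
    key = "".join(barcodes)
    index = _index if _index is not None else dictionary.barcode_index
    hit = index.get(key)
    if hit is not None or max_mismatch == 0:
        return hit
    candidates = [
        eid
        for bc, eid in index.items()
        if len(bc) == len(key) and _hamming(bc, key) <= max_mismatch
    ]
    if len(candidates) == 1:
        return candidates[0]
    return None


def count_reads(
    fastq_by_sample: dict[str, str | Path | tuple],
    design: AmpliconDesign,
    dictionary: LigaDictionary,
    *,
    max_flank_mismatch: int = 0,
    max_mismatch: int = 0,
) -> CountMatrix:
    """Tally reads per dictionary entry for each sample.

    ``fastq_by_sample`` maps sample name to an R1 path or an (R1, R2) tuple;
    only the forward read is searched for barcodes, the mate is carried as a
    pass-through check of record pairing when present.
    """
    entry_ids = [e.entry_id for e in dictionary.entries]
    index = dictionary.barcode_index
    counts = pd.DataFrame(0, index=entry_ids, columns=list(fastq_by_sample))
    totals = pd.DataFrame(
        0,
        index=list(fastq_by_sample),
        columns=["total", "mapped", "unmapped", "unassigned_index"],
    )
    for sample, paths in fastq_by_sample.items():
        if isinstance(paths, (tuple, list)):
            r1, r2 = paths[0], paths[1] if len(paths) > 1 else None
        else:
            r1, r2 = paths, None
        mate = read_fastq(r2) if r2 is not None else None
        for name, seq, _ in read_fastq(r1):
            if mate is not None:
                try:
                    next(mate)
                except StopIteration:
                    raise FastqFormatError(
                        f"{r2}: fewer records than {r1} (orphan read {name!r})"
                    )
            totals.loc[sample, "total"] += 1
            barcodes = extract_sdb(seq, design, max_flank_mismatch)
            if barcodes is None:
                totals.loc[sample, "unmapped"] += 1
                continue
            eid = map_entry(barcodes, dictionary, max_mismatch, _index=index)
            if eid is None:
                totals.loc[sample, "unmapped"] += 1
            else:
                counts.loc[eid, sample] += 1
                totals.loc[sample, "mapped"] += 1
    return CountMatrix(counts=counts, totals=totals)
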