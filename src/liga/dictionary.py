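"""LiGA dictionaries: silent double barcodes (SDBs) mapped to glycans and densities.

A LiGA (liquid glycan array) is a mixture of M13 phage clones, each displaying
one glycan structure at a controlled mean density on the pVIII coat protein
(~2700 copies per virion).  Clones are identified by a silent double barcode:
two short variable DNA regions whose variants all encode the same peptide
(here ``SVEKY``), so the barcode changes the genome but not the coat protein.
The dictionary is the lookup table from barcode pair to (glycan structure,
modification class, mean display density) that turns deep-sequencing read
counts into glycan-level measurements.
"""

from __future__ import annotations

import csv
import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "GlycanStructure",
    "LigaEntry",
    "LigaDictionary",
    "SilentCodingReport",
    "read_dictionary",
    "write_dictionary",
    "validate_silent_coding",
    "build_fixture",
    "density_to_occupancy",
    "round_sigfig",
    "DEFAULT_AVAILABLE_PVIII",
    "DEFAULT_EXPECTED_PEPTIDE",
]

DEFAULT_AVAILABLE_PVIII = 2700
DEFAULT_EXPECTED_PEPTIDE = "SVEKY"

MODIFICATION_CLASSES = ("glycan", "azidoethanol", "unmodified")

_TSV_COLUMNS = [
    "entry_id",
    "library_id",
    "sdb1",
    "sdb2",
    "modification_class",
    "structure_id",
    "cfg_name",
    "composition",
    "mean_density",
]


class DictionaryError(ValueError):
    """Raised for malformed or inconsistent dictionary tables."""


@dataclass(frozen=True)
class GlycanStructure:
    """One glycan structure with a CFG-style name and monosaccharide composition.

    ``composition`` maps monosaccharide classes (Hex, HexNAc, Neu5Ac, dHex) to
    residue counts; ``terminal_tags`` records exposed termini relevant to
    lectin recognition (e.g. "Gal", "Neu5Ac-a2,6").
    """

    structure_id: str
    cfg_name: str
    composition: dict[str, int] = field(default_factory=dict)
    terminal_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for mono, n in self.composition.items():
            if n < 0:
                raise ValueError(f"negative composition count for {mono!r}")
        object.__setattr__(self, "terminal_tags", frozenset(self.terminal_tags))


@dataclass(frozen=True)
class LigaEntry:
    """One barcoded phage clone: barcode pair, modification class and density."""

    entry_id: str
    sdb_sequences: tuple[str, ...]
    modification_class: str
    glycan: GlycanStructure | None = None
    mean_density: int = 0

    def __post_init__(self) -> None:
        seqs = tuple(s.upper() for s in self.sdb_sequences)
        object.__setattr__(self, "sdb_sequences", seqs)
        for s in seqs:
            if not s or set(s) - set("ACGT"):
                raise DictionaryError(
                    f"entry {self.entry_id!r}: non-ACGT barcode {s!r}"
                )
        if self.modification_class not in MODIFICATION_CLASSES:
            raise DictionaryError(
                f"entry {self.entry_id!r}: unknown modification class "
                f"{self.modification_class!r}"
            )
        if (self.glycan is not None) != (self.modification_class == "glycan"):
            raise DictionaryError(
                f"entry {self.entry_id!r}: glycan must be present iff "
                "modification_class is 'glycan'"
            )
        if self.mean_density < 0:
            raise DictionaryError(
                f"entry {self.entry_id!r}: negative density {self.mean_density}"
            )

    @property
    def barcode(self) -> str:
        """Concatenated SDB1+SDB2 lookup key."""
        return "".join(self.sdb_sequences)

    @property
    def is_invariant(self) -> bool:
        """Blank clones (azidoethanol-capped or unmodified) assumed invariant."""
        return self.modification_class != "glycan"


@dataclass
class LigaDictionary:
    """A LiGA mixture's barcode-to-glycan lookup table."""

    library_id: str
    entries: list[LigaEntry] = field(default_factory=list)
    available_pviii: int = DEFAULT_AVAILABLE_PVIII
    sdb_frame_offset: int = 0
    expected_peptide: str = DEFAULT_EXPECTED_PEPTIDE

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries:
            if e.barcode in seen:
                raise DictionaryError(
                    f"duplicate barcode {e.barcode!r} shared by entries "
                    f"{seen[e.barcode]!r} and {e.entry_id!r}"
                )
            seen[e.barcode] = e.entry_id
            if e.mean_density > self.available_pviii:
                raise DictionaryError(
                    f"entry {e.entry_id!r}: density {e.mean_density} exceeds "
                    f"available pVIII copies ({self.available_pviii})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def barcode_index(self) -> dict[str, str]:
        """Concatenated barcode -> entry_id."""
        return {e.barcode: e.entry_id for e in self.entries}

    @property
    def glycan_entries(self) -> list[LigaEntry]:
        return [e for e in self.entries if e.modification_class == "glycan"]

    @property
    def invariant_entries(self) -> list[LigaEntry]:
        return [e for e in self.entries if e.is_invariant]

    def entry(self, entry_id: str) -> LigaEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)


# ---------------------------------------------------------------------------
# composition (de)serialisation: "Hex:5;HexNAc:4;Neu5Ac:2"

def _format_composition(comp: dict[str, int]) -> str:
    return ";".join(f"{k}:{v}" for k, v in comp.items())


def _parse_composition(text: str) -> dict[str, int]:
    comp: dict[str, int] = {}
    if not text:
        return comp
    for token in text.split(";"):
        mono, _, n = token.partition(":")
        comp[mono.strip()] = int(n)
    return comp


# ---------------------------------------------------------------------------
# reader / writer

def read_dictionary(
    path: str | Path,
    *,
    delimiter: str = "\t",
    library_id: str | None = None,
    available_pviii: int = DEFAULT_AVAILABLE_PVIII,
    expected_peptide: str = DEFAULT_EXPECTED_PEPTIDE,
) -> LigaDictionary:
    """Read a dictionary table (canonical dialect: UTF-8 TSV).

    Pass ``delimiter=","`` to import comma-delimited tables with the same
    columns.  Duplicate barcodes, non-ACGT barcodes and negative densities
    raise :class:`DictionaryError`.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise DictionaryError(f"{path}: empty file, expected a header row")
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise DictionaryError(
                f"{path}: missing mandatory column(s): {sorted(missing)}"
            )
        entries = []
        lib_ids = set()
        for row in reader:
            lib_ids.add(row["library_id"])
            mod = row["modification_class"]
            glycan = None
            if mod == "glycan":
                glycan = GlycanStructure(
                    structure_id=row["structure_id"],
                    cfg_name=row["cfg_name"],
                    composition=_parse_composition(row["composition"]),
                )
            density = int(row["mean_density"])
            if density < 0:
                raise DictionaryError(
                    f"entry {row['entry_id']!r}: negative density {density}"
                )
            entries.append(
                LigaEntry(
                    entry_id=row["entry_id"],
                    sdb_sequences=(row["sdb1"], row["sdb2"]),
                    modification_class=mod,
                    glycan=glycan,
                    mean_density=density,
                )
            )
    if library_id is None:
        library_id = lib_ids.pop() if len(lib_ids) == 1 else "??"
    return LigaDictionary(
        library_id=library_id,
        entries=entries,
        available_pviii=available_pviii,
        expected_peptide=expected_peptide,
    )


def write_dictionary(d: LigaDictionary, path: str | Path) -> None:
    """Write the canonical TSV dialect; round-trips byte-identically."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(_TSV_COLUMNS)
    for e in d.entries:
        g = e.glycan
        writer.writerow(
            [
                e.entry_id,
                d.library_id,
                e.sdb_sequences[0],
                e.sdb_sequences[1] if len(e.sdb_sequences) > 1 else "",
                e.modification_class,
                g.structure_id if g else "",
                g.cfg_name if g else "",
                _format_composition(g.composition) if g else "",
                e.mean_density,
            ]
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# silent-coding validation

@dataclass
class SilentCodingReport:
    """Per-entry translated peptides plus an overall pass flag."""

    expected_peptide: str
    peptides: dict[str, tuple[str, ...]]  # entry_id -> peptide per SDB region
    violations: list[str]

    @property
    def passed(self) -> bool:
        return not self.violations


def validate_silent_coding(
    d: LigaDictionary, *, codon_table: str | int = "Standard"
) -> SilentCodingReport:
    """Check that every SDB region encodes the dictionary's expected peptide.

    Each barcode region is translated in the frame given by
    ``sdb_frame_offset``; an entry passes iff all its regions translate to
    ``expected_peptide``.  Stop codons and wrong peptides are flagged as
    violations, not raised.  A barcode whose length (after the offset) is not
    a codon multiple raises, because the frame itself is then ill-defined.
    """
    table = CodonTable.unambiguous_dna_by_id[codon_table] if isinstance(
        codon_table, int
    ) else CodonTable.unambiguous_dna_by_name[codon_table]
    peptides: dict[str, tuple[str, ...]] = {}
    violations: list[str] = []
    for e in d.entries:
        region_peps = []
        for s in e.sdb_sequences:
            coding = s[d.sdb_frame_offset:]
            if len(coding) % 3 != 0:
                raise DictionaryError(
                    f"entry {e.entry_id!r}: barcode length {len(s)} minus "
                    f"offset {d.sdb_frame_offset} is not a codon multiple"
                )
            pep = str(Seq(coding).translate(table=table.id))
            region_peps.append(pep)
            if pep != d.expected_peptide:
                violations.append(
                    f"{e.entry_id}: region translates to {pep!r}, "
                    f"expected {d.expected_peptide!r}"
                )
        peptides[e.entry_id] = tuple(region_peps)
    return SilentCodingReport(
        expected_peptide=d.expected_peptide,
        peptides=peptides,
        violations=violations,
    )


# ---------------------------------------------------------------------------
# fixture dictionaries

#: The six N-glycan structures of the density-series library (six structures
#: at five densities each).  Compositions are biantennary-core based;
#: terminal tags drive nothing downstream but make fixtures realistic.
_LIGA6X5_STRUCTURES = [
    GlycanStructure("Man3", "Man3GlcNAc2", {"Hex": 3, "HexNAc": 2}, {"Man"}),
    GlycanStructure("GnGn", "GlcNAc2Man3GlcNAc2", {"Hex": 3, "HexNAc": 4}, {"GlcNAc"}),
    GlycanStructure("NA2", "Gal2GlcNAc2Man3GlcNAc2", {"Hex": 5, "HexNAc": 4}, {"Gal"}),
    GlycanStructure(
        "A1", "Neu5AcGal2GlcNAc2Man3GlcNAc2",
        {"Hex": 5, "HexNAc": 4, "Neu5Ac": 1}, {"Gal", "Neu5Ac-a2,6"},
    ),
    GlycanStructure(
        "A2", "Neu5Ac2Gal2GlcNAc2Man3GlcNAc2",
        {"Hex": 5, "HexNAc": 4, "Neu5Ac": 2}, {"Neu5Ac-a2,6"},
    ),
    GlycanStructure(
        "A2F", "Neu5Ac2Gal2GlcNAc2Man3GlcNAc2Fuc",
        {"Hex": 5, "HexNAc": 4, "Neu5Ac": 2, "dHex": 1}, {"Neu5Ac-a2,6"},
    ),
]

_MAN3 = _LIGA6X5_STRUCTURES[0]

DENSITY_SERIES = (50, 150, 500, 750, 1000)

# synonymous codons of SVEKY under the standard genetic code
_SVEKY_CODONS = [
    ("AGT", "AGC", "TCT", "TCC", "TCA", "TCG"),  # Ser
    ("GTT", "GTC", "GTA", "GTG"),                # Val
    ("GAA", "GAG"),                              # Glu
    ("AAA", "AAG"),                              # Lys
    ("TAT", "TAC"),                              # Tyr
]


def _sdb_variants(rng: np.random.Generator) -> list[str]:
    """All 192 synonymous SVEKY codings, in a seeded deterministic order."""
    variants = ["".join(c) for c in itertools.product(*_SVEKY_CODONS)]
    rng.shuffle(variants)
    return variants


def _barcode_pairs(n: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    v1 = _sdb_variants(rng)
    v2 = _sdb_variants(rng)
    if n > len(v1):
        # fall back to the full cross product for very large dictionaries
        if n > len(v1) * len(v2):
            raise ValueError(f"cannot generate {n} distinct barcode pairs")
        return list(itertools.islice(itertools.product(v1, v2), n))
    # zip of two independently shuffled variant lists: pairs differ in both
    # regions, so concatenated barcodes are >= Hamming distance 2 apart
    return list(zip(v1[:n], v2[:n]))


def build_fixture(
    library: str, seed: int = 0, *, n_invariant: int = 10
) -> LigaDictionary:
    """Generate a synthetic dictionary mirroring a published library design.

    ``liga6x5``
        six N-glycan structures x five densities (50, 150, 500, 750, 1000
        glycans/phage) = 30 glycan entries, plus ``n_invariant``
        azidoethanol-capped invariant clones.
    ``msdb_man3``
        paucimannose at the five densities, each encoded by seven distinct
        barcodes (35 glycan entries), plus invariant clones.
    ``invivo``
        the 30 liga6x5 glycan entries plus 16 unmodified and 10
        azidoethanol "blank" clones (the in vivo baseline set).

    Barcodes are synonymous-codon variants of the silent peptide, so every
    fixture passes :func:`validate_silent_coding` by construction.
    """
    rng = np.random.default_rng(seed)
    entries: list[LigaEntry] = []

    def glycan_entry(eid, sdb, structure, density):
        return LigaEntry(eid, sdb, "glycan", glycan=structure, mean_density=density)

    def blank_entries(n_azido, n_unmod, pairs):
        out = []
        for i in range(n_azido):
            out.append(LigaEntry(f"AZ{i + 1:02d}", pairs.pop(0), "azidoethanol"))
        for i in range(n_unmod):
            out.append(LigaEntry(f"UN{i + 1:02d}", pairs.pop(0), "unmodified"))
        return out

    if library == "liga6x5":
        pairs = _barcode_pairs(30 + n_invariant, rng)
        for s in _LIGA6X5_STRUCTURES:
            for dens in DENSITY_SERIES:
                entries.append(
                    glycan_entry(f"{s.structure_id}-{dens}", pairs.pop(0), s, dens)
                )
        entries.extend(blank_entries(n_invariant, 0, pairs))
        lib_id = "L6"
    elif library == "msdb_man3":
        pairs = _barcode_pairs(35 + n_invariant, rng)
        for dens in DENSITY_SERIES:
            for rep in range(7):
                entries.append(
                    glycan_entry(
                        f"Man3-{dens}-b{rep + 1}", pairs.pop(0), _MAN3, dens
                    )
                )
        entries.extend(blank_entries(n_invariant, 0, pairs))
        lib_id = "MS"
    elif library == "invivo":
        pairs = _barcode_pairs(30 + 26, rng)
        for s in _LIGA6X5_STRUCTURES:
            for dens in DENSITY_SERIES:
                entries.append(
                    glycan_entry(f"{s.structure_id}-{dens}", pairs.pop(0), s, dens)
                )
        entries.extend(blank_entries(10, 16, pairs))
        lib_id = "IV"
    else:
        raise ValueError(
            f"unknown fixture library {library!r}; "
            "expected liga6x5, msdb_man3 or invivo"
        )
    return LigaDictionary(library_id=lib_id, entries=entries)


# ---------------------------------------------------------------------------
# density <-> pVIII occupancy

def round_sigfig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (half away from zero)."""
    if x == 0:
        return 0.0
    from decimal import Decimal, ROUND_HALF_UP

    d = Decimal(repr(float(x)))
    shift = sig - 1 - int(np.floor(np.log10(abs(x))))
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def density_to_occupancy(
    density: float,
    available: int = DEFAULT_AVAILABLE_PVIII,
    *,
    sigfig: int | None = None,
) -> float:
    """Percent of pVIII coat proteins carrying a glycan at the given density.

    ``sigfig=1`` reproduces the coarse one-significant-figure percentages
    used when speaking of occupancy classes (1000/2700 -> 37.04% -> "40%").
    """
    if not 0 <= density <= available:
        raise ValueError(f"density {density} outside [0, {available}]")
    pct = 100.0 * density / available
    if sigfig is not None:
        pct = round_sigfig(pct, sigfig)
    return pct
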