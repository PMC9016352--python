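"""Protein sequences, phosphovariants and net-charge arithmetic.

The TDP-43 low-complexity domain (LCD, residues 261-414 of the 414-aa human
protein) is hyperphosphorylated on C-terminal serines in ALS/FTD.  This module
builds the standard variant set used throughout the package: phosphomimetic
S->D substitutions ("2D", "5D", "12D"), S->A controls ("2A", "5A", "12A") and
true phosphoserine variants ("5pS", "12pS"), all addressed in full-length
(1-based) residue numbering.

Phosphoserine is encoded with the lowercase one-letter code ``'s'``; every
other residue uses its canonical uppercase one-letter code.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PHOSPHOSERINE",
    "CANONICAL_AA",
    "CANONICAL_SITES",
    "ProteinSequence",
    "VariantSpec",
    "PkaTable",
    "load_fasta",
    "write_fasta",
    "extract_region",
    "build_variant",
    "load_variant_specs",
    "net_charge",
    "canonical_tdp43",
    "canonical_variant_spec",
    "tdp43_lcd",
    "LCD_START",
    "LCD_END",
]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: one-letter code used for phosphoserine (SEP)
PHOSPHOSERINE = "s"
ALPHABET = CANONICAL_AA | {PHOSPHOSERINE}

LCD_START = 261
LCD_END = 414

#: disease phosphosite sets, full-length numbering (nested: 2 < 5 < 12)
CANONICAL_SITES: dict[int, frozenset[int]] = {
    2: frozenset({409, 410}),
    5: frozenset({379, 403, 404, 409, 410}),
    12: frozenset(
        {373, 375, 379, 387, 389, 393, 395, 403, 404, 407, 409, 410}
    ),
}


@dataclass(frozen=True)
class ProteinSequence:
    """A residue string with a full-length numbering offset.

    ``offset`` is the full-length (1-based) position of the first residue, so
    the LCD extracted from full-length TDP-43 keeps its native numbering
    (261..414).
    """

    id: str
    residues: str
    offset: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        if self.offset < 1:
            raise ValueError(f"offset must be >= 1, got {self.offset}")
        for i, code in enumerate(self.residues):
            if code not in ALPHABET:
                raise ValueError(
                    f"illegal residue code {code!r} at position "
                    f"{self.offset + i} in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def end(self) -> int:
        """Full-length position of the last residue."""
        return self.offset + len(self.residues) - 1

    def residue_at(self, position: int) -> str:
        """Residue code at a full-length position."""
        if not self.offset <= position <= self.end:
            raise IndexError(
                f"position {position} outside [{self.offset}, {self.end}]"
            )
        return self.residues[position - self.offset]

    def index_of(self, position: int) -> int:
        """0-based local index of a full-length position."""
        self.residue_at(position)
        return position - self.offset

    @property
    def phospho_positions(self) -> tuple[int, ...]:
        return tuple(
            self.offset + i
            for i, c in enumerate(self.residues)
            if c == PHOSPHOSERINE
        )


@dataclass(frozen=True)
class VariantSpec:
    """A set of serine substitutions at full-length positions.

    ``substitution`` is one of ``"ASP"`` (phosphomimetic S->D), ``"ALA"``
    (control S->A), ``"SEP"`` (true phosphoserine) or ``"NONE"``.
    """

    name: str
    sites: frozenset[int] = frozenset()
    substitution: str = "NONE"

    _CODES = {"ASP": "D", "ALA": "A", "SEP": PHOSPHOSERINE, "NONE": None}

    def __post_init__(self) -> None:
        if self.substitution not in self._CODES:
            raise ValueError(f"unknown substitution {self.substitution!r}")
        if self.substitution != "NONE" and not self.sites:
            raise ValueError("sites must be nonempty unless substitution NONE")
        object.__setattr__(self, "sites", frozenset(self.sites))

    @property
    def target_code(self) -> str | None:
        return self._CODES[self.substitution]


def load_variant_specs(path: str | Path) -> list[VariantSpec]:
    """Variant specs from a YAML config: a list of entries with ``name`` and
    either a canonical name alone or explicit ``sites`` + ``substitution``."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    specs = []
    for entry in raw:
        if isinstance(entry, str):
            specs.append(canonical_variant_spec(entry))
        else:
            specs.append(
                VariantSpec(
                    name=entry["name"],
                    sites=frozenset(entry.get("sites", ())),
                    substitution=entry.get("substitution", "NONE"),
                )
            )
    return specs


def canonical_variant_spec(name: str) -> VariantSpec:
    """Variant spec from a conventional name: Wt, 2D/5D/12D, 2A/5A/12A, 5pS/12pS."""
    if name.lower() in {"wt", "wildtype", "wild-type"}:
        return VariantSpec("Wt")
    for suffix, sub in (("pS", "SEP"), ("D", "ASP"), ("A", "ALA")):
        if name.endswith(suffix):
            stem = name[: -len(suffix)]
            if stem.isdigit() and int(stem) in CANONICAL_SITES:
                return VariantSpec(name, CANONICAL_SITES[int(stem)], sub)
    raise ValueError(f"unknown variant name {name!r}")


# ---------------------------------------------------------------------------
# FASTA I/O


def load_fasta(
    path: str | Path,
    modifications: Mapping[int, str] | None = None,
) -> list[ProteinSequence]:
    """Read FASTA records into :class:`ProteinSequence` objects.

    Residues are uppercased (plain FASTA has no phospho encoding); phospho
    marks can be applied afterwards via ``modifications`` (full-length
    position -> ``"SEP"``), which targets the first record.
    """
    path = Path(path)
    records: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                records.append((line[1:].split()[0] or "unnamed", []))
            else:
                if not records:
                    raise ValueError(f"{path}: sequence data before header")
                records[-1][1].append(line.upper())
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seqs = []
    for rid, chunks in records:
        seq = "".join(chunks)
        for i, c in enumerate(seq):
            if c not in CANONICAL_AA:
                raise ValueError(
                    f"{path}: illegal residue {c!r} at position {i + 1} "
                    f"of record {rid!r}"
                )
        seqs.append(ProteinSequence(rid, seq))
    if modifications:
        target = seqs[0]
        spec = VariantSpec(
            "modified",
            frozenset(
                p for p, mod in modifications.items() if mod.upper() == "SEP"
            ),
            "SEP",
        )
        seqs[0] = replace(build_variant(target, spec), id=target.id)
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write FASTA; phosphoserines appear as lowercase ``s`` and are also
    listed in a ``<path>.mods.csv`` sidecar (position, modification)."""
    path = Path(path)
    mods: list[tuple[str, int]] = []
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id} offset={seq.offset}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i : i + 60] + "\n")
            mods.extend((seq.id, p) for p in seq.phospho_positions)
    with open(path.with_suffix(path.suffix + ".mods.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sequence_id", "position", "modification"])
        for rid, pos in mods:
            writer.writerow([rid, pos, "SEP"])


# ---------------------------------------------------------------------------
# Region extraction and variant construction


def extract_region(seq: ProteinSequence, start: int, end: int) -> ProteinSequence:
    """Sub-sequence [start, end] in full-length coordinates (inclusive)."""
    if start > end:
        raise ValueError(f"inverted bounds: start {start} > end {end}")
    if start < seq.offset or end > seq.end:
        raise ValueError(
            f"region [{start}, {end}] outside sequence span "
            f"[{seq.offset}, {seq.end}]"
        )
    return ProteinSequence(
        id=f"{seq.id}_{start}-{end}",
        residues=seq.residues[start - seq.offset : end - seq.offset + 1],
        offset=start,
    )


def build_variant(seq: ProteinSequence, spec: VariantSpec) -> ProteinSequence:
    """Apply a serine-substitution spec; every site must be Ser in ``seq``."""
    if spec.substitution == "NONE":
        return replace(seq, id=f"{seq.id}_{spec.name}" if spec.name else seq.id)
    residues = list(seq.residues)
    for site in sorted(spec.sites):
        idx = seq.index_of(site)  # raises IndexError if out of range
        if residues[idx] != "S":
            raise ValueError(
                f"site {site} is {residues[idx]!r}, not serine, in {seq.id!r}"
            )
        residues[idx] = spec.target_code
    return ProteinSequence(
        id=f"{seq.id}_{spec.name}", residues="".join(residues), offset=seq.offset
    )


# ---------------------------------------------------------------------------
# Net charge


_DEFAULT_PKA_FILE = "pka_protein_calculator.csv"
ACIDIC = frozenset("DECY")
BASIC = frozenset("HKR")


@dataclass(frozen=True)
class PkaTable:
    """pKa values for ionizable groups plus the phospho-charge convention.

    ``phospho_mode`` is ``"FIXED_MINUS_2"`` (each phosphoserine contributes
    exactly -2 e; matches the paper's -4.1 -> -28.1 arithmetic) or
    ``"HENDERSON"`` (phosphate -1 plus a second Henderson-Hasselbalch
    ionization at ``sep_pka2``).
    """

    pka: Mapping[str, float]
    n_term: float
    c_term: float
    phospho_mode: str = "FIXED_MINUS_2"
    sep_pka2: float = 5.96

    def __post_init__(self) -> None:
        if self.phospho_mode not in {"FIXED_MINUS_2", "HENDERSON"}:
            raise ValueError(f"unknown phospho_mode {self.phospho_mode!r}")
        for name, value in [*self.pka.items(), ("N_TERM", self.n_term),
                            ("C_TERM", self.c_term)]:
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa for {name} out of (0, 14): {value}")

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "PkaTable":
        values: dict[str, float] = {}
        with open(path) as fh:
            for row in csv.DictReader(
                r for r in fh if not r.lstrip().startswith("#")
            ):
                values[row["group"].strip()] = float(row["pka"])
        n_term = values.pop("N_TERM")
        c_term = values.pop("C_TERM")
        return cls(pka=values, n_term=n_term, c_term=c_term, **kwargs)

    @classmethod
    def default(cls, **kwargs) -> "PkaTable":
        with resources.as_file(
            resources.files("lcdphase.data") / _DEFAULT_PKA_FILE
        ) as p:
            return cls.from_csv(p, **kwargs)


def _acid_charge(pka: float, ph: float) -> float:
    return -1.0 / (1.0 + 10.0 ** (pka - ph))


def _base_charge(pka: float, ph: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def net_charge(
    seq: ProteinSequence,
    ph: float = 7.4,
    pka_table: PkaTable | None = None,
    include_termini: bool = True,
) -> float:
    """Henderson-Hasselbalch net charge in elementary charges.

    Acidic groups contribute ``-1/(1+10^(pKa-pH))``, basic groups
    ``+1/(1+10^(pH-pKa))``.  Phosphoserine contributes exactly -2 in
    ``FIXED_MINUS_2`` mode.
    """
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH out of (0, 14): {ph}")
    table = pka_table if pka_table is not None else PkaTable.default()
    total = 0.0
    if include_termini:
        total += _base_charge(table.n_term, ph)
        total += _acid_charge(table.c_term, ph)
    for code in seq.residues:
        if code == PHOSPHOSERINE:
            if table.phospho_mode == "FIXED_MINUS_2":
                total += -2.0
            else:
                total += -1.0 + _acid_charge(table.sep_pka2, ph)
        elif code in ACIDIC:
            total += _acid_charge(table.pka[code], ph)
        elif code in BASIC:
            total += _base_charge(table.pka[code], ph)
    return total


# ---------------------------------------------------------------------------
# Bundled canonical sequence


def canonical_tdp43() -> ProteinSequence:
    """The bundled canonical 414-aa human TDP-43 sequence (UniProt Q13148)."""
    with resources.as_file(
        resources.files("lcdphase.data") / "Q13148.fasta"
    ) as p:
        return load_fasta(p)[0]


def tdp43_lcd(variant: str | VariantSpec = "Wt") -> ProteinSequence:
    """The TDP-43 LCD (aa. 261-414), optionally with a canonical variant applied.

    Substitutions are applied on the full-length sequence first, so site
    numbering is always full-length.
    """
    spec = (
        variant
        if isinstance(variant, VariantSpec)
        else canonical_variant_spec(variant)
    )
    full = build_variant(canonical_tdp43(), spec)
    lcd = extract_region(full, LCD_START, LCD_END)
    return replace(lcd, id=f"TDP43_LCD_{spec.name}")
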