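"""Discrete morphological character matrices and character-group metadata.

A :class:`CharacterMatrix` holds unordered multistate codings (states 0-9)
for a set of taxa, with ``?`` (missing) and ``-`` (inapplicable) sentinels.
Both sentinels are treated identically downstream (any state), following
common TNT/NONA practice for morphological data.

Supported dialects: NEXUS (read via dendropy, written directly), TNT
``xread`` and a plain CSV layout (first column taxon label, header row of
1-based character ids, one single-symbol state per cell).

Character groups map 1-based character ids to anatomical structures (for
the copulatory-structure data: thelycum sternites S6/AS7/PS7/S8 and petasma
lobes PI/LA/PM/PE) and define the named partitions used for the separate
female-only / male-only / total-evidence analyses.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml

from .errors import FormatError, ValidationError

MISSING = -1
INAPPLICABLE = -2

_SYMBOLS = {str(d): d for d in range(10)}
_SYMBOLS["?"] = MISSING
_SYMBOLS["-"] = INAPPLICABLE
_RENDER = {v: k for k, v in _SYMBOLS.items()}

FORMATS = ("nexus", "tnt", "csv")


@dataclass
class CharacterMatrix:
    """Taxa x characters matrix of unordered discrete states."""

    taxa: list
    codes: np.ndarray  # (n_taxa, n_chars), int8; >=0 states, MISSING, INAPPLICABLE
    char_ids: np.ndarray = None  # 1-based ids, len n_chars
    weights: np.ndarray = None  # per-character positive weights
    ordered_flags: np.ndarray = None  # all False here (unordered characters)

    def __post_init__(self):
        self.taxa = list(self.taxa)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValidationError("codes must be a 2-D taxa x characters array")
        n_taxa, n_chars = self.codes.shape
        if n_taxa == 0:
            raise ValidationError("matrix must contain at least one taxon")
        if n_chars == 0:
            raise ValidationError("matrix must contain at least one character")
        if len(self.taxa) != n_taxa:
            raise ValidationError("taxon list length does not match code rows")
        if len(set(self.taxa)) != n_taxa:
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        valid = (self.codes >= 0) & (self.codes <= 9)
        valid |= (self.codes == MISSING) | (self.codes == INAPPLICABLE)
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValidationError(
                f"invalid state code {int(self.codes[i, j])} at taxon "
                f"{self.taxa[i]!r}, character column {j + 1}"
            )
        if self.char_ids is None:
            self.char_ids = np.arange(1, n_chars + 1)
        self.char_ids = np.asarray(self.char_ids, dtype=int)
        if self.char_ids.shape != (n_chars,):
            raise ValidationError("char_ids length does not match character count")
        if self.weights is None:
            self.weights = np.ones(n_chars)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n_chars,) or (self.weights < 0).any():
            raise ValidationError("weights must be non-negative, one per character")
        if self.ordered_flags is None:
            self.ordered_flags = np.zeros(n_chars, dtype=bool)
        self.ordered_flags = np.asarray(self.ordered_flags, dtype=bool)

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_chars(self) -> int:
        return self.codes.shape[1]

    @property
    def shape(self) -> tuple:
        return self.codes.shape

    def column(self, char_id: int) -> np.ndarray:
        """Codes of the character with the given 1-based id."""
        idx = np.nonzero(self.char_ids == char_id)[0]
        if idx.size == 0:
            raise KeyError(f"no character with id {char_id}")
        return self.codes[:, idx[0]]

    def taxon_index(self) -> dict:
        return {t: i for i, t in enumerate(self.taxa)}

    def reorder_taxa(self, order: list) -> "CharacterMatrix":
        if sorted(order) != sorted(self.taxa):
            raise ValidationError("reordering must be a permutation of the taxa")
        idx = [self.taxa.index(t) for t in order]
        return CharacterMatrix(order, self.codes[idx], self.char_ids.copy(),
                               self.weights.copy(), self.ordered_flags.copy())

    def select_columns(self, positions: np.ndarray) -> "CharacterMatrix":
        positions = np.asarray(positions, dtype=int)
        return CharacterMatrix(list(self.taxa), self.codes[:, positions],
                               self.char_ids[positions], self.weights[positions],
                               self.ordered_flags[positions])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (self.taxa == other.taxa
                and np.array_equal(self.codes, other.codes)
                and np.array_equal(self.char_ids, other.char_ids)
                and np.allclose(self.weights, other.weights))


# --------------------------------------------------------------------------
# Character groups
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterGroup:
    gid: int
    label: str
    ranges: tuple  # ((lo, hi), ...) inclusive 1-based ranges

    def character_ids(self) -> list:
        out = []
        for lo, hi in self.ranges:
            out.extend(range(lo, hi + 1))
        return out


@dataclass
class CharacterGroupMap:
    """Anatomical groups of characters plus named partitions of groups."""

    groups: dict  # gid -> CharacterGroup
    partitions: dict = field(default_factory=dict)  # name -> [gid, ...]

    def __post_init__(self):
        seen = {}
        for g in self.groups.values():
            for c in g.character_ids():
                if c in seen:
                    raise ValidationError(
                        f"character {c} assigned to groups {seen[c]} and {g.gid}")
                seen[c] = g.gid
        for name, gids in self.partitions.items():
            for gid in gids:
                if gid not in self.groups:
                    raise ValidationError(
                        f"partition {name!r} references unknown group {gid}")

    def group_of(self, char_id: int):
        for g in self.groups.values():
            if any(lo <= char_id <= hi for lo, hi in g.ranges):
                return g.gid
        return None

    def grouped_character_ids(self) -> list:
        out = []
        for gid in sorted(self.groups):
            out.extend(self.groups[gid].character_ids())
        return out

    def partition_character_ids(self, name: str) -> list:
        if name not in self.partitions:
            raise KeyError(f"unknown partition {name!r}; "
                           f"known: {sorted(self.partitions)}")
        out = []
        for gid in self.partitions[name]:
            out.extend(self.groups[gid].character_ids())
        return sorted(out)

    def validate_against(self, m: CharacterMatrix) -> None:
        present = set(m.char_ids.tolist())
        missing = [c for c in self.grouped_character_ids() if c not in present]
        if missing:
            raise ValidationError(
                f"grouped characters absent from matrix: {missing[:10]}")

    # ------------------------------------------------------------ YAML I/O

    def to_yaml(self, path) -> None:
        doc = {
            "groups": {
                gid: {"label": g.label,
                      "ranges": [list(r) for r in g.ranges]}
                for gid, g in sorted(self.groups.items())
            },
            "partitions": {k: list(v) for k, v in self.partitions.items()},
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "CharacterGroupMap":
        doc = yaml.safe_load(Path(path).read_text())
        groups = {
            int(gid): CharacterGroup(
                int(gid), spec["label"],
                tuple((int(lo), int(hi)) for lo, hi in spec["ranges"]))
            for gid, spec in doc["groups"].items()
        }
        return cls(groups, {k: [int(g) for g in v]
                            for k, v in doc.get("partitions", {}).items()})


def default_group_map() -> CharacterGroupMap:
    """The copulatory-structure group layout.

    Eight anatomical groups: four thelycum sternite regions (S6, AS7, PS7,
    S8) spanning characters 1-48 and four petasma lobes (PI, LA, PM, PE)
    spanning characters 49-74.  The named partitions are the female-only
    ("thelycum") and male-only ("petasma") character sets.
    """
    spec = [
        (1, "S6", ((1, 9),)),
        (2, "AS7", ((10, 25),)),
        (3, "PS7", ((26, 39),)),
        (4, "S8", ((40, 48),)),
        (5, "PI", ((49, 50),)),
        (6, "LA", ((51, 56),)),
        (7, "PM", ((57, 64),)),
        (8, "PE", ((65, 74),)),
    ]
    groups = {gid: CharacterGroup(gid, label, ranges) for gid, label, ranges in spec}
    return CharacterGroupMap(groups, {"thelycum": [1, 2, 3, 4],
                                      "petasma": [5, 6, 7, 8]})


def select_partition(m: CharacterMatrix, gmap: CharacterGroupMap,
                     name: str) -> CharacterMatrix:
    """Sub-matrix of the columns belonging to a named partition.

    Original character ids are retained so that downstream reports refer to
    the same character numbers as the full matrix.
    """
    wanted = set(gmap.partition_character_ids(name))
    positions = np.nonzero(np.isin(m.char_ids, list(wanted)))[0]
    if positions.size == 0:
        raise ValidationError(f"partition {name!r} selects no characters")
    return m.select_columns(positions)


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def read_matrix(path, format: str) -> CharacterMatrix:
    """Read a character matrix in one of the supported dialects."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    text = Path(path).read_text()
    if format == "csv":
        return _read_csv(text)
    if format == "tnt":
        return _read_tnt(text)
    return _read_nexus(text)


def write_matrix(m: CharacterMatrix, path, format: str) -> None:
    """Write a matrix so that re-reading yields an equal matrix."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "csv":
        out = _write_csv(m)
    elif format == "tnt":
        out = _write_tnt(m)
    else:
        out = _write_nexus(m)
    Path(path).write_text(out)


def _decode_cell(sym: str, taxon: str, pos: int) -> int:
    if sym not in _SYMBOLS:
        raise ValidationError(
            f"unknown state symbol {sym!r} for taxon {taxon!r}, character {pos}")
    return _SYMBOLS[sym]


def _rows_to_matrix(taxa, rows, char_ids=None) -> CharacterMatrix:
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        bad = next(t for t, r in zip(taxa, rows)
                   if len(r) != len(rows[0]))
        raise FormatError(f"ragged matrix: taxon {bad!r} codes a different "
                          f"number of characters than the first row")
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValidationError(f"duplicate taxon label: {dupes}")
    codes = np.array([[_decode_cell(s, t, j + 1)
                       for j, s in enumerate(row)]
                      for t, row in zip(taxa, rows)], dtype=np.int8)
    return CharacterMatrix(list(taxa), codes, char_ids)


# ---- CSV ----

def _read_csv(text: str) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty CSV matrix")
    header = [c.strip() for c in lines[0].split(",")]
    try:
        char_ids = [int(c) for c in header[1:]]
    except ValueError as exc:
        raise FormatError(f"CSV header must list integer character ids: {exc}")
    taxa, rows = [], []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(",")]
        taxa.append(cells[0])
        row = cells[1:]
        if len(row) != len(char_ids):
            raise FormatError(
                f"ragged matrix: taxon {cells[0]!r} has {len(row)} cells, "
                f"header declares {len(char_ids)}")
        rows.append(row)
    return _rows_to_matrix(taxa, rows, np.array(char_ids))


def _write_csv(m: CharacterMatrix) -> str:
    buf = io.StringIO()
    buf.write("taxon," + ",".join(str(c) for c in m.char_ids) + "\n")
    for t, row in zip(m.taxa, m.codes):
        buf.write(t + "," + ",".join(_RENDER[int(v)] for v in row) + "\n")
    return buf.getvalue()


# ---- TNT xread ----

def _read_tnt(text: str) -> CharacterMatrix:
    body = text.strip()
    if not body.lower().startswith("xread"):
        raise FormatError("TNT file must start with 'xread'")
    body = body[len("xread"):].strip()
    if body.startswith("'"):
        end = body.index("'", 1)
        body = body[end + 1:].strip()
    mnum = re.match(r"(\d+)\s+(\d+)", body)
    if not mnum:
        raise FormatError("TNT xread requires 'nchar ntax' counts")
    n_chars, n_taxa = int(mnum.group(1)), int(mnum.group(2))
    rest = body[mnum.end():].strip()
    if rest.endswith(";"):
        rest = rest[:-1]
    taxa, rows = [], []
    for ln in rest.splitlines():
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"malformed TNT matrix row: {ln!r}")
        taxa.append(parts[0])
        rows.append(list(parts[1].replace(" ", "")))
    if len(taxa) != n_taxa:
        raise FormatError(f"TNT header declares {n_taxa} taxa, found {len(taxa)}")
    if any(len(r) != n_chars for r in rows):
        bad = next(t for t, r in zip(taxa, rows) if len(r) != n_chars)
        raise FormatError(f"ragged matrix: taxon {bad!r} does not code "
                          f"{n_chars} characters")
    return _rows_to_matrix(taxa, rows)


def _write_tnt(m: CharacterMatrix) -> str:
    buf = io.StringIO()
    buf.write(f"xread 'exported matrix' {m.n_chars} {m.n_taxa}\n")
    width = max(len(t) for t in m.taxa) + 2
    for t, row in zip(m.taxa, m.codes):
        seq = "".join(_RENDER[int(v)] for v in row)
        buf.write(t.replace(" ", "_").ljust(width) + seq + "\n")
    buf.write(";\n")
    return buf.getvalue()


# ---- NEXUS ----

def _read_nexus(text: str) -> CharacterMatrix:
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus",
                                                    preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"could not parse NEXUS matrix: {exc}")
    taxa, rows = [], []
    for taxon in dmat.taxon_namespace:
        seq = dmat[taxon]
        taxa.append(taxon.label)
        rows.append([str(s) for s in seq.symbols_as_list()])
    return _rows_to_matrix(taxa, rows)


def _write_nexus(m: CharacterMatrix) -> str:
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_chars};\n")
    buf.write("    FORMAT DATATYPE=STANDARD SYMBOLS=\"0123456789\" "
              "MISSING=? GAP=-;\n")
    buf.write("    MATRIX\n")
    width = max(len(t) for t in m.taxa) + 2
    for t, row in zip(m.taxa, m.codes):
        label = t.replace(" ", "_")
        seq = "".join(_RENDER[int(v)] for v in row)
        buf.write("        " + label.ljust(width) + seq + "\n")
    buf.write("    ;\nEND;\n")
    return buf.getvalue()
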