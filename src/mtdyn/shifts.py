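"""Chemical-shift assignment tables.

A :class:`ChemicalShiftTable` maps (residue number, atom name) to a chemical
shift in ppm and is the bridge between solution-state assignments and peaks
observed in the solid state.  Tables are read from delimited text (CSV/TSV/
whitespace) or from a minimal NMR-STAR-like ``loop_`` block.
"""
from __future__ import annotations

import io
import re
from pathlib import Path
from typing import Iterable

import pandas as pd

COLUMNS = ["residue_number", "residue_type", "atom_name", "shift"]

# NMR-STAR atom-shift loop tags mapped onto our column names
_STAR_TAGS = {
    "comp_index_id": "residue_number",
    "seq_id": "residue_number",
    "comp_id": "residue_type",
    "atom_id": "atom_name",
    "val": "shift",
    "value": "shift",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ShiftTableError(ValueError):
    pass


class ChemicalShiftTable:
    """Per-(residue, atom) chemical shifts in ppm, at most one row per key."""

    def __init__(self, df: pd.DataFrame):
        df = df[COLUMNS].copy()
        df["residue_number"] = df["residue_number"].astype(int)
        df["shift"] = df["shift"].astype(float)
        dup = df.duplicated(subset=["residue_number", "atom_name"], keep=False)
        if dup.any():
            keys = df.loc[dup, ["residue_number", "atom_name"]].drop_duplicates()
            pairs = [f"({r}, {a})" for r, a in keys.itertuples(index=False)]
            raise ShiftTableError("duplicate (residue, atom) keys: " + ", ".join(pairs))
        self.df = df.reset_index(drop=True)
        self._index = {
            (r, a): s
            for r, a, s in zip(df["residue_number"], df["atom_name"], df["shift"])
        }

    def __len__(self) -> int:
        return len(self.df)

    def get(self, residue_number: int, atom_name: str) -> float | None:
        return self._index.get((residue_number, atom_name))

    def residues(self) -> list[int]:
        return sorted(int(r) for r in self.df["residue_number"].unique())

    def residue_type(self, residue_number: int) -> str:
        sel = self.df.loc[self.df["residue_number"] == residue_number, "residue_type"]
        if sel.empty:
            raise KeyError(residue_number)
        return sel.iloc[0]

    def atoms_of(self, residue_number: int) -> list[str]:
        sel = self.df.loc[self.df["residue_number"] == residue_number, "atom_name"]
        return list(sel)

    def subset(self, atoms: Iterable[str]) -> "ChemicalShiftTable":
        atoms = set(atoms)
        return ChemicalShiftTable(self.df[self.df["atom_name"].isin(atoms)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ChemicalShiftTable):
            return NotImplemented
        a = self.df.sort_values(["residue_number", "atom_name"]).reset_index(drop=True)
        b = other.df.sort_values(["residue_number", "atom_name"]).reset_index(drop=True)
        return a.equals(b)

    def write(self, path: str | Path | None = None) -> str | None:
        text = self.df.to_csv(index=False, float_format="%.4f")
        if path is None:
            return text
        Path(path).write_text(text)
        return None


def _read_star_like(lines: list[str]) -> pd.DataFrame:
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "loop_":
            in_loop = True
            tags, rows = [], []
            continue
        if not in_loop:
            continue
        if line.startswith("_"):
            tags.append(line.split(".")[-1].lower())
            continue
        if line in ("stop_", "save_"):
            break
        rows.append(line.split())
    cols = [_STAR_TAGS.get(t) for t in tags]
    if "shift" not in cols or "residue_number" not in cols:
        raise ShiftTableError("NMR-STAR-like block lacks residue/shift tags")
    out = {c: [] for c in COLUMNS}
    for row in rows:
        rec = dict.fromkeys(COLUMNS)
        for col, val in zip(cols, row):
            if col is not None and rec.get(col) is None:
                rec[col] = val
        rt = rec["residue_type"] or "X"
        rec["residue_type"] = _THREE_TO_ONE.get(rt.upper(), rt)
        for c in COLUMNS:
            out[c].append(rec[c])
    return pd.DataFrame(out)


def read_shift_table(source: str | Path) -> ChemicalShiftTable:
    """Read a shift table from a path or from literal text.

    Accepts comma/tab/whitespace-delimited text with a header naming the
    columns ``residue_number, residue_type, atom_name, shift`` (any order),
    or an NMR-STAR-like ``loop_`` block with standard atom-shift tags.
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    lines = text.splitlines()
    if any(line.strip() == "loop_" for line in lines):
        df = _read_star_like(lines)
    else:
        body = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
        if not body:
            raise ShiftTableError("empty shift table source")
        sep = "," if "," in body[0] else r"\s+"
        df = pd.read_csv(io.StringIO("\n".join(body)), sep=sep, engine="python")
        df.columns = [c.strip().lower() for c in df.columns]
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ShiftTableError(f"missing columns: {missing}")
    for i, val in enumerate(df["shift"]):
        try:
            float(val)
        except (TypeError, ValueError):
            raise ShiftTableError(f"unparsable shift {val!r} in data row {i + 1}")
    return ChemicalShiftTable(df)


def parse_assignment_label(label: str) -> tuple[int, tuple[str, ...]] | None:
    """Parse a Sparky-style assignment label like ``I86CB-HB`` or ``A82N-H``.

    Returns (residue_number, atom names) or ``None`` for unassigned (``?``).
    Pseudo-atom ``Q`` prefixes (one peak for several equivalent protons) are
    aliased to the corresponding ``H`` group.
    """
    label = label.strip()
    if label in ("?", "?-?", ""):
        return None
    m = re.match(r"^([A-Z])(\d+)([A-Z][A-Z0-9']*)((?:-[A-Z][A-Z0-9']*)+)$", label)
    if m is None:
        raise ShiftTableError(f"cannot parse assignment label {label!r}")
    atoms = [m.group(3)] + m.group(4).lstrip("-").split("-")
    atoms = [("H" + a[1:]) if a.startswith("Q") else a for a in atoms]
    return int(m.group(2)), tuple(atoms)
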