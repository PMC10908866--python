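"""Packaged reference chemical-shift library.

Two sources are shipped as a static in-repo table (never fetched at
run time): ``bmrb_average`` — approximate database-average shifts with
standard deviations — and ``random_coil`` — random-coil reference values
used for secondary-shift (helicity) analysis.  See docs/methods.md for
provenance; the snapshot is approximate, not a specific database release.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

SOURCES = ("bmrb_average", "random_coil")


class ReferenceLookupError(KeyError):
    pass


@dataclass(frozen=True)
class ShiftStatistic:
    mean: float  # ppm
    sd: float    # ppm
    n: int | None = None


class ReferenceShiftLibrary:
    def __init__(self, df: pd.DataFrame):
        self.df = df
        self._index = {
            (r, a, s): ShiftStatistic(m, sd)
            for r, a, s, m, sd in df[
                ["residue_type", "atom_name", "source", "mean_ppm", "sd_ppm"]
            ].itertuples(index=False)
        }

    def lookup(
        self, residue_type: str, atom_name: str, source: str = "bmrb_average"
    ) -> ShiftStatistic:
        if source not in SOURCES:
            raise ReferenceLookupError(f"unknown source {source!r}")
        key = (residue_type, atom_name, source)
        if key not in self._index:
            raise ReferenceLookupError(
                f"no {source} entry for ({residue_type}, {atom_name})"
            )
        return self._index[key]

    def has(self, residue_type: str, atom_name: str, source: str) -> bool:
        return (residue_type, atom_name, source) in self._index

    def atoms_for(self, residue_type: str, source: str = "bmrb_average") -> list[str]:
        sel = self.df[
            (self.df["residue_type"] == residue_type) & (self.df["source"] == source)
        ]
        return list(sel["atom_name"])

    def check_complete(self) -> None:
        """Every residue type must have CA, HA and (except Gly) CB in both sources."""
        missing = []
        for res in "ACDEFGHIKLMNPQRSTVWY":
            atoms = ["CA", "HA"] + ([] if res == "G" else ["CB"])
            for atom in atoms:
                for source in SOURCES:
                    if not self.has(res, atom, source):
                        missing.append((res, atom, source))
        if missing:
            raise ReferenceLookupError(f"incomplete reference library: {missing}")


def load_reference_library() -> ReferenceShiftLibrary:
    ref = importlib.resources.files("mtdyn.data") / "reference_shifts.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return ReferenceShiftLibrary(df)


def lookup_reference_shift(
    residue_type: str,
    atom_name: str,
    library: ReferenceShiftLibrary,
    source: str = "bmrb_average",
) -> ShiftStatistic:
    """Deterministic lookup of (residue type, atom) in the packaged library."""
    return library.lookup(residue_type, atom_name, source)
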