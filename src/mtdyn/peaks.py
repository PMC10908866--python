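"""Sparky-style peak lists.

Peaks carry ppm coordinates in acquisition order (13C before 1H for CH
experiments, 1H before 15N for NH-TROSY), an intensity, optional linewidths
(FWHM, ppm) and an assignment label.  Round-trips through text are exact at
four decimals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .shifts import parse_assignment_label


class PeakListError(ValueError):
    pass


@dataclass
class Peak:
    position: tuple[float, ...]
    intensity: float = 1.0
    linewidth: tuple[float, ...] | None = None
    label: str = "?"

    @property
    def assignment(self) -> tuple[int, tuple[str, ...]] | None:
        return parse_assignment_label(self.label)


@dataclass
class PeakList:
    dims: int
    peaks: list[Peak] = field(default_factory=list)
    channel: str = "none"  # dipolar | scalar | none
    experiment: str = ""   # e.g. CH-2D, CCH-3D, NH-TROSY
    condition: dict = field(default_factory=dict)  # salt_mM, ligand_uM, ...

    def __post_init__(self):
        for p in self.peaks:
            if len(p.position) != self.dims:
                raise PeakListError(
                    f"peak {p.label!r} has {len(p.position)} coordinates, "
                    f"list is {self.dims}-dimensional"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def by_label(self) -> dict[str, Peak]:
        return {p.label: p for p in self.peaks if p.label != "?"}

    def write(self, path: str | Path | None = None) -> str | None:
        w_cols = " ".join(f"{'w' + str(i + 1):>9s}" for i in range(self.dims))
        lines = [f"{'Assignment':>14s} {w_cols} {'Height':>12s}"]
        for p in self.peaks:
            coords = " ".join(f"{x:9.4f}" for x in p.position)
            line = f"{p.label:>14s} {coords} {p.intensity:12.6g}"
            if p.linewidth is not None:
                line += " " + " ".join(f"{lw:7.4f}" for lw in p.linewidth)
            lines.append(line)
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        Path(path).write_text(text)
        return None


def read_peak_list(
    source: str | Path,
    dims: int,
    channel: str = "none",
    experiment: str = "",
    condition: dict | None = None,
) -> PeakList:
    """Read a whitespace-delimited Sparky-style peak list.

    Columns: assignment label (``?`` if unassigned), w1..wN in ppm, then
    optionally intensity and per-dimension linewidths.
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    peaks: list[Peak] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.lower().startswith("assignment") or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 1 + dims:
            raise PeakListError(
                f"row {line!r}: expected at least {1 + dims} columns for "
                f"{dims}-dimensional peaks"
            )
        label = fields[0]
        try:
            position = tuple(float(x) for x in fields[1 : 1 + dims])
        except ValueError:
            raise PeakListError(f"row {line!r}: unparsable ppm value")
        rest = [float(x) for x in fields[1 + dims :]]
        intensity = rest[0] if rest else 1.0
        linewidth = tuple(rest[1 : 1 + dims]) if len(rest) > dims else None
        # sanity: a float column count that matches neither "+height" nor
        # "+height+linewidths" signals a dims mismatch
        if len(rest) not in (0, 1, 1 + dims):
            raise PeakListError(
                f"row {line!r}: column count does not match dims={dims}"
            )
        peaks.append(Peak(position, intensity, linewidth, label))
    return PeakList(dims, peaks, channel, experiment, condition or {})


def ch_label(residue_type: str, residue_number: int, c_atom: str, h_atom: str) -> str:
    return f"{residue_type}{residue_number}{c_atom}-{h_atom}"


def nh_label(residue_type: str, residue_number: int) -> str:
    return f"{residue_type}{residue_number}H-N"
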