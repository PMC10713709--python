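"""Multi-frame XYZ trajectory I/O and subsampling.

Units are fixed project-wide: Ångström for coordinates, picoseconds for
time.  The comment line of each XYZ block carries a ``t= <ps>`` token on
write; on read the token is optional and a uniform spacing may be supplied
instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "Frame",
    "Trajectory",
    "XyzParseError",
    "read_xyz_trajectory",
    "write_xyz",
    "subsample",
]

# Symbols of the first six periods -- enough for any organometallic system.
_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm",
    "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W",
    "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
}

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eEdD]+)")


class XyzParseError(ValueError):
    """Raised for malformed XYZ input; the message names the frame index."""


def _normalize_symbol(raw: str, frame_number: int) -> str:
    sym = raw.strip().capitalize()
    if sym not in _ELEMENTS:
        raise XyzParseError(
            f"frame {frame_number}: unknown element symbol {raw!r}"
        )
    return sym


@dataclass
class Frame:
    """One snapshot: element symbols plus Cartesian coordinates (Å)."""

    index: int
    time: float  # ps
    elements: list[str]
    coords: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError(
                f"frame {self.index}: {len(self.elements)} element symbols "
                f"but {self.coords.shape[0]} coordinate rows"
            )
        if self.time < 0:
            raise ValueError(f"frame {self.index}: negative time {self.time}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class Trajectory:
    """Ordered frames sharing one element list.

    Frame times must be strictly increasing; spacing may be irregular.
    """

    frames: list[Frame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames:
            ref = self.frames[0].elements
            for fr in self.frames[1:]:
                if fr.elements != ref:
                    raise ValueError(
                        f"frame {fr.index}: element list differs from frame 0"
                    )
            times = [fr.time for fr in self.frames]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def native_spacing(self) -> float:
        """Median inter-frame spacing (ps); 0.0 for <2 frames."""
        if len(self.frames) < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))


def read_xyz_trajectory(
    path: str | Path, frame_spacing: float | None = None
) -> Trajectory:
    """Read a multi-frame XYZ file.

    The comment line is scanned for a ``t= <ps>`` token; where absent, times
    are assigned as ``index * frame_spacing`` (default spacing 1.0 ps).  The
    reader does not otherwise depend on the comment-line content.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    spacing = 1.0 if frame_spacing is None else float(frame_spacing)
    while pos < len(lines):
        if not lines[pos].strip():  # trailing blank lines
            pos += 1
            continue
        fidx = len(frames)
        # error messages number frames from 1, matching how runs are discussed
        fnum = fidx + 1
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise XyzParseError(
                f"frame {fnum}: expected atom count, got {lines[pos]!r}"
            ) from None
        if pos + 2 + natoms > len(lines):
            raise XyzParseError(
                f"frame {fnum}: declares {natoms} atoms but file is truncated"
            )
        comment = lines[pos + 1]
        m = _TIME_RE.search(comment)
        time = float(m.group(1).replace("D", "e").replace("d", "e")) if m \
            else fidx * spacing
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for i in range(natoms):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise XyzParseError(
                    f"frame {fnum}: atom line {i} has {len(parts)} fields, "
                    "expected 'El x y z'"
                )
            elements.append(_normalize_symbol(parts[0], fnum))
            try:
                coords[i] = [float(v) for v in parts[1:4]]
            except ValueError:
                raise XyzParseError(
                    f"frame {fnum}: non-numeric coordinate on atom line {i}"
                ) from None
        frames.append(Frame(index=fidx, time=time, elements=elements,
                            coords=coords))
        pos += 2 + natoms
    if frames:
        ref = frames[0].elements
        for fr in frames:
            if fr.elements != ref:
                raise XyzParseError(
                    f"frame {fr.index + 1}: atom list inconsistent with frame 1"
                )
    return Trajectory(frames=frames, metadata={"source": str(path)})


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as standard multi-frame XYZ, 6-decimal precision."""
    path = Path(path)
    with path.open("w") as fh:
        for fr in traj:
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"t= {fr.time:.6f}\n")
            for el, (x, y, z) in zip(fr.elements, fr.coords):
                fh.write(f"{el:<2s} {x:15.6f} {y:15.6f} {z:15.6f}\n")


def subsample(traj: Trajectory, rate: float) -> Trajectory:
    """Keep frames whose time is an integer multiple of ``rate`` (ps).

    Matching tolerance is half the native spacing, so a 100-ps trajectory
    stored every 50 fs subsampled at 1 ps keeps exactly the 100 frames at
    t = 1, 2, ... 100 ps.  Idempotent, order-preserving, never invents
    frames.
    """
    if rate <= 0:
        raise ValueError(f"subsample rate must be positive, got {rate}")
    spacing = traj.native_spacing
    if spacing and rate < spacing - 1e-12:
        raise ValueError(
            f"rate {rate} ps is finer than the native spacing {spacing} ps"
        )
    tol = spacing / 2 if spacing else 1e-9
    kept = []
    for fr in traj.frames:
        k = round(fr.time / rate)
        if abs(fr.time - k * rate) < max(tol, 1e-9):
            kept.append(fr)
    new = [
        Frame(index=i, time=fr.time, elements=fr.elements, coords=fr.coords)
        for i, fr in enumerate(kept)
    ]
    return Trajectory(frames=new, metadata=dict(traj.metadata))
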