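"""Fragment pair-interaction-energy (PIE) bookkeeping.

The structures are partitioned into five fragments — the [Cp*Rh]2+ scaffold
(id 1), three waters (ids 2–4) and the aromatic ligand X (id 5).  Each
fragment pair carries a total pair interaction energy and its five-term
energy decomposition (electrostatic, exchange-repulsion, charge-transfer,
dispersion, solvation), which must sum to the total.  On top of that data
model this module provides

* ``e_int``      — ligand–complex interaction energy: the sum of the PIEs
                   between X and the four metal-complex fragments, an
                   encounter-complex stability estimate;
* ``tpie``       — total PIE: the sum over all unordered fragment pairs;
* ``delta_tpie`` — TPIE(product adduct) − TPIE(encounter complex), the
                   PIE-based estimator of the ligand-exchange reaction
                   enthalpy;
* explicit-water series fits and crossing estimates, η6-segment statistics,
  per-component η6 averages and fragment-charge tracking.

All energies are kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EDA_COMPONENTS",
    "Fragment",
    "FragmentScheme",
    "PieRecord",
    "PieTable",
    "PieTableError",
    "WaterSeriesPoint",
    "parse_pie_table",
    "write_pie_table",
    "e_int",
    "tpie",
    "delta_tpie",
    "relative_series",
    "water_series_analysis",
    "eta6_segment_stats",
    "eda_segment_means",
    "charge_series",
]

EDA_COMPONENTS = ("E_es", "E_ex", "E_ct", "E_disp", "E_solv")

PIE_COLUMNS = (
    "frame", "time_ps", "frag_i", "frag_j",
    *EDA_COMPONENTS, "PIE_total",
)

# component sum must match the total at parse time; generated tables are exact
CLOSURE_TOL = 1e-3


class PieTableError(ValueError):
    """Malformed or inconsistent PIE table."""


@dataclass
class Fragment:
    atoms: list[int]
    label: str


@dataclass
class FragmentScheme:
    """Partition of atom indices into the five FMO fragments, plus roles.

    ``rings`` maps a ring name (e.g. ``"phenyl"``, ``"pyrrole"``) to the
    ordered indices of its ring atoms; ``heteroatoms`` maps a coordinating
    heteroatom index to its element kind; ``donors`` lists (donor, H) index
    pairs for hydrogen-bond analysis.  The ``merged`` variant moves the
    H-bond-partner water's atoms into the X fragment (keeping id 5), as
    used when the ligand and its directly H-bonded water are treated as one
    fragment.
    """

    fragments: dict[int, Fragment]
    rh_index: int | None = None
    rings: dict[str, list[int]] = field(default_factory=dict)
    heteroatoms: dict[int, str] = field(default_factory=dict)
    water_oxygens: list[int] = field(default_factory=list)
    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    variant: str = "separate"

    def __post_init__(self) -> None:
        all_atoms: list[int] = []
        for frag in self.fragments.values():
            all_atoms.extend(frag.atoms)
        if len(all_atoms) != len(set(all_atoms)):
            raise ValueError("fragment atom sets overlap")
        x_ids = [i for i, f in self.fragments.items() if f.label == "X"]
        if len(x_ids) != 1:
            raise ValueError("exactly one fragment must be labelled 'X'")

    @property
    def n_atoms(self) -> int:
        return sum(len(f.atoms) for f in self.fragments.values())

    @property
    def x_id(self) -> int:
        return next(i for i, f in self.fragments.items() if f.label == "X")

    @property
    def scaffold_id(self) -> int:
        return next(
            i for i, f in self.fragments.items() if f.label == "CpRh-scaffold"
        )

    @property
    def fragment_ids(self) -> list[int]:
        return sorted(self.fragments)

    def atoms_of(self, fragment_id: int) -> list[int]:
        return self.fragments[fragment_id].atoms

    def merged(self, water_id: int) -> "FragmentScheme":
        """Return the variant with water ``water_id``'s atoms folded into X."""
        if self.fragments[water_id].label == "X":
            raise ValueError("cannot merge X into itself")
        frags = {
            i: Fragment(list(f.atoms), f.label)
            for i, f in self.fragments.items()
            if i != water_id
        }
        frags[self.x_id].atoms = (
            self.fragments[self.x_id].atoms + self.fragments[water_id].atoms
        )
        return replace(self, fragments=frags, variant="merged")

    # -- YAML round trip (scheme files used by the CLI) ------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "fragments": {
                int(i): {"atoms": [int(a) for a in f.atoms], "label": f.label}
                for i, f in self.fragments.items()
            },
            "rh_index": self.rh_index,
            "rings": {k: [int(a) for a in v] for k, v in self.rings.items()},
            "heteroatoms": {int(k): v for k, v in self.heteroatoms.items()},
            "water_oxygens": [int(a) for a in self.water_oxygens],
            "donors": [[int(d), int(h)] for d, h in self.donors],
            "acceptors": [int(a) for a in self.acceptors],
            "variant": self.variant,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FragmentScheme":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            fragments={
                int(i): Fragment(list(entry["atoms"]), entry["label"])
                for i, entry in doc["fragments"].items()
            },
            rh_index=doc.get("rh_index"),
            rings={k: list(v) for k, v in doc.get("rings", {}).items()},
            heteroatoms={int(k): v
                         for k, v in doc.get("heteroatoms", {}).items()},
            water_oxygens=list(doc.get("water_oxygens", [])),
            donors=[tuple(p) for p in doc.get("donors", [])],
            acceptors=list(doc.get("acceptors", [])),
            variant=doc.get("variant", "separate"),
        )


@dataclass
class PieRecord:
    """One fragment pair in one frame; components sum to the total."""

    frame: int
    pair: tuple[int, int]
    E_es: float
    E_ex: float
    E_ct: float
    E_disp: float
    E_solv: float
    pie_total: float
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        i, j = self.pair
        if i == j:
            raise ValueError("a pair must join two distinct fragments")
        self.pair = (min(i, j), max(i, j))

    @property
    def components(self) -> tuple[float, ...]:
        return (self.E_es, self.E_ex, self.E_ct, self.E_disp, self.E_solv)

    @property
    def closure_error(self) -> float:
        return abs(sum(self.components) - self.pie_total)


class PieTable:
    """Per-frame, per-pair PIE records with optional fragment charges.

    Backed by a pandas DataFrame with the documented TSV columns; at most
    one record per (frame, pair).
    """

    def __init__(self, df: pd.DataFrame,
                 charges: pd.DataFrame | None = None) -> None:
        df = df.copy()
        lo = df[["frag_i", "frag_j"]].min(axis=1)
        hi = df[["frag_i", "frag_j"]].max(axis=1)
        if (lo == hi).any():
            raise PieTableError("self-pair (I == J) found")
        df["frag_i"], df["frag_j"] = lo, hi
        dup = df.duplicated(subset=["frame", "frag_i", "frag_j"])
        if dup.any():
            row = df[dup].iloc[0]
            raise PieTableError(
                f"duplicate record for frame {int(row.frame)} pair "
                f"({int(row.frag_i)}, {int(row.frag_j)})"
            )
        err = (df[list(EDA_COMPONENTS)].sum(axis=1) - df["PIE_total"]).abs()
        if (err > CLOSURE_TOL).any():
            row = df[err > CLOSURE_TOL].iloc[0]
            raise PieTableError(
                "EDA components do not sum to PIE_total "
                f"(|error| {err.max():.3g}) at frame {int(row.frame)} pair "
                f"({int(row.frag_i)}, {int(row.frag_j)})"
            )
        self.df = df.sort_values(
            ["frame", "frag_i", "frag_j"], kind="stable"
        ).reset_index(drop=True)
        self.charges = charges.copy() if charges is not None else None

    # ------------------------------------------------------------------
    @property
    def n_fragments(self) -> int:
        return len(
            set(self.df["frag_i"]).union(self.df["frag_j"])
        )

    @property
    def frames(self) -> list[int]:
        return sorted(self.df["frame"].unique())

    def frame_records(self, frame: int) -> pd.DataFrame:
        sub = self.df[self.df["frame"] == frame]
        if sub.empty:
            raise KeyError(f"no records for frame {frame}")
        return sub

    def pair_value(self, frame: int, pair: tuple[int, int],
                   column: str = "PIE_total") -> float:
        i, j = min(pair), max(pair)
        sub = self.df[
            (self.df["frame"] == frame)
            & (self.df["frag_i"] == i)
            & (self.df["frag_j"] == j)
        ]
        if sub.empty:
            raise KeyError(f"no record for frame {frame} pair ({i}, {j})")
        return float(sub[column].iloc[0])

    def pair_series(self, pair: tuple[int, int],
                    column: str = "PIE_total") -> pd.Series:
        """Per-frame values for one pair, indexed by frame."""
        i, j = min(pair), max(pair)
        sub = self.df[(self.df["frag_i"] == i) & (self.df["frag_j"] == j)]
        return sub.set_index("frame")[column]

    def records(self) -> Iterable[PieRecord]:
        for row in self.df.itertuples(index=False):
            yield PieRecord(
                frame=int(row.frame), pair=(int(row.frag_i), int(row.frag_j)),
                E_es=row.E_es, E_ex=row.E_ex, E_ct=row.E_ct,
                E_disp=row.E_disp, E_solv=row.E_solv,
                pie_total=row.PIE_total, time_ps=float(row.time_ps),
            )


def parse_pie_table(path: str | Path,
                    charges_path: str | Path | None = None) -> PieTable:
    """Read the tab-separated PIE dialect (and an optional charge file).

    Columns: ``frame  time_ps  frag_i  frag_j  E_es  E_ex  E_ct  E_disp
    E_solv  PIE_total``; charge file: ``frame  frag  charge``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(PIE_COLUMNS) - set(df.columns)
    if missing:
        raise PieTableError(f"missing columns: {sorted(missing)}")
    charges = None
    if charges_path is not None:
        charges = pd.read_csv(charges_path, sep="\t")
        if set(charges.columns) < {"frame", "frag", "charge"}:
            raise PieTableError("charge file needs frame/frag/charge columns")
    return PieTable(df[list(PIE_COLUMNS)], charges)


def write_pie_table(table: PieTable, path: str | Path,
                    charges_path: str | Path | None = None) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    if charges_path is not None and table.charges is not None:
        table.charges.to_csv(charges_path, sep="\t", index=False,
                             float_format="%.6f")


# ----------------------------------------------------------------------
# scalar bookkeeping
# ----------------------------------------------------------------------

def e_int(table: PieTable, frame: int, scheme: FragmentScheme) -> float:
    """Ligand–complex interaction energy for one frame.

    Sum of the PIEs between the X fragment and every other fragment of the
    aquo complex.  Missing X pairs are an error: silently treating them as
    zero would corrupt the estimate.
    """
    x = scheme.x_id
    others = [i for i in scheme.fragment_ids if i != x]
    if not others:
        raise PieTableError("scheme has no non-X fragments")
    return float(sum(table.pair_value(frame, (x, i)) for i in others))


def tpie(table: PieTable, frame: int) -> float:
    """Total PIE of one frame: sum over all unordered fragment pairs."""
    sub = table.frame_records(frame)
    return float(sub["PIE_total"].sum())


def delta_tpie(tpie_pa: float, tpie_ec: float) -> float:
    """TPIE difference, product adduct minus encounter complex.

    Because the ligand exchange breaks no covalent bonds, this difference
    estimates the reaction enthalpy.
    """
    return tpie_pa - tpie_ec


def relative_series(values: Sequence[float], reference: int = 0) -> list[float]:
    """Shift a series so the reference entry maps to 0.0."""
    if len(values) == 0:
        raise ValueError("empty series")
    ref = values[reference]
    return [float(v - ref) for v in values]


# ----------------------------------------------------------------------
# explicit-water series
# ----------------------------------------------------------------------

@dataclass
class WaterSeriesPoint:
    """X–scaffold PIE at a given number of explicit water molecules."""

    n_waters: int
    pie_x_scaffold: float
    variant: str = "separate"

    def __post_init__(self) -> None:
        if not 0 <= self.n_waters <= 3:
            raise ValueError("n_waters must be between 0 and 3")


@dataclass
class WaterSeriesFit:
    slope: float       # kcal/mol per water
    intercept: float   # kcal/mol at zero waters
    n_points: int

    def predict(self, n: float) -> float:
        return self.slope * n + self.intercept


def _fit_line(points: Sequence[WaterSeriesPoint]) -> WaterSeriesFit:
    if len(points) < 2:
        raise ValueError("need at least two points per ligand")
    x = np.array([p.n_waters for p in points], dtype=float)
    y = np.array([p.pie_x_scaffold for p in points], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return WaterSeriesFit(float(slope), float(intercept), len(points))


def water_series_analysis(
    points: Mapping[str, Sequence[WaterSeriesPoint]],
) -> dict:
    """Linear trends of X–scaffold PIE vs explicit-water count.

    Returns per-ligand least-squares fits and, for every ligand pair, the
    analytically solved crossing water count; a crossing outside the
    observed range is flagged ``extrapolated``, identical slopes are
    reported as no crossing.
    """
    fits = {lig: _fit_line(pts) for lig, pts in points.items()}
    crossings: dict[tuple[str, str], dict | None] = {}
    ligs = sorted(points)
    for a_i, a in enumerate(ligs):
        for b in ligs[a_i + 1:]:
            fa, fb = fits[a], fits[b]
            dslope = fa.slope - fb.slope
            if abs(dslope) < 1e-12:
                crossings[(a, b)] = None
                continue
            n_cross = (fb.intercept - fa.intercept) / dslope
            observed = [p.n_waters for p in points[a]] + \
                       [p.n_waters for p in points[b]]
            crossings[(a, b)] = {
                "n": float(n_cross),
                "pie": fa.predict(n_cross),
                "extrapolated": not (min(observed) <= n_cross <= max(observed)),
            }
    return {"fits": fits, "crossings": crossings}


# ----------------------------------------------------------------------
# η6-segment statistics and charge tracking
# ----------------------------------------------------------------------

def _eta6_mask(states: Sequence) -> np.ndarray:
    return np.array([getattr(s, "hapticity", s) == 6 for s in states])


def eta6_segment_stats(pie_series: Sequence[float],
                       states: Sequence) -> tuple[float, float, int] | None:
    """Mean, sample sd and count of the PIE over η6-labelled frames.

    ``states`` may be CoordinationState objects or plain hapticity counts.
    Returns None when no frame is η6 (an empty statistic, not a number).
    """
    pie = np.asarray(pie_series, dtype=float)
    if len(pie) != len(states):
        raise ValueError("PIE series and state series lengths differ")
    mask = _eta6_mask(states)
    n = int(mask.sum())
    if n == 0:
        return None
    seg = pie[mask]
    sd = float(np.std(seg, ddof=1)) if n > 1 else 0.0
    return float(seg.mean()), sd, n


def eda_segment_means(table: PieTable, states: Sequence,
                      pair: tuple[int, int]) -> dict[str, float] | None:
    """Average each EDA component of one pair over η6 frames.

    The component means sum to the total mean exactly (linearity of the
    mean).  Returns None when no frame is η6.
    """
    frames = table.frames
    if len(frames) != len(states):
        raise ValueError("table frames and state series lengths differ")
    mask = _eta6_mask(states)
    keep = [f for f, m in zip(frames, mask) if m]
    if not keep:
        return None
    i, j = min(pair), max(pair)
    sub = table.df[
        (table.df["frag_i"] == i) & (table.df["frag_j"] == j)
        & table.df["frame"].isin(keep)
    ]
    out = {c: float(sub[c].mean()) for c in EDA_COMPONENTS}
    out["PIE_total"] = float(sub["PIE_total"].mean())
    return out


def charge_series(table: PieTable, fragment: int) -> pd.Series:
    """Per-frame FMO charge of one fragment (e.g. Q3 of the scaffold)."""
    if table.charges is None:
        raise PieTableError("table carries no fragment charges")
    sub = table.charges[table.charges["frag"] == fragment]
    if sub.empty:
        raise PieTableError(f"no charges recorded for fragment {fragment}")
    return sub.set_index("frame")["charge"].sort_index()
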