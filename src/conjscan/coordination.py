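"""Per-frame Rh coordination analysis.

Hapticity is assigned from plain distance criteria: a ring C (or pyrrolic
N) counts as bound to Rh when its distance is strictly below 3.0 Å, a
phenolic or water O when strictly below 2.5 Å.  The hapticity ηn of a ring
is the number of its atoms simultaneously bound; bicyclic ligands are
book-kept per ring and labelled by the dominant ring (ties broken toward
the phenyl ring).  A bound heteroatom alone is κ1; a heteroatom bound
together with two ring carbons gives the composite η3(O,C1,C2) motif seen
for phenol-type ligands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fmo_energetics import FragmentScheme
from .traj_io import Frame, Trajectory

__all__ = [
    "CoordinationThresholds",
    "CoordinationState",
    "Event",
    "rh_distances",
    "assign_state",
    "state_series",
    "detect_events",
    "replay_water_counts",
    "hydrogen_bonds",
]


@dataclass
class CoordinationThresholds:
    """Distance (Å) and angle (deg) criteria for bonding assignments.

    ``cn_rh_bond`` applies to ring C and to N donors; ``o_rh_bond`` to the
    phenolic O; ``water_o_rh_bond`` to water oxygens.  Comparisons are
    strict: an atom exactly at the threshold is unbound.
    """

    cn_rh_bond: float = 3.0
    o_rh_bond: float = 2.5
    water_o_rh_bond: float = 2.5
    hbond_da_max: float = 3.5
    hbond_angle_min: float = 120.0

    def __post_init__(self) -> None:
        for name in ("cn_rh_bond", "o_rh_bond", "water_o_rh_bond",
                     "hbond_da_max"):
            v = getattr(self, name)
            if not 0 < v < 5.0:
                raise ValueError(f"{name} must be in (0, 5) Å, got {v}")


@dataclass
class CoordinationState:
    """Coordination picture of one frame."""

    frame: int
    time: float
    bound_ring_atoms: dict[str, frozenset[int]]
    bound_heteroatoms: frozenset[int]
    bound_water_count: int
    hapticity: int          # bound-atom count of the dominant ring
    dominant_ring: str | None
    label: str

    @property
    def is_unbound(self) -> bool:
        return self.hapticity == 0 and not self.bound_heteroatoms


@dataclass(frozen=True)
class Event:
    kind: str   # water_release | water_rebind | eta_up | eta_down | ligand_detach
    frame: int
    size: int = 1   # magnitude of the step (e.g. waters released at once)


def rh_distances(frame: Frame, scheme: FragmentScheme) -> pd.DataFrame:
    """Distances from Rh to every monitored atom (ring C/N, heteroatoms,
    water O); one row per atom."""
    if scheme.rh_index is None:
        raise ValueError("scheme does not identify the Rh atom")
    rows = []
    rh = frame.coords[scheme.rh_index]
    for ring, atoms in scheme.rings.items():
        for a in atoms:
            rows.append((a, "ring", ring))
    for a, kind in scheme.heteroatoms.items():
        rows.append((a, f"het_{kind}", ""))
    for a in scheme.water_oxygens:
        rows.append((a, "water_O", ""))
    idx = [r[0] for r in rows]
    dist = np.linalg.norm(frame.coords[idx] - rh, axis=1)
    return pd.DataFrame({
        "atom": idx,
        "role": [r[1] for r in rows],
        "ring": [r[2] for r in rows],
        "distance": dist,
    })


def _hapticity_label(
    ring_counts: dict[str, int],
    dominant: str | None,
    het_bound: dict[int, str],
) -> str:
    n = ring_counts.get(dominant, 0) if dominant else 0
    het_kinds = sorted(set(het_bound.values()))
    if n == 0 and not het_kinds:
        return "unbound"
    if n == 0:
        return "+".join(f"κ1-{k}" for k in het_kinds)
    ring_part = f"η{n}"
    if len(ring_counts) > 1 and dominant:
        ring_part += f"({dominant})"
    if not het_kinds:
        return ring_part
    # heteroatom and ring simultaneously bound
    if "O" in het_kinds and n == 2:
        return "η3(O,C1,C2)"
    return "+".join(f"κ1-{k}" for k in het_kinds) + "+" + ring_part


def assign_state(
    frame: Frame,
    scheme: FragmentScheme,
    thr: CoordinationThresholds | None = None,
) -> CoordinationState:
    """Classify one frame's Rh coordination by the distance criteria."""
    thr = thr or CoordinationThresholds()
    dist = rh_distances(frame, scheme)
    by_atom = dict(zip(dist["atom"], dist["distance"]))

    bound_rings: dict[str, frozenset[int]] = {}
    for ring, atoms in scheme.rings.items():
        bound_rings[ring] = frozenset(
            a for a in atoms if by_atom[a] < thr.cn_rh_bond
        )
    het_bound = {
        a: kind
        for a, kind in scheme.heteroatoms.items()
        if by_atom[a] < (thr.o_rh_bond if kind == "O" else thr.cn_rh_bond)
    }
    waters = sum(
        1 for a in scheme.water_oxygens if by_atom[a] < thr.water_o_rh_bond
    )
    counts = {r: len(s) for r, s in bound_rings.items()}
    dominant = None
    if any(counts.values()):
        best = max(counts.values())
        tied = [r for r, c in counts.items() if c == best]
        # tie toward the phenyl ring where the scheme names one
        dominant = next((r for r in tied if r == "phenyl"), tied[0])
    return CoordinationState(
        frame=frame.index,
        time=frame.time,
        bound_ring_atoms=bound_rings,
        bound_heteroatoms=frozenset(het_bound),
        bound_water_count=waters,
        hapticity=counts.get(dominant, 0) if dominant else 0,
        dominant_ring=dominant,
        label=_hapticity_label(counts, dominant, het_bound),
    )


def state_series(
    traj: Trajectory,
    scheme: FragmentScheme,
    thr: CoordinationThresholds | None = None,
) -> list[CoordinationState]:
    """assign_state applied frame-by-frame, order preserved."""
    return [assign_state(fr, scheme, thr) for fr in traj]


# ----------------------------------------------------------------------
# event detection
# ----------------------------------------------------------------------

def _step_events(values: Sequence[int], up: str, down: str,
                 min_dwell: int) -> list[Event]:
    """Debounced transitions of an integer series.

    A change at frame i is emitted only if the series does not revert past
    the new value within the following ``min_dwell`` frames: a decrease
    must not be followed by a value above the new one inside the window
    (and symmetrically for increases).  Single-frame flicker is thereby
    suppressed while a fast monotone cascade still yields one event per
    step.
    """
    events: list[Event] = []
    n = len(values)
    for i in range(1, n):
        prev, cur = values[i - 1], values[i]
        if cur == prev:
            continue
        window = values[i:min(n, i + min_dwell)]
        if cur < prev and all(v <= cur for v in window):
            events.append(Event(down, i, prev - cur))
        elif cur > prev and all(v >= cur for v in window):
            events.append(Event(up, i, cur - prev))
    return events


def detect_events(states: Sequence[CoordinationState],
                  min_dwell: int = 3) -> list[Event]:
    """Water release/rebind, hapticity up/down and ligand-detach events.

    Events are debounced (a condition must persist ``min_dwell`` frames)
    and returned time-ordered.
    """
    if not states:
        raise ValueError("empty state series")
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    water = [s.bound_water_count for s in states]
    eta = [s.hapticity for s in states]
    contact = [0 if s.is_unbound else 1 for s in states]
    events = _step_events(water, "water_rebind", "water_release", min_dwell)
    events += _step_events(eta, "eta_up", "eta_down", min_dwell)
    events += [
        e for e in _step_events(contact, "ligand_attach", "ligand_detach",
                                min_dwell)
        if e.kind == "ligand_detach"
    ]
    return sorted(events, key=lambda e: (e.frame, e.kind))


def replay_water_counts(initial: int, events: Sequence[Event],
                        n_frames: int) -> list[int]:
    """Reconstruct the debounced bound-water series from release/rebind
    events; inverse check for detect_events."""
    out = []
    cur = initial
    ev = {e.frame: e for e in events
          if e.kind in ("water_release", "water_rebind")}
    for i in range(n_frames):
        if i in ev:
            cur += ev[i].size if ev[i].kind == "water_rebind" \
                else -ev[i].size
        out.append(cur)
    return out


# ----------------------------------------------------------------------
# hydrogen bonds
# ----------------------------------------------------------------------

def hydrogen_bonds(
    frame: Frame,
    scheme: FragmentScheme,
    thr: CoordinationThresholds | None = None,
) -> list[tuple[int, int, int]]:
    """Geometric H-bond contacts (donor, H, acceptor).

    Contact iff donor–acceptor distance < ``hbond_da_max`` and the D–H...A
    angle exceeds ``hbond_angle_min``; a donor never pairs with its own
    heavy atom.
    """
    thr = thr or CoordinationThresholds()
    out = []
    for d, h in scheme.donors:
        for a in scheme.acceptors:
            if a == d:
                continue
            vda = frame.coords[a] - frame.coords[d]
            rda = np.linalg.norm(vda)
            if rda >= thr.hbond_da_max:
                continue
            vhd = frame.coords[d] - frame.coords[h]
            vha = frame.coords[a] - frame.coords[h]
            cosang = np.dot(vhd, vha) / (
                np.linalg.norm(vhd) * np.linalg.norm(vha)
            )
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle > thr.hbond_angle_min:
                out.append((d, h, a))
    return out
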