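"""Helix-axis fitting and the inter-helix tilt-angle statistic.

The crossing angle between the two DNA-recognition helices of a dimeric
transcription factor discriminates the BZR architecture (≈78°) from the
canonical bHLH one (50–65°). The axis of a helix is fitted as the dominant
principal axis of its Cα positions — robust for the short (~10 residue)
basic-region helices this statistic is applied to — with its sign fixed to
point from the N-terminal toward the C-terminal end.

The tilt angle is folded to [0°, 90°] (arccos of the absolute dot product),
making the statistic independent of the N→C orientation convention; every
reported value in the regime of interest lies below 90°, so the fold is
observationally neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import StructureModel, Trajectory

__all__ = [
    "HelixRange",
    "HelixAxis",
    "TiltSeries",
    "fit_helix_axis",
    "tilt_angle",
    "tilt_angle_series",
    "detect_helices",
]

MIN_HELIX_RESIDUES = 6  # two helical turns; shorter ranges give unstable axes


@dataclass(frozen=True)
class HelixRange:
    """An inclusive author-numbered residue range on one chain."""

    chain_id: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.last_residue - self.first_residue < MIN_HELIX_RESIDUES - 1:
            raise ValueError(
                f"helix range {self.chain_id}:{self.first_residue}-{self.last_residue} "
                f"spans fewer than {MIN_HELIX_RESIDUES} residues"
            )

    @property
    def n_residues(self) -> int:
        return self.last_residue - self.first_residue + 1

    @classmethod
    def parse(cls, text: str) -> "HelixRange":
        """Parse 'CHAIN:FIRST-LAST', e.g. 'C:30-45'."""
        try:
            chain, _, span = text.partition(":")
            first_s, _, last_s = span.partition("-")
            return cls(chain, int(first_s), int(last_s))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"bad helix range {text!r}; expected CHAIN:FIRST-LAST") from exc


@dataclass(frozen=True)
class HelixAxis:
    """Fitted axis: Cα centroid anchor + unit direction oriented N→C."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("axis direction must be unit length within 1e-9")
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        object.__setattr__(self, "direction", d)


@dataclass
class TiltSeries:
    """Per-frame inter-helix angles in degrees with summary statistics."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values))


def _ca_coords_for_range(model: StructureModel, rng: HelixRange) -> np.ndarray:
    by_resnum: dict[int, np.ndarray] = {}
    for a in model.atoms:
        if a.chain_id == rng.chain_id and a.name == "CA":
            by_resnum.setdefault(a.residue_number, a.coordinates)
    coords = []
    for num in range(rng.first_residue, rng.last_residue + 1):
        if num not in by_resnum:
            raise ValueError(
                f"residue {rng.chain_id}:{num} has no Cα atom in the model"
            )
        coords.append(by_resnum[num])
    return np.stack(coords)


def fit_helix_axis(model: StructureModel, rng: HelixRange) -> HelixAxis:
    """Fit a helix axis to the Cα atoms of ``rng``.

    Direction = dominant principal axis (largest-variance direction) of the
    Cα coordinates after averaging over a one-turn (4-residue) sliding
    window; the turn averaging cancels the helical winding phase, which would
    otherwise tilt the raw principal axis of a short helix by several
    degrees. Sign is fixed so the direction points from the Cα of the first
    residue toward that of the last (residue numbers, not file order, govern
    orientation). Anchor = Cα centroid.
    """
    ca = _ca_coords_for_range(model, rng)
    centroid = ca.mean(axis=0)
    # one-turn moving average: ~3.6 residues/turn, window 4 cancels most of
    # the circular excursion while keeping >= 3 points for the 6-residue
    # minimum range
    window = 4
    smoothed = np.stack(
        [ca[i:i + window].mean(axis=0) for i in range(len(ca) - window + 1)]
    )
    centered = smoothed - smoothed.mean(axis=0)
    # dominant right singular vector == largest-variance principal axis
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    nc = ca[-1] - ca[0]
    if np.dot(direction, nc) < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    return HelixAxis(anchor=centroid, direction=direction)


def tilt_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Crossing angle between two axes in degrees, folded to [0°, 90°]."""
    for ax in (a, b):
        if not np.isclose(np.linalg.norm(ax.direction), 1.0, atol=1e-9):
            raise ValueError("axis directions must be unit vectors")
    cosine = abs(float(np.dot(a.direction, b.direction)))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def tilt_angle_series(traj: Trajectory, range_a: HelixRange, range_b: HelixRange) -> TiltSeries:
    """Per-frame axis fits for both ranges and their crossing angle."""
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.frame_model(i)
        axis_a = fit_helix_axis(frame, range_a)
        axis_b = fit_helix_axis(frame, range_b)
        values[i] = tilt_angle(axis_a, axis_b)
    return TiltSeries(values=values)


def detect_helices(model: StructureModel, chain_id: str) -> list[HelixRange]:
    """Propose helical residue ranges on one chain from Cα(i)→Cα(i+4) distances.

    In a regular α-helix the i→i+4 Cα distance sits near 6 Å (one turn);
    extended or coil geometry pushes it well outside [5.0, 6.5] Å. Maximal
    runs of residues passing the window, covering at least 6 residues, are
    returned. May return an empty list.
    """
    ca: list[tuple[int, np.ndarray]] = []
    seen: set[int] = set()
    for a in model.atoms:
        if a.chain_id == chain_id and a.name == "CA" and a.residue_number not in seen:
            seen.add(a.residue_number)
            ca.append((a.residue_number, a.coordinates))
    ca.sort(key=lambda t: t[0])
    if len(ca) < 7:
        raise ValueError(f"chain {chain_id!r} has {len(ca)} Cα atoms; need >= 7")
    nums = [n for n, _ in ca]
    coords = np.stack([c for _, c in ca])
    # i passes if residue i+4 is sequentially present and within the window
    passing: list[int] = []
    index_of = {n: i for i, n in enumerate(nums)}
    for n in nums:
        j = index_of.get(n + 4)
        if j is None:
            continue
        d = float(np.linalg.norm(coords[index_of[n]] - coords[j]))
        if 5.0 <= d <= 6.5:
            passing.append(n)
    ranges: list[HelixRange] = []
    run_start: int | None = None
    prev: int | None = None
    for n in passing + [None]:  # sentinel flushes the final run
        if run_start is not None and (n is None or n != prev + 1):
            first, last = run_start, prev + 4
            if last - first + 1 >= MIN_HELIX_RESIDUES:
                ranges.append(HelixRange(chain_id, first, last))
            run_start = None
        if n is not None and run_start is None:
            run_start = n
        prev = n
    return ranges
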