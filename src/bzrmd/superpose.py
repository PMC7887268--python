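"""Optimal rigid-body superposition (Kabsch) and trajectory RMSD.

The validation protocol fits every trajectory frame to the crystal reference
on one atom selection (the protein Cα atoms) and reports RMSD on possibly
different selections (Cα, DNA phosphorus atoms) of the fitted frame — the
fit-on / measure-on split is first-class here.

Superposition is unweighted: no mass or B-factor weights. SDs over frames
are population SDs (divide by n), so "mean ± SD" summaries are well-defined
descriptive statistics of the frame set itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Selection, StructureModel, Trajectory, select

__all__ = ["RigidTransform", "RmsdSeries", "kabsch_fit", "rmsd", "trajectory_rmsd"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: x ↦ R·x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthogonal within 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation determinant must be +1 (no reflections)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) for one measure selection, with summary stats."""

    values: np.ndarray
    fit_selection: str
    measure_selection: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        # population SD: descriptive spread of the recorded frames
        return float(np.std(self.values))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between paired coordinates; no fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not N×3: {a.shape} vs {b.shape}")
    if a.shape[0] < 1:
        raise ValueError("need at least one atom")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimizing RMSD over all rotations and
    translations, and the minimized RMSD. Reflections are excluded by flipping
    the sign of the smallest singular value when det(V·Wᵀ) < 0.

    Raises for fewer than 3 points or a degenerate (collinear) point set,
    for which the rotation about the common line is undetermined.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must share an N×3 shape: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 points, got {n}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinearity: the two smallest singular values of the covariance vanish
    scale = max(S[0], 1.0)
    if S[1] / scale < 1e-8:
        raise ValueError("ill-conditioned superposition: points are (nearly) collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    return transform, rmsd(transform.apply(P), Q)


def trajectory_rmsd(
    traj: Trajectory,
    reference: StructureModel,
    fit_selection: str,
    measure_selections: list[str] | tuple[str, ...],
) -> list[RmsdSeries]:
    """Per-frame fit on ``fit_selection``; RMSD on each measure selection.

    Every frame is independently superposed onto the fixed reference (no
    progressive or average-structure fitting). Selections are resolved on the
    trajectory topology and on the reference and must pick equally many atoms
    on both.
    """
    fit_top = select(traj.topology, fit_selection)
    fit_ref = select(reference, fit_selection)
    if len(fit_top) != len(fit_ref):
        raise ValueError(
            f"fit selection resolves to {len(fit_top)} atoms on the trajectory "
            f"but {len(fit_ref)} on the reference"
        )
    if len(fit_top) < 3:
        raise ValueError(
            f"fit selection {fit_selection!r} resolves to {len(fit_top)} atoms; need >= 3"
        )
    measures: list[tuple[str, Selection, Selection]] = []
    for expr in measure_selections:
        m_top = select(traj.topology, expr)
        m_ref = select(reference, expr)
        if len(m_top) != len(m_ref):
            raise ValueError(
                f"measure selection {expr!r} resolves to {len(m_top)} trajectory "
                f"atoms but {len(m_ref)} reference atoms"
            )
        if len(m_top) == 0:
            raise ValueError(f"measure selection {expr!r} matches no atoms")
        measures.append((expr, m_top, m_ref))

    ref_fit_xyz = fit_ref.coordinates(reference)
    ref_measure_xyz = [m_ref.coordinates(reference) for _, _, m_ref in measures]
    per_measure = [np.empty(traj.n_frames) for _ in measures]
    for fi in range(traj.n_frames):
        frame = traj.frames[fi]
        transform, _ = kabsch_fit(fit_top.coordinates(frame), ref_fit_xyz)
        fitted = transform.apply(frame)
        for mi, (_, m_top, _) in enumerate(measures):
            per_measure[mi][fi] = rmsd(m_top.coordinates(fitted), ref_measure_xyz[mi])
    return [
        RmsdSeries(values=vals, fit_selection=fit_selection, measure_selection=expr)
        for vals, (expr, _, _) in zip(per_measure, measures)
    ]
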