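"""Alchemical free-energy estimators and the binding ΔΔG thermodynamic cycle.

The protocol: a base pair is transformed from one sequence into another
across a schedule of λ states (21 states = 19 intermediates between the two
end states); each adjacent pair of states contributes a free-energy step
estimated with the Bennett acceptance ratio (BAR) from forward and reverse
reduced-energy differences; the steps sum to ΔG for the transformation. The
binding free-energy change of the substitution is the thermodynamic cycle

    ΔΔG = ΔG(complex, 1→2) − ΔG(free DNA, 1→2),

positive when the substitution weakens binding. The protocol is replicated
(six independent repeats in the reference workflow) and the replicate SD is
the headline uncertainty.

Energies are reduced (units of kT) internally; :func:`kt_to_kcal_per_mol`
converts at a stated temperature. This module consumes sampled energy
tables — it never runs dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

__all__ = [
    "LambdaSchedule",
    "WorkSamples",
    "FreeEnergyResult",
    "BindingDDG",
    "BaseSubstitution",
    "make_lambda_schedule",
    "bar_delta_f",
    "zwanzig_delta_f",
    "stratified_delta_g",
    "binding_ddg",
    "apply_substitution",
    "kt_to_kcal_per_mol",
    "read_sample_table",
    "write_sample_table",
]

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/mol/K


def kt_to_kcal_per_mol(value_kt: float, temperature: float = 300.0) -> float:
    """Convert a reduced free energy (kT) to kcal/mol at ``temperature`` K."""
    return value_kt * KB_KCAL * temperature


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered alchemical coupling values from 0 to 1."""

    states: tuple[float, ...]

    def __post_init__(self) -> None:
        s = tuple(float(x) for x in self.states)
        if len(s) < 2:
            raise ValueError("a schedule needs at least the two end states")
        if s[0] != 0.0 or s[-1] != 1.0:
            raise ValueError("schedule must start at λ=0 and end at λ=1")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("λ states must be strictly increasing")
        object.__setattr__(self, "states", s)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_steps(self) -> int:
        """Number of adjacent-state transitions."""
        return len(self.states) - 1

    @property
    def n_intermediates(self) -> int:
        return len(self.states) - 2

    def reversed(self) -> "LambdaSchedule":
        return LambdaSchedule(tuple(1.0 - x for x in reversed(self.states)))


def make_lambda_schedule(n_states: int = 21) -> LambdaSchedule:
    """Uniformly spaced schedule; 21 states gives 19 intermediate states."""
    if n_states < 2:
        raise ValueError("need at least 2 λ states")
    return LambdaSchedule(tuple(np.linspace(0.0, 1.0, n_states)))


@dataclass
class WorkSamples:
    """Forward/reverse reduced-energy differences for one adjacent λ pair.

    ``forward``: u_{i+1}(x) − u_i(x) on samples drawn from state i.
    ``reverse``: u_i(x) − u_{i+1}(x) on samples drawn from state i+1.
    Both in kT.
    """

    forward: np.ndarray
    reverse: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.forward, dtype=float).ravel()
        r = np.asarray(self.reverse, dtype=float).ravel()
        if f.size < 1 or r.size < 1:
            raise ValueError("forward and reverse sample sets must be nonempty")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(r))):
            raise ValueError("work samples must be finite")
        self.forward = f
        self.reverse = r

    @property
    def n_forward(self) -> int:
        return self.forward.size

    @property
    def n_reverse(self) -> int:
        return self.reverse.size

    def swapped(self) -> "WorkSamples":
        return WorkSamples(forward=self.reverse.copy(), reverse=self.forward.copy())


@dataclass
class FreeEnergyResult:
    """Total ΔG (kT) with per-step decomposition and uncertainty."""

    delta_g: float
    uncertainty: float
    per_step: list[tuple[float, float]]  # (ΔG_i, uncertainty_i)
    estimator: str

    def __post_init__(self) -> None:
        total = sum(dg for dg, _ in self.per_step)
        if abs(total - self.delta_g) > 1e-9:
            raise ValueError("delta_g must equal the sum of per-step contributions")


@dataclass
class BindingDDG:
    """Thermodynamic-cycle ΔΔG with replicate statistics.

    ``replicate_values`` holds one ΔΔG per independent repeat; ``mean``/``sd``
    summarize them (sample SD, ddof=1, matching the n-replicate protocol).
    """

    dg_complex: float
    dg_dna: float
    ddg: float
    replicate_values: list[float]
    replicate_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.ddg - (self.dg_complex - self.dg_dna)) > 1e-9:
            raise ValueError("ddg must equal dg_complex - dg_dna")
        if not self.replicate_values:
            raise ValueError("at least one replicate is required")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_values))

    @property
    def sd(self) -> float:
        vals = np.asarray(self.replicate_values)
        return float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def zwanzig_delta_f(forward: np.ndarray) -> float:
    """One-sided exponential-averaging estimate: −ln⟨exp(−u_f)⟩.

    Log-sum-exp stabilized. Used here as an independent cross-check of BAR;
    it is biased at finite sample size and noisier when overlap is poor.
    """
    w = np.asarray(forward, dtype=float).ravel()
    if w.size < 1:
        raise ValueError("need at least one forward sample")
    return float(-(logsumexp(-w) - np.log(w.size)))


def bar_delta_f(
    forward: np.ndarray,
    reverse: np.ndarray,
    tolerance: float = 1e-12,
    bracket_width: float = 50.0,
) -> tuple[float, float]:
    """Bennett-acceptance-ratio ΔF (kT) with its asymptotic standard error.

    Solves the maximum-likelihood self-consistency condition

        Σ_fwd f(u_f − C) = Σ_rev f(u_r + C),   C = ΔF − ln(n_f/n_r),

    with f the Fermi function 1/(1+e^x), by bracketed root finding. The left
    side increases and the right side decreases in ΔF, so the root is unique.
    Failure to bracket within ±``bracket_width`` kT of the initial guess
    signals (near-)zero phase-space overlap between the two states — the
    remedy is a finer λ schedule, not a wider bracket.

    The uncertainty is the standard asymptotic variance of the BAR estimator
    evaluated at the solution.
    """
    ws = WorkSamples(forward=forward, reverse=reverse)
    uf, ur = ws.forward, ws.reverse
    log_ratio = np.log(ws.n_forward / ws.n_reverse)

    def imbalance(delta_f: float) -> float:
        c = delta_f - log_ratio
        # log Σ f(x) computed stably: f(x) = 1/(1+e^x) = sigmoid(-x)
        lhs = logsumexp(np.log(expit(-(uf - c))))
        rhs = logsumexp(np.log(expit(-(ur + c))))
        return lhs - rhs

    guess = zwanzig_delta_f(uf)
    lo, hi = guess - 1.0, guess + 1.0
    while imbalance(lo) > 0:
        lo -= 5.0
        if guess - lo > bracket_width:
            raise ValueError(
                "BAR self-consistency equation has no root within "
                f"±{bracket_width} kT: forward/reverse distributions do not "
                "overlap; use more λ states"
            )
    while imbalance(hi) < 0:
        hi += 5.0
        if hi - guess > bracket_width:
            raise ValueError(
                "BAR self-consistency equation has no root within "
                f"±{bracket_width} kT: forward/reverse distributions do not "
                "overlap; use more λ states"
            )
    delta_f = float(brentq(imbalance, lo, hi, xtol=tolerance))

    c = delta_f - log_ratio
    ff = expit(-(uf - c))
    fr = expit(-(ur + c))
    var = (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / ws.n_forward + (
        np.mean(fr**2) / np.mean(fr) ** 2 - 1.0
    ) / ws.n_reverse
    return delta_f, float(np.sqrt(max(var, 0.0)))


def stratified_delta_g(
    schedule: LambdaSchedule,
    per_step_samples: list[WorkSamples] | dict[int, WorkSamples],
    estimator: str = "bar",
) -> FreeEnergyResult:
    """Sum per-step ΔG estimates over every adjacent λ pair of the schedule.

    Uncertainty is the root-sum-square of per-step uncertainties (steps use
    independent samples). ``estimator`` is "bar" or "zwanzig".
    """
    if estimator not in ("bar", "zwanzig"):
        raise ValueError(f"unknown estimator {estimator!r}; use 'bar' or 'zwanzig'")
    if isinstance(per_step_samples, dict):
        samples = []
        for i in range(schedule.n_steps):
            if i not in per_step_samples:
                pair = (schedule.states[i], schedule.states[i + 1])
                raise ValueError(f"missing samples for λ pair {pair}")
            samples.append(per_step_samples[i])
    else:
        samples = list(per_step_samples)
        if len(samples) != schedule.n_steps:
            raise ValueError(
                f"schedule has {schedule.n_steps} adjacent pairs but "
                f"{len(samples)} sample sets were given"
            )
    per_step: list[tuple[float, float]] = []
    for ws in samples:
        if estimator == "bar":
            dg, err = bar_delta_f(ws.forward, ws.reverse)
        else:
            dg, err = zwanzig_delta_f(ws.forward), float("nan")
        per_step.append((dg, err))
    total = float(sum(dg for dg, _ in per_step))
    errs = np.array([e for _, e in per_step])
    unc = float(np.sqrt(np.nansum(errs**2)))
    return FreeEnergyResult(delta_g=total, uncertainty=unc, per_step=per_step, estimator=estimator)


def binding_ddg(
    replicates: list[tuple[FreeEnergyResult | float, FreeEnergyResult | float]],
    labels: list[str] | None = None,
) -> BindingDDG:
    """Thermodynamic-cycle ΔΔG = ΔG(complex) − ΔG(free DNA) over replicates.

    ``replicates`` holds (complex, dna) pairs, as results or raw kT totals.
    The first replicate supplies the headline ``dg_complex``/``dg_dna``;
    mean ± SD across replicates is the reported statistic. ``labels`` may
    mark which strand was altered in each repeat.
    """
    if not replicates:
        raise ValueError("at least one (complex, dna) replicate pair is required")

    def total(x) -> float:
        return x.delta_g if isinstance(x, FreeEnergyResult) else float(x)

    values = [total(c) - total(d) for c, d in replicates]
    if labels is None:
        labels = [f"rep{i + 1}" for i in range(len(values))]
    if len(labels) != len(values):
        raise ValueError("one label per replicate required")
    c0, d0 = replicates[0]
    return BindingDDG(
        dg_complex=total(c0),
        dg_dna=total(d0),
        ddg=total(c0) - total(d0),
        replicate_values=values,
        replicate_labels=list(labels),
    )


# ---------------------------------------------------------------------------
# Base-substitution bookkeeping
# ---------------------------------------------------------------------------

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class BaseSubstitution:
    """A single-position substitution of a double-stranded motif.

    Alchemical transformations stay within a chemical class (purine↔purine or
    pyrimidine↔pyrimidine); the Watson–Crick partner on the paired strand is
    transformed simultaneously so the duplex stays base-paired.
    """

    motif: str
    position: int  # 1-based
    from_base: str
    to_base: str

    def __post_init__(self) -> None:
        motif = self.motif.upper()
        object.__setattr__(self, "motif", motif)
        object.__setattr__(self, "from_base", self.from_base.upper())
        object.__setattr__(self, "to_base", self.to_base.upper())
        if not 1 <= self.position <= len(motif):
            raise ValueError(f"position {self.position} outside motif of length {len(motif)}")
        if motif[self.position - 1] != self.from_base:
            raise ValueError(
                f"motif has {motif[self.position - 1]} at position {self.position}, "
                f"not {self.from_base}"
            )


@dataclass(frozen=True)
class SubstitutionRecord:
    """The altered motif and the implied complementary-strand change."""

    altered_motif: str
    strand_change: str  # e.g. "C1->T1"
    paired_change: str  # e.g. "G->A at paired position"


def apply_substitution(sub: BaseSubstitution) -> SubstitutionRecord:
    """Apply a same-class base substitution and record the paired-strand change.

    Rejects purine↔pyrimidine requests: transforming across chemical classes
    is outside the alchemical transformation class this protocol models.
    """
    frm, to = sub.from_base, sub.to_base
    same_class = (frm in _PURINES and to in _PURINES) or (
        frm in _PYRIMIDINES and to in _PYRIMIDINES
    )
    if frm == to:
        raise ValueError("substitution must change the base")
    if not same_class:
        raise ValueError(
            f"{frm}->{to} crosses the purine/pyrimidine class boundary; only "
            "purine↔purine or pyrimidine↔pyrimidine transformations are supported"
        )
    motif = list(sub.motif)
    motif[sub.position - 1] = to
    return SubstitutionRecord(
        altered_motif="".join(motif),
        strand_change=f"{frm}{sub.position}->{to}{sub.position}",
        paired_change=(
            f"{_COMPLEMENT[frm]}->{_COMPLEMENT[to]} at the paired position of the "
            "complementary strand"
        ),
    )


# ---------------------------------------------------------------------------
# Per-step sample tables (tab-separated: step_index direction value_kT)
# ---------------------------------------------------------------------------

def write_sample_table(samples: list[WorkSamples], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("step_index\tdirection\tvalue_kT\n")
        for i, ws in enumerate(samples):
            for v in ws.forward:
                fh.write(f"{i}\tforward\t{v:.10g}\n")
            for v in ws.reverse:
                fh.write(f"{i}\treverse\t{v:.10g}\n")


def read_sample_table(path: str | Path) -> list[WorkSamples]:
    fwd: dict[int, list[float]] = {}
    rev: dict[int, list[float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["step_index", "direction", "value_kT"]:
            raise ValueError(f"{path}: unexpected sample-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            step_s, direction, value_s = line.rstrip("\n").split("\t")
            dest = fwd if direction == "forward" else rev if direction == "reverse" else None
            if dest is None:
                raise ValueError(f"{path}:{lineno}: unknown direction {direction!r}")
            dest.setdefault(int(step_s), []).append(float(value_s))
    steps = sorted(set(fwd) | set(rev))
    if steps != list(range(len(steps))):
        raise ValueError(f"{path}: step indices must be contiguous from 0")
    out = []
    for i in steps:
        if i not in fwd or i not in rev:
            raise ValueError(f"{path}: step {i} lacks forward or reverse samples")
        out.append(WorkSamples(forward=np.array(fwd[i]), reverse=np.array(rev[i])))
    return out
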