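"""Study summaries and fixed-effect inverse-variance pooling.

A trial comparing a treatment and a control arm on a continuous outcome is
summarised by its mean-difference estimate, an *effective* sample size
``n = (1/N_T + 1/N_C)^-1`` (so that Var(effect) = sigma^2 / n for a common
within-arm variance sigma^2), a pooled within-study variance estimate ``s2``
and its degrees of freedom.  Cumulative meta-analysis pools the first *i*
summaries with unnormalised inverse-variance weights ``w_j = n_j / s2_j``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "StudySummary",
    "CumulativeMeta",
    "effective_sample_size",
    "combine_fixed",
    "read_studies",
    "write_studies",
]

#: relative tolerance when checking arm sizes against a supplied n_eff
#: (published effective sizes are typically rounded to 2 d.p.)
_ARM_TOL = 1e-2


def effective_sample_size(n_treat: int, n_control: int) -> float:
    """Effective sample size ``(1/N_T + 1/N_C)^-1`` of a two-arm trial.

    For a balanced trial of total size ``N`` this equals ``N/4``.

    Parameters
    ----------
    n_treat, n_control
        Per-arm sample sizes, both at least 1.
    """
    if n_treat < 1 or n_control < 1:
        raise ValueError("arm sizes must be positive")
    return 1.0 / (1.0 / n_treat + 1.0 / n_control)


@dataclass(frozen=True)
class StudySummary:
    """One trial's summary: effect estimate, effective size, variance, d.f.

    ``effect`` may be NaN for a trial whose effect estimate is unknown but
    whose size/variance enter planning computations; such studies cannot be
    pooled.  ``arm_sizes``, when given, must be consistent with ``n_eff``.
    """

    effect: float
    n_eff: float
    s2: float
    df: int
    arm_sizes: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.n_eff > 0:
            raise ValueError("n_eff must be > 0")
        if not self.s2 > 0:
            raise ValueError("s2 must be > 0")
        if int(self.df) < 1:
            raise ValueError("df must be >= 1")
        if self.arm_sizes is not None:
            nt, nc = self.arm_sizes
            if nt < 1 or nc < 1:
                raise ValueError("arm sizes must be positive")
            implied = effective_sample_size(nt, nc)
            if abs(implied - self.n_eff) > _ARM_TOL * implied:
                raise ValueError(
                    f"n_eff={self.n_eff} inconsistent with arms {self.arm_sizes} "
                    f"(implied {implied:.4f})"
                )

    @classmethod
    def from_arms(
        cls,
        effect: float,
        n_treat: int,
        n_control: int,
        s2: float,
        df: int | None = None,
    ) -> "StudySummary":
        """Build a summary from per-arm sizes; default d.f. is ``N - 2``."""
        if df is None:
            df = n_treat + n_control - 2
        return cls(
            effect=effect,
            n_eff=effective_sample_size(n_treat, n_control),
            s2=s2,
            df=df,
            arm_sizes=(n_treat, n_control),
        )

    @property
    def variance(self) -> float:
        """Estimated variance of the effect estimate, ``s2 / n_eff``."""
        return self.s2 / self.n_eff

    @property
    def weight(self) -> float:
        """Unnormalised inverse-variance weight ``n_eff / s2``."""
        return self.n_eff / self.s2


@dataclass(frozen=True)
class CumulativeMeta:
    """Fixed-effect pooled result over a list of studies."""

    combined_effect: float
    weights: tuple[float, ...]
    total_weight: float
    variance: float
    normalized_weights: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.normalized_weights:
            object.__setattr__(
                self,
                "normalized_weights",
                tuple(w / self.total_weight for w in self.weights),
            )


def combine_fixed(studies: Sequence[StudySummary]) -> CumulativeMeta:
    """Pool studies with fixed-effect inverse-variance weights.

    Weights are ``w_j = n_eff_j / s2_j``; the combined effect is the
    weighted mean and its variance ``1 / sum(w_j)``.  A study with zero
    weight contributes nothing and is dropped.
    """
    studies = [s for s in studies if s.weight > 0.0]
    if not studies:
        raise ValueError("no studies with positive weight to combine")
    for s in studies:
        if math.isnan(s.effect):
            raise ValueError("cannot pool a study with unknown effect")
    weights = tuple(s.weight for s in studies)
    total = sum(weights)
    combined = sum(w * s.effect for w, s in zip(weights, studies)) / total
    return CumulativeMeta(
        combined_effect=combined,
        weights=weights,
        total_weight=total,
        variance=1.0 / total,
    )


def _row_to_summary(row: pd.Series) -> StudySummary:
    has_arms = pd.notna(row.get("n_treat")) and pd.notna(row.get("n_control"))
    has_neff = pd.notna(row.get("n_eff"))
    if has_arms == has_neff:
        raise ValueError(
            f"study {row.get('study_id')!r}: exactly one of arm sizes or n_eff required"
        )
    effect = float(row["effect"]) if pd.notna(row.get("effect")) else float("nan")
    if has_arms:
        df = int(row["df"]) if pd.notna(row.get("df")) else None
        return StudySummary.from_arms(
            effect, int(row["n_treat"]), int(row["n_control"]), float(row["s2"]), df
        )
    return StudySummary(
        effect=effect, n_eff=float(row["n_eff"]), s2=float(row["s2"]), df=int(row["df"])
    )


def read_studies(path, sep: str | None = None) -> list[StudySummary]:
    """Read study summaries from a delimited table.

    Expected header columns: ``study_id, effect, n_treat, n_control`` (the
    arm pair optional), ``n_eff`` (optional), ``s2, df``.  Each row must
    carry exactly one of {arm pair, n_eff}.  The delimiter is sniffed when
    ``sep`` is None.
    """
    table = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return [_row_to_summary(row) for _, row in table.iterrows()]


def write_studies(studies: Iterable[StudySummary], path, sep: str = ",") -> None:
    """Write summaries in the format :func:`read_studies` accepts."""
    rows = []
    for i, s in enumerate(studies, start=1):
        rows.append(
            {
                "study_id": i,
                "effect": s.effect,
                "n_treat": s.arm_sizes[0] if s.arm_sizes else None,
                "n_control": s.arm_sizes[1] if s.arm_sizes else None,
                "n_eff": None if s.arm_sizes else s.n_eff,
                "s2": s.s2,
                "df": s.df,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
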